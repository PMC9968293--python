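"""End-to-end orchestration: simulate -> endpoints -> ddm -> kernels.

Every stage persists its intermediates (CSV/JSON) under the output
directory so each can be rerun and inspected independently; the run report
collects per-stage status, the key statistics, and a planted-vs-recovered
comparison against the generator's ground truth.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .cohort import CohortConfig, Dataset, read_dataset, simulate_cohort, write_dataset
from .ddm import (
    MCMCConfig,
    MODEL_SPECS,
    compare_models,
    fit_hierarchical,
    fit_subject_mle,
)
from .endpoints import (
    apply_exclusions,
    compute_endpoints,
    paired_sign_test,
    spearman_robust,
    wilcoxon_signed_rank,
    within_subject_ci,
)
from .kernels import TIMESPANS_MS, compare_kernel_stats, compute_kernel, kernel_stats

__all__ = ["PipelineConfig", "ConfigError", "run_pipeline", "validate_config"]

log = logging.getLogger("coreg")


class ConfigError(ValueError):
    """Configuration contains unknown or invalid keys."""


@dataclass
class PipelineConfig:
    """Full pipeline configuration; every random stage is explicitly seeded."""

    cohort: CohortConfig = field(default_factory=CohortConfig)
    seed: int = 0
    paired_test: str = "sign"          # 'sign' or 'signed_rank'
    ddm_mode: str = "mle"              # 'mle' or 'hierarchical'
    ddm_specs: tuple = tuple(MODEL_SPECS)
    ddm_max_subjects: int | None = None  # subsample for the hierarchical mode
    mcmc: MCMCConfig = field(default_factory=MCMCConfig)
    timespans: tuple = TIMESPANS_MS
    stages: tuple = ("simulate", "endpoints", "ddm", "kernels")

    def __post_init__(self) -> None:
        if self.paired_test not in ("sign", "signed_rank"):
            raise ConfigError(f"paired_test must be 'sign' or 'signed_rank', "
                              f"got {self.paired_test!r}")
        if self.ddm_mode not in ("mle", "hierarchical"):
            raise ConfigError(f"ddm_mode must be 'mle' or 'hierarchical', "
                              f"got {self.ddm_mode!r}")
        unknown = set(self.ddm_specs) - set(MODEL_SPECS)
        if unknown:
            raise ConfigError(f"unknown ddm specs: {sorted(unknown)}")

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


def validate_config(raw: dict) -> PipelineConfig:
    """Build a PipelineConfig from a plain dict, rejecting unknown keys."""
    raw = dict(raw)
    known = {f.name for f in dataclasses.fields(PipelineConfig)}
    unknown = set(raw) - known
    if unknown:
        raise ConfigError(f"unknown configuration keys: {sorted(unknown)}")
    if "cohort" in raw:
        cohort_known = {f.name for f in dataclasses.fields(CohortConfig)}
        bad = set(raw["cohort"]) - cohort_known
        if bad:
            raise ConfigError(f"unknown cohort keys: {sorted(bad)}")
        raw["cohort"] = CohortConfig(**raw["cohort"])
    if "mcmc" in raw:
        mcmc_known = {f.name for f in dataclasses.fields(MCMCConfig)}
        bad = set(raw["mcmc"]) - mcmc_known
        if bad:
            raise ConfigError(f"unknown mcmc keys: {sorted(bad)}")
        raw["mcmc"] = MCMCConfig(**raw["mcmc"])
    for key in ("ddm_specs", "timespans", "stages"):
        if key in raw:
            raw[key] = tuple(raw[key])
    return PipelineConfig(**raw)


def _paired(endpoint_table: pd.DataFrame, session: str, measure: str, how: str):
    wide = endpoint_table[endpoint_table["session"] == session].pivot(
        index="participant_id", columns="condition", values=measure
    ).dropna()
    if wide.shape[0] < 6 or {"fast", "slow"} - set(wide.columns):
        return None, None
    test = paired_sign_test if how == "sign" else wilcoxon_signed_rank
    return test(wide["fast"].to_numpy(), wide["slow"].to_numpy()), wide


def _endpoint_stage(dataset: Dataset, config: PipelineConfig, out: Path) -> dict:
    filt = apply_exclusions(dataset)
    table = compute_endpoints(filt)
    table.to_csv(out / "endpoints.csv", index=False)
    (out / "exclusions.json").write_text(json.dumps({
        "counts": filt.report.counts,
        "retained_fraction": filt.report.retained_fraction,
    }, indent=2))

    results = {"exclusions": filt.report.counts, "tests": {}}
    cis = {}
    deltas = {}
    for session in ("decision", "movement"):
        for measure in ("decision_duration", "success_probability",
                        "tap_duration", "movement_accuracy"):
            res, wide = _paired(table, session, measure, config.paired_test)
            if res is None:
                continue
            results["tests"][f"{session}/{measure}"] = {
                "statistic_name": res.statistic_name,
                "statistic": res.statistic, "p": res.p, "n": res.n,
                "median_difference_fast_minus_slow": res.median_difference,
                "ci": [res.ci_low, res.ci_high],
            }
            if measure in ("decision_duration", "tap_duration"):
                deltas[(session, measure)] = wide["fast"] - wide["slow"]
                cis[f"{session}/{measure}"] = within_subject_ci(wide).to_dict()
    # cross-participant coregulation: instructed change vs coregulated change
    for session, instructed, induced in (
        ("decision", "decision_duration", "tap_duration"),
        ("movement", "tap_duration", "decision_duration"),
    ):
        a = deltas.get((session, instructed))
        b = deltas.get((session, induced))
        if a is None or b is None:
            continue
        common = a.index.intersection(b.index)
        if len(common) >= 10:
            rob = spearman_robust(a.loc[common].to_numpy(), b.loc[common].to_numpy(),
                                  random_state=config.seed)
            results["tests"][f"{session}/coregulation_spearman"] = {
                "rho_full": rob.rho_full, "p_full": rob.p_full,
                "rho_clean": rob.rho_clean, "p_clean": rob.p_clean,
                "n_outliers": int(rob.outlier_mask.sum()), "n": rob.n,
            }
    (out / "tests.json").write_text(json.dumps(results["tests"], indent=2))
    (out / "within_subject_ci.json").write_text(json.dumps(cis, indent=2, default=str))
    return results


def _ddm_trials(dataset: Dataset, session: str) -> dict[str, pd.DataFrame]:
    """Per-subject rt/response/condition frames for one session (rt in s)."""
    tr = dataset.trials
    sub = tr[(tr["session"] == session) & tr["choice"].isin(["left", "right"])
             & tr["rt"].notna()].copy()
    sub["rt_s"] = sub["rt"] / 1000.0
    out = {}
    for pid, g in sub.groupby("participant_id"):
        out[pid] = pd.DataFrame({
            "rt": g["rt_s"].to_numpy(),
            "response": g["decision_correct"].astype(int).to_numpy(),
            "condition": g["condition"].to_numpy(),
        })
    return out


def _ddm_stage(dataset: Dataset, config: PipelineConfig, out: Path) -> dict:
    rng = np.random.default_rng(config.seed + 101)
    summary = {}
    for session in ("decision", "movement"):
        per_subject = _ddm_trials(dataset, session)
        if config.ddm_max_subjects:
            keep = sorted(per_subject)[: config.ddm_max_subjects]
            per_subject = {k: per_subject[k] for k in keep}
        if config.ddm_mode == "hierarchical":
            fits = {}
            for spec in config.ddm_specs:
                fits[spec] = fit_hierarchical(per_subject, spec, config.mcmc)
            table = compare_models(fits)
            best = fits[table["spec"].iloc[0]]
            summary[session] = {
                "mode": "hierarchical",
                "comparison": table.to_dict(orient="records"),
                "best_spec": best.spec,
                "group_means": {k: float(np.mean(v))
                                for k, v in best.group_mean_samples.items()},
                "effect_probabilities": {
                    k: {"p": v, "label": best.effect_label(k)}
                    for k, v in best.effect_probabilities.items()
                },
                "gelman_rubin_max": float(max(best.gelman_rubin.values())),
            }
        else:
            total = {spec: {"loglik": 0.0, "k": 0, "n": 0} for spec in config.ddm_specs}
            per_fit = {spec: [] for spec in config.ddm_specs}
            for pid, trials in per_subject.items():
                counts = trials.groupby("condition").size()
                if counts.min() < 50 or len(counts) < 2:
                    log.warning("ddm: %s skipped (too few trials per condition)", pid)
                    continue
                for spec in config.ddm_specs:
                    fit = fit_subject_mle(trials, spec, rng=rng)
                    total[spec]["loglik"] += fit.loglik
                    total[spec]["k"] += 3 + len(MODEL_SPECS[spec])
                    total[spec]["n"] += fit.n_trials
                    per_fit[spec].append((pid, fit))
            comp = []
            for spec, acc in total.items():
                if acc["n"] == 0:
                    continue
                comp.append({
                    "spec": spec, "loglik": acc["loglik"],
                    "aic": 2 * acc["k"] - 2 * acc["loglik"],
                    "bic": acc["k"] * np.log(acc["n"]) - 2 * acc["loglik"],
                })
            comp.sort(key=lambda r: r["bic"])
            best_spec = comp[0]["spec"] if comp else None
            cond_effects = {}
            if best_spec:
                for pname in MODEL_SPECS[best_spec]:
                    diffs = [
                        getattr(f.estimates["fast"], pname) - getattr(f.estimates["slow"], pname)
                        for _, f in per_fit[best_spec]
                    ]
                    if len(diffs) >= 6:
                        res = paired_sign_test(np.asarray(diffs), np.zeros(len(diffs)))
                        cond_effects[f"d{pname}"] = {
                            "mean": float(np.mean(diffs)), "S": res.statistic, "p": res.p,
                        }
            summary[session] = {
                "mode": "mle", "comparison": comp, "best_spec": best_spec,
                "condition_effects": cond_effects,
            }
    (out / "ddm_fit.json").write_text(json.dumps(summary, indent=2, default=float))
    return summary


def _kernel_stage(dataset: Dataset, config: PipelineConfig, out: Path) -> dict:
    filt = apply_exclusions(dataset)
    rows, stat_rows = [], []
    for (session, cond, pid), sub in filt.valid.groupby(
        ["session", "condition", "participant_id"]
    ):
        for ts in config.timespans:
            try:
                k = compute_kernel(sub, ts)
                st = kernel_stats(k, float(sub["rt"].median()))
            except ValueError as exc:
                log.warning("kernel %s/%s/%s ts=%s skipped: %s",
                            session, cond, pid, ts, exc)
                continue
            frame = k.as_frame()
            frame["session"], frame["condition"], frame["participant_id"] = session, cond, pid
            rows.append(frame)
            stat_rows.append({
                "session": session, "condition": cond, "participant_id": pid,
                "timespan": ts, "slope_per_s": st.slope_per_s,
                "peak_latency_ms": st.peak_latency_ms, "median_rt_ms": st.median_rt_ms,
            })
    kernels = pd.concat(rows, ignore_index=True)
    kstats = pd.DataFrame(stat_rows)
    kernels.to_csv(out / "kernels.csv", index=False)
    kstats.to_csv(out / "kernel_stats.csv", index=False)

    tests = {}
    for session in ("decision", "movement"):
        for measure in ("slope_per_s", "peak_latency_ms"):
            sub = kstats[kstats["session"] == session]
            piv = {
                cond: sub[sub["condition"] == cond].pivot(
                    index="participant_id", columns="timespan", values=measure
                )
                for cond in ("fast", "slow")
            }
            try:
                table = compare_kernel_stats(piv["fast"], piv["slow"], measure)
            except ValueError as exc:
                log.warning("kernel comparison %s/%s skipped: %s", session, measure, exc)
                continue
            tests[f"{session}/{measure}"] = table.to_dict(orient="records")
    (out / "kernel_tests.json").write_text(json.dumps(tests, indent=2, default=float))
    return tests


def _recovery_table(dataset: Dataset, report: dict) -> list[dict]:
    """Planted-vs-recovered comparison from the generator's ground truth."""
    truth = dataset.meta.get("ground_truth", {})
    if not truth:
        return []
    rows = []
    tests = report.get("endpoints", {}).get("tests", {})
    for session in ("decision", "movement"):
        taps = [
            t[session]["tap_interval_mean"]["fast"] - t[session]["tap_interval_mean"]["slow"]
            for t in truth.values()
        ]
        key = f"{session}/tap_duration"
        if key in tests:
            rows.append({
                "session": session, "quantity": "tap_duration_diff_ms",
                "planted_mean": float(np.mean(taps)),
                "recovered_median": tests[key]["median_difference_fast_minus_slow"],
                "p": tests[key]["p"],
            })
        mds = [
            t[session]["motor_delay_mean"]["fast"] - t[session]["motor_delay_mean"]["slow"]
            for t in truth.values()
        ]
        key = f"{session}/decision_duration"
        if key in tests:
            rows.append({
                "session": session, "quantity": "decision_duration_diff_ms",
                "planted_motor_delay_diff_ms": float(np.mean(mds)),
                "recovered_median": tests[key]["median_difference_fast_minus_slow"],
                "p": tests[key]["p"],
            })
    return rows


def run_pipeline(config: PipelineConfig, out_dir: str | Path,
                 dataset: Dataset | None = None) -> dict:
    """Execute the configured stages and write the machine-readable report.

    Returns the report dict; ``report['status']`` is 'ok' when every stage
    completed, otherwise 'partial' with per-stage diagnostics.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=logging.INFO, format="%(levelname)s %(name)s: %(message)s")
    report: dict = {
        "version": __version__,
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "stages": {},
        "status": "ok",
    }
    (out / "config.json").write_text(json.dumps(asdict(config), indent=2, default=str))

    for stage in config.stages:
        t0 = time.time()
        try:
            if stage == "simulate":
                cohort_cfg = dataclasses.replace(config.cohort, seed=config.seed)
                dataset = simulate_cohort(cohort_cfg)
                write_dataset(dataset, out / "data")
                report["stages"][stage] = {"status": "ok",
                                           "n_trials": int(len(dataset.trials))}
            else:
                if dataset is None:
                    dataset = read_dataset(out / "data")
                if stage == "endpoints":
                    report["endpoints"] = _endpoint_stage(dataset, config, out)
                elif stage == "ddm":
                    report["ddm"] = _ddm_stage(dataset, config, out)
                elif stage == "kernels":
                    report["kernels"] = _kernel_stage(dataset, config, out)
                else:
                    raise ConfigError(f"unknown stage {stage!r}")
                report["stages"][stage] = {"status": "ok"}
        except Exception as exc:  # noqa: BLE001 - stage isolation by design
            log.exception("stage %s failed", stage)
            report["stages"][stage] = {"status": "failed", "error": repr(exc)}
            report["status"] = "partial"
        report["stages"][stage]["seconds"] = round(time.time() - t0, 2)

    if dataset is not None:
        report["recovery"] = _recovery_table(dataset, report)
    (out / "report.json").write_text(json.dumps(report, indent=2, default=float))
    summary = [f"coreg {__version__} run (config {report['config_hash']})"]
    for stage, info in report["stages"].items():
        summary.append(f"  {stage}: {info['status']} ({info['seconds']} s)")
    (out / "summary.txt").write_text("\n".join(summary) + "\n")
    return report
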