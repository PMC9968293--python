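"""Behavioral endpoint measures, exclusion rules and robust statistics.

Four endpoint measures summarise each participant x session x condition
cell: *decision duration* (mean reaction time minus the mean simple
reaction time of the matching SRT block), *success probability* (objective
probability that the chosen banana wins, evaluated at the response frame),
*tap duration* (mean inter-tap interval) and *movement accuracy* (fraction
of movement-correct trials).

Paired condition contrasts use the exact sign test or the Wilcoxon
signed-rank test; across-participant monotonic relationships use Spearman
correlations with a fast-MCD robustness pass; condition means carry
within-subject (Cousineau-Morey) confidence intervals; families of tests
are Holm-corrected.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.covariance import MinCovDet

from .cohort import Dataset
from .task import TaskDesign, _success_table, rt_to_frame, str_to_steps

__all__ = [
    "ExclusionReport",
    "FilteredData",
    "PairedTestResult",
    "RobustCorrelationResult",
    "apply_exclusions",
    "compute_endpoints",
    "trial_success_probability",
    "paired_sign_test",
    "wilcoxon_signed_rank",
    "spearman_robust",
    "within_subject_ci",
    "holm_adjust",
]

MIN_DECISION_DURATION_MS = 150.0
MIN_SRT_MS = 50.0
MIN_TRIALS_PER_CELL = 5


@dataclass
class ExclusionReport:
    """Counts of removed trials per exclusion rule."""

    counts: dict = field(default_factory=dict)
    retained_fraction: dict = field(default_factory=dict)

    @property
    def total_excluded(self) -> int:
        return int(sum(self.counts.values()))


@dataclass
class FilteredData:
    """Per-measure trial frames after exclusion rules.

    ``valid`` holds every main-task trial that survives the generic rules;
    ``for_decision`` additionally restricts to movement-correct trials
    (decision duration, success probability) and ``for_movement`` to
    decision-correct trials (movement accuracy).
    """

    valid: pd.DataFrame
    for_decision: pd.DataFrame
    for_movement: pd.DataFrame
    srt: pd.DataFrame
    srt_means: pd.Series  # indexed by (participant_id, session, condition)
    report: ExclusionReport


def _matched_srt_mean(srt_means: pd.Series, pid: str, session: str, condition: str) -> float:
    """Mean SRT of the matching block; the decision session has one
    snake-free SRT block shared by both conditions."""
    try:
        return float(srt_means.loc[(pid, session, condition)])
    except KeyError:
        return float(srt_means.loc[(pid, session, "none")])


def apply_exclusions(dataset: Dataset) -> FilteredData:
    """Apply the trial exclusion rules and split trials per measure.

    Removed from the main task: no-response trials, pre-decision-phase
    (premature) presses, trials whose frame rate deviated from 60 Hz, and
    anticipations — trials whose decision duration (reaction time minus the
    participant's mean SRT in the matching condition) is below 150 ms.
    SRT trials are removed when flagged premature or faster than 50 ms.
    """
    trials, srt = dataset.trials, dataset.srt

    srt_premature = srt["premature"].astype(bool) | (srt["rt"] < MIN_SRT_MS)
    srt_valid = srt[~srt_premature].copy()
    srt_means = srt_valid.groupby(["participant_id", "session", "condition"])["rt"].mean()

    counted = srt_valid.groupby("participant_id").size()
    dropped_participants = set(trials["participant_id"].unique()) - set(counted.index)
    if dropped_participants:
        warnings.warn(
            f"participants without valid SRT trials dropped: {sorted(dropped_participants)}"
        )
        trials = trials[~trials["participant_id"].isin(dropped_participants)]

    no_response = trials["choice"].eq("none") | trials["rt"].isna()
    premature = trials["premature_press"].astype(bool)
    frame_rate = ~trials["frame_rate_ok"].astype(bool)

    matched = np.array([
        _matched_srt_mean(srt_means, p, s, c)
        for p, s, c in zip(trials["participant_id"], trials["session"], trials["condition"])
    ])
    decision_duration = trials["rt"].to_numpy() - matched
    anticipation = (~no_response) & (~premature) & (decision_duration < MIN_DECISION_DURATION_MS)

    excluded = no_response | premature | frame_rate | anticipation
    valid = trials[~excluded].copy()
    valid["decision_duration"] = decision_duration[~excluded.to_numpy()]

    report = ExclusionReport(
        counts={
            "no_response": int(no_response.sum()),
            "premature_press": int((premature & ~no_response).sum()),
            "frame_rate": int((frame_rate & ~no_response & ~premature).sum()),
            "anticipation": int((anticipation & ~frame_rate).sum()),
            "srt_anticipation": int(srt_premature.sum()),
        },
        retained_fraction={
            "main": float(len(valid) / len(trials)) if len(trials) else 0.0,
            "decision_measures": float(
                (valid["movement_correct"].astype(bool)).sum() / len(trials)
            ) if len(trials) else 0.0,
            "movement_accuracy": float(
                (valid["decision_correct"].astype(bool)).sum() / len(trials)
            ) if len(trials) else 0.0,
            "srt": float(len(srt_valid) / len(srt)) if len(srt) else 0.0,
        },
    )
    return FilteredData(
        valid=valid,
        for_decision=valid[valid["movement_correct"].astype(bool)].copy(),
        for_movement=valid[valid["decision_correct"].astype(bool)].copy(),
        srt=srt_valid,
        srt_means=srt_means,
        report=report,
    )


def trial_success_probability(
    steps, rt_ms: float, choice: str, design: TaskDesign | None = None
) -> float:
    """Objective probability that the chosen banana wins, given the
    evidence lead at the frame containing the key press."""
    design = design or TaskDesign()
    if isinstance(steps, str):
        steps = str_to_steps(steps)
    frame = rt_to_frame(rt_ms, design)
    lead = int(np.cumsum(steps)[frame - 1])
    signed = lead if choice == "right" else -lead
    table = _success_table(design.n_frames)
    return float(table[signed + design.n_frames, design.n_frames - frame])


def compute_endpoints(filtered: FilteredData, design: TaskDesign | None = None) -> pd.DataFrame:
    """Endpoint table: one row per participant x session x condition.

    Cells with fewer than five usable trials for a measure are set missing
    with a warning.
    """
    design = design or TaskDesign()
    rows = []
    cells = filtered.valid.groupby(["participant_id", "session", "condition"]).groups.keys()
    for pid, session, condition in cells:
        row = {"participant_id": pid, "session": session, "condition": condition}

        dec = filtered.for_decision.query(
            "participant_id == @pid and session == @session and condition == @condition"
        )
        row["n_decision"] = len(dec)
        if len(dec) >= MIN_TRIALS_PER_CELL:
            srt_mean = _matched_srt_mean(filtered.srt_means, pid, session, condition)
            row["decision_duration"] = float(dec["rt"].mean() - srt_mean)
            row["success_probability"] = float(np.mean([
                trial_success_probability(s, rt, c, design)
                for s, rt, c in zip(dec["steps"], dec["rt"], dec["choice"])
            ]))
        else:
            warnings.warn(f"cell {(pid, session, condition)}: <{MIN_TRIALS_PER_CELL} "
                          "decision-measure trials, set missing")
            row["decision_duration"] = np.nan
            row["success_probability"] = np.nan

        tap_cols = ["tap1", "tap2", "tap3", "tap4"]
        valid_cell = filtered.valid.query(
            "participant_id == @pid and session == @session and condition == @condition"
        )
        taps = valid_cell[tap_cols].dropna()
        row["n_tap"] = len(taps)
        row["tap_duration"] = (
            float(taps.to_numpy().mean()) if len(taps) >= MIN_TRIALS_PER_CELL else np.nan
        )

        mov = filtered.for_movement.query(
            "participant_id == @pid and session == @session and condition == @condition"
        )
        row["n_movement"] = len(mov)
        row["movement_accuracy"] = (
            float(mov["movement_correct"].mean()) if len(mov) >= MIN_TRIALS_PER_CELL else np.nan
        )
        rows.append(row)
    return pd.DataFrame(rows)


@dataclass
class PairedTestResult:
    statistic_name: str
    statistic: float
    p: float
    n: int
    median_difference: float
    ci_low: float
    ci_high: float
    all_zero: bool = False

    def __post_init__(self) -> None:
        if not (0.0 <= self.p <= 1.0):
            raise ValueError("p must lie in [0, 1]")


def _median_difference_ci(diffs: np.ndarray, level: float = 0.95) -> tuple[float, float, float]:
    """Distribution-free CI for the median difference from order statistics."""
    d = np.sort(diffs)
    n = len(d)
    k = int(stats.binom.ppf((1 - level) / 2, n, 0.5))
    k = max(k, 0)
    hi = min(n - 1 - k, n - 1)
    return float(np.median(d)), float(d[k]), float(d[hi])


def paired_sign_test(x, y) -> PairedTestResult:
    """Exact sign test on paired values.

    The statistic S is the number of positive differences (x - y) after
    dropping zeros; the p-value is the exact two-sided binomial
    probability.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if len(x) != len(y):
        raise ValueError("paired inputs must have equal length")
    diffs = x - y
    nonzero = diffs[diffs != 0]
    med, lo, hi = _median_difference_ci(diffs) if len(diffs) else (0.0, 0.0, 0.0)
    if len(nonzero) == 0:
        return PairedTestResult("S_sign", 0.0, 1.0, 0, med, lo, hi, all_zero=True)
    s = int((nonzero > 0).sum())
    p = float(stats.binomtest(s, len(nonzero), 0.5).pvalue)
    return PairedTestResult("S_sign", float(s), p, len(nonzero), med, lo, hi)


def wilcoxon_signed_rank(x, y) -> PairedTestResult:
    """Wilcoxon signed-rank test (mid-ranks for ties, zeros dropped)."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    diffs = x - y
    nonzero = diffs[diffs != 0]
    med, lo, hi = _median_difference_ci(diffs) if len(diffs) else (0.0, 0.0, 0.0)
    if len(nonzero) == 0:
        return PairedTestResult("V_signed_rank", 0.0, 1.0, 0, med, lo, hi, all_zero=True)
    res = stats.wilcoxon(nonzero, alternative="two-sided", zero_method="wilcox")
    return PairedTestResult(
        "V_signed_rank", float(res.statistic), float(res.pvalue), len(nonzero), med, lo, hi
    )


@dataclass
class RobustCorrelationResult:
    rho_full: float
    t_full: float
    p_full: float
    n: int
    outlier_mask: np.ndarray
    rho_clean: float
    t_clean: float
    p_clean: float
    ci_full: tuple
    ci_clean: tuple


def _spearman_with_t(x, y) -> tuple[float, float, float]:
    rho = float(stats.spearmanr(x, y).statistic)
    n = len(x)
    if abs(rho) >= 1.0:
        return rho, np.inf * np.sign(rho), 0.0
    t = rho * np.sqrt((n - 2) / (1.0 - rho ** 2))
    p = 2 * stats.t.sf(abs(t), n - 2)
    return rho, float(t), float(p)


def _fisher_ci(rho: float, n: int, level: float = 0.95) -> tuple[float, float]:
    if abs(rho) >= 1.0 or n <= 3:
        return (rho, rho)
    z = np.arctanh(rho)
    half = stats.norm.ppf(0.5 + level / 2) / np.sqrt(n - 3)
    return (float(np.tanh(z - half)), float(np.tanh(z + half)))


def spearman_robust(x, y, random_state: int = 0) -> RobustCorrelationResult:
    """Spearman correlation plus a fast-MCD outlier-robustness pass.

    Bivariate outliers are points whose robust (reweighted fast-MCD)
    squared Mahalanobis distance exceeds the chi-square(2) 97.5% cutoff;
    the correlation is re-estimated on the clean subset.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if len(x) < 10:
        raise ValueError("need at least 10 points")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation undefined for constant input")
    rho_f, t_f, p_f = _spearman_with_t(x, y)

    mcd = MinCovDet(random_state=random_state).fit(np.column_stack([x, y]))
    cutoff = stats.chi2.ppf(0.975, df=2)
    mask = mcd.dist_ > cutoff
    xc, yc = x[~mask], y[~mask]
    if np.ptp(xc) == 0 or np.ptp(yc) == 0 or len(xc) < 4:
        rho_c, t_c, p_c = np.nan, np.nan, np.nan
    else:
        rho_c, t_c, p_c = _spearman_with_t(xc, yc)
    return RobustCorrelationResult(
        rho_full=rho_f, t_full=t_f, p_full=p_f, n=len(x), outlier_mask=mask,
        rho_clean=rho_c, t_clean=t_c, p_clean=p_c,
        ci_full=_fisher_ci(rho_f, len(x)),
        ci_clean=_fisher_ci(rho_c, int((~mask).sum())) if np.isfinite(rho_c) else (np.nan, np.nan),
    )


def within_subject_ci(values: pd.DataFrame, level: float = 0.95) -> pd.DataFrame:
    """Condition means with within-subject confidence intervals.

    ``values`` is a participants x conditions table.  Each participant's
    scores are centred by replacing their own mean with the grand mean
    (removing between-subject variance); the t-based CI of each condition
    mean on the centred data is widened by the Morey factor
    sqrt(C / (C - 1)).  Participants with missing cells are dropped.
    """
    complete = values.dropna(axis=0)
    if complete.shape[0] < values.shape[0]:
        warnings.warn(f"{values.shape[0] - complete.shape[0]} participants with "
                      "missing cells dropped from within-subject CI")
    n, n_cond = complete.shape
    if n < 2 or n_cond < 2:
        raise ValueError("need >= 2 participants and >= 2 conditions")
    centred = complete.sub(complete.mean(axis=1), axis=0) + complete.to_numpy().mean()
    morey = np.sqrt(n_cond / (n_cond - 1))
    tcrit = stats.t.ppf(0.5 + level / 2, n - 1)
    half = centred.std(axis=0, ddof=1) / np.sqrt(n) * morey * tcrit
    return pd.DataFrame({
        "mean": complete.mean(axis=0),
        "ci_half_width": half,
        "n": n,
    })


def holm_adjust(pvals) -> np.ndarray:
    """Holm step-down adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(pvals, float)
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = len(p)
    order = np.argsort(p)
    adjusted = np.empty(m)
    running = 0.0
    for rank, idx in enumerate(order):
        running = max(running, (m - rank) * p[idx])
        adjusted[idx] = min(running, 1.0)
    return adjusted
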