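"""Diffusion model: density, simulator, fitting, comparison, effects."""

import numpy as np
import pandas as pd
import pytest
from scipy.integrate import quad

from coreg.ddm import (
    DDMParams,
    HierarchicalFit,
    MCMCConfig,
    MODEL_SPECS,
    absorption_probability_upper,
    compare_models,
    effect_probability,
    fit_hierarchical,
    fit_subject_mle,
    mean_decision_time,
    posterior_predictive_check,
    simulate_ddm,
    wfpt_density,
)

GRID = [
    DDMParams(a=3.17, v=0.97, t0=0.73),   # slow-decision group means
    DDMParams(a=2.0, v=2.0, t0=0.3),
    DDMParams(a=1.2, v=-0.5, t0=0.2),
]


def test_density_zero_before_nondecision_time():
    p = GRID[0]
    assert wfpt_density(p.t0 - 0.01, p, "upper") == 0.0
    assert wfpt_density(p.t0, p, "lower") == 0.0


@pytest.mark.parametrize("params", GRID)
def test_density_normalises_over_both_boundaries(params):
    total = sum(
        quad(lambda t: wfpt_density(t, params, b), params.t0, 60.0, limit=300)[0]
        for b in ("upper", "lower")
    )
    assert total == pytest.approx(1.0, abs=1e-6)


def test_density_matches_simulation_histogram(rng):
    params = DDMParams(a=2.0, v=1.0, t0=0.2)
    sim = simulate_ddm(params, 20000, rng, dt=2e-4)
    up = sim[sim.response == 1]["rt"].to_numpy()
    # compare simulated upper-boundary CDF with the integrated density
    for q in (0.6, 1.0, 1.6):
        model, _ = quad(lambda t: wfpt_density(t, params, "upper"), params.t0, q,
                        limit=200)
        emp = (up <= q).sum() / len(sim)
        se = np.sqrt(model * (1 - model) / len(sim))
        assert abs(emp - model) < 4 * se + 0.004


def test_simulator_matches_closed_forms(rng):
    params = DDMParams(a=2.5, v=1.2, t0=0.0)
    n = 20000
    sim = simulate_ddm(params, n, rng, dt=1e-4)
    p_up = absorption_probability_upper(params)
    se_p = np.sqrt(p_up * (1 - p_up) / n)
    assert abs(sim.response.mean() - p_up) < 4 * se_p
    mdt = mean_decision_time(params)
    se_t = sim.rt.std() / np.sqrt(n)
    assert abs(sim.rt.mean() - mdt) < 4 * se_t


def test_zero_drift_symmetry(rng):
    sim = simulate_ddm(DDMParams(a=2.0, v=0.0, t0=0.0), 8000, rng, dt=2e-4)
    assert abs(sim.response.mean() - 0.5) < 4 * 0.5 / np.sqrt(8000)


def test_invalid_params_rejected():
    with pytest.raises(ValueError):
        DDMParams(a=-1.0, v=0.0, t0=0.1)
    with pytest.raises(ValueError):
        DDMParams(a=1.0, v=0.0, t0=-0.1)
    with pytest.raises(ValueError):
        wfpt_density(1.0, GRID[0], "sideways")


def test_mle_recovers_generating_parameters(rng):
    truth = DDMParams(a=3.17, v=0.97, t0=0.73)
    sim = simulate_ddm(truth, 400, rng, dt=2e-4, include_outliers=True,
                       outlier_max_rt=4.0)
    sim["condition"] = "slow"
    fit = fit_subject_mle(sim, "fixed", rng=rng)
    est = fit.estimates["slow"]
    assert est.a == pytest.approx(truth.a, rel=0.15)
    assert est.v == pytest.approx(truth.v, rel=0.20)
    assert est.t0 == pytest.approx(truth.t0, rel=0.10)


def test_nested_model_likelihood_ordering(rng):
    slow = DDMParams(a=3.0, v=1.2, t0=0.6)
    fast = DDMParams(a=2.2, v=0.6, t0=0.4)  # drift genuinely differs
    frames = []
    for cond, p in (("slow", slow), ("fast", fast)):
        sim = simulate_ddm(p, 300, rng, dt=2e-4)
        sim["condition"] = cond
        frames.append(sim)
    data = pd.concat(frames, ignore_index=True)
    restricted = fit_subject_mle(data, "a+t0", rng=rng)
    full = fit_subject_mle(data, "a+t0+v", rng=rng)
    assert full.loglik >= restricted.loglik - 0.5  # nested, up to optimiser slack
    assert full.loglik > restricted.loglik + 2.0   # and clearly better here


def test_fit_is_deterministic_under_fixed_seed(rng):
    sim = simulate_ddm(DDMParams(a=2.0, v=1.0, t0=0.3), 200, rng, dt=2e-4)
    sim["condition"] = "slow"
    f1 = fit_subject_mle(sim, "fixed", rng=np.random.default_rng(7))
    f2 = fit_subject_mle(sim, "fixed", rng=np.random.default_rng(7))
    assert np.allclose(f1.theta, f2.theta)


def test_fit_requires_enough_trials(rng):
    sim = simulate_ddm(DDMParams(a=2.0, v=1.0, t0=0.3), 30, rng, dt=5e-4)
    sim["condition"] = "slow"
    with pytest.raises(ValueError, match="trials"):
        fit_subject_mle(sim, "fixed", rng=rng)


def test_effect_probability_limits():
    assert effect_probability(-np.ones(4000)) == 1.0
    assert effect_probability(np.ones(4000)) == 0.0
    rng = np.random.default_rng(0)
    sym = rng.normal(0, 1, 4000)
    assert abs(effect_probability(sym) - 0.5) < 0.05


def _dummy_hier(spec, dbar, p_d):
    return HierarchicalFit(
        spec=spec, param_names=["a", "v", "t0"],
        group_mean_samples={"a": np.zeros(10)}, group_sd_samples={},
        subject_samples={}, deviance_samples=np.full(10, dbar),
        dbar=dbar, dhat=dbar - p_d, p_d=p_d,
        bpic=dbar + 2 * p_d, dic=dbar + p_d,
        gelman_rubin={"a": 1.0}, effect_probabilities={}, converged=True,
    )


def test_bpic_penalises_effective_parameters():
    small = _dummy_hier("fixed", 1000.0, 5.0)
    large = _dummy_hier("a+t0", 1000.0, 12.0)
    table = compare_models({"fixed": small, "a+t0": large})
    assert table.iloc[0]["spec"] == "fixed"
    assert large.bpic > small.bpic


def test_compare_models_flags_missing():
    table = compare_models({"fixed": _dummy_hier("fixed", 10.0, 1.0), "a": None})
    assert (table[table.spec == "a"]["flag"] == "missing").all()


def test_effect_label_resolution():
    fit = _dummy_hier("a", 0.0, 0.0)
    fit.effect_probabilities = {"da": 1.0}
    fit.group_mean_samples["da"] = -np.ones(4000)
    assert fit.effect_label("da") == "> 99.975%"


def test_hierarchical_sampler_bookkeeping(rng):
    data = {}
    for i in range(3):
        sim = simulate_ddm(DDMParams(a=2.0, v=1.0, t0=0.3), 60, rng, dt=5e-4)
        sim["condition"] = "slow"
        data[f"S{i}"] = sim
    mc = MCMCConfig(burn_in=60, n_samples=150, thin=3, chains=2, seed=1)
    fit = fit_hierarchical(data, "fixed", mc)
    assert len(fit.group_mean_samples["a"]) == 2 * 50
    assert set(fit.gelman_rubin) == {"a", "v", "t0", "sd_a", "sd_v", "sd_t0"}
    assert np.isfinite(fit.bpic)


def test_posterior_predictive_check_flags_planted_misfit(rng):
    truth = DDMParams(a=2.5, v=1.0, t0=0.4)
    sim = simulate_ddm(truth, 300, rng, dt=2e-4)
    sim["condition"] = "slow"
    good = posterior_predictive_check({"slow": truth}, sim, np.random.default_rng(1),
                                      n_rep=60)
    frac_flagged = good[good.statistic != "skipped"]["flagged"].mean()
    assert frac_flagged <= 0.25

    shifted = DDMParams(a=truth.a, v=truth.v, t0=truth.t0 + 0.3)
    bad = posterior_predictive_check({"slow": shifted}, sim, np.random.default_rng(1),
                                     n_rep=60)
    medians = bad[bad.statistic == "rt_q50_correct"]
    assert medians["flagged"].all()


def test_posterior_predictive_check_skips_empty_condition(rng):
    sim = simulate_ddm(DDMParams(a=2.0, v=1.0, t0=0.3), 5, rng, dt=5e-4)
    sim["condition"] = "slow"
    out = posterior_predictive_check({"slow": GRID[1]}, sim, rng, n_rep=5)
    assert (out["statistic"] == "skipped").all()
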