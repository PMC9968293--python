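"""Endpoint measures, exclusion rules and the robust statistics toolbox."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from coreg.cohort import Dataset
from coreg.endpoints import (
    apply_exclusions,
    compute_endpoints,
    holm_adjust,
    paired_sign_test,
    spearman_robust,
    trial_success_probability,
    wilcoxon_signed_rank,
    within_subject_ci,
)


def _toy_dataset():
    """Ten decision-session trials with planted rule violations."""
    base = dict(session="decision", condition="slow", block_index=0,
                trial_type="random", winner="right", steps="R" * 179,
                choice="right", decision_correct=True, commit_frame=60,
                tap1=180.0, tap2=180.0, tap3=180.0, tap4=180.0,
                movement_correct=True, frame_rate_ok=True, premature_press=False)
    rows = []
    for i in range(10):
        row = dict(base, participant_id="P0", trial_id=i, rt=1000.0 + i)
        rows.append(row)
    rows[0].update(choice="none", rt=np.nan)       # no response
    rows[1].update(choice="none", rt=np.nan)       # no response
    rows[2].update(rt=430.0)                       # decision duration 30 ms -> anticipation
    trials = pd.DataFrame(rows)
    srt = pd.DataFrame({
        "participant_id": "P0", "session": "decision", "condition": "none",
        "rt": [400.0] * 10, "premature": [False] * 10,
    })
    return Dataset(trials=trials, srt=srt, meta={})


def test_exclusion_rules_on_toy_fixture():
    filt = apply_exclusions(_toy_dataset())
    assert len(filt.valid) == 7
    assert filt.report.counts["no_response"] == 2
    assert filt.report.counts["anticipation"] == 1
    assert filt.report.counts["premature_press"] == 0


def test_all_valid_trials_give_zero_counts():
    ds = _toy_dataset()
    ds.trials = ds.trials.iloc[3:].reset_index(drop=True)
    filt = apply_exclusions(ds)
    assert filt.report.total_excluded == 0
    assert filt.report.retained_fraction["main"] == 1.0


def test_srt_anticipations_removed():
    ds = _toy_dataset()
    ds.srt.loc[0, "rt"] = 20.0
    ds.srt.loc[1, "premature"] = True
    filt = apply_exclusions(ds)
    assert filt.report.counts["srt_anticipation"] == 2
    assert len(filt.srt) == 8


def test_decision_duration_is_rt_minus_matched_srt():
    filt = apply_exclusions(_toy_dataset())
    table = compute_endpoints(filt)
    row = table.iloc[0]
    expected = filt.for_decision["rt"].mean() - 400.0
    assert row["decision_duration"] == pytest.approx(expected)
    assert row["tap_duration"] == pytest.approx(180.0)
    assert row["movement_accuracy"] == 1.0


def test_success_probability_certain_at_final_frame():
    # answered at the last frame having chosen the winner: no frames remain
    assert trial_success_probability("R" * 179, 2983.0, "right") == 1.0
    assert trial_success_probability("R" * 179, 2983.0, "left") == 0.0


def test_success_probability_midtrial_value():
    steps = "R" * 99 + "L" * 80  # lead +99 after 99 frames
    # response in frame 99 -> delta 99, remaining 80 -> near-certain win
    p = trial_success_probability(steps, 99 * 1000 / 60, "right")
    assert 0.99 < p <= 1.0


def test_endpoints_permutation_invariant(small_cohort):
    filt = apply_exclusions(small_cohort)
    table1 = compute_endpoints(filt).sort_values(
        ["participant_id", "session", "condition"]).reset_index(drop=True)
    shuffled = Dataset(
        trials=small_cohort.trials.sample(frac=1.0, random_state=1).reset_index(drop=True),
        srt=small_cohort.srt.sample(frac=1.0, random_state=2).reset_index(drop=True),
        meta=small_cohort.meta,
    )
    table2 = compute_endpoints(apply_exclusions(shuffled)).sort_values(
        ["participant_id", "session", "condition"]).reset_index(drop=True)
    pd.testing.assert_frame_equal(table1, table2)


def test_lapse_rate_recovered_in_retention(small_cohort):
    cfg = small_cohort.meta["config"]
    filt = apply_exclusions(small_cohort)
    n = len(small_cohort.trials)
    # no-response trials: half the lapse rate plus late-commitment timeouts
    frac_no_resp = filt.report.counts["no_response"] / n
    assert frac_no_resp >= cfg["lapse_prob"] / 2 - 3 * np.sqrt(0.02 / n)
    assert filt.report.retained_fraction["main"] > 0.75


def test_sign_test_exact_cases():
    res = paired_sign_test([1, 1, 1, 1, 1, 1], [0, 0, 0, 0, 0, 0])
    assert res.statistic == 6 and res.p == pytest.approx(2 * 0.5 ** 6)
    res = paired_sign_test([0, 2, 0, 2], [1, 1, 1, 1])
    assert res.p == pytest.approx(1.0)
    # 2 positive differences among 58: p at the reported order of magnitude
    x = np.r_[np.ones(2), -np.ones(56)]
    res = paired_sign_test(x, np.zeros(58))
    manual = 2 * sum(stats.binom.pmf(k, 58, 0.5) for k in range(0, 3))
    assert res.statistic == 2
    assert res.p == pytest.approx(manual, rel=1e-10)
    assert res.p < 1e-12


def test_sign_test_all_zero_differences():
    res = paired_sign_test([1.0, 1.0], [1.0, 1.0])
    assert res.p == 1.0 and res.statistic == 0 and res.all_zero


def test_wilcoxon_agrees_with_scipy():
    rng = np.random.default_rng(3)
    x = rng.normal(0.4, 1, 30)
    y = rng.normal(0.0, 1, 30)
    res = wilcoxon_signed_rank(x, y)
    ref = stats.wilcoxon(x - y)
    assert res.statistic == pytest.approx(ref.statistic)
    assert res.p == pytest.approx(ref.pvalue)


def test_holm_stepdown_hand_case_and_properties():
    out = holm_adjust([0.01, 0.02, 0.03, 0.04])
    assert np.allclose(out, [0.04, 0.06, 0.06, 0.06])
    assert holm_adjust([0.2]) == pytest.approx([0.2])
    rng = np.random.default_rng(0)
    for _ in range(20):
        p = rng.uniform(size=rng.integers(1, 12))
        adj = holm_adjust(p)
        assert (adj >= p - 1e-15).all() and (adj <= 1.0).all()
        # cross-check against the reference implementation
        from statsmodels.stats.multitest import multipletests

        ref = multipletests(p, method="holm")[1]
        assert np.allclose(adj, ref)


def test_within_subject_ci_degenerate_and_morey_factor():
    values = pd.DataFrame({"a": [1.0, 2.0, 3.0], "b": [1.0, 2.0, 3.0]})
    ci = within_subject_ci(values)
    assert np.allclose(ci["ci_half_width"], 0.0)

    rng = np.random.default_rng(1)
    raw = pd.DataFrame({"a": rng.normal(0, 1, 12), "b": rng.normal(1, 1, 12)})
    ci = within_subject_ci(raw)
    centred = raw.sub(raw.mean(axis=1), axis=0) + raw.to_numpy().mean()
    manual = (centred.std(ddof=1) / np.sqrt(12) * np.sqrt(2.0)
              * stats.t.ppf(0.975, 11))
    assert np.allclose(ci["ci_half_width"], manual)


def test_within_subject_ci_difference_coverage():
    """The within-subject intervals support inference on condition
    differences: for C = 2 the implied CI of the mean difference
    (half-width sqrt(2) times the per-condition half-width) covers the true
    difference ~95% of the time, regardless of between-subject variance."""
    rng = np.random.default_rng(9)
    hits = 0
    reps = 300
    for _ in range(reps):
        subj = rng.normal(0, 5, (20, 1))  # large between-subject variance
        data = pd.DataFrame(subj + rng.normal([0.0, 1.0], 1.0, (20, 2)),
                            columns=["a", "b"])
        ci = within_subject_ci(data)
        diff = ci.loc["b", "mean"] - ci.loc["a", "mean"]
        half_diff = np.sqrt(2.0) * ci.loc["b", "ci_half_width"]
        hits += abs(diff - 1.0) <= half_diff
    coverage = hits / reps
    assert 0.92 <= coverage <= 0.98


def test_spearman_perfect_and_matches_reference():
    x = np.arange(20.0)
    y = x ** 2
    res = spearman_robust(x + 0.0, y)
    assert res.rho_full == pytest.approx(1.0)
    rng = np.random.default_rng(2)
    x = rng.normal(size=40)
    y = 0.5 * x + rng.normal(size=40)
    res = spearman_robust(x, y)
    assert res.rho_full == pytest.approx(stats.spearmanr(x, y).statistic)


def test_spearman_robust_flags_planted_outliers():
    rng = np.random.default_rng(0)
    x = rng.normal(size=50)
    y = 0.7 * x + rng.normal(scale=0.7, size=50)
    gx = np.r_[x, [10, 11, -10, 10.5, -11]]
    gy = np.r_[y, [-10, -11, 10, -10.5, 11]]
    res = spearman_robust(gx, gy, random_state=0)
    assert res.outlier_mask[-5:].all()
    assert res.rho_clean > res.rho_full


def test_spearman_robust_false_flag_rate():
    rng = np.random.default_rng(5)
    rates = []
    for _ in range(10):
        x = rng.normal(size=60)
        y = rng.normal(size=60)
        res = spearman_robust(x, y, random_state=0)
        rates.append(res.outlier_mask.mean())
    assert np.mean(rates) <= 0.10


def test_spearman_degenerate_input():
    with pytest.raises(ValueError, match="constant"):
        spearman_robust(np.ones(20), np.arange(20.0))
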