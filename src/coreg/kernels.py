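"""Psychophysical kernels: response-locked evidence-choice correlations.

Momentary evidence is the sliding-window sum of frame-wise steps (-1 for a
left-banana frame, +1 for a right-banana frame) over timespans of 200, 300,
400 or 500 ms (12, 18, 24 or 30 frames).  For every lag relative to the
response frame, the window sum presented at that lag is correlated across
trials with the signed decision (-1 left, +1 right).  The resulting kernel
rises towards a peak marking decisional commitment and collapses
afterwards, because evidence seen after commitment can no longer influence
the choice.

Two summary statistics carry the condition comparisons: the kernel *slope*
from the expected decision onset (negative median reaction time) to the
peak, a proxy for the decisional speed-accuracy tradeoff, and the *peak
latency* (time between peak and response), a proxy for sensorimotor delay.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .endpoints import holm_adjust, wilcoxon_signed_rank
from .task import FRAME_MS, TaskDesign, rt_to_frame, str_to_steps

__all__ = [
    "TIMESPANS_MS",
    "Kernel",
    "KernelStats",
    "momentary_evidence_series",
    "compute_kernel",
    "kernel_stats",
    "compare_kernel_stats",
]

TIMESPANS_MS = (200, 300, 400, 500)
MIN_TRIALS_PER_KERNEL = 30
MIN_TRIALS_PER_LAG = 10
MIN_RT_MS = 150.0


def _window_frames(timespan_ms: float, design: TaskDesign) -> int:
    w = timespan_ms / design.frame_ms
    if abs(w - round(w)) > 1e-9:
        raise ValueError(
            f"timespan {timespan_ms} ms is not a whole number of frames; "
            f"legal timespans include {TIMESPANS_MS}"
        )
    return int(round(w))


def momentary_evidence_series(steps, timespan_ms: float,
                              design: TaskDesign | None = None) -> np.ndarray:
    """Sliding sums of the evidence steps over windows of the timespan.

    Window positions are indexed by their final frame: entry j corresponds
    to the window ending at frame w + j (1-based), i.e. the evidence fully
    presented by that moment.
    """
    design = design or TaskDesign()
    if isinstance(steps, str):
        steps = str_to_steps(steps)
    steps = np.asarray(steps, float)
    w = _window_frames(timespan_ms, design)
    c = np.concatenate([[0.0], np.cumsum(steps)])
    return c[w:] - c[:-w]


@dataclass
class Kernel:
    """Point-biserial correlation between momentary evidence and choice,
    per response-locked lag (ms; negative = before the response)."""

    timespan_ms: float
    lags_ms: np.ndarray
    r: np.ndarray
    n_trials: np.ndarray

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "timespan": self.timespan_ms,
            "lag_ms": self.lags_ms,
            "r": self.r,
            "n_trials": self.n_trials,
        })


def compute_kernel(
    trials: pd.DataFrame,
    timespan_ms: float,
    design: TaskDesign | None = None,
    min_trials: int = MIN_TRIALS_PER_KERNEL,
) -> Kernel:
    """Response-locked kernel across the given trials.

    ``trials`` needs columns steps (L/R string or array), rt (ms) and
    choice ('left'/'right').  Reaction times below 150 ms are discarded.
    Lag 0 is the window ending at the response frame; at each more negative
    lag, trials whose reaction time is too short to contain the window are
    dropped, and lags retaining fewer than 10 trials are left undefined.
    """
    design = design or TaskDesign()
    w = _window_frames(timespan_ms, design)
    df = trials[(trials["rt"] >= MIN_RT_MS) & trials["choice"].isin(["left", "right"])]
    if len(df) < min_trials:
        raise ValueError(f"kernel needs >= {min_trials} usable trials, got {len(df)}")

    sums = [momentary_evidence_series(s, timespan_ms, design) for s in df["steps"]]
    rframe = np.array([rt_to_frame(rt, design) for rt in df["rt"]])
    decision = np.where(df["choice"].to_numpy() == "right", 1.0, -1.0)

    max_depth = int(rframe.max() - w)  # most negative lag index with data
    lag_idx = np.arange(-max_depth, 1)
    r = np.full(len(lag_idx), np.nan)
    n_used = np.zeros(len(lag_idx), int)
    for i, lag in enumerate(lag_idx):
        end_frame = rframe + lag            # window's final frame per trial
        usable = end_frame >= w
        if usable.sum() < MIN_TRIALS_PER_LAG:
            continue
        x = np.array([sums[j][end_frame[j] - w] for j in np.nonzero(usable)[0]])
        y = decision[usable]
        if np.ptp(x) == 0 or np.ptp(y) == 0:
            continue
        r[i] = np.corrcoef(x, y)[0, 1]
        n_used[i] = int(usable.sum())
    return Kernel(
        timespan_ms=timespan_ms,
        lags_ms=lag_idx * design.frame_ms,
        r=r,
        n_trials=n_used,
    )


@dataclass
class KernelStats:
    """Slope to peak and peak latency of one kernel."""

    slope_per_s: float
    peak_latency_ms: float
    peak_lag_ms: float
    peak_r: float
    median_rt_ms: float


def kernel_stats(kernel: Kernel, median_rt_ms: float) -> KernelStats:
    """Peak and slope statistics over the decision epoch.

    The peak is the maximum correlation between the expected decision onset
    (negative median reaction time) and the response; ties break toward the
    response.  The slope is the least-squares slope of r against time (in
    seconds) from decision onset to the peak.
    """
    window = (kernel.lags_ms >= -median_rt_ms) & (kernel.lags_ms <= 0)
    defined = window & np.isfinite(kernel.r)
    if defined.sum() < 2:
        raise ValueError("kernel undefined over the decision epoch")
    lags = kernel.lags_ms[defined]
    r = kernel.r[defined]
    best = np.nanmax(r)
    peak_lag = float(lags[np.nonzero(r == best)[0][-1]])  # tie -> closest to response

    seg = defined & (kernel.lags_ms <= peak_lag)
    x = kernel.lags_ms[seg] / 1000.0
    y = kernel.r[seg]
    slope = 0.0 if len(x) < 2 or np.ptp(x) == 0 else float(np.polyfit(x, y, 1)[0])
    return KernelStats(
        slope_per_s=slope,
        peak_latency_ms=-peak_lag,
        peak_lag_ms=peak_lag,
        peak_r=float(best),
        median_rt_ms=float(median_rt_ms),
    )


def compare_kernel_stats(
    stats_a: pd.DataFrame,
    stats_b: pd.DataFrame,
    measure: str,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Paired condition comparison of a kernel statistic per timespan.

    Inputs are participant x timespan tables (index participant, columns
    timespans) for condition A and B.  Per timespan, the paired differences
    are tested with a paired t-test when a Shapiro-Wilk test does not
    reject normality (at alpha), otherwise with the Wilcoxon signed-rank
    test; p-values are Holm-corrected across timespans.
    """
    common = stats_a.index.intersection(stats_b.index)
    dropped = len(stats_a.index.union(stats_b.index)) - len(common)
    if dropped:
        warnings.warn(f"{dropped} participants without complete pairs dropped")
    if len(common) < 10:
        raise ValueError("need paired statistics for >= 10 participants")

    rows = []
    for ts in stats_a.columns:
        d = (stats_a.loc[common, ts] - stats_b.loc[common, ts]).dropna()
        if d.nunique() <= 1:
            # degenerate differences (e.g. identical peak latencies)
            rows.append({
                "measure": measure, "timespan": ts, "test": "degenerate",
                "statistic": np.nan, "p": 1.0, "mean_difference": float(d.mean()),
                "n": len(d), "shapiro_p": np.nan,
            })
            continue
        sw_p = float(stats.shapiro(d).pvalue)
        if sw_p >= alpha:
            res = stats.ttest_rel(stats_a.loc[common, ts], stats_b.loc[common, ts],
                                  nan_policy="omit")
            test, statistic, p = "paired_t", float(res.statistic), float(res.pvalue)
        else:
            r = wilcoxon_signed_rank(stats_a.loc[common, ts].to_numpy(),
                                     stats_b.loc[common, ts].to_numpy())
            test, statistic, p = "signed_rank", r.statistic, r.p
        rows.append({
            "measure": measure, "timespan": ts, "test": test,
            "statistic": statistic, "p": p,
            "mean_difference": float(d.mean()), "n": len(d), "shapiro_p": sw_p,
        })
    out = pd.DataFrame(rows)
    out["p_holm"] = holm_adjust(out["p"].to_numpy())
    return out
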