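"""FRAP trace normalization and mobility metrics.

A FRAP recording consists of a bleached region of interest (ROI), an
unbleached reference region of similar intensity (tracking acquisition
photobleaching), and a background region outside cell boundaries.  The
double-normalized intensity

    I_dn(t) = [mean_pre(ref - bg) / (ref(t) - bg(t))]
              * [(roi(t) - bg(t)) / mean_pre(roi - bg)]

cancels background offset and any photobleaching decay shared by ROI and
reference, and has pre-bleach mean 1 by construction.

Recovery is summarized by fitting I(t) = I0 + A(1 - exp(-k t)) on the
post-bleach frames and deriving:

* mobile fraction, m.f. = 100 * (I_max - I0) / (1 - I0), the recovered share
  of the pre-bleach (=1) signal;
* maximal recovery I_max = I0 + A (plateau), relative to pre-bleach;
* AUC, the trapezoidal integral of I_dn over the first 120 s post-bleach
  (a curve pinned at 1.0 integrates to 120);
* t_half, the earliest time at which I(t) reaches halfway between I0 and
  I_max, linearly interpolated between frames (equivalently ln2/k from the
  fit on a clean exponential).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

DEFAULT_AUC_WINDOW_S = 120.0


@dataclass
class FrapTrace:
    """Raw ROI / reference / background time series with bleach at t = 0."""

    time_s: np.ndarray
    roi: np.ndarray
    reference: np.ndarray
    background: np.ndarray
    n_pre: int

    def __post_init__(self) -> None:
        self.time_s = np.asarray(self.time_s, dtype=float)
        self.roi = np.asarray(self.roi, dtype=float)
        self.reference = np.asarray(self.reference, dtype=float)
        self.background = np.asarray(self.background, dtype=float)
        n = self.time_s.size
        if not (self.roi.size == self.reference.size == self.background.size == n):
            raise ValueError("all series must have equal length")
        if self.n_pre < 1:
            raise ValueError("need at least one pre-bleach frame")
        if self.n_pre >= n:
            raise ValueError("n_pre must leave post-bleach frames")
        if np.any(np.diff(self.time_s) <= 0):
            raise ValueError("time_s must be strictly increasing")
        if self.time_s[self.n_pre - 1] >= 0 or self.time_s[self.n_pre] < 0:
            raise ValueError("bleach must occur at t=0 after n_pre frames")

    def to_dataframe(self) -> pd.DataFrame:
        is_pre = np.zeros(self.time_s.size, dtype=bool)
        is_pre[: self.n_pre] = True
        return pd.DataFrame(
            {
                "time_s": self.time_s,
                "roi": self.roi,
                "reference": self.reference,
                "background": self.background,
                "is_pre_bleach": is_pre,
            }
        )

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "FrapTrace":
        n_pre = int(df["is_pre_bleach"].sum())
        return cls(
            time_s=df["time_s"].to_numpy(),
            roi=df["roi"].to_numpy(),
            reference=df["reference"].to_numpy(),
            background=df["background"].to_numpy(),
            n_pre=n_pre,
        )


@dataclass
class FitParams:
    I0: float
    amplitude: float
    rate: float
    fit_ok: bool


@dataclass
class FrapMetrics:
    mobile_fraction_pct: float
    auc: float
    max_recovery: float
    t_half_s: float
    t_half_fit_s: float
    fit: FitParams


def normalize_trace(trace: FrapTrace) -> np.ndarray:
    """Double-normalized intensity series; pre-bleach mean equals 1."""
    ref_corr = trace.reference - trace.background
    if np.any(ref_corr <= 0):
        raise ValueError("reference minus background must be strictly positive")
    roi_corr = trace.roi - trace.background
    pre = slice(0, trace.n_pre)
    mean_pre_ref = ref_corr[pre].mean()
    mean_pre_roi = roi_corr[pre].mean()
    if mean_pre_roi <= 0:
        raise ValueError("pre-bleach ROI minus background must be positive")
    return (mean_pre_ref / ref_corr) * (roi_corr / mean_pre_roi)


def full_scale_normalize(normalized: np.ndarray, n_pre: int) -> np.ndarray:
    """Rescale a double-normalized curve so the first post-bleach point is 0.

    Off by default throughout this package: the maximal-recovery and mobile
    fraction conventions here are defined on the double-normalized scale.
    """
    i0 = normalized[n_pre]
    if i0 >= 1:
        raise ValueError("no bleach depth to rescale")
    return (normalized - i0) / (1.0 - i0)


def _recovery(t: np.ndarray, i0: float, a: float, k: float) -> np.ndarray:
    return i0 + a * (1.0 - np.exp(-k * t))


def fit_recovery(time_s: np.ndarray, normalized: np.ndarray, n_pre: int) -> FitParams:
    """Least-squares single-exponential fit of the post-bleach recovery.

    Initial values: I0 from the first post-bleach point, amplitude from the
    last point, and rate from the first midpoint crossing.  ``fit_ok`` is
    False when the optimizer fails or the fitted amplitude is nonpositive;
    callers then fall back to a plateau estimated from the last 5 frames.
    """
    t = np.asarray(time_s, dtype=float)[n_pre:]
    y = np.asarray(normalized, dtype=float)[n_pre:]
    if t.size < 5:
        raise ValueError("need at least 5 post-bleach frames")
    i0_init = y[0]
    a_init = y[-1] - i0_init
    if a_init <= 0:
        return FitParams(I0=i0_init, amplitude=0.0, rate=np.nan, fit_ok=False)
    mid = i0_init + 0.5 * a_init
    above = np.nonzero(y >= mid)[0]
    t_cross = t[above[0]] if above.size and t[above[0]] > 0 else (t[1] - t[0])
    k_init = math.log(2.0) / t_cross
    try:
        popt, _ = curve_fit(
            _recovery, t, y, p0=[i0_init, a_init, k_init], maxfev=20000
        )
    except RuntimeError:
        return FitParams(I0=i0_init, amplitude=a_init, rate=np.nan, fit_ok=False)
    i0, a, k = (float(v) for v in popt)
    ok = a > 0 and k > 0 and np.isfinite(k)
    return FitParams(I0=i0, amplitude=a, rate=k, fit_ok=ok)


def compute_metrics(
    time_s: np.ndarray,
    normalized: np.ndarray,
    n_pre: int,
    fit: FitParams | None = None,
    auc_window_s: float = DEFAULT_AUC_WINDOW_S,
) -> FrapMetrics:
    """Mobility metrics from a double-normalized recovery curve."""
    t = np.asarray(time_s, dtype=float)[n_pre:]
    y = np.asarray(normalized, dtype=float)[n_pre:]
    if fit is None:
        fit = fit_recovery(time_s, normalized, n_pre)

    if fit.fit_ok:
        i0 = fit.I0
        i_max = fit.I0 + fit.amplitude
        t_half_fit = math.log(2.0) / fit.rate
    else:
        i0 = y[0]
        i_max = float(np.mean(y[-5:]))  # fallback plateau
        t_half_fit = np.nan

    if i0 < 1.0:
        mf = 100.0 * (i_max - i0) / (1.0 - i0)
    else:
        mf = np.nan  # no bleach depth: mobile fraction undefined

    # AUC over [0, window]; interpolate the endpoint when frames bracket it.
    t_end = min(auc_window_s, t[-1])
    grid = t[(t >= 0) & (t <= t_end)]
    if grid.size == 0 or grid[-1] < t_end:
        grid = np.append(grid, t_end)
    vals = np.interp(grid, t, y)
    auc = float(np.trapezoid(vals, grid))

    # Earliest interpolated crossing of the half-recovery level.
    target = i0 + 0.5 * (i_max - i0)
    t_half = np.nan
    if i_max > i0:
        above = np.nonzero(y >= target)[0]
        if above.size:
            j = above[0]
            if j == 0:
                t_half = t[0]
            else:
                frac = (target - y[j - 1]) / (y[j] - y[j - 1])
                t_half = t[j - 1] + frac * (t[j] - t[j - 1])
    return FrapMetrics(
        mobile_fraction_pct=float(mf),
        auc=auc,
        max_recovery=float(i_max),
        t_half_s=float(t_half),
        t_half_fit_s=float(t_half_fit),
        fit=fit,
    )


def analyze_trace(trace: FrapTrace, auc_window_s: float = DEFAULT_AUC_WINDOW_S) -> FrapMetrics:
    """Normalize a raw trace and compute its mobility metrics."""
    normalized = normalize_trace(trace)
    return compute_metrics(trace.time_s, normalized, trace.n_pre, auc_window_s=auc_window_s)


def analyze_traces_frame(df: pd.DataFrame, auc_window_s: float = DEFAULT_AUC_WINDOW_S) -> pd.DataFrame:
    """Per-trace metrics for a CSV-style frame, grouped by ``trace_id``.

    Frames without a ``trace_id`` column are treated as a single trace.
    """
    if "trace_id" not in df.columns:
        df = df.assign(trace_id="trace_0")
    rows = []
    for tid, grp in df.groupby("trace_id", sort=False):
        m = analyze_trace(FrapTrace.from_dataframe(grp), auc_window_s=auc_window_s)
        rows.append(
            {
                "trace_id": tid,
                "mobile_fraction_pct": m.mobile_fraction_pct,
                "auc": m.auc,
                "max_recovery": m.max_recovery,
                "t_half_s": m.t_half_s,
                "t_half_fit_s": m.t_half_fit_s,
                "fit_I0": m.fit.I0,
                "fit_amplitude": m.fit.amplitude,
                "fit_rate": m.fit.rate,
                "fit_ok": m.fit.fit_ok,
            }
        )
    return pd.DataFrame(rows)
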