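"""Deactivation time-course analysis of agonist-evoked current traces.

The decay after rapid agonist removal is fitted with a sum of two
exponentials,

    I(t) = A_fast * exp(-t / tau_fast) + A_slow * exp(-t / tau_slow),

and summarized by the amplitude-weighted time constant

    tau_w = (A_fast * tau_fast + A_slow * tau_slow) / (A_fast + A_slow),

which is always a convex combination of the two time constants.  Traces whose
peak does not rise sufficiently above the baseline noise are reported as too
small to measure rather than fitted.  Currents are stored as positive
amplitudes (inward current magnitude), in pA or pA/pF when normalized to cell
capacitance.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np
from lmfit import Model

__all__ = [
    "CurrentTrace",
    "BiexpFit",
    "fit_deactivation",
    "weighted_tau",
    "rise_time_10_90",
    "desensitization_extent",
    "charge_transfer_product",
]

#: degenerate biexponential: taus within this relative spread collapse to one
TAU_DEGENERACY_RTOL = 0.05
#: minimal slow amplitude (fraction of peak) for a genuine second component
MIN_COMPONENT_FRACTION = 1e-3
#: peak must exceed this many baseline SDs to be measurable
TOO_SMALL_SD_FACTOR = 3.0


@dataclass
class CurrentTrace:
    """Uniformly sampled time/current record of one agonist application."""

    cell_id: str
    time_ms: np.ndarray
    current: np.ndarray
    application_window_ms: tuple[float, float]
    construct_id: str = ""

    def __post_init__(self) -> None:
        self.time_ms = np.asarray(self.time_ms, dtype=float)
        self.current = np.asarray(self.current, dtype=float)
        if self.time_ms.shape != self.current.shape:
            raise ValueError("time and current arrays differ in length")
        dt = np.diff(self.time_ms)
        if self.time_ms.size < 8 or np.any(dt <= 0):
            raise ValueError("time must be a strictly increasing grid")
        if not np.allclose(dt, dt[0], rtol=1e-6):
            raise ValueError("time grid must be uniform")
        start, end = self.application_window_ms
        if not (self.time_ms[0] <= start < end <= self.time_ms[-1]):
            raise ValueError("application window must lie within the trace")

    @property
    def sample_interval_ms(self) -> float:
        return float(self.time_ms[1] - self.time_ms[0])


@dataclass
class BiexpFit:
    """Two-exponential decay fit and its weighted time constant."""

    amp_fast: float
    tau_fast: float
    amp_slow: float
    tau_slow: float
    tau_weighted: float
    peak: float
    rss: float
    status: str = "ok"  # ok | single_exp | too_small | failed
    cell_id: str = ""

    def __post_init__(self) -> None:
        if self.status in ("ok", "single_exp"):
            if self.tau_fast > self.tau_slow:
                raise ValueError("tau_fast must not exceed tau_slow")
            if self.amp_fast < 0 or self.amp_slow < 0:
                raise ValueError("amplitudes must be non-negative")
            lo, hi = sorted((self.tau_fast, self.tau_slow))
            if not (lo - 1e-9 <= self.tau_weighted <= hi + 1e-9):
                raise ValueError("tau_weighted must lie between the two taus")


def weighted_tau(fit: BiexpFit) -> float:
    """Amplitude-weighted deactivation time constant of a biexponential fit."""
    total = fit.amp_fast + fit.amp_slow
    if total <= 0:
        raise ValueError("weighted tau undefined: zero total amplitude")
    return (fit.amp_fast * fit.tau_fast + fit.amp_slow * fit.tau_slow) / total


def _baseline(trace: CurrentTrace):
    pre = trace.current[trace.time_ms < trace.application_window_ms[0]]
    if pre.size >= 2:
        return float(pre.mean()), float(pre.std(ddof=1))
    return 0.0, 0.0


def fit_deactivation(trace: CurrentTrace,
                     baseline_sd: Optional[float] = None) -> BiexpFit:
    """Fit the post-application decay with a sum of two exponentials.

    The decay segment starts one sample interval after the end of the agonist
    application.  When the second component is degenerate (taus within 5% or a
    vanishing slow amplitude) the fit collapses to a single exponential and
    ``tau_weighted`` equals that time constant.  Peaks below three baseline
    standard deviations return status ``"too_small"`` without a fit.
    """
    base, base_sd = _baseline(trace)
    if baseline_sd is not None:
        base_sd = baseline_sd
    y = trace.current - base
    t_end = trace.application_window_ms[1]

    window = (trace.time_ms >= trace.application_window_ms[0]) & (trace.time_ms <= t_end)
    # light smoothing before peak detection so a single noisy sample cannot
    # lift a sub-threshold response above the too-small criterion
    kernel = np.ones(min(5, max(1, window.sum()))) / min(5, max(1, window.sum()))
    smoothed = np.convolve(y, kernel, mode="same")
    peak = float(smoothed[window].max()) if window.any() else float(smoothed.max())
    if base_sd > 0 and peak < TOO_SMALL_SD_FACTOR * base_sd:
        return BiexpFit(np.nan, np.nan, np.nan, np.nan, np.nan, peak, np.nan,
                        status="too_small", cell_id=trace.cell_id)

    sel = trace.time_ms > t_end + trace.sample_interval_ms / 2
    td = trace.time_ms[sel] - trace.time_ms[sel][0]
    yd = y[sel]
    if td.size < 8:
        raise ValueError("decay segment too short to fit")

    # crude single-exponential time scale from the 1/e crossing
    y0 = max(yd[0], peak * 0.5)
    below = np.nonzero(yd < y0 / np.e)[0]
    tau0 = float(td[below[0]]) if below.size else float(td[-1] / 2)
    tau0 = max(tau0, 2 * trace.sample_interval_ms)

    model = Model(lambda t, af, tf, as_, ts:
                  af * np.exp(-t / tf) + as_ * np.exp(-t / ts),
                  independent_vars=["t"])
    params = model.make_params(af=0.6 * y0, tf=tau0 / 2, as_=0.4 * y0, ts=tau0 * 3)
    for name in ("af", "as_"):
        params[name].set(min=0.0)
    for name in ("tf", "ts"):
        params[name].set(min=trace.sample_interval_ms / 10, max=50 * td[-1])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = model.fit(yd, params, t=td)
    if not res.success:
        return BiexpFit(np.nan, np.nan, np.nan, np.nan, np.nan, peak, np.nan,
                        status="failed", cell_id=trace.cell_id)

    af, tf = float(res.params["af"].value), float(res.params["tf"].value)
    as_, ts = float(res.params["as_"].value), float(res.params["ts"].value)
    if tf > ts:  # canonical order: fast component first
        af, tf, as_, ts = as_, ts, af, tf
    rss = float(np.sum(res.residual ** 2))

    total = af + as_
    degenerate = ts <= tf * (1 + TAU_DEGENERACY_RTOL)
    tiny_slow = total > 0 and min(af, as_) < MIN_COMPONENT_FRACTION * total
    if degenerate or tiny_slow:
        single = Model(lambda t, a, tau: a * np.exp(-t / tau),
                       independent_vars=["t"])
        sp = single.make_params(a=y0, tau=tau0)
        sp["a"].set(min=0.0)
        sp["tau"].set(min=trace.sample_interval_ms / 10, max=50 * td[-1])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            sres = single.fit(yd, sp, t=td)
        a, tau = float(sres.params["a"].value), float(sres.params["tau"].value)
        return BiexpFit(a, tau, 0.0, tau, tau, peak,
                        float(np.sum(sres.residual ** 2)),
                        status="single_exp", cell_id=trace.cell_id)

    fit = BiexpFit(af, tf, as_, ts, (af * tf + as_ * ts) / total, peak, rss,
                   status="ok", cell_id=trace.cell_id)
    return fit


def rise_time_10_90(trace: CurrentTrace) -> float:
    """10-90% rise time (ms) of the onset, by linear interpolation.

    Measured on the baseline-subtracted rising phase from application start to
    the peak sample.
    """
    base, base_sd = _baseline(trace)
    y = trace.current - base
    start = trace.application_window_ms[0]
    onset = trace.time_ms >= start
    t, yo = trace.time_ms[onset], y[onset]
    ipeak = int(np.argmax(yo))
    peak = float(yo[ipeak])
    if peak <= max(3 * base_sd, 1e-12):
        raise ValueError("no identifiable peak above baseline")
    t, yo = t[: ipeak + 1], yo[: ipeak + 1]

    def crossing(level: float) -> float:
        above = np.nonzero(yo >= level)[0]
        if above.size == 0:
            raise ValueError("onset never reaches the requested level")
        i = above[0]
        if i == 0:
            return float(t[0])
        frac = (level - yo[i - 1]) / (yo[i] - yo[i - 1])
        return float(t[i - 1] + frac * (t[i] - t[i - 1]))

    return crossing(0.9 * peak) - crossing(0.1 * peak)


def desensitization_extent(trace: CurrentTrace) -> float:
    """Fractional sag from peak to steady state during prolonged application.

    Steady state is the mean of the final 10% of the application window;
    returns ``1 - steady/peak``.
    """
    base, _ = _baseline(trace)
    y = trace.current - base
    start, end = trace.application_window_ms
    window = (trace.time_ms >= start) & (trace.time_ms <= end)
    if window.sum() < 10:
        raise ValueError("application window too short for a steady-state segment")
    yw = y[window]
    tw = trace.time_ms[window]
    peak = float(yw.max())
    if peak <= 0:
        raise ValueError("no response during the application window")
    tail = tw >= end - 0.1 * (end - start)
    steady = float(yw[tail].mean())
    return 1.0 - steady / peak


def charge_transfer_product(peak: float, tau_weighted: float) -> float:
    """Charge-transfer estimate: peak amplitude times weighted tau (pA*ms)."""
    if peak < 0 or tau_weighted < 0:
        raise ValueError("peak and tau_weighted must be non-negative")
    return peak * tau_weighted
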