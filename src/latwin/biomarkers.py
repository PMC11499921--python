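"""Electrophysiological biomarkers: APD restitution (Smax) and dominant frequency.

The restitution curve at a node relates the action-potential duration at
90% repolarization (APD90) to the preceding diastolic interval (DI):

    APD = y0 + A1 * (1 - exp(-DI / tau1))

fitted by nonlinear least squares; its slope A1/tau1 * exp(-DI/tau1) is
monotone decreasing in DI, so the maximal slope over the observed range
(Smax) is evaluated at the smallest observed DI.  Smax > 1 marks tissue
prone to APD alternans and wave break.

The dominant frequency (DF) of a node is the frequency of maximal
spectral power of its membrane-potential signal (mean removed, Hann
taper, 4x zero padding) within a physiologic band, computed over a 6-s
window during sustained AF/AT — a surrogate for local driver rate.

Regional aggregation reports per-region means plus the cohort summary
statistics: global mean, highest-region mean, lowest-region mean, and
the Delta-regional spread (highest - lowest).
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy.optimize import curve_fit

from .myocyte import ModelError
from .substrate import REGION_NAMES

DF_BAND_HZ = (1.0, 20.0)
DF_WINDOW_S = (17.0, 23.0)


@dataclasses.dataclass
class RestitutionFit:
    """Exponential restitution fit and its maximal observed slope."""

    fitted: bool
    y0_ms: float = np.nan
    a1_ms: float = np.nan
    tau1_ms: float = np.nan
    smax: float = np.nan
    di_min_ms: float = np.nan
    n_points: int = 0
    rss: float = np.nan
    reason: str = ""


@dataclasses.dataclass
class DFValue:
    """Dominant frequency of one node (Hz) and the window used."""

    found: bool
    df_hz: float = np.nan
    power: float = np.nan
    window_s: tuple = DF_WINDOW_S


@dataclasses.dataclass
class RegionalSummary:
    """Per-region means and the cohort-level aggregates of one biomarker."""

    region_means: dict
    region_counts: dict
    mean: float
    highest: float
    lowest: float
    delta_regional: float
    n_valid: int
    n_invalid: int
    low_confidence: bool = False

    @classmethod
    def from_values(cls, values: np.ndarray, region_labels: np.ndarray) -> "RegionalSummary":
        values = np.asarray(values, dtype=float)
        labels = np.asarray(region_labels)
        valid = np.isfinite(values) & (labels >= 0)
        means, counts = {}, {}
        for r, name in enumerate(REGION_NAMES):
            sel = valid & (labels == r)
            counts[name] = int(sel.sum())
            means[name] = float(np.mean(values[sel])) if sel.any() else np.nan
        present = {k: v for k, v in means.items() if np.isfinite(v)}
        if not present:
            return cls(means, counts, np.nan, np.nan, np.nan, np.nan,
                       0, int((labels >= 0).sum()), low_confidence=True)
        hi = max(present.values())
        lo = min(present.values())
        n_valid = int(valid.sum())
        n_region_nodes = int((labels >= 0).sum())
        return cls(
            region_means=means, region_counts=counts,
            mean=float(np.mean(values[valid])),
            highest=hi, lowest=lo, delta_regional=hi - lo,
            n_valid=n_valid, n_invalid=n_region_nodes - n_valid,
            low_confidence=(n_valid < 0.5 * n_region_nodes))


# ---------------------------------------------------------------------------
# APD / DI extraction
# ---------------------------------------------------------------------------

def _beat_events(t: np.ndarray, v: np.ndarray, threshold_mV: float = -40.0):
    """Per-beat (activation time, 90%-repolarization time) pairs of a trace."""
    up = np.flatnonzero((v[:-1] < threshold_mV) & (v[1:] >= threshold_mV))
    if up.size == 0:
        return []
    dvdt = np.diff(v) / np.diff(t)
    events = []
    bounds = list(up) + [v.size - 1]
    for bi, k in enumerate(up):
        w0 = np.searchsorted(t, t[k] - 5.0)
        w1 = min(v.size - 1, np.searchsorted(t, t[k] + 5.0))
        i_act = w0 + int(np.argmax(dvdt[w0:w1]))
        p0 = np.searchsorted(t, t[i_act] - 50.0)
        v_takeoff = float(np.min(v[p0:i_act + 1])) if i_act > p0 else float(v[i_act])
        seg_end = bounds[bi + 1]
        seg = v[i_act:seg_end + 1]
        if seg.size < 2:
            continue
        v_peak = float(np.max(seg))
        amp = v_peak - v_takeoff
        if amp <= 0:
            continue
        level = v_peak - 0.9 * amp
        i_peak = i_act + int(np.argmax(seg))
        below = np.flatnonzero(v[i_peak:seg_end + 1] <= level)
        if below.size == 0:
            continue
        i_r = i_peak + below[0]
        if i_r > 0 and v[i_r - 1] > level:
            frac = (v[i_r - 1] - level) / (v[i_r - 1] - v[i_r])
            t_rep = t[i_r - 1] + frac * (t[i_r] - t[i_r - 1])
        else:
            t_rep = t[i_r]
        events.append((float(t[i_act]), float(t_rep)))
    return events


def extract_apd_di(times_ms: np.ndarray, vm_mV: np.ndarray,
                   threshold_mV: float = -40.0):
    """(DI, APD90) pairs from consecutive beats of one node's trace.

    For beats k and k+1: DI = activation(k+1) - repol90(k) and the paired
    APD90 is that of beat k+1 (the restitution response to the preceding
    DI).  Non-physiologic pairs (DI <= 0) are dropped and counted.
    Returns (pairs array of shape (m, 2), n_dropped); an empty array with
    a diagnostic count when fewer than two beats are found.
    """
    t = np.asarray(times_ms, dtype=float)
    v = np.asarray(vm_mV, dtype=float)
    events = _beat_events(t, v, threshold_mV)
    if len(events) < 2:
        return np.empty((0, 2)), 0
    pairs, dropped = [], 0
    for (a0, r0), (a1, r1) in zip(events[:-1], events[1:]):
        di = a1 - r0
        apd = r1 - a1
        if di <= 0 or apd <= 0:
            dropped += 1
            continue
        pairs.append((di, apd))
    return np.asarray(pairs, dtype=float).reshape(-1, 2), dropped


def fit_restitution(pairs: np.ndarray) -> RestitutionFit:
    """Least-squares exponential restitution fit and Smax at the minimum DI.

    Requires >= 4 pairs spanning >= 2 distinct DIs; failures are reported
    in the returned object (``fitted=False``), never silently zeroed.
    """
    pairs = np.asarray(pairs, dtype=float).reshape(-1, 2)
    if pairs.shape[0] < 4:
        return RestitutionFit(False, n_points=pairs.shape[0],
                              reason="fewer than 4 (DI, APD) pairs")
    di = pairs[:, 0]
    apd = pairs[:, 1]
    if np.unique(np.round(di, 6)).size < 2:
        return RestitutionFit(False, n_points=di.size,
                              reason="degenerate DI span")
    apd_range = float(np.ptp(apd))
    if apd_range < 1e-9:
        # flat restitution: zero slope everywhere
        return RestitutionFit(True, y0_ms=float(apd[0]), a1_ms=0.0,
                              tau1_ms=np.nan, smax=0.0,
                              di_min_ms=float(di.min()),
                              n_points=di.size, rss=0.0)

    def model(x, y0, a1, tau1):
        return y0 + a1 * (1.0 - np.exp(-x / tau1))

    p0 = (float(apd.min()), apd_range, float(np.median(di)))
    try:
        # weight by observed APD: measurement noise on APD is closer to
        # multiplicative than additive, so relative residuals are fitted
        popt, _ = curve_fit(
            model, di, apd, p0=p0, sigma=apd,
            bounds=([-np.inf, 0.0, 1.0], [np.inf, np.inf, 1000.0]),
            maxfev=5000)
    except (RuntimeError, ValueError) as exc:
        return RestitutionFit(False, n_points=di.size, reason=str(exc))
    y0, a1, tau1 = (float(x) for x in popt)
    di_min = float(di.min())
    smax = (a1 / tau1) * float(np.exp(-di_min / tau1))
    rss = float(np.sum((model(di, *popt) - apd) ** 2))
    return RestitutionFit(True, y0_ms=y0, a1_ms=a1, tau1_ms=tau1,
                          smax=smax, di_min_ms=di_min,
                          n_points=di.size, rss=rss)


def restitution_slope(a1_ms: float, tau1_ms: float, di_ms: float) -> float:
    """Closed-form slope of the fitted restitution curve at a given DI."""
    return (a1_ms / tau1_ms) * float(np.exp(-di_ms / tau1_ms))


def smax_map(trace, region_labels: np.ndarray,
             t_start_ms: float = 0.0, t_end_ms: float | None = None,
             mode: str = "all", threshold_mV: float = -40.0):
    """Per-node Smax from the ramp-pacing window plus a regional summary.

    ``mode='all'`` fits all valid ramp beats of each node;
    ``mode='last3'`` restricts each node to its last three (DI, APD)
    pairs (the short-DI beats just after wave break).  Unfittable nodes
    are NaN and excluded from regional means, with counts reported; a
    summary with more than 50% unfittable nodes is flagged low-confidence.
    """
    if mode not in ("all", "last3"):
        raise ModelError(f"unknown smax mode {mode!r}")
    t = trace.frame_times_ms
    sel = t >= t_start_ms
    if t_end_ms is not None:
        sel &= t <= t_end_ms
    tw = t[sel]
    smax = np.full(trace.n_nodes, np.nan)
    for k in range(trace.n_nodes):
        pairs, _ = extract_apd_di(tw, trace.frames[sel, k].astype(float),
                                  threshold_mV)
        if mode == "last3":
            pairs = pairs[-3:]
        fit = fit_restitution(pairs)
        if fit.fitted:
            smax[k] = fit.smax
    return smax, RegionalSummary.from_values(smax, region_labels)


# ---------------------------------------------------------------------------
# dominant frequency
# ---------------------------------------------------------------------------

def dominant_frequency(times_ms: np.ndarray, vm_mV: np.ndarray,
                       window_s: tuple[float, float] = DF_WINDOW_S,
                       band_hz: tuple[float, float] = DF_BAND_HZ,
                       pad_factor: int = 4) -> DFValue:
    """Dominant frequency of one node over a time window.

    Mean removal, Hann taper, zero padding to ``pad_factor`` times the
    window length; the DF is the maximal-magnitude bin within
    ``band_hz``.  A flat signal yields ``found=False``.
    """
    t = np.asarray(times_ms, dtype=float)
    v = np.asarray(vm_mV, dtype=float)
    t0, t1 = window_s[0] * 1e3, window_s[1] * 1e3
    dt_samp = float(np.median(np.diff(t)))
    if t[0] > t0 + dt_samp or t[-1] < t1 - dt_samp:
        raise ModelError(
            f"trace [{t[0]:.0f}, {t[-1]:.0f}] ms does not cover the DF "
            f"window [{t0:.0f}, {t1:.0f}] ms")
    sel = (t >= t0) & (t <= t1)
    x = v[sel] - np.mean(v[sel])
    n = x.size
    if n < 8 or np.max(np.abs(x)) < 1e-9:
        return DFValue(False, window_s=tuple(window_s))
    fs = 1e3 / float(np.median(np.diff(t[sel])))  # Hz
    xw = x * np.hanning(n)
    nfft = pad_factor * n
    spec = np.abs(np.fft.rfft(xw, nfft))
    freqs = np.fft.rfftfreq(nfft, d=1.0 / fs)
    band = (freqs >= band_hz[0]) & (freqs <= band_hz[1])
    if not band.any():
        return DFValue(False, window_s=tuple(window_s))
    i = int(np.argmax(spec[band]))
    return DFValue(True, df_hz=float(freqs[band][i]),
                   power=float(spec[band][i] ** 2),
                   window_s=tuple(window_s))


def df_map(trace, region_labels: np.ndarray,
           window_s: tuple[float, float] = DF_WINDOW_S,
           band_hz: tuple[float, float] = DF_BAND_HZ):
    """Per-node dominant frequency plus a regional summary.

    The requested window must be covered by the trace; nodes without a
    resolvable spectral peak are NaN and reported in the summary counts.
    Vectorized across nodes (one FFT over the frame matrix).
    """
    t = trace.frame_times_ms
    t0, t1 = window_s[0] * 1e3, window_s[1] * 1e3
    dt_samp = float(np.median(np.diff(t)))
    if t[0] > t0 + dt_samp or t[-1] < t1 - dt_samp:
        raise ModelError(
            f"trace [{t[0]:.0f}, {t[-1]:.0f}] ms does not cover the DF "
            f"window [{t0:.0f}, {t1:.0f}] ms")
    sel = (t >= t0) & (t <= t1)
    x = trace.frames[sel].astype(float)
    x -= x.mean(axis=0)
    n = x.shape[0]
    fs = 1e3 / float(np.median(np.diff(t[sel])))
    nfft = 4 * n
    spec = np.abs(np.fft.rfft(x * np.hanning(n)[:, None], nfft, axis=0))
    freqs = np.fft.rfftfreq(nfft, d=1.0 / fs)
    band = (freqs >= band_hz[0]) & (freqs <= band_hz[1])
    peak = freqs[band][np.argmax(spec[band], axis=0)]
    flat = np.max(np.abs(x), axis=0) < 1e-9
    df = np.where(flat, np.nan, peak)
    df[region_labels < 0] = np.nan
    return df, RegionalSummary.from_values(df, region_labels)


def sustained_df_window(trace, outcome=None, length_s: float = 6.0,
                        window_s: tuple[float, float] = DF_WINDOW_S):
    """The DF window to use for a trace, shifted when observation is short.

    Returns the nominal window when the trace covers it; otherwise the
    last ``length_s`` seconds of the trace (or the full trace if shorter),
    so shortened observation windows still yield a recorded, reported
    window.
    """
    t_end_s = trace.t_end_ms / 1e3
    if t_end_s >= window_s[1]:
        return tuple(window_s)
    lo = max(0.0, t_end_s - length_s)
    return (lo, t_end_s)
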