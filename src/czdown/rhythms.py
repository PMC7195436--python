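"""Long/short cycle decomposition, gap handling and analytic phases.

The long cycle is a causal 2-day moving average (1440 samples on the
2-min grid); the short cycle is the residual smoothed by a causal
20-sample (40-min) moving average.  Gaps shorter than 2 h (60 samples)
are filled with Gaussian noise drawn from the non-missing statistics;
longer gaps stay missing and poison phase validity for 60 samples on
either side.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import find_peaks, hilbert

LONG_WINDOW = 1440
SHORT_WINDOW = 20
GAP_FILL_MAX = 60          # strictly-less-than threshold, samples
BOUNDARY_EXCLUSION = 60    # samples


class EmptySeriesError(ValueError):
    pass


class InsufficientSpanError(ValueError):
    pass


@dataclass
class RhythmSet:
    """Long- and short-cycle components of one feature signal plus phases."""

    long_cycle: np.ndarray
    short_cycle: np.ndarray
    long_phase: np.ndarray
    short_phase: np.ndarray
    valid: np.ndarray              # per-timestamp phase validity
    reduced_support: np.ndarray | None = None


def causal_moving_average(x: np.ndarray, window: int,
                          return_support: bool = False):
    """Trailing mean of the most recent ``window`` available samples.

    NaNs are ignored; the warm-up region (< window history) averages what
    exists.  Output is NaN only where no finite sample lies in the window.
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    x = np.asarray(x, dtype=float)
    finite = np.isfinite(x)
    vals = np.where(finite, x, 0.0)
    csum = np.concatenate([[0.0], np.cumsum(vals)])
    ccnt = np.concatenate([[0], np.cumsum(finite)])
    n = x.size
    idx = np.arange(n)
    lo = np.maximum(idx - window + 1, 0)
    s = csum[idx + 1] - csum[lo]
    c = ccnt[idx + 1] - ccnt[lo]
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(c > 0, s / np.maximum(c, 1), np.nan)
    if return_support:
        return out, c < window
    return out


def anticausal_moving_average(x: np.ndarray, window: int) -> np.ndarray:
    """Zero-lag variant: forward pass then backward pass of the same MA."""
    fwd = causal_moving_average(x, window)
    return causal_moving_average(fwd[::-1], window)[::-1]


def decompose(x: np.ndarray, long_window: int = LONG_WINDOW,
              short_window: int = SHORT_WINDOW,
              anticausal: bool = False) -> tuple[np.ndarray, np.ndarray]:
    """Split a feature series into (long_cycle, short_cycle)."""
    ma = anticausal_moving_average if anticausal else causal_moving_average
    long_cycle = ma(x, long_window)
    short_cycle = ma(np.asarray(x, dtype=float) - long_cycle, short_window)
    return long_cycle, short_cycle


def _gap_runs(missing: np.ndarray) -> list[tuple[int, int]]:
    """Half-open [start, stop) runs of True."""
    missing = np.asarray(missing, dtype=bool)
    if not missing.any():
        return []
    d = np.diff(missing.astype(int))
    starts = list(np.flatnonzero(d == 1) + 1)
    stops = list(np.flatnonzero(d == -1) + 1)
    if missing[0]:
        starts.insert(0, 0)
    if missing[-1]:
        stops.append(missing.size)
    return list(zip(starts, stops))


def fill_gaps(x: np.ndarray, max_gap: int = GAP_FILL_MAX, seed: int = 0,
              stats: str = "global") -> tuple[np.ndarray, list[tuple[int, int]]]:
    """Gaussian-fill gaps strictly shorter than ``max_gap`` samples.

    Fill statistics come from the non-missing data, either globally
    (``stats="global"``) or from the history preceding each gap
    (``stats="causal"``, for pseudoprospective use).  Each gap's draws are
    seeded by ``(seed, gap start)`` so fills are reproducible and do not
    depend on later data.  Longer gaps are left missing.  Returns the
    filled series and the list of filled ``[start, stop)`` runs.
    """
    x = np.asarray(x, dtype=float).copy()
    finite = np.isfinite(x)
    if not finite.any():
        raise EmptySeriesError("series is entirely missing")
    if stats == "global":
        g_mean, g_sd = float(x[finite].mean()), float(x[finite].std())
    filled: list[tuple[int, int]] = []
    for start, stop in _gap_runs(~finite):
        if stop - start >= max_gap:
            continue
        if stats == "causal":
            prior = x[:start][np.isfinite(x[:start])]
            if prior.size < 10:
                continue
            mean, sd = float(prior.mean()), float(prior.std())
        else:
            mean, sd = g_mean, g_sd
        rng = np.random.default_rng(np.random.SeedSequence([seed & 0x7FFFFFFF, start]))
        x[start:stop] = rng.normal(mean, sd, size=stop - start)
        filled.append((start, stop))
    return x, filled


def long_gap_runs(x: np.ndarray, max_gap: int = GAP_FILL_MAX) -> list[tuple[int, int]]:
    """Runs of missing samples at or above the fill threshold."""
    return [(a, b) for a, b in _gap_runs(~np.isfinite(np.asarray(x, dtype=float)))
            if b - a >= max_gap]


def analytic_phase(x: np.ndarray, long_gaps=None,
                   boundary_exclusion: int = BOUNDARY_EXCLUSION,
                   exclude_end: bool = True, seed: int = 0
                   ) -> tuple[np.ndarray, np.ndarray]:
    """Hilbert phase of a mean-removed cycle series, with validity flags.

    Any remaining long gaps are noise-filled (so the transform is
    computable), then marked invalid together with ``boundary_exclusion``
    samples on either side.  Record boundaries are excluded likewise; the
    trailing edge can be kept valid (``exclude_end=False``) for causal,
    real-time use where the record end IS the operating point.
    """
    x = np.asarray(x, dtype=float)
    if long_gaps is None:
        long_gaps = long_gap_runs(x, max_gap=1)   # any remaining missing run
    finite = np.isfinite(x)
    if not finite.any():
        raise EmptySeriesError("series is entirely missing")
    work = x.copy()
    if not finite.all():
        mean, sd = float(x[finite].mean()), float(x[finite].std())
        rng = np.random.default_rng(np.random.SeedSequence([seed & 0x7FFFFFFF, 991]))
        work[~finite] = rng.normal(mean, sd if sd > 0 else 1.0, size=(~finite).sum())
    analytic = hilbert(work - work.mean())
    phase = np.angle(analytic)
    phase = np.mod(phase + np.pi, 2 * np.pi) - np.pi
    valid = np.ones(x.size, dtype=bool)
    for start, stop in long_gaps:
        valid[max(0, start - boundary_exclusion):stop + boundary_exclusion] = False
    if boundary_exclusion > 0:
        valid[:boundary_exclusion] = False
        if exclude_end:
            valid[-boundary_exclusion:] = False
    return phase, valid


def edge_phase(cycle: np.ndarray, exclude: int, fit_window: int) -> float:
    """Phase at the last sample, by linear extrapolation of interior phase.

    The Hilbert phase of a truncated record is distorted near the trailing
    edge — exactly the operating point of a real-time forecast.  This
    estimator unwraps the interior phase, fits a line over
    ``[-exclude - fit_window, -exclude)`` and extrapolates to the final
    sample, which tracks slowly varying rhythms far better than the raw
    edge value.
    """
    cycle = np.asarray(cycle, dtype=float)
    finite = np.isfinite(cycle)
    if not finite.any():
        raise EmptySeriesError("cycle series is entirely missing")
    work = cycle.copy()
    if not finite.all():
        work[~finite] = float(cycle[finite].mean())
    ph = np.unwrap(np.angle(hilbert(work - work.mean())))
    n = ph.size
    hi = max(n - exclude, 2)
    lo = max(hi - fit_window, 0)
    if hi - lo < 2:
        return float(np.mod(ph[-1] + np.pi, 2 * np.pi) - np.pi)
    t = np.arange(lo, hi)
    slope, intercept = np.polyfit(t, ph[lo:hi], 1)
    est = slope * (n - 1) + intercept
    return float(np.mod(est + np.pi, 2 * np.pi) - np.pi)


def edge_phase_projection(cycle: np.ndarray, fit_window: int,
                          period_band: tuple[float, float]) -> float:
    """Phase at the last sample via least-squares sinusoid projection.

    The dominant period inside ``period_band`` (samples) is taken from the
    spectrum of the trailing ``3 * fit_window`` samples; a sinusoid at
    that frequency is then fit over the trailing ``fit_window`` samples.
    Unlike the raw Hilbert edge value this has no boundary bias and
    averages noise over the whole fit window, which makes it the
    estimator of choice for noisy short (circadian) cycles.
    """
    x = np.asarray(cycle, dtype=float)
    x = x[np.isfinite(x)]
    if x.size < 8:
        raise EmptySeriesError("too few finite samples for edge phase")
    seg = x[-min(3 * fit_window, x.size):]
    seg = seg - seg.mean()
    spec = np.abs(np.fft.rfft(seg))
    freqs = np.fft.rfftfreq(seg.size)
    with np.errstate(divide="ignore"):
        periods = 1.0 / np.maximum(freqs, 1e-12)
    sel = (freqs > 0) & (periods >= period_band[0]) & (periods <= period_band[1])
    if not sel.any():
        raise InsufficientSpanError("no spectral support inside the period band")
    f0 = freqs[sel][int(np.argmax(spec[sel]))]
    w = x[-min(fit_window, x.size):]
    t = np.arange(w.size, dtype=float) - (w.size - 1)   # 0 at the last sample
    design = np.column_stack([np.ones_like(t),
                              np.cos(2 * np.pi * f0 * t),
                              np.sin(2 * np.pi * f0 * t)])
    coef, *_ = np.linalg.lstsq(design, w, rcond=None)
    # w ~ b cos(wt) + c sin(wt) = A cos(wt - phi) with phi = atan2(c, b);
    # at t = 0 the instantaneous phase is -phi relative to the cosine peak
    return float(np.arctan2(-coef[2], coef[1]))


def extract_rhythms(x: np.ndarray, seed: int = 0, anticausal: bool = False,
                    long_window: int = LONG_WINDOW, short_window: int = SHORT_WINDOW,
                    max_gap: int = GAP_FILL_MAX,
                    boundary_exclusion: int = BOUNDARY_EXCLUSION,
                    exclude_end: bool = True,
                    stats: str = "global") -> RhythmSet:
    """Full per-signal pipeline: fill short gaps, decompose, phase-extract."""
    x = np.asarray(x, dtype=float)
    filled, _ = fill_gaps(x, max_gap=max_gap, seed=seed, stats=stats)
    gaps = long_gap_runs(filled, max_gap=1)
    long_cycle, short_cycle = decompose(filled, long_window, short_window,
                                        anticausal=anticausal)
    long_phase, valid_l = analytic_phase(long_cycle, gaps, boundary_exclusion,
                                         exclude_end, seed=seed + 1)
    short_phase, valid_s = analytic_phase(short_cycle, gaps, boundary_exclusion,
                                          exclude_end, seed=seed + 2)
    _, reduced = causal_moving_average(filled, long_window, return_support=True)
    return RhythmSet(long_cycle, short_cycle, long_phase, short_phase,
                     valid_l & valid_s, reduced)


def dominant_periods(x: np.ndarray, cadence_s: float = 120.0, seed: int = 0,
                     prominence_sigma: float = 3.0,
                     circadian_band_days: tuple[float, float] = (0.9, 1.1),
                     multidien_band_days: tuple[float, float] = (3.0, 30.0)) -> dict:
    """Spectral peaks of a (noise-filled, mean-removed) feature series.

    Returns ``{"peaks": [(period_days, power), ...], "circadian": bool,
    "multidien": bool}`` with peaks sorted by power.  Requires the record
    to span at least twice the longest period sought.
    """
    x = np.asarray(x, dtype=float)
    span_days = x.size * cadence_s / 86400.0
    if span_days < 2 * circadian_band_days[1]:
        raise InsufficientSpanError(
            f"record spans {span_days:.2f} d; need >= {2 * circadian_band_days[1]} d")
    finite = np.isfinite(x)
    if not finite.any():
        raise EmptySeriesError("series is entirely missing")
    work = x.copy()
    if not finite.all():
        mean, sd = float(x[finite].mean()), float(x[finite].std())
        rng = np.random.default_rng(np.random.SeedSequence([seed & 0x7FFFFFFF, 421]))
        work[~finite] = rng.normal(mean, sd if sd > 0 else 1.0, size=(~finite).sum())
    spec = np.abs(np.fft.rfft(work - work.mean()))
    freqs = np.fft.rfftfreq(work.size, d=cadence_s)          # Hz
    spec, freqs = spec[1:], freqs[1:]                        # drop DC
    floor = np.median(spec)
    noise_sd = np.median(np.abs(spec - floor)) * 1.4826      # robust sigma
    idx, _ = find_peaks(spec, height=floor + prominence_sigma * noise_sd,
                        prominence=prominence_sigma * noise_sd)
    periods_days = 1.0 / freqs[idx] / 86400.0
    order = np.argsort(spec[idx])[::-1]
    peaks = [(float(periods_days[i]), float(spec[idx[i]])) for i in order]
    circ = any(circadian_band_days[0] <= p <= circadian_band_days[1] for p, _ in peaks)
    multi = any(multidien_band_days[0] <= p <= multidien_band_days[1] for p, _ in peaks)
    return {"peaks": peaks, "circadian": circ, "multidien": multi,
            "span_days": span_days, "freq_resolution_per_day": 1.0 / span_days}
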