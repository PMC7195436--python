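"""Biomarker extraction: segment variance, autocorrelation width, spike rate.

Per-segment estimators follow the population conventions used throughout:
variance with divisor ``T`` and the biased autocorrelation

    C_lag = (1/T) * sum_{t=1..T-lag} (y_t - mean)(y_{t+lag} - mean) / V_y

so that ``C_0 == 1`` exactly.  The slowing biomarker is the width of the
autocorrelation at half maximum (first downward 0.5-crossing, linearly
interpolated between bracketing lags).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal as sps

from .segments import SegmentStream


class DegenerateSegmentError(ValueError):
    """Segment variance is zero; the autocorrelation is undefined."""


class InvalidTemplateError(ValueError):
    pass


DEFAULT_MAX_LAG = 200  # half the 1-s window at 400 Hz


@dataclass
class FeatureSeries:
    """Per-channel biomarker values on the segment time grid.

    ``acfw`` is in lag-samples (units of 1/rate_hz seconds), ``variance``
    in squared signal units, ``spike_rate`` in detections per segment.
    Missing entries are NaN and flagged in ``mask``.
    """

    timestamps: np.ndarray
    acfw: np.ndarray           # (n_channels, n_segments)
    variance: np.ndarray
    spike_rate: np.ndarray
    mask: np.ndarray           # (n_segments,) True = missing
    cadence_min: float = 2.0
    rate_hz: float = 400.0
    metadata: dict = field(default_factory=dict)

    SIGNALS = ("acfw", "variance", "spike_rate")

    def __post_init__(self) -> None:
        self.timestamps = np.asarray(self.timestamps, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        for name in self.SIGNALS:
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.ndim == 1:
                arr = arr[None, :]
            setattr(self, name, arr)

    @property
    def n_channels(self) -> int:
        return self.acfw.shape[0]

    @property
    def n_segments(self) -> int:
        return self.timestamps.shape[0]

    def signal(self, name: str) -> np.ndarray:
        if name not in self.SIGNALS:
            raise KeyError(f"unknown signal {name!r}")
        return getattr(self, name)

    def mask_spans(self, spans_s) -> "FeatureSeries":
        """Return a copy with segments inside ``(start_s, stop_s)`` spans masked."""
        mask = self.mask.copy()
        for start, stop in spans_s:
            mask |= (self.timestamps >= start) & (self.timestamps < stop)
        out = FeatureSeries(
            self.timestamps.copy(), self.acfw.copy(), self.variance.copy(),
            self.spike_rate.copy(), mask, self.cadence_min, self.rate_hz,
            dict(self.metadata),
        )
        for name in self.SIGNALS:
            getattr(out, name)[:, mask] = np.nan
        return out

    def to_csv(self, path) -> None:
        frames = []
        for ch in range(self.n_channels):
            frames.append(pd.DataFrame({
                "timestamp_s": self.timestamps,
                "channel": ch,
                "acfw": self.acfw[ch],
                "variance": self.variance[ch],
                "spikes": self.spike_rate[ch],
            }))
        pd.concat(frames, ignore_index=True).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, cadence_min: float = 2.0, rate_hz: float = 400.0) -> "FeatureSeries":
        df = pd.read_csv(path)
        ts = np.sort(df["timestamp_s"].unique())
        channels = np.sort(df["channel"].unique())
        shape = (len(channels), len(ts))
        acfw = np.full(shape, np.nan)
        var = np.full(shape, np.nan)
        spk = np.full(shape, np.nan)
        t_index = {t: i for i, t in enumerate(ts)}
        for ch_i, ch in enumerate(channels):
            sub = df[df["channel"] == ch]
            idx = np.array([t_index[t] for t in sub["timestamp_s"]])
            acfw[ch_i, idx] = sub["acfw"].to_numpy()
            var[ch_i, idx] = sub["variance"].to_numpy()
            spk[ch_i, idx] = sub["spikes"].to_numpy()
        mask = np.all(np.isnan(acfw), axis=0)
        return cls(ts, acfw, var, spk, mask, cadence_min, rate_hz)


# ---------------------------------------------------------------------------
# low-pass pre-processing of raw 3-s snapshots
# ---------------------------------------------------------------------------

def design_lowpass(rate_hz: float, cutoff_hz: float = 170.0, numtaps: int = 201) -> np.ndarray:
    if rate_hz <= 2 * cutoff_hz:
        raise ValueError("sampling rate must exceed twice the cutoff")
    return sps.firwin(numtaps, cutoff_hz, fs=rate_hz)


def preprocess_segment(raw: np.ndarray, rate_hz: float = 400.0,
                       cutoff_hz: float = 170.0, taps: np.ndarray | None = None) -> np.ndarray:
    """FIR low-pass a 3-s snapshot and keep the central second.

    Dropping the edge seconds removes the filter transients, so a
    zero-phase (forward-backward) application keeps the retained second
    aligned with the raw timeline.
    """
    raw = np.asarray(raw, dtype=float)
    n_expected = int(round(3 * rate_hz))
    if raw.shape[-1] != n_expected:
        raise ValueError(f"malformed segment: expected {n_expected} samples, got {raw.shape[-1]}")
    if taps is None:
        taps = design_lowpass(rate_hz, cutoff_hz)
    filtered = sps.filtfilt(taps, [1.0], raw, axis=-1)
    n = int(round(rate_hz))
    return filtered[..., n:2 * n]


# ---------------------------------------------------------------------------
# variance / autocorrelation estimators
# ---------------------------------------------------------------------------

def segment_variance(y: np.ndarray) -> float:
    """Population variance (divisor T)."""
    y = np.asarray(y, dtype=float)
    if y.size < 2:
        raise ValueError("need at least 2 samples")
    return float(np.mean((y - y.mean()) ** 2))


def autocorrelation_function(y: np.ndarray, max_lag: int = DEFAULT_MAX_LAG) -> np.ndarray:
    """Biased sample autocorrelation ``C_0..C_max_lag`` (``C_0 == 1``)."""
    y = np.asarray(y, dtype=float)
    T = y.size
    if max_lag >= T:
        raise ValueError("max_lag must be smaller than the segment length")
    d = y - y.mean()
    v = np.mean(d * d)
    if v == 0:
        raise DegenerateSegmentError("zero-variance segment: ACF undefined")
    acov = np.correlate(d, d, mode="full")[T - 1:T + max_lag]
    return acov / (T * v)


def acf_halfwidth(C: np.ndarray) -> tuple[float, bool]:
    """First lag at which the ACF drops to 0.5, linearly interpolated.

    Returns ``(width, saturated)``; when the ACF never reaches 0.5 within
    the available lags the maximum lag is returned with ``saturated=True``.
    """
    C = np.asarray(C, dtype=float)
    below = C <= 0.5
    if not below.any():
        return float(C.size - 1), True
    lam = int(np.argmax(below))
    if lam == 0:
        return 0.0, False
    c_hi, c_lo = C[lam - 1], C[lam]
    frac = (c_hi - 0.5) / (c_hi - c_lo)
    return float(lam - 1 + frac), False


def _batch_acf(data: np.ndarray, max_lag: int) -> tuple[np.ndarray, np.ndarray]:
    """FFT autocorrelation for a batch of segments.

    ``data`` has shape (..., T); returns (acf (..., max_lag+1), variance (...)).
    Degenerate segments yield NaN ACF rows.
    """
    T = data.shape[-1]
    d = data - np.nanmean(data, axis=-1, keepdims=True)
    v = np.mean(d * d, axis=-1)
    nfft = int(2 ** np.ceil(np.log2(2 * T)))
    spec = np.fft.rfft(d, n=nfft, axis=-1)
    acov = np.fft.irfft(spec * np.conj(spec), n=nfft, axis=-1)[..., :max_lag + 1]
    with np.errstate(invalid="ignore", divide="ignore"):
        acf = acov / (T * v[..., None])
    acf[v == 0] = np.nan
    return acf, v


def _batch_halfwidth(acf: np.ndarray) -> np.ndarray:
    """Vectorized half-maximum width over the last axis; NaN rows stay NaN."""
    n_lag = acf.shape[-1]
    below = acf <= 0.5
    has = below.any(axis=-1)
    lam = np.argmax(below, axis=-1)
    lam_safe = np.clip(lam, 1, n_lag - 1)
    c_hi = np.take_along_axis(acf, (lam_safe - 1)[..., None], axis=-1)[..., 0]
    c_lo = np.take_along_axis(acf, lam_safe[..., None], axis=-1)[..., 0]
    with np.errstate(invalid="ignore", divide="ignore"):
        width = lam_safe - 1 + (c_hi - 0.5) / (c_hi - c_lo)
    width = np.where(lam == 0, 0.0, width)
    width = np.where(has, width, float(n_lag - 1))
    width = np.where(np.isnan(acf[..., 0]), np.nan, width)
    return width


# ---------------------------------------------------------------------------
# spike template construction and detection
# ---------------------------------------------------------------------------

def build_spike_template(candidates, align: bool = True) -> np.ndarray:
    """Average aligned candidate waveforms into a unit-norm template.

    Candidates are peak-aligned (on the absolute maximum) before the
    pointwise mean; the result is L2-normalized.
    """
    arrs = [np.asarray(c, dtype=float) for c in candidates]
    if len(arrs) < 2:
        raise ValueError("need at least 2 candidate waveforms")
    n = arrs[0].size
    if any(a.size != n for a in arrs):
        raise ValueError("candidate waveforms must have equal length")
    if align:
        peaks = [int(np.argmax(np.abs(a))) for a in arrs]
        ref = peaks[0]
        arrs = [np.roll(a, ref - p) for a, p in zip(arrs, peaks)]
    template = np.mean(arrs, axis=0)
    norm = np.linalg.norm(template)
    if norm == 0:
        raise InvalidTemplateError("candidates average to a flat template")
    return template / norm


def detect_spikes(y: np.ndarray, template: np.ndarray,
                  threshold: float = 0.85) -> tuple[int, np.ndarray]:
    """Count template matches via sliding normalized (signed) correlation.

    Local maxima of the Pearson correlation above ``threshold`` are kept
    with greedy non-overlap suppression of one template length.
    """
    y = np.asarray(y, dtype=float)
    template = np.asarray(template, dtype=float)
    L = template.size
    if L >= y.size:
        raise InvalidTemplateError("template must be shorter than the segment")
    if not 0 < threshold <= 1:
        raise ValueError("threshold must be in (0, 1]")
    t_sd = template.std()
    if t_sd == 0:
        raise InvalidTemplateError("flat template")
    windows = np.lib.stride_tricks.sliding_window_view(y, L)
    w_mean = windows.mean(axis=-1)
    w_sd = windows.std(axis=-1)
    num = windows @ (template - template.mean())
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = num / (L * w_sd * t_sd)
    corr = np.nan_to_num(corr, nan=-1.0)
    order = np.argsort(corr)[::-1]
    taken: list[int] = []
    for idx in order:
        if corr[idx] < threshold:
            break
        if all(abs(idx - t) >= L for t in taken):
            taken.append(int(idx))
    taken.sort()
    return len(taken), np.array(taken, dtype=int)


# ---------------------------------------------------------------------------
# full-stream extraction
# ---------------------------------------------------------------------------

def compute_features(stream: SegmentStream, template: np.ndarray | None = None,
                     max_lag: int = DEFAULT_MAX_LAG,
                     spike_threshold: float = 0.85) -> FeatureSeries:
    """ACFW, variance and (optionally) spike counts for every segment.

    Masked segments propagate as NaN.  Spike counting is skipped (zeros)
    when no template is supplied.
    """
    data = stream.data.astype(float)
    n_ch, n_seg, _ = data.shape
    acf, var = _batch_acf(np.nan_to_num(data, nan=0.0), max_lag)
    acfw = _batch_halfwidth(acf)
    spikes = np.zeros((n_ch, n_seg), dtype=float)
    if template is not None:
        for ch in range(n_ch):
            for si in np.flatnonzero(~stream.mask):
                count, _ = detect_spikes(data[ch, si], template, spike_threshold)
                spikes[ch, si] = count
    missing = stream.mask
    for arr in (acfw, var, spikes):
        arr[:, missing] = np.nan
    return FeatureSeries(
        timestamps=stream.timestamps, acfw=acfw, variance=var, spike_rate=spikes,
        mask=missing.copy(), cadence_min=stream.cadence_min, rate_hz=stream.rate_hz,
        metadata={"max_lag": max_lag},
    )


# ---------------------------------------------------------------------------
# fine-scale peri-seizure analysis
# ---------------------------------------------------------------------------

@dataclass
class PeriSeizureProfile:
    rel_time_s: np.ndarray
    acfw_norm: np.ndarray
    var_norm: np.ndarray
    peak: tuple[float, float]        # (value, rel_time_s) of the ACFW peak
    trough: tuple[float, float]      # (value, rel_time_s) after the peak
    baseline_window_s: tuple[float, float]
    baseline_shrunk: bool = False


def periseizure_profile(continuous: np.ndarray, rate_hz: float, onset_s: float,
                        seizure_duration_s: float = 60.0,
                        window_s: float = 5.0, overlap_s: float = 0.5,
                        span_h: float = 3.0, baseline_min: float = 5.0,
                        record_start_s: float = 0.0,
                        literal_overlap: bool = True,
                        max_lag: int = DEFAULT_MAX_LAG) -> PeriSeizureProfile:
    """Windowed ACFW/variance around one onset, baseline-normalized.

    ``literal_overlap=True`` reads "half a second overlap" as consecutive
    5-s windows sharing 0.5 s (4.5-s step); ``False`` uses a 0.5-s step.
    The peak is searched in [-5 min, onset + seizure duration] and the
    trough after the peak within the post-onset search window.
    """
    continuous = np.asarray(continuous, dtype=float)
    step_s = window_s - overlap_s if literal_overlap else overlap_s
    n_win = int(window_s * rate_hz)
    step = max(1, int(step_s * rate_hz))
    onset_idx = (onset_s - record_start_s) * rate_hz
    span = span_h * 3600.0
    starts = np.arange(0, continuous.size - n_win + 1, step)
    centers_s = record_start_s + (starts + n_win / 2) / rate_hz
    keep = np.abs(centers_s - onset_s) <= span
    starts, centers_s = starts[keep], centers_s[keep]
    if starts.size == 0:
        raise ValueError("no complete windows around the onset")
    windows = np.stack([continuous[s:s + n_win] for s in starts])
    lag = min(max_lag, n_win - 1)
    acf, var = _batch_acf(windows, lag)
    acfw = _batch_halfwidth(acf)
    rel = centers_s - onset_s

    base_lo, base_hi = -baseline_min * 60.0, 0.0
    in_base = (rel >= base_lo) & (rel < base_hi)
    shrunk = False
    if not in_base.any():
        in_base = rel < 0
        shrunk = True
        warnings.warn("insufficient pre-onset data; baseline shrunk to available history")
    if not in_base.any():
        raise ValueError("no pre-onset data for baseline normalization")
    acfw_n = acfw / np.nanmean(acfw[in_base])
    var_n = var / np.nanmean(var[in_base])

    search = (rel >= -300.0) & (rel <= seizure_duration_s)
    idx_search = np.flatnonzero(search)
    pk_local = idx_search[int(np.nanargmax(acfw_n[idx_search]))]
    peak = (float(acfw_n[pk_local]), float(rel[pk_local]))
    after = np.flatnonzero((np.arange(rel.size) > pk_local)
                           & (rel <= seizure_duration_s + 600.0))
    if after.size:
        tr_local = after[int(np.nanargmin(acfw_n[after]))]
        trough = (float(acfw_n[tr_local]), float(rel[tr_local]))
    else:
        trough = (float("nan"), float("nan"))
    return PeriSeizureProfile(rel, acfw_n, var_n, peak, trough,
                              (base_lo, base_hi), shrunk)
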