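"""Phase-locking between seizures and cycle phases, channel selection and
cross-electrode signal similarity.

The synchronization index is the modulus of the mean unit phasor,
``SI = |mean(exp(i theta))|``: 1 for perfect locking, 0 for uniform
phases.  Seizure phases are always taken at the last valid sample
strictly before the onset.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .rhythms import causal_moving_average


def _wrap(phi):
    return np.mod(np.asarray(phi) + np.pi, 2 * np.pi) - np.pi


def synchronization_index(phases) -> tuple[float, float]:
    """``(SI, mean_phase)`` of a set of phases (radians)."""
    phases = np.asarray(phases, dtype=float)
    if phases.size == 0:
        raise ValueError("empty phase set")
    if not np.all(np.isfinite(phases)):
        raise ValueError("phases must be finite")
    phasor = np.exp(1j * phases).mean()
    return float(np.abs(phasor)), float(np.angle(phasor))


@dataclass
class SeizurePhaseSample:
    seizure_id: int
    phase: float
    valid: bool
    sample_index: int


def seizure_phases(phase_series: np.ndarray, valid: np.ndarray,
                   timestamps_s: np.ndarray, onsets_s: np.ndarray
                   ) -> list[SeizurePhaseSample]:
    """Phase at the sample prior to each onset (strictly earlier timestamp).

    Seizures whose prior sample is invalid (dropout-adjacent) carry
    ``valid=False`` and are excluded from SI/histogram computations.
    """
    out: list[SeizurePhaseSample] = []
    for sid, onset in enumerate(np.asarray(onsets_s, dtype=float)):
        idx = int(np.searchsorted(timestamps_s, onset, side="left")) - 1
        if idx < 0:
            out.append(SeizurePhaseSample(sid, np.nan, False, -1))
            continue
        ok = bool(valid[idx]) and np.isfinite(phase_series[idx])
        out.append(SeizurePhaseSample(sid, float(phase_series[idx]) if ok else np.nan,
                                      ok, idx))
    return out


def valid_phases(samples) -> np.ndarray:
    return np.array([s.phase for s in samples if s.valid])


def seizure_phase_histogram(phases, n_bins: int = 20) -> dict:
    """Equal-width histogram over [-pi, pi) plus the unbinned SI."""
    phases = _wrap(np.asarray(phases, dtype=float))
    if phases.size == 0:
        raise ValueError("need at least one valid seizure phase")
    edges = np.linspace(-np.pi, np.pi, n_bins + 1)
    idx = np.clip(((phases + np.pi) / (2 * np.pi) * n_bins).astype(int), 0, n_bins - 1)
    counts = np.bincount(idx, minlength=n_bins)
    si, mean_phase = synchronization_index(phases)
    return {"counts": counts, "normalized": counts / counts.sum(),
            "edges": edges, "si": si, "mean_phase": mean_phase}


def signal_phase_uniformity(phase_series: np.ndarray,
                            valid: np.ndarray | None = None) -> float:
    """SI of the signal's own (validity-masked) phase occupancy."""
    phase_series = np.asarray(phase_series, dtype=float)
    if valid is not None:
        phase_series = phase_series[np.asarray(valid, dtype=bool)]
    phase_series = phase_series[np.isfinite(phase_series)]
    si, _ = synchronization_index(phase_series)
    return si


def select_channel(si_per_channel) -> tuple[int, bool]:
    """Argmax-SI channel; exact ties break to the lowest index.

    Returns ``(channel, tied)``.  All-missing rows are excluded.
    """
    si = np.asarray(si_per_channel, dtype=float)
    finite = np.isfinite(si)
    if not finite.any():
        raise ValueError("no channel has a defined SI")
    best = np.nanmax(si)
    winners = np.flatnonzero(finite & (si == best))
    return int(winners[0]), bool(winners.size > 1)


def electrode_similarity(feature_matrix: np.ndarray,
                         smooth_window: int = 20) -> dict:
    """Mean off-diagonal Pearson correlation across channels.

    Each channel series is smoothed by a causal moving average, then
    timestamps missing on ANY channel are removed (listwise) before the
    channel-by-channel correlation matrix is formed.  The reported mean
    covers the strictly-upper-triangle entries.
    """
    X = np.asarray(feature_matrix, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("need a (channels, time) matrix with >= 2 channels")
    sm = np.vstack([causal_moving_average(row, smooth_window) for row in X])
    keep = np.all(np.isfinite(sm), axis=0)
    if keep.sum() < 2:
        raise ValueError("fewer than 2 overlapping valid samples")
    sm = sm[:, keep]
    corr = np.corrcoef(sm)
    iu = np.triu_indices_from(corr, k=1)
    vals = corr[iu]
    ok = np.isfinite(vals)
    return {"matrix": corr, "mean": float(vals[ok].mean()),
            "n_pairs": int(ok.sum()), "n_excluded_pairs": int((~ok).sum()),
            "n_samples": int(keep.sum())}


def per_channel_seizure_si(phase_stack: np.ndarray, valid_stack: np.ndarray,
                           timestamps_s: np.ndarray, onsets_s: np.ndarray
                           ) -> np.ndarray:
    """Seizure SI per channel for one (signal, cycle) pair.

    ``phase_stack``/``valid_stack`` are (n_channels, n_time).  Channels
    with no valid seizure phase get NaN.
    """
    n_ch = phase_stack.shape[0]
    out = np.full(n_ch, np.nan)
    for ch in range(n_ch):
        phases = valid_phases(seizure_phases(phase_stack[ch], valid_stack[ch],
                                             timestamps_s, onsets_s))
        if phases.size:
            out[ch], _ = synchronization_index(phases)
    return out
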