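"""Phase-conditioned seizure probability, risk thresholds and forecasting.

Per (signal, cycle) pair the per-sample seizure probability in a phase
bin is ``P(S|theta) = S_theta / N_theta`` (seizures in the bin over
visits to the bin).  The six tables are combined multiplicatively under
an independence assumption.  Two optimized thresholds split the combined
trace into low/medium/high risk; the scalar score is the "performance
product" = (fraction of time in low) x (fraction of seizures in high).

Method M1 is within-sample (anti-causal rhythm filtering, trained on all
seizures, strict threshold criteria).  Method M2 is pseudoprospective:
bootstrapped from the first 10 seizures, refit after every seizure on a
trailing 50-day window, causal filtering only, relaxed criteria.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .features import FeatureSeries
from .rhythms import edge_phase, edge_phase_projection, extract_rhythms
from .segments import SeizureCatalog
from .synchrony import per_channel_seizure_si, seizure_phases, select_channel, valid_phases

CYCLES = ("long", "short")


class UntrainableError(ValueError):
    """No valid seizure phases to train a probability model on."""


class NoFeasibleSolutionError(RuntimeError):
    """Strict threshold criteria (C3/C4) admit no solution."""


class InsufficientHistoryError(ValueError):
    """Method M2 requires at least bootstrap + 1 seizures."""


def _wrap(phi):
    return np.mod(np.asarray(phi) + np.pi, 2 * np.pi) - np.pi


def phase_bin_index(phases, n_bins: int = 20) -> np.ndarray:
    """Bin index over [-pi, pi): -pi maps to bin 0, pi - eps to the last."""
    phases = _wrap(np.asarray(phases, dtype=float))
    return np.clip(((phases + np.pi) / (2 * np.pi) * n_bins).astype(int), 0, n_bins - 1)


@dataclass
class PhaseTable:
    """One (signal, cycle) probability-given-phase table."""

    probs: np.ndarray
    s_counts: np.ndarray
    n_counts: np.ndarray
    edges: np.ndarray
    empty_bins: np.ndarray

    def lookup(self, phases) -> np.ndarray:
        return self.probs[phase_bin_index(phases, self.probs.size)]


def probability_given_phase(signal_phases: np.ndarray, signal_valid: np.ndarray,
                            seizure_phases_rad: np.ndarray,
                            n_bins: int = 20) -> PhaseTable:
    """``S_theta / N_theta`` per phase bin; empty bins get 0 and a flag."""
    seizure_phases_rad = np.asarray(seizure_phases_rad, dtype=float)
    seizure_phases_rad = seizure_phases_rad[np.isfinite(seizure_phases_rad)]
    if seizure_phases_rad.size == 0:
        raise UntrainableError("zero valid seizure phases")
    sig = np.asarray(signal_phases, dtype=float)
    ok = np.asarray(signal_valid, dtype=bool) & np.isfinite(sig)
    n_counts = np.bincount(phase_bin_index(sig[ok], n_bins), minlength=n_bins)
    s_counts = np.bincount(phase_bin_index(seizure_phases_rad, n_bins), minlength=n_bins)
    with np.errstate(invalid="ignore", divide="ignore"):
        probs = np.where(n_counts > 0, s_counts / np.maximum(n_counts, 1), 0.0)
    return PhaseTable(probs, s_counts, n_counts,
                      np.linspace(-np.pi, np.pi, n_bins + 1), n_counts == 0)


def combine_probabilities(tables: dict, phase_sets: dict
                          ) -> tuple[np.ndarray, np.ndarray]:
    """Pointwise product of bin-looked-up probabilities.

    ``tables`` maps ``(signal, cycle)`` to :class:`PhaseTable`;
    ``phase_sets`` maps the same keys to ``(phases, valid)`` on a common
    grid.  Timestamps invalid in any component are masked (NaN).
    """
    keys = list(tables)
    n = phase_sets[keys[0]][0].size
    p = np.ones(n)
    valid = np.ones(n, dtype=bool)
    for key in keys:
        phases, v = phase_sets[key]
        valid &= np.asarray(v, dtype=bool) & np.isfinite(phases)
        safe = np.where(np.isfinite(phases), phases, 0.0)
        p *= tables[key].lookup(safe)
    p[~valid] = np.nan
    return p, valid


# ---------------------------------------------------------------------------
# threshold optimization and risk mapping
# ---------------------------------------------------------------------------

def optimize_thresholds(trace: np.ndarray, valid: np.ndarray,
                        seizure_probs: np.ndarray, mode: str = "strict",
                        max_candidates: int = 512) -> tuple[float, float, dict]:
    """Brute-force search for (Th1 <= Th2) maximizing C1 x C2.

    C1 = fraction of (valid) time below Th1, C2 = fraction of seizures at
    or above Th2.  ``mode="strict"`` zeroes grid points violating the
    ordering criteria C3 (time: low > med > high) and C4 (seizures:
    low < med < high) and raises :class:`NoFeasibleSolutionError` when
    nothing survives.  The candidate grid is the sorted set of unique
    trace values (quantile-thinned above ``max_candidates``) plus an
    above-maximum sentinel, which is exhaustive for the step-valued
    objective.  Ties break toward more time in low, then larger Th2.
    """
    trace = np.asarray(trace, dtype=float)
    pv = trace[np.asarray(valid, dtype=bool) & np.isfinite(trace)]
    sz = np.asarray(seizure_probs, dtype=float)
    sz = sz[np.isfinite(sz)]
    if sz.size == 0:
        raise UntrainableError("no scored seizures for threshold optimization")
    if pv.size == 0:
        raise UntrainableError("empty probability trace")
    vals = np.unique(pv)
    if vals.size > max_candidates:
        qs = np.quantile(vals, np.linspace(0, 1, max_candidates))
        vals = np.unique(qs)
    cand = np.append(vals, vals[-1] + max(1e-12, abs(vals[-1]) * 1e-9))
    sorted_p = np.sort(pv)
    sorted_s = np.sort(sz)
    F = np.searchsorted(sorted_p, cand, side="left") / pv.size
    Fs = np.searchsorted(sorted_s, cand, side="left") / sz.size

    time_low = F[:, None]
    time_med = F[None, :] - F[:, None]
    time_high = 1.0 - F[None, :]
    seiz_low = Fs[:, None]
    seiz_med = Fs[None, :] - Fs[:, None]
    seiz_high = 1.0 - Fs[None, :]

    obj = time_low * seiz_high
    upper = cand[:, None] <= cand[None, :]
    feasible = upper.copy()
    if mode == "strict":
        feasible &= (time_low > time_med) & (time_med > time_high)
        feasible &= (seiz_low < seiz_med) & (seiz_med < seiz_high)
        if not feasible.any():
            raise NoFeasibleSolutionError(
                "criteria C3/C4 cannot be satisfied on this trace")
    obj = np.where(feasible, obj, -np.inf)
    best = obj.max()
    ii, jj = np.nonzero(obj == best)
    order = np.lexsort((cand[jj], F[ii]))      # last entry = preferred tie-break
    pick = order[-1]
    i, j = int(ii[pick]), int(jj[pick])
    diag = {
        "objective": float(best),
        "time_fractions": (float(F[i]), float(F[j] - F[i]), float(1 - F[j])),
        "seizure_fractions": (float(Fs[i]), float(Fs[j] - Fs[i]), float(1 - Fs[j])),
        "n_candidates": int(cand.size),
        "mode": mode,
    }
    return float(cand[i]), float(cand[j]), diag


def risk_levels(trace: np.ndarray, th1: float, th2: float) -> np.ndarray:
    """Map probabilities to levels 1/2/3 (low/medium/high); NaN -> 0.

    Boundary convention: ``p < Th1`` low, ``Th1 <= p < Th2`` medium,
    ``p >= Th2`` high.
    """
    if th1 > th2:
        raise ValueError("Th1 must not exceed Th2")
    trace = np.asarray(trace, dtype=float)
    levels = np.ones(trace.shape, dtype=np.int8)
    levels[trace >= th1] = 2
    levels[trace >= th2] = 3
    levels[~np.isfinite(trace)] = 0
    return levels


@dataclass
class ForecastReport:
    method: str
    seizure_fractions: tuple[float, float, float]
    time_fractions: tuple[float, float, float]
    performance_product: float
    mean_risk: float
    n_seizures_scored: int
    n_seizures_excluded: int
    thresholds: tuple[float, float]
    roc: dict | None = None
    diagnostics: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        out = {
            "method": self.method,
            "seizure_fractions": list(self.seizure_fractions),
            "time_fractions": list(self.time_fractions),
            "performance_product": self.performance_product,
            "mean_risk": self.mean_risk,
            "n_seizures_scored": self.n_seizures_scored,
            "n_seizures_excluded": self.n_seizures_excluded,
            "thresholds": list(self.thresholds),
            "diagnostics": {k: v for k, v in self.diagnostics.items()
                            if isinstance(v, (str, int, float, bool, list))},
        }
        if self.roc is not None:
            out["roc"] = {k: np.asarray(v).tolist() for k, v in self.roc.items()}
        return out


def roc_curve(trace: np.ndarray, valid: np.ndarray,
              seizure_probs: np.ndarray) -> dict:
    """Single-threshold sweep: sensitivity vs time-based false positives."""
    pv = np.asarray(trace, dtype=float)[np.asarray(valid, dtype=bool)]
    pv = pv[np.isfinite(pv)]
    sz = np.asarray(seizure_probs, dtype=float)
    sz = sz[np.isfinite(sz)]
    thr = np.concatenate([[-np.inf], np.unique(pv), [np.inf]])
    sens = np.array([(sz >= t).mean() if sz.size else np.nan for t in thr])
    fpr = np.array([(pv >= t).mean() for t in thr])
    order = np.argsort(fpr)
    return {"fpr": fpr[order], "sensitivity": sens[order], "thresholds": thr[order]}


def score(levels: np.ndarray, valid: np.ndarray, seizure_levels: np.ndarray,
          thresholds: tuple[float, float], method: str = "",
          trace: np.ndarray | None = None,
          seizure_probs: np.ndarray | None = None,
          n_excluded: int = 0, diagnostics: dict | None = None) -> ForecastReport:
    """Aggregate report: occupancy fractions, performance product, ROC."""
    seizure_levels = np.asarray(seizure_levels)
    seizure_levels = seizure_levels[seizure_levels > 0]
    if seizure_levels.size == 0:
        raise UntrainableError("zero scored seizures")
    lv = np.asarray(levels)
    lv = lv[np.asarray(valid, dtype=bool) & (lv > 0)]
    time_fracs = tuple(float((lv == q).mean()) for q in (1, 2, 3))
    seiz_fracs = tuple(float((seizure_levels == q).mean()) for q in (1, 2, 3))
    roc = None
    if trace is not None and seizure_probs is not None:
        roc = roc_curve(trace, valid, seizure_probs)
    return ForecastReport(
        method=method,
        seizure_fractions=seiz_fracs,
        time_fractions=time_fracs,
        performance_product=time_fracs[0] * seiz_fracs[2],
        mean_risk=float(seizure_levels.mean()),
        n_seizures_scored=int(seizure_levels.size),
        n_seizures_excluded=int(n_excluded),
        thresholds=thresholds,
        roc=roc,
        diagnostics=diagnostics or {},
    )


# ---------------------------------------------------------------------------
# phase-set assembly shared by M1/M2
# ---------------------------------------------------------------------------

@dataclass
class ForecastConfig:
    n_bins: int = 20
    signals: tuple = ("acfw", "variance", "spike_rate")
    window_days: float = 50.0
    bootstrap_seizures: int = 10
    max_candidates: int = 512
    seed: int = 0
    m1_fallback_relaxed: bool = True
    risk_ma_window: int = 5
    # edge-phase estimation (samples) for causal real-time assignment:
    # long cycles -> linear extrapolation of interior Hilbert phase,
    # short cycles -> sinusoid projection over the trailing window
    edge_exclude_long: int = 1000
    edge_fit_long: int = 4000
    edge_fit_short: int = 1440
    edge_band_short: tuple = (500.0, 1000.0)   # period band, samples


def _usable_signals(features: FeatureSeries, signals) -> list[str]:
    out = []
    for s in signals:
        arr = features.signal(s)
        if np.nanstd(arr) > 0:
            out.append(s)
    return out


def _channel_phase_stacks(features: FeatureSeries, signal: str, *,
                          anticausal: bool, exclude_end: bool, seed: int,
                          stats: str, channels=None) -> dict:
    """Per-channel RhythmSets for one signal; returns stacked phase/valid."""
    arr = features.signal(signal)
    channels = range(arr.shape[0]) if channels is None else channels
    stacks = {cyc: ([], []) for cyc in CYCLES}
    for ch in channels:
        rs = extract_rhythms(arr[ch], seed=seed + 104729 * (ch + 1),
                             anticausal=anticausal, exclude_end=exclude_end,
                             stats=stats)
        stacks["long"][0].append(rs.long_phase)
        stacks["long"][1].append(rs.valid)
        stacks["short"][0].append(rs.short_phase)
        stacks["short"][1].append(rs.valid)
    return {cyc: (np.vstack(ph), np.vstack(vd)) for cyc, (ph, vd) in stacks.items()}


def select_channels(features: FeatureSeries, onsets_s: np.ndarray,
                    cfg: ForecastConfig, *, anticausal: bool,
                    exclude_end: bool, stats: str) -> dict:
    """Best-SI channel per (signal, cycle) pair."""
    selection = {}
    for sig in _usable_signals(features, cfg.signals):
        stacks = _channel_phase_stacks(features, sig, anticausal=anticausal,
                                       exclude_end=exclude_end, seed=cfg.seed,
                                       stats=stats)
        for cyc in CYCLES:
            ph, vd = stacks[cyc]
            si = per_channel_seizure_si(ph, vd, features.timestamps, onsets_s)
            if np.all(np.isnan(si)):
                continue
            ch, tied = select_channel(si)
            selection[(sig, cyc)] = {"channel": ch, "si": float(np.nanmax(si)),
                                     "tied": tied}
    if not selection:
        raise UntrainableError("no usable (signal, cycle) pair")
    return selection


def _rhythms_for_selection(features: FeatureSeries, selection: dict, *,
                           anticausal: bool, exclude_end: bool, seed: int,
                           stats: str, upto: int | None = None) -> dict:
    """RhythmSet per selected (signal, cycle), optionally on a prefix."""
    cache: dict = {}
    out: dict = {}
    for (sig, cyc), info in selection.items():
        ch = info["channel"]
        key = (sig, ch)
        if key not in cache:
            arr = features.signal(sig)[ch]
            if upto is not None:
                arr = arr[:upto]
            cache[key] = extract_rhythms(arr, seed=seed + 104729 * (ch + 1),
                                         anticausal=anticausal,
                                         exclude_end=exclude_end, stats=stats)
        out[(sig, cyc)] = cache[key]
    return out


def _phase_sets_for_selection(features: FeatureSeries, selection: dict, *,
                              anticausal: bool, exclude_end: bool, seed: int,
                              stats: str, upto: int | None = None) -> dict:
    """(phases, valid) per selected (signal, cycle), optionally on a prefix."""
    rsets = _rhythms_for_selection(features, selection, anticausal=anticausal,
                                   exclude_end=exclude_end, seed=seed,
                                   stats=stats, upto=upto)
    return {key: ((rs.long_phase if key[1] == "long" else rs.short_phase), rs.valid)
            for key, rs in rsets.items()}


def _prior_sample_indices(timestamps_s: np.ndarray, onsets_s) -> np.ndarray:
    return np.searchsorted(timestamps_s, np.asarray(onsets_s, dtype=float),
                           side="left") - 1


def _train_tables(phase_sets: dict, timestamps_s: np.ndarray,
                  onsets_s: np.ndarray, n_bins: int,
                  window_idx: np.ndarray | None = None) -> dict:
    """Eq-style tables per (signal, cycle); optionally restricted to a window."""
    tables = {}
    for key, (phases, valid) in phase_sets.items():
        samples = seizure_phases(phases, valid, timestamps_s, onsets_s)
        seiz_ph = valid_phases(samples)
        if window_idx is None:
            sig_ph, sig_ok = phases, valid
        else:
            sig_ph, sig_ok = phases[window_idx], valid[window_idx]
        tables[key] = probability_given_phase(sig_ph, sig_ok, seiz_ph, n_bins)
    return tables


# ---------------------------------------------------------------------------
# Method M1: within-sample
# ---------------------------------------------------------------------------

def forecast_m1(features: FeatureSeries, catalog: SeizureCatalog,
                cfg: ForecastConfig | None = None) -> ForecastReport:
    """Within-sample forecast: anti-causal rhythms, all seizures, strict mode."""
    report, _, _, _ = _forecast_m1_full(features, catalog, cfg)
    return report


def _forecast_m1_full(features: FeatureSeries, catalog: SeizureCatalog,
                      cfg: ForecastConfig | None = None):
    """M1 plus the artifacts needed by the chance model.

    Returns ``(report, levels, valid, prior_indices)`` where ``levels`` is
    the full risk-level sequence and ``prior_indices`` the seizure scoring
    samples (indices into the timestamp grid, -1 where unavailable).
    """
    cfg = cfg or ForecastConfig()
    onsets = catalog.onsets_s
    if onsets.size == 0:
        raise UntrainableError("no seizures")
    selection = select_channels(features, onsets, cfg, anticausal=True,
                                exclude_end=True, stats="global")
    phase_sets = _phase_sets_for_selection(features, selection, anticausal=True,
                                           exclude_end=True, seed=cfg.seed,
                                           stats="global")
    tables = _train_tables(phase_sets, features.timestamps, onsets, cfg.n_bins)
    trace, valid = combine_probabilities(tables, phase_sets)
    prior_idx = _prior_sample_indices(features.timestamps, onsets)
    seiz_p = np.array([trace[i] if (i >= 0 and valid[i]) else np.nan
                       for i in prior_idx])
    scored = np.isfinite(seiz_p)
    fallback = False
    try:
        th1, th2, diag = optimize_thresholds(trace, valid, seiz_p[scored],
                                             mode="strict",
                                             max_candidates=cfg.max_candidates)
    except NoFeasibleSolutionError:
        if not cfg.m1_fallback_relaxed:
            raise
        fallback = True
        th1, th2, diag = optimize_thresholds(trace, valid, seiz_p[scored],
                                             mode="relaxed",
                                             max_candidates=cfg.max_candidates)
    levels = risk_levels(trace, th1, th2)
    seiz_levels = np.where(scored, risk_levels(np.nan_to_num(seiz_p, nan=-1.0),
                                               th1, th2), 0)
    seiz_levels[~scored] = 0
    diag.update({"strict_fallback_to_relaxed": fallback,
                 "selection": {f"{s}/{c}": v for (s, c), v in selection.items()}})
    report = score(levels, valid, seiz_levels, (th1, th2), method="M1",
                   trace=trace, seizure_probs=seiz_p[scored],
                   n_excluded=int((~scored).sum()), diagnostics=diag)
    return report, levels, valid, prior_idx


def forecast_random(features: FeatureSeries, catalog: SeizureCatalog,
                    cfg: ForecastConfig | None = None,
                    n_realizations: int = 100) -> dict:
    """Chance model: random Markov chains built from the M1 level sequence.

    Returns the per-realization product distribution together with the
    reference M1 report, for side-by-side comparison.
    """
    cfg = cfg or ForecastConfig()
    report, levels, valid, prior_idx = _forecast_m1_full(features, catalog, cfg)
    vi = np.flatnonzero(valid)
    remap = -np.ones(levels.size, dtype=int)
    remap[vi] = np.arange(vi.size)
    pos = remap[prior_idx[prior_idx >= 0]]
    pos = pos[pos >= 0]
    chance = random_markov_predictor(levels[vi], pos,
                                     n_realizations=n_realizations,
                                     seed=cfg.seed)
    chance["reference_report"] = report
    return chance


# ---------------------------------------------------------------------------
# Method M2: pseudoprospective
# ---------------------------------------------------------------------------

@dataclass
class M2Result:
    report: ForecastReport
    seizure_levels: np.ndarray       # 0 = excluded, 1..3 otherwise
    seizure_risk_ma: np.ndarray      # 5-seizure moving average over scored ones
    refit_times_s: np.ndarray
    thresholds_history: list


def forecast_m2(features: FeatureSeries, catalog: SeizureCatalog,
                cfg: ForecastConfig | None = None) -> M2Result:
    """Pseudoprospective forecast with per-seizure refits.

    The model (tables + relaxed thresholds) is bootstrapped from the
    first ``bootstrap_seizures`` seizures and, after every subsequent
    seizure, refit on seizures inside the trailing ``window_days``
    window.  All rhythm filtering, gap filling and phase estimation for
    the risk assigned to seizure j uses only data recorded strictly
    before its onset, so truncating the record after seizure j cannot
    change the levels assigned to seizures <= j.
    """
    cfg = cfg or ForecastConfig()
    onsets = catalog.onsets_s
    nb = cfg.bootstrap_seizures
    if onsets.size < nb + 1:
        raise InsufficientHistoryError(
            f"M2 needs more than {nb} seizures, got {onsets.size}")
    ts = features.timestamps
    window_s = cfg.window_days * 86400.0

    def prefix_len(t_s: float) -> int:
        return int(np.searchsorted(ts, t_s, side="left"))

    def causal_phase_sets(selection, upto):
        return _phase_sets_for_selection(features, selection, anticausal=False,
                                         exclude_end=False, seed=cfg.seed,
                                         stats="causal", upto=upto)

    # real-time (edge-estimated) phases per seizure, frozen at assignment
    # time; threshold calibration looks past seizures up under the CURRENT
    # tables through these stored phases, so the thresholds see the same
    # estimator noise as future assignments
    assigned_phases: dict[int, dict] = {}

    def edge_phases(rsets) -> dict:
        out = {}
        for (sig, cyc), rs in rsets.items():
            if cyc == "long":
                out[(sig, cyc)] = edge_phase(rs.long_cycle, cfg.edge_exclude_long,
                                             cfg.edge_fit_long)
            else:
                out[(sig, cyc)] = edge_phase_projection(
                    rs.short_cycle, cfg.edge_fit_short, cfg.edge_band_short)
        return out

    def refit(selection, t_now_s):
        upto = prefix_len(t_now_s)
        phase_sets = causal_phase_sets(selection, upto)
        in_window = (ts[:upto] > t_now_s - window_s)
        window_idx = np.flatnonzero(in_window)
        past_mask = (onsets <= t_now_s) & (onsets > t_now_s - window_s)
        past = onsets[past_mask]
        tables = _train_tables(phase_sets, ts[:upto], past, cfg.n_bins,
                               window_idx=window_idx)
        trace, valid = combine_probabilities(tables, phase_sets)
        seiz_p = []
        prior_idx = _prior_sample_indices(ts[:upto], past)
        for sj, pi in zip(np.flatnonzero(past_mask), prior_idx):
            if sj in assigned_phases:
                p = 1.0
                for key, phi in assigned_phases[sj].items():
                    p *= float(tables[key].lookup(phi))
                seiz_p.append(p)
            elif pi >= 0 and valid[pi]:
                seiz_p.append(trace[pi])
        seiz_p = np.asarray(seiz_p, dtype=float)
        seiz_p = seiz_p[np.isfinite(seiz_p)]
        w_trace, w_valid = trace[window_idx], valid[window_idx]
        th1, th2, _ = optimize_thresholds(w_trace, w_valid, seiz_p,
                                          mode="relaxed",
                                          max_candidates=cfg.max_candidates)
        return tables, (th1, th2)

    # bootstrap at the onset of seizure #nb (0-based index nb-1)
    t_boot = float(onsets[nb - 1])
    boot_upto = prefix_len(t_boot)
    boot_features = FeatureSeries(
        ts[:boot_upto], features.acfw[:, :boot_upto],
        features.variance[:, :boot_upto], features.spike_rate[:, :boot_upto],
        features.mask[:boot_upto], features.cadence_min, features.rate_hz)
    selection = select_channels(boot_features, onsets[:nb], cfg,
                                anticausal=False, exclude_end=False,
                                stats="causal")
    tables, thresholds = refit(selection, t_boot)
    refit_times = [t_boot]
    thresholds_history = [thresholds]

    seiz_levels = np.zeros(onsets.size, dtype=np.int8)
    interval_levels: list[np.ndarray] = []
    interval_valid: list[np.ndarray] = []
    prev_upto = prefix_len(t_boot)
    for j in range(nb, onsets.size):
        onset = float(onsets[j])
        upto = prefix_len(onset)
        rsets = _rhythms_for_selection(features, selection, anticausal=False,
                                       exclude_end=False, stats="causal",
                                       seed=cfg.seed, upto=upto)
        th1, th2 = thresholds
        prior = upto - 1
        # real-time assignment: interior-extrapolated phase at the edge
        if prior >= 0 and all(rs.valid[prior] for rs in rsets.values()):
            phis = edge_phases(rsets)
            assigned_phases[j] = phis
            p_now = 1.0
            for key, phi in phis.items():
                p_now *= float(tables[key].lookup(phi))
            seiz_levels[j] = risk_levels(np.array([p_now]), th1, th2)[0]
        # occupancy of the elapsed interval under the frozen model
        phase_sets = {key: ((rs.long_phase if key[1] == "long" else rs.short_phase),
                            rs.valid) for key, rs in rsets.items()}
        trace, valid = combine_probabilities(tables, phase_sets)
        interval_levels.append(risk_levels(trace[prev_upto:upto], th1, th2))
        interval_valid.append(valid[prev_upto:upto])
        prev_upto = upto
        tables, thresholds = refit(selection, onset)
        refit_times.append(onset)
        thresholds_history.append(thresholds)

    # trailing interval after the last seizure, under the last frozen model
    phase_sets = causal_phase_sets(selection, None)
    trace, valid = combine_probabilities(tables, phase_sets)
    th1, th2 = thresholds
    interval_levels.append(risk_levels(trace[prev_upto:], th1, th2))
    interval_valid.append(valid[prev_upto:])

    levels = np.concatenate(interval_levels)
    valid_all = np.concatenate(interval_valid)
    scored_mask = seiz_levels[nb:] > 0
    scored_levels = seiz_levels[nb:][scored_mask]
    if scored_levels.size == 0:
        raise UntrainableError("every pseudoprospective seizure was excluded")
    w = cfg.risk_ma_window
    ma = np.array([scored_levels[max(0, i - w + 1):i + 1].mean()
                   for i in range(scored_levels.size)])
    report = score(levels, valid_all, scored_levels,
                   thresholds_history[-1], method="M2",
                   n_excluded=int((~scored_mask).sum()),
                   diagnostics={"n_refits": len(refit_times),
                                "selection": {f"{s}/{c}": v
                                              for (s, c), v in selection.items()}})
    return M2Result(report, seiz_levels, ma, np.array(refit_times),
                    thresholds_history)


# ---------------------------------------------------------------------------
# random Markov chance predictor
# ---------------------------------------------------------------------------

def transition_matrix(level_sequence: np.ndarray) -> np.ndarray:
    """3x3 row-stochastic transition matrix estimated from a level sequence."""
    seq = np.asarray(level_sequence)
    seq = seq[seq > 0]
    T = np.zeros((3, 3))
    np.add.at(T, (seq[:-1] - 1, seq[1:] - 1), 1.0)
    rows = T.sum(axis=1, keepdims=True)
    out = np.where(rows > 0, T / np.maximum(rows, 1), 0.0)
    for q in range(3):
        if rows[q, 0] == 0:
            out[q, q] = 1.0   # unvisited state: self-absorbing, flagged by caller
    return out


def simulate_markov(P: np.ndarray, n: int, n_realizations: int,
                    rng: np.random.Generator, initial: int = 1) -> np.ndarray:
    """Simulate level chains (values 1..3), vectorized across realizations."""
    cum = np.cumsum(P, axis=1)
    states = np.empty((n_realizations, n), dtype=np.int8)
    states[:, 0] = initial
    u = rng.random((n_realizations, n))
    for t in range(1, n):
        prev = states[:, t - 1] - 1
        states[:, t] = 1 + (u[:, t, None] > cum[prev]).sum(axis=1)
    return states


def random_markov_predictor(level_sequence: np.ndarray,
                            seizure_positions: np.ndarray,
                            n_realizations: int = 100,
                            seed: int = 0) -> dict:
    """Chance distribution: random level chains scored on the real seizures.

    ``level_sequence`` is the reference (valid-sample) risk sequence and
    ``seizure_positions`` index into it.  Returns per-realization
    performance products and occupancy/sensitivity arrays.
    """
    seq = np.asarray(level_sequence)
    seq = seq[seq > 0]
    pos = np.asarray(seizure_positions, dtype=int)
    pos = pos[(pos >= 0) & (pos < seq.size)]
    if pos.size == 0:
        raise UntrainableError("no seizure positions to score")
    P = transition_matrix(seq)
    rng = np.random.default_rng(seed)
    chains = simulate_markov(P, seq.size, n_realizations, rng, initial=int(seq[0]))
    time_low = (chains == 1).mean(axis=1)
    time_high = (chains == 3).mean(axis=1)
    seiz_at = chains[:, pos]
    seiz_high = (seiz_at == 3).mean(axis=1)
    seiz_low = (seiz_at == 1).mean(axis=1)
    products = time_low * seiz_high
    degenerate = bool(np.any(np.diag(P) == 1.0))
    return {"products": products, "time_low": time_low, "time_high": time_high,
            "seizure_high": seiz_high, "seizure_low": seiz_low,
            "mean_risk": seiz_at.mean(axis=1),
            "transition_matrix": P, "degenerate": degenerate}
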