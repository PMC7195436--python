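"""Ground-truth-labelled synthetic recordings from a driven bistable model.

Time convention: the dimensionless state equation is integrated with
1 time-unit = 1 hour, so a circadian drive spans 24 units and the default
multidien drive 252 units (10.5 days).  The latent state is mapped to
iEEG-like snapshots by an AR(1) renderer whose correlation time follows
the linearized relaxation time of the current equilibrium — the minimal
construction that provably exhibits critical slowing down (autocorrelation
width and variance both grow as the drive approaches the fold).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq
from scipy.special import i0, i1

from . import model
from .features import FeatureSeries
from .segments import SegmentStream, SeizureCatalog

HOUR_S = 3600.0


class ConfigError(ValueError):
    pass


class StepSizeError(RuntimeError):
    """The integrated trajectory diverged; reduce dt or the noise level."""


def _wrap(phi):
    return np.mod(np.asarray(phi) + np.pi, 2 * np.pi) - np.pi


@dataclass
class SimulatorConfig:
    """All knobs of the synthetic recording generator.

    Drive: ``k(t) = k_baseline + k_circadian_amp * sin(2 pi t / T_c)
    + k_multidien_amp * sin(2 pi t / T_m)`` with t in hours.
    """

    r: float = 500.0
    k_baseline: float = 0.0
    k_circadian_amp: float = 0.0
    k_multidien_amp: float = 0.0
    circadian_period_h: float = 24.0
    multidien_period_h: float = 252.0          # 10.5 days
    noise_sd: float = 0.1                      # state noise per sqrt(hour)
    dt: float = 0.01                           # integrator step, hours
    n_channels: int = 16
    segment_rate_hz: float = 400.0
    segment_length_s: float = 1.0
    cadence_min: float = 2.0
    duration_days: float = 30.0
    # seizure rendering / bookkeeping
    seizure_duration_s: tuple[float, float] = (30.0, 90.0)
    refractory_min: float = 10.0
    seizure_freq_hz: float = 6.0
    seizure_amp_factor: float = 10.0
    # snapshot rendering
    tau_to_lag: float = 5.0                    # AR lag-samples per unit tau (hours)
    tau_cap_h: float = 20.0
    segment_noise_sd: float = 1.0              # AR innovation SD
    measurement_noise_sd: float = 0.1
    feature_rel_noise: float = 0.1             # used by the fast feature path
    # epileptiform spikes
    spike_template: np.ndarray | None = None
    spike_rate_base: float = 0.0               # events per hour per channel
    spike_rate_mod: float = 0.0                # modulation depth in [0, 1]
    spike_snr: float = 5.0
    # dropouts: list of (start_s, length_s) or {"target_fraction": f}
    dropout_spec: object = None
    seed: int = 0

    def validate(self) -> None:
        if self.r <= 0:
            raise ConfigError("r must be > 0")
        if self.noise_sd < 0:
            raise ConfigError("noise_sd must be >= 0")
        if self.dt <= 0:
            raise ConfigError("dt must be > 0")
        if self.cadence_min * 60.0 <= self.segment_length_s:
            raise ConfigError("cadence must exceed the segment length")
        if self.spike_template is not None:
            if len(self.spike_template) >= self.segment_length_s * self.segment_rate_hz:
                raise ConfigError("spike template longer than a segment")
        if not 0 <= self.spike_rate_mod <= 1:
            raise ConfigError("spike_rate_mod must be in [0, 1]")

    @property
    def duration_h(self) -> float:
        return self.duration_days * 24.0

    @property
    def n_segments(self) -> int:
        return int(np.floor(self.duration_h * 60.0 / self.cadence_min))

    def segment_times_s(self) -> np.ndarray:
        return np.arange(self.n_segments) * self.cadence_min * 60.0


@dataclass
class Trajectory:
    """Latent state and drive on the integrator grid (hours)."""

    t_h: np.ndarray
    z: np.ndarray
    k: np.ndarray
    onsets_h: np.ndarray
    durations_s: np.ndarray
    r: float


@dataclass
class SyntheticRecording:
    segments: SegmentStream | None
    seizure_catalog: SeizureCatalog
    true_drive: np.ndarray                 # k(t) on the segment grid
    true_phases: dict                      # {"circadian": ..., "multidien": ...}
    spike_truth: list                      # per-channel arrays of event times (s)
    features: FeatureSeries | None = None
    trajectory: Trajectory | None = None


def default_spike_template(rate_hz: float = 400.0, length_s: float = 0.15) -> np.ndarray:
    """Sharp biphasic transient followed by a slow wave, unit-normalized."""
    n = int(length_s * rate_hz)
    t = np.arange(n) / rate_hz
    spike = np.exp(-((t - 0.03) ** 2) / (2 * 0.006 ** 2))
    wave = -0.45 * np.exp(-((t - 0.085) ** 2) / (2 * 0.022 ** 2))
    tpl = spike + wave
    return tpl / np.linalg.norm(tpl)


def drive_trace(config: SimulatorConfig, t_h: np.ndarray) -> np.ndarray:
    return (config.k_baseline
            + config.k_circadian_amp * np.sin(2 * np.pi * t_h / config.circadian_period_h)
            + config.k_multidien_amp * np.sin(2 * np.pi * t_h / config.multidien_period_h))


def drive_phase(t_h: np.ndarray, period_h: float) -> np.ndarray:
    """Analytic phase of the sinusoidal drive component (0 at its maximum)."""
    return _wrap(2 * np.pi * np.asarray(t_h) / period_h - np.pi / 2)


# ---------------------------------------------------------------------------
# state integration and seizure labelling
# ---------------------------------------------------------------------------

def simulate_state(config: SimulatorConfig, rng: np.random.Generator | None = None,
                   k_override: np.ndarray | None = None,
                   z0: float | None = None) -> Trajectory:
    """Euler-Maruyama integration of the driven bistable state.

    Upward crossings of the unstable branch are recorded as seizure
    onsets; the state is held on the upper branch for a drawn duration
    and then reset to the lower branch, with a refractory period that
    suppresses re-detection.
    """
    config.validate()
    if rng is None:
        rng = np.random.default_rng(config.seed)
    n = int(round(config.duration_h / config.dt))
    if n < 2:
        raise ConfigError("dt too large for the requested duration")
    t = np.arange(n) * config.dt
    k = drive_trace(config, t) if k_override is None else np.asarray(k_override, dtype=float)
    if k.shape != t.shape:
        raise ConfigError("k_override must match the integrator grid")
    thr = model.unstable_branch(config.r, k)
    z_lo, z_up = model.stable_branches(config.r, k)
    noise = rng.standard_normal(n) * config.noise_sd * np.sqrt(config.dt)
    a = model.A_SCALE * config.r

    z = np.empty(n)
    z[0] = z_lo[0] if z0 is None else float(z0)
    onsets: list[float] = []
    durations: list[float] = []
    z_bound = 10.0 * max(1.0, np.sqrt(a))
    in_seizure_until = -1.0
    refractory_until = -1.0
    refractory_h = config.refractory_min / 60.0
    dlo, dhi = config.seizure_duration_s

    zi = z[0]
    dt = config.dt
    for i in range(1, n):
        ti = t[i]
        if ti < in_seizure_until:
            zi = z_up[i]
        else:
            if onsets and ti - dt < in_seizure_until <= ti:
                zi = z_lo[i]  # seizure just ended: reset to the lower branch
            drift = -zi ** 3 + a * zi + model.A_SCALE * k[i - 1]
            zi = zi + drift * dt + noise[i]
            if abs(zi) > z_bound:
                raise StepSizeError(f"trajectory diverged at t={ti:.3f} h; reduce dt")
            if zi > thr[i] and z[i - 1] <= thr[i - 1] and ti >= refractory_until:
                dur_s = float(rng.uniform(dlo, dhi))
                onsets.append(ti)
                durations.append(dur_s)
                in_seizure_until = ti + dur_s / HOUR_S
                refractory_until = in_seizure_until + refractory_h
                zi = z_up[i]
        z[i] = zi
    return Trajectory(t, z, k, np.array(onsets), np.array(durations), config.r)


def label_seizures(traj: Trajectory, config: SimulatorConfig) -> SeizureCatalog:
    """Detect upward unstable-branch crossings in a state trace.

    Pure function of the trajectory: re-derives onsets from ``z`` with the
    configured refractory period, and measures each event's duration as
    the time spent above the unstable branch (consistent with the resets
    applied by :func:`simulate_state`).
    """
    thr = model.unstable_branch(traj.r, traj.k)
    above = traj.z > thr
    crossings = np.flatnonzero(above[1:] & ~above[:-1]) + 1
    refractory_h = config.refractory_min / 60.0
    onsets: list[float] = []
    durations: list[float] = []
    last_end = -np.inf
    for idx in crossings:
        t0 = traj.t_h[idx]
        if t0 < last_end + refractory_h:
            continue
        run_end = idx
        while run_end < above.size and above[run_end]:
            run_end += 1
        t1 = traj.t_h[min(run_end, traj.t_h.size - 1)]
        onsets.append(t0)
        durations.append((t1 - t0) * HOUR_S)
        last_end = t1
    return SeizureCatalog(np.array(onsets) * HOUR_S, np.array(durations))


# ---------------------------------------------------------------------------
# snapshot rendering
# ---------------------------------------------------------------------------

def _segment_tau_h(config: SimulatorConfig, k_seg: np.ndarray) -> np.ndarray:
    """Linearized relaxation time at the lower-branch equilibrium, capped."""
    z_lo, _ = model.stable_branches(config.r, k_seg)
    d = model.drift_dz(z_lo, config.r)
    tau = 1.0 / np.maximum(np.abs(d), 1.0 / config.tau_cap_h)
    tau[d >= 0] = config.tau_cap_h
    return tau


def _ar_coefficients(config: SimulatorConfig, k_seg: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-segment AR(1) coefficient and lag constant from the drive."""
    tau = _segment_tau_h(config, k_seg)
    n_samples = int(config.segment_length_s * config.segment_rate_hz)
    lag = np.clip(config.tau_to_lag * tau, 0.5, 0.45 * n_samples)
    return np.exp(-1.0 / lag), lag


def synthesize_segments(traj: Trajectory, config: SimulatorConfig,
                        rng: np.random.Generator | None = None,
                        catalog: SeizureCatalog | None = None) -> SegmentStream:
    """Render 1-s AR(1) snapshots whose correlation time tracks the drive.

    Stationary AR variance ``sd^2 / (1 - a^2)`` and half-width
    ``lag * ln 2`` both grow with the linearized relaxation time, so the
    measured biomarkers rise on the approach to the fold.  Seizure
    intervals are rendered as large-amplitude oscillations.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed + 1)
    times_s = config.segment_times_s()
    n_seg = times_s.size
    T = int(config.segment_length_s * config.segment_rate_hz)
    k_seg = np.interp(times_s / HOUR_S, traj.t_h, traj.k)
    a, _ = _ar_coefficients(config, k_seg)
    stat_sd = config.segment_noise_sd / np.sqrt(1.0 - a ** 2)

    data = np.empty((config.n_channels, n_seg, T))
    for ch in range(config.n_channels):
        e = rng.standard_normal((n_seg, T)) * config.segment_noise_sd
        x = np.empty((n_seg, T))
        x[:, 0] = rng.standard_normal(n_seg) * stat_sd
        for s in range(1, T):
            x[:, s] = a * x[:, s - 1] + e[:, s]
        x += rng.standard_normal((n_seg, T)) * config.measurement_noise_sd
        data[ch] = x

    if catalog is None:
        catalog = SeizureCatalog(traj.onsets_h * HOUR_S, traj.durations_s)
    amp = config.seizure_amp_factor * float(np.median(stat_sd))
    tt = np.arange(T) / config.segment_rate_hz
    for onset, dur in zip(catalog.onsets_s, catalog.durations_s):
        sel = np.flatnonzero((times_s + config.segment_length_s > onset)
                             & (times_s < onset + dur))
        for si in sel:
            phase0 = rng.uniform(0, 2 * np.pi)
            osc = amp * np.sin(2 * np.pi * config.seizure_freq_hz * tt + phase0)
            data[:, si, :] = osc + rng.standard_normal(
                (config.n_channels, T)) * config.measurement_noise_sd

    return SegmentStream(
        timestamps=times_s, data=data, mask=np.zeros(n_seg, dtype=bool),
        rate_hz=config.segment_rate_hz, cadence_min=config.cadence_min,
        metadata={"generator": "ar1", "seed": config.seed},
    )


def synthesize_continuous(traj: Trajectory, config: SimulatorConfig,
                          t_start_s: float, t_stop_s: float,
                          rng: np.random.Generator | None = None,
                          catalog: SeizureCatalog | None = None) -> np.ndarray:
    """Continuous single-channel rendering (for peri-seizure analysis)."""
    if rng is None:
        rng = np.random.default_rng(config.seed + 2)
    rate = config.segment_rate_hz
    n = int((t_stop_s - t_start_s) * rate)
    t_s = t_start_s + np.arange(n) / rate
    k_t = np.interp(t_s / HOUR_S, traj.t_h, traj.k)
    a, _ = _ar_coefficients(config, k_t)
    e = rng.standard_normal(n) * config.segment_noise_sd
    x = np.empty(n)
    x[0] = e[0] / np.sqrt(1 - a[0] ** 2)
    for i in range(1, n):
        x[i] = a[i] * x[i - 1] + e[i]
    x += rng.standard_normal(n) * config.measurement_noise_sd
    if catalog is None:
        catalog = SeizureCatalog(traj.onsets_h * HOUR_S, traj.durations_s)
    amp = config.seizure_amp_factor * config.segment_noise_sd / np.sqrt(
        1 - np.median(a) ** 2)
    for onset, dur in zip(catalog.onsets_s, catalog.durations_s):
        sel = (t_s >= onset) & (t_s < onset + dur)
        if sel.any():
            x[sel] = amp * np.sin(2 * np.pi * config.seizure_freq_hz * (t_s[sel] - onset))
    return x


# ---------------------------------------------------------------------------
# spikes and dropouts
# ---------------------------------------------------------------------------

def inject_spikes(stream: SegmentStream, config: SimulatorConfig,
                  rng: np.random.Generator | None = None,
                  modulation_phase: np.ndarray | None = None,
                  channel_factors: np.ndarray | None = None
                  ) -> tuple[SegmentStream, list]:
    """Add template-shaped events at rhythm-modulated Poisson times.

    The per-channel base rates differ (spatial heterogeneity); the common
    modulation follows ``1 + mod * cos(phase)``.  Events land only inside
    non-missing segments; ground-truth times are returned per channel.
    """
    config.validate()
    if rng is None:
        rng = np.random.default_rng(config.seed + 3)
    template = config.spike_template
    if template is None:
        template = default_spike_template(stream.rate_hz)
    template = np.asarray(template, dtype=float)
    T = stream.n_samples
    if template.size >= T:
        raise ConfigError("spike template longer than a segment")

    out = stream.copy()
    truth: list = []
    if config.spike_rate_base <= 0:
        return out, [np.empty(0) for _ in range(stream.n_channels)]

    if channel_factors is None:
        channel_factors = np.exp(rng.normal(0.0, 0.3, size=stream.n_channels))
    mod = np.ones(stream.n_segments)
    if modulation_phase is not None and config.spike_rate_mod > 0:
        mod = 1.0 + config.spike_rate_mod * np.cos(modulation_phase)
    duty_s = stream.n_samples / stream.rate_hz
    tpl_norm = template / np.linalg.norm(template)
    L = template.size
    seg_sd = np.nanstd(out.data, axis=2)  # (ch, seg)
    for ch in range(stream.n_channels):
        rate_per_seg = config.spike_rate_base * channel_factors[ch] * mod * duty_s / HOUR_S
        rate_per_seg[stream.mask] = 0.0
        counts = rng.poisson(rate_per_seg)
        ch_times: list[float] = []
        for si in np.flatnonzero(counts):
            for _ in range(counts[si]):
                pos = int(rng.integers(0, T - L + 1))
                # match-filter SNR: unit-norm template at amplitude
                # snr * sd * sqrt(L) yields correlation ~ snr/sqrt(snr^2+1)
                amp = config.spike_snr * np.sqrt(L) * max(seg_sd[ch, si], 1e-12)
                out.data[ch, si, pos:pos + L] += amp * tpl_norm
                ch_times.append(stream.timestamps[si] + pos / stream.rate_hz)
        truth.append(np.sort(np.array(ch_times)))
    return out, truth


def _random_gaps(n_seg: int, cadence_s: float, target_fraction: float,
                 rng: np.random.Generator) -> list[tuple[float, float]]:
    """Mixed-length gaps (minutes to days) until the target fraction is hit."""
    total_s = n_seg * cadence_s
    mask = np.zeros(n_seg, dtype=bool)
    gaps: list[tuple[float, float]] = []
    means_h = np.array([0.5, 4.0, 24.0])
    probs = np.array([0.70, 0.25, 0.05])
    guard = 0
    while mask.mean() < target_fraction and guard < 100000:
        guard += 1
        comp = rng.choice(3, p=probs)
        length_s = min(float(rng.exponential(means_h[comp])) * HOUR_S, 72 * HOUR_S)
        # trim the closing gap so the realized fraction lands on target
        deficit_seg = int(np.ceil((target_fraction - mask.mean()) * n_seg)) + 1
        length_s = min(length_s, deficit_seg * cadence_s)
        start_s = float(rng.uniform(0, total_s))
        i0_, i1_ = int(start_s // cadence_s), int(np.ceil((start_s + length_s) / cadence_s))
        mask[i0_:min(i1_, n_seg)] = True
        gaps.append((start_s, length_s))
    return gaps


def inject_dropouts(stream: SegmentStream, dropout_spec, seed: int = 0) -> SegmentStream:
    """Mask segments inside the given gaps (overlaps merged, not rejected)."""
    out = stream.copy()
    if dropout_spec is None:
        return out
    cadence_s = stream.cadence_min * 60.0
    if isinstance(dropout_spec, dict):
        rng = np.random.default_rng(seed)
        gaps = _random_gaps(stream.n_segments, cadence_s,
                            float(dropout_spec["target_fraction"]), rng)
    else:
        gaps = [(float(s), float(l)) for s, l in dropout_spec]
    for start_s, length_s in gaps:
        sel = (stream.timestamps >= start_s) & (stream.timestamps < start_s + length_s)
        out.mask |= sel
    out.data[:, out.mask, :] = np.nan
    out.metadata["missing_fraction"] = float(out.mask.mean())
    return out


# ---------------------------------------------------------------------------
# fast feature-level rendering and phase-locked catalogs
# ---------------------------------------------------------------------------

def synthesize_features(traj: Trajectory, config: SimulatorConfig,
                        rng: np.random.Generator | None = None,
                        catalog: SeizureCatalog | None = None) -> FeatureSeries:
    """Biomarker series derived directly from the latent drive.

    Skips the 400-Hz rendering: ACFW and variance are set to their AR(1)
    population values (``lag * ln2`` and ``sd^2/(1-a^2)``) at the
    segment-local relaxation time, with independent multiplicative noise
    per channel; spike counts are Poisson with drive-modulated rates.
    Orders of magnitude faster than :func:`synthesize_segments` and
    statistically equivalent for rhythm/forecast analyses.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed + 4)
    times_s = config.segment_times_s()
    k_seg = np.interp(times_s / HOUR_S, traj.t_h, traj.k)
    a, lag = _ar_coefficients(config, k_seg)
    acfw_true = lag * np.log(2.0)
    var_true = config.segment_noise_sd ** 2 / (1.0 - a ** 2) \
        + config.measurement_noise_sd ** 2
    n_ch, n_seg = config.n_channels, times_s.size
    rel = config.feature_rel_noise
    acfw = acfw_true[None, :] * (1.0 + rel * rng.standard_normal((n_ch, n_seg)))
    var = var_true[None, :] * (1.0 + rel * rng.standard_normal((n_ch, n_seg)))
    acfw = np.maximum(acfw, 1.0)
    var = np.maximum(var, 1e-9)

    phase_c = drive_phase(times_s / HOUR_S, config.circadian_period_h)
    phase_m = drive_phase(times_s / HOUR_S, config.multidien_period_h)
    channel_factors = np.exp(rng.normal(0.0, 0.3, size=n_ch))
    duty_s = config.segment_length_s
    mod = np.clip((1.0 + config.spike_rate_mod * np.cos(phase_m))
                  * (1.0 + 0.5 * config.spike_rate_mod * np.cos(phase_c)), 0.0, None)
    mu = config.spike_rate_base * channel_factors[:, None] * mod[None, :] * duty_s / HOUR_S
    spikes = rng.poisson(mu).astype(float)

    if catalog is None and traj.onsets_h.size:
        catalog = SeizureCatalog(traj.onsets_h * HOUR_S, traj.durations_s)
    if catalog is not None:
        for onset, dur in zip(catalog.onsets_s, catalog.durations_s):
            sel = (times_s + duty_s > onset) & (times_s < onset + dur)
            acfw[:, sel] *= 2.0
            var[:, sel] *= 25.0
    return FeatureSeries(
        timestamps=times_s, acfw=acfw, variance=var, spike_rate=spikes,
        mask=np.zeros(n_seg, dtype=bool), cadence_min=config.cadence_min,
        rate_hz=config.segment_rate_hz, metadata={"generator": "feature-level"},
    )


def synthesize_rhythmic_features(config: SimulatorConfig,
                                 rng: np.random.Generator | None = None,
                                 circadian_depth: float = 0.6,
                                 multidien_depth: float = 0.4,
                                 rel_noise: float = 0.03,
                                 base_levels: dict | None = None) -> FeatureSeries:
    """Biomarker series with directly injected circadian/multidien rhythms.

    Unlike :func:`synthesize_features` (whose rhythm content passes through
    the relaxation time of the bistable model), this generator imposes the
    two rhythms on each biomarker at controlled modulation depths:
    ``base * (1 + d_c cos(phi_c) + d_m cos(phi_m))`` with multiplicative
    noise for ACFW/variance and Poisson counts for the spike rate.  It is
    the generator of choice for forecaster experiments, where the quantity
    under control is rhythm SNR rather than fold proximity.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed + 6)
    base = {"acfw": 5.0, "variance": 3.0, "spike_rate": 5.0}
    if base_levels:
        base.update(base_levels)
    ts = config.segment_times_s()
    t_h = ts / HOUR_S
    phi_c = drive_phase(t_h, config.circadian_period_h)
    phi_m = drive_phase(t_h, config.multidien_period_h)
    mod = 1.0 + circadian_depth * np.cos(phi_c) + multidien_depth * np.cos(phi_m)
    n_ch, n_seg = config.n_channels, ts.size
    out = {}
    for name, b in base.items():
        level = np.clip(b * mod, 0.0, None)
        if name == "spike_rate":
            arr = rng.poisson(np.broadcast_to(level, (n_ch, n_seg))).astype(float)
        else:
            arr = level[None, :] * (1.0 + rel_noise * rng.standard_normal((n_ch, n_seg)))
            arr = np.maximum(arr, 1e-9)
        out[name] = arr
    return FeatureSeries(
        timestamps=ts, acfw=out["acfw"], variance=out["variance"],
        spike_rate=out["spike_rate"], mask=np.zeros(n_seg, dtype=bool),
        cadence_min=config.cadence_min, rate_hz=config.segment_rate_hz,
        metadata={"generator": "rhythm-injection"},
    )


def kappa_for_si(target_si: float) -> float:
    """Von Mises concentration giving mean resultant length ``target_si``."""
    if not 0 <= target_si < 1:
        raise ValueError("target SI must be in [0, 1)")
    if target_si == 0:
        return 0.0
    return float(brentq(lambda kp: i1(kp) / i0(kp) - target_si, 1e-6, 500.0))


def phase_locked_catalog(config: SimulatorConfig, n_seizures: int,
                         rng: np.random.Generator | None = None,
                         kappa_multidien: float = 5.3, kappa_circadian: float = 0.0,
                         mean_phase_multidien: float = 0.0,
                         mean_phase_circadian: float = 0.0,
                         min_separation_s: float = 3600.0,
                         duration_s: float = 60.0) -> SeizureCatalog:
    """Seizure onsets preferentially at given drive phases (von Mises).

    Onset times are drawn from the segment grid with weights
    ``exp(kappa_m cos(phi_m - mu_m) + kappa_c cos(phi_c - mu_c))`` and a
    minimum separation; the realized per-cycle SI approaches
    ``I1(kappa)/I0(kappa)`` for large n.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed + 5)
    times_s = config.segment_times_s()
    t_h = times_s / HOUR_S
    phi_m = drive_phase(t_h, config.multidien_period_h)
    phi_c = drive_phase(t_h, config.circadian_period_h)
    logw = (kappa_multidien * np.cos(phi_m - mean_phase_multidien)
            + kappa_circadian * np.cos(phi_c - mean_phase_circadian))
    w = np.exp(logw - logw.max())
    w /= w.sum()
    chosen: list[float] = []
    guard = 0
    while len(chosen) < n_seizures and guard < 200 * n_seizures:
        guard += 1
        t = float(times_s[rng.choice(times_s.size, p=w)]) \
            + float(rng.uniform(0, config.cadence_min * 60.0))
        if all(abs(t - c) >= min_separation_s for c in chosen):
            chosen.append(t)
    if len(chosen) < n_seizures:
        raise RuntimeError("could not place the requested number of seizures")
    onsets = np.sort(np.array(chosen))
    return SeizureCatalog(onsets, np.full(onsets.size, duration_s))


# ---------------------------------------------------------------------------
# orchestration
# ---------------------------------------------------------------------------

def simulate_recording(config: SimulatorConfig,
                       render: str = "segments") -> SyntheticRecording:
    """End-to-end generation: integrate, label, render, drop out, spike.

    ``render`` selects ``"segments"`` (full 400-Hz snapshots),
    ``"features"`` (fast biomarker-level path) or ``"both"``.
    All randomness derives from ``config.seed``.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    traj = simulate_state(config, rng=np.random.default_rng(rng.integers(2 ** 63)))
    catalog = SeizureCatalog(traj.onsets_h * HOUR_S, traj.durations_s)
    times_s = config.segment_times_s()
    t_h = times_s / HOUR_S
    true_drive = np.interp(t_h, traj.t_h, traj.k)
    true_phases = {
        "circadian": drive_phase(t_h, config.circadian_period_h),
        "multidien": drive_phase(t_h, config.multidien_period_h),
    }

    segments = None
    features = None
    spike_truth: list = []
    if render in ("segments", "both"):
        segments = synthesize_segments(
            traj, config, rng=np.random.default_rng(rng.integers(2 ** 63)),
            catalog=catalog)
        if config.dropout_spec is not None:
            segments = inject_dropouts(segments, config.dropout_spec,
                                       seed=int(rng.integers(2 ** 31)))
        if config.spike_rate_base > 0:
            segments, spike_truth = inject_spikes(
                segments, config, rng=np.random.default_rng(rng.integers(2 ** 63)),
                modulation_phase=true_phases["multidien"])
    if render in ("features", "both"):
        features = synthesize_features(
            traj, config, rng=np.random.default_rng(rng.integers(2 ** 63)),
            catalog=catalog)
        if config.dropout_spec is not None and render == "features":
            tmp = SegmentStream(times_s, np.zeros((1, times_s.size, 1)),
                                np.zeros(times_s.size, dtype=bool),
                                config.segment_rate_hz, config.cadence_min)
            tmp = inject_dropouts(tmp, config.dropout_spec,
                                  seed=int(rng.integers(2 ** 31)))
            features = features.mask_spans(
                [(times_s[i], times_s[i] + config.cadence_min * 60.0)
                 for i in np.flatnonzero(tmp.mask)])
    return SyntheticRecording(segments, catalog, true_drive, true_phases,
                              spike_truth, features, traj)


def write_ground_truth(rec: SyntheticRecording, path) -> None:
    """Drive, phases and spike times as an HDF5 sidecar."""
    import h5py

    with h5py.File(path, "w") as f:
        f.create_dataset("true_drive", data=rec.true_drive)
        for name, phase in rec.true_phases.items():
            f.create_dataset(f"phase_{name}", data=phase)
        for ch, times in enumerate(rec.spike_truth):
            f.create_dataset(f"spike_times/ch{ch:02d}", data=times)
        f.create_dataset("seizure_onsets_s", data=rec.seizure_catalog.onsets_s)
        f.create_dataset("seizure_durations_s", data=rec.seizure_catalog.durations_s)
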