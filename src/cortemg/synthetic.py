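"""Multi-session synthetic generator for cortico-muscular gait recordings.

Emulates the statistical structure of chronic bipedal-treadmill recordings
around a lateral (right) thoracic spinal hemisection, with recording from the
left (contralesional) motor cortex:

* gait-phase-tuned cortical units firing as inhomogeneous Poisson processes,
  with a session-to-session decline in unit count (electrode instability);
* six hindlimb muscles (LS, RS, LRF, RRF, RTA, LST) whose EMG envelope is a
  per-cycle raised-cosine burst scaled by a coupling-weighted drive from the
  unit population plus rectified additive Gaussian noise, emitted at 1 kHz;
* a unit-to-muscle coupling matrix abruptly attenuated at the lesion session
  (right/ipsilesional side worse than left/contralesional) that relaxes
  exponentially back toward baseline over post-lesion sessions;
* walking behaviour organised into runs of consecutive steps whose length and
  total count collapse at the lesion and recover with the coupling;
* occasional broadband movement artifacts: simultaneous deflections on every
  EMG channel plus coincident threshold events on all units.

Everything is deterministic given ``(config.seed, session_index)``.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter1d

from .data import (
    EMGTrace,
    GaitAnnotation,
    MUSCLES,
    Session,
    SpikeTrain,
    muscle_side,
    write_session,
)

# Burst centre (fraction of the gait cycle) and width for each muscle class;
# stance extensors burst early, swing flexors late, right leg half a cycle
# out of phase with the left.
_BURST_PHASE = {"S": 0.30, "RF": 0.10, "TA": 0.60, "ST": 0.50}
_BURST_WIDTH = 0.35


class ConfigurationError(ValueError):
    """Raised for an invalid generator configuration."""


@dataclass
class GeneratorConfig:
    """Study-shape and physiology parameters of the generator.

    Defaults describe a macaque-scale chronic study: 13 weekly sessions (3 before
    the hemisection, 10 after, the first post-lesion session three weeks
    after surgery), ~1 Hz stepping at treadmill speeds 0.30-0.55 m/s, 64
    initial units declining ~5 %/session, a severe ipsilesional /moderate
    contralesional coupling drop at the lesion, and gradual exponential
    recovery.  Pre-lesion runs average 85 consecutive steps; immediately
    post-lesion runs shrink to ~15 steps and little of the session is spent
    walking, recovering to ~50-step runs.
    """

    seed: int = 0
    n_sessions: int = 13
    lesion_session: int = 3
    gait_frequency: float = 1.0          # steps/s at 0.30-0.55 m/s belt speed
    session_duration: float = 600.0      # s of recording per day
    n_units_initial: int = 64
    unit_dropout_rate: float = 0.05      # fraction of units lost per session
    muscles: tuple[str, ...] = MUSCLES
    baseline_coupling: np.ndarray | None = None   # (units, muscles) in [0,1]
    lesion_attenuation_ipsi: float = 0.10
    lesion_attenuation_contra: float = 0.60
    recovery_rate: float = 0.15          # per-session relaxation to baseline
    noise_sd: float = 0.10               # additive EMG sensor noise (a.u.)
    # per-step burst-timing jitter (fraction of the gait cycle) and log-normal
    # burst-amplitude jitter at full coupling deficit; both scale with
    # (1 - recovery gain), so activation is weak, mistimed and erratic right
    # after the lesion and reorganises as coupling recovers
    phase_jitter_sd: float = 0.18
    amp_jitter_sd: float = 0.6
    # ~0.5 s of recording is excluded per detected artifact (event duration
    # plus detection window and padding), so 3.5 events/min removes ~3 % of
    # the recording
    artifact_rate: float = 3.5           # broadband artifact events / minute
    artifact_duration: float = 0.3       # s per artifact
    # behaviour: consecutive-step runs and fraction of the session walking
    steps_per_run_pre: float = 85.0
    steps_per_run_post: tuple[float, float] = (15.0, 50.0)
    walk_fraction_pre: float = 0.80
    walk_fraction_post: tuple[float, float] = (0.06, 0.65)
    step_cv: float = 0.05                # step-duration jitter
    # unit tuning: baseline and modulation firing-rate ranges (Hz); hindlimb
    # M1 units modulate strongly with the step cycle during walking
    tuning_baseline_hz: tuple[float, float] = (2.0, 10.0)
    tuning_modulation_hz: tuple[float, float] = (20.0, 60.0)
    dead_time_ms: float = 1.5            # absolute refractory period per unit
    speed: float = 0.4                   # treadmill speed, m/s (metadata)

    def validate(self) -> None:
        if self.session_duration <= 0:
            raise ConfigurationError("session_duration must be positive")
        if self.n_units_initial < 1:
            raise ConfigurationError("need at least one unit")
        if self.n_sessions < 1:
            raise ConfigurationError("need at least one session")
        if not (0 <= self.lesion_session <= self.n_sessions):
            raise ConfigurationError("lesion_session outside study")
        if not (0 < self.lesion_attenuation_ipsi <= 1
                and 0 < self.lesion_attenuation_contra <= 1):
            raise ConfigurationError("attenuations must lie in (0, 1]")
        if self.lesion_attenuation_ipsi > self.lesion_attenuation_contra:
            raise ConfigurationError(
                "ipsilesional deficit must be at least as severe as the "
                "contralesional one (attenuation_ipsi <= attenuation_contra)")
        if not (0 <= self.recovery_rate <= 1):
            raise ConfigurationError("recovery_rate must lie in [0, 1]")
        if not (0 <= self.unit_dropout_rate < 1):
            raise ConfigurationError("unit_dropout_rate must lie in [0, 1)")


@dataclass
class UnitPopulation:
    """Per-unit tuning parameters, fixed across the whole study."""

    baseline_hz: np.ndarray
    modulation_hz: np.ndarray
    preferred_phase: np.ndarray
    channel_id: np.ndarray

    @property
    def n_units(self) -> int:
        return int(self.baseline_hz.size)

    @property
    def mean_rate_hz(self) -> np.ndarray:
        # time-average of b + a*max(0, cos(.)): the rectified-cosine mean is a/pi
        return self.baseline_hz + self.modulation_hz / np.pi


def _study_rng(config: GeneratorConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng([int(config.seed), int(stream)])


def draw_population(config: GeneratorConfig) -> UnitPopulation:
    """Draw the unit roster (tuning + channel) from the study-level stream."""
    rng = _study_rng(config, 0)
    n = config.n_units_initial
    b0, b1 = config.tuning_baseline_hz
    a0, a1 = config.tuning_modulation_hz
    return UnitPopulation(
        baseline_hz=rng.uniform(b0, b1, n),
        modulation_hz=rng.uniform(a0, a1, n),
        preferred_phase=rng.uniform(0, 2 * np.pi, n),
        channel_id=rng.integers(0, 64, n),
    )


def draw_baseline_coupling(config: GeneratorConfig) -> np.ndarray:
    """Baseline (pre-lesion) unit-to-muscle coupling gains in [0, 1]."""
    if config.baseline_coupling is not None:
        coupling = np.asarray(config.baseline_coupling, dtype=float)
        expected = (config.n_units_initial, len(config.muscles))
        if coupling.shape != expected:
            raise ConfigurationError(
                f"baseline_coupling must have shape {expected}")
        if coupling.min() < 0 or coupling.max() > 1:
            raise ConfigurationError("coupling gains must lie in [0, 1]")
        return coupling
    rng = _study_rng(config, 1)
    return rng.uniform(0.2, 1.0, (config.n_units_initial, len(config.muscles)))


def unit_count_schedule(config: GeneratorConfig) -> np.ndarray:
    """Units available per session: round(n_k * (1 - dropout)) recursion."""
    counts = np.empty(config.n_sessions, dtype=int)
    n = config.n_units_initial
    for k in range(config.n_sessions):
        counts[k] = n
        n = max(1, int(np.floor(n * (1.0 - config.unit_dropout_rate) + 0.5)))
    return counts


def recovery_gain(attenuation: float, recovery_rate: float, k: int) -> float:
    """Coupling multiplier ``k`` sessions after the lesion.

    Exponential relaxation toward baseline: g_k = 1 - (1 - a)(1 - rho)^k,
    so g_0 = a at the lesion session and g_k -> 1.
    """
    return 1.0 - (1.0 - attenuation) * (1.0 - recovery_rate) ** k


def coupling_schedule(config: GeneratorConfig, session_index: int) -> np.ndarray:
    """Unit-by-muscle coupling gains for one session.

    Pre-lesion sessions return the baseline matrix.  At and after the lesion
    each muscle column is multiplied by its side's recovery gain, which never
    exceeds one, so gains never exceed baseline.
    """
    config.validate()
    if not (0 <= session_index < config.n_sessions):
        raise IndexError(
            f"session_index {session_index} outside 0..{config.n_sessions - 1}")
    base = draw_baseline_coupling(config)
    if session_index < config.lesion_session:
        return base.copy()
    k = session_index - config.lesion_session
    gains = np.array([
        recovery_gain(
            config.lesion_attenuation_ipsi if muscle_side(m) == "ipsi"
            else config.lesion_attenuation_contra,
            config.recovery_rate, k)
        for m in config.muscles
    ])
    return base * gains[np.newaxis, :]


def day_index_of(config: GeneratorConfig, session_index: int) -> int:
    """Calendar day relative to the lesion: weekly pre sessions, first post
    session three weeks after surgery, weekly thereafter."""
    if session_index < config.lesion_session:
        return -7 * (config.lesion_session - session_index)
    return 21 + 7 * (session_index - config.lesion_session)


def _behaviour_params(config: GeneratorConfig,
                      session_index: int) -> tuple[float, float]:
    """(mean steps per run, walking fraction) for one session."""
    if session_index < config.lesion_session:
        return config.steps_per_run_pre, config.walk_fraction_pre
    k = session_index - config.lesion_session
    g = recovery_gain(config.lesion_attenuation_ipsi, config.recovery_rate, k)
    frac = (g - config.lesion_attenuation_ipsi) / max(
        1e-12, 1.0 - config.lesion_attenuation_ipsi)
    r0, r1 = config.steps_per_run_post
    w0, w1 = config.walk_fraction_post
    return r0 + (r1 - r0) * frac, w0 + (w1 - w0) * frac


def _simulate_gait(config: GeneratorConfig, session_index: int,
                   rng: np.random.Generator) -> GaitAnnotation:
    """Runs of consecutive steps separated by rest gaps."""
    mean_run, walk_fraction = _behaviour_params(config, session_index)
    nominal = 1.0 / config.gait_frequency
    duration = config.session_duration

    steps: list[tuple[float, float]] = []
    run_ids: list[int] = []
    reasons: dict[int, str] = {}
    t = min(2.0, 0.02 * duration)  # settle time before the first run
    run = 0
    while t + nominal < duration:
        n_steps = max(1, int(rng.poisson(mean_run)))
        durs = nominal * np.clip(
            1.0 + config.step_cv * rng.standard_normal(n_steps), 0.7, 1.3)
        truncated = False
        for d in durs:
            if t + d > duration:
                truncated = True
                break
            steps.append((t, t + d))
            run_ids.append(run)
            t += d
        if run_ids and run_ids[-1] == run:
            if truncated:
                reasons[run] = "session_end"
            else:
                reasons[run] = str(rng.choice(
                    ["hindpaw_drag", "posture_change"]))
            run += 1
        if truncated:
            break
        walk_time = float(np.sum(durs))
        gap = walk_time * (1.0 - walk_fraction) / max(walk_fraction, 1e-6)
        t += gap * rng.uniform(0.5, 1.5)
    if not steps:  # degenerate short session: one step
        steps = [(0.0, min(nominal, duration))]
        run_ids = [0]
        reasons = {0: "session_end"}
    return GaitAnnotation(steps=np.array(steps), run_ids=np.array(run_ids),
                          termination_reason=reasons)


def _phase_arrays(gait: GaitAnnotation, duration: float,
                  fs: float) -> tuple[np.ndarray, np.ndarray]:
    """(gait phase in [0,1), walking mask) sampled at ``fs``."""
    n = int(round(duration * fs))
    phase = np.zeros(n)
    walking = np.zeros(n, dtype=bool)
    for start, end in gait.steps:
        i0, i1 = int(np.ceil(start * fs)), min(n, int(np.ceil(end * fs)))
        if i1 <= i0:
            continue
        t = np.arange(i0, i1) / fs
        phase[i0:i1] = (t - start) / (end - start)
        walking[i0:i1] = True
    return phase, walking


def _burst_template(muscle: str, phase: np.ndarray) -> np.ndarray:
    """Raised-cosine activation burst at the muscle's canonical gait phase."""
    key = muscle[1:]  # strip the L/R side prefix
    centre = _BURST_PHASE[key]
    if muscle.startswith("R"):
        centre = (centre + 0.5) % 1.0
    delta = np.mod(phase - centre + 0.5, 1.0) - 0.5
    inside = np.abs(delta) <= _BURST_WIDTH / 2
    burst = np.zeros_like(phase)
    burst[inside] = 0.5 * (1 + np.cos(2 * np.pi * delta[inside] / _BURST_WIDTH))
    return burst


def _poisson_spikes(lam_of_t, lam_max: float, duration: float,
                    rng: np.random.Generator,
                    dead_time_s: float = 0.0) -> np.ndarray:
    """Inhomogeneous Poisson spike times by thinning a rate-``lam_max`` train,
    then greedily enforcing an absolute refractory period."""
    n_cand = rng.poisson(lam_max * duration)
    cand = np.sort(rng.uniform(0.0, duration, n_cand))
    keep = rng.uniform(0.0, lam_max, n_cand) < lam_of_t(cand)
    times = cand[keep]
    if dead_time_s <= 0 or times.size < 2:
        return times
    kept = [times[0]]
    last = times[0]
    for t in times[1:]:
        if t - last >= dead_time_s:
            kept.append(t)
            last = t
    return np.asarray(kept)


def simulate_session(config: GeneratorConfig, session_index: int) -> Session:
    """Generate one session deterministically from (seed, session_index)."""
    config.validate()
    if not (0 <= session_index < config.n_sessions):
        raise IndexError(
            f"session_index {session_index} outside 0..{config.n_sessions - 1}")

    population = draw_population(config)
    coupling = coupling_schedule(config, session_index)
    n_units = unit_count_schedule(config)[session_index]
    rng = _study_rng(config, 100 + session_index)

    gait = _simulate_gait(config, session_index, rng)
    fs = 1000.0
    duration = config.session_duration
    phase_ms, walking_ms = _phase_arrays(gait, duration, fs)

    # --- spike trains: gait-locked inhomogeneous Poisson, thinning method ---
    trains: list[SpikeTrain] = []
    for u in range(n_units):
        b = population.baseline_hz[u]
        a = population.modulation_hz[u]
        phi = population.preferred_phase[u]

        def lam(t: np.ndarray, b=b, a=a, phi=phi) -> np.ndarray:
            idx = np.minimum((t * fs).astype(int), phase_ms.size - 1)
            mod = a * np.maximum(
                0.0, np.cos(2 * np.pi * phase_ms[idx] - phi))
            return b + np.where(walking_ms[idx], mod, 0.0)

        times = _poisson_spikes(lam, b + a, duration, rng,
                                dead_time_s=config.dead_time_ms / 1000.0)
        trains.append(SpikeTrain(unit_id=u,
                                 channel_id=int(population.channel_id[u]),
                                 times=np.unique(times)))

    # --- population drive at 20 ms resolution, per muscle -------------------
    bin_w = 0.02
    edges = np.arange(0.0, duration + bin_w, bin_w)
    n_bins = edges.size - 1
    counts = np.zeros((n_bins, n_units))
    for u, train in enumerate(trains):
        counts[:, u], _ = np.histogram(train.times, bins=edges)
    smooth = gaussian_filter1d(counts, sigma=2.5, axis=0, mode="reflect")

    expected_counts = population.mean_rate_hz[:n_units] * bin_w
    base = draw_baseline_coupling(config)[:n_units, :]
    norms = base.T @ expected_counts            # per-muscle normaliser
    drive_bins = smooth @ coupling[:n_units, :]  # (n_bins, n_muscles)
    drive_bins /= np.maximum(norms, 1e-12)[np.newaxis, :]

    bin_centres = (edges[:-1] + edges[1:]) / 2
    t_ms = np.arange(int(round(duration * fs))) / fs

    # per-muscle recovery gains drive both amplitude and burst-timing
    # disorganisation (per-step phase jitter shrinks as coupling recovers)
    if session_index < config.lesion_session:
        muscle_gains = np.ones(len(config.muscles))
    else:
        k_post = session_index - config.lesion_session
        muscle_gains = np.array([
            recovery_gain(
                config.lesion_attenuation_ipsi if muscle_side(m) == "ipsi"
                else config.lesion_attenuation_contra,
                config.recovery_rate, k_post)
            for m in config.muscles
        ])

    # --- EMG: burst envelope x drive, emitted as modulated interference -----
    traces: list[EMGTrace] = []
    step_sample_slices = [
        (int(np.ceil(start * fs)), min(t_ms.size, int(np.ceil(end * fs))))
        for start, end in gait.steps
    ]
    for j, muscle in enumerate(config.muscles):
        drive = np.interp(t_ms, bin_centres, drive_bins[:, j])
        deficit = 1.0 - muscle_gains[j]
        jitter_sd = config.phase_jitter_sd * deficit
        amp_sd = config.amp_jitter_sd * deficit
        shift = np.zeros(t_ms.size)
        gain = np.ones(t_ms.size)
        if deficit > 0 and gait.n_steps:
            deltas = rng.normal(0.0, jitter_sd, gait.n_steps)
            amps = np.exp(rng.normal(0.0, amp_sd, gait.n_steps)
                          - amp_sd ** 2 / 2)
            for (i0, i1), delta, amp in zip(step_sample_slices, deltas, amps):
                shift[i0:i1] = delta
                gain[i0:i1] = amp
        envelope = _burst_template(muscle, phase_ms - shift) * drive * gain
        envelope[~walking_ms] = 0.0
        raw = np.maximum(
            0.0,
            envelope + config.noise_sd * rng.standard_normal(t_ms.size))
        traces.append(EMGTrace(muscle=muscle, sample_rate=fs, samples=raw))

    # --- broadband artifacts: all EMG channels + coincident unit events -----
    n_artifacts = rng.poisson(config.artifact_rate * duration / 60.0)
    artifact_times = np.sort(rng.uniform(0.0, max(
        1e-6, duration - config.artifact_duration), n_artifacts))
    for t0 in artifact_times:
        i0 = int(t0 * fs)
        i1 = min(t_ms.size, i0 + int(config.artifact_duration * fs))
        blast = 25.0 * rng.standard_normal(i1 - i0)
        for trace in traces:
            trace.samples[i0:i1] += blast
        for train in trains:
            train.times = np.unique(np.concatenate(
                [train.times, [t0 + 1e-4 * train.unit_id / max(1, n_units)]]))

    return Session(
        session_id=f"S{session_index:02d}",
        day_index=day_index_of(config, session_index),
        duration=duration,
        speed=config.speed,
        spike_trains=trains,
        emg_traces=traces,
        gait=gait,
    )


def simulate_study(config: GeneratorConfig,
                   out_dir: str | Path | None = None) -> list[Session]:
    """Generate all sessions; optionally write them plus a study manifest."""
    config.validate()
    sessions = [simulate_session(config, k) for k in range(config.n_sessions)]
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        rows = []
        for session in sessions:
            write_session(session, out_dir / session.session_id)
            rows.append({
                "session_id": session.session_id,
                "day_index": session.day_index,
                "phase": session.phase,
                "speed_m_per_s": session.speed,
                "n_units": session.n_units,
                "n_steps": session.gait.n_steps,
            })
        pd.DataFrame(rows).to_csv(out_dir / "manifest.tsv", sep="\t",
                                  index=False)
    return sessions


def study_manifest(config: GeneratorConfig) -> pd.DataFrame:
    """Study manifest without simulating spikes/EMG (shape bookkeeping)."""
    counts = unit_count_schedule(config)
    rows = [{
        "session_id": f"S{k:02d}",
        "day_index": day_index_of(config, k),
        "phase": "pre" if day_index_of(config, k) < 0 else "post",
        "speed_m_per_s": config.speed,
        "n_units": int(counts[k]),
    } for k in range(config.n_sessions)]
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# optional raw-trace mode (exercises threshold-crossing spike extraction)
# ---------------------------------------------------------------------------

def synthesize_raw_trace(spike_times: np.ndarray, duration: float,
                         sample_rate: float = 40_000.0,
                         noise_sd: float = 1.0, amplitude: float = 10.0,
                         seed: int = 0) -> np.ndarray:
    """Broadband extracellular voltage: Gaussian noise plus biphasic spikes.

    Each spike is a negative-leading biphasic waveform of peak
    ``amplitude * noise_sd`` inserted at its event time; used to exercise
    RMS-threshold spike extraction without storing 40 kHz data.
    """
    rng = np.random.default_rng(seed)
    n = int(round(duration * sample_rate))
    trace = noise_sd * rng.standard_normal(n)
    # 0.8 ms biphasic template: sharp negative lobe then smaller positive lobe
    w = int(0.0008 * sample_rate)
    t = np.arange(w) / sample_rate
    template = -np.sin(np.pi * t / t[-1]) * np.exp(-t / 3e-4)
    template[w // 2:] *= -0.4
    template *= amplitude * noise_sd / np.abs(template).max()
    for s in np.atleast_1d(spike_times):
        i0 = int(round(s * sample_rate))
        i1 = min(n, i0 + w)
        if i0 < n:
            trace[i0:i1] += template[: i1 - i0]
    return trace


__all__ = [
    "ConfigurationError",
    "GeneratorConfig",
    "UnitPopulation",
    "coupling_schedule",
    "day_index_of",
    "draw_baseline_coupling",
    "draw_population",
    "recovery_gain",
    "simulate_session",
    "simulate_study",
    "study_manifest",
    "synthesize_raw_trace",
    "unit_count_schedule",
]
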