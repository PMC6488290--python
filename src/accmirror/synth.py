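"""Ground-truth synthetic experiments.

Generates complete recording sessions — trial schedules, spike trains with
waveform snippets, multi-contact continuous voltage, ethograms, head-angle
traces and audio time–frequency energy tracks — with a known unit-level
ground truth, emulating a three-session design: witnessing footshocks to a
conspecific (ShockObs), first-hand nociceptive heat-laser pulses (Laser),
and playback of a fear-conditioned tone (CS).

Spiking is an inhomogeneous Poisson process: a stationary baseline rate
plus, for each trial of a condition the unit's profile responds to, an
expected number of added spikes distributed over the session's response
window according to a unimodal alpha kernel. Habituation multiplies the
gain by a per-trial decay factor (applied to the ShockObs and CS sessions
only, where habituation is empirically observed). Waveform drift across
sessions scales the template amplitude and adds shape noise so the
cross-session cleanup filters have calibrated positives and negatives.

All randomness flows from one master seed through named substreams, so a
fixed seed reproduces schedules, spikes, noise and behavior bit-for-bit.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .windows import RESPONSE_WINDOWS, SESSION_TYPES

# --------------------------------------------------------------------------
# seeding

def substream(seed: int, *names: str) -> np.random.Generator:
    """Named child generator of a master seed (stable across runs)."""
    keys = [zlib.crc32(n.encode()) for n in names]
    return np.random.default_rng(np.random.SeedSequence([int(seed) % (2**31), *keys]))


# --------------------------------------------------------------------------
# trial schedules

INTENSITY_CODE = {"Ctrl": 0, "Low": 1, "High": 2}


@dataclass
class ScheduleDesign:
    """Session design: trial counts per condition, timing, gaps."""

    session_type: str
    counts: dict[str, int]
    gap_choices: tuple[float, ...]
    duration_s: float
    baseline_s: float

    @classmethod
    def shockobs(cls, n_high=10, n_low=10, n_ctrl=20, baseline_s=720.0):
        """Shock-observation session; the full design has 10 High (1.5 mA),
        10 Low (0.4 mA) and 20 Ctrl 1 s shocks at 60/90 s gaps."""
        return cls(
            "ShockObs",
            {"High": n_high, "Low": n_low, "Ctrl": n_ctrl},
            (60.0, 90.0),
            1.0,
            baseline_s,
        )

    @classmethod
    def laser(cls, n_high=10, n_low=10, n_ctrl=20, baseline_s=300.0):
        """Laser session: 200 ms pulses, 24/36 s inter-stimulus intervals."""
        return cls(
            "Laser",
            {"High": n_high, "Low": n_low, "Ctrl": n_ctrl},
            (24.0, 36.0),
            0.2,
            baseline_s,
        )

    @classmethod
    def cs(cls, n_cs=10, baseline_s=720.0):
        """CS recall session: ten 20 s tone presentations at 60/90 s gaps."""
        return cls("CS", {"CS": n_cs}, (60.0, 90.0), 20.0, baseline_s)


@dataclass
class TrialSchedule:
    """Ordered stimulus events of one session.

    ``trials`` columns: trial_index, condition, intensity_code (nullable —
    CS trials carry none), onset_s, duration_s. Onsets strictly increase
    and successive inter-onset gaps come only from the design's gap set.
    """

    session_id: str
    trials: pd.DataFrame

    @property
    def n_trials(self) -> int:
        return len(self.trials)

    @property
    def onsets(self) -> np.ndarray:
        return self.trials["onset_s"].to_numpy(float)

    @property
    def conditions(self) -> np.ndarray:
        return self.trials["condition"].to_numpy()

    def onsets_for(self, condition: str) -> np.ndarray:
        m = self.trials["condition"] == condition
        return self.trials.loc[m, "onset_s"].to_numpy(float)

    @property
    def session_duration(self) -> float:
        """End of the rendered session: last event + 30 s tail."""
        if self.n_trials == 0:
            return 30.0
        last = self.trials.iloc[-1]
        return float(last["onset_s"] + max(last["duration_s"], 1.0) + 30.0)


def make_schedule(design: ScheduleDesign, seed: int) -> TrialSchedule:
    """Pseudo-randomly interleaved trial schedule, deterministic per seed."""
    if design.session_type not in SESSION_TYPES:
        raise ValueError(f"unknown session type: {design.session_type!r}")
    if any(n < 0 for n in design.counts.values()):
        raise ValueError("trial counts must be non-negative")
    rng = substream(seed, "schedule", design.session_type)
    labels = [c for c, n in sorted(design.counts.items()) for _ in range(n)]
    rng.shuffle(labels)
    onsets, t = [], design.baseline_s
    for _ in labels:
        onsets.append(t)
        t += rng.choice(design.gap_choices)
    codes = [INTENSITY_CODE.get(c, pd.NA) for c in labels]
    trials = pd.DataFrame(
        {
            "trial_index": np.arange(len(labels)),
            "condition": labels,
            "intensity_code": pd.array(codes, dtype="Int64"),
            "onset_s": onsets,
            "duration_s": design.duration_s,
        }
    )
    return TrialSchedule(design.session_type, trials)


# --------------------------------------------------------------------------
# ground-truth units

PROFILES = (
    "pain_mirror",
    "fear_mirror",
    "unselective_mirror",
    "social_only",
    "laser_only",
    "cs_only",
    "nonresponsive",
)

#: (session, condition) gain keys that are nonzero for each profile.
#: ShockObs responses are graded (High and a weaker Low) in every socially
#: responsive profile; Laser responses appear only at High intensity (the
#: Low laser is calibrated below the nociceptive threshold); CS gains exist
#: only in fear-selective and unselective profiles.
PROFILE_GAIN_KEYS = {
    "pain_mirror": (("ShockObs", "High"), ("ShockObs", "Low"), ("Laser", "High")),
    "fear_mirror": (("ShockObs", "High"), ("ShockObs", "Low"), ("CS", "CS")),
    "unselective_mirror": (
        ("ShockObs", "High"),
        ("ShockObs", "Low"),
        ("Laser", "High"),
        ("CS", "CS"),
    ),
    "social_only": (("ShockObs", "High"), ("ShockObs", "Low")),
    "laser_only": (("Laser", "High"),),
    "cs_only": (("CS", "CS"),),
    "nonresponsive": (),
}

#: Sessions whose responses habituate across repeated trials.
HABITUATING_SESSIONS = frozenset({"ShockObs", "CS"})


@dataclass
class DriftParams:
    """Per-session waveform drift: amplitude scaling and shape noise SD
    (absolute, in template units)."""

    amplitude_scale: float = 1.0
    shape_noise_sd: float = 0.0


def default_template(n_samples: int = 32) -> np.ndarray:
    """Biphasic extracellular spike template spanning 1 ms."""
    t = np.linspace(0.0, 1.0, n_samples)
    w = -np.exp(-(((t - 0.25) / 0.08) ** 2)) + 0.45 * np.exp(
        -(((t - 0.55) / 0.15) ** 2)
    )
    return 80.0 * w  # microvolt scale


@dataclass
class GroundTruthUnit:
    """A simulated neuron with a known response profile."""

    unit_id: str
    profile: str
    baseline_rate: float = 5.0
    gains: dict[tuple[str, str], float] = field(default_factory=dict)
    response_windows: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(RESPONSE_WINDOWS)
    )
    habituation_factor: float = 1.0
    waveform_template: np.ndarray = field(default_factory=default_template)
    session_drift: dict[str, DriftParams] = field(default_factory=dict)
    home_contact: int = 0

    def __post_init__(self) -> None:
        if self.profile not in PROFILES:
            raise ValueError(f"unknown profile: {self.profile!r}")
        if self.baseline_rate < 0:
            raise ValueError("baseline_rate must be >= 0")
        if any(g < 0 for g in self.gains.values()):
            raise ValueError("gains must be >= 0")
        if not 0 < self.habituation_factor <= 1:
            raise ValueError("habituation_factor must be in (0, 1]")

    def gain(self, session_id: str, condition: str) -> float:
        return self.gains.get((session_id, condition), 0.0)


def make_units(
    composition: dict[str, int],
    seed: int,
    gain: float = 8.0,
    low_gain_fraction: float = 0.5,
    baseline_rate: float = 5.0,
    habituation_factor: float = 0.93,
    n_contacts: int = 30,
) -> list[GroundTruthUnit]:
    """Build a unit population from a ``{profile: count}`` composition.

    Gains follow the profile contract (nonzero exactly for the profile's
    conditions); baseline rates are jittered log-normally around
    ``baseline_rate`` so the population is heterogeneous; home contacts
    are assigned round-robin.
    """
    rng = substream(seed, "units")
    units: list[GroundTruthUnit] = []
    i = 0
    for profile in PROFILES:
        for _ in range(composition.get(profile, 0)):
            gains = {}
            for key in PROFILE_GAIN_KEYS[profile]:
                g = gain * (low_gain_fraction if key[1] == "Low" else 1.0)
                gains[key] = g
            base = float(baseline_rate * rng.lognormal(0.0, 0.3))
            units.append(
                GroundTruthUnit(
                    unit_id=f"u{i:03d}",
                    profile=profile,
                    baseline_rate=base,
                    gains=gains,
                    habituation_factor=habituation_factor,
                    home_contact=i % n_contacts,
                )
            )
            i += 1
    return units


def ground_truth_table(units: list[GroundTruthUnit]) -> pd.DataFrame:
    rows = []
    for u in units:
        row = {
            "unit_id": u.unit_id,
            "profile": u.profile,
            "baseline_rate": u.baseline_rate,
            "habituation_factor": u.habituation_factor,
            "home_contact": u.home_contact,
        }
        for (sess, cond), g in u.gains.items():
            row[f"gain_{sess}_{cond}"] = g
        rows.append(row)
    return pd.DataFrame(rows).fillna(0.0)


# --------------------------------------------------------------------------
# spike simulation

@dataclass
class SpikeTrain:
    """Spike times (s) of one unit in one session, with optional per-spike
    waveform snippets aligned row-for-row with ``times``."""

    unit_id: str
    session_id: str
    times: np.ndarray
    waveforms: np.ndarray | None = None

    @property
    def n_spikes(self) -> int:
        return len(self.times)

    def rate(self, duration: float) -> float:
        return self.n_spikes / duration if duration > 0 else np.nan


def response_kernel(
    window: tuple[float, float],
    rise_ms: float = 50.0,
    decay_ms: float = 300.0,
    dt: float = 0.001,
) -> tuple[np.ndarray, np.ndarray]:
    """Unit-area alpha-style kernel supported on the response window.

    Difference-of-exponentials with the given rise and decay constants,
    truncated to the window and renormalized to integrate to 1.
    """
    start, end = window
    u = np.arange(0.0, end - start, dt)
    k = np.exp(-u / (decay_ms / 1000.0)) - np.exp(-u / (rise_ms / 1000.0))
    k = np.clip(k, 0.0, None)
    area = k.sum() * dt
    if area <= 0:
        raise ValueError("degenerate kernel")
    return start + u, k / area


def _sample_kernel_offsets(rng, n, window, rise_ms=50.0, decay_ms=300.0):
    grid, k = response_kernel(window, rise_ms, decay_ms)
    cdf = np.cumsum(k)
    cdf /= cdf[-1]
    return np.interp(rng.random(n), cdf, grid)


def simulate_spikes(
    units: list[GroundTruthUnit],
    schedule: TrialSchedule,
    seed: int,
    duration: float | None = None,
    kernel_rise_ms: float = 50.0,
    kernel_decay_ms: float = 300.0,
) -> list[SpikeTrain]:
    """Inhomogeneous-Poisson spike trains for every unit over one session.

    rate(t) = baseline + Σ_trials gain(condition)·h^k·kernel(t − onset),
    with h the habituation factor and k the trial index within its
    condition (habituating sessions only). The kernel integrates to 1, so
    ``gain`` is the expected number of added spikes on the first trial.
    """
    duration = schedule.session_duration if duration is None else duration
    session = schedule.session_id
    out = []
    for u in units:
        rng = substream(seed, "spikes", session, u.unit_id)
        n_base = rng.poisson(u.baseline_rate * duration)
        times = [rng.uniform(0.0, duration, n_base)]
        window = u.response_windows.get(session, RESPONSE_WINDOWS[session])
        habituate = session in HABITUATING_SESSIONS
        cond_counter: dict[str, int] = {}
        for _, tr in schedule.trials.iterrows():
            cond = tr["condition"]
            k = cond_counter.get(cond, 0)
            cond_counter[cond] = k + 1
            g = u.gain(session, cond)
            if g <= 0:
                continue
            if habituate:
                g *= u.habituation_factor**k
            n_resp = rng.poisson(g)
            if n_resp:
                offs = _sample_kernel_offsets(
                    rng, n_resp, window, kernel_rise_ms, kernel_decay_ms
                )
                times.append(tr["onset_s"] + offs)
        t = np.sort(np.concatenate(times))
        out.append(SpikeTrain(u.unit_id, session, t))
    return out


def expected_window_count(
    unit: GroundTruthUnit,
    session: str,
    condition: str,
    window: tuple[float, float],
    trial_index_in_condition: int = 0,
) -> float:
    """Closed-form expected spike count in a peri-onset window.

    Baseline contributes rate × length; the response kernel contributes
    its integral over the window times the (habituated) gain.
    """
    g = unit.gain(session, condition)
    if session in HABITUATING_SESSIONS:
        g *= unit.habituation_factor**trial_index_in_condition
    grid, k = response_kernel(unit.response_windows.get(session, RESPONSE_WINDOWS[session]))
    dt = grid[1] - grid[0]
    mask = (grid >= window[0]) & (grid < window[1])
    return unit.baseline_rate * (window[1] - window[0]) + g * k[mask].sum() * dt


# --------------------------------------------------------------------------
# continuous rendering

@dataclass
class ProbeGeometry:
    """Multi-shank probe: ``n_shafts`` vertical columns of ``n_contacts``
    contacts each; channel index = shaft·n_contacts + position."""

    n_shafts: int = 5
    n_contacts: int = 6

    @property
    def n_channels(self) -> int:
        return self.n_shafts * self.n_contacts

    @property
    def shaft_map(self) -> list[list[int]]:
        n = self.n_contacts
        return [list(range(s * n, (s + 1) * n)) for s in range(self.n_shafts)]


@dataclass
class NoiseConfig:
    white_sd: float = 5.0
    pink_sd: float = 2.0
    #: Artifact injection: trial onsets (s) at which a large transient is
    #: added simultaneously on a fraction of contacts.
    artifact_onsets: tuple[float, ...] = ()
    artifact_amplitude: float = 2000.0
    artifact_duration_s: float = 0.1
    artifact_channel_fraction: float = 1.0


@dataclass
class ContinuousRecording:
    """Multi-contact voltage matrix (channels × samples, float32)."""

    data: np.ndarray
    fs_hz: float
    shaft_map: list[list[int]]
    channel_names: list[str] | None = None
    meta: dict = field(default_factory=dict)

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.fs_hz


def _pink_noise(rng, n, sd):
    """1/f-shaped Gaussian noise normalized to the requested SD."""
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    f = np.fft.rfftfreq(n)
    f[0] = f[1] if n > 1 else 1.0
    spec /= np.sqrt(f)
    x = np.fft.irfft(spec, n)
    s = x.std()
    return x * (sd / s) if s > 0 else x


def render_continuous(
    spike_trains: list[SpikeTrain],
    units: list[GroundTruthUnit],
    duration: float,
    geometry: ProbeGeometry | None = None,
    fs_hz: float = 8000.0,
    noise: NoiseConfig | None = None,
    seed: int = 0,
    neighbor_attenuation: float = 0.4,
) -> ContinuousRecording:
    """Render spike trains into a multi-contact continuous recording.

    Each spike inserts the unit's waveform template (resampled from its
    native 1 ms span to ``fs_hz``) at the unit's home contact, with
    attenuated copies on the vertically adjacent contacts; additive white
    plus 1/f noise; optional artifact transients on a configurable
    fraction of contacts.
    """
    if fs_hz < 4000.0:
        raise ValueError("sampling rate must be >= 4 kHz to support a 1 kHz high-pass")
    geometry = geometry or ProbeGeometry()
    noise = noise or NoiseConfig()
    rng = substream(seed, "noise")
    n_samp = int(round(duration * fs_hz))
    data = np.zeros((geometry.n_channels, n_samp), dtype=np.float64)

    by_id = {u.unit_id: u for u in units}
    for st in spike_trains:
        u = by_id[st.unit_id]
        tpl = u.waveform_template
        n_tpl = max(2, int(round(len(tpl) * fs_hz / 32000.0)))
        tpl_fs = np.interp(
            np.linspace(0, 1, n_tpl), np.linspace(0, 1, len(tpl)), tpl
        )
        home = u.home_contact % geometry.n_channels
        shaft, pos = divmod(home, geometry.n_contacts)
        targets = [(home, 1.0)]
        if pos > 0:
            targets.append((home - 1, neighbor_attenuation))
        if pos < geometry.n_contacts - 1:
            targets.append((home + 1, neighbor_attenuation))
        idx0 = np.round(st.times * fs_hz).astype(int)
        for i0 in idx0:
            i1 = min(i0 + n_tpl, n_samp)
            if i0 >= n_samp or i1 <= i0:
                continue
            for ch, w in targets:
                data[ch, i0:i1] += w * tpl_fs[: i1 - i0]

    if noise.white_sd > 0 or noise.pink_sd > 0:
        for ch in range(geometry.n_channels):
            if noise.white_sd > 0:
                data[ch] += rng.normal(0.0, noise.white_sd, n_samp)
            if noise.pink_sd > 0:
                data[ch] += _pink_noise(rng, n_samp, noise.pink_sd)

    if noise.artifact_onsets:
        n_art = max(1, int(round(noise.artifact_channel_fraction * geometry.n_channels)))
        chans = rng.choice(geometry.n_channels, size=n_art, replace=False)
        # per-contact gain spread: real artifacts are never perfectly
        # common-mode, so they survive pairwise re-referencing
        gains = rng.uniform(0.5, 1.5, n_art)
        n_dur = int(round(noise.artifact_duration_s * fs_hz))
        for onset in noise.artifact_onsets:
            i0 = int(round(onset * fs_hz))
            i1 = min(i0 + n_dur, n_samp)
            if i0 >= n_samp:
                continue
            burst = noise.artifact_amplitude * np.sin(
                2 * np.pi * 2000.0 * np.arange(i1 - i0) / fs_hz
            )
            data[chans[:, None], np.arange(i0, i1)[None, :]] += gains[:, None] * burst

    names = [f"sh{s}c{p}" for s in range(geometry.n_shafts) for p in range(geometry.n_contacts)]
    return ContinuousRecording(
        data=data.astype(np.float32),
        fs_hz=fs_hz,
        shaft_map=geometry.shaft_map,
        channel_names=names,
    )


# --------------------------------------------------------------------------
# behavior and audio

@dataclass
class AudioEnergyTrack:
    """Time–frequency energy matrix (freqs × times), non-negative."""

    times: np.ndarray  # bin centers, s
    freqs: np.ndarray  # Hz
    energy: np.ndarray  # (n_freqs, n_times)

    @property
    def dt(self) -> float:
        return float(self.times[1] - self.times[0]) if len(self.times) > 1 else np.nan

    def window(self, t0: float, t1: float) -> np.ndarray:
        """Energy submatrix with bin centers in [t0, t1)."""
        m = (self.times >= t0) & (self.times < t1)
        return self.energy[:, m]


@dataclass
class BehaviorParams:
    squeak_prob_high: float = 1.0
    squeak_prob_low: float = 0.5
    squeak_duration_s: float = 0.3
    squeak_energy: float = 20.0
    n_usv_22khz: int = 5
    usv_energy: float = 8.0
    freezing_fraction: float = 0.3
    attention_rise_s: float = 3.0
    audio_dt: float = 0.05
    audio_fmax: float = 80_000.0
    audio_nfreq: int = 41
    background_energy: float = 1.0


@dataclass
class Ethogram:
    """Labeled behavior intervals + head-angle time series."""

    intervals: pd.DataFrame  # behavior, start_s, stop_s
    head_angle: pd.DataFrame  # time_s, alpha_deg


@dataclass
class BehaviorData:
    ethogram: Ethogram
    audio: AudioEnergyTrack
    squeak_times: np.ndarray
    jump_times: np.ndarray


def simulate_behavior(
    schedule: TrialSchedule, params: BehaviorParams | None = None, seed: int = 0
) -> BehaviorData:
    """Demonstrator/observer behavior time-locked to a ShockObs or CS session.

    Squeaks and jumps land within (0, 1) s after High shocks (always, at the
    default probability) and Low shocks (reduced probability), never after
    Ctrl; 22 kHz vocalizations are placed without time-locking; freezing
    bouts fill a configurable fraction of the session; the head-angle trace
    drops toward the demonstrator (high attention) after shocks.
    """
    if schedule.session_id not in ("ShockObs", "CS"):
        raise ValueError("behavior simulation requires a ShockObs or CS session")
    params = params or BehaviorParams()
    rng = substream(seed, "behavior", schedule.session_id)
    duration = schedule.session_duration

    # -- squeaks / jumps ------------------------------------------------
    squeaks, jumps = [], []
    for _, tr in schedule.trials.iterrows():
        cond = tr["condition"]
        p = {"High": params.squeak_prob_high, "Low": params.squeak_prob_low}.get(cond, 0.0)
        if rng.random() < p:
            t = tr["onset_s"] + rng.uniform(0.0, max(1.0 - params.squeak_duration_s, 0.0))
            squeaks.append(t)
            jumps.append(t)
    squeaks = np.array(sorted(squeaks))
    jumps = np.array(sorted(jumps))

    # -- audio energy track --------------------------------------------
    times = np.arange(0.0, duration, params.audio_dt) + params.audio_dt / 2
    freqs = np.linspace(0.0, params.audio_fmax, params.audio_nfreq)
    energy = params.background_energy * (
        1.0 + 0.1 * rng.random((params.audio_nfreq, len(times)))
    )
    for t in squeaks:  # broadband burst: all frequency rows
        m = (times >= t) & (times < t + params.squeak_duration_s)
        energy[:, m] += params.squeak_energy
    usv_rows = (freqs >= 20_000.0) & (freqs <= 24_000.0)
    for _ in range(params.n_usv_22khz):
        t = rng.uniform(0.0, duration)
        m = (times >= t) & (times < t + 1.0)
        energy[np.ix_(usv_rows, m)] += params.usv_energy
    audio = AudioEnergyTrack(times=times, freqs=freqs, energy=energy)

    # -- freezing bouts -------------------------------------------------
    rows = []
    if params.freezing_fraction > 0:
        bout = 8.0
        t = 5.0
        while t + bout < duration:
            if rng.random() < params.freezing_fraction:
                rows.append(("freezing", t, t + bout * params.freezing_fraction))
            t += bout
    intervals = pd.DataFrame(rows, columns=["behavior", "start_s", "stop_s"])

    # -- head angle -----------------------------------------------------
    at = np.arange(0.0, duration, 0.2)
    alpha = np.clip(100.0 + np.cumsum(rng.normal(0, 4, len(at))), 40.0, 180.0)
    for _, tr in schedule.trials.iterrows():
        if tr["condition"] in ("High", "Low"):
            m = (at >= tr["onset_s"]) & (at < tr["onset_s"] + params.attention_rise_s)
            alpha[m] = rng.uniform(5.0, 25.0, m.sum())
    head = pd.DataFrame({"time_s": at, "alpha_deg": alpha})

    return BehaviorData(
        ethogram=Ethogram(intervals=intervals, head_angle=head),
        audio=audio,
        squeak_times=squeaks,
        jump_times=jumps,
    )


# --------------------------------------------------------------------------
# waveform drift

def drift_waveforms(
    unit: GroundTruthUnit, session_id: str, n_snippets: int, seed: int
) -> np.ndarray:
    """Per-session waveform snippets: amplitude-scaled template + shape noise.

    Drift parameters come from ``unit.session_drift[session_id]`` (identity
    drift when absent); with them, snippet populations can be placed on
    either side of the cross-session cleanup boundaries (0.85 waveform
    correlation, ±15% peak amplitude).
    """
    drift = unit.session_drift.get(session_id, DriftParams())
    rng = substream(seed, "drift", session_id, unit.unit_id)
    tpl = unit.waveform_template
    base = drift.amplitude_scale * tpl
    noise = rng.normal(0.0, drift.shape_noise_sd, (n_snippets, len(tpl)))
    return base[None, :] + noise


# --------------------------------------------------------------------------
# full experiment

@dataclass
class ExperimentConfig:
    """Composition and strength of a full three-session synthetic study."""

    composition: dict[str, int] = field(
        default_factory=lambda: {
            "pain_mirror": 25,
            "fear_mirror": 11,
            "unselective_mirror": 3,
            "social_only": 20,
            "nonresponsive": 14,
        }
    )
    gain: float = 8.0
    baseline_rate: float = 5.0
    habituation_factor: float = 0.93
    n_waveform_snippets: int = 100
    shockobs: ScheduleDesign | None = None
    laser: ScheduleDesign | None = None
    cs: ScheduleDesign | None = None
    behavior: BehaviorParams = field(default_factory=BehaviorParams)


@dataclass
class SyntheticDataset:
    """Everything one synthetic study produces, plus its ground truth."""

    schedules: dict[str, TrialSchedule]
    spike_trains: dict[str, list[SpikeTrain]]  # session -> trains
    units: list[GroundTruthUnit]
    ground_truth: pd.DataFrame
    behavior: BehaviorData | None = None
    recordings: dict[str, ContinuousRecording] = field(default_factory=dict)

    def trains_for(self, unit_id: str) -> dict[str, SpikeTrain]:
        return {
            sess: next(st for st in sts if st.unit_id == unit_id)
            for sess, sts in self.spike_trains.items()
        }


def simulate_experiment(
    config: ExperimentConfig | None = None,
    seed: int = 0,
    render: bool = False,
    simulate_behavior_track: bool = True,
) -> SyntheticDataset:
    """Generate a complete three-session experiment from one master seed."""
    config = config or ExperimentConfig()
    designs = {
        "ShockObs": config.shockobs or ScheduleDesign.shockobs(baseline_s=60.0),
        "Laser": config.laser or ScheduleDesign.laser(baseline_s=60.0),
        "CS": config.cs or ScheduleDesign.cs(baseline_s=60.0),
    }
    schedules = {s: make_schedule(d, seed) for s, d in designs.items()}
    units = make_units(
        config.composition,
        seed,
        gain=config.gain,
        baseline_rate=config.baseline_rate,
        habituation_factor=config.habituation_factor,
    )
    spike_trains = {}
    for sess, sched in schedules.items():
        trains = simulate_spikes(units, sched, seed)
        for st in trains:
            u = next(x for x in units if x.unit_id == st.unit_id)
            st.waveforms = drift_waveforms(
                u, sess, min(config.n_waveform_snippets, max(st.n_spikes, 1)), seed
            )
        spike_trains[sess] = trains

    behavior = (
        simulate_behavior(schedules["ShockObs"], config.behavior, seed)
        if simulate_behavior_track
        else None
    )
    recordings = {}
    if render:
        for sess, sched in schedules.items():
            recordings[sess] = render_continuous(
                spike_trains[sess], units, sched.session_duration, seed=seed
            )
    return SyntheticDataset(
        schedules=schedules,
        spike_trains=spike_trains,
        units=units,
        ground_truth=ground_truth_table(units),
        behavior=behavior,
        recordings=recordings,
    )
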