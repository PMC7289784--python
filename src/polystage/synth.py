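"""Synthetic polysomnography with stage-dependent structure.

No clinical recordings ship with this package, so every downstream component
is exercised on simulated data that carries the statistical features the
pipeline relies on:

* stage-dependent spectral content following the textbook AASM signatures —
  alpha-dominant wake, theta N1, spindle-bearing N2, high-amplitude delta N3,
  theta REM with saccadic anti-phase EOG deflections and EMG atonia;
* stage-transition structure from a first-order Markov chain (sleep is
  continuous — the 3-epoch splice exploits exactly this);
* arousals (brief wake-like intrusions that inflate N1) and severe class
  imbalance (N3 rare, W plentiful) via scenario presets shaped like a
  clinical OSA population;
* electrode-falloff artifacts (flatline, amplifier saturation, broadband
  noise) that the noise detector must catch.

Signals are generated at the 200 Hz source rate; the pipeline's own
anti-alias decimation is applied downstream, never here.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .io import Channel, Hypnogram, PSGRecord, ROLES, STAGES, STAGE_INDEX

SOURCE_RATE = 200.0
EPOCH_S = 30.0

EEG_ROLES = ("EEG_C3A2", "EEG_C4A1")
EOG_ROLES = ("EOG_L", "EOG_R")

Band = tuple[float, float, float]  # (low Hz, high Hz, relative power)


# ---------------------------------------------------------------------------
# Parameters
# ---------------------------------------------------------------------------

@dataclass
class StageSignalParams:
    """Spectral and event model per (stage, channel-role).

    ``bands[stage][role]`` lists (f_low, f_high, relative power) components;
    ``amplitude[stage][role]`` is the target RMS in µV.  A white-noise floor
    (``white_floor`` of total power, spread to the source Nyquist) keeps the
    stages learnable rather than trivially separable.
    """

    bands: dict[str, dict[str, list[Band]]]
    amplitude: dict[str, dict[str, float]]
    white_floor: float = 0.04
    spindle_rate_per_epoch: float = 2.0      # N2 only, 11–16 Hz bursts
    saccade_rate_per_epoch: float = 5.0      # REM only, anti-phase EOG
    nyquist: float = SOURCE_RATE / 2.0

    def validate(self) -> None:
        for stage in STAGES:
            if stage not in self.bands or stage not in self.amplitude:
                raise ValueError(f"missing signal parameters for stage {stage}")
            for role in ROLES:
                if role not in self.bands[stage] or role not in self.amplitude[stage]:
                    raise ValueError(
                        f"missing signal parameters for stage {stage}, role {role}"
                    )
                for lo, hi, p in self.bands[stage][role]:
                    if p < 0:
                        raise ValueError("relative band power must be >= 0")
                    if not (0 < lo < hi <= self.nyquist):
                        raise ValueError(
                            f"band ({lo}, {hi}) outside (0, Nyquist={self.nyquist}]"
                        )


def default_stage_params() -> StageSignalParams:
    """Textbook stage signatures at clinically plausible amplitudes."""
    eeg = {
        "W":  [(0.5, 4, 0.10), (4, 8, 0.15), (8, 13, 0.55), (13, 30, 0.20)],
        "N1": [(0.5, 4, 0.20), (4, 8, 0.55), (8, 13, 0.15), (13, 30, 0.10)],
        "N2": [(0.5, 4, 0.35), (4, 8, 0.35), (8, 11, 0.10), (11, 16, 0.12), (16, 30, 0.08)],
        "N3": [(0.5, 2, 0.75), (2, 8, 0.15), (8, 13, 0.05), (13, 30, 0.05)],
        "R":  [(0.5, 4, 0.15), (4, 8, 0.50), (8, 13, 0.20), (13, 30, 0.15)],
    }
    eog = {
        "W":  [(0.3, 2, 0.50), (4, 8, 0.20), (8, 13, 0.30)],
        "N1": [(0.3, 2, 0.60), (4, 8, 0.30), (8, 13, 0.10)],
        "N2": [(0.3, 2, 0.50), (4, 8, 0.35), (11, 16, 0.15)],
        "N3": [(0.5, 2, 0.80), (2, 8, 0.20)],
        "R":  [(0.3, 2, 0.45), (4, 8, 0.40), (8, 13, 0.15)],
    }
    emg = {s: [(10.0, 95.0, 1.0)] for s in STAGES}
    eeg_amp = {"W": 30.0, "N1": 35.0, "N2": 45.0, "N3": 80.0, "R": 30.0}
    eog_amp = {"W": 40.0, "N1": 45.0, "N2": 35.0, "N3": 60.0, "R": 35.0}
    emg_amp = {"W": 30.0, "N1": 10.0, "N2": 8.0, "N3": 6.0, "R": 2.5}
    bands = {
        s: {**{r: list(eeg[s]) for r in EEG_ROLES},
            **{r: list(eog[s]) for r in EOG_ROLES},
            "EMG": list(emg[s])}
        for s in STAGES
    }
    amplitude = {
        s: {**{r: eeg_amp[s] for r in EEG_ROLES},
            **{r: eog_amp[s] for r in EOG_ROLES},
            "EMG": emg_amp[s]}
        for s in STAGES
    }
    return StageSignalParams(bands=bands, amplitude=amplitude)


@dataclass
class FalloffEvent:
    """One electrode-falloff artifact on a single channel role."""

    role: str
    start_epoch: int
    n_epochs: int
    mode: str                 # flatline | saturation | hf_noise
    rail_uv: float = 250.0
    hf_noise_uv: float = 150.0

    def validate(self, total_epochs: int) -> None:
        if self.mode not in ("flatline", "saturation", "hf_noise"):
            raise ValueError(f"unknown falloff mode {self.mode!r}")
        if self.role not in ROLES:
            raise ValueError(f"unknown channel role {self.role!r}")
        if self.start_epoch < 0 or self.start_epoch + self.n_epochs > total_epochs:
            raise ValueError("falloff event extends outside the record")


@dataclass
class SynthScenario:
    """One simulated recording: length, stage dynamics, artifacts, seed."""

    n_epochs: int = 200
    transition_matrix: np.ndarray | None = None
    start_dist: np.ndarray | None = None
    arousal_count: int = 0
    falloff_events: list[FalloffEvent] = field(default_factory=list)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.transition_matrix is None:
            self.transition_matrix = SEVERE_OSA_TRANSITIONS.copy()
        self.transition_matrix = np.asarray(self.transition_matrix, dtype=np.float64)
        validate_transition_matrix(self.transition_matrix)
        if self.start_dist is not None:
            self.start_dist = np.asarray(self.start_dist, dtype=np.float64)
            if self.start_dist.shape != (5,) or np.any(self.start_dist < 0) or \
                    abs(self.start_dist.sum() - 1.0) > 1e-8:
                raise ValueError("start_dist must be a probability 5-vector")
        for ev in self.falloff_events:
            ev.validate(self.n_epochs)


def validate_transition_matrix(P: np.ndarray) -> None:
    if P.shape != (5, 5):
        raise ValueError("transition matrix must be 5×5")
    if np.any(P < 0) or np.any(np.abs(P.sum(axis=1) - 1.0) > 1e-8):
        raise ValueError("transition matrix rows must be non-negative and sum to 1")


def stationary_distribution(P: np.ndarray) -> np.ndarray:
    """Left eigenvector of the transition matrix for eigenvalue 1."""
    w, v = np.linalg.eig(P.T)
    k = int(np.argmin(np.abs(w - 1.0)))
    pi = np.real(v[:, k])
    return pi / pi.sum()


# Stage dynamics emulating a severe-OSA clinical night: fragmented sleep with
# plentiful wake, scarce N3 (< 3% stationary mass) and moderate REM.
# Stage order: W, N1, N2, N3, R.
SEVERE_OSA_TRANSITIONS = np.array([
    [0.86, 0.09, 0.040, 0.000, 0.010],
    [0.12, 0.66, 0.200, 0.000, 0.020],
    [0.05, 0.06, 0.850, 0.006, 0.034],
    [0.02, 0.00, 0.280, 0.700, 0.000],
    [0.06, 0.04, 0.050, 0.000, 0.850],
])

# Consolidated sleep with a healthy N3 share, for contrast.
NORMAL_TRANSITIONS = np.array([
    [0.80, 0.15, 0.040, 0.000, 0.010],
    [0.05, 0.55, 0.370, 0.000, 0.030],
    [0.01, 0.03, 0.870, 0.060, 0.030],
    [0.00, 0.00, 0.100, 0.900, 0.000],
    [0.02, 0.03, 0.050, 0.000, 0.900],
])

SCENARIO_PRESETS: dict[str, np.ndarray] = {
    "severe_osa": SEVERE_OSA_TRANSITIONS,
    "normal": NORMAL_TRANSITIONS,
}


def scenario_preset(name: str, n_epochs: int = 200, seed: int = 0, **kw) -> SynthScenario:
    if name not in SCENARIO_PRESETS:
        raise ValueError(f"unknown scenario preset {name!r}; have {sorted(SCENARIO_PRESETS)}")
    return SynthScenario(
        n_epochs=n_epochs, transition_matrix=SCENARIO_PRESETS[name].copy(),
        seed=seed, **kw,
    )


# ---------------------------------------------------------------------------
# Hypnogram simulation
# ---------------------------------------------------------------------------

def simulate_hypnogram(scenario: SynthScenario) -> Hypnogram:
    """Draw a stage sequence from the scenario's first-order Markov chain."""
    rng = np.random.default_rng(scenario.seed)
    P = scenario.transition_matrix
    start = scenario.start_dist
    if start is None:
        start = np.zeros(5)
        start[STAGE_INDEX["W"]] = 1.0       # nights begin awake
    states = np.empty(scenario.n_epochs, dtype=np.int64)
    states[0] = rng.choice(5, p=start)
    for t in range(1, scenario.n_epochs):
        states[t] = rng.choice(5, p=P[states[t - 1]])
    return Hypnogram.from_indices(states, EPOCH_S)


# ---------------------------------------------------------------------------
# Signal synthesis
# ---------------------------------------------------------------------------

def _band_noise(rng: np.random.Generator, n: int, rate: float,
                bands: list[Band], white_floor: float, rms: float) -> np.ndarray:
    """Gaussian noise with a piecewise-flat band spectrum, via random-phase rFFT."""
    freqs = np.fft.rfftfreq(n, d=1.0 / rate)
    density = np.zeros_like(freqs)
    total_rel = sum(p for _, _, p in bands)
    for lo, hi, p in bands:
        sel = (freqs >= lo) & (freqs < hi)
        if np.any(sel) and p > 0:
            density[sel] += p / (hi - lo)
    if total_rel > 0 and white_floor > 0:
        nyq = rate / 2.0
        density += white_floor * total_rel / nyq
    density[0] = 0.0
    spec = np.sqrt(density) * (rng.standard_normal(len(freqs))
                               + 1j * rng.standard_normal(len(freqs)))
    x = np.fft.irfft(spec, n=n)
    sd = x.std()
    if sd > 0:
        x *= rms / sd
    return x


def _hann_burst(n: int, rate: float, onset_s: float, dur_s: float,
                freq: float, amp: float, phase: float = 0.0) -> np.ndarray:
    """A windowed sinusoid burst (spindle / alpha intrusion)."""
    out = np.zeros(n)
    i0 = int(onset_s * rate)
    m = int(dur_s * rate)
    m = min(m, n - i0)
    if m <= 0:
        return out
    t = np.arange(m) / rate
    env = 0.5 * (1 - np.cos(2 * np.pi * np.arange(m) / max(m - 1, 1)))
    out[i0:i0 + m] = amp * env * np.sin(2 * np.pi * freq * t + phase)
    return out


def _saccade_pulse(n: int, rate: float, onset_s: float, dur_s: float,
                   amp: float) -> np.ndarray:
    """Smoothed rectangular deflection: a rapid-eye-movement excursion."""
    out = np.zeros(n)
    i0 = int(onset_s * rate)
    m = min(int(dur_s * rate), n - i0)
    if m <= 0:
        return out
    ramp = max(2, m // 5)
    pulse = np.ones(m)
    pulse[:ramp] = np.linspace(0, 1, ramp)
    pulse[-ramp:] = np.linspace(1, 0, ramp)
    out[i0:i0 + m] = amp * pulse
    return out


def synthesize_psg(
    hypnogram: Hypnogram,
    params: StageSignalParams | None = None,
    scenario: SynthScenario | None = None,
    source_rate: float = SOURCE_RATE,
) -> PSGRecord:
    """Render a hypnogram into a five-channel record at the source rate.

    Each epoch is drawn from its stage's spectral model plus stage-specific
    transient events (spindles in N2, anti-phase EOG saccades with EMG atonia
    in R); epochs are crossfaded over 0.25 s so the record is continuous.
    Fully deterministic given the scenario seed.
    """
    params = params or default_stage_params()
    params.validate()
    seed = scenario.seed if scenario is not None else 0
    rng = np.random.default_rng((seed, 1))

    n_ep = len(hypnogram)
    spe = int(round(hypnogram.epoch_s * source_rate))
    xfade = int(round(0.25 * source_rate))
    data = np.zeros((len(ROLES), n_ep * spe))
    ramp = np.linspace(0.0, 1.0, xfade)

    for e, stage in enumerate(hypnogram.labels):
        epoch = np.zeros((len(ROLES), spe + xfade))
        for ci, role in enumerate(ROLES):
            epoch[ci] = _band_noise(
                rng, spe + xfade, source_rate,
                params.bands[stage][role], params.white_floor,
                params.amplitude[stage][role],
            )
        if stage == "N2" and params.spindle_rate_per_epoch > 0:
            for _ in range(rng.poisson(params.spindle_rate_per_epoch)):
                onset = rng.uniform(0, hypnogram.epoch_s - 1.2)
                f = rng.uniform(11, 16)
                burst = _hann_burst(spe + xfade, source_rate, onset,
                                    rng.uniform(0.6, 1.2), f, 35.0,
                                    rng.uniform(0, 2 * np.pi))
                for ci, role in enumerate(EEG_ROLES):
                    epoch[ci] += burst
        if stage == "R" and params.saccade_rate_per_epoch > 0:
            for _ in range(rng.poisson(params.saccade_rate_per_epoch)):
                onset = rng.uniform(0, hypnogram.epoch_s - 1.0)
                amp = rng.uniform(60, 120) * rng.choice([-1.0, 1.0])
                pulse = _saccade_pulse(spe + xfade, source_rate, onset,
                                       rng.uniform(0.3, 0.8), amp)
                epoch[ROLES.index("EOG_L")] += pulse
                epoch[ROLES.index("EOG_R")] -= pulse      # anti-phase
        i0 = e * spe
        if e == 0:
            data[:, i0:i0 + spe] = epoch[:, :spe]
        else:
            head = epoch[:, :xfade]
            data[:, i0:i0 + xfade] = (1 - ramp) * _prev_tail + ramp * head
            data[:, i0 + xfade:i0 + spe] = epoch[:, xfade:spe]
        _prev_tail = epoch[:, spe:spe + xfade]

    channels = [
        Channel(role.replace("_", " "), role, data[i], source_rate)
        for i, role in enumerate(ROLES)
    ]
    record = PSGRecord(channels, n_ep * hypnogram.epoch_s)

    if scenario is not None:
        for ev in scenario.falloff_events:
            record = inject_falloff(record, ev)
    return record


# ---------------------------------------------------------------------------
# Artifact injection
# ---------------------------------------------------------------------------

@dataclass
class ArousalEvent:
    epoch: int
    onset_s: float
    duration_s: float
    relabelled: bool


def inject_arousals(
    hypnogram: Hypnogram,
    record: PSGRecord,
    count: int,
    seed: int = 0,
    relabel_prob: float = 0.5,
    epoch_s: float = EPOCH_S,
) -> tuple[Hypnogram, PSGRecord, list[ArousalEvent]]:
    """Overlay ``count`` brief wake-like intrusions on sleep epochs.

    Each arousal overlays 3–15 s of alpha-band EEG plus an EMG tone burst on
    one uniformly chosen sleep (non-W) epoch, and relabels that epoch to N1
    with probability ``relabel_prob`` — arousals fragment sleep and inflate
    the N1 share, which is what makes heavily-aroused records ambiguous.
    """
    rng = np.random.default_rng((seed, 2))
    labels = list(hypnogram.labels)
    eligible = [i for i, l in enumerate(labels) if l != "W"]
    if count > len(eligible):
        raise ValueError(
            f"cannot place {count} arousals in {len(eligible)} sleep epochs"
        )
    if count == 0:
        return hypnogram, record, []

    chosen = rng.choice(len(eligible), size=count, replace=False)
    chosen = sorted(eligible[int(i)] for i in chosen)
    data = record.as_array().copy()
    rate = record.channels[0].rate
    spe = int(round(epoch_s * rate))
    events: list[ArousalEvent] = []
    for e in chosen:
        dur = float(rng.uniform(3.0, 15.0))
        onset = float(rng.uniform(0.0, epoch_s - dur))
        n = data.shape[1]
        alpha = _hann_burst(n, rate, e * epoch_s + onset, dur,
                            rng.uniform(8, 13), 45.0, rng.uniform(0, 2 * np.pi))
        for role in EEG_ROLES:
            data[ROLES.index(role)] += alpha
        i0 = int((e * epoch_s + onset) * rate)
        m = int(dur * rate)
        data[ROLES.index("EMG"), i0:i0 + m] += 25.0 * rng.standard_normal(m)
        relab = bool(rng.random() < relabel_prob)
        if relab:
            labels[e] = "N1"
        events.append(ArousalEvent(e, onset, dur, relab))

    channels = [
        Channel(c.name, c.role, data[i], c.rate)
        for i, c in enumerate(record.channels)
    ]
    return (Hypnogram(labels, hypnogram.epoch_s),
            PSGRecord(channels, record.duration_s), events)


def inject_falloff(record: PSGRecord, event: FalloffEvent,
                   epoch_s: float = EPOCH_S, seed: int = 0) -> PSGRecord:
    """Corrupt one channel over a span of epochs with an electrode artifact.

    flatline — near-zero constant with tiny jitter; saturation — amplifier
    rails (signal driven into clipping at ±rail); hf_noise — broadband noise
    far above physiological amplitude.  Samples outside the event are
    untouched.
    """
    n_ep = record.n_epochs(epoch_s)
    event.validate(n_ep)
    rng = np.random.default_rng((seed, 3, event.start_epoch))
    channels = []
    for c in record.channels:
        if c.role != event.role:
            channels.append(c)
            continue
        x = c.samples.copy()
        i0 = int(event.start_epoch * epoch_s * c.rate)
        i1 = int((event.start_epoch + event.n_epochs) * epoch_s * c.rate)
        seg = slice(i0, i1)
        if event.mode == "flatline":
            x[seg] = 0.01 * rng.standard_normal(i1 - i0)
        elif event.mode == "saturation":
            # drive the signal hard into the rails regardless of its amplitude
            gain = 20.0 * event.rail_uv / max(float(np.std(x[seg])), 1e-6)
            x[seg] = np.clip(x[seg] * gain, -event.rail_uv, event.rail_uv)
        else:  # hf_noise
            x[seg] = x[seg] + event.hf_noise_uv * rng.standard_normal(i1 - i0)
        channels.append(Channel(c.name, c.role, x, c.rate))
    return PSGRecord(channels, record.duration_s)


# ---------------------------------------------------------------------------
# Whole-record convenience
# ---------------------------------------------------------------------------

def generate_record(
    scenario: SynthScenario,
    params: StageSignalParams | None = None,
) -> tuple[PSGRecord, Hypnogram, list[ArousalEvent]]:
    """Hypnogram → signal → arousals → falloff, all from the scenario seed."""
    hyp = simulate_hypnogram(scenario)
    scenario_no_falloff = replace(scenario, falloff_events=[])
    rec = synthesize_psg(hyp, params, scenario_no_falloff)
    hyp, rec, events = inject_arousals(
        hyp, rec, scenario.arousal_count, seed=scenario.seed
    )
    for ev in scenario.falloff_events:
        rec = inject_falloff(rec, ev, seed=scenario.seed)
    return rec, hyp, events
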