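"""Synthetic motor-imagery EEG with known ERD/ERS ground truth.

The generator emulates a cue-based imagery paradigm: runs of cue-locked
trials, one of several conditions per trial in randomized order, constant
inter-trial period.  Each channel carries 1/f^β background noise plus
narrow-band oscillatory components (alpha ~10 Hz, beta ~20 Hz by default)
plus a white floor.  Condition effects are event-related
desynchronization/synchronization: inside a declared (band, window,
channel) region the band-limited *amplitude* is multiplied by a factor
(< 1 ERD, > 1 ERS) with raised-cosine on/off ramps, so band *power* scales
by the factor squared.

Everything is reproducible from one integer seed; paradigm randomness and
noise sample paths use independent derived streams, so one can be varied
while the other is held fixed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.signal import butter, sosfiltfilt

from .signal_model import EventTable, Recording, standard_1020_montage
from .tfr import TFRSet

__all__ = [
    "EffectSpec",
    "NoiseSpec",
    "generate_paradigm",
    "simulate_session",
    "generate_null_epochs",
    "default_effects",
    "demo_session",
]

RAMP_S = 0.1  # effect on/off raised-cosine ramp length


@dataclass(frozen=True)
class EffectSpec:
    """One condition-locked band-power modulation (ERD if factor < 1)."""

    condition: str
    channels: tuple[str, ...]
    band: tuple[float, float]
    window: tuple[float, float]
    amplitude_factor: float

    def __post_init__(self) -> None:
        if not self.amplitude_factor > 0:
            raise ValueError("amplitude_factor must be positive")
        if not 0 < self.band[0] < self.band[1]:
            raise ValueError("band must satisfy 0 < f_lo < f_hi")
        if not self.window[0] < self.window[1]:
            raise ValueError("window must satisfy t0 < t1")


@dataclass(frozen=True)
class NoiseSpec:
    """Background model: 1/f^β + narrow-band rhythms + white floor (µV RMS)."""

    background_exponent: float = 1.0
    background_rms: float = 10.0
    band_components: tuple[tuple[float, float, float], ...] = (
        (10.0, 2.0, 5.0),  # alpha rhythm: center Hz, bandwidth Hz, RMS µV
        (20.0, 4.0, 3.0),  # beta rhythm
    )
    white_rms: float = 2.0

    def __post_init__(self) -> None:
        if self.background_rms < 0 or self.white_rms < 0:
            raise ValueError("RMS values must be non-negative")
        if any(rms < 0 for _, _, rms in self.band_components):
            raise ValueError("RMS values must be non-negative")


def generate_paradigm(
    n_runs: int,
    trials_per_condition_per_run: int,
    conditions: Sequence[str],
    trial_period_s: float = 8.0,
    fs: float = 250.0,
    seed: int = 0,
    start_s: float = 4.0,
) -> EventTable:
    """Cue events for ``n_runs`` runs with randomized condition order per run.

    Events are uniformly spaced ``trial_period_s`` apart (the period must
    leave room for the 2 s fixation lead-in and the 6 s imagery window, i.e.
    ≥ 7.25 s with the ramp conventions here); per-condition counts come out
    to ``n_runs × trials_per_condition_per_run``.
    """
    if n_runs < 1 or trials_per_condition_per_run < 1 or len(conditions) < 1:
        raise ValueError("run/trial/condition counts must all be ≥ 1")
    if trial_period_s < 7.25:
        raise ValueError("trial_period_s must be ≥ 7.25 s to fit one trial")
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0x5EED]))
    labels: list[str] = []
    for _ in range(n_runs):
        run = list(conditions) * trials_per_condition_per_run
        rng.shuffle(run)
        labels.extend(run)
    samples = np.round((start_s + np.arange(len(labels)) * trial_period_s) * fs).astype(np.int64)
    return EventTable(samples=samples, conditions=labels, condition_set=tuple(conditions))


def _pink_noise(n: int, beta: float, fs: float, rng: np.random.Generator) -> np.ndarray:
    """Gaussian noise with a 1/f^β power spectrum, unit RMS."""
    white = rng.standard_normal(n)
    if beta == 0:
        x = white
    else:
        spec = np.fft.rfft(white)
        f = np.fft.rfftfreq(n, 1.0 / fs)
        scale = np.zeros_like(f)
        scale[1:] = f[1:] ** (-beta / 2.0)
        x = np.fft.irfft(spec * scale, n)
    sd = x.std()
    return x / sd if sd > 0 else x


def _band_sos(f_lo: float, f_hi: float, fs: float):
    nyq = fs / 2.0
    lo = max(f_lo, 0.1) / nyq
    hi = min(f_hi, nyq * 0.99) / nyq
    return butter(4, [lo, hi], btype="bandpass", output="sos")


def _ramped_gain(n: int, fs: float) -> np.ndarray:
    """Unit plateau with raised-cosine ramps of RAMP_S at both ends."""
    env = np.ones(n)
    nr = min(int(round(RAMP_S * fs)), n // 2)
    if nr > 0:
        ramp = 0.5 * (1.0 - np.cos(np.pi * np.arange(nr) / nr))
        env[:nr] = ramp
        env[n - nr:] = ramp[::-1]
    return env


def simulate_session(
    channel_labels: Sequence[str],
    events: EventTable,
    effects: Sequence[EffectSpec],
    noise: NoiseSpec,
    fs: float = 250.0,
    duration_s: float | None = None,
    seed: int = 0,
) -> Recording:
    """Continuous multichannel recording with condition-locked ERD/ERS.

    Per channel: background = 1/f^β + oscillatory components + white floor.
    For every event of condition c and every matching effect, the
    band-limited amplitude at the effect's channels is multiplied by
    ``amplitude_factor`` inside the event-relative window (smooth ramps).
    """
    channel_labels = list(channel_labels)
    for eff in effects:
        unknown = set(eff.channels) - set(channel_labels)
        if unknown:
            raise ValueError(f"effect references unknown channels {sorted(unknown)}")
    if duration_s is None:
        last = float(events.samples[-1]) / fs if len(events) else 0.0
        duration_s = last + 8.0
    n = int(round(duration_s * fs))
    if len(events) and events.samples[-1] + int(round(6.0 * fs)) > n:
        raise ValueError("duration does not cover all event windows")

    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0x0153]))
    data = np.zeros((len(channel_labels), n))
    for ci in range(len(channel_labels)):
        if noise.background_rms > 0:
            data[ci] += noise.background_rms * _pink_noise(n, noise.background_exponent, fs, rng)
        for center, bw, rms in noise.band_components:
            if rms == 0:
                continue
            comp = sosfiltfilt(_band_sos(center - bw / 2, center + bw / 2, fs), rng.standard_normal(n))
            sd = comp.std()
            if sd > 0:
                comp *= rms / sd
            data[ci] += comp
        if noise.white_rms > 0:
            data[ci] += noise.white_rms * rng.standard_normal(n)

    # apply effects: add (factor − 1) × band-limited signal inside each window
    for eff in effects:
        sos = _band_sos(*eff.band, fs)
        ch_idx = [channel_labels.index(c) for c in eff.channels]
        band_sig = sosfiltfilt(sos, data[ch_idx], axis=-1)
        ev_samples = [s for s, c in zip(events.samples, events.conditions) if c == eff.condition]
        gain = eff.amplitude_factor - 1.0
        for ev in ev_samples:
            a = int(ev) + int(round(eff.window[0] * fs))
            b = int(ev) + int(round(eff.window[1] * fs))
            a, b = max(a, 0), min(b, n)
            if b <= a:
                continue
            env = gain * _ramped_gain(b - a, fs)
            data[ch_idx, a:b] += env * band_sig[:, a:b]

    montage = None
    try:
        montage = standard_1020_montage(channel_labels)
    except KeyError:
        pass  # non-standard labels: no positions attached
    return Recording(data=data, fs=fs, channel_labels=channel_labels, montage=montage)


def generate_null_epochs(
    n_groups: int,
    trials_per_group: int,
    n_channels: int,
    n_freqs: int,
    n_times: int,
    seed: int = 0,
) -> tuple[TFRSet, dict[str, np.ndarray]]:
    """Null "TFR" data for type-I calibration: i.i.d. χ²₁ pixels, labels
    assigned independently of the data."""
    if n_groups < 2:
        raise ValueError("need at least two groups")
    if min(trials_per_group, n_channels, n_freqs, n_times) < 1:
        raise ValueError("all counts must be ≥ 1")
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0x0B11]))
    n_trials = n_groups * trials_per_group
    power = rng.standard_normal((n_trials, n_channels, n_freqs, n_times)) ** 2
    conds = [f"g{i + 1}" for i in range(n_groups)]
    labels = [conds[t % n_groups] for t in range(n_trials)]
    fs = 250.0
    tfr = TFRSet(
        power=power,
        freqs=np.arange(1, n_freqs + 1, dtype=float),
        times=np.arange(n_times) / fs,
        fs=fs,
        labels=labels,
        channel_labels=[f"ch{i}" for i in range(n_channels)],
        condition_set=tuple(conds),
    )
    groups = {c: np.flatnonzero(np.asarray(labels, dtype=object) == c) for c in conds}
    return tfr, groups


def default_effects() -> list[EffectSpec]:
    """Four-condition motor-imagery ground truth used by the demo session.

    Contralateral alpha-band ERD for hand imagery (left hand → right motor
    cortex C4 and vice versa), midline beta ERD for foot, midline alpha ERS
    for tongue; Pz is left untouched as a control channel.
    """
    return [
        EffectSpec("left", ("C4",), (9.0, 13.0), (0.5, 3.5), 0.4),
        EffectSpec("right", ("C3",), (9.0, 13.0), (0.5, 3.5), 0.4),
        EffectSpec("foot", ("Cz",), (18.0, 26.0), (0.5, 3.5), 0.5),
        EffectSpec("tongue", ("Cz",), (9.0, 13.0), (0.5, 3.5), 1.8),
    ]


def demo_session(
    seed: int = 0,
    channels: Sequence[str] = ("C3", "Cz", "C4", "Pz"),
    n_runs: int = 6,
    trials_per_condition_per_run: int = 12,
    fs: float = 250.0,
    effects: Sequence[EffectSpec] | None = None,
    noise: NoiseSpec | None = None,
) -> tuple[Recording, EventTable, list[EffectSpec]]:
    """Paradigm + recording for the standard 4-condition demo session."""
    effects = list(effects) if effects is not None else default_effects()
    noise = noise or NoiseSpec()
    conditions = ("left", "right", "foot", "tongue")
    events = generate_paradigm(
        n_runs, trials_per_condition_per_run, conditions, trial_period_s=8.0, fs=fs, seed=seed
    )
    rec = simulate_session(channels, events, effects, noise, fs=fs, seed=seed)
    return rec, events, effects
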