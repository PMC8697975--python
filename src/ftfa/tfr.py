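"""Trial-wise time-frequency power via complex Morlet wavelets.

The decomposition is a continuous wavelet transform implemented as
same-length convolution of each trial with a bank of unit-energy complex
Morlet kernels (a Gaussian-windowed complex exponential with ``n_cycles``
cycles under the Gaussian envelope, σ_t = n_cycles / (2π f)).  Power is the
squared convolution magnitude by default; plain magnitude is available via
:class:`WaveletParams`.

Post-cue power is expressed relative to the mean pre-cue (baseline) power at
the same frequency, per trial, channel and frequency — ``ratio`` (divide),
``percent`` (100·(x−μ)/μ) or ``dB`` (10·log10(x/μ)).

A cone-of-influence half-width (±5 σ_t per frequency) is carried on the
:class:`TFRSet` so edge-contaminated pixels can be masked downstream;
nothing is blanked automatically.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
from scipy.signal import fftconvolve

__all__ = [
    "WaveletParams",
    "TFRSet",
    "morlet_kernel",
    "cwt_power",
    "compute_tfr",
    "baseline_normalize",
    "average_tfr_by_condition",
]

_BASELINE_MODES = ("none", "ratio", "percent", "dB")


class FrequencyError(ValueError):
    """Requested analysis frequency is not below Nyquist (or not positive)."""


class BaselineError(ValueError):
    """Baseline interval invalid or baseline power degenerate (zero mean)."""


@dataclass(frozen=True)
class WaveletParams:
    """Morlet wavelet configuration.

    n_cycles : cycles under the Gaussian envelope (fixed across frequencies).
    power : ``"squared"`` for |W|² (power), ``"magnitude"`` for |W|.
    """

    n_cycles: float = 7.0
    power: str = "squared"

    def __post_init__(self) -> None:
        if not self.n_cycles > 0:
            raise ValueError("n_cycles must be positive")
        if self.power not in ("squared", "magnitude"):
            raise ValueError("power must be 'squared' or 'magnitude'")

    def sigma_t(self, freq_hz: float) -> float:
        """Gaussian SD in seconds at *freq_hz*."""
        return self.n_cycles / (2.0 * np.pi * freq_hz)


def morlet_kernel(freq_hz: float, params: WaveletParams, fs: float) -> np.ndarray:
    """Unit-energy complex Morlet kernel at *freq_hz*.

    Odd length covering ±5 Gaussian SDs; Σ|w|² = 1, so convolution power is
    an energy density comparable across frequencies.
    """
    if not 0 < freq_hz < fs / 2:
        raise FrequencyError(f"frequency {freq_hz} Hz not in (0, Nyquist={fs / 2}) ")
    sigma = params.sigma_t(freq_hz)
    half = int(np.ceil(5.0 * sigma * fs))
    t = np.arange(-half, half + 1) / fs
    kern = np.exp(2j * np.pi * freq_hz * t) * np.exp(-(t**2) / (2.0 * sigma**2))
    kern /= np.sqrt(np.sum(np.abs(kern) ** 2))
    return kern


def cwt_power(
    signal: np.ndarray,
    freqs: Sequence[float],
    params: WaveletParams,
    fs: float,
) -> np.ndarray:
    """Time-frequency power of a 1-D signal: freqs × times matrix.

    Entry (f, t) is the squared magnitude (or magnitude, per *params*) of
    the same-length, zero-padded convolution with the Morlet kernel at f.
    Kernels longer than the signal are allowed; the affected pixels simply
    sit inside the cone of influence.
    """
    signal = np.asarray(signal, dtype=float)
    if signal.ndim != 1:
        raise ValueError("cwt_power expects a 1-D signal")
    freqs = np.asarray(list(freqs), dtype=float)
    if freqs.size == 0:
        raise ValueError("freqs must be non-empty")
    out = np.empty((freqs.size, signal.size))
    for i, f in enumerate(freqs):
        w = fftconvolve(signal, morlet_kernel(float(f), params, fs), mode="same")
        mag = np.abs(w)
        out[i] = mag**2 if params.power == "squared" else mag
    return out


@dataclass
class TFRSet:
    """Per-trial time-frequency power: trials × channels × freqs × times.

    Units are µV²·sample (raw) or arbitrary units after baseline
    normalization.  ``coi_halfwidth_s`` gives, per frequency, the ±5 σ_t
    span inside which edge effects reach.
    """

    power: np.ndarray
    freqs: np.ndarray
    times: np.ndarray
    fs: float
    labels: list[str]
    channel_labels: list[str]
    condition_set: tuple[str, ...] = ()
    baseline_mode: str = "none"
    baseline_interval: tuple[float, float] | None = None
    wavelet: WaveletParams = field(default_factory=WaveletParams)
    coi_halfwidth_s: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.power = np.asarray(self.power)
        self.freqs = np.asarray(self.freqs, dtype=float)
        self.times = np.asarray(self.times, dtype=float)
        if self.power.ndim != 4:
            raise ValueError("power must be 4-D (trials × channels × freqs × times)")
        if self.power.shape[2] != self.freqs.size or self.power.shape[3] != self.times.size:
            raise ValueError("power shape inconsistent with freqs/times axes")
        if np.any(np.diff(self.freqs) <= 0):
            raise ValueError("freqs must be strictly increasing")
        if len(self.labels) != self.power.shape[0]:
            raise ValueError("one condition label per trial required")
        if self.baseline_mode not in _BASELINE_MODES:
            raise ValueError(f"baseline_mode must be one of {_BASELINE_MODES}")
        if self.baseline_mode in ("none", "ratio") and self.power.size:
            if np.nanmin(self.power) < 0:
                raise ValueError("power must be non-negative under mode 'none'/'ratio'")
        if not self.condition_set:
            self.condition_set = tuple(sorted(set(self.labels)))

    @property
    def n_trials(self) -> int:
        return self.power.shape[0]

    @property
    def n_channels(self) -> int:
        return self.power.shape[1]


def _batch_cwt(signals: np.ndarray, freqs: np.ndarray, params: WaveletParams, fs: float) -> np.ndarray:
    """CWT power for a (batch, times) stack, one FFT convolution per frequency."""
    n_batch, n_times = signals.shape
    out = np.empty((n_batch, freqs.size, n_times), dtype=np.float64)
    for i, f in enumerate(freqs):
        kern = morlet_kernel(float(f), params, fs)
        w = fftconvolve(signals, kern[np.newaxis, :], mode="same", axes=1)
        mag = np.abs(w)
        out[:, i, :] = mag**2 if params.power == "squared" else mag
    return out


def compute_tfr(epochs, freqs: Sequence[float], params: WaveletParams | None = None) -> TFRSet:
    """Trial-wise wavelet power for every channel of an EpochSet."""
    params = params or WaveletParams()
    freqs = np.asarray(list(freqs), dtype=float)
    if freqs.size == 0:
        raise ValueError("freqs must be non-empty")
    n_tr, n_ch, n_samp = epochs.data.shape
    flat = epochs.data.reshape(n_tr * n_ch, n_samp)
    power = _batch_cwt(flat, freqs, params, epochs.fs).reshape(n_tr, n_ch, freqs.size, n_samp)
    coi = 5.0 * params.n_cycles / (2.0 * np.pi * freqs)
    return TFRSet(
        power=power,
        freqs=freqs,
        times=epochs.times,
        fs=epochs.fs,
        labels=list(epochs.labels),
        channel_labels=list(epochs.channel_labels),
        condition_set=epochs.condition_set,
        wavelet=params,
        coi_halfwidth_s=coi,
    )


def baseline_normalize(
    tfr: TFRSet,
    baseline_interval: tuple[float, float],
    mode: str = "ratio",
) -> TFRSet:
    """Normalize power by mean baseline power, per trial, channel and frequency.

    ratio → x/μ;  percent → 100·(x−μ)/μ;  dB → 10·log10(x/μ), where μ is the
    mean over the baseline samples at that (trial, channel, frequency).
    """
    if mode not in ("ratio", "percent", "dB"):
        raise ValueError(f"mode must be ratio|percent|dB, got {mode!r}")
    t0, t1 = baseline_interval
    tmin, tmax = tfr.times[0], tfr.times[-1]
    if t0 >= t1 or t0 < tmin - 0.5 / tfr.fs or t1 > tmax + 1.0 / tfr.fs:
        raise BaselineError(
            f"baseline interval ({t0}, {t1}) outside epoch time axis [{tmin}, {tmax}]"
        )
    sel = (tfr.times >= t0) & (tfr.times < t1)
    if not np.any(sel):
        raise BaselineError("baseline interval contains no samples")
    mu = tfr.power[..., sel].mean(axis=-1, keepdims=True)
    if np.any(mu == 0):
        raise BaselineError("zero mean baseline power at some (trial, channel, frequency)")
    if mode == "ratio":
        out = tfr.power / mu
    elif mode == "percent":
        out = 100.0 * (tfr.power - mu) / mu
    else:
        out = 10.0 * np.log10(tfr.power / mu)
    return replace(tfr, power=out, baseline_mode=mode, baseline_interval=(float(t0), float(t1)))


def average_tfr_by_condition(
    tfr: TFRSet, groups: Mapping[str, np.ndarray]
) -> dict[str, np.ndarray]:
    """Arithmetic mean over each group's trials → condition → (ch, f, t) map."""
    out: dict[str, np.ndarray] = {}
    for cond, idx in groups.items():
        idx = np.asarray(idx, dtype=np.intp)
        if idx.size == 0:
            raise ValueError(f"empty trial group for condition {cond!r}")
        if idx.min() < 0 or idx.max() >= tfr.n_trials:
            raise IndexError(f"group {cond!r} references trial outside 0..{tfr.n_trials - 1}")
        out[cond] = tfr.power[idx].mean(axis=0)
    return out
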