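"""F-value time-frequency (FTF) statistics.

The core statistic is a mass-univariate one-way ANOVA: at every
(channel, frequency, time) pixel, the per-trial power values Y_ij (trial j
of condition group i) are compared across K condition groups by

    F = between-group variance / within-group variance

with

    between = Σ_i n_i (Ȳ_i − Ȳ)² / (K − 1)
    within  = Σ_i Σ_j (Y_ij − Ȳ_i)² / (N − K)

where n_i are group sizes, N = Σ n_i, Ȳ_i group means and Ȳ the grand mean.
Degrees of freedom are (K − 1, N − K); a pixel is significant at level α
when F exceeds the upper-tail F quantile at those degrees of freedom (the
study configuration of four 72-trial groups gives df = (3, 284) and a 1 %
threshold of 3.851286).

Degenerate-pixel conventions: within = 0 with between > 0 → +∞ (all trials
agree within group but groups differ — maximally significant); within = 0
and between = 0 (all trials identical) → F = 0.

Averaging F maps across subjects or channels reproduces the usual summary
display, but the mean of F values is *not* F distributed: on averaged maps
a critical line is annotation, not inference.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "GroupedPixelSamples",
    "FTFMap",
    "Topography",
    "group_dof",
    "between_group_variance",
    "within_group_variance",
    "f_value",
    "ftf_map",
    "critical_f",
    "significance_mask",
    "average_maps",
    "band_topography",
]


class GroupCountError(ValueError):
    """Fewer than two groups."""


class ReplicationError(ValueError):
    """No residual degrees of freedom (N − K < 1)."""


@dataclass
class GroupedPixelSamples:
    """Per-group sample lists Y_ij for a single pixel."""

    values_by_group: dict[str, np.ndarray]

    def __post_init__(self) -> None:
        self.values_by_group = {
            k: np.asarray(v, dtype=float).ravel() for k, v in self.values_by_group.items()
        }
        if len(self.values_by_group) < 2:
            raise GroupCountError("at least two groups required")
        if any(v.size < 1 for v in self.values_by_group.values()):
            raise ValueError("every group needs at least one sample")

    @property
    def group_sizes(self) -> list[int]:
        return [v.size for v in self.values_by_group.values()]

    @property
    def K(self) -> int:
        return len(self.values_by_group)

    @property
    def N(self) -> int:
        return sum(self.group_sizes)

    @property
    def group_means(self) -> np.ndarray:
        return np.array([v.mean() for v in self.values_by_group.values()])

    @property
    def grand_mean(self) -> float:
        return float(np.concatenate(list(self.values_by_group.values())).mean())


def group_dof(group_sizes: Sequence[int]) -> tuple[int, int]:
    """(df_between, df_within) = (K − 1, N − K) for the given group sizes."""
    K = len(group_sizes)
    if K < 2:
        raise GroupCountError("ANOVA needs at least two groups")
    if any(n < 1 for n in group_sizes):
        raise ValueError("every group must contain at least one trial")
    N = int(sum(group_sizes))
    if N - K < 1:
        raise ReplicationError("N − K must be at least 1 (need replication within groups)")
    return K - 1, N - K


def between_group_variance(samples: GroupedPixelSamples) -> float:
    """Σ n_i (Ȳ_i − Ȳ)² / (K − 1)."""
    gm = samples.grand_mean
    n = np.asarray(samples.group_sizes, dtype=float)
    means = samples.group_means
    return float(np.sum(n * (means - gm) ** 2) / (samples.K - 1))


def within_group_variance(samples: GroupedPixelSamples) -> float:
    """Σ_i Σ_j (Y_ij − Ȳ_i)² / (N − K)."""
    dfw = samples.N - samples.K
    if dfw < 1:
        raise ReplicationError("N − K must be at least 1")
    ss = sum(float(((v - v.mean()) ** 2).sum()) for v in samples.values_by_group.values())
    return ss / dfw


def f_value(samples: GroupedPixelSamples) -> float:
    """One-way ANOVA F for one pixel, with the degenerate conventions above."""
    bw = between_group_variance(samples)
    wn = within_group_variance(samples)
    if wn == 0.0:
        return float("inf") if bw > 0.0 else 0.0
    return bw / wn


@dataclass
class FTFMap:
    """Channel × frequency × time map of F values with DOF metadata."""

    f_values: np.ndarray
    df_between: int
    df_within: int
    group_sizes: dict[str, int]
    freqs: np.ndarray
    times: np.ndarray
    channel_labels: list[str]

    def __post_init__(self) -> None:
        self.f_values = np.asarray(self.f_values, dtype=float)
        self.freqs = np.asarray(self.freqs, dtype=float)
        self.times = np.asarray(self.times, dtype=float)
        if self.f_values.ndim != 3:
            raise ValueError("f_values must be 3-D (channels × freqs × times)")
        if self.f_values.shape[1:] != (self.freqs.size, self.times.size):
            raise ValueError("f_values shape inconsistent with freqs/times")
        if np.any(self.f_values < 0):
            raise ValueError("F values must be non-negative")
        if self.df_between != len(self.group_sizes) - 1:
            raise ValueError("df_between must equal K − 1")
        if self.df_within != sum(self.group_sizes.values()) - len(self.group_sizes):
            raise ValueError("df_within must equal N − K")

    @property
    def n_channels(self) -> int:
        return self.f_values.shape[0]

    def _axes_match(self, other: "FTFMap") -> bool:
        return (
            self.f_values.shape == other.f_values.shape
            and np.array_equal(self.freqs, other.freqs)
            and np.array_equal(self.times, other.times)
        )


def ftf_map(tfr, groups: Mapping[str, np.ndarray]) -> FTFMap:
    """F map over every (channel, frequency, time) pixel of a trial TFR set.

    At each pixel the per-trial values form the Y_ij entering the one-way
    ANOVA; the whole map shares one set of group sizes, hence one DOF pair.
    Vectorised over pixels; identical pixel-by-pixel to :func:`f_value`.
    """
    # canonical (sorted) group order so results are independent of dict order
    idx_by_group = {k: np.asarray(groups[k], dtype=np.intp) for k in sorted(groups)}
    sizes = {k: int(v.size) for k, v in idx_by_group.items()}
    df_b, df_w = group_dof(list(sizes.values()))
    for k, v in idx_by_group.items():
        if v.size and (v.min() < 0 or v.max() >= tfr.n_trials):
            raise IndexError(f"group {k!r} references trial outside the TFR set")

    X = np.asarray(tfr.power, dtype=np.float64)
    N = sum(sizes.values())
    grand = np.zeros(X.shape[1:], dtype=np.float64)
    ss_between = np.zeros_like(grand)
    ss_within = np.zeros_like(grand)
    means = {}
    for k, idx in idx_by_group.items():
        means[k] = X[idx].mean(axis=0)
        grand += sizes[k] * means[k]
    grand /= N
    for k, idx in idx_by_group.items():
        ss_between += sizes[k] * (means[k] - grand) ** 2
        ss_within += ((X[idx] - means[k]) ** 2).sum(axis=0)
    bw = ss_between / df_b
    wn = ss_within / df_w
    with np.errstate(divide="ignore", invalid="ignore"):
        f = bw / wn
    f[(wn == 0) & (bw == 0)] = 0.0
    f[(wn == 0) & (bw > 0)] = np.inf
    # guard against tiny negative rounding in the sums
    f = np.where(f < 0, 0.0, f)
    return FTFMap(
        f_values=f,
        df_between=df_b,
        df_within=df_w,
        group_sizes=sizes,
        freqs=tfr.freqs,
        times=tfr.times,
        channel_labels=list(tfr.channel_labels),
    )


def critical_f(alpha: float, df_between: int, df_within: int) -> float:
    """Upper-tail F quantile: q with P(F_{df1,df2} > q) = alpha."""
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    if df_between < 1 or df_within < 1:
        raise ValueError("degrees of freedom must be ≥ 1")
    return float(stats.f.isf(alpha, df_between, df_within))


def significance_mask(
    fmap: FTFMap, alpha: float = 0.01, correction: str = "none"
) -> tuple[np.ndarray, float]:
    """Boolean significance map plus the F threshold actually applied.

    ``none`` compares every pixel to the single critical value at *alpha*
    (the display convention for FTF maps); ``bonferroni`` divides alpha by
    the number of tested pixels; ``bh-fdr`` runs Benjamini–Hochberg step-up
    on the per-pixel upper-tail p-values (the returned threshold is then the
    smallest F called significant, or +inf when nothing survives).
    """
    n_pix = fmap.f_values.size
    if correction == "none":
        thr = critical_f(alpha, fmap.df_between, fmap.df_within)
        return fmap.f_values > thr, thr
    if correction == "bonferroni":
        thr = critical_f(alpha / n_pix, fmap.df_between, fmap.df_within)
        return fmap.f_values > thr, thr
    if correction == "bh-fdr":
        pvals = stats.f.sf(fmap.f_values, fmap.df_between, fmap.df_within).ravel()
        reject, _, _, _ = multipletests(pvals, alpha=alpha, method="fdr_bh")
        mask = reject.reshape(fmap.f_values.shape)
        thr = float(fmap.f_values[mask].min()) if mask.any() else float("inf")
        return mask, thr
    raise ValueError(f"unknown correction {correction!r} (none|bonferroni|bh-fdr)")


def average_maps(maps: Sequence[FTFMap] | Sequence[np.ndarray]) -> FTFMap | np.ndarray:
    """Element-wise arithmetic mean of aligned maps (identical axes required).

    Note the caveat in the module docstring: an average of F maps is a
    summary image, not an F statistic.
    """
    maps = list(maps)
    if not maps:
        raise ValueError("need at least one map")
    if isinstance(maps[0], FTFMap):
        first = maps[0]
        for m in maps[1:]:
            if not first._axes_match(m):
                raise ValueError("axis mismatch between maps")
        mean = np.mean([m.f_values for m in maps], axis=0)
        return replace(first, f_values=mean)
    arrs = [np.asarray(m) for m in maps]
    if any(a.shape != arrs[0].shape for a in arrs):
        raise ValueError("axis mismatch between maps")
    return np.mean(arrs, axis=0)


@dataclass
class Topography:
    """Per-channel scalar (mean F) for one band and one time window."""

    channel_values: dict[str, float]
    positions: dict[str, tuple[float, float]]
    band: tuple[float, float]
    window: tuple[float, float]

    def __post_init__(self) -> None:
        missing = [c for c in self.channel_values if c not in self.positions]
        if missing:
            raise ValueError(f"no scalp position for channels {missing}")

    def to_frame(self):
        import pandas as pd

        rows = [
            {"label": c, "x": self.positions[c][0], "y": self.positions[c][1], "value": v}
            for c, v in self.channel_values.items()
        ]
        return pd.DataFrame(rows)


def band_topography(
    fmap: FTFMap,
    f_lo: float,
    f_hi: float,
    windows: Sequence[tuple[float, float]],
    montage: Mapping[str, tuple[float, float]],
) -> list[Topography]:
    """Mean F per channel over an inclusive frequency band, per time window.

    Band edges are inclusive on the frequency grid (17–27 Hz on a 1-Hz grid
    averages 11 rows); time windows are half-open [t0, t1).
    """
    fsel = (fmap.freqs >= f_lo) & (fmap.freqs <= f_hi)
    if not np.any(fsel):
        raise ValueError(f"band ({f_lo}, {f_hi}) Hz selects no frequency bins")
    missing = [c for c in fmap.channel_labels if c not in montage]
    if missing:
        raise ValueError(f"montage lacks positions for {missing}")
    out = []
    for t0, t1 in windows:
        tsel = (fmap.times >= t0) & (fmap.times < t1)
        if not np.any(tsel):
            raise ValueError(f"window ({t0}, {t1}) s selects no time bins")
        vals = fmap.f_values[:, fsel][:, :, tsel].mean(axis=(1, 2))
        out.append(
            Topography(
                channel_values={c: float(v) for c, v in zip(fmap.channel_labels, vals)},
                positions={c: montage[c] for c in fmap.channel_labels},
                band=(float(f_lo), float(f_hi)),
                window=(float(t0), float(t1)),
            )
        )
    return out
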