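"""Figure rendering: time-frequency images, multi-channel grids, topographies.

All images put time on the x axis and frequency on the y axis; the colorbar
is labelled "F-value" for FTF maps and "AU" for baseline-normalized power.
Cue onset (t = 0) is marked with a vertical line.  Rendering is
deterministic: the same artifact and style yield identical image bytes
(PNG metadata that varies run-to-run is suppressed).
"""

from __future__ import annotations

from pathlib import Path
from typing import Mapping, Sequence

import matplotlib

matplotlib.use("Agg", force=False)
import matplotlib.pyplot as plt
import numpy as np
from scipy.interpolate import griddata

from .ftf import FTFMap, Topography

__all__ = ["render_map", "render_channel_grid", "render_topography"]

_DETERMINISTIC_PNG = {"Software": "ftfa"}


def _save(fig, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    kwargs = {}
    if path.suffix.lower() == ".png":
        kwargs["metadata"] = _DETERMINISTIC_PNG
    elif path.suffix.lower() == ".svg":
        kwargs["metadata"] = {"Date": None}
    fig.savefig(path, dpi=120, **kwargs)
    plt.close(fig)
    return path


def _imshow_tf(ax, values: np.ndarray, times: np.ndarray, freqs: np.ndarray, **kw):
    finite = values[np.isfinite(values)]
    vmax = kw.pop("vmax", float(finite.max()) if finite.size else 1.0)
    im = ax.imshow(
        np.where(np.isfinite(values), values, vmax),
        origin="lower",
        aspect="auto",
        extent=(times[0], times[-1], freqs[0], freqs[-1]),
        vmax=vmax,
        **kw,
    )
    ax.axvline(0.0, color="red", lw=1.0)
    ax.set_xlabel("time (s)")
    ax.set_ylabel("frequency (Hz)")
    return im


def render_map(
    values: np.ndarray | FTFMap,
    path: str | Path,
    times: np.ndarray | None = None,
    freqs: np.ndarray | None = None,
    channel: int | str = 0,
    unit: str = "F-value",
    title: str | None = None,
) -> Path:
    """Render one channel's freq × time map (FTF or mean TFR) to PNG/SVG."""
    if isinstance(values, FTFMap):
        if isinstance(channel, str):
            channel = values.channel_labels.index(channel)
        times, freqs = values.times, values.freqs
        img = values.f_values[channel]
        if title is None:
            title = values.channel_labels[channel]
    else:
        img = np.asarray(values)
        if img.ndim == 3:
            img = img[channel if isinstance(channel, int) else 0]
        if times is None or freqs is None:
            raise ValueError("times and freqs required for a bare array")
    if img.size == 0:
        raise ValueError("empty selection: nothing to render")
    fig, ax = plt.subplots(figsize=(6, 4))
    im = _imshow_tf(ax, img, np.asarray(times), np.asarray(freqs))
    fig.colorbar(im, ax=ax, label=unit)
    if title:
        ax.set_title(title)
    fig.tight_layout()
    return _save(fig, path)


def render_channel_grid(fmap: FTFMap, path: str | Path, unit: str = "F-value") -> Path:
    """One freq × time panel per channel, shared color scale."""
    n = fmap.n_channels
    ncols = int(np.ceil(np.sqrt(n)))
    nrows = int(np.ceil(n / ncols))
    finite = fmap.f_values[np.isfinite(fmap.f_values)]
    vmax = float(finite.max()) if finite.size else 1.0
    fig, axes = plt.subplots(nrows, ncols, figsize=(3.2 * ncols, 2.4 * nrows), squeeze=False)
    ims = []
    for i in range(nrows * ncols):
        ax = axes[i // ncols][i % ncols]
        if i >= n:
            ax.axis("off")
            continue
        ims.append(_imshow_tf(ax, fmap.f_values[i], fmap.times, fmap.freqs, vmax=vmax))
        ax.set_title(fmap.channel_labels[i], fontsize=9)
    fig.colorbar(ims[0], ax=axes, label=unit, shrink=0.8)
    return _save(fig, path)


def render_topography(
    topos: Topography | Sequence[Topography],
    path: str | Path,
    unit: str = "F-value",
) -> Path:
    """Scalp map(s): interpolated F over the head circle, one panel per window."""
    if isinstance(topos, Topography):
        topos = [topos]
    topos = list(topos)
    if not topos:
        raise ValueError("empty selection: no topographies to render")
    vals = np.concatenate([list(t.channel_values.values()) for t in topos])
    vmin, vmax = float(vals.min()), float(vals.max())
    fig, axes = plt.subplots(1, len(topos), figsize=(3.0 * len(topos), 3.2), squeeze=False)
    grid = np.linspace(-1.1, 1.1, 64)
    gx, gy = np.meshgrid(grid, grid)
    for ax, topo in zip(axes[0], topos):
        pts = np.array([topo.positions[c] for c in topo.channel_values])
        v = np.array(list(topo.channel_values.values()))
        if len(pts) >= 4:
            img = griddata(pts, v, (gx, gy), method="cubic")
            img = np.where(gx**2 + gy**2 <= 1.21, img, np.nan)
            ax.imshow(img, origin="lower", extent=(-1.1, 1.1, -1.1, 1.1), vmin=vmin, vmax=vmax)
        sc = ax.scatter(pts[:, 0], pts[:, 1], c=v, vmin=vmin, vmax=vmax, edgecolors="k", s=40)
        ax.add_patch(plt.Circle((0, 0), 1.0, fill=False, lw=1.5))
        ax.set_xlim(-1.2, 1.2)
        ax.set_ylim(-1.2, 1.2)
        ax.set_aspect("equal")
        ax.axis("off")
        ax.set_title(
            f"{topo.band[0]:g}–{topo.band[1]:g} Hz, "
            f"{topo.window[0]:g}–{topo.window[1]:g} s",
            fontsize=8,
        )
    fig.colorbar(sc, ax=axes, label=unit, shrink=0.8)
    return _save(fig, path)
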