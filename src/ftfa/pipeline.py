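"""End-to-end driver: inputs → epochs → trial TFR → FTF map → masks/figures.

``run_pipeline`` is deterministic given a config (which includes the seed):
running it twice produces bit-identical containers.  Every artifact carries
the config and its hash as provenance.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np

from . import containers
from .config import AnalysisConfig
from .ftf import band_topography, ftf_map, significance_mask
from .signal_model import (
    epoch_extract,
    group_trials,
    read_edf,
    read_events_csv,
    read_montage_csv,
    standard_1020_montage,
)
from .synthetic import demo_session
from .tfr import WaveletParams, average_tfr_by_condition, baseline_normalize, compute_tfr

logger = logging.getLogger("ftfa")

__all__ = ["run_pipeline"]


def _load_inputs(config: AnalysisConfig):
    if config.simulate:
        rec, events, _ = demo_session(
            seed=config.seed,
            channels=config.channels,
            n_runs=config.n_runs,
            trials_per_condition_per_run=config.trials_per_condition_per_run,
        )
        return rec, events
    rec_path = Path(config.recording)
    if not rec_path.exists():
        raise FileNotFoundError(f"recording not found: {rec_path}")
    if rec_path.suffix.lower() == ".edf":
        rec = read_edf(rec_path)
    else:
        rec = containers.load_recording(rec_path)
    events = read_events_csv(config.events)
    bad = events.samples[events.samples >= rec.n_samples]
    if bad.size:
        row = int(np.argmax(events.samples >= rec.n_samples))
        raise ValueError(
            f"events CSV row {row}: sample {int(bad[0])} beyond recording "
            f"length {rec.n_samples}"
        )
    if config.montage:
        rec.montage = read_montage_csv(config.montage)
    return rec, events


def run_pipeline(config: AnalysisConfig) -> dict[str, Path]:
    """Run the full analysis; returns a name → path map of artifacts."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log_path = out / "run.log"
    handler = logging.FileHandler(log_path, mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)
    provenance = {"config": config.to_dict(), "config_hash": config.config_hash()}
    artifacts: dict[str, Path] = {"log": log_path}
    try:
        logger.info("config hash %s", config.config_hash())
        rec, events = _load_inputs(config)
        logger.info(
            "recording: %d channels, %.1f s at %g Hz; %d events",
            rec.n_channels, rec.duration_s, rec.fs, len(events),
        )
        epochs = epoch_extract(rec, events, config.tmin_s, config.tmax_s)
        groups = group_trials(epochs)
        logger.info("epochs: %s", {k: int(v.size) for k, v in groups.items()})

        params = WaveletParams(n_cycles=config.n_cycles)
        tfr = compute_tfr(epochs, config.freqs(), params)
        if config.baseline_mode != "none":
            tfr = baseline_normalize(tfr, config.baseline_s, config.baseline_mode)
        tfr_path = out / "tfr.h5"
        containers.save_tfr(tfr_path, tfr, provenance)
        artifacts["tfr"] = tfr_path

        fmap = ftf_map(tfr, groups)
        mask, thr = significance_mask(fmap, config.alpha, config.correction)
        logger.info(
            "FTF: df=(%d, %d), threshold F=%.6g, significant fraction %.4f",
            fmap.df_between, fmap.df_within, thr, float(mask.mean()),
        )
        ftf_path = out / "ftf.h5"
        containers.save_ftf(ftf_path, fmap, mask, thr, provenance)
        artifacts["ftf"] = ftf_path

        montage = rec.montage or standard_1020_montage(rec.channel_labels)
        for f_lo, f_hi in config.topo_bands:
            topos = band_topography(fmap, f_lo, f_hi, config.topo_windows, montage)
            csv_path = out / f"topography_{f_lo:g}-{f_hi:g}Hz.csv"
            frames = []
            for topo in topos:
                df = topo.to_frame()
                df.insert(0, "t1_s", topo.window[1])
                df.insert(0, "t0_s", topo.window[0])
                frames.append(df)
            import pandas as pd

            pd.concat(frames, ignore_index=True).to_csv(csv_path, index=False)
            artifacts[f"topography_{f_lo:g}-{f_hi:g}"] = csv_path
            if config.figures:
                from .viz import render_topography

                png = out / f"topography_{f_lo:g}-{f_hi:g}Hz.png"
                render_topography(topos, png)
                artifacts[f"topography_fig_{f_lo:g}-{f_hi:g}"] = png

        if config.figures:
            from .viz import render_channel_grid, render_map

            cond_means = average_tfr_by_condition(tfr, groups)
            for cond, mean_map in cond_means.items():
                p = out / f"tfr_mean_{cond}.png"
                render_map(mean_map[0], p, times=tfr.times, freqs=tfr.freqs,
                           unit="AU", title=f"{cond} ({tfr.channel_labels[0]})")
                artifacts[f"tfr_mean_{cond}"] = p
            artifacts["ftf_fig"] = render_map(fmap, out / "ftf_ch0.png")
            artifacts["ftf_grid"] = render_channel_grid(fmap, out / "ftf_grid.png")
        logger.info("done: %d artifacts", len(artifacts))
    finally:
        logger.removeHandler(handler)
        handler.close()
    return artifacts
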