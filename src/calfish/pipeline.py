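"""End-to-end orchestration: movie + stacks + ROIs -> run report.

The pipeline is strictly linear, mirroring the experimental workflow:

1. calcium scoring — per-channel background, F340/F385 traces per ROI,
   baseline-corrected AUC per agonist, KCl viability gate;
2. registration — similarity transform from the transmitted-light pair
   (or landmarks), ROI propagation into the confocal frame;
3. RNAscope quantification — average-intensity projection, per-cell
   background-subtracted signal, negative-control threshold;
4. classification — non-responder Gaussian threshold, four-way
   concordance categories;
5. statistics — Pearson correlation over the union set, per
   channel/agonist pairing.

A run is fully described by a :class:`RunConfig` (YAML) and a seed;
identical configuration and seed produce byte-identical reports.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as _io
from ._util import background_mode, sha256_of_array
from .calcium import ApplicationWindow, extract_traces, score_cells
from .classify import (classify_cells, fit_nonresponder_threshold, select_union)
from .registration import SimilarityTransform, estimate_transform, map_rois
from .rnascope import fit_negative_control, measure_cells, project_stack
from .stats import run_correlation
from .synthetic import SynthConfig, SyntheticDataset, config_from_dict, generate_dataset

NON_PROBE_CHANNELS = {"dapi", "trans"}


@dataclass
class PipelineOptions:
    kcl_min_delta: float = 0.1
    channel_order: tuple[str, str] = ("340", "385")
    rnascope_statistic: str = "mean"
    log_transform: bool = False
    landmarks: tuple[np.ndarray, np.ndarray] | None = None
    pairings: tuple[tuple[str, str], ...] | None = None  # (channel, agonist)
    registration_downsample: int = 2


@dataclass
class InputBundle:
    """Everything one analysis run consumes, already in memory."""

    movie: np.ndarray                   # (t, 2, y, x); ch 0 = 340 nm
    roi_labels: np.ndarray              # wide-field frame
    widefield_trans: np.ndarray
    confocal: dict[str, np.ndarray]     # channel -> (z, y, x)
    confocal_trans: np.ndarray
    negative_controls: np.ndarray
    schedule: tuple[ApplicationWindow, ...]
    frame_rate: float = 1.0

    @classmethod
    def from_dataset(cls, ds: SyntheticDataset) -> "InputBundle":
        return cls(movie=ds.movie, roi_labels=ds.roi_labels,
                   widefield_trans=ds.widefield_trans, confocal=ds.confocal,
                   confocal_trans=ds.confocal_trans,
                   negative_controls=ds.negative_controls,
                   schedule=tuple(ds.config.schedule),
                   frame_rate=ds.config.frame_rate)


def _mean_frame(movie: np.ndarray, channel: int, step: int = 10) -> np.ndarray:
    return movie[::step, channel].mean(axis=0)


def run_pipeline(inputs: InputBundle | SyntheticDataset,
                 options: PipelineOptions | None = None) -> dict:
    """Run the full analysis and return the (JSON-serializable) report."""
    if isinstance(inputs, SyntheticDataset):
        ds = inputs
        inputs = InputBundle.from_dataset(ds)
        if options is None:
            options = PipelineOptions(
                pairings=tuple((cp.name, cp.agonist) for cp in ds.config.channels))
    options = options or PipelineOptions()

    report: dict = {"stages": {}}
    report["input_hashes"] = {
        "movie": sha256_of_array(inputs.movie),
        "roi_labels": sha256_of_array(inputs.roi_labels),
        "widefield_trans": sha256_of_array(inputs.widefield_trans),
        "confocal_trans": sha256_of_array(inputs.confocal_trans),
        **{f"confocal_{k}": sha256_of_array(v) for k, v in sorted(inputs.confocal.items())},
    }

    # --- stage 1: calcium -------------------------------------------------
    try:
        roi_mask = inputs.roi_labels > 0
        bg340 = background_mode(_mean_frame(inputs.movie, 0), exclude=roi_mask)
        bg385 = background_mode(_mean_frame(inputs.movie, 1), exclude=roi_mask)
        traces = extract_traces(inputs.movie[:, 0], inputs.movie[:, 1],
                                inputs.roi_labels, bg340, bg385,
                                frame_rate=inputs.frame_rate)
        scores = score_cells(traces, list(inputs.schedule),
                             kcl_min_delta=options.kcl_min_delta)
    except Exception as exc:
        raise RuntimeError(f"stage 'calcium' failed: {exc}") from exc
    kcl_pass = scores.groupby("cell_id")["kcl_pass"].first()
    report["stages"]["calcium"] = {
        "background_340": bg340, "background_385": bg385,
        "n_cells": int(len(traces)), "n_kcl_pass": int(kcl_pass.sum()),
    }

    # --- stage 2: registration -------------------------------------------
    try:
        tf, reg_info = estimate_transform(
            np.asarray(inputs.widefield_trans, dtype=float),
            np.asarray(inputs.confocal_trans, dtype=float),
            landmarks=options.landmarks,
            downsample=options.registration_downsample, full_output=True)
        conf_shape = inputs.confocal_trans.shape
        labels_conf, dropped = map_rois(inputs.roi_labels, tf, conf_shape)
    except Exception as exc:
        raise RuntimeError(f"stage 'registration' failed: {exc}") from exc
    report["stages"]["registration"] = {
        "transform": tf.to_dict(), "dropped_rois": dropped, **reg_info}

    # --- stage 3: rnascope ------------------------------------------------
    try:
        control_model = fit_negative_control(inputs.negative_controls)
        intensities: dict[str, pd.DataFrame] = {}
        for name, stack in inputs.confocal.items():
            if name.lower() in NON_PROBE_CHANNELS:
                continue
            proj = project_stack(stack, mode="average")
            intensities[name] = measure_cells(
                proj, labels_conf, channel=name,
                statistic=options.rnascope_statistic)
    except Exception as exc:
        raise RuntimeError(f"stage 'rnascope' failed: {exc}") from exc
    report["stages"]["rnascope"] = {
        "negative_control": control_model.to_dict(),
        "channels": sorted(intensities),
    }

    # --- stages 4-5: classification and correlation -----------------------
    pairings = options.pairings or tuple(
        (ch, ag) for ch, ag in (("trpa1", "aitc"), ("trpv1", "capsaicin"))
        if ch in intensities)
    results = {}
    classified_tables = {}
    for channel, agonist in pairings:
        if channel not in intensities:
            raise RuntimeError(
                f"stage 'classify' failed: no confocal channel {channel!r}")
        sub = scores.loc[scores["agonist"] == agonist,
                         ["cell_id", "auc", "kcl_pass"]]
        if sub.empty:
            raise RuntimeError(
                f"stage 'classify' failed: agonist {agonist!r} not in schedule")
        merged = sub.merge(
            intensities[channel].rename(columns={"mean_intensity": "rnascope_intensity"})
            [["cell_id", "rnascope_intensity"]],
            on="cell_id", how="inner")
        n_unmatched = len(sub) - len(merged)
        try:
            fmodel = fit_nonresponder_threshold(
                merged.loc[merged["kcl_pass"], "auc"])
            classified, counts = classify_cells(merged, fmodel, control_model)
            union = select_union(classified)
            corr = run_correlation(classified, channel, agonist,
                                   log_transform=options.log_transform)
        except Exception as exc:
            raise RuntimeError(
                f"stage 'classify/stats' failed for {channel}/{agonist}: {exc}"
            ) from exc
        classified_tables[(channel, agonist)] = classified
        results[f"{channel}_{agonist}"] = {
            "functional_threshold": fmodel.to_dict(),
            "rnascope_threshold": control_model.threshold,
            "counts": counts,
            "n_gated": int(sum(counts.values())),
            "n_union": int(len(union)),
            "n_unmatched_rois": int(n_unmatched),
            "correlation": corr.to_dict(),
        }
    report["results"] = results
    report["_tables"] = classified_tables  # stripped before serialization
    return report


def serializable_report(report: dict) -> dict:
    """Deep-convert the report to plain JSON types, dropping tables."""
    def conv(v):
        if isinstance(v, dict):
            return {str(k): conv(x) for k, x in v.items() if not str(k).startswith("_")}
        if isinstance(v, (list, tuple)):
            return [conv(x) for x in v]
        if isinstance(v, (np.floating, np.integer)):
            return v.item()
        if isinstance(v, np.bool_):
            return bool(v)
        return v
    return conv({k: v for k, v in report.items() if not k.startswith("_")})


# ---------------------------------------------------------------------------
# config-file driven runs


@dataclass
class RunConfig:
    """One analysis run: synthetic conditions or real input paths."""

    synthetic: SynthConfig | None = None
    inputs: dict | None = None
    schedule: tuple[ApplicationWindow, ...] | None = None
    options: PipelineOptions = field(default_factory=PipelineOptions)
    seed: int | None = None
    output: str | None = None

    def validate(self) -> None:
        if (self.synthetic is None) == (self.inputs is None):
            raise ValueError(
                "exactly one of 'synthetic' and 'inputs' must be configured")
        if self.inputs is not None and self.schedule is None:
            raise ValueError("real-input runs need an application schedule")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        synth = raw.get("synthetic")
        schedule = raw.get("schedule")
        if schedule is not None:
            schedule = tuple(ApplicationWindow(**w) for w in schedule)
        opts = raw.get("options") or {}
        if "channel_order" in opts:
            opts["channel_order"] = tuple(str(c) for c in opts["channel_order"])
        if "pairings" in opts:
            opts["pairings"] = tuple(tuple(p) for p in opts["pairings"])
        cfg = cls(
            synthetic=config_from_dict(synth) if synth is not None else None,
            inputs=raw.get("inputs"),
            schedule=schedule,
            options=PipelineOptions(**opts),
            seed=raw.get("seed"),
            output=raw.get("output"),
        )
        cfg.validate()
        return cfg


def load_inputs(paths: dict, schedule, frame_rate: float = 1.0,
                channel_order=("340", "385")) -> InputBundle:
    """Assemble an InputBundle from the file paths of a RunConfig."""
    confocal = {name: _io.read_stack(p)
                for name, p in dict(paths["confocal"]).items()}
    return InputBundle(
        movie=_io.read_movie(paths["movie"], channel_order=channel_order),
        roi_labels=_io.read_labels(paths["roi_labels"]),
        widefield_trans=np.squeeze(_io.read_stack(paths["widefield_trans"])),
        confocal=confocal,
        confocal_trans=np.squeeze(_io.read_stack(paths["confocal_trans"])),
        negative_controls=_io.read_controls(paths["negative_controls"]),
        schedule=tuple(schedule),
        frame_rate=frame_rate,
    )


def run_from_config(config: RunConfig) -> dict:
    """Execute a configured run and write its artifacts if requested."""
    config.validate()
    if config.synthetic is not None:
        synth = config.synthetic
        if config.seed is not None:
            from dataclasses import replace
            synth = replace(synth, seed=int(config.seed))
        ds = generate_dataset(synth)
        if config.options.pairings is None:
            config.options.pairings = tuple(
                (cp.name, cp.agonist) for cp in synth.channels)
        bundle = InputBundle.from_dataset(ds)
    else:
        bundle = load_inputs(config.inputs, config.schedule,
                             channel_order=config.options.channel_order)
    report = run_pipeline(bundle, config.options)
    if config.output:
        out = Path(config.output)
        out.mkdir(parents=True, exist_ok=True)
        _io.write_json(out / "report.json", serializable_report(report))
        for (channel, agonist), table in report.get("_tables", {}).items():
            table.to_csv(out / f"classified_{channel}_{agonist}.csv", index=False)
    return report
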