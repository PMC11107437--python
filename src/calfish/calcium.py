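"""Fura-2 ratiometric trace extraction and agonist response scoring.

The functional recording is a 1 Hz sequence of 340 nm / 385 nm excitation
frame pairs.  After per-channel background subtraction the pixelwise
F340/F385 ratio tracks cytosolic calcium independent of dye load.  Each
cell's trace is the mean ratio over its ROI; the response to an agonist is
the baseline-corrected area under the trace for 60 s from application
onset, and viability (neuron identity) is gated on the depolarization
response to 60 mM KCl at the end of the protocol.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._util import background_mode

#: length (s) of the integration window after agonist onset
AUC_SPAN = 60.0
#: baseline is averaged over [start - 8 s, start - 3 s)
BASELINE_OFFSET = 8.0
BASELINE_SPAN = 5.0


@dataclass(frozen=True)
class ApplicationWindow:
    """One agonist application: name, molar concentration, onset and duration (s)."""

    agonist: str
    concentration: float
    start: float
    duration: float

    def __post_init__(self) -> None:
        if self.duration <= 0:
            raise ValueError(f"duration must be > 0, got {self.duration}")
        if self.start < 0:
            raise ValueError(f"start must be >= 0, got {self.start}")

    @property
    def end(self) -> float:
        return self.start + self.duration


def default_schedule() -> list[ApplicationWindow]:
    """AITC 100 uM / 60 s, capsaicin 1 uM / 30 s, KCl 60 mM / 15 s.

    Washout gaps are long enough (~2 min) that the decaying tail of one
    response has fallen below the noise floor before the next baseline
    window, so per-window flat-baseline correction stays unbiased.
    """
    return [
        ApplicationWindow("aitc", 100e-6, 20.0, 60.0),
        ApplicationWindow("capsaicin", 1e-6, 210.0, 30.0),
        ApplicationWindow("kcl", 60e-3, 290.0, 15.0),
    ]


def validate_schedule(schedule: list[ApplicationWindow]) -> None:
    """Applications must be ordered and non-overlapping."""
    for a, b in zip(schedule, schedule[1:]):
        if b.start < a.end:
            raise ValueError(
                f"applications overlap: {a.agonist} ends at {a.end} s but "
                f"{b.agonist} starts at {b.start} s"
            )


@dataclass
class RatioTrace:
    """Per-cell F340/F385 time series on the acquisition time grid."""

    cell_id: int
    times: np.ndarray
    ratio: np.ndarray
    roi_area: int = 0

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.ratio = np.asarray(self.ratio, dtype=float)
        if self.times.shape != self.ratio.shape:
            raise ValueError("times and ratio must have equal length")
        if len(self.times) > 1 and not np.all(np.diff(self.times) > 0):
            raise ValueError("times must be strictly increasing")


@dataclass(frozen=True)
class AUCScore:
    cell_id: int
    agonist: str
    baseline: float
    auc: float
    kcl_pass: bool


def compute_ratio(frame_340: np.ndarray, frame_385: np.ndarray,
                  background_340: float, background_385: float) -> np.ndarray:
    """Background-subtracted per-pixel F340/F385 ratio.

    Pixels whose background-subtracted 385 nm denominator is <= 0 carry no
    usable signal and are returned as NaN; downstream ROI means must skip
    them.
    """
    f340 = np.asarray(frame_340, dtype=float)
    f385 = np.asarray(frame_385, dtype=float)
    if f340.shape != f385.shape:
        raise ValueError(f"frame shapes differ: {f340.shape} vs {f385.shape}")
    if background_340 < 0 or background_385 < 0:
        raise ValueError("background intensities must be >= 0")
    num = f340 - background_340
    den = f385 - background_385
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = num / den
    ratio[den <= 0] = np.nan
    return ratio


def estimate_background(image: np.ndarray, roi_labels: np.ndarray) -> float:
    """Background estimate for one channel: intensity mode outside all ROIs."""
    return background_mode(np.asarray(image, dtype=float), exclude=np.asarray(roi_labels) > 0)


def extract_trace(ratio_movie: np.ndarray, roi_labels: np.ndarray, cell_id: int,
                  frame_rate: float = 1.0, min_area: int = 3) -> RatioTrace:
    """Mean valid-ratio trace for one ROI from a (t, y, x) ratio movie."""
    labels = np.asarray(roi_labels)
    mask = labels == cell_id
    area = int(mask.sum())
    if area == 0:
        raise ValueError(f"cell_id {cell_id} not present in ROI labels")
    if area < min_area:
        raise ValueError(f"ROI for cell {cell_id} has {area} px < minimum {min_area}")
    vals = np.asarray(ratio_movie, dtype=float)[:, mask]
    with np.errstate(invalid="ignore"):
        trace = np.nanmean(vals, axis=1)
    if np.all(np.isnan(vals), axis=1).any():
        raise ValueError(f"ROI for cell {cell_id} has frames with no valid ratio pixel")
    times = np.arange(vals.shape[0], dtype=float) / frame_rate
    return RatioTrace(cell_id=int(cell_id), times=times, ratio=trace, roi_area=area)


def extract_traces(movie_340: np.ndarray, movie_385: np.ndarray,
                   roi_labels: np.ndarray,
                   background_340: float, background_385: float,
                   frame_rate: float = 1.0) -> dict[int, RatioTrace]:
    """Vectorized per-cell ratio traces for every ROI in a label image.

    Works frame by frame (the ratio image is never materialized for the whole
    movie) and averages valid ratio pixels per label with ``np.bincount``.
    """
    labels = np.asarray(roi_labels)
    if movie_340.shape != movie_385.shape:
        raise ValueError("340 and 385 movies must have identical shape")
    if movie_340.shape[1:] != labels.shape:
        raise ValueError("ROI label image does not match frame shape")
    ids = np.unique(labels)
    ids = ids[ids > 0]
    n_lab = int(labels.max()) + 1
    flat = labels.ravel()
    areas = np.bincount(flat, minlength=n_lab)
    n_t = movie_340.shape[0]
    sums = np.zeros((n_t, n_lab))
    counts = np.zeros((n_t, n_lab))
    for t in range(n_t):
        ratio = compute_ratio(movie_340[t], movie_385[t], background_340, background_385)
        r = ratio.ravel()
        ok = np.isfinite(r)
        sums[t] = np.bincount(flat[ok], weights=r[ok], minlength=n_lab)
        counts[t] = np.bincount(flat[ok], minlength=n_lab)
    times = np.arange(n_t, dtype=float) / frame_rate
    out: dict[int, RatioTrace] = {}
    with np.errstate(invalid="ignore"):
        means = sums / counts
    for i in ids:
        out[int(i)] = RatioTrace(cell_id=int(i), times=times, ratio=means[:, i],
                                 roi_area=int(areas[i]))
    return out


def compute_baseline(trace: RatioTrace, window: ApplicationWindow) -> float:
    """Pre-application baseline: mean ratio over [start-8 s, start-3 s)."""
    lo = window.start - BASELINE_OFFSET
    hi = window.start - (BASELINE_OFFSET - BASELINE_SPAN)
    sel = (trace.times >= lo) & (trace.times < hi)
    n_expected = BASELINE_SPAN  # 5 samples at 1 Hz
    if lo < trace.times[0] or sel.sum() < n_expected:
        raise ValueError(
            f"insufficient baseline: need samples covering [{lo}, {hi}) s "
            f"before {window.agonist} at {window.start} s"
        )
    return float(np.mean(trace.ratio[sel]))


def compute_auc(trace: RatioTrace, window: ApplicationWindow,
                baseline: float | None = None, span: float = AUC_SPAN) -> float:
    """Baseline-corrected trapezoidal area under the trace over
    [start, start + span] seconds (ratio*s; may be negative)."""
    if baseline is None:
        baseline = compute_baseline(trace, window)
    hi = window.start + span
    if trace.times[-1] < hi:
        raise ValueError(
            f"recording ends at {trace.times[-1]} s, before {window.agonist} "
            f"window end {hi} s"
        )
    sel = (trace.times >= window.start) & (trace.times <= hi)
    t = trace.times[sel]
    y = trace.ratio[sel] - baseline
    return float(np.trapezoid(y, t))


def kcl_gate(trace: RatioTrace, kcl_window: ApplicationWindow,
             min_delta: float = 0.1, tail: float = 10.0) -> bool:
    """Viability gate: peak baseline-corrected ratio within the KCl window
    (plus a short tail for slow risers) must reach ``min_delta``."""
    hi = kcl_window.end + tail
    if trace.times[-1] < kcl_window.end:
        raise ValueError("KCl window extends beyond the recording")
    baseline = compute_baseline(trace, kcl_window)
    sel = (trace.times >= kcl_window.start) & (trace.times <= hi)
    peak = float(np.max(trace.ratio[sel] - baseline))
    return peak >= min_delta


def score_cells(traces: dict[int, RatioTrace], schedule: list[ApplicationWindow],
                kcl_min_delta: float = 0.1) -> pd.DataFrame:
    """Score every trace against every non-KCl application.

    Returns a tidy frame with one row per (cell, agonist): baseline, AUC and
    the cell's KCl gate result.
    """
    validate_schedule(schedule)
    kcl = [w for w in schedule if w.agonist.lower() == "kcl"]
    if not kcl:
        raise ValueError("schedule contains no KCl viability application")
    agonists = [w for w in schedule if w.agonist.lower() != "kcl"]
    rows = []
    for cid, tr in traces.items():
        passed = kcl_gate(tr, kcl[0], min_delta=kcl_min_delta)
        for w in agonists:
            b = compute_baseline(tr, w)
            rows.append(
                {
                    "cell_id": cid,
                    "agonist": w.agonist,
                    "baseline": b,
                    "auc": compute_auc(tr, w, baseline=b),
                    "kcl_pass": passed,
                }
            )
    return pd.DataFrame(rows)
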