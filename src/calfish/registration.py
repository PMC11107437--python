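"""Similarity registration between the confocal and wide-field coordinate frames.

The confocal acquisition (RNAscope channels, DAPI, transmitted light) is made
after fixation on a different microscope than the wide-field functional
recording, so the two coordinate frames differ by an in-plane rotation,
translation and a small isotropic scale change (different optics).  This
module estimates that similarity transform — either from paired landmarks or
automatically from the two transmitted-light images — applies it to images
and point sets, and propagates ROI label images from the wide-field frame
into the confocal frame so each cell's functional score can be paired with
its in situ signal.

Coordinate convention: ``(x, y)`` with ``x`` rightward (column), ``y``
downward (row), origin at the top-left pixel center, 0-based.  A transform
maps *moving* (confocal) coordinates into the *fixed* (wide-field) frame::

    p_fixed = scale * R(rotation) @ p_moving + translation
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize
from skimage import transform as _skt
from skimage.registration import phase_cross_correlation


class LowConfidenceWarning(UserWarning):
    """Raised when the intensity-based correlation peak is weak."""


@dataclass(frozen=True)
class SimilarityTransform:
    """Rotation (degrees, counter-clockwise in the x-right/y-down frame),
    translation (pixels) and isotropic scale mapping moving -> fixed."""

    rotation_deg: float = 0.0
    translation: tuple[float, float] = (0.0, 0.0)
    scale: float = 1.0

    def __post_init__(self) -> None:
        if not self.scale > 0:
            raise ValueError(f"scale must be > 0, got {self.scale}")

    @property
    def matrix(self) -> np.ndarray:
        """3x3 homogeneous matrix acting on (x, y, 1) column vectors."""
        th = np.deg2rad(self.rotation_deg)
        s = self.scale
        dx, dy = self.translation
        return np.array(
            [
                [s * np.cos(th), -s * np.sin(th), dx],
                [s * np.sin(th), s * np.cos(th), dy],
                [0.0, 0.0, 1.0],
            ]
        )

    @classmethod
    def from_matrix(cls, m: np.ndarray) -> "SimilarityTransform":
        scale = float(np.hypot(m[0, 0], m[1, 0]))
        rot = float(np.rad2deg(np.arctan2(m[1, 0], m[0, 0])))
        return cls(rotation_deg=rot, translation=(float(m[0, 2]), float(m[1, 2])), scale=scale)

    @classmethod
    def identity(cls) -> "SimilarityTransform":
        return cls()

    def inverse(self) -> "SimilarityTransform":
        return SimilarityTransform.from_matrix(np.linalg.inv(self.matrix))

    def compose(self, other: "SimilarityTransform") -> "SimilarityTransform":
        """Return self o other (apply ``other`` first)."""
        return SimilarityTransform.from_matrix(self.matrix @ other.matrix)

    def apply_points(self, points: np.ndarray) -> np.ndarray:
        """Map an (n, 2) array of (x, y) points exactly."""
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        out = pts @ self.matrix[:2, :2].T + self.matrix[:2, 2]
        return out

    def to_skimage(self) -> _skt.SimilarityTransform:
        return _skt.SimilarityTransform(matrix=self.matrix)

    def to_dict(self) -> dict:
        return {
            "rotation_deg": float(self.rotation_deg),
            "dx_px": float(self.translation[0]),
            "dy_px": float(self.translation[1]),
            "scale": float(self.scale),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SimilarityTransform":
        return cls(
            rotation_deg=float(d["rotation_deg"]),
            translation=(float(d["dx_px"]), float(d["dy_px"])),
            scale=float(d["scale"]),
        )

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2, sort_keys=True)

    @classmethod
    def load(cls, path) -> "SimilarityTransform":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


def _center_transform(rotation_deg: float, scale: float, offset: tuple[float, float],
                      center: tuple[float, float]) -> SimilarityTransform:
    """Similarity that rotates/scales about ``center`` then shifts by ``offset``."""
    th = np.deg2rad(rotation_deg)
    c, s = np.cos(th), np.sin(th)
    cx, cy = center
    dx = cx + offset[0] - scale * (c * cx - s * cy)
    dy = cy + offset[1] - scale * (s * cx + c * cy)
    return SimilarityTransform(rotation_deg=rotation_deg, translation=(dx, dy), scale=scale)


def apply_transform(image: np.ndarray, transform: SimilarityTransform,
                    output_shape: tuple[int, int] | None = None,
                    order: int = 1) -> tuple[np.ndarray, np.ndarray]:
    """Resample a moving-frame image into the fixed frame.

    Returns ``(warped, valid)`` where ``valid`` is a boolean mask marking
    pixels whose value came from inside the moving image; out-of-frame
    pixels are NaN in ``warped`` and must be excluded from ROI statistics.
    """
    img = np.asarray(image, dtype=float)
    tf = transform.to_skimage()
    warped = _skt.warp(img, inverse_map=tf.inverse, order=order,
                       output_shape=output_shape, cval=np.nan,
                       preserve_range=True)
    valid = np.isfinite(warped)
    return warped, valid


def transform_points(points: np.ndarray, transform: SimilarityTransform) -> np.ndarray:
    """Map (x, y) points exactly (no resampling)."""
    return transform.apply_points(points)


def map_rois(labels: np.ndarray, transform: SimilarityTransform,
             output_shape: tuple[int, int]) -> tuple[np.ndarray, list[int]]:
    """Carry an ROI label image from the fixed (wide-field) frame into the
    moving (confocal) frame.

    ``transform`` maps moving -> fixed, so each output (confocal) pixel looks
    up the wide-field label at its transformed position (nearest neighbour;
    labels are categorical).  ROIs that land entirely outside the confocal
    field are dropped from the output and reported.

    Returns ``(mapped_labels, dropped_ids)``.
    """
    lab = np.asarray(labels)
    tf = transform.to_skimage()
    # output frame = moving frame; output->input map is exactly `transform`
    mapped = _skt.warp(lab.astype(float), inverse_map=tf, order=0,
                       output_shape=output_shape, cval=0, preserve_range=True)
    mapped = mapped.astype(lab.dtype)
    in_ids = set(np.unique(lab)) - {0}
    out_ids = set(np.unique(mapped)) - {0}
    dropped = sorted(int(i) for i in in_ids - out_ids)
    return mapped, dropped


def estimate_landmark_transform(fixed_points: np.ndarray,
                                moving_points: np.ndarray) -> SimilarityTransform:
    """Least-squares similarity fit from paired (x, y) landmarks."""
    fixed_points = np.atleast_2d(np.asarray(fixed_points, dtype=float))
    moving_points = np.atleast_2d(np.asarray(moving_points, dtype=float))
    if fixed_points.shape != moving_points.shape or fixed_points.shape[0] < 2:
        raise ValueError("need >= 2 paired landmarks of identical shape")
    if hasattr(_skt.SimilarityTransform, "from_estimate"):
        tf = _skt.SimilarityTransform.from_estimate(moving_points, fixed_points)
        if not tf:
            raise ValueError("degenerate landmark configuration")
    else:  # scikit-image < 0.26
        tf = _skt.SimilarityTransform()
        if not tf.estimate(moving_points, fixed_points):
            raise ValueError("degenerate landmark configuration")
    return SimilarityTransform.from_matrix(tf.params)


def _ncc(a: np.ndarray, b: np.ndarray, mask: np.ndarray) -> float:
    if mask.sum() < 64:
        return -1.0
    x = a[mask] - a[mask].mean()
    y = b[mask] - b[mask].mean()
    nx = np.linalg.norm(x)
    ny = np.linalg.norm(y)
    if nx == 0 or ny == 0:
        return -1.0
    return float(np.dot(x, y) / (nx * ny))


def _score(fixed: np.ndarray, moving: np.ndarray, tf: SimilarityTransform) -> float:
    warped, valid = apply_transform(moving, tf, output_shape=fixed.shape)
    return _ncc(fixed, np.nan_to_num(warped), valid)


def _block_mean(img: np.ndarray, k: int) -> np.ndarray:
    h, w = img.shape
    img = img[: h - h % k, : w - w % k]
    return img.reshape(h // k, k, w // k, k).mean(axis=(1, 3))


def estimate_transform(fixed: np.ndarray, moving: np.ndarray,
                       landmarks: tuple[np.ndarray, np.ndarray] | None = None,
                       angle_range: tuple[float, float] = (-16.0, 16.0),
                       angle_step: float = 2.0,
                       scale_range: tuple[float, float] = (0.88, 1.13),
                       scale_step: float = 0.04,
                       refine: bool = True,
                       confidence_floor: float = 0.2,
                       downsample: int = 1,
                       full_output: bool = False):
    """Estimate the similarity transform mapping ``moving`` onto ``fixed``.

    With ``landmarks`` (a pair of (n, 2) arrays ``(fixed_pts, moving_pts)``)
    the fit is a closed-form least-squares similarity.  Otherwise the
    estimate is intensity-based: a grid of candidate (rotation, scale) pairs
    is scored by phase correlation (for the translation) plus normalized
    cross-correlation, and the best candidate is polished by local
    optimization of the NCC over all four parameters.

    A final NCC below ``confidence_floor`` triggers a
    :class:`LowConfidenceWarning`; the best transform is still returned.
    """
    if landmarks is not None:
        fixed_pts, moving_pts = landmarks
        tf = estimate_landmark_transform(fixed_pts, moving_pts)
        if full_output:
            return tf, {"mode": "landmarks", "n_landmarks": int(np.atleast_2d(fixed_pts).shape[0])}
        return tf

    fixed = np.asarray(fixed, dtype=float)
    moving = np.asarray(moving, dtype=float)

    if downsample > 1:
        k = int(downsample)
        out = estimate_transform(
            _block_mean(fixed, k), _block_mean(moving, k),
            angle_range=angle_range, angle_step=angle_step,
            scale_range=scale_range, scale_step=scale_step, refine=refine,
            confidence_floor=confidence_floor, downsample=1,
            full_output=full_output)
        tf_ds, info = out if full_output else (out, None)
        # block centers: p_ds = p_full / k - (k - 1) / (2 k)
        off = -(k - 1) / (2.0 * k)
        down = SimilarityTransform(0.0, (off, off), 1.0 / k)
        tf = down.inverse().compose(tf_ds).compose(down)
        return (tf, info) if full_output else tf

    center = ((moving.shape[1] - 1) / 2.0, (moving.shape[0] - 1) / 2.0)

    angles = np.arange(angle_range[0], angle_range[1] + 1e-9, angle_step)
    scales = np.arange(scale_range[0], scale_range[1] + 1e-9, scale_step)

    best = None
    for ang in angles:
        for sc in scales:
            t0 = _center_transform(ang, sc, (0.0, 0.0), center)
            warped, valid = apply_transform(moving, t0, output_shape=fixed.shape)
            warped = np.nan_to_num(warped)
            shift, _, _ = phase_cross_correlation(
                fixed * 1.0, warped, upsample_factor=4, normalization=None
            )
            cand = _center_transform(ang, sc, (float(shift[1]), float(shift[0])), center)
            score = _score(fixed, moving, cand)
            if best is None or score > best[0]:
                best = (score, ang, sc, float(shift[1]), float(shift[0]))

    score0, ang, sc, dx, dy = best
    x0 = np.array([ang, np.log(sc), dx, dy])

    if refine:
        def neg(x):
            tf = _center_transform(x[0], float(np.exp(x[1])), (x[2], x[3]), center)
            return -_score(fixed, moving, tf)

        res = minimize(neg, x0, method="Powell",
                       options={"xtol": 1e-4, "ftol": 1e-7, "maxiter": 400})
        x = res.x
        final_score = -float(res.fun)
        if final_score < score0:  # Powell wandered off; keep grid winner
            x, final_score = x0, score0
    else:
        x, final_score = x0, score0

    tf = _center_transform(float(x[0]), float(np.exp(x[1])), (float(x[2]), float(x[3])), center)
    if final_score < confidence_floor:
        warnings.warn(
            f"registration NCC {final_score:.3f} below confidence floor "
            f"{confidence_floor:.3f}; estimate is low-confidence",
            LowConfidenceWarning,
        )
    if full_output:
        return tf, {"mode": "intensity", "ncc": final_score,
                    "grid_ncc": score0, "low_confidence": final_score < confidence_floor}
    return tf
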