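"""Small shared numeric helpers."""

from __future__ import annotations

import numpy as np


def background_mode(image: np.ndarray, exclude: np.ndarray | None = None,
                    bin_width: float | None = None) -> float:
    """Mode of the intensity distribution outside all ROIs.

    The mode is a robust background estimator for fluorescence images: the
    background occupies most of the field and forms the dominant histogram
    peak, while cells only add a bright tail.  Values are histogrammed at
    ``bin_width`` (default: Freedman-Diaconis, floored at a sensible minimum
    for near-integer count data) and the center of the tallest bin is
    returned.
    """
    img = np.asarray(image, dtype=float)
    vals = img[~exclude] if exclude is not None else img.ravel()
    vals = vals[np.isfinite(vals)]
    if vals.size == 0:
        raise ValueError("no pixels available for background estimation")
    if vals.size < 16 or np.ptp(vals) == 0:
        return float(np.median(vals))
    if bin_width is None:
        q75, q25 = np.percentile(vals, [75, 25])
        iqr = q75 - q25
        bin_width = 2 * iqr / vals.size ** (1 / 3) if iqr > 0 else 0.0
        bin_width = max(bin_width, np.ptp(vals) / 512, 1e-9)
    lo, hi = vals.min(), vals.max() + bin_width
    edges = np.arange(lo, hi + bin_width, bin_width)
    counts, edges = np.histogram(vals, bins=edges)
    k = int(np.argmax(counts))
    return float(0.5 * (edges[k] + edges[k + 1]))


def sha256_of_array(arr: np.ndarray) -> str:
    """Stable content hash of an array (dtype+shape+bytes)."""
    import hashlib

    h = hashlib.sha256()
    a = np.ascontiguousarray(arr)
    h.update(str(a.dtype).encode())
    h.update(str(a.shape).encode())
    h.update(a.tobytes())
    return h.hexdigest()
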