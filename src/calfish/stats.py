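"""Pearson correlation of RNAscope intensity against functional AUC.

The headline statistic of the analysis: the Pearson product-moment
correlation between a cell's in situ signal and its agonist response,
computed over the union set (cells positive on either modality).  The
p-value is the conventional two-sided t-transform with n-2 degrees of
freedom; a seeded permutation alternative is available as a robustness
check.  Fisher z confidence intervals are provided for simulation-recovery
comparisons.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .classify import select_union


@dataclass(frozen=True)
class CorrelationResult:
    channel: str
    agonist: str
    r: float
    p_value: float
    n: int

    def to_dict(self) -> dict:
        return {"channel": self.channel, "agonist": self.agonist,
                "r": self.r, "p_value": self.p_value, "n": self.n}


def pearson(x, y, channel: str = "", agonist: str = "",
            method: str = "t", n_permutations: int = 10000,
            seed: int | None = 0) -> CorrelationResult:
    """Pearson product-moment correlation with two-sided p-value.

    ``method="t"`` uses the exact t-distribution with n-2 df;
    ``method="permutation"`` shuffles ``y`` (seeded) and reports the
    fraction of |r*| >= |r|.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D arrays of equal length")
    n = x.size
    if n < 3:
        raise ValueError(f"need n >= 3 for a correlation, got {n}")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero variance in x or y; correlation undefined")
    res = sps.pearsonr(x, y)
    r = float(res.statistic)
    if method == "t":
        p = float(res.pvalue)
    elif method == "permutation":
        rng = np.random.default_rng(seed)
        xc = x - x.mean()
        yc = y - y.mean()
        denom = np.linalg.norm(xc) * np.linalg.norm(yc)
        robs = float(np.dot(xc, yc) / denom)
        count = 0
        for _ in range(n_permutations):
            rp = np.dot(xc, rng.permutation(yc)) / denom
            if abs(rp) >= abs(robs) - 1e-15:
                count += 1
        p = (count + 1) / (n_permutations + 1)
    else:
        raise ValueError(f"unknown method {method!r}")
    return CorrelationResult(channel=channel, agonist=agonist, r=r,
                             p_value=p, n=int(n))


def fisher_interval(rho: float, n: int, level: float = 0.95) -> tuple[float, float]:
    """Fisher z confidence interval around a correlation at sample size n."""
    if n < 4:
        raise ValueError("Fisher interval needs n >= 4")
    z = np.arctanh(rho)
    half = sps.norm.ppf(0.5 + level / 2) / np.sqrt(n - 3)
    return float(np.tanh(z - half)), float(np.tanh(z + half))


def run_correlation(classified: pd.DataFrame, channel: str, agonist: str,
                    log_transform: bool = False,
                    method: str = "t", seed: int | None = 0) -> CorrelationResult:
    """Correlate (rnascope_intensity, auc) over the union set.

    ``log_transform`` applies log1p to both variables before correlating
    (off by default; the headline analysis uses raw values).
    """
    union = select_union(classified)
    if len(union) < 3:
        raise ValueError(
            f"degenerate union set (n={len(union)}) for {channel}/{agonist}")
    x = union["rnascope_intensity"].to_numpy(dtype=float)
    y = union["auc"].to_numpy(dtype=float)
    if log_transform:
        x = np.log1p(np.clip(x, 0, None))
        y = np.log1p(np.clip(y, 0, None))
    return pearson(x, y, channel=channel, agonist=agonist, method=method, seed=seed)
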