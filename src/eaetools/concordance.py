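"""Cross-treatment concordance of log2 fold-change profiles.

Pearson r over all genes expressed above background in both arrays, with
the correlation t statistic

    t = r * sqrt(df) / sqrt(1 - r^2),   df = n - 2,

two-tailed p from the t distribution, an ordinary least-squares regression
of profile B on profile A (a slope < 1 reads as "treatment A more potent"),
and a per-gene treatment-specificity classification at a fold threshold.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ConcordanceResult",
    "correlation_t_pvalue",
    "pearson_concordance",
    "classify_regulated",
    "CLASSES",
]

CLASSES = ("a_specific", "b_specific", "shared_same_direction",
           "shared_opposite", "unregulated")


@dataclass(frozen=True)
class ConcordanceResult:
    r: float
    n: int
    df: int
    t: float
    p: float
    slope: float
    intercept: float


def correlation_t_pvalue(r: float, n: int) -> tuple[float, int, float]:
    """Closed-form t, df and two-tailed p for a Pearson coefficient.

    df = n - 2 exactly; at |r| = 1 the t is infinite and p is reported as
    the smallest positive float rather than 0.
    """
    if n < 3:
        raise ValueError("need n >= 3")
    df = n - 2
    r = float(r)
    if abs(r) >= 1.0:
        return float(np.sign(r) * np.inf), df, float(np.nextafter(0.0, 1.0))
    t = r * np.sqrt(df) / np.sqrt(1.0 - r * r)
    p = 2.0 * stats.t.sf(abs(t), df)
    return float(t), df, float(max(p, np.nextafter(0.0, 1.0)))


def pearson_concordance(
    a: np.ndarray,
    b: np.ndarray,
    expressed_mask: np.ndarray | None = None,
) -> ConcordanceResult:
    """Concordance between two log2 fold-change vectors.

    ``expressed_mask`` restricts the comparison to genes expressed above
    background in both arrays.  The regression is of B on A (slope is not
    symmetric; r, t and p are).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("profiles must have the same length")
    if expressed_mask is not None:
        mask = np.asarray(expressed_mask, dtype=bool)
        a, b = a[mask], b[mask]
    n = a.size
    if n < 3:
        raise ValueError("need >= 3 genes after masking")
    if np.std(a) == 0.0 or np.std(b) == 0.0:
        raise ValueError("zero variance: Pearson r undefined")
    r = float(np.corrcoef(a, b)[0, 1])
    t, df, p = correlation_t_pvalue(r, n)
    reg = stats.linregress(a, b)
    return ConcordanceResult(r=r, n=n, df=df, t=t, p=p,
                             slope=float(reg.slope),
                             intercept=float(reg.intercept))


def classify_regulated(
    a: np.ndarray,
    b: np.ndarray,
    threshold: float = 0.6,
) -> np.ndarray:
    """Treatment-specificity class per gene at a |log2fc| threshold.

    a_specific: regulated beyond the threshold in A only; b_specific:
    in B only; shared_same_direction / shared_opposite: beyond it in both;
    unregulated otherwise.  The classes partition the gene set.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("profiles must have the same length")
    reg_a = np.abs(a) > threshold
    reg_b = np.abs(b) > threshold
    out = np.full(a.shape, "unregulated", dtype=object)
    out[reg_a & ~reg_b] = "a_specific"
    out[~reg_a & reg_b] = "b_specific"
    same = np.sign(a) == np.sign(b)
    out[reg_a & reg_b & same] = "shared_same_direction"
    out[reg_a & reg_b & ~same] = "shared_opposite"
    return out
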