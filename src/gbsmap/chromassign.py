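"""Preliminary allocation of SNPs to linkage groups by marker regression.

The proportion of major-allele reads P_A is computed per individual and
tested by one-way ANOVA against the genotype classes of every marker of an
existing anchor map; a SNP is allocated to a linkage group when exactly
one group contains an anchor explaining more than 25% of the variance.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .markers import MISSING


@dataclass
class AnchorMap:
    """Markers of an established map with per-offspring genotype classes."""

    names: list
    lgs: np.ndarray
    positions: np.ndarray
    calls: np.ndarray  # (n_anchors, n_offspring), MISSING = -1

    def __post_init__(self):
        self.lgs = np.asarray(self.lgs)
        self.positions = np.asarray(self.positions, dtype=float)
        self.calls = np.asarray(self.calls)
        for k in range(len(self.names)):
            row = self.calls[k]
            if np.unique(row[row != MISSING]).size < 2:
                raise ValueError(f"anchor {self.names[k]} has < 2 classes")


def major_allele_proportion(major: np.ndarray, minor: np.ndarray) -> np.ndarray:
    """P_A = major / (major + minor); NaN where total depth is zero."""
    major = np.asarray(major, dtype=float)
    minor = np.asarray(minor, dtype=float)
    total = major + minor
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(total > 0, major / np.maximum(total, 1e-12), np.nan)


def anova_r2(values: np.ndarray, classes: np.ndarray,
             min_joint: int = 50) -> tuple[float, float]:
    """One-way ANOVA of values on class labels: (R^2 percent, F p-value).

    Pairs with missing values or class labels are dropped; degenerate
    anchors (a single class or too few joint observations) return (0, 1).
    """
    ok = np.isfinite(values) & (classes != MISSING)
    v, c = values[ok], classes[ok]
    if v.size < min_joint:
        return 0.0, 1.0
    labels, inverse = np.unique(c, return_inverse=True)
    if labels.size < 2:
        return 0.0, 1.0
    counts = np.bincount(inverse)
    if (counts < 2).any():
        keep = counts[inverse] >= 2
        v, inverse = v[keep], inverse[keep]
        labels, inverse = np.unique(inverse, return_inverse=True)
        if labels.size < 2 or v.size < min_joint:
            return 0.0, 1.0
        counts = np.bincount(inverse)
    grand = v.mean()
    means = np.bincount(inverse, weights=v) / counts
    ssb = (counts * (means - grand) ** 2).sum()
    sst = ((v - grand) ** 2).sum()
    if sst <= 1e-10 * v.size * max(1.0, grand ** 2):
        return 0.0, 1.0
    k, n = labels.size, v.size
    ssw = sst - ssb
    if ssw <= 0:
        return 100.0, 0.0
    f = (ssb / (k - 1)) / (ssw / (n - k))
    p = float(stats.f.sf(f, k - 1, n - k))
    return float(100.0 * ssb / sst), p


def marker_regression(pa: np.ndarray, anchors: AnchorMap,
                      min_joint: int = 50) -> pd.DataFrame:
    """P_A against every anchor marker; best anchor per linkage group."""
    rows = []
    for k in range(len(anchors.names)):
        r2, p = anova_r2(pa, anchors.calls[k], min_joint)
        rows.append((anchors.names[k], anchors.lgs[k], anchors.positions[k], r2, p))
    df = pd.DataFrame(rows, columns=["anchor", "lg", "pos", "r2", "p"])
    best = df.loc[df.groupby("lg")["r2"].idxmax()].reset_index(drop=True)
    return best


def allocate(best_per_lg: pd.DataFrame, min_r2: float = 25.0) -> dict:
    """Allocation decision from per-LG best R^2 values.

    R^2 strictly greater than ``min_r2`` on exactly one group allocates
    the SNP there; on two or more groups the SNP is 'multi-LG'; otherwise
    'unallocated'.
    """
    over = best_per_lg[best_per_lg["r2"] > min_r2]
    if len(over) == 1:
        row = over.iloc[0]
        return {"decision": "allocated", "lg": row["lg"],
                "anchor": row["anchor"], "r2": float(row["r2"])}
    if len(over) >= 2:
        return {"decision": "multi-LG", "lg": None, "anchor": None,
                "r2": float(over["r2"].max())}
    return {"decision": "unallocated", "lg": None, "anchor": None,
            "r2": float(best_per_lg["r2"].max()) if len(best_per_lg) else 0.0}


def allocate_snps(major: np.ndarray, minor: np.ndarray, snp_ids,
                  anchors: AnchorMap, min_r2: float = 25.0,
                  min_joint: int = 50) -> pd.DataFrame:
    """Allocate every SNP in a count matrix (offspring columns only)."""
    rows = []
    for k, sid in enumerate(snp_ids):
        pa = major_allele_proportion(major[k], minor[k])
        best = marker_regression(pa, anchors, min_joint)
        dec = allocate(best, min_r2)
        rows.append((sid, dec["decision"], dec["lg"], dec["anchor"], dec["r2"]))
    return pd.DataFrame(rows, columns=["snp_id", "decision", "lg", "anchor", "r2"])
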