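"""SNP filtering and genotype calling from allele read counts.

SNPs are first filtered on read support (mean depth, quality score,
excess heterozygosity).  Genotypes are then called per SNP by plotting
each individual's (major, minor) read counts on square-root axes: assumed
homozygotes hug the horizontal or vertical axis while heterozygotes form
an inclined line.  The heterozygote line is fitted by functional
(errors-in-both-variables) regression and each individual classified to
the nearest of the three lines.  A classification is kept only if the
major-allele proportion is well separated between the called classes
(R-squared of the one-way regression >= 50%) and the classes are
compatible with the parental calls.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .counts import CountMatrix
from .markers import MISSING

CALL_AA, CALL_AB, CALL_BB = 0, 1, 2


def filter_snps(counts: CountMatrix, n_individuals: int | None = None,
                min_mean_depth: float = 10.0, min_quality: float = 10_000.0,
                max_het: float = 0.90) -> tuple[CountMatrix, pd.DataFrame]:
    """Retain SNPs passing the three read-support filters.

    (i) mean reads per offspring >= ``min_mean_depth`` (equivalently a
    total offspring read count of n * min_mean_depth); (ii) quality score
    >= ``min_quality``; (iii) provisional heterozygosity < ``max_het``,
    where an individual is provisionally heterozygous when both alleles
    have >= 2 reads, out of individuals with >= 2 reads in total.
    """
    off = counts.offspring_idx
    n = n_individuals if n_individuals is not None else len(off)
    if n <= 0:
        raise ValueError("n_individuals must be positive")
    major, minor = counts.major_minor()
    total = (major + minor)[:, off]
    depth_ok = total.sum(axis=1) >= min_mean_depth * n
    qual_ok = counts.quality >= min_quality
    het = (major[:, off] >= 2) & (minor[:, off] >= 2)
    scored = total >= 2
    with np.errstate(invalid="ignore"):
        het_prop = np.where(scored.sum(axis=1) > 0,
                            het.sum(axis=1) / np.maximum(scored.sum(axis=1), 1), 0.0)
    het_ok = het_prop < max_het
    keep = depth_ok & qual_ok & het_ok
    report = pd.DataFrame({
        "snp_id": counts.snp_ids,
        "total_reads": total.sum(axis=1),
        "quality": counts.quality,
        "het_prop": het_prop,
        "pass_depth": depth_ok,
        "pass_quality": qual_ok,
        "pass_het": het_ok,
        "retained": keep,
    })
    return counts.subset(keep), report


@dataclass
class HetLine:
    slope: float
    intercept: float
    n_points: int


def fit_het_line(major: np.ndarray, minor: np.ndarray,
                 seed_frac: tuple = (0.15, 0.85), min_total: int = 4,
                 min_points: int = 5, max_iter: int = 10,
                 tol: float = 1e-6) -> HetLine | None:
    """Errors-in-both-variables line through presumed heterozygotes.

    Works on (sqrt(major), sqrt(minor)); the fit is the principal axis of
    the seed points (orthogonal regression with unit error-variance
    ratio).  The seed set (minor fraction within ``seed_frac``, total >=
    ``min_total``) is refined by classify-and-refit iterations.  Returns
    None when too few heterozygote candidates exist.
    """
    major = np.asarray(major, dtype=float)
    minor = np.asarray(minor, dtype=float)
    total = major + minor
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = np.where(total > 0, minor / np.maximum(total, 1), np.nan)
    seed = (total >= min_total) & (frac >= seed_frac[0]) & (frac <= seed_frac[1])
    if seed.sum() < min_points:
        return None
    x_all, y_all = np.sqrt(major), np.sqrt(minor)

    def orth_fit(mask):
        x, y = x_all[mask], y_all[mask]
        xm, ym = x.mean(), y.mean()
        cov = np.cov(np.vstack([x - xm, y - ym]))
        vals, vecs = np.linalg.eigh(cov)
        v = vecs[:, np.argmax(vals)]
        if abs(v[0]) < 1e-12:
            return HetLine(np.inf, xm, int(mask.sum()))
        slope = v[1] / v[0]
        return HetLine(float(slope), float(ym - slope * xm), int(mask.sum()))

    line = orth_fit(seed)
    for _ in range(max_iter):
        calls = classify_offspring(major, minor, line)
        new_mask = calls == CALL_AB
        if new_mask.sum() < min_points:
            break
        new_line = orth_fit(new_mask)
        if np.isfinite(new_line.slope) and abs(new_line.slope - line.slope) < tol:
            line = new_line
            break
        line = new_line
    return line


def classify_offspring(major: np.ndarray, minor: np.ndarray,
                       line: HetLine) -> np.ndarray:
    """Calls by minimum perpendicular distance on sqrt-count axes.

    Nearest of: horizontal axis (AA, homozygous major), vertical axis
    (BB), inclined heterozygote line (AB).  Individuals with both counts
    <= 1 are missing.  Distance ties go to AB (conservative for linkage).
    """
    major = np.asarray(major, dtype=float)
    minor = np.asarray(minor, dtype=float)
    x, y = np.sqrt(major), np.sqrt(minor)
    d_aa = y
    d_bb = x
    if np.isfinite(line.slope):
        d_ab = np.abs(y - (line.intercept + line.slope * x)) / np.sqrt(1 + line.slope ** 2)
    else:
        d_ab = np.abs(x - line.intercept)
    calls = np.where((d_ab <= d_aa) & (d_ab <= d_bb), CALL_AB,
                     np.where(d_aa < d_bb, CALL_AA, CALL_BB)).astype(np.int8)
    calls[(major <= 1) & (minor <= 1)] = MISSING
    return calls


def class_r2(values: np.ndarray, classes: np.ndarray) -> float:
    """One-way R^2 (percent) of values on class labels, missing excluded."""
    ok = (classes != MISSING) & np.isfinite(values)
    v, c = values[ok], classes[ok]
    if v.size == 0:
        return 0.0
    sst = ((v - v.mean()) ** 2).sum()
    if sst == 0:
        return 0.0
    ssb = 0.0
    for k in np.unique(c):
        grp = v[c == k]
        ssb += grp.size * (grp.mean() - v.mean()) ** 2
    return float(100.0 * ssb / sst)


def assess_classification(calls: np.ndarray, major: np.ndarray,
                          minor: np.ndarray, parent_calls,
                          min_r2: float = 50.0, min_class_frac: float = 0.05,
                          min_offspring: int = 20):
    """Accept or reject a SNP's classification.

    Rejects monomorphic SNPs, fits with R^2 of the major-allele proportion
    on the called class below ``min_r2`` percent, and classifications
    clearly incompatible with the parental calls (e.g. both parents called
    the same homozygote while offspring segregate into disallowed
    classes).  Returns (accepted, r2_percent, reason).
    """
    ok = calls != MISSING
    if ok.sum() < min_offspring:
        return False, 0.0, "too_few_calls"
    total = (major + minor).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        pa = np.where(total > 0, major / np.maximum(total, 1), np.nan)
    present = _present_classes(calls, min_class_frac)
    if len(present) < 2:
        return False, class_r2(pa, calls), "monomorphic"
    r2 = class_r2(pa, calls)
    if r2 < min_r2:
        return False, r2, "low_r2"
    reason = _parent_compatibility(present, parent_calls)
    if reason:
        return False, r2, reason
    return True, r2, ""


def _present_classes(calls, min_frac=0.05):
    ok = calls != MISSING
    n = max(int(ok.sum()), 1)
    out = []
    for k in (CALL_AA, CALL_AB, CALL_BB):
        if (calls == k).sum() >= max(2, min_frac * n):
            out.append(k)
    return out


def _parent_compatibility(present, parent_calls) -> str:
    p1, p2 = parent_calls
    known = [p for p in (p1, p2) if p != MISSING]
    if len(known) < 2:
        return ""  # parent unknown: never force rejection
    pset = sorted(known)
    if pset == [CALL_AA, CALL_AA] and (CALL_AB in present or CALL_BB in present):
        return "incompatible_parents"
    if pset == [CALL_BB, CALL_BB] and (CALL_AB in present or CALL_AA in present):
        return "incompatible_parents"
    return ""


def assign_segregation_type(calls: np.ndarray, parent_calls,
                            min_class_frac: float = 0.05) -> str:
    """JoinMap-style segregation type from offspring classes + parents.

    Two offspring classes with the first (Latham) parent heterozygous give
    ABxAA; with the second parent heterozygous, AAxAB.  Three classes with
    both parents heterozygous give ABxAB; three classes with an apparently
    homozygous parent are flagged for the null-allele module
    ("null_ABxAO" / "null_AOxAB" orientation by the heterozygous parent,
    or "null_AOxBO" when both parents look like different homozygotes).
    """
    present = _present_classes(calls, min_class_frac)
    p1, p2 = parent_calls
    if len(present) == 2 and CALL_AB in present:
        if p1 == CALL_AB and p2 != CALL_AB:
            return "ABxAA"
        if p2 == CALL_AB and p1 != CALL_AB:
            return "AAxAB"
        if p1 == CALL_AB and p2 == CALL_AB:
            return "ABxAB"  # one homozygote class may be undersampled
        return "unknown"
    if len(present) == 3:
        if p1 == CALL_AB and p2 == CALL_AB:
            return "ABxAB"
        if p1 == CALL_AB and p2 in (CALL_AA, CALL_BB):
            return "null_ABxAO"
        if p2 == CALL_AB and p1 in (CALL_AA, CALL_BB):
            return "null_AOxAB"
        if {p1, p2} == {CALL_AA, CALL_BB}:
            return "null_AOxBO"
        return "unknown"
    return "rejected"


def call_snps(counts: CountMatrix, min_r2: float = 50.0) -> pd.DataFrame:
    """Run the full calling path for every SNP in a count matrix.

    Returns a DataFrame with per-SNP type, R^2, acceptance, parental
    calls, and the offspring call matrix in the ``calls`` column (one
    int8 array per row).
    """
    major, minor = counts.major_minor()
    off = counts.offspring_idx
    par = list(counts.parent_idx)
    rows = []
    for k in range(counts.n_snps):
        line = fit_het_line(major[k, off], minor[k, off])
        if line is None:
            rows.append((counts.snp_ids[k], "unclassifiable", 0.0, False,
                         MISSING, MISSING, None))
            continue
        calls = classify_offspring(major[k, off], minor[k, off], line)
        pcalls = classify_offspring(major[k, par], minor[k, par], line)
        accepted, r2, reason = assess_classification(
            calls, major[k, off], minor[k, off], tuple(pcalls), min_r2=min_r2)
        seg = assign_segregation_type(calls, tuple(pcalls)) if accepted else "rejected"
        rows.append((counts.snp_ids[k], seg, r2, accepted,
                     int(pcalls[0]), int(pcalls[1]), calls))
    return pd.DataFrame(rows, columns=[
        "snp_id", "seg_type", "r2", "accepted", "parent1", "parent2", "calls",
    ])
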