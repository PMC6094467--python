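"""Detection and recoding of null-allele segregation patterns.

Two configurations occur in a CP cross when one SNP allele fails to
amplify (a null allele O):

* AB x AO (or AO x AB): one parent heterozygous, the other apparently
  homozygous, with three offspring phenotype classes in a 2:1:1 ratio
  (genotypes AA:AO:AB:BO in 1:1:1:1).  The marker is split into two
  derived markers: "n1", the B allele segregating 1:1, and "n3", the A
  allele segregating 3:1 (dominant, because AA and AO cannot be told
  apart).

* AO x BO: parents look like different homozygotes yet the offspring show
  AA, AB and BB in roughly 1:1:1 (the OO quarter of the offspring is
  called missing).  Confirmed loci are recoded as a four-class AB x CD
  marker ("n4"), imputing OO for offspring whose overall missingness is
  otherwise low (< 10%).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .chromassign import AnchorMap, anova_r2, major_allele_proportion
from .markers import MISSING, PhasedMarker

CALL_AA, CALL_AB, CALL_BB, CALL_OO = 0, 1, 2, 3


def _class_counts(calls):
    return np.array([(calls == c).sum() for c in (CALL_AA, CALL_AB, CALL_BB)],
                    dtype=float)


def detect_abxao(calls: np.ndarray, parent_calls, alpha: float = 0.001):
    """Detect the AB x AO pattern: (detected, null_parent_index).

    Requires three offspring phenotype classes fitting 2:1:1 (the doubled
    class being the homozygous-looking parent's phenotype) and one parent
    called heterozygous while the other is called homozygous.
    """
    p1, p2 = parent_calls
    if {p1, p2} not in ({CALL_AB, CALL_AA}, {CALL_AB, CALL_BB}):
        return False, None
    null_parent = 0 if p1 != CALL_AB else 1
    homo = p1 if p1 != CALL_AB else p2
    counts = _class_counts(calls)
    if (counts == 0).any():
        return False, None
    order = [homo, CALL_AB, CALL_BB if homo == CALL_AA else CALL_AA]
    obs = np.array([counts[c] for c in order])
    expected = np.array([0.5, 0.25, 0.25]) * obs.sum()
    p = stats.chisquare(obs, expected).pvalue
    return bool(p >= alpha), (null_parent if p >= alpha else None)


def split_abxao(marker_name: str, lg, calls: np.ndarray, parent_calls,
                null_parent: int):
    """Derive the n1 (1:1) and n3 (3:1 dominant) markers.

    With the homozygous-looking parent carrying A and O, phenotypes code
    as: B-homozygote = carries the het parent's B allele and no A; AB =
    carries both; A-homozygote = no B.  n1 scores B-presence (AB or
    B-only = carrier), n3 scores A-presence (A-only or AB).

    Returns ((n1 marker, n1 calls), (n3 marker, n3 calls)).
    """
    p1, p2 = parent_calls
    homo = p1 if null_parent == 0 else p2
    b_pheno = CALL_BB if homo == CALL_AA else CALL_AA  # the het-only allele
    a_pheno = homo
    carrier = (calls == CALL_AB) | (calls == b_pheno)
    a_present = (calls == CALL_AB) | (calls == a_pheno)
    missing = calls == MISSING

    n1_calls = np.where(carrier, CALL_AB, CALL_AA).astype(np.int8)
    n1_calls[missing] = MISSING
    if null_parent == 1:  # Latham is the heterozygous parent
        n1 = PhasedMarker(f"n1_{marker_name}", lg, np.nan,
                          ("A", "B"), ("A", "A"), "ABxAA")
    else:
        n1 = PhasedMarker(f"n1_{marker_name}", lg, np.nan,
                          ("A", "A"), ("A", "B"), "AAxAB")

    n3_calls = np.where(a_present, CALL_AA, CALL_BB).astype(np.int8)
    n3_calls[missing] = MISSING
    if null_parent == 1:  # Moy carries A/O, Latham A/B
        n3 = PhasedMarker(f"n3_{marker_name}", lg, np.nan,
                          ("A", "B"), ("A", "O"), "ABxAO", dominant_a=True)
    else:
        n3 = PhasedMarker(f"n3_{marker_name}", lg, np.nan,
                          ("A", "O"), ("A", "B"), "AOxAB", dominant_a=True)
    return (n1, n1_calls), (n3, n3_calls)


def merge_abxao(n1_calls: np.ndarray, n3_calls: np.ndarray,
                parent_calls, null_parent: int) -> np.ndarray:
    """Invert :func:`split_abxao` back to the original phenotypes."""
    p1, p2 = parent_calls
    homo = p1 if null_parent == 0 else p2
    b_pheno = CALL_BB if homo == CALL_AA else CALL_AA
    carrier = n1_calls == CALL_AB
    a_present = n3_calls == CALL_AA
    out = np.full(n1_calls.shape, MISSING, dtype=np.int8)
    out[carrier & a_present] = CALL_AB
    out[carrier & ~a_present] = b_pheno
    out[~carrier & a_present] = homo
    out[(n1_calls == MISSING) | (n3_calls == MISSING)] = MISSING
    return out


def detect_aoxbo(calls: np.ndarray, major: np.ndarray, minor: np.ndarray,
                 parent_calls, anchors: AnchorMap | None,
                 marker_missing_median: float, alpha: float = 0.001,
                 min_r2: float = 25.0) -> bool:
    """Detect the AO x BO pattern.

    Requires (a) three phenotype classes fitting 1:1:1, (b) parents called
    as different homozygotes, (c) when anchors are available, each
    allele's read-count fraction associating (R^2 > 25) with anchors
    heterozygous in a different parent, and (d) marker missingness above
    the marker-set median (the OO quarter shows up as extra missing).
    """
    p1, p2 = parent_calls
    if {p1, p2} != {CALL_AA, CALL_BB}:
        return False
    counts = _class_counts(calls)
    if (counts == 0).any():
        return False
    p = stats.chisquare(counts, np.full(3, counts.sum() / 3.0)).pvalue
    if p < alpha:
        return False
    miss_rate = (calls == MISSING).sum() / max(calls.size, 1)
    if miss_rate <= marker_missing_median:
        return False
    if anchors is not None:
        # each allele's own read counts (sqrt-stabilised): the A count
        # tracks the parent contributing A, the B count the other parent
        ca = np.sqrt(np.asarray(major, dtype=float))
        cb = np.sqrt(np.asarray(minor, dtype=float))
        best_major = _best_r2_by_parent(ca, anchors)
        best_minor = _best_r2_by_parent(cb, anchors)
        ok = ((best_major[0] > min_r2 and best_minor[1] > min_r2)
              or (best_major[1] > min_r2 and best_minor[0] > min_r2))
        if not ok:
            return False
    return True


def _best_r2_by_parent(values: np.ndarray, anchors: AnchorMap):
    """Max anchor R^2 separately for Latham- and Moy-informative anchors.

    The anchor's informative parent must be supplied in ``anchors`` via a
    parallel attribute ``parents`` (0 = Latham, 1 = Moy); anchors without
    one count for both.
    """
    parents = getattr(anchors, "parents", None)
    best = [0.0, 0.0]
    for k in range(len(anchors.names)):
        r2, _ = anova_r2(values, anchors.calls[k])
        if parents is None:
            best[0] = max(best[0], r2)
            best[1] = max(best[1], r2)
        else:
            p = parents[k]
            for side in ((0, 1) if p is None else (p,)):
                best[side] = max(best[side], r2)
    return best


def impute_oo(marker_name: str, lg, calls: np.ndarray,
              offspring_missing_rate: np.ndarray,
              threshold: float = 0.10):
    """Recode a confirmed AO x BO marker as a four-class AB x CD ("n4").

    Offspring missing here but with an overall missing rate below the
    threshold are imputed as OO; others stay missing.  Phenotypes map to
    the four genotype classes AO ("A"), AB, BO ("B"), OO.
    """
    out = calls.copy().astype(np.int8)
    imput = (calls == MISSING) & (np.asarray(offspring_missing_rate) < threshold)
    out[imput] = CALL_OO
    marker = PhasedMarker(f"n4_{marker_name}", lg, np.nan,
                          ("A", "O"), ("B", "O"), "AOxBO", oo_observable=True)
    return marker, out
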