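"""Phased marker representation for an outbred diploid F1 (CP) cross.

Each marker carries the two parental haplotypes: the first parent ("Latham"
in the reference cross) has homologs labelled A and B, the second parent
("Glen Moy") homologs C and D.  An offspring's inheritance state at a locus
is which homolog it received from each parent, giving the four states
AC, AD, BC, BD.  Marker alleles live in {A, B, O} where O is a null allele
that produces no sequencing reads: AO is indistinguishable from AA at the
phenotype level and OO yields no reads at all.

The observable phenotype classes are coded as small integers:

    0 = "A"  (only the major SNP allele visible; AA or AO)
    1 = "AB" (both alleles visible)
    2 = "B"  (only the minor allele visible; BB or BO)
    3 = "OO" (no amplifiable allele; only observable after imputation)
    MISSING = -1

This single representation drives the simulator's truth tables, the
two-point recombination-fraction likelihoods and the inheritance HMM.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

MISSING = -1
PHENOTYPE_LABELS = ("A", "AB", "B", "OO")
N_CLASSES = 4

#: inheritance states in order; u = Latham homolog (0=A, 1=B),
#: v = Moy homolog (0=C, 1=D); state index s = 2*u + v.
STATE_LABELS = ("AC", "AD", "BC", "BD")
STATE_U = np.array([0, 0, 1, 1])
STATE_V = np.array([0, 1, 0, 1])

#: segregation types and the (unordered) parental allele pairs they imply
SEG_TYPES = ("ABxAA", "AAxAB", "ABxAB", "ABxAO", "AOxAB", "AOxBO")


@dataclass(frozen=True)
class PhasedMarker:
    """A marker with phased parental genotypes.

    ``latham`` / ``moy`` give the allele carried by each homolog of the
    respective parent, e.g. ``latham=("A", "B")`` means homolog A of the
    first parent carries the major allele and homolog B the minor allele.
    """

    name: str
    lg: int
    pos: float
    latham: tuple[str, str]
    moy: tuple[str, str]
    seg_type: str
    dominant_a: bool = False  # n3 coding: only A-presence is scored
    oo_observable: bool = False  # n4 coding: OO imputed as a real class

    def genotype(self, state: int) -> tuple[str, str]:
        return (self.latham[STATE_U[state]], self.moy[STATE_V[state]])

    def phenotype_codes(self) -> np.ndarray:
        """Length-4 array: observable class per inheritance state.

        ``MISSING`` marks states whose true phenotype cannot be observed
        (OO genotypes when OO is not an imputed class).
        """
        out = np.empty(4, dtype=np.int8)
        for s in range(4):
            alleles = {a for a in self.genotype(s) if a != "O"}
            if not alleles:
                out[s] = 3 if self.oo_observable else MISSING
            elif alleles == {"A"}:
                out[s] = 0
            elif alleles == {"B"}:
                out[s] = 2
            else:
                out[s] = 1
            if self.dominant_a and out[s] in (0, 1):
                out[s] = 0  # A-presence collapses "A" and "AB"
        return out

    def observable_classes(self) -> np.ndarray:
        """Sorted class codes that can actually occur for this marker."""
        codes = self.phenotype_codes()
        return np.unique(codes[codes != MISSING])

    def informative_for(self) -> tuple[bool, bool]:
        """Whether the phenotype depends on the Latham / Moy homolog."""
        ph = self.phenotype_codes()
        latham = bool(np.any(ph[[0, 1]] != ph[[2, 3]]))
        moy = bool(np.any(ph[[0, 2]] != ph[[1, 3]]))
        return latham, moy

    def flipped(self, flip_latham: bool = False, flip_moy: bool = False) -> "PhasedMarker":
        m = self
        if flip_latham:
            m = replace(m, latham=(m.latham[1], m.latham[0]))
        if flip_moy:
            m = replace(m, moy=(m.moy[1], m.moy[0]))
        return m


def seg_type_alleles(seg_type: str, rng: np.random.Generator) -> tuple[tuple[str, str], tuple[str, str]]:
    """Random phased parental alleles consistent with a segregation type."""
    def perm(a, b):
        return (a, b) if rng.random() < 0.5 else (b, a)

    if seg_type == "ABxAA":
        return perm("A", "B"), ("A", "A")
    if seg_type == "AAxAB":
        return ("A", "A"), perm("A", "B")
    if seg_type == "ABxAB":
        return perm("A", "B"), perm("A", "B")
    if seg_type == "ABxAO":
        return perm("A", "B"), perm("A", "O")
    if seg_type == "AOxAB":
        return perm("A", "O"), perm("A", "B")
    if seg_type == "AOxBO":
        return perm("A", "O"), perm("B", "O")
    raise ValueError(f"unknown segregation type: {seg_type}")


def expected_class_ratio(marker: PhasedMarker) -> dict[int, float]:
    """Expected Mendelian phenotype-class frequencies among observed calls.

    States are equifrequent (1/4 each); states whose phenotype is missing
    (unobservable OO) are excluded and the rest renormalised.
    """
    ph = marker.phenotype_codes()
    obs = ph[ph != MISSING]
    classes, counts = np.unique(obs, return_counts=True)
    total = counts.sum()
    return {int(c): n / total for c, n in zip(classes, counts)}


def emission_matrix(marker: PhasedMarker, error_rate: float) -> np.ndarray:
    """4 x N_CLASSES emission matrix P(observed class | state).

    A state whose implied phenotype matches the observed class has
    probability 1 - eps; the remaining eps is spread uniformly over the
    other observable classes of this marker.  States with an unobservable
    (OO) phenotype emit each observable class with a small leak eps/c so
    that an observed call never has zero likelihood; in practice such
    offspring are recorded missing and emit the all-ones missing vector.
    """
    classes = marker.observable_classes()
    c = len(classes)
    ph = marker.phenotype_codes()
    B = np.zeros((4, N_CLASSES))
    for s in range(4):
        if ph[s] == MISSING:
            B[s, classes] = error_rate / max(c, 1)
            continue
        if c == 1:
            B[s, ph[s]] = 1.0
            continue
        B[s, classes] = error_rate / (c - 1)
        B[s, ph[s]] = 1.0 - error_rate
    return B
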