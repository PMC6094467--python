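"""Synthetic outbred F1 crosses with read-count observations and QTL traits.

The simulator emulates the statistical structure of a genotyping-by-
sequencing experiment on a full-sib family from two outbred parents:
markers of the five CP segregation types (including the two null-allele
configurations), meioses under a genetic map function, overdispersed read
depths with a configurable read-error rate, and quantitative traits driven
by the inheritance state at known QTL positions.  Everything is
deterministic under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .counts import CountMatrix
from .mapfun import get_map_function
from .markers import MISSING, PhasedMarker, seg_type_alleles

TYPE_ORDER = ("ABxAA", "AAxAB", "ABxAB", "ABxAO", "AOxBO")


@dataclass(frozen=True)
class QTLSpec:
    """A single additive QTL: four inheritance-class means plus noise.

    ``class_means`` are the trait means of the AC, AD, BC, BD classes.
    The residual standard deviation can be given directly or implied by
    ``pct_var``, the percentage of trait variance the QTL should explain
    (classes are equifrequent, so the genetic variance is the population
    variance of the four means).
    """

    lg: int
    pos: float
    class_means: tuple
    residual_sd: float | None = None
    pct_var: float | None = None

    def sd(self) -> float:
        if self.residual_sd is not None:
            return float(self.residual_sd)
        if self.pct_var is None:
            raise ValueError("QTLSpec needs residual_sd or pct_var")
        m = np.asarray(self.class_means, dtype=float)
        var_g = m.var()
        if not 0 < self.pct_var < 100:
            raise ValueError("pct_var must be in (0, 100)")
        return float(np.sqrt(var_g * (100.0 - self.pct_var) / self.pct_var))


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for one simulated cross."""

    n_offspring: int = 184
    lg_lengths: tuple = (100.0,)
    markers_per_lg: tuple = (100,)
    #: per-LG fractions over (ABxAA, AAxAB, ABxAB, ABxAO, AOxBO); a single
    #: 5-tuple is broadcast to every linkage group
    type_proportions: tuple = ((0.62, 0.20, 0.18, 0.0, 0.0),)
    mean_depth: float = 30.0
    depth_dispersion: float = 5.0
    error_rate: float = 0.01
    missing_rate: float = 0.02
    parent_depth_factor: float = 2.0
    qtl_specs: tuple = ()
    map_function: str = "haldane"
    seed: int = 0

    def __post_init__(self):
        props = self.type_proportions
        if props and np.isscalar(props[0]):
            props = (tuple(props),)
        if len(props) == 1 and len(self.lg_lengths) > 1:
            props = tuple(props) * len(self.lg_lengths)
        object.__setattr__(self, "type_proportions", props)
        if len(self.markers_per_lg) == 1 and len(self.lg_lengths) > 1:
            object.__setattr__(
                self, "markers_per_lg", tuple(self.markers_per_lg) * len(self.lg_lengths)
            )
        if not (len(self.lg_lengths) == len(self.markers_per_lg) == len(self.type_proportions)):
            raise ValueError("per-LG field lengths disagree")
        for p in self.type_proportions:
            if len(p) != 5:
                raise ValueError("type_proportions rows must have 5 entries")
            if abs(sum(p) - 1.0) > 1e-9:
                raise ValueError("type_proportions must sum to 1")
        if any(l <= 0 for l in self.lg_lengths):
            raise ValueError("linkage-group lengths must be positive")
        if any(m <= 0 for m in self.markers_per_lg):
            raise ValueError("every linkage group needs at least one marker")
        if not 0.0 <= self.error_rate < 0.5:
            raise ValueError("error_rate must be in [0, 0.5)")
        if self.mean_depth <= 0:
            raise ValueError("mean_depth must be positive")
        for q in self.qtl_specs:
            length = self.lg_lengths[q.lg]
            if not 0.0 <= q.pos <= length:
                raise ValueError(f"QTL at {q.pos} cM is off LG{q.lg} (length {length})")

    @property
    def n_lgs(self) -> int:
        return len(self.lg_lengths)

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


def simulate_map(config: SimConfig, rng: np.random.Generator | None = None) -> list:
    """Draw marker positions, segregation types and phases for every LG."""
    rng = rng or config.rng()
    markers: list[PhasedMarker] = []
    idx = 1
    for lg in range(config.n_lgs):
        n = config.markers_per_lg[lg]
        pos = np.sort(rng.uniform(0.0, config.lg_lengths[lg], size=n))
        types = rng.choice(5, size=n, p=np.asarray(config.type_proportions[lg]))
        for k in range(n):
            seg = TYPE_ORDER[types[k]]
            if seg == "ABxAO" and rng.random() < 0.5:
                seg = "AOxAB"  # the null parent can be either one
            latham, moy = seg_type_alleles(seg, rng)
            markers.append(
                PhasedMarker(
                    name=f"s{idx}_lg{lg + 1}",
                    lg=lg,
                    pos=float(pos[k]),
                    latham=latham,
                    moy=moy,
                    seg_type=seg,
                )
            )
            idx += 1
    return markers


@dataclass
class InheritanceTruth:
    """Hidden homolog-origin paths for every offspring and linkage group.

    ``positions[lg]`` is the sorted union of marker and QTL positions on
    that group; ``U[lg]``/``V[lg]`` are (n_offspring, n_positions) binary
    matrices giving which Latham / Moy homolog each offspring carries.
    Paths are piecewise constant between the sampled positions.
    """

    positions: list
    U: list
    V: list
    map_function: str = "haldane"

    @property
    def n_offspring(self) -> int:
        return self.U[0].shape[0]

    def _index(self, lg: int, pos: float) -> int:
        p = self.positions[lg]
        i = int(np.searchsorted(p, pos + 1e-9)) - 1
        return max(i, 0)

    def state_at(self, lg: int, pos: float) -> np.ndarray:
        """Inheritance state (0..3 = AC, AD, BC, BD) per offspring."""
        i = self._index(lg, pos)
        return (2 * self.U[lg][:, i] + self.V[lg][:, i]).astype(np.int8)

    def states(self, lg: int) -> np.ndarray:
        """(n_offspring, n_positions) state matrix for one LG."""
        return (2 * self.U[lg] + self.V[lg]).astype(np.int8)

    def crossover_counts(self, lg: int) -> np.ndarray:
        """Observable homolog switches per offspring on one LG (both parents)."""
        du = np.abs(np.diff(self.U[lg].astype(np.int8), axis=1)).sum(axis=1)
        dv = np.abs(np.diff(self.V[lg].astype(np.int8), axis=1)).sum(axis=1)
        return du + dv


def simulate_meioses(
    positions_by_lg: list,
    n_offspring: int,
    map_function: str = "haldane",
    rng: np.random.Generator | None = None,
) -> InheritanceTruth:
    """Sample homolog-origin paths along each linkage group.

    Between adjacent sampled positions d cM apart, each parent's homolog
    switches independently with probability r(d) given by the inverse of
    the chosen map function (Haldane: r = (1 - exp(-2d/100)) / 2).
    """
    rng = rng or np.random.default_rng()
    _, inv = get_map_function(map_function)
    U, V, P = [], [], []
    for pos in positions_by_lg:
        pos = np.sort(np.asarray(pos, dtype=float))
        if pos.size == 0:
            raise ValueError("linkage group with zero positions")
        r = inv(np.diff(pos))
        paths = []
        for _ in range(2):  # Latham then Moy
            start = rng.integers(0, 2, size=(n_offspring, 1), dtype=np.uint8)
            if pos.size > 1:
                sw = (rng.random((n_offspring, pos.size - 1)) < r).astype(np.uint8)
                path = np.bitwise_xor.accumulate(np.hstack([start, sw]), axis=1)
            else:
                path = start
            paths.append(path)
        P.append(pos)
        U.append(paths[0])
        V.append(paths[1])
    return InheritanceTruth(positions=P, U=U, V=V, map_function=map_function)


def true_calls(markers: list, truth: InheritanceTruth) -> np.ndarray:
    """Error-free phenotype calls implied by the hidden states.

    Returns an (n_markers, n_offspring) int8 matrix of phenotype-class
    codes; unobservable OO genotypes are MISSING.
    """
    out = np.empty((len(markers), truth.n_offspring), dtype=np.int8)
    for k, m in enumerate(markers):
        codes = m.phenotype_codes()
        out[k] = codes[truth.state_at(m.lg, m.pos)]
    return out


def parent_phenotypes(markers: list) -> np.ndarray:
    """(n_markers, 2) phenotype codes of the two parents themselves."""
    out = np.empty((len(markers), 2), dtype=np.int8)
    for k, m in enumerate(markers):
        for j, geno in enumerate((m.latham, m.moy)):
            alleles = {a for a in geno if a != "O"}
            if not alleles:
                out[k, j] = MISSING
            elif alleles == {"A"}:
                out[k, j] = 0
            elif alleles == {"B"}:
                out[k, j] = 2
            else:
                out[k, j] = 1
    return out


def _emit_counts(genotypes, mean_depth, dispersion, error_rate, missing_rate, rng):
    """Read counts for a vector of genotypes (pairs of allele chars)."""
    n = len(genotypes)
    n_amp = np.array([(a != "O") + (b != "O") for a, b in genotypes])
    p_a = np.empty(n)
    for i, (a, b) in enumerate(genotypes):
        vis = {x for x in (a, b) if x != "O"}
        if vis == {"A"}:
            p_a[i] = 1.0 - error_rate
        elif vis == {"B"}:
            p_a[i] = error_rate
        else:  # heterozygote or OO (depth 0, p irrelevant)
            p_a[i] = 0.5
    mu = mean_depth * n_amp / 2.0
    depth = np.zeros(n, dtype=np.int64)
    amp = n_amp > 0
    if amp.any():
        k = dispersion
        depth[amp] = rng.negative_binomial(k, k / (k + mu[amp]), size=amp.sum())
    if missing_rate > 0:
        depth[rng.random(n) < missing_rate] = 0
    ref = rng.binomial(depth, p_a)
    return ref, depth - ref


def emit_observations(
    markers: list,
    truth: InheritanceTruth,
    config: SimConfig,
    rng: np.random.Generator | None = None,
) -> CountMatrix:
    """Overdispersed allele read counts for parents and offspring.

    Read depth is negative-binomial around the configured mean; a null
    allele contributes no reads, so AO genotypes run at half depth and OO
    at zero.  Each read reports the wrong SNP allele with probability
    ``error_rate``.  Parents are sequenced at ``parent_depth_factor`` times
    the offspring depth and appear as the first two sample columns.
    """
    rng = rng or np.random.default_rng()
    n = truth.n_offspring
    M = len(markers)
    ref = np.zeros((M, n + 2), dtype=np.int64)
    alt = np.zeros((M, n + 2), dtype=np.int64)
    for k, m in enumerate(markers):
        pg = [m.latham, m.moy]
        pr, pa = _emit_counts(
            pg, config.mean_depth * config.parent_depth_factor,
            config.depth_dispersion, config.error_rate, 0.0, rng,
        )
        states = truth.state_at(m.lg, m.pos)
        genotypes = [m.genotype(s) for s in states]
        orr, oa = _emit_counts(
            genotypes, config.mean_depth, config.depth_dispersion,
            config.error_rate, config.missing_rate, rng,
        )
        ref[k, :2], alt[k, :2] = pr, pa
        ref[k, 2:], alt[k, 2:] = orr, oa
    total = (ref + alt)[:, 2:].sum(axis=1)
    quality = total * rng.uniform(20.0, 60.0, size=M)
    samples = ["Latham", "GlenMoy"] + [f"off{i + 1:03d}" for i in range(n)]
    return CountMatrix(
        snp_ids=np.array([m.name for m in markers]),
        samples=samples,
        ref=ref,
        alt=alt,
        quality=quality,
        parent_idx=(0, 1),
    )


def simulate_trait(
    truth: InheritanceTruth,
    qtl_specs,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Trait = sum of QTL class means at the true states + Gaussian noise.

    With several QTLs the residual standard deviations combine in
    quadrature.  ``pct_var`` in a spec is interpreted against that QTL's
    own genetic variance.
    """
    rng = rng or np.random.default_rng()
    qtl_specs = list(qtl_specs)
    if not qtl_specs:
        raise ValueError("no QTLs specified")
    y = np.zeros(truth.n_offspring)
    var = 0.0
    for q in qtl_specs:
        means = np.asarray(q.class_means, dtype=float)
        y += means[truth.state_at(q.lg, q.pos)]
        var += q.sd() ** 2
    if var > 0:
        y += rng.normal(0.0, np.sqrt(var), size=y.size)
    return y


def simulate_ripening_profiles(
    truth: InheritanceTruth,
    qtl_specs,
    dates: np.ndarray | None = None,
    n_reps: int = 2,
    base_time: float = 18.0,
    stage_gap: float = 9.0,
    plot_sd: float = 2.0,
    stage_jitter: float = 0.5,
    rng: np.random.Generator | None = None,
):
    """Plot-level 1-7 ripening score profiles with QTL-shifted timing.

    Each genotype has a latent start time shifted by the QTL class means
    (in days); stages 2..7 are reached at evenly spaced intervals after
    it, with plot-level noise on the start and a small per-stage jitter
    (sorted, so scores stay monotone).  The score at a date is one plus
    the number of stages already reached.  Defaults emulate a May-July
    field scoring season with two replicate plots per genotype.
    """
    from .traits import RipeningProfiles

    rng = rng or np.random.default_rng()
    if dates is None:
        dates = np.arange(10.0, 80.0, 7.0)
    dates = np.asarray(dates, dtype=float)
    if np.any(np.diff(dates) <= 0):
        raise ValueError("dates must be increasing")
    n = truth.n_offspring
    shift = np.zeros(n)
    for q in qtl_specs:
        means = np.asarray(q.class_means, dtype=float)
        shift += means[truth.state_at(q.lg, q.pos)]
    scores = np.empty((n * n_reps, dates.size), dtype=np.int8)
    genotype = np.repeat(np.arange(n), n_reps)
    for p, g in enumerate(genotype):
        tau = base_time + shift[g] + rng.normal(0.0, plot_sd)
        reach = tau + stage_gap * np.arange(6)  # stages 2..7
        if stage_jitter > 0:
            reach = np.sort(reach + rng.normal(0.0, stage_jitter, size=6))
        scores[p] = 1 + (reach[None, :] <= dates[:, None]).sum(axis=1)
    return RipeningProfiles(scores=scores, dates=dates, genotype=genotype)


def trait_r2(trait: np.ndarray, states: np.ndarray) -> float:
    """Realised % variance explained by the true inheritance classes."""
    y = np.asarray(trait, dtype=float)
    fit = np.zeros_like(y)
    for s in range(4):
        m = states == s
        if m.any():
            fit[m] = y[m].mean()
    sst = ((y - y.mean()) ** 2).sum()
    if sst == 0:
        return 0.0
    return 100.0 * (1.0 - ((y - fit) ** 2).sum() / sst)


@dataclass
class SimulatedCross:
    """Bundle of everything the downstream stages need, with full truth."""

    config: SimConfig
    markers: list
    truth: InheritanceTruth
    calls: np.ndarray  # offspring phenotype codes, error-free
    parent_calls: np.ndarray
    counts: CountMatrix | None = None
    trait: np.ndarray | None = None

    def markers_on(self, lg: int) -> list:
        return [m for m in self.markers if m.lg == lg]

    def calls_on(self, lg: int) -> np.ndarray:
        mask = np.array([m.lg == lg for m in self.markers])
        return self.calls[mask]

    def anchor_map(self, n_per_lg: int = 12, rng: np.random.Generator | None = None):
        """Evenly spaced subset of markers serving as an anchor linkage map.

        Only markers segregating with >= 2 observable offspring classes are
        eligible (every CP type qualifies).  Returns (markers, calls).
        """
        rng = rng or np.random.default_rng(self.config.seed + 7)
        sel: list[int] = []
        for lg in range(self.config.n_lgs):
            idx = [i for i, m in enumerate(self.markers) if m.lg == lg]
            if len(idx) <= n_per_lg:
                sel.extend(idx)
                continue
            # spread anchors along the group
            targets = np.linspace(0, len(idx) - 1, n_per_lg).round().astype(int)
            sel.extend(idx[t] for t in targets)
        sel = sorted(set(sel))
        return [self.markers[i] for i in sel], self.calls[sel]


def simulate_cross(config: SimConfig, with_counts: bool = True,
                   with_trait: bool | None = None) -> SimulatedCross:
    """Run the full generator: map, meioses, calls, counts and trait."""
    rng = config.rng()
    markers = simulate_map(config, rng)
    positions = []
    for lg in range(config.n_lgs):
        pos = [m.pos for m in markers if m.lg == lg]
        pos += [q.pos for q in config.qtl_specs if q.lg == lg]
        positions.append(np.unique(np.asarray(pos)))
    truth = simulate_meioses(positions, config.n_offspring, config.map_function, rng)
    calls = true_calls(markers, truth)
    pcalls = parent_phenotypes(markers)
    counts = emit_observations(markers, truth, config, rng) if with_counts else None
    if with_trait is None:
        with_trait = bool(config.qtl_specs)
    trait = simulate_trait(truth, config.qtl_specs, rng) if with_trait else None
    return SimulatedCross(
        config=config, markers=markers, truth=truth, calls=calls,
        parent_calls=pcalls, counts=counts, trait=trait,
    )
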