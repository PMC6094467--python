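# Methods

This package implements linkage-map construction and QTL interval mapping
for an outbred diploid F1 ("CP") cross genotyped by sequencing, together
with a simulator that generates crosses with the statistical structure of
the reference raspberry population (Glen Moy x Latham: 184 offspring,
seven linkage groups of roughly 85-130 cM, marker types heavily skewed
toward one parent). All downstream stages are exercised end to end on
synthetic data; nothing requires the unreleased experimental data.

## The cross model

Both parents are outbred, so every marker segregates in a parent-specific
pattern. With Latham homologs labelled A/B and Glen Moy homologs C/D, each
offspring carries one homolog from each parent, giving four inheritance
states AC, AD, BC, BD per locus. Marker alleles live in {A, B, O}, where O
is a null allele that yields no sequencing reads. The observable phenotype
of a genotype is the set of its amplifiable alleles: AO reads like AA, and
OO produces no reads at all (recorded missing). The five segregation types
and their phenotype ratios among offspring are:

| type   | parents     | offspring phenotypes |
|--------|-------------|----------------------|
| ABxAA  | AB x AA     | AA : AB = 1 : 1      |
| AAxAB  | AA x AB     | AA : AB = 1 : 1      |
| ABxAB  | AB x AB     | AA : AB : BB = 1:2:1 |
| ABxAO  | AB x AO     | AA : AB : BB = 2:1:1 |
| AOxBO  | AO x BO     | AA : AB : BB : miss = 1:1:1:1 |

A single dataclass (`PhasedMarker`) carries the phased parental alleles
plus two coding flags (a dominance collapse for the derived "n3" markers,
an observable-OO flag for imputed "n4" markers), and drives the simulator,
the two-point likelihoods and the HMM from one representation.

## Simulator

Meioses are sampled as Markov switch processes along each linkage group:
between adjacent sampled positions d cM apart, each parent's homolog
switches independently with probability r(d) from the map function
(Haldane by default, r = (1 - exp(-2d/100))/2; Kosambi optional). The map
is sex-averaged (one r per interval), matching the reference map. QTL
positions are included in the sampled position set, so trait states are
exact, not interpolated.

Read counts: depth is negative binomial (default mean 30 reads per
offspring, dispersion 5; parents at twice the depth, echoing their deeper
sequencing); each read reports the wrong SNP allele with probability
`error_rate` (default 0.01); null alleles contribute no reads, so AO runs
at half depth and OO at zero; a `missing_rate` (default 0.02) adds
technical dropout. Traits are the QTL class mean at the true state plus
Gaussian noise; the residual SD can be derived from a target percentage
of explained variance (the headline simulations use the ~15%-variance
four-class means of the largest ripening-profile QTL). Ripening profiles
threshold a latent timing process: each genotype's start time is shifted
by its QTL class (in days), stages 2-7 follow at a fixed gap with
plot-level noise, and the 1-7 score at each scoring date counts stages
reached, which makes profiles monotone by construction.

What the generator does not emulate: read mapping artefacts, allele-
specific amplification bias (other than nulls), segregation distortion,
linked QTLs, crossover interference, or environment-by-genotype effects.
Passing tests therefore demonstrate correctness of the algorithms under
the stated statistical model, not robustness to every artefact of real
GbS data.

## Genotype calling

SNPs are filtered on (i) mean offspring depth >= 10 (for n = 184, a total
of >= 1840 reads), (ii) variant quality >= 10,000, (iii) provisional
heterozygosity < 90% (an individual counts as provisionally heterozygous
when both alleles have >= 2 reads). Calling plots (sqrt major, sqrt minor)
counts per individual; the heterozygote line is fitted by orthogonal
(errors-in-both-variables) regression with unit error-variance ratio —
the square root stabilises Poisson-like count variance — seeded from
individuals with minor-allele fraction in [0.15, 0.85] and >= 4 reads,
then refined by classify-and-refit (<= 10 iterations, slope tolerance
1e-6). Individuals are assigned to AA / AB / BB by smallest perpendicular
distance to the horizontal axis, the fitted line, or the vertical axis;
ties go to AB (conservative for linkage); both counts <= 1 is missing.
A SNP is kept only if the one-way regression of major-allele proportion
on the called class explains >= 50% of variance, the classes are not
monomorphic, and they are compatible with the parental calls (both
parents called the same homozygote with segregating offspring is the
clearly-incompatible case; missing parent calls never force rejection).

## Chromosome allocation

The major-allele proportion P_A per individual is tested by one-way ANOVA
against every marker of an anchor map; a SNP joins a linkage group when
R^2 > 25% for exactly one group (ties across groups -> "multi-LG";
nothing above 25% -> unallocated). A floor of 50 joint observations per
anchor guards against spurious R^2 from missingness.

## Null alleles

Three-class SNPs with one heterozygous and one apparently homozygous
parent are tested against 2:1:1 (chi-square, alpha = 0.001) and split
into a 1:1 "n1" allele (presence of the het-parent-only allele) and a
3:1 dominant "n3" allele (A-presence; AA and AO are indistinguishable).
Three-class SNPs with parents called as different homozygotes are tested
against 1:1:1 plus three corroborations: each allele's (sqrt) read counts
associate with a different parent's anchors, and the marker's missingness
exceeds the marker-set median (the OO quarter). Confirmed AOxBO loci are
recoded as four-class ABxCD markers ("n4"), imputing OO for offspring
whose overall missing rate is below 10% and leaving others missing.

## Two-point linkage

For each marker pair the sex-averaged recombination fraction is the MLE
of a two-locus latent-state model: states (4 per locus) are uniform a
priori, the two parental transmissions switch independently with the same
r, and phenotypes are deterministic functions of the phased alleles. EM
over the joint phenotype-class counts (start r = 0.25, |dr| < 1e-6 or
200 iterations, r clipped to [1e-6, 0.4999]) is run for all four relative
phase flips of the second marker, batched across all pairs with an
active-set freeze for converged pairs; the best phase is kept and
LOD = log10 L(r-hat) - log10 L(0.5). Pairs heterozygous in different
single parents are structurally uninformative (LOD 0, r undefined). The
EM matches brute-force grid search (acceptance suite) and reduces to
recombinants/total for coupling 1:1 pairs.

Absolute phases propagate along maximum spanning trees (LOD weights) of
one phase graph per parent. Pairs of parent-symmetric markers (two ABxAB
markers) are excluded from these graphs: under the sex-averaged model
their likelihood cannot distinguish a Latham flip from a Moy flip, so
such markers are phased through single-parent or asymmetric neighbours.

Pre-ordering filters: duplicate call vectors collapse to one
representative; round 1 drops markers with > 40 missing values or
segregation-distortion p < 1e-4 against the type's Mendelian ratio;
round 2 drops only markers with >= 45 missing values.

## Ordering

Two-point r converts to cM (Haldane), LOD or LOD^2 weights, and a
weighted least-squares metric MDS (SMACOF majorisation, classical-scaling
initialisation, 300 iterations or relative stress change < 1e-8) embeds
the group in 2 or 3 dimensions. Outliers — markers whose mean weighted
absolute residual exceeds the median by 3 robust SDs and is at least
twice the median (absolute floor 0.5 cM) — are removed once and the MDS
rerun. A principal curve (first principal component initialisation, 10
iterations of lowess smoothing and polyline re-projection) gives arc-
length positions, rescaled against the two-point distances of pairs
closer than 50 cM (beyond that the map-function inversion saturates and
would shrink the group). Candidate orders from {LOD, LOD^2} x {2d, 3d}
are compared by mean nearest-informative-neighbour fit (NNfit); ties
prefer LOD^2 in 3d. Maps are oriented by rank correlation with anchor
positions when available.

## Map checking with the inheritance HMM

The HMM has the four inheritance states per locus, uniform initial
distribution, transitions that factorise into two independent parental
switches with interval probability r_k, and emissions that match the
state-implied phenotype with probability 1 - eps (eps spread uniformly
over the marker's other observable classes; missing observations emit 1
in every state; unobservable-OO states emit a small leak so no observed
call has zero likelihood). Forward-backward uses scaled linear-domain
recursions; Viterbi runs in log space. Both match exhaustive state-path
enumeration to 1e-10 (acceptance suite).

Viterbi paths give an intervals x offspring recombination matrix split
by parent; HMM_mean is total inferred recombinations per offspring.
Order improvement greedily evaluates every adjacent swap and every
non-trivial triplet permutation by the total Viterbi recombination count,
applies the best reducing move, re-estimates interval distances (from
two-point r via shortest paths through informative pairs, or fixed
position slots), and repeats to a fixed point; exclusions are evaluated
and reported per marker, never auto-applied. Move evaluation uses a tiny
emission error rate (1e-6) by design: with a loose error rate the Viterbi
path can reinterpret a terminal marker's genuine recombinants as
genotyping errors, making wrong orders look spuriously good; with the
strict rate every discrepant call costs recombinations and badly scored
markers surface in the exclusion report instead.

## QTL mapping

Genotype probabilities on a 1 cM grid come from the same HMM with
uninformative pseudo-loci inserted at grid positions. At each position
the trait is regressed on the four class probabilities (means
parameterisation, no intercept; rank-deficient positions are skipped with
LOD 0), giving LOD = (n/2) log10(RSS0/RSS1) against the overall-mean
model and %var = 100 (1 - RSS1/RSS0) (unadjusted). Support intervals are
the maximal contiguous runs within 1 (or 2) LOD of the peak; peak ties
break leftmost. The key parent comes from t-tests (alpha 0.05, n - 4 df)
of the Latham contrast (AC+AD vs BC+BD) and the Moy contrast (AC+BC vs
AD+BD). The genome-wide threshold is the empirical 95th percentile of the
maximum LOD over 200 trait permutations, computed against precomputed
per-position pseudo-inverses so all permutations are a single batched
least-squares pass. The neighbour-window comparator recomputes genotype
probabilities from at most five non-missing markers per side of each grid
position (exact within the window, blind outside it), reproducing the
irregular profiles that full-information methods avoid on parentally
imbalanced maps.

## Traits from ripening profiles

Plot-level 1-7 score profiles are summarised by principal coordinates of
the city-block (L1) distance matrix (double-centred -D^2/2,
eigendecomposition; negative eigenvalues are reported, and only
positive-eigenvalue axes become coordinates). Axes are oriented to
correlate non-negatively with the mean score so that "high PCO1 = slower
development" is reproducible, screened by one-way ANOVA over genotypes at
p < 0.001, and averaged over replicate plots. Times to reach stages 2-6
are interpolated linearly between scoring dates (running-maximum cleanup
for recording slips; stages already reached at the first date get that
date; never-reached stages are missing) and screened at p < 0.05.

## Study scales used by the tests and acceptance script

The QTL simulation study uses single linkage groups with 456 markers
(the density of the reference imbalanced group; the balanced group is
matched) and n = 184 with complete, error-free calls; 20 replicates per
condition. The permutation-threshold surrogate uses a 7-LG genome with
the reference lengths and per-LG type compositions at 80 markers per
group — information saturates well below the real density, and the
threshold is driven by genome length and offspring count. Order-recovery
checks use 100-marker groups (50 replicates) and 30-marker groups for
the swap-repair trials. The end-to-end pipeline demonstration in
`analysis/` runs 50 markers per group so the whole workflow (calling
through QTL scan) completes in about a minute.

## Known limitations

* The sex-averaged single-r model cannot separate male and female
  recombination rates; sex-specific maps are out of scope.
* Adjacent markers heterozygous in different single parents have no
  mutual recombination signature; their local order rests entirely on
  flanking context, and the order-improvement step rightly leaves
  unidentifiable swaps alone.
* Dominant (n3) markers enter the likelihoods with their collapsed
  phenotype, losing the AA/AO distinction by construction.
* The greedy order improvement is a local search; it repairs local
  scrambles but cannot undo large-scale misordering, which is the MDS
  stage's job.
* Map lengths from noisy small samples are biased (two-point r noise
  inflates, distance-cap saturation shrinks); orders are much more
  stable than lengths.
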