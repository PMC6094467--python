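"""Preset cross configurations emulating the reference mapping populations.

The raspberry (Glen Moy x Latham) presets reproduce the statistical shape of
that cross: seven linkage groups of roughly 85-130 cM, 184 offspring, and a
strongly imbalanced mix of marker segregation types dominated by markers
heterozygous only in Latham.  The balanced preset mirrors a blackcurrant map
with similar numbers of markers segregating from each parent, used as the
control condition in the QTL profile-smoothness comparison.
"""

from __future__ import annotations

from .simcross import QTLSpec, SimConfig

#: linkage-group lengths (cM) of the integrated raspberry map
GLEN_MOY_LG_LENGTHS = (114.1, 107.1, 128.2, 91.5, 85.4, 88.6, 100.2)

#: per-LG mapped-marker class fractions over
#: (ABxAA, AAxAB, ABxAB, ABxAO, AOxBO); rows renormalise to 1.
GLEN_MOY_TYPE_PROPORTIONS = (
    (223, 3, 38, 19, 12),     # LG1
    (286, 90, 14, 34, 32),    # LG2
    (447, 45, 13, 39, 13),    # LG3
    (253, 70, 30, 39, 43),    # LG4
    (287, 66, 26, 63, 44),    # LG5
    (284, 15, 2, 9, 5),       # LG6
    (216, 1, 20, 6, 0),       # LG7
)

#: four QTL genotype-class means and trait variance explained for the
#: largest ripening-profile QTL (trait PCO4), used to size simulated QTLs
PCO4_CLASS_MEANS = (-0.01, -0.05, 0.03, 0.03)
PCO4_PCT_VAR = 15.22

#: simulated QTL positions (cM) in the profile-smoothness study
IMBALANCED_QTL_POS = 67.0
BALANCED_QTL_POS = 29.0


def _norm(row):
    t = float(sum(row))
    return tuple(x / t for x in row)


def lg2_like_config(n_markers: int = 456, n_offspring: int = 184,
                    qtl_pct_var: float = PCO4_PCT_VAR, seed: int = 0) -> SimConfig:
    """Single imbalanced linkage group shaped like raspberry LG2.

    62% of markers segregate from Latham only, 20% from Glen Moy only and
    18% from both parents; marker data are complete and error-free, with a
    single additive QTL at 67 cM sized like the PCO4 QTL.
    """
    return SimConfig(
        n_offspring=n_offspring,
        lg_lengths=(107.1,),
        markers_per_lg=(n_markers,),
        type_proportions=((0.62, 0.20, 0.18, 0.0, 0.0),),
        error_rate=0.0,
        missing_rate=0.0,
        qtl_specs=(QTLSpec(lg=0, pos=IMBALANCED_QTL_POS,
                           class_means=PCO4_CLASS_MEANS,
                           pct_var=qtl_pct_var),),
        seed=seed,
    )


def balanced_config(n_markers: int = 456, n_offspring: int = 184,
                    qtl_pct_var: float = PCO4_PCT_VAR, seed: int = 0) -> SimConfig:
    """Single balanced linkage group shaped like a blackcurrant map.

    28% of markers from each single parent and 44% segregating in both;
    single additive QTL at 29 cM with the same size as the imbalanced case.
    The 75 cM length is typical of the blackcurrant GbS linkage groups.
    """
    return SimConfig(
        n_offspring=n_offspring,
        lg_lengths=(75.0,),
        markers_per_lg=(n_markers,),
        type_proportions=((0.28, 0.28, 0.44, 0.0, 0.0),),
        error_rate=0.0,
        missing_rate=0.0,
        qtl_specs=(QTLSpec(lg=0, pos=BALANCED_QTL_POS,
                           class_means=PCO4_CLASS_MEANS,
                           pct_var=qtl_pct_var),),
        seed=seed,
    )


def glen_moy_genome_config(markers_per_lg: int = 80, n_offspring: int = 184,
                           seed: int = 0, **overrides) -> SimConfig:
    """Seven-LG genome emulating the integrated raspberry map."""
    cfg = dict(
        n_offspring=n_offspring,
        lg_lengths=GLEN_MOY_LG_LENGTHS,
        markers_per_lg=(markers_per_lg,) * 7,
        type_proportions=tuple(_norm(r) for r in GLEN_MOY_TYPE_PROPORTIONS),
        seed=seed,
    )
    cfg.update(overrides)
    return SimConfig(**cfg)
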