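"""Simulate the reference cross: 7 linkage groups, 184 offspring, GbS counts.

Generates a synthetic Glen Moy x Latham-like cross (Table-3-like linkage
group lengths and marker-type compositions, 50 markers per group), with a
PCO4-sized QTL on LG2 driving both a quantitative trait and plot-level
ripening score profiles.  Writes the read counts (VCF and TSV), an anchor
map, the full simulation truth and the scoring profiles under
results/simulated/.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from gbsmap import io
from gbsmap.presets import PCO4_CLASS_MEANS, PCO4_PCT_VAR, glen_moy_genome_config
from gbsmap.simcross import QTLSpec, simulate_cross, simulate_ripening_profiles

OUT = Path(__file__).resolve().parents[1] / "results" / "simulated"
SEED = 20060515  # the field season the emulated scorings come from

def main(seed: int = SEED) -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    qtl = QTLSpec(lg=1, pos=88.0, class_means=PCO4_CLASS_MEANS,
                  pct_var=PCO4_PCT_VAR)
    # ripening QTL: the same locus shifts developmental timing by days
    timing_qtl = QTLSpec(lg=1, pos=88.0, class_means=(0.0, 0.0, 3.0, 3.0),
                         residual_sd=0.0)
    config = glen_moy_genome_config(markers_per_lg=50, seed=seed,
                                    qtl_specs=(qtl,))
    sc = simulate_cross(config)
    rng = np.random.default_rng(seed + 1)
    profiles = simulate_ripening_profiles(sc.truth, (timing_qtl,), rng=rng)

    io.write_counts_vcf(sc.counts, OUT / "counts.vcf")
    io.write_counts_tsv(sc.counts, OUT / "counts.tsv")
    io.write_marker_truth(sc.markers, OUT / "markers_truth.tsv")
    io.write_calls_tsv(sc.markers, sc.calls, OUT / "true_calls.tsv")
    amk, acalls = sc.anchor_map(12)
    io.write_calls_tsv(amk, acalls, OUT / "anchor_calls.tsv")
    io.write_marker_truth(amk, OUT / "anchor_markers.tsv")
    pd.DataFrame({
        "plot": np.arange(profiles.scores.shape[0]),
        "genotype": profiles.genotype,
        **{f"day{int(d)}": profiles.scores[:, j]
           for j, d in enumerate(profiles.dates)},
    }).to_csv(OUT / "ripening_scores.tsv", sep="\t", index=False)
    io.PipelineConfig(seed=seed).to_yaml(OUT / "config.yaml")

    n_types = pd.Series([m.seg_type for m in sc.markers]).value_counts()
    print(f"simulated {len(sc.markers)} markers on 7 LGs, "
          f"{config.n_offspring} offspring -> {OUT}")
    print("marker types:", dict(n_types))
    print(f"QTL: LG2 @ 88.0 cM, {PCO4_PCT_VAR}% variance")


if __name__ == "__main__":
    main()
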