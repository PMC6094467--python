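"""QTL interval mapping of the ripening traits on the built maps.

Reads the phased per-LG maps from 02_build_linkage_maps.py and the plot
ripening scores from 01_simulate_cross.py, derives QTL-ready traits
(principal coordinates of the city-block profile distances plus
interpolated stage times), estimates the genome-wide LOD threshold by a
200-permutation test, and scans every trait on every linkage group with
the inheritance HMM.  Writes a Table-4-style QTL summary and per-trait
LOD profiles.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from gbsmap import hmmengine, io, qtlscan
from gbsmap.traits import RipeningProfiles, genotype_trait_table

BASE = Path(__file__).resolve().parents[1] / "results"
SIM = BASE / "simulated"
MAPS = BASE / "maps"
OUT = BASE / "qtl"


def load_lgs(config):
    models, observations, lgs = [], [], []
    for path in sorted(MAPS.glob("phased_lg*.tsv")):
        lg = path.stem.replace("phased_lg", "")
        markers = io.read_phased_markers(path)
        _, _, calls = io.read_calls_tsv(MAPS / f"calls_lg{lg}.tsv")
        models.append(hmmengine.build_model(markers, config.error_rate,
                                            config.map_function))
        observations.append(calls.T)
        lgs.append(lg)
    return lgs, models, observations


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    config = io.PipelineConfig.from_yaml(SIM / "config.yaml")
    scores = pd.read_csv(SIM / "ripening_scores.tsv", sep="\t")
    day_cols = [c for c in scores.columns if c.startswith("day")]
    profiles = RipeningProfiles(
        scores=scores[day_cols].to_numpy(),
        dates=np.array([float(c[3:]) for c in day_cols]),
        genotype=scores["genotype"].to_numpy(),
    )
    traits = genotype_trait_table(profiles)
    print("traits retained for mapping:", list(traits.columns))

    lgs, models, observations = load_lgs(config)
    design = qtlscan.genome_design(models, observations,
                                   step=config.grid_step)
    rows = []
    for name in traits.columns:
        y = traits[name].to_numpy(dtype=float)
        thr = qtlscan.permutation_threshold(design, y,
                                            n_perm=config.n_permutations,
                                            alpha=config.alpha,
                                            seed=config.seed)
        for lg, model, obs in zip(lgs, models, observations):
            grid, probs = qtlscan.genotype_probs(model, obs,
                                                 step=config.grid_step)
            res = qtlscan.scan(probs, y, grid, model=model)
            pd.DataFrame({"cM": grid, "LOD": res.lod}).to_csv(
                OUT / f"profile_{name}_lg{lg}.tsv", sep="\t", index=False)
            if res.peak_lod < thr:
                continue
            p = res.peak_index
            rows.append({
                "LG": lg, "Trait": name, "Pos": res.peak_pos,
                "Mean_AC": round(res.means[p, 0], 3),
                "Mean_AD": round(res.means[p, 1], 3),
                "Mean_BC": round(res.means[p, 2], 3),
                "Mean_BD": round(res.means[p, 3], 3),
                "pct_var": round(res.pct_var[p], 2),
                "LOD": round(res.peak_lod, 2),
                "threshold": round(thr, 2),
                "support_1lod": res.support_1lod,
                "support_2lod": res.support_2lod,
                "Nearest_SNP": res.nearest_marker,
                "Key_parent": res.key_parent,
            })
    qtl = pd.DataFrame(rows)
    qtl.to_csv(OUT / "qtl_table.tsv", sep="\t", index=False)
    if len(qtl):
        print(qtl.to_string(index=False))
    else:
        print("no QTL exceeded the genome-wide threshold")


if __name__ == "__main__":
    main()
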