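"""End-to-end pipeline: filter, allocate, call, recode, map, check, scan.

The stages mirror the reference workflow: read-support filtering,
allocation to linkage groups by anchor-map marker regression, genotype
calling from read counts, null-allele recoding, two-point linkage, MDS
ordering, HMM map checking, and (when traits are supplied) HMM-based QTL
interval mapping with a permutation threshold.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import genocall, hmmengine, mdsorder, nullalleles, qtlscan, twopoint
from .chromassign import AnchorMap, allocate_snps
from .counts import CountMatrix
from .io import PipelineConfig, write_calls_tsv, write_map_tsv
from .markers import MISSING, PhasedMarker

_CANONICAL = {
    "ABxAA": (("A", "B"), ("A", "A")),
    "AAxAB": (("A", "A"), ("A", "B")),
    "ABxAB": (("A", "B"), ("A", "B")),
}


@dataclass
class PipelineResult:
    filter_report: pd.DataFrame
    allocation: pd.DataFrame
    calls_table: pd.DataFrame
    lg_maps: dict
    summary: pd.DataFrame
    scans: dict = field(default_factory=dict)
    threshold: float | None = None


def _build_marker_objects(calls_df: pd.DataFrame, allocation: pd.DataFrame,
                          counts: CountMatrix, config: PipelineConfig):
    """Typed marker objects + call rows per LG, with null recoding."""
    alloc = allocation.set_index("snp_id")
    major, minor = counts.major_minor()
    off = counts.offspring_idx
    snp_row = {sid: k for k, sid in enumerate(counts.snp_ids)}
    # per-offspring overall missing rate over accepted SNPs
    acc = calls_df[calls_df["accepted"]]
    if len(acc):
        stack = np.vstack(list(acc["calls"]))
        off_missing = (stack == MISSING).mean(axis=0)
        marker_missing = (stack == MISSING).mean(axis=1)
        miss_median = float(np.median(marker_missing))
    else:
        off_missing = np.zeros(len(off))
        miss_median = 0.0
    out: dict[object, list] = {}
    for _, row in calls_df.iterrows():
        sid = row["snp_id"]
        if sid not in alloc.index or alloc.loc[sid, "decision"] != "allocated":
            continue
        lg = alloc.loc[sid, "lg"]
        seg = row["seg_type"]
        calls = row["calls"]
        if calls is None:
            continue
        entries = out.setdefault(lg, [])
        if seg in _CANONICAL:
            lat, moy = _CANONICAL[seg]
            marker = PhasedMarker(sid, lg, np.nan, lat, moy, seg)
            # calls in classes impossible for the assigned type are obvious
            # miscalls; mask them so the HMM never sees a zero-probability
            # observation
            ok_classes = marker.observable_classes()
            masked = np.where(np.isin(calls, ok_classes), calls, MISSING)
            entries.append((marker, masked.astype(np.int8)))
        elif seg in ("null_ABxAO", "null_AOxAB"):
            pc = (row["parent1"], row["parent2"])
            det, null_parent = nullalleles.detect_abxao(
                calls, pc, alpha=config.ratio_alpha)
            if det:
                (n1, c1), (n3, c3) = nullalleles.split_abxao(
                    sid, lg, calls, pc, null_parent)
                entries.append((n1, c1))
                entries.append((n3, c3))
        elif seg == "null_AOxBO":
            k = snp_row[sid]
            det = nullalleles.detect_aoxbo(
                calls, major[k, off], minor[k, off],
                (row["parent1"], row["parent2"]), None, miss_median,
                alpha=config.ratio_alpha)
            if det:
                n4, c4 = nullalleles.impute_oo(
                    sid, lg, calls, off_missing, config.oo_impute_threshold)
                entries.append((n4, c4))
    return out


def _map_one_group(markers, calls, config: PipelineConfig,
                   improve: bool = True):
    """Two-point -> phase -> MDS -> HMM greedy improvement for one LG."""
    pre = twopoint.prefilter(markers, calls, round=1,
                             max_missing_round1=config.max_missing_round1,
                             distortion_alpha=config.distortion_alpha)
    keep = np.flatnonzero(pre["retained"].to_numpy())
    markers = [markers[i] for i in keep]
    calls = calls[keep]
    r, lod, pair_df = twopoint.pairwise_matrices(markers, calls)
    # unlinkable markers (outside the main linkage component) cannot be
    # ordered; drop them and re-estimate on the remainder
    comp = mdsorder.largest_connected(lod, min_lod=1.0)
    if len(comp) < len(markers):
        markers = [markers[i] for i in comp]
        calls = calls[comp]
        r, lod, pair_df = twopoint.pairwise_matrices(markers, calls)
    phased, _, unresolved = twopoint.phase_markers(markers, pair_df)
    lg_map, order, nnfits = mdsorder.select_weighting(
        r, lod, markers=phased, map_function=config.map_function)
    ordered = [replace(m, pos=float(p))
               for m, p in zip(lg_map.markers, lg_map.positions)]
    obs = calls[order].T
    model = hmmengine.build_model(ordered, config.error_rate, config.map_function)
    _, R0 = hmmengine.reconstruct_states(model, obs)
    mean_before = hmmengine.hmm_mean(R0)
    if improve:
        # slot mode: markers are permuted through the fixed MDS position
        # slots, so before/after recombination means are directly comparable
        res = hmmengine.improve_order(ordered, obs,
                                      map_function=config.map_function)
        ordered = [replace(m, pos=float(p))
                   for m, p in zip(res["markers"], res["positions"])]
        obs = res["obs"]
        model = hmmengine.build_model(ordered, config.error_rate,
                                      config.map_function)
        _, R1 = hmmengine.reconstruct_states(model, obs)
        mean_after = hmmengine.hmm_mean(R1)
    else:
        mean_after = mean_before
    final = mdsorder.LinkageGroupMap(
        markers=ordered,
        positions=np.array([m.pos for m in ordered]),
        nnfit=lg_map.nnfit, config=lg_map.config, dropped=lg_map.dropped)
    return final, obs, model, mean_before, mean_after, unresolved


def run_pipeline(counts: CountMatrix, anchors: AnchorMap,
                 config: PipelineConfig | None = None,
                 traits: pd.DataFrame | None = None,
                 outdir=None, improve_orders: bool = True) -> PipelineResult:
    """Run every stage on a count matrix and return all artifacts.

    ``traits`` is an offspring-indexed DataFrame of trait values; when
    given, each trait is scanned on every mapped linkage group against the
    genome-wide permutation threshold.
    """
    config = config or PipelineConfig()
    filtered, filt_report = genocall.filter_snps(
        counts, min_mean_depth=config.min_mean_depth,
        min_quality=config.min_quality, max_het=config.max_het)
    major, minor = filtered.major_minor()
    off = filtered.offspring_idx
    allocation = allocate_snps(major[:, off], minor[:, off],
                               filtered.snp_ids, anchors,
                               min_r2=config.min_r2_allocate)
    calls_df = genocall.call_snps(filtered, min_r2=config.min_r2_call)
    groups = _build_marker_objects(calls_df, allocation, filtered, config)

    lg_maps, models, observations = {}, {}, {}
    rows = []
    for lg in sorted(groups):
        markers = [m for m, _ in groups[lg]]
        calls = np.vstack([c for _, c in groups[lg]])
        if len(markers) < 4:
            continue
        lg_map, obs, model, before, after, unresolved = _map_one_group(
            markers, calls, config, improve=improve_orders)
        lg_maps[lg] = lg_map
        models[lg] = model
        observations[lg] = obs
        seg_counts = pd.Series([m.seg_type for m in lg_map.markers]).value_counts()
        rows.append({
            "lg": lg, "n_markers": len(lg_map.markers),
            "length_cM": round(lg_map.length, 1),
            "hmm_mean_mds": round(before, 3),
            "hmm_mean_improved": round(after, 3),
            "nnfit": round(lg_map.nnfit, 3) if lg_map.nnfit else None,
            "n_unresolved_phase": len(unresolved),
            **{f"n_{k}": int(v) for k, v in seg_counts.items()},
        })
    summary = pd.DataFrame(rows)

    result = PipelineResult(filter_report=filt_report, allocation=allocation,
                            calls_table=calls_df, lg_maps=lg_maps,
                            summary=summary)
    if traits is not None and lg_maps:
        order = sorted(lg_maps)
        design = qtlscan.genome_design([models[g] for g in order],
                                       [observations[g] for g in order],
                                       step=config.grid_step)
        for name in traits.columns:
            y = traits[name].to_numpy(dtype=float)
            thr = qtlscan.permutation_threshold(
                design, y, n_perm=config.n_permutations,
                alpha=config.alpha, seed=config.seed)
            scans = {}
            for g in order:
                grid, probs = qtlscan.genotype_probs(
                    models[g], observations[g], step=config.grid_step)
                res = qtlscan.scan(probs, y, grid, model=models[g])
                res.threshold = thr
                scans[g] = res
            result.scans[name] = scans
            result.threshold = thr

    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        filt_report.to_csv(outdir / "filter_report.tsv", sep="\t", index=False)
        allocation.to_csv(outdir / "allocation.tsv", sep="\t", index=False)
        write_map_tsv(lg_maps, outdir / "maps.tsv")
        summary.to_csv(outdir / "summary.tsv", sep="\t", index=False)
        for lg, m in lg_maps.items():
            write_calls_tsv(m.markers, observations[lg].T,
                            outdir / f"calls_lg{lg}.tsv")
    return result
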