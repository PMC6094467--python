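"""File formats: count tables (VCF / TSV), JoinMap locus files, maps,
truth tables and the YAML pipeline configuration."""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .counts import CountMatrix
from .markers import MISSING, PhasedMarker

CALL_LABELS = {0: "AA", 1: "AB", 2: "BB", 3: "OO", MISSING: "--"}
LABEL_CALLS = {v: k for k, v in CALL_LABELS.items()}


# ---------------------------------------------------------------------------
# read counts


def read_counts(path, parents=("Latham", "GlenMoy")) -> CountMatrix:
    """Read a count matrix from a VCF (per-sample AD) or a TSV table."""
    path = Path(path)
    if path.suffix in (".vcf", ".gz", ".bcf"):
        return read_counts_vcf(path, parents)
    return read_counts_tsv(path)


def read_counts_vcf(path, parents=("Latham", "GlenMoy")) -> CountMatrix:
    """Biallelic SNP allele depths from a VCF's AD format field.

    Multi-allelic records are skipped (their number is available as the
    ``skipped_records`` attribute of the returned matrix); records
    without per-sample AD raise.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    ids, refs, alts, quals = [], [], [], []
    skipped = 0
    for var in vcf:
        if len(var.ALT) != 1:
            skipped += 1
            continue
        ad = var.format("AD")
        if ad is None or ad.shape[1] < 2:
            raise ValueError(f"record {var.ID or var.POS} lacks per-sample AD")
        ad = np.where(ad < 0, 0, ad)
        ids.append(var.ID or f"{var.CHROM}_{var.POS}")
        refs.append(ad[:, 0])
        alts.append(ad[:, 1])
        quals.append(var.QUAL if var.QUAL is not None else 0.0)
    pidx = tuple(samples.index(p) for p in parents)
    cm = CountMatrix(
        snp_ids=np.array(ids), samples=samples,
        ref=np.array(refs), alt=np.array(alts),
        quality=np.array(quals), parent_idx=pidx,
    )
    cm.skipped_records = skipped
    return cm


def write_counts_vcf(cm: CountMatrix, path) -> None:
    """Write counts as a minimal VCF with per-sample AD (via pysam)."""
    import pysam

    header = pysam.VariantHeader()
    header.add_line('##contig=<ID=1,length=1000000000>')
    header.add_line('##FORMAT=<ID=AD,Number=R,Type=Integer,'
                    'Description="Allelic depths">')
    header.add_line('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
    for s in cm.samples:
        header.add_sample(s)
    with pysam.VariantFile(str(path), "w", header=header) as out:
        for k in range(cm.n_snps):
            rec = out.new_record(contig="1", start=k, stop=k + 1,
                                 alleles=("A", "C"), id=str(cm.snp_ids[k]))
            rec.qual = float(cm.quality[k])
            for j, s in enumerate(cm.samples):
                rec.samples[s]["AD"] = (int(cm.ref[k, j]), int(cm.alt[k, j]))
            out.write(rec)


def write_counts_tsv(cm: CountMatrix, path) -> None:
    cols = {"snp_id": cm.snp_ids, "quality": cm.quality}
    for j, s in enumerate(cm.samples):
        cols[f"{s}.ref"] = cm.ref[:, j]
        cols[f"{s}.alt"] = cm.alt[:, j]
    df = pd.DataFrame(cols)
    with open(path, "w") as fh:
        fh.write("#parents=" + ",".join(cm.samples[i] for i in cm.parent_idx) + "\n")
        df.to_csv(fh, sep="\t", index=False)


def read_counts_tsv(path) -> CountMatrix:
    with open(path) as fh:
        first = fh.readline().strip()
        parents = first.split("=", 1)[1].split(",") if first.startswith("#parents=") else []
        df = pd.read_csv(fh, sep="\t")
    samples = [c[:-4] for c in df.columns if c.endswith(".ref")]
    ref = np.column_stack([df[f"{s}.ref"] for s in samples])
    alt = np.column_stack([df[f"{s}.alt"] for s in samples])
    pidx = tuple(samples.index(p) for p in parents) if parents else (0, 1)
    return CountMatrix(snp_ids=df["snp_id"].to_numpy(), samples=samples,
                       ref=ref, alt=alt,
                       quality=df["quality"].to_numpy(), parent_idx=pidx)


# ---------------------------------------------------------------------------
# JoinMap CP locus files


def _joinmap_coding(marker: PhasedMarker):
    """(segregation code, call code -> genotype string) for one marker."""
    seg = marker.seg_type
    if marker.oo_observable:  # n4: AO="ad", AB="ac", BO="bc", OO="bd"
        return "<abxcd>", {0: "ad", 1: "ac", 2: "bc", 3: "bd", MISSING: "--"}
    if marker.dominant_a:  # dominant A-presence, 3:1
        return "<hkxhk>", {0: "h-", 2: "kk", MISSING: "--"}
    if seg in ("ABxAA", "n1L"):
        return "<lmxll>", {0: "ll", 1: "lm", MISSING: "--"}
    if seg in ("AAxAB", "n1M"):
        return "<nnxnp>", {0: "nn", 1: "np", MISSING: "--"}
    if seg == "ABxAB":
        return "<hkxhk>", {0: "hh", 1: "hk", 2: "kk", MISSING: "--"}
    raise ValueError(f"marker {marker.name} has no JoinMap coding ({seg})")


def write_joinmap_loc(markers, calls: np.ndarray, path,
                      population: str = "cross") -> None:
    """Write a JoinMap CP-format .loc file for typed, called markers."""
    n = calls.shape[1]
    lines = [f"name = {population}", "popt = CP", f"nloc = {len(markers)}",
             f"nind = {n}", ""]
    for k, m in enumerate(markers):
        code, table = _joinmap_coding(m)
        geno = " ".join(table.get(int(c), "--") for c in calls[k])
        lines.append(f"{m.name} {code} {geno}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_joinmap_loc(path):
    """Read back a CP .loc file; returns (names, seg codes, call matrix)."""
    inverse = {
        "<lmxll>": {"ll": 0, "lm": 1},
        "<nnxnp>": {"nn": 0, "np": 1},
        "<hkxhk>": {"hh": 0, "hk": 1, "kk": 2, "h-": 0},
        "<abxcd>": {"ad": 0, "ac": 1, "bc": 2, "bd": 3},
    }
    names, codes, rows = [], [], []
    for line in Path(path).read_text().splitlines():
        parts = line.split()
        if len(parts) < 3 or not parts[1].startswith("<"):
            continue
        name, code = parts[0], parts[1]
        table = inverse[code]
        rows.append(np.array([table.get(g, MISSING) for g in parts[2:]],
                             dtype=np.int8))
        names.append(name)
        codes.append(code)
    return names, codes, np.vstack(rows)


# ---------------------------------------------------------------------------
# maps and truth tables


def write_map_tsv(lg_maps: dict, path) -> None:
    """Write {lg: LinkageGroupMap} as a (marker, lg, cM, type) table."""
    rows = []
    for lg, m in lg_maps.items():
        for name, pos, mk in zip(m.names, m.positions, m.markers):
            rows.append((name, lg, round(float(pos), 4), mk.seg_type))
    pd.DataFrame(rows, columns=["marker", "lg", "cM", "seg_type"]).to_csv(
        path, sep="\t", index=False)


def write_marker_truth(markers, path) -> None:
    rows = [(m.name, m.lg, round(m.pos, 4), m.seg_type,
             "".join(m.latham), "".join(m.moy)) for m in markers]
    pd.DataFrame(rows, columns=[
        "marker", "lg", "cM", "seg_type", "latham_phase", "moy_phase",
    ]).to_csv(path, sep="\t", index=False)


def write_calls_tsv(markers, calls: np.ndarray, path, sample_names=None) -> None:
    n = calls.shape[1]
    names = sample_names or [f"off{i + 1:03d}" for i in range(n)]
    df = pd.DataFrame(
        [[CALL_LABELS.get(int(c), "--") for c in row] for row in calls],
        columns=names,
    )
    df.insert(0, "marker", [m.name for m in markers])
    df.insert(1, "seg_type", [m.seg_type for m in markers])
    df.to_csv(path, sep="\t", index=False)


def write_phased_markers(markers, path) -> None:
    """Persist ordered, phased markers (enough to rebuild an HMM)."""
    rows = [(m.name, m.lg, round(float(m.pos), 4), m.seg_type,
             "".join(m.latham), "".join(m.moy),
             int(m.dominant_a), int(m.oo_observable)) for m in markers]
    pd.DataFrame(rows, columns=[
        "marker", "lg", "cM", "seg_type", "latham", "moy",
        "dominant_a", "oo_observable",
    ]).to_csv(path, sep="\t", index=False)


def read_phased_markers(path) -> list:
    df = pd.read_csv(path, sep="\t")
    return [
        PhasedMarker(name=r.marker, lg=r.lg, pos=float(r.cM),
                     latham=tuple(str(r.latham)), moy=tuple(str(r.moy)),
                     seg_type=r.seg_type, dominant_a=bool(r.dominant_a),
                     oo_observable=bool(r.oo_observable))
        for r in df.itertuples()
    ]


def read_calls_tsv(path):
    """Inverse of :func:`write_calls_tsv`: (names, seg types, call matrix)."""
    df = pd.read_csv(path, sep="\t")
    names = df["marker"].tolist()
    segs = df["seg_type"].tolist()
    sample_cols = [c for c in df.columns if c not in ("marker", "seg_type")]
    calls = np.array([[LABEL_CALLS.get(v, MISSING) for v in df[c]]
                      for c in sample_cols]).T.astype(np.int8)
    return names, segs, calls


# ---------------------------------------------------------------------------
# pipeline configuration


@dataclass
class PipelineConfig:
    """All pipeline thresholds; defaults are the reference analysis values."""

    min_mean_depth: float = 10.0
    min_quality: float = 10_000.0
    max_het: float = 0.90
    min_r2_allocate: float = 25.0
    min_r2_call: float = 50.0
    max_missing_round1: int = 40
    min_missing_round2: int = 45
    distortion_alpha: float = 1e-4
    ratio_alpha: float = 1e-3
    oo_impute_threshold: float = 0.10
    n_permutations: int = 200
    alpha: float = 0.05
    map_function: str = "haldane"
    error_rate: float = 0.01
    grid_step: float = 1.0
    seed: int = 0

    def __post_init__(self):
        if not 0 < self.oo_impute_threshold < 1:
            raise ValueError("oo_impute_threshold must be in (0, 1)")
        if not 0 <= self.error_rate < 0.5:
            raise ValueError("error_rate must be in [0, 0.5)")
        if self.n_permutations < 20:
            raise ValueError("need at least 20 permutations")

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self)))

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        return cls(**yaml.safe_load(Path(path).read_text()))
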