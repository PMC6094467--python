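"""Read-count container shared by the simulator, IO and genotype calling."""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np


@dataclass
class CountMatrix:
    """Per-SNP x per-sample allele read counts with a per-SNP quality score.

    ``ref``/``alt`` hold the counts of the two SNP alleles as encoded in the
    source file; major/minor status is a population-wide property derived
    from total depth (see :meth:`major_minor`).  Parents are ordinary
    columns flagged by ``parent_idx`` (first parent, second parent).
    """

    snp_ids: np.ndarray
    samples: list
    ref: np.ndarray
    alt: np.ndarray
    quality: np.ndarray
    parent_idx: tuple

    def __post_init__(self):
        self.snp_ids = np.asarray(self.snp_ids)
        self.ref = np.asarray(self.ref, dtype=np.int64)
        self.alt = np.asarray(self.alt, dtype=np.int64)
        self.quality = np.asarray(self.quality, dtype=float)
        if self.ref.shape != self.alt.shape:
            raise ValueError("ref/alt count shapes differ")
        if (self.ref < 0).any() or (self.alt < 0).any():
            raise ValueError("negative read counts")

    @property
    def n_snps(self) -> int:
        return self.ref.shape[0]

    @property
    def n_samples(self) -> int:
        return self.ref.shape[1]

    @property
    def offspring_idx(self) -> np.ndarray:
        mask = np.ones(self.n_samples, dtype=bool)
        for i in self.parent_idx:
            mask[i] = False
        return np.flatnonzero(mask)

    @property
    def n_offspring(self) -> int:
        return self.n_samples - len(self.parent_idx)

    def major_minor(self) -> tuple[np.ndarray, np.ndarray]:
        """Counts oriented so the first array is the population-major allele."""
        flip = self.alt.sum(axis=1) > self.ref.sum(axis=1)
        major = np.where(flip[:, None], self.alt, self.ref)
        minor = np.where(flip[:, None], self.ref, self.alt)
        return major, minor

    def total(self) -> np.ndarray:
        return self.ref + self.alt

    def subset(self, snp_mask) -> "CountMatrix":
        snp_mask = np.asarray(snp_mask)
        return replace(
            self,
            snp_ids=self.snp_ids[snp_mask],
            ref=self.ref[snp_mask],
            alt=self.alt[snp_mask],
            quality=self.quality[snp_mask],
        )
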