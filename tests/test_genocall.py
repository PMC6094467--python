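"""Read-support filters and genotype calling from allele counts."""

import numpy as np
import pytest

from gbsmap.counts import CountMatrix
from gbsmap.genocall import (
    CALL_AA,
    CALL_AB,
    CALL_BB,
    HetLine,
    assess_classification,
    assign_segregation_type,
    call_snps,
    classify_offspring,
    filter_snps,
    fit_het_line,
)
from gbsmap.markers import MISSING
from gbsmap.simcross import SimConfig, simulate_cross


def _matrix(ref, alt, quality):
    ref = np.asarray(ref)
    n = ref.shape[1]
    samples = ["P1", "P2"] + [f"o{i}" for i in range(n - 2)]
    return CountMatrix(
        snp_ids=np.array([f"s{i}" for i in range(ref.shape[0])]),
        samples=samples, ref=ref, alt=np.asarray(alt),
        quality=np.asarray(quality, dtype=float), parent_idx=(0, 1),
    )


class TestFilters:
    def test_depth_rule_boundary(self):
        n = 184
        # row 0: 1839 offspring reads total; row 1: 1840
        ref = np.zeros((2, n + 2), dtype=int)
        ref[0, 2:] = 9
        ref[0, 2] = 1839 - 9 * (n - 1)
        ref[1, 2:] = 10
        cm = _matrix(ref, np.zeros_like(ref), [1e6, 1e6])
        kept, rep = filter_snps(cm, n_individuals=n, max_het=1.1)
        assert rep["retained"].tolist() == [False, True]

    def test_quality_boundary(self):
        ref = np.full((2, 12), 100)
        cm = _matrix(ref, np.zeros_like(ref), [9_999, 10_000])
        kept, rep = filter_snps(cm, n_individuals=10, max_het=1.1)
        assert rep["retained"].tolist() == [False, True]

    def test_het_boundary(self):
        n = 100
        ref = np.full((2, n + 2), 20)
        alt = np.zeros_like(ref)
        alt[0, 2:92] = 20   # 90% of offspring heterozygous
        alt[1, 2:91] = 20   # 89%
        cm = _matrix(ref, alt, [1e6, 1e6])
        kept, rep = filter_snps(cm, n_individuals=n)
        assert rep["retained"].tolist() == [False, True]

    def test_idempotent(self, noisy_cross):
        once, _ = filter_snps(noisy_cross.counts)
        twice, _ = filter_snps(once)
        assert (once.snp_ids == twice.snp_ids).all()

    def test_bad_n_raises(self, noisy_cross):
        with pytest.raises(ValueError):
            filter_snps(noisy_cross.counts, n_individuals=0)


class TestHetLine:
    def test_perfect_diagonal(self):
        counts = np.array([[16, 16], [25, 25], [36, 36], [9, 9], [49, 49]])
        line = fit_het_line(counts[:, 0], counts[:, 1])
        assert line.slope == pytest.approx(1.0, abs=1e-9)
        assert line.intercept == pytest.approx(0.0, abs=1e-9)

    def test_orthogonal_consistency(self, rng):
        # points on y = 0.5 x with perpendicular noise, 500 points
        x = rng.uniform(3, 12, 500)
        y = 0.5 * x
        nrm = np.array([-0.5, 1.0]) / np.sqrt(1.25)
        eps = rng.normal(0, 0.15, 500)
        xs, ys = x + eps * nrm[0], y + eps * nrm[1]
        line = fit_het_line(xs ** 2, np.maximum(ys, 0.05) ** 2,
                            seed_frac=(0.01, 0.99))
        assert abs(line.slope - 0.5) < 0.05

    def test_axis_swap_inverts_slope(self, rng):
        x = rng.uniform(3, 10, 200)
        y = 0.5 * x + rng.normal(0, 0.1, 200)
        a = fit_het_line(x ** 2, y ** 2, seed_frac=(0.01, 0.99))
        b = fit_het_line(y ** 2, x ** 2, seed_frac=(0.01, 0.99))
        assert a.slope * b.slope == pytest.approx(1.0, abs=0.05)

    def test_too_few_candidates(self):
        assert fit_het_line(np.array([40, 50]), np.array([0, 1])) is None


class TestClassify:
    line = HetLine(slope=1.0, intercept=0.0, n_points=50)

    def test_low_depth_missing(self):
        calls = classify_offspring(np.array([1, 0, 1]), np.array([1, 1, 0]),
                                   self.line)
        assert (calls == MISSING).all()

    def test_examples(self):
        calls = classify_offspring(np.array([25, 13, 0]),
                                   np.array([0, 12, 25]), self.line)
        assert calls.tolist() == [CALL_AA, CALL_AB, CALL_BB]

    def test_scaling_invariance(self):
        maj = np.array([30, 2, 16, 40, 25, 3, 18, 22, 28, 4, 14, 19, 21, 15])
        mnr = np.array([0, 28, 15, 1, 0, 30, 17, 0, 1, 25, 13, 20, 19, 16])
        a_line = fit_het_line(maj, mnr)
        b_line = fit_het_line(maj * 4, mnr * 4)
        a = classify_offspring(maj, mnr, a_line)
        b = classify_offspring(maj * 4, mnr * 4, b_line)
        assert (a == b).all()


class TestAssess:
    def _pa_data(self, delta):
        # two classes, values 0 +/- delta and 1 +/- delta: R2 = .25/(.25+d^2)
        k = 30
        calls = np.array([CALL_AA] * (2 * k) + [CALL_AB] * (2 * k),
                         dtype=np.int8)
        pa = np.concatenate([
            np.tile([1.0 - delta, 1.0 + delta], k),
            np.tile([0.5 - delta, 0.5 + delta], k),
        ])
        major = pa * 100.0
        return calls, major, 100.0 - major

    def test_r2_boundary(self):
        for delta, expect in ((0.251, False), (0.249, True)):
            calls, major, minor = self._pa_data(delta)
            ok, r2, reason = assess_classification(
                calls, major, minor, (CALL_AB, CALL_AA))
            assert ok is expect, (delta, r2, reason)

    def test_monomorphic_rejected(self):
        calls = np.full(100, CALL_AA, dtype=np.int8)
        major = np.full(100, 30)
        ok, _, reason = assess_classification(calls, major,
                                              np.zeros(100, dtype=int),
                                              (CALL_AA, CALL_AA))
        assert not ok and reason == "monomorphic"

    def test_perfect_separation(self):
        calls = np.array([CALL_AA] * 30 + [CALL_AB] * 30, dtype=np.int8)
        major = np.array([30] * 30 + [15] * 30)
        minor = np.array([0] * 30 + [15] * 30)
        ok, r2, _ = assess_classification(calls, major, minor,
                                          (CALL_AB, CALL_AA))
        assert ok and r2 == pytest.approx(100.0)

    def test_incompatible_parents(self):
        calls = np.array([CALL_AA] * 50 + [CALL_AB] * 50, dtype=np.int8)
        major = np.array([30] * 50 + [15] * 50)
        minor = np.array([0] * 50 + [15] * 50)
        ok, _, reason = assess_classification(calls, major, minor,
                                              (CALL_AA, CALL_AA))
        assert not ok and reason == "incompatible_parents"


class TestSegregationType:
    def test_abxaa(self):
        calls = np.array([CALL_AA] * 90 + [CALL_AB] * 94, dtype=np.int8)
        assert assign_segregation_type(calls, (CALL_AB, CALL_AA)) == "ABxAA"

    def test_abxab(self):
        calls = np.array([CALL_AA] * 46 + [CALL_AB] * 92 + [CALL_BB] * 46,
                         dtype=np.int8)
        assert assign_segregation_type(calls, (CALL_AB, CALL_AB)) == "ABxAB"

    def test_null_candidate(self):
        calls = np.array([CALL_AA] * 92 + [CALL_AB] * 46 + [CALL_BB] * 46,
                         dtype=np.int8)
        assert assign_segregation_type(calls, (CALL_AB, CALL_AA)) == "null_ABxAO"

    def test_no_pattern_rejected(self):
        calls = np.array([CALL_AA] * 50 + [CALL_BB] * 50, dtype=np.int8)
        assert assign_segregation_type(calls, (CALL_AA, CALL_BB)) == "rejected"


def test_calling_accuracy_against_truth():
    """>= 99% of non-missing calls match truth at depth 30, eps = 0.01."""
    cfg = SimConfig(n_offspring=184, lg_lengths=(80.0,), markers_per_lg=(60,),
                    type_proportions=((0.4, 0.3, 0.3, 0.0, 0.0),),
                    mean_depth=30.0, error_rate=0.01, missing_rate=0.0,
                    seed=17)
    sc = simulate_cross(cfg)
    table = call_snps(sc.counts)
    # align call codes with the simulator's phenotype codes: the simulator
    # emits ref = the A allele, calls code 0 = homozygous population-major
    flip = sc.counts.alt.sum(axis=1) > sc.counts.ref.sum(axis=1)
    agree = total = 0
    for k, row in table.iterrows():
        if row["calls"] is None:
            continue
        called = row["calls"].copy()
        if flip[k]:
            called = np.where(called == CALL_AA, CALL_BB,
                              np.where(called == CALL_BB, CALL_AA, called))
        truth = sc.calls[k]
        ok = (called != MISSING) & (truth != MISSING)
        agree += (called[ok] == truth[ok]).sum()
        total += ok.sum()
    assert total > 0.9 * sc.calls.size
    assert agree / total >= 0.99
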