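"""Simulator: marker generation, meioses, read counts, traits, profiles."""

import numpy as np
import pytest
from scipy import stats

from gbsmap.markers import MISSING, PhasedMarker, expected_class_ratio
from gbsmap.simcross import (
    QTLSpec,
    SimConfig,
    simulate_cross,
    simulate_map,
    simulate_meioses,
    simulate_ripening_profiles,
    simulate_trait,
    trait_r2,
    true_calls,
)


class TestSimulateMap:
    def test_type_proportions_respected(self):
        cfg = SimConfig(markers_per_lg=(5000,), lg_lengths=(100.0,),
                        type_proportions=((0.62, 0.20, 0.18, 0.0, 0.0),),
                        seed=1)
        markers = simulate_map(cfg)
        frac = np.mean([m.seg_type == "ABxAA" for m in markers])
        assert abs(frac - 0.62) < 3 * np.sqrt(0.62 * 0.38 / 5000)

    def test_degenerate_mixture(self):
        cfg = SimConfig(markers_per_lg=(50,), lg_lengths=(80.0,),
                        type_proportions=((1.0, 0, 0, 0, 0),), seed=2)
        assert all(m.seg_type == "ABxAA" for m in simulate_map(cfg))

    def test_deterministic_under_seed(self):
        cfg = SimConfig(markers_per_lg=(40,), lg_lengths=(60.0,), seed=5)
        assert simulate_map(cfg) == simulate_map(cfg)

    def test_zero_markers_rejected(self):
        with pytest.raises(ValueError):
            SimConfig(markers_per_lg=(0,), lg_lengths=(50.0,))

    def test_phases_consistent_with_type(self):
        cfg = SimConfig(markers_per_lg=(300,), lg_lengths=(100.0,),
                        type_proportions=((0.2, 0.2, 0.2, 0.2, 0.2),), seed=3)
        for m in simulate_map(cfg):
            if m.seg_type == "ABxAA":
                assert sorted(m.latham) == ["A", "B"] and m.moy == ("A", "A")
            elif m.seg_type == "AOxBO":
                assert sorted(m.latham) == ["A", "O"]
                assert sorted(m.moy) == ["B", "O"]


class TestMeioses:
    def test_haldane_switch_probability(self):
        # d = 10 cM: r = (1 - exp(-0.2)) / 2 ~ 0.0906
        pos = [np.array([0.0, 10.0])]
        truth = simulate_meioses(pos, 50_000, "haldane",
                                 np.random.default_rng(7))
        r_true = 0.5 * (1 - np.exp(-0.2))
        for path in (truth.U[0], truth.V[0]):
            frac = (path[:, 0] != path[:, 1]).mean()
            assert abs(frac - r_true) < 3 * np.sqrt(r_true * (1 - r_true) / 50_000)

    def test_zero_distance_never_switches(self):
        truth = simulate_meioses([np.array([5.0, 5.0])], 2000, "haldane",
                                 np.random.default_rng(1))
        assert (truth.U[0][:, 0] == truth.U[0][:, 1]).all()

    def test_large_distance_approaches_half(self):
        truth = simulate_meioses([np.array([0.0, 5000.0])], 20_000, "haldane",
                                 np.random.default_rng(1))
        frac = (truth.U[0][:, 0] != truth.U[0][:, 1]).mean()
        assert abs(frac - 0.5) < 0.02

    def test_crossover_rate_matches_length(self):
        # dense sampling: observable switches per meiosis ~ length / 100
        pos = [np.linspace(0, 100, 201)]
        truth = simulate_meioses(pos, 4000, "haldane",
                                 np.random.default_rng(3))
        mean_xo = truth.crossover_counts(0).mean()
        assert abs(mean_xo - 2.0) < 0.1  # two meioses per offspring


class TestObservations:
    def test_error_free_homozygote(self):
        cfg = SimConfig(markers_per_lg=(20,), lg_lengths=(50.0,),
                        type_proportions=((1.0, 0, 0, 0, 0),),
                        error_rate=0.0, missing_rate=0.0, seed=4)
        sc = simulate_cross(cfg)
        major, minor = sc.counts.major_minor()
        off = sc.counts.offspring_idx
        homo = sc.calls == 0
        assert (minor[:, off][homo] == 0).all()

    def test_heterozygote_allele_balance(self):
        cfg = SimConfig(n_offspring=10_000, markers_per_lg=(1,),
                        lg_lengths=(10.0,),
                        type_proportions=((1.0, 0, 0, 0, 0),),
                        mean_depth=30.0, error_rate=0.0, missing_rate=0.0,
                        seed=6)
        sc = simulate_cross(cfg)
        off = sc.counts.offspring_idx
        het = sc.calls[0] == 1
        maj = sc.counts.ref[0, off][het].astype(float)
        tot = sc.counts.total()[0, off][het].astype(float)
        frac = (maj[tot > 0] / tot[tot > 0]).mean()
        assert abs(frac - 0.5) < 3 * 0.5 / np.sqrt(30 * het.sum())

    def test_oo_yields_missing_depth(self):
        cfg = SimConfig(n_offspring=400, markers_per_lg=(5,),
                        lg_lengths=(30.0,),
                        type_proportions=((0, 0, 0, 0, 1.0),),
                        error_rate=0.0, missing_rate=0.0, seed=9)
        sc = simulate_cross(cfg)
        oo = sc.calls == MISSING
        assert oo.any()
        total = sc.counts.total()[:, sc.counts.offspring_idx]
        assert (total[oo] == 0).all()

    @pytest.mark.parametrize("seg,ratio", [
        ("ABxAA", {0: 0.5, 1: 0.5}),
        ("ABxAB", {0: 0.25, 1: 0.5, 2: 0.25}),
        ("ABxAO", {0: 0.5, 1: 0.25, 2: 0.25}),
        ("AOxBO", {0: 1 / 3, 1: 1 / 3, 2: 1 / 3}),
    ])
    def test_segregation_ratios(self, seg, ratio):
        idx = {"ABxAA": 0, "AAxAB": 1, "ABxAB": 2, "ABxAO": 3, "AOxBO": 4}[seg]
        props = [0.0] * 5
        props[idx] = 1.0
        cfg = SimConfig(n_offspring=5000, markers_per_lg=(6,),
                        lg_lengths=(60.0,), type_proportions=(tuple(props),),
                        error_rate=0.0, missing_rate=0.0, seed=10)
        sc = simulate_cross(cfg, with_counts=False)
        for k, m in enumerate(sc.markers):
            calls = sc.calls[k]
            obs = calls[calls != MISSING]
            classes = sorted(ratio)
            counts = np.array([(obs == c).sum() for c in classes])
            expected = np.array([ratio[c] for c in classes]) * counts.sum()
            p = stats.chisquare(counts, expected).pvalue
            assert p > 0.001, (m.seg_type, counts)
            assert expected_class_ratio(m) == pytest.approx(ratio)


class TestTrait:
    def test_zero_noise_gives_four_values(self, clean_lg):
        q = QTLSpec(lg=0, pos=50.0, class_means=(0, 1, 2, 3), residual_sd=0.0)
        y = simulate_trait(clean_lg.truth, [q], np.random.default_rng(1))
        assert set(np.unique(y)) <= {0.0, 1.0, 2.0, 3.0}

    def test_equal_means_pure_noise(self, clean_lg):
        q = QTLSpec(lg=0, pos=50.0, class_means=(1, 1, 1, 1), residual_sd=0.5)
        y = simulate_trait(clean_lg.truth, [q], np.random.default_rng(1))
        st = clean_lg.truth.state_at(0, 50.0)
        assert trait_r2(y, st) < 8.0

    def test_pct_var_realised(self):
        # target ~15% explained variance at n = 184, averaged over replicates
        r2s = []
        for seed in range(12):
            cfg = SimConfig(n_offspring=184, markers_per_lg=(2,),
                            lg_lengths=(50.0,), seed=seed,
                            qtl_specs=(QTLSpec(0, 25.0,
                                               (-0.01, -0.05, 0.03, 0.03),
                                               pct_var=15.0),))
            sc = simulate_cross(cfg, with_counts=False)
            st = sc.truth.state_at(0, 25.0)
            r2s.append(trait_r2(sc.trait, st))
        assert abs(np.mean(r2s) - 15.0) < 4.0

    def test_off_map_qtl_rejected(self):
        with pytest.raises(ValueError):
            SimConfig(markers_per_lg=(5,), lg_lengths=(40.0,),
                      qtl_specs=(QTLSpec(0, 55.0, (0, 0, 0, 1),
                                         residual_sd=0.1),))


class TestRipening:
    def test_scores_monotone(self, clean_lg):
        q = QTLSpec(lg=0, pos=40.0, class_means=(0, 0, 4, 4), residual_sd=0.0)
        prof = simulate_ripening_profiles(clean_lg.truth, [q],
                                          rng=np.random.default_rng(3))
        assert (np.diff(prof.scores, axis=1) >= 0).all()
        assert prof.scores.min() >= 1 and prof.scores.max() <= 7

    def test_no_qtl_no_noise_identical_profiles(self, clean_lg):
        q = QTLSpec(lg=0, pos=40.0, class_means=(0, 0, 0, 0), residual_sd=0.0)
        prof = simulate_ripening_profiles(
            clean_lg.truth, [q], plot_sd=0.0, stage_jitter=0.0,
            rng=np.random.default_rng(3))
        assert (prof.scores == prof.scores[0]).all()

    def test_timing_shift_recovered(self, clean_lg):
        from gbsmap.traits import interpolate_stage_times

        shift = 5.0
        q = QTLSpec(lg=0, pos=40.0, class_means=(0, 0, shift, shift),
                    residual_sd=0.0)
        # daily scoring: interpolation of the step profile snaps to the
        # date grid, so a coarse grid would quantise the shift
        prof = simulate_ripening_profiles(
            clean_lg.truth, [q], plot_sd=0.0, stage_jitter=0.0,
            rng=np.random.default_rng(3), dates=np.arange(5.0, 90.0, 1.0))
        st = interpolate_stage_times(prof)
        states = clean_lg.truth.state_at(0, 40.0)[prof.genotype]
        latham_b = states >= 2
        for col in ("stage3", "stage4"):
            v = st[col].to_numpy()
            diff = np.nanmean(v[latham_b]) - np.nanmean(v[~latham_b])
            assert abs(diff - shift) < 1.0


def test_cross_deterministic_under_seed():
    cfg = SimConfig(markers_per_lg=(15,), lg_lengths=(40.0,), seed=21)
    a = simulate_cross(cfg)
    b = simulate_cross(cfg)
    assert (a.calls == b.calls).all()
    assert (a.counts.ref == b.counts.ref).all()
    assert [m.name for m in a.markers] == [m.name for m in b.markers]
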