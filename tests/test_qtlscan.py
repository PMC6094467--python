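"""QTL interval mapping: scans, thresholds, support intervals, comparator."""

import numpy as np
import pytest

from gbsmap import hmmengine as H
from gbsmap import qtlscan as Q
from gbsmap.mapfun import haldane_r
from gbsmap.markers import MISSING, PhasedMarker
from gbsmap.simcross import QTLSpec, SimConfig, simulate_cross, simulate_trait


@pytest.fixture(scope="module")
def scan_setup(clean_lg):
    model = H.build_model(clean_lg.markers, 0.01)
    obs = clean_lg.calls.T
    grid, probs = Q.genotype_probs(model, obs, step=1.0)
    return clean_lg, model, obs, grid, probs


class TestGenotypeProbs:
    def test_rows_sum_to_one(self, scan_setup):
        _, _, _, _, probs = scan_setup
        assert np.allclose(probs.sum(axis=2), 1.0)

    def test_all_missing_uniform(self, scan_setup):
        _, model, _, _, _ = scan_setup
        obs = np.full((2, model.n_markers), MISSING, dtype=np.int8)
        _, probs = Q.genotype_probs(model, obs, step=10.0)
        assert np.allclose(probs, 0.25)

    def test_informative_marker_point_mass(self):
        markers = [PhasedMarker(f"m{k}", 0, 10.0 * k, ("A", "O"), ("B", "O"),
                                "AOxBO", oo_observable=True)
                   for k in range(3)]
        model = H.build_model(markers, 1e-9)
        codes = markers[0].phenotype_codes()
        obs = codes[np.array([1, 1, 1])][None, :]  # state AD everywhere
        grid, probs = Q.genotype_probs(model, obs, grid=np.array([10.0]))
        assert probs[0, 0, 1] > 1 - 1e-6

    def test_midpoint_closed_form(self):
        # two fully informative markers 20 cM apart, same state at both:
        # per parent P(stay at midpoint) = (1-r)^2 / ((1-r)^2 + r^2)
        markers = [PhasedMarker("a", 0, 0.0, ("A", "O"), ("B", "O"), "AOxBO",
                                oo_observable=True),
                   PhasedMarker("b", 0, 20.0, ("A", "O"), ("B", "O"), "AOxBO",
                                oo_observable=True)]
        model = H.build_model(markers, 1e-12)
        codes = markers[0].phenotype_codes()
        obs = codes[np.array([0, 0])][None, :]  # AC at both ends
        _, probs = Q.genotype_probs(model, obs, grid=np.array([10.0]))
        r = float(haldane_r(10.0))
        stay = (1 - r) ** 2 / ((1 - r) ** 2 + r ** 2)
        expect = np.array([stay * stay, stay * (1 - stay),
                           (1 - stay) * stay, (1 - stay) ** 2])
        assert np.abs(probs[0, 0] - expect).max() < 1e-9


class TestScan:
    def test_pct_var_100_for_deterministic_trait(self, scan_setup):
        clean_lg, model, obs, grid, probs = scan_setup
        qpos = 50.0
        states = clean_lg.truth.state_at(0, qpos)
        trait = (states == 0).astype(float)
        res = Q.scan(probs, trait, grid, model=model)
        assert abs(res.peak_pos - qpos) < 4.0
        assert res.pct_var[res.peak_index] > 90.0

    def test_affine_invariance(self, scan_setup):
        clean_lg, model, obs, grid, probs = scan_setup
        trait = simulate_trait(clean_lg.truth,
                               [QTLSpec(0, 40.0, (0, 0, 1, 1),
                                        residual_sd=1.0)],
                               np.random.default_rng(5))
        a = Q.scan(probs, trait, grid)
        b = Q.scan(probs, 3.0 * trait - 7.0, grid)
        assert np.allclose(a.lod, b.lod, atol=1e-8)
        assert (a.pct_var >= -1e-9).all() and (a.pct_var <= 100 + 1e-9).all()

    def test_needs_30_offspring(self, scan_setup):
        _, _, _, grid, probs = scan_setup
        trait = np.full(probs.shape[0], np.nan)
        trait[:20] = 1.0
        with pytest.raises(ValueError):
            Q.scan(probs, trait, grid)


class TestSupportIntervals:
    def test_flat_profile_whole_group(self):
        grid = np.arange(0.0, 50.0)
        lod = np.ones(50)
        assert Q.support_interval(grid, lod, 0, 1.0) == (0.0, 49.0)

    def test_triangular_profile(self):
        grid = np.arange(0.0, 101.0)
        lod = np.maximum(6 - 0.5 * np.abs(grid - 50.0), 0.0)
        peak = int(np.argmax(lod))
        assert Q.support_interval(grid, lod, peak, 1.0) == (48.0, 52.0)
        lo2, hi2 = Q.support_interval(grid, lod, peak, 2.0)
        assert lo2 <= 48.0 and hi2 >= 52.0

    def test_contains_peak(self):
        grid = np.arange(0.0, 30.0)
        rng = np.random.default_rng(3)
        lod = rng.random(30)
        peak = int(np.argmax(lod))
        lo, hi = Q.support_interval(grid, lod, peak, 1.0)
        assert lo <= grid[peak] <= hi


class TestKeyParent:
    def test_latham(self):
        assert Q.key_parent(np.array([0, 0, 1, 1.0]),
                            np.full(4, 0.05), 184) == "Latham"

    def test_moy(self):
        assert Q.key_parent(np.array([0, 1, 0, 1.0]),
                            np.full(4, 0.05), 184) == "Moy"

    def test_both(self):
        assert Q.key_parent(np.array([0, 1, 1, 2.0]),
                            np.full(4, 0.05), 184) == "Both"

    def test_none_when_flat(self):
        assert Q.key_parent(np.array([0.5, 0.5, 0.5, 0.5]),
                            np.full(4, 0.5), 184) == "none"


class TestPermutationThreshold:
    def test_constant_trait_zero(self, scan_setup):
        _, model, obs, _, _ = scan_setup
        design = Q.genome_design([model], [obs], step=2.0)
        thr = Q.permutation_threshold(design, np.ones(obs.shape[0]),
                                      n_perm=25, seed=1)
        assert thr == 0.0

    def test_deterministic_under_seed(self, scan_setup, rng):
        _, model, obs, _, _ = scan_setup
        design = Q.genome_design([model], [obs], step=2.0)
        y = rng.normal(size=obs.shape[0])
        a = Q.permutation_threshold(design, y, n_perm=30, seed=9)
        b = Q.permutation_threshold(design, y, n_perm=30, seed=9)
        assert a == b

    def test_min_permutations(self, scan_setup):
        _, model, obs, _, _ = scan_setup
        design = Q.genome_design([model], [obs], step=2.0)
        with pytest.raises(ValueError):
            Q.permutation_threshold(design, np.ones(obs.shape[0]), n_perm=5)

    def test_grows_with_genome_size(self):
        cfg = SimConfig(n_offspring=150, lg_lengths=(80.0,) * 4,
                        markers_per_lg=(30,) * 4,
                        type_proportions=((0.4, 0.3, 0.3, 0, 0),),
                        error_rate=0.0, missing_rate=0.0, seed=19)
        sc = simulate_cross(cfg, with_counts=False)
        models = [H.build_model(sc.markers_on(g), 0.01) for g in range(4)]
        obss = [sc.calls_on(g).T for g in range(4)]
        y = np.random.default_rng(0).normal(size=150)
        small = Q.genome_design(models[:1], obss[:1], step=1.0)
        large = Q.genome_design(models, obss, step=1.0)
        t_small = Q.permutation_threshold(small, y, n_perm=100, seed=3)
        t_large = Q.permutation_threshold(large, y, n_perm=100, seed=3)
        assert t_large > t_small


class TestNeighborWindow:
    def test_full_window_equals_hmm(self, clean_lg):
        markers = clean_lg.markers[:12]
        obs = clean_lg.calls[:12].T
        model = H.build_model(markers, 0.01)
        grid = np.linspace(model.positions[0], model.positions[-1], 9)
        _, full = Q.genotype_probs(model, obs, grid=grid)
        _, win = Q.neighbor_window_probs(model, obs, k=12, grid=grid)
        assert np.abs(full - win).max() < 1e-10

    def test_handles_missing_calls(self, clean_lg, rng):
        markers = clean_lg.markers[:12]
        obs = clean_lg.calls[:12].T.copy()
        obs[rng.random(obs.shape) < 0.15] = MISSING
        model = H.build_model(markers, 0.01)
        grid = np.array([20.0, 40.0])
        _, win = Q.neighbor_window_probs(model, obs, k=3, grid=grid)
        assert np.allclose(win.sum(axis=2), 1.0)


def test_profile_roughness_measures_curvature():
    smooth = np.sin(np.linspace(0, 3, 100))
    rough = smooth + np.random.default_rng(1).normal(0, 0.2, 100)
    assert Q.profile_roughness(rough) > Q.profile_roughness(smooth)
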