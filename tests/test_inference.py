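"""Bootstrap null, p-values, FDR and activation calls."""

import numpy as np
import pytest
from scipy.stats import ks_2samp

from timelock import (
    NoiseSpec,
    NullConfig,
    Scenario,
    admissible_cube_centers,
    build_null,
    call_activation,
    cube_edge_from_mm,
    fdr_adjust,
    p_value,
    periodogram_psd,
    resolve_target,
    sample_cube_signal,
    simulate_cohort,
    simulate_run,
)
from timelock.inference import NullDistribution

from conftest import make_run, resting_scenario


def bh_oracle(p):
    """Brute-force BH step-up: q_(i) = min_{j>=i} m*p_(j)/j, capped at 1."""
    p = np.asarray(p, dtype=float)
    m = p.size
    order = np.argsort(p, kind="stable")
    q_sorted = np.empty(m)
    for i in range(m):
        q_sorted[i] = min(
            1.0, min(m * p[order[j]] / (j + 1) for j in range(i, m))
        )
    q = np.empty(m)
    q[order] = q_sorted
    return q


class TestCubeEdge:
    def test_paper_geometry(self):
        assert cube_edge_from_mm(39.0, 3.0) == 13

    def test_non_integer_rejected(self):
        with pytest.raises(ValueError):
            cube_edge_from_mm(40.0, 3.0)


class TestSampleCubeSignal:
    def test_edge_one_returns_voxel_series(self, design, atlas20):
        rng = np.random.default_rng(0)
        data = 100 + rng.normal(size=(20, 20, 20, 145))
        run = make_run(data, design, condition="resting")
        center = (10, 10, 10)
        sig = sample_cube_signal(run, atlas20, center, 1)
        np.testing.assert_array_equal(sig.values, data[10, 10, 10, 5:])

    def test_constant_fixture_gives_constant_signal(self, design, atlas20):
        run = make_run(np.full((20, 20, 20, 145), 100.0), design,
                       condition="resting")
        sig = sample_cube_signal(run, atlas20, (10, 10, 10), 5)
        np.testing.assert_array_equal(sig.values, 100.0)

    def test_matches_triple_loop_oracle(self, design, atlas20):
        rng = np.random.default_rng(1)
        data = 100 + rng.normal(size=(20, 20, 20, 145))
        run = make_run(data, design, condition="resting")
        center, edge = (9, 10, 11), 5
        sig = sample_cube_signal(run, atlas20, center, edge)
        total = np.zeros(140)
        count = 0
        for i in range(center[0] - 2, center[0] + 3):
            for j in range(center[1] - 2, center[1] + 3):
                for k in range(center[2] - 2, center[2] + 3):
                    if atlas20.brain_mask[i, j, k]:
                        total += data[i, j, k, 5:]
                        count += 1
        np.testing.assert_allclose(sig.values, total / count, rtol=1e-12)

    def test_out_of_bounds_rejected(self, design, atlas20):
        run = make_run(np.zeros((20, 20, 20, 145)), design,
                       condition="resting")
        with pytest.raises(ValueError, match="outside"):
            sample_cube_signal(run, atlas20, (1, 10, 10), 5)

    def test_insufficient_mask_coverage_rejected(self, design, atlas20):
        run = make_run(np.zeros((20, 20, 20, 145)), design,
                       condition="resting")
        with pytest.raises(ValueError, match="mask"):
            sample_cube_signal(run, atlas20, (2, 2, 2), 5)


class TestAdmissibleCenters:
    def test_matches_brute_force(self, atlas20):
        edge = 5
        centers = {tuple(c) for c in admissible_cube_centers(atlas20, edge)}
        half = edge // 2
        for i in range(20):
            for j in range(20):
                for k in range(20):
                    in_grid = all(half <= c <= 20 - edge + half
                                  for c in (i, j, k))
                    if not in_grid:
                        ok = False
                    else:
                        cube = atlas20.brain_mask[
                            i - half:i - half + edge,
                            j - half:j - half + edge,
                            k - half:k - half + edge,
                        ]
                        ok = cube.sum() * 2 >= edge**3
                    assert ((i, j, k) in centers) == ok

    def test_edge_larger_than_grid_rejected(self, atlas20):
        with pytest.raises(ValueError):
            admissible_cube_centers(atlas20, 25)


class TestBuildNull:
    def test_constant_resting_data_gives_all_zero_null(self, design, atlas20):
        sc = Scenario((20, 20, 20), design, {}, NoiseSpec(sigma=0.0), seed=0)
        rest = simulate_cohort(sc, atlas20, "resting", 3)
        tgt = resolve_target(design, 140)
        null = build_null(rest, atlas20, tgt,
                          NullConfig(n_boot=100, cube_edge=5, seed=1))
        np.testing.assert_array_equal(null.values, 0.0)

    def test_seed_determinism(self, design, atlas20):
        rest = simulate_cohort(resting_scenario((20, 20, 20), 3), atlas20,
                               "resting", 3)
        tgt = resolve_target(design, 140)
        cfg = NullConfig(n_boot=200, cube_edge=5, seed=5)
        a = build_null(rest, atlas20, tgt, cfg)
        b = build_null(rest, atlas20, tgt, cfg)
        np.testing.assert_array_equal(a.values, b.values)

    def test_replicate_matches_public_path(self, design, atlas20):
        """The bootstrap loop's fast power path agrees with
        sample_cube_signal + periodogram_psd."""
        rest = simulate_cohort(resting_scenario((20, 20, 20), 3), atlas20,
                               "resting", 3)
        tgt = resolve_target(design, 140)
        null = build_null(rest, atlas20, tgt,
                          NullConfig(n_boot=100, cube_edge=5, seed=5))
        for b in (0, 57, 99):
            acc = 0.0
            for s, run in enumerate(rest):
                sig = sample_cube_signal(run, atlas20, null.centers[b, s], 5)
                acc += periodogram_psd(sig, design.tr).psd[tgt.bin_index]
            assert null.values[b] == pytest.approx(acc / len(rest),
                                                   rel=1e-12)

    def test_matches_independent_sampler(self, design, atlas20):
        """Null values are distributed like an independently coded
        cube-resampling sampler (two-sample KS)."""
        rest = simulate_cohort(resting_scenario((20, 20, 20), 13), atlas20,
                               "resting", 4)
        tgt = resolve_target(design, 140)
        null = build_null(rest, atlas20, tgt,
                          NullConfig(n_boot=600, cube_edge=5, seed=21))

        # independent re-implementation: own rng, explicit loops
        edge, half = 5, 2
        rng = np.random.default_rng(987654)
        centers = []
        for i in range(20):
            for j in range(20):
                for k in range(20):
                    if not all(half <= c <= 20 - edge + half
                               for c in (i, j, k)):
                        continue
                    cube_mask = atlas20.brain_mask[i - half:i + 3,
                                                   j - half:j + 3,
                                                   k - half:k + 3]
                    if cube_mask.sum() * 2 >= edge**3:
                        centers.append((i, j, k))
        other = []
        for _ in range(600):
            acc = 0.0
            for run in rest:
                ci, cj, ck = centers[rng.integers(len(centers))]
                cube = run.data[ci - half:ci + 3, cj - half:cj + 3,
                                ck - half:ck + 3]
                m = atlas20.brain_mask[ci - half:ci + 3, cj - half:cj + 3,
                                       ck - half:ck + 3]
                x = cube[m].mean(axis=0)[5:]
                acc += periodogram_psd(x, design.tr).psd[tgt.bin_index]
            other.append(acc / len(rest))
        assert ks_2samp(null.values, np.array(other)).pvalue > 0.01

    def test_no_resting_runs_rejected(self, design, atlas20):
        tgt = resolve_target(design, 140)
        with pytest.raises(ValueError):
            build_null([], atlas20, tgt, NullConfig(n_boot=100, cube_edge=5))


class TestPValue:
    def test_observed_below_all_null(self):
        null = np.linspace(1, 2, 1000)
        assert p_value(0.5, null) == 1.0

    def test_observed_above_all_null(self):
        null = np.linspace(0, 1, 10_000)
        assert p_value(2.0, null) == pytest.approx(1 / 10_001)

    def test_observed_at_median(self):
        null = np.arange(1, 1002, dtype=float)  # odd B = 1001
        med = np.median(null)
        p = p_value(med, null)
        assert p == pytest.approx((1 + 501) / 1002)

    def test_monotone_in_observed_power(self):
        rng = np.random.default_rng(3)
        null = rng.exponential(size=500)
        obs = np.sort(rng.uniform(0, 3, size=50))
        ps = [p_value(o, null) for o in obs]
        assert all(p1 >= p2 for p1, p2 in zip(ps, ps[1:]))

    def test_nonfinite_rejected(self):
        with pytest.raises(ValueError):
            p_value(np.nan, np.ones(100))


class TestFdrAdjust:
    def test_hand_computed_example(self):
        q = fdr_adjust([0.001, 0.02, 0.4])
        np.testing.assert_allclose(q, [0.003, 0.03, 0.4], rtol=1e-12)
        assert (q < 0.01).tolist() == [True, False, False]

    def test_identical_p_values_unchanged(self):
        np.testing.assert_allclose(fdr_adjust([0.2] * 7), 0.2, rtol=1e-12)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_brute_force_definition(self, seed):
        p = np.random.default_rng(seed).uniform(0.001, 1.0, size=23)
        np.testing.assert_allclose(fdr_adjust(p), bh_oracle(p), rtol=1e-12)

    def test_rejections_nested_across_levels(self):
        p = np.random.default_rng(7).uniform(1e-4, 1.0, size=60)
        q = fdr_adjust(p)
        strict = set(np.flatnonzero(q < 0.01))
        loose = set(np.flatnonzero(q < 0.05))
        assert strict <= loose

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            fdr_adjust([])
        with pytest.raises(ValueError):
            fdr_adjust([0.0, 0.5])


class TestCallActivation:
    def _null_dist(self, design, values):
        tgt = resolve_target(design, 140)
        cfg = NullConfig(n_boot=len(values), cube_edge=5, seed=0)
        return NullDistribution(values=np.asarray(values, float),
                                config=cfg, target=tgt), cfg

    def test_single_region_median_power(self, design):
        null, cfg = self._null_dist(design, np.arange(1, 200, dtype=float))
        obs = float(np.median(null.values))
        results = call_activation({("r1", "GM"): obs}, null, cfg)
        assert len(results) == 1
        assert results[0].q_value == results[0].p_value
        assert not results[0].significant

    def test_family_is_pooled_gm_and_wm(self, design):
        null, cfg = self._null_dist(design,
                                    np.linspace(0, 1, 1000))
        powers = {("a", "GM"): 5.0, ("b", "WM"): 5.0, ("c", "GM"): 0.2}
        results = call_activation(powers, null, cfg)
        by_id = {r.region_id: r for r in results}
        p_sorted = sorted(r.p_value for r in results)
        # q of the best two = m * p / rank with m = 3 pooled regions
        assert by_id["a"].q_value == pytest.approx(3 * p_sorted[0] / 2)
        assert by_id["a"].significant and by_id["b"].significant
        assert not by_id["c"].significant

    def test_empty_regions_rejected(self, design):
        null, cfg = self._null_dist(design, np.ones(100))
        with pytest.raises(ValueError):
            call_activation({}, null, cfg)


class TestCalibration:
    def test_p_values_superuniform_under_null(self, design):
        """Resting data analyzed against an independently built null gives
        empirical CDF(alpha) <= alpha + 3*sqrt(alpha(1-alpha)/R)."""
        from timelock import make_atlas_fixture

        atlas = make_atlas_fixture((20, 20, 20), 8, 2, seed=3)
        tgt = resolve_target(design, 140)
        rest_null = simulate_cohort(resting_scenario((20, 20, 20), 101),
                                    atlas, "resting", 6)
        null = build_null(rest_null, atlas, tgt,
                          NullConfig(n_boot=1000, cube_edge=5, seed=55))

        rest_obs = simulate_cohort(resting_scenario((20, 20, 20), 202),
                                   atlas, "resting", 6)
        centers = admissible_cube_centers(atlas, 5)
        rng = np.random.default_rng(77)
        picks = centers[rng.choice(len(centers), size=200, replace=False)]
        ps = []
        for c in picks:
            powers = [
                periodogram_psd(sample_cube_signal(r, atlas, c, 5),
                                design.tr).psd[tgt.bin_index]
                for r in rest_obs
            ]
            ps.append(p_value(float(np.mean(powers)), null))
        ps = np.array(ps)
        for alpha in (0.01, 0.05, 0.1, 0.25):
            bound = alpha + 3 * np.sqrt(alpha * (1 - alpha) / ps.size)
            assert np.mean(ps <= alpha) <= bound
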