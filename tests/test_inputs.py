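"""Grid/LEC input generators, remapping, and cue corruption."""

import math

import numpy as np
import pytest
from scipy.spatial.distance import cdist

from hippocirc.inputs import (
    DEFAULT_MODULES,
    KAPPA_DEFAULT,
    GridCell,
    build_population,
    calibrate_kappa,
    grid_coverage,
    grid_rate,
    make_cue,
    make_cue_set,
    random_pattern_set,
    remap,
    sample_locations,
)
from hippocirc.metrics import cross_correlations, pearson
from hippocirc.topology import RegionSpec


def single_cell(spacing=0.5, orientation=0.0, phase=(0.0, 0.0), kappa=0.3,
                seed=0, arena=1.0):
    c = GridCell(module_id=1, spacing=spacing, orientation_deg=orientation,
                 phase=np.array(phase, dtype=float), radius=kappa * spacing)
    c.build_fields(arena, np.random.default_rng(seed))
    return c


class TestGridRate:
    def test_peak_at_field_center(self):
        c = single_cell()
        center = c.base_centers[0]
        assert grid_rate(c, center) == pytest.approx(c.peak_rates[0], rel=1e-12)

    def test_border_value_is_one_fifth_of_peak(self):
        c = single_cell()
        # step exactly one radius away from a central field, in a direction
        # that stays closest to that field
        idx = int(np.argmin(np.linalg.norm(c.base_centers - 0.5, axis=1)))
        center = c.base_centers[idx]
        loc = center + np.array([c.radius, 0.0])
        d = cdist([loc], c.base_centers).ravel()
        assert d.argmin() == idx  # the intended field is still the nearest
        assert grid_rate(c, loc) == pytest.approx(0.2 * c.peak_rates[idx], rel=1e-9)

    def test_two_radii_value(self):
        # small fields so 2 radii is still well inside the nearest field's cell
        c = single_cell(kappa=0.1)
        idx = int(np.argmin(np.linalg.norm(c.base_centers - 0.5, axis=1)))
        center = c.base_centers[idx]
        loc = center + np.array([0.0, 2 * c.radius])
        d = cdist([loc], c.base_centers).ravel()
        assert d.argmin() == idx
        expected = math.exp(-4 * math.log(5)) * c.peak_rates[idx]
        assert grid_rate(c, loc) == pytest.approx(expected, rel=1e-9)

    def test_hexagonal_lattice_six_nearest_neighbors(self):
        c = single_cell(spacing=0.4, orientation=17.0)
        center_idx = int(np.argmin(np.linalg.norm(c.base_centers - 0.5, axis=1)))
        d = np.linalg.norm(c.base_centers - c.base_centers[center_idx], axis=1)
        d = np.sort(d)
        assert d[0] == 0.0
        assert np.allclose(d[1:7], 0.4, atol=1e-9)
        assert d[7] > 0.4 + 1e-6

    def test_batch_matches_scalar(self, rng):
        c = single_cell(seed=3)
        locs = rng.uniform(0, 1, size=(5, 2))
        batch = grid_rate(c, locs)
        for i in range(5):
            assert batch[i] == pytest.approx(grid_rate(c, locs[i]))


class TestRandomPatterns:
    def test_active_counts_and_determinism(self):
        region = RegionSpec("EC", 200, 0.35)
        ps1 = random_pattern_set(region, 10, np.random.default_rng(11))
        ps2 = random_pattern_set(region, 10, np.random.default_rng(11))
        assert np.allclose(ps1.rates, ps2.rates)
        assert np.all((ps1.rates > 0).sum(axis=1) == region.k_winners)

    def test_patterns_nearly_uncorrelated(self):
        region = RegionSpec("EC", 1100, 0.35)
        ps = random_pattern_set(region, 30, np.random.default_rng(5))
        c = cross_correlations(ps.rates, ps.rates)
        off = c[~np.eye(30, dtype=bool)]
        assert abs(off.mean()) < 0.05

    def test_invalid_count(self):
        with pytest.raises(ValueError):
            random_pattern_set(RegionSpec("EC", 10, 0.5), 0,
                               np.random.default_rng(0))


class TestPopulation:
    def test_module_proportions_and_parameter_spread(self):
        m = build_population(100, 0, np.random.default_rng(2))
        table = m.parameter_table()
        counts = table.groupby("module").size()
        assert list(counts[[1, 2, 3, 4]]) == [40, 30, 20, 10]
        for mod in DEFAULT_MODULES:
            sub = table[table.module == mod.module_id]
            assert abs(sub.spacing.mean() - mod.mean_spacing) < 0.05
            assert abs(sub.orientation.mean() - mod.mean_orientation) < 2.0
            assert np.allclose(sub.radius, KAPPA_DEFAULT * sub.spacing)

    def test_lec_cells_counted(self):
        m = build_population(10, 7, np.random.default_rng(0))
        assert m.n_cells == 17
        assert (m.parameter_table().kind == "lec").sum() == 7

    def test_empty_population_rejected(self):
        with pytest.raises(ValueError):
            build_population(0, 0, np.random.default_rng(0))


class TestSampleLocations:
    def test_lattice_geometry(self):
        locs = sample_locations(1.0, 400)
        assert locs.shape == (400, 2)
        xs = np.unique(locs[:, 0])
        assert xs.size == 20
        assert np.allclose(np.diff(xs), 0.05)
        assert xs[0] == pytest.approx(0.025)

    def test_uniform_mode(self):
        locs = sample_locations(2.0, 33, mode="uniform",
                                rng=np.random.default_rng(1))
        assert locs.shape == (33, 2)
        assert locs.min() >= 0.0 and locs.max() <= 2.0

    def test_non_square_lattice_rejected(self):
        with pytest.raises(ValueError):
            sample_locations(1.0, 401)


@pytest.fixture(scope="module")
def ec_model():
    return build_population(100, 10, np.random.default_rng(9))


class TestECPatterns:
    def test_joint_kwta_counts(self, ec_model):
        region = RegionSpec("EC", ec_model.n_cells, 0.35)
        locs = sample_locations(1.0, 25)
        ps = ec_model.pattern_set_at(locs, region)
        assert np.all((ps.rates > 0).sum(axis=1) == region.k_winners)

    def test_nearby_more_correlated_than_far(self, ec_model):
        region = RegionSpec("EC", ec_model.n_cells, 0.35)
        locs = np.array([[0.30, 0.30], [0.32, 0.30], [0.80, 0.80]])
        ps = ec_model.pattern_set_at(locs, region)
        near = pearson(ps.rates[0], ps.rates[1])
        far = pearson(ps.rates[0], ps.rates[2])
        assert near > far

    def test_determinism_of_rate_matrix(self, ec_model):
        locs = sample_locations(1.0, 16)
        a = ec_model.rate_matrix(locs)
        b = ec_model.rate_matrix(locs)
        assert np.array_equal(a, b)


@pytest.fixture(scope="module")
def remap_model():
    m = build_population(60, 12, np.random.default_rng(21))
    remap(m, 1, np.random.default_rng(22))
    return m


class TestRemap:
    def test_spacing_preserved(self, remap_model):
        env = remap_model.environments[1]
        arena = remap_model.arena
        for c in remap_model.grid_cells[:5]:
            centers = c.centers_in(env, arena)
            d = cdist(centers, centers)
            np.fill_diagonal(d, np.inf)
            assert np.min(d) == pytest.approx(c.spacing, rel=1e-9)

    def test_same_module_cells_keep_relative_phase(self, remap_model):
        cells = [c for c in remap_model.grid_cells if c.module_id == 1][:2]
        a, b = cells
        env0, env1 = remap_model.environments[0], remap_model.environments[1]

        def offset(env):
            ca = a.centers_in(env, remap_model.arena)
            cb = b.centers_in(env, remap_model.arena)
            d = cdist(ca[:1], cb)
            return float(d.min())

        # the nearest-field offset between two co-module cells is invariant
        # under the shared rigid transform
        assert offset(env1) == pytest.approx(offset(env0), abs=1e-9)

    def test_lec_maps_fresh(self, remap_model):
        locs = sample_locations(1.0, 100)
        region = RegionSpec("EC", remap_model.n_cells, 0.35)
        r0 = remap_model.rate_matrix(locs, 0)[len(remap_model.grid_cells):]
        r1 = remap_model.rate_matrix(locs, 1)[len(remap_model.grid_cells):]
        cors = [pearson(r0[i], r1[i]) for i in range(r0.shape[0])]
        assert abs(np.mean(cors)) < 0.3

    def test_rotation_range(self, remap_model):
        env = remap_model.environments[1]
        for rot in env.rotations.values():
            assert 0.0 <= rot < 60.0


@pytest.fixture(scope="module")
def cue_pattern():
    region = RegionSpec("EC", 500, 0.35)
    return random_pattern_set(region, 1, np.random.default_rng(4)).pattern(0)


class TestCues:
    def test_zero_wrong_is_exact_copy(self, cue_pattern):
        cue, spec = make_cue(cue_pattern, 0, np.random.default_rng(0))
        assert np.array_equal(cue.rates, cue_pattern.rates)
        assert spec.quality == 1.0

    def test_quality_decreases_with_corruption(self, cue_pattern):
        rng = np.random.default_rng(8)
        qualities = []
        for n_wrong in [0, 100, 250, 450]:
            qs = [make_cue(cue_pattern, n_wrong, rng)[1].quality for _ in range(20)]
            qualities.append(np.mean(qs))
        assert all(a > b for a, b in zip(qualities, qualities[1:]))

    def test_donor_is_never_the_cell_itself(self, cue_pattern):
        # corrupting every cell with itself would leave the cue_pattern intact;
        # with self-donation excluded a full corruption must change something
        rng = np.random.default_rng(3)
        for _ in range(10):
            cue, _ = make_cue(cue_pattern, cue_pattern.n_cells, rng)
            assert not np.array_equal(cue.rates, cue_pattern.rates)

    def test_donor_rates_come_from_original(self, cue_pattern):
        cue, _ = make_cue(cue_pattern, 200, np.random.default_rng(5))
        assert set(np.unique(cue.rates)) <= set(np.unique(cue_pattern.rates))

    def test_cue_set_shapes(self):
        region = RegionSpec("EC", 120, 0.3)
        ps = random_pattern_set(region, 6, np.random.default_rng(2))
        cues, q = make_cue_set(ps, 30, np.random.default_rng(3))
        assert cues.shape == (6, 120)
        assert q.shape == (6,)
        assert np.all(q < 1.0) and np.all(q > -1.0)

    def test_out_of_range(self, cue_pattern):
        with pytest.raises(ValueError):
            make_cue(cue_pattern, cue_pattern.n_cells + 1, np.random.default_rng(0))


class TestCoverageCalibration:
    def test_default_kappa_hits_target_coverage(self):
        locs = sample_locations(1.0, 400)
        covs = [grid_coverage(build_population(150, 0, np.random.default_rng(s)),
                              locs)
                for s in (101, 202, 303)]
        assert np.mean(covs) == pytest.approx(0.35, abs=0.02)

    def test_calibration_recovers_a_known_kappa(self):
        # measure coverage at some kappa, then calibrate to that coverage
        locs = sample_locations(1.0, 400)
        m = build_population(200, 0, np.random.default_rng(77), kappa=0.3)
        target = grid_coverage(m, locs)
        k = calibrate_kappa(np.random.default_rng(77), target=target, n_grid=100)
        m2 = build_population(200, 0, np.random.default_rng(123), kappa=k)
        assert grid_coverage(m2, locs) == pytest.approx(target, abs=0.03)
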