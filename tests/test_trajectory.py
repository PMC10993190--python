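import numpy as np
import pytest

from respmoco import trajectory as tj


@pytest.fixture(scope="module")
def grid():
    return tj.GridSpec(200, 60)


class TestShutter:
    def test_dc_inside(self):
        g = tj.GridSpec(8, 8)
        assert tj.make_shutter(g)[g.center]

    def test_area_ratio_converges_to_quarter_pi(self):
        mask = tj.make_shutter(tj.GridSpec(200, 200))
        ratio = mask.mean()
        assert abs(ratio - np.pi / 4) < 0.005 * np.pi / 4
        # brute-force oracle: direct point-in-ellipse count
        cy = cz = 100
        count = sum(
            ((ky - cy) / 100) ** 2 + ((kz - cz) / 100) ** 2 <= 1
            for ky in range(200)
            for kz in range(0, 200, 7)
        )
        sub = mask[:, ::7].sum()
        assert count == sub

    def test_mirror_symmetry(self):
        g = tj.GridSpec(64, 32)
        m = tj.make_shutter(g)
        # reflection about the DC index maps the lattice onto itself except
        # for the unpaired first row/column
        assert np.array_equal(m[1:, 1:], m[1:, 1:][::-1, ::-1])

    def test_grid_too_small(self):
        with pytest.raises(ValueError):
            tj.GridSpec(4, 64)


class TestGenerate:
    def test_full_sampling_covers_shutter(self, grid):
        t = tj.generate_caspr(grid, 1.0, n_heartbeats=48, rng_seed=0)
        assert t.unique_locations().shape[0] == tj.make_shutter(grid).sum()

    @pytest.mark.parametrize("accel", [3, 4, 7])
    def test_unique_count_matches_budget(self, grid, accel):
        t = tj.generate_caspr(grid, accel, n_heartbeats=48, rng_seed=1)
        budget = round(int(tj.make_shutter(grid).sum()) / accel)
        assert abs(t.unique_locations().shape[0] - budget) <= 48

    def test_deterministic_under_seed(self, grid):
        a = tj.generate_caspr(grid, 7, n_heartbeats=48, rng_seed=5)
        b = tj.generate_caspr(grid, 7, n_heartbeats=48, rng_seed=5)
        assert np.array_equal(a.readouts, b.readouts)
        assert np.array_equal(a.heartbeat, b.heartbeat)

    def test_center_fully_covered(self, grid):
        t = tj.generate_caspr(grid, 7, n_heartbeats=48, rng_seed=2, r_center=0.1)
        r = tj.elliptical_radius(grid)
        need = np.argwhere(tj.make_shutter(grid) & (r <= 0.1))
        got = {tuple(p) for p in t.unique_locations().tolist()}
        assert all(tuple(p) in got for p in need.tolist())

    def test_readouts_valid(self, grid):
        t = tj.generate_caspr(grid, 4, n_heartbeats=48, rng_seed=3)
        t.validate()  # inside shutter, no intra-beat duplicates

    def test_center_disc_exceeding_budget_fails(self):
        with pytest.raises(ValueError):
            tj.generate_caspr(tj.GridSpec(64, 64), 60.0, n_heartbeats=8, r_center=0.5)


class TestEffectiveAccel:
    @pytest.mark.parametrize("nominal,expected", [(3, 3.8), (4, 5.1), (7, 8.9)])
    def test_printed_factors(self, grid, nominal, expected):
        t = tj.generate_caspr(grid, nominal, n_heartbeats=48, rng_seed=nominal)
        assert round(tj.effective_accel_rectangular(t), 1) == expected

    def test_full_elliptical_sampling_is_four_over_pi(self, grid):
        t = tj.full_trajectory(grid)
        assert abs(tj.effective_accel_rectangular(t) - 4 / np.pi) < 0.01


class TestAnnulusProfile:
    def test_fully_sampled_fractions_are_one(self, grid):
        t = tj.full_trajectory(grid)
        p = tj.measure_annulus_profile(t, 20)
        assert p.n_annuli == 20
        assert np.allclose(p.acquired_fraction[~np.isnan(p.acquired_fraction)], 1.0)

    def test_matches_brute_force(self, grid):
        t = tj.generate_caspr(grid, 4, n_heartbeats=48, rng_seed=7)
        n_annuli = 20
        p = tj.measure_annulus_profile(t, n_annuli)
        # independent double loop over the grid
        cy, cz = grid.center
        shutter_counts = np.zeros(n_annuli)
        acq_counts = np.zeros(n_annuli)
        acquired = {tuple(q) for q in t.unique_locations().tolist()}
        for ky in range(grid.n_ky):
            for kz in range(grid.n_kz):
                r = np.hypot((ky - cy) / 100.0, (kz - cz) / 30.0)
                if r > 1:
                    continue
                a = min(int(r * n_annuli), n_annuli - 1)
                shutter_counts[a] += 1
                if (ky, kz) in acquired:
                    acq_counts[a] += 1
        np.testing.assert_array_equal(shutter_counts, p.shutter_counts)
        np.testing.assert_allclose(
            acq_counts / np.maximum(shutter_counts, 1),
            np.nan_to_num(p.acquired_fraction),
        )

    def test_rejects_single_annulus(self, grid):
        with pytest.raises(ValueError):
            tj.measure_annulus_profile(tj.full_trajectory(grid), 1)


@pytest.fixture(scope="module")
def source():
    return tj.generate_caspr(tj.GridSpec(200, 60), 4, n_heartbeats=48, rng_seed=11)


@pytest.fixture(scope="module")
def target():
    t7 = tj.generate_caspr(tj.GridSpec(200, 60), 7, n_heartbeats=48, rng_seed=12)
    return tj.measure_annulus_profile(t7, 20)


class TestRetrospectiveUndersampling:
    def test_identity_when_target_equals_source(self, source):
        p = tj.measure_annulus_profile(source, 20)
        out = tj.retrospective_undersample(source, p, rng_seed=0)
        assert np.array_equal(np.sort(out.readouts, axis=0), np.sort(source.readouts, axis=0))

    def test_strict_subset_with_heartbeats(self, source, target):
        out = tj.retrospective_undersample(source, target, rng_seed=1)
        src = {tuple(r) for r in np.c_[source.readouts, source.heartbeat].tolist()}
        assert out.n_readouts < source.n_readouts
        assert all(tuple(r) in src for r in np.c_[out.readouts, out.heartbeat].tolist())

    def test_per_annulus_fraction_within_one_readout(self, source, target):
        out = tj.retrospective_undersample(source, target, rng_seed=2)
        m = tj.measure_annulus_profile(out, 20)
        err = np.abs(m.acquired_fraction - target.acquired_fraction) * m.shutter_counts
        assert np.nanmax(err) <= 1.0

    def test_subset_effective_accel(self, source, target):
        out = tj.retrospective_undersample(source, target, rng_seed=3)
        eff = tj.effective_accel_rectangular(out)
        assert abs(eff - 7 * 4 / np.pi) / (7 * 4 / np.pi) < 0.02

    def test_infeasible_target_names_annulus(self, source):
        p = tj.measure_annulus_profile(source, 20)
        bad = tj.AnnulusProfile(
            p.boundaries, np.minimum(p.acquired_fraction * 2.0, 1.0), p.shutter_counts
        )
        with pytest.raises(ValueError, match="annulus"):
            tj.retrospective_undersample(source, bad, rng_seed=0)

    def test_deterministic(self, source, target):
        a = tj.retrospective_undersample(source, target, rng_seed=9)
        b = tj.retrospective_undersample(source, target, rng_seed=9)
        assert np.array_equal(a.readouts, b.readouts)
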