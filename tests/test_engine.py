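import numpy as np
import pytest

from voxdose.engine import (
    DoseBatch,
    EngineScene,
    batch_uncertainty,
    merge_batches,
    run_batch,
    run_batches,
    spawn_batch_seeds,
    transport_electron,
    transport_photon,
)
from voxdose.lu177 import DecayData, EmissionLine, build_spectrum
from voxdose.materials import klein_nishina_total, pe_mass_water
from voxdose.phantom import OrganMask, make_source_image

from conftest import water_block

KEV_TO_J = 1.602176634e-16


def local_deposit_nuclide(energy_kev=5.0):
    """Electron line below the transport cut: pure local deposition."""
    return DecayData(spectrum=None, lines=(
        EmissionLine("auger", energy_kev, 1.0),
    ))


def monoenergetic_electron(energy_kev=300.0):
    return DecayData(spectrum=None, lines=(
        EmissionLine("conversion_electron", energy_kev, 1.0),
    ))


def center_mm(phantom):
    return tuple((n - 1) * phantom.voxel_size_mm / 2.0 for n in phantom.shape)


class TestTransportElectron:
    def test_full_absorption_deep_in_water(self, block_phantom, block_scene):
        dep = transport_electron(300.0, center_mm(block_phantom), (1, 0, 0),
                                 block_phantom, scene=block_scene)
        assert dep == pytest.approx(300.0, rel=1e-9)

    def test_escape_near_edge(self, block_phantom, block_scene):
        pos = (0.0, center_mm(block_phantom)[1], center_mm(block_phantom)[2])
        dep = transport_electron(300.0, pos, (-1, 0, 0), block_phantom,
                                 scene=block_scene)
        assert 0.0 < dep < 300.0

    def test_deposit_grid_accumulates(self, block_phantom, block_scene):
        grid = np.zeros(block_phantom.shape)
        dep = transport_electron(100.0, center_mm(block_phantom), (0, 0, 1),
                                 block_phantom, deposit=grid, scene=block_scene)
        assert grid.sum() == pytest.approx(dep, rel=1e-12)

    def test_fine_step_oracle_absorbed_fraction(self):
        # absorbed fraction of the full electron spectrum in a 0.54 cm^3
        # sphere: half-voxel steps vs a 10x finer-step oracle, within 2%
        from voxdose.pipeline import sphere_block_phantom

        ph, lab = sphere_block_phantom(0.54, 0.4, margin_mm=3.0)
        data = build_spectrum()
        electrons_only = DecayData(spectrum=data.spectrum, lines=data.beta_branches)
        act = make_source_image(ph, lab)
        mask = OrganMask.from_labels(ph, lab)
        fractions = {}
        for tag, frac in (("coarse", 0.5), ("fine", 0.05)):
            scene = EngineScene(ph, decay_data=electrons_only, step_fraction=frac,
                                step_cap_mm=None)
            b = run_batch(ph, act, 150_000, 11, scene=scene)
            flat = b.dose.reshape(-1)[mask.flat_indices]
            mass_kg = ph.voxel_volume_cm3 * 1e-3  # unit density
            fractions[tag] = float((flat * mass_kg).sum())
        assert fractions["coarse"] == pytest.approx(fractions["fine"], rel=0.02)


class TestTransportPhoton:
    def test_all_air_grid_deposits_nothing(self):
        from voxdose.phantom import (OrganDef, PhantomConfig, ResolutionSpec,
                                     Sphere, build_phantom)

        cfg = PhantomConfig(
            resolution=ResolutionSpec(shape=(20, 20, 20), voxel_size_mm=1.0),
            body=OrganDef("body", "air", Sphere((9.5, 9.5, 9.5), 40.0),
                          organ_class="body"),
        )
        ph = build_phantom(cfg)
        dep = transport_photon(208.0, center_mm(ph), (0, 0, 1), ph, seed=3)
        assert dep == pytest.approx(0.0, abs=1e-9)

    def test_attenuation_matches_closed_form(self, block_phantom, block_scene):
        # fraction of 208 keV photons traversing depth d without interaction
        h_cm = block_phantom.voxel_size_mm / 10.0
        n = block_phantom.shape[2]
        start = (center_mm(block_phantom)[0], center_mm(block_phantom)[1], 0.0)
        depth_cm = n * h_cm
        mu = 1.0 * (pe_mass_water(208.0) + klein_nishina_total(208.0) * 1e-24
                    * 3.3428e23)
        p_expect = float(np.exp(-mu * depth_cm))
        n_try = 4000
        survived = 0
        for i in range(n_try):
            dep = transport_photon(208.0, start, (0, 0, 1), block_phantom,
                                   seed=i, scene=block_scene)
            survived += dep == 0.0
        p_hat = survived / n_try
        sigma = np.sqrt(p_expect * (1 - p_expect) / n_try)
        assert abs(p_hat - p_expect) < 3 * sigma + 1e-9

    def test_large_grid_limits_to_full_absorption(self):
        # mean deposited fraction grows toward 1 as the water grid grows
        fractions = []
        for n, voxel in ((30, 5.0), (60, 5.0), (60, 8.0)):  # 15/30/48 cm cubes
            ph = water_block(n=n, voxel_mm=voxel)
            scene = EngineScene(ph)
            c = center_mm(ph)
            total = sum(
                transport_photon(208.0, c, (0, 0, 1), ph, seed=i, scene=scene)
                for i in range(400)
            )
            fractions.append(total / (400 * 208.0))
        assert fractions[0] < fractions[1] < fractions[2]
        assert fractions[2] > 0.6

    def test_kahn_sampler_matches_klein_nishina_oracle(self):
        import numba
        import voxdose._kernels as k
        from voxdose.materials import klein_nishina_mean_scatter_fraction

        @numba.njit
        def mean_scatter(seed, n, e):
            np.random.seed(seed)
            tot = 0.0
            for _ in range(n):
                es, _ct = k._kahn_scatter(e)
                tot += es
            return tot / n

        for e in (112.95, 208.37):
            oracle = klein_nishina_mean_scatter_fraction(e) * e
            got = mean_scatter(3, 40_000, e)
            assert got == pytest.approx(oracle, rel=0.01)


class TestRunBatch:
    def test_local_deposit_dose_definition(self, block_phantom, block_scene):
        data = local_deposit_nuclide(5.0)
        scene = EngineScene(block_phantom, decay_data=data)
        act = make_source_image(block_phantom, 1)
        # restrict source to a single voxel
        one = np.zeros_like(act.grid)
        idx = tuple(s // 2 for s in block_phantom.shape)
        one[idx] = 1.0
        from voxdose.phantom import ActivityImage

        act1 = ActivityImage(grid=one, source_label=1)
        b = run_batch(block_phantom, act1, 1, seed=5, scene=scene)
        mass_kg = block_phantom.voxel_volume_cm3 * 1e-3
        want = 5.0 * KEV_TO_J / mass_kg
        assert b.dose[idx] == pytest.approx(want, rel=1e-12)
        assert np.count_nonzero(b.dose) == 1

    def test_n_primaries_recorded(self, block_phantom):
        data = local_deposit_nuclide()
        scene = EngineScene(block_phantom, decay_data=data)
        act = make_source_image(block_phantom, 1)
        b = run_batch(block_phantom, act, 37, seed=0, scene=scene)
        assert b.n_primaries == 37

    def test_unnormalized_activity_rejected(self, block_phantom, block_scene):
        from voxdose.phantom import ActivityImage

        with pytest.raises(ValueError):
            ActivityImage(grid=np.ones(block_phantom.shape), source_label=1)

    def test_seed_determinism_bit_identical(self, block_phantom):
        scene = EngineScene(block_phantom)
        act = make_source_image(block_phantom, 1)
        a = run_batch(block_phantom, act, 3000, seed=9, scene=scene)
        b = run_batch(block_phantom, act, 3000, seed=9, scene=scene)
        assert np.array_equal(a.dose, b.dose)
        assert np.array_equal(a.dose_sq, b.dose_sq)

    def test_energy_conservation_electron_only_contained(self, block_phantom):
        # monoenergetic electron source in a fully containing block:
        # deposited equals emitted within 0.1% (here: to float precision)
        data = monoenergetic_electron(300.0)
        scene = EngineScene(block_phantom, decay_data=data)
        # source confined to the central voxel so every range is contained
        from voxdose.phantom import ActivityImage

        one = np.zeros(block_phantom.shape)
        one[tuple(s // 2 for s in block_phantom.shape)] = 1.0
        act = ActivityImage(grid=one, source_label=1)
        n = 5000
        b = run_batch(block_phantom, act, n, seed=21, scene=scene)
        mass_kg = block_phantom.density_grid() * block_phantom.voxel_volume_cm3 * 1e-3
        deposited = float((b.dose * mass_kg).sum() / KEV_TO_J)
        emitted = n * 300.0
        assert deposited <= emitted * (1 + 1e-9)
        assert deposited == pytest.approx(emitted, rel=1e-3)


class TestMergeAndUncertainty:
    def _fake(self, arr, n=10, seed=0):
        arr = np.asarray(arr, dtype=float)
        return DoseBatch(dose=arr, dose_sq=arr**2, n_primaries=n, seed=seed)

    def test_single_batch_identity(self):
        b = self._fake(np.random.default_rng(0).random((3, 3, 3)))
        m = merge_batches([b])
        assert np.array_equal(m.dose, b.dose)

    def test_two_identical_batches(self):
        g = np.random.default_rng(1).random((3, 3, 3))
        m = merge_batches([self._fake(g), self._fake(g)])
        assert np.allclose(m.dose, g)

    def test_paper_scale_totals(self):
        batches = [self._fake(np.ones((2, 2, 2)), n=125_000_000) for _ in range(40)]
        m = merge_batches(batches)
        assert m.n_primaries == 5_000_000_000
        assert m.n_batches == 40

    def test_shape_mismatch_raises(self):
        with pytest.raises(ValueError):
            merge_batches([self._fake(np.ones((2, 2, 2))),
                           self._fake(np.ones((3, 3, 3)))])

    def test_identical_batches_zero_delta(self):
        g = np.random.default_rng(2).random((3, 3, 3))
        u = batch_uncertainty([self._fake(g), self._fake(g)])
        assert np.allclose(u.delta, 0.0)

    def test_two_value_sample_variance_oracle(self):
        a = self._fake(np.full((1, 1, 1), 1.0))
        b = self._fake(np.full((1, 1, 1), 3.0))
        u = batch_uncertainty([a, b])
        # direct oracle: delta = sqrt((1/(N-1)) (sum D^2/N - (sum D/N)^2))
        assert u.delta[0, 0, 0] == pytest.approx(1.0)

    def test_rel_is_ratio(self):
        a = self._fake(np.full((1, 1, 1), 0.8))
        b = self._fake(np.full((1, 1, 1), 1.2))
        u = batch_uncertainty([a, b])
        assert u.rel[0, 0, 0] == pytest.approx(u.delta[0, 0, 0] / 1.0)

    def test_rel_nan_where_zero_dose(self):
        z = self._fake(np.zeros((2, 2, 2)))
        u = batch_uncertainty([z, z])
        assert np.all(np.isnan(u.rel))

    def test_single_batch_uncertainty_raises(self):
        with pytest.raises(ValueError):
            batch_uncertainty([self._fake(np.ones((2, 2, 2)))])

    def test_brute_force_formula_equivalence(self, rng):
        batches = [self._fake(rng.random((4, 4, 4))) for _ in range(6)]
        u = batch_uncertainty(batches)
        stack = np.stack([b.dose for b in batches])
        n = len(batches)
        oracle = np.sqrt(
            (np.sum(stack**2, axis=0) / n - (np.sum(stack, axis=0) / n) ** 2)
            / (n - 1)
        )
        assert np.allclose(u.delta, oracle, rtol=1e-12, atol=1e-15)


class TestBatchOrchestration:
    def test_merge_order_independence(self, block_phantom):
        scene = EngineScene(block_phantom)
        act = make_source_image(block_phantom, 1)
        batches = run_batches(block_phantom, act, 4000, 4, master_seed=17,
                              scene=scene)
        m1 = merge_batches(batches)
        m2 = merge_batches(batches[::-1])
        assert np.array_equal(m1.dose, m2.dose)

    def test_spawned_seeds_deterministic(self):
        assert spawn_batch_seeds(5, 4) == spawn_batch_seeds(5, 4)
        assert spawn_batch_seeds(5, 4) != spawn_batch_seeds(6, 4)

    def test_inverse_sqrt_n_scaling(self):
        # median relative uncertainty in the source halves at 4x primaries
        from voxdose.pipeline import sphere_block_phantom

        ph, lab = sphere_block_phantom(0.2, 0.625, margin_mm=2.0)
        scene = EngineScene(ph)
        act = make_source_image(ph, lab)
        mask = OrganMask.from_labels(ph, lab)

        def median_eps(n):
            batches = run_batches(ph, act, n, 8, master_seed=99, scene=scene)
            u = batch_uncertainty(batches)
            m = merge_batches(batches)
            rel = u.rel.reshape(-1)[mask.flat_indices]
            return float(np.nanmedian(rel))

        ratio = median_eps(20_000) / median_eps(80_000)
        assert ratio == pytest.approx(2.0, rel=0.10)
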