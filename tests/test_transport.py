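import math

import numpy as np
import pytest
from scipy import stats

from ramanmc.geometry import LayeredGeometry
from ramanmc.spectra import DispersionModel, Material, Spectrum
from ramanmc.transport import (
    ABSORBED,
    ESCAPED,
    ArrayStream,
    MaterialTable,
    RandomStream,
    RunConfig,
    SourceSpec,
    launch_photon,
    propagate_photon,
    run_simulation,
)

GRID3 = np.array([785.0, 810.0, 900.0])


def const_material(mat_id=1, mu_s=1.0, g=0.0, n=1.0, mu_a=0.0,
                   rho_R=None, rho_F=None):
    return Material(
        id=mat_id,
        dispersion=DispersionModel(a1=mu_s, a2=0.0, a3=g, a4=0.0, a5=n, a6=0.0),
        mu_a=Spectrum(np.array([500.0, 1000.0]), np.array([mu_a, mu_a])),
        rho_R=None if rho_R is None else Spectrum(GRID3, np.asarray(rho_R, float)),
        rho_F=None if rho_F is None else Spectrum(GRID3, np.asarray(rho_F, float)),
    )


def slab(mat_id=1, thickness=10.0, half=50.0):
    return LayeredGeometry([0.0, thickness], [mat_id], half_x=half, half_y=half)


class TestLaunch:
    def test_pencil_beam(self):
        src = SourceSpec(radius_mm=0.0, std_mm=0.0, half_angle_deg=0.0)
        stream = RandomStream(np.random.default_rng(0))
        for _ in range(5):
            pos, d = launch_photon(src, stream)
            np.testing.assert_allclose(pos[:2], [0.0, 0.0])
            np.testing.assert_allclose(d, [0.0, 0.0, 1.0])

    def test_truncated_gaussian_offsets(self):
        src = SourceSpec(radius_mm=0.2, std_mm=1e-4, half_angle_deg=8.0)
        stream = RandomStream(np.random.default_rng(1))
        offsets = []
        for _ in range(20_000):
            pos, _ = launch_photon(src, stream)
            offsets.append(pos[:2])
        offsets = np.asarray(offsets)
        r = np.hypot(offsets[:, 0], offsets[:, 1])
        assert r.max() < src.radius_mm
        assert offsets[:, 0].std() == pytest.approx(1e-4, rel=0.05)

    def test_cone_is_uniform_in_solid_angle(self):
        src = SourceSpec(radius_mm=0.0, std_mm=0.0, half_angle_deg=8.0)
        stream = RandomStream(np.random.default_rng(2))
        cos_min = math.cos(math.radians(8.0))
        cz = np.array([launch_photon(src, stream)[1][2] for _ in range(20_000)])
        assert cz.min() >= cos_min - 1e-12
        # uniform in solid angle <=> cos(theta) uniform on [cos_min, 1]
        u = (1.0 - cz) / (1.0 - cos_min)
        assert stats.kstest(u, "uniform").pvalue > 0.01


class TestPropagateReference:
    def test_certain_absorption(self):
        # opaque medium: photons entering it die on their first segment
        # (a few immediately U-turn and exit through the surface instead)
        mat = const_material(mu_s=10.0, mu_a=1e6, g=0.9)
        table = MaterialTable.build([mat], GRID3)
        stream = RandomStream(np.random.default_rng(3))
        states = []
        for _ in range(200):
            pos, d = launch_photon(SourceSpec(radius_mm=0, std_mm=0,
                                              half_angle_deg=0), stream)
            rec = propagate_photon(pos, d, 0, slab(), table, stream)
            states.append(rec["state"])
            if rec["state"] == ABSORBED:
                assert rec["n_iterations"] <= 3
                assert rec["z"] < 2.0  # died within a few mean free paths
            assert not rec["has_raman"] and not rec["has_fluoresced"]
        assert np.mean(np.asarray(states) == ABSORBED) > 0.9

    def test_conservative_medium_all_escape(self):
        # no absorption, no conversions, index matched to void
        mat = const_material(mu_a=0.0, n=1.0)
        table = MaterialTable.build([mat], GRID3)
        geom = slab(thickness=1.0, half=5.0)
        stream = RandomStream(np.random.default_rng(4))
        src = SourceSpec(radius_mm=0, std_mm=0, half_angle_deg=0)
        for _ in range(50):
            pos, d = launch_photon(src, stream)
            rec = propagate_photon(pos, d, 0, geom, table, stream)
            assert rec["state"] == ESCAPED
            assert not rec["has_raman"] and not rec["has_fluoresced"]
            assert rec["wl_index"] == 0

    def test_hand_traced_event_sequence(self):
        """Scripted variate stream reproduces a pencil-and-paper trace.

        Matched-index slab, mu_s = 1/mm, g = 0, mu_a = 0.5/mm, Raman CDF
        [0, 0.2, 0.4] on a 3-point grid.  The script forces: entry,
        Raman shift to grid point 2, a 2 mm lateral step (survives), a
        1 mm step (absorbed, no fluorescence).
        """
        mat = const_material(mu_s=1.0, g=0.0, n=1.0, mu_a=0.5,
                             rho_R=[0.0, 0.2, 0.4])
        table = MaterialTable.build([mat], GRID3)
        stream = ArrayStream([
            0.5,                    # xi7 at entry: R=0 (matched) -> transmit
            0.3,                    # xi6: 0.3 < 0.4 -> Raman, index 2 chosen
            1.0 - math.exp(-2.0),   # xi1: step of exactly 2 mm
            0.0,                    # xi2: phi = 0
            0.5,                    # xi3: g=0 -> cos theta = 0 (90 deg)
            0.7,                    # xi4: 0.7 > 1-e^-1 -> survives 2 mm
            0.9,                    # xi6: no second shift (0.9 > 0.4)
            1.0 - math.exp(-1.0),   # xi1: step of exactly 1 mm
            0.75,                   # xi2: phi = 3pi/2
            1.0,                    # xi3: cos theta = 1 (straight on)
            0.1,                    # xi4: 0.1 < 1-e^-0.5 -> absorbed
            0.5,                    # xi5: rho_F total 0 -> annihilated
        ])
        pos, d = launch_photon(SourceSpec(radius_mm=0, std_mm=0,
                                          half_angle_deg=0), stream)
        rec = propagate_photon(pos, d, 0, slab(), table, stream)
        assert rec["state"] == ABSORBED
        assert rec["n_iterations"] == 3
        assert rec["has_raman"] and not rec["has_fluoresced"]
        assert rec["wl_index"] == 2
        assert rec["raman_depth_mm"] == pytest.approx(0.0, abs=1e-5)
        # first scatter turned the photon sideways: 2 mm + 1 mm along +x
        assert rec["x"] == pytest.approx(3.0, abs=1e-9)
        assert rec["y"] == pytest.approx(0.0, abs=1e-9)
        assert rec["z"] == pytest.approx(0.0, abs=1e-5)
        assert stream.cursor == len(stream.values)  # every draw consumed

    def test_nan_state_raises(self):
        mat = const_material()
        table = MaterialTable.build([mat], GRID3)
        with pytest.raises(FloatingPointError):
            propagate_photon([0, 0, math.nan], [0, 0, 1], 0, slab(), table,
                             RandomStream(np.random.default_rng(0)))


class TestRunSimulation:
    def test_accounting_and_determinism(self, tiny_depth_fixture, warm_kernel):
        cfg = tiny_depth_fixture.run_config(400, 3, seed=9)
        r1 = run_simulation(cfg)
        r2 = run_simulation(cfg)
        assert sum(r1.meta["counts"].values()) == cfg.n_photons
        assert r1.meta["config_digest"] == r2.meta["config_digest"]
        # byte-identical records on re-run with the same seed
        assert r1.records.equals(r2.records)

    def test_seed_changes_records(self, tiny_depth_fixture, warm_kernel):
        r1 = run_simulation(tiny_depth_fixture.run_config(300, 1, seed=1))
        r2 = run_simulation(tiny_depth_fixture.run_config(300, 1, seed=2))
        assert not r1.records.equals(r2.records)

    def test_raman_records_carry_depth_and_stokes_shift(self, two_layer_fixture,
                                                        warm_kernel):
        res = run_simulation(two_layer_fixture.run_config(3000, 1, seed=5))
        r = res.records
        shifted = r[r.has_raman]
        assert len(shifted) > 0
        assert (shifted.raman_depth_mm >= 0).all()
        assert (shifted.wavelength_nm > 785.0).all()

    def test_mean_steps_grow_with_scattering(self):
        # conversion-free, absorption-free, index-matched slab
        means = []
        for mu_s in (1.0, 5.0, 10.0):
            mat = const_material(mu_s=mu_s, g=0.0, n=1.0)
            geom = slab(thickness=2.0, half=20.0)
            cfg = RunConfig(geometry=geom, materials=[mat], grid=GRID3,
                            source=SourceSpec(radius_mm=0, std_mm=0,
                                              half_angle_deg=0),
                            photons_per_batch=2000, n_batches=1, seed=3)
            res = run_simulation(cfg)
            means.append(res.records.n_iterations.mean())
        assert means[0] < means[1] < means[2]

    def test_diffuse_reflectance_decreases_with_absorption(self):
        refl = []
        for mu_a in (0.01, 0.3, 3.0):
            mat = const_material(mu_s=10.0, g=0.9, n=1.0, mu_a=mu_a)
            geom = slab(thickness=5.0, half=20.0)
            cfg = RunConfig(geometry=geom, materials=[mat], grid=GRID3,
                            source=SourceSpec(radius_mm=0, std_mm=0,
                                              half_angle_deg=0),
                            photons_per_batch=3000, n_batches=1, seed=8)
            res = run_simulation(cfg)
            r = res.records
            top = (r.state == ESCAPED) & (r.z <= 1e-6) & (r.uz < 0)
            refl.append(top.mean())
        assert refl[0] > refl[1] > refl[2]
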