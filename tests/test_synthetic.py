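"""Rayleigh-integral simulator, phantom builders, noise and cross-talk."""

import numpy as np
import pytest

import opusdmi as od
from opusdmi.synthetic import SimulationError

from conftest import relative_l2

C = 1500.0


class TestSimulator:
    def test_first_arrival_timing(self, small_acquisition, burst):
        """Scatterer at 5 mm, source at origin: onset at 6.667 us."""
        geometry = od.ProbeGeometry(source_centers=[[0, 0, 0]],
                                    receiver_position=[0, 0, 0],
                                    aperture_width=1e-3)
        bscan = od.simulate_bscan(od.make_point_phantom(), geometry,
                                  small_acquisition, burst)
        trace = bscan.samples[:, 0]
        # low threshold: the Hann-windowed burst rises gently from zero
        onset = np.argmax(np.abs(trace) > 0.002 * np.abs(trace).max())
        assert 0 <= small_acquisition.time_axis[onset] - 2 * 5e-3 / C \
            <= 2 * small_acquisition.dt

    def test_born_superposition(self, small_geometry, small_acquisition,
                                burst):
        p1 = od.make_point_phantom(depth=4e-3, lateral=-0.5e-3)
        p2 = od.make_point_phantom(depth=5e-3, lateral=0.8e-3,
                                   reflectivity=0.2)
        both = od.Phantom(scatterers=np.vstack([p1.scatterers,
                                                p2.scatterers]),
                          reflectivity=np.concatenate([p1.reflectivity,
                                                       p2.reflectivity]))
        b1 = od.simulate_bscan(p1, small_geometry, small_acquisition, burst)
        b2 = od.simulate_bscan(p2, small_geometry, small_acquisition, burst)
        b12 = od.simulate_bscan(both, small_geometry, small_acquisition,
                                burst)
        assert np.allclose(b12.samples, b1.samples + b2.samples,
                           rtol=1e-9, atol=1e-12 * np.abs(b12.samples).max())

    def test_linear_in_reflectivity(self, small_geometry, small_acquisition,
                                    burst):
        p = od.make_point_phantom(depth=4e-3)
        p5 = od.make_point_phantom(depth=4e-3,
                                   reflectivity=5 * p.reflectivity[0])
        b = od.simulate_bscan(p, small_geometry, small_acquisition, burst)
        b5 = od.simulate_bscan(p5, small_geometry, small_acquisition, burst)
        assert np.allclose(b5.samples, 5 * b.samples, rtol=1e-10)

    def test_agrees_with_system_matrix_but_not_identical(
            self, small_geometry, small_acquisition, burst):
        """Two independent forward models: <=5% apart, never bit-identical
        (the inverse-crime guard)."""
        phantom = od.make_point_phantom(depth=4e-3, lateral=0.4e-3)
        grid = od.ImageGrid(x_extent=(0.4e-3, 0.4e-3),
                            z_extent=(4e-3, 4e-3))
        matrix = od.build_system_matrix(small_geometry, grid,
                                        small_acquisition, burst)
        projected = od.forward_project(matrix, phantom.reflectivity)
        simulated = od.simulate_bscan(phantom, small_geometry,
                                      small_acquisition, burst)
        assert relative_l2(simulated.samples, projected.samples) < 0.05
        assert not np.array_equal(simulated.samples, projected.samples)

    def test_subelement_convergence(self, small_geometry, small_acquisition,
                                    burst):
        """Halving the sub-element pitch changes the record by < 1%."""
        phantom = od.make_point_phantom(depth=4e-3, lateral=-0.7e-3)
        coarse = od.simulate_bscan(phantom, small_geometry,
                                   small_acquisition, burst,
                                   subelement_pitch=25e-6)
        fine = od.simulate_bscan(phantom, small_geometry, small_acquisition,
                                 burst, subelement_pitch=12.5e-6)
        assert relative_l2(coarse.samples, fine.samples) < 0.01

    def test_coarse_pitch_rejected(self, small_geometry, small_acquisition,
                                   burst):
        with pytest.raises(SimulationError, match="um"):
            od.simulate_bscan(od.make_point_phantom(), small_geometry,
                              small_acquisition, burst,
                              subelement_pitch=50e-6)


class TestPointPhantom:
    def test_default_position_and_born_reflectivity(self):
        p = od.make_point_phantom()
        assert np.allclose(p.scatterers[0], [0, 0, 5e-3])
        assert p.reflectivity[0] == pytest.approx(2 * 70 / 1500)

    def test_zero_depth_rejected(self):
        with pytest.raises(ValueError):
            od.make_point_phantom(depth=0.0)

    def test_deterministic(self):
        a, b = od.make_point_phantom(), od.make_point_phantom()
        assert np.array_equal(a.scatterers, b.scatterers)


class TestDiscPhantom:
    def test_contrast_bands(self):
        p = od.make_disc_phantom(seed=1)
        for (clo, chi), cx in zip(((1497, 1503), (1480, 1520), (1440, 1560)),
                                  (-3e-3, 0.0, 3e-3)):
            in_disc = np.abs(p.scatterers[:, 0] - cx) <= 1e-3
            r = p.reflectivity[in_disc]
            lim = 2 * (chi - 1500) / 1500
            assert np.all(np.abs(r) <= lim + 1e-12)
            assert np.abs(r).max() > 0.5 * lim    # the band is actually used

    def test_rms_ratio_strong_to_weak_disc(self):
        """Uniform half-widths 60 vs 3 m/s give an RMS reflectivity ratio
        of 20 (checked Monte-Carlo over the lattice draw)."""
        p = od.make_disc_phantom(pitch=25e-6, seed=2)
        x = p.scatterers[:, 0]
        rms = [np.sqrt(np.mean(p.reflectivity[np.abs(x - cx) <= 1e-3] ** 2))
               for cx in (-3e-3, 3e-3)]
        assert rms[1] / rms[0] == pytest.approx(20.0, rel=0.1)

    def test_seeded_draws(self):
        assert np.array_equal(od.make_disc_phantom(seed=7).reflectivity,
                              od.make_disc_phantom(seed=7).reflectivity)
        assert not np.array_equal(od.make_disc_phantom(seed=7).reflectivity,
                                  od.make_disc_phantom(seed=8).reflectivity)


class TestLayeredPhantom:
    def test_speed_mode_interface_coefficients(self):
        p = od.make_layered_phantom("speed")
        depths = np.unique(p.scatterers[:, 2])
        assert np.allclose(depths, [3e-3, 6e-3])
        r1 = p.reflectivity[p.scatterers[:, 2] == 3e-3][0]
        r2 = p.reflectivity[p.scatterers[:, 2] == 6e-3][0]
        assert r1 == pytest.approx((1500 - 1450) / (1500 + 1450), rel=1e-6)
        assert r2 == pytest.approx((1540 - 1500) / (1540 + 1500), rel=1e-6)

    def test_density_mode_interface_coefficients(self):
        p = od.make_layered_phantom("density")
        r2 = p.reflectivity[p.scatterers[:, 2] == 6e-3][0]
        assert r2 == pytest.approx((1027 - 1000) / (1027 + 1000), rel=1e-6)

    def test_unknown_mode(self):
        with pytest.raises(ValueError):
            od.make_layered_phantom("attenuation")


class TestVesselPhantom:
    def test_no_needle_means_no_strong_reflector(self):
        p = od.make_vessel_phantom(with_needle=False)
        wall = (1570 - 1500) / (1570 + 1500)
        assert np.abs(p.reflectivity).max() == pytest.approx(wall, rel=1e-6)

    def test_needle_dominates_wall(self):
        """Impedance arithmetic: needle >10x the lumen-boundary contrast."""
        p = od.make_vessel_phantom(with_needle=True)
        wall = (1570 * 1000 - 1500 * 1000) / (1570 * 1000 + 1500 * 1000)
        needle = (2000 * 1500 - 1500 * 1000) / (2000 * 1500 + 1500 * 1000)
        assert np.abs(p.reflectivity).max() == pytest.approx(needle,
                                                             rel=1e-6)
        assert needle / wall > 10

    def test_seeded_reproducibility(self):
        a = od.make_vessel_phantom(True, seed=3)
        b = od.make_vessel_phantom(True, seed=3)
        assert np.array_equal(a.scatterers, b.scatterers)


class TestNoise:
    def test_infinite_snr_unchanged(self, small_acquisition, small_geometry):
        rng = np.random.default_rng(0)
        b = od.BScan(samples=rng.standard_normal((512, 8)),
                     acquisition=small_acquisition, geometry=small_geometry)
        out = od.add_noise(b, np.inf, 1)
        assert np.array_equal(out.samples, b.samples)

    def test_measured_snr_within_tolerance(self, small_geometry):
        """On >=64k samples the realised SNR is within 0.2 dB of request."""
        acq = od.AcquisitionSettings(n_time_samples=1004)
        geometry = od.make_default_probe(64, 15e-3, 0.0, 0)
        rng = np.random.default_rng(1)
        clean = rng.standard_normal((1004, 64))
        b = od.BScan(samples=clean, acquisition=acq, geometry=geometry)
        noisy = od.add_noise(b, 20.0, 2)
        noise = noisy.samples - clean
        snr = 20 * np.log10(np.sqrt(np.mean(clean ** 2))
                            / np.sqrt(np.mean(noise ** 2)))
        assert snr == pytest.approx(20.0, abs=0.2)

    def test_seeded(self, small_acquisition, small_geometry):
        b = od.BScan(samples=np.ones((512, 8)),
                     acquisition=small_acquisition, geometry=small_geometry)
        assert np.array_equal(od.add_noise(b, 10, 5).samples,
                              od.add_noise(b, 10, 5).samples)
        assert not np.array_equal(od.add_noise(b, 10, 5).samples,
                                  od.add_noise(b, 10, 6).samples)


class TestCrosstalk:
    def test_arrival_per_channel(self, small_geometry, small_acquisition,
                                 burst):
        """Direct-wave onset between the near-edge and centre arrival."""
        xt = od.simulate_crosstalk(small_geometry, small_acquisition, burst)
        a = small_geometry.source_radius
        for k in range(small_geometry.n_sources):
            trace = xt.samples[:, k]
            onset = np.argmax(np.abs(trace) > 0.002 * np.abs(trace).max())
            centre = np.linalg.norm(small_geometry.source_centers[k]) / C
            t_on = small_acquisition.time_axis[onset]
            assert (centre - a / C) - small_acquisition.dt <= t_on \
                <= centre + 2 * small_acquisition.dt

    def test_add_then_subtract_recovers_echoes(self, small_geometry,
                                               small_acquisition, burst):
        echoes = od.simulate_bscan(od.make_point_phantom(), small_geometry,
                                   small_acquisition, burst)
        xt = od.simulate_crosstalk(small_geometry, small_acquisition, burst)
        total = od.BScan(samples=echoes.samples + xt.samples,
                         acquisition=small_acquisition,
                         geometry=small_geometry)
        clean = od.subtract_crosstalk(total, xt)
        assert np.allclose(clean.samples, echoes.samples,
                           atol=1e-9 * np.abs(xt.samples).max())

    def test_crosstalk_dominates_echo(self, burst):
        """With the default probe (sources down to ~120 um from the
        receiver) the direct wave peaks above the point-scatterer echo."""
        geometry = od.make_default_probe()
        acq = od.AcquisitionSettings(n_time_samples=704)
        echoes = od.simulate_bscan(od.make_point_phantom(), geometry, acq,
                                   burst)
        xt = od.simulate_crosstalk(geometry, acq, burst)
        assert np.abs(xt.samples).max() > np.abs(echoes.samples).max()
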