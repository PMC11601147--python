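"""Piston SIR, channel traces and system-matrix assembly."""

import numpy as np
import pytest

import opusdmi as od
from opusdmi.forward import ForwardModelError, system_matrix_bytes
from opusdmi.synthetic import _disc_tiling

from conftest import relative_l2

C = 1500.0
A = 100e-6


def rayleigh_spectrum_oracle(field_point, center, radius, c, omega,
                             pitch=5e-6):
    """Brute-force surface integral: H = sum dA exp(-i w r / c) / (2 pi r)."""
    pts, area = _disc_tiling(radius, pitch)
    sub = np.asarray(center, float)[None, :] + np.column_stack(
        [pts, np.zeros(len(pts))])
    r = np.linalg.norm(np.asarray(field_point, float)[None, :] - sub, axis=1)
    return (area / (2 * np.pi * r)[None, :]
            * np.exp(-1j * np.outer(omega, r) / c)).sum(axis=1)


class TestPistonSirTime:
    def test_on_axis_rectangle(self):
        """On-axis SIR is a rectangle of height c on [z/c, sqrt(z²+a²)/c]."""
        z = 5e-3
        t_lo, t_hi = z / C, np.hypot(z, A) / C
        assert t_lo == pytest.approx(3.33333e-6, rel=1e-5)
        assert t_hi == pytest.approx(3.33400e-6, rel=1e-5)
        t = np.array([t_lo - 1e-10, t_lo + 1e-10, (t_lo + t_hi) / 2,
                      t_hi - 1e-10, t_hi + 1e-10])
        h = od.piston_sir_time([0, 0, z], [0, 0, 0], A, C, t)
        assert np.allclose(h, [0, C, C, C, 0])

    def test_integral_matches_rayleigh_oracle(self):
        """∫h dt equals the monopole surface integral at zero frequency."""
        for fp in ([0, 0, 5e-3], [0.3e-3, 0, 4e-3], [2e-3, 0.2e-3, 3e-3]):
            H0 = od.piston_sir_spectrum(fp, [0, 0, 0], A, C, [0.0])[0]
            ref = rayleigh_spectrum_oracle(fp, [0, 0, 0], A, C,
                                           np.array([0.0]))[0]
            assert H0 == pytest.approx(ref, rel=1e-3)

    def test_far_field_integral_value(self):
        """Far beyond the Rayleigh distance |∫h dt| -> area/(2 pi r)."""
        lam = C / 11e6
        rayleigh = np.pi * A ** 2 / lam
        r = 10 * max(rayleigh, 1e-3)
        H0 = od.piston_sir_spectrum([0, 0, r], [0, 0, 0], A, C, [0.0])[0]
        assert abs(H0) == pytest.approx(np.pi * A ** 2 / (2 * np.pi * r),
                                        rel=0.01)

    def test_on_disc_rejected(self):
        with pytest.raises(ForwardModelError):
            od.piston_sir_time([50e-6, 0, 0], [0, 0, 0], A, C, [1e-6])
        with pytest.raises(ForwardModelError):
            od.piston_sir_spectrum([0, 0, 0], [0, 0, 0], A, C, [0.0])


class TestPistonSirSpectrum:
    def test_point_source_limit(self):
        """a -> 0 at fixed field point: H -> area exp(-i w r/c) / (2 pi r)."""
        fp = [1e-3, 0, 4e-3]
        r = np.linalg.norm(fp)
        omega = 2 * np.pi * np.array([1e6, 5e6, 11e6, 20e6])
        a_small = 2e-6
        H = od.piston_sir_spectrum(fp, [0, 0, 0], a_small, C, omega)
        expected = np.pi * a_small ** 2 * np.exp(-1j * omega * r / C) \
            / (2 * np.pi * r)
        assert np.allclose(H, expected, rtol=1e-3)

    def test_matches_rayleigh_oracle_broadband(self):
        """GL quadrature agrees with the brute-force surface sum to <1%."""
        omega = 2 * np.pi * np.linspace(0, 30e6, 40)
        for fp in ([0.4e-3, 0, 5e-3], [1.5e-3, 0.3e-3, 3.5e-3]):
            H = od.piston_sir_spectrum(fp, [0, 0, 0], A, C, omega)
            ref = rayleigh_spectrum_oracle(fp, [0, 0, 0], A, C, omega,
                                           pitch=3e-6)
            assert relative_l2(H, ref) < 0.01


class TestChannelTrace:
    def test_onset_at_two_way_delay(self, small_acquisition):
        """Source+receiver at origin, pixel 5 mm deep: onset at 6.667 us."""
        geometry = od.ProbeGeometry(source_centers=[[0, 0, 0]],
                                    receiver_position=[0, 0, 0],
                                    aperture_width=1e-3)
        trace = od.channel_trace([0, 0, 5e-3], 0, geometry,
                                 small_acquisition,
                                 od.SourceSignature(kind="delta"))
        onset = np.argmax(np.abs(trace) > 0.05 * np.abs(trace).max())
        t_onset = small_acquisition.time_axis[onset]
        assert abs(t_onset - 2 * 5e-3 / C) <= small_acquisition.dt

    def test_far_field_amplitude_quarters(self, burst):
        """Doubling both legs in the far field scales the peak by ~1/4."""
        geometry = od.ProbeGeometry(source_centers=[[0, 0, 0]],
                                    receiver_position=[0, 0, 0],
                                    aperture_width=1e-3)
        import scipy.signal

        acq = od.AcquisitionSettings(n_time_samples=8192)
        # envelope peaks: the raw sampled peak wobbles with the carrier
        # phase at only ~5.7 samples per cycle
        p1 = np.abs(scipy.signal.hilbert(
            od.channel_trace([0, 0, 40e-3], 0, geometry, acq, burst))).max()
        p2 = np.abs(scipy.signal.hilbert(
            od.channel_trace([0, 0, 80e-3], 0, geometry, acq, burst))).max()
        assert p1 / p2 == pytest.approx(4.0, rel=0.03)

    def test_matches_timedomain_oracle(self, small_geometry,
                                       small_acquisition, burst):
        """Spectral assembly vs independent time-domain convolution, <=1%."""
        rng = np.random.default_rng(12)
        for _ in range(5):
            # stay inside the 8.19 us record for every source
            px = np.array([rng.uniform(-1.5e-3, 1.5e-3), 0.0,
                           rng.uniform(3e-3, 4.8e-3)])
            k = int(rng.integers(0, small_geometry.n_sources))
            spec = od.channel_trace(px, k, small_geometry,
                                    small_acquisition, burst)
            ref = od.channel_trace_timedomain(px, k, small_geometry,
                                              small_acquisition, burst)
            assert relative_l2(spec, ref) < 0.01

    def test_causal_before_two_way_delay(self, small_geometry,
                                         small_acquisition, burst):
        """Traces vanish (<1e-6 of peak) before the geometric delay minus
        one pulse length."""
        for px in ([1e-3, 0, 5e-3], [-1.5e-3, 0, 3.5e-3]):
            for k in (0, small_geometry.n_sources - 1):
                trace = od.channel_trace(np.array(px), k, small_geometry,
                                         small_acquisition, burst)
                tau = (np.linalg.norm(px - small_geometry.source_centers[k])
                       + np.linalg.norm(px)) / C
                early = small_acquisition.time_axis < tau - burst.duration
                assert np.abs(trace[early]).max() < 1e-6 * np.abs(trace).max()

    def test_receiver_leg_depends_only_on_distance(self, small_acquisition,
                                                   burst):
        """Backscatter Green's leg reciprocity: equidistant receivers on
        either side of the pixel give identical traces."""
        px = np.array([0.0, 0.0, 4e-3])
        traces = []
        for rx in (1.5e-3, -1.5e-3):
            geometry = od.ProbeGeometry(source_centers=[[0, 0, 0],
                                                        [rx, 0, 0]],
                                        receiver_position=[rx, 0, 0],
                                        aperture_width=4e-3)
            traces.append(od.channel_trace(px, 0, geometry,
                                           small_acquisition, burst))
        assert np.array_equal(traces[0], traces[1])

    def test_quadrature_refinement_converged(self, small_geometry,
                                             small_acquisition, burst):
        """Halving the quadrature density changes traces by < 0.5%."""
        px = np.array([-1.2e-3, 0, 4.5e-3])
        full = od.channel_trace(px, 1, small_geometry, small_acquisition,
                                burst, quad_density=1.0)
        half = od.channel_trace(px, 1, small_geometry, small_acquisition,
                                burst, quad_density=0.5)
        assert relative_l2(half, full) < 0.005

    def test_preconditions(self, small_geometry, small_acquisition, burst):
        with pytest.raises(ForwardModelError, match="z > 0"):
            od.channel_trace([0, 0, -1e-3], 0, small_geometry,
                             small_acquisition, burst)
        short = od.AcquisitionSettings(n_time_samples=16)
        with pytest.raises(ForwardModelError, match="record too short"):
            od.channel_trace([0, 0, 5e-3], 0, small_geometry, short, burst)


class TestSystemMatrix:
    def test_single_pixel_matrix_is_channel_trace(self, small_geometry,
                                                  small_acquisition, burst):
        grid = od.ImageGrid(x_extent=(0.5e-3, 0.5e-3),
                            z_extent=(4e-3, 4e-3))
        sm = od.build_system_matrix(small_geometry, grid, small_acquisition,
                                    burst)
        n_t = small_acquisition.n_time_samples
        for k in range(small_geometry.n_sources):
            trace = od.channel_trace([0.5e-3, 0, 4e-3], k, small_geometry,
                                     small_acquisition, burst)
            assert np.array_equal(sm.entries[k * n_t:(k + 1) * n_t, 0],
                                  trace.astype(np.float32))

    def test_rebuild_bitwise_deterministic(self, tiny_setup, tiny_system):
        cfg = tiny_setup
        matrix, _ = tiny_system
        again = od.build_system_matrix(cfg.geometry, cfg.grid_main,
                                       cfg.acquisition_main, cfg.signature)
        assert np.array_equal(matrix.entries, again.entries)

    def test_columns_match_recomputed_traces(self, tiny_setup, tiny_system):
        """Spot-checked columns equal independently recomputed channel
        traces (to the last-bit batching noise of the FFT backend, ~1e-15
        of the trace peak on otherwise-zero pre-onset samples)."""
        cfg = tiny_setup
        matrix, _ = tiny_system
        rng = np.random.default_rng(5)
        pixels = cfg.grid_main.pixel_positions()
        n_t = cfg.acquisition_main.n_time_samples
        for j in rng.choice(cfg.grid_main.n_pixels, 10, replace=False):
            for k in (0, cfg.geometry.n_sources - 1):
                trace = od.channel_trace(pixels[j], k, cfg.geometry,
                                         cfg.acquisition_main, cfg.signature)
                col = matrix.entries[k * n_t:(k + 1) * n_t, j]
                assert np.allclose(col, trace.astype(np.float32), rtol=1e-6,
                                   atol=1e-9 * np.abs(trace).max())

    def test_memory_budget_enforced(self, small_geometry, small_acquisition,
                                    burst, small_grid):
        need = system_matrix_bytes(small_geometry, small_acquisition,
                                   small_grid)
        with pytest.raises(ForwardModelError, match="GiB"):
            od.build_system_matrix(small_geometry, small_grid,
                                   small_acquisition, burst,
                                   memory_budget=need - 1)

    def test_full_size_storage_requirement(self):
        geometry = od.make_default_probe()
        bytes_ = system_matrix_bytes(geometry, od.AcquisitionSettings(),
                                     od.ImageGrid())
        assert bytes_ == 64 * 1004 * 56481 * 4
        assert bytes_ / 2 ** 30 == pytest.approx(13.5, abs=0.1)


class TestForwardProject:
    def test_unit_vector_gives_column(self, tiny_setup, tiny_system):
        cfg = tiny_setup
        matrix, _ = tiny_system
        j = 57
        e = np.zeros(cfg.grid_main.n_pixels)
        e[j] = 1.0
        bscan = od.forward_project(matrix, e)
        assert np.array_equal(bscan.flatten(),
                              matrix.entries[:, j].astype(np.float64))

    def test_linearity_and_superposition(self, tiny_setup, tiny_system):
        cfg = tiny_setup
        matrix, _ = tiny_system
        rng = np.random.default_rng(8)
        r1 = rng.standard_normal(cfg.grid_main.n_pixels)
        r2 = rng.standard_normal(cfg.grid_main.n_pixels)
        combo = od.forward_project(matrix, 2.0 * r1 + 3.0 * r2)
        parts = 2.0 * od.forward_project(matrix, r1).samples \
            + 3.0 * od.forward_project(matrix, r2).samples
        assert np.allclose(combo.samples, parts, rtol=1e-4, atol=1e-6
                           * np.abs(parts).max())

    def test_shape_mismatch(self, tiny_system):
        matrix, _ = tiny_system
        with pytest.raises(ForwardModelError):
            od.forward_project(matrix, np.zeros(3))
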