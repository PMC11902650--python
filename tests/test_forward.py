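"""Forward simulator: Green operators, fields, noise."""

import numpy as np
import pytest
from scipy.integrate import dblquad
from scipy.special import hankel2

from mwtomo import forward as fwd
from mwtomo.phantoms import DielectricMap, make_austria

from conftest import random_map


class TestGreenOperators:
    def test_domain_operator_symmetric(self, austria16):
        _, _, ops, _ = austria16
        G = ops.G_D_dense()
        np.testing.assert_allclose(G, G.T, rtol=0, atol=1e-13)

    def test_self_term_matches_brute_force_quadrature(self, austria16):
        m, _, ops, _ = austria16
        k = ops.k_b.real
        h = m.cell_size / 2

        def kern(re):
            def f(y, x):
                r = max(np.hypot(x, y), 1e-10)  # integrable log singularity
                val = -1j * k**2 / 4 * hankel2(0, k * r)
                return val.real if re else val.imag
            return f

        re, _ = dblquad(kern(True), -h, h, -h, h)
        im, _ = dblquad(kern(False), -h, h, -h, h)
        quad = re + 1j * im
        # the analytic self term integrates over an equal-area disk; the
        # residual disk-vs-square discrepancy is below one percent
        self_term = ops.G_D_dense()[0, 0]
        assert abs(self_term - quad) / abs(quad) < 1e-2

    def test_far_cells_match_hankel_asymptote(self, austria16):
        from scipy.special import jv

        m, _, ops, _ = austria16
        k = ops.k_b.real
        G = ops.G_D_dense()
        i, j = 0, m.n_cells - 1  # opposite corners, k*rho ~ 22
        X, Y = m.cell_grid()
        x, y = X.ravel(), Y.ravel()
        rho = np.hypot(x[i] - x[j], y[i] - y[j])
        a = m.cell_size / np.sqrt(np.pi)
        # |H0^(2)(z)| -> sqrt(2/(pi z)) at large argument
        pred = abs(-1j * np.pi * k * a / 2 * jv(1, k * a)) * np.sqrt(
            2 / (np.pi * k * rho)
        )
        assert abs(G[i, j]) == pytest.approx(pred, rel=0.01)

    def test_rejects_antenna_inside_domain(self):
        m = make_austria(16)
        arr = fwd.ArrayConfig(radius=0.5, frequencies=(400e6,))
        with pytest.raises(ValueError, match="outside"):
            fwd.build_green_operators(m, arr, 400e6)


class TestIncidentField:
    def test_helmholtz_residual_small_away_from_source(self):
        m = DielectricMap(np.ones((48, 48)), np.zeros((48, 48)), 2.0 / 48)
        arr = fwd.ArrayConfig(radius=1.5, frequencies=(400e6,))
        fields = fwd.incident_field(m, arr, 400e6)
        k = fwd.wavenumber(400e6, 1.0)
        E = fields.E_inc[0].reshape(m.shape)
        h = m.cell_size
        lap = (
            E[:-2, 1:-1] + E[2:, 1:-1] + E[1:-1, :-2] + E[1:-1, 2:]
            - 4 * E[1:-1, 1:-1]
        ) / h**2
        resid = lap + k**2 * E[1:-1, 1:-1]
        assert np.linalg.norm(resid) / np.linalg.norm(k**2 * E[1:-1, 1:-1]) < 1e-2

    def test_magnitude_decays_with_distance(self):
        m = DielectricMap(np.ones((32, 32)), np.zeros((32, 32)), 2.0 / 32)
        arr = fwd.ArrayConfig(radius=1.5, frequencies=(400e6,))
        fields = fwd.incident_field(m, arr, 400e6)
        tx = arr.tx_positions()[0]
        X, Y = m.cell_grid()
        d = np.hypot(X.ravel() - tx[0], Y.ravel() - tx[1])
        order = np.argsort(d)
        mags = np.abs(fields.E_inc[0])[order]
        assert np.all(np.diff(mags) <= 1e-9)  # |H0^(2)| monotone for d > 0

    def test_rotating_array_and_grid_preserves_magnitude(self):
        n = 24
        m = DielectricMap(np.ones((n, n)), np.zeros((n, n)), 2.0 / n)
        freq = 400e6
        arr = fwd.ArrayConfig(radius=1.5, frequencies=(freq,),
                              n_antennas=32, tx_indices=(0,))
        f1 = fwd.incident_field(m, arr, freq)
        # move the transmitter a quarter turn around the ring; the field
        # magnitude pattern on the (square) grid rotates with it
        arr90 = fwd.ArrayConfig(radius=1.5, frequencies=(freq,),
                                n_antennas=32, tx_indices=(8,))
        f2 = fwd.incident_field(m, arr90, freq)
        a = np.abs(f1.E_inc[0]).reshape(n, n)
        b = np.abs(f2.E_inc[0]).reshape(n, n)
        np.testing.assert_allclose(np.rot90(a, k=1), b, rtol=1e-9)


class TestContrast:
    def test_direct_substitution_cases(self):
        n = 4
        m = DielectricMap(np.full((n, n), 2.0), np.zeros((n, n)), 0.01)
        chi = fwd.contrast_of(m, 400e6)
        np.testing.assert_allclose(chi, 1.0 + 0j)
        bg = DielectricMap(np.full((n, n), 3.0), np.full((n, n), 0.2), 0.01,
                           eps_b=3.0, sigma_b=0.2)
        np.testing.assert_allclose(fwd.contrast_of(bg, 1e9), 0.0)

    def test_conductivity_term_normalized_by_absolute_permittivity(self):
        n = 2
        m = DielectricMap(np.full((n, n), 10.0), np.full((n, n), 0.1395),
                          0.01, eps_b=10.0, sigma_b=0.0)
        chi = fwd.contrast_of(m, 1e9)
        expect = -1j * 0.1395 / (2 * np.pi * 1e9 * fwd.EPS0 * 10.0)
        np.testing.assert_allclose(chi, expect, rtol=1e-12)
        assert chi[0].imag == pytest.approx(-0.2507, abs=2e-4)


class TestScattering:
    def test_zero_contrast_identities(self, austria16):
        m, arr, ops, fields = austria16
        bgm = m.background_like()
        fs = fwd.solve_total_field(bgm, ops, fields)
        np.testing.assert_array_equal(fs.E_tot, fields.E_inc)
        data = fwd.scattered_field(bgm, ops, fs)
        np.testing.assert_array_equal(data, 0)

    def test_solution_satisfies_integral_equation(self, austria16):
        m, arr, ops, fields = austria16
        fs = fwd.solve_total_field(m, ops, fields, tol=1e-10)
        chi = fwd.contrast_of(m, ops.frequency)
        resid = fs.E_tot - ops.gd.matvec(chi[None, :] * fs.E_tot) - fields.E_inc
        assert np.linalg.norm(resid) / np.linalg.norm(fields.E_inc) < 1e-6

    def test_born_regime_linearity(self, rng):
        n = 12
        m1 = DielectricMap(1 + 1e-3 * rng.random((n, n)), np.zeros((n, n)),
                           2.0 / n)
        m2 = DielectricMap(1 + 2 * (m1.eps_r - 1), np.zeros((n, n)), 2.0 / n)
        arr = fwd.ArrayConfig(radius=1.5, frequencies=(400e6,))
        ops = fwd.build_green_operators(m1, arr, 400e6)
        fields = fwd.incident_field(m1, arr, 400e6)
        d1 = fwd.scattered_field(m1, ops, fwd.solve_total_field(m1, ops, fields, tol=1e-12))
        d2 = fwd.scattered_field(m2, ops, fwd.solve_total_field(m2, ops, fields, tol=1e-12))
        assert np.linalg.norm(d2 - 2 * d1) / np.linalg.norm(d2) < 5e-3

    def test_reciprocity_of_transmit_receive_swap(self, rng):
        # unit line sources: measurement (tx=i, rx=j) equals (tx=j, rx=i)
        n = 12
        m = random_map(rng, n=n, eps_max=1.6, cell=2.0 / n)
        arr = fwd.ArrayConfig(radius=1.5, frequencies=(400e6,),
                              tx_indices=(2, 9))
        ops = fwd.build_green_operators(m, arr, 400e6)
        fields = fwd.incident_field(m, arr, 400e6)
        fs = fwd.solve_total_field(m, ops, fields, tol=1e-12)
        data = fwd.scattered_field(m, ops, fs)
        assert data[0, 9] == pytest.approx(data[1, 2], rel=1e-8)


class TestNoise:
    def _meas(self, rng, nf=2, nt=3, nr=30):
        data = rng.standard_normal((nf, nt, nr)) + 1j * rng.standard_normal(
            (nf, nt, nr)
        )
        arr = fwd.ArrayConfig(radius=1.5, frequencies=(4e8, 5e8))
        return fwd.MeasurementSet(data=data, frequencies=arr.frequencies,
                                  array=arr)

    def test_none_means_unchanged(self, rng):
        meas = self._meas(rng)
        out = fwd.add_noise(meas, None, seed=5)
        np.testing.assert_array_equal(out.data, meas.data)
        assert out.meta["noise_applied"] is False

    def test_zero_db_noise_power_equals_signal_power(self, rng):
        meas = self._meas(rng, nt=1, nr=2000)
        out = fwd.add_noise(meas, 0.0, seed=5)
        p_sig = np.mean(np.abs(meas.data) ** 2)
        p_noise = np.mean(np.abs(out.data - meas.data) ** 2)
        assert p_noise == pytest.approx(p_sig, rel=0.1)

    def test_deterministic_given_seed(self, rng):
        meas = self._meas(rng)
        a = fwd.add_noise(meas, 10.0, seed=7)
        b = fwd.add_noise(meas, 10.0, seed=7)
        np.testing.assert_array_equal(a.data, b.data)

    def test_noiseless_preserved_in_expectation(self, rng):
        meas = self._meas(rng, nf=1, nt=1, nr=30)
        copies = np.stack([
            fwd.add_noise(meas, 10.0, seed=s).data for s in range(1000)
        ])
        mean = copies.mean(axis=0)
        # standard error of the mean of the injected noise, per sample
        sig = np.sqrt(np.mean(np.abs(meas.data) ** 2) / 10.0 / 1000)
        assert np.all(np.abs(mean - meas.data) < 3 * sig * 4)

    def test_rejects_zero_signal(self):
        arr = fwd.ArrayConfig(radius=1.5, frequencies=(4e8,))
        meas = fwd.MeasurementSet(np.zeros((1, 1, 30), complex),
                                  arr.frequencies, arr)
        with pytest.raises(ValueError, match="SNR undefined"):
            fwd.add_noise(meas, 10.0, seed=1)


class TestSimulateExperiment:
    def test_zero_contrast_zero_measurements(self):
        m = make_austria(16).background_like()
        arr = fwd.ArrayConfig(radius=1.5, frequencies=(400e6,))
        meas = fwd.simulate_experiment(m, arr, snr_db=None, seed=0, fine_factor=1)
        np.testing.assert_array_equal(meas.data, 0)

    def test_metadata_records_provenance(self):
        m = make_austria(16)
        arr = fwd.ArrayConfig(radius=1.5, frequencies=(400e6,))
        meas = fwd.simulate_experiment(m, arr, snr_db=15.0, seed=42, fine_factor=2)
        assert meas.meta["seed"] == 42
        assert meas.meta["snr_db"] == 15.0
        assert meas.meta["fine_factor"] == 2
        assert meas.noise_seed == 42

    def test_grid_refinement_gap_is_small_but_nonzero(self):
        arr = fwd.ArrayConfig(radius=1.5, frequencies=(400e6,))
        coarse = make_austria(64)
        fine = make_austria(128)
        d1 = fwd.simulate_experiment(coarse, arr, fine_factor=1).data
        d2 = fwd.simulate_experiment(coarse, arr, fine_factor=2,
                                     fine_map=fine).data
        gap = np.linalg.norm(d2 - d1) / np.linalg.norm(d1)
        assert 0 < gap < 0.05
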