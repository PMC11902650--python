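"""Subspace-enhanced distorted-Born machinery."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mwtomo import forward as fwd
from mwtomo import subspace_inverse as si
from mwtomo.metrics_io import xi_signal
from mwtomo.phantoms import make_austria

from conftest import random_map


@pytest.fixture(scope="module")
def bg16(austria16):
    """Background operators about a random non-trivial contrast, 16x16."""
    m, arr, ops, fields = austria16
    rng = np.random.default_rng(11)
    chi_b = 0.4 * rng.random(m.n_cells) + 0.05j * rng.random(m.n_cells)
    return si.background_operators(chi_b, ops, fields, tol=1e-12), ops, fields


class TestBackgroundOperators:
    def test_zero_background_reduces_to_homogeneous(self, austria16):
        m, arr, ops, fields = austria16
        bg = si.background_operators(np.zeros(m.n_cells), ops, fields)
        np.testing.assert_array_equal(bg.E_bac, fields.E_inc)
        np.testing.assert_array_equal(bg.G_bS, ops.G_S)

    def test_matches_dense_formula(self, bg16):
        bg, ops, fields = bg16
        inv = np.linalg.inv(
            np.eye(ops.n_cells) - np.diag(bg.chi_b) @ ops.G_D_dense()
        )
        ref = ops.G_S @ inv
        err = np.linalg.norm(bg.G_bS - ref) / np.linalg.norm(ref)
        assert err < 1e-8
        ref_E = np.linalg.solve(
            np.eye(ops.n_cells) - ops.G_D_dense() @ np.diag(bg.chi_b),
            fields.E_inc.T,
        ).T
        np.testing.assert_allclose(bg.E_bac, ref_E, rtol=1e-7, atol=1e-12)

    def test_weak_background_neumann_expansion(self, austria16, rng):
        m, arr, ops, fields = austria16
        chi = 1e-3 * rng.random(m.n_cells)
        bg = si.background_operators(chi, ops, fields, tol=1e-13)
        first_order = ops.G_S + (ops.G_S * chi[None, :]) @ ops.G_D_dense()
        err = np.linalg.norm(bg.G_bS - first_order)
        scale = np.linalg.norm(bg.G_bS - ops.G_S)
        assert err < 0.01 * scale  # second-order remainder only

    def test_g_bd_matches_dense_formula(self, bg16, rng):
        bg, ops, fields = bg16
        C = rng.standard_normal((3, ops.n_cells)) + 1j * rng.standard_normal(
            (3, ops.n_cells)
        )
        G_bD = ops.G_D_dense() @ np.linalg.inv(
            np.eye(ops.n_cells) - np.diag(bg.chi_b) @ ops.G_D_dense()
        )
        np.testing.assert_allclose(
            bg.g_bd_apply(C), C @ G_bD.T, rtol=1e-6, atol=1e-10
        )


class TestSubspaceBasis:
    def test_svd_identities(self, bg16):
        bg, ops, _ = bg16
        basis = si.svd_subspace(bg)
        rec = (basis.U * basis.S[None, :]) @ basis.V.conj().T
        assert np.linalg.norm(rec - bg.G_bS) / np.linalg.norm(bg.G_bS) < 1e-10
        assert np.all(np.diff(basis.S) <= 0)
        assert basis.rank <= 30
        assert np.allclose(basis.U.conj().T @ basis.U, np.eye(basis.rank),
                           atol=1e-10)

    def test_full_rank_current_reproduces_residual(self, bg16, rng):
        # with L = Nr the current is the minimum-norm solution of
        # G_bS C = residual, so it reproduces the residual exactly
        bg, ops, _ = bg16
        basis = si.svd_subspace(bg)
        residual = rng.standard_normal((4, 30)) + 1j * rng.standard_normal((4, 30))
        C = si.deterministic_current(basis, residual, basis.rank)
        np.testing.assert_allclose(C @ bg.G_bS.T, residual, rtol=1e-8)
        C_pinv = residual @ np.linalg.pinv(bg.G_bS).T
        np.testing.assert_allclose(C, C_pinv, rtol=1e-6, atol=1e-12)

    def test_zero_rank_and_orthogonal_residual_give_zero(self, bg16):
        bg, ops, _ = bg16
        basis = si.svd_subspace(bg)
        assert not np.any(si.deterministic_current(basis, np.ones((2, 30)), 0))
        # residual orthogonal to the leading L left vectors
        L = 5
        resid = basis.U[:, L + 1][None, :]
        C = si.deterministic_current(basis, resid, L)
        assert np.linalg.norm(C) < 1e-10

    def test_zero_singular_value_raises_with_index(self):
        basis = si.SubspaceBasis(
            U=np.eye(4), S=np.array([2.0, 1.0, 0.0, 0.0]), V=np.eye(4)
        )
        with pytest.raises(ValueError, match="singular value 3"):
            si.deterministic_current(basis, np.ones((1, 4)), 3)


class TestHalfMaxRank:
    @pytest.mark.parametrize(
        "S, L",
        [((4, 3, 2.1, 1.9, 1), 3), ((2, 2, 2), 3), ((1,), 1)],
    )
    def test_examples(self, S, L):
        assert si.half_max_rank(np.array(S, float)) == L

    @given(st.lists(st.floats(min_value=1e-6, max_value=1e6), min_size=1,
                    max_size=30))
    @settings(deadline=None, max_examples=50)
    def test_definition_on_sorted_spectra(self, vals):
        S = np.sort(np.asarray(vals))[::-1]
        L = si.half_max_rank(S)
        assert 1 <= L <= len(S)
        assert S[L - 1] >= S[0] / 2
        if L < len(S):
            assert S[L] < S[0] / 2


class TestTotalFieldApproximation:
    def test_zero_current_returns_secondary_incident(self, bg16):
        bg, _, _ = bg16
        E = si.total_field_approximation(bg, np.zeros_like(bg.E_bac))
        np.testing.assert_array_equal(E, bg.E_bac)

    def test_linearity_in_current(self, bg16, rng):
        bg, ops, _ = bg16
        C = rng.standard_normal((10, ops.n_cells)) + 0j
        e1 = si.total_field_approximation(bg, C) - bg.E_bac
        e2 = si.total_field_approximation(bg, 2 * C) - bg.E_bac
        np.testing.assert_allclose(e2, 2 * e1, rtol=1e-6, atol=1e-10)

    def test_error_nonincreasing_in_rank_noise_free(self, rng):
        # with the true contrast as background and exact data, adding more
        # singular triplets can only improve the total-field estimate
        n = 12
        truth = random_map(rng, n=n, eps_max=1.8, cell=2.0 / n)
        start = random_map(rng, n=n, eps_max=1.4, cell=2.0 / n)
        arr = fwd.ArrayConfig(radius=1.5, frequencies=(400e6,))
        f = 400e6
        ops = fwd.build_green_operators(truth, arr, f)
        fields = fwd.incident_field(truth, arr, f)
        fs_true = fwd.solve_total_field(truth, ops, fields, tol=1e-12)
        data = fwd.scattered_field(truth, ops, fs_true)[None]
        bg = si.background_operators(
            fwd.contrast_of(start, f), ops, fields, tol=1e-12
        )
        basis = si.svd_subspace(bg)
        resid = si.data_residual(bg, data[0])
        errs = []
        for L in range(0, basis.rank + 1, 3):
            C = si.deterministic_current(basis, resid, L)
            E = si.total_field_approximation(bg, C)
            errs.append(np.linalg.norm(E - fs_true.E_tot))
        errs = np.array(errs)
        assert errs[-1] < errs[0]
        assert np.mean(np.diff(errs)) < 0


class TestUpdateProblem:
    def _problem(self, bg16, rng, gamma=1.0):
        bg, ops, _ = bg16
        data = rng.standard_normal((1, 10, 30)) + 1j * rng.standard_normal(
            (1, 10, 30)
        )
        return si.assemble_update_problem(
            [bg], [bg.E_bac], data, gamma, None, 1.0, 0.0
        )

    def test_adjoint_consistency(self, bg16, rng):
        prob = self._problem(bg16, rng)
        x = rng.standard_normal(prob.n_unknowns)
        y = rng.standard_normal(300) + 1j * rng.standard_normal(300)
        lhs = np.vdot(y, prob.matvec(x)).real
        rhs = x @ prob.rmatvec(y)
        assert abs(lhs - rhs) <= 1e-10 * abs(lhs)

    def test_zero_update_cost_is_residual_norm(self, bg16, rng):
        prob = self._problem(bg16, rng)
        z = np.zeros(prob.n_unknowns)
        assert prob.cost(z) == pytest.approx(
            np.vdot(prob.rhs, prob.rhs).real, rel=1e-12
        )

    def test_strong_regularization_shrinks_minimizer(self, bg16, rng):
        weak = si.twist_solve(self._problem(bg16, rng, gamma=1e-2))
        strong = si.twist_solve(self._problem(bg16, rng, gamma=1e6))
        assert np.linalg.norm(strong.x) < 1e-3 * np.linalg.norm(weak.x)

    def test_empty_mask_rejected(self, bg16, rng):
        bg, ops, _ = bg16
        data = np.zeros((1, 10, 30), complex)
        with pytest.raises(ValueError, match="empty"):
            si.assemble_update_problem(
                [bg], [bg.E_bac], data, 1.0,
                np.zeros((16, 16), bool), 1.0, 0.0
            )


class TestTwist:
    def test_zero_residual_returns_zero(self, bg16, rng):
        # data exactly explained by the background: rhs = 0 and the
        # minimizer of the regularized problem is the zero update
        bg, _, _ = bg16
        data = ((bg.chi_b[None, :] * bg.E_bac) @ bg.ops.G_S.T)[None]
        prob = si.assemble_update_problem([bg], [bg.E_bac], data, 1.0, None,
                                          1.0, 0.0)
        assert np.linalg.norm(prob.rhs) < 1e-8
        res = si.twist_solve(prob)
        assert np.linalg.norm(res.x) < 1e-10
        assert res.cost <= 1e-12

    def test_matches_closed_form_and_descends(self, bg16, rng):
        bg, _, _ = bg16
        data = rng.standard_normal((1, 10, 30)) + 1j * rng.standard_normal(
            (1, 10, 30)
        )
        prob = si.assemble_update_problem([bg], [bg.E_bac], data, None, None,
                                          1.0, 0.0)
        res = si.twist_solve(prob, si.TwISTParams(max_inner=4000,
                                                  inner_tol=1e-13))
        # dense closed form of the real-parameterized normal equations
        A = np.empty((prob.rhs.size, prob.n_unknowns), complex)
        for i in range(prob.n_unknowns):
            e = np.zeros(prob.n_unknowns)
            e[i] = 1.0
            A[:, i] = prob.matvec(e)
        M = (A.conj().T @ A).real + prob.gamma * np.eye(prob.n_unknowns)
        x_ref = np.linalg.solve(M, (A.conj().T @ prob.rhs).real)
        assert np.linalg.norm(res.x - x_ref) <= 1e-6 * np.linalg.norm(x_ref)
        assert res.cost <= prob.cost(np.zeros(prob.n_unknowns)) + 1e-12
        assert res.cost == pytest.approx(prob.cost(res.x), rel=1e-10)

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            si.TwISTParams(alpha=2.5)
        with pytest.raises(ValueError):
            si.TwISTParams(beta=-1.0)


class TestNoiseFreeFixedPoint:
    def test_true_background_gives_tiny_signal_error(self, rng):
        # 8x8 toy: linearizing about the exact contrast with exact data
        # leaves a vanishing residual, so one update stays at the truth
        n = 8
        truth = random_map(rng, n=n, eps_max=1.7, cell=2.0 / n)
        arr = fwd.ArrayConfig(radius=1.5, frequencies=(400e6,))
        f = 400e6
        ops = fwd.build_green_operators(truth, arr, f)
        fields = fwd.incident_field(truth, arr, f)
        fs = fwd.solve_total_field(truth, ops, fields, tol=1e-13)
        data = fwd.scattered_field(truth, ops, fs)[None]
        bg = si.background_operators(fwd.contrast_of(truth, f), ops, fields,
                                     tol=1e-13)
        pred = (bg.chi_b[None, :] * bg.E_bac) @ ops.G_S.T
        assert xi_signal(pred[None], data) < 1e-6
        prob = si.assemble_update_problem([bg], [bg.E_bac], data, None, None,
                                          truth.eps_b, 0.0)
        res = si.twist_solve(prob)
        assert np.linalg.norm(res.x) < 1e-5
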