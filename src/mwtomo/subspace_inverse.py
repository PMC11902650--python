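"""One subspace-enhanced distorted-Born update (S-TwIST inner machinery).

The distorted Born iterative method linearizes the scattering equations
about the current estimate (the "inhomogeneous background") and solves a
regularized linear problem for the contrast perturbation.  The subspace
enhancement retrieves, before linearizing, the *deterministic* part of the
induced contrast source directly from the data: the receiver-space Green
operator of the inhomogeneous background

    G_bS = G_S (I - chi G_D)^{-1}

has a thin SVD ``G_bS = sum_i u_i s_i v_i*`` whose leading modes carry the
radiating (data-visible) part of any current.  Projecting the data residual
onto the first L modes,

    C = sum_{i<=L} (u_i* . r / s_i) v_i,        r = Esca - G_S chi E_bac,

gives an induced current that refines the total-field estimate,
``E_tot = E_bac + G_bD C``.  L = 0 recovers plain DBIM; L = Nr uses the
whole receiver-space range (and amplifies noise through the small singular
values).  The contrast update then minimizes the Tikhonov-regularized cost

    F(dx) = || r - G_bS diag(dchi(dx)) E_tot ||^2 + gamma ||dx||^2

by a two-step iterative shrinkage/thresholding (TwIST) recursion.  The real
unknown per cell is the relative-permittivity update; conductivity is
either held at zero or slaved to permittivity through the linear tissue
model, so ``dchi = c_f * dx`` with a frequency-dependent complex scalar.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .forward import EPS0, FieldSet, GreenOperators

__all__ = [
    "BackgroundOperators",
    "SubspaceBasis",
    "LinearUpdateProblem",
    "TwISTParams",
    "TwistResult",
    "TwistDivergence",
    "background_operators",
    "svd_subspace",
    "deterministic_current",
    "half_max_rank",
    "total_field_approximation",
    "data_residual",
    "assemble_update_problem",
    "twist_solve",
]


#: default Tikhonov weight as a fraction of ||A^T rhs||_inf; chosen so the
#: implied distorted-Born step stays inside the linearization's trust region
GAMMA_SCALE = 1.0


class TwistDivergence(RuntimeError):
    """TwIST cost increased over many consecutive steps."""

    def __init__(self, message, diagnostics=None):
        super().__init__(message)
        self.diagnostics = diagnostics or {}


@dataclass
class BackgroundOperators:
    """Inhomogeneous-background operators for one frequency.

    ``E_bac`` is the secondary incident field (the total field of the
    background estimate), ``G_bS`` the receiver Green operator of the
    background, both obtained from solves against ``(I - G_D diag(chi_b))``.
    ``G_bD`` is exposed matrix-free through :meth:`g_bd_apply`.
    """

    frequency: float
    chi_b: np.ndarray
    ops: GreenOperators
    E_bac: np.ndarray  # (n_tx, Ni)
    G_bS: np.ndarray  # (n_rx, Ni)
    tol: float = 1e-8
    _warm: dict = field(default_factory=dict, repr=False)

    def g_bd_apply(self, C: np.ndarray) -> np.ndarray:
        """Apply G_bD = G_D (I - chi G_D)^{-1} to currents C (n_tx, Ni).

        Uses the push-through identity
        ``(I - chi G_D)^{-1} = I + chi (I - G_D chi)^{-1} G_D`` so that the
        solve shares its operator with the background-field systems.
        """
        if not np.any(self.chi_b):
            return self.ops.gd.matvec(C)
        t = self.ops.gd.matvec(C)
        warm = self._warm.get("gbd")
        if warm is not None and warm.shape != t.shape:
            warm = None
        s = self.ops.solver(self.chi_b, tol=self.tol).solve(t, x0=warm)
        self._warm["gbd"] = s
        return self.ops.gd.matvec(C + self.chi_b[None, :] * s)


def background_operators(
    chi_b: np.ndarray,
    ops: GreenOperators,
    fields: FieldSet,
    tol: float = 1e-8,
    warm: np.ndarray | None = None,
) -> BackgroundOperators:
    """Build E_bac and G_bS for the current background contrast.

    ``E_bac`` solves ``(I - G_D diag(chi_b)) E_bac = E_inc``; the rows of
    ``G_bS`` come from the adjoint relation
    ``G_bS^T = (I - G_D diag(chi_b))^{-1} G_S^T`` (G_D is symmetric), so all
    n_tx + n_rx right-hand sides share one batched solve.  ``warm`` may
    carry the previous outer iteration's stacked solution as an initial
    guess.
    """
    chi_b = np.asarray(chi_b, dtype=complex).ravel()
    if not np.any(chi_b):
        return BackgroundOperators(
            frequency=ops.frequency,
            chi_b=chi_b,
            ops=ops,
            E_bac=fields.E_inc.copy(),
            G_bS=ops.G_S.copy(),
            tol=tol,
        )
    B = np.vstack([fields.E_inc, ops.G_S])
    if warm is not None and warm.shape != B.shape:
        warm = None
    X = ops.solver(chi_b, tol=tol).solve(B, x0=warm)
    n_tx = fields.E_inc.shape[0]
    bg = BackgroundOperators(
        frequency=ops.frequency,
        chi_b=chi_b,
        ops=ops,
        E_bac=X[:n_tx],
        G_bS=X[n_tx:],
        tol=tol,
    )
    bg._warm["stacked"] = X
    return bg


@dataclass
class SubspaceBasis:
    """Thin SVD of G_bS with an optional truncation rank."""

    U: np.ndarray  # (n_rx, r)
    S: np.ndarray  # (r,) descending, non-negative
    V: np.ndarray  # (Ni, r)
    L: int | None = None

    def __post_init__(self):
        if np.any(np.diff(self.S) > 0) or np.any(self.S < 0):
            raise ValueError("singular values must be non-negative, descending")

    @property
    def rank(self) -> int:
        return len(self.S)


def svd_subspace(bg: BackgroundOperators) -> SubspaceBasis:
    """Thin SVD of the inhomogeneous receiver Green operator."""
    try:
        U, S, Vh = np.linalg.svd(bg.G_bS, full_matrices=False)
    except np.linalg.LinAlgError as exc:  # pragma: no cover - rare
        raise RuntimeError("SVD of G_bS failed to converge") from exc
    return SubspaceBasis(U=U, S=S, V=Vh.conj().T)


def deterministic_current(
    basis: SubspaceBasis, residual: np.ndarray, L: int
) -> np.ndarray:
    """Deterministic induced current from the leading L singular triplets.

    ``residual`` has shape (n_tx, n_rx); the result has shape (n_tx, Ni).
    L = 0 returns the zero current (plain DBIM).
    """
    residual = np.atleast_2d(residual)
    n_tx = residual.shape[0]
    if not 0 <= L <= basis.rank:
        raise ValueError(f"L={L} outside [0, {basis.rank}]")
    if L == 0:
        return np.zeros((n_tx, basis.V.shape[0]), dtype=complex)
    if np.any(basis.S[:L] == 0):
        bad = int(np.argmax(basis.S[:L] == 0)) + 1
        raise ValueError(
            f"singular value {bad} is zero; lower L below the numerical rank"
        )
    coeff = (basis.U[:, :L].conj().T @ residual.T) / basis.S[:L, None]
    return (basis.V[:, :L] @ coeff).T


def half_max_rank(S: np.ndarray) -> int:
    """Largest L whose singular value is at least half the leading one.

    This is the empirical sweet spot between information preservation and
    noise suppression for the subspace current.
    """
    S = np.asarray(S, dtype=float)
    if S.size == 0:
        raise ValueError("empty singular-value array")
    return int(np.sum(S >= S[0] / 2.0))


def total_field_approximation(bg: BackgroundOperators, C: np.ndarray) -> np.ndarray:
    """``E_tot = E_bac + G_bD . C`` (matrix-free G_bD application)."""
    if not np.any(C):
        return bg.E_bac.copy()
    return bg.E_bac + bg.g_bd_apply(C)


def data_residual(bg: BackgroundOperators, data_f: np.ndarray) -> np.ndarray:
    """``r = Esca - G_S . chi_b . E_bac`` for one frequency, (n_tx, n_rx)."""
    return data_f - (bg.chi_b[None, :] * bg.E_bac) @ bg.ops.G_S.T


def contrast_coefficient(
    frequency: float,
    eps_b: float,
    sigma_slope: float = 0.0,
    eps_r=None,
):
    """d(chi)/d(eps_r) when conductivity is slaved to permittivity.

    ``dchi = dx/eps_b - j (d sigma/d eps_r) dx/(omega eps0 eps_b)`` with the
    tissue-model derivative ``sigma_slope`` above the clamp root of the
    linear fit and 0 below it (conductivity is floored at zero there).
    Passing the current per-cell permittivity ``eps_r`` yields a per-cell
    coefficient vector; otherwise a scalar with the full slope is returned.
    """
    omega = 2 * np.pi * frequency
    if sigma_slope == 0.0 or eps_r is None:
        return 1.0 / eps_b - 1j * sigma_slope / (omega * EPS0 * eps_b)
    from .phantoms import SIGMA_INTERCEPT, SIGMA_SLOPE

    root = -SIGMA_INTERCEPT / SIGMA_SLOPE if sigma_slope == SIGMA_SLOPE else 0.0
    slope_vec = np.where(np.asarray(eps_r, dtype=float) > root, sigma_slope, 0.0)
    return 1.0 / eps_b - 1j * slope_vec / (omega * EPS0 * eps_b)


@dataclass
class LinearUpdateProblem:
    """Stacked linear problem for the real permittivity update.

    The operator maps the masked, real-valued permittivity perturbation to
    the complex prediction ``G_bS diag(dchi) E_tot`` stacked over
    (frequency, tx, rx) in row-major order; ``rhs`` is the stacked data
    residual.  The adjoint is the real part of the complex adjoint, matching
    the real parameterization of the unknown.
    """

    P: list  # per freq: E_tot restricted to mask, (n_tx, n_mask)
    Q: list  # per freq: c_f * G_bS restricted to mask, (n_rx, n_mask)
    rhs: np.ndarray  # stacked complex residual
    gamma: float
    n_unknowns: int
    mask_indices: np.ndarray
    #: optional per-cell box [lb, ub] on the permittivity update, derived
    #: from the prior bounds and the current estimate; enforced inside the
    #: proximal step so the solver fits the data within the feasible cone
    #: instead of spending the step on directions the projection removes
    lb: np.ndarray | None = None
    ub: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    def matvec(self, x: np.ndarray) -> np.ndarray:
        out = [((P * x[None, :]) @ Q.T).ravel() for P, Q in zip(self.P, self.Q)]
        return np.concatenate(out)

    def rmatvec(self, y: np.ndarray) -> np.ndarray:
        out = np.zeros(self.n_unknowns)
        off = 0
        for P, Q in zip(self.P, self.Q):
            n_tx, n_rx = P.shape[0], Q.shape[0]
            Y = y[off : off + n_tx * n_rx].reshape(n_tx, n_rx)
            out += np.einsum("ti,ti->i", P.conj(), Y @ Q.conj()).real
            off += n_tx * n_rx
        return out

    def cost(self, x: np.ndarray) -> float:
        r = self.rhs - self.matvec(x)
        return float(np.vdot(r, r).real + self.gamma * (x @ x))


def assemble_update_problem(
    bgs: list,
    E_tots: list,
    data: np.ndarray,
    gamma: float | None,
    mask: np.ndarray | None,
    eps_b: float,
    sigma_slope: float = 0.0,
    eps_r: np.ndarray | None = None,
) -> LinearUpdateProblem:
    """Assemble the stacked Tikhonov problem over a frequency group.

    ``data`` holds the measured scattered field for the same frequencies as
    ``bgs``, shape (n_freq, n_tx, n_rx).  ``mask`` restricts the unknowns
    (reconstruction prior); None means every cell.  ``gamma=None`` applies
    the scale-aware default ``GAMMA_SCALE * ||A^T rhs||_inf``; the weight
    both conditions the linear problem and damps the outer distorted-Born
    step, so it must be large enough to keep successive updates inside the
    linearization's validity region.
    """
    data = np.asarray(data, dtype=complex)
    if len(bgs) != len(E_tots) or len(bgs) != data.shape[0]:
        raise ValueError("inconsistent frequency stacking")
    ni = bgs[0].ops.n_cells
    if mask is None:
        idx = np.arange(ni)
    else:
        idx = np.flatnonzero(np.asarray(mask, dtype=bool).ravel())
        if idx.size == 0:
            raise ValueError("empty reconstruction mask")
    eps_sel = None if eps_r is None else np.asarray(eps_r).ravel()[idx]
    P, Q, rhs = [], [], []
    for bg, E_tot, data_f in zip(bgs, E_tots, data):
        c = contrast_coefficient(bg.frequency, eps_b, sigma_slope, eps_sel)
        P.append(E_tot[:, idx])
        Q.append(c * bg.G_bS[:, idx])
        rhs.append(data_residual(bg, data_f).ravel())
    rhs = np.concatenate(rhs)
    prob = LinearUpdateProblem(
        P=P, Q=Q, rhs=rhs, gamma=0.0, n_unknowns=idx.size, mask_indices=idx
    )
    if gamma is None:
        gamma = GAMMA_SCALE * float(np.max(np.abs(prob.rmatvec(rhs)))) if rhs.size else 0.0
    if gamma < 0:
        raise ValueError("gamma must be non-negative")
    prob.gamma = float(gamma)
    return prob


@dataclass
class TwISTParams:
    """Two-step iteration weights and stopping control.

    ``alpha``/``beta`` default to the spectral rule for the Tikhonov
    normal system (eigenvalues in [g, 1 + g] after operator normalization,
    g the scaled regularization weight): ``alpha = 2/(1 + sqrt(1 - rho^2))``
    with ``rho = 1/(1 + 2 g)`` and ``beta = 2 alpha (1 + g)/(1 + 2 g)``.
    """

    alpha: float | None = None
    beta: float | None = None
    max_inner: int = 200
    inner_tol: float = 1e-5

    def __post_init__(self):
        if self.alpha is not None and not 0 < self.alpha < 2:
            raise ValueError("alpha must lie in (0, 2)")
        if self.beta is not None and self.beta <= 0:
            raise ValueError("beta must be positive")


@dataclass
class TwistResult:
    x: np.ndarray
    cost: float
    diagnostics: dict


def twist_solve(
    problem: LinearUpdateProblem, params: TwISTParams | None = None
) -> TwistResult:
    """Minimize ``||rhs - A x||^2 + gamma ||x||^2`` by the TwIST recursion.

        x_{k+1} = (1 - alpha) x_{k-1} + (alpha - beta) x_k
                  + beta Psi(x_k + A^H (y - A x_k)),   Psi(v) = v / (1 + gamma)

    applied after normalizing the operator to unit spectral norm (the
    classical TwIST stability condition).  With the linear Tikhonov proximal
    map the recursion is a stationary two-step Richardson iteration whose
    fixed point is the regularized normal-equations solution.
    """
    params = params or TwISTParams()
    n = problem.n_unknowns
    y = problem.rhs
    if not np.any(y):
        return TwistResult(
            x=np.zeros(n),
            cost=0.0,
            diagnostics={"iterations": 0, "cost_initial": 0.0, "cost_final": 0.0,
                         "gamma": problem.gamma, "converged": True},
        )

    # spectral-norm estimate of A by power iteration on A^T A; the start
    # vector mixes a deterministic direction with a seeded random one so a
    # poor overlap with the top eigenvector cannot stall the iteration
    pi_rng = np.random.default_rng(0)
    v = np.ones(n) + 0.5 * pi_rng.standard_normal(n)
    v /= np.linalg.norm(v)
    s2 = 0.0
    for _ in range(100):
        w = problem.rmatvec(problem.matvec(v))
        nw = np.linalg.norm(w)
        if nw == 0:
            break
        if s2 > 0 and abs(nw - s2) <= 1e-4 * s2:
            s2 = nw
            break
        s2 = nw
        v = w / nw
    if s2 == 0:
        return TwistResult(np.zeros(n), float(np.vdot(y, y).real),
                           {"iterations": 0, "gamma": problem.gamma,
                            "converged": True})
    s2 *= 1.15  # margin so the normalized operator has norm <= 1
    gbar = problem.gamma / s2

    alpha, beta = params.alpha, params.beta
    if alpha is None or beta is None:
        # smallest eigenvalue of the normalized normal system: gbar exactly
        # when A has a null space, so the two-step weights must not assume
        # a larger floor or the null-space components become unstable
        a = max(gbar, 1e-12)
        rho = 1.0 / (1.0 + 2.0 * a)
        alpha_d = 2.0 / (1.0 + np.sqrt(1.0 - rho**2))
        beta_d = 2.0 * alpha_d * (1.0 + gbar) / (1.0 + 2.0 * a)
        alpha = alpha_d if alpha is None else alpha
        beta = beta_d if beta is None else beta

    s = np.sqrt(s2)
    ybar = y / s
    shrink = 1.0 / (1.0 + gbar)
    if problem.lb is not None or problem.ub is not None:
        lb = -np.inf if problem.lb is None else problem.lb
        ub = np.inf if problem.ub is None else problem.ub
        psi = lambda v: np.clip(shrink * v, lb, ub)
    else:
        psi = lambda v: shrink * v

    x_old = np.zeros(n)
    x = np.zeros(n)
    Ax = np.zeros_like(ybar)
    cost_prev = np.inf
    cost_best = np.inf
    f0 = float(np.vdot(ybar, ybar).real) * s2
    n_increase = 0
    converged = False
    k = 0
    for k in range(1, params.max_inner + 1):
        r = ybar - Ax
        cost_here = float((np.vdot(r, r).real + gbar * (x @ x)) * s2)
        # the projected two-step recursion may oscillate benignly near a
        # constraint face; declare divergence only for sustained growth
        # clearly above the best cost reached so far
        if cost_here > cost_prev * (1 + 1e-12):
            n_increase += 1
            if n_increase >= 10 and cost_here > 1.01 * cost_best:
                raise TwistDivergence(
                    "TwIST cost increased over 10 consecutive steps",
                    diagnostics={"iterations": k, "cost_initial": f0,
                                 "cost_last": cost_here, "gamma": problem.gamma,
                                 "alpha": alpha, "beta": beta},
                )
        else:
            n_increase = 0
        cost_prev = cost_here
        cost_best = min(cost_best, cost_here)
        grad_pt = x + problem.rmatvec(r) / s
        if k == 1:
            x_new = psi(grad_pt)  # plain IST first step
        else:
            x_new = (1 - alpha) * x_old + (alpha - beta) * x + beta * psi(grad_pt)
        step = np.linalg.norm(x_new - x)
        x_old, x = x, x_new
        Ax = problem.matvec(x) / s
        if step <= params.inner_tol * max(np.linalg.norm(x_old), 1e-300):
            converged = True
            break
    r = ybar - Ax
    cost_final = float((np.vdot(r, r).real + gbar * (x @ x)) * s2)
    return TwistResult(
        x=x,
        cost=cost_final,
        diagnostics={
            "iterations": k,
            "cost_initial": f0,
            "cost_final": cost_final,
            "gamma": problem.gamma,
            "alpha": float(alpha),
            "beta": float(beta),
            "converged": converged,
        },
    )
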