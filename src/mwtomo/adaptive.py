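"""Outer reconstruction loop with adaptive subspace-rank selection.

The distorted-Born outer iteration alternates between rebuilding the
inhomogeneous-background operators at the current estimate and solving one
regularized linear update.  Robustness to unknown noise hinges on the
subspace truncation rank L: too large and the small singular values
amplify noise into the induced current, too small and the total-field
estimate is biased.  Rather than fixing L, the adaptive policy evaluates a
small candidate set (default L = 5, 10, 15, 20) every outer iteration on a
half-resolution copy of the problem and keeps the rank whose regularized
cost is smallest; only the chosen rank crosses back to full resolution,
where the update is recomputed.  Measurements are grouped by frequency
(low to high, default three per group, five outer iterations per group)
for multi-frequency scenarios.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field, replace

import numpy as np

from . import forward as fwd
from .forward import ArrayConfig, MeasurementSet
from .metrics_io import xi_pixel
from .phantoms import DielectricMap, downsample, sigma_from_eps
from .solvers import SolverFailure
from .subspace_inverse import (
    TwISTParams,
    TwistDivergence,
    assemble_update_problem,
    background_operators,
    data_residual,
    deterministic_current,
    svd_subspace,
    total_field_approximation,
    twist_solve,
)

__all__ = [
    "ReconConfig",
    "IterationRecord",
    "ReconResult",
    "frequency_schedule",
    "evaluate_candidates",
    "select_L",
    "reconstruct",
    "born_initial_guess",
]


@dataclass
class ReconConfig:
    """Reconstruction policy and stopping control.

    ``policy`` is "adaptive" (rank chosen per iteration from
    ``l_candidates`` by half-resolution cost evaluation) or "fixed"
    (``fixed_L`` throughout; 0 is plain DBIM).  ``outer_tol`` stops the
    outer loop when the relative change of the permittivity estimate falls
    below it.  ``bounds`` is the permittivity prior interval enforced by
    projection after every update; ``sigma_slope`` > 0 slaves conductivity
    to permittivity through the linear tissue model.  ``init`` selects the
    starting estimate: "born" (linearized inversion from the homogeneous
    background), "lower_bound", or "custom" (caller-supplied map).
    """

    policy: str = "adaptive"
    fixed_L: int = 0
    l_candidates: tuple[int, ...] = (5, 10, 15, 20)
    coarse_factor: int = 2
    outer_tol: float = 1e-4
    max_outer: int = 50
    freq_group_size: int = 3
    iters_per_group: int = 5
    bounds: tuple[float, float] = (1.0, 3.0)
    init: str = "born"
    gamma: float | None = None
    sigma_slope: float = 0.0
    solver_tol: float = 1e-5  # background-operator solves; looser than the
    # forward simulator since the linearization error dominates the update
    carry_coarse_solution: bool = False
    twist: TwISTParams = field(default_factory=TwISTParams)

    def __post_init__(self):
        if self.policy not in ("adaptive", "fixed"):
            raise ValueError("policy must be 'adaptive' or 'fixed'")
        if self.coarse_factor < 1:
            raise ValueError("coarse_factor must be >= 1")
        if self.outer_tol <= 0:
            raise ValueError("outer_tol must be positive")
        if self.init not in ("born", "lower_bound", "custom"):
            raise ValueError("init must be born | lower_bound | custom")
        if min(self.l_candidates, default=0) < 0:
            raise ValueError("l_candidates must be non-negative")


@dataclass
class IterationRecord:
    """Bookkeeping for one outer iteration (one convergence-curve point)."""

    outer_index: int
    frequency_group: tuple[float, ...]
    chosen_L: int
    candidate_costs: dict | None
    cost: float
    rel_update: float  # relative change of the solution norm (stop criterion)
    rel_step: float = 0.0  # relative size of the raw update step (diagnostic)
    xi_pixel: float | None = None


@dataclass
class ReconResult:
    """Final reconstruction plus full iteration history."""

    map: DielectricMap
    history: list[IterationRecord]
    config: ReconConfig
    xi_initial: float | None = None
    meta: dict = field(default_factory=dict)

    @property
    def converged(self) -> bool:
        return bool(self.meta.get("converged", False))

    @property
    def final_xi_pixel(self) -> float | None:
        return self.history[-1].xi_pixel if self.history else self.xi_initial

    @property
    def final_cost(self) -> float | None:
        return self.history[-1].cost if self.history else None


def frequency_schedule(frequencies, group_size: int, iters_per_group: int):
    """Partition frequencies into low-to-high groups and repeat each group.

    Groups hold ``group_size`` consecutive frequencies (the last group keeps
    the remainder) and each group is emitted ``iters_per_group`` times, so
    ten frequencies with groups of three yield groups of sizes (3, 3, 3, 1)
    and 20 outer steps at five iterations each.
    """
    freqs = tuple(float(f) for f in frequencies)
    if not freqs:
        raise ValueError("empty frequency list")
    if list(freqs) != sorted(freqs):
        raise ValueError("frequencies must be sorted ascending")
    if group_size < 1 or iters_per_group < 1:
        raise ValueError("group_size and iters_per_group must be >= 1")
    groups = [freqs[i : i + group_size] for i in range(0, len(freqs), group_size)]
    return [g for g in groups for _ in range(iters_per_group)]


def select_L(candidate_costs: dict) -> int:
    """Candidate with the smallest finite cost; ties break to smaller L."""
    finite = {int(L): c for L, c in candidate_costs.items() if np.isfinite(c)}
    if not finite:
        raise ValueError(
            "all candidate costs are non-finite; fall back to L = 0 (plain DBIM)"
        )
    best = min(finite.items(), key=lambda kv: (kv[1], kv[0]))
    return best[0]


def _coarsen_for_eval(m: DielectricMap, factor: int) -> DielectricMap:
    """Block-average a map for candidate evaluation, cropping odd edges.

    When the grid size is not divisible by ``factor`` the trailing rows or
    columns (domain-boundary background cells) are cropped before block
    averaging; the grid origin is shifted so cell centers stay aligned with
    the physical geometry.
    """
    n1, n2 = m.shape
    r1, r2 = n1 % factor, n2 % factor
    if r1 or r2:
        m = replace(
            m,
            eps_r=m.eps_r[: n1 - r1, : n2 - r2],
            sigma=m.sigma[: n1 - r1, : n2 - r2],
            mask=None if m.mask is None else m.mask[: n1 - r1, : n2 - r2],
            origin=(
                m.origin[0] - r1 * m.cell_size / 2.0,
                m.origin[1] - r2 * m.cell_size / 2.0,
            ),
        )
    out = downsample(m, factor)
    if min(out.shape) < 8:
        raise ValueError("coarse grid too small (< 8 cells per axis)")
    return out


@dataclass
class ReconState:
    """Mutable context shared by the outer loop and candidate evaluation."""

    current: DielectricMap
    array: ArrayConfig
    config: ReconConfig
    freq_group: tuple[float, ...]
    caches: dict = field(default_factory=dict)


def _freq_indices(meas: MeasurementSet, group) -> list[int]:
    return [meas.frequencies.index(f) for f in group]


#: extra tolerance slack for the half-resolution candidate evaluation — it
#: only ranks candidate ranks, so its solves can be cruder than the update's
COARSE_TOL_FACTOR = 10.0


def _group_background(state, m, meas, coarse: bool):
    """Background operators + bases for the active group on one grid."""
    cfg = state.config
    key = "coarse" if coarse else "full"
    caches = state.caches.setdefault(key, {"ops": {}, "fields": {}, "warm": {}})
    tol = cfg.solver_tol * (COARSE_TOL_FACTOR if coarse else 1.0)
    bgs = []
    for fi in _freq_indices(meas, state.freq_group):
        f = meas.frequencies[fi]
        if fi not in caches["ops"]:
            caches["ops"][fi] = fwd.build_green_operators(m, state.array, f)
            caches["fields"][fi] = fwd.incident_field(m, state.array, f)
        chi_b = fwd.contrast_of(m, f)
        bg = background_operators(
            chi_b,
            caches["ops"][fi],
            caches["fields"][fi],
            tol=tol,
            warm=caches["warm"].get(fi),
        )
        caches["warm"][fi] = bg._warm.get("stacked")
        gbd_key = ("gbd", fi)
        if gbd_key in caches["warm"]:
            bg._warm["gbd"] = caches["warm"][gbd_key]
        bgs.append((fi, bg))
    return bgs, caches


def _subspace_update(state, bgs, data, L, mask, eps_b, caches=None, gamma=None,
                     eps_r=None):
    """One full S-TwIST update for a fixed rank L; returns (dx, cost, diag)."""
    cfg = state.config
    E_tots = []
    for fi, bg in bgs:
        if L == 0:
            E_tots.append(bg.E_bac)
            continue
        basis = svd_subspace(bg)
        Lf = min(L, basis.rank)
        res = data_residual(bg, data[_data_row(bgs, fi)])
        C = deterministic_current(basis, res, Lf)
        E_tots.append(total_field_approximation(bg, C))
        if caches is not None:
            caches["warm"][("gbd", fi)] = bg._warm.get("gbd")
    prob = assemble_update_problem(
        [bg for _, bg in bgs],
        E_tots,
        data,
        cfg.gamma if gamma is None else gamma,
        mask,
        eps_b,
        cfg.sigma_slope,
        eps_r,
    )
    if eps_r is not None:
        _set_update_box(prob, eps_r, cfg.bounds)
    result = twist_solve(prob, cfg.twist)
    return result.x, result.cost, result.diagnostics, prob


def _set_update_box(prob, eps_r, bounds):
    """Constrain the permittivity update so eps stays inside the prior box."""
    lo, hi = bounds
    e = np.asarray(eps_r).ravel()[prob.mask_indices]
    prob.lb = lo - e
    prob.ub = hi - e


def _data_row(bgs, fi):
    return [i for i, (fj, _) in enumerate(bgs) if fj == fi][0]


def evaluate_candidates(
    state: ReconState,
    meas: MeasurementSet,
    candidates,
    coarse_factor: int,
):
    """Cost of each candidate rank on the half-resolution problem.

    The current map (and its mask) is block-averaged onto the coarse grid;
    the physical measurements are unchanged — only operators and unknowns
    are coarsened.  Returns ``{L: (cost, dx_coarse)}``.
    """
    if not candidates:
        raise ValueError("empty candidate list")
    candidates = [int(L) for L in candidates]
    cm = _coarsen_for_eval(state.current, coarse_factor)
    fis = _freq_indices(meas, state.freq_group)
    data = meas.data[fis]
    bgs, caches = _group_background(state, cm, meas, coarse=True)
    # one regularization weight per frequency group, frozen at first visit,
    # so candidate costs are directly comparable across L and iterations
    gammas = state.caches.setdefault("gamma_coarse", {})
    gamma = gammas.get(state.freq_group)

    # all candidates share E_bac, G_bS and the SVD; their induced-current
    # fields are obtained from one batched G_bD solve per frequency
    E_tots = {L: [] for L in candidates}
    try:
        for k, (fi, bg) in enumerate(bgs):
            basis = svd_subspace(bg)
            res = data_residual(bg, data[k])
            n_tx = res.shape[0]
            stacked = np.concatenate(
                [deterministic_current(basis, res, min(L, basis.rank))
                 for L in candidates]
            )
            fields = bg.E_bac[None, :, :] + bg.g_bd_apply(stacked).reshape(
                len(candidates), n_tx, -1
            )
            for j, L in enumerate(candidates):
                E_tots[L].append(fields[j])
    except (SolverFailure, ValueError):
        return {L: (np.inf, None) for L in candidates}

    # ranking candidates does not need the update solved to full depth:
    # a lighter inner budget keeps the cost ordering while cutting the
    # evaluation's share of the outer-iteration cost
    tw = state.config.twist
    tw_coarse = TwISTParams(
        alpha=tw.alpha,
        beta=tw.beta,
        max_inner=min(tw.max_inner, 100),
        inner_tol=max(tw.inner_tol, 1e-4),
    )
    out = {}
    for L in candidates:
        try:
            prob = assemble_update_problem(
                [bg for _, bg in bgs], E_tots[L], data, gamma,
                cm.mask, cm.eps_b, state.config.sigma_slope, cm.eps_r,
            )
            _set_update_box(prob, cm.eps_r, state.config.bounds)
            if gamma is None:
                gamma = gammas[state.freq_group] = prob.gamma
            result = twist_solve(prob, tw_coarse)
            dx, cost = result.x, result.cost
        except (TwistDivergence, ValueError):
            dx, cost = None, np.inf
        out[L] = (float(cost), dx)
    return out


def _upsample_dx(dx, coarse_map, fine_map, factor):
    """Nearest-neighbour upsampling of a coarse masked update to full grid."""
    full = np.zeros(coarse_map.n_cells)
    idxc = (
        np.arange(coarse_map.n_cells)
        if coarse_map.mask is None
        else np.flatnonzero(coarse_map.mask.ravel())
    )
    full[idxc] = dx
    fine = np.kron(full.reshape(coarse_map.shape), np.ones((factor, factor)))
    n1, n2 = fine_map.shape
    padded = np.zeros((n1, n2))
    padded[: fine.shape[0], : fine.shape[1]] = fine
    idxf = (
        np.arange(fine_map.n_cells)
        if fine_map.mask is None
        else np.flatnonzero(fine_map.mask.ravel())
    )
    return padded.ravel()[idxf]


def reconstruct(
    meas: MeasurementSet,
    config: ReconConfig,
    array: ArrayConfig | None = None,
    domain: DielectricMap | None = None,
    truth: DielectricMap | None = None,
    init_map: DielectricMap | None = None,
) -> ReconResult:
    """Run the full adaptive (or fixed-rank) reconstruction.

    ``domain`` supplies the reconstruction grid, background medium and
    optional support mask (it is reset to background before use); ``truth``
    enables per-iteration image-error bookkeeping.  The frequency schedule
    is extended by repeating its last group until ``max_outer`` so that
    single-frequency scenarios can iterate to convergence.
    """
    array = array or meas.array
    if domain is None:
        raise ValueError("a domain map (grid + background + mask) is required")
    cfg = config
    lo, hi = cfg.bounds

    if cfg.init == "custom":
        if init_map is None:
            raise ValueError("init='custom' requires init_map")
        current = init_map.copy()
    elif cfg.init == "lower_bound":
        # keep any known structure the domain map carries outside the mask
        # (e.g. a skin ring supplied as prior); only masked cells start at
        # the lower bound
        current = domain.copy()
        inside = slice(None) if current.mask is None else current.mask
        current.eps_r[inside] = lo
        if cfg.sigma_slope > 0:
            current.sigma[inside] = sigma_from_eps(current.eps_r[inside])
        else:
            current.sigma[inside] = current.sigma_b
    else:  # born
        current = born_initial_guess(meas, array, domain, config=cfg)

    mask = current.mask
    idx = np.arange(current.n_cells) if mask is None else np.flatnonzero(mask.ravel())
    xi0 = None if truth is None else xi_pixel(current, truth, mask)

    schedule = frequency_schedule(
        meas.frequencies, cfg.freq_group_size, cfg.iters_per_group
    )
    while len(schedule) < cfg.max_outer:
        schedule.append(schedule[-1])
    schedule = schedule[: cfg.max_outer]

    history: list[IterationRecord] = []
    meta = {"converged": False, "aborted": None, "array_radius": array.radius,
            "snr_db": meas.snr_db, "noise_seed": meas.noise_seed,
            "wall_time_s": None}
    t0 = time.time()
    state = ReconState(current=current, array=array, config=cfg, freq_group=())

    for outer, group in enumerate(schedule, start=1):
        state.current = current
        state.freq_group = tuple(group)
        try:
            bgs, caches = _group_background(state, current, meas, coarse=False)
            fis = _freq_indices(meas, group)
            data = meas.data[fis]
            candidate_costs = None
            dx_coarse = None
            if cfg.policy == "adaptive":
                cand = evaluate_candidates(
                    state, meas, cfg.l_candidates, cfg.coarse_factor
                )
                candidate_costs = {L: c for L, (c, _) in cand.items()}
                chosen_L = select_L(candidate_costs)
                dx_coarse = cand[chosen_L][1]
            else:
                chosen_L = int(cfg.fixed_L)
            gammas = state.caches.setdefault("gamma_full", {})
            gamma = gammas.get(state.freq_group)
            dx, cost, diag, prob = _subspace_update(
                state, bgs, data, chosen_L, mask, current.eps_b, caches, gamma,
                current.eps_r,
            )
            if gamma is None:
                gammas[state.freq_group] = prob.gamma
            if cfg.carry_coarse_solution and dx_coarse is not None:
                # optional variant: keep the upsampled coarse update instead
                cm = _coarsen_for_eval(current, cfg.coarse_factor)
                dx = _upsample_dx(dx_coarse, cm, current, cfg.coarse_factor)
        except (TwistDivergence, SolverFailure) as exc:
            meta["aborted"] = f"{type(exc).__name__}: {exc}"
            break

        eps_old = current.eps_r.ravel()[idx].copy()
        eps_flat = current.eps_r.ravel()
        eps_flat[idx] = np.clip(eps_flat[idx] + dx, lo, hi)
        current.eps_r = eps_flat.reshape(current.shape)
        if cfg.sigma_slope > 0:
            sig = current.sigma.ravel()
            sig[idx] = sigma_from_eps(eps_flat[idx])
            current.sigma = sig.reshape(current.shape)
        # convergence is judged on the relative update of the solution norm
        # (the estimate's norm stabilizes at the noise plateau even though
        # individual pixels keep fluctuating); the raw step size is kept as
        # a diagnostic
        norm_old = np.linalg.norm(eps_old)
        rel_update = float(
            abs(np.linalg.norm(eps_flat[idx]) - norm_old) / max(norm_old, 1e-300)
        )
        rel_step = float(
            np.linalg.norm(eps_flat[idx] - eps_old) / max(norm_old, 1e-300)
        )
        history.append(
            IterationRecord(
                outer_index=outer,
                frequency_group=tuple(group),
                chosen_L=chosen_L,
                candidate_costs=candidate_costs,
                cost=float(cost),
                rel_update=rel_update,
                rel_step=rel_step,
                xi_pixel=None if truth is None else xi_pixel(current, truth, mask),
            )
        )
        if rel_update < cfg.outer_tol:
            meta["converged"] = True
            break

    meta["wall_time_s"] = time.time() - t0
    return ReconResult(
        map=current, history=history, config=cfg, xi_initial=xi0, meta=meta
    )


def born_initial_guess(
    meas: MeasurementSet,
    array: ArrayConfig,
    domain: DielectricMap,
    gamma: float | None = None,
    config: ReconConfig | None = None,
) -> DielectricMap:
    """Linearized (Born) inversion from the homogeneous background.

    Approximates ``Esca ~ G_S diag(chi) E_inc`` and solves the Tikhonov
    least-squares problem for the permittivity perturbation, then clips to
    the configured bounds.  Zero measurements return the background map.
    """
    cfg = config or ReconConfig()
    m = domain.background_like()
    bgs = []
    for f in meas.frequencies:
        ops = fwd.build_green_operators(m, array, f)
        fields = fwd.incident_field(m, array, f)
        chi0 = np.zeros(m.n_cells, dtype=complex)
        bgs.append(background_operators(chi0, ops, fields, tol=cfg.solver_tol))
    prob = assemble_update_problem(
        bgs,
        [bg.E_bac for bg in bgs],
        meas.data,
        gamma if gamma is not None else cfg.gamma,
        m.mask,
        m.eps_b,
        cfg.sigma_slope,
        m.eps_r,
    )
    # no in-solver box here: the linearized Born problem is underdetermined
    # and the Tikhonov term alone should select the minimum-norm image;
    # bounds are enforced by clipping afterwards
    result = twist_solve(prob, cfg.twist)
    lo, hi = cfg.bounds
    idx = np.arange(m.n_cells) if m.mask is None else np.flatnonzero(m.mask.ravel())
    eps_flat = m.eps_r.ravel()
    eps_flat[idx] = np.clip(eps_flat[idx] + result.x, lo, hi)
    m.eps_r = eps_flat.reshape(m.shape)
    if cfg.sigma_slope > 0:
        sig = m.sigma.ravel()
        sig[idx] = sigma_from_eps(eps_flat[idx])
        m.sigma = sig.reshape(m.shape)
    return m
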