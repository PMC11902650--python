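"""Frequency-domain forward scattering simulator (2D TMz).

A circular transceiver array surrounds a square domain of interest.  Each
antenna is a unit-amplitude electric line source; the field obeys the
scalar volume integral equation

    E_tot = E_inc + G_D . chi . E_tot,        E_sca = G_S . chi . E_tot,

with the outgoing 2D Green kernel ``-(j k_b^2 / 4) H0^(2)(k_b |r - r'|)``
(time convention ``e^{+j omega t}``).  The discretization is a pulse-basis /
point-matching method of moments: kernel entries are integrated over an
equal-area disk per cell (Richmond's rule), which yields closed forms for
both the off-diagonal and the singular self term.

The contrast is ``chi = eps_r/eps_b - 1 - j (sigma - sigma_b)/(omega eps0 eps_b)``,
with the conductivity term normalized by the absolute background
permittivity so that chi is dimensionless.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import hankel2, jv

from .phantoms import DielectricMap
from .solvers import ConvolutionOperator, ScatteringSolver

__all__ = [
    "EPS0",
    "MU0",
    "C0",
    "ArrayConfig",
    "GreenOperators",
    "FieldSet",
    "MeasurementSet",
    "build_green_operators",
    "incident_field",
    "contrast_of",
    "solve_total_field",
    "scattered_field",
    "add_noise",
    "simulate_experiment",
]

EPS0 = 8.8541878128e-12  # F/m
MU0 = 4e-7 * np.pi  # H/m
C0 = 1.0 / np.sqrt(EPS0 * MU0)  # m/s


def _default_tx(n_antennas: int, n_tx: int) -> tuple[int, ...]:
    """Uniformly spaced transmitting subset (every n/n_tx-th antenna)."""
    if n_antennas % n_tx:
        raise ValueError("n_tx must divide n_antennas for the default subset")
    step = n_antennas // n_tx
    return tuple(range(0, n_antennas, step))


@dataclass(frozen=True)
class ArrayConfig:
    """Circular transceiver array geometry and frequency list.

    By default 30 antennas are uniformly distributed on a ring and every
    third one transmits (10 transmitters, 30 receivers).
    """

    radius: float
    frequencies: tuple[float, ...]
    n_antennas: int = 30
    tx_indices: tuple[int, ...] | None = None

    def __post_init__(self):
        freqs = tuple(float(f) for f in self.frequencies)
        if any(f <= 0 for f in freqs):
            raise ValueError("frequencies must be positive")
        if list(freqs) != sorted(freqs):
            raise ValueError("frequencies must be sorted ascending")
        object.__setattr__(self, "frequencies", freqs)
        tx = self.tx_indices
        if tx is None:
            tx = _default_tx(self.n_antennas, 10)
        tx = tuple(int(i) for i in tx)
        if not set(tx) <= set(range(self.n_antennas)):
            raise ValueError("tx_indices must be valid antenna indices")
        object.__setattr__(self, "tx_indices", tx)
        if self.radius <= 0:
            raise ValueError("radius must be positive")

    @property
    def n_tx(self) -> int:
        return len(self.tx_indices)

    @property
    def n_rx(self) -> int:
        return self.n_antennas

    def positions(self) -> np.ndarray:
        """Antenna coordinates, shape (n_antennas, 2)."""
        ang = 2 * np.pi * np.arange(self.n_antennas) / self.n_antennas
        return self.radius * np.column_stack([np.cos(ang), np.sin(ang)])

    def tx_positions(self) -> np.ndarray:
        return self.positions()[list(self.tx_indices)]


def wavenumber(frequency: float, eps_b: float, sigma_b: float = 0.0) -> complex:
    """Background wavenumber; real in the lossless case."""
    omega = 2 * np.pi * frequency
    k = omega * np.sqrt(MU0 * EPS0 * eps_b)
    if sigma_b == 0.0:
        return k
    return k * np.sqrt(1.0 - 1j * sigma_b / (omega * EPS0 * eps_b))


@dataclass
class GreenOperators:
    """Homogeneous-background Green matrices for one frequency.

    G_S maps cell currents to the receiver ring (dense, Nr x Ni); the
    domain-to-domain operator G_D is held as an FFT convolution and applied
    matrix-free (``gd.matvec``); ``gd.dense()`` materializes it on small
    grids.  Both use cell-integrated (equal-area disk) kernel entries.
    """

    frequency: float
    k_b: complex
    cell_size: float
    shape: tuple[int, int]
    G_S: np.ndarray
    gd: ConvolutionOperator
    rx_pos: np.ndarray
    tx_pos: np.ndarray

    @property
    def n_cells(self) -> int:
        return self.shape[0] * self.shape[1]

    def G_D_dense(self) -> np.ndarray:
        return self.gd.dense()

    def solver(self, chi: np.ndarray, tol: float = 1e-8) -> ScatteringSolver:
        """A solver for (I - G_D diag(chi)) with this operator."""
        return ScatteringSolver(self.gd, chi, tol=tol)


def build_green_operators(
    grid: DielectricMap,
    array: ArrayConfig,
    frequency: float,
    eps_b: float | None = None,
    sigma_b: float | None = None,
) -> GreenOperators:
    """Assemble G_S and the matrix-free G_D for one frequency.

    Off-diagonal entries integrate the Hankel kernel over an equal-area disk
    of radius ``a = cell/sqrt(pi)``:

        G(m, n) = -(j pi k a / 2) J1(k a) H0^(2)(k rho_mn),

    and the singular self term uses the analytic disk integral

        G(n, n) = -(j pi k a / 2) H1^(2)(k a) - 1.
    """
    if frequency <= 0:
        raise ValueError("frequency must be positive")
    eps_b = grid.eps_b if eps_b is None else eps_b
    sigma_b = grid.sigma_b if sigma_b is None else sigma_b
    k = wavenumber(frequency, eps_b, sigma_b)
    cell = grid.cell_size
    a = cell / np.sqrt(np.pi)
    coef = -1j * np.pi * k * a / 2.0
    half_diag = 0.5 * np.hypot(*grid.domain_size)
    if array.radius <= half_diag:
        raise ValueError(
            f"antenna ring (radius {array.radius} m) must lie outside the "
            f"domain (half diagonal {half_diag:.3f} m)"
        )

    def kernel(dx, dy):
        rho = np.hypot(dx, dy)
        with np.errstate(invalid="ignore", divide="ignore"):
            out = coef * jv(1, k * a) * hankel2(0, k * rho)
        return np.where(rho == 0, 0.0, out)

    self_term = coef * hankel2(1, k * a) - 1.0
    gd = ConvolutionOperator(kernel, self_term, grid.shape, cell)

    X, Y = grid.cell_grid()
    pos = array.positions()
    rho_s = np.hypot(
        pos[:, 0:1] - X.ravel()[None, :], pos[:, 1:2] - Y.ravel()[None, :]
    )
    G_S = coef * jv(1, k * a) * hankel2(0, k * rho_s)
    return GreenOperators(
        frequency=frequency,
        k_b=k,
        cell_size=cell,
        shape=grid.shape,
        G_S=G_S,
        gd=gd,
        rx_pos=pos,
        tx_pos=array.tx_positions(),
    )


@dataclass
class FieldSet:
    """Incident/total fields at cell centers for one frequency.

    ``E_inc`` and ``E_tot`` have shape (n_tx, Ni); ``E_inc_rx`` holds the
    incident field at the receiver ring with the transmitting antenna's own
    entry zeroed (a receiver co-located with its source has no finite
    incident value).
    """

    frequency: float
    E_inc: np.ndarray
    E_tot: np.ndarray | None = None
    E_inc_rx: np.ndarray | None = None


def incident_field(
    grid: DielectricMap,
    array: ArrayConfig,
    frequency: float,
    eps_b: float | None = None,
    sigma_b: float | None = None,
) -> FieldSet:
    """Unit-amplitude line-source fields ``H0^(2)(k_b |r - r_tx|)``."""
    k = wavenumber(
        frequency,
        grid.eps_b if eps_b is None else eps_b,
        grid.sigma_b if sigma_b is None else sigma_b,
    )
    X, Y = grid.cell_grid()
    tx = array.tx_positions()
    rho = np.hypot(tx[:, 0:1] - X.ravel()[None, :], tx[:, 1:2] - Y.ravel()[None, :])
    E_inc = hankel2(0, k * rho)
    pos = array.positions()
    rho_rx = np.hypot(tx[:, 0:1] - pos[None, :, 0], tx[:, 1:2] - pos[None, :, 1])
    with np.errstate(invalid="ignore", divide="ignore"):
        E_rx = hankel2(0, k * rho_rx)
    E_rx = np.where(rho_rx == 0, 0.0, E_rx)
    return FieldSet(frequency=frequency, E_inc=E_inc, E_inc_rx=E_rx)


def contrast_of(m: DielectricMap, frequency: float) -> np.ndarray:
    """Complex contrast per cell (flattened C order)."""
    if frequency <= 0:
        raise ValueError("frequency must be positive")
    omega = 2 * np.pi * frequency
    chi = (
        m.eps_r / m.eps_b
        - 1.0
        - 1j * (m.sigma - m.sigma_b) / (omega * EPS0 * m.eps_b)
    )
    return chi.ravel()


def solve_total_field(
    m: DielectricMap,
    ops: GreenOperators,
    fields: FieldSet,
    tol: float = 1e-8,
) -> FieldSet:
    """Solve ``(I - G_D diag(chi)) E_tot = E_inc`` per transmitter."""
    chi = contrast_of(m, ops.frequency)
    if not np.any(chi):
        return FieldSet(
            frequency=ops.frequency,
            E_inc=fields.E_inc,
            E_tot=fields.E_inc.copy(),
            E_inc_rx=fields.E_inc_rx,
        )
    E_tot = ops.solver(chi, tol=tol).solve(fields.E_inc)
    return FieldSet(
        frequency=ops.frequency,
        E_inc=fields.E_inc,
        E_tot=E_tot,
        E_inc_rx=fields.E_inc_rx,
    )


def scattered_field(
    m: DielectricMap, ops: GreenOperators, fields: FieldSet
) -> np.ndarray:
    """Receiver data ``G_S . chi . E_tot``, shape (n_tx, n_rx)."""
    if fields.E_tot is None:
        raise ValueError("solve the total field first")
    chi = contrast_of(m, ops.frequency)
    if fields.E_tot.shape[1] != ops.n_cells:
        raise ValueError("field/operator grid mismatch")
    return (chi[None, :] * fields.E_tot) @ ops.G_S.T


@dataclass
class MeasurementSet:
    """Scattered-field data indexed (frequency, tx, rx) with noise metadata."""

    data: np.ndarray  # complex, (n_freq, n_tx, n_rx)
    frequencies: tuple[float, ...]
    array: ArrayConfig
    snr_db: float | None = None
    noise_seed: int | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=complex)
        if self.data.ndim != 3:
            raise ValueError("data must be (n_freq, n_tx, n_rx)")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("measurement data must be finite")

    @property
    def n_freq(self):
        return self.data.shape[0]

    @property
    def n_tx(self):
        return self.data.shape[1]

    @property
    def n_rx(self):
        return self.data.shape[2]


def add_noise(meas: MeasurementSet, snr_db: float | None, seed: int) -> MeasurementSet:
    """Add circularly-symmetric complex white Gaussian noise.

    The noise variance is set per (frequency, transmitter) receiver vector so
    that mean signal power / noise variance = 10^(snr_db/10).  ``snr_db=None``
    returns the data unchanged.
    """
    if snr_db is None:
        out = MeasurementSet(
            data=meas.data.copy(),
            frequencies=meas.frequencies,
            array=meas.array,
            snr_db=None,
            noise_seed=seed,
            meta=dict(meas.meta, noise_applied=False),
        )
        return out
    if not np.isfinite(snr_db):
        raise ValueError("snr_db must be finite (or None for noiseless)")
    power = np.mean(np.abs(meas.data) ** 2, axis=2)  # (n_freq, n_tx)
    if np.any(power == 0):
        raise ValueError("SNR undefined for an all-zero signal vector")
    var = power * 10.0 ** (-snr_db / 10.0)
    rng = np.random.default_rng(seed)
    shape = meas.data.shape
    noise = np.sqrt(var / 2.0)[:, :, None] * (
        rng.standard_normal(shape) + 1j * rng.standard_normal(shape)
    )
    return MeasurementSet(
        data=meas.data + noise,
        frequencies=meas.frequencies,
        array=meas.array,
        snr_db=float(snr_db),
        noise_seed=seed,
        meta=dict(meas.meta, noise_applied=True),
    )


def _refine(m: DielectricMap, factor: int) -> DielectricMap:
    """Nearest-neighbour refinement of a map (forward-grid oversampling)."""
    if factor == 1:
        return m
    eps = np.kron(m.eps_r, np.ones((factor, factor)))
    sig = np.kron(m.sigma, np.ones((factor, factor)))
    mask = None
    if m.mask is not None:
        mask = np.kron(m.mask, np.ones((factor, factor), dtype=bool))
    return DielectricMap(
        eps_r=eps,
        sigma=sig,
        cell_size=m.cell_size / factor,
        eps_b=m.eps_b,
        sigma_b=m.sigma_b,
        origin=m.origin,
        mask=mask,
    )


def simulate_experiment(
    m: DielectricMap,
    array: ArrayConfig,
    snr_db: float | None = None,
    seed: int = 0,
    fine_factor: int = 1,
    fine_map: DielectricMap | None = None,
    tol: float = 1e-8,
) -> MeasurementSet:
    """Run the full forward chain over all array frequencies.

    The scattering systems are solved on a grid refined by ``fine_factor``
    relative to ``m`` (inverse-crime avoidance: the reconstruction never sees
    data produced at its own resolution).  When ``fine_map`` is supplied it
    is used directly as the fine-grid truth (e.g. a phantom regenerated at
    the fine resolution, avoiding staircase replication); otherwise ``m`` is
    oversampled.  Noise is applied last.
    """
    if fine_factor < 1:
        raise ValueError("fine_factor must be >= 1")
    fm = fine_map if fine_map is not None else _refine(m, fine_factor)
    data = np.empty((len(array.frequencies), array.n_tx, array.n_rx), dtype=complex)
    for i, f in enumerate(array.frequencies):
        ops = build_green_operators(fm, array, f)
        fs = incident_field(fm, array, f)
        fs = solve_total_field(fm, ops, fs, tol=tol)
        data[i] = scattered_field(fm, ops, fs)
    meas = MeasurementSet(
        data=data,
        frequencies=array.frequencies,
        array=array,
        snr_db=None,
        noise_seed=None,
        meta={
            "seed": seed,
            "snr_db": snr_db,
            "fine_factor": fine_factor,
            "array_radius": array.radius,
            "grid_shape": fm.shape,
        },
    )
    return add_noise(meas, snr_db, seed)
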