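"""Ground-truth dielectric maps for 2D microwave tomography.

This module generates the benchmark scatterers used throughout the package:
the classic "Austria" profile (two disks plus an annulus in free space), a
seeded synthetic breast slice (skin ring, adipose interior, fibroglandular
blobs), and a plain-text raster reader for externally supplied permittivity
maps.  Conductivity is tied to relative permittivity through the linear
tissue model ``sigma = 0.0190 * eps_r - 0.0505`` (clamped at zero), which
collapses the unknowns of the imaging problem to a single real parameter per
pixel.

Coordinate convention: the grid is centered on the origin, x rightward and
y upward, with cell centers at ``(i + 0.5) * cell_size`` offsets from the
lower-left corner.  All geometry is in meters.  Arrays are indexed
``[ix, iy]`` and flattened in C order wherever a per-cell vector is needed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from scipy import ndimage

__all__ = [
    "DielectricMap",
    "PhantomSpec",
    "make_austria",
    "sigma_from_eps",
    "make_synthetic_breast",
    "read_raster",
    "write_raster",
    "downsample",
    "save_png",
]

#: slope / intercept of the linear permittivity-to-conductivity tissue model
SIGMA_SLOPE = 0.0190
SIGMA_INTERCEPT = -0.0505

#: permittivity bounds for breast tissue reconstructions
BREAST_EPS_BOUNDS = (2.0, 55.0)


@dataclass
class DielectricMap:
    """Gridded relative permittivity and conductivity over a square domain.

    Parameters
    ----------
    eps_r : ndarray, shape (Nx, Ny)
        Relative permittivity per cell (dimensionless, >= 1).
    sigma : ndarray, shape (Nx, Ny)
        Conductivity per cell in S/m (>= 0).
    cell_size : float
        Cell edge length in meters.
    eps_b, sigma_b : float
        Background medium relative permittivity and conductivity.
    origin : tuple of float
        Coordinates of the grid center in meters.
    mask : ndarray of bool or None
        Optional reconstructable-region prior (e.g. breast support); cells
        outside the mask hold background values.
    """

    eps_r: np.ndarray
    sigma: np.ndarray
    cell_size: float
    eps_b: float = 1.0
    sigma_b: float = 0.0
    origin: tuple[float, float] = (0.0, 0.0)
    mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.eps_r = np.asarray(self.eps_r, dtype=float)
        self.sigma = np.asarray(self.sigma, dtype=float)
        if self.eps_r.ndim != 2:
            raise ValueError("eps_r must be a 2D grid")
        if self.eps_r.shape != self.sigma.shape:
            raise ValueError("eps_r and sigma must have identical shapes")
        if self.mask is not None:
            self.mask = np.asarray(self.mask, dtype=bool)
            if self.mask.shape != self.eps_r.shape:
                raise ValueError("mask shape must match eps_r")
        if not np.all(np.isfinite(self.eps_r)) or np.any(self.eps_r < 1.0):
            raise ValueError("eps_r must be finite and >= 1 everywhere")
        if not np.all(np.isfinite(self.sigma)) or np.any(self.sigma < 0.0):
            raise ValueError("sigma must be finite and >= 0 everywhere")
        if self.cell_size <= 0:
            raise ValueError("cell_size must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return self.eps_r.shape

    @property
    def n_cells(self) -> int:
        return self.eps_r.size

    @property
    def domain_size(self) -> tuple[float, float]:
        return (self.shape[0] * self.cell_size, self.shape[1] * self.cell_size)

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """Return 1D arrays of x and y cell-center coordinates."""
        n1, n2 = self.shape
        xs = (np.arange(n1) - (n1 - 1) / 2.0) * self.cell_size + self.origin[0]
        ys = (np.arange(n2) - (n2 - 1) / 2.0) * self.cell_size + self.origin[1]
        return xs, ys

    def cell_grid(self) -> tuple[np.ndarray, np.ndarray]:
        """Return 2D meshes of cell-center coordinates, indexed [ix, iy]."""
        xs, ys = self.cell_centers()
        return np.meshgrid(xs, ys, indexing="ij")

    def background_like(self) -> "DielectricMap":
        """A copy holding background values everywhere (same grid/mask)."""
        return replace(
            self,
            eps_r=np.full(self.shape, self.eps_b),
            sigma=np.full(self.shape, self.sigma_b),
            mask=None if self.mask is None else self.mask.copy(),
        )

    def copy(self) -> "DielectricMap":
        return replace(
            self,
            eps_r=self.eps_r.copy(),
            sigma=self.sigma.copy(),
            mask=None if self.mask is None else self.mask.copy(),
        )


@dataclass(frozen=True)
class PhantomSpec:
    """Declarative phantom request (used by the CLI and presets)."""

    kind: str  # austria | synthetic_breast | external_raster
    grid_shape: tuple[int, int] = (100, 100)
    domain_size: float = 2.0
    seed: int = 0
    density_class: str = "II"  # I..IV, synthetic breast only
    path: str | None = None  # external_raster only

    def __post_init__(self) -> None:
        if self.kind not in ("austria", "synthetic_breast", "external_raster"):
            raise ValueError(f"unknown phantom kind {self.kind!r}")
        if self.domain_size <= 0:
            raise ValueError("domain_size must be positive")
        if min(self.grid_shape) < 8:
            raise ValueError("grid_shape entries must be >= 8")


def make_phantom(spec: PhantomSpec) -> DielectricMap:
    if spec.kind == "austria":
        return make_austria(spec.grid_shape, spec.domain_size)
    if spec.kind == "synthetic_breast":
        return make_synthetic_breast(spec)
    if spec.path is None:
        raise ValueError("external_raster spec requires a path")
    return read_raster(spec.path)


# ---------------------------------------------------------------------------
# Austria profile
# ---------------------------------------------------------------------------

_AUSTRIA_DISKS = (((0.3, 0.6), 0.2), ((-0.3, 0.6), 0.2))
_AUSTRIA_ANNULUS = ((0.0, -0.2), 0.3, 0.6)
_AUSTRIA_EPS = 2.0


def austria_membership(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Exact point-in-object test for the Austria profile geometry.

    Two solid disks of radius 0.2 m centered at (+-0.3, 0.6) m and an
    annulus centered at (0, -0.2) m with inner radius 0.3 m and outer
    radius 0.6 m.
    """
    inside = np.zeros(np.broadcast(x, y).shape, dtype=bool)
    for (cx, cy), r in _AUSTRIA_DISKS:
        inside |= (x - cx) ** 2 + (y - cy) ** 2 <= r**2
    (cx, cy), r_in, r_out = _AUSTRIA_ANNULUS
    d2 = (x - cx) ** 2 + (y - cy) ** 2
    inside |= (d2 >= r_in**2) & (d2 <= r_out**2)
    return inside


def make_austria(
    grid_shape: tuple[int, int] | int = (100, 100), domain_size: float = 2.0
) -> DielectricMap:
    """Build the Austria profile on a square grid over a 2 m x 2 m domain.

    Cells whose centers fall inside either disk or the annulus take
    eps_r = 2; everywhere else (and the background) is free space.
    Membership uses cell-center point tests, matching pixelated
    ground-truth renderings of this benchmark.
    """
    if np.isscalar(grid_shape):
        grid_shape = (int(grid_shape), int(grid_shape))
    n1, n2 = grid_shape
    if n1 != n2:
        raise ValueError("Austria profile requires a square grid")
    cell = domain_size / n1
    if cell > 0.15:
        raise ValueError(
            "grid too coarse to resolve the annulus width (cell_size > 0.15 m)"
        )
    m = DielectricMap(
        eps_r=np.ones(grid_shape),
        sigma=np.zeros(grid_shape),
        cell_size=cell,
        eps_b=1.0,
        sigma_b=0.0,
    )
    X, Y = m.cell_grid()
    m.eps_r[austria_membership(X, Y)] = _AUSTRIA_EPS
    return m


# ---------------------------------------------------------------------------
# Tissue model
# ---------------------------------------------------------------------------


def sigma_from_eps(eps_r):
    """Conductivity (S/m) from relative permittivity via the linear tissue fit.

    ``sigma = max(0, 0.0190 * eps_r - 0.0505)``, elementwise.  The clamp keeps
    conductivity physical below the root of the affine map (eps_r ~ 2.66),
    which lies below the breast-tissue permittivity lower bound of 2 used in
    reconstructions.
    """
    eps = np.asarray(eps_r, dtype=float)
    if not np.all(np.isfinite(eps)) or np.any(eps < 0):
        raise ValueError("eps_r must be finite and non-negative")
    out = np.maximum(0.0, SIGMA_SLOPE * eps + SIGMA_INTERCEPT)
    return out if out.ndim else float(out)


# ---------------------------------------------------------------------------
# Synthetic breast slices
# ---------------------------------------------------------------------------

#: target areal fraction of fibroglandular tissue inside the breast interior,
#: by mammographic density class (I mostly fatty .. IV extremely dense)
_DENSITY_FRACTION = {"I": 0.10, "II": 0.25, "III": 0.45, "IV": 0.65}

_SKIN_EPS = 36.0  # typical literature value for skin at ~1 GHz
_SKIN_THICKNESS = 2.0e-3  # meters


def make_synthetic_breast(spec: PhantomSpec) -> DielectricMap:
    """Generate a seeded 2D coronal breast slice.

    The phantom emulates the structure of MRI-derived numerical breast
    models: an outer skin ring (eps_r = 36, ~2 mm), an adipose interior
    (eps_r in [2, 10]) and smoothly varying fibroglandular blobs
    (eps_r in [35, 55]) whose areal fraction grows with the density class.
    Conductivity follows the linear tissue model; the background is a
    lossless matching medium with eps_r = 10.  The returned mask marks the
    breast support (skin included) and is the reconstruction prior.
    """
    if spec.density_class not in _DENSITY_FRACTION:
        raise ValueError("density_class must be one of I, II, III, IV")
    n1, n2 = spec.grid_shape
    cell = spec.domain_size / n1
    if _SKIN_THICKNESS < cell:
        raise ValueError(
            "grid too small to contain a skin ring at least one cell thick"
        )
    rng = np.random.default_rng(spec.seed)

    m = DielectricMap(
        eps_r=np.full(spec.grid_shape, 10.0),
        sigma=np.zeros(spec.grid_shape),
        cell_size=cell,
        eps_b=10.0,
        sigma_b=0.0,
    )
    X, Y = m.cell_grid()
    half = spec.domain_size / 2.0

    # Breast support: an ellipse with a low-order random radial perturbation.
    theta = np.arctan2(Y, X)
    ax = half * rng.uniform(0.78, 0.88)
    ay = half * rng.uniform(0.70, 0.82)
    wobble = np.zeros_like(theta)
    for k in (2, 3):
        wobble += rng.uniform(0.0, 0.04) * np.cos(k * theta + rng.uniform(0, 2 * np.pi))
    r_norm = np.sqrt((X / ax) ** 2 + (Y / ay) ** 2)
    support = r_norm <= 1.0 + wobble
    # Signed distance (in meters) to the support boundary, for the skin ring.
    dist_in = ndimage.distance_transform_edt(support) * cell
    skin = support & (dist_in <= _SKIN_THICKNESS)
    interior = support & ~skin

    # Smooth random texture field in [0, 1] over the interior.
    f = ndimage.gaussian_filter(rng.standard_normal(spec.grid_shape), sigma=n1 / 18.0)
    # Bias fibroglandular content toward the center, as in real coronal slices.
    f = f - 0.8 * r_norm
    fi = f[interior]
    lo, hi = fi.min(), fi.max()
    f01 = np.zeros_like(f)
    f01[interior] = (f[interior] - lo) / max(hi - lo, 1e-12)

    frac = _DENSITY_FRACTION[spec.density_class]
    t = np.quantile(f01[interior], 1.0 - frac)
    t = min(max(t, 0.05), 0.95)

    eps = np.full(spec.grid_shape, m.eps_b)
    # adipose: [2, 10]; fibroglandular: [35, 55]; smooth blend across threshold
    adipose = 2.0 + 8.0 * np.clip(f01 / max(t, 1e-9), 0.0, 1.0) ** 2
    fibro = 35.0 + 20.0 * np.clip((f01 - t) / max(1.0 - t, 1e-9), 0.0, 1.0)
    blend = 1.0 / (1.0 + np.exp(-(f01 - t) / 0.02))
    eps[interior] = (adipose * (1 - blend) + fibro * blend)[interior]
    eps[skin] = _SKIN_EPS
    eps[support] = np.clip(eps[support], *BREAST_EPS_BOUNDS)

    m.eps_r = eps
    m.sigma = np.where(support, sigma_from_eps(eps), m.sigma_b)
    m.mask = support
    return m


# ---------------------------------------------------------------------------
# Raster I/O (self-describing plain text) and resampling
# ---------------------------------------------------------------------------

_RASTER_MAGIC = "# mwtomo raster v1"


def write_raster(m: DielectricMap, path) -> None:
    """Serialize a dielectric map as a self-describing text raster.

    Header lines carry the grid metadata; the payload stacks the requested
    layers (eps_r, then optional sigma and mask) as row-major float blocks.
    """
    layers = ["eps_r", "sigma"]
    blocks = [m.eps_r, m.sigma]
    if m.mask is not None:
        layers.append("mask")
        blocks.append(m.mask.astype(float))
    with open(path, "w") as fh:
        fh.write(_RASTER_MAGIC + "\n")
        fh.write(f"# shape = {m.shape[0]} {m.shape[1]}\n")
        fh.write(f"# cell_size = {m.cell_size!r}\n")
        fh.write(f"# eps_b = {m.eps_b!r}\n")
        fh.write(f"# sigma_b = {m.sigma_b!r}\n")
        fh.write(f"# origin = {m.origin[0]!r} {m.origin[1]!r}\n")
        fh.write(f"# layers = {' '.join(layers)}\n")
        np.savetxt(fh, np.concatenate(blocks, axis=0), fmt="%.12g")


def read_raster(path) -> DielectricMap:
    """Read a text raster written by :func:`write_raster` (or compatible).

    The file must start with a header declaring shape, cell_size and the
    background medium; an eps_r layer is mandatory.  When no sigma layer is
    present, conductivity is filled from the linear tissue model.
    """
    path = Path(path)
    header: dict[str, str] = {}
    with open(path) as fh:
        first = fh.readline().strip()
        if first != _RASTER_MAGIC:
            raise ValueError(f"{path}: not an mwtomo raster (bad magic line)")
        pos = fh.tell()
        while True:
            line = fh.readline()
            if not line.startswith("#"):
                fh.seek(pos)
                break
            pos = fh.tell()
            body = line[1:].strip()
            if "=" in body:
                key, _, val = body.partition("=")
                header[key.strip()] = val.strip()
        try:
            n1, n2 = (int(v) for v in header["shape"].split())
            cell = float(header["cell_size"])
            eps_b = float(header["eps_b"])
            sigma_b = float(header.get("sigma_b", "0.0"))
        except (KeyError, ValueError) as exc:
            raise ValueError(f"{path}: malformed raster header") from exc
        layers = header.get("layers", "eps_r").split()
        data = np.loadtxt(fh, ndmin=2)
    if data.shape != (n1 * len(layers), n2):
        raise ValueError(
            f"{path}: payload shape {data.shape} inconsistent with header"
        )
    blocks = {name: data[i * n1 : (i + 1) * n1] for i, name in enumerate(layers)}
    if "eps_r" not in blocks:
        raise ValueError(f"{path}: missing eps_r layer")
    eps = blocks["eps_r"]
    if np.any(eps < 1.0):
        raise ValueError(f"{path}: eps_r < 1 encountered")
    sigma = blocks.get("sigma")
    if sigma is None:
        sigma = sigma_from_eps(eps)
    mask = blocks.get("mask")
    origin = (0.0, 0.0)
    if "origin" in header:
        ox, oy = (float(v) for v in header["origin"].split())
        origin = (ox, oy)
    return DielectricMap(
        eps_r=eps,
        sigma=sigma,
        cell_size=cell,
        eps_b=eps_b,
        sigma_b=sigma_b,
        origin=origin,
        mask=None if mask is None else mask > 0.5,
    )


def downsample(m: DielectricMap, factor: int) -> DielectricMap:
    """Block-average a map onto a grid coarser by an integer factor.

    eps_r and sigma are averaged over factor x factor blocks; a mask cell is
    kept when at least half of its block is masked, and unmasked coarse
    cells are reset to background to preserve the mask invariant.
    """
    factor = int(factor)
    if factor < 1:
        raise ValueError("factor must be >= 1")
    if factor == 1:
        return m.copy()
    n1, n2 = m.shape
    if n1 % factor or n2 % factor:
        raise ValueError(f"factor {factor} does not divide grid shape {m.shape}")

    def block(a: np.ndarray) -> np.ndarray:
        return a.reshape(n1 // factor, factor, n2 // factor, factor).mean(axis=(1, 3))

    eps = block(m.eps_r)
    sig = block(m.sigma)
    mask = None
    if m.mask is not None:
        mask = block(m.mask.astype(float)) >= 0.5
        eps = np.where(mask, eps, m.eps_b)
        sig = np.where(mask, sig, m.sigma_b)
    return DielectricMap(
        eps_r=eps,
        sigma=sig,
        cell_size=m.cell_size * factor,
        eps_b=m.eps_b,
        sigma_b=m.sigma_b,
        origin=m.origin,
        mask=mask,
    )


def save_png(m: DielectricMap, path, quantity: str = "eps_r", cmap: str = "viridis"):
    """Export a map layer as a PNG image (x rightward, y upward)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    arr = getattr(m, quantity)
    half_x = m.shape[0] * m.cell_size / 2
    half_y = m.shape[1] * m.cell_size / 2
    fig, ax = plt.subplots(figsize=(4, 4))
    im = ax.imshow(
        arr.T,
        origin="lower",
        extent=(-half_x, half_x, -half_y, half_y),
        cmap=cmap,
    )
    fig.colorbar(im, ax=ax, label=quantity)
    ax.set_xlabel("x (m)")
    ax.set_ylabel("y (m)")
    fig.savefig(path, dpi=150, bbox_inches="tight")
    plt.close(fig)
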