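"""Synthetic tissue phantoms and the time-harmonic forward model.

The forward model is the exact 2-D transverse-magnetic (TM) scalar equation
for the longitudinal electric field ``Ez`` over an in-plane admittivity map
``gamma = sigma + i*omega*eps``::

    lap(Ez) - i*omega*mu0*gamma*Ez = 0

solved with a 5-point finite-difference discretization and Dirichlet boundary
values.  The positively rotating RF magnetic field is then

    H+ = (dEz/dx + i*dEz/dy) / (2*omega*mu0)

which follows from Faraday's law for the TM mode.  Multi-echo spin-echo data
are synthesized from H+ under the transceive assumption (echo phase equals
twice the transmit phase) with T2 decay and complex Gaussian noise.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla
from scipy.special import jv

from .core import EPS0, GridSpec, PhysicsConfig, admittivity

__all__ = [
    "Disk",
    "Annulus",
    "Rectangle",
    "Union",
    "PhantomMap",
    "ComplexFieldMap",
    "EchoData",
    "make_phantom",
    "plane_wave_field",
    "birdcage_field",
    "solve_forward_ez",
    "derive_hplus",
    "synthesize_echoes",
    "combine_echoes",
]


# ---------------------------------------------------------------------------
# shapes and phantom construction
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Disk:
    """Filled disk; center and radius in meters (grid-centered coordinates)."""

    cx: float
    cy: float
    r: float

    def contains(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        return (x - self.cx) ** 2 + (y - self.cy) ** 2 <= self.r**2

    def bounds(self) -> tuple[float, float, float, float]:
        return (self.cx - self.r, self.cx + self.r, self.cy - self.r, self.cy + self.r)


@dataclass(frozen=True)
class Annulus:
    cx: float
    cy: float
    r_in: float
    r_out: float

    def contains(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        r2 = (x - self.cx) ** 2 + (y - self.cy) ** 2
        return (r2 <= self.r_out**2) & (r2 >= self.r_in**2)

    def bounds(self) -> tuple[float, float, float, float]:
        return (self.cx - self.r_out, self.cx + self.r_out, self.cy - self.r_out, self.cy + self.r_out)


@dataclass(frozen=True)
class Rectangle:
    x0: float
    x1: float
    y0: float
    y1: float

    def contains(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        return (x >= self.x0) & (x <= self.x1) & (y >= self.y0) & (y <= self.y1)

    def bounds(self) -> tuple[float, float, float, float]:
        return (self.x0, self.x1, self.y0, self.y1)


@dataclass(frozen=True)
class Union:
    shapes: tuple

    def contains(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        m = np.zeros(x.shape, dtype=bool)
        for s in self.shapes:
            m |= s.contains(x, y)
        return m

    def bounds(self) -> tuple[float, float, float, float]:
        bs = [s.bounds() for s in self.shapes]
        return (
            min(b[0] for b in bs),
            max(b[1] for b in bs),
            min(b[2] for b in bs),
            max(b[3] for b in bs),
        )


@dataclass
class PhantomMap:
    """Per-pixel ground-truth electrical properties.

    ``sigma`` is conductivity (S/m), ``eps_r`` relative permittivity and
    ``labels`` an integer tissue-label map (0 = free-space background).
    """

    sigma: np.ndarray
    eps_r: np.ndarray
    labels: np.ndarray
    grid: GridSpec

    def object_mask(self) -> np.ndarray:
        return self.labels != 0

    def gamma(self, physics: PhysicsConfig) -> np.ndarray:
        return admittivity(self.sigma, self.eps_r, physics)


@dataclass
class ComplexFieldMap:
    """Complex scalar field on the grid; ``kind`` is 'Ez' or 'Hplus'."""

    values: np.ndarray
    kind: str
    grid: GridSpec


@dataclass
class EchoData:
    """Multi-echo transceive phase (radians, wrapped) and magnitude maps."""

    phase: np.ndarray  # (n_echoes, ny, nx)
    magnitude: np.ndarray  # (n_echoes, ny, nx)
    te_ms: np.ndarray

    @property
    def n_echoes(self) -> int:
        return len(self.te_ms)


def make_phantom(
    grid: GridSpec,
    regions: Sequence[tuple[object, float, float, int]] = (),
) -> PhantomMap:
    """Rasterize an ordered list of ``(shape, sigma, eps_r, label)`` regions.

    Later regions overwrite earlier ones.  Background is free space
    (sigma = 0, eps_r = 1, label 0).  A shape extending outside the grid
    raises a ``ValueError`` naming the offending region.
    """
    x, y = grid.coords()
    sigma = np.zeros(grid.shape)
    eps_r = np.ones(grid.shape)
    labels = np.zeros(grid.shape, dtype=int)
    half_x = (grid.nx - 1) / 2.0 * grid.dx
    half_y = (grid.ny - 1) / 2.0 * grid.dy
    for idx, (shape, sig, er, lab) in enumerate(regions):
        x0, x1, y0, y1 = shape.bounds()
        if x0 < -half_x or x1 > half_x or y0 < -half_y or y1 > half_y:
            raise ValueError(
                f"region {idx} (label {lab}, {type(shape).__name__}) extends outside the grid"
            )
        if sig < 0:
            raise ValueError(f"region {idx}: sigma must be non-negative")
        m = shape.contains(x, y)
        sigma[m] = sig
        eps_r[m] = er
        labels[m] = lab
    return PhantomMap(sigma=sigma, eps_r=eps_r, labels=labels, grid=grid)


# ---------------------------------------------------------------------------
# analytic illumination fields
# ---------------------------------------------------------------------------

def plane_wave_field(
    grid: GridSpec, physics: PhysicsConfig, sigma: float = 0.0, eps_r: float = 1.0
) -> np.ndarray:
    """Plane wave ``Ez = exp(-i*k*x)`` with ``k**2 = -i*omega*mu0*gamma``.

    For a lossless medium this reduces to ``k = omega*sqrt(mu0*eps)``.
    The branch with decaying amplitude (Im k <= 0) is selected.
    """
    gamma = sigma + 1j * physics.omega * EPS0 * eps_r
    k = np.sqrt(-1j * physics.omega * physics.mu0 * gamma)
    if k.imag > 0:
        k = -k
    x, _ = grid.coords()
    return np.exp(-1j * k * x)


def birdcage_field(
    grid: GridSpec, physics: PhysicsConfig, sigma: float, eps_r: float
) -> np.ndarray:
    """Cylindrical standing wave ``Ez = J0(k*r)``, a birdcage-coil-like mode.

    ``k`` is taken from the (typically object-average) admittivity supplied;
    the resulting field has the central-brightening structure of measured B1
    maps and a phase whose Laplacian carries the conductivity, which makes
    it a sensible default illumination for phase-based reconstruction.
    """
    gamma = sigma + 1j * physics.omega * EPS0 * eps_r
    k = np.sqrt(-1j * physics.omega * physics.mu0 * gamma)
    x, y = grid.coords()
    r = np.hypot(x, y)
    return jv(0, k * r)


# ---------------------------------------------------------------------------
# finite-difference forward solver
# ---------------------------------------------------------------------------

def solve_forward_ez(
    phantom: PhantomMap,
    physics: PhysicsConfig,
    boundary: np.ndarray,
    check_residual: bool = True,
) -> ComplexFieldMap:
    """Solve ``lap(Ez) - i*omega*mu0*gamma*Ez = 0`` with Dirichlet boundaries.

    Parameters
    ----------
    boundary : ndarray (ny, nx), complex
        Field template whose outermost ring supplies the Dirichlet values
        (interior entries are ignored).  Use :func:`plane_wave_field` or
        :func:`birdcage_field` to build one.

    Returns
    -------
    ComplexFieldMap with ``kind='Ez'``.  The assembled sparse system is
    solved by a direct method; the relative residual is checked to 1e-10.
    """
    grid = phantom.grid
    ny, nx = grid.shape
    boundary = np.asarray(boundary, dtype=complex)
    if boundary.shape != grid.shape:
        raise ValueError("boundary template shape mismatch")
    gamma = phantom.gamma(physics)

    n_int = (ny - 2) * (nx - 2)
    idx = -np.ones(grid.shape, dtype=int)
    idx[1:-1, 1:-1] = np.arange(n_int).reshape(ny - 2, nx - 2)

    inv_dx2 = 1.0 / grid.dx**2
    inv_dy2 = 1.0 / grid.dy**2
    diag = -2.0 * (inv_dx2 + inv_dy2) - 1j * physics.omega * physics.mu0 * gamma[1:-1, 1:-1]

    rows, cols, vals = [], [], []
    b = np.zeros(n_int, dtype=complex)
    ii, jj = np.nonzero(idx >= 0)
    me = idx[ii, jj]
    rows.append(me)
    cols.append(me)
    vals.append(diag.ravel())
    for di, dj, w in ((0, 1, inv_dx2), (0, -1, inv_dx2), (1, 0, inv_dy2), (-1, 0, inv_dy2)):
        ni, nj = ii + di, jj + dj
        nbr = idx[ni, nj]
        inside = nbr >= 0
        rows.append(me[inside])
        cols.append(nbr[inside])
        vals.append(np.full(inside.sum(), w, dtype=complex))
        # Dirichlet neighbours move to the right-hand side
        np.add.at(b, me[~inside], -w * boundary[ni[~inside], nj[~inside]])

    A = sp.csr_matrix(
        (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
        shape=(n_int, n_int),
    )
    with warnings.catch_warnings():
        warnings.simplefilter("error", spla.MatrixRankWarning)
        try:
            sol = spla.spsolve(A, b)
        except (spla.MatrixRankWarning, RuntimeError) as exc:  # pragma: no cover
            raise np.linalg.LinAlgError(f"singular forward system: {exc}") from exc
    if not np.all(np.isfinite(sol)):
        raise np.linalg.LinAlgError("forward system produced non-finite values")
    if check_residual:
        res = np.linalg.norm(A @ sol - b)
        scale = np.linalg.norm(b)
        if scale > 0 and res / scale > 1e-10:
            raise np.linalg.LinAlgError(
                f"forward solve residual {res / scale:.2e} exceeds 1e-10; "
                "system may be near-singular"
            )

    ez = boundary.copy()
    ez[1:-1, 1:-1] = sol.reshape(ny - 2, nx - 2)
    return ComplexFieldMap(values=ez, kind="Ez", grid=grid)


def derive_hplus(ez: ComplexFieldMap, physics: PhysicsConfig) -> ComplexFieldMap:
    """Positively rotating field ``H+ = (dEz/dx + i*dEz/dy)/(2*omega*mu0)``.

    Central differences in the interior, one-sided second-order at the edges.
    """
    if ez.kind != "Ez":
        raise ValueError(f"expected an Ez field, got kind={ez.kind!r}")
    dy_, dx_ = np.gradient(ez.values, ez.grid.dy, ez.grid.dx)
    hplus = (dx_ + 1j * dy_) / (2.0 * physics.omega * physics.mu0)
    return ComplexFieldMap(values=hplus, kind="Hplus", grid=ez.grid)


# ---------------------------------------------------------------------------
# echo synthesis and combination
# ---------------------------------------------------------------------------

def wrap_phase(phi: np.ndarray) -> np.ndarray:
    """Wrap to (-pi, pi]."""
    return np.pi - np.mod(np.pi - phi, 2.0 * np.pi)


def synthesize_echoes(
    hplus: ComplexFieldMap,
    te_ms: Sequence[float] = (12, 24, 36, 48, 60, 72),
    t2_ms: float | np.ndarray = 80.0,
    snr: float = np.inf,
    seed: int | None = 0,
) -> EchoData:
    """Simulate multi-echo spin-echo transceive data from H+.

    Noiseless echo phase is twice the transmit phase, ``2*arg(H+)``;
    magnitude is ``|H+| * exp(-TE/T2)``.  Independent complex Gaussian noise
    is added per echo with per-channel standard deviation
    ``mean(|H+|) / snr``.  Defaults follow a 6-echo acquisition with first
    echo 12 ms and 12 ms spacing.
    """
    te = np.asarray(te_ms, dtype=float)
    if len(te) < 1 or np.any(np.diff(te) <= 0):
        raise ValueError("te_ms must be non-empty and strictly increasing")
    t2 = np.broadcast_to(np.asarray(t2_ms, dtype=float), hplus.grid.shape)
    if np.any(t2 <= 0):
        raise ValueError("T2 must be positive everywhere")
    if not snr > 0:
        raise ValueError("snr must be positive")

    u = hplus.values
    phase_true = 2.0 * np.angle(u)
    mag0 = np.abs(u)
    rng = np.random.default_rng(seed)
    noise_sd = 0.0 if np.isinf(snr) else float(np.mean(mag0)) / snr

    phases = np.empty((len(te),) + hplus.grid.shape)
    mags = np.empty_like(phases)
    for e, te_e in enumerate(te):
        signal = mag0 * np.exp(-te_e / t2) * np.exp(1j * phase_true)
        if noise_sd > 0:
            signal = signal + noise_sd * (
                rng.standard_normal(signal.shape) + 1j * rng.standard_normal(signal.shape)
            )
        phases[e] = wrap_phase(np.angle(signal))
        mags[e] = np.abs(signal)
    return EchoData(phase=phases, magnitude=mags, te_ms=te)


def combine_echoes(echoes: EchoData) -> tuple[np.ndarray, np.ndarray]:
    """Combine echoes into one phase and one magnitude map.

    Phase: magnitude-squared-weighted circular mean, ``arg(sum m^2 e^{i phi})``
    — a maximum-likelihood-like weighting that is insensitive to phase wraps.
    Magnitude: plain mean across echoes.
    """
    if not np.any(echoes.magnitude > 0):
        raise ValueError("all echo magnitudes are zero; nothing to combine")
    z = np.sum(echoes.magnitude**2 * np.exp(1j * echoes.phase), axis=0)
    phase = np.angle(z)
    # pixels where the weighted sum cancels exactly fall back to echo 1
    dead = np.abs(z) == 0
    if np.any(dead):
        phase[dead] = echoes.phase[0][dead]
    return phase, echoes.magnitude.mean(axis=0)
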