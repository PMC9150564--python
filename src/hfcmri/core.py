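"""Grid and physics primitives shared by the forward and inverse stages.

All spatial quantities are in SI units (meters); conductivity in S/m;
permittivity as relative permittivity (dimensionless).  Arrays are stored
``(ny, nx)`` with x along the last axis; physical coordinates are centered
on the grid, ``x = (ix - (nx-1)/2) * dx``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: Proton gyromagnetic ratio, MHz per tesla.
GYROMAGNETIC_RATIO_MHZ_PER_T = 42.577

#: Vacuum permeability, H/m.
MU0 = 4.0e-7 * np.pi

#: Vacuum permittivity, F/m.
EPS0 = 8.8541878128e-12


def larmor_frequency_hz(b0_tesla: float) -> float:
    """Proton Larmor frequency (Hz) at field strength ``b0_tesla``."""
    return GYROMAGNETIC_RATIO_MHZ_PER_T * 1e6 * b0_tesla


@dataclass(frozen=True)
class GridSpec:
    """Uniform 2-D pixel grid.

    Parameters
    ----------
    nx, ny : int
        Pixel counts along x and y.  At least 16 each.
    dx, dy : float
        Pixel spacing in meters.
    """

    nx: int
    ny: int
    dx: float
    dy: float

    def __post_init__(self) -> None:
        if self.nx < 16 or self.ny < 16:
            raise ValueError(f"grid must be at least 16x16, got {self.nx}x{self.ny}")
        if self.dx <= 0 or self.dy <= 0:
            raise ValueError("pixel spacing must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return (self.ny, self.nx)

    def coords(self) -> tuple[np.ndarray, np.ndarray]:
        """Centered physical coordinate arrays ``(X, Y)``, each (ny, nx)."""
        x = (np.arange(self.nx) - (self.nx - 1) / 2.0) * self.dx
        y = (np.arange(self.ny) - (self.ny - 1) / 2.0) * self.dy
        return np.meshgrid(x, y)


@dataclass(frozen=True)
class PhysicsConfig:
    """RF physics constants for the simulation and reconstruction.

    ``freq_hz`` defaults to the proton Larmor frequency at ``b0_tesla``
    (42.577 MHz/T x 3 T ~ 128 MHz on a clinical 3 T system).
    """

    b0_tesla: float = 3.0
    freq_hz: float = field(default=0.0)
    mu0: float = MU0

    def __post_init__(self) -> None:
        if self.freq_hz == 0.0:
            object.__setattr__(self, "freq_hz", larmor_frequency_hz(self.b0_tesla))
        if self.freq_hz <= 0:
            raise ValueError("freq_hz must be positive")

    @property
    def omega(self) -> float:
        """Angular frequency, rad/s."""
        return 2.0 * np.pi * self.freq_hz


def admittivity(sigma: np.ndarray, eps_r: np.ndarray, physics: PhysicsConfig) -> np.ndarray:
    """Complex admittivity gamma = sigma + i*omega*eps0*eps_r."""
    return np.asarray(sigma, dtype=complex) + 1j * physics.omega * EPS0 * np.asarray(eps_r, dtype=float)


def interior_mask(shape: tuple[int, int], margin: int) -> np.ndarray:
    """Boolean mask that is True away from a ``margin``-pixel rim."""
    m = np.zeros(shape, dtype=bool)
    if margin == 0:
        m[:] = True
    elif 2 * margin < min(shape):
        m[margin:-margin, margin:-margin] = True
    return m
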