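"""Analytic free-energy surfaces G(z) with exact gradients.

These serve as ground truth for testing umbrella-sampling reconstruction:
a Brownian walker sampled under a harmonic bias on one of these surfaces
has a known stationary distribution, and the WHAM output can be compared
against the analytic profile.

The ``membrane_double_well`` surface mimics the qualitative shape of a
one-dimensional free-energy profile of an amphiphilic solute across a lipid
bilayer: zero in bulk water, a well of depth ``D`` at +/- ``z_min`` (one per
leaflet), and a central barrier that sits ``B`` above the well bottom, i.e.
G(0) = B - D.  With that construction the desorption barrier
G(z_max) - G_min equals D and the translocation barrier G(0) - G_min
equals B exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Dict

import numpy as np

__all__ = ["FreeEnergySurface", "reference_surface", "SURFACE_NAMES"]


@dataclass(frozen=True)
class FreeEnergySurface:
    """An analytic free-energy surface G(z) in kJ/mol over z in nm.

    ``energy`` and ``gradient`` accept scalars or numpy arrays.
    """

    name: str
    energy: Callable[[np.ndarray], np.ndarray]
    gradient: Callable[[np.ndarray], np.ndarray]
    z_max: float = 4.0
    params: Dict[str, float] = field(default_factory=dict)

    def __call__(self, z):
        return self.energy(np.asarray(z, dtype=float))


def _smoothstep(u: np.ndarray) -> np.ndarray:
    # cubic smoothstep on [0, 1]: s(0)=0, s(1)=1, s'(0)=s'(1)=0
    return u * u * (3.0 - 2.0 * u)


def _smoothstep_d(u: np.ndarray) -> np.ndarray:
    return 6.0 * u * (1.0 - u)


def _membrane_double_well(D: float, z_min: float, B: float, z_max: float):
    """Piecewise-C1 double well: minima -D at +/-z_min, G(0)=B-D, G(z_max)=0."""
    if not (0.0 < z_min < z_max):
        raise ValueError("need 0 < z_min < z_max")
    if D <= 0 or B < 0:
        raise ValueError("well depth D must be > 0 and barrier B >= 0")
    span = z_max - z_min

    def energy(z):
        z = np.asarray(z, dtype=float)
        a = np.abs(z)
        inner = np.clip(a / z_min, 0.0, 1.0)
        outer = np.clip((a - z_min) / span, 0.0, 1.0)
        g_in = (B - D) - B * _smoothstep(inner)
        g_out = -D + D * _smoothstep(outer)
        return np.where(a <= z_min, g_in, g_out)

    def gradient(z):
        z = np.asarray(z, dtype=float)
        a = np.abs(z)
        sgn = np.sign(z)
        inner = np.clip(a / z_min, 0.0, 1.0)
        outer = np.clip((a - z_min) / span, 0.0, 1.0)
        d_in = -B * _smoothstep_d(inner) / z_min
        d_out = np.where(a <= z_max, D * _smoothstep_d(outer) / span, 0.0)
        return sgn * np.where(a <= z_min, d_in, d_out)

    return energy, gradient


def _square_well(depth: float, z_lo: float, z_hi: float):
    """Discontinuous well: G = -depth on [z_lo, z_hi], 0 elsewhere.

    The gradient is defined as 0 away from the edges (and taken as 0 at
    the edges too); this surface is meant for quadrature tests, not for
    Brownian sampling.
    """
    if z_hi <= z_lo:
        raise ValueError("need z_hi > z_lo")

    def energy(z):
        z = np.asarray(z, dtype=float)
        return np.where((z >= z_lo) & (z <= z_hi), -depth, 0.0)

    def gradient(z):
        z = np.asarray(z, dtype=float)
        return np.zeros_like(z)

    return energy, gradient


SURFACE_NAMES = ("flat", "harmonic", "square_well", "membrane_double_well")


def reference_surface(name: str, **params) -> FreeEnergySurface:
    """Build one of the canonical analytic surfaces.

    Parameters
    ----------
    name:
        One of ``flat``, ``harmonic`` (params: ``k_surface`` kJ/mol/nm^2),
        ``square_well`` (params: ``depth`` kJ/mol, ``z_lo``/``z_hi`` nm) or
        ``membrane_double_well`` (params: ``D`` well depth kJ/mol,
        ``z_min`` nm, ``B`` central barrier above the well kJ/mol).
    params:
        Surface parameters; ``z_max`` (nm, default 4.0) is accepted by all.
    """
    z_max = float(params.pop("z_max", 4.0))
    if name == "flat":
        energy = lambda z: np.zeros_like(np.asarray(z, dtype=float))  # noqa: E731
        gradient = lambda z: np.zeros_like(np.asarray(z, dtype=float))  # noqa: E731
        used = {}
    elif name == "harmonic":
        k = float(params.pop("k_surface", 10.0))
        energy = lambda z: 0.5 * k * np.asarray(z, dtype=float) ** 2  # noqa: E731
        gradient = lambda z: k * np.asarray(z, dtype=float)  # noqa: E731
        used = {"k_surface": k}
    elif name == "square_well":
        depth = float(params.pop("depth", 40.0))
        z_lo = float(params.pop("z_lo", 1.0))
        z_hi = float(params.pop("z_hi", 1.5))
        energy, gradient = _square_well(depth, z_lo, z_hi)
        used = {"depth": depth, "z_lo": z_lo, "z_hi": z_hi}
    elif name == "membrane_double_well":
        D = float(params.pop("D", 40.0))
        z_min = float(params.pop("z_min", 1.4))
        B = float(params.pop("B", 25.0))
        energy, gradient = _membrane_double_well(D, z_min, B, z_max)
        used = {"D": D, "z_min": z_min, "B": B}
    else:
        raise ValueError(
            f"unknown surface {name!r}; valid names: {', '.join(SURFACE_NAMES)}"
        )
    if params:
        raise TypeError(f"unused parameters for surface {name!r}: {sorted(params)}")
    used["z_max"] = z_max
    return FreeEnergySurface(name=name, energy=energy, gradient=gradient,
                             z_max=z_max, params=used)
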