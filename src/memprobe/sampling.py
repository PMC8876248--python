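"""Overdamped Brownian sampling of a biased 1-D reaction coordinate.

Stands in for restrained (umbrella) molecular-dynamics windows: a walker
moves on U(z) = G(z) + (k/2)(z - z_ref)^2 under Euler-Maruyama dynamics

    z <- z - U'(z) * D * dt / RT + sqrt(2 * D * dt) * xi,   xi ~ N(0, 1)

whose stationary density is exp(-U(z)/RT) (up to O(k*D*dt/RT) discretization
bias; the stability contract k*D*dt/RT < 0.1 keeps that bias small).
Inertia is deliberately absent: only stationary statistics matter for
testing histogram reweighting, and the overdamped update has a one-line
stability condition.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .constants import rt
from .surfaces import FreeEnergySurface

__all__ = [
    "BiasSpec",
    "UmbrellaWindowSeries",
    "sample_biased_window",
    "sample_umbrella_windows",
]

#: stability contract: k * D * dt / RT must stay below this
STABILITY_LIMIT = 0.1


@dataclass(frozen=True)
class BiasSpec:
    """Harmonic restraint (k/2)(z - z_ref)^2; z_ref in nm, k in kJ/mol/nm^2."""

    z_ref: float
    k: float

    def __post_init__(self):
        if self.k < 0:
            raise ValueError(f"force constant must be >= 0, got {self.k}")

    def energy(self, z):
        return 0.5 * self.k * (np.asarray(z, dtype=float) - self.z_ref) ** 2

    def gradient(self, z):
        return self.k * (np.asarray(z, dtype=float) - self.z_ref)


@dataclass
class UmbrellaWindowSeries:
    """One umbrella window's reaction-coordinate time series.

    ``times`` in ps (strictly increasing), ``z`` in nm, plus the harmonic
    bias the window was run under.
    """

    times: np.ndarray
    z: np.ndarray
    bias: BiasSpec

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.z = np.asarray(self.z, dtype=float)
        if self.times.shape != self.z.shape:
            raise ValueError("times and z must have equal length")
        if self.times.size and np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")

    def __len__(self):
        return self.z.size

    def slice_time(self, t_start: float, t_end: float) -> "UmbrellaWindowSeries":
        """Sub-series with t_start <= t <= t_end (closed interval)."""
        m = (self.times >= t_start) & (self.times <= t_end)
        return UmbrellaWindowSeries(self.times[m], self.z[m], self.bias)


def _check_stability(k: float, diffusion: float, dt: float, temperature: float):
    crit = k * diffusion * dt / rt(temperature)
    if crit >= STABILITY_LIMIT:
        raise ValueError(
            f"unstable integration: k*D*dt/RT = {crit:.3g} >= {STABILITY_LIMIT}; "
            "reduce dt or diffusion"
        )


def sample_umbrella_windows(
    surface: FreeEnergySurface,
    biases: Sequence[BiasSpec],
    n_steps: int,
    dt: float = 0.1,
    diffusion: float = 4e-4,
    temperature: float = 298.15,
    seed: int = 0,
    burn_in: float = 0.1,
    z0: Sequence[float] | None = None,
) -> list[UmbrellaWindowSeries]:
    """Run all umbrella windows at once (vectorized over windows).

    Each window gets an independent child stream of ``seed``; the walker
    starts at its window's z_ref unless ``z0`` is given.  The first
    ``burn_in`` fraction of steps is discarded.

    Parameters
    ----------
    surface : ground-truth free-energy surface G(z), kJ/mol.
    biases : harmonic restraints, one per window.
    n_steps : steps retained per window *before* burn-in removal is applied
        to the total run of ``n_steps`` (i.e. the returned series has
        ``n_steps - floor(burn_in * n_steps)`` samples).
    dt : time step, ps.
    diffusion : D, nm^2/ps.
    temperature : K.
    seed : base seed; same seed and inputs give identical output.
    """
    if n_steps < 1:
        raise ValueError("n_steps must be >= 1")
    if not 0 <= burn_in < 1:
        raise ValueError("burn_in fraction must be in [0, 1)")
    biases = list(biases)
    kmax = max(b.k for b in biases)
    _check_stability(kmax, diffusion, dt, temperature)

    n_win = len(biases)
    z_ref = np.array([b.z_ref for b in biases], dtype=float)
    k = np.array([b.k for b in biases], dtype=float)
    beta_step = diffusion * dt / rt(temperature)
    noise_sd = np.sqrt(2.0 * diffusion * dt)

    rng = np.random.default_rng(np.random.SeedSequence(seed))
    z = np.array(z_ref if z0 is None else z0, dtype=float).copy()
    if z.shape != (n_win,):
        raise ValueError("z0 must have one entry per window")

    n_burn = int(np.floor(burn_in * n_steps))
    kept = n_steps - n_burn
    out = np.empty((n_win, kept), dtype=float)
    grad = surface.gradient
    for step in range(n_steps):
        g = grad(z) + k * (z - z_ref)
        if not np.all(np.isfinite(g)):
            bad = int(np.flatnonzero(~np.isfinite(g))[0])
            raise FloatingPointError(
                f"non-finite gradient at z={z[bad]:.4f} nm (window {bad})"
            )
        z = z - g * beta_step + noise_sd * rng.standard_normal(n_win)
        if step >= n_burn:
            out[:, step - n_burn] = z

    times = dt * (np.arange(n_burn, n_steps) + 1)
    return [
        UmbrellaWindowSeries(times.copy(), out[i], biases[i]) for i in range(n_win)
    ]


def sample_biased_window(
    surface: FreeEnergySurface,
    bias: BiasSpec,
    n_steps: int,
    dt: float = 0.1,
    diffusion: float = 4e-4,
    temperature: float = 298.15,
    seed: int = 0,
    burn_in: float = 0.1,
    z0: float | None = None,
) -> UmbrellaWindowSeries:
    """Sample a single biased window; see :func:`sample_umbrella_windows`."""
    z0_arr = None if z0 is None else [float(z0)]
    (series,) = sample_umbrella_windows(
        surface, [bias], n_steps, dt=dt, diffusion=diffusion,
        temperature=temperature, seed=seed, burn_in=burn_in, z0=z0_arr,
    )
    return series
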