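"""Weighted Histogram Analysis Method for umbrella-sampling data.

Reconstructs a potential of mean force G(z) from harmonically biased
window histograms by the standard self-consistent iteration

    p_b  proportional to  (sum_i n_ib) / (sum_i N_i exp((f_i - c_ib)/RT))
    f_i = -RT ln sum_b p_b exp(-c_ib/RT)

with c_ib = (k_i/2)(z_b - z_ref,i)^2 evaluated at bin centers, iterated
until the per-window free energies f_i stop moving.  Includes block
bootstrapping for pointwise error bands, convergence scans over time
sub-ranges, and extraction of translocation/desorption barriers.

Conventions: the profile is one-sided over z in [0, z_max] (one leaflet),
anchored so that G = 0 in the water phase at z = z_max; the translocation
barrier is G(0) - G_min and the desorption barrier G(z_max) - G_min.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components
from scipy import stats

from .constants import rt
from .sampling import BiasSpec, UmbrellaWindowSeries

__all__ = [
    "WindowHistograms",
    "FreeEnergyProfile",
    "BarrierSummary",
    "build_histograms",
    "solve_wham",
    "bootstrap_uncertainty",
    "convergence_scan",
    "extract_barriers",
    "barrier_trend",
]


@dataclass
class WindowHistograms:
    """Per-window histograms of the reaction coordinate on a shared grid."""

    bin_edges: np.ndarray            # (n_bins + 1,) nm, strictly increasing
    counts: np.ndarray               # (n_windows, n_bins) int
    biases: list[BiasSpec]
    n_samples: np.ndarray            # (n_windows,) samples per window (binned)
    n_outside: np.ndarray            # (n_windows,) samples outside z_range

    def __post_init__(self):
        self.bin_edges = np.asarray(self.bin_edges, dtype=float)
        self.counts = np.asarray(self.counts, dtype=np.int64)
        self.n_samples = np.asarray(self.n_samples, dtype=np.int64)
        self.n_outside = np.asarray(self.n_outside, dtype=np.int64)
        if np.any(np.diff(self.bin_edges) <= 0):
            raise ValueError("bin_edges must be strictly increasing")
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")
        if not np.array_equal(self.counts.sum(axis=1), self.n_samples):
            raise ValueError("row sums of counts must equal n_samples")

    @property
    def bin_centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])

    def overlap_fraction(self, i: int, j: int) -> float:
        """Fraction of window i's samples falling in bins also hit by j."""
        shared = (self.counts[i] > 0) & (self.counts[j] > 0)
        n = self.n_samples[i]
        return float(self.counts[i, shared].sum() / n) if n else 0.0


@dataclass
class FreeEnergyProfile:
    """PMF G(z) on a grid, optionally with a pointwise error band.

    Bins never visited carry ``nan`` in G (masked).  ``anchor`` records the
    zero convention ('zmax': G = 0 at the largest sampled z; 'min': G = 0 at
    the minimum).
    """

    z: np.ndarray
    G: np.ndarray
    temperature: float
    err: np.ndarray | None = None
    anchor: str = "zmax"
    window_free_energies: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self):
        self.z = np.asarray(self.z, dtype=float)
        self.G = np.asarray(self.G, dtype=float)
        if self.z.shape != self.G.shape:
            raise ValueError("z and G must have equal length")
        if self.err is not None:
            self.err = np.asarray(self.err, dtype=float)
            if self.err.shape != self.G.shape:
                raise ValueError("err must match G in length")

    def value_at(self, z0: float) -> float:
        """G at the grid point nearest to z0 (nan if masked there)."""
        idx = int(np.argmin(np.abs(self.z - z0)))
        return float(self.G[idx])


@dataclass(frozen=True)
class BarrierSummary:
    """Well location/depth and the two free-energy barriers (kJ/mol)."""

    z_min: float
    G_min: float
    translocation: float   # G(0) - G_min
    desorption: float      # G(z_max) - G_min


def build_histograms(
    windows: Sequence[UmbrellaWindowSeries],
    bin_width: float = 0.02,
    z_range: tuple[float, float] = (0.0, 4.0),
) -> WindowHistograms:
    """Histogram every window's samples on a shared grid.

    Samples outside ``z_range`` are counted per window and reported in
    ``n_outside`` but not binned.
    """
    if len(windows) < 1:
        raise ValueError("need at least one window")
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    lo, hi = z_range
    if hi <= lo:
        raise ValueError("z_range must be increasing")
    n_bins = int(round((hi - lo) / bin_width))
    edges = lo + bin_width * np.arange(n_bins + 1)

    counts = np.zeros((len(windows), n_bins), dtype=np.int64)
    n_samples = np.zeros(len(windows), dtype=np.int64)
    n_outside = np.zeros(len(windows), dtype=np.int64)
    for i, w in enumerate(windows):
        if len(w) == 0:
            raise ValueError(f"window {i} (z_ref={w.bias.z_ref}) has no samples")
        c, _ = np.histogram(w.z, bins=edges)
        counts[i] = c
        n_samples[i] = c.sum()
        n_outside[i] = len(w) - c.sum()
    return WindowHistograms(edges, counts, [w.bias for w in windows],
                            n_samples, n_outside)


def _check_overlap_connectivity(counts: np.ndarray):
    """Raise if the windows do not form one histogram-overlap component."""
    occ = counts > 0
    adj = (occ @ occ.T) > 0   # windows sharing >= 1 occupied bin
    n_comp, labels = connected_components(csr_matrix(adj), directed=False)
    if n_comp > 1:
        groups = [np.flatnonzero(labels == c).tolist() for c in range(n_comp)]
        raise ValueError(
            "umbrella windows do not overlap into a single connected set; "
            f"disconnected groups (window indices): {groups}"
        )


def solve_wham(
    hists: WindowHistograms,
    temperature: float = 298.15,
    tol: float = 1e-6,
    max_iter: int = 100_000,
    anchor: Literal["zmax", "min"] = "zmax",
) -> FreeEnergyProfile:
    """Self-consistent WHAM solution of the biased histograms.

    Iterates the coupled equations for the unbiased bin probabilities and
    the per-window free energies f_i until max_i |delta f_i| < ``tol``
    (kJ/mol, after gauge-fixing f to zero mean).  Empty bins are masked
    (nan) in the returned profile.
    """
    if tol <= 0:
        raise ValueError("tol must be positive")
    RT = rt(temperature)
    centers = hists.bin_centers
    counts = hists.counts
    N = hists.n_samples.astype(float)
    total = counts.sum(axis=0).astype(float)
    occupied = total > 0
    _check_overlap_connectivity(counts)

    # c_ib: bias energy of window i at bin center b, in RT units
    z_ref = np.array([b.z_ref for b in hists.biases])
    k = np.array([b.k for b in hists.biases])
    c = 0.5 * k[:, None] * (centers[None, :] - z_ref[:, None]) ** 2 / RT

    log_N = np.log(N)
    log_total = np.where(occupied, np.log(np.where(occupied, total, 1.0)), -np.inf)
    c_occ = c[:, occupied]
    log_total_occ = log_total[occupied]
    n_occ = int(occupied.sum())

    def _lse(a, axis):
        m = a.max(axis=axis, keepdims=True)
        return (m + np.log(np.exp(a - m).sum(axis=axis, keepdims=True))) \
            .squeeze(axis)

    f = np.zeros(len(N))  # in RT units
    log_p_occ = np.full(n_occ, -np.log(n_occ))
    for it in range(max_iter):
        # log p_b = log(total_b) - logsumexp_i [log N_i + f_i - c_ib]
        log_p_occ = log_total_occ - _lse((log_N + f)[:, None] - c_occ, axis=0)
        log_p_occ -= _lse(log_p_occ, axis=0)
        f_new = -_lse(log_p_occ[None, :] - c_occ, axis=1)
        f_new -= f_new.mean()
        delta = np.max(np.abs(f_new - f))
        f = f_new
        if delta * RT < tol:
            break
    else:
        raise RuntimeError(
            f"WHAM did not converge in {max_iter} iterations "
            f"(residual {delta * RT:.3g} kJ/mol > tol {tol:g})"
        )

    log_p = np.full(occupied.size, -np.inf)
    log_p[occupied] = log_p_occ
    G = np.where(occupied, -RT * log_p, np.nan)
    G = _apply_anchor(centers, G, anchor)
    return FreeEnergyProfile(centers, G, temperature, anchor=anchor,
                             window_free_energies=f * RT)


def _apply_anchor(z: np.ndarray, G: np.ndarray, anchor: str) -> np.ndarray:
    ok = np.isfinite(G)
    if not ok.any():
        raise ValueError("profile has no sampled bins")
    if anchor == "zmax":
        ref = G[np.flatnonzero(ok)[-1]]     # largest sampled z
    elif anchor == "min":
        ref = np.nanmin(G)
    else:
        raise ValueError(f"unknown anchor convention {anchor!r}")
    return G - ref


def bootstrap_uncertainty(
    windows: Sequence[UmbrellaWindowSeries],
    n_boot: int = 20,
    seed: int = 0,
    block_length: float | None = None,
    bin_width: float = 0.02,
    z_range: tuple[float, float] = (0.0, 4.0),
    temperature: float = 298.15,
    tol: float = 1e-6,
    max_iter: int = 100_000,
    anchor: Literal["zmax", "min"] = "zmax",
) -> FreeEnergyProfile:
    """PMF with a pointwise bootstrap error band.

    Resampling unit: within each window, contiguous time blocks of
    ``block_length`` ps drawn with replacement (block bootstrap; defaults
    to 5% of the window length, at least one sample).  ``err`` is the
    pointwise standard deviation of the anchored PMFs over ``n_boot``
    resamples; the central profile is the full-data WHAM solution.
    """
    if n_boot < 2:
        raise ValueError("n_boot must be >= 2")
    hists = build_histograms(windows, bin_width=bin_width, z_range=z_range)
    center = solve_wham(hists, temperature=temperature, tol=tol,
                        max_iter=max_iter, anchor=anchor)

    rng = np.random.default_rng(np.random.SeedSequence(seed))
    profiles = np.full((n_boot, center.z.size), np.nan)
    for b in range(n_boot):
        resampled = []
        for w in windows:
            dt = w.times[1] - w.times[0] if len(w) > 1 else 1.0
            span = block_length if block_length is not None \
                else 0.05 * (w.times[-1] - w.times[0] + dt)
            blk = max(1, int(round(span / dt)))
            n_blocks = int(np.ceil(len(w) / blk))
            starts = rng.integers(0, max(1, len(w) - blk + 1), size=n_blocks)
            idx = (starts[:, None] + np.arange(blk)[None, :]).ravel()[: len(w)]
            resampled.append(UmbrellaWindowSeries(w.times, w.z[idx], w.bias))
        h = build_histograms(resampled, bin_width=bin_width, z_range=z_range)
        prof = solve_wham(h, temperature=temperature, tol=tol,
                          max_iter=max_iter, anchor=anchor)
        profiles[b] = prof.G

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-nan columns
        err = np.nanstd(profiles, axis=0, ddof=1)
    center.err = err
    return center


def extract_barriers(profile: FreeEnergyProfile) -> BarrierSummary:
    """Well position plus translocation and desorption barriers.

    z_min is the argmin of G over the sampled grid (smallest z on ties);
    translocation = G(0) - G_min, desorption = G(z_max) - G_min, where
    G(0) and G(z_max) are read at the first and last grid points.
    """
    G = profile.G
    if not np.isfinite(G[0]):
        raise ValueError("profile is masked at z = 0; cannot compute barriers")
    if not np.isfinite(G[-1]):
        raise ValueError("profile is masked at z_max; cannot compute barriers")
    finite = np.isfinite(G)
    Gf = np.where(finite, G, np.inf)
    i_min = int(np.argmin(Gf))          # argmin returns the first (smallest z)
    z_min = float(profile.z[i_min])
    G_min = float(G[i_min])
    return BarrierSummary(
        z_min=z_min,
        G_min=G_min,
        translocation=float(G[0] - G_min),
        desorption=float(G[-1] - G_min),
    )


def convergence_scan(
    windows: Sequence[UmbrellaWindowSeries],
    scheme: Literal["discard_initial", "discard_final", "block"] = "block",
    increment: float | None = None,
    block_length: float | None = None,
    bin_width: float = 0.02,
    z_range: tuple[float, float] = (0.0, 4.0),
    temperature: float = 298.15,
    tol: float = 1e-6,
    max_iter: int = 100_000,
    anchor: Literal["zmax", "min"] = "zmax",
) -> list[tuple[tuple[float, float], FreeEnergyProfile, BarrierSummary]]:
    """Re-solve the PMF on systematic time sub-ranges of the windows.

    ``discard_initial``: ranges [t0, T] for t0 = start, start+inc, ...;
    ``discard_final``:  ranges [start, T - j*inc];
    ``block``: consecutive disjoint windows of ``block_length`` ps.
    Ranges in which some window has no samples are skipped with a warning.
    Returns (t_range, profile, barriers) per analyzed range.
    """
    t0 = min(w.times[0] for w in windows)
    t1 = max(w.times[-1] for w in windows)
    if scheme == "block":
        if block_length is None:
            raise ValueError("block scheme requires block_length")
        edges = np.arange(t0, t1, block_length)
        ranges = [(float(a), float(min(a + block_length, t1))) for a in edges]
    else:
        if increment is None:
            raise ValueError(f"{scheme} scheme requires increment")
        n = int(np.floor((t1 - t0) / increment))
        if scheme == "discard_initial":
            ranges = [(float(t0 + j * increment), float(t1)) for j in range(n + 1)]
        elif scheme == "discard_final":
            ranges = [(float(t0), float(t1 - j * increment)) for j in range(n + 1)]
        else:
            raise ValueError(f"unknown scheme {scheme!r}")
        ranges = [(a, b) for a, b in ranges if b > a]

    results = []
    for a, b in ranges:
        sliced = [w.slice_time(a, b) for w in windows]
        if any(len(s) == 0 for s in sliced):
            warnings.warn(f"time range ({a:g}, {b:g}) ps has an empty window; skipped")
            continue
        hists = build_histograms(sliced, bin_width=bin_width, z_range=z_range)
        prof = solve_wham(hists, temperature=temperature, tol=tol,
                          max_iter=max_iter, anchor=anchor)
        results.append(((a, b), prof, extract_barriers(prof)))
    return results


def barrier_trend(
    scan: Sequence[tuple[tuple[float, float], FreeEnergyProfile, BarrierSummary]],
    which: Literal["translocation", "desorption"] = "desorption",
    confidence: float = 0.95,
) -> dict:
    """Linear trend of a barrier across scan blocks, with a slope CI.

    A stationary series should give a confidence interval containing 0;
    a drifting one should not.
    """
    if len(scan) < 3:
        raise ValueError("need at least 3 scan points for a trend")
    x = np.arange(len(scan), dtype=float)
    y = np.array([getattr(b, which) for _, _, b in scan])
    res = stats.linregress(x, y)
    tcrit = stats.t.ppf(0.5 + confidence / 2, len(scan) - 2)
    half = tcrit * res.stderr
    lo, hi = res.slope - half, res.slope + half
    return {
        "slope": float(res.slope),
        "ci": (float(lo), float(hi)),
        "significant": not (lo <= 0.0 <= hi),
        "which": which,
        "confidence": confidence,
    }
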