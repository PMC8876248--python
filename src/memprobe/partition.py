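"""Lipid/water partition coefficients from PMFs and from titrations.

Two independent routes to the partition coefficient K_P = [probe]_lipid /
[probe]_water of a membrane probe:

* from a free-energy profile, as the (relative, nm-weighted) Boltzmann
  integral over the membrane-spanning coordinate,
      K_P  proportional to  integral_0^a exp(-G(z)/RT) dz,
  meaningful only as a ratio between probes (the proportionality constant
  is undefined), hence :func:`normalize_kp`;

* from a fluorescence titration against lipid concentration, by nonlinear
  least squares on the partition binding curve
      I([L]) = (S_W + S_M * K_P * Vbar * [L]) / (1 + K_P * Vbar * [L]),
  where S_W and S_M are the fluorescence signals of the fully aqueous and
  fully membrane-bound dye and Vbar is the lipid molar volume
  (0.8 dm^3/mol for POPC).

Replicate titrations are aggregated on the log scale (mean of ln K_P with
a Student-t confidence interval), since K_P estimates scatter multiplica-
tively.  Henderson-Hasselbalch bookkeeping for the probes' ionization
states is also provided.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats

from .constants import rt
from .wham import FreeEnergyProfile

__all__ = [
    "PartitionModel",
    "PartitionFitResult",
    "AggregateKP",
    "IonizationSpec",
    "partition_intensity",
    "kp_integral",
    "normalize_kp",
    "fit_partition_model",
    "aggregate_kp",
    "species_fractions",
]

#: POPC molar volume in the membrane, dm^3/mol
VBAR_POPC = 0.8


@dataclass(frozen=True)
class PartitionModel:
    """Parameters of the partition binding curve."""

    S_W: float                 # signal, all dye aqueous (arbitrary units)
    S_M: float                 # signal, all dye membrane-bound
    K_P: float                 # partition coefficient, dimensionless
    V_bar: float = VBAR_POPC   # lipid molar volume, dm^3/mol

    def __post_init__(self):
        if self.K_P <= 0:
            raise ValueError(f"K_P must be positive, got {self.K_P}")
        if self.V_bar <= 0:
            raise ValueError(f"V_bar must be positive, got {self.V_bar}")

    def intensity(self, lipid_conc) -> np.ndarray:
        return partition_intensity(lipid_conc, self.S_W, self.S_M,
                                   self.K_P, self.V_bar)


def partition_intensity(lipid_conc, S_W, S_M, K_P, V_bar=VBAR_POPC):
    """Fluorescence intensity of a partitioning dye vs lipid concentration."""
    c = np.asarray(lipid_conc, dtype=float)
    x = K_P * V_bar * c
    return (S_W + S_M * x) / (1.0 + x)


@dataclass
class PartitionFitResult:
    """Least-squares estimates of (S_W, S_M, K_P) with standard errors."""

    S_W: float
    S_M: float
    K_P: float
    se_S_W: float
    se_S_M: float
    se_ln_K_P: float
    residual_norm: float
    converged: bool
    replicate_id: str = ""
    message: str = ""
    V_bar: float = VBAR_POPC

    @property
    def se_K_P(self) -> float:
        # delta method on the log-parameterization
        return self.K_P * self.se_ln_K_P

    @property
    def sm_sw_ratio(self) -> float:
        return self.S_M / self.S_W


@dataclass(frozen=True)
class AggregateKP:
    """Characteristic K_P over replicates: exp(mean ln K_P) with a t-CI."""

    K_P: float
    ci_lower: float
    ci_upper: float
    confidence: float
    n: int

    def __post_init__(self):
        if not (self.ci_lower <= self.K_P <= self.ci_upper):
            raise ValueError("CI must bracket the characteristic K_P")


@dataclass(frozen=True)
class IonizationSpec:
    """Acid-base transitions of a probe: one pKa per deprotonation step.

    ``species`` labels the n+1 protonation states from most protonated to
    least (e.g. cation -> neutral), matching the order of ``pkas``.
    """

    pkas: tuple
    species: tuple

    def __post_init__(self):
        if len(self.species) != len(self.pkas) + 1:
            raise ValueError("need exactly one more species label than pKa values")
        if not all(np.isfinite(self.pkas)):
            raise ValueError("pKa values must be finite")


def kp_integral(profile: FreeEnergyProfile, a: float = 4.0,
                temperature: float | None = None) -> float:
    """Relative partition coefficient: trapezoidal integral of exp(-G/RT).

    Integrates over z in [0, a] nm.  The result is nm-weighted and
    unnormalized: only ratios between probes are physically meaningful.
    The profile must be anchored so G is ~0 in the water phase near z = a.
    Masked (nan) bins are linearly interpolated with a warning.
    """
    T = profile.temperature if temperature is None else temperature
    RT = rt(T)
    z, G = profile.z, profile.G
    step = z[1] - z[0] if z.size > 1 else 0.0
    # bin-center grids legitimately stop half a step short of the
    # integration limits; pad by up to one step with edge values
    if a < z[0] - 1e-12 or a > z[-1] + step + 1e-12:
        raise ValueError(f"a = {a} nm lies outside the profile grid "
                         f"[{z[0]:.3g}, {z[-1]:.3g}]")
    mask = np.isfinite(G)
    if not mask.all():
        warnings.warn(f"{(~mask).sum()} masked bins interpolated linearly "
                      "inside kp_integral")
        G = np.interp(z, z[mask], G[mask])
    if z[0] > 0.0:
        z = np.concatenate([[max(0.0, z[0] - step)], z])
        G = np.concatenate([[G[0]], G])
    m = z <= a + 1e-12
    zz, gg = z[m], G[m]
    if zz[-1] < a:   # extend to the exact upper limit (np.interp clamps)
        zz = np.append(zz, a)
        gg = np.append(gg, np.interp(a, z, G))
    return float(np.trapezoid(np.exp(-gg / RT), zz))


def normalize_kp(values, reference_index: int = 0) -> np.ndarray:
    """Divide relative K_P values by a chosen reference entry."""
    v = np.asarray(values, dtype=float)
    ref = v[reference_index]
    if ref <= 0:
        raise ValueError(f"reference value must be positive, got {ref}")
    return v / ref


def fit_partition_model(
    titration,
    V_bar: float = VBAR_POPC,
    initial: tuple[float, float, float] | None = None,
) -> PartitionFitResult:
    """Fit (S_W, S_M, K_P) to one titration by nonlinear least squares.

    K_P is constrained positive through a log parameterization; standard
    errors come from the Gauss-Newton approximation of the Hessian at the
    optimum (an exploding ``se_ln_K_P`` flags an unidentifiable K_P, e.g.
    when S_M is indistinguishable from S_W).

    Parameters
    ----------
    titration : object with ``lipid_concs`` (mol/dm^3), ``intensities``
        and ``replicate_id`` attributes (see synthetic.TitrationSeries).
    """
    c = np.asarray(titration.lipid_concs, dtype=float)
    y = np.asarray(titration.intensities, dtype=float)
    if np.unique(c).size < 4:
        raise ValueError("need at least 4 distinct lipid concentrations")
    if not np.all(np.isfinite(y)):
        raise ValueError("intensities must be finite")

    if initial is None:
        s_w0 = y[np.argmin(c)]
        s_m0 = y[np.argmax(c)]
        if np.isclose(s_w0, s_m0):
            s_m0 = s_w0 * 1.5 + 1.0
        # half-effect concentration as K_P V c ~ 1
        mid = 0.5 * (s_w0 + s_m0)
        i_mid = int(np.argmin(np.abs(y - mid)))
        c_mid = c[i_mid] if c[i_mid] > 0 else np.median(c[c > 0])
        kp0 = 1.0 / (V_bar * c_mid)
    else:
        s_w0, s_m0, kp0 = initial
    theta0 = np.array([s_w0, s_m0, np.log(max(kp0, 1e-12))])

    def residuals(theta):
        s_w, s_m, ln_kp = theta
        return partition_intensity(c, s_w, s_m, np.exp(ln_kp), V_bar) - y

    sol = optimize.least_squares(residuals, theta0, method="lm", xtol=1e-12,
                                 ftol=1e-12, max_nfev=20_000)
    s_w, s_m, ln_kp = sol.x
    resid = sol.fun
    dof = max(1, c.size - 3)
    s2 = float(resid @ resid) / dof
    JTJ = sol.jac.T @ sol.jac
    try:
        cov = s2 * np.linalg.inv(JTJ)
        ses = np.sqrt(np.maximum(np.diag(cov), 0.0))
    except np.linalg.LinAlgError:
        ses = np.full(3, np.inf)
    converged = bool(sol.success) and np.all(np.isfinite(sol.x))
    return PartitionFitResult(
        S_W=float(s_w), S_M=float(s_m), K_P=float(np.exp(ln_kp)),
        se_S_W=float(ses[0]), se_S_M=float(ses[1]), se_ln_K_P=float(ses[2]),
        residual_norm=float(np.sqrt(resid @ resid)),
        converged=converged,
        replicate_id=str(getattr(titration, "replicate_id", "")),
        message=str(sol.message), V_bar=V_bar,
    )


def aggregate_kp(fits, confidence: float = 0.90) -> AggregateKP:
    """Characteristic K_P across replicate fits.

    exp(mean ln K_P) with a Student-t interval
    exp(mean +/- t_{1-(1-conf)/2, n-1} * sd(ln K_P)/sqrt(n)).
    """
    kps = np.array([f.K_P for f in fits if f.converged], dtype=float)
    n = kps.size
    if n < 2:
        raise ValueError(f"need >= 2 converged fits, got {n}")
    ln = np.log(kps)
    mean, sd = ln.mean(), ln.std(ddof=1)
    tcrit = stats.t.ppf(0.5 + confidence / 2, n - 1)
    half = tcrit * sd / np.sqrt(n)
    return AggregateKP(
        K_P=float(np.exp(mean)),
        ci_lower=float(np.exp(mean - half)),
        ci_upper=float(np.exp(mean + half)),
        confidence=confidence, n=int(n),
    )


def species_fractions(spec: IonizationSpec, pH: float) -> dict:
    """Equilibrium fraction of each protonation state at the given pH.

    Sequential Henderson-Hasselbalch: relative population of state j
    (0 = fully protonated) is prod_{i<j} 10^(pH - pKa_i), normalized.
    For a single transition this reduces to
    f_acid = 1/(1 + 10^(pH - pKa)), f_base = 1 - f_acid.
    """
    if not np.isfinite(pH):
        raise ValueError("pH must be finite")
    log_rel = np.concatenate([[0.0], np.cumsum(pH - np.asarray(spec.pkas))])
    rel = np.power(10.0, log_rel - log_rel.max())
    frac = rel / rel.sum()
    return dict(zip(spec.species, frac.tolist()))
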