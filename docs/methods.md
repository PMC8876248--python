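# Methods

This note records the models implemented in `memprobe`, their
assumptions, the default parameters and why they were chosen, what the
synthetic-data layer does and does not emulate, and the numerical
decisions a maintainer would want spelled out.

## Reaction coordinate and umbrella sampling

The reaction coordinate is the probe depth *z*: the distance along the
bilayer normal between the probe's center of mass and the bilayer center
of mass. To keep the reference meaningful on an undulating membrane, the
center is computed locally — only lipids whose in-plane COM lies within a
cylinder of radius 1.1 nm around the probe contribute
(`structure.local_bilayer_com`). The coordinate is one-sided over
[0, 4] nm (one leaflet); profiles are not symmetrized, symmetrization is
applied to density profiles instead.

Umbrella windows restrain *z* with harmonic biases *k*/2 (*z* − *z*ᵢ)².
The default layout is 41 windows at 0.1 nm spacing with
*k* = 3000 kJ mol⁻¹ nm⁻², which at 298.15 K gives a restrained standard
deviation of √(RT/k) ≈ 0.029 nm — windows overlap in their tails, which
is what WHAM needs.

## WHAM

`wham.solve_wham` iterates the standard self-consistent equations with
bias energies evaluated at bin centers, entirely in log space (the bias
energy reaches ~10⁴ RT at the far end of the grid, so linear-space
arithmetic would overflow). Defaults: bin width 0.02 nm over [0, 4] nm
(≥5 bins per window spacing), tolerance 10⁻⁶ kJ/mol on the per-window
free energies, 10⁵ iteration cap. Empty bins are masked (`nan`), never
imputed. Before iterating, the windows' occupied-bin overlap graph is
checked for connectedness; disconnected window sets are a hard error
naming the groups, because WHAM would silently return arbitrary relative
offsets between them.

The profile is anchored to G = 0 at the largest sampled *z* (the water
phase), configurable to anchoring at the minimum. The water anchor is the
natural choice here because the downstream Boltzmann integral assumes the
integrand ≈ 1 in water.

Barriers: translocation = G(0) − G_min, desorption = G(z_max) − G_min,
with the minimum searched over the grid and ties broken toward the
smallest *z* for determinism.

**Uncertainty.** Block bootstrap within each window: contiguous time
blocks (default 5% of the window length) resampled with replacement,
WHAM re-solved per resample, pointwise standard deviation reported.
Whole-window resampling would lose the time-correlation structure that
dominates umbrella-sampling noise; very short blocks would understate it.

**Convergence scans.** The PMF is re-solved on systematic time
sub-ranges (growing head-discard, growing tail-discard, or disjoint
blocks) and the barrier series is tested for a monotone trend by linear
regression with a t-based slope CI (`wham.barrier_trend`). Stationary
data should give a CI containing zero; drift in the window means shows up
as a significant slope. This is a diagnostic, not a proof of convergence.

## Partition coefficients

**From the PMF.** K_P ∝ ∫₀ᵃ exp(−ΔG(z)/RT) dz with a = 4 nm, by
trapezoid on the profile grid. The proportionality constant is undefined
(the integral is nm-weighted and depends on the reference-state
convention), so the package only reports the raw integral and normalized
ratios between probes (`normalize_kp`). Masked bins are linearly
interpolated with a warning; bin-center grids are padded by up to one
grid step so the integration limits [0, a] are reachable. A Richardson
check (halving the grid changes the result by <0.1% for smooth profiles)
is part of the test suite.

**From titrations.** The binding curve
I([L]) = (S_W + S_M·K_P·V̄·[L])/(1 + K_P·V̄·[L]) is fit by
Levenberg–Marquardt least squares with K_P log-parameterized (positivity
by construction), uniform weights (no weighting scheme is implied by the
data model), and standard errors from the Gauss–Newton Hessian at the
optimum. An unidentifiable K_P — e.g. S_M ≈ S_W, so the curve is flat —
manifests as an exploding standard error on ln K_P rather than a silent
failure. V̄ defaults to 0.8 dm³/mol, the molar volume of a
phosphatidylcholine in the membrane.

Replicates are aggregated on the log scale: characteristic
K_P = exp(mean ln K_P) with a Student-t interval (90% by default).
K_P estimates scatter multiplicatively, and the t-interval on ln K_P is
the simplest interval consistent with that; the interval method is a
package decision and is configurable. Simulation and titration
temperatures are independent explicit parameters (298.15 K and 310.15 K
defaults respectively); nothing couples them implicitly.

**Ionization.** `species_fractions` applies sequential
Henderson–Hasselbalch bookkeeping (fraction of state j ∝ Π 10^(pH−pKaᵢ)).
It deliberately does not mix PMFs across protonation states: aqueous pKa
values need not hold for membrane-inserted dyes, and no correction for
that is attempted.

## Structural descriptors

All coordinates are nm; *z* = 0 at the (global or local) lipid COM.

* **Density profiles** re-center each frame on the lipid COM, histogram
  mass over z, divide by bin volume and average over frames; optional
  (ρ(z)+ρ(−z))/2 symmetrization (exactly even on the symmetric grid) and
  a display scale factor for dilute species. Mass is conserved to binning
  tolerance (tested).
* **Depths** are leaflet-folded |z| of per-molecule group COMs, mean ± sd
  over frames and molecules.
* **Area per lipid** is Lx·Ly/(n_lipids/2) per frame.
* **Order parameters**: for interior chain carbon i the local axis is
  C(i−1)→C(i+1); the two methylene C–H unit vectors are reconstructed in
  tetrahedral geometry (in the plane of the C–C–C bisector and plane
  normal, perpendicular to the local axis), which is the standard
  treatment for united-atom chains without explicit hydrogens;
  S_CD = ⟨(3cos²θ_CH − 1)/2⟩ and −S_CD is reported. Near-collinear
  neighbors (undefined azimuth) fall back to the analytic azimuthal
  average (1 − cos²θ_axis)/2. Terminal carbons are omitted.
* **Tilts** are measured against the outward normal of the molecule's own
  leaflet (sign of its COM z), so a symmetric probe in a symmetric
  bilayer peaks at 90°; a raw +z convention is available. The probe long
  axis is the vector through the two amino-bearing ring termini (N1→N2),
  the short axis runs from the xanthene COM to the benzoic-ring COM, and
  the lipid headgroup axis is P→N. Histograms are normalized to unit
  area over [0, 180]°.
* **Hydrogen bonds** use the geometric criterion donor–acceptor distance
  ≤ 0.35 nm and H–donor–acceptor angle ≤ 30° (the conventional cutoffs
  for this class of force fields), minimum-image in all three box
  dimensions, acceptors in the donor's own residue excluded, and at most
  one bond per donor hydrogen per frame (nearest qualifying acceptor).
  The implementation is vectorized; an O(N²) triple-loop oracle in the
  test suite must agree exactly on random periodic fixtures.

## Synthetic data: what it emulates, and what it does not

**Brownian windows.** `sampling.sample_biased_window` integrates
overdamped (inertialess) Langevin dynamics,
z ← z − U′(z)·D·dt/RT + √(2·D·dt)·ξ, on U = G + bias. Only stationary
statistics matter for testing histogram reweighting, and the overdamped
update has a one-line stability contract: k·D·dt/RT < 0.1 is enforced.
Defaults D = 4×10⁻⁴ nm²/ps (a small aromatic dye in water) and
dt = 0.1 ps give k·D·dt/RT ≈ 0.048 at the stiffest default bias, where
the Euler–Maruyama discretization inflates the stationary variance by
≈ k·D·dt/(2RT) ≈ 2.4% — visible in, and accounted for by, the Boltzmann
tests. The first 10% of steps are discarded as burn-in, mirroring the
usual practice of dropping the initial segment of restrained runs.

**Toy bilayer.** `toybilayer.generate_membrane_frames` draws i.i.d.
frames of a 128-lipid bilayer (two leaflets of 64 on a jittered grid,
box 6.4 × 6.4 × 9 nm, area per lipid 0.64 nm²) with 4 probe molecules.
Lipids are pseudo-atom models (choline N placed from P by a P–N vector of
prescribed tilt, phosphate/carbonyl oxygens at prescribed depths, a rigid
all-trans zigzag chain of 15 carbons at a prescribed tilt); probes carry
xanthene dummies, amino termini with hydrogens, benzoic dummies and an
ester site, placed at a per-leaflet Gaussian depth (default
1.5 ± 0.4 nm, the observed COM depth of the cationic dye) and prescribed
long-axis tilt. Acceptor-only waters are planted at ideal hydrogen-bond
geometry relative to probe donor hydrogens at a prescribed per-donor
rate; the rest sit far away in the water slab. How the 4 probes split
between leaflets is an explicit parameter (`probes_upper`), since an even
split is an assumption, not a given.

Because every observable is drawn directly from its target distribution,
passing tests demonstrate that the *descriptors* measure what they claim
on geometry with known statistics. They do not demonstrate anything about
real bilayers: there is no bonded physics, no water structure, no
electrostatics, no coupling between observables, and no time correlation
between frames. Likewise the Brownian sampler validates the WHAM/
bootstrap/scan machinery, not force-field accuracy.

**Titrations.** Intensities follow the binding curve with multiplicative
Gaussian noise (fluorescence error scales with signal), default
CV 2%. Default design: 12 log-spaced lipid concentrations plus a
lipid-free point — enough to pin S_W, S_M and K_P when the highest
concentration reaches K_P·V̄·[L] ≳ 1.

## Problem sizes

The test suite and drivers run at desk scale by design: 2×10⁵ Brownian
samples per window for full-scale recovery checks (recovering the 40 and
25 kJ/mol barriers to within ~1 kJ/mol of statistical noise), 2–5×10⁴
samples for plumbing tests, 20–40 frames of the toy bilayer, and 100
seeded titration repeats for the recovery averages. These sizes were
chosen so the statistical error of each check sits comfortably inside its
assertion tolerance.

## Known limitations

* WHAM only; no MBAR or umbrella-integration estimators, no 2-D
  coordinates, no automatic window placement.
* The bootstrap resamples within windows; correlated errors *between*
  windows (e.g. a shared slow bilayer mode) are not modeled.
* The titration fit assumes a single fluorescent species; ionization
  mixtures enter only through the separate Henderson–Hasselbalch
  bookkeeping.
* The toy bilayer's i.i.d. frames make time-series diagnostics on it
  trivially stationary; drift fixtures for the convergence scan are
  constructed at the window-series level instead.
* GRO parsing is fixed-column and strict; malformed records are rejected,
  not coerced. Binary trajectories (XTC/TRR) are delegated to MDAnalysis.
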