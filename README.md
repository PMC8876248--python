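# memprobe

Analysis toolkit for the interaction of fluorescent probes (rhodamine-like
dyes) with lipid bilayers: reconstruction of free-energy profiles from
umbrella-sampling data, lipid/water partition coefficients estimated from
both simulation and fluorescence titrations, and the standard structural
descriptors of bilayer/probe systems. A synthetic-data layer generates
every input with known ground truth, so the whole pipeline is testable at
desk scale without molecular-dynamics production runs.

## What it computes

**Potential of mean force (PMF).** Umbrella-sampling windows restrain the
probe depth *z* (distance between the probe's center of mass and the local
bilayer center of mass) with harmonic biases *k*/2 (*z* − *z*ᵢ)². The
unbiased profile ΔG(*z*) is recovered by the Weighted Histogram Analysis
Method — the self-consistent equations

```
p_b ∝ Σᵢ n_ib / Σᵢ Nᵢ exp((fᵢ − c_ib)/RT),    fᵢ = −RT ln Σ_b p_b exp(−c_ib/RT)
```

iterated to a tolerance on the window free energies fᵢ, with block
bootstrapping for pointwise error bands and convergence scans over
simulation-time sub-ranges. From the profile, the **translocation barrier**
ΔG(0) − ΔG_min and the **desorption barrier** ΔG(*z*_max) − ΔG_min are
extracted.

**Partition coefficients.** Two independent routes to
K_P = [probe]_lipid/[probe]_water:

* from a PMF, the relative Boltzmann integral
  K_P ∝ ∫₀ᵃ exp(−ΔG(z)/RT) dz (a = 4 nm); only ratios between probes are
  meaningful, so values are reported normalized to a reference probe;
* from a fluorescence titration against lipid concentration [L], by
  nonlinear least squares on
  I([L]) = (S_W + S_M·K_P·V̄·[L]) / (1 + K_P·V̄·[L]),
  with V̄ = 0.8 dm³/mol the lipid molar volume; replicate fits are
  aggregated as exp(mean ln K_P) with a Student-t confidence interval.

**Structural descriptors.** Symmetrized mass-density profiles along the
bilayer normal, leaflet-folded group depths, area per lipid, sn-1
deuterium order parameters −S_CD (united-atom C–H reconstruction), axis
tilt distributions (xanthene long/short axes, lipid P–N vector) against
the outward leaflet normal, geometric hydrogen bonds (donor–acceptor
≤ 0.35 nm and H–donor–acceptor angle ≤ 30°), and the local-cylinder
bilayer center of mass that defines the reaction coordinate.

**Synthetic data.** Overdamped Brownian sampling on analytic free-energy
surfaces (the stationary law is exactly Boltzmann, so WHAM output can be
checked against ground truth), toy bilayer/probe trajectories with
prescribed depth/orientation/H-bond statistics, and titration curves with
multiplicative noise.

## Worked example

```python
import numpy as np
import memprobe as mp

# umbrella sampling on a membrane-like double well (well 40 kJ/mol at
# 1.4 nm, central barrier 25 kJ/mol above the well)
surface = mp.reference_surface("membrane_double_well", D=40, z_min=1.4, B=25)
biases = [mp.BiasSpec(z, 3000.0) for z in np.linspace(0, 4, 41)]
windows = mp.sample_umbrella_windows(surface, biases, n_steps=200_000, seed=0)

profile = mp.solve_wham(mp.build_histograms(windows))
b = mp.extract_barriers(profile)
print(f"translocation {b.translocation:.1f} kJ/mol, desorption {b.desorption:.1f}")
# translocation 24.7 kJ/mol, desorption 40.8

# partition coefficient from a synthetic titration
model = mp.PartitionModel(S_W=100, S_M=10, K_P=190, V_bar=0.8)
tit = mp.generate_titration(model, mp.default_lipid_concs(), noise_cv=0.02, seed=1)
fit = mp.fit_partition_model(tit)
print(f"K_P = {fit.K_P:.0f}")
# K_P = 178
```

The recovered barriers sit within the bootstrap uncertainty of the 25 and
40 kJ/mol ground truth. A single titration replicate at 2% noise scatters
around the generating K_P = 190 by 5–10%; aggregating replicates on the
log scale (`aggregate_kp`, as in `analysis/04_partition_coefficients.py`)
narrows this to a few percent.

## Analysis scripts

The numbered drivers under `analysis/` walk through the full study on
synthetic data and write tables under `results/analysis/`:

1. `01_simulate_umbrella_windows.py` — 41 biased Brownian windows, pull-XVG.
2. `02_reconstruct_pmf.py` — WHAM + bootstrap band + barriers.
3. `03_convergence_diagnostics.py` — barrier stability over time sub-ranges.
4. `04_partition_coefficients.py` — Boltzmann integrals, titration fits,
   ionization fractions.
5. `05_bilayer_descriptors.py` — densities, depths, order, tilts, H bonds.

A YAML-configured pipeline with the same stages is exposed as a CLI:
`memprobe run config.yaml --stage all`, plus `memprobe fit-titration` and
`memprobe kp-from-pmf`.

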