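"""Synthetic bilayer + probe trajectories with known ground truth.

Builds toy frames of a POPC-like bilayer carrying rhodamine-like probe
molecules, using pseudo-atoms with realistic names and masses but no
bonded physics: every structural descriptor in :mod:`memprobe.structure`
only needs geometry, so each observable (atom depths, axis tilts,
hydrogen-bond contacts, chain order) is drawn directly from a prescribed
distribution whose parameters are the ground truth the tests check
against.

Model molecules:

* lipid (resname POPC, 21 atoms): choline N placed from the phosphate P
  by a P-N vector of prescribed tilt; phosphate oxygens O8/O9 and
  carbonyl oxygens O12/O14 at prescribed depths; an all-trans zigzag
  sn-1-like chain C2..C16 tilted by a prescribed angle from the normal.
* probe (resname RHD, 12 atoms): three xanthene dummies X1-X3 on the long
  axis, amino termini N1/N2 (each with an H) marking the long-axis
  endpoints, four benzoic dummies B1-B4 whose center of mass sits on the
  short axis, and an ester/COO site EST beyond it.
* water (resname SOL, single OW site), acceptor-only; a fraction of
  waters is placed at ideal hydrogen-bond geometry relative to probe
  donor hydrogens at a prescribed per-donor rate, the rest sit far away
  in the water slab.

Frames are i.i.d. draws (no dynamics) -- sufficient for testing
time-averaged descriptors.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Dict, Tuple

import numpy as np

from .trajectory import SelectionSpec, Trajectory

__all__ = ["ToyBilayerSpec", "generate_membrane_frames", "default_selections"]

logger = logging.getLogger(__name__)

_MASS = {"N": 14.007, "P": 30.974, "O": 15.999, "C": 12.011, "H": 1.008}

# all-trans zigzag geometry: C-C bond 0.153 nm, tetrahedral angle
_CC_BOND = 0.153
_HALF_ANGLE = np.deg2rad(35.25)           # bond vs chain-axis angle
_CHAIN_STEP = _CC_BOND * np.cos(_HALF_ANGLE)
_CHAIN_AMP = 0.5 * _CC_BOND * np.sin(_HALF_ANGLE)

_N_CHAIN = 15                              # C2..C16
LIPID_ATOMS = ["N", "P", "O8", "O9", "O12", "O14"] + [
    f"C{i}" for i in range(2, 2 + _N_CHAIN)
]
PROBE_ATOMS = ["N1", "HN1", "N2", "HN2", "X1", "X2", "X3",
               "B1", "B2", "B3", "B4", "EST"]

#: ideal donor-acceptor distance used for planted hydrogen bonds, nm
HBOND_DA_DISTANCE = 0.28


@dataclass
class ToyBilayerSpec:
    """Parameters (means/sds in nm or degrees) of the toy bilayer."""

    box: Tuple[float, float, float] = (6.4, 6.4, 9.0)
    n_lipids: int = 128
    n_probes: int = 4
    #: probes in the upper leaflet (rest go to the lower); None = even split
    probes_upper: int | None = None
    #: |z| depth (mean, sd) of selected lipid atoms, nm
    lipid_depths: Dict[str, Tuple[float, float]] = field(default_factory=lambda: {
        "P": (1.88, 0.05),
        "O8": (1.80, 0.06),
        "O9": (1.80, 0.06),
        "O12": (1.55, 0.06),
        "O14": (1.50, 0.06),
    })
    pn_length: float = 0.45
    pn_tilt_mean: float = 76.0     # deg, vs outward leaflet normal
    pn_tilt_sd: float = 18.0
    chain_top_depth: float = 1.45  # |z| of C2, nm
    chain_tilt_sd: float = 15.0    # deg, chain axis vs inward normal
    probe_depth: Tuple[float, float] = (1.5, 0.4)   # |z| of probe COM
    probe_tilt_mean: float = 90.0  # deg, xanthene long axis vs outward normal
    probe_tilt_sd: float = 20.0
    hbond_rate: float = 0.5        # planted water H-bonds per donor H per frame
    n_waters: int = 48

    def __post_init__(self):
        if self.n_lipids % 2:
            raise ValueError("n_lipids must be even (two leaflets)")
        if any(e <= 0 for e in self.box):
            raise ValueError("box edges must be positive")
        sds = [sd for _, sd in self.lipid_depths.values()]
        sds += [self.pn_tilt_sd, self.chain_tilt_sd, self.probe_depth[1],
                self.probe_tilt_sd]
        if any(sd < 0 for sd in sds):
            raise ValueError("all standard deviations must be >= 0")
        if not 0 <= self.hbond_rate <= 1:
            raise ValueError("hbond_rate must be in [0, 1]")
        if self.probes_upper is not None and not 0 <= self.probes_upper <= self.n_probes:
            raise ValueError("probes_upper must be within [0, n_probes]")


def _unit_from_tilt(rng, tilt_mean_deg, tilt_sd_deg, outward):
    """Unit vector at a Gaussian-sampled tilt from ``outward`` (+/-z), uniform azimuth."""
    theta = np.deg2rad(rng.normal(tilt_mean_deg, tilt_sd_deg))
    phi = rng.uniform(0, 2 * np.pi)
    v = np.array([np.sin(theta) * np.cos(phi),
                  np.sin(theta) * np.sin(phi),
                  np.cos(theta)])
    if outward < 0:
        v[2] = -v[2]
    return v


def _perp_basis(u, rng):
    """Two orthonormal vectors perpendicular to u, at a uniform rotation."""
    ref = np.array([0.0, 0.0, 1.0]) if abs(u[2]) < 0.9 else np.array([1.0, 0.0, 0.0])
    v = np.cross(u, ref)
    v /= np.linalg.norm(v)
    w = np.cross(u, v)
    psi = rng.uniform(0, 2 * np.pi)
    return np.cos(psi) * v + np.sin(psi) * w, None


def _probe_template():
    """Local-frame probe coordinates: rows match PROBE_ATOMS.

    e1 = long axis (N1 -> N2), e2 = short axis (xanthene COM -> benzoic COM),
    e3 = e1 x e2.  Xanthene COM at the origin.
    """
    return np.array([
        [-0.50, 0.00, 0.00],   # N1
        [-0.60, 0.00, 0.00],   # HN1
        [+0.50, 0.00, 0.00],   # N2
        [+0.60, 0.00, 0.00],   # HN2
        [-0.35, 0.00, 0.00],   # X1
        [0.00, 0.00, 0.00],    # X2
        [+0.35, 0.00, 0.00],   # X3
        [+0.08, 0.45, 0.00],   # B1
        [-0.08, 0.45, 0.00],   # B2
        [0.00, 0.45, +0.08],   # B3
        [0.00, 0.45, -0.08],   # B4
        [0.00, 0.65, 0.00],    # EST
    ])


def _atom_metadata(spec: ToyBilayerSpec):
    names, masses, resids, resnames = [], [], [], []
    rid = 0
    for _ in range(spec.n_lipids):
        rid += 1
        for a in LIPID_ATOMS:
            names.append(a)
            masses.append(_MASS[a[0]])
            resids.append(rid)
            resnames.append("POPC")
    for _ in range(spec.n_probes):
        rid += 1
        for a in PROBE_ATOMS:
            names.append(a)
            masses.append(_MASS["H"] if a.startswith("H") else
                          _MASS["N"] if a in ("N1", "N2") else _MASS["C"])
            resids.append(rid)
            resnames.append("RHD")
    for _ in range(spec.n_waters):
        rid += 1
        names.append("OW")
        masses.append(_MASS["O"])
        resids.append(rid)
        resnames.append("SOL")
    return (np.array(names), np.array(masses), np.array(resids),
            np.array(resnames))


def generate_membrane_frames(spec: ToyBilayerSpec, n_frames: int,
                             seed: int = 0) -> Trajectory:
    """Draw ``n_frames`` i.i.d. toy bilayer configurations.

    Coordinates are lab-frame nm with the bilayer midplane at z = Lz/2
    (so lipid COM recentering in the descriptors is exercised).  Probe
    depths falling outside the box are wrapped by the periodic convention
    with a logged warning.  Atom identity and count are identical across
    frames.
    """
    if n_frames < 0:
        raise ValueError("n_frames must be >= 0")
    names, masses, resids, resnames = _atom_metadata(spec)
    n_atoms = names.size
    Lx, Ly, Lz = spec.box
    zmid = Lz / 2.0
    rng = np.random.default_rng(np.random.SeedSequence(seed))

    per_leaflet = spec.n_lipids // 2
    grid = int(np.ceil(np.sqrt(per_leaflet)))
    sx, sy = Lx / grid, Ly / grid
    template = _probe_template()
    n_up = spec.n_probes // 2 if spec.probes_upper is None else spec.probes_upper

    frames = np.empty((n_frames, n_atoms, 3))
    wrapped = 0
    for fi in range(n_frames):
        xyz = np.empty((n_atoms, 3))
        ptr = 0
        # --- lipids
        for li in range(spec.n_lipids):
            leaflet = 1.0 if li < per_leaflet else -1.0
            site = li % per_leaflet
            x0 = (site % grid + 0.5) * sx + rng.normal(0, 0.05)
            y0 = (site // grid + 0.5) * sy + rng.normal(0, 0.05)
            at = {}
            for a in ("P", "O8", "O9", "O12", "O14"):
                mu, sd = spec.lipid_depths[a]
                at[a] = np.array([x0 + rng.normal(0, 0.05),
                                  y0 + rng.normal(0, 0.05),
                                  zmid + leaflet * rng.normal(mu, sd)])
            pn = _unit_from_tilt(rng, spec.pn_tilt_mean, spec.pn_tilt_sd, leaflet)
            at["N"] = at["P"] + spec.pn_length * pn
            # all-trans chain pointing toward the midplane
            tilt = abs(rng.normal(0.0, spec.chain_tilt_sd)) \
                if spec.chain_tilt_sd > 0 else 0.0
            axis = _unit_from_tilt(rng, tilt, 0.0, -leaflet)
            lat, _ = _perp_basis(axis, rng)
            top = np.array([x0, y0, zmid + leaflet * spec.chain_top_depth])
            for ci in range(_N_CHAIN):
                at[f"C{ci + 2}"] = (top + ci * _CHAIN_STEP * axis
                                    + ((-1) ** ci) * _CHAIN_AMP * lat)
            for a in LIPID_ATOMS:
                xyz[ptr] = at[a]
                ptr += 1
        # --- probes
        for pi in range(spec.n_probes):
            leaflet = 1.0 if pi < n_up else -1.0
            depth = rng.normal(*spec.probe_depth)
            z_com = zmid + leaflet * depth
            if not 0.0 <= z_com <= Lz:
                z_com %= Lz
                wrapped += 1
            e1 = _unit_from_tilt(rng, spec.probe_tilt_mean, spec.probe_tilt_sd,
                                 leaflet)
            e2, _ = _perp_basis(e1, rng)
            e3 = np.cross(e1, e2)
            com = np.array([rng.uniform(0, Lx), rng.uniform(0, Ly), z_com])
            R = np.column_stack([e1, e2, e3])
            xyz[ptr:ptr + len(PROBE_ATOMS)] = com + template @ R.T
            ptr += len(PROBE_ATOMS)
        # --- waters (acceptor-only); one water is dedicated to each probe
        # donor H and planted at ideal H-bond geometry at the given rate
        donors = []
        for pi in range(spec.n_probes):
            base = spec.n_lipids * len(LIPID_ATOMS) + pi * len(PROBE_ATOMS)
            donors.append((base + 0, base + 1))    # N1, HN1
            donors.append((base + 2, base + 3))    # N2, HN2
        for wi in range(spec.n_waters):
            planted = False
            if wi < len(donors) and rng.random() < spec.hbond_rate:
                n_idx, h_idx = donors[wi]
                direction = xyz[h_idx] - xyz[n_idx]
                direction /= np.linalg.norm(direction)
                xyz[ptr] = xyz[n_idx] + HBOND_DA_DISTANCE * direction
                planted = True
            if not planted:
                side = 1.0 if rng.random() < 0.5 else -1.0
                xyz[ptr] = [rng.uniform(0, Lx), rng.uniform(0, Ly),
                            zmid + side * rng.uniform(3.0, zmid - 0.2)]
            ptr += 1
        frames[fi] = xyz

    if wrapped:
        logger.warning("%d probe placements fell outside the box and were "
                       "wrapped periodically", wrapped)
        warnings.warn(f"{wrapped} probe placements wrapped by the periodic "
                      "convention")
    boxes = np.tile(np.asarray(spec.box, dtype=float), (n_frames, 1))
    return Trajectory(names, masses, resids, resnames, boxes, frames)


def default_selections(traj: Trajectory) -> SelectionSpec:
    """Named groups for the toy system (lipid atoms, probe parts, water)."""
    groups = {
        "lipids": traj.select(resname="POPC"),
        "probes": traj.select(resname="RHD"),
        "xanthene": np.concatenate([traj.select(name=n, resname="RHD")
                                    for n in ("X1", "X2", "X3")]),
        "benzoic_ring": np.concatenate([traj.select(name=n, resname="RHD")
                                        for n in ("B1", "B2", "B3", "B4")]),
        "N1": traj.select(name="N1", resname="RHD"),
        "N2": traj.select(name="N2", resname="RHD"),
        "ester": traj.select(name="EST", resname="RHD"),
        "donor_N": np.sort(np.concatenate([
            traj.select(name="N1", resname="RHD"),
            traj.select(name="N2", resname="RHD")])),
        "donor_H": np.sort(np.concatenate([
            traj.select(name="HN1", resname="RHD"),
            traj.select(name="HN2", resname="RHD")])),
        "lipid_P": traj.select(name="P", resname="POPC"),
        "lipid_N": traj.select(name="N", resname="POPC"),
        "lipid_O": np.sort(np.concatenate([
            traj.select(name=n, resname="POPC")
            for n in ("O8", "O9", "O12", "O14")])),
        "water": traj.select(resname="SOL"),
    }
    chain = {f"C{i}": traj.select(name=f"C{i}", resname="POPC")
             for i in range(2, 2 + _N_CHAIN)}
    groups.update(chain)
    spec = SelectionSpec(groups)
    spec.validate(traj.n_atoms)
    return spec
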