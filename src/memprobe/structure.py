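"""Structural descriptors of bilayer/probe trajectories.

Everything a membrane-probe study reads off equilibrium trajectories:
mass density profiles along the bilayer normal, atomic/group depths,
area per lipid, acyl-chain deuterium order parameters, axis tilt
distributions, geometric hydrogen bonds, and the local-cylinder bilayer
center of mass that defines the umbrella-sampling reaction coordinate.

Conventions: coordinates in nm; z = 0 at the bilayer center (global lipid
COM, or the local-cylinder COM for the reaction coordinate); depths are
folded to one leaflet by |z|; tilts are measured against the outward
normal of the molecule's own leaflet (so a symmetric probe in a symmetric
bilayer peaks at 90 degrees), configurable to the raw +z axis.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Callable, Dict, Literal, Sequence

import numpy as np

from .constants import AMU_KG
from .trajectory import SelectionSpec, Trajectory

__all__ = [
    "DensityProfile",
    "OrderParameterProfile",
    "TiltDistribution",
    "HBondSummary",
    "density_profile",
    "average_positions",
    "area_per_lipid",
    "order_parameters",
    "tilt_distribution",
    "hydrogen_bonds",
    "local_bilayer_com",
    "probe_depth_series",
]

#: amu/nm^3 -> kg/m^3
DENSITY_FACTOR = AMU_KG / 1e-27


def _minimum_image(d: np.ndarray, box: np.ndarray) -> np.ndarray:
    return d - box * np.round(d / box)


def _com(coords: np.ndarray, masses: np.ndarray) -> np.ndarray:
    """Mass-weighted center over the first axis."""
    return (coords * masses[:, None]).sum(axis=0) / masses.sum()


def _bilayer_center_z(traj: Trajectory, frame: int, lipid_idx: np.ndarray) -> float:
    m = traj.masses[lipid_idx]
    z = traj.coords[frame, lipid_idx, 2]
    return float((m * z).sum() / m.sum())


# ---------------------------------------------------------------------------
# density profiles and depths

@dataclass
class DensityProfile:
    """Mass density (kg/m^3) vs bilayer-centered z (nm)."""

    z: np.ndarray
    density: np.ndarray
    selection: str
    symmetrized: bool
    scale: float
    bin_width: float


def density_profile(
    traj: Trajectory,
    sel: SelectionSpec,
    group: str,
    bin_width: float = 0.1,
    symmetrize: bool = False,
    scale: float = 1.0,
    center_group: str = "lipids",
    z_half: float | None = None,
) -> DensityProfile:
    """Mass density profile of a selection along the bilayer normal.

    Each frame is re-centered on the lipid COM before binning; the density
    is the mass histogram divided by the bin volume (box area x bin width),
    averaged over frames.  ``symmetrize`` averages rho(z) with rho(-z);
    ``scale`` multiplies the profile (used for dilute-probe visibility).
    """
    if traj.n_frames == 0:
        raise ValueError("trajectory has no frames")
    if np.any(traj.boxes[:, 2] <= 0):
        raise ValueError("zero-thickness box")
    idx = sel[group]
    lipid_idx = sel[center_group]
    if z_half is None:
        z_half = float(traj.boxes[:, 2].max()) / 2.0 + 0.5
    n_half = int(np.ceil(z_half / bin_width))
    edges = bin_width * np.arange(-n_half, n_half + 1)
    centers = 0.5 * (edges[:-1] + edges[1:])

    masses = traj.masses[idx]
    acc = np.zeros(centers.size)
    for f in range(traj.n_frames):
        z0 = _bilayer_center_z(traj, f, lipid_idx)
        z = traj.coords[f, idx, 2] - z0
        hist, _ = np.histogram(z, bins=edges, weights=masses)
        area = traj.boxes[f, 0] * traj.boxes[f, 1]
        acc += hist / (area * bin_width)
    rho = DENSITY_FACTOR * acc / traj.n_frames
    if symmetrize:
        rho = 0.5 * (rho + rho[::-1])
    return DensityProfile(centers, scale * rho, group, symmetrize, scale,
                          bin_width)


def average_positions(
    traj: Trajectory,
    sel: SelectionSpec,
    groups: Sequence[str] | None = None,
    center_group: str = "lipids",
) -> Dict[str, tuple[float, float]]:
    """Leaflet-folded mean depth |z| +/- sd per named group (nm).

    Each group is split into molecules by residue id; the per-molecule
    group COM z (relative to the bilayer center) is folded by absolute
    value, and mean/sd are taken over frames and molecules.
    """
    if groups is None:
        groups = sel.names()
    lipid_idx = sel[center_group]
    out: Dict[str, tuple[float, float]] = {}
    for g in groups:
        mols = traj.molecules(sel[g])
        depths = []
        for f in range(traj.n_frames):
            z0 = _bilayer_center_z(traj, f, lipid_idx)
            for mol in mols:
                m = traj.masses[mol]
                zc = float((m * traj.coords[f, mol, 2]).sum() / m.sum())
                depths.append(abs(zc - z0))
        d = np.asarray(depths)
        out[g] = (float(d.mean()), float(d.std(ddof=1)) if d.size > 1 else 0.0)
    return out


def area_per_lipid(traj: Trajectory, n_lipids: int) -> tuple[float, float]:
    """Mean +/- sd of Lx*Ly/(n_lipids/2) over frames (nm^2)."""
    if n_lipids <= 0:
        raise ValueError("n_lipids must be positive")
    if n_lipids % 2:
        raise ValueError("n_lipids must be even (two leaflets)")
    a = traj.boxes[:, 0] * traj.boxes[:, 1] / (n_lipids / 2)
    sd = float(a.std(ddof=1)) if a.size > 1 else 0.0
    return float(a.mean()), sd


# ---------------------------------------------------------------------------
# order parameters

@dataclass
class OrderParameterProfile:
    """-S_CD per acyl carbon index (interior carbons only)."""

    carbons: np.ndarray        # carbon numbers n (e.g. 3..15)
    minus_s_cd: np.ndarray
    chain: str = "sn-1"


_COS_HALF_HCH = np.cos(np.deg2rad(109.47 / 2))
_SIN_HALF_HCH = np.sin(np.deg2rad(109.47 / 2))


def _reconstructed_ch_cos2(r_prev, r_here, r_next):
    """cos^2 of the two reconstructed C-H directions vs z, per site.

    United-atom reconstruction: the methylene H's are placed in the plane
    spanned by the C-C-C bisector and the plane normal, perpendicular to
    the C(i-1)->C(i+1) axis.  For (near-)collinear neighbors the azimuth
    is undefined and the azimuthally averaged value
    (1 - cos^2 theta_axis) / 2 is used for both H's.
    """
    u = r_prev - r_here
    w = r_next - r_here
    u /= np.linalg.norm(u, axis=-1, keepdims=True)
    w /= np.linalg.norm(w, axis=-1, keepdims=True)
    b = u + w
    n = np.cross(u, w)
    bn = np.linalg.norm(b, axis=-1, keepdims=True)
    nn = np.linalg.norm(n, axis=-1, keepdims=True)
    collinear = (nn[..., 0] < 1e-10) | (bn[..., 0] < 1e-10)
    bn = np.where(bn < 1e-10, 1.0, bn)
    nn = np.where(nn < 1e-10, 1.0, nn)
    b /= bn
    n /= nn
    h1z = -b[..., 2] * _COS_HALF_HCH + n[..., 2] * _SIN_HALF_HCH
    h2z = -b[..., 2] * _COS_HALF_HCH - n[..., 2] * _SIN_HALF_HCH
    cos2 = 0.5 * (h1z ** 2 + h2z ** 2)
    if np.any(collinear):
        axis = r_next - r_prev
        axis /= np.linalg.norm(axis, axis=-1, keepdims=True)
        iso = 0.5 * (1.0 - axis[..., 2] ** 2)
        cos2 = np.where(collinear, iso, cos2)
    return cos2


def order_parameters(
    traj: Trajectory,
    sel: SelectionSpec,
    chain_names: Sequence[str],
    chain: str = "sn-1",
) -> OrderParameterProfile:
    """Deuterium order parameter profile -S_CD for an ordered carbon chain.

    ``chain_names`` lists the selection groups of consecutive chain
    carbons (e.g. C2..C16), each holding one atom per lipid in matching
    residue order.  For interior carbon i the local molecular axis is
    C(i-1)->C(i+1); C-H directions are reconstructed perpendicular to it
    in tetrahedral geometry and S_CD = <(3 cos^2 theta_CH - 1)/2> over
    frames, molecules and both hydrogens.  Terminal carbons are omitted.
    """
    if len(chain_names) < 3:
        raise ValueError("chain must have at least 3 carbons")
    # (n_carbons, n_lipids) atom indices, residue-aligned
    per_carbon = []
    for name in chain_names:
        idx = sel[name]
        per_carbon.append(idx[np.argsort(traj.resids[idx], kind="stable")])
    sizes = {a.size for a in per_carbon}
    if len(sizes) != 1:
        raise ValueError("all chain carbon groups must have one atom per lipid")
    stack = np.stack(per_carbon)                     # (C, L)
    pos = traj.coords[:, stack, :]                   # (F, C, L, 3)

    carbons, values = [], []
    for i in range(1, len(chain_names) - 1):
        cos2 = _reconstructed_ch_cos2(pos[:, i - 1], pos[:, i], pos[:, i + 1])
        s_cd = 0.5 * (3.0 * cos2 - 1.0)
        carbons.append(int("".join(ch for ch in chain_names[i] if ch.isdigit())))
        values.append(-float(s_cd.mean()))
    return OrderParameterProfile(np.array(carbons), np.array(values), chain)


# ---------------------------------------------------------------------------
# tilt distributions

@dataclass
class TiltDistribution:
    """Normalized tilt-angle distribution over [0, 180] degrees."""

    theta: np.ndarray          # bin centers, degrees
    density: np.ndarray        # per degree; integrates to 1
    mean_theta: float
    axis: str
    angles: np.ndarray = None  # raw per-(frame, molecule) angles, degrees


def _axis_vectors(traj, sel, axis, frame):
    """Per-molecule axis vectors and molecule COM z for one frame."""
    coords = traj.coords[frame]
    if axis == "PN":
        p_mols = traj.molecules(sel["lipid_P"])
        n_mols = traj.molecules(sel["lipid_N"])
        vecs = np.array([coords[n[0]] - coords[p[0]]
                         for p, n in zip(p_mols, n_mols)])
        ref_z = np.array([coords[p[0], 2] for p in p_mols])
        return vecs, ref_z
    if axis == "xanthene_long":
        n1_mols = traj.molecules(sel["N1"])
        n2_mols = traj.molecules(sel["N2"])
        vecs = np.array([coords[b[0]] - coords[a[0]]
                         for a, b in zip(n1_mols, n2_mols)])
        mols = traj.molecules(sel["probes"])
    elif axis == "xanthene_short":
        x_mols = traj.molecules(sel["xanthene"])
        b_mols = traj.molecules(sel["benzoic_ring"])
        vecs = np.array([
            _com(coords[b], traj.masses[b]) - _com(coords[x], traj.masses[x])
            for x, b in zip(x_mols, b_mols)])
        mols = traj.molecules(sel["probes"])
    else:
        raise ValueError(f"unknown axis {axis!r}; use xanthene_long, "
                         "xanthene_short or PN")
    ref_z = np.array([_com(coords[m], traj.masses[m])[2] for m in mols])
    return vecs, ref_z


def tilt_distribution(
    traj: Trajectory,
    axis: Literal["xanthene_long", "xanthene_short", "PN"],
    sel: SelectionSpec,
    bins: int = 60,
    center_group: str = "lipids",
    convention: Literal["leaflet_outward", "raw_z"] = "leaflet_outward",
) -> TiltDistribution:
    """Tilt of a molecular axis relative to the bilayer normal.

    theta is the angle between the axis vector and the outward normal of
    the molecule's leaflet (+z upper, -z lower), or the raw +z axis if
    ``convention='raw_z'``.  The histogram over [0, 180] degrees is
    normalized to unit area.
    """
    lipid_idx = sel[center_group]
    angles = []
    for f in range(traj.n_frames):
        vecs, ref_z = _axis_vectors(traj, sel, axis, f)
        z0 = _bilayer_center_z(traj, f, lipid_idx)
        norms = np.linalg.norm(vecs, axis=1)
        ok = norms > 1e-12
        if not ok.all():
            warnings.warn(f"zero-length {axis} vector in frame {f}; skipped")
        leaflet = np.where(ref_z - z0 >= 0, 1.0, -1.0)
        if convention == "raw_z":
            leaflet = np.ones_like(leaflet)
        cosang = leaflet[ok] * vecs[ok, 2] / norms[ok]
        angles.append(np.rad2deg(np.arccos(np.clip(cosang, -1.0, 1.0))))
    angles = np.concatenate(angles) if angles else np.array([])
    edges = np.linspace(0.0, 180.0, bins + 1)
    hist, _ = np.histogram(angles, bins=edges)
    width = edges[1] - edges[0]
    density = hist / max(1, angles.size) / width
    centers = 0.5 * (edges[:-1] + edges[1:])
    mean = float(angles.mean()) if angles.size else float("nan")
    return TiltDistribution(centers, density, mean, axis, angles)


# ---------------------------------------------------------------------------
# hydrogen bonds

@dataclass
class HBondSummary:
    """Average instantaneous H-bond counts per donor atom and partner class."""

    per_donor_class: Dict[tuple, float]   # (donor name, partner class) -> mean
    n_frames: int
    n_donors: Dict[str, int]
    r_cut: float
    angle_cut: float

    def mean_count(self, donor: str, partner: str | None = None) -> float:
        """Mean bonds per frame per donor atom of this name (and partner)."""
        total = sum(v for (d, p), v in self.per_donor_class.items()
                    if d == donor and (partner is None or p == partner))
        return total

    def total_per_frame(self) -> float:
        return sum(v * self.n_donors[d] for (d, _), v in
                   ((k, v) for k, v in self.per_donor_class.items()))


def default_partner_classifier(traj: Trajectory) -> Callable[[int], str]:
    def classify(idx: int) -> str:
        rn = traj.resnames[idx]
        if rn == "POPC":
            return f"lipid:{traj.names[idx]}"
        if rn == "SOL":
            return "water"
        if rn == "RHD":
            return "other_rh"
        return str(traj.names[idx])
    return classify


def hbond_pairs_frame(
    coords: np.ndarray,
    box: np.ndarray,
    donor_atoms: np.ndarray,
    donor_hydrogens: np.ndarray,
    acceptor_atoms: np.ndarray,
    r_cut: float,
    angle_cut: float,
    exclude_resid: np.ndarray | None = None,
    resids: np.ndarray | None = None,
) -> list[tuple[int, int]]:
    """Hydrogen bonds in one frame as (hydrogen index, acceptor index) pairs.

    Geometric criterion: minimum-image donor-acceptor distance <= r_cut and
    H-donor-acceptor angle <= angle_cut.  Each donor hydrogen binds at most
    one acceptor (the nearest qualifying one); acceptors in the donor's own
    residue are excluded when ``resids`` is given.
    """
    pairs = []
    cos_cut = np.cos(np.deg2rad(angle_cut))
    d_pos = coords[donor_atoms]
    a_pos = coords[acceptor_atoms]
    for j, (di, hi) in enumerate(zip(donor_atoms, donor_hydrogens)):
        disp = _minimum_image(a_pos - d_pos[j], box)
        dist = np.linalg.norm(disp, axis=1)
        dh = _minimum_image(coords[hi] - d_pos[j], box)
        dh_norm = np.linalg.norm(dh)
        if dh_norm < 1e-12:
            raise ValueError(f"donor atom {int(di)} has a zero-length D-H bond")
        with np.errstate(invalid="ignore", divide="ignore"):
            cosang = disp @ dh / (dist * dh_norm)
        ok = (dist <= r_cut) & (dist > 1e-12) & (cosang >= cos_cut)
        if resids is not None:
            ok &= resids[acceptor_atoms] != resids[di]
        cand = np.flatnonzero(ok)
        if cand.size:
            best = cand[np.argmin(dist[cand])]
            pairs.append((int(hi), int(acceptor_atoms[best])))
    return pairs


def hydrogen_bonds(
    traj: Trajectory,
    donors: SelectionSpec,
    acceptors: SelectionSpec,
    r_cut: float = 0.35,
    angle_cut: float = 30.0,
    donor_group: str = "donor_N",
    hydrogen_group: str = "donor_H",
    acceptor_groups: Sequence[str] | None = None,
    classifier: Callable[[int], str] | None = None,
) -> HBondSummary:
    """Geometric hydrogen-bond counts, averaged over frames.

    ``donors[donor_group]`` and ``donors[hydrogen_group]`` must be aligned
    (hydrogen j is bonded to donor j); a length mismatch means a declared
    donor lacks its hydrogen and is an error.  Partner classes default to
    lipid oxygen name / water / other probe.
    """
    if r_cut <= 0 or angle_cut <= 0:
        raise ValueError("cutoffs must be positive")
    d_atoms = donors[donor_group]
    h_atoms = donors[hydrogen_group]
    if d_atoms.size != h_atoms.size:
        missing = traj.names[d_atoms[h_atoms.size:]] if d_atoms.size > h_atoms.size \
            else traj.names[h_atoms[d_atoms.size:]]
        raise ValueError(
            "each declared donor needs exactly one hydrogen; mismatched "
            f"atoms: {list(missing)}"
        )
    if acceptor_groups is None:
        acceptor_groups = acceptors.names()
    a_atoms = np.unique(np.concatenate([acceptors[g] for g in acceptor_groups]))
    classify = classifier or default_partner_classifier(traj)

    counts: Dict[tuple, float] = {}
    for f in range(traj.n_frames):
        pairs = hbond_pairs_frame(
            traj.coords[f], traj.boxes[f], d_atoms, h_atoms, a_atoms,
            r_cut, angle_cut, resids=traj.resids,
        )
        h_to_donor = dict(zip(h_atoms.tolist(), d_atoms.tolist()))
        for hi, ai in pairs:
            key = (str(traj.names[h_to_donor[hi]]), classify(ai))
            counts[key] = counts.get(key, 0.0) + 1.0

    donor_names, tally = np.unique(traj.names[d_atoms], return_counts=True)
    n_donors = dict(zip(donor_names.tolist(), tally.tolist()))
    n_frames = max(1, traj.n_frames)
    per = {k: v / (n_frames * n_donors[k[0]]) for k, v in counts.items()}
    return HBondSummary(per, traj.n_frames, n_donors, r_cut, angle_cut)


# ---------------------------------------------------------------------------
# local bilayer COM and the reaction coordinate

def local_bilayer_com(
    traj: Trajectory,
    frame: int,
    probe_indices: np.ndarray,
    lipid_indices: np.ndarray,
    radius: float = 1.1,
) -> float:
    """z of the COM of lipids within an in-plane cylinder around the probe.

    Lipids whose in-plane (minimum-image) COM distance to the probe's
    in-plane COM is <= radius contribute; this local reference absorbs
    bilayer undulations when defining the probe depth.
    """
    if radius <= 0:
        raise ValueError("radius must be positive")
    coords = traj.coords[frame]
    box = traj.boxes[frame]
    probe_com = _com(coords[probe_indices], traj.masses[probe_indices])
    mols = traj.molecules(lipid_indices)
    coms = np.array([_com(coords[m], traj.masses[m]) for m in mols])
    masses = np.array([traj.masses[m].sum() for m in mols])
    d_xy = _minimum_image(coms[:, :2] - probe_com[:2], box[:2])
    inside = np.linalg.norm(d_xy, axis=1) <= radius
    if not inside.any():
        raise ValueError(
            f"no lipid COM within {radius} nm of the probe in frame {frame}; "
            "try a larger radius"
        )
    return float((masses[inside] * coms[inside, 2]).sum() / masses[inside].sum())


def probe_depth_series(
    traj: Trajectory,
    probe_sel: np.ndarray,
    lipid_sel: np.ndarray,
    radius: float = 1.1,
    dt: float = 1.0,
) -> list[np.ndarray]:
    """Per-probe depth z(t): probe COM z minus the local bilayer COM z.

    One array of length n_frames per probe molecule (split by residue id).
    The output is the umbrella-sampling reaction coordinate recomputed
    from a trajectory; pair it with times ``dt * (1..n_frames)`` to build
    an UmbrellaWindowSeries.
    """
    probes = traj.molecules(np.asarray(probe_sel))
    series = [np.empty(traj.n_frames) for _ in probes]
    for f in range(traj.n_frames):
        for pi, mol in enumerate(probes):
            z_ref = local_bilayer_com(traj, f, mol, lipid_sel, radius)
            z_com = _com(traj.coords[f, mol], traj.masses[mol])[2]
            series[pi][f] = z_com - z_ref
    return series
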