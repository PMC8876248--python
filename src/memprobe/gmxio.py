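"""File formats: GRO coordinates, pull-coordinate XVG, titration CSV.

GRO files are fixed-column (nm, 3 decimals) and may hold multiple
concatenated frames; the pull XVG dialect is two columns (time ps,
coordinate nm) with '#'/'@' comment lines.  Readers reject malformed
records instead of coercing them.  Binary trajectories (XTC/TRR) are read
through MDAnalysis.
"""

from __future__ import annotations

import os
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .sampling import BiasSpec, UmbrellaWindowSeries
from .titration import TitrationSeries
from .trajectory import SelectionSpec, Trajectory
from .wham import FreeEnergyProfile

__all__ = [
    "read_gro",
    "write_gro",
    "load_trajectory",
    "read_pull_xvg",
    "read_pull_series",
    "write_pull_xvg",
    "write_window_set",
    "read_titrations",
    "write_titrations",
    "write_pmf",
    "read_pmf",
]

_ELEMENT_MASS = {"H": 1.008, "C": 12.011, "N": 14.007, "O": 15.999,
                 "P": 30.974, "S": 32.06}


def _guess_mass(name: str) -> float:
    for ch in name:
        if ch.isalpha():
            return _ELEMENT_MASS.get(ch.upper(), 12.011)
    return 12.011


# ---------------------------------------------------------------------------
# GRO

def write_gro(traj: Trajectory, path, title: str = "memprobe toy system"):
    """Write all frames as a (multi-frame) GRO file: nm, 3 decimals."""
    with open(path, "w") as fh:
        for f in range(traj.n_frames):
            fh.write(f"{title}, t= {float(f):.3f}\n")
            fh.write(f"{traj.n_atoms:5d}\n")
            for i in range(traj.n_atoms):
                x, y, z = traj.coords[f, i]
                fh.write(
                    f"{int(traj.resids[i]) % 100000:5d}"
                    f"{str(traj.resnames[i]):<5.5s}"
                    f"{str(traj.names[i]):>5.5s}"
                    f"{(i + 1) % 100000:5d}"
                    f"{x:8.3f}{y:8.3f}{z:8.3f}\n"
                )
            bx, by, bz = traj.boxes[f]
            fh.write(f"{bx:10.5f}{by:10.5f}{bz:10.5f}\n")


def read_gro(path) -> Trajectory:
    """Read a single- or multi-frame GRO file (coordinates in nm)."""
    lines = Path(path).read_text().splitlines()
    frames, boxes = [], []
    names = resids = resnames = None
    ln = 0
    while ln < len(lines):
        if not lines[ln].strip() and ln == len(lines) - 1:
            break
        if ln + 1 >= len(lines):
            raise ValueError(f"{path}: truncated frame header at line {ln + 1}")
        try:
            n_atoms = int(lines[ln + 1].strip())
        except ValueError:
            raise ValueError(
                f"{path}: expected atom count at line {ln + 2}, got "
                f"{lines[ln + 1]!r}"
            ) from None
        if ln + 2 + n_atoms >= len(lines):
            raise ValueError(
                f"{path}: truncated frame (needs {n_atoms} atom lines plus a "
                f"box line) starting at line {ln + 1}"
            )
        f_names, f_resids, f_resnames = [], [], []
        xyz = np.empty((n_atoms, 3))
        for i in range(n_atoms):
            line = lines[ln + 2 + i]
            if len(line) < 44:
                raise ValueError(f"{path}: short atom record at line {ln + 3 + i}")
            try:
                f_resids.append(int(line[0:5]))
                f_resnames.append(line[5:10].strip())
                f_names.append(line[10:15].strip())
                xyz[i] = (float(line[20:28]), float(line[28:36]),
                          float(line[36:44]))
            except ValueError:
                raise ValueError(
                    f"{path}: malformed atom record at line {ln + 3 + i}: "
                    f"{line!r}"
                ) from None
        box_fields = lines[ln + 2 + n_atoms].split()
        if len(box_fields) < 3:
            raise ValueError(f"{path}: malformed box line at line "
                             f"{ln + 3 + n_atoms}")
        boxes.append([float(v) for v in box_fields[:3]])
        frames.append(xyz)
        if names is None:
            names, resids, resnames = f_names, f_resids, f_resnames
        elif f_names != names:
            raise ValueError(f"{path}: atom identity changes between frames")
        ln += 3 + n_atoms
    if not frames:
        raise ValueError(f"{path}: no frames found")
    masses = np.array([_guess_mass(n) for n in names])
    return Trajectory(np.array(names), masses, np.array(resids),
                      np.array(resnames), np.array(boxes), np.array(frames))


def load_trajectory(
    coord_path,
    traj_path=None,
    selection_rules: Mapping[str, Mapping[str, str]] | None = None,
) -> tuple[Trajectory, SelectionSpec | None]:
    """Load coordinates (GRO) and optionally a binary trajectory (XTC/TRR).

    The GRO provides atom metadata (and frames, if multi-frame); a binary
    trajectory replaces the frames and must match the atom count.  Binary
    formats are read with MDAnalysis (positions converted Angstrom -> nm).
    Selections are resolved from name/resname rules if given.
    """
    if not os.path.exists(coord_path):
        raise FileNotFoundError(f"coordinate file not found: {coord_path}")
    traj = read_gro(coord_path)
    if traj_path is not None:
        import MDAnalysis as mda

        u = mda.Universe(str(coord_path), str(traj_path))
        if u.atoms.n_atoms != traj.n_atoms:
            raise ValueError(
                f"atom count mismatch: {coord_path} has {traj.n_atoms}, "
                f"{traj_path} has {u.atoms.n_atoms}"
            )
        frames, boxes = [], []
        for ts in u.trajectory:
            frames.append(ts.positions / 10.0)
            boxes.append(ts.dimensions[:3] / 10.0)
        traj = Trajectory(traj.names, traj.masses, traj.resids, traj.resnames,
                          np.array(boxes), np.array(frames))
    sel = None
    if selection_rules is not None:
        sel = SelectionSpec.from_rules(traj, selection_rules)
        sel.validate(traj.n_atoms)
    return traj, sel


# ---------------------------------------------------------------------------
# pull XVG

def write_pull_xvg(series: UmbrellaWindowSeries, path):
    """Write one window in the pull XVG dialect (time ps, z nm)."""
    with open(path, "w") as fh:
        fh.write("# memprobe umbrella window\n")
        fh.write(f"# bias: z_ref = {series.bias.z_ref:.6g} nm, "
                 f"k = {series.bias.k:.6g} kJ/mol/nm^2\n")
        fh.write('@    title "Umbrella window reaction coordinate"\n')
        fh.write('@    xaxis  label "Time (ps)"\n')
        fh.write('@    yaxis  label "Position (nm)"\n')
        for t, z in zip(series.times, series.z):
            fh.write(f"{t:.6f}\t{z:.9f}\n")


def read_pull_xvg(path, bias: BiasSpec | None = None) -> UmbrellaWindowSeries:
    """Read one pull XVG file; '#'/'@' lines are skipped.

    If ``bias`` is not given, the writer's '# bias:' comment is parsed;
    a file without either is an error.
    """
    times, zs = [], []
    parsed_bias = None
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            s = line.strip()
            if not s:
                continue
            if s.startswith(("#", "@")):
                if s.startswith("# bias:"):
                    try:
                        parts = s.replace(",", " ").split()
                        z_ref = float(parts[parts.index("z_ref") + 2])
                        k = float(parts[parts.index("k") + 2])
                        parsed_bias = BiasSpec(z_ref=z_ref, k=k)
                    except (ValueError, IndexError):
                        pass
                continue
            fields = s.split()
            if len(fields) < 2:
                raise ValueError(f"{path}:{lineno}: expected two columns, got "
                                 f"{s!r}")
            times.append(float(fields[0]))
            zs.append(float(fields[1]))
    if not times:
        raise ValueError(f"{path}: no data rows (only comments?)")
    times = np.asarray(times)
    if np.any(np.diff(times) <= 0):
        raise ValueError(f"{path}: times are not strictly increasing")
    use_bias = bias if bias is not None else parsed_bias
    if use_bias is None:
        raise ValueError(f"{path}: no bias parameters given or found in header")
    return UmbrellaWindowSeries(times, np.asarray(zs), use_bias)


def write_window_set(windows: Sequence[UmbrellaWindowSeries], out_dir,
                     prefix: str = "window") -> list[str]:
    """Write windows as XVG files plus a YAML sidecar with the biases."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths, sidecar = [], []
    for i, w in enumerate(windows):
        p = out_dir / f"{prefix}_{i:03d}.xvg"
        write_pull_xvg(w, p)
        paths.append(str(p))
        sidecar.append({"path": p.name, "z_ref": float(w.bias.z_ref),
                        "k": float(w.bias.k)})
    with open(out_dir / f"{prefix}s.yaml", "w") as fh:
        yaml.safe_dump({"windows": sidecar}, fh, sort_keys=False)
    return paths


def read_pull_series(
    paths: Sequence | None = None,
    sidecar=None,
    biases: Sequence[BiasSpec] | None = None,
) -> list[UmbrellaWindowSeries]:
    """Read a set of pull XVG files into window series.

    Bias parameters come from (in priority order) an explicit ``biases``
    list, a YAML ``sidecar`` written by :func:`write_window_set`, or the
    per-file header comment.
    """
    if sidecar is not None:
        sidecar = Path(sidecar)
        cfg = yaml.safe_load(sidecar.read_text())
        entries = cfg["windows"]
        paths = [sidecar.parent / e["path"] for e in entries]
        biases = [BiasSpec(z_ref=float(e["z_ref"]), k=float(e["k"]))
                  for e in entries]
    if paths is None:
        raise ValueError("either paths or a sidecar file is required")
    if biases is not None and len(biases) != len(paths):
        raise ValueError("one bias per file is required")
    return [
        read_pull_xvg(p, bias=None if biases is None else biases[i])
        for i, p in enumerate(paths)
    ]


# ---------------------------------------------------------------------------
# titration CSV, PMF tables

def write_titrations(series: Sequence[TitrationSeries], path):
    rows = []
    for s in series:
        for c, i in zip(s.lipid_concs, s.intensities):
            rows.append({"replicate_id": s.replicate_id, "lipid_conc": c,
                         "intensity": i})
    pd.DataFrame(rows).to_csv(path, index=False)


def read_titrations(path) -> list[TitrationSeries]:
    df = pd.read_csv(path)
    required = {"replicate_id", "lipid_conc", "intensity"}
    if not required.issubset(df.columns):
        raise ValueError(f"{path}: titration CSV needs columns {sorted(required)}")
    out = []
    for rid, grp in df.groupby("replicate_id", sort=True):
        out.append(TitrationSeries(grp["lipid_conc"].to_numpy(),
                                   grp["intensity"].to_numpy(),
                                   replicate_id=str(rid)))
    return out


def write_pmf(profile: FreeEnergyProfile, path):
    """PMF as CSV: z, G, err (err empty if no band)."""
    df = pd.DataFrame({"z": profile.z, "G": profile.G})
    df["err"] = profile.err if profile.err is not None else np.nan
    df.to_csv(path, index=False)


def read_pmf(path, temperature: float = 298.15) -> FreeEnergyProfile:
    df = pd.read_csv(path)
    if not {"z", "G"}.issubset(df.columns):
        raise ValueError(f"{path}: PMF CSV needs columns z, G")
    err = df["err"].to_numpy() if "err" in df and df["err"].notna().any() else None
    return FreeEnergyProfile(df["z"].to_numpy(), df["G"].to_numpy(),
                             temperature, err=err)
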