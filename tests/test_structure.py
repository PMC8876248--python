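"""Bilayer/probe descriptors: densities, depths, order, tilts, H bonds."""

import numpy as np
import pytest
from scipy import stats

import memprobe as mp
from memprobe import structure as st
from memprobe.trajectory import SelectionSpec, Trajectory


def _simple_traj(coords, box=(4.0, 4.0, 8.0), names=None, masses=None,
                 resids=None, resnames=None):
    coords = np.asarray(coords, dtype=float)
    if coords.ndim == 2:
        coords = coords[None]
    n = coords.shape[1]
    return Trajectory(
        names=names if names is not None else [f"A{i}" for i in range(n)],
        masses=masses if masses is not None else np.ones(n),
        resids=resids if resids is not None else np.arange(1, n + 1),
        resnames=resnames if resnames is not None else ["MOL"] * n,
        boxes=np.tile(box, (coords.shape[0], 1)),
        coords=coords,
    )


# ---------------------------------------------------------------------------
# density profiles

class TestDensityProfile:
    def test_single_atom_density_value(self):
        # one atom of mass m in one bin: rho = m / (A * dz), here in kg/m^3
        traj = _simple_traj([[1.0, 1.0, 5.0], [1.0, 1.0, 3.0]],
                            masses=np.array([10.0, 10.0]))
        sel = SelectionSpec({"all": [0, 1], "center": [0, 1]})
        prof = st.density_profile(traj, sel, "all", bin_width=0.2,
                                  center_group="center")
        # atoms at +/-1 from their COM (z=4)
        expected = 10.0 * st.DENSITY_FACTOR / (4.0 * 4.0 * 0.2)
        peak_bins = np.abs(prof.density - expected) < 1e-6
        assert peak_bins.sum() == 2
        assert prof.density.sum() == pytest.approx(2 * expected)

    def test_symmetrize_splits_a_delta_peak(self):
        traj = _simple_traj([[1.0, 1.0, 5.0], [1.0, 1.0, 4.0]],
                            masses=np.array([8.0, 1e9]))
        # heavy second atom pins the center at ~z=4; light atom sits at +1
        sel = SelectionSpec({"probe": [0], "center": [1]})
        sym = st.density_profile(traj, sel, "probe", bin_width=0.2,
                                 symmetrize=True, center_group="center")
        raw = st.density_profile(traj, sel, "probe", bin_width=0.2,
                                 symmetrize=False, center_group="center")
        assert np.allclose(sym.density, sym.density[::-1])
        assert sym.density.max() == pytest.approx(raw.density.max() / 2)

    def test_mass_conservation(self, toy_traj):
        spec, traj, sel = toy_traj
        prof = st.density_profile(traj, sel, "lipids", bin_width=0.1)
        area = spec.box[0] * spec.box[1]
        total = prof.density.sum() * prof.bin_width * area / st.DENSITY_FACTOR
        assert total == pytest.approx(traj.masses[sel["lipids"]].sum(), rel=1e-9)

    def test_uniform_slab_is_flat(self):
        rng = np.random.default_rng(0)
        n = 40_000
        coords = np.column_stack([rng.uniform(0, 4, n), rng.uniform(0, 4, n),
                                  rng.uniform(2, 6, n)])
        traj = _simple_traj(coords, resids=np.ones(n, dtype=int))
        sel = SelectionSpec({"all": np.arange(n), "center": np.arange(n)})
        prof = st.density_profile(traj, sel, "all", bin_width=0.25,
                                  center_group="center")
        inside = np.abs(prof.z) < 1.8
        rho = prof.density[inside]
        assert rho.std() / rho.mean() < 0.05

    def test_scale_factor_applied(self, toy_traj):
        _, traj, sel = toy_traj
        p1 = st.density_profile(traj, sel, "probes", scale=1.0)
        p16 = st.density_profile(traj, sel, "probes", scale=16.0)
        assert np.allclose(p16.density, 16.0 * p1.density)


class TestAveragePositions:
    def test_leaflet_folding(self):
        traj = _simple_traj([[0, 0, 5.5], [0, 0, 2.5], [0, 0, 4.0]],
                            masses=np.array([1.0, 1.0, 1e12]))
        sel = SelectionSpec({"pair": [0, 1], "center": [2]})
        mean, sd = st.average_positions(traj, sel, groups=["pair"],
                                        center_group="center")["pair"]
        assert mean == pytest.approx(1.5, abs=1e-6)
        assert sd == pytest.approx(0.0, abs=1e-6)

    def test_group_com_is_mass_weighted(self):
        traj = _simple_traj([[0, 0, 5.0], [0, 0, 6.0], [0, 0, 4.0]],
                            masses=np.array([2.0, 1.0, 1e12]),
                            resids=np.array([1, 1, 2]))
        sel = SelectionSpec({"mol": [0, 1], "center": [2]})
        mean, _ = st.average_positions(traj, sel, groups=["mol"],
                                       center_group="center")["mol"]
        # COM z = (2*5 + 1*6)/3 = 5.333 -> depth 1.333
        assert mean == pytest.approx(4.0 / 3.0, abs=1e-6)


class TestAreaPerLipid:
    def test_arithmetic(self):
        traj = _simple_traj(np.zeros((1, 1, 3)), box=(8.0, 8.0, 10.0))
        mean, sd = st.area_per_lipid(traj, 128)
        assert mean == pytest.approx(1.0)
        assert sd == 0.0

    def test_fluctuating_box_sd(self):
        rng = np.random.default_rng(3)
        n_frames = 400
        lx = 6.4 * (1 + 0.01 * rng.standard_normal(n_frames))
        boxes = np.column_stack([lx, np.full(n_frames, 6.4),
                                 np.full(n_frames, 9.0)])
        traj = Trajectory(["A"], [1.0], [1], ["MOL"], boxes,
                          np.zeros((n_frames, 1, 3)))
        mean, sd = st.area_per_lipid(traj, 128)
        imposed = (boxes[:, 0] * 6.4 / 64).std(ddof=1)
        assert sd == pytest.approx(imposed, rel=1e-9)

    def test_invalid_counts_rejected(self):
        traj = _simple_traj(np.zeros((1, 1, 3)))
        with pytest.raises(ValueError):
            st.area_per_lipid(traj, 0)
        with pytest.raises(ValueError):
            st.area_per_lipid(traj, 127)


# ---------------------------------------------------------------------------
# order parameters

def _chain_traj(axis_tilt_deg, n_carbons=7):
    """Rigid all-trans zigzag chain tilted from +z by a given angle."""
    step, amp = 0.1249, 0.0442
    t = np.deg2rad(axis_tilt_deg)
    axis = np.array([np.sin(t), 0.0, -np.cos(t)])
    lat = np.array([np.cos(t), 0.0, np.sin(t)])
    pos = np.array([i * step * axis + ((-1) ** i) * amp * lat
                    for i in range(n_carbons)]) + [2.0, 2.0, 6.0]
    names = [f"C{i + 2}" for i in range(n_carbons)]
    return _simple_traj(pos[None], names=names,
                        resids=np.ones(n_carbons, dtype=int),
                        resnames=["POPC"] * n_carbons), names


class TestOrderParameters:
    def test_all_trans_chain_along_normal(self):
        traj, names = _chain_traj(0.0)
        sel = SelectionSpec({n: traj.select(name=n) for n in names})
        prof = st.order_parameters(traj, sel, names)
        assert np.allclose(prof.minus_s_cd, 0.5, atol=1e-12)
        assert prof.carbons.size == len(names) - 2  # terminals omitted

    def test_isotropic_chain_orientations_average_to_zero(self):
        rng = np.random.default_rng(8)
        n_frames, n_carbons = 600, 5
        step, amp = 0.1249, 0.0442
        coords = np.empty((n_frames, n_carbons, 3))
        for f in range(n_frames):
            v = rng.standard_normal(3)
            v /= np.linalg.norm(v)
            ref = rng.standard_normal(3)
            lat = np.cross(v, ref)
            lat /= np.linalg.norm(lat)
            coords[f] = [i * step * v + ((-1) ** i) * amp * lat + 4.0
                         for i in range(n_carbons)]
        names = [f"C{i + 2}" for i in range(n_carbons)]
        traj = _simple_traj(coords, names=names,
                            resids=np.ones(n_carbons, dtype=int),
                            resnames=["POPC"] * n_carbons)
        sel = SelectionSpec({n: traj.select(name=n) for n in names})
        prof = st.order_parameters(traj, sel, names)
        assert np.all(np.abs(prof.minus_s_cd) < 3.0 / np.sqrt(n_frames))

    @pytest.mark.parametrize("tilt", [0.0, 30.0, 60.0, 90.0])
    def test_tilted_rigid_chain_matches_geometric_oracle(self, tilt):
        """Brute-force oracle: reconstruct the two tetrahedral C-H unit
        vectors explicitly from the constructed geometry and average
        P2(cos theta) by hand."""
        traj, names = _chain_traj(tilt)
        sel = SelectionSpec({n: traj.select(name=n) for n in names})
        prof = st.order_parameters(traj, sel, names)

        pos = traj.coords[0]
        expected = []
        phi = np.deg2rad(109.47 / 2)
        for i in range(1, len(names) - 1):
            u = pos[i - 1] - pos[i]
            w = pos[i + 1] - pos[i]
            u, w = u / np.linalg.norm(u), w / np.linalg.norm(w)
            b = (u + w) / np.linalg.norm(u + w)
            nrm = np.cross(u, w)
            nrm /= np.linalg.norm(nrm)
            vals = []
            for sgn in (+1, -1):
                h = -b * np.cos(phi) + sgn * nrm * np.sin(phi)
                vals.append(0.5 * (3 * h[2] ** 2 - 1))
            expected.append(-np.mean(vals))
        assert np.allclose(prof.minus_s_cd, expected, atol=1e-10)

    def test_bounds_respected(self, toy_traj):
        _, traj, sel = toy_traj
        prof = st.order_parameters(traj, sel,
                                   [f"C{i}" for i in range(2, 17)])
        assert np.all(prof.minus_s_cd >= -1.0)
        assert np.all(prof.minus_s_cd <= 0.5 + 1e-12)

    def test_short_chain_rejected(self, toy_traj):
        _, traj, sel = toy_traj
        with pytest.raises(ValueError, match="3 carbons"):
            st.order_parameters(traj, sel, ["C2", "C3"])


# ---------------------------------------------------------------------------
# tilt distributions

def _probe_like_traj(long_axes, com_z=5.5):
    """Probe molecules with prescribed long-axis unit vectors (lab frame)."""
    long_axes = np.asarray(long_axes, dtype=float)
    n = long_axes.shape[0]
    names, resids, coords, masses, resnames = [], [], [], [], []
    # heavy center atom defines the bilayer center at z=4
    names += ["CTR"]
    resids += [999]
    resnames += ["POPC"]
    masses += [1e12]
    coords += [[2.0, 2.0, 4.0]]
    for i, v in enumerate(long_axes):
        com = np.array([1.0 + i * 0.5, 2.0, com_z])
        for nm, off in (("N1", -0.5), ("X2", 0.0), ("N2", +0.5)):
            names.append(nm)
            resids.append(i + 1)
            resnames.append("RHD")
            masses.append(1.0)
            coords.append(com + off * v)
    traj = _simple_traj(np.asarray(coords)[None], names=names,
                        masses=np.asarray(masses),
                        resids=np.asarray(resids),
                        resnames=np.asarray(resnames))
    sel = SelectionSpec({
        "lipids": traj.select(name="CTR"),
        "probes": traj.select(resname="RHD"),
        "N1": traj.select(name="N1"),
        "N2": traj.select(name="N2"),
    })
    return traj, sel


class TestTiltDistribution:
    def test_axis_along_normal_is_zero_degrees(self):
        traj, sel = _probe_like_traj([[0.0, 0.0, 1.0]])
        d = st.tilt_distribution(traj, "xanthene_long", sel)
        assert d.angles[0] == pytest.approx(0.0, abs=1e-9)

    def test_in_plane_axis_is_ninety_degrees(self):
        traj, sel = _probe_like_traj([[1.0, 0.0, 0.0]])
        d = st.tilt_distribution(traj, "xanthene_long", sel)
        assert d.angles[0] == pytest.approx(90.0, abs=1e-9)

    def test_lower_leaflet_measured_against_outward_normal(self):
        traj, sel = _probe_like_traj([[0.0, 0.0, -1.0]], com_z=2.5)
        d = st.tilt_distribution(traj, "xanthene_long", sel)
        assert d.angles[0] == pytest.approx(0.0, abs=1e-9)
        d_raw = st.tilt_distribution(traj, "xanthene_long", sel,
                                     convention="raw_z")
        assert d_raw.angles[0] == pytest.approx(180.0, abs=1e-9)

    def test_isotropic_axes_give_sine_distribution(self):
        rng = np.random.default_rng(12)
        v = rng.standard_normal((4000, 3))
        v /= np.linalg.norm(v, axis=1, keepdims=True)
        traj, sel = _probe_like_traj(v)
        d = st.tilt_distribution(traj, "xanthene_long", sel, bins=18)
        width = d.theta[1] - d.theta[0]
        assert d.density.sum() * width == pytest.approx(1.0)
        assert d.mean_theta == pytest.approx(90.0, abs=2.0)
        # chi^2 against the solid-angle density sin(theta)/2 (per degree)
        expected_p = (np.sin(np.deg2rad(d.theta))
                      * np.deg2rad(width) / 2.0)
        expected_p /= expected_p.sum()
        observed = d.density * width * v.shape[0]
        res = stats.chisquare(observed, expected_p * v.shape[0])
        assert res.pvalue > 0.01

    def test_mirror_symmetric_orientations_average_to_ninety(self):
        rng = np.random.default_rng(5)
        half = rng.standard_normal((300, 3))
        half /= np.linalg.norm(half, axis=1, keepdims=True)
        mirrored = half * [1, 1, -1]
        traj, sel = _probe_like_traj(np.vstack([half, mirrored]))
        d = st.tilt_distribution(traj, "xanthene_long", sel)
        assert d.mean_theta == pytest.approx(90.0, abs=1e-9)

    def test_pn_axis_on_toy_bilayer(self, toy_traj):
        spec, traj, sel = toy_traj
        d = st.tilt_distribution(traj, "PN", sel)
        se = spec.pn_tilt_sd / np.sqrt(traj.n_frames * spec.n_lipids)
        assert abs(d.mean_theta - spec.pn_tilt_mean) < 4 * se


# ---------------------------------------------------------------------------
# hydrogen bonds

def _hbond_oracle(coords, box, donors, hydrogens, acceptors, r_cut, angle_cut,
                  resids):
    """Plain triple-loop reference implementation."""
    found = []
    for d, h in zip(donors, hydrogens):
        best, best_dist = None, None
        for a in acceptors:
            if resids[a] == resids[d]:
                continue
            dv = coords[a] - coords[d]
            dv -= box * np.round(dv / box)
            dist = float(np.sqrt((dv**2).sum()))
            if dist > r_cut or dist < 1e-12:
                continue
            hv = coords[h] - coords[d]
            hv -= box * np.round(hv / box)
            cosang = float(dv @ hv / (dist * np.sqrt((hv**2).sum())))
            ang = np.degrees(np.arccos(np.clip(cosang, -1, 1)))
            if ang <= angle_cut and (best is None or dist < best_dist):
                best, best_dist = a, dist
        if best is not None:
            found.append((int(h), int(best)))
    return found


class TestHydrogenBonds:
    def _triple(self, d_pos, h_pos, a_pos):
        coords = np.array([d_pos, h_pos, a_pos])
        traj = _simple_traj(coords[None], names=["N1", "HN1", "O8"],
                            resids=np.array([1, 1, 2]),
                            resnames=np.array(["RHD", "RHD", "POPC"]))
        sel = SelectionSpec({"donor_N": [0], "donor_H": [1], "acc": [2]})
        return traj, sel

    def test_ideal_linear_geometry_counts_one(self):
        traj, sel = self._triple([2, 2, 2], [2, 2, 2.1], [2, 2, 2.28])
        s = st.hydrogen_bonds(traj, sel, sel, acceptor_groups=["acc"])
        assert s.mean_count("N1") == 1.0
        assert s.per_donor_class[("N1", "lipid:O8")] == 1.0

    def test_pair_beyond_distance_cutoff_counts_zero(self):
        traj, sel = self._triple([2, 2, 2], [2, 2, 2.1], [2, 2, 2.40])
        s = st.hydrogen_bonds(traj, sel, sel, acceptor_groups=["acc"])
        assert s.mean_count("N1") == 0.0

    def test_bent_geometry_beyond_angle_cutoff_counts_zero(self):
        # acceptor at 45 degrees from the D-H direction
        traj, sel = self._triple([2, 2, 2], [2, 2, 2.1],
                                 [2, 2 + 0.28 / np.sqrt(2), 2 + 0.28 / np.sqrt(2)])
        s = st.hydrogen_bonds(traj, sel, sel, acceptor_groups=["acc"])
        assert s.mean_count("N1") == 0.0

    def test_missing_hydrogen_is_an_error(self):
        traj, _ = self._triple([2, 2, 2], [2, 2, 2.1], [2, 2, 2.28])
        sel = SelectionSpec({"donor_N": [0], "donor_H": [1], "acc": [2]})
        bad = SelectionSpec({"donor_N": [0, 2], "donor_H": [1], "acc": [2]})
        with pytest.raises(ValueError, match="hydrogen"):
            st.hydrogen_bonds(traj, bad, sel, acceptor_groups=["acc"])

    def test_matches_brute_force_oracle_on_random_fixtures(self):
        """Vectorized implementation equals the O(N^2) triple-loop oracle
        exactly, including minimum-image wrapping and the nearest-acceptor
        uniqueness rule."""
        rng = np.random.default_rng(77)
        box = np.array([2.0, 2.0, 2.0])
        for trial in range(25):
            nd, na = 6, 40
            coords = rng.uniform(0, 2.0, size=(nd * 2 + na, 3))
            # hydrogens sit 0.1 nm from their donors
            for j in range(nd):
                off = rng.standard_normal(3)
                coords[nd + j] = coords[j] + 0.1 * off / np.linalg.norm(off)
            donors = np.arange(nd)
            hydros = np.arange(nd, 2 * nd)
            accept = np.arange(2 * nd, 2 * nd + na)
            resids = np.concatenate([np.arange(1, nd + 1),
                                     np.arange(1, nd + 1),
                                     np.arange(nd + 1, nd + na + 1)])
            got = st.hbond_pairs_frame(coords, box, donors, hydros, accept,
                                       0.35, 30.0, resids=resids)
            want = _hbond_oracle(coords, box, donors, hydros, accept,
                                 0.35, 30.0, resids)
            assert got == want, f"trial {trial}"

    def test_planted_water_bond_rate_recovered(self, toy_traj):
        spec, traj, sel = toy_traj
        s = st.hydrogen_bonds(traj, sel, sel,
                              acceptor_groups=["lipid_O", "water"])
        per_donor_water = 0.5 * (s.per_donor_class.get(("N1", "water"), 0.0)
                                 + s.per_donor_class.get(("N2", "water"), 0.0))
        n = traj.n_frames * spec.n_probes * 2
        se = np.sqrt(spec.hbond_rate * (1 - spec.hbond_rate) / n)
        assert abs(per_donor_water - spec.hbond_rate) < 4 * se


# ---------------------------------------------------------------------------
# local bilayer COM and depth series

class TestLocalBilayerCom:
    def _two_lipid_traj(self):
        coords = np.array([
            [1.0, 1.0, 4.2],   # lipid 1 near probe
            [3.0, 3.0, 5.0],   # lipid 2 far away, higher
            [1.3, 1.0, 5.5],   # probe, slightly offset in-plane
        ])
        traj = _simple_traj(coords[None], names=["P", "P", "X2"],
                            resids=np.array([1, 2, 3]),
                            resnames=np.array(["POPC", "POPC", "RHD"]))
        sel = SelectionSpec({"lipids": [0, 1], "probe": [2]})
        return traj, sel

    def test_large_radius_recovers_global_com(self):
        traj, sel = self._two_lipid_traj()
        z = st.local_bilayer_com(traj, 0, sel["probe"], sel["lipids"],
                                 radius=10.0)
        assert z == pytest.approx(4.6)

    def test_small_radius_uses_local_lipids_only(self):
        traj, sel = self._two_lipid_traj()
        z = st.local_bilayer_com(traj, 0, sel["probe"], sel["lipids"],
                                 radius=0.5)
        assert z == pytest.approx(4.2)

    def test_empty_cylinder_is_an_error(self):
        traj, sel = self._two_lipid_traj()
        with pytest.raises(ValueError, match="radius"):
            st.local_bilayer_com(traj, 0, sel["probe"], sel["lipids"],
                                 radius=1e-6)

    def test_flat_toy_bilayer_local_equals_midplane(self, toy_traj):
        spec, traj, sel = toy_traj
        probes = traj.molecules(sel["probes"])
        z = st.local_bilayer_com(traj, 0, probes[0], sel["lipids"],
                                 radius=1.1)
        assert z == pytest.approx(spec.box[2] / 2, abs=0.3)

    def test_in_plane_translation_invariance(self, toy_traj):
        spec, traj, sel = toy_traj
        probes = traj.molecules(sel["probes"])
        shifted = mp.Trajectory(traj.names, traj.masses, traj.resids,
                                traj.resnames, traj.boxes,
                                traj.coords + np.array([3.7, -2.2, 0.0]))
        for f in (0, 1):
            a = st.local_bilayer_com(traj, f, probes[0], sel["lipids"], 1.1)
            b = st.local_bilayer_com(shifted, f, probes[0], sel["lipids"], 1.1)
            assert a == pytest.approx(b, abs=1e-9)

    def test_depth_series_constant_for_static_system(self):
        coords = np.array([[1.0, 1.0, 4.0], [1.0, 1.0, 5.5]])
        frames = np.tile(coords, (6, 1, 1))
        traj = _simple_traj(frames, names=["P", "X2"],
                            resids=np.array([1, 2]),
                            resnames=np.array(["POPC", "RHD"]))
        series = st.probe_depth_series(traj, traj.select(resname="RHD"),
                                       traj.select(resname="POPC"), radius=2.0)
        assert len(series) == 1
        assert series[0].shape == (6,)
        assert np.allclose(series[0], 1.5)

    def test_depth_series_statistics_match_generator(self, toy_traj):
        spec, traj, sel = toy_traj
        series = st.probe_depth_series(traj, sel["probes"], sel["lipids"],
                                       radius=3.0)
        depths = np.abs(np.concatenate(series))
        se = spec.probe_depth[1] / np.sqrt(depths.size)
        # local-cylinder reference adds jitter; allow a generous band
        assert abs(depths.mean() - spec.probe_depth[0]) < 10 * se
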