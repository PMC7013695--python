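"""Geometry kernels against independent oracles and closed forms."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import switchmd as sm
from switchmd.geometry import Selection, helix_axis
from switchmd.synthetic import place_atom

from conftest import make_trajectory


# ---------------------------------------------------------------------------
# independent dihedral oracle: two-plane-normal atan2 formula
# ---------------------------------------------------------------------------

def dihedral_oracle(p1, p2, p3, p4):
    """Angle between the p1p2p3 and p2p3p4 plane normals, signed by which
    side of the first plane the far bond points to (IUPAC)."""
    b1, b2, b3 = p2 - p1, p3 - p2, p4 - p3
    n1, n2 = np.cross(b1, b2), np.cross(b2, b3)
    n1 /= np.linalg.norm(n1)
    n2 /= np.linalg.norm(n2)
    mag = np.degrees(np.arccos(np.clip(np.dot(n1, n2), -1.0, 1.0)))
    sign = np.sign(np.dot(np.cross(n1, n2), b2))
    ang = mag if sign >= 0 else -mag
    return ang if ang > -180.0 else ang + 360.0


def test_dihedral_cis_and_trans():
    p = [np.array(v, float) for v in
         [(1, 1, 0), (1, 0, 0), (0, 0, 0), (0, 1, 0)]]
    assert sm.dihedral(*p) == pytest.approx(0.0, abs=1e-12)
    p[3] = np.array([0.0, -1.0, 0.0])
    assert sm.dihedral(*p) == pytest.approx(180.0, abs=1e-12)


def test_dihedral_matches_oracles_on_random_quadruples():
    rng = np.random.default_rng(7)
    pts = rng.normal(0, 5, (120, 4, 3))
    for q in pts:
        got = sm.dihedral(*q)
        assert got == pytest.approx(dihedral_oracle(*q), abs=1e-9)
    # cross-check against MDAnalysis as a second, external oracle
    mda = pytest.importorskip("MDAnalysis")
    from MDAnalysis.lib.distances import calc_dihedrals
    ref = np.degrees(calc_dihedrals(pts[:, 0], pts[:, 1], pts[:, 2], pts[:, 3]))
    got = sm.dihedral(pts[:, 0], pts[:, 1], pts[:, 2], pts[:, 3])
    diff = np.abs((got - ref + 180) % 360 - 180)
    assert diff.max() < 1e-3  # MDAnalysis computes in float32


def test_degenerate_dihedral_raises():
    a = np.array([0.0, 0.0, 0.0])
    with pytest.raises(sm.GeometryError):
        sm.dihedral(a, a + [1, 0, 0], a + [2, 0, 0], a + [3, 1, 0])


def test_chi1_from_internal_coordinates():
    n = np.array([0.0, 1.4, 0.3])
    ca = np.array([0.0, 0.0, 0.0])
    cb = place_atom(np.array([1.0, 2.0, 0.0]), n, ca, 1.53, 111.0, 60.0)
    for target in (-60.0, 75.0, 180.0):
        g = place_atom(n, ca, cb, 1.52, 114.0, target)
        assert sm.dihedral(n, ca, cb, g) == pytest.approx(target, abs=1e-9)


def test_chi1_on_generator_residue(noiseless):
    traj, rmap, truth = noiseless
    got = sm.chi1(traj.frame(0), rmap.resolve("7.53"))
    assert got == pytest.approx(-60.0, abs=1e-6)


def test_chi1_unsupported_and_missing():
    traj = make_trajectory(np.zeros((1, 2, 3)), res_ids=[1, 1],
                           atom_names=["N", "CA"], res_names=["GLY", "GLY"])
    with pytest.raises(sm.UnsupportedResidueError):
        sm.chi1(traj.frame(0), ("A", 1))
    traj2 = make_trajectory(np.zeros((1, 2, 3)), res_ids=[1, 1],
                            atom_names=["N", "CA"], res_names=["TRP", "TRP"])
    with pytest.raises(sm.MissingAtomError, match="CB"):
        sm.chi1(traj2.frame(0), ("A", 1))


def test_com_single_pair_and_bruteforce():
    coords = np.array([[[0, 0, 0], [2, 0, 0], [1, 3, 5], [4, 4, 4], [0, 1, 2]]],
                      dtype=float)
    traj = make_trajectory(coords)
    f = traj.frame(0)
    assert np.allclose(sm.com(f, Selection([0])), [0, 0, 0])
    assert np.allclose(sm.com(f, Selection([0, 1])), [1, 0, 0])
    sel = Selection(np.arange(5))
    assert np.allclose(sm.com(f, sel), coords[0].sum(axis=0) / 5)


def test_com_distance_series_constant():
    base = np.zeros((3, 2, 3))
    base[:, 1, 0] = 12.0
    traj = make_trajectory(base)
    s = sm.com_distance_series(traj, Selection([0]), Selection([1]))
    assert np.allclose(s.values, 12.0)
    same = sm.com_distance_series(traj, Selection([0, 1]), Selection([0, 1]))
    assert np.allclose(same.values, 0.0)


# ---------------------------------------------------------------------------
# superposition
# ---------------------------------------------------------------------------

def test_superpose_identity_and_rigid_motion():
    rng = np.random.default_rng(1)
    ref = rng.normal(0, 3, (10, 3))
    sel = Selection(np.arange(10))
    moved, R, t = sm.superpose(ref, ref, sel)
    assert np.allclose(moved, ref, atol=1e-9)
    from scipy.spatial.transform import Rotation
    rot = Rotation.random(rng=rng).as_matrix()
    mobile = ref @ rot.T + [5.0, -3.0, 2.0]
    fitted, _, _ = sm.superpose(mobile, ref, sel)
    assert sm.rmsd(fitted, ref) < 1e-6


def test_superpose_beats_random_rotations():
    rng = np.random.default_rng(2)
    ref = rng.normal(0, 3, (10, 3))
    mob = rng.normal(0, 3, (10, 3))
    sel = Selection(np.arange(10))
    fitted, _, _ = sm.superpose(mob, ref, sel)
    best = sm.rmsd(fitted, ref)
    from scipy.spatial.transform import Rotation
    rots = Rotation.random(10_000, rng=rng).as_matrix()
    mc = mob - mob.mean(axis=0)
    rc = ref - ref.mean(axis=0)
    trial = np.einsum("kij,nj->kni", rots, mc)
    rmsds = np.sqrt(((trial - rc) ** 2).sum(axis=2).mean(axis=1))
    assert best <= rmsds.min() + 1e-9


def test_superpose_collinear_rejected():
    pts = np.stack([np.arange(5.0), np.zeros(5), np.zeros(5)], axis=1)
    with pytest.raises(sm.GeometryError):
        sm.superpose(pts, pts, Selection(np.arange(5)))


def test_rmsd_series_static_and_noise_expectation():
    rng = np.random.default_rng(3)
    base = rng.normal(0, 10, (200, 3))
    static = make_trajectory(np.repeat(base[None], 5, axis=0))
    sel = Selection(np.arange(200))
    assert np.allclose(sm.rmsd_series(static, sel).values, 0.0, atol=1e-9)
    sigma = 0.4
    coords = base[None] + rng.normal(0, sigma, (100, 200, 3))
    coords[0] = base  # reference frame stays exact
    noisy = make_trajectory(coords)
    mean_rmsd = sm.rmsd_series(noisy, sel).values[1:].mean()
    assert mean_rmsd == pytest.approx(sigma * np.sqrt(3), rel=0.05)


def test_rmsf_static_jitter_and_permutation():
    rng = np.random.default_rng(4)
    base = rng.normal(0, 10, (50, 3))
    sel_fixed = Selection(np.arange(1, 50))
    static = make_trajectory(np.repeat(base[None], 4, axis=0))
    assert np.allclose(sm.rmsf(static, sel_fixed, Selection(np.arange(50))),
                       0.0, atol=1e-9)
    sigma = 0.5
    coords = np.repeat(base[None], 400, axis=0)
    coords[:, 0, :] += rng.normal(0, sigma, (400, 3))
    traj = make_trajectory(coords)
    vals = sm.rmsf(traj, sel_fixed, Selection(np.arange(50)))
    assert vals[0] == pytest.approx(sigma * np.sqrt(3), rel=0.05)
    assert np.all(vals[1:] < 1e-9)
    # frame order does not matter
    perm = rng.permutation(400)
    traj_p = make_trajectory(coords[perm])
    vals_p = sm.rmsf(traj_p, sel_fixed, Selection(np.arange(50)))
    assert np.allclose(vals, vals_p, atol=1e-9)


# ---------------------------------------------------------------------------
# minimum-distance matrices
# ---------------------------------------------------------------------------

def _min_dist_oracle(frame, res_a, res_b):
    traj = frame.trajectory
    out = np.empty((len(res_a), len(res_b)))
    for i, (ca_, ra) in enumerate(res_a):
        ia = traj.residue_indices(ca_, ra)
        for j, (cb_, rb) in enumerate(res_b):
            ib = traj.residue_indices(cb_, rb)
            best = np.inf
            for x in ia:
                for y in ib:
                    d = np.linalg.norm(frame.coords[x] - frame.coords[y])
                    best = min(best, d)
            out[i, j] = best
    return out


def test_contact_threshold_cases():
    coords = np.array([[[0, 0, 0], [2.5, 0, 0], [6.0, 0, 0]]], float)
    traj = make_trajectory(coords, res_ids=[1, 2, 3])
    f = traj.frame(0)
    mat, mask = sm.residue_min_distance_matrix(f, [("A", 1)], [("A", 2), ("A", 3)])
    assert mat[0, 0] == pytest.approx(2.5)
    assert mask[0, 0] and not mask[0, 1]
    mat2, mask2 = sm.residue_min_distance_matrix(f, [("A", 1)], [("A", 2)],
                                                 contact_cutoff=3.0)
    assert mask2[0, 0]
    coords[0, 1, 0] = 3.5
    traj2 = make_trajectory(coords, res_ids=[1, 2, 3])
    _, m = sm.residue_min_distance_matrix(traj2.frame(0), [("A", 1)], [("A", 2)])
    assert not m[0, 0]


def test_min_distance_matches_bruteforce():
    rng = np.random.default_rng(5)
    n_res, atoms_per = 6, 4
    coords = rng.normal(0, 8, (1, n_res * atoms_per, 3))
    res_ids = np.repeat(np.arange(1, n_res + 1), atoms_per)
    traj = make_trajectory(coords, res_ids=res_ids,
                           atom_names=["CA", "CB", "CG", "CD"] * n_res)
    res = [("A", i) for i in range(1, n_res + 1)]
    f = traj.frame(0)
    mat, _ = sm.residue_min_distance_matrix(f, res[:3], res[3:])
    assert np.allclose(mat, _min_dist_oracle(f, res[:3], res[3:]), atol=1e-12)


# ---------------------------------------------------------------------------
# helix axes and the TM6 kink
# ---------------------------------------------------------------------------

def _line_traj(n=8):
    pts = np.stack([np.zeros(n), np.zeros(n), np.arange(n, dtype=float)], axis=1)
    return make_trajectory(pts[None], res_ids=list(range(1, n + 1)))


def test_helix_axis_on_line_and_orientation():
    traj = _line_traj()
    res = [("A", i) for i in range(1, 9)]
    axis, _ = helix_axis(traj.frame(0), res)
    assert np.allclose(axis, [0, 0, 1], atol=1e-12)
    axis_r, _ = helix_axis(traj.frame(0), res[::-1])
    assert np.allclose(axis_r, [0, 0, -1], atol=1e-12)
    with pytest.raises(sm.GeometryError):
        helix_axis(traj.frame(0), res[:4])


def test_helix_axis_on_ideal_helix():
    n = 24  # long enough that the principal axis tracks the true axis
    i = np.arange(n)
    pts = np.stack([2.3 * np.cos(np.radians(100) * i),
                    2.3 * np.sin(np.radians(100) * i),
                    1.5 * i], axis=1)
    traj = make_trajectory(pts[None], res_ids=list(range(1, n + 1)))
    axis, _ = helix_axis(traj.frame(0), [("A", k) for k in range(1, n + 1)])
    angle = np.degrees(np.arccos(np.clip(axis @ [0, 0, 1], -1, 1)))
    assert angle < 1.0


def test_tm6_kink_straight_bent_and_rotation_invariant():
    straight, rmap0, _ = sm.generate_bundle(
        sm.SyntheticSpec(n_frames=1, noise_sigma=0.0, tm6_bend=0.0))
    assert sm.tm6_kink(straight.frame(0), rmap0) < 5.0
    bent, rmap, _ = sm.generate_bundle(
        sm.SyntheticSpec(n_frames=1, noise_sigma=0.0, tm6_bend=30.0))
    k = sm.tm6_kink(bent.frame(0), rmap)
    assert k == pytest.approx(30.0, abs=3.0)
    from scipy.spatial.transform import Rotation
    R = Rotation.from_euler("xyz", [30, -50, 110], degrees=True).as_matrix()
    rot = make_trajectory((bent.coords[0] @ R.T + 7.0)[None],
                          res_ids=bent.residue_ids,
                          atom_names=list(bent.atom_names),
                          res_names=list(bent.residue_names),
                          chains=list(bent.chain_ids))
    assert sm.tm6_kink(rot.frame(0), rmap) == pytest.approx(k, abs=1e-6)
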