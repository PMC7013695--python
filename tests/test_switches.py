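"""Hallmark metrics: rotamers, locks, trends, interface distances."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import switchmd as sm
from switchmd.geometry import DistanceSeries
from switchmd.switches import coupling_trend, interface_residue_distances

from conftest import make_trajectory


# ---------------------------------------------------------------------------
# rotamer binning
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("angle,expected", [
    (-60.0, "gauche-"), (60.0, "gauche+"), (180.0, "trans"),
    (-120.0, "trans"),            # boundary: half-open bins
    (-119.999, "gauche-"), (0.0, "gauche-"), (0.001, "gauche+"),
    (120.0, "gauche+"), (120.001, "trans"), (-179.9, "trans"),
])
def test_rotamer_bins(angle, expected):
    assert sm.rotamer_classify(angle) == expected


@settings(derandomize=True, max_examples=100)
@given(st.floats(min_value=-179.999, max_value=180.0))
def test_rotamer_bins_partition_the_circle(angle):
    label = sm.rotamer_classify(angle)
    assert label in ("gauche-", "gauche+", "trans")
    # vectorised call agrees with scalar call
    assert sm.rotamer_classify(np.array([angle]))[0] == label


# ---------------------------------------------------------------------------
# switch time series
# ---------------------------------------------------------------------------

def test_switch_series_static_and_planted_flips(noiseless):
    traj, rmap, truth = noiseless
    series = sm.switch_timeseries(traj, rmap)
    assert set(series) == {"6.48", "6.44", "6.55", "7.53"}
    for label, s in series.items():
        assert len(s.chi1) == traj.n_frames
    # 6.48 has planted two-state kinetics; recover the exact state sequence
    got = np.where(series["6.48"].state == "gauche-", 0, 1)
    assert np.array_equal(got, truth.rotamer_states["6.48"])
    assert np.allclose(series["6.48"].chi1, truth.chi1["6.48"], atol=1e-6)
    # the stable switches never leave their planted rotamer
    assert np.allclose(series["7.53"].chi1, -60.0, atol=1e-6)


def test_w648_chi1_stabilized_near_minus_60_under_noise():
    # the toggle tryptophan holds its gauche- rotamer in a stable receptor:
    # the series oscillates about -60 deg and rarely leaves the bin
    spec = sm.SyntheticSpec(n_frames=200, noise_sigma=0.1, seed=5)
    traj, rmap, _ = sm.generate_trajectory(spec)
    series = sm.switch_timeseries(traj, rmap, ["6.48"])["6.48"]
    assert abs(series.chi1.mean() + 60.0) < 15.0
    assert np.mean(series.state == "gauche-") > 0.95


# ---------------------------------------------------------------------------
# ionic lock
# ---------------------------------------------------------------------------

def _lock_frame(pairs):
    """Arg guanidinium + Glu carboxylate at explicit positions."""
    names, resn, rid, coords = [], [], [], []
    for name, xyz in pairs:
        names.append(name)
        if name.startswith("N"):
            resn.append("ARG"); rid.append(1)
        else:
            resn.append("GLU"); rid.append(2)
        coords.append(xyz)
    return make_trajectory(np.array(coords, float)[None], res_ids=rid,
                           atom_names=names, res_names=resn)


def test_ionic_lock_constructed_salt_bridge():
    traj = _lock_frame([("NH1", (0, 0, 0)), ("NE", (0, 1.5, 0)),
                        ("NH2", (0, -1.5, 0)),
                        ("OE1", (2.8, 0, 0)), ("OE2", (4.0, 0.5, 0))])
    d = sm.ionic_lock_distance(traj.frame(0), _map_to(1, 2))
    assert d == pytest.approx(2.8, abs=1e-12)


def _map_to(arg_rid, glu_rid):
    """Map whose 3.50 resolves to arg_rid and 6.30 to glu_rid."""
    return sm.ResidueMap(anchors={3: ("A", arg_rid - 0), 6: ("A", glu_rid + 20)},
                         spans={3: (arg_rid, arg_rid),
                                6: (glu_rid, glu_rid + 40)})


def test_ionic_lock_matches_enumeration_oracle():
    rng = np.random.default_rng(9)
    for _ in range(100):
        npos = rng.normal(0, 4, (3, 3))
        opos = rng.normal(2, 4, (2, 3))
        pairs = list(zip(("NE", "NH1", "NH2"), npos)) + \
            list(zip(("OE1", "OE2"), opos))
        traj = _lock_frame(pairs)
        d = sm.ionic_lock_distance(traj.frame(0), _map_to(1, 2))
        oracle = min(np.linalg.norm(a - b) for a in npos for b in opos)
        assert d == pytest.approx(oracle, abs=1e-12)


def test_ionic_lock_on_generator_truth(noiseless):
    traj, rmap, truth = noiseless
    d = sm.ionic_lock_distance(traj.frame(0), rmap)
    assert d == pytest.approx(truth.lock_distance, abs=1e-9)


def test_ionic_lock_missing_sidechain():
    traj = _lock_frame([("NH1", (0, 0, 0)), ("OE1", (3, 0, 0))])
    bad = make_trajectory(np.zeros((1, 1, 3)), res_ids=[1],
                          atom_names=["CA"], res_names=["ARG"])
    with pytest.raises(sm.MissingAtomError):
        sm.ionic_lock_distance(bad.frame(0), _map_to(1, 2))


# ---------------------------------------------------------------------------
# TM5-TM7 distance
# ---------------------------------------------------------------------------

def test_tm5_tm7_constructed_distance():
    coords = np.array([[[0, 0, 0], [10, 0, 0]]], float)
    traj = make_trajectory(coords, res_ids=[558, 753],
                           atom_names=["CA", "CA"], res_names=["TYR", "TYR"])
    rmap = sm.ResidueMap(anchors={5: ("A", 550), 7: ("A", 750)},
                         spans={5: (540, 565), 7: (740, 760)})
    assert sm.tm5_tm7_distance(traj.frame(0), rmap) == pytest.approx(10.0)


def test_tm5_tm7_symmetric_and_planted():
    spec = sm.SyntheticSpec(n_frames=1, noise_sigma=0.0, tm5_tm7=19.4)
    traj, rmap, _ = sm.generate_trajectory(spec)
    assert sm.tm5_tm7_distance(traj.frame(0), rmap) == pytest.approx(19.4, abs=1e-9)


# ---------------------------------------------------------------------------
# coupling trend
# ---------------------------------------------------------------------------

def test_trend_constant_series_is_flat():
    s = DistanceSeries("d", np.arange(10.0), np.full(10, 20.0))
    t = coupling_trend(s, threshold=0.001)
    assert t.slope == pytest.approx(0.0, abs=1e-12)
    assert t.classification == "flat"


def test_trend_exact_line_recovered():
    times = np.arange(0.0, 1000.0)
    s = DistanceSeries("d", times, 20.0 - 0.002 * times)
    t = coupling_trend(s, threshold=0.001)
    assert t.slope == pytest.approx(-0.002, abs=1e-9)
    assert t.intercept == pytest.approx(20.0, abs=1e-9)
    assert t.classification == "approaching"


def test_trend_degenerate_inputs():
    with pytest.raises(sm.DegenerateInputError):
        coupling_trend(DistanceSeries("d", np.array([0.0]), np.array([1.0])))


def test_trend_windowed_fit():
    times = np.arange(100.0)
    vals = np.where(times < 50, 10.0, 10.0 + 0.1 * (times - 50))
    s = DistanceSeries("d", times, vals)
    t_full = coupling_trend(s)
    t_late = coupling_trend(s, window=slice(50, 100))
    assert t_late.slope == pytest.approx(0.1, abs=1e-9)
    assert t_full.slope < t_late.slope


def test_trend_recovery_under_noise_quick():
    # a 10-seed mini version of the full Monte-Carlo acceptance check
    ok = 0
    for seed in range(10):
        spec = sm.SyntheticSpec(n_frames=1000, noise_sigma=0.5, seed=seed,
                                drift_slope=-0.003)
        traj, rmap, truth = sm.generate_trajectory(spec)
        series = sm.coupling_distance_series(
            traj, rmap, [("B", r) for r in range(351, 356)])
        t = coupling_trend(series, threshold=0.0005)
        if (t.classification == "approaching"
                and abs(t.slope - truth.drift_slope) <= 0.2 * 0.003):
            ok += 1
    assert ok >= 9


# ---------------------------------------------------------------------------
# interface distances and H-bonds
# ---------------------------------------------------------------------------

def test_interface_static_distance():
    coords = np.zeros((3, 4, 3))
    coords[:, 1] = [1.0, 0, 0]           # res 1 side chain centroid at (0.5,0,0)
    coords[:, 2] = [8.0, 0, 0]
    coords[:, 3] = [9.0, 0, 0]           # res 2 centroid at (8.5,0,0)
    traj = make_trajectory(coords, res_ids=[1, 1, 2, 2],
                           atom_names=["CB", "CG", "CB", "CG"],
                           res_names=["LEU"] * 4)
    out = interface_residue_distances(traj, [(("A", 1), ("A", 2))])
    (mean, sd), = out.values()
    assert mean == pytest.approx(8.0)
    assert sd == pytest.approx(0.0, abs=1e-12)


def test_interface_window_matches_direct_average():
    rng = np.random.default_rng(12)
    coords = np.zeros((20, 2, 3))
    coords[:, 1, 0] = 10.0 + 0.2 * np.arange(20) + rng.normal(0, 0.1, 20)
    traj = make_trajectory(coords, res_ids=[1, 2],
                           atom_names=["CB", "CB"], res_names=["LEU", "LEU"])
    pair = [(("A", 1), ("A", 2))]
    d = np.abs(coords[:, 1, 0])
    full = interface_residue_distances(traj, pair)
    late = interface_residue_distances(traj, pair, window=slice(10, 20))
    assert list(full.values())[0][0] == pytest.approx(d.mean(), abs=1e-9)
    assert list(late.values())[0][0] == pytest.approx(d[10:].mean(), abs=1e-9)
    assert list(full.values())[0][0] != list(late.values())[0][0]


def test_interface_glycine_falls_back_to_ca():
    coords = np.zeros((1, 2, 3))
    coords[0, 1, 0] = 7.5
    traj = make_trajectory(coords, res_ids=[1, 2],
                           atom_names=["CA", "CB"], res_names=["GLY", "LEU"])
    with pytest.warns(UserWarning, match="no side chain"):
        out = interface_residue_distances(traj, [(("A", 1), ("A", 2))])
    assert list(out.values())[0][0] == pytest.approx(7.5)


def _two_residue_frame(atoms1, atoms2):
    names = [n for n, _ in atoms1] + [n for n, _ in atoms2]
    coords = np.array([x for _, x in atoms1] + [x for _, x in atoms2], float)
    rids = [1] * len(atoms1) + [2] * len(atoms2)
    return make_trajectory(coords[None], res_ids=rids, atom_names=names,
                           res_names=["ARG"] * len(atoms1) + ["ASP"] * len(atoms2))


def test_hbond_within_and_beyond_cutoff():
    t = _two_residue_frame([("NH1", (0, 0, 0)), ("CB", (0, 2, 0))],
                           [("OD1", (2.9, 0, 0)), ("CG", (3.5, 1, 0))])
    present, (dn, an, d) = sm.hbond_present(t.frame(0), ("A", 1), ("A", 2))
    assert present and (dn, an) == ("NH1", "OD1")
    assert d == pytest.approx(2.9)
    t2 = _two_residue_frame([("NH1", (0, 0, 0))], [("OD1", (4.2, 0, 0))])
    present2, _ = sm.hbond_present(t2.frame(0), ("A", 1), ("A", 2))
    assert not present2


def test_hbond_matches_enumeration_oracle():
    rng = np.random.default_rng(21)
    for _ in range(100):
        a = [("N", rng.normal(0, 3, 3)), ("NE", rng.normal(0, 3, 3)),
             ("CB", rng.normal(0, 3, 3))]
        b = [("O", rng.normal(1, 3, 3)), ("OD1", rng.normal(1, 3, 3)),
             ("CG", rng.normal(1, 3, 3))]
        t = _two_residue_frame(a, b)
        got, (_, _, dmin) = sm.hbond_present(t.frame(0), ("A", 1), ("A", 2))
        polar_a = [x for n, x in a if n[0] in "NO"]
        polar_b = [x for n, x in b if n[0] in "NO"]
        oracle = min(np.linalg.norm(p - q) for p in polar_a for q in polar_b)
        assert dmin == pytest.approx(oracle, abs=1e-12)
        assert got == (oracle <= 3.5)
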