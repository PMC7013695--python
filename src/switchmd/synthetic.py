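"""Synthetic receptor/G-alpha/water trajectories with known ground truth.

The generator builds a toy 7-helix bundle that carries exactly the
features the analysis battery measures, each planted with an exact,
recoverable value:

* ideal poly-Leu C-alpha helices (rise 1.5 A, 100 deg/residue) on a
  circle, with the conserved class-A motifs (DRY in TM3, CWxP in TM6,
  NPxxY in TM7) and every battery residue placed at its Ballesteros-
  Weinstein position (residue_id = 1000*helix + position, so 3.50 is
  residue 3050);
* TM6 bent by a chosen angle at W6.48;
* switch residues built with full N/CA/CB/gamma internal coordinates so
  their chi1 equals the planted value exactly, evolving as a two-state
  Markov chain per frame;
* an 8-residue alpha5-helix mimic (chain B, residues 348-355) whose
  centroid distance to the receptor probe follows an exact line of the
  requested slope;
* an R3.50/E6.30 atom pair whose minimum charged-group distance equals
  the requested ionic-lock distance exactly;
* a water wire along the 3.32 -> 7.53 axis that is continuous, blocked at
  the hydrophobic barrier, or alternating frame by frame (blocked-frame
  waters are relocated to a bulk site so the atom count never changes);
* i.i.d. Gaussian coordinate noise added last, so every planted value is
  the noiseless truth and recovery tolerances scale with sigma*sqrt(3).

Randomness comes from one ``numpy.random.default_rng(seed)`` stream with
a fixed draw order (rotamer flips for each switch in label order, then
the noise block), so equal seeds give byte-identical output.

The dynamics are statistical mimicry only: no force field, membrane or
physical kinetics — just the signal structure (linear trends + noise,
two-state chi1 dynamics, open/blocked hydration) that real activation
trajectories show.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Mapping

import numpy as np
from scipy.spatial.transform import Rotation

from .errors import GenerationError
from .io import Trajectory, write_trajectory
from .numbering import ResidueMap
from .switches import COUPLING_RECEPTOR_LABELS

# residue-id scheme: helix h position p -> 1000*h + p
_P_FIRST, _P_LAST = 28, 65
_HELIX_DIRECTION = {h: (-1.0 if h % 2 == 1 else 1.0) for h in range(1, 8)}
# per-helix axial offset of the x.50 C-alpha (A); aligns the intracellular
# ends (3.50, 6.30, 7.53) and the orthosteric locus 3.32 the way a receptor
# bundle does
_HELIX_Z50 = {1: 0.0, 2: -2.0, 3: -13.0, 4: 0.0, 5: 2.0, 6: 17.0, 7: -5.5}

#: planted one-letter identities (helix, position) -> residue type
_PLANTED = {
    (2, 42): "LEU", (2, 43): "ILE", (2, 46): "LEU",
    (3, 32): "ASP", (3, 43): "LEU", (3, 46): "ILE",
    (3, 49): "ASP", (3, 50): "ARG", (3, 51): "TYR",
    (5, 43): "SER", (5, 46): "SER", (5, 50): "PRO",
    (5, 54): "THR", (5, 58): "TYR",
    (6, 28): "LYS", (6, 30): "GLU", (6, 36): "MET", (6, 40): "VAL",
    (6, 44): "PHE", (6, 47): "CYS", (6, 48): "TRP", (6, 49): "LEU",
    (6, 50): "PRO", (6, 55): "HIS", (6, 58): "ARG",
    (7, 34): "TYR", (7, 38): "THR", (7, 49): "ASN", (7, 50): "PRO",
    (7, 51): "ILE", (7, 52): "ILE", (7, 53): "TYR", (7, 56): "PHE",
}

_ALPHA5_NAMES = {348: "LEU", 349: "LEU", 350: "LEU", 351: "ASP",
                 352: "CYS", 353: "GLY", 354: "LEU", 355: "PHE"}

_DEFAULT_CHI1 = {"6.48": -60.0, "6.44": 180.0, "6.55": 180.0, "7.53": -60.0}


@dataclasses.dataclass(frozen=True)
class BundleGeometry:
    n_helices: int = 7
    bundle_radius: float = 14.0   # A, helix centers on this circle
    helix_radius: float = 2.3     # A, C-alpha radius of an ideal helix
    rise: float = 1.5             # A per residue
    twist: float = 100.0          # deg per residue


@dataclasses.dataclass(frozen=True)
class SyntheticSpec:
    """Ground-truth parameters of one synthetic trajectory."""

    n_frames: int = 1000
    dt: float = 1.0                     # ns per frame
    seed: int = 0
    drift_slope: float = 0.0            # A/ns, alpha5 approach (<0) / recede (>0)
    noise_sigma: float = 0.5            # A per axis, i.i.d. Gaussian
    tm6_bend: float = 0.0               # deg, kink planted at 6.48
    #: switch label -> (flip probability per frame, (state0 deg, state1 deg))
    rotamer_rates: Mapping[str, tuple[float, tuple[float, float]]] = \
        dataclasses.field(default_factory=dict)
    channel_state: str = "open"         # open | blocked | alternating
    lock_distance: float = 3.0          # A, planted R3.50-E6.30 minimum
    tm5_tm7: float | None = None        # A, optional planted Y5.58-Y7.53 CA
    geometry: BundleGeometry = BundleGeometry()

    def __post_init__(self):
        if self.n_frames < 1:
            raise GenerationError("n_frames must be >= 1")
        if self.noise_sigma < 0:
            raise GenerationError("noise_sigma must be >= 0")
        if self.channel_state not in ("open", "blocked", "alternating"):
            raise GenerationError(
                f"unknown channel_state {self.channel_state!r}")
        for label, (p, _states) in self.rotamer_rates.items():
            if not 0.0 <= p <= 1.0:
                raise GenerationError(
                    f"flip probability for {label} outside [0, 1]")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["rotamer_rates"] = {k: [v[0], list(v[1])]
                              for k, v in self.rotamer_rates.items()}
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SyntheticSpec":
        d = dict(d)
        if "geometry" in d and isinstance(d["geometry"], dict):
            d["geometry"] = BundleGeometry(**d["geometry"])
        rates = {k: (float(v[0]), (float(v[1][0]), float(v[1][1])))
                 for k, v in (d.get("rotamer_rates") or {}).items()}
        d["rotamer_rates"] = rates
        if d.get("tm5_tm7") is not None:
            d["tm5_tm7"] = float(d["tm5_tm7"])
        return cls(**d)


@dataclasses.dataclass
class GroundTruth:
    """Planted per-frame and scalar truths, exported for recovery tests."""

    spec: SyntheticSpec
    alpha5_distance: np.ndarray          # noiseless exact distance, A
    channel_open: np.ndarray             # bool per frame
    rotamer_states: dict[str, np.ndarray]  # label -> 0/1 per frame
    chi1: dict[str, np.ndarray]          # label -> planted chi1 deg per frame
    lock_distance: float
    tm6_bend: float
    drift_slope: float
    initial_distance: float


# ---------------------------------------------------------------------------
# Internal-coordinate construction
# ---------------------------------------------------------------------------

def place_atom(a: np.ndarray, b: np.ndarray, c: np.ndarray,
               bond: float, angle_deg: float, dihedral_deg: float
               ) -> np.ndarray:
    """Place atom D with |CD| = bond, angle(B,C,D) = angle and
    dihedral(A,B,C,D) = dihedral (NeRF construction)."""
    theta = np.radians(angle_deg)
    phi = np.radians(dihedral_deg)
    bc = c - b
    bc /= np.linalg.norm(bc)
    n = np.cross(b - a, bc)
    nn = np.linalg.norm(n)
    if nn < 1e-10:
        raise GenerationError("collinear reference atoms in NeRF placement")
    n /= nn
    m = np.cross(n, bc)
    d_local = bond * np.array([-np.cos(theta),
                               np.sin(theta) * np.cos(phi),
                               np.sin(theta) * np.sin(phi)])
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


class _AtomTable:
    def __init__(self):
        self.names: list[str] = []
        self.res_names: list[str] = []
        self.res_ids: list[int] = []
        self.chains: list[str] = []
        self.elements: list[str] = []
        self.coords: list[np.ndarray] = []

    def add(self, name, res_name, res_id, chain, xyz, element=None):
        self.names.append(name)
        self.res_names.append(res_name)
        self.res_ids.append(int(res_id))
        self.chains.append(chain)
        self.elements.append(element or name[0])
        self.coords.append(np.asarray(xyz, dtype=float))
        return len(self.coords) - 1


def _helix_ca(geom: BundleGeometry, helix: int, positions: np.ndarray
              ) -> np.ndarray:
    """Ideal-helix C-alpha coordinates for BW positions of one helix."""
    phi0 = 2.0 * np.pi * (helix - 1) / geom.n_helices
    center = geom.bundle_radius * np.array([np.cos(phi0), np.sin(phi0), 0.0])
    s = _HELIX_DIRECTION[helix]
    rel = positions - 50.0
    ang = np.radians(geom.twist) * rel + helix  # per-helix phase
    x = geom.helix_radius * np.cos(ang)
    y = geom.helix_radius * np.sin(ang)
    z = _HELIX_Z50[helix] + s * geom.rise * rel
    return center + np.stack([x, y, z], axis=1)


def _switch_labels(spec: SyntheticSpec) -> dict[str, tuple[float, tuple[float, float]]]:
    """Effective rotamer kinetics: spec overrides on top of stable defaults."""
    rates = {}
    for label, base in _DEFAULT_CHI1.items():
        rates[label] = (0.0, (base, 180.0 if base != 180.0 else -60.0))
    rates.update(spec.rotamer_rates)
    return rates


def generate_bundle(spec: SyntheticSpec
                    ) -> tuple[Trajectory, ResidueMap, GroundTruth]:
    """Single-frame bundle: :func:`generate_trajectory` with n_frames=1."""
    one = dataclasses.replace(spec, n_frames=1)
    return generate_trajectory(one)


def _build_base(spec: SyntheticSpec):
    """Construct the noiseless frame-0 structure and all per-frame
    modification hooks (atom index groups, alternative gamma positions,
    water chain geometry)."""
    geom = spec.geometry
    if geom.n_helices != 7:
        raise GenerationError("the bundle is a 7-TM receptor mimic")
    spacing = 2.0 * geom.bundle_radius * np.sin(np.pi / geom.n_helices)
    if spacing < 2.5 * geom.helix_radius:
        raise GenerationError(
            f"helices overlap: center spacing {spacing:.2f} A")

    table = _AtomTable()
    positions = np.arange(_P_FIRST, _P_LAST + 1, dtype=float)
    ca_index: dict[tuple[int, int], int] = {}
    switch_rates = _switch_labels(spec)
    switch_gamma: dict[str, dict] = {}

    for h in range(1, 8):
        cas = _helix_ca(geom, h, positions)
        for p, xyz in zip(positions.astype(int), cas):
            res_name = _PLANTED.get((h, p), "LEU")
            rid = 1000 * h + p
            i = table.add("CA", res_name, rid, "A", xyz, "C")
            ca_index[(h, p)] = i

    # side chains needed by the battery ---------------------------------
    # switch residues: N, CB and gamma placed by internal coordinates so
    # chi1 is exact; two gamma positions precomputed (one per Markov state)
    for label, (_prob, states) in switch_rates.items():
        h, p = int(label.split(".")[0]), int(label.split(".")[1])
        rid = 1000 * h + p
        res_name = _PLANTED[(h, p)]
        ca = table.coords[ca_index[(h, p)]]
        ca_prev = table.coords[ca_index[(h, p - 1)]]
        back = (ca_prev - ca) / np.linalg.norm(ca_prev - ca)
        perp = np.cross(back, [0.0, 0.0, 1.0])
        if np.linalg.norm(perp) < 1e-6:
            perp = np.cross(back, [1.0, 0.0, 0.0])
        perp /= np.linalg.norm(perp)
        n_dir = back + 0.6 * perp
        n = ca + 1.46 * n_dir / np.linalg.norm(n_dir)
        cb = place_atom(ca_prev, n, ca, 1.53, 111.0, 122.0)
        table.add("N", res_name, rid, "A", n, "N")
        cb_i = table.add("CB", res_name, rid, "A", cb, "C")
        gamma_name = {"ILE": "CG1", "VAL": "CG1", "SER": "OG",
                      "THR": "OG1", "CYS": "SG"}.get(res_name, "CG")
        g0 = place_atom(n, ca, cb, 1.52, 114.0, states[0])
        g1 = place_atom(n, ca, cb, 1.52, 114.0, states[1])
        g_i = table.add(gamma_name, res_name, rid, "A", g0, gamma_name[0])
        switch_gamma[label] = {"index": g_i, "g0": g0, "g1": g1,
                               "cb": cb_i}

    # ionic lock: R3.50 guanidinium / E6.30 carboxylate with an exact
    # planted minimum distance along the inter-CA line
    ca_r = table.coords[ca_index[(3, 50)]]
    ca_e = table.coords[ca_index[(6, 30)]]
    u = (ca_e - ca_r) / np.linalg.norm(ca_e - ca_r)
    perp = np.cross(u, [0.0, 0.0, 1.0])
    perp /= np.linalg.norm(perp)
    mid = 0.5 * (ca_r + ca_e)
    nh1 = mid - 0.5 * spec.lock_distance * u
    oe1 = mid + 0.5 * spec.lock_distance * u
    table.add("NH1", "ARG", 3050, "A", nh1, "N")
    table.add("NE", "ARG", 3050, "A", nh1 - 1.3 * u + 0.8 * perp, "N")
    table.add("NH2", "ARG", 3050, "A", nh1 - 0.9 * u - 1.1 * perp, "N")
    table.add("OE1", "GLU", 6030, "A", oe1, "O")
    table.add("OE2", "GLU", 6030, "A", oe1 + 1.0 * u + 0.9 * perp, "O")

    # ICL3 arginine mimic (R233): side chain pointing toward the G protein
    r233_ca = np.array([6.0, 6.0, -22.0])
    table.add("CA", "ARG", 233, "A", r233_ca, "C")
    table.add("CB", "ARG", 233, "A", r233_ca + [0.0, -1.0, -1.2], "C")
    table.add("NE", "ARG", 233, "A", r233_ca + [-1.0, -2.2, -2.4], "N")
    table.add("NH1", "ARG", 233, "A", r233_ca + [-2.0, -3.0, -3.0], "N")
    table.add("NH2", "ARG", 233, "A", r233_ca + [-0.2, -3.2, -3.2], "N")

    # alpha5 mimic: chain B, residues 348-355 rising toward the receptor
    galpha_atoms: list[int] = []
    for k, (rid, res_name) in enumerate(sorted(_ALPHA5_NAMES.items())):
        ang = np.radians(100.0) * k
        xyz = np.array([2.3 * np.cos(ang), 2.3 * np.sin(ang),
                        -28.0 + 1.5 * k])
        galpha_atoms.append(table.add("CA", res_name, rid, "B", xyz, "C"))
        if res_name == "ASP":  # D351 carboxylate for H-bond/interface checks
            galpha_atoms.append(table.add("CB", res_name, rid, "B",
                                          xyz + [1.2, 0.6, -0.4], "C"))
            galpha_atoms.append(table.add("CG", res_name, rid, "B",
                                          xyz + [2.4, 1.2, -0.8], "C"))
            galpha_atoms.append(table.add("OD1", res_name, rid, "B",
                                          xyz + [3.2, 1.6, 0.0], "O"))
            galpha_atoms.append(table.add("OD2", res_name, rid, "B",
                                          xyz + [2.8, 1.4, -2.0], "O"))

    # TM6 bend: rotate everything above W6.48 about a tangential axis
    # through the 6.48 C-alpha; rotation preserves side-chain internal
    # coordinates, so chi1 stays exact
    if spec.tm6_bend != 0.0:
        pivot = table.coords[ca_index[(6, 48)]].copy()
        phi6 = 2.0 * np.pi * 5 / 7
        axis = np.array([-np.sin(phi6), np.cos(phi6), 0.0])
        rot = Rotation.from_rotvec(np.radians(spec.tm6_bend) * axis)
        for i in range(len(table.coords)):
            rid = table.res_ids[i]
            if table.chains[i] == "A" and 6049 <= rid <= 6000 + _P_LAST:
                table.coords[i] = pivot + rot.apply(table.coords[i] - pivot)
        for label, info in switch_gamma.items():
            h, p = (int(x) for x in label.split("."))
            if h == 6 and p >= 49:
                info["g0"] = pivot + rot.apply(info["g0"] - pivot)
                info["g1"] = pivot + rot.apply(info["g1"] - pivot)

    # optional planted Y5.58-Y7.53 CA distance: translate helix 7 radially
    if spec.tm5_tm7 is not None:
        a = table.coords[ca_index[(5, 58)]]
        b = table.coords[ca_index[(7, 53)]]
        v = b - a
        shift = a + spec.tm5_tm7 * v / np.linalg.norm(v) - b
        for i in range(len(table.coords)):
            if table.chains[i] == "A" and 7000 <= table.res_ids[i] < 8000:
                table.coords[i] = table.coords[i] + shift
        for label, info in switch_gamma.items():
            if label.startswith("7."):
                info["g0"] = info["g0"] + shift
                info["g1"] = info["g1"] + shift

    # water wire along the 3.32 -> 7.53 axis ----------------------------
    top = table.coords[ca_index[(3, 32)]].copy()
    bottom = table.coords[ca_index[(7, 53)]].copy()
    wire = bottom - top
    length = float(np.linalg.norm(wire))
    uw = wire / length
    n_w = int(np.ceil((length - 4.0) / 3.0)) + 1
    s_vals = np.linspace(2.0, length - 2.0, n_w)
    open_pos = np.array([top + s * uw for s in s_vals])
    gap = (s_vals >= length / 2 - 4.5) & (s_vals <= length / 2 + 4.5)
    bulk = np.array([[60.0 + 3.0 * i, 60.0, 40.0] for i in range(n_w)])
    blocked_pos = open_pos.copy()
    blocked_pos[gap] = bulk[gap]
    water_idx = []
    for i in range(n_w):
        water_idx.append(table.add("O", "HOH", 9001 + i, "W",
                                   open_pos[i], "O"))

    rmap = ResidueMap(
        anchors={h: ("A", 1000 * h + 50) for h in range(1, 8)},
        spans={h: (1000 * h + _P_FIRST, 1000 * h + _P_LAST)
               for h in range(1, 8)},
        receptor_chain="A", galpha_chain="B",
        special={"R233": ("A", 233),
                 "alpha5": [("B", r) for r in range(351, 356)]},
    )

    base = np.stack(table.coords)
    probe_rec = [ca_index[(int(l.split(".")[0]), int(l.split(".")[1]))]
                 for l in COUPLING_RECEPTOR_LABELS]
    probe_g = [i for i, (c, r, nm) in
               enumerate(zip(table.chains, table.res_ids, table.names))
               if c == "B" and 351 <= r <= 355 and nm == "CA"]
    chain_b = [i for i, c in enumerate(table.chains) if c == "B"]
    return (table, base, rmap, switch_gamma, switch_rates,
            np.array(water_idx), open_pos, blocked_pos,
            np.array(probe_rec), np.array(probe_g), np.array(chain_b))


def generate_trajectory(spec: SyntheticSpec
                        ) -> tuple[Trajectory, ResidueMap, GroundTruth]:
    """Build a full synthetic trajectory plus its residue map and the
    per-frame ground-truth labels."""
    (table, base, rmap, switch_gamma, switch_rates, water_idx,
     open_pos, blocked_pos, probe_rec, probe_g, chain_b) = _build_base(spec)
    rng = np.random.default_rng(spec.seed)
    m = spec.n_frames
    n_atoms = base.shape[0]
    coords = np.repeat(base[None], m, axis=0)
    t_ns = np.arange(m) * spec.dt

    # (1) rotamer flips, in sorted label order
    states: dict[str, np.ndarray] = {}
    chi1_truth: dict[str, np.ndarray] = {}
    for label in sorted(switch_rates):
        prob, state_pair = switch_rates[label]
        flips = rng.random(m) < prob
        flips[0] = False
        s = np.cumsum(flips) % 2
        states[label] = s.astype(int)
        chi1_truth[label] = np.where(s == 0, state_pair[0], state_pair[1])
        info = switch_gamma[label]
        coords[:, info["index"], :] = np.where(
            s[:, None] == 0, info["g0"][None], info["g1"][None])

    # alpha5 drift along the exact probe-to-probe line
    com_r = base[probe_rec].mean(axis=0)
    com_g = base[probe_g].mean(axis=0)
    d0 = float(np.linalg.norm(com_g - com_r))
    u = (com_g - com_r) / d0
    drift = spec.drift_slope * t_ns
    if np.any(d0 + drift <= 0):
        raise GenerationError("drift drives the alpha5 probe through the "
                              "receptor probe (distance <= 0)")
    coords[:, chain_b, :] += drift[:, None, None] * u[None, None, :]
    alpha5_distance = d0 + drift

    # channel state per frame
    if spec.channel_state == "open":
        open_flags = np.ones(m, dtype=bool)
    elif spec.channel_state == "blocked":
        open_flags = np.zeros(m, dtype=bool)
    else:  # alternating, starting open
        open_flags = (np.arange(m) % 2 == 0)
    closed = ~open_flags
    coords[np.ix_(np.nonzero(closed)[0], water_idx)] = blocked_pos[None]
    coords[np.ix_(np.nonzero(open_flags)[0], water_idx)] = open_pos[None]

    # (2) Gaussian coordinate noise, added last
    if spec.noise_sigma > 0:
        coords += rng.normal(0.0, spec.noise_sigma, size=(m, n_atoms, 3))

    traj = Trajectory(coords, table.names, table.res_names, table.res_ids,
                      table.chains, table.elements, times=t_ns,
                      source=f"synthetic(seed={spec.seed})")
    truth = GroundTruth(
        spec=spec, alpha5_distance=alpha5_distance, channel_open=open_flags,
        rotamer_states=states, chi1=chi1_truth,
        lock_distance=spec.lock_distance, tm6_bend=spec.tm6_bend,
        drift_slope=spec.drift_slope, initial_distance=d0,
    )
    return traj, rmap, truth


# ---------------------------------------------------------------------------
# Presets: the labelled study conditions the battery must discriminate
# ---------------------------------------------------------------------------

# Presets carry noise_sigma = 0.1 A: the level of residual coordinate
# scatter at which every planted hallmark (including hydrogen-bonded water
# wires, whose 0.5 A link margin cannot survive larger jitter) stays
# decodable, emulating imaged, well-equilibrated frames.  Harsher noise
# regimes are exercised explicitly where a recovery test states them.
PRESETS: dict[str, dict] = {
    # agonist-bound receptor that couples: G protein approaches, TM6 bent,
    # continuous water channel, ionic lock broken
    "active-coupled": dict(drift_slope=-0.003, tm6_bend=30.0,
                           channel_state="open", lock_distance=12.0,
                           noise_sigma=0.1),
    # decoupling receptor: G protein recedes, TM6 straight, channel blocked
    # at the hydrophobic barrier, ionic lock formed
    "inactive-decoupled": dict(drift_slope=0.003, tm6_bend=0.0,
                               channel_state="blocked", lock_distance=3.0,
                               noise_sigma=0.1),
    # hydration stops at the barrier; no net coupling trend
    "blocked-barrier": dict(drift_slope=0.0, tm6_bend=0.0,
                            channel_state="blocked", lock_distance=3.0,
                            noise_sigma=0.1),
    # channel toggles open/closed every frame (open fraction 0.5)
    "alternating-channel": dict(drift_slope=0.0, tm6_bend=15.0,
                                channel_state="alternating",
                                lock_distance=6.0, noise_sigma=0.1),
}


def preset_spec(name: str, seed: int = 0, n_frames: int = 1000,
                **overrides) -> SyntheticSpec:
    if name not in PRESETS:
        raise GenerationError(
            f"unknown preset {name!r}; choose from {sorted(PRESETS)}")
    kwargs = dict(PRESETS[name])
    kwargs.update(overrides)
    return SyntheticSpec(n_frames=n_frames, seed=seed, **kwargs)


def write_outputs(traj: Trajectory, rmap: ResidueMap, truth: GroundTruth,
                  out_dir: str | Path) -> dict[str, Path]:
    """Write trajectory (multi-model PDB), residue-map config, truth-label
    table and the spec echo; returns the paths."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {
        "trajectory": out_dir / "trajectory.pdb",
        "map": out_dir / "residue_map.yaml",
        "truth": out_dir / "truth.tsv",
        "spec": out_dir / "spec.json",
    }
    write_trajectory(traj, paths["trajectory"])
    rmap.to_config(paths["map"])
    import pandas as pd
    cols = {"frame": np.arange(traj.n_frames), "time_ns": traj.times,
            "alpha5_distance": truth.alpha5_distance,
            "channel_open": truth.channel_open.astype(int)}
    for label in sorted(truth.rotamer_states):
        cols[f"state_{label}"] = truth.rotamer_states[label]
        cols[f"chi1_{label}"] = truth.chi1[label]
    pd.DataFrame(cols).to_csv(paths["truth"], sep="\t", index=False)
    with open(paths["spec"], "w") as fh:
        json.dump(truth.spec.to_dict(), fh, indent=1)
    return paths
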