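"""Trajectory I/O: multi-model PDB in, tabular analysis reports out.

The canonical trajectory dialect is multi-model PDB (one ``MODEL`` per
sampled time point).  Parsing is delegated to :mod:`biotite`; this module
wraps it in the package's own vectorised :class:`Trajectory` container and
enforces the contracts the analyses rely on: identical atom ordering and
count in every frame, 1-based residue numbering preserved from the source,
insertion codes rejected, highest-occupancy altloc kept, and waters
(HOH/TIP3/SOL/WAT) retained but flagged.

A reader adapter only needs to produce a :class:`Trajectory`; binary
trajectory formats can be plugged in behind :func:`read_structure` later
without touching any analysis code.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import biotite.structure as struc
import biotite.structure.io.pdb as pdbio

from .errors import ParseError, StructureError

WATER_RESIDUE_NAMES = frozenset({"HOH", "TIP3", "SOL", "WAT"})

_THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}

_BACKBONE_ATOMS = frozenset({"N", "CA", "C", "O", "OXT"})


@dataclasses.dataclass(frozen=True)
class AtomRecord:
    """One atom of one frame, with source-file identity preserved."""

    atom_name: str
    element: str
    residue_name: str
    residue_id: int
    chain_id: str
    coords: np.ndarray  # shape (3,), Angstrom


class Frame:
    """A lightweight per-time-point view into a :class:`Trajectory`."""

    def __init__(self, trajectory: "Trajectory", index: int):
        self.trajectory = trajectory
        self.index = int(index)

    @property
    def time(self) -> float:
        return float(self.trajectory.times[self.index])

    @property
    def coords(self) -> np.ndarray:
        """(n_atoms, 3) coordinates of this frame, Angstrom."""
        return self.trajectory.coords[self.index]

    @property
    def atoms(self) -> list[AtomRecord]:
        t = self.trajectory
        xyz = self.coords
        return [
            AtomRecord(t.atom_names[i], t.elements[i], t.residue_names[i],
                       int(t.residue_ids[i]), t.chain_ids[i], xyz[i])
            for i in range(t.n_atoms)
        ]

    def __repr__(self) -> str:  # pragma: no cover
        return f"<Frame {self.index} of {self.trajectory!r}>"


class Trajectory:
    """Ordered frames over a fixed atom table.

    Coordinates are held as one ``(n_frames, n_atoms, 3)`` float64 array so
    every analysis can vectorise over time; the per-atom metadata
    (name/residue/chain/element) is shared by all frames, which *is* the
    atom-ordering invariant: a selection computed on frame 0 indexes the
    same atoms everywhere.
    """

    def __init__(self, coords: np.ndarray, atom_names: Sequence[str],
                 residue_names: Sequence[str], residue_ids: Sequence[int],
                 chain_ids: Sequence[str], elements: Sequence[str] | None = None,
                 times: Sequence[float] | None = None, source: str = "<memory>"):
        coords = np.asarray(coords, dtype=float)
        if coords.ndim == 2:
            coords = coords[None]
        if coords.ndim != 3 or coords.shape[2] != 3:
            raise StructureError(f"coords must be (n_frames, n_atoms, 3); got {coords.shape}")
        if coords.shape[0] < 1:
            raise StructureError("a trajectory needs at least one frame")
        if not np.all(np.isfinite(coords)):
            raise StructureError("non-finite coordinates")
        self.coords = coords
        n = coords.shape[1]
        self.atom_names = np.asarray(atom_names, dtype=object)
        self.residue_names = np.asarray(residue_names, dtype=object)
        self.residue_ids = np.asarray(residue_ids, dtype=int)
        self.chain_ids = np.asarray(chain_ids, dtype=object)
        if elements is None:
            elements = [str(a)[:1] for a in self.atom_names]
        self.elements = np.asarray(elements, dtype=object)
        for arr, label in ((self.atom_names, "atom_names"),
                           (self.residue_names, "residue_names"),
                           (self.residue_ids, "residue_ids"),
                           (self.chain_ids, "chain_ids"),
                           (self.elements, "elements")):
            if len(arr) != n:
                raise StructureError(f"{label} length {len(arr)} != n_atoms {n}")
        if times is None:
            times = np.arange(coords.shape[0], dtype=float)
        self.times = np.asarray(times, dtype=float)
        if len(self.times) != coords.shape[0]:
            raise StructureError("times length != n_frames")
        if len(self.times) > 1 and not np.all(np.diff(self.times) > 0):
            raise StructureError("frame times must be strictly increasing")
        self.source = source
        self.is_water = np.isin(self.residue_names.astype(str),
                                list(WATER_RESIDUE_NAMES))
        self._atom_lookup: dict[tuple[str, int, str], int] = {}
        for i in range(n):
            key = (str(self.chain_ids[i]), int(self.residue_ids[i]),
                   str(self.atom_names[i]))
            self._atom_lookup.setdefault(key, i)

    # -- basic shape ------------------------------------------------------
    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[1]

    @property
    def chains(self) -> set[str]:
        return set(str(c) for c in self.chain_ids)

    @property
    def frames(self) -> list[Frame]:
        return [Frame(self, i) for i in range(self.n_frames)]

    def frame(self, index: int) -> Frame:
        return Frame(self, index)

    def __repr__(self) -> str:  # pragma: no cover
        return (f"Trajectory({self.n_frames} frames, {self.n_atoms} atoms, "
                f"source={self.source!r})")

    # -- lookups ----------------------------------------------------------
    def atom_index(self, chain_id: str, residue_id: int, atom_name: str) -> int:
        key = (str(chain_id), int(residue_id), str(atom_name))
        try:
            return self._atom_lookup[key]
        except KeyError:
            raise KeyError(f"no atom {atom_name} in residue "
                           f"{chain_id}/{residue_id}") from None

    def has_atom(self, chain_id: str, residue_id: int, atom_name: str) -> bool:
        return (str(chain_id), int(residue_id), str(atom_name)) in self._atom_lookup

    def residue_indices(self, chain_id: str, residue_id: int,
                        heavy_only: bool = True,
                        sidechain_only: bool = False) -> np.ndarray:
        mask = (self.chain_ids == str(chain_id)) & (self.residue_ids == int(residue_id))
        if heavy_only:
            mask &= self.elements.astype(str) != "H"
        if sidechain_only:
            mask &= ~np.isin(self.atom_names.astype(str), list(_BACKBONE_ATOMS))
        return np.nonzero(mask)[0]

    def residue_name(self, chain_id: str, residue_id: int) -> str:
        idx = self.residue_indices(chain_id, residue_id, heavy_only=False)
        if len(idx) == 0:
            raise KeyError(f"no residue {chain_id}/{residue_id}")
        return str(self.residue_names[idx[0]])

    def water_oxygen_indices(self) -> np.ndarray:
        """Indices of water oxygens (waters are represented by O only
        downstream; hydrogens, if present, are ignored)."""
        return np.nonzero(self.is_water
                          & (self.elements.astype(str) == "O"))[0]

    def sequence(self, chain_id: str) -> tuple[str, list[int]]:
        """One-letter sequence and residue ids of a chain (waters and
        unknown residues excluded / 'X')."""
        seq, ids = [], []
        seen = set()
        for i in range(self.n_atoms):
            if str(self.chain_ids[i]) != str(chain_id) or self.is_water[i]:
                continue
            rid = int(self.residue_ids[i])
            if rid in seen:
                continue
            seen.add(rid)
            seq.append(_THREE_TO_ONE.get(str(self.residue_names[i]), "X"))
            ids.append(rid)
        order = np.argsort(ids)
        return "".join(seq[i] for i in order), [ids[i] for i in order]


# ---------------------------------------------------------------------------
# Reading
# ---------------------------------------------------------------------------

def _prescan_pdb(path: Path) -> None:
    """Reject insertion codes and malformed coordinate fields with errors
    that name the offending line."""
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.startswith(("ATOM", "HETATM")):
                continue
            if len(line) >= 27 and line[26] not in (" ", "\n", ""):
                raise ParseError(
                    f"{path}: line {lineno}: insertion code "
                    f"{line[26]!r} is not supported")
            try:
                for lo, hi in ((30, 38), (38, 46), (46, 54)):
                    float(line[lo:hi])
            except (ValueError, IndexError):
                raise ParseError(
                    f"{path}: line {lineno}: malformed coordinate field") from None


def read_structure(path: str | Path) -> Trajectory:
    """Read a (multi-model) PDB file into a :class:`Trajectory`.

    One frame per ``MODEL`` record; exactly one frame if the file has no
    MODEL records.  Waters are retained and flagged.  For altloc groups the
    highest-occupancy conformer is kept (ties: first encountered).

    Raises
    ------
    ParseError
        Malformed coordinate field or insertion code, naming the line.
    StructureError
        Models disagree in atom count or ordering.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    _prescan_pdb(path)
    pdb_file = pdbio.PDBFile.read(str(path))
    try:
        stack = pdb_file.get_structure(model=None, altloc="occupancy")
    except Exception as exc:
        raise StructureError(f"{path}: inconsistent models: {exc}") from exc
    if isinstance(stack, struc.AtomArray):  # pragma: no cover - defensive
        stack = struc.stack([stack])
    return Trajectory(
        coords=np.asarray(stack.coord, dtype=float),
        atom_names=stack.atom_name.astype(object),
        residue_names=stack.res_name.astype(object),
        residue_ids=stack.res_id,
        chain_ids=stack.chain_id.astype(object),
        elements=stack.element.astype(object),
        source=str(path),
    )


def write_trajectory(traj: Trajectory, path: str | Path) -> None:
    """Write a trajectory as multi-model PDB (inverse of
    :func:`read_structure` up to the format's 3-decimal precision)."""
    n = traj.n_atoms
    template = struc.AtomArray(n)
    template.coord = traj.coords[0].astype(np.float32)
    template.atom_name = traj.atom_names.astype("U6")
    template.res_name = traj.residue_names.astype("U5")
    template.res_id = traj.residue_ids
    template.chain_id = traj.chain_ids.astype("U4")
    template.element = traj.elements.astype("U2")
    template.hetero = traj.is_water
    stack = struc.stack([template] * traj.n_frames)
    stack.coord = traj.coords.astype(np.float32)
    pdb_file = pdbio.PDBFile()
    pdb_file.set_structure(stack)
    pdb_file.write(str(path))


# ---------------------------------------------------------------------------
# Report tables
# ---------------------------------------------------------------------------

def write_table(df: pd.DataFrame, path: str | Path,
                metadata: dict | None = None) -> None:
    """Write one tab-separated metric table with '#'-prefixed run-metadata
    header lines (round-trip readable via :func:`read_table`)."""
    path = Path(path)
    with open(path, "w") as fh:
        for key, value in (metadata or {}).items():
            fh.write(f"# {key}={value}\n")
        df.to_csv(fh, sep="\t", index=False, float_format="%.6f")


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")


def write_report(report, out_dir: str | Path,
                 metadata: dict | None = None) -> dict[str, Path]:
    """Write an activation report as one TSV per metric family.

    ``report`` is anything exposing ``tables() -> dict[str, DataFrame]``
    (see :class:`switchmd.model.ActivationResults`).  Returns the mapping of
    family name to written path.  Empty families produce a header-only file.
    """
    out_dir = Path(out_dir)
    try:
        out_dir.mkdir(parents=True, exist_ok=True)
    except OSError as exc:
        raise OSError(f"cannot create output directory {out_dir}: {exc}") from exc
    written: dict[str, Path] = {}
    for family, df in report.tables().items():
        p = out_dir / f"{family}.tsv"
        write_table(df, p, metadata=metadata)
        written[family] = p
    return written
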