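"""Ballesteros-Weinstein (BW) numbering for class-A GPCRs.

A BW label ``h.p`` names position ``p`` on transmembrane helix ``h``
relative to the helix's most conserved residue, which is defined to be
``h.50``.  Within a helix the mapping is pure arithmetic:
``residue_id = anchor_id + (p - 50)``.  Anchors (the x.50 residues) are
supplied explicitly in a mapping config — the auditable path — or proposed
from the sequence via the conserved class-A motifs:

* ``DRY`` (TM3): the arginine is R3.50,
* ``CWxP`` (TM6): the tryptophan is W6.48, so the anchor 6.50 sits two
  residues after it,
* ``NPxxY`` (TM7): the tyrosine is Y7.53, so the anchor 7.50 sits three
  residues before it.

Intracellular-loop residues (e.g. the ICL3 arginine R233 of the D2 long/
short isoforms) carry no BW label and are addressed as (chain, residue_id)
through the config's ``special`` table.
"""

from __future__ import annotations

import dataclasses
import re
from pathlib import Path
from typing import Iterable

import yaml

from .errors import MappingError

#: motif regex -> (helix, offset of the x.50 anchor from the match start)
_MOTIFS = {
    "DRY": ("DRY", 3, 1),        # R (index 1 in match) is 3.50
    "CWxP": ("CW.P", 6, 3),      # W is 6.48 => anchor = W_pos + 2 = start + 3
    "NPxxY": ("NP..Y", 7, 1),    # Y is 7.53 => anchor = Y_pos - 3 = start + 1
}


@dataclasses.dataclass(frozen=True)
class BWAnchor:
    """The x.50 residue of one helix."""

    helix: int
    chain_id: str
    residue_id: int
    motif: str | None = None       # provenance when autodetected
    support: int = 0               # co-occurring motif count (ranking key)


def parse_label(label: str) -> tuple[int, int]:
    m = re.fullmatch(r"([1-7])\.(\d{1,2})", str(label).strip())
    if not m:
        raise MappingError(f"not a BW label: {label!r} (expected h.p, 1<=h<=7)")
    return int(m.group(1)), int(m.group(2))


class ResidueMap:
    """Bidirectional BW-label <-> (chain, residue_id) mapping.

    Parameters
    ----------
    anchors
        Mapping helix -> BWAnchor (or (chain, residue_id) pair) for the
        x.50 residue of each helix present.
    spans
        Optional helix -> (first_id, last_id) residue-id spans used to
        validate resolution; defaults to anchor +/- 25.
    receptor_chain, galpha_chain
        Chain assignments used by the battery.
    special
        Named residues outside the helical bundle, e.g.
        ``{"R233": ("A", 233), "alpha5": [("B", 351), ...]}``.
    """

    DEFAULT_HALF_SPAN = 25

    def __init__(self, anchors: dict[int, BWAnchor | tuple[str, int]],
                 spans: dict[int, tuple[int, int]] | None = None,
                 receptor_chain: str = "A", galpha_chain: str | None = None,
                 special: dict | None = None):
        self.anchors: dict[int, BWAnchor] = {}
        for h, a in anchors.items():
            h = int(h)
            if not isinstance(a, BWAnchor):
                a = BWAnchor(h, str(a[0]), int(a[1]))
            if a.helix != h:
                raise MappingError(f"anchor helix {a.helix} filed under {h}")
            if h in self.anchors:
                raise MappingError(f"duplicate anchor for helix {h}")
            self.anchors[h] = a
        self.spans: dict[int, tuple[int, int]] = {}
        for h, a in self.anchors.items():
            if spans and h in spans:
                lo, hi = spans[h]
            else:
                lo = a.residue_id - self.DEFAULT_HALF_SPAN
                hi = a.residue_id + self.DEFAULT_HALF_SPAN
            if not (lo <= a.residue_id <= hi):
                raise MappingError(
                    f"helix {h} anchor {a.residue_id} outside span [{lo}, {hi}]")
            self.spans[h] = (int(lo), int(hi))
        self.receptor_chain = str(receptor_chain)
        self.galpha_chain = None if galpha_chain is None else str(galpha_chain)
        self.special = dict(special or {})

    # -- resolution -------------------------------------------------------
    def resolve(self, label: str) -> tuple[str, int]:
        """BW label -> (chain_id, residue_id); raises MappingError outside
        the helix span."""
        h, p = parse_label(label)
        if h not in self.anchors:
            raise MappingError(f"no anchor for helix {h}")
        a = self.anchors[h]
        rid = a.residue_id + (p - 50)
        lo, hi = self.spans[h]
        if not (lo <= rid <= hi):
            raise MappingError(
                f"label {label} -> residue {rid} outside helix {h} span [{lo}, {hi}]")
        return a.chain_id, rid

    def label_of(self, chain_id: str, residue_id: int) -> str:
        """(chain, residue_id) -> BW label; inverse of :meth:`resolve`."""
        for h, a in self.anchors.items():
            lo, hi = self.spans[h]
            if str(chain_id) == a.chain_id and lo <= int(residue_id) <= hi:
                return f"{h}.{50 + int(residue_id) - a.residue_id}"
        raise MappingError(f"residue {chain_id}/{residue_id} not in any helix span")

    def helix_residues(self, helix: int, first_pos: int,
                       last_pos: int) -> list[tuple[str, int]]:
        """All (chain, residue_id) for BW positions first_pos..last_pos of a
        helix, clipped to the helix span."""
        if helix not in self.anchors:
            raise MappingError(f"no anchor for helix {helix}")
        a = self.anchors[helix]
        lo, hi = self.spans[helix]
        out = []
        for p in range(first_pos, last_pos + 1):
            rid = a.residue_id + (p - 50)
            if lo <= rid <= hi:
                out.append((a.chain_id, rid))
        return out

    def special_residue(self, name: str) -> tuple[str, int]:
        try:
            c, r = self.special[name]
        except KeyError:
            raise MappingError(f"no special residue named {name!r}") from None
        return str(c), int(r)

    # -- config I/O -------------------------------------------------------
    @classmethod
    def from_config(cls, path: str | Path) -> "ResidueMap":
        """Load a mapping from a YAML config file.

        Expected keys: ``receptor_chain``, optional ``galpha_chain``,
        ``anchors`` (helix -> residue_id, on the receptor chain unless a
        [chain, id] pair is given), optional ``spans`` (helix -> [lo, hi]),
        optional ``special`` (name -> [chain, id] or list thereof).
        """
        with open(path) as fh:
            cfg = yaml.safe_load(fh) or {}
        return cls.from_dict(cfg)

    @classmethod
    def from_dict(cls, cfg: dict) -> "ResidueMap":
        chain = str(cfg.get("receptor_chain", "A"))
        anchors = {}
        for h, v in (cfg.get("anchors") or {}).items():
            if isinstance(v, (list, tuple)):
                anchors[int(h)] = (str(v[0]), int(v[1]))
            else:
                anchors[int(h)] = (chain, int(v))
        spans = {int(h): (int(v[0]), int(v[1]))
                 for h, v in (cfg.get("spans") or {}).items()}
        special = {}
        for name, v in (cfg.get("special") or {}).items():
            if v and isinstance(v[0], (list, tuple)):
                special[name] = [(str(c), int(r)) for c, r in v]
            else:
                special[name] = (str(v[0]), int(v[1]))
        return cls(anchors, spans or None, receptor_chain=chain,
                   galpha_chain=cfg.get("galpha_chain"), special=special)

    def to_dict(self) -> dict:
        d: dict = {"receptor_chain": self.receptor_chain}
        if self.galpha_chain is not None:
            d["galpha_chain"] = self.galpha_chain
        d["anchors"] = {h: [a.chain_id, a.residue_id]
                        for h, a in sorted(self.anchors.items())}
        d["spans"] = {h: list(s) for h, s in sorted(self.spans.items())}
        if self.special:
            d["special"] = {
                k: ([list(t) for t in v] if isinstance(v, list) else list(v))
                for k, v in self.special.items()}
        return d

    def to_config(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)


def detect_motifs(sequence: str, residue_ids: Iterable[int] | None = None,
                  chain_id: str = "A") -> list[BWAnchor]:
    """Propose x.50 anchors from conserved class-A motifs in a one-letter
    sequence.

    Returns candidate anchors ranked by the number of co-occurring motifs
    found in the same sequence (all three present ranks highest).  An empty
    list — no motif found — is a valid result, not an error.  Candidates
    must be confirmed by the user; explicit config anchors take precedence.
    """
    seq = str(sequence).upper()
    if residue_ids is None:
        ids = list(range(1, len(seq) + 1))
    else:
        ids = [int(r) for r in residue_ids]
        if len(ids) != len(seq):
            raise MappingError("residue_ids length != sequence length")
    found: list[tuple[int, str, int]] = []  # (helix, motif name, anchor seq index)
    for name, (pattern, helix, anchor_offset) in _MOTIFS.items():
        for m in re.finditer(pattern, seq):
            found.append((helix, name, m.start() + anchor_offset))
    n_motifs_present = len({name for _, name, _ in found})
    anchors = [
        BWAnchor(helix=h, chain_id=chain_id, residue_id=ids[idx],
                 motif=name, support=n_motifs_present)
        for h, name, idx in found
        if idx < len(ids)
    ]
    anchors.sort(key=lambda a: (-a.support, a.helix, a.residue_id))
    return anchors
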