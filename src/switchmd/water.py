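"""Internal water-channel continuity and hydrophobic-barrier hydration.

Activation of a class-A GPCR opens a continuous internal water pathway
from the orthosteric pocket down past the NPxxY motif; in the inactive
state a hydrophobic barrier (L2.42, I2.43, L3.43, I3.46, M6.36 in the
dopamine D2 receptor) blocks it.  The channel is modelled on water
oxygens only: waters inside a cylinder around the 3.32->7.53 axis form a
graph with edges at hydrogen-bonding heavy-atom distance, and the channel
is open when that graph connects the top of the pocket to the bottom gate.

The numeric criteria (cylinder radius 8 A, O-O link cutoff 3.5 A,
endpoint attach cutoff 4 A) are this package's own operational definition
of calls that are usually made by visual inspection; they are exposed on
:class:`ChannelSpec` and recorded in output metadata.
"""

from __future__ import annotations

import dataclasses

import networkx as nx
import numpy as np
from scipy.spatial.distance import cdist

from .errors import MappingError
from .io import Frame, Trajectory
from .numbering import ResidueMap

BARRIER_LABELS = ("2.42", "2.43", "3.43", "3.46", "6.36")


@dataclasses.dataclass(frozen=True)
class ChannelSpec:
    """Geometric definition of the internal water channel."""

    top_ref: str = "3.32"          # orthosteric-site locus
    bottom_ref: str = "7.53"       # NPxxY gate
    cylinder_radius: float = 8.0   # A, lateral extent around the axis
    link_cutoff: float = 3.5       # A, O-O hydrogen-bond distance
    attach_cutoff: float = 4.0     # A, water-to-endpoint-CA attachment
    axial_margin: float = 3.0      # A, tolerance beyond the axis endpoints
    barrier_labels: tuple[str, ...] = BARRIER_LABELS
    barrier_cutoff: float = 4.0    # A, water-to-barrier-heavy-atom

    def __post_init__(self):
        for name in ("cylinder_radius", "link_cutoff", "attach_cutoff",
                     "barrier_cutoff"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


def _axis_endpoints(frame: Frame, rmap: ResidueMap, spec: ChannelSpec
                    ) -> tuple[np.ndarray, np.ndarray]:
    traj = frame.trajectory
    pts = []
    for label in (spec.top_ref, spec.bottom_ref):
        chain, rid = rmap.resolve(label)
        if not traj.has_atom(chain, rid, "CA"):
            raise MappingError(f"channel reference {label} lacks CA")
        pts.append(frame.coords[traj.atom_index(chain, rid, "CA")])
    return pts[0], pts[1]


def select_channel_waters(frame: Frame, rmap: ResidueMap,
                          spec: ChannelSpec = ChannelSpec()) -> np.ndarray:
    """Indices of water oxygens inside the channel cylinder: within
    ``cylinder_radius`` of the top->bottom axis segment and axially between
    the endpoints (with a small margin).  No waters -> empty selection."""
    traj = frame.trajectory
    widx = traj.water_oxygen_indices()
    if len(widx) == 0:
        return widx
    top, bottom = _axis_endpoints(frame, rmap, spec)
    axis = bottom - top
    length = float(np.linalg.norm(axis))
    u = axis / length
    rel = frame.coords[widx] - top
    s = rel @ u                                  # axial coordinate
    radial = np.linalg.norm(rel - np.outer(s, u), axis=1)
    keep = ((s >= -spec.axial_margin) & (s <= length + spec.axial_margin)
            & (radial <= spec.cylinder_radius))
    return widx[keep]


def channel_continuity(frame: Frame, rmap: ResidueMap,
                       spec: ChannelSpec = ChannelSpec()
                       ) -> tuple[bool, int | None]:
    """Is there a continuous water wire from the pocket to the gate?

    Builds a graph on the channel waters (edges: O-O <= link cutoff) and
    asks for a path from any water attached to the top reference to any
    water attached to the bottom reference.  Returns (open, number of
    waters on the shortest such wire; None when closed).
    """
    traj = frame.trajectory
    widx = select_channel_waters(frame, rmap, spec)
    if len(widx) == 0:
        return False, None
    top, bottom = _axis_endpoints(frame, rmap, spec)
    pos = frame.coords[widx]
    sources = np.nonzero(np.linalg.norm(pos - top, axis=1)
                         <= spec.attach_cutoff)[0]
    sinks = np.nonzero(np.linalg.norm(pos - bottom, axis=1)
                       <= spec.attach_cutoff)[0]
    if len(sources) == 0 or len(sinks) == 0:
        return False, None
    g = nx.Graph()
    g.add_nodes_from(range(len(widx)))
    d = cdist(pos, pos)
    ii, jj = np.nonzero(np.triu(d <= spec.link_cutoff, k=1))
    g.add_edges_from(zip(ii.tolist(), jj.tolist()))
    # virtual terminals collapse the many-source/many-sink search
    g.add_edges_from(("top", int(s)) for s in sources)
    g.add_edges_from(("bottom", int(s)) for s in sinks)
    if not nx.has_path(g, "top", "bottom"):
        return False, None
    path = nx.shortest_path(g, "top", "bottom")
    return True, len(path) - 2  # exclude the two virtual terminals


def barrier_occupancy(frame: Frame, rmap: ResidueMap,
                      spec: ChannelSpec = ChannelSpec()
                      ) -> tuple[int, dict[str, int]]:
    """Number of water oxygens hydrating the hydrophobic barrier: within
    ``barrier_cutoff`` of any heavy atom of the five barrier residues.
    Also returns per-residue counts (a water near two residues counts for
    both, but once in the total)."""
    traj = frame.trajectory
    widx = traj.water_oxygen_indices()
    per = {label: 0 for label in spec.barrier_labels}
    if len(widx) == 0:
        return 0, per
    wpos = frame.coords[widx]
    near_any = np.zeros(len(widx), dtype=bool)
    for label in spec.barrier_labels:
        chain, rid = rmap.resolve(label)
        idx = traj.residue_indices(chain, rid, heavy_only=True)
        if len(idx) == 0:
            raise MappingError(f"barrier residue {label} has no heavy atoms")
        near = cdist(wpos, frame.coords[idx]).min(axis=1) <= spec.barrier_cutoff
        per[label] = int(near.sum())
        near_any |= near
    return int(near_any.sum()), per


def open_fraction(traj: Trajectory, rmap: ResidueMap,
                  spec: ChannelSpec = ChannelSpec()) -> float:
    """Fraction of frames with a continuous water channel, in [0, 1]."""
    flags = [channel_continuity(traj.frame(i), rmap, spec)[0]
             for i in range(traj.n_frames)]
    return float(np.mean(flags))


def open_series(traj: Trajectory, rmap: ResidueMap,
                spec: ChannelSpec = ChannelSpec()) -> np.ndarray:
    return np.array([channel_continuity(traj.frame(i), rmap, spec)[0]
                     for i in range(traj.n_frames)], dtype=bool)
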