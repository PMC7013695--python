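"""Shared fixtures: all test structures are generated programmatically."""

import numpy as np
import pytest

import switchmd as sm


@pytest.fixture(scope="session")
def noiseless():
    """Small noiseless trajectory with every planted feature active."""
    spec = sm.SyntheticSpec(
        n_frames=50, dt=1.0, seed=11, drift_slope=-0.003, noise_sigma=0.0,
        tm6_bend=30.0, channel_state="open", lock_distance=12.0,
        rotamer_rates={"6.48": (0.15, (-60.0, 180.0))},
    )
    return sm.generate_trajectory(spec)


@pytest.fixture(scope="session")
def inactive_reference(tmp_path_factory):
    """Synthetic stand-in for an inactive-state receptor crystal structure.

    A single-frame bundle constructed to carry the two inactive-state
    hallmark values reported for the dopamine D2 receptor crystal
    structure: Y5.58-Y7.53 C-alpha distance 19.4 A and an R3.50-E6.30
    charged-group minimum of 3.0 A.  This is a constructed reference, not
    deposited coordinates; it validates that the measurement pipeline
    recovers the planted values from a PDB file on disk.
    """
    spec = sm.SyntheticSpec(n_frames=1, noise_sigma=0.0, lock_distance=3.0,
                            tm5_tm7=19.4, seed=0)
    traj, rmap, _ = sm.generate_trajectory(spec)
    path = tmp_path_factory.mktemp("ref") / "synthetic_inactive_reference.pdb"
    sm.write_trajectory(traj, path)
    return path, rmap


def make_trajectory(coords, times=None, res_ids=None, atom_names=None,
                    res_names=None, chains=None):
    """Tiny ad-hoc trajectory from a coordinate array (frames, atoms, 3)."""
    coords = np.asarray(coords, dtype=float)
    if coords.ndim == 2:
        coords = coords[None]
    n = coords.shape[1]
    return sm.Trajectory(
        coords,
        atom_names=atom_names or ["CA"] * n,
        residue_names=res_names or ["ALA"] * n,
        residue_ids=res_ids if res_ids is not None else list(range(1, n + 1)),
        chain_ids=chains or ["A"] * n,
        times=times,
    )
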