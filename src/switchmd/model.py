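"""The activation-hallmark battery as a fitted model.

:class:`ActivationModel` is built from a trajectory plus its residue map
and analysis configuration; :meth:`ActivationModel.fit` runs every enabled
hallmark metric and returns an :class:`ActivationResults` carrying the
estimates (coupling-trend slope with its OLS standard error, lock and
Y5.58-Y7.53 distance series, TM6 kink series, chi1 switch series, water-
channel open fraction, interface distances, PCA), a ``summary()`` table,
and per-metric error slots: one failing metric never aborts the run.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np
import pandas as pd

from . import geometry, pca, switches, water
from .errors import MappingError, SwitchMDError
from .geometry import DistanceSeries, Selection
from .io import Trajectory, write_report
from .numbering import ResidueMap


@dataclasses.dataclass
class AnalysisConfig:
    """Knobs of the battery; defaults are the package's operational
    definitions of calls the literature makes qualitatively."""

    switch_labels: Sequence[str] = switches.DEFAULT_SWITCH_LABELS
    coupling_receptor_labels: Sequence[str] = switches.COUPLING_RECEPTOR_LABELS
    alpha5_residues: Sequence[tuple[str, int]] | None = None  # from map if None
    trend_threshold: float = 0.0005     # A/ns; 0.5 A drift over 1 us
    trend_window: slice | None = None   # default: all frames
    kink_threshold: float = 15.0        # deg; "bent" above this
    channel: water.ChannelSpec | None = water.ChannelSpec()
    interface_pairs: Sequence[tuple[tuple[str, int], tuple[str, int]]] = ()
    interface_window: slice | None = None
    run_switches: bool = True
    run_channel: bool = True
    run_coupling: bool = True
    run_pca: bool = True
    pca_analysis_helix: int = 6         # TM6 motion, per the standard battery
    pca_span: tuple[int, int] = (30, 60)
    pca_window: slice | None = None


@dataclasses.dataclass
class ActivationResults:
    """Everything the battery measured on one trajectory."""

    n_frames: int
    times: np.ndarray
    config: AnalysisConfig
    coupling_series: DistanceSeries | None = None
    coupling: switches.CouplingTrend | None = None
    ionic_lock: DistanceSeries | None = None
    tm5_tm7: DistanceSeries | None = None
    kink: np.ndarray | None = None
    switches: dict[str, switches.SwitchSeries] = dataclasses.field(default_factory=dict)
    channel_open_fraction: float | None = None
    channel_open: np.ndarray | None = None
    interface_distances: dict = dataclasses.field(default_factory=dict)
    pca: pca.PCAResult | None = None
    covariance: pca.CovarianceResult | None = None
    errors: dict[str, str] = dataclasses.field(default_factory=dict)
    label: str = ""

    # -- classifications --------------------------------------------------
    @property
    def coupling_class(self) -> str | None:
        return None if self.coupling is None else self.coupling.classification

    @property
    def kink_class(self) -> str | None:
        if self.kink is None:
            return None
        return ("bent" if float(np.mean(self.kink)) >= self.config.kink_threshold
                else "straight")

    # -- presentation -----------------------------------------------------
    def summary(self) -> str:
        rows = []
        if self.coupling is not None:
            c = self.coupling
            rows.append(("coupling slope (A/ns)",
                         f"{c.slope:+.6f} +/- {c.stderr:.6f}",
                         c.classification))
        if self.ionic_lock is not None:
            rows.append(("ionic lock R3.50-E6.30 (A)",
                         f"{self.ionic_lock.values.mean():.2f} "
                         f"+/- {self.ionic_lock.values.std():.2f}", ""))
        if self.tm5_tm7 is not None:
            rows.append(("Y5.58-Y7.53 CA (A)",
                         f"{self.tm5_tm7.values.mean():.2f} "
                         f"+/- {self.tm5_tm7.values.std():.2f}", ""))
        if self.kink is not None:
            rows.append(("TM6 kink (deg)",
                         f"{float(np.mean(self.kink)):.1f}", self.kink_class))
        for label, s in self.switches.items():
            vals, counts = np.unique(s.state, return_counts=True)
            dominant = str(vals[np.argmax(counts)])
            circ = np.degrees(np.angle(np.exp(1j * np.radians(s.chi1)).mean()))
            rows.append((f"chi1({label}) (deg)", f"{circ:+.1f}", dominant))
        if self.channel_open_fraction is not None:
            rows.append(("water channel open fraction",
                         f"{self.channel_open_fraction:.3f}", ""))
        for pair, (mean, sd) in self.interface_distances.items():
            a, b = pair
            rows.append((f"interface {a[0]}/{a[1]} - {b[0]}/{b[1]} (A)",
                         f"{mean:.2f} +/- {sd:.2f}", ""))
        if self.pca is not None and self.pca.eigenvalues.sum() > 0:
            vf = self.pca.variance_fractions
            rows.append(("PCA PC1/PC2 variance fraction",
                         f"{vf[0]:.3f} / {vf[1]:.3f}" if len(vf) > 1
                         else f"{vf[0]:.3f}", ""))
        for metric, msg in self.errors.items():
            rows.append((metric, "ERROR", msg))
        head = f"Activation battery {self.label or ''} ({self.n_frames} frames)"
        width = max(len(r[0]) for r in rows) if rows else 10
        lines = [head, "=" * len(head)]
        lines += [f"{name:<{width}}  {value:>24}  {note}"
                  for name, value, note in rows]
        return "\n".join(lines)

    def tables(self) -> dict[str, pd.DataFrame]:
        """One DataFrame per metric family (for :func:`switchmd.io.write_report`)."""
        out: dict[str, pd.DataFrame] = {}
        dist = {"frame": np.arange(self.n_frames), "time_ns": self.times}
        if self.coupling_series is not None:
            dist["receptor_alpha5"] = self.coupling_series.values
        if self.ionic_lock is not None:
            dist["ionic_lock"] = self.ionic_lock.values
        if self.tm5_tm7 is not None:
            dist["tm5_tm7"] = self.tm5_tm7.values
        if self.kink is not None:
            dist["tm6_kink_deg"] = self.kink
        out["distances"] = pd.DataFrame(dist)
        sw = {"frame": np.arange(self.n_frames), "time_ns": self.times}
        for label, s in self.switches.items():
            sw[f"chi1_{label}"] = s.chi1
            sw[f"state_{label}"] = s.state
        out["switches"] = pd.DataFrame(sw)
        ch = {"frame": np.arange(self.n_frames), "time_ns": self.times}
        if self.channel_open is not None:
            ch["channel_open"] = self.channel_open.astype(int)
        out["channel"] = pd.DataFrame(ch)
        if self.pca is not None:
            out["pca"] = pd.DataFrame({
                "time_ns": self.pca.times,
                "PC1": self.pca.projections[:, 0],
                "PC2": (self.pca.projections[:, 1]
                        if self.pca.projections.shape[1] > 1
                        else np.zeros(len(self.pca.times))),
            })
        if self.interface_distances:
            out["interface"] = pd.DataFrame([
                {"residue_a": f"{a[0]}/{a[1]}", "residue_b": f"{b[0]}/{b[1]}",
                 "mean_A": m, "sd_A": s}
                for (a, b), (m, s) in self.interface_distances.items()])
        if self.coupling is not None:
            out["trend"] = pd.DataFrame([{
                "slope_A_per_ns": self.coupling.slope,
                "stderr": self.coupling.stderr,
                "intercept_A": self.coupling.intercept,
                "threshold_A_per_ns": self.coupling.threshold,
                "classification": self.coupling.classification,
            }])
        return out

    def write(self, out_dir, metadata=None):
        return write_report(self, out_dir, metadata=metadata)


class ActivationModel:
    """Hallmark battery bound to one trajectory.

    Parameters
    ----------
    trajectory
        The :class:`~switchmd.io.Trajectory` to analyse.
    residue_map
        Ballesteros-Weinstein mapping resolving every battery label.
    config
        :class:`AnalysisConfig`; defaults analyse everything.
    """

    def __init__(self, trajectory: Trajectory, residue_map: ResidueMap,
                 config: AnalysisConfig | None = None, label: str = ""):
        self.trajectory = trajectory
        self.residue_map = residue_map
        self.config = config or AnalysisConfig()
        self.label = label

    @classmethod
    def from_files(cls, traj_path, map_path, config=None, label="") -> "ActivationModel":
        from .io import read_structure
        traj = read_structure(traj_path)
        rmap = ResidueMap.from_config(map_path)
        return cls(traj, rmap, config, label or str(traj_path))

    def _alpha5_residues(self) -> list[tuple[str, int]]:
        if self.config.alpha5_residues:
            return list(self.config.alpha5_residues)
        res = self.residue_map.special.get("alpha5")
        if not res:
            raise MappingError("no alpha5 residues in config or residue map")
        return [(str(c), int(r)) for c, r in res]

    def fit(self) -> ActivationResults:
        """Run every enabled metric; failures are recorded per metric."""
        traj, rmap, cfg = self.trajectory, self.residue_map, self.config
        res = ActivationResults(n_frames=traj.n_frames, times=traj.times,
                                config=cfg, label=self.label)

        def attempt(name, fn):
            try:
                fn()
            except SwitchMDError as exc:
                res.errors[name] = str(exc)

        if cfg.run_coupling:
            def _coupling():
                series = switches.coupling_distance_series(
                    traj, rmap, self._alpha5_residues())
                res.coupling_series = series
                res.coupling = switches.coupling_trend(
                    series, cfg.trend_threshold, cfg.trend_window)
            attempt("coupling", _coupling)

        attempt("ionic_lock",
                lambda: setattr(res, "ionic_lock",
                                switches.ionic_lock_series(traj, rmap)))
        attempt("tm5_tm7",
                lambda: setattr(res, "tm5_tm7",
                                switches.tm5_tm7_series(traj, rmap)))
        attempt("kink",
                lambda: setattr(res, "kink",
                                geometry.tm6_kink_series(traj, rmap)))

        if cfg.run_switches:
            attempt("switches",
                    lambda: setattr(res, "switches",
                                    switches.switch_timeseries(
                                        traj, rmap, cfg.switch_labels)))

        if cfg.run_channel and cfg.channel is not None:
            def _channel():
                flags = water.open_series(traj, rmap, cfg.channel)
                res.channel_open = flags
                res.channel_open_fraction = float(flags.mean())
            attempt("channel", _channel)

        if cfg.interface_pairs:
            attempt("interface",
                    lambda: setattr(res, "interface_distances",
                                    switches.interface_residue_distances(
                                        traj, cfg.interface_pairs,
                                        cfg.interface_window)))

        if cfg.run_pca:
            def _pca():
                h, (lo, hi) = cfg.pca_analysis_helix, cfg.pca_span
                analysis = Selection.ca_of(
                    traj, rmap.helix_residues(h, lo, hi), f"TM{h}")
                fit_res = []
                for helix in sorted(rmap.anchors):
                    fit_res += rmap.helix_residues(helix, 30, 60)
                fit_sel = Selection.ca_of(
                    traj,
                    [r for r in fit_res if traj.has_atom(*r, "CA")],
                    "receptor-CA")
                cov = pca.build_covariance(traj, fit_sel, analysis)
                res.covariance = cov
                res.pca = pca.pca_project(cov, traj, cfg.pca_window,
                                          n_components=min(10, cov.matrix.shape[0]))
            attempt("pca", _pca)

        return res


def build_activation_report(traj: Trajectory, rmap: ResidueMap,
                            config: AnalysisConfig | None = None,
                            label: str = "") -> ActivationResults:
    """Functional entry point: fit the battery and return the results."""
    return ActivationModel(traj, rmap, config, label).fit()
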