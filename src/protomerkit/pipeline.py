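"""Pipeline orchestration: config, logging, and the full analysis run.

A run executes the standard post-simulation order — geometric stability
metrics, interaction persistence, conformational clustering, then the
medoid-based single-point analyses (residue energy decomposition, alanine
scan) and, when monomer runs are available, the dimer formation energy.
Stages fail independently: an exception in one stage is recorded in the
bundle without aborting the others.  Every bundle embeds the fully
resolved configuration (including applied defaults) and package version.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import __version__ as _pkg_version
from . import plotting
from .clustering import gromos_cluster, rmsd_matrix
from .core import Trajectory, select
from .energetics import decompose_interface_energy, dimer_formation_energy
from .interactions import (
    ALL_TYPES,
    InteractionCriteria,
    interaction_count_series,
    persistence_profile,
)
from .io_structures import read_topology, read_trajectory, write_report, write_structure
from .mutagenesis import alanine_scan
from .structure_metrics import rmsd_series, rmsf, sse_series
from .synthetic_data import PlantedContact, PlantedSpec, make_toy_dimer, make_trajectory

logger = logging.getLogger("protomerkit")

__all__ = ["RunConfig", "run_pipeline"]


@dataclass
class RunConfig:
    """Resolved configuration of one analysis run."""

    output_dir: str = "protomerkit_out"
    seed: int = 0
    stride: int = 1
    cluster_cutoff: float = 2.0
    energy_cutoff: float = 12.0
    persistence_threshold: float = 0.30
    window: str = "second-half"  # energy averaging window
    interaction_types: list = field(default_factory=lambda: list(ALL_TYPES))
    criteria: dict = field(default_factory=dict)
    chain_a: str = "A"
    chain_b: str = "B"
    scan_residues: list | None = None
    make_plots: bool = True
    synthetic: dict | None = None
    inputs: dict | None = None

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)

    def resolved(self) -> dict:
        out = dataclasses.asdict(self)
        out["criteria_resolved"] = InteractionCriteria(**self.criteria).as_dict()
        out["package_version"] = _pkg_version
        return out


def _load_inputs(config: RunConfig):
    """Returns (dimer trajectory, monomer trajectory A or None, B or None)."""
    if config.synthetic is not None and config.inputs is not None:
        raise ValueError("config must set either 'synthetic' or 'inputs', not both")
    if config.synthetic is not None:
        s = dict(config.synthetic)
        contacts = s.pop("contacts", ["salt_bridge", "hbond"])
        occupancies = s.pop("occupancies", [1.0] * len(contacts))
        n_res_a = s.pop("n_res_a", max(4, len(contacts)))
        n_res_b = s.pop("n_res_b", max(4, len(contacts)))
        n_frames = s.pop("n_frames", 100)
        wobble = s.pop("wobble_sigma", 0.05)
        filler = s.pop("filler", "GLY")
        if s:
            raise ValueError(f"unknown synthetic keys: {sorted(s)}")
        top, xyz, planted = make_toy_dimer(n_res_a, n_res_b, contacts, filler)
        for pc, occ in zip(planted, occupancies):
            pc.occupancy = occ
        spec = PlantedSpec(contacts=planted, wobble_sigma=wobble,
                           seed=config.seed)
        traj, _ = make_trajectory(top, xyz, spec, n_frames)
        logger.info("synthetic dimer: %d atoms, %d frames, contacts %s",
                    top.n_atoms, n_frames, contacts)
        # separated-monomer runs: each chain alone, same conformations
        mono = []
        for chain in (config.chain_a, config.chain_b):
            idx = top.chain_atoms(chain)
            sub = top.subset(idx)
            mono.append(Trajectory(sub, [f[idx] for f in traj.frames]))
        return traj, mono[0], mono[1]
    if config.inputs is None:
        raise ValueError("config needs 'synthetic' or 'inputs'")
    inp = dict(config.inputs)
    top = read_topology(inp.pop("dimer_topology"),
                        inp.pop("parameter_table", None))
    traj = read_trajectory(top, inp.pop("dimer_trajectory"))
    mono_a = mono_b = None
    if "monomer_a_topology" in inp:
        ta = read_topology(inp.pop("monomer_a_topology"))
        mono_a = read_trajectory(ta, inp.pop("monomer_a_trajectory"))
    if "monomer_b_topology" in inp:
        tb = read_topology(inp.pop("monomer_b_topology"))
        mono_b = read_trajectory(tb, inp.pop("monomer_b_trajectory"))
    if inp:
        raise ValueError(f"unknown input keys: {sorted(inp)}")
    return traj, mono_a, mono_b


def run_pipeline(config: RunConfig) -> dict:
    """Execute all analysis stages; returns the report bundle.

    The bundle maps stage name -> result summary (and "error" on failure);
    numeric tables and plots are written under ``config.output_dir``.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    bundle: dict = {"config": config.resolved()}
    logger.info("resolved config: %s", bundle["config"])

    traj, mono_a, mono_b = _load_inputs(config)
    if config.stride > 1:
        traj = traj.sliced(range(0, traj.n_frames, config.stride))
    top = traj.topology
    criteria = InteractionCriteria(**config.criteria)
    group_a = top.chain_atoms(config.chain_a, include_solvent=False)
    group_b = top.chain_atoms(config.chain_b, include_solvent=False)
    ca_sel = [i for i in range(top.n_atoms)
              if top.atoms[i].name == "CA" and not top.atoms[i].is_solvent]

    def stage(name, fn):
        try:
            bundle[name] = fn()
            logger.info("stage %s done", name)
        except Exception as exc:  # stage isolation is the contract
            logger.error("stage %s failed: %s", name, exc)
            bundle[name] = {"error": str(exc)}

    def metrics_stage():
        series = rmsd_series(traj, 0, ca_sel)
        write_report([{"frame": i, "rmsd": v} for i, v in enumerate(series)],
                     out / "rmsd.csv")
        rmsf_vals = rmsf(traj) if traj.n_frames >= 2 else {}
        if rmsf_vals:
            write_report([{"chain": c, "residue": n, "rmsf": v}
                          for (c, n), v in sorted(rmsf_vals.items())],
                         out / "rmsf.csv")
        sse = sse_series(traj)
        write_report([{"frame": i, "helix_pct": h, "strand_pct": s}
                      for i, (h, s) in enumerate(zip(sse.helix_fraction,
                                                     sse.strand_fraction))],
                     out / "sse.csv")
        if config.make_plots:
            plotting.series_plot(series, out / "rmsd.png", "RMSD (A)")
            if rmsf_vals:
                plotting.rmsf_plot(rmsf_vals, out / "rmsf.png")
            plotting.sse_plot(sse.helix_fraction, sse.strand_fraction,
                              out / "sse.png")
        return {"rmsd_mean": float(np.mean(series)),
                "rmsd_final": float(series[-1]),
                "helix_pct_mean": float(np.mean(sse.helix_fraction))}

    def interactions_stage():
        profile = persistence_profile(traj, group_a, group_b,
                                      config.interaction_types, criteria)
        write_report(profile.to_records(), out / "persistence.csv")
        persistent = profile.filtered(config.persistence_threshold)
        counts = {}
        for t in config.interaction_types:
            _, mean, sd = interaction_count_series(traj, group_a, group_b, t,
                                                   criteria)
            counts[t] = {"mean": mean, "sd": sd}
        write_report([{"type": t, **v} for t, v in counts.items()],
                     out / "interaction_counts.csv")
        if config.make_plots:
            plotting.persistence_heatmap(profile, out / "persistence.png")
        return {"n_pairs": len(profile.entries),
                "n_persistent": len(persistent),
                "counts": counts}

    def clustering_stage():
        dm = rmsd_matrix(traj, ca_sel)
        result = gromos_cluster(dm, config.cluster_cutoff)
        write_report([{"frame": i, "cluster": int(c)}
                      for i, c in enumerate(result.labels)],
                     out / "clusters.csv")
        medoid = result.medoids[0]
        write_structure(top, traj.frames[medoid], out / "medoid.pdb")
        bundle["_medoid_frame"] = medoid
        return {"n_clusters": result.n_clusters, "sizes": result.sizes,
                "medoids": result.medoids}

    def decomposition_stage():
        medoid = bundle.get("_medoid_frame", 0)
        dec = decompose_interface_energy(traj.frames[medoid], top,
                                         config.chain_a, config.chain_b,
                                         config.energy_cutoff)
        write_report(dec.to_records(), out / "decomposition.csv")
        return {"E_inter_total": dec.total, "medoid_frame": medoid}

    def formation_stage():
        if mono_a is None or mono_b is None:
            return {"skipped": "no monomer trajectories supplied"}
        window = None
        if config.window == "full":
            window = {"dimer": list(range(traj.n_frames)),
                      "monomer_a": list(range(mono_a.n_frames)),
                      "monomer_b": list(range(mono_b.n_frames))}
        dfe = dimer_formation_energy(traj, mono_a, mono_b, window,
                                     config.energy_cutoff)
        with open(out / "formation_energy.json", "w") as fh:
            json.dump(dfe.to_dict(), fh, indent=1)
        if config.make_plots:
            plotting.energy_term_bars(dfe.term_means, dfe.term_sds,
                                      out / "energy_terms.png")
        return dfe.to_dict()

    def scan_stage():
        medoid = bundle.get("_medoid_frame", 0)
        residues = config.scan_residues
        if residues is not None:
            residues = [tuple(r) for r in residues]
        entries = alanine_scan(traj.frames[medoid], top, config.chain_a,
                               config.chain_b,
                               cutoff=config.energy_cutoff,
                               link_polymer=config.inputs is not None,
                               residues=residues)
        write_report([dataclasses.asdict(e) for e in entries],
                     out / "ala_scan.csv")
        return {"n_entries": len(entries),
                "n_skipped": sum(e.skipped for e in entries)}

    stage("metrics", metrics_stage)
    stage("interactions", interactions_stage)
    stage("clustering", clustering_stage)
    stage("decomposition", decomposition_stage)
    stage("formation_energy", formation_stage)
    stage("alanine_scan", scan_stage)
    bundle.pop("_medoid_frame", None)

    with open(out / "provenance.json", "w") as fh:
        json.dump(bundle, fh, indent=1, default=str)
    return bundle
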