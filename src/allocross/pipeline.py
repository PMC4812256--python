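"""Workflow orchestration: per-system analyses and meta-trajectory clustering.

``run_system`` executes the geometry / interactions / fluctuations stages
on the tail windows of one ligand state's runs; ``run_meta`` concatenates
the tails of *all* runs into a meta-trajectory, clusters configured residue
subsets with the gromos method and decomposes cluster populations by
ligand-state label.  Both return plain nested dicts ("reports") that are
serialised as canonical JSON — every number in a report is recomputable
from the manifest, the configuration and the seed, and a rerun with the
same inputs is byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import os
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import yaml

from . import __version__
from .core import Frame, Selection, Topology, Trajectory, build_meta, select
from .clustering import decompose_by_label, gromos_cluster, representative, rmsd_matrix
from .fluctuations import coordination_score, distance_fluctuation_map
from .geometry import (
    circular_mean,
    com_cloud,
    dihedral,
    distance_from_start,
    pair_distance_distribution,
    rmsd_series,
)
from .interactions import (
    contact_series,
    hbond_series,
    interface_map,
    persistence_filter,
    strand_content,
)
from .io import RunSet, write_pdb

__all__ = ["AnalysisConfig", "run_system", "run_meta", "run_all", "report_json"]


@dataclass
class AnalysisConfig:
    """All tunable analysis parameters, collected in one place.

    Residue intervals are 1-based inclusive.  Defaults follow DnaK
    numbering (anchor domain 1–380, mobile domain 393–603, linker
    383–396); for other topologies set the intervals explicitly.
    """

    fit_range: tuple[int, int] = (1, 380)  # anchor (NBD) Cα fit
    com_range: tuple[int, int] = (393, 603)  # mobile (SBD) COM selection
    linker_range: tuple[int, int] = (383, 396)
    subsets: dict[str, tuple[tuple[int, int], float]] = field(
        default_factory=lambda: {
            "linker-nbd": ((373, 393), 0.35),
            "linker-bsbd": ((393, 433), 0.35),
            "bsbd": ((393, 503), 0.15),
        }
    )
    df_range: tuple[int, int] | None = None  # None → all residues
    df_statistic: str = "variance"
    lobe_blocks: tuple[tuple[int, int], tuple[int, int]] | None = None
    hinge_dihedrals: tuple[tuple[int, str], ...] = ()  # (resid, "phi"|"psi")
    contact_cutoff: float = 0.45  # nm
    hbond_distance: float = 0.35  # nm
    hbond_angle: float = 30.0  # deg
    interface_threshold: float = 6.0  # Å
    persistence: float = 0.30
    tail_ns: float = 90.0
    bin_width: float = 1.0  # Å
    top_k: int = 3
    strand: bool = False  # needs backbone atoms
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AnalysisConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        kwargs = {}
        for key, value in raw.items():
            if key == "subsets":
                kwargs[key] = {
                    name: (tuple(v["residues"]), float(v["cutoff"]))
                    for name, v in value.items()
                }
            elif key == "hinge_dihedrals":
                kwargs[key] = tuple((int(d["residue"]), d["kind"]) for d in value)
            elif isinstance(value, list):
                kwargs[key] = tuple(value)
            else:
                kwargs[key] = value
        return cls(**kwargs)

    def digest(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=list)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _tail(runs: Sequence[Trajectory], tail_ns: float) -> list[Trajectory]:
    meta = build_meta(list(runs), tail_ns)
    return [traj.slice(window) for traj, window in meta.segments]


def _residues(interval: tuple[int, int]) -> list[int]:
    return list(range(interval[0], interval[1] + 1))


def _backbone_dihedral_atoms(
    top: Topology, resid: int, kind: str
) -> tuple[int, int, int, int] | None:
    def atom(r: int, name: str) -> int | None:
        for i in top.residue_atoms(r):
            if top.atoms[i].name == name:
                return i
        return None

    span = top.residue_span
    if kind == "psi":
        if resid + 1 > span[1]:
            return None
        quad = (atom(resid, "N"), atom(resid, "CA"), atom(resid, "C"), atom(resid + 1, "N"))
    elif kind == "phi":
        if resid - 1 < span[0]:
            return None
        quad = (atom(resid - 1, "C"), atom(resid, "N"), atom(resid, "CA"), atom(resid, "C"))
    else:
        raise ValueError("dihedral kind must be 'phi' or 'psi'")
    return None if any(a is None for a in quad) else quad  # type: ignore[return-value]


def _provenance(config: AnalysisConfig) -> dict:
    return {
        "package_version": __version__,
        "config_hash": config.digest(),
        "seed": config.seed,
    }


def run_system(
    reference: tuple[Topology, Frame],
    runs: Sequence[Trajectory],
    config: AnalysisConfig,
    system_id: str = "",
) -> dict:
    """Per-ligand-state report: COM cloud summaries, persistent interactions,
    distance-fluctuation statistics, optional strand/dihedral summaries."""
    if not runs:
        raise ValueError(f"system {system_id!r}: manifest lists no runs")
    top, ref_frame = reference
    tails = _tail(runs, config.tail_ns)

    report: dict = {"system": system_id, "provenance": _provenance(config)}
    stage = "com"
    try:
        fit_sel = select(top, config.fit_range, {"CA"})
        com_sel = select(top, config.com_range, "all")
        cloud = com_cloud(tails, fit_sel, com_sel, reference)
        dstart = distance_from_start(cloud, config.bin_width)
        pairs = pair_distance_distribution(cloud, config.bin_width, seed=config.seed)
        report["com"] = {
            "n_frames": len(cloud),
            "distance_from_start_mean_A": round(dstart.mean, 6),
            "distance_from_start_peak_A": dstart.peak,
            "pair_distance_peak_A": pairs.peak,
        }

        stage = "fluctuations"
        df_res = (
            _residues(config.df_range) if config.df_range else top.residue_ids
        )
        dfmap = distance_fluctuation_map(
            build_meta(tails, config.tail_ns), df_res, statistic=config.df_statistic
        )
        flat = dfmap.values[np.triu_indices(len(df_res), k=1)]
        report["fluctuations"] = {
            "mean_nm2": round(float(flat.mean()), 9),
            "max_nm2": round(float(flat.max()), 9),
        }
        if config.lobe_blocks is not None:
            a, b = config.lobe_blocks
            report["fluctuations"]["interlobe_coordination_nm2"] = round(
                coordination_score(dfmap, _residues(a), _residues(b)), 9
            )

        stage = "interactions"
        meta = build_meta(tails, config.tail_ns)
        linker = _residues(config.linker_range)
        partners = [
            r
            for r in top.residue_ids
            if r not in set(linker)
        ]
        contacts = contact_series(meta, partners, linker, config.contact_cutoff)
        names = {a.name[:1] for a in top.atoms}
        if {"N", "O"} <= names:
            hbonds = hbond_series(
                meta, partners, linker, config.hbond_distance, config.hbond_angle
            )
        else:  # Cα-only model: no donors/acceptors to test
            hbonds = {}
        report["interactions"] = {
            "persistent_contacts": [
                [r.residue_a, r.residue_b, round(r.occupancy, 6)]
                for r in persistence_filter(contacts, config.persistence, "contact")
            ],
            "persistent_hbonds": [
                [r.residue_a, r.residue_b, round(r.occupancy, 6)]
                for r in persistence_filter(hbonds, config.persistence, "hbond")
            ],
        }
        iface = interface_map(
            meta,
            _residues(config.fit_range),
            _residues(config.com_range),
            config.interface_threshold,
        )
        report["interface"] = {
            "anchor_side": iface.side_a,
            "mobile_side": iface.side_b,
        }

        if config.strand:
            stage = "strand"
            sc = strand_content(meta, config.linker_range)
            report["strand_content"] = round(sc.content, 6)

        if config.hinge_dihedrals:
            stage = "dihedrals"
            dihedrals = {}
            for resid, kind in config.hinge_dihedrals:
                quad = _backbone_dihedral_atoms(top, resid, kind)
                if quad is None:
                    continue
                angles = np.array(
                    [
                        dihedral(*(meta.xyz[f][list(quad)]))
                        for f in range(meta.n_frames)
                    ]
                )
                mean, var = circular_mean(angles)
                dihedrals[f"{kind}_{resid}"] = {
                    "circular_mean_deg": round(mean, 6),
                    "circular_variance": round(var, 6),
                }
            report["dihedrals"] = dihedrals

        stage = "rmsd"
        if len(tails) >= 2 and tails[0].n_frames == tails[1].n_frames:
            series = rmsd_series(tails[0], tails[1], fit_sel)
            report["replica_rmsd_mean_nm"] = round(float(series.mean()), 9)
    except Exception as exc:
        raise RuntimeError(
            f"system {system_id!r}: stage {stage!r} failed: {exc}"
        ) from exc
    return report


def run_meta(
    reference: tuple[Topology, Frame],
    runs_by_system: Mapping[str, Sequence[Trajectory]],
    config: AnalysisConfig,
    outdir: str | Path | None = None,
) -> dict:
    """Meta-trajectory report: subset clustering + per-label decomposition."""
    if len(runs_by_system) < 2:
        raise ValueError("meta analysis needs at least 2 systems")
    top, _ = reference
    all_runs = [t for runs in runs_by_system.values() for t in runs]
    meta = build_meta(all_runs, config.tail_ns)
    report: dict = {"provenance": _provenance(config), "subsets": {}}
    for name, (interval, cutoff) in sorted(config.subsets.items()):
        sel = select(top, interval, {"CA"})
        matrix = rmsd_matrix(meta, sel, fit=True)
        result = gromos_cluster(matrix, cutoff)
        table = decompose_by_label(result, meta, config.top_k)
        entry = {
            "cutoff_nm": cutoff,
            "n_clusters": result.n_clusters,
            "populations": [round(float(p), 6) for p in result.populations],
            "centers": [int(c) for c in result.centers],
            "decomposition": {
                label: {c: round(float(v), 6) for c, v in row.items()}
                for label, row in table.table.iterrows()
            },
        }
        report["subsets"][name] = entry
        if outdir is not None:
            outdir = Path(outdir)
            outdir.mkdir(parents=True, exist_ok=True)
            table.table.to_csv(outdir / f"decomposition_{name}.csv")
            for cid in range(1, min(config.top_k, result.n_clusters) + 1):
                frame = representative(result, cid, meta, matrix)
                write_pdb(top, frame, outdir / f"representative_{name}_c{cid}.pdb")
    return report


def run_all(runset: RunSet, config: AnalysisConfig, outdir: str | Path) -> dict:
    """Manifest-driven full workflow; writes report.json and per-stage CSVs."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    reference = runset.load_reference()
    top, _ = reference
    runs_by_system = {
        s.system_id: runset.load_runs(s.system_id, top) for s in runset.systems
    }
    report = {
        "provenance": _provenance(config),
        "systems": {
            sid: run_system(reference, runs, config, sid)
            for sid, runs in sorted(runs_by_system.items())
        },
    }
    if len(runs_by_system) >= 2:
        report["meta"] = run_meta(reference, runs_by_system, config, outdir)
    body = report_json(report)
    (outdir / "report.json").write_text(body)
    manifest = {
        "config_hash": config.digest(),
        "files": sorted(os.listdir(outdir)),
    }
    (outdir / "MANIFEST.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return report


def report_json(report: Mapping) -> str:
    """Canonical JSON serialisation of a report (stable key order)."""
    return json.dumps(report, sort_keys=True, indent=2)
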