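"""Config-driven orchestration of the analysis stages.

Stages: ``synth`` (write synthetic fixtures), ``cluster`` (ensemble
clustering + descriptors), ``contacts`` (top-fraction selection and
contact-probability profiles), ``filter`` (productive-complex
identification), ``traj`` (trajectory metrics).  Every run writes a JSON
manifest with input checksums, a parameter echo, and the package version;
rerunning an identical config on identical inputs reproduces byte-identical
tabular outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import pandas as pd
import yaml

from . import __version__
from .dockmap import (
    ContactParams,
    ligand_contact_profile,
    read_pose_set,
    receptor_contact_profile,
    select_top_fraction,
)
from .ensemblecluster import (
    ClusterParams,
    cluster_table,
    ensemble_descriptors,
    gromos_cluster,
    pairwise_rmsd_matrix,
    write_representatives,
)
from .errors import ConfigurationError, EncompassError
from .prodfilter import filter_productive, rank_by_segment_rmsd
from .structio import (
    ConformerEnsemble,
    SegmentSpec,
    read_pdb,
    write_pdb,
    write_score_table,
)
from .synthgen import (
    SynthSpec,
    make_complex_trajectory,
    make_conformer_ensemble,
    make_pose_set,
)
from .trajanal import (
    Trajectory,
    acf_relaxation,
    min_distance_series,
    receptor_fit_rmsd_series,
    transient_contact_profile,
)

logger = logging.getLogger("encompass.pipeline")

ALL_STAGES = ("synth", "cluster", "contacts", "filter", "traj")


@dataclass
class RunConfig:
    """Validated run configuration (see ``RunConfig.from_yaml``)."""

    output_dir: Path
    seed: int = 0
    stages: tuple[str, ...] = ALL_STAGES
    synth: dict[str, Any] = field(default_factory=dict)
    inputs: dict[str, str] = field(default_factory=dict)
    cluster: ClusterParams = field(default_factory=ClusterParams)
    contacts: ContactParams = field(default_factory=ContactParams)
    selection_fraction: float = 0.1
    coverage_target: float = 0.5
    max_axis_angle: float = 30.0
    min_hotspot_count: int = 6
    segments: dict[str, str] = field(default_factory=dict)
    dt_ps: float = 20.0

    def __post_init__(self) -> None:
        self.output_dir = Path(self.output_dir)
        if not 0 < self.selection_fraction <= 1:
            raise ConfigurationError("selection_fraction must be in (0, 1]")
        if not 0 < self.coverage_target <= 1:
            raise ConfigurationError("coverage_target must be in (0, 1]")
        unknown = set(self.stages) - set(ALL_STAGES)
        if unknown:
            raise ConfigurationError(f"unknown stage(s): {sorted(unknown)}")
        for key, path in self.inputs.items():
            if not Path(path).exists():
                raise ConfigurationError(
                    f"input {key!r}: file {path} does not exist"
                )
        for label, text in self.segments.items():
            try:
                SegmentSpec.from_string(text)
            except ValueError as exc:
                raise ConfigurationError(
                    f"segment {label!r}: {exc}"
                ) from exc

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides: Any) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        raw.update({k: v for k, v in overrides.items() if v is not None})
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict[str, Any]) -> "RunConfig":
        kwargs = dict(raw)
        if "stages" in kwargs:
            kwargs["stages"] = tuple(kwargs["stages"])
        if "cluster" in kwargs and isinstance(kwargs["cluster"], dict):
            kwargs["cluster"] = ClusterParams(**kwargs["cluster"])
        if "contacts" in kwargs and isinstance(kwargs["contacts"], dict):
            kwargs["contacts"] = ContactParams(**kwargs["contacts"])
        try:
            return cls(**kwargs)
        except TypeError as exc:
            raise ConfigurationError(str(exc)) from exc

    def synth_spec(self) -> SynthSpec:
        return SynthSpec(seed=self.seed, **self.synth)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for block in iter(lambda: fh.read(65536), b""):
            h.update(block)
    return h.hexdigest()


def _write_table(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.6f")


class _Run:
    def __init__(self, config: RunConfig):
        self.config = config
        self.outputs: list[Path] = []
        self.counts: dict[str, int] = {}
        config.output_dir.mkdir(parents=True, exist_ok=True)

    def out(self, name: str) -> Path:
        path = self.config.output_dir / name
        self.outputs.append(path)
        return path

    # -- inputs ----------------------------------------------------------
    def ensemble(self):
        if "ensemble" in self.config.inputs:
            return read_pdb(self.config.inputs["ensemble"],
                            model_policy="all")
        return make_conformer_ensemble(self.config.synth_spec()).ensemble

    def pose_data(self):
        inp = self.config.inputs
        if {"receptor", "ligand_poses", "scores"} <= set(inp):
            return read_pose_set(inp["receptor"], inp["ligand_poses"],
                                 inp["scores"]), None
        synth = make_pose_set(self.config.synth_spec())
        return synth.pose_set, synth

    # -- stages ----------------------------------------------------------
    def stage_synth(self) -> None:
        spec = self.config.synth_spec()
        ens = make_conformer_ensemble(spec)
        write_pdb(ens.ensemble, self.out("synthetic_ensemble.pdb"))
        synth = make_pose_set(spec)
        write_pdb(synth.pose_set.receptor, self.out("synthetic_receptor.pdb"))
        write_pdb(
            ConformerEnsemble(
                topology=synth.pose_set.ligand_topology,
                coordinates=synth.pose_set.ligand_coordinates,
                labels=synth.pose_set.labels,
            ),
            self.out("synthetic_poses.pdb"),
        )
        write_score_table(
            pd.Series(synth.pose_set.scores, index=synth.pose_set.labels),
            self.out("synthetic_scores.tsv"),
        )
        _write_table(
            pd.DataFrame({
                "pose": synth.pose_set.labels,
                "productive": synth.productive_mask.astype(int),
            }),
            self.out("synthetic_ground_truth.tsv"),
        )
        self.counts["synthetic_poses"] = synth.pose_set.n_poses

    def stage_cluster(self) -> None:
        ens = self.ensemble()
        matrix = pairwise_rmsd_matrix(ens, self.config.cluster)
        result = gromos_cluster(matrix, self.config.cluster.cutoff)
        _write_table(cluster_table(result, ens.labels),
                     self.out("clusters.tsv"))
        reps = write_representatives(
            ens, result, self.out("representatives.pdb"),
            coverage_target=self.config.coverage_target,
        )
        rg, propensity = ensemble_descriptors(ens)
        _write_table(
            pd.DataFrame({"conformer": ens.labels, "rg": rg}),
            self.out("radius_of_gyration.tsv"),
        )
        _write_table(propensity, self.out("helix_propensity.tsv"))
        self.counts["conformers"] = ens.n_conformers
        self.counts["clusters"] = len(result.clusters)
        self.counts["representatives_at_coverage"] = len(reps)
        logger.info("cluster: %d conformers -> %d clusters (%d cover %.0f%%)",
                    ens.n_conformers, len(result.clusters), len(reps),
                    100 * self.config.coverage_target)

    def _segment(self, key: str, default: str) -> SegmentSpec:
        return SegmentSpec.from_string(self.config.segments.get(key, default))

    def stage_contacts(self) -> None:
        poses, _ = self.pose_data()
        top = select_top_fraction(poses, self.config.selection_fraction)
        lig = ligand_contact_profile(top, self.config.contacts)
        lig.write(self.out("ligand_contact_profile.tsv"))
        recognition = self._segment("recognition", "A:9-18")
        rec = receptor_contact_profile(top, [recognition],
                                       self.config.contacts)
        rec.write(self.out("receptor_contact_profile.tsv"))
        self.counts["poses_in"] = poses.n_poses
        self.counts["poses_selected"] = top.n_poses
        logger.info("contacts: kept top %d of %d poses",
                    top.n_poses, poses.n_poses)

    def stage_filter(self) -> None:
        poses, synth = self.pose_data()
        if synth is None:
            raise ConfigurationError(
                "filter stage requires synthetic pose data or an external "
                "criteria definition; file-based criteria must supply "
                "hot-spot residues and a reference complex"
            )
        criteria = dataclasses.replace(
            synth.criteria,
            max_axis_angle=self.config.max_axis_angle,
            hotspots=dataclasses.replace(
                synth.criteria.hotspots,
                min_count=self.config.min_hotspot_count,
            ),
        )
        top = select_top_fraction(poses, self.config.selection_fraction)
        report = filter_productive(top, criteria)
        report.write(self.out("productive_report.tsv"))
        n_pass = int(report.table["passes"].sum())
        ranked = rank_by_segment_rmsd(report, max(n_pass, 1)) if n_pass \
            else []
        _write_table(pd.DataFrame({"rank": range(1, len(ranked) + 1),
                                   "pose": ranked}),
                     self.out("productive_ranked.tsv"))
        self.counts["poses_filtered"] = top.n_poses
        self.counts["productive"] = n_pass
        logger.info("filter: %d of %d selected poses productive",
                    n_pass, top.n_poses)

    def stage_traj(self) -> None:
        if "trajectory" in self.config.inputs:
            ens = read_pdb(self.config.inputs["trajectory"],
                           model_policy="all")
            traj = Trajectory(ens.topology, ens.coordinates,
                              dt=self.config.dt_ps)
            synth = None
        else:
            synth = make_complex_trajectory(self.config.synth_spec())
            traj = synth.trajectory
        reference = traj.topology.with_coords(traj.frames[0])
        rec_res = traj.topology.residue_numbers[
            traj.topology.chain_ids == "R"]
        fit_seg = SegmentSpec("receptor", "R", int(rec_res.min()),
                              int(rec_res.max()))
        report_seg = self._segment("recognition", "A:9-18")
        rmsd = receptor_fit_rmsd_series(traj, reference, fit_seg,
                                        [report_seg])
        _write_table(rmsd, self.out("rmsd_series.tsv"))
        dist = min_distance_series(traj, report_seg, fit_seg)
        _write_table(
            pd.DataFrame({"time_ps": traj.times, "min_distance": dist}),
            self.out("min_distance_series.tsv"),
        )
        profile = transient_contact_profile(
            traj, report_seg, "R", self.config.contacts
        )
        profile.write(self.out("transient_contact_profile.tsv"))
        series = synth.distance_series if synth is not None else dist
        rows = []
        for method in ("integral", "exponential_fit"):
            res = acf_relaxation(series, traj.dt, method=method)
            rows.append({"method": method,
                         "relaxation_time_ps": res.relaxation_time})
        _write_table(pd.DataFrame(rows), self.out("relaxation_times.tsv"))
        self.counts["frames"] = traj.n_frames


def run_pipeline(config: RunConfig) -> dict[str, Any]:
    """Execute the requested stages in order and write the run manifest.

    Aborts on the first stage failure, naming the stage and cause; outputs
    written before the failure are listed in the manifest as partial.
    """
    run = _Run(config)
    stage_fns = {
        "synth": run.stage_synth,
        "cluster": run.stage_cluster,
        "contacts": run.stage_contacts,
        "filter": run.stage_filter,
        "traj": run.stage_traj,
    }
    completed: list[str] = []
    failure: tuple[str, str] | None = None
    for stage in config.stages:
        try:
            stage_fns[stage]()
            completed.append(stage)
        except EncompassError as exc:
            failure = (stage, str(exc))
            break
    manifest = {
        "tool": "encompass",
        "version": __version__,
        "seed": config.seed,
        "parameters": {
            "cluster": dataclasses.asdict(config.cluster),
            "contacts": dataclasses.asdict(config.contacts),
            "selection_fraction": config.selection_fraction,
            "coverage_target": config.coverage_target,
            "max_axis_angle": config.max_axis_angle,
            "min_hotspot_count": config.min_hotspot_count,
            "segments": config.segments,
            "synth": config.synth,
            "dt_ps": config.dt_ps,
        },
        "inputs": {
            key: {"path": str(path), "sha256": _sha256(Path(path))}
            for key, path in config.inputs.items()
        },
        "stages_completed": completed,
        "counts": run.counts,
        "outputs": [
            {"path": str(p), "sha256": _sha256(p)}
            for p in run.outputs if p.exists()
        ],
        "partial": failure is not None,
    }
    manifest_path = config.output_dir / "manifest.json"
    with open(manifest_path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    if failure is not None:
        stage, cause = failure
        raise ConfigurationError(
            f"stage {stage!r} failed: {cause} (partial outputs flagged in "
            f"{manifest_path})"
        )
    return manifest
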