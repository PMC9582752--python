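"""Pipeline stages behind the command-line interface.

Each ``cmd_*`` function takes a :class:`RunConfig`, runs one analysis stage
through the library, writes its tables (TSV/CSV + JSON) and a reproducibility
manifest (config, seed, package version, config hash) into the output
directory, and returns the in-memory result for programmatic use.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd

from . import __version__, kinetics, pose, structure, subsites, synth

__all__ = [
    "RunConfig",
    "StageError",
    "cmd_analyze_poses",
    "cmd_fit_kinetics",
    "cmd_simulate",
    "cmd_gen_fixtures",
]

log = logging.getLogger("gtase")


class StageError(RuntimeError):
    """A pipeline stage failed; the message names the stage and context."""


@dataclass
class RunConfig:
    """Settings shared by the pipeline stages."""

    output_dir: Path = Path("results")
    seed: int = 0
    # pose analysis
    receptor_path: Path | None = None
    reference_path: Path | None = None
    poses_path: Path | None = None
    reference_residue: str = "ARX"
    reference_anchors: tuple[str, str, str] = ("C4A", "C1", "N4A")
    reference_moiety_map: dict[str, int] | None = None
    match_threshold: float = 1.0  # A
    subsite_max_distance: float = 2.0  # A
    contact_residues: tuple[tuple[str, int], ...] = ()
    # kinetics
    kinetics_paths: tuple[Path, ...] = ()
    activity_path: Path | None = None
    enzyme_concentration: float = 0.097  # mg/ml
    enzyme_molar_mass: float = 76002.0  # Da
    calibration_slope: float | None = None  # ug amylose per A660 unit
    # simulator
    preset: str = "GH57_PSGT"
    profile_overrides: dict[str, Any] = field(default_factory=dict)
    initial_species: dict[str, float] = field(default_factory=lambda: {"G5": 10.0})
    duration_min: float = 120.0
    snapshot_min: float = 2.0
    sim_mode: str = "deterministic"

    def outdir(self) -> Path:
        out = Path(self.output_dir)
        out.mkdir(parents=True, exist_ok=True)
        return out


def _config_hash(config: RunConfig) -> str:
    payload = json.dumps(
        dataclasses.asdict(config), sort_keys=True, default=str
    ).encode()
    return hashlib.sha256(payload).hexdigest()[:16]


def _write_manifest(config: RunConfig, stage: str, outputs: list[str]) -> None:
    manifest = {
        "stage": stage,
        "tool_version": __version__,
        "seed": config.seed,
        "config_hash": _config_hash(config),
        "config": dataclasses.asdict(config),
        "outputs": outputs,
    }
    path = config.outdir() / f"manifest_{stage}.json"
    path.write_text(json.dumps(manifest, indent=2, default=str) + "\n")
    log.info("stage %s: wrote %s (version %s, seed %d, config %s)",
             stage, path, __version__, config.seed, _config_hash(config))


def _load_reference(config: RunConfig) -> structure.ReferenceLigand:
    if config.reference_path is None:
        raise StageError("analyze-poses: no reference ligand path configured")
    if not Path(config.reference_path).exists():
        raise StageError(f"analyze-poses: missing file {config.reference_path}")
    model = structure.read_structure(config.reference_path, dialect="pdb")
    if config.reference_moiety_map is None:
        raise StageError("analyze-poses: a reference moiety map is required")
    return structure.extract_reference_ligand(
        model,
        residue_name=config.reference_residue,
        anchors=config.reference_anchors,
        moiety_map=config.reference_moiety_map,
    )


def _load_poses(config: RunConfig) -> list[pose.DockedPose]:
    if config.poses_path is None:
        raise StageError("analyze-poses: no poses path configured")
    path = Path(config.poses_path)
    if not path.exists():
        raise StageError(f"analyze-poses: missing file {path}")
    dialect = "pdbqt_minimal" if path.suffix == ".pdbqt" else "multi_model_pdb"
    models = structure.read_structure(path, dialect=dialect)
    poses = []
    for rank, model in enumerate(models, start=1):
        heavy = model.heavy_atoms()
        poses.append(
            pose.DockedPose(
                ligand_name=path.stem,
                model_rank=rank,
                docking_score=float("nan"),
                atoms=heavy,
            )
        )
    return poses


def analyze_poses(
    reference: structure.ReferenceLigand,
    poses: list[pose.DockedPose],
    receptor: structure.StructureModel | None = None,
    contact_residues: tuple[tuple[str, int], ...] = (),
    match_threshold: float = 1.0,
    subsite_max_distance: float = 2.0,
) -> pd.DataFrame:
    """Per-pose geometry metrics table (library entry point).

    One row per pose: positional coordinate along the binding axis, greedy
    sub-angstrom match percentage, nearest calibrated subsite, and minimum
    side-chain distances to any configured contact residues.
    """
    axis = pose.build_binding_axis(reference)
    calibration = pose.calibrate_subsites(reference, axis)
    rows = []
    for p in poses:
        coord = pose.positional_coordinate(p, axis)
        metrics = pose.greedy_match_percent(p, reference, threshold=match_threshold)
        row: dict[str, Any] = {
            "ligand": p.ligand_name,
            "rank": p.model_rank,
            "score": p.docking_score,
            "coordinate_A": coord,
            "match_percent": metrics.match_percent,
            "subsite": pose.assign_subsite(
                coord, calibration, max_distance=subsite_max_distance
            ),
        }
        if receptor is not None:
            for chain, resnum in contact_residues:
                contact = pose.min_residue_ligand_distance(
                    receptor, chain, resnum, p.atoms
                )
                row[f"dist_{chain}{resnum}_A"] = contact.distance
        rows.append(row)
    return pd.DataFrame(rows)


def cmd_analyze_poses(
    config: RunConfig,
    reference: structure.ReferenceLigand | None = None,
    poses: list[pose.DockedPose] | None = None,
    receptor: structure.StructureModel | None = None,
) -> pd.DataFrame:
    """Pose-geometry stage: metrics TSV + JSON summary + manifest.

    The reference/poses/receptor may be passed in memory (synthetic runs) or
    read from the configured paths.
    """
    try:
        if reference is None:
            reference = _load_reference(config)
        if poses is None:
            poses = _load_poses(config)
        if receptor is None and config.receptor_path is not None:
            if not Path(config.receptor_path).exists():
                raise StageError(
                    f"analyze-poses: missing file {config.receptor_path}"
                )
            receptor = structure.read_structure(config.receptor_path, dialect="pdb")
        table = analyze_poses(
            reference,
            poses,
            receptor=receptor,
            contact_residues=config.contact_residues,
            match_threshold=config.match_threshold,
            subsite_max_distance=config.subsite_max_distance,
        )
    except StageError:
        raise
    except Exception as exc:
        raise StageError(f"analyze-poses failed: {exc}") from exc
    out = config.outdir()
    tsv = out / "pose_metrics.tsv"
    table.to_csv(tsv, sep="\t", index=False)
    summary = {
        "n_poses": int(len(table)),
        "mean_match_percent": float(table["match_percent"].mean()),
        "subsite_counts": table["subsite"].value_counts().to_dict(),
    }
    (out / "pose_metrics.json").write_text(json.dumps(summary, indent=2) + "\n")
    _write_manifest(config, "analyze_poses", [str(tsv)])
    return table


def cmd_fit_kinetics(
    config: RunConfig,
    datasets: list[kinetics.KineticDataset] | None = None,
    activities: dict[str, kinetics.ActivityMeasurement] | None = None,
) -> dict[str, Any]:
    """Kinetics stage: per-acceptor KM/kcat/efficiency plus TF table.

    A fit failure for one acceptor is reported in its row without aborting
    the others.
    """
    if datasets is None:
        datasets = []
        for path in config.kinetics_paths:
            path = Path(path)
            if not path.exists():
                raise StageError(f"fit-kinetics: missing file {path}")
            frame = pd.read_csv(path)
            pts = [
                kinetics.RatePoint(row.concentration_mM, row.velocity)
                for row in frame.itertuples()
            ]
            datasets.append(kinetics.KineticDataset(acceptor=path.stem, points=pts))
    if not datasets:
        raise StageError("fit-kinetics: no kinetic datasets provided")

    fit_rows = []
    for ds in datasets:
        row: dict[str, Any] = {"acceptor": ds.acceptor}
        try:
            fit = kinetics.fit_lineweaver_burk(ds)
            kinetics.complete_fit(
                fit, config.enzyme_concentration, config.enzyme_molar_mass
            )
            row.update(
                KM_mM=fit.KM,
                Vmax=fit.Vmax,
                kcat_per_min=fit.kcat,
                efficiency_per_min_per_mM=fit.efficiency,
                r_squared=fit.r_squared,
                error="",
            )
        except (ValueError, kinetics.FitFailureError) as exc:
            row.update(
                KM_mM=np.nan, Vmax=np.nan, kcat_per_min=np.nan,
                efficiency_per_min_per_mM=np.nan, r_squared=np.nan,
                error=str(exc),
            )
            log.warning("fit-kinetics: acceptor %s failed: %s", ds.acceptor, exc)
        fit_rows.append(row)
    fits = pd.DataFrame(fit_rows)

    tf_rows = []
    if activities:
        baseline = activities.get("no acceptor")
        if baseline is None:
            raise StageError("fit-kinetics: activity table lacks a 'no acceptor' row")
        for name, meas in activities.items():
            if name == "no acceptor":
                continue
            factor, sd = kinetics.transglycosylation_factor(meas, baseline)
            tf_rows.append(
                {
                    "acceptor": name,
                    "specific_activity": meas.specific_activity,
                    "transglycosylation_factor": round(factor, 1),
                    "tf_sd": round(sd, 1) if sd is not None else None,
                }
            )
    tfs = pd.DataFrame(tf_rows)

    out = config.outdir()
    fits.to_csv(out / "kinetic_fits.csv", index=False)
    report = {"fits": fit_rows, "transglycosylation": tf_rows}
    (out / "kinetic_fits.json").write_text(
        json.dumps(report, indent=2, default=float) + "\n"
    )
    if not tfs.empty:
        tfs.to_csv(out / "transglycosylation_factors.csv", index=False)
    _write_manifest(config, "fit_kinetics", [str(out / "kinetic_fits.csv")])
    return report


def cmd_simulate(config: RunConfig) -> subsites.SimulationResult:
    """Simulator stage: trajectory CSV + early product-profile summary."""
    presets = {
        "GH57_PSGT": subsites.gh57_preset,
        "GH77_contrast": subsites.gh77_contrast_preset,
    }
    try:
        profile = presets[config.preset](**config.profile_overrides)
    except KeyError as exc:
        raise StageError(f"simulate: unknown preset {config.preset!r}") from exc
    state = subsites.ReactionState(
        amounts={
            subsites.GlycanSpecies.parse(name): amt
            for name, amt in config.initial_species.items()
        }
    )
    result = subsites.simulate(
        state,
        profile,
        duration=config.duration_min,
        mode=config.sim_mode,
        seed=config.seed,
    )
    out = config.outdir()
    tidy = result.to_tidy()
    csv = out / f"simulation_{config.preset}.csv"
    tidy.to_csv(csv, index=False)
    profile_frame = subsites.product_profile(result, config.snapshot_min)
    summary = {
        "preset": config.preset,
        "snapshot_min": config.snapshot_min,
        "top_products": subsites.top_products(result, config.snapshot_min, n=4),
        "profile": profile_frame.to_dict(orient="records"),
        "warnings": result.warnings,
    }
    (out / f"simulation_{config.preset}_summary.json").write_text(
        json.dumps(summary, indent=2, default=float) + "\n"
    )
    _write_manifest(config, f"simulate_{config.preset}", [str(csv)])
    return result


def cmd_gen_fixtures(config: RunConfig) -> dict[str, Path]:
    """Write a synthetic reference ligand, docked poses, and kinetic CSVs."""
    out = config.outdir()
    reference = synth.gen_reference_ligand(seed=config.seed)
    ref_model = structure.StructureModel(atoms=reference.atoms)
    ref_path = out / "reference_ligand.pdb"
    structure.write_structure(ref_model, ref_path)
    poses = synth.gen_poses(
        reference,
        synth.PoseGenConfig(n_poses=20, displacement_along_axis=0.0, seed=config.seed),
    )
    pose_models = [structure.StructureModel(atoms=p.atoms) for p in poses]
    poses_path = out / "poses.pdb"
    structure.write_structure(pose_models, poses_path)
    mm = synth.gen_mm_dataset(synth.MMGenConfig(KM=0.86, kcat=2635.0, seed=config.seed))
    mm_path = out / "kinetics_maltotriose.csv"
    pd.DataFrame(
        {
            "concentration_mM": mm.concentrations(),
            "velocity": mm.velocities(),
        }
    ).to_csv(mm_path, index=False)
    sidecar = {
        "reference": {"moiety_map": reference.moiety_map},
        "poses": [p.ground_truth for p in poses],
        "kinetics": mm.ground_truth,
    }
    (out / "fixtures_ground_truth.json").write_text(
        json.dumps(sidecar, indent=2, default=float) + "\n"
    )
    _write_manifest(config, "gen_fixtures", [str(ref_path), str(poses_path)])
    return {"reference": ref_path, "poses": poses_path, "kinetics": mm_path}
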