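"""End-to-end pipeline: simulate → calibrate → cluster → stats → annotate →
proteases, as one configured, logged, checksum-manifested run.

One global seed fans out to per-stage child seeds through
``numpy.random.SeedSequence`` (see :func:`pepticlust.synthetic.generate_study`),
so every stage is independently reproducible and a repeated run with the same
config produces byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time as _time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__, annotation, calibration, clustering, io, proteases
from . import stats as dstats
from . import synthetic

logger = logging.getLogger("pepticlust")

STAGES = ("simulate", "calibrate", "cluster", "stats", "annotate", "proteases")


@dataclass
class PipelineConfig:
    seed: int = 0
    outdir: str = "pepticlust_run"
    peaks_dir: str | None = None  # user peak lists; None → synthetic
    design_path: str | None = None
    calibrants_path: str | None = None
    rules_path: str | None = None
    stages: tuple[str, ...] = STAGES
    drop_calibrants: bool = True
    local_time_calibration: bool = False
    protein_of_interest: str = synthetic.UMOD_NAME
    study: synthetic.StudyConfig = field(default_factory=synthetic.StudyConfig)
    tolerances: clustering.ToleranceConfig = field(default_factory=clustering.ToleranceConfig)
    stats: dstats.StatsConfig = field(default_factory=dstats.StatsConfig)

    def validate(self) -> None:
        unknown = set(self.stages) - set(STAGES)
        if unknown:
            raise ValueError(f"unknown stage(s): {sorted(unknown)}")
        self.study.validate()
        if self.peaks_dir is None and "simulate" not in self.stages:
            raise ValueError("either enable the simulate stage or supply peaks_dir")

    # -- serialization ------------------------------------------------------

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["stages"] = list(self.stages)
        d["study"] = synthetic.config_to_dict(self.study)
        d["tolerances"] = dataclasses.asdict(self.tolerances)
        d["stats"] = dataclasses.asdict(self.stats)
        return d

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        data = dict(data)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")

        def sub(key, klass):
            block = dict(data.pop(key, {}) or {})
            names = {f.name for f in dataclasses.fields(klass)}
            bad = set(block) - names
            if bad:
                raise ValueError(f"unknown {key} config key(s): {sorted(bad)}")
            for k, v in block.items():
                if isinstance(v, list):
                    block[k] = tuple(v)
            return klass(**block)

        study = sub("study", synthetic.StudyConfig)
        tolerances = sub("tolerances", clustering.ToleranceConfig)
        stats_cfg = sub("stats", dstats.StatsConfig)
        if "stages" in data:
            data["stages"] = tuple(data["stages"])
        return cls(study=study, tolerances=tolerances, stats=stats_cfg, **data)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


@dataclass
class RunManifest:
    config_hash: str
    seed: int
    versions: dict
    stages: dict = field(default_factory=dict)  # stage -> {outputs, seconds, counts}

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True))


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"stage {stage!r} failed: {message}")
        self.stage = stage


def validate_inputs(peaks_dir: str | Path, design_path: str | Path) -> list[str]:
    """Schema diagnostics for user-supplied inputs; empty list = clean."""
    diagnostics: list[str] = []
    peaks_dir = Path(peaks_dir)
    try:
        design = io.read_design(design_path)
    except Exception as exc:  # noqa: BLE001 - report, don't crash
        return [f"design: {exc}"]
    for sample_id in design["sample_id"]:
        path = peaks_dir / f"{sample_id}.tsv"
        if not path.exists():
            diagnostics.append(f"design references missing sample file for {sample_id!r}")
            continue
        try:
            io.read_peak_list(path)
        except Exception as exc:  # noqa: BLE001
            diagnostics.append(str(exc))
    return diagnostics


def run_pipeline(config: PipelineConfig, seed: int | None = None) -> RunManifest:
    """Execute the enabled stages in order; fail fast naming the stage."""
    config.validate()
    if seed is not None:
        config = dataclasses.replace(config, seed=seed)
        config.study = dataclasses.replace(config.study, seed=seed)
    else:
        config.study = dataclasses.replace(config.study, seed=config.seed)
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    config_yaml = outdir / "config.yaml"
    config.to_yaml(config_yaml)
    manifest = RunManifest(
        config_hash=hashlib.sha256(config_yaml.read_bytes()).hexdigest(),
        seed=config.seed,
        versions={"pepticlust": __version__, "pandas": pd.__version__},
    )

    state: dict = {}

    def record(stage: str, t0: float, outputs: list[Path], counts: dict) -> None:
        manifest.stages[stage] = {
            "seconds": round(_time.monotonic() - t0, 3),
            "outputs": {p.name: io.sha256_file(p) for p in outputs},
            "counts": counts,
        }
        logger.info("stage %s: %s", stage, counts)

    for stage in STAGES:
        if stage not in config.stages:
            continue
        t0 = _time.monotonic()
        try:
            outputs, counts = _STAGE_FUNCS[stage](config, outdir, state)
        except PipelineError:
            raise
        except Exception as exc:  # noqa: BLE001
            raise PipelineError(stage, str(exc)) from exc
        record(stage, t0, outputs, counts)

    manifest.to_json(outdir / "manifest.json")
    return manifest


# ---------------------------------------------------------------------------
# stages


def _stage_simulate(config: PipelineConfig, outdir: Path, state: dict):
    if config.peaks_dir is not None:
        # load user data instead of simulating
        design = io.read_design(config.design_path)
        peaks = {
            s: io.read_peak_list(Path(config.peaks_dir) / f"{s}.tsv")
            for s in design["sample_id"]
        }
        reference = (
            io.read_table(config.calibrants_path)
            if config.calibrants_path
            else synthetic.calibrant_reference(config.study.n_calibrants)
        )
        state.update(peaks=peaks, design=design, reference=reference, ground_truth=None)
        return [], {"samples": len(peaks), "peaks": sum(map(len, peaks.values()))}

    study = synthetic.generate_study(config.study)
    peaks_dir = outdir / "peaks"
    peaks_dir.mkdir(exist_ok=True)
    outputs = []
    for sample_id, df in study.peak_lists.items():
        path = peaks_dir / f"{sample_id}.tsv"
        io.write_peak_list(df, path)
        outputs.append(path)
    io.write_design(study.design, outdir / "design.tsv")
    io.write_table(study.ground_truth, outdir / "ground_truth.tsv")
    io.write_table(study.calibrant_reference, outdir / "calibrants.tsv")
    io.write_fasta(study.protein_db, outdir / "proteins.fasta")
    outputs += [outdir / "design.tsv", outdir / "ground_truth.tsv",
                outdir / "calibrants.tsv", outdir / "proteins.fasta"]
    state.update(
        peaks=study.peak_lists,
        design=study.design,
        reference=study.calibrant_reference,
        ground_truth=study.ground_truth,
        protein_db=study.protein_db,
    )
    return outputs, {
        "samples": len(study.peak_lists),
        "peaks": sum(map(len, study.peak_lists.values())),
    }


def _stage_calibrate(config: PipelineConfig, outdir: Path, state: dict):
    calibrated, report = calibration.calibrate_study(
        state["peaks"],
        state["reference"],
        drop_calibrants=config.drop_calibrants,
        local=config.local_time_calibration,
    )
    state["calibrated"] = calibrated
    path = outdir / "calibration_report.tsv"
    io.write_table(report, path)
    return [path], {
        "samples_calibrated": len(calibrated),
        "mean_residual_sd_time": round(float(report.residual_sd_time.mean()), 4),
    }


def _stage_cluster(config: PipelineConfig, outdir: Path, state: dict):
    clusters = clustering.cluster_peaks(state["calibrated"], config.tolerances)
    matrix, summary = clustering.build_matrix(clusters, state["design"])
    state.update(clusters=clusters, matrix=matrix, cluster_summary=summary)
    p1 = outdir / "clusters.tsv"
    p2 = outdir / "matrix.tsv"
    io.write_table(summary, p1)
    io.write_matrix(matrix, p2)
    return [p1, p2], {"clusters": len(clusters)}


def _stage_stats(config: PipelineConfig, outdir: Path, state: dict):
    results = dstats.run_differential(
        state["matrix"],
        state["design"],
        config.stats,
        hypertensive=(
            config.study.hypertensive
            if config.study.hypertensive in set(state["design"].strain)
            else None
        ),
    )
    state["results"] = results
    outputs = []
    for tp, table in results.per_comparison.items():
        path = outdir / f"results_{tp}.tsv"
        io.write_table(table, path)
        outputs.append(path)
    path = outdir / "patterns.tsv"
    io.write_table(results.patterns, path)
    outputs.append(path)
    summary = dstats.summarize_regulation(results)
    path = outdir / "regulation_summary.tsv"
    io.write_table(summary, path)
    outputs.append(path)
    n_sig = int(results.patterns.retained_for_analysis.sum())
    return outputs, {
        "peptides_tested": len(results.retained_ids),
        "retained_for_analysis": n_sig,
    }


def _stage_annotate(config: PipelineConfig, outdir: Path, state: dict):
    if state.get("ground_truth") is None:
        raise PipelineError(
            "annotate", "no candidate table: annotation needs ground truth "
            "(synthetic run) or user identifications"
        )
    candidates = annotation.candidate_table_from_ground_truth(state["ground_truth"])
    annotations = annotation.annotate_clusters(
        state["cluster_summary"], candidates, cfg=config.tolerances
    )
    state["annotations"] = annotations
    path = outdir / "annotations.tsv"
    io.write_table(annotations, path)
    outputs = [path]
    counts = {"annotated": len(annotations)}
    protein = config.protein_of_interest
    if (annotations.parent_protein == protein).any():
        summary = annotation.summarize_protein(
            state["matrix"], annotations, protein, state["design"],
            hypertensive=config.study.hypertensive,
        )
        state["protein_summary"] = summary
        path = outdir / "protein_summary.tsv"
        io.write_table(summary.fold_changes.assign(protein=protein), path)
        outputs.append(path)
        counts["protein_peptides"] = len(summary.peptide_ids)
    return outputs, counts


def _stage_proteases(config: PipelineConfig, outdir: Path, state: dict):
    rules = (
        proteases.load_rules(config.rules_path)
        if config.rules_path
        else proteases.DEFAULT_RULES
    )
    parents = {rec.id: str(rec.seq) for rec in state.get("protein_db", [])}
    report = proteases.predict_for_study(state["annotations"], parents, rules)
    path = outdir / "protease_predictions.tsv"
    io.write_table(report, path)
    named = report[report.protease != ""]
    return [path], {
        "sites": int(report.groupby(["protein", "position", "terminus_role"]).ngroups)
        if len(report)
        else 0,
        "predictions": len(named),
    }


_STAGE_FUNCS = {
    "simulate": _stage_simulate,
    "calibrate": _stage_calibrate,
    "cluster": _stage_cluster,
    "stats": _stage_stats,
    "annotate": _stage_annotate,
    "proteases": _stage_proteases,
}
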