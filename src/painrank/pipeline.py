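"""File-based pipeline orchestration.

Stages (each independently re-runnable from its input files):

``simulate``  -> cohort files (features.tsv + features.yaml, GO TSV,
                 edge list, labels, validation GMT, truth JSON)
``featurize`` -> scaled feature matrix, topology profiles, split lists
``train``     -> fitted ensemble artifacts: model card, CV report,
                 feature importance
``score``     -> pain_scores.tsv (gene, pain score, rank)
``validate``  -> held-out confusion metrics of the score table
``enrich``    -> enrichment report against GMT sets, with and without
                 leakage removal

``run`` executes all of them under one master seed and writes a
manifest plus a log that records the resolved configuration and the
two documented interpretation choices (significance direction
FDR < 0.05; correlation-filter trigger |r| >= 0.75).
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import pandas as pd
import yaml

from . import features as feat
from . import simulate as sim
from .enrichment import read_gmt, validate_against_sets
from .ensemble import DEFAULT_SEED, DEFAULT_WEIGHT_MULTISET
from .metrics import confusion_from_predictions, metric_set
from .model import PainGeneClassifier
from .topology import compute_topology, write_profiles

__all__ = ["PipelineConfig", "validate_config", "run_pipeline"]

_INTERPRETATION_NOTES = [
    "composite LFC: entries with FDR >= 0.05 are zeroed (significance at FDR < 0.05)",
    "correlation filter: |Pearson r| >= threshold marks a pair as highly "
    "correlated; the lower-variance member is removed",
]


@dataclasses.dataclass
class PipelineConfig:
    """Resolved, validated configuration for a pipeline run."""

    sim: sim.SimConfig
    seed: int = DEFAULT_SEED
    train_fraction: float = 0.7
    corr_threshold: float = 0.75
    n_go_components: int = 2
    method: str = "voting"
    weight_multiset: tuple = DEFAULT_WEIGHT_MULTISET
    cv_folds: int = 10
    select_features: bool = False
    n_perm: int = 1000

    def as_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["sim"] = dataclasses.asdict(self.sim)
        d["weight_multiset"] = list(self.weight_multiset)
        return d


_TOP_KEYS = {f.name for f in dataclasses.fields(PipelineConfig)} - {"sim"}
_SIM_KEYS = {f.name for f in dataclasses.fields(sim.SimConfig)}


def validate_config(source: str | Path | dict, seed: int | None = None) -> PipelineConfig:
    """Parse and validate a YAML config (strict keys, all errors at once)."""
    if isinstance(source, dict):
        raw = dict(source)
    else:
        with open(source) as fh:
            raw = yaml.safe_load(fh) or {}
    errors: list[str] = []
    sim_raw = raw.pop("sim", {}) or {}
    for key in sorted(set(raw) - _TOP_KEYS):
        errors.append(f"unknown configuration key: {key!r}")
    for key in sorted(set(sim_raw) - _SIM_KEYS):
        errors.append(f"unknown sim key: {key!r}")
    raw = {k: v for k, v in raw.items() if k in _TOP_KEYS}
    sim_raw = {k: v for k, v in sim_raw.items() if k in _SIM_KEYS}
    if seed is not None:
        raw["seed"] = seed
        sim_raw["seed"] = seed

    tf = raw.get("train_fraction", 0.7)
    if not 0 < tf < 1:
        errors.append(f"train_fraction must lie in (0, 1), got {tf}")
    if raw.get("method", "voting") not in ("voting", "stacking"):
        errors.append(f"method must be voting|stacking, got {raw.get('method')!r}")
    if raw.get("cv_folds", 10) < 0:
        errors.append("cv_folds must be >= 0")
    if raw.get("n_perm", 1000) < 1:
        errors.append("n_perm must be >= 1")
    try:
        sim_cfg = sim.SimConfig(**sim_raw)
    except (ValueError, TypeError) as exc:
        errors.append(str(exc))
        sim_cfg = None
    if errors:
        raise ValueError("invalid configuration:\n  " + "\n  ".join(errors))
    if "weight_multiset" in raw:
        raw["weight_multiset"] = tuple(raw["weight_multiset"])
    return PipelineConfig(sim=sim_cfg, **raw)


def run_pipeline(cfg: PipelineConfig, outdir: str | Path) -> dict:
    """Full run: simulate -> featurize -> train -> score -> validate -> enrich.

    Returns the manifest (also written as ``run_manifest.json``); on a
    stage failure a FAILED marker naming the stage is left behind and
    the exception propagates.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"config": cfg.as_dict(), "outputs": {}, "stages": []}
    log_lines = [f"resolved config: {json.dumps(cfg.as_dict(), sort_keys=True)}",
                 f"master seed: {cfg.seed}"]
    log_lines += [f"interpretation: {n}" for n in _INTERPRETATION_NOTES]

    stage = "simulate"
    try:
        cohort_dir = outdir / "cohort"
        cohort = sim.generate(cfg.sim, outdir=cohort_dir)
        _record(manifest, stage, cohort_dir, ["features.tsv", "features.yaml",
                "go_annotations.tsv", "edges.tsv", "labels.tsv",
                "validation.gmt", "truth.json"])

        stage = "featurize"
        topo = compute_topology(cohort.graph)
        write_profiles(topo, outdir / "topology.tsv")
        model = PainGeneClassifier.from_cohort(
            cohort, seed=cfg.seed, weight_multiset=cfg.weight_multiset,
            train_fraction=cfg.train_fraction,
            n_go_components=cfg.n_go_components,
            corr_threshold=cfg.corr_threshold, topology_profiles=topo,
        )
        feat.write_feature_matrix(model.features, outdir / "feature_matrix.tsv")
        (outdir / "train_genes.txt").write_text("\n".join(model.train_genes) + "\n")
        (outdir / "val_genes.txt").write_text("\n".join(model.val_genes) + "\n")
        _record(manifest, stage, outdir, ["topology.tsv", "feature_matrix.tsv",
                                          "train_genes.txt", "val_genes.txt"])

        stage = "train"
        results = model.fit(method=cfg.method, cv_folds=cfg.cv_folds,
                            select_features=cfg.select_features)
        results.save(outdir)
        files = ["model_card.json", "pain_scores.tsv"]
        if results.cv is not None:
            results.cv.as_frame().to_csv(outdir / "cv_report.tsv", sep="\t",
                                         index_label="fold")
            files.append("cv_report.tsv")
        if results.feature_importance is not None:
            files.append("feature_importance.tsv")
        _record(manifest, stage, outdir, files)

        stage = "score"  # pain_scores.tsv written by results.save above
        _record(manifest, stage, outdir, ["pain_scores.tsv"])

        stage = "validate"
        scores = results.scores.table.set_index("gene_id")["pain_score"]
        yval = model.features.y.loc[model.val_genes]
        m = metric_set(confusion_from_predictions(
            yval.to_numpy(), (scores.loc[model.val_genes] >= 0.5).astype(int).to_numpy()))
        pd.DataFrame([m.as_dict()]).to_csv(outdir / "validation_report.tsv",
                                           sep="\t", index=False)
        _record(manifest, stage, outdir, ["validation_report.tsv"])

        stage = "enrich"
        sets = read_gmt(cohort_dir / "validation.gmt")
        report = validate_against_sets(results.scores, sets,
                                       results.training_positives,
                                       n_perm=cfg.n_perm, seed=cfg.seed)
        report.to_csv(outdir / "enrichment.tsv", sep="\t", index=False,
                      float_format="%.10g")
        _record(manifest, stage, outdir, ["enrichment.tsv"])
    except Exception as exc:
        (outdir / "FAILED").write_text(f"stage {stage}: {exc}\n")
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    log_lines.append(f"stages completed: {[s for s in manifest['stages']]}")
    (outdir / "run.log").write_text("\n".join(log_lines) + "\n")
    with open(outdir / "run_manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return manifest


def _record(manifest: dict, stage: str, base: Path, names: list[str]) -> None:
    for name in names:
        path = base / name
        if not path.exists():
            raise FileNotFoundError(f"stage {stage} did not produce {path}")
        manifest["outputs"][name] = str(path)
    manifest["stages"].append(stage)
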