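"""End-to-end orchestration: simulate -> pca -> tsp -> svm -> evaluate.

Every artifact is a plain-text TSV or JSON file; a ``manifest.json`` records
the seed, the package version, each artifact's SHA-256 checksum and the
stage inputs, so a rerun with the same configuration is verifiably
bit-identical for the deterministic stages.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import __version__
from .evaluate import bootstrap_epe, confusion, empirical_p, monte_carlo_null
from .exceptions import ValidationError
from .io import (
    TRAIN,
    VALIDATION,
    FeatureMatrix,
    read_feature_table,
    subset_split,
    write_feature_table,
)
from .pca import export_biplot_data, fit_pca
from .simulate import CohortConfig, generate_cohort
from .svm import SvmConfig, train_svm
from .tsp import fit_tsp

logger = logging.getLogger(__name__)

STAGES = ("simulate", "pca", "tsp", "svm", "evaluate")


@dataclass
class RunConfig:
    """Configuration of one pipeline run."""

    output_dir: Path
    input_path: Path | None = None  # None -> simulate a cohort
    label_column: str = "label"
    split_column: str = "split"
    delimiter: str = "\t"
    stages: tuple[str, ...] = STAGES
    seed: int = 0
    n_per_class: int = 47
    null_iterations: int = 10000
    bootstrap_replicates: int = 10000
    svm_config: SvmConfig | None = None

    def validate(self) -> None:
        unknown = [s for s in self.stages if s not in STAGES]
        if unknown:
            raise ValidationError(f"unknown stage(s): {unknown}; valid: {STAGES}")
        if self.input_path is None and "simulate" not in self.stages:
            raise ValidationError("no input_path and no simulate stage")
        if "svm" in self.stages and "tsp" not in self.stages:
            raise ValidationError("svm stage requires the tsp stage (pair selection)")
        if "evaluate" in self.stages and "tsp" not in self.stages:
            raise ValidationError("evaluate stage requires the tsp stage")


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _spawn_seeds(seed: int, n: int) -> list[int]:
    # independent substreams so each stage is individually reproducible
    state = np.random.SeedSequence(seed).generate_state(n)
    return [int(s % 2**31) for s in state]


def run_pipeline(config: RunConfig) -> dict:
    """Run the configured stages in dependency order; return the run report."""
    config.validate()
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = dict(zip(("simulate", "svm", "null_tsp", "null_svm", "boot_tsp", "boot_svm"),
                     _spawn_seeds(config.seed, 6)))
    artifacts: dict[str, dict] = {}
    report: dict = {"seed": config.seed, "stages": list(config.stages)}

    def register(name: str, path: Path, inputs: list[str]) -> None:
        artifacts[name] = {
            "path": path.name,
            "sha256": _sha256(path),
            "inputs": inputs,
        }

    # -- input ---------------------------------------------------------------
    if config.input_path is not None:
        fm = read_feature_table(
            config.input_path,
            label_column=config.label_column,
            split_column=config.split_column,
            delimiter=config.delimiter,
        )
        input_name = str(config.input_path)
    else:
        cohort = generate_cohort(
            CohortConfig(n_per_class=config.n_per_class, seed=seeds["simulate"])
        )
        path = cohort.write(out / "cohort.tsv")
        register("cohort", path, inputs=[f"seed={seeds['simulate']}"])
        fm = cohort.to_feature_matrix()
        input_name = "cohort.tsv"
        logger.info("simulated cohort: %d samples x %d features", fm.n_samples, fm.n_features)

    # -- pca -----------------------------------------------------------------
    if "pca" in config.stages:
        res = fit_pca(fm)
        for suffix, table in (
            ("scores", res.scores_table()),
            ("loadings", res.loadings_table()),
            ("variance", res.variance_table()),
        ):
            path = out / f"pca.{suffix}.tsv"
            table.to_csv(path, sep="\t", float_format="%.12g")
            register(f"pca_{suffix}", path, inputs=[input_name])
        if res.n_components >= 3:
            path = out / "pca.biplot.tsv"
            export_biplot_data(res).to_csv(path, sep="\t", float_format="%.12g")
            register("pca_biplot", path, inputs=[input_name])
        report["pca"] = {
            "n_components": res.n_components,
            "cumulative_top3": float(res.cumulative_ratio[min(2, res.n_components - 1)]),
        }

    train = subset_split(fm, TRAIN)
    valid = subset_split(fm, VALIDATION)

    # -- tsp -----------------------------------------------------------------
    tsp_model = None
    if "tsp" in config.stages:
        tsp_model = fit_tsp(train)
        path = tsp_model.save(out / "tsp_model.json")
        register("tsp_model", path, inputs=[input_name])
        pairs_path = out / "tsp_pair_scores.tsv"
        with pairs_path.open("w") as fh:
            fh.write("feature_i\tfeature_j\tp1\tp2\tdelta\tgamma\n")
            for s in tsp_model.pair_scores:
                fh.write(
                    f"{s.feature_i}\t{s.feature_j}\t{s.p1:.12g}\t{s.p2:.12g}"
                    f"\t{s.delta:.12g}\t{s.gamma:.12g}\n"
                )
        register("tsp_pair_scores", pairs_path, inputs=[input_name])
        pred = tsp_model.predict(valid)
        pred_path = out / "tsp_predictions.tsv"
        pred.rename_axis("sample_id").to_csv(pred_path, sep="\t")
        register("tsp_predictions", pred_path, inputs=["tsp_model.json", input_name])
        report["tsp"] = {
            "pair": list(tsp_model.pair),
            "orientation": tsp_model.orientation,
            "delta": tsp_model.delta,
        }

    # -- svm -----------------------------------------------------------------
    svm_model = None
    if "svm" in config.stages:
        if config.svm_config is not None:
            svm_cfg = config.svm_config
        else:
            smallest = int(train.labels.value_counts().min())
            svm_cfg = SvmConfig(cv_folds=min(10, smallest), seed=seeds["svm"])
        svm_model = train_svm(train.select_features(tsp_model.pair), svm_cfg)
        path = svm_model.save(out / "svm_model.json")
        register("svm_model", path, inputs=["tsp_model.json", input_name])
        report["svm"] = {
            "training_error": svm_model.training_error,
            "cv_error": svm_model.cv_error,
            "sigma": svm_model.sigma,
        }

    # -- evaluate ------------------------------------------------------------
    if "evaluate" in config.stages:
        evaluation: dict = {}
        lines: list[str] = []
        models = [("tsp", tsp_model)]
        if svm_model is not None:
            models.append(("svm", svm_model))
        for name, model in models:
            pred = model.predict(valid)
            cm = confusion(valid.labels, pred, class_levels=valid.class_levels)
            null = monte_carlo_null(
                model, valid, n_iterations=config.null_iterations,
                seed=seeds[f"null_{name}"],
            )
            pval = empirical_p(cm.prediction_error, null)
            boot = bootstrap_epe(
                model, valid, n_replicates=config.bootstrap_replicates,
                seed=seeds[f"boot_{name}"],
            )
            cm_path = out / f"{name}_confusion.tsv"
            cm.to_dataframe().to_csv(cm_path, sep="\t")
            register(f"{name}_confusion", cm_path, inputs=[f"{name}_model.json", input_name])
            evaluation[name] = {
                "confusion": cm.counts.tolist(),
                "correct": cm.correct,
                "total": cm.total,
                "accuracy": cm.accuracy,
                "epe": cm.prediction_error,
                "null_mean_error": null.mean_error,
                "p_value": pval.p,
                "p_r": pval.r,
                "bootstrap_mean_error": boot.mean_error,
                "ci_low": boot.ci_low,
                "ci_high": boot.ci_high,
            }
            lines += [
                f"== {name} model ==",
                f"confusion ({' / '.join(cm.class_levels)}):",
                cm.to_dataframe().to_string(),
                f"correctly classified: {cm.correct} of {cm.total} "
                f"({100 * cm.accuracy:.2f}%)",
                f"empirical prediction error: {cm.prediction_error:.4f}",
                f"Monte Carlo null mean error (N={null.n_iterations}): "
                f"{null.mean_error:.4f}",
                f"empirical p-value: {pval.p:.6g} (r={pval.r})",
                f"bootstrap mean error (R={boot.n_replicates}): "
                f"{boot.mean_error:.4f}, 95% BCa CI "
                f"[{boot.ci_low:.4f}, {boot.ci_high:.4f}]",
                "",
            ]
        eval_path = out / "evaluation.json"
        eval_path.write_text(json.dumps(evaluation, indent=2) + "\n")
        register("evaluation", eval_path, inputs=[input_name])
        report_path = out / "report.txt"
        report_path.write_text("\n".join(lines))
        register("report", report_path, inputs=["evaluation.json"])
        report["evaluation"] = evaluation

    manifest = {
        "package": "stresspair",
        "version": __version__,
        "seed": config.seed,
        "stage_seeds": seeds,
        "input": input_name,
        "artifacts": artifacts,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    report["manifest"] = manifest
    return report
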