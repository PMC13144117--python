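"""End-to-end orchestration: simulate-or-read, explore, select, combine, score.

A single declarative config (YAML or an in-memory dict) drives the run.
Exactly one of ``input`` (matrix + labels paths) or ``synthetic`` (a
:class:`~panselect.simulate.SyntheticSpec` block) must be present.  One
global seed fans out deterministically to per-stage seeds, so one number
reproduces the whole run.  Every stage writes its outputs under the
configured output directory, and a ``manifest.json`` records the config
echo, derived seeds, and per-stage row/feature counts.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as pio
from .annotate import cog_distribution, hypothetical_count, write_cog_tsv
from .consensus import build_consensus, write_venn_tsv
from .evaluate import evaluate_method, metrics_report
from .explore import cluster, elbow_select_k, run_pca
from .pangenome import LabeledPangenome
from .selectors import (
    METHODS,
    SelectorConfig,
    run_selector,
    write_selection_tsv,
)
from .simulate import SyntheticSpec, generate_pangenome, planted_truth

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "load_config", "run_all", "stage_seed"]

# Fixed per-stage offsets for the seed fan-out (one global seed reproduces all).
_STAGE_OFFSETS = {
    "simulate": 1,
    "explore": 2,
    "select_lr": 3,
    "select_svm": 4,
    "select_rf": 5,
    "evaluate": 6,
}


def stage_seed(global_seed: int, stage: str) -> int:
    """Deterministic per-stage seed derived from the global seed."""
    ss = np.random.SeedSequence([global_seed, _STAGE_OFFSETS[stage]])
    return int(ss.generate_state(1)[0] % (2**31))


@dataclass
class PipelineConfig:
    output_dir: str = "panselect_out"
    seed: int = 0
    matrix_path: str | None = None
    labels_path: str | None = None
    annotations_path: str | None = None
    fasta_path: str | None = None
    synthetic: SyntheticSpec | None = None
    selector_overrides: dict = field(default_factory=dict)  # method -> kwargs
    n_eval_iterations: int = 100
    test_fraction: float = 0.1
    cv_folds: int | None = 10
    run_explore: bool = True

    def __post_init__(self) -> None:
        has_input = self.matrix_path is not None
        has_synth = self.synthetic is not None
        if has_input == has_synth:
            raise ValueError(
                "exactly one of an input matrix path or a synthetic block is required"
            )
        if has_input and self.labels_path is None:
            raise ValueError("an input matrix requires a labels path")

    def selector_config(self, method: str) -> SelectorConfig:
        kwargs = dict(self.selector_overrides.get(method, {}))
        kwargs.setdefault("seed", stage_seed(self.seed, f"select_{method}"))
        return SelectorConfig(method=method, **kwargs)


def load_config(path: str | Path) -> PipelineConfig:
    """Build a PipelineConfig from a YAML file."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    synth = raw.pop("synthetic", None)
    if synth is not None:
        synth = SyntheticSpec(**synth)
    return PipelineConfig(synthetic=synth, **raw)


def _load_pangenome(config: PipelineConfig) -> LabeledPangenome:
    if config.synthetic is not None:
        spec = config.synthetic
        if spec.seed == 0:
            spec = dataclasses.replace(spec, seed=stage_seed(config.seed, "simulate"))
        return generate_pangenome(spec)
    matrix_path = Path(config.matrix_path)
    if matrix_path.suffix.lower() == ".csv":
        matrix = pio.read_presence_csv(matrix_path)
    else:
        matrix = pio.read_rtab(matrix_path)
    labels = pio.read_labels(config.labels_path)
    return pio.attach_labels(matrix, labels)


def run_all(config: PipelineConfig) -> dict:
    """Execute every stage and return the manifest dict (also written to disk)."""
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "seed": config.seed,
        "stages": {},
        "stage_seeds": {s: stage_seed(config.seed, s) for s in _STAGE_OFFSETS},
    }

    stage = "load"
    try:
        pangenome = _load_pangenome(config)
        manifest["stages"]["load"] = {
            "n_genomes": pangenome.n_genomes,
            "n_families": pangenome.n_families,
            "group_counts": {str(k): int(v) for k, v in pangenome.group_counts().items()},
        }
        pio.write_rtab(pangenome, outdir / "matrix.Rtab")
        pio.write_labels(pangenome.labels, outdir / "labels.tsv")

        if config.run_explore:
            stage = "explore"
            pca = run_pca(pangenome)
            k = elbow_select_k(
                pca.projection_2d,
                k_min=1,
                k_max=min(8, pangenome.n_genomes),
                seed=stage_seed(config.seed, "explore"),
            )
            assignment = cluster(
                pca.projection_2d, k, seed=stage_seed(config.seed, "explore")
            )
            pd.DataFrame(
                {
                    "component": np.arange(1, len(pca.cumulative_curve) + 1),
                    "cumulative_variance": pca.cumulative_curve,
                }
            ).to_csv(outdir / "pca_cumulative.tsv", sep="\t", index=False)
            pd.DataFrame(
                {
                    "genome_id": pangenome.genome_ids,
                    "pc1": pca.projection_2d[:, 0],
                    "pc2": pca.projection_2d[:, 1],
                    "cluster": assignment,
                }
            ).to_csv(outdir / "pca_projection.tsv", sep="\t", index=False)
            manifest["stages"]["explore"] = {
                "n_components_90": pca.n_components_90,
                "elbow_k": int(k),
            }

        stage = "select"
        selections = []
        for method in METHODS:
            sel = run_selector(pangenome, config.selector_config(method))
            write_selection_tsv(sel, outdir / f"selection_{method}.tsv")
            selections.append(sel)
        manifest["stages"]["select"] = {
            sel.method: {"n_retained": len(sel.retained)} for sel in selections
        }

        stage = "consensus"
        sequences = (
            pio.read_protein_fasta(config.fasta_path) if config.fasta_path else None
        )
        result = build_consensus(selections, sequences)
        write_venn_tsv(result, outdir / "venn_counts.tsv")
        (outdir / "union_nonredundant.txt").write_text(
            "".join(f + "\n" for f in sorted(result.union_nonredundant))
        )
        manifest["stages"]["consensus"] = {
            "per_method": result.per_method_counts,
            "venn": {r: len(s) for r, s in result.venn_regions.items()},
            "union_nonredundant": len(result.union_nonredundant),
        }

        stage = "evaluate"
        summaries = [
            evaluate_method(
                pangenome,
                config.selector_config(method),
                n_iterations=config.n_eval_iterations,
                test_fraction=config.test_fraction,
                cv_folds=config.cv_folds,
                seed=stage_seed(config.seed, "evaluate"),
            )
            for method in METHODS
        ]
        report = metrics_report(summaries)
        report.to_csv(outdir / "metrics.tsv", sep="\t", index=False)
        manifest["stages"]["evaluate"] = {
            row["method"]: {
                "roc_auc": row["ROC AUC"],
                "f1": row["F1-score"],
                "cv_accuracy": row["Cross-validation"],
                "accuracy": row["Accuracy"],
            }
            for row in report.to_dict("records")
        }

        if config.annotations_path:
            stage = "annotate"
            records = pio.read_emapper(config.annotations_path)
            subsets = {
                sel.method: set(sel.retained) for sel in selections
            }
            subsets["union"] = result.union_nonredundant
            distributions = {
                name: cog_distribution(records, subset) for name, subset in subsets.items()
            }
            write_cog_tsv(distributions, outdir / "cog_distribution.tsv")
            n_hypothetical = hypothetical_count(
                {
                    r.query_id: r.description
                    for r in records
                    if r.query_id in result.union_nonredundant
                }
            )
            manifest["stages"]["annotate"] = {
                "total_annotated_union": distributions["union"].total_annotated,
                "hypothetical_in_union": n_hypothetical,
            }

        if config.synthetic is not None:
            truth = planted_truth(config.synthetic)
            manifest["planted_truth_size"] = len(truth)
    except Exception as exc:
        raise RuntimeError(f"pipeline stage '{stage}' failed: {exc}") from exc

    (outdir / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True, default=float)
    )
    return manifest
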