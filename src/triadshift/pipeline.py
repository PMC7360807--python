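"""End-to-end orchestration: simulate -> deg -> bias -> enrich -> concord.

One :class:`PipelineConfig` (typically loaded from YAML) drives the whole
run. Every stage writes its TSV outputs under ``outdir`` and contributes
headline numbers to a machine-readable run summary (JSON sidecar). All
randomness flows from the single top-level seed, fanned out per stage
deterministically, so identical config + seed reproduce identical outputs.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import yaml

from . import __version__
from .concordance import concordance_report
from .diffexpr import proportion_test, test_differential
from .enrichment import enrich
from .errors import PipelineDependencyError, StageError
from .homoeobias import classify_triads, summarize_categories, trace_shifts
from .iodata import (
    read_annotation,
    read_expression_matrix,
    read_pyro_table,
    read_triad_map,
    write_annotation,
    write_expression_matrix,
    write_results,
    write_triad_map,
)
from .synthetic import GeneratorConfig, generate_dataset, generate_pyro_table

logger = logging.getLogger("triadshift")

__all__ = ["PipelineConfig", "run_pipeline"]

_STAGES = ("simulate", "deg", "bias", "enrich", "concord")


@dataclass
class PipelineConfig:
    """Configuration of a full pipeline run.

    When ``simulate`` is enabled the generator provides all inputs; when it
    is disabled, ``inputs`` must point at matrix/design/triads/annotation
    (and optionally pyro) TSVs.
    """

    outdir: str = "triadshift_run"
    seed: int = 0
    reference_condition: str = "hexaploid"
    test_condition: str = "nonaploid"
    expression_threshold: float = 0.5
    fold: float = 2.0
    fdr: float = 0.05
    pseudocount: float = 1.0
    max_distance: float = 0.15
    n_triads_assayed: int = 18
    pyro_noise_sd: float = 3.0
    stages: dict = field(default_factory=lambda: {s: True for s in _STAGES})
    generator: dict = field(default_factory=dict)
    inputs: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        toggles = {s: True for s in _STAGES}
        toggles.update(self.stages)
        unknown = set(toggles) - set(_STAGES)
        if unknown:
            raise PipelineDependencyError(f"unknown stages: {sorted(unknown)}")
        self.stages = toggles

    @classmethod
    def from_dict(cls, d: Mapping[str, Any]) -> "PipelineConfig":
        known = set(cls.__dataclass_fields__)
        unknown = set(d) - known
        if unknown:
            raise PipelineDependencyError(f"unknown config fields: {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh) or {}
        return cls.from_dict(d)

    def generator_config(self) -> GeneratorConfig:
        overrides = dict(self.generator)
        overrides.setdefault("seed", self.seed)
        overrides.setdefault("reference_condition", self.reference_condition)
        overrides.setdefault("test_condition", self.test_condition)
        overrides.setdefault("expression_threshold", self.expression_threshold)
        return GeneratorConfig.from_dict(overrides)


def _require(config: PipelineConfig, stage: str, needed: str) -> None:
    if not config.stages.get(needed, False):
        raise PipelineDependencyError(
            f"stage {stage!r} requires stage {needed!r}, which is disabled"
        )


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the enabled stages in dependency order; return the run summary.

    The summary (also written to ``outdir/run_summary.json``) holds per-stage
    record counts and headline statistics: expressed genes, DEG counts and
    the up-vs-down proportion test, activated/silenced counts, per-category
    triad proportions per condition, the conserved-shift fraction,
    significant GO terms per query class, and the concordance pass count.
    """
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    summary: dict[str, Any] = {
        "version": __version__,
        "seed": config.seed,
        "outdir": str(out),
        "stages": {s: bool(config.stages[s]) for s in _STAGES},
    }

    matrix = triads = annotation = truth = pyro = None
    deg_table = None
    classifications: dict[str, Any] = {}

    # --- simulate / load ------------------------------------------------------
    try:
        if config.stages["simulate"]:
            gen_cfg = config.generator_config()
            logger.info("simulating dataset (seed=%d)", gen_cfg.seed)
            matrix, triads, annotation, truth = generate_dataset(gen_cfg)
            pyro = generate_pyro_table(
                truth, config.n_triads_assayed, config.pyro_noise_sd
            )
            write_expression_matrix(matrix, out / "matrix.tsv", out / "design.tsv")
            write_triad_map(triads, out / "triads.tsv")
            write_annotation(annotation, out / "annotation.tsv")
            write_results(truth.triads, out / "truth_triads.tsv")
            write_results(truth.genes, out / "truth_genes.tsv")
            write_results(pyro, out / "pyro.tsv")
            with open(out / "generator_params.json", "w") as fh:
                json.dump(gen_cfg.to_dict(), fh, indent=2, sort_keys=True)
            summary["simulate"] = {
                "n_genes": int(matrix.values.shape[0]),
                "n_triads": len(triads),
                "n_annotation_pairs": int(len(annotation.pairs)),
                "enriched_term": truth.enriched_term,
            }
        else:
            inputs = config.inputs
            for key in ("matrix", "design", "triads"):
                if key not in inputs:
                    raise PipelineDependencyError(
                        f"stage 'simulate' disabled but no input path for {key!r}"
                    )
            matrix = read_expression_matrix(inputs["matrix"], inputs["design"])
            triads = read_triad_map(inputs["triads"])
            if "annotation" in inputs:
                annotation = read_annotation(inputs["annotation"])
            if "pyro" in inputs:
                pyro = read_pyro_table(inputs["pyro"])
    except Exception as exc:  # noqa: BLE001 - re-raise with stage context
        raise StageError("simulate", exc) from exc

    ref, tst = config.reference_condition, config.test_condition

    # --- differential expression ---------------------------------------------
    if config.stages["deg"]:
        try:
            logger.info("calling differential expression (%s vs %s)", tst, ref)
            deg_table = test_differential(
                matrix,
                ref,
                tst,
                pseudocount=config.pseudocount,
                fdr=config.fdr,
                fold=config.fold,
                threshold=config.expression_threshold,
            )
            write_results(
                deg_table.reset_index(), out / "deg.tsv", params=deg_table.attrs["params"]
            )
            counts = deg_table["status"].value_counts()
            n_up = int(counts.get("up", 0))
            n_down = int(counts.get("down", 0))
            prop = proportion_test(n_up, n_down) if (n_up + n_down) else None
            summary["deg"] = {
                "n_genes": int(len(deg_table)),
                "n_expressed": int((deg_table["status"] != "not_expressed").sum()),
                "n_up": n_up,
                "n_down": n_down,
                "n_activated": int(counts.get("activated", 0)),
                "n_silenced": int(counts.get("silenced", 0)),
                "prop_test_p": None if prop is None else prop.pvalue,
            }
        except Exception as exc:  # noqa: BLE001
            raise StageError("deg", exc) from exc

    # --- homoeolog bias -------------------------------------------------------
    if config.stages["bias"]:
        try:
            logger.info("classifying triad bias")
            bias_summary: dict[str, Any] = {}
            for role, cond in (("reference", ref), ("test", tst)):
                cls = classify_triads(
                    matrix, triads, cond, threshold=config.expression_threshold
                )
                classifications[role] = cls
                write_results(cls, out / f"bias_{cond}.tsv")
                summ = summarize_categories(cls)
                write_results(summ, out / f"bias_summary_{cond}.tsv")
                bias_summary[role] = {
                    "condition": cond,
                    "n_expressed_triads": int(cls["expressed"].sum()),
                    "proportions": dict(
                        zip(summ["category"], summ["proportion"].round(6))
                    ),
                }
            shifts = trace_shifts(classifications["reference"], classifications["test"])
            write_results(shifts.counts.reset_index(), out / "shift_matrix.tsv")
            write_results(shifts.to_long(), out / "shift_long.tsv")
            bias_summary["shift"] = {
                "n_traced": shifts.total,
                "n_conserved": shifts.conserved,
                "n_shifted": shifts.shifted,
                "conserved_fraction": shifts.conserved_fraction,
                "n_direct_opposite": shifts.n_direct_opposite,
            }
            summary["bias"] = bias_summary
        except Exception as exc:  # noqa: BLE001
            raise StageError("bias", exc) from exc

    # --- GO enrichment --------------------------------------------------------
    if config.stages["enrich"]:
        _require(config, "enrich", "deg")
        if annotation is None:
            raise StageError(
                "enrich", PipelineDependencyError("no annotation available")
            )
        try:
            logger.info("running GO enrichment")
            population = set(
                deg_table.index[deg_table["status"] != "not_expressed"]
            )
            enr_summary = {}
            for klass in ("up", "down", "activated", "silenced"):
                query = set(deg_table.index[deg_table["status"] == klass])
                if not query:
                    enr_summary[klass] = {"n_query": 0, "n_significant": 0}
                    continue
                table = enrich(query, annotation, population, fdr=config.fdr)
                write_results(table, out / f"enrich_{klass}.tsv")
                enr_summary[klass] = {
                    "n_query": len(query),
                    "n_tested_terms": int(len(table)),
                    "n_significant": int(table["significant"].sum()),
                    "top_term": table["term_id"].iloc[0] if len(table) else None,
                }
            summary["enrich"] = enr_summary
        except StageError:
            raise
        except Exception as exc:  # noqa: BLE001
            raise StageError("enrich", exc) from exc

    # --- pyro concordance -----------------------------------------------------
    if config.stages["concord"]:
        _require(config, "concord", "bias")
        if pyro is None:
            raise StageError(
                "concord", PipelineDependencyError("no pyrosequencing table available")
            )
        try:
            logger.info("checking pyrosequencing concordance")
            report = concordance_report(
                pyro, classifications["reference"], max_distance=config.max_distance
            )
            write_results(report.table, out / "concordance.tsv")
            summary["concord"] = report.summary()
        except StageError:
            raise
        except Exception as exc:  # noqa: BLE001
            raise StageError("concord", exc) from exc

    with open(out / "run_summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
    logger.info("run complete: %s", out / "run_summary.json")
    return summary
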