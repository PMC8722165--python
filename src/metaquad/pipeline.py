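"""End-to-end orchestration: simulate -> correct -> cluster -> subtype ->
score -> deconvolve -> survive/associate, with a JSON manifest and a log.

Each stage draws its randomness from a named substream derived by hashing
(run_seed, stage_name), so adding or toggling a stage never shifts another
stage's stream and stage-level reruns reproduce in isolation.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import batch_correct, cohort_stats, io_formats, metabolic_subtype, signature_scores
from .consensus_cluster import (
    consensus_cluster as _run_consensus,
    select_pathway_modules as _select_modules,
    zscore_rows as _zscore_rows,
)
from . import immune_deconv, synthetic_cohort
from .errors import ConfigError

log = logging.getLogger(__name__)

__all__ = ["RunConfig", "derive_seed", "run_pipeline"]

STAGES = ("simulate", "correct", "cluster", "subtype", "score", "deconvolve", "survive", "associate")


def derive_seed(run_seed: int, stage: str) -> int:
    """Deterministic per-stage seed below 2^31, keyed by stage name."""
    digest = hashlib.blake2s(f"{run_seed}:{stage}".encode(), digest_size=4).digest()
    return int.from_bytes(digest, "big") % (2**31)


@dataclass
class RunConfig:
    """Validated parameters for one pipeline run."""

    out_dir: str = "metaquad_run"
    seed: int = 0
    stages: tuple[str, ...] = STAGES
    simulation: dict = field(default_factory=dict)
    expression_path: str | None = None  # used instead of simulation when set
    clinical_path: str | None = None
    reps: int = 1000
    p_item: float = 0.8
    p_feature: float = 1.0
    k_max: int = 10
    fixed_k: int | None = 10
    delta_threshold: float = 0.05
    ssgsea_alpha: float = 0.75
    n_perm: int = 100
    alteration_mode: str = "cnv_loss"
    alteration_genes: tuple[str, ...] = ("RB1", "LRP1B")

    def __post_init__(self) -> None:
        unknown = set(self.stages) - set(STAGES)
        if unknown:
            raise ConfigError(f"unknown stage(s): {sorted(unknown)}")
        if "subtype" in self.stages and "cluster" not in self.stages:
            raise ConfigError("subtyping requires the cluster stage (no modules file given)")
        if "cluster" in self.stages and "correct" not in self.stages:
            raise ConfigError("clustering requires the correct stage")
        if "simulate" not in self.stages and self.expression_path is None:
            raise ConfigError("either enable the simulate stage or give expression_path")
        if not (0 < self.p_item <= 1) or not (0 < self.p_feature <= 1):
            raise ConfigError("p_item and p_feature must lie in (0, 1]")
        if self.reps < 1 or self.k_max < 2 or self.n_perm < 0:
            raise ConfigError("reps >= 1, k_max >= 2, n_perm >= 0 required")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "stages" in raw:
            raw["stages"] = tuple(raw["stages"])
        if "alteration_genes" in raw:
            raw["alteration_genes"] = tuple(raw["alteration_genes"])
        return cls(**raw)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: RunConfig) -> Path:
    """Execute the configured stages in order; returns the run directory.

    Every stage writes its outputs under the run directory and records
    parameters + output checksums in manifest.json. A stage failure aborts
    the run but retains the partial manifest.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "run.log")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(name)s %(message)s"))
    root = logging.getLogger("metaquad")
    root.addHandler(handler)
    root.setLevel(logging.INFO)

    manifest: dict = {"seed": config.seed, "parameters": asdict(config), "stages": {}}

    def record(stage: str, outputs: dict[str, Path], extra: dict | None = None) -> None:
        manifest["stages"][stage] = {
            "seed": derive_seed(config.seed, stage),
            "outputs": {k: {"path": str(p), "sha256": _sha256(p)} for k, p in outputs.items()},
            **(extra or {}),
        }
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))

    truth = variants = clinical = signature = None
    try:
        if "simulate" in config.stages:
            cfg = synthetic_cohort.SimulationConfig(
                **{**config.simulation, "seed": derive_seed(config.seed, "simulate")}
            )
            expr, clinical, variants, truth, signature = synthetic_cohort.simulate_cohorts(cfg)
            io_formats.write_expression(expr, out / "expression.tsv")
            io_formats.write_clinical(clinical, out / "clinical.tsv")
            io_formats.write_variants(variants, out / "snv.tsv", out / "cnv.tsv")
            io_formats.write_gmt(cfg.pathway_sets(), out / "pathways.gmt")
            truth.activities.to_csv(out / "truth.tsv", sep="\t")
            signature.rename_axis("gene").to_csv(out / "signature.tsv", sep="\t")
            record(
                "simulate",
                {
                    "expression": out / "expression.tsv",
                    "clinical": out / "clinical.tsv",
                    "snv": out / "snv.tsv",
                    "cnv": out / "cnv.tsv",
                    "pathways": out / "pathways.gmt",
                    "truth": out / "truth.tsv",
                    "signature": out / "signature.tsv",
                },
            )
            pathway_sets = cfg.pathway_sets()
        else:
            expr = io_formats.read_expression(config.expression_path)
            if config.clinical_path:
                clinical = io_formats.read_clinical(config.clinical_path)
            pathway_sets = None

        if "correct" in config.stages:
            corrected, _model = batch_correct.combat_correct(expr)
            report = batch_correct.pca_batch_check(expr, corrected)
            io_formats.write_expression(corrected, out / "corrected.tsv")
            (out / "pca_report.json").write_text(
                json.dumps(
                    {k: v for k, v in report.items() if not k.startswith("pc_scores")}, indent=2
                )
            )
            record(
                "correct",
                {"corrected": out / "corrected.tsv", "pca_report": out / "pca_report.json"},
                {"silhouette_before": report["silhouette_before"],
                 "silhouette_after": report["silhouette_after"]},
            )
            expr = corrected

        modules = None
        zscored = None
        if "cluster" in config.stages:
            if pathway_sets is None:
                raise ConfigError("clustering needs pathway gene sets (simulate stage provides them)")
            pathway_genes = [
                g
                for name in pathway_sets.names
                for g in pathway_sets.genes(name)
                if g in set(expr.gene_ids)
            ]
            zscored = _zscore_rows(expr)
            sub = zscored.subset_genes([g for g in pathway_genes if g in set(zscored.gene_ids)])
            result = _run_consensus(
                sub,
                k_range=range(2, config.k_max + 1),
                reps=config.reps,
                p_item=config.p_item,
                p_feature=config.p_feature,
                seed=derive_seed(config.seed, "cluster"),
                fixed_k=config.fixed_k,
                delta_threshold=config.delta_threshold,
            )
            modules = _select_modules(
                result,
                pathway_sets.genes("GLYCOLYSIS"),
                pathway_sets.genes("CHOLESTEROL_BIOSYNTHESIS"),
                Z=sub,
            )
            pd.DataFrame(
                {"gene": result.items, "cluster": result.labels[result.chosen_k]}
            ).to_csv(out / "clusters.tsv", sep="\t", index=False)
            area = pd.DataFrame(
                {"k": result.k_values, "area": [result.area[k] for k in result.k_values],
                 "delta": [result.delta_area[k] for k in result.k_values]}
            )
            area.to_csv(out / "cdf_area.tsv", sep="\t", index=False)
            io_formats.write_gmt(
                io_formats.GeneSetCollection(
                    {"MODULE_GLYCOLYTIC": ("co-expressed module", modules[0]),
                     "MODULE_CHOLESTEROGENIC": ("co-expressed module", modules[1])}
                ),
                out / "modules.gmt",
            )
            record(
                "cluster",
                {"clusters": out / "clusters.tsv", "cdf_area": out / "cdf_area.tsv",
                 "modules": out / "modules.gmt"},
                {"chosen_k": result.chosen_k},
            )

        assignment = None
        if "subtype" in config.stages:
            assignment = metabolic_subtype.subtype_cohort(zscored, modules[0], modules[1])
            assignment.table.rename_axis("sample").to_csv(out / "subtypes.tsv", sep="\t")
            extra = {"proportions": assignment.proportions.to_dict()}
            if truth is not None:
                acc = float((assignment.labels == truth.labels).mean())
                extra["subtype_recovery_accuracy"] = acc
            record("subtype", {"subtypes": out / "subtypes.tsv"}, extra)

        if "score" in config.stages and assignment is not None:
            anchors = [a for a in ("PDK1", "PDK2", "PDK3") if a in set(expr.gene_ids)]
            screen = signature_scores.correlation_screen(expr, anchors=anchors)
            pd.Series(screen.intersection, name="gene").to_csv(
                out / "pdk_intersection.tsv", sep="\t", index=False
            )
            if clinical is not None and "stemness_index" in clinical.records.columns:
                scores = clinical.records["stemness_index"].to_frame("stemness_index").T
            else:  # fall back to the module median scores themselves
                scores = assignment.table[["score_g", "score_c"]].T
            comp = signature_scores.score_group_comparison(scores, assignment.labels)
            comp.to_csv(out / "score_anova.tsv", sep="\t")
            record(
                "score",
                {"pdk_intersection": out / "pdk_intersection.tsv",
                 "score_anova": out / "score_anova.tsv"},
                {"n_pdk_intersection": len(screen.intersection)},
            )

        if "deconvolve" in config.stages and signature is not None:
            est = immune_deconv.deconvolve(
                expr.values.loc[[g for g in signature.index if g in set(expr.gene_ids)]],
                signature,
                n_perm=config.n_perm,
                seed=derive_seed(config.seed, "deconvolve"),
            )
            est.fractions.to_csv(out / "fractions.tsv", sep="\t")
            record("deconvolve", {"fractions": out / "fractions.tsv"})

        if "survive" in config.stages and clinical is not None and assignment is not None:
            fit = cohort_stats.km_logrank(clinical, assignment.labels)
            cox = cohort_stats.cox_fit(
                clinical, labels=assignment.labels, covariates=("age", "gender", "grade", "stage")
            )
            cox.summary.rename_axis("term").to_csv(out / "cox.tsv", sep="\t")
            record(
                "survive",
                {"cox": out / "cox.tsv"},
                {"logrank_stat": fit.logrank_stat, "logrank_p": fit.logrank_p},
            )

        if "associate" in config.stages and variants is not None and assignment is not None:
            tests = cohort_stats.alteration_frequency_test(
                variants, assignment.labels, list(config.alteration_genes),
                mode=config.alteration_mode,
            )
            rows = [
                {"gene": g, "p": r.p, "q": r.q, **{f"pct_{k}": v for k, v in r.frequencies.items()}}
                for g, r in tests.items()
            ]
            pd.DataFrame(rows).to_csv(out / "alterations.tsv", sep="\t", index=False)
            record("associate", {"alterations": out / "alterations.tsv"})
    except Exception as exc:
        manifest["error"] = {"stage": _current_stage(manifest), "message": str(exc)}
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
        root.removeHandler(handler)
        handler.close()
        raise
    root.removeHandler(handler)
    handler.close()
    return out


def _current_stage(manifest: dict) -> str:
    done = list(manifest["stages"])
    for s in STAGES:
        if s not in done:
            return s
    return "unknown"
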