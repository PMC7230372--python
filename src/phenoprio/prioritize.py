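"""Combine phenotype and genotype scores and rank candidate genes.

The combined score is a two-feature logistic regression over the genotype
(variant) score and the phenotype score, trained on labelled
disease/benign score pairs with 10-fold cross-validation; a fitted default
model ships with the package.  When the phenotype prioritiser is disabled,
the combined score reduces to the genotype score (variant-only analysis).

Genes are ranked per mode of inheritance by descending combined score; tied
scores share the average of the rank positions they span.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import expit
from scipy.stats import rankdata
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold, cross_val_score

from .config import AnalysisConfig
from .inheritance import AnalysisMoi, ModeOfInheritance
from .knowledge import KnowledgeBase
from .phenotype import PhenotypeMatchResult, PhenotypeProfile, apply_moi_consistency_penalty
from .scoring import (
    GenotypeScore,
    genotype_score,
    report_round,
    select_contributing,
    variant_score,
)
from .variants import (
    assemble_candidate_genotypes,
    max_maf,
    parse_vcf,
    quality_filter,
    variant_effect_filter,
)

__all__ = [
    "CombinerModel",
    "GeneResult",
    "AnalysisResult",
    "combine",
    "train_combiner",
    "default_combiner",
    "rank_results",
    "run_analysis",
]


@dataclass(frozen=True)
class CombinerModel:
    """Logistic coefficients combining genotype and phenotype scores."""

    intercept: float
    w_variant: float
    w_phenotype: float

    def __post_init__(self) -> None:
        if self.w_variant <= 0 or self.w_phenotype <= 0:
            warnings.warn(
                "combiner weights are not both positive; the combined score "
                "is no longer monotone in its inputs",
                stacklevel=2,
            )

    def combine(self, phenotype_score: float, genotype_score: float) -> float:
        return float(
            expit(
                self.intercept
                + self.w_variant * genotype_score
                + self.w_phenotype * phenotype_score
            )
        )

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "intercept": self.intercept,
                    "w_variant": self.w_variant,
                    "w_phenotype": self.w_phenotype,
                },
                fh,
                indent=2,
            )

    @classmethod
    def from_json(cls, path) -> "CombinerModel":
        with open(path) as fh:
            doc = json.load(fh)
        return cls(doc["intercept"], doc["w_variant"], doc["w_phenotype"])


def combine(
    phenotype_score: float, genotype_score: float, model: CombinerModel
) -> float:
    """Logistic combination of the two scores under *model* (already in [0, 1])."""
    return model.combine(phenotype_score, genotype_score)


def train_combiner(
    phenotype_scores: Sequence[float],
    genotype_scores: Sequence[float],
    is_disease: Sequence[int],
    folds: int = 10,
    seed: int = 0,
) -> tuple[CombinerModel, float]:
    """Maximum-likelihood logistic fit with stratified k-fold CV accuracy.

    Returns the fitted model and the mean cross-validated accuracy; errors
    on degenerate single-class data.
    """
    X = np.column_stack([np.asarray(genotype_scores), np.asarray(phenotype_scores)])
    y = np.asarray(is_disease, dtype=int)
    if len(np.unique(y)) < 2:
        raise ValueError("training data must contain both classes")
    clf = LogisticRegression(C=1e6, solver="lbfgs", max_iter=1000)
    cv = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    accuracy = float(cross_val_score(clf, X, y, cv=cv, scoring="accuracy").mean())
    clf.fit(X, y)
    model = CombinerModel(
        intercept=float(clf.intercept_[0]),
        w_variant=float(clf.coef_[0][0]),
        w_phenotype=float(clf.coef_[0][1]),
    )
    return model, accuracy


def default_combiner() -> CombinerModel:
    """The packaged combiner, fit once on seeded synthetic training pairs."""
    ref = resources.files("phenoprio").joinpath("data/combiner_default.json")
    with resources.as_file(ref) as path:
        return CombinerModel.from_json(path)


@dataclass(frozen=True)
class GeneResult:
    gene: str
    moi: AnalysisMoi
    phenotype_score: float
    genotype_score: float
    combined_score: float
    contributing: tuple[tuple, ...]  # variant keys
    best_genotype: GenotypeScore
    phenotype_detail: PhenotypeMatchResult | None = None
    rank: float | None = None


def rank_results(results: Sequence[GeneResult]) -> list[GeneResult]:
    """Sort descending by combined score and assign tie-averaged (mid)ranks."""
    if not results:
        return []
    scores = np.array([r.combined_score for r in results])
    ranks = rankdata(-scores, method="average")
    ranked = [replace(r, rank=float(k)) for r, k in zip(results, ranks)]
    ranked.sort(key=lambda r: (r.rank, r.gene))
    return ranked


@dataclass
class AnalysisResult:
    gene_results: dict[AnalysisMoi, list[GeneResult]]
    variants: pd.DataFrame
    filter_counts: dict[str, int]

    def write(self, prefix) -> list[Path]:
        """Emit per-MOI ranked TSVs, the variant-level TSV and a JSON summary."""
        prefix = Path(prefix)
        prefix.parent.mkdir(parents=True, exist_ok=True)
        written: list[Path] = []
        for moi, results in self.gene_results.items():
            path = Path(f"{prefix}_{moi.value}.tsv")
            rows = []
            for r in results:
                detail = r.phenotype_detail
                rows.append(
                    {
                        "RANK": r.rank,
                        "GENE": r.gene,
                        "MOI": moi.value,
                        "COMBINED_SCORE": report_round(r.combined_score),
                        "PHENOTYPE_SCORE": report_round(r.phenotype_score),
                        "VARIANT_SCORE": report_round(r.genotype_score),
                        "MOI_PENALIZED": bool(detail and detail.moi_penalized),
                        "BEST_PHENO_SOURCE": (
                            detail.best_model.source.value
                            if detail and detail.best_model
                            else ""
                        ),
                        "VIA_NEIGHBOR": detail.via_neighbor if detail else "",
                        "CONTRIBUTING": ";".join(
                            f"{c}:{p}:{ref}:{alt}" for c, p, ref, alt in r.contributing
                        ),
                    }
                )
            pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
            written.append(path)
        vpath = Path(f"{prefix}_variants.tsv")
        self.variants.to_csv(vpath, sep="\t", index=False)
        written.append(vpath)
        jpath = Path(f"{prefix}_summary.json")
        with open(jpath, "w") as fh:
            json.dump(
                {
                    "filter_counts": self.filter_counts,
                    "genes_per_moi": {
                        moi.value: len(res) for moi, res in self.gene_results.items()
                    },
                },
                fh,
                indent=2,
            )
        written.append(jpath)
        return written


def run_analysis(
    config: AnalysisConfig,
    knowledge: KnowledgeBase,
    *,
    sex: str = "unknown",
    combiner: CombinerModel | None = None,
    neighbor_weight: float = 0.75,
) -> AnalysisResult:
    """Execute the full pipeline for one patient.

    Filter cascade (in configured step order) -> per-MOI candidate genotype
    assembly -> variant/genotype scoring with contributing-variant selection
    -> gene phenotype scores with the inheritance-consistency penalty ->
    logistic combination -> per-MOI tie-average ranking.  With the phenotype
    prioritiser disabled the combined score is the genotype score.
    """
    if config.vcf_path is None:
        raise ValueError("config.vcf_path is not set")
    if not config.hpo_ids and config.run_hiphive:
        raise ValueError("phenotype-aware analysis needs a patient HPO profile")

    records = parse_vcf(
        config.vcf_path,
        pass_only=config.analysis_mode == "PASS_ONLY",
        sex=sex,
        frequencies=knowledge.frequencies,
        pathogenicity=knowledge.pathogenicity,
        whitelist=knowledge.whitelist,
    )
    counts = {"parsed": len(records)}
    surviving = records
    for step in config.steps:
        if step == "qualityFilter":
            surviving = [v for v in surviving if quality_filter(v, config.min_quality)]
        elif step == "variantEffectFilter":
            surviving = [
                v for v in surviving if variant_effect_filter(v, config.remove_effects)
            ]
        elif step == "frequencyFilter":
            surviving = [
                v
                for v in surviving
                if v.whitelisted
                or max_maf(v, config.frequency_sources) <= config.max_frequency
            ]
        else:
            continue
        counts[step] = len(surviving)

    breakdowns = {
        v.key: variant_score(v, config.frequency_sources, config.pathogenicity_sources)
        for v in surviving
    }
    if "pathogenicityFilter" in config.steps and not config.keep_non_pathogenic:
        surviving = [
            v
            for v in surviving
            if v.whitelisted or breakdowns[v.key].pathogenicity_score >= 0.5
        ]
        counts["pathogenicityFilter"] = len(surviving)

    by_gene: dict[str, list] = {}
    for v in surviving:
        by_gene.setdefault(v.gene, []).append(v)

    # candidate genotypes, grouped by reporting-level MOI
    per_moi: dict[AnalysisMoi, dict[str, list[GenotypeScore]]] = {}
    for sub_moi in config.inheritance_modes:
        analysis_moi = sub_moi.analysis_moi
        bucket = per_moi.setdefault(analysis_moi, {})
        for gene, gene_vars in by_gene.items():
            cands = assemble_candidate_genotypes(
                gene_vars,
                sub_moi,
                config.inheritance_modes,
                frequency_sources=config.frequency_sources,
                sex=sex,
            )
            if cands:
                bucket.setdefault(gene, []).extend(
                    genotype_score(c, breakdowns) for c in cands
                )

    scorer = (
        knowledge.scorer(neighbor_weight=neighbor_weight) if config.run_hiphive else None
    )
    query = (
        PhenotypeProfile.of(config.hpo_ids).resolved(knowledge.ontology)
        if config.run_hiphive
        else None
    )
    model = combiner or (default_combiner() if config.run_hiphive else None)

    gene_results: dict[AnalysisMoi, list[GeneResult]] = {}
    for analysis_moi, genes in per_moi.items():
        results: list[GeneResult] = []
        for gene in sorted(genes):
            best = select_contributing(genes[gene], breakdowns)
            if best is None:
                continue
            if scorer is not None:
                detail = scorer.score_gene(query, gene)
                if config.run_omim:
                    detail = apply_moi_consistency_penalty(detail, analysis_moi)
                phenotype = detail.score
                combined = model.combine(phenotype, best.score)
            else:
                detail = None
                phenotype = 0.0
                combined = best.score
            results.append(
                GeneResult(
                    gene=gene,
                    moi=analysis_moi,
                    phenotype_score=phenotype,
                    genotype_score=best.score,
                    combined_score=combined,
                    contributing=tuple(v.key for v in best.contributing),
                    best_genotype=best,
                    phenotype_detail=detail,
                )
            )
        gene_results[analysis_moi] = rank_results(results)

    variant_rows = []
    contributing_keys = {
        (moi, key)
        for moi, results in gene_results.items()
        for r in results
        for key in r.contributing
    }
    for v in surviving:
        b = breakdowns[v.key]
        variant_rows.append(
            {
                "CHROM": v.chrom,
                "POS": v.pos,
                "REF": v.ref,
                "ALT": v.alt,
                "GENE": v.gene,
                "CONSEQUENCE": v.consequence.value,
                "GENOTYPE": v.genotype.value,
                "MAX_MAF": b.max_maf,
                "FREQUENCY_SCORE": report_round(b.frequency_score),
                "PATHOGENICITY_SCORE": report_round(b.pathogenicity_score),
                "VARIANT_SCORE": report_round(b.variant_score),
                "WHITELIST": v.whitelisted,
                "CONTRIBUTING": any(
                    (moi, v.key) in contributing_keys for moi in gene_results
                ),
            }
        )
    variants_df = pd.DataFrame(variant_rows)
    return AnalysisResult(
        gene_results=gene_results, variants=variants_df, filter_counts=counts
    )
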