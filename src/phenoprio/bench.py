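"""Cohort benchmarking: where does the correct diagnosed genotype rank?

For each patient the pipeline is run and the rank of the causal gene in the
ranked table of the solved mode of inheritance is noted (AR for homozygous
and compound-heterozygous truths, AD for heterozygous, XR for hemizygous).
A causal gene absent from that table is "filtered out"; a causal gene whose
contributing variants do not include all diagnosed variants is "not
prioritized" (its gene rank is kept for reporting).
"""

from __future__ import annotations

from typing import Iterable

from .config import AnalysisConfig
from .prioritize import AnalysisResult, CombinerModel, run_analysis
from .simulate import Cohort, TruthRecord
from .stats import FILTERED_OUT, NOT_PRIORITIZED, RankOutcome

__all__ = ["rank_outcome_for_truth", "benchmark_cohort"]


def rank_outcome_for_truth(result: AnalysisResult, truth: TruthRecord) -> RankOutcome:
    """Classify one patient's result against its ground truth."""
    results = result.gene_results.get(truth.moi, [])
    hit = next((r for r in results if r.gene == truth.gene), None)
    if hit is None:
        return RankOutcome(truth.patient_id, sentinel=FILTERED_OUT)
    if set(truth.variants) <= set(hit.contributing):
        return RankOutcome(truth.patient_id, rank=hit.rank)
    return RankOutcome(
        truth.patient_id,
        sentinel=NOT_PRIORITIZED,
        gene_rank_if_not_prioritized=hit.rank,
    )


def benchmark_cohort(
    cohort: Cohort,
    config: AnalysisConfig,
    combiner: CombinerModel | None = None,
    patients: Iterable[str] | None = None,
) -> list[RankOutcome]:
    """Run one analysis setting over a generated cohort and collect outcomes."""
    wanted = set(patients) if patients is not None else None
    outcomes: list[RankOutcome] = []
    for truth in cohort.truths:
        if wanted is not None and truth.patient_id not in wanted:
            continue
        patient_config = config.with_vcf(
            cohort.vcf_path(truth.patient_id), truth.profile
        )
        result = run_analysis(
            patient_config, cohort.knowledge, sex=truth.sex, combiner=combiner
        )
        outcomes.append(rank_outcome_for_truth(result, truth))
    return outcomes
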