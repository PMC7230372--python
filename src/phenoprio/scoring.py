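"""Variant and genotype scoring: rarity x predicted pathogenicity.

The variant score in [0, 1] is the product of a frequency score and a
pathogenicity score.  The frequency score maps the maximum minor allele
frequency f (percent, across the selected reference datasets) through

    1.13533 - 0.13533 * exp(f)

clamped to 1 at f = 0 and to 0 for f > 2 percent.  (The exponent is
100 * f with f expressed as a proportion, which equals f on the percent
scale used throughout.)  The pathogenicity score is the maximum of the
selected source scores after normalization to [0, 1], overridden by fixed
values for clinically unambiguous consequence classes, or by a
consequence-based preset when no source has data.  Whitelisted variants
receive a variant score of 1 outright.

For a compound-heterozygote candidate, the genotype score is the arithmetic
mean of its two variant scores; for all other candidates it is the single
variant score.  Within each gene and mode of inheritance, the best-scoring
candidate genotype's variants are flagged as "contributing".
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

from .variants import (
    CandidateGenotype,
    Consequence,
    LOSS_OF_FUNCTION,
    VariantRecord,
    max_maf,
)
from .inheritance import ModeOfInheritance

__all__ = [
    "VariantScoreBreakdown",
    "GenotypeScore",
    "frequency_score",
    "normalize_source_score",
    "pathogenicity_score",
    "variant_score",
    "genotype_score",
    "select_contributing",
    "CONSEQUENCE_PRESETS",
    "report_round",
]

#: Preset pathogenicity used when no selected source has data for a variant.
#: Only the inframe value is attested by a worked example; the others are
#: package defaults chosen monotone with clinical severity.
CONSEQUENCE_PRESETS: dict[Consequence, float] = {
    Consequence.MISSENSE_VARIANT: 0.6,
    Consequence.INFRAME_DELETION: 0.85,
    Consequence.INFRAME_INSERTION: 0.85,
    Consequence.SYNONYMOUS_VARIANT: 0.1,
}

SPLICE_REGION_SCORE = 0.8
FIXED_LOF_SCORE = 1.0


def report_round(x: float, ndigits: int = 3) -> float:
    """Round-half-even for reported scores; internal math stays full precision."""
    return round(x, ndigits)


def frequency_score(f: float) -> float:
    """Frequency score in [0, 1] from the maximum MAF *f* in percent."""
    if f < 0:
        raise ValueError(f"allele frequency must be non-negative, got {f}")
    if f == 0.0:
        return 1.0
    if f > 2.0:
        return 0.0
    score = 1.13533 - 0.13533 * math.exp(f)
    return min(max(score, 0.0), 1.0)


_IDENTITY_SOURCES = frozenset(
    {
        "POLYPHEN",
        "MUTATION_TASTER",
        "REVEL",
        "M_CAP",
        "MPC",
        "MVP",
        "PRIMATE_AI",
    }
)


def normalize_source_score(source: str, raw: float) -> float:
    """Map a source's native score onto [0, 1], 1 being most pathogenic.

    SIFT is inverted (0 is most deleterious), CADD phred scores are mapped
    through ``1 - 10**(-phred/10)``, and the remaining sources are already
    pathogenicity probabilities (clamped).
    """
    source = source.upper().replace("-", "_")
    if source == "SIFT":
        value = 1.0 - raw
    elif source == "CADD":
        value = 1.0 - 10.0 ** (-raw / 10.0)
    elif source in _IDENTITY_SOURCES:
        value = raw
    else:
        warnings.warn(
            f"no normalization registered for source {source!r}; clamping raw value",
            stacklevel=2,
        )
        value = raw
    if not 0.0 <= value <= 1.0:
        warnings.warn(
            f"normalized {source} score {value:.4g} outside [0, 1]; clamped",
            stacklevel=2,
        )
        value = min(max(value, 0.0), 1.0)
    return value


def pathogenicity_score(
    v: VariantRecord, selected_sources: Sequence[str]
) -> tuple[float, str]:
    """Pathogenicity score in [0, 1] plus the label of the winning path.

    Loss-of-function classes are fixed at 1.0 and splice-region variants at
    0.8 regardless of source predictions; otherwise the maximum normalized
    selected source wins, falling back to the consequence preset table.
    """
    if v.consequence in LOSS_OF_FUNCTION:
        return FIXED_LOF_SCORE, f"fixed:{v.consequence.value}"
    if v.consequence is Consequence.SPLICE_REGION_VARIANT:
        return SPLICE_REGION_SCORE, "fixed:SPLICE_REGION_VARIANT"
    available = [
        (normalize_source_score(s, v.pathogenicity[s]), s)
        for s in selected_sources
        if s in v.pathogenicity
    ]
    if available:
        score, source = max(available, key=lambda t: (t[0], t[1]))
        return score, source
    preset = CONSEQUENCE_PRESETS.get(v.consequence, 0.0)
    return preset, f"preset:{v.consequence.value}"


@dataclass(frozen=True)
class VariantScoreBreakdown:
    frequency_score: float
    pathogenicity_score: float
    variant_score: float
    whitelist_override: bool
    winning_path_source: str
    max_maf: float


def variant_score(
    v: VariantRecord,
    frequency_sources: Sequence[str],
    pathogenicity_sources: Sequence[str],
) -> VariantScoreBreakdown:
    """Score one variant: frequency x pathogenicity, or 1.0 when whitelisted."""
    f = max_maf(v, frequency_sources)
    freq = frequency_score(f)
    path, provenance = pathogenicity_score(v, pathogenicity_sources)
    if v.whitelisted:
        return VariantScoreBreakdown(
            frequency_score=freq,
            pathogenicity_score=path,
            variant_score=1.0,
            whitelist_override=True,
            winning_path_source=provenance,
            max_maf=f,
        )
    return VariantScoreBreakdown(
        frequency_score=freq,
        pathogenicity_score=path,
        variant_score=freq * path,
        whitelist_override=False,
        winning_path_source=provenance,
        max_maf=f,
    )


@dataclass(frozen=True)
class GenotypeScore:
    genotype: CandidateGenotype
    score: float
    contributing: tuple[VariantRecord, ...]


def genotype_score(
    g: CandidateGenotype,
    breakdowns: Mapping[tuple, VariantScoreBreakdown],
) -> GenotypeScore:
    """Mean of the two variant scores for a compound het; the single score otherwise."""
    scores = [breakdowns[v.key].variant_score for v in g.variants]
    return GenotypeScore(
        genotype=g,
        score=sum(scores) / len(scores),
        contributing=tuple(g.variants),
    )


def _tie_break_key(
    gs: GenotypeScore, breakdowns: Mapping[tuple, VariantScoreBreakdown]
) -> tuple:
    # deterministic preference among equal scores: more pathogenic, rarer,
    # then genomic position
    paths = sorted(
        (breakdowns[v.key].pathogenicity_score for v in gs.genotype.variants),
        reverse=True,
    )
    mafs = sorted(breakdowns[v.key].max_maf for v in gs.genotype.variants)
    positions = sorted((v.chrom, v.pos, v.alt) for v in gs.genotype.variants)
    return (
        -gs.score,
        tuple(-p for p in paths),
        tuple(mafs),
        tuple(positions),
    )


def select_contributing(
    genotype_scores: Sequence[GenotypeScore],
    breakdowns: Mapping[tuple, VariantScoreBreakdown],
) -> GenotypeScore | None:
    """Pick the best-scoring candidate genotype of a gene/MOI bucket.

    Its variants are the gene's "contributing" variants for that mode; ties
    resolve deterministically by higher pathogenicity, lower frequency, then
    position.
    """
    if not genotype_scores:
        return None
    return min(genotype_scores, key=lambda gs: _tie_break_key(gs, breakdowns))
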