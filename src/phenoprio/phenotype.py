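"""Gene-specific phenotype scoring against cross-species annotations.

A patient's phenotype profile (a small set of ontology terms) is compared
with every known phenotype annotation of a candidate gene: human diseases,
mouse and zebrafish models, and — scaled down — the models of
protein-interaction neighbours.  The per-term-pair similarity is the
PhenoDigm-style geometric mean of ancestor-set Jaccard overlap and the
information content of the most informative common ancestor:

    score(q, h) = sqrt( jaccard(q, h) * IC(MICA(q, h)) )

Profile-level similarity normalizes the best and mean per-query-term scores
by their self-match ideals, so a profile matched against itself scores 1.

If the winning match is a human disease whose annotated mode of inheritance
is inconsistent with the candidate genotype's mode, the phenotype score is
halved (applied at most once).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Iterable, Mapping, Sequence

from .inheritance import AnalysisMoi, DiseaseMoi, moi_compatible
from .ontology import (
    AnnotationCorpus,
    Ontology,
    TermId,
    information_content,
    jaccard_similarity,
    most_informative_common_ancestor,
)

__all__ = [
    "Source",
    "PhenotypeProfile",
    "GenePhenotypeModel",
    "PpiNetwork",
    "PhenotypeMatchResult",
    "PhenotypeScorer",
    "term_pair_score",
    "profile_similarity",
    "gene_phenotype_score",
    "apply_moi_consistency_penalty",
    "DEFAULT_NEIGHBOR_WEIGHT",
]

#: Scale factor on interaction-neighbour evidence.  Strictly below 1 so that
#: direct annotation beats equal-quality neighbour evidence.
DEFAULT_NEIGHBOR_WEIGHT = 0.75


class Source(str, Enum):
    HUMAN_DISEASE = "HUMAN_DISEASE"
    MOUSE = "MOUSE"
    ZEBRAFISH = "ZEBRAFISH"


@dataclass(frozen=True)
class PhenotypeProfile:
    """A non-empty, ordered, duplicate-free set of ontology term ids."""

    terms: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.terms:
            raise ValueError("phenotype profile must contain at least one term")
        deduped = tuple(dict.fromkeys(TermId(t) for t in self.terms))
        object.__setattr__(self, "terms", deduped)

    @classmethod
    def of(cls, terms: Iterable[str]) -> "PhenotypeProfile":
        return cls(tuple(terms))

    def resolved(self, ontology: Ontology) -> "PhenotypeProfile":
        """Drop terms unknown to *ontology* (with a warning); error if none remain."""
        known = tuple(t for t in self.terms if t in ontology)
        dropped = [t for t in self.terms if t not in ontology]
        if dropped:
            warnings.warn(f"dropping unresolvable term(s): {dropped}", stacklevel=2)
        if not known:
            raise ValueError("no profile term resolves in the ontology")
        if len(known) == len(self.terms):
            return self
        return PhenotypeProfile(known)

    def __iter__(self):
        return iter(self.terms)

    def __len__(self) -> int:
        return len(self.terms)


@dataclass(frozen=True)
class GenePhenotypeModel:
    """One annotated phenotype model (disease or organism model) for a gene."""

    gene: str
    source: Source
    model_id: str
    profile: PhenotypeProfile
    disease_moi: DiseaseMoi | None = None

    def __post_init__(self) -> None:
        if self.disease_moi is not None and self.source is not Source.HUMAN_DISEASE:
            raise ValueError("disease_moi is only meaningful for HUMAN_DISEASE models")


class PpiNetwork:
    """Undirected protein-protein interaction edges with confidences in [0, 1]."""

    def __init__(self, edges: Iterable[tuple[str, str, float]] = ()) -> None:
        self._adj: dict[str, dict[str, float]] = {}
        for a, b, conf in edges:
            self.add_edge(a, b, conf)

    def add_edge(self, a: str, b: str, confidence: float) -> None:
        if a == b:
            raise ValueError(f"self-loop on {a}")
        if not 0.0 <= confidence <= 1.0:
            raise ValueError(f"confidence {confidence} outside [0, 1]")
        self._adj.setdefault(a, {})[b] = confidence
        self._adj.setdefault(b, {})[a] = confidence

    def neighbors(self, gene: str) -> Mapping[str, float]:
        return self._adj.get(gene, {})

    def __len__(self) -> int:
        return sum(len(v) for v in self._adj.values()) // 2

    @classmethod
    def from_tsv(cls, path) -> "PpiNetwork":
        net = cls()
        with open(path) as fh:
            for line in fh:
                line = line.rstrip("\n")
                if not line or line.startswith("#"):
                    continue
                a, b, conf = line.split("\t")
                net.add_edge(a, b, float(conf))
        return net

    def to_tsv(self, path) -> None:
        seen = set()
        with open(path, "w") as fh:
            for a in self._adj:
                for b, conf in self._adj[a].items():
                    key = (min(a, b), max(a, b))
                    if key in seen:
                        continue
                    seen.add(key)
                    fh.write(f"{key[0]}\t{key[1]}\t{conf:.6g}\n")


@dataclass(frozen=True)
class PhenotypeMatchResult:
    """The phenotype score of a gene with the evidence that produced it."""

    gene: str
    score: float
    best_model: GenePhenotypeModel | None = None
    via_neighbor: str | None = None
    per_source_scores: Mapping[str, float] = field(default_factory=dict)
    moi_penalized: bool = False


def term_pair_score(
    ontology: Ontology, corpus: AnnotationCorpus, q: str, h: str
) -> float:
    """sqrt(jaccard(q, h) * IC(MICA(q, h))); 0 for cross-root pairs."""
    _, ic = most_informative_common_ancestor(ontology, corpus, q, h)
    if ic == 0.0:
        return 0.0
    return math.sqrt(jaccard_similarity(ontology, q, h) * ic)


class PhenotypeScorer:
    """Caches term-pair and profile similarities over one knowledge background.

    A cohort reuses a handful of query profiles against the same models, so
    memoizing ``(query profile, model profile)`` pairs makes whole-cohort
    phenotype scoring effectively free after the first patient.
    """

    def __init__(
        self,
        ontology: Ontology,
        corpus: AnnotationCorpus,
        models_by_gene: Mapping[str, Sequence[GenePhenotypeModel]] | None = None,
        ppi: PpiNetwork | None = None,
        neighbor_weight: float = DEFAULT_NEIGHBOR_WEIGHT,
    ) -> None:
        if not 0.0 < neighbor_weight < 1.0:
            raise ValueError("neighbor_weight must lie strictly inside (0, 1)")
        self.ontology = ontology
        self.corpus = corpus
        self.models_by_gene = dict(models_by_gene or {})
        self.ppi = ppi or PpiNetwork()
        self.neighbor_weight = neighbor_weight
        self._pair_cache: dict[tuple[str, str], float] = {}
        self._profile_cache: dict[tuple[tuple[str, ...], tuple[str, ...]], float] = {}
        self._gene_cache: dict[tuple[tuple[str, ...], str], PhenotypeMatchResult] = {}

    def term_pair_score(self, q: str, h: str) -> float:
        key = (q, h) if q <= h else (h, q)
        score = self._pair_cache.get(key)
        if score is None:
            score = term_pair_score(self.ontology, self.corpus, q, h)
            self._pair_cache[key] = score
        return score

    def profile_similarity(
        self, query: PhenotypeProfile, model: PhenotypeProfile
    ) -> float:
        key = (query.terms, model.terms)
        score = self._profile_cache.get(key)
        if score is None:
            score = self._profile_similarity(query, model)
            self._profile_cache[key] = score
        return score

    def _profile_similarity(
        self, query: PhenotypeProfile, model: PhenotypeProfile
    ) -> float:
        best = [max(self.term_pair_score(q, h) for h in model) for q in query]
        ideal = [max(self.term_pair_score(q, p) for p in query) for q in query]
        ideal_max = max(ideal)
        ideal_avg = sum(ideal) / len(ideal)
        if ideal_max == 0.0 or ideal_avg == 0.0:
            return 0.0
        raw_max = max(best)
        raw_avg = sum(best) / len(best)
        score = 0.5 * (raw_max / ideal_max + raw_avg / ideal_avg)
        return min(max(score, 0.0), 1.0)

    def score_gene(self, query: PhenotypeProfile, gene: str) -> PhenotypeMatchResult:
        cached = self._gene_cache.get((query.terms, gene))
        if cached is None:
            cached = self._score_gene(query, gene)
            self._gene_cache[(query.terms, gene)] = cached
        return cached

    def _score_gene(self, query: PhenotypeProfile, gene: str) -> PhenotypeMatchResult:
        per_source: dict[str, float] = {}
        best_score = 0.0
        best_model: GenePhenotypeModel | None = None
        via_neighbor: str | None = None
        for model in self.models_by_gene.get(gene, ()):
            s = self.profile_similarity(query, model.profile)
            if s > per_source.get(model.source.value, 0.0):
                per_source[model.source.value] = s
            if s > best_score:
                best_score, best_model, via_neighbor = s, model, None
        neighbor_best = 0.0
        for neighbor, conf in sorted(self.ppi.neighbors(gene).items()):
            for model in self.models_by_gene.get(neighbor, ()):
                s = (
                    self.neighbor_weight
                    * conf
                    * self.profile_similarity(query, model.profile)
                )
                if s > neighbor_best:
                    neighbor_best = s
                if s > best_score:
                    best_score, best_model, via_neighbor = s, model, neighbor
        if neighbor_best > 0.0:
            per_source["PPI"] = neighbor_best
        return PhenotypeMatchResult(
            gene=gene,
            score=best_score,
            best_model=best_model,
            via_neighbor=via_neighbor,
            per_source_scores=per_source,
        )


# -- module-level operation surface -----------------------------------------

def profile_similarity(
    ontology: Ontology,
    corpus: AnnotationCorpus,
    query: PhenotypeProfile,
    model: PhenotypeProfile,
) -> float:
    return PhenotypeScorer(ontology, corpus).profile_similarity(query, model)


def gene_phenotype_score(
    query: PhenotypeProfile,
    gene: str,
    models_by_gene: Mapping[str, Sequence[GenePhenotypeModel]],
    ppi: PpiNetwork | None,
    ontology: Ontology,
    corpus: AnnotationCorpus,
    neighbor_weight: float = DEFAULT_NEIGHBOR_WEIGHT,
) -> PhenotypeMatchResult:
    scorer = PhenotypeScorer(
        ontology, corpus, models_by_gene, ppi, neighbor_weight=neighbor_weight
    )
    return scorer.score_gene(query, gene)


def apply_moi_consistency_penalty(
    result: PhenotypeMatchResult,
    candidate_moi: AnalysisMoi,
    winning_model: GenePhenotypeModel | None = None,
) -> PhenotypeMatchResult:
    """Halve the phenotype score when the best human-disease match disagrees
    with the candidate genotype's mode of inheritance.

    Only the winning (best-match) disease's annotation is consulted; matches
    won by organism models or via a neighbour gene, UNKNOWN annotations, and
    already-penalized results are left untouched, so the penalty is applied
    at most once.
    """
    model = winning_model if winning_model is not None else result.best_model
    if result.moi_penalized or model is None:
        return result
    if model.source is not Source.HUMAN_DISEASE or result.via_neighbor is not None:
        return result
    if model.disease_moi is None or model.disease_moi is DiseaseMoi.UNKNOWN:
        return result
    if moi_compatible(model.disease_moi, candidate_moi):
        return result
    return replace(result, score=result.score / 2.0, moi_penalized=True)
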