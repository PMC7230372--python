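"""Shared fixtures: toy ontologies, a random-DAG builder, and a session cohort."""

from __future__ import annotations

import numpy as np
import pytest

from phenoprio import (
    AnalysisConfig,
    AnnotationCorpus,
    FixtureSpec,
    Ontology,
    benchmark_cohort,
    make_cohort,
)


@pytest.fixture
def chain_ontology() -> Ontology:
    """root <- A <- B"""
    return Ontology(
        {"HP:0000001": set(), "HP:0000002": {"HP:0000001"}, "HP:0000003": {"HP:0000002"}},
        {"HP:0000001": "root", "HP:0000002": "A", "HP:0000003": "B"},
    )


@pytest.fixture
def diamond_ontology() -> Ontology:
    """root <- {A, B} <- D (two parents)."""
    return Ontology(
        {
            "HP:0000001": set(),
            "HP:0000002": {"HP:0000001"},
            "HP:0000003": {"HP:0000001"},
            "HP:0000004": {"HP:0000002", "HP:0000003"},
        }
    )


@pytest.fixture
def two_root_ontology() -> Ontology:
    return Ontology(
        {
            "HP:0000001": set(),
            "HP:0000002": {"HP:0000001"},
            "MP:0000001": set(),
            "MP:0000002": {"MP:0000001"},
        }
    )


def random_dag(n_terms: int, seed: int, max_parents: int = 3) -> Ontology:
    """A random single-root DAG: term i draws parents among terms < i."""
    rng = np.random.default_rng(seed)
    parents: dict[str, set[str]] = {"HP:0000001": set()}
    ids = ["HP:0000001"]
    for i in range(2, n_terms + 1):
        t = f"HP:{i:07d}"
        k = 1 + int(rng.integers(max_parents))
        k = min(k, len(ids))
        picks = rng.choice(len(ids), size=k, replace=False)
        parents[t] = {ids[int(j)] for j in picks}
        ids.append(t)
    return Ontology(parents)


def random_corpus(ontology: Ontology, n_entities: int, seed: int) -> AnnotationCorpus:
    rng = np.random.default_rng(seed)
    terms = sorted(ontology.terms)
    entity_terms = {}
    for e in range(n_entities):
        k = 1 + int(rng.integers(4))
        picks = rng.choice(len(terms), size=min(k, len(terms)), replace=False)
        entity_terms[f"E{e:03d}"] = [terms[int(i)] for i in picks]
    return AnnotationCorpus(entity_terms)


@pytest.fixture
def small_corpus() -> AnnotationCorpus:
    """Hand-sized corpus over the 6-term ontology used in similarity tests."""
    return AnnotationCorpus(
        {
            "e1": ["HP:0000011"],  # A1
            "e2": ["HP:0000012"],  # A2
            "e3": ["HP:0000021"],  # B1
            "e4": ["HP:0000021"],
        }
    )


@pytest.fixture
def small_ontology() -> Ontology:
    """R <- {A, B}; A <- {A1, A2}; B <- B1 — ICs are simple log fractions."""
    return Ontology(
        {
            "HP:0000001": set(),
            "HP:0000010": {"HP:0000001"},
            "HP:0000020": {"HP:0000001"},
            "HP:0000011": {"HP:0000010"},
            "HP:0000012": {"HP:0000010"},
            "HP:0000021": {"HP:0000020"},
        }
    )


# -- session-scoped spiked cohort (used by integration + acceptance tests) --

COHORT_SEED = 1


@pytest.fixture(scope="session")
def cohort50(tmp_path_factory):
    spec = FixtureSpec(n_patients=50)
    directory = tmp_path_factory.mktemp("cohort50")
    return make_cohort(spec, directory, seed=COHORT_SEED)


@pytest.fixture(scope="session")
def default_outcomes(cohort50):
    return benchmark_cohort(cohort50, AnalysisConfig.default())


@pytest.fixture(scope="session")
def variant_only_outcomes(cohort50):
    return benchmark_cohort(cohort50, AnalysisConfig.variant_only())
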