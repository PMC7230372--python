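"""The flat-file knowledge bundle consumed by a prioritization run.

A knowledge directory contains:

    ontology.obo        phenotype ontology (minimal OBO dialect)
    models.tsv          gene, source, model_id, moi, pipe-separated terms
    ppi.tsv             geneA, geneB, confidence in [0, 1]
    frequencies.tsv     chrom, pos, ref, alt, source, MAF in percent
    pathogenicity.tsv   chrom, pos, ref, alt, source, raw score
    whitelist.tsv       chrom, pos, ref, alt

The annotation corpus backing information content is derived from all
models across sources (one entity per model).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import pandas as pd

from .inheritance import DiseaseMoi
from .ontology import AnnotationCorpus, Ontology, load_ontology
from .phenotype import (
    GenePhenotypeModel,
    PhenotypeProfile,
    PhenotypeScorer,
    PpiNetwork,
    Source,
)
from .variants import VariantKey, normalize_chrom

__all__ = ["KnowledgeBase"]

_FREQ_COLUMNS = ["CHROM", "POS", "REF", "ALT", "SOURCE", "MAF_PERCENT"]
_PATH_COLUMNS = ["CHROM", "POS", "REF", "ALT", "SOURCE", "RAW_SCORE"]


@dataclass
class KnowledgeBase:
    ontology: Ontology
    models_by_gene: dict[str, tuple[GenePhenotypeModel, ...]]
    ppi: PpiNetwork
    frequencies: dict[VariantKey, dict[str, float]] = field(default_factory=dict)
    pathogenicity: dict[VariantKey, dict[str, float]] = field(default_factory=dict)
    whitelist: set[VariantKey] = field(default_factory=set)
    _corpus: AnnotationCorpus | None = field(default=None, repr=False)
    _scorer: PhenotypeScorer | None = field(default=None, repr=False)

    @property
    def corpus(self) -> AnnotationCorpus:
        if self._corpus is None:
            entity_terms = {
                model.model_id: model.profile.terms
                for models in self.models_by_gene.values()
                for model in models
            }
            self._corpus = AnnotationCorpus(entity_terms)
        return self._corpus

    def scorer(self, neighbor_weight: float = 0.75) -> PhenotypeScorer:
        if self._scorer is None or self._scorer.neighbor_weight != neighbor_weight:
            self._scorer = PhenotypeScorer(
                self.ontology,
                self.corpus,
                self.models_by_gene,
                self.ppi,
                neighbor_weight=neighbor_weight,
            )
        return self._scorer

    # -- persistence --------------------------------------------------------
    @classmethod
    def load(cls, directory) -> "KnowledgeBase":
        directory = Path(directory)
        ontology = load_ontology(str(directory / "ontology.obo"))
        models = pd.read_csv(
            directory / "models.tsv", sep="\t", dtype=str, keep_default_na=False
        )
        models_by_gene: dict[str, list[GenePhenotypeModel]] = {}
        for row in models.itertuples(index=False):
            moi = DiseaseMoi(row.MOI) if row.MOI else None
            model = GenePhenotypeModel(
                gene=row.GENE,
                source=Source(row.SOURCE),
                model_id=row.MODEL_ID,
                profile=PhenotypeProfile.of(row.TERMS.split("|")),
                disease_moi=moi,
            )
            models_by_gene.setdefault(row.GENE, []).append(model)
        ppi = PpiNetwork.from_tsv(directory / "ppi.tsv")
        freq = _read_variant_table(directory / "frequencies.tsv", "MAF_PERCENT")
        path = _read_variant_table(directory / "pathogenicity.tsv", "RAW_SCORE")
        wl_df = pd.read_csv(directory / "whitelist.tsv", sep="\t", dtype=str)
        whitelist = {
            (normalize_chrom(r.CHROM), int(r.POS), r.REF, r.ALT)
            for r in wl_df.itertuples(index=False)
        }
        return cls(
            ontology=ontology,
            models_by_gene={g: tuple(ms) for g, ms in models_by_gene.items()},
            ppi=ppi,
            frequencies=freq,
            pathogenicity=path,
            whitelist=whitelist,
        )

    def save(self, directory) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        self._write_obo(directory / "ontology.obo")
        rows = []
        for gene in sorted(self.models_by_gene):
            for m in self.models_by_gene[gene]:
                rows.append(
                    {
                        "GENE": m.gene,
                        "SOURCE": m.source.value,
                        "MODEL_ID": m.model_id,
                        "MOI": m.disease_moi.value if m.disease_moi else "",
                        "TERMS": "|".join(m.profile.terms),
                    }
                )
        pd.DataFrame(rows, columns=["GENE", "SOURCE", "MODEL_ID", "MOI", "TERMS"]).to_csv(
            directory / "models.tsv", sep="\t", index=False
        )
        self.ppi.to_tsv(directory / "ppi.tsv")
        _write_variant_table(
            directory / "frequencies.tsv", self.frequencies, _FREQ_COLUMNS
        )
        _write_variant_table(
            directory / "pathogenicity.tsv", self.pathogenicity, _PATH_COLUMNS
        )
        with open(directory / "whitelist.tsv", "w") as fh:
            fh.write("CHROM\tPOS\tREF\tALT\n")
            for chrom, pos, ref, alt in sorted(self.whitelist):
                fh.write(f"{chrom}\t{pos}\t{ref}\t{alt}\n")

    def _write_obo(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("format-version: 1.2\nontology: synthetic-phenotype\n")
            for term in sorted(self.ontology.terms):
                fh.write("\n[Term]\n")
                fh.write(f"id: {term}\n")
                fh.write(f"name: {self.ontology.labels.get(term, term)}\n")
                for parent in sorted(self.ontology.parents(term)):
                    label = self.ontology.labels.get(parent, parent)
                    fh.write(f"is_a: {parent} ! {label}\n")


def _read_variant_table(path, value_column: str) -> dict[VariantKey, dict[str, float]]:
    df = pd.read_csv(path, sep="\t", dtype={"CHROM": str, "REF": str, "ALT": str})
    table: dict[VariantKey, dict[str, float]] = {}
    for row in df.itertuples(index=False):
        key = (normalize_chrom(row.CHROM), int(row.POS), row.REF, row.ALT)
        table.setdefault(key, {})[row.SOURCE] = float(getattr(row, value_column))
    return table


def _write_variant_table(
    path, table: Mapping[VariantKey, Mapping[str, float]], columns: list[str]
) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(columns) + "\n")
        for key in sorted(table):
            chrom, pos, ref, alt = key
            for source in sorted(table[key]):
                value = table[key][source]
                fh.write(f"{chrom}\t{pos}\t{ref}\t{alt}\t{source}\t{value:.6g}\n")
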