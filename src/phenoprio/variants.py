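"""Single-sample VCF parsing and the variant filter cascade.

Variants are filtered by call quality, predicted consequence class, and
per-mode-of-inheritance maximum allele frequency, then assembled into
candidate genotypes (dominant singletons, recessive homozygotes, compound
heterozygote pairs, hemizygotes, mitochondrial).  Whitelisted variants
bypass the consequence and frequency filters.

All allele frequencies are in percent; frequency cutoffs are boundary
inclusive.  Coordinates are 1-based as in VCF; chromosome names are
normalized by stripping a leading ``chr``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from enum import Enum
from itertools import combinations
from typing import Iterable, Mapping, Sequence

import pysam

from .inheritance import ModeOfInheritance

__all__ = [
    "Consequence",
    "Genotype",
    "VariantRecord",
    "CandidateGenotype",
    "LOSS_OF_FUNCTION",
    "DEFAULT_REMOVE_EFFECTS",
    "parse_vcf",
    "write_vcf",
    "quality_filter",
    "variant_effect_filter",
    "max_maf",
    "frequency_filter",
    "whitelist_bypass",
    "assemble_candidate_genotypes",
    "load_whitelist",
]


class Consequence(str, Enum):
    FRAMESHIFT_VARIANT = "FRAMESHIFT_VARIANT"
    STOP_GAINED = "STOP_GAINED"
    SPLICE_ACCEPTOR_VARIANT = "SPLICE_ACCEPTOR_VARIANT"
    SPLICE_DONOR_VARIANT = "SPLICE_DONOR_VARIANT"
    STOP_LOST = "STOP_LOST"
    START_LOST = "START_LOST"
    SPLICE_REGION_VARIANT = "SPLICE_REGION_VARIANT"
    MISSENSE_VARIANT = "MISSENSE_VARIANT"
    INFRAME_DELETION = "INFRAME_DELETION"
    INFRAME_INSERTION = "INFRAME_INSERTION"
    SYNONYMOUS_VARIANT = "SYNONYMOUS_VARIANT"
    FIVE_PRIME_UTR_EXON_VARIANT = "FIVE_PRIME_UTR_EXON_VARIANT"
    FIVE_PRIME_UTR_INTRON_VARIANT = "FIVE_PRIME_UTR_INTRON_VARIANT"
    THREE_PRIME_UTR_EXON_VARIANT = "THREE_PRIME_UTR_EXON_VARIANT"
    THREE_PRIME_UTR_INTRON_VARIANT = "THREE_PRIME_UTR_INTRON_VARIANT"
    NON_CODING_TRANSCRIPT_EXON_VARIANT = "NON_CODING_TRANSCRIPT_EXON_VARIANT"
    NON_CODING_TRANSCRIPT_INTRON_VARIANT = "NON_CODING_TRANSCRIPT_INTRON_VARIANT"
    CODING_TRANSCRIPT_INTRON_VARIANT = "CODING_TRANSCRIPT_INTRON_VARIANT"
    UPSTREAM_GENE_VARIANT = "UPSTREAM_GENE_VARIANT"
    DOWNSTREAM_GENE_VARIANT = "DOWNSTREAM_GENE_VARIANT"
    INTERGENIC_VARIANT = "INTERGENIC_VARIANT"
    REGULATORY_REGION_VARIANT = "REGULATORY_REGION_VARIANT"


#: Consequences whose pathogenicity is clinically fixed at the maximum.
LOSS_OF_FUNCTION = frozenset(
    {
        Consequence.FRAMESHIFT_VARIANT,
        Consequence.STOP_GAINED,
        Consequence.SPLICE_ACCEPTOR_VARIANT,
        Consequence.SPLICE_DONOR_VARIANT,
        Consequence.STOP_LOST,
        Consequence.START_LOST,
    }
)

#: Default removal list of the variant-effect filter (non-coding classes).
DEFAULT_REMOVE_EFFECTS = (
    Consequence.FIVE_PRIME_UTR_EXON_VARIANT,
    Consequence.FIVE_PRIME_UTR_INTRON_VARIANT,
    Consequence.THREE_PRIME_UTR_EXON_VARIANT,
    Consequence.THREE_PRIME_UTR_INTRON_VARIANT,
    Consequence.NON_CODING_TRANSCRIPT_EXON_VARIANT,
    Consequence.UPSTREAM_GENE_VARIANT,
    Consequence.INTERGENIC_VARIANT,
    Consequence.REGULATORY_REGION_VARIANT,
    Consequence.CODING_TRANSCRIPT_INTRON_VARIANT,
    Consequence.NON_CODING_TRANSCRIPT_INTRON_VARIANT,
    Consequence.DOWNSTREAM_GENE_VARIANT,
)


class Genotype(str, Enum):
    HET = "HET"
    HOM_ALT = "HOM_ALT"
    HEMI = "HEMI"


VariantKey = tuple[str, int, str, str]


def normalize_chrom(chrom: str) -> str:
    chrom = chrom[3:] if chrom.lower().startswith("chr") else chrom
    return "MT" if chrom in ("M", "MT") else chrom


@dataclass(frozen=True)
class VariantRecord:
    """One called alternate allele with its annotations and knowledge lookups."""

    chrom: str
    pos: int
    ref: str
    alt: str
    gene: str
    consequence: Consequence
    genotype: Genotype
    qual: float | None
    filter_field: str = "PASS"
    frequencies: Mapping[str, float] = field(default_factory=dict)
    pathogenicity: Mapping[str, float] = field(default_factory=dict)
    whitelisted: bool = False

    def __post_init__(self) -> None:
        object.__setattr__(self, "chrom", normalize_chrom(self.chrom))
        if self.pos < 1:
            raise ValueError(f"1-based position must be >= 1, got {self.pos}")
        for source, maf in self.frequencies.items():
            if not 0.0 <= maf <= 100.0:
                raise ValueError(f"MAF {maf} for {source} outside [0, 100] percent")

    @property
    def key(self) -> VariantKey:
        return (self.chrom, self.pos, self.ref, self.alt)

    @property
    def is_x(self) -> bool:
        return self.chrom == "X"

    @property
    def is_mt(self) -> bool:
        return self.chrom == "MT"

    @property
    def is_autosomal(self) -> bool:
        return not (self.is_x or self.is_mt or self.chrom == "Y")


@dataclass(frozen=True)
class CandidateGenotype:
    """One or two variants proposed as causal under a mode of inheritance."""

    gene: str
    moi: ModeOfInheritance
    variants: tuple[VariantRecord, ...]

    def __post_init__(self) -> None:
        n = len(self.variants)
        if self.moi in (ModeOfInheritance.AR_COMPHET, ModeOfInheritance.XR_COMPHET):
            if n != 2 or self.variants[0].key == self.variants[1].key:
                raise ValueError("compound heterozygote needs 2 distinct variants")
            if any(v.genotype is not Genotype.HET for v in self.variants):
                raise ValueError("compound heterozygote variants must be HET calls")
        elif n != 1:
            raise ValueError(f"{self.moi.value} candidate needs exactly 1 variant")
        if self.moi in (ModeOfInheritance.AR_HOM, ModeOfInheritance.XR_HOM) and any(
            v.genotype is Genotype.HET for v in self.variants
        ):
            raise ValueError("a heterozygous call cannot form a homozygous candidate")


def _genotype_from_gt(
    gt: tuple[int | None, ...], chrom: str, sex: str
) -> Genotype | None:
    alleles = [a for a in gt if a is not None]
    if not alleles or all(a == 0 for a in alleles):
        return None
    chrom = normalize_chrom(chrom)
    if len(alleles) == 1:
        return Genotype.HEMI if chrom in ("X", "Y", "MT") else Genotype.HOM_ALT
    if all(a > 0 for a in alleles):
        if chrom in ("X", "Y") and sex == "male":
            return Genotype.HEMI
        return Genotype.HOM_ALT
    return Genotype.HET


def parse_vcf(
    path,
    *,
    pass_only: bool = True,
    sex: str = "unknown",
    frequencies: Mapping[VariantKey, Mapping[str, float]] | None = None,
    pathogenicity: Mapping[VariantKey, Mapping[str, float]] | None = None,
    whitelist: Iterable[VariantKey] | None = None,
) -> list[VariantRecord]:
    """Parse a single-sample VCF into :class:`VariantRecord` objects.

    Consequence and gene symbol are read from the required ``CSQ`` and
    ``GENE`` INFO keys (the package does not re-annotate transcripts).
    Frequency/pathogenicity side tables and the whitelist are attached by
    ``(chrom, pos, ref, alt)``.  Under ``pass_only``, records whose FILTER
    is neither PASS nor ``.`` are dropped; reference or missing genotypes
    are skipped with a warning; multiallelic rows must be decomposed first.
    """
    frequencies = frequencies or {}
    pathogenicity = pathogenicity or {}
    wl = {(normalize_chrom(c), p, r, a) for (c, p, r, a) in (whitelist or ())}
    records: list[VariantRecord] = []
    with pysam.VariantFile(str(path)) as vcf:
        samples = list(vcf.header.samples)
        if len(samples) != 1:
            raise ValueError(
                f"expected a single-sample VCF, found {len(samples)} samples; "
                "multi-sample/pedigree analysis is out of scope"
            )
        for rec in vcf:
            if rec.alts is None:
                continue
            if len(rec.alts) > 1:
                raise ValueError(
                    f"multiallelic site at {rec.chrom}:{rec.pos}; decompose the VCF first"
                )
            filters = list(rec.filter)
            filter_field = ";".join(filters) if filters else "."
            if pass_only and filters not in ([], ["PASS"]):
                continue
            call = rec.samples[samples[0]]
            gt = call.get("GT")
            if gt is None or all(a is None for a in gt):
                warnings.warn(
                    f"missing genotype at {rec.chrom}:{rec.pos}; record skipped",
                    stacklevel=2,
                )
                continue
            genotype = _genotype_from_gt(gt, rec.chrom, sex)
            if genotype is None:
                continue
            info = dict(rec.info)
            if "GENE" not in info or "CSQ" not in info:
                raise ValueError(
                    f"record {rec.chrom}:{rec.pos} lacks GENE/CSQ INFO annotation"
                )
            csq = info["CSQ"]
            if isinstance(csq, tuple):
                csq = csq[0]
            key = (normalize_chrom(rec.chrom), rec.pos, rec.ref, rec.alts[0])
            records.append(
                VariantRecord(
                    chrom=rec.chrom,
                    pos=rec.pos,
                    ref=rec.ref,
                    alt=rec.alts[0],
                    gene=str(info["GENE"]),
                    consequence=Consequence(str(csq)),
                    genotype=genotype,
                    qual=None if rec.qual is None else float(rec.qual),
                    filter_field=filter_field,
                    frequencies=dict(frequencies.get(key, {})),
                    pathogenicity=dict(pathogenicity.get(key, {})),
                    whitelisted=key in wl,
                )
            )
    return records


_GT_STRINGS = {Genotype.HET: "0/1", Genotype.HOM_ALT: "1/1", Genotype.HEMI: "1"}

VCF_CONTIGS = tuple(str(c) for c in range(1, 23)) + ("X", "Y", "MT")


def vcf_header(sample: str) -> str:
    lines = ["##fileformat=VCFv4.2"]
    lines += [f"##contig=<ID={c}>" for c in VCF_CONTIGS]
    lines += [
        '##INFO=<ID=GENE,Number=1,Type=String,Description="Gene symbol">',
        '##INFO=<ID=CSQ,Number=1,Type=String,Description="Predicted consequence">',
        '##FILTER=<ID=q10,Description="Low call quality">',
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + sample,
    ]
    return "\n".join(lines) + "\n"


def write_vcf(records: Sequence[VariantRecord], path, sample: str = "SAMPLE") -> None:
    """Write records back out as a minimal single-sample VCF 4.2 text file."""
    rows = sorted(records, key=lambda v: (VCF_CONTIGS.index(v.chrom), v.pos, v.alt))
    with open(path, "w") as fh:
        fh.write(vcf_header(sample))
        for v in rows:
            qual = "." if v.qual is None else f"{v.qual:.6g}"
            fh.write(
                f"{v.chrom}\t{v.pos}\t.\t{v.ref}\t{v.alt}\t{qual}\t{v.filter_field}"
                f"\tGENE={v.gene};CSQ={v.consequence.value}\tGT\t{_GT_STRINGS[v.genotype]}\n"
            )


# -- filters ----------------------------------------------------------------

def quality_filter(v: VariantRecord, min_quality: float) -> bool:
    """Pass iff the call quality is present and >= *min_quality* (inclusive)."""
    return v.qual is not None and v.qual >= min_quality


def variant_effect_filter(
    v: VariantRecord,
    remove: Iterable[Consequence] = DEFAULT_REMOVE_EFFECTS,
    strict: bool = True,
) -> bool:
    """Fail iff the consequence is on the removal list; whitelist bypasses."""
    if v.whitelisted:
        return True
    remove_set = set()
    for item in remove:
        try:
            remove_set.add(Consequence(item))
        except ValueError:
            if strict:
                raise
            warnings.warn(f"unknown consequence label {item!r} ignored", stacklevel=2)
    return v.consequence not in remove_set


def max_maf(v: VariantRecord, sources: Sequence[str]) -> float:
    """Maximum MAF (percent) over the selected sources; 0.0 when absent from all."""
    return max((v.frequencies.get(s, 0.0) for s in sources), default=0.0)


def frequency_filter(f: float, max_frequency: float) -> bool:
    """Pass iff the maximum MAF (percent) is <= the cutoff (inclusive)."""
    return f <= max_frequency


def whitelist_bypass(
    v: VariantRecord, whitelist: Iterable[VariantKey]
) -> VariantRecord:
    """Flag the variant when its (chrom, pos, ref, alt) is whitelisted."""
    wl = {(normalize_chrom(c), p, r, a) for (c, p, r, a) in whitelist}
    if v.key in wl and not v.whitelisted:
        return replace(v, whitelisted=True)
    return v


def load_whitelist(path) -> set[VariantKey]:
    """Read a whitelist TSV (CHROM, POS, REF, ALT) into a key set."""
    keys: set[VariantKey] = set()
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#") or line.startswith("CHROM\t"):
                continue
            chrom, pos, ref, alt = line.split("\t")
            keys.add((normalize_chrom(chrom), int(pos), ref, alt))
    return keys


# -- genotype assembly ------------------------------------------------------

def _passes_moi_cutoff(
    v: VariantRecord, cutoff: float, sources: Sequence[str]
) -> bool:
    return v.whitelisted or max_maf(v, sources) <= cutoff


def assemble_candidate_genotypes(
    gene_variants: Sequence[VariantRecord],
    moi: ModeOfInheritance,
    cutoffs: Mapping[ModeOfInheritance, float],
    *,
    frequency_sources: Sequence[str],
    sex: str = "unknown",
) -> list[CandidateGenotype]:
    """Enumerate candidate genotypes for one gene under one inheritance sub-mode.

    Variants are first restricted to the sub-mode's chromosome domain and its
    MAF cutoff (whitelist bypasses).  Compound-heterozygote modes emit every
    unordered pair of distinct heterozygous calls (the cohort is singletons,
    so no phase information is available); homozygous modes emit only
    homozygous/hemizygous calls, which is what excludes causal variants
    erroneously called heterozygous.  With unknown sample sex, an X-chromosome
    homozygote is considered under both AR_HOM and XR_HOM.
    """
    if moi not in cutoffs:
        return []
    cutoff = cutoffs[moi]
    passing = [
        v
        for v in gene_variants
        if _passes_moi_cutoff(v, cutoff, frequency_sources)
    ]
    if not passing:
        return []
    gene = passing[0].gene
    out: list[CandidateGenotype] = []

    def singleton(v: VariantRecord) -> None:
        out.append(CandidateGenotype(gene=gene, moi=moi, variants=(v,)))

    if moi is ModeOfInheritance.AD:
        for v in passing:
            if v.is_autosomal and v.genotype in (Genotype.HET, Genotype.HOM_ALT):
                singleton(v)
    elif moi is ModeOfInheritance.AR_HOM:
        for v in passing:
            on_domain = v.is_autosomal or (v.is_x and sex == "unknown")
            if on_domain and v.genotype is Genotype.HOM_ALT:
                singleton(v)
    elif moi is ModeOfInheritance.AR_COMPHET:
        hets = [v for v in passing if v.is_autosomal and v.genotype is Genotype.HET]
        for a, b in combinations(hets, 2):
            out.append(CandidateGenotype(gene=gene, moi=moi, variants=(a, b)))
    elif moi is ModeOfInheritance.XD:
        for v in passing:
            if v.is_x:
                singleton(v)
    elif moi is ModeOfInheritance.XR_HOM:
        for v in passing:
            if v.is_x and v.genotype in (Genotype.HOM_ALT, Genotype.HEMI):
                singleton(v)
    elif moi is ModeOfInheritance.XR_COMPHET:
        hets = [v for v in passing if v.is_x and v.genotype is Genotype.HET]
        for a, b in combinations(hets, 2):
            out.append(CandidateGenotype(gene=gene, moi=moi, variants=(a, b)))
    elif moi is ModeOfInheritance.MT:
        for v in passing:
            if v.is_mt:
                singleton(v)
    return out
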