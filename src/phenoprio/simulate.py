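"""Synthetic knowledge bases and spiked-causal patient exomes.

Everything the pipeline consumes — ontology, cross-species annotation
corpora, interaction network, frequency/pathogenicity tables, whitelist and
single-sample VCFs — is generated here with the statistical structure of a
solved rare-disease exome cohort:

* solved-genotype mix 53.7% homozygous / 29.1% compound heterozygous /
  9.7% heterozygous / 7.5% hemizygous (hemizygous patients are male, with
  the causal gene on the X chromosome);
* a post-filter variant load per exome with mean ~474 (truncated to the
  229-1276 range), drawn from a shared population pool so that allele
  frequencies are consistent across patients;
* 19 diagnosis labels, each with a fixed representative profile of one to
  six ontology terms;
* a configurable fraction of "novel" causal genes carrying no human
  disease annotation, discoverable only through organism models or an
  interaction neighbour.

A corruption flag can rewrite a homozygous/hemizygous causal genotype as a
heterozygous call, which the recessive inheritance filters then (correctly)
refuse to assemble — the generated analogue of a variant-calling error.

All generation is deterministic under (spec, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .inheritance import AnalysisMoi, DiseaseMoi
from .knowledge import KnowledgeBase
from .ontology import Ontology
from .phenotype import GenePhenotypeModel, PhenotypeProfile, PpiNetwork, Source
from .variants import Consequence, DEFAULT_REMOVE_EFFECTS, VCF_CONTIGS, VariantKey, vcf_header

__all__ = [
    "FixtureSpec",
    "TruthRecord",
    "SyntheticKnowledge",
    "Cohort",
    "make_knowledge_base",
    "make_patient",
    "make_cohort",
    "make_combiner_training_set",
    "read_truth_table",
]

_BASES = "ACGT"
_N_BRANCHES = 6


@dataclass(frozen=True)
class FixtureSpec:
    """Knobs of the synthetic study; defaults are the emulated cohort conditions."""

    n_genes: int = 400
    n_terms: int = 120
    n_patients: int = 134
    n_diagnoses: int = 19
    genotype_mix: tuple[tuple[str, float], ...] = (
        ("HOM", 0.537),
        ("COMPHET", 0.291),
        ("HET", 0.097),
        ("HEMI", 0.075),
    )
    mean_variants: float = 474.0
    variants_range: tuple[int, int] = (229, 1276)
    nb_dispersion: float = 12.0
    profile_terms_range: tuple[int, int] = (1, 6)
    novel_gene_fraction: float = 0.05
    whitelist_fraction: float = 0.10
    hpo_noise_terms: int = 0
    miscall_fraction: float = 0.0
    pool_size: int = 6000

    def __post_init__(self) -> None:
        total = sum(w for _, w in self.genotype_mix)
        if abs(total - 1.0) > 1e-9:
            raise ValueError("genotype_mix must sum to 1")
        if self.n_terms < 40 or self.n_genes < 80 or self.n_diagnoses < 5:
            raise ValueError("fixture spec too small to emulate the cohort structure")


@dataclass(frozen=True)
class TruthRecord:
    """Ground truth for one simulated patient."""

    patient_id: str
    diagnosis: str
    gene: str
    moi: AnalysisMoi
    genotype_class: str  # HOM / COMPHET / HET / HEMI
    variants: tuple[VariantKey, ...]
    profile: tuple[str, ...]
    sex: str
    miscalled: bool = False
    whitelisted: bool = False


@dataclass(frozen=True)
class _PoolVariant:
    chrom: str
    pos: int
    ref: str
    alt: str
    gene: str
    consequence: Consequence
    fail_mode: str | None  # None | common | effect | lowqual | filter


@dataclass
class _Diagnosis:
    name: str
    profile: tuple[str, ...]
    genes_by_role: dict[str, list[str]]  # AR / AD / XR -> gene symbols


@dataclass
class SyntheticKnowledge:
    """A knowledge base plus the generator-internal state needed to spike patients."""

    spec: FixtureSpec
    kb: KnowledgeBase
    diagnoses: dict[str, _Diagnosis]
    pool: list[_PoolVariant]
    gene_loci: dict[str, tuple[str, int]]
    _passing_idx: np.ndarray = field(default_factory=lambda: np.empty(0, int))
    _failing_idx: np.ndarray = field(default_factory=lambda: np.empty(0, int))


# -- ontology ---------------------------------------------------------------

def _term_id(i: int) -> str:
    return f"HP:{i:07d}"


def _make_ontology(spec: FixtureSpec, rng: np.random.Generator):
    parents: dict[str, set[str]] = {}
    labels: dict[str, str] = {}
    counter = [0]

    def new_term(label: str, ps: set[str]) -> str:
        counter[0] += 1
        t = _term_id(counter[0])
        parents[t] = ps
        labels[t] = label
        return t

    root = new_term("phenotypic abnormality", set())
    branch_terms: list[list[str]] = []
    for b in range(_N_BRANCHES):
        broot = new_term(f"organ system {b} abnormality", {root})
        mid1 = new_term(f"system {b} morphology", {broot})
        mid2 = new_term(f"system {b} fine structure", {mid1})
        branch_terms.append([broot, mid1, mid2])
    remaining = spec.n_terms - counter[0]
    for i in range(remaining):
        b = i % _N_BRANCHES
        bt = branch_terms[b]
        lo = len(bt) // 2
        ps = {bt[int(rng.integers(lo, len(bt)))]}
        if rng.random() < 0.25:
            ps.add(bt[int(rng.integers(0, len(bt)))])
        bt.append(new_term(f"system {b} phenotype {len(bt)}", ps))
    return Ontology(parents, labels), branch_terms


def _sample_profile(
    rng: np.random.Generator, branch: Sequence[str], size: int
) -> tuple[str, ...]:
    deep = branch[max(3, len(branch) // 3):]
    size = min(size, len(deep))
    picks = rng.choice(len(deep), size=size, replace=False)
    return tuple(deep[int(i)] for i in sorted(picks))


def _generalize(
    rng: np.random.Generator, ontology: Ontology, profile: Sequence[str], p: float
) -> tuple[str, ...]:
    """Replace terms by a parent with probability *p* (less specific annotation)."""
    out = []
    for t in profile:
        if rng.random() < p:
            ps = sorted(ontology.parents(t))
            if ps:
                t = ps[int(rng.integers(len(ps)))]
        out.append(t)
    return tuple(dict.fromkeys(out))


# -- knowledge base ---------------------------------------------------------

def make_knowledge_base(spec: FixtureSpec, seed: int) -> SyntheticKnowledge:
    """Build the ontology, corpora, interaction network and population variant pool."""
    rng = np.random.default_rng([seed, 0])
    ontology, branches = _make_ontology(spec, rng)

    # diagnoses with fixed representative profiles
    lo, hi = spec.profile_terms_range
    diagnoses: dict[str, _Diagnosis] = {}
    for i in range(spec.n_diagnoses):
        name = f"DIAG_{i + 1:02d}"
        branch = branches[i % _N_BRANCHES]
        size = lo + int(rng.integers(hi - lo + 1))
        diagnoses[name] = _Diagnosis(
            name=name, profile=_sample_profile(rng, branch, size), genes_by_role={}
        )

    # gene symbols and loci; XR-capable genes sit on chromosome X
    gene_counter = [0]
    chrom_counts: dict[str, int] = {}

    def new_gene(chrom: str | None = None) -> str:
        gene_counter[0] += 1
        g = f"GENE{gene_counter[0]:04d}"
        if chrom is None:
            chrom = str(1 + (gene_counter[0] % 22))
        start = 1_000_000 * (chrom_counts.get(chrom, 0) + 1)
        chrom_counts[chrom] = chrom_counts.get(chrom, 0) + 1
        gene_loci[g] = (chrom, start)
        return g

    gene_loci: dict[str, tuple[str, int]] = {}
    models_by_gene: dict[str, list[GenePhenotypeModel]] = {}
    model_counter = [0]

    def add_model(gene: str, source: Source, profile, moi: DiseaseMoi | None) -> None:
        model_counter[0] += 1
        prefix = {
            Source.HUMAN_DISEASE: "DIS",
            Source.MOUSE: "MUS",
            Source.ZEBRAFISH: "DAN",
        }[source]
        models_by_gene.setdefault(gene, []).append(
            GenePhenotypeModel(
                gene=gene,
                source=source,
                model_id=f"{prefix}:{model_counter[0]:06d}",
                profile=PhenotypeProfile.of(profile),
                disease_moi=moi,
            )
        )

    ppi = PpiNetwork()
    xr_diagnoses = [f"DIAG_{i + 1:02d}" for i in range(0, spec.n_diagnoses, 4)]

    for name, diag in diagnoses.items():
        roles = [("AR", DiseaseMoi.AR), ("AR", DiseaseMoi.AR), ("AD", DiseaseMoi.AD)]
        if name in xr_diagnoses:
            roles.append(("XR", DiseaseMoi.XR))
        for role, moi in roles:
            gene = new_gene("X" if role == "XR" else None)
            diag.genes_by_role.setdefault(role, []).append(gene)
            novel = rng.random() < spec.novel_gene_fraction
            if novel:
                # no human annotation: organism model plus a confident
                # interaction edge to an annotated gene of the same disease
                add_model(gene, Source.MOUSE, diag.profile, None)
                anchors = [
                    g for gs in diag.genes_by_role.values() for g in gs if g != gene
                ]
                if anchors:
                    ppi.add_edge(gene, anchors[0], 0.9)
            else:
                add_model(gene, Source.HUMAN_DISEASE, diag.profile, moi)
                if rng.random() < 0.6:
                    add_model(
                        gene,
                        Source.MOUSE,
                        _generalize(rng, ontology, diag.profile, 0.5),
                        None,
                    )
                if rng.random() < 0.3:
                    add_model(
                        gene,
                        Source.ZEBRAFISH,
                        _generalize(rng, ontology, diag.profile, 0.7),
                        None,
                    )

    # background genes: partial annotation with unrelated profiles
    while gene_counter[0] < spec.n_genes:
        chrom = "X" if rng.random() < 0.04 else None
        gene = new_gene(chrom)
        if rng.random() < 0.5:
            branch = branches[int(rng.integers(_N_BRANCHES))]
            profile = _sample_profile(rng, branch, 2 + int(rng.integers(3)))
            moi = DiseaseMoi(["AR", "AD"][int(rng.integers(2))])
            add_model(gene, Source.HUMAN_DISEASE, profile, moi)
        if rng.random() < 0.3:
            branch = branches[int(rng.integers(_N_BRANCHES))]
            profile = _sample_profile(rng, branch, 2 + int(rng.integers(3)))
            add_model(gene, Source.MOUSE, profile, None)

    all_genes = sorted(gene_loci)
    for gene in all_genes:
        for _ in range(2):
            other = all_genes[int(rng.integers(len(all_genes)))]
            if other != gene and other not in ppi.neighbors(gene):
                ppi.add_edge(gene, other, float(rng.uniform(0.4, 0.95)))

    kb = KnowledgeBase(
        ontology=ontology,
        models_by_gene={g: tuple(ms) for g, ms in models_by_gene.items()},
        ppi=ppi,
    )
    sk = SyntheticKnowledge(
        spec=spec, kb=kb, diagnoses=diagnoses, pool=[], gene_loci=gene_loci
    )
    _make_pool(sk, rng)
    return sk


_REMOVABLE = tuple(DEFAULT_REMOVE_EFFECTS)
_PASSING_CSQ = (
    (Consequence.MISSENSE_VARIANT, 0.55),
    (Consequence.SYNONYMOUS_VARIANT, 0.20),
    (Consequence.SPLICE_REGION_VARIANT, 0.08),
    (Consequence.INFRAME_DELETION, 0.03),
    (Consequence.INFRAME_INSERTION, 0.02),
    (Consequence.FRAMESHIFT_VARIANT, 0.05),
    (Consequence.STOP_GAINED, 0.04),
    (Consequence.SPLICE_ACCEPTOR_VARIANT, 0.02),
    (Consequence.SPLICE_DONOR_VARIANT, 0.01),
)


def _alleles(rng: np.random.Generator, csq: Consequence) -> tuple[str, str]:
    ref = _BASES[int(rng.integers(4))]
    if csq is Consequence.FRAMESHIFT_VARIANT:
        return ref + _BASES[int(rng.integers(4))], ref
    if csq is Consequence.INFRAME_DELETION:
        tail = "".join(_BASES[int(rng.integers(4))] for _ in range(3))
        return ref + tail, ref
    if csq is Consequence.INFRAME_INSERTION:
        tail = "".join(_BASES[int(rng.integers(4))] for _ in range(3))
        return ref, ref + tail
    alt = _BASES[(int(_BASES.index(ref)) + 1 + int(rng.integers(3))) % 4]
    return ref, alt


def _make_pool(sk: SyntheticKnowledge, rng: np.random.Generator) -> None:
    spec = sk.spec
    genes = sorted(sk.gene_loci)
    csq_values = [c for c, _ in _PASSING_CSQ]
    csq_probs = np.array([p for _, p in _PASSING_CSQ])
    csq_probs = csq_probs / csq_probs.sum()
    offsets: dict[str, int] = {}
    passing_idx, failing_idx = [], []
    freq_sources = ("LOCAL", "THOUSAND_GENOMES", "TOPMED", "UK10K", "GNOMAD_E_NFE")
    for i in range(spec.pool_size):
        gene = genes[int(rng.integers(len(genes)))]
        chrom, start = sk.gene_loci[gene]
        offsets[gene] = offsets.get(gene, 0) + 1
        pos = start + 13 + 37 * offsets[gene]
        failing = rng.random() >= 0.78
        fail_mode = None
        if failing:
            fail_mode = ["common", "effect", "lowqual", "filter"][
                int(rng.choice(4, p=[0.4, 0.3, 0.15, 0.15]))
            ]
        if fail_mode == "effect":
            csq = _REMOVABLE[int(rng.integers(len(_REMOVABLE)))]
        else:
            csq = csq_values[int(rng.choice(len(csq_values), p=csq_probs))]
        ref, alt = _alleles(rng, csq)
        key = (chrom, pos, ref, alt)
        # population frequencies (percent); ~10% of passing alleles are
        # absent from every reference dataset (novel singletons)
        if fail_mode == "common":
            maf = float(rng.uniform(2.5, 25.0))
        elif rng.random() < 0.10:
            maf = 0.0
        else:
            maf = float(10 ** rng.uniform(np.log10(5e-4), np.log10(2.0)))
        if maf > 0.0:
            primary = freq_sources[int(rng.integers(len(freq_sources)))]
            rows = {primary: maf}
            for s in freq_sources:
                if s != primary and rng.random() < 0.4:
                    rows[s] = maf * float(rng.uniform(0.2, 0.9))
            sk.kb.frequencies[key] = rows
        if csq is Consequence.MISSENSE_VARIANT:
            damaging = rng.random() < 0.15
            path: dict[str, float] = {}
            if damaging:
                path["POLYPHEN"] = float(rng.uniform(0.95, 1.0))
                path["SIFT"] = float(rng.uniform(0.0, 0.05))
                path["MUTATION_TASTER"] = float(rng.uniform(0.95, 1.0))
            else:
                path["POLYPHEN"] = float(rng.beta(2, 2))
                path["SIFT"] = float(rng.beta(2, 2))
                path["MUTATION_TASTER"] = float(rng.beta(2, 2))
            if rng.random() < 0.5:
                path["CADD"] = float(rng.uniform(0.0, 35.0))
            sk.kb.pathogenicity[key] = path
        sk.pool.append(
            _PoolVariant(
                chrom=chrom, pos=pos, ref=ref, alt=alt, gene=gene,
                consequence=csq, fail_mode=fail_mode,
            )
        )
        (failing_idx if failing else passing_idx).append(i)
    sk._passing_idx = np.array(passing_idx)
    sk._failing_idx = np.array(failing_idx)


# -- patients ---------------------------------------------------------------

def _draw_variant_count(spec: FixtureSpec, rng: np.random.Generator) -> int:
    k = spec.nb_dispersion
    p = k / (k + spec.mean_variants)
    lo, hi = spec.variants_range
    for _ in range(1000):
        n = int(rng.negative_binomial(k, p))
        if lo <= n <= hi:
            return n
    return int(spec.mean_variants)


def _vcf_line(chrom, pos, ref, alt, qual, filt, gene, csq, gt) -> str:
    return (
        f"{chrom}\t{pos}\t.\t{ref}\t{alt}\t{qual:.1f}\t{filt}"
        f"\tGENE={gene};CSQ={csq.value}\tGT\t{gt}\n"
    )


def _causal_allele(
    sk: SyntheticKnowledge,
    rng: np.random.Generator,
    gene: str,
    serial: int,
    kind: str,
) -> tuple[VariantKey, Consequence]:
    chrom, start = sk.gene_loci[gene]
    pos = start + 900_000 + serial
    if kind == "lof":
        csq = Consequence.FRAMESHIFT_VARIANT
    elif kind == "missense":
        csq = Consequence.MISSENSE_VARIANT
    else:
        csq = Consequence.INFRAME_DELETION
    ref, alt = _alleles(rng, csq)
    key = (chrom, pos, ref, alt)
    if rng.random() < 0.5:
        sk.kb.frequencies[key] = {"LOCAL": 0.0097}
    if csq is Consequence.MISSENSE_VARIANT:
        sk.kb.pathogenicity[key] = {
            "MUTATION_TASTER": 1.0,
            "POLYPHEN": float(rng.uniform(0.97, 1.0)),
            "SIFT": 0.0,
        }
    return key, csq


def make_patient(
    sk: SyntheticKnowledge,
    truth: TruthRecord,
    path,
    rng: np.random.Generator,
) -> None:
    """Write one spiked single-sample VCF for *truth* (mutates the shared
    frequency/pathogenicity tables with the causal alleles' rows)."""
    spec = sk.spec
    if truth.genotype_class == "HEMI" and truth.sex != "male":
        raise ValueError("hemizygous truth requires a male-coded sample")
    n = _draw_variant_count(spec, rng)
    picks = rng.choice(sk._passing_idx, size=min(n, len(sk._passing_idx)), replace=False)
    extra = rng.choice(
        sk._failing_idx,
        size=min(int(0.25 * n), len(sk._failing_idx)),
        replace=False,
    )
    contig_order = {c: i for i, c in enumerate(VCF_CONTIGS)}
    rows: list[tuple[tuple, str]] = []
    for idx in np.concatenate([picks, extra]):
        pv = sk.pool[int(idx)]
        if truth.miscalled and pv.gene == truth.gene:
            # the corrupted het must stand alone in its gene, so that the
            # recessive inheritance filter removes the causal genotype
            continue
        if pv.fail_mode == "lowqual":
            qual = float(rng.uniform(3.0, 29.0))
        else:
            qual = float(max(30.5, rng.normal(80.0, 25.0)))
        filt = "q10" if pv.fail_mode == "filter" else "PASS"
        if truth.sex == "male" and pv.chrom == "X":
            gt = "1"
        else:
            gt = "1/1" if rng.random() < 0.12 else "0/1"
        line = _vcf_line(pv.chrom, pv.pos, pv.ref, pv.alt, qual, filt, pv.gene, pv.consequence, gt)
        rows.append(((contig_order[pv.chrom], pv.pos, pv.alt), line))
    # spike the causal genotype
    for key, csq in zip(truth.variants, _truth_consequences(truth)):
        chrom, pos, ref, alt = key
        qual = float(max(35.0, rng.normal(90.0, 20.0)))
        if truth.genotype_class == "HOM":
            gt = "0/1" if truth.miscalled else "1/1"
        elif truth.genotype_class == "HEMI":
            gt = "0/1" if truth.miscalled else "1"
        else:
            gt = "0/1"
        line = _vcf_line(chrom, pos, ref, alt, qual, "PASS", truth.gene, csq, gt)
        rows.append(((contig_order[chrom], pos, alt), line))
    rows.sort(key=lambda t: t[0])
    with open(path, "w") as fh:
        fh.write(vcf_header(truth.patient_id))
        for _, line in rows:
            fh.write(line)


def _truth_consequences(truth: TruthRecord) -> list[Consequence]:
    """Causal consequences by construction: indel refs encode the class."""
    out = []
    for _, _, ref, alt in truth.variants:
        if len(ref) == 2 and len(alt) == 1:
            out.append(Consequence.FRAMESHIFT_VARIANT)
        elif len(ref) == 4 and len(alt) == 1:
            out.append(Consequence.INFRAME_DELETION)
        else:
            out.append(Consequence.MISSENSE_VARIANT)
    return out


# -- cohort -----------------------------------------------------------------

@dataclass
class Cohort:
    spec: FixtureSpec
    seed: int
    directory: Path
    knowledge: KnowledgeBase
    truths: list[TruthRecord]

    def vcf_path(self, patient_id: str) -> Path:
        return self.directory / "patients" / f"{patient_id}.vcf"


def _allocate_classes(spec: FixtureSpec, n: int) -> list[str]:
    """Largest-remainder allocation of the genotype mix to n patients."""
    shares = [(cls, w * n) for cls, w in spec.genotype_mix]
    counts = {cls: int(s) for cls, s in shares}
    short = n - sum(counts.values())
    by_frac = sorted(shares, key=lambda t: -(t[1] - int(t[1])))
    for cls, _ in by_frac[:short]:
        counts[cls] += 1
    out: list[str] = []
    for cls, _ in spec.genotype_mix:
        out.extend([cls] * counts[cls])
    return out


def make_cohort(spec: FixtureSpec, directory, seed: int) -> Cohort:
    """Generate the knowledge directory, per-patient VCFs and truth table."""
    directory = Path(directory)
    (directory / "patients").mkdir(parents=True, exist_ok=True)
    sk = make_knowledge_base(spec, seed)
    rng = np.random.default_rng([seed, 1])
    classes = _allocate_classes(spec, spec.n_patients)
    rng.shuffle(classes)
    diag_names = sorted(sk.diagnoses)
    xr_diags = [d for d in diag_names if sk.diagnoses[d].genes_by_role.get("XR")]
    truths: list[TruthRecord] = []
    serial = 0
    for i, cls in enumerate(classes):
        pid = f"P{i + 1:03d}"
        if cls == "HEMI":
            diag = sk.diagnoses[xr_diags[i % len(xr_diags)]]
            role = "XR"
        elif cls == "HET":
            diag = sk.diagnoses[diag_names[i % len(diag_names)]]
            role = "AD"
        else:
            diag = sk.diagnoses[diag_names[i % len(diag_names)]]
            role = "AR"
        genes = diag.genes_by_role[role]
        gene = genes[int(rng.integers(len(genes)))]
        sex = "male" if cls == "HEMI" else ("male" if rng.random() < 0.5 else "female")
        moi = {"HOM": AnalysisMoi.AR, "COMPHET": AnalysisMoi.AR,
               "HET": AnalysisMoi.AD, "HEMI": AnalysisMoi.XR}[cls]
        whitelisted = bool(rng.random() < spec.whitelist_fraction)
        miscalled = cls in ("HOM", "HEMI") and bool(rng.random() < spec.miscall_fraction)
        kinds = {
            "HOM": ["lof"],
            "HEMI": ["lof"],
            "HET": ["missense"],
            "COMPHET": ["lof", "inframe" if rng.random() < 0.4 else "missense"],
        }[cls]
        keys = []
        for kind in kinds:
            serial += 1
            key, _ = _causal_allele(sk, rng, gene, serial, kind)
            keys.append(key)
        if whitelisted:
            sk.kb.whitelist.add(keys[0])
        profile = list(diag.profile)
        if spec.hpo_noise_terms:
            universe = sorted(sk.kb.ontology.terms - set(profile))
            noise = rng.choice(len(universe), size=spec.hpo_noise_terms, replace=False)
            profile.extend(universe[int(j)] for j in noise)
        truth = TruthRecord(
            patient_id=pid,
            diagnosis=diag.name,
            gene=gene,
            moi=moi,
            genotype_class=cls,
            variants=tuple(keys),
            profile=tuple(profile),
            sex=sex,
            miscalled=miscalled,
            whitelisted=whitelisted,
        )
        truths.append(truth)
        make_patient(sk, truth, directory / "patients" / f"{pid}.vcf", rng)
    sk.kb.save(directory / "knowledge")
    _write_truth_table(truths, directory / "truth.tsv")
    return Cohort(
        spec=spec, seed=seed, directory=directory, knowledge=sk.kb, truths=truths
    )


def _write_truth_table(truths: Sequence[TruthRecord], path) -> None:
    with open(path, "w") as fh:
        fh.write(
            "PATIENT_ID\tDIAGNOSIS\tGENE\tMOI\tGENOTYPE_CLASS\tVARIANTS\tHPO\tSEX"
            "\tMISCALLED\tWHITELISTED\n"
        )
        for t in truths:
            variants = ";".join(f"{c}:{p}:{r}:{a}" for c, p, r, a in t.variants)
            fh.write(
                f"{t.patient_id}\t{t.diagnosis}\t{t.gene}\t{t.moi.value}"
                f"\t{t.genotype_class}\t{variants}\t{'|'.join(t.profile)}\t{t.sex}"
                f"\t{int(t.miscalled)}\t{int(t.whitelisted)}\n"
            )


def read_truth_table(path) -> list[TruthRecord]:
    truths = []
    with open(path) as fh:
        fh.readline()
        for line in fh:
            (pid, diag, gene, moi, cls, variants, hpo, sex, miscalled, wl) = (
                line.rstrip("\n").split("\t")
            )
            keys = []
            for item in variants.split(";"):
                chrom, pos, ref, alt = item.split(":")
                keys.append((chrom, int(pos), ref, alt))
            truths.append(
                TruthRecord(
                    patient_id=pid,
                    diagnosis=diag,
                    gene=gene,
                    moi=AnalysisMoi(moi),
                    genotype_class=cls,
                    variants=tuple(keys),
                    profile=tuple(hpo.split("|")),
                    sex=sex,
                    miscalled=bool(int(miscalled)),
                    whitelisted=bool(int(wl)),
                )
            )
    return truths


# -- combiner training data -------------------------------------------------

def make_combiner_training_set(
    n_disease: int = 10_000, n_benign: int = 10_000, seed: int = 0
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Labelled (phenotype, genotype) score pairs for fitting the combiner.

    Disease pairs concentrate near (1, 1) and benign pairs near the origin,
    with enough overlap that the fitted decision surface is a genuine
    trade-off rather than a separator.
    """
    rng = np.random.default_rng(seed)
    phen = np.concatenate([rng.beta(5.0, 1.5, n_disease), rng.beta(1.3, 4.0, n_benign)])
    geno = np.concatenate([rng.beta(8.0, 2.0, n_disease), rng.beta(1.6, 4.0, n_benign)])
    labels = np.concatenate([np.ones(n_disease, int), np.zeros(n_benign, int)])
    return phen, geno, labels
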