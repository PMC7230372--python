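"""VCF parsing, filter predicates, whitelist bypass and genotype assembly."""

from __future__ import annotations

import itertools

import numpy as np
import pytest

from phenoprio import (
    CandidateGenotype,
    Consequence,
    Genotype,
    ModeOfInheritance,
    VariantRecord,
    assemble_candidate_genotypes,
    frequency_filter,
    max_maf,
    parse_vcf,
    quality_filter,
    variant_effect_filter,
    whitelist_bypass,
    write_vcf,
)
from phenoprio.variants import DEFAULT_REMOVE_EFFECTS, vcf_header

TOY_ROWS = [
    "1\t1000\t.\tA\tT\t50.0\tPASS\tGENE=G1;CSQ=MISSENSE_VARIANT\tGT\t0/1",
    "1\t2000\t.\tG\tC\t80.0\tq10\tGENE=G1;CSQ=MISSENSE_VARIANT\tGT\t0/1",
    "2\t3000\t.\tC\tA\t60.0\t.\tGENE=G2;CSQ=STOP_GAINED\tGT\t1/1",
]


def write_toy_vcf(path, rows=TOY_ROWS, sample="S1"):
    path.write_text(vcf_header(sample) + "\n".join(rows) + "\n")
    return path


def make_record(
    chrom="1",
    pos=100,
    ref="A",
    alt="T",
    gene="G1",
    consequence=Consequence.MISSENSE_VARIANT,
    genotype=Genotype.HET,
    qual=50.0,
    frequencies=None,
    pathogenicity=None,
    whitelisted=False,
):
    return VariantRecord(
        chrom=chrom,
        pos=pos,
        ref=ref,
        alt=alt,
        gene=gene,
        consequence=consequence,
        genotype=genotype,
        qual=qual,
        frequencies=frequencies or {},
        pathogenicity=pathogenicity or {},
        whitelisted=whitelisted,
    )


class TestParseVcf:
    def test_pass_only_drops_non_pass_filter(self, tmp_path):
        path = write_toy_vcf(tmp_path / "toy.vcf")
        records = parse_vcf(path, pass_only=True)
        assert len(records) == 2  # q10 row dropped, "." kept
        assert parse_vcf(path, pass_only=False)[1].filter_field == "q10"

    def test_genotype_mapping(self, tmp_path):
        path = write_toy_vcf(tmp_path / "toy.vcf")
        records = parse_vcf(path)
        assert records[0].genotype is Genotype.HET
        assert records[1].genotype is Genotype.HOM_ALT

    def test_male_x_hom_and_haploid_are_hemizygous(self, tmp_path):
        rows = [
            "X\t500\t.\tA\tT\t50.0\tPASS\tGENE=GX;CSQ=MISSENSE_VARIANT\tGT\t1/1",
            "X\t600\t.\tG\tC\t50.0\tPASS\tGENE=GX;CSQ=MISSENSE_VARIANT\tGT\t1",
        ]
        path = write_toy_vcf(tmp_path / "x.vcf", rows)
        male = parse_vcf(path, sex="male")
        assert [v.genotype for v in male] == [Genotype.HEMI, Genotype.HEMI]
        female = parse_vcf(path, sex="female")
        assert female[0].genotype is Genotype.HOM_ALT

    def test_multiallelic_is_an_error(self, tmp_path):
        rows = ["1\t100\t.\tA\tT,C\t50.0\tPASS\tGENE=G1;CSQ=MISSENSE_VARIANT\tGT\t1/2"]
        path = write_toy_vcf(tmp_path / "multi.vcf", rows)
        with pytest.raises(ValueError, match="[Mm]ultiallelic|decompose"):
            parse_vcf(path)

    def test_multi_sample_is_an_error(self, tmp_path):
        header = vcf_header("S1").replace("FORMAT\tS1", "FORMAT\tS1\tS2")
        path = tmp_path / "two.vcf"
        path.write_text(
            header + "1\t100\t.\tA\tT\t50.0\tPASS\tGENE=G1;CSQ=MISSENSE_VARIANT\tGT\t0/1\t0/1\n"
        )
        with pytest.raises(ValueError, match="single-sample"):
            parse_vcf(path)

    def test_missing_genotype_skipped_with_warning(self, tmp_path):
        rows = ["1\t100\t.\tA\tT\t50.0\tPASS\tGENE=G1;CSQ=MISSENSE_VARIANT\tGT\t./."]
        path = write_toy_vcf(tmp_path / "nogt.vcf", rows)
        with pytest.warns(UserWarning, match="missing genotype"):
            assert parse_vcf(path) == []

    def test_side_tables_and_whitelist_attach_by_key(self, tmp_path):
        path = write_toy_vcf(tmp_path / "toy.vcf")
        key = ("1", 1000, "A", "T")
        records = parse_vcf(
            path,
            frequencies={key: {"LOCAL": 0.01}},
            pathogenicity={key: {"SIFT": 0.0}},
            whitelist={key},
        )
        v = records[0]
        assert v.frequencies == {"LOCAL": 0.01}
        assert v.pathogenicity == {"SIFT": 0.0}
        assert v.whitelisted

    def test_round_trip_on_generated_exome(self, tmp_path, cohort50):
        truth = cohort50.truths[0]
        original = parse_vcf(cohort50.vcf_path(truth.patient_id), pass_only=False,
                             sex=truth.sex)
        assert len(original) > 200
        out = tmp_path / "rt.vcf"
        write_vcf(original, out, sample=truth.patient_id)
        again = parse_vcf(out, pass_only=False, sex=truth.sex)
        assert len(again) == len(original)
        for a, b in zip(original, again):
            assert (a.key, a.gene, a.consequence, a.genotype, a.filter_field) == (
                b.key, b.gene, b.consequence, b.genotype, b.filter_field
            )
            assert a.qual == pytest.approx(b.qual, rel=1e-5)


class TestRecordInvariants:
    def test_position_and_maf_validation(self):
        with pytest.raises(ValueError):
            make_record(pos=0)
        with pytest.raises(ValueError):
            make_record(frequencies={"LOCAL": 150.0})

    def test_chrom_normalization(self):
        assert make_record(chrom="chrX").chrom == "X"
        assert make_record(chrom="chrM").chrom == "MT"


class TestQualityFilter:
    def test_boundary_inclusive(self):
        assert quality_filter(make_record(qual=30.0), 30.0)
        assert not quality_filter(make_record(qual=29.9), 30.0)
        assert not quality_filter(make_record(qual=None), 30.0)

    def test_random_quals_match_threshold_oracle(self):
        rng = np.random.default_rng(0)
        quals = rng.uniform(0, 60, size=1000)
        passed = sum(quality_filter(make_record(qual=q), 30.0) for q in quals)
        assert passed == int((quals >= 30.0).sum())


class TestEffectFilter:
    def test_removal_list_and_whitelist_bypass(self):
        utr = make_record(consequence=Consequence.FIVE_PRIME_UTR_EXON_VARIANT)
        assert not variant_effect_filter(utr, DEFAULT_REMOVE_EFFECTS)
        assert variant_effect_filter(make_record(), DEFAULT_REMOVE_EFFECTS)
        wl = make_record(
            consequence=Consequence.FIVE_PRIME_UTR_EXON_VARIANT, whitelisted=True
        )
        assert variant_effect_filter(wl, DEFAULT_REMOVE_EFFECTS)

    def test_unknown_label_strict_or_warning(self):
        with pytest.raises(ValueError):
            variant_effect_filter(make_record(), ["NOT_A_CONSEQUENCE"])
        with pytest.warns(UserWarning):
            assert variant_effect_filter(make_record(), ["NOT_A_CONSEQUENCE"], strict=False)


class TestFrequency:
    def test_max_maf_cases(self):
        assert max_maf(make_record(), ["LOCAL"]) == 0.0
        v = make_record(frequencies={"GNOMAD_E_NFE": 0.01, "LOCAL": 0.0097})
        assert max_maf(v, ["GNOMAD_E_NFE", "LOCAL"]) == 0.01
        assert max_maf(v, ["LOCAL"]) == 0.0097

    def test_max_maf_matches_bruteforce_oracle(self):
        rng = np.random.default_rng(1)
        sources = [f"S{i}" for i in range(6)]
        for _ in range(50):
            freqs = {
                s: float(rng.uniform(0, 5)) for s in sources if rng.random() < 0.6
            }
            chosen = [s for s in sources if rng.random() < 0.7]
            v = make_record(frequencies=freqs)
            expected = max([freqs[s] for s in chosen if s in freqs], default=0.0)
            assert max_maf(v, chosen) == expected

    def test_frequency_filter_boundary(self):
        assert frequency_filter(2.0, 2.0)
        assert not frequency_filter(2.5, 2.0)


class TestWhitelist:
    def test_exact_tuple_match_only(self):
        wl = {("1", 100, "A", "T")}
        assert whitelist_bypass(make_record(), wl).whitelisted
        assert not whitelist_bypass(make_record(alt="G"), wl).whitelisted

    def test_flag_set_equals_membership_oracle(self):
        rng = np.random.default_rng(2)
        keys = [("1", int(p), "A", "T") for p in rng.integers(1, 500, size=100)]
        wl = {k for k in keys if rng.random() < 0.5}
        for k in keys:
            v = make_record(pos=k[1])
            assert whitelist_bypass(v, wl).whitelisted == (k in wl)


CUTOFFS = {
    ModeOfInheritance.AD: 0.1,
    ModeOfInheritance.AR_HOM: 0.5,
    ModeOfInheritance.AR_COMPHET: 2.0,
    ModeOfInheritance.XR_HOM: 0.5,
    ModeOfInheritance.XR_COMPHET: 2.0,
    ModeOfInheritance.MT: 0.2,
}
SOURCES = ("LOCAL",)


def assemble(variants, moi, sex="unknown"):
    return assemble_candidate_genotypes(
        variants, moi, CUTOFFS, frequency_sources=SOURCES, sex=sex
    )


class TestAssembly:
    def test_single_het_yields_no_recessive_candidate(self):
        het = make_record()
        assert assemble([het], ModeOfInheritance.AR_HOM) == []
        assert assemble([het], ModeOfInheritance.AR_COMPHET) == []

    def test_three_hets_give_all_pairs(self):
        hets = [make_record(pos=100 + i) for i in range(3)]
        pairs = assemble(hets, ModeOfInheritance.AR_COMPHET)
        assert len(pairs) == 3  # C(3, 2)
        seen = {frozenset(v.pos for v in c.variants) for c in pairs}
        assert seen == {frozenset(p) for p in itertools.combinations([100, 101, 102], 2)}

    def test_per_moi_cutoffs_differ(self):
        rare_ish = make_record(frequencies={"LOCAL": 0.3})
        assert assemble([rare_ish], ModeOfInheritance.AD) == []  # 0.3 > 0.1
        partner = make_record(pos=200, frequencies={"LOCAL": 0.01})
        pairs = assemble([rare_ish, partner], ModeOfInheritance.AR_COMPHET)
        assert len(pairs) == 1  # both <= 2.0

    def test_whitelist_bypasses_moi_cutoff(self):
        common = make_record(frequencies={"LOCAL": 1.5}, whitelisted=True)
        assert len(assemble([common], ModeOfInheritance.AD)) == 1

    def test_het_never_forms_homozygous_candidate(self):
        # the generated analogue of a mis-called homozygote: filtered out
        het_on_x = make_record(chrom="X", genotype=Genotype.HET)
        assert assemble([het_on_x], ModeOfInheritance.XR_HOM) == []
        with pytest.raises(ValueError):
            CandidateGenotype(
                gene="G1", moi=ModeOfInheritance.AR_HOM, variants=(make_record(),)
            )

    def test_unknown_sex_x_hom_counts_as_ar_and_xr(self):
        x_hom = make_record(chrom="X", genotype=Genotype.HOM_ALT)
        assert len(assemble([x_hom], ModeOfInheritance.AR_HOM, sex="unknown")) == 1
        assert len(assemble([x_hom], ModeOfInheritance.XR_HOM, sex="unknown")) == 1
        assert assemble([x_hom], ModeOfInheritance.AR_HOM, sex="female") == []

    def test_chromosome_domains(self):
        mt = make_record(chrom="MT", genotype=Genotype.HOM_ALT, frequencies={"LOCAL": 0.1})
        assert len(assemble([mt], ModeOfInheritance.MT)) == 1
        assert assemble([mt], ModeOfInheritance.AD) == []
        hemi = make_record(chrom="X", genotype=Genotype.HEMI)
        assert len(assemble([hemi], ModeOfInheritance.XR_HOM)) == 1

    def test_filter_cascade_is_order_invariant(self):
        rng = np.random.default_rng(3)
        consequences = list(Consequence)
        records = [
            make_record(
                pos=1 + i,
                qual=float(rng.uniform(0, 60)),
                consequence=consequences[int(rng.integers(len(consequences)))],
                frequencies={"LOCAL": float(rng.uniform(0, 4))},
            )
            for i in range(200)
        ]
        filters = [
            lambda v: quality_filter(v, 30.0),
            lambda v: variant_effect_filter(v, DEFAULT_REMOVE_EFFECTS),
            lambda v: v.whitelisted or frequency_filter(max_maf(v, SOURCES), 2.0),
        ]
        results = []
        for order in itertools.permutations(filters):
            surviving = records
            for f in order:
                surviving = [v for v in surviving if f(v)]
            results.append([v.key for v in surviving])
        assert all(r == results[0] for r in results)
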