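"""Frequency/pathogenicity normalization, variant and genotype scores."""

from __future__ import annotations

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from phenoprio import (
    Consequence,
    Genotype,
    ModeOfInheritance,
    frequency_score,
    genotype_score,
    normalize_source_score,
    pathogenicity_score,
    select_contributing,
    variant_score,
)
from phenoprio.variants import CandidateGenotype

from test_variants import make_record


class TestFrequencyScore:
    def test_absent_allele_scores_one(self):
        assert frequency_score(0.0) == 1.0

    def test_worked_rare_allele(self):
        # max MAF 0.0097 percent -> 0.9987, i.e. 0.999 at report precision
        s = frequency_score(0.0097)
        assert s == pytest.approx(1.13533 - 0.13533 * math.exp(0.0097))
        assert round(s, 3) == 0.999

    def test_clipped_above_two_percent(self):
        assert frequency_score(3.0) == 0.0
        assert frequency_score(2.0001) == 0.0

    def test_formula_zero_crossing_clamped(self):
        # 1.13533 = 0.13533 * e^f  =>  f = ln(1.13533/0.13533) ~ 2.1269 percent
        crossing = math.log(1.13533 / 0.13533)
        assert 2.12 < crossing < 2.13
        # the raw formula would be negative past the crossing but stays clamped
        assert frequency_score(2.0) > 0.0

    def test_strictly_decreasing_on_open_interval(self):
        grid = np.linspace(1e-6, 2.0, 500)
        values = [frequency_score(f) for f in grid]
        assert all(a > b for a, b in zip(values, values[1:]))

    def test_negative_frequency_is_an_error(self):
        with pytest.raises(ValueError):
            frequency_score(-0.1)

    @given(st.floats(min_value=0.0, max_value=100.0, allow_nan=False))
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_always_within_unit_interval(self, f):
        assert 0.0 <= frequency_score(f) <= 1.0


class TestNormalization:
    def test_sift_inverted(self):
        assert normalize_source_score("SIFT", 0.0) == 1.0
        assert normalize_source_score("SIFT", 1.0) == 0.0

    def test_cadd_phred_closed_form(self):
        assert normalize_source_score("CADD", 10.0) == pytest.approx(0.9)
        assert normalize_source_score("CADD", 20.0) == pytest.approx(0.99)

    @pytest.mark.parametrize(
        "source", ["POLYPHEN", "MUTATION_TASTER", "REVEL", "M_CAP", "MPC", "MVP", "PRIMATE_AI"]
    )
    def test_identity_sources_clamped(self, source):
        assert normalize_source_score(source, 0.7) == 0.7
        with pytest.warns(UserWarning):
            assert normalize_source_score(source, 1.4) == 1.0

    def test_monotone_in_deleteriousness(self):
        # increasing raw deleteriousness must increase the normalized score
        grid = np.linspace(0.0, 1.0, 21)
        sift = [normalize_source_score("SIFT", r) for r in grid]
        assert all(a >= b for a, b in zip(sift, sift[1:]))
        cadd = [normalize_source_score("CADD", r) for r in np.linspace(0, 50, 21)]
        assert all(a <= b for a, b in zip(cadd, cadd[1:]))


class TestPathogenicityScore:
    def test_lof_fixed_at_one_despite_conflicting_source(self):
        v = make_record(
            consequence=Consequence.FRAMESHIFT_VARIANT, pathogenicity={"SIFT": 0.6}
        )
        score, provenance = pathogenicity_score(v, ["SIFT"])
        assert score == 1.0
        assert provenance.startswith("fixed:")

    def test_splice_region_fixed(self):
        v = make_record(consequence=Consequence.SPLICE_REGION_VARIANT)
        assert pathogenicity_score(v, ["SIFT"])[0] == 0.8

    def test_max_of_selected_sources(self):
        v = make_record(
            pathogenicity={"SIFT": 0.4, "POLYPHEN": 0.55, "MUTATION_TASTER": 0.9}
        )
        score, provenance = pathogenicity_score(v, ["SIFT", "POLYPHEN", "MUTATION_TASTER"])
        assert score == 0.9
        assert provenance == "MUTATION_TASTER"
        # unselected sources are invisible
        assert pathogenicity_score(v, ["POLYPHEN"])[0] == 0.55

    @pytest.mark.parametrize(
        "csq,preset",
        [
            (Consequence.INFRAME_DELETION, 0.85),
            (Consequence.INFRAME_INSERTION, 0.85),
            (Consequence.MISSENSE_VARIANT, 0.6),
            (Consequence.SYNONYMOUS_VARIANT, 0.1),
        ],
    )
    def test_presets_when_no_source_has_data(self, csq, preset):
        v = make_record(consequence=csq)
        score, provenance = pathogenicity_score(v, ["SIFT", "POLYPHEN"])
        assert score == preset
        assert provenance.startswith("preset:")

    def test_fixed_scores_invariant_to_source_selection(self):
        v = make_record(
            consequence=Consequence.STOP_GAINED, pathogenicity={"SIFT": 0.9, "CADD": 5.0}
        )
        for sources in ([], ["SIFT"], ["CADD"], ["SIFT", "CADD"]):
            assert pathogenicity_score(v, sources)[0] == 1.0


class TestVariantScore:
    def test_product_rule_reproduces_worked_splice_acceptor(self):
        v = make_record(
            consequence=Consequence.SPLICE_ACCEPTOR_VARIANT,
            frequencies={"LOCAL": 0.0097},
            pathogenicity={"MUTATION_TASTER": 1.0},
        )
        b = variant_score(v, ["LOCAL"], ["MUTATION_TASTER"])
        assert b.pathogenicity_score == 1.0
        assert round(b.variant_score, 3) == 0.999

    def test_whitelist_override_dominates(self):
        v = make_record(
            frequencies={"LOCAL": 1.5},
            pathogenicity={"POLYPHEN": 0.3},
            whitelisted=True,
        )
        b = variant_score(v, ["LOCAL"], ["POLYPHEN"])
        assert b.variant_score == 1.0
        assert b.whitelist_override

    def test_zero_pathogenicity_annihilates(self):
        v = make_record(
            consequence=Consequence.MISSENSE_VARIANT, pathogenicity={"SIFT": 1.0}
        )
        assert variant_score(v, ["LOCAL"], ["SIFT"]).variant_score == 0.0

    @given(
        st.floats(min_value=0.0, max_value=5.0),
        st.floats(min_value=0.0, max_value=1.0),
    )
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_score_in_unit_interval(self, maf, raw):
        v = make_record(frequencies={"LOCAL": maf}, pathogenicity={"POLYPHEN": raw})
        b = variant_score(v, ["LOCAL"], ["POLYPHEN"])
        assert 0.0 <= b.variant_score <= 1.0
        assert b.variant_score == pytest.approx(
            b.frequency_score * b.pathogenicity_score
        )


def _scored_pair(v1, v2, sources=("LOCAL",), path_sources=("MUTATION_TASTER",)):
    moi = ModeOfInheritance.AR_COMPHET
    g = CandidateGenotype(gene=v1.gene, moi=moi, variants=(v1, v2))
    breakdowns = {
        v.key: variant_score(v, sources, path_sources) for v in (v1, v2)
    }
    return g, breakdowns


class TestGenotypeScore:
    def test_comphet_mean_reproduces_worked_example(self):
        # whitelisted frameshift (1.0) + inframe deletion at preset 0.85 with
        # a rare allele -> mean 0.924 at report precision
        v1 = make_record(
            pos=100, consequence=Consequence.FRAMESHIFT_VARIANT, whitelisted=True
        )
        v2 = make_record(
            pos=200,
            consequence=Consequence.INFRAME_DELETION,
            frequencies={"LOCAL": 0.0},
        )
        g, breakdowns = _scored_pair(v1, v2)
        gs = genotype_score(g, breakdowns)
        assert breakdowns[v2.key].variant_score == pytest.approx(0.85)
        assert gs.score == pytest.approx((1.0 + 0.85) / 2)

    def test_comphet_mean_of_equal_scores(self):
        vals = []
        for pos in (100, 200):
            v = make_record(
                pos=pos,
                consequence=Consequence.SPLICE_ACCEPTOR_VARIANT,
                frequencies={"LOCAL": 0.0097},
            )
            vals.append(v)
        g, breakdowns = _scored_pair(*vals)
        gs = genotype_score(g, breakdowns)
        assert round(gs.score, 3) == 0.999

    def test_homozygote_score_is_single_variant_score(self):
        v = make_record(genotype=Genotype.HOM_ALT, consequence=Consequence.STOP_GAINED)
        g = CandidateGenotype(gene="G1", moi=ModeOfInheritance.AR_HOM, variants=(v,))
        breakdowns = {v.key: variant_score(v, ["LOCAL"], [])}
        gs = genotype_score(g, breakdowns)
        assert gs.score == breakdowns[v.key].variant_score
        assert gs.contributing == (v,)

    def test_mean_bounded_by_member_scores(self):
        v1 = make_record(pos=100, consequence=Consequence.STOP_GAINED)
        v2 = make_record(pos=200, frequencies={"LOCAL": 1.0},
                         pathogenicity={"MUTATION_TASTER": 0.5})
        g, breakdowns = _scored_pair(v1, v2)
        gs = genotype_score(g, breakdowns)
        member = [breakdowns[v.key].variant_score for v in g.variants]
        assert min(member) <= gs.score <= max(member)


class TestSelectContributing:
    def test_best_pair_wins(self):
        v1 = make_record(pos=100, consequence=Consequence.STOP_GAINED)
        v2 = make_record(pos=200, consequence=Consequence.STOP_GAINED)
        v3 = make_record(pos=300, pathogenicity={"MUTATION_TASTER": 0.5})
        scores = []
        for a, b in [(v1, v2), (v1, v3), (v2, v3)]:
            g, breakdowns = _scored_pair(a, b)
            scores.append(genotype_score(g, breakdowns))
        all_breakdowns = {
            v.key: variant_score(v, ["LOCAL"], ["MUTATION_TASTER"])
            for v in (v1, v2, v3)
        }
        best = select_contributing(scores, all_breakdowns)
        assert {v.pos for v in best.contributing} == {100, 200}

    def test_matches_argmax_oracle_exhaustively(self):
        rng = np.random.default_rng(4)
        variants = [
            make_record(
                pos=100 + i,
                frequencies={"LOCAL": float(rng.uniform(0, 1.5))},
                pathogenicity={"MUTATION_TASTER": float(rng.uniform(0, 1))},
            )
            for i in range(5)
        ]
        breakdowns = {
            v.key: variant_score(v, ["LOCAL"], ["MUTATION_TASTER"]) for v in variants
        }
        import itertools

        scores = []
        for a, b in itertools.combinations(variants, 2):
            g = CandidateGenotype(
                gene="G1", moi=ModeOfInheritance.AR_COMPHET, variants=(a, b)
            )
            scores.append(genotype_score(g, breakdowns))
        best = select_contributing(scores, breakdowns)
        assert best.score == max(gs.score for gs in scores)

    def test_a_better_partner_displaces_a_true_variant(self):
        # one diagnosed het is beaten by a higher-scoring background partner:
        # only one of the two true variants ends up contributing
        true1 = make_record(pos=100, consequence=Consequence.STOP_GAINED)
        true2 = make_record(pos=200, consequence=Consequence.INFRAME_DELETION)
        background = make_record(pos=300, consequence=Consequence.STOP_GAINED)
        breakdowns = {
            v.key: variant_score(v, ["LOCAL"], []) for v in (true1, true2, background)
        }
        import itertools

        scores = [
            genotype_score(
                CandidateGenotype(
                    gene="G1", moi=ModeOfInheritance.AR_COMPHET, variants=(a, b)
                ),
                breakdowns,
            )
            for a, b in itertools.combinations((true1, true2, background), 2)
        ]
        best = select_contributing(scores, breakdowns)
        positions = {v.pos for v in best.contributing}
        assert positions == {100, 300}  # true2 displaced
        assert not {100, 200} <= positions

    def test_tie_break_is_deterministic(self):
        a = make_record(pos=100, consequence=Consequence.STOP_GAINED)
        b = make_record(pos=200, consequence=Consequence.STOP_GAINED,
                        frequencies={"LOCAL": 0.01})
        breakdowns = {v.key: variant_score(v, ["LOCAL"], []) for v in (a, b)}
        gs = [
            genotype_score(
                CandidateGenotype(gene="G1", moi=ModeOfInheritance.AD, variants=(v,)),
                breakdowns,
            )
            for v in (a, b)
        ]
        # a: score 1.0 at MAF 0; b: score <1 -> a wins; with equal scores the
        # lower-MAF candidate would win, and ordering of the input is irrelevant
        assert select_contributing(gs, breakdowns).contributing[0].pos == 100
        assert select_contributing(gs[::-1], breakdowns).contributing[0].pos == 100
        assert select_contributing([], breakdowns) is None
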