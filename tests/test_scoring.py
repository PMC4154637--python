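import numpy as np
import pytest

from pep2path.errors import EmptyDatabaseError, UnknownMonomerError
from pep2path.model import BGCDatabase, NRPSModule, SpecificityPrediction, TaxonQuery
from pep2path.scoring import (
    Alignment,
    ScoringParams,
    baseline_probability,
    colinearity_index,
    enumerate_orderings,
    match_value,
    position_score,
    rank_bgcs,
    score_tag_against_bgc,
)
from pep2path.tags import TagPosition, reverse_tag

from _reference import ref_best_score
from conftest import (
    make_entry,
    make_prediction,
    random_small_bgc,
    random_tag,
    singleton_tag,
)

# ln(P(A|M)/P(A)) at Ibar=1, P(A)=0.05, defaults c=1, x=0.01, eta=2
PERFECT_TERM = 2.9862818177424737
# ln(x / (c + x)) at Ibar=0, defaults
ZERO_TERM = -4.61512051684126


def _module(pred: SpecificityPrediction) -> NRPSModule:
    return NRPSModule(gene_id="g", index_in_gene=0, prediction=pred)


class TestBaseline:
    def test_smoothed_frequencies(self, small_freq):
        assert baseline_probability("ala", small_freq) == pytest.approx(0.5)
        assert baseline_probability("ser", small_freq) == pytest.approx(0.125)

    def test_degenerate_position_uses_flat_alphabet_baseline(self, uniform20_freq):
        pos = TagPosition(candidates=frozenset({"thr", "ser"}))
        assert baseline_probability(pos, uniform20_freq) == pytest.approx(0.05)

    def test_degenerate_baseline_ignores_counts(self, small_freq):
        pos = TagPosition(candidates=frozenset({"ala", "gly"}))
        assert baseline_probability(pos, small_freq) == pytest.approx(0.25)

    def test_monomer_outside_alphabet_rejected(self, small_freq):
        with pytest.raises(UnknownMonomerError):
            baseline_probability("orn", small_freq)


class TestMatchValue:
    def test_mean_of_svm_and_stachelhaus_channels(self):
        pred = SpecificityPrediction(
            stachelhaus_best_match=frozenset({"val"}),
            stachelhaus_identity=0.7,
            svm_single=frozenset(),
            svm_small_class=frozenset(),
            svm_large_class=frozenset({"val", "ile"}),
            svm_three_class=frozenset({"val", "ile", "leu"}),
        )
        pos = TagPosition(candidates=frozenset({"val"}))
        assert match_value(pos, _module(pred)) == pytest.approx((0.5 + 0.7) / 2)

    def test_no_support_anywhere_scores_zero(self):
        pred = make_prediction("ala")
        pos = TagPosition(candidates=frozenset({"trp"}))
        assert match_value(pos, _module(pred)) == 0.0

    def test_degenerate_position_takes_best_candidate(self):
        pred = make_prediction("leu")  # svm single + stachelhaus identity 1.0
        pos = TagPosition(candidates=frozenset({"ile", "leu"}))
        assert match_value(pos, _module(pred)) == 1.0

    def test_missing_stachelhaus_channel_leaves_svm_alone(self):
        pred = SpecificityPrediction(
            svm_single=frozenset({"val"}),
            svm_small_class=frozenset({"val"}),
            svm_large_class=frozenset({"val"}),
            svm_three_class=frozenset({"val"}),
        )
        pos = TagPosition(candidates=frozenset({"val"}))
        assert match_value(pos, _module(pred)) == 1.0

    def test_missing_svm_channel_leaves_stachelhaus_alone(self):
        pred = SpecificityPrediction(
            stachelhaus_best_match=frozenset({"val"}), stachelhaus_identity=0.8
        )
        pos = TagPosition(candidates=frozenset({"val"}))
        assert match_value(pos, _module(pred)) == pytest.approx(0.8)

    def test_explicit_no_call_counts_as_zero_tier(self):
        pred = SpecificityPrediction(
            stachelhaus_best_match=frozenset({"val"}),
            stachelhaus_identity=1.0,
            svm_single=frozenset(), svm_small_class=frozenset(),
            svm_large_class=frozenset(), svm_three_class=frozenset(),
        )
        pos = TagPosition(candidates=frozenset({"val"}))
        assert match_value(pos, _module(pred)) == pytest.approx(0.5)


class TestPositionScore:
    def test_perfect_match_worked_value(self):
        assert position_score(1.0, 0.05, ScoringParams()) == pytest.approx(
            PERFECT_TERM, abs=1e-9
        )

    def test_zero_support_worked_value(self):
        for p_a in (0.05, 0.2, 0.9):
            assert position_score(0.0, p_a, ScoringParams()) == pytest.approx(
                ZERO_TERM, abs=1e-9
            )

    def test_c_zero_is_exactly_baseline_neutral(self):
        for i_bar in (0.0, 0.3, 1.0):
            assert position_score(i_bar, 0.1, ScoringParams(c=0.0)) == 0.0

    def test_strictly_increasing_in_support(self):
        params = ScoringParams()
        values = [position_score(i / 10, 0.05, params) for i in range(11)]
        assert all(b > a for a, b in zip(values, values[1:]))

    def test_nonincreasing_in_eta_below_perfect_support(self):
        for i_bar in (0.2, 0.5, 0.9):
            scores = [
                position_score(i_bar, 0.05, ScoringParams(eta=eta))
                for eta in (1.0, 2.0, 3.0, 5.0)
            ]
            assert all(b <= a for a, b in zip(scores, scores[1:]))

    def test_eta_invariant_at_support_extremes(self):
        for i_bar in (0.0, 1.0):
            reference = position_score(i_bar, 0.05, ScoringParams(eta=1.0))
            for eta in (2.0, 4.0):
                assert position_score(i_bar, 0.05, ScoringParams(eta=eta)) == pytest.approx(
                    reference, abs=1e-12
                )

    def test_invalid_baseline_rejected(self):
        with pytest.raises(ValueError):
            position_score(0.5, 0.0, ScoringParams())


class TestOrderings:
    def test_two_genes_give_two_orderings_of_all_modules(self):
        bgc = make_entry("x", [["ala", "gly"], ["ser", "val", "thr"]])
        orderings, capped = enumerate_orderings(bgc)
        assert len(orderings) == 2
        assert all(len(o) == 5 for o in orderings)
        assert not capped

    def test_single_gene_has_one_ordering(self):
        orderings, capped = enumerate_orderings(make_entry("x", [["ala", "gly"]]))
        assert len(orderings) == 1 and not capped

    def test_four_genes_give_24(self):
        bgc = make_entry("x", [["ala"], ["gly"], ["ser"], ["val"]])
        orderings, _ = enumerate_orderings(bgc)
        assert len(orderings) == 24

    def test_cap_truncates_deterministically_and_flags(self):
        bgc = make_entry("x", [["ala"], ["gly"], ["ser"], ["val"]])
        full, _ = enumerate_orderings(bgc)
        truncated, capped = enumerate_orderings(bgc, cap=10)
        assert capped
        assert [[m.prediction for m in o] for o in truncated] == [
            [m.prediction for m in o] for o in full[:10]
        ]


class TestColinearity:
    def _alignment(self, modules, orientation="forward"):
        pos = TagPosition(candidates=frozenset({"ala"}))
        return Alignment(
            ordering=("g",), offset=0, orientation=orientation,
            pairs=tuple((pos, m) for m in modules),
        )

    def test_native_forward_run_scores_one(self):
        bgc = make_entry("x", [["ala", "gly", "ser"]])
        assert colinearity_index(self._alignment(bgc.genes[0].modules)) == 1.0

    def test_reversed_run_scores_zero(self):
        bgc = make_entry("x", [["ala", "gly", "ser"]])
        al = self._alignment(tuple(reversed(bgc.genes[0].modules)), "reversed")
        assert colinearity_index(al) == 0.0

    def test_half_colinear_across_permuted_gene_boundary(self):
        bgc = make_entry("x", [["ala", "gly"], ["ser"]])
        g1, g2 = bgc.genes
        # tag meets g1/0, g1/1 (native-consecutive), then g2/0 (break)
        al = self._alignment((g1.modules[0], g1.modules[1], g2.modules[0]))
        assert colinearity_index(al) == 0.5

    def test_length_one_is_one_by_convention(self):
        bgc = make_entry("x", [["ala"]])
        assert colinearity_index(self._alignment(bgc.genes[0].modules[:1])) == 1.0


class TestClusterScore:
    def test_perfect_eight_position_match_sums_terms(self, uniform20_freq):
        monomers = ["val", "val", "thr", "ser", "ala", "ile", "val", "gly"]
        bgc = make_entry("perfect", [monomers])
        tag = singleton_tag(monomers)
        sc = score_tag_against_bgc(tag, bgc, uniform20_freq)
        assert sc.S == pytest.approx(8 * PERFECT_TERM, abs=1e-9)
        assert sc.colinearity == 1.0
        assert round(sc.S, 2) == 23.89

    def test_all_mismatches_sum_zero_terms(self, uniform20_freq):
        bgc = make_entry("wrong", [["trp", "trp", "trp", "trp"]])
        tag = singleton_tag(["ala", "gly", "ser", "val"])
        sc = score_tag_against_bgc(tag, bgc, uniform20_freq)
        assert sc.S == pytest.approx(4 * ZERO_TERM, abs=1e-9)

    def test_extending_a_perfect_match_adds_exactly_one_term(self, uniform20_freq):
        short = ["val", "thr", "ala", "gly"]
        bgc = make_entry("x", [short + ["ser"]])
        s_short = score_tag_against_bgc(singleton_tag(short), bgc, uniform20_freq).S
        s_long = score_tag_against_bgc(
            singleton_tag(short + ["ser"]), bgc, uniform20_freq
        ).S
        assert s_long - s_short == pytest.approx(PERFECT_TERM, abs=1e-9)

    def test_tag_longer_than_module_chain_is_inadmissible(self, uniform20_freq):
        bgc = make_entry("tiny", [["ala", "gly"]])
        sc = score_tag_against_bgc(
            singleton_tag(["ala", "gly", "ser"]), bgc, uniform20_freq
        )
        assert not sc.admissible and sc.S == float("-inf")

    def test_orientation_symmetry(self, uniform20_freq):
        rng = np.random.default_rng(21)
        for i in range(10):
            bgc = random_small_bgc(rng, f"b{i}")
            tag = random_tag(rng, int(rng.integers(2, 6)))
            fwd = score_tag_against_bgc(tag, bgc, uniform20_freq)
            rev = score_tag_against_bgc(reverse_tag(tag), bgc, uniform20_freq)
            assert fwd.S == pytest.approx(rev.S, abs=1e-12)

    def test_baseline_neutral_when_c_is_zero(self, uniform20_freq):
        rng = np.random.default_rng(3)
        bgc = random_small_bgc(rng, "b")
        tag = random_tag(rng, 3)
        sc = score_tag_against_bgc(tag, bgc, uniform20_freq, ScoringParams(c=0.0))
        assert sc.S == 0.0

    def test_matches_exhaustive_enumeration_exactly(self, uniform20_freq):
        rng = np.random.default_rng(42)
        for i in range(40):
            bgc = random_small_bgc(rng, f"bgc{i}")
            tag = random_tag(rng, int(rng.integers(2, 6)))
            got = score_tag_against_bgc(tag, bgc, uniform20_freq)
            want = ref_best_score(tag, bgc, uniform20_freq)
            if not got.admissible:
                assert want == float("-inf")
                continue
            assert got.S == pytest.approx(want, abs=1e-12), f"bgc{i}"
            # the reported argmax alignment must itself attain the score
            recomputed = sum(
                position_score(
                    match_value(p, m), baseline_probability(p, uniform20_freq),
                    ScoringParams(),
                )
                for p, m in got.best_alignment.pairs
            )
            assert recomputed == pytest.approx(got.S, abs=1e-12)


class TestRanking:
    def test_planted_perfect_bgc_ranks_first(self, uniform20_freq):
        monomers = ["val", "thr", "ala", "gly", "ser", "leu"]
        planted = make_entry("planted", [monomers])
        decoys = [
            make_entry(f"d{i}", [["trp", "his", "met", "phe", "arg", "tyr"]])
            for i in range(5)
        ]
        db = BGCDatabase(entries=(planted, *decoys))
        ranked = rank_bgcs(singleton_tag(monomers), db, uniform20_freq)
        assert ranked[0].cluster_id == "planted" and ranked[0].rank == 1

    def test_identical_entries_share_rank_one(self, uniform20_freq):
        a = make_entry("aa", [["val", "thr"]])
        b = make_entry("bb", [["val", "thr"]])
        db = BGCDatabase(entries=(a, b))
        ranked = rank_bgcs(singleton_tag(["val", "thr"]), db, uniform20_freq)
        assert [sc.rank for sc in ranked] == [1, 1]
        # next distinct score would take rank 3 (competition ranking)

    def test_single_entry_ranks_first_regardless_of_score(self, uniform20_freq):
        db = BGCDatabase(entries=(make_entry("only", [["trp", "trp"]]),))
        ranked = rank_bgcs(singleton_tag(["ala", "gly"]), db, uniform20_freq)
        assert ranked[0].rank == 1

    def test_inadmissible_entries_rank_last(self, uniform20_freq):
        tiny = make_entry("tiny", [["ala"]])
        big = make_entry("big", [["trp", "trp", "trp"]])
        db = BGCDatabase(entries=(tiny, big))
        ranked = rank_bgcs(singleton_tag(["ala", "gly", "ser"]), db, uniform20_freq)
        assert ranked[-1].cluster_id == "tiny"
        assert not ranked[-1].admissible

    def test_colinearity_breaks_score_ties(self, uniform20_freq):
        # same module content, one entry natively ordered, one reversed:
        # equal S (both orientations searched) but different CI
        fwd = make_entry("fwd", [["val", "thr", "gly"]])
        rev = make_entry("rev", [["gly", "thr", "val"]])
        db = BGCDatabase(entries=(rev, fwd))
        ranked = rank_bgcs(
            singleton_tag(["val", "thr", "gly"]), db, uniform20_freq
        )
        assert ranked[0].cluster_id == "fwd"
        assert ranked[0].colinearity == 1.0
        assert ranked[1].colinearity == 0.0
        assert [sc.rank for sc in ranked] == [1, 2]

    def test_empty_database_after_filter_raises(self, uniform20_freq, two_entry_db):
        with pytest.raises(EmptyDatabaseError):
            rank_bgcs(
                singleton_tag(["ala"]), two_entry_db, uniform20_freq,
                taxon=TaxonQuery(value="archaea", rank="domain"),
            )
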