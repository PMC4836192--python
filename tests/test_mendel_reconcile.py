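"""Mendelian checks, FAP/IAP reconciliation and locus classification."""

from itertools import product

import numpy as np
import pytest

from aluktrio.core_io import (
    AluCall,
    Call,
    FapObservation,
    IapObservation,
    StrGenotype,
)
from aluktrio.kinship import trio_transmission_probability
from aluktrio.mendel_reconcile import (
    CompatibilitySet,
    Genotype,
    InterpretationMode,
    alu_compatibility_set,
    alu_trio_congruent,
    classify_dataset,
    classify_locus,
    count_consistent_autosomal,
    mask_iap,
    reconcile_call,
    reconcile_fap_iap,
    sex_marker_consistent,
    str_trio_consistent,
    str_trio_report,
    summarize,
)

STRICT = InterpretationMode.STRICT
TOLERANT = InterpretationMode.DROPOUT_TOLERANT


def g(a, b, locus="L"):
    return StrGenotype(locus, a, b)


def cset(*genotypes):
    return CompatibilitySet("L", "S", frozenset(Genotype(x) for x in genotypes))


def make_call(fap_p, fap_a, iap=IapObservation.NOT_TESTED, ancient=True,
              sample="S", locus="Alu_x"):
    return reconcile_call(
        AluCall(sample, locus, FapObservation(fap_p, fap_a), iap, ancient=ancient)
    )


# -- independent congruence oracle: transmitted-insert-count arithmetic -----

_TRANSMISSIBLE = {Genotype.PP: {1}, Genotype.PA: {0, 1}, Genotype.AA: {0}}
_CHILD_COUNT = {Genotype.PP: 2, Genotype.PA: 1, Genotype.AA: 0}


def oracle_congruent(m_set, f_set, c_set):
    """A trio is congruent iff some (gm, gf, gc) choice lets the child's
    insert count equal one transmitted count from each parent."""
    for gm, gf, gc in product(m_set.genotypes, f_set.genotypes, c_set.genotypes):
        for tm in _TRANSMISSIBLE[gm]:
            for tf in _TRANSMISSIBLE[gf]:
                if tm + tf == _CHILD_COUNT[gc]:
                    return True
    return False


def all_nonempty_sets():
    genos = list(Genotype)
    out = []
    for mask in range(1, 8):
        out.append(frozenset(genos[i] for i in range(3) if mask >> i & 1))
    return out


class TestStrTrioConsistent:
    @pytest.mark.parametrize(
        "mother,father,child,expected",
        [
            (("28", "29"), ("30.2", "32.2"), ("29", "32.2"), True),
            (("17", "19"), ("17", "19"), ("17", "17"), True),
            (("8", "8"), ("8", "8"), ("9", "12"), False),
            (("13", "14"), ("14", "15"), ("14", "14"), True),
        ],
    )
    def test_examples(self, mother, father, child, expected):
        assert str_trio_consistent(g(*mother), g(*father), g(*child)) is expected

    def test_missing_genotype_is_indeterminate(self):
        assert str_trio_consistent(None, g("1", "2"), g("1", "1")) is None

    def test_equivalent_to_positive_transmission_probability(self):
        """Cross-module oracle: consistency <=> transmission prob > 0."""
        rng = np.random.default_rng(7)
        labels = [str(i) for i in range(8, 13)]
        for _ in range(1000):
            m = g(*rng.choice(labels, 2))
            f = g(*rng.choice(labels, 2))
            c = g(*rng.choice(labels, 2))
            assert str_trio_consistent(m, f, c) == (
                trio_transmission_probability(m, f, c) > 0
            )


class TestSexMarker:
    def test_daughter(self):
        assert sex_marker_consistent(g("X", "Y"), g("X", "X"), g("X", "X"))

    def test_son(self):
        assert sex_marker_consistent(g("X", "Y"), g("X", "X"), g("X", "Y"))

    def test_unexplained_y(self):
        assert not sex_marker_consistent(g("X", "X"), g("X", "X"), g("X", "Y"))

    def test_invalid_mother_is_an_error(self):
        with pytest.raises(ValueError, match="mother"):
            sex_marker_consistent(g("X", "Y"), g("X", "Y"), g("X", "X"))

    def test_malformed_genotype_is_an_error(self):
        with pytest.raises(ValueError, match="malformed"):
            sex_marker_consistent(g("X", "12"), g("X", "X"), g("X", "X"))


class TestCompatibilitySets:
    @pytest.mark.parametrize(
        "call,mode,expected",
        [
            (Call.PA, STRICT, {"PA"}),
            (Call.PP, STRICT, {"PP"}),
            (Call.AA, STRICT, {"AA"}),
            (Call.P_ANY, STRICT, {"PP", "PA"}),
            (Call.P_ANY, TOLERANT, {"PP", "PA"}),
            (Call.A_ONLY, STRICT, {"AA"}),
            (Call.A_ONLY, TOLERANT, {"AA", "PA"}),
        ],
    )
    def test_mapping(self, call, mode, expected):
        record = AluCall(
            "S", "L", FapObservation(False, False), IapObservation.NOT_TESTED,
            call=call,
        )
        got = alu_compatibility_set(record, mode)
        assert {x.value for x in got.genotypes} == expected

    def test_missing_call_rejected(self):
        record = AluCall(
            "S", "L", FapObservation(False, False), IapObservation.NOT_TESTED,
            call=Call.MISSING,
        )
        with pytest.raises(ValueError):
            alu_compatibility_set(record, STRICT)

    def test_empty_set_forbidden(self):
        with pytest.raises(ValueError):
            CompatibilitySet("L", "S", frozenset())


class TestCongruence:
    def test_de_novo_insert_is_incongruent(self):
        assert not alu_trio_congruent(cset("AA"), cset("AA"), cset("PA"))

    def test_heterozygote_from_mixed_parents(self):
        assert alu_trio_congruent(cset("PP", "PA"), cset("AA"), cset("PA"))

    def test_matches_independent_enumerator_everywhere(self):
        """Full agreement with the insert-count oracle on all 343 set triples."""
        sets = all_nonempty_sets()
        for gm, gf, gc in product(sets, sets, sets):
            m, f, c = (CompatibilitySet("L", "S", s) for s in (gm, gf, gc))
            assert alu_trio_congruent(m, f, c) == oracle_congruent(m, f, c)

    def test_congruence_is_monotone_in_set_inclusion(self):
        """Enlarging any compatibility set never flips congruent -> not."""
        sets = all_nonempty_sets()
        for gm, gf, gc in product(sets, sets, sets):
            m, f, c = (CompatibilitySet("L", "S", s) for s in (gm, gf, gc))
            if alu_trio_congruent(m, f, c):
                grown = CompatibilitySet("L", "S", gc | {Genotype.PA})
                assert alu_trio_congruent(m, f, grown)

    def test_dropout_tolerant_implied_by_strict(self):
        """Any trio of ancient calls congruent under strict interpretation
        stays congruent under dropout_tolerant (sets only grow)."""
        calls = [Call.PP, Call.PA, Call.AA, Call.P_ANY, Call.A_ONLY]
        for trio in product(calls, repeat=3):
            records = [
                AluCall("S", "L", FapObservation(False, False),
                        IapObservation.NOT_TESTED, call=c)
                for c in trio
            ]
            strict_sets = [alu_compatibility_set(r, STRICT) for r in records]
            tolerant_sets = [alu_compatibility_set(r, TOLERANT) for r in records]
            if alu_trio_congruent(*strict_sets):
                assert alu_trio_congruent(*tolerant_sets)

    def test_all_pa_capable_trios_congruent_in_tolerant_mode(self):
        """When every member could be PA the trio can never be incongruent."""
        pa_capable = [Call.PA, Call.P_ANY, Call.A_ONLY]
        for trio in product(pa_capable, repeat=3):
            sets = [
                alu_compatibility_set(
                    AluCall("S", "L", FapObservation(False, False),
                            IapObservation.NOT_TESTED, call=c),
                    TOLERANT,
                )
                for c in trio
            ]
            assert alu_trio_congruent(*sets)


class TestReconciliation:
    def test_truth_table_is_total(self):
        """Every (fap, iap, ancient) combination maps to exactly one call."""
        for p, a in product([True, False], repeat=2):
            for iap in IapObservation:
                for ancient in (True, False):
                    call, _ = reconcile_fap_iap(FapObservation(p, a), iap, ancient)
                    assert isinstance(call, Call)

    @pytest.mark.parametrize(
        "fap_p,fap_a,iap,ancient,expected",
        [
            (True, True, IapObservation.NOT_TESTED, True, Call.PA),
            (True, False, IapObservation.NOT_TESTED, True, Call.P_ANY),
            (True, False, IapObservation.NOT_TESTED, False, Call.PP),
            (False, True, IapObservation.BAND, True, Call.PA),  # the CR case
            (False, True, IapObservation.NO_BAND, True, Call.A_ONLY),
            (False, True, IapObservation.NOT_TESTED, False, Call.AA),
            (False, False, IapObservation.BAND, True, Call.P_ANY),
            (False, False, IapObservation.NOT_TESTED, True, Call.MISSING),
        ],
    )
    def test_truth_table(self, fap_p, fap_a, iap, ancient, expected):
        call, _ = reconcile_fap_iap(FapObservation(fap_p, fap_a), iap, ancient)
        assert call is expected

    def test_depleted_extract_records_reason(self):
        call, reason = reconcile_fap_iap(
            FapObservation(False, False), IapObservation.EXTRACT_DEPLETED, True
        )
        assert call is Call.MISSING
        assert reason == "extract_depleted"

    def test_mask_iap_hides_internal_primer_evidence(self):
        original = AluCall("S", "L", FapObservation(False, True),
                           IapObservation.BAND, ancient=True)
        assert reconcile_call(original).call is Call.PA
        assert reconcile_call(mask_iap(original)).call is Call.A_ONLY


class TestClassification:
    def test_all_heterozygous_definite(self):
        calls = [make_call(True, True, sample=s) for s in "MFC"]
        result = classify_locus(*calls)
        assert result.status == "definite"
        assert result.resolved_by == "FAP"

    def test_missing_father_incomplete(self):
        mother = make_call(True, True)
        father = make_call(False, False)
        child = make_call(True, True)
        assert classify_locus(mother, father, child).status == "incomplete"

    def test_presence_child_from_absence_parents_incongruent(self):
        mother = make_call(False, True)
        father = make_call(False, True)
        child = make_call(True, False)
        assert classify_locus(mother, father, child).status == "incongruent"

    def test_depleted_extract_not_investigated(self):
        mother = make_call(True, False)
        father = make_call(True, True)
        child = make_call(False, False, iap=IapObservation.EXTRACT_DEPLETED)
        assert classify_locus(mother, father, child).status == "not_investigated"

    def test_incomplete_beats_incongruent(self):
        """A missing member takes precedence over a parental conflict."""
        mother = make_call(False, True)
        father = make_call(False, True)
        child = make_call(False, False)  # missing trumps any congruence verdict
        result = classify_locus(mother, father, child)
        assert result.status == "incomplete"

    def test_combined_result_flagged_on_child(self):
        mother = make_call(True, False)
        father = make_call(False, True)
        child = make_call(False, True, iap=IapObservation.BAND)
        result = classify_locus(mother, father, child)
        assert result.status == "definite"
        assert result.child_cr
        assert result.resolved_by == "FAP+IAP"

    def test_empty_summary(self):
        s = summarize([])
        assert s.total == 0


class TestPaperFixtureClassification:
    def test_fap_and_iap_pass(self, paper_dataset):
        summary = summarize(classify_dataset(paper_dataset, use_iap=True))
        assert summary.definite == 26
        assert summary.incongruent == 2
        assert summary.not_investigated == 2

    def test_fap_only_pass(self, paper_dataset):
        summary = summarize(classify_dataset(paper_dataset, use_iap=False))
        assert summary.definite == 22

    def test_combined_results_are_the_documented_loci(self, paper_dataset):
        classifications = classify_dataset(paper_dataset, use_iap=True)
        cr = {c.locus_id for c in classifications if c.child_cr}
        assert cr == {"Alu_16", "Alu_26", "Alu_27"}
        rescued = {
            c.locus_id
            for c in classifications
            if c.resolved_by == "FAP+IAP" and c.status == "definite"
        }
        assert rescued == {"Alu_3", "Alu_14", "Alu_16", "Alu_19", "Alu_20",
                           "Alu_26", "Alu_27"}


class TestStrTrioReport:
    def test_paper_tables_fully_consistent(self, paper_dataset):
        report = str_trio_report(paper_dataset)
        assert count_consistent_autosomal(report) == 13
        amel = report[report["marker_type"] == "sex"]
        assert len(amel) == 1
        assert bool(amel["consistent"].iloc[0])

    def test_forced_breach_detected(self, paper_dataset):
        import copy

        ds = copy.copy(paper_dataset)
        ds.str_genotypes = dict(paper_dataset.str_genotypes)
        ds.str_genotypes[("DO3750", "D13S317")] = StrGenotype("D13S317", "10", "11")
        report = str_trio_report(ds)
        assert count_consistent_autosomal(report) == 12
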