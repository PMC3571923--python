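import math

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pkddi import synthetic
from pkddi.relation_rules import (CueEvidence, DEFAULT_CONFIG,
                                  IN_VITRO_LABELS, IN_VIVO_LABELS,
                                  InteractionCandidate, QuantEvidence,
                                  RuleConfig, classify, classify_cues,
                                  classify_quant, cue_polarity,
                                  label_sentence, percent_to_fold,
                                  rank_parameter)
from pkddi.tagger import KeyTerm, Span


def term(cat, norm, start=0):
    return KeyTerm(Span(0, start, start + max(1, len(norm)), norm), cat,
                   norm)


class TestPercentToFold:
    @pytest.mark.parametrize("pct,direction,expected", [
        (64, "decrease", 0.36),
        (0, "increase", 1.0),
        (50, "increase", 1.5),
    ])
    def test_arithmetic(self, pct, direction, expected):
        assert percent_to_fold(pct, direction) == pytest.approx(expected)

    def test_domain_error(self):
        with pytest.raises(ValueError):
            percent_to_fold(-150, "increase")
        with pytest.raises(ValueError):
            percent_to_fold(120, "decrease")


class TestRankParameter:
    def test_auc_outranks_cmax(self):
        auc = QuantEvidence("AUC", "fold_change", 1.5)
        cmax = QuantEvidence("Cmax", "fold_change", 1.3)
        assert rank_parameter([cmax, auc], "in_vivo") is auc

    def test_ki_outranks_ic50(self):
        ki = QuantEvidence("Ki", "ki", 24.9)
        ic50 = QuantEvidence("IC50", "ic50", 5.0)
        assert rank_parameter([ic50, ki], "in_vitro") is ki

    def test_unranked_below_ranked(self):
        mr = QuantEvidence("MR", "fold_change", 5.0)
        cmax = QuantEvidence("Cmax", "fold_change", 1.1)
        assert rank_parameter([mr, cmax], "in_vivo") is cmax

    def test_single_item(self):
        ev = QuantEvidence("AUC", "fold_change", 2.0)
        assert rank_parameter([ev], "in_vivo") is ev

    def test_empty_list_errors(self):
        with pytest.raises(ValueError):
            rank_parameter([], "in_vivo")

    def test_tie_broken_by_log_fold_magnitude(self):
        small = QuantEvidence("AUC", "fold_change", 1.2)
        big = QuantEvidence("AUC", "fold_change", 3.0)
        assert rank_parameter([small, big], "in_vivo") is big


# hand-enumerated truth table from the strict band inequalities
IN_VIVO_GRID = {
    (0.3, 0.01): "DDI", (0.3, 0.2): "ADDI",
    (0.67, 0.01): "ADDI", (0.67, 0.2): "ADDI",   # boundary -> ambiguous
    (1.0, 0.01): "ADDI", (1.0, 0.2): "NDDI",
    (1.5, 0.01): "ADDI", (1.5, 0.2): "ADDI",     # boundary -> ambiguous
    (2.0, 0.01): "DDI", (2.0, 0.2): "ADDI",
}
KI_GRID = {
    (5.0, 0.01): "DEI", (5.0, 0.2): "ADEI",
    (50.0, 0.01): "ADEI", (50.0, 0.2): "ADEI",
    (500.0, 0.01): "ADEI", (500.0, 0.2): "NDEI",
}


class TestClassifyQuant:
    @pytest.mark.parametrize("fc,p", sorted(IN_VIVO_GRID))
    def test_in_vivo_truth_table(self, fc, p):
        ev = QuantEvidence("AUC", "fold_change", fc, p, "eq")
        assert classify_quant(ev, "in_vivo") == IN_VIVO_GRID[(fc, p)]

    @pytest.mark.parametrize("ki,p", sorted(KI_GRID))
    def test_in_vitro_truth_table(self, ki, p):
        ev = QuantEvidence("Ki", "ki", ki, p, "eq")
        assert classify_quant(ev, "in_vitro", "drug_enzyme") == \
            KI_GRID[(ki, p)]

    def test_in_vitro_drug_drug_uses_ddi_family(self):
        ev = QuantEvidence("Ki", "ki", 5.0, 0.01, "eq")
        assert classify_quant(ev, "in_vitro", "drug_drug") == "DDI"

    def test_le_relation_significant_at_threshold(self):
        ev = QuantEvidence("AUC", "fold_change", 2.0, 0.05, "le")
        assert classify_quant(ev, "in_vivo") == "DDI"

    def test_gt_relation_never_significant(self):
        ev = QuantEvidence("AUC", "fold_change", 2.0, 0.04, "gt")
        assert classify_quant(ev, "in_vivo") == "ADDI"

    def test_missing_p_lets_band_decide(self):
        ev = QuantEvidence("CL", "percent_change", 64.0,
                           direction="decrease")
        assert classify_quant(ev, "in_vivo") == "DDI"

    def test_missing_p_ambiguous_policy(self):
        config = RuleConfig(missing_p="ambiguous")
        ev = QuantEvidence("CL", "percent_change", 64.0,
                           direction="decrease")
        assert classify_quant(ev, "in_vivo", config=config) == "ADDI"

    def test_wrong_kind_for_setting_errors(self):
        with pytest.raises(ValueError):
            classify_quant(QuantEvidence("Ki", "ki", 5.0), "in_vivo")
        with pytest.raises(ValueError):
            classify_quant(QuantEvidence("AUC", "fold_change", 2.0),
                           "in_vitro")

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(st.floats(0.05, 20.0), st.floats(0.001, 0.9))
    def test_in_vivo_band_structure(self, fc, p):
        """Holding p, the label depends only on which band FC occupies."""
        label = classify_quant(
            QuantEvidence("AUC", "fold_change", fc, p, "eq"), "in_vivo")
        sig = p <= 0.05
        if fc in (0.67, 1.5):
            assert label == "ADDI"
        elif 0.67 < fc < 1.5:
            assert label == ("ADDI" if sig else "NDDI")
        else:
            assert label == ("DDI" if sig else "ADDI")

    def test_reciprocal_fold_symmetry_near_boundary(self):
        # 1/1.5 = 0.666... lies below the printed 0.67 boundary, so both
        # directions of the same relative change land in the definite band
        for fc in (1.51, 1 / 1.51):
            ev = QuantEvidence("AUC", "fold_change", fc, 0.01, "eq")
            assert classify_quant(ev, "in_vivo") == "DDI"

    def test_in_vitro_definiteness_non_increasing_in_ki(self):
        order = {"DEI": 0, "ADEI": 1, "NDEI": 2}
        labels = [classify_quant(QuantEvidence("Ki", "ki", ki, 0.2, "eq"),
                                 "in_vitro", "drug_enzyme")
                  for ki in (1.0, 5.0, 20.0, 80.0, 150.0, 1000.0)]
        ranks = [order[lab] for lab in labels]
        assert ranks == sorted(ranks)


class TestCues:
    @pytest.mark.parametrize("phrase,polarity", [
        ("significantly altered", "definite"),
        ("did not significantly changed", "negative"),
        ("potent inhibitor", "definite"),
        ("slightly induced", "negative"),
        ("may moderately affect", "ambiguous"),
        ("of minor significance", "negative"),
        ("doesn't interact", "negative"),
        ("blue", None),
    ])
    def test_polarity(self, phrase, polarity):
        assert cue_polarity(phrase) == polarity

    def test_family_resolution(self):
        assert classify_cues([CueEvidence("definite", "significantly")],
                             "ddi") == "DDI"
        assert classify_cues([CueEvidence("negative", "not significantly")],
                             "ddi") == "NDDI"
        assert classify_cues([CueEvidence("definite", "potent inhibitor")],
                             "dei") == "DEI"
        assert classify_cues([CueEvidence("ambiguous", "may")],
                             "dei") == "ADEI"

    def test_empty_cue_list_is_none(self):
        assert classify_cues([], "ddi") == "NONE"

    def test_negative_beaten_by_definite(self):
        cues = [CueEvidence("negative", "slightly"),
                CueEvidence("definite", "significantly")]
        assert classify_cues(cues, "ddi") == "DDI"


class TestClassify:
    def test_worked_examples_all_reproduced(self):
        for rid, candidate, label in synthetic.table9_records():
            assert classify(candidate) == label, rid

    def test_c1_false_is_none(self):
        cand = InteractionCandidate(
            "a", "b", c1=False,
            cues=(CueEvidence("definite", "significantly"),))
        assert classify(cand) == "NONE"

    def test_c2_false_is_none(self):
        cand = InteractionCandidate(
            "a", "b", c2=False,
            quant=(QuantEvidence("AUC", "fold_change", 3.0, 0.01, "lt"),))
        assert classify(cand) == "NONE"

    def test_conflicting_ki_bands_give_ambiguous(self):
        cand = InteractionCandidate(
            "dpt", "CYP2C9", setting="in_vitro", pair_type="drug_enzyme",
            quant=(QuantEvidence("Ki", "ki", 3.5),
                   QuantEvidence("Ki", "ki", 24.9)))
        assert classify(cand) == "ADEI"

    def test_quant_precedence_over_cues(self):
        # hedged wording does not override a clearly significant change
        cand = InteractionCandidate(
            "a", "b",
            quant=(QuantEvidence("AUC", "fold_change", 2.33, 0.26, "eq"),),
            cues=(CueEvidence("definite", "significantly"),))
        assert classify(cand) == "ADDI"

    def test_boundary_value_resolved_by_cue(self):
        cand = InteractionCandidate(
            "a", "b",
            quant=(QuantEvidence("AUC", "fold_change", 1.5, 0.01, "le"),),
            cues=(CueEvidence("definite", "significantly"),))
        assert classify(cand) == "DDI"
        no_cue = InteractionCandidate(
            "a", "b",
            quant=(QuantEvidence("AUC", "fold_change", 1.5, 0.01, "le"),))
        assert classify(no_cue) == "ADDI"

    def test_entity_order_invariant(self):
        for _, cand, _ in synthetic.table9_records():
            swapped = InteractionCandidate(
                cand.entity_b, cand.entity_a, cand.setting, cand.pair_type,
                cand.c1, cand.c2, cand.quant, cand.cues)
            assert classify(swapped) == classify(cand)

    def test_deterministic(self):
        for _, cand, _ in synthetic.table9_records():
            assert classify(cand) == classify(cand)


class TestLabelSets:
    def test_in_vivo_has_three_labels(self):
        assert len(IN_VIVO_LABELS) == 3

    def test_in_vitro_has_six_labels(self):
        assert len(IN_VITRO_LABELS) == 6


class TestLabelSentence:
    def test_two_drugs_with_statement_is_cddis(self):
        terms = [term("DRUG", "verapamil"),
                 term("CHANGE", "significantly", 10),
                 term("DRUG", "lovastatin", 30)]
        assert label_sentence(terms) == "CDDIS"

    def test_one_drug_statement_context_is_vddis(self):
        terms = [term("DRUG", "verapamil"),
                 term("MECHANISM", "inhibit", 10)]
        assert label_sentence(terms, has_context_partner=True) == "VDDIS"
        assert label_sentence(terms) == "NONE"

    def test_two_drugs_without_statement_is_none(self):
        terms = [term("DRUG", "verapamil"),
                 term("DRUG", "lovastatin", 10)]
        assert label_sentence(terms) == "NONE"


class TestRuleConfig:
    def test_save_load_round_trip(self, tmp_path):
        config = RuleConfig(fc_upper=1.4, missing_p="ambiguous")
        path = tmp_path / "rules.cfg"
        config.save(path)
        assert RuleConfig.load(path) == config

    def test_invalid_threshold_rejected(self):
        with pytest.raises(ValueError):
            RuleConfig(fc_upper=-1.0)

    def test_thresholds_configurable(self):
        config = RuleConfig(fc_upper=2.0)
        ev = QuantEvidence("AUC", "fold_change", 1.8, 0.01, "eq")
        assert classify_quant(ev, "in_vivo", config=config) == "ADDI"
        assert classify_quant(ev, "in_vivo") == "DDI"
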