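"""Declarative trait-rule evaluation against observed phenotypes."""

import pytest

from vinekit import (
    ConfigError,
    TraitRule,
    evaluate_flower_sex_panel,
    evaluate_haplotype_rule,
    evaluate_rule,
    rules_from_records,
)

from conftest import gm_from_calls

COLLAPSE = {1: "non-colored", 2: "non-colored", 5: "colored", 6: "colored"}
COLOR_RULE = TraitRule(
    rule_id="color",
    trait="berry_color_oiv",
    marker_ids=("COLOR",),
    predicate="allele_present",
    predicted_class="colored",
)


def test_dominant_color_rule_scoring():
    gm = gm_from_calls(
        {"ok_het": ["AB"], "ok_ref": ["AA"], "wrong": ["AA"], "nocall": ["NC"]},
        marker_ids=["COLOR"],
    )
    pheno = {"ok_het": 6, "ok_ref": 1, "wrong": 5, "nocall": 6}
    ev = evaluate_rule(gm, COLOR_RULE, pheno, collapse=COLLAPSE)
    assert ev.n_evaluable == 3  # the no-call sample is excluded
    assert ev.n_correct == 2
    assert ev.wrong_sample_ids == ["wrong"]
    assert not ev.fully_predictive


def test_rule_invariant_to_sample_order_and_non_evaluables():
    gm = gm_from_calls(
        {"a": ["AB"], "b": ["AA"], "c": ["NC"]}, marker_ids=["COLOR"]
    )
    pheno = {"a": 6, "b": 1, "c": 6}
    ev1 = evaluate_rule(gm, COLOR_RULE, pheno, collapse=COLLAPSE)
    gm2 = gm.subset(samples=["b", "c", "a"])
    ev2 = evaluate_rule(gm2, COLOR_RULE, pheno, collapse=COLLAPSE)
    gm3 = gm.subset(samples=["a", "b"])  # drop the non-evaluable sample
    ev3 = evaluate_rule(gm3, COLOR_RULE, pheno, collapse=COLLAPSE)
    assert ev1.n_correct == ev2.n_correct == ev3.n_correct
    assert ev1.n_wrong == ev2.n_wrong == ev3.n_wrong


def test_planted_penetrant_rules_are_fully_predictive(sim):
    pheno = sim.samples.set_index("sample_id")
    exclude = [b for _, b in sim.truth.duplicate_pairs]
    t = sim.truth.traits
    for rule, column, collapse in [
        (t.color_rule, "berry_color_oiv", t.color_collapse),
        (t.seed_rule, "seed_development", None),
        (t.muscat_rule, "berry_taste", None),
    ]:
        ev = evaluate_rule(gm=sim.gm, rule=rule, phenotypes=pheno[column].to_dict(),
                           collapse=collapse, exclude=exclude)
        assert ev.fully_predictive, rule.rule_id


def test_flower_sex_combined_calls():
    fs_rule = TraitRule("fs", "flower_sex", ("FS1",), "allele_present", "male")
    ms_rule = TraitRule("ms", "flower_sex", ("MS1",), "homozygous_B", "female")
    gm = gm_from_calls(
        {
            "male": ["AB", "AA"],
            "female": ["AA", "BB"],
            "herm": ["AA", "AA"],
            "confl": ["AB", "BB"],
            "unk": ["NC", "AA"],
        },
        marker_ids=["FS1", "MS1"],
    )
    pheno = {"male": "male", "female": "female", "herm": "hermaphrodite",
             "confl": "male", "unk": "male"}
    rep = evaluate_flower_sex_panel(gm, [fs_rule], [ms_rule], pheno)
    calls = rep.combined.set_index("sample_id")["combined_call"]
    assert calls["male"] == "male"
    assert calls["female"] == "female"
    assert calls["herm"] == "hermaphrodite"
    assert calls["confl"] == "conflict"
    assert calls["unk"] == "unknown"
    correct = rep.combined.set_index("sample_id")["correct"]
    assert correct["confl"] is None and correct["unk"] is None


def test_planted_recombination_leaves_seven_of_nine_predictive(sim):
    pheno = sim.samples.set_index("sample_id")["flower_sex"].to_dict()
    exclude = [b for _, b in sim.truth.duplicate_pairs]
    t = sim.truth.traits
    rep = evaluate_flower_sex_panel(
        sim.gm, t.female_sterility_rules, t.male_sterility_rules, pheno, exclude=exclude
    )
    assert rep.n_markers == 9
    assert rep.n_fully_predictive == 7
    faulty = {m for m, _ in t.recombinant_sex_markers}
    wrong_counts = {
        ev.rule_id: ev.n_wrong for ev in rep.per_marker if ev.n_wrong > 0
    }
    assert {rid.split("sex_")[1] for rid in wrong_counts} == faulty
    # the planted case counts are recovered exactly
    assert sorted(wrong_counts.values()) == sorted(
        n for _, n in t.recombinant_sex_markers
    )


HAP_RULE = TraitRule(
    rule_id="hap",
    trait="taste",
    marker_ids=("H1", "H2", "H3"),
    predicate="haplotype_match",
    predicted_class="herbaceous",
    expected_vector=("BB", "AB", "any"),
)


def test_haplotype_carrier_logic():
    gm = gm_from_calls(
        {
            "carrier": ["BB", "AB", "AA"],
            "carrier2": ["BB", "AB", "NC"],  # NC at an 'any' position still carries
            "miss": ["BB", "NC", "AA"],      # NC at a required position
            "non": ["AB", "AB", "AA"],
        },
        marker_ids=["H1", "H2", "H3"],
    )
    pheno = {"carrier": "herbaceous", "non": "none"}
    out = evaluate_haplotype_rule(gm, HAP_RULE, pheno)
    assert sorted(out.carriers) == ["carrier", "carrier2"]
    assert out.carriers_without_phenotype == ["carrier2"]
    assert out.non_evaluable == ["miss"]
    assert out.evaluation.fully_predictive


def test_planted_haplotypes_partition_exactly(sim):
    pheno = sim.samples.set_index("sample_id")["berry_taste"].to_dict()
    t = sim.truth.traits
    seen = {}
    for rule in t.haplotype_rules:
        out = evaluate_haplotype_rule(sim.gm, rule, pheno)
        seen[rule.rule_id] = sorted(out.carriers)
    assert seen == t.haplotype_groups


def test_rule_parsing_and_validation():
    rules = rules_from_records(
        [
            {
                "rule_id": "r1",
                "trait": "color",
                "marker_ids": "M1",
                "predicate": "allele_present",
                "predicted_class": "colored",
            },
            {
                "rule_id": "r2",
                "trait": "taste",
                "marker_ids": "M1;M2",
                "predicate": "haplotype_match",
                "predicted_class": "herbaceous",
                "expected_vector": "BB;any",
            },
        ]
    )
    assert rules[0].marker_ids == ("M1",)
    assert rules[1].expected_vector == ("BB", "any")
    with pytest.raises(ConfigError, match="unknown predicate"):
        TraitRule("bad", "t", ("M1",), "nope", "x")
    with pytest.raises(ConfigError, match="expected_vector"):
        TraitRule("bad", "t", ("M1", "M2"), "haplotype_match", "x",
                  expected_vector=("BB",))
    with pytest.raises(ConfigError, match="exactly one marker"):
        TraitRule("bad", "t", ("M1", "M2"), "allele_present", "x")
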