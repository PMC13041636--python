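"""Declarative validation of trait-predictive markers against phenotypes.

Rules are data, not code: each rule maps a genotype predicate at one or
more candidate markers to a predicted phenotype class. A rule is evaluated
two-sidedly — when the predicate holds the sample must show the predicted
class, when it does not hold the sample must not — so a "dominant B"
berry-colour rule is wrong both for an AA sample with coloured berries and
for an AB sample with green-yellow berries.

Observed phenotype labels can be collapsed before comparison through an
explicit class-collapse map (e.g. OIV-225 codes 5 and 6 -> "colored",
1 and 2 -> "non-colored"), mirroring how ordinal descriptors are grouped
for marker validation.

Predicates
----------
- ``allele_present``   at least one B allele (dominant B)
- ``allele_absent``    homozygous A (no B allele)
- ``homozygous_B``     BB (recessive B)
- ``homozygous_A``     AA
- ``haplotype_match``  the calls at all rule markers equal an expected
  vector over {AA, AB, BB, any}
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .errors import ConfigError
from .io import GenotypeMatrix

PREDICATES = (
    "allele_present",
    "allele_absent",
    "homozygous_B",
    "homozygous_A",
    "haplotype_match",
)

_CALL_CODE = {"AA": 0, "AB": 1, "BB": 2}


@dataclass(frozen=True)
class TraitRule:
    """One declarative genotype -> phenotype prediction rule.

    ``applicability`` optionally restricts evaluation to a sample subset
    (e.g. one taxon class); ``expected_vector`` is required by, and only
    by, the ``haplotype_match`` predicate and has one entry per marker.
    """

    rule_id: str
    trait: str
    marker_ids: tuple[str, ...]
    predicate: str
    predicted_class: str
    expected_vector: tuple[str, ...] | None = None
    applicability: frozenset[str] | None = None

    def __post_init__(self) -> None:
        if not self.marker_ids:
            raise ConfigError(f"rule {self.rule_id!r}: marker_ids is empty")
        if self.predicate not in PREDICATES:
            raise ConfigError(
                f"rule {self.rule_id!r}: unknown predicate {self.predicate!r}"
            )
        if self.predicate == "haplotype_match":
            if self.expected_vector is None or len(self.expected_vector) != len(
                self.marker_ids
            ):
                raise ConfigError(
                    f"rule {self.rule_id!r}: expected_vector length must equal "
                    f"the number of markers"
                )
            bad = set(self.expected_vector) - {"AA", "AB", "BB", "any"}
            if bad:
                raise ConfigError(
                    f"rule {self.rule_id!r}: invalid expected_vector entries {bad}"
                )
        elif len(self.marker_ids) != 1:
            raise ConfigError(
                f"rule {self.rule_id!r}: predicate {self.predicate!r} takes "
                f"exactly one marker"
            )


@dataclass
class RuleEvaluation:
    rule_id: str
    n_evaluable: int
    n_correct: int
    n_wrong: int
    wrong_sample_ids: list[str] = field(default_factory=list)

    @property
    def fully_predictive(self) -> bool:
        return self.n_wrong == 0 and self.n_evaluable > 0


def _predicate_holds(rule: TraitRule, calls: Sequence[int]) -> bool:
    if rule.predicate == "haplotype_match":
        assert rule.expected_vector is not None
        for call, expected in zip(calls, rule.expected_vector):
            if expected == "any":
                continue
            if call != _CALL_CODE[expected]:
                return False
        return True
    g = calls[0]
    if rule.predicate == "allele_present":
        return g >= 1
    if rule.predicate == "allele_absent":
        return g == 0
    if rule.predicate == "homozygous_B":
        return g == 2
    if rule.predicate == "homozygous_A":
        return g == 0
    raise ConfigError(f"unknown predicate {rule.predicate!r}")


def _required_positions(rule: TraitRule) -> list[int]:
    """Marker positions whose call must be present (non-NC) to evaluate."""
    if rule.predicate == "haplotype_match":
        assert rule.expected_vector is not None
        return [i for i, e in enumerate(rule.expected_vector) if e != "any"]
    return [0]


def _collapse(label: object, collapse: Mapping | None) -> object:
    if collapse is None:
        return label
    return collapse.get(label, label)


def evaluate_rule(
    gm: GenotypeMatrix,
    rule: TraitRule,
    phenotypes: Mapping[str, object],
    collapse: Mapping | None = None,
    exclude: Iterable[str] = (),
) -> RuleEvaluation:
    """Score one rule against observed phenotypes.

    Samples lacking a phenotype, carrying a no-call at a required marker,
    outside the rule's applicability set or listed in ``exclude`` (e.g.
    duplicate mates) do not count as evaluable. Observed labels pass
    through the ``collapse`` map before comparison with the predicted
    class.
    """
    cols = [gm.marker_index(m) for m in rule.marker_ids]
    required = _required_positions(rule)
    excluded = set(exclude)
    n_correct = n_wrong = 0
    wrong: list[str] = []
    for i, sid in enumerate(gm.sample_ids):
        if sid in excluded:
            continue
        if rule.applicability is not None and sid not in rule.applicability:
            continue
        observed = phenotypes.get(sid)
        if observed is None or (isinstance(observed, float) and pd.isna(observed)):
            continue
        calls = [int(gm.codes[i, c]) for c in cols]
        if any(calls[j] < 0 for j in required):
            continue
        predicted_positive = _predicate_holds(rule, calls)
        observed_c = _collapse(observed, collapse)
        correct = (
            observed_c == rule.predicted_class
            if predicted_positive
            else observed_c != rule.predicted_class
        )
        if correct:
            n_correct += 1
        else:
            n_wrong += 1
            wrong.append(sid)
    return RuleEvaluation(
        rule_id=rule.rule_id,
        n_evaluable=n_correct + n_wrong,
        n_correct=n_correct,
        n_wrong=n_wrong,
        wrong_sample_ids=wrong,
    )


@dataclass
class HaplotypeEvaluation:
    evaluation: RuleEvaluation
    carriers: list[str]
    carriers_without_phenotype: list[str]
    non_evaluable: list[str]


def evaluate_haplotype_rule(
    gm: GenotypeMatrix,
    rule: TraitRule,
    phenotypes: Mapping[str, object],
    collapse: Mapping | None = None,
    exclude: Iterable[str] = (),
) -> HaplotypeEvaluation:
    """Evaluate a haplotype-match rule and list its carriers.

    A carrier matches the expected vector at every non-'any' position;
    a sample with a no-call at a required position is non-evaluable.
    Carriers lacking phenotype data are listed separately rather than
    scored.
    """
    if rule.predicate != "haplotype_match":
        raise ConfigError(f"rule {rule.rule_id!r} is not a haplotype rule")
    cols = [gm.marker_index(m) for m in rule.marker_ids]
    required = _required_positions(rule)
    excluded = set(exclude)
    carriers: list[str] = []
    carriers_wo_pheno: list[str] = []
    non_evaluable: list[str] = []
    for i, sid in enumerate(gm.sample_ids):
        if sid in excluded:
            continue
        if rule.applicability is not None and sid not in rule.applicability:
            continue
        calls = [int(gm.codes[i, c]) for c in cols]
        if any(calls[j] < 0 for j in required):
            non_evaluable.append(sid)
            continue
        if _predicate_holds(rule, calls):
            carriers.append(sid)
            observed = phenotypes.get(sid)
            if observed is None or (
                isinstance(observed, float) and pd.isna(observed)
            ):
                carriers_wo_pheno.append(sid)
    evaluation = evaluate_rule(gm, rule, phenotypes, collapse, exclude)
    return HaplotypeEvaluation(
        evaluation=evaluation,
        carriers=carriers,
        carriers_without_phenotype=carriers_wo_pheno,
        non_evaluable=non_evaluable,
    )


@dataclass
class FlowerSexReport:
    """Per-marker evaluations plus a combined sex call per sample."""

    per_marker: list[RuleEvaluation]
    combined: pd.DataFrame
    n_fully_predictive: int
    n_markers: int


def evaluate_flower_sex_panel(
    gm: GenotypeMatrix,
    female_sterility_rules: Sequence[TraitRule],
    male_sterility_rules: Sequence[TraitRule],
    phenotypes: Mapping[str, object],
    exclude: Iterable[str] = (),
) -> FlowerSexReport:
    """Validate a flower-sex marker panel and derive combined sex calls.

    Grapevine sex behaves as one locus: an allele causing female sterility
    (male plants) and an allele causing male sterility (female plants),
    with hermaphrodites carrying neither. Each marker is scored by its own
    rule; the combined call per sample is:

    - ``male``          female-sterility allele present, no male-sterility allele
    - ``female``        male-sterility allele present, no female-sterility allele
    - ``hermaphrodite`` neither allele present
    - ``conflict``      both present (flagged, excluded from accuracy)
    - ``unknown``       one side entirely no-call

    Allele presence per side is "at least one B among the side's called
    markers".
    """
    per_marker = [
        evaluate_rule(gm, r, phenotypes, exclude=exclude)
        for r in list(female_sterility_rules) + list(male_sterility_rules)
    ]
    fs_cols = [gm.marker_index(r.marker_ids[0]) for r in female_sterility_rules]
    ms_cols = [gm.marker_index(r.marker_ids[0]) for r in male_sterility_rules]
    excluded = set(exclude)
    rows = []
    for i, sid in enumerate(gm.sample_ids):
        if sid in excluded:
            continue
        fs_calls = [int(gm.codes[i, c]) for c in fs_cols]
        ms_calls = [int(gm.codes[i, c]) for c in ms_cols]
        fs_known = [c for c in fs_calls if c >= 0]
        ms_known = [c for c in ms_calls if c >= 0]
        if not fs_known or not ms_known:
            call = "unknown"
        else:
            fs_present = any(c >= 1 for c in fs_known)
            ms_present = any(c >= 1 for c in ms_known)
            if fs_present and ms_present:
                call = "conflict"
            elif fs_present:
                call = "male"
            elif ms_present:
                call = "female"
            else:
                call = "hermaphrodite"
        observed = phenotypes.get(sid)
        if observed is None or (isinstance(observed, float) and pd.isna(observed)):
            observed = ""
        correct = (
            call == observed if call not in ("conflict", "unknown") and observed else None
        )
        rows.append(
            {
                "sample_id": sid,
                "combined_call": call,
                "observed": observed,
                "correct": correct,
            }
        )
    combined = pd.DataFrame(
        rows, columns=["sample_id", "combined_call", "observed", "correct"]
    )
    n_full = sum(ev.fully_predictive for ev in per_marker)
    return FlowerSexReport(
        per_marker=per_marker,
        combined=combined,
        n_fully_predictive=n_full,
        n_markers=len(per_marker),
    )


# -- rule (de)serialization ---------------------------------------------------


def rules_from_records(records: Iterable[Mapping]) -> list[TraitRule]:
    """Build rules from plain dicts (YAML/CSV rows).

    Expected keys: rule_id, trait, marker_ids (list or ';'-separated
    string), predicate, predicted_class; optional expected_vector (list or
    ';'-separated) and applicability (list of sample ids).
    """
    rules = []
    for rec in records:
        markers = rec["marker_ids"]
        if isinstance(markers, str):
            markers = [m.strip() for m in markers.split(";") if m.strip()]
        vector = rec.get("expected_vector")
        if isinstance(vector, str):
            vector = [v.strip() for v in vector.split(";") if v.strip()]
        applicability = rec.get("applicability")
        rules.append(
            TraitRule(
                rule_id=str(rec["rule_id"]),
                trait=str(rec["trait"]),
                marker_ids=tuple(markers),
                predicate=str(rec["predicate"]),
                predicted_class=str(rec["predicted_class"]),
                expected_vector=tuple(vector) if vector else None,
                applicability=(
                    frozenset(applicability) if applicability else None
                ),
            )
        )
    return rules


def load_rules_yaml(path) -> list[TraitRule]:
    import yaml

    with open(path) as fh:
        data = yaml.safe_load(fh)
    if not isinstance(data, list):
        raise ConfigError(f"rule file {path} must contain a list of rules")
    return rules_from_records(data)
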