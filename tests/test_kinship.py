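"""Duo/trio statistics, pedigree inference, duplicates and the ordination."""

from itertools import product

import numpy as np
import pandas as pd
import pytest

from vinekit import (
    all_pairs_duos,
    classify_relationships,
    compute_duo,
    compute_trio,
    expected_relationships,
    find_duplicates,
    infer_relationships,
    run_iterative_curation,
    simulate_panel,
)
from vinekit.simulate import default_config

from conftest import gm_from_calls, random_gm


def test_duo_counts_on_enumerated_pair():
    # brute-force over the 3 compared markers: (AA,BB) opposing,
    # (AB,AA) directional het a->b, (BB,BB) identical; (NC,AA) excluded
    gm = gm_from_calls({"a": ["AA", "AB", "BB", "NC"], "b": ["BB", "AA", "BB", "AA"]})
    d = compute_duo(gm, "a", "b")
    assert d.n_compared == 3
    assert d.n_opposing_hom == 1
    assert d.duo_errors_perc == pytest.approx(33.33, abs=0.01)
    assert d.het_mismatch_A1A2 == 1
    assert d.het_mismatch_A2A1 == 0
    assert d.perc_mismatches == pytest.approx(100 / 3)


def test_duo_identity_has_no_errors():
    gm = gm_from_calls({"a": ["AA", "AB", "BB", "NC"]})
    gm2 = gm_from_calls({"a": ["AA", "AB", "BB", "NC"], "b": ["AA", "AB", "BB", "NC"]})
    d = compute_duo(gm2, "a", "b")
    assert d.n_opposing_hom == 0 and d.perc_mismatches == 0.0


def test_duo_swap_contract_on_random_pairs():
    rng = np.random.default_rng(13)
    gm = random_gm(rng, 48, 120)
    ids = gm.sample_ids
    for _ in range(1000):
        a, b = rng.choice(ids, 2, replace=False)
        d = compute_duo(gm, a, b)
        assert d.swapped() == compute_duo(gm, b, a)


def gamete_pairing_oracle(o, p1, p2):
    """Brute force over {A,B}^2 gamete pairings on letter genotypes."""
    alleles = {"AA": "AA", "AB": "AB", "BB": "BB"}
    for g1, g2 in product(alleles[p1], alleles[p2]):
        if "".join(sorted(g1 + g2)) == o:
            return False
    return True


def test_trio_matches_gamete_pairing_oracle_exactly():
    calls = ["AA", "AB", "BB"]
    for o, p1, p2 in product(calls, repeat=3):
        gm = gm_from_calls({"o": [o], "m": [p1], "f": [p2]})
        t = compute_trio(gm, "o", "m", "f")
        assert bool(t.n_incompatible) == gamete_pairing_oracle(o, p1, p2), (o, p1, p2)


def test_trio_examples():
    gm = gm_from_calls({"o": ["AB", "AA"], "m": ["AA", "BB"], "f": ["BB", "BB"]})
    t = compute_trio(gm, "o", "m", "f")
    assert t.n_evaluable == 2
    assert t.n_incompatible == 1  # AB from AAxBB fine; AA from BBxBB impossible


def test_find_duplicates_reports_identical_and_planted_pairs():
    gm = gm_from_calls(
        {
            "a": ["AA", "AB", "BB", "NC"],
            "b": ["AA", "AB", "BB", "AA"],  # identical where both called
            "c": ["BB", "BB", "AA", "BB"],
        }
    )
    hits = find_duplicates(gm, max_diff=0)
    assert hits == [(("a", "b"), 0)]


def test_planted_duplicates_have_exact_discordance_without_missingness():
    cfg = default_config(seed=3, missing_rate_base=0.0, missing_rate_wild_boost=0.0,
                        n_low_call_rate_samples=0)
    sim = simulate_panel(cfg)
    hits = dict(find_duplicates(sim.gm, max_diff=10))
    for pair in sim.truth.duplicate_pairs:
        assert hits[pair] == cfg.duplicate_discordance  # "6 differences excluding NC"


def test_divergent_founders_are_not_duplicates(sim):
    hits = {frozenset(p) for p, _ in find_duplicates(sim.gm, max_diff=10)}
    assert hits == {frozenset(p) for p in sim.truth.duplicate_pairs}


def _po_matrix(n_markers, n_opposing, rng):
    """Parent/child rows sharing an allele except n_opposing planted errors."""
    parent = rng.integers(0, 3, n_markers).astype(np.int8)
    child = np.where(parent == 1, rng.integers(0, 2, n_markers) * 2, 1).astype(np.int8)
    child[:n_opposing] = np.int8(2)
    parent[:n_opposing] = np.int8(0)
    return parent, child


def test_threshold_relaxes_to_max_known_po_error():
    rng = np.random.default_rng(23)
    n = 1000
    p1, c1 = _po_matrix(n, 9, rng)  # 0.9% duo error
    p2, c2 = _po_matrix(n, 2, rng)  # 0.2%
    codes = np.vstack([p1, c1, p2, c2])
    from vinekit import GenotypeMatrix

    gm = GenotypeMatrix(["P1", "C1", "P2", "C2"], [f"M{i}" for i in range(n)], codes)
    ped = pd.DataFrame(
        {"sample_id": ["C1", "C2"], "mother_id": ["P1", "P2"], "father_id": ["", ""]}
    )
    inf = infer_relationships(gm, ped, duo_threshold_init=0.5)
    assert inf.threshold_used == pytest.approx(0.9)
    cand = {frozenset((d.sample_a, d.sample_b)) for d in inf.duos}
    assert {frozenset({"P1", "C1"}), frozenset({"P2", "C2"})} <= cand


def test_no_known_po_keeps_initial_threshold():
    rng = np.random.default_rng(29)
    gm = random_gm(rng, 6, 200)
    ped = pd.DataFrame({"sample_id": [], "mother_id": [], "father_id": []})
    inf = infer_relationships(gm, ped, duo_threshold_init=0.5)
    assert inf.threshold_used == 0.5


def test_low_error_full_siblings_appear_as_candidate_duos():
    # an undeclared pair with duo error below the threshold is reported as a
    # candidate PO (the expected false positive later separated by the
    # relationship ordination)
    gm = gm_from_calls(
        {"x": ["AA", "AB", "AB", "BB"] * 50, "y": ["AA", "AB", "BB", "BB"] * 50}
    )
    ped = pd.DataFrame({"sample_id": [], "mother_id": [], "father_id": []})
    inf = infer_relationships(gm, ped, duo_threshold_init=0.5)
    assert {frozenset((d.sample_a, d.sample_b)) for d in inf.duos} == {
        frozenset({"x", "y"})
    }


def test_iterative_curation_fixed_point_without_bad_markers():
    cfg = default_config(
        seed=5,
        n_noisy_markers=0,
        genotyping_error_rate=0.0,
        n_markers_per_chromosome=30,
    )
    sim = simulate_panel(cfg)
    run = run_iterative_curation(sim.nuclear_gm, sim.pedigree)
    assert run.converged
    assert run.removed_per_iteration == []


def test_iterative_curation_reaches_fixed_point(sim, curation_run):
    from vinekit.curation import filter_mendelian
    from vinekit.kinship import confirmed_relationship_set

    run = curation_run["run"]
    assert run.converged
    # fixed point: one more filter pass on the curated matrix removes nothing
    inf = infer_relationships(run.gm, sim.pedigree)
    confirmed = confirmed_relationship_set(inf, sim.pedigree)
    result = filter_mendelian(run.gm, confirmed, max_error=0.03)
    assert result.removed == []


def test_trio_errors_decrease_after_marker_removal(sim, curation_run):
    gm_u = curation_run["gm_unique"]
    run = curation_run["run"]
    inf_before = infer_relationships(gm_u, sim.pedigree)
    before = np.mean([t.trio_errors_perc for t in inf_before.trios])
    after = np.mean([t.trio_errors_perc for t in run.trios])
    assert after < before


def test_expected_relationship_classes():
    ped = pd.DataFrame(
        [
            ("A", "", ""), ("B", "", ""), ("C", "", ""),
            ("K1", "A", "B"), ("K2", "A", "B"), ("K3", "A", "C"),
            ("G", "K1", ""),
        ],
        columns=["sample_id", "mother_id", "father_id"],
    )
    rel = expected_relationships(ped)
    assert rel[frozenset({"A", "K1"})] == "PO"
    assert rel[frozenset({"K1", "K2"})] == "FS"
    assert rel[frozenset({"K1", "K3"})] == "HS"
    assert rel[frozenset({"G", "A"})] == "GP"
    assert rel[frozenset({"G", "K2"})] == "UN"
    assert frozenset({"B", "C"}) not in rel


def test_ordination_supplementary_contract(sim, curation_run):
    gm_u = curation_run["gm_unique"]
    table = all_pairs_duos(gm_u)
    labels = expected_relationships(sim.pedigree)
    full = classify_relationships(table, labels)
    active_only = classify_relationships(
        table[
            [
                labels.get(frozenset((a, b)), "OTHER") != "OTHER"
                for a, b in zip(table.sample_a, table.sample_b)
            ]
        ],
        labels,
    )
    # OTHER pairs are projected without influencing the eigendecomposition
    np.testing.assert_allclose(
        full.explained_variance_ratio, active_only.explained_variance_ratio
    )
    # per-axis variable contributions are percentages summing to 100
    np.testing.assert_allclose(full.contributions.sum(axis=0), 100.0)
    # the axis dominated by duo_errors_perc separates PO from FS
    axis = full.contributions.loc["duo_errors_perc"].idxmax()
    coords = full.coordinates
    po = coords[coords.expected_class == "PO"][axis]
    fs = coords[coords.expected_class == "FS"][axis]
    gap = abs(po.mean() - fs.mean())
    assert gap > 2 * max(po.std(), fs.std())
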