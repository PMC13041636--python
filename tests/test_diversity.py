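"""Heterozygosity summaries, genotype PCA and platform concordance."""

import numpy as np
import pandas as pd
import pytest

from vinekit import (
    SimulationConfig,
    genotype_pca,
    platform_concordance,
    simulate_panel,
    species_het_summary,
)
from vinekit.simulate import PopulationConfig

from conftest import gm_from_calls


def test_het_summary_basic_statistics():
    gm = gm_from_calls(
        {
            "S1": ["AB", "AA", "AA", "AA", "AA"],   # het 0.2
            "S2": ["AB", "AB", "AB", "AA", "NC"],   # het 0.75 over 4 calls
            "S3": ["AB", "AA", "AA", "AA", "AB"],   # het 0.4
        }
    )
    samples = pd.DataFrame(
        {"sample_id": ["S1", "S2", "S3"], "species": ["solo", "duo", "duo"]}
    )
    out = species_het_summary(gm, samples).set_index("species")
    assert out.loc["solo", "het_mean"] == out.loc["solo", "het_min"] == out.loc["solo", "het_max"]
    assert out.loc["duo", "het_mean"] == pytest.approx((0.75 + 0.4) / 2)
    assert out.loc["duo", "call_count_mean"] == pytest.approx(4.5)


def test_wild_species_show_ascertainment_bias(sim):
    out = species_het_summary(sim.gm, sim.samples).set_index("species")
    vinifera = out.loc["V. vinifera", "het_mean"]
    for wild in ("V. riparia", "V. amurensis", "M. rotundifolia"):
        assert out.loc[wild, "het_mean"] < vinifera


def _two_pop_sim(seed=7):
    cfg = SimulationConfig(
        chromosomes=("chr01", "chr02"),
        n_markers_per_chromosome=200,
        populations=(
            PopulationConfig("popA", 0.05, 20, species="A"),
            PopulationConfig("popB", 0.30, 20, species="B"),
        ),
        crosses=(),
        plant_traits=False,
        n_duplicate_pairs=0,
        n_noisy_markers=0,
        seed=seed,
    )
    return simulate_panel(cfg)


def test_pca_separates_planted_populations():
    sim = _two_pop_sim()
    pca = genotype_pca(sim.gm)
    from sklearn.metrics import silhouette_score

    labels = sim.samples.set_index("sample_id").loc[
        pca.coordinates.sample_id, "population"
    ]
    score = silhouette_score(pca.coordinates[["PC1"]], labels)
    assert score > 0
    ratios = pca.explained_variance_ratio
    assert ratios.sum() <= 1.0 + 1e-9
    assert np.all(np.diff(ratios) <= 1e-12)


def test_pca_duplicates_nearly_coincide(sim):
    pca = genotype_pca(sim.gm)
    coords = pca.coordinates.set_index("sample_id")
    pc1_range = coords["PC1"].max() - coords["PC1"].min()
    for a, b in sim.truth.duplicate_pairs:
        dist = abs(coords.loc[a, "PC1"] - coords.loc[b, "PC1"])
        assert dist < 0.01 * pc1_range


def test_pca_is_deterministic(sim):
    a = genotype_pca(sim.gm)
    b = genotype_pca(sim.gm)
    np.testing.assert_array_equal(a.coordinates["PC1"], b.coordinates["PC1"])


def test_concordance_identical_matrices():
    gm = gm_from_calls({"S1": ["AA", "AB", "BB"], "S2": ["AB", "AB", "NC"]})
    for r in platform_concordance(gm, gm):
        assert r.concordance_perc == 100.0


def test_concordance_counts_zygosity_flips():
    calls_a = ["AA"] * 50 + ["AB"] * 50
    calls_b = list(calls_a)
    for i in (0, 1, 50):  # 3 zygosity flips among 100 shared called markers
        calls_b[i] = "AB" if calls_a[i] == "AA" else "AA"
    gm_a = gm_from_calls({"S1": calls_a})
    gm_b = gm_from_calls({"S1": calls_b})
    (r,) = platform_concordance(gm_a, gm_b, mode="zygosity")
    assert r.n_shared_markers == 100
    assert r.concordance_perc == pytest.approx(97.0)


def test_concordance_excludes_missing_and_flags_non_evaluable():
    gm_a = gm_from_calls({"S1": ["AA", "NC", "BB"]})
    gm_b = gm_from_calls({"S1": ["NC", "AB", "BB"]})
    (r,) = platform_concordance(gm_a, gm_b)
    assert r.n_shared_markers == 1 and r.evaluable
    gm_c = gm_from_calls({"S1": ["NC", "NC", "NC"]})
    (r2,) = platform_concordance(gm_a, gm_c)
    assert not r2.evaluable


def test_strict_mode_harmonizes_swapped_alleles():
    rng = np.random.default_rng(31)
    codes = rng.integers(0, 3, (6, 80)).astype(np.int8)
    from vinekit import GenotypeMatrix

    ids = [f"S{i}" for i in range(6)]
    markers = [f"M{j}" for j in range(80)]
    gm_a = GenotypeMatrix(ids, markers, codes)
    swapped = codes.copy()
    swapped[:, :40] = 2 - swapped[:, :40]  # platform B swaps A/B on half
    gm_b = GenotypeMatrix(ids, markers, swapped)
    strict = platform_concordance(gm_a, gm_b, mode="strict", harmonize=True)
    zygo = platform_concordance(gm_a, gm_b, mode="zygosity")
    for rs, rz in zip(strict, zygo):
        assert rs.concordance_perc == rz.concordance_perc == 100.0


def test_concordance_invariant_to_marker_order():
    rng = np.random.default_rng(37)
    from conftest import random_gm

    gm_a = random_gm(rng, 5, 60)
    gm_b = random_gm(rng, 5, 60)
    perm = list(rng.permutation(gm_a.marker_ids))
    r1 = platform_concordance(gm_a, gm_b)
    r2 = platform_concordance(gm_a.subset(markers=perm), gm_b)
    for a, b in zip(r1, r2):
        assert a.concordance_perc == b.concordance_perc
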