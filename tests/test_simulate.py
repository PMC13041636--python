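"""Generator contracts: determinism, Mendelian transmission, planted truth."""

import numpy as np
import pytest
from scipy import stats

from vinekit import (
    ConfigError,
    SimulationConfig,
    compute_duo,
    default_config,
    simulate_panel,
)
from vinekit.simulate import CrossConfig, PopulationConfig


def test_fixed_seed_reproduces_byte_identical_panels():
    a = simulate_panel(default_config(seed=9))
    b = simulate_panel(default_config(seed=9))
    assert a.gm == b.gm
    assert a.samples.equals(b.samples)
    assert a.truth.chlorotypes == b.truth.chlorotypes
    c = simulate_panel(default_config(seed=10))
    assert not np.array_equal(a.gm.codes, c.gm.codes)


def _noiseless_config(seed=11, **kw):
    # every planted perturbation off, including the sex-marker
    # recombination cases (deliberate transmission-breaking overwrites)
    return default_config(
        seed=seed,
        genotyping_error_rate=0.0,
        missing_rate_base=0.0,
        missing_rate_wild_boost=0.0,
        n_noisy_markers=0,
        n_low_call_rate_samples=0,
        sex_recombination=(),
        n_markers_per_chromosome=40,
        **kw,
    )


def test_planted_po_pairs_have_zero_opposing_homozygotes_without_noise():
    sim = simulate_panel(_noiseless_config())
    gm = sim.nuclear_gm  # maternally inherited plastid loci are exempt
    for a, b in sim.truth.po_pairs:
        d = compute_duo(gm, a, b)
        assert d.n_opposing_hom == 0, (a, b)


def test_founder_genotypes_in_hardy_weinberg_proportions():
    cfg = SimulationConfig(
        chromosomes=("chr01", "chr02"),
        n_markers_per_chromosome=250,
        populations=(PopulationConfig("popA", 0.02, 200, species="A"),),
        crosses=(),
        plant_traits=False,
        genotyping_error_rate=0.0,
        missing_rate_base=0.0,
        n_duplicate_pairs=0,
        n_noisy_markers=0,
        n_low_call_rate_samples=0,
        seed=13,
    )
    sim = simulate_panel(cfg)
    codes = sim.gm.codes[:, :500]
    n = codes.shape[0]
    rejected = 0
    tested = 0
    for j in range(codes.shape[1]):
        col = codes[:, j]
        n_aa, n_ab, n_bb = (col == 0).sum(), (col == 1).sum(), (col == 2).sum()
        p = (2 * n_aa + n_ab) / (2 * n)
        if min(p, 1 - p) < 0.05:
            continue
        expected = n * np.array([p**2, 2 * p * (1 - p), (1 - p) ** 2])
        chi2 = (((np.array([n_aa, n_ab, n_bb]) - expected) ** 2) / expected).sum()
        tested += 1
        if chi2 > stats.chi2.ppf(0.99, df=1):
            rejected += 1
    assert tested > 300
    assert rejected / tested < 0.05  # nominal 1% plus sampling slack


def test_plastid_calls_are_maternal_and_never_heterozygous(sim):
    plastid_cols = [sim.gm.marker_index(m) for m in sim.truth.plastid_marker_ids]
    block = sim.gm.codes[:, plastid_cols]
    assert not (block == 1).any()
    # haplotype string equals the planted truth for every sample
    for i, sid in enumerate(sim.gm.sample_ids):
        hap = "".join("A" if c == 0 else "B" for c in block[i])
        assert hap == sim.truth.chlorotypes[sid]


def test_cross_referencing_unknown_parent_is_config_error():
    cfg = default_config(
        seed=1, crosses=(CrossConfig("GHOST", "VIN_001", 1, "G1"),)
    )
    with pytest.raises(ConfigError, match="unknown parent"):
        simulate_panel(cfg)


def test_probability_validation():
    with pytest.raises(ConfigError, match="genotyping_error_rate"):
        default_config(seed=1, genotyping_error_rate=1.5)
    with pytest.raises(ConfigError, match="fst"):
        PopulationConfig("x", 0.0, 5)


def test_candidate_vcf_truth_labels(tmp_path, candidate_pool):
    truth = candidate_pool["truth"]
    cfg = default_config(seed=1)
    v = cfg.candidate_vcf
    n_cells = len(cfg.populations) * len(cfg.chromosomes)
    flag_counts = {}
    for flags in truth.values():
        for f in flags:
            flag_counts[f] = flag_counts.get(f, 0) + 1
    assert flag_counts["low_qual"] == n_cells * v.n_low_qual
    assert flag_counts["proximity"] == n_cells * v.n_proximal_pairs * 2
    clean = [rid for rid, flags in truth.items() if not flags]
    assert len(clean) == n_cells * v.n_clean_per_cell
    # planted proximal pairs are 20 nt apart; clean records sit 1 kb apart
    variants = {x.marker_id: x for x in candidate_pool["variants"]}
    prox_pos = sorted(
        variants[rid].position for rid, fl in truth.items()
        if fl == ["proximity"] and variants[rid].chromosome == "chr01"
    )
    gaps = np.diff(prox_pos)
    assert (gaps == 20).sum() == len(prox_pos) // 2


def test_duplicate_phenotypes_and_metadata_follow_source(sim):
    meta = sim.samples.set_index("sample_id")
    for src, dup in sim.truth.duplicate_pairs:
        assert meta.loc[dup, "duplicate_of"] == src
        assert meta.loc[dup, "species"] == meta.loc[src, "species"]
        assert meta.loc[dup, "flower_sex"] == meta.loc[src, "flower_sex"]
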