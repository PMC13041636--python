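"""Candidate filtering, proximity flagging and quota selection."""

import numpy as np
import pytest

from vinekit import (
    CandidateVariant,
    ConfigError,
    FilterThresholds,
    SelectionQuota,
    apply_variant_filters,
    flag_proximal,
    select_markers,
)


def make_variant(chrom="chr01", pos=1000, ref="A", alt=("G",), qual=200.0,
                 depths=None, missing=0.0, species="vinifera", mid="", score=None):
    n = 10
    depths = depths if depths is not None else [20] * n
    n_missing = round(missing * n)
    called = [False] * n_missing + [True] * (n - n_missing)
    return CandidateVariant(
        chromosome=chrom,
        position=pos,
        ref_allele=ref,
        alt_alleles=tuple(alt),
        quality=qual,
        per_sample_depth=tuple(depths),
        per_sample_called=tuple(called),
        missing_fraction=missing,
        species_of_origin=species,
        score=score,
        marker_id=mid or f"{chrom}:{pos}",
    )


@pytest.mark.parametrize(
    "variant_kwargs, expected_flags",
    [
        ({}, set()),
        ({"ref": "A", "alt": ("T",)}, {"at_cg"}),
        ({"ref": "C", "alt": ("G",)}, {"at_cg"}),
        ({"missing": 0.25}, {"high_missing"}),
        ({"missing": 0.20}, set()),  # boundary: strictly more than 20% fails
        ({"qual": 50.0}, {"low_qual"}),
        ({"qual": None}, set()),  # absent QUAL is not a low QUAL
        ({"ref": "AT", "alt": ("A",)}, {"indel"}),
        ({"alt": ("G", "C")}, {"multiallelic"}),
        ({"depths": [4] + [20] * 9}, {"low_depth"}),
    ],
)
def test_filter_flags(variant_kwargs, expected_flags):
    v = make_variant(**variant_kwargs)
    kept, rejected = apply_variant_filters([v])
    assert v.flags == expected_flags
    assert (v in kept) == (not expected_flags)


def test_mean_depth_mode():
    v = make_variant(depths=[4] + [20] * 9)  # mean 18.4 >= 8
    thresholds = FilterThresholds(dp_mode="mean")
    kept, _ = apply_variant_filters([v], thresholds)
    assert v.flags == set() and v in kept


def test_filters_partition_and_are_idempotent():
    variants = [
        make_variant(pos=1000),
        make_variant(pos=5000, qual=10.0),
        make_variant(pos=9000, ref="A", alt=("T",), missing=0.5),
    ]
    kept, rejected = apply_variant_filters(variants)
    assert sorted(v.marker_id for v in kept + rejected) == sorted(
        v.marker_id for v in variants
    )
    assert all(v.flags for v in rejected) and not any(v.flags for v in kept)
    flags_before = [set(v.flags) for v in variants]
    apply_variant_filters(variants)
    assert [set(v.flags) for v in variants] == flags_before


@pytest.mark.parametrize(
    "positions, chroms, window, expected",
    [
        ((100, 135), ("chr01", "chr01"), 35, {True, True}),
        ((100, 136), ("chr01", "chr01"), 35, {False}),
        ((100, 110), ("chr01", "chr02"), 35, {False}),
        ((100, 120), ("chr01", "chr01"), 35, {True}),
        ((100, 200), ("chr01", "chr01"), 35, {False}),
    ],
)
def test_proximity_boundary(positions, chroms, window, expected):
    variants = [
        make_variant(chrom=c, pos=p) for p, c in zip(positions, chroms)
    ]
    flag_proximal(variants, window)
    assert {("proximity" in v.flags) for v in variants} == expected


def brute_force_proximal(variants, window):
    flagged = set()
    for i, a in enumerate(variants):
        for b in variants[i + 1 :]:
            if a.chromosome == b.chromosome and abs(a.position - b.position) <= window:
                flagged.add(a.marker_id)
                flagged.add(b.marker_id)
    return flagged


def test_proximity_matches_all_pairs_oracle():
    rng = np.random.default_rng(11)
    variants = [
        make_variant(
            chrom=f"chr{rng.integers(1, 4):02d}",
            pos=int(rng.integers(1, 3000)),
            mid=f"v{i}",
        )
        for i in range(1000)
    ]
    flag_proximal(variants, 35)
    got = {v.marker_id for v in variants if "proximity" in v.flags}
    assert got == brute_force_proximal(variants, 35)


def _pool(n_per_cell, species, chroms, spacing=1000, score=None):
    out = []
    for sp in species:
        for c in chroms:
            for k in range(n_per_cell):
                out.append(
                    make_variant(
                        chrom=c,
                        pos=100_000 + k * spacing,
                        species=sp,
                        mid=f"{sp}_{c}_{k}",
                        score=score(k) if score else None,
                    )
                )
    return out


def test_quota_counts_and_shortfall():
    pool = _pool(500, ["vinifera"], ["chr01"]) + _pool(25, ["riparia"], ["chr01"])
    result = select_markers(pool, SelectionQuota())
    counts = result.table.groupby("species").size()
    assert counts["vinifera"] == 130
    assert counts["riparia"] == 25  # min(quota, available)
    row = result.shortfalls.query("species == 'riparia'").iloc[0]
    assert row.shortfall == 15


def test_r_locus_bonus_matches_recount():
    species = ["vinifera", "riparia", "amurensis"]
    pool = _pool(300, species, ["chr01", "chr12"])
    quota = SelectionQuota(r_locus_chromosomes=frozenset({"chr12"}))
    result = select_markers(pool, quota)
    t = result.table
    # brute-force recount from the selection table itself
    for sp in ("riparia", "amurensis"):
        assert len(t.query("species == @sp and chromosome == 'chr01'")) == 40
    chr12_wild = t.query("species != 'vinifera' and chromosome == 'chr12'")
    assert len(chr12_wild) == 2 * 40 + 60
    assert chr12_wild.groupby("species").size().tolist() == [70, 70]  # even split
    assert len(t.query("species == 'vinifera' and chromosome == 'chr12'")) == 130


def test_selection_prefers_score_then_spacing():
    # two score groups; quota cuts inside the low group
    pool = _pool(10, ["vinifera"], ["chr01"], score=lambda k: 1.0 if k < 3 else 0.0)
    result = select_markers(pool, SelectionQuota(per_chromosome_vinifera=5))
    chosen = set(result.table.marker_id)
    assert {"vinifera_chr01_0", "vinifera_chr01_1", "vinifera_chr01_2"} <= chosen
    # remaining two picked from the tied group by greedy max-min spacing:
    # the far end first, then the midpoint
    assert "vinifera_chr01_9" in chosen and "vinifera_chr01_5" in chosen


def test_selection_is_deterministic():
    pool = _pool(200, ["vinifera", "riparia"], ["chr01", "chr02"])
    a = select_markers(pool, SelectionQuota())
    b = select_markers(list(reversed(pool)), SelectionQuota())
    assert a.table.equals(b.table)


def test_unknown_species_label_is_config_error():
    pool = _pool(5, ["mystery"], ["chr01"])
    with pytest.raises(ConfigError, match="unknown species"):
        select_markers(pool, SelectionQuota(), wild_species=["riparia"])
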