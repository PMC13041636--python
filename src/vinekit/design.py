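"""Candidate-variant filtering and quota-based marker selection for array design.

The design stage consumes a pool of candidate variants (typically read from a
multi-sample VCF of resequencing-derived SNPs), removes candidates unsuitable
for probe design, flags variants with close neighbours that would interfere
with hybridization probes, and then fills per-(species, chromosome) quotas so
that the final array represents every species with a controlled number of
markers per chromosome. Chromosomes carrying known disease-resistance (R) loci
receive an extra pool of markers shared across the wild species.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigError

# Flag vocabulary -----------------------------------------------------------

FLAG_LOW_QUAL = "low_qual"
FLAG_INDEL = "indel"
FLAG_MULTIALLELIC = "multiallelic"
FLAG_LOW_DEPTH = "low_depth"
FLAG_HIGH_MISSING = "high_missing"
FLAG_AT_CG = "at_cg"
FLAG_PROXIMITY = "proximity"

ALL_FLAGS = frozenset(
    {
        FLAG_LOW_QUAL,
        FLAG_INDEL,
        FLAG_MULTIALLELIC,
        FLAG_LOW_DEPTH,
        FLAG_HIGH_MISSING,
        FLAG_AT_CG,
        FLAG_PROXIMITY,
    }
)

#: Allele pairs excluded because both probe strands read the same bases,
#: making the two alleles indistinguishable on a single-colour assay.
_AMBIGUOUS_PAIRS = ({"A", "T"}, {"C", "G"})


@dataclass
class CandidateVariant:
    """One candidate SNP/indel considered for inclusion on the array.

    ``quality`` is ``None`` when the VCF carried a missing QUAL (``.``) —
    absent is deliberately distinct from zero. ``per_sample_depth`` entries
    may be ``None`` when DP was not emitted for a sample.
    """

    chromosome: str
    position: int
    ref_allele: str
    alt_alleles: tuple[str, ...]
    quality: float | None = None
    per_sample_depth: tuple[int | None, ...] = ()
    per_sample_called: tuple[bool, ...] = ()
    missing_fraction: float = 0.0
    species_of_origin: str = ""
    score: float | None = None
    marker_id: str = ""
    flags: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        if self.position < 1:
            raise ConfigError(
                f"variant position must be >= 1, got {self.position}"
            )
        if not 0.0 <= self.missing_fraction <= 1.0:
            raise ConfigError(
                f"missing_fraction must be in [0, 1], got {self.missing_fraction}"
            )

    @property
    def n_alleles(self) -> int:
        return 1 + len(self.alt_alleles)

    @property
    def is_snv(self) -> bool:
        return len(self.ref_allele) == 1 and all(
            len(a) == 1 for a in self.alt_alleles
        )

    @property
    def is_biallelic(self) -> bool:
        return self.n_alleles == 2


@dataclass(frozen=True)
class FilterThresholds:
    """Thresholds of the candidate-filter chain.

    ``dp_mode`` selects how the depth criterion aggregates: ``"per_sample"``
    fails a site when any called sample has DP below ``min_depth`` (matching
    per-sample DP semantics of common callers), ``"mean"`` compares the mean
    depth over called samples.
    """

    min_qual: float = 100.0
    min_depth: int = 8
    max_missing: float = 0.20
    dp_mode: str = "per_sample"
    exclude_at_cg: bool = True
    proximity_window: int = 35
    apply_proximity: bool = True
    reject_proximal: bool = True

    def __post_init__(self) -> None:
        if self.dp_mode not in ("per_sample", "mean"):
            raise ConfigError(f"unknown dp_mode {self.dp_mode!r}")
        if self.proximity_window < 0:
            raise ConfigError("proximity_window must be >= 0")


@dataclass(frozen=True)
class SelectionQuota:
    """Per-chromosome marker quotas used to fill the array.

    Defaults follow the published design: 40 SNPs per chromosome for each
    wild species, 130 per chromosome for V. vinifera, and 60 additional SNPs
    on chromosomes carrying known R loci. The bonus is attached to the
    chromosome, not to a species, and is shared round-robin across the wild
    species present there.
    """

    per_chromosome_wild: int = 40
    per_chromosome_vinifera: int = 130
    r_locus_bonus: int = 60
    r_locus_chromosomes: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if min(self.per_chromosome_wild, self.per_chromosome_vinifera, self.r_locus_bonus) < 0:
            raise ConfigError("quotas must be non-negative")


def flag_proximal(
    variants: Sequence[CandidateVariant], window: int = 35
) -> list[CandidateVariant]:
    """Flag variants lying within ``window`` nt of any other variant.

    The criterion is symmetric and inclusive (|delta position| <= window) and
    considers every polymorphism regardless of type or of whether it is
    later filtered out, since probe interference does not depend on why a
    neighbour was eventually dropped. A variant is within ``window`` of some
    other variant iff it is within ``window`` of its nearest neighbour, so a
    single pass over the positions sorted per chromosome suffices.

    Mutates ``variants`` in place (adds/removes the ``proximity`` flag) and
    returns the input sequence as a list in its original order.
    """
    if window < 0:
        raise ConfigError("window must be >= 0")
    order = sorted(
        range(len(variants)),
        key=lambda i: (variants[i].chromosome, variants[i].position),
    )
    for v in variants:
        v.flags.discard(FLAG_PROXIMITY)
    for a, b in zip(order, order[1:]):
        va, vb = variants[a], variants[b]
        if va.chromosome != vb.chromosome:
            continue
        if vb.position - va.position <= window:
            va.flags.add(FLAG_PROXIMITY)
            vb.flags.add(FLAG_PROXIMITY)
    return list(variants)


def _core_flags(v: CandidateVariant, t: FilterThresholds) -> set[str]:
    flags: set[str] = set()
    if v.quality is not None and v.quality < t.min_qual:
        flags.add(FLAG_LOW_QUAL)
    if not v.is_snv:
        flags.add(FLAG_INDEL)
    if not v.is_biallelic:
        flags.add(FLAG_MULTIALLELIC)
    depths = [
        d
        for d, called in zip(v.per_sample_depth, v.per_sample_called)
        if called and d is not None
    ]
    if depths:
        if t.dp_mode == "per_sample":
            if min(depths) < t.min_depth:
                flags.add(FLAG_LOW_DEPTH)
        elif float(np.mean(depths)) < t.min_depth:
            flags.add(FLAG_LOW_DEPTH)
    if v.missing_fraction > t.max_missing:
        flags.add(FLAG_HIGH_MISSING)
    if t.exclude_at_cg and v.is_snv and v.is_biallelic:
        pair = {v.ref_allele.upper(), v.alt_alleles[0].upper()}
        if pair in _AMBIGUOUS_PAIRS:
            flags.add(FLAG_AT_CG)
    return flags


def apply_variant_filters(
    variants: Sequence[CandidateVariant],
    thresholds: FilterThresholds | None = None,
) -> tuple[list[CandidateVariant], list[CandidateVariant]]:
    """Partition candidates into (kept, rejected) and annotate flags.

    Every rejected variant carries at least one flag naming the failed
    criterion; kept variants carry no rejecting flag. Flags are recomputed
    from scratch on each call, so the operation is idempotent. Proximity is
    evaluated first, against all polymorphisms (see :func:`flag_proximal`);
    whether a proximity flag rejects is controlled by
    ``thresholds.reject_proximal``.
    """
    t = thresholds or FilterThresholds()
    variants = list(variants)
    for v in variants:
        v.flags.clear()
    if t.apply_proximity:
        flag_proximal(variants, t.proximity_window)
    kept: list[CandidateVariant] = []
    rejected: list[CandidateVariant] = []
    for v in variants:
        v.flags |= _core_flags(v, t)
        rejecting = set(v.flags)
        if not t.reject_proximal:
            rejecting.discard(FLAG_PROXIMITY)
        (rejected if rejecting else kept).append(v)
    return kept, rejected


# Quota selection ------------------------------------------------------------


def _rank_cell(cands: list[CandidateVariant]) -> list[CandidateVariant]:
    """Full deterministic ranking of one (species, chromosome) cell.

    Candidates are consumed in descending score order (absent scores last);
    within a score tie the next pick greedily maximizes the minimum distance
    to the markers already ranked, breaking ties by position and then by
    marker id, so re-runs are byte-identical.
    """
    by_score: dict[float, list[CandidateVariant]] = {}
    for v in cands:
        key = -np.inf if v.score is None else float(v.score)
        by_score.setdefault(key, []).append(v)

    ranked: list[CandidateVariant] = []
    positions: list[int] = []
    for key in sorted(by_score, reverse=True):
        group = sorted(by_score[key], key=lambda v: (v.position, v.marker_id))
        if len(group) == 1:
            ranked.append(group[0])
            positions.append(group[0].position)
            continue
        pos = np.array([v.position for v in group], dtype=np.int64)
        taken = np.zeros(len(group), dtype=bool)
        if positions:
            mindist = np.min(
                np.abs(pos[:, None] - np.array(positions, dtype=np.int64)[None, :]),
                axis=1,
            )
        else:
            # first pick of an empty selection: smallest position
            first = 0
            taken[first] = True
            ranked.append(group[first])
            positions.append(group[first].position)
            mindist = np.abs(pos - pos[first])
        while not taken.all():
            d = np.where(taken, -1, mindist)
            best = np.flatnonzero(d == d.max())
            # ties: smaller position, then marker_id (group pre-sorted)
            pick = int(best[0])
            taken[pick] = True
            ranked.append(group[pick])
            positions.append(group[pick].position)
            mindist = np.minimum(mindist, np.abs(pos - pos[pick]))
    return ranked


@dataclass
class SelectionResult:
    """Output of :func:`select_markers`.

    ``table`` has one row per selected marker (species, chromosome,
    marker_id, position, score, rank, bonus); ``shortfalls`` records, per
    cell, how many requested slots could not be filled.
    """

    table: pd.DataFrame
    shortfalls: pd.DataFrame


def select_markers(
    candidates: Sequence[CandidateVariant],
    quota: SelectionQuota | None = None,
    *,
    vinifera_label: str = "vinifera",
    wild_species: Iterable[str] | None = None,
) -> SelectionResult:
    """Fill per-(species, chromosome) quotas from a pre-filtered pool.

    Each cell receives exactly ``min(quota, available)`` markers; wild-species
    cells on R-locus chromosomes additionally share a per-chromosome bonus
    pool of ``quota.r_locus_bonus`` markers, distributed round-robin across
    the wild species present on that chromosome (alphabetical order), each
    species continuing down its own ranking.
    """
    q = quota or SelectionQuota()
    species_seen = sorted({v.species_of_origin for v in candidates})
    if "" in species_seen:
        raise ConfigError("candidates without species_of_origin cannot be allocated")
    if wild_species is not None:
        allowed = set(wild_species) | {vinifera_label}
        unknown = [s for s in species_seen if s not in allowed]
        if unknown:
            raise ConfigError(f"unknown species label(s): {unknown}")
        wild = sorted(set(wild_species) & set(species_seen))
    else:
        wild = [s for s in species_seen if s != vinifera_label]

    cells: dict[tuple[str, str], list[CandidateVariant]] = {}
    for v in candidates:
        cells.setdefault((v.species_of_origin, v.chromosome), []).append(v)

    rows: list[dict] = []
    shortfall_rows: list[dict] = []
    rankings: dict[tuple[str, str], list[CandidateVariant]] = {}
    cursor: dict[tuple[str, str], int] = {}

    for (sp, chrom) in sorted(cells):
        ranking = _rank_cell(cells[(sp, chrom)])
        rankings[(sp, chrom)] = ranking
        base = (
            q.per_chromosome_vinifera if sp == vinifera_label else q.per_chromosome_wild
        )
        n_take = min(base, len(ranking))
        for rank, v in enumerate(ranking[:n_take], start=1):
            rows.append(
                {
                    "species": sp,
                    "chromosome": chrom,
                    "marker_id": v.marker_id,
                    "position": v.position,
                    "score": v.score,
                    "rank": rank,
                    "bonus": False,
                }
            )
        cursor[(sp, chrom)] = n_take
        shortfall_rows.append(
            {
                "species": sp,
                "chromosome": chrom,
                "quota": base,
                "selected": n_take,
                "shortfall": base - n_take,
            }
        )

    # R-locus bonus: a per-chromosome pool shared round-robin by wild species.
    chroms_with_wild = sorted(
        {c for (sp, c) in cells if sp in wild} & set(q.r_locus_chromosomes)
    )
    for chrom in chroms_with_wild:
        present = [sp for sp in wild if (sp, chrom) in cells]
        remaining = q.r_locus_bonus
        assigned = 0
        while remaining > 0:
            progressed = False
            for sp in present:
                if remaining == 0:
                    break
                key = (sp, chrom)
                i = cursor[key]
                if i < len(rankings[key]):
                    v = rankings[key][i]
                    cursor[key] = i + 1
                    rows.append(
                        {
                            "species": sp,
                            "chromosome": chrom,
                            "marker_id": v.marker_id,
                            "position": v.position,
                            "score": v.score,
                            "rank": i + 1,
                            "bonus": True,
                        }
                    )
                    remaining -= 1
                    assigned += 1
                    progressed = True
            if not progressed:
                break
        shortfall_rows.append(
            {
                "species": "__r_locus_bonus__",
                "chromosome": chrom,
                "quota": q.r_locus_bonus,
                "selected": assigned,
                "shortfall": q.r_locus_bonus - assigned,
            }
        )

    table = pd.DataFrame(
        rows,
        columns=["species", "chromosome", "marker_id", "position", "score", "rank", "bonus"],
    )
    table = table.sort_values(
        ["species", "chromosome", "bonus", "rank"], kind="stable"
    ).reset_index(drop=True)
    shortfalls = pd.DataFrame(
        shortfall_rows,
        columns=["species", "chromosome", "quota", "selected", "shortfall"],
    )
    shortfalls = shortfalls.sort_values(["species", "chromosome"], kind="stable").reset_index(
        drop=True
    )
    return SelectionResult(table=table, shortfalls=shortfalls)
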