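"""Duplicate detection, duo/trio pedigree inference and relationship PCA.

The method is pure Mendelian-incompatibility counting on diploid biallelic
calls, no likelihood model: a putative parent-offspring (PO) pair is
contradicted by opposing homozygotes (AA vs BB), a parent-parent-offspring
(PPO) trio by any genotype the offspring could not assemble from one allele
of each parent. Four pairwise statistics drive both the inference and the
relationship-class ordination:

- ``duo_errors_perc``      : 100 * opposing homozygotes / markers compared
- ``het_mismatch_A1A2``    : markers where the first sample is AB, the second homozygous
- ``het_mismatch_A2A1``    : the reverse direction
- ``perc_mismatches``      : 100 * (both directional counts) / markers compared

Markers with a no-call in any member of a pair/trio are excluded from the
denominators. The directional counters follow the documented convention
(first-listed sample heterozygous); swapping the pair swaps the counters.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .curation import (
    MendelianFilterResult,
    RelationshipSet,
    _trio_incompatible,
    filter_mendelian,
)
from .errors import ConfigError
from .io import GenotypeMatrix

DUO_COLUMNS = [
    "sample_a",
    "sample_b",
    "n_compared",
    "n_opposing_hom",
    "duo_errors_perc",
    "het_mismatch_A1A2",
    "het_mismatch_A2A1",
    "perc_mismatches",
    "is_candidate_po",
]

RELATIONSHIP_CLASSES = ("PO", "FS", "GP", "HS", "UN", "OTHER")


@dataclass
class DuoResult:
    """Pairwise Mendelian-incompatibility summary for one sample pair."""

    sample_a: str
    sample_b: str
    n_compared: int
    n_opposing_hom: int
    duo_errors_perc: float
    het_mismatch_A1A2: int
    het_mismatch_A2A1: int
    perc_mismatches: float
    is_candidate_po: bool
    evaluable: bool = True

    def swapped(self) -> "DuoResult":
        """The same duo with the samples listed in the opposite order."""
        return DuoResult(
            sample_a=self.sample_b,
            sample_b=self.sample_a,
            n_compared=self.n_compared,
            n_opposing_hom=self.n_opposing_hom,
            duo_errors_perc=self.duo_errors_perc,
            het_mismatch_A1A2=self.het_mismatch_A2A1,
            het_mismatch_A2A1=self.het_mismatch_A1A2,
            perc_mismatches=self.perc_mismatches,
            is_candidate_po=self.is_candidate_po,
            evaluable=self.evaluable,
        )


@dataclass
class TrioResult:
    """Trio (offspring + parent pair) incompatibility summary."""

    offspring: str
    parent1: str
    parent2: str
    n_evaluable: int
    n_incompatible: int
    trio_errors_perc: float
    is_candidate_ppo: bool
    evaluable: bool = True


def compute_duo(
    gm: GenotypeMatrix, a: str, b: str, po_threshold: float = 0.92
) -> DuoResult:
    """Duo statistics for one ordered sample pair.

    ``po_threshold`` is the maximum ``duo_errors_perc`` (in percent) for the
    pair to count as a candidate parent-offspring relationship.
    """
    ga = gm.sample_calls(a)
    gb = gm.sample_calls(b)
    both = (ga >= 0) & (gb >= 0)
    n = int(both.sum())
    opp = int((((ga == 0) & (gb == 2)) | ((ga == 2) & (gb == 0)))[both].sum())
    hm_ab = int(((ga == 1) & ((gb == 0) | (gb == 2)))[both].sum())
    hm_ba = int(((gb == 1) & ((ga == 0) | (ga == 2)))[both].sum())
    if n == 0:
        return DuoResult(a, b, 0, 0, 0.0, 0, 0, 0.0, False, evaluable=False)
    duo_perc = 100.0 * opp / n
    return DuoResult(
        sample_a=a,
        sample_b=b,
        n_compared=n,
        n_opposing_hom=opp,
        duo_errors_perc=duo_perc,
        het_mismatch_A1A2=hm_ab,
        het_mismatch_A2A1=hm_ba,
        perc_mismatches=100.0 * (hm_ab + hm_ba) / n,
        is_candidate_po=duo_perc <= po_threshold,
    )


def compute_trio(
    gm: GenotypeMatrix,
    offspring: str,
    p1: str,
    p2: str,
    ppo_threshold: float = 1.0,
) -> TrioResult:
    """Trio statistics; a marker is evaluable when all three are called."""
    go = gm.sample_calls(offspring)
    g1 = gm.sample_calls(p1)
    g2 = gm.sample_calls(p2)
    all3 = (go >= 0) & (g1 >= 0) & (g2 >= 0)
    n = int(all3.sum())
    inc = int(_trio_incompatible(go, g1, g2)[all3].sum())
    if n == 0:
        return TrioResult(offspring, p1, p2, 0, 0, 0.0, False, evaluable=False)
    perc = 100.0 * inc / n
    return TrioResult(
        offspring=offspring,
        parent1=p1,
        parent2=p2,
        n_evaluable=n,
        n_incompatible=inc,
        trio_errors_perc=perc,
        is_candidate_ppo=perc <= ppo_threshold,
    )


# -- all-pairs machinery ------------------------------------------------------


def _pair_count_matrices(gm: GenotypeMatrix) -> dict[str, np.ndarray]:
    """Dense n x n pairwise counting kernels via boolean matrix products."""
    hom_a = (gm.codes == 0).astype(np.float32)
    het = (gm.codes == 1).astype(np.float32)
    hom_b = (gm.codes == 2).astype(np.float32)
    called = hom_a + het + hom_b
    hom = hom_a + hom_b
    n_compared = called @ called.T
    opposing = hom_a @ hom_b.T + hom_b @ hom_a.T
    het_vs_hom = het @ hom.T  # row het, column hom
    n_same = hom_a @ hom_a.T + het @ het.T + hom_b @ hom_b.T
    return {
        "n_compared": np.rint(n_compared).astype(np.int64),
        "opposing": np.rint(opposing).astype(np.int64),
        "het_vs_hom": np.rint(het_vs_hom).astype(np.int64),
        "n_same": np.rint(n_same).astype(np.int64),
    }


def all_pairs_duos(gm: GenotypeMatrix, po_threshold: float = 0.92) -> pd.DataFrame:
    """Duo statistics for every unordered sample pair (a listed before b).

    Columns follow the duo report vocabulary (``duo_errors_perc``,
    ``het_mismatch_A1A2``, ``het_mismatch_A2A1``, ``perc_mismatches``).
    """
    k = _pair_count_matrices(gm)
    rows = []
    ids = gm.sample_ids
    for i, j in combinations(range(len(ids)), 2):
        n = int(k["n_compared"][i, j])
        opp = int(k["opposing"][i, j])
        hm_ab = int(k["het_vs_hom"][i, j])
        hm_ba = int(k["het_vs_hom"][j, i])
        duo_perc = 100.0 * opp / n if n else 0.0
        rows.append(
            (
                ids[i],
                ids[j],
                n,
                opp,
                duo_perc,
                hm_ab,
                hm_ba,
                100.0 * (hm_ab + hm_ba) / n if n else 0.0,
                bool(n and duo_perc <= po_threshold),
            )
        )
    return pd.DataFrame(rows, columns=DUO_COLUMNS)


def find_duplicates(
    gm: GenotypeMatrix, max_diff: int = 10
) -> list[tuple[tuple[str, str], int]]:
    """All unordered pairs whose call discordance (both called, calls
    differ) is at most ``max_diff``, sorted ascending by the difference
    count. Pairs with no marker called in both are never reported."""
    k = _pair_count_matrices(gm)
    n_diff = k["n_compared"] - k["n_same"]
    ids = gm.sample_ids
    hits = []
    for i, j in combinations(range(len(ids)), 2):
        if k["n_compared"][i, j] > 0 and n_diff[i, j] <= max_diff:
            hits.append(((ids[i], ids[j]), int(n_diff[i, j])))
    hits.sort(key=lambda h: (h[1], h[0]))
    return hits


# -- pedigree expectations ----------------------------------------------------


def known_po_pairs(pedigree: pd.DataFrame) -> set[frozenset[str]]:
    """Parent-offspring pairs declared by the pedigree table."""
    pairs: set[frozenset[str]] = set()
    for row in pedigree.itertuples(index=False):
        for parent in (row.mother_id, row.father_id):
            if parent:
                pairs.add(frozenset((row.sample_id, parent)))
    return pairs


def expected_relationships(pedigree: pd.DataFrame) -> dict[frozenset[str], str]:
    """Pedigree-expected relationship class for every related pair.

    Classes: PO (parent-offspring), FS (full siblings), GP (grandparent),
    HS (half siblings), UN (avuncular: full sib of a parent). These are the
    close-kin classes (kinship coefficient r > 0.25 plus the r = 0.25 ring
    used in practice); any pair not reached by these rules is OTHER and is
    simply absent from the returned mapping.
    """
    parents: dict[str, tuple[str, str]] = {}
    for row in pedigree.itertuples(index=False):
        parents[row.sample_id] = (row.mother_id or "", row.father_id or "")

    rel: dict[frozenset[str], str] = {}

    def put(a: str, b: str, cls: str) -> None:
        if a != b:
            rel.setdefault(frozenset((a, b)), cls)

    ids = list(parents)
    # PO
    for s, (m, f) in parents.items():
        for p in (m, f):
            if p:
                put(s, p, "PO")
    # FS / HS
    for a, b in combinations(ids, 2):
        pa = {p for p in parents[a] if p}
        pb = {p for p in parents[b] if p}
        shared = pa & pb
        if len(shared) == 2:
            put(a, b, "FS")
        elif len(shared) == 1:
            put(a, b, "HS")
    # GP: parent of parent
    for s, (m, f) in parents.items():
        for p in (m, f):
            if p and p in parents:
                for gp in parents[p]:
                    if gp:
                        put(s, gp, "GP")
    # UN: full sibling of a parent
    fs_of: dict[str, set[str]] = {}
    for pair, cls in rel.items():
        if cls == "FS":
            a, b = tuple(pair)
            fs_of.setdefault(a, set()).add(b)
            fs_of.setdefault(b, set()).add(a)
    for s, (m, f) in parents.items():
        for p in (m, f):
            if p:
                for un in fs_of.get(p, ()):
                    put(s, un, "UN")
    return rel


# -- inference ---------------------------------------------------------------


@dataclass
class InferredRelationships:
    """Candidate PO duos and PPO trios plus the thresholds actually used."""

    duos: list[DuoResult]
    trios: list[TrioResult]
    threshold_used: float
    duo_table: pd.DataFrame
    trio_threshold_used: float = 1.0


def infer_relationships(
    gm: GenotypeMatrix,
    pedigree: pd.DataFrame | None,
    duo_threshold_init: float = 0.5,
    trio_threshold: float = 1.0,
) -> InferredRelationships:
    """Candidate PO/PPO inference with known-pair threshold relaxation.

    The first pass screens all pairs at ``duo_threshold_init`` (percent).
    If the pedigree declares PO pairs whose observed error exceeds the
    initial threshold, the threshold is raised to the maximum
    ``duo_errors_perc`` observed among known PO pairs, so that every
    expected true PO pair is captured. Trios are then evaluated for every
    sample against each pair of its candidate parents; the trio threshold
    is relaxed the same way, to the maximum error observed among
    pedigree-declared trios whose parents are both candidate-PO, so that
    every expected trio is retained even before high-error markers have
    been filtered out.
    """
    table = all_pairs_duos(gm, po_threshold=duo_threshold_init)
    threshold = duo_threshold_init
    if pedigree is not None and len(pedigree):
        known = known_po_pairs(pedigree)
        present = {s for pair in known for s in pair} & set(gm.sample_ids)
        mask = [
            frozenset((a, b)) in known
            for a, b in zip(table["sample_a"], table["sample_b"])
        ]
        known_rows = table[np.array(mask, dtype=bool) & (table["n_compared"] > 0)]
        if len(known_rows):
            max_known = float(known_rows["duo_errors_perc"].max())
            if max_known > threshold:
                threshold = max_known
        del present
    table = table.copy()
    table["is_candidate_po"] = (table["n_compared"] > 0) & (
        table["duo_errors_perc"] <= threshold
    )

    duos = [
        DuoResult(
            sample_a=r.sample_a,
            sample_b=r.sample_b,
            n_compared=int(r.n_compared),
            n_opposing_hom=int(r.n_opposing_hom),
            duo_errors_perc=float(r.duo_errors_perc),
            het_mismatch_A1A2=int(r.het_mismatch_A1A2),
            het_mismatch_A2A1=int(r.het_mismatch_A2A1),
            perc_mismatches=float(r.perc_mismatches),
            is_candidate_po=True,
        )
        for r in table[table["is_candidate_po"]].itertuples(index=False)
    ]

    partners: dict[str, list[str]] = {}
    for d in duos:
        partners.setdefault(d.sample_a, []).append(d.sample_b)
        partners.setdefault(d.sample_b, []).append(d.sample_a)

    trio_thr = trio_threshold
    if pedigree is not None and len(pedigree):
        known_errors = []
        samples = set(gm.sample_ids)
        for row in pedigree.itertuples(index=False):
            o, m, f = row.sample_id, row.mother_id, row.father_id
            if not (m and f) or {o, m, f} - samples:
                continue
            if m in partners.get(o, ()) and f in partners.get(o, ()):
                t = compute_trio(gm, o, m, f, ppo_threshold=trio_threshold)
                if t.evaluable:
                    known_errors.append(t.trio_errors_perc)
        if known_errors and max(known_errors) > trio_thr:
            trio_thr = max(known_errors)

    trios: list[TrioResult] = []
    for s in gm.sample_ids:
        ps = sorted(partners.get(s, []))
        for p1, p2 in combinations(ps, 2):
            t = compute_trio(gm, s, p1, p2, ppo_threshold=trio_thr)
            if t.evaluable and t.is_candidate_ppo:
                trios.append(t)
    return InferredRelationships(
        duos=duos,
        trios=trios,
        threshold_used=threshold,
        duo_table=table,
        trio_threshold_used=trio_thr,
    )


def confirmed_relationship_set(
    inferred: InferredRelationships, pedigree: pd.DataFrame
) -> RelationshipSet:
    """Intersect inferred candidates with the declared pedigree.

    Only pairs/trios that are both inferred and pedigree-declared count as
    confirmed for Mendelian marker filtering, so that coincidental
    low-error pairs (e.g. full siblings) do not contaminate the filter.
    Every confirmed duo enters the set alongside the confirmed trios, so
    the per-marker error rate pools both checks' transmissions.
    """
    known = known_po_pairs(pedigree)
    declared = {
        row.sample_id: frozenset((row.mother_id, row.father_id))
        for row in pedigree.itertuples(index=False)
        if row.mother_id and row.father_id
    }
    trios = tuple(
        (t.offspring, t.parent1, t.parent2)
        for t in inferred.trios
        if declared.get(t.offspring) == frozenset((t.parent1, t.parent2))
    )
    duos = tuple(
        (d.sample_a, d.sample_b)
        for d in inferred.duos
        if frozenset((d.sample_a, d.sample_b)) in known
    )
    return RelationshipSet(duos=duos, trios=trios)


@dataclass
class IterativeCurationResult:
    gm: GenotypeMatrix
    duos: list[DuoResult]
    trios: list[TrioResult]
    removed_per_iteration: list[list[str]]
    threshold_used: float
    converged: bool

    @property
    def removed_markers(self) -> list[str]:
        return [m for it in self.removed_per_iteration for m in it]


def run_iterative_curation(
    gm: GenotypeMatrix,
    pedigree: pd.DataFrame,
    max_error: float = 0.03,
    duo_threshold_init: float = 0.5,
    trio_threshold: float = 1.0,
    max_iterations: int = 10,
) -> IterativeCurationResult:
    """Alternate relationship inference and Mendelian marker filtering.

    Each round infers candidate PO/PPO relationships, confirms them against
    the pedigree, and removes markers with a Mendelian error rate above
    ``max_error`` (a fraction, default 0.03). The loop stops at a fixed
    point (no marker removed) or after ``max_iterations`` rounds, in which
    case a warning is emitted and the partial result returned.
    """
    current = gm
    removed_log: list[list[str]] = []
    converged = False
    inferred = infer_relationships(
        current, pedigree, duo_threshold_init, trio_threshold
    )
    for _ in range(max_iterations):
        confirmed = confirmed_relationship_set(inferred, pedigree)
        result: MendelianFilterResult = filter_mendelian(
            current, confirmed, max_error=max_error
        )
        if not result.removed:
            converged = True
            break
        removed_log.append(result.removed)
        current = current.drop_markers(result.removed)
        inferred = infer_relationships(
            current, pedigree, duo_threshold_init, trio_threshold
        )
    if not converged:
        warnings.warn(
            f"Mendelian curation did not reach a fixed point in "
            f"{max_iterations} iterations; returning partial result",
            stacklevel=2,
        )
    return IterativeCurationResult(
        gm=current,
        duos=inferred.duos,
        trios=inferred.trios,
        removed_per_iteration=removed_log,
        threshold_used=inferred.threshold_used,
        converged=converged,
    )


# -- relationship-class ordination --------------------------------------------

PCA_VARIABLES = [
    "duo_errors_perc",
    "het_mismatch_A1A2",
    "het_mismatch_A2A1",
    "perc_mismatches",
]


@dataclass
class RelationshipOrdination:
    """PCA of the four duo variables with supplementary OTHER pairs.

    ``coordinates`` carries one row per pair with its class, supplementary
    status and axis scores; ``contributions`` the percent contribution of
    each variable to each axis (columns sum to 100).
    """

    coordinates: pd.DataFrame
    explained_variance_ratio: np.ndarray
    contributions: pd.DataFrame


def classify_relationships(
    duo_table: pd.DataFrame,
    labels: Mapping[frozenset[str], str] | pd.DataFrame,
) -> RelationshipOrdination:
    """PCA of standardized duo variables; OTHER pairs projected only.

    The eigendecomposition is fitted exclusively on pairs with a primary
    relationship class (PO/FS/GP/HS/UN); OTHER pairs are projected onto the
    fitted axes using the active centering/scaling/rotation without
    influencing them, the supplementary-individuals treatment of
    correlation-matrix PCA.
    """
    if isinstance(labels, pd.DataFrame):
        labels = {
            frozenset((r.sample_a, r.sample_b)): r.expected_class
            for r in labels.itertuples(index=False)
        }
    df = duo_table.copy()
    cls = [
        labels.get(frozenset((a, b)), "OTHER")
        for a, b in zip(df["sample_a"], df["sample_b"])
    ]
    df["expected_class"] = cls
    df["supplementary"] = df["expected_class"] == "OTHER"
    active = df[~df["supplementary"]]
    if len(active) < 3:
        raise ConfigError(
            f"ordination needs at least 3 non-OTHER pairs, got {len(active)}"
        )
    X = df[PCA_VARIABLES].to_numpy(dtype=float)
    act = X[~df["supplementary"].to_numpy()]
    mean = act.mean(axis=0)
    std = act.std(axis=0, ddof=0)
    if np.any(std == 0):
        flat = [v for v, s in zip(PCA_VARIABLES, std) if s == 0]
        raise ConfigError(f"variable(s) with zero variance among active pairs: {flat}")
    Z_act = (act - mean) / std

    from sklearn.decomposition import PCA

    pca = PCA(n_components=len(PCA_VARIABLES), svd_solver="full")
    pca.fit(Z_act)
    components = pca.components_  # (axes, variables)
    # deterministic sign: the variable with the largest |loading| is positive
    for k in range(components.shape[0]):
        j = int(np.argmax(np.abs(components[k])))
        if components[k, j] < 0:
            components[k] = -components[k]
    Z_all = (X - mean) / std
    coords = Z_all @ components.T
    axes = [f"PC{k + 1}" for k in range(components.shape[0])]
    out = df[["sample_a", "sample_b", "expected_class", "supplementary"]].copy()
    for k, name in enumerate(axes):
        out[name] = coords[:, k]
    contributions = pd.DataFrame(
        100.0 * components.T**2, index=PCA_VARIABLES, columns=axes
    )
    return RelationshipOrdination(
        coordinates=out.reset_index(drop=True),
        explained_variance_ratio=np.asarray(pca.explained_variance_ratio_),
        contributions=contributions,
    )


def deduplicate_samples(
    gm: GenotypeMatrix, duplicates: Sequence[tuple[tuple[str, str], int]]
) -> GenotypeMatrix:
    """Drop the lexicographically later member of each duplicate pair."""
    drop = {max(pair) for pair, _ in duplicates}
    keep = [s for s in gm.sample_ids if s not in drop]
    return gm.subset(samples=keep)
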