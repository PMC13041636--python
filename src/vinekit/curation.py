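"""Post-genotyping sample and marker QC on exported genotype calls.

Mirrors the call-level part of an array-curation workflow: per-sample call
rate and observed heterozygosity against a QC call-rate threshold (default
0.85, lowered from the usual 0.97 to accommodate multi-species panels),
per-marker call rate / MAF / monomorphy classification, and exclusion of
markers whose Mendelian segregation error across confirmed parent-offspring
relationships exceeds a threshold (default 3%).

Intensity-based marker classes (PolyHighResolution and friends) cannot be
reproduced from calls alone; the status enum here is a declared call-level
proxy. Markers showing all three genotype classes at a minor allele
frequency below the floor are tagged EXTRA_CLASS_SUSPECT, a call-level
analogue of spurious-cluster removal.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
import numpy as np

from .io import GenotypeMatrix

STATUS_PASS = "PASS"
STATUS_MONO = "MONO"
STATUS_LOW_CALL_RATE = "LOW_CALL_RATE"
STATUS_HIGH_MENDELIAN_ERROR = "HIGH_MENDELIAN_ERROR"
STATUS_EXTRA_CLASS_SUSPECT = "EXTRA_CLASS_SUSPECT"


@dataclass
class SampleQC:
    sample_id: str
    call_rate: float
    observed_heterozygosity: float | None
    passes: bool


@dataclass
class MarkerQC:
    marker_id: str
    call_rate: float
    maf: float
    n_classes_observed: int
    status: str
    mendelian_error_rate: float | None = None


@dataclass
class RelationshipSet:
    """Confirmed parent-offspring links used for Mendelian filtering.

    ``duos``: (sample, sample) pairs confirmed as parent-offspring;
    ``trios``: (offspring, parent1, parent2) triples.
    """

    duos: tuple[tuple[str, str], ...] = ()
    trios: tuple[tuple[str, str, str], ...] = ()

    def __len__(self) -> int:
        return len(self.duos) + len(self.trios)


@dataclass
class MendelianFilterResult:
    kept: list[str]
    removed: list[str]
    error_rates: dict[str, float | None] = field(repr=False, default_factory=dict)


def sample_qc(
    gm: GenotypeMatrix, min_call_rate: float = 0.85
) -> list[SampleQC]:
    """Per-sample call rate and observed heterozygosity.

    Observed heterozygosity is n_AB / n_called; a sample with zero called
    markers has no defined heterozygosity and fails QC outright.
    """
    called = gm.codes >= 0
    n_called = called.sum(axis=1)
    n_het = (gm.codes == 1).sum(axis=1)
    call_rate = n_called / gm.n_markers
    out = []
    for i, sid in enumerate(gm.sample_ids):
        if n_called[i] == 0:
            het: float | None = None
            passes = False
        else:
            het = float(n_het[i] / n_called[i])
            passes = bool(call_rate[i] >= min_call_rate)
        out.append(
            SampleQC(
                sample_id=sid,
                call_rate=float(call_rate[i]),
                observed_heterozygosity=het,
                passes=passes,
            )
        )
    return out


def marker_qc(
    gm: GenotypeMatrix,
    min_call_rate: float = 0.85,
    maf_floor: float = 0.05,
) -> list[MarkerQC]:
    """Per-marker call rate, allele-count MAF and status classification.

    MAF uses allele counts, min(p, 1-p) with p = (2 n_AA + n_AB)/(2 n_called);
    no-calls are excluded from every denominator. Status precedence:
    LOW_CALL_RATE > EXTRA_CLASS_SUSPECT > MONO > PASS.
    """
    codes = gm.codes
    n_aa = (codes == 0).sum(axis=0)
    n_ab = (codes == 1).sum(axis=0)
    n_bb = (codes == 2).sum(axis=0)
    n_called = n_aa + n_ab + n_bb
    call_rate = n_called / gm.n_samples
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(n_called > 0, (2 * n_aa + n_ab) / (2 * np.maximum(n_called, 1)), np.nan)
    maf = np.minimum(p, 1 - p)
    n_classes = (n_aa > 0).astype(int) + (n_ab > 0).astype(int) + (n_bb > 0).astype(int)

    out = []
    for j, mid in enumerate(gm.marker_ids):
        if call_rate[j] < min_call_rate:
            status = STATUS_LOW_CALL_RATE
        elif n_classes[j] == 3 and maf[j] < maf_floor:
            status = STATUS_EXTRA_CLASS_SUSPECT
        elif n_classes[j] == 1:
            status = STATUS_MONO
        else:
            status = STATUS_PASS
        out.append(
            MarkerQC(
                marker_id=mid,
                call_rate=float(call_rate[j]),
                maf=float(maf[j]) if n_called[j] > 0 else float("nan"),
                n_classes_observed=int(n_classes[j]),
                status=status,
            )
        )
    return out


def mendelian_error_rates(
    gm: GenotypeMatrix, relationships: RelationshipSet
) -> tuple[np.ndarray, np.ndarray]:
    """Per-marker (incompatible, evaluable) transmission counts.

    A duo transmission is evaluable when both members are called and
    incompatible on opposing homozygotes (AA vs BB). A trio transmission is
    evaluable when all three members are called and incompatible when the
    offspring genotype cannot receive one allele from each parent.
    """
    m = gm.n_markers
    err = np.zeros(m, dtype=np.int64)
    ev = np.zeros(m, dtype=np.int64)
    for a, b in relationships.duos:
        ga = gm.sample_calls(a)
        gb = gm.sample_calls(b)
        both = (ga >= 0) & (gb >= 0)
        opp = ((ga == 0) & (gb == 2)) | ((ga == 2) & (gb == 0))
        ev += both
        err += opp & both
    for o, p1, p2 in relationships.trios:
        go = gm.sample_calls(o)
        g1 = gm.sample_calls(p1)
        g2 = gm.sample_calls(p2)
        all3 = (go >= 0) & (g1 >= 0) & (g2 >= 0)
        inc = _trio_incompatible(go, g1, g2)
        ev += all3
        err += inc & all3
    return err, ev


def _trio_incompatible(go: np.ndarray, g1: np.ndarray, g2: np.ndarray) -> np.ndarray:
    """Closed-form biparental transmission check on call codes.

    Offspring AA is impossible if either parent is BB (and vice versa);
    offspring AB is impossible only when both parents are homozygous for
    the same allele.
    """
    return np.where(
        go == 0,
        (g1 == 2) | (g2 == 2),
        np.where(
            go == 2,
            (g1 == 0) | (g2 == 0),
            np.where(
                go == 1,
                ((g1 == 0) & (g2 == 0)) | ((g1 == 2) & (g2 == 2)),
                False,
            ),
        ),
    )


def filter_mendelian(
    gm: GenotypeMatrix,
    relationships: RelationshipSet,
    max_error: float = 0.03,
) -> MendelianFilterResult:
    """Remove markers whose Mendelian error rate exceeds ``max_error``.

    The rate pools incompatible transmissions across all confirmed duos and
    trios over evaluable transmissions (all members called). Markers with no
    evaluable transmission are kept (rate undefined). An empty relationship
    set removes nothing and emits a warning.
    """
    if len(relationships) == 0:
        warnings.warn(
            "empty relationship set: no markers removed by Mendelian filter",
            stacklevel=2,
        )
        return MendelianFilterResult(
            kept=list(gm.marker_ids),
            removed=[],
            error_rates={m: None for m in gm.marker_ids},
        )
    err, ev = mendelian_error_rates(gm, relationships)
    with np.errstate(invalid="ignore", divide="ignore"):
        rate = np.where(ev > 0, err / np.maximum(ev, 1), np.nan)
    removed_mask = (ev > 0) & (rate > max_error)
    kept, removed, rates = [], [], {}
    for j, mid in enumerate(gm.marker_ids):
        rates[mid] = float(rate[j]) if ev[j] > 0 else None
        (removed if removed_mask[j] else kept).append(mid)
    return MendelianFilterResult(kept=kept, removed=removed, error_rates=rates)
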