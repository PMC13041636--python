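"""Chloroplast haplotype assignment and maternal-lineage verdicts.

The chloroplast genome is haploid and maternally inherited in grapevine, so
a handful of plastid SNPs define a chlorotype that every offspring must
share with its seed parent. On an array, plastid loci are reported as
homozygous diploid calls (AA/BB); a heterozygous plastid call is a technical
artifact (not heteroplasmy), so it is masked and counted per sample.

Haplotype labels (Type1..TypeK) are panel-relative, ordered by descending
frequency with lexicographic tie-break — mapping them to published
chlorotype letters is a user-supplied correspondence, never inferred.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import ConfigError
from .io import GenotypeMatrix

VERDICT_CONFIRMED = "confirmed"
VERDICT_INCONCLUSIVE = "inconclusive"
VERDICT_EXCLUDED = "excluded"
VERDICT_UNASSESSABLE = "unassessable"


@dataclass
class ChlorotypeAssignment:
    """Per-sample plastid haplotype and panel-relative type label.

    ``haplotype`` is a string over {A, B, N} (N = no-call or masked
    heterozygous call), one character per plastid marker in input order.
    ``type_label`` is None when the haplotype has a no-call at a
    discriminating (non-monomorphic) position.
    """

    sample_id: str
    haplotype: str
    type_label: str | None
    n_het_calls: int


@dataclass
class ChlorotypeResult:
    assignments: list[ChlorotypeAssignment]
    plastid_markers: list[str]
    #: type label -> full-length haplotype pattern (monomorphic positions
    #: filled with their panel consensus)
    type_haplotypes: dict[str, str]
    monomorphic_markers: list[str]
    discriminating_markers: list[str]

    def by_sample(self) -> dict[str, ChlorotypeAssignment]:
        return {a.sample_id: a for a in self.assignments}


def assign_chlorotypes(
    gm: GenotypeMatrix, plastid_markers: Sequence[str]
) -> ChlorotypeResult:
    """Build per-sample plastid haplotypes and label the distinct types.

    Homozygous calls map to the allele letter (AA -> A, BB -> B); AB is
    counted in ``n_het_calls`` and masked to N. Markers monomorphic across
    the called panel are reported as non-discriminating and ignored for
    typing; distinct complete haplotypes are labelled Type1..TypeK by
    descending panel frequency, ties broken lexicographically.
    """
    plastid_markers = list(plastid_markers)
    if not plastid_markers:
        raise ConfigError("empty plastid marker set")
    cols = [gm.marker_index(m) for m in plastid_markers]
    codes = gm.codes[:, cols]

    chars = np.full(codes.shape, "N", dtype="U1")
    chars[codes == 0] = "A"
    chars[codes == 2] = "B"
    n_het = (codes == 1).sum(axis=1)

    mono_mask = []
    for j in range(len(plastid_markers)):
        seen = set(chars[:, j]) - {"N"}
        mono_mask.append(len(seen) <= 1)
    mono_mask = np.asarray(mono_mask)
    discriminating = [m for m, mono in zip(plastid_markers, mono_mask) if not mono]
    monomorphic = [m for m, mono in zip(plastid_markers, mono_mask) if mono]

    disc_idx = np.flatnonzero(~mono_mask)
    keys = ["".join(row[disc_idx]) for row in chars]
    complete = ["N" not in k for k in keys]

    freq: dict[str, int] = {}
    for k, ok in zip(keys, complete):
        if ok:
            freq[k] = freq.get(k, 0) + 1
    ordered = sorted(freq, key=lambda k: (-freq[k], k))
    label_of = {k: f"Type{i + 1}" for i, k in enumerate(ordered)}

    # consensus character at monomorphic positions, for the full pattern
    consensus = []
    for j in range(len(plastid_markers)):
        seen = sorted(set(chars[:, j]) - {"N"})
        consensus.append(seen[0] if seen else "N")
    type_haplotypes = {}
    for k, label in label_of.items():
        full = list(consensus)
        for pos, j in enumerate(disc_idx):
            full[j] = k[pos]
        type_haplotypes[label] = "".join(full)

    assignments = [
        ChlorotypeAssignment(
            sample_id=sid,
            haplotype="".join(chars[i]),
            type_label=label_of[keys[i]] if complete[i] else None,
            n_het_calls=int(n_het[i]),
        )
        for i, sid in enumerate(gm.sample_ids)
    ]
    return ChlorotypeResult(
        assignments=assignments,
        plastid_markers=plastid_markers,
        type_haplotypes=type_haplotypes,
        monomorphic_markers=monomorphic,
        discriminating_markers=discriminating,
    )


def maternal_lineage(
    chlorotypes: ChlorotypeResult | Sequence[ChlorotypeAssignment],
    pedigree: pd.DataFrame,
) -> pd.DataFrame:
    """Maternal-lineage verdict for every offspring with two recorded parents.

    Verdicts:

    - ``confirmed``     parents carry different types and the offspring
      matches the recorded mother;
    - ``inconclusive``  both parents carry the same type (either could be
      the seed parent) and the offspring matches it;
    - ``excluded``      the offspring's type contradicts the recorded
      mother — either it matches only the recorded father (the parents'
      roles are inverted) or it matches neither parent;
    - ``unassessable``  the offspring or a parent has no assigned type.
    """
    if isinstance(chlorotypes, ChlorotypeResult):
        by_sample = chlorotypes.by_sample()
    else:
        by_sample = {a.sample_id: a for a in chlorotypes}

    rows = []
    for rec in pedigree.itertuples(index=False):
        mother, father = rec.mother_id or "", rec.father_id or ""
        if not mother or not father:
            continue
        o = by_sample.get(rec.sample_id)
        m = by_sample.get(mother)
        f = by_sample.get(father)
        to = o.type_label if o else None
        tm = m.type_label if m else None
        tf = f.type_label if f else None
        if to is None or tm is None or tf is None:
            verdict, candidate = VERDICT_UNASSESSABLE, ""
        elif tm == tf:
            if to == tm:
                verdict, candidate = VERDICT_INCONCLUSIVE, ""
            else:
                verdict, candidate = VERDICT_EXCLUDED, ""  # matches neither parent
        elif to == tm:
            verdict, candidate = VERDICT_CONFIRMED, mother
        elif to == tf:
            # recorded mother mismatches; the recorded father carries the type
            verdict, candidate = VERDICT_EXCLUDED, father
        else:
            verdict, candidate = VERDICT_EXCLUDED, ""
        rows.append(
            {
                "sample_id": rec.sample_id,
                "mother_id": mother,
                "father_id": father,
                "offspring_type": to or "",
                "mother_type": tm or "",
                "father_type": tf or "",
                "verdict": verdict,
                "maternal_candidate": candidate,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "sample_id",
            "mother_id",
            "father_id",
            "offspring_type",
            "mother_type",
            "father_type",
            "verdict",
            "maternal_candidate",
        ],
    )
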