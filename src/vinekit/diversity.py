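"""Panel-level diversity statistics, genotype PCA and platform concordance.

Observed heterozygosity per species summarizes how informative a marker set
is in each taxon: markers ascertained in one species are systematically less
polymorphic in divergent species (ascertainment bias), so wild clusters show
lower heterozygosity than the cultivated pool on a vinifera-heavy array.

The genotype PCA codes calls as B-allele dosage (0/1/2), mean-imputes
no-calls per marker, drops markers below a minor-allele-frequency floor
(default 0.05) and reports per-axis variance fractions with a fixed sign
convention (the marker with the largest |loading| is positive on each axis).

Cross-platform concordance compares two call matrices on shared markers,
discarding markers with a no-call on either platform for a sample. The
default "zygosity" mode scores agreement of the {hom, het} class, because
A/B allele assignment is platform-specific; "strict" mode requires exact
call identity after optional per-marker allele-swap harmonization.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ConfigError
from .io import GenotypeMatrix


@dataclass
class ConcordanceResult:
    sample_id: str
    n_shared_markers: int
    n_concordant: int
    concordance_perc: float
    evaluable: bool = True


def species_het_summary(
    gm: GenotypeMatrix, samples: pd.DataFrame, species_column: str = "species"
) -> pd.DataFrame:
    """Per-species accession count, observed-heterozygosity stats and mean
    call count. Species with zero samples in the matrix are omitted;
    rounding is left to presentation."""
    if species_column not in samples.columns:
        raise ConfigError(f"sample metadata lacks column {species_column!r}")
    called = gm.codes >= 0
    n_called = called.sum(axis=1)
    n_het = (gm.codes == 1).sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        het = np.where(n_called > 0, n_het / np.maximum(n_called, 1), np.nan)
    per_sample = pd.DataFrame(
        {
            "sample_id": gm.sample_ids,
            "observed_heterozygosity": het,
            "call_count": n_called,
        }
    )
    merged = per_sample.merge(
        samples[["sample_id", species_column]], on="sample_id", how="inner"
    )
    rows = []
    for sp, grp in merged.groupby(species_column, sort=True):
        rows.append(
            {
                "species": sp,
                "n_accessions": len(grp),
                "het_mean": grp["observed_heterozygosity"].mean(),
                "het_min": grp["observed_heterozygosity"].min(),
                "het_max": grp["observed_heterozygosity"].max(),
                "call_count_mean": grp["call_count"].mean(),
            }
        )
    return pd.DataFrame(
        rows,
        columns=["species", "n_accessions", "het_mean", "het_min", "het_max", "call_count_mean"],
    )


@dataclass
class GenotypeOrdination:
    coordinates: pd.DataFrame
    explained_variance_ratio: np.ndarray
    n_markers_used: int


def genotype_pca(
    gm: GenotypeMatrix,
    maf_floor: float = 0.05,
    n_components: int = 10,
    standardize: bool = False,
) -> GenotypeOrdination:
    """PCA of the 0/1/2 dosage matrix after MAF filtering.

    No-calls are mean-imputed per marker (the common PLINK-style practice,
    keeping small panels intact); columns are centered and optionally
    standardized. Variance fractions are relative to the total variance of
    the centered matrix, so they are non-increasing and sum to <= 1.
    """
    dosage = gm.dosage()
    with np.errstate(invalid="ignore"):
        p_b = np.nanmean(dosage, axis=0) / 2.0
    maf = np.minimum(p_b, 1.0 - p_b)
    keep = np.flatnonzero(~np.isnan(maf) & (maf >= maf_floor))
    if keep.size == 0:
        raise ConfigError(f"no markers survive the MAF floor {maf_floor}")
    X = dosage[:, keep]
    col_mean = np.nanmean(X, axis=0)
    nan_r, nan_c = np.nonzero(np.isnan(X))
    X[nan_r, nan_c] = col_mean[nan_c]
    X = X - col_mean
    if standardize:
        sd = X.std(axis=0, ddof=0)
        sd[sd == 0] = 1.0
        X = X / sd
    total_var = float((X**2).sum())
    k = min(n_components, min(X.shape) - 1) if min(X.shape) > 1 else 1
    U, s, Vt = np.linalg.svd(X, full_matrices=False)
    U, s, Vt = U[:, :k], s[:k], Vt[:k]
    # sign convention: largest-|loading| marker positive on each axis
    for i in range(k):
        j = int(np.argmax(np.abs(Vt[i])))
        if Vt[i, j] < 0:
            Vt[i] = -Vt[i]
            U[:, i] = -U[:, i]
    coords = U * s
    ratio = (s**2) / total_var if total_var > 0 else np.zeros(k)
    out = pd.DataFrame(
        coords, index=gm.sample_ids, columns=[f"PC{i + 1}" for i in range(k)]
    )
    out.insert(0, "sample_id", gm.sample_ids)
    return GenotypeOrdination(
        coordinates=out.reset_index(drop=True),
        explained_variance_ratio=ratio,
        n_markers_used=int(keep.size),
    )


def _aligned_codes(
    gm_a: GenotypeMatrix,
    gm_b: GenotypeMatrix,
    shared_markers: pd.DataFrame | list | None,
) -> tuple[list[str], np.ndarray, np.ndarray]:
    if shared_markers is None:
        ids = [m for m in gm_a.marker_ids if m in set(gm_b.marker_ids)]
        pairs = [(m, m) for m in ids]
    elif isinstance(shared_markers, pd.DataFrame):
        pairs = list(zip(shared_markers.iloc[:, 0], shared_markers.iloc[:, 1]))
    else:
        pairs = [(m, m) if isinstance(m, str) else tuple(m) for m in shared_markers]
    if not pairs:
        raise ConfigError("no shared markers between the two platforms")
    samples = [s for s in gm_a.sample_ids if s in set(gm_b.sample_ids)]
    if not samples:
        raise ConfigError("no shared samples between the two platforms")
    ai = [gm_a.marker_index(a) for a, _ in pairs]
    bi = [gm_b.marker_index(b) for _, b in pairs]
    ra = [gm_a.sample_index(s) for s in samples]
    rb = [gm_b.sample_index(s) for s in samples]
    return samples, gm_a.codes[np.ix_(ra, ai)], gm_b.codes[np.ix_(rb, bi)]


def platform_concordance(
    gm_a: GenotypeMatrix,
    gm_b: GenotypeMatrix,
    shared_markers: pd.DataFrame | list | None = None,
    mode: str = "zygosity",
    harmonize: bool = True,
) -> list[ConcordanceResult]:
    """Per-sample concordance between two genotyping platforms.

    ``shared_markers`` maps marker ids across platforms (two-column frame
    id_a,id_b; a plain list of common ids; or None for the id
    intersection). Markers with a no-call on either platform are discarded
    per sample. ``mode="zygosity"`` scores {hom, het} class agreement;
    ``mode="strict"`` requires identical calls, after per-marker allele-swap
    harmonization when ``harmonize`` (a marker whose A/B labels are swapped
    on one platform is flipped if that strictly increases call agreement).
    """
    if mode not in ("zygosity", "strict"):
        raise ConfigError(f"unknown concordance mode {mode!r}")
    samples, A, B = _aligned_codes(gm_a, gm_b, shared_markers)
    both = (A >= 0) & (B >= 0)
    if mode == "strict" and harmonize:
        swapped = np.where(B >= 0, 2 - B, B)  # hom flip, het fixed point
        agree = ((A == B) & both).sum(axis=0)
        agree_sw = ((A == swapped) & both).sum(axis=0)
        B = np.where((agree_sw > agree)[None, :], swapped, B)
    if mode == "zygosity":
        conc = (A == 1) == (B == 1)
    else:
        conc = A == B
    out = []
    for i, sid in enumerate(samples):
        n = int(both[i].sum())
        c = int((conc[i] & both[i]).sum())
        if n == 0:
            out.append(ConcordanceResult(sid, 0, 0, 0.0, evaluable=False))
        else:
            out.append(ConcordanceResult(sid, n, c, 100.0 * c / n))
    return out
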