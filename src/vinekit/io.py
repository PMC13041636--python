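"""Readers and writers for the external representations.

Central object: :class:`GenotypeMatrix`, a dense samples x markers table of
diploid biallelic calls in {AA, AB, BB, NC} stored internally as int8 codes
(NC=-1, AA=0, AB=1, BB=2 — the same numbering used by Axiom Analysis Suite
numeric exports, with the no-call mapped to -1). Genotype tables on disk are
tab-separated, either marker-major (AxAS "Genotype - Export" style, the
default) or sample-major, with letter or numeric call coding; both axes of
variability are captured by :class:`GenotypeDialect`.

Metadata (samples, markers, pedigree) travels as CSV and is returned as
pandas DataFrames; the :class:`SampleRecord` / :class:`MarkerRecord`
dataclasses define and validate the row vocabulary.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .design import CandidateVariant
from .errors import ConfigError, FormatError

# Call coding ----------------------------------------------------------------

NC, AA, AB, BB = -1, 0, 1, 2

CODE_TO_CALL = {NC: "NC", AA: "AA", AB: "AB", BB: "BB"}
CALL_TO_CODE = {
    "AA": AA,
    "AB": AB,
    "BA": AB,
    "BB": BB,
    "NC": NC,
    "NOCALL": NC,
    "---": NC,
}
NUMERIC_TO_CODE = {"-1": NC, "0": AA, "1": AB, "2": BB}

_MARKER_HEADER_KEYWORDS = {"probeset_id", "marker_id", "marker", "markers", "snp_id"}
_SAMPLE_HEADER_KEYWORDS = {"sample_id", "sample", "samples", "accession"}


class GenotypeMatrix:
    """Samples x markers table of categorical diploid calls.

    Parameters
    ----------
    sample_ids, marker_ids
        Ordered, duplicate-free identifier lists.
    codes
        int8 array of shape (n_samples, n_markers) over {-1, 0, 1, 2}.
    """

    def __init__(
        self,
        sample_ids: Sequence[str],
        marker_ids: Sequence[str],
        codes: np.ndarray,
    ) -> None:
        self.sample_ids = [str(s) for s in sample_ids]
        self.marker_ids = [str(m) for m in marker_ids]
        codes = np.asarray(codes, dtype=np.int8)
        if codes.shape != (len(self.sample_ids), len(self.marker_ids)):
            raise FormatError(
                f"calls shape {codes.shape} does not match "
                f"({len(self.sample_ids)} samples, {len(self.marker_ids)} markers)"
            )
        if codes.size and (codes.min() < -1 or codes.max() > 2):
            bad = np.argwhere((codes < -1) | (codes > 2))[0]
            raise FormatError(
                f"invalid call code at sample {self.sample_ids[bad[0]]!r}, "
                f"marker {self.marker_ids[bad[1]]!r}"
            )
        for name, ids in (("sample", self.sample_ids), ("marker", self.marker_ids)):
            if len(set(ids)) != len(ids):
                seen: set[str] = set()
                dup = next(i for i in ids if i in seen or seen.add(i))
                raise FormatError(f"duplicate {name} identifier {dup!r}")
        self.codes = codes
        self._sample_index = {s: i for i, s in enumerate(self.sample_ids)}
        self._marker_index = {m: j for j, m in enumerate(self.marker_ids)}

    # -- basic protocol ------------------------------------------------

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_markers(self) -> int:
        return len(self.marker_ids)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GenotypeMatrix):
            return NotImplemented
        return (
            self.sample_ids == other.sample_ids
            and self.marker_ids == other.marker_ids
            and np.array_equal(self.codes, other.codes)
        )

    def __repr__(self) -> str:
        return f"GenotypeMatrix({self.n_samples} samples x {self.n_markers} markers)"

    # -- accessors -------------------------------------------------------

    def sample_index(self, sample_id: str) -> int:
        try:
            return self._sample_index[sample_id]
        except KeyError:
            raise KeyError(f"unknown sample {sample_id!r}") from None

    def marker_index(self, marker_id: str) -> int:
        try:
            return self._marker_index[marker_id]
        except KeyError:
            raise KeyError(f"unknown marker {marker_id!r}") from None

    def sample_calls(self, sample_id: str) -> np.ndarray:
        """Call codes of one sample across all markers."""
        return self.codes[self.sample_index(sample_id)]

    def marker_calls(self, marker_id: str) -> np.ndarray:
        """Call codes of one marker across all samples."""
        return self.codes[:, self.marker_index(marker_id)]

    def subset(
        self,
        samples: Sequence[str] | None = None,
        markers: Sequence[str] | None = None,
    ) -> "GenotypeMatrix":
        rows = (
            [self.sample_index(s) for s in samples]
            if samples is not None
            else slice(None)
        )
        cols = (
            [self.marker_index(m) for m in markers]
            if markers is not None
            else slice(None)
        )
        sub = self.codes[rows][:, cols] if markers is not None else self.codes[rows]
        return GenotypeMatrix(
            list(samples) if samples is not None else list(self.sample_ids),
            list(markers) if markers is not None else list(self.marker_ids),
            sub.copy(),
        )

    def drop_markers(self, marker_ids: Sequence[str]) -> "GenotypeMatrix":
        drop = set(marker_ids)
        keep = [m for m in self.marker_ids if m not in drop]
        return self.subset(markers=keep)

    def copy(self) -> "GenotypeMatrix":
        return GenotypeMatrix(list(self.sample_ids), list(self.marker_ids), self.codes.copy())

    # -- conversions -----------------------------------------------------

    @classmethod
    def from_calls(cls, calls: pd.DataFrame) -> "GenotypeMatrix":
        """Build from a samples x markers DataFrame of letter calls."""
        arr = calls.to_numpy(dtype=object)
        codes = np.empty(arr.shape, dtype=np.int8)
        for (i, j), val in np.ndenumerate(arr):
            try:
                codes[i, j] = CALL_TO_CODE[str(val).upper()]
            except KeyError:
                raise FormatError(
                    f"unknown call {val!r} at sample {calls.index[i]!r}, "
                    f"marker {calls.columns[j]!r}"
                ) from None
        return cls(list(calls.index), list(calls.columns), codes)

    def to_calls(self) -> pd.DataFrame:
        """Samples x markers DataFrame of letter calls (AA/AB/BB/NC)."""
        lut = np.array(["NC", "AA", "AB", "BB"], dtype=object)
        return pd.DataFrame(
            lut[self.codes + 1], index=self.sample_ids, columns=self.marker_ids
        )

    def dosage(self) -> np.ndarray:
        """Float B-allele dosage (0/1/2) with NC as NaN."""
        d = self.codes.astype(float)
        d[d < 0] = np.nan
        return d


@dataclass(frozen=True)
class GenotypeDialect:
    """How a genotype table is laid out on disk.

    ``coding``: "letters" (AA/AB/BB/NC), "numeric" (-1/0/1/2) or "auto".
    ``orientation``: "markers_rows" (AxAS export style, the default),
    "samples_rows", or "auto" (detected from the header keyword).
    """

    coding: str = "auto"
    orientation: str = "auto"
    sep: str = "\t"

    def __post_init__(self) -> None:
        if self.coding not in ("auto", "letters", "numeric"):
            raise ConfigError(f"unknown coding {self.coding!r}")
        if self.orientation not in ("auto", "markers_rows", "samples_rows"):
            raise ConfigError(f"unknown orientation {self.orientation!r}")


def read_genotype_matrix(
    path: str | Path, dialect: GenotypeDialect | None = None
) -> GenotypeMatrix:
    """Read a genotype-call table, normalizing to samples x markers.

    Numeric call codes (-1/0/1/2) map to (NC/AA/AB/BB); marker-major files
    are transposed. Unknown call symbols and duplicate identifiers raise
    :class:`FormatError` naming the offending row/column.
    """
    d = dialect or GenotypeDialect()
    df = pd.read_csv(path, sep=d.sep, index_col=0, dtype=str)
    index_name = (df.index.name or "").strip().lower()

    orientation = d.orientation
    if orientation == "auto":
        if index_name in _SAMPLE_HEADER_KEYWORDS:
            orientation = "samples_rows"
        elif index_name in _MARKER_HEADER_KEYWORDS:
            orientation = "markers_rows"
        else:
            orientation = "markers_rows"
    if orientation == "markers_rows":
        df = df.T  # normalize to samples x markers

    coding = d.coding
    if coding == "auto":
        tokens = {str(t).upper() for t in pd.unique(df.to_numpy().ravel())}
        coding = "numeric" if tokens <= set(NUMERIC_TO_CODE) else "letters"

    table = NUMERIC_TO_CODE if coding == "numeric" else CALL_TO_CODE
    arr = df.to_numpy(dtype=object)
    codes = np.empty(arr.shape, dtype=np.int8)
    for (i, j), val in np.ndenumerate(arr):
        key = str(val).strip()
        if coding == "letters":
            key = key.upper()
        if key not in table:
            raise FormatError(
                f"unknown call code {val!r} at row {df.index[i]!r}, "
                f"column {df.columns[j]!r} in {path}"
            )
        codes[i, j] = table[key]
    return GenotypeMatrix(list(df.index), list(df.columns), codes)


def write_genotype_matrix(
    gm: GenotypeMatrix, path: str | Path, dialect: GenotypeDialect | None = None
) -> Path:
    """Write a genotype table; default is marker-major with letter calls."""
    d = dialect or GenotypeDialect(coding="letters", orientation="markers_rows")
    coding = "letters" if d.coding == "auto" else d.coding
    orientation = "markers_rows" if d.orientation == "auto" else d.orientation
    if coding == "letters":
        df = gm.to_calls()
    else:
        df = pd.DataFrame(
            gm.codes.astype(int), index=gm.sample_ids, columns=gm.marker_ids
        )
    if orientation == "markers_rows":
        df = df.T
        df.index.name = "probeset_id"
    else:
        df.index.name = "sample_id"
    path = Path(path)
    df.to_csv(path, sep=d.sep)
    return path


# Metadata records ------------------------------------------------------------

MARKER_SOURCES = ("prior_chip", "trait_candidate", "resequencing")

FLOWER_SEX_CLASSES = ("female", "hermaphrodite", "male")
SEED_CLASSES = ("complete", "none")
TASTE_CLASSES = ("foxy", "herbaceous", "muscat", "muscat-like aromatic", "none")
#: OIV descriptor 225 codes used in the panel phenotyping (1 green-yellow,
#: 2 rose, 5 dark red violet, 6 blue-black).
BERRY_COLOR_OIV_CODES = (1, 2, 3, 4, 5, 6)

TAXON_CLASSES = (
    "V. vinifera ssp. sativa",
    "V. vinifera ssp. sylvestris",
    "non-vinifera",
    "Vitis hybrid",
    "Vitis complex hybrid",
)

SAMPLE_METADATA_COLUMNS = [
    "sample_id",
    "species",
    "taxon_class",
    "mother_id",
    "father_id",
    "flower_sex",
    "seed_development",
    "berry_color_oiv",
    "berry_taste",
]
MARKER_METADATA_COLUMNS = [
    "marker_id",
    "chromosome",
    "position",
    "source",
    "species_of_origin",
    "is_plastid",
    "trait_annotation",
]
PEDIGREE_COLUMNS = ["sample_id", "mother_id", "father_id"]


@dataclass
class MarkerRecord:
    """Descriptive metadata of one array marker."""

    marker_id: str
    chromosome: str
    position: int
    source: str = "resequencing"
    species_of_origin: str = ""
    is_plastid: bool = False
    trait_annotation: str = ""

    def __post_init__(self) -> None:
        if self.position < 1:
            raise ConfigError(f"position must be >= 1, got {self.position}")
        if self.source not in MARKER_SOURCES:
            raise ConfigError(f"unknown marker source {self.source!r}")


@dataclass
class SampleRecord:
    """One panel accession: taxonomy, pedigree links and phenotypes.

    Unknown parents are the empty string — "unknown" is never a sample id.
    """

    sample_id: str
    species: str = ""
    taxon_class: str = ""
    mother_id: str = ""
    father_id: str = ""
    phenotypes: dict[str, object] = field(default_factory=dict)

    def __post_init__(self) -> None:
        sex = self.phenotypes.get("flower_sex")
        if sex is not None and sex not in FLOWER_SEX_CLASSES:
            raise ConfigError(f"unknown flower sex class {sex!r}")
        seed = self.phenotypes.get("seed_development")
        if seed is not None and seed not in SEED_CLASSES:
            raise ConfigError(f"unknown seed development class {seed!r}")
        taste = self.phenotypes.get("berry_taste")
        if taste is not None and taste not in TASTE_CLASSES:
            raise ConfigError(f"unknown berry taste class {taste!r}")
        color = self.phenotypes.get("berry_color_oiv")
        if color is not None and int(color) not in BERRY_COLOR_OIV_CODES:
            raise ConfigError(f"unknown OIV-225 code {color!r}")


def read_sample_metadata(path: str | Path) -> pd.DataFrame:
    """Sample metadata CSV -> DataFrame (missing parents become "")."""
    df = pd.read_csv(path, dtype={"sample_id": str})
    missing = [c for c in ("sample_id",) if c not in df.columns]
    if missing:
        raise FormatError(f"sample metadata lacks column(s) {missing} in {path}")
    for col in ("mother_id", "father_id"):
        if col in df.columns:
            df[col] = df[col].fillna("").astype(str)
    if df["sample_id"].duplicated().any():
        dup = df["sample_id"][df["sample_id"].duplicated()].iloc[0]
        raise FormatError(f"duplicate sample_id {dup!r} in {path}")
    return df


def read_marker_metadata(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"marker_id": str, "chromosome": str})
    if "marker_id" not in df.columns:
        raise FormatError(f"marker metadata lacks 'marker_id' in {path}")
    if df["marker_id"].duplicated().any():
        dup = df["marker_id"][df["marker_id"].duplicated()].iloc[0]
        raise FormatError(f"duplicate marker_id {dup!r} in {path}")
    return df


def read_pedigree(path: str | Path) -> pd.DataFrame:
    """Pedigree CSV (sample_id, mother_id, father_id); "" = unknown parent."""
    df = pd.read_csv(path, dtype=str)
    missing = [c for c in PEDIGREE_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"pedigree lacks column(s) {missing} in {path}")
    df = df[PEDIGREE_COLUMNS].copy()
    for col in ("mother_id", "father_id"):
        df[col] = df[col].fillna("").astype(str)
    return df


def write_report_tables(
    results: Mapping[str, pd.DataFrame], out_dir: str | Path
) -> list[Path]:
    """Write result tables as CSV with deterministic row/column order.

    Rows are sorted by the leading (identifier) column(s); the same inputs
    always produce byte-identical files. Empty tables yield header-only CSVs.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    for name in sorted(results):
        df = results[name]
        if len(df.columns) and len(df):
            id_cols = [df.columns[0]]
            if len(df.columns) > 1 and str(df.columns[1]).endswith(("_id", "_b")):
                id_cols.append(df.columns[1])
            df = df.sort_values(id_cols, kind="stable")
        path = out / f"{name}.csv"
        df.to_csv(path, index=False, lineterminator="\n")
        written.append(path)
    return written


# VCF -------------------------------------------------------------------------


def read_candidate_vcf(path: str | Path) -> list[CandidateVariant]:
    """Read candidate variants from a VCF 4.x file.

    One :class:`~vinekit.design.CandidateVariant` per record, carrying QUAL
    (``None`` when the file has ``.``), per-sample DP and called/missing
    status, and all alternate alleles — multiallelic records are preserved;
    filtering happens downstream. Optional INFO tags ``SPECIES`` and
    ``SCORE`` populate the species-of-origin and recommendation score.
    """
    from cyvcf2 import VCF

    path = str(path)
    try:
        vcf = VCF(path, gts012=True)
    except Exception as exc:  # cyvcf2 raises bare exceptions on bad files
        raise FormatError(f"cannot parse VCF {path}: {exc}") from exc
    if "##FORMAT=<ID=GT" not in vcf.raw_header:
        raise FormatError(f"VCF {path} defines no GT FORMAT field")
    n = len(vcf.samples)
    if n == 0:
        raise FormatError(f"VCF {path} carries no sample columns")

    out: list[CandidateVariant] = []
    for v in vcf:
        if v.POS < 1:
            raise FormatError(f"malformed coordinate {v.CHROM}:{v.POS} in {path}")
        gt_types = v.gt_types  # gts012: 0/1/2 called, 3 unknown
        called = tuple(bool(t != 3) for t in gt_types)
        dp = v.format("DP")
        if dp is None:
            depths: tuple[int | None, ...] = (None,) * n
        else:
            col = dp[:, 0]
            depths = tuple(None if d < 0 else int(d) for d in col)
        score = v.INFO.get("SCORE")
        out.append(
            CandidateVariant(
                chromosome=v.CHROM,
                position=int(v.POS),
                ref_allele=v.REF,
                alt_alleles=tuple(v.ALT),
                quality=None if v.QUAL is None else float(v.QUAL),
                per_sample_depth=depths,
                per_sample_called=called,
                missing_fraction=float(np.mean([not c for c in called])),
                species_of_origin=str(v.INFO.get("SPECIES") or ""),
                score=None if score is None else float(score),
                marker_id=v.ID or f"{v.CHROM}:{v.POS}",
            )
        )
    return out
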