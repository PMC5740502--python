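"""Tabular interchange formats for metagenomic SNV subspecies analysis.

This module defines the in-memory containers shared by the rest of the
package and the readers/writers for their on-disk TSV dialects:

* :class:`FrequencyTable` — variant positions x samples, non-reference
  allele frequencies (metaSNV-style: row id ``species:contig:pos:ref>alt``,
  missing values encoded as ``-1`` on disk, `numpy.nan` in memory).
* :class:`CoverageSummary` — per (sample, species) vertical (mean depth)
  and horizontal (breadth) coverage.
* :class:`AbundanceTable` — taxa (species, subspecies or genes) x samples
  relative abundances.
* :class:`SampleMetadata` — subject, time point, country, study and
  phenotype columns per sample.
* model (de)serialization for fitted subspecies models, as a single JSON
  document with a schema version.

All readers accept gzip-compressed input (pandas infers compression from
the file name). Coordinates are 1-based and fully closed, as in VCF.
"""

from __future__ import annotations

import gzip
import json
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "PositionKey",
    "FrequencyTable",
    "CoverageSummary",
    "AbundanceTable",
    "SampleMetadata",
    "FormatError",
    "read_frequency_table",
    "write_frequency_table",
    "read_coverage_summary",
    "write_coverage_summary",
    "read_abundance_table",
    "write_abundance_table",
    "read_sample_metadata",
    "write_sample_metadata",
    "read_model",
    "write_model",
    "MODEL_SCHEMA_VERSION",
]

MODEL_SCHEMA_VERSION = 1

#: disk sentinel for a position without sufficient coverage in a sample
MISSING_SENTINEL = -1.0

_ROW_ID_RE = re.compile(
    r"^(?P<species>[^:]+):(?P<contig>[^:]+):(?P<pos>\d+):"
    r"(?P<ref>[ACGTacgt])>(?P<alt>[ACGTacgt])$"
)


class FormatError(ValueError):
    """Raised on malformed or invalid interchange files."""


@dataclass(frozen=True, order=True)
class PositionKey:
    """A variant position against a species' representative genome."""

    species_id: str
    contig_id: str
    position: int
    ref_allele: str
    alt_allele: str

    def __post_init__(self) -> None:
        if self.position < 1:
            raise FormatError(f"position must be >= 1, got {self.position}")
        if self.ref_allele == self.alt_allele:
            raise FormatError(
                f"ref and alt allele identical at {self.contig_id}:{self.position}"
            )

    def __str__(self) -> str:
        return (
            f"{self.species_id}:{self.contig_id}:{self.position}:"
            f"{self.ref_allele}>{self.alt_allele}"
        )

    @classmethod
    def parse(cls, row_id: str) -> "PositionKey":
        m = _ROW_ID_RE.match(row_id)
        if m is None:
            raise FormatError(
                f"malformed position id {row_id!r}; expected "
                "'species:contig:pos:ref>alt'"
            )
        return cls(
            species_id=m.group("species"),
            contig_id=m.group("contig"),
            position=int(m.group("pos")),
            ref_allele=m.group("ref").upper(),
            alt_allele=m.group("alt").upper(),
        )


@dataclass
class FrequencyTable:
    """Non-reference allele frequencies at variant positions across samples.

    ``freq`` is a (positions x samples) float array with values in [0, 1]
    or NaN for missing (position not sufficiently covered in that sample).
    ``depth`` is an optional aligned integer read-depth matrix.
    """

    positions: list[PositionKey]
    samples: list[str]
    freq: np.ndarray
    depth: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.freq = np.asarray(self.freq, dtype=float)
        if self.freq.shape != (len(self.positions), len(self.samples)):
            raise FormatError(
                f"freq shape {self.freq.shape} does not match "
                f"{len(self.positions)} positions x {len(self.samples)} samples"
            )
        if len(set(self.samples)) != len(self.samples):
            raise FormatError("sample identifiers are not unique")
        if len(set(self.positions)) != len(self.positions):
            raise FormatError("position keys are not unique")
        with np.errstate(invalid="ignore"):
            bad = (self.freq < 0) | (self.freq > 1)
        if bad.any():
            raise FormatError("frequencies outside [0, 1] present")
        if self.depth is not None:
            self.depth = np.asarray(self.depth)
            if self.depth.shape != self.freq.shape:
                raise FormatError("depth matrix shape differs from freq")
            if (self.depth < 0).any():
                raise FormatError("negative read depth present")

    @property
    def n_positions(self) -> int:
        return len(self.positions)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    def species_ids(self) -> list[str]:
        seen: dict[str, None] = {}
        for p in self.positions:
            seen.setdefault(p.species_id, None)
        return list(seen)

    def restrict_species(self, species_id: str) -> "FrequencyTable":
        keep = [i for i, p in enumerate(self.positions) if p.species_id == species_id]
        return self.subset(position_idx=keep)

    def subset(
        self,
        position_idx: Sequence[int] | None = None,
        sample_ids: Sequence[str] | None = None,
    ) -> "FrequencyTable":
        pos_idx = (
            np.arange(self.n_positions)
            if position_idx is None
            else np.asarray(position_idx, dtype=int)
        )
        if sample_ids is None:
            samp_idx = np.arange(self.n_samples)
            samples = list(self.samples)
        else:
            lookup = {s: j for j, s in enumerate(self.samples)}
            missing = [s for s in sample_ids if s not in lookup]
            if missing:
                raise FormatError(f"samples not in table: {missing}")
            samp_idx = np.asarray([lookup[s] for s in sample_ids], dtype=int)
            samples = list(sample_ids)
        return FrequencyTable(
            positions=[self.positions[i] for i in pos_idx],
            samples=samples,
            freq=self.freq[np.ix_(pos_idx, samp_idx)],
            depth=None if self.depth is None else self.depth[np.ix_(pos_idx, samp_idx)],
        )

    def sample_vector(self, sample_id: str) -> np.ndarray:
        return self.freq[:, self.samples.index(sample_id)]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.freq, index=[str(p) for p in self.positions], columns=self.samples
        )

    def equals(self, other: "FrequencyTable") -> bool:
        if self.positions != other.positions or self.samples != other.samples:
            return False
        if not np.allclose(self.freq, other.freq, equal_nan=True, atol=1e-12):
            return False
        if (self.depth is None) != (other.depth is None):
            return False
        if self.depth is not None and not np.array_equal(self.depth, other.depth):
            return False
        return True


@dataclass
class CoverageSummary:
    """Per-(sample, species) vertical depth and horizontal breadth."""

    table: pd.DataFrame  # columns: sample_id, species_id, vertical, horizontal

    REQUIRED = ("sample_id", "species_id", "vertical", "horizontal")

    def __post_init__(self) -> None:
        df = pd.DataFrame(self.table)
        missing = [c for c in self.REQUIRED if c not in df.columns]
        if missing:
            raise FormatError(f"coverage summary missing columns: {missing}")
        df = df.loc[:, list(self.REQUIRED)].reset_index(drop=True)
        if (df["vertical"] < 0).any():
            raise FormatError("negative vertical coverage")
        if ((df["horizontal"] < 0) | (df["horizontal"] > 1)).any():
            raise FormatError("horizontal coverage outside [0, 1]")
        dup = df.duplicated(subset=["sample_id", "species_id"])
        if dup.any():
            pairs = df.loc[dup, ["sample_id", "species_id"]].values.tolist()
            raise FormatError(f"duplicate (sample, species) rows: {pairs}")
        self.table = df

    def for_species(self, species_id: str) -> pd.DataFrame:
        return self.table[self.table["species_id"] == species_id]

    def species_ids(self) -> list[str]:
        return list(dict.fromkeys(self.table["species_id"]))


@dataclass
class AbundanceTable:
    """Relative abundances of taxa (species, subspecies or genes) x samples."""

    table: pd.DataFrame  # index: taxa ids, columns: samples

    def __post_init__(self) -> None:
        df = pd.DataFrame(self.table)
        if df.index.has_duplicates:
            raise FormatError("duplicate taxa identifiers")
        if (df.to_numpy(dtype=float) < 0).any():
            raise FormatError("negative abundances present")
        self.table = df.astype(float)

    @property
    def taxa(self) -> list[str]:
        return list(self.table.index)

    @property
    def samples(self) -> list[str]:
        return list(self.table.columns)

    def abundance(self, taxon: str, sample: str) -> float:
        return float(self.table.at[taxon, sample])


@dataclass
class SampleMetadata:
    """Per-sample subject, time and phenotype annotations.

    Required columns: sample_id, subject_id, collection_day, country,
    study.  Any further columns are treated as phenotypes and may contain
    missing values.
    """

    table: pd.DataFrame

    REQUIRED = ("sample_id", "subject_id", "collection_day", "country", "study")

    def __post_init__(self) -> None:
        df = pd.DataFrame(self.table).reset_index(drop=True)
        missing = [c for c in self.REQUIRED if c not in df.columns]
        if missing:
            raise FormatError(f"sample metadata missing columns: {missing}")
        if df["sample_id"].duplicated().any():
            dups = df.loc[df["sample_id"].duplicated(), "sample_id"].tolist()
            raise FormatError(f"duplicate sample_id values: {dups}")
        self.table = df

    @property
    def samples(self) -> list[str]:
        return list(self.table["sample_id"])

    def row(self, sample_id: str) -> pd.Series:
        sub = self.table[self.table["sample_id"] == sample_id]
        if sub.empty:
            raise KeyError(sample_id)
        return sub.iloc[0]

    def phenotype_columns(self) -> list[str]:
        return [c for c in self.table.columns if c not in self.REQUIRED]


# ---------------------------------------------------------------------------
# frequency table I/O


def read_frequency_table(
    path: str | Path,
    scale_hint: str = "auto",
    depth_path: str | Path | None = None,
) -> FrequencyTable:
    """Read a metaSNV-style allele-frequency TSV.

    Row ids are ``species:contig:pos:ref>alt``; the header row holds sample
    ids; ``-1`` marks a missing value.  ``scale_hint`` is one of ``auto``
    (divide by 100 when any value exceeds 1), ``fraction`` or ``percent``.
    """
    if scale_hint not in ("auto", "fraction", "percent"):
        raise ValueError(f"unknown scale_hint {scale_hint!r}")
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    positions = []
    for lineno, row_id in enumerate(df.index, start=2):
        try:
            positions.append(PositionKey.parse(str(row_id)))
        except FormatError as exc:
            raise FormatError(f"{path}, line {lineno}: {exc}") from exc
    try:
        values = df.to_numpy(dtype=float)
    except ValueError as exc:
        raise FormatError(f"{path}: non-numeric frequency value ({exc})") from exc
    with np.errstate(invalid="ignore"):
        if ((values < MISSING_SENTINEL) | (values > 100)).any():
            raise FormatError(f"{path}: frequency values outside [-1, 100]")
        missing = values == MISSING_SENTINEL
        if ((values < 0) & ~missing).any():
            raise FormatError(f"{path}: negative non-sentinel frequency values")
    values = values.copy()
    values[missing] = np.nan
    finite = values[~np.isnan(values)]
    if scale_hint == "percent" or (
        scale_hint == "auto" and finite.size and np.nanmax(finite) > 1.0
    ):
        values = values / 100.0
    with np.errstate(invalid="ignore"):
        if ((values < 0) | (values > 1)).any():
            raise FormatError(f"{path}: frequencies outside [0, 1] after scaling")
    depth = None
    if depth_path is not None:
        ddf = pd.read_csv(depth_path, sep="\t", index_col=0)
        if list(ddf.index) != list(df.index) or list(ddf.columns) != list(df.columns):
            raise FormatError("depth table rows/columns do not match frequency table")
        depth = ddf.to_numpy(dtype=int)
    return FrequencyTable(
        positions=positions, samples=list(df.columns), freq=values, depth=depth
    )


def write_frequency_table(
    ft: FrequencyTable,
    path: str | Path,
    depth_path: str | Path | None = None,
) -> None:
    """Write a :class:`FrequencyTable` on fraction scale; NaN becomes -1."""
    values = ft.freq.copy()
    values[np.isnan(values)] = MISSING_SENTINEL
    df = pd.DataFrame(values, index=[str(p) for p in ft.positions], columns=ft.samples)
    df.to_csv(path, sep="\t", float_format="%.10g")
    if depth_path is not None:
        if ft.depth is None:
            raise FormatError("table has no depth matrix to write")
        pd.DataFrame(
            ft.depth, index=[str(p) for p in ft.positions], columns=ft.samples
        ).to_csv(depth_path, sep="\t")


# ---------------------------------------------------------------------------
# coverage / abundance / metadata I/O


def read_coverage_summary(path: str | Path) -> CoverageSummary:
    df = pd.read_csv(path, sep="\t")
    rename = {"sample": "sample_id", "species": "species_id"}
    df = df.rename(columns=rename)
    return CoverageSummary(df)


def write_coverage_summary(cov: CoverageSummary, path: str | Path) -> None:
    cov.table.to_csv(path, sep="\t", index=False)


def read_abundance_table(path: str | Path) -> AbundanceTable:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return AbundanceTable(df)


def write_abundance_table(tab: AbundanceTable, path: str | Path) -> None:
    tab.table.to_csv(path, sep="\t")


def read_sample_metadata(path: str | Path) -> SampleMetadata:
    df = pd.read_csv(path, sep="\t")
    return SampleMetadata(df)


def write_sample_metadata(meta: SampleMetadata, path: str | Path) -> None:
    meta.table.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# model serialization


def _open_text(path: str | Path, mode: str):
    p = Path(path)
    if p.suffix == ".gz":
        return gzip.open(p, mode + "t")
    return open(p, mode)


def write_model(model, path: str | Path) -> None:
    """Serialize a fitted subspecies model to a versioned JSON document."""
    doc = {"schema_version": MODEL_SCHEMA_VERSION, "model": model.to_dict()}
    with _open_text(path, "w") as fh:
        json.dump(doc, fh, indent=1, sort_keys=True)
        fh.write("\n")


def read_model(path: str | Path):
    """Read a model written by :func:`write_model`; strict about schema."""
    from .cluster import SubspeciesModel

    try:
        with _open_text(path, "r") as fh:
            doc = json.load(fh)
    except (json.JSONDecodeError, EOFError) as exc:
        raise FormatError(f"{path}: truncated or invalid model file ({exc})") from exc
    if not isinstance(doc, dict) or "schema_version" not in doc:
        raise FormatError(f"{path}: not a subspec model document")
    if doc["schema_version"] != MODEL_SCHEMA_VERSION:
        raise FormatError(
            f"{path}: unsupported model schema version {doc['schema_version']} "
            f"(expected {MODEL_SCHEMA_VERSION})"
        )
    return SubspeciesModel.from_dict(doc["model"])
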