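"""Domain types and tabular/interval readers and writers.

All genomic coordinates are 0-based half-open. Chromosome names are matched
as exact strings (no ``chr`` normalization). Missing methylation values are
encoded as ``NA`` on disk and ``NaN`` in memory — never as 0, which is a
legal methylation value.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Optional, Sequence

import numpy as np
import pandas as pd


class ValidationError(ValueError):
    """Raised when an input violates a domain invariant."""


ROLES = frozenset({"control", "patient", "corrected"})
CELL_TYPES = frozenset({"iPSC", "fibroblast", "blood", "hESC"})
DMR_CLASSES = frozenset({"germline", "secondary", "none"})
ORIGINS = frozenset({"maternal", "paternal", "none"})


# ---------------------------------------------------------------------------
# Matrices
# ---------------------------------------------------------------------------

class _Matrix:
    """Shared behaviour for unit × sample float matrices (NaN = missing)."""

    def __init__(self, data: pd.DataFrame):
        if data.index.has_duplicates:
            dups = data.index[data.index.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate unit ids: {dups}")
        if data.columns.has_duplicates:
            dups = data.columns[data.columns.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate sample ids: {dups}")
        try:
            data = data.astype(float)
        except (TypeError, ValueError) as exc:
            raise ValidationError(f"non-numeric matrix value: {exc}") from exc
        self._check_values(data)
        self.data = data

    def _check_values(self, data: pd.DataFrame) -> None:  # pragma: no cover
        raise NotImplementedError

    @property
    def unit_ids(self) -> list:
        return self.data.index.tolist()

    @property
    def sample_ids(self) -> list:
        return self.data.columns.tolist()

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy()

    def sample(self, sample_id: str) -> pd.Series:
        if sample_id not in self.data.columns:
            raise ValidationError(f"unknown sample: {sample_id!r}")
        return self.data[sample_id]

    def __repr__(self) -> str:
        return (f"<{type(self).__name__} {self.data.shape[0]} units × "
                f"{self.data.shape[1]} samples>")


class BetaMatrix(_Matrix):
    """Methylation fractions per (unit, sample); values in [0, 1] or NaN."""

    def _check_values(self, data: pd.DataFrame) -> None:
        arr = data.to_numpy()
        bad = (arr < 0) | (arr > 1)
        if np.any(bad & ~np.isnan(arr)):
            r, c = np.argwhere(bad & ~np.isnan(arr))[0]
            raise ValidationError(
                f"beta value {arr[r, c]} outside [0, 1] at unit "
                f"{data.index[r]!r}, sample {data.columns[c]!r}")


class MMatrix(_Matrix):
    """log2 methylated/unmethylated ratios; finite where non-missing."""

    def _check_values(self, data: pd.DataFrame) -> None:
        arr = data.to_numpy()
        if np.any(np.isinf(arr)):
            r, c = np.argwhere(np.isinf(arr))[0]
            raise ValidationError(
                f"non-finite M-value at unit {data.index[r]!r}, sample "
                f"{data.columns[c]!r}")


def _read_matrix_frame(path) -> pd.DataFrame:
    try:
        df = pd.read_csv(path, sep="\t", index_col=0, na_values=["NA"])
    except pd.errors.EmptyDataError:
        raise ValidationError(f"{path}: no data rows") from None
    if df.shape[0] == 0:
        raise ValidationError(f"{path}: no data rows")
    return df


def read_beta_matrix(path) -> BetaMatrix:
    """Read a TSV with a sample-id header row and unit ids in column 1."""
    return BetaMatrix(_read_matrix_frame(path))


def read_detection_matrix(path) -> pd.DataFrame:
    """Read a detection p-value matrix (same layout as a beta matrix)."""
    df = _read_matrix_frame(path).astype(float)
    arr = df.to_numpy()
    if np.any((arr < 0) | (arr > 1)):
        raise ValidationError(f"{path}: detection p-values outside [0, 1]")
    return df


def write_matrix(matrix: _Matrix, path, index_label: str = "unit_id") -> None:
    matrix.data.to_csv(path, sep="\t", float_format="%.6f", na_rep="NA",
                       index_label=index_label)


write_beta_matrix = write_matrix


# ---------------------------------------------------------------------------
# Regions
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Region:
    """A named 0-based half-open genomic interval with imprinting metadata."""

    name: str
    chrom: str
    start: int
    end: int
    dmr_class: str = "none"
    parental_origin: str = "none"

    def __post_init__(self):
        if self.start < 0 or self.start >= self.end:
            raise ValidationError(
                f"region {self.name!r}: invalid interval [{self.start}, {self.end})")
        if self.dmr_class not in DMR_CLASSES:
            raise ValidationError(f"region {self.name!r}: bad dmr_class {self.dmr_class!r}")
        if self.parental_origin not in ORIGINS:
            raise ValidationError(
                f"region {self.name!r}: bad parental_origin {self.parental_origin!r}")

    def contains(self, chrom: str, pos: int) -> bool:
        """Half-open containment: pos == start is inside, pos == end is not."""
        return chrom == self.chrom and self.start <= pos < self.end

    @property
    def length(self) -> int:
        return self.end - self.start


class RegionSet:
    """An ordered collection of uniquely named regions."""

    def __init__(self, regions: Iterable[Region]):
        regions = list(regions)
        names = [r.name for r in regions]
        if len(set(names)) != len(names):
            dups = sorted({n for n in names if names.count(n) > 1})
            raise ValidationError(f"duplicate region names: {dups}")
        self._regions = regions
        self._by_name = {r.name: r for r in regions}

    def __iter__(self) -> Iterator[Region]:
        return iter(self._regions)

    def __len__(self) -> int:
        return len(self._regions)

    def __contains__(self, name: str) -> bool:
        return name in self._by_name

    def get(self, name: str) -> Region:
        return self._by_name[name]

    @property
    def names(self) -> list:
        return [r.name for r in self._regions]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(r.chrom, r.start, r.end, r.name, r.dmr_class, r.parental_origin)
             for r in self._regions],
            columns=["chrom", "start", "end", "name", "dmr_class", "parental_origin"])


def read_regions(path) -> RegionSet:
    """Read a BED-like TSV: chrom, start, end, name[, dmr_class, parental_origin]."""
    try:
        df = pd.read_csv(path, sep="\t", header=None, comment="#",
                         na_values=["."], dtype=str)
    except pd.errors.EmptyDataError:
        raise ValidationError(f"{path}: no data rows") from None
    if df.shape[1] < 4:
        raise ValidationError(f"{path}: need at least 4 columns (chrom start end name)")
    regions = []
    for row in df.itertuples(index=False):
        vals = list(row) + ["none"] * (6 - len(row))
        chrom, start, end, name, cls, origin = vals[:6]
        cls = "none" if pd.isna(cls) else cls
        origin = "none" if pd.isna(origin) else origin
        regions.append(Region(name=str(name), chrom=str(chrom),
                              start=int(start), end=int(end),
                              dmr_class=cls, parental_origin=origin))
    return RegionSet(regions)


def write_regions(regions: RegionSet, path) -> None:
    with open(path, "w") as fh:
        for r in regions:
            fh.write(f"{r.chrom}\t{r.start}\t{r.end}\t{r.name}\t"
                     f"{r.dmr_class}\t{r.parental_origin}\n")


# ---------------------------------------------------------------------------
# Probe manifest
# ---------------------------------------------------------------------------

class ProbeManifest:
    """Probe id → (chrom, 0-based pos) plus SNP-overlap and sex-chromosome flags."""

    REQUIRED = ("probe_id", "chrom", "pos", "snp_overlap", "sex_chrom")

    def __init__(self, frame: pd.DataFrame):
        missing = [c for c in self.REQUIRED if c not in frame.columns]
        if missing:
            raise ValidationError(f"manifest missing columns: {missing}")
        frame = frame.loc[:, list(self.REQUIRED)].copy()
        if frame["probe_id"].duplicated().any():
            dups = frame.loc[frame["probe_id"].duplicated(), "probe_id"].tolist()
            raise ValidationError(f"duplicate probe ids: {dups}")
        frame["pos"] = frame["pos"].astype(int)
        if (frame["pos"] < 0).any():
            raise ValidationError("manifest positions must be >= 0")
        for col in ("snp_overlap", "sex_chrom"):
            frame[col] = _to_bool(frame[col])
        self.frame = frame.set_index("probe_id", drop=False)

    @property
    def probe_ids(self) -> list:
        return self.frame["probe_id"].tolist()

    def __len__(self) -> int:
        return len(self.frame)


def _to_bool(series: pd.Series) -> pd.Series:
    if series.dtype == bool:
        return series
    mapping = {"true": True, "false": False, "1": True, "0": False}
    out = series.astype(str).str.strip().str.lower().map(mapping)
    if out.isna().any():
        raise ValidationError(f"unparseable boolean values in column {series.name!r}")
    return out.astype(bool)


def read_manifest(path) -> ProbeManifest:
    try:
        df = pd.read_csv(path, sep="\t", dtype=str)
    except pd.errors.EmptyDataError:
        raise ValidationError(f"{path}: no data rows") from None
    return ProbeManifest(df)


def write_manifest(manifest: ProbeManifest, path) -> None:
    manifest.frame.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Sample sheet
# ---------------------------------------------------------------------------

class SampleSheet:
    """Sample roles: control, patient, or corrected clone (with parentage)."""

    def __init__(self, frame: pd.DataFrame):
        required = ("sample_id", "role", "cell_type")
        missing = [c for c in required if c not in frame.columns]
        if missing:
            raise ValidationError(f"sample sheet missing columns: {missing}")
        frame = frame.copy()
        if "parent_patient" not in frame.columns:
            frame["parent_patient"] = None
        frame["parent_patient"] = frame["parent_patient"].replace(
            {"none": None, "": None, np.nan: None})
        if frame["sample_id"].duplicated().any():
            raise ValidationError("duplicate sample ids in sheet")
        bad_roles = set(frame["role"]) - ROLES
        if bad_roles:
            raise ValidationError(f"unknown roles: {sorted(bad_roles)}")
        bad_ct = set(frame["cell_type"]) - CELL_TYPES
        if bad_ct:
            raise ValidationError(f"unknown cell types: {sorted(bad_ct)}")
        patients = set(frame.loc[frame["role"] == "patient", "sample_id"])
        for row in frame.itertuples(index=False):
            if row.role == "corrected":
                if row.parent_patient is None:
                    raise ValidationError(
                        f"corrected sample {row.sample_id!r} lacks parent_patient")
                if row.parent_patient not in patients:
                    raise ValidationError(
                        f"corrected sample {row.sample_id!r}: parent_patient "
                        f"{row.parent_patient!r} is not a patient sample")
            elif row.parent_patient is not None:
                raise ValidationError(
                    f"sample {row.sample_id!r} (role {row.role}) must not set "
                    f"parent_patient")
        self.frame = frame.set_index("sample_id", drop=False)
        if len(self.controls()) < 2:
            warnings.warn("fewer than 2 iPSC controls: reference computation "
                          "will fail", stacklevel=2)

    def controls(self, cell_type: Optional[str] = "iPSC") -> list:
        """Control sample ids; by default restricted to the iPSC panel."""
        mask = self.frame["role"] == "control"
        if cell_type is not None:
            mask &= self.frame["cell_type"] == cell_type
        return self.frame.loc[mask, "sample_id"].tolist()

    def patients(self) -> list:
        return self.frame.loc[self.frame["role"] == "patient", "sample_id"].tolist()

    def corrected(self) -> list:
        return self.frame.loc[self.frame["role"] == "corrected", "sample_id"].tolist()

    def parent_of(self, sample_id: str) -> str:
        row = self.frame.loc[sample_id]
        if row["role"] != "corrected":
            raise ValidationError(f"{sample_id!r} is not a corrected clone")
        return row["parent_patient"]

    def clones_of(self, patient_id: str) -> list:
        mask = (self.frame["role"] == "corrected") & \
               (self.frame["parent_patient"] == patient_id)
        return self.frame.loc[mask, "sample_id"].tolist()

    def __len__(self) -> int:
        return len(self.frame)


def read_sample_sheet(path) -> SampleSheet:
    try:
        df = pd.read_csv(path, sep="\t", dtype=str)
    except pd.errors.EmptyDataError:
        raise ValidationError(f"{path}: no data rows") from None
    return SampleSheet(df)


def write_sample_sheet(sheet: SampleSheet, path) -> None:
    out = sheet.frame.copy()
    out["parent_patient"] = out["parent_patient"].fillna("none")
    out.to_csv(path, sep="\t", index=False,
               columns=["sample_id", "role", "parent_patient", "cell_type"])


# ---------------------------------------------------------------------------
# ChIP read counts
# ---------------------------------------------------------------------------

class ChipCountTable:
    """Long-format per-region IP/input read counts with library depths."""

    REQUIRED = ("region", "condition", "replicate", "ip_count", "input_count",
                "ip_depth", "input_depth")

    def __init__(self, frame: pd.DataFrame):
        missing = [c for c in self.REQUIRED if c not in frame.columns]
        if missing:
            raise ValidationError(f"chip count table missing columns: {missing}")
        frame = frame.loc[:, list(self.REQUIRED)].copy()
        for col in ("ip_count", "input_count", "ip_depth", "input_depth"):
            frame[col] = frame[col].astype(np.int64)
        if (frame[["ip_count", "input_count"]].to_numpy() < 0).any():
            raise ValidationError("negative read counts")
        if (frame[["ip_depth", "input_depth"]].to_numpy() <= 0).any():
            raise ValidationError("library depths must be positive")
        if (frame["ip_count"] > frame["ip_depth"]).any() or \
           (frame["input_count"] > frame["input_depth"]).any():
            raise ValidationError("read count exceeds library depth")
        self.frame = frame

    def __len__(self) -> int:
        return len(self.frame)


def read_chip_counts(path) -> ChipCountTable:
    try:
        df = pd.read_csv(path, sep="\t")
    except pd.errors.EmptyDataError:
        raise ValidationError(f"{path}: no data rows") from None
    return ChipCountTable(df)


def write_chip_counts(table: ChipCountTable, path) -> None:
    table.frame.to_csv(path, sep="\t", index=False)
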