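"""Data model and I/O for vesicle section measurements and cell counts.

A section record is one measured vesicle profile from an immunogold EM
micrograph: strain, brain region, animal, the noradrenergic/adrenergic
(N/E) marker that identified it (DbH or VMAT2, or none for an NPY-only
profile), whether it carries an NPY colabel, and the measured horizontal
and vertical radii in nm.  The working diameter of a (possibly slightly
elliptical) profile is ``radius_h + radius_v`` — twice the mean radius —
matching the convention of averaging the two measured radii.

Files are plain CSV, UTF-8, dot decimal, one header row.  Rows that
violate the vocabulary or numeric invariants are rejected individually,
with line-numbered diagnostics, rather than failing the whole file.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "STRAINS",
    "REGIONS",
    "CELL_COUNT_REGIONS",
    "NE_MARKERS",
    "SectionRecord",
    "CellCountRecord",
    "MeasurementSet",
    "Diagnostic",
    "read_sections",
    "write_sections",
    "sections_from_frame",
    "pool_ne_markers",
    "filter_diameter_range",
    "to_histogram",
    "read_cell_counts",
    "write_cell_counts",
]

STRAINS = ("WR", "SHR")
#: EM regions (CVLM appears only in the confocal arm but is valid vocabulary).
REGIONS = ("NTS", "RVLM", "LC", "CVLM")
#: Confocal cell-count regions; the NTS is split rostro-caudally.
CELL_COUNT_REGIONS = ("NTS_caudal", "NTS_rostral", "CVLM", "RVLM", "LC")
NE_MARKERS = ("DbH", "VMAT2", "none")

SECTION_COLUMNS = [
    "animal_id",
    "strain",
    "region",
    "ne_marker",
    "npy_label",
    "radius_h",
    "radius_v",
]

CELL_COUNT_COLUMNS = [
    "animal_id",
    "strain",
    "region",
    "n_dbh_only",
    "n_npy_only",
    "n_coloc",
]


@dataclass(frozen=True)
class SectionRecord:
    """One measured vesicle profile."""

    animal_id: str
    strain: str
    region: str
    ne_marker: str
    npy_label: bool
    radius_h: float
    radius_v: float

    @property
    def diameter(self) -> float:
        """Equivalent profile diameter: twice the mean measured radius."""
        return self.radius_h + self.radius_v

    def __post_init__(self) -> None:
        if self.strain not in STRAINS:
            raise ValueError(f"unknown strain {self.strain!r}")
        if self.region not in REGIONS:
            raise ValueError(f"unknown region {self.region!r}")
        if self.ne_marker not in NE_MARKERS:
            raise ValueError(f"unknown ne_marker {self.ne_marker!r}")
        if not (self.radius_h > 0 and self.radius_v > 0):
            raise ValueError("radii must be > 0")
        if self.ne_marker == "none" and not self.npy_label:
            raise ValueError("a record with no N/E marker must carry an NPY label")


@dataclass(frozen=True)
class CellCountRecord:
    """Per-animal confocal cell-body counts for one region."""

    animal_id: str
    strain: str
    region: str
    n_dbh_only: int
    n_npy_only: int
    n_coloc: int

    def __post_init__(self) -> None:
        if self.strain not in STRAINS:
            raise ValueError(f"unknown strain {self.strain!r}")
        if self.region not in CELL_COUNT_REGIONS:
            raise ValueError(f"unknown region {self.region!r}")
        if min(self.n_dbh_only, self.n_npy_only, self.n_coloc) < 0:
            raise ValueError("cell counts must be >= 0")

    @property
    def n_dbh_total(self) -> int:
        """All DbH-immunoreactive cell bodies (with or without NPY)."""
        return self.n_dbh_only + self.n_coloc

    @property
    def coexpression_percent(self) -> float:
        if self.n_dbh_total == 0:
            raise ZeroDivisionError("animal has no DbH-ir cells")
        return 100.0 * self.n_coloc / self.n_dbh_total


@dataclass(frozen=True)
class Diagnostic:
    """A rejected input row: 1-based line number plus reason."""

    line: int
    message: str

    def __str__(self) -> str:
        return f"line {self.line}: {self.message}"


@dataclass
class MeasurementSet:
    """A validated collection of section records with provenance.

    Backed by a pandas DataFrame with the schema columns plus the derived
    ``diameter`` and (after pooling) ``ne_labeled``.  Operations return
    new sets and append a description of themselves to ``filters``.
    """

    df: pd.DataFrame
    source: str = "<memory>"
    filters: list = field(default_factory=list)
    diagnostics: list = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.df)

    @property
    def diameters(self) -> np.ndarray:
        return self.df["diameter"].to_numpy(dtype=float)

    def subset(self, strain: str | None = None, region: str | None = None) -> "MeasurementSet":
        df = self.df
        if strain is not None:
            df = df[df["strain"] == strain]
        if region is not None:
            df = df[df["region"] == region]
        return replace(self, df=df.reset_index(drop=True),
                       filters=self.filters + [f"subset(strain={strain}, region={region})"])

    def records(self) -> list[SectionRecord]:
        return [
            SectionRecord(
                animal_id=str(r.animal_id),
                strain=r.strain,
                region=r.region,
                ne_marker=r.ne_marker,
                npy_label=bool(r.npy_label),
                radius_h=float(r.radius_h),
                radius_v=float(r.radius_v),
            )
            for r in self.df.itertuples(index=False)
        ]


def _parse_bool(value) -> bool:
    if isinstance(value, (bool, np.bool_)):
        return bool(value)
    s = str(value).strip().lower()
    if s in ("true", "1", "yes"):
        return True
    if s in ("false", "0", "no"):
        return False
    raise ValueError(f"not a boolean: {value!r}")


def sections_from_frame(df: pd.DataFrame, source: str = "<memory>") -> MeasurementSet:
    """Validate a raw frame row-by-row into a MeasurementSet.

    Invalid rows are dropped and reported as :class:`Diagnostic` entries
    (line numbers count the header as line 1).
    """
    missing = [c for c in SECTION_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{source}: missing required columns {missing}")
    rows = []
    diagnostics = []
    for pos, (_, row) in enumerate(df.iterrows()):
        line = pos + 2  # header is line 1
        try:
            rec = SectionRecord(
                animal_id=str(row["animal_id"]),
                strain=str(row["strain"]),
                region=str(row["region"]),
                ne_marker=str(row["ne_marker"]),
                npy_label=_parse_bool(row["npy_label"]),
                radius_h=float(row["radius_h"]),
                radius_v=float(row["radius_v"]),
            )
        except (ValueError, TypeError) as exc:
            diagnostics.append(Diagnostic(line, str(exc)))
            continue
        rows.append(
            (rec.animal_id, rec.strain, rec.region, rec.ne_marker,
             rec.npy_label, rec.radius_h, rec.radius_v, rec.diameter)
        )
    out = pd.DataFrame(rows, columns=SECTION_COLUMNS + ["diameter"])
    return MeasurementSet(out, source=source, diagnostics=diagnostics)


def read_sections(path) -> MeasurementSet:
    """Read and validate a sections CSV file."""
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    return sections_from_frame(df, source=str(path))


def write_sections(mset: MeasurementSet, path) -> None:
    """Write a sections CSV (schema columns only; diameter is derived)."""
    out = mset.df[SECTION_COLUMNS].copy()
    out["npy_label"] = out["npy_label"].map(lambda b: "true" if b else "false")
    # repr-round-trip floats so read_sections(write_sections(m)) is exact
    for col in ("radius_h", "radius_v"):
        out[col] = out[col].map(lambda x: repr(float(x)))
    out.to_csv(path, index=False)


def pool_ne_markers(mset: MeasurementSet) -> MeasurementSet:
    """Flag DbH- and VMAT2-labeled records as one pooled N/E class.

    The two markers label the same vesicle population with alike size
    distributions, so downstream analysis treats them as one class; the
    original marker column is retained for audit.  Idempotent.
    """
    df = mset.df.copy()
    df["ne_labeled"] = df["ne_marker"].isin(("DbH", "VMAT2"))
    return replace(mset, df=df, filters=mset.filters + ["pool_ne_markers"])


def filter_diameter_range(mset: MeasurementSet, low: float, high: float) -> MeasurementSet:
    """Keep records with ``low <= diameter <= high`` (bounds inclusive).

    The numbers removed below and above are recorded in the new set's
    ``filters`` entry and returned set attributes ``n_removed_below`` /
    ``n_removed_above``.
    """
    if not low < high:
        raise ValueError(f"inverted diameter bounds [{low}, {high}]")
    d = mset.df["diameter"]
    below = int((d < low).sum())
    above = int((d > high).sum())
    kept = mset.df[(d >= low) & (d <= high)].reset_index(drop=True)
    out = replace(
        mset,
        df=kept,
        filters=mset.filters
        + [f"filter_diameter_range({low:g}, {high:g}): removed {below} below, {above} above"],
    )
    out.n_removed_below = below  # type: ignore[attr-defined]
    out.n_removed_above = above  # type: ignore[attr-defined]
    return out


def to_histogram(mset: MeasurementSet, grid):
    """Bin the set's diameters on a grid (half-open bins, last closed)."""
    from .geometry import ApparentHistogram, DiameterGrid

    if len(mset) == 0:
        raise ValueError("cannot histogram an empty measurement set")
    if not isinstance(grid, DiameterGrid):
        grid = DiameterGrid(np.asarray(grid, dtype=float))
    return ApparentHistogram.from_samples(mset.diameters, grid)


def read_cell_counts(path) -> list[CellCountRecord]:
    """Read a confocal cell-count CSV into validated records."""
    df = pd.read_csv(path)
    missing = [c for c in CELL_COUNT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")
    records = []
    for _, row in df.iterrows():
        records.append(
            CellCountRecord(
                animal_id=str(row["animal_id"]),
                strain=str(row["strain"]),
                region=str(row["region"]),
                n_dbh_only=int(row["n_dbh_only"]),
                n_npy_only=int(row["n_npy_only"]),
                n_coloc=int(row["n_coloc"]),
            )
        )
    return records


def write_cell_counts(records, path) -> None:
    df = pd.DataFrame(
        [
            (r.animal_id, r.strain, r.region, r.n_dbh_only, r.n_npy_only, r.n_coloc)
            for r in records
        ],
        columns=CELL_COUNT_COLUMNS,
    )
    df.to_csv(path, index=False)
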