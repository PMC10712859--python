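"""Readers and writers for every table the pipeline touches.

All formats are plain UTF-8 CSV with a header row; calibration fits and
model reports are JSON.  Melt plates come in two dialects:

* ``long`` (canonical): columns ``well, temperature, fluorescence``;
* ``wide``: a ``temperature`` column plus one column per well.

Readers validate hard (strictly increasing temperatures per well, unique
ids, methylation in [0, 100], metadata role/fraction consistency) and every
error names the offending well, row or column.  Each reader/writer pair is
a lossless round trip on its own output.
"""

from __future__ import annotations

import datetime
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .age_model import MethylationDataset, SampleRecord, compute_age
from .errors import FormatError, ValidationError
from .melt import MeltCurve

__all__ = [
    "PlateExport",
    "SampleMetadata",
    "read_melt_table",
    "write_melt_table",
    "read_sample_metadata",
    "write_sample_metadata",
    "read_methylation_dataset",
    "write_methylation_dataset",
]

_METADATA_COLUMNS = [
    "sample_id",
    "individual_id",
    "sex",
    "birth_date",
    "birth_known",
    "collection_date",
    "role",
    "nominal_fraction_pct",
    "replicate",
]


@dataclass
class PlateExport:
    """One plate's worth of melt curves."""

    curves: list[MeltCurve]
    plate_id: str = "plate"
    dialect: str = "long"

    def __post_init__(self):
        wells = [c.well_id for c in self.curves]
        if len(set(wells)) != len(wells):
            dup = sorted({w for w in wells if wells.count(w) > 1})
            raise ValidationError(f"plate {self.plate_id!r}: duplicate well ids {dup}")
        if self.dialect not in ("long", "wide"):
            raise FormatError(f"unknown melt-table dialect {self.dialect!r}")

    def well(self, well_id: str) -> MeltCurve:
        for c in self.curves:
            if c.well_id == well_id:
                return c
        raise KeyError(well_id)


def _require_columns(frame: pd.DataFrame, required, what: str) -> None:
    for col in required:
        if col not in frame.columns:
            raise FormatError(f"{what}: missing required column {col!r}")


def _numeric(series: pd.Series, column: str) -> pd.Series:
    try:
        return pd.to_numeric(series, errors="raise")
    except (ValueError, TypeError) as exc:
        raise ValidationError(f"non-numeric value in column {column!r}: {exc}") from exc


def read_melt_table(
    path, dialect: str = "long", gene_id: str = "", plate_id: str | None = None
) -> PlateExport:
    """Read a plate export of melting-curve fluorescence per well."""
    frame = pd.read_csv(path, float_precision="round_trip")
    plate_id = plate_id or str(path)
    curves = []
    if dialect == "long":
        _require_columns(frame, ["well", "temperature", "fluorescence"], "long melt table")
        frame = frame.assign(
            temperature=_numeric(frame["temperature"], "temperature"),
            fluorescence=_numeric(frame["fluorescence"], "fluorescence"),
        )
        for well, grp in frame.groupby("well", sort=False):
            curves.append(
                MeltCurve(str(well), gene_id, grp["temperature"].to_numpy(), grp["fluorescence"].to_numpy())
            )
    elif dialect == "wide":
        _require_columns(frame, ["temperature"], "wide melt table")
        temps = _numeric(frame["temperature"], "temperature").to_numpy()
        for col in frame.columns:
            if col == "temperature":
                continue
            curves.append(MeltCurve(str(col), gene_id, temps, _numeric(frame[col], col).to_numpy()))
    else:
        raise FormatError(f"unknown melt-table dialect {dialect!r}")
    if not curves:
        raise ValidationError(f"plate {plate_id!r}: no wells found")
    return PlateExport(curves=curves, plate_id=plate_id, dialect=dialect)


def write_melt_table(plate: PlateExport, path, dialect: str | None = None) -> None:
    """Write a plate in either dialect (wide requires a shared grid)."""
    dialect = dialect or plate.dialect
    if dialect == "long":
        frames = [
            pd.DataFrame(
                {"well": c.well_id, "temperature": c.temperatures, "fluorescence": c.fluorescence}
            )
            for c in plate.curves
        ]
        pd.concat(frames, ignore_index=True).to_csv(path, index=False)
    elif dialect == "wide":
        grid = plate.curves[0].temperatures
        for c in plate.curves[1:]:
            if not np.array_equal(c.temperatures, grid):
                raise ValidationError(
                    f"well {c.well_id!r}: wide dialect needs a shared temperature grid"
                )
        out = pd.DataFrame({"temperature": grid})
        for c in plate.curves:
            out[c.well_id] = c.fluorescence
        out.to_csv(path, index=False)
    else:
        raise FormatError(f"unknown melt-table dialect {dialect!r}")


@dataclass
class SampleMetadata:
    """One metadata row: identity, dates, and role on the plate."""

    sample_id: str
    individual_id: str
    sex: str
    birth_date: datetime.date | None
    birth_known: bool
    collection_date: datetime.date | None
    role: str
    nominal_fraction_pct: float | None
    replicate: int = 1

    def __post_init__(self):
        if self.sex not in ("female", "male", "unknown"):
            raise ValidationError(f"row {self.sample_id!r}: sex {self.sex!r}")
        if self.role not in ("sample", "standard", "baseline"):
            raise ValidationError(f"row {self.sample_id!r}: role {self.role!r}")
        if self.role == "sample":
            if self.nominal_fraction_pct is not None:
                raise ValidationError(
                    f"row {self.sample_id!r}: role=sample must not carry a nominal fraction"
                )
            if (
                self.birth_date is not None
                and self.collection_date is not None
                and self.collection_date < self.birth_date
            ):
                raise ValidationError(
                    f"row {self.sample_id!r}: collection date precedes birth date"
                )
        else:
            if self.nominal_fraction_pct is None:
                raise ValidationError(
                    f"row {self.sample_id!r}: role={self.role} requires a nominal fraction"
                )
            if not 0.0 <= self.nominal_fraction_pct <= 100.0:
                raise ValidationError(
                    f"row {self.sample_id!r}: nominal fraction outside [0, 100]"
                )
        if self.replicate < 1:
            raise ValidationError(f"row {self.sample_id!r}: replicate must be >= 1")


def _parse_date(value, row_id: str, column: str) -> datetime.date | None:
    if value is None or (isinstance(value, float) and np.isnan(value)) or value == "":
        return None
    try:
        return datetime.date.fromisoformat(str(value))
    except ValueError as exc:
        raise ValidationError(f"row {row_id!r}: bad ISO date in {column!r}: {value!r}") from exc


def read_sample_metadata(path) -> list[SampleMetadata]:
    """Read the sample metadata CSV (ISO-8601 dates, unknown sex allowed)."""
    frame = pd.read_csv(path, float_precision="round_trip")
    _require_columns(frame, _METADATA_COLUMNS, "sample metadata")
    rows = []
    for _, rec in frame.iterrows():
        sid = str(rec["sample_id"])
        frac = rec["nominal_fraction_pct"]
        rows.append(
            SampleMetadata(
                sample_id=sid,
                individual_id=str(rec["individual_id"]),
                sex=str(rec["sex"]),
                birth_date=_parse_date(rec["birth_date"], sid, "birth_date"),
                birth_known=bool(rec["birth_known"]),
                collection_date=_parse_date(rec["collection_date"], sid, "collection_date"),
                role=str(rec["role"]),
                nominal_fraction_pct=None if pd.isna(frac) else float(frac),
                replicate=int(rec["replicate"]),
            )
        )
    return rows


def write_sample_metadata(rows: list[SampleMetadata], path) -> None:
    frame = pd.DataFrame(
        [
            {
                "sample_id": r.sample_id,
                "individual_id": r.individual_id,
                "sex": r.sex,
                "birth_date": "" if r.birth_date is None else r.birth_date.isoformat(),
                "birth_known": r.birth_known,
                "collection_date": "" if r.collection_date is None else r.collection_date.isoformat(),
                "role": r.role,
                "nominal_fraction_pct": r.nominal_fraction_pct,
                "replicate": r.replicate,
            }
            for r in rows
        ],
        columns=_METADATA_COLUMNS,
    )
    frame.to_csv(path, index=False)


def read_methylation_dataset(
    path,
    genes: list[str],
    column_map: dict[str, str] | None = None,
) -> MethylationDataset:
    """Read a per-sample methylation-rate table (CSV, or XLSX by suffix).

    Canonical columns: ``sample_id, individual_id, sex, age_years`` (or
    ``birth_date`` + ``collection_date``, from which age is computed as
    days/365.25) plus one column per gene.  ``column_map`` renames
    non-canonical layouts, e.g. ``{"ID": "sample_id", "RALYL(%)": "RALYL"}``.
    """
    if str(path).lower().endswith((".xlsx", ".xls")):
        frame = pd.read_excel(path)
    else:
        frame = pd.read_csv(path, float_precision="round_trip")
    if column_map:
        frame = frame.rename(columns=column_map)
    _require_columns(frame, ["sample_id", "individual_id"], "methylation dataset")
    for gene in genes:
        if gene not in frame.columns:
            raise FormatError(f"methylation dataset: missing column for gene {gene!r}")
    has_age = "age_years" in frame.columns
    if not has_age and not {"birth_date", "collection_date"} <= set(frame.columns):
        raise FormatError(
            "methylation dataset: need either an 'age_years' column or both "
            "'birth_date' and 'collection_date'"
        )
    records = []
    for _, rec in frame.iterrows():
        sid = str(rec["sample_id"])
        if has_age and not pd.isna(rec["age_years"]):
            age = float(_numeric(pd.Series([rec["age_years"]]), "age_years").iloc[0])
            collection = (
                _parse_date(rec.get("collection_date", ""), sid, "collection_date")
                if "collection_date" in frame.columns
                else None
            )
        else:
            birth = _parse_date(rec["birth_date"], sid, "birth_date")
            collection = _parse_date(rec["collection_date"], sid, "collection_date")
            if birth is None or collection is None:
                raise ValidationError(f"row {sid!r}: missing dates and no age_years")
            age = compute_age(birth, collection)
        meth = {}
        for gene in genes:
            value = float(_numeric(pd.Series([rec[gene]]), gene).iloc[0])
            if not 0.0 <= value <= 100.0:
                raise ValidationError(
                    f"row {sid!r}: {gene} methylation {value} outside [0, 100]"
                )
            meth[gene] = value
        records.append(
            SampleRecord(
                sample_id=sid,
                individual_id=str(rec["individual_id"]),
                sex=str(rec["sex"]) if "sex" in frame.columns else "unknown",
                age_years=age,
                methylation=meth,
                birth_known=bool(rec["birth_known"]) if "birth_known" in frame.columns else True,
                collection_date=collection,
            )
        )
    return MethylationDataset(records, list(genes))


def write_methylation_dataset(dataset: MethylationDataset, path) -> None:
    dataset.to_frame().to_csv(path, index=False)
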