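"""Long-format plate tables: typed well records and CSV/XLSX round-trip.

One well per row for every platform. qPCR/TLDA rows carry a Ct (or the
literal ``Undetermined``); ddPCR rows carry droplet counts and leave the
Ct cell empty. This single schema serves all four experiments of the
study design (centrifugation comparison, patient cohort in two plasma
materials, platform agreement, pooled-sample precision).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence, Union

import pandas as pd

from .errors import SchemaError, ValidationError

#: PCR cycle count of the thermal program; Ct values beyond this are not
#: meaningful and are mapped to the undetermined state on ingestion.
CYCLE_MAX = 40.0

#: De facto droplet volume of the QX100 droplet reader, in nanolitres.
DEFAULT_DROPLET_VOLUME_NL = 0.85

ASSAYS = ("miR-92a", "miR-126", "miR-16", "cel-miR-39")
CT_PLATFORMS = ("qPCR", "TLDA")
DDPCR_PLATFORM = "ddPCR"
PLATFORMS = CT_PLATFORMS + (DDPCR_PLATFORM,)
MATERIALS = ("PPP", "standard_plasma", "pool")
PROTOCOLS = ("dual", "single", "none")

#: On-disk column set, exact order.
COLUMNS = (
    "experiment_id",
    "sample_id",
    "subject_id",
    "material",
    "protocol",
    "draw_order",
    "run_day",
    "rt_replicate",
    "pcr_replicate",
    "platform",
    "assay",
    "ct",
    "positives",
    "total_droplets",
    "droplet_volume_nl",
)

UNDETERMINED = "Undetermined"


@dataclass(frozen=True)
class SampleMeta:
    """Identity and design position of one well's sample.

    ``draw_order`` is present only for the centrifugation experiment,
    where tubes are numbered consecutively in the order of blood draw
    (odd numbers -> dual centrifugation, even -> prolonged single).
    ``(run_day, rt_replicate, pcr_replicate)`` identify a well within an
    experiment x assay x platform.
    """

    sample_id: str
    subject_id: str
    material: str
    protocol: str
    experiment_id: str = ""
    draw_order: int | None = None
    run_day: int = 1
    rt_replicate: int = 1
    pcr_replicate: int = 1

    def __post_init__(self):
        if self.material not in MATERIALS:
            raise ValidationError(f"unknown material {self.material!r}")
        if self.protocol not in PROTOCOLS:
            raise ValidationError(f"unknown protocol {self.protocol!r}")
        if self.draw_order is not None and self.draw_order < 1:
            raise ValidationError("draw_order must be a positive integer")
        if self.run_day < 1:
            raise ValidationError("run_day must be >= 1")
        if self.rt_replicate not in (1, 2):
            raise ValidationError("rt_replicate must be 1 or 2")
        if self.pcr_replicate not in (1, 2, 3):
            raise ValidationError("pcr_replicate must be 1, 2 or 3")


@dataclass(frozen=True)
class CtMeasurement:
    """One qPCR or TLDA well: a cycle-threshold value or undetermined.

    ``ct is None`` encodes the undetermined state explicitly; no sentinel
    number is ever used. Cts above :data:`CYCLE_MAX` cannot be observed
    within the thermal program and are rejected (the reader maps them to
    undetermined instead).
    """

    meta: SampleMeta
    assay: str
    platform: str
    ct: float | None

    def __post_init__(self):
        if self.assay not in ASSAYS:
            raise ValidationError(f"unknown assay {self.assay!r}")
        if self.platform not in CT_PLATFORMS:
            raise ValidationError(
                f"platform {self.platform!r} invalid for a Ct measurement"
            )
        if self.ct is not None:
            if not math.isfinite(self.ct) or self.ct <= 0 or self.ct > CYCLE_MAX:
                raise ValidationError(
                    f"ct {self.ct!r} outside (0, {CYCLE_MAX}]; use ct=None "
                    "for undetermined wells"
                )

    @property
    def undetermined(self) -> bool:
        return self.ct is None


@dataclass(frozen=True)
class DropletCount:
    """One ddPCR well: positive droplets out of the accepted total."""

    meta: SampleMeta
    assay: str
    positives: int
    total_droplets: int
    droplet_volume_nl: float = DEFAULT_DROPLET_VOLUME_NL
    platform: str = field(default=DDPCR_PLATFORM, init=False)

    def __post_init__(self):
        if self.assay not in ASSAYS:
            raise ValidationError(f"unknown assay {self.assay!r}")
        if self.total_droplets < 1:
            raise ValidationError("total_droplets must be >= 1")
        if not 0 <= self.positives <= self.total_droplets:
            raise ValidationError(
                f"positives={self.positives} outside [0, {self.total_droplets}]"
            )
        if self.droplet_volume_nl <= 0:
            raise ValidationError("droplet_volume_nl must be positive")


Measurement = Union[CtMeasurement, DropletCount]


def _fmt(x) -> str:
    if x is None:
        return ""
    if isinstance(x, float):
        return repr(x)
    return str(x)


def measurements_to_frame(records: Sequence[Measurement]) -> pd.DataFrame:
    """Flatten typed records into the on-disk column layout.

    Ct cells hold floats with NaN for undetermined/ddPCR rows; droplet
    cells are NaN on qPCR/TLDA rows.
    """
    rows = []
    for rec in records:
        m = rec.meta
        row = {
            "experiment_id": m.experiment_id,
            "sample_id": m.sample_id,
            "subject_id": m.subject_id,
            "material": m.material,
            "protocol": m.protocol,
            "draw_order": m.draw_order,
            "run_day": m.run_day,
            "rt_replicate": m.rt_replicate,
            "pcr_replicate": m.pcr_replicate,
            "platform": rec.platform,
            "assay": rec.assay,
            "ct": float("nan"),
            "positives": float("nan"),
            "total_droplets": float("nan"),
            "droplet_volume_nl": float("nan"),
            "undetermined": False,
        }
        if isinstance(rec, CtMeasurement):
            row["ct"] = float("nan") if rec.ct is None else rec.ct
            row["undetermined"] = rec.ct is None
        else:
            row["positives"] = rec.positives
            row["total_droplets"] = rec.total_droplets
            row["droplet_volume_nl"] = rec.droplet_volume_nl
        rows.append(row)
    return pd.DataFrame(rows, columns=list(COLUMNS) + ["undetermined"])


def _parse_int(cell: str, column: str, rownum: int) -> int | None:
    if cell == "":
        return None
    try:
        return int(cell)
    except ValueError:
        raise ValidationError(
            f"row {rownum}: column {column!r} has non-integer value {cell!r}"
        ) from None


def _parse_float(cell: str, column: str, rownum: int) -> float | None:
    if cell == "":
        return None
    try:
        return float(cell)
    except ValueError:
        raise ValidationError(
            f"row {rownum}: column {column!r} has non-numeric value {cell!r}"
        ) from None


def _infer_dialect(path: Path, dialect: str | None) -> str:
    if dialect is not None:
        if dialect not in ("csv", "xlsx"):
            raise ValueError(f"dialect must be 'csv' or 'xlsx', got {dialect!r}")
        return dialect
    return "xlsx" if path.suffix.lower() in (".xlsx", ".xlsm") else "csv"


def read_measurements(
    path: str | Path, dialect: str | None = None
) -> list[Measurement]:
    """Read a long-format plate table into typed records.

    Row order is preserved; every row becomes exactly one record. Ct
    cells holding the literal ``Undetermined`` (case-insensitive) or left
    empty map to the undetermined state, as do Ct values beyond the
    40-cycle program.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if _infer_dialect(path, dialect) == "xlsx":
        raw = pd.read_excel(path, dtype=str).fillna("")
    else:
        raw = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in COLUMNS if c not in raw.columns]
    if missing:
        raise SchemaError(f"missing mandatory column(s): {', '.join(missing)}")

    records: list[Measurement] = []
    for i, row in enumerate(raw.itertuples(index=False), start=2):
        cells = {c: str(getattr(row, c)).strip() for c in COLUMNS}
        platform = cells["platform"]
        if platform not in PLATFORMS:
            raise ValidationError(f"row {i}: unknown platform {platform!r}")
        if cells["assay"] not in ASSAYS:
            raise ValidationError(f"row {i}: unknown assay {cells['assay']!r}")
        try:
            meta = SampleMeta(
                sample_id=cells["sample_id"],
                subject_id=cells["subject_id"],
                material=cells["material"],
                protocol=cells["protocol"],
                experiment_id=cells["experiment_id"],
                draw_order=_parse_int(cells["draw_order"], "draw_order", i),
                run_day=_parse_int(cells["run_day"], "run_day", i) or 1,
                rt_replicate=_parse_int(cells["rt_replicate"], "rt_replicate", i)
                or 1,
                pcr_replicate=_parse_int(cells["pcr_replicate"], "pcr_replicate", i)
                or 1,
            )
        except ValidationError as exc:
            raise ValidationError(f"row {i}: {exc}") from None
        if platform == DDPCR_PLATFORM:
            k = _parse_int(cells["positives"], "positives", i)
            n = _parse_int(cells["total_droplets"], "total_droplets", i)
            if k is None or n is None:
                raise ValidationError(
                    f"row {i}: ddPCR row lacks positives/total_droplets"
                )
            vol = _parse_float(cells["droplet_volume_nl"], "droplet_volume_nl", i)
            try:
                records.append(
                    DropletCount(
                        meta=meta,
                        assay=cells["assay"],
                        positives=k,
                        total_droplets=n,
                        droplet_volume_nl=(
                            DEFAULT_DROPLET_VOLUME_NL if vol is None else vol
                        ),
                    )
                )
            except ValidationError as exc:
                raise ValidationError(f"row {i}: {exc}") from None
        else:
            ct_cell = cells["ct"]
            if ct_cell == "" or ct_cell.lower() == UNDETERMINED.lower():
                ct: float | None = None
            else:
                ct = _parse_float(ct_cell, "ct", i)
                if ct is not None and ct > CYCLE_MAX:
                    ct = None  # beyond the thermal program: undetermined
            try:
                records.append(
                    CtMeasurement(meta=meta, assay=cells["assay"],
                                  platform=platform, ct=ct)
                )
            except ValidationError as exc:
                raise ValidationError(f"row {i}: {exc}") from None
    return records


def write_measurements(
    records: Iterable[Measurement], path: str | Path, dialect: str | None = None
) -> Path:
    """Write records in the deterministic on-disk column order.

    Re-reading the file reproduces the records exactly (round-trip
    identity). Undetermined Cts are written as the literal
    ``Undetermined``, matching the ABI export convention.
    """
    records = list(records)
    if not records:
        raise ValueError("cannot write an empty record collection")
    path = Path(path)

    rows = []
    for rec in records:
        m = rec.meta
        row = {
            "experiment_id": m.experiment_id,
            "sample_id": m.sample_id,
            "subject_id": m.subject_id,
            "material": m.material,
            "protocol": m.protocol,
            "draw_order": "" if m.draw_order is None else m.draw_order,
            "run_day": m.run_day,
            "rt_replicate": m.rt_replicate,
            "pcr_replicate": m.pcr_replicate,
            "platform": rec.platform,
            "assay": rec.assay,
            "ct": "",
            "positives": "",
            "total_droplets": "",
            "droplet_volume_nl": "",
        }
        if isinstance(rec, CtMeasurement):
            row["ct"] = UNDETERMINED if rec.ct is None else _fmt(rec.ct)
        else:
            row["positives"] = rec.positives
            row["total_droplets"] = rec.total_droplets
            row["droplet_volume_nl"] = _fmt(rec.droplet_volume_nl)
        rows.append(row)
    frame = pd.DataFrame(rows, columns=list(COLUMNS))
    if _infer_dialect(path, dialect) == "xlsx":
        frame.to_excel(path, index=False)
    else:
        frame.to_csv(path, index=False)
    return path


def with_meta(rec: Measurement, **meta_updates) -> Measurement:
    """Return a copy of ``rec`` with fields of its SampleMeta replaced."""
    return replace(rec, meta=replace(rec.meta, **meta_updates))
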