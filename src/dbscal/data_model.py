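"""Domain types, device registry and measurement-table I/O.

The pipeline starts from integrated LC-MS/MS peak areas: one
:class:`MeasurementRecord` per injection holds the analyte and internal-standard
(IS) peak areas together with the experimental context (device, analyte, role in
the validation design, nominal concentration, day/replicate, injection time for
stability series).  Quantification everywhere uses the analyte/IS area *ratio*.

Devices are described by :class:`DeviceProfile`: the actual blood volume the
device samples (the quantity cross-device volume normalisation relies on),
per-analyte extraction efficiency, per-(analyte, level-band) matrix effect, and
the noise parameters the synthetic generator uses.  The built-in registry
carries the three dried-blood-spot systems studied here; because e.g. the
actual volume of Mitra tips varies between manufacturing batches, the registry
is data and can be overridden from a YAML/JSON config file.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import pandas as pd
import yaml

__all__ = [
    "ANALYTES",
    "ROLES",
    "MeasurementRecord",
    "DeviceProfile",
    "MeasurementSet",
    "SchemaError",
    "RowParseError",
    "load_measurement_table",
    "write_measurement_table",
    "get_device_profile",
    "builtin_device_profiles",
    "load_device_registry",
]

#: The two phosphatidylethanol homologues the assay quantifies.
ANALYTES = ("peth_16_0_18_1", "peth_16_0_18_2")

#: Roles a measurement can play in the validation design.
ROLES = ("calibration", "qc", "neat_standard", "post_spike", "pre_spike", "stability")

#: Concentration (ng/mL) below which the "low" matrix-effect band applies.
LEVEL_BAND_THRESHOLD = 100.0

#: Columns of the measurement-table CSV format.
TABLE_COLUMNS = [
    "device",
    "analyte",
    "role",
    "nominal_conc",
    "day",
    "replicate",
    "time_h",
    "analyte_area",
    "is_area",
]


class SchemaError(ValueError):
    """A measurement table is structurally invalid (e.g. missing column)."""


class RowParseError(ValueError):
    """A single row of a measurement table could not be parsed."""


@dataclass(frozen=True)
class MeasurementRecord:
    """One injection: peak areas plus the experimental context.

    ``ratio`` (analyte area / IS area) is derived, never stored, so it can
    never disagree with the areas.
    """

    device: str
    analyte: str
    role: str
    nominal_conc: float
    day: int
    replicate: int
    analyte_area: float
    is_area: float
    time_h: float | None = None

    def __post_init__(self) -> None:
        if self.analyte not in ANALYTES:
            raise ValueError(f"unknown analyte {self.analyte!r}; expected one of {ANALYTES}")
        if self.role not in ROLES:
            raise ValueError(f"unknown role {self.role!r}; expected one of {ROLES}")
        if not self.nominal_conc >= 0:
            raise ValueError(f"nominal_conc must be >= 0, got {self.nominal_conc}")
        if self.day < 1 or self.replicate < 1:
            raise ValueError("day and replicate are 1-based positive integers")
        if not self.analyte_area >= 0:
            raise ValueError(f"analyte_area must be >= 0, got {self.analyte_area}")
        if not self.is_area > 0:
            raise ValueError(f"is_area must be > 0, got {self.is_area}")
        if (self.role == "stability") != (self.time_h is not None):
            raise ValueError("time_h must be present iff role == 'stability'")
        if self.time_h is not None and not self.time_h >= 0:
            raise ValueError(f"time_h must be >= 0, got {self.time_h}")
        if not math.isfinite(self.ratio):
            raise ValueError("analyte/IS ratio is not finite")

    @property
    def ratio(self) -> float:
        """Analyte / internal-standard peak-area ratio (the quantified response)."""
        return self.analyte_area / self.is_area

    @property
    def key(self) -> tuple:
        """Identity of the design point this record occupies."""
        return (
            self.device,
            self.analyte,
            self.role,
            self.nominal_conc,
            self.day,
            self.replicate,
            self.time_h,
        )


@dataclass(frozen=True)
class DeviceProfile:
    """A DBS sampling device: volumes, recovery, matrix effect, noise.

    Parameters
    ----------
    name
        Device identifier (``whatman``, ``mitra``, ``capitainer`` built in).
    nominal_volume, actual_volume
        Nominal and actual blood volume in µL.  Cross-device quantification
        corrects concentrations by the ratio of *actual* volumes.
    extraction_efficiency
        Fraction of analyte recovered from the dried spot, per analyte, in
        (0, 1].
    matrix_effect
        Signal alteration by co-extracted matrix, per analyte and level band
        (``low``/``high``, split at ``LEVEL_BAND_THRESHOLD`` ng/mL), as a
        positive fraction (1.0 = no effect).
    cv_within, cv_between
        Within-day and between-day coefficients of variation of the response,
        as fractions; used by the synthetic generator.
    """

    name: str
    nominal_volume: float
    actual_volume: float
    extraction_efficiency: dict[str, float]
    matrix_effect: dict[str, dict[str, float]]
    cv_within: float
    cv_between: float

    def __post_init__(self) -> None:
        if not self.actual_volume > 0:
            raise ValueError(f"actual_volume must be > 0, got {self.actual_volume}")
        for analyte, ee in self.extraction_efficiency.items():
            if not 0 < ee <= 1:
                raise ValueError(f"extraction_efficiency[{analyte!r}] must be in (0, 1], got {ee}")
        for analyte, bands in self.matrix_effect.items():
            for band, me in bands.items():
                if not me > 0:
                    raise ValueError(f"matrix_effect[{analyte!r}][{band!r}] must be > 0, got {me}")
        if self.cv_within < 0 or self.cv_between < 0:
            raise ValueError("cv_within and cv_between must be >= 0")

    def ee(self, analyte: str) -> float:
        return self.extraction_efficiency[analyte]

    def me(self, analyte: str, conc: float) -> float:
        band = "low" if conc < LEVEL_BAND_THRESHOLD else "high"
        return self.matrix_effect[analyte][band]

    def replace(self, **changes) -> "DeviceProfile":
        return dataclasses.replace(self, **changes)


@dataclass
class MeasurementSet:
    """A collection of measurement records plus their provenance.

    Rejects duplicate design points: two records may not share the full
    (device, analyte, role, nominal_conc, day, replicate, time_h) key.
    """

    records: list[MeasurementRecord]
    provenance: str = ""

    def __post_init__(self) -> None:
        if not self.records:
            raise ValueError("MeasurementSet must be non-empty")
        seen: set[tuple] = set()
        for rec in self.records:
            if rec.key in seen:
                raise ValueError(f"duplicate measurement key {rec.key}")
            seen.add(rec.key)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def filter(self, **criteria) -> "MeasurementSet":
        """Subset by record attributes, e.g. ``s.filter(role="qc", nominal_conc=210.0)``."""
        kept = [
            r for r in self.records
            if all(getattr(r, k) == v for k, v in criteria.items())
        ]
        if not kept:
            raise ValueError(f"no records match {criteria}")
        return MeasurementSet(kept, provenance=self.provenance)

    def ratios(self) -> list[float]:
        return [r.ratio for r in self.records]

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "device": r.device,
                "analyte": r.analyte,
                "role": r.role,
                "nominal_conc": r.nominal_conc,
                "day": r.day,
                "replicate": r.replicate,
                "time_h": r.time_h,
                "analyte_area": r.analyte_area,
                "is_area": r.is_area,
            }
            for r in self.records
        ]
        return pd.DataFrame(rows, columns=TABLE_COLUMNS)

    @staticmethod
    def merge(sets: Iterable["MeasurementSet"], provenance: str = "") -> "MeasurementSet":
        records: list[MeasurementRecord] = []
        for s in sets:
            records.extend(s.records)
        return MeasurementSet(records, provenance=provenance)


# --- measurement-table I/O -------------------------------------------------
#
# CSV dialect: comma-separated, UTF-8, '.' decimal separator, mandatory header,
# column order free (header-keyed).  Floats are written with repr() precision
# so load(write(s)) reproduces every field bit-identically.

_REQUIRED = [c for c in TABLE_COLUMNS if c != "time_h"]


def load_measurement_table(path: str | Path) -> MeasurementSet:
    """Read a measurement-table CSV into a :class:`MeasurementSet`.

    Raises
    ------
    SchemaError
        If a mandatory column is missing.
    RowParseError
        If a row holds non-numeric areas or otherwise fails validation; the
        message carries the (0-based) row index.
    """
    path = Path(path)
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    for col in _REQUIRED:
        if col not in df.columns:
            raise SchemaError(f"measurement table {path} lacks mandatory column {col!r}")
    has_time = "time_h" in df.columns
    records = []
    for idx, row in enumerate(df.itertuples(index=False)):
        raw = dict(zip(df.columns, row))
        try:
            time_raw = raw.get("time_h", "") if has_time else ""
            time_h = float(time_raw) if time_raw not in ("", "nan") else None
            records.append(
                MeasurementRecord(
                    device=raw["device"],
                    analyte=raw["analyte"],
                    role=raw["role"],
                    nominal_conc=float(raw["nominal_conc"]),
                    day=int(raw["day"]),
                    replicate=int(raw["replicate"]),
                    time_h=time_h,
                    analyte_area=float(raw["analyte_area"]),
                    is_area=float(raw["is_area"]),
                )
            )
        except (TypeError, ValueError) as exc:
            raise RowParseError(f"row {idx} of {path}: {exc}") from exc
    return MeasurementSet(records, provenance=str(path))


def write_measurement_table(mset: MeasurementSet, path: str | Path) -> Path:
    """Write a :class:`MeasurementSet` to CSV; round-trips bit-identically."""
    path = Path(path)
    lines = [",".join(TABLE_COLUMNS)]
    for r in mset:
        lines.append(
            ",".join(
                [
                    r.device,
                    r.analyte,
                    r.role,
                    repr(r.nominal_conc),
                    str(r.day),
                    str(r.replicate),
                    "" if r.time_h is None else repr(r.time_h),
                    repr(r.analyte_area),
                    repr(r.is_area),
                ]
            )
        )
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")
    return path


# --- device registry -------------------------------------------------------
#
# Actual sample volumes: 20 µL (Whatman 903 filter paper), 23.7 µL (Mitra
# VAMS tips, batch-dependent), 10 µL (Capitainer B Vanadate).  Extraction
# efficiencies are the per-device means (67/57/69 %); matrix effects the
# per-device means (103/97/99 %), applied in both level bands so the response
# stays strictly proportional to concentration across the calibration range
# (band-specific values such as the Mitra low-level ion suppression can be
# configured explicitly).  CVs are set so simulated repeatability and
# intermediate-precision RSDs fall inside the observed per-device ranges.


def _uniform_me(value: float) -> dict[str, dict[str, float]]:
    return {a: {"low": value, "high": value} for a in ANALYTES}


def builtin_device_profiles() -> dict[str, DeviceProfile]:
    """The three studied DBS devices with study-condition parameters."""
    return {
        "whatman": DeviceProfile(
            name="whatman",
            nominal_volume=20.0,
            actual_volume=20.0,
            extraction_efficiency={a: 0.67 for a in ANALYTES},
            matrix_effect=_uniform_me(1.03),
            cv_within=0.028,
            cv_between=0.028,
        ),
        "mitra": DeviceProfile(
            name="mitra",
            nominal_volume=20.0,
            actual_volume=23.7,
            extraction_efficiency={a: 0.57 for a in ANALYTES},
            matrix_effect=_uniform_me(0.97),
            cv_within=0.040,
            cv_between=0.040,
        ),
        "capitainer": DeviceProfile(
            name="capitainer",
            nominal_volume=10.0,
            actual_volume=10.0,
            extraction_efficiency={a: 0.69 for a in ANALYTES},
            matrix_effect=_uniform_me(0.99),
            cv_within=0.023,
            cv_between=0.023,
        ),
    }


def get_device_profile(
    name: str, registry: dict[str, DeviceProfile] | None = None
) -> DeviceProfile:
    """Look up a device profile by name in the registry (built-in by default)."""
    registry = registry if registry is not None else builtin_device_profiles()
    try:
        return registry[name]
    except KeyError:
        raise KeyError(
            f"unknown device {name!r}; registered devices: {sorted(registry)}"
        ) from None


def load_device_registry(path: str | Path) -> dict[str, DeviceProfile]:
    """Load a device registry from a YAML or JSON config file.

    The file maps device names to DeviceProfile fields; devices not listed fall
    back to the built-in profiles, listed devices replace them entirely.
    """
    path = Path(path)
    text = path.read_text(encoding="utf-8")
    data = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    registry = builtin_device_profiles()
    for name, fields in (data or {}).items():
        registry[name] = DeviceProfile(name=name, **fields)
    return registry
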