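"""Cross-device quantification, transferability matrix and study orchestration.

The central question: can a QC sampled on one dried-blood-spot device be
quantified accurately with the calibration curve of *another* device?  Because
the devices sample different actual blood volumes (Whatman 20 µL, Mitra
23.7 µL, Capitainer 10 µL), back-calculated concentrations are multiplied by
the volume-correction factor V_cal / V_sample before comparison with nominal.
Each (sample device, calibration device, QC level, analyte) cell is summarised
by bias, repeatability RSD and intermediate-precision RSD, classified into
traffic-light bands (|value| < 10 % green, 10-15 % yellow, > 15 % red) and a
(sample, cal) device pair passes the GTFCh criterion iff every one of its
cells keeps |bias| and both RSDs within 15 %.

``run_full_study`` orchestrates a complete synthetic validation: per device
and homologue it generates calibration, low-range, QC, matrix-effect/recovery
and stability sets, fits and qualifies the calibrations, computes the
validation metrics and builds the full 3 x 3 transferability matrix, writing
JSON, CSV and Markdown reports.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import synthgen
from .calibration import (
    CalibrationFit,
    back_calculate,
    cochran_test,
    din32645_limits,
    fit_weighted_calibration,
    mandel_test,
    screen_outliers,
)
from .data_model import ANALYTES, DeviceProfile, MeasurementSet
from .synthgen import (
    EXTERNAL_QC_TARGETS,
    GeneratorConfig,
    generate_calibration_set,
    generate_lodloq_set,
    generate_me_ee_sets,
    generate_qc_series,
    generate_stability_series,
)
from .valmetrics import (
    RSD_BIAS_LIMIT,
    extraction_efficiency,
    matrix_effect,
    precision_accuracy,
    stability_assess,
)

__all__ = [
    "TransferabilityCell",
    "TransferabilityReport",
    "volume_correction_factor",
    "cross_quantify",
    "classify_band",
    "build_transferability_matrix",
    "gtfch_acceptance",
    "run_full_study",
]

DEVICES = ("whatman", "mitra", "capitainer")


def volume_correction_factor(cal_device: DeviceProfile, sample_device: DeviceProfile) -> float:
    """Multiplicative correction V_cal / V_sample for foreign-calibration results."""
    if cal_device.actual_volume <= 0 or sample_device.actual_volume <= 0:
        raise ValueError("actual volumes must be > 0")
    return cal_device.actual_volume / sample_device.actual_volume


def classify_band(value: float) -> str:
    """Traffic-light band of a bias/RSD percentage (absolute value)."""
    if math.isnan(value):
        raise ValueError("cannot classify NaN")
    v = abs(value)
    if v < 10.0:
        return "green"
    if v <= 15.0:
        return "yellow"
    return "red"


def cross_quantify(
    qc: MeasurementSet,
    fit: CalibrationFit,
    cal_device: DeviceProfile,
    sample_device: DeviceProfile,
) -> tuple[np.ndarray, np.ndarray]:
    """Quantify QC records with a (possibly foreign) calibration.

    Back-calculates every record's ratio with ``fit`` and applies the
    volume-correction factor.  Returns (corrected concentrations, flags) where
    a flag marks a back-calculated value outside the calibration range
    (extrapolation) or below zero; flagged values are retained, not dropped.
    """
    mismatched = {r.device for r in qc} - {sample_device.name}
    if mismatched:
        raise ValueError(
            f"QC records from devices {sorted(mismatched)} do not match sample device "
            f"{sample_device.name!r}"
        )
    ratios = np.array(qc.ratios())
    raw, neg = back_calculate(fit, ratios)
    lo, hi = fit.range
    flags = neg | (raw < lo) | (raw > hi)
    factor = volume_correction_factor(cal_device, sample_device)
    return raw * factor, flags


@dataclass(frozen=True)
class TransferabilityCell:
    """One (sample device, calibration device, QC level, analyte) combination."""

    sample_device: str
    cal_device: str
    analyte: str
    qc_level: float
    corrected_concs: tuple[float, ...]
    bias: float
    rsd_r: float
    rsd_I: float
    band_bias: str
    band_rsd: str
    n_flagged: int = 0

    @property
    def acceptable(self) -> bool:
        return (
            abs(self.bias) <= RSD_BIAS_LIMIT
            and self.rsd_r <= RSD_BIAS_LIMIT
            and self.rsd_I <= RSD_BIAS_LIMIT
        )

    def to_dict(self) -> dict:
        return {
            "sample_device": self.sample_device,
            "cal_device": self.cal_device,
            "analyte": self.analyte,
            "qc_level": self.qc_level,
            "bias": self.bias,
            "rsd_r": self.rsd_r,
            "rsd_I": self.rsd_I,
            "band_bias": self.band_bias,
            "band_rsd": self.band_rsd,
            "n_flagged": self.n_flagged,
            "acceptable": self.acceptable,
        }


@dataclass
class TransferabilityReport:
    """All transferability cells plus per-(sample, cal) pair verdicts."""

    cells: list[TransferabilityCell]
    provenance: dict = field(default_factory=dict)
    gaps: list[dict] = field(default_factory=list)

    def pairs(self) -> list[tuple[str, str]]:
        return sorted({(c.sample_device, c.cal_device) for c in self.cells})

    def cells_for(self, sample_device: str, cal_device: str) -> list[TransferabilityCell]:
        return [
            c for c in self.cells
            if c.sample_device == sample_device and c.cal_device == cal_device
        ]

    def diagonal(self) -> list[TransferabilityCell]:
        return [c for c in self.cells if c.sample_device == c.cal_device]

    def to_dict(self) -> dict:
        return {
            "cells": [c.to_dict() for c in self.cells],
            "verdicts": {f"{s}|{c}": v for (s, c), v in gtfch_acceptance(self).items()},
            "gaps": self.gaps,
            "provenance": self.provenance,
        }


def gtfch_acceptance(report: TransferabilityReport) -> dict[tuple[str, str], bool]:
    """Per (sample, cal) pair: every cell within +-15 % for bias and both RSDs."""
    return {
        pair: all(c.acceptable for c in report.cells_for(*pair))
        for pair in report.pairs()
    }


def _cell_from_concs(
    sample_device: str,
    cal_device: str,
    analyte: str,
    level: float,
    concs: np.ndarray,
    flags: np.ndarray,
    days: np.ndarray,
) -> TransferabilityCell:
    order = np.argsort(days, kind="stable")
    concs, days = concs[order], days[order]
    by_day = [concs[days == d] for d in np.unique(days)]
    dec = precision_accuracy(by_day, nominal=level)
    worst_rsd = max(dec.rsd_r, dec.rsd_I)
    return TransferabilityCell(
        sample_device=sample_device,
        cal_device=cal_device,
        analyte=analyte,
        qc_level=level,
        corrected_concs=tuple(float(c) for c in concs),
        bias=dec.bias,
        rsd_r=dec.rsd_r,
        rsd_I=dec.rsd_I,
        band_bias=classify_band(dec.bias),
        band_rsd=classify_band(worst_rsd),
        n_flagged=int(flags.sum()),
    )


def build_transferability_matrix(
    qc_sets: dict[tuple[str, str], MeasurementSet],
    fits: dict[tuple[str, str], CalibrationFit],
    profiles: dict[str, DeviceProfile],
    provenance: dict | None = None,
) -> TransferabilityReport:
    """Populate every (sample, cal, level, analyte) cell of the matrix.

    ``qc_sets`` and ``fits`` are keyed by (device, analyte).  A missing
    (sample, cal, analyte) combination produces an explicit gap entry rather
    than a silently absent cell.
    """
    cells: list[TransferabilityCell] = []
    gaps: list[dict] = []
    devices = sorted({d for d, _ in qc_sets} | {d for d, _ in fits})
    analytes = sorted({a for _, a in qc_sets})
    for analyte in analytes:
        for sample_dev in devices:
            for cal_dev in devices:
                qc = qc_sets.get((sample_dev, analyte))
                fit = fits.get((cal_dev, analyte))
                if qc is None or fit is None:
                    gaps.append(
                        {"sample_device": sample_dev, "cal_device": cal_dev,
                         "analyte": analyte,
                         "missing": "qc" if qc is None else "calibration"}
                    )
                    continue
                levels = sorted({r.nominal_conc for r in qc})
                for level in levels:
                    sub = qc.filter(nominal_conc=level)
                    concs, flags = cross_quantify(
                        sub, fit, profiles[cal_dev], profiles[sample_dev]
                    )
                    days = np.array([r.day for r in sub])
                    cells.append(
                        _cell_from_concs(sample_dev, cal_dev, analyte, level, concs, flags, days)
                    )
    return TransferabilityReport(cells=cells, provenance=provenance or {}, gaps=gaps)


# --- full-study orchestration ----------------------------------------------


def _config_hash(config: GeneratorConfig) -> str:
    blob = json.dumps(
        {
            "devices": {
                n: {
                    "nominal_volume": p.nominal_volume,
                    "actual_volume": p.actual_volume,
                    "extraction_efficiency": p.extraction_efficiency,
                    "matrix_effect": p.matrix_effect,
                    "cv_within": p.cv_within,
                    "cv_between": p.cv_between,
                }
                for n, p in sorted(config.device_profiles.items())
            },
            "response_factor": config.response_factor,
            "is_amount": config.is_amount,
            "is_response_factor": config.is_response_factor,
            "noise_model": config.noise_model,
            "day_effect_sd": config.day_effect_sd,
            "degradation_per_h": config.degradation_per_h,
        },
        sort_keys=True,
    )
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _validate_one(config: GeneratorConfig, device: str, analyte: str, seed: int) -> dict:
    """Single-device validation: calibration qualification, limits, ME/EE, stability."""
    cal_set = generate_calibration_set(config, device, analyte, seed)
    points = [(r.nominal_conc, r.ratio) for r in cal_set]
    fit = fit_weighted_calibration(points, weighting="one_over_x")
    levels = sorted({r.nominal_conc for r in cal_set})
    groups = [[r.ratio for r in cal_set if r.nominal_conc == lv] for lv in levels]

    lod_set = generate_lodloq_set(config, device, analyte, seed)
    limits = din32645_limits([(r.nominal_conc, r.ratio) for r in lod_set])

    me_ee = generate_me_ee_sets(config, device, analyte, seed)
    me_results, ee_results = [], []
    for level in sorted({r.nominal_conc for r in me_ee}):
        neat = me_ee.filter(nominal_conc=level, role="neat_standard").ratios()
        post = me_ee.filter(nominal_conc=level, role="post_spike").ratios()
        pre = me_ee.filter(nominal_conc=level, role="pre_spike").ratios()
        me_results.append(matrix_effect(neat, post, level=level))
        ee_results.append(extraction_efficiency(pre, post, level=level))

    stab = generate_stability_series(config, device, analyte, seed)
    stab_results = [
        stability_assess(
            [(r.time_h, r.analyte_area) for r in stab.filter(nominal_conc=level)],
            level=level,
        )
        for level in sorted({r.nominal_conc for r in stab})
    ]

    return {
        "fit": fit,
        "mandel": mandel_test(points),
        "cochran": cochran_test(groups),
        "outliers": screen_outliers(points),
        "limits": limits,
        "matrix_effect": me_results,
        "extraction_efficiency": ee_results,
        "stability": stab_results,
    }


def run_full_study(
    config: GeneratorConfig | None = None,
    seed: int = 0,
    out_dir: str | Path | None = None,
) -> tuple[TransferabilityReport, dict]:
    """Run the complete simulated validation and cross-validation study.

    Generates all designs for the three devices and both homologues, qualifies
    and fits the calibrations, computes the per-device validation metrics and
    the full transferability matrix, and (if ``out_dir`` is given) writes
    ``transferability.json`` / ``transferability.csv`` / ``report.md``.
    Fully reproducible from (config, seed).
    """
    config = config or GeneratorConfig()
    validation: dict[tuple[str, str], dict] = {}
    fits: dict[tuple[str, str], CalibrationFit] = {}
    qc_sets: dict[tuple[str, str], MeasurementSet] = {}
    devices = sorted(config.device_profiles)
    for device in devices:
        for analyte in ANALYTES:
            validation[(device, analyte)] = _validate_one(config, device, analyte, seed)
            fits[(device, analyte)] = validation[(device, analyte)]["fit"]
            qc_sets[(device, analyte)] = generate_qc_series(
                config, device, analyte, seed, include_external=True
            )

    provenance = {"seed": seed, "config_hash": _config_hash(config)}
    report = build_transferability_matrix(
        qc_sets, fits, config.device_profiles, provenance=provenance
    )

    validation_summary = {
        f"{device}|{analyte}": {
            "calibration": {
                **v["fit"].to_dict(),
                "mandel": v["mandel"].to_dict(),
                "cochran": v["cochran"].to_dict(),
                "outliers": v["outliers"].to_dict(),
            },
            "limits": {"lod": v["limits"].lod, "loq": v["limits"].loq},
            "matrix_effect": [m.to_dict() for m in v["matrix_effect"]],
            "extraction_efficiency": [m.to_dict() for m in v["extraction_efficiency"]],
            "stability": [m.to_dict() for m in v["stability"]],
        }
        for (device, analyte), v in sorted(validation.items())
    }

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        try:
            _write_reports(out, report, validation_summary)
        except Exception:
            for name in ("transferability.json", "transferability.csv", "report.md", "validation.json"):
                (out / name).unlink(missing_ok=True)
            raise
    return report, validation_summary


def _write_reports(out: Path, report: TransferabilityReport, validation: dict) -> None:
    (out / "transferability.json").write_text(
        json.dumps(report.to_dict(), indent=2, sort_keys=True) + "\n", encoding="utf-8"
    )
    (out / "validation.json").write_text(
        json.dumps(validation, indent=2, sort_keys=True) + "\n", encoding="utf-8"
    )
    header = "sample_device,cal_device,analyte,qc_level,bias,rsd_r,rsd_I,band_bias,band_rsd,n_flagged,acceptable"
    rows = [header] + [
        f"{c.sample_device},{c.cal_device},{c.analyte},{c.qc_level:g},"
        f"{c.bias:.6f},{c.rsd_r:.6f},{c.rsd_I:.6f},{c.band_bias},{c.band_rsd},"
        f"{c.n_flagged},{str(c.acceptable).lower()}"
        for c in report.cells
    ]
    (out / "transferability.csv").write_text("\n".join(rows) + "\n", encoding="utf-8")
    (out / "report.md").write_text(_markdown_report(report), encoding="utf-8")


def _markdown_report(report: TransferabilityReport) -> str:
    lines = ["# Cross-device calibration transferability", ""]
    lines.append(f"Provenance: `{report.provenance}`")
    verdicts = gtfch_acceptance(report)
    for analyte in sorted({c.analyte for c in report.cells}):
        lines += ["", f"## {analyte}", ""]
        acells = [c for c in report.cells if c.analyte == analyte]
        for metric, attr in (("bias %", "bias"), ("RSD_r %", "rsd_r"), ("RSD_I %", "rsd_I")):
            lines += [f"### {metric}", ""]
            sample_devs = sorted({c.sample_device for c in acells})
            cal_devs = sorted({c.cal_device for c in acells})
            lines.append("| sample \\ calibration | " + " | ".join(cal_devs) + " |")
            lines.append("|---" * (len(cal_devs) + 1) + "|")
            for s in sample_devs:
                row = [s]
                for c_dev in cal_devs:
                    cells = [c for c in acells if c.sample_device == s and c.cal_device == c_dev]
                    entries = [
                        f"{getattr(c, attr):+.1f} ({classify_band(getattr(c, attr))})"
                        if attr == "bias"
                        else f"{getattr(c, attr):.1f} ({classify_band(getattr(c, attr))})"
                        for c in sorted(cells, key=lambda c: c.qc_level)
                    ]
                    row.append("<br>".join(entries) if entries else "gap")
                lines.append("| " + " | ".join(row) + " |")
            lines.append("")
    lines += ["## GTFCh verdicts (all cells within +-15 %)", ""]
    for (s, c_dev), ok in sorted(verdicts.items()):
        lines.append(f"- sample `{s}` with `{c_dev}` calibration: {'PASS' if ok else 'FAIL'}")
    return "\n".join(lines) + "\n"
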