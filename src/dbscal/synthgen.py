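"""Seeded synthetic measurement generator.

Emulates the statistical structure of the validation study so every downstream
stage is testable without instrument data.  The detector model is linear: the
expected analyte/IS peak-area ratio for a sample at nominal concentration
``C`` (ng/mL) on a device with actual volume ``V`` (µL) is

* pre-extraction spike / calibration / QC / stability samples (analyte went
  through the dried matrix)::

      E[ratio] = kappa * C * V * EE * ME / (m_IS * kappa_IS)

* post-extraction spikes (analyte added to a blank extract, so no extraction
  loss)::

      E[ratio] = kappa * C * V * ME / (m_IS * kappa_IS)

* neat standards in solvent (no matrix at all)::

      E[ratio] = kappa * C * V / (m_IS * kappa_IS)

with ``kappa`` the analyte response factor (counts per ng/mL·µL), ``EE`` the
device extraction efficiency, ``ME`` the matrix effect, ``m_IS`` the absolute
internal-standard amount (20 µL of a 50 ng/mL working solution = 1 ng) and
``kappa_IS`` its response factor (counts per ng).  Neat standards and
post-extraction spikes use the device's actual volume as the reference volume,
so the matrix-effect and extraction-efficiency estimators isolate exactly the
ME and EE factors.

Noise is multiplicative lognormal with unit mean: a within-day factor drawn
per record (CV ``cv_within``) and a between-day factor shared by all
replicates of a (device, analyte, level, day) cell (CV ``cv_between``), which
is the variance component the day-wise ANOVA precision estimator must recover.
The IS area carries the within-day CV but no EE/ME factor, so the generator's
ME parameter coincides with the ratio-level ME the estimators report.
Lognormal parameters are chosen so the realised CV equals the configured CV
(sigma^2 = ln(1 + cv^2), mu = -sigma^2/2); at the small CVs relevant here
(2-8 %) lognormal and normal noise are indistinguishable, but areas stay
strictly positive.
"""

from __future__ import annotations

import math
import zlib
from dataclasses import dataclass, field, replace

import numpy as np

from .data_model import (
    ANALYTES,
    DeviceProfile,
    MeasurementRecord,
    MeasurementSet,
    builtin_device_profiles,
)

__all__ = [
    "GeneratorConfig",
    "CALIBRATION_LEVELS",
    "LODLOQ_LEVELS",
    "QC_LEVELS",
    "EXTERNAL_QC_TARGETS",
    "ME_EE_LEVELS",
    "STABILITY_TIMES_H",
    "expected_ratio",
    "simulate_measurement",
    "generate_calibration_set",
    "generate_lodloq_set",
    "generate_qc_series",
    "generate_me_ee_sets",
    "generate_stability_series",
]

#: 8-point calibration levels, ng/mL, analysed on 6 days.
CALIBRATION_LEVELS = (10.0, 25.0, 50.0, 100.0, 200.0, 300.0, 400.0, 500.0)
CALIBRATION_DAYS = 6

#: Low equidistant calibration for detection/quantification limits, ng/mL.
LODLOQ_LEVELS = (2.0, 4.0, 6.0, 8.0, 10.0, 12.0)

#: In-house QC pool levels, ng/mL; duplicates on 8 days.
QC_LEVELS = (20.0, 210.0, 450.0)
QC_DAYS = 8
QC_REPLICATES = 2

#: Certified targets of the external whole-blood accuracy control, ng/mL.
EXTERNAL_QC_TARGETS = {"peth_16_0_18_1": 52.8, "peth_16_0_18_2": 22.6}

#: Low/high levels for matrix-effect / extraction-efficiency triads, ng/mL.
ME_EE_LEVELS = (20.0, 350.0)
ME_EE_REPLICATES = 5

#: Injection times of the processed-sample stability series, hours.
STABILITY_TIMES_H = (0.0, 1.0, 2.0, 4.0, 24.0, 48.0)

_ROLE_STREAM = {
    "calibration": 1,
    "qc": 2,
    "neat_standard": 3,
    "post_spike": 4,
    "pre_spike": 5,
    "stability": 6,
}


@dataclass(frozen=True)
class GeneratorConfig:
    """Everything the generator needs besides a seed.

    ``response_factor`` maps concentration x volume to counts per analyte; the
    detector response and IS magnitude are not reported for the assay, so the
    defaults are free parameters chosen to give realistic area magnitudes
    (~1e4-5e5 counts) and are plainly configuration, not science.
    """

    device_profiles: dict[str, DeviceProfile] = field(default_factory=builtin_device_profiles)
    response_factor: dict[str, float] = field(
        default_factory=lambda: {"peth_16_0_18_1": 50.0, "peth_16_0_18_2": 45.0}
    )
    is_amount: float = 1.0  # ng: 20 µL of the 50 ng/mL IS working solution
    is_response_factor: float = 1.0e6  # counts per ng
    noise_model: str = "lognormal"
    day_effect_sd: float | None = None  # override of per-device cv_between
    degradation_per_h: float = 0.0  # stability: fractional area loss per hour

    def __post_init__(self) -> None:
        if any(v <= 0 for v in self.response_factor.values()):
            raise ValueError("response factors must be > 0")
        if self.is_amount <= 0 or self.is_response_factor <= 0:
            raise ValueError("IS amount and response factor must be > 0")
        if self.noise_model not in ("lognormal", "truncated_normal"):
            raise ValueError(f"unknown noise_model {self.noise_model!r}")

    def noiseless(self) -> "GeneratorConfig":
        """Copy with all noise switched off (closed-form outputs)."""
        profiles = {
            name: p.replace(cv_within=0.0, cv_between=0.0)
            for name, p in self.device_profiles.items()
        }
        return replace(self, device_profiles=profiles, day_effect_sd=0.0)

    def device(self, name: str) -> DeviceProfile:
        try:
            return self.device_profiles[name]
        except KeyError:
            raise KeyError(
                f"unknown device {name!r}; registered: {sorted(self.device_profiles)}"
            ) from None


def expected_ratio(
    config: GeneratorConfig,
    nominal: float,
    device: DeviceProfile,
    analyte: str,
    role: str,
) -> float:
    """Closed-form expected analyte/IS ratio under the generator model."""
    if nominal < 0:
        raise ValueError(f"nominal concentration must be >= 0, got {nominal}")
    kappa = config.response_factor[analyte]
    is_expected = config.is_amount * config.is_response_factor
    base = kappa * nominal * device.actual_volume / is_expected
    if role == "neat_standard":
        return base
    if role == "post_spike":
        return base * device.me(analyte, nominal)
    # calibration / qc / pre_spike / stability: through the matrix
    return base * device.ee(analyte) * device.me(analyte, nominal)


def _unit_mean_factor(rng: np.random.Generator, cv: float, model: str) -> float:
    """One multiplicative noise draw with E[factor] = 1 and SD = cv."""
    if cv == 0:
        return 1.0
    if model == "lognormal":
        sigma2 = math.log1p(cv * cv)
        return float(rng.lognormal(mean=-sigma2 / 2, sigma=math.sqrt(sigma2)))
    # truncated normal: resample into (0, inf); negligible truncation at small cv
    while True:
        f = float(rng.normal(1.0, cv))
        if f > 0:
            return f


def _day_factor(
    config: GeneratorConfig,
    seed: int,
    device: DeviceProfile,
    analyte: str,
    level: float,
    day: int,
) -> float:
    """Between-day factor, deterministically shared within a (level, day) cell."""
    cv = config.day_effect_sd if config.day_effect_sd is not None else device.cv_between
    if cv == 0:
        return 1.0
    key = [
        seed,
        zlib.crc32(device.name.encode()),
        ANALYTES.index(analyte),
        int(round(level * 1000)),
        day,
        7919,
    ]
    rng = np.random.default_rng(key)
    return _unit_mean_factor(rng, cv, config.noise_model)


def simulate_measurement(
    config: GeneratorConfig,
    seed: int,
    nominal: float,
    device: DeviceProfile,
    analyte: str,
    role: str,
    context: dict,
    rng: np.random.Generator,
) -> MeasurementRecord:
    """Draw one measurement record.

    ``context`` supplies ``day`` and ``replicate`` (and ``time_h`` for
    stability samples).  The between-day factor is derived from ``seed`` and
    the (device, analyte, level, day) cell, not from ``rng``, so replicates of
    a day share it no matter how records are interleaved.
    """
    if nominal < 0:
        raise ValueError(f"nominal concentration must be >= 0, got {nominal}")
    day = int(context.get("day", 1))
    replicate = int(context.get("replicate", 1))
    time_h = context.get("time_h")

    is_expected = config.is_amount * config.is_response_factor
    is_area = is_expected * _unit_mean_factor(rng, device.cv_within, config.noise_model)

    mean_ratio = expected_ratio(config, nominal, device, analyte, role)
    ratio = (
        mean_ratio
        * _day_factor(config, seed, device, analyte, nominal, day)
        * _unit_mean_factor(rng, device.cv_within, config.noise_model)
    )
    if role == "stability" and time_h is not None and config.degradation_per_h:
        ratio *= (1.0 - config.degradation_per_h) ** float(time_h)

    return MeasurementRecord(
        device=device.name,
        analyte=analyte,
        role=role,
        nominal_conc=nominal,
        day=day,
        replicate=replicate,
        time_h=float(time_h) if role == "stability" else None,
        analyte_area=ratio * is_area,
        is_area=is_area,
    )


def _design_rng(seed: int, role: str, device: DeviceProfile, analyte: str) -> np.random.Generator:
    return np.random.default_rng(
        [seed, _ROLE_STREAM[role], ANALYTES.index(analyte), zlib.crc32(device.name.encode())]
    )


def generate_calibration_set(
    config: GeneratorConfig, device_name: str, analyte: str, seed: int
) -> MeasurementSet:
    """8 levels (10-500 ng/mL) x 6 days of calibration samples."""
    device = config.device(device_name)
    rng = _design_rng(seed, "calibration", device, analyte)
    records = [
        simulate_measurement(
            config, seed, level, device, analyte, "calibration",
            {"day": day, "replicate": 1}, rng,
        )
        for day in range(1, CALIBRATION_DAYS + 1)
        for level in CALIBRATION_LEVELS
    ]
    return MeasurementSet(records, provenance=f"synthgen:calibration seed={seed} device={device_name} analyte={analyte}")


def generate_lodloq_set(
    config: GeneratorConfig, device_name: str, analyte: str, seed: int
) -> MeasurementSet:
    """Single-day low calibration (2-12 ng/mL, equidistant) for DIN 32645 limits."""
    device = config.device(device_name)
    rng = _design_rng(seed, "calibration", device, analyte)
    records = [
        simulate_measurement(
            config, seed + 104729, level, device, analyte, "calibration",
            {"day": 1, "replicate": 1}, rng,
        )
        for level in LODLOQ_LEVELS
    ]
    return MeasurementSet(records, provenance=f"synthgen:lodloq seed={seed} device={device_name} analyte={analyte}")


def generate_qc_series(
    config: GeneratorConfig,
    device_name: str,
    analyte: str,
    seed: int,
    levels: tuple[float, ...] | None = None,
    days: int = QC_DAYS,
    replicates: int = QC_REPLICATES,
    include_external: bool = False,
) -> MeasurementSet:
    """QC pools measured in replicate over several days (default duplicate x 8).

    With ``include_external`` the certified external accuracy control is added
    at its analyte-specific target (52.8 ng/mL for PEth 16:0/18:1, 22.6 ng/mL
    for PEth 16:0/18:2).
    """
    device = config.device(device_name)
    if levels is None:
        levels = QC_LEVELS
    levels = tuple(levels)
    if include_external:
        levels = tuple(sorted(set(levels) | {EXTERNAL_QC_TARGETS[analyte]}))
    rng = _design_rng(seed, "qc", device, analyte)
    records = [
        simulate_measurement(
            config, seed, level, device, analyte, "qc",
            {"day": day, "replicate": rep}, rng,
        )
        for level in levels
        for day in range(1, days + 1)
        for rep in range(1, replicates + 1)
    ]
    return MeasurementSet(records, provenance=f"synthgen:qc seed={seed} device={device_name} analyte={analyte}")


def generate_me_ee_sets(
    config: GeneratorConfig,
    device_name: str,
    analyte: str,
    seed: int,
    levels: tuple[float, float] = ME_EE_LEVELS,
    n: int = ME_EE_REPLICATES,
) -> MeasurementSet:
    """Matrix-effect / extraction-efficiency triads.

    Per level: n neat standards in solvent, n post-extraction spiked blank
    extracts and n pre-extraction spiked blood samples (default 5 each at 20
    and 350 ng/mL -> 30 records).
    """
    device = config.device(device_name)
    rng = _design_rng(seed, "neat_standard", device, analyte)
    records = [
        simulate_measurement(
            config, seed, level, device, analyte, role,
            {"day": 1, "replicate": rep}, rng,
        )
        for level in levels
        for role in ("neat_standard", "post_spike", "pre_spike")
        for rep in range(1, n + 1)
    ]
    return MeasurementSet(records, provenance=f"synthgen:me_ee seed={seed} device={device_name} analyte={analyte}")


def generate_stability_series(
    config: GeneratorConfig,
    device_name: str,
    analyte: str,
    seed: int,
    levels: tuple[float, ...] = ME_EE_LEVELS,
    times_h: tuple[float, ...] = STABILITY_TIMES_H,
) -> MeasurementSet:
    """Processed-sample aliquots injected at 0/1/2/4/24/48 h per level.

    ``config.degradation_per_h`` applies a (1 - r)^t area decay; the default 0
    reflects processed-sample stability over the 48 h window.
    """
    device = config.device(device_name)
    rng = _design_rng(seed, "stability", device, analyte)
    records = [
        simulate_measurement(
            config, seed, level, device, analyte, "stability",
            {"day": 1, "replicate": 1, "time_h": t}, rng,
        )
        for level in levels
        for t in times_h
    ]
    return MeasurementSet(records, provenance=f"synthgen:stability seed={seed} device={device_name} analyte={analyte}")
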