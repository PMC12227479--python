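"""Matrix effect, extraction efficiency, stability, precision and accuracy.

Implements the validation estimators of the GTFCh (German Society of
Toxicology and Forensic Chemistry) guideline as used for dried-blood-spot
assays:

* matrix effect (ME) and extraction efficiency (EE, recovery) from the
  three-set design of Matuszewski: neat standards in solvent, blank extracts
  spiked after extraction (post-spike) and blood spiked before extraction
  (pre-spike), n replicates each at a low and a high level.  Both estimators
  are ratios of set means (ratio-of-means, the "plot set A against set B"
  convention).  Acceptance: ME within 75-125 %, EE >= 50 %, replicate RSD of
  each compared set <= 25 %.
* processed-sample stability as the spread of absolute analyte peak areas
  over the injection-time series, 100 * (max - min) / mean by default.
* precision and accuracy from QC pools measured in replicate over several
  days, decomposed by one-way ANOVA into repeatability (within-day) and
  time-different intermediate precision, with bias against nominal.
  Acceptance: RSD and |bias| within 15 %.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

__all__ = [
    "MetricResult",
    "PrecisionDecomposition",
    "matrix_effect",
    "extraction_efficiency",
    "stability_assess",
    "precision_accuracy",
]

ME_ACCEPTANCE = (75.0, 125.0)
EE_ACCEPTANCE = (50.0, None)  # one-sided: >= 50 %
DISPERSION_MAX = 25.0  # replicate RSD bound for ME / EE sets, %
RSD_BIAS_LIMIT = 15.0  # GTFCh precision / accuracy window, %


def _rsd(values: np.ndarray) -> float:
    """Relative standard deviation in %, sample SD over the mean."""
    mean = values.mean()
    if mean == 0:
        raise ZeroDivisionError("RSD undefined for zero mean")
    return float(100.0 * values.std(ddof=1) / mean)


@dataclass(frozen=True)
class MetricResult:
    """One validation metric with its acceptance verdict.

    ``passed`` refers to the value band alone; ``dispersion_passed`` to the
    separate replicate-scatter bound (RSD <= 25 % where defined);
    ``acceptable`` requires both.
    """

    metric: str
    value: float
    dispersion: float | None
    n: int
    level: float
    acceptance: tuple[float | None, float | None]
    passed: bool
    dispersion_passed: bool = True

    @property
    def acceptable(self) -> bool:
        return self.passed and self.dispersion_passed

    def to_dict(self) -> dict:
        return {
            "metric": self.metric,
            "value": self.value,
            "dispersion": self.dispersion,
            "n": self.n,
            "level": self.level,
            "acceptance": list(self.acceptance),
            "passed": self.passed,
            "dispersion_passed": self.dispersion_passed,
        }


def _band_verdict(value: float, low: float | None, high: float | None) -> bool:
    if low is not None and value < low:
        return False
    if high is not None and value > high:
        return False
    return True


@dataclass(frozen=True)
class PrecisionDecomposition:
    """Day-wise ANOVA decomposition of QC results (concentration domain).

    ``s_r`` is the repeatability (within-day) SD, ``s_between`` the between-day
    component and ``s_I`` the time-different intermediate SD with
    s_I^2 = s_r^2 + s_between^2; RSDs are relative to the observed grand mean,
    bias relative to the nominal concentration.
    """

    grand_mean: float
    s_r: float
    s_between: float
    s_I: float
    rsd_r: float
    rsd_I: float
    bias: float
    nominal: float
    n_days: int
    n_replicates: int
    intermediate_defined: bool = True

    def __post_init__(self) -> None:
        if self.s_I < self.s_r - 1e-12:
            raise ValueError("intermediate SD cannot be below repeatability SD")

    @property
    def acceptable(self) -> bool:
        """GTFCh window: RSDs and |bias| within 15 %."""
        return (
            self.rsd_r <= RSD_BIAS_LIMIT
            and self.rsd_I <= RSD_BIAS_LIMIT
            and abs(self.bias) <= RSD_BIAS_LIMIT
        )

    def to_dict(self) -> dict:
        return {
            "grand_mean": self.grand_mean,
            "s_r": self.s_r,
            "s_between": self.s_between,
            "s_I": self.s_I,
            "rsd_r": self.rsd_r,
            "rsd_I": self.rsd_I,
            "bias": self.bias,
            "nominal": self.nominal,
            "n_days": self.n_days,
            "n_replicates": self.n_replicates,
            "intermediate_defined": self.intermediate_defined,
        }


def matrix_effect(
    neat: Sequence[float], post_spike: Sequence[float], level: float = float("nan")
) -> MetricResult:
    """Matrix effect in %: post-extraction-spike vs neat-standard response.

    value = 100 * mean(post_spike ratios) / mean(neat ratios); the replicate
    scatter reported is the RSD of the post-spike set.
    """
    neat_arr = np.asarray(neat, dtype=float)
    post_arr = np.asarray(post_spike, dtype=float)
    if neat_arr.size == 0 or post_arr.size == 0:
        raise ValueError("both sets must be non-empty")
    if neat_arr.mean() == 0:
        raise ZeroDivisionError("matrix effect undefined: neat-standard mean response is 0")
    value = float(100.0 * post_arr.mean() / neat_arr.mean())
    dispersion = _rsd(post_arr) if post_arr.size > 1 else None
    return MetricResult(
        metric="matrix_effect",
        value=value,
        dispersion=dispersion,
        n=int(post_arr.size),
        level=level,
        acceptance=ME_ACCEPTANCE,
        passed=_band_verdict(value, *ME_ACCEPTANCE),
        dispersion_passed=dispersion is None or dispersion <= DISPERSION_MAX,
    )


def extraction_efficiency(
    pre_spike: Sequence[float], post_spike: Sequence[float], level: float = float("nan")
) -> MetricResult:
    """Extraction efficiency (recovery) in %: pre- vs post-extraction spikes."""
    pre_arr = np.asarray(pre_spike, dtype=float)
    post_arr = np.asarray(post_spike, dtype=float)
    if pre_arr.size == 0 or post_arr.size == 0:
        raise ValueError("both sets must be non-empty")
    if post_arr.mean() == 0:
        raise ZeroDivisionError("extraction efficiency undefined: post-spike mean response is 0")
    value = float(100.0 * pre_arr.mean() / post_arr.mean())
    dispersion = _rsd(pre_arr) if pre_arr.size > 1 else None
    return MetricResult(
        metric="extraction_efficiency",
        value=value,
        dispersion=dispersion,
        n=int(pre_arr.size),
        level=level,
        acceptance=EE_ACCEPTANCE,
        passed=_band_verdict(value, *EE_ACCEPTANCE),
        dispersion_passed=dispersion is None or dispersion <= DISPERSION_MAX,
    )


def stability_assess(
    series: Sequence[tuple[float, float]],
    level: float = float("nan"),
    denominator: str = "mean",
    threshold: float | None = None,
) -> MetricResult:
    """Processed-sample drift: spread of absolute analyte areas over time.

    drift = 100 * (max area - min area) / denominator, with the series mean as
    the default denominator (``min`` and ``first`` are available since "differ
    between each other" admits several readings).  No acceptance bound is
    applied unless ``threshold`` is given.
    """
    pts = sorted((float(t), float(a)) for t, a in series)
    if len(pts) < 2:
        raise ValueError("stability assessment needs >= 2 time points")
    areas = np.array([a for _, a in pts])
    if np.all(areas == 0):
        raise ZeroDivisionError("stability drift undefined: all areas are zero")
    denom = {
        "mean": areas.mean(),
        "min": areas.min(),
        "first": areas[0],
    }[denominator]
    value = float(100.0 * (areas.max() - areas.min()) / denom)
    return MetricResult(
        metric="stability_drift",
        value=value,
        dispersion=_rsd(areas),
        n=len(pts),
        level=level,
        acceptance=(None, threshold),
        passed=_band_verdict(value, None, threshold),
    )


def precision_accuracy(
    concs_by_day: Sequence[Sequence[float]], nominal: float
) -> PrecisionDecomposition:
    """Repeatability / intermediate precision and bias from day-wise QC results.

    ``concs_by_day`` holds the back-calculated concentrations (ng/mL), one
    inner sequence per day with an equal number of replicates.  One-way ANOVA
    by day gives s_r^2 = MS_within and
    s_between^2 = max(0, (MS_between - MS_within) / n_rep); a between-day mean
    square below the within-day one truncates the component at zero.  With a
    single day the intermediate precision is undefined and flagged; the
    repeatability is still returned.
    """
    groups = [np.asarray(g, dtype=float) for g in concs_by_day]
    if not groups:
        raise ValueError("no data")
    sizes = {len(g) for g in groups}
    if len(sizes) != 1:
        raise ValueError(f"equal replicates per day required, got sizes {sorted(sizes)}")
    (n_rep,) = sizes
    if n_rep < 2:
        raise ValueError("need >= 2 replicates per day for repeatability")
    k = len(groups)
    all_vals = np.concatenate(groups)
    grand = float(all_vals.mean())
    if grand == 0:
        raise ZeroDivisionError("RSD undefined for zero grand mean")

    ms_within = float(sum(np.sum((g - g.mean()) ** 2) for g in groups) / (k * (n_rep - 1)))
    s_r = math.sqrt(ms_within)
    if k >= 2:
        ms_between = float(n_rep * sum((g.mean() - grand) ** 2 for g in groups) / (k - 1))
        s_between = math.sqrt(max(0.0, (ms_between - ms_within) / n_rep))
        intermediate_defined = True
    else:
        s_between = 0.0
        intermediate_defined = False
    s_i = math.sqrt(s_r**2 + s_between**2)

    return PrecisionDecomposition(
        grand_mean=grand,
        s_r=s_r,
        s_between=s_between,
        s_I=s_i,
        rsd_r=100.0 * s_r / grand,
        rsd_I=100.0 * s_i / grand,
        bias=100.0 * (grand - nominal) / nominal,
        nominal=nominal,
        n_days=k,
        n_replicates=n_rep,
        intermediate_defined=intermediate_defined,
    )
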