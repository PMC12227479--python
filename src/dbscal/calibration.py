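"""Weighted calibration, linearity/homogeneity/outlier tests, DIN 32645 limits.

Calibration follows forensic-toxicology practice: the analyte/IS area ratio y
is regressed on nominal concentration x with 1/x weighting (the weighting
applied throughout the assay), unknowns are quantified by inverse prediction
x = (y - a) / b, and the line is qualified with the Mandel fitting test
(linear vs quadratic residual variance), the Cochran test for variance
homogeneity across levels, and a Grubbs screen of standardized residuals.
Detection and quantification limits come from the calibration-line procedure
of DIN 32645 on a separate low, equidistant calibration.

Mandel, Cochran and Grubbs operate on the unweighted data, following
DIN 38402-style practice; the 1/x weighting applies only to the
quantification fit.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

__all__ = [
    "CalibrationFit",
    "TestResult",
    "Limits",
    "fit_weighted_calibration",
    "predict",
    "back_calculate",
    "mandel_test",
    "cochran_test",
    "cochran_critical_value",
    "grubbs_outlier_test",
    "din32645_limits",
]


@dataclass(frozen=True)
class CalibrationFit:
    """A fitted (possibly weighted) calibration line y = a + b*x.

    ``s_yx`` is the weighted residual standard deviation in ratio units and
    ``s_x0 = s_yx / b`` the procedural standard deviation in ng/mL; ``x_bar``
    and ``Q_x`` are the unweighted design moments DIN 32645 needs.
    """

    slope: float
    intercept: float
    weighting: str
    r: float
    s_yx: float
    s_x0: float
    x_bar: float
    q_x: float
    n_points: int
    range: tuple[float, float]

    def __post_init__(self) -> None:
        if self.slope == 0:
            raise ValueError("calibration slope must be non-zero")
        if self.n_points < 3:
            raise ValueError("calibration needs at least 3 points")

    def to_dict(self) -> dict:
        return {
            "slope": self.slope,
            "intercept": self.intercept,
            "weighting": self.weighting,
            "r": self.r,
            "s_yx": self.s_yx,
            "s_x0": self.s_x0,
            "x_bar": self.x_bar,
            "q_x": self.q_x,
            "n_points": self.n_points,
            "range": list(self.range),
        }

    @staticmethod
    def from_dict(d: dict) -> "CalibrationFit":
        d = dict(d)
        d["range"] = tuple(d["range"])
        return CalibrationFit(**d)


@dataclass(frozen=True)
class TestResult:
    """Outcome of a statistical qualification test."""

    name: str
    statistic: float
    critical_value: float
    alpha: float
    df: str
    passed: bool
    flagged_index: int | None = None
    degenerate: bool = False

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "statistic": self.statistic,
            "critical_value": self.critical_value,
            "alpha": self.alpha,
            "df": self.df,
            "passed": self.passed,
            "flagged_index": self.flagged_index,
            "degenerate": self.degenerate,
        }


@dataclass(frozen=True)
class Limits:
    """DIN 32645 detection and quantification limits (ng/mL)."""

    lod: float
    loq: float
    alpha: float
    k: float
    n_future: int

    def __post_init__(self) -> None:
        # zero residual scatter (exactly collinear data) degenerates both
        # limits to 0; otherwise 0 < LOD < LOQ must hold
        if self.lod == self.loq == 0.0:
            return
        if not 0 < self.lod < self.loq:
            raise ValueError(f"expected 0 < LOD < LOQ, got {self.lod}, {self.loq}")


_WEIGHTS = {"none", "one_over_x", "one_over_x2"}


def _weights(x: np.ndarray, weighting: str) -> np.ndarray:
    if weighting not in _WEIGHTS:
        raise ValueError(f"unknown weighting {weighting!r}; expected one of {sorted(_WEIGHTS)}")
    if weighting == "none":
        w = np.ones_like(x)
    else:
        if np.any(x <= 0):
            raise ValueError(f"weighting {weighting!r} requires all concentrations > 0")
        w = 1.0 / x if weighting == "one_over_x" else 1.0 / x**2
    # normalized to mean 1: leaves the fit invariant, keeps s_yx comparable
    return w / w.mean()


def fit_weighted_calibration(
    points: Sequence[tuple[float, float]], weighting: str = "one_over_x"
) -> CalibrationFit:
    """Fit y = a + b*x by weighted least squares with weights 1/x (default).

    ``points`` are (concentration ng/mL, analyte/IS ratio) pairs; at least 3
    distinct concentration levels are required.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValueError("points must be (conc, ratio) pairs")
    x, y = pts[:, 0], pts[:, 1]
    if len(np.unique(x)) < 3:
        raise ValueError("need >= 3 distinct concentration levels")
    w = _weights(x, weighting)

    xw = np.average(x, weights=w)
    yw = np.average(y, weights=w)
    sxx = float(np.sum(w * (x - xw) ** 2))
    sxy = float(np.sum(w * (x - xw) * (y - yw)))
    syy = float(np.sum(w * (y - yw) ** 2))
    if sxx == 0:
        raise ValueError("singular design: all concentrations identical")
    b = sxy / sxx
    a = yw - b * xw
    resid = y - a - b * x
    n = len(x)
    s_yx = math.sqrt(float(np.sum(w * resid**2)) / (n - 2)) if n > 2 else 0.0
    r = sxy / math.sqrt(sxx * syy) if syy > 0 else 1.0
    if b == 0:
        raise ValueError("fit produced zero slope; calibration unusable")
    return CalibrationFit(
        slope=b,
        intercept=a,
        weighting=weighting,
        r=r,
        s_yx=s_yx,
        s_x0=s_yx / abs(b),
        x_bar=float(x.mean()),
        q_x=float(np.sum((x - x.mean()) ** 2)),
        n_points=n,
        range=(float(x.min()), float(x.max())),
    )


def predict(fit: CalibrationFit, conc: float | np.ndarray) -> float | np.ndarray:
    """Expected ratio at a concentration."""
    return fit.intercept + fit.slope * conc


def back_calculate(fit: CalibrationFit, ratio: float | np.ndarray):
    """Inverse prediction: concentration = (ratio - intercept) / slope.

    Negative concentrations are returned as-is (no clamping); scalar inputs
    return ``(conc, below_zero_flag)``, arrays return ``(concs, flags)``.
    """
    conc = (np.asarray(ratio, dtype=float) - fit.intercept) / fit.slope
    flags = conc < 0
    if np.isscalar(ratio) or np.ndim(ratio) == 0:
        return float(conc), bool(flags)
    return conc, flags


# --- linearity / homogeneity / outliers ------------------------------------


def mandel_test(points: Sequence[tuple[float, float]], alpha: float = 0.01) -> TestResult:
    """Mandel fitting test: is a quadratic significantly better than a line?

    With N points, the linear fit gives residual variance s1^2 on N-2 df and
    the quadratic s2^2 on N-3 df; the variance difference
    DS^2 = (N-2) s1^2 - (N-3) s2^2 is compared against s2^2 by an F test with
    (1, N-3) degrees of freedom.  Passing (F <= F_crit) supports linearity.
    """
    pts = np.asarray(points, dtype=float)
    x, y = pts[:, 0], pts[:, 1]
    n = len(x)
    if len(np.unique(x)) < 5:
        raise ValueError("Mandel test needs >= 5 distinct levels")
    ssr1 = float(np.sum((y - np.polyval(np.polyfit(x, y, 1), x)) ** 2))
    ssr2 = float(np.sum((y - np.polyval(np.polyfit(x, y, 2), x)) ** 2))
    s2_sq = ssr2 / (n - 3)
    # DS^2 = (N-2)s1^2 - (N-3)s2^2; clamp tiny negative values from float
    # cancellation so an exact line yields F = 0
    ds_sq = max(0.0, ssr1 - ssr2)
    if s2_sq == 0:
        # exact quadratic (incl. exact line): no evidence against linearity
        # unless the quadratic removed residual variance the line left behind
        statistic = math.inf if ds_sq > 0 else 0.0
    else:
        statistic = ds_sq / s2_sq
    critical = float(stats.f.ppf(1 - alpha, 1, n - 3))
    return TestResult(
        name="mandel",
        statistic=statistic,
        critical_value=critical,
        alpha=alpha,
        df=f"(1, {n - 3})",
        passed=statistic <= critical,
    )


def cochran_critical_value(alpha: float, k: int, nu: int) -> float:
    """Cochran C critical value from the F-quantile closed form.

    C_crit = [1 + (k-1) / F(1 - alpha/k; nu, (k-1) nu)]^-1, with k groups of
    nu + 1 replicates each.  Matches the published Cochran tables.
    """
    f_crit = stats.f.ppf(1 - alpha / k, nu, (k - 1) * nu)
    return float(1.0 / (1.0 + (k - 1) / f_crit))


def cochran_test(groups: Sequence[Sequence[float]], alpha: float = 0.01) -> TestResult:
    """Cochran test of variance homogeneity across calibration levels.

    C = s^2_max / sum(s^2_i) over k groups with equal replicate counts.
    Passing (C <= C_crit) supports homoscedasticity.
    """
    sizes = {len(g) for g in groups}
    if len(sizes) != 1:
        raise ValueError(f"Cochran test requires equal group sizes, got {sorted(sizes)}")
    (size,) = sizes
    k = len(groups)
    if k < 2 or size < 2:
        raise ValueError("need >= 2 groups of >= 2 replicates")
    variances = np.array([np.var(g, ddof=1) for g in groups])
    total = float(variances.sum())
    if total == 0:
        return TestResult(
            name="cochran", statistic=0.0, critical_value=1.0, alpha=alpha,
            df=f"(k={k}, nu={size - 1})", passed=True, degenerate=True,
        )
    statistic = float(variances.max() / total)
    critical = cochran_critical_value(alpha, k, size - 1)
    return TestResult(
        name="cochran",
        statistic=statistic,
        critical_value=critical,
        alpha=alpha,
        df=f"(k={k}, nu={size - 1})",
        passed=statistic <= critical,
    )


def grubbs_outlier_test(values: Sequence[float], alpha: float = 0.01) -> TestResult:
    """Two-sided Grubbs test; flags at most the single most extreme value.

    G = max|v_i - mean| / sd with the t-based critical value
    G_crit = (n-1)/sqrt(n) * sqrt(t^2 / (n - 2 + t^2)),
    t = t(1 - alpha/(2n); n-2).  The pipeline applies this to standardized
    residuals of the pooled calibration fit.
    """
    v = np.asarray(values, dtype=float)
    n = len(v)
    if n < 3:
        raise ValueError("Grubbs test needs n >= 3")
    sd = float(v.std(ddof=1))
    if sd == 0:
        return TestResult(
            name="grubbs", statistic=0.0, critical_value=math.inf, alpha=alpha,
            df=f"n={n}", passed=True, degenerate=True,
        )
    dev = np.abs(v - v.mean())
    idx = int(np.argmax(dev))
    g = float(dev[idx] / sd)
    t = float(stats.t.ppf(1 - alpha / (2 * n), n - 2))
    critical = (n - 1) / math.sqrt(n) * math.sqrt(t * t / (n - 2 + t * t))
    passed = g <= critical
    return TestResult(
        name="grubbs",
        statistic=g,
        critical_value=float(critical),
        alpha=alpha,
        df=f"n={n}",
        passed=passed,
        flagged_index=None if passed else idx,
    )


def screen_outliers(points: Sequence[tuple[float, float]], alpha: float = 0.01) -> TestResult:
    """Grubbs screen on standardized residuals of the pooled 1/x-weighted fit."""
    fit = fit_weighted_calibration(points, weighting="one_over_x")
    pts = np.asarray(points, dtype=float)
    resid = pts[:, 1] - predict(fit, pts[:, 0])
    w = _weights(pts[:, 0], "one_over_x")
    standardized = resid * np.sqrt(w) / fit.s_yx if fit.s_yx > 0 else np.zeros(len(resid))
    return grubbs_outlier_test(standardized, alpha=alpha)


# --- DIN 32645 detection / quantification limits ---------------------------


def din32645_limits(
    points: Sequence[tuple[float, float]],
    alpha: float = 0.01,
    k: float = 3.0,
    n_future: int = 1,
) -> Limits:
    """Detection and quantification limits by the DIN 32645 calibration-line method.

    From the unweighted fit of a low, preferably equidistant calibration with
    m points and f = m - 2 degrees of freedom, with t the one-sided t-quantile
    at 1 - alpha:

        LOD = s_x0 * t * sqrt(1/m + 1/n + x_bar^2 / Q_x)

    and the quantification limit is the fixed point of

        x = k * s_x0 * t * sqrt(1/m + 1/n + (x - x_bar)^2 / Q_x)

    iterated from x0 = 3 * LOD to 1e-9 relative tolerance.  k = 3 bounds the
    relative uncertainty of a result at the LOQ by 1/k (~33 %).
    """
    fit = fit_weighted_calibration(points, weighting="none")
    if fit.slope <= 0:
        raise ValueError("DIN 32645 requires a positive calibration slope")
    m = fit.n_points
    f = m - 2
    if f < 1:
        raise ValueError("need at least 3 points for DIN 32645")
    t = float(stats.t.ppf(1 - alpha, f))
    base = 1.0 / m + 1.0 / n_future
    lod = fit.s_x0 * t * math.sqrt(base + fit.x_bar**2 / fit.q_x)

    x = 3.0 * lod
    for _ in range(100):
        x_new = k * fit.s_x0 * t * math.sqrt(base + (x - fit.x_bar) ** 2 / fit.q_x)
        if abs(x_new - x) <= 1e-9 * max(abs(x_new), 1e-300):
            return Limits(lod=lod, loq=x_new, alpha=alpha, k=k, n_future=n_future)
        x = x_new
    raise RuntimeError("DIN 32645 LOQ fixed-point iteration did not converge in 100 steps")
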