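"""Enzyme-assay analysis: Michaelis-Menten fits, KIE from paired fits,
Nash-assay calibration, initial rates from A340 traces, soluble-enzyme
fraction and inhibition summaries.

Michaelis-Menten parameters and their confidence intervals follow the
classic nonlinear-least-squares contract: Levenberg-Marquardt optimum
(seeded from a Lineweaver-Burk line, with multistart) and t-based
intervals from the asymptotic covariance at the optimum.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats

__all__ = [
    "MMFit",
    "CalibrationCurve",
    "ExpressionFractions",
    "NashResult",
    "fit_michaelis_menten",
    "kie_from_paired_fits",
    "fit_calibration",
    "nash_quantify",
    "rate_from_absorbance",
    "soluble_fraction",
    "fractional_inhibition",
    "per_level_velocity_ratio",
]

#: NADH molar extinction coefficient at 340 nm, M^-1 cm^-1.
NADH_EXTINCTION_340 = 6220.0


def michaelis_menten(s, vmax, km):
    s = np.asarray(s, dtype=float)
    return vmax * s / (km + s)


@dataclass(frozen=True)
class MMFit:
    """Michaelis-Menten parameters with t-based confidence intervals."""

    vmax: float
    km: float
    vmax_ci: tuple[float, float]
    km_ci: tuple[float, float]
    vmax_se: float
    km_se: float
    cov: np.ndarray
    residual_sd: float
    dof: int
    ci_level: float
    converged: bool
    flags: tuple[str, ...] = ()

    def predict(self, s):
        return michaelis_menten(s, self.vmax, self.km)


def _lineweaver_burk_seed(s: np.ndarray, v: np.ndarray) -> tuple[float, float]:
    mask = (s > 0) & (v > 0)
    if mask.sum() >= 2:
        res = stats.linregress(1.0 / s[mask], 1.0 / v[mask])
        if res.intercept > 0 and res.slope > 0:
            vmax = 1.0 / res.intercept
            km = res.slope * vmax
            if km > 0:
                return vmax, km
    return float(np.max(v)) or 1.0, float(np.median(s[s > 0])) if np.any(s > 0) else 1.0


def fit_michaelis_menten(
    substrate,
    velocity,
    ci_level: float = 0.95,
) -> MMFit:
    """Least-squares fit of v = Vmax*S/(Km + S).

    Requires >= 3 distinct substrate levels.  Deterministic: seeded from
    the Lineweaver-Burk line with a small fixed grid of fallback starts,
    keeping the lowest-SSR optimum.  Intervals are
    ``theta_hat +/- t_{1-(1-ci)/2, n-2} * se`` from the Jacobian-based
    covariance.  A negative parameter estimate is flagged as a failure.
    """
    s = np.asarray(substrate, dtype=float)
    v = np.asarray(velocity, dtype=float)
    if s.shape != v.shape:
        raise ValueError("substrate and velocity must have equal length")
    if np.any(s < 0):
        raise ValueError("substrate concentrations must be non-negative")
    if np.unique(s).size < 3:
        raise ValueError("need at least 3 distinct substrate levels")

    seeds = [_lineweaver_burk_seed(s, v)]
    vscale = max(float(np.max(np.abs(v))), 1e-12)
    sscale = float(np.median(s[s > 0])) if np.any(s > 0) else 1.0
    seeds += [(vscale, sscale), (2 * vscale, 0.5 * sscale)]

    best = None
    for p0 in seeds:
        try:
            popt, pcov = optimize.curve_fit(
                michaelis_menten, s, v, p0=p0, maxfev=20000
            )
        except RuntimeError:
            continue
        ssr = float(np.sum((v - michaelis_menten(s, *popt)) ** 2))
        if best is None or ssr < best[2]:
            best = (popt, pcov, ssr)
    if best is None:
        raise RuntimeError(
            "Michaelis-Menten fit did not converge from any start; "
            f"data: n={s.size}, v range [{v.min():.3g}, {v.max():.3g}]"
        )
    popt, pcov, ssr = best
    dof = max(s.size - 2, 1)
    residual_sd = math.sqrt(ssr / dof)
    se = np.sqrt(np.diag(pcov))
    tval = stats.t.ppf(1.0 - (1.0 - ci_level) / 2.0, dof)
    flags: tuple[str, ...] = ()
    converged = True
    if popt[0] <= 0 or popt[1] <= 0:
        flags = ("negative_parameter_estimate",)
        converged = False
    return MMFit(
        vmax=float(popt[0]), km=float(popt[1]),
        vmax_ci=(float(popt[0] - tval * se[0]), float(popt[0] + tval * se[0])),
        km_ci=(float(popt[1] - tval * se[1]), float(popt[1] + tval * se[1])),
        vmax_se=float(se[0]), km_se=float(se[1]),
        cov=pcov, residual_sd=residual_sd, dof=dof,
        ci_level=ci_level, converged=converged, flags=flags,
    )


def kie_from_paired_fits(
    fit_h: MMFit,
    fit_d: MMFit,
    n_samples: int = 10000,
    seed: int = 0,
) -> dict:
    """alpha = Vmax_H / Vmax_D with a Monte-Carlo interval.

    The two fits are independent, so Vmax draws are sampled from each
    fit's asymptotic normal and the ratio summarised.  Raises when the
    deuterated Vmax interval spans zero (the ratio is then undefined at
    the stated confidence).
    """
    if not (fit_h.converged and fit_d.converged):
        raise ValueError("both fits must have converged")
    if fit_d.vmax_ci[0] <= 0 <= fit_d.vmax_ci[1]:
        raise ValueError("deuterated Vmax confidence interval spans zero")
    rng = np.random.default_rng(seed)
    vh = fit_h.vmax + fit_h.vmax_se * rng.standard_normal(n_samples)
    vd = fit_d.vmax + fit_d.vmax_se * rng.standard_normal(n_samples)
    ratio = vh / np.where(vd == 0, np.nan, vd)
    ratio = ratio[np.isfinite(ratio)]
    point = fit_h.vmax / fit_d.vmax
    sd = float(ratio.std(ddof=1))
    lo, hi = np.percentile(ratio, [2.5, 97.5])
    return {
        "alpha": point,
        "sd": sd,
        "interval": (point - sd, point + sd),
        "percentile_interval": (float(lo), float(hi)),
        "n_samples": n_samples,
    }


def per_level_velocity_ratio(substrate, velocity_h, velocity_d):
    """Diagnostic: v_H/v_D at each substrate level (reveals Km isotope effects)."""
    s = np.asarray(substrate, dtype=float)
    vh = np.asarray(velocity_h, dtype=float)
    vd = np.asarray(velocity_d, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        return s, vh / vd


@dataclass(frozen=True)
class CalibrationCurve:
    """Linear response curve for a colorimetric standard series."""

    slope: float
    intercept: float
    r_squared: float
    conc_range: tuple[float, float]
    residual_sd: float = 0.0
    n: int = 0
    forced_origin: bool = False

    def __post_init__(self) -> None:
        if self.slope <= 0:
            raise ValueError("calibration slope must be positive")


def fit_calibration(concentrations, responses, force_origin: bool = False) -> CalibrationCurve:
    """Fit a standard curve (response vs concentration).

    Default keeps a free intercept, since blank wells drift; forcing
    through the origin is recorded on the curve.
    """
    c = np.asarray(concentrations, dtype=float)
    a = np.asarray(responses, dtype=float)
    if c.size < 3:
        raise ValueError("need at least 3 standards")
    if force_origin:
        slope = float(np.sum(c * a) / np.sum(c * c))
        intercept = 0.0
        pred = slope * c
    else:
        res = stats.linregress(c, a)
        slope, intercept = float(res.slope), float(res.intercept)
        pred = slope * c + intercept
    ss_res = float(np.sum((a - pred) ** 2))
    ss_tot = float(np.sum((a - a.mean()) ** 2))
    r2 = 1.0 if ss_tot == 0 else 1.0 - ss_res / ss_tot
    dof = max(c.size - (1 if force_origin else 2), 1)
    return CalibrationCurve(
        slope=slope, intercept=intercept, r_squared=r2,
        conc_range=(float(c.min()), float(c.max())),
        residual_sd=math.sqrt(ss_res / dof), n=int(c.size),
        forced_origin=force_origin,
    )


@dataclass(frozen=True)
class NashResult:
    concentrations: np.ndarray
    flags: tuple[tuple[str, ...], ...]


def nash_quantify(a412, curve: CalibrationCurve) -> NashResult:
    """Formaldehyde concentrations (uM) from A412 readings.

    Negative back-calculated values are floored at zero with a flag;
    readings above the calibrated range are flagged as extrapolation.
    """
    a = np.atleast_1d(np.asarray(a412, dtype=float))
    conc = (a - curve.intercept) / curve.slope
    flags: list[tuple[str, ...]] = []
    out = np.empty_like(conc)
    for i, c in enumerate(conc):
        f: list[str] = []
        if c < 0:
            f.append("negative_floored")
            c = 0.0
        if c > curve.conc_range[1]:
            f.append("above_calibrated_range")
        out[i] = c
        flags.append(tuple(f))
    return NashResult(concentrations=out, flags=tuple(flags))


def _initial_linear_window(t: np.ndarray, y: np.ndarray,
                           min_points: int, r2_threshold: float) -> int:
    """Length of the longest prefix whose linear fit has r^2 >= threshold."""
    best = 0
    for n in range(min_points, t.size + 1):
        res = stats.linregress(t[:n], y[:n])
        ss_tot = float(np.sum((y[:n] - y[:n].mean()) ** 2))
        r2 = 1.0 if ss_tot == 0 else res.rvalue ** 2
        if r2 >= r2_threshold:
            best = n
    return best if best else min_points


def rate_from_absorbance(
    times_min,
    absorbance,
    extinction: float = NADH_EXTINCTION_340,
    path_cm: float = 1.0,
    mode: str = "extinction",
    curve: CalibrationCurve | None = None,
    min_points: int = 4,
    r2_threshold: float = 0.99,
) -> dict:
    """Initial reaction velocity from an A340 trace.

    The initial window is the longest prefix with a linear fit of
    r^2 >= ``r2_threshold`` (minimum ``min_points``).  ``extinction``
    mode converts the AU/min slope by Beer-Lambert (result in M/min);
    ``standard_curve`` mode first maps each reading to concentration via
    a fitted NADH standard curve (result in the curve's concentration
    units per min).
    """
    t = np.asarray(times_min, dtype=float)
    a = np.asarray(absorbance, dtype=float)
    if t.size != a.size:
        raise ValueError("times and absorbance must have equal length")
    if t.size < min_points:
        raise ValueError(f"need at least {min_points} points in the trace")
    if mode == "standard_curve":
        if curve is None:
            raise ValueError("standard_curve mode requires a fitted calibration curve")
        y = (a - curve.intercept) / curve.slope
    elif mode == "extinction":
        y = a
    else:
        raise ValueError(f"unknown mode {mode!r}")
    n = _initial_linear_window(t, y, min_points, r2_threshold)
    res = stats.linregress(t[:n], y[:n])
    slope = float(res.slope)
    velocity = slope / (extinction * path_cm) if mode == "extinction" else slope
    return {
        "velocity": velocity,
        "slope": slope,
        "window_points": n,
        "mode": mode,
        "r_squared": float(res.rvalue**2) if np.std(y[:n]) > 0 else 1.0,
    }


@dataclass(frozen=True)
class ExpressionFractions:
    """Inputs of the soluble-enzyme fraction calculation.

    ``protein_s``/``protein_i``: total protein in the soluble/insoluble
    lysate fraction; ``pct_s_mdh``/``pct_i_mdh``: percent of each
    fraction's protein attributable to the dehydrogenase band.
    """

    protein_s: float
    protein_i: float
    pct_s_mdh: float
    pct_i_mdh: float

    def __post_init__(self) -> None:
        if self.protein_s < 0 or self.protein_i < 0:
            raise ValueError("protein amounts must be non-negative")
        for name in ("pct_s_mdh", "pct_i_mdh"):
            p = getattr(self, name)
            if not 0 <= p <= 100:
                raise ValueError(f"{name} must be in [0, 100]")


def soluble_fraction(e: ExpressionFractions) -> float:
    """Percent of total enzyme found in the soluble fraction."""
    s = e.protein_s * e.pct_s_mdh
    i = e.protein_i * e.pct_i_mdh
    if s + i == 0:
        raise ValueError("both soluble and insoluble enzyme amounts are zero")
    return 100.0 * s / (s + i)


def fractional_inhibition(v_control: float, v_treated: float) -> float:
    """Percent activity lost relative to an untreated control."""
    if v_control <= 0:
        raise ValueError("control velocity must be positive")
    return 100.0 * (1.0 - v_treated / v_control)
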