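"""Gibbs-energy arithmetic for NAD-dependent methanol oxidation.

The reaction under study is

    CH3OH + NAD+  <->  CH2O + NADH + H+      (dG0' = +34.2 kJ/mol)

which is thermodynamically uphill: at typical intracellular NAD:NADH
ratios the reaction sits close to equilibrium unless formaldehyde is
drained rapidly by a downstream sink.  This module provides

* the reaction quotient and dG = dG0 + RT ln Q,
* the equilibrium concentration of any single species,
* the flux-force relationship dG = -RT ln(J+/J-) between the Gibbs
  energy and the ratio of unidirectional fluxes, and
* the paired-steady-state reversibility bound: comparing steady-state
  formaldehyde in a strain expressing only the dehydrogenase (assumed at
  or below equilibrium) with a strain expressing the full assimilation
  pathway bounds J+/J- from below by the fold reduction in formaldehyde,
  without needing dG0 or the intracellular methanol concentration.

Concentrations are molar throughout; CSV-facing code converts from uM.
Activities are taken equal to concentrations (no ionic-strength
correction), and formaldehyde is treated as a single pool, which is what
a Nash assay of the supernatant measures.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from typing import Callable

import numpy as np

__all__ = [
    "R_GAS",
    "DEFAULT_TEMPERATURE",
    "DG0_METHANOL_OXIDATION",
    "ConcentrationState",
    "ThermoResult",
    "SteadyStateObservation",
    "ReversibilityEstimate",
    "PropagationResult",
    "reaction_quotient",
    "delta_g",
    "delta_g_at",
    "equilibrium_concentration",
    "flux_ratio_from_dg",
    "dg_from_flux_ratio",
    "forward_fraction_from_flux_ratio",
    "reversibility_bound",
    "reversibility_bound_from_ratio",
    "propagate_uncertainty",
]

#: Gas constant, kJ mol^-1 K^-1.
R_GAS = 8.3145e-3

#: Assay temperature, 37 C.
DEFAULT_TEMPERATURE = 310.15

#: Standard transformed Gibbs energy of NAD-dependent methanol oxidation, kJ/mol.
DG0_METHANOL_OXIDATION = 34.2

#: Cap used to report an effectively infinite flux-ratio bound.
FLUX_RATIO_CAP = 1e9


@dataclass(frozen=True)
class ConcentrationState:
    """Molar concentrations entering the reaction quotient.

    ``nad``/``nadh`` may be omitted in favour of ``nad_ratio`` (the
    NAD:NADH ratio) when only the ratio is known; absolute values are
    then flagged unknown and operations that need them raise.
    """

    methanol: float
    formaldehyde: float
    nad: float | None = None
    nadh: float | None = None
    nad_ratio: float | None = None
    temperature: float = DEFAULT_TEMPERATURE

    def __post_init__(self) -> None:
        for name in ("methanol", "formaldehyde", "nad", "nadh", "nad_ratio"):
            value = getattr(self, name)
            if value is not None and value < 0:
                raise ValueError(f"{name} must be non-negative, got {value}")
        if self.temperature <= 0:
            raise ValueError("temperature must be positive (kelvin)")
        if self.nad_ratio is None and (self.nad is None or self.nadh is None):
            raise ValueError("supply either nad and nadh, or nad_ratio")
        if self.nad_ratio is not None and (self.nad is not None or self.nadh is not None):
            raise ValueError("supply nad/nadh or nad_ratio, not both")

    @property
    def has_absolute_nad(self) -> bool:
        return self.nad_ratio is None

    @property
    def ratio(self) -> float:
        """NAD:NADH ratio, whichever way it was supplied."""
        if self.nad_ratio is not None:
            return self.nad_ratio
        if self.nadh == 0:
            raise ZeroDivisionError("nadh is zero; NAD:NADH ratio undefined")
        return self.nad / self.nadh


@dataclass(frozen=True)
class ThermoResult:
    """A Gibbs energy together with the quotient it came from."""

    delta_g: float
    reaction_quotient: float
    temperature: float = DEFAULT_TEMPERATURE
    is_upper_bound: bool = False


@dataclass(frozen=True)
class SteadyStateObservation:
    """One steady-state formaldehyde measurement (uM) for one strain.

    ``pathway`` is ``"mdh_only"`` (dehydrogenase alone, assumed at or
    below equilibrium) or ``"full_pathway"`` (dehydrogenase plus the
    formaldehyde-assimilating enzymes).
    """

    formaldehyde_um: float
    formaldehyde_sd_um: float = 0.0
    nad_ratio: float | None = None
    nad_ratio_sd: float = 0.0
    condition: str = ""
    pathway: str = "full_pathway"
    n_replicates: int = 3

    def __post_init__(self) -> None:
        if self.formaldehyde_um < 0:
            raise ValueError("formaldehyde_um must be non-negative")
        if self.formaldehyde_sd_um < 0 or self.nad_ratio_sd < 0:
            raise ValueError("standard deviations must be non-negative")
        if self.pathway not in ("mdh_only", "full_pathway"):
            raise ValueError(f"unknown pathway {self.pathway!r}")


@dataclass(frozen=True)
class ReversibilityEstimate:
    """Forward-flux fraction of the dehydrogenase, as bound or point estimate.

    ``flux_ratio`` is J+/J-; ``forward_fraction`` = flux_ratio/(1+flux_ratio).
    ``interval`` is (lo, hi) on the forward fraction.  ``bound_kind`` is
    ``"lower_bound"`` (thermodynamic pairing) or ``"point_estimate"``
    (isotope-effect framework).
    """

    forward_fraction: float
    flux_ratio: float
    bound_kind: str
    interval: tuple[float, float] = (math.nan, math.nan)
    flags: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.bound_kind not in ("lower_bound", "point_estimate"):
            raise ValueError(f"unknown bound_kind {self.bound_kind!r}")
        if math.isfinite(self.flux_ratio):
            expected = self.flux_ratio / (1.0 + self.flux_ratio)
            if abs(expected - self.forward_fraction) > 1e-12:
                raise ValueError(
                    "forward_fraction inconsistent with flux_ratio: "
                    f"{self.forward_fraction} vs {expected}"
                )
        lo, hi = self.interval
        if math.isfinite(lo) and math.isfinite(hi) and lo > hi:
            raise ValueError("interval lo must not exceed hi")

    @classmethod
    def from_flux_ratio(
        cls,
        flux_ratio: float,
        bound_kind: str,
        interval: tuple[float, float] = (math.nan, math.nan),
        flags: tuple[str, ...] = (),
    ) -> "ReversibilityEstimate":
        return cls(
            forward_fraction=forward_fraction_from_flux_ratio(flux_ratio),
            flux_ratio=flux_ratio,
            bound_kind=bound_kind,
            interval=interval,
            flags=flags,
        )

    @property
    def percent(self) -> int:
        """Forward fraction as integer percent, rounded half-up."""
        return percent_round_half_up(self.forward_fraction)


def percent_round_half_up(fraction: float) -> int:
    return int(math.floor(fraction * 100.0 + 0.5))


def reaction_quotient(state: ConcentrationState) -> float:
    """Q = ([CH2O][NADH]) / ([CH3OH][NAD]).

    With only the NAD:NADH ratio known this is [CH2O]/([CH3OH] * ratio),
    identical because the absolute dinucleotide levels cancel.
    """
    if state.methanol == 0:
        raise ZeroDivisionError("methanol is zero: reaction quotient undefined (field 'methanol')")
    if state.has_absolute_nad:
        if state.nad == 0:
            raise ZeroDivisionError("nad is zero: reaction quotient undefined (field 'nad')")
        return (state.formaldehyde * state.nadh) / (state.methanol * state.nad)
    if state.nad_ratio == 0:
        raise ZeroDivisionError("nad_ratio is zero: reaction quotient undefined (field 'nad_ratio')")
    return state.formaldehyde / (state.methanol * state.nad_ratio)


def delta_g(dg0: float, q: float, temperature: float = DEFAULT_TEMPERATURE) -> float:
    """dG = dG0 + RT ln Q (kJ/mol).  Q = 0 returns -inf with a warning."""
    if q < 0:
        raise ValueError(f"reaction quotient must be non-negative, got {q}")
    if q == 0:
        warnings.warn("reaction quotient is zero; returning -inf", stacklevel=2)
        return -math.inf
    return dg0 + R_GAS * temperature * math.log(q)


def delta_g_at(
    state: ConcentrationState,
    dg0: float = DG0_METHANOL_OXIDATION,
    is_upper_bound: bool = False,
) -> ThermoResult:
    q = reaction_quotient(state)
    return ThermoResult(
        delta_g=delta_g(dg0, q, state.temperature),
        reaction_quotient=q,
        temperature=state.temperature,
        is_upper_bound=is_upper_bound,
    )


_NUMERATOR = ("formaldehyde", "nadh")
_DENOMINATOR = ("methanol", "nad")


def equilibrium_concentration(
    dg0: float,
    state: ConcentrationState,
    solve_for: str = "formaldehyde",
) -> float:
    """Concentration of ``solve_for`` (M) that makes dG = 0.

    All other species are held at the values in ``state``.  In ratio
    mode only ``formaldehyde`` and ``methanol`` can be solved for, since
    the dinucleotides enter the quotient only through their ratio.
    """
    q_eq = math.exp(-dg0 / (R_GAS * state.temperature))
    ratio_mode = not state.has_absolute_nad
    if solve_for in ("nad", "nadh") and ratio_mode:
        raise ValueError(f"cannot solve for {solve_for!r} when only the NAD:NADH ratio is known")
    if solve_for not in _NUMERATOR + _DENOMINATOR:
        raise ValueError(f"species {solve_for!r} does not appear in the reaction quotient")

    def fixed(name: str) -> float:
        value = getattr(state, name)
        if value is None or value <= 0:
            raise ValueError(f"fixed species {name!r} must be positive to solve for {solve_for!r}")
        return value

    if ratio_mode:
        if solve_for == "formaldehyde":
            return q_eq * fixed("methanol") * fixed("nad_ratio")
        return fixed("formaldehyde") / (q_eq * fixed("nad_ratio"))
    if solve_for in _NUMERATOR:
        other = "nadh" if solve_for == "formaldehyde" else "formaldehyde"
        return q_eq * fixed("methanol") * fixed("nad") / fixed(other)
    other = "nad" if solve_for == "methanol" else "methanol"
    return fixed("formaldehyde") * fixed("nadh") / (q_eq * fixed(other))


def flux_ratio_from_dg(dg: float, temperature: float = DEFAULT_TEMPERATURE) -> float:
    """J+/J- = exp(-dG/RT): the flux-force relationship."""
    return math.exp(-dg / (R_GAS * temperature))


def dg_from_flux_ratio(flux_ratio: float, temperature: float = DEFAULT_TEMPERATURE) -> float:
    """Inverse of :func:`flux_ratio_from_dg`."""
    if flux_ratio <= 0:
        raise ValueError("flux ratio must be positive")
    return -R_GAS * temperature * math.log(flux_ratio)


def forward_fraction_from_flux_ratio(flux_ratio):
    """J+/(J+ + J-) = r/(1+r) for r = J+/J-.  Accepts arrays."""
    r = np.asarray(flux_ratio, dtype=float)
    with np.errstate(invalid="ignore"):
        out = np.where(np.isinf(r), 1.0, r / (1.0 + r))
    if np.ndim(flux_ratio) == 0:
        return float(out)
    return out


@dataclass(frozen=True)
class PropagationResult:
    """Monte-Carlo (or delta-method) uncertainty for a scalar estimator."""

    point: float
    mean: float
    sd: float
    interval: tuple[float, float]          # mean +/- sd, the reporting convention here
    percentile_interval: tuple[float, float]
    n_valid: int
    n_samples: int
    method: str = "monte_carlo"

    @property
    def invalid_fraction(self) -> float:
        return 1.0 - self.n_valid / self.n_samples


def propagate_uncertainty(
    point_fn: Callable[..., np.ndarray],
    inputs: dict[str, tuple[float, float]],
    n_samples: int = 10000,
    seed: int = 0,
    method: str = "monte_carlo",
) -> PropagationResult:
    """Propagate mean/sd input uncertainty through ``point_fn``.

    ``point_fn`` must accept keyword arrays (one draw per element) and
    return an array; draws on which it returns non-finite values are
    dropped.  Monte Carlo is the default because ratios of noisy
    positive quantities are skewed; a first-order delta method is kept
    for cross-checks.  Deterministic for a fixed ``seed``.
    """
    for name, (_, sd) in inputs.items():
        if sd < 0:
            raise ValueError(f"sd for {name!r} must be non-negative")
    means = {name: mu for name, (mu, _) in inputs.items()}
    point = float(np.asarray(point_fn(**means)))

    if method == "delta":
        var = 0.0
        for name, (mu, sd) in inputs.items():
            if sd == 0:
                continue
            h = 1e-6 * max(abs(mu), 1.0)
            hi = dict(means, **{name: mu + h})
            lo = dict(means, **{name: mu - h})
            grad = (float(point_fn(**hi)) - float(point_fn(**lo))) / (2 * h)
            var += (grad * sd) ** 2
        sd_out = math.sqrt(var)
        return PropagationResult(
            point=point, mean=point, sd=sd_out,
            interval=(point - sd_out, point + sd_out),
            percentile_interval=(point - 1.96 * sd_out, point + 1.96 * sd_out),
            n_valid=n_samples, n_samples=n_samples, method="delta",
        )
    if method != "monte_carlo":
        raise ValueError(f"unknown method {method!r}")
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")

    rng = np.random.default_rng(seed)
    draws = {
        name: (mu + sd * rng.standard_normal(n_samples) if sd > 0
               else np.full(n_samples, mu))
        for name, (mu, sd) in inputs.items()
    }
    with np.errstate(all="ignore"):
        values = np.asarray(point_fn(**draws), dtype=float)
    valid = np.isfinite(values)
    n_valid = int(valid.sum())
    if n_valid < 0.5 * n_samples:
        bad = [name for name, (mu, sd) in inputs.items() if sd > 0]
        raise ValueError(
            "estimator undefined on more than half of the Monte-Carlo draws; "
            f"check domains of noisy inputs {bad}"
        )
    values = values[valid]
    mean = float(values.mean())
    sd_out = float(values.std(ddof=1)) if n_valid > 1 else 0.0
    lo, hi = (np.percentile(values, [2.5, 97.5]) if n_valid > 1 else (mean, mean))
    return PropagationResult(
        point=point, mean=mean, sd=sd_out,
        interval=(mean - sd_out, mean + sd_out),
        percentile_interval=(float(lo), float(hi)),
        n_valid=n_valid, n_samples=n_samples, method="monte_carlo",
    )


def reversibility_bound_from_ratio(
    fold_ratio: float,
    fold_ratio_sd: float = 0.0,
    nad_ratio_correction: float = 1.0,
    nad_ratio_correction_sd: float = 0.0,
    n_samples: int = 10000,
    seed: int = 0,
) -> ReversibilityEstimate:
    """Reversibility bound from a measured fold reduction in formaldehyde.

    ``fold_ratio`` = [CH2O]_mdh_only / [CH2O]_full_pathway.  The bound is
    J+/J- >= fold_ratio * (NAD:NADH ratio full)/(NAD:NADH ratio mdh-only);
    with matched redox states the correction is 1 and the bound reduces
    to the bare fold reduction.
    """
    if fold_ratio < 0 or nad_ratio_correction <= 0:
        raise ValueError("fold_ratio must be >= 0 and nad_ratio_correction > 0")
    flags: tuple[str, ...] = ()
    if not math.isfinite(fold_ratio) or fold_ratio > FLUX_RATIO_CAP:
        return ReversibilityEstimate.from_flux_ratio(
            FLUX_RATIO_CAP, "lower_bound", (1.0, 1.0), ("infinite_bound_capped",)
        )

    def estimator(ratio, correction):
        r = np.asarray(ratio, dtype=float) * np.asarray(correction, dtype=float)
        r = np.where(r <= 0, np.nan, r)
        return forward_fraction_from_flux_ratio(r)

    prop = propagate_uncertainty(
        estimator,
        {"ratio": (fold_ratio, fold_ratio_sd),
         "correction": (nad_ratio_correction, nad_ratio_correction_sd)},
        n_samples=n_samples, seed=seed,
    )
    return ReversibilityEstimate.from_flux_ratio(
        fold_ratio * nad_ratio_correction, "lower_bound", prop.interval, flags
    )


def reversibility_bound(
    obs_mdh_only: SteadyStateObservation,
    obs_full: SteadyStateObservation,
    n_samples: int = 10000,
    seed: int = 0,
) -> ReversibilityEstimate:
    """Paired-steady-state lower bound on the forward-flux fraction.

    The strain expressing only the dehydrogenase is assumed at (or below)
    equilibrium, so J+/J- >= [CH2O]_mdh_only/[CH2O]_full, corrected by the
    ratio of NAD:NADH ratios when both observations carry one.
    """
    if obs_full.formaldehyde_um == 0:
        return ReversibilityEstimate.from_flux_ratio(
            FLUX_RATIO_CAP, "lower_bound", (1.0, 1.0), ("infinite_bound_capped",)
        )

    def estimator(f1, f2, c1, c2):
        f1 = np.asarray(f1, dtype=float)
        f2 = np.asarray(f2, dtype=float)
        r = np.where((f1 <= 0) | (f2 <= 0) | (c1 <= 0) | (c2 <= 0),
                     np.nan, (f1 / f2) * (np.asarray(c2) / np.asarray(c1)))
        return forward_fraction_from_flux_ratio(r)

    have_nad = obs_mdh_only.nad_ratio is not None and obs_full.nad_ratio is not None
    c1 = (obs_mdh_only.nad_ratio, obs_mdh_only.nad_ratio_sd) if have_nad else (1.0, 0.0)
    c2 = (obs_full.nad_ratio, obs_full.nad_ratio_sd) if have_nad else (1.0, 0.0)
    prop = propagate_uncertainty(
        estimator,
        {"f1": (obs_mdh_only.formaldehyde_um, obs_mdh_only.formaldehyde_sd_um),
         "f2": (obs_full.formaldehyde_um, obs_full.formaldehyde_sd_um),
         "c1": c1, "c2": c2},
        n_samples=n_samples, seed=seed,
    )
    flux_ratio = (obs_mdh_only.formaldehyde_um / obs_full.formaldehyde_um) * (c2[0] / c1[0])
    flags = () if have_nad else ("nad_ratio_assumed_equal",)
    return ReversibilityEstimate.from_flux_ratio(flux_ratio, "lower_bound", prop.interval, flags)
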