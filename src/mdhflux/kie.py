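"""Kinetic-isotope-effect flux partitioning at the formaldehyde node.

Feeding deuterated methanol (CD3OD) slows the dehydrogenase forward step
by the primary KIE alpha = k1H/k1D, while the back reaction carries the
equilibrium isotope effect gamma = K_H/K_D (~1.07 for NAD-dependent
primary alcohol oxidations).  At steady state the ratio of formaldehyde
pools with protonated vs deuterated substrate,

    R = [CH2O]_ss / [CD2O]_ss = (gamma + alpha*beta) / (1 + beta),

interpolates between gamma (fully reversible dehydrogenase, beta = 0)
and alpha (fully forward, beta -> inf), where beta is the ratio of the
irreversible sink flux to the reverse dehydrogenase flux.  Inverting:

    beta = (gamma - R) / (R - alpha)
    MDH_F/MDH_R = 1 + beta = (gamma - alpha)/(R - alpha)
    forward fraction = (1 + beta)/(2 + beta) = (gamma - alpha)/(gamma + R - 2 alpha)

so a single measured concentration ratio yields a *point estimate* of
the dehydrogenase reversibility, complementing the thermodynamic lower
bound of :mod:`mdhflux.thermo`.  The secondary KIE of the sink enzyme
(~1.04) is neglected in this algebra, as the derivation assumes; an
optional numeric correction mode quantifies the approximation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .dynamics import KineticState
from .thermo import (
    PropagationResult,
    ReversibilityEstimate,
    propagate_uncertainty,
)

__all__ = [
    "IsotopeEffects",
    "PairedSteadyState",
    "beta_from_ratio",
    "forward_fraction_from_kie",
    "reversibility_ratio_from_kie",
    "predicted_ratio_from_kinetics",
    "deuterated_state",
    "validate_ratio",
    "kie_partition_with_uncertainty",
]

DEFAULT_ALPHA = 3.2
DEFAULT_GAMMA = 1.07
DEFAULT_HPS_SECONDARY_KIE = 1.04


@dataclass(frozen=True)
class IsotopeEffects:
    """Primary KIE alpha, equilibrium isotope effect gamma, secondary sink KIE.

    alpha > gamma > 0 is required: it is what makes R a strictly
    monotone readout of reversibility.  ``hps_secondary_kie`` is stored
    for provenance and optional sensitivity analysis but neglected in
    the closed-form algebra.
    """

    alpha: float = DEFAULT_ALPHA
    gamma: float = DEFAULT_GAMMA
    hps_secondary_kie: float = DEFAULT_HPS_SECONDARY_KIE
    gamma_provenance: str = "NAD-dependent primary alcohol oxidation EIE (literature)"

    def __post_init__(self) -> None:
        if not (self.alpha > self.gamma > 0):
            raise ValueError(
                f"require alpha > gamma > 0, got alpha={self.alpha}, gamma={self.gamma}"
            )
        if self.hps_secondary_kie <= 0:
            raise ValueError("hps_secondary_kie must be positive")


@dataclass(frozen=True)
class PairedSteadyState:
    """Steady-state formaldehyde (uM) with protonated vs deuterated methanol."""

    f_ss_h: float | None = None
    f_ss_h_sd: float = 0.0
    f_ss_d: float | None = None
    f_ss_d_sd: float = 0.0
    ratio: float | None = None
    ratio_sd: float = 0.0
    condition: str = ""

    def __post_init__(self) -> None:
        if self.ratio is None:
            if self.f_ss_h is None or self.f_ss_d is None:
                raise ValueError("supply either both concentrations or a ratio")
            if self.f_ss_d <= 0:
                raise ValueError("deuterated steady state must be positive")
            object.__setattr__(self, "ratio", self.f_ss_h / self.f_ss_d)
            if self.f_ss_h > 0:
                sd = self.ratio * math.sqrt(
                    (self.f_ss_h_sd / self.f_ss_h) ** 2
                    + (self.f_ss_d_sd / self.f_ss_d) ** 2
                )
                object.__setattr__(self, "ratio_sd", sd)
        elif self.f_ss_h is not None and self.f_ss_d is not None and self.f_ss_d > 0:
            if abs(self.ratio - self.f_ss_h / self.f_ss_d) > 1e-9 * abs(self.ratio):
                raise ValueError("supplied ratio inconsistent with concentrations")
        if self.ratio is not None and self.ratio <= 0:
            raise ValueError("ratio must be positive")


def validate_ratio(
    ratio: float,
    effects: IsotopeEffects,
    policy: str = "strict",
) -> tuple[float, tuple[str, ...]]:
    """Check R against its physical domain [gamma, alpha].

    ``strict`` raises outside the domain; ``clamp`` projects onto the
    nearest endpoint and records a flag.  Values exactly at an endpoint
    are valid but flagged, since they imply a degenerate (fully
    reversible / fully forward) regime.
    """
    if policy not in ("strict", "clamp"):
        raise ValueError(f"unknown policy {policy!r}")
    flags: list[str] = []
    r = float(ratio)
    if r < effects.gamma:
        if policy == "strict":
            raise ValueError(
                f"ratio {r} below the equilibrium isotope effect {effects.gamma}"
            )
        r = effects.gamma
        flags.append("clamped_to_eie")
    elif r > effects.alpha:
        if policy == "strict":
            raise ValueError(f"ratio {r} above the kinetic isotope effect {effects.alpha}")
        r = effects.alpha
        flags.append("clamped_to_kie")
    if r == effects.gamma:
        flags.append("at_eie_limit")
    if r == effects.alpha:
        flags.append("at_kie_limit")
    return r, tuple(flags)


def beta_from_ratio(ratio: float, effects: IsotopeEffects | None = None,
                    policy: str = "strict") -> float:
    """beta = (gamma - R)/(R - alpha); infinite at R = alpha."""
    effects = effects or IsotopeEffects()
    r, _ = validate_ratio(ratio, effects, policy)
    if r == effects.alpha:
        return math.inf
    return (effects.gamma - r) / (r - effects.alpha)


def reversibility_ratio_from_kie(ratio: float, effects: IsotopeEffects | None = None,
                                 policy: str = "strict") -> float:
    """Forward-to-reverse dehydrogenase flux ratio, (gamma - alpha)/(R - alpha)."""
    effects = effects or IsotopeEffects()
    r, _ = validate_ratio(ratio, effects, policy)
    if r == effects.alpha:
        return math.inf
    return (effects.gamma - effects.alpha) / (r - effects.alpha)


def forward_fraction_from_kie(ratio, effects: IsotopeEffects | None = None,
                              policy: str = "strict"):
    """Forward-flux fraction (gamma - alpha)/(gamma + R - 2 alpha), in [0.5, 1].

    Accepts scalars or arrays; arrays are evaluated without domain
    checking (callers clamp per draw), scalars honour ``policy``.
    """
    effects = effects or IsotopeEffects()
    a, g = effects.alpha, effects.gamma
    if np.ndim(ratio) > 0:
        r = np.asarray(ratio, dtype=float)
        return (g - a) / (g + r - 2.0 * a)
    r, _ = validate_ratio(float(ratio), effects, policy)
    return (g - a) / (g + r - 2.0 * a)


def deuterated_state(state: KineticState, effects: IsotopeEffects,
                     apply_secondary: bool = False) -> KineticState:
    """Rate constants for the deuterated channel.

    k1D = k1H/alpha and k_-1D = gamma*k_-1H/alpha (so that the
    equilibrium constants differ by exactly gamma).  The sink constant
    is unchanged unless ``apply_secondary``, which divides k2 by the
    secondary KIE for sensitivity analysis.
    """
    from dataclasses import replace
    k2 = state.k2 / effects.hps_secondary_kie if apply_secondary else state.k2
    return replace(state, k1=state.k1 / effects.alpha,
                   k_minus1=effects.gamma * state.k_minus1 / effects.alpha, k2=k2)


def predicted_ratio_from_kinetics(state_h: KineticState,
                                  effects: IsotopeEffects | None = None,
                                  apply_secondary: bool = False) -> float:
    """Forward model: R predicted from mass-action constants.

    Computed from the steady states of the protonated state and its
    derived deuterated counterpart, so the secondary-KIE correction mode
    falls out numerically rather than from the closed form.
    """
    from .dynamics import analytic_steady_state
    effects = effects or IsotopeEffects()
    state_d = deuterated_state(state_h, effects, apply_secondary)
    if state_h.relaxation_rate == 0 or state_d.relaxation_rate == 0:
        raise ValueError("undefined steady state: both sink and reverse flux are zero")
    return analytic_steady_state(state_h) / analytic_steady_state(state_d)


def kie_partition_with_uncertainty(
    paired: PairedSteadyState,
    effects: IsotopeEffects | None = None,
    alpha_sd: float = 0.0,
    gamma_sd: float = 0.0,
    n_samples: int = 10000,
    seed: int = 0,
) -> tuple[ReversibilityEstimate, PropagationResult, float]:
    """Point estimate plus Monte-Carlo interval for the forward fraction.

    The point estimate is evaluated at the means (clamped to [gamma,
    alpha] with flags); each Monte-Carlo draw is clamped to its own
    drawn domain, and the fraction of clamped draws is returned so a
    boundary condition (R at the KIE limit) is visible in reports.
    Returns ``(estimate, propagation, clamp_fraction)``.
    """
    effects = effects or IsotopeEffects()
    n_clamped = 0

    def estimator(r, a, g):
        r = np.asarray(r, dtype=float)
        a = np.asarray(a, dtype=float)
        g = np.asarray(g, dtype=float)
        bad = ~(a > g)
        clamped = (r < g) | (r > a)
        nonlocal n_clamped
        if r.size > 1:
            n_clamped = int(np.sum(clamped & ~bad))
        rc = np.clip(r, g, a)
        out = (g - a) / (g + rc - 2.0 * a)
        out = np.where(np.isclose(rc, a) & ~bad, 1.0, out)
        return np.where(bad, np.nan, out)

    prop = propagate_uncertainty(
        estimator,
        {"r": (paired.ratio, paired.ratio_sd),
         "a": (effects.alpha, alpha_sd),
         "g": (effects.gamma, gamma_sd)},
        n_samples=n_samples, seed=seed,
    )
    clamp_fraction = n_clamped / n_samples
    r_point, flags = validate_ratio(paired.ratio, effects, policy="clamp")
    if r_point == effects.alpha:
        flux_ratio = math.inf
        fraction = 1.0
    else:
        flux_ratio = reversibility_ratio_from_kie(r_point, effects)
        fraction = forward_fraction_from_kie(r_point, effects)
    estimate = ReversibilityEstimate(
        forward_fraction=fraction,
        flux_ratio=flux_ratio,
        bound_kind="point_estimate",
        interval=prop.interval,
        flags=flags,
    )
    return estimate, prop, clamp_fraction
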