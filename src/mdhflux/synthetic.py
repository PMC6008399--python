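"""Synthetic-data generators with known ground truth.

Every dataset the analysis modules consume can be generated here from a
seed, so the full pipeline is testable end to end without measurements:
paired H/D formaldehyde timecourses from the mass-action model, the
steady-state observation table (including the bundled in-study fixture
of printed values), Michaelis-Menten assay plates, Nash calibration
standards and mass isotopomer distributions.

Noise on concentrations is multiplicative log-normal parameterised by a
coefficient of variation (colorimetric readings are positive and
CV-dominated); the log-normal is mean-preserving.  Every generator is a
pure function of its seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import dynamics, enzymology, isotopes, kie
from .dynamics import KineticState, SimulationConfig, Timecourse, detect_steady_state, simulate
from .kie import IsotopeEffects

__all__ = [
    "GroundTruth",
    "PairedKieExperiment",
    "generate_paired_kie_experiment",
    "recover_forward_fraction",
    "generate_steady_state_table",
    "paper_fixture_table",
    "generate_mm_assay",
    "generate_mid",
    "generate_nash_standards",
]

#: Substrate levels (mM) of the dehydrogenase assay plates.
MM_SUBSTRATE_LEVELS_MM = (6.0, 12.0, 35.0, 70.0, 150.0, 300.0)


def _lognormal_noise(rng: np.random.Generator, shape, cv: float) -> np.ndarray:
    """Mean-one multiplicative noise with coefficient of variation ``cv``."""
    if cv == 0:
        return np.ones(shape)
    sigma = math.sqrt(math.log(1.0 + cv * cv))
    return rng.lognormal(mean=-0.5 * sigma * sigma, sigma=sigma, size=shape)


@dataclass(frozen=True)
class GroundTruth:
    """True parameters behind a paired H/D experiment.

    ``forward_fraction`` and ``beta`` are linked by
    beta = (2f - 1)/(1 - f); the kinetic constants are chosen in
    dimensionless units with k1[NAD][CH3OH] = 1 and k_-1[NADH] = 1, so
    k2[Ru5P] = beta and the protonated steady state is 1/(1 + beta).
    """

    forward_fraction: float
    effects: IsotopeEffects = field(default_factory=IsotopeEffects)
    noise_cv: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.5 < self.forward_fraction < 1.0:
            raise ValueError("forward_fraction must lie strictly inside (0.5, 1)")

    @property
    def beta(self) -> float:
        f = self.forward_fraction
        return (2.0 * f - 1.0) / (1.0 - f)

    @property
    def state_h(self) -> KineticState:
        return KineticState(k1=1.0, k_minus1=1.0, k2=self.beta)

    @property
    def ratio(self) -> float:
        """True steady-state ratio R = (gamma + alpha*beta)/(1 + beta)."""
        a, g, b = self.effects.alpha, self.effects.gamma, self.beta
        return (g + a * b) / (1.0 + b)


@dataclass(frozen=True)
class PairedKieExperiment:
    truth: GroundTruth
    timecourses_h: tuple[Timecourse, ...]
    timecourses_d: tuple[Timecourse, ...]


def generate_paired_kie_experiment(
    truth: GroundTruth,
    noise_cv: float | None = None,
    n_replicates: int = 3,
    seed: int | None = None,
    n_points: int = 60,
) -> PairedKieExperiment:
    """Simulate paired H/D formaldehyde timecourses with known truth.

    The deuterated channel uses k1D = k1H/alpha and
    k_-1D = gamma*k_-1H/alpha, exactly the relations the analysis
    inverts.  Traces run to 12 relaxation times so the plateau is well
    established, then receive multiplicative log-normal noise.
    """
    noise_cv = truth.noise_cv if noise_cv is None else noise_cv
    seed = truth.seed if seed is None else seed
    rng = np.random.default_rng(seed)
    state_h = truth.state_h
    state_d = kie.deuterated_state(state_h, truth.effects)

    out: dict[str, list[Timecourse]] = {"H": [], "D": []}
    for label, state in (("H", state_h), ("D", state_d)):
        config = SimulationConfig(t_end=12.0 / state.relaxation_rate,
                                  n_points=n_points, method="adaptive")
        clean = simulate(state, config)
        for rep in range(n_replicates):
            noisy = clean.formaldehyde * _lognormal_noise(rng, clean.formaldehyde.shape, noise_cv)
            meta = dict(clean.metadata, isotope=label, replicate=rep, seed=seed,
                        noise_cv=noise_cv, true_forward_fraction=truth.forward_fraction)
            out[label].append(Timecourse(clean.times, noisy, meta))
    return PairedKieExperiment(truth, tuple(out["H"]), tuple(out["D"]))


def recover_forward_fraction(
    experiment: PairedKieExperiment,
    rel_tol: float = 0.05,
    window: int = 5,
) -> dict:
    """Analyse a paired experiment back to a forward-flux fraction.

    Steady states are extracted per replicate trace, averaged per
    channel, ratioed, and pushed through the isotope-effect algebra with
    clamping (noise can push R past either physical limit).
    """
    ss_h = [detect_steady_state(tc, rel_tol=rel_tol, window=window) for tc in experiment.timecourses_h]
    ss_d = [detect_steady_state(tc, rel_tol=rel_tol, window=window) for tc in experiment.timecourses_d]
    mean_h = float(np.mean([d.value for d in ss_h]))
    mean_d = float(np.mean([d.value for d in ss_d]))
    ratio = mean_h / mean_d
    fraction = kie.forward_fraction_from_kie(ratio, experiment.truth.effects, policy="clamp")
    return {
        "ratio": ratio,
        "forward_fraction": float(fraction),
        "steady_state_h": mean_h,
        "steady_state_d": mean_d,
        "all_reached": all(d.reached for d in ss_h + ss_d),
    }


# ---------------------------------------------------------------------------
# Steady-state observation tables

_FIXTURE_ROWS = [
    # condition, fold reduction (mdh-only vs full pathway), H/D formaldehyde
    # ratio (full pathway), printed steady-state concentrations where available.
    {
        "condition": "unsupplemented",
        "fold_reduction": 1.2, "fold_reduction_sd": 0.1,
        "hd_ratio": 1.5, "hd_ratio_sd": 0.3,
        "formaldehyde_mdh_uM": 56.0, "formaldehyde_mdh_sd_uM": 4.0,
        "formaldehyde_full_uM": np.nan, "formaldehyde_full_sd_uM": np.nan,
        "n_replicates": 3,
    },
    {
        "condition": "xylose",
        "fold_reduction": 4.7, "fold_reduction_sd": 1.7,
        "hd_ratio": np.nan, "hd_ratio_sd": np.nan,   # pool too low to measure
        "formaldehyde_mdh_uM": np.nan, "formaldehyde_mdh_sd_uM": np.nan,
        "formaldehyde_full_uM": 7.5, "formaldehyde_full_sd_uM": 2.6,
        "n_replicates": 3,
    },
    {
        "condition": "ia_glpx",
        "fold_reduction": 3.0, "fold_reduction_sd": 0.3,
        "hd_ratio": 3.2, "hd_ratio_sd": 0.4,
        "formaldehyde_mdh_uM": 52.0, "formaldehyde_mdh_sd_uM": 1.0,
        "formaldehyde_full_uM": 17.0, "formaldehyde_full_sd_uM": 1.5,
        "n_replicates": 3,
    },
]


def paper_fixture_table() -> pd.DataFrame:
    """The in-study observation fixture (wide "ratio layout").

    One row per condition, holding the printed fold reduction in
    steady-state formaldehyde between the dehydrogenase-only and
    full-pathway strains, the printed H/D formaldehyde ratio where one
    was measurable (NaN marks an indeterminate condition), and the
    printed concentrations where available.
    """
    return pd.DataFrame(_FIXTURE_ROWS)


def generate_steady_state_table(conditions: list[dict] | None = None) -> pd.DataFrame:
    """Long-layout observation table (one row per strain x isotope).

    ``conditions`` entries are dicts with keys ``condition``, ``pathway``
    (mdh_only|full_pathway), ``isotope`` (H|D), ``formaldehyde_uM``,
    ``formaldehyde_sd_uM`` and optionally ``nad_ratio``/``nad_ratio_sd``
    and ``n_replicates``.  With no argument, returns a header-only table.
    """
    columns = ["condition", "pathway", "isotope", "formaldehyde_uM",
               "formaldehyde_sd_uM", "nad_ratio", "nad_ratio_sd", "n_replicates"]
    if not conditions:
        return pd.DataFrame(columns=columns)
    frame = pd.DataFrame(conditions)
    for col in columns:
        if col not in frame.columns:
            frame[col] = np.nan
    return frame[columns]


# ---------------------------------------------------------------------------
# Assay plates and standards

def generate_mm_assay(
    vmax: float,
    km: float,
    substrate_levels=MM_SUBSTRATE_LEVELS_MM,
    noise_sd: float = 0.0,
    n_replicates: int = 3,
    seed: int = 0,
    condition: str = "",
    isotope: str = "H",
) -> pd.DataFrame:
    """Michaelis-Menten velocities at the assay substrate levels.

    Gaussian noise of absolute sd ``noise_sd`` (same units as velocity)
    is added per well, matching the homoscedastic error model of the
    nonlinear fit.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for rep in range(n_replicates):
        for s in substrate_levels:
            v = enzymology.michaelis_menten(s, vmax, km)
            v_noisy = v + noise_sd * rng.standard_normal()
            rows.append({"substrate_mM": s, "velocity": v_noisy,
                         "replicate": rep, "condition": condition, "isotope": isotope})
    return pd.DataFrame(rows)


def generate_nash_standards(
    slope: float = 0.0045,
    intercept: float = 0.05,
    concentrations=None,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Formaldehyde calibration standards, 0-100 uM, A412 responses."""
    rng = np.random.default_rng(seed)
    conc = np.linspace(0.0, 100.0, 6) if concentrations is None else np.asarray(concentrations, float)
    a412 = slope * conc + intercept + noise_sd * rng.standard_normal(conc.shape)
    return pd.DataFrame({"concentration_uM": conc, "a412": a412})


def generate_mid(
    true_profile,
    n_carbons: int | None = None,
    abundance_13c: float = isotopes.NATURAL_13C_ABUNDANCE,
    tracer_purity: float = 1.0,
    noise_cv: float = 0.0,
    seed: int = 0,
    metabolite: str = "f6p",
    condition: str = "",
) -> pd.DataFrame:
    """Measured-style MID: profile convolved with natural abundance + noise.

    Returns the long CSV schema (metabolite, condition, isotope_shift,
    fraction); fractions are renormalised after noise so they sum to one.
    """
    profile = np.asarray(true_profile, dtype=float)
    n = profile.size - 1 if n_carbons is None else n_carbons
    mid = isotopes.MassDistribution(profile / profile.sum(), n, metabolite)
    measured = isotopes.convolve_natural_abundance(mid, abundance_13c, tracer_purity)
    rng = np.random.default_rng(seed)
    noisy = measured.fractions * _lognormal_noise(rng, measured.fractions.shape, noise_cv)
    noisy = noisy / noisy.sum()
    return pd.DataFrame({
        "metabolite": metabolite,
        "condition": condition,
        "isotope_shift": np.arange(n + 1),
        "fraction": noisy,
    })
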