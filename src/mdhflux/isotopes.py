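"""Mass-isotopomer handling for 13C-methanol labeling experiments.

A measured mass isotopomer distribution (MID) of an n-carbon metabolite
mixes the biological labeling signal with 13C natural abundance (and,
optionally, imperfect tracer purity).  Both effects are linear: the
measured MID is ``M @ x`` where ``x`` is the underlying distribution and
``M`` a binomial convolution matrix.  Correction solves the linear
system by non-negative least squares and renormalises.

Only carbon is modelled (the tracer is 13C-methanol; H/O isotope
contributions are second order for the small metabolites involved).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats

__all__ = [
    "NATURAL_13C_ABUNDANCE",
    "MassDistribution",
    "EnrichmentResult",
    "correction_matrix",
    "convolve_natural_abundance",
    "correct_natural_abundance",
    "mean_enrichment",
    "m0_fold_change",
    "quantify_internal_standard",
]

#: Natural abundance of 13C.
NATURAL_13C_ABUNDANCE = 0.0107

#: Default isotopic purity of 13C-methanol tracer.
DEFAULT_TRACER_PURITY = 0.99


@dataclass(frozen=True)
class MassDistribution:
    """Fractions M+0..M+n of an n-carbon metabolite, summing to one."""

    fractions: np.ndarray
    n_carbons: int
    metabolite: str = ""
    flags: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        f = np.asarray(self.fractions, dtype=float)
        if f.size < self.n_carbons + 1:
            raise ValueError(
                f"expected at least {self.n_carbons + 1} fractions for "
                f"{self.n_carbons} carbons, got {f.size}"
            )
        # trailing zero-probability isotopomers beyond n_carbons are tolerated
        if f.size > self.n_carbons + 1 and np.any(f[self.n_carbons + 1:] > 1e-12):
            raise ValueError("non-zero fractions beyond the metabolite's carbon count")
        if np.any(f < -1e-9):
            raise ValueError("fractions must be non-negative")
        total = f.sum()
        if abs(total - 1.0) > 1e-6:
            raise ValueError(f"fractions must sum to 1 (got {total})")
        object.__setattr__(self, "fractions", f)

    @classmethod
    def from_fractions(cls, fractions, metabolite: str = "",
                       flags: tuple[str, ...] = ()) -> "MassDistribution":
        f = np.asarray(fractions, dtype=float)
        f = f / f.sum()
        return cls(f, n_carbons=f.size - 1, metabolite=metabolite, flags=flags)

    @property
    def m0(self) -> float:
        return float(self.fractions[0])


@dataclass(frozen=True)
class EnrichmentResult:
    mean_enrichment: float
    m0: float
    metabolite: str = ""


def correction_matrix(
    n_carbons: int,
    abundance_13c: float = NATURAL_13C_ABUNDANCE,
    tracer_purity: float = 1.0,
) -> np.ndarray:
    """Matrix mapping an underlying MID to the measured MID.

    Column ``j`` is the mass distribution observed for a molecule with
    ``j`` tracer-labeled carbons: the remaining ``n - j`` positions pick
    up 13C at natural abundance (binomial), and, when ``tracer_purity``
    < 1, each of the ``j`` tracer positions is truly 13C only with that
    probability.  With perfect purity the matrix is lower triangular and
    its columns sum to one (carbon-only model conserves total fraction).
    """
    if not 0 <= abundance_13c < 1:
        raise ValueError("abundance must be in [0, 1)")
    if not 0 < tracer_purity <= 1:
        raise ValueError("tracer purity must be in (0, 1]")
    n = n_carbons
    m = np.zeros((n + 1, n + 1))
    for j in range(n + 1):
        natural = stats.binom.pmf(np.arange(n - j + 1), n - j, abundance_13c)
        tracer = stats.binom.pmf(np.arange(j + 1), j, tracer_purity)
        m[:, j] = np.convolve(tracer, natural)[: n + 1]
    return m


def convolve_natural_abundance(
    mid: MassDistribution,
    abundance_13c: float = NATURAL_13C_ABUNDANCE,
    tracer_purity: float = 1.0,
) -> MassDistribution:
    """Forward model: what an instrument would measure for ``mid``."""
    m = correction_matrix(mid.n_carbons, abundance_13c, tracer_purity)
    return MassDistribution.from_fractions(m @ mid.fractions, mid.metabolite)


def correct_natural_abundance(
    raw: MassDistribution,
    abundance_13c: float = NATURAL_13C_ABUNDANCE,
    tracer_purity: float = 1.0,
) -> MassDistribution:
    """Remove natural abundance (and optional tracer impurity) from a MID.

    Solved by non-negative least squares, so small negative components
    from measurement noise are absorbed rather than propagated; the mass
    moved by the non-negativity constraint is reported via the
    ``clipped_mass`` flag.  Convolve-then-correct is the identity to
    ~1e-8 on exact inputs.
    """
    m = correction_matrix(raw.n_carbons, abundance_13c, tracer_purity)
    if np.linalg.cond(m) > 1e12:
        raise ValueError("correction matrix is ill-conditioned")
    x, residual = optimize.nnls(m, raw.fractions)
    total = x.sum()
    if total == 0:
        raise ValueError("correction produced an all-zero distribution")
    flags: tuple[str, ...] = ()
    if residual > 1e-9:
        flags = (f"clipped_mass={residual:.3e}",)
    return MassDistribution(x / total, raw.n_carbons, raw.metabolite, flags)


def mean_enrichment(mid: MassDistribution) -> float:
    """Fraction of carbon positions labeled: sum_i i*M_i / n_carbons.

    Invariant under padding with zero-probability isotopomers beyond the
    true carbon count (the index-weighted sum is unchanged).
    """
    if mid.n_carbons == 0:
        raise ValueError("mean enrichment undefined for a zero-carbon metabolite")
    idx = np.arange(mid.fractions.size)
    return float(np.dot(idx, mid.fractions) / mid.n_carbons)


def enrichment_summary(mid: MassDistribution) -> EnrichmentResult:
    return EnrichmentResult(mean_enrichment(mid), mid.m0, mid.metabolite)


def m0_fold_change(mid_a: MassDistribution, mid_b: MassDistribution) -> float:
    """M+0(a)/M+0(b): rise of the unlabeled fraction between conditions."""
    if mid_a.metabolite and mid_b.metabolite and mid_a.metabolite != mid_b.metabolite:
        raise ValueError("fold change requires the same metabolite")
    if mid_b.m0 == 0:
        raise ZeroDivisionError("reference M+0 fraction is zero")
    return mid_a.m0 / mid_b.m0


def quantify_internal_standard(
    area_unlabeled: float,
    area_fully_labeled: float,
    standard_amount: float,
) -> float:
    """Concentration from an unlabeled peak against a fully-13C spike.

    The biological (unlabeled) peak area is normalised to the co-eluting
    fully labeled internal standard of known amount; the result is
    linear in the unlabeled area, so ratios of pool sizes across
    conditions are independent of the standard amount.
    """
    if area_fully_labeled <= 0:
        raise ValueError("fully labeled area must be positive")
    if area_unlabeled < 0:
        raise ValueError("unlabeled area must be non-negative")
    return standard_amount * area_unlabeled / area_fully_labeled
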