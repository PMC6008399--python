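"""Constraint-based model amendment for methanol assimilation.

Adds the three heterologous reactions (methanol dehydrogenase, hexulose
phosphate synthase, phosphohexulose isomerase) plus passive methanol
uptake to a genome-scale (or toy) stoichiometric model, and provides
the uptake-matching comparison: vary substrate uptake until the optimal
growth rate matches a reference within a tolerance, then compare fluxes
normalised per carbon-mole of substrate so one-carbon and six-carbon
feeds are commensurate.

All tests run on a ~20-reaction toy network built here in code; a
genome-scale SBML file can be supplied externally through the same API.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import cobra
from cobra import Metabolite, Model, Reaction

__all__ = [
    "HeterologousReactionSpec",
    "heterologous_reactions",
    "amend_model",
    "build_toy_model",
    "read_sbml",
    "write_sbml",
    "match_growth_by_uptake",
    "proportional_flux",
    "flux_range",
]

#: Elemental formulas (and charges) for the metabolites the added
#: reactions touch, BiGG-style identifiers.
METABOLITE_FORMULAS: dict[str, tuple[str, int, str]] = {
    "meoh_e": ("CH4O", 0, "methanol (extracellular)"),
    "meoh_c": ("CH4O", 0, "methanol"),
    "fald_c": ("CH2O", 0, "formaldehyde"),
    "nad_c": ("C21H26N7O14P2", -1, "NAD+"),
    "nadh_c": ("C21H27N7O14P2", -2, "NADH"),
    "h_c": ("H", 1, "proton"),
    "ru5p__D_c": ("C5H9O8P", -2, "ribulose 5-phosphate"),
    "h6p_c": ("C6H11O9P", -2, "arabino-3-hexulose 6-phosphate"),
    "f6p_c": ("C6H11O9P", -2, "fructose 6-phosphate"),
}

ELEMENTS = ("C", "H", "O", "N", "P")


@dataclass(frozen=True)
class HeterologousReactionSpec:
    """One reaction to graft onto a host model."""

    id: str
    name: str
    stoichiometry: dict[str, float]       # metabolite id -> coefficient
    reversible: bool = False
    new_metabolites: tuple[str, ...] = ()  # ids absent from typical hosts

    @property
    def lower_bound(self) -> float:
        return -1000.0 if self.reversible else 0.0

    @property
    def upper_bound(self) -> float:
        return 1000.0

    def element_balance(self) -> dict[str, float]:
        """Net elemental change; all-zero for a balanced reaction."""
        import re

        totals = dict.fromkeys(ELEMENTS, 0.0)
        for met_id, coef in self.stoichiometry.items():
            formula = METABOLITE_FORMULAS[met_id][0]
            for element, count in re.findall(r"([A-Z][a-z]?)(\d*)", formula):
                if element in totals:
                    totals[element] += coef * (int(count) if count else 1)
        return totals

    def is_balanced(self, tol: float = 1e-9) -> bool:
        return all(abs(v) < tol for v in self.element_balance().values())


def heterologous_reactions() -> list[HeterologousReactionSpec]:
    """The methanol-assimilation reactions and passive methanol uptake."""
    return [
        HeterologousReactionSpec(
            id="MEOHt",
            name="methanol passive diffusion",
            stoichiometry={"meoh_e": -1, "meoh_c": 1},
            reversible=True,
            new_metabolites=("meoh_e", "meoh_c"),
        ),
        HeterologousReactionSpec(
            id="MDH",
            name="methanol dehydrogenase (NAD)",
            stoichiometry={
                "meoh_c": -1, "nad_c": -1,
                "fald_c": 1, "nadh_c": 1, "h_c": 1,
            },
            reversible=True,
            new_metabolites=("fald_c",),
        ),
        HeterologousReactionSpec(
            id="HPS",
            name="hexulose phosphate synthase",
            stoichiometry={"fald_c": -1, "ru5p__D_c": -1, "h6p_c": 1},
            new_metabolites=("h6p_c",),
        ),
        HeterologousReactionSpec(
            id="PHI",
            name="phosphohexulose isomerase",
            stoichiometry={"h6p_c": -1, "f6p_c": 1},
        ),
    ]


def amend_model(
    model: Model,
    specs: list[HeterologousReactionSpec] | None = None,
    add_exchange: bool = True,
) -> Model:
    """Add the heterologous reactions (in place) and return the model.

    Metabolites already present in the host are reused; new ones get the
    formulas from :data:`METABOLITE_FORMULAS`.  An exchange reaction for
    extracellular methanol is added (closed by default: lower bound 0).
    """
    specs = specs if specs is not None else heterologous_reactions()
    for spec in specs:
        if spec.id in model.reactions:
            continue
        rxn = Reaction(spec.id, name=spec.name,
                       lower_bound=spec.lower_bound, upper_bound=spec.upper_bound)
        stoich = {}
        for met_id, coef in spec.stoichiometry.items():
            if met_id in model.metabolites:
                met = model.metabolites.get_by_id(met_id)
            else:
                formula, charge, name = METABOLITE_FORMULAS[met_id]
                met = Metabolite(met_id, formula=formula, charge=charge, name=name,
                                 compartment="e" if met_id.endswith("_e") else "c")
            stoich[met] = coef
        rxn.add_metabolites(stoich)
        model.add_reactions([rxn])
    if add_exchange and "EX_meoh_e" not in model.reactions and "meoh_e" in model.metabolites:
        model.add_boundary(model.metabolites.get_by_id("meoh_e"),
                           type="exchange", lb=0.0, ub=1000.0)
    return model


def build_toy_model() -> Model:
    """A minimal host network for testing the amendment workflow.

    Lumped glycolysis/pentose-phosphate chemistry with glucose as the
    native substrate and a one-pyruvate biomass reaction.  Growth on
    methanol becomes feasible only after all three heterologous
    reactions are added: the sink regenerates Ru5P from fructose
    6-phosphate via a lumped rearrangement (2 F6P + G3P -> 3 Ru5P).
    Cofactor chemistry is deliberately coarse (carbon bookkeeping is
    exact; protons and phosphate are not tracked).
    """
    model = Model("toy_methylotroph")

    def met(mid, formula, name, compartment=None):
        return Metabolite(mid, formula=formula, name=name,
                          compartment=compartment or ("e" if mid.endswith("_e") else "c"))

    glc_e = met("glc__D_e", "C6H12O6", "glucose (extracellular)")
    glc_c = met("glc__D_c", "C6H12O6", "glucose")
    f6p = met("f6p_c", "C6H11O9P", "fructose 6-phosphate")
    g3p = met("g3p_c", "C3H5O6P", "glyceraldehyde 3-phosphate")
    pyr = met("pyr_c", "C3H3O3", "pyruvate")
    ru5p = met("ru5p__D_c", "C5H9O8P", "ribulose 5-phosphate")
    nad = met("nad_c", "C21H26N7O14P2", "NAD+")
    nadh = met("nadh_c", "C21H27N7O14P2", "NADH")
    atp = met("atp_c", "C10H12N5O13P3", "ATP")
    adp = met("adp_c", "C10H12N5O10P2", "ADP")
    h = met("h_c", "H", "proton")
    o2 = met("o2_c", "O2", "oxygen")
    co2 = met("co2_c", "CO2", "carbon dioxide")

    def rxn(rid, name, stoich, lb=0.0, ub=1000.0):
        r = Reaction(rid, name=name, lower_bound=lb, upper_bound=ub)
        r.add_metabolites(stoich)
        return r

    reactions = [
        rxn("GLCt", "glucose uptake", {glc_e: -1, glc_c: 1}),
        rxn("HEX", "hexokinase + isomerase (lumped)",
            {glc_c: -1, atp: -1, f6p: 1, adp: 1}),
        rxn("FBA_L", "fructose bisphosphate aldolase (lumped upper glycolysis)",
            {f6p: -1, atp: -1, g3p: 2, adp: 1}),
        rxn("LGLY", "lower glycolysis (lumped GAPDH..PYK)",
            {g3p: -1, nad: -1, adp: -2, pyr: 1, nadh: 1, atp: 2, h: 1}),
        rxn("PPPR", "pentose rearrangement (lumped TKT/TAL/SBPase + RPE/RPI)",
            {f6p: -2, g3p: -1, ru5p: 3}, lb=-1000.0),
        rxn("PDHX", "pyruvate oxidation (lumped, for redox balance)",
            {pyr: -1, nad: -1, o2: -1, co2: 3, nadh: 1, h: 1}),
        rxn("OXPHOS", "oxidative phosphorylation (lumped)",
            {nadh: -1, h: -1, o2: -0.5, adp: -2, nad: 1, atp: 2}),
        rxn("ATPM", "ATP maintenance", {atp: -1, adp: 1}),
        rxn("BIOMASS", "biomass from pyruvate",
            {pyr: -1, atp: -3, nadh: -1, adp: 3, nad: 1, h: -1}),
    ]
    model.add_reactions(reactions)
    model.add_boundary(glc_e, type="exchange", lb=0.0, ub=1000.0)
    for gas in (o2, co2, h):
        model.add_boundary(gas, type="sink")  # freely exchanged small species
    model.objective = "BIOMASS"
    return model


def read_sbml(path) -> Model:
    return cobra.io.read_sbml_model(str(path))


def write_sbml(model: Model, path) -> None:
    cobra.io.write_sbml_model(model, str(path))


def match_growth_by_uptake(
    model: Model,
    exchange_id: str,
    target_growth: float,
    tol: float = 0.02,
    max_uptake: float = 1000.0,
    max_iter: int = 60,
) -> float:
    """Smallest uptake whose optimal growth is within ``tol`` of the target.

    Assumes growth is monotone non-decreasing in the uptake bound, so a
    bisection on the exchange lower bound suffices.  Raises when the
    target is unreachable even at ``max_uptake``.
    """
    if tol <= 0:
        raise ValueError("tol must be positive")
    exchange = model.reactions.get_by_id(exchange_id)

    def growth_at(uptake: float) -> float:
        with model:
            exchange.lower_bound = -uptake
            value = model.slim_optimize(error_value=float("nan"))
        return value if value == value else 0.0

    floor = target_growth * (1.0 - tol)
    hi_growth = growth_at(max_uptake)
    if hi_growth < floor:
        raise ValueError(
            f"target growth {target_growth:.4g} unreachable: maximum achievable "
            f"at uptake {max_uptake:.4g} is {hi_growth:.4g}"
        )
    lo, hi = 0.0, max_uptake
    for _ in range(max_iter):
        mid = 0.5 * (lo + hi)
        if growth_at(mid) >= floor:
            hi = mid
        else:
            lo = mid
        if hi - lo < 1e-9 * max(1.0, hi):
            break
    return hi


def proportional_flux(
    solution,
    reaction_id: str,
    exchange_id: str,
    substrate_carbons: int,
) -> float:
    """|flux| per carbon-mole of substrate uptake.

    Normalising by C-mol makes comparisons across substrates with
    different carbon counts commensurate (one six-carbon mole carries
    six times the carbon of a one-carbon mole).
    """
    uptake = -float(solution.fluxes[exchange_id])
    if uptake <= 0:
        raise ValueError(f"no uptake through {exchange_id} in this solution")
    if substrate_carbons <= 0:
        raise ValueError("substrate_carbons must be positive")
    return abs(float(solution.fluxes[reaction_id])) / (uptake * substrate_carbons)


def flux_range(model: Model, reaction_ids, fraction_of_optimum: float = 1.0):
    """Flux-variability min/max for the listed reactions (alternate-optima guard)."""
    from cobra.flux_analysis import flux_variability_analysis

    return flux_variability_analysis(
        model, reaction_list=list(reaction_ids),
        fraction_of_optimum=fraction_of_optimum,
    )
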