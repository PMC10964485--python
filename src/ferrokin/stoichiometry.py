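"""Reaction stoichiometry for reductive bioleaching.

The process chemistry is captured by four reactions:

* goethite acid dissolution      FeOOH + 3 H+ ↔ Fe3+ + 2 H2O
* microbial sulfur-coupled
  Fe(III) reduction              6 Fe3+ + S0 + 4 H2O → 6 Fe2+ + SO4²⁻ + 8 H+
* Mn-oxide reduction by Fe(II)   MnO2 + 2 Fe2+ + 4 H+ → Mn2+ + 2 Fe3+ + 2 H2O
* cell synthesis on ammonium     1/5 CO2 + 1/20 HCO3⁻ + 1/20 NH4+ + H+ + e⁻
                                   → 1/20 C5H7O2N + 9/20 H2O

Coefficients are exact rationals (`fractions.Fraction`) so element and
charge balance checks are exact, including the twentieths of the cell
synthesis reaction. Molar couplings (Fe3+ per S0, NH4+ per CO2, the 5:1
biomass C:N ratio) are derived from the reaction objects, not hard-coded.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from numbers import Rational
from typing import Mapping

from .constants import MOLAR_MASS

__all__ = [
    "Species",
    "Reaction",
    "SPECIES",
    "REACTIONS",
    "check_balance",
    "electrons_transferred",
    "fe3_per_s0",
    "fe2_per_mno2",
    "biomass_c_to_n",
    "ammonium_demand_from_co2",
]


@dataclass(frozen=True)
class Species:
    """A chemical species: element composition and formal charge."""

    name: str
    composition: Mapping[str, int]
    charge: int = 0

    def __post_init__(self) -> None:
        if any(n < 0 for n in self.composition.values()):
            raise ValueError("element counts must be nonnegative")


def _sp(name: str, charge: int = 0, **elements: int) -> Species:
    return Species(name, dict(elements), charge)


#: Species appearing in the process reactions. The electron is a charge
#: carrier with empty composition.
SPECIES: dict[str, Species] = {
    s.name: s
    for s in [
        _sp("FeOOH", Fe=1, O=2, H=1),
        _sp("Fe3+", charge=3, Fe=1),
        _sp("Fe2+", charge=2, Fe=1),
        _sp("S0", S=1),
        _sp("SO4 2-", charge=-2, S=1, O=4),
        _sp("MnO2", Mn=1, O=2),
        _sp("Mn2+", charge=2, Mn=1),
        _sp("H+", charge=1, H=1),
        _sp("H2O", H=2, O=1),
        _sp("O2", O=2),
        _sp("CO2", C=1, O=2),
        _sp("HCO3-", charge=-1, H=1, C=1, O=3),
        _sp("NH4+", charge=1, N=1, H=4),
        _sp("C5H7O2N", C=5, H=7, O=2, N=1),
        _sp("e-", charge=-1),
    ]
}


@dataclass(frozen=True)
class Reaction:
    """A reaction with exact rational coefficients, reactants → products."""

    name: str
    reactants: Mapping[str, Fraction]
    products: Mapping[str, Fraction]

    def __post_init__(self) -> None:
        for side in (self.reactants, self.products):
            for sp, coeff in side.items():
                if sp not in SPECIES:
                    raise KeyError(f"unknown species {sp!r}")
                if not isinstance(coeff, Rational):
                    raise TypeError("coefficients must be exact rationals")
                if coeff <= 0:
                    raise ValueError("stoichiometric coefficients must be positive")

    def net(self) -> dict[str, Fraction]:
        """Signed coefficients, products positive."""
        out: dict[str, Fraction] = {}
        for sp, c in self.products.items():
            out[sp] = out.get(sp, Fraction(0)) + Fraction(c)
        for sp, c in self.reactants.items():
            out[sp] = out.get(sp, Fraction(0)) - Fraction(c)
        return out


def _rxn(name: str, reactants: dict, products: dict) -> Reaction:
    conv = lambda d: {k: Fraction(v) for k, v in d.items()}
    return Reaction(name, conv(reactants), conv(products))


#: The process reactions by name. `sulfur_oxidation_aerobic` is the growth
#: reactor's aerobic sulfur oxidation, included for simulator bookkeeping
#: (it is not one of the four leaching reactions above).
REACTIONS: dict[str, Reaction] = {
    r.name: r
    for r in [
        _rxn("goethite_dissolution", {"FeOOH": 1, "H+": 3}, {"Fe3+": 1, "H2O": 2}),
        _rxn(
            "iron_bioreduction",
            {"Fe3+": 6, "S0": 1, "H2O": 4},
            {"Fe2+": 6, "SO4 2-": 1, "H+": 8},
        ),
        _rxn(
            "mn_oxide_reduction",
            {"MnO2": 1, "Fe2+": 2, "H+": 4},
            {"Mn2+": 1, "Fe3+": 2, "H2O": 2},
        ),
        _rxn(
            "cell_synthesis",
            {
                "CO2": Fraction(1, 5),
                "HCO3-": Fraction(1, 20),
                "NH4+": Fraction(1, 20),
                "H+": 1,
                "e-": 1,
            },
            {"C5H7O2N": Fraction(1, 20), "H2O": Fraction(9, 20)},
        ),
        _rxn(
            "sulfur_oxidation_aerobic",
            {"S0": 1, "O2": Fraction(3, 2), "H2O": 1},
            {"SO4 2-": 1, "H+": 2},
        ),
    ]
}


def check_balance(reaction: Reaction) -> dict[str, Fraction]:
    """Element and charge residuals (products − reactants); all zero iff balanced.

    Electrons count with charge −1 and empty composition. Residual keys are
    element symbols plus ``"charge"``.
    """
    residuals: dict[str, Fraction] = {"charge": Fraction(0)}
    for sp_name, coeff in reaction.net().items():
        sp = SPECIES[sp_name]
        residuals["charge"] += coeff * sp.charge
        for elem, count in sp.composition.items():
            residuals[elem] = residuals.get(elem, Fraction(0)) + coeff * count
    return residuals


def _oxidation_state(species: Species, element: str) -> Fraction:
    """Formal oxidation state of `element`, by the usual O = −II, H = +I rules."""
    fixed = {"O": -2, "H": 1}
    if element in fixed:
        raise ValueError("oxidation-state bookkeeping targets the redox-active element")
    count = species.composition.get(element, 0)
    if count == 0:
        raise ValueError(f"{species.name} contains no {element}")
    others = sum(
        Fraction(fixed[e]) * n for e, n in species.composition.items() if e in fixed
    )
    other_actives = [e for e in species.composition if e not in fixed and e != element]
    if other_actives:
        raise ValueError(f"ambiguous oxidation state: {species.name} also contains {other_actives}")
    return (Fraction(species.charge) - others) / count


def electrons_transferred(reactant: str, product: str, element: str) -> Fraction:
    """Electrons released per atom of `element` going reactant → product.

    Positive for an oxidation (e.g. S0 → SO4²⁻ releases 6), negative for a
    reduction (Fe3+ → Fe2+ releases −1).
    """
    return _oxidation_state(SPECIES[product], element) - _oxidation_state(
        SPECIES[reactant], element
    )


def fe3_per_s0() -> int:
    """Moles of Fe3+ reduced per mole of S0 fully oxidized to sulfate.

    Derived by electron balance: S(0) → S(+VI) releases six electrons, each
    reducing one Fe3+ to Fe2+. Returns 6.
    """
    released = electrons_transferred("S0", "SO4 2-", "S")
    consumed = -electrons_transferred("Fe3+", "Fe2+", "Fe")
    ratio = released / consumed
    assert ratio.denominator == 1
    return int(ratio)


def fe2_per_mno2() -> int:
    """Moles of Fe2+ oxidized per mole of MnO2 reduced to Mn2+ (acid demand 4 H+).

    Mn(+IV) → Mn(+II) consumes two electrons, each from one Fe2+. Returns 2.
    """
    consumed = -electrons_transferred("MnO2", "Mn2+", "Mn")
    released = electrons_transferred("Fe2+", "Fe3+", "Fe")
    ratio = consumed / released
    assert ratio.denominator == 1
    return int(ratio)


def biomass_c_to_n() -> Fraction:
    """C:N molar ratio of cell synthesis, from the reaction coefficients.

    (CO2 + HCO3⁻ carbon) : (NH4+ nitrogen) = (1/5 + 1/20) : 1/20 = 5.
    """
    r = REACTIONS["cell_synthesis"]
    carbon = sum(
        c * SPECIES[sp].composition.get("C", 0) for sp, c in r.reactants.items()
    )
    nitrogen = sum(
        c * SPECIES[sp].composition.get("N", 0) for sp, c in r.reactants.items()
    )
    return Fraction(carbon) / Fraction(nitrogen)


def ammonium_demand_from_co2(co2_uptake: float, volume: float) -> float:
    """Stoichiometric NH4+ demand (mmol·h⁻¹) from a CO2 uptake rate.

    Parameters
    ----------
    co2_uptake : float
        Volumetric CO2 fixation rate, mg·L⁻¹·h⁻¹ (≈40 for acidophilic
        bioleaching cultures).
    volume : float
        Reactor liquid volume, L.

    The molar CO2 flux is co2_uptake·volume / M(CO2); the NH4+ demand is
    that flux times the NH4+:CO2 coefficient ratio of the cell-synthesis
    reaction (1/4, equivalently 1/C:N-ratio·(C-fraction from CO2) — the
    nitrogen demand per total carbon fixed follows the 5:1 C:N ratio).
    """
    if co2_uptake < 0 or volume < 0:
        raise ValueError("co2_uptake and volume must be nonnegative")
    r = REACTIONS["cell_synthesis"]
    nh4_per_co2 = r.reactants["NH4+"] / r.reactants["CO2"]
    co2_flux_mmol_h = co2_uptake * volume / MOLAR_MASS["CO2"]
    return float(co2_flux_mmol_h * nh4_per_co2)
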