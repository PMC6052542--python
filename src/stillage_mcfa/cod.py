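"""Chemical-oxygen-demand bookkeeping.

COD (chemical oxygen demand) is the mass of O2 required to fully oxidize a
compound, and is used throughout this package as a conserved reducing-
equivalent currency: every concentration and mass flow can be expressed in
COD units, which makes fermentation conversions, digestion and combustion
commensurable on one scale.

This module houses the per-compound constants (elemental formulas,
theoretical oxygen demands, chain-length classes, aqueous solubilities) and
the unit conversions between mass and COD. Lumped analytical pools that have
no single formula — total protein (BCA assay), total carbohydrate (anthrone
assay), and the unidentified remainder of measured COD — carry fixed
literature factors instead of stoichiometric ones.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from importlib import resources
from typing import Optional

import pandas as pd

__all__ = [
    "ATOMIC_MASS",
    "ChemicalFormula",
    "CompoundSpec",
    "ConcentrationMeasurement",
    "ChainClass",
    "ChainParity",
    "CompoundRegistry",
    "REGISTRY",
    "theoretical_oxygen_demand",
    "mass_to_cod",
    "cod_to_mass",
    "classify_compound",
]

#: Standard atomic masses (g/mol) used for all stoichiometry.
ATOMIC_MASS = {"C": 12.011, "H": 1.008, "O": 15.999, "N": 14.007}


class InvalidCompoundError(ValueError):
    """Raised for formulas that cannot be oxidized (ThOD expression <= 0)."""


class UnknownCompoundError(KeyError):
    """Raised when a compound name is not in the registry."""


@dataclass(frozen=True)
class ChemicalFormula:
    """Elemental composition C/H/O/N of an organic compound."""

    carbon: int
    hydrogen: int
    oxygen: int = 0
    nitrogen: int = 0

    def __post_init__(self) -> None:
        for name in ("carbon", "hydrogen", "oxygen", "nitrogen"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} count must be >= 0")
        if self.carbon < 1:
            raise ValueError("organic compounds require carbon >= 1")

    @property
    def molecular_weight(self) -> float:
        """Molecular weight in g/mol."""
        return (
            self.carbon * ATOMIC_MASS["C"]
            + self.hydrogen * ATOMIC_MASS["H"]
            + self.oxygen * ATOMIC_MASS["O"]
            + self.nitrogen * ATOMIC_MASS["N"]
        )


def theoretical_oxygen_demand(formula: ChemicalFormula) -> float:
    """Theoretical oxygen demand (ThOD) in g COD per g compound.

    Oxidation is taken to CO2 and H2O with organic nitrogen released as NH3
    (the standard COD convention — N is *not* oxidized to nitrate):

        CcHhOoNn + (c + h/4 - o/2 - 3n/4) O2 -> c CO2 + (h-3n)/2 H2O + n NH3

    so ThOD = 32 * (c + h/4 - o/2 - 3n/4) / MW.

    Raises
    ------
    InvalidCompoundError
        If the stoichiometric O2 coefficient is not positive (the compound
        is already fully oxidized, e.g. CO2 itself).
    """
    o2_mol = (
        formula.carbon
        + formula.hydrogen / 4.0
        - formula.oxygen / 2.0
        - 0.75 * formula.nitrogen
    )
    if o2_mol <= 0:
        raise InvalidCompoundError(
            f"formula {formula} is not oxidizable (O2 coefficient {o2_mol:g} <= 0)"
        )
    return 32.0 * o2_mol / formula.molecular_weight


class ChainClass(enum.Enum):
    """Carboxylic-acid chain-length class.

    SCFA: linear monocarboxylic acids of 2-5 carbons (acetic through
    pentanoic). MCFA: 6-8 carbons (hexanoic through octanoic), the product
    class of interest — lower aqueous solubility makes them extractable.
    Everything else (sugars, alcohols, lumped pools, C1 formate) is OTHER.
    """

    SCFA = "SCFA"
    MCFA = "MCFA"
    OTHER = "other"


class ChainParity(enum.Enum):
    ODD = "odd_chain"
    EVEN = "even_chain"
    NA = "n/a"


@dataclass(frozen=True)
class CompoundSpec:
    """Chemical identity plus the constants the analysis needs.

    ``thod`` is g COD per g compound. For compounds with a formula it equals
    :func:`theoretical_oxygen_demand`; lumped pools (protein 1.5, anthrone
    carbohydrate 1.06, unknown COD 1.0) carry fixed factors and are flagged
    ``lumped_factor_source="literature"``.
    """

    name: str
    thod: float
    carbon_count: int = 0
    formula: Optional[ChemicalFormula] = None
    is_monocarboxylic_acid: bool = False
    solubility_g_per_L: Optional[float] = None
    lumped_factor_source: str = "formula"

    def __post_init__(self) -> None:
        if self.thod <= 0:
            raise ValueError(f"{self.name}: thod must be > 0")
        if self.formula is not None and self.lumped_factor_source == "formula":
            ref = theoretical_oxygen_demand(self.formula)
            if abs(self.thod - ref) > 1e-6 * max(1.0, abs(ref)):
                raise ValueError(
                    f"{self.name}: thod {self.thod} inconsistent with formula "
                    f"ThOD {ref:.6f}"
                )

    @property
    def chain_class(self) -> ChainClass:
        return classify_compound(self)[0]


@dataclass(frozen=True)
class ConcentrationMeasurement:
    """One timestamped concentration in canonical units (mg COD/L)."""

    compound: str
    value: float
    time: float = 0.0
    sd: float = 0.0

    def __post_init__(self) -> None:
        if self.value < 0:
            raise ValueError("concentration must be >= 0")
        if self.sd < 0:
            raise ValueError("sd must be >= 0")
        if self.time < 0:
            raise ValueError("time must be >= 0")


def classify_compound(compound: CompoundSpec) -> tuple[ChainClass, ChainParity]:
    """Chain-length class and carbon parity of a compound.

    Linear monocarboxylic acids with 2-5 carbons are SCFA and with 6-8
    carbons are MCFA; parity (odd/even carbon number, which tracks the
    chain-elongation route) is reported for monocarboxylic acids only.
    Total function: anything else maps to (OTHER, NA).
    """
    if compound.is_monocarboxylic_acid:
        n = compound.carbon_count
        parity = ChainParity.ODD if n % 2 else ChainParity.EVEN
        if 2 <= n <= 5:
            return ChainClass.SCFA, parity
        if 6 <= n <= 8:
            return ChainClass.MCFA, parity
        return ChainClass.OTHER, parity
    return ChainClass.OTHER, ChainParity.NA


class CompoundRegistry:
    """Name -> CompoundSpec lookup backed by the packaged compounds.csv."""

    def __init__(self, compounds: Optional[dict[str, CompoundSpec]] = None):
        self._compounds: dict[str, CompoundSpec] = dict(compounds or {})

    @classmethod
    def from_csv(cls, path=None) -> "CompoundRegistry":
        if path is None:
            path = resources.files("stillage_mcfa.data") / "compounds.csv"
        df = pd.read_csv(path)
        reg = cls()
        for row in df.itertuples(index=False):
            formula = None
            if pd.notna(row.C):
                formula = ChemicalFormula(
                    int(row.C), int(row.H), int(row.O), int(row.N)
                )
            sol = float(row.solubility_g_per_L) if pd.notna(row.solubility_g_per_L) else None
            reg.register(
                CompoundSpec(
                    name=row.name,
                    thod=float(row.thod),
                    carbon_count=int(row.carbon_count),
                    formula=formula,
                    is_monocarboxylic_acid=bool(row.acid_flag),
                    solubility_g_per_L=sol,
                    lumped_factor_source=str(row.source),
                )
            )
        return reg

    def register(self, compound: CompoundSpec) -> None:
        self._compounds[compound.name] = compound

    def __contains__(self, name: str) -> bool:
        return name in self._compounds

    def __iter__(self):
        return iter(self._compounds.values())

    def names(self) -> list[str]:
        return sorted(self._compounds)

    def get(self, name: str) -> CompoundSpec:
        try:
            return self._compounds[name]
        except KeyError:
            raise UnknownCompoundError(
                f"unknown compound {name!r}; registered: {', '.join(self.names())}"
            ) from None


#: Default shared registry (the compounds quantified in the stillage assays).
REGISTRY = CompoundRegistry.from_csv()


def _resolve(compound: CompoundSpec | str, registry: Optional[CompoundRegistry]) -> CompoundSpec:
    if isinstance(compound, CompoundSpec):
        return compound
    return (registry or REGISTRY).get(compound)


def mass_to_cod(
    concentration: float,
    compound: CompoundSpec | str,
    registry: Optional[CompoundRegistry] = None,
) -> float:
    """Convert mg compound/L (or kg/h) to the same quantity on a COD basis."""
    if concentration < 0:
        raise ValueError("concentration must be >= 0")
    return concentration * _resolve(compound, registry).thod


def cod_to_mass(
    concentration_cod: float,
    compound: CompoundSpec | str,
    registry: Optional[CompoundRegistry] = None,
) -> float:
    """Inverse of :func:`mass_to_cod`: mg COD/L (or kg COD/h) to mass units."""
    if concentration_cod < 0:
        raise ValueError("concentration must be >= 0")
    return concentration_cod / _resolve(compound, registry).thod
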