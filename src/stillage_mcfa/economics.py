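"""Capital scaling, operating costs and co-product revenues.

Equipment costs follow the standard power-law scaling convention
(``cost = base * (size/base_size)^n`` with n typically 0.6, the
"six-tenths rule") with multiplicative installation factors; chemical
prices are quoted per short ton (907.185 kg — the only reading under which
the packaged 2-octanol price and make-up rate reproduce the reference
annual cost); all results are expressed in 2007 USD, converting across
cost years with a GDP-deflator style index.
"""

from __future__ import annotations

from dataclasses import dataclass

from .scenario import (
    KG_PER_SHORT_TON,
    CapexItem,
    FinancialConfig,
    OpexItem,
    RevenueItem,
    ScenarioConfig,
)

__all__ = [
    "deflate",
    "scale_equipment_cost",
    "total_capital_investment",
    "annual_opex_and_revenue",
    "CostSummary",
    "build_cost_summary",
]

REPORT_YEAR = 2007


class MissingIndexYearError(KeyError):
    """Raised when the cost index lacks an entry for a requested year."""


def deflate(amount: float, from_year: int, to_year: int, index: dict[int, float]) -> float:
    """Convert ``amount`` between cost years with a price index.

    Deflation then inflation through the same index pair is the identity.
    """
    if from_year == to_year:
        return amount
    try:
        return amount * index[to_year] / index[from_year]
    except KeyError as exc:
        raise MissingIndexYearError(
            f"cost index has no entry for year {exc.args[0]}; known years: {sorted(index)}"
        ) from None


def scale_equipment_cost(
    item: CapexItem,
    cost_index: dict[int, float] | None = None,
    to_year: int = REPORT_YEAR,
) -> float:
    """Installed cost (USD, ``to_year`` dollars) of one equipment line.

    installed = count * base_purchased * (actual/base)^exponent * factor.
    """
    scaled = (
        item.count
        * item.base_purchased_cost
        * (item.actual_size / item.base_size) ** item.scaling_exponent
        * item.installation_factor
    )
    if item.cost_year == to_year:
        return scaled
    if cost_index is None:
        raise MissingIndexYearError(
            f"{item.description}: cost year {item.cost_year} needs a cost index"
        )
    return deflate(scaled, item.cost_year, to_year, cost_index)


def total_capital_investment(
    baseline_tci: float,
    installed_additions: list[float],
    indirect_multiplier: float,
) -> float:
    """TCI = baseline + indirect multiplier x sum of installed additions.

    The multiplier carries the indirect cost structure (engineering,
    contingency, ...) applied to the added direct capital.
    """
    if indirect_multiplier < 1:
        raise ValueError("indirect multiplier must be >= 1")
    return baseline_tci + indirect_multiplier * sum(installed_additions)


def _annual_opex(item: OpexItem, hours: float) -> float:
    if item.basis == "per_short_ton":
        return item.usage_rate * hours / KG_PER_SHORT_TON * item.unit_price
    if item.basis == "per_kwh":
        return item.usage_rate * hours * item.unit_price
    raise ValueError(f"{item.description}: unknown opex basis {item.basis!r}")


def _annual_revenue(item: RevenueItem, hours: float) -> float:
    if item.basis == "per_kg":
        return item.rate * hours * item.unit_price
    if item.basis == "per_kwh":
        return item.rate * hours * item.unit_price
    raise ValueError(f"{item.description}: unknown revenue basis {item.basis!r}")


def annual_opex_and_revenue(
    opex: list[OpexItem],
    revenue: list[RevenueItem],
    operating_hours: float,
) -> dict:
    """Itemized and total annual operating expense and co-product revenue."""
    if not 0 < operating_hours <= 8760:
        raise ValueError("operating hours must be in (0, 8760]")
    opex_items = {it.description: _annual_opex(it, operating_hours) for it in opex}
    revenue_items = {it.description: _annual_revenue(it, operating_hours) for it in revenue}
    return {
        "annual_opex_usd_yr": sum(opex_items.values()),
        "annual_revenue_usd_yr": sum(revenue_items.values()),
        "opex_itemized": opex_items,
        "revenue_itemized": revenue_items,
    }


@dataclass
class CostSummary:
    """Itemized cost model of one scenario (2007 USD)."""

    capex_itemized: dict[str, float]
    capex_direct_total: float
    tci: float
    baseline_tci: float
    opex_itemized: dict[str, float]
    annual_opex: float
    revenue_itemized: dict[str, float]
    annual_revenue: float

    @property
    def delta_tci(self) -> float:
        return self.tci - self.baseline_tci

    def to_dict(self) -> dict:
        return {
            "capex_installed_usd": self.capex_itemized,
            "capex_direct_total_usd": self.capex_direct_total,
            "total_capital_investment_usd": self.tci,
            "baseline_tci_usd": self.baseline_tci,
            "opex_usd_yr": self.opex_itemized,
            "annual_opex_usd_yr": self.annual_opex,
            "revenue_usd_yr": self.revenue_itemized,
            "annual_revenue_usd_yr": self.annual_revenue,
        }


def build_cost_summary(
    config: ScenarioConfig,
    revenue_overrides: dict[str, float] | None = None,
) -> CostSummary:
    """Assemble the full cost model for one scenario.

    ``revenue_overrides`` replaces revenue item *rates* by description
    (used by the balance-driven revenue mode).
    """
    fin: FinancialConfig = config.financial
    capex_items = {
        it.description: scale_equipment_cost(it, fin.cost_index) for it in config.capex
    }
    direct = sum(capex_items.values())
    tci = total_capital_investment(
        fin.baseline_tci_usd, list(capex_items.values()), fin.indirect_cost_multiplier
    )
    revenue = config.revenue
    if revenue_overrides:
        revenue = [
            it.model_copy(update={"rate": revenue_overrides.get(it.description, it.rate)})
            for it in revenue
        ]
    flows = annual_opex_and_revenue(config.opex, revenue, fin.operating_hours_per_yr)
    return CostSummary(
        capex_itemized=capex_items,
        capex_direct_total=direct,
        tci=tci,
        baseline_tci=fin.baseline_tci_usd,
        opex_itemized=flows["opex_itemized"],
        annual_opex=flows["annual_opex_usd_yr"],
        revenue_itemized=flows["revenue_itemized"],
        annual_revenue=flows["annual_revenue_usd_yr"],
    )
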