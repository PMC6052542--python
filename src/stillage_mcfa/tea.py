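"""Technoeconomic model of MCFA co-production (model/results interface).

`BiorefineryTEA` composes the three computation stages — COD mass/energy
balance, itemized cost model, calibrated discounted cash flow — for one
:class:`~stillage_mcfa.scenario.ScenarioConfig`. ``fit()`` returns a
`TEAResults` carrying the balance, the cost table, the solved baseline and
co-production MESPs, and the full cash-flow table, with a ``summary()``
table in the style of a TEA report.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import pandas as pd

from .biorefinery import BalanceResult, run_balance
from .cashflow import DCFEngine, MESPResult, incremental_mesp
from .economics import CostSummary, build_cost_summary
from .scenario import ScenarioConfig

__all__ = ["BiorefineryTEA", "TEAResults"]


class BiorefineryTEA:
    """Technoeconomic model of one ethanol + electricity + MCFA scenario.

    Parameters
    ----------
    scenario : ScenarioConfig
        Complete scenario (defaults to the packaged reference operating
        point when constructed with ``BiorefineryTEA()``).
    engine : DCFEngine, optional
        A pre-calibrated cash-flow engine to reuse across fits.
    """

    def __init__(self, scenario: Optional[ScenarioConfig] = None, engine: Optional[DCFEngine] = None):
        self.scenario = scenario or ScenarioConfig()
        self.engine = engine or DCFEngine(self.scenario.financial)

    @classmethod
    def from_yaml(cls, path) -> "BiorefineryTEA":
        return cls(ScenarioConfig.from_yaml(path))

    def fit(self, mode: str = "full_dcf") -> "TEAResults":
        """Run balance -> costs -> MESP. ``mode``: full_dcf | incremental."""
        if mode not in ("full_dcf", "incremental"):
            raise ValueError(f"unknown mode {mode!r}")
        cfg = self.scenario
        balance = run_balance(cfg)
        overrides = None
        if cfg.revenue_from_balance:
            overrides = {
                "HA": balance.separation.recovered_kg_h.get("hexanoic acid", 0.0),
                "OA": balance.separation.recovered_kg_h.get("octanoic acid", 0.0),
                "Electricity": max(balance.energy.net_export_kw, 0.0),
            }
        costs = build_cost_summary(cfg, revenue_overrides=overrides)

        fin = cfg.financial
        baseline = self.engine.baseline_mesp()
        if mode == "full_dcf":
            coproduction = self.engine.solve_mesp(
                tci=costs.tci,
                coproduct_revenue=costs.annual_revenue,
                added_opex=costs.annual_opex,
            )
        else:
            coproduction = incremental_mesp(
                baseline.mesp,
                delta_revenue=costs.annual_revenue - fin.baseline_coproduct_revenue_usd_yr,
                delta_opex=costs.annual_opex,
                delta_tci=costs.delta_tci,
                fin=fin,
            )
        table = self.engine.table(
            coproduction.mesp, tci=costs.tci,
            coproduct_revenue=costs.annual_revenue, added_opex=costs.annual_opex,
        )
        return TEAResults(self, balance, costs, baseline, coproduction, table)


@dataclass
class TEAResults:
    """Fitted technoeconomic results for one scenario."""

    model: BiorefineryTEA
    balance: BalanceResult
    costs: CostSummary
    baseline: MESPResult
    coproduction: MESPResult
    cashflow_table: pd.DataFrame

    @property
    def mesp_reduction_pct(self) -> float:
        return 100.0 * (self.baseline.mesp - self.coproduction.mesp) / self.baseline.mesp

    def to_dict(self) -> dict:
        return {
            "balance": self.balance.to_dict(),
            "economics": self.costs.to_dict(),
            "mesp": {
                "baseline": self.baseline.to_dict(),
                "coproduction": self.coproduction.to_dict(),
                "reduction_pct": self.mesp_reduction_pct,
            },
        }

    def summary(self) -> str:
        b, c = self.balance, self.costs
        rows = [
            "Technoeconomic summary: ethanol-electricity-MCFA co-production",
            "",
            "Mass/energy balance",
            f"  stillage COD to fermentation   {b.stillage.cod_flow:>12,.0f} kg COD/h",
            f"  recovered hexanoic acid        {b.separation.recovered_kg_h.get('hexanoic acid', 0):>12,.0f} kg/h",
            f"  recovered octanoic acid        {b.separation.recovered_kg_h.get('octanoic acid', 0):>12,.0f} kg/h",
            f"  COD to anaerobic digestion     {b.energy.ad_feed_kg_cod_h:>12,.0f} kg COD/h",
            f"  biogas                         {b.energy.biogas_kg_h:>12,.0f} kg/h",
            f"  power generation               {b.energy.generation_mw:>12.1f} MW",
            f"  net electricity (computed)     {b.energy.net_export_mw:>12.2f} MW",
            f"  reactors                       {b.reactor_count} x {b.reactor_unit_volume_mg:g} MG"
            f" = {b.total_reactor_volume_mg:g} MG",
            "",
            "Capital (installed, 2007 USD)",
        ]
        for name, cost in c.capex_itemized.items():
            rows.append(f"  {name:<42s}${cost:>12,.0f}")
        rows += [
            f"  {'direct additions total':<42s}${c.capex_direct_total:>12,.0f}",
            f"  {'total capital investment':<42s}${c.tci:>12,.0f}  (baseline ${c.baseline_tci:,.0f})",
            "",
            "Annual operating expense / co-product revenue",
        ]
        for name, cost in c.opex_itemized.items():
            rows.append(f"  {name:<42s}${cost:>12,.0f}/yr")
        for name, rev in c.revenue_itemized.items():
            rows.append(f"  {name + ' revenue':<42s}${rev:>12,.0f}/yr")
        rows += [
            f"  {'total co-product revenue':<42s}${c.annual_revenue:>12,.0f}/yr",
            "",
            f"MESP  baseline      ${self.baseline.mesp:.2f}/gal  (${self.baseline.mesp_gge:.2f}/gal gasoline-eq)",
            f"MESP  co-production ${self.coproduction.mesp:.2f}/gal  (${self.coproduction.mesp_gge:.2f}/gal gasoline-eq)"
            f"  [{self.coproduction.mode}]",
            f"MESP  reduction     {self.mesp_reduction_pct:.0f}%",
        ]
        return "\n".join(rows)
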