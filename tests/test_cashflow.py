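"""Discounted cash flow, MESP solver, incremental mode and GGE conversion."""

import numpy as np
import pandas as pd
import pytest

from stillage_mcfa.cashflow import (
    BracketError,
    DCFEngine,
    build_cashflow_table,
    capital_recovery_factor,
    gasoline_gallon_equivalent,
    incremental_mesp,
    npv,
)
from stillage_mcfa.scenario import FinancialConfig


def flows_table(pairs):
    return pd.DataFrame(
        {"year": [t for t, _ in pairs], "net_cash_flow": [v for _, v in pairs]}
    )


class TestNPV:
    def test_zero_rate_is_plain_sum(self):
        table = flows_table([(0, -100.0), (1, 60.0), (2, 60.0)])
        assert npv(table, 0.0) == pytest.approx(20.0)

    def test_single_period_discount(self):
        table = flows_table([(1, 1.10e6)])
        assert npv(table, 0.10) == pytest.approx(1.00e6)

    def test_capital_recovery_factor_annuity_repays_principal(self):
        crf = capital_recovery_factor(0.10, 30)
        assert crf == pytest.approx(0.10608, abs=5e-6)
        table = flows_table([(0, -1.0e6)] + [(t, crf * 1.0e6) for t in range(1, 31)])
        assert npv(table, 0.10) == pytest.approx(0.0, abs=1.0)


class TestCashFlowTable:
    def test_depreciation_never_exceeds_depreciable_capital(self, fin):
        table = build_cashflow_table(2.0, 400e6, 6.6e6, 90e6, fin)
        fixed = 400e6 / (1 + fin.working_capital_fraction)
        assert table["depreciation"].sum() == pytest.approx(fixed, rel=1e-9)
        assert (table["depreciation"] >= 0).all()

    def test_construction_spend_matches_profile(self, fin):
        table = build_cashflow_table(2.0, 400e6, 6.6e6, 90e6, fin)
        fixed = 400e6 / (1 + fin.working_capital_fraction)
        spends = table["capital_outlay"].to_numpy()[:3]
        expected = np.array(fin.construction_spend_profile) * fixed
        expected[-1] += 400e6 - fixed  # working capital with final payment
        assert spends == pytest.approx(expected)

    def test_loan_fully_amortized(self, fin):
        table = build_cashflow_table(2.0, 400e6, 6.6e6, 90e6, fin)
        principal0 = (1 - fin.equity_fraction) * 400e6
        assert table["loan_principal"].sum() == pytest.approx(principal0, rel=1e-9)


class TestMESPSolver:
    def test_baseline_calibration_gate(self, engine, fin):
        """The calibrated engine must return the packaged baseline MESP."""
        result = engine.baseline_mesp()
        assert result.mesp == pytest.approx(fin.baseline_mesp_usd_gal, abs=0.01)
        assert abs(result.npv_at_solution) < 1000.0

    def test_coproduction_scenario(self, engine):
        result = engine.solve_mesp(
            tci=441.2e6, coproduct_revenue=56.75e6, added_opex=23.66e6
        )
        assert result.mesp == pytest.approx(1.76, abs=0.02)
        assert abs(result.npv_at_solution) < 1000.0

    def test_doubling_coproduct_revenue_lowers_mesp(self, engine):
        lo = engine.solve_mesp(coproduct_revenue=6.6e6)
        hi = engine.solve_mesp(coproduct_revenue=13.2e6)
        assert hi.mesp < lo.mesp

    def test_mesp_partial_derivative_signs(self, engine, fin):
        """dMESP/dTCI > 0, dMESP/dRevenue < 0, dMESP/dOpex > 0."""
        base = engine.solve_mesp().mesp
        assert engine.solve_mesp(tci=fin.baseline_tci_usd + 10e6).mesp > base
        assert engine.solve_mesp(coproduct_revenue=fin.baseline_coproduct_revenue_usd_yr + 10e6).mesp < base
        assert engine.solve_mesp(added_opex=10e6).mesp > base

    def test_no_root_in_bracket_reports_endpoints(self, fin):
        engine = DCFEngine(fin, baseline_opex=1e12)  # absurd opex: no root below $10/gal
        with pytest.raises(BracketError, match="NPV"):
            engine.solve_mesp()


class TestIncrementalMode:
    def test_zero_deltas_identity(self, fin):
        res = incremental_mesp(2.15, 0.0, 0.0, 0.0, fin)
        assert res.mesp == pytest.approx(2.15)
        assert res.mode == "incremental"

    def test_opex_equal_revenue_cancels(self, fin):
        res = incremental_mesp(2.15, 30e6, 30e6, 0.0, fin)
        assert res.mesp == pytest.approx(2.15)

    def test_reference_deltas_hand_arithmetic(self, fin):
        res = incremental_mesp(2.15, 50.2e6, 23.66e6, 18.3e6, fin)
        expected = 2.15 - (50.2e6 - 23.66e6 - capital_recovery_factor(0.10, 30) * 18.3e6) / 61e6
        assert res.mesp == pytest.approx(expected, rel=1e-12)
        assert res.mesp == pytest.approx(1.747, abs=0.002)

    @pytest.mark.parametrize("delta_rev", [-60e6, -20e6, 20e6, 60e6])
    def test_agrees_with_full_dcf_within_three_cents(self, engine, fin, delta_rev):
        full = engine.solve_mesp(
            coproduct_revenue=fin.baseline_coproduct_revenue_usd_yr + delta_rev
        )
        inc = incremental_mesp(fin.baseline_mesp_usd_gal, delta_rev, 0.0, 0.0, fin)
        assert abs(full.mesp - inc.mesp) <= 0.03


class TestGasolineEquivalent:
    def test_reference_pairs_to_the_cent(self, fin):
        assert round(gasoline_gallon_equivalent(2.15, fin), 2) == 3.27
        assert round(gasoline_gallon_equivalent(1.76, fin), 2) == 2.68

    def test_ratio_one_is_identity(self, fin):
        unity = fin.model_copy(update={"gasoline_lhv_ratio": 1.0 - 1e-12})
        assert gasoline_gallon_equivalent(2.0, unity) == pytest.approx(2.0)
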