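"""COD mass and energy balance of the modified biorefinery."""

import numpy as np
import pytest

from stillage_mcfa.biorefinery import (
    CODStream,
    apply_fermentation_conversions,
    energy_balance,
    run_balance,
    separation_train,
    size_fermentation_reactors,
)
from stillage_mcfa.scenario import (
    THOD_2_OCTANOL,
    ConversionSpec,
    EnergySpec,
    ScenarioConfig,
    SeparationSpec,
)


def total_split_cod(split):
    return (
        sum(s.cod_flow for s in split.products.values())
        + split.offgas.cod_flow
        + split.residual.cod_flow
    )


class TestFermentationConversions:
    def test_hand_arithmetic_at_25000_kg_cod_h(self):
        split = apply_fermentation_conversions(CODStream("s", 25000.0), ConversionSpec())
        ha = split.products["hexanoic acid"]
        oa = split.products["octanoic acid"]
        assert ha.cod_flow == pytest.approx(4000.0)
        assert ha.mass_flows["hexanoic acid"] == pytest.approx(1815.0, abs=0.5)
        assert oa.cod_flow == pytest.approx(425.0)
        assert oa.mass_flows["octanoic acid"] == pytest.approx(174.1, abs=0.1)
        assert split.offgas.cod_flow == pytest.approx(2275.0)
        assert split.residual.cod_flow == pytest.approx(13200.0)
        assert total_split_cod(split) == pytest.approx(25000.0, rel=1e-12)

    def test_zero_flow_gives_all_zero(self):
        split = apply_fermentation_conversions(CODStream("s", 0.0), ConversionSpec())
        assert total_split_cod(split) == 0.0

    def test_zero_fractions_pass_input_through(self):
        spec = ConversionSpec(acetic=0, butyric=0, hexanoic=0, octanoic=0, offgas=0)
        split = apply_fermentation_conversions(CODStream("s", 1234.5), spec)
        assert split.residual.cod_flow == pytest.approx(1234.5)

    def test_fractions_summing_above_one_rejected(self):
        with pytest.raises(ValueError, match="> 1"):
            ConversionSpec(acetic=0.5, butyric=0.5, hexanoic=0.2, octanoic=0.0, offgas=0.0)


class TestReactorSizing:
    def test_reference_point_16_mg_in_four_units(self):
        count, volume = size_fermentation_reactors(16.0 / 6.0, 6.0, 4.0)
        assert volume == pytest.approx(16.0)
        assert count == 4

    def test_ceiling_on_partial_units(self):
        count, volume = size_fermentation_reactors(1.0, 6.0, 4.0)
        assert volume == pytest.approx(6.0)
        assert count == 2

    def test_volume_linear_in_flow_and_srt(self):
        _, v1 = size_fermentation_reactors(2.0, 6.0, 4.0)
        _, v2 = size_fermentation_reactors(4.0, 6.0, 4.0)
        _, v3 = size_fermentation_reactors(2.0, 12.0, 4.0)
        assert v2 == pytest.approx(2 * v1)
        assert v3 == pytest.approx(2 * v1)

    def test_nonpositive_inputs_rejected(self):
        with pytest.raises(ValueError):
            size_fermentation_reactors(0.0, 6.0, 4.0)


class TestSeparation:
    def test_reference_recoveries(self):
        split = apply_fermentation_conversions(CODStream("s", 26822.0), ConversionSpec())
        sep = separation_train(split, SeparationSpec())
        assert sep.recovered_kg_h["hexanoic acid"] == pytest.approx(1877.0, abs=1.0)
        assert sep.recovered_kg_h["octanoic acid"] == pytest.approx(
            split.products["octanoic acid"].mass_flows["octanoic acid"] * 0.999
        )
        assert sep.solvent_makeup_kg_h == pytest.approx(745.0)
        assert sep.total_duty_mw == pytest.approx(7.05)

    def test_scfa_not_extracted(self):
        split = apply_fermentation_conversions(CODStream("s", 10000.0), ConversionSpec())
        sep = separation_train(split, SeparationSpec())
        scfa_cod = split.products["acetic acid"].cod_flow + split.products["butyric acid"].cod_flow
        assert sep.aqueous_return.cod_flow >= scfa_cod

    def test_perfect_recovery_zero_loss_leaves_no_mcfa_in_aqueous(self):
        split = apply_fermentation_conversions(CODStream("s", 10000.0), ConversionSpec())
        spec = SeparationSpec(
            recovery_hexanoic=1.0, recovery_octanoic=1.0, solvent_loss_kg_h=0.0
        )
        sep = separation_train(split, spec)
        expected_aqueous = (
            split.residual.cod_flow
            + split.products["acetic acid"].cod_flow
            + split.products["butyric acid"].cod_flow
        )
        assert sep.aqueous_return.cod_flow == pytest.approx(expected_aqueous, rel=1e-12)

    def test_zero_product_feed_still_incurs_solvent_makeup(self):
        spec_conv = ConversionSpec(acetic=0, butyric=0, hexanoic=0, octanoic=0, offgas=0)
        split = apply_fermentation_conversions(CODStream("s", 1000.0), spec_conv)
        sep = separation_train(split, SeparationSpec())
        assert sep.recovered_kg_h["hexanoic acid"] == 0.0
        assert sep.solvent_makeup_kg_h == pytest.approx(745.0)


def test_cod_conserved_on_randomized_scenarios():
    """Fermentation + separation close the COD balance to 0.1% across 1,000
    randomized conversion/recovery/flow draws."""
    rng = np.random.default_rng(2024)
    for _ in range(1000):
        fracs = rng.dirichlet(np.ones(6))  # 4 products + offgas + residual
        conv = ConversionSpec(
            acetic=fracs[0], butyric=fracs[1], hexanoic=fracs[2],
            octanoic=fracs[3], offgas=fracs[4],
        )
        sep_spec = SeparationSpec(
            recovery_hexanoic=rng.uniform(0.5, 1.0),
            recovery_octanoic=rng.uniform(0.5, 1.0),
            solvent_feed_kg_h=rng.uniform(0, 20000),
            solvent_loss_kg_h=0.0,
        )
        sep_spec = sep_spec.model_copy(
            update={"solvent_loss_kg_h": sep_spec.solvent_feed_kg_h * rng.uniform(0, 0.2)}
        )
        flow = rng.uniform(100.0, 1e5)
        split = apply_fermentation_conversions(CODStream("s", flow), conv)
        sep = separation_train(split, sep_spec)
        cod_in = flow + sep.solvent_makeup_kg_h * THOD_2_OCTANOL
        cod_out = (
            sum(sep.recovered_cod_kg_h.values())
            + split.offgas.cod_flow
            + sep.aqueous_return.cod_flow
        )
        assert abs(cod_out - cod_in) <= 1e-3 * cod_in


def test_increasing_hexanoic_fraction_monotone_effects():
    """More COD to hexanoate means more recovered product and less residual
    COD for digestion, hence less biogas."""
    recovered, biogas = [], []
    for frac in (0.10, 0.16, 0.22):
        conv = ConversionSpec(hexanoic=frac)
        split = apply_fermentation_conversions(CODStream("s", 26822.0), conv)
        sep = separation_train(split, SeparationSpec())
        spec = EnergySpec(ad_feed_anchor_kg_cod_h=None)
        res = energy_balance(sep.aqueous_return, spec)
        recovered.append(sep.recovered_kg_h["hexanoic acid"])
        biogas.append(res.biogas_kg_h)
    assert recovered[0] < recovered[1] < recovered[2]
    assert biogas[0] > biogas[1] > biogas[2]


class TestEnergyBalance:
    def test_calibrated_biogas_yield_reproduces_reference_pair(self):
        res = energy_balance(CODStream("ad", 21000.0), EnergySpec())
        assert res.biogas_kg_h == pytest.approx(16600.0, rel=1e-6)

    def test_net_export_anchor_arithmetic(self):
        res = energy_balance(CODStream("ad", 21000.0), EnergySpec(), added_duties_mw=7.05)
        assert res.generation_mw == pytest.approx(38.0)
        assert res.net_export_mw == pytest.approx(13.7 - 3.0 - 7.05, abs=1e-9)

    def test_baseline_identity_with_no_diversion_or_duties(self):
        spec = EnergySpec(scenario_generation_anchor_mw=None)
        res = energy_balance(CODStream("ad", 21900.0 / spec.biogas_yield_kg_per_kg_cod), spec)
        assert res.generation_mw == pytest.approx(41.0)
        assert res.net_export_mw == pytest.approx(13.7)

    def test_uncalibrated_yield_rejected(self):
        with pytest.raises(Exception):
            EnergySpec(biogas_yield_kg_per_kg_cod=0.0)


def test_full_balance_reference_scenario(scenario):
    result = run_balance(scenario)
    assert result.cod_closure_rel_error < 1e-3
    assert result.energy.biogas_kg_h == pytest.approx(16600.0, rel=1e-6)
    assert result.reactor_count == 4
    assert result.total_reactor_volume_mg == pytest.approx(16.0)
    assert result.energy.net_export_mw == pytest.approx(3.65, abs=1e-9)
    d = result.to_dict()
    assert d["recovered_kg_h"]["hexanoic acid"] == pytest.approx(1877.0, abs=1.0)
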