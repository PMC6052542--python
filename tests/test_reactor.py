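"""Reactor performance metrics, steady-state summaries and feed arithmetic."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from stillage_mcfa import datasets
from stillage_mcfa.reactor import (
    FeedReference,
    PerformanceRecord,
    ReactorPerformanceModel,
    ReactorTimeSeries,
    SamplePoint,
    UndefinedMetricError,
    feed_characterization,
    performance_metrics,
    productivity_and_titer,
    steady_state_summary,
)


def make_series(samples, feed=None, srt=6.0):
    feed = feed or FeedReference(
        "f", {"acetic acid": 2550.0}, total_soluble_cod=95600.0, total_carbohydrate=40100.0
    )
    return ReactorTimeSeries(samples=samples, feed_schedule=[(0.0, feed)], srt=srt)


def test_sample_identical_to_feed_gives_zero_metrics():
    feed = FeedReference("f", {}, total_soluble_cod=95600.0, total_carbohydrate=40100.0)
    series = make_series(
        [SamplePoint(1.0, {}, total_soluble_cod=95600.0, total_carbohydrate=40100.0)], feed
    )
    (rec,) = performance_metrics(series)
    assert rec.cod_removed == 0.0
    assert rec.carbohydrate_conversion == 0.0
    assert rec.scfa_conversion == 0.0
    assert rec.mcfa_conversion == 0.0


def test_carbohydrate_conversion_and_mcfa_conversion_hand_values():
    # residual carbs chosen so (40100 - x)/40100 = 0.97; hexanoate alone
    # at 15,296 mg COD/L against 95,600 mg COD/L feed gives 16.0%
    series = make_series(
        [
            SamplePoint(
                40.0,
                {"hexanoic acid": 15296.0},
                total_soluble_cod=80000.0,
                total_carbohydrate=1203.0,
            )
        ]
    )
    (rec,) = performance_metrics(series)
    assert rec.carbohydrate_conversion == pytest.approx(97.0, abs=0.01)
    assert rec.mcfa_conversion == pytest.approx(16.0, abs=0.01)
    assert rec.scfa_conversion == 0.0
    assert rec.mcfa_share_of_acids == pytest.approx(100.0)


def test_zero_feed_cod_raises():
    feed = FeedReference("f", {}, total_soluble_cod=0.0, total_carbohydrate=1.0)
    series = make_series([SamplePoint(1.0, {}, 0.0, 1.0)], feed)
    with pytest.raises(UndefinedMetricError):
        performance_metrics(series)


def test_subtract_feed_acids_mode_nets_out_feed_acetate():
    series = make_series(
        [SamplePoint(1.0, {"acetic acid": 2550.0}, 95600.0, 40100.0)]
    )
    (gross,) = performance_metrics(series)
    (net,) = performance_metrics(series, subtract_feed_acids=True)
    assert gross.scfa_conversion > 0
    assert net.scfa_conversion == pytest.approx(0.0, abs=1e-12)


def test_batch_switch_uses_feed_active_at_sample_time():
    b1 = FeedReference("b1", {}, total_soluble_cod=100000.0, total_carbohydrate=100.0)
    b2 = FeedReference("b2", {}, total_soluble_cod=50000.0, total_carbohydrate=100.0)
    series = ReactorTimeSeries(
        samples=[
            SamplePoint(100.0, {}, 50000.0, 100.0),
            SamplePoint(130.0, {}, 50000.0, 100.0),
        ],
        feed_schedule=[(0.0, b1), (120.0, b2)],
        srt=6.0,
    )
    before, after = performance_metrics(series)
    assert before.cod_removed == pytest.approx(50.0)
    assert after.cod_removed == pytest.approx(0.0)


@given(k=st.floats(min_value=1e-3, max_value=1e3, allow_nan=False))
def test_metrics_scale_invariant(k):
    """Multiplying every concentration by k leaves all percent metrics fixed."""
    def build(scale):
        feed = FeedReference(
            "f",
            {"acetic acid": 2550.0 * scale},
            total_soluble_cod=95600.0 * scale,
            total_carbohydrate=40100.0 * scale,
        )
        return make_series(
            [
                SamplePoint(
                    10.0,
                    {"hexanoic acid": 15000.0 * scale, "butyric acid": 9000.0 * scale},
                    total_soluble_cod=87000.0 * scale,
                    total_carbohydrate=1500.0 * scale,
                )
            ],
            feed,
        )

    (base,), (scaled,) = performance_metrics(build(1.0)), performance_metrics(build(k))
    for m in ("cod_removed", "carbohydrate_conversion", "scfa_conversion",
              "mcfa_conversion", "mcfa_share_of_acids"):
        assert getattr(scaled, m) == pytest.approx(getattr(base, m), rel=1e-9)


def _const_records(values):
    return [
        PerformanceRecord(t, 0.0, 0.0, 0.0, v, 0.0, 0.0)
        for t, v in zip((30.0, 40.0, 50.0), values)
    ]


def test_steady_state_mean_and_sample_sd():
    ss = steady_state_summary(_const_records([16.0, 18.0, 20.0]), window=(30, 60))
    assert ss.mean["mcfa_conversion"] == pytest.approx(18.0)
    assert ss.sd["mcfa_conversion"] == pytest.approx(2.0)  # sample (n-1) SD
    const = steady_state_summary(_const_records([18.0, 18.0, 18.0]), window=(30, 60))
    assert const.sd["mcfa_conversion"] == 0.0


def test_steady_state_empty_window_names_available_range():
    with pytest.raises(ValueError, match=r"\[300.0?, 400.0?\]"):
        steady_state_summary(_const_records([1, 2, 3]), window=(300.0, 400.0))


def test_productivity_and_titer_reference_products():
    """Hexanoic at 15.6 g COD/L over a 6-day SRT is 2.6 g COD/L/d and ~66%
    of its 10.8 g/L solubility; octanoic at 0.27 g COD/L/d is ~98% of 0.68."""
    samples = [
        SamplePoint(t, {"hexanoic acid": 15600.0, "octanoic acid": 1620.0}, 90000.0, 1000.0)
        for t in (30.0, 60.0, 90.0)
    ]
    series = make_series(samples, srt=6.0)
    hexa = productivity_and_titer(series, "hexanoic acid")
    assert hexa.productivity == pytest.approx(2.6, rel=1e-9)
    assert hexa.productivity_basis == "g COD L-1 d-1"
    assert hexa.titer_fraction == pytest.approx(65.5, abs=0.1)
    octa = productivity_and_titer(series, "octanoic acid")
    assert octa.productivity == pytest.approx(0.27, rel=1e-9)
    assert octa.titer_fraction == pytest.approx(100.0 * 0.27 * 6 / 2.440817 / 0.68, rel=1e-9)


def test_titer_fraction_productivity_identity():
    """titer_fraction = 100 * productivity * SRT / (thod * solubility), exactly."""
    samples = [SamplePoint(t, {"hexanoic acid": 8000.0}, 90000.0, 1000.0) for t in (30.0, 36.0)]
    series = make_series(samples, srt=6.0)
    p = productivity_and_titer(series, "hexanoic acid")
    expected = 100.0 * p.productivity * series.srt / (2.203857 * 10.8)
    assert p.titer_fraction == pytest.approx(expected, rel=1e-9)


def test_zero_concentration_gives_zero_productivity_and_titer():
    samples = [SamplePoint(t, {}, 90000.0, 1000.0) for t in (30.0, 36.0)]
    p = productivity_and_titer(make_series(samples), "hexanoic acid")
    assert p.productivity == 0.0
    assert p.titer_fraction == 0.0


def test_missing_solubility_warns_and_omits_titer():
    samples = [SamplePoint(30.0, {"butyric acid": 1000.0}, 90000.0, 1000.0)]
    with pytest.warns(UserWarning, match="solubility"):
        p = productivity_and_titer(make_series(samples), "butyric acid", window=(0, 50))
    assert p.titer_fraction is None
    assert p.productivity > 0


def test_feed_characterization_reference_liquors():
    report = feed_characterization(
        datasets.hydrolysate(),
        datasets.fermented_hydrolysate(),
        [datasets.stillage_batch1(), datasets.stillage_batch2()],
    )
    assert report["xylose_consumed_pct"] == pytest.approx(47.2, abs=0.05)
    assert report["glucose_consumed_pct"] == pytest.approx(99.9, abs=0.05)
    assert report["stillage_cod_fraction_pct"] == pytest.approx(59.75, abs=0.01)
    assert report["residual_ethanol_pct"] == pytest.approx(2.75, abs=0.01)


def test_feed_characterization_missing_component_warns_not_raises():
    hyd = FeedReference("h", {"xylose": 100.0}, 0.0, 0.0)
    ferm = FeedReference("f", {"xylose": 50.0}, 1000.0, 0.0)
    still = FeedReference("s", {}, 600.0, 0.0)
    with pytest.warns(UserWarning):
        report = feed_characterization(hyd, ferm, still)
    assert report["xylose_consumed_pct"] == pytest.approx(50.0)
    assert "glucose_consumed_pct" not in report
    assert "residual_ethanol_pct" not in report


def test_model_fit_summary_contains_key_metrics(noiseless_results):
    text = noiseless_results.summary()
    assert "mcfa_conversion" in text
    assert "hexanoic acid" in text
    frame = noiseless_results.frame
    assert {"time", "mcfa_conversion"} <= set(frame.columns)
    assert len(frame) == len(noiseless_results.records)
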