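"""Synthetic reactor time series and TEA scenarios.

The generator emulates the structure of the 252-day stillage-fed CSTR
experiment so that every pipeline stage is testable without any external
data: a ~30-day acclimation phase in which carbohydrate conversion ramps
up and odd-chain acids (propionic, valeric, heptanoic) transiently
accumulate before even-chain products take over, followed by a steady
state in which each product class holds a configured conversion of feed
COD. Measurement noise is multiplicative lognormal with unit mean (CVs of
a few percent up to ~17% span the technical-replicate scatter of the
reference assays; lognormal keeps concentrations positive).

The acclimation shape is qualitative scaffolding for testing windowing
logic, not a kinetic model. At zero noise every configured steady-state
target is recovered exactly by the metrics stage; with noise the
recovered means are unbiased.
"""

from __future__ import annotations

import copy
from typing import Optional

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, model_validator

from . import datasets
from .cod import REGISTRY
from .reactor import FeedReference, ReactorTimeSeries, SamplePoint
from .scenario import ScenarioConfig

__all__ = [
    "SyntheticReactorConfig",
    "generate_reactor_series",
    "generate_tea_scenario",
    "write_series_csv",
    "write_feed_csv",
]


class SyntheticReactorConfig(BaseModel):
    """Configuration of one synthetic reactor run.

    Steady-state targets are fractions of feed soluble COD (conversions)
    or dimensionless ratios; they default to the reference experiment's
    steady-state structure.
    """

    srt_days: float = Field(6.0, gt=0)
    duration_days: float = Field(252.0, gt=0)
    sampling_interval_days: float = Field(6.0, gt=0)
    acclimation_days: float = Field(30.0, ge=0)
    initial_ocfa_fraction: float = Field(0.5, ge=0, le=1)
    mcfa_conversion: float = Field(0.177, ge=0, le=1)
    scfa_conversion: float = Field(0.204, ge=0, le=1)
    carbohydrate_conversion: float = Field(0.97, ge=0, le=1)
    offgas_fraction: float = Field(0.091, ge=0, le=1)
    hexanoate_octanoate_cod_ratio: float = Field(0.16 / 0.017, gt=0)
    acetate_butyrate_cod_ratio: float = Field(0.054 / 0.15, gt=0)
    noise_cv: float = Field(0.0, ge=0)
    seed: int = 0
    two_feed_batches: bool = False  # batch switch at the reference day 120

    @model_validator(mode="after")
    def _mass_balance(self) -> "SyntheticReactorConfig":
        total = self.mcfa_conversion + self.scfa_conversion + self.offgas_fraction
        if total > 1.0:
            raise ValueError(
                f"conversion targets + offgas = {total:.3f} exceed the COD balance"
            )
        return self


def _smoothstep(t: np.ndarray | float, t_end: float) -> np.ndarray | float:
    """C1 ramp from 0 at t=0 to exactly 1 at t >= t_end."""
    if t_end <= 0:
        return np.ones_like(np.asarray(t, dtype=float))
    x = np.clip(np.asarray(t, dtype=float) / t_end, 0.0, 1.0)
    return x * x * (3.0 - 2.0 * x)


def _lognormal_unit_mean(rng: np.random.Generator, cv: float, size=None):
    """Multiplicative noise with E[X] = 1 and SD/mean = cv."""
    if cv == 0:
        return np.ones(size) if size else 1.0
    sigma = np.sqrt(np.log1p(cv * cv))
    return rng.lognormal(mean=-0.5 * sigma * sigma, sigma=sigma, size=size)


def generate_reactor_series(config: SyntheticReactorConfig) -> ReactorTimeSeries:
    """Generate one deterministic-under-seed synthetic reactor series."""
    rng = np.random.default_rng(config.seed)
    if config.two_feed_batches:
        schedule = datasets.default_feed_schedule()
    else:
        schedule = [(0.0, datasets.stillage_batch1())]
    # Close the feed COD balance exactly: identified + unknown = total.
    for _, feed in schedule:
        identified = sum(v for k, v in feed.components.items() if k != "unknown")
        feed.components["unknown"] = feed.total_soluble_cod - identified

    times = np.arange(
        config.sampling_interval_days,
        config.duration_days + 1e-9,
        config.sampling_interval_days,
    )
    samples: list[SamplePoint] = []
    accl = config.acclimation_days
    for t in times:
        feed = schedule[0][1]
        for start, f in schedule:
            if t >= start:
                feed = f
        ramp = float(_smoothstep(t, accl))
        # Odd-chain transient: rises early in acclimation, exactly 0 from
        # the end of acclimation onward so steady-state classes are pure.
        if accl > 0 and t < accl:
            x = t / accl
            ocfa = config.initial_ocfa_fraction * 4.0 * x * (1.0 - x)
        else:
            ocfa = 0.0

        mcfa_cod = config.mcfa_conversion * ramp * feed.total_soluble_cod
        scfa_cod = config.scfa_conversion * ramp * feed.total_soluble_cod
        r_ho = config.hexanoate_octanoate_cod_ratio
        r_ab = config.acetate_butyrate_cod_ratio
        conc = {
            "hexanoic acid": mcfa_cod * (1.0 - ocfa) * r_ho / (1.0 + r_ho),
            "octanoic acid": mcfa_cod * (1.0 - ocfa) * 1.0 / (1.0 + r_ho),
            "heptanoic acid": mcfa_cod * ocfa,
            "acetic acid": scfa_cod * (1.0 - ocfa) * r_ab / (1.0 + r_ab),
            "butyric acid": scfa_cod * (1.0 - ocfa) * 1.0 / (1.0 + r_ab),
            "propionic acid": scfa_cod * ocfa * 0.6,
            "pentanoic acid": scfa_cod * ocfa * 0.4,
        }
        carb_conv = config.carbohydrate_conversion * ramp
        residual_carb = feed.total_carbohydrate * (1.0 - carb_conv)
        xylose_share = feed.components.get("xylose", 0.0) / max(feed.total_carbohydrate, 1e-12)
        conc["xylose"] = residual_carb * xylose_share
        conc["carbohydrate"] = residual_carb * (1.0 - xylose_share)
        total_cod = feed.total_soluble_cod * (1.0 - config.offgas_fraction * ramp)

        noise = _lognormal_unit_mean(rng, config.noise_cv, size=len(conc) + 2)
        noisy = {k: v * n for (k, v), n in zip(conc.items(), noise)}
        samples.append(
            SamplePoint(
                time=float(t),
                components=noisy,
                total_soluble_cod=total_cod * float(noise[-2]),
                total_carbohydrate=residual_carb * float(noise[-1]),
            )
        )
    return ReactorTimeSeries(
        samples=samples, feed_schedule=schedule, srt=config.srt_days, registry=REGISTRY
    )


def _deep_update(base: dict, overrides: dict) -> dict:
    out = copy.deepcopy(base)
    for key, val in overrides.items():
        if isinstance(val, dict) and isinstance(out.get(key), dict):
            out[key] = _deep_update(out[key], val)
        else:
            out[key] = val
    return out


def generate_tea_scenario(overrides: Optional[dict] = None) -> ScenarioConfig:
    """The reference TEA scenario, optionally with field overrides.

    Overrides are a nested dict mirroring the ScenarioConfig schema, e.g.
    ``{"conversions": {"hexanoic": 0.0}}``; validation is re-run on the
    merged configuration so invalid overrides fail with field-level errors.
    """
    base = ScenarioConfig().model_dump(mode="json")
    if overrides:
        base = _deep_update(base, overrides)
    return ScenarioConfig.model_validate(base)


# ---------------------------------------------------------------------------
# CSV serialization (matches reactor.read_series_csv / read_feed_csv)


def write_series_csv(series: ReactorTimeSeries, path) -> None:
    rows = []
    for s in series.samples:
        for name, value in sorted(s.components.items()):
            rows.append((s.time, name, repr(float(value)), "mg_COD_per_L", ""))
        rows.append((s.time, "soluble_cod", repr(float(s.total_soluble_cod)), "mg_COD_per_L", ""))
        rows.append((s.time, "total_carbohydrate", repr(float(s.total_carbohydrate)), "mg_COD_per_L", ""))
    df = pd.DataFrame(rows, columns=["time_day", "compound", "value", "unit", "sd"])
    df.to_csv(path, index=False)


def write_feed_csv(schedule: list[tuple[float, FeedReference]], path) -> None:
    rows = []
    for start, feed in schedule:
        for name, value in sorted(feed.components.items()):
            rows.append(
                (feed.batch_id, start, name, repr(float(value)), "mg_COD_per_L",
                 feed.component_sd.get(name, 0.0))
            )
        rows.append((feed.batch_id, start, "soluble_cod", repr(float(feed.total_soluble_cod)), "mg_COD_per_L", 0.0))
        rows.append((feed.batch_id, start, "total_carbohydrate", repr(float(feed.total_carbohydrate)), "mg_COD_per_L", 0.0))
    df = pd.DataFrame(rows, columns=["batch_id", "start_day", "compound", "value", "unit", "sd"])
    df.to_csv(path, index=False)
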