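"""Reactor performance metrics for a stillage-fed mixed-culture fermenter.

The experimental system is a flow-through CSTR (SRT = HRT, no biomass
recycle) fed lignocellulosic ethanol stillage, in which an anaerobic
community ferments residual xylose and complex carbohydrates to short- and
medium-chain monocarboxylic acids (chain elongation / carboxylate platform).
All concentrations are carried on a COD basis so that removal, conversion
and product yields share one currency.

Per time point the module computes:

* ``cod_removed``              = 100 * (feed COD - reactor COD) / feed COD
* ``carbohydrate_conversion``  = 100 * (feed carbs - reactor carbs) / feed carbs
* ``scfa_conversion``          = 100 * sum(reactor SCFA COD) / feed COD
* ``mcfa_conversion``          = 100 * sum(reactor MCFA COD) / feed COD

Product conversions divide by *total feed soluble COD* (not by removed
COD), and feed acids are by default not subtracted from reactor acids —
gross reactor concentrations are what the downstream technoeconomics uses.
A net-of-feed mode is available via ``subtract_feed_acids``.

`ReactorPerformanceModel` wraps these metrics in a model/results pair:
``ReactorPerformanceModel(series).fit(window=(30, 252))`` returns a
`ReactorPerformanceResults` holding the per-sample records, steady-state
means and sample SDs, and product productivities/titers.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .cod import (
    REGISTRY,
    ChainClass,
    ChainParity,
    CompoundRegistry,
    CompoundSpec,
    classify_compound,
    mass_to_cod,
)

logger = logging.getLogger(__name__)

__all__ = [
    "FeedReference",
    "SamplePoint",
    "ReactorTimeSeries",
    "PerformanceRecord",
    "SteadyStateSummary",
    "performance_metrics",
    "steady_state_summary",
    "productivity_and_titer",
    "feed_characterization",
    "ReactorPerformanceModel",
    "ReactorPerformanceResults",
    "read_series_csv",
    "read_feed_csv",
]

#: Default steady-state averaging window (days): after the ~30-day
#: acclimation phase through the end of the 252-day experiment.
DEFAULT_WINDOW = (30.0, 252.0)


class UndefinedMetricError(ZeroDivisionError):
    """Raised when a metric's denominator (feed COD or carbs) is zero."""


@dataclass
class FeedReference:
    """Composition of one stillage feed batch (all values mg COD/L)."""

    batch_id: str
    components: dict[str, float]
    total_soluble_cod: float
    total_carbohydrate: float
    component_sd: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.total_soluble_cod < 0 or self.total_carbohydrate < 0:
            raise ValueError("feed totals must be >= 0")

    def component(self, name: str) -> Optional[float]:
        return self.components.get(name)


@dataclass
class SamplePoint:
    """One reactor sampling event (all values mg COD/L)."""

    time: float
    components: dict[str, float]
    total_soluble_cod: float
    total_carbohydrate: float


@dataclass
class ReactorTimeSeries:
    """Time-ordered reactor samples against a (possibly switching) feed.

    ``feed_schedule`` maps the start day of each feed batch to its
    reference; a sample is compared against the batch active at its time.
    """

    samples: list[SamplePoint]
    feed_schedule: list[tuple[float, FeedReference]]
    srt: float
    registry: CompoundRegistry = field(default_factory=lambda: REGISTRY)

    def __post_init__(self) -> None:
        if self.srt <= 0:
            raise ValueError("srt must be > 0 days")
        times = [s.time for s in self.samples]
        if any(t2 <= t1 for t1, t2 in zip(times, times[1:])):
            raise ValueError("sample times must be strictly increasing")
        if not self.feed_schedule:
            raise ValueError("at least one feed batch is required")
        self.feed_schedule = sorted(self.feed_schedule, key=lambda kv: kv[0])

    def feed_for(self, time: float) -> FeedReference:
        active = self.feed_schedule[0][1]
        for start, feed in self.feed_schedule:
            if time >= start:
                active = feed
        return active


@dataclass
class PerformanceRecord:
    """Per-time-point performance metrics (percent)."""

    time: float
    cod_removed: float
    carbohydrate_conversion: float
    scfa_conversion: float
    mcfa_conversion: float
    mcfa_share_of_acids: float  # 100 * MCFA / (SCFA + MCFA) COD
    ocfa_fraction: float  # odd-chain acid share of all monocarboxylates


_METRICS = (
    "cod_removed",
    "carbohydrate_conversion",
    "scfa_conversion",
    "mcfa_conversion",
    "mcfa_share_of_acids",
    "ocfa_fraction",
)


@dataclass
class SteadyStateSummary:
    """Mean and sample SD (ddof=1) of each metric over a time window."""

    window: tuple[float, float]
    n: int
    mean: dict[str, float]
    sd: dict[str, float]

    def to_dict(self) -> dict:
        return {
            "window_days": list(self.window),
            "n_samples": self.n,
            "mean_pct": self.mean,
            "sd_pct": self.sd,
        }


def _acid_cod_by_class(
    components: dict[str, float], registry: CompoundRegistry
) -> tuple[float, float, float]:
    """(SCFA COD, MCFA COD, odd-chain acid COD) of a composition."""
    scfa = mcfa = odd = 0.0
    for name, value in components.items():
        if name not in registry:
            continue
        spec = registry.get(name)
        cls, parity = classify_compound(spec)
        if cls is ChainClass.SCFA:
            scfa += value
        elif cls is ChainClass.MCFA:
            mcfa += value
        if spec.is_monocarboxylic_acid and parity is ChainParity.ODD and cls is not ChainClass.OTHER:
            odd += value
    return scfa, mcfa, odd


def performance_metrics(
    series: ReactorTimeSeries,
    subtract_feed_acids: bool = False,
) -> list[PerformanceRecord]:
    """Compute the per-time-point performance record for every sample.

    Negative conversions arising from measurement noise are retained (no
    truncation at zero, which would bias window means) but logged.
    """
    records: list[PerformanceRecord] = []
    for sample in series.samples:
        feed = series.feed_for(sample.time)
        if feed.total_soluble_cod <= 0:
            raise UndefinedMetricError(
                f"feed total soluble COD is zero at day {sample.time}"
            )
        comps = dict(sample.components)
        if subtract_feed_acids:
            for name in list(comps):
                if name in series.registry and series.registry.get(name).is_monocarboxylic_acid:
                    comps[name] = comps[name] - feed.components.get(name, 0.0)
        scfa, mcfa, odd = _acid_cod_by_class(comps, series.registry)
        total_acids = scfa + mcfa

        cod_removed = 100.0 * (feed.total_soluble_cod - sample.total_soluble_cod) / feed.total_soluble_cod
        if feed.total_carbohydrate > 0:
            carb = 100.0 * (feed.total_carbohydrate - sample.total_carbohydrate) / feed.total_carbohydrate
        else:
            carb = math.nan
        rec = PerformanceRecord(
            time=sample.time,
            cod_removed=cod_removed,
            carbohydrate_conversion=carb,
            scfa_conversion=100.0 * scfa / feed.total_soluble_cod,
            mcfa_conversion=100.0 * mcfa / feed.total_soluble_cod,
            mcfa_share_of_acids=(100.0 * mcfa / total_acids) if total_acids > 0 else 0.0,
            ocfa_fraction=(100.0 * odd / total_acids) if total_acids > 0 else 0.0,
        )
        if rec.carbohydrate_conversion < 0 or rec.cod_removed < 0:
            logger.debug("negative conversion at day %.1f (noise): %s", sample.time, rec)
        records.append(rec)
    return records


def records_to_frame(records: Sequence[PerformanceRecord]) -> pd.DataFrame:
    return pd.DataFrame([{"time": r.time, **{m: getattr(r, m) for m in _METRICS}} for r in records])


def steady_state_summary(
    records: Sequence[PerformanceRecord],
    window: tuple[float, float] = DEFAULT_WINDOW,
) -> SteadyStateSummary:
    """Arithmetic mean and sample SD of each metric over the window."""
    lo, hi = window
    if not lo < hi:
        raise ValueError("window start must precede window end")
    inside = [r for r in records if lo <= r.time <= hi]
    if len(inside) < 2:
        times = [r.time for r in records]
        raise ValueError(
            f"need >= 2 records in window [{lo}, {hi}]; available times span "
            f"[{min(times, default=float('nan'))}, {max(times, default=float('nan'))}]"
        )
    mean: dict[str, float] = {}
    sd: dict[str, float] = {}
    for m in _METRICS:
        vals = np.array([getattr(r, m) for r in inside], dtype=float)
        mean[m] = float(np.nanmean(vals))
        sd[m] = float(np.nanstd(vals, ddof=1))
    return SteadyStateSummary(window=(lo, hi), n=len(inside), mean=mean, sd=sd)


@dataclass
class ProductPerformance:
    """Steady-state productivity and titer of one product acid.

    ``productivity`` is on a COD basis (g COD per L per day = mean
    steady-state concentration divided by SRT, the washout rate of a
    flow-through CSTR); ``titer_fraction`` is the mean titer in mass units
    as a percent of the compound's aqueous solubility.
    """

    product: str
    productivity: float
    productivity_basis: str
    mean_titer_g_cod_per_L: float
    mean_titer_g_per_L: float
    titer_fraction: Optional[float]


def productivity_and_titer(
    series: ReactorTimeSeries,
    product: CompoundSpec | str,
    window: tuple[float, float] = DEFAULT_WINDOW,
) -> ProductPerformance:
    """Volumetric productivity (g COD/L/d) and titer as % of solubility.

    The two are linked exactly by
    ``titer_fraction = 100 * productivity * SRT / (thod * solubility)``.
    """
    spec = product if isinstance(product, CompoundSpec) else series.registry.get(product)
    lo, hi = window
    concs = [
        s.components.get(spec.name, 0.0)
        for s in series.samples
        if lo <= s.time <= hi
    ]
    if not concs:
        raise ValueError(f"no samples in window [{lo}, {hi}]")
    mean_cod_g_L = float(np.mean(concs)) / 1000.0  # mg -> g COD/L
    productivity = mean_cod_g_L / series.srt
    mass_g_L = mean_cod_g_L / spec.thod
    if spec.solubility_g_per_L is None:
        warnings.warn(f"{spec.name}: no solubility registered; titer fraction omitted")
        frac = None
    else:
        frac = 100.0 * mass_g_L / spec.solubility_g_per_L
    return ProductPerformance(
        product=spec.name,
        productivity=productivity,
        productivity_basis="g COD L-1 d-1",
        mean_titer_g_cod_per_L=mean_cod_g_L,
        mean_titer_g_per_L=mass_g_L,
        titer_fraction=frac,
    )


def feed_characterization(
    hydrolysate: FeedReference,
    fermented: FeedReference,
    stillage: FeedReference | Sequence[FeedReference],
) -> dict[str, float]:
    """Upstream mass-balance arithmetic across the three process liquors.

    Reports, in percent: xylose and glucose consumed during the ethanol
    fermentation, the fraction of fermented-hydrolysate COD retained in
    stillage after distillation, and the ethanol remaining in stillage
    relative to the fermentation broth. Stillage values are averaged across
    batches when several are given. Missing components are omitted from the
    report with a warning rather than raised.
    """
    batches = [stillage] if isinstance(stillage, FeedReference) else list(stillage)
    report: dict[str, float] = {}

    for sugar, key in (("xylose", "xylose_consumed_pct"), ("glucose", "glucose_consumed_pct")):
        before, after = hydrolysate.component(sugar), fermented.component(sugar)
        if before is None or after is None or before <= 0:
            warnings.warn(f"feed characterization: {sugar} missing; {key} omitted")
            continue
        report[key] = 100.0 * (before - after) / before

    if fermented.total_soluble_cod > 0:
        mean_stillage_cod = float(np.mean([b.total_soluble_cod for b in batches]))
        report["stillage_cod_fraction_pct"] = 100.0 * mean_stillage_cod / fermented.total_soluble_cod

    ferm_etoh = fermented.component("ethanol")
    etoh_vals = [b.component("ethanol") for b in batches]
    if ferm_etoh and all(v is not None for v in etoh_vals):
        report["residual_ethanol_pct"] = 100.0 * float(np.mean(etoh_vals)) / ferm_etoh
    else:
        warnings.warn("feed characterization: ethanol missing; residual_ethanol_pct omitted")
    return report


# ---------------------------------------------------------------------------
# Model / Results presentation layer


class ReactorPerformanceModel:
    """Performance model of a stillage-fed MCFA reactor time series.

    Parameters
    ----------
    series : ReactorTimeSeries
        Samples, feed schedule and SRT.
    subtract_feed_acids : bool
        Net-of-feed mode (subtract feed acid COD from reactor acid COD).

    ``fit(window)`` averages over the steady-state window and returns a
    :class:`ReactorPerformanceResults`.
    """

    def __init__(self, series: ReactorTimeSeries, subtract_feed_acids: bool = False):
        self.series = series
        self.subtract_feed_acids = subtract_feed_acids

    @classmethod
    def from_csv(
        cls,
        series_path,
        feed_path,
        srt: float,
        registry: Optional[CompoundRegistry] = None,
        **kwargs,
    ) -> "ReactorPerformanceModel":
        series = read_series_csv(series_path, feed_path, srt, registry=registry)
        return cls(series, **kwargs)

    def fit(
        self,
        window: tuple[float, float] = DEFAULT_WINDOW,
        products: Iterable[str] = ("hexanoic acid", "octanoic acid"),
    ) -> "ReactorPerformanceResults":
        records = performance_metrics(self.series, self.subtract_feed_acids)
        summary = steady_state_summary(records, window)
        prod = {}
        for name in products:
            if name in self.series.registry:
                prod[name] = productivity_and_titer(self.series, name, window)
        return ReactorPerformanceResults(self, records, summary, prod)


class ReactorPerformanceResults:
    """Fitted steady-state performance of a reactor series."""

    def __init__(self, model, records, steady_state, products):
        self.model = model
        self.records: list[PerformanceRecord] = records
        self.steady_state: SteadyStateSummary = steady_state
        self.products: dict[str, ProductPerformance] = products

    @property
    def frame(self) -> pd.DataFrame:
        return records_to_frame(self.records)

    def to_dict(self) -> dict:
        d = self.steady_state.to_dict()
        d["srt_days"] = self.model.series.srt
        d["products"] = {
            name: {
                "productivity": p.productivity,
                "productivity_basis": p.productivity_basis,
                "mean_titer_g_per_L": p.mean_titer_g_per_L,
                "titer_fraction_pct_of_solubility": p.titer_fraction,
            }
            for name, p in self.products.items()
        }
        return d

    def summary(self) -> str:
        ss = self.steady_state
        lines = [
            "Reactor steady-state performance",
            f"  window: day {ss.window[0]:g}-{ss.window[1]:g}  (n = {ss.n} samples, SRT = {self.model.series.srt:g} d)",
            "  metric                     mean     sd   (%)",
        ]
        for m in _METRICS:
            lines.append(f"  {m:<25s}{ss.mean[m]:7.1f}{ss.sd[m]:7.1f}")
        for name, p in self.products.items():
            tf = f"{p.titer_fraction:5.1f}% of solubility" if p.titer_fraction is not None else "n/a"
            lines.append(
                f"  {name:<18s} productivity {p.productivity:5.2f} {p.productivity_basis}, "
                f"titer {p.mean_titer_g_per_L:5.2f} g/L = {tf}"
            )
        return "\n".join(lines)


# ---------------------------------------------------------------------------
# CSV interfaces (long format)

_TOTAL_COD = "soluble_cod"
_TOTAL_CARB = "total_carbohydrate"
_UNITS = {"mg_per_L", "mg_COD_per_L"}


def _to_cod(value: float, compound: str, unit: str, registry: CompoundRegistry) -> float:
    if unit not in _UNITS:
        raise ValueError(f"unknown unit {unit!r}; expected one of {sorted(_UNITS)}")
    if unit == "mg_COD_per_L":
        return value
    return mass_to_cod(value, compound, registry)


def read_feed_csv(path, registry: Optional[CompoundRegistry] = None) -> list[tuple[float, FeedReference]]:
    """Read a feed schedule from CSV.

    Columns: ``compound, value, unit, sd`` plus optional ``batch_id`` and
    ``start_day`` (default one batch starting at day 0). Reserved compound
    names ``soluble_cod`` and ``total_carbohydrate`` carry the totals.
    """
    registry = registry or REGISTRY
    df = pd.read_csv(path)
    if "batch_id" not in df.columns:
        df["batch_id"] = "feed"
    if "start_day" not in df.columns:
        df["start_day"] = 0.0
    if "sd" not in df.columns:
        df["sd"] = 0.0
    schedule = []
    for (batch, start), grp in df.groupby(["batch_id", "start_day"], sort=True):
        comps, sds = {}, {}
        total_cod = total_carb = 0.0
        for row in grp.itertuples(index=False):
            val = _to_cod(float(row.value), row.compound, row.unit, registry)
            if row.compound == _TOTAL_COD:
                total_cod = val
            elif row.compound == _TOTAL_CARB:
                total_carb = val
            else:
                comps[row.compound] = val
                sds[row.compound] = float(row.sd) if pd.notna(row.sd) else 0.0
        schedule.append(
            (float(start), FeedReference(str(batch), comps, total_cod, total_carb, sds))
        )
    return schedule


def read_series_csv(
    series_path,
    feed_path,
    srt: float,
    registry: Optional[CompoundRegistry] = None,
) -> ReactorTimeSeries:
    """Read a reactor time series (long CSV: time_day, compound, value, unit, sd)."""
    registry = registry or REGISTRY
    df = pd.read_csv(series_path)
    if df.empty:
        raise ValueError(f"series file {series_path} contains no samples")
    samples = []
    for time, grp in df.groupby("time_day", sort=True):
        comps = {}
        total_cod = total_carb = 0.0
        for row in grp.itertuples(index=False):
            val = _to_cod(float(row.value), row.compound, row.unit, registry)
            if row.compound == _TOTAL_COD:
                total_cod = val
            elif row.compound == _TOTAL_CARB:
                total_carb = val
            else:
                comps[row.compound] = val
        samples.append(SamplePoint(float(time), comps, total_cod, total_carb))
    schedule = read_feed_csv(feed_path, registry)
    return ReactorTimeSeries(samples=samples, feed_schedule=schedule, srt=srt, registry=registry)
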