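"""Packaged reference compositions of the switchgrass process liquors.

These are the characterization data of the upstream streams used as package
defaults: AFEX-pretreated switchgrass hydrolysate before and after the
yeast ethanol fermentation, and the two batches of stillage (the liquor
remaining after ethanol is distilled off) that fed the MCFA reactor. All
values are mg COD/L; aromatic lignotoxins are carried as pass-through
metadata in ug COD/L (they contribute < 0.05% of stillage COD and are not
part of the balance).
"""

from __future__ import annotations

from .reactor import FeedReference

__all__ = [
    "hydrolysate",
    "fermented_hydrolysate",
    "stillage_batch1",
    "stillage_batch2",
    "default_feed_schedule",
    "STILLAGE_AROMATICS_UG_COD_PER_L",
    "FEED_SWITCH_DAY",
]

#: Day at which the reactor feed switched from stillage batch 1 to batch 2.
FEED_SWITCH_DAY = 120.0


def hydrolysate() -> FeedReference:
    """Switchgrass hydrolysate prior to the ethanol fermentation."""
    comps = {
        "glucose": 56000.0,
        "xylose": 36000.0,
        "glycerol": 310.0,
        "acetic acid": 2065.0,
        "ethanol": 0.0,  # below detection (< 100 mg COD/L)
    }
    sds = {"glucose": 300.0, "xylose": 230.0, "glycerol": 0.86, "acetic acid": 30.0}
    return FeedReference(
        "hydrolysate", comps, total_soluble_cod=0.0, total_carbohydrate=92000.0,
        component_sd=sds,
    )


def fermented_hydrolysate() -> FeedReference:
    """Hydrolysate after ethanol fermentation (S. cerevisiae Y128)."""
    comps = {
        "glucose": 44.0,
        "xylose": 19000.0,
        "glycerol": 2500.0,
        "acetic acid": 1600.0,
        "ethanol": 51000.0,
    }
    sds = {"glucose": 1.7, "xylose": 4500.0, "glycerol": 130.0,
           "acetic acid": 68.0, "ethanol": 2900.0}
    return FeedReference(
        "fermented hydrolysate", comps,
        total_soluble_cod=160000.0, total_carbohydrate=19044.0,
        component_sd=sds,
    )


def stillage_batch1() -> FeedReference:
    """Stillage batch 1 (fed to the reactor through day 120)."""
    comps = {
        "unknown": 38300.0,
        "xylose": 20800.0,
        "carbohydrate": 19300.0,  # anthrone carbohydrates other than xylose
        "acetamide": 4030.0,
        "glycerol": 3900.0,
        "acetic acid": 2550.0,
        "protein": 2200.0,
        "ethanol": 1220.0,
    }
    sds = {
        "unknown": 3250.0, "xylose": 148.0, "carbohydrate": 2310.0,
        "acetamide": 270.0, "glycerol": 32.1, "acetic acid": 21.1,
        "protein": 145.0, "ethanol": 305.0,
    }
    return FeedReference(
        "stillage batch 1", comps,
        total_soluble_cod=95400.0, total_carbohydrate=40100.0,
        component_sd=sds,
    )


def stillage_batch2() -> FeedReference:
    """Stillage batch 2 (fed to the reactor from day 120)."""
    comps = {
        "unknown": 42100.0,
        "xylose": 20900.0,
        "carbohydrate": 15500.0,
        "acetamide": 4200.0,
        "glycerol": 3920.0,
        "acetic acid": 2580.0,
        "protein": 1910.0,
        "ethanol": 1590.0,
    }
    sds = {
        "unknown": 3190.0, "xylose": 168.0, "carbohydrate": 2230.0,
        "acetamide": 340.0, "glycerol": 36.3, "acetic acid": 20.5,
        "protein": 162.0, "ethanol": 161.0,
    }
    return FeedReference(
        "stillage batch 2", comps,
        total_soluble_cod=95800.0, total_carbohydrate=36400.0,
        component_sd=sds,
    )


def default_feed_schedule() -> list[tuple[float, FeedReference]]:
    """Batch 1 from day 0, batch 2 from the switch day."""
    return [(0.0, stillage_batch1()), (FEED_SWITCH_DAY, stillage_batch2())]


#: Aromatic (lignotoxin) characterization, ug COD/L, per stillage batch —
#: pass-through metadata only.
STILLAGE_AROMATICS_UG_COD_PER_L = {
    "coumaroyl amide": (13000.0, 5400.0),
    "feruloyl amide": (12000.0, 3200.0),
    "p-coumaric acid": (3500.0, 1100.0),
    "benzoic acid": (1700.0, 2000.0),
    "vanillamide": (290.0, 230.0),
    "4-hydroxybenzoic acid": (380.0, 320.0),
    "vanillic acid": (320.0, 370.0),
    "ferulic acid": (250.0, 390.0),
    "4-hydroxybenzyl alcohol": (240.0, 110.0),
    "syringamide": (230.0, 138.0),
}
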