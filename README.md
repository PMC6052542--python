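# stillage-mcfa

Technoeconomic and reactor-performance modelling of medium-chain fatty acid
(MCFA) co-production from lignocellulosic ethanol stillage.

When a cellulosic biorefinery distils ethanol from fermented switchgrass
hydrolysate, the liquid residue (stillage) still holds roughly 60% of the
broth's chemical oxygen demand (COD) — residual xylose, complex
carbohydrates, glycerol, acetamide and uncharacterized organics. A
mixed-culture anaerobic fermentation (the carboxylate platform, chain
elongation by reverse β-oxidation) can convert part of that COD into
hexanoic and octanoic acids, which are more valuable than the biogas and
electricity the stillage would otherwise yield. This package is for
bioprocess and TEA practitioners who want to reproduce, stress or extend
that analysis chain:

* **`cod`** — COD bookkeeping: theoretical oxygen demand
  ThOD = 32·(C + H/4 − O/2 − 3N/4)/MW from elemental stoichiometry
  (organic N → NH₃), mass↔COD conversion, SCFA (C2–C5) / MCFA (C6–C8)
  chain-length classification, and the packaged compound registry.
* **`reactor`** — performance metrics of a stillage-fed flow-through CSTR
  (SRT = HRT): COD removal, carbohydrate conversion, conversion of feed COD
  to SCFA/MCFA, steady-state means ± sample SD over a time window, and
  product productivity (g COD L⁻¹ d⁻¹ = titer/SRT) with titers as percent
  of aqueous solubility. `ReactorPerformanceModel(series).fit()` returns a
  results object with a `summary()` table.
* **`biorefinery`** — the steady-state COD mass/energy balance of the
  modified flowsheet: fermentation conversions, reactor sizing,
  liquid–liquid extraction into 2-octanol plus two distillation columns
  (flowsheet-simulation parameters, not recomputed), anaerobic digestion
  with a calibrated biogas yield, and CHP/net-electricity accounting.
* **`economics`** — power-law equipment cost scaling with installation
  factors, total capital investment, annual operating costs and co-product
  revenues in 2007 USD.
* **`cashflow`** — a 30-year discounted cash flow to equity and the minimum
  ethanol selling price (MESP): the ethanol price at which NPV = 0 at a 10%
  internal rate of return, solved with Brent's method. The engine
  calibrates one lumped baseline operating cost so that the ethanol-only
  biorefinery (TCI $422.9M, co-product revenue $6.6M/yr) returns the
  published $2.15/gal, then perturbs capital, revenue and opex around that
  anchor. `BiorefineryTEA(scenario).fit()` returns a results object.
* **`simulate`** — a synthetic 252-day reactor series generator
  (acclimation ramp, odd-chain transient, lognormal measurement noise) and
  TEA scenario factory, so the whole pipeline is testable with no external
  data.

## Worked example

```python
from stillage_mcfa import BiorefineryTEA, ReactorPerformanceModel
from stillage_mcfa.simulate import SyntheticReactorConfig, generate_reactor_series

series = generate_reactor_series(SyntheticReactorConfig(noise_cv=0.02, seed=42))
perf = ReactorPerformanceModel(series).fit(window=(30, 252))
print(perf.summary())

tea = BiorefineryTEA().fit()
print(tea.summary())
```

The reactor summary prints (abridged):

```
Reactor steady-state performance
  window: day 30-252  (n = 38 samples, SRT = 6 d)
  metric                     mean     sd   (%)
  cod_removed                  9.2    1.7
  carbohydrate_conversion     97.0    0.1
  scfa_conversion             20.3    0.3
  mcfa_conversion             17.7    0.2
  hexanoic acid      productivity  2.54 g COD L-1 d-1, titer  6.92 g/L =  64.1% of solubility
  octanoic acid      productivity  0.27 g COD L-1 d-1, titer  0.67 g/L =  98.1% of solubility
```

i.e. at steady state 17.7 ± 0.2% of the stillage COD leaves as C6–C8
acids, and the octanoate titer sits essentially at its solubility limit.
The TEA summary ends with:

```
MESP  baseline      $2.15/gal  ($3.27/gal gasoline-eq)
MESP  co-production $1.76/gal  ($2.68/gal gasoline-eq)  [full_dcf]
MESP  reduction     18%
```

meaning MCFA co-production ($56.7M/yr extra revenue against $18.3M extra
capital and $23.7M/yr extra operating cost) lowers the ethanol price
needed for a 10% return by 18%.

The same analyses are available from the shell:

```bash
stillage-mcfa simulate reactor --out-series series.csv --out-feed feed.csv --seed 42
stillage-mcfa reactor-metrics --series series.csv --feed feed.csv --srt 6 --window 30 252
stillage-mcfa tea --report report.json
stillage-mcfa calibrate   # baseline $2.15 cash-flow gate
```

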