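# Methods

This note documents the models, conventions and design choices behind
`stillage-mcfa`: what each stage computes, which constants it carries and
why, and what its synthetic tests do and do not demonstrate.

## COD as the conserved currency

Every stream — reactor concentrations, biorefinery mass flows, digestion
feed — is carried in chemical oxygen demand units, the mass of O₂ needed
to oxidize the material to CO₂ and H₂O. COD is conserved across
fermentation, extraction and digestion, which makes it the natural
currency for a balance that spans compounds of very different reduction
states. Theoretical oxygen demand is computed from elemental composition
as ThOD = 32·(C + H/4 − O/2 − 3N/4)/MW with organic nitrogen released as
ammonia, the standard COD convention; atomic masses C 12.011, H 1.008,
O 15.999, N 14.007. Lumped analytical pools carry fixed factors instead:
protein 1.5 g COD/g (albumin-equivalent), anthrone carbohydrate
1.06 g COD/g (consistent with glucose/xylose, whose ThOD is 1.066), and
"unknown COD" — defined as measured soluble COD minus the COD of
identified components — is already in COD units (factor 1). Acetamide has
no published factor in the reference characterization; we compute it from
C₂H₅NO (1.083 g COD/g).

Solubility constants used for titer reporting are ambient-temperature
handbook values: hexanoic acid 10.8 g/L, octanoic acid 0.68 g/L,
overridable in the registry CSV. They back-reproduce the observed
titer-to-solubility fractions (≈66% and ≈97%) from the measured
productivities, which is the consistency check the tests encode.

## Reactor metrics

The experimental reactor is a flow-through CSTR with SRT = HRT = 6 days.
Per sample, against the feed batch active at that time (batch switch at
day 120 by default):

* COD removed = 100·(feed COD − reactor COD)/feed COD. The reactor is
  open; removal reflects off-gas (CO₂, H₂) rather than measured gas flow,
  so the balance module treats it as unclosed balance, not a measurement.
* Carbohydrate conversion = 100·(feed carbs − reactor carbs)/feed carbs,
  both anthrone totals on a COD basis.
* Conversion to SCFA/MCFA = 100·(Σ reactor acid COD in class)/feed soluble
  COD. Dividing by *total feed COD* (not removed COD), and *not*
  subtracting the acids already present in the feed (acetate at
  ~2,550 mg COD/L), is the reading under which a 16% hexanoate conversion,
  the observed conversion trajectory, and the TEA's gross product flows
  are mutually consistent; a net-of-feed mode exists behind
  `subtract_feed_acids`.

Steady-state summaries average over a user window (default days 30–252,
after acclimation) with sample (n−1) SD across time points. Negative
conversions from noise are retained — truncating at zero would bias the
means upward.

Productivity is reported as g COD L⁻¹ d⁻¹ = mean steady-state titer (g
COD/L) divided by SRT. The COD basis is deliberate: it is the only basis
under which the reported productivity pair (2.6, 0.27) is consistent with
the titer-vs-solubility fractions and the handbook solubilities, so the
results object carries an explicit `productivity_basis` field rather than
converting silently. The identity
titer_fraction = 100·productivity·SRT/(ThOD·solubility) holds exactly and
is property-tested.

## Biorefinery balance

Fermentation conversion is a linear partition of stillage COD: 5.4%
acetic, 15% butyric, 16% hexanoic, 1.7% octanoic, 9.1% off-gas, remainder
residual. Product mass = COD/ThOD. The stillage COD mass flow into the
MCFA step is not fixed by the reference data; the default 26,822 kg COD/h
is back-solved so that the hexanoic chain (16% conversion, 96.4%
recovery) reproduces the reference 1,877 kg/h recovered product. The
octanoic chain then yields 187 kg/h where the reference table lists 169 —
the 1.7% fraction is rounded too coarsely to pin both products with one
flow — so the economics defaults carry the reference product rates
directly and `revenue_from_balance = True` switches to balance-derived
rates.

The separation train is parametric: recoveries (96.4% / 99.9%), the
9,000 kg/h 2-octanol solvent feed, its 745 kg/h loss to the aqueous phase
(modelled as a fixed loss *fraction* of solvent feed so scaled scenarios
behave sensibly), and the two column duties (6.3 + 0.75 MW) come from
flowsheet simulation and are inputs, not outputs. Lost solvent COD
(ThOD 2.949 g COD/g) joins the digester feed. COD closure across
fermentation + separation is enforced to 0.1% and fuzz-tested over 1,000
random scenarios.

Digestion and CHP run in **anchor mode**. The biogas yield is one lumped
coefficient, 16,600/21,000 = 0.7905 kg biogas per kg COD fed, calibrated
from the reference feed/biogas pair. Total COD to digestion
(21,000 kg COD/h including lignin and biosolids) is itself an anchor: the
lignin/biosolids split is not resolved by the available data, and the
stillage-derived aqueous return alone (~22,000 kg COD/h at the default
flow) shows the published stream table does not close bottom-up.
Generation likewise anchors to the published 41.0 MW (baseline) and
38.0 MW (scenario) rather than re-deriving CHP output from the 21%
efficiency and a COD heating value (13.9 MJ/kg, available in a
first-principles mode when the anchor is unset — it lands at 35.6 MW,
confirming the anchors embed information the parameters alone do not).
Net export = 13.7 − (41.0 − 38.0) − (6.3 + 0.75) = 3.65 MW; the reference
revenue table uses 3,759 kW, a 0.11 MW gap we do not attempt to resolve
(heat integration credits are a plausible source). Both values are
reported: 3,759 kW is the default revenue basis, 3.65 MW appears in the
balance block.

## Cost model

Equipment follows cost = count·base·(size/base size)^n·installation
factor, n defaulting to 0.6. Reference installed costs (reactors $7.54M,
agitators $317k, pumps $227k, caustic $29.8k, LLE $860k, solvent feed
$29.2k, columns $1.42M/$797k; total $11.22M in 2007 USD) are carried with
per-unit purchased costs back-derived from count and factor, so the
scaling law is exact at the reference sizes and extrapolates off-design.
TCI = baseline $422.9M + 1.631 × installed additions; the 1.631 indirect
multiplier is back-solved from the published TCI pair because the
underlying indirect-cost structure is not reprinted.

Chemical prices are per **short ton** (907.185 kg) — the only reading
under which 745 kg/h of 2-octanol at $1,402/ton gives the published
≈$9.66M/yr (we compute $9.68M; the accompanying running text says $8.3M,
which we disregard in favour of the tabulated value that feeds the cash
flow). KOH usage (1,744 kg/h) is back-solved from $14.0M/yr at $866/ton.
Operating hours 8,410 h/yr (96% uptime) and electricity at $0.0572/kWh
are validated by the electricity-revenue back-calculation
(3,759 kW → $1.81M/yr). MCFA prices (HA $3.006/kg, OA $5.270/kg, 2007
USD) are back-solved from the published annual revenues. A two-point GDP
deflator index (2007: 92.486, 2016: 104.669, 2012 = 100) supports cost
year conversion; the packaged defaults are already in 2007 USD.

## Discounted cash flow and MESP

The MESP is solved as the root of NPV(price) = 0 (Brent, bracket
[0, 10] $/gal, tolerance well under $0.001) where NPV discounts cash
flows to equity at the 10% target IRR, year 0 = start of construction.
The table is built with standard NREL-style biorefinery financing
conventions, all exposed in `FinancialConfig`: 3-year construction
spending 8/60/32% of fixed capital; working capital 5% of fixed capital,
recovered in the final year; 40% equity with the remainder on a 10-year
8% level-annuity loan; 35% income tax with loss carryforward; 200%
declining-balance depreciation over 7 years with straight-line switch;
first operating year at 50% revenue and 75% operating cost (6-month
startup); 30 operating years; 61 M gal/yr ethanol.

Because the baseline biorefinery's operating cost is not available at
line-item level, the engine **calibrates** a single lumped baseline
annual opex (it lands near $83M/yr) so the baseline case returns exactly
$2.15/gal. This makes the published baseline the anchor of correctness;
the co-production solve then changes only what the scenario changes (TCI
+$18.3M, co-product revenue $6.6M → $56.75M/yr, opex +$23.68M/yr) and
returns $1.76/gal ($2.68/gge at the LHV ratio 0.6575, itself back-solved
from the published 2.15/3.27 pair). Revenue and opex deltas pass through
the tax structure one-for-one, so the solved deltas are insensitive to
the calibrated level; only the effective capital charge depends on the
financing constants, and its plausible range moves the answer by under
two cents — which is why the calibration-gate design is sound. A fast
incremental mode, MESP = baseline − (ΔR − ΔC − CRF·ΔTCI)/V with
CRF(10%, 30 yr) = 0.10608, agrees with the full DCF to ≤ $0.03/gal over
±$60M/yr perturbations (property-tested). The whole TEA path is
deterministic: no RNG anywhere.

## Synthetic data generator

`generate_reactor_series` emulates the 252-day experiment's structure:
feed = the packaged stillage batch 1 composition (optionally switching to
batch 2 at day 120), 6-day sampling, a 30-day acclimation during which
carbohydrate conversion and product formation follow a smoothstep ramp
and odd-chain acids (propionic, valeric, heptanoic) rise and fall, then a
steady state holding the configured conversion targets (defaults: MCFA
0.177 split hexanoate:octanoate 16:1.7, SCFA 0.204 split
acetate:butyrate 5.4:15, carbohydrate 0.97, off-gas 0.091). The generated
feed closes identified + unknown = total soluble COD exactly (the
packaged characterization table itself under-closes by ~3%, presumably
netting unprinted minor species; the generator recomputes the unknown
pool by closure). Noise is multiplicative lognormal with **unit mean**
(σ² = ln(1+CV²), mean offset −σ²/2), so recovered conversions are
unbiased; CVs of 0.02–0.17 span the technical-replicate scatter of the
reference assays. One `numpy` `default_rng(seed)` drives everything — no
global state; identical seeds give byte-identical CSVs.

What passing synthetic tests show: the metrics stage inverts the
generator's conversion structure exactly at zero noise and without bias
under noise, and the windowing/batch-switch logic is correct. What they
do not show: anything about real acclimation kinetics, pH/lactate
dynamics, or community behaviour — the acclimation shape is scaffolding,
not a kinetic model.

## Numerical choices and limitations

* Root solves: Brent everywhere (MESP price, baseline-opex calibration,
  bracket failures raise with NPV endpoints). Calibration tolerance $1 on
  opex ≈ 10⁻⁸ $/gal on MESP.
* Reactor count uses a ceiling with a 10⁻⁹ guard against float dust at
  exact multiples (16/4 → 4 units, not 5).
* Degenerate inputs: zero feed COD raises; zero stillage flow returns
  all-zero partitions; empty steady-state windows raise naming the
  available time range; missing solubility warns and omits the titer.
* Problem sizes: the default test/acceptance runs use the experiment's
  own scales (42-sample series, 30-year tables, 1,000-draw conservation
  fuzz), chosen because the methods are closed-form or low-dimensional —
  nothing here needs scaling down.
* Known limitations: no transient CSTR kinetics or spike-feed dynamics;
  no KOH titration chemistry (the dose is a cost input); no
  thermodynamic separation model; single-step cost-year conversion only;
  the published stream table's internal inconsistencies (net export
  3.65 vs 3.76 MW, octanoate 187 vs 169 kg/h, digester feed closure) are
  surfaced, anchored to the tabulated values that feed the cash flow, and
  not resolved.
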