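# Methods

## Scope and model structure

`fortiplan` implements a population-level (not individual-level)
fortification model with three scenario axes: current vitamin D intake
percentile, carrier-food consumption percentile, and the nutritional
target. Everything is deterministic algebra on a small set of published
inputs; the only synthetic component is the monthly baseline serum
trajectory (below).

Pipeline stages: `parameters` (validated inputs and selection
conventions) → `baseline` (monthly baseline 25(OH)D) → `engine`
(fortification levels, clustering, scenario grid) → `response`
(serum response, risk envelopes, safety flags) → `pipeline`/`cli`
(orchestration, CSV export, manifest).

## Inputs and selection conventions

The packaged defaults (`fortiplan/data/table1_defaults.yaml`) hold the
German inputs: carrier consumption percentiles by gender from the
National Nutritional Survey II, mean dietary vitamin D intake (men 3.4,
women 2.8 μg/day), mean supplement intake 0.3 μg/day, the IOM (15 μg),
DGE (20 μg) and UL (100 μg) intake targets, serum targets of 50 and
75 nmol/L, and the intake-to-serum conversion factor
c_f = 2.32 nmol/L per μg/day.

Two conventions collapse the gendered tables to scenario scalars:

* **Carrier consumption** — for the mean and 95th-percentile scenarios
  the larger of the two gender values is used. This is conservative:
  higher consumption means a smaller added dose suffices, so nobody in
  the modeled group is over-fortified. For the 5th-percentile scenario
  the smaller value is used (for bread and juice that is women; for milk
  it is men, who drink less at that percentile).
* **Vitamin D intake** — the unweighted mean of the men/women values
  ((3.4 + 2.8)/2 = 3.1 μg at the mean), plus the supplement mean, which
  is applied identically in every percentile scenario because no
  supplement percentiles are available.

Dietary-intake 5th/95th percentiles are not published. The defaults carry
documented placeholders (half and double the mean, per gender). They
never enter the headline fortification levels — those use only the means
— and the risk-envelope tests assert ordering properties rather than
absolute values wherever placeholders are involved.

## Synthetic baseline serum trajectory

The monthly baseline concentrations L_a(m) for Germany are produced
upstream by a bottom-up sun-exposure/diet model whose monthly values are
not published; only the annual mean (45 nmol/L) is. The package therefore
generates a stand-in:

    L_a(m) = annual_mean + region_offset − amplitude · cos(2π(m − trough_month)/12)

A single harmonic is the minimal model consistent with "varies by month
with a winter trough": its 12-month mean is exactly the annual mean and
it is symmetric about the trough. The default amplitude of 17.2 nmol/L is
*calibrated*, not published: inverting the January worked example
(75 − 11.3 · 2.32 · 1.8 = 27.8 nmol/L) pins January at 27.8, hence
amplitude = 45 − 27.8 = 17.2. The trough month is taken as January; the
worked example is the only constraint on it, and a February/March trough
cannot be excluded.

What the synthetic trajectory deliberately does not emulate: per-region
(federal-state) variation beyond an additive offset, UV-radiation physics,
behavioral or age structure, and any asymmetry or skew in the real
seasonal curve. Consequently, passing tests demonstrate correct model
arithmetic under a plausible seasonal cycle, not fidelity to measured
German serum data in months other than January. Any measured 12-month
trajectory can be substituted via `SerumTrajectory.from_csv` (columns
`month, region, value_nmol_per_L`).

An optional Gaussian month-level noise term (`noise_sd`, nmol/L, default
0) exists for robustness testing and is reproducibly seeded; all defaults
are noise-free and deterministic.

## Fortification engine

* **Flooring.** Both formulas floor at zero: a baseline above target or
  an intake above the recommendation needs no fortification, never a
  negative one.
* **Zero consumption.** Scenarios with F_i = 0 (the 5th percentile of
  juice consumers) have no finite fortification level. Single-cell calls
  raise `InfeasibleScenarioError`; the scenario grid flags the cell
  infeasible (level NaN) so one empty cell cannot fail a whole grid.
* **Clustering.** Monthly seasonal levels are collapsed into two blocks
  because changing a product's recipe every month is impractical. The
  summer block is the longest circular run of consecutive
  zero-requirement months (circular so a December–January run counts as
  one block; ties go to the earliest calendar start). The winter block's
  single level defaults to the **maximum** monthly requirement — the only
  aggregate that never undershoots the serum target in any winter month;
  under the default calibration that maximum is the January (trough)
  requirement. A mean aggregate is available (`aggregate="mean"`) for
  cost-oriented analyses that tolerate undershoot.
* **Precision.** All arithmetic is full double precision; rounding to one
  decimal happens only in display output. Engine results are
  property-tested against independent one-line arithmetic at 1e−12
  relative tolerance.

## Response and risk

The serum response L_n(m) = L_a(m) + c_f · F_i · level(m)/100 treats the
conversion factor as linear and season-independent. Published estimates
of c_f vary severalfold (values down to 0.5–1.5 nmol/L per μg have been
argued), so absolute serum predictions inherit that uncertainty; the
parameter is a single YAML field precisely so sensitivity re-runs are
trivial.

Risk envelopes evaluate a plan sized for the *mean* consumer on the
extremes: upper = 95th-percentile carrier consumption with
95th-percentile vitamin D intake; lower = 5th/5th. Safety flags are
per-month booleans for total intake strictly above the UL (100 μg/day)
and serum strictly above the intoxication region (500 nmol/L). Strict
inequality is deliberate: the UL is a limit, so sitting exactly on it
does not flag.

Intake multipliers (how many times more fortified-food vitamin D one
percentile receives than another) reduce to consumption ratios because
the fortification level cancels. A zero denominator yields NaN rather
than an exception. By default the quantities follow the scenario
selection rule; a `gender` argument computes single-gender ratios.

## Determinism and problem sizes

With the default (noise-free) configuration the whole pipeline is
deterministic: repeated runs write byte-identical CSVs, and the manifest
records the config checksum, package version and seed. The full scenario
grid is small by construction — 3 carriers × 3 × 3 percentile
combinations × 3 intake targets (81 constant cells) plus 2 serum targets
(54 seasonal cells × 12 months) — so every test and the acceptance script
run in seconds. Property suites use 100 derandomized draws per invariant
and a 1000-draw oracle-equivalence check.

## Known limitations

* Population averages only; no individual-level or distributional
  prediction (e.g. no probability that a random person exceeds the UL).
* The seasonal trajectory is synthetic and single-harmonic (see above).
* Two-cluster (summer/winter) plans only; finer seasonal staging is out
  of scope.
* Fortification is modeled per 100 g of food, not per 100 kcal; results
  are not directly comparable to energy-based fortification models.
* The upper risk envelope depends on the placeholder dietary-intake
  percentiles; its absolute intake numbers should be re-derived with
  survey percentiles before policy use.
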