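# fortiplan

Planning tool for vitamin D food fortification. Given the consumption
habits of a population for a carrier food (bread, milk, juice, or any
custom product), its current vitamin D intake, and a nutritional goal,
`fortiplan` computes how much cholecalciferol (μg per 100 g of carrier)
must be added — either as one constant year-round level, or as seasonally
varying levels that hold serum 25-hydroxyvitamin D (25(OH)D) flat across
the year — and then forward-models the resulting serum trajectories and
upper-intake-level risk for extreme consumers. It is aimed at nutritional
epidemiologists and risk managers evaluating fortification policy options.

## The model

Three scenario axes define each fortification intensity: the population's
current vitamin D intake percentile (5th / mean / 95th), the carrier
consumption percentile, and the target.

**Constant fortification** targets a daily-intake recommendation
*I<sub>r</sub>* (IOM 15 μg, DGE 20 μg, or the tolerable upper intake
level of 100 μg):

```
f_c = max(0, (I_r − I_a) · 100 / F_i)        [μg per 100 g]
```

where *I<sub>a</sub>* is current intake from food and supplements (μg/day)
and *F<sub>i</sub>* the daily carrier consumption (g/day).

**Seasonally varying fortification** targets a serum concentration
*L<sub>r</sub>* (50 or 75 nmol/L) month by month, given the baseline
monthly serum concentration *L<sub>a</sub>(m)* and a conversion factor
*c<sub>f</sub>* = 2.32 nmol/L serum rise per μg/day of fortified intake:

```
f_v(m) = max(0, (L_r − L_a(m)) · 100 / (c_f · F_i))
```

Months whose baseline already exceeds the target are floored to level 0;
the monthly levels are then clustered into a zero-level summer block and a
single-level winter block. The predicted serum response to any plan is

```
L_n(m) = L_a(m) + c_f · F_i · level(m) / 100
```

Because the monthly baseline values behind the German annual mean of
45 nmol/L are not published, the package generates them with a calibrated
single-harmonic cosine (trough 27.8 nmol/L in January); any external
12-month trajectory can be supplied as a CSV instead. See
`docs/methods.md` for assumptions, parameters, and limitations.

## Worked example

```
$ fortiplan plan --carrier bread --mode constant --target iom
bread constant fortification for target IOM (15 ug/day): 6.4 ug per 100 g
```

An average German bread consumer eats 180 g/day and takes in 3.4 μg
vitamin D (3.1 μg diet + 0.3 μg supplements); adding 6.4 μg per 100 g of
bread closes the gap to the IOM's 15 μg/day recommendation
(6.44 × 1.8 + 3.4 ≈ 15).

```
$ fortiplan plan --carrier milk --mode seasonal --target serum:50
milk seasonal fortification for target serum50 (50 nmol/L): winter level 4.3 ug per 100 g; zero-level months: [5, 6, 7, 8, 9]
```

For the 50 nmol/L serum goal, milk needs 4.3 μg per 100 g from October
through April and none at all May–September, when summer sun keeps the
baseline above target.

```
$ fortiplan simulate --carrier bread
 month  baseline_nmol_L  new_nmol_L  total_intake_ug  ul_flag  intox_flag
     1             27.8        75.0             23.7    False       False
     2             30.1        77.3             23.7    False       False
     ...
     7             62.2       109.4             23.7    False       False
```

Bread fortified at the January-sized winter level (11.3 μg per 100 g)
lifts the mean consumer to exactly 75 nmol/L in the January trough — at a
total intake of 23.7 μg/day, well below the 100 μg upper limit — and
overshoots benignly in milder months. `fortiplan risk --carrier juice`
shows the flip side: the 95th-percentile juice drinker (1.2 L/day) gets a
far larger dose than the plan intended, while the 5th percentile (0 g/day)
gets none.

`fortiplan run --outdir results/` writes the full scenario grid
(`plans.csv`), mean-consumer trajectories (`trajectories.csv`), risk
envelopes (`risk.csv`) and a provenance manifest.

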