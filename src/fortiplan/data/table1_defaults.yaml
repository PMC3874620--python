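# Default model inputs for the German population.
#
# Carrier consumption (g/day) comes from the National Nutritional Survey II
# percentiles; dietary vitamin D means and the 45 nmol/L annual serum mean
# come from the upstream bottom-up serum model.  Dietary p5/p95 are NOT
# survey values: they are configurable placeholders (half / double of the
# mean) used only for ordering-type risk analyses, never for the headline
# fortification arithmetic.
carriers:
  bread:
    p5: {men: 46.0, women: 43.0}
    mean: {men: 180.0, women: 134.0}
    p95: {men: 377.0, women: 270.0}
  milk:
    p5: {men: 16.0, women: 22.0}
    mean: {men: 222.0, women: 203.0}
    p95: {men: 712.0, women: 555.0}
  juice:
    p5: {men: 0.0, women: 0.0}
    mean: {men: 270.0, women: 232.0}
    p95: {men: 1200.0, women: 1000.0}
intake:
  dietary:
    p5: {men: 1.7, women: 1.4}      # placeholder, not a survey percentile
    mean: {men: 3.4, women: 2.8}
    p95: {men: 6.8, women: 5.6}     # placeholder, not a survey percentile
  supplement_mean: 0.3
targets:
  intake:
    IOM: 15.0
    DGE: 20.0
    UL: 100.0
  serum:
    serum50: 50.0
    serum75: 75.0
conversion_factor: 2.32             # nmol/L serum rise per 1 ug/day fortified intake
limits:
  ul_intake: 100.0                  # ug/day tolerable upper intake level (> 8 y)
  intoxication_serum: 500.0         # nmol/L
baseline:
  annual_mean: 45.0                 # nmol/L, population annual average
  amplitude: 17.2                   # nmol/L; calibrated so January = 27.8
  trough_month: 1
  region: germany
  region_offset: 0.0
  noise_sd: 0.0
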