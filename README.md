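# clotwave

Turbidimetric clot waveform analysis for plasma coagulation assays:
overall hemostasis / coagulation / fibrinolysis potentials (OHP / OCP /
OFP), the five fibrin-turbidity curve parameters, condition-level
reporting against a pooled-normal-plasma (PNP) normal range, fiber
thickness summaries, and a calibrated synthetic clot-kinetics generator.

## The problem

In the combined OHP / fibrin clot turbidity assay, clotting is triggered
in a microplate well (thrombin + CaCl₂ + phospholipid) and the 405-nm
absorbance is recorded every 12 s for 1 h. Each condition is run in two
arms: without t-PA (clot formation only) and with t-PA (formation plus
fibrinolysis). The raw record is reduced to:

- **Abs-sum AUC** — Σᵢ max(Aᵢ − baseline, 0), a plain summation over
  readings. Without t-PA this is the **OCP**; with t-PA the **OHP**; and
  **OFP = ((OCP − OHP)/OCP) × 100 %** is the fraction of clot potential
  removed by lysis.
- **Turbidity parameters** from the no-t-PA curve: lag time (onset of
  turbidity growth), max Abs (plateau median − lag-phase turbidity),
  clotting rate (least-squares slope of the growth phase, AU/min), time
  to plateau (TTP), and slope time (TTP − lag).

The intended user is a coagulation lab analyzing plate-reader kinetics —
in particular for the in vitro severe hemophilia-A model (FVIII-deficient
plasma) spiked with an emicizumab sequence-identical analogue (SIA) and
the bypassing agents aPCC and rFVIIa, where the question is whether an
agent combination pushes the readout from hypo- toward hypercoagulable.
Wells in which no aggregation occurs within the hour are **ND**
(nondetectable) — a value, not an error — and ND propagates to
condition-level rows by a replicate-majority rule.

Because no raw curves are publicly deposited for this assay, the package
ships a synthetic generator (`clotwave.simulate`) whose dose–response
layer is loosely calibrated to the published condition means, so every
stage of the pipeline is exercisable and testable against known ground
truth. See `docs/methods.md` for the model and its limits.

## Worked example

```sh
clotwave simulate --seed 42 --out-dir run       # 30 conditions × 2 arms × 3 replicates
clotwave analyze    --curves run/curves.csv --conditions run/conditions.csv --out run/params.csv
clotwave potentials --curves run/curves.csv --conditions run/conditions.csv --out run/potentials.csv
clotwave report     --params run/params.csv --potentials run/potentials.csv --out run/report.csv
```

The report's first rows (seed 42):

```
Condition,OCP (Abs-sum),OHP (Abs-sum),Lag time (min),Time to peak (min),Slope (AU/min),...,OFP (%)
Pooled normal plasma,42.9 ± 0.56,17.3 ± 0.44,10 ± 0,15.9 ± 0.12,0.031 ± 0.00045,...,59.6 ± 1.2
FVIII-deficient plasma,ND,ND,ND,ND,ND,...,ND
SIA (600 nM),40.7 ± 0.078,24 ± 0.074,13.1 ± 0.12,29.8 ± 0.4,0.0122 ± 0.00014,...,41 ± 0.21
...
aPCC (500 mU/mL) + SIA (600 nM),32 ± 0.14,9.25 ± 0.2,1.2 ± 0,2.6 ± 0,0.0778 ± 0.00049,...,71.1 ± 0.63
```

Reading this: PNP clots with a 10-min lag, reaches plateau at ~16 min at
0.03 AU/min, and t-PA removes ~60 % of its clot potential. FVIII-deficient
plasma alone never aggregates (ND). SIA 600 nM restores slow clotting
(lag 13 min, rate 0.012). The SIA + aPCC combination is strongly
synergistic — the lag collapses to ~1 min with a rate above the normal
range, the hypercoagulable pattern the assay is designed to flag.
(OCP/OHP magnitudes are in this package's Abs-sum units and are not
comparable across instruments; ratios and times are.)

The same operations are available as a library:

```python
from clotwave import simulate_curve, turbidity_params, ClotKinetics

kin = ClotKinetics(lag_s=600, rise_rate_au_per_min=0.03, max_rise_au=0.18)
tp = turbidity_params(simulate_curve(kin, (12.0, 3600.0), seed=0))
print(tp.lag_time_min, tp.time_to_plateau_min, tp.clotting_rate_au_per_min)
# 10.0 16.0 0.0307...
```

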