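# rheoprint

Interpretable machine-learning analysis of extrusion-printability in
hydrogel ink formulations, from bulk rheology to explained random-forest
decisions.

Hydrogel inks for extrusion bioprinting are routinely made printable by
rheology additives (microgels, nanoclays, self-assembling peptides), but
*which* bulk rheological properties actually render a formulation printable
is hard to read off individual case studies. `rheoprint` implements the
full computational chain for answering that question on a formulation
library:

1. **Printability scoring** — a two-layer mesh design whose fiber spacing
   grows in multiples of the nozzle diameter (D<sub>i</sub> = 410 µm);
   printed masks are scored per mesh window and combined into a
   difficulty-weighted index, score = Σ w<sub>c</sub> r<sub>c</sub> / Σ w<sub>c</sub>
   with w<sub>c</sub> = 1/multiplier; score > 0.33 ⇒ printable.
2. **Feature engineering** — 65 named features per formulation from a
   7-step rheological protocol (frequency sweep, amplitude sweep,
   three-interval recovery tests, stress ramp, steady flow curve with a
   Carreau–Yasuda fit η(γ̇) = η<sub>∞</sub> + (η₀−η<sub>∞</sub>)[1+(λγ̇)<sup>a</sup>]<sup>(n−1)/a</sup>),
   plus printing observations and ratio-to-base-polymer counterparts.
3. **All-relevant feature selection** — the Boruta shadow-feature test
   (binomial tail at α = 0.005) inside a class-imbalance-aware stability
   wrapper: repeated 75:25 not-printable:printable subsamples admitted only
   when a 200-tree random forest reaches a held-out printable-class
   F-score = TP/(TP + ½(FP+FN)) above 0.80.
4. **Evaluation and explanation** — n-repeated stratified k-fold CV
   (n = 20, k = 5) with per-class F-scores and out-of-bag scores; exact
   tree-path Shapley attributions accumulated across CV repeats (local
   accuracy |E(f(x)) + Σφ − p̂| ≤ 10⁻⁶); waterfall, dependence and partial-
   dependence views; split-rule threshold mining over every tree; Spearman
   correlation clustering of the selected features.

Because real formulation libraries of this kind are not publicly deposited,
the package includes a first-class synthetic-data generator
(`rheoprint.synthetic`) that emulates the study conditions: ~180
formulations driven by one latent network strength, 13 informative features
among 65, and ~14 % printable prevalence. Real data enter as tidy CSV curve
exports plus mask images in the same directory layout.

## Worked example

```python
import pandas as pd
from rheoprint import sample_cohort, build_feature_table
from rheoprint.grid import difficulty_weights, score_print
from rheoprint.features import KEY_FEATURES
from rheoprint.model import PrintabilityModel

cohort = sample_cohort(180, seed=21)
weights = difficulty_weights(cohort.design)
scores = pd.DataFrame([
    {"id": f.id,
     "score": (r := score_print(cohort.records[f.id].mask, cohort.design, weights)).score,
     "printable": r.printable}
    for f in cohort.formulations
])
table = build_feature_table(cohort, scores, seed=21)

model = PrintabilityModel(table[KEY_FEATURES + ["score", "printable"]])
res = model.fit(n_repeats=20, k=5, seed=0)
print(res.summary())
print(res.global_importance().head(5).round(4))
```

prints

```
Printability random-forest classifier
==============================================================
No. observations:                  180
No. features:                       13
Printable prevalence:            0.133
Trees:                             200
CV:                             20 x 5-fold
--------------------------------------------------------------
class              F mean      min      max       sd
printable           0.899    0.600    1.000    0.095
not_printable       0.985    0.935    1.000    0.014
--------------------------------------------------------------
Mean OoB score:                  0.974

yield_eta_peak     0.0777
cy_lambda          0.0298
amp_tand_14p8      0.0205
print_flow_prop    0.0204
amp_tand_100       0.0183
```

Reading this: 24 of 180 synthetic formulations (13.3 %) resolve more than
33 % of the weighted grid area. Under 20×5-fold CV the forest reaches a
mean printable-class F-score of 0.90 (the minority class is the hard one;
the majority class sits at 0.985) and a mean out-of-bag accuracy of 0.97.
The top of the Shapley importance ranking is the yield viscosity — the
viscosity at the stress-ramp maximum — followed by the Carreau–Yasuda time
constant λ and the damping factor at 14.8 % strain, matching the monotone
structure the generator plants (see `docs/methods.md`).

The same chain is available as a CLI over a run directory:

```bash
rheoprint run --seed 1 --out runs/demo          # simulate→score→extract→select→explain
rheoprint select --out runs/demo --n-iterations 500
rheoprint init-config my.toml                   # editable TOML configuration
```

Each stage writes plain CSV/JSON artifacts (`features.csv`,
`selection.json`, `cv_report.json`, `shap_values.csv`, `split_catalog.json`,
`clusters.json`, plot-ready beeswarm/waterfall/dependence/PD tables) plus a
consolidated `report.json`; identical seeds and configuration reproduce
every artifact byte for byte.

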