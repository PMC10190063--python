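# vadcea — cost-utility analysis of venous access devices

`vadcea` is a decision-analytic model comparing the three vascular-access
strategies used for long-term breast-cancer chemotherapy — central venous
catheters (**CVC**), peripherally inserted central catheters (**PICC**) and
implantable venous access ports (**IVAP**) — on expected cost (USD) and
quality-adjusted life years (QALYs), from the perspective of a medical
institution. It is aimed at health-economics analysts and methods
researchers who want a fully scripted, testable replica of this class of
three-arm decision-tree cost-utility analysis, including the data pipeline
usually hidden inside spreadsheet or TreeAge models.

## The model

Each arm is a single-shot decision tree whose branches split patients into
those with and without complications; the complication branch fans out over
the observed complication types with their constituent ratios (27 terminal
paths across the three arms). For a single-catheter arm (PICC, IVAP) with
insertion cost $c_{ins}$, per-visit maintenance cost $c_m$ billed every
$\Delta$ years, removal cost $c_{rem}$, complication probability $p$,
type mix $w_t$ with treatment costs $c_t$, utilities $u$ / $u_c$, and
median catheter survival $T$:

$$E[\text{cost}] = c_{ins} + \frac{\min(d, T)}{\Delta}\,c_m + c_{rem} + p\sum_t w_t c_t,
\qquad E[\text{QALY}] = \min(d, T)\,\bigl(p\,u_c + (1-p)\,u\bigr),$$

where $d$ is the dwell-time scenario (6 months, 12 months, or the full
course $d=T$). The CVC arm is a composite cycle of $\bar k$ short catheter
episodes separated by $\bar k - 1$ intermissions of length $\tau$ lived at
utility $u_\tau$:

$$E[\text{cost}] = \bar k\,(c_{ins}+c_m+c_{rem}) + p\sum_t w_t c_t,
\qquad E[\text{QALY}] = \bar k\,T\,(p\,u_c + (1-p)\,u) + (\bar k-1)\,\tau\,u_\tau .$$

Strategies are compared by cost-effectiveness ratios ($CER = C/E$),
pairwise incremental ratios ($ICER = \Delta C/\Delta E$, with dominance
flags when the increments disagree in sign), and net monetary benefit
($NMB = \lambda E - C$) at a willingness-to-pay threshold $\lambda$
(default $34{,}794.81 USD/QALY).

Around that core the package provides the full analysis pipeline:

* `vadcea.parameters` — typed parameter set, packaged base-case values,
  JSON/YAML config I/O, moment-matched sampling distributions;
* `vadcea.cohort` — synthetic patient-level cohort generator (confounded
  device assignment, Bernoulli/categorical complications, gamma costs,
  lognormal/Gompertz catheter survival, CVC reinsertion cycles);
* `vadcea.matching` — 1:2:2 nearest-neighbour caliper propensity matching
  with balance diagnostics;
* `vadcea.survival` — right-censored MLE for exponential / Weibull /
  lognormal / Gompertz families with AIC selection and a Kaplan–Meier
  cross-check;
* `vadcea.estimation` — cohort → parameter estimation and the Pearson
  χ² complication contrast;
* `vadcea.tree`, `vadcea.cea`, `vadcea.sensitivity` — the decision tree,
  the cost-effectiveness algebra, and one-way (tornado) plus probabilistic
  (CEAC, scatter) sensitivity analysis;
* `vadcea.model` — the `VenousAccessCUA` / `CUAResults` front end;
* `vadcea.cli` — a `vadcea` console pipeline (`simulate`, `match`,
  `fit-survival`, `estimate`, `evaluate`, `dsa`, `psa`, `replicate-paper`).

## Worked example

```python
from vadcea import VenousAccessCUA

results = VenousAccessCUA().fit(dwells=("6m", "12m", "full"))
print(results.summary())
```

```
Venous-access cost-utility analysis (decision tree)
========================================================
...
Dwell scenario: full
 arm     cost  qaly      cer       nmb  icer_vs_CVC  icer_vs_PICC
 CVC   542.36  0.24 2,226.72  7,932.63          NaN           NaN
PICC   827.82  0.36 2,275.74 11,829.13     2,375.08           NaN
IVAP 2,043.12  2.69   758.99 91,620.40       612.98        522.01

Willingness to pay: 34,794.81 USD/QALY
Recommended arm (max net monetary benefit): IVAP
```

Reading the full-course row: a CVC course costs \$542.36 for 0.24 QALYs, a
PICC \$827.82 for 0.36 QALYs, and an IVAP \$2,043.12 for 2.69 QALYs. The
IVAP has the lowest cost per QALY (758.99) and buying its extra
effectiveness costs \$612.98 per QALY versus CVC and \$522.01 versus PICC —
far below the willingness-to-pay threshold, so the port is the recommended
strategy at every dwell time.

Sensitivity analyses hang off the same results object:

```python
tornado = results.dsa(pair=("IVAP", "CVC"))     # one-way excursions
draws   = results.psa(n=1000, seed=0)           # probabilistic draws
```

and the synthetic pipeline closes the loop from patient-level data:

```bash
vadcea simulate --seed 1 --outdir out
vadcea match    --cohort out/cohort.csv --outdir out
vadcea estimate --cohort out/matched_cohort.csv --outdir out
vadcea evaluate --config out/estimated_parameters.json --outdir out
```

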