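# fpetki

Functional-PET quantification of **task-specific dopamine synthesis** with
6-[¹⁸F]FDOPA, for imaging scientists who want to separate task-induced from
baseline tracer trapping within a single bolus+infusion scan — together with
the behavioral modelling of the monetary incentive delay (MID) task that
such studies pair with the imaging.

6-[¹⁸F]FDOPA is decarboxylated by AADC and trapped; its net influx constant

    Ki = K₁·k₃ / (k₂ + k₃)        [1/min]

indexes dopamine synthesis capacity. Because synthesis enzymes are
upregulated by neuronal firing, a cognitive task transiently raises k₃, and
a within-scan general linear model can separate that extra uptake from the
baseline. The toolkit implements the full chain:

* **blood** — arterial input functions: linear plasma/whole-blood ratio fit,
  adaptation of a pure-bolus 3-OMFD metabolite fraction to a
  bolus+infusion protocol by bolus superposition, input-function assembly;
* **metabolite correction** — reference-region (occipital) one-tissue fit
  with task/motion nuisance terms, convolution-based 3-OMFD brain signal
  estimation, subtraction with an explicit 5% whole-blood component;
* **glm** — zero-phase low-pass filter (half-power at 2.5 min), per-block
  ramp-and-hold task regressors (1 kBq/frame slope), gray-matter-average
  baseline regressor, motion PC1, ordinary least squares;
* **patlak** — Gjedde–Patlak graphical analysis from t* = 25 min for the
  baseline, beta-conversion of block coefficients to task-specific Ki with
  a Patlak-difference cross-check, performance weighting, percent signal
  change Ki_task/Ki_baseline·100;
* **behavior** — block-centered reaction times, stepwise polynomial
  RT-versus-amount models, Bonferroni–Holm-corrected t-tests, exact
  small-sample Spearman correlations;
* **synthetic** — a first-class session generator (kinetics, blood,
  metabolite, motion, adaptive-staircase MID behavior) with recorded
  ground truth for parameter-recovery validation.

## Worked example

Simulate a session and quantify it:

```bash
fpetki simulate --out session/ --seed 7
fpetki quantify --session session/ --out results/
fpetki report --results results/
```

which prints:

```
fpetki 0.1.0 run 8da0baac8120f448
reference 1TC: K1=0.0600 mL/cm3/min, k2=0.0501/min, residual RMS=0.00922 kBq/mL
3-OMFD AUC reduction vs pure bolus: 57.3%
vstr: Ki_baseline=0.0090/min  Ki_gain=0.0140  Ki_loss=0.0091  PSC gain/loss = 156%/101%
```

The generator was configured with baseline Ki = 0.009/min and task-specific
influx of 0.014 (gain) and 0.009/min (loss); the pipeline recovers the
reference-region kinetics (truth K₁ = 0.06, k₂ = 0.05), the baseline and
both condition-specific values within ~1%. `results/results.tsv` holds the
per-block Ki values, performance weights and percent signal changes;
`qc.json` carries fit diagnostics (design condition number, residuals,
negative-value counts after metabolite subtraction).

The same from Python:

```python
from fpetki.studies import run_recovery_session
res = run_recovery_session(ki_baseline=0.009,
                           task_ki={"gain": 0.014, "loss": 0.009}, seed=7)
print(res.ki_baseline_recovered, res.ki_gain, res.ki_loss)
```

Behavioral modelling (stepwise selection on pooled mean-centered trial
data simulated from an inverted-U RT model):

```python
from fpetki.studies import behavior_recovery_study, WOMEN_RT_MODEL
fit = behavior_recovery_study(WOMEN_RT_MODEL, seed=3)
print(fit["terms"], fit["coef"])
# (1, 2) {1: -0.947, 2: -1.205}   # generative: -0.95, -1.16 (ms per EUR, EUR^2)
```

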