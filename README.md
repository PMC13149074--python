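# survpool

Pooled Bayesian parametric survival analysis from published Kaplan–Meier
curves.

## Who this is for

Evidence-synthesis and HTA analysts comparing many oncology regimens whose
trials report only Kaplan–Meier figures — no individual patient data (IPD).
The motivating setting is first-line systemic therapy for unresectable
hepatocellular carcinoma, where a dozen-plus randomized trials share
sorafenib as the common comparator, but the machinery is generic: any
network of right-censored trial arms connected by shared treatment labels.

## What it does

1. **Reconstruction.** Guyot's iterative algorithm inverts each digitized KM
   curve plus its number-at-risk table (optionally a published event total)
   into pseudo-IPD: integer event and censoring counts are allocated to the
   digitized drop points so the rebuilt product-limit curve tracks the
   published one and the implied at-risk counts match the printed ones.
2. **Modelling.** The pooled records enter one fixed-effect accelerated
   failure time (AFT) likelihood per parametric family — exponential,
   Weibull, gamma, log-logistic, log-normal. Treatment indicators shift the
   location on the log-time scale (positive effect = longer survival), with
   one shared ancillary parameter. For the log-normal,

   S(t | treatment) = 1 − Φ((ln t − μ₀ − δ_treatment) / σ),

   so the hazard ratio vs the reference is time-varying by construction —
   the non-proportional-hazards behaviour seen when survival curves of
   immunotherapy combinations cross their comparators'.
3. **Fitting and selection.** Posteriors are sampled with a seeded ensemble
   MCMC under effectively flat priors (3 chains × 4,000 iterations, 2,000
   warmup by default), convergence is summarized by split-R̂, and the family
   with the lowest deviance information criterion, DIC = mean D + p_D, is
   carried forward.
4. **Effects.** From the selected fit: time-dependent HR(t) curves vs the
   reference with 95% credible bands, survival curves extrapolated to a
   horizon (60 months by default), predicted survival at fixed time points
   (12/24/36/60 months), and treatment rankings by posterior-mean predicted
   survival.
5. **Synthetic networks.** A simulator generates multi-arm trials from known
   AFT parameters with uniform accrual and administrative censoring, then
   emits exactly the CSV inputs the pipeline reads — so the whole path is
   testable against ground truth.

## Worked example

```python
from pathlib import Path
from survpool.synth import uhcc_scenario, write_network_inputs
from survpool.pipeline import AnalysisConfig, run_pipeline
from survpool.fit import McmcConfig

work = Path("demo")
write_network_inputs(uhcc_scenario(n_scale=0.3), work / "inputs", seed=5)
config = AnalysisConfig(
    endpoints=("OS",),
    mcmc=McmcConfig(chains=3, iterations=600, warmup=300),
    seed=5,
)
bundle = run_pipeline(config, work / "inputs", work / "results")
res = bundle.endpoints["OS"]
print(res.selection.table.round(2).to_string(index=False))
rank36 = res.rankings[res.rankings.time_months == 36.0]
print(rank36[["rank", "treatment", "mean", "lo", "hi"]].round(3).to_string(index=False))
```

prints

```
endpoint      family     dic  p_d  selected
      OS exponential 5515.87 5.84     False
      OS     weibull 5384.22 6.70     False
      OS       gamma 5356.22 6.88     False
      OS loglogistic 5333.09 6.76     False
      OS   lognormal 5316.64 6.94      True

 rank                treatment  mean    lo    hi
    1  tremelimumab+durvalumab 0.222 0.167 0.282
    2 atezolizumab+bevacizumab 0.210 0.153 0.279
    3 camrelizumab+rivoceranib 0.196 0.133 0.266
    4               lenvatinib 0.171 0.130 0.222
    5                sorafenib 0.105 0.083 0.131
    6               durvalumab 0.105 0.074 0.143
```

The synthetic network was generated from log-normal ground truth, and the
DIC comparison recovers the log-normal as the best-fitting family (lowest
DIC, `selected = True`), with the exponential — the only
proportional-hazards family here — fitting worst. The ranking table reads:
at 36 months the tremelimumab+durvalumab arm has the highest posterior-mean
predicted OS probability (0.222, 95% CrI 0.167–0.282), and the reference
sorafenib sits near the bottom, consistent with the positive simulated
effects of the combination regimens. `work/results/OS/` also contains the
reconstructed `ipd.csv`, per-family fit JSONs and draws, `predictions.csv`,
`rankings.csv`, the HR and survival surfaces, and plots.

The same analysis is available from a shell:

```sh
survpool simulate --out demo/inputs --seed 5
survpool run --input demo/inputs --out demo/results --seed 5
survpool sensitivity --input demo/inputs --out demo/sens --seed 5
```

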