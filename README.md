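# protclock

Proteomic aging clocks and their genetic determinants.

Plasma proteomes drift with age, and a penalised regression on a protein
panel predicts chronological age well enough that the *residual* — how much
older or younger someone's proteome looks than their birth certificate —
behaves like a biological aging rate. `protclock` implements that analysis
end to end for biostatisticians and genetic epidemiologists:

1. **QC + imputation** — drop samples then proteins with >10% missingness,
   impute the rest to sex-specific means;
2. **clock** — elastic net (α = 0.5, 10-fold CV over a λ grid) predicting
   age from all retained proteins; *proteomic age acceleration* =
   predicted − chronological age;
3. **importance** — top-100 coefficient screen, then Monte-Carlo Shapley
   attribution to rank the top-20 proteins;
4. **association** — exact per-variant OLS scan of acceleration
   (MAF > 0.1%), greedy 1 Mb signal selection, joint-regression conditional
   secondaries (R² < 5%), per-signal pQTL scans at Bonferroni
   0.05/n_proteins, gene-burden tests with collapsed carrier coding;
5. **signal classification** — for each signal, retrain the clock *without*
   the signal's pQTL proteins and re-test: a signal that evaporates was
   driven by its own pQTL(s); one that survives acts broadly on the
   proteome;
6. **outcomes** — logistic/linear outcome models adjusted for age and age²,
   Cox mortality with Schoenfeld diagnostics, Kaplan–Meier curves for the
   oldest age-adjusted decile;
7. **MR** — two-sample IVW and MR-Egger on instrument-level summary
   statistics.

Individual-level biobank proteomics is not redistributable, so the package
ships a synthetic-cohort generator (`protclock.synthgen`) with planted
age-responsive proteins, a latent biological-age offset, cis/trans pQTLs,
MCAR missingness, survival and disease outcomes — every stage is validated
against this planted truth. See `docs/methods.md` for the models and their
assumptions.

## Worked example

The bundled demo simulates 3000 samples × 300 proteins with two planted
genome-wide signals — a cis-pQTL acting through a single heavily weighted
protein, and a widespread factor nudging 60 proteins weakly — and runs all
stages:

```bash
protclock run-all --seed 1 --outdir demo_run
```

or in Python:

```python
from protclock.pipeline import run_pipeline, default_config
run_pipeline(default_config(seed=1), "demo_run")
```

Artifacts from that exact run:

- `clock_metrics.json` — in-sample Pearson R 0.923, MAE 2.66 y;
  out-of-fold R 0.915, MAE 2.79 y. The clock tracks age to within a few
  years; the gap between the two tells you how much is optimism.
- `signals.tsv` — both planted variants surface as primary signals
  (var00010 β = 0.84 y/allele, p = 5.7e-19; var00002 β = 0.68 y/allele,
  p = 2.3e-13).
- `signal_classification.tsv`:

  | signal | pre p | post p | attenuation | verdict |
  |---|---|---|---|---|
  | var00010 | 5.7e-19 | 7.4e-17 | 0.94 | widespread |
  | var00002 | 2.3e-13 | 2.5e-2 | 0.31 | single_pqtl_only |

  Removing the cis target protein from the clock kills var00002's
  association (its whole effect flowed through one protein); var00010
  barely attenuates because no small exclusion set carries its effect.
- `cox_mortality.tsv` — each year of predicted proteomic age raises
  all-cause mortality hazard by ~8% (HR 1.079, 95% CI 1.054–1.106) after
  adjusting for age at recruitment and sex; the oldest age-adjusted decile
  separates on the KM plot (log-rank p = 1.3e-4).
- `mr_results.tsv` — with a planted causal slope 0.3 and directional
  pleiotropy 0.02, IVW is biased upward (0.52 ± 0.06) while Egger recovers
  the slope (0.29 ± 0.10) and flags the pleiotropy
  (intercept 0.031 ± 0.011) — the reason both estimators are reported.

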