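# gsdesign

Training-set design for genomic selection in inbred crop panels.

Breeding programs that adopt genomic selection must decide how large a
training set to phenotype, which germplasm it should span, and how many
markers to genotype. `gsdesign` implements the analysis machinery for
answering those questions on a single large field-trialled panel:

* a **one-step GBLUP mixed model** — phenotypes from a gridded,
  non-replicated trial with repeated checks are analysed jointly with
  genome-wide markers:

      y = Xτ + Zu + Z_g(a + p) + e,   a ~ N(0, σ²_a K),  p ~ N(0, σ²_p I),
      e ~ N(0, σ² R),  R = AR1(ρ_r) ⊗ AR1(ρ_c),  K = MM′/s,  s = tr(MM′)/n

  fitted by REML, with GBLUPs â = σ²_a K Z_g′ P y;
* **marker effects** by kinship back-solve q = M_t′K_t⁻¹â_t (or a direct
  reduced-rank fit when markers are fewer than training lines), and
  validation predictions â_v = M_v q;
* **structured cross-validation designs**: training-set-size series within
  folds, four K-means-cluster designs (all clusters / within cluster /
  between-narrow / between-broad), and breeding-cohort designs (one to
  three prior years predicting the next);
* **marker-density thinning**: equal-cM map bins keeping the highest-MAF
  marker per bin, with density-table summaries;
* a **synthetic breeding-program generator** (multi-pool populations,
  families, serial cohorts under truncation selection, AR1⊗AR1 trial
  errors) so the whole pipeline is testable without any data download.

Prediction accuracy throughout is the Pearson correlation between
validation predictions and the additive GBLUPs from the full-data model.

## Worked example

Simulate a small panel, fit the full model, and run a training-set-size
series from the shell:

```sh
gsdesign simulate --out fix --seed 7 --pops 3 --lines-per-pop 80 \
    --markers 400 --cohorts 1
# fixture written to fix (240 lines, 400 markers)

gsdesign fit --data fix --trait trait_quant --out fit
# loglik=-751.211 converged=True
```

`fit/variance_components.csv` then holds the REML estimates:

```
sigma2     53.12     # residual plot variance
sigma2_a  144.71     # additive genetic variance (trace-scaled kinship)
sigma2_p   18.11     # residual genetic variance
rho_r       0.62     # row-direction spatial autocorrelation
rho_c       0.44     # column-direction spatial autocorrelation
```

and `fit/gblups.csv` the per-line additive GBLUPs. A size series:

```sh
gsdesign size-series --data fix --trait trait_quant --seed 2 \
    --sizes 60,120 --out ss
# design       size
# size_series  60      0.531
#              120     0.669
#              189     0.815
```

Median accuracy rises from 0.53 with 60 training lines to 0.67 with 120
and 0.81 with the full ~190-line pool: the diminishing-returns curve that
sets the economics of training-set size. The same pattern, plus the
cluster, cohort and marker-density experiments, is available through
`gsdesign cluster-cv`, `cohort-cv`, `density` and `density-by-structure`,
or programmatically via `gsdesign.experiments`.

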