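# devswitch

Detection of developmental expression switches between receptor-subunit
gene variants in population brain-transcriptome data.

Synaptic receptors are assembled from subunits with multiple variants coded
by paralogous genes (NR2B→NR2A in NMDA receptors, GABA-A α3→α6, glycine
receptor α2→α3, serotonin 5-HT1A/5-HT5A, …). During development the brain
can switch which variant it uses, retuning synaptic kinetics and
plasticity. Given log2 expression matrices of postmortem brain samples with
donor ages (from 10 post-conception weeks to late adulthood), devswitch
finds candidate switch pairs and asks two separate questions about each:

1. **Do the life-long trends mirror each other?** Candidate pairs — genes
   sharing a pathway element whose proteins align at ≥ 30% identity
   (Needleman–Wunsch, BLOSUM62, gap cost 11 + L) — are screened per brain
   region for anti-correlated expression profiles, with a 1.5 log2
   expression-range filter and Benjamini–Hochberg FDR within each region
   (switch: q < 0.01 and ρ < 0).
2. **Do the two genes co-vary across subjects beyond age?** Each gene's
   population trend x̄(t) is fitted with a least-squares cubic spline on
   log2 age, using the smallest number of quantile knots whose mean squared
   error drops below a sliding-window noise estimate σ̂². The *age-corrected
   correlation* is the correlation of the residuals x_t − x̄(t) with
   y_t − ȳ(t) — a nonlinear analogue of the partial correlation of x and y
   given age, to which it reduces exactly when trends are linear. Fit
   quality is tracked by leave-one-sample-out
   R² = 1 − Σ(y_i − ŷ_i)²/Σ(y_i − ȳ)².

The package is aimed at computational neuroscientists and genomics analysts
working with developmental expression cohorts. It ships null models
(random-pair baselines, permutation bin-enrichment tests, housekeeping-gene
baselines, subject subsampling) and a synthetic-cohort generator with known
ground truth for every stage. See `docs/methods.md` for the full model
description and design decisions.

## Worked example

Simulate one switch pair — anti-correlated logistic trends crossing at
birth, plus a shared subject-level factor giving a planted residual
correlation of 0.5 — and analyze it:

```python
import devswitch as ds
from devswitch.datatypes import Sample, ExpressionProfile

ages = ds.sample_ages(100, seed=7)                 # PCD, all age groups covered
spec = ds.SwitchPairSpec()                          # planted residual corr 0.5
va, vb, _ = ds.simulate_switch_pair(spec, ages, seed=8)

def prof(v, g):
    return ExpressionProfile(g, v, [Sample(f"s{i}", f"s{i}", "CBC", a)
                                    for i, a in enumerate(ages)])

x, y = prof(va, "GRIN2B_like"), prof(vb, "GRIN2A_like")
res = ds.age_corrected_correlation(x, y)
m = ds.fit_trend_spline(x)
```

which prints:

```
raw correlation:      rho = -0.725  (p = 1.40e-17)
trend correlation:    rho = -0.942
residual correlation: rho = +0.411  (p = 2.21e-05)
trend fit: 2 knots, mse = 0.430, sigma2_hat = 0.529, relaxed = False
LOO R^2 = 0.807
```

The raw correlation is strongly negative — the two genes look like a
switch — yet after removing each gene's age trend the subjects' residuals
are significantly *positively* correlated, recovering the planted shared
regulation that the opposing trends masked. The trend model used 2 interior
knots, its in-sample MSE sits below the window noise estimate, and the
leave-one-out R² shows most expression variance is explained by age.

## Command line

The `devswitch` command exposes each stage and the full pipeline:

```sh
devswitch simulate --seed 7 --out-prefix sim/           # demo cohort + truth
devswitch candidates --fasta sim/sequences.fasta --elements sim/elements.tsv \
    --out sim/pairs.tsv
devswitch run --expr sim/expression.tsv --meta sim/metadata.tsv \
    --fasta sim/sequences.fasta --elements sim/elements.tsv --outdir sim/out
```

`run` writes `pairs.tsv`, `report.tsv` (per pair × region: trend ρ/q,
residual ρ/q, LOO R², filter and significance flags), `ranking.tsv`
(pairs ordered by mean −log10 q across regions, gray cells excluded) and a
`manifest.json` recording configuration and input checksums. Two runs with
the same inputs and seed produce byte-identical outputs.

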