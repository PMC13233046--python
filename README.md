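# crossmut

Cross-species analysis of mutagen-induced somatic mutation burden.

When primary fibroblasts from mammalian species are challenged with a
direct-acting point mutagen such as ENU (N-ethyl-N-nitrosourea), the number
of extra mutations a culture accumulates measures the *accuracy* of that
species' DNA repair — and the comparative-biology hypothesis is that
longer-lived species repair more accurately. `crossmut` implements the
computational side of such a study, starting from call-level somatic SNV
data (the output of an error-corrected single-molecule sequencing assay):

* **96-channel mutation spectra** — each SNV classified by its
  pyrimidine-strand substitution class and flanking bases,
  `A[C>T]G`-style, in canonical COSMIC order;
* **humanization** — cross-species spectrum normalization
  `n'_c = n_c · f_human(t_c) / f_species(t_c)`, where `f(t)` is the
  genome-wide frequency of the category's strand-collapsed trinucleotide
  `t_c`, making spectra comparable across genomes with different base
  composition;
* **excess mutation burden** —
  `ΔSNV = mean(treated SNV/Mb) − mean(control SNV/Mb)` per species, after a
  two-rule germline filter (matched variant set + cross-sample recurrence),
  with percentile-bootstrap confidence intervals;
* **comparative regressions** — OLS of excess burden on maximum lifespan
  (MLS), body mass, or longevity quotient (LQ), with leave-one-out
  sensitivity refits, Spearman rank correlation (exact permutation p for
  small n), paired t and Wilcoxon signed-rank tests;
* **de novo mutational signatures** — in-house NMF minimizing the
  generalized Kullback–Leibler divergence `D(M ‖ WH)` by multiplicative
  updates with seeded restarts, cosine matching against a reference
  catalog, per-group contribution fractions, and signature-vs-lifespan
  association;
* **a synthetic-data generator** — study-shaped cohorts (ten species with
  maximum lifespans from 3 to 211 years, paired control/treated samples,
  Poisson SNV counts drawn from ENU-like and clock-like signature mixtures,
  context-faithful placement on simulated genomes, shared germline
  variants) so the entire pipeline is testable without any sequencing data.

## Worked example

Run the default synthetic ten-species experiment end to end:

```bash
crossmut run --out demo_run --seed 1
```

which prints (abridged):

```
Per-species excess mutation frequency (per Mb):
  mouse            dSNV=0.900 [0.833, 0.993] (control 0.280, treated 1.180)
  ...
  whale            dSNV=0.213 [0.140, 0.287] (control 0.307, treated 0.520)

Regressions (excess frequency vs covariate):
  mls  : slope=-0.002159 R2=0.3843 p=0.000258 n=30
  mls   excluding whale: slope=-0.001102 R2=0.0429 p=0.3 n=27

Signature matches (top reference per extracted signature):
  S1 -> ENU_like_synthetic (cosine 0.978)

S1 contribution: mean 82.8% in treated groups; paired t vs control: t=25.427 p=1.08e-09
```

Reading this: the short-lived mouse gains 0.90 extra SNVs per megabase of
callable sequence under treatment while the long-lived whale gains only
0.21; regressing each treated sample's excess against lifespan gives a
negative slope (R² = 0.38, n = 30 samples), which weakens when the whale is
excluded — exactly the kind of influence a leave-one-out analysis is meant
to expose. The dominant extracted signature S1 is the mutagen's: it matches
the ENU-like reference at cosine 0.978 and contributes 83% of treated-group
mutations versus far less in controls. The run directory holds the full
tables (`delta_snv.tsv`, `regressions.tsv`, `signatures_W.tsv`, ...),
figures, and a `manifest.json` recording seeds and input checksums; re-runs
with the same config and seed are byte-identical.

Every stage is also a library call (`crossmut.delta_snv`,
`crossmut.humanize_counts`, `crossmut.nmf_extract`, ...) and a CLI
subcommand (`simulate`, `spectrum`, `humanize`, `burden`, `delta`,
`regress`, `signatures`).

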