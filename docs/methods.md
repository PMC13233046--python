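# Methods

## The analysis in one paragraph

Each species contributes paired fibroblast cultures: untreated controls and
cultures exposed to a low dose of the direct-acting point mutagen ENU. An
error-corrected sequencing assay yields, per sample, a set of somatic SNV
calls and a callable-base denominator. The pipeline removes inherited
variants, converts call counts to per-megabase frequencies, summarizes each
species by its excess mutation frequency ΔSNV (treated mean minus control
mean), relates ΔSNV to lifespan covariates by simple linear regression with
leave-one-out sensitivity checks, and — after humanizing each species'
96-channel spectrum to a common trinucleotide background — extracts de novo
mutational signatures by non-negative matrix factorization and matches them
to a reference catalog by cosine similarity.

## Conventions

Substitutions are expressed on the pyrimidine strand: a purine-reference
call is reverse-complemented (alleles complemented, flanks swapped and
complemented) before lookup, giving 6 substitution classes × 16 flank pairs
= 96 categories, ordered substitution-major with alphabetical flanks (the
COSMIC matrix order). Genome trinucleotide frequencies use the matching
convention: a width-3 window slides with step 1, windows containing
ambiguity codes are skipped, purine-centered windows are counted as their
reverse complement, yielding 32 strand-collapsed frequencies that sum to 1.

## Humanization

For category `c` with trinucleotide `t(c)`,
`n'_c = n_c · f_target(t(c)) / f_species(t(c))`. Ratios are per
trinucleotide (32), not per category (96): a trinucleotide's abundance is a
property of the genome, not of the mutation type, so the three substitution
classes sharing a trinucleotide share one ratio. Humanized counts are *not*
renormalized to preserve the sample total (a `preserve_total` switch
rescales for sensitivity analysis). A zero species-frequency under a
non-zero count is an error naming the trinucleotide, never a silent
pseudocount. The operation is linear and self-inverse (swap the frequency
pair), which the test suite verifies to 1e-9 on randomized inputs.
Humanization is applied to the spectra entering signature extraction;
burdens are compared on raw counts by default (`humanize_burdens` switches
this), since a per-Mb excess frequency is already denominator-normalized.

## Germline filtering

Two rules, both tallied per removal: (a) drop calls matching a supplied
germline variant set on (chrom, pos, ref, alt); (b) drop calls recurring at
the same (chrom, pos, alt) in ≥ 2 distinct samples of the species — somatic
mutations of independent cultures are private, inherited variants are
shared. The threshold is configurable; with a single sample and no side
file the recurrence rule is disabled with a logged warning. This is a
deliberately simple stand-in for the caller's full post-alignment
filtering, which operates on read-level evidence the pipeline never sees.

## Excess burden and its uncertainty

`freq = n_snv / callable_bases × 1e6` (per Mb; the scale is configurable).
`ΔSNV = mean(treated freqs) − mean(control freqs)` over a species' samples;
a `paired` mode averages per-pair differences instead. Uncertainty is a
95% percentile bootstrap (default 2000 resamples, within-condition,
seed-controlled); with ≤ 3 samples per arm the percentile interval is
clipped to contain the point estimate. The estimator is exactly unbiased
for the simulated rate difference; the acceptance suite confirms mean bias
within 3 standard errors of zero over 100 replicate cohorts.

## Comparative statistics

OLS via the closed form with a two-sided t(n−2) slope test. The default
regression response is per-treated-sample excess (sample frequency minus
the species' control mean, n = 30 points in the default cohort) rather than
per-species means (n = 10): with ten species a modest R² cannot reach the
small p-values per-sample analyses report, and the per-sample design
retains within-species variation; a `species_mean` mode is provided.
Body mass is regressed in raw grams by default with a `log10` switch.
Leave-one-out refits (default: human, whale, rat) are literal re-fits on
the retained subset. Spearman's rho uses midranks; its two-sided p is an
exact full-permutation enumeration for n ≤ 9 and the t approximation
above. Paired t and Wilcoxon signed-rank (exact null for ≤ 25 non-zero
differences) delegate to SciPy behind the module surface; degenerate
all-zero-difference inputs are explicit errors, and a constant non-zero
shift returns an infinite t with p = 0.

## Signature extraction

`M ≈ WH` with `M` the 96 × G humanized spectra matrix (G = species ×
condition groups, 20 by default), minimized under the generalized
Kullback–Leibler divergence by the classic multiplicative updates, which
are monotone non-increasing in the objective (recorded per iteration).
Defaults: 30 restarts with seeds derived deterministically from the stage
seed, 2000 max iterations, relative tolerance 1e-9, best final objective
wins; hitting the iteration cap flags `converged=False` rather than
raising. `W` columns are normalized to probability vectors with
compensating row scaling of `H`; signatures are named S1..Sk in descending
total-contribution order (no convention exists for this, so the package
fixes one). A Frobenius variant sits behind `method="frobenius"`.

Initialization is deliberately structured: `W` and a k-vector pattern come
from the restart seed alone, and each `H` column is that pattern scaled by
the corresponding data column's total. Because no initialization state is
tied to column *position*, permuting the data columns permutes the entire
update trajectory — extraction is exactly equivariant under group
reordering, which the suite tests. Plain i.i.d. random `H` inits lack this
property and also land on different points of the KL optimum's flat
manifold between runs (signatures that share a uniform floor can exchange
that floor mass without changing `WH`).

That flat-manifold point matters for interpretation: a planted-signature
recovery experiment is only meaningful when the planted set is
identifiable. The acceptance suite therefore plants three *peaked*
signatures (ENU-like T>A, CpG-deamination C>T, oxidative-like C>A) under
spiky Dirichlet group weights — the standard separability condition — and
recovers each at cosine ≥ 0.95 from 1e5-count groups. The generator's
default flat clock-like background is, by construction, not separable from
the floors of the other signatures, and no factorization method could pin
it; users fitting k signatures to real spectra should expect the same
ambiguity whenever one component is near-uniform.

Matching ranks catalog entries by cosine similarity (ties broken by name).
The bundled catalog is synthetic — the generator's own ENU-like, flat, and
CpG signatures — so the test suite needs no download; a real COSMIC-format
TSV (categories × named columns) plus an experimental ENU entry can be
supplied instead via `catalog_path`. The lifespan association correlates a
chosen signature's per-species contribution fraction (control-condition
groups by default, since treated fractions are dominated by the mutagen)
with MLS by Spearman, after excluding named outlier species (default:
human).

## The synthetic cohort

The generator emulates *call-level* output of single-molecule mutation
sequencing; it does not simulate reads, rolling-circle structure,
sequencing error, indels, or structural variants. Defaults define the
study conditions:

| parameter | default | note |
| --- | --- | --- |
| species | 10: mouse, hamster, rat (MLS 3 y) … human (120 y), whale (211 y) | MLS/body-mass typical literature maxima; LQ = MLS / (4.88·M_g^0.153) |
| samples | 3 control + 3 treated per species | |
| callable bases | 5·10⁷ per sample | desk-scale stand-in for the assay's interrogated fraction |
| genome | 10⁵ bp i.i.d. sequence, GC 0.42 | context source for placement and humanization |
| control rate | 0.3 SNV/Mb | culture background |
| treated rate | control + excess; excess declines log-linearly in MLS from 0.8 (3 y) to 0.35 (211 y) per Mb | the mutagen-sensitivity model |
| signature weights | control (0, 0.6, 0.4), treated (0.8, 0.12, 0.08) over (ENU-like, flat, CpG) | treated spectra are T>A-dominated |
| ENU-like signature | 0.75 mass uniform on the 16 T>A categories, rest uniform | synthetic shape, not a published signature |
| germline density | 1 per Mb of genome, shared by all samples of a species | gives the filter real work |

Mutation counts are Poisson(rate × callable/1e6); categories are
multinomial from the condition's mixture; positions are rejection-sampled
uniformly among genome positions whose strand-collapsed trinucleotide
matches the drawn category, so classifying any emitted record reproduces
its category exactly (within-sample collisions are redrawn; an unplaceable
category is an explicit error naming it). Everything derives from one seed
via `numpy.random.SeedSequence` spawning, so identical configurations
produce byte-identical cohort directories.

What passing tests on this cohort do *not* show: robustness to alignment
artifacts, reference-genome quality differences between species, clonal
structure in cultures, context-dependent mutagen kinetics beyond the fixed
signature mixture, or germline variants in linkage patterns more complex
than exact sharing. The generator's lifespan effect is *imposed*; recovery
demonstrates estimator correctness and power under the stated model, not
biological truth.

## Numerical choices and degenerate inputs

* Ambiguity-code windows and off-contig flanks are skipped and tallied,
  never imputed; a REF/genome mismatch is always a hard error.
* Empty call sets give all-zero spectra (not an error); all-zero spectra
  columns are rejected at NMF input.
* Per-stage seeds derive as `SeedSequence(global_seed, spawn_key=(i,))`
  with a fixed stage order (simulate=0, bootstrap=1, nmf=2), truncated
  below 2³¹, so stages re-run in isolation reproduce a full run.
* Problem sizes in the test and acceptance runs (100 kb genomes, 50 Mb
  callable, 100 cohort replicates, 20 NMF replicates) are the package's
  chosen desk-scale defaults; they keep every distributional check
  well-powered while the whole suite runs in well under a minute of
  simulation time.

## Known limitations

Single-nucleotide substitutions only; no transcriptional-strand spectra;
no signature refitting against fixed catalogs (matching is cosine-only);
no phylogenetic comparative methods (species are treated as independent
points); the recurrence-based germline rule assumes cultures from distinct
individuals, and will over-filter true somatic hotspots shared across
samples if that assumption fails.
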