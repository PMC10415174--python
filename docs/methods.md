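# Methods

This note records the statistical model behind each component, the
parameters that matter, and the design choices made where more than one
defensible convention exists.

## Data model and provenance

The central object is a `DataSet`: a samples × proteins matrix of
(log-scale) intensities, sample metadata aligned to it, and an
append-only log of preprocessing steps. Each step stores its complete
parameter set, seeds included, so `reset_preprocessing` followed by
`replay(log)` reproduces the current matrix bit-for-bit; the test suite
asserts this for randomized pipelines. Two semantics were open and are
fixed as follows: (1) the raw snapshot is re-based when samples are
subset, so *reset undoes preprocessing but not subsetting*; (2)
per-protein annotations and contaminant flags are kept on the full
original protein index and re-indexed at the point of use, so
protein-removing steps remain exactly replayable.

Intensity semantics: search engines write 0 for "not quantified", so
loaders keep zeros losslessly and `zero_to_missing` converts them
explicitly before `log2_transform` (which rejects nonpositive values
rather than silently offsetting them).

## Import dialects

Column conventions per engine are fixed in `io_import.DIALECTS`
(MaxQuant id = `Majority protein IDs` with `LFQ intensity ` preferred
over raw `Intensity `; DIA-NN id = `Protein.Group`, samples = run-path
basenames; FragPipe `<sample> MaxLFQ Intensity` preferred; Spectronaut
long format pivoted on `PG.ProteinGroups` × `R.FileName`; AlphaPept CSV;
mzTab PRT section via pyteomics). Duplicate protein rows and duplicate
(protein, sample) observations are hard errors — silent aggregation
hides upstream problems. Contaminants are flagged from marker columns
(`+` in `Potential contaminant`/`Reverse`/…), identifier prefixes
(`CON__`, `REV__`, FragPipe's `contam_`) applied to every `;`-separated
member accession, and optional user accession lists; flagging is
idempotent and monotone.

## Normalization

All three methods are per-sample scale/location operations on observed
values only; missing cells stay missing.

* `median_center`: shift each sample so its observed median equals the
  grand median of sample medians (preserves the intensity scale).
* `quantile`: each sample's observed values are replaced by reference
  order statistics (mean of sorted values across samples). With missing
  cells, the reference comes from complete samples when any exist, else
  from per-rank means over available values; a sample with fewer
  observations than the reference length interpolates at its rank
  quantiles; ties receive the mean of the reference values their ranks
  span. Complete samples therefore share an identical sorted value
  multiset (tested at 1e-9).
* `zscore`: observed mean 0, sd 1 per sample; requires ≥ 2 observed
  values and nonzero variance per sample.

## Imputation

Imputation is per protein (across samples) — proteins are the measured
entities — and never alters an observed cell.

* `mean` / `median`: per-protein statistic over observed samples.
* `knn` (default k = 3): a missing cell is filled with the mean of the k
  nearest samples *that observe the protein*; distances are Euclidean
  over mutually observed proteins scaled by the number of shared
  proteins (an RMS distance, so sparsity does not shrink distances);
  ties break by sample order; samples sharing no observed protein are
  excluded; a cell with no eligible donor falls back to the protein
  mean. The whole procedure is deterministic.
* `tree_iterative`: iterative chained imputation with extra-trees
  regressors (scikit-learn's `IterativeImputer`), proteins as features,
  missing cells initialized at per-protein means, features revisited in
  descending-missingness order until 10 rounds or relative change
  < 1e-3. Defaults: 100 trees, seeded. This is the missForest-style
  random-forest imputation widely reported to perform best on proteomics
  missingness.

## Differential expression

Missing values are handled by observed-only analysis gated by `min_obs`
(default 2 per group); skipped proteins carry status `skipped_low_n` and
undefined p. A protein with zero within-group scatter and unequal means
is also skipped rather than patched with an epsilon, because epsilon
choices silently reorder rankings. BH adjustment runs over tested
proteins only (m = number of defined p-values).

ANCOVA fits `y ~ intercept + group indicators + covariates` by least
squares per protein and reports the partial F-test against the
covariate-only model; rank-deficient observed designs are skipped. Note
that even a truly inert covariate changes the residual degrees of
freedom, so ANCOVA p-values equal ANOVA p-values only when the covariate
list is empty — the tests use an independent nested least-squares oracle
rather than that folklore equivalence.

## SAM

Two-class unpaired SAM with score `d_i = r_i / (s_i + s0)`, `r_i` the
group mean difference and `s_i` the pooled standard error. `s0` (auto
mode) is chosen among the 0,5,…,100th percentiles of `{s_i}`: proteins
are windowed by quantiles of `s` (up to 20 windows, ≥ 5 proteins each),
the MAD of `d` is computed per window, and the candidate minimizing the
coefficient of variation of those MADs wins — the classic criterion that
makes `d`'s spread independent of variance stratum.

The null comes from label permutations: exhaustive enumeration when the
number of distinct assignments is ≤ `n_perm` (identity included),
otherwise `n_perm` seeded uniform draws. Expected order statistics
`d̄₍ᵢ₎` are per-rank means over permutations. Calling scans outward from
the origin of the observed-vs-expected plot: the up-cut is the smallest
ordered score on the `d̄ ≥ 0` branch whose deviation reaches delta
(symmetrically for the down branch), and every score beyond a cut is
called. Branch restriction matters: on null data all `d ≈ 0` while the
`d̄` order statistics span both signs, and an unrestricted absolute
deviation rule would call everything.

FDR(delta) = π₀ · median over permutations of the number of permuted
scores outside the cuts, divided by the number of calls (clipped to
[0, 1]); π₀ = min(1, fraction of observed `d` inside the permutation
null's 25th–75th percentile band / 0.5). Per-protein permutation
p-values use the +1 correction, `p_i = (1 + #{|d_i^b| ≥ |d_i|})/(1+B)`,
so they are never exactly zero. On unimputed data a permuted split can
leave a group with no observation for a protein; such entries contribute
d = 0 (no evidence). In practice SAM runs after imputation and this path
is never exercised.

The exhaustive-permutation oracle in the tests re-implements all of the
above independently (plain Python loops) and is compared exactly on 3v3
and 4v4 designs.

## PCA and clustering

PCA mean-centers columns and uses a full SVD; signs are fixed by making
the largest-magnitude loading of each component positive, so results are
reproducible across runs. Clustering uses SciPy's agglomerative linkage
on euclidean or correlation distances; constant rows are rejected under
correlation (undefined), and duplicate items merge first at height 0.

## Visualization

Volcano classification: `up` iff log2 fold change ≥ cutoff and
−log10 p ≥ −log10 alpha (symmetrically `down`); the y-axis uses raw p by
default with BH-adjusted opt-in; p = 0 is clamped to the smallest
positive double and flagged. SVG output is fully deterministic (fixed
element order, fixed 4-decimal coordinate formatting, no timestamps), so
end-to-end runs are byte-comparable. Point labels are opt-in.

## Spike-in simulator

The generator emulates a two-group LFQ experiment on the log2 scale:
per-protein base abundances uniform on [20, 32] (a typical log2 LFQ
intensity span), a fixed `log2_effect` added to spiked proteins in the
second group, i.i.d. Gaussian noise per cell (default sd 0.3), then
missingness — MCAR dropout first (default 5%), then MNAR dropout where
cells whose *noise-free* underlying intensity lies below the 25%
quantile are removed with probability 0.6. Defaults describe a small
MNAR-heavy study: 480 background + 20 spiked proteins, 5 samples per
group, effect 1.0. Protein positions are shuffled so spiked proteins are
not positionally clustered.

What the simulator does **not** emulate: correlation between background
proteins (real proteomes are co-regulated), peptide-level effects,
batch structure, heavy-tailed noise. Benchmark results therefore show
how pipelines cope with intensity-dependent dropout and group structure,
not with biological covariance; the advantage of tree-ensemble
imputation here comes from its ability to exploit the mutual information
among the spiked proteins, which is a conservative stand-in for the
richer correlation structure of real data.

`evaluate_auc` is the rank-based AUC (ties count ½) of a chosen score —
−log10 raw p by default (threshold-free) — with skipped proteins ranked
below everything tested. `compare_pipelines` runs every
normalization × imputation combination on the *same* generated dataset
and sorts rows by descending AUC; row failures are isolated. For the
benchmark the tree imputer runs with 50 trees and 2 rounds
(`BENCH_TREE_PARAMS`): on the default design the first round reaches the
quality plateau (AUC identical to three decimals across 50/2, 100/2,
100/3 configurations), and the reduced setting keeps the 500-protein
benchmark to ~1–2 minutes.

## Problem sizes and numerical choices

* Null-calibration runs use 500 proteins, 6 samples per group, 500
  permutations; SAM ranking-power runs use 10 samples per group with a
  2-pooled-SD effect (a size at which a power calculation puts the
  expected shifted score ≈ 4.5 against a null extreme ≈ 3.3 over 480
  proteins).
* Tolerances: quantile/zscore postconditions 1e-9, PCA reconstruction
  1e-8, oracle equalities 1e-12 (exact arithmetic paths).
* TSV output uses shortest-round-trip float formatting and is read back
  with round-trip parsing, so serialization is bit-exact.
* All text I/O is UTF-8, decimal points only; no comma-decimal
  auto-detection.

## Known limitations

No peptide/PSM-level import or isotopic labeling channels; no
variance-stabilizing transform beyond log2; no batch correction or
outlier auto-exclusion; no paired or multi-class SAM; ORA requires a
user-supplied term→protein table (no bundled ontology, no web services);
figures are static SVG.
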