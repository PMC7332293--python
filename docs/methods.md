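# Methods

## The scoring model

A multi-bait AP-MS panel is treated as its own control experiment. The key
empirical fact the design exploits is that all purifications share a large
common background of non-specifically co-purifying proteins, while each
bait's genuine partners are enriched only in that bait's samples. The
pipeline therefore has three statistical stages:

1. **Background-proteome normalization.** The background is the set of
   proteins detected in at least a fraction *t* of all samples (default
   t = 0.9 — "commonly detected" without demanding presence in literally
   every run), minus the contaminant list. Sample scale factors are
   median-of-ratios over background members: each background protein's row
   reference is its median intensity across the samples where it was
   detected, and a sample's factor is the median of (raw / row reference)
   over background members detected in it. This estimator is insensitive to
   a minority of enriched proteins in any one sample and makes the results
   invariant (up to the O(1/n) movement of row-reference medians) to
   rescaling any sample. Fewer than 10 background members, or fewer than 3
   background observations in any sample, aborts with a diagnostic rather
   than normalizing unreliably.

2. **Per-bait enrichment.** Each bait's replicates are compared against the
   pooled samples of all other baits, protein by protein, on
   log2(normalized intensity + 1). The pooled panel is the control group:
   no separate mock IP is assumed. The defaults are

   * *pooled-variance two-sample t-test*. With only two technical
     duplicates per bait, the bait-side variance estimate has a single
     degree of freedom; Welch's statistic is then anticonservative (when
     the bait variance estimate collapses, the statistic explodes while
     the Satterthwaite degrees of freedom remain dominated by the control
     term — on simulated nulls the p < 0.05 rate reaches ~0.12). The
     pooled-variance test borrows the control group's ~40 degrees of
     freedom and is exact under the panel's homoscedastic null. Welch
     remains available (`method="welch"`) for heteroscedastic panels with
     more replicates; the statistic sits behind one interface so moderated
     variants can be added.
   * *pseudocount* ε = 1 intensity unit before log2, avoiding −∞ on
     near-zero cells without distorting high-intensity ratios.
   * *missing-value policy.* Bait-side missing cells are dropped: detection
     with the bait coupled to absence in controls is the very signal of
     interest. Control-side missing cells are imputed by seeded normal
     draws around the protein's own observed control mean, with spread
     equal to the median across proteins of the within-protein sd of log2
     intensity. Imputing instead from a global low-abundance point (the
     Perseus-style left-shifted draw, available as
     `imputation="low_abundance"`) inserts low outliers into mid-abundance
     control groups and inflates the pooled variance, making the test
     strongly conservative for partially observed proteins (simulated null
     rate 0.003 among imputed records). A protein never detected in any
     control sample is not imputed at all: it has no basis for a fold
     change and is flagged (`n_ctrl_obs = 0`, missing p) for the
     exclusivity path.
   * *no multiple-testing filter.* The interaction filter uses the raw
     p < 0.05 criterion; Benjamini–Hochberg q-values are computed per bait
     and reported as a courtesy column only.

3. **Spectral-index (SINQ) exclusivity rescue.** The spectral index of a
   protein in a sample is its summed peptide intensity (spectral counts can
   be substituted when intensities are absent), normalized by the sample
   total and by protein length in residues. By construction the detected
   score × length products sum to one per sample, so scores are comparable
   across samples and proportional to molar-like abundance per residue. A
   protein detected in exactly one bait's samples is called an exclusive
   interactor when its per-sample maximum score is ≥ 1 × 10⁻⁷, its spectral
   counts summed over the bait's replicates exceed 1, and it is not a
   contaminant. The count is summed across technical duplicates (the
   permissive reading; the scope is configurable).

**HCIP calling and merging.** The four-criterion filter (p < 0.05, strictly
positive log2 fold change, ≥ 2 unique peptides, not a contaminant) is
applied per (bait, protein) record; "unique peptides" means distinct peptide
sequences observed for the protein anywhere in that bait's samples, matching
the per-bait scope of the decision. Ties at log2FC = 0 fail. Bait
self-detection never becomes an edge; its summed intensity across its own
samples is kept as the bait's raw abundance. Merging is a union keyed on
(bait, prey) with enrichment provenance winning; exclusivity-derived records
pass by construction. Tightening any threshold can only shrink the call set.

**Network summaries.** Prey degree is binned 1/2/3/≥4; the abundance
correlation is Pearson's r between bait raw abundance and HCIP count
(undefined and reported missing under zero variance); secretory
classification is ER/membrane iff any of TMD, signal peptide,
N-glycosylation or disulphide annotation is present, with unannotated preys
labelled unknown and excluded from the fraction; prior-knowledge overlap is
exact unordered-pair membership in the supplied edge list. The heat map is
the bait × prey matrix of −log10 p (0 where missing, including
exclusivity-only calls), clustered on both axes with average linkage on
Euclidean distances — both choices exposed as configuration, since nothing
deeper constrains them — with deterministic leaf orders for fixed input.

## Input formats

* Quant table: TSV/CSV (delimiter auto-detected, gzip transparent) with
  columns `protein`, `peptide`, then `<sample_id>.intensity` and
  `<sample_id>.sc` per sample. Peptide rows are rolled up to protein level
  by summation; a cell with spectral count 0 is stored as missing, never 0.
* Sample sheet: TSV `sample_id`, `bait_id`, `replicate`.
* FASTA for lengths (UniProt `sp|ACC|NAME` headers unwrapped); contaminant
  list: one accession per line, `#` comments; prior edges: TSV `protein_a`,
  `protein_b` (undirected); annotations: TSV with `protein_acc`,
  `length_aa` and the four boolean feature flags.

Accessions are opaque, case-sensitive strings; protein-group ambiguity from
shared peptides is out of scope — each row's accession is authoritative.

## The synthetic generator

`apmspipe.simulate` emulates the statistical structure of the panel, not its
chemistry. Defaults describe the target study design: 21 baits × 2 technical
duplicates, 400 background proteins, 8 spiked interactors and 2 exclusive
preys per bait, 30 contaminants.

| parameter | default | meaning |
|---|---|---|
| `background_log2_mean_sd` | (20, 2) | base log2 intensity of background proteins (arbitrary units, ~10⁶ linear) |
| `log2_effect_range` | (2, 6) | uniform spike added in the cognate bait's samples |
| `noise_cv` | 0.25 | per-cell noise, sd = log2(1 + CV) ≈ 0.32 |
| `detection_midpoint`, `detection_slope` | 16, 1 | logistic P(detect) in log2 intensity — intensity-dependent missingness, so the imputation policy is actually exercised |
| `count_scale` | 2¹⁹ | spectral count = 1 + Poisson(I / κ); background median ≈ 3–4, keeping the ">1 spectral count" criterion non-vacuous |
| `peptide_count_scale` | 2²⁵ | distinct peptides per detected cell = 1 + Poisson(I / κ_pep); background cells are mostly one-peptide identifications |
| `min_two_peptides_prob` | 0.95 | probability that a spiked/exclusive prey's cognate cells carry ≥ 2 peptides |

Peptide pools are ordered by detectability: a cell supported by k peptides
carries the protein's top k, so the same flyer peptides recur across
replicates and a background protein's per-bait unique-peptide count stays
near 1. This makes the ≥2-unique-peptides criterion do real work — it is
what separates the stream of ordinary p < 0.05 fluctuations (≈ 2.5% of null
records after the positive-fold-change cut) from genuine preys, keeping the
empirical FDR of the merged calls near 5–10% without any multiple-testing
correction. Exclusive preys are generated only in cognate samples;
contaminants everywhere at high intensity; each bait's own protein only in
its own samples (the raw-abundance signal). The generator writes exactly the
file dialect the readers consume and returns the ground truth (roles,
cognate baits, true effects) for scoring.

What it does **not** model: retention-time alignment, peptide chemistry and
charge states, correlated (batch) noise, protein-group ambiguity, crosstalk
between baits sharing complexes, or abundance-dependent contaminant binding.
Passing recovery tests on this generator therefore demonstrates the
statistical machinery under idealized independence assumptions, not
performance on real chromatograms.

## Problem sizes and runtime

The default panel (42 samples, ~490 proteins, ~8900 records) runs the whole
pipeline in a few seconds on one core; the test suite and the acceptance
script each complete in well under a minute. These sizes were chosen to give
stable recovery statistics (binomial error on sensitivity over 168 true
pairs ≈ 1.5%) while keeping simulation-heavy tests fast.

## Numerical conventions and degenerate inputs

* Medians of even-length sets are midpoints of the two central order
  statistics throughout (numpy convention).
* Zero variance in both groups of a t-test resolves by the limit: equal
  means → p = 1, distinct means → p = 0.
* A bait with one replicate, or a panel with fewer than two other baits,
  raises rather than producing a variance-free test; a sample with no
  detected signal yields zero spectral-index scores with a warning;
  clustering with fewer than two baits or preys returns input order with a
  warning.
* All randomness flows from one integer seed; per-bait imputation streams
  are derived from (seed, bait-name hash) so results are independent of
  bait iteration order and stable across platforms.

## Known limitations

* The pooled-variance default assumes comparable within-protein variance
  between the bait and the pooled controls; panels with strong bait-specific
  variance should use `method="welch"` with more replicates.
* Technical duplicates are treated as independent replicates, so p-values
  describe technical, not biological, reproducibility.
* With ~8000 records at uncorrected α = 0.05, tens of false edges are
  expected by design; the reported q-values quantify this but deliberately
  do not gate the calls.
* The exclusivity path has no error model — it is a deterministic filter,
  and its false-positive behaviour is governed entirely by the contaminant
  list and the spectral-count threshold.
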