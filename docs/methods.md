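# Methods

This note documents the models and procedures implemented in `ppibench`,
the parameters that matter, and the design decisions taken where more than
one defensible choice existed.

## 1. The synthetic universe

The generator produces a proteome plus a ground-truth interactome with the
statistical structure that makes PPI benchmarking hard. All randomness
derives from a single seed; each stage (network, annotations, expression,
sequences) draws from its own deterministic substream, so stages can be
regenerated independently and identical config + seed gives bit-identical
universes.

### 1.1 Network

A Barabási–Albert preferential-attachment graph: each new protein attaches
to `n_edges_per_new_node` (default **m = 2**) existing proteins with
probability proportional to current degree. This is the canonical
scale-free generator and reproduces the few-hubs/many-lone-proteins
topology of curated interactomes. *Hubs* are defined throughout as the top
`ceil(0.20 · n)` proteins by positive-set degree, ties broken by
lexicographic id for determinism.

Default size is n = 2,000 proteins (~4,000 interactions). The density
default m = 2 is an instrument-calibration choice: annotation signal is
planted per interacting pair (§1.2), so hub term sets grow with degree and
dilute overlap similarity. At higher densities this dilution is strong
enough that even a maximal planted signal is only moderately detectable on
the hub-heavy T1 set, i.e. the generator could not span its intended range
from chance (no signal) to strong separation (strong signal). At m = 2 the
instrument spans AUROC ≈ 0.5 to ≈ 0.95.

### 1.2 Annotations

Five facets: biological process, cellular compartment, molecular function,
domain, motif; vocabularies of 400/80/250/300/200 terms. Real compartment
vocabularies are small, which is why that facet's vocabulary is the
smallest and its baseline overlap the noisiest. Generation order:

1. **Background terms** — each protein draws `base_terms_per_protein`
   (default 4) terms per facet without replacement; hubs draw
   `hub_annotation_inflation ×` as many (default 3×), emulating the
   annotation depth of well-studied proteins.
2. **Planted signal** — for each interacting pair and facet independently,
   with probability `fg_signal` (default 0.6) one vocabulary term is added
   to both proteins. Because planting is per pair, a degree-d hub
   accumulates up to d planted terms per facet: hub annotations are both
   inflated and less specific, which is exactly the mechanism that makes
   overlap-based features uninformative for hubs.
3. **Missingness** — per protein and facet, the whole facet is masked with
   probability `missing_rate_per_facet`. Defaults: 0.58 for domains, 0.89
   for motifs, 0 elsewhere, matching the coverage of curated human domain
   and motif annotation. Masking whole facets (not single terms) matches
   how real annotation databases fail — a protein simply has no entry.
   Masking runs last, so planted signal can be lost to missingness like any
   informative annotation.

### 1.3 Expression

Proteins belong to latent co-expression modules (default 12 modules, 20
conditions). Interacting pairs are co-assigned with probability 0.7
(propagated along edges in canonical order). A profile is its module mean
(standard-normal entries) plus i.i.d. Gaussian noise (`expr_noise_sd`,
default 0.5). With one condition, or constant profiles, the downstream
correlation feature is flagged missing rather than computed.

### 1.4 Sequences

Uniform-random sequences over the 20 canonical amino acids (length 80–300).
Interaction signal is planted as **lock–key motifs**: a fixed dictionary of
16 complementary length-6 peptide pairs ships with the package; each
universe activates a seeded random subset (`motif_active_count`, default
4). For each interacting pair, with probability `motif_signal` (default
0.5) an active entry's lock is spliced into one endpoint and its key into
the other (in-place substitution avoiding previously planted spans, so one
planted motif never destroys another). The per-universe active subset
emulates species-specific interface vocabularies: a sequence model trained
in one universe has learned motif combinations that mostly do not mediate
interaction in another, while annotation-overlap rules transfer unchanged.
This is the mechanism behind the cross-universe transfer contrast in the
test suite.

### 1.5 What the generator does not emulate

No GO term hierarchy or semantic similarity between distinct terms; no
biophysically meaningful sequences or structures; no assortativity control
beyond what preferential attachment induces; no study-bias correlation
between annotation depth and *evidence* (positives are complete and
error-free). Passing tests on this generator therefore validate the
*pipeline machinery and its statistical guarantees* — exact prevalences,
leakage control, sampler marginals, metric correctness, and the
direction of topology/overlap/transfer effects — not absolute performance
levels on real interactomes.

## 2. Gold standards

**Curation.** Evidence records are grouped by unordered pair; self-pairs
are dropped; a pair survives if *any* record's method class is outside the
excluded set (default `{colocalization, predicted}` — colocalization alone
does not demonstrate physical interaction, and predicted interactions would
be circular as training data). An empty result raises rather than returning
an empty gold standard.

**Negative sampling.** Negatives are random non-positive pairs (true
interactions are sparse, so the false-negative risk is low). Two endpoint
marginals: *uniform* (every protein equal mass) and *balanced* (mass
proportional to positive-set endpoint frequency; zero-degree proteins get
zero mass). Pair construction is a separate choice from the marginal:

- *independent* — endpoints drawn i.i.d. with rejection of self-pairs,
  positives and duplicates. Default for uniform, where per-pair uniformity
  is the point.
- *matched* (default for balanced) — endpoint quotas apportioned to the
  marginal by largest remainder, then stubs randomly matched
  configuration-model style with rewiring of conflicts.

The matched mechanism exists because the uniqueness constraint makes
independent sampling systematically under-represent high-mass endpoints as
popular pairs are used up, and because even without that bias the
multinomial noise of a 10,000-pair draw over hundreds of proteins exceeds
the marginal-matching guarantee balanced sampling is supposed to provide.
Quota matching realizes the target endpoint frequencies up to rounding
(total-variation distance ≈ 0.04 at 10,000 draws on a 500-protein
universe, chi-square goodness-of-fit p ≈ 1).

A caveat measured and worth knowing: endpoint-marginal matching does not
constrain the *joint* degree distribution of pairs. Preferential-attachment
positives are hub-attached beyond what independent pairing produces, so at
sparse density (m = 2) the balanced negatives' pair-level hub share sits
~0.06 below the positives' share; at interactome-like density (m = 3) the
residual is within 0.05.

**Infeasibility** is detected up front by counting candidate pairs in the
marginal's support; a request that cannot be satisfied raises immediately.

## 3. Splits

Inputs: a gold standard, a held-out protein set (default 10% of the
proteome, uniform), and size/prevalence targets. All `fraction × size`
computations use round-half-up, documented so realized counts are exactly
reproducible. Defaults: T1 2,000 pairs at 50% positive; T2 2,000 pairs at
1% positive.

Allocation order:

1. Pairs are provisionally stratified by held-out endpoint count (0/1/2).
2. **T1** draws positives and negatives separately to hit its prevalence
   exactly, filling overlap strata as evenly as the pools allow: targets
   are even thirds (remainder to `both-seen`), filled scarcest first
   (`none-seen`, then `one-seen`, then `both-seen`) with deficits cascading
   forward and then back. A stratum with an empty pool raises an error
   naming it, rather than silently rebalancing.
3. **T2** draws its positives from the remaining gold positives and its
   negatives *fresh* with the uniform scheme (balanced sampling is a
   training device; evaluation sets should represent the real pair
   population), excluding every gold pair.
4. **train** is every remaining pair with both endpoints outside the
   held-out set.
5. Gold pairs touching held-out proteins that T1/T2 did not absorb can be
   placed nowhere without defeating the hold-out; they are emitted with
   split label `unused` rather than dropped, so every input pair appears
   exactly once and the bookkeeping is auditable.

Overlap strata in the output are recomputed against the *realized* train
protein set (a protein all of whose pairs went to T1 is genuinely unseen in
training even if it was not held out). Topology strata come from the
degree table's hub flags. `check_assignment` re-derives every overlap label
from scratch and raises on any mismatch.

## 4. Features

Per-facet **Jaccard similarity** |A∩B|/|A∪B| with an explicit missing flag:
if either protein lacks the facet, similarity is imputed 0 and the flag set,
so linear models can learn missingness effects instead of conflating "no
overlap" with "no data". Jaccard is the default overlap measure; the
similarity is a strategy argument so alternatives (overlap coefficient,
included) can be plugged in. **Expression** similarity is Spearman rank
correlation (robust to monotone transforms), flagged missing for absent
profiles, fewer than 3 conditions, or constant vectors. **Sequence**
features (optional, off by default for FG models): k-mer count cosine
(k = 3), a shared-motif indicator, and per-dictionary-entry lock–key
co-occurrence indicators. All features are symmetric in the pair by
construction.

## 5. Models

Reference families behind one fit/score interface: logistic regression
(standardized inputs), Gaussian naive Bayes, random forest, gradient
boosting (XGBoost), and `kmer_logistic` — logistic regression restricted to
the sequence feature columns, the desk-scale stand-in for sequence models
so topology/overlap/transfer analyses run end to end. Scores are
probabilities; fits are seed-deterministic; logistic families expose
coefficients; training wall-time is recorded for the resource report.
Scoring matches columns by name (permutation-safe) and fails loudly,
naming missing columns. `agreement_rate` reports the fraction of pairs on
which two models make the same thresholded decision (threshold 0.5).

## 6. Evaluation

- AUROC via midranks (ties counted half). This is algebraically the
  trapezoidal area under the empirical ROC curve; both the brute-force
  concordant-pair count and the midrank formula compute the same
  half-integer statistic, so the test suite asserts exact equality.
- AUPRC as step-wise average precision, tied scores processed as a block.
  Chosen over trapezoidal PR interpolation, which is optimistically biased.
- DeLong's two-sided test for correlated ROC curves, from placement-value
  covariances. Degenerate cases: zero variance with equal AUROCs gives
  p = 1; zero variance with unequal AUROCs raises (the normal reference is
  not applicable). The implementation is checked against a stratified
  permutation oracle (model identity swapped per pair) in the test suite;
  at n = 20 the asymptotic and permutation p-values agree at the ±0.05
  level on average, which is the expected accuracy of the normal
  approximation at that size.
- Stratified reports never drop a stratum: single-class strata are marked
  not-evaluable with a reason.
- Carbon accounting: energy = hours × (cores × W/core × usage + GB × W/GB)
  × PUE / 1000, emissions = energy × intensity. Defaults (PUE 1.67,
  475 gCO2e/kWh, 12 W/core, 0.3725 W/GB) are calculator-style conventions,
  shipped as editable arguments, not measurements.

## 7. Reporting and reproducibility

`run_benchmark` fans one master seed into per-stage seeds via a fixed
`SeedSequence` derivation, executes simulate → curate → sample → split →
featurize → train → evaluate → report, and writes a SHA-256 manifest of
every artifact. Data artifacts (universe files, gold standard, splits,
feature tables, curve CSVs) are byte-reproducible under the same seed;
model files and sheets embed training wall-time — a required reporting
field — and are therefore excluded from byte-level determinism claims.
Sheets are idempotent given identical inputs. Any stage failure is
re-raised naming the stage.

## 8. Problem sizes used in the test suite

The suite exercises the pipeline at n = 2,000 proteins for design-parameter
and sampling checks, 500–800 proteins for repeated-universe mechanism
checks (10 seeds for the topology contrast, 5 universe pairs for the
transfer contrast), 1,000 Monte-Carlo replicates for DeLong type-I
calibration, and 10,000-swap permutation oracles at n = 20. These sizes
give the stated tolerances comfortable sampling margins while keeping the
default run desk-scale.

## 9. Known limitations

- Signal-recovery checks isolate the annotation channel by switching hub
  inflation off (inflation couples annotations to topology by design; the
  topology analyses switch it back on). Real data never grants such
  isolation.
- The balanced sampler guarantees endpoint marginals, not joint degree
  structure (§2).
- The DeLong implementation targets two models on one test set; comparing
  across test sets, or more than two models jointly, requires multiple
  comparisons handling the toolkit does not provide.
- The carbon model is a linear convention; it does not measure hardware.
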