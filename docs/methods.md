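# Methods

This note records the models, parameter choices and conventions behind
`lsp-suite`, and what the synthetic benchmarks do and do not demonstrate.

## The problem setting

Leaderless secretory proteins (LSPs) are secreted without the N-terminal
signal peptide (SP) that routes classical secretory proteins through the
ER–Golgi pathway. Because very few plant LSPs are experimentally
validated, no direct positive training set exists. The suite therefore
builds *putative* positives in two complementary ways:

* **LSPpred schemes** treat proteins repeatedly observed in secretome
  studies despite lacking any secretory feature — and supported by
  interaction/domain/term evidence linking them to classical secretory
  proteins — as putative LSPs.
* **SPLpred schemes** adopt the "common feature" hypothesis: train on
  classical secretory proteins with their SP computationally removed, so
  the model learns mature-chain properties shared with LSPs.

Both are hypotheses, not ground truth; everything downstream (FPR-bounded
thresholds, bias reports, high/low-confidence modes) exists to keep the
resulting predictions honest about that.

## Gene categories

Genes are classified from per-isoform annotations (SP presence and
cleavage position, TMD count, GPI flag, secretome observation):

* isoforms disagreeing on possession of SP/GPI → `SECRETORY_ISOFORM`
  (excluded — the gene cannot be confidently assigned);
* TMDs as the only secretory feature → `TM_ONLY` (excluded — membrane
  proteins are neither clean positives nor clean negatives);
* otherwise features × observation give `SEC`, `SPT`, `UNCLASSIFIED`,
  `NONSEC`. A gene is observed if any isoform is.

SP and GPI both count as classifying features because both commit a
protein to the classical pathway surface route. Cleavage positions are
1-based inclusive (residues `1..pos` are the SP).

## Evidence tiers

Each UNCLASSIFIED protein is scored per category (network, PFAM, GO) with
the points of its single highest qualifying tier, summed across
categories (maximum 9). This keeps the High boundary (≥ 5) reachable only
through strong evidence in at least two categories.

Conventions that were genuinely open and are fixed here:

* the network Tier-1 rule tests the *partner's* profile: a candidate
  qualifies when some SPT interaction partner itself has > 1 SEC and 0
  NONSEC partners. The published phrasing is ambiguous about whose
  profile is tested; this is the closest literal reading.
* "predominantly in SEC, possibly in SPT" (annotation Tier 1) is
  operationalised as: ≥ 50 % of the accession's carriers lie in
  SEC ∪ SPT and at least one carrier is SEC. The criteria are majority /
  exclusivity rules, not statistical enrichment, by design — the class
  sizes are too skewed for enrichment tests to behave.
* the NONSEC-partner cutoff (33) separating network Tiers 2/3 is a named
  constant; it is corpus-derived and should be retuned for other data.
* GO terms are compared as given — no ontology expansion.
* homodimer self-interactions are annotated at 0.5 points but never
  added: they mark a category of interest without affecting labels.
* candidates whose only evidence is a homodimer flag stay in Low (they
  are not removed from the database).

## Feature extraction

Sequences are validated to the 20-letter alphabet (non-canonical residues
dropped with a warning by default, or rejected by configuration) and
encoded by a versioned registry (~200 features; export with
`FeatureRegistry.export`). Families:

* length, molecular weight (average masses), isoelectric point, GRAVY;
* amino-acid composition (20) and per-residue Shannon entropy terms
  `-p log2 p` (20, plus the total) — single-residue entropies are kept
  separate because individual terms (glycine in particular) carry signal
  for LSP candidates;
* compressed-alphabet compositions and full CTD
  (composition/transition/distribution) encodings on six three-state
  property alphabets (hydrophobicity, polarity, polarizability, charge,
  solvent accessibility, secondary-structure propensity);
* sliding-window hydropathy summaries (windows 5/11/21; max/min/mean)
  and Moran autocorrelation of the hydropathy series at lags 1–4;
* terminal features: initiator-methionine indicator and mean hydropathy
  of the first/last 20 residues;
* PTM motifs: the N-glycosylation sequon N-X-[S/T], X ≠ P (overlapping
  occurrences all count).

Numerical conventions: hydropathy defaults to Kyte–Doolittle (GRAVY's
defining scale); pI is solved by root bisection of the
Henderson–Hasselbalch net charge with the EMBOSS pKa set (|charge| <
1e-4 at the root); entropy uses log2; zero-variance autocorrelation
returns 0; sequences shorter than a window use the whole-sequence mean;
lags beyond the sequence return 0. Every feature is finite for every
valid sequence of length ≥ 1.

Scaling is per-feature min–max to [0, 1], fitted on the training set and
applied unchanged to test/prediction data (no leakage). Constant columns
scale to 0.

This registry implements the named feature *families* of the ProFET
tradition with documented membership; it does not attempt to replicate
any external tool's exact 1170-feature output, and secondary-structure
features are propensity-alphabet CTD encodings, not predicted structures.

## Dataset assembly

All isoforms of each classified gene enter the pool; redundancy is then
reduced per class to ≤ 40 % pairwise identity by greedy longest-first
clustering (CD-HIT-style). Identity is matches over global-alignment
length (match 1, mismatch 0, gap open −1, extend −0.5); a shared-4-mer
screen (≥ 8 shared 4-mers) skips hopeless alignments on large inputs and
can be disabled for exact small-fixture behaviour. The 40 % default
balances independence of training examples against the small positive
pools.

Scheme definitions are in `lspsuite.datasets.SCHEMES`. Decisions where
the design was open: SPLpred4 duplicates positives only (negatives remain
single intact copies); SPLpred3 negatives are intact; the mean-SP prefix
length for SPLpred2 negatives is the half-up-rounded mean of observed SP
cleavage positions; redundancy reduction runs after gene→protein
expansion, per class. Low-confidence and unscored UNCLASSIFIED proteins
are never trained on — they are reserved as evaluation data. Manual
curation (e.g. removing ribosomal-complex artefacts) is supported only as
a user-supplied exclusion list. Every modified record keeps a retrievable
unmodified twin for bias analysis.

## Classifier and calibration

The classifier is a balanced random forest: each of 500 trees (default)
is fit on a bootstrap of `m` samples per class, where `m` is the
minority count, with sqrt-feature sampling and unlimited depth. Balanced
bootstraps address the heavy class imbalance (negatives dominate) without
reweighting tricks. One master seed fans out deterministically to the
split, fold assignment and per-tree bootstraps.

Training protocol per scheme: stratified 75/25 train/test split;
stratified 5-fold CV on the training part; per fold, the smallest score
threshold whose fold FPR ≤ 0.05 (equivalently, maximum TPR subject to
the bound; if no threshold qualifies, just above the top negative score);
the operating threshold and its TPR estimate are the means over folds.
Features are ranked by mean cross-fold Gini importance and the upper
quartile retained (ties at the 75th percentile all kept — an all-equal
vector retains everything). The ensemble is refit on the full training
part restricted to retained features, and the held-out test part is
reported as balanced accuracy — (TPR + TNR)/2, appropriate under
imbalance — at the calibrated threshold and at 0.5.

Bias estimation scores matched modified/unmodified pairs with a trained
bundle and reports the mean signed difference (modified − unmodified)
plus its distribution. The report is evidence for choosing among
schemes, not a thresholded decision: a model whose scores shift strongly
when only the modification changes has learned the modification, not the
biology. The suite's tests verify the directional phenomenon on
synthetic data: a model trained on prefix-removed positives shifts its
scores by an order of magnitude more than one trained on unmodified data
when both score the same modified/unmodified pairs (the missing
initiator methionine is the dominant artefact).

Prediction: high-confidence calls use the calibrated threshold
(equality counts as positive), low-confidence calls use 0.5. The
LSPpred/SPLpred consensus defaults to AND — conservative, consistent
with the FPR-control intent — with OR available.

## Synthetic data

`lspsuite.synth` emulates the inputs the pipeline assumes:

* background sequences: initiator Met + i.i.d. residues from Swiss-Prot
  average frequencies (shipped data file); lengths ~ N(300, 80) truncated
  at 50 — typical proteome-scale values;
* signal peptides: Met + n-region (2–5 residues, 60 % K/R) + h-region
  (7–15 from {A,I,L,F,V,M,W}) + c-region (3–7 ending A-X-A) — textbook
  SP architecture, giving SP regions measurably higher GRAVY than mature
  regions;
* LSP-like sequences: background with glycine up-weighted by +0.10
  before renormalisation (realised excess ≈ 0.09). Glycine is the
  default shifted residue because simple glycine composition/entropy
  features are exactly the kind of signal LSP candidates show; the
  benchmark's recovery of `comp_G`/`entropy_G` among top-ranked features
  checks that the importance machinery finds a planted compositional
  signal;
* SEC/SPT mature regions carry the same compositional shift by default
  (`sec_mature_shifted`): this encodes the common-feature hypothesis in
  the fixture, so SP-removal schemes have genuine signal to learn rather
  than only modification artefacts. Setting it false produces fixtures
  where any SPLpred-style accuracy *is* pure modification artefact — a
  useful negative control for the bias analysis;
* evidence tables wired so configured numbers of UNCLASSIFIED proteins
  satisfy each tier exactly, with ground truth emitted alongside.

What the fixtures do **not** emulate: real domain/motif structure,
homology families (i.i.d. sequences barely cluster at 40 % identity),
realistic PPI topology, GO hierarchy, annotation errors (observation
noise is available but defaults to 0). Passing benchmarks therefore
demonstrate that the machinery is correct and calibrated under its own
assumptions — not that comparable accuracy will hold on real proteomes,
where class overlap is far greater and published AUROCs (≈ 0.84–0.90)
and TPRs (≈ 35–62 % at 5 % FPR) are the realistic reference points.

## Benchmark problem sizes

The replicated calibration study uses 60 positives / 600 negatives per
replicate and 20 replicates — a 1:10 imbalance large enough to exercise
the balanced bootstrap and the per-fold threshold rule while keeping the
full study runnable in minutes on one CPU. The acceptance criterion is
that the mean held-out FPR at the calibrated threshold stays within two
Monte-Carlo standard errors of the 5 % design target; in practice it
lands well below (the per-fold rule is conservative: it picks the
threshold *at or below* the FPR budget in every fold before averaging).

## Known limitations

* The balanced random forest is implemented in-package (sklearn trees on
  balanced bootstraps); it follows the standard balanced-forest recipe
  but is not a drop-in for any external implementation's exact output.
* Greedy redundancy reduction depends on visit order (longest first, id
  tie-break); it guarantees no retained pair above threshold but not a
  minimum-size representative set.
* The k-mer prescreen can, in principle, miss a just-above-threshold
  pair with pathologically scattered matches; exact mode is available
  and used for all oracle comparisons.
* Tier scoring treats accession sets as flat; GO hierarchy expansion
  would change PFAM/GO tiers and is deliberately out of scope.
* The suite is designed for plant proteomes with secretome observation
  data; applying it to other kingdoms is out of its intended scope.
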