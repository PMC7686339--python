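# Methods

This note records the modelling choices in `kcrpred`: what is computed, the
assumptions behind it, the defaults and why, and what the synthetic-data
tests do and do not establish.

## Problem and data model

Lysine crotonylation is predicted from local sequence context alone. A
protein with annotated modified lysines is decomposed into 31-mer peptide
windows (15 residues of flank on each side of a lysine): windows centred on
annotated sites are positives, all other lysine-centred windows negatives.
Lysines with fewer than 15 residues on either side, or whose window contains
a nonstandard letter (B, J, O, U, X, Z), are dropped and counted rather than
padded — positions and windows therefore always live on the canonical
20-letter alphabet, and annotations are 1-based with window span
[p−15, p+15].

Assumptions this inherits: the modification signal is local (≤15 residues),
sequence-only (no structure), and stationary across proteins. Negative
labels are taken at face value; in real corpora unannotated lysines may
simply be unobserved, which deflates apparent performance uniformly.

## Redundancy reduction and splitting

Homologous proteins inflate cross-validation estimates, so proteins are
clustered greedily before window extraction: sequences are visited
longest-first, each joins the first retained representative with global
alignment identity ≥ 30% (identical columns / alignment length), otherwise
it becomes a representative. This is a deliberate simplification of CD-HIT
(no word-count pre-filter, no short-word heuristics); it reproduces CD-HIT's
greedy longest-first semantics, which is what matters for leakage, at
O(n²) alignments. Skip it (`--no-cluster`, the CLI default for synthetic
data, which is non-homologous by construction) when input is pre-clustered.

Train/test splitting is stratified at the window level (80/20 by default),
matching how per-site counts are usually reported; a protein-level split
option exists because window-level splitting can still leak homologous
windows when clustering is skipped. Training sets are balanced by random
undersampling of negatives (all positives kept). All randomness flows from
explicit seeds; the CLI derives stage seeds from one master seed via CRC32
of the stage name.

## Encoders

Residue order is alphabetic (`ACDEFGHIKLMNPQRSTVWY`) in every encoder.
Dimensionalities on a 31-mer: AAC 20, AAPC 400, BE 620, CKSAAP 1600 (gaps
k = 1..4), EAAC 540 (27 sliding 5-mers × 20), EGAAC 135 (27 × 5 groups),
PSSM 620, incorporated 3935.

Two normalization choices were genuinely open:

- **AAPC** — a dipeptide count divided by n(n−1) does not normalize
  adjacent-pair counts. The default counts the 30 adjacent ordered
  dipeptides and divides by n−1 (the conventional dipeptide composition);
  `mode="all_pairs"` counts every ordered position pair at any separation
  and divides by n(n−1). Both sum to 1; the mode is recorded in metadata.
- **CKSAAP** — each gap-k block is divided by its pair count n−k−1 so each
  block sums to 1 (common practice); raw counts are available with
  `normalize=False`.

EAAC/EGAAC use only the 27 complete 5-mers (no truncated terminal windows),
which is what yields the 540/135 dimensions. The EGAAC grouping is the
standard five physicochemical classes — aliphatic GAVLMI, aromatic FYW,
positively charged KRH, negatively charged DE, uncharged STCPNQ — and any
disjoint covering 5-group mapping can be substituted.

## PSSM features

The canonical PSSM feature is the window's 31×20 score matrix passed through
the logistic Φ(S) = 1/(1+exp(−S/w)) with w = 31, flattened position-major to
620 dimensions. (A 20×20 row-summed variant, where rows sharing the same
observed residue are added before squashing, is available via
`row_summed_feature` but is not the default: all downstream dimension
arithmetic uses 620.)

Scores come from either of:

- a PSI-BLAST ASCII profile (`-out_ascii_pssm`) of the parent protein — the
  first (log-odds) score block is read and columns reordered from PSI-BLAST's
  ARNDCQEGHILKMFPSTWYV to alphabetic; running PSI-BLAST itself is out of
  scope; or
- an **internal fallback** needing no external tool: a per-position log-odds
  table S(i,j) = log₂(p̂ᵢⱼ/q̂ⱼ) estimated from positive training windows with
  pseudo-count 1 (p̂ᵢⱼ = (cᵢⱼ+1)/(N+20)), against the equally smoothed overall
  residue frequency of the training corpus. A window's profile is the table
  masked by its observed residues — entry (i,j) is S(i,j) where the window
  carries residue j at position i, 0 elsewhere — so windows matching
  positionally enriched residues score high and the feature is
  window-specific. The source (`psiblast_file` / `internal_fallback`) is
  carried in metadata.

## Feature ranking

- **chi2**: continuous features are binarized at their global mean (median
  optional); the 2×2 table of binarized value × class gives the 1-df
  statistic N(ad−bc)²/((a+b)(c+d)(a+c)(b+d)) with no continuity correction,
  and p-values from the χ²₁ survival function. Binarization at the mean is a
  pragmatic default for frequency-valued features concentrated near 0.
- **gbm**: impurity importances of a seeded
  `GradientBoostingClassifier` (100 trees, depth 3 by default); the
  conventional subset keeps features above mean importance. LightGBM is the
  usual tool for this step; sklearn's gradient boosting is used here because
  it is a guaranteed dependency, and the mechanism (rank by split-gain-style
  importance, keep above average) is unchanged.
- **mrmd**: score = |Pearson r(feature, label)| + mean pairwise distance to
  the other feature columns, on min-max scaled columns (Euclidean default;
  cosine and Tanimoto available). Relevance and distance are summed
  unweighted; zero-variance columns get relevance 0.

Selection is top-k or (chi2) p < 0.05, with ties broken by original column
order. Per-dataset selected counts are emergent, never hard-coded.

## Classifiers and evaluation

SVM-RBF with C ∈ {2⁰..2¹⁰} × γ ∈ {2⁻¹⁰..2⁰} (121 points) and random forest
with trees ∈ {1400..2400 step 200}. Hyperparameters are chosen by internal
stratified 5-fold CV accuracy; ties keep the smaller C, then the larger γ,
or the smaller forest — fixed so reruns are bit-identical. Decision
thresholds: 0 on SVM decision values, 0.5 on forest probabilities.

Cross-validation is stratified 10-fold with a seeded shuffle; the headline
AUC pools out-of-fold scores (the mean of per-fold AUCs is also reported,
since the two can differ and conventions vary). ROC/AUC are by threshold
sweep with trapezoid integration, equal to concordance with ties at ½. MCC
is defined as 0 when a denominator factor vanishes. Cross-species transfer
trains on one dataset (undersampled) and scores the entirety of the other.

## Composition statistics

Position frequency matrices (31 × 20, rows summing to 1) and a cell-wise
positive-vs-negative comparison: Δ = freq_a − freq_b with a per-cell
two-sided test, Bonferroni-corrected across the 620 cells by default.

The per-cell test is **Fisher's exact test**, not the two-proportion z-test
one might reach for first. The reason is quantitative: the Bonferroni cut
0.05/620 ≈ 8×10⁻⁵ lies far in the tail of a skewed binomial at typical
residue frequencies (~1/20), where the pooled-z normal approximation is
anti-conservative by a factor of 2–4; exact binomial enumeration puts its
real family-wise error at 8–20% per dataset instead of the nominal ≤5%,
with or without continuity correction. Fisher's exact test restores the
guarantee (it is conservative under discreteness). The pooled z statistic is
still reported per cell for direction/effect size, and `method="z"` selects
the normal-approximation p-value for comparison.

## Synthetic data

The generator emulates the empirical signature of crotonylation corpora —
elevated K and E abundance in the flanks of modified sites — as a stated
world: proteins of length 50–400 drawn i.i.d. from a uniform background
(1/20 each), ~Poisson(1.5) positives per protein placed on lysines with full
flanks, and positive flank residues resampled from

    p′(r) = (1 − 2δ) p(r) + δ·1[r=K] + δ·1[r=E],   δ = 0.3 by default,

so each enriched residue's expected excess is δ(1 − 2p(r)). δ = 0 makes
positive and negative flanks identically distributed (null datasets).
`species_shift` moves the enrichment to L and S — a species with a different
substrate motif — for transfer experiments; `motif_mode` confines the tilt
to positions ±1, ±2 for testing position-aware encoders (BE/PSSM). Output
is byte-reproducible FASTA + TSV under a fixed seed.

One property of this construction deserves emphasis: tilting flanks toward
K necessarily *creates* lysines inside enriched regions, and those become
negative windows with partially enriched flanks. The corpus-level
positive-minus-negative flank frequency difference is therefore ~0.13 at
δ = 0.3, well below the clean-negative expectation of 0.27, and roughly half
of all negatives carry partial signal. This is not a defect — real corpora
behave the same way, since lysines near true sites share their context (and
may be unverified sites) — but it means measured AUCs understate what a
contamination-free benchmark would show.

What the generator does **not** emulate: realistic residue background
(uniform, not Robinson–Robinson), homology structure (proteins are
independent, so clustering is a no-op), protein-level composition biases,
and any positional motif beyond the optional `motif_mode`. A green test on
this world therefore establishes that the pipeline recovers diffuse
flank-composition signal and is calibrated under the null — not that any
particular real-data accuracy is reproduced.

## Numerical and degenerate-input choices

- Metrics on empty margins: Sn/Sp fall back to 0, MCC to 0 (flagged by the
  zero denominator); all-zero confusion tables are an error.
- Undersampling with negatives ≤ positives returns input unchanged with a
  warning; empty classes are errors.
- Grid search with a single-point grid skips the internal CV entirely.
- Rankings use stable sorts so ties preserve original column order;
  permuting columns changes only tie-breaks.
- The logistic PSSM squashing can collapse nearly equal scores to the same
  float; order is preserved in the weak (non-strict) sense.

## Known limitations

- The CD-HIT surrogate is O(n²) in protein count and lacks CD-HIT's word
  heuristics; for thousands of proteins, pre-cluster externally.
- `gbm` ranking on the full 3935-dim incorporated feature is the slowest
  selection path; chi2/MRMD are preferred there.
- The full SVM grid (121 points × 5 inner folds) inside 10-fold CV is
  expensive; use a reduced grid for exploratory runs.
- `predict` recomputes composition encoders only; models trained on PSSM
  features require the training-time profile and are not supported there.
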