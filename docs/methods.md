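# Methods

## Model

motifreg treats the enrichment score of a ChIP-Seq peak as a quantity to be
explained by the peak sequence's similarity to a library of candidate
binding motifs. With peaks *i* = 1…n and motifs *j* = 1…m, the model is a
sparse linear regression on motif-match features:

    log y_i = b + Σ_j w_j v_ij + ε_i,

minimized as  Σ_i (log y_i − b − w·v_i)² + λ‖w‖₁.

`y_i` is the caller-assigned peak score (natural log), `v_ij` the
normalized match feature of motif *j* in peak *i* (below), and the L1
penalty drives the coefficients of redundant or uninformative motifs to
exactly zero, so the surviving coefficients are directly interpretable:
positive ⇒ the motif strengthens binding signal, negative ⇒ it weakens it.

## Motif-match features

Each motif is a position probability matrix over ACGT with a background
composition. It is converted to base-2 log-odds with a pseudocount c:

    lom[p, a] = log2( (probs[p, a] + c) / (1 + 4c) / background[a] ).

For a peak sequence of width W and a motif of length L, the match score is
the maximum windowed sum of log-odds over all W − L + 1 offsets and, by
default, both strands (the reverse strand is scanned by scoring the
reverse-complemented matrix against the forward sequence, keeping offsets
in forward coordinates). The raw feature is

    raw_ij = best_match_ij − max_score_j,

where max_score_j is the score of the motif's consensus — the best any
sequence can do — so raw_ij ≤ 0 with equality exactly at a perfect
consensus match. Per peak, the raw vector is shifted by its minimum
(making entries nonnegative) and divided by its Euclidean norm. A row
whose shifted vector is identically zero (all motifs tie, possible only in
degenerate configurations such as a single motif) is an error, not a
silent zero. N bases contribute zero to every window score, so masked runs
neither match nor penalize.

Ties in the best match are broken toward the forward strand, then the
smallest offset. Scaling every log-odds matrix by a common positive
constant scales raw scores but leaves the normalized features invariant.

## Regression and cross-validation

Five fitters share one interface; all return per-motif coefficients in the
original motif space so rankings are comparable:

- **l1 (the default)** — lasso; the penalty weight λ applies to the
  unscaled objective above (internally mapped to scikit-learn's
  α = λ/2n). λ = 0 falls back to OLS.
- **ols** — minimum-norm least squares; warns when m ≥ n. On duplicated
  columns the minimum-norm solution splits weight evenly — the benign
  version of the sign-flip instability that makes unregularized
  coefficients hard to interpret.
- **ridge** — L2 penalty; shrinks but does not sparsify.
- **pls / pcr** — regression on latent components (default 10), with
  coefficients back-projected through the loadings.

Hyperparameters are selected by Monte-Carlo cross-validation: 30 random
train/test splits (test fraction 1/3), scoring the Pearson correlation
between predicted and observed log scores on each test set. The selected
λ maximizes the mean test correlation over iterations; the reported
coefficient vector is the average of the per-iteration fits at that λ.
Two summaries are emitted: the mean correlation at the selected value, and
the mean of each iteration's best value (which upper-bounds the former).
Splits with constant test targets are resampled; constant predictions
(e.g. a fully shrunk lasso) score correlation 0 with a warning.

The default λ grid is 25 log-spaced values in [1e−4, 1e2], spanning
near-OLS to full shrinkage. Features are used exactly as produced by the
per-peak normalization — no column standardization, which would silently
change the penalized solution.

Rankings divide coefficients by the largest absolute coefficient (top row
= ±1), sort by magnitude with id tie-breaks, and label signs
strengthening/weakening.

## Composite motifs

Motifs with normalized coefficient > τ (default 0.4, strengthening side)
are selected; each peak becomes a binary vector of their presence calls
(present ⇔ best match ≥ α·max_score, α default 0.8). K-means (Euclidean,
10 restarts, fixed seed) clusters these vectors; K defaults to the best
silhouette score over 2–10. Per cluster, motif tuples with joint presence
frequency ≥ a floor are reported as composite candidates. Binary vectors
cannot encode multiplicity, so homotypic composites (the same motif twice
in one peak) are detected separately by counting placements above the α
threshold in the match map.

## SNP depletion

Genomic base positions covered by matches of the selected motifs (score ≥
α·max_score, union over motifs and peaks, each base once) are intersected
with a SNP set. With N total peak-window positions, K of them
SNP-carrying, n motif-mapped positions and k SNP-carrying among those, the
depletion test is the lower hypergeometric tail P(X ≤ k), computed by
scipy stably at genomic scale. An upper-tail option covers enrichment. N
counts distinct bases across overlapping windows by default; a
length-with-multiplicity mode is available (`--count-mode`).

## Synthetic data generator

The generator emulates the pipeline's input universe with known ground
truth: one synthetic chromosome of consecutive 200-bp peak windows with
uniform background composition; a library of random sharp motifs;
instances of the "planted" motifs sampled from their probability matrices
and written into half the peaks each (plant probability 0.5, roughly a
primary motif's occurrence rate among its factor's peaks); peak scores
drawn from the model itself — log score = 3 + Σ_j w_j x_ij + N(0, σ) with
σ = 0.1, where x_ij are the pipeline's own normalized features recomputed
on the generated sequences; SNPs dropped per-base at rate 0.005,
optionally thinned inside planted footprints by a depletion factor.
Defaults: 500 peaks × 50 motifs (five planted, weights +3, +2, +1, −1,
−2), a desk-scale version of the thousands-of-peaks × ~800-motif regime
the method targets.

Per-position consensus probabilities are drawn uniformly in
consensus_prob ± 0.1 rather than fixed: motifs sharing one column profile
have log-odds matrices with identical entry values, so distinct motifs tie
exactly on best-match scores and whole feature rows collapse to a
constant — a degeneracy real discovered motifs, with their heterogeneous
information content, do not exhibit.

Because the latent score model operates on the same features the pipeline
computes, weight recovery is well-posed by construction. Passing recovery
tests therefore demonstrates correctness of the estimation machinery, not
performance on real ChIP-Seq: the generator has no read-level noise, no
mappability or nucleosome structure, no correlated motif co-occurrence
beyond chance, uniform background composition, and planted instances only
on the forward strand (the scanner looks at both regardless).

Identical specs (including seed) produce byte-identical output files.

## Numerical choices

- Log base 2 for PSSM scores (bits); pseudocount 0.01 (zero is allowed and
  yields −∞ for zero-probability letters, which can never win a scan
  unless every placement is impossible).
- Natural log for the regression target; the base only rescales
  coefficients uniformly.
- Window uniformization puts the odd leftover base on the right for both
  enlargement and trimming; windows crossing a chromosome boundary are
  shifted inward with a warning.
- Score-cluster remainders of fewer than half a group are merged into the
  previous cluster; score ties break by peak id.
- Lasso: coordinate descent at tol 1e−10, max 100k iterations; active-set
  counts use a 1e−10 magnitude floor.
- Ridge uses the SVD solver for determinism; PCR uses full SVD.
- CV seed default 17; every CLI output records the seed in its manifest.

## Problem sizes in the shipped checks

The test suite and the reproduction script run the generator at its
default 500 × 50 scale for recovery checks, 200-replicate × (200 peaks ×
200 bp) simulations for p-value calibration, and 1,000 peaks for the
depletion power run; the exact hypergeometric oracle is evaluated at the
full genomic-scale counts (N ≈ 3.3M). These sizes give stable statistics
while keeping the whole suite in the low minutes on one core.

## Known limitations

- Ungapped, mononucleotide PSSMs only; no higher-order background.
- Peaks arrive pre-called and pre-scored; no read processing or Q-value
  computation.
- Motif discovery is external: the package emits per-cluster FASTA inputs
  and consumes MEME-format motif files, but does not run a discovery tool.
- The composite report enumerates tuples within K-means clusters; it does
  not model spacing or orientation between motif occurrences.
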