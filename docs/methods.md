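# Methods

This note documents the models, conventions and numerical choices
behind `binppi`, in the order the pipeline applies them.

## Pair and network conventions

Protein pairs are unordered and canonicalized under case-sensitive
lexicographic order, so `(x, y)` and `(y, x)` are one object and every
table, partition and ranking is deterministic. Self-pairs are rejected;
self-loops encountered at load time are dropped and counted. Duplicate
detection records for the same pair merge: experiment counts sum,
source tags union, and the detection scale upgrades to `small_scale` if
any record claims it (rank: small_scale > high_throughput > unknown).
Missing evidence values are stored as missing (NaN) at the I/O layer —
the raw table is lossless — and are taken as 0 only at binning and
classification time, on the reading that absent evidence is
uninformative rather than unknown-but-present.

## Evidence channels

**FS-weight (simplified variant).** For neighbor sets N_x, N_y
(direct neighbors, the protein itself excluded),

    S(x,y) = [2|N_x∩N_y| / (|N_x−N_y| + 2|N_x∩N_y| + 1)]
           × [2|N_x∩N_y| / (|N_y−N_x| + 2|N_x∩N_y| + 1)].

When (x, y) is itself an edge, each endpoint sits in the other's
difference set; that is the literal reading of "direct neighbors" and
is flagged here because published FS-weight variants differ on it. The
score is symmetric, lies in [0, 1), and is 0 exactly when the pair has
no common neighbor.

**Expression correlation.** The absolute Pearson correlation of the
two expression profiles — strong anti-correlation counts as evidence,
matching the absolute value in the defining formula. A zero-variance
profile makes the coefficient undefined; such pairs score 0 (the
uninformative value) with a logged warning rather than erroring.

**Domain interactions.** The number of ordered domain combinations
(d_i from x, d_j from y) whose unordered pair is a known domain–domain
interaction. The DDI set is unordered (homodomain pairs permitted) but
counting is over ordered realizations, matching the set-builder
definition of the score.

**Ingested channels.** IRAP, PathRatio, BLAST bit-scores and
homologous-interaction counts are consumed as precomputed per-pair
columns (maximum kept on duplicates); their algorithms are defined in
their own publications and are out of scope here.

## Score binning

Training pairs (P ∪ N only — unknown pairs never enter a partition)
are sorted by raw score descending, ties broken by canonical pair.
Groups of μ = max(1, ⌈n·μ_rel⌉) pairs are cut greedily; each group
absorbs every pair tying its boundary score, so equal scores are never
split; a final group smaller than μ merges into its predecessor. Bin
confidence is the exact positive fraction of the bin, which gives the
conservation identity Σ_bins size·confidence = |P| and makes the
size-weighted mean confidence equal |P|/n exactly.

Lookup for arbitrary (including unseen) scores treats confidence as a
step function of score extended constantly beyond the training range:
scores above the global maximum take the first bin's confidence, below
the minimum the last bin's; a score falling in the gap between two
bins goes to the nearer boundary, exact midpoints to the higher-score
bin. Lookup is vectorized via the midpoint thresholds between
consecutive bins.

Sort direction is descending (bin 1 = best scores); the confidence
semantics are direction-invariant. The denominator of the confidence
counts training pairs only: unknown pairs falling in a bin's interval
receive its confidence but do not dilute it. μ_rel defaults to 0.01, a
good operating point for training sets of a few thousand pairs; the
sweep in
`evaluate.mu_sweep` exists precisely because both extremes hurt (few
samples per bin → noisy confidences; few bins → no resolution).

## Integration

**Noisy-OR.** 1 − Π_i (1 − p_i) over per-channel probabilities.
Monotone in every input, permutation-invariant, and saturates at 1 as
soon as any channel is certain — no clipping is applied, so an exact
1.0 bin confidence legitimately forces a 1.0 output. Bin confidences
are valid inputs by construction. Raw scores are not probabilities, so
raw mode requires an explicit map; the evaluation protocol supplies
the training-fold per-channel min-max normalization (clipped to
[0, 1]) as that map.

**Linear max-margin model.** A linear-kernel SVM with C = 1.0
(polynomial and Gaussian kernels perform comparably on this problem,
so only the linear model is exposed). Bin-confidence features are used
unscaled (already in [0, 1]); raw features are min-max scaled per
channel with training-time ranges. The learned weights and bias are
stored in the model JSON, so a reloaded model reproduces decision
values without sklearn state.

Rankings sort by decision value descending with canonical-pair
tie-breaks.

## Labels

Positives: detection scale `small_scale`, or ≥ 3 supporting
experiments, or a configured trusted-source tag (a stand-in for
curated high-quality subsets such as a core dataset, without shipping
those databases). Negatives: both proteins carry ≥ 1
cellular-component annotation and their CC best-match-average
similarity is < 0.4. A pair meeting both rules resolves to positive —
direct detection evidence trumps localization dissimilarity — with a
logged conflict. Everything else among detected edges is unknown, the
population the classifiers adjudicate. IEA-coded GO annotations are
included by default (exclusion is a configuration option; the
appropriate choice depends on the annotation corpus).

## GO semantic similarity

IC(t) = −log(fraction of annotated proteins reaching t), with
annotations propagated over is_a and part_of, so the namespace root
has IC 0. Term similarity defaults to Lin,
2·IC(MICA)/(IC(g1)+IC(g2)); normalized Resnik (IC(MICA)/max corpus
IC) is available, and the term measure is a plug-in because the
protein-level aggregation — the symmetric best-match average — is the
load-bearing definition here, not any particular term measure.
Identical terms score 1 by convention (for normalized Resnik this is
imposed rather than implied by the formula). Terms never reached by
the corpus have infinite IC; comparisons involving them fall back to
0. Validation similarity defaults to the biological-process namespace,
negative labeling to cellular-component; both are configurable.

## Evaluation protocol

Stratified k-fold CV (default k = 5, seeded shuffle). Bin partitions
are rebuilt inside each training fold; test-fold features come from
interval lookup only, so altering test-fold labels cannot change any
partition (the leakage guard in the test suite asserts bit-identical
partitions). Single channels are evaluated as one-feature classifiers
(decision value = raw score or bin confidence), making per-channel and
integrated AUCs directly comparable on identical folds. AUC uses the
rank-statistic convention (ties count half); the test suite checks it
against an exhaustive pairwise-comparison oracle.

False-negative candidates are the non-adjacent pairs with ≥ 2 common
neighbors, enumerated over 2-hop neighborhoods (not all pairs) and
returned in canonical order. Top-k validation curves average the GO
similarity of the top-ranked pairs, skipping (and counting) pairs
without a similarity value.

## Synthetic data

The generator plants ground truth at every stage. The true interactome
is Erdős–Rényi (default) or a simple duplication–divergence process;
the observed network keeps each true edge with probability 1 − fn_rate
and adds spurious non-edges so the expected false fraction of observed
edges is fp_rate. Each channel draws a raw score per observed pair
from Beta(a, b) conditional on true status and withholds a
1 − coverage fraction. Labels come from true status with an optional
flip rate. One pseudo-random stream per component is spawned from the
master seed, so adding a channel never perturbs the network draw.

The default benchmark — the conditions under which the package's
claims are tested — is: 1500 proteins, edge probability 0.0024
(≈ 2700 true edges), fn_rate 0.1, fp_rate 0.5, 1000 positive + 1000
negative noise-free labels, and four channels whose score shapes
deliberately differ wildly, as real evidence scores do (topological
common-neighbor scores pile up near 0 on sparse networks while
path-based reliability scores pile up near 1):

| channel       | true dist      | false dist     | coverage | engineered AUC |
|---------------|----------------|----------------|----------|----------------|
| topo_sparse   | Beta(1.0, 2.4) | Beta(0.6, 3.2) | 1.0      | ≈ 0.71         |
| topo_path     | Beta(6.0, 0.7) | Beta(2.6, 0.8) | 1.0      | ≈ 0.71         |
| genomic       | Beta(2.6, 2.0) | Beta(2.0, 2.6) | 0.8      | ≈ 0.67         |
| uninformative | Beta(6.0, 0.7) | Beta(6.0, 0.7) | 1.0      | 0.5            |

The uninformative channel shares the top-massed shape: fed raw into
the noisy-OR it injects large −log(1−p) noise and drags integration
down, while its bin confidences calibrate to a flat ≈ 0.5 that leaves
the ranking untouched — the mechanism by which calibration rescues the
Bayesian combiner. Because the conditional densities are closed-form,
P(true | score) is exact (`posterior_true_probability`), which is what
calibration studies compare empirical bin confidences against.

What the generator does **not** emulate: degree heterogeneity of real
interactomes (hubs, modules), correlated evidence channels, systematic
(non-uniform) detection bias, and identifier-mapping noise. Passing
tests therefore demonstrate the statistical machinery — calibration,
leakage-free evaluation, integration benefit under heterogeneous score
scales — not performance on any particular database snapshot.

## Problem sizes and determinism

Tests and the acceptance script run the benchmark at 1500 proteins
(≈ 5000 observed edges, 2000 training pairs) with 10 seeded
replicates for stochastic claims and 100 replicates × 2000 pairs for
calibration coverage — sizes at which the stochastic properties are
stable while the full suite stays fast. All randomness (network,
observation noise, channels, labeling, fold shuffles, SVM) is driven
by explicit seeds; identical seeds give bit-identical outputs.

## Known limitations

- Identifier harmonization across databases is assumed done upstream.
- The PSI-MI TAB reader consumes only interactor IDs and the detection
  method column.
- Raw-mode noisy-OR depends on the supplied raw→probability map;
  min-max is a pragmatic default, not a calibration.
- Bin confidences are empirical fractions; no smoothing or isotonic
  regression is applied (by design), so very small μ yields noisy,
  overfit-prone confidences — visible in the μ-sweep.
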