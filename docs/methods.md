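# Methods

`hpofactor` predicts missing protein–phenotype annotations by completing a
sparse binary annotation matrix with a graph-regularized non-negative
factorization. This note documents the model, the numerical choices, the
synthetic study conditions, and what the shipped experiments do and do not
show.

## The model

Let `Y ∈ {0,1}^{N_p×N_h}` be the protein × phenotype-term annotation matrix,
ancestor-closed under the ontology's is-a hierarchy (the true-path rule: an
annotation to a term implies annotations to all of its ancestors). The model
seeks non-negative factors `U` (`N_p×K`) and `V` (`N_h×K`) minimizing

```
J(U,V) = ‖W ⊙ (Y − U Vᵀ)‖²_F
       + λ (‖U‖²_F + ‖V‖²_F)
       + α Σ_k tr(Uᵀ L^{p_k} U)
       + β tr(Vᵀ L^h V)
```

with `W` a binary loss mask, `L^{p_k} = D − S^{p_k}` the unnormalized
Laplacians of `t` protein–protein networks (a single shared coefficient `α`,
uniform across networks), and `L^h` the Laplacian of a semantic-similarity
network over terms. Since `tr(XᵀLX) = ½ Σ_ij S_ij ‖X_i − X_j‖²`, the trace
terms pull network-adjacent proteins (terms) toward nearby latent positions.
Predicted scores are `Ŷ = U Vᵀ`; ranking cells by `Ŷ` ranks candidate
annotations.

### Mask semantics

Unannotated cells are exactly the prediction targets, so they cannot all be
masked out: if every `Y = 0` cell had `W = 0` the loss would see no negatives
and the trivial all-ones model would be optimal. `W` is therefore 1
everywhere — zeros act as observed weak negatives — except cells explicitly
held out for validation or testing, which get `W = 0`.

### Term-similarity network

For terms `s, t` with annotation probabilities `p(s) = count(s)/N_p`
(counts taken after ancestor closure, terms with zero annotated proteins
dropped), the information content is `I(s) = −ln p(s)` ≥ 0 and the
similarity is the Lin-style ratio

```
S^h_{s,t} = 2·I(mca(s,t)) / (I(s) + I(t))
```

where `mca` is the common ancestor with minimal `p` (reflexive: a term is
its own ancestor). The score lies in [0,1]; it is defined as 0 when
`I(s)+I(t) = 0` (both terms annotated to every protein — nothing shared
beyond the trivial root). Ties in the `mca` argmin are broken by
lexicographically smallest id; the score depends only on `I(mca)`, so the
tie-break never changes it. The diagonal of `S^h` is forced to 0 before
Laplacian construction (a graph Laplacian ignores self-loops). `S^h` is
computed dense over all retained-term pairs; a top-k-per-row sparsification
is available but off by default. Multi-rooted ontologies are unified under a
synthetic global root so that every term pair has a common ancestor.
Whenever annotations are split into training and test parts, `S^h` is
rebuilt from the training part only — building it from the full matrix leaks
held-out co-annotations.

### Optimization

`J` is biconvex; it is minimized by alternating multiplicative updates
derived from the KKT complementarity conditions, with each Laplacian split
as `L = L⁺ − L⁻`, `L± = (|L| ± L)/2` (for `L = D − S` this is `L⁺ = D`,
`L⁻ = S`):

```
V ← V ⊙ √( [(W⊙Y)ᵀU + β L^{h−}V] / [(W⊙UVᵀ)ᵀU + λV + β L^{h+}V] )
U ← U ⊙ √( [(W⊙Y)V + α Σ_k L^{p_k−}U] / [(W⊙UVᵀ)V + λU + α Σ_k L^{p_k+}U] )
```

Numerical choices:

- **Initialization.** `U, V ~ Uniform(0,1) · √(mean(Y)/K)`, seeded, so
  `UVᵀ` starts at the data's magnitude. Multiplicative updates keep exact
  zeros at zero, so a strictly positive start is essential.
- **Division guard.** ε = 1e-12 is added to update denominators;
  multiplicative ratios are undefined at exact zeros and ε preserves fixed
  points to reporting precision.
- **Convergence.** Relative objective change < `tol` (default 1e-5; the
  shipped experiments use 1e-6) or `max_iter` (default 500; experiments use
  300). The objective is recorded every iteration and is non-increasing
  (asserted in tests to 1e-9 relative slack); the KKT residual
  `max |min(X, ∂J/∂X)|` drops below 1e-4 on small instances run to tight
  tolerance.
- **Degenerate inputs.** Empty `Y`, all-zero masks, non-finite intermediate
  values, and coefficient/network mismatches (`α > 0` with no protein
  network, `β > 0` with no term network) are hard errors.

### Model variants

`NMF` (α = β = 0), `NMF-PPN` (β = 0, exactly one protein network),
`NMF-NHPO` (α = 0), `AiPA` (both regularizers, one protein network), and
`HPOAnnotator` (both regularizers, all provided protein networks) are
configuration presets over the same solver, validated by `variant_config`.

### Hyperparameters

| parameter | meaning | default | why |
|---|---|---|---|
| `K` | latent rank | experiment-specific | set to the planted rank in synthetic runs; on real corpora selected by grid search (typical range 100–200) |
| `λ` | ℓ2 shrinkage | 0.5 | mild overfitting control; results are flat over 0.1–1 |
| `α` | protein-network coefficient (shared across networks) | 0.5 | selected once by internal validation sweeps over the 2⁻⁷..2⁷ grid on synthetic scenarios; larger values over-smooth |
| `β` | term-network coefficient | 2⁻⁷ ≈ 0.008 | the dense `S^h` has large row sums, so small β already contributes; larger values over-smooth `V` |
| `tol`, `max_iter` | stopping | 1e-6 / 300 | objective change per iteration is far below metric resolution at this point |

`grid_search` implements selection by internal five-fold cross-validation on
the training positives, scored by annotation-centric AUPR on the validation
fold (AUPR is the most discriminative criterion under extreme sparsity).

## Evaluation protocol

Eight criteria: annotation-centric AUC/AUPR over all evaluable cells pooled;
per-protein averaged AUC/AUPR (reported as micro-AUC/AUPR); per-term
averaged AUC/AUPR (macro-AUC/AUPR); and the per-term averages restricted to
ontology leaves (leaf-AUC/AUPR). The micro/macro names are kept for
continuity with the reports this package mirrors, but note both are
macro-style averages (per-protein, per-term) rather than the pooled "micro"
of the ML literature. Entities with undefined curves (no positives or no
negatives among their evaluable cells) are skipped and counted, not averaged
as zero. A five-bin breakdown ([1–10], [11–30], [31–100], [101–300], [≥301]
training annotations per term) localizes performance by term rarity; bins
are computed from training-fold counts.

AUC is rank-based with average-rank tie handling (ties count ½); AUPR is
step-wise average precision without interpolation (both via scikit-learn).

**Cross-validation with descendant removal.** Known annotations are
partitioned into 5 random folds (optionally repeated). Because rows are
ancestor-closed, a held-out pair (p, h) is implied by any retained training
pair (p, d) with d a descendant of h; all such pairs are removed from
training. They are *excluded* from scoring as well — they are known
positives hidden from the model, so scoring them as negatives would be wrong
and scoring them as extra positives would double-count the hierarchy. The
removal is essential: in our synthetic conditions, with plain random-cell
holdout the closure shortcut lets an unregularized factorization reach
held-out AUPR ≈ 0.86 while the planted-signal oracle only reaches ≈ 0.04 —
the task degenerates into reading off the hierarchy.

**Independent release testing.** Train on all positives of an earlier
release; test positives are pairs added in a later release, restricted to
the earlier release's protein/term universe (the model has no row/column for
new entities; they are dropped and counted). Evaluable negatives are cells
zero in both releases.

## The bi-random-walk baseline

`Y_t = decay · P Y_{t−1} G + (1 − decay) · Y₀` with `P, G` the symmetrically
normalized (`D^{−1/2} S D^{−1/2}`, zero-degree rows left zero) protein and
term networks. With spectral norms of `P` and `G` at most 1 and decay < 1
the map is a contraction (successive Frobenius-norm differences shrink at
ratio ≤ decay), so the fixed point is unique; iteration stops at max-change
< 1e-8 or 1000 iterations. This is the fixed-point form of the bi-random
walk, not the truncated walk-length variant.

## Synthetic study conditions

The generator produces the structure the model assumes, at desk scale:

- **Ontology**: a random single-rooted DAG; each non-root term draws 1–3
  parents among earlier terms.
- **Annotations**: planted non-negative factors `U*, V*` with Exponential(1)
  entries (30% zeroed), cell probabilities logistic in the planted signal,
  `p_ij = σ(c·(U*V*ᵀ)_ij − b)` with offset `b = 6` so no-signal cells keep a
  small baseline probability (σ(c·m) alone is bounded below by ½ for m ≥ 0
  and cannot produce sparse matrices). The gain `c` is calibrated by
  bisection on the realized density *after* ancestor closure (the draw's
  uniforms are frozen, so realized density is monotone in `c`). Default
  scenario: 300 proteins × 200 terms, rank 10, density 0.05.
- **Protein networks**: edge weights track the cosine similarity of `U*`
  rows plus Gaussian noise (scenario default 0.05), thresholded to 5% edge
  density. Two networks are generated with independent noise — comparably
  informative sources — and each covers only a random 70% of the proteome,
  mirroring real network databases, each of which connects only a subset of
  the annotated proteins. Partial coverage is what makes combining networks
  genuinely useful: each network regularizes proteins the other misses.

What passing the synthetic experiments shows: the solver optimizes the
stated objective correctly, the protocol is leak-free, and the
regularizers contribute exactly when the networks carry information the
training annotations lack. What it does not show: performance on real
corpora, whose term-frequency distribution is heavy-tailed, whose zeros are
biased by curation order, and whose networks carry correlated (not
independent) noise. The generator makes no attempt to mimic term-frequency
power laws beyond the five-bin spread.

## Known limitations

- Dense `N_p × N_h` arithmetic throughout the solver; fine to a few thousand
  proteins/terms, not tuned for the 10⁵ scale.
- A single shared `α` across protein networks (per-network weights are
  exposed but default to uniform), matching the model formulation.
- Only is-a edges are honored in the ontology; part-of and other
  relationship types are ignored, and obsolete terms are dropped without
  remapping.
- The independent-test setting cannot score annotations of proteins or terms
  absent from the training release.
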