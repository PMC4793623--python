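# Methods

## Model and assumptions

The predictor operates on a heterogeneous weighted graph with drug and
protein-target nodes and three edge types: drug–drug chemical similarity,
target–target sequence similarity (both in (0, 1]), and known drug–target
interactions at weight 1. Its core assumption is *guilt by association
along short paths*: a drug and a protein are more likely to interact the
more simple paths connect them, because each path chains high-confidence
relations (similar drugs tend to share targets, and vice versa). The score

score(c, t) = Σ over simple paths p of (Π edge weights)^(α·len(p))

aggregates all simple paths of at most `max_len` edges. Since weights are
≤ 1 and α·len(p) > 0, each path contributes at most 1, and contributions
shrink exponentially with path length and with weak similarities. The
model is purely topological: it uses no chemical features beyond the
precomputed similarity matrices, and it cannot score a drug that is
disconnected from the rest of the graph (all its scores are 0).

## Parameters

| parameter    | default | meaning |
|--------------|---------|---------|
| `alpha`      | 2.26    | decay exponent; applied as α·len(p) to each path's weight product. Larger values concentrate the score on short, strong paths; below ~1.5 long path families can dominate. The default is the value that maximizes average benchmark accuracy in the original study of this scoring function. |
| `max_len`    | 3       | maximum path length in edges. Length 3 admits the informative drug→target→drug→target pattern while keeping enumeration cheap; the engines accept other values (DFS only for > 3). |
| `sim_cutoff` | 0.5     | similarity edges strictly below this value are dropped at graph construction; a similarity exactly at the cutoff is kept. Set 0 to retain every positive similarity. Whether the published benchmark numbers were produced with the cutoff active during scoring is ambiguous in the source description, so the benchmark tests try both settings and accept whichever reproduces the reference values. |

All similarity weights are used as-is; nothing in the model description
suggests re-normalization.

## Ranking and tie handling

For prediction output, targets are ranked by descending score with ties
broken by ascending target identifier — an arbitrary but reproducible
rule. For cross-validation *metrics*, tie handling is pessimistic: the
held-out target is placed after every tied non-removed competitor, so a
degenerate all-zero score vector can never count as a hit. In the per-drug
protocol, where a whole set of targets is held out, a tied position is
credited only when every competitor at that score is itself a removed
target (then any deterministic tie-break must put a removed target first).
Known targets are never excluded from the ranking: a held-out link must
outrank the drug's remaining known targets to count as top-1. The
alternative rank-after-removing-known-targets criterion is provided as a
separate evaluation mode.

## Cross-validation and ROC

Per-interaction LOOCV removes one known edge per round; per-drug LOOCV
removes all of a drug's edges, emulating a new drug without annotations;
k-fold CV removes seeded random folds of edges en bloc (`k = n` reproduces
LOOCV exactly, which is asserted in the suite). Rounds reuse one graph and
patch edges in place, restoring them afterwards; equality with full
rebuilds is tested. The ROC pools, across all rounds, the held-out link
scores as positives and the scores of the round's drug against its
non-interacting targets as negatives; the drug's other known targets are
neither. AUC uses the rank-based (trapezoidal/midrank) convention via
scikit-learn. A per-round-averaged AUC is available behind a switch
(`pooling="per-round"`); pooled is the default because the protocol is
described as varying a global score threshold.

## Engines and numerics

The DFS engine is the reference: recursive depth-limited search marking
nodes on entry and unmarking on return, so each simple path is enumerated
exactly once. The matrix engine exploits the fact that the exponent
depends only on path length: with A_L the adjacency matrix transformed
elementwise as w^(α·L), length-1 and length-2 contributions are A_1 and
A_2², and the length-3 contribution is A_3³ minus node-revisiting walks,
which for length 3 are exactly the walks whose middle node equals an
endpoint: S3 = A_3³ − A_3∘diag(A_3²)_cols − diag(A_3²)_rows∘A_3 + A_3∘³
(inclusion–exclusion for the doubly-degenerate back-and-forth walk). The
two engines agree entrywise within 1e-9 on random fixtures (asserted), and
differences observed in practice are at machine-epsilon level. The matrix
engine is O(n³) dense and restricted to `max_len ≤ 3`; `engine="auto"`
selects it whenever applicable. Scores are kept at full float64 precision;
report percentages are rounded to 2 decimals only at output.

## Synthetic data

The fixture generator emulates the one statistical property the model
relies on: similar drugs share targets. Drugs and targets are partitioned
into matched clusters; similarity entries are drawn at
`within_cluster_sim` (default 0.9) inside a cluster and
`between_cluster_sim` (default 0.1) across, with Gaussian noise (default
sd 0.05) symmetrized by averaging and clipped to [0, 1], unit diagonal;
interactions are planted only inside matched clusters at
`interaction_density` (default 0.5). Defaults describe a small
(12 drugs × 10 targets, 3 clusters) but structurally faithful instance;
the noise-free, density-1 variant is the exact-recovery condition under
which LOOCV top-1 is provably 100 % (every held-out link is restored by
unit-weight twin paths that strictly outscore intact known targets, and
cross-cluster scores are 0). What the generator does *not* emulate:
the heavy-tailed degree distributions, block-free similarity structure and
similarity score distributions of real SIMCOMP/Smith–Waterman matrices.
Passing on synthetic data therefore validates the algorithmic machinery
and its invariants, not real-data accuracy; the gold-standard benchmark
tests cover the latter when the public distribution files are supplied.

## Design choices made where the design was open

* The similarity cutoff is applied to the computational graph, not only to
  display, but is exposed as a parameter so both regimes are testable.
* The α-crossing test uses one length-2 path against *two* length-3 paths:
  for single paths against single paths the crossing condition is
  α-independent (the exponents scale together), so a multiplicity
  imbalance is the minimal construction with a genuine finite crossing,
  at α* = ln 2 / (2 ln a − 3 ln b).
* k-fold folds are an unstratified seeded shuffle of the interaction list.
* The brute-force path oracle (all node sequences, ≤ 20 nodes) and the DFS
  are compared as sets of node sequences, and the DFS is additionally
  cross-checked against networkx's independent simple-path enumerator.

## Problem sizes

The default test suite and the acceptance script run entirely on generated
fixtures of roughly 6–20 drugs and 5–16 targets (up to ~36 interactions,
100 random oracle graphs of ≤ 15 nodes), chosen so every check is exact or
well-resolved at desk scale; the complete run takes a few seconds. The
matrix engine handles the public benchmark sets (hundreds of drugs and
targets) in minutes.

## Known limitations

* Exact enumeration only; no sampling fallback for very dense graphs with
  `max_len > 3`.
* Dense adjacency in the matrix engine: memory grows as (n_drugs +
  n_targets)².
* Drugs (or targets) with no similarity edges cannot be scored after their
  interactions are removed — their predictions are all-zero ties, counted
  as misses by the pessimistic rule.
* The loader requires complete similarity matrices; missing entries are
  not representable and absent files are an error.
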