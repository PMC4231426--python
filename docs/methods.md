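# Methods

This note records the models, conventions and numerical choices behind
`pgtr`, including the places where the underlying method family leaves the
design open and what this package chose.

## Input model

The experimental design is a complete single-knockout compendium: a
wild-type expression vector `wt` (length n) and a knockout matrix `ko`
(n × n, row *i* = all genes measured after deleting gene *i*), both on an
arbitrary non-negative expression scale. Log₂-fold-change matrices can be
mapped onto this scale with `lfc_to_expression` (G = 2^L). Designs that
perturb only m < n genes are handled by `handle_partial_perturbation`:
full inference on the m × m sub-network plus PG-only candidate edges
toward unperturbed genes (no reduction is possible there — no paths exist
between unperturbed targets).

## Perturbation-graph statistics

* **Z-scores.** μ_j and σ_j pool all n+1 measurements of gene *j*
  (its n knockout values, including the self-knockout, plus the wild
  type). σ uses the sample convention (`ddof=1`, configurable); with
  n+1 observed values this matches common z-score practice on complete
  compendia. Thresholds are strict (`>`). A zero-variance column yields
  all-zero z-scores plus a `DegenerateDataWarning` rather than a failure:
  a flat gene is uninformative, not fatal.
* **Conditional correlation.** `c_ij` is the Pearson correlation of the
  columns *i* and *j* over the wild-type row and every knockout row except
  the one deleting *j* (`drop_j`, the default). The stricter
  `drop_i_and_j` rule (also discard the row deleting *i*) is offered as an
  option; the two differ only in one row of the n+1. Zero-variance pairs
  give c = 0 with a warning.
* **Z^c.** |C| is standardized per *target* column *j* over its n−1
  off-diagonal entries (sample sd), then one **global** offset makes the
  smallest off-diagonal entry exactly 1e−6. The offset magnitude is
  arbitrary as long as it is positive and common to all entries — only
  ratios and orderings of Z^c enter the downstream rules.
* **Ranking weights.** W^r is min–max normalized **globally** over all
  off-diagonal entries (per-gene normalization would break cross-gene
  comparability of the final ranking).
* **TR weights per PG flavour.** `pgnew` uses W^t = 1 − Z^c. For `pg1`
  and `pg2` the original methods never defined a TR weight (they were
  paired with unweighted reduction); this package extrapolates
  1 − minmax(|Z|) and 1 − |c| respectively so that every flavour can be
  combined with weighted reduction. Note W^t may be negative where Z^c
  exceeds 1; only order and ratios matter.

## Path search

Explaining paths must be simple, avoid the edge they explain, reproduce its
sign as the product of edge signs, and (in weighted mode) keep every edge
weight strictly below α·w_ij. Exact search is a pruned depth-first
enumeration of simple paths — exponential in the worst case, but it is only
needed for 2-paths (local TR) and for moderate graphs; neighbour lists are
sorted by gene identifier so the returned witness is deterministic
(lexicographically first). The approximate mode is a label-correcting
dynamic program over (node, accumulated-sign) states on walks of at most L
edges minimizing the bottleneck weight: polynomial, complete with respect
to simple paths (a simple path is a walk), but its witness may revisit
nodes, which occasionally lets a non-simple walk justify a removal the
exact mode would refuse. Unsigned edges count as positive in sign products.

## Transitive reduction

* **Bottleneck rule** (`transwesd`): strict `<` in `w_max(P) < α·w_ij`;
  defaults α = 0.95 for unbounded path length and α = 1.50 when the
  length cap is 2, mirroring the benchmark settings. `weighted=False`
  drops the bound (equivalent to α = ∞). Removal order: highest weight
  first, ties broken lexicographically by (source, target) gene id so runs
  are reproducible.
* **Full check.** With `full_check` on, an edge is only deleted if
  afterwards every edge of the original PG is still present or explainable
  in the remaining graph. Implementation detail: a witness path is cached
  for every removed edge and only the witnesses that used the deleted edge
  are recomputed — equivalent to re-checking everything, polynomially
  cheaper. Edges that fail the re-check are never removed (equivalent to
  remove-then-reinsert). With `full_check` off, all decisions are frozen
  against the original graph and the whole removable set falls.
* **Local rule** (`ltr`): an edge is a candidate if a feed-forward loop
  *i* → *k* → *j* exists, signs are consistent (s_ij = s_ik·s_kj), and
  `α·Zc_ij ≤ Zc_ik·Zc_kj` (non-strict; `Zc = 1 − W^t`; a large value
  here means high confidence). α = 0 or `weighted=False` drops the weight
  condition. Removal order is ascending Zc of the candidate (lowest
  confidence first). The re-check uses *well-founded recursive support*: a
  removed edge stays justified if some qualifying 2-path has each leg
  either present or itself a justified removed edge (least fixpoint, so
  circular justifications never count). The design rationale: an indirect
  effect explained by a 2-path through another explained indirect effect
  is ultimately grounded in a chain of direct edges, and without this
  chaining 2-path reduction could never fully strip the closure of a
  simple chain A→B→C→D — the regime in which local reduction is supposed
  to shine. This is the one place the package's semantics are deliberately
  more permissive than a literal "2-path in the remaining graph".
* **Cross-component rule** (`drffl`): candidates are judged on the
  original graph and removed simultaneously; on cyclic graphs this does
  not guarantee reachability preservation — a known weakness of the legacy
  scheme, preserved faithfully.

## Ranking and evaluation

Within a tier, pairs sort by W^r descending with lexicographic
tie-breaking; tiers are enforced by a +2 offset per tier on [0,1]-scores
(only order matters). AUPR sweeps the full ranking one pair at a time and
integrates precision over recall trapezoidally, anchored at
(0, precision@1); challenge evaluators that interpolate PR differently can
deviate in the third decimal. AUROC is computed as the Mann–Whitney
statistic of gold versus non-gold rank positions (exact, no tie correction
needed since the ranking is a strict total order). Silver-standard scoring
restricts counting to nodes common to predictions and reference. A
hypergeometric enrichment p-value for top-k overlap is provided
(`hypergeom_pvalue`).

## Synthetic benchmark

* **Topology.** Out-degree stubs are allocated by a capped discrete power
  law (exponent 2.5, cap n/10 with a small-n floor), targets drawn with
  geometric in-degree propensities, biased so ≈70% of edges stay within
  one of ⌈√n/2⌉ modules; self-loops and duplicates are rejected (error
  after 1000 rejection rounds). The stub allocation is exact, so the
  realized edge count equals round(n·K); a >10% deviation raises. Signs
  are activating with probability `activation_fraction` (default 0.5).
* **Kinetics (a documented stand-in).** The reference simulator's exact
  equations are not public in detail; this package uses a multiplicative
  Hill model chosen so that noise-free effects propagate with attenuation
  and correct signs: basal level b_j = θ^syn_j/θ^deg_j with
  θ ~ N(1, σ_θ) floored at 0.1 (drawn once per network realization),
  steady state x_j = b_j·∏_i r(x_i) over regulators with
  r = (1+aH)/(1+a/2) for activators and its reciprocal form for
  inhibitors, H = x^m/(x^m+1), defaults a = 1, m = 1 (so an unregulated
  wild type sits exactly at its basal level). Solved by damped fixed-point
  iteration (damping 0.5, tolerance 1e−9, at most 500 iterations;
  non-convergence raises naming the experiment). A knockout clamps the
  gene to exactly 0 (a configurable residual would model knockdowns; not
  exposed). Measurement noise multiplies every reported value by
  exp(ν), ν ~ N(0, σ_ν). The 3 × 3 noise grid crosses
  σ_θ, σ_ν ∈ {0.025, 0.05, 0.1} (labels LL…HH, first letter =
  biological level). Seeds split into independent topology / kinetics /
  noise substreams, so the nine noise configurations of one topology share
  wiring and differ only in noise scales.
  Because the kinetics are a stand-in, absolute benchmark scores of the
  original large-scale compendium are not reproducible — only qualitative
  behaviours (noise degradation, weighted-vs-unweighted, signed-vs-
  unsigned) are asserted, and at desk scale (100 genes, 10 seeds) rather
  than 5000 genes.
* **Closure oracle.** For acyclic signed digraphs, `transitive_closure`
  returns every ordered pair connected by a path together with all
  realized path signs; cyclic input is refused. The recovery study uses
  DAGs whose edge signs derive from node potentials (s_ij = σ_i·σ_j, so
  all paths between two nodes share one sign, and every feed-forward loop
  is positive) and which are transitively reduced before closure. Both
  properties are necessary: a true edge parallel to a same-sign path is
  indistinguishable from an induced closure edge, so no reduction method
  could recover a non-minimal graph from its closure.
* **What the generator does not emulate:** combinatorial regulation logic
  (effects multiply independently), measurement-platform artefacts,
  heteroscedastic or correlated noise, unperturbed residual expression in
  knockouts, and time-course dynamics. Passing tests therefore demonstrate
  correctness of the inference machinery under the stated noise model, not
  performance on any particular real platform.

## Defaults

| Parameter | Default | Meaning |
|-----------|---------|---------|
| β | 2.0 | z-score threshold (strict) |
| γ | 0.05 | correlation-magnitude threshold (strict) |
| α (transwesd, L=∞) | 0.95 | bottleneck confidence factor |
| α (transwesd, L=2) | 1.50 | local bottleneck factor |
| α (ltr) | 0.15 | multiplicative 2-path factor |
| k | 100 | top-k cut for TP@k |
| ε (Z^c offset) | 1e−6 | positivity floor of Z^c |

## Known limitations

* Exact sign-constrained path search is exponential in the worst case; on
  large cyclic graphs use `path_exact=False` (complete, but may justify a
  removal with a non-simple walk) and/or `full_check=False`.
* The DREAM-style "overall score" (geometric mean of p-values against the
  challenge's private null tables) is out of scope; AUPR/AUROC/TP@k are
  reported instead.
* Knockdown (partial-loss) experiments and time series are not modelled.
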