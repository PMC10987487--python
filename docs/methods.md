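# Methods

## Problem and model

A grown simple undirected network is observed as a final topology; each edge
carries an unknown arrival position α_i ∈ {1..E} (a bijection). Sometimes a
coarse history is available instead: snapshot labels such that edges within
one snapshot have indistinguishable order. The package restores the full
sequence α̂ from the topology plus a small sample of edge pairs with known
relative age, under two standing assumptions: edges persist once created (no
deletion dynamics), and the pairs available for training are an unbiased
sample of the distinguishable pairs.

The pipeline is: per-edge vector views → pairwise age comparators → ensemble
→ Borda aggregation → restored sequence, with a closed-form error theory, a
cross-network transfer mechanism, and downstream growth/link-prediction
analyses.

## Edge views

Views 1–5 are Hadamard products of endpoint node embeddings, so every view
is symmetric in endpoint order. The five embedding estimators are
implemented in-package (dense linear algebra; intended scale is up to a few
thousand nodes):

* **n2v** — 10 sampled uniform random walks of length 40 per node, window 5;
  the symmetric co-occurrence count matrix is log-compressed (`log1p`) and
  factorised by truncated SVD. Counts rather than PMI are factorised
  deliberately: walk visitation scales with degree, and that popularity
  signal — which PMI normalisation removes — is the component of the
  geometry that survives cross-network alignment.
* **dw** — the closed-form (NetMF) factorisation of the expected walk
  co-occurrence under the skip-gram objective, window 5, no sampling.
* **line** — half the dimensions from an SVD of the adjacency (first-order
  proximity), half from the log-compressed one-step transition matrix
  (second-order proximity).
* **sdne** — a one-hidden-layer autoencoder on adjacency rows (tanh
  bottleneck = embedding), non-zero entries over-weighted ×5, Adam, 30
  epochs.
* **s2v** — structural-role features per node (log degree, log coreness,
  clustering, one- and two-hop neighbour-degree statistics, log-binned
  neighbour-degree histogram), standardised and rotated to principal axes.
  These coordinates are comparable across networks by construction.

Default dimension 64; SVD signs are fixed deterministically; isolated nodes
receive zero vectors. View 6 holds eleven classical edge features computed
on the final topology and standardised column-wise (zero-variance columns
become zeros). The feature list is surfaced as
`netchrono.CLASSICAL_FEATURES` and computed symmetrically (sums, mins,
maxes — never ordered endpoint pairs).

All features are computed on the final topology only: the method never sees
history at representation time.

## Comparators and ensemble

Each comparator is a shared-trunk comparative network: a tanh MLP scorer
f: R^d → R (one hidden layer of 16 units) applied to both edge vectors, with
pairwise output σ(f(e_i) − f(e_j)). This enforces o(i,j) + o(j,i) = 1 and
o(i,i) = 0.5 exactly and makes per-edge scores sufficient for all-pairs
prediction (O(E) scorer evaluations, O(E²) cheap comparisons). Training
minimises the logistic loss with Adam (lr 5e-3, 40 epochs, batch 1024),
deterministic given the seed. Two regularisation choices matter:

* input columns are standardised with training-edge statistics; columns with
  near-zero deviation (< 1e-8 of the largest) are dropped rather than
  standardised, since dividing by a vanishing deviation only amplifies
  numerical noise;
* Gaussian input noise (σ = 0.3 after standardisation) is added during
  training, pushing the scorer towards population-level directions of the
  view rather than per-edge detail. This costs a little in-network accuracy
  and helps when the scorer is later applied to another network's aligned
  representations.

The seventh output compares the single classical feature with the highest
training-pair accuracy under the fixed rule "strictly larger value ⇒ newer"
(ties contribute 0, i.e. "not newer"); feature ties are broken by lowest
index. Ensemble weights w_1..w_7 (simplex, step 0.1 → 8008 grid points) are
chosen by exhaustive search maximising pairwise accuracy on a 20% validation
split of the training pairs; the lexicographically first optimum is returned
for reproducibility. One caveat found while testing: when one component is
perfectly separated, many grid points attain perfect validation accuracy, so
the first optimum need not concentrate all mass on the perfect component —
only the largest single weight lands there.

Pairwise accuracy x counts a pair correct only if the thresholded output is
strictly on the right side of 0.5; exact ties score as incorrect.

Note on interpreting x: training and test pairs are distinct pairs but share
the same edge population, so in-network accuracies (~0.9 on synthetic
networks) partly reflect edge-level memorisation. Accuracy on pairs of
*unseen* edges — the regime that matters for transfer — is topology-limited:
with m = 2 growth, even the best degree-based rules reach only ~0.67–0.77
depending on the model.

## Borda aggregation

u_i = number of edges judged older than i across all pairs; edges are ranked
by ascending u_i, ties broken stably by input edge order. Each unordered
pair is decided exactly once from the antisymmetrised ensemble margin
g(i,j) = o(i,j) − o(j,i) (exact ties of g go to the lower input index), so
Σ u_i = E(E−1)/2 always. All-pairs prediction is exact and O(E²); no
subsampling shortcut is applied.

## Error theory

For permutations α, α̂ the overall error is the RMSE of D_i/E. Under
independent pairwise corruption at accuracy x, the normalised Borda counts
are uniform on [1−x, x] in expectation and the mean-field inversion gives
E(α̂_i) = α_i and Var(α̂_i/E) = x(1−x)/(E(2x−1)²), hence
E_theory = sqrt(x(1−x))/(2x−1)/sqrt(E), valid for x > 0.5 + 1/(4·sqrt(E));
below that bound a hard error is raised (the expression diverges at x=0.5).

The corruption simulation flips exactly ⌊|S|(1−x)⌋ pairs (not i.i.d.
Bernoulli), matching the definition of x as a realised fraction. Monte-Carlo
agreement with the closed form is within a few percent for x ≥ 0.7 and
within ~10% at x = 0.6 (the bound's neighbourhood); the 1/sqrt(E) scaling is
reproduced with slope −0.48 over E ∈ [250, 2000].

Two finite-size caveats, both visible in the test suite: the mean-field
inversion is biased at the sequence boundaries (α̂ is clamped to [1, E]), so
roughly the outer 4–5% of positions fail a ±3·SEM unbiasedness check at
E = 300, R = 200 even though all interior positions pass; and the variance
law is checked only on the interior band [0.2E, 0.8E] for the same reason.

Coarse-grained ground truth is handled by intermediate sequences α*: uniform
within-snapshot shuffles of the block ranges l_1..l_n. Displacements of a
fixed restoration against R drawn α* ("real-data" procedure) are directly
comparable to a pure simulation that corrupts the fine order at the measured
x; a two-sample KS statistic below 0.1 on matched settings is verified in
the tests. Default pooling is R = 200 (configurable); enough for stable
summary statistics at the problem sizes used here.

## Transfer

Degree-quantile correspondence: both node sets sorted by degree descending
(ties by node id string, frozen for reproducibility); unequal sizes are
handled by matching rank r of the smaller list to rank ⌊r·N_large/N_small⌋
of the larger. Per embedding view, L = argmin ‖H_B L − H_A‖_F via
`lstsq` (pseudo-inverse fallback when H_B is rank-deficient, flagged).
Node vectors are aligned before the Hadamard product; the classical-feature
view is topology-intrinsic and only re-standardised on the target. Direct
validation feeds the target's raw representations into the source ensemble.

Measured behaviour under the package's default study conditions (N ∈ {500,
1000}, m = 2): transfer accuracy ~0.69, direct validation ~0.65, with
transfer > direct consistently across seeds. The gap to much higher
published transfer accuracies on nominally similar synthetic settings is
explained by the unseen-edge ceiling above: accuracy rises steeply with the
edges-per-node parameter m (the bare min-endpoint-degree rule alone climbs
from ~0.72 at m = 2 to ~0.81–0.85 at m = 5), so denser growth conditions
make the task substantially easier. The package keeps m = 2 as its stated
condition rather than tuning it.

## Synthetic generators (study conditions)

* **BA**: m-clique seed, each new node attaches m edges degree-
  proportionally (m = 1 seeds a single node and the first attachment is
  uniform). E = m(m−1)/2 + m(n−m), deterministic.
* **fitness**: identical machinery with attachment ∝ degree × fitness;
  default fitness ~ Uniform(0,1] drawn per node at birth; two-point and
  constant distributions available.
* **PSO**: node t at radius 2 ln t, uniform angle; popularity fading
  r_s(t) = β r_s + (1−β) r_t with β = 0.5; new node connects to the m
  hyperbolically nearest predecessors at T = 0 (stable nearest-first), or
  samples without replacement with Boltzmann weights exp(−d/(2T)) at T > 0
  (default T = 0.1). The Boltzmann form reduces to nearest-choice as T → 0.
* **pure-PA null**: edges between existing nodes with endpoints ∝ degree;
  isolated base nodes are brought in at a steady rate, each arrival
  attaching degree-proportionally, so the final average degree matches the
  target. A uniform fallback resolves the dense-graph corner where
  degree-proportional rejection sampling stalls.

Within one node-arrival step the m new edges get consecutive positions in
draw order; ties within a step are below the method's resolution. Snapshot
coarsening splits the arrival sequence into contiguous near-equal blocks,
remainder to the earliest blocks (frozen convention).

What the generators do **not** emulate — and hence what passing tests do not
show about real data: (1) no edge/node deletion; (2) no densification —
every edge attaches a newly arriving node, so "future" edges always involve
unseen nodes. Consequence: the link-prediction comparison on a synthetic
holdout of the last 10% of edges is vacuous (neither the temporally weighted
nor the binary method can rank pairs involving unseen nodes; both score
zero and the ≥-comparison holds trivially). On real, densifying networks the
temporal weighting can matter; on an artificial densified variant where
internal links follow hyperbolic proximity, the *binary* baseline wins,
because proximity favours old popular pairs while the decay suppresses old
edges. The value of the temporal weighting therefore hinges on
recency-biased densification, which no generator here produces; (3) training
pairs are sampled uniformly, whereas real coarse histories concentrate
usable pairs in late snapshots.

## Growth analysis

The attachment kernel is estimated by replaying edges in a given order:
every endpoint already present counts one attachment to its current degree
class, and each class's exposure accumulates the number of its nodes at each
arrival event. κ(k) is the running sum of π(k) = attachments/exposure,
normalised to κ(k_max) = 1. Degree classes below k_min = 2 are excluded:
a newcomer's second edge within one arrival step registers as an attachment
to a transient degree-1 class of near-zero exposure, which would otherwise
swamp the kernel. With this estimator, BA replayed in true order shows
log-log slope ≈ 2 (linear PA) and uniform-attachment growth ≈ 1. Note that
replaying a heavy-tailed network in *random* order also yields an apparent
superlinear kernel — the estimator conditions on the final degree sequence —
so kernel slopes discriminate growth rules only under (approximately) true
orderings, not against shuffled ones.

Structural trajectories evaluate modularity (greedy partition), degree
assortativity, mean local clustering and mean shortest path (over connected
pairs only) on first-c-edges subgraphs; undefined values (assortativity on
regular checkpoints, paths on empty graphs) are reported as None, never NaN.
Meso-level matrices count label-pair edges with same-label mass on the
diagonal; the matrix total always equals the checkpoint edge count.

Link prediction: X(u,v) = θ^(max α̂ − α̂_i) on edges (newest weight exactly
1), rank-r truncated SVD reconstruction scores all non-edges; θ = 1 (binary
adjacency) must be requested explicitly. θ and r are grid-searched
(θ ∈ {0.1..0.9}, r ∈ {2,4,8,16,32}) on a validation split by hits-sum.

## Numerical and reproducibility choices

All randomness flows from explicit integer seeds through
`numpy.random.default_rng`; view-building spawns per-method child seeds from
a `SeedSequence`. Pairwise decisions, Borda ties, degree ties and grid-search
ties all have frozen deterministic tie-breaks (documented at each site). The
sigmoid is evaluated in a numerically symmetric two-branch form; pair
decisions are made once per unordered pair so count conservation holds
exactly in floating point.

Problem sizes used by the shipped tests and the acceptance script — chosen
as the package's own working scale: networks of 60–2000 nodes, corruption
simulations up to E = 2000, transfer studies at N ∈ {500, 1000} with 3
seeds, training-pair budgets capped at 30 000 (pairwise accuracy saturates
well below this, consistent with the saturation of accuracy in the training
fraction).

## Known limitations

* No deletion dynamics; restored positions are meaningless for systems where
  edges disappear.
* Transfer assumes the two networks share a generative mechanism; aligning
  across mechanisms (or real heterogeneous data) is out of scope.
* The mean-field theory degrades at sequence boundaries and near x = 0.5.
* In-network accuracy conflates edge memorisation with generalisation; use
  unseen-edge or cross-network evaluation when the distinction matters.
* Dense linear algebra bounds practical network size to a few thousand
  nodes.
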