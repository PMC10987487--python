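"""Pairwise edge-age comparators, their ensemble, and Borda aggregation.

The model predicts, for any two edges i and j of the final topology, the
probability that i was added later than j.  Six comparative neural networks
(one per edge view) share the architecture: a small scorer ``f`` maps an edge
vector to a scalar and the pairwise output is ``o(i, j) = sigma(f(e_i) -
f(e_j))``, which is antisymmetric by construction (``o(i, j) + o(j, i) = 1``
and ``o(i, i) = 0.5``).  A seventh output compares the single classical
feature that best orders the training pairs ("larger value means newer",
ties count as "not newer").  The final output is a convex combination of the
seven, with weights found by exhaustive grid search on the probability
simplex (step 0.1).

All pairwise decisions are aggregated by Borda count: ``u_i`` is the number
of edges judged older than i, and ranking edges by ascending ``u_i`` (stable
in input order on ties) yields the restored arrival sequence.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from ._nn import MLP, sigmoid
from .embeddings import EdgeViewSet
from .network import Edge, TemporalNetwork, distinguishable_pair_count


# ---------------------------------------------------------------------------
# labeled pairs
# ---------------------------------------------------------------------------

@dataclass
class LabeledPairs:
    """Edge-index pairs with relative-age labels: ``y = 1`` iff edge ``i`` is
    newer than edge ``j``.  Indices refer to the network's input edge order."""

    i: np.ndarray
    j: np.ndarray
    y: np.ndarray
    pair_ids: Optional[np.ndarray] = None  # ids in the triu enumeration

    def __len__(self) -> int:
        return self.i.shape[0]


def _distinguishable_pairs(net: TemporalNetwork) -> Tuple[np.ndarray, np.ndarray]:
    """All unordered pairs (a < b by arrival index) whose order is knowable."""
    e = net.n_edges
    a, b = np.triu_indices(e, k=1)
    if net.snapshots is not None:
        snap = np.asarray(net.snapshots)
        keep = snap[a] != snap[b]
        a, b = a[keep], b[keep]
    return a, b


def make_training_pairs(net: TemporalNetwork, fraction: float, seed: int = 0,
                        max_pairs: Optional[int] = None) -> LabeledPairs:
    """Uniformly sample a fraction of the distinguishable edge pairs.

    Each sampled pair is given a random orientation so the label classes are
    balanced by construction.  Edges are indexed by their position in the
    network's edge list (arrival order), and edge ``b > a`` is the newer one.
    """
    if not 0.0 < fraction <= 1.0:
        raise ValueError("fraction must lie in (0, 1]")
    a, b = _distinguishable_pairs(net)
    n = a.shape[0]
    if n == 0:
        raise ValueError("no edge pairs with distinguishable order")
    take = int(np.floor(fraction * n))
    take = max(take, 1)
    if max_pairs is not None:
        take = min(take, max_pairs)
    rng = np.random.default_rng(seed)
    ids = rng.permutation(n)[:take]
    a, b = a[ids], b[ids]
    flip = rng.random(take) < 0.5
    i = np.where(flip, a, b)
    j = np.where(flip, b, a)
    y = (i > j).astype(np.int64)  # arrival index order is the truth
    return LabeledPairs(i=i, j=j, y=y, pair_ids=ids)


def sample_test_pairs(net: TemporalNetwork, n_pairs: int, seed: int = 0,
                      exclude: Optional[np.ndarray] = None) -> LabeledPairs:
    """Sample labelled pairs disjoint from ``exclude`` (triu pair ids)."""
    a, b = _distinguishable_pairs(net)
    n = a.shape[0]
    mask = np.ones(n, dtype=bool)
    if exclude is not None:
        mask[exclude] = False
    avail = np.flatnonzero(mask)
    if avail.size == 0:
        raise ValueError("no pairs left to sample")
    rng = np.random.default_rng(seed)
    ids = avail[rng.permutation(avail.size)[:min(n_pairs, avail.size)]]
    a, b = a[ids], b[ids]
    flip = rng.random(ids.size) < 0.5
    i = np.where(flip, a, b)
    j = np.where(flip, b, a)
    return LabeledPairs(i=i, j=j, y=(i > j).astype(np.int64), pair_ids=ids)


# ---------------------------------------------------------------------------
# the comparative scorer
# ---------------------------------------------------------------------------

class Comparator:
    """Shared-trunk comparative network over one edge view.

    The scorer ``f`` is a small tanh MLP; the pairwise probability is
    ``sigma(f(e_i) - f(e_j))``, trained on the logistic loss.  Edge vectors
    are standardised with statistics of the training edges.  Gaussian input
    noise during training regularises the scorer towards the dominant,
    population-level directions of the view rather than per-edge detail,
    which matters when the scorer is later applied to another network's
    aligned representations.
    """

    def __init__(self, hidden: Sequence[int] = (16,), epochs: int = 40,
                 batch: int = 1024, lr: float = 5e-3, noise: float = 0.3,
                 seed: int = 0):
        self.hidden = tuple(hidden)
        self.epochs = epochs
        self.batch = batch
        self.lr = lr
        self.noise = noise
        self.seed = seed
        self._mlp: Optional[MLP] = None
        self._mu: Optional[np.ndarray] = None
        self._sd: Optional[np.ndarray] = None

    def fit(self, vectors: np.ndarray, pairs: LabeledPairs) -> "Comparator":
        if len(pairs) < 2:
            raise ValueError("need at least two labelled pairs")
        if len(np.unique(pairs.y)) < 2:
            raise ValueError("degenerate labels: only one class present")
        rng = np.random.default_rng(self.seed)
        used = np.union1d(pairs.i, pairs.j)
        self._mu = vectors[used].mean(axis=0)
        sd = vectors[used].std(axis=0)
        # near-constant columns carry no order information; standardising by
        # a vanishing deviation would only amplify numerical noise
        tol = 1e-8 * max(float(sd.max()), 1e-30)
        self._sd = np.where(sd > tol, sd, np.inf)
        x = (vectors - self._mu) / self._sd
        self._mlp = MLP([x.shape[1], *self.hidden, 1], rng)
        n = len(pairs)
        order = np.arange(n)
        lr = self.lr
        for _ in range(self.epochs):
            rng.shuffle(order)
            for s in range(0, n, self.batch):
                sel = order[s:s + self.batch]
                xi, xj = x[pairs.i[sel]], x[pairs.j[sel]]
                if self.noise > 0:
                    xi = xi + self.noise * rng.standard_normal(xi.shape)
                    xj = xj + self.noise * rng.standard_normal(xj.shape)
                yi = pairs.y[sel]
                fi, acts_i = self._mlp.forward(xi)
                fj, acts_j = self._mlp.forward(xj)
                o = sigmoid((fi - fj).ravel())
                g = ((o - yi) / sel.shape[0])[:, None]
                gwi, gbi = self._mlp.backward(acts_i, g)
                gwj, gbj = self._mlp.backward(acts_j, -g)
                self._mlp.adam_step([a + b for a, b in zip(gwi, gwj)],
                                    [a + b for a, b in zip(gbi, gbj)], lr=lr)
            lr *= 0.99
        return self

    def scores(self, vectors: np.ndarray) -> np.ndarray:
        """Per-edge scalar f(e); pairwise output is sigma(s_i - s_j)."""
        if self._mlp is None:
            raise RuntimeError("comparator is not trained")
        x = (vectors - self._mu) / self._sd
        return self._mlp(x).ravel()

    def predict_proba(self, vectors: np.ndarray, i: np.ndarray, j: np.ndarray) -> np.ndarray:
        s = self.scores(vectors)
        return sigmoid(s[i] - s[j])


# ---------------------------------------------------------------------------
# best classical feature
# ---------------------------------------------------------------------------

def best_feature_outputs(values: np.ndarray, i: np.ndarray, j: np.ndarray) -> np.ndarray:
    """o7 = 1 if edge i has the strictly larger value, else 0 (ties -> 0)."""
    return (values[i] > values[j]).astype(float)


def select_best_feature(classical_raw: np.ndarray, pairs: LabeledPairs) -> Tuple[int, float]:
    """Index of the classical feature whose "larger means newer" rule best
    matches the training pairs; ties broken by lowest index."""
    if len(pairs) == 0:
        raise ValueError("no training pairs")
    accs = []
    for f in range(classical_raw.shape[1]):
        o = best_feature_outputs(classical_raw[:, f], pairs.i, pairs.j)
        accs.append(float(np.mean(o == pairs.y)))
    best = int(np.argmax(accs))
    return best, accs[best]


# ---------------------------------------------------------------------------
# ensemble
# ---------------------------------------------------------------------------

_GRID_CACHE: Dict[Tuple[int, int], np.ndarray] = {}


def simplex_grid(n_components: int = 7, steps: int = 10) -> np.ndarray:
    """All weight vectors with entries k/steps summing to 1, in lexicographic
    ascending order (the tie-break order of the grid search)."""
    key = (n_components, steps)
    if key not in _GRID_CACHE:
        rows = []
        for combo in itertools.combinations_with_replacement(range(n_components), steps):
            w = np.zeros(n_components)
            for c in combo:
                w[c] += 1.0 / steps
            rows.append(w)
        grid = np.unique(np.array(rows), axis=0)
        order = np.lexsort(grid.T[::-1])
        _GRID_CACHE[key] = grid[order]
    return _GRID_CACHE[key]


def _accuracy_from_outputs(o_final: np.ndarray, y: np.ndarray) -> float:
    correct = ((o_final > 0.5) & (y == 1)) | ((o_final < 0.5) & (y == 0))
    return float(np.mean(correct))


def fit_ensemble_weights(outputs: np.ndarray, y: np.ndarray,
                         steps: int = 10) -> np.ndarray:
    """Exhaustive simplex grid search maximising pairwise accuracy.

    ``outputs`` is (n_pairs, 7).  Deterministic: the first lexicographic
    optimum is returned.
    """
    if outputs.shape[0] == 0:
        raise ValueError("empty validation set")
    grid = simplex_grid(outputs.shape[1], steps)
    best_acc, best_idx = -1.0, 0
    for s in range(0, grid.shape[0], 512):
        block = grid[s:s + 512]
        o = outputs @ block.T  # (n, B)
        correct = ((o > 0.5) & (y[:, None] == 1)) | ((o < 0.5) & (y[:, None] == 0))
        accs = correct.mean(axis=0)
        k = int(np.argmax(accs))
        if accs[k] > best_acc + 1e-12:
            best_acc, best_idx = float(accs[k]), s + k
    return grid[best_idx]


@dataclass
class PairwiseOrderModel:
    """Trained ensemble: six comparators, the best-feature index, and the
    simplex weights ``w_1..w_7``."""

    comparators: List[Comparator]
    best_feature: int
    weights: np.ndarray
    seed: int
    train_fraction: float
    best_feature_train_acc: float = float("nan")
    component_val_acc: Optional[np.ndarray] = None

    def component_outputs(self, views: EdgeViewSet, i: np.ndarray,
                          j: np.ndarray) -> np.ndarray:
        """The seven component outputs o^1..o^7 for index pairs (i, j)."""
        cols = [c.predict_proba(v, i, j)
                for c, v in zip(self.comparators, views.views)]
        cols.append(best_feature_outputs(views.classical_raw[:, self.best_feature], i, j))
        return np.column_stack(cols)

    def predict(self, views: EdgeViewSet, i: np.ndarray, j: np.ndarray) -> np.ndarray:
        """Final ensemble probability that edge i is newer than edge j."""
        return self.component_outputs(views, i, j) @ self.weights


def ensemble_predict(model: PairwiseOrderModel, views: EdgeViewSet,
                     edge_i: Edge, edge_j: Edge) -> float:
    """Convenience scalar form of :meth:`PairwiseOrderModel.predict`."""
    i = np.array([views.edge_index(edge_i)])
    j = np.array([views.edge_index(edge_j)])
    return float(model.predict(views, i, j)[0])


def pairwise_accuracy(model: PairwiseOrderModel, views: EdgeViewSet,
                      pairs: LabeledPairs) -> float:
    """Fraction of test pairs ordered correctly; exact ties count as wrong."""
    if len(pairs) == 0:
        raise ValueError("empty test set")
    o = model.predict(views, pairs.i, pairs.j)
    return _accuracy_from_outputs(o, pairs.y)


def fit_order_model(net: TemporalNetwork, views: EdgeViewSet,
                    train_fraction: float = 0.05, seed: int = 0,
                    val_fraction: float = 0.2,
                    max_pairs: Optional[int] = None,
                    comparator_kwargs: Optional[dict] = None) -> PairwiseOrderModel:
    """Train the full ensemble on a network with (at least coarse) history.

    A ``val_fraction`` share of the sampled training pairs is held aside for
    the weight grid search; the six comparators and the best-feature choice
    use the remainder.
    """
    pairs = make_training_pairs(net, train_fraction, seed=seed, max_pairs=max_pairs)
    rng = np.random.default_rng(seed + 1)
    n = len(pairs)
    perm = rng.permutation(n)
    n_val = max(1, int(val_fraction * n))
    val_sel, tr_sel = perm[:n_val], perm[n_val:]
    if tr_sel.size < 2:
        raise ValueError("too few training pairs after validation split")
    tr = LabeledPairs(pairs.i[tr_sel], pairs.j[tr_sel], pairs.y[tr_sel],
                      pairs.pair_ids[tr_sel])
    va = LabeledPairs(pairs.i[val_sel], pairs.j[val_sel], pairs.y[val_sel],
                      pairs.pair_ids[val_sel])
    ckw = dict(comparator_kwargs or {})
    comparators = []
    for l, v in enumerate(views.views):
        comparators.append(Comparator(seed=seed * 7 + l, **ckw).fit(v, tr))
    best, best_acc = select_best_feature(views.classical_raw, tr)
    model = PairwiseOrderModel(comparators=comparators, best_feature=best,
                               weights=np.ones(7) / 7.0, seed=seed,
                               train_fraction=train_fraction,
                               best_feature_train_acc=best_acc)
    outputs = model.component_outputs(views, va.i, va.j)
    model.weights = fit_ensemble_weights(outputs, va.y)
    model.component_val_acc = np.array(
        [_accuracy_from_outputs(outputs[:, k], va.y) for k in range(outputs.shape[1])])
    model.training_pairs = pairs  # type: ignore[attr-defined]
    return model


# ---------------------------------------------------------------------------
# Borda aggregation
# ---------------------------------------------------------------------------

@dataclass
class RestoredSequence:
    """Restored arrival order: ``positions[k]`` is the 1-based position of
    input edge ``k`` (oldest first); ``borda[k]`` its Borda count."""

    edges: List[Edge]
    positions: np.ndarray
    borda: np.ndarray
    source: str = ""

    def __post_init__(self) -> None:
        e = len(self.edges)
        if not np.array_equal(np.sort(self.positions), np.arange(1, e + 1)):
            raise ValueError("positions must be a permutation of 1..E")

    def edges_in_restored_order(self) -> List[Edge]:
        out: List[Edge] = [None] * len(self.edges)  # type: ignore[list-item]
        for k, pos in enumerate(self.positions):
            out[pos - 1] = self.edges[k]
        return out


def borda_counts(decisions: Dict[Tuple[int, int], bool], n_edges: int) -> np.ndarray:
    """Borda counts from explicit pair decisions.

    ``decisions[(i, j)]`` (with i < j) is True iff edge i is judged newer than
    edge j; exactly one entry per unordered pair is required.
    """
    u = np.zeros(n_edges, dtype=np.int64)
    seen = set()
    for (i, j), i_newer in decisions.items():
        a, b = min(i, j), max(i, j)
        if a == b or (a, b) in seen:
            raise ValueError(f"bad or duplicate pair ({i}, {j})")
        seen.add((a, b))
        newer = i if i_newer else j
        u[newer] += 1
    if len(seen) != n_edges * (n_edges - 1) // 2:
        raise ValueError("a decision is missing for at least one pair")
    return u


def restore_sequence(u: np.ndarray, edges: Sequence[Edge], source: str = "") -> RestoredSequence:
    """Rank edges by ascending Borda count; ties broken stably by input order."""
    u = np.asarray(u)
    order = np.argsort(u, kind="stable")
    positions = np.empty(u.shape[0], dtype=np.int64)
    positions[order] = np.arange(1, u.shape[0] + 1)
    return RestoredSequence(edges=list(edges), positions=positions,
                            borda=u.astype(np.int64), source=source)


def restore_network(model: PairwiseOrderModel, views: EdgeViewSet,
                    block: int = 256) -> RestoredSequence:
    """Exact all-pairs ensemble prediction + Borda ranking.

    Works blockwise on the antisymmetrised ensemble margin
    ``g(i, j) = o(i, j) - o(j, i)``; edge i is judged newer than j iff
    ``g > 0`` (exact ties resolved against the lower index).  O(E^2) but fully
    vectorised; per-edge comparator scores are computed once.
    """
    e = len(views.edges)
    s = np.stack([c.scores(v) for c, v in zip(model.comparators, views.views)])
    b = views.classical_raw[:, model.best_feature]
    w = model.weights
    u = np.zeros(e, dtype=np.int64)
    idx = np.arange(e)
    for start in range(0, e, block):
        rows = slice(start, min(start + block, e))
        g = np.zeros((rows.stop - rows.start, e))
        for l in range(6):
            g += w[l] * (2.0 * sigmoid(s[l][rows, None] - s[l][None, :]) - 1.0)
        g += w[6] * np.sign(b[rows, None] - b[None, :])
        # decide each unordered pair once (j > i); ties go to the lower index
        upper = idx[None, :] > idx[rows, None]
        row_newer = g >= 0
        u[rows] += (row_newer & upper).sum(axis=1)
        u += (~row_newer & upper).sum(axis=0)
    return restore_sequence(u, views.edges, source=f"ensemble(seed={model.seed})")
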