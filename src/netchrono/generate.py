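"""Synthetic growing-network generators with full ground-truth arrival order.

Three growth models are provided:

* ``ba`` — Barabási–Albert preferential attachment: each new node attaches
  ``m`` edges to existing nodes with probability proportional to degree.
* ``pso`` — popularity–similarity optimisation: nodes live in a hyperbolic
  disk (radial coordinate = popularity/age, angle = similarity); a new node
  connects to the ``m`` hyperbolically closest predecessors at temperature
  ``T = 0``, or samples them with Boltzmann weights ``exp(-d / (2T))`` at
  ``T > 0``.  Popularity fading moves earlier nodes outward as
  ``r_s(t) = beta * r_s + (1 - beta) * r_t``.
* ``fitness`` — Bianconi–Barabási growth: attachment probability proportional
  to degree × fitness, fitness drawn i.i.d. per node at birth.

BA and fitness growth start from an ``m``-node clique so the final edge count
is deterministic: ``E = m (m - 1) / 2 + m (n - m)``.  Within one node-arrival
step the ``m`` new edges receive consecutive arrival positions in the order
the attachment targets were drawn.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import numpy as np

from .network import Edge, TemporalNetwork, canonical_edge


@dataclass
class GeneratorConfig:
    """Configuration of a synthetic growth run.

    ``model_params`` holds model-specific knobs: PSO temperature ``T`` and
    popularity-fading exponent ``beta``; fitness distribution spec
    ``fitness_dist`` (``("uniform", low, high)`` or ``("two_point", lo, hi, p_hi)``).
    """

    model: str
    n_nodes: int
    m: int = 2
    seed: int = 0
    model_params: Dict[str, object] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.model not in ("ba", "pso", "fitness"):
            raise ValueError(f"unknown model {self.model!r}")
        if self.m < 1 or self.n_nodes <= self.m:
            raise ValueError("require n_nodes > m >= 1")


def generate(config: GeneratorConfig) -> TemporalNetwork:
    """Dispatch on ``config.model``."""
    return {"ba": generate_ba, "pso": generate_pso, "fitness": generate_fitness}[config.model](config)


# ---------------------------------------------------------------------------
# degree-proportional growth (BA and fitness share the machinery)
# ---------------------------------------------------------------------------

def _grow_degree_fitness(n: int, m: int, fitness: Optional[np.ndarray],
                         rng: np.random.Generator) -> List[Edge]:
    """Grow from an m-clique; new node t attaches m edges to distinct existing
    nodes with probability proportional to degree (× fitness when given)."""
    edges: List[Edge] = []
    deg = np.zeros(n)
    for u in range(m):
        for v in range(u + 1, m):
            edges.append((u, v))
            deg[u] += 1
            deg[v] += 1
    if m == 1:
        # single-node seed has no edges; the first newcomer attaches uniformly
        deg[0] = 0.0
    for t in range(m, n):
        w = deg[:t].copy()
        if fitness is not None:
            w = w * fitness[:t]
        if w.sum() <= 0:
            w = np.ones(t)
        targets: List[int] = []
        for _ in range(m):
            p = w / w.sum()
            tgt = int(rng.choice(t, p=p))
            targets.append(tgt)
            w[tgt] = 0.0  # no duplicate edges from one newcomer
            if w.sum() <= 0 and len(targets) < m:
                remaining = [u for u in range(t) if u not in targets]
                targets.extend(remaining[: m - len(targets)])
                break
        for tgt in targets:
            edges.append(canonical_edge(tgt, t))
            deg[tgt] += 1
            deg[t] += 1
    return edges


def generate_ba(config: GeneratorConfig) -> TemporalNetwork:
    """Barabási–Albert growth with recorded arrival order."""
    rng = np.random.default_rng(config.seed)
    edges = _grow_degree_fitness(config.n_nodes, config.m, None, rng)
    return TemporalNetwork(edges)


def generate_fitness(config: GeneratorConfig) -> TemporalNetwork:
    """Bianconi–Barabási fitness growth; default fitness ~ Uniform(0, 1]."""
    rng = np.random.default_rng(config.seed)
    dist = config.model_params.get("fitness_dist", ("uniform", 0.0, 1.0))
    n = config.n_nodes
    if dist[0] == "uniform":
        lo, hi = float(dist[1]), float(dist[2])
        if not hi > lo:
            raise ValueError("degenerate uniform fitness range")
        # Uniform(lo, hi] — strictly positive when lo >= 0
        fitness = hi - rng.random(n) * (hi - lo)
    elif dist[0] == "two_point":
        lo, hi, p_hi = float(dist[1]), float(dist[2]), float(dist[3])
        if lo <= 0 or hi <= 0 or not 0 < p_hi < 1:
            raise ValueError("degenerate two-point fitness spec")
        fitness = np.where(rng.random(n) < p_hi, hi, lo)
    elif dist[0] == "constant":
        fitness = np.full(n, float(dist[1]))
        if fitness[0] <= 0:
            raise ValueError("constant fitness must be positive")
    else:
        raise ValueError(f"unknown fitness distribution {dist[0]!r}")
    edges = _grow_degree_fitness(n, config.m, fitness, rng)
    net = TemporalNetwork(edges)
    net.fitness = {i: float(fitness[i]) for i in range(n)}  # type: ignore[attr-defined]
    return net


# ---------------------------------------------------------------------------
# popularity-similarity optimisation in the hyperbolic disk
# ---------------------------------------------------------------------------

def _hyperbolic_distance(r1: float, th1: np.ndarray, r2: np.ndarray, th2: np.ndarray) -> np.ndarray:
    dth = np.pi - np.abs(np.pi - np.abs(th1 - th2))
    arg = np.cosh(r1) * np.cosh(r2) - np.sinh(r1) * np.sinh(r2) * np.cos(dth)
    return np.arccosh(np.maximum(arg, 1.0))


def generate_pso(config: GeneratorConfig) -> TemporalNetwork:
    """PSO growth: trade-off between popularity (radius) and similarity (angle)."""
    rng = np.random.default_rng(config.seed)
    n, m = config.n_nodes, config.m
    temp = float(config.model_params.get("T", 0.1))
    beta = float(config.model_params.get("beta", 0.5))
    if temp < 0:
        raise ValueError("temperature T must be >= 0")
    if not 0 < beta <= 1:
        raise ValueError("popularity fading beta must lie in (0, 1]")

    theta = rng.random(n) * 2 * np.pi
    r_birth = np.array([2.0 * math.log(t + 1) for t in range(n)])
    edges: List[Edge] = []
    for t in range(1, n):
        r_t = r_birth[t]
        # popularity fading: earlier nodes drift outward toward r_t
        r_now = beta * r_birth[:t] + (1.0 - beta) * r_t
        d = _hyperbolic_distance(r_t, theta[t], r_now, theta[:t])
        k = min(m, t)
        if temp == 0.0:
            order = np.lexsort((np.arange(t), d))  # stable nearest-first
            targets = order[:k].tolist()
        else:
            logits = -d / (2.0 * temp)
            logits -= logits.max()
            w = np.exp(logits)
            targets = []
            for _ in range(k):
                p = w / w.sum()
                tgt = int(rng.choice(t, p=p))
                targets.append(tgt)
                w[tgt] = 0.0
        for tgt in targets:
            edges.append(canonical_edge(tgt, t))
    net = TemporalNetwork(edges)
    net.coordinates = {i: (float(r_birth[i]), float(theta[i])) for i in range(n)}  # type: ignore[attr-defined]
    return net


# ---------------------------------------------------------------------------
# coarse-graining and the pure-PA null
# ---------------------------------------------------------------------------

def coarsen_to_snapshots(net: TemporalNetwork, n_snapshots: int) -> TemporalNetwork:
    """Assign snapshot labels by splitting the arrival sequence into
    ``n_snapshots`` contiguous blocks of near-equal size, earlier blocks taking
    the remainder.  The fine arrival order is retained for evaluation."""
    e = net.n_edges
    if not 1 <= n_snapshots <= e:
        raise ValueError("n_snapshots must lie in [1, E]")
    base, rem = divmod(e, n_snapshots)
    labels: List[int] = []
    for k in range(n_snapshots):
        labels.extend([k + 1] * (base + (1 if k < rem else 0)))
    return TemporalNetwork(list(net.edges), snapshots=labels, node_labels=net.node_labels)


def grow_pure_pa(base: TemporalNetwork, n_edges_target: int, seed: int) -> TemporalNetwork:
    """Grow a pure preferential-attachment null from ``base``.

    Repeatedly adds edges whose endpoints are drawn with probability
    proportional to degree (no duplicates or self-loops) until
    ``n_edges_target`` edges.  Isolated base nodes are treated as not yet
    arrived: they are brought in at a steady rate (so all nodes are present
    by the time the target is reached), each arrival attaching its first edge
    to a degree-proportionally chosen partner.  The final average degree thus
    matches the target network while attachment follows the pure PA rule.
    """
    if base.n_edges == 0:
        raise ValueError("base network must be non-empty")
    nodes = base.nodes
    n = len(nodes)
    capacity = n * (n - 1) // 2
    if not base.n_edges <= n_edges_target <= capacity:
        raise ValueError("n_edges_target outside [|base edges|, simple-graph capacity]")
    idx = {u: i for i, u in enumerate(nodes)}
    deg = np.zeros(n)
    present = set()
    edges: List[Edge] = list(base.edges)
    for u, v in base.edges:
        deg[idx[u]] += 1
        deg[idx[v]] += 1
        present.add((min(idx[u], idx[v]), max(idx[u], idx[v])))
    rng = np.random.default_rng(seed)
    stall = 0
    while len(edges) < n_edges_target:
        isolated = np.flatnonzero(deg == 0)
        edges_left = n_edges_target - len(edges)
        p_new = min(1.0, isolated.size / max(edges_left, 1))
        p = deg / deg.sum()
        if isolated.size and rng.random() < p_new:
            i = int(rng.choice(isolated))
            j = int(rng.choice(n, p=p))
        else:
            i = int(rng.choice(n, p=p))
            j = int(rng.choice(n, p=p))
        if i == j:
            continue
        key = (min(i, j), max(i, j))
        if key in present:
            stall += 1
            if stall > 500:
                # dense corner: fall back to a uniform unused pair
                free = [(a, b) for a in range(n) for b in range(a + 1, n)
                        if (a, b) not in present]
                key = free[int(rng.integers(len(free)))]
                i, j = key
                stall = 0
            else:
                continue
        stall = 0
        present.add(key)
        edges.append(canonical_edge(nodes[i], nodes[j]))
        deg[i] += 1
        deg[j] += 1
    return TemporalNetwork(edges, extra_nodes=list(nodes), node_labels=base.node_labels)
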