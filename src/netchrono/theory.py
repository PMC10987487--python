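"""Error metric for restored sequences and its mean-field closed form.

Given a true arrival sequence ``alpha`` and a restored one ``alpha_hat`` (both
permutations of ``{1..E}``), the per-edge displacement is
``D_i = alpha_i - alpha_hat_i`` and the overall error is the RMSE of ``D_i/E``:

    E = sqrt( (1/E) * sum_i (D_i / E)^2 )

Under a mean-field treatment of Borda aggregation of pairwise decisions that
are each correct with probability ``x``, the restored position is an unbiased
estimate of the true one with variance ``x(1-x) / (E (2x-1)^2)``, so

    E_theory = sqrt(x (1-x)) / (2x - 1) / sqrt(E),

valid well above the singular point ``x = 0.5`` (we require
``x > 0.5 + 1/(4 sqrt(E))``).

The simulation helpers corrupt a known ground-truth pairwise order at a given
accuracy and push it through Borda ranking, with optional coarse-grained
(snapshot) ground truth handled by drawing intermediate sequences that shuffle
edges within snapshots.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import List, Optional, Sequence

import numpy as np
from scipy import stats


@dataclass
class ErrorReport:
    """Displacements and summary statistics for one restored sequence."""

    displacements: np.ndarray  # D_i = alpha_i - alpha_hat_i
    overall_error: float
    kendall_tau: float
    spearman_rho: float
    theory_error: Optional[float] = None


@dataclass
class CorruptionSpec:
    """Parameters of the corrupted-pairwise-order simulation."""

    E: int
    x: float
    R: int = 20
    seed: int = 0

    def __post_init__(self) -> None:
        if self.E < 2:
            raise ValueError("E must be >= 2")
        if not 0.0 <= self.x <= 1.0:
            raise ValueError("x must lie in [0, 1]")
        if self.R < 1:
            raise ValueError("R must be >= 1")

    @property
    def n_pairs(self) -> int:
        return self.E * (self.E - 1) // 2

    @property
    def M(self) -> int:
        """Number of pairs assigned the correct order."""
        return math.floor(self.n_pairs * self.x)


def _check_permutation(a: np.ndarray, name: str) -> None:
    e = a.shape[0]
    if not np.array_equal(np.sort(a), np.arange(1, e + 1)):
        raise ValueError(f"{name} is not a permutation of 1..{e}")


def overall_error(truth: Sequence[int], restored: Sequence[int],
                  x: Optional[float] = None) -> ErrorReport:
    """Overall error, Kendall tau and Spearman rho of a restored sequence.

    ``truth[i]`` and ``restored[i]`` are the 1-based positions of edge ``i``
    in the true and restored sequences.  When the pairwise accuracy ``x`` is
    supplied, the closed-form prediction is attached for comparison.
    """
    alpha = np.asarray(truth, dtype=float)
    alpha_hat = np.asarray(restored, dtype=float)
    if alpha.shape != alpha_hat.shape:
        raise ValueError("sequence length mismatch")
    _check_permutation(alpha, "truth")
    _check_permutation(alpha_hat, "restored")
    e = alpha.shape[0]
    d = alpha - alpha_hat
    err = math.sqrt(float(np.mean((d / e) ** 2)))
    tau = float(stats.kendalltau(alpha, alpha_hat).statistic)
    rho = float(stats.spearmanr(alpha, alpha_hat).statistic)
    theory = theoretical_error(x, e) if x is not None else None
    return ErrorReport(displacements=d, overall_error=err,
                       kendall_tau=tau, spearman_rho=rho, theory_error=theory)


def validity_bound(E: int) -> float:
    """Smallest pairwise accuracy at which the closed form is trusted."""
    return 0.5 + 1.0 / (4.0 * math.sqrt(E))


def theoretical_error(x: float, E: int) -> float:
    """Mean-field overall error sqrt(x(1-x)) / (2x-1) / sqrt(E)."""
    bound = validity_bound(E)
    if not x > bound:
        raise ValueError(
            f"closed form requires x > {bound:.6g} (got x={x}); it diverges at x=0.5")
    if x > 1.0:
        raise ValueError("x must be <= 1")
    if x == 1.0:
        return 0.0
    return math.sqrt(x * (1.0 - x)) / (2.0 * x - 1.0) / math.sqrt(E)


# ---------------------------------------------------------------------------
# corrupted-ranking simulations
# ---------------------------------------------------------------------------

def _pair_index_arrays(E: int) -> tuple:
    iu = np.triu_indices(E, k=1)
    return iu[0], iu[1]  # i < j; edge j is the newer one in truth


def _borda_rank(u: np.ndarray) -> np.ndarray:
    """1-based restored positions: ascending Borda count, stable ties."""
    order = np.argsort(u, kind="stable")
    alpha_hat = np.empty(u.shape[0], dtype=np.int64)
    alpha_hat[order] = np.arange(1, u.shape[0] + 1)
    return alpha_hat


def corrupt_and_rank(E: int, M: int, rng: np.random.Generator) -> np.ndarray:
    """One corruption round: exactly M random pairs keep the correct order,
    the rest are flipped; returns the Borda-restored positions alpha_hat."""
    ii, jj = _pair_index_arrays(E)
    n_pairs = ii.shape[0]
    correct = np.zeros(n_pairs, dtype=bool)
    correct[rng.permutation(n_pairs)[:M]] = True
    winners = np.where(correct, jj, ii)  # winner = edge judged newer
    u = np.bincount(winners, minlength=E)
    return _borda_rank(u)


def simulate_corrupted_ranking(spec: CorruptionSpec) -> dict:
    """Algorithm-1-style simulation: the ground truth is the identity sequence
    and each repetition corrupts exactly ``M = floor(|S| x)`` pairwise orders.

    Returns pooled displacements (R x E), per-repetition overall errors, and
    the closed-form prediction when ``x`` lies in its validity region.
    """
    rng = np.random.default_rng(spec.seed)
    disp = np.empty((spec.R, spec.E), dtype=np.int64)
    errs = np.empty(spec.R)
    truth = np.arange(1, spec.E + 1)
    for r in range(spec.R):
        alpha_hat = corrupt_and_rank(spec.E, spec.M, rng)
        disp[r] = truth - alpha_hat
        errs[r] = math.sqrt(float(np.mean((disp[r] / spec.E) ** 2)))
    try:
        theory = theoretical_error(spec.x, spec.E)
    except ValueError:
        theory = None
    return {"displacements": disp, "errors": errs, "theory_error": theory,
            "restored_last": alpha_hat}


def _draw_intermediate(snapshot_sizes: Sequence[int], rng: np.random.Generator) -> np.ndarray:
    """Uniformly shuffle positions within each snapshot block: edge i of block k
    gets a position in {l_1+..+l_{k-1}+1, ..., l_1+..+l_k}."""
    alpha_star = np.empty(int(np.sum(snapshot_sizes)), dtype=np.int64)
    start = 0
    for l in snapshot_sizes:
        alpha_star[start:start + l] = start + 1 + rng.permutation(l)
        start += l
    return alpha_star


def displacement_vs_coarse_truth(snapshot_sizes,
                                 restored,
                                 R: int = 200, seed: int = 0) -> np.ndarray:
    """Displacements of a fixed restored sequence against R intermediate
    sequences drawn by shuffling the coarse ground truth within snapshots
    (the "real data" displacement procedure).  Returns an (R, E) array of
    ``D_i = alpha*_i - alpha_hat_i``.

    ``snapshot_sizes`` may be the block sizes l_1..l_n or a TemporalNetwork
    carrying snapshot labels; ``restored`` may be a position array or a
    RestoredSequence."""
    if hasattr(snapshot_sizes, "snapshot_sizes"):
        snapshot_sizes = snapshot_sizes.snapshot_sizes()
    if hasattr(restored, "positions"):
        restored = restored.positions
    sizes = [int(l) for l in snapshot_sizes]
    if any(l < 1 for l in sizes) or not sizes:
        raise ValueError("snapshot sizes must be positive")
    alpha_hat = np.asarray(restored, dtype=np.int64)
    e = int(np.sum(sizes))
    if alpha_hat.shape[0] != e:
        raise ValueError("restored length must equal sum of snapshot sizes")
    _check_permutation(alpha_hat, "restored")
    rng = np.random.default_rng(seed)
    disp = np.empty((R, e), dtype=np.int64)
    for r in range(R):
        disp[r] = _draw_intermediate(sizes, rng) - alpha_hat
    return disp


def displacement_sim_coarse(snapshot_sizes: Sequence[int], x: float,
                            R: int = 200, seed: int = 0) -> np.ndarray:
    """Simulation counterpart: per repetition draw an intermediate sequence,
    corrupt the fine pairwise order at accuracy ``x``, Borda-rank, and report
    ``D_i = alpha*_i - alpha_hat_i``."""
    sizes = [int(l) for l in snapshot_sizes]
    if any(l < 1 for l in sizes) or not sizes:
        raise ValueError("snapshot sizes must be positive")
    if not 0.5 < x <= 1.0:
        raise ValueError("x must lie in (0.5, 1]")
    e = int(np.sum(sizes))
    n_pairs = e * (e - 1) // 2
    m_correct = math.floor(n_pairs * x)
    rng = np.random.default_rng(seed)
    disp = np.empty((R, e), dtype=np.int64)
    for r in range(R):
        alpha_star = _draw_intermediate(sizes, rng)
        alpha_hat = corrupt_and_rank(e, m_correct, rng)
        disp[r] = alpha_star - alpha_hat
    return disp
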