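"""High-level entry points tying views, ensemble and Borda together."""

from __future__ import annotations

from typing import Optional, Tuple

import numpy as np

from .embeddings import EdgeViewSet, build_edge_views
from .network import TemporalNetwork
from .ordermodel import (PairwiseOrderModel, RestoredSequence, fit_order_model,
                         pairwise_accuracy, restore_network, sample_test_pairs)
from .transfer import (direct_validate, fit_alignment, transfer_restore)


def restore(net: TemporalNetwork, dim: int = 64, train_fraction: float = 0.05,
            seed: int = 0, max_pairs: Optional[int] = None,
            comparator_kwargs: Optional[dict] = None,
            views: Optional[EdgeViewSet] = None,
            ) -> Tuple[RestoredSequence, PairwiseOrderModel, EdgeViewSet]:
    """Full in-network restoration: views -> ensemble -> all-pairs Borda."""
    if views is None:
        views = build_edge_views(net, dim=dim, seed=seed)
    model = fit_order_model(net, views, train_fraction=train_fraction,
                            seed=seed, max_pairs=max_pairs,
                            comparator_kwargs=comparator_kwargs)
    seq = restore_network(model, views)
    return seq, model, views


def transfer_experiment(net_a: TemporalNetwork, net_b: TemporalNetwork,
                        dim: int = 64, train_fraction: float = 0.05,
                        seed: int = 0, max_pairs: Optional[int] = None,
                        n_test_pairs: int = 20000,
                        comparator_kwargs: Optional[dict] = None) -> dict:
    """Train on A (with history), evaluate on B by transfer and directly.

    Returns the in-network test accuracy on A, the transfer accuracy ``x_T``
    and the direct-validation accuracy ``x_D`` on B's held-out pairs.
    """
    views_a = build_edge_views(net_a, dim=dim, seed=seed)
    model = fit_order_model(net_a, views_a, train_fraction=train_fraction,
                            seed=seed, max_pairs=max_pairs,
                            comparator_kwargs=comparator_kwargs)
    test_a = sample_test_pairs(net_a, n_test_pairs, seed=seed + 101,
                               exclude=model.training_pairs.pair_ids)
    x_a = pairwise_accuracy(model, views_a, test_a)

    views_b = build_edge_views(net_b, dim=dim, seed=seed + 1)
    test_b = sample_test_pairs(net_b, n_test_pairs, seed=seed + 202)
    alignment = fit_alignment(views_a, views_b, net_a, net_b)
    res = transfer_restore(net_b, views_b, model, alignment,
                           test_pairs=test_b, restore=False)
    x_t = res["accuracy"]
    x_d = direct_validate(net_b, views_b, model, test_b)
    return {"x_source": x_a, "x_transfer": x_t, "x_direct": x_d,
            "model": model, "alignment": alignment}
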