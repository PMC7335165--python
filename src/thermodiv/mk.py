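"""Symmetric two-state Markov (Mk) character likelihood on a tree.

Used to fit the neutral transition rate behind permutation nulls for
binary-trait rate tests, and as one factor of the independent product
oracle for state-dependent birth-death likelihoods.
"""

from __future__ import annotations

from typing import Mapping

import numpy as np
from scipy.optimize import minimize_scalar

from .trees import Phylogeny

__all__ = ["mk_loglik", "mk_ml_q"]


def _states_vector(tree: Phylogeny, states: Mapping[str, int]) -> np.ndarray:
    labels = tree.tip_labels
    missing = [l for l in labels if l not in states]
    if missing:
        raise ValueError(f"states missing for tips: {missing[:5]}")
    vec = np.array([int(states[l]) for l in labels])
    if not np.all((vec == 0) | (vec == 1)):
        raise ValueError("states must be binary 0/1")
    return vec


def mk_loglik(
    tree: Phylogeny,
    states: Mapping[str, int],
    q: float,
    root: str = "stationary",
) -> float:
    """Log-likelihood of binary tip states under the symmetric Mk model.

    ``q`` is the per-Myr flip rate (off-diagonal rate-matrix entry).
    Root options: ``stationary`` averages the two root states with weight
    1/2 each; ``fitzjohn`` weights each root state by its own conditional
    likelihood (matching the root treatment of the SSE likelihoods).
    """
    if q < 0:
        raise ValueError("q must be non-negative")
    vec = _states_vector(tree, states)
    a = tree.arrays
    L = np.zeros((a.n_nodes, 2))
    L[np.arange(a.n_tips), vec] = 1.0
    logscale = 0.0
    for v in a.postorder:
        kids = a.children[v]
        if not kids:
            continue
        part = np.ones(2)
        for c in kids:
            t = a.blen[c]
            same = 0.5 * (1.0 + np.exp(-2.0 * q * t))
            diff = 1.0 - same
            part *= np.array(
                [same * L[c, 0] + diff * L[c, 1], diff * L[c, 0] + same * L[c, 1]]
            )
        m = part.max()
        if m <= 0:
            return -np.inf
        logscale += np.log(m)
        L[v] = part / m
    root_L = L[a.root]
    if root == "stationary":
        lik = 0.5 * root_L.sum()
    elif root == "fitzjohn":
        s = root_L.sum()
        lik = (root_L**2).sum() / s if s > 0 else 0.0
    else:
        raise ValueError(f"unknown root treatment {root!r}")
    if lik <= 0:
        return -np.inf
    return float(np.log(lik) + logscale)


def mk_ml_q(
    tree: Phylogeny,
    states: Mapping[str, int],
    floor: float | None = None,
    root: str = "stationary",
) -> float:
    """ML symmetric flip rate, bounded below by a configurable floor.

    The default floor corresponds to one expected transition across the
    whole tree (1 / total branch length), which prevents a degenerate
    zero-rate null when the observed states happen to be clumpy.
    """
    if floor is None:
        floor = 1.0 / tree.total_length
    res = minimize_scalar(
        lambda lq: -mk_loglik(tree, states, np.exp(lq), root=root),
        bounds=(np.log(1e-7), np.log(50.0)),
        method="bounded",
        options={"xatol": 1e-8},
    )
    return float(max(np.exp(res.x), floor))
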