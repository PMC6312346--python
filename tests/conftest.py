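"""Shared fixtures and independent reference oracles.

The oracles here (hypergeometric table enumeration, random tree generation)
are deliberately written without using the code paths they validate.
"""

from __future__ import annotations

import numpy as np
import pytest
from scipy.stats import hypergeom

from mztevo.simulate import SimulationConfig, simulate_dataset


@pytest.fixture(scope="session")
def noisy_sim():
    """Default-condition simulation: cv 0.2, leak 0.1, 14 tips."""
    return simulate_dataset(SimulationConfig(n_genes=400, seed=11))


@pytest.fixture(scope="session")
def noiseless_sim():
    """Zero replicate noise and zero leak: classification must be exact."""
    return simulate_dataset(
        SimulationConfig(n_genes=300, replicate_cv=0.0, leak_prob=0.0, seed=7)
    )


def random_tree_newick(rng: np.random.Generator, n_tips: int) -> str:
    """Random rooted binary tree with uniform(0.05, 2) branch lengths."""
    labels = [f"t{i}" for i in range(n_tips)]

    def build(lbls):
        if len(lbls) == 1:
            return f"{lbls[0]}:{rng.uniform(0.05, 2):.6f}"
        k = int(rng.integers(1, len(lbls)))
        return f"({build(lbls[:k])},{build(lbls[k:])}):{rng.uniform(0.05, 2):.6f}"

    k = int(rng.integers(1, n_tips))
    return f"({build(labels[:k])},{build(labels[k:])});"


def fisher_enum_p(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher p by summing hypergeometric probabilities of every
    table with the observed margins that is no more probable than the
    observed one (with the conventional 1+1e-7 tie tolerance)."""
    N = a + b + c + d
    K = a + c
    n = a + b
    lo = max(0, n - (N - K))
    hi = min(K, n)
    pmf = hypergeom.pmf(np.arange(lo, hi + 1), N, K, n)
    p_obs = hypergeom.pmf(a, N, K, n)
    return float(min(1.0, pmf[pmf <= p_obs * (1 + 1e-7)].sum()))
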