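"""Presence/absence character evolution on a fixed rooted phylogeny.

Transcript presence at each embryonic stage (mean FPKM >= threshold) is a
binary character per (gene, stage).  Characters evolve under a two-state
continuous-time Markov model (the Mk model with k=2) with gain rate ``q01``
(absent -> present) and loss rate ``q10`` per unit branch length.  The
transition probabilities over a branch of length t have the closed form

    P(1->1) = pi1 + pi0 * exp(-(q01+q10) t),   P(1->0) = 1 - P(1->1)
    P(0->0) = pi0 + pi1 * exp(-(q01+q10) t),   P(0->1) = 1 - P(0->0)

with stationary frequencies pi1 = q01/(q01+q10), pi0 = 1 - pi1.

Marginal posterior state probabilities at every node are computed exactly by
the pruning (up) pass followed by an outside (down) pass, with rates fitted
by maximum likelihood across all characters of a stage and the root prior
fixed to the stationary distribution (empirical Bayes).  A gain is called on
a branch when the parent is absent and the child present, each with
posterior >= 0.9 (configurable); a loss is the mirror image.  Branches
ending in a tip with unknown state are skipped.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import product

import numpy as np
import pandas as pd
from scipy.optimize import minimize

from .io import STAGES
from .trees import Tree

UNKNOWN = -1

RATE_BOUNDS = (1e-6, 1e3)


@dataclass(frozen=True)
class MkModel:
    """Two-state CTMC: rates per unit branch length plus a root prior."""

    q01: float
    q10: float
    root_prior: tuple[float, float] | None = None  # (pi0, pi1); None = stationary

    def __post_init__(self) -> None:
        if not (self.q01 > 0 and self.q10 > 0 and np.isfinite(self.q01) and np.isfinite(self.q10)):
            raise ValueError("rates must be finite and positive")
        if self.root_prior is not None:
            if abs(sum(self.root_prior) - 1.0) > 1e-9 or min(self.root_prior) < 0:
                raise ValueError("root prior must be a probability pair")

    @property
    def stationary(self) -> tuple[float, float]:
        s = self.q01 + self.q10
        return (self.q10 / s, self.q01 / s)

    @property
    def prior(self) -> np.ndarray:
        return np.asarray(self.root_prior if self.root_prior is not None else self.stationary)

    def transition_matrix(self, t: float) -> np.ndarray:
        """P[i, j] = probability of state j after time t given state i."""
        pi0, pi1 = self.stationary
        e = np.exp(-(self.q01 + self.q10) * t)
        return np.array(
            [[pi0 + pi1 * e, pi1 * (1 - e)], [pi0 * (1 - e), pi1 + pi0 * e]]
        )


# ---------------------------------------------------------------------------
# character coding


def encode_characters(
    conditions: dict[str, pd.DataFrame],
    orthologs: pd.DataFrame,
    threshold: float = 1.0,
) -> pd.DataFrame:
    """Binary presence characters per (gene, stage) over species.

    Returns an int8 frame indexed by the MultiIndex (gene, stage) with one
    column per species: 1 present (mean FPKM >= threshold), 0 absent,
    -1 unknown (blank ortholog).
    """
    from .io import ortholog_matrix

    blocks = []
    for stage in STAGES:
        mat = ortholog_matrix(conditions, orthologs, stage)
        states = pd.DataFrame(
            np.where(mat.isna(), UNKNOWN, (mat.to_numpy(dtype=float) >= threshold)),
            index=mat.index,
            columns=mat.columns,
            dtype=np.int8,
        )
        states.index = pd.MultiIndex.from_product(
            [states.index, [stage]], names=["gene", "stage"]
        )
        blocks.append(states)
    out = pd.concat(blocks).sort_index()
    return out


def character_frequencies(matrix: pd.DataFrame) -> tuple[float, float, float]:
    """(f_present, f_absent, f_unknown) over all matrix entries."""
    arr = matrix.to_numpy()
    if arr.size == 0:
        raise ValueError("empty character matrix")
    n = arr.size
    return (
        float((arr == 1).sum() / n),
        float((arr == 0).sum() / n),
        float((arr == UNKNOWN).sum() / n),
    )


def states_array(matrix: pd.DataFrame, tree: Tree, stage: str | None = None) -> tuple[np.ndarray, pd.Index]:
    """Character x tip int8 array aligned to ``tree.tips`` order."""
    sub = matrix.xs(stage, level="stage") if stage is not None else matrix
    missing = [sp for sp in tree.tip_labels if sp not in sub.columns]
    if missing:
        raise ValueError(f"character matrix lacks species: {missing}")
    return sub[tree.tip_labels].to_numpy(dtype=np.int8), sub.index


# ---------------------------------------------------------------------------
# pruning likelihood and marginal posteriors


def _tip_partials(tree: Tree, states: np.ndarray) -> np.ndarray:
    """Partial likelihood array (n_nodes, n_char, 2) with tips filled in."""
    n_char = states.shape[0]
    L = np.ones((tree.n_nodes, n_char, 2))
    for k, tip in enumerate(tree.tips):
        s = states[:, k]
        L[tip, s == 0, 1] = 0.0
        L[tip, s == 1, 0] = 0.0
    return L


def _transition_matrices(tree: Tree, model: MkModel) -> np.ndarray:
    P = np.empty((tree.n_nodes, 2, 2))
    for v in range(tree.n_nodes):
        P[v] = model.transition_matrix(tree.blen[v])
    return P


def _upward(tree: Tree, states: np.ndarray, model: MkModel):
    """Pruning pass; returns (L, logscale, P) with per-character scaling."""
    L = _tip_partials(tree, states)
    P = _transition_matrices(tree, model)
    logscale = np.zeros(states.shape[0])
    for v in range(tree.n_nodes):
        if tree.is_tip(v):
            continue
        acc = np.ones_like(L[v])
        for c in tree.children[v]:
            acc *= L[c] @ P[c].T
        scale = acc.max(axis=1)
        safe = np.where(scale > 0, scale, 1.0)
        L[v] = acc / safe[:, None]
        with np.errstate(divide="ignore"):
            logscale += np.where(scale > 0, np.log(safe), -np.inf)
    return L, logscale, P

def pruning_loglik(tree: Tree, states: np.ndarray, model: MkModel) -> np.ndarray:
    """Log-likelihood per character (rows of ``states``) by Felsenstein pruning.

    Unknown tip states contribute partial likelihood (1, 1); impossible data
    yield -inf.
    """
    states = np.atleast_2d(np.asarray(states, dtype=np.int8))
    if (states == UNKNOWN).all(axis=1).any():
        raise ValueError("character with all tips unknown")
    L, logscale, _ = _upward(tree, states, model)
    site = L[tree.root] @ model.prior
    with np.errstate(divide="ignore"):
        return np.log(site) + logscale


def pruning_likelihood(tree: Tree, states: np.ndarray, model: MkModel) -> float:
    """Single-character convenience wrapper around :func:`pruning_loglik`."""
    return float(pruning_loglik(tree, states, model)[0])


def marginal_posteriors(tree: Tree, states: np.ndarray, model: MkModel) -> np.ndarray:
    """Marginal P(state) at every node: array (n_char, n_nodes, 2).

    Up-down (inside-outside) algorithm; observed tips come out exactly
    one-hot, unknown tips get their true marginal.  Rows with impossible
    data are NaN.
    """
    states = np.atleast_2d(np.asarray(states, dtype=np.int8))
    n_char = states.shape[0]
    L, _, P = _upward(tree, states, model)
    out = np.zeros((tree.n_nodes, n_char, 2))
    out[tree.root] = model.prior
    # messages child -> parent, reused in the outside recursion
    msg = {c: L[c] @ P[c].T for c in range(tree.n_nodes - 1)}
    for u in reversed(range(tree.n_nodes)):  # preorder = reverse postorder
        if tree.is_tip(u):
            continue
        for c in tree.children[u]:
            other = out[u].copy()
            for c2 in tree.children[u]:
                if c2 != c:
                    other *= msg[c2]
            res = other @ P[c]
            norm = res.sum(axis=1, keepdims=True)
            out[c] = np.divide(res, norm, out=np.zeros_like(res), where=norm > 0)
    post = out * L
    total = post.sum(axis=2, keepdims=True)
    post = np.divide(post, total, out=np.full_like(post, np.nan), where=total > 0)
    return np.transpose(post, (1, 0, 2))


def brute_force_marginals(tree: Tree, states: np.ndarray, model: MkModel) -> np.ndarray:
    """Exact marginals for one character by enumerating every assignment of
    states to internal nodes and unknown tips.  Exponential in tree size;
    reference implementation for validating the up-down recursion."""
    states = np.asarray(states, dtype=np.int8)
    free = [v for v in range(tree.n_nodes) if tree.is_tip(v)
            and states[tree.tips.index(v)] == UNKNOWN] + tree.internal
    fixed = {
        v: int(states[k]) for k, v in enumerate(tree.tips) if states[k] != UNKNOWN
    }
    prior = model.prior
    P = _transition_matrices(tree, model)
    joint = np.zeros((tree.n_nodes, 2))
    for assign in product((0, 1), repeat=len(free)):
        full = dict(fixed)
        full.update(dict(zip(free, assign)))
        p = prior[full[tree.root]]
        for v in range(tree.n_nodes - 1):
            p *= P[v][full[tree.parent[v]], full[v]]
        for v, s in full.items():
            joint[v, s] += p
    total = joint[tree.root].sum()
    return joint / total if total > 0 else np.full_like(joint, np.nan)


# ---------------------------------------------------------------------------
# rate fitting


def fit_rates(
    tree: Tree,
    states: np.ndarray,
    x0: tuple[float, float] = (1.0, 1.0),
) -> MkModel:
    """Maximum-likelihood gain/loss rates shared across all characters.

    Optimizes the summed pruning log-likelihood over (log q01, log q10) with
    the root prior tied to the stationary distribution of the trial rates.
    Rates are bounded in [1e-6, 1e3]; hitting a bound emits a warning.
    """
    states = np.atleast_2d(np.asarray(states, dtype=np.int8))
    lo, hi = np.log(RATE_BOUNDS[0]), np.log(RATE_BOUNDS[1])

    def nll(x: np.ndarray) -> float:
        model = MkModel(q01=float(np.exp(x[0])), q10=float(np.exp(x[1])))
        ll = pruning_loglik(tree, states, model)
        return float(np.inf if not np.isfinite(ll).all() else -ll.sum())

    res = minimize(
        nll,
        x0=np.log(np.asarray(x0, dtype=float)),
        method="L-BFGS-B",
        bounds=[(lo, hi), (lo, hi)],
    )
    q01, q10 = np.exp(res.x)
    if np.any(np.isclose(res.x, lo, atol=1e-6)) or np.any(np.isclose(res.x, hi, atol=1e-6)):
        warnings.warn(
            f"rate estimate at optimizer bound (q01={q01:.3g}, q10={q10:.3g}); "
            "data may be uninformative for one direction"
        )
    return MkModel(q01=float(q01), q10=float(q10))


# ---------------------------------------------------------------------------
# event calling


def call_transitions(
    tree: Tree,
    posteriors: np.ndarray,
    char_index,
    states: np.ndarray | None = None,
    threshold: float = 0.90,
) -> pd.DataFrame:
    """Gain/loss events on branches at a posterior threshold.

    ``posteriors`` is (n_char, n_nodes, 2); ``char_index`` labels the
    characters (anything list-like, e.g. the (gene, stage) index).  When
    ``states`` is given, branches ending in an unknown tip are skipped.
    Per branch and character at most one event: gain iff parent P0 >=
    threshold and child P1 >= threshold, loss for the mirror image.
    """
    rows = []
    tip_pos = {v: k for k, v in enumerate(tree.tips)}
    for c in range(tree.n_nodes - 1):
        u = tree.parent[c]
        keep = np.ones(posteriors.shape[0], dtype=bool)
        if states is not None and c in tip_pos:
            keep = states[:, tip_pos[c]] != UNKNOWN
        p_u1 = posteriors[:, u, 1]
        p_c1 = posteriors[:, c, 1]
        gain = keep & (1 - p_u1 >= threshold) & (p_c1 >= threshold)
        loss = keep & (p_u1 >= threshold) & (1 - p_c1 >= threshold)
        for idx in np.nonzero(gain)[0]:
            rows.append((char_index[idx], tree.labels[u], tree.labels[c], "gain",
                         float(1 - p_u1[idx]), float(p_c1[idx])))
        for idx in np.nonzero(loss)[0]:
            rows.append((char_index[idx], tree.labels[u], tree.labels[c], "loss",
                         float(p_u1[idx]), float(1 - p_c1[idx])))
    return pd.DataFrame(
        rows, columns=["character", "parent", "child", "direction", "parent_P", "child_P"]
    )


# ---------------------------------------------------------------------------
# Fitch parsimony (low-rate-limit oracle)


def mpr_state_sets(tree: Tree, states: np.ndarray) -> dict[int, set[int]]:
    """Per-internal-node state sets over *all* most-parsimonious
    reconstructions of one character, by exhaustive minimization.

    Exponential in the internal node count; reference oracle for the
    low-rate limit of the marginal reconstruction (Fitch first-pass sets do
    not enumerate MPR states at non-root nodes).  Unknown tips are treated
    as free, like internal nodes.
    """
    states = np.asarray(states, dtype=np.int8)
    fixed = {v: int(states[k]) for k, v in enumerate(tree.tips) if states[k] != UNKNOWN}
    free = [v for v in range(tree.n_nodes) if v not in fixed]
    best: int | None = None
    sets: dict[int, set[int]] = {}
    for assign in product((0, 1), repeat=len(free)):
        full = dict(fixed)
        full.update(dict(zip(free, assign)))
        cost = sum(full[v] != full[tree.parent[v]] for v in range(tree.n_nodes - 1))
        if best is None or cost < best:
            best = cost
            sets = {v: {full[v]} for v in tree.internal}
        elif cost == best:
            for v in tree.internal:
                sets[v].add(full[v])
    return sets


def fitch_parsimony(tree: Tree, states: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Fitch first pass over binary characters.

    Returns (changes, sets): minimum change count per character, and the
    per-node most-parsimonious state sets encoded as bitmasks (1 = {0},
    2 = {1}, 3 = {0, 1}).  Unknown tips carry {0, 1}.
    """
    states = np.atleast_2d(np.asarray(states, dtype=np.int8))
    n_char = states.shape[0]
    sets = np.zeros((tree.n_nodes, n_char), dtype=np.uint8)
    for k, tip in enumerate(tree.tips):
        s = states[:, k]
        sets[tip] = np.where(s == UNKNOWN, 3, np.where(s == 1, 2, 1))
    changes = np.zeros(n_char, dtype=int)
    for v in range(tree.n_nodes):
        if tree.is_tip(v):
            continue
        inter = np.full(n_char, 3, dtype=np.uint8)
        union = np.zeros(n_char, dtype=np.uint8)
        for c in tree.children[v]:
            inter &= sets[c]
            union |= sets[c]
        empty = inter == 0
        changes += empty.astype(int)
        sets[v] = np.where(empty, union, inter)
    return changes, sets.T
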