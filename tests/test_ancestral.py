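"""Mk-model likelihood, marginal reconstruction, event calling, parsimony."""

import numpy as np
import pandas as pd
import pytest

from mztevo import ancestral as anc
from mztevo.ancestral import MkModel, UNKNOWN
from mztevo.trees import read_tree
from conftest import random_tree_newick


@pytest.fixture(scope="module")
def quartet():
    return read_tree("((a:0.3,b:0.4):0.2,(c:0.5,d:0.1):0.3);")


def test_encode_characters_boundaries_and_blanks():
    conditions = {
        "A": pd.DataFrame({"stage2": [1.0, 0.99], "stage5": [0.0, 5.0]}, index=["gx@A", "gy@A"]),
        "B": pd.DataFrame({"stage2": [2.0, 0.0], "stage5": [2.0, 0.0]}, index=["gx@B", "gy@B"]),
    }
    orth = pd.DataFrame({"A": ["gx@A", "gy@A"], "B": ["gx@B", np.nan]}, index=["gx", "gy"])
    chars = anc.encode_characters(conditions, orth)
    assert chars.loc[("gx", "stage2"), "A"] == 1  # FPKM 1.0 is present
    assert chars.loc[("gy", "stage2"), "A"] == 0  # 0.99 is below threshold
    assert chars.loc[("gy", "stage2"), "B"] == UNKNOWN
    assert chars.loc[("gy", "stage5"), "B"] == UNKNOWN
    f1, f0, fu = anc.character_frequencies(chars)
    assert f1 + f0 + fu == pytest.approx(1.0)
    # 8 entries: gx present 3x, absent 1x; gy present 1x, absent 1x, unknown 2x
    assert (f1, f0, fu) == (pytest.approx(4 / 8), pytest.approx(2 / 8), pytest.approx(2 / 8))


def test_degenerate_tree_likelihood_reduces_to_prior():
    # zero-length branches: observing (1, 1) forces the root to state 1
    tree = read_tree("(a:0.0,b:0.0);")
    model = MkModel(q01=0.7, q10=0.3)
    ll = anc.pruning_likelihood(tree, np.array([1, 1], dtype=np.int8), model)
    assert ll == pytest.approx(np.log(model.stationary[1]))


def test_impossible_data_is_minus_inf():
    tree = read_tree("(a:0.0,b:0.0);")
    model = MkModel(q01=0.5, q10=0.5)
    ll = anc.pruning_likelihood(tree, np.array([0, 1], dtype=np.int8), model)
    assert ll == -np.inf


def test_all_unknown_character_rejected(quartet):
    with pytest.raises(ValueError, match="unknown"):
        anc.pruning_loglik(quartet, np.full(4, UNKNOWN, dtype=np.int8), MkModel(1, 1))


def test_three_tip_likelihood_matches_state_enumeration():
    """Brute-force sum over the two internal nodes equals pruning."""
    tree = read_tree("((a:0.3,b:0.7):0.4,c:0.6);")
    model = MkModel(q01=0.8, q10=0.4)
    P = {v: model.transition_matrix(tree.blen[v]) for v in range(tree.n_nodes)}
    tips = dict(zip(tree.tip_labels, [1, 0, 1]))
    states = np.array([tips[lbl] for lbl in tree.tip_labels], dtype=np.int8)
    # nodes: postorder puts the (a,b) ancestor before the root
    inner = [v for v in tree.internal if v != tree.root][0]
    a, b = tree.children[inner]
    total = 0.0
    for s_root in (0, 1):
        for s_in in (0, 1):
            p = model.prior[s_root]
            p *= P[inner][s_root, s_in]
            p *= P[a][s_in, tips[tree.labels[a]]] * P[b][s_in, tips[tree.labels[b]]]
            c = [v for v in tree.children[tree.root] if v != inner][0]
            p *= P[c][s_root, tips[tree.labels[c]]]
            total += p
    assert anc.pruning_likelihood(tree, states, model) == pytest.approx(np.log(total), abs=1e-12)


def test_likelihood_scale_invariance(quartet):
    rng = np.random.default_rng(0)
    states = rng.integers(0, 2, (20, 4)).astype(np.int8)
    m1 = MkModel(q01=0.9, q10=0.4)
    m2 = MkModel(q01=0.9 * 3, q10=0.4 * 3)
    scaled = read_tree("((a:0.1,b:0.13333333333333333):0.06666666666666667,"
                       "(c:0.16666666666666666,d:0.03333333333333333):0.1);")
    ll1 = anc.pruning_loglik(quartet, states, m1)
    ll2 = anc.pruning_loglik(scaled, states, m2)
    np.testing.assert_allclose(ll1, ll2, atol=1e-12)
    p1 = anc.marginal_posteriors(quartet, states, m1)
    p2 = anc.marginal_posteriors(scaled, states, m2)
    np.testing.assert_allclose(p1, p2, atol=1e-12)


def test_marginals_match_enumeration_on_random_instances():
    """Up-down marginals equal brute-force enumeration (trees of 3-6 tips,
    random rates and branch lengths, unknown states included)."""
    rng = np.random.default_rng(123)
    max_dev = 0.0
    for _ in range(100):
        tree = read_tree(random_tree_newick(rng, int(rng.integers(3, 7))))
        model = MkModel(
            q01=float(rng.uniform(0.05, 3)), q10=float(rng.uniform(0.05, 3))
        )
        states = rng.choice([0, 1, UNKNOWN], size=len(tree.tips), p=[0.4, 0.4, 0.2]).astype(np.int8)
        if (states == UNKNOWN).all():
            states[0] = 1
        exact = anc.brute_force_marginals(tree, states, model)
        fast = anc.marginal_posteriors(tree, states[None, :], model)[0]
        max_dev = max(max_dev, float(np.max(np.abs(fast - exact))))
    assert max_dev < 1e-8


def test_marginal_limits(quartet):
    # zero-length branches, all tips present: every node is present
    tree0 = read_tree("((a:0,b:0):0,(c:0,d:0):0);")
    post = anc.marginal_posteriors(tree0, np.ones((1, 4), dtype=np.int8), MkModel(0.5, 0.5))
    np.testing.assert_allclose(post[0, :, 1], 1.0)
    # very long branches: internal posteriors revert to the root prior
    treeL = read_tree("((a:500,b:500):500,(c:500,d:500):500);")
    model = MkModel(q01=0.75, q10=0.25)
    post = anc.marginal_posteriors(treeL, np.array([[1, 0, 1, 0]], dtype=np.int8), model)
    for v in treeL.internal:
        np.testing.assert_allclose(post[0, v], model.prior, atol=1e-6)
    # posterior rows always sum to one
    rng = np.random.default_rng(7)
    states = rng.integers(0, 2, (50, 4)).astype(np.int8)
    post = anc.marginal_posteriors(quartet, states, model)
    np.testing.assert_allclose(post.sum(axis=2), 1.0, atol=1e-12)


def test_rate_recovery_from_simulated_characters():
    """ML rates on 2,000 characters recover the generating rates within 20%."""
    from mztevo.simulate import DEFAULT_TREE, simulate_presence

    tree = read_tree(DEFAULT_TREE)
    rng = np.random.default_rng(99)
    true_q01, true_q10 = 0.5, 1.0
    states = simulate_presence(tree, true_q01, true_q10, None, 2000, rng)
    tips = states[tree.tips, :].T
    model = anc.fit_rates(tree, tips)
    assert model.q01 == pytest.approx(true_q01, rel=0.2)
    assert model.q10 == pytest.approx(true_q10, rel=0.2)


def test_constant_characters_drive_loss_rate_to_bound(quartet):
    states = np.ones((50, 4), dtype=np.int8)
    with pytest.warns(UserWarning, match="bound"):
        model = anc.fit_rates(quartet, states)
    assert model.q10 == pytest.approx(anc.RATE_BOUNDS[0], rel=1e-3)


def test_transition_calls_and_threshold_monotonicity(quartet):
    post = np.zeros((1, quartet.n_nodes, 2))
    post[..., 0] = 0.95
    post[..., 1] = 0.05
    a = quartet.tip_index["a"]
    post[0, a] = [0.05, 0.95]  # a present, everything else absent
    states = np.array([[1, 0, 0, 0]], dtype=np.int8)
    events = anc.call_transitions(quartet, post, ["g1"], states, threshold=0.90)
    assert len(events) == 1
    ev = events.iloc[0]
    assert ev["direction"] == "gain" and ev["child"] == "a"
    # below-threshold child posterior: no call
    post[0, a] = [0.15, 0.85]
    assert len(anc.call_transitions(quartet, post, ["g1"], states, 0.90)) == 0
    # loss is the mirror image
    post[..., 0] = 0.07
    post[..., 1] = 0.93
    post[0, a] = [0.93, 0.07]
    states = np.array([[0, 1, 1, 1]], dtype=np.int8)
    events = anc.call_transitions(quartet, post, ["g1"], states, 0.90)
    assert list(events["direction"]) == ["loss"]
    # raising the threshold never adds events
    rng = np.random.default_rng(5)
    post = rng.dirichlet((1, 1), size=(40, quartet.n_nodes))
    states = rng.integers(0, 2, (40, 4)).astype(np.int8)
    counts = [
        len(anc.call_transitions(quartet, post, list(range(40)), states, thr))
        for thr in (0.5, 0.7, 0.9, 0.99)
    ]
    assert counts == sorted(counts, reverse=True)


def test_unknown_tip_branches_are_skipped(quartet):
    post = np.zeros((1, quartet.n_nodes, 2))
    post[..., 0] = 0.95
    post[..., 1] = 0.05
    a = quartet.tip_index["a"]
    post[0, a] = [0.05, 0.95]
    states = np.array([[UNKNOWN, 0, 0, 0]], dtype=np.int8)
    assert len(anc.call_transitions(quartet, post, ["g1"], states, 0.90)) == 0


def test_fitch_textbook_cases(quartet):
    changes, _ = anc.fitch_parsimony(quartet, np.array([[1, 1, 1, 1]], dtype=np.int8))
    assert changes[0] == 0
    # balanced quartet ((1,1),(0,0)): one change
    changes, _ = anc.fitch_parsimony(quartet, np.array([[1, 1, 0, 0]], dtype=np.int8))
    assert changes[0] == 1
    changes, _ = anc.fitch_parsimony(quartet, np.array([[1, 0, 1, 0]], dtype=np.int8))
    assert changes[0] == 2


def test_fitch_matches_exhaustive_minimization():
    """Fitch counts equal the minimum changes over all internal assignments."""
    from itertools import product

    rng = np.random.default_rng(11)
    tree = read_tree(random_tree_newick(rng, 6))
    states = rng.integers(0, 2, (30, 6)).astype(np.int8)
    changes, _ = anc.fitch_parsimony(tree, states)
    internal = tree.internal
    for row, expected in zip(states, changes):
        tips = dict(zip(tree.tips, row))
        best = np.inf
        for assign in product((0, 1), repeat=len(internal)):
            full = dict(tips)
            full.update(dict(zip(internal, assign)))
            cost = sum(
                full[v] != full[tree.parent[v]] for v in range(tree.n_nodes - 1)
            )
            best = min(best, cost)
        assert expected == best


def test_low_rate_limit_agrees_with_parsimony():
    """At rate x height << 1, MAP marginal states match the unique
    most-parsimonious state wherever one exists."""
    rng = np.random.default_rng(21)
    tree = read_tree(random_tree_newick(rng, 6))
    scale = 1e-4 / (tree.height() or 1.0)
    model = MkModel(q01=scale, q10=scale)
    states = rng.integers(0, 2, (200, 6)).astype(np.int8)
    post = anc.marginal_posteriors(tree, states, model)
    agree = total = 0
    for i, row in enumerate(states):
        for v, mp in anc.mpr_state_sets(tree, row).items():
            if len(mp) == 1:
                total += 1
                agree += int(post[i, v, 1] > 0.5) == next(iter(mp))
    assert agree / total >= 0.99
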