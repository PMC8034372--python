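"""Independent reference implementations used only as test oracles.

These deliberately avoid the package's bitmask state encoding and pruning
recursion: states are frozensets of area letters, cladogenetic weights are
rebuilt from the model definitions, transition matrices come straight from
scipy's expm, and the likelihood is an explicit sum over every assignment
of states to internal nodes. Slow, but correct by construction on tiny
instances.
"""

from __future__ import annotations

import itertools
from typing import FrozenSet

import numpy as np
from scipy.linalg import expm


def oracle_states(areas: str, max_range_size: int, exclusions=()):
    """All allowed non-null states as frozensets, plus the null set."""
    excl = {frozenset(e) for e in exclusions}
    out = [frozenset()]
    for r in range(1, max_range_size + 1):
        for combo in itertools.combinations(areas, r):
            s = frozenset(combo)
            if s not in excl:
                out.append(s)
    return out


def oracle_rate_matrix(states, areas: str, d: float, e: float) -> np.ndarray:
    idx = {s: i for i, s in enumerate(states)}
    n = len(states)
    Q = np.zeros((n, n))
    for s in states:
        if not s:
            continue
        for a in areas:
            if a not in s and frozenset(s | {a}) in idx:
                Q[idx[s], idx[frozenset(s | {a})]] += d * len(s)
            if a in s and frozenset(s - {a}) in idx:
                Q[idx[s], idx[frozenset(s - {a})]] += e
    np.fill_diagonal(Q, -Q.sum(axis=1))
    return Q


def oracle_clado(parent: FrozenSet[str], family: str, j: float, areas: str, allowed):
    """Scenario dict {(left, right): (category, prob)} rebuilt from the
    model definitions with set arithmetic."""
    allowed_set = {s for s in allowed if s}
    raw = {}

    def put(l, r, cat, w):
        if l in allowed_set and r in allowed_set and w > 0:
            raw.setdefault((l, r), (cat, w))

    if family == "DEC":
        if len(parent) == 1:
            put(parent, parent, "sympatry-copy", 1.0)
        else:
            for a in sorted(parent):
                put(parent, frozenset({a}), "subset-sympatry", 1.0)
                put(frozenset({a}), parent, "subset-sympatry", 1.0)
                put(frozenset({a}), parent - {a}, "vicariance", 1.0)
                put(parent - {a}, frozenset({a}), "vicariance", 1.0)
    elif family == "DIVALIKE":
        if len(parent) == 1:
            put(parent, parent, "sympatry-copy", 1.0)
        else:
            members = sorted(parent)
            for r in range(1, len(members)):
                for combo in itertools.combinations(members, r):
                    left = frozenset(combo)
                    put(left, parent - left, "vicariance", 1.0)
    elif family == "BAYAREALIKE":
        put(parent, parent, "sympatry-copy", 1.0)
    else:
        raise ValueError(family)
    if j > 0:
        for a in areas:
            if a not in parent:
                put(parent, frozenset({a}), "jump", j)
                put(frozenset({a}), parent, "jump", j)
    total = sum(w for _, w in raw.values())
    return {k: (cat, w / total) for k, (cat, w) in raw.items()}


def _tree_tables(tree):
    internal = [i for i in tree.postorder if not tree.is_tip[i]]
    return internal


def brute_force_likelihood(
    tree, codings: dict, areas: str, max_range_size: int,
    d: float, e: float, j: float = 0.0, family: str = "DEC",
    exclusions=(), root_state: FrozenSet[str] | None = None,
    want_marginals: bool = False,
):
    """Exhaustive likelihood (and optionally node marginals) by summing over
    every assignment of non-null states to internal nodes.

    ``codings`` maps tip label -> set of letters.
    """
    states = oracle_states(areas, max_range_size, exclusions)
    idx = {s: i for i, s in enumerate(states)}
    Q = oracle_rate_matrix(states, areas, d, e)
    P = {
        i: expm(Q * tree.edge_length[i])
        for i in range(tree.n_nodes)
        if tree.parent[i] >= 0
    }
    nonnull = [s for s in states if s]
    clado = {
        s: oracle_clado(s, family, j, areas, states) for s in nonnull
    }
    internal = _tree_tables(tree)
    tip_state = {
        i: frozenset(codings[tree.tip_label[i]])
        for i in range(tree.n_nodes)
        if tree.is_tip[i]
    }
    if root_state is None:
        prior = {s: 1.0 / len(nonnull) for s in nonnull}
    else:
        prior = {frozenset(root_state): 1.0}

    total = 0.0
    marg = {i: np.zeros(len(states)) for i in internal}
    for assign in itertools.product(nonnull, repeat=len(internal)):
        state_of = dict(zip(internal, assign))
        s_root = state_of[tree.root_index]
        if s_root not in prior:
            continue
        p = prior[s_root]
        for v in internal:
            cx, cy = tree.children[v]
            sx_end = tip_state.get(cx, state_of.get(cx))
            sy_end = tip_state.get(cy, state_of.get(cy))
            term = 0.0
            for (l, r), (_, w) in clado[state_of[v]].items():
                term += (
                    w * P[cx][idx[l], idx[sx_end]] * P[cy][idx[r], idx[sy_end]]
                )
            p *= term
            if p == 0.0:
                break
        total += p
        if want_marginals and p > 0:
            for v in internal:
                marg[v][idx[state_of[v]]] += p
    lnL = np.log(total) if total > 0 else -np.inf
    if not want_marginals:
        return lnL, states
    for v in internal:
        marg[v] /= total
    return lnL, states, marg


def brute_force_binary(tree, tips01: dict, rate: float):
    """Two-state likelihood and per-node presence marginals by enumeration."""
    internal = _tree_tables(tree)

    def p_same(t):
        return 0.5 + 0.5 * np.exp(-2.0 * rate * t)

    def trans(t, a, b):
        return p_same(t) if a == b else 1.0 - p_same(t)

    state_at_tip = {
        i: tips01[tree.tip_label[i]] for i in range(tree.n_nodes) if tree.is_tip[i]
    }
    total = 0.0
    present = {i: 0.0 for i in internal}
    for assign in itertools.product((0, 1), repeat=len(internal)):
        state_of = dict(zip(internal, assign))
        p = 0.5  # root prior
        for v in internal:
            for c in tree.children[v]:
                sc = state_at_tip.get(c, state_of.get(c))
                p *= trans(tree.edge_length[c], state_of[v], sc)
        total += p
        for v in internal:
            if state_of[v] == 1:
                present[v] += p
    return np.log(total), {v: present[v] / total for v in internal}
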