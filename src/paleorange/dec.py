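"""Dispersal-extinction-cladogenesis (DEC) family likelihoods.

The model is a continuous-time Markov chain over range states (subsets of
areas). Along a branch (anagenesis) a lineage gains area ``a`` at rate
``d * |S|`` (every occupied area is a potential source) and loses an
occupied area at rate ``e``; the null (empty) range is absorbing. At each
split (cladogenesis) the parent range is partitioned between the two
daughters according to the model family:

* ``DEC`` — single-area parents are copied to both daughters (sympatry);
  wider parents either pass the full range to one daughter and a single
  constituent area to the other (subset sympatry) or split into two
  disjoint ranges with one daughter receiving exactly one area (classic
  vicariance constraint).
* ``DIVALIKE`` — single-area parents are copied; wider parents undergo
  vicariance into any ordered disjoint bipartition.
* ``BAYAREALIKE`` — both daughters always copy the parent range.

With founder-event ("jump") dispersal enabled, any parent may additionally
send one daughter to a single *unoccupied* area while the other daughter
keeps the full parent range; each jump scenario carries weight ``j``
against weight 1 for each non-jump scenario, and the per-parent weights
are normalized to a probability distribution. Setting ``j = 0`` recovers
the base model exactly, so the +j variant nests it.

The likelihood is computed by Felsenstein pruning with per-branch matrix
exponentials and a cladogenetic convolution at each internal node; the
root likelihood averages the conditional likelihoods uniformly over the
allowed non-null states (no cladogenetic event above the root). Excluded
range states are absent from the state space altogether — they have no
rows in the rate matrix and never appear in cladogenetic outcomes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, NamedTuple, Sequence

import numpy as np
from scipy.linalg import expm
from scipy.optimize import minimize

from paleorange.chronogram import Chronogram
from paleorange.ranges import RangeData, StateSpace

__all__ = [
    "DECParams",
    "FitResult",
    "AncestralReconstruction",
    "CladoScenario",
    "build_rate_matrix",
    "clado_distribution",
    "loglik",
    "fit_ml",
    "ancestral_marginals",
    "PruningEngine",
]

Family = Literal["DEC", "DIVALIKE", "BAYAREALIKE"]
FAMILIES = ("DEC", "DIVALIKE", "BAYAREALIKE")

J_MAX = 3.0


@dataclass(frozen=True)
class DECParams:
    """Free parameters of a DEC-family model.

    d : range-expansion (dispersal) rate, events per source area per Ma
    e : range-loss (local extinction) rate, per occupied area per Ma
    j : founder-event weight (dimensionless, 0 <= j <= 3); 0 for -j models
    family : cladogenetic model family
    """

    d: float
    e: float
    j: float = 0.0
    family: Family = "DEC"

    def __post_init__(self) -> None:
        if self.d < 0 or self.e < 0:
            raise ValueError("rates must be non-negative")
        if not (0.0 <= self.j <= J_MAX):
            raise ValueError(f"j must lie in [0, {J_MAX}]")
        if self.family not in FAMILIES:
            raise ValueError(f"unknown model family {self.family!r}")

    @property
    def plus_j(self) -> bool:
        return self.j > 0.0

    @property
    def k(self) -> int:
        """Free-parameter count: 2 for the base model, 3 with +j."""
        return 3 if self.plus_j else 2

    @property
    def name(self) -> str:
        return self.family + ("+J" if self.plus_j else "")


class CladoScenario(NamedTuple):
    left: int  # state bitmask inherited by the left daughter
    right: int
    category: str  # sympatry-copy | subset-sympatry | vicariance | jump
    prob: float


def build_rate_matrix(params: DECParams, space: StateSpace) -> np.ndarray:
    """Anagenetic generator Q over the state space (per-Ma rates).

    Q[S, S + a] = d * |S| for each gainable area a; Q[S, S - a] = e; rows
    sum to zero. Transitions into excluded states simply do not exist.
    """
    n = len(space)
    all_areas = (1 << len(space.areas)) - 1
    Q = np.zeros((n, n))
    for i, s in enumerate(space.states):
        if s == 0:
            continue  # null range is absorbing
        size = bin(s).count("1")
        gain = all_areas & ~s
        while gain:
            a = gain & -gain
            gain ^= a
            t = s | a
            jdx = space.index.get(t)
            if jdx is not None:
                Q[i, jdx] += params.d * size
        lose = s
        while lose:
            a = lose & -lose
            lose ^= a
            t = s & ~a
            jdx = space.index.get(t)
            if jdx is not None:
                Q[i, jdx] += params.e
    np.fill_diagonal(Q, Q.diagonal() - Q.sum(axis=1))
    return Q


def _enumerate_splits(s: int) -> list[tuple[int, int]]:
    """All ordered disjoint bipartitions (L, R) with L | R = s, both non-empty."""
    bits = [1 << i for i in range(s.bit_length()) if s >> i & 1]
    out = []
    for pick in range(1, 1 << len(bits)):
        left = 0
        for k, b in enumerate(bits):
            if pick >> k & 1:
                left |= b
        right = s & ~left
        if right:
            out.append((left, right))
    return out


def clado_distribution(
    parent: int, params: DECParams, space: StateSpace
) -> list[CladoScenario]:
    """Cladogenetic outcome distribution for a non-null parent state.

    Scenario weights are 1 per non-jump scenario and ``j`` per jump
    scenario, normalized per parent. Outcomes whose daughter states are not
    in the allowed state space are dropped before normalization.
    """
    if parent == 0:
        raise ValueError("null range cannot undergo cladogenesis")
    if parent not in space.index:
        raise ValueError("parent state not in the state space")
    size = bin(parent).count("1")
    raw: dict[tuple[int, int], tuple[str, float]] = {}

    def add(left: int, right: int, cat: str, w: float) -> None:
        if left in space.index and right in space.index and w > 0:
            raw.setdefault((left, right), (cat, w))

    fam = params.family
    if fam == "DEC":
        if size == 1:
            add(parent, parent, "sympatry-copy", 1.0)
        else:
            singles = [1 << i for i in range(parent.bit_length()) if parent >> i & 1]
            for a in singles:
                add(parent, a, "subset-sympatry", 1.0)
                add(a, parent, "subset-sympatry", 1.0)
            for left, right in _enumerate_splits(parent):
                if min(bin(left).count("1"), bin(right).count("1")) == 1:
                    add(left, right, "vicariance", 1.0)
    elif fam == "DIVALIKE":
        if size == 1:
            add(parent, parent, "sympatry-copy", 1.0)
        else:
            for left, right in _enumerate_splits(parent):
                add(left, right, "vicariance", 1.0)
    else:  # BAYAREALIKE
        add(parent, parent, "sympatry-copy", 1.0)

    if params.j > 0:
        unocc = ((1 << len(space.areas)) - 1) & ~parent
        while unocc:
            a = unocc & -unocc
            unocc ^= a
            add(parent, a, "jump", params.j)
            add(a, parent, "jump", params.j)

    total = sum(w for _, w in raw.values())
    if total <= 0:
        raise ValueError(
            f"no allowed cladogenetic outcome for parent "
            f"{space.areas.letters(parent)} under {params.name}"
        )
    return [
        CladoScenario(left, right, cat, w / total)
        for (left, right), (cat, w) in sorted(raw.items())
    ]


class _IndexedClado:
    """Per-parent scenario arrays in state-index form, for fast convolution."""

    def __init__(self, params: DECParams, space: StateSpace) -> None:
        self.space = space
        self.left: list[np.ndarray] = []
        self.right: list[np.ndarray] = []
        self.prob: list[np.ndarray] = []
        self.cat: list[list[str]] = []
        for s in space.states:
            if s == 0:
                self.left.append(np.empty(0, dtype=int))
                self.right.append(np.empty(0, dtype=int))
                self.prob.append(np.empty(0))
                self.cat.append([])
                continue
            rows = clado_distribution(s, params, space)
            self.left.append(np.array([space.index[r.left] for r in rows], dtype=int))
            self.right.append(np.array([space.index[r.right] for r in rows], dtype=int))
            self.prob.append(np.array([r.prob for r in rows]))
            self.cat.append([r.category for r in rows])


class _TransitionCalculator:
    """P(t) = expm(Q t), with an eigendecomposition fast path.

    Q is diagonalized once; per-branch matrices are then two small matrix
    products. The decomposition is verified against scipy's expm on the
    longest branch and the dense route is used whenever Q is defective or
    ill-conditioned.
    """

    def __init__(self, Q: np.ndarray, check_t: float = 1.0) -> None:
        self.Q = Q
        self._eig = None
        try:
            w, V = np.linalg.eig(Q)
            Vinv = np.linalg.inv(V)
            P_fast = (V * np.exp(w * check_t)) @ Vinv
            P_ref = expm(Q * check_t)
            if np.max(np.abs(P_fast.real - P_ref)) < 1e-10:
                self._eig = (w, V, Vinv)
        except np.linalg.LinAlgError:
            pass

    def __call__(self, t: float) -> np.ndarray:
        if t == 0.0:
            return np.eye(self.Q.shape[0])
        if self._eig is not None:
            w, V, Vinv = self._eig
            P = ((V * np.exp(w * t)) @ Vinv).real
        else:
            P = expm(self.Q * t)
        np.clip(P, 0.0, None, out=P)
        return P


@dataclass
class FitResult:
    """Outcome of a maximum-likelihood fit."""

    params: DECParams
    lnL: float
    k: int
    n: int
    converged: bool
    trace: list[dict] = field(default_factory=list)

    def __repr__(self) -> str:
        p = self.params
        return (
            f"<FitResult {p.name}: lnL={self.lnL:.4f} d={p.d:.4g} e={p.e:.4g}"
            + (f" j={p.j:.4g}" if p.plus_j else "")
            + f" k={self.k} n={self.n} converged={self.converged}>"
        )


@dataclass
class AncestralReconstruction:
    """Per-node probability vectors over the state space."""

    space: StateSpace
    probs: dict  # node id -> np.ndarray over states
    method: str  # "ML-marginal" or "BBM-posterior"

    def vector(self, node_id) -> np.ndarray:
        return self.probs[node_id]

    def top_state(self, node_id) -> str:
        v = self.probs[node_id]
        return self.space.labels()[int(np.argmax(v))]

    def top_prob(self, node_id) -> float:
        return float(np.max(self.probs[node_id]))

    def to_rows(self) -> list[tuple]:
        """(node, state, probability) rows, descending probability per node."""
        labels = self.space.labels()
        rows = []
        for nid, v in self.probs.items():
            order = np.argsort(v)[::-1]
            for idx in order:
                if v[idx] > 1e-12:
                    rows.append((nid, labels[idx], float(v[idx])))
        return rows


class PruningEngine:
    """Shared machinery: partial likelihoods, marginals, joint sampling.

    Keeps the per-node downward partials and per-branch transition matrices
    so the likelihood, the marginal reconstruction, and stochastic mapping
    all run off one consistent set of quantities.
    """

    def __init__(
        self,
        tree: Chronogram,
        data: RangeData,
        params: DECParams,
        space: StateSpace,
        root_state: str | None = None,
        condition_survival: bool = False,
    ) -> None:
        if not tree.is_binary:
            raise ValueError(
                "the cladogenesis model requires a strictly bifurcating tree; "
                "resolve polytomies before fitting"
            )
        data.validate_against(tree, strict=False)
        self.tree = tree
        self.data = data
        self.params = params
        self.space = space
        self.Q = build_rate_matrix(params, space)
        self.clado = _IndexedClado(params, space)
        tcheck = max(max(tree.edge_length), 1.0)
        self.Pcalc = _TransitionCalculator(self.Q, check_t=tcheck)
        self.condition_survival = condition_survival
        self.P: dict[int, np.ndarray] = {
            i: self.Pcalc(tree.edge_length[i])
            for i in range(tree.n_nodes)
            if tree.parent[i] >= 0
        }
        if condition_survival and space.include_null:
            # condition each branch on the lineage not going globally
            # extinct: renormalize transition rows over non-null endpoints
            # (the null range is absorbing, so a non-null endpoint implies
            # the null state was never visited)
            null = space.index[0]
            for i, P in self.P.items():
                P = P.copy()
                surv = 1.0 - P[:, null]
                surv[surv <= 0.0] = 1.0
                P /= surv[:, None]
                P[:, null] = 0.0
                self.P[i] = P
        nn = space.nonnull_indices
        self.root_prior = np.zeros(len(space))
        if root_state is None:
            self.root_prior[nn] = 1.0 / len(nn)
        else:
            self.root_prior[space.index[space.mask_of(root_state)]] = 1.0
        self._run_up()

    # -- upward (post-order) pass ------------------------------------
    def _run_up(self) -> None:
        tree, space = self.tree, self.space
        ns = len(space)
        self.L = np.zeros((tree.n_nodes, ns))  # partials at each node
        self.M = np.zeros((tree.n_nodes, ns))  # P(t) @ L, indexed by daughter top-state
        self.logscale = np.zeros(tree.n_nodes)
        for i in tree.postorder:
            if tree.is_tip[i]:
                mask = self.data[tree.tip_label[i]]
                self.L[i, space.index[mask]] = 1.0
            else:
                cx, cy = tree.children[i]
                vec = np.zeros(ns)
                for s_idx in space.nonnull_indices:
                    li, ri, pr = (
                        self.clado.left[s_idx],
                        self.clado.right[s_idx],
                        self.clado.prob[s_idx],
                    )
                    vec[s_idx] = np.sum(pr * self.M[cx, li] * self.M[cy, ri])
                self.L[i] = vec
                self.logscale[i] = (
                    self.logscale[cx] + self.logscale[cy]
                )
            top = np.max(self.L[i])
            if top <= 0:
                raise ValueError("likelihood underflow: zero partial (data impossible?)")
            self.L[i] /= top
            self.logscale[i] += np.log(top)
            p = tree.parent[i]
            if p >= 0:
                self.M[i] = self.P[i] @ self.L[i]

    @property
    def lnL(self) -> float:
        r = self.tree.root_index
        total = float(self.root_prior @ self.L[r])
        if total <= 0 or not np.isfinite(total):
            return -np.inf
        return np.log(total) + self.logscale[r]

    # -- downward (pre-order) pass for marginals ---------------------
    def marginals(self) -> AncestralReconstruction:
        tree, space = self.tree, self.space
        ns = len(space)
        O = np.zeros((tree.n_nodes, ns))  # outside likelihoods
        O[tree.root_index] = self.root_prior
        for i in reversed(tree.postorder):  # pre-order
            if tree.is_tip[i]:
                continue
            cx, cy = tree.children[i]
            for child, sib in ((cx, cy), (cy, cx)):
                A = np.zeros(ns)  # weight on each daughter top-state
                for s_idx in space.nonnull_indices:
                    if O[i, s_idx] == 0.0:
                        continue
                    li, ri, pr = (
                        self.clado.left[s_idx],
                        self.clado.right[s_idx],
                        self.clado.prob[s_idx],
                    )
                    if child == cx:
                        np.add.at(A, li, O[i, s_idx] * pr * self.M[sib, ri])
                    else:
                        np.add.at(A, ri, O[i, s_idx] * pr * self.M[sib, li])
                O[child] = A @ self.P[child]
                top = np.max(O[child])
                if top > 0:
                    O[child] /= top
        probs = {}
        for i in tree.postorder:
            v = self.L[i] * O[i]
            tot = v.sum()
            if tot <= 0:
                raise ValueError("degenerate marginal (zero posterior mass)")
            probs[tree.node_id[i]] = v / tot
        return AncestralReconstruction(space, probs, "ML-marginal")

    # -- joint sampling of node states (for stochastic mapping) ------
    def sample_joint_states(self, rng: np.random.Generator) -> dict[int, dict]:
        """One draw from the joint posterior over node states and
        cladogenetic scenarios, conditional on the tip data.

        Returns a per-node-index record with the node state index, the
        sampled scenario category, and each daughter's inherited (top)
        state index.
        """
        tree, space = self.tree, self.space
        out: dict[int, dict] = {}
        r = tree.root_index
        w = self.root_prior * self.L[r]
        s_r = int(rng.choice(len(space), p=w / w.sum()))
        out[r] = {"state": s_r}
        stack = [r]
        while stack:
            i = stack.pop()
            if tree.is_tip[i]:
                continue
            s_i = out[i]["state"]
            cx, cy = tree.children[i]
            li, ri, pr = (
                self.clado.left[s_i],
                self.clado.right[s_i],
                self.clado.prob[s_i],
            )
            wsc = pr * self.M[cx, li] * self.M[cy, ri]
            ksc = int(rng.choice(len(wsc), p=wsc / wsc.sum()))
            out[i]["category"] = self.clado.cat[s_i][ksc]
            out[i]["left_top"], out[i]["right_top"] = int(li[ksc]), int(ri[ksc])
            for child, top in ((cx, out[i]["left_top"]), (cy, out[i]["right_top"])):
                wc = self.P[child][top] * self.L[child]
                s_c = int(rng.choice(len(space), p=wc / wc.sum()))
                out.setdefault(child, {})["state"] = s_c
                out[child]["top"] = top
                stack.append(child)
        return out


def loglik(
    tree: Chronogram,
    data: RangeData,
    params: DECParams,
    space: StateSpace,
    root_state: str | None = None,
    condition_survival: bool = False,
) -> float:
    """Log-likelihood of the tip ranges under a DEC-family model.

    ``root_state`` conditions the root on a single range (letters string);
    by default the root is averaged uniformly over allowed non-null states.
    ``condition_survival`` conditions every branch on its lineage escaping
    the absorbing null range, the appropriate likelihood for data that by
    construction contain only extant (surviving) lineages.
    """
    return PruningEngine(
        tree, data, params, space,
        root_state=root_state, condition_survival=condition_survival,
    ).lnL


_START_GRID = [
    (0.01, 0.01, 0.1),
    (0.001, 0.001, 0.01),
    (0.1, 0.1, 0.5),
    (0.03, 0.003, 1.0),
    (0.003, 0.03, 0.05),
]

_RATE_LO, _RATE_HI = 1e-9, 10.0


def _logistic(x: float) -> float:
    return J_MAX / (1.0 + np.exp(-x))


def _logit(p: float) -> float:
    p = min(max(p / J_MAX, 1e-9), 1 - 1e-9)
    return float(np.log(p / (1 - p)))


def fit_ml(
    tree: Chronogram,
    data: RangeData,
    family: Family = "DEC",
    plus_j: bool = False,
    space: StateSpace | None = None,
    n_starts: int = 5,
    root_state: str | None = None,
    condition_survival: bool = False,
) -> FitResult:
    """Maximum-likelihood fit of (d, e[, j]) by multi-start bounded
    quasi-Newton on log-transformed rates (logistic-transformed j).

    Starts come from a fixed grid, so the fit is deterministic. A fit that
    fails to converge from every start is returned flagged, not raised.
    """
    if space is None:
        raise ValueError("a StateSpace is required")
    data.validate_against(tree, strict=False)

    def unpack(x: np.ndarray) -> DECParams:
        d = float(np.exp(x[0]))
        e = float(np.exp(x[1]))
        j = _logistic(float(x[2])) if plus_j else 0.0
        return DECParams(d=d, e=e, j=j, family=family)

    def nll(x: np.ndarray) -> float:
        try:
            val = loglik(
                tree, data, unpack(x), space,
                root_state=root_state, condition_survival=condition_survival,
            )
        except (ValueError, FloatingPointError):
            return 1e10
        return 1e10 if not np.isfinite(val) else -val

    lo, hi = np.log(_RATE_LO), np.log(_RATE_HI)
    bounds = [(lo, hi), (lo, hi)] + ([(-20.0, 20.0)] if plus_j else [])
    best = None
    trace = []
    any_ok = False
    for d0, e0, j0 in _START_GRID[: max(1, n_starts)]:
        x0 = [np.log(d0), np.log(e0)] + ([_logit(j0)] if plus_j else [])
        res = minimize(nll, np.array(x0), method="L-BFGS-B", bounds=bounds)
        trace.append(
            {"start": (d0, e0, j0), "lnL": -res.fun, "success": bool(res.success)}
        )
        any_ok = any_ok or bool(res.success)
        if best is None or res.fun < best.fun:
            best = res
    params = unpack(best.x)
    return FitResult(
        params=params,
        lnL=-float(best.fun),
        k=3 if plus_j else 2,
        n=tree.n_tips,
        converged=any_ok,
        trace=trace,
    )


def ancestral_marginals(
    tree: Chronogram,
    data: RangeData,
    params: DECParams,
    space: StateSpace,
    root_state: str | None = None,
) -> AncestralReconstruction:
    """Marginal ancestral-range probabilities at every node, conditioning
    on all tip data (up-down pass)."""
    return PruningEngine(tree, data, params, space, root_state=root_state).marginals()
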