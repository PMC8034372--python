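"""Per-node biogeographic event counts by stochastic character mapping.

Given a fitted DEC-family model, histories are sampled from the joint
posterior over ancestral states conditional on the tip data; anagenetic
histories along branches are drawn by uniformization (endpoint-conditioned
CTMC paths). Events in a focal node's window are tallied:

* dispersal — an anagenetic range gain on the node's subtending branch,
  or a founder-event (jump) cladogenesis at the node;
* extinction — an anagenetic range loss on the subtending branch;
* vicariance — a vicariant cladogenesis at the node.

The default window is the node's cladogenesis plus its subtending branch
(``window="branch+clado"``); ``window="clado"`` restricts to the split
itself. Modal counts over the sampled maps are reported alongside the
posterior expectations.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

import numpy as np

from paleorange.chronogram import Chronogram
from paleorange.dec import DECParams, PruningEngine
from paleorange.ranges import RangeData, StateSpace

__all__ = ["EventMatrix", "count_events", "sample_conditioned_path"]


@dataclass
class EventMatrix:
    """Dispersal/vicariance/extinction counts at one focal node."""

    node_id: object
    method: str
    dispersal: int
    vicariance: int
    extinction: int
    expected_dispersal: float
    expected_vicariance: float
    expected_extinction: float
    n_maps: int

    def as_dict(self) -> dict:
        return {
            "node": self.node_id,
            "method": self.method,
            "dispersal": self.dispersal,
            "vicariance": self.vicariance,
            "extinction": self.extinction,
            "expected_dispersal": self.expected_dispersal,
            "expected_vicariance": self.expected_vicariance,
            "expected_extinction": self.expected_extinction,
            "n_maps": self.n_maps,
        }


class _Uniformizer:
    """Endpoint-conditioned CTMC path sampler by uniformization."""

    def __init__(self, Q: np.ndarray) -> None:
        self.Q = Q
        self.mu = float(np.max(-np.diag(Q)))
        n = Q.shape[0]
        if self.mu > 0:
            self.R = np.eye(n) + Q / self.mu
        else:
            self.R = np.eye(n)
        self._powers = [np.eye(n), self.R]

    def _Rpow(self, k: int) -> np.ndarray:
        while len(self._powers) <= k:
            self._powers.append(self._powers[-1] @ self.R)
        return self._powers[k]

    def sample_transitions(
        self, a: int, b: int, t: float, P_t: np.ndarray, rng: np.random.Generator
    ) -> list[tuple[int, int]]:
        """States visited: list of (from, to) real transitions on a path
        from state ``a`` to state ``b`` over duration ``t``."""
        if self.mu == 0.0 or t == 0.0:
            return []
        pab = P_t[a, b]
        if pab <= 0:
            raise ValueError("impossible endpoint pair for conditioned path")
        # draw the number of uniformized (virtual) jumps
        mu_t = self.mu * t
        log_pois = -mu_t
        u = rng.random() * pab
        acc = 0.0
        n_jumps = 0
        max_jumps = max(50, int(mu_t + 12 * np.sqrt(mu_t) + 12))
        log_fact = 0.0
        while True:
            term = np.exp(log_pois + n_jumps * np.log(mu_t) - log_fact if n_jumps else log_pois)
            acc += term * self._Rpow(n_jumps)[a, b]
            if acc >= u or n_jumps >= max_jumps:
                break
            n_jumps += 1
            log_fact += np.log(n_jumps)
        # sample the state sequence of the bridge
        seq = [a]
        cur = a
        for k in range(1, n_jumps + 1):
            back = self._Rpow(n_jumps - k)
            w = self.R[cur] * back[:, b]
            tot = w.sum()
            if tot <= 0:
                cur = b
            else:
                cur = int(rng.choice(len(w), p=w / tot))
            seq.append(cur)
        if n_jumps > 0:
            seq[-1] = b
        elif a != b:
            seq.append(b)  # defensive; cannot happen when R has zero diagonal mass
        return [(x, y) for x, y in zip(seq, seq[1:]) if x != y]


def _classify_anagenetic(space: StateSpace, frm: int, to: int) -> str:
    c1 = bin(space.states[frm]).count("1")
    c2 = bin(space.states[to]).count("1")
    return "dispersal" if c2 > c1 else "extinction"


def count_events(
    tree: Chronogram,
    data: RangeData,
    params: DECParams,
    space: StateSpace,
    node: object,
    n_maps: int = 500,
    seed: int = 0,
    window: str = "branch+clado",
) -> EventMatrix:
    """Tally dispersal/vicariance/extinction at a focal node by stochastic
    mapping (``n_maps`` posterior history draws)."""
    if n_maps < 1:
        raise ValueError("n_maps must be >= 1")
    if window not in ("branch+clado", "clado"):
        raise ValueError("window must be 'branch+clado' or 'clado'")
    i = tree.index_of(node)
    if tree.is_tip[i]:
        raise ValueError(f"node {node!r} is a tip; event windows need a cladogenesis")
    engine = PruningEngine(tree, data, params, space)
    unif = _Uniformizer(engine.Q)
    rng = np.random.default_rng(seed)
    has_branch = tree.parent[i] >= 0 and window == "branch+clado"
    t_branch = tree.edge_length[i]
    P_branch = engine.P.get(i)

    triples = []
    for _ in range(n_maps):
        joint = engine.sample_joint_states(rng)
        disp = vic = ext = 0
        cat = joint[i]["category"]
        if cat == "vicariance":
            vic += 1
        elif cat == "jump":
            disp += 1
        if has_branch:
            a, b = joint[i]["top"], joint[i]["state"]
            for frm, to in unif.sample_transitions(a, b, t_branch, P_branch, rng):
                if _classify_anagenetic(space, frm, to) == "dispersal":
                    disp += 1
                else:
                    ext += 1
        triples.append((disp, vic, ext))

    arr = np.array(triples)
    modal = [Counter(arr[:, k]).most_common(1)[0][0] for k in range(3)]
    exp = arr.mean(axis=0)
    return EventMatrix(
        node_id=node,
        method=params.name,
        dispersal=int(modal[0]),
        vicariance=int(modal[1]),
        extinction=int(modal[2]),
        expected_dispersal=float(exp[0]),
        expected_vicariance=float(exp[1]),
        expected_extinction=float(exp[2]),
        n_maps=n_maps,
    )


def sample_conditioned_path(
    Q: np.ndarray,
    a: int,
    b: int,
    t: float,
    rng: np.random.Generator,
    P_t: np.ndarray | None = None,
) -> list[tuple[int, int]]:
    """Real transitions of one endpoint-conditioned CTMC path (testing hook)."""
    from scipy.linalg import expm

    if P_t is None:
        P_t = expm(Q * t)
    return _Uniformizer(Q).sample_transitions(a, b, t, P_t, rng)
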