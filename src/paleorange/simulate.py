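"""Synthetic-data generators for every pipeline stage.

Provides dated pure-birth chronograms, range data simulated forward under
any DEC-family model (with the true history recorded), gene trees with
controlled topological discordance (random NNI moves plus random taxon
deletion), and codon alignments with an elevated third-position rate. The
study-emulation preset mirrors the shape of a 29-taxon, five-area
tarantula-scale analysis: root age 120 Ma, maximum range size 2.

All randomness flows from one seeded generator per call; re-running with
the same seed reproduces identical outputs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import dendropy
import numpy as np

from paleorange.chronogram import Chronogram
from paleorange.dec import DECParams, build_rate_matrix, clado_distribution
from paleorange.ranges import RangeData, StateSpace, build_state_space, default_areas
from paleorange.supermatrix import GeneAlignment, GeneTree

__all__ = [
    "SimulationRecord",
    "simulate_chronogram",
    "simulate_ranges",
    "simulate_discordant_genetrees",
    "simulate_codon_alignment",
    "study_preset",
]

DEFAULT_ROOT_AGE = 120.0  # Ma, basal-theraphosid scale
STUDY_N_TIPS = 29
STUDY_MAX_RANGE = 2


@dataclass
class SimulationRecord:
    """A simulated range-evolution history with full ground truth."""

    seed: int
    params: DECParams
    tree: Chronogram
    true_states: dict  # node id -> range bitmask (state at the node)
    clado_events: dict  # internal node id -> scenario category
    branch_events: dict  # node id -> (n_dispersal, n_extinction) on its branch
    tip_data: RangeData = None  # type: ignore[assignment]
    restarts: int = 0

    def total_events(self) -> dict[str, int]:
        disp = sum(d for d, _ in self.branch_events.values())
        ext = sum(e for _, e in self.branch_events.values())
        vic = sum(1 for c in self.clado_events.values() if c == "vicariance")
        jump = sum(1 for c in self.clado_events.values() if c == "jump")
        return {
            "anagenetic_dispersal": disp,
            "anagenetic_extinction": ext,
            "vicariance": vic,
            "jump_dispersal": jump,
        }

    def write_truth_json(self, path: str | Path) -> None:
        space = self.tip_data.space
        out = {
            "seed": self.seed,
            "params": {
                "d": self.params.d,
                "e": self.params.e,
                "j": self.params.j,
                "family": self.params.family,
            },
            "restarts": self.restarts,
            "true_states": {
                str(k): space.areas.letters(v) for k, v in self.true_states.items()
            },
            "clado_events": {str(k): v for k, v in self.clado_events.items()},
            "branch_events": {str(k): list(v) for k, v in self.branch_events.items()},
            "totals": self.total_events(),
        }
        Path(path).write_text(json.dumps(out, indent=2) + "\n")


def simulate_chronogram(
    n_tips: int,
    birth_rate: float = 0.05,
    seed: int = 0,
    root_age: float | None = DEFAULT_ROOT_AGE,
) -> Chronogram:
    """Ultrametric pure-birth (Yule) tree rescaled to ``root_age`` Ma.

    The process starts at the root split with two lineages; each lineage
    splits at rate ``birth_rate``; after the (n_tips - 1)-th split one more
    exponential waiting time runs out the clock to the present.
    ``root_age=None`` keeps the natural (unscaled) time axis.
    """
    if n_tips < 3:
        raise ValueError("need at least 3 tips")
    if birth_rate <= 0:
        raise ValueError("birth rate must be positive")
    rng = np.random.default_rng(seed)
    # node: [children, split_time]; active lineages carry their birth time
    nodes: list[dict] = [{"children": [], "time": 0.0}]
    active = [(0, 0.0)]  # (node index, birth time) -- root splits immediately
    t = 0.0
    # root split
    for _ in range(2):
        nodes.append({"children": [], "time": None})
        nodes[0]["children"].append(len(nodes) - 1)
    active = [(1, 0.0), (2, 0.0)]
    while len(active) < n_tips:
        k = len(active)
        t += rng.exponential(1.0 / (birth_rate * k))
        pick = rng.integers(k)
        idx, _ = active.pop(int(pick))
        nodes[idx]["time"] = t
        for _ in range(2):
            nodes.append({"children": [], "time": None})
            nodes[idx]["children"].append(len(nodes) - 1)
        active.append((len(nodes) - 2, t))
        active.append((len(nodes) - 1, t))
    t_end = t + rng.exponential(1.0 / (birth_rate * n_tips))
    scale = 1.0 if root_age is None else root_age / t_end
    tip_counter = iter(range(1, n_tips + 1))

    def newick(idx: int, parent_time: float) -> str:
        nd = nodes[idx]
        if not nd["children"]:
            bl = (t_end - parent_time) * scale
            return f"t{next(tip_counter)}:{bl:.10f}"
        inner = ",".join(newick(c, nd["time"]) for c in nd["children"])
        bl = (nd["time"] - parent_time) * scale
        return f"({inner}):{bl:.10f}"

    inner = ",".join(newick(c, 0.0) for c in nodes[0]["children"])
    return Chronogram.from_newick_string(f"({inner});")


def _gillespie_branch(
    state_idx: int,
    t: float,
    Q: np.ndarray,
    space: StateSpace,
    rng: np.random.Generator,
) -> tuple[int, int, int]:
    """Exact CTMC simulation along one branch.

    Returns (end state index, n gains, n losses)."""
    gains = losses = 0
    s = state_idx
    remaining = t
    while True:
        total = -Q[s, s]
        if total <= 0:
            return s, gains, losses
        wait = rng.exponential(1.0 / total)
        if wait >= remaining:
            return s, gains, losses
        remaining -= wait
        rates = Q[s].copy()
        rates[s] = 0.0
        nxt = int(rng.choice(len(rates), p=rates / rates.sum()))
        c_old = bin(space.states[s]).count("1")
        c_new = bin(space.states[nxt]).count("1")
        if c_new > c_old:
            gains += 1
        else:
            losses += 1
        s = nxt


def simulate_ranges(
    tree: Chronogram,
    params: DECParams,
    space: StateSpace,
    seed: int = 0,
    max_restarts: int = 1000,
) -> SimulationRecord:
    """Forward-simulate range evolution on a chronogram.

    The root state is drawn uniformly from the allowed singleton ranges;
    anagenesis is exact event-by-event CTMC simulation; cladogenesis draws
    from the model's scenario distribution. Because all tips are extant,
    the history is conditioned on survival: a branch whose lineage reaches
    the absorbing null range is redrawn (up to ``max_restarts`` times per
    branch), with the total number of redraws recorded. This per-branch
    conditioning is the standard survivorship device in range simulators;
    at plausible extinction rates its bias is negligible, and a whole-tree
    rejection scheme would never accept a deep many-tip history.
    """
    if not tree.is_binary:
        raise ValueError("range simulation requires a bifurcating chronogram")
    rng = np.random.default_rng(seed)
    Q = build_rate_matrix(params, space)
    singletons = [
        i for i in space.nonnull_indices if bin(space.states[i]).count("1") == 1
    ]
    clado_cache: dict[int, list] = {}
    null_idx = space.index.get(0)
    restarts = 0

    true_states: dict = {}
    clado_events: dict = {}
    branch_events: dict = {}
    codings: dict[str, int] = {}
    root = tree.root_index
    state_at = {root: int(rng.choice(singletons))}
    stack = [root]
    while stack:
        i = stack.pop()
        s = state_at[i]
        nid = tree.node_id[i]
        true_states[nid] = space.states[s]
        if tree.is_tip[i]:
            codings[tree.tip_label[i]] = space.states[s]
            continue
        if s not in clado_cache:
            clado_cache[s] = clado_distribution(space.states[s], params, space)
        rows = clado_cache[s]
        probs = np.array([r.prob for r in rows])
        k = int(rng.choice(len(rows), p=probs))
        clado_events[nid] = rows[k].category
        tops = (space.index[rows[k].left], space.index[rows[k].right])
        for child, top in zip(tree.children[i], tops):
            for _ in range(max_restarts + 1):
                end, g, l = _gillespie_branch(
                    top, tree.edge_length[child], Q, space, rng
                )
                if end != null_idx:
                    break
                restarts += 1
            else:
                raise RuntimeError(
                    f"no surviving history in {max_restarts} restarts on one "
                    "branch; extinction rate too high"
                )
            branch_events[tree.node_id[child]] = (g, l)
            state_at[child] = end
            stack.append(child)
    rec = SimulationRecord(
        seed=seed,
        params=params,
        tree=tree,
        true_states=true_states,
        clado_events=clado_events,
        branch_events=branch_events,
        restarts=restarts,
    )
    rec.tip_data = RangeData(space, codings)
    return rec


def simulate_discordant_genetrees(
    reference: GeneTree,
    n_trees: int,
    nni_moves: int = 0,
    missing_fraction: float = 0.0,
    seed: int = 0,
) -> list[GeneTree]:
    """Gene trees derived from a reference by random NNI moves and random
    tip deletion. Each NNI changes at most one internal edge, so RF to the
    reference is bounded by 2 * nni_moves."""
    if len(reference.tip_labels) < 6:
        raise ValueError("reference needs at least 6 tips")
    if not (0.0 <= missing_fraction < 1.0):
        raise ValueError("missing_fraction must be in [0, 1)")
    if nni_moves < 0 or n_trees < 0:
        raise ValueError("counts must be non-negative")
    rng = np.random.default_rng(seed)
    out = []
    for k in range(n_trees):
        t = reference.tree.clone(depth=1)
        for _ in range(nni_moves):
            _random_nni(t, rng)
        labels = sorted(lf.taxon.label for lf in t.leaf_node_iter())
        n_drop = int(round(missing_fraction * len(labels)))
        n_drop = min(n_drop, len(labels) - 4)
        if n_drop > 0:
            drop = rng.choice(len(labels), size=n_drop, replace=False)
            keep = [lab for i, lab in enumerate(labels) if i not in set(drop.tolist())]
            t = t.extract_tree_with_taxa_labels(labels=keep)
        out.append(GeneTree(f"{reference.og_id}_sim{k}", t))
    return out


def _random_nni(tree: dendropy.Tree, rng: np.random.Generator) -> None:
    """One nearest-neighbour interchange across a random internal edge."""
    internal = [
        nd
        for nd in tree.preorder_node_iter()
        if nd.parent_node is not None
        and not nd.is_leaf()
        and nd.parent_node.parent_node is not None
    ]
    if not internal:
        internal = [
            nd
            for nd in tree.preorder_node_iter()
            if nd.parent_node is not None and not nd.is_leaf()
        ]
        if not internal:
            return
    v = internal[int(rng.integers(len(internal)))]
    u = v.parent_node
    sibs = [c for c in u.child_nodes() if c is not v]
    kids = v.child_nodes()
    if not sibs or len(kids) < 2:
        return
    s = sibs[int(rng.integers(len(sibs)))]
    c = kids[int(rng.integers(len(kids)))]
    u.remove_child(s)
    v.remove_child(c)
    u.add_child(c)
    v.add_child(s)


_BASES = "ACGT"


def simulate_codon_alignment(
    tree: GeneTree,
    length_codons: int,
    third_position_rate_multiplier: float = 1.0,
    seed: int = 0,
    rate: float = 1.0,
) -> GeneAlignment:
    """Jukes-Cantor DNA simulation with a third-position rate multiplier.

    ``rate`` is expected substitutions per site per unit branch length at
    first/second positions; third positions evolve ``multiplier`` times
    faster, emulating synonymous-site saturation.
    """
    if length_codons < 10:
        raise ValueError("need at least 10 codons")
    if third_position_rate_multiplier <= 0:
        raise ValueError("rate multiplier must be positive")
    rng = np.random.default_rng(seed)
    L = 3 * length_codons
    site_rate = np.full(L, rate)
    site_rate[2::3] *= third_position_rate_multiplier
    seqs: dict[str, np.ndarray] = {}
    root_seq = rng.integers(0, 4, size=L)

    def evolve(parent_seq: np.ndarray, t: float) -> np.ndarray:
        # JC69: P(site unchanged) = 1/4 + 3/4 exp(-4/3 r t)
        p_same = 0.25 + 0.75 * np.exp(-4.0 / 3.0 * site_rate * t)
        child = parent_seq.copy()
        hit = rng.random(L) > p_same
        if hit.any():
            shift = rng.integers(1, 4, size=int(hit.sum()))
            child[hit] = (child[hit] + shift) % 4
        return child

    state: dict[int, np.ndarray] = {}
    for nd in tree.tree.preorder_node_iter():
        if nd.parent_node is None:
            state[id(nd)] = root_seq
        else:
            bl = nd.edge.length or 0.0
            state[id(nd)] = evolve(state[id(nd.parent_node)], bl)
        if nd.is_leaf():
            seqs[nd.taxon.label] = state[id(nd)]
    out = {t: "".join(_BASES[b] for b in s) for t, s in seqs.items()}
    return GeneAlignment(tree.og_id, out, codon_aligned=True)


def study_preset(
    seed: int = 0,
    params: DECParams | None = None,
) -> tuple[Chronogram, StateSpace, SimulationRecord]:
    """Study-shaped instance: 29 tips, five areas A-E, max range size 2,
    root age 120 Ma, DEC generating rates d=0.008, e=0.004 per Ma."""
    params = params or DECParams(d=0.008, e=0.004, j=0.0, family="DEC")
    tree = simulate_chronogram(STUDY_N_TIPS, birth_rate=0.04, seed=seed)
    space = build_state_space(default_areas(), STUDY_MAX_RANGE, include_null=True)
    rec = simulate_ranges(tree, params, space, seed=seed + 1)
    return tree, space, rec
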