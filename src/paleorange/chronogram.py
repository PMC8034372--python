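"""Time-calibrated phylogeny I/O and queries.

A :class:`Chronogram` is a rooted ultrametric tree whose branch lengths are
absolute time in millions of years (Ma). It is the fixed scaffold on which
all range inference runs: the tree is always an *input* here, never
estimated. DendroPy does the Newick/NEXUS parsing; this module adds
validation (rootedness, ultrametricity within a relative tolerance, unique
tip labels), node ages, induced-subtree extraction, and stable node ids
that mirror integer internal labels when the input carries them.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import dendropy

__all__ = [
    "Chronogram",
    "NodeAgeRecord",
    "ChronogramError",
    "FormatError",
    "ValidationError",
    "read_newick",
    "write_newick",
    "write_node_age_report",
]


class ChronogramError(Exception):
    """Base class for chronogram problems."""


class FormatError(ChronogramError):
    """The input file could not be parsed."""


class ValidationError(ChronogramError):
    """The tree parsed but violates a chronogram invariant."""


@dataclass(frozen=True)
class NodeAgeRecord:
    """A node's point age and 95% HPD interval, all in Ma."""

    node_id: int | str
    age: float
    hpd_min: float | None = None
    hpd_max: float | None = None

    def __post_init__(self) -> None:
        if self.age < 0:
            raise ValueError(f"negative age for node {self.node_id}")
        if self.hpd_min is not None and self.hpd_max is not None:
            if not (self.hpd_min <= self.age <= self.hpd_max):
                raise ValueError(
                    f"node {self.node_id}: HPD [{self.hpd_min}, {self.hpd_max}] "
                    f"does not bracket age {self.age}"
                )


class Chronogram:
    """Rooted ultrametric tree with branch lengths in Ma.

    Nodes are addressed by public ids: tip label for leaves; for internal
    nodes, the integer label from the input file when present, otherwise a
    deterministic post-order index (counting from ``n_tips``). Internal
    structure is exposed through parallel post-order arrays used by the
    likelihood engines.

    Parameters
    ----------
    tree:
        A rooted :class:`dendropy.Tree` with branch lengths.
    ultrametric_rtol:
        Tolerance on root-to-tip path spread, relative to tree height.
    require_ultrametric:
        Set false to accept non-ultrametric trees (e.g. gene trees).
    """

    def __init__(
        self,
        tree: dendropy.Tree,
        *,
        ultrametric_rtol: float = 1e-6,
        require_ultrametric: bool = True,
    ) -> None:
        self._tree = tree
        self.ultrametric_rtol = ultrametric_rtol
        self._index_structure()
        self._validate(require_ultrametric)

    # ------------------------------------------------------------------
    # construction
    # ------------------------------------------------------------------
    @classmethod
    def from_newick_string(cls, newick: str, **kwargs) -> "Chronogram":
        try:
            tree = dendropy.Tree.get(
                data=newick, schema="newick", rooting="force-rooted",
                suppress_internal_node_taxa=True,
            )
        except Exception as exc:  # dendropy raises several error types
            if "Duplicate taxon labels" in str(exc):
                raise ValidationError(f"duplicate tip labels: {exc}") from exc
            raise FormatError(f"could not parse Newick: {exc}") from exc
        return cls(tree, **kwargs)

    @classmethod
    def from_file(cls, path: str | Path, **kwargs) -> "Chronogram":
        path = Path(path)
        if not path.exists():
            raise FileNotFoundError(path)
        text = path.read_text()
        schema = "nexus" if text.lstrip().upper().startswith("#NEXUS") else "newick"
        try:
            tree = dendropy.Tree.get(
                data=text, schema=schema, rooting="force-rooted",
                suppress_internal_node_taxa=True,
            )
        except Exception as exc:
            raise FormatError(f"{path}: could not parse {schema}: {exc}") from exc
        return cls(tree, **kwargs)

    def _index_structure(self) -> None:
        nodes = list(self._tree.postorder_node_iter())
        self._nodes = nodes
        self._pos = {id(nd): i for i, nd in enumerate(nodes)}
        n = len(nodes)
        self.parent = [-1] * n
        self.children: list[list[int]] = [[] for _ in range(n)]
        self.edge_length = [0.0] * n
        self.is_tip = [False] * n
        self.tip_label: list[str | None] = [None] * n
        root = self._tree.seed_node
        for i, nd in enumerate(nodes):
            if nd.parent_node is not None:
                p = self._pos[id(nd.parent_node)]
                self.parent[i] = p
                self.children[p].append(i)
                bl = nd.edge.length
                if bl is None:
                    raise ValidationError("branch without a length")
                self.edge_length[i] = float(bl)
            if nd.is_leaf():
                self.is_tip[i] = True
                label = nd.taxon.label if nd.taxon is not None else nd.label
                if label is None or label == "":
                    raise ValidationError("tip without a label")
                self.tip_label[i] = str(label)
        self.root_index = self._pos[id(root)]
        self.postorder = list(range(n))  # nodes already stored post-order
        # depths from root
        self._depth = [0.0] * n
        for i in reversed(range(n)):
            p = self.parent[i]
            self._depth[i] = 0.0 if p < 0 else self._depth[p] + self.edge_length[i]
        self.height = max(
            (self._depth[i] for i in range(n) if self.is_tip[i]), default=0.0
        )
        self._assign_ids()

    def _assign_ids(self) -> None:
        """Tips keep their labels; internal nodes take integer labels from
        the file when every internal label parses as an integer, otherwise
        deterministic post-order indices starting at ``n_tips``."""
        internal = [i for i in range(len(self._nodes)) if not self.is_tip[i]]
        labels = [self._nodes[i].label for i in internal]
        use_file_labels = all(
            lab is not None and str(lab).strip().lstrip("-").isdigit() for lab in labels
        ) and len(labels) > 0
        ids: list[int | str] = [None] * len(self._nodes)  # type: ignore[list-item]
        for i in range(len(self._nodes)):
            if self.is_tip[i]:
                ids[i] = self.tip_label[i]  # type: ignore[assignment]
        if use_file_labels:
            for i, lab in zip(internal, labels):
                ids[i] = int(str(lab).strip())
        else:
            counter = self.n_tips
            for i in internal:
                ids[i] = counter
                counter += 1
        self.node_id = ids
        self._by_id = {}
        for i, nid in enumerate(ids):
            if nid in self._by_id:
                raise ValidationError(f"duplicate node id {nid!r}")
            self._by_id[nid] = i

    def _validate(self, require_ultrametric: bool) -> None:
        n = len(self._nodes)
        if self.n_tips < 2:
            raise ValidationError("tree needs at least 2 tips")
        labels = [self.tip_label[i] for i in range(n) if self.is_tip[i]]
        if len(set(labels)) != len(labels):
            dup = sorted({x for x in labels if labels.count(x) > 1})
            raise ValidationError(f"duplicate tip labels: {dup}")
        for i in range(n):
            if not self.is_tip[i] and len(self.children[i]) < 2:
                raise ValidationError("internal node with a single child (unifurcation)")
            if self.edge_length[i] < 0:
                raise ValidationError("negative branch length")
        if require_ultrametric:
            tol = self.ultrametric_rtol * max(self.height, 1e-300)
            depths = sorted(self._depth[i] for i in range(n) if self.is_tip[i])
            ref = depths[len(depths) // 2]  # majority depth, so deviants get named
            for i in range(n):
                if self.is_tip[i] and abs(self._depth[i] - ref) > tol:
                    raise ValidationError(
                        f"tree is not ultrametric: tip {self.tip_label[i]!r} has "
                        f"root-to-tip length {self._depth[i]:g} vs height {ref:g}"
                    )

    # ------------------------------------------------------------------
    # queries
    # ------------------------------------------------------------------
    @property
    def n_tips(self) -> int:
        return sum(self.is_tip)

    @property
    def n_nodes(self) -> int:
        return len(self._nodes)

    @property
    def tip_labels(self) -> list[str]:
        return [self.tip_label[i] for i in range(self.n_nodes) if self.is_tip[i]]

    @property
    def is_binary(self) -> bool:
        return all(
            self.is_tip[i] or len(self.children[i]) == 2 for i in range(self.n_nodes)
        )

    @property
    def node_ids(self) -> list[int | str]:
        return list(self.node_id)

    def index_of(self, node_id: int | str) -> int:
        try:
            return self._by_id[node_id]
        except KeyError:
            raise KeyError(f"unknown node id {node_id!r}") from None

    def node_age(self, node_id: int | str) -> float:
        """Age of a node in Ma: tree height minus root-to-node distance.

        Extant tips return 0 (up to the ultrametric tolerance, clamped).
        """
        i = self.index_of(node_id)
        age = self.height - self._depth[i]
        return 0.0 if abs(age) < self.ultrametric_rtol * max(self.height, 1.0) else age

    def mrca_id(self, tip_labels: Iterable[str]) -> int | str:
        """Node id of the most recent common ancestor of the given tips."""
        want = set(tip_labels)
        missing = want - set(self.tip_labels)
        if missing:
            raise KeyError(f"unknown tip labels: {sorted(missing)}")
        # post-order accumulation of tip sets
        have: list[set | None] = [None] * self.n_nodes
        for i in self.postorder:
            if self.is_tip[i]:
                have[i] = {self.tip_label[i]} & want
            else:
                have[i] = set().union(*(have[c] for c in self.children[i]))
            if have[i] == want:
                return self.node_id[i]
        return self.node_id[self.root_index]

    def node_ages(self) -> dict[int | str, float]:
        return {self.node_id[i]: self.node_age(self.node_id[i]) for i in self.postorder}

    # ------------------------------------------------------------------
    # manipulation / output
    # ------------------------------------------------------------------
    def extract_subtree(self, tip_subset: Sequence[str]) -> "Chronogram":
        """Induced subtree on ``tip_subset``, rooted at their MRCA.

        Degree-2 nodes are suppressed with their branch lengths summed, so
        retained nodes keep their original ages and the result is still
        ultrametric.
        """
        subset = list(dict.fromkeys(tip_subset))
        if len(subset) < 2:
            raise ValueError("need at least 2 tips to extract a subtree")
        missing = set(subset) - set(self.tip_labels)
        if missing:
            raise KeyError(f"unknown tip labels: {sorted(missing)}")
        sub = self._tree.extract_tree_with_taxa_labels(
            labels=subset, suppress_unifurcations=True
        )
        # collapse any leftover unifurcation chain above the MRCA
        while len(sub.seed_node.child_nodes()) == 1:
            child = sub.seed_node.child_nodes()[0]
            sub.seed_node.remove_child(child)
            sub.seed_node = child
        sub.seed_node.edge.length = None
        sub.seed_node.parent_node = None
        return Chronogram(sub, ultrametric_rtol=self.ultrametric_rtol)

    def to_newick(self, *, node_labels: dict[int | str, str] | None = None) -> str:
        """Newick string; optionally annotate internal nodes with labels."""
        if node_labels:
            for i in range(self.n_nodes):
                if not self.is_tip[i] and self.node_id[i] in node_labels:
                    self._nodes[i].label = node_labels[self.node_id[i]]
        s = self._tree.as_string(schema="newick", suppress_rooting=True)
        return s.strip()

    def __repr__(self) -> str:
        return f"<Chronogram: {self.n_tips} tips, height {self.height:.4g} Ma>"


def read_newick(path: str | Path, **kwargs) -> Chronogram:
    """Read a chronogram from a Newick (or NEXUS trees-block) file."""
    return Chronogram.from_file(path, **kwargs)


def write_newick(tree: Chronogram, path: str | Path, **kwargs) -> None:
    Path(path).write_text(tree.to_newick(**kwargs) + "\n")


def write_node_age_report(
    tree: Chronogram,
    path: str | Path,
    hpd: dict[int | str, tuple[float, float]] | None = None,
) -> None:
    """CSV of (node, age, hpd_min, hpd_max); HPDs are user-supplied metadata."""
    hpd = hpd or {}
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["node", "age", "hpd_min", "hpd_max"])
        for nid, age in sorted(tree.node_ages().items(), key=lambda kv: str(kv[0])):
            lo, hi = hpd.get(nid, ("", ""))
            w.writerow([nid, f"{age:.6g}", lo, hi])
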