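"""Phylogenomic supermatrix construction filters.

The pipeline mirrors a strict core-ortholog workflow: keep only ortholog
groups (OGs) sampled for *every* required taxon; drop OGs whose gene tree
is topologically discordant with a trusted reference (Robinson-Foulds
symmetric-difference distance at or above a threshold, after pruning each
gene tree to the taxa shared with the reference); strip third codon
positions from the codon-aligned DNA to blunt saturation; and concatenate
the survivors into a partitioned supermatrix with a completeness report.

RF distances are computed on unrooted topologies, branch lengths ignored,
trivial bipartitions excluded.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import dendropy
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "GeneAlignment",
    "GeneTree",
    "Supermatrix",
    "read_fasta_alignment",
    "write_fasta_alignment",
    "occupancy_filter",
    "rf_distance",
    "filter_by_rf",
    "strip_third_positions",
    "concatenate",
]

_ALPHABET = set("ACGTN-?")


@dataclass
class GeneAlignment:
    """One ortholog group's aligned DNA sequences (taxon -> row)."""

    og_id: str
    sequences: dict[str, str]
    codon_aligned: bool = False

    def __post_init__(self) -> None:
        if not self.sequences:
            raise ValueError(f"{self.og_id}: empty alignment")
        self.sequences = {t: s.upper() for t, s in self.sequences.items()}
        lengths = {len(s) for s in self.sequences.values()}
        if len(lengths) != 1:
            raise ValueError(f"{self.og_id}: unequal sequence lengths {sorted(lengths)}")
        bad = set("".join(self.sequences.values())) - _ALPHABET
        if bad:
            raise ValueError(f"{self.og_id}: illegal characters {sorted(bad)}")
        if self.codon_aligned and self.length % 3 != 0:
            raise ValueError(
                f"{self.og_id}: codon-aligned length {self.length} not divisible by 3"
            )

    @property
    def length(self) -> int:
        return len(next(iter(self.sequences.values())))

    @property
    def taxa(self) -> set[str]:
        return set(self.sequences)


@dataclass
class GeneTree:
    """An unrooted gene tree for one ortholog group."""

    og_id: str
    tree: dendropy.Tree

    @classmethod
    def from_newick(cls, og_id: str, newick: str) -> "GeneTree":
        t = dendropy.Tree.get(data=newick, schema="newick")
        return cls(og_id, t)

    @property
    def tip_labels(self) -> set[str]:
        return {lf.taxon.label for lf in self.tree.leaf_node_iter()}

    def newick(self) -> str:
        return self.tree.as_string(schema="newick").strip()


def read_fasta_alignment(
    path: str | Path, og_id: str | None = None, codon_aligned: bool = False
) -> GeneAlignment:
    records = {r.id: str(r.seq) for r in SeqIO.parse(str(path), "fasta")}
    return GeneAlignment(og_id or Path(path).stem, records, codon_aligned)


def write_fasta_alignment(aln: GeneAlignment, path: str | Path) -> None:
    recs = [
        SeqRecord(Seq(s), id=t, description="") for t, s in sorted(aln.sequences.items())
    ]
    SeqIO.write(recs, str(path), "fasta")


def occupancy_filter(
    alignments: Sequence[GeneAlignment], required_taxa: Iterable[str]
) -> list[GeneAlignment]:
    """Keep only OGs whose taxon set covers every required taxon."""
    required = set(required_taxa)
    if not required:
        raise ValueError("required_taxa must be non-empty")
    return [a for a in alignments if a.taxa >= required]


def _nontrivial_splits(tree: dendropy.Tree, keep: set[str]) -> set[frozenset[str]]:
    """Non-trivial bipartitions of an unrooted tree restricted to ``keep``,
    each split canonicalized as the side not containing the reference taxon."""
    ref = min(keep)
    n = len(keep)
    splits: set[frozenset[str]] = set()
    below: dict[int, set[str]] = {}
    for nd in tree.postorder_node_iter():
        if nd.is_leaf():
            lab = nd.taxon.label
            below[id(nd)] = {lab} if lab in keep else set()
        else:
            below[id(nd)] = set().union(*(below[id(c)] for c in nd.child_nodes()))
    for nd in tree.postorder_node_iter():
        if nd.parent_node is None:
            continue
        side = below[id(nd)]
        if ref in side:
            side = keep - side
        if 2 <= len(side) <= n - 2:
            splits.add(frozenset(side))
    return splits


def rf_distance(t1: GeneTree, t2: GeneTree) -> int:
    """Robinson-Foulds symmetric-difference distance on the shared taxa.

    Both trees are restricted to their shared tip set first; at least four
    shared taxa are required for any non-trivial bipartition to exist.
    """
    shared = t1.tip_labels & t2.tip_labels
    if len(shared) < 4:
        raise ValueError(
            f"RF undefined: only {len(shared)} shared taxa between "
            f"{t1.og_id} and {t2.og_id} (need >= 4)"
        )
    s1 = _nontrivial_splits(t1.tree, shared)
    s2 = _nontrivial_splits(t2.tree, shared)
    return len(s1 ^ s2)


def filter_by_rf(
    gene_trees: Sequence[GeneTree],
    reference: GeneTree,
    threshold: int = 6,
) -> tuple[list[str], list[tuple[str, int | None, str]]]:
    """Partition gene trees into congruent and discordant sets.

    A tree is retained iff its RF distance to the reference (computed on
    the shared taxa) is strictly below ``threshold``; the conventional
    cutoff discards scores >= 6. Trees whose distance cannot be evaluated
    (too few shared taxa) are discarded with the reason recorded.

    Returns (retained og ids, discarded entries as (og id, score, reason)).
    """
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    retained: list[str] = []
    discarded: list[tuple[str, int | None, str]] = []
    for gt in gene_trees:
        try:
            score = rf_distance(gt, reference)
        except ValueError as exc:
            discarded.append((gt.og_id, None, str(exc)))
            continue
        if score >= threshold:
            discarded.append((gt.og_id, score, f"RF {score} >= {threshold}"))
        else:
            retained.append(gt.og_id)
    return retained, discarded


def strip_third_positions(aln: GeneAlignment) -> GeneAlignment:
    """Remove every third alignment column (positions 3, 6, 9, ...).

    Operates on codon-aligned matrices only, where columns come in
    triplets; the result keeps first and second positions and is no longer
    flagged codon-aligned.
    """
    if not aln.codon_aligned:
        raise ValueError(f"{aln.og_id}: not codon-aligned; refusing to strip")
    keep = [i for i in range(aln.length) if i % 3 != 2]
    new = {t: "".join(s[i] for i in keep) for t, s in aln.sequences.items()}
    return GeneAlignment(aln.og_id, new, codon_aligned=False)


@dataclass
class Supermatrix:
    """Concatenated partitioned character matrix."""

    taxa: list[str]
    matrix: dict[str, str]
    partitions: dict[str, tuple[int, int]] = field(default_factory=dict)

    @property
    def length(self) -> int:
        return len(next(iter(self.matrix.values())))

    @property
    def completeness(self) -> float:
        """Percent of cells that are unambiguous nucleotides (A/C/G/T)."""
        total = len(self.taxa) * self.length
        present = sum(
            1 for s in self.matrix.values() for c in s if c in "ACGT"
        )
        return 100.0 * present / total

    def describe(self) -> str:
        return (
            f"{self.completeness:.0f}% complete DNA alignment of "
            f"{len(self.taxa)} taxa and {self.length:,} characters"
        )

    def write_fasta(self, path: str | Path) -> None:
        recs = [SeqRecord(Seq(self.matrix[t]), id=t, description="") for t in self.taxa]
        SeqIO.write(recs, str(path), "fasta")

    def write_partitions(self, path: str | Path) -> None:
        """RAxML-style partition file: 'DNA, og = start-end' (1-based)."""
        lines = [
            f"DNA, {og} = {a}-{b}" for og, (a, b) in self.partitions.items()
        ]
        Path(path).write_text("\n".join(lines) + "\n")


def concatenate(alignments: Sequence[GeneAlignment]) -> Supermatrix:
    """Concatenate OG alignments; missing taxon-gene cells become '?'."""
    if not alignments:
        raise ValueError("nothing to concatenate")
    ids = [a.og_id for a in alignments]
    if len(set(ids)) != len(ids):
        dup = sorted({x for x in ids if ids.count(x) > 1})
        raise ValueError(f"duplicate gene ids: {dup}")
    taxa = sorted(set().union(*(a.taxa for a in alignments)))
    parts: dict[str, tuple[int, int]] = {}
    chunks: dict[str, list[str]] = {t: [] for t in taxa}
    pos = 0
    for a in alignments:
        parts[a.og_id] = (pos + 1, pos + a.length)
        for t in taxa:
            chunks[t].append(a.sequences.get(t, "?" * a.length))
        pos += a.length
    matrix = {t: "".join(chunks[t]) for t in taxa}
    return Supermatrix(taxa=taxa, matrix=matrix, partitions=parts)
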