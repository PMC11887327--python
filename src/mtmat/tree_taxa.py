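"""Phylogenetic tree handling, genus partitions and abundance filters.

The test operates on a rooted binary phylogenetic tree whose leaves are the
OTU/ASVs of a 16S profiling experiment.  For a genus of interest with M1
member taxa, every internal node k of the genus subtree defines a split of
its descendant leaves into the leaf sets of its left and right children
(L_k, R_k); these splits, plus the pooled genus-vs-rest contrast, are the
units of association testing.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import dendropy
import numpy as np
import pandas as pd

__all__ = [
    "RootedBinaryTree",
    "TestNode",
    "GenusPartition",
    "CountTable",
    "parse_tree",
    "to_newick",
    "enumerate_test_nodes",
    "filter_taxa",
    "filter_samples",
]


class TreeValidationError(ValueError):
    """Raised when a tree violates the rooted-binary contract."""


@dataclass(frozen=True)
class TestNode:
    """One internal node of a genus subtree with its child leaf sets."""

    k: int
    left_leaves: frozenset
    right_leaves: frozenset

    def __post_init__(self):
        if not self.left_leaves or not self.right_leaves:
            raise TreeValidationError("test node with empty child leaf set")
        if self.left_leaves & self.right_leaves:
            raise TreeValidationError("left/right leaf sets overlap")


@dataclass
class RootedBinaryTree:
    """Validated rooted binary tree with named leaves.

    ``children`` maps each internal node id to its (left, right) children in
    Newick order: the first-listed child is the left child.  Leaf node ids map
    to taxon names through ``leaf_taxon``.
    """

    root: int
    children: dict
    leaf_taxon: dict

    @property
    def taxa(self) -> frozenset:
        return frozenset(self.leaf_taxon.values())

    def leaves_under(self, node: int) -> frozenset:
        """Taxon names of all leaves descending from ``node`` (inclusive)."""
        out = []
        stack = [node]
        while stack:
            n = stack.pop()
            if n in self.leaf_taxon:
                out.append(self.leaf_taxon[n])
            else:
                stack.extend(self.children[n])
        return frozenset(out)


@dataclass
class GenusPartition:
    """A genus of interest: member taxa, the complement, and its test nodes.

    ``M1`` counts the statistics tested for the genus: the pooled
    genus-vs-reference contrast plus one per internal node of the genus
    subtree, i.e. M1 = number of member taxa.
    """

    genus: str
    member_taxa: tuple
    other_taxa: tuple
    test_nodes: list = field(default_factory=list)

    @property
    def M1(self) -> int:
        return len(self.member_taxa)


@dataclass
class CountTable:
    """Taxa x sample absolute abundances with subject/visit indexing.

    ``counts`` is indexed by taxon (rows) and sample id (columns).
    ``samples`` carries one row per sample with columns ``subject_id`` and
    ``visit`` (integer, ascending within subject).  ``library_size`` is the
    per-sample total read count, frozen at construction so that taxon
    filtering does not silently change the CPM denominator.
    """

    counts: pd.DataFrame
    samples: pd.DataFrame
    library_size: pd.Series = None

    def __post_init__(self):
        if (self.counts.values < 0).any():
            raise ValueError("negative counts")
        if list(self.counts.columns) != list(self.samples.index):
            raise ValueError("counts columns and sample index disagree")
        if self.library_size is None:
            self.library_size = self.counts.sum(axis=0)

    @property
    def taxa(self) -> list:
        return list(self.counts.index)

    @property
    def n_samples(self) -> int:
        return self.counts.shape[1]

    def visits_per_subject(self) -> pd.Series:
        return self.samples.groupby("subject_id", sort=False).size()


def parse_tree(newick_text: str, resolve_polytomies: bool = False) -> RootedBinaryTree:
    """Parse a Newick string into a validated :class:`RootedBinaryTree`.

    Branch lengths are ignored.  Multifurcating nodes are rejected unless
    ``resolve_polytomies`` is set, in which case each polytomy is resolved
    deterministically into a left-leaning caterpillar preserving child order.
    """
    try:
        tree = dendropy.Tree.get(
            data=newick_text, schema="newick", suppress_internal_node_taxa=True,
            preserve_underscores=True,
        )
    except Exception as exc:  # dendropy raises several error types
        if "Duplicate taxon" in str(exc):
            raise TreeValidationError("duplicate leaf names in tree") from None
        raise ValueError(f"malformed Newick: {exc}") from None

    names = [lf.taxon.label for lf in tree.leaf_node_iter()]
    if len(names) != len(set(names)):
        raise TreeValidationError("duplicate leaf names in tree")
    if any(n is None for n in names):
        raise TreeValidationError("unnamed leaf in tree")

    children: dict = {}
    leaf_taxon: dict = {}
    counter = 0

    def build(node) -> int:
        nonlocal counter
        nid = counter
        counter += 1
        kids = node.child_nodes()
        if not kids:
            leaf_taxon[nid] = node.taxon.label
            return nid
        if len(kids) == 1:
            # unifurcation: collapse through
            counter -= 1
            return build(kids[0])
        if len(kids) > 2:
            if not resolve_polytomies:
                raise TreeValidationError(
                    f"non-binary node with {len(kids)} children"
                )
            # left-leaning caterpillar: ((((c1,c2),c3),c4)...)
            left = build(kids[0])
            for kid in kids[1:]:
                right = build(kid)
                inner = counter
                counter += 1
                children[inner] = (left, right)
                left = inner
            return left
        left = build(kids[0])
        right = build(kids[1])
        children[nid] = (left, right)
        return nid

    root = build(tree.seed_node)
    if root in leaf_taxon and not children:
        raise TreeValidationError("tree has a single leaf")
    return RootedBinaryTree(root=root, children=children, leaf_taxon=leaf_taxon)


def to_newick(tree: RootedBinaryTree) -> str:
    """Serialize back to Newick (topology only, child order preserved)."""
    def rec(n: int) -> str:
        if n in tree.leaf_taxon:
            return tree.leaf_taxon[n]
        left, right = tree.children[n]
        return f"({rec(left)},{rec(right)})"
    return rec(tree.root) + ";"


def enumerate_test_nodes(
    tree: RootedBinaryTree,
    genus_taxa,
    genus_name: str = "",
    strict: bool = True,
    tolerate=frozenset(),
) -> GenusPartition:
    """Enumerate the test nodes of a genus as a :class:`GenusPartition`.

    The genus subtree is the clade spanned by ``genus_taxa``; its internal
    nodes are numbered k = 1..M1-1 in pre-order starting from the subtree
    root.  In strict mode the clade must contain exactly the genus taxa
    (monophyly); lenient mode restricts the minimal spanning clade to genus
    members and warns about foreign leaves.  Leaves in ``tolerate`` (e.g.
    congeners removed by the abundance filter) never count as foreign.
    """
    genus_taxa = frozenset(genus_taxa)
    if not genus_taxa:
        raise ValueError("empty genus")
    if not genus_taxa <= tree.taxa:
        missing = sorted(genus_taxa - tree.taxa)
        raise ValueError(f"genus taxa absent from tree: {missing}")

    # find the MRCA: walk down from the root while one child contains all
    node = tree.root
    while node in tree.children:
        left, right = tree.children[node]
        if genus_taxa <= tree.leaves_under(left):
            node = left
        elif genus_taxa <= tree.leaves_under(right):
            node = right
        else:
            break
    clade_leaves = tree.leaves_under(node)
    foreign = clade_leaves - genus_taxa - frozenset(tolerate)
    if foreign:
        if strict:
            raise TreeValidationError(
                f"genus {genus_name or genus_taxa} is not monophyletic; "
                f"foreign leaves in spanning clade: {sorted(foreign)}"
            )
        warnings.warn(
            f"genus {genus_name}: excluding {len(foreign)} foreign leaves "
            "from spanning clade",
            stacklevel=2,
        )

    test_nodes = []
    k = 1
    order = _preorder_internal(tree, node)
    for n in order:
        left, right = tree.children[n]
        L = tree.leaves_under(left) & genus_taxa
        R = tree.leaves_under(right) & genus_taxa
        if not L or not R:
            # node does not split genus members (all foreign on one side)
            continue
        test_nodes.append(TestNode(k=k, left_leaves=L, right_leaves=R))
        k += 1

    member = tuple(sorted(genus_taxa))
    other = tuple(sorted(tree.taxa - genus_taxa))
    part = GenusPartition(
        genus=genus_name, member_taxa=member, other_taxa=other, test_nodes=test_nodes
    )
    if len(test_nodes) != part.M1 - 1:
        raise TreeValidationError(
            f"genus {genus_name}: expected {part.M1 - 1} test nodes, "
            f"found {len(test_nodes)}"
        )
    return part


def _preorder_internal(tree: RootedBinaryTree, start: int) -> list:
    out = []
    stack = [start]
    while stack:
        n = stack.pop()
        if n in tree.children:
            out.append(n)
            left, right = tree.children[n]
            stack.append(right)
            stack.append(left)
    return out


def filter_taxa(table: CountTable, min_mean_prop: float = 0.001) -> CountTable:
    """Drop taxa whose mean relative abundance across all samples is below
    ``min_mean_prop``.

    Proportions are computed per sample against the frozen library size and
    averaged over all samples (subject-visits pooled).  Library sizes are not
    recomputed, so the CPM denominator is unaffected by the filter.
    """
    lib = table.library_size.values.astype(float)
    props = table.counts.values / np.where(lib > 0, lib, 1.0)
    keep = props.mean(axis=1) >= min_mean_prop
    if not keep.any():
        raise ValueError("all taxa removed by abundance filter")
    return CountTable(
        counts=table.counts.loc[keep],
        samples=table.samples.copy(),
        library_size=table.library_size.copy(),
    )


def filter_samples(table: CountTable, min_reads: int = 3000) -> CountTable:
    """Drop samples with library size below ``min_reads`` (subjects losing
    every visit disappear entirely)."""
    keep = table.library_size >= min_reads
    if not keep.any():
        warnings.warn("all samples removed by read-count filter", stacklevel=2)
    cols = table.counts.columns[keep.values]
    return CountTable(
        counts=table.counts[cols],
        samples=table.samples.loc[cols].copy(),
        library_size=table.library_size[cols].copy(),
    )
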