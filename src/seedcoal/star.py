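"""Species-tree estimation by average ranks of coalescence (STAR).

Each rooted gene tree induces a pairwise distance between the species it
contains: twice the topological rank of the pair's most recent common
ancestor, where the root of a gene tree with ``n`` tips has rank ``n - 1``
and ranks decrease by one per level towards the tips.  Averaging these
distances across gene trees and running neighbor joining on the mean matrix
yields a statistically consistent species-tree estimate under the
multispecies coalescent.  The rank convention at the root (``n - 1`` versus
``n``) shifts all distances by a constant and leaves the neighbor-joining
topology unchanged.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import dendropy
import numpy as np

from .genetrees import neighbor_joining, root_with_outgroup
from .trees import DEFAULT_SEP, split_label


class CoverageError(ValueError):
    """Some species pair never co-occurs in any gene tree."""


@dataclass
class RankDistanceMatrix:
    species: list[str]
    mean_distance: np.ndarray   # (n, n) symmetric, zero diagonal
    pair_counts: np.ndarray     # (n, n) genes where both species occur

    def to_tsv(self, path: str) -> None:
        with open(path, "w") as fh:
            fh.write("species\t" + "\t".join(self.species) + "\n")
            for i, sp in enumerate(self.species):
                row = "\t".join(f"{v:.6g}" for v in self.mean_distance[i])
                fh.write(f"{sp}\t{row}\n")


def node_ranks(tree: dendropy.Tree,
               root_rank_offset: int = 0) -> dict[dendropy.Node, int]:
    """Topological ranks of internal nodes.

    The root has rank ``n - 1 + root_rank_offset`` for ``n`` tips; every
    child internal node has its parent's rank minus one (children of a
    polytomy share the same rank).  Tips carry no rank.
    """
    if not tree.is_rooted:
        raise ValueError("node ranks require a rooted tree")
    n = sum(1 for _ in tree.leaf_node_iter())
    if n < 2:
        raise ValueError("need at least two tips")
    ranks: dict[dendropy.Node, int] = {}
    for node in tree.preorder_node_iter():
        if node.is_leaf():
            continue
        if node is tree.seed_node:
            ranks[node] = n - 1 + root_rank_offset
        else:
            ranks[node] = ranks[node.parent_node] - 1
    return ranks


def _tree_pair_distances(tree: dendropy.Tree, sep: str,
                         root_rank_offset: int) -> dict[tuple[str, str], int]:
    """2 x MRCA-rank for every species pair in one gene tree."""
    ranks = node_ranks(tree, root_rank_offset)
    spsets: dict[dendropy.Node, set[str]] = {}
    dists: dict[tuple[str, str], int] = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            sp, _ = split_label(node.taxon.label, sep)
            spsets[node] = {sp}
            continue
        children = node.child_nodes()
        sets = [spsets[ch] for ch in children]
        merged: set[str] = set()
        for a_idx in range(len(sets)):
            for b_idx in range(a_idx + 1, len(sets)):
                for s1 in sets[a_idx]:
                    for s2 in sets[b_idx]:
                        if s1 == s2:
                            raise ValueError(
                                f"species {s1!r} has multiple tips in a gene "
                                "tree; prune paralogues first")
                        key = (min(s1, s2), max(s1, s2))
                        dists[key] = 2 * ranks[node]
        for s in sets:
            merged |= s
        spsets[node] = merged
    return dists


def star_distances(gene_trees: Sequence[dendropy.Tree],
                   sep: str = DEFAULT_SEP,
                   root_rank_offset: int = 0,
                   rank_normalization: str = "global") -> RankDistanceMatrix:
    """Average 2x-rank distances over gene trees.

    With ``rank_normalization="global"`` (the default) the root of every
    gene tree is ranked ``N - 1`` for ``N`` the total species count across
    all trees, so distances from trees with different taxon subsets live on
    a common scale; ``"local"`` uses each tree's own tip count (``n - 1``),
    which biases pairs that co-occur mainly in sparsely sampled trees when
    taxa are missing non-uniformly.  ``root_rank_offset`` shifts every root
    rank by a constant, which shifts all distances by a constant and leaves
    the downstream neighbor-joining topology unchanged.

    Gene trees with fewer than two species (after tip-to-species mapping)
    are skipped with a warning.  A species pair that never co-occurs raises
    :class:`CoverageError` naming the missing pairs.
    """
    if not gene_trees:
        raise ValueError("no gene trees")
    if rank_normalization not in ("global", "local"):
        raise ValueError(f"unknown rank_normalization {rank_normalization!r}")
    species: set[str] = set()
    usable: list[tuple[dendropy.Tree, int]] = []
    for t in gene_trees:
        sps = {split_label(lf.taxon.label, sep)[0]
               for lf in t.leaf_node_iter()}
        if len(sps) < 2:
            warnings.warn("skipping gene tree with fewer than two species")
            continue
        species |= sps
        usable.append((t, sum(1 for _ in t.leaf_node_iter())))
    if not usable:
        raise ValueError("no usable gene trees")
    n_total = len(species)
    per_tree: list[dict[tuple[str, str], int]] = []
    for t, n_tips in usable:
        offset = root_rank_offset
        if rank_normalization == "global":
            offset += n_total - n_tips
        per_tree.append(_tree_pair_distances(t, sep, offset))
    sp = sorted(species)
    idx = {s: i for i, s in enumerate(sp)}
    n = len(sp)
    total = np.zeros((n, n))
    counts = np.zeros((n, n), dtype=int)
    for dists in per_tree:
        for (s1, s2), d in dists.items():
            i, j = idx[s1], idx[s2]
            total[i, j] += d
            total[j, i] += d
            counts[i, j] += 1
            counts[j, i] += 1
    missing = [(sp[i], sp[j]) for i in range(n) for j in range(i + 1, n)
               if counts[i, j] == 0]
    if missing:
        raise CoverageError("species pairs never co-occur in any gene tree: "
                            + ", ".join(f"{a}-{b}" for a, b in missing))
    mean = np.zeros((n, n))
    off = counts > 0
    mean[off] = total[off] / counts[off]
    return RankDistanceMatrix(species=sp, mean_distance=mean,
                              pair_counts=counts)


def star_species_tree(gene_trees: Sequence[dendropy.Tree],
                      outgroup: str,
                      sep: str = DEFAULT_SEP,
                      root_rank_offset: int = 0,
                      rank_normalization: str = "global") -> dendropy.Tree:
    """STAR point estimate: NJ on the mean rank-distance matrix, rooted by
    the outgroup.  Tip labels of the result are species names."""
    rd = star_distances(gene_trees, sep=sep, root_rank_offset=root_rank_offset,
                        rank_normalization=rank_normalization)
    if outgroup not in rd.species:
        raise ValueError(f"outgroup {outgroup!r} not among species "
                         f"{rd.species}")
    tree = neighbor_joining(rd.species, rd.mean_distance)
    return root_with_outgroup(tree, outgroup, sep)
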