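"""Shared tree helpers built on :mod:`dendropy`.

Throughout the package, gene-tree tips are labelled ``species<sep>sequence_id``
(default separator ``|``), while species-tree tips carry the bare species
name.  The helpers here centralise label parsing, Newick I/O, and the
species-level bipartition encoding used for topology comparison and
bootstrap support.
"""

from __future__ import annotations

from typing import Iterable

import dendropy

DEFAULT_SEP = "|"


class LabelError(ValueError):
    """A tip label does not parse as species + sequence id."""


def split_label(label: str, sep: str = DEFAULT_SEP) -> tuple[str, str]:
    """Split ``species|seqid`` into its parts.

    A label without the separator is treated as a bare species name (the
    convention for species-tree tips): both parts are the label itself.
    """
    if sep in label:
        species, _, seqid = label.partition(sep)
        if not species or not seqid:
            raise LabelError(f"malformed tip label {label!r} (empty species or id)")
        return species, seqid
    return label, label


def leaf_labels(tree: dendropy.Tree) -> list[str]:
    return [lf.taxon.label for lf in tree.leaf_node_iter()]


def leaf_species(tree: dendropy.Tree, sep: str = DEFAULT_SEP) -> list[str]:
    return [split_label(lb, sep)[0] for lb in leaf_labels(tree)]


def parse_newick(newick: str, rooted: bool | None = None) -> dendropy.Tree:
    """Parse a single Newick string into a tree with its own taxon namespace."""
    tree = dendropy.Tree.get(data=newick, schema="newick",
                             preserve_underscores=True)
    if rooted is not None:
        tree.is_rooted = rooted
    return tree


def read_trees(path: str) -> list[dendropy.Tree]:
    """Read all trees from a Newick file (one or more trees)."""
    tl = dendropy.TreeList.get(path=path, schema="newick",
                               preserve_underscores=True)
    return list(tl)


def write_trees(trees: Iterable[dendropy.Tree], path: str) -> None:
    with open(path, "w") as fh:
        for t in trees:
            fh.write(to_newick(t) + "\n")


def to_newick(tree: dendropy.Tree) -> str:
    return tree.as_string(schema="newick", suppress_rooting=True,
                          unquoted_underscores=True).strip()


def species_bipartitions(tree: dendropy.Tree,
                         sep: str = DEFAULT_SEP) -> set[frozenset[str]]:
    """Non-trivial unrooted bipartitions, encoded at the species level.

    Each internal edge splits the species set in two; the split is encoded
    canonically as the side NOT containing the lexicographically smallest
    species, so rooted and unrooted representations of the same topology
    compare equal.
    """
    all_sp = frozenset(leaf_species(tree, sep))
    anchor = min(all_sp)
    n = len(all_sp)
    splits: set[frozenset[str]] = set()
    for node in tree.preorder_node_iter():
        if node is tree.seed_node or node.is_leaf():
            continue
        below = frozenset(split_label(lf.taxon.label, sep)[0]
                          for lf in node.leaf_iter())
        side = all_sp - below if anchor in below else below
        if 2 <= len(side) <= n - 2:
            splits.add(side)
    return splits


def rooted_species_clades(tree: dendropy.Tree,
                          sep: str = DEFAULT_SEP) -> set[frozenset[str]]:
    """Species sets of all internal nodes except the root (rooted clades)."""
    clades: set[frozenset[str]] = set()
    for node in tree.preorder_node_iter():
        if node is tree.seed_node or node.is_leaf():
            continue
        clades.add(frozenset(split_label(lf.taxon.label, sep)[0]
                             for lf in node.leaf_iter()))
    return clades


def same_topology(a: dendropy.Tree, b: dendropy.Tree,
                  sep: str = DEFAULT_SEP) -> bool:
    """Unrooted species-level topology equality (same species, same splits)."""
    if set(leaf_species(a, sep)) != set(leaf_species(b, sep)):
        return False
    return species_bipartitions(a, sep) == species_bipartitions(b, sep)


def extract_clade(tree: dendropy.Tree, labels: Iterable[str]) -> dendropy.Tree:
    """Independent copy of the subtree induced by the given tip labels."""
    sub = tree.extract_tree_with_taxa_labels(labels=set(labels))
    sub.is_rooted = tree.is_rooted
    return sub


def prune_to_labels(tree: dendropy.Tree, keep: Iterable[str]) -> dendropy.Tree:
    """Clone of ``tree`` restricted to the given tip labels."""
    return extract_clade(tree, keep)
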