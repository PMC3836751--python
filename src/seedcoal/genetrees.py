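"""Gene-tree estimation and single-copy decomposition.

The built-in tree engine is Jukes-Cantor distances plus neighbor joining,
used both for per-gene trees and (downstream) for the STAR species tree and
the concatenation estimator.  External maximum-likelihood estimators can be
plugged in as a command template (see :class:`ExternalTreeEstimator`).

Rooted gene trees are reduced to single-copy inputs for coalescent species
tree estimation in two steps: monophyly masking (collapse same-species
clades to one representative) and iterative paralogue pruning (repeatedly
extract the maximally inclusive subtree holding at most one sequence per
species).
"""

from __future__ import annotations

import math
import os
import shlex
import subprocess
import tempfile
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import dendropy
import numpy as np

from .trees import DEFAULT_SEP, parse_newick, split_label

_CODE = np.full(256, 255, dtype=np.uint8)
for _i, _c in enumerate("ACGT"):
    _CODE[ord(_c)] = _i
    _CODE[ord(_c.lower())] = _i


class SaturationError(ValueError):
    """Observed divergence is outside the model's correctable range."""


class RootingError(ValueError):
    pass


def encode_rows(rows: Sequence[str]) -> np.ndarray:
    """Rows to a (n, sites) uint8 matrix; A,C,G,T -> 0..3, all else 255."""
    raw = np.array([list(r.encode()) for r in rows], dtype=np.uint8)
    return _CODE[raw]


def p_distance(rows: Sequence[str]) -> np.ndarray:
    """Pairwise mismatch proportions over columns where both rows have an
    unambiguous nucleotide.  Pairs without comparable columns get NaN."""
    mat = encode_rows(rows)
    n = mat.shape[0]
    d = np.zeros((n, n))
    valid = mat < 4
    for i in range(n):
        for j in range(i + 1, n):
            both = valid[i] & valid[j]
            nc = int(both.sum())
            if nc == 0:
                d[i, j] = d[j, i] = math.nan
                continue
            p = float((mat[i][both] != mat[j][both]).sum()) / nc
            d[i, j] = d[j, i] = p
    return d


def jc_distance(rows: Sequence[str],
                labels: Sequence[str] | None = None) -> np.ndarray:
    """Jukes-Cantor corrected distances, d = -(3/4) ln(1 - (4/3) p).

    Raises :class:`SaturationError` when a pair's mismatch proportion reaches
    3/4 (the correction is undefined) and ``ValueError`` when a pair shares
    no comparable columns.
    """
    if len(rows) < 2:
        raise ValueError("need at least two rows")
    p = p_distance(rows)
    n = p.shape[0]
    names = list(labels) if labels is not None else [str(i) for i in range(n)]
    d = np.zeros_like(p)
    for i in range(n):
        for j in range(i + 1, n):
            pij = p[i, j]
            if math.isnan(pij):
                raise ValueError(f"no comparable columns between "
                                 f"{names[i]!r} and {names[j]!r}")
            if pij >= 0.75:
                raise SaturationError(
                    f"pair ({names[i]!r}, {names[j]!r}) is saturated "
                    f"(p = {pij:.3f} >= 3/4)")
            d[i, j] = d[j, i] = -0.75 * math.log1p(-4.0 * pij / 3.0)
    return d


def neighbor_joining(labels: Sequence[str], d: np.ndarray) -> dendropy.Tree:
    """Saitou-Nei neighbor joining.

    Ties in the Q-matrix minimisation are broken by the lexicographically
    smallest (sorted) pair of cluster labels, where a cluster's label is the
    smallest tip label it contains.  A negative branch length at a join is
    clamped to zero with the deficit moved to the sister edge (at the final
    trifurcation the deficit is split over the other two edges).  The result
    is an unrooted tree with a trifurcating seed node.
    """
    d = np.asarray(d, dtype=float)
    n = len(labels)
    if n < 3:
        raise ValueError("neighbor joining needs at least 3 taxa")
    if d.shape != (n, n):
        raise ValueError("distance matrix shape mismatch")
    if np.isnan(d).any() or (d < 0).any():
        raise ValueError("distances must be finite and non-negative")
    if not np.allclose(d, d.T):
        raise ValueError("distance matrix must be symmetric")

    ns = dendropy.TaxonNamespace()
    node_of: dict[int, dendropy.Node] = {}
    for i, lab in enumerate(labels):
        taxon = dendropy.Taxon(label=lab)
        ns.add_taxon(taxon)
        node_of[i] = dendropy.Node(taxon=taxon)
    clab = {i: lab for i, lab in enumerate(labels)}  # tie-break label
    active = list(range(n))
    dist = {(min(i, j), max(i, j)): d[i, j]
            for i in range(n) for j in range(i + 1, n)}
    next_id = n

    def dd(i: int, j: int) -> float:
        return dist[(min(i, j), max(i, j))]

    while len(active) > 3:
        m = len(active)
        r = {i: sum(dd(i, k) for k in active if k != i) for i in active}
        best = None
        best_q = math.inf
        for ai in range(m):
            for aj in range(ai + 1, m):
                i, j = active[ai], active[aj]
                q = (m - 2) * dd(i, j) - r[i] - r[j]
                pair_key = tuple(sorted((clab[i], clab[j])))
                if (q < best_q - 1e-12 or
                        (abs(q - best_q) <= 1e-12 and best is not None
                         and pair_key < best[2])):
                    best, best_q = (i, j, pair_key), q
        i, j, _ = best
        dij = dd(i, j)
        li = 0.5 * dij + (r[i] - r[j]) / (2 * (m - 2))
        lj = dij - li
        if li < 0:
            lj += li
            li = 0.0
        if lj < 0:
            li = max(li + lj, 0.0)
            lj = 0.0
        u = dendropy.Node()
        ci, cj = node_of[i], node_of[j]
        u.add_child(ci)
        u.add_child(cj)
        ci.edge.length = li
        cj.edge.length = lj
        node_of[next_id] = u
        clab[next_id] = min(clab[i], clab[j])
        for k in active:
            if k in (i, j):
                continue
            dist[(min(next_id, k), max(next_id, k))] = \
                0.5 * (dd(i, k) + dd(j, k) - dij)
        active = [k for k in active if k not in (i, j)] + [next_id]
        next_id += 1

    a, b, c = active
    la = 0.5 * (dd(a, b) + dd(a, c) - dd(b, c))
    lb = 0.5 * (dd(a, b) + dd(b, c) - dd(a, c))
    lc = 0.5 * (dd(a, c) + dd(b, c) - dd(a, b))
    lens = [la, lb, lc]
    for idx in range(3):
        if lens[idx] < 0:
            deficit = lens[idx]
            lens[idx] = 0.0
            for other in range(3):
                if other != idx:
                    lens[other] = max(lens[other] + deficit / 2, 0.0)
    root = dendropy.Node()
    for k, ln in zip((a, b, c), lens):
        root.add_child(node_of[k])
        node_of[k].edge.length = ln
    tree = dendropy.Tree(taxon_namespace=ns)
    tree.seed_node = root
    tree.is_rooted = False
    return tree


def _outgroup_score(node: dendropy.Node, n_out: int, n_in: int,
                    sep: str, outgroup: str) -> int:
    k = i = 0
    for lf in node.leaf_iter():
        sp, _ = split_label(lf.taxon.label, sep)
        if sp == outgroup:
            k += 1
        else:
            i += 1
    return max(k - i, (n_out - k) - (n_in - i))


def root_with_outgroup(tree: dendropy.Tree, outgroup_species: str,
                       sep: str = DEFAULT_SEP) -> dendropy.Tree:
    """Root on the edge separating the outgroup tips from the rest.

    When the outgroup tips are not separable by one edge, the edge whose
    split best isolates them (maximising outgroup-minus-ingroup tips on a
    side, ties to the smallest preorder index) is used and a warning is
    emitted.  The chosen edge is bisected at its midpoint when it has a
    length.  Returns a new rooted tree; the input is left untouched.
    """
    t = tree.clone(depth=1)
    species = [split_label(lf.taxon.label, sep)[0]
               for lf in t.leaf_node_iter()]
    n_out = sum(1 for sp in species if sp == outgroup_species)
    n_in = len(species) - n_out
    if n_out == 0:
        raise RootingError(f"outgroup species {outgroup_species!r} absent")
    if n_in == 0:
        t.is_rooted = True
        return t
    best_node, best_score = None, -len(species) - 1
    for node in t.preorder_node_iter():
        if node is t.seed_node:
            continue
        score = _outgroup_score(node, n_out, n_in, sep, outgroup_species)
        if score > best_score:
            best_node, best_score = node, score
    if best_score < n_out:
        warnings.warn("outgroup tips are not separable by a single edge; "
                      "rooting on the best-scoring edge")
    edge = best_node.edge
    if edge.length is not None:
        half = edge.length / 2.0
        t.reroot_at_edge(edge, length1=half, length2=half,
                         update_bipartitions=False)
    else:
        t.reroot_at_edge(edge, update_bipartitions=False)
    t.is_rooted = True
    return t


def monophyly_mask(tree: dendropy.Tree,
                   lengths: Mapping[str, int] | None = None,
                   sep: str = DEFAULT_SEP) -> dendropy.Tree:
    """Collapse every maximal same-species clade to a single tip.

    The representative is the tip whose underlying sequence is longest
    (``lengths`` maps sequence id to length); ties go to the
    lexicographically smallest sequence id.  The kept tip retains its own
    original terminal branch length.  Idempotent.
    """
    if not tree.is_rooted:
        raise ValueError("monophyly masking requires a rooted tree")
    t = tree.clone(depth=1)
    spset: dict[dendropy.Node, set[str]] = {}
    for node in t.postorder_node_iter():
        if node.is_leaf():
            spset[node] = {split_label(node.taxon.label, sep)[0]}
        else:
            s: set[str] = set()
            for ch in node.child_nodes():
                s |= spset[ch]
            spset[node] = s
    drop: list[str] = []
    keep_lengths: dict[str, float | None] = {}
    for node in t.preorder_node_iter():
        if node.is_leaf() or len(spset[node]) != 1:
            continue
        parent = node.parent_node
        if parent is not None and len(spset[parent]) == 1:
            continue  # not maximal
        leaves = list(node.leaf_iter())

        def _key(lf: dendropy.Node) -> tuple[float, str]:
            label = lf.taxon.label
            _, sid = split_label(label, sep)
            ln = 0.0
            if lengths:
                ln = float(lengths.get(label, lengths.get(sid, 0)))
            return (-ln, sid)

        kept = min(leaves, key=_key)
        keep_lengths[kept.taxon.label] = kept.edge.length
        drop.extend(lf.taxon.label for lf in leaves if lf is not kept)
    if drop:
        t.prune_taxa_with_labels(drop, suppress_unifurcations=True)
        for lf in t.leaf_node_iter():
            if lf.taxon.label in keep_lengths:
                lf.edge.length = keep_lengths[lf.taxon.label]
    return t


@dataclass
class SubtreeFilterRules:
    min_species: int = 7
    min_frac_of_cluster_species: float = 0.60


def _single_copy(node: dendropy.Node, sep: str) -> tuple[bool, int, int]:
    """(is single-copy, n_species, n_tips) for the clade at ``node``."""
    seen: set[str] = set()
    tips = 0
    for lf in node.leaf_iter():
        sp, _ = split_label(lf.taxon.label, sep)
        if sp in seen:
            return False, 0, 0
        seen.add(sp)
        tips += 1
    return True, len(seen), tips


def best_single_copy_clade(tree: dendropy.Tree,
                           sep: str = DEFAULT_SEP) -> dendropy.Node:
    """The maximally inclusive clade with at most one tip per species.

    Scored by species count, then tip count, then smallest preorder index.
    Single tips always qualify, so a best clade always exists.
    """
    best = None
    best_key = None
    for idx, node in enumerate(tree.preorder_node_iter()):
        ok, nsp, ntip = _single_copy(node, sep)
        if not ok:
            continue
        key = (-nsp, -ntip, idx)
        if best_key is None or key < best_key:
            best, best_key = node, key
    return best


def paralogue_prune(tree: dendropy.Tree,
                    sep: str = DEFAULT_SEP) -> list[dendropy.Tree]:
    """Iteratively extract maximally inclusive single-copy subtrees.

    Repeat until the remaining tree has at most one sequence per species:
    find the clade (whole tree and single tips included) with no more than
    one tip per species, maximising species count, then tip count, then the
    smallest preorder index; emit it; delete its tips and suppress unary
    nodes.  The remainder is emitted last.  Emitted pieces with fewer than
    two tips are discarded.
    """
    if not tree.is_rooted:
        raise ValueError("paralogue pruning requires a rooted tree")
    t = tree.clone(depth=1)
    out: list[dendropy.Tree] = []
    while True:
        leaves = list(t.leaf_node_iter())
        if not leaves:
            break
        best = best_single_copy_clade(t, sep)
        labels = [lf.taxon.label for lf in best.leaf_iter()]
        if len(labels) >= 2:
            sub = t.extract_tree_with_taxa_labels(labels=set(labels))
            sub.is_rooted = True
            out.append(sub)
        if best is t.seed_node or len(labels) == len(leaves):
            break
        t.prune_taxa_with_labels(labels, suppress_unifurcations=True)
        remaining = list(t.leaf_node_iter())
        if len(remaining) < 2:
            break
    return out


def subtree_filter(subtrees: Sequence[dendropy.Tree],
                   rules: SubtreeFilterRules,
                   original_cluster_species: set[str],
                   sep: str = DEFAULT_SEP) -> list[dendropy.Tree]:
    """Keep subtrees with enough species, absolutely and relative to the
    originating cluster (real-valued comparison, no rounding)."""
    kept = []
    # epsilon guards float rounding at exact fractions only
    need = (rules.min_frac_of_cluster_species
            * len(original_cluster_species) - 1e-9)
    for st in subtrees:
        nsp = len({split_label(lf.taxon.label, sep)[0]
                   for lf in st.leaf_node_iter()})
        if nsp >= rules.min_species and nsp >= need:
            kept.append(st)
    return kept


class ExternalTreeEstimator:
    """Adapter for an external gene-tree program.

    ``command_template`` is a shell-style template with ``{fasta}`` and
    ``{newick}`` placeholders; the program must read the FASTA alignment and
    write a Newick tree.  The output is validated before use.
    """

    def __init__(self, command_template: str):
        self.command_template = command_template

    def __call__(self, labels: Sequence[str],
                 rows: Sequence[str]) -> dendropy.Tree:
        with tempfile.TemporaryDirectory() as tmp:
            fasta = os.path.join(tmp, "aln.fasta")
            newick = os.path.join(tmp, "tree.nwk")
            with open(fasta, "w") as fh:
                for lab, row in zip(labels, rows):
                    fh.write(f">{lab}\n{row}\n")
            cmd = self.command_template.format(fasta=shlex.quote(fasta),
                                               newick=shlex.quote(newick))
            subprocess.run(cmd, shell=True, check=True)
            if not os.path.exists(newick):
                raise RuntimeError("external estimator produced no tree file")
            with open(newick) as fh:
                tree = parse_newick(fh.read())
        got = {lf.taxon.label for lf in tree.leaf_node_iter()}
        if got != set(labels):
            raise RuntimeError("external estimator tree labels do not match "
                               f"the alignment: {got ^ set(labels)}")
        return tree


def nj_gene_tree(labels: Sequence[str], rows: Sequence[str],
                 outgroup: str | None = None,
                 sep: str = DEFAULT_SEP) -> dendropy.Tree:
    """Built-in gene-tree engine: JC distances + NJ, optionally rooted."""
    d = jc_distance(rows, labels)
    tree = neighbor_joining(labels, d)
    if outgroup is not None:
        tree = root_with_outgroup(tree, outgroup, sep)
    return tree
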