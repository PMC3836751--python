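"""Orthology clustering: similarity graph, Markov clustering, cluster filters.

All-vs-all protein similarity hits (blast outfmt-6 style) are thresholded at
an e-value cutoff and turned into a weighted undirected graph; Markov
clustering (MCL) partitions the graph into putative gene families; a set of
five retention filters then keeps clusters suitable for low-copy nuclear
phylogenetics (outgroup present, enough species, long enough sequences, and
bounded per-species copy number).
"""

from __future__ import annotations

import math
import statistics
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .trees import DEFAULT_SEP, LabelError, split_label

WEIGHT_CAP = 200.0


@dataclass(frozen=True)
class SimilarityHit:
    query_id: str
    subject_id: str
    evalue: float

    def __post_init__(self) -> None:
        if self.evalue < 0:
            raise ValueError(f"negative e-value for {self.query_id} vs "
                             f"{self.subject_id}")


@dataclass
class SimilarityGraph:
    """Undirected weighted graph over sequence identifiers."""

    nodes: list[str]
    edges: dict[tuple[str, str], float] = field(default_factory=dict)

    def weight(self, u: str, v: str) -> float | None:
        return self.edges.get((min(u, v), max(u, v)))


@dataclass
class GeneCluster:
    cluster_id: str
    members: list[tuple[str, str, int]]  # (species, sequence_id, length_aa)

    @property
    def species_counts(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for sp, _, _ in self.members:
            out[sp] = out.get(sp, 0) + 1
        return out

    @property
    def species(self) -> set[str]:
        return {sp for sp, _, _ in self.members}

    @property
    def sequence_ids(self) -> list[str]:
        return [sid for _, sid, _ in self.members]


@dataclass
class ClusterFilterRules:
    require_outgroup_species: str
    min_species: int = 4
    min_len_aa: int = 100
    max_mean_seqs_per_species: float = 5.0   # strict <
    max_median_seqs_per_species: float = 2.0  # strict <


def parse_hits_table(path: str) -> list[SimilarityHit]:
    """Read a 12-column tabular hit file (qseqid sseqid ... evalue bitscore).

    Only columns 1, 2 and 11 are consumed.
    """
    hits: list[SimilarityHit] = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) < 11:
                raise ValueError(f"{path}:{ln}: expected >=11 tab-separated "
                                 f"columns, got {len(cols)}")
            hits.append(SimilarityHit(cols[0], cols[1], float(cols[10])))
    return hits


def build_similarity_graph(hits: Iterable[SimilarityHit],
                           evalue_threshold: float = 1e-20,
                           sep: str = DEFAULT_SEP) -> SimilarityGraph:
    """Threshold hits and build the undirected similarity graph.

    An edge exists iff some hit in either direction has
    ``evalue <= evalue_threshold`` and query != subject.  The weight is
    ``min(-log10(evalue), 200)`` of the best hit over both directions
    (an e-value of exactly zero maps to the cap).  Self-hits are discarded.
    """
    if evalue_threshold <= 0:
        raise ValueError("evalue_threshold must be > 0")
    nodes: dict[str, None] = {}
    edges: dict[tuple[str, str], float] = {}
    for i, hit in enumerate(hits):
        for ident in (hit.query_id, hit.subject_id):
            if sep not in ident:
                raise LabelError(
                    f"hit {i + 1}: identifier {ident!r} has no species tag "
                    f"(expected 'species{sep}locus')")
            split_label(ident, sep)
        nodes.setdefault(hit.query_id, None)
        nodes.setdefault(hit.subject_id, None)
        if hit.query_id == hit.subject_id:
            continue
        if hit.evalue > evalue_threshold:
            continue
        w = WEIGHT_CAP if hit.evalue == 0 else min(-math.log10(hit.evalue),
                                                   WEIGHT_CAP)
        key = (min(hit.query_id, hit.subject_id),
               max(hit.query_id, hit.subject_id))
        edges[key] = max(edges.get(key, 0.0), w)
    return SimilarityGraph(nodes=sorted(nodes), edges=edges)


class MCLConvergenceWarning(UserWarning):
    pass


def _connected_components(graph: SimilarityGraph) -> list[list[str]]:
    parent = {n: n for n in graph.nodes}

    def find(x: str) -> str:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for u, v in graph.edges:
        parent[find(u)] = find(v)
    comps: dict[str, list[str]] = {}
    for n in graph.nodes:
        comps.setdefault(find(n), []).append(n)
    return [sorted(c) for c in comps.values()]


def _mcl_component(graph: SimilarityGraph, nodes: list[str],
                   inflation: float, expansion: int, prune_threshold: float,
                   tol: float, max_iter: int) -> list[list[str]]:
    """Run the MCL iteration on one connected component and read clusters
    from the attractor structure of its limit matrix."""
    if len(nodes) == 1:
        return [list(nodes)]
    index = {n: i for i, n in enumerate(nodes)}
    n = len(nodes)
    a = np.zeros((n, n))
    for (u, v), w in graph.edges.items():
        if u in index and v in index:
            a[index[u], index[v]] = w
            a[index[v], index[u]] = w
    # Self-loops at the node's maximum incident weight keep the
    # column-stochastic iteration well behaved.
    diag = a.max(axis=0)
    diag[diag == 0] = 1.0
    np.fill_diagonal(a, diag)
    m = a / a.sum(axis=0, keepdims=True)
    converged = False
    for _ in range(max_iter):
        prev = m
        m = np.linalg.matrix_power(m, expansion)
        m = np.power(m, inflation)
        m[m < prune_threshold] = 0.0
        colsum = m.sum(axis=0, keepdims=True)
        colsum[colsum == 0] = 1.0
        m = m / colsum
        if np.abs(m - prev).max() < tol:
            converged = True
            break
    if not converged:
        warnings.warn("MCL did not converge within "
                      f"{max_iter} iterations; using the last iterate",
                      MCLConvergenceWarning)

    attractors = [i for i in range(n) if m[i, i] > prune_threshold]
    if not attractors:  # degenerate limit; fall back to row support
        attractors = [i for i in range(n) if m[i].sum() > 0] or list(range(n))
    # Attractor systems: connected components of the attractor-attractor
    # support graph.
    parent = list(range(n))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for i in attractors:
        for j in attractors:
            if m[i, j] > 0 or m[j, i] > 0:
                parent[find(i)] = find(j)
    systems: dict[int, list[int]] = {}
    for i in attractors:
        systems.setdefault(find(i), []).append(i)

    # Every node goes to the attractor system holding most of its
    # probability mass; ties to the lexicographically smaller cluster.
    # A node whose limit column pruned to zero mass becomes a singleton.
    assignment: dict[int, int] = {}
    for j in range(n):
        best_root, best_mass = None, 0.0
        for root, members in systems.items():
            mass = float(sum(m[i, j] for i in members))
            if mass > best_mass:
                best_root, best_mass = root, mass
            elif mass == best_mass and best_root is not None and mass > 0:
                key_new = tuple(sorted(nodes[i] for i in members))
                key_old = tuple(sorted(nodes[i]
                                       for i in systems[best_root]))
                if key_new < key_old:
                    best_root = root
        if best_mass <= 0:
            assignment[j] = find(j) if j in set(attractors) else -(j + 1)
        else:
            assignment[j] = find(best_root)

    groups: dict[int, list[int]] = {}
    for j, root in assignment.items():
        groups.setdefault(root, []).append(j)
    return [sorted(nodes[j] for j in g) for g in groups.values()]


def mcl_cluster(graph: SimilarityGraph,
                inflation: float = 5.0,
                expansion: int = 2,
                prune_threshold: float = 1e-6,
                tol: float = 1e-8,
                max_iter: int = 1000,
                lengths: Mapping[str, int] | None = None,
                sep: str = DEFAULT_SEP) -> list[GeneCluster]:
    """Markov clustering of the similarity graph.

    Iterates expansion (matrix power ``expansion``) and inflation
    (element-wise power ``inflation`` followed by column renormalisation,
    with per-column pruning of entries below ``prune_threshold``) until the
    largest element change drops below ``tol``.  Clusters are read from the
    attractor structure of the limit matrix; a node attracted to several
    clusters goes to the one holding more of its probability mass, ties to
    the cluster with the lexicographically smaller member tuple.
    """
    if inflation <= 1:
        raise ValueError("inflation must be > 1")
    if not graph.nodes:
        raise ValueError("empty graph")
    member_lists: list[list[str]] = []
    for comp in _connected_components(graph):
        member_lists.extend(
            _mcl_component(graph, comp, inflation, expansion,
                           prune_threshold, tol, max_iter))
    member_lists.sort(key=lambda g: g[0])
    clusters = []
    width = max(4, len(str(len(member_lists))))
    for k, ids in enumerate(member_lists):
        members = []
        for sid in ids:
            sp, _ = split_label(sid, sep)
            members.append((sp, sid, int(lengths[sid]) if lengths else 0))
        clusters.append(GeneCluster(cluster_id=f"C{k:0{width}d}",
                                    members=members))
    return clusters


def filter_clusters(clusters: Sequence[GeneCluster],
                    rules: ClusterFilterRules) -> list[GeneCluster]:
    """Apply the five retention filters.

    A cluster is kept iff it (i) contains the outgroup species, (ii) spans at
    least ``min_species`` species, (iii) every member is at least
    ``min_len_aa`` residues, (iv) has a mean of strictly fewer than
    ``max_mean_seqs_per_species`` sequences per species, and (v) a median of
    strictly fewer than ``max_median_seqs_per_species``.  Mean and median are
    taken over the species present in the cluster.
    """
    kept = []
    for c in clusters:
        counts = list(c.species_counts.values())
        if rules.require_outgroup_species not in c.species:
            continue
        if len(counts) < rules.min_species:
            continue
        if any(length < rules.min_len_aa for _, _, length in c.members):
            continue
        if statistics.mean(counts) >= rules.max_mean_seqs_per_species:
            continue
        if statistics.median(counts) >= rules.max_median_seqs_per_species:
            continue
        kept.append(c)
    return kept


def write_cluster_tsv(clusters: Sequence[GeneCluster], path: str) -> None:
    with open(path, "w") as fh:
        fh.write("cluster_id\tspecies\tsequence_id\n")
        for c in clusters:
            for sp, sid, _ in c.members:
                fh.write(f"{c.cluster_id}\t{sp}\t{sid}\n")


def write_cluster_fastas(clusters: Sequence[GeneCluster],
                         sequences: Mapping[str, str],
                         out_dir: str) -> None:
    import os
    os.makedirs(out_dir, exist_ok=True)
    for c in clusters:
        with open(os.path.join(out_dir, f"{c.cluster_id}.faa"), "w") as fh:
            for _, sid, _ in c.members:
                fh.write(f">{sid}\n{sequences[sid]}\n")
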