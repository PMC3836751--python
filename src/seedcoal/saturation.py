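"""Site-rate partitioning and substitution-saturation diagnostics.

Per-site evolutionary rate is proxied by Observed Variability (OV): the
number of mismatching sequence pairs at a site, a tree-independent measure.
Parsimony-informative sites sorted by OV are split into two equal "slow" and
"fast" partitions.  Saturation within a partition is quantified by the
entropy-based index of substitution saturation: Iss is the ratio of the mean
observed site entropy to the mean entropy expected at full saturation
(sites redrawn from the global base composition).  Iss is compared against
critical values Iss.c estimated by simulation on an asymmetrical
(caterpillar) and a symmetrical (balanced) true topology: Iss.c is the Iss
level at which neighbor joining still recovers the true topology in 95% of
simulations.  An Iss not smaller than Iss.c indicates substantial
saturation; an Iss significantly below it (two-tailed one-sample t-test
over site-bootstrap replicates) indicates none.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from typing import Sequence

import dendropy
import numpy as np
from scipy import stats

from .genetrees import encode_rows, neighbor_joining, p_distance
from .trees import species_bipartitions

MAX_OTU = 32


@dataclass
class RatePartition:
    label: str                 # "slow" | "fast"
    site_indices: list[int]    # into the supermatrix
    ov_scores: list[int]


@dataclass
class SaturationReport:
    label: str
    iss: float
    iss_replicates: list[float]
    iss_c1: float              # asymmetrical true topology
    iss_c2: float              # symmetrical true topology
    p_value_c1: float
    p_value_c2: float
    n_otu_used: int
    verdict: str               # "no evidence of saturation" | ...
    zero_variance: bool = False

    def to_dict(self) -> dict:
        return {
            "label": self.label,
            "iss": self.iss,
            "iss_c1": self.iss_c1,
            "iss_c2": self.iss_c2,
            "p_value_c1": self.p_value_c1,
            "p_value_c2": self.p_value_c2,
            "n_otu_used": self.n_otu_used,
            "verdict": self.verdict,
            "zero_variance": self.zero_variance,
            "n_replicates": len(self.iss_replicates),
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2)


def ov_scores(rows: Sequence[str], sites: Sequence[int] | None = None) -> list[int]:
    """Observed Variability per site: mismatching unordered sequence pairs.

    Only cells with an unambiguous nucleotide are counted; a pair with a gap
    or ambiguity code at the site is skipped.
    """
    mat = encode_rows(rows)
    if sites is not None:
        mat = mat[:, list(sites)]
    counts = np.stack([(mat == b).sum(axis=0) for b in range(4)])  # (4, S)
    n = counts.sum(axis=0)
    total_pairs = n * (n - 1) // 2
    same_pairs = (counts * (counts - 1) // 2).sum(axis=0)
    return (total_pairs - same_pairs).astype(int).tolist()


def partition_by_rate(sites: Sequence[int],
                      scores: Sequence[int]) -> tuple[RatePartition, RatePartition]:
    """Sort sites by (OV ascending, index ascending) and split into two
    equal halves; with an odd count the slow partition gets the extra site."""
    if len(sites) < 2:
        raise ValueError("need at least two sites to partition")
    order = sorted(range(len(sites)), key=lambda i: (scores[i], sites[i]))
    half = math.ceil(len(sites) / 2)
    slow_idx, fast_idx = order[:half], order[half:]
    slow = RatePartition("slow", [sites[i] for i in slow_idx],
                         [scores[i] for i in slow_idx])
    fast = RatePartition("fast", [sites[i] for i in fast_idx],
                         [scores[i] for i in fast_idx])
    return slow, fast


def _site_entropies(mat: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-site entropy (bits) over counted cells, and counted-cell counts."""
    counts = np.stack([(mat == b).sum(axis=0) for b in range(4)]).astype(float)
    n = counts.sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        p = np.where(n > 0, counts / np.maximum(n, 1), 0.0)
        h = -np.where(p > 0, p * np.log2(p), 0.0).sum(axis=0)
    h[n == 0] = 0.0
    return h, n.astype(int)


def iss(rows: Sequence[str], n_mc: int = 200,
        seed: int = 0) -> tuple[float, list[float]]:
    """Index of substitution saturation with site-bootstrap replicates.

    ``iss = H / H_FSS`` where ``H`` is the mean per-site entropy of the
    observed alignment (gaps and ambiguities excluded from the counts) and
    ``H_FSS`` the mean entropy of ``n_mc`` randomisations in which each
    site's counted cells are redrawn independently from the global base
    composition (the full-saturation expectation).  The replicate vector
    holds Iss recomputed on ``n_mc`` bootstrap resamples of sites, against
    the same ``H_FSS``.
    """
    if len(rows) < 4:
        raise ValueError("need at least four sequences")
    mat = encode_rows(rows)
    h, n = _site_entropies(mat)
    if (n == 0).all():
        raise ValueError("undefined index: no counted cells at any site")
    s = mat.shape[1]
    freq_counts = np.array([(mat == b).sum() for b in range(4)], dtype=float)
    if freq_counts.sum() == 0:
        raise ValueError("no unambiguous nucleotides in alignment")
    comp = freq_counts / freq_counts.sum()
    rng = np.random.default_rng(seed)

    # Full-saturation expectation: redraw each site's counted cells from the
    # global composition, n_mc times.
    h_fss_total = 0.0
    for _ in range(n_mc):
        rand_counts = rng.multinomial(n, comp).T.astype(float)  # (4, S)
        ntot = rand_counts.sum(axis=0)
        with np.errstate(divide="ignore", invalid="ignore"):
            p = np.where(ntot > 0, rand_counts / np.maximum(ntot, 1), 0.0)
            hr = -np.where(p > 0, p * np.log2(p), 0.0).sum(axis=0)
        h_fss_total += hr.mean()
    h_fss = h_fss_total / n_mc
    if h_fss == 0:
        # happens only for a single-state composition; the observed entropy
        # is then necessarily 0 too and the index is 0 by continuity
        if float(h.mean()) == 0.0:
            return 0.0, [0.0] * n_mc
        raise ValueError("undefined index: saturated-expectation entropy is 0")
    value = float(h.mean() / h_fss)
    reps = []
    for _ in range(n_mc):
        idx = rng.integers(0, s, size=s)
        reps.append(float(h[idx].mean() / h_fss))
    return value, reps


def _shape_topology(n_otu: int, shape: str) -> dendropy.Tree:
    """Caterpillar (asymmetrical) or recursively balanced (symmetrical)
    topology with unit branch lengths."""
    labels = [f"t{i:02d}" for i in range(n_otu)]
    ns = dendropy.TaxonNamespace(labels)

    def leaf(lab: str) -> dendropy.Node:
        return dendropy.Node(taxon=ns.get_taxon(lab))

    if shape == "asymmetrical":
        node = leaf(labels[0])
        node.edge.length = 1.0
        for lab in labels[1:]:
            parent = dendropy.Node()
            tip = leaf(lab)
            tip.edge.length = 1.0
            parent.add_child(node)
            parent.add_child(tip)
            node = parent
        root = node
    elif shape == "symmetrical":
        def build(labs: list[str]) -> dendropy.Node:
            if len(labs) == 1:
                nd = leaf(labs[0])
                nd.edge.length = 1.0
                return nd
            mid = len(labs) // 2
            nd = dendropy.Node()
            left, right = build(labs[:mid]), build(labs[mid:])
            nd.add_child(left)
            nd.add_child(right)
            nd.edge.length = 1.0
            return nd
        root = build(labels)
    else:
        raise ValueError(f"unknown shape {shape!r}")
    tree = dendropy.Tree(taxon_namespace=ns)
    tree.seed_node = root
    tree.is_rooted = True
    for node in tree.preorder_node_iter():
        if node is tree.seed_node:
            node.edge.length = None
        elif node.edge.length is None:
            node.edge.length = 1.0
    return tree


def _scale_to_height(tree: dendropy.Tree, height: float) -> None:
    depths = []
    for lf in tree.leaf_node_iter():
        d, node = 0.0, lf
        while node.parent_node is not None:
            d += node.edge.length or 0.0
            node = node.parent_node
        depths.append(d)
    factor = height / max(depths)
    for node in tree.preorder_node_iter():
        if node.edge.length is not None:
            node.edge.length *= factor


def iss_critical(n_otu: int, n_sites: int, shape: str = "asymmetrical",
                 seed: int = 0, n_sim: int = 20,
                 loads: Sequence[float] = (0.5, 1.0, 1.5, 2.0, 3.0, 4.5,
                                           7.0, 10.0),
                 recovery_target: float = 0.95) -> float:
    """Critical Iss by reduced simulation.

    Sequences evolve under Jukes-Cantor on the chosen true topology scaled
    to a grid of increasing root-to-tip substitution loads.  At each load
    the mean Iss and the proportion of simulations in which neighbor joining
    (on uncorrected p-distances, which stay defined under saturation)
    recovers the true topology are recorded; the critical value is the Iss
    linearly interpolated at the load where recovery crosses
    ``recovery_target``.  The taxon count is capped at 32, mirroring the
    method's published tabulation limit.  Deterministic given ``seed``.
    """
    from .simulate import SeqSimConfig, simulate_sequences

    if n_otu < 4:
        raise ValueError("need at least 4 OTUs")
    n_otu = min(n_otu, MAX_OTU)
    length = max(50, min(n_sites, 800))
    rng = np.random.default_rng(seed)
    base = _shape_topology(n_otu, shape)
    true_splits = species_bipartitions(base)
    mean_iss, recovery = [], []
    for load in loads:
        tree = base.clone(depth=1)
        _scale_to_height(tree, load)
        hits = 0
        iss_sum = 0.0
        for s in range(n_sim):
            cfg = SeqSimConfig(model="JC", length=length,
                               seed=int(rng.integers(0, 2**31)))
            aln = simulate_sequences(tree, cfg)
            labels = list(aln)
            rows = [aln[lab] for lab in labels]
            est = neighbor_joining(labels, p_distance(rows))
            if species_bipartitions(est) == true_splits:
                hits += 1
            # a light Monte-Carlo replicate count is enough inside the grid
            value, _reps = iss(rows, n_mc=20,
                               seed=int(rng.integers(0, 2**31)))
            iss_sum += value
        mean_iss.append(iss_sum / n_sim)
        recovery.append(hits / n_sim)
    # walk the grid for the first crossing below the recovery target
    for k in range(1, len(loads)):
        if recovery[k - 1] >= recovery_target > recovery[k]:
            span = recovery[k - 1] - recovery[k]
            w = (recovery[k - 1] - recovery_target) / span if span > 0 else 0.5
            return float(mean_iss[k - 1] + w * (mean_iss[k] - mean_iss[k - 1]))
    if min(recovery) >= recovery_target:
        return float(max(mean_iss))
    return float(min(mean_iss))


def saturation_test(rows: Sequence[str], label: str = "",
                    n_mc: int = 200, seed: int = 0,
                    shape_convention: str = "asymmetrical",
                    alpha: float = 0.001,
                    critical_kwargs: dict | None = None) -> SaturationReport:
    """Full saturation assessment of one alignment slice.

    Computes Iss with site-bootstrap replicates, the two critical values
    (asymmetrical and symmetrical true topologies), and two-tailed
    one-sample t-tests of the replicates against each critical value.  The
    verdict follows the configured shape convention: "substantial
    saturation" iff Iss is not smaller than Iss.c, otherwise "no evidence of
    saturation" when the t-test is significant at ``alpha``.
    """
    n_taxa = len(rows)
    n_otu = min(n_taxa, MAX_OTU)
    n_sites = len(rows[0])
    value, reps = iss(rows, n_mc=n_mc, seed=seed)
    kw = dict(critical_kwargs or {})
    c1 = iss_critical(n_otu, n_sites, "asymmetrical", seed=seed + 1, **kw)
    c2 = iss_critical(n_otu, n_sites, "symmetrical", seed=seed + 2, **kw)
    arr = np.asarray(reps)
    zero_var = bool(np.allclose(arr.std(), 0.0))
    if zero_var:
        p1 = 0.0 if value != c1 else 1.0
        p2 = 0.0 if value != c2 else 1.0
    else:
        p1 = float(stats.ttest_1samp(arr, c1).pvalue)
        p2 = float(stats.ttest_1samp(arr, c2).pvalue)
    crit = c1 if shape_convention == "asymmetrical" else c2
    p = p1 if shape_convention == "asymmetrical" else p2
    if value >= crit:
        verdict = "substantial saturation"
    elif p < alpha:
        verdict = "no evidence of saturation"
    else:
        verdict = "inconclusive"
    return SaturationReport(label=label, iss=value, iss_replicates=reps,
                            iss_c1=c1, iss_c2=c2, p_value_c1=p1,
                            p_value_c2=p2, n_otu_used=n_otu, verdict=verdict,
                            zero_variance=zero_var)


def write_partition_tsv(partitions: Sequence[RatePartition], path: str) -> None:
    """Site-index table, 1-based site coordinates."""
    with open(path, "w") as fh:
        fh.write("partition\tsite\tov\n")
        for part in partitions:
            for s, score in zip(part.site_indices, part.ov_scores):
                fh.write(f"{part.label}\t{s + 1}\t{score}\n")
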