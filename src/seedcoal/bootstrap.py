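"""Multilocus bootstrap and bipartition-based branch support.

Uncertainty is propagated at two levels: genes are resampled with
replacement, then sites are resampled with replacement within each drawn
gene.  Each replicate data set is pushed through the same species-tree
estimator as the point estimate (STAR or concatenation), and support for
each internal edge of the point estimate is the percentage of replicate
trees containing the same unrooted species bipartition.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Sequence

import dendropy
import numpy as np

from .alignment import CodonAlignment
from .trees import (DEFAULT_SEP, leaf_species, species_bipartitions,
                    split_label, to_newick)


@dataclass
class BootstrapConfig:
    n_replicates: int = 200
    master_seed: int = 0
    engine: str = "star"  # "star" | "concat"
    codon_units: bool = False

    def __post_init__(self) -> None:
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")
        if self.engine not in ("star", "concat"):
            raise ValueError(f"unknown engine {self.engine!r}")


@dataclass
class SupportedTree:
    """A point-estimate tree with per-internal-edge bootstrap percentages."""

    tree: dendropy.Tree
    support: dict[frozenset, float]
    n_replicates_used: int = 0
    n_replicates_dropped: int = 0
    replicates: list = field(default_factory=list)  # kept only on request

    def manifest(self, master_seed: int | None = None) -> dict:
        return {"master_seed": master_seed,
                "n_replicates_used": self.n_replicates_used,
                "n_replicates_dropped": self.n_replicates_dropped}

    def write_replicates(self, path: str) -> None:
        with open(path, "w") as fh:
            for t in self.replicates:
                fh.write(to_newick(t) + "\n")

    def min_support(self) -> float:
        return min(self.support.values()) if self.support else 100.0

    def newick_with_support(self) -> str:
        """Newick with supports written as internal node labels."""
        t = self.tree.clone(depth=1)
        all_sp = frozenset(leaf_species(t))
        anchor = min(all_sp)
        n = len(all_sp)
        for node in t.preorder_node_iter():
            if node is t.seed_node or node.is_leaf():
                continue
            below = frozenset(split_label(lf.taxon.label)[0]
                              for lf in node.leaf_iter())
            side = all_sp - below if anchor in below else below
            if 2 <= len(side) <= n - 2 and side in self.support:
                node.label = f"{self.support[side]:g}"
        return to_newick(t)


def multilocus_resample(genes: Sequence[CodonAlignment], seed: int,
                        codon_units: bool = False) -> list[CodonAlignment]:
    """One multilocus bootstrap replicate.

    Draws ``G`` gene indices with replacement (``G`` = input count), then for
    each drawn gene independently resamples its nucleotide columns with
    replacement.  With ``codon_units`` the columns are drawn as codon
    triplets, preserving reading frame (and the amino-acid alignment);
    the default resamples single nucleotide sites, in which case the
    replicate is nucleotide-only.  Deterministic given ``seed``; the gene
    draw uses a random stream separate from the per-gene site draws.
    """
    if not genes:
        raise ValueError("no genes to resample")
    g = len(genes)
    gene_rng = np.random.default_rng([seed, 0])
    picks = gene_rng.integers(0, g, size=g)
    out: list[CodonAlignment] = []
    for k, gi in enumerate(picks):
        gene = genes[int(gi)]
        site_rng = np.random.default_rng([seed, 1, k])
        mat = np.array([list(r.encode()) for r in gene.nt], dtype=np.uint8)
        if codon_units:
            n_codons = gene.n_nt_columns // 3
            cols = site_rng.integers(0, n_codons, size=n_codons)
            nt_cols = (3 * cols[:, None] + np.arange(3)).ravel()
            nt = [bytes(row).decode() for row in mat[:, nt_cols]]
            aa = (["".join(row[c] for c in cols) for row in gene.aa]
                  if gene.aa is not None else None)
        else:
            n_sites = gene.n_nt_columns
            cols = site_rng.integers(0, n_sites, size=n_sites)
            nt = [bytes(row).decode() for row in mat[:, cols]]
            aa = None
        out.append(CodonAlignment(gene_id=gene.gene_id, taxa=list(gene.taxa),
                                  nt=nt, aa=aa))
    return out


def bipartition_support(reference: dendropy.Tree,
                        replicates: Sequence[dendropy.Tree],
                        sep: str = DEFAULT_SEP) -> SupportedTree:
    """Map replicate bipartition frequencies onto the reference tree.

    All trees must cover the same species set; a mismatch raises an error
    listing the symmetric difference.
    """
    ref_sp = set(leaf_species(reference, sep))
    for r in replicates:
        rep_sp = set(leaf_species(r, sep))
        if rep_sp != ref_sp:
            raise ValueError("replicate species set differs from reference: "
                             f"{sorted(rep_sp ^ ref_sp)}")
    ref_splits = species_bipartitions(reference, sep)
    counts = {s: 0 for s in ref_splits}
    for r in replicates:
        rep_splits = species_bipartitions(r, sep)
        for s in ref_splits:
            if s in rep_splits:
                counts[s] += 1
    n = len(replicates)
    support = {s: (100.0 * c / n if n else 0.0) for s, c in counts.items()}
    return SupportedTree(tree=reference.clone(depth=1), support=support,
                         n_replicates_used=n)


Estimator = Callable[[Sequence[CodonAlignment]], dendropy.Tree]


def run_bootstrap(genes: Sequence[CodonAlignment],
                  config: BootstrapConfig,
                  estimator: Estimator,
                  keep_replicates: bool = False) -> SupportedTree:
    """Point estimate plus multilocus bootstrap support.

    Replicate ``r`` uses seed ``master_seed + r``.  A replicate whose
    estimation fails is dropped and the support denominator adjusted; a
    warning is emitted if more than 5% are dropped.
    """
    point = estimator(genes)
    point_sp = set(leaf_species(point))
    reps: list[dendropy.Tree] = []
    dropped = 0
    for r in range(config.n_replicates):
        rep_genes = multilocus_resample(genes, seed=config.master_seed + r,
                                        codon_units=config.codon_units)
        try:
            t = estimator(rep_genes)
        except Exception as exc:  # noqa: BLE001 - any estimation failure
            dropped += 1
            warnings.warn(f"bootstrap replicate {r} failed: {exc}")
            continue
        if set(leaf_species(t)) != point_sp:
            # the gene draw missed every gene containing some species
            dropped += 1
            continue
        reps.append(t)
    if dropped > 0.05 * config.n_replicates:
        warnings.warn(f"{dropped} of {config.n_replicates} bootstrap "
                      "replicates dropped (>5%)")
    st = bipartition_support(point, reps)
    st.n_replicates_dropped = dropped
    if keep_replicates:
        st.replicates = reps
    return st
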