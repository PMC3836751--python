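"""End-to-end orchestration: clustering through species trees and rates.

The stages mirror a transcriptome phylogenomics workflow: all-vs-all
protein hits are clustered into gene families, families are filtered,
codon alignments built, gene trees estimated and decomposed into
single-copy subtrees, and species trees inferred by both the coalescent
(STAR) and concatenation routes with multilocus bootstrap support.
Rate partitioning and saturation diagnostics run on the concatenated
matrix.  Every stage is a pure function of (inputs, config, seed).
"""

from __future__ import annotations

import glob
import json
import os
import warnings
from dataclasses import asdict, dataclass, field
from typing import Mapping, Sequence

import dendropy
import numpy as np

from .alignment import (CodonAlignment, Supermatrix, MatrixStats,
                        backtranslate, concatenate, coverage_filter,
                        parsimony_informative_sites, read_fasta,
                        write_gene_spans, write_phylip)
from .bootstrap import (BootstrapConfig, SupportedTree, bipartition_support,
                        multilocus_resample, run_bootstrap)
from .genetrees import (SubtreeFilterRules, jc_distance, monophyly_mask,
                        neighbor_joining, nj_gene_tree, paralogue_prune,
                        root_with_outgroup, subtree_filter)
from .homology import (ClusterFilterRules, GeneCluster, build_similarity_graph,
                       filter_clusters, mcl_cluster, parse_hits_table)
from .saturation import (RatePartition, SaturationReport, ov_scores,
                         partition_by_rate, saturation_test)
from .star import star_species_tree
from .trees import DEFAULT_SEP, leaf_species, split_label, to_newick


@dataclass
class PipelineConfig:
    outgroup: str = "out"
    sep: str = DEFAULT_SEP
    evalue_threshold: float = 1e-20
    mcl_inflation: float = 5.0
    min_coverage: float = 0.70
    cluster_rules: dict = field(default_factory=dict)   # overrides
    subtree_min_species: int = 7
    subtree_min_frac: float = 0.60
    n_bootstrap: int = 200
    master_seed: int = 0
    subsample_sizes: tuple[int, ...] = ()
    subsample_replicates: int = 10
    saturation_mc: int = 200
    critical_kwargs: dict = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2, sort_keys=True)


@dataclass
class PipelineResult:
    config: PipelineConfig
    n_clusters_total: int
    n_clusters_retained: int
    gene_alignments: list[CodonAlignment]
    single_copy_genes: list[CodonAlignment]
    star: SupportedTree
    concat: SupportedTree
    supermatrix: Supermatrix
    stats: MatrixStats
    informative_sites: list[int]
    slow: RatePartition
    fast: RatePartition
    saturation: dict[str, SaturationReport]


# --- data loading ----------------------------------------------------------

def load_sequence_dir(path: str) -> dict[str, str]:
    """Merge all FASTA files in a directory into one id -> sequence map."""
    out: dict[str, str] = {}
    for fn in sorted(glob.glob(os.path.join(path, "*"))):
        if fn.endswith((".fa", ".faa", ".fna", ".fasta")):
            out.update(read_fasta(fn))
    return out


# --- stage functions -------------------------------------------------------

def cluster_stage(hits_path: str, proteins: Mapping[str, str],
                  config: PipelineConfig) -> tuple[list[GeneCluster],
                                                   list[GeneCluster]]:
    """Similarity graph -> MCL -> retention filters.

    Returns (all clusters, retained clusters).
    """
    hits = parse_hits_table(hits_path)
    graph = build_similarity_graph(hits, config.evalue_threshold, config.sep)
    lengths = {sid: len(seq) for sid, seq in proteins.items()}
    clusters = mcl_cluster(graph, inflation=config.mcl_inflation,
                           lengths=lengths, sep=config.sep)
    rules = ClusterFilterRules(require_outgroup_species=config.outgroup,
                               **config.cluster_rules)
    return clusters, filter_clusters(clusters, rules)


def build_gene_alignment(cluster: GeneCluster,
                         proteins: Mapping[str, str],
                         cds: Mapping[str, str],
                         config: PipelineConfig,
                         aligned_aa: Mapping[str, str] | None = None
                         ) -> CodonAlignment:
    """Codon alignment for one cluster.

    ``aligned_aa`` supplies externally aligned amino-acid rows; when absent
    the protein sequences themselves must already be aligned (equal length),
    which holds for the bundled gapless fixtures.
    """
    taxa = [(sp, sid) for sp, sid, _ in cluster.members]
    source = aligned_aa if aligned_aa is not None else proteins
    aa_rows = [source[sid] for _, sid in taxa]
    if len({len(r) for r in aa_rows}) > 1:
        raise ValueError(f"{cluster.cluster_id}: amino-acid rows are not "
                         "aligned (unequal lengths); supply aligned input")
    aln = backtranslate(cluster.cluster_id, taxa, aa_rows, cds)
    return coverage_filter(aln, config.min_coverage)


def single_copy_alignments(aln: CodonAlignment,
                           config: PipelineConfig
                           ) -> list[CodonAlignment]:
    """Gene tree -> monophyly mask -> paralogue pruning -> subtree filter.

    Emits one single-copy alignment per retained subtree, its rows
    restricted to the subtree's tips.  Each emitted subtree is re-rooted on
    the outgroup when present (the induced rooting is kept otherwise).
    """
    sep = config.sep
    labels = [sid for _, sid in aln.taxa]
    outgroup = (config.outgroup
                if config.outgroup in aln.species else None)
    tree = nj_gene_tree(labels, aln.nt, outgroup, sep)
    if outgroup is None:
        tree = _midpoint_rooted(tree)
    lengths = {sid: sum(1 for c in row if c != "-")
               for (_, sid), row in zip(aln.taxa, aln.nt)}
    masked = monophyly_mask(tree, lengths=lengths, sep=sep)
    subtrees = paralogue_prune(masked, sep=sep)
    rules = SubtreeFilterRules(min_species=config.subtree_min_species,
                               min_frac_of_cluster_species=config.subtree_min_frac)
    kept = subtree_filter(subtrees, rules, set(aln.species), sep=sep)
    out = []
    index = {sid: i for i, (_, sid) in enumerate(aln.taxa)}
    for k, st in enumerate(kept):
        tips = [lf.taxon.label for lf in st.leaf_node_iter()]
        rows = [index[t] for t in tips]
        sub = aln.subset_rows(rows)
        sub.gene_id = aln.gene_id if len(kept) == 1 else f"{aln.gene_id}.{k}"
        out.append(sub)
    return out


def _midpoint_rooted(tree: dendropy.Tree) -> dendropy.Tree:
    t = tree.clone(depth=1)
    t.reroot_at_midpoint(update_bipartitions=False)
    t.is_rooted = True
    return t


def _gene_tree_for(gene: CodonAlignment, config: PipelineConfig
                   ) -> dendropy.Tree:
    labels = [sid for _, sid in gene.taxa]
    if config.outgroup in gene.species:
        return nj_gene_tree(labels, gene.nt, config.outgroup, config.sep)
    return _midpoint_rooted(nj_gene_tree(labels, gene.nt, None, config.sep))


def make_star_estimator(config: PipelineConfig):
    """Estimator: per-gene JC+NJ trees rooted by the outgroup, then STAR."""
    def estimator(genes: Sequence[CodonAlignment]) -> dendropy.Tree:
        trees = [_gene_tree_for(g, config) for g in genes]
        return star_species_tree(trees, config.outgroup, config.sep)
    return estimator


def make_concat_estimator(config: PipelineConfig):
    """Estimator: concatenate -> JC distances -> NJ -> outgroup rooting."""
    def estimator(genes: Sequence[CodonAlignment]) -> dendropy.Tree:
        species = sorted({sp for g in genes for sp in g.species})
        m, _ = concatenate(genes, species)
        d = jc_distance([m.rows[sp] for sp in species], species)
        tree = neighbor_joining(species, d)
        return root_with_outgroup(tree, config.outgroup, config.sep)
    return estimator


def rates_stage(m: Supermatrix, config: PipelineConfig
                ) -> tuple[list[int], RatePartition, RatePartition,
                           dict[str, SaturationReport]]:
    """OV scoring of parsimony-informative sites, two-way partition, and
    per-partition saturation assessment."""
    rows = [m.rows[sp] for sp in m.species]
    sites = parsimony_informative_sites(m)
    scores = ov_scores(rows, sites)
    slow, fast = partition_by_rate(sites, scores)
    reports = {}
    for part in (slow, fast):
        sl = m.site_slice(part.site_indices)
        reports[part.label] = saturation_test(
            [sl.rows[sp] for sp in m.species], label=part.label,
            n_mc=config.saturation_mc, seed=config.master_seed,
            critical_kwargs=config.critical_kwargs)
    return sites, slow, fast, reports


# --- full run --------------------------------------------------------------

def run_full_pipeline(data_dir: str, config: PipelineConfig | None = None,
                      out_dir: str | None = None) -> PipelineResult:
    """Run every stage on an on-disk dataset (real or generated).

    Expects ``hits.tsv``, ``proteins/`` and ``cds/`` under ``data_dir``.
    """
    config = config or PipelineConfig()
    hits_path = os.path.join(data_dir, "hits.tsv")
    if not os.path.exists(hits_path):
        raise FileNotFoundError(f"expected hit table at {hits_path}")
    proteins = load_sequence_dir(os.path.join(data_dir, "proteins"))
    cds = load_sequence_dir(os.path.join(data_dir, "cds"))
    if not proteins or not cds:
        raise FileNotFoundError(f"expected FASTA under {data_dir}/proteins "
                                f"and {data_dir}/cds")

    clusters, retained = cluster_stage(hits_path, proteins, config)
    gene_alignments = []
    for c in retained:
        try:
            gene_alignments.append(build_gene_alignment(c, proteins, cds,
                                                        config))
        except ValueError as exc:
            warnings.warn(f"skipping cluster {c.cluster_id}: {exc}")
    single_copy: list[CodonAlignment] = []
    for aln in gene_alignments:
        single_copy.extend(single_copy_alignments(aln, config))
    if not single_copy:
        raise ValueError("no single-copy gene alignments survived filtering")

    star_est = make_star_estimator(config)
    concat_est = make_concat_estimator(config)
    boot = BootstrapConfig(n_replicates=config.n_bootstrap,
                           master_seed=config.master_seed)
    star_tree = run_bootstrap(single_copy, boot, star_est)
    concat_tree = run_bootstrap(single_copy, boot, concat_est)

    species = sorted({sp for g in single_copy for sp in g.species})
    m, stats = concatenate(single_copy, species)
    sites, slow, fast, reports = rates_stage(m, config)

    result = PipelineResult(
        config=config, n_clusters_total=len(clusters),
        n_clusters_retained=len(retained),
        gene_alignments=gene_alignments, single_copy_genes=single_copy,
        star=star_tree, concat=concat_tree, supermatrix=m, stats=stats,
        informative_sites=sites, slow=slow, fast=fast, saturation=reports)
    if out_dir:
        write_outputs(result, out_dir)
    return result


def write_outputs(result: PipelineResult, out_dir: str) -> None:
    os.makedirs(out_dir, exist_ok=True)
    with open(os.path.join(out_dir, "config.json"), "w") as fh:
        fh.write(result.config.to_json())
    with open(os.path.join(out_dir, "star_tree.nwk"), "w") as fh:
        fh.write(result.star.newick_with_support() + "\n")
    with open(os.path.join(out_dir, "concat_tree.nwk"), "w") as fh:
        fh.write(result.concat.newick_with_support() + "\n")
    write_phylip(result.supermatrix, os.path.join(out_dir, "supermatrix.phy"))
    write_gene_spans(result.supermatrix,
                     os.path.join(out_dir, "gene_spans.tsv"))
    with open(os.path.join(out_dir, "matrix_stats.json"), "w") as fh:
        fh.write(result.stats.to_json())
    sat = {k: v.to_dict() for k, v in result.saturation.items()}
    summary = {
        "n_clusters_total": result.n_clusters_total,
        "n_clusters_retained": result.n_clusters_retained,
        "n_single_copy_genes": len(result.single_copy_genes),
        "n_sites": result.stats.n_sites,
        "pct_missing": result.stats.pct_missing,
        "n_informative_sites": len(result.informative_sites),
        "sites_per_partition": [len(result.slow.site_indices),
                                len(result.fast.site_indices)],
        "saturation": sat,
    }
    with open(os.path.join(out_dir, "summary.json"), "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)


# --- gene subsampling experiment -------------------------------------------

def clade_support(replicates: Sequence[dendropy.Tree],
                  clade: frozenset[str],
                  all_species: frozenset[str],
                  sep: str = DEFAULT_SEP) -> float:
    """Percent of replicate trees containing the unrooted split defined by
    ``clade`` against the remaining species."""
    from .trees import species_bipartitions
    anchor = min(all_species)
    side = all_species - clade if anchor in clade else clade
    n = 0
    for t in replicates:
        if side in species_bipartitions(t, sep):
            n += 1
    return 100.0 * n / len(replicates) if replicates else 0.0


def subsample_experiment(genes: Sequence[CodonAlignment],
                         sizes: Sequence[int],
                         n_reps: int,
                         config: PipelineConfig,
                         focal_clades: Mapping[str, frozenset[str]],
                         seed: int = 0) -> list[dict]:
    """Random gene subsampling: for each size and replicate, draw genes
    without replacement, run the STAR and concatenation bootstrap, and
    record focal-clade bootstrap percentages."""
    g = len(genes)
    for size in sizes:
        if size > g:
            raise ValueError(f"subsample size {size} exceeds gene count {g}")
    all_species = frozenset(sp for gene in genes for sp in gene.species)
    estimators = {"star": make_star_estimator(config),
                  "concat": make_concat_estimator(config)}
    rows = []
    for size in sizes:
        for rep in range(n_reps):
            rng = np.random.default_rng([seed, size, rep])
            idx = rng.choice(g, size=size, replace=False)
            subset = [genes[int(i)] for i in idx]
            for method, est in estimators.items():
                trees = []
                dropped = 0
                for b in range(config.n_bootstrap):
                    rep_genes = multilocus_resample(
                        subset, seed=config.master_seed + b)
                    try:
                        trees.append(est(rep_genes))
                    except Exception:  # noqa: BLE001
                        dropped += 1
                record = {"size": size, "replicate": rep, "method": method,
                          "n_dropped": dropped}
                for name, clade in focal_clades.items():
                    kept = [t for t in trees
                            if frozenset(leaf_species(t,
                                                      config.sep)) == all_species]
                    record[name] = clade_support(kept, clade, all_species,
                                                 config.sep)
                rows.append(record)
    return rows


def summarize_subsample(rows: Sequence[dict],
                        focal_names: Sequence[str],
                        threshold: float = 80.0) -> list[dict]:
    """Condense per-replicate records into a size x method table with
    per-replicate BPs and whether any replicate met the threshold."""
    table: dict[tuple[int, str], dict] = {}
    for r in rows:
        key = (r["size"], r["method"])
        entry = table.setdefault(key, {name: [] for name in focal_names})
        for name in focal_names:
            entry[name].append(r[name])
    out = []
    for (size, method), entry in sorted(table.items()):
        row = {"size": size, "method": method}
        for name in focal_names:
            bps = entry[name]
            row[f"{name}_bps"] = bps
            row[f"{name}_any_ge_{int(threshold)}"] = any(
                bp >= threshold for bp in bps)
        out.append(row)
    return out
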