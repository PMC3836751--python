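"""Synthetic data: multispecies-coalescent gene trees, sequence evolution,
paralogue injection, and a full study-shaped fixture dataset.

The generator emulates the structure of a deep-phylogeny transcriptome
study: ~14 species with one designated outgroup, tens of gene families with
heterogeneous gene trees drawn from the multispecies coalescent (MSC),
per-gene missing species, occasional recent paralogues, and nucleotide
sites spanning slow (unsaturated) to fast (saturated) substitution rates.
All generators are deterministic under a fixed seed.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import dendropy
import numpy as np
from Bio.Seq import Seq

from .trees import DEFAULT_SEP, to_newick

# Coalescent-unit branch lengths are converted to substitutions/site with
# this scale before sequence simulation.
COAL_TO_SUBS = 0.05

_BASES = "ACGT"
_STOPS = {"TAA", "TAG", "TGA"}


@dataclass
class MSCModel:
    species_tree: dendropy.Tree          # branch lengths in coalescent units
    samples_per_species: int = 1


@dataclass
class SeqSimConfig:
    model: str = "JC"                    # "JC" | "HKY"
    kappa: float = 2.0
    base_freqs: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25)
    gamma_shape: float | None = None
    rate_multiplier: float = 1.0
    length: int = 1000
    seed: int = 0
    site_rates: np.ndarray | None = None  # explicit per-site multipliers

    def __post_init__(self) -> None:
        if self.length < 1:
            raise ValueError("length must be >= 1")
        if abs(sum(self.base_freqs) - 1.0) > 1e-8:
            raise ValueError("base_freqs must sum to 1")


def simulate_msc_gene_trees(model: MSCModel, n_genes: int,
                            seed: int = 0,
                            sep: str = DEFAULT_SEP) -> list[dendropy.Tree]:
    """Sample gene trees under the standard multispecies coalescent.

    Within each species-tree branch, the ``k`` lineages present coalesce at
    rate ``k (k - 1) / 2`` per coalescent time unit; lineages that fail to
    coalesce are passed rootward, and everything merges above the species
    root.  Gene-tree branch lengths are in coalescent units.  Tip labels are
    ``species|species_i``.
    """
    if n_genes < 1:
        raise ValueError("n_genes must be >= 1")
    sp_tree = model.species_tree
    rng = np.random.default_rng(seed)

    # depth coordinate: distance from species root, increasing tipward
    depth: dict[dendropy.Node, float] = {}
    for node in sp_tree.preorder_node_iter():
        if node.parent_node is None:
            depth[node] = 0.0
        else:
            depth[node] = depth[node.parent_node] + (node.edge.length or 0.0)

    out: list[dendropy.Tree] = []
    for _ in range(n_genes):
        ns = dendropy.TaxonNamespace()
        # lineages[v]: list of (gene_node, u) waiting at species node v
        lineages: dict[dendropy.Node, list[tuple[dendropy.Node, float]]] = {}

        def coalesce(pool: list[tuple[dendropy.Node, float]],
                     u_start: float, u_stop: float | None
                     ) -> list[tuple[dendropy.Node, float]]:
            """Run the coalescent from coordinate u_start down to u_stop
            (None = minus infinity)."""
            pool = list(pool)
            u = u_start
            while len(pool) >= 2:
                k = len(pool)
                w = rng.exponential(1.0 / (k * (k - 1) / 2.0))
                if u_stop is not None and u - w < u_stop:
                    break
                u -= w
                i, j = rng.choice(k, size=2, replace=False)
                (ni, ui), (nj, uj) = pool[i], pool[j]
                parent = dendropy.Node()
                parent.add_child(ni)
                parent.add_child(nj)
                ni.edge.length = ui - u
                nj.edge.length = uj - u
                pool = [pool[m] for m in range(k) if m not in (i, j)]
                pool.append((parent, u))
            if u_stop is not None:
                pool = [(n, u_stop) for n, _ in pool]
            return pool

        for v in sp_tree.postorder_node_iter():
            if v.is_leaf():
                tips = []
                for i in range(model.samples_per_species):
                    lab = f"{v.taxon.label}{sep}{v.taxon.label}_{i}"
                    taxon = dendropy.Taxon(label=lab)
                    ns.add_taxon(taxon)
                    tips.append((dendropy.Node(taxon=taxon), depth[v]))
                lineages[v] = tips
            else:
                pool = []
                for ch in v.child_nodes():
                    pool.extend(coalesce(lineages[ch], depth[ch], depth[v]))
                lineages[v] = pool
        root_pool = coalesce(lineages[sp_tree.seed_node],
                             depth[sp_tree.seed_node], None)
        root = root_pool[0][0]
        gt = dendropy.Tree(taxon_namespace=ns)
        gt.seed_node = root
        gt.is_rooted = True
        out.append(gt)
    return out


def _rate_matrix(cfg: SeqSimConfig) -> tuple[np.ndarray, np.ndarray]:
    """(Q, pi) with mean rate normalised to 1 substitution/site/unit."""
    pi = np.asarray(cfg.base_freqs, dtype=float)
    if cfg.model == "JC":
        pi = np.full(4, 0.25)
        kappa = 1.0
    elif cfg.model == "HKY":
        kappa = cfg.kappa
    else:
        raise ValueError(f"unknown model {cfg.model!r}")
    # order A, C, G, T; transitions: A<->G, C<->T
    q = np.zeros((4, 4))
    for i in range(4):
        for j in range(4):
            if i == j:
                continue
            rate = pi[j]
            if (i, j) in ((0, 2), (2, 0), (1, 3), (3, 1)):
                rate *= kappa
            q[i, j] = rate
    np.fill_diagonal(q, -q.sum(axis=1))
    mu = -(pi * np.diag(q)).sum()
    q /= mu
    return q, pi


def simulate_sequences(tree: dendropy.Tree,
                       cfg: SeqSimConfig) -> dict[str, str]:
    """Evolve nucleotide sequences down a tree with branch lengths.

    Branch lengths are expected substitutions/site before
    ``rate_multiplier`` (and optional per-site Gamma or explicit
    multipliers) are applied.  Root states are drawn iid from the model's
    stationary frequencies.  Returns tip label -> sequence.
    """
    rng = np.random.default_rng(cfg.seed)
    q, pi = _rate_matrix(cfg)
    # reversible Q diagonalised via the symmetrising similarity transform
    sq = np.sqrt(pi)
    b = (sq[:, None] * q) / sq[None, :]
    lam, v = np.linalg.eigh((b + b.T) / 2.0)
    right = v / sq[:, None]
    left = v.T * sq[None, :]

    s = cfg.length
    if cfg.site_rates is not None:
        r = np.asarray(cfg.site_rates, dtype=float)
        if r.shape != (s,):
            raise ValueError("site_rates length mismatch")
    elif cfg.gamma_shape is not None:
        r = rng.gamma(cfg.gamma_shape, 1.0 / cfg.gamma_shape, size=s)
    else:
        r = np.ones(s)
    r = r * cfg.rate_multiplier

    states: dict[dendropy.Node, np.ndarray] = {}
    root = tree.seed_node
    states[root] = rng.choice(4, size=s, p=pi)
    for node in tree.preorder_node_iter():
        if node is root:
            continue
        if node.edge.length is None:
            raise ValueError("simulation requires branch lengths everywhere")
        t = node.edge.length * r                       # (S,)
        # P_s = right @ diag(exp(lam * t_s)) @ left, per site
        e = np.exp(np.outer(t, lam))                   # (S, 4)
        parent_states = states[node.parent_node]
        # rows of P needed: P_s[parent_s, :]
        rows = np.einsum("sj,sj,jk->sk", right[parent_states], e, left)
        rows = np.clip(rows, 0.0, None)
        rows /= rows.sum(axis=1, keepdims=True)
        u = rng.random(s)
        states[node] = (rows.cumsum(axis=1) < u[:, None]).sum(axis=1)
    base = np.frombuffer(_BASES.encode(), dtype=np.uint8)
    out = {}
    for lf in tree.leaf_node_iter():
        out[lf.taxon.label] = base[states[lf]].tobytes().decode()
    return out


def inject_paralogs(tree: dendropy.Tree, p_dup: float, seed: int = 0,
                    dup_branch: float = 0.05,
                    sep: str = DEFAULT_SEP) -> dendropy.Tree:
    """Duplicate each tip independently with probability ``p_dup``.

    The duplicate is attached as the tip's sister on a short branch
    (a recent duplication); its sequence id gains a ``_p1`` suffix.
    """
    if not 0 <= p_dup <= 1:
        raise ValueError("p_dup must be in [0, 1]")
    t = tree.clone(depth=1)
    rng = np.random.default_rng(seed)
    for leaf in list(t.leaf_node_iter()):
        if rng.random() >= p_dup:
            continue
        parent = leaf.parent_node
        orig_len = leaf.edge.length
        stem = dendropy.Node()
        if parent is None:  # single-tip tree
            t.seed_node = stem
        else:
            parent.remove_child(leaf)
            parent.add_child(stem)
        delta = (dup_branch if orig_len is None
                 else min(dup_branch, orig_len / 2.0))
        stem.edge.length = (None if orig_len is None else orig_len - delta)
        dup_label = leaf.taxon.label + "_p1"
        dup_taxon = dendropy.Taxon(label=dup_label)
        t.taxon_namespace.add_taxon(dup_taxon)
        dup = dendropy.Node(taxon=dup_taxon)
        stem.add_child(leaf)
        stem.add_child(dup)
        leaf.edge.length = None if orig_len is None else delta
        dup.edge.length = None if orig_len is None else delta
    return t


# --- the full fixture ------------------------------------------------------

@dataclass
class FixtureDataset:
    """In-memory view of a generated dataset (also written to disk)."""

    out_dir: str
    species: list[str]
    outgroup: str
    species_tree: dendropy.Tree            # coalescent-unit branch lengths
    proteins: dict[str, str]               # sequence id -> aa
    cds: dict[str, str]                    # sequence id -> nucleotides
    lengths_aa: dict[str, int]
    gene_families: dict[str, list[str]]    # gene id -> member sequence ids
    fast_sites: dict[str, list[int]]       # gene id -> gene-local nt indices
    paralog_tips: dict[str, list[str]]
    manifest: dict = field(default_factory=dict)

    @property
    def hits_path(self) -> str:
        return os.path.join(self.out_dir, "hits.tsv")


def _random_balanced_topology(labels: list[str], rng: np.random.Generator,
                              internal_len: float,
                              tip_len: float) -> dendropy.Node:
    """Random balanced-ish rooted topology via recursive bisection."""
    labs = list(labels)
    rng.shuffle(labs)

    def build(part: list[str]) -> dendropy.Node:
        if len(part) == 1:
            nd = dendropy.Node()
            nd.label = part[0]  # taxon attached later
            nd.edge.length = tip_len
            return nd
        mid = len(part) // 2
        nd = dendropy.Node()
        nd.add_child(build(part[:mid]))
        nd.add_child(build(part[mid:]))
        nd.edge.length = internal_len
        return nd

    return build(labs)


def make_species_tree(n_species: int, outgroup: str, seed: int,
                      internal_len: float = 3.0, tip_len: float = 3.0,
                      outgroup_stem: float = 5.0) -> dendropy.Tree:
    """Random balanced ingroup topology plus a long-stemmed outgroup.

    Internal branches default to 3 coalescent units: deep enough that most
    gene trees track the species tree, shallow enough that incomplete
    lineage sorting is visible (about 5% discordance per branch).  Long
    terminal branches mirror the deep divergences of the study system.
    """
    ingroup = [f"sp{i:02d}" for i in range(1, n_species)]
    rng = np.random.default_rng(seed)
    ns = dendropy.TaxonNamespace()
    root = dendropy.Node()
    ing = _random_balanced_topology(ingroup, rng, internal_len, tip_len)
    root.add_child(ing)
    out_nd = dendropy.Node()
    out_nd.label = outgroup
    out_nd.edge.length = outgroup_stem
    root.add_child(out_nd)
    tree = dendropy.Tree(taxon_namespace=ns)
    tree.seed_node = root
    for node in tree.leaf_node_iter():
        taxon = dendropy.Taxon(label=node.label)
        ns.add_taxon(taxon)
        node.taxon = taxon
        node.label = None
    tree.is_rooted = True
    return tree


def make_fixture_dataset(out_dir: str,
                         n_species: int = 14,
                         n_genes: int = 50,
                         outgroup: str = "out",
                         slow_fast_split: float = 0.5,
                         missing_frac: float = 0.3,
                         p_dup: float = 0.1,
                         gene_length_aa: int = 170,
                         slow_multiplier: float = 0.3,
                         fast_multiplier: float = 4.0,
                         seed: int = 0,
                         sep: str = DEFAULT_SEP) -> FixtureDataset:
    """Generate and write a full study-shaped toy dataset.

    Per gene: a random subset of species is present (the outgroup always
    is), a gene tree is drawn from the MSC on the induced species tree,
    recent paralogues are injected, and codon sequences are simulated with
    a designated fraction of fast (saturated) nucleotide sites.  Writes
    per-species protein and CDS FASTA, an all-vs-all similarity hit table
    consistent with the gene families, the true species tree, and a
    ground-truth manifest.  Byte-identical output for a fixed seed.
    """
    if n_species < 4:
        raise ValueError("need at least 4 species")
    os.makedirs(out_dir, exist_ok=True)
    rng = np.random.default_rng(seed)
    sp_tree = make_species_tree(n_species, outgroup,
                                seed=int(rng.integers(0, 2**31)))
    species = sorted(lf.taxon.label for lf in sp_tree.leaf_node_iter())
    ingroup = [s for s in species if s != outgroup]

    proteins: dict[str, str] = {}
    cds: dict[str, str] = {}
    lengths: dict[str, int] = {}
    families: dict[str, list[str]] = {}
    fast_sites: dict[str, list[int]] = {}
    paralog_tips: dict[str, list[str]] = {}
    genes_meta = []

    n_nt = 3 * gene_length_aa
    for g in range(n_genes):
        gid = f"g{g:03d}"
        while True:
            present = [outgroup] + [s for s in ingroup
                                    if rng.random() >= missing_frac]
            if len(present) >= 4:
                break
        sub_sp = sp_tree.extract_tree_with_taxa_labels(labels=set(present))
        sub_sp.is_rooted = True
        gene_tree = simulate_msc_gene_trees(
            MSCModel(sub_sp), 1, seed=int(rng.integers(0, 2**31)),
            sep=sep)[0]
        gene_tree = inject_paralogs(gene_tree, p_dup,
                                    seed=int(rng.integers(0, 2**31)),
                                    sep=sep)
        for node in gene_tree.preorder_node_iter():
            if node.edge.length is not None:
                node.edge.length *= COAL_TO_SUBS
        n_fast = int(round(slow_fast_split * n_nt))
        fast = sorted(rng.choice(n_nt, size=n_fast, replace=False).tolist())
        rates = np.full(n_nt, slow_multiplier)
        rates[fast] = fast_multiplier
        cfg = SeqSimConfig(model="JC", length=n_nt, site_rates=rates,
                           seed=int(rng.integers(0, 2**31)))
        aln = simulate_sequences(gene_tree, cfg)

        members = []
        ptips = []
        for label in sorted(aln):
            sp, sid = label.split(sep, 1)
            seq_id = f"{sp}{sep}{gid}_{sid.split('_', 1)[1]}"
            seq = _sanitize_stops(aln[label])
            cds[seq_id] = seq
            proteins[seq_id] = str(Seq(seq).translate())
            lengths[seq_id] = gene_length_aa
            members.append(seq_id)
            if sid.endswith("_p1"):
                ptips.append(seq_id)
        families[gid] = members
        fast_sites[gid] = fast
        paralog_tips[gid] = ptips
        genes_meta.append({"gene_id": gid, "species": sorted(present),
                           "n_members": len(members),
                           "paralog_tips": ptips,
                           "fast_sites": fast})

    # per-species FASTA
    for sub, seqs in (("proteins", proteins), ("cds", cds)):
        d = os.path.join(out_dir, sub)
        os.makedirs(d, exist_ok=True)
        by_sp: dict[str, list[str]] = {s: [] for s in species}
        for sid in sorted(seqs):
            by_sp[sid.split(sep, 1)[0]].append(sid)
        ext = "faa" if sub == "proteins" else "fna"
        for s in species:
            with open(os.path.join(d, f"{s}.{ext}"), "w") as fh:
                for sid in by_sp[s]:
                    fh.write(f">{sid}\n{seqs[sid]}\n")

    _write_hits(out_dir, families, proteins, rng)

    with open(os.path.join(out_dir, "species.txt"), "w") as fh:
        fh.write("\n".join(species) + "\n")
    with open(os.path.join(out_dir, "true_species_tree.nwk"), "w") as fh:
        fh.write(to_newick(sp_tree) + "\n")
    manifest = {
        "seed": seed,
        "n_species": n_species,
        "n_genes": n_genes,
        "outgroup": outgroup,
        "slow_fast_split": slow_fast_split,
        "missing_frac": missing_frac,
        "p_dup": p_dup,
        "gene_length_aa": gene_length_aa,
        "slow_multiplier": slow_multiplier,
        "fast_multiplier": fast_multiplier,
        "coal_to_subs": COAL_TO_SUBS,
        "true_species_tree": to_newick(sp_tree),
        "genes": genes_meta,
    }
    with open(os.path.join(out_dir, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)

    return FixtureDataset(out_dir=out_dir, species=species, outgroup=outgroup,
                          species_tree=sp_tree, proteins=proteins, cds=cds,
                          lengths_aa=lengths, gene_families=families,
                          fast_sites=fast_sites, paralog_tips=paralog_tips,
                          manifest=manifest)


def _sanitize_stops(seq: str) -> str:
    """Replace in-frame stop codons by near neighbours (T->C at the first
    position), mirroring the upstream exclusion of stop-containing CDS."""
    codons = [seq[i:i + 3] for i in range(0, len(seq), 3)]
    return "".join("C" + c[1:] if c in _STOPS else c for c in codons)


def _write_hits(out_dir: str, families: Mapping[str, Sequence[str]],
                proteins: Mapping[str, str],
                rng: np.random.Generator) -> None:
    """Blast-style 12-column hit table consistent with the gene families:
    strong within-family hits (both directions), self-hits at e-value 0,
    and sparse weak cross-family hits above any sensible threshold."""
    path = os.path.join(out_dir, "hits.tsv")
    gene_ids = sorted(families)
    with open(path, "w") as fh:
        def row(q: str, s: str, ev: float) -> None:
            length = len(proteins[q])
            fh.write(f"{q}\t{s}\t95.0\t{length}\t3\t0\t1\t{length}\t1\t"
                     f"{length}\t{ev:.3g}\t{200.0:.1f}\n")

        for gid in gene_ids:
            members = sorted(families[gid])
            for q in members:
                row(q, q, 0.0)
                for s in members:
                    if q != s:
                        row(q, s, 10.0 ** (-rng.uniform(30, 180)))
        # weak cross-family noise, one hit per adjacent family pair
        for a, b in zip(gene_ids, gene_ids[1:]):
            row(sorted(families[a])[0], sorted(families[b])[0], 1e-5)
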