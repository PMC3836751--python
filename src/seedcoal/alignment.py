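"""Per-gene codon alignments, supermatrix concatenation, and matrix statistics.

A :class:`CodonAlignment` pairs an amino-acid alignment with its codon-level
nucleotide alignment (three nucleotide columns per amino-acid column).
Genes are concatenated end-to-end into a :class:`Supermatrix`; species absent
from a gene are padded with the undetermined symbol ``?``, while ``-`` marks
within-alignment gaps.  Both count as missing data in the summary statistics.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from Bio.Data import CodonTable

GAP = "-"
MISSING = "?"
_NUC = frozenset("ACGT")

_STANDARD_TABLE = CodonTable.unambiguous_dna_by_id[1]


class EmptyAlignmentError(ValueError):
    """Every row was removed from an alignment."""


class BackTranslationError(ValueError):
    """A CDS is inconsistent with its aligned amino-acid row."""


@dataclass
class CodonAlignment:
    """One gene's aligned sequences.

    ``taxa`` holds ``(species, sequence_id)`` per row, aligned one-to-one
    with ``nt`` (and ``aa`` when present).  ``aa`` may be ``None`` for
    matrices that only exist at the nucleotide level, e.g. bootstrap
    replicates resampled at single-site granularity.
    """

    gene_id: str
    taxa: list[tuple[str, str]]
    nt: list[str]
    aa: list[str] | None = None

    def __post_init__(self) -> None:
        if len(self.taxa) != len(self.nt):
            raise ValueError(f"{self.gene_id}: {len(self.taxa)} taxa vs "
                             f"{len(self.nt)} nucleotide rows")
        if len({len(r) for r in self.nt}) > 1:
            raise ValueError(f"{self.gene_id}: ragged nucleotide rows")
        if self.aa is not None:
            if len(self.aa) != len(self.nt):
                raise ValueError(f"{self.gene_id}: aa/nt row count mismatch")
            if self.nt and len(self.nt[0]) != 3 * len(self.aa[0]):
                raise ValueError(f"{self.gene_id}: nt length "
                                 f"{len(self.nt[0])} != 3 x aa length "
                                 f"{len(self.aa[0])}")

    @property
    def n_rows(self) -> int:
        return len(self.taxa)

    @property
    def n_nt_columns(self) -> int:
        return len(self.nt[0]) if self.nt else 0

    @property
    def species(self) -> list[str]:
        return [sp for sp, _ in self.taxa]

    def subset_rows(self, indices: Sequence[int]) -> "CodonAlignment":
        return CodonAlignment(
            gene_id=self.gene_id,
            taxa=[self.taxa[i] for i in indices],
            nt=[self.nt[i] for i in indices],
            aa=[self.aa[i] for i in indices] if self.aa is not None else None,
        )


def backtranslate(gene_id: str,
                  taxa: Sequence[tuple[str, str]],
                  aa_rows: Sequence[str],
                  cds: Mapping[str, str]) -> CodonAlignment:
    """Thread unaligned CDS onto an amino-acid alignment, codon by codon.

    Each amino-acid residue is replaced by its source codon and each gap by
    ``---``.  Every row is validated: the CDS must be exactly three times the
    ungapped residue count and each codon must translate to its residue under
    the standard genetic code.
    """
    nt_rows: list[str] = []
    for (species, seqid), aa in zip(taxa, aa_rows):
        seq = cds[seqid].upper()
        n_res = sum(1 for c in aa if c != GAP)
        if len(seq) != 3 * n_res:
            raise BackTranslationError(
                f"{gene_id}/{seqid}: CDS length {len(seq)} != 3 x "
                f"{n_res} aligned residues")
        out = []
        pos = 0
        for res in aa:
            if res == GAP:
                out.append("---")
                continue
            codon = seq[pos:pos + 3]
            pos += 3
            try:
                trans = _STANDARD_TABLE.forward_table.get(codon)
            except KeyError:  # pragma: no cover - ambiguity handled below
                trans = None
            if trans is None or trans != res.upper():
                raise BackTranslationError(
                    f"{gene_id}/{seqid}: codon {codon!r} at residue offset "
                    f"{pos // 3 - 1} does not encode {res!r}")
            out.append(codon)
        nt_rows.append("".join(out))
    return CodonAlignment(gene_id=gene_id, taxa=list(taxa), nt=nt_rows,
                          aa=[r.upper() for r in aa_rows])


def coverage_filter(aln: CodonAlignment, min_frac: float = 0.70) -> CodonAlignment:
    """Drop rows covering less than ``min_frac`` of the alignment length.

    Coverage is the fraction of amino-acid columns with a residue (non-gap);
    rows at exactly the threshold are kept (the cutoff is strict "less than").
    """
    if not 0 < min_frac <= 1:
        raise ValueError("min_frac must be in (0, 1]")
    if aln.aa is None:
        raise ValueError(f"{aln.gene_id}: coverage filter needs the amino-acid"
                         " alignment")
    ncol = len(aln.aa[0]) if aln.aa else 0
    # tiny epsilon so exact-threshold rows survive float rounding
    keep = [i for i, row in enumerate(aln.aa)
            if sum(1 for c in row if c != GAP) >= min_frac * ncol - 1e-9]
    if not keep:
        raise EmptyAlignmentError(f"{aln.gene_id}: coverage filter removed "
                                  "every row")
    return aln.subset_rows(keep)


def drop_gappy_columns(aln: CodonAlignment,
                       max_gap_frac: float = 0.5) -> CodonAlignment:
    """Optional column filter: drop aa columns whose gap fraction exceeds
    ``max_gap_frac`` (with the corresponding codon columns).  Off by default
    in the pipeline; pre-trimmed alignments are the expected input."""
    if aln.aa is None:
        raise ValueError("column filter needs the amino-acid alignment")
    nrow = aln.n_rows
    keep = [j for j in range(len(aln.aa[0]))
            if sum(1 for row in aln.aa if row[j] == GAP) / nrow <= max_gap_frac]
    aa = ["".join(row[j] for j in keep) for row in aln.aa]
    nt = ["".join(row[3 * j:3 * j + 3] for j in keep) for row in aln.nt]
    return CodonAlignment(gene_id=aln.gene_id, taxa=list(aln.taxa),
                          nt=nt, aa=aa)


@dataclass
class Supermatrix:
    """Concatenated nucleotide matrix over a fixed species set.

    ``gene_spans`` are 0-based half-open column intervals internally;
    reports convert to 1-based inclusive.
    """

    species: list[str]
    rows: dict[str, str]
    gene_spans: list[tuple[str, int, int]] = field(default_factory=list)

    @property
    def n_sites(self) -> int:
        return len(next(iter(self.rows.values()))) if self.rows else 0

    def row_matrix(self) -> np.ndarray:
        """Rows as a (n_species, n_sites) byte matrix in ``species`` order."""
        return np.array([list(self.rows[sp].encode()) for sp in self.species],
                        dtype=np.uint8)

    def column(self, j: int) -> str:
        return "".join(self.rows[sp][j] for sp in self.species)

    def site_slice(self, sites: Sequence[int]) -> "Supermatrix":
        rows = {sp: "".join(self.rows[sp][j] for j in sites)
                for sp in self.species}
        return Supermatrix(species=list(self.species), rows=rows,
                           gene_spans=[("slice", 0, len(sites))])

    def gene_alignment(self, gene_id: str) -> dict[str, str]:
        """Recover one gene's block (species -> row), padding included."""
        for gid, start, end in self.gene_spans:
            if gid == gene_id:
                return {sp: self.rows[sp][start:end] for sp in self.species}
        raise KeyError(gene_id)


@dataclass
class MatrixStats:
    n_sites: int
    pct_missing: float
    per_species_gc: dict[str, float]

    def to_json(self) -> str:
        return json.dumps({"n_sites": self.n_sites,
                           "pct_missing": self.pct_missing,
                           "per_species_gc": self.per_species_gc}, indent=2)


def concatenate(genes: Sequence[CodonAlignment],
                all_species: Sequence[str]) -> tuple[Supermatrix, MatrixStats]:
    """Lay genes end-to-end over ``all_species``.

    Species absent from a gene are padded with ``?`` across that gene's
    span.  A species appearing twice within one gene is an error: monophyly
    masking and paralogue pruning must run first.
    """
    parts: dict[str, list[str]] = {sp: [] for sp in all_species}
    spans: list[tuple[str, int, int]] = []
    offset = 0
    for g in genes:
        width = g.n_nt_columns
        seen: dict[str, str] = {}
        for (sp, _), row in zip(g.taxa, g.nt):
            if sp in seen:
                raise ValueError(f"{g.gene_id}: species {sp!r} appears more "
                                 "than once (prune paralogues first)")
            seen[sp] = row
        for sp in all_species:
            parts[sp].append(seen.get(sp, MISSING * width))
        spans.append((g.gene_id, offset, offset + width))
        offset += width
    rows = {sp: "".join(parts[sp]) for sp in all_species}
    m = Supermatrix(species=list(all_species), rows=rows, gene_spans=spans)
    return m, matrix_stats(m)


def matrix_stats(m: Supermatrix) -> MatrixStats:
    """Site count, % missing (gaps plus undetermined), and per-species GC."""
    n_sites = m.n_sites
    total = n_sites * len(m.species)
    missing = 0
    gc: dict[str, float] = {}
    for sp in m.species:
        row = m.rows[sp]
        counts = {c: row.count(c) for c in "ACGT"}
        counted = sum(counts.values())
        missing += n_sites - counted
        gc[sp] = (100.0 * (counts["G"] + counts["C"]) / counted
                  if counted else math.nan)
    pct = 100.0 * missing / total if total else 0.0
    return MatrixStats(n_sites=n_sites, pct_missing=pct, per_species_gc=gc)


def parsimony_informative_sites(m: Supermatrix) -> list[int]:
    """0-based indices of parsimony-informative columns.

    A column is informative iff at least two of the states A/C/G/T each occur
    in at least two rows; gaps and ambiguity codes never count as states.
    """
    mat = m.row_matrix()
    out = []
    codes = [ord(c) for c in "ACGT"]
    counts = np.stack([(mat == c).sum(axis=0) for c in codes])  # (4, n_sites)
    informative = (counts >= 2).sum(axis=0) >= 2
    out = np.nonzero(informative)[0].tolist()
    return out


# --- I/O -------------------------------------------------------------------

def write_fasta(rows: Mapping[str, str], path: str) -> None:
    with open(path, "w") as fh:
        for name, seq in rows.items():
            fh.write(f">{name}\n{seq}\n")


def read_fasta(path: str) -> dict[str, str]:
    from Bio import SeqIO
    return {rec.id: str(rec.seq).upper()
            for rec in SeqIO.parse(path, "fasta")}


def write_phylip(m: Supermatrix, path: str) -> None:
    """Relaxed PHYLIP (name, space, sequence; no name truncation)."""
    with open(path, "w") as fh:
        fh.write(f"{len(m.species)} {m.n_sites}\n")
        for sp in m.species:
            fh.write(f"{sp}  {m.rows[sp]}\n")


def write_gene_spans(m: Supermatrix, path: str) -> None:
    """Gene span table, 1-based inclusive coordinates."""
    with open(path, "w") as fh:
        fh.write("gene_id\tstart\tend\n")
        for gid, start, end in m.gene_spans:
            fh.write(f"{gid}\t{start + 1}\t{end}\n")
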