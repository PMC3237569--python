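"""Protein sequence and genome-table I/O, pairwise identity, redundancy
reduction, and ranked homolog lists.

A *genome set* couples a protein FASTA with a gene-order table (one row per
protein: genome, replicon, 0-based gene index internally, strand, protein id).
Gene order is what the downstream adjacency analysis consumes; the ranked
homolog lists produced here (or imported from external search output in the
BLAST ``outfmt 6`` tabular dialect) are what partial phylogenetic profiling
walks.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Align import PairwiseAligner, substitution_matrices
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord
from scipy import sparse

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
VALID_RESIDUES = frozenset(AMINO_ACIDS + "X")

#: Default substitution scheme for the internal aligner. This is a documented
#: stand-in for an external similarity search; the matrix and gap penalties
#: mirror common protein-search defaults.
DEFAULT_MATRIX = "BLOSUM62"
DEFAULT_GAP_OPEN = -11.0
DEFAULT_GAP_EXTEND = -1.0

GENE_TABLE_COLUMNS = ["genome_id", "replicon_id", "gene_index", "strand", "protein_id"]


class LoadError(ValueError):
    """Raised when a FASTA/gene-table pair violates its cross-references."""


@dataclass(frozen=True)
class ProteinRecord:
    """One protein with its genome coordinates.

    ``gene_index`` is 0-based and orders genes along a replicon; files and
    reports use 1-based indices.
    """

    protein_id: str
    genome_id: str
    replicon_id: str
    gene_index: int
    strand: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"{self.protein_id}: empty sequence")
        bad = set(self.sequence) - VALID_RESIDUES
        if bad:
            raise ValueError(f"{self.protein_id}: invalid residues {sorted(bad)}")
        if self.strand not in {"+", "-"}:
            raise ValueError(f"{self.protein_id}: strand must be '+' or '-'")
        if self.gene_index < 0:
            raise ValueError(f"{self.protein_id}: negative gene_index")

    def __len__(self) -> int:
        return len(self.sequence)


class GenomeSet:
    """Proteins grouped by genome, ordered by (replicon, gene index)."""

    def __init__(self, records: Iterable[ProteinRecord]):
        genomes: dict[str, list[ProteinRecord]] = {}
        seen: set[tuple[str, str]] = set()
        pos_seen: set[tuple[str, str, int]] = set()
        for rec in records:
            key = (rec.genome_id, rec.protein_id)
            if key in seen:
                raise LoadError(f"duplicate protein id {rec.protein_id!r} in genome {rec.genome_id!r}")
            seen.add(key)
            pos = (rec.genome_id, rec.replicon_id, rec.gene_index)
            if pos in pos_seen:
                raise LoadError(
                    f"duplicate gene_index {rec.gene_index} on replicon {rec.replicon_id!r} of {rec.genome_id!r}"
                )
            pos_seen.add(pos)
            genomes.setdefault(rec.genome_id, []).append(rec)
        for recs in genomes.values():
            recs.sort(key=lambda r: (r.replicon_id, r.gene_index))
        self.genomes: dict[str, list[ProteinRecord]] = genomes
        self._by_protein: dict[str, ProteinRecord] = {}
        for recs in genomes.values():
            for rec in recs:
                # protein ids are unique per genome; for cross-genome lookup we
                # require them to be globally unique as well (generator and
                # loaders guarantee this)
                if rec.protein_id in self._by_protein:
                    raise LoadError(f"protein id {rec.protein_id!r} occurs in more than one genome")
                self._by_protein[rec.protein_id] = rec

    def __len__(self) -> int:
        return len(self.genomes)

    def __contains__(self, genome_id: str) -> bool:
        return genome_id in self.genomes

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GenomeSet):
            return NotImplemented
        return self.genomes == other.genomes

    @property
    def n_genomes(self) -> int:
        return len(self.genomes)

    def proteins(self) -> Iterable[ProteinRecord]:
        for gid in sorted(self.genomes):
            yield from self.genomes[gid]

    @property
    def n_proteins(self) -> int:
        return len(self._by_protein)

    def get_protein(self, protein_id: str) -> ProteinRecord:
        try:
            return self._by_protein[protein_id]
        except KeyError:
            raise KeyError(f"unknown protein id {protein_id!r}") from None

    def genome_of(self, protein_id: str) -> str:
        return self.get_protein(protein_id).genome_id

    # ------------------------------------------------------------------ I/O

    def write(self, fasta_path: str | Path, table_path: str | Path) -> None:
        """Write the FASTA + gene table pair (1-based indices on disk)."""
        records = [
            SeqRecord(Seq(rec.sequence), id=rec.protein_id, description="")
            for rec in self.proteins()
        ]
        SeqIO.write(records, str(fasta_path), "fasta")
        rows = [
            (rec.genome_id, rec.replicon_id, rec.gene_index + 1, rec.strand, rec.protein_id)
            for rec in self.proteins()
        ]
        pd.DataFrame(rows, columns=GENE_TABLE_COLUMNS).to_csv(table_path, sep="\t", index=False)


@dataclass
class RankedHitList:
    """Homologs of one query, best-scoring first.

    ``hits`` rows are ``(subject_id, genome_id, similarity)`` with similarity
    non-increasing and no duplicate subjects.
    """

    query_id: str
    hits: list[tuple[str, str, float]] = field(default_factory=list)

    def __post_init__(self) -> None:
        subjects = [h[0] for h in self.hits]
        if len(subjects) != len(set(subjects)):
            raise ValueError(f"{self.query_id}: duplicate subject ids in hit list")
        sims = [h[2] for h in self.hits]
        if any(a < b for a, b in zip(sims, sims[1:])):
            raise ValueError(f"{self.query_id}: similarities not non-increasing")

    def __len__(self) -> int:
        return len(self.hits)

    def write(self, path: str | Path) -> None:
        """Export in the 12-column tabular search dialect (coordinates dummy)."""
        with open(path, "w") as fh:
            for subject_id, _genome_id, sim in self.hits:
                fh.write(
                    f"{self.query_id}\t{subject_id}\t0.0\t0\t0\t0\t0\t0\t0\t0\t0.0\t{sim:g}\n"
                )


# --------------------------------------------------------------------------
# loading


def read_genome_set(fasta_source: str | Path, gene_table_source: str | Path) -> GenomeSet:
    """Load a FASTA + gene-table pair into a :class:`GenomeSet`.

    Every table row must have a FASTA record and vice versa; table indices are
    1-based on disk and converted to 0-based internally.
    """
    seqs: dict[str, str] = {}
    for rec in SeqIO.parse(str(fasta_source), "fasta"):
        if rec.id in seqs:
            raise LoadError(f"duplicate FASTA record {rec.id!r}")
        seqs[rec.id] = str(rec.seq)
    table = pd.read_csv(gene_table_source, sep="\t", dtype={"gene_index": int})
    missing_cols = set(GENE_TABLE_COLUMNS) - set(table.columns)
    if missing_cols:
        raise LoadError(f"gene table missing columns {sorted(missing_cols)}")
    records = []
    for row in table.itertuples(index=False):
        pid = str(row.protein_id)
        if pid not in seqs:
            raise LoadError(f"gene-table protein {pid!r} has no FASTA record")
        records.append(
            ProteinRecord(
                protein_id=pid,
                genome_id=str(row.genome_id),
                replicon_id=str(row.replicon_id),
                gene_index=int(row.gene_index) - 1,
                strand=str(row.strand),
                sequence=seqs[pid],
            )
        )
    table_ids = {str(p) for p in table["protein_id"]}
    orphans = set(seqs) - table_ids
    if orphans:
        raise LoadError(f"FASTA records without gene-table rows: {sorted(orphans)[:5]}")
    return GenomeSet(records)


# --------------------------------------------------------------------------
# alignment


def _global_aligner() -> PairwiseAligner:
    aligner = PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = substitution_matrices.load(DEFAULT_MATRIX)
    aligner.open_gap_score = DEFAULT_GAP_OPEN
    aligner.extend_gap_score = DEFAULT_GAP_EXTEND
    # free end gaps: identity is computed over the aligned core, terminal
    # overhang excluded, so the alignment itself should not pay for overhang
    try:
        aligner.open_end_insertion_score = 0.0
        aligner.extend_end_insertion_score = 0.0
        aligner.open_end_deletion_score = 0.0
        aligner.extend_end_deletion_score = 0.0
    except AttributeError:  # older attribute names
        aligner.target_end_open_gap_score = 0.0
        aligner.target_end_extend_gap_score = 0.0
        aligner.query_end_open_gap_score = 0.0
        aligner.query_end_extend_gap_score = 0.0
    return aligner


def _local_aligner() -> PairwiseAligner:
    aligner = PairwiseAligner()
    aligner.mode = "local"
    aligner.substitution_matrix = substitution_matrices.load(DEFAULT_MATRIX)
    aligner.open_gap_score = DEFAULT_GAP_OPEN
    aligner.extend_gap_score = DEFAULT_GAP_EXTEND
    return aligner


_GLOBAL = _global_aligner()
_LOCAL = _local_aligner()


def local_score(seq_a: str, seq_b: str) -> float:
    """Smith-Waterman score under the package's default substitution scheme."""
    if not seq_a or not seq_b:
        return 0.0
    return float(_LOCAL.score(seq_a, seq_b))


def pairwise_identity(seq_a: str, seq_b: str) -> float:
    """Fraction of identical columns in a global alignment.

    The denominator is the number of aligned columns excluding terminal gap
    overhang (columns before the first or after the last position where both
    sequences are aligned). Symmetric in its arguments.
    """
    if not seq_a or not seq_b:
        raise ValueError("pairwise_identity requires non-empty sequences")
    # canonical argument order: co-optimal alignments are tie-broken by the
    # aligner, so symmetry is guaranteed by aligning a sorted pair
    seq_a, seq_b = sorted((seq_a, seq_b))
    alignment = _GLOBAL.align(seq_a, seq_b)[0]
    a_row, b_row = str(alignment[0]), str(alignment[1])
    # trim terminal overhang: columns outside [first, last] both-aligned region
    cols = [i for i in range(len(a_row)) if a_row[i] != "-" and b_row[i] != "-"]
    if not cols:
        return 0.0
    lo, hi = cols[0], cols[-1] + 1
    matches = sum(1 for i in range(lo, hi) if a_row[i] == b_row[i] and a_row[i] != "-")
    return matches / (hi - lo)


def reduce_redundancy(
    sequences: Mapping[str, str] | Sequence[tuple[str, str]],
    max_identity: float,
) -> list[str]:
    """Greedy longest-first redundancy reduction.

    Sequences are visited in order (length desc, id asc); each is retained only
    if its identity to every already-retained sequence is ``<= max_identity``.
    Returns the retained ids in visiting order.
    """
    if not 0.0 < max_identity <= 1.0:
        raise ValueError("max_identity must be in (0, 1]")
    items = list(sequences.items()) if isinstance(sequences, Mapping) else list(sequences)
    items.sort(key=lambda kv: (-len(kv[1]), kv[0]))
    retained: list[tuple[str, str]] = []
    for sid, seq in items:
        if all(pairwise_identity(seq, kept) <= max_identity for _, kept in retained):
            retained.append((sid, seq))
    return [sid for sid, _ in retained]


# --------------------------------------------------------------------------
# homolog ranking (internal similarity-search stand-in)


@dataclass(frozen=True)
class ScoringParams:
    """Parameters of the internal homolog ranking.

    ``score_floor`` excludes weak hits (raw Smith-Waterman score). The exact
    shared-k-mer prefilter bounds how many subjects are aligned per query;
    ``max_candidates=None`` disables it (exhaustive ranking). ``max_hits``
    truncates the final list, mirroring a capped search report.
    """

    score_floor: float = 150.0
    max_hits: int | None = 100
    kmer: int = 4
    max_candidates: int | None = 400


def _kmer_matrix(seqs: list[str], k: int) -> tuple[sparse.csr_matrix, dict[str, int]]:
    vocab: dict[str, int] = {}
    indptr = [0]
    indices: list[int] = []
    for s in seqs:
        kmers = {s[i : i + k] for i in range(len(s) - k + 1)}
        for km in kmers:
            indices.append(vocab.setdefault(km, len(vocab)))
        indptr.append(len(indices))
    data = np.ones(len(indices), dtype=np.int32)
    mat = sparse.csr_matrix(
        (data, np.asarray(indices), np.asarray(indptr)),
        shape=(len(seqs), len(vocab)),
    )
    return mat, vocab


class HomologRanker:
    """Ranks database proteins by local-alignment score against queries.

    A deterministic internal stand-in for an external similarity search.
    Subjects are prefiltered by exact shared-k-mer count (ties broken by
    subject id) and the surviving candidates Smith-Waterman scored; the final
    order is (score desc, subject_id asc). Results are independent of the
    database's input order.
    """

    def __init__(self, database: GenomeSet, params: ScoringParams | None = None):
        if database.n_proteins == 0:
            raise ValueError("empty database")
        self.params = params or ScoringParams()
        self.database = database
        self._subjects = sorted(p.protein_id for p in database.proteins())
        self._seqs = [database.get_protein(pid).sequence for pid in self._subjects]
        self._genomes = [database.get_protein(pid).genome_id for pid in self._subjects]
        if self.params.max_candidates is not None:
            self._mat, self._vocab = _kmer_matrix(self._seqs, self.params.kmer)
        else:
            self._mat, self._vocab = None, None

    def _candidates(self, query_seq: str) -> list[int]:
        p = self.params
        if self._mat is None or p.max_candidates >= len(self._subjects):
            return list(range(len(self._subjects)))
        k = p.kmer
        cols = sorted(
            {self._vocab[query_seq[i : i + k]] for i in range(len(query_seq) - k + 1)
             if query_seq[i : i + k] in self._vocab}
        )
        if not cols:
            return []
        counts = np.asarray(self._mat[:, cols].sum(axis=1)).ravel()
        order = np.lexsort((np.arange(len(counts)), -counts))  # count desc, id asc
        order = [int(i) for i in order if counts[i] > 0]
        return order[: p.max_candidates]

    def rank(self, query: ProteinRecord) -> RankedHitList:
        p = self.params
        scored: list[tuple[float, str, str]] = []
        for idx in self._candidates(query.sequence):
            s = local_score(query.sequence, self._seqs[idx])
            if s >= p.score_floor:
                scored.append((s, self._subjects[idx], self._genomes[idx]))
        scored.sort(key=lambda t: (-t[0], t[1]))
        hits = [(sid, gid, s) for s, sid, gid in scored]
        if p.max_hits is not None:
            hits = hits[: p.max_hits]
        return RankedHitList(query_id=query.protein_id, hits=hits)


def rank_homologs(
    query: ProteinRecord,
    database: GenomeSet,
    scoring_params: ScoringParams | None = None,
) -> RankedHitList:
    """One-shot homolog ranking (builds a :class:`HomologRanker` per call).

    For many queries against one database, construct the ranker once.
    """
    return HomologRanker(database, scoring_params).rank(query)


def import_ranked_hits(
    tabular_source: str | Path,
    subject_to_genome: Mapping[str, str] | str | Path,
    query_id: str | None = None,
) -> RankedHitList:
    """Import a ranked hit list from 12-column tabular search output.

    File order is preserved; duplicate subjects collapse to their best-scoring
    row. ``subject_to_genome`` maps subject ids to genome ids (mapping or
    two-column TSV); an unmappable subject is an error.
    """
    if not isinstance(subject_to_genome, Mapping):
        df = pd.read_csv(subject_to_genome, sep="\t", header=None, names=["subject", "genome"])
        subject_to_genome = dict(zip(df["subject"].astype(str), df["genome"].astype(str)))
    cols = [
        "qseqid", "sseqid", "pident", "length", "mismatch", "gapopen",
        "qstart", "qend", "sstart", "send", "evalue", "bitscore",
    ]
    try:
        table = pd.read_csv(tabular_source, sep="\t", header=None, names=cols)
    except pd.errors.EmptyDataError:
        return RankedHitList(query_id=query_id or "", hits=[])
    if query_id is None:
        query_id = str(table["qseqid"].iloc[0])
    table = table[table["qseqid"].astype(str) == query_id]
    best: dict[str, float] = {}
    order: list[str] = []
    for row in table.itertuples(index=False):
        sid = str(row.sseqid)
        score = float(row.bitscore)
        if sid not in best:
            best[sid] = score
            order.append(sid)
        elif score > best[sid]:
            best[sid] = score
    unmapped = [sid for sid in order if sid not in subject_to_genome]
    if unmapped:
        raise LoadError(f"subjects without genome mapping: {unmapped}")
    # collapse may break monotonicity of the file order; re-sort by score desc
    # preserving file order among equal scores
    rank = {sid: i for i, sid in enumerate(order)}
    order.sort(key=lambda sid: (-best[sid], rank[sid]))
    hits = [(sid, subject_to_genome[sid], best[sid]) for sid in order]
    return RankedHitList(query_id=query_id, hits=hits)


def checksum(path: str | Path) -> str:
    """SHA-256 of a file, for run-manifest determinism checks."""
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()
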