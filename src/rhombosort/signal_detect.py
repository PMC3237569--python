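"""Detection of tripartite C-terminal sorting signals.

The signal (GlyGly-CTERM in *Shewanella*/*Vibrio*-type Proteobacteria,
Myxo-CTERM in Myxococcales) has three parts, in order, at the extreme C
terminus of a protein:

1. a short signature motif containing at least one Gly (often ``SGGS``),
2. a hydrophobic transmembrane helix, and
3. a cluster of basic residues (Arg/Lys) followed by at most a few residues
   before the final one.

Class assignment rests on a single hard rule: the GlyGly-type motif never
contains Cys, the Myxo-type motif always does.

Transmembrane and signal-peptide screens are explicit hydropathy / n-h-c
heuristics with import hooks for externally computed calls; they are screens,
not topology predictors.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .sequence_io import AMINO_ACIDS, ProteinRecord

#: Kyte-Doolittle hydropathy scale. X (unknown residue) is treated as neutral.
KYTE_DOOLITTLE: dict[str, float] = {
    "A": 1.8, "R": -4.5, "N": -3.5, "D": -3.5, "C": 2.5,
    "Q": -3.5, "E": -3.5, "G": -0.4, "H": -3.2, "I": 4.5,
    "L": 3.8, "K": -3.9, "M": 1.9, "F": 2.8, "P": -1.6,
    "S": -0.8, "T": -0.7, "W": -0.9, "Y": -1.3, "V": 4.2,
    "X": 0.0,
}

BASIC = frozenset("RK")


class SignalClass(str, Enum):
    GLYGLY = "GLYGLY"
    MYXO = "MYXO"


@dataclass(frozen=True)
class HydropathyParams:
    """Sliding-window hydropathy screen settings (Kyte-Doolittle scale)."""

    window: int = 19
    threshold: float = 1.6
    min_tm_len: int = 15


@dataclass(frozen=True)
class TripartiteParams:
    """Tunables of the tripartite C-terminal scan.

    ``search_window`` residues from the C terminus are examined; the motif is
    the sub-region between the window start and the transmembrane start. The
    default motif rule requires at least one Gly; ``require_consecutive_gly``
    switches to the stricter two-consecutive-Gly curation rule.
    """

    search_window: int = 35
    min_tm_len: int = 15
    max_tail: int = 5
    min_gly: int = 1
    require_consecutive_gly: bool = False
    hydropathy: HydropathyParams = field(default_factory=HydropathyParams)
    #: mean window hydropathy required of the TM stretch inside the scan
    tm_threshold: float = 1.6

    def __post_init__(self) -> None:
        if self.search_window < self.min_tm_len + self.max_tail + 3:
            raise ValueError("search_window too small for min_tm_len + max_tail + motif")


@dataclass(frozen=True)
class TripartiteHit:
    """A detected tripartite signal (all intervals 0-based half-open)."""

    protein_id: str
    motif_interval: tuple[int, int]
    motif_seq: str
    tm_interval: tuple[int, int]
    basic_positions: tuple[int, ...]
    tail_len: int
    signal_class: SignalClass
    score: float

    def validate(self, sequence: str, params: TripartiteParams) -> None:
        ms, me = self.motif_interval
        ts, te = self.tm_interval
        L = len(sequence)
        assert me <= ts, "motif must end at or before TM start"
        assert te + self.tail_len == L, "TM end + tail must reach sequence end"
        assert all(te <= p < L for p in self.basic_positions), "basic residues outside tail"
        assert self.tail_len <= params.max_tail
        assert sequence[ms:me] == self.motif_seq
        if self.signal_class is SignalClass.GLYGLY:
            assert "G" in self.motif_seq and "C" not in self.motif_seq
        else:
            assert "C" in self.motif_seq


@dataclass(frozen=True)
class SignalPeptideCall:
    present: bool
    cleavage_pos: int | None = None

    def __post_init__(self) -> None:
        if not self.present and self.cleavage_pos is not None:
            raise ValueError("cleavage_pos only valid when present")


# --------------------------------------------------------------------------
# hydropathy screens


def _window_means(sequence: str, window: int) -> np.ndarray:
    vals = np.array([KYTE_DOOLITTLE[c] for c in sequence])
    if len(vals) < window:
        return np.empty(0)
    kernel = np.ones(window) / window
    return np.convolve(vals, kernel, mode="valid")


def detect_tm_segments(
    sequence: str, hydropathy_params: HydropathyParams | None = None
) -> list[tuple[int, int]]:
    """Candidate transmembrane segments by windowed Kyte-Doolittle hydropathy.

    A window of ``window`` residues qualifies when its mean hydropathy is at
    least ``threshold``; maximal unions of overlapping qualifying windows form
    segments, and segments shorter than ``min_tm_len`` are dropped. Returns
    sorted, non-overlapping 0-based half-open intervals; a sequence shorter
    than the window yields none.
    """
    p = hydropathy_params or HydropathyParams()
    means = _window_means(sequence, p.window)
    if means.size == 0:
        return []
    # epsilon guards exact-threshold windows against summation-order rounding
    starts = np.flatnonzero(means >= p.threshold - 1e-9)
    if starts.size == 0:
        return []
    segments: list[tuple[int, int]] = []
    seg_start = int(starts[0])
    seg_end = seg_start + p.window
    for s in starts[1:]:
        s = int(s)
        if s <= seg_end:  # windows overlap or touch: extend
            seg_end = s + p.window
        else:
            segments.append((seg_start, seg_end))
            seg_start, seg_end = s, s + p.window
    segments.append((seg_start, seg_end))
    return [(a, b) for a, b in segments if b - a >= p.min_tm_len]


def _mean_hydropathy(segment: str) -> float:
    return float(np.mean([KYTE_DOOLITTLE[c] for c in segment]))


def _max_gly_run(motif: str) -> int:
    best = run = 0
    for c in motif:
        run = run + 1 if c == "G" else 0
        best = max(best, run)
    return best


def classify_signal(motif_seq: str) -> SignalClass:
    """GLYGLY if the motif lacks Cys, MYXO if it contains one.

    Requires a non-empty motif with at least one Gly.
    """
    if not motif_seq or "G" not in motif_seq:
        raise ValueError("motif must be non-empty and contain at least one Gly")
    return SignalClass.MYXO if "C" in motif_seq else SignalClass.GLYGLY


def scan_cterm(protein: ProteinRecord, params: TripartiteParams | None = None) -> TripartiteHit | None:
    """Scan the C-terminal window of one protein for the tripartite signal.

    Enumerates all (TM start, TM end) placements inside the C-terminal search
    window with ``tail_len <= max_tail`` and TM length ``>= min_tm_len`` whose
    mean hydropathy clears the threshold, requires at least one basic residue
    in the tail and a Gly-containing motif between the window start and the TM,
    and returns the highest-scoring placement (score: Gly-run length + TM
    hydropathy + basic count; ties toward the most C-terminal TM). Returns
    ``None`` when no placement satisfies all three rules.
    """
    p = params or TripartiteParams()
    seq = protein.sequence
    L = len(seq)
    if L <= p.search_window:
        return None
    win_start = L - p.search_window
    best: tuple[float, int, int] | None = None  # (score, tm_start, tm_end)
    for tm_end in range(L - p.max_tail, L + 1):
        tail = seq[tm_end:]
        basic = [i for i in range(tm_end, L) if seq[i] in BASIC]
        if not basic:
            continue
        for tm_start in range(win_start + 1, tm_end - p.min_tm_len + 1):
            tm = seq[tm_start:tm_end]
            hyd = _mean_hydropathy(tm)
            if hyd < p.tm_threshold - 1e-9:
                continue
            motif = seq[win_start:tm_start]
            if motif.count("G") < p.min_gly:
                continue
            if p.require_consecutive_gly and _max_gly_run(motif) < 2:
                continue
            score = _max_gly_run(motif) + hyd + len(basic)
            key = (score, tm_start, tm_end)
            if best is None or key > best:
                best = key
    if best is None:
        return None
    _, tm_start, tm_end = best
    motif = seq[win_start:tm_start]
    basic = tuple(i for i in range(tm_end, L) if seq[i] in BASIC)
    return TripartiteHit(
        protein_id=protein.protein_id,
        motif_interval=(win_start, tm_start),
        motif_seq=motif,
        tm_interval=(tm_start, tm_end),
        basic_positions=basic,
        tail_len=L - tm_end,
        signal_class=classify_signal(motif),
        score=best[0],
    )


# --------------------------------------------------------------------------
# signal peptide heuristic

_SP_HYDROPHOBIC = frozenset("AILMFVWC")
_SP_SMALL = frozenset("AGS")


def predict_signal_peptide(sequence: str) -> SignalPeptideCall:
    """N-terminal signal peptide screen over the first 70 residues.

    Requires an n-region (>=1 Lys/Arg in the first five residues), an h-region
    (a run of seven hydrophobic residues), and a c-region cleavage context
    (small residues Ala/Gly/Ser at the -1 and -3 positions of a candidate
    cleavage site between residues 15 and 40, 1-based). The earliest
    qualifying cleavage site is reported (0-based index of the first mature
    residue).
    """
    head = sequence[:70]
    if len(head) < 15:
        return SignalPeptideCall(present=False)
    if not any(c in BASIC for c in head[:5]):
        return SignalPeptideCall(present=False)
    h_ok = [False] * (len(head) + 1)  # h_ok[i]: hydrophobic 7-run ends before i
    run = 0
    for i, c in enumerate(head):
        run = run + 1 if c in _SP_HYDROPHOBIC else 0
        h_ok[i + 1] = h_ok[i] or run >= 7
    # cleavage after residue pos (1-based pos in 15..40): -1 residue head[pos-1],
    # -3 residue head[pos-3]; the h-region must lie before the cleavage site
    for pos in range(15, min(40, len(head)) + 1):
        if head[pos - 1] in _SP_SMALL and head[pos - 3] in _SP_SMALL and h_ok[pos]:
            return SignalPeptideCall(present=True, cleavage_pos=pos)
    return SignalPeptideCall(present=False)


def read_signal_peptide_calls(path: str | Path) -> dict[str, SignalPeptideCall]:
    """Import externally computed signal-peptide calls.

    TSV columns: ``protein_id  present  cleavage_pos`` (cleavage_pos empty or
    0 when absent; 1-based on disk).
    """
    df = pd.read_csv(path, sep="\t")
    calls = {}
    for row in df.itertuples(index=False):
        present = bool(row.present)
        pos = int(row.cleavage_pos) if present and not pd.isna(row.cleavage_pos) else None
        calls[str(row.protein_id)] = SignalPeptideCall(
            present=present, cleavage_pos=(pos if pos is None else pos)  # 1-based == index of first mature residue
        )
    return calls


def check_topology(
    protein: ProteinRecord,
    hit: TripartiteHit | None,
    sp_call: SignalPeptideCall | None = None,
    hydropathy_params: HydropathyParams | None = None,
) -> bool:
    """True iff no TM segment lies strictly between the signal peptide end
    (or position 0) and the motif start.

    Single-pass topology: mature N terminus outside, the C-terminal TM the
    only membrane crossing, basic cluster cytosolic.
    """
    if hit is None:
        raise ValueError("check_topology requires a detected hit")
    start = 0
    if sp_call is not None and sp_call.present and sp_call.cleavage_pos is not None:
        start = sp_call.cleavage_pos
    motif_start = hit.motif_interval[0]
    for seg_start, seg_end in detect_tm_segments(protein.sequence, hydropathy_params):
        if seg_start >= start and seg_end <= motif_start:
            return False
    return True


# --------------------------------------------------------------------------
# species-specific iterative refinement


@dataclass
class RefineResult:
    hits: dict[str, TripartiteHit]
    iterations: int
    converged: bool


_BACKGROUND = {aa: 0.05 for aa in AMINO_ACIDS}


def _pssm_from_windows(windows: Sequence[str], pseudocount: float = 1.0) -> np.ndarray:
    """Pseudocount-smoothed log-odds profile over fixed-length C-terminal windows."""
    width = len(windows[0])
    if any(len(w) != width for w in windows):
        raise ValueError("windows must share one length")
    idx = {aa: i for i, aa in enumerate(AMINO_ACIDS)}
    counts = np.full((width, 20), pseudocount)
    for w in windows:
        for j, c in enumerate(w):
            if c in idx:
                counts[j, idx[c]] += 1.0
    freqs = counts / counts.sum(axis=1, keepdims=True)
    bg = np.array([_BACKGROUND[aa] for aa in AMINO_ACIDS])
    return np.log2(freqs / bg)


def _pssm_score(pssm: np.ndarray, window: str) -> float:
    idx = {aa: i for i, aa in enumerate(AMINO_ACIDS)}
    return float(sum(pssm[j, idx[c]] for j, c in enumerate(window) if c in idx))


def refine_model(
    seed_hits: Mapping[str, TripartiteHit],
    genome_proteins: Iterable[ProteinRecord],
    params: TripartiteParams | None = None,
    cutoff_fraction: float = 0.3,
    max_iterations: int = 10,
) -> RefineResult:
    """Species-specific iterative profile refinement.

    Builds a position-specific scoring profile from the seed hits' C-terminal
    windows, rescans the genome, and admits proteins whose C-terminal window
    scores at least ``cutoff_fraction`` of the lowest seed self-score *and*
    that pass the structural tripartite rules (:func:`scan_cterm`). Iterates
    to a fixed point (hit set monotonically non-decreasing; seeds are never
    removed), capped at ``max_iterations``.
    """
    if len(seed_hits) < 2:
        raise ValueError("refine_model needs at least two seed hits")
    p = params or TripartiteParams()
    proteins = {rec.protein_id: rec for rec in genome_proteins}
    hits: dict[str, TripartiteHit] = dict(seed_hits)
    width = p.search_window

    def cterm_window(rec: ProteinRecord) -> str | None:
        return rec.sequence[-width:] if len(rec.sequence) > width else None

    iterations = 0
    converged = False
    for iterations in range(1, max_iterations + 1):
        windows = [
            w for pid in sorted(hits)
            if pid in proteins and (w := cterm_window(proteins[pid])) is not None
        ]
        if not windows:
            break
        pssm = _pssm_from_windows(windows)
        trusted = cutoff_fraction * min(_pssm_score(pssm, w) for w in windows)
        added = False
        for pid in sorted(proteins):
            if pid in hits:
                continue
            w = cterm_window(proteins[pid])
            if w is None or _pssm_score(pssm, w) < trusted:
                continue
            hit = scan_cterm(proteins[pid], p)
            if hit is not None:
                hits[pid] = hit
                added = True
        if not added:
            converged = True
            break
    return RefineResult(hits=hits, iterations=iterations, converged=converged)


# --------------------------------------------------------------------------
# bulk scanning + report


def scan_genome_set(genome_set, params: TripartiteParams | None = None) -> dict[str, TripartiteHit]:
    """Run :func:`scan_cterm` over every protein; map protein_id -> hit."""
    p = params or TripartiteParams()
    out: dict[str, TripartiteHit] = {}
    for rec in genome_set.proteins():
        hit = scan_cterm(rec, p)
        if hit is not None:
            out[rec.protein_id] = hit
    return out


def hits_to_frame(hits: Mapping[str, TripartiteHit]) -> pd.DataFrame:
    """Hits report (intervals 1-based inclusive, as in all files)."""
    rows = []
    for pid in sorted(hits):
        h = hits[pid]
        rows.append(
            {
                "protein_id": pid,
                "class": h.signal_class.value,
                "motif_seq": h.motif_seq,
                "motif_start": h.motif_interval[0] + 1,
                "motif_end": h.motif_interval[1],
                "tm_start": h.tm_interval[0] + 1,
                "tm_end": h.tm_interval[1],
                "tail_len": h.tail_len,
                "basic_count": len(h.basic_positions),
                "score": round(h.score, 3),
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "protein_id", "class", "motif_seq", "motif_start", "motif_end",
            "tm_start", "tm_end", "tail_len", "basic_count", "score",
        ],
    )
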