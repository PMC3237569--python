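"""Peptide-to-protein coverage mapping.

Observed peptides (already identification-filtered upstream) are mapped onto
precursor protein sequences. A peptide counts only if it occurs in exactly one
protein of the supplied set; nested peptides (strictly contained in a longer
one) are collapsed to the longest. The question the coverage map answers for a
sorting-signal candidate: does any observed peptide overlap the detected
C-terminal domain (motif start through sequence end)? Consistent absence of
such overlap across proteins with proteomics evidence is what a proteolytic
removal of the C-terminal region predicts.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .signal_detect import TripartiteHit

TRYPTIC_RESIDUES = frozenset("KR")


@dataclass
class CoverageMap:
    protein_id: str
    protein_len: int
    intervals: list[tuple[int, int]]  # sorted, non-nested, 0-based half-open
    n_unique: int
    n_nested_removed: int
    covered_fraction: float
    domain_overlap: bool = False


def remove_nested(intervals: Sequence[tuple[int, int]]) -> list[tuple[int, int]]:
    """Drop every interval strictly contained in another; keep partial overlaps.

    Input must be sorted by start. Containment here means the container covers
    the contained interval and is strictly longer. Idempotent.
    """
    ivs = list(intervals)
    if any(a > b for (a, _), (b, _) in zip(ivs, ivs[1:])):
        raise ValueError("intervals must be sorted by start")
    # sweep in (start asc, end desc) order: an interval is nested iff some
    # earlier-sorted interval already reaches its end (duplicates keep one copy)
    order = sorted(ivs, key=lambda iv: (iv[0], -iv[1]))
    kept: list[tuple[int, int]] = []
    max_end = -1
    for s, e in order:
        if e > max_end:
            kept.append((s, e))
            max_end = e
    kept.sort()
    return kept


def _union_len(intervals: Iterable[tuple[int, int]]) -> int:
    total = 0
    prev_end = -1
    for s, e in sorted(intervals):
        s = max(s, prev_end)
        if e > s:
            total += e - s
            prev_end = e
        prev_end = max(prev_end, e)
    return total


def map_peptides(
    peptides: Iterable[str],
    proteins: Mapping[str, str],
) -> tuple[list[CoverageMap], list[str]]:
    """Map peptides onto proteins; returns (coverage maps, skipped peptides).

    A peptide maps only when it occurs as a substring of exactly one protein
    in the set; peptides found in zero or in several proteins are skipped and
    reported. All occurrences within the unique host protein are recorded.
    Nested occurrences are collapsed afterwards (longest kept).
    """
    peptides = [p for p in peptides]
    for pep in peptides:
        if len(pep) < 6:
            raise ValueError(f"peptide too short (<6): {pep!r}")
    hits: dict[str, list[tuple[int, int]]] = {pid: [] for pid in proteins}
    unique_counts: dict[str, int] = {pid: 0 for pid in proteins}
    skipped: list[str] = []
    for pep in dict.fromkeys(peptides):  # de-duplicate, keep order
        hosts = [pid for pid, seq in proteins.items() if pep in seq]
        if len(hosts) != 1:
            skipped.append(pep)
            continue
        pid = hosts[0]
        seq = proteins[pid]
        start = seq.find(pep)
        while start != -1:
            hits[pid].append((start, start + len(pep)))
            start = seq.find(pep, start + 1)
        unique_counts[pid] += 1
    maps: list[CoverageMap] = []
    for pid in sorted(proteins):
        ivs = sorted(set(hits[pid]))
        kept = remove_nested(ivs)
        maps.append(
            CoverageMap(
                protein_id=pid,
                protein_len=len(proteins[pid]),
                intervals=kept,
                n_unique=unique_counts[pid],
                n_nested_removed=len(ivs) - len(kept),
                covered_fraction=_union_len(kept) / len(proteins[pid]),
            )
        )
    return maps, skipped


def domain_overlap_check(coverage: CoverageMap, tripartite_hit: TripartiteHit) -> bool:
    """True iff any covered interval intersects the C-terminal domain.

    The domain spans from the motif start to the end of the protein.
    """
    if coverage.protein_id != tripartite_hit.protein_id:
        raise ValueError(
            f"coverage is for {coverage.protein_id!r}, hit for {tripartite_hit.protein_id!r}"
        )
    dom_start = tripartite_hit.motif_interval[0]
    dom_end = coverage.protein_len
    return any(s < dom_end and e > dom_start for s, e in coverage.intervals)


def check_tryptic(peptide: str, protein: str, position: int) -> bool:
    """Is the peptide placement consistent with trypsin cleavage?

    The peptide's final residue must be Lys/Arg or lie at the protein's C
    terminus, and the residue preceding the peptide must be Lys/Arg or the
    peptide must start the protein.
    """
    end = position + len(peptide)
    if protein[position:end] != peptide:
        raise ValueError("peptide does not occur at the stated position")
    c_ok = peptide[-1] in TRYPTIC_RESIDUES or end == len(protein)
    n_ok = position == 0 or protein[position - 1] in TRYPTIC_RESIDUES
    return c_ok and n_ok


def read_peptides(path: str | Path) -> list[str]:
    """One peptide per line, or TSV whose first column is the peptide."""
    peps: list[str] = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        peps.append(line.split("\t")[0])
    return peps


def coverage_frame(maps: Sequence[CoverageMap]) -> pd.DataFrame:
    rows = [
        {
            "protein_id": m.protein_id,
            "n_unique": m.n_unique,
            "n_nested_removed": m.n_nested_removed,
            "covered_fraction": round(m.covered_fraction, 4),
            "domain_overlap": m.domain_overlap,
            "intervals": ";".join(f"{s + 1}-{e}" for s, e in m.intervals),
        }
        for m in maps
    ]
    return pd.DataFrame(
        rows,
        columns=["protein_id", "n_unique", "n_nested_removed", "covered_fraction", "domain_overlap", "intervals"],
    )


def coverage_blocks_text(cov: CoverageMap, width: int = 60) -> str:
    """Aligned-blocks rendering: protein ruler with covered runs marked '='."""
    mask = bytearray(b"." * cov.protein_len)
    for s, e in cov.intervals:
        for i in range(s, e):
            mask[i] = ord("=")
    lines = [f"> {cov.protein_id}  covered={cov.covered_fraction:.1%}"]
    for off in range(0, cov.protein_len, width):
        chunk = mask[off : off + width].decode()
        lines.append(f"{off + 1:>6} {chunk}")
    return "\n".join(lines) + "\n"
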