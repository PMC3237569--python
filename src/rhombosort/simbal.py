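"""SIMBAL: sliding-window subsequence discrimination.

Given one query protein and a protein family partitioned into YES members
(from genomes carrying the trait) and NO members (from genomes without it),
every subsequence window of the query — lengths from 6 up to the full query
length — is scored for how well its best local-alignment matches separate the
YES set from the NO set. Each window's ranked match list is walked exactly as
in partial phylogenetic profiling, maximizing a binomial enrichment score over
list depth with ``p = |YES| / (|YES| + |NO|)``; sequences, not genomes, are
the counting unit, since the partition is a sequence set after redundancy
reduction. The result is a triangular (length x start) score surface whose
peak localizes the trait-predictive residues of the query.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .phyloprofile import BinomialScore, PhyloProfile, binomial_score
from .sequence_io import local_score, reduce_redundancy


@dataclass(frozen=True)
class Partition:
    """YES/NO family members, redundancy-reduced, fragments removed."""

    yes_seqs: tuple[tuple[str, str], ...]  # (id, sequence)
    no_seqs: tuple[tuple[str, str], ...]
    profile_id: str = ""
    redundancy_threshold: float = 0.80

    def __post_init__(self) -> None:
        yes_ids = {i for i, _ in self.yes_seqs}
        no_ids = {i for i, _ in self.no_seqs}
        if yes_ids & no_ids:
            raise ValueError("YES and NO partitions share ids")

    @property
    def n_yes(self) -> int:
        return len(self.yes_seqs)

    @property
    def n_no(self) -> int:
        return len(self.no_seqs)

    @property
    def p(self) -> float:
        return self.n_yes / (self.n_yes + self.n_no)


@dataclass(frozen=True)
class SimbalCell:
    length: int
    start: int
    score: float
    depth: int
    k: int
    n: int

    @property
    def center(self) -> float:
        return self.start + self.length / 2.0

    @property
    def end(self) -> int:
        return self.start + self.length


@dataclass
class SimbalMatrix:
    """Triangular score surface: one cell per (window length, start)."""

    query_id: str
    query_len: int
    min_len: int
    cells: dict[tuple[int, int], SimbalCell]

    def expected_cell_count(self) -> int:
        L, m = self.query_len, self.min_len
        return sum(L - l + 1 for l in range(m, L + 1))

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "length": c.length,
                "start": c.start + 1,  # 1-based in files
                "center": c.start + (c.length + 1) / 2.0,  # center of 1-based window
                "n": c.n,
                "k": c.k,
                "score": round(c.score, 4),
            }
            for c in sorted(self.cells.values(), key=lambda c: (c.length, c.start))
        ]
        return pd.DataFrame(rows, columns=["length", "start", "center", "n", "k", "score"])

    def write(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    def plot(self, path: str | Path) -> None:
        """Render the triangular heat map (window center vs length)."""
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        L, m = self.query_len, self.min_len
        # center-indexed grid at 2x resolution so half-integer centers land on cells
        grid = np.full((L - m + 1, 2 * L), np.nan)
        for (l, s), cell in self.cells.items():
            grid[l - m, int(round(2 * cell.center)) - 1] = cell.score
        fig, ax = plt.subplots(figsize=(8, 4.5))
        im = ax.imshow(
            grid, origin="lower", aspect="auto", cmap="RdYlBu_r",
            extent=(0.5, L + 0.5, m - 0.5, L + 0.5), interpolation="nearest",
        )
        ax.set_xlabel("window center (sequence position)")
        ax.set_ylabel("window length")
        ax.set_title(f"SIMBAL heat map: {self.query_id}")
        fig.colorbar(im, ax=ax, label="-log10 binomial probability")
        fig.tight_layout()
        fig.savefig(path, dpi=120)
        plt.close(fig)


def partition_family(
    members: Mapping[str, str] | Sequence[tuple[str, str]],
    member_genomes: Mapping[str, str],
    profile: PhyloProfile,
    max_identity: float = 0.80,
    min_len: int = 30,
) -> Partition:
    """Split family members into YES/NO sides by their genome's label.

    Fragments (length < ``min_len``) are dropped, then each side is
    redundancy-reduced to ``max_identity`` (greedy longest-first). Members
    from excluded genomes are dropped. An empty side is an error: the
    discrimination scan is undefined without both classes.
    """
    items = list(members.items()) if isinstance(members, Mapping) else list(members)
    yes_pool: dict[str, str] = {}
    no_pool: dict[str, str] = {}
    for mid, seq in items:
        if len(seq) < min_len:
            continue
        gid = member_genomes[mid]
        if gid in profile.excluded:
            continue
        if gid not in profile.labels:
            raise KeyError(f"member genome {gid!r} not in profile")
        (yes_pool if profile.labels[gid] == 1 else no_pool)[mid] = seq
    yes_ids = reduce_redundancy(yes_pool, max_identity)
    no_ids = reduce_redundancy(no_pool, max_identity)
    if not yes_ids or not no_ids:
        raise ValueError("partition has an empty side; SIMBAL undefined")
    return Partition(
        yes_seqs=tuple((i, yes_pool[i]) for i in yes_ids),
        no_seqs=tuple((i, no_pool[i]) for i in no_ids),
        redundancy_threshold=max_identity,
    )


def _best_depth(
    order: list[tuple[float, str, bool]], n_yes: int, n_no: int
) -> tuple[BinomialScore, int]:
    """PPP-style prefix maximization over a ranked (score, id, is_yes) list."""
    # reuse the binomial machinery with a synthetic K/N matching p = yes/(yes+no)
    K, N = n_yes, n_yes + n_no
    best: BinomialScore | None = None
    best_depth = 0
    n = k = 0
    for depth, (_s, _sid, is_yes) in enumerate(order, start=1):
        n += 1
        k += 1 if is_yes else 0
        sc = binomial_score(n, k, K, N, "point")
        if best is None or sc.score > best.score:
            best, best_depth = sc, depth
    assert best is not None
    return best, best_depth


def simbal_scan(
    query_seq: str,
    partition: Partition,
    min_len: int = 6,
    query_id: str = "query",
) -> SimbalMatrix:
    """Score every window of the query against the partition.

    For each window (length ``min_len``..query length, every start), all
    partition sequences are ranked by best local-alignment score of the window
    against the sequence (ties broken by member id ascending), each sequence
    counted once, and the binomial enrichment maximized over ranked-list
    depth. Cells store ``(score, depth, k, n)``.
    """
    L = len(query_seq)
    if L < min_len:
        raise ValueError("query shorter than the minimum window length")
    members = [(sid, seq, True) for sid, seq in partition.yes_seqs] + [
        (sid, seq, False) for sid, seq in partition.no_seqs
    ]
    n_yes, n_no = partition.n_yes, partition.n_no
    cells: dict[tuple[int, int], SimbalCell] = {}
    for l in range(min_len, L + 1):
        for s in range(0, L - l + 1):
            window = query_seq[s : s + l]
            order = sorted(
                ((local_score(window, seq), sid, is_yes) for sid, seq, is_yes in members),
                key=lambda t: (-t[0], t[1]),
            )
            best, depth = _best_depth(order, n_yes, n_no)
            cells[(l, s)] = SimbalCell(
                length=l, start=s, score=best.score, depth=depth, k=best.k, n=best.n
            )
    return SimbalMatrix(query_id=query_id, query_len=L, min_len=min_len, cells=cells)


def find_peak(matrix: SimbalMatrix) -> SimbalCell:
    """Maximum-score cell; ties go to the shortest window, then leftmost."""
    if not matrix.cells:
        raise ValueError("empty SIMBAL matrix")
    return min(matrix.cells.values(), key=lambda c: (-c.score, c.length, c.start))


def peak_summary(matrix: SimbalMatrix) -> dict:
    c = find_peak(matrix)
    return {
        "query_id": matrix.query_id,
        "length": c.length,
        "start": c.start + 1,
        "end": c.end,
        "center": c.start + (c.length + 1) / 2.0,
        "score": round(c.score, 4),
        "n": c.n,
        "k": c.k,
        "depth": c.depth,
    }
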