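"""Phylogenetic profiles and Partial Phylogenetic Profiling (PPP).

A phylogenetic profile is a binary vector over genomes: 1 ("YES") where the
trait of interest — here, carrying at least one (or at least two) tripartite
C-terminal sorting signals — is present, 0 ("NO") elsewhere. PPP asks, for
each protein, how improbably the genomes contributing its top-ranked homologs
are enriched for YES labels: the ranked hit list is walked depth by depth,
each genome counted once at its first occurrence, and each depth scored by the
binomial probability of drawing ``k`` YES genomes among ``n`` distinct genomes
when the background YES rate is ``p = K/N``. The reported score is the best
(maximum) ``-log10`` probability over all depths.

Scores are computed entirely in log space (``scipy.special``), so depths in
the tens of thousands pose no underflow risk.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Literal, Mapping

import numpy as np
import pandas as pd
from scipy.special import gammaln, logsumexp

from .sequence_io import GenomeSet, HomologRanker, RankedHitList, ScoringParams

LOG10 = np.log(10.0)

Mode = Literal["point", "upper_tail"]


@dataclass(frozen=True)
class PhyloProfile:
    """Binary genome labels with the genomes removed from the analysis."""

    labels: Mapping[str, int]
    excluded: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if set(self.labels) & self.excluded:
            raise ValueError("excluded genomes must not carry labels")
        if any(v not in (0, 1) for v in self.labels.values()):
            raise ValueError("labels must be 0/1")

    @property
    def K(self) -> int:
        return sum(self.labels.values())

    @property
    def N(self) -> int:
        return len(self.labels)

    @property
    def p(self) -> float:
        return self.K / self.N

    def write(self, path: str | Path) -> None:
        rows = [{"genome_id": g, "label": l} for g, l in sorted(self.labels.items())]
        rows += [{"genome_id": g, "label": "excluded"} for g in sorted(self.excluded)]
        pd.DataFrame(rows).to_csv(path, sep="\t", index=False)

    @classmethod
    def read(cls, path: str | Path) -> "PhyloProfile":
        df = pd.read_csv(path, sep="\t", dtype=str)
        labels = {}
        excluded = set()
        for row in df.itertuples(index=False):
            if row.label == "excluded":
                excluded.add(row.genome_id)
            else:
                labels[row.genome_id] = int(row.label)
        return cls(labels=labels, excluded=frozenset(excluded))


@dataclass(frozen=True)
class BinomialScore:
    """One depth's enrichment score: ``-log10 P(k of n | p)``."""

    n: int
    k: int
    p: float
    mode: Mode
    score: float


@dataclass(frozen=True)
class PPPResult:
    query_id: str
    best: BinomialScore
    depth: int  # number of ranked hits consumed at the optimum


def build_profile(
    genome_set: GenomeSet,
    hits: Mapping[str, object] | Iterable[str],
    min_count: int = 1,
) -> PhyloProfile:
    """Label genomes by their count of trait-positive proteins.

    ``hits`` is a collection of protein ids carrying the trait. With
    ``min_count=1`` a genome is YES iff it has at least one hit. With
    ``min_count=2`` a genome is YES iff it has at least two; genomes with
    exactly one are excluded from the analysis entirely (removed from N) —
    the stricter profile that guards against single-call curation errors.
    """
    if genome_set.n_genomes == 0:
        raise ValueError("empty genome set")
    if min_count not in (1, 2):
        raise ValueError("min_count must be 1 or 2")
    counts: dict[str, int] = {gid: 0 for gid in genome_set.genomes}
    for pid in hits:
        counts[genome_set.genome_of(pid)] += 1
    labels: dict[str, int] = {}
    excluded: set[str] = set()
    for gid, c in counts.items():
        if min_count == 2 and c == 1:
            excluded.add(gid)
        else:
            labels[gid] = 1 if c >= min_count else 0
    return PhyloProfile(labels=labels, excluded=frozenset(excluded))


# --------------------------------------------------------------------------
# binomial scoring


def _log_binom_pmf(n: int, k: np.ndarray | int, log_p: float, log_q: float) -> np.ndarray:
    k = np.asarray(k, dtype=float)
    return (
        gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)
        + k * log_p + (n - k) * log_q
    )


def binomial_score(n: int, k: int, K: int, N: int, mode: Mode = "point") -> BinomialScore:
    """Enrichment of ``k`` YES among ``n`` distinct genomes at rate ``p=K/N``.

    ``mode="point"`` scores the binomial point probability
    ``-log10[C(n,k) p^k (1-p)^(n-k)]``; ``mode="upper_tail"`` scores the
    probability of ``k`` or more successes. Log-space throughout.
    """
    if n < 1 or not 0 <= k <= n:
        raise ValueError(f"invalid (n={n}, k={k})")
    if not 1 <= K < N:
        raise ValueError(f"invalid (K={K}, N={N}); need 1 <= K < N")
    if mode not in ("point", "upper_tail"):
        raise ValueError(f"unknown mode {mode!r}")
    p = K / N
    log_p, log_q = np.log(p), np.log1p(-p)
    if mode == "point":
        logP = float(_log_binom_pmf(n, k, log_p, log_q))
    else:
        js = np.arange(k, n + 1)
        logP = float(logsumexp(_log_binom_pmf(n, js, log_p, log_q)))
        logP = min(logP, 0.0)  # guard rounding above 1
    return BinomialScore(n=n, k=k, p=p, mode=mode, score=max(0.0, -logP / LOG10))


# --------------------------------------------------------------------------
# depth optimization


def ppp_score_protein(
    hit_list: RankedHitList,
    profile: PhyloProfile,
    mode: Mode = "point",
) -> PPPResult:
    """Walk a ranked hit list and return the best depth's binomial score.

    Each genome is counted once, at its first occurrence in the list; hits
    from excluded genomes are skipped. A hit from a genome absent from the
    profile altogether is an error. Ties in the optimal score go to the
    earliest depth. An empty list scores 0 at depth 0.
    """
    K, N = profile.K, profile.N
    best: BinomialScore | None = None
    best_depth = 0
    seen: set[str] = set()
    n = k = 0
    for depth, (subject_id, genome_id, _sim) in enumerate(hit_list.hits, start=1):
        if genome_id in profile.excluded:
            continue
        if genome_id in seen:
            continue
        if genome_id not in profile.labels:
            raise KeyError(f"hit genome {genome_id!r} not in profile")
        seen.add(genome_id)
        n += 1
        k += profile.labels[genome_id]
        s = binomial_score(n, k, K, N, mode)
        # earliest depth wins ties; the epsilon keeps mathematically exact
        # ties (which float noise can order either way) at the earlier depth
        if best is None or s.score > best.score + 1e-9:
            best, best_depth = s, depth
    if best is None:
        best = BinomialScore(n=0, k=0, p=profile.p, mode=mode, score=0.0)
    return PPPResult(query_id=hit_list.query_id, best=best, depth=best_depth)


def ppp_genome(
    genome_id: str,
    database: GenomeSet,
    profile: PhyloProfile,
    ranking: HomologRanker | Mapping[str, RankedHitList] | None = None,
    mode: Mode = "point",
    scoring_params: ScoringParams | None = None,
) -> list[PPPResult]:
    """Score every protein of one genome against the profile.

    ``ranking`` is either a prebuilt :class:`HomologRanker`, a mapping of
    precomputed (e.g. imported) ranked hit lists keyed by protein id, or
    ``None`` to build an internal ranker over ``database``. Results are
    sorted by score descending, ties by protein id ascending.
    """
    if genome_id not in database:
        raise KeyError(f"unknown genome {genome_id!r}")
    if ranking is None:
        ranking = HomologRanker(database, scoring_params)
    results: list[PPPResult] = []
    for rec in database.genomes[genome_id]:
        if isinstance(ranking, HomologRanker):
            hit_list = ranking.rank(rec)
        else:
            hit_list = ranking[rec.protein_id]
        results.append(ppp_score_protein(hit_list, profile, mode))
    results.sort(key=lambda r: (-r.best.score, r.query_id))
    return results


def ppp_results_frame(results: Iterable[PPPResult]) -> pd.DataFrame:
    rows = [
        {
            "protein_id": r.query_id,
            "score": round(r.best.score, 4),
            "depth": r.depth,
            "n": r.best.n,
            "k": r.best.k,
        }
        for r in results
    ]
    return pd.DataFrame(rows, columns=["protein_id", "score", "depth", "n", "k"])
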