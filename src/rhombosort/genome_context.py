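"""Dedicated-system detection from gene order.

A sorting enzyme paired with a single target in a genome is a *dedicated
system*: the genome encodes exactly one trait-positive target protein, and the
candidate processing enzyme sits no more than about one gene away from it on
the same replicon. Genomes with multiple targets are never called dedicated —
in such genomes the enzyme serves many substrates and shows no adjacency
preference. Distances are gene-index differences; strand is carried in the
records but deliberately ignored.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd

from .sequence_io import GenomeSet


@dataclass(frozen=True)
class AdjacencyCall:
    genome_id: str
    target_protein_id: str
    enzyme_protein_id: str
    gene_distance: int
    same_replicon: bool
    dedicated: bool


def find_dedicated_systems(
    genome_set: GenomeSet,
    target_hits: Iterable[str],
    enzyme_hits: Iterable[str],
    max_gap: int = 2,
) -> list[AdjacencyCall]:
    """Pair each target with its closest enzyme and flag dedicated systems.

    For every genome with at least one enzyme, each target is paired with the
    minimum-distance enzyme (same-replicon pairs preferred; ties broken by
    enzyme id). ``dedicated`` requires: the genome has exactly one target, the
    pair shares a replicon, and ``|gene_index difference| <= max_gap``
    (default 2: adjacent, or one intervening gene — "no more than one gene
    apart"; set 1 for strict adjacency). Output order is (genome, target),
    independent of input ordering.
    """
    targets_by_genome: dict[str, list[str]] = {}
    enzymes_by_genome: dict[str, list[str]] = {}
    for pid in target_hits:
        targets_by_genome.setdefault(genome_set.genome_of(pid), []).append(pid)
    for pid in enzyme_hits:
        enzymes_by_genome.setdefault(genome_set.genome_of(pid), []).append(pid)

    calls: list[AdjacencyCall] = []
    for gid in sorted(set(targets_by_genome) & set(enzymes_by_genome)):
        targets = sorted(targets_by_genome[gid])
        enzymes = sorted(enzymes_by_genome[gid])
        single_target = len(targets) == 1
        for tid in targets:
            t = genome_set.get_protein(tid)
            # closest enzyme: same-replicon first, then distance, then id
            best = min(
                enzymes,
                key=lambda eid: (
                    genome_set.get_protein(eid).replicon_id != t.replicon_id,
                    abs(genome_set.get_protein(eid).gene_index - t.gene_index),
                    eid,
                ),
            )
            e = genome_set.get_protein(best)
            same_rep = e.replicon_id == t.replicon_id
            dist = abs(e.gene_index - t.gene_index)
            calls.append(
                AdjacencyCall(
                    genome_id=gid,
                    target_protein_id=tid,
                    enzyme_protein_id=best,
                    gene_distance=dist,
                    same_replicon=same_rep,
                    dedicated=single_target and same_rep and dist <= max_gap,
                )
            )
    return calls


def adjacency_frame(calls: Sequence[AdjacencyCall]) -> pd.DataFrame:
    rows = [
        {
            "genome_id": c.genome_id,
            "target_id": c.target_protein_id,
            "enzyme_id": c.enzyme_protein_id,
            "gene_distance": c.gene_distance,
            "same_replicon": c.same_replicon,
            "dedicated": c.dedicated,
        }
        for c in calls
    ]
    return pd.DataFrame(
        rows,
        columns=["genome_id", "target_id", "enzyme_id", "gene_distance", "same_replicon", "dedicated"],
    )
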