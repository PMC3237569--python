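"""Amino-acid composition of transmembrane cores.

The hydrophobic core of a C-terminal sorting signal is expected to deviate
from a generic transmembrane composition: strongly Leu/Gly-skewed, depleted in
the beta-branched Val/Ile that dominate ordinary single-pass helices. This
module pools residue counts over detected TM intervals (signature-motif
columns excluded by default) and compares the result against a reference
composition by per-residue log2 ratios and a likelihood-ratio G statistic.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from .sequence_io import AMINO_ACIDS
from .signal_detect import TripartiteHit


@dataclass(frozen=True)
class CompositionTable:
    freq: Mapping[str, float]
    n_residues: int
    label: str = ""

    def __post_init__(self) -> None:
        total = sum(self.freq.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"frequencies sum to {total}, not 1")
        if any(v < 0 for v in self.freq.values()):
            raise ValueError("negative frequency")

    def to_frame(self) -> pd.DataFrame:
        rows = [{"residue": aa, "freq": self.freq.get(aa, 0.0)} for aa in AMINO_ACIDS]
        return pd.DataFrame(rows)


#: Reference single-pass TM-helix composition. The three leading values follow
#: the published TMbase ordering (Leu 17%, Val 12%, Ile 12%); the remaining
#: mass is spread uniformly over the other 17 residues. This fill-in is an
#: artifact convention for comparison plumbing, not measured data.
TM_REFERENCE = CompositionTable(
    freq={
        aa: (0.17 if aa == "L" else 0.12 if aa in "VI" else (1.0 - 0.41) / 17)
        for aa in AMINO_ACIDS
    },
    n_residues=10_000,
    label="tm_reference",
)


def tm_core_composition(
    hits: Mapping[str, TripartiteHit],
    proteins: Mapping[str, str],
    exclude_motif: bool = True,
    label: str = "tm_core",
) -> CompositionTable:
    """Pooled residue frequencies over the hits' TM intervals.

    With ``exclude_motif`` (default) only the TM interval proper is counted,
    i.e. the signature motif upstream of it never contributes; passing
    ``False`` widens the window to include the motif columns.
    """
    counts: dict[str, int] = {aa: 0 for aa in AMINO_ACIDS}
    total = 0
    for pid in sorted(hits):
        hit = hits[pid]
        seq = proteins[pid]
        start = hit.tm_interval[0] if exclude_motif else hit.motif_interval[0]
        for c in seq[start : hit.tm_interval[1]]:
            if c in counts:
                counts[c] += 1
                total += 1
    if total == 0:
        raise ValueError("no TM residues pooled")
    return CompositionTable(
        freq={aa: counts[aa] / total for aa in AMINO_ACIDS}, n_residues=total, label=label
    )


def compare_composition(a: CompositionTable, b: CompositionTable) -> pd.DataFrame:
    """Per-residue log2 enrichment of ``a`` over ``b`` plus a G statistic.

    Frequencies are smoothed with a pseudocount of ``0.5/n`` (n = residues in
    ``a``) before the ratio; the G statistic is the likelihood-ratio
    ``2 * sum O_i * ln(O_i / E_i)`` with ``b`` supplying expectations, using
    the same smoothed frequencies. The frame carries ``G`` and ``df`` as
    attributes (``.attrs``).
    """
    if set(a.freq) != set(b.freq):
        raise ValueError("composition alphabets differ")
    if a.n_residues == 0 or b.n_residues == 0:
        raise ValueError("empty composition")
    alphabet = sorted(a.freq)
    delta = 0.5 / a.n_residues
    A = len(alphabet)

    def smooth(freq: Mapping[str, float]) -> np.ndarray:
        v = np.array([freq[aa] for aa in alphabet]) + delta
        return v / v.sum()

    fa, fb = smooth(a.freq), smooth(b.freq)
    log2_ratio = np.log2(fa / fb)
    observed = fa * a.n_residues
    expected = fb * a.n_residues
    G = float(2.0 * np.sum(observed * np.log(observed / expected)))
    out = pd.DataFrame({"residue": alphabet, "freq_a": fa, "freq_b": fb, "log2_ratio": log2_ratio})
    out.attrs["G"] = max(G, 0.0)
    out.attrs["df"] = A - 1
    return out
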