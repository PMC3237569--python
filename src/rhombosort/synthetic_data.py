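"""Seeded synthetic pangenomes with planted sorting signals and ground truth.

The generator emulates the statistical structure the discovery analysis
assumes, at desk scale: a pangenome in which a minority of genomes ("YES")
carry 1-13 proteins ending in a planted tripartite C-terminal signal plus
exactly one cognate protease whose near-active-site window is discriminative,
while every genome carries non-cognate protease paralogs of the same family
and unrelated decoy proteins. All randomness flows from one
``numpy.random.Generator`` seeded in the config; runs are byte-identical
under a fixed seed.

Planted regions (signature motif, TM, basic cluster, the enzyme patch) are
kept free of substitutions and indels so ground-truth coordinates stay exact;
the enzyme family scaffold mutates per site at the configured rate. Genome
labels are assigned independently — the sporadic taxonomic distribution of
the real trait is emulated without phylogenetic correlation between genomes.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict, replace
from pathlib import Path

import numpy as np

from .sequence_io import AMINO_ACIDS, GenomeSet, ProteinRecord

#: Background residue frequencies for decoy proteins and target bodies:
#: hydrophilic-leaning, so spurious C-terminal TM stretches are rare.
BACKGROUND_FREQ: dict[str, float] = {
    "A": 0.07, "R": 0.06, "N": 0.05, "D": 0.06, "C": 0.01,
    "Q": 0.05, "E": 0.07, "G": 0.08, "H": 0.02, "I": 0.04,
    "L": 0.08, "K": 0.07, "M": 0.02, "F": 0.03, "P": 0.05,
    "S": 0.09, "T": 0.06, "W": 0.01, "Y": 0.03, "V": 0.05,
}

#: Leu-rich TM-core frequencies for planted transmembrane stretches. The
#: Leu/Gly skew mirrors what sorting-signal TM cores show relative to generic
#: single-pass helices.
TM_FREQ: dict[str, float] = {
    "L": 0.40, "A": 0.10, "G": 0.10, "F": 0.09, "I": 0.09, "V": 0.09,
    "M": 0.04, "C": 0.02, "S": 0.03, "T": 0.02, "W": 0.01, "Y": 0.01,
}

_SP_HYDRO = "LVIFAM"


@dataclass(frozen=True)
class PangenomeConfig:
    """Generator settings; defaults are the package's standard study conditions."""

    n_genomes: int = 200
    n_yes: int = 40
    targets_per_yes: tuple[int, int] = (1, 13)
    genes_per_genome: int = 60
    protein_length_range: tuple[int, int] = (60, 140)
    motif_template: str = "SGGS"
    tm_len: int = 18
    tail_basic: str = "RRK"
    max_extra_tail: int = 2
    decoy_family_count: int = 1  # non-cognate protease paralogs per genome
    enzyme_len: int = 60
    patch_yes: str = "SGMLH"
    patch_no: str = "YGMLF"
    patch_pos: int = 30
    adjacency_max_gap: int = 2
    mutation_rate: float = 0.15
    search_window: int = 35  # C-terminal region peptides must avoid
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.targets_per_yes
        if not (1 <= lo <= hi <= 13):
            raise ValueError("targets_per_yes must lie within [1, 13]")
        if self.n_yes >= self.n_genomes:
            raise ValueError("n_yes must be < n_genomes")
        if len(self.patch_yes) != len(self.patch_no):
            raise ValueError("patch variants must share one length")
        if hi + 1 + self.decoy_family_count > self.genes_per_genome:
            raise ValueError("more planted genes than gene slots")


@dataclass
class PlantedTarget:
    protein_id: str
    genome_id: str
    motif_start: int  # start of the signature motif (0-based)
    domain_start: int  # start of the C-terminal search region the scan reports
    tm_interval: tuple[int, int]
    signal_class: str
    length: int


@dataclass
class GroundTruth:
    """Everything the generator planted, for parameter-recovery tests."""

    labels: dict[str, int]
    targets: dict[str, PlantedTarget]
    cognates: dict[str, str]  # YES genome -> cognate enzyme protein id
    decoy_enzymes: list[str]
    patch_interval: tuple[int, int]  # on every enzyme sequence
    adjacency: list[tuple[str, str, str, int]]  # (genome, target, cognate, distance)
    seed: int

    def targets_of(self, genome_id: str) -> list[str]:
        return sorted(t.protein_id for t in self.targets.values() if t.genome_id == genome_id)

    @property
    def enzyme_ids(self) -> list[str]:
        return sorted(list(self.cognates.values()) + self.decoy_enzymes)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "labels": self.labels,
            "targets": {k: asdict(v) for k, v in self.targets.items()},
            "cognates": self.cognates,
            "decoy_enzymes": self.decoy_enzymes,
            "patch_interval": list(self.patch_interval),
            "adjacency": [list(t) for t in self.adjacency],
            "seed": self.seed,
        }
        Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))

    @classmethod
    def from_json(cls, path: str | Path) -> "GroundTruth":
        d = json.loads(Path(path).read_text())
        targets = {
            k: PlantedTarget(**{**v, "tm_interval": tuple(v["tm_interval"])})
            for k, v in d["targets"].items()
        }
        return cls(
            labels=d["labels"],
            targets=targets,
            cognates=d["cognates"],
            decoy_enzymes=d["decoy_enzymes"],
            patch_interval=tuple(d["patch_interval"]),
            adjacency=[tuple(t) for t in d["adjacency"]],
            seed=d["seed"],
        )


# --------------------------------------------------------------------------
# sequence builders


def _draw(rng: np.random.Generator, n: int, freq: dict[str, float]) -> str:
    letters = list(freq)
    probs = np.array([freq[a] for a in letters])
    probs = probs / probs.sum()
    return "".join(rng.choice(letters, size=n, p=probs))


def _background_no_cys(n: int, rng: np.random.Generator) -> str:
    freq = {a: f for a, f in BACKGROUND_FREQ.items() if a != "C"}
    return _draw(rng, n, freq)


def _signal_prefix(rng: np.random.Generator) -> str:
    """A 16-residue signal peptide: n-region MKK, hydrophobic h-region, GSA/QA
    c-region with an Ala at the -1 and -3 cleavage positions."""
    h = "".join(rng.choice(list(_SP_HYDRO), size=8))
    return "MKK" + h + "GSAQA"


def _make_target(rng: np.random.Generator, cfg: PangenomeConfig, pid: str, gid: str) -> tuple[str, PlantedTarget]:
    lo, hi = cfg.protein_length_range
    extra_tail = int(rng.integers(0, cfg.max_extra_tail + 1))
    tail = cfg.tail_basic + _draw(rng, extra_tail, {a: 1.0 for a in "ASTQNDEG"})
    tm = _draw(rng, cfg.tm_len, TM_FREQ)
    prefix = _signal_prefix(rng)
    fixed = len(prefix) + len(cfg.motif_template) + len(tm) + len(tail)
    body_len = int(rng.integers(max(lo - fixed, 20), hi - fixed + 1))
    body = _background_no_cys(body_len, rng)
    seq = prefix + body + cfg.motif_template + tm + tail
    L = len(seq)
    motif_start = len(prefix) + body_len
    tm_start = motif_start + len(cfg.motif_template)
    planted = PlantedTarget(
        protein_id=pid,
        genome_id=gid,
        motif_start=motif_start,
        domain_start=L - cfg.search_window,
        tm_interval=(tm_start, tm_start + cfg.tm_len),
        signal_class="MYXO" if "C" in cfg.motif_template else "GLYGLY",
        length=L,
    )
    return seq, planted


def _make_enzyme(
    rng: np.random.Generator, cfg: PangenomeConfig, scaffold: str, patch: str
) -> str:
    """Mutate the family scaffold per site (patch region immune), then plant
    the patch variant."""
    ppos = cfg.patch_pos
    chars = list(scaffold)
    mutate = rng.random(len(chars)) < cfg.mutation_rate
    subs = rng.integers(0, 20, size=len(chars))
    for i in range(len(chars)):
        if ppos <= i < ppos + len(patch):
            continue
        if mutate[i]:
            chars[i] = AMINO_ACIDS[int(subs[i])]
    chars[ppos : ppos + len(patch)] = list(patch)
    return "".join(chars)


# --------------------------------------------------------------------------
# pangenome assembly


def generate_pangenome(config: PangenomeConfig | None = None) -> tuple[GenomeSet, GroundTruth]:
    """Build a seeded pangenome and its complete ground truth."""
    cfg = config or PangenomeConfig()
    rng = np.random.default_rng(cfg.seed)
    scaffold = _draw(rng, cfg.enzyme_len, BACKGROUND_FREQ)
    genome_ids = [f"g{i:04d}" for i in range(cfg.n_genomes)]
    yes_idx = set(rng.choice(cfg.n_genomes, size=cfg.n_yes, replace=False).tolist())
    labels = {gid: int(i in yes_idx) for i, gid in enumerate(genome_ids)}

    records: list[ProteinRecord] = []
    targets: dict[str, PlantedTarget] = {}
    cognates: dict[str, str] = {}
    decoy_enzymes: list[str] = []
    adjacency: list[tuple[str, str, str, int]] = []
    lo, hi = cfg.targets_per_yes
    gap = cfg.adjacency_max_gap

    for gi, gid in enumerate(genome_ids):
        G = cfg.genes_per_genome
        slots: dict[int, tuple[str, str]] = {}  # gene index -> (kind, payload)
        n_targets = int(rng.integers(lo, hi + 1)) if labels[gid] else 0

        if n_targets == 1:
            # dedicated system: cognate within the adjacency gap of the target
            t_slot = int(rng.integers(gap, G - gap))
            offsets = [o for o in range(-gap, gap + 1) if o != 0]
            c_slot = t_slot + int(rng.choice(offsets))
            slots[t_slot] = ("target", "")
            slots[c_slot] = ("cognate", "")
        elif n_targets > 1:
            free = list(range(G))
            t_slots = sorted(rng.choice(free, size=n_targets, replace=False).tolist())
            for s in t_slots:
                slots[s] = ("target", "")
            # place the cognate away from every target; when targets are so
            # dense that no slot is clear of the gap, take the farthest one
            open_slots = [s for s in free if s not in slots]
            far = [s for s in open_slots if all(abs(s - t) > gap for t in t_slots)]
            if far:
                slots[int(rng.choice(far))] = ("cognate", "")
            else:
                slots[max(open_slots, key=lambda s: min(abs(s - t) for t in t_slots))] = ("cognate", "")

        # decoy enzyme paralogs: in dedicated genomes, keep them out of the
        # target's adjacency gap so planted truth is the only dedicated signal
        forbidden = set()
        if n_targets == 1:
            t_slot = next(s for s, (k, _) in slots.items() if k == "target")
            forbidden = {t_slot + o for o in range(-gap, gap + 1)}
        for _ in range(cfg.decoy_family_count):
            open_slots = [s for s in range(G) if s not in slots and s not in forbidden]
            slots[int(rng.choice(open_slots))] = ("decoy_enzyme", "")

        t_count = e_count = 0
        for s in range(G):
            kind = slots.get(s, ("random", ""))[0]
            pid = f"{gid}_p{s:03d}"
            if kind == "target":
                seq, planted = _make_target(rng, cfg, pid, gid)
                targets[pid] = planted
                t_count += 1
            elif kind == "cognate":
                seq = _make_enzyme(rng, cfg, scaffold, cfg.patch_yes)
                cognates[gid] = pid
            elif kind == "decoy_enzyme":
                seq = _make_enzyme(rng, cfg, scaffold, cfg.patch_no)
                decoy_enzymes.append(pid)
                e_count += 1
            else:
                n = int(rng.integers(*cfg.protein_length_range))
                seq = _draw(rng, n, BACKGROUND_FREQ)
            records.append(
                ProteinRecord(
                    protein_id=pid,
                    genome_id=gid,
                    replicon_id="chr",
                    gene_index=s,
                    strand="+" if rng.random() < 0.5 else "-",
                    sequence=seq,
                )
            )
        if n_targets == 1:
            t_slot = next(s for s, (k, _) in slots.items() if k == "target")
            c_slot = next(s for s, (k, _) in slots.items() if k == "cognate")
            adjacency.append((gid, f"{gid}_p{t_slot:03d}", f"{gid}_p{c_slot:03d}", abs(t_slot - c_slot)))

    truth = GroundTruth(
        labels=labels,
        targets=targets,
        cognates=cognates,
        decoy_enzymes=sorted(decoy_enzymes),
        patch_interval=(cfg.patch_pos, cfg.patch_pos + len(cfg.patch_yes)),
        adjacency=sorted(adjacency),
        seed=cfg.seed,
    )
    return GenomeSet(records), truth


def generate_labeled_proteins(
    n_pos: int = 500, n_neg: int = 500, config: PangenomeConfig | None = None, seed: int = 0
) -> tuple[list[ProteinRecord], dict[str, bool]]:
    """A flat labeled set for detector benchmarking: ``n_pos`` proteins built
    with the planted tripartite signal, ``n_neg`` background decoys."""
    cfg = replace(config or PangenomeConfig(), seed=seed)
    rng = np.random.default_rng(seed)
    records: list[ProteinRecord] = []
    labels: dict[str, bool] = {}
    for i in range(n_pos):
        pid = f"pos{i:04d}"
        seq, _ = _make_target(rng, cfg, pid, "bench")
        records.append(ProteinRecord(pid, "bench", "chr", i, "+", seq))
        labels[pid] = True
    for i in range(n_neg):
        pid = f"neg{i:04d}"
        n = int(rng.integers(*cfg.protein_length_range))
        records.append(
            ProteinRecord(pid, "bench", "chr", n_pos + i, "+", _draw(rng, n, BACKGROUND_FREQ))
        )
        labels[pid] = False
    return records, labels


# --------------------------------------------------------------------------
# in-silico proteomics


def digest_tryptic(sequence: str, missed_cleavages: int = 0) -> list[tuple[int, str]]:
    """Tryptic fragments (cut after Lys/Arg, not before Pro) with positions."""
    cut_after = [
        i for i in range(len(sequence) - 1)
        if sequence[i] in "KR" and sequence[i + 1] != "P"
    ]
    bounds = [0] + [i + 1 for i in cut_after] + [len(sequence)]
    frags = [(bounds[i], sequence[bounds[i]:bounds[i + 1]]) for i in range(len(bounds) - 1)]
    if missed_cleavages > 0:
        joined = []
        for mc in range(1, missed_cleavages + 1):
            for i in range(len(frags) - mc):
                start = frags[i][0]
                joined.append((start, "".join(f[1] for f in frags[i : i + mc + 1])))
        frags += joined
    return frags


def generate_peptides(
    genome_set: GenomeSet,
    truth: GroundTruth,
    include_cterm: bool = False,
    missed_cleavages: int = 0,
    sample_fraction: float = 0.6,
    min_len: int = 6,
    max_len: int = 35,
    seed: int | None = None,
) -> tuple[list[str], dict[str, list[tuple[int, int]]]]:
    """Sampled in-silico tryptic peptides from the planted target proteins.

    By default peptides overlapping the C-terminal domain (from the search
    region start to the sequence end) are excluded, emulating the observed
    absence of coverage there; ``include_cterm=True`` keeps them. Returns the
    peptide list plus the planted coverage intervals per protein.
    """
    rng = np.random.default_rng(truth.seed if seed is None else seed)
    peptides: list[str] = []
    planted: dict[str, list[tuple[int, int]]] = {}
    for pid in sorted(truth.targets):
        seq = genome_set.get_protein(pid).sequence
        dom_start = truth.targets[pid].domain_start
        intervals: list[tuple[int, int]] = []
        for start, frag in digest_tryptic(seq, missed_cleavages):
            if not (min_len <= len(frag) <= max_len):
                continue
            end = start + len(frag)
            if not include_cterm and end > dom_start:
                continue
            if rng.random() < sample_fraction:
                peptides.append(frag)
                intervals.append((start, end))
        planted[pid] = intervals
    return peptides, planted
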