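"""End-to-end discovery workflow.

Stages, in order: tripartite C-terminal signal detection (optionally with
species-specific refinement) -> phylogenetic profile construction -> PPP over
the YES genomes -> assembly of the top-scoring family -> YES/NO partition and
SIMBAL scan of a chosen query -> dedicated-system adjacency calls -> optional
proteomics-coverage and TM-composition reports. Every stage writes TSV/JSON
under one run directory; a manifest records the seed, parameters and output
checksums, so a rerun with the same config is checksum-identical.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .composition_stats import TM_REFERENCE, compare_composition, tm_core_composition
from .genome_context import adjacency_frame, find_dedicated_systems
from .phyloprofile import build_profile, ppp_genome, ppp_results_frame
from .proteomics_coverage import coverage_frame, domain_overlap_check, map_peptides
from .sequence_io import HomologRanker, ScoringParams, checksum, read_genome_set
from .signal_detect import TripartiteParams, hits_to_frame, scan_genome_set
from .simbal import partition_family, peak_summary, simbal_scan
from .synthetic_data import PangenomeConfig, generate_pangenome, generate_peptides

logger = logging.getLogger("rhombosort")


class StageError(RuntimeError):
    """A pipeline stage failed; partial outputs remain in the run directory."""


@dataclass
class RunConfig:
    """Configuration of one discovery run.

    Either ``fasta``/``gene_table`` point at real inputs, or ``synthetic``
    asks for a generated pangenome under ``seed``.
    """

    out_dir: str = "run"
    fasta: str | None = None
    gene_table: str | None = None
    synthetic: bool = True
    seed: int = 0
    min_count: int = 1
    detect: bool = True
    simbal: bool = True
    context: bool = True
    proteomics: bool = True
    composition: bool = True
    tripartite: TripartiteParams = field(default_factory=TripartiteParams)
    scoring: ScoringParams = field(default_factory=ScoringParams)
    pangenome: PangenomeConfig | None = None
    simbal_min_len: int = 6


def run_discovery(config: RunConfig) -> dict:
    """Run the full workflow; returns the manifest dict."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "seed": config.seed,
        "stages": {},
        "outputs": {},
    }
    t0 = time.time()

    def stage(name: str):
        logger.info("stage %s", name)
        manifest["stages"][name] = {"started_at": round(time.time() - t0, 2)}
        return time.time()

    def done(name: str, t: float) -> None:
        manifest["stages"][name]["seconds"] = round(time.time() - t, 2)

    # ---- inputs
    t = stage("load")
    truth = None
    if config.synthetic:
        pcfg = config.pangenome or PangenomeConfig(seed=config.seed)
        genome_set, truth = generate_pangenome(pcfg)
        genome_set.write(out / "pangenome.fasta", out / "pangenome.genes.tsv")
        truth.to_json(out / "truth.json")
        manifest["outputs"]["truth"] = "truth.json"
    else:
        if not config.fasta or not config.gene_table:
            raise StageError("load: need fasta and gene_table when synthetic=False")
        genome_set = read_genome_set(config.fasta, config.gene_table)
    done("load", t)

    # ---- detection
    if not config.detect:
        raise StageError("detect: stage disabled and no precomputed hits provided")
    t = stage("detect")
    hits = scan_genome_set(genome_set, config.tripartite)
    hits_to_frame(hits).to_csv(out / "hits.tsv", sep="\t", index=False)
    done("detect", t)

    # ---- profile
    t = stage("profile")
    profile = build_profile(genome_set, hits, min_count=config.min_count)
    profile.write(out / "profile.tsv")
    done("profile", t)

    # ---- PPP over YES genomes
    t = stage("ppp")
    ranker = HomologRanker(genome_set, config.scoring)
    yes_genomes = sorted(g for g, l in profile.labels.items() if l == 1)
    top_rows = []
    for gid in yes_genomes:
        results = ppp_genome(gid, genome_set, profile, ranker)
        frame = ppp_results_frame(results)
        frame.insert(0, "genome_id", gid)
        top_rows.append(frame.head(5))
    ppp_report = (
        pd.concat(top_rows, ignore_index=True)
        if top_rows
        else pd.DataFrame(columns=["genome_id", "protein_id", "score", "depth", "n", "k"])
    )
    ppp_report.to_csv(out / "ppp_top.tsv", sep="\t", index=False)
    done("ppp", t)

    # ---- assemble the top family: the best-scoring protein per YES genome,
    # expanded to everything it recruits above the score floor
    t = stage("family")
    family: dict[str, str] = {}
    query_id = None
    best_score = -1.0
    for gid in yes_genomes:
        sub = ppp_report[ppp_report["genome_id"] == gid]
        if sub.empty:
            continue
        top = sub.iloc[0]
        if top["score"] > best_score:
            best_score = float(top["score"])
            query_id = str(top["protein_id"])
    if query_id is not None:
        for sid, _g, _s in ranker.rank(genome_set.get_protein(query_id)).hits:
            family[sid] = genome_set.get_protein(sid).sequence
    manifest["top_family_query"] = query_id
    manifest["top_family_size"] = len(family)
    done("family", t)

    # ---- SIMBAL
    if config.simbal and query_id is not None and len(family) >= 4:
        t = stage("simbal")
        member_genomes = {pid: genome_set.genome_of(pid) for pid in family}
        try:
            partition = partition_family(family, member_genomes, profile)
        except ValueError as exc:
            raise StageError(f"simbal: {exc}") from exc
        matrix = simbal_scan(
            genome_set.get_protein(query_id).sequence,
            partition,
            min_len=config.simbal_min_len,
            query_id=query_id,
        )
        matrix.write(out / "simbal.tsv")
        (out / "simbal_peak.json").write_text(json.dumps(peak_summary(matrix), indent=1))
        done("simbal", t)

    # ---- genome context
    if config.context:
        t = stage("context")
        enzyme_ids = sorted(family) if family else []
        calls = find_dedicated_systems(genome_set, sorted(hits), enzyme_ids)
        adjacency_frame(calls).to_csv(out / "dedicated.tsv", sep="\t", index=False)
        done("context", t)

    # ---- proteomics (synthetic runs only: needs generated peptides)
    if config.proteomics and truth is not None:
        t = stage("proteomics")
        peptides, _planted = generate_peptides(genome_set, truth)
        proteins = {pid: genome_set.get_protein(pid).sequence for pid in truth.targets}
        maps, skipped = map_peptides(peptides, proteins)
        for m in maps:
            if m.protein_id in hits:
                m.domain_overlap = domain_overlap_check(m, hits[m.protein_id])
        coverage_frame(maps).to_csv(out / "coverage.tsv", sep="\t", index=False)
        manifest["peptides_skipped"] = len(skipped)
        done("proteomics", t)

    # ---- composition
    if config.composition and hits:
        t = stage("composition")
        proteins = {pid: genome_set.get_protein(pid).sequence for pid in hits}
        comp = tm_core_composition(hits, proteins)
        comp.to_frame().to_csv(out / "tm_composition.tsv", sep="\t", index=False)
        cmp_frame = compare_composition(comp, TM_REFERENCE)
        cmp_frame.to_csv(out / "tm_vs_reference.tsv", sep="\t", index=False)
        manifest["composition_G"] = round(cmp_frame.attrs["G"], 3)
        done("composition", t)

    # ---- manifest with output checksums
    for p in sorted(out.iterdir()):
        if p.name != "manifest.json" and p.is_file():
            manifest["outputs"][p.name] = checksum(p)
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return manifest
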