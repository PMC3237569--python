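# rhombosort

Comparative-genomics discovery of C-terminal protein-sorting signals and their
processing proteases, for people who study bacterial protein export and
genome-context-based function prediction.

Certain Proteobacteria sort a subset of exported proteins with a tripartite
C-terminal signal — a Gly-containing signature motif (often `SGGS`), a
hydrophobic transmembrane helix, and a cluster of basic residues at the
extreme C terminus (GlyGly-CTERM; the Cys-containing analogue in Myxococcales
is Myxo-CTERM). The candidate processing enzyme is a rhomboid-protease
subfamily, the rhombosortase. This package implements the full discovery
pipeline that pairs the two:

1. **Signal detection** — heuristic tripartite scan of every protein's
   C-terminal region (hydropathy TM screen, motif and basic-cluster rules,
   signal-peptide and topology checks, iterative profile refinement).
2. **Phylogenetic profiling** — binary YES/NO genome labels from detections
   (with the stricter two-or-more variant that excludes single-hit genomes).
3. **PPP (Partial Phylogenetic Profiling)** — each protein's ranked homolog
   list is walked depth by depth; depth `n` with `k` YES genomes scores
   `S = -log10[C(n,k) p^k (1-p)^(n-k)]`, `p = K/N`, and the best depth is
   reported. Computed in log space; no underflow at any realistic depth.
4. **SIMBAL** — the same maximizer applied to every subsequence window of a
   query protein against its YES/NO-partitioned family, yielding a triangular
   heat map whose peak localizes trait-predictive residues.
5. **Genome context** — dedicated-system calls: genomes with exactly one
   target whose enzyme sits within about one gene of it.
6. **Proteomics coverage** — peptide-to-protein mapping, nested-peptide
   removal, and the does-coverage-ever-touch-the-domain check.
7. **Synthetic pangenomes** — a seeded generator planting signals, cognate
   enzymes with a discriminative near-active-site patch, decoy paralogs and
   adjacency structure, with complete ground truth for every test.

See `docs/methods.md` for the model, heuristics, and generator design.

## Worked example

Run the whole pipeline on a synthetic pangenome (200 genomes, 40 of them
carrying 1-13 planted targets plus one cognate enzyme each):

```sh
$ rhombosort run-all --seed 13 --out run
{"top_family_query": "g0140_p058", "top_family_size": 100}
manifest -> run/manifest.json
```

`g0140_p058` — the protein whose homolog list best matches the trait profile
across all YES genomes — is indeed the planted cognate enzyme of genome
`g0140` (`run/truth.json` lists the ground truth). The SIMBAL stage then scans
that query against its family, split into members from YES vs NO genomes:

```sh
$ cat run/simbal_peak.json
{
 "query_id": "g0140_p058",
 "length": 6, "start": 28, "end": 33, "center": 30.5,
 "score": 3.4645, "n": 19, "k": 19, "depth": 19
}
```

The peak window (residues 28-33, 1-based) overlaps the planted discriminative
patch at residues 31-35: the 19 best-matching family members for that window
all come from YES genomes (`k = n = 19`), which under the partition's YES
fraction has probability `10^-3.46`. `run/dedicated.tsv` lists the adjacency
calls (single-target genomes with the enzyme at gene distance <= 2),
`run/coverage.tsv` the peptide coverage maps (no peptide touches a C-terminal
domain under default generation), and `run/tm_composition.tsv` the Leu/Gly-
skewed TM-core composition against a generic TM reference.

Individual stages are available as subcommands (`simulate`, `scan`,
`profile`, `ppp`, `simbal`, `context`, `proteomics`, `composition`), all
operating on plain FASTA + TSV gene tables, so externally computed inputs
(search results in tabular `outfmt 6`, precomputed signal-peptide calls,
peptide lists) can replace any internal stand-in.

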