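# Methods

## The problem

Some bacterial lineages sort a subset of their exported proteins with a
*tripartite C-terminal signal*: a short Gly-containing signature motif (often
`SGGS`), a hydrophobic transmembrane (TM) helix, and a cluster of basic
residues within a few positions of the C terminus. The GlyGly-CTERM form
(*Shewanella*, *Vibrio* and relatives) never carries Cys in the motif; the
Myxo-CTERM form (Myxococcales) always does. The processing enzyme proposed for
GlyGly-CTERM is a rhomboid-protease subfamily (rhombosortase). This package
implements the comparative-genomics machinery by which such a target/enzyme
pairing is discovered: detect the signal across a pangenome, turn detections
into a binary phylogenetic profile, score every protein of every trait-positive
genome for co-occurrence with the profile (Partial Phylogenetic Profiling,
PPP), localize trait-predictive residues within the best-scoring family
(SIMBAL), and check the gene-neighborhood and proteomics-coverage corollaries.

## Scoring model

A phylogenetic profile assigns each genome a label, YES (1) or NO (0), with
`K` YES among `N` genomes and background rate `p = K/N`. Given a protein's
ranked homolog list, walk it depth by depth, counting each genome once at its
first occurrence. After `n` distinct genomes of which `k` are YES, the
enrichment score is the binomial point surprisal

    S(n, k) = -log10 [ C(n,k) p^k (1-p)^(n-k) ]

and the reported PPP score is `max_n S(n, k(n))` with the earliest depth on
ties (ties are compared with a 1e-9 epsilon, since mathematically exact ties —
e.g. `C(5,1) p (1-p)^4 = (1-p)^4` at `p = 0.2` — land on either side of float
rounding). An upper-tail variant (probability of `k` or more) is provided; in
the strong-enrichment regime where the method's results live (`k` near `n`,
`p` small) it differs from the point form by less than 0.01 log10 units. At
marginal enrichment (`k/n` only a few times `p`) the two forms differ
materially, so the point form is the default and the one all reported numbers
use. Note the point surprisal is not monotone in `k` below the binomial mode;
monotonicity (more agreement, higher score) holds on the enrichment side
`k >= np`, which is the only regime the maximizer visits for real signals.
Everything is computed in log space (`scipy.special.gammaln`, `logsumexp`);
depths of 10^4 pose no difficulty.

SIMBAL applies the same maximizer to every subsequence window of one query
(lengths 6 up to full length, every start), ranking a YES/NO-partitioned,
redundancy-reduced family by best local-alignment score of window versus
member. Sequences, not genomes, are the counting unit there, because the
partition is a sequence set after redundancy reduction; `p` is the YES
fraction of the partition.

## Detection heuristics

External topology predictors are deliberately not dependencies; the screens
they provided are explicit, documented heuristics with import hooks for
precomputed calls:

- **TM segments**: Kyte-Doolittle hydropathy, window 19, threshold 1.6; a
  segment is a maximal union of qualifying windows at least 15 residues long.
  Comparisons carry a 1e-9 epsilon because scale values have one decimal and
  summation order can flip an exact-threshold window.
- **Tripartite scan**: within the last 35 residues, enumerate TM placements
  (length >= 15, mean hydropathy >= 1.6, tail after the TM <= 5 residues
  containing >= 1 Lys/Arg); the motif is the window prefix before the TM and
  must contain a Gly (optionally two consecutive). The highest-scoring
  placement wins (Gly-run + TM hydropathy + basic count), ties toward the most
  C-terminal TM. Class: Cys in motif = Myxo-type, else GlyGly-type.
- **Signal peptide**: n-region (Lys/Arg in the first five residues), h-region
  (seven consecutive hydrophobics), c-region (Ala/Gly/Ser at -1 and -3 of a
  cleavage site between positions 15 and 40).
- **Iterative refinement**: a pseudocount-smoothed log-odds profile over the
  seeds' C-terminal windows, rescanning the genome and admitting windows that
  score at least 0.3x the lowest seed self-score *and* pass the structural
  scan; iterated to a fixed point (cap 10). The 0.3 default sits between the
  background score distribution (max ~8 on generator background sequences)
  and the score range of genuinely divergent true instances (~10-25), so
  recovery does not depend on near-identity to the seeds; the structural rules
  are the second gate.

## Internal homolog ranking

Real database searching is out of scope; the ranker is a deterministic
stand-in. Similarity is the Smith-Waterman score under BLOSUM62 with gap
open/extend 11/1. On large databases an exact shared-4-mer prefilter
(scipy.sparse product) selects up to 400 candidate subjects per query before
alignment; with the default score floor this matches the exhaustive ranking
for everything that can clear the floor, and the prefilter can be disabled.
The floor default (150 raw score) is calibrated to full-length family
homology: it is far above chance local matches *and* above the ~100-point
chains that unrelated proteins sharing only the short sorting signal (motif +
TM + basic cluster) can produce, so hit lists reflect protein families rather
than the 25-residue signal itself. Percent identity for redundancy reduction
is computed from a global alignment with free end gaps, identities divided by
aligned columns excluding terminal overhang; the argument pair is sorted
before aligning so co-optimal-alignment tie-breaks cannot break symmetry.
Redundancy reduction is greedy longest-first (ties by id).

## The synthetic pangenome

The generator defines the package's standard study conditions (desk scale,
chosen once):

| parameter | default | rationale |
|---|---|---|
| genomes | 200 (40 YES) | minority-trait profile, p = 0.2 |
| genes per genome | 60, one replicon | enough slots for adjacency structure |
| targets per YES genome | uniform 1-13 | observed per-genome copy range |
| target signal | `SGGS` + 18-mer TM + `RRK` + 0-2 tail | canonical tripartite layout |
| TM composition | Leu 40%, Ala/Gly 10%, Phe/Ile/Val 9%... | Leu/Gly-skewed sorting-signal TM |
| enzyme family | 60-aa scaffold, 1 cognate per YES genome, 1 decoy paralog per genome | every genome carries non-cognate family members |
| discriminative patch | `SGMLH` (cognate) vs `YGMLF` (decoy) at 30 | near-active-site window; Ser/His vs Tyr/Phe swap |
| mutation rate | 0.15 per site on enzyme scaffolds | family identity ~74%, below the 80% redundancy cut |
| adjacency | single-target YES genomes place the cognate within 2 genes; decoys kept outside that window | dedicated-system ground truth is exact |

Planted regions (motif, TM, basic cluster, patch) take no substitutions and no
indels, keeping truth coordinates exact. Target bodies and decoys draw from a
hydrophilic-leaning background (Cys-free in target bodies, so the detected
motif region is unambiguous GlyGly-type). Labels are assigned independently:
the sporadic taxonomic distribution is emulated without phylogenetic
correlation between genomes, so tree-aware corrections are untestable here by
design. One `numpy.random.Generator` drives a run; equal seeds give
byte-identical FASTA/TSV output.

In-silico proteomics digests target proteins with trypsin rules (cut after
Lys/Arg, not before Pro), samples 60% of peptides of length 6-35, and by
default excludes anything overlapping the C-terminal search region — the
coverage pattern a processed C terminus would produce. `include_cterm=True`
inverts that for negative-control tests.

What passing tests on this generator do *not* show: performance on real
proteomes with shared domain architectures, fragmentary gene calls,
phylogenetically correlated presence/absence, or curation-grade motif
boundaries. The census-style quantities of the original study (genome counts,
the 34% Leu TM core, specific peak scores on real proteins) require the real
proteome collection and are out of reach by construction; the package instead
verifies the machinery's behavior against planted ground truth.

## Problem sizes used in the checks

PPP parameter recovery runs the full standard pangenome (12,000 proteins,
~2,400 queries). SIMBAL parameter recovery uses 20 seeded replicates, each a
fresh pangenome, scanning one 60-residue cognate (1,540 windows) against its
~200-member partition, paired with a patch-collapsed rerun of the same seeds.
The enzyme length of 60 keeps a full triangular scan cheap while leaving the
patch a small fraction of the sequence; peak localization is not easier at
this length than at full protease length, since the number of competing
windows per length is unchanged around the patch.

## Numerical and degenerate-input conventions

- Intervals are 0-based half-open internally, 1-based inclusive in every file.
- An empty ranked list scores 0 at depth 0; genomes excluded by the
  two-or-more profile variant are skipped during walks.
- `reduce_redundancy` visits sequences longest-first with id tie-break, so
  output is order-independent.
- SIMBAL cell ties: ranked members by (score desc, id asc); peak ties by
  (score desc, shortest length, leftmost start).
- Nested-peptide removal keeps both partial overlaps, drops strict
  containment, collapses duplicates to one copy; it is idempotent.
- The TM-composition reference table quotes only the three published leading
  values (Leu 17%, Val 12%, Ile 12%) and spreads the remainder uniformly; it
  is comparison plumbing, not measured data.
- `find_dedicated_systems` ignores strand and uses gene-index distance;
  "no more than one gene apart" is `|Δ| <= 2` by default with a strict
  `max_gap=1` option.

## Known limitations

- The per-hit detector score is an artifact convention (the original work used
  curation judgment, not a numeric threshold).
- The local aligner is one fixed scheme, not a tuned search engine; E-values
  are out of scope, so ranked-list truncation is by raw score and list length.
- `pairwise_identity` reports the tie-broken optimal alignment's identity, not
  the maximum over all co-optimal alignments.
- The generator's enzyme family is a single scaffold; real rhomboid diversity
  (multiple subfamilies, variable architecture) is not modeled.
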