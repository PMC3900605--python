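# phagekit

Comparative genomics and growth-kinetics toolkit for large, modular tailed
phages (Spounavirinae-like myoviruses). It implements, as a tested and
reusable pipeline, the chain of analyses used to place a newly isolated
phage into a genome-based group:

- **Genome structure** — detect a collapsed long terminal repeat (LTR) from
  per-position read coverage of a circularized assembly (a linear genome
  with identical terminal repeats assembles into a circle in which the
  repeat carries ~2× depth), find flanking tandem repeats, and linearize,
  with the length accounting `total = unique + LTR`.
- **Consensus annotation** — vote CDS calls across several gene-predictor
  tracks grouped by (strand, stop codon); compute GC%, strand counts,
  start/stop-codon usage, and CDS density.
- **Whole-genome similarity** — a seed-and-extend ungapped local alignment
  engine with Karlin–Altschul statistics (`E = K·m·n·e^{−λS}`,
  `P = 1 − e^{−E}`), used in two ways: fragmented translated comparison
  (genomes tiled into 50 bp fragments scored in all 6×6 reading-frame
  pairs under BLOSUM62, normalized by fragment self-score — an asymmetric
  percent-similarity matrix) and nucleotide comparison (word size 7,
  +1/−2) for the similarity network.
- **Network clustering** — edges weighted by HSP P-values
  (attraction = min(1, −log₁₀ p / 200)), Fruchterman–Reingold layout, and
  groups as connected components at a P-value cutoff.
- **Phylogenomics** — neighbor joining on distances
  `d(A,B) = 100 − (sim_{AB} + sim_{BA})/2`, patristic distance matrices,
  and a separation statistic: two groups are *separated* when their mean
  between-group patristic distance exceeds the largest within-group
  distance of either.
- **Tree congruence** — maximum agreement subtree (MAST) size by a
  directed-edge dynamic program, and the congruence index
  `I_cong = MAST / E[MAST under random trees]` with a seedable Monte-Carlo
  (PDA) null and permutation p-value.
- **Growth kinetics** — adsorption rate constant
  `k_t = (2.303 / B·t) · log₁₀(P₀/P_t)` from titre decay, and eclipse/latent
  periods plus burst size (plateau / infective centres) from one-step
  growth curves.

A first-class synthetic-data module generates every input the pipeline
consumes — modular genome communities with conserved core synteny, collapsed
assemblies with shotgun coverage, marker protein families evolved on a known
tree, predictor tracks with per-tool error rates, and noisy titre series —
so the whole chain is testable without downloads.

## Worked example

Detect a collapsed terminal repeat on a simulated 150 kb assembly whose
generating repeat is 2669 bp (400 nt reads, ~50× depth):

```bash
$ phagekit structure --coverage coverage.tsv --fasta assembly.fasta --out structure/
LTR 147295..2565 (2602 bp, 1.97x); total genome 149933 bp
```

The detected segment wraps the circular origin, its length recovers the
generating 2669 bp within a fraction of a read length, the plateau depth is
1.97× the background (the expectation for a collapsed duplication is 2×),
and the linearized genome length is `unique + LTR`.

One-step growth analysis on a simulated experiment (burst 153, latent
35 min, samples every 10 min, 4 replicates, 10% lognormal noise):

```bash
$ phagekit simulate-kinetics --kind one_step --seed 11 --out titers.tsv
$ phagekit kinetics --titers titers.tsv
{
  "burst": 154.41480643769515,
  "latent_min": 40.0,
  "eclipse_min": 30.0,
  "censored": false
}
```

The burst estimate lands within 1% of the generating value; latent and
eclipse periods are resolved to the 10-minute sampling grid.

Full pipeline on a synthetic community (3 groups × 4 genomes plus an
unrelated outgroup):

```bash
$ phagekit run-all --seed 7 --markers 2 --out out/
```

The summary reports the three groups recovered exactly as network clusters
(`cluster0..cluster2`), the outgroup as a distant singleton, every group
monophyletic on the NJ tree, and all between-group separation flags true —
the qualitative signature by which a coherent new phage group is argued.
Stage outputs (similarity/distance matrices as TSV and PHYLIP, graph edge
list, layout coordinates, Newick trees, patristic matrix, separation and
congruence JSON, provenance log) land in `out/`.

Each stage is also exposed separately (`simulate`, `structure`, `annotate`,
`similarity`, `cluster`, `tree`, `congruence`, `kinetics`), and everything
is importable as a library (`phagekit.similarity.fragmented_similarity`,
`phagekit.trees.nj_tree`, ...).

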