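# agioskit

Genome relatedness for bacterial taxonomy, computed as the **mean
Needleman–Wunsch nucleotide identity over orthologous genes**: for each
genome pair, an exact all-vs-all Smith–Waterman protein search finds
homologs, strict 1:1 reciprocal-best-hit (RBH) pairing selects orthologs,
and each ortholog pair's CDS sequences are globally aligned; the pair
statistic is the unweighted mean of the per-pair percent identities.
Multi-genome runs produce a square matrix: diagonal = gene counts, upper
triangle = shared ortholog counts, lower triangle = mean identities.

Also included:

- **ORFan classification** — a gene is an ORFan iff no homology hit clears
  the two-tier significance rule (E < 1e-03 for alignments > 80 aa,
  E < 1e-05 otherwise), using internal searches or externally produced
  12-column hit tables.
- **Genome statistics** — assembly size, G+C over unambiguous bases,
  coding density (union of CDS intervals), COG-category summaries from a
  user-supplied assignment table.
- **16S species delineation** — global-alignment identity against the
  98.7% threshold (strictly below ⇒ candidate new species).
- **Simulator** — star-phylogeny descendants of a shared ancestor gene
  pool with exact closed-form expected divergence, optional codon indels,
  gene loss/gain, and full ground truth for validating the pipeline.

## CLI

```sh
# simulate two descendants at 10% expected per-site divergence
agioskit simulate --n-genes 200 --p-sub 0.1 --seed 42 --out sim/

# compare all genomes in a directory of paired <name>.fna/<name>.faa files
agioskit compare --genomes sim/ --out matrix.tsv --report report.json

# genome summary statistics
agioskit stats --assembly genome.fna --genes genes.tsv --cogs cogs.tsv \
    --out stats.json

# ORFans against a reference gene set (or a precomputed --hits table)
agioskit orfans --cds a.fna --proteins a.faa \
    --reference-cds b.fna --reference-proteins b.faa --out orfans.json

# 16S identity + species-delineation verdict
agioskit delineate --query q16S.fna --reference r16S.fna
```

Key defaults (all configurable): nucleotide alignment match +5 / mismatch
−4, gap open 10 / extend 0.5 (EMBOSS-needle convention; a gap of length L
costs `open + (L−1)·extend`); protein search BLOSUM62, gap 11/1, with
Karlin–Altschul λ = 0.267, K = 0.041; RBH filters identity ≥ 25%, coverage
≥ 50% on both sequences, search keep-threshold E ≤ 1e-05. Percent identity
divides by **all** alignment columns including terminal gaps; pass
`--identity-denominator aligned` to divide by gap-free columns instead.

## Library layout

| module | contents |
| --- | --- |
| `agioskit.seqio` | FASTA/gene-set/assembly I/O, hit tables, matrix TSV |
| `agioskit.pairwise` | affine-gap global/local alignment, E-values |
| `agioskit.orthology` | all-vs-all search, RBH pairing, ORFan calling |
| `agioskit.agios` | pair comparison, matrix assembly, range reports |
| `agioskit.genome_stats` | size/G+C/coding density, 16S delineation, COGs |
| `agioskit.simulate` | ancestor-pool simulator with ground truth |
| `agioskit.cli` | `agioskit` command-line entry points |
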