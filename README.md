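# mitoforge

Structural and post-transcriptional analysis of multipartite circular
organelle genomes, built as a tested, reusable pipeline:

- **genome model** — circular chromosomes, 1-based wrap-aware coordinate
  arithmetic, base-composition statistics;
- **repeat scan** — dispersed direct/inverted repeat pairs (seed-and-extend,
  length/identity thresholds), microsatellites with MISA-style class minima
  (`1-10 2-6 3-5 4-5 5-5 6-5`), and a simplified tandem-repeat detector;
- **recombination** — enumeration of repeat-mediated recombination products
  (split / fusion / inversion), 500 bp flank junction references, long-read
  junction-spanning classification (Myers bit-vector edit distance), and
  major/minor configuration abundance estimation;
- **RNA editing** — C→U editing-site calling from RNA pileups (coverage ≥ 5,
  frequency ≥ 0.1) with DNA-based SNP masking and codon-consequence
  annotation, including start-codon (ACG→AUG) and stop-codon
  (UAA/UAG/UGA) acquisition;
- **organelle homology** — mito↔plastid / mito↔nuclear homologous segments
  (≥ 100 bp filter) with transfer summaries and per-gene transfer status;
- **synthetic data** — deterministic generators for multipartite genomes
  with planted repeats/SSRs/genes, configuration-mixture long reads, and
  RNA/DNA pileups with planted editing sites and SNPs, all with truth tables.

## Test

```sh
python -m pytest -q tests/
```

The suite includes brute-force oracle checks (maximal exact repeats, SSR
enumeration, edit-distance DP), planted-truth round trips, and
`tests/test_acceptance.py` with one test per acceptance criterion.  One test
is skipped unless `MITOFORGE_ACCESSION_FASTA` points to a local FASTA of the
two deposited mitochondrial chromosome sequences (a network download).

## CLI

```sh
mitoforge composition --genome genome.fasta
mitoforge repeats     --genome genome.fasta --min-length 1000 --min-identity 99
mitoforge ssr         --genome genome.fasta --misa-thresholds "1-10 2-6 3-5 4-5 5-5 6-5"
mitoforge tandem      --genome genome.fasta --min-total 14
mitoforge recomb      --genome genome.fasta --repeats repeats.tsv \
                      --reads reads.fastq --flank 500 --min-anchor 100
mitoforge edit        --genome genome.fasta --gff genes.gff3 \
                      --rna rna.sam --dna dna.sam --min-cov 5 --min-freq 0.1
mitoforge transfer    --mito mito.fasta --other plastome.fasta --preset mtpt
mitoforge simulate genome|longreads|editing --spec spec.yaml --seed 7
```

All stages log their parameters and seeds to stderr; rerunning with the same
seed reproduces outputs byte-identically.  FASTA records are circular by
default (add a `topology=linear` header token to override).  Inverted repeat
units in the repeats TSV are written with start > end, denoting the
minus-strand unit occupying `[end, start]` on the plus strand.

## Notes on scope

Genome assembly, read QC, gene annotation, phylogenetics, PCR primer
design, and figure drawing are out of scope.  The tandem-repeat detector is
deliberately simplified (period self-match with a mismatch budget), not a
reimplementation of the Tandem Repeats Finder scoring model.  Repeat
detection reports ungapped locally maximal alignments; E-values are not
computed — filtering is by length and identity.
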