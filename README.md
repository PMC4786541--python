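# distamo

Distribution analysis of short DNA motifs on bacterial chromosomes, using
codon redundancy as the null model.

## The problem

Short DNA motifs — Dam-methylated GATC sites, FtsK-orienting KOPS
(`GGGNAGGG`), and many others — are bound by chromosome-maintenance proteins,
and their placement along a bacterial chromosome is often under selection.
Deciding whether a motif is over- or under-represented in a gene or region
requires a null model, and nucleotide-composition (Markov-chain) nulls
conflate coding and non-coding constraints. This package scores motif
abundance **inside protein-coding regions only**, against the freedom the
genetic code actually leaves: a position where the encoded amino acids
*could* spell the motif through synonymous codon choice is a **potential
motif**, and the question becomes how often that potential is realized.

It is aimed at microbial genomics work: scoring single genes, functional
gene sets (e.g. COG groups supplied as locus-tag lists), sliding windows
around the chromosome, and chromosome-scale biases (leading/lagging strand,
coding/template strand, ori/ter halves, replichores, gene subsets).

## The model

For a motif of length *l* starting at offset *p* ∈ {0, 1, 2} within a codon,
the motif spans ⌈(*p* + *l*)/3⌉ consecutive codons. For each such window with
peptide *pep*, the realization probability is estimated from genome-wide
in-frame codon *n*-gram frequencies *f*:

    P_mot(pep) = Σ f(cod_mot | pep) / Σ f(cod | pep)

summing in the numerator over codon strings that encode *pep* **and**
contain the motif at that offset, and in the denominator over all codon
strings encoding *pep*. Assuming independence of potential motifs, the
motif count of a gene (or any merged set of windows) follows a
Poisson-binomial distribution with

    m̄ = Σ P_mot(pep)        s = sqrt( Σ P_mot(pep) (1 − P_mot(pep)) )

and the observed count *m* is reported as the z-score
*z* = (*m* − m̄)/*s*, with |z| ≥ 2 the conventional significance threshold.
Chromosome-scale biases compare per-gene z-scores between two gene classes;
the observed mean difference is standardized against a Monte-Carlo null
(10,000 label/orientation randomizations by default).

A useful identity: when the frequency table is built from exactly the gene
set being scored, the set-wide expectation telescopes to the observed count,
so whole-genome z-scores are ~0 by construction — enrichment is always
*relative*, visible per gene, per subset, or per window.

## Worked example

Generate a 20-gene synthetic replicon in which every gene carries exactly
12 potential GATC windows, 9 of them realized, then scan it:

```
$ distamo simulate --length 900 --motif GATC --n-potential 12 --n-real 9 \
      --n-genes 20 --seed 11 --out sim
wrote sim/genome.fasta (20 genes)

$ distamo scan --fasta sim/genome.fasta --gff sim/genome.gff \
      --motif GATC --ori 0 --out scan
{
  "replicon": "synth_replicon",
  "length": 18690,
  "motif": "GATC",
  "genes_retained": 20,
  "genes_excluded": 0,
  "genes_significant_coding": 0
}

$ head -4 scan/genes.tsv | cut -f1,8-13
gene_id  half  n_windows_coding  m_coding  m_bar_coding  s_coding  z_coding
sim000   ori   12                9         8.982         1.47219   0.0122279
sim001   ori   12                9         8.85703       1.48726   0.0961333
sim002   ori   12                9         9.31108       1.41303   -0.220153
```

Every gene realizes 9 of its 12 potential windows, and because the codon
frequencies are estimated from this same genome the expectation m̄ ≈ 9:
uniform enrichment is absorbed into the null, so no gene stands out
(`genes_significant_coding: 0`). Bias tests on the same files:

```
$ distamo bias --fasta sim/genome.fasta --gff sim/genome.gff --motif GATC \
      --ori 0 --tests ori_ter,replichore --replicates 10000 --seed 3 --out bias
bias_kind   observed    null_mean     null_sd    z_bias     n_replicates  n_genes
ori_ter     -0.0731245  -0.000311835  0.0854433  -0.852176  10000         20
replichore   0.0126399   0.000614355  0.0845068   0.142302  10000         20
```

Neither chromosome half nor replichore deviates (|z_bias| < 2), as expected
for a uniformly planted motif. `distamo profile` renders the z-scores as
circular sliding-window rings (50–500 kb in 50 kb steps on real
chromosomes, red ≥ +2 / blue ≤ −2), and `distamo average` maps per-gene
z-scores of several genomes onto a 1000-bin ori-anchored scaled axis with
SEM bands. The same operations are available as library functions
(`distamo.genome_scan`, `distamo.bias_test`, `distamo.kmer_sweep`,
`distamo.sliding_window_rings`, `distamo.scale_and_average`,
`distamo.synthetic.*`).

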