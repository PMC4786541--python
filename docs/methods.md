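# Methods

## Model

The unit of analysis is the protein-coding gene. A **potential motif** is a
pair (position, in-codon offset *p* ∈ {0,1,2}) in a coding sequence where
the encoded amino-acid window admits the DNA motif through synonymous codon
choice; a motif of length *l* at offset *p* spans ⌈(*p*+*l*)/3⌉ codons, so
the set of possible spans is {⌊l/3⌋, ⌊l/3⌋+1} for l ≡ 0 (mod 3),
{⌊l/3⌋+1} for l ≡ 1, and {⌊l/3⌋+1, ⌊l/3⌋+2} for l ≡ 2.

The realization probability of a window with peptide *pep* is the ratio of
genome-wide in-frame codon *n*-gram counts: codings of *pep* containing the
motif at that offset over all codings of *pep*. Counts are accumulated over
consecutive in-frame codons within single CDSs, never across gene
boundaries, with the trailing stop codon trimmed. No smoothing or
pseudocounts are applied: a window whose peptide *n*-gram is unobserved has
no defined probability and is excluded from both the expectation and the
observed count; a window whose peptide was observed but never with the
motif has P = 0 and is by definition not a potential motif. Degenerate
IUPAC motifs are handled as the union of their concrete expansions (a
coding "contains the motif" if any expansion matches; no double counting
within one window).

Treating window realizations as independent Bernoulli trials, the motif
count is Poisson-binomial with mean m̄ = ΣP and standard deviation
s = sqrt(ΣP(1−P)); genes, gene sets and chromosomal windows are scored as
z = (m − m̄)/s, merging probability lists (and summing m) for sets. The
additive sufficient statistics (ΣP, ΣP(1−P), m) make window/ring merging
exact without re-enumeration.

Strand semantics: the template-strand profile of a motif is the
coding-strand profile of its reverse complement; a gene's leading-strand
profile is its coding profile if the gene lies on the leading strand of its
replichore and its template profile otherwise. Palindromic motifs therefore
carry no strand information (coding ≡ template).

### Self-calibration identity

When the frequency table is estimated from exactly the gene set being
scored, Σ P over all windows of a motif equals the number of realized
motifs in the set: each peptide window's denominator is the number of
occurrences of that peptide and its numerator the number of motif-bearing
occurrences, so the ratio summed over occurrences telescopes. Whole-set
z-scores against a self-table are thus ≡ 0 (asserted as a property test).
This is a feature, not a defect: enrichment is always relative to the
genome-wide codon usage, and signal lives in per-gene, per-subset and
per-window contrasts.

## Bias tests

Five chromosome-scale biases are standardized by Monte-Carlo randomization
(default 10,000 replicates, seeded, gene as the randomization unit):

- **leading/lagging** and **coding/template**: per-gene difference of the
  two strand z-scores (leading/lagging picks the pair per the gene's
  replication context); observed statistic is the mean difference, the null
  flips each gene's orientation independently (sign flip of its
  difference).
- **ori/ter** and **replichore**: difference of class means of the chosen
  strand-mode z; the null shuffles class labels at fixed class sizes. The
  spec left open whether positions or labels are randomized; label
  randomization is used (equivalent under exchangeability, cheaper, and the
  natural reading of "randomized orientations ... of genes" extended to the
  positional tests).
- **subset**: mean z of the subset minus the genome-wide mean; the null
  resamples size-matched gene sets without replacement.

Genes with a missing z in a required quantity are dropped (complete-case);
classes with fewer than two usable genes refuse with an error. Sign
convention: positive observed = first-named class (leading, coding, ori,
left, subset) enriched. Antisymmetry under class-label swap is exact for
the strand biases at fixed seed. Under label randomization the bias z is
approximately standard normal (tested: mean within ±0.1, variance within
0.8–1.2 over 500 permuted fixtures).

## Replication context

Coordinates are 0-based half-open; GFF3 input is converted on read. The
terminus defaults to the point diametrically opposite the origin when not
supplied (configurable — the dif site is not inferred). The *right*
replichore is the arc ori→ter in ascending circular coordinates; a gene is
*leading* iff (right, +) or (left, −); the *ori half* contains genes whose
midpoint is circularly closer to ori than to ter, with exact ties assigned
to ori (deterministic tie-break). Gene membership everywhere is by circular
midpoint, so genes straddling the sequence start are handled by modular
arithmetic. Context operations require a circular replicon with an origin
and refuse otherwise.

## Profiles

Sliding-window rings use window sizes 50–500 kb in 50 kb steps by default
(ten rings), step = window/10, circular wrap-around, window membership by
gene midpoint (each gene in exactly one window per ring position). Scaled
averaging maps genes to ⌊1000 · circular-distance-from-ori / L⌋ bins (ori
at bin 0/1000); bins average gene z within a genome, then mean and SEM are
taken **across genomes** (SEM 0 for a single genome); no smoothing beyond
the binning is applied. Anchoring at ori makes profiles invariant to the
arbitrary coordinate start. Ring plots use a diverging map saturating red
at z ≥ +2 and blue at z ≤ −2 (threshold configurable).

## Synthetic data

The generator reproduces the randomized-sequence study conditions:
3000 bp coding sequences with exact counts of potential windows
(`n_potential`) and realized motifs (`n_real`) by default. "Potential" at
generation time is combinatorial (some synonymous re-encoding spells the
motif), independent of any table. Construction draws a random peptide
(uniform amino acids, ATG start) and codons (uniform synonymous by default,
optionally table-driven), plants non-overlapping motif-admitting peptide
windows separated by at least one codon — chosen so the planted range hosts
exactly one potential position, realized or not as required — and repairs
accidental potential windows by local amino-acid substitution until an
audit matches the targets exactly; infeasible targets fail explicitly after
bounded attempts. Everything is deterministic per seed.

`resample_genome_like` builds whole FASTA+GFF3 genomes whose per-gene
(potential, realized) counts match a reference table; `leading_bias_genome`
plants enrichment only into leading-strand genes of a balanced circular
fixture; `random_codon_corpus` bulk-generates plain random genes for
genome-scale frequency tables; `codon_resample_null` re-draws a gene's
codons from the table's synonymous-codon frequencies to sample its null z
distribution; `coupling_experiment` and `interdependence_experiment`
implement the motif-interference studies (the latter pairs per-gene
z-scores, per the self-calibration identity above, enriching a quarter of
the genes by about three per-gene standard deviations as a biological
enrichment level).

What the generator does **not** emulate: intergenic DNA and operon
structure, GC skew and strand-compositional asymmetry, amino-acid
composition of real proteomes, and biological co-occurrence of motifs.
Passing tests therefore demonstrate the statistical machinery under the
stated model, not the biology of any particular genome.

## Numerical choices and problem sizes

- z with s = 0: 0 when m = m̄, signed infinity otherwise (an explicit
  undefined-extreme marker); genes with no usable window report z as
  missing, never 0.
- Monte-Carlo moments use the population standard deviation over
  replicates; bias z-scores are exact functions of the seed.
- P_mot lookups are cached per (peptide, offset, motif) on the table; the
  genome scan uses a peptide *k*-gram index so each distinct window peptide
  is evaluated once (linear-time indexed search, verified identical to a
  naive per-position scan). The k-mer sweep enumerates each distinct
  (peptide, offset) once for all 4^k motifs simultaneously.
- Test and acceptance problem sizes: fixture genomes of 16–30 genes
  (~900 bp), a 150-gene oracle pool, a 2000-gene (600k codon) corpus for
  null calibration, 4 enriched + 4 control interdependence genomes of 20
  genes, 100 shuffled-label runs at 1000 replicates, 10,000 replicates for
  the headline bias test.

## Limitations

- The no-smoothing estimator truncates rare windows: peptides never
  observed with the motif get P = 0 and drop out, which biases resampled
  gene z-scores slightly negative when the frequency table is built from a
  small corpus (measured ≈ −0.15 at 45k codons, vanishing by ~600k codons).
  Tables should be estimated from genome-scale coding sets, which real
  bacterial chromosomes provide.
- Window independence is assumed; overlapping potential windows share
  codons, so extreme enrichment of one motif perturbs overlapping
  (positively) and site-sharing (negatively) motifs — quantified by the
  coupling experiment; at biological enrichment levels the effect on other
  motifs' significance rates is within Monte-Carlo error.
- Alternative start codons are kept as literal DNA (they host motifs) but
  translated as Met, so windows covering a non-ATG start use the Met coding
  family for their probability; the discrepancy affects only first-codon
  windows.
- Eukaryotic gene models (splicing), automatic ori detection and
  Markov-chain nulls are out of scope.
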