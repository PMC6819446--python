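# Methods

## Scope and model

`epiamplicon` analyses targeted bisulfite amplicon sequencing at
single-molecule resolution. The object of study is a short PCR amplicon on
the top strand of a locus (typically a promoter), with CpG cytosines as
readout positions. Bisulfite converts unmethylated cytosine to uracil
(sequenced as T) while 5-methylcytosine (5mC) and
5-hydroxymethylcytosine (5hmC) resist conversion and read as C; oxidative
bisulfite (oxBS) first oxidises 5hmC so that it, too, converts. One merged
read pair is one molecule, and its per-CpG binary call vector is its
epiallele.

Assumptions baked into the pipeline:

- **Directional, top-strand libraries.** The bisulfite primers are
  strand-specific, so all reads present the same converted top-strand
  sequence; no bottom-strand or non-directional logic exists.
- **Fixed-length amplicons, ungapped matching.** Reads are anchored at the
  amplicon 5′ end (offset 0 after primer matching). Indel-containing reads
  fail the identity filter and are dropped rather than gap-aligned,
  because a gap would shift every downstream CpG index.
- **Conversion events are independent across positions.** This is what
  lets the per-read conversion filter be modelled by a binomial closed
  form and the per-site means by binomial standard errors.

## Coordinates

Internally all positions are 0-based indices into the amplicon reference.
User-facing CpG labels are TSS-relative with the TSS base at +1 and no
position 0 (…, −2, −1, +1, +2, …), the convention of promoter bisulfite
maps. When an amplicon has no meaningful TSS (e.g. a spike-in control),
labels are 1-based amplicon-local positions.

## Read processing

1. **Merging.** For each pair, R1 is compared with the reverse complement
   of R2 at every ungapped overlap; the overlap maximising the raw match
   count wins. Pairs whose best overlap is < 40 nt (`min_overlap`) or
   whose overlap identity is < 0.9 are rejected and counted. Disagreeing
   overlap bases are resolved to the higher-quality base, ties to R1.
   Match-count maximisation mildly favours long overlaps on repetitive
   sequence; amplicons with internal periodicity should be checked for
   spurious self-overlap (none of the shipped synthetic constructs are
   periodic).
2. **Assignment.** The forward primer (IUPAC-degenerate: Y matches C/T, R
   matches A/G — degenerate letters sit where the original strand had C/G)
   must match the read 5′ end with ≤ 2 mismatches; among matching
   amplicons the highest full-length identity against the fully converted
   reference (non-CpG C → T, CpG C → Y) wins, with identity < 0.8 left
   unassigned and exact ties going to the lexicographically smallest
   amplicon name.
3. **Calling.** At each CpG cytosine: C → 1, T → 0, anything else (or an
   uncovered site) → ambiguous. Non-CpG reference-C positions score the
   read's own conversion efficiency; primer footprints are excluded from
   conversion and identity statistics because those bases derive from the
   primer oligo, not the molecule (CpG calls inside a primer footprint are
   still reported, and on real data should be interpreted with that
   caveat).
4. **Filtering.** Defaults: per-read conversion ≥ 0.98 (undefined — no
   non-CpG C covered — passes), identity ≥ 0.8, zero ambiguous CpG calls.
   These cut-offs are package defaults exposed in the API and CLI, chosen
   to sit well above typical conversion chemistry (≥ 0.99) while not
   discarding reads for single-base noise. A read failing several checks
   is counted once, in the order conversion → identity → ambiguity, so
   reason counts always sum to the number of failed reads.
5. **Spike-in.** A fully unmethylated control amplicon estimates
   sample-level conversion pooled over *all* of its cytosines (CpG
   included — the control has no true methylation). Zero covered
   cytosines yields an undefined estimate with a warning, never 0 or 1.

## Epiallele statistics

- **Tables.** All 2^n patterns are materialised as columns (zero-filled)
  so downstream consumers see a fixed pattern space. Molecules with any
  ambiguous CpG call are excluded from the table (a pattern is a
  whole-molecule object) but still contribute their unambiguous sites to
  per-CpG means.
- **Rarefaction.** Per-sample multivariate hypergeometric subsampling
  (without replacement) to a common depth, defaulting to the smallest
  sample total; seeded and reproducible. Rarefaction never introduces a
  pattern absent from the source sample.
- **Summaries.** Site mean = methylated/(methylated+unmethylated), in
  percent; zero-coverage sites are reported as missing, never 0. The
  amplicon mean is the *unweighted* mean over site means, and group
  summaries report mean ± SEM across replicate samples.
- **PCA.** Counts → proportions → column centering → SVD. Proportions make
  the ordination depth-invariant by construction; unit-variance scaling is
  off by default so that abundant epialleles carry their quantitative
  weight in the biplot (a `scale=True` switch gives correlation-style PCA).
  Sign convention: each component is oriented so its largest-magnitude
  loading is positive, which fixes the SVD sign ambiguity across BLAS
  builds. Zero-variance input is returned flagged (`degenerate=True`) with
  all explained-variance fractions zero rather than raising.
- **HCA.** Average-linkage clustering on Euclidean distances between
  proportion vectors via `scipy.cluster.hierarchy`, with Newick export.
  Metric and linkage are arguments; the defaults are declared package
  defaults, not a claim about any particular historical analysis.

## 5hmC estimation

Per CpG, the 5hmC estimate is the difference of apparent methylation
between matched BS and oxBS arms. Each arm is first summarised per sample;
per-site means are then averaged across replicates and subtracted, and the
standard error is the quadrature sum of the two arm SEs (replicate SEM
when ≥ 2 samples per arm, else the binomial SE from that arm's coverage).
The raw difference can be negative by sampling noise or arm imbalance;
both the raw and the zero-clamped value are always reported, because
silently clamping would hide exactly the QC signal a negative value
carries. Sites covered in only one arm are undefined (NaN). The method is
population-level only — it cannot produce single-molecule 5hmC epialleles,
since BS and oxBS reads come from different molecules.

## Synthetic data generator

The generator emulates the study design the pipeline targets: mixtures of
cell subpopulations with distinct epiallele compositions sequenced to
~10^4–10^5 molecules per sample on a 281 × 2-cycle paired-end run, with an
unmethylated spike-in for conversion control. Populations are specified
either by per-site (C, 5mC, 5hmC) probabilities (sites independent) or by
an explicit epiallele distribution (arbitrary between-site correlation).

Defaults, chosen once as realistic operating conditions:

| parameter | default | meaning |
|---|---|---|
| `n_molecules` | 10 000 | molecules (read pairs) per sample |
| `conversion_rate` | 0.995 | P(unmethylated C reads T); typical of fresh bisulfite chemistry |
| `mc_failure_rate` | 0.005 | P(5mC reads T) |
| `oxbs_hmc_conversion` | 0.95 | P(5hmC reads T under oxBS); oxidation is not quite complete in practice |
| `seq_error_rate` | 0.001 | per-base substitution rate, MiSeq-class |
| `read_len` | 281 | cycles per mate |

Reads are exact windows of the molecule (R1 = 5′ window, R2 = reverse
complement of the 3′ window, overlap = 2·read_len − amplicon length), with
uniform substitution errors, no indels, and constant Q40 qualities
independent of error. What the generator deliberately does **not**
emulate: PCR amplification bias and chimeras, bisulfite-induced
fragmentation, coverage non-uniformity, quality-correlated errors, and
adapter read-through. Passing recovery tests therefore demonstrates the
correctness of the calling and statistics under the stated chemistry
model, not robustness to those instrument artefacts.

The shipped reference constructs are synthetic: `synthetic_promoter_amplicon`
is a random 363-nt sequence carrying CpGs at exactly +7/+101/+217/+334
downstream of a TSS at +1 (the coordinate geometry of a four-CpG promoter
region) and `synthetic_spikein_amplicon` a random 349-nt unmethylated
control; they reproduce coordinate geometry, not real genomic sequence.
Their degenerate primers are derived from the construct ends (C → Y on the
forward primer, C → R on the reverse), mirroring how bisulfite primers
mark original cytosines.

## Numerical and validation choices

- Ground-truth expectations are closed-form; stochastic recovery tests
  assert within 3 binomial standard errors at the simulated depth, and
  counting/identity properties are exact.
- Validation problem sizes: 5 000 molecules for exact end-to-end epiallele
  recovery, 10 000 reads per arm for site-mean and 5hmC recovery, 200
  seeded draws for rarefaction calibration, 12 samples (4 groups × 3
  replicates, 1 000 molecules each) for the ordination check — depths at
  which the 3·SE bands are a few tenths of a percent to ~2 percentage
  points.
- The BIOM export is a hand-written BIOM 1.0 (JSON dialect) dense table;
  it round-trips through standard BIOM readers.
- Seeds: every stochastic routine takes an explicit seed or
  `numpy.random.Generator`; `simulate_sample` threads one generator
  through molecule sampling, chemistry and error injection so a fixed
  config seed reproduces FASTQ output byte-for-byte (gzip written with
  `mtime=0`).

## Known limitations

- No quality-based trimming or adapter removal; inputs are assumed to be
  amplicon reads whose geometry matches the panel.
- Primer-footprint CpGs are called from primer-synthesised bases on real
  data; the synthetic generator has no such artefact, so this caveat is
  untested against real libraries.
- The subtraction estimator for 5hmC inherits the usual BS−oxBS caveats:
  it is unbiased only insofar as conversion and 5mC-failure rates are
  equal across arms, and its per-site variance is the sum of two binomial
  variances, making low-coverage estimates noisy.
- Amplicons whose sequence is internally periodic can defeat
  match-count-based overlap selection during merging.
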