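# Methods

## Model and procedure

The pipeline detects tumors whose somatic mutation load is dominated by the
footprint of unrepaired 5-methylcytosine deamination. Deamination of 5mC at
a CpG dinucleotide yields a T:G mismatch; unrepaired, it fixes as a C>T
transition whose 3' neighbour is G (or, read from the opposite strand, a
G>A whose 5' neighbour is C). The screen therefore rests on two summary
statistics per tumor: the somatic SNV count and the fraction of SNVs that
are CpG>TpG after strand collapse.

### Strand collapse and the 96-channel spectrum

Each SNV is annotated with the reference trinucleotide centred on its
position. If the reference base is a purine, substitution and context are
jointly reverse-complemented, so every channel is pyrimidine-centred — the
standard SBS96 convention. Channel order is fixed (substitutions C>A, C>G,
C>T, T>A, T>C, T>G; within each, 5' then 3' flank alphabetical), making
serialized spectra bit-comparable. CpG>TpG is the sum of the four C>T
channels with 3' flank G. The denominator of the CpG>TpG fraction is
classifiable SNVs only: indels and SNVs whose context is unavailable
(contig edge, N in the 3-mer) are tallied separately and excluded from both
numerator and denominator. Transcriptional (sense/antisense) strand
assignment is deliberately not modelled; it would require a gene
annotation and does not affect the screen statistic.

### Filter cascade

Somatic calls are the union of per-caller call sets on identity
(chrom, pos, ref, alt). When callers disagree on depths, the
(somatic depth, allele depth) pair of the caller reporting the highest
somatic depth is kept — union semantics are permissive, so the most
confident observation wins; germline depth takes the maximum and
population frequency the minimum of the non-missing values. The cascade
then rejects a record iff any strict inequality holds:

| rule | default | rejected when |
|---|---|---|
| germline depth | 10 reads | DP_germline < 10 |
| somatic depth | 10 reads | DP_somatic < 10 |
| allele depth | 6 reads | AD < 6 |
| allele fraction | 0.05 | AD / DP_somatic < 0.05 |
| population frequency | 0.01 | freq > 0.01 |

Records exactly at a threshold are retained (AD/DP = 0.05 passes,
freq = 0.01 passes). Missing annotations never reject: a variant absent
from population databases has no frequency to filter on, and a table
without depth columns cannot fail depth rules; the same policy covers an
empty caller set under the optional `min_callers` rule (default 1, i.e.
plain union). The allele-fraction denominator is the somatic depth; no
caller-specific DP is consulted. The audit counts each record once under
every rule it fails, so per-rule counts can exceed the number of rejected
records. Manual review of calls in a genome browser cannot be automated
and is represented only by optional whitelist/blacklist inputs.

### Cohort screen

A sample is *hypermutated* when its classifiable SNV count strictly
exceeds 200, *enriched* when CpG>TpG/SNVs strictly exceeds 0.6, and a
*hit* when both hold. Both cuts are strict because the phenotype of
interest is a clear outlier, not a boundary case. Burden context is a
fold-change over the cohort baseline: the arithmetic mean SNV count of the
other samples (self excluded, so a single extreme outlier does not inflate
its own baseline; median available by configuration). Fold-changes are
reported to one decimal. Hits are ordered by descending CpG>TpG fraction,
then descending burden, then sample id, so reports are invariant to input
order. The per-sample table carries the two scatter coordinates used to
visualise the screen: fraction of C>T at CpG and fraction of C>T in other
contexts. The >200-SNV cut is applied to SNVs only; whether published
pan-cancer tallies counted all variant types at that cut is not
determinable from the outside, and this assumption is recorded here.

### Lineage summaries

Variant identity across samples is (chrom, pos, ref, alt); depths are
irrelevant to sharing. The shared matrix is pairwise intersection counts
with set sizes on the diagonal. A metastasis is polyphyly-consistent iff
it shares strictly more variants with the primary than with every sibling
metastasis; ties fail conservatively with a tie flag. Acquired SNVs are
the set difference against a reference set — by default the primary
sample's variants, an explicit proxy for the inferred founding clone
(clonal deconvolution is not performed here; outputs flag the proxy).
The cluster-retention rule keeps clusters with at least 5 SNVs and a mean
cancer-cell fraction of at least 0.10 in at least one sample; both
boundaries inclusive.

## Synthetic data: what it emulates and what it does not

The generator reproduces the *statistical shape* of a low-burden cohort
harbouring deamination hypermutators:

- background samples: SNV counts Poisson with mean 15 (negative-binomial
  optional), CpG>TpG channel weight 0.25 — below the <30% background band
  seen in real low-burden cohorts;
- hypermutators: counts uniform on [300, 1500], CpG>TpG weight 0.95 —
  inside the 91–97% band of MBD4-deficient tumors; the planted fraction
  of a cohort defaults to 0.1;
- reference: a single seeded random contig (default 100 kb, GC 0.45,
  within ±2% by construction at that length) with guaranteed CpG sites;
- depths: germline ~Poisson(30), somatic ~Poisson(100) (matching typical
  exome designs), allele fraction ~Beta(8,12) (mean 0.4, clonal-ish),
  clamped so clean records pass every filter rule; records planted to
  violate a rule are constructed to violate exactly that one rule;
- callers: each variant is detected by a uniformly random non-empty subset
  of three caller labels, all reporting identical annotations, so the
  union reconstructs the input exactly;
- patients: a star topology — a clonal trunk in all samples, one
  primary subclone per metastasis (sizes 20–50) making each metastasis
  genuinely polyphyletic, and 18–44 private SNVs per metastasis at CpG>TpG
  weight 0.95, emulating ongoing deamination during progression.

Channel-first placement (draw the channel from the planted weights, then a
position whose strand-collapsed context matches, without replacement
within a sample) makes planted spectra exact by construction, so recovered
fractions differ from planted weights only by multinomial sampling noise.

Not emulated: read-level errors and mapping artefacts, copy number and
LOH, subclonal VAF structure, real genome context composition (CpG islands,
methylation landscapes), inter-caller disagreement on depths, and germline
variation. Passing tests therefore demonstrate correctness of the
*analysis* under clean, well-specified inputs — not robustness to the
failure modes of real sequencing data.

## Numerical and design choices

- Coordinates are 1-based inclusive everywhere internally (MAF/VCF
  native); BED-style half-open appears only at export boundaries.
- Soft-masked (lowercase) reference bases are uppercased; any N in a
  3-mer disqualifies the record from spectra and increments a diagnostics
  tally. Reading never silently drops rows: parse failures raise with the
  line number.
- Every generator operation derives its PRNG stream from
  `(seed, operation-index)` via NumPy's seed-sequence mechanism, so single
  calls are reproducible under a fixed seed regardless of call order;
  passing one explicit generator chains operations on a single stream.
- The functional class of a variant (synonymous / non-synonymous) is
  consumed as input metadata, never computed — it depends on a transcript
  set outside this package's scope.
- Study sizes used by the acceptance script: 100 cohorts × 20 samples for
  the screen-recovery study and 200 samples × 1000 SNVs for estimator
  recovery, on a shared 100 kb reference. At these sizes the binomial
  standard error of a recovered fraction at weight 0.95 is ~0.007, so the
  mean absolute error bound of 0.01 is a meaningful unbiasedness check,
  not a tautology.

## Known limitations

- The fold-change baseline assumes the cohort is predominantly
  non-hypermutated; in a cohort of mostly hypermutators the mean baseline
  is inflated and fold-changes compress toward 1.
- The CpG>TpG fraction is undefined at n_SNV = 0 and reported as 0 with a
  flag; screens never promote such samples.
- The polyphyly check is a consistency statement about sharing counts,
  not a phylogenetic reconstruction; it can be confounded by convergent
  mutations at hypermutable sites, which the simulator does not plant.
- Very small references can exhaust context pools for extreme planted
  counts; the generator fails loudly with a capacity error rather than
  silently truncating.
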