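# Methods

## Model and assumptions

The pipeline analyses F1 embryos of two inbred, fully sequenced lines.
Three genetic assumptions do all the work:

1. **Maternal deposit is monoallelic.** Transcripts loaded during oogenesis
   were made from the mother's genome and carry only maternal SNP alleles.
2. **Zygotic transcription is biallelic and balanced.** The embryo's
   diploid nuclei transcribe both homologs, so newly made transcripts carry
   maternal and paternal alleles in equal expectation. No imprinting model
   is assumed; genes with paternal excess are treated like any other
   zygotic gene.
3. **Sequencing error sets a floor, not a ceiling.** In a strictly maternal
   mRNA pool a read can still be assigned paternal when an error converts
   the SNP base to the paternal allele. With per-base error rate e and the
   erroneous base uniform over the three alternatives, a single-SNP read
   flips with probability e/3; at e = 0.005 this gives ≈0.17% paternal
   misassignment, inside the empirically observed 0.1–1% band.

A gene-stage with informative reads N = M + P and paternal fraction
f = P/N is called **zygotic** iff f ≥ f_min and the exact binomial tail
Pr[X ≥ P | X ~ Bin(N, p₀)] survives per-stage Benjamini–Hochberg control at
level α. The deliberate asymmetry — an error-ceiling test rather than a
test against f = 0.5 — keeps genes with a large maternal deposit *plus*
genuine zygotic synthesis (f well below 0.5 but far above the error band)
in the zygotic class, where a symmetric test would wrongly reject them.
The attached estimator z = min(1, 2P/N) reads the paternal count as half
of a balanced biallelic contribution: z ≈ 1 for purely zygotic genes,
z ≈ 2e/3 ≈ 0 for purely maternal ones, intermediate for mixtures.

## Parameters that matter

| parameter | default | units | why |
|---|---|---|---|
| error ceiling p₀ | 0.01 | fraction | top of the observed 0.1–1% misassignment band |
| min paternal fraction f_min | 0.10 | fraction | complement of a ">90% maternal" rule; keeps marginal excesses out |
| α | 0.05 | — | significance on the BH-adjusted binomial tail |
| low-information threshold | 5 | reads | below this no call is attempted |
| confident-maternal depth | 100 | reads | depth at which a maternal call is well powered |
| SNP spacing | 200 | bp | density typical of crosses between sequenced inbred lines |
| read length | 36 | nt | early short-read platforms; maximises single-SNP reads |
| per-base error | 0.005 | — | places e/3 misassignment mid-band |
| elongation rates | 1500 / 4300 | nt/min | measured fly (Hsp70) and human-cell Pol II rates |
| translation rate | 540 | aa/min | standard eukaryotic ribosome estimate |
| interphase window | 10 | min | upper bound on pre-blastoderm interphases |

The Benjamini–Hochberg correction (per stage, over genes with N ≥ 5) is
this package's addition: simulated panels sweep hundreds of genes and the
promised ≥99% specificity does not hold without it. Published count tables
are small enough that the correction changes few calls.

## What the simulator emulates — and what it does not

`synthetic_data` generates: a diploid transcriptome whose paternal
haplotype differs at geometrically spaced substitutions (memoryless
spacing, since the stated density is an average); stage-structured
expression in which the maternal deposit is constant and zygotic output
accumulates per nuclear cycle from an onset cycle, optionally scaled by
the 2^(n−1) expected nuclei of cycle n, with stage pools c3_6 (cycles 3–6),
c7, c8; uniform read starts with i.i.d. substitution errors; and Mendelian
crosses by independent uniform gamete choice.

It does **not** model indels, paired ends, position- or quality-dependent
error profiles, PCR duplicates, mappability or alignment bias, transcript
degradation, or X dosage compensation. Reads come with known transcript
placements (the truth table), so passing tests validate the assignment,
normalisation and classification logic — not short-read alignment, which
this package deliberately leaves to standard mappers. An exact-substring
placer is provided for FASTQ-only input, but it is exact-match by design.

The standard validation panel (`example_panel`) holds 170 maternal-only
genes with lognormal deposits (median 50 copies) and 30 zygotic genes
(half purely zygotic, half with a 20-copy deposit on top, zygotic rate 2
per haplotype per nucleus-unit) with onset cycles spread over 1–8;
transcript lengths are uniform on 600–1400 nt so cross-sample
normalisation is non-trivial. Simulations in the test suite use 2.5×10⁵
reads per stage, which gives every post-onset zygotic gene ≳100
informative reads and half the maternal genes ≥100 — enough depth that
the sensitivity/specificity targets are a property of the method rather
than of sampling noise.

## Numerical choices

- The binomial tail is computed exactly (`scipy.stats.binom.sf`); the test
  suite cross-checks it against independent rational-arithmetic pmf
  summation to 10⁻¹² absolute for N ≤ 500.
- Normalisation anchors every sample to the **first** sample's autosomal
  RPKM total. Any constant satisfies the "constant autosomal total"
  requirement; anchoring makes outputs reproducible and the operation
  idempotent. X-linked genes are scaled by their sample's factor but never
  enter the constraint.
- All internal coordinates are 0-based half-open; SNP tables are 1-based
  on disk (VCF convention), gene models BED12. Reads extending past a
  transcript end are an error, never clipped.
- Conflict reads (discordant SNP votes) are excluded from M and P. They
  cannot be rescued without an error model per site, and exclusion can
  only lose signal, never fabricate it.
- The feasibility boundary is inclusive (total time ≤ window counts as
  feasible): the question is plausibility, not a sharp threshold.
- One master seed feeds named substreams (crc32-keyed) per operation and
  stage, so the full pipeline is byte-for-byte reproducible and
  subcommands run in isolation reproduce the pipeline's files.

## Design decisions taken where the design was open

- **Blank cells** in the packaged published count table are treated as "no
  informative reads detected", not zero expression: they yield no count
  row. The duplicated *scw* rows are both kept, keyed by row index, and
  excluded from gene-level onset aggregation; the duplication is
  unexplained in the source. Footnote flags (unannotated transcript,
  overlap with a neighbour, single-region reads) are preserved as metadata
  so users can filter suspected false positives (e.g. very large
  transcripts) themselves — the classifier does not apply a size rule.
- **Cross direction** resolves maternal/paternal labels at tabulation
  time: SNP tables are stored oriented for the forward cross and flipped
  for reciprocal-cross samples, after which reciprocal samples merge on a
  common maternal axis.
- **Read placement** is taken as known (simulator truth or exact-substring
  placement); heuristic alignment is out of scope, as the contribution is
  the assignment and classification machinery.
- The per-sample library-size denominator for RPKM defaults to the sum of
  the tabulated counts, since all mapped reads of the simulated world are
  in the table; an explicit total can be supplied for imported data.

## Known limitations

- The classifier's power at a stage depends on informative depth; genes
  with few SNPs or low expression remain low_information regardless of
  their true state, mirroring the sensitivity limits of the original
  assay.
- The zygotic-fraction estimator assumes balanced biallelic zygotic
  synthesis; allelic imbalance would bias it, though the zygotic call
  itself only requires excess over the error ceiling.
- Published-table reproduction is approximate by construction: the
  original cohort's membership criterion was qualitative, and a handful of
  genes with 1–2 paternal reads are statistically indistinguishable from
  the error floor at their depth.
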