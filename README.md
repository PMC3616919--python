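# zygotrace

Allele-specific RNA-seq analysis of the onset of zygotic transcription in
pre-blastoderm *Drosophila* embryos.

## The problem

The early fly embryo runs its first syncytial nuclear divisions on a
maternal dowry, and has classically been considered transcriptionally
silent before the syncytial blastoderm. Embryos from a cross of two
sequenced inbred lines offer a direct test: the F1 carries one maternal and
one paternal chromosome set that differ at single-nucleotide polymorphisms
every ~200 bp, so any sequencing read overlapping a SNP reveals which
chromosome it came from. Maternally deposited mRNAs carry only maternal
alleles; transcripts made by the embryo's own diploid genome appear with
both alleles in roughly equal numbers. `zygotrace` implements this analysis
as a tested, reusable pipeline for anyone working on maternal-to-zygotic
transition timing, allele-specific expression, or parent-of-origin read
assignment — together with a ground-truth simulator so every stage can be
validated without any sequencing data.

## The method

For each gene *g* at each developmental stage, reads overlapping SNPs are
assigned maternal (M) or paternal (P) by comparing the read base with the
two parental alleles; a base matching neither (a sequencing error) is
uninformative, and reads with discordant sites are excluded. With
N = M + P informative reads and paternal fraction f = P/N, a gene-stage is
called **zygotic** when

* f ≥ f_min (default 0.10, the complement of a ">90% maternal" criterion), and
* the one-sided binomial tail Pr[X ≥ P], X ~ Binomial(N, p₀), falls below α
  after per-stage Benjamini–Hochberg correction, where p₀ (default 0.01) is
  the ceiling of the paternal fraction attributable to sequencing error
  alone (empirically 0.1–1% in deeply covered maternal-only genes).

Otherwise the call is **maternal** (or **low_information** below N = 5).
The earliest zygotic stage is the gene's onset. Expression is summarised
as RPKM with samples rescaled to a constant autosomal RPKM total, and a
kinetics helper asks whether a transcript/protein of given length can be
synthesised within a <10-minute interphase at measured polymerase
(1.5 or 4.3 kb/min) and ribosome (540 aa/min) rates.

The simulator builds the matching ground truth: a diploid transcriptome
with geometrically spaced SNPs, per-gene expression programs (maternal
deposit, zygotic rate, onset nuclear cycle, 2^(n−1) nuclei scaling),
error-bearing truth-labeled 36-nt reads, and Mendelian crosses.

## Worked example

Re-classify the packaged published count table (per-gene M/P counts for
embryo pools at nuclear cycles 3–6, 7 and 8):

```python
from zygotrace import classify_table, load_table1_fixture

rows, annotations = load_table1_fixture()
results, summary = classify_table(rows)
print(summary["n_zygotic_genes"], summary["onset_per_gene"]["zen"])
```

Running `python examples/03_reclassify_published_table.py` prints:

```
89 gene-stage count pairs over 68 genes
called zygotic at >= 1 stage: 64 (94%)
zen onset:  c8   (deposit first, biallelic by cycle 8)
sisA onset: c7   (X-numerator gene, active by cycle 7)
```

94% of the published cohort is recovered as zygotic at at least one stage.
*zen* illustrates the deposit-then-activate pattern — purely maternal
counts (25/0, 12/0) early, near-balanced counts (88/83) at cycle 8 — while
the X-numerator gene *sisA* is already biallelic (9/13) at cycle 7. The
few genes not recovered have paternal counts statistically compatible with
the 1% sequencing-error ceiling.

The other scripts in `examples/` walk through read simulation, the full
assign-and-classify chain on truth-labeled data, synthesis-time
feasibility, and Mendelian segregation. The same stages are available from
the shell via the `zygotrace` command (`simulate`, `assign`, `quantify`,
`classify`, `kinetics`, `report`, `run`).

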