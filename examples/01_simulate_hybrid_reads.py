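"""Simulate F1-hybrid reads with known parental origin.

Builds a small diploid transcriptome (maternal haplotype = reference,
paternal haplotype differing at SNPs spaced ~200 bp apart), expresses a
mixed maternal/zygotic gene panel at the cycle-8 stage, and draws
error-bearing 36-nt reads with per-read truth labels.
"""

from zygotrace import (
    build_diploid_transcriptome,
    example_panel,
    simulate_expression,
    simulate_reads,
)

refs, program = example_panel(n_maternal=17, n_zygotic=3, seed=1)
maternal, paternal, snps = build_diploid_transcriptome(refs, mean_snp_spacing=200.0, seed=1)
print(f"{len(refs)} transcripts, {len(snps)} SNPs "
      f"(~{sum(map(len, refs.values())) / len(snps):.0f} bp apart)")

copies = simulate_expression(program, stage="c8")
reads = simulate_reads(maternal, paternal, copies, read_length=36,
                       per_base_error_rate=0.005, n_reads=20_000, seed=1, stage="c8")
truth = reads.truth_table()
frac_pat = (truth["haplotype_of_origin"] == "paternal").mean()
print(f"{len(reads)} reads drawn; {frac_pat:.1%} truly paternal")
print("A paternal share well below 50% reflects the maternal deposit that")
print("dominates the pool; only zygotically transcribed genes emit paternal reads.")
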