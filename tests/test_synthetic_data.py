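"""Simulator: diploid transcriptome, expression programs, reads, crosses."""

import math

import numpy as np
import pytest

from zygotrace.io_formats import STAGES
from zygotrace.synthetic_data import (
    CrossDesign,
    ExpressionProgram,
    GeneProgram,
    GenotypeSpec,
    build_diploid_transcriptome,
    example_panel,
    expected_nuclei,
    random_sequences,
    simulate_cross,
    simulate_expression,
    simulate_reads,
)


class TestExpectedNuclei:
    @pytest.mark.parametrize("cycle,count", [(1, 1), (2, 2), (3, 4), (6, 32), (7, 64)])
    def test_doubling(self, cycle, count):
        """Nuclei double each cycle: 2^(cycle-1), four nuclei at cycle 3."""
        assert expected_nuclei(cycle) == count

    def test_rejects_cycle_below_one(self):
        with pytest.raises(ValueError):
            expected_nuclei(0)


class TestDiploidTranscriptome:
    def test_mean_spacing_near_target(self):
        """Geometric SNP spacing with mean 200 bp lands within 10% over 100 kb."""
        refs = random_sequences(10, 10_000, seed=3)
        _, _, snps = build_diploid_transcriptome(refs, 200.0, seed=3)
        assert len(snps) >= 100
        observed = 10 * 10_000 / len(snps)
        assert abs(observed - 200.0) / 200.0 < 0.10

    def test_haplotypes_differ_only_at_snps(self, small_diploid):
        _, maternal, paternal, snps, _ = small_diploid
        snp_sites = {(s.chrom, s.pos) for s in snps}
        for gid in maternal:
            for i, (a, b) in enumerate(zip(maternal[gid], paternal[gid])):
                if a != b:
                    assert (gid, i) in snp_sites
        for s in snps:
            assert maternal[s.chrom][s.pos] == s.maternal_allele
            assert paternal[s.chrom][s.pos] == s.paternal_allele

    def test_zero_spacing_means_no_snps(self):
        refs = random_sequences(3, 500, seed=5)
        maternal, paternal, snps = build_diploid_transcriptome(refs, 0.0, seed=5)
        assert snps == []
        assert maternal == paternal

    def test_seed_determinism(self):
        refs = random_sequences(5, 2000, seed=9)
        out1 = build_diploid_transcriptome(refs, 150.0, seed=42)
        out2 = build_diploid_transcriptome(refs, 150.0, seed=42)
        assert out1 == out2

    def test_negative_spacing_rejected(self):
        with pytest.raises(ValueError):
            build_diploid_transcriptome({"g": "ACGT"}, -1.0, seed=0)


class TestSimulateExpression:
    def test_maternal_only_has_no_paternal_copies(self):
        prog = ExpressionProgram({"g": GeneProgram("maternal_only", maternal_copies=25)})
        for stage in STAGES:
            m, p = simulate_expression(prog, stage)["g"]
            assert m == 25 and p == 0

    def test_zygotic_only_is_symmetric(self):
        prog = ExpressionProgram(
            {"g": GeneProgram("zygotic_only", zygotic_rate=1.5, onset_cycle=1)}
        )
        for stage in STAGES:
            m, p = simulate_expression(prog, stage)["g"]
            assert m == p > 0

    def test_mixed_gene_turns_paternal_on_after_onset(self):
        """Deposit-then-activate: early stage maternal-only, later biallelic."""
        prog = ExpressionProgram(
            {
                "g": GeneProgram(
                    "mixed", maternal_copies=25, zygotic_rate=1.0, onset_cycle=7
                )
            }
        )
        m, p = simulate_expression(prog, "c3_6")["g"]
        assert m == 25 and p == 0
        for stage in ("c7", "c8"):
            m, p = simulate_expression(prog, stage)["g"]
            assert p > 0 and m == 25 + p

    def test_nuclei_scaling(self):
        prog = ExpressionProgram(
            {"g": GeneProgram("zygotic_only", zygotic_rate=1.0, onset_cycle=1)}
        )
        # c3_6 pools cycles 3-6: 4 + 8 + 16 + 32 = 60 nucleus-units
        m, p = simulate_expression(prog, "c3_6")["g"]
        assert m == p == 60.0
        m, p = simulate_expression(prog, "c8")["g"]
        assert m == p == 128.0

    def test_unscaled_rate_counts_cycles(self):
        prog = ExpressionProgram(
            {
                "g": GeneProgram(
                    "zygotic_only", zygotic_rate=2.0, onset_cycle=4,
                    scale_with_nuclei=False,
                )
            }
        )
        # cycles 4, 5, 6 active within c3_6
        m, p = simulate_expression(prog, "c3_6")["g"]
        assert m == p == 6.0

    def test_unknown_stage_rejected(self):
        prog = ExpressionProgram({"g": GeneProgram("maternal_only", maternal_copies=1)})
        with pytest.raises(ValueError):
            simulate_expression(prog, "c14")

    def test_program_invariants(self):
        with pytest.raises(ValueError):
            GeneProgram("maternal_only", maternal_copies=1, zygotic_rate=1)
        with pytest.raises(ValueError):
            GeneProgram("zygotic_only", maternal_copies=1, zygotic_rate=1)
        with pytest.raises(ValueError):
            GeneProgram("mixed", onset_cycle=0)

    def test_yaml_round_trip(self, tmp_path):
        prog = ExpressionProgram(
            {
                "a": GeneProgram("maternal_only", maternal_copies=10),
                "b": GeneProgram("mixed", maternal_copies=5, zygotic_rate=2, onset_cycle=7),
            }
        )
        p = tmp_path / "prog.yaml"
        prog.to_yaml(p)
        assert ExpressionProgram.from_yaml(p).genes == prog.genes


class TestSimulateReads:
    def test_error_free_reads_are_exact_substrings(self, small_diploid):
        _, maternal, paternal, _, _ = small_diploid
        copies = {g: (2.0, 1.0) for g in maternal}
        rs = simulate_reads(maternal, paternal, copies, 36, 0.0, 500, seed=1)
        haps = (maternal, paternal)
        for read in rs:
            source = haps[read.haplotype_of_origin == "paternal"][read.gene_id]
            assert source[read.start : read.start + 36] == read.sequence

    def test_snp_base_flips_to_other_parent_at_rate_e_over_3(self):
        """A sequencing error lands on the other parent's allele with
        probability e/3; checked against the analytic value over >1e6 bases."""
        maternal = {"g": "A" * 36}
        paternal = {"g": "G" + "A" * 35}  # SNP at position 0; reads cover it
        e = 0.01
        n = 40_000
        rs = simulate_reads(maternal, paternal, {"g": (1.0, 0.0)}, 36, e, n, seed=4)
        flips = sum(1 for r in rs if r.sequence[0] == "G")
        expect = n * e / 3
        se = math.sqrt(n * (e / 3) * (1 - e / 3))
        assert abs(flips - expect) <= 3 * se

    def test_zero_copies_yield_zero_reads(self, small_diploid):
        _, maternal, paternal, _, _ = small_diploid
        copies = {g: (0.0, 0.0) for g in maternal}
        silent = sorted(maternal)[0]
        copies[sorted(maternal)[1]] = (5.0, 0.0)
        rs = simulate_reads(maternal, paternal, copies, 36, 0.0, 300, seed=2)
        assert len(rs) == 300
        assert all(r.gene_id != silent for r in rs)

    def test_deleted_gene_yields_zero_reads(self, small_diploid):
        """A null allele (no deposit, no zygotic output) never emits reads,
        like a gene removed by a deficiency chromosome."""
        _, maternal, paternal, _, _ = small_diploid
        gids = sorted(maternal)
        prog = ExpressionProgram(
            {gids[0]: GeneProgram.deleted(),
             gids[1]: GeneProgram("maternal_only", maternal_copies=10)}
        )
        copies = simulate_expression(prog, "c8")
        rs = simulate_reads(
            {g: maternal[g] for g in gids[:2]},
            {g: paternal[g] for g in gids[:2]},
            copies, 36, 0.005, 1000, seed=6,
        )
        assert all(r.gene_id == gids[1] for r in rs)

    def test_fastq_byte_determinism(self, small_diploid, tmp_path):
        _, maternal, paternal, _, _ = small_diploid
        copies = {g: (1.0, 1.0) for g in maternal}
        paths = []
        for tag in ("a", "b"):
            rs = simulate_reads(maternal, paternal, copies, 36, 0.005, 2000, seed=99)
            p = tmp_path / f"{tag}.fastq"
            rs.to_fastq(p)
            paths.append(p.read_bytes())
        assert paths[0] == paths[1]

    def test_truth_labels_conserved(self, small_diploid):
        """Every read's recorded haplotype matches where its error-free
        bases came from; labels are assigned at draw time, not inferred."""
        _, maternal, paternal, _, _ = small_diploid
        copies = {g: (3.0, 3.0) for g in maternal}
        rs = simulate_reads(maternal, paternal, copies, 50, 0.0, 1000, seed=12)
        tt = rs.truth_table()
        assert len(tt) == 1000
        haps = {"maternal": maternal, "paternal": paternal}
        for rec in tt.itertuples():
            seq = haps[rec.haplotype_of_origin][rec.gene_id]
            assert rs.sequence(rec.Index) == seq[rec.start : rec.start + 50]

    def test_read_length_longer_than_all_transcripts_rejected(self):
        with pytest.raises(ValueError):
            simulate_reads({"g": "ACGTACGT"}, {"g": "ACGTACGT"}, {"g": (1.0, 0.0)},
                           100, 0.0, 10, seed=0)

    def test_invalid_error_rate_rejected(self):
        with pytest.raises(ValueError):
            simulate_reads({"g": "A" * 50}, {"g": "A" * 50}, {"g": (1.0, 0.0)},
                           36, 1.5, 10, seed=0)


class TestSimulateCross:
    def test_heterozygous_cross_gives_quarter_mutants(self):
        """en/+ x en/+ segregates ~1/4 mutant offspring."""
        spec = GenotypeSpec(
            locus="en",
            parent1=("en", "+"),
            parent2=("en", "+"),
            phenotype_map={"en/en": "mutant", "+/en": "normal", "+/+": "normal"},
        )
        n = 20_000
        _, phenotypes = simulate_cross(spec, n, seed=8)
        frac = phenotypes["mutant"] / n
        se = math.sqrt(0.25 * 0.75 / n)
        assert abs(frac - 0.25) <= 3 * se

    def test_wildtype_cross_has_no_mutants(self):
        spec = GenotypeSpec(
            locus="en",
            parent1=("+", "+"),
            parent2=("+", "+"),
            phenotype_map={"+/+": "normal"},
        )
        _, phenotypes = simulate_cross(spec, 5000, seed=1)
        assert phenotypes == {"normal": 5000}

    def test_deficiency_over_point_allele(self):
        """Df/+ x en/+: enumerating the four gamete combinations, exactly one
        (Df/en) is mutant, so the expected mutant fraction is 1/4."""
        spec = GenotypeSpec(
            locus="en",
            parent1=("Df", "+"),
            parent2=("en", "+"),
            phenotype_map={
                "Df/en": "mutant", "+/Df": "normal", "+/en": "normal", "+/+": "normal",
            },
        )
        reachable = spec.reachable_genotypes()
        assert reachable == {"Df/en", "+/Df", "+/en", "+/+"}
        n = 40_000
        genotypes, phenotypes = simulate_cross(spec, n, seed=3)
        assert sum(genotypes.values()) == n
        se = math.sqrt(0.25 * 0.75 / n)
        assert abs(phenotypes["mutant"] / n - 0.25) <= 3 * se

    def test_missing_reachable_genotype_rejected(self):
        with pytest.raises(ValueError, match="missing reachable"):
            GenotypeSpec(
                locus="en",
                parent1=("en", "+"),
                parent2=("en", "+"),
                phenotype_map={"en/en": "mutant"},
            )


class TestCrossDesign:
    def test_reciprocal_orients_snps(self):
        from zygotrace.io_formats import SnpRecord

        snps = [SnpRecord("g", 5, "A", "G")]
        fwd = CrossDesign("line-A", "line-B")
        rev = CrossDesign("line-B", "line-A", reciprocal=True)
        assert fwd.orient_snps(snps) == snps
        assert rev.orient_snps(snps) == [SnpRecord("g", 5, "G", "A")]

    def test_same_line_rejected(self):
        with pytest.raises(ValueError):
            CrossDesign("line-A", "line-A")


class TestExamplePanel:
    def test_panel_composition(self):
        refs, prog = example_panel(seed=0)
        assert len(refs) == len(prog) == 200
        modes = [p.mode for p in prog.genes.values()]
        assert modes.count("maternal_only") == 170
        onsets = {p.onset_cycle for p in prog.genes.values() if p.mode != "maternal_only"}
        assert onsets == set(range(1, 9))
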