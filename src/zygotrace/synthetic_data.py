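"""Ground-truth simulator for F1-hybrid allele-specific RNA-seq.

The analysis this package implements rests on a simple genetic fact: an
embryo from a cross of two inbred lines carries one maternal and one
paternal chromosome set, so transcripts deposited by the mother carry only
maternal SNP alleles while transcripts made by the embryo's own (diploid)
genome carry both in roughly equal amounts. This module builds that world
from scratch so every downstream stage can be tested against known truth:

* a diploid transcriptome in which the paternal haplotype differs from the
  maternal one by single-nucleotide substitutions spaced geometrically with
  a configurable mean (default 200 bp, the density typical of crosses
  between sequenced inbred lines);
* a stage-structured expression program (maternal deposit vs zygotic
  transcription switching on at a chosen nuclear cycle, optionally scaling
  with the 2^(n-1) nuclei of cycle n);
* an error-bearing single-end short-read simulator with per-read truth
  labels; and
* a Mendelian cross simulator for phenotype-ratio checks.

All randomness flows from one master seed through named substreams, so a
full pipeline run is reproducible from a single integer.
"""

from __future__ import annotations

import zlib
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .io_formats import STAGE_CYCLES, STAGES, SnpRecord, _open_text

__all__ = [
    "CrossDesign",
    "GeneProgram",
    "ExpressionProgram",
    "SimulatedRead",
    "ReadSet",
    "GenotypeSpec",
    "substream",
    "expected_nuclei",
    "build_diploid_transcriptome",
    "simulate_expression",
    "simulate_reads",
    "simulate_cross",
    "random_sequences",
    "example_panel",
]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_CODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _CODE[_b] = _i
    _CODE[_b + 32] = _i  # lowercase


def _encode(seq: str) -> np.ndarray:
    arr = _CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]
    if (arr == 255).any():
        bad = seq[int(np.argmax(arr == 255))]
        raise ValueError(f"non-ACGT character in sequence: {bad!r}")
    return arr


def _decode(codes: np.ndarray) -> str:
    return _BASES[codes].tobytes().decode("ascii")


def substream(seed: int, *names: str | int) -> np.random.Generator:
    """A named, reproducible child RNG of the master seed.

    Stream identity is (seed, crc32(name), ...) so the same (seed, names)
    pair always yields the same stream, independent of call order.
    """
    keys = [int(seed) & 0x7FFFFFFF]
    for name in names:
        keys.append(zlib.crc32(str(name).encode()) & 0x7FFFFFFF)
    return np.random.default_rng(keys)


# ---------------------------------------------------------------------------
# Cross design and expression programs
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CrossDesign:
    """Which inbred line is the mother. In the reciprocal cross the lines swap
    roles, so a SNP table oriented for the forward cross must have its
    maternal/paternal allele labels flipped before assignment."""

    maternal_line: str
    paternal_line: str
    reciprocal: bool = False

    def __post_init__(self) -> None:
        if self.maternal_line == self.paternal_line:
            raise ValueError("maternal and paternal lines must differ")

    def orient_snps(self, snps: Iterable[SnpRecord]) -> list[SnpRecord]:
        """Resolve SNP allele labels for this cross direction."""
        if self.reciprocal:
            return [s.flipped() for s in snps]
        return list(snps)


@dataclass(frozen=True)
class GeneProgram:
    """Expression program of one gene.

    mode:
        ``maternal_only`` — deposit only; ``zygotic_only`` — embryonic
        transcription only; ``mixed`` — deposit plus zygotic transcription.
    maternal_copies:
        transcript copies deposited during oogenesis (abundance units);
        they sit on the maternal haplotype only.
    zygotic_rate:
        zygotic output per haplotype per active-cycle unit (see
        :func:`simulate_expression`); split equally between haplotypes.
    onset_cycle:
        first nuclear cycle with zygotic transcription.
    scale_with_nuclei:
        if set, each cycle's zygotic output is multiplied by the expected
        nucleus count 2^(cycle-1).
    """

    mode: str
    maternal_copies: float = 0.0
    zygotic_rate: float = 0.0
    onset_cycle: int = 1
    scale_with_nuclei: bool = True

    def __post_init__(self) -> None:
        if self.mode not in ("maternal_only", "zygotic_only", "mixed"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.maternal_copies < 0 or self.zygotic_rate < 0:
            raise ValueError("copies and rates must be >= 0")
        if self.onset_cycle < 1:
            raise ValueError("onset_cycle must be >= 1")
        if self.mode == "maternal_only" and self.zygotic_rate != 0:
            raise ValueError("maternal_only genes cannot have a zygotic rate")
        if self.mode == "zygotic_only" and self.maternal_copies != 0:
            raise ValueError("zygotic_only genes cannot carry a maternal deposit")

    @classmethod
    def deleted(cls) -> "GeneProgram":
        """A null allele: no deposit, no zygotic output — zero reads ever."""
        return cls(mode="maternal_only", maternal_copies=0.0)


@dataclass
class ExpressionProgram:
    """Per-gene expression programs for one simulated embryo pool."""

    genes: dict[str, GeneProgram] = field(default_factory=dict)

    def __getitem__(self, gene_id: str) -> GeneProgram:
        return self.genes[gene_id]

    def __iter__(self) -> Iterator[str]:
        return iter(self.genes)

    def __len__(self) -> int:
        return len(self.genes)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ExpressionProgram":
        with _open_text(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls({gid: GeneProgram(**spec) for gid, spec in raw.items()})

    def to_yaml(self, path: str | Path) -> None:
        raw = {
            gid: {
                "mode": p.mode,
                "maternal_copies": p.maternal_copies,
                "zygotic_rate": p.zygotic_rate,
                "onset_cycle": p.onset_cycle,
                "scale_with_nuclei": p.scale_with_nuclei,
            }
            for gid, p in self.genes.items()
        }
        with _open_text(path, "wt") as fh:
            yaml.safe_dump(raw, fh, sort_keys=True)


def expected_nuclei(cycle: int) -> int:
    """Expected nucleus count at nuclear cycle ``cycle``: 2^(cycle-1).

    The early embryo doubles its nuclei with near-perfect fidelity, so
    cycle 1 has one nucleus, cycle 3 has four, cycle 6 has thirty-two.
    """
    if cycle < 1:
        raise ValueError(f"nuclear cycle must be >= 1, got {cycle}")
    return 2 ** (cycle - 1)


def simulate_expression(
    program: ExpressionProgram, stage: str
) -> dict[str, tuple[float, float]]:
    """Expected per-haplotype transcript copy numbers at a stage.

    Returns {gene_id: (maternal_copies, paternal_copies)}. The maternal
    deposit contributes only to the maternal haplotype; zygotic
    transcription contributes equally to both haplotypes from the gene's
    onset cycle onward, summed over the nuclear cycles pooled in ``stage``
    (scaled by expected nuclei per cycle when ``scale_with_nuclei``).
    """
    if stage not in STAGE_CYCLES:
        raise ValueError(f"unknown stage {stage!r}; expected one of {STAGES}")
    cycles = STAGE_CYCLES[stage]
    out: dict[str, tuple[float, float]] = {}
    for gid, p in program.genes.items():
        zyg = 0.0
        if p.mode != "maternal_only" and p.zygotic_rate > 0:
            for c in cycles:
                if c >= p.onset_cycle:
                    mult = expected_nuclei(c) if p.scale_with_nuclei else 1
                    zyg += p.zygotic_rate * mult
        maternal = p.maternal_copies + zyg
        paternal = zyg
        out[gid] = (maternal, paternal)
    return out


# ---------------------------------------------------------------------------
# Diploid transcriptome
# ---------------------------------------------------------------------------


def random_sequences(
    n_genes: int,
    length: int | Sequence[int],
    seed: int,
    prefix: str = "g",
) -> dict[str, str]:
    """Random A/C/G/T transcript sequences, one per gene."""
    rng = substream(seed, "refseq")
    lengths = [length] * n_genes if isinstance(length, int) else list(length)
    if len(lengths) != n_genes:
        raise ValueError("length list must have n_genes entries")
    out: dict[str, str] = {}
    for i, L in enumerate(lengths):
        out[f"{prefix}{i:04d}"] = _decode(rng.integers(0, 4, size=L).astype(np.uint8))
    return out


def build_diploid_transcriptome(
    reference_sequences: Mapping[str, str],
    mean_snp_spacing: float,
    seed: int,
) -> tuple[dict[str, str], dict[str, str], list[SnpRecord]]:
    """Derive a two-haplotype transcriptome from a reference.

    The maternal haplotype is the reference; the paternal haplotype differs
    only at simulated SNPs whose inter-site distances are geometric with
    mean ``mean_snp_spacing`` (memoryless placement — the stated spacing is
    an average, not a lattice). The substituted allele is uniform over the
    three alternatives. ``mean_snp_spacing = 0`` is the no-SNP flag value.

    Each transcript is treated as its own single-exon contig, so SNP
    coordinates are transcript offsets and ``chrom`` is the gene id.
    """
    if mean_snp_spacing < 0:
        raise ValueError("mean_snp_spacing must be >= 0")
    rng = substream(seed, "diploid")
    maternal = {gid: seq.upper() for gid, seq in reference_sequences.items()}
    paternal: dict[str, str] = {}
    snps: list[SnpRecord] = []
    for gid in maternal:
        seq = maternal[gid]
        enc = _encode(seq)
        if mean_snp_spacing == 0 or len(seq) == 0:
            paternal[gid] = seq
            continue
        p = min(1.0, 1.0 / mean_snp_spacing)
        # oversample gaps, then trim to the transcript
        n_draw = max(8, int(3 * len(seq) * p) + 8)
        positions: list[int] = []
        last = -1
        while True:
            gaps = rng.geometric(p, size=n_draw)
            for g in gaps:
                last += int(g)
                if last >= len(seq):
                    break
                positions.append(last)
            if last >= len(seq):
                break
        pat = enc.copy()
        for pos in positions:
            shift = rng.integers(1, 4)
            pat[pos] = (pat[pos] + shift) % 4
            snps.append(
                SnpRecord(
                    chrom=gid,
                    pos=int(pos),
                    maternal_allele=chr(_BASES[enc[pos]]),
                    paternal_allele=chr(_BASES[pat[pos]]),
                )
            )
        paternal[gid] = _decode(pat)
    snps.sort()
    return maternal, paternal, snps


# ---------------------------------------------------------------------------
# Read simulation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SimulatedRead:
    """One simulated read with its ground-truth provenance. The haplotype of
    origin is recorded at draw time, before any errors, and is never derived
    from the sequence."""

    read_id: str
    gene_id: str
    haplotype_of_origin: str  # "maternal" | "paternal"
    start: int  # 0-based offset on the transcript
    length: int
    sequence: str
    stage: str

    def __post_init__(self) -> None:
        if len(self.sequence) != self.length:
            raise ValueError("sequence length does not match declared length")
        if self.haplotype_of_origin not in ("maternal", "paternal"):
            raise ValueError(f"bad haplotype {self.haplotype_of_origin!r}")


class ReadSet:
    """A batch of simulated reads held as arrays (sequence codes, gene index,
    haplotype, start) with iteration, FASTQ export and a truth table.

    Array storage keeps simulation and assignment of 10^5-10^6 reads cheap;
    :meth:`__iter__` materialises :class:`SimulatedRead` objects on demand.
    """

    def __init__(
        self,
        gene_ids: list[str],
        gene_index: np.ndarray,
        haplotype: np.ndarray,
        start: np.ndarray,
        seq_codes: np.ndarray,
        stage: str,
    ) -> None:
        n = len(gene_index)
        if not (len(haplotype) == len(start) == seq_codes.shape[0] == n):
            raise ValueError("inconsistent array lengths")
        self.gene_ids = gene_ids
        self.gene_index = gene_index
        self.haplotype = haplotype  # 0 = maternal, 1 = paternal
        self.start = start
        self.seq_codes = seq_codes
        self.stage = stage

    def __len__(self) -> int:
        return len(self.gene_index)

    @property
    def read_length(self) -> int:
        return self.seq_codes.shape[1] if len(self) else 0

    def read_id(self, i: int) -> str:
        return f"{self.stage}_r{i:07d}"

    def sequence(self, i: int) -> str:
        return _decode(self.seq_codes[i])

    def __iter__(self) -> Iterator[SimulatedRead]:
        hap_names = ("maternal", "paternal")
        for i in range(len(self)):
            yield SimulatedRead(
                read_id=self.read_id(i),
                gene_id=self.gene_ids[self.gene_index[i]],
                haplotype_of_origin=hap_names[self.haplotype[i]],
                start=int(self.start[i]),
                length=self.read_length,
                sequence=self.sequence(i),
                stage=self.stage,
            )

    def truth_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "read_id": [self.read_id(i) for i in range(len(self))],
                "gene_id": [self.gene_ids[g] for g in self.gene_index],
                "haplotype_of_origin": np.where(
                    self.haplotype == 0, "maternal", "paternal"
                ),
                "start": self.start,
                "length": self.read_length,
                "stage": self.stage,
            }
        )

    def to_fastq(self, path: str | Path, quality_char: str = "I") -> None:
        """Write reads as FASTQ with constant Sanger-encoded quality."""
        qual = quality_char * self.read_length
        with _open_text(path, "wt") as fh:
            for i in range(len(self)):
                fh.write(f"@{self.read_id(i)}\n{self.sequence(i)}\n+\n{qual}\n")

    def write_truth_table(self, path: str | Path) -> None:
        self.truth_table().to_csv(path, sep="\t", index=False)


def simulate_reads(
    maternal_seqs: Mapping[str, str],
    paternal_seqs: Mapping[str, str],
    copy_numbers: Mapping[str, tuple[float, float]],
    read_length: int,
    per_base_error_rate: float,
    n_reads: int,
    seed: int,
    stage: str = "c8",
) -> ReadSet:
    """Draw single-end reads from a diploid transcript pool.

    A read's source (gene, haplotype) is drawn with probability proportional
    to copy number x transcript length; its start is uniform over valid
    placements; substitution errors are i.i.d. per base with the erroneous
    base uniform over the three alternatives. Transcripts shorter than the
    read length cannot host a read and get zero weight.
    """
    if not 0 <= per_base_error_rate < 1:
        raise ValueError("per_base_error_rate must be in [0, 1)")
    if n_reads < 0:
        raise ValueError("n_reads must be >= 0")
    if read_length < 1:
        raise ValueError("read_length must be >= 1")

    gene_ids = sorted(copy_numbers)
    sources: list[tuple[int, int, np.ndarray]] = []  # (gene_idx, hap, encoded seq)
    weights: list[float] = []
    for gi, gid in enumerate(gene_ids):
        m_copies, p_copies = copy_numbers[gid]
        for hap, (copies, seqs) in enumerate(
            ((m_copies, maternal_seqs), (p_copies, paternal_seqs))
        ):
            if copies < 0:
                raise ValueError(f"negative copy number for {gid}")
            seq = seqs[gid]
            if copies == 0 or len(seq) < read_length:
                continue
            sources.append((gi, hap, _encode(seq)))
            weights.append(copies * len(seq))

    if n_reads == 0 or not weights:
        total_copies = sum(sum(c) for c in copy_numbers.values())
        if n_reads > 0 and total_copies > 0:
            raise ValueError("read_length exceeds every expressed transcript")
        empty = np.empty(0, dtype=np.int64)
        return ReadSet(
            gene_ids, empty, empty.astype(np.uint8), empty,
            np.empty((0, read_length), dtype=np.uint8), stage,
        )

    rng = substream(seed, "reads", stage)
    probs = np.asarray(weights) / np.sum(weights)
    counts = rng.multinomial(n_reads, probs)

    gene_index = np.empty(n_reads, dtype=np.int64)
    haplotype = np.empty(n_reads, dtype=np.uint8)
    starts = np.empty(n_reads, dtype=np.int64)
    seq_codes = np.empty((n_reads, read_length), dtype=np.uint8)
    offsets = np.arange(read_length)
    pos = 0
    for (gi, hap, enc), cnt in zip(sources, counts):
        if cnt == 0:
            continue
        s = rng.integers(0, len(enc) - read_length + 1, size=cnt)
        gene_index[pos : pos + cnt] = gi
        haplotype[pos : pos + cnt] = hap
        starts[pos : pos + cnt] = s
        seq_codes[pos : pos + cnt] = enc[s[:, None] + offsets]
        pos += cnt

    if per_base_error_rate > 0:
        err = rng.random((n_reads, read_length)) < per_base_error_rate
        n_err = int(err.sum())
        if n_err:
            shift = rng.integers(1, 4, size=n_err).astype(np.uint8)
            seq_codes[err] = (seq_codes[err] + shift) % 4

    perm = rng.permutation(n_reads)
    return ReadSet(
        gene_ids, gene_index[perm], haplotype[perm], starts[perm],
        seq_codes[perm], stage,
    )


# ---------------------------------------------------------------------------
# Mendelian crosses
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GenotypeSpec:
    """One locus, two parents, and a genotype-to-phenotype map.

    Genotypes are canonicalised as "a/b" with alleles sorted, so "en/+" and
    "+/en" name the same genotype. The phenotype map must cover every
    genotype reachable from the parents' gametes.
    """

    locus: str
    parent1: tuple[str, str]
    parent2: tuple[str, str]
    phenotype_map: Mapping[str, str]

    @staticmethod
    def genotype_key(a: str, b: str) -> str:
        return "/".join(sorted((a, b)))

    def reachable_genotypes(self) -> set[str]:
        return {
            self.genotype_key(a, b) for a in self.parent1 for b in self.parent2
        }

    def __post_init__(self) -> None:
        canonical = {
            self.genotype_key(*k.split("/")): v for k, v in self.phenotype_map.items()
        }
        missing = self.reachable_genotypes() - set(canonical)
        if missing:
            raise ValueError(
                f"phenotype map missing reachable genotypes: {sorted(missing)}"
            )
        object.__setattr__(self, "phenotype_map", canonical)


def simulate_cross(
    spec: GenotypeSpec, n_offspring: int, seed: int
) -> tuple[Counter, Counter]:
    """Simulate independent uniform gamete choice from each parent.

    Returns ``(genotype_counts, phenotype_counts)``.
    """
    if n_offspring < 0:
        raise ValueError("n_offspring must be >= 0")
    rng = substream(seed, "cross", spec.locus)
    g1 = rng.integers(0, 2, size=n_offspring)
    g2 = rng.integers(0, 2, size=n_offspring)
    genotypes = Counter()
    for a_idx in (0, 1):
        for b_idx in (0, 1):
            key = GenotypeSpec.genotype_key(spec.parent1[a_idx], spec.parent2[b_idx])
            genotypes[key] += int(np.sum((g1 == a_idx) & (g2 == b_idx)))
    phenotypes = Counter()
    for gt, cnt in genotypes.items():
        phenotypes[spec.phenotype_map[gt]] += cnt
    return genotypes, phenotypes


# ---------------------------------------------------------------------------
# Standard simulated study panel
# ---------------------------------------------------------------------------


def example_panel(
    n_maternal: int = 170,
    n_zygotic: int = 30,
    seed: int = 0,
    transcript_length: int = 1000,
) -> tuple[dict[str, str], ExpressionProgram]:
    """The standard simulated gene panel used for classifier validation.

    170 strictly maternal genes with lognormal-spread deposits plus 30
    zygotic genes (half purely zygotic, half with a maternal deposit on top)
    whose onset cycles are spread over nuclear cycles 1-8. Transcript
    lengths are uniform on [0.6, 1.4] x ``transcript_length`` so samples
    differ in length composition and normalisation is non-trivial. Returns
    the reference sequences and the expression program; pair with
    :func:`build_diploid_transcriptome` and :func:`simulate_reads`.
    """
    rng = substream(seed, "panel")
    n = n_maternal + n_zygotic
    lengths = rng.integers(
        int(0.6 * transcript_length), int(1.4 * transcript_length) + 1, size=n
    )
    refs = random_sequences(n, [int(x) for x in lengths], seed, prefix="gene")
    gene_ids = sorted(refs)
    programs: dict[str, GeneProgram] = {}
    deposits = np.exp(rng.normal(np.log(50.0), 0.5, size=n_maternal))
    for gid, dep in zip(gene_ids[:n_maternal], deposits):
        programs[gid] = GeneProgram(mode="maternal_only", maternal_copies=float(dep))
    onsets = [1 + (i * 8) // n_zygotic for i in range(n_zygotic)]
    for j, gid in enumerate(gene_ids[n_maternal:]):
        onset = onsets[j]
        # rate chosen so post-onset output is comparable to a typical deposit
        rate = 2.0
        if j % 2 == 0:
            programs[gid] = GeneProgram(
                mode="zygotic_only", zygotic_rate=rate, onset_cycle=onset
            )
        else:
            programs[gid] = GeneProgram(
                mode="mixed",
                maternal_copies=20.0,
                zygotic_rate=rate,
                onset_cycle=onset,
            )
    return refs, ExpressionProgram(programs)
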