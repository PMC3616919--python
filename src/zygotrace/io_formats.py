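"""Readers and writers for the formats the pipeline touches.

Coordinate conventions are strict: everything held in memory is 0-based,
half-open. On disk, the SNP table follows the VCF convention (1-based POS)
and gene models follow BED12 (0-based half-open). The readers convert on
the way in, the writers on the way out.

The SNP table is a minimal VCF-like TSV with four columns
(CHROM, POS, REF, ALT) where REF is the allele carried by the line used as
the mother in the *forward* cross and ALT the other line's allele. Which
allele is "maternal" in a given sample is resolved per sample from the
cross direction (see :class:`zygotrace.synthetic_data.CrossDesign`).
"""

from __future__ import annotations

import gzip
import io
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import IO, Iterable, Sequence

import pandas as pd

__all__ = [
    "STAGES",
    "STAGE_CYCLES",
    "SnpRecord",
    "GeneModel",
    "AlleleCountRow",
    "read_snp_table",
    "write_snp_table",
    "read_gene_models",
    "write_gene_models",
    "load_table1_fixture",
    "read_counts",
    "write_counts",
    "read_results",
    "write_results",
    "read_fasta",
    "write_fasta",
]

DNA = frozenset("ACGT")

#: Developmental stages assayed, in temporal order. ``c3_6`` pools nuclear
#: cycles 3-6 (embryos staged as "cycle 6 and younger"); ``c7`` and ``c8``
#: are single-cycle pools.
STAGES: tuple[str, ...] = ("c3_6", "c7", "c8")

#: Nuclear cycles contributing to each stage pool.
STAGE_CYCLES: dict[str, tuple[int, ...]] = {
    "c3_6": (3, 4, 5, 6),
    "c7": (7,),
    "c8": (8,),
}


class ParseError(ValueError):
    """A malformed line in an input file; carries the offending line number."""


def _open_text(path: str | Path, mode: str = "rt") -> IO[str]:
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)  # type: ignore[return-value]
    return open(path, mode)


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True, order=True)
class SnpRecord:
    """One biallelic substitution distinguishing the two parental lines.

    ``maternal_allele``/``paternal_allele`` are named for the forward cross;
    a reciprocal-cross sample swaps their roles (see
    :meth:`SnpRecord.flipped`). ``pos`` is 0-based.
    """

    chrom: str
    pos: int
    maternal_allele: str
    paternal_allele: str

    def __post_init__(self) -> None:
        if self.pos < 0:
            raise ValueError(f"SNP position must be >= 0, got {self.pos}")
        for allele in (self.maternal_allele, self.paternal_allele):
            if len(allele) != 1 or allele not in DNA:
                raise ValueError(
                    f"allele must be a single base in ACGT, got {allele!r}"
                )
        if self.maternal_allele == self.paternal_allele:
            raise ValueError(
                f"SNP at {self.chrom}:{self.pos} has identical alleles "
                f"({self.maternal_allele}); not a polymorphism"
            )

    def flipped(self) -> "SnpRecord":
        """The same site with maternal/paternal roles swapped (reciprocal cross)."""
        return SnpRecord(
            self.chrom, self.pos, self.paternal_allele, self.maternal_allele
        )


@dataclass(frozen=True)
class GeneModel:
    """A gene as the unit of read counting and classification.

    ``exons`` are 0-based half-open genomic intervals, sorted and
    non-overlapping. ``transcript_length_nt`` is always the sum of exon
    lengths and ``intron_count`` the number of gaps between exons.
    """

    gene_id: str
    chrom: str
    strand: str
    exons: tuple[tuple[int, int], ...]
    is_autosomal: bool = True

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        if not self.exons:
            raise ValueError(f"gene {self.gene_id} has no exons")
        prev_end = None
        for start, end in self.exons:
            if end <= start:
                raise ValueError(
                    f"gene {self.gene_id}: zero- or negative-length exon "
                    f"[{start}, {end})"
                )
            if prev_end is not None and start < prev_end:
                raise ValueError(
                    f"gene {self.gene_id}: exons overlap or are unsorted at "
                    f"[{start}, {end})"
                )
            prev_end = end

    @property
    def transcript_length_nt(self) -> int:
        return sum(end - start for start, end in self.exons)

    @property
    def intron_count(self) -> int:
        return len(self.exons) - 1

    def project_to_transcript(self, genomic_pos: int) -> int | None:
        """Map a genomic coordinate to a transcript offset, or None if intronic
        or outside the gene. Projection is in genomic (left-to-right) order;
        reads are likewise simulated and placed in that orientation, so
        strand does not enter the arithmetic.
        """
        offset = 0
        for start, end in self.exons:
            if start <= genomic_pos < end:
                return offset + (genomic_pos - start)
            offset += end - start
        return None


@dataclass(frozen=True)
class AlleleCountRow:
    """Per gene, per stage: maternal-assigned (M), paternal-assigned (P) and
    uninformative read counts. M + P is the informative read total N."""

    gene_id: str
    stage: str
    maternal_reads: int
    paternal_reads: int
    uninformative_reads: int = 0

    def __post_init__(self) -> None:
        if self.stage not in STAGES:
            raise ValueError(f"unknown stage {self.stage!r}; expected one of {STAGES}")
        for name in ("maternal_reads", "paternal_reads", "uninformative_reads"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0 for gene {self.gene_id}")

    @property
    def informative_total(self) -> int:
        return self.maternal_reads + self.paternal_reads


# ---------------------------------------------------------------------------
# SNP table (VCF-subset TSV)
# ---------------------------------------------------------------------------


def read_snp_table(path: str | Path) -> list[SnpRecord]:
    """Read a VCF-subset SNP table: tab-separated CHROM, POS (1-based), REF,
    ALT; ``#`` lines are comments. Positions are converted to 0-based and the
    result is sorted by (chrom, pos). Multi-nucleotide alleles are rejected."""
    records: list[SnpRecord] = []
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise ParseError(
                    f"{path}:{lineno}: expected 4 tab-separated fields "
                    f"(CHROM, POS, REF, ALT), got {len(fields)}"
                )
            chrom, pos_s, ref, alt = fields[:4]
            try:
                pos1 = int(pos_s)
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: POS is not an integer: {pos_s!r}") from exc
            if pos1 < 1:
                raise ParseError(f"{path}:{lineno}: POS must be >= 1 (1-based), got {pos1}")
            if len(ref) != 1 or len(alt) != 1:
                raise ParseError(
                    f"{path}:{lineno}: not a single-nucleotide substitution "
                    f"(REF={ref!r}, ALT={alt!r})"
                )
            try:
                records.append(SnpRecord(chrom, pos1 - 1, ref.upper(), alt.upper()))
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from exc
    records.sort()
    return records


def write_snp_table(records: Iterable[SnpRecord], path: str | Path) -> None:
    """Write SNPs back out in the 1-based VCF-subset dialect."""
    with _open_text(path, "wt") as fh:
        fh.write("#CHROM\tPOS\tREF\tALT\n")
        for rec in sorted(records):
            fh.write(
                f"{rec.chrom}\t{rec.pos + 1}\t{rec.maternal_allele}\t{rec.paternal_allele}\n"
            )


# ---------------------------------------------------------------------------
# Gene models (BED12)
# ---------------------------------------------------------------------------


def read_gene_models(
    path: str | Path, x_chroms: Sequence[str] = ("X",)
) -> list[GeneModel]:
    """Read gene models from BED12; block fields define exons.

    Chromosomes listed in ``x_chroms`` mark genes as X-linked
    (``is_autosomal=False``); everything else is autosomal.
    """
    genes: list[GeneModel] = []
    x_set = set(x_chroms)
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 12:
                raise ParseError(
                    f"{path}:{lineno}: BED12 requires 12 fields, got {len(fields)}"
                )
            chrom = fields[0]
            chrom_start = int(fields[1])
            chrom_end = int(fields[2])
            name = fields[3]
            strand = fields[5]
            block_count = int(fields[9])
            block_sizes = [int(x) for x in fields[10].rstrip(",").split(",")]
            block_starts = [int(x) for x in fields[11].rstrip(",").split(",")]
            if len(block_sizes) != block_count or len(block_starts) != block_count:
                raise ParseError(
                    f"{path}:{lineno}: blockCount={block_count} does not match "
                    f"blockSizes/blockStarts"
                )
            exons = tuple(
                (chrom_start + bs, chrom_start + bs + sz)
                for bs, sz in zip(block_starts, block_sizes)
            )
            if exons and exons[-1][1] != chrom_end:
                raise ParseError(
                    f"{path}:{lineno}: last block does not end at chromEnd"
                )
            try:
                genes.append(
                    GeneModel(
                        gene_id=name,
                        chrom=chrom,
                        strand=strand,
                        exons=exons,
                        is_autosomal=chrom not in x_set,
                    )
                )
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from exc
    return genes


def write_gene_models(genes: Iterable[GeneModel], path: str | Path) -> None:
    """Write gene models as BED12 (score 0, thick range = full range)."""
    with _open_text(path, "wt") as fh:
        for g in genes:
            start = g.exons[0][0]
            end = g.exons[-1][1]
            sizes = ",".join(str(e - s) for s, e in g.exons)
            starts = ",".join(str(s - start) for s, _ in g.exons)
            fh.write(
                f"{g.chrom}\t{start}\t{end}\t{g.gene_id}\t0\t{g.strand}\t"
                f"{start}\t{end}\t0\t{len(g.exons)}\t{sizes}\t{starts}\n"
            )


# ---------------------------------------------------------------------------
# Published count-table fixture
# ---------------------------------------------------------------------------

_STAGE_COLUMNS = {"c3_6": ("m_c3_6", "p_c3_6"), "c7": ("m_c7", "p_c7"), "c8": ("m_c8", "p_c8")}


def _fixture_frame() -> pd.DataFrame:
    data = resources.files("zygotrace.data").joinpath("table1_counts.tsv").read_text()
    return pd.read_csv(
        io.StringIO(data),
        sep="\t",
        comment="#",
        dtype={"gene": str, "flags": str},
        keep_default_na=True,
    )


def load_table1_fixture() -> tuple[list[AlleleCountRow], pd.DataFrame]:
    """Load the packaged published count table.

    Returns ``(rows, annotations)``. ``rows`` holds one :class:`AlleleCountRow`
    per non-blank (gene, stage) cell pair; blank cells produce no row (they
    mean "no informative reads detected", not zero expression). Where a gene
    appears more than once (scw does), the gene_id is suffixed ``#<row_index>``
    on every duplicated row so rows stay distinct; such duplicates are excluded
    from gene-level aggregation downstream.

    ``annotations`` is a DataFrame indexed by row_index with columns gene,
    size_nt, introns, flags, x_linked. size_nt is float because one printed
    value is non-integral and is preserved verbatim.
    """
    df = _fixture_frame()
    dup_genes = set(df["gene"][df["gene"].duplicated(keep=False)])
    rows: list[AlleleCountRow] = []
    for _, r in df.iterrows():
        gene = r["gene"]
        if gene in dup_genes:
            gene = f"{gene}#{int(r['row_index'])}"
        for stage, (mcol, pcol) in _STAGE_COLUMNS.items():
            if pd.isna(r[mcol]) or pd.isna(r[pcol]):
                continue
            rows.append(
                AlleleCountRow(
                    gene_id=gene,
                    stage=stage,
                    maternal_reads=int(r[mcol]),
                    paternal_reads=int(r[pcol]),
                )
            )
    ann = df.set_index("row_index")[["gene", "size_nt", "introns", "flags", "x_linked"]].copy()
    ann["x_linked"] = ann["x_linked"].astype(bool)
    return rows, ann


# ---------------------------------------------------------------------------
# Count / result tables (TSV round-trip)
# ---------------------------------------------------------------------------

_COUNT_COLUMNS = ["gene_id", "stage", "maternal_reads", "paternal_reads", "uninformative_reads"]


def write_counts(rows: Iterable[AlleleCountRow], path: str | Path) -> None:
    """Write allele count rows as TSV. Column order is fixed:
    gene_id, stage, maternal_reads, paternal_reads, uninformative_reads."""
    rows = list(rows)
    with _open_text(path, "wt") as fh:
        fh.write("\t".join(_COUNT_COLUMNS) + "\n")
        for r in rows:
            fh.write(
                f"{r.gene_id}\t{r.stage}\t{r.maternal_reads}\t"
                f"{r.paternal_reads}\t{r.uninformative_reads}\n"
            )


def read_counts(path: str | Path) -> list[AlleleCountRow]:
    """Read a count TSV written by :func:`write_counts`."""
    rows: list[AlleleCountRow] = []
    with _open_text(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != _COUNT_COLUMNS:
            raise ParseError(f"{path}:1: unexpected header {header}")
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) != len(_COUNT_COLUMNS):
                raise ParseError(f"{path}:{lineno}: expected {len(_COUNT_COLUMNS)} fields")
            try:
                rows.append(
                    AlleleCountRow(
                        gene_id=fields[0],
                        stage=fields[1],
                        maternal_reads=int(fields[2]),
                        paternal_reads=int(fields[3]),
                        uninformative_reads=int(fields[4]),
                    )
                )
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from exc
    return rows


def write_results(results: pd.DataFrame, path: str | Path) -> None:
    """Write a classification results table (one row per gene per stage)."""
    results.to_csv(path, sep="\t", index=False)


def read_results(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# FASTA (thin wrappers; sequences are plain transcript strings)
# ---------------------------------------------------------------------------


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read a FASTA file into an ordered {name: sequence} dict."""
    seqs: dict[str, str] = {}
    name = None
    chunks: list[str] = []
    with _open_text(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith(">"):
                if name is not None:
                    seqs[name] = "".join(chunks)
                name = line[1:].split()[0]
                chunks = []
            elif line:
                chunks.append(line.upper())
    if name is not None:
        seqs[name] = "".join(chunks)
    return seqs


def write_fasta(seqs: dict[str, str], path: str | Path, width: int = 70) -> None:
    with _open_text(path, "wt") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")
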