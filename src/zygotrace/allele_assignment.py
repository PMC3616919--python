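"""Assign reads to the maternal or paternal chromosome via SNP overlap.

Each read placed on a transcript is compared, base by base, against the two
parental alleles at every SNP it overlaps. A site votes maternal, paternal,
or neither (a third base, attributable to sequencing error). The read-level
call is maternal if only maternal votes exist, paternal if only paternal
votes exist, conflict if both, and uninformative if no site votes.
Conflict reads are excluded from the maternal/paternal totals rather than
majority-voted: with short reads and ~200 bp SNP spacing multi-SNP reads
are rare, and exclusion cannot inflate the zygotic signal.

SNP coordinates are projected from the genome onto transcript coordinates
through the gene's exon structure before any comparison, which silently
drops intronic SNPs (mRNA reads never cover them).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .io_formats import AlleleCountRow, GeneModel, SnpRecord
from .synthetic_data import CrossDesign, ReadSet, _CODE, _encode

__all__ = [
    "AlleleAssignment",
    "TranscriptSnpIndex",
    "find_overlapping_snps",
    "assign_read",
    "assign_readset",
    "tabulate_counts",
    "place_reads_exact",
    "write_assignments",
]

CALLS = ("maternal", "paternal", "conflict", "uninformative")


@dataclass(frozen=True)
class AlleleAssignment:
    """Per-read assignment outcome over the SNPs the read overlapped."""

    read_id: str
    gene_id: str
    informative_sites: int
    maternal_matches: int
    paternal_matches: int
    neither_matches: int
    call: str

    def __post_init__(self) -> None:
        if (
            self.maternal_matches + self.paternal_matches + self.neither_matches
            != self.informative_sites
        ):
            raise ValueError("site votes do not sum to informative_sites")
        if self.call not in CALLS:
            raise ValueError(f"unknown call {self.call!r}")


def _call_from_votes(m: int, p: int) -> str:
    if m > 0 and p > 0:
        return "conflict"
    if m > 0:
        return "maternal"
    if p > 0:
        return "paternal"
    return "uninformative"


class TranscriptSnpIndex:
    """SNPs per gene in transcript coordinates, ready for overlap queries.

    Built either from transcript-space SNPs (chrom = gene id, as the
    simulator emits) or from genomic SNPs plus gene models, in which case
    each SNP is projected through the exon structure and intronic SNPs are
    dropped. A :class:`CrossDesign` re-orients allele labels for
    reciprocal-cross samples before indexing.
    """

    def __init__(
        self,
        positions: dict[str, np.ndarray],
        maternal_codes: dict[str, np.ndarray],
        paternal_codes: dict[str, np.ndarray],
        transcript_lengths: dict[str, int],
    ) -> None:
        self.positions = positions
        self.maternal_codes = maternal_codes
        self.paternal_codes = paternal_codes
        self.transcript_lengths = transcript_lengths

    @classmethod
    def from_transcript_snps(
        cls,
        snps: Iterable[SnpRecord],
        transcript_lengths: Mapping[str, int],
        cross: CrossDesign | None = None,
    ) -> "TranscriptSnpIndex":
        if cross is not None:
            snps = cross.orient_snps(snps)
        per_gene: dict[str, list[tuple[int, int, int]]] = {}
        for s in snps:
            if s.chrom not in transcript_lengths:
                raise KeyError(f"SNP references unknown transcript {s.chrom!r}")
            if s.pos >= transcript_lengths[s.chrom]:
                raise ValueError(
                    f"SNP at {s.chrom}:{s.pos} beyond transcript end"
                )
            per_gene.setdefault(s.chrom, []).append(
                (s.pos, _CODE[ord(s.maternal_allele)], _CODE[ord(s.paternal_allele)])
            )
        return cls._build(per_gene, dict(transcript_lengths))

    @classmethod
    def from_genomic_snps(
        cls,
        snps: Iterable[SnpRecord],
        gene_models: Sequence[GeneModel],
        cross: CrossDesign | None = None,
    ) -> "TranscriptSnpIndex":
        if cross is not None:
            snps = cross.orient_snps(snps)
        by_chrom: dict[str, list[SnpRecord]] = {}
        for s in snps:
            by_chrom.setdefault(s.chrom, []).append(s)
        per_gene: dict[str, list[tuple[int, int, int]]] = {}
        lengths: dict[str, int] = {}
        for g in gene_models:
            lengths[g.gene_id] = g.transcript_length_nt
            hits: list[tuple[int, int, int]] = []
            for s in by_chrom.get(g.chrom, ()):
                tpos = g.project_to_transcript(s.pos)
                if tpos is not None:
                    hits.append(
                        (tpos, _CODE[ord(s.maternal_allele)], _CODE[ord(s.paternal_allele)])
                    )
            per_gene[g.gene_id] = hits
        return cls._build(per_gene, lengths)

    @classmethod
    def _build(
        cls,
        per_gene: dict[str, list[tuple[int, int, int]]],
        lengths: dict[str, int],
    ) -> "TranscriptSnpIndex":
        positions: dict[str, np.ndarray] = {}
        mat: dict[str, np.ndarray] = {}
        pat: dict[str, np.ndarray] = {}
        for gid in lengths:
            triples = sorted(per_gene.get(gid, []))
            positions[gid] = np.asarray([t[0] for t in triples], dtype=np.int64)
            mat[gid] = np.asarray([t[1] for t in triples], dtype=np.uint8)
            pat[gid] = np.asarray([t[2] for t in triples], dtype=np.uint8)
        return cls(positions, mat, pat, lengths)

    def snps_for(self, gene_id: str) -> list[SnpRecord]:
        from .synthetic_data import _BASES

        return [
            SnpRecord(
                chrom=gene_id,
                pos=int(p),
                maternal_allele=chr(_BASES[m]),
                paternal_allele=chr(_BASES[q]),
            )
            for p, m, q in zip(
                self.positions[gene_id],
                self.maternal_codes[gene_id],
                self.paternal_codes[gene_id],
            )
        ]


def find_overlapping_snps(
    gene_id: str,
    start: int,
    length: int,
    index: TranscriptSnpIndex,
) -> list[tuple[SnpRecord, int]]:
    """SNPs whose transcript coordinate lies in the half-open window
    [start, start + length), each with its offset within the read."""
    if gene_id not in index.transcript_lengths:
        raise KeyError(f"unknown gene {gene_id!r}")
    tlen = index.transcript_lengths[gene_id]
    if start < 0 or start + length > tlen:
        raise ValueError(
            f"read [{start}, {start + length}) extends outside transcript "
            f"{gene_id} of length {tlen}"
        )
    pos = index.positions[gene_id]
    lo = int(np.searchsorted(pos, start, side="left"))
    hi = int(np.searchsorted(pos, start + length, side="left"))
    snps = index.snps_for(gene_id)
    return [(snps[i], int(pos[i]) - start) for i in range(lo, hi)]


def assign_read(
    read_id: str,
    gene_id: str,
    sequence: str,
    overlaps: Sequence[tuple[SnpRecord, int]],
) -> AlleleAssignment:
    """Vote each overlapped SNP site and call the read's parent of origin."""
    codes = _encode(sequence)  # validates the alphabet
    m = p = neither = 0
    for snp, offset in overlaps:
        if not 0 <= offset < len(sequence):
            raise ValueError(f"SNP offset {offset} outside read of length {len(sequence)}")
        code = codes[offset]
        if code == _CODE[ord(snp.maternal_allele)]:
            m += 1
        elif code == _CODE[ord(snp.paternal_allele)]:
            p += 1
        else:
            neither += 1
    return AlleleAssignment(
        read_id=read_id,
        gene_id=gene_id,
        informative_sites=len(overlaps),
        maternal_matches=m,
        paternal_matches=p,
        neither_matches=neither,
        call=_call_from_votes(m, p),
    )


def assign_readset(
    readset: ReadSet,
    index: TranscriptSnpIndex,
    with_read_ids: bool = True,
) -> pd.DataFrame:
    """Assign every read in a batch; vectorised per gene.

    Returns a DataFrame with one row per read: read_id (optional), gene_id,
    informative_sites, maternal_matches, paternal_matches, neither_matches,
    call, plus the truth haplotype for validation.
    """
    n = len(readset)
    L = readset.read_length
    inf_sites = np.zeros(n, dtype=np.int64)
    m_votes = np.zeros(n, dtype=np.int64)
    p_votes = np.zeros(n, dtype=np.int64)

    for gi, gid in enumerate(readset.gene_ids):
        sel = np.flatnonzero(readset.gene_index == gi)
        if sel.size == 0:
            continue
        if gid not in index.transcript_lengths:
            raise KeyError(f"reads reference gene {gid!r} absent from the SNP index")
        pos = index.positions[gid]
        starts = readset.start[sel]
        if starts.size and (starts.min() < 0 or (starts + L).max() > index.transcript_lengths[gid]):
            raise ValueError(f"a read extends outside transcript {gid}")
        if pos.size == 0:
            continue
        lo = np.searchsorted(pos, starts, side="left")
        hi = np.searchsorted(pos, starts + L, side="left")
        cnt = hi - lo
        inf_sites[sel] = cnt
        max_cnt = int(cnt.max())
        if max_cnt == 0:
            continue
        span = np.arange(max_cnt)
        snp_mat = lo[:, None] + span
        mask = snp_mat < hi[:, None]
        read_rel, _ = np.nonzero(mask)
        snp_idx = snp_mat[mask]
        read_abs = sel[read_rel]
        offsets = pos[snp_idx] - readset.start[read_abs]
        bases = readset.seq_codes[read_abs, offsets]
        is_m = bases == index.maternal_codes[gid][snp_idx]
        is_p = bases == index.paternal_codes[gid][snp_idx]
        np.add.at(m_votes, read_abs, is_m.astype(np.int64))
        np.add.at(p_votes, read_abs, is_p.astype(np.int64))

    call = np.full(n, "uninformative", dtype=object)
    call[(m_votes > 0) & (p_votes == 0)] = "maternal"
    call[(p_votes > 0) & (m_votes == 0)] = "paternal"
    call[(m_votes > 0) & (p_votes > 0)] = "conflict"

    data = {
        "gene_id": [readset.gene_ids[g] for g in readset.gene_index],
        "informative_sites": inf_sites,
        "maternal_matches": m_votes,
        "paternal_matches": p_votes,
        "neither_matches": inf_sites - m_votes - p_votes,
        "call": call,
        "truth_haplotype": np.where(readset.haplotype == 0, "maternal", "paternal"),
    }
    if with_read_ids:
        data = {"read_id": [readset.read_id(i) for i in range(n)], **data}
    return pd.DataFrame(data)


def tabulate_counts(
    assignments: pd.DataFrame,
    stage: str,
    known_genes: Iterable[str] | None = None,
    cross: CrossDesign | None = None,
) -> list[AlleleCountRow]:
    """Collapse per-read assignments into per-gene count rows.

    M and P are the maternal- and paternal-called reads; conflict and
    uninformative reads land in ``uninformative_reads``, so totals are
    conserved. For a reciprocal-cross sample pass its :class:`CrossDesign`:
    the maternal/paternal labels swap before counting, which is how
    reciprocal samples are merged onto a common maternal axis.
    """
    if known_genes is not None:
        known = set(known_genes)
        unknown = set(assignments["gene_id"]) - known
        if unknown:
            raise KeyError(f"assignments reference unknown genes: {sorted(unknown)[:5]}")
    m_label, p_label = ("maternal", "paternal")
    if cross is not None and cross.reciprocal:
        m_label, p_label = p_label, m_label
    rows: list[AlleleCountRow] = []
    for gid, grp in assignments.groupby("gene_id", sort=True):
        calls = grp["call"].to_numpy()
        m = int((calls == m_label).sum())
        p = int((calls == p_label).sum())
        rows.append(
            AlleleCountRow(
                gene_id=str(gid),
                stage=stage,
                maternal_reads=m,
                paternal_reads=p,
                uninformative_reads=len(grp) - m - p,
            )
        )
    return rows


def place_reads_exact(
    sequences: Mapping[str, str],
    reads: Iterable[tuple[str, str]],
) -> list[tuple[str, str, int] | None]:
    """Place FASTQ-only reads by exact substring search against transcripts.

    ``reads`` yields (read_id, sequence). Returns, per read, a
    (gene_id, read_id, start) placement, or None when the read matches no
    transcript or matches ambiguously (several transcripts, or several
    positions in one). This is deliberately exact-match only: error-bearing
    reads without truth placements are outside what this placer promises.
    """
    out: list[tuple[str, str, int] | None] = []
    for read_id, seq in reads:
        hits: list[tuple[str, int]] = []
        for gid, tseq in sequences.items():
            i = tseq.find(seq)
            if i != -1:
                if tseq.find(seq, i + 1) != -1:
                    hits = [("", -1), ("", -2)]  # ambiguous within transcript
                    break
                hits.append((gid, i))
                if len(hits) > 1:
                    break
        if len(hits) == 1:
            gid, start = hits[0]
            out.append((gid, read_id, start))
        else:
            out.append(None)
    return out


def write_assignments(assignments: pd.DataFrame, path: str | Path) -> None:
    assignments.to_csv(path, sep="\t", index=False)
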