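"""RPKM computation and cross-sample normalisation.

Expression is summarised as RPKM (reads per kilobase of transcript per
million mapped reads) and samples are made comparable by rescaling each so
that its total autosomal RPKM equals a common constant — the first
sample's pre-scaling total, which makes the output reproducible without
changing anything that matters (any constant would do). X-linked genes are
carried along by their sample's factor but never enter the constraint,
because X dosage differs between stages and sexes while autosomes do not.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

from .io_formats import GeneModel

__all__ = ["SampleQuant", "rpkm", "normalize_autosomal"]


def rpkm(gene_read_count: float, transcript_length_nt: int, total_mapped_reads: int) -> float:
    """count / ((length/1000) * (total/1e6))."""
    if transcript_length_nt <= 0:
        raise ValueError("transcript_length_nt must be > 0")
    if total_mapped_reads <= 0:
        raise ValueError("total_mapped_reads must be > 0")
    if gene_read_count < 0:
        raise ValueError("gene_read_count must be >= 0")
    return gene_read_count / ((transcript_length_nt / 1e3) * (total_mapped_reads / 1e6))


@dataclass
class SampleQuant:
    """Per-sample quantification: raw counts, RPKM, and the scale factor
    applied by :func:`normalize_autosomal` (1.0 until normalised)."""

    stage: str
    counts: dict[str, float]
    rpkm: dict[str, float] = field(default_factory=dict)
    scale_factor: float = 1.0

    @classmethod
    def from_counts(
        cls,
        stage: str,
        counts: Mapping[str, float],
        gene_models: Mapping[str, GeneModel],
        total_mapped_reads: int | None = None,
    ) -> "SampleQuant":
        """Build RPKMs from raw counts. ``total_mapped_reads`` defaults to the
        sum of the counts themselves (all mapped reads are in the table)."""
        total = int(total_mapped_reads) if total_mapped_reads else int(sum(counts.values()))
        vals = {
            gid: rpkm(c, gene_models[gid].transcript_length_nt, total)
            for gid, c in counts.items()
        }
        return cls(stage=stage, counts=dict(counts), rpkm=vals)

    def autosomal_total(self, gene_models: Mapping[str, GeneModel]) -> float:
        return sum(
            v for gid, v in self.rpkm.items() if gene_models[gid].is_autosomal
        )


def normalize_autosomal(
    samples: Sequence[SampleQuant],
    gene_models: Mapping[str, GeneModel],
) -> list[float]:
    """Scale samples so the autosomal RPKM total is constant across them.

    The constant is the first sample's pre-scaling autosomal total. All
    genes (X-linked included) are multiplied by their sample's factor;
    only autosomal genes define it. Mutates the samples in place and
    returns the factors. Idempotent: renormalising yields factors of 1.
    """
    if not samples:
        raise ValueError("need at least one sample")
    totals = []
    for s in samples:
        t = s.autosomal_total(gene_models)
        if t <= 0:
            raise ValueError(
                f"sample {s.stage!r} has no autosomal signal; cannot normalise"
            )
        totals.append(t)
    target = totals[0]
    factors = [target / t for t in totals]
    for s, f in zip(samples, factors):
        s.rpkm = {gid: v * f for gid, v in s.rpkm.items()}
        s.scale_factor *= f
    return factors
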