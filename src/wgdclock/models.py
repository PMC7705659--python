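"""Shared domain types.

Most result types live next to the code that produces them; this module
holds only :class:`GeneModel`, which is consumed by nearly every stage
(simulation, GFF3 IO, synteny detection, annotation statistics).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Mapping


@dataclass(frozen=True)
class GeneModel:
    """One annotated protein-coding gene.

    Parameters
    ----------
    gene_id : str
        Unique identifier.
    seq_id : str
        Chromosome / scaffold the gene sits on.
    start, end : int
        1-based inclusive coordinates, ``start <= end``.
    strand : str
        ``"+"`` or ``"-"``.
    rank : int
        0-based ordinal among the genes of ``seq_id`` sorted by ``start``.
        Collinearity is chained on ranks, not base-pair coordinates.
    cds : str, optional
        Spliced coding sequence (5'->3' on the coding strand).
    exon_count : int, optional
        Number of exons; used only by annotation statistics.
    """

    gene_id: str
    seq_id: str
    start: int
    end: int
    strand: str
    rank: int
    cds: str | None = None
    exon_count: int | None = None

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"{self.gene_id}: start {self.start} > end {self.end}")
        if self.strand not in ("+", "-"):
            raise ValueError(f"{self.gene_id}: bad strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    def with_cds(self, cds: str) -> "GeneModel":
        return replace(self, cds=cds)


def assign_ranks(genes: Iterable[GeneModel]) -> list[GeneModel]:
    """Recompute 0-based ranks per ``seq_id`` from start coordinates.

    Ties on ``start`` are broken by ``gene_id`` so the ordering is total.
    """
    out: list[GeneModel] = []
    by_seq: dict[str, list[GeneModel]] = {}
    for g in genes:
        by_seq.setdefault(g.seq_id, []).append(g)
    for seq_id in sorted(by_seq):
        ordered = sorted(by_seq[seq_id], key=lambda g: (g.start, g.gene_id))
        for i, g in enumerate(ordered):
            out.append(replace(g, rank=i))
    return out


def gene_index(genes: Iterable[GeneModel]) -> Mapping[str, GeneModel]:
    """Index genes by ``gene_id``; duplicate ids are an annotation bug."""
    idx: dict[str, GeneModel] = {}
    for g in genes:
        if g.gene_id in idx:
            raise ValueError(f"duplicate gene_id {g.gene_id}")
        idx[g.gene_id] = g
    return idx
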