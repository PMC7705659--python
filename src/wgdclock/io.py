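"""Readers and writers for the plain-text formats the pipeline speaks.

FASTA goes through Biopython, GFF3 through gffutils, tables through pandas.
All writers emit records in deterministic (sorted or input) order so that a
fixed simulation seed yields byte-identical files.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Mapping

import gffutils
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .models import GeneModel, assign_ranks

#: column names of the de-facto 12-column tabular alignment format
HIT_COLUMNS = [
    "query_id",
    "subject_id",
    "pct_identity",
    "length",
    "mismatches",
    "gap_opens",
    "q_start",
    "q_end",
    "s_start",
    "s_end",
    "e_value",
    "score",
]


# ---------------------------------------------------------------- FASTA

def read_fasta(path: str | Path) -> dict[str, str]:
    """Read a FASTA file into an ``{id: sequence}`` dict (insertion-ordered)."""
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(records: Mapping[str, str], path: str | Path, width: int = 60) -> None:
    recs = [
        SeqRecord(Seq(seq), id=name, description="") for name, seq in records.items()
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(recs)


# ---------------------------------------------------------------- GFF3

def read_gff3_genes(path: str | Path) -> list[GeneModel]:
    """Load ``gene`` features from a GFF3 file as ranked :class:`GeneModel`.

    Ranks are recomputed from coordinates, so any upstream ordering is fine.
    """
    db = gffutils.create_db(
        str(path), ":memory:", force=True, keep_order=True, merge_strategy="error"
    )
    genes = []
    for feat in db.features_of_type("gene"):
        gid = feat.attributes.get("ID", [feat.id])[0]
        genes.append(
            GeneModel(
                gene_id=gid,
                seq_id=feat.seqid,
                start=feat.start,
                end=feat.end,
                strand=feat.strand if feat.strand in "+-" else "+",
                rank=-1,
            )
        )
    return assign_ranks(genes)


def write_gff3(genes: Iterable[GeneModel], path: str | Path, source: str = "wgdclock") -> None:
    """Write genes as 1-based inclusive GFF3 ``gene`` features with ID attrs."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in sorted(genes, key=lambda g: (g.seq_id, g.start, g.gene_id)):
            fh.write(
                f"{g.seq_id}\t{source}\tgene\t{g.start}\t{g.end}\t.\t{g.strand}\t.\t"
                f"ID={g.gene_id}\n"
            )


# ---------------------------------------------------------------- hit tables

def read_hits_table(path: str | Path) -> pd.DataFrame:
    """Read a 12-column tabular homology-hit file (BLAST ``outfmt 6`` layout)."""
    df = pd.read_csv(path, sep="\t", header=None, names=HIT_COLUMNS, comment="#")
    return df


def write_hits_table(hits: pd.DataFrame, path: str | Path) -> None:
    cols = [c for c in HIT_COLUMNS if c in hits.columns]
    hits.to_csv(path, sep="\t", header=False, index=False, columns=cols)


# ---------------------------------------------------------------- block files

def write_blocks(blocks, path: str | Path) -> None:
    """Write collinear blocks: one ``#block`` header line then one anchor/line."""
    with open(path, "w") as fh:
        for b in blocks:
            fh.write(
                f"#block\t{b.block_id}\t{b.seq_pair[0]}\t{b.seq_pair[1]}\t"
                f"{b.orientation}\t{b.score:.6g}\t{b.n_anchors}\n"
            )
            for gene_a, gene_b, rank_a, rank_b in b.anchors:
                fh.write(f"{gene_a}\t{gene_b}\t{rank_a}\t{rank_b}\n")


def read_blocks(path: str | Path):
    from .synteny import CollinearBlock  # local import: avoid cycle

    blocks = []
    header = None
    anchors: list[tuple[str, str, int, int]] = []

    def flush():
        if header is not None:
            bid, sa, sb, orient, score, _n = header
            blocks.append(
                CollinearBlock(
                    block_id=bid,
                    seq_pair=(sa, sb),
                    anchors=list(anchors),
                    orientation=orient,
                    score=float(score),
                )
            )

    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("#block\t"):
                flush()
                header = line.split("\t")[1:]
                anchors = []
            else:
                qa, qb, ra, rb = line.split("\t")
                anchors.append((qa, qb, int(ra), int(rb)))
        flush()
    return blocks


# ---------------------------------------------------------------- misc tables

def read_expression(path: str | Path) -> pd.DataFrame:
    """Genes x samples TSV with gene ids in the first column."""
    return pd.read_csv(path, sep="\t", index_col=0)


def read_kmer_histogram(path: str | Path) -> pd.DataFrame:
    """2-column (depth, count) TSV, no header required."""
    df = pd.read_csv(path, sep="\t", header=None, names=["depth", "count"], comment="#")
    return df


def read_ltr_pairs_fasta(path: str | Path) -> dict[str, tuple[str, str]]:
    """Pair up LTR sequences whose ids end in ``_5LTR`` / ``_3LTR``.

    Returns ``{element_id: (ltr5, ltr3)}``; unpaired records raise.
    """
    seqs = read_fasta(path)
    five: dict[str, str] = {}
    three: dict[str, str] = {}
    for name, seq in seqs.items():
        if name.endswith("_5LTR"):
            five[name[:-5]] = seq
        elif name.endswith("_3LTR"):
            three[name[:-5]] = seq
        else:
            raise ValueError(f"LTR record {name!r} lacks _5LTR/_3LTR suffix")
    if set(five) != set(three):
        missing = set(five) ^ set(three)
        raise ValueError(f"unpaired LTR elements: {sorted(missing)}")
    return {eid: (five[eid], three[eid]) for eid in sorted(five)}


def read_config(path: str | Path) -> dict[str, str]:
    """Flat ``key=value`` config file (one pair per line, # comments)."""
    out: dict[str, str] = {}
    for line in Path(path).read_text().splitlines():
        line = line.split("#", 1)[0].strip()
        if not line:
            continue
        key, _, val = line.partition("=")
        out[key.strip()] = val.strip()
    return out
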