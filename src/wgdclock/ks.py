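"""Protein-guided codon alignment and Nei-Gojobori (1986) Ka/Ks estimation.

The NG86 estimator counts, per codon, fractional synonymous (S) and
nonsynonymous (N) sites by enumerating the three possible single-nucleotide
changes at each position (changes producing stop codons are excluded from
both numerator and denominator), and counts synonymous/nonsynonymous
differences (Sd, Nd) between codon pairs by averaging over all minimal
mutational pathways with equal weights, excluding pathways through stop
codons. Proportions ps = Sd/S and pn = Nd/N are Jukes-Cantor corrected:
Ks = -(3/4) ln(1 - (4/3) ps), Ka likewise. Site counts are averaged between
the two sequences (the standard NG86 convention; fixed, not configurable).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import permutations
from typing import Mapping, Sequence

import pandas as pd
from Bio import Align
from Bio.Data import CodonTable
from Bio.Seq import Seq
from Bio.Align import substitution_matrices

BASES = "ACGT"
_TABLE = CodonTable.unambiguous_dna_by_id[1]
STOP_CODONS = frozenset(_TABLE.stop_codons)
SENSE_CODONS = tuple(sorted(_TABLE.forward_table))


def _aa(codon: str) -> str:
    return _TABLE.forward_table[codon]


@dataclass(frozen=True)
class CodonAlignment:
    """A pair of gap-aware codon strings of equal aligned length."""

    pair: tuple[str, str]
    codons_a: tuple[str, ...]
    codons_b: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.codons_a) != len(self.codons_b):
            raise ValueError("aligned codon lengths differ")


@dataclass
class KsRecord:
    """NG86 site/difference counts and distances for one gene pair."""

    pair: tuple[str, str]
    S: float = 0.0
    N: float = 0.0
    Sd: float = 0.0
    Nd: float = 0.0
    ps: float = float("nan")
    pn: float = float("nan")
    Ks: float = float("nan")
    Ka: float = float("nan")
    omega: float = float("nan")
    n_codons: int = 0
    valid: bool = False
    reason: str = ""


# ------------------------------------------------------------------ NG86 tables

_SITE_CACHE: dict[str, tuple[float, float]] = {}
_DIFF_CACHE: dict[tuple[str, str], tuple[float, float]] = {}


def _site_counts(codon: str) -> tuple[float, float]:
    """Fractional (synonymous, nonsynonymous) site counts of one codon."""
    try:
        return _SITE_CACHE[codon]
    except KeyError:
        pass
    s = n = 0.0
    for pos in range(3):
        syn = non = 0
        for base in BASES:
            if base == codon[pos]:
                continue
            mutant = codon[:pos] + base + codon[pos + 1 :]
            if mutant in STOP_CODONS:
                continue  # stop-codon changes excluded from both counts
            if _aa(mutant) == _aa(codon):
                syn += 1
            else:
                non += 1
        total = syn + non
        if total:
            s += syn / total
            n += non / total
    _SITE_CACHE[codon] = (s, n)
    return s, n


def _pathway_counts(c1: str, c2: str) -> tuple[float, float]:
    """(Sd, Nd) between two sense codons, averaged over minimal pathways.

    Pathways passing through stop codons are excluded; in the degenerate
    case where every pathway is blocked, all pathways are used with steps
    into/out of stop codons counted as nonsynonymous.
    """
    key = (c1, c2)
    try:
        return _DIFF_CACHE[key]
    except KeyError:
        pass
    diff_pos = [i for i in range(3) if c1[i] != c2[i]]
    if not diff_pos:
        _DIFF_CACHE[key] = (0.0, 0.0)
        return 0.0, 0.0

    def walk(order, allow_stops: bool):
        syn = non = 0.0
        cur = c1
        for pos in order:
            nxt = cur[:pos] + c2[pos] + cur[pos + 1 :]
            if nxt in STOP_CODONS:
                if not allow_stops:
                    return None
                non += 1.0
            elif cur in STOP_CODONS:
                non += 1.0
            elif _aa(nxt) == _aa(cur):
                syn += 1.0
            else:
                non += 1.0
            cur = nxt
        return syn, non

    paths = [walk(order, False) for order in permutations(diff_pos)]
    valid = [p for p in paths if p is not None]
    if not valid:
        valid = [walk(order, True) for order in permutations(diff_pos)]
    sd = sum(p[0] for p in valid) / len(valid)
    nd = sum(p[1] for p in valid) / len(valid)
    _DIFF_CACHE[key] = (sd, nd)
    return sd, nd


def jukes_cantor(p: float) -> float:
    """JC69 multiple-hit correction of a proportion of differing sites."""
    if p < 0:
        raise ValueError("proportion must be >= 0")
    arg = 1.0 - 4.0 * p / 3.0
    if arg <= 0:
        return float("nan")
    return -0.75 * math.log(arg)


# ------------------------------------------------------------------ alignment

_aligner: Align.PairwiseAligner | None = None


def _protein_aligner() -> Align.PairwiseAligner:
    global _aligner
    if _aligner is None:
        _aligner = Align.PairwiseAligner()
        _aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
        _aligner.open_gap_score = -10.0
        _aligner.extend_gap_score = -0.5
        _aligner.mode = "global"
    return _aligner


class PairSkipped(ValueError):
    """Raised when a gene pair cannot be codon-aligned (reason in args)."""


def _strip_stop(cds: str) -> str:
    if len(cds) % 3:
        raise PairSkipped("CDS length not a multiple of 3")
    if cds[-3:].upper() in STOP_CODONS:
        cds = cds[:-3]
    return cds.upper()


def _check_cds(cds: str, protein: str | None) -> str:
    cds = _strip_stop(cds)
    prot = str(Seq(cds).translate())
    if "*" in prot:
        raise PairSkipped("internal stop codon")
    if protein is not None and prot != protein.upper().rstrip("*"):
        raise PairSkipped("CDS does not translate to the given protein")
    return cds


def align_pair(
    protein_a: str | None,
    protein_b: str | None,
    cds_a: str,
    cds_b: str,
    pair: tuple[str, str] = ("A", "B"),
) -> CodonAlignment:
    """Globally align two proteins and back-translate onto their CDS.

    Proteins may be ``None``, in which case they are derived by translating
    the CDS. Gaps are introduced in whole-codon units only.
    """
    cds_a = _check_cds(cds_a, protein_a)
    cds_b = _check_cds(cds_b, protein_b)
    pa = str(Seq(cds_a).translate())
    pb = str(Seq(cds_b).translate())
    aln = _protein_aligner().align(pa, pb)[0]
    codons_a: list[str] = []
    codons_b: list[str] = []
    ia = ib = 0
    for col_a, col_b in zip(aln[0], aln[1]):
        if col_a == "-":
            codons_a.append("---")
        else:
            codons_a.append(cds_a[3 * ia : 3 * ia + 3])
            ia += 1
        if col_b == "-":
            codons_b.append("---")
        else:
            codons_b.append(cds_b[3 * ib : 3 * ib + 3])
            ib += 1
    return CodonAlignment(pair=pair, codons_a=tuple(codons_a), codons_b=tuple(codons_b))


# ------------------------------------------------------------------ estimator

def ng86(aln: CodonAlignment, min_codons: int = 30) -> KsRecord:
    """NG86 Ka/Ks for one codon alignment.

    Columns with gaps or ambiguous nucleotides are dropped pairwise. Records
    with fewer than ``min_codons`` ungapped columns, zero synonymous sites,
    or saturated proportions (ps or pn >= 3/4) are flagged invalid.
    """
    rec = KsRecord(pair=aln.pair)
    s1 = s2 = n1 = n2 = sd = nd = 0.0
    n_cols = 0
    for ca, cb in zip(aln.codons_a, aln.codons_b):
        if "-" in ca or "-" in cb:
            continue
        if set(ca) - set(BASES) or set(cb) - set(BASES):
            continue
        if ca in STOP_CODONS or cb in STOP_CODONS:
            continue
        n_cols += 1
        sa, na = _site_counts(ca)
        sb, nb = _site_counts(cb)
        s1 += sa
        n1 += na
        s2 += sb
        n2 += nb
        d_s, d_n = _pathway_counts(ca, cb)
        sd += d_s
        nd += d_n
    rec.n_codons = n_cols
    rec.S = (s1 + s2) / 2.0
    rec.N = (n1 + n2) / 2.0
    rec.Sd = sd
    rec.Nd = nd
    if n_cols < min_codons:
        rec.reason = "too_short"
        return rec
    if rec.S <= 0:
        rec.reason = "no_synonymous_sites"
        return rec
    rec.ps = rec.Sd / rec.S
    rec.pn = rec.Nd / rec.N if rec.N > 0 else float("nan")
    if rec.ps >= 0.75 or (rec.N > 0 and rec.pn >= 0.75):
        rec.reason = "saturated"
        return rec
    rec.Ks = jukes_cantor(rec.ps)
    rec.Ka = jukes_cantor(rec.pn) if rec.N > 0 else float("nan")
    rec.omega = rec.Ka / rec.Ks if rec.Ks > 0 else float("nan")
    rec.valid = True
    return rec


def ks_for_pair(
    cds_a: str, cds_b: str, pair: tuple[str, str] = ("A", "B"), min_codons: int = 30
) -> KsRecord:
    """Convenience: align two CDS and run NG86."""
    try:
        aln = align_pair(None, None, cds_a, cds_b, pair=pair)
    except PairSkipped as exc:
        rec = KsRecord(pair=pair)
        rec.reason = str(exc)
        return rec
    return ng86(aln, min_codons=min_codons)


def ks_for_blocks(
    blocks: Sequence,
    cds_store: Mapping[str, str],
    min_codons: int = 30,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """NG86 for every anchor of every collinear block.

    Returns ``(records, per_block)``: one row per anchor (invalid rows carry
    a reason; anchors with missing CDS are counted as skipped), and a
    per-block table with the median Ks over valid records.
    """
    rows = []
    for blk in blocks:
        for gene_a, gene_b, _ra, _rb in blk.anchors:
            if gene_a not in cds_store or gene_b not in cds_store:
                rows.append(
                    {
                        "block_id": blk.block_id,
                        "gene_a": gene_a,
                        "gene_b": gene_b,
                        "valid": False,
                        "reason": "missing_cds",
                    }
                )
                continue
            rec = ks_for_pair(
                cds_store[gene_a], cds_store[gene_b], (gene_a, gene_b), min_codons
            )
            rows.append(
                {
                    "block_id": blk.block_id,
                    "gene_a": gene_a,
                    "gene_b": gene_b,
                    "S": rec.S,
                    "N": rec.N,
                    "Sd": rec.Sd,
                    "Nd": rec.Nd,
                    "ps": rec.ps,
                    "pn": rec.pn,
                    "Ka": rec.Ka,
                    "Ks": rec.Ks,
                    "omega": rec.omega,
                    "n_codons": rec.n_codons,
                    "valid": rec.valid,
                    "reason": rec.reason,
                }
            )
    records = pd.DataFrame(rows)
    if records.empty:
        return records, pd.DataFrame(columns=["block_id", "n_anchors", "n_valid", "median_ks"])
    grp = records.groupby("block_id", sort=True)
    per_block = grp.apply(
        lambda df: pd.Series(
            {
                "n_anchors": len(df),
                "n_valid": int(df["valid"].sum()),
                "median_ks": df.loc[df["valid"], "Ks"].median()
                if df["valid"].any()
                else float("nan"),
            }
        ),
        include_groups=False,
    ).reset_index()
    return records, per_block
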