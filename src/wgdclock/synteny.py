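"""Homology-hit filtering and collinear-block detection between two genomes.

The chaining stage re-implements the classic collinearity search used by
tools of the MCScanX/ColinearScan family: homologous gene pairs are placed on
the (rank_A, rank_B) plane and maximal-scoring chains with bounded rank gaps
are extracted per chromosome pair and orientation by dynamic programming on a
weighted DAG. Anchors within a block are strictly monotone in both genomes
(increasing/increasing for ``same`` orientation, increasing/decreasing for
``inverted``), and a gene pair belongs to at most one block.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import Align
from Bio.Align import substitution_matrices

from .models import GeneModel, gene_index

#: nominal gapped Karlin-Altschul parameters for the surrogate e-value of the
#: builtin scorer. These are fixed constants: the surrogate is a monotone
#: transform of the alignment score for ranking/thresholding within this
#: package and is NOT comparable to e-values of any external search tool.
KA_LAMBDA = 0.267
KA_K = 0.041


@dataclass(frozen=True)
class HomologyHit:
    query_id: str
    subject_id: str
    score: float
    e_value: float


@dataclass
class CollinearBlock:
    """An ordered chain of homologous gene pairs between two sequences."""

    block_id: str
    seq_pair: tuple[str, str]
    anchors: list[tuple[str, str, int, int]]  # (gene_a, gene_b, rank_a, rank_b)
    orientation: str  # "same" | "inverted"
    score: float

    @property
    def n_anchors(self) -> int:
        return len(self.anchors)

    def __post_init__(self) -> None:
        ra = [a[2] for a in self.anchors]
        rb = [a[3] for a in self.anchors]
        if any(y <= x for x, y in zip(ra, ra[1:])):
            raise ValueError(f"{self.block_id}: rank_A not strictly increasing")
        if self.orientation == "same":
            ok = all(y > x for x, y in zip(rb, rb[1:]))
        else:
            ok = all(y < x for x, y in zip(rb, rb[1:]))
        if not ok:
            raise ValueError(f"{self.block_id}: rank_B not monotone for {self.orientation}")


# ------------------------------------------------------------------ filtering

def filter_hits(
    hits: pd.DataFrame,
    e_max: float = 1e-5,
    best_n: int | None = None,
) -> pd.DataFrame:
    """Filter a homology-hit table.

    Keeps hits with ``e_value <= e_max``, drops self-hits, and caps the
    number of hits per query at ``best_n`` by descending score (ties broken
    by subject id, lexicographic). Columns required: ``query_id``,
    ``subject_id``, ``score``, ``e_value``.
    """
    if hits.empty:
        return hits.copy()
    out = hits[hits["e_value"] <= e_max]
    out = out[out["query_id"] != out["subject_id"]]
    out = out.sort_values(
        ["query_id", "score", "subject_id"], ascending=[True, False, True]
    )
    if best_n is not None and math.isfinite(best_n):
        out = out.groupby("query_id", sort=False).head(int(best_n))
    return out.reset_index(drop=True)


# ------------------------------------------------------------------ builtin scorer

def _kmer_set(seq: str, k: int) -> set[str]:
    return {seq[i : i + k] for i in range(len(seq) - k + 1)}


def _make_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -10.0
    aligner.extend_gap_score = -0.5
    aligner.mode = "global"
    return aligner

_AA = set("ACDEFGHIKLMNPQRSTVWY")


def score_homologs_builtin(
    proteins_a: Mapping[str, str],
    proteins_b: Mapping[str, str],
    k: int = 8,
    min_shared_kmers: int | None = None,
    min_score_ratio: float = 0.35,
    self_comparison: bool | None = None,
) -> pd.DataFrame:
    """All-vs-all protein homology scoring without an external aligner.

    Candidate pairs sharing enough k-mers are scored; by default the
    threshold adapts to the shorter sequence (2 shared k-mers below 300
    residues, up to 4 for long proteins — random k-mer sharing grows with
    the length product, homologous sharing with the length), or pass
    ``min_shared_kmers`` to fix it. Candidates are then scored
    by global alignment (BLOSUM62, affine gaps); a surrogate e-value is
    derived from the score via a Karlin-Altschul form with fixed nominal
    parameters (see :data:`KA_LAMBDA`/:data:`KA_K`) — it orders hits
    consistently with the score but is not calibrated against any database
    search. Because global alignment of equal-length unrelated sequences can
    score positively on composition alone, hits must also reach
    ``min_score_ratio`` of the smaller self-alignment score (a bit-score-
    ratio-style homology filter). When ``proteins_a is proteins_b`` (self
    comparison) each unordered pair is reported once, ids in lexicographic
    order.
    """
    if self_comparison is None:
        self_comparison = proteins_a is proteins_b

    def clean(prots: Mapping[str, str], label: str) -> dict[str, str]:
        ok = {}
        for name, seq in prots.items():
            if set(seq) - _AA:
                import warnings

                warnings.warn(f"{label} record {name}: non-amino-acid symbols, skipped")
                continue
            ok[name] = seq
        return ok

    pa = clean(proteins_a, "A")
    pb = pa if self_comparison else clean(proteins_b, "B")

    index: dict[str, list[str]] = {}
    for name, seq in pb.items():
        for km in _kmer_set(seq, k):
            index.setdefault(km, []).append(name)

    aligner = _make_aligner()
    self_scores: dict[str, float] = {}

    def self_score(name: str, seq: str) -> float:
        if name not in self_scores:
            self_scores[name] = float(aligner.score(seq, seq))
        return self_scores[name]

    rows = []
    for qname in sorted(pa):
        qseq = pa[qname]
        counts: dict[str, int] = {}
        for km in _kmer_set(qseq, k):
            for sname in index.get(km, ()):
                counts[sname] = counts.get(sname, 0) + 1
        for sname in sorted(counts):
            if min_shared_kmers is not None:
                threshold = min_shared_kmers
            else:
                min_len = min(len(qseq), len(pb[sname]))
                threshold = max(2, min(4, min_len // 100))
            if counts[sname] < threshold:
                continue
            if self_comparison and sname <= qname:
                continue  # no self-hits; report each unordered pair once
            score = float(aligner.score(qseq, pb[sname]))
            floor = min_score_ratio * min(
                self_score(qname, qseq), self_score(sname, pb[sname])
            )
            if score < floor:
                continue
            e_val = KA_K * len(qseq) * len(pb[sname]) * math.exp(-KA_LAMBDA * max(score, 0.0))
            rows.append((qname, sname, score, e_val))
    return pd.DataFrame(rows, columns=["query_id", "subject_id", "score", "e_value"])


# ------------------------------------------------------------------ tandem collapse

def collapse_tandems(
    hits: pd.DataFrame,
    genes_a: Mapping[str, GeneModel],
    genes_b: Mapping[str, GeneModel],
    max_rank_gap: int = 2,
) -> pd.DataFrame:
    """Collapse tandem arrays to their highest-scoring member.

    A tandem array shows up as several near-adjacent genes of one genome
    (rank distance <= ``max_rank_gap`` on the same sequence) all hitting the
    same partner gene; only the best-scoring member per array is kept.
    Prevents a single homology relation from inflating chain scores.
    """
    if hits.empty:
        return hits.copy()

    rows = hits.reset_index(drop=True)
    keep_mask = np.ones(len(rows), dtype=bool)
    for side, gene_col, genes in (("s", "query_id", genes_a), ("q", "subject_id", genes_b)):
        partner_col = "subject_id" if gene_col == "query_id" else "query_id"
        for _, grp in rows[keep_mask].groupby(partner_col, sort=False):
            anno = sorted(
                (genes[g].seq_id, genes[g].rank, sc, g, idx)
                for idx, g, sc in zip(grp.index, grp[gene_col], grp["score"])
            )
            cluster: list[tuple] = []
            for item in anno:
                if cluster and item[0] == cluster[-1][0] and item[1] - cluster[-1][1] <= max_rank_gap:
                    cluster.append(item)
                else:
                    _drop_losers(cluster, keep_mask)
                    cluster = [item]
            _drop_losers(cluster, keep_mask)
    return rows[keep_mask].reset_index(drop=True)


def _drop_losers(cluster: list[tuple], keep_mask: np.ndarray) -> None:
    if len(cluster) <= 1:
        return
    winner = max(cluster, key=lambda t: (t[2], t[3]))
    for item in cluster:
        if item is not winner:
            keep_mask[item[4]] = False


# ------------------------------------------------------------------ chaining

def _best_chain(
    points: list[tuple[int, int, float, int]],
    max_gap: int,
    gap_penalty: float,
) -> tuple[float, list[int]]:
    """Maximum-score chain over (rank_a, rank_b, score, idx) points.

    Edges require 0 < d_a <= max_gap and 0 < d_b <= max_gap (callers encode
    the inverted orientation by negating rank_b); edge cost is
    ``gap_penalty * (d_a + d_b - 2)``. Returns (score, point indices).
    """
    if not points:
        return -math.inf, []
    pts = sorted(points, key=lambda p: (p[0], p[1]))
    n = len(pts)
    best = [p[2] for p in pts]
    prev = [-1] * n
    for j in range(n):
        aj, bj, sj, _ = pts[j]
        for i in range(j - 1, -1, -1):
            ai, bi, _, _ = pts[i]
            da = aj - ai
            if da > max_gap:
                break  # pts sorted by rank_a: all earlier i are further away? not strictly; see below
            if da <= 0:
                continue
            db = bj - bi
            if db <= 0 or db > max_gap:
                continue
            cand = best[i] + sj - gap_penalty * (da + db - 2)
            if cand > best[j] + 1e-12:
                best[j] = cand
                prev[j] = i
    # NOTE on the early break: pts are sorted by rank_a ascending, so walking
    # i downward from j-1 gives non-increasing rank_a; once da > max_gap every
    # smaller i also violates the gap bound.
    j = int(np.argmax(best))
    # deterministic tie-break: smallest index among maxima (argmax does this)
    chain = []
    while j != -1:
        chain.append(pts[j][3])
        j = prev[j]
    chain.reverse()
    return float(max(best)), chain


def detect_collinear_blocks(
    hits: pd.DataFrame,
    genes_a: Sequence[GeneModel] | Mapping[str, GeneModel],
    genes_b: Sequence[GeneModel] | Mapping[str, GeneModel],
    max_gap: int = 25,
    min_block_size: int = 5,
    gap_penalty: float = 1.0,
    collapse_tandem: bool = True,
) -> list[CollinearBlock]:
    """Chain filtered homology hits into collinear blocks.

    Per sequence pair, maximal-scoring chains are peeled off iteratively
    (best chain first, its gene pairs removed) for both orientations until no
    chain of at least ``min_block_size`` anchors remains.
    """
    idx_a = genes_a if isinstance(genes_a, Mapping) else gene_index(genes_a)
    idx_b = genes_b if isinstance(genes_b, Mapping) else gene_index(genes_b)
    _check_ranks(idx_a)
    if idx_b is not idx_a:
        _check_ranks(idx_b)

    missing = [
        g
        for g in pd.concat([hits["query_id"], hits["subject_id"]]).unique()
        if g not in idx_a and g not in idx_b
    ]
    if missing:
        raise KeyError(f"hits reference unknown genes, e.g. {missing[:3]}")

    if collapse_tandem and not hits.empty:
        hits = collapse_tandems(hits, idx_a, idx_b)

    # bucket hits by sequence pair
    self_cmp = idx_b is idx_a
    buckets: dict[tuple[str, str], list[tuple[int, int, float, tuple]]] = {}
    for q, s, score in zip(hits["query_id"], hits["subject_id"], hits["score"]):
        ga, gb = idx_a.get(q), idx_b.get(s)
        if ga is None or gb is None:
            ga, gb = idx_a.get(s), idx_b.get(q)
            q, s = s, q
        if self_cmp and (gb.seq_id, gb.rank) < (ga.seq_id, ga.rank):
            # canonical orientation so a chromosome pair lands in one bucket
            q, s, ga, gb = s, q, gb, ga
        key = (ga.seq_id, gb.seq_id)
        buckets.setdefault(key, []).append((ga.rank, gb.rank, float(score), (q, s)))

    blocks: list[CollinearBlock] = []
    counter = 0
    for key in sorted(buckets):
        pool = {p[3]: p for p in buckets[key]}
        while pool:
            pts = [(ra, rb, sc, pair) for (ra, rb, sc, pair) in pool.values()]
            same_pts = [(ra, rb, sc, pair) for ra, rb, sc, pair in pts]
            inv_pts = [(ra, -rb, sc, pair) for ra, rb, sc, pair in pts]
            s_score, s_chain = _best_chain(same_pts, max_gap, gap_penalty)
            i_score, i_chain = _best_chain(inv_pts, max_gap, gap_penalty)
            if max(len(s_chain), len(i_chain)) < min_block_size:
                break
            # prefer the higher score; ties go to 'same', then longer chain
            if len(s_chain) >= min_block_size and (
                s_score >= i_score or len(i_chain) < min_block_size
            ):
                orientation, chain, score = "same", s_chain, s_score
            else:
                orientation, chain, score = "inverted", i_chain, i_score
            counter += 1
            anchors = []
            for pair in chain:
                ra, rb, sc, _ = pool.pop(pair)
                anchors.append((pair[0], pair[1], ra, rb))
            blocks.append(
                CollinearBlock(
                    block_id=f"b{counter:04d}",
                    seq_pair=key,
                    anchors=anchors,
                    orientation=orientation,
                    score=score,
                )
            )
    return blocks


def _check_ranks(idx: Mapping[str, GeneModel]) -> None:
    per_seq: dict[str, list[int]] = {}
    for g in idx.values():
        per_seq.setdefault(g.seq_id, []).append(g.rank)
    for seq_id, ranks in per_seq.items():
        if len(set(ranks)) != len(ranks):
            raise ValueError(f"duplicate gene ranks on {seq_id} (annotation bug)")


# ------------------------------------------------------------------ dotplot

def dotplot_table(
    blocks: Sequence[CollinearBlock],
    genes_a: Sequence[GeneModel] | Mapping[str, GeneModel],
    genes_b: Sequence[GeneModel] | Mapping[str, GeneModel],
) -> pd.DataFrame:
    """One row per anchor with cumulative-rank coordinates for dotplotting.

    Sequences are laid out in sorted seq_id order on each axis; ``x``/``y``
    are genome-wide cumulative ranks of the anchor genes.
    """
    if not blocks:
        raise ValueError("no blocks to tabulate")
    idx_a = genes_a if isinstance(genes_a, Mapping) else gene_index(genes_a)
    idx_b = genes_b if isinstance(genes_b, Mapping) else gene_index(genes_b)

    def offsets(idx) -> dict[str, int]:
        sizes: dict[str, int] = {}
        for g in idx.values():
            sizes[g.seq_id] = max(sizes.get(g.seq_id, 0), g.rank + 1)
        off, cum = {}, 0
        for seq_id in sorted(sizes):
            off[seq_id] = cum
            cum += sizes[seq_id]
        return off

    off_a, off_b = offsets(idx_a), offsets(idx_b)
    rows = []
    for b in blocks:
        sa, sb = b.seq_pair
        for gene_a, gene_b, ra, rb in b.anchors:
            rows.append(
                (b.block_id, gene_a, gene_b, off_a[sa] + ra, off_b[sb] + rb, b.orientation)
            )
    return pd.DataFrame(
        rows, columns=["block_id", "gene_a", "gene_b", "x", "y", "orientation"]
    )
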