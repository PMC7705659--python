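"""Independent brute-force oracles used to validate the fast implementations.

Deliberately naive: direct enumeration, translation via Bio.Seq at every
step, no caching, no shared code with the package.
"""

from __future__ import annotations

import math

from Bio.Seq import Seq

BASES = "ACGT"


def _tr(codon: str) -> str:
    return str(Seq(codon).translate())


def oracle_site_counts(codon: str) -> tuple[float, float]:
    """Fractional synonymous/nonsynonymous sites of one codon by enumeration."""
    s_total = n_total = 0.0
    aa = _tr(codon)
    for pos in range(3):
        syn = non = 0
        for base in BASES:
            if base == codon[pos]:
                continue
            mut = codon[:pos] + base + codon[pos + 1 :]
            if _tr(mut) == "*":
                continue
            if _tr(mut) == aa:
                syn += 1
            else:
                non += 1
        if syn + non:
            s_total += syn / (syn + non)
            n_total += non / (syn + non)
    return s_total, n_total


def oracle_pathway_counts(c1: str, c2: str) -> tuple[float, float]:
    """Average synonymous/nonsynonymous steps over minimal mutational paths.

    Recursive enumeration (not itertools): at each step try changing any one
    still-mismatched position. Paths through stop codons are discarded; if
    every path is discarded, rerun counting stop steps as nonsynonymous.
    """

    def enumerate_paths(current: str, allow_stop: bool):
        if current == c2:
            return [(0.0, 0.0)]
        out = []
        for pos in range(3):
            if current[pos] == c2[pos]:
                continue
            nxt = current[:pos] + c2[pos] + current[pos + 1 :]
            stop_step = _tr(nxt) == "*" or _tr(current) == "*"
            if stop_step and not allow_stop and _tr(nxt) == "*":
                continue
            for s_rest, n_rest in enumerate_paths(nxt, allow_stop):
                if stop_step:
                    out.append((s_rest, n_rest + 1.0))
                elif _tr(nxt) == _tr(current):
                    out.append((s_rest + 1.0, n_rest))
                else:
                    out.append((s_rest, n_rest + 1.0))
        return out

    paths = enumerate_paths(c1, False)
    if not paths:
        paths = enumerate_paths(c1, True)
    sd = sum(p[0] for p in paths) / len(paths)
    nd = sum(p[1] for p in paths) / len(paths)
    return sd, nd


def oracle_ng86_counts(codons_a, codons_b):
    """S, N, Sd, Nd for a gapless codon alignment, fully by enumeration."""
    s1 = n1 = s2 = n2 = sd = nd = 0.0
    for ca, cb in zip(codons_a, codons_b):
        sa, na = oracle_site_counts(ca)
        sb, nb = oracle_site_counts(cb)
        s1 += sa
        n1 += na
        s2 += sb
        n2 += nb
        d_s, d_n = oracle_pathway_counts(ca, cb)
        sd += d_s
        nd += d_n
    return (s1 + s2) / 2.0, (n1 + n2) / 2.0, sd, nd


def oracle_max_chain(points, max_gap: int, gap_penalty: float) -> float:
    """Exhaustive maximum chain score over (rank_a, rank_b, score) points.

    Chains must be strictly increasing in rank_a and rank_b with both gaps
    bounded by ``max_gap``; the caller encodes orientation by negating
    rank_b. Exponential — only for small instances.
    """
    best = -math.inf

    def extend(last, score):
        nonlocal best
        if score > best:
            best = score
        for p in points:
            da = p[0] - last[0]
            db = p[1] - last[1]
            if 0 < da <= max_gap and 0 < db <= max_gap:
                extend(p, score + p[2] - gap_penalty * (da + db - 2))

    for p in points:
        extend(p, p[2])
    return best


def oracle_n50(lengths) -> tuple[int, int]:
    """N50/L50 by checking every candidate prefix explicitly."""
    ls = sorted(lengths, reverse=True)
    total = sum(ls)
    for k in range(1, len(ls) + 1):
        if sum(ls[:k]) * 2 >= total:
            return ls[k - 1], k
    raise ValueError("empty input")
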