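"""Post-WGD subgenome behaviour: gene retention and expression dominance.

After a WGD the two subgenomes may lose duplicates unevenly (biased
fractionation) and one subgenome's surviving homoeologs may be systematically
more expressed (genome dominance). Both patterns are tested per genomic
block, against a reference genome's gene order for retention and against an
expression matrix for dominance. Absence of both is the signature of an
autopolyploid origin.

Statistical choices (assumption-light standards, all adjustable): an exact
two-sided binomial test of singly-retained genes against p = 1/2 for
retention bias, a Wilcoxon signed-rank test of per-pair mean log2 expression
ratios against zero for dominance, Benjamini-Hochberg correction across
blocks, pseudocount 1 in ratios, and a minimum effect size (log2 units)
before a block may be called dominant.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.stats import binomtest, wilcoxon
from statsmodels.stats.multitest import multipletests


@dataclass
class BlockAssignment:
    """Retention status of one reference block in the two subgenomes."""

    block_id: str
    ref_gene_ids: list[str]
    retained_a: set[str] = field(default_factory=set)
    retained_b: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        ref = set(self.ref_gene_ids)
        if not self.retained_a <= ref or not self.retained_b <= ref:
            raise ValueError(f"{self.block_id}: retained genes outside the reference set")


@dataclass
class DominanceResult:
    block_id: str
    n_pairs: int
    median_log2_ratio: float
    p_value: float
    q_value: float
    verdict: str  # A-dominant | B-dominant | none
    flag: str = ""


def assignments_from_table(table: pd.DataFrame) -> list[BlockAssignment]:
    """Build assignments from a (block, ref_gene, status) table.

    ``status`` is one of ``A``/``B``/``both``/``lost``.
    """
    out = []
    for block_id, grp in table.groupby("block", sort=True):
        genes = list(grp["ref_gene"])
        status = dict(zip(grp["ref_gene"], grp["status"]))
        out.append(
            BlockAssignment(
                block_id=str(block_id),
                ref_gene_ids=genes,
                retained_a={g for g in genes if status[g] in ("A", "both")},
                retained_b={g for g in genes if status[g] in ("B", "both")},
            )
        )
    return out


def retention_rates(
    assignments: Sequence[BlockAssignment], alpha: float = 0.05
) -> tuple[pd.DataFrame, dict]:
    """Per-block and genome-wide subgenome retention rates with bias tests.

    The bias test conditions on genes retained in exactly one subgenome and
    asks whether their split deviates from 1:1 (exact binomial, two-sided);
    p-values are BH-adjusted across blocks. The pooled genome-wide rate is
    the gene-count-weighted mean of block rates (an exact identity, since
    both are total retained / total reference genes).
    """
    rows = []
    for asg in assignments:
        n_ref = len(asg.ref_gene_ids)
        if n_ref == 0:
            import warnings

            warnings.warn(f"block {asg.block_id} has an empty reference set; skipped")
            continue
        a_only = len(asg.retained_a - asg.retained_b)
        b_only = len(asg.retained_b - asg.retained_a)
        n_single = a_only + b_only
        p = binomtest(a_only, n_single, 0.5).pvalue if n_single else 1.0
        rows.append(
            {
                "block_id": asg.block_id,
                "n_ref": n_ref,
                "retained_A": len(asg.retained_a),
                "retained_B": len(asg.retained_b),
                "rate_A": len(asg.retained_a) / n_ref,
                "rate_B": len(asg.retained_b) / n_ref,
                "a_only": a_only,
                "b_only": b_only,
                "p_value": float(p),
            }
        )
    if not rows:
        raise ValueError("no usable blocks")
    per_block = pd.DataFrame(rows)
    per_block["q_value"] = multipletests(per_block["p_value"], method="fdr_bh")[1]
    per_block["biased"] = per_block["q_value"] < alpha

    tot_ref = int(per_block["n_ref"].sum())
    tot_a_only = int(per_block["a_only"].sum())
    tot_b_only = int(per_block["b_only"].sum())
    n_single = tot_a_only + tot_b_only
    pooled_p = binomtest(tot_a_only, n_single, 0.5).pvalue if n_single else 1.0
    genome_wide = {
        "rate_A": float(per_block["retained_A"].sum() / tot_ref),
        "rate_B": float(per_block["retained_B"].sum() / tot_ref),
        "a_only": tot_a_only,
        "b_only": tot_b_only,
        "pooled_p_value": float(pooled_p),
        "n_biased_blocks": int(per_block["biased"].sum()),
    }
    return per_block, genome_wide


def expression_dominance(
    pairs: Iterable[tuple[str, str, str]],
    expression: pd.DataFrame,
    alpha: float = 0.05,
    effect_floor: float = 1.0,
    pseudocount: float = 1.0,
    min_pairs: int = 5,
) -> list[DominanceResult]:
    """Test each block's homoeolog pairs for expression dominance.

    ``pairs`` yields ``(block_id, gene_a, gene_b)``; ``expression`` is a
    genes x samples matrix of non-negative values. Per pair the log2 ratio
    (A+c)/(B+c) is averaged over the samples both members share; per block a
    Wilcoxon signed-rank test compares the ratios to zero, with BH
    adjustment across blocks. A verdict other than ``none`` additionally
    requires |median ratio| >= ``effect_floor``; blocks with fewer than
    ``min_pairs`` pairs keep their p-value but are forced to ``none`` and
    flagged underpowered.
    """
    by_block: dict[str, list[float]] = {}
    for block_id, gene_a, gene_b in pairs:
        if gene_a not in expression.index or gene_b not in expression.index:
            continue
        ea = expression.loc[gene_a]
        eb = expression.loc[gene_b]
        shared = ea.index[ea.notna() & eb.notna()]
        if len(shared) == 0:
            continue
        ratios = np.log2((ea[shared] + pseudocount) / (eb[shared] + pseudocount))
        by_block.setdefault(str(block_id), []).append(float(ratios.mean()))

    results: list[DominanceResult] = []
    pvals = []
    for block_id in sorted(by_block):
        ratios = np.asarray(by_block[block_id])
        if np.allclose(ratios, 0.0):
            p = 1.0
        else:
            p = float(wilcoxon(ratios, zero_method="wilcox").pvalue)
        flag = "underpowered" if len(ratios) < min_pairs else ""
        results.append(
            DominanceResult(
                block_id=block_id,
                n_pairs=len(ratios),
                median_log2_ratio=float(np.median(ratios)),
                p_value=p,
                q_value=float("nan"),
                verdict="none",
                flag=flag,
            )
        )
        pvals.append(p)
    if not results:
        return results
    qvals = multipletests(pvals, method="fdr_bh")[1]
    for res, q in zip(results, qvals):
        res.q_value = float(q)
        if (
            res.flag != "underpowered"
            and q < alpha
            and abs(res.median_log2_ratio) >= effect_floor
        ):
            res.verdict = "A-dominant" if res.median_log2_ratio > 0 else "B-dominant"
    return results


def dominance_table(results: Sequence[DominanceResult]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "block_id": [r.block_id for r in results],
            "n_pairs": [r.n_pairs for r in results],
            "median_log2_ratio": [r.median_log2_ratio for r in results],
            "p_value": [r.p_value for r in results],
            "q_value": [r.q_value for r in results],
            "verdict": [r.verdict for r in results],
            "flag": [r.flag for r in results],
        }
    )
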