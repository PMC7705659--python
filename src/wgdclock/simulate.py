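"""Synthetic genome pairs, LTR pairs and expression matrices with known truth.

The generator emulates the comparative setting of a Brassicaceae-style study:
an ancestral diploid genome undergoes a whole-genome duplication (WGD) shared
by two descendant lineages; the lineages split; the focal lineage L then
undergoes a second, lineage-specific WGD and evolves with an elevated
substitution rate, while the reference lineage C keeps the base rate.
Fractionation (duplicate loss), inversions and translocations reshape the
focal genome. Every surviving duplicate/ortholog pair is recorded in a truth
ledger together with the synonymous divergence its path through the gene tree
implies, so downstream synteny detection, Ks estimation and WGD dating can be
validated against known ages.

Sequence model
--------------
Coding sequences are built from a codon family with fourfold-degenerate third
positions (Ala/Val/Thr/Ser/Pro/Gly bodies between a fixed ATG and TAA).
Synonymous change is a Jukes-Cantor process on third positions at the neutral
rate; nonsynonymous change swaps the codon prefix to another family member at
rate ``omega`` relative to neutral. Within the family every third-position
change is synonymous and every prefix swap is nonsynonymous, so the
synonymous clock is exact by construction and internal stops cannot arise.

Rate asymmetry follows the relative-rate convention used by Ks-based rate
correction: lineage L accumulates (1 + r) times the synonymous divergence of
lineage C over the *entire* path since the shared WGD, so that the shared
peak satisfies k_L = (1 + r) * k_C exactly. The physically shared pre-split
branch is simulated once at the base rate and L's excess over that stretch is
added to L's post-split stem.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, NamedTuple, Sequence

import numpy as np
import pandas as pd

from . import io as wio
from .models import GeneModel

BASES = "ACGT"
#: codon-family prefixes; third position is fourfold degenerate for all six
PREFIXES = ("GC", "GT", "AC", "TC", "CC", "GG")
#: single-nucleotide prefix moves that stay inside the family (all nonsynonymous)
PREFIX_NEIGHBORS = {
    0: (1, 2, 3, 4, 5),  # GC -> GT, AC, TC, CC, GG
    1: (0, 5),           # GT -> GC, GG
    2: (0, 3, 4),        # AC -> GC, TC, CC
    3: (0, 2, 4),        # TC -> GC, AC, CC
    4: (0, 2, 3),        # CC -> GC, AC, TC
    5: (0, 1),           # GG -> GC, GT
}

KS_SATURATION_BOUND = 3.0


class PairRecord(NamedTuple):
    """One surviving homologous pair and the event that created it."""

    gene_a: str
    gene_b: str
    event: str  # specific | shared_L | shared_C | ortholog


class LTRElement(NamedTuple):
    element_id: str
    ltr5: str
    ltr3: str
    age_years: float


@dataclass(frozen=True)
class SimConfig:
    """Scenario parameters for :func:`simulate_genome_pair`.

    Ages are in Mya; ``subst_rate`` is per site per year. The default ages
    encode the study scenario: a shared WGD at 52.01 Mya, a lineage split at
    21.53 Mya and a focal-lineage WGD dated 22.99 Mya. The focal duplication
    age exceeding the split age is tolerated: the duplication is placed on
    the focal stem at the split and its pair divergence is backdated so each
    duplicate pair carries 2 * rate_L * specific_wgd_age of divergence.
    """

    n_genes_ancestor: int = 2000
    n_chromosomes: int = 8
    shared_wgd_age_mya: float = 52.01
    specific_wgd_age_mya: float = 22.99
    split_age_mya: float = 21.53
    subst_rate: float = 8.22e-9
    rate_asymmetry_r: float = 0.0
    loss_rate: float = 0.3
    n_inversions: int = 5
    n_translocations: int = 2
    omega: float = 0.2
    seed: int = 0

    def validate(self) -> None:
        if self.n_genes_ancestor < 50:
            raise ValueError(
                "n_genes_ancestor < 50: collinear blocks would be undetectable"
            )
        for name in ("shared_wgd_age_mya", "specific_wgd_age_mya", "split_age_mya"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for name in ("subst_rate", "loss_rate", "omega"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.rate_asymmetry_r < 0:
            raise ValueError("rate_asymmetry_r must be >= 0")
        if self.loss_rate > 1:
            raise ValueError("loss_rate is a probability")
        if self.shared_wgd_age_mya < max(self.split_age_mya, self.specific_wgd_age_mya):
            raise ValueError(
                "shared WGD must be the oldest event in this two-lineage scenario"
            )
        if self.n_chromosomes < 1:
            raise ValueError("need at least one chromosome")

    @classmethod
    def from_file(cls, path: str | Path) -> "SimConfig":
        raw = wio.read_config(path)
        kwargs = {
            name: _cast(name, raw[name])
            for name in cls.__dataclass_fields__
            if name in raw
        }
        return cls(**kwargs)


def _cast(name: str, value: str):
    int_fields = {
        "n_genes_ancestor",
        "n_chromosomes",
        "n_inversions",
        "n_translocations",
        "seed",
    }
    return int(value) if name in int_fields else float(value)


@dataclass
class SimTruth:
    """Ground-truth ledger emitted alongside a simulated genome pair.

    ``expected_ks_*`` are the synonymous divergences implied by the branch
    lengths of the relevant pair's path through the gene tree (2 x rate x
    time summed over the path), i.e. what an unbiased Ks estimator should
    recover on average.
    """

    expected_ks_shared: float
    expected_ks_specific: float
    expected_ks_ortholog: float
    expected_ks_shared_ref: float
    subgenome_labels: dict[str, str] = field(default_factory=dict)
    pair_registry: list[PairRecord] = field(default_factory=list)
    ltr_ages: dict[str, float] = field(default_factory=dict)
    losses: dict[str, int] = field(default_factory=dict)
    config: SimConfig | None = None

    def pairs(self, event: str) -> list[PairRecord]:
        return [p for p in self.pair_registry if p.event == event]


# ------------------------------------------------------------------ sequence

def _random_gene_arrays(rng: np.random.Generator, n_codons: int):
    prefixes = rng.integers(0, len(PREFIXES), n_codons)
    thirds = rng.integers(0, 4, n_codons)
    return prefixes, thirds


def _evolve(prefixes, thirds, d: float, omega: float, rng: np.random.Generator):
    """Evolve one gene copy along a branch of ``d`` substitutions/site.

    Synonymous: per-site Jukes-Cantor transition with branch length ``d``
    (stay probability 1/4 + 3/4 e^{-4d/3}). Nonsynonymous: Poisson(2 d omega)
    prefix-swap events per codon, each to a uniform family neighbour.
    """
    prefixes = prefixes.copy()
    thirds = thirds.copy()
    n = len(thirds)
    if n == 0 or d <= 0:
        return prefixes, thirds
    stay = 0.25 + 0.75 * np.exp(-4.0 * d / 3.0)
    changed = rng.random(n) >= stay
    k = int(changed.sum())
    if k:
        thirds[changed] = (thirds[changed] + rng.integers(1, 4, k)) % 4
    n_events = rng.poisson(2.0 * d * omega * n)
    for _ in range(n_events):
        i = int(rng.integers(0, n))
        nb = PREFIX_NEIGHBORS[int(prefixes[i])]
        prefixes[i] = nb[int(rng.integers(0, len(nb)))]
    return prefixes, thirds


def _to_cds(prefixes, thirds) -> str:
    body = "".join(PREFIXES[p] + BASES[t] for p, t in zip(prefixes, thirds))
    return "ATG" + body + "TAA"


# ------------------------------------------------------------------ genome pair

def simulate_genome_pair(config: SimConfig):
    """Simulate the focal (L) and reference (C) genomes plus a truth ledger.

    Returns ``(genes_L, genes_C, truth)`` where the gene lists carry CDS and
    coordinates, and ``truth`` records expected Ks per event class, subgenome
    labels of the focal genome (by specific-WGD subgenome), the surviving
    pair registry and exact loss counts.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)

    b = config.subst_rate * 1e6  # substitutions/site/My
    r = config.rate_asymmetry_r
    t_sh, t_sp, t_spec = (
        config.shared_wgd_age_mya,
        config.split_age_mya,
        config.specific_wgd_age_mya,
    )
    d_common = b * (t_sh - t_sp)
    d_ref_term = b * t_sp
    rate_l = b * (1.0 + r)
    # L's excess over the shared pre-split branch plus its own stem
    d_focal_stem = r * d_common + rate_l * max(t_sp - t_spec, 0.0)
    d_focal_term = rate_l * t_spec

    truth = SimTruth(
        expected_ks_shared=2.0 * (d_common + d_focal_stem + d_focal_term),
        expected_ks_specific=2.0 * d_focal_term,
        expected_ks_ortholog=d_ref_term + d_focal_stem + d_focal_term,
        expected_ks_shared_ref=2.0 * b * t_sh,
        config=config,
    )
    for name in ("shared", "specific", "ortholog", "shared_ref"):
        val = getattr(truth, f"expected_ks_{name}")
        if val > KS_SATURATION_BOUND:
            warnings.warn(
                f"expected_ks_{name} = {val:.3f} exceeds the Ks saturation bound "
                f"{KS_SATURATION_BOUND}; estimates will be unreliable",
                stacklevel=2,
            )

    n = config.n_genes_ancestor
    n_chrom = config.n_chromosomes
    per_chrom = -(-n // n_chrom)  # ceil

    cds_store: dict[str, str] = {}
    alive: set[str] = set()
    # chromosome -> ordered [(gene_id, strand)]; L gets 4 copies, C gets 2
    chrom_l: dict[str, list[tuple[str, str]]] = {}
    chrom_c: dict[str, list[tuple[str, str]]] = {}

    copy_tree: list[dict] = []  # per ancestral gene: terminal copy ids

    for i in range(n):
        gid = f"g{i:05d}"
        n_codons = int(rng.integers(100, 501))  # 300..1503 nt with ATG+stop
        anc = _random_gene_arrays(rng, n_codons)
        strand = "+" if rng.random() < 0.5 else "-"
        entry: dict = {"strand": strand, "copies": {}}
        for s, sub in ((1, "A"), (2, "B")):
            # shared pre-split branch: simulated once, inherited by both lineages
            node = _evolve(*anc, d_common, config.omega, rng)
            c_id = f"C_{gid}_{sub}"
            c_arr = _evolve(*node, d_ref_term, config.omega, rng)
            cds_store[c_id] = _to_cds(*c_arr)
            stem = _evolve(*node, d_focal_stem, config.omega, rng)
            l_ids = []
            for x in ("a", "b"):
                l_id = f"L_{gid}_{sub}{x}"
                l_arr = _evolve(*stem, d_focal_term, config.omega, rng)
                cds_store[l_id] = _to_cds(*l_arr)
                l_ids.append(l_id)
            entry["copies"][sub] = {"C": c_id, "L": l_ids}
        copy_tree.append(entry)

    # lay out chromosomes in ancestral order
    for c in range(n_chrom):
        lo, hi = c * per_chrom, min((c + 1) * per_chrom, n)
        if lo >= hi:
            continue
        for sub in ("A", "B"):
            chrom_c[f"C_chr{c + 1:02d}{sub}"] = [
                (copy_tree[i]["copies"][sub]["C"], copy_tree[i]["strand"])
                for i in range(lo, hi)
            ]
            for xi, x in enumerate(("a", "b")):
                chrom_l[f"L_chr{c + 1:02d}{sub}{x}"] = [
                    (copy_tree[i]["copies"][sub]["L"][xi], copy_tree[i]["strand"])
                    for i in range(lo, hi)
                ]

    _apply_rearrangements(chrom_l, config, rng)

    # fractionation: one random member of each most-recent-WGD duplicate pair
    losses_l = losses_c = 0
    alive = set(cds_store)
    for entry in copy_tree:
        for sub in ("A", "B"):
            if config.loss_rate > 0 and rng.random() < config.loss_rate:
                victim = entry["copies"][sub]["L"][int(rng.integers(0, 2))]
                alive.discard(victim)
                losses_l += 1
        if config.loss_rate > 0 and rng.random() < config.loss_rate:
            sub = ("A", "B")[int(rng.integers(0, 2))]
            alive.discard(entry["copies"][sub]["C"])
            losses_c += 1
    truth.losses = {"L": losses_l, "C": losses_c}

    genes_l = _materialize(chrom_l, alive, cds_store)
    genes_c = _materialize(chrom_c, alive, cds_store)

    for g in genes_l:
        truth.subgenome_labels[g.gene_id] = "A" if g.gene_id.endswith("a") else "B"

    _register_pairs(truth, copy_tree, alive)
    return genes_l, genes_c, truth


def _apply_rearrangements(chroms: dict, config: SimConfig, rng: np.random.Generator):
    """In-place inversions then translocations; breakpoints at gene boundaries."""
    names = sorted(chroms)
    for _ in range(config.n_inversions):
        cands = [nm for nm in names if len(chroms[nm]) >= 2]
        if not cands:
            break
        nm = cands[int(rng.integers(0, len(cands)))]
        genes = chroms[nm]
        i, j = sorted(rng.choice(len(genes), 2, replace=False))
        if i == j:
            continue
        seg = [(gid, "+" if st == "-" else "-") for gid, st in genes[i : j + 1]][::-1]
        chroms[nm] = genes[:i] + seg + genes[j + 1 :]
    for _ in range(config.n_translocations):
        cands = [nm for nm in names if len(chroms[nm]) >= 4]
        if len(cands) < 2 or len(names) < 2:
            break
        src = cands[int(rng.integers(0, len(cands)))]
        genes = chroms[src]
        seg_len = int(rng.integers(1, max(2, len(genes) // 4)))
        i = int(rng.integers(0, len(genes) - seg_len))
        seg = genes[i : i + seg_len]
        chroms[src] = genes[:i] + genes[i + seg_len :]
        others = [nm for nm in names if nm != src]
        dst = others[int(rng.integers(0, len(others)))]
        pos = int(rng.integers(0, len(chroms[dst]) + 1))
        chroms[dst] = chroms[dst][:pos] + seg + chroms[dst][pos:]


def _materialize(chroms: dict, alive: set, cds_store: dict) -> list[GeneModel]:
    spacer = 200
    out: list[GeneModel] = []
    for seq_id in sorted(chroms):
        pos = 1
        rank = 0
        for gid, strand in chroms[seq_id]:
            if gid not in alive:
                continue
            cds = cds_store[gid]
            out.append(
                GeneModel(
                    gene_id=gid,
                    seq_id=seq_id,
                    start=pos,
                    end=pos + len(cds) - 1,
                    strand=strand,
                    rank=rank,
                    cds=cds,
                )
            )
            pos += len(cds) + spacer
            rank += 1
    return out


def _register_pairs(truth: SimTruth, copy_tree: list, alive: set) -> None:
    reg = truth.pair_registry
    for entry in copy_tree:
        survivors: dict[str, list[str]] = {}
        for sub in ("A", "B"):
            info = entry["copies"][sub]
            l_alive = [g for g in info["L"] if g in alive]
            survivors[sub] = l_alive
            if len(l_alive) == 2:
                reg.append(PairRecord(l_alive[0], l_alive[1], "specific"))
            if info["C"] in alive and l_alive:
                reg.append(PairRecord(info["C"], l_alive[0], "ortholog"))
        if survivors["A"] and survivors["B"]:
            reg.append(PairRecord(survivors["A"][0], survivors["B"][0], "shared_L"))
        c_a, c_b = entry["copies"]["A"]["C"], entry["copies"]["B"]["C"]
        if c_a in alive and c_b in alive:
            reg.append(PairRecord(c_a, c_b, "shared_C"))


# ------------------------------------------------------------------ LTR pairs

def simulate_ltr_elements(
    n: int,
    age_range: tuple[float, float] = (0.0, 5e6),
    mu: float = 7e-9,
    seed: int = 0,
    ltr_length: int = 1000,
) -> list[LTRElement]:
    """Simulate intact LTR retrotransposon termini of known insertion age.

    The two LTRs of an element are identical at insertion; each then evolves
    independently under Jukes-Cantor at ``mu`` per site per year, so the
    expected pairwise divergence of an element of age ``t`` is ``2 mu t``.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    lo, hi = age_range
    if lo < 0 or hi < lo:
        raise ValueError("age_range must satisfy 0 <= lo <= hi")
    if hi > 2e7:
        raise ValueError("age_range must lie within [0, 20 Myr]")
    rng = np.random.default_rng(seed)
    out = []
    for i in range(n):
        age = float(rng.uniform(lo, hi))
        base = rng.integers(0, 4, ltr_length)
        copies = []
        for _ in range(2):
            d = mu * age
            stay = 0.25 + 0.75 * np.exp(-4.0 * d / 3.0)
            arr = base.copy()
            changed = rng.random(ltr_length) >= stay
            k = int(changed.sum())
            if k:
                arr[changed] = (arr[changed] + rng.integers(1, 4, k)) % 4
            copies.append("".join(BASES[x] for x in arr))
        out.append(LTRElement(f"ltr{i:04d}", copies[0], copies[1], age))
    return out


def write_ltr_fasta(elements: Iterable[LTRElement], path: str | Path) -> None:
    recs: dict[str, str] = {}
    for el in elements:
        recs[f"{el.element_id}_5LTR"] = el.ltr5
        recs[f"{el.element_id}_3LTR"] = el.ltr3
    wio.write_fasta(recs, path)


# ------------------------------------------------------------------ expression

def simulate_expression(
    pair_registry: Sequence,
    n_samples: int = 3,
    dominance_log2fc: float = 0.0,
    noise_sd: float = 0.5,
    seed: int = 0,
) -> pd.DataFrame:
    """Homoeolog expression matrix (genes x samples, linear scale).

    For each duplicate pair the first member (subgenome A) is expressed at
    ``dominance_log2fc`` log2 units above the second, plus Gaussian noise per
    sample; ``dominance_log2fc=0`` encodes the no-dominance null. The default
    three samples mirror a flower/leaf/stem tissue panel.
    """
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    pairs = [
        (p.gene_a, p.gene_b) if isinstance(p, PairRecord) else (p[0], p[1])
        for p in pair_registry
        if not isinstance(p, PairRecord) or p.event == "specific"
    ]
    rng = np.random.default_rng(seed)
    rows: dict[str, np.ndarray] = {}
    for a, b_ in pairs:
        base = rng.normal(8.0, 1.5)
        la = base + dominance_log2fc + rng.normal(0.0, noise_sd, n_samples)
        lb = base + rng.normal(0.0, noise_sd, n_samples)
        rows[a] = np.exp2(la)
        rows[b_] = np.exp2(lb)
    cols = [f"sample_{j + 1}" for j in range(n_samples)]
    return pd.DataFrame.from_dict(rows, orient="index", columns=cols)


# ------------------------------------------------------------------ writers

def translate_cds(cds: str) -> str:
    from Bio.Seq import Seq

    prot = str(Seq(cds).translate())
    return prot[:-1] if prot.endswith("*") else prot


def write_genome(genes: Sequence[GeneModel], out_dir: str | Path, prefix: str) -> None:
    """Write CDS FASTA, protein FASTA and GFF3 for one simulated genome."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cds = {g.gene_id: g.cds for g in genes if g.cds}
    wio.write_fasta(cds, out / f"{prefix}.cds.fasta")
    wio.write_fasta(
        {gid: translate_cds(s) for gid, s in cds.items()}, out / f"{prefix}.protein.fasta"
    )
    wio.write_gff3(genes, out / f"{prefix}.gff3")


def write_truth(truth: SimTruth, out_dir: str | Path) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(truth.pair_registry).to_csv(
        out / "pair_registry.tsv", sep="\t", index=False
    )
    pd.DataFrame(
        sorted(truth.subgenome_labels.items()), columns=["gene_id", "subgenome"]
    ).to_csv(out / "subgenome_labels.tsv", sep="\t", index=False)
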