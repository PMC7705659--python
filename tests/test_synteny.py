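"""Hit filtering, builtin scoring, chaining vs brute force, dotplot."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from oracles import oracle_max_chain
from wgdclock.models import GeneModel
from wgdclock.simulate import SimConfig, simulate_genome_pair, translate_cds
from wgdclock.synteny import (
    _best_chain,
    collapse_tandems,
    detect_collinear_blocks,
    dotplot_table,
    filter_hits,
    score_homologs_builtin,
)


def _hits(rows):
    return pd.DataFrame(rows, columns=["query_id", "subject_id", "score", "e_value"])


def _chrom(seq_id, gene_ids, start=1):
    genes = []
    pos = start
    for rank, gid in enumerate(gene_ids):
        genes.append(GeneModel(gid, seq_id, pos, pos + 299, "+", rank))
        pos += 500
    return genes


class TestFilterHits:
    def test_e_value_threshold(self):
        hits = _hits([("q1", "s1", 50.0, 1e-4), ("q1", "s2", 50.0, 1e-6)])
        out = filter_hits(hits, e_max=1e-5)
        assert list(out["subject_id"]) == ["s2"]

    def test_infinite_bounds_identity(self):
        hits = _hits([("q1", "s1", 5.0, 0.9), ("q2", "s3", 1.0, 10.0)])
        out = filter_hits(hits, e_max=np.inf, best_n=None)
        assert len(out) == 2

    def test_self_hits_removed(self):
        hits = _hits([("g1", "g1", 99.0, 0.0), ("g1", "g2", 50.0, 1e-9)])
        assert list(filter_hits(hits)["subject_id"]) == ["g2"]

    def test_best_n_cap_with_tie_break(self):
        rows = [("q1", f"s{i}", float(10 - (i % 5)), 1e-9) for i in range(10)]
        out = filter_hits(_hits(rows), best_n=5)
        assert len(out) == 5
        # descending score; within equal scores, lexicographic subject order
        expected = sorted(rows, key=lambda r: (-r[2], r[1]))[:5]
        assert list(out["subject_id"]) == [r[1] for r in expected]

    def test_empty_input_is_empty_output(self):
        out = filter_hits(_hits([]))
        assert out.empty


class TestBuiltinScorer:
    def test_identical_sequences_maximal(self):
        prots = {"a": "MGATSPAVTG" * 8, "b": "MGATSPAVTG" * 8, "c": "MTTTTTTTTT" * 8}
        hits = score_homologs_builtin(prots, dict(prots), self_comparison=False)
        hits = hits.set_index(["query_id", "subject_id"])
        best = hits.loc[("a", "a"), "score"]
        assert best >= hits["score"].max() - 1e-9
        assert hits.loc[("a", "a"), "e_value"] == hits["e_value"].min()

    def test_score_symmetry(self, rng):
        alphabet = np.array(list("AVTSPG"))
        a = "M" + "".join(rng.choice(alphabet, 120))
        b = list(a)
        for pos in rng.choice(np.arange(1, 121), 6, replace=False):
            b[pos] = "G" if b[pos] != "G" else "A"
        b = "".join(b)
        h1 = score_homologs_builtin({"x": a}, {"y": b})
        h2 = score_homologs_builtin({"x": b}, {"y": a})
        assert h1.loc[0, "score"] == h2.loc[0, "score"]

    def test_full_recall_of_true_pairs_among_decoys(self, rng):
        # 20 diverged duplicate pairs + 200 unrelated decoys
        cfg = SimConfig(
            n_genes_ancestor=110,
            n_chromosomes=2,
            loss_rate=0.0,
            n_inversions=0,
            n_translocations=0,
            seed=21,
        )
        genes_l, _, truth = simulate_genome_pair(cfg)
        cds = {g.gene_id: g.cds for g in genes_l}
        pairs = truth.pairs("specific")[:20]
        prots = {}
        for p in pairs:
            prots[p.gene_a] = translate_cds(cds[p.gene_a])
            prots[p.gene_b] = translate_cds(cds[p.gene_b])
        from wgdclock.simulate import _to_cds

        for i in range(200):
            pre = rng.integers(0, 6, 150)
            thr = rng.integers(0, 4, 150)
            prots[f"decoy{i:03d}"] = translate_cds(_to_cds(pre, thr))
        hits = score_homologs_builtin(prots, prots)
        found = {tuple(sorted((q, s))) for q, s in zip(hits["query_id"], hits["subject_id"])}
        for p in pairs:
            assert tuple(sorted((p.gene_a, p.gene_b))) in found

    def test_non_amino_acid_records_skipped_with_warning(self):
        with pytest.warns(UserWarning, match="non-amino-acid"):
            hits = score_homologs_builtin(
                {"ok": "MGATSPAVTG" * 8, "bad": "MGATX!"}, {"ok2": "MGATSPAVTG" * 8}
            )
        assert set(hits["query_id"]) == {"ok"}


class TestChaining:
    def test_perfectly_collinear_single_block(self):
        ga = _chrom("A1", [f"a{i}" for i in range(10)])
        gb = _chrom("B1", [f"b{i}" for i in range(10)])
        hits = _hits([(f"a{i}", f"b{i}", 10.0, 1e-9) for i in range(10)])
        blocks = detect_collinear_blocks(hits, ga, gb)
        assert len(blocks) == 1
        assert blocks[0].n_anchors == 10
        assert blocks[0].orientation == "same"

    def test_internal_inversion_yields_two_blocks(self):
        # middle 6 genes reversed in genome B
        ga = _chrom("A1", [f"a{i}" for i in range(16)])
        order = list(range(5)) + list(range(10, 4, -1)) + list(range(11, 16))
        gb = _chrom("B1", [f"b{i}" for i in order])
        hits = _hits([(f"a{i}", f"b{i}", 10.0, 1e-9) for i in range(16)])
        blocks = detect_collinear_blocks(hits, ga, gb, min_block_size=5)
        orientations = sorted(b.orientation for b in blocks)
        assert orientations == ["inverted", "same"]

    def test_gene_pair_in_at_most_one_block(self, small_pair):
        genes_l, _, _ = small_pair
        prots = {g.gene_id: translate_cds(g.cds) for g in genes_l}
        hits = filter_hits(score_homologs_builtin(prots, prots))
        blocks = detect_collinear_blocks(hits, genes_l, genes_l)
        seen = set()
        for b in blocks:
            for ga, gb, _, _ in b.anchors:
                key = tuple(sorted((ga, gb)))
                assert key not in seen
                seen.add(key)

    def test_lossless_simulation_blocks_cover_chromosomes(self):
        cfg = SimConfig(
            n_genes_ancestor=120,
            n_chromosomes=2,
            loss_rate=0.0,
            n_inversions=0,
            n_translocations=0,
            omega=0.1,  # strong purifying selection keeps proteins alignable
            seed=31,
        )
        genes_l, genes_c, _ = simulate_genome_pair(cfg)
        prots_l = {g.gene_id: translate_cds(g.cds) for g in genes_l}
        prots_c = {g.gene_id: translate_cds(g.cds) for g in genes_c}
        hits = filter_hits(score_homologs_builtin(prots_l, prots_c))
        blocks = detect_collinear_blocks(hits, genes_l, genes_c)
        per_chrom = 60
        sizes: dict[tuple, list[int]] = {}
        for b in blocks:
            sizes.setdefault(b.seq_pair, []).append(b.n_anchors)
        # every L chromosome is homologous to the two C copies of its
        # ancestral chromosome: one dominant block covering >=95% of its
        # genes (occasional slivers of spurious hits may chain separately)
        for c in ("01", "02"):
            for sub in ("A", "B"):
                for x in ("a", "b"):
                    for csub in ("A", "B"):
                        key = (f"L_chr{c}{sub}{x}", f"C_chr{c}{csub}")
                        ns = sorted(sizes[key], reverse=True)
                        assert ns[0] >= 0.95 * per_chrom, (key, ns)
                        assert all(n < 10 for n in ns[1:]), (key, ns)

    def test_duplicate_ranks_rejected(self):
        ga = _chrom("A1", ["a0", "a1"])
        ga[1] = GeneModel("a1", "A1", 501, 800, "+", 0)  # rank clash
        hits = _hits([("a0", "b0", 1.0, 1e-9)])
        gb = _chrom("B1", ["b0"])
        with pytest.raises(ValueError, match="duplicate gene ranks"):
            detect_collinear_blocks(hits, ga, gb)

    def test_chain_matches_bruteforce_on_random_instances(self, rng):
        """DP chaining equals exhaustive enumeration on 200 small instances."""
        for trial in range(200):
            n = int(rng.integers(2, 13))
            pts = [
                (int(rng.integers(0, 15)), int(rng.integers(0, 15)), float(rng.integers(1, 10)), i)
                for i in range(n)
            ]
            max_gap = int(rng.integers(2, 8))
            same_best, _ = _best_chain(pts, max_gap, 1.0)
            inv_pts = [(a, -b, s, i) for a, b, s, i in pts]
            inv_best, _ = _best_chain(inv_pts, max_gap, 1.0)
            oracle = max(
                oracle_max_chain([(a, b, s) for a, b, s, _ in pts], max_gap, 1.0),
                oracle_max_chain([(a, -b, s) for a, b, s, _ in pts], max_gap, 1.0),
            )
            assert max(same_best, inv_best) == pytest.approx(oracle), trial

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(
        st.lists(
            st.tuples(
                st.integers(0, 12), st.integers(0, 12), st.integers(1, 9)
            ),
            min_size=1,
            max_size=10,
        ),
        st.integers(2, 6),
    )
    def test_chain_bruteforce_property(self, pts, max_gap):
        pts4 = [(a, b, float(s), i) for i, (a, b, s) in enumerate(pts)]
        got, _ = _best_chain(pts4, max_gap, 1.0)
        want = oracle_max_chain([(a, b, float(s)) for a, b, s in pts], max_gap, 1.0)
        assert got == pytest.approx(want)


class TestTandemCollapse:
    def test_adjacent_duplicates_collapsed_to_best(self):
        # ranks: a0=0, a1=1, a2=2, fillers 3-5, a9=6
        ga = _chrom("A1", ["a0", "a1", "a2", "f3", "f4", "f5", "a9"])
        gb = _chrom("B1", ["b0"])
        from wgdclock.models import gene_index

        hits = _hits(
            [("a0", "b0", 5.0, 1e-9), ("a1", "b0", 9.0, 1e-9), ("a2", "b0", 7.0, 1e-9),
             ("a9", "b0", 6.0, 1e-9)]
        )
        out = collapse_tandems(hits, gene_index(ga), gene_index(gb))
        # a0/a1/a2 form one array (winner a1); a9 is 4 ranks past a2, kept
        assert sorted(out["query_id"]) == ["a1", "a9"]


class TestDotplot:
    def test_row_count_equals_total_anchors(self):
        ga = _chrom("A1", [f"a{i}" for i in range(10)])
        gb = _chrom("B1", [f"b{i}" for i in range(10)])
        hits = _hits([(f"a{i}", f"b{i}", 10.0, 1e-9) for i in range(10)])
        blocks = detect_collinear_blocks(hits, ga, gb)
        table = dotplot_table(blocks, ga, gb)
        assert len(table) == sum(b.n_anchors for b in blocks) == 10

    def test_wgd_signature_reference_region_in_two_blocks(self):
        # one reference chromosome matched by two focal regions (1:2 pattern)
        gb = _chrom("R1", [f"r{i}" for i in range(10)])
        ga = _chrom("F1", [f"x{i}" for i in range(10)]) + _chrom(
            "F2", [f"y{i}" for i in range(10)]
        )
        hits = _hits(
            [(f"x{i}", f"r{i}", 10.0, 1e-9) for i in range(10)]
            + [(f"y{i}", f"r{i}", 10.0, 1e-9) for i in range(10)]
        )
        blocks = detect_collinear_blocks(hits, ga, gb)
        table = dotplot_table(blocks, ga, gb)
        assert table["block_id"].nunique() == 2
        # each reference gene appears in both focal blocks
        counts = table.groupby("gene_b")["block_id"].nunique()
        assert (counts == 2).all()
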