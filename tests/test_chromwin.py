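import numpy as np
import pandas as pd
import pytest

from respiroscreen.errors import ValidationError
from respiroscreen.chromwin import (find_regions, merge_windows, ncrna_adjacency,
                                    scan_windows)
from respiroscreen.tables_io import GeneMap


def _map(n, chrom="chr1", biotypes=None):
    biotypes = biotypes or ["coding"] * n
    return GeneMap.from_frame(pd.DataFrame({
        "gene_id": [f"{chrom}_g{i}" for i in range(1, n + 1)],
        "chrom": chrom, "start": np.arange(n) * 1000 + 1,
        "end": np.arange(n) * 1000 + 500, "strand": "+", "biotype": biotypes,
    }))


def _concat(*maps):
    return GeneMap.from_frame(pd.concat([m.data.drop(columns="rank") for m in maps],
                                        ignore_index=True))


def brute_force_windows(gene_map, fc, window=10, min_count=6, fold=2.0):
    """Independent oracle: enumerate every window on every chromosome."""
    thr = np.log2(fold)
    flagged = set()
    for chrom in gene_map.chromosomes():
        genes = list(gene_map.data.loc[gene_map.data["chrom"] == chrom, "gene_id"])
        for start in range(0, len(genes) - window + 1):
            win = genes[start:start + window]
            n_up = sum(1 for g in win if fc.get(g, 0.0) > thr)
            n_down = sum(1 for g in win if fc.get(g, 0.0) < -thr)
            if n_up >= min_count:
                flagged.add((chrom, start + 1, start + window, "induced", n_up))
            if n_down >= min_count:
                flagged.add((chrom, start + 1, start + window, "repressed", n_down))
    return flagged


class TestScanWindows:
    def test_six_of_ten_is_flagged(self):
        gm = _map(10)
        fc = {f"chr1_g{i}": 2.0 for i in range(1, 7)}
        out = scan_windows(gm, fc)
        assert len(out) == 1
        row = out.iloc[0]
        assert (row["direction"], row["count"]) == ("induced", 6)
        assert set(row["members"]) == set(fc)

    def test_five_of_ten_is_not_flagged(self):
        gm = _map(10)
        fc = {f"chr1_g{i}": 2.0 for i in range(1, 6)}
        assert len(scan_windows(gm, fc)) == 0

    def test_threshold_is_strictly_more_than_twofold(self):
        gm = _map(10)
        fc = {f"chr1_g{i}": 1.0 for i in range(1, 8)}  # exactly twofold
        assert len(scan_windows(gm, fc)) == 0

    def test_short_chromosome_yields_no_windows(self):
        gm = _map(5)
        assert len(scan_windows(gm, {f"chr1_g{i}": 3.0 for i in range(1, 6)})) == 0

    def test_windows_do_not_span_chromosomes(self):
        gm = _concat(_map(6, "chr1"), _map(6, "chr2"))
        fc = {g: 2.0 for g in gm.data["gene_id"]}
        # 12 qualifying genes but no single chromosome holds a 10-gene window
        assert len(scan_windows(gm, fc)) == 0

    def test_missing_fold_changes_count_as_non_qualifying(self):
        gm = _map(10)
        fc = {f"chr1_g{i}": 2.0 for i in range(1, 6)}  # 5 qualify, 5 unobserved
        assert len(scan_windows(gm, fc)) == 0

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_brute_force_on_random_instances(self, seed):
        rng = np.random.default_rng(seed)
        gm = _concat(_map(120, "chr1"), _map(80, "chr2"))
        genes = list(gm.data["gene_id"])
        fc = {g: float(rng.normal(0, 1.2)) for g in rng.choice(genes, 150, replace=False)}
        out = scan_windows(gm, fc, min_count=4)
        got = {(r.chrom, r.start_rank, r.end_rank, r.direction, r["count"])
               for _, r in out.iterrows()}
        assert got == brute_force_windows(gm, fc, min_count=4)

    def test_invariant_to_gene_renaming(self):
        rng = np.random.default_rng(3)
        gm = _map(60)
        fc = {g: float(rng.normal(0, 1.5)) for g in gm.data["gene_id"]}
        out1 = scan_windows(gm, fc, min_count=4)
        renamed = gm.data.drop(columns="rank").copy()
        renamed["gene_id"] = ["x" + g for g in renamed["gene_id"]]
        out2 = scan_windows(GeneMap.from_frame(renamed),
                            {"x" + g: v for g, v in fc.items()}, min_count=4)
        cols = ["chrom", "start_rank", "end_rank", "direction", "count"]
        pd.testing.assert_frame_equal(out1[cols], out2[cols])


class TestMergeWindows:
    def test_overlapping_windows_merge(self):
        gm = _map(11)
        fc = {f"chr1_g{i}": 2.0 for i in range(2, 11)}  # g2..g10 induced
        regions = find_regions(gm, fc)
        assert len(regions) == 1
        assert (regions[0].start_rank, regions[0].end_rank) == (1, 11)
        assert regions[0].max_count == 9

    def test_opposite_directions_stay_separate(self):
        gm = _map(20)
        fc = {f"chr1_g{i}": 2.0 for i in range(1, 8)}
        fc.update({f"chr1_g{i}": -2.0 for i in range(11, 18)})
        regions = find_regions(gm, fc)
        assert {r.direction for r in regions} == {"induced", "repressed"}

    @pytest.mark.parametrize("seed", range(5))
    def test_merged_regions_equal_overlap_graph_components(self, seed):
        import networkx as nx
        rng = np.random.default_rng(100 + seed)
        gm = _map(150)
        fc = {g: float(rng.normal(0, 1.5)) for g in gm.data["gene_id"]}
        flagged = scan_windows(gm, fc, min_count=4)
        regions = merge_windows(flagged)
        graph = nx.Graph()
        wins = list(flagged.itertuples())
        graph.add_nodes_from(range(len(wins)))
        for i, a in enumerate(wins):
            for j, b in enumerate(wins):
                if (i < j and a.chrom == b.chrom and a.direction == b.direction
                        and a.start_rank <= b.end_rank + 1
                        and b.start_rank <= a.end_rank + 1):
                    graph.add_edge(i, j)
        expected = set()
        for comp in nx.connected_components(graph):
            ws = [wins[i] for i in comp]
            expected.add((ws[0].chrom, min(w.start_rank for w in ws),
                          max(w.end_rank for w in ws), ws[0].direction))
        got = {(r.chrom, r.start_rank, r.end_rank, r.direction) for r in regions}
        assert got == expected


class TestNcrnaAdjacency:
    def test_isolated_ncrna_not_adjacent(self):
        gm = _map(3, biotypes=["coding", "ncRNA", "coding"])
        res = ncrna_adjacency(gm, de_coding=set(), de_ncrna={"chr1_g2"})
        assert res.fraction == 0.0 and res.pairs == []

    def test_neighbouring_de_coding_gene_counts(self):
        gm = _map(3, biotypes=["coding", "ncRNA", "coding"])
        res = ncrna_adjacency(gm, de_coding={"chr1_g3"}, de_ncrna={"chr1_g2"})
        assert res.fraction == 1.0
        assert res.pairs == [("chr1_g2", "chr1_g3")]

    def test_no_wraparound_at_chromosome_ends(self):
        gm = _concat(_map(2, "chr1", ["ncRNA", "coding"]),
                     _map(2, "chr2", ["coding", "coding"]))
        # the last chr2 gene is not a neighbour of the first chr1 ncRNA
        res = ncrna_adjacency(gm, de_coding={"chr2_g1", "chr2_g2"},
                              de_ncrna={"chr1_g1"})
        assert res.fraction == 0.0

    def test_empty_ncrna_set_is_undefined_not_zero(self):
        gm = _map(3)
        res = ncrna_adjacency(gm, de_coding={"chr1_g1"}, de_ncrna=set())
        assert res.fraction is None

    def test_unknown_gene_is_error(self):
        gm = _map(3)
        with pytest.raises(ValidationError, match="absent from the gene map"):
            ncrna_adjacency(gm, de_coding={"nope"}, de_ncrna=set())

    def test_planted_pairs_recovered_at_negligible_dispersion(self):
        from respiroscreen import expr, synthdata
        sim = synthdata.simulate_expression(n_genes=600, de_log2fc=2.0,
                                            nb_dispersion=0.0,
                                            nb_mean_range=(2000, 8000),
                                            block_spec=(), seed=11)
        fc = expr.call_de(sim.counts, sim.meta, ("glycerol", "glucose"))
        de = fc.genes("up") | fc.genes("down")
        bio = sim.gene_map.data.set_index("gene_id")["biotype"]
        res = ncrna_adjacency(sim.gene_map,
                              de_coding={g for g in de if bio[g] == "coding"},
                              de_ncrna={g for g in de if bio[g] == "ncRNA"})
        assert set(sim.truth.adjacency_pairs) <= set(res.pairs)
        assert res.fraction >= 0.7
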