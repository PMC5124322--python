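import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from respiroscreen.errors import DataError, ValidationError
from respiroscreen import screen, synthdata
from respiroscreen.screen import (RatioTable, aggregate_replicates, call_hits,
                                  cluster_strains, compute_ratios, consensus_hits,
                                  default_design, normalize_plate)
from respiroscreen.tables_io import ColonyTable


def _plate(sizes, plate_id="p1", strains=None):
    n = len(sizes)
    strains = strains or [f"s{i}" for i in range(n)]
    return ColonyTable.from_frame(pd.DataFrame({
        "plate_id": plate_id, "medium": "glucose",
        "row": np.arange(n) + 1, "col": 1,
        "strain_id": strains, "size": sizes,
    }))


class TestNormalizePlate:
    @pytest.mark.parametrize("sizes,expected", [
        ([2.0, 4.0, 4.0, 6.0], [0.5, 1.0, 1.0, 1.5]),
        ([3.0, 3.0, 3.0], [1.0, 1.0, 1.0]),
        # even count: median is the mean of the two middle values (2.5)
        ([1.0, 2.0, 3.0, 4.0], [0.4, 0.8, 1.2, 1.6]),
    ])
    def test_divides_by_plate_median(self, sizes, expected):
        out = normalize_plate(_plate(sizes))
        assert out.data["size"].tolist() == pytest.approx(expected)

    def test_missing_propagates_and_median_ignores_it(self):
        out = normalize_plate(_plate([2.0, np.nan, 4.0, 6.0]))
        assert out.data["size"].tolist()[0] == pytest.approx(0.5)
        assert np.isnan(out.data["size"].tolist()[1])

    def test_all_missing_plate_is_error(self):
        with pytest.raises(DataError, match="p1"):
            normalize_plate(_plate([np.nan, np.nan]))

    def test_plates_normalized_independently(self):
        t1, t2 = _plate([2.0, 4.0]), _plate([20.0, 40.0], plate_id="p2")
        both = ColonyTable(pd.concat([t1.data, t2.data], ignore_index=True))
        out = normalize_plate(both)
        assert out.data["size"].tolist() == pytest.approx([2 / 3, 4 / 3, 2 / 3, 4 / 3])


class TestAggregateReplicates:
    @pytest.mark.parametrize("values,expected", [
        ([0.9, 1.0, 1.0, 1.1], 1.0),
        ([1.0, 1.0, 1.0, 5.0], 1.0),     # median is outlier-robust
    ])
    def test_median_of_replicates(self, values, expected):
        table = _plate(values, strains=["s"] * 4)
        agg = aggregate_replicates(table)
        assert agg["s"] == pytest.approx(expected)

    def test_min_present_policy(self):
        table = _plate([1.0, np.nan, np.nan, np.nan], strains=["s"] * 4)
        assert np.isnan(aggregate_replicates(table, min_present=2)["s"])
        assert aggregate_replicates(table, min_present=1)["s"] == 1.0

    def test_unmapped_strain_is_error(self):
        table = _plate([1.0, 1.0])
        with pytest.raises(DataError, match="ghost"):
            aggregate_replicates(table, replicate_map={"ghost": []})


class TestComputeRatios:
    def test_floor_applied(self):
        rt = compute_ratios({"s1": pd.Series({"a": 0.1})},
                            {"s1": pd.Series({"a": 1.0})})
        assert rt.values.loc["a", "s1"] == 0.2

    def test_identity_ratio(self):
        rt = compute_ratios({"s1": pd.Series({"a": 0.8})},
                            {"s1": pd.Series({"a": 0.8})})
        assert rt.values.loc["a", "s1"] == pytest.approx(1.0)

    def test_incomplete_strain_removed(self):
        resp = {"s1": pd.Series({"a": 1.0, "b": 1.0}),
                "s2": pd.Series({"a": 1.0, "b": 1.0})}
        ferm = {"s1": pd.Series({"a": 1.0, "b": np.nan}),
                "s2": pd.Series({"a": 1.0, "b": 1.0})}
        rt = compute_ratios(resp, ferm)
        assert list(rt.strains) == ["a"]

    def test_zero_fermentative_is_missing_not_division_error(self):
        rt = compute_ratios({"s1": pd.Series({"a": 1.0})},
                            {"s1": pd.Series({"a": 0.0})}, drop_incomplete=False)
        assert np.isnan(rt.values.loc["a", "s1"])

    def test_floor_is_global_minimum(self):
        rng = np.random.default_rng(0)
        resp = {"s1": pd.Series(rng.uniform(0.01, 2, 50))}
        ferm = {"s1": pd.Series(np.ones(50))}
        rt = compute_ratios(resp, ferm, floor=0.2)
        assert rt.values.min().min() >= 0.2


class TestCallHits:
    def test_strict_threshold_boundary(self):
        rt = RatioTable(pd.DataFrame({"s1": [0.84, 0.85]}, index=["a", "b"]))
        hits = call_hits(rt, threshold=0.85)
        assert hits["s1"] == frozenset({"a"})

    @given(st.lists(st.floats(0.2, 2.0), min_size=1, max_size=30),
           st.floats(0.5, 0.9), st.floats(0.0, 0.4))
    @settings(deadline=None, max_examples=50, derandomize=True)
    def test_hits_monotone_in_threshold(self, ratios, low, delta):
        rt = RatioTable(pd.DataFrame({"s1": ratios},
                                     index=[f"g{i}" for i in range(len(ratios))]))
        assert call_hits(rt, low)["s1"] <= call_hits(rt, low + delta)["s1"]

    def test_consensus_majority(self):
        hits = {"s1": frozenset("ab"), "s2": frozenset("a"), "s3": frozenset("ac")}
        assert consensus_hits(hits) == frozenset("a")
        assert consensus_hits(hits, min_screens=1) == frozenset("abc")


class TestPlateInvariance:
    def test_plate_scaling_changes_nothing(self):
        """Multiplying every colony on a plate by c>0 leaves normalized sizes,
        ratios and hits exactly unchanged (plate-median normalization)."""
        sim = synthdata.simulate_screen(n_strains=96, seed=2, noise_cv=0.1,
                                        missing_rate=0.0)
        ratios = screen.score_screens(sim.colonies, sim.design)
        scaled = {}
        for table_id, table in sim.colonies.items():
            df = table.data.copy()
            df["size"] = df["size"] * 4.0  # power of two: exact in binary fp
            scaled[table_id] = ColonyTable(df)
        ratios2 = screen.score_screens(scaled, sim.design)
        pd.testing.assert_frame_equal(ratios.values, ratios2.values)
        assert call_hits(ratios) == call_hits(ratios2)


class TestClusterStrains:
    @staticmethod
    def _two_archetype_table(n=40):
        rng = np.random.default_rng(5)
        screens = [f"s{i}" for i in range(9)]
        healthy = pd.DataFrame(1.0 + rng.normal(0, 0.02, (n, 9)),
                               index=[f"h{i}" for i in range(n)], columns=screens)
        sick = pd.DataFrame(0.3 + rng.normal(0, 0.02, (n, 9)),
                            index=[f"d{i}" for i in range(n)], columns=screens)
        return RatioTable(pd.concat([healthy, sick]))

    def test_separable_profiles_split_perfectly(self):
        rt = self._two_archetype_table()
        for algorithm in ("som", "kmeans"):
            result = cluster_strains(rt, algorithm=algorithm, k=2, grid=(1, 2), seed=0)
            healthy = set(result.labels[result.labels.index.str.startswith("h")])
            sick = set(result.labels[result.labels.index.str.startswith("d")])
            assert len(healthy) == len(sick) == 1 and healthy != sick

    def test_k_exceeding_strains_is_error(self):
        rt = self._two_archetype_table(n=2)
        with pytest.raises(ValidationError, match="exceeds"):
            cluster_strains(rt, k=100, grid=(10, 10))

    def test_som_labels_invariant_to_input_order(self):
        rt = self._two_archetype_table()
        res = cluster_strains(rt, algorithm="som", k=4, grid=(2, 2), seed=0)
        shuffled = RatioTable(rt.values.sample(frac=1, random_state=9))
        res2 = cluster_strains(shuffled, algorithm="som", k=4, grid=(2, 2), seed=0)
        assert (res2.labels.reindex(res.labels.index) == res.labels).all()

    def test_planted_backgrounds_get_distinct_flags(self):
        sim = synthdata.simulate_screen(n_strains=600, seed=7, deficient_frac=0.1)
        ratios = screen.score_screens(sim.colonies, sim.design)
        result = cluster_strains(ratios, algorithm="som", k=12, seed=0,
                                 design=sim.design)
        p_clusters = {c for c, f in result.flags.items() if f == "P-like"}
        a_clusters = {c for c, f in result.flags.items() if f == "A-like"}
        assert p_clusters and a_clusters
        p_strains = [s for s, b in sim.truth.deficient.items()
                     if b == "prototroph" and s in result.labels.index]
        a_strains = [s for s, b in sim.truth.deficient.items()
                     if b == "auxotroph" and s in result.labels.index]
        assert set(result.labels[p_strains].mode()) <= p_clusters
        assert set(result.labels[a_strains].mode()) <= a_clusters


def test_default_design_has_nine_screens_two_backgrounds():
    design = default_design()
    assert len(design) == 9
    assert len(design.by_background("prototroph")) == 7
    assert len(design.by_background("auxotroph")) == 2


def test_design_round_trips_through_tsv(tmp_path):
    design = default_design()
    design.to_tsv(tmp_path / "d.tsv")
    assert screen.ScreenDesign.from_tsv(tmp_path / "d.tsv") == design
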