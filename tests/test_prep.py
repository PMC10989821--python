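import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from salinet.prep import (
    assign_salinity_groups,
    classify_abundance,
    clr_transform,
    prevalence_filter,
    rarefy,
)


class TestRarefy:
    def test_exact_depth_and_drop_report(self):
        table = pd.DataFrame(
            {"deep": [60, 40, 0], "shallow": [50, 30, 20], "short": [10, 5, 0]},
            index=["a", "b", "c"],
        )
        res = rarefy(table, depth=80, seed=0)
        assert res.dropped == ["short"]
        assert list(res.table.columns) == ["deep", "shallow"]
        assert (res.table.sum(axis=0) == 80).all()

    def test_subsample_equals_sample_at_full_depth(self):
        table = pd.DataFrame({"s": [2, 0]}, index=["a", "b"])
        res = rarefy(table, depth=2, seed=1)
        assert res.table["s"].tolist() == [2, 0]

    def test_hypergeometric_mean(self):
        """Subsampling (60, 40) to depth 10 has expectation (6, 4)."""
        table = pd.DataFrame({"s": [60, 40]}, index=["a", "b"])
        draws = np.array(
            [rarefy(table, 10, seed=k).table["s"].to_numpy() for k in range(2000)]
        )
        assert (draws.sum(axis=1) == 10).all()
        # brute-force hypergeometric oracle: E = depth * 60/100 = 6
        assert abs(draws[:, 0].mean() - 6.0) < 0.15

    def test_all_samples_too_shallow(self):
        table = pd.DataFrame({"s": [3, 2]}, index=["a", "b"])
        with pytest.raises(ValueError, match="fewer than"):
            rarefy(table, depth=100)

    def test_subsample_never_exceeds_original(self):
        rng = np.random.default_rng(0)
        table = pd.DataFrame(rng.integers(0, 50, (20, 4)))
        table.index = table.index.astype(str)
        table.columns = table.columns.astype(str)
        res = rarefy(table, depth=int(table.sum(axis=0).min()), seed=3)
        assert (res.table.to_numpy() <= table[res.table.columns].to_numpy()).all()


class TestClassifyAbundance:
    @pytest.mark.parametrize(
        "mean_ra, expected",
        [(0.002, "abundant"), (0.00005, "rare"), (0.0005, "intermediate")],
    )
    def test_threshold_sides(self, mean_ra, expected):
        # taxon 0 at the requested mean relative abundance, filler taxon takes the rest
        depth = 1_000_000
        counts = pd.DataFrame(
            {"s1": [int(mean_ra * depth), depth - int(mean_ra * depth)]},
            index=["focal", "filler"],
        )
        assert classify_abundance(counts)["focal"] == expected

    def test_boundary_is_intermediate(self):
        depth = 100_000
        counts = pd.DataFrame(
            {"s1": [100, 10, depth - 110]}, index=["at_abundant", "at_rare", "filler"]
        )
        classes = classify_abundance(counts)
        assert classes["at_abundant"] == "intermediate"  # exactly 0.1%
        assert classes["at_rare"] == "intermediate"  # exactly 0.01%

    def test_invariant_to_global_rescale(self, tiny_table):
        assert classify_abundance(tiny_table).equals(classify_abundance(tiny_table * 13))


class TestSalinityGroups:
    def test_sorted_chunking(self):
        meta = pd.DataFrame({"salinity": [4.0, 1.0, 6.0, 3.0, 2.0, 5.0]},
                            index=list("abcdef"))
        groups = assign_salinity_groups(meta, 2)
        assert set(groups[0].sample_ids) == {"b", "e", "d"}
        assert set(groups[1].sample_ids) == {"a", "f", "c"}
        assert groups[0].mean_salinity < groups[1].mean_salinity

    def test_equal_groups_of_eight(self):
        meta = pd.DataFrame({"salinity": np.linspace(0.8, 21, 48)},
                            index=[f"s{i:02d}" for i in range(48)])
        groups = assign_salinity_groups(meta, 6)
        assert len(groups) == 6
        assert all(len(g.sample_ids) == 8 for g in groups)
        assert [g.mean_salinity for g in groups] == sorted(g.mean_salinity for g in groups)

    def test_tie_broken_by_sample_id(self):
        meta = pd.DataFrame({"salinity": [1.0, 1.0, 2.0, 3.0]}, index=["z", "a", "m", "q"])
        groups = assign_salinity_groups(meta, 2)
        assert groups[0].sample_ids == ("a", "z")

    def test_remainder_policies(self):
        meta = pd.DataFrame({"salinity": np.arange(7.0)}, index=list("abcdefg"))
        with pytest.raises(ValueError, match="divisible"):
            assign_salinity_groups(meta, 2)
        groups = assign_salinity_groups(meta, 2, remainder="trim")
        assert sum(len(g.sample_ids) for g in groups) == 6
        # the highest-salinity sample is the one trimmed
        assert "g" not in {s for g in groups for s in g.sample_ids}


class TestPrevalenceFilter:
    def test_all_samples_mode_removes_partial_taxa(self, tiny_table):
        kept = prevalence_filter(tiny_table, ["s1", "s2", "s3"], 1.0)
        assert list(kept.index) == ["taxB"]

    def test_half_prevalence_retains(self, tiny_table):
        kept = prevalence_filter(tiny_table, ["s1", "s2"], 0.5)
        assert "taxA" in kept.index  # present in 1 of 2 >= ceil(0.5*2)=1

    def test_all_positive_identity(self):
        table = pd.DataFrame(np.ones((3, 4)), index=list("abc"), columns=list("wxyz"))
        assert prevalence_filter(table, list("wxyz"), 1.0).shape == (3, 4)


class TestCLR:
    def test_equal_composition_maps_to_zero(self):
        table = pd.DataFrame({"s": [1, 1, 1, 1]}, index=list("abcd"))
        assert np.allclose(clr_transform(table, 0.0)["s"], 0.0)

    def test_geometric_progression(self):
        table = pd.DataFrame({"s": [1.0, np.e, np.e**2, np.e**3]}, index=list("abcd"))
        assert np.allclose(clr_transform(table, 0.0)["s"], [-1.5, -0.5, 0.5, 1.5])

    def test_zero_requires_pseudocount(self, tiny_table):
        with pytest.raises(ValueError, match="pseudocount"):
            clr_transform(tiny_table, 0.0)

    @given(
        st.lists(
            st.lists(st.integers(min_value=0, max_value=10_000), min_size=3, max_size=3),
            min_size=2,
            max_size=8,
        )
    )
    @settings(max_examples=50, deadline=None)
    def test_samples_sum_to_zero(self, rows):
        table = pd.DataFrame(rows).T
        table.index = [f"t{i}" for i in range(3)]
        table.columns = [f"s{i}" for i in range(table.shape[1])]
        out = clr_transform(table, pseudocount=1.0)
        assert np.abs(out.sum(axis=0)).max() < 1e-10

    def test_matches_skbio_on_positive_data(self, rng):
        skbio_comp = pytest.importorskip("skbio.stats.composition")
        x = rng.integers(1, 500, (6, 5)).astype(float)
        table = pd.DataFrame(x, index=list("abcdef"), columns=list("vwxyz"))
        ours = clr_transform(table, pseudocount=0.0).to_numpy()
        theirs = np.column_stack(
            [skbio_comp.clr(x[:, j] / x[:, j].sum()) for j in range(x.shape[1])]
        )
        assert np.allclose(ours, theirs, atol=1e-10)
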