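import networkx as nx
import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from salinet.roles import (
    breadth_comparison,
    class_gap,
    freeman_theta,
    levins_breadth,
    relative_degree,
    role_trends,
)


def _classes(mapping):
    return pd.Series(mapping, dtype=object)


class TestRelativeDegree:
    def test_definition(self):
        g = nx.star_graph(8)  # hub degree 8, leaves 1; avg = 16/9
        rec = relative_degree(g, _classes({n: "abundant" for n in g}))
        hub = rec.set_index("taxon").loc[0]
        assert hub["relative_degree"] == pytest.approx(8 / (16 / 9))

    def test_mean_identity(self, rng):
        for seed in range(5):
            g = nx.gnp_random_graph(25, 0.2, seed=seed)
            g.remove_nodes_from(list(nx.isolates(g)))
            rec = relative_degree(g, _classes({n: "rare" for n in g}))
            assert rec["relative_degree"].mean() == pytest.approx(1.0, abs=1e-12)

    def test_regular_graph_all_ones(self):
        g = nx.cycle_graph(10)
        rec = relative_degree(g, _classes({n: "abundant" for n in g}))
        assert np.allclose(rec["relative_degree"], 1.0)

    def test_edgeless_rejected(self):
        with pytest.raises(ValueError, match="edgeless"):
            relative_degree(nx.empty_graph(3), _classes({}))


class TestClassGap:
    def _records(self, ab, ra):
        rows = [{"abundance_class": "abundant", "relative_degree": v} for v in ab]
        rows += [{"abundance_class": "rare", "relative_degree": v} for v in ra]
        return pd.DataFrame(rows)

    def test_direct_arithmetic(self):
        gap = class_gap(self._records([2.0, 2.0], [0.5, 0.5]))
        assert gap.difference == pytest.approx(1.5)
        assert gap.defined

    def test_identical_distributions_zero(self):
        gap = class_gap(self._records([1.0, 2.0], [1.0, 2.0]))
        assert gap.difference == pytest.approx(0.0)

    def test_missing_class_flagged(self):
        with pytest.warns(UserWarning, match="absent"):
            gap = class_gap(self._records([1.0], []))
        assert not gap.defined
        assert np.isnan(gap.difference)


class TestFreemanTheta:
    def _brute(self, a, b):
        p = sum(x > y for x in a for y in b)
        q = sum(x < y for x in a for y in b)
        return abs(p - q) / (len(a) * len(b))

    def test_complete_separation(self):
        assert freeman_theta([3, 4], [1, 2]) == 1.0

    def test_identical_pairs_zero(self):
        assert freeman_theta([1, 2], [1, 2]) == 0.0

    def test_ties_count_to_neither(self):
        assert freeman_theta([1, 2, 3], [2]) == 0.0

    @given(
        st.lists(st.integers(-5, 5), min_size=1, max_size=12),
        st.lists(st.integers(-5, 5), min_size=1, max_size=12),
    )
    @settings(max_examples=200, deadline=None)
    def test_matches_brute_force(self, a, b):
        assert freeman_theta(a, b) == pytest.approx(self._brute(a, b), abs=1e-12)

    @given(
        st.lists(st.floats(-10, 10, allow_nan=False), min_size=2, max_size=8),
        st.lists(st.floats(-10, 10, allow_nan=False), min_size=2, max_size=8),
    )
    @settings(max_examples=100, deadline=None)
    def test_symmetry_and_monotone_invariance(self, a, b):
        theta = freeman_theta(a, b)
        assert 0.0 <= theta <= 1.0
        assert theta == pytest.approx(freeman_theta(b, a))
        # doubling is strictly monotone and exact in binary floats, so the
        # pair ordering (and hence theta) is preserved without rounding
        assert freeman_theta([2 * x for x in a], [2 * x for x in b]) == pytest.approx(theta)


class TestRoleTrends:
    def _records_for(self, g, classes):
        return relative_degree(g, classes)

    def test_identical_networks_give_flat_trends(self):
        g = nx.gnp_random_graph(30, 0.3, seed=0)
        g.remove_nodes_from(list(nx.isolates(g)))
        classes = _classes(
            {n: ("abundant" if n % 3 == 0 else "rare" if n % 3 == 1 else "intermediate")
             for n in g}
        )
        recs = [self._records_for(g, classes) for _ in range(4)]
        trends = role_trends(recs, [1.0, 6.0, 12.0, 20.0])
        for t in trends.values():
            assert t.slope == pytest.approx(0.0, abs=1e-12)

    def test_planted_hub_erosion_recovered(self):
        """Abundant hubs lose edges along the gradient while rare nodes
        gain: abundant relative degree and theta fall, rare rises."""
        rng = np.random.default_rng(1)
        salinities = [2.0, 6.0, 10.0, 14.0, 18.0]
        recs = []
        for i, s in enumerate(salinities):
            g = nx.Graph()
            ab = [f"a{k}" for k in range(10)]
            ra = [f"r{k}" for k in range(10)]
            p_ab, p_ra = 0.9 - 0.04 * s, 0.05 + 0.02 * s
            for grp, p in ((ab, p_ab), (ra, p_ra)):
                for x in range(len(grp)):
                    for y in range(x + 1, len(grp)):
                        if rng.random() < p:
                            g.add_edge(grp[x], grp[y])
            g.add_edge(ab[0], ra[0])  # keep the graph non-degenerate
            classes = _classes({**{n: "abundant" for n in ab}, **{n: "rare" for n in ra}})
            recs.append(self._records_for(g, classes))
        trends = role_trends(recs, salinities)
        assert trends["abundant_relative_degree"].slope < 0
        assert trends["rare_relative_degree"].slope > 0
        assert trends["freeman_theta"].slope < 0
        assert trends["class_gap"].slope < 0

    def test_two_networks_rejected(self):
        g = nx.path_graph(4)
        classes = _classes({n: "abundant" for n in g})
        recs = [self._records_for(g, classes)] * 2
        with pytest.raises(ValueError, match="3 networks"):
            role_trends(recs, [1.0, 2.0])


class TestLevinsBreadth:
    def test_uniform_occupancy(self):
        table = pd.DataFrame(np.ones((1, 8)), index=["t"], columns=[f"s{i}" for i in range(8)])
        assert levins_breadth(table).loc["t", "levins_B"] == pytest.approx(8.0)

    def test_single_sample_occupancy(self):
        table = pd.DataFrame([[9, 0, 0]], index=["t"], columns=list("abc"))
        out = levins_breadth(table)
        assert out.loc["t", "levins_B"] == pytest.approx(1.0)
        assert out.loc["t", "standardized_B_A"] == pytest.approx(0.0)

    def test_half_half(self):
        table = pd.DataFrame([[5, 5, 0, 0]], index=["t"], columns=list("abcd"))
        assert levins_breadth(table).loc["t", "levins_B"] == pytest.approx(2.0)

    def test_scale_invariance_and_bounds(self, rng):
        table = pd.DataFrame(rng.integers(0, 50, (30, 12)) + rng.integers(0, 2, (30, 12)))
        table.index = [f"t{i}" for i in range(30)]
        table = table[table.sum(axis=1) > 0]
        b1 = levins_breadth(table)["levins_B"]
        b2 = levins_breadth(table * 7)["levins_B"]
        assert np.allclose(b1, b2)
        assert ((b1 >= 1 - 1e-12) & (b1 <= 12 + 1e-12)).all()

    def test_all_zero_taxon_excluded(self):
        table = pd.DataFrame([[1, 2], [0, 0]], index=["ok", "zero"], columns=["a", "b"])
        with pytest.warns(UserWarning, match="all-zero"):
            out = levins_breadth(table)
        assert "zero" not in out.index


class TestBreadthComparison:
    def _breadth_frame(self, ab_vals, ra_vals):
        rows = [{"levins_B": v, "abundance_class": "abundant"} for v in ab_vals]
        rows += [{"levins_B": v, "abundance_class": "rare"} for v in ra_vals]
        return pd.DataFrame(rows, index=[f"t{i}" for i in range(len(rows))])

    def test_separated_distributions_significant(self):
        frame = self._breadth_frame([8.0] * 12, [1.0] * 12)
        stat, p = breadth_comparison(frame)
        assert p < 0.001

    def test_matches_scipy_direct(self, rng):
        ab = rng.uniform(1, 8, 9)
        ra = rng.uniform(1, 8, 7)
        frame = self._breadth_frame(list(ab), list(ra))
        stat, p = breadth_comparison(frame)
        ref = stats.mannwhitneyu(ab, ra, alternative="two-sided", method="exact")
        assert stat == pytest.approx(float(ref.statistic))
        assert p == pytest.approx(float(ref.pvalue))

    def test_single_member_class_still_computes(self):
        frame = self._breadth_frame([5.0], [1.0, 2.0, 3.0])
        stat, p = breadth_comparison(frame)
        assert 0 < p <= 1

    def test_missing_class_rejected(self):
        frame = self._breadth_frame([5.0], [])
        with pytest.raises(ValueError, match="represented"):
            breadth_comparison(frame)
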