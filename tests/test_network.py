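"""Interaction unification, bipartite construction, degree statistics."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

import mirnetkit as mk
from mirnetkit.network import EmptyNetworkError, InsufficientDegreeSupportError


def records(rows, source="db1"):
    return pd.DataFrame(rows, columns=["mirna_id", "gene_symbol"]).assign(source_db=source)


def diff_frame(mapping):
    return pd.DataFrame(
        {
            "mirna_id": list(mapping),
            "direction": list(mapping.values()),
            "fc_line1": 2.0,
            "fc_line2": 2.0,
        }
    )


class TestNameNormalization:
    @pytest.mark.parametrize(
        "raw,expected",
        [
            ("MIR-34A-5P", "miR-34a-5p"),
            (" miR-34a-5p ", "miR-34a-5p"),
            ("mir - 34a - 5p", "miR-34a-5p"),
            ("hsa-MIR-21", "hsa-miR-21"),
        ],
    )
    def test_mirna_canonical_form(self, raw, expected):
        assert mk.normalize_mirna(raw) == expected

    def test_gene_upper_cased_trimmed(self):
        assert mk.normalize_gene(" cdk4 ") == "CDK4"

    def test_accession_variants_stay_distinct(self):
        assert mk.normalize_mirna("miR-34a") != mk.normalize_mirna("miR-34a-5p")


class TestUnify:
    def test_same_pair_in_two_sources_one_edge(self):
        a = records([("miR-1", "TP53")], "db1")
        b = records([("miR-1", "TP53")], "db2")
        out = mk.unify_interactions([a, b])
        assert len(out) == 1
        assert out.loc[0, "sources"] == "db1;db2"

    def test_case_variants_collapse_to_one_pair(self):
        out = mk.unify_interactions(
            records([("MIR-34A-5P", "cdk4"), ("miR-34a-5p", "CDK4")])
        )
        assert len(out) == 1
        assert out.loc[0, "mirna_id"] == "miR-34a-5p"
        assert out.loc[0, "gene_symbol"] == "CDK4"

    def test_malformed_rows_skipped(self):
        df = records([("miR-1", "TP53"), ("", "TP53"), ("miR-2", None)])
        assert len(mk.unify_interactions(df)) == 1

    def test_idempotent(self, bundle):
        again = mk.unify_interactions(bundle.pairs.assign(source_db=bundle.pairs["sources"]))
        assert len(again) == len(bundle.pairs)
        assert again["mirna_id"].tolist() == bundle.pairs["mirna_id"].tolist()

    def test_order_and_partition_independent(self, bundle):
        cat = pd.concat(bundle.sources.values(), ignore_index=True)
        shuffled = cat.sample(frac=1.0, random_state=1).reset_index(drop=True)
        bounds = np.linspace(0, len(shuffled), 8, dtype=int)
        repartitioned = [shuffled.iloc[a:b] for a, b in zip(bounds[:-1], bounds[1:])]
        out = mk.unify_interactions(repartitioned)
        pd.testing.assert_frame_equal(out, bundle.pairs)


class TestBuildNetwork:
    def test_restriction_to_differential(self):
        pairs = mk.unify_interactions(records([("miR-1", "A"), ("miR-2", "B")]))
        net = mk.build_network(pairs, diff_frame({"miR-1": "up"}))
        assert net.n_edges == 1
        assert net.mirnas == ["miR-1"] and net.genes == ["A"]
        assert net.graph.nodes["miR-1"]["direction"] == "up"

    def test_all_non_differential_gives_empty(self):
        pairs = mk.unify_interactions(records([("miR-1", "A")]))
        net = mk.build_network(pairs, diff_frame({"miR-9": "down"}))
        assert net.n_edges == 0

    def test_degree_bookkeeping(self, bundle):
        g = bundle.net.graph
        mirna_deg = sum(g.degree[m] for m in bundle.net.mirnas)
        gene_deg = sum(g.degree[n] for n in bundle.net.genes)
        assert mirna_deg == gene_deg == bundle.net.n_edges

    def test_restriction_monotonicity(self, bundle):
        smaller = bundle.differential.iloc[:30]
        net_small = mk.build_network(bundle.pairs, smaller)
        assert net_small.n_edges <= bundle.net.n_edges
        assert set(net_small.graph.edges()) <= set(bundle.net.graph.edges())


class TestDegreeDistribution:
    def star(self):
        pairs = mk.unify_interactions(records([("miR-1", g) for g in "ABCDE"]))
        return mk.build_network(pairs, diff_frame({"miR-1": "up"}))

    def test_star_gene_side(self):
        dist = mk.degree_distribution(self.star(), side="gene")
        assert dist.to_dict() == {1: 1.0}

    def test_star_mirna_side(self):
        dist = mk.degree_distribution(self.star(), side="mirna")
        assert dist.to_dict() == {5: 1.0}

    def test_two_mirna_split(self):
        pairs = mk.unify_interactions(
            records([("miR-1", "A"), ("miR-2", "B"), ("miR-2", "C"), ("miR-2", "D")])
        )
        net = mk.build_network(pairs, diff_frame({"miR-1": "up", "miR-2": "up"}))
        dist = mk.degree_distribution(net, side="mirna")
        assert dist.to_dict() == {1: 0.5, 3: 0.5}

    def test_frequencies_sum_to_one(self, bundle):
        for side in ("mirna", "gene", "both"):
            assert mk.degree_distribution(bundle.net, side=side).sum() == pytest.approx(1.0)

    def test_empty_network_raises(self):
        net = mk.BipartiteNetwork(graph=__import__("networkx").Graph())
        with pytest.raises(EmptyNetworkError):
            mk.degree_distribution(net)


def closed_form_ols(x, y):
    """Independent two-variable OLS: slope/intercept/R^2 from moments."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    sxx = np.sum((x - x.mean()) ** 2)
    sxy = np.sum((x - x.mean()) * (y - y.mean()))
    slope = sxy / sxx
    intercept = y.mean() - slope * x.mean()
    ss_res = np.sum((y - intercept - slope * x) ** 2)
    ss_tot = np.sum((y - y.mean()) ** 2)
    return slope, intercept, 1.0 - ss_res / ss_tot


class TestScaleFreeFit:
    def test_exact_power_law_recovered(self):
        k = np.array([1, 2, 4, 8], dtype=float)
        p = k**-2.0
        fit = mk.scale_free_fit(pd.Series(p / p.sum(), index=k))
        assert fit.slope == pytest.approx(-2.0, abs=1e-10)
        assert fit.r_squared == pytest.approx(1.0, abs=1e-10)

    def test_flat_distribution_degenerate(self):
        dist = pd.Series([0.25] * 4, index=[1.0, 2.0, 3.0, 4.0])
        fit = mk.scale_free_fit(dist)
        assert fit.degenerate and fit.r_squared == 1.0 and fit.slope == 0.0

    def test_three_point_fit_matches_hand_ols(self):
        dist = pd.Series([0.6, 0.3, 0.1], index=[1.0, 2.0, 4.0])
        fit = mk.scale_free_fit(dist)
        slope, intercept, r2 = closed_form_ols(np.log10(dist.index), np.log10(dist.values))
        assert fit.slope == pytest.approx(slope, rel=1e-10)
        assert fit.intercept == pytest.approx(intercept, rel=1e-10)
        assert fit.r_squared == pytest.approx(r2, rel=1e-10)

    def test_insufficient_support_raises(self):
        with pytest.raises(InsufficientDegreeSupportError):
            mk.scale_free_fit(pd.Series([0.5, 0.5], index=[1.0, 2.0]))

    @given(
        st.lists(
            st.tuples(st.integers(1, 500), st.floats(1e-6, 1.0)),
            min_size=3,
            max_size=10,
            unique_by=lambda t: t[0],
        )
    )
    def test_fit_matches_closed_form_on_random_points(self, points):
        ks = np.array([p[0] for p in points], float)
        ps = np.array([p[1] for p in points], float)
        dist = pd.Series(ps, index=ks)
        x, y = np.log10(ks), np.log10(ps)
        if len(np.unique(x)) < 3 or np.ptp(y) < 1e-3:
            return  # degenerate or ill-conditioned; covered by the flat test
        slope, intercept, r2 = closed_form_ols(x, y)
        fit = mk.scale_free_fit(dist)
        assert fit.slope == pytest.approx(slope, rel=1e-9, abs=1e-9)
        assert fit.intercept == pytest.approx(intercept, rel=1e-9, abs=1e-9)
        assert fit.r_squared == pytest.approx(r2, rel=1e-9, abs=1e-9)

    def test_fixture_network_fit_is_heavy_tailed(self, bundle):
        fit = mk.scale_free_fit(mk.degree_distribution(bundle.net, side="both"))
        assert fit.slope < 0
        assert 0.0 < fit.r_squared <= 1.0
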