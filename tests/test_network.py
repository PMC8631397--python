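"""Network construction from printed tables and from simulated cohorts."""

import numpy as np
import pandas as pd
import pytest

from oculonet.datasets import load_paper_tables, target_correlation_matrix
from oculonet.exceptions import ComputationError, FixtureError
from oculonet.measures import (
    ALL_MEASURES,
    COGNITIVE_MEASURES,
    DOMAINS,
    OCULOMOTOR_MEASURES,
)
from oculonet.network import (
    CorrelationNetworkModel,
    CorrelationNetworkResults,
    Network,
)


def _cognitive_only(printed_results):
    cog = list(COGNITIVE_MEASURES)
    return CorrelationNetworkResults(
        corr=printed_results.corr.loc[cog, cog],
        domains={m: "cognitive" for m in cog},
        sig_codes=printed_results.sig_codes.loc[cog, cog],
    )


def _oculomotor_only(printed_results):
    ocu = list(OCULOMOTOR_MEASURES)
    return CorrelationNetworkResults(
        corr=printed_results.corr.loc[ocu, ocu],
        domains={m: "oculomotor" for m in ocu},
        sig_codes=printed_results.sig_codes.loc[ocu, ocu],
    )


class TestPaperTables:
    def test_published_cells_are_loaded_verbatim(self, paper_tables):
        cog = paper_tables.cognitive
        row = cog[(cog.row_label == "DS") & (cog.col_label == "SC")].iloc[0]
        assert row.r == 0.63 and row.sig_code == ".001"
        ocu = paper_tables.oculomotor
        row = ocu[(ocu.row_label == "ASELs") & (ocu.col_label == "ASEs")].iloc[0]
        assert row.r == 0.02 and row.sig_code == "ns"
        cross = paper_tables.cross
        row = cross[(cross.row_label == "ASLs") & (cross.col_label == "SC")].iloc[0]
        assert row.r == -0.46 and row.sig_code == ".001"

    def test_target_matrix_is_valid_correlation_input(self, paper_tables):
        mat = target_correlation_matrix(paper_tables)
        vals = mat.to_numpy()
        assert np.allclose(vals, vals.T)
        assert np.allclose(np.diag(vals), 1.0)
        assert np.linalg.eigvalsh(vals).min() > 0

    def test_missing_fixture_raises_naming_file(self, monkeypatch):
        from oculonet import datasets

        monkeypatch.setitem(datasets._FIXTURES, "cognitive", "no_such_table.csv")
        with pytest.raises(FixtureError, match="no_such_table.csv"):
            load_paper_tables()


class TestFullNetwork:
    def test_cross_domain_neighbour_counts_match_printed_claims(self, printed_results):
        net = printed_results.full_network(alpha=0.05)
        assert net.cross_domain_degree("SC") == 5
        assert net.cross_domain_degree("DS") == 4
        assert net.cross_domain_degree("ASELs") == 0
        assert net.cross_domain_degree("TMT") == 0
        assert net.cross_domain_degree("VF") == 3  # ASLs, GnGLs, GnGELs
        assert net.cross_domain_degree("VM") == 1  # GnGEs only
        assert net.cross_domain_degree("TL") == 1  # ASLs only

    def test_marginal_codes_are_excluded_at_alpha_05(self, printed_results):
        # ASEs-VF is printed at the p<0.1 level only
        net = printed_results.full_network(alpha=0.05)
        assert not net.graph.has_edge("ASEs", "VF")
        net10 = printed_results.full_network(alpha=0.1)
        assert net10.graph.has_edge("ASEs", "VF")

    def test_all_ns_table_gives_empty_network(self):
        names = ["a", "b", "c"]
        corr = pd.DataFrame(np.eye(3) * 0 + 0.2, index=names, columns=names)
        codes = pd.DataFrame("ns", index=names, columns=names)
        res = CorrelationNetworkResults(
            corr=corr, domains={n: "cognitive" for n in names}, sig_codes=codes
        )
        assert res.full_network(0.05).n_edges == 0


class TestThresholdedNetwork:
    def test_cognitive_table_has_11_edges_with_vf_sc_central(self, printed_results):
        net = _cognitive_only(printed_results).thresholded_network(0.4)
        assert net.n_edges == 11
        assert net.degree("VF") == 5
        assert net.degree("SC") == 5
        assert net.central_nodes() == {"VF", "SC"}

    def test_oculomotor_latency_error_nodes_tie(self, printed_results):
        net = _oculomotor_only(printed_results).thresholded_network(0.4)
        assert net.degree("ASLs") == net.degree("GnGLs") == net.degree("ASEs") == 3

    def test_combined_network_cross_domain_structure(self, printed_results):
        net = printed_results.thresholded_network(0.4)
        assert net.n_cross_domain_edges == 3
        for node in ("ASLs", "GnGLs", "ASEs"):
            assert net.cross_domain_degree(node) == 1
        assert net.degree("ASELs") == 0  # isolated at tau = 0.4
        assert net.central_nodes() == {"SC"}

    def test_threshold_is_strict(self, printed_results):
        # r(DS, TMT) = 0.39 and r(ASEs, GnGEs) = 0.41 bracket the cut
        net = printed_results.thresholded_network(0.4)
        assert not net.graph.has_edge("DS", "TMT")
        assert net.graph.has_edge("ASEs", "GnGEs")

    def test_zero_correlations_give_no_edges(self):
        names = ["a", "b"]
        corr = pd.DataFrame(np.eye(2), index=names, columns=names)
        res = CorrelationNetworkResults(
            corr=corr, domains={n: "cognitive" for n in names}
        )
        assert res.thresholded_network(0.4).n_edges == 0


class TestNetworkInvariants:
    def test_thresholded_edges_nest_inside_full(self, printed_results):
        full = printed_results.full_network(0.05)
        thr = printed_results.thresholded_network(0.4)
        for a, b in thr.graph.edges:
            assert full.graph.has_edge(a, b)

    def test_monotone_in_tau_and_alpha(self, printed_results):
        e_tau = [
            printed_results.thresholded_network(tau).n_edges
            for tau in (0.2, 0.3, 0.4, 0.5, 0.6)
        ]
        assert e_tau == sorted(e_tau, reverse=True)
        e_alpha = [
            printed_results.full_network(alpha).n_edges
            for alpha in (0.1, 0.05, 0.01, 0.001)
        ]
        assert e_alpha == sorted(e_alpha, reverse=True)

    def test_sign_structure_within_vs_cross_domain(self, printed_results):
        net = printed_results.thresholded_network(0.4)
        for a, b, d in net.graph.edges(data=True):
            same = net.graph.nodes[a]["domain"] == net.graph.nodes[b]["domain"]
            assert d["sign"] == (1 if same else -1)

    def test_degree_errors_on_unknown_node(self, printed_results):
        net = printed_results.thresholded_network(0.4)
        with pytest.raises(ValueError):
            net.degree("XYZ")

    def test_central_nodes_on_empty_domain_filter(self, printed_results):
        net = printed_results.thresholded_network(0.4)
        assert "SC" in net.central_nodes(domain="cognitive")
        with pytest.raises(ComputationError):
            empty = Network(graph=net.graph.subgraph([]).copy(), mode="x", param=0)
            empty.central_nodes()

    def test_single_edge_ties_both_endpoints(self):
        names = ["a", "b", "c"]
        corr = pd.DataFrame(np.eye(3), index=names, columns=names)
        corr.loc["a", "b"] = corr.loc["b", "a"] = 0.9
        res = CorrelationNetworkResults(
            corr=corr, domains={n: "cognitive" for n in names}
        )
        assert res.thresholded_network(0.4).central_nodes() == {"a", "b"}


class TestCorrelationModel:
    def test_independent_noise_yields_no_structure(self):
        rng = np.random.default_rng(0)
        df = pd.DataFrame(
            rng.normal(size=(10_000, 12)), columns=list(ALL_MEASURES)
        )
        res = CorrelationNetworkModel.from_dataframe(df, DOMAINS).fit()
        off = res.corr.to_numpy()[~np.eye(12, dtype=bool)]
        assert np.max(np.abs(off)) < 0.05

    def test_duplicated_column_correlates_perfectly(self):
        rng = np.random.default_rng(1)
        df = pd.DataFrame(
            rng.normal(size=(50, 12)), columns=list(ALL_MEASURES)
        )
        df["SC"] = df["DS"]
        res = CorrelationNetworkModel.from_dataframe(df, DOMAINS).fit()
        assert res.corr.loc["DS", "SC"] == pytest.approx(1.0)

    def test_pairwise_complete_handles_missing_cells(self):
        rng = np.random.default_rng(2)
        df = pd.DataFrame(
            rng.normal(size=(40, 12)), columns=list(ALL_MEASURES)
        )
        df.loc[:4, "ASELs"] = np.nan  # subjects with no error saccades
        res = CorrelationNetworkModel.from_dataframe(df, DOMAINS).fit()
        assert res.nobs.loc["ASELs", "SC"] == 35
        assert np.isfinite(res.corr.loc["ASELs", "SC"])

    def test_insufficient_pairs_warn_and_stay_missing(self):
        rng = np.random.default_rng(3)
        df = pd.DataFrame(
            rng.normal(size=(10, 12)), columns=list(ALL_MEASURES)
        )
        df.loc[2:, "ASELs"] = np.nan
        with pytest.warns(UserWarning, match="ASELs"):
            res = CorrelationNetworkModel.from_dataframe(df, DOMAINS).fit()
        assert np.isnan(res.corr.loc["ASELs", "SC"])

    def test_summary_mentions_central_node(self, printed_results):
        text = printed_results.summary()
        assert "SC" in text
        assert "thresholded network" in text


class TestExport:
    @pytest.mark.parametrize("fmt", ["graphml", "edge-list"])
    def test_files_written(self, printed_results, tmp_path, fmt):
        net = printed_results.thresholded_network(0.4)
        path = tmp_path / ("net.graphml" if fmt == "graphml" else "net.csv")
        net.export(path, format=fmt)
        assert path.exists() and path.stat().st_size > 0

    def test_graphml_round_trip_preserves_structure(self, printed_results, tmp_path):
        net = printed_results.thresholded_network(0.4)
        path = tmp_path / "net.graphml"
        net.export(path)
        back = Network.from_graphml(path)
        assert set(back.graph.nodes) == set(net.graph.nodes)
        assert set(map(frozenset, back.graph.edges)) == set(
            map(frozenset, net.graph.edges)
        )
        for a, b, d in net.graph.edges(data=True):
            assert back.graph[a][b]["weight"] == pytest.approx(d["weight"])
            assert back.graph[a][b]["sign"] == d["sign"]

    def test_empty_network_exports_all_nodes(self, printed_results, tmp_path):
        net = printed_results.thresholded_network(0.99)
        assert net.n_edges == 0
        path = tmp_path / "empty.graphml"
        net.export(path)
        assert len(Network.from_graphml(path).graph.nodes) == 12

    def test_cognitive_thresholded_edge_records(self, printed_results, tmp_path):
        net = _cognitive_only(printed_results).thresholded_network(0.4)
        path = tmp_path / "edges.csv"
        net.export(path, format="edge-list")
        assert len(pd.read_csv(path)) == 11

    def test_unknown_format_rejected(self, printed_results, tmp_path):
        net = printed_results.thresholded_network(0.4)
        with pytest.raises(ValueError):
            net.export(tmp_path / "x", format="dot")
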