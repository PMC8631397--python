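"""Two-domain correlation network: model, results, graphs, centrality.

The core object is :class:`CorrelationNetworkModel`, built from a subjects
x measures table with a domain label (cognitive / oculomotor) per measure.
``fit()`` computes pairwise-complete Pearson correlations with p-values
and returns a :class:`CorrelationNetworkResults`, from which two graphs
are derived:

* the *full* network — an edge for every pair significant at ``alpha``
  (default 0.05);
* the *thresholded* network — an edge for every pair with |r| strictly
  above ``tau`` (default 0.4).

Results can equally be constructed from printed correlation tables whose
cells carry a coefficient and a significance code instead of a p-value.
Centrality is degree (connection count); cross-domain degree counts only
opposite-domain neighbours.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations
from typing import Mapping

import networkx as nx
import numpy as np
import pandas as pd

from . import datasets
from .exceptions import ComputationError
from .measures import DOMAINS, SIG_CODE_LEVELS, sig_code_for_p
from .stats import pearson

__all__ = [
    "MeasureTable",
    "CorrelationNetworkModel",
    "CorrelationNetworkResults",
    "Network",
]

MIN_PAIRS = 3  # complete observation pairs needed for a correlation


@dataclass
class MeasureTable:
    """Subjects x measures matrix with a domain label per measure."""

    data: pd.DataFrame
    domains: Mapping[str, str]
    subject_ids: list[str] | None = None

    def __post_init__(self) -> None:
        unknown = set(self.data.columns) - set(self.domains)
        if unknown:
            raise ValueError(f"measures without a domain label: {sorted(unknown)}")
        bad = {d for d in self.domains.values()} - {"cognitive", "oculomotor"}
        if bad:
            raise ValueError(f"unknown domains: {sorted(bad)}")

    @classmethod
    def from_dataframe(
        cls,
        df: pd.DataFrame,
        domains: Mapping[str, str] | None = None,
        group: str | None = None,
    ) -> "MeasureTable":
        """Build from a data frame holding the 12 canonical measure columns.

        ``group`` filters on a ``group`` column when present (the network
        is built on patients only by default in the pipeline).
        """
        if group is not None and "group" in df.columns:
            df = df[df["group"] == group]
        subject_ids = (
            list(df["subject_id"]) if "subject_id" in df.columns else None
        )
        cols = [c for c in df.columns if c in (domains or DOMAINS)]
        if not cols:
            raise ValueError("no known measure columns found")
        return cls(
            data=df[cols].astype(float).reset_index(drop=True),
            domains={c: (domains or DOMAINS)[c] for c in cols},
            subject_ids=subject_ids,
        )

    @property
    def measure_names(self) -> list[str]:
        return list(self.data.columns)


class CorrelationNetworkModel:
    """Pairwise correlation model of a two-domain measure table."""

    def __init__(self, table: MeasureTable):
        self.table = table

    @classmethod
    def from_dataframe(
        cls,
        df: pd.DataFrame,
        domains: Mapping[str, str] | None = None,
        group: str | None = None,
    ) -> "CorrelationNetworkModel":
        return cls(MeasureTable.from_dataframe(df, domains, group))

    def fit(self) -> "CorrelationNetworkResults":
        """Compute pairwise-complete Pearson r, p and n for all measure pairs.

        Pairs with fewer than 3 complete observations are left missing
        with a warning.
        """
        names = self.table.measure_names
        k = len(names)
        r = pd.DataFrame(np.eye(k), index=names, columns=names)
        p = pd.DataFrame(np.zeros((k, k)), index=names, columns=names)
        n = pd.DataFrame(np.zeros((k, k), dtype=int), index=names, columns=names)
        data = self.table.data
        for a, b in combinations(names, 2):
            pair = data[[a, b]].dropna()
            if len(pair) < MIN_PAIRS:
                warnings.warn(
                    f"pair ({a}, {b}): only {len(pair)} complete observations; "
                    "correlation left missing"
                )
                r.loc[a, b] = r.loc[b, a] = np.nan
                p.loc[a, b] = p.loc[b, a] = np.nan
                continue
            res = pearson(pair[a].to_numpy(), pair[b].to_numpy())
            r.loc[a, b] = r.loc[b, a] = res.statistic
            p.loc[a, b] = p.loc[b, a] = res.p_value
            n.loc[a, b] = n.loc[b, a] = res.n
        return CorrelationNetworkResults(
            corr=r, pvalues=p, nobs=n, domains=dict(self.table.domains), model=self
        )


@dataclass
class CorrelationNetworkResults:
    """Fitted pairwise correlations and the graphs derived from them.

    ``pvalues`` may be absent when the results were built from printed
    tables; the significance codes then gate the full network.
    """

    corr: pd.DataFrame
    domains: dict[str, str]
    pvalues: pd.DataFrame | None = None
    nobs: pd.DataFrame | None = None
    sig_codes: pd.DataFrame | None = None
    model: CorrelationNetworkModel | None = None

    def __post_init__(self) -> None:
        if self.sig_codes is None and self.pvalues is not None:
            codes = self.pvalues.map(
                lambda p: "" if not np.isfinite(p) else sig_code_for_p(p)
            )
            np.fill_diagonal(codes.values, "")
            self.sig_codes = codes

    @property
    def measure_names(self) -> list[str]:
        return list(self.corr.columns)

    @classmethod
    def from_printed_tables(
        cls, tables: datasets.PaperTables | None = None
    ) -> "CorrelationNetworkResults":
        """Build results directly from the packaged published tables."""
        corr = datasets.target_correlation_matrix(tables)
        codes = datasets.sig_code_table(tables)
        return cls(corr=corr, domains=dict(DOMAINS), sig_codes=codes)

    # ----- edge rules ------------------------------------------------------

    def _significant(self, a: str, b: str, alpha: float) -> bool | None:
        """p < alpha, from p-values when available else from the code."""
        if self.pvalues is not None:
            p = self.pvalues.loc[a, b]
            if np.isfinite(p):
                return bool(p < alpha)
        if self.sig_codes is not None:
            code = self.sig_codes.loc[a, b]
            if code == "ns":
                return False
            level = SIG_CODE_LEVELS.get(code)
            if level is not None:
                return level <= alpha
        return None

    def full_network(self, alpha: float = 0.05) -> "Network":
        """Edge for every measure pair significant at ``alpha``."""
        g = self._empty_graph()
        for a, b in combinations(self.measure_names, 2):
            sig = self._significant(a, b, alpha)
            if sig is None:
                warnings.warn(f"pair ({a}, {b}): no p-value or code; skipped")
                continue
            if sig:
                self._add_edge(g, a, b)
        return Network(graph=g, mode="full", param=alpha)

    def thresholded_network(self, tau: float = 0.4) -> "Network":
        """Edge for every measure pair with |r| strictly above ``tau``."""
        g = self._empty_graph()
        for a, b in combinations(self.measure_names, 2):
            r = self.corr.loc[a, b]
            if np.isfinite(r) and abs(r) > tau:
                self._add_edge(g, a, b)
        return Network(graph=g, mode="thresholded", param=tau)

    def _empty_graph(self) -> nx.Graph:
        g = nx.Graph()
        for name in self.measure_names:
            g.add_node(name, domain=self.domains[name])
        return g

    def _add_edge(self, g: nx.Graph, a: str, b: str) -> None:
        r = float(self.corr.loc[a, b])
        code = ""
        if self.sig_codes is not None:
            code = str(self.sig_codes.loc[a, b])
        g.add_edge(a, b, weight=r, sign=1 if r >= 0 else -1, sig_code=code)

    # ----- reporting -------------------------------------------------------

    def summary(self, alpha: float = 0.05, tau: float = 0.4) -> str:
        """Human-readable account of the fit and both derived networks."""
        lines = ["Two-domain correlation network", "=" * 34]
        k = len(self.measure_names)
        lines.append(f"measures: {k} ({sum(1 for d in self.domains.values() if d == 'cognitive')} cognitive, "
                     f"{sum(1 for d in self.domains.values() if d == 'oculomotor')} oculomotor)")
        if self.nobs is not None:
            tri = self.nobs.values[np.triu_indices(k, 1)]
            lines.append(f"observations per pair: {int(tri.min())}–{int(tri.max())}")
        for label, net in (
            (f"full network (p < {alpha:g})", self.full_network(alpha)),
            (f"thresholded network (|r| > {tau:g})", self.thresholded_network(tau)),
        ):
            central = ", ".join(sorted(net.central_nodes())) if net.n_edges else "—"
            lines.append(
                f"{label}: {net.n_edges} edges "
                f"({net.n_cross_domain_edges} cross-domain); "
                f"most central: {central}"
            )
        lines.append("")
        lines.append("correlation matrix:")
        lines.append(self.corr.round(2).to_string())
        return "\n".join(lines)


@dataclass
class Network:
    """Undirected signed correlation graph over the 12 measures."""

    graph: nx.Graph
    mode: str  # "full" | "thresholded"
    param: float  # alpha or tau

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    @property
    def n_cross_domain_edges(self) -> int:
        return sum(
            1
            for a, b in self.graph.edges
            if self.graph.nodes[a]["domain"] != self.graph.nodes[b]["domain"]
        )

    def _check_node(self, node: str) -> None:
        if node not in self.graph:
            raise ValueError(f"unknown node {node!r}")

    def degree(self, node: str) -> int:
        """Number of incident edges."""
        self._check_node(node)
        return int(self.graph.degree[node])

    def cross_domain_degree(self, node: str) -> int:
        """Number of neighbours in the opposite domain."""
        self._check_node(node)
        mine = self.graph.nodes[node]["domain"]
        return sum(
            1 for nb in self.graph[node] if self.graph.nodes[nb]["domain"] != mine
        )

    def central_nodes(self, domain: str | None = None) -> set[str]:
        """All nodes attaining the maximal degree (ties as a set).

        ``domain`` restricts the candidate nodes; degrees still count all
        incident edges.
        """
        nodes = [
            n
            for n, d in self.graph.nodes(data=True)
            if domain is None or d["domain"] == domain
        ]
        if not nodes:
            raise ComputationError("network has no nodes in the requested domain")
        degs = {n: self.graph.degree[n] for n in nodes}
        top = max(degs.values())
        return {n for n, d in degs.items() if d == top}

    def centrality_table(self) -> pd.DataFrame:
        """Node, domain, degree and cross-domain degree for every node."""
        rows = [
            {
                "node": n,
                "domain": self.graph.nodes[n]["domain"],
                "degree": self.degree(n),
                "cross_domain_degree": self.cross_domain_degree(n),
            }
            for n in self.graph.nodes
        ]
        return pd.DataFrame(rows)

    def edges_dataframe(self) -> pd.DataFrame:
        rows = [
            {
                "source": a,
                "target": b,
                "weight": d["weight"],
                "sign": d["sign"],
                "sig_code": d.get("sig_code", ""),
            }
            for a, b, d in self.graph.edges(data=True)
        ]
        return pd.DataFrame(
            rows, columns=["source", "target", "weight", "sign", "sig_code"]
        )

    # ----- export ----------------------------------------------------------

    def export(self, path, format: str = "graphml") -> None:
        """Write the network as GraphML or an edge-list CSV."""
        if format == "graphml":
            g = self.graph.copy()
            g.graph["mode"] = self.mode
            g.graph["param"] = self.param
            nx.write_graphml(g, path)
        elif format == "edge-list":
            self.edges_dataframe().to_csv(path, index=False)
        else:
            raise ValueError(f"unknown export format {format!r}")

    @classmethod
    def from_graphml(cls, path) -> "Network":
        g = nx.read_graphml(path)
        g = nx.relabel_nodes(g, {n: str(n) for n in g.nodes})
        mode = g.graph.get("mode", "full")
        param = float(g.graph.get("param", 0.05))
        out = nx.Graph()
        for n, d in g.nodes(data=True):
            out.add_node(n, domain=d["domain"])
        for a, b, d in g.edges(data=True):
            out.add_edge(
                a,
                b,
                weight=float(d["weight"]),
                sign=int(d["sign"]),
                sig_code=d.get("sig_code", ""),
            )
        return cls(graph=out, mode=mode, param=param)

    def plot(self, ax=None):
        """Draw the two-domain graph (cognitive left, oculomotor right)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(7, 5))
        cog = [n for n, d in self.graph.nodes(data=True) if d["domain"] == "cognitive"]
        ocu = [n for n, d in self.graph.nodes(data=True) if d["domain"] == "oculomotor"]
        pos = {}
        for i, n in enumerate(cog):
            pos[n] = (-1.0, 1.0 - 2.0 * i / max(1, len(cog) - 1))
        for i, n in enumerate(ocu):
            pos[n] = (1.0, 1.0 - 2.0 * i / max(1, len(ocu) - 1))
        colors = ["#1f77b4" if n in cog else "#d62728" for n in self.graph.nodes]
        widths = [2 + 4 * abs(d["weight"]) for _, _, d in self.graph.edges(data=True)]
        styles = [
            "solid" if d["sign"] > 0 else "dashed"
            for _, _, d in self.graph.edges(data=True)
        ]
        nx.draw_networkx(
            self.graph,
            pos=pos,
            ax=ax,
            node_color=colors,
            width=widths,
            style=styles,
            font_size=8,
            node_size=900,
        )
        ax.set_axis_off()
        ax.set_title(f"{self.mode} network ({self.param:g})")
        return ax
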