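"""Bipartite miRNA-target network construction and scale-free diagnostics.

Validated-interaction exports from several curated databases are unified
into a duplicate-free (miRNA, gene) pair set under exact-match
canonicalized names, restricted to the differential miRNA set, and held as
a networkx bipartite graph. The degree distribution P(k) is fitted on
log10-log10 axes by ordinary least squares; the coefficient of
determination of that line is the conventional quick scale-free-ness
statistic for regulatory networks of this size.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable

import networkx as nx
import numpy as np
import pandas as pd

from .names import normalize_gene, normalize_mirna

logger = logging.getLogger(__name__)


class EmptyNetworkError(ValueError):
    """Operation undefined on an empty network."""


class InsufficientDegreeSupportError(ValueError):
    """Fewer than three distinct degree values: the log-log fit is undefined."""


def unify_interactions(records: Iterable[pd.DataFrame] | pd.DataFrame) -> pd.DataFrame:
    """De-duplicate interaction records from one or more source tables.

    miRNA names and gene symbols are canonicalized (see
    :mod:`mirnetkit.names`); the identity key is the canonicalized
    (miRNA, gene) pair. Contributing source labels are retained as a
    sorted, ``;``-joined annotation. Rows with a missing miRNA or gene
    field are skipped with a logged count. Output is sorted by
    (mirna_id, gene_symbol), so it is independent of input record order
    and of how records were partitioned across source files.
    """
    if isinstance(records, pd.DataFrame):
        records = [records]
    frames = [df for df in records]
    if not frames:
        return pd.DataFrame(columns=["mirna_id", "gene_symbol", "sources"])
    cat = pd.concat(frames, ignore_index=True)
    if cat.empty:
        return pd.DataFrame(columns=["mirna_id", "gene_symbol", "sources"])
    if "source_db" not in cat.columns:
        cat["source_db"] = "unknown"
    bad = cat["mirna_id"].isna() | cat["gene_symbol"].isna()
    bad |= cat["mirna_id"].astype(str).str.strip().eq("") | cat["gene_symbol"].astype(str).str.strip().eq("")
    if int(bad.sum()):
        logger.warning("skipped %d malformed interaction rows (missing field)", int(bad.sum()))
        cat = cat.loc[~bad]
    cat = cat.assign(
        mirna_id=cat["mirna_id"].map(normalize_mirna),
        gene_symbol=cat["gene_symbol"].map(normalize_gene),
    )
    grouped = (
        cat.groupby(["mirna_id", "gene_symbol"], sort=True)["source_db"]
        .agg(lambda s: ";".join(sorted(set(map(str, s)))))
        .reset_index()
        .rename(columns={"source_db": "sources"})
    )
    logger.info("unified %d records into %d unique pairs", len(cat), len(grouped))
    return grouped


@dataclass
class BipartiteNetwork:
    """Unique miRNA->gene edges restricted to differential miRNAs.

    Wraps an undirected networkx graph whose nodes carry
    ``node_type`` ("mirna"/"gene"), miRNA nodes additionally ``direction``;
    edges carry their contributing ``sources`` annotation.
    """

    graph: nx.Graph

    @property
    def mirnas(self) -> list[str]:
        return sorted(n for n, t in self.graph.nodes(data="node_type") if t == "mirna")

    @property
    def genes(self) -> list[str]:
        return sorted(n for n, t in self.graph.nodes(data="node_type") if t == "gene")

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def targets_of(self, mirna: str) -> set[str]:
        if mirna not in self.graph:
            return set()
        return set(self.graph.neighbors(mirna))

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for u, v, data in self.graph.edges(data=True):
            m, g = (u, v) if self.graph.nodes[u]["node_type"] == "mirna" else (v, u)
            rows.append((m, g, data.get("sources", ""), self.graph.nodes[m].get("direction", "")))
        return pd.DataFrame(
            rows, columns=["mirna_id", "gene_symbol", "sources", "mirna_direction"]
        ).sort_values(["mirna_id", "gene_symbol"], ignore_index=True)


def build_network(pairs: pd.DataFrame, differential: pd.DataFrame) -> BipartiteNetwork:
    """Restrict unified pairs to differential miRNAs and build the graph.

    ``differential`` is the screen output (columns mirna_id, direction).
    Isolated nodes never appear; miRNA nodes are annotated with their
    concordant direction. miRNA and gene namespaces must not collide.
    """
    directions = dict(
        zip(differential["mirna_id"].map(normalize_mirna), differential["direction"])
    )
    g = nx.Graph()
    kept = 0
    for m, gene, sources in pairs[["mirna_id", "gene_symbol", "sources"]].itertuples(index=False):
        if m not in directions:
            continue
        if gene in directions:
            raise ValueError(f"name collision between miRNA and gene namespaces: {gene!r}")
        g.add_node(m, node_type="mirna", direction=directions[m])
        g.add_node(gene, node_type="gene")
        g.add_edge(m, gene, sources=sources)
        kept += 1
    if kept == 0:
        logger.warning("restriction produced an empty network")
    net = BipartiteNetwork(g)
    logger.info(
        "network: %d edges, %d miRNA nodes, %d gene nodes",
        net.n_edges, len(net.mirnas), len(net.genes),
    )
    return net


def network_from_frame(frame: pd.DataFrame) -> BipartiteNetwork:
    """Rebuild a BipartiteNetwork from an edge-list table
    (mirna_id, gene_symbol[, sources, mirna_direction])."""
    g = nx.Graph()
    for row in frame.itertuples(index=False):
        m, gene = row.mirna_id, row.gene_symbol
        g.add_node(m, node_type="mirna", direction=getattr(row, "mirna_direction", ""))
        g.add_node(gene, node_type="gene")
        g.add_edge(m, gene, sources=getattr(row, "sources", ""))
    return BipartiteNetwork(g)


def degree_distribution(
    net: BipartiteNetwork, side: str = "both", cumulative: bool = False
) -> pd.Series:
    """Degree frequency table P(k) for the chosen node side.

    P(k) is the proportion of the side's nodes having degree k; frequencies
    sum to 1. With ``cumulative=True`` the complementary cumulative form
    P(K >= k) is returned instead.
    """
    if net.n_edges == 0:
        raise EmptyNetworkError("degree distribution undefined on an empty network")
    if side == "mirna":
        nodes = net.mirnas
    elif side == "gene":
        nodes = net.genes
    elif side == "both":
        nodes = net.mirnas + net.genes
    else:
        raise ValueError(f"side must be mirna/gene/both, got {side!r}")
    degrees = pd.Series([net.graph.degree[n] for n in nodes], dtype=int)
    freq = degrees.value_counts(normalize=True).sort_index()
    freq.index.name = "k"
    freq.name = "p"
    if cumulative:
        freq = freq[::-1].cumsum()[::-1]
    return freq


@dataclass(frozen=True)
class PowerLawFit:
    """Log-log OLS fit of a degree frequency table.

    slope and intercept describe log10 P(k) = intercept + slope * log10 k;
    r_squared = 1 - SS_res/SS_tot. A flat (zero-variance) response is
    reported as a perfect degenerate fit (slope 0, R^2 = 1) rather than a
    division-by-zero failure.
    """

    slope: float
    intercept: float
    r_squared: float
    n_points: int
    degenerate: bool = False


def scale_free_fit(dist: pd.Series, log_binning: bool = False, n_bins: int = 10) -> PowerLawFit:
    """OLS of log10 P(k) on log10 k over nonzero-frequency degrees.

    ``log_binning`` optionally averages frequencies within geometrically
    spaced degree bins before fitting (an alternative for noisy tails); by
    default raw unbinned frequencies are fitted.
    """
    dist = dist[dist > 0]
    if log_binning and len(dist) > 2:
        edges = np.geomspace(dist.index.min(), dist.index.max() + 1, n_bins + 1)
        binned_k, binned_p = [], []
        for lo, hi in zip(edges[:-1], edges[1:]):
            mask = (dist.index >= lo) & (dist.index < hi)
            if mask.any():
                binned_k.append(float(np.mean(dist.index[mask])))
                binned_p.append(float(dist[mask].mean()))
        x, y = np.log10(binned_k), np.log10(binned_p)
    else:
        x = np.log10(dist.index.to_numpy(dtype=float))
        y = np.log10(dist.to_numpy(dtype=float))
    if len(np.unique(x)) < 3:
        raise InsufficientDegreeSupportError(
            f"need >= 3 distinct degree values for the log-log fit, got {len(np.unique(x))}"
        )
    slope, intercept = np.polyfit(x, y, 1)
    resid = y - (intercept + slope * x)
    ss_res = float(np.sum(resid**2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot == 0.0:
        return PowerLawFit(slope=0.0, intercept=float(y.mean()), r_squared=1.0,
                           n_points=len(x), degenerate=True)
    return PowerLawFit(
        slope=float(slope),
        intercept=float(intercept),
        r_squared=1.0 - ss_res / ss_tot,
        n_points=len(x),
    )
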