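"""Hypergeometric miRNA-pathway enrichment and the significant-pair network.

For a gene universe of size N containing a pathway of K genes, and a miRNA
with M targets in the universe of which x fall in the pathway, the default
("exclusive") p value is

    P(X > x) = 1 - sum_{t=0}^{x} C(K, t) C(N-K, M-t) / C(N, M),

the probability of an overlap strictly greater than observed. The
conventional enrichment tail P(X >= x) is available as tail="inclusive"
(identical to the exclusive tail at x-1). The exclusive form is the
default because it is the statistic the screening protocol this package
reproduces is calibrated to; the inclusive switch makes the difference
visible rather than hidden.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping

import networkx as nx
import pandas as pd
from scipy.stats import hypergeom

logger = logging.getLogger(__name__)

TAILS = ("exclusive", "inclusive")


class PathwayNotFoundError(KeyError):
    """Requested pathway name absent from the collection."""


@dataclass(frozen=True)
class GeneSetCollection:
    """Named pathway gene sets over a common gene universe."""

    sets: Mapping[str, frozenset[str]]
    universe: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if not self.universe:
            object.__setattr__(
                self, "universe", frozenset(g for gs in self.sets.values() for g in gs)
            )
        for name, genes in self.sets.items():
            if not genes <= self.universe:
                raise ValueError(f"pathway {name!r} is not a subset of the universe")

    def get(self, name: str) -> frozenset[str]:
        try:
            return self.sets[name]
        except KeyError:
            available = ", ".join(sorted(self.sets))
            raise PathwayNotFoundError(
                f"pathway {name!r} not in collection; available: {available}"
            ) from None

    def __len__(self) -> int:
        return len(self.sets)


def hypergeom_p(N: int, K: int, M: int, x: int, tail: str = "exclusive") -> float:
    """Hypergeometric enrichment probability for an overlap of x.

    ``tail="exclusive"`` returns P(X > x) (the formula above, exactly);
    ``tail="inclusive"`` returns P(X >= x). X ~ Hypergeometric(N, K, M).
    Computed via scipy's log-space survival function and clamped to [0, 1].
    """
    for name, value in (("N", N), ("K", K), ("M", M), ("x", x)):
        if value < 0:
            raise ValueError(f"{name} must be >= 0, got {value}")
    if K > N:
        raise ValueError(f"K <= N violated: K={K}, N={N}")
    if M > N:
        raise ValueError(f"M <= N violated: M={M}, N={N}")
    if x > min(K, M):
        raise ValueError(f"x <= min(K, M) violated: x={x}, K={K}, M={M}")
    if tail not in TAILS:
        raise ValueError(f"tail must be one of {TAILS}, got {tail!r}")
    threshold = x if tail == "exclusive" else x - 1
    # exact boundary identities (also cover the degenerate N = 0 case)
    if threshold < 0:
        return 1.0
    if threshold >= min(K, M):
        return 0.0
    p = float(hypergeom.sf(threshold, N, K, M))
    return min(1.0, max(0.0, p))


def enrich(
    net,
    sets: GeneSetCollection,
    alpha: float = 0.05,
    tail: str = "exclusive",
) -> pd.DataFrame:
    """Test every (miRNA, pathway) pair of a bipartite target network.

    Each miRNA's neighbour gene set is the input list; pathway membership
    and target sets are intersected with the collection's universe before
    counting. Significance is strict: p < alpha. miRNAs with no targets in
    the universe are skipped with a log entry. Results are sorted by
    (p, mirna_id, pathway).
    """
    universe = sets.universe
    N = len(universe)
    if N == 0:
        raise ValueError("empty gene universe")
    rows = []
    skipped = 0
    pathway_genes = {name: genes & universe for name, genes in sets.sets.items()}
    for mirna in net.mirnas:
        targets = net.targets_of(mirna) & universe
        M = len(targets)
        if M == 0:
            skipped += 1
            continue
        for name, genes in pathway_genes.items():
            K = len(genes)
            x = len(targets & genes)
            p = hypergeom_p(N, K, M, x, tail=tail)
            rows.append((mirna, name, N, K, M, x, p, p < alpha))
    if skipped:
        logger.info("enrichment: skipped %d miRNAs with no targets in the universe", skipped)
    out = pd.DataFrame(
        rows, columns=["mirna_id", "pathway", "N", "K", "M", "x", "p", "significant"]
    )
    return out.sort_values(["p", "mirna_id", "pathway"], ignore_index=True)


def benjamini_hochberg(results: pd.DataFrame, alpha: float = 0.05) -> pd.DataFrame:
    """Optional FDR control over the enrichment table (not used by default:
    the screening protocol thresholds raw p values)."""
    out = results.sort_values("p", ignore_index=True).copy()
    n = len(out)
    if n == 0:
        out["p_adjusted"] = pd.Series(dtype=float)
        return out
    import numpy as np

    ranked = out["p"].to_numpy() * n / np.arange(1, n + 1)
    out["p_adjusted"] = np.minimum(np.minimum.accumulate(ranked[::-1])[::-1], 1.0)
    out["significant"] = out["p_adjusted"] < alpha
    return out


def build_mirna_pathway_network(results: pd.DataFrame) -> nx.Graph:
    """Bipartite graph of the significant (miRNA, pathway) pairs.

    Nodes carry node_type ("mirna"/"pathway"); edges carry the p value.
    An empty graph is a valid result when nothing is significant.
    """
    g = nx.Graph()
    sig = results.loc[results["significant"]]
    for mirna, pathway, p in sig[["mirna_id", "pathway", "p"]].itertuples(index=False):
        g.add_node(mirna, node_type="mirna")
        g.add_node(pathway, node_type="pathway")
        g.add_edge(mirna, pathway, p=float(p))
    n_mirna = sum(1 for _, t in g.nodes(data="node_type") if t == "mirna")
    logger.info(
        "miRNA-pathway network: %d interactions, %d miRNAs, %d pathways",
        g.number_of_edges(), n_mirna, g.number_of_nodes() - n_mirna,
    )
    return g
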