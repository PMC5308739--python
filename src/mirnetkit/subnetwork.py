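"""Single-pathway miRNA-mRNA subnetwork extraction and reference comparison.

The subnetwork of a pathway is exactly the intersection of the bipartite
target network's edges with (differential miRNAs x pathway genes). Each
miRNA carries its treatment-response direction from the differential
screen; genes targeted by two or more subnetwork miRNAs are flagged as
co-regulated. A packaged canonical reference (the 19-edge pancreatic-cancer
list) supports precision/recall comparison.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import pandas as pd

from .names import normalize_gene, normalize_mirna


@dataclass
class PathwaySubnetwork:
    """Edges of one pathway's miRNA-mRNA view, with direction annotations."""

    pathway: str
    edges: pd.DataFrame  # mirna_id, gene_symbol, mirna_direction, co_regulated

    @property
    def mirnas(self) -> list[str]:
        return sorted(self.edges["mirna_id"].unique())

    @property
    def genes(self) -> list[str]:
        return sorted(self.edges["gene_symbol"].unique())

    @property
    def pairs(self) -> set[tuple[str, str]]:
        return set(zip(self.edges["mirna_id"], self.edges["gene_symbol"]))

    def to_graph(self) -> nx.Graph:
        g = nx.Graph()
        for m, gene, direction, co in self.edges[
            ["mirna_id", "gene_symbol", "mirna_direction", "co_regulated"]
        ].itertuples(index=False):
            g.add_node(m, node_type="mirna", direction=direction)
            g.add_node(gene, node_type="gene")
            g.add_edge(m, gene, co_regulated=bool(co))
        return g


@dataclass(frozen=True)
class ComparisonReport:
    """Edge-set agreement between an extracted subnetwork and a reference."""

    true_positive: frozenset[tuple[str, str]]
    missing: frozenset[tuple[str, str]]
    extra: frozenset[tuple[str, str]]
    precision: float
    recall: float
    vacuous_precision: bool = False
    vacuous_recall: bool = False
    mirna_delta: int = 0
    gene_delta: int = 0

    def text_block(self) -> str:
        lines = [
            f"edges: {len(self.true_positive)} shared, "
            f"{len(self.missing)} missing, {len(self.extra)} extra",
            f"precision: {self.precision:.3f}" + (" (vacuous)" if self.vacuous_precision else ""),
            f"recall: {self.recall:.3f}" + (" (vacuous)" if self.vacuous_recall else ""),
            f"node deltas: {self.mirna_delta:+d} miRNAs, {self.gene_delta:+d} genes",
        ]
        return "\n".join(lines)


def extract_subnetwork(
    net,
    pathway_genes,
    differential: pd.DataFrame,
    pathway_name: str = "",
) -> PathwaySubnetwork:
    """Restrict a bipartite target network to one pathway's genes.

    ``net`` is a BipartiteNetwork (or anything exposing ``to_frame``);
    miRNA directions are taken from the differential screen output. Genes
    with in-subnetwork degree >= 2 are flagged co-regulated.
    """
    genes = {normalize_gene(g) for g in pathway_genes}
    directions = dict(zip(differential["mirna_id"].map(normalize_mirna), differential["direction"]))
    frame = net.to_frame()
    keep = frame["gene_symbol"].isin(genes) & frame["mirna_id"].isin(directions)
    edges = frame.loc[keep, ["mirna_id", "gene_symbol"]].copy()
    edges["mirna_direction"] = edges["mirna_id"].map(directions)
    gene_degree = edges["gene_symbol"].value_counts()
    edges["co_regulated"] = edges["gene_symbol"].map(gene_degree).ge(2)
    edges = edges.sort_values(["mirna_id", "gene_symbol"], ignore_index=True)
    return PathwaySubnetwork(pathway=pathway_name, edges=edges)


def compare_to_canonical(sub: PathwaySubnetwork, ref) -> ComparisonReport:
    """Set comparison of subnetwork edges against a reference edge list.

    precision = TP/|sub|, recall = TP/|ref|; an empty denominator is
    reported as 1 with a vacuous flag. ``ref`` is a CanonicalEdgeList or
    any object with ``pairs``/``mirnas``/``genes``.
    """
    sub_pairs = sub.pairs
    ref_pairs = set(ref.pairs)
    tp = sub_pairs & ref_pairs
    missing = ref_pairs - sub_pairs
    extra = sub_pairs - ref_pairs
    vac_p, vac_r = len(sub_pairs) == 0, len(ref_pairs) == 0
    precision = 1.0 if vac_p else len(tp) / len(sub_pairs)
    recall = 1.0 if vac_r else len(tp) / len(ref_pairs)
    return ComparisonReport(
        true_positive=frozenset(tp),
        missing=frozenset(missing),
        extra=frozenset(extra),
        precision=precision,
        recall=recall,
        vacuous_precision=vac_p,
        vacuous_recall=vac_r,
        mirna_delta=len(sub.mirnas) - len(set(ref.mirnas)),
        gene_delta=len(sub.genes) - len(set(ref.genes)),
    )


def summarize(sub: PathwaySubnetwork) -> dict[str, int]:
    """Exact counts of a pathway subnetwork, in deterministic key order."""
    per_mirna = sub.edges.drop_duplicates("mirna_id")
    return {
        "mirnas": len(sub.mirnas),
        "genes": len(sub.genes),
        "edges": len(sub.edges),
        "up_mirnas": int((per_mirna["mirna_direction"] == "up").sum()),
        "down_mirnas": int((per_mirna["mirna_direction"] == "down").sum()),
        "co_regulated_genes": int(sub.edges.loc[sub.edges["co_regulated"], "gene_symbol"].nunique()),
    }
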