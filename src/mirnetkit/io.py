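"""Round-trip readers and writers for every format the pipeline touches.

All tabular artifacts are tab-separated text with optional ``#``-prefixed
header comment lines carrying provenance (seed, parameters); gene sets use
the standard GMT dialect (set name, description, then tab-separated gene
symbols); networks export to SIF and GraphML for Cytoscape-style tools.
Write followed by read is the identity on the in-memory model.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Mapping

import networkx as nx
import pandas as pd

from .enrichment import GeneSetCollection


class ParseError(ValueError):
    """Malformed input file; message carries the 1-based line number."""


def _write_comments(handle, comments: Mapping[str, object] | None) -> None:
    for key, value in (comments or {}).items():
        handle.write(f"# {key}: {value}\n")


def write_table(df: pd.DataFrame, path, comments: Mapping[str, object] | None = None,
                index: bool = False) -> None:
    path = Path(path)
    with path.open("w") as fh:
        _write_comments(fh, comments)
        df.to_csv(fh, sep="\t", index=index)


def read_table(path, index_col=None) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", index_col=index_col)


def write_expression(matrix: pd.DataFrame, path, comments: Mapping[str, object] | None = None) -> None:
    """Expression TSV: first column mirna_id, one column per sample."""
    write_table(matrix, path, comments=comments, index=True)


def read_expression(path) -> pd.DataFrame:
    """Read an expression TSV; duplicate probe rows are preserved."""
    df = pd.read_csv(path, sep="\t", comment="#", index_col=0)
    df.index.name = "mirna_id"
    bad = df.columns[df.dtypes.eq(object)]
    if len(bad):
        raise ParseError(f"non-numeric intensity column(s): {list(bad)}")
    return df


def write_interactions(sources: Mapping[str, pd.DataFrame], out_dir) -> list[Path]:
    """Write the four source tables as source_1.tsv .. source_N.tsv."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    for i, (db, df) in enumerate(sources.items(), start=1):
        p = out_dir / f"source_{i}.tsv"
        write_table(df, p, comments={"source_db": db})
        paths.append(p)
    return paths


def read_interactions(paths) -> list[pd.DataFrame]:
    frames = []
    for p in paths:
        df = read_table(p)
        expected = {"mirna_id", "gene_symbol", "source_db"}
        if not expected <= set(df.columns):
            raise ParseError(f"{p}: expected columns {sorted(expected)}, got {list(df.columns)}")
        frames.append(df)
    return frames


def write_gmt(sets: GeneSetCollection | Mapping[str, frozenset], path,
              descriptions: Mapping[str, str] | None = None) -> None:
    mapping = sets.sets if isinstance(sets, GeneSetCollection) else sets
    path = Path(path)
    with path.open("w") as fh:
        for name, genes in mapping.items():
            desc = (descriptions or {}).get(name, "synthetic")
            fh.write("\t".join([name, desc, *sorted(genes)]) + "\n")


def read_gmt(path) -> GeneSetCollection:
    """Parse a GMT file into a GeneSetCollection.

    Each line: set name, description, then >= 1 gene symbol. Duplicate set
    names and short lines raise line-numbered parse errors.
    """
    sets: dict[str, frozenset[str]] = {}
    with Path(path).open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(
                    f"{path}:{lineno}: GMT line needs name, description and >= 1 gene "
                    f"(got {len(fields)} fields)"
                )
            name = fields[0]
            if name in sets:
                raise ParseError(f"{path}:{lineno}: duplicate GMT set name {name!r}")
            sets[name] = frozenset(g for g in fields[2:] if g)
    return GeneSetCollection(sets=sets)


def write_sif(graph: nx.Graph, path, relation: str = "targets") -> None:
    """SIF export: ``mirna <relation> gene`` per edge."""
    with Path(path).open("w") as fh:
        for u, v in graph.edges():
            if graph.nodes[u].get("node_type") != "mirna":
                u, v = v, u
            fh.write(f"{u}\t{relation}\t{v}\n")


def write_graphml(graph: nx.Graph, path) -> None:
    nx.write_graphml(graph, path)


def read_graphml(path) -> nx.Graph:
    return nx.read_graphml(path)


def write_report(report: dict, path) -> None:
    Path(path).write_text(json.dumps(report, indent=2, sort_keys=True) + "\n")


def read_report(path) -> dict:
    return json.loads(Path(path).read_text())
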