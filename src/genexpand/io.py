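"""Readers and writers for every artifact the pipeline touches.

Formats are deliberately plain: TSV for matrices and tables, ZIP of
per-seed TSVs for expansion archives, Cytoscape.js ``elements`` JSON for
graph export.  Every writer/reader pair round-trips byte-for-byte.
"""

from __future__ import annotations

import json
import warnings
import zipfile
from pathlib import Path
from typing import Iterable, Optional

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import networkx as nx
import pandas as pd

from .model import (
    DataFormatError,
    ExpansionList,
    ExpansionParams,
    ExpansionRecord,
    ExpressionMatrix,
    GeneAnnotation,
    GeneNetwork,
)

__all__ = [
    "read_expression_matrix",
    "write_expression_matrix",
    "read_annotation",
    "write_expansion_archive",
    "read_expansion_archive",
    "export_graph_json",
    "read_graph_json",
    "write_network_tables",
    "read_network_tables",
    "write_network_png",
]


def _fmt(x: float) -> str:
    """Shortest string that round-trips the float exactly."""
    return repr(float(x))


def read_expression_matrix(path) -> ExpressionMatrix:
    """Read a genes-x-samples TSV: first column gene IDs, header row sample IDs.

    Duplicate gene IDs or non-numeric cells raise :class:`DataFormatError`
    naming the offending location.  Genes with zero variance are reported
    with a warning; they are kept in the matrix so the caller can decide.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str, comment="#")
    if df.index.has_duplicates:
        dupes = sorted(df.index[df.index.duplicated()].unique())
        raise DataFormatError(f"duplicate gene identifiers: {dupes}")
    try:
        values = df.astype(float)
    except ValueError:
        for gene, row in df.iterrows():
            for sample, cell in row.items():
                try:
                    float(cell)
                except (TypeError, ValueError):
                    raise DataFormatError(
                        f"non-numeric cell {cell!r} at gene {gene!r}, sample {sample!r}"
                    ) from None
        raise
    if values.isna().any().any():
        gene = values.index[values.isna().any(axis=1)][0]
        sample = values.columns[values.isna().any(axis=0)][0]
        raise DataFormatError(f"non-numeric cell at gene {gene!r}, sample {sample!r}")
    matrix = ExpressionMatrix.from_dataframe(values)
    flat = matrix.zero_variance_genes()
    if flat:
        warnings.warn(f"{len(flat)} gene(s) with zero variance: {flat[:10]}", stacklevel=2)
    return matrix


def write_expression_matrix(matrix: ExpressionMatrix, path, header_comment: Optional[str] = None) -> None:
    path = Path(path)
    with path.open("w") as fh:
        if header_comment:
            for line in header_comment.splitlines():
                fh.write(f"# {line}\n")
        fh.write("gene\t" + "\t".join(matrix.sample_ids) + "\n")
        for gene, row in zip(matrix.gene_ids, matrix.values):
            fh.write(gene + "\t" + "\t".join(_fmt(v) for v in row) + "\n")


def read_annotation(path) -> GeneAnnotation:
    """Read a gene annotation TSV with columns v1_id, vcost_id, symbol, category."""
    df = pd.read_csv(path, sep="\t", dtype=str, comment="#").fillna("")
    if "v1_id" not in df.columns:
        raise DataFormatError("annotation table must have a 'v1_id' column")
    return GeneAnnotation(df.set_index("v1_id"))


# ---------------------------------------------------------------------------
# Expansion archives: a ZIP with one TSV member per seed.  Each member starts
# with '# key: value' header lines carrying the seed and the run parameters.
# ---------------------------------------------------------------------------

_ARCHIVE_COLUMNS = ["gene", "input_count", "output_count", "f_rel", "pearson_r", "rank"]
_REQUIRED_META = ["seed", "n_iterations", "tile_size", "alpha", "rng_seed"]


def _expansion_list_to_text(lst: ExpansionList) -> str:
    p = lst.params
    lines = [
        f"# seed: {lst.seed}",
        f"# n_iterations: {p.n_iterations}",
        f"# tile_size: {p.tile_size}",
        f"# alpha: {_fmt(p.alpha)}",
        f"# rng_seed: {p.rng_seed}",
        "\t".join(_ARCHIVE_COLUMNS),
    ]
    for r in lst.records:
        lines.append(
            "\t".join(
                [
                    r.gene,
                    str(r.input_count),
                    str(r.output_count),
                    _fmt(r.f_rel),
                    _fmt(r.pearson_r),
                    str(r.rank),
                ]
            )
        )
    return "\n".join(lines) + "\n"


def _expansion_list_from_text(text: str, member: str) -> ExpansionList:
    meta: dict[str, str] = {}
    lines = text.splitlines()
    i = 0
    while i < len(lines) and lines[i].startswith("#"):
        body = lines[i][1:].strip()
        if ":" in body:
            key, _, val = body.partition(":")
            meta[key.strip()] = val.strip()
        i += 1
    missing = [k for k in _REQUIRED_META if k not in meta]
    if missing:
        raise DataFormatError(f"archive member {member!r} missing header metadata: {missing}")
    if i >= len(lines) or lines[i].split("\t") != _ARCHIVE_COLUMNS:
        raise DataFormatError(f"archive member {member!r} missing column header")
    records = []
    for line in lines[i + 1 :]:
        if not line:
            continue
        gene, inc, outc, frel, r, rank = line.split("\t")
        records.append(
            ExpansionRecord(
                gene=gene,
                input_count=int(inc),
                output_count=int(outc),
                f_rel=float(frel),
                pearson_r=float(r),
                rank=int(rank),
            )
        )
    params = ExpansionParams(
        n_iterations=int(meta["n_iterations"]),
        tile_size=int(meta["tile_size"]),
        alpha=float(meta["alpha"]),
        rng_seed=int(meta["rng_seed"]),
    )
    return ExpansionList(seed=meta["seed"], records=records, params=params)


def write_expansion_archive(lists: Iterable[ExpansionList], path) -> None:
    """Write a ZIP archive with one TSV member per expansion list."""
    lists = list(lists)
    if not lists:
        raise ValueError("cannot write an empty expansion archive")
    seen: set[str] = set()
    with zipfile.ZipFile(path, "w", compression=zipfile.ZIP_DEFLATED) as zf:
        for lst in lists:
            if lst.seed in seen:
                raise ValueError(f"duplicate seed in archive: {lst.seed!r}")
            seen.add(lst.seed)
            info = zipfile.ZipInfo(f"{lst.seed}.tsv")  # fixed timestamp: reproducible bytes
            zf.writestr(info, _expansion_list_to_text(lst))


def read_expansion_archive(path) -> list[ExpansionList]:
    out = []
    with zipfile.ZipFile(path) as zf:
        for member in sorted(zf.namelist()):
            if not member.endswith(".tsv"):
                continue
            out.append(_expansion_list_from_text(zf.read(member).decode(), member))
    return out


# ---------------------------------------------------------------------------
# Network export: edge table TSV, node table TSV, Cytoscape.js elements JSON,
# static PNG.
# ---------------------------------------------------------------------------


def export_graph_json(net: GeneNetwork, path) -> None:
    """Write the network in the Cytoscape.js ``elements`` dialect."""
    nodes = []
    for g in net.nodes:
        attrs = net.graph.nodes[g]
        nodes.append(
            {
                "data": {
                    "id": g,
                    "v1_id": attrs.get("v1_id", g),
                    "vcost_id": attrs.get("vcost_id", ""),
                    "symbol": attrs.get("symbol", ""),
                }
            }
        )
    edges = []
    for a, b, d in net.edges:
        edges.append(
            {
                "data": {
                    "id": f"{a}--{b}",
                    "source": a,
                    "target": b,
                    "weight": d["weight"],
                    "sign": d["sign"],
                    "weight_class": d["weight_class"],
                }
            }
        )
    payload = {"elements": {"nodes": nodes, "edges": edges}}
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")


def read_graph_json(path) -> GeneNetwork:
    payload = json.loads(Path(path).read_text())
    net = GeneNetwork()
    for node in payload["elements"]["nodes"]:
        d = node["data"]
        net.add_node(d["id"], v1_id=d.get("v1_id", d["id"]), vcost_id=d.get("vcost_id", ""), symbol=d.get("symbol", ""))
    for edge in payload["elements"]["edges"]:
        d = edge["data"]
        net.add_edge(d["source"], d["target"], weight=d["weight"], sign=d["sign"], weight_class=d["weight_class"])
    return net


def write_network_tables(net: GeneNetwork, edge_path, node_path) -> None:
    nt = net.node_table()
    et = net.edge_table().copy()
    if len(et):
        et["weight"] = et["weight"].map(_fmt)
    nt.to_csv(node_path, sep="\t", index=False)
    et.to_csv(edge_path, sep="\t", index=False)


def read_network_tables(edge_path, node_path) -> GeneNetwork:
    net = GeneNetwork()
    nt = pd.read_csv(node_path, sep="\t", dtype=str).fillna("")
    for _, row in nt.iterrows():
        net.add_node(row["id"], v1_id=row["v1_id"], vcost_id=row["vcost_id"], symbol=row["symbol"], category=row.get("category", ""))
    et = pd.read_csv(edge_path, sep="\t", dtype=str)
    for _, row in et.iterrows():
        net.add_edge(row["source"], row["target"], weight=float(row["weight"]), sign=row["sign"], weight_class=row["weight_class"])
    return net


_EDGE_STYLE = {"solid": "solid", "dashed": "dashed", "dotted": "dotted"}


def write_network_png(net: GeneNetwork, path, seed: int = 0) -> None:
    """Static rendering: spring layout, line style by weight class, red for
    anticorrelated edges."""
    g = net.graph
    fig, ax = plt.subplots(figsize=(8, 8))
    pos = nx.spring_layout(g, seed=seed)
    nx.draw_networkx_nodes(g, pos, ax=ax, node_color="#cfe2f3", edgecolors="#333333", node_size=600)
    labels = {n: (g.nodes[n].get("symbol") or n) for n in g.nodes}
    nx.draw_networkx_labels(g, pos, labels=labels, ax=ax, font_size=7)
    for a, b, d in g.edges(data=True):
        color = "red" if d.get("sign") == "-" else "#555555"
        style = _EDGE_STYLE.get(d.get("weight_class", "solid"), "solid")
        nx.draw_networkx_edges(
            g, pos, edgelist=[(a, b)], ax=ax, edge_color=color, style=style,
            width=1.0 + 2.0 * float(d.get("weight", 0.5)),
        )
    ax.set_axis_off()
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
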