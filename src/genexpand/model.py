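"""Domain types shared across the package.

The central objects are the expression matrix (genes x samples), the
per-seed expansion list produced by the iterated-skeleton engine, and the
undirected weighted gene network assembled from mutual presence in
expansion lists.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator, Optional

import networkx as nx
import numpy as np
import pandas as pd

__all__ = [
    "ExpressionMatrix",
    "GeneAnnotation",
    "ExpansionParams",
    "ExpansionRecord",
    "ExpansionList",
    "GeneNetwork",
    "DegenerateInputError",
    "DataFormatError",
]


class DataFormatError(ValueError):
    """Raised when an input file violates its documented format."""


class DegenerateInputError(ValueError):
    """Raised on numerically degenerate input (singular matrix, zero variance)."""


@dataclass
class ExpressionMatrix:
    """Normalized expression values for a set of genes across samples.

    Rows are genes, columns are samples.  Gene and sample identifiers are
    opaque case-sensitive strings; values must be finite.
    """

    gene_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise ValueError(
                f"values shape {self.values.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.sample_ids)} samples"
            )
        if len(set(self.gene_ids)) != len(self.gene_ids):
            dupes = sorted({g for g in self.gene_ids if self.gene_ids.count(g) > 1})
            raise DataFormatError(f"duplicate gene identifiers: {dupes}")
        if not np.all(np.isfinite(self.values)):
            raise DataFormatError("expression matrix contains non-finite values")
        self._index = {g: i for i, g in enumerate(self.gene_ids)}

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def row(self, gene: str) -> np.ndarray:
        return self.values[self._index[gene]]

    def index_of(self, gene: str) -> int:
        return self._index[gene]

    def __contains__(self, gene: str) -> bool:
        return gene in self._index

    def zero_variance_genes(self) -> list[str]:
        """Genes whose expression is constant across samples."""
        sd = self.values.std(axis=1)
        return [g for g, s in zip(self.gene_ids, sd) if s == 0.0]

    def subset(self, genes: Iterable[str]) -> "ExpressionMatrix":
        genes = list(genes)
        idx = [self._index[g] for g in genes]
        return ExpressionMatrix(genes, list(self.sample_ids), self.values[idx])

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.sample_ids)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "ExpressionMatrix":
        return cls(list(map(str, df.index)), list(map(str, df.columns)), df.to_numpy(dtype=float))


@dataclass
class GeneAnnotation:
    """Lookup table mapping primary gene IDs to alternate IDs, symbols and
    functional category codes.

    Genes absent from the table keep their raw ID with empty symbol and
    category.  IDs are opaque strings; mapping between identifier systems
    is a lookup, never parsing.
    """

    table: pd.DataFrame  # index: v1_id; columns: vcost_id, symbol, category

    def __post_init__(self) -> None:
        if self.table.index.has_duplicates:
            dupes = sorted(self.table.index[self.table.index.duplicated()].unique())
            raise DataFormatError(f"duplicate v1_id in annotation table: {dupes}")
        for col in ("vcost_id", "symbol", "category"):
            if col not in self.table.columns:
                self.table[col] = ""
        self.table = self.table.fillna("")

    def lookup(self, gene: str) -> dict:
        if gene in self.table.index:
            row = self.table.loc[gene]
            return {
                "v1_id": gene,
                "vcost_id": str(row["vcost_id"]),
                "symbol": str(row["symbol"]),
                "category": str(row["category"]),
            }
        return {"v1_id": gene, "vcost_id": "", "symbol": "", "category": ""}

    def category_of(self, gene: str) -> str:
        return self.lookup(gene)["category"]


@dataclass(frozen=True)
class ExpansionParams:
    """Parameters of one seed-gene expansion.

    The production-scale defaults are 2000 iterations over tiles of 1000
    genes (the seed plus 999 sampled without replacement) at alpha = 0.05.
    """

    n_iterations: int = 2000
    tile_size: int = 1000
    alpha: float = 0.05
    rng_seed: int = 0
    max_order: Optional[int] = None
    fixed_tiles: bool = False

    def __post_init__(self) -> None:
        if self.n_iterations < 1:
            raise ValueError("n_iterations must be positive")
        if self.tile_size < 2:
            raise ValueError("tile_size must be >= 2")
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must be in (0, 1)")


@dataclass(frozen=True)
class ExpansionRecord:
    """One ranked gene in an expansion list.

    f_rel is the relative frequency: the number of skeleton runs in which
    the gene remained adjacent to the seed divided by the number of runs
    whose input tile contained it.  pearson_r is the plain correlation of
    the gene with the seed over all samples, carried so that network edges
    can be signed.
    """

    gene: str
    input_count: int
    output_count: int
    f_rel: float
    pearson_r: float
    rank: int

    def __post_init__(self) -> None:
        if self.output_count > self.input_count:
            raise ValueError("output_count cannot exceed input_count")
        if self.input_count > 0:
            expected = self.output_count / self.input_count
            if abs(self.f_rel - expected) > 1e-12:
                raise ValueError("f_rel inconsistent with output_count/input_count")


@dataclass
class ExpansionList:
    """The ranked outcome of expanding one seed gene."""

    seed: str
    records: list[ExpansionRecord]
    params: ExpansionParams

    def __post_init__(self) -> None:
        if any(r.gene == self.seed for r in self.records):
            raise ValueError("seed must not appear among its own expansion records")
        frels = [r.f_rel for r in self.records]
        if any(a < b for a, b in zip(frels, frels[1:])):
            raise ValueError("records must be ordered by descending f_rel")
        ranks = [r.rank for r in self.records]
        if ranks != list(range(1, len(ranks) + 1)):
            raise ValueError("ranks must be 1..N without gaps")

    def __iter__(self) -> Iterator[ExpansionRecord]:
        return iter(self.records)

    def __len__(self) -> int:
        return len(self.records)

    def record_for(self, gene: str) -> Optional[ExpansionRecord]:
        for r in self.records:
            if r.gene == gene:
                return r
        return None

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "gene": r.gene,
                    "input_count": r.input_count,
                    "output_count": r.output_count,
                    "f_rel": r.f_rel,
                    "pearson_r": r.pearson_r,
                    "rank": r.rank,
                }
                for r in self.records
            ]
        )


@dataclass
class GeneNetwork:
    """Undirected weighted signed gene network.

    Edge weight is the mean relative frequency of the pair's mutual
    expansion records; sign is negative when the underlying Pearson
    correlation is negative; weight_class bins the weight for display
    (solid/dashed/dotted).
    """

    graph: nx.Graph = field(default_factory=nx.Graph)

    def add_node(self, gene: str, **attrs) -> None:
        self.graph.add_node(gene, **attrs)

    def add_edge(self, a: str, b: str, weight: float, sign: str, weight_class: str) -> None:
        if a == b:
            raise ValueError("self-edges are not allowed")
        if sign not in {"+", "-"}:
            raise ValueError("sign must be '+' or '-'")
        self.graph.add_edge(a, b, weight=weight, sign=sign, weight_class=weight_class)

    @property
    def nodes(self) -> list[str]:
        return sorted(self.graph.nodes)

    @property
    def edges(self) -> list[tuple[str, str, dict]]:
        out = []
        for a, b, d in self.graph.edges(data=True):
            a, b = sorted((a, b))
            out.append((a, b, dict(d)))
        return sorted(out, key=lambda t: (t[0], t[1]))

    def node_table(self) -> pd.DataFrame:
        rows = []
        for g in self.nodes:
            attrs = self.graph.nodes[g]
            rows.append(
                {
                    "id": g,
                    "v1_id": attrs.get("v1_id", g),
                    "vcost_id": attrs.get("vcost_id", ""),
                    "symbol": attrs.get("symbol", ""),
                    "category": attrs.get("category", ""),
                    "degree": self.graph.degree(g),
                }
            )
        return pd.DataFrame(rows, columns=["id", "v1_id", "vcost_id", "symbol", "category", "degree"])

    def edge_table(self) -> pd.DataFrame:
        rows = [
            {
                "source": a,
                "target": b,
                "weight": d["weight"],
                "sign": d["sign"],
                "weight_class": d["weight_class"],
            }
            for a, b, d in self.edges
        ]
        return pd.DataFrame(rows, columns=["source", "target", "weight", "sign", "weight_class"])

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GeneNetwork):
            return NotImplemented
        if set(self.graph.nodes) != set(other.graph.nodes):
            return False
        return self.edges == other.edges
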