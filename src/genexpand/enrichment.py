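"""GO over-representation analysis and promoter FASTA preparation.

The enrichment is the classic per-term one-sided Fisher/hypergeometric
test on propagated (true-path) annotations, reported for the Biological
Process or Molecular Function namespace, ranked by raw p-value with a
Benjamini-Hochberg adjusted column.  Promoter extraction emits the
upstream region of each requested gene (default 1 kb, strand-aware,
clipped at chromosome boundaries) as FASTA for downstream motif tools.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional

import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .model import DataFormatError

__all__ = [
    "GOAnnotation",
    "read_gene2terms",
    "read_obo",
    "load_go_annotation",
    "propagate_annotations",
    "hypergeom_tail",
    "go_enrichment",
    "extract_promoters",
    "write_promoter_fasta",
]

_NAMESPACE_CODES = {
    "biological_process": "BP",
    "molecular_function": "MF",
    "cellular_component": "CC",
}


@dataclass
class GOAnnotation:
    """Gene -> GO-term annotations plus the term parent DAG.

    ``gene2terms`` holds direct annotations; ``term_parents`` the is_a /
    part_of parent relation; ``term_names`` maps a term to its label and
    namespace code (BP, MF, CC).  ``propagated`` records whether the
    true-path closure has been applied.
    """

    gene2terms: dict[str, set[str]]
    term_parents: dict[str, set[str]] = field(default_factory=dict)
    term_names: dict[str, tuple[str, str]] = field(default_factory=dict)
    propagated: bool = False

    def namespace_of(self, term: str) -> Optional[str]:
        info = self.term_names.get(term)
        return info[1] if info else None

    def ancestors(self, term: str) -> set[str]:
        out: set[str] = set()
        stack = list(self.term_parents.get(term, ()))
        while stack:
            t = stack.pop()
            if t in out:
                continue
            out.add(t)
            stack.extend(self.term_parents.get(t, ()))
        return out


def read_gene2terms(path) -> dict[str, set[str]]:
    """Two-column TSV gene<TAB>term (one pair per line, '#' comments)."""
    gene2terms: dict[str, set[str]] = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) != 2:
            raise DataFormatError(f"line {lineno}: expected 2 tab-separated columns, got {len(parts)}")
        gene, term = parts
        gene2terms.setdefault(gene, set()).add(term)
    return gene2terms


def read_obo(path) -> tuple[dict[str, set[str]], dict[str, tuple[str, str]]]:
    """Parse an OBO ontology into (term_parents, term_names).

    Parents are the union of ``is_a`` and ``part_of`` relationships;
    namespaces are folded to the two-letter codes BP/MF/CC.
    """
    import obonet

    graph = obonet.read_obo(path)
    term_parents: dict[str, set[str]] = {}
    term_names: dict[str, tuple[str, str]] = {}
    for term, data in graph.nodes(data=True):
        ns = _NAMESPACE_CODES.get(data.get("namespace", ""), data.get("namespace", ""))
        term_names[term] = (data.get("name", ""), ns)
        # obonet edges point child -> parent, keyed by relationship type
        term_parents[term] = {
            p for _, p, k in graph.out_edges(term, keys=True) if k in {"is_a", "part_of"}
        }
    return term_parents, term_names


def load_go_annotation(gene2terms_path, obo_path=None) -> GOAnnotation:
    gene2terms = read_gene2terms(gene2terms_path)
    if obo_path is not None:
        term_parents, term_names = read_obo(obo_path)
    else:
        term_parents, term_names = {}, {}
    return GOAnnotation(gene2terms=gene2terms, term_parents=term_parents, term_names=term_names)


def _check_acyclic(term_parents: dict[str, set[str]]) -> None:
    WHITE, GRAY, BLACK = 0, 1, 2
    color: dict[str, int] = {}

    def visit(t: str) -> None:
        color[t] = GRAY
        for p in term_parents.get(t, ()):
            c = color.get(p, WHITE)
            if c == GRAY:
                raise DataFormatError(f"cycle in term parent relation involving {p!r}")
            if c == WHITE:
                visit(p)
        color[t] = BLACK

    for t in list(term_parents):
        if color.get(t, WHITE) == WHITE:
            visit(t)


def propagate_annotations(ann: GOAnnotation) -> GOAnnotation:
    """Apply the true-path rule: a gene annotated to a term is annotated to
    all its ancestors.  Idempotent; cycles in the parent relation raise."""
    _check_acyclic(ann.term_parents)
    cache: dict[str, set[str]] = {}

    def closure(term: str) -> set[str]:
        if term not in cache:
            cache[term] = {term} | ann.ancestors(term)
        return cache[term]

    gene2terms = {g: set().union(*(closure(t) for t in terms)) if terms else set()
                  for g, terms in ann.gene2terms.items()}
    return GOAnnotation(
        gene2terms=gene2terms,
        term_parents=ann.term_parents,
        term_names=ann.term_names,
        propagated=True,
    )


def hypergeom_tail(k: int, pop_size: int, pop_count: int, study_size: int) -> float:
    """Over-representation tail P(X >= k), X ~ Hypergeom(pop_size, pop_count, study_size).

    This is the one-sided Fisher exact p-value of the 2x2 table
    (study/population) x (in-term/not-in-term).
    """
    p = float(stats.hypergeom.sf(k - 1, pop_size, pop_count, study_size))
    return min(p, 1.0)


def go_enrichment(
    study: Iterable[str],
    population: Iterable[str],
    ann: GOAnnotation,
    namespace: Optional[str] = None,
) -> pd.DataFrame:
    """Per-term over-representation of a study set within a population.

    For every term annotating at least one study gene, the one-sided
    hypergeometric tail P(X >= study_count) is computed from the 2x2 table
    of study/population membership against in-term/not-in-term, and a
    Benjamini-Hochberg adjusted column is added.  Rows are ranked by
    ascending raw p-value.  ``namespace`` restricts to BP or MF terms
    (terms without namespace metadata are kept only when namespace is
    None).  Annotations should be propagated first.
    """
    study = set(study)
    population = set(population)
    missing = study - population
    if missing:
        raise ValueError(f"study genes absent from population: {sorted(missing)[:10]}")
    if namespace is not None and namespace not in {"BP", "MF", "CC"}:
        raise ValueError("namespace must be one of BP, MF, CC")

    term_study: dict[str, int] = {}
    term_pop: dict[str, int] = {}
    for gene in population:
        for term in ann.gene2terms.get(gene, ()):
            term_pop[term] = term_pop.get(term, 0) + 1
            if gene in study:
                term_study[term] = term_study.get(term, 0) + 1

    pop_size, study_size = len(population), len(study)
    rows = []
    for term, k in term_study.items():
        if namespace is not None and ann.namespace_of(term) != namespace:
            continue
        K = term_pop[term]
        p = hypergeom_tail(k, pop_size, K, study_size)
        name, ns = ann.term_names.get(term, ("", ""))
        rows.append(
            {
                "term": term,
                "name": name,
                "namespace": ns,
                "study_count": k,
                "study_size": study_size,
                "pop_count": K,
                "pop_size": pop_size,
                "expected": study_size * K / pop_size,
                "p_value": p,
            }
        )
    df = pd.DataFrame(
        rows,
        columns=[
            "term", "name", "namespace", "study_count", "study_size",
            "pop_count", "pop_size", "expected", "p_value",
        ],
    )
    if len(df):
        df = df.sort_values(by=["p_value", "term"], kind="mergesort").reset_index(drop=True)
        df["p_adjusted"] = multipletests(df["p_value"].to_numpy(), method="fdr_bh")[1]
    else:
        df["p_adjusted"] = pd.Series(dtype=float)
    return df


# ---------------------------------------------------------------------------
# Promoter extraction
# ---------------------------------------------------------------------------


def _gene_features(gff_path, genes: set[str]):
    import gffutils

    db = gffutils.create_db(
        str(gff_path), dbfn=":memory:", merge_strategy="create_unique", keep_order=True
    )
    found: dict[str, object] = {}
    for feat in db.all_features():
        ids = set(feat.attributes.get("ID", [])) | set(feat.attributes.get("Name", []))
        for g in ids & genes:
            if g not in found or feat.featuretype == "gene":
                found[g] = feat
    return found


def extract_promoters(genome_path, gff_path, genes: Iterable[str], length: int = 1000) -> list[tuple[str, str]]:
    """Upstream promoter sequences as (gene, sequence) pairs.

    Coordinates are 1-based inclusive GFF.  A plus-strand gene starting at
    s yields bases [s - length, s - 1]; a minus-strand gene ending at e
    yields the reverse complement of [e + 1, e + length].  Regions are
    clipped at chromosome boundaries, so promoters near an end may be
    shorter than requested.  Case is preserved from the genome.
    """
    from Bio.Seq import Seq
    from pyfaidx import Fasta

    genes = list(genes)
    if length < 1:
        raise ValueError("length must be positive")
    features = _gene_features(gff_path, set(genes))
    missing = [g for g in genes if g not in features]
    if missing:
        raise ValueError(f"genes without a GFF feature: {missing}")
    fasta = Fasta(str(genome_path), as_raw=True, sequence_always_upper=False)
    out = []
    for g in genes:
        feat = features[g]
        if feat.seqid not in fasta:
            raise ValueError(f"chromosome {feat.seqid!r} absent from genome FASTA")
        chrom = fasta[feat.seqid]
        chrom_len = len(chrom)
        if feat.strand == "-":
            lo = feat.end  # 0-based start of region [end+1, end+length]
            hi = min(chrom_len, feat.end + length)
            seq = str(Seq(chrom[lo:hi]).reverse_complement()) if hi > lo else ""
        else:
            lo = max(0, feat.start - 1 - length)
            hi = feat.start - 1
            seq = chrom[lo:hi] if hi > lo else ""
        out.append((g, seq))
    return out


def write_promoter_fasta(promoters: list[tuple[str, str]], path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for gene, seq in promoters:
            fh.write(f">{gene}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")
            if not seq:
                fh.write("\n")
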