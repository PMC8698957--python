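"""Network construction and aggregation from expansion lists.

Two tools operate on a collection of per-seed expansion lists:

* ``create_network`` — the seeds are the node set; an edge joins two
  seeds when each appears in the other's trimmed list (mutual presence),
  weighted by the mean of the two relative frequencies and signed by the
  Pearson correlation of the pair.
* ``expand_network`` — unions all records across lists into a candidate
  table and filters it by one of four criteria: relative-frequency
  threshold, rank threshold, functional-category pattern, or the number
  of input lists sharing the gene.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Optional, Union

import pandas as pd

from .model import ExpansionList, GeneAnnotation, GeneNetwork

__all__ = [
    "AggregationCriterion",
    "trim_list",
    "weight_class",
    "create_network",
    "expand_network",
]

logger = logging.getLogger(__name__)

_CRITERION_KINDS = {"frel", "rank", "pattern", "shared"}


@dataclass(frozen=True)
class AggregationCriterion:
    """Filter applied by ``expand_network``.

    kind ``frel`` keeps candidates with max F_rel >= threshold (real);
    ``rank`` keeps best rank <= threshold (integer); ``pattern`` keeps
    genes whose annotation category code starts with the threshold string
    (e.g. the transcription-factor code prefix); ``shared`` keeps genes
    present in at least threshold input lists (integer).
    """

    kind: str
    threshold: Union[float, int, str]

    def __post_init__(self) -> None:
        if self.kind not in _CRITERION_KINDS:
            raise ValueError(f"unknown criterion kind {self.kind!r}; expected one of {sorted(_CRITERION_KINDS)}")
        if self.kind == "frel" and not 0.0 <= float(self.threshold) <= 1.0:
            raise ValueError("frel threshold must be in [0, 1]")
        if self.kind in {"rank", "shared"} and int(self.threshold) < 1:
            raise ValueError(f"{self.kind} threshold must be a positive integer")
        if self.kind == "pattern" and not isinstance(self.threshold, str):
            raise ValueError("pattern threshold must be a category-code string")


def trim_list(lst: ExpansionList, f_min: float) -> ExpansionList:
    """Keep records with f_rel >= f_min; order (and original ranks) preserved."""
    if not 0.0 <= f_min <= 1.0:
        raise ValueError("f_min must be in [0, 1]")
    kept = [r for r in lst.records if r.f_rel >= f_min]
    return ExpansionList(seed=lst.seed, records=kept, params=lst.params)


def weight_class(weight: float, f_min: float = 0.5) -> str:
    """Display class of an edge weight: equal thirds of the band [f_min, 1].

    With the default band [0.5, 1]: solid on [0.8333, 1], dashed on
    [0.6667, 0.8333), dotted on [0.5, 0.6667).  Weights below f_min raise.
    """
    if not 0.0 <= f_min < 1.0:
        raise ValueError("f_min must be in [0, 1)")
    if weight < f_min or weight > 1.0:
        raise ValueError(f"weight {weight} outside the displayed band [{f_min}, 1]")
    third = (1.0 - f_min) / 3.0
    if weight >= f_min + 2 * third:
        return "solid"
    if weight >= f_min + third:
        return "dashed"
    return "dotted"


def create_network(
    lists: Iterable[ExpansionList],
    f_min: float,
    annotation: Optional[GeneAnnotation] = None,
    one_sided: bool = False,
) -> GeneNetwork:
    """Build the network among the input seeds from their expansion lists.

    Seeds are the node set (isolated seeds stay in the network).  Under
    the default mutual rule, an edge (A, B) exists iff B is in A's trimmed
    list AND A is in B's; its weight is the mean of the two relative
    frequencies.  ``one_sided=True`` relaxes the rule: presence in one
    direction suffices and the weight is the single available F_rel
    (if it survives trimming).  Edge sign is negative when either
    direction's stored Pearson correlation is negative; a sign
    discordance between the two directions is logged.
    """
    lists = list(lists)
    if len(lists) < 2:
        raise ValueError("create_network needs at least two expansion lists")
    seeds = [lst.seed for lst in lists]
    if len(set(seeds)) != len(seeds):
        dupes = sorted({s for s in seeds if seeds.count(s) > 1})
        raise ValueError(f"duplicate seeds among input lists: {dupes}")

    trimmed = {lst.seed: trim_list(lst, f_min) for lst in lists}
    net = GeneNetwork()
    ann = annotation
    for s in seeds:
        attrs = ann.lookup(s) if ann else {"v1_id": s, "vcost_id": "", "symbol": "", "category": ""}
        net.add_node(s, **attrs)

    for idx, a in enumerate(seeds):
        for b in seeds[idx + 1 :]:
            rec_ab = trimmed[a].record_for(b)  # b as seen from a's list
            rec_ba = trimmed[b].record_for(a)
            if rec_ab is not None and rec_ba is not None:
                weight = (rec_ab.f_rel + rec_ba.f_rel) / 2.0
                negatives = [rec_ab.pearson_r < 0, rec_ba.pearson_r < 0]
                if negatives[0] != negatives[1]:
                    logger.warning(
                        "Pearson sign discordance for edge %s--%s (%.3f vs %.3f); flagging negative",
                        a, b, rec_ab.pearson_r, rec_ba.pearson_r,
                    )
                sign = "-" if any(negatives) else "+"
            elif one_sided and (rec_ab is not None or rec_ba is not None):
                rec = rec_ab if rec_ab is not None else rec_ba
                weight = rec.f_rel
                sign = "-" if rec.pearson_r < 0 else "+"
            else:
                continue
            net.add_edge(a, b, weight=weight, sign=sign, weight_class=weight_class(weight, f_min))
    return net


def expand_network(
    lists: Iterable[ExpansionList],
    criterion: AggregationCriterion,
    annotation: Optional[GeneAnnotation] = None,
) -> pd.DataFrame:
    """Aggregate expansion lists into a filtered candidate table.

    All records across lists are unioned into per-gene candidates carrying
    the set of source seeds, the max and mean F_rel over sources, and the
    best (smallest) rank; the criterion then filters the candidates.  The
    table is sorted by descending max F_rel, ties broken by larger
    absolute Pearson correlation then gene ID — the same tie-breaking the
    expansion engine uses.
    """
    lists = list(lists)
    if not lists:
        raise ValueError("expand_network needs at least one expansion list")
    if criterion.kind == "pattern" and annotation is None:
        raise ValueError("pattern criterion requires an annotation table")

    agg: dict[str, dict] = {}
    for lst in lists:
        for r in lst.records:
            c = agg.setdefault(
                r.gene,
                {"source_seeds": set(), "f_rels": [], "best_rank": r.rank, "best_abs_r": 0.0},
            )
            c["source_seeds"].add(lst.seed)
            c["f_rels"].append(r.f_rel)
            c["best_rank"] = min(c["best_rank"], r.rank)
            c["best_abs_r"] = max(c["best_abs_r"], abs(r.pearson_r))

    rows = []
    for gene, c in agg.items():
        rows.append(
            {
                "gene": gene,
                "source_seeds": ",".join(sorted(c["source_seeds"])),
                "n_source_seeds": len(c["source_seeds"]),
                "max_f_rel": max(c["f_rels"]),
                "mean_f_rel": sum(c["f_rels"]) / len(c["f_rels"]),
                "best_rank": c["best_rank"],
                "max_abs_pearson_r": c["best_abs_r"],
                "category": annotation.category_of(gene) if annotation else "",
            }
        )
    df = pd.DataFrame(
        rows,
        columns=[
            "gene", "source_seeds", "n_source_seeds", "max_f_rel", "mean_f_rel",
            "best_rank", "max_abs_pearson_r", "category",
        ],
    )
    if criterion.kind == "frel":
        df = df[df["max_f_rel"] >= float(criterion.threshold)]
    elif criterion.kind == "rank":
        df = df[df["best_rank"] <= int(criterion.threshold)]
    elif criterion.kind == "shared":
        df = df[df["n_source_seeds"] >= int(criterion.threshold)]
    elif criterion.kind == "pattern":
        df = df[df["category"].str.startswith(str(criterion.threshold))]
    df = df.sort_values(
        by=["max_f_rel", "max_abs_pearson_r", "gene"],
        ascending=[False, False, True],
        kind="mergesort",
    ).reset_index(drop=True)
    return df
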