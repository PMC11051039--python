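"""Essential-subset extraction and cross-list consensus.

The maximum point of an IFS curve is the smallest prefix size achieving the
best weighted F1. When that maximum sits at or beyond ``k_threshold``
features, a "relatively high" point — the smallest earlier prefix whose
score is within ``delta`` of the maximum — replaces it, trading a little
performance for a much smaller gene set. The surviving prefixes (one per
ranked list) are the essential subsets; the consensus table counts how many
lists selected each gene and tabulates exact list-combination cells in
upset-diagram style.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from .ifs import IFSCurve
from .ranking import top_prefix

logger = logging.getLogger(__name__)


@dataclass
class EssentialSubset:
    ranker_name: str
    classifier_name: str
    point_kind: str  # "max" | "relative_high"
    k: int
    score: float
    gene_ids: list[str]

    def __post_init__(self) -> None:
        if self.point_kind not in ("max", "relative_high"):
            raise ValueError(f"bad point_kind {self.point_kind!r}")
        if len(self.gene_ids) != self.k:
            raise ValueError("gene_ids length must equal k")


@dataclass
class ConsensusTable:
    """Per-gene selection counts plus exact-combination (upset) cells."""

    counts: dict[str, int]
    selecting_lists: dict[str, list[str]]
    upset_cells: dict[tuple[str, ...], int] = field(default_factory=dict)

    def to_records(self) -> list[dict]:
        rows = []
        for gene in sorted(self.counts, key=lambda g: (-self.counts[g], g)):
            rows.append({
                "gene_id": gene,
                "count": self.counts[gene],
                "lists": ",".join(self.selecting_lists[gene]),
            })
        return rows

    def upset_records(self) -> list[dict]:
        rows = []
        for combo in sorted(self.upset_cells, key=lambda c: (-len(c), c)):
            rows.append({
                "lists": list(combo),
                "degree": len(combo),
                "n_genes": self.upset_cells[combo],
            })
        return rows


def _subset_from_curve(curve: IFSCurve, ranked_lists, kind: str, k: int,
                       score: float) -> EssentialSubset:
    if ranked_lists is not None and curve.ranker_name in ranked_lists:
        genes = top_prefix(ranked_lists[curve.ranker_name], k)
    elif curve.gene_ids is not None and len(curve.gene_ids) >= k:
        genes = list(curve.gene_ids[:k])
    else:
        # curve built without gene identities (e.g. re-read from a bare
        # score table): keep rank placeholders
        genes = [f"rank_{i}" for i in range(k)]
    return EssentialSubset(
        ranker_name=curve.ranker_name,
        classifier_name=curve.classifier_name,
        point_kind=kind,
        k=k,
        score=score,
        gene_ids=genes,
    )


def find_max_point(curve: IFSCurve, ranked_lists=None) -> EssentialSubset:
    """Smallest k achieving the curve's maximum weighted F1."""
    if not curve.records:
        raise ValueError("empty curve")
    scores = curve.scores("weighted_f1")
    best = max(scores)
    k_best = curve.ks[scores.index(best)]  # first occurrence = smallest k
    return _subset_from_curve(curve, ranked_lists, "max", k_best, best)


def find_relative_high_point(
    curve: IFSCurve,
    delta: float = 0.015,
    k_threshold: int = 100,
    ranked_lists=None,
) -> EssentialSubset | None:
    """Smaller prefix within ``delta`` of the maximum, if the maximum needs
    at least ``k_threshold`` features; None otherwise."""
    if delta < 0:
        raise ValueError("delta must be nonnegative")
    max_point = find_max_point(curve)
    if max_point.k < k_threshold:
        return None
    target = max_point.score - delta
    for k, score in zip(curve.ks, curve.scores("weighted_f1")):
        if score >= target:
            if k == max_point.k:
                return None
            return _subset_from_curve(curve, ranked_lists, "relative_high", k, score)
    return None


def essential_subsets(
    curves: list[IFSCurve],
    ranked_lists: dict | None = None,
    delta: float = 0.015,
    k_threshold: int = 100,
) -> list[EssentialSubset]:
    """One essential subset per curve: the max point, replaced by its
    relative-high point when one qualifies."""
    out = []
    for curve in curves:
        chosen = find_relative_high_point(
            curve, delta=delta, k_threshold=k_threshold, ranked_lists=ranked_lists
        )
        if chosen is None:
            chosen = find_max_point(curve, ranked_lists=ranked_lists)
        logger.info(
            "essential_subsets ranker=%s kind=%s k=%d score=%.4f",
            curve.ranker_name, chosen.point_kind, chosen.k, chosen.score,
        )
        out.append(chosen)
    return out


def consensus(subsets: list[EssentialSubset]) -> ConsensusTable:
    """Selection frequency of every gene across essential subsets, plus
    upset-style exact-combination cell sizes."""
    if not subsets:
        raise ValueError("need at least one subset")
    membership: dict[str, set[str]] = {}
    for sub in subsets:
        for gene in sub.gene_ids:
            membership.setdefault(gene, set()).add(sub.ranker_name)
    counts = {g: len(lists) for g, lists in membership.items()}
    selecting = {g: sorted(lists) for g, lists in membership.items()}
    cells: dict[tuple[str, ...], int] = {}
    for g, lists in selecting.items():
        combo = tuple(lists)
        cells[combo] = cells.get(combo, 0) + 1
    return ConsensusTable(counts=counts, selecting_lists=selecting,
                          upset_cells=cells)
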