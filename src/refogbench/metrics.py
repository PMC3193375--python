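"""Scoring of predicted orthologous groups against curated reference groups.

Each RefOG is scored at two levels:

* **gene level** — the predicted OG with the largest overlap with the RefOG
  is identified; RefOG members absent from it are *missing genes* and
  non-members present in it are *erroneously assigned genes*;
* **group level** — the number of predicted OGs over which RefOG members are
  dispersed yields *fission* events (an unsplit RefOG scores zero), and
  every member-bearing OG carrying more than three erroneously assigned
  genes counts as a *fusion* event.

These per-RefOG quantities aggregate into six per-method scoring schemes
(strict gene-level accuracy, error totals, affected-RefOG percentages, group
accuracy, event totals, event-affected percentages), and methods are ranked
by their total error count.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Optional, Sequence

from .model import GeneRecord, PredictedOGSet, RefOG, RefOGSet

__all__ = [
    "FusionThreshold",
    "RefOGComparison",
    "MethodSummary",
    "best_matching_og",
    "gene_level_errors",
    "group_level_events",
    "evaluate_refog",
    "evaluate_all",
    "summarize_method",
    "summarize_comparisons",
    "rank_methods",
    "format_pct",
]


@dataclass(frozen=True)
class FusionThreshold:
    """Minimum erroneously assigned genes for a member-bearing OG to count as a fusion.

    The default of 4 encodes the "more than three erroneously assigned
    genes" rule: three aliens are tolerated, four are a fusion.
    """

    min_erroneous_for_fusion: int = 4

    def __post_init__(self) -> None:
        if self.min_erroneous_for_fusion < 1:
            raise ValueError("min_erroneous_for_fusion must be >= 1")


@dataclass(frozen=True)
class RefOGComparison:
    """The outcome of scoring one RefOG against one method's predictions.

    ``member_bearing_ogs`` lists every predicted OG containing at least one
    RefOG member (sorted); ``fission_events`` is ``max(0, len - 1)`` so the
    raw OG count is recoverable.  ``missing`` and ``erroneous`` are judged
    against the best-matching OG only.
    """

    refog_id: str
    refog_size: int
    matched_og_id: Optional[str]
    overlap_size: int
    missing: frozenset[GeneRecord]
    erroneous: frozenset[GeneRecord]
    member_bearing_ogs: tuple[str, ...]
    fission_events: int
    fusion_events: int
    gene_strict: bool
    group_accurate: bool

    @property
    def n_member_bearing_ogs(self) -> int:
        return len(self.member_bearing_ogs)


@dataclass(frozen=True)
class MethodSummary:
    """The six scoring schemes aggregated over a RefOG set for one method."""

    method_name: str
    n_refogs: int
    gene_strict_accuracy_pct: float
    total_missing: int
    total_erroneous: int
    pct_refogs_with_missing: float
    pct_refogs_with_erroneous: float
    group_accuracy_pct: float
    total_fissions: int
    total_fusions: int
    pct_refogs_fissioned: float
    pct_refogs_fused: float

    @property
    def total_errors(self) -> int:
        """Ranking statistic: missing + erroneous + fissions + fusions."""
        return (self.total_missing + self.total_erroneous
                + self.total_fissions + self.total_fusions)


def format_pct(value: float) -> str:
    """Report percentages to one decimal place, round-half-up."""
    return str(Decimal(repr(value)).quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


def best_matching_og(
    refog: RefOG, predictions: PredictedOGSet
) -> tuple[Optional[str], int]:
    """Find the predicted OG with the largest overlap with ``refog``.

    Ties are broken by (1) fewer non-member genes in the OG, then (2) the
    lexicographically smallest og_id.  Returns ``(None, 0)`` when no OG
    contains any RefOG member.
    """
    member_ids = refog.member_ids
    best: Optional[str] = None
    best_key: Optional[tuple[int, int, str]] = None
    best_overlap = 0
    for og_id, members in predictions.ogs.items():
        overlap = sum(1 for g in members if g.gene_id in member_ids)
        if overlap == 0:
            continue
        key = (-overlap, len(members) - overlap, og_id)
        if best_key is None or key < best_key:
            best_key, best, best_overlap = key, og_id, overlap
    return best, best_overlap


def gene_level_errors(
    refog: RefOG, matched_og: Iterable[GeneRecord]
) -> tuple[frozenset[GeneRecord], frozenset[GeneRecord]]:
    """Missing = RefOG \\ matched OG; erroneous = matched OG \\ RefOG."""
    matched = frozenset(matched_og)
    member_ids = refog.member_ids
    matched_ids = frozenset(g.gene_id for g in matched)
    missing = frozenset(g for g in refog.members if g.gene_id not in matched_ids)
    erroneous = frozenset(g for g in matched if g.gene_id not in member_ids)
    return missing, erroneous


def group_level_events(
    refog: RefOG,
    predictions: PredictedOGSet,
    threshold: FusionThreshold = FusionThreshold(),
) -> tuple[int, int, tuple[str, ...]]:
    """Count fission and fusion events for one RefOG.

    Fissions: one less than the number of member-bearing OGs (never
    negative), so an unsplit RefOG scores zero.  Fusions: member-bearing OGs
    whose count of non-member genes reaches the threshold.
    """
    member_ids = refog.member_ids
    bearing: list[str] = []
    fusions = 0
    for og_id, members in predictions.ogs.items():
        n_members = sum(1 for g in members if g.gene_id in member_ids)
        if n_members == 0:
            continue
        bearing.append(og_id)
        if len(members) - n_members >= threshold.min_erroneous_for_fusion:
            fusions += 1
    bearing.sort()
    fissions = max(0, len(bearing) - 1)
    return fissions, fusions, tuple(bearing)


def evaluate_refog(
    refog: RefOG,
    predictions: PredictedOGSet,
    threshold: FusionThreshold = FusionThreshold(),
    strict_group_mode: bool = False,
) -> RefOGComparison:
    """Score one RefOG: best match, gene-level error sets, group-level events.

    ``gene_strict`` holds when the best-matching OG reproduces the RefOG
    exactly (no missing, no erroneous genes).  ``group_accurate`` holds when
    there are no fission and no fusion events; in ``strict_group_mode`` any
    erroneously assigned gene in a member-bearing OG also voids it.
    """
    matched_id, overlap = best_matching_og(refog, predictions)
    matched_members = predictions.ogs.get(matched_id, frozenset()) if matched_id else frozenset()
    missing, erroneous = gene_level_errors(refog, matched_members)
    fissions, fusions, bearing = group_level_events(refog, predictions, threshold)

    group_ok = fissions == 0 and fusions == 0
    if strict_group_mode:
        member_ids = refog.member_ids
        any_alien = any(
            any(g.gene_id not in member_ids for g in predictions.ogs[og_id])
            for og_id in bearing
        )
        group_ok = group_ok and not any_alien
    return RefOGComparison(
        refog_id=refog.refog_id,
        refog_size=refog.size,
        matched_og_id=matched_id,
        overlap_size=overlap,
        missing=missing,
        erroneous=erroneous,
        member_bearing_ogs=bearing,
        fission_events=fissions,
        fusion_events=fusions,
        gene_strict=(not missing and not erroneous),
        group_accurate=group_ok,
    )


def evaluate_all(
    refogs: RefOGSet,
    predictions: PredictedOGSet,
    threshold: FusionThreshold = FusionThreshold(),
    strict_group_mode: bool = False,
) -> list[RefOGComparison]:
    return [
        evaluate_refog(r, predictions, threshold, strict_group_mode) for r in refogs
    ]


def summarize_comparisons(
    method_name: str, comparisons: Sequence[RefOGComparison]
) -> MethodSummary:
    """Aggregate per-RefOG comparisons into the six scoring schemes."""
    n = len(comparisons)
    if n == 0:
        raise ValueError("cannot summarize an empty RefOG set")

    def pct(k: int) -> float:
        return 100.0 * k / n

    return MethodSummary(
        method_name=method_name,
        n_refogs=n,
        gene_strict_accuracy_pct=pct(sum(c.gene_strict for c in comparisons)),
        total_missing=sum(len(c.missing) for c in comparisons),
        total_erroneous=sum(len(c.erroneous) for c in comparisons),
        pct_refogs_with_missing=pct(sum(bool(c.missing) for c in comparisons)),
        pct_refogs_with_erroneous=pct(sum(bool(c.erroneous) for c in comparisons)),
        group_accuracy_pct=pct(sum(c.group_accurate for c in comparisons)),
        total_fissions=sum(c.fission_events for c in comparisons),
        total_fusions=sum(c.fusion_events for c in comparisons),
        pct_refogs_fissioned=pct(sum(c.fission_events > 0 for c in comparisons)),
        pct_refogs_fused=pct(sum(c.fusion_events > 0 for c in comparisons)),
    )


def summarize_method(
    refogs: RefOGSet,
    predictions: PredictedOGSet,
    threshold: FusionThreshold = FusionThreshold(),
    strict_group_mode: bool = False,
) -> MethodSummary:
    """Evaluate every RefOG and aggregate into a :class:`MethodSummary`."""
    if len(refogs) == 0:
        raise ValueError("cannot summarize an empty RefOG set")
    comparisons = evaluate_all(refogs, predictions, threshold, strict_group_mode)
    return summarize_comparisons(predictions.method_name, comparisons)


def rank_methods(summaries: Sequence[MethodSummary]) -> list[MethodSummary]:
    """Order methods from more to less accurate by total error count.

    Ties go to the higher strict gene-level accuracy, then to the
    lexicographically smaller method name.
    """
    if not summaries:
        raise ValueError("rank_methods needs at least one summary")
    return sorted(
        summaries,
        key=lambda s: (s.total_errors, -s.gene_strict_accuracy_pct, s.method_name),
    )
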