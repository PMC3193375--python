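"""Family-complexity factors and their association with error burden.

Four per-family factors are computed and used to stratify reference
orthologous groups:

* **size** — member count; small (<14), medium (14-40), large (>40);
* **rate of evolution** — mean pairwise identity (MeanID) over the family
  MSA; slow (>=0.7), medium ([0.5, 0.7)), fast (<0.5).  High identity means
  slow evolution;
* **alignment quality** — a normalized mean-similarity score in [0, 1]
  (a norMD-style stand-in, not a bit-exact norMD implementation); high
  (>0.6) vs low;
* **domain complexity** — average predicted domains per member; <2, [2, 4],
  >4.

Boundary values (exactly 14 or 40 members; exactly 0.5 or 0.7 identity) are
assigned to the middle size class and the slower rate class respectively.

Association between a factor and an error type is tested with a Spearman
rank correlation on the continuous factor plus a Kruskal-Wallis rank test
across the factor's classes; p-values are Benjamini-Hochberg adjusted over
the whole factor x error-type grid and flagged significant at adjusted
p < 0.05.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
from scipy import stats
from Bio.Align import substitution_matrices

from .model import Alignment, GAP_CHARS, RefOG

__all__ = [
    "FamilyComplexity",
    "FactorClassification",
    "AssociationResult",
    "ClassThresholds",
    "mean_pairwise_identity",
    "alignment_quality_score",
    "average_domain_count",
    "classify_family",
    "compute_complexity",
    "factor_error_association",
    "benjamini_hochberg",
]


@dataclass(frozen=True)
class ClassThresholds:
    """Classification cut points for the four complexity factors.

    Defaults follow the established benchmarking conventions for metazoan
    families; all are configurable.
    """

    size_small_below: int = 14
    size_large_above: int = 40
    rate_slow_min: float = 0.7
    rate_fast_below: float = 0.5
    align_high_above: float = 0.6
    domains_low_below: float = 2.0
    domains_high_above: float = 4.0


@dataclass(frozen=True)
class FamilyComplexity:
    refog_id: str
    size: int
    mean_id: Optional[float] = None
    align_quality: Optional[float] = None
    avg_domains: float = 0.0

    def __post_init__(self) -> None:
        if self.size < 1:
            raise ValueError("size must be >= 1")
        for name in ("mean_id", "align_quality"):
            v = getattr(self, name)
            if v is not None and not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if self.avg_domains < 0:
            raise ValueError("avg_domains must be >= 0")


@dataclass(frozen=True)
class FactorClassification:
    """One label per complexity axis; rate/align are None without an MSA."""

    size_class: str
    rate_class: Optional[str]
    align_class: Optional[str]
    domain_class: str


@dataclass(frozen=True)
class AssociationResult:
    factor: str
    error_type: str
    test: str  # "spearman" or "kruskal"
    statistic: float
    p_value: float
    adjusted_p: float
    significant: bool
    degenerate: bool = False


def mean_pairwise_identity(msa: Alignment) -> float:
    """Mean pairwise identity (MeanID) over all unordered row pairs.

    For each pair, identity = identical aligned positions / positions where
    both rows are ungapped.  A pair with no co-ungapped position contributes
    zero.  Gaps never count as matches or mismatches.
    """
    if msa.n_rows < 2:
        raise ValueError("mean_pairwise_identity needs >= 2 rows")
    total = 0.0
    n_pairs = 0
    for (_, a), (_, b) in itertools.combinations(msa.rows, 2):
        co = same = 0
        for x, y in zip(a, b):
            if x in GAP_CHARS or y in GAP_CHARS:
                continue
            co += 1
            if x == y:
                same += 1
        total += same / co if co else 0.0
        n_pairs += 1
    return total / n_pairs


def _similarity_lookup(matrix_name: str) -> dict[tuple[str, str], float]:
    try:
        mat = substitution_matrices.load(matrix_name)
    except FileNotFoundError as exc:
        raise ValueError(f"unknown substitution matrix {matrix_name!r}") from exc
    sim: dict[tuple[str, str], float] = {}
    alphabet = mat.alphabet
    diag = {a: mat[a, a] for a in alphabet}
    for a in alphabet:
        for b in alphabet:
            # residues with non-positive self-score (e.g. X in BLOSUM62)
            # cannot be self-normalized; their pairs score 0
            if diag[a] <= 0 or diag[b] <= 0:
                sim[(a, b)] = 0.0
            else:
                sim[(a, b)] = min(1.0, max(0.0, mat[a, b] / math.sqrt(diag[a] * diag[b])))
    return sim


def alignment_quality_score(msa: Alignment, matrix: str = "BLOSUM62") -> float:
    """Normalized mean pair-similarity of an alignment, in [0, 1].

    Per column, each co-ungapped residue pair scores S(a,b) /
    sqrt(S(a,a)*S(b,b)) clipped to [0, 1]; pairs with at least one gap score
    0.  The column score is the mean over all row pairs and the overall
    score is the mean over columns containing at least one residue (all-gap
    columns are excluded).  This is a norMD-style normalized similarity
    objective, not a bit-exact norMD implementation.
    """
    if msa.n_rows < 2:
        raise ValueError("alignment_quality_score needs >= 2 rows")
    sim = _similarity_lookup(matrix)
    n_pairs = msa.n_rows * (msa.n_rows - 1) // 2
    col_scores: list[float] = []
    for i in range(msa.n_columns):
        col = msa.column(i)
        if all(c in GAP_CHARS for c in col):
            continue
        s = 0.0
        for x, y in itertools.combinations(col, 2):
            if x in GAP_CHARS or y in GAP_CHARS:
                continue
            s += sim.get((x.upper(), y.upper()), 0.0)
        col_scores.append(s / n_pairs)
    return float(np.mean(col_scores)) if col_scores else 0.0


def average_domain_count(refog: RefOG, domains: Mapping[str, int]) -> float:
    """Sum of predicted domains over members divided by the family size.

    Members absent from the domain table count zero domains.
    """
    total = sum(domains.get(g.gene_id, 0) for g in refog.members)
    return total / refog.size


def compute_complexity(
    refog: RefOG,
    domains: Optional[Mapping[str, int]] = None,
    matrix: str = "BLOSUM62",
) -> FamilyComplexity:
    """All four complexity factors for one RefOG (MSA factors need an MSA)."""
    mean_id = align = None
    if refog.msa is not None:
        mean_id = mean_pairwise_identity(refog.msa)
        align = alignment_quality_score(refog.msa, matrix)
    avg_dom = average_domain_count(refog, domains) if domains is not None else 0.0
    return FamilyComplexity(refog.refog_id, refog.size, mean_id, align, avg_dom)


def classify_family(
    cx: FamilyComplexity, thresholds: ClassThresholds = ClassThresholds()
) -> FactorClassification:
    """Assign the four class labels for one family."""
    t = thresholds
    if cx.size < t.size_small_below:
        size_class = "small"
    elif cx.size <= t.size_large_above:
        size_class = "medium"
    else:
        size_class = "large"

    rate_class = None
    if cx.mean_id is not None:
        if cx.mean_id >= t.rate_slow_min:
            rate_class = "slow"
        elif cx.mean_id >= t.rate_fast_below:
            rate_class = "medium"
        else:
            rate_class = "fast"

    align_class = None
    if cx.align_quality is not None:
        align_class = "high" if cx.align_quality > t.align_high_above else "low"

    if cx.avg_domains < t.domains_low_below:
        domain_class = "le1"
    elif cx.avg_domains <= t.domains_high_above:
        domain_class = "two_to_four"
    else:
        domain_class = "gt4"

    return FactorClassification(size_class, rate_class, align_class, domain_class)


def benjamini_hochberg(p_values: Sequence[float]) -> list[float]:
    """Benjamini-Hochberg adjusted p-values (step-up FDR)."""
    if len(p_values) == 0:
        return []
    return stats.false_discovery_control(p_values, method="bh").tolist()


_CLASSERS = {
    "size": lambda v, t: ("small" if v < t.size_small_below
                          else "medium" if v <= t.size_large_above else "large"),
    "mean_id": lambda v, t: ("slow" if v >= t.rate_slow_min
                             else "medium" if v >= t.rate_fast_below else "fast"),
    "align_quality": lambda v, t: "high" if v > t.align_high_above else "low",
    "avg_domains": lambda v, t: ("le1" if v < t.domains_low_below
                                 else "two_to_four" if v <= t.domains_high_above
                                 else "gt4"),
}


def factor_error_association(
    errors: Mapping[str, Mapping[str, int]],
    factors: Mapping[str, Mapping[str, float]],
    alpha: float = 0.05,
    thresholds: ClassThresholds = ClassThresholds(),
    class_tests: bool = True,
) -> list[AssociationResult]:
    """Test each complexity factor against each error type.

    ``errors`` maps refog_id -> {error_type: count} and ``factors`` maps
    refog_id -> {factor: value}.  Each factor x error-type cell gets a
    Spearman rank correlation and (when the factor has a known class rule
    and >= 2 observed classes) a Kruskal-Wallis test across classes.
    P-values are adjusted with Benjamini-Hochberg over the whole grid;
    constant factors give an undefined statistic and are excluded from the
    adjustment.
    """
    shared = sorted(set(errors) & set(factors))
    if len(shared) < 5:
        raise ValueError("need >= 5 families with both error and factor values")
    factor_names = sorted({f for r in shared for f in factors[r]})
    error_names = sorted({e for r in shared for e in errors[r]})

    results: list[AssociationResult] = []
    testable_idx: list[int] = []
    for fac in factor_names:
        ids = [r for r in shared if factors[r].get(fac) is not None]
        fvals = np.array([factors[r][fac] for r in ids], dtype=float)
        degenerate_factor = len(ids) < 5 or np.all(fvals == fvals[0])
        for err in error_names:
            evals = np.array([errors[r].get(err, 0) for r in ids], dtype=float)
            if degenerate_factor or np.all(evals == evals[0]):
                results.append(AssociationResult(fac, err, "spearman",
                                                 float("nan"), float("nan"),
                                                 float("nan"), False, degenerate=True))
            else:
                rho, p = stats.spearmanr(fvals, evals)
                testable_idx.append(len(results))
                results.append(AssociationResult(fac, err, "spearman",
                                                 float(rho), float(p), float(p), False))
            if class_tests and fac in _CLASSERS and not degenerate_factor:
                labels = [_CLASSERS[fac](v, thresholds) for v in fvals]
                groups = [evals[[l == lab for l in labels]]
                          for lab in sorted(set(labels))]
                if len(groups) >= 2 and not np.all(evals == evals[0]):
                    try:
                        h, p = stats.kruskal(*groups)
                    except ValueError:  # all values identical within groups
                        h, p = float("nan"), float("nan")
                    if math.isnan(p):
                        results.append(AssociationResult(fac, err, "kruskal",
                                                         float("nan"), float("nan"),
                                                         float("nan"), False,
                                                         degenerate=True))
                    else:
                        testable_idx.append(len(results))
                        results.append(AssociationResult(fac, err, "kruskal",
                                                         float(h), float(p),
                                                         float(p), False))
                else:
                    results.append(AssociationResult(fac, err, "kruskal",
                                                     float("nan"), float("nan"),
                                                     float("nan"), False,
                                                     degenerate=True))

    adjusted = benjamini_hochberg([results[i].p_value for i in testable_idx])
    for i, adj in zip(testable_idx, adjusted):
        r = results[i]
        results[i] = AssociationResult(r.factor, r.error_type, r.test, r.statistic,
                                       r.p_value, adj, adj < alpha)
    return results
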