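"""Synthetic benchmark generator with a ground-truth error ledger.

Generates a gene universe partitioned into reference orthologous groups
(defaults mimic a curated metazoan benchmark: 12 species, 70 families,
family sizes from single-copy groups up to ~100 members), then perturbs it
into a "predicted" OG set by planting the four error types a real method
makes — dropped members (missing genes), inserted aliens (erroneously
assigned genes), family splits (fissions) and decoy-block merges (fusions).

Every planted event is recorded in a :class:`TruthLedger` from which the
expected value of all six scoring schemes can be derived by pure arithmetic,
independently of the prediction files — the oracle for the scoring engine.

Aliens and merge blocks are drawn from a decoy gene pool disjoint from all
reference families, so erroneous-gene attribution is unambiguous.  All
randomness flows from one seed; stages consume independent child streams in
a fixed order (sizes, species, drops, splits, aliens, merges) so partial
configurations stay reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Optional, Sequence

import numpy as np

from .model import (
    Alignment,
    GeneRecord,
    PredictedOGSet,
    ReferenceSpeciesSet,
    RefOG,
    RefOGSet,
)
from .metrics import FusionThreshold, MethodSummary

__all__ = [
    "PerturbationConfig",
    "PartRecord",
    "RefOGPlant",
    "TruthLedger",
    "generate_reference_set",
    "perturb_to_predictions",
    "expected_comparison_counts",
    "expected_summary",
    "generate_family_msa",
    "expected_pairwise_identity",
    "AMINO_ACIDS",
]

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"


def _default_size_distribution(rng: np.random.Generator) -> int:
    """Family sizes: lognormal, clipped to [2, 100] (mean ~23 members)."""
    return int(np.clip(round(rng.lognormal(3.0, 0.6)), 2, 100))


def generate_reference_set(
    n_species: int = 12,
    n_refogs: int = 70,
    size_distribution: Optional[Callable[[np.random.Generator], int] | int] = None,
    seed: int = 0,
    species_ids: Optional[Sequence[str]] = None,
) -> tuple[RefOGSet, frozenset[GeneRecord]]:
    """Generate a disjoint set of reference families over an n-species universe.

    Species are assigned round-robin from a random start with jitter, with
    the first two members forced onto distinct species so every family spans
    at least two species.  Deterministic for a fixed seed.
    """
    if n_species < 2:
        raise ValueError("need n_species >= 2")
    if n_refogs < 1:
        raise ValueError("need n_refogs >= 1")
    if species_ids is None:
        species_ids = [f"sp{i:02d}" for i in range(n_species)]
    else:
        species_ids = list(species_ids)
        if len(species_ids) != n_species:
            raise ValueError("species_ids length must equal n_species")

    size_rng = np.random.default_rng([seed, 0])
    species_rng = np.random.default_rng([seed, 1])

    if size_distribution is None:
        draw_size: Callable[[np.random.Generator], int] = _default_size_distribution
    elif isinstance(size_distribution, int):
        fixed = size_distribution
        draw_size = lambda rng: fixed  # noqa: E731
    else:
        draw_size = size_distribution

    sizes = []
    for _ in range(n_refogs):
        s = draw_size(size_rng)
        if s < 2:
            raise ValueError(f"family size {s} < 2 cannot span two species")
        sizes.append(s)

    refogs = []
    counter = 0
    for i, size in enumerate(sizes):
        start = int(species_rng.integers(n_species))
        members = []
        for j in range(size):
            if j < 2:
                sp_idx = (start + j) % n_species
            elif species_rng.random() < 0.25:  # jitter off the round-robin lattice
                sp_idx = int(species_rng.integers(n_species))
            else:
                sp_idx = (start + j) % n_species
            members.append(GeneRecord(f"G{counter:06d}", species_ids[sp_idx]))
            counter += 1
        refogs.append(RefOG(f"R{i:03d}", frozenset(members)))
    refog_set = RefOGSet(refogs)
    return refog_set, refog_set.universe


@dataclass(frozen=True)
class PerturbationConfig:
    """Rates of the four planted error types.

    ``p_drop``: per-gene deletion probability (missing genes).
    ``p_split``: per-family probability of fission into ``k`` parts, ``k``
    drawn uniformly from ``split_parts``.
    ``p_alien``: per-OG probability of inserting aliens, the count drawn
    uniformly from ``alien_counts`` (small counts stay below the fusion
    threshold).
    ``p_merge``: per-family probability of appending a contiguous decoy
    block of ``merge_block_size`` genes to one of its OGs; the default block
    of 5 crosses the more-than-three-aliens fusion threshold.
    """

    p_drop: float = 0.0
    p_split: float = 0.0
    split_parts: tuple[int, ...] = (2, 3)
    p_alien: float = 0.0
    alien_counts: tuple[int, ...] = (1, 2)
    p_merge: float = 0.0
    merge_block_size: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("p_drop", "p_split", "p_alien", "p_merge"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if any(k < 2 for k in self.split_parts):
            raise ValueError("split_parts must all be >= 2")
        if any(c < 1 for c in self.alien_counts):
            raise ValueError("alien_counts must all be >= 1")
        if self.merge_block_size < 1:
            raise ValueError("merge_block_size must be >= 1")


@dataclass(frozen=True)
class PartRecord:
    """One predicted OG derived from a reference family: survivors + aliens."""

    og_id: str
    n_members: int
    n_aliens: int


@dataclass(frozen=True)
class RefOGPlant:
    """All planted events for one reference family."""

    refog_id: str
    refog_size: int
    dropped: tuple[str, ...]
    parts: tuple[PartRecord, ...]
    merged: bool

    @property
    def n_dropped(self) -> int:
        return len(self.dropped)


@dataclass(frozen=True)
class TruthLedger:
    """The complete record of planted events for one synthetic run."""

    method_name: str
    plants: tuple[RefOGPlant, ...]

    def write_tsv(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write("refog_id\trefog_size\tn_dropped\tog_id\tn_members\tn_aliens\tmerged\n")
            for p in self.plants:
                if not p.parts:
                    fh.write(f"{p.refog_id}\t{p.refog_size}\t{p.n_dropped}\t-\t0\t0\t{int(p.merged)}\n")
                for part in p.parts:
                    fh.write(
                        f"{p.refog_id}\t{p.refog_size}\t{p.n_dropped}\t"
                        f"{part.og_id}\t{part.n_members}\t{part.n_aliens}\t{int(p.merged)}\n"
                    )


def perturb_to_predictions(
    refogs: RefOGSet,
    config: PerturbationConfig,
    method_name: str = "synthetic",
) -> tuple[PredictedOGSet, TruthLedger]:
    """Plant drops, splits, aliens and merges into a copy of the RefOGs.

    With all probabilities zero the predictions reproduce the RefOGs exactly
    and the ledger records no events.
    """
    drop_rng = np.random.default_rng([config.seed, 2])
    split_rng = np.random.default_rng([config.seed, 3])
    alien_rng = np.random.default_rng([config.seed, 4])
    merge_rng = np.random.default_rng([config.seed, 5])

    species_pool = sorted({g.species_id for r in refogs for g in r.members})
    decoy_counter = 0

    def make_decoys(n: int, rng: np.random.Generator) -> list[GeneRecord]:
        nonlocal decoy_counter
        out = []
        for _ in range(n):
            sp = species_pool[int(rng.integers(len(species_pool)))]
            out.append(GeneRecord(f"DECOY{decoy_counter:06d}", sp))
            decoy_counter += 1
        return out

    # stage: drops
    survivors: dict[str, list[GeneRecord]] = {}
    dropped: dict[str, list[str]] = {}
    for r in refogs:
        surv, drp = [], []
        for g in sorted(r.members, key=lambda g: g.gene_id):
            if drop_rng.random() < config.p_drop:
                drp.append(g.gene_id)
            else:
                surv.append(g)
        survivors[r.refog_id] = surv
        dropped[r.refog_id] = drp

    # stage: splits (uniform partition into k non-empty parts: shuffle + cuts)
    parts: dict[str, list[list[GeneRecord]]] = {}
    for r in refogs:
        surv = survivors[r.refog_id]
        do_split = split_rng.random() < config.p_split
        if do_split:
            k = int(split_rng.choice(config.split_parts))
        if not surv:
            parts[r.refog_id] = []
            continue
        if not do_split or len(surv) < 2:
            parts[r.refog_id] = [list(surv)]
            continue
        k = min(k, len(surv))
        order = list(split_rng.permutation(len(surv)))
        cuts = sorted(split_rng.choice(len(surv) - 1, size=k - 1, replace=False) + 1)
        shuffled = [surv[i] for i in order]
        bounds = [0, *cuts, len(surv)]
        parts[r.refog_id] = [shuffled[a:b] for a, b in zip(bounds, bounds[1:])]

    # stage: aliens
    aliens: dict[tuple[str, int], list[GeneRecord]] = {}
    for r in refogs:
        for j in range(len(parts[r.refog_id])):
            if alien_rng.random() < config.p_alien:
                n = int(alien_rng.choice(config.alien_counts))
                aliens[(r.refog_id, j)] = make_decoys(n, alien_rng)

    # stage: merges (a contiguous decoy block lands in one part)
    merged_flags: dict[str, bool] = {}
    for r in refogs:
        ps = parts[r.refog_id]
        merged = bool(ps) and merge_rng.random() < config.p_merge
        merged_flags[r.refog_id] = merged
        if merged:
            j = int(merge_rng.integers(len(ps)))
            aliens.setdefault((r.refog_id, j), []).extend(
                make_decoys(config.merge_block_size, merge_rng)
            )

    ogs: dict[str, list[GeneRecord]] = {}
    plants: list[RefOGPlant] = []
    for r in refogs:
        records = []
        for j, part_members in enumerate(parts[r.refog_id]):
            og_id = f"{r.refog_id}.p{j}"
            extra = aliens.get((r.refog_id, j), [])
            ogs[og_id] = part_members + extra
            records.append(PartRecord(og_id, len(part_members), len(extra)))
        plants.append(
            RefOGPlant(
                refog_id=r.refog_id,
                refog_size=r.size,
                dropped=tuple(dropped[r.refog_id]),
                parts=tuple(records),
                merged=merged_flags[r.refog_id],
            )
        )
    return (
        PredictedOGSet(method_name, ogs),
        TruthLedger(method_name, tuple(plants)),
    )


def expected_comparison_counts(
    plant: RefOGPlant, threshold: FusionThreshold = FusionThreshold()
) -> dict[str, int | bool | None]:
    """Expected per-family scoring outcome from the planted events alone.

    Mirrors the scoring definitions (best overlap with ties broken by fewer
    aliens then og_id; fissions = parts - 1; fusions = parts at or above the
    alien threshold) using only ledger arithmetic — never the predictions.
    """
    if not plant.parts:
        return {
            "matched_og_id": None, "overlap": 0,
            "n_missing": plant.refog_size, "n_erroneous": 0,
            "fissions": 0, "fusions": 0,
            "gene_strict": False, "group_accurate": True,
        }
    matched = min(plant.parts, key=lambda p: (-p.n_members, p.n_aliens, p.og_id))
    n_missing = plant.refog_size - matched.n_members
    n_err = matched.n_aliens
    fissions = len(plant.parts) - 1
    fusions = sum(p.n_aliens >= threshold.min_erroneous_for_fusion for p in plant.parts)
    return {
        "matched_og_id": matched.og_id, "overlap": matched.n_members,
        "n_missing": n_missing, "n_erroneous": n_err,
        "fissions": fissions, "fusions": fusions,
        "gene_strict": n_missing == 0 and n_err == 0,
        "group_accurate": fissions == 0 and fusions == 0,
    }


def expected_summary(
    ledger: TruthLedger, threshold: FusionThreshold = FusionThreshold()
) -> MethodSummary:
    """The six scoring schemes derived purely from the ledger."""
    rows = [expected_comparison_counts(p, threshold) for p in ledger.plants]
    n = len(rows)
    if n == 0:
        raise ValueError("empty ledger")

    def pct(k: int) -> float:
        return 100.0 * k / n

    return MethodSummary(
        method_name=ledger.method_name,
        n_refogs=n,
        gene_strict_accuracy_pct=pct(sum(r["gene_strict"] for r in rows)),
        total_missing=sum(r["n_missing"] for r in rows),
        total_erroneous=sum(r["n_erroneous"] for r in rows),
        pct_refogs_with_missing=pct(sum(r["n_missing"] > 0 for r in rows)),
        pct_refogs_with_erroneous=pct(sum(r["n_erroneous"] > 0 for r in rows)),
        group_accuracy_pct=pct(sum(r["group_accurate"] for r in rows)),
        total_fissions=sum(r["fissions"] for r in rows),
        total_fusions=sum(r["fusions"] for r in rows),
        pct_refogs_fissioned=pct(sum(r["fissions"] > 0 for r in rows)),
        pct_refogs_fused=pct(sum(r["fusions"] > 0 for r in rows)),
    )


def expected_pairwise_identity(p: float) -> float:
    """Closed-form expected pairwise identity of the uniform-substitution model.

    Two rows match at a site when both kept the ancestral residue, prob
    (1-p)^2, or both substituted to the same one of the 19 alternatives,
    prob p^2/19.
    """
    return (1.0 - p) ** 2 + p * p / 19.0


def generate_family_msa(
    n_rows: int,
    length: int,
    per_site_substitution_prob: float,
    seed: int = 0,
    gene_ids: Optional[Sequence[str]] = None,
    disjoint_rows: bool = False,
) -> Alignment:
    """Simulate a gapless family alignment under uniform substitution.

    A random ancestral sequence is drawn, then each row independently
    substitutes each site with the given probability to a uniformly chosen
    different residue.  With ``disjoint_rows`` each row substitutes within
    its own disjoint alphabet slice (needs n_rows <= 10), so at probability
    1 rows share no residues and pairwise identity is exactly 0.
    """
    if n_rows < 2:
        raise ValueError("need n_rows >= 2")
    p = per_site_substitution_prob
    if not (0.0 <= p <= 1.0):
        raise ValueError("substitution probability must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    anc = rng.integers(0, 20, size=length)
    if gene_ids is None:
        gene_ids = [f"seq{i}" for i in range(n_rows)]
    if disjoint_rows:
        width = len(AMINO_ACIDS) // n_rows
        if width < 1:
            raise ValueError("disjoint_rows supports at most 20 rows")
    rows = []
    for i in range(n_rows):
        mutate = rng.random(length) < p
        if disjoint_rows:
            sub = rng.integers(i * width, (i + 1) * width, size=length)
        else:
            sub = (anc + rng.integers(1, 20, size=length)) % 20
        idx = np.where(mutate, sub, anc)
        rows.append((gene_ids[i], "".join(AMINO_ACIDS[j] for j in idx)))
    return Alignment(tuple(rows))
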