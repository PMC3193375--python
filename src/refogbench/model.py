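"""Core data model: genes, species, reference orthologous groups, predictions.

An orthologous group (OG) is the set of genes descended from a single
ancestral gene in the last common ancestor of the species compared.  A
reference orthologous group (RefOG) is a manually curated OG used as ground
truth when scoring automated predictions.  A predicted OG set is one
method's partition of its gene universe into OGs.

Gene identity is the bare identifier after stripping an optional
``species|`` prefix; comparisons are exact string matches with no case
folding, because orthology-database dumps differ only in their prefix
conventions, not in the identifiers themselves.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping, Optional

__all__ = [
    "GeneRecord",
    "ReferenceSpeciesSet",
    "DEFAULT_REFERENCE_SPECIES",
    "Alignment",
    "RefOG",
    "RefOGSet",
    "PredictedOGSet",
    "PartitionViolationError",
    "restrict_genes",
]


class PartitionViolationError(ValueError):
    """A gene was assigned to more than one group of a partition."""


@dataclass(frozen=True, slots=True)
class GeneRecord:
    """A gene with its species tag.

    ``gene_id`` is an opaque identifier, unique within a gene universe.
    ``species_id`` is a short species tag (e.g. ``h_sapiens``).
    """

    gene_id: str
    species_id: str

    def __post_init__(self) -> None:
        if not self.gene_id:
            raise ValueError("gene_id must be non-empty")
        if not self.species_id:
            raise ValueError("species_id must be non-empty")


# The 12 bilaterian reference species shared by the major public orthology
# resources, used as the default analysis universe.
DEFAULT_REFERENCE_SPECIES = (
    "c_elegans",
    "d_melanogaster",
    "c_intestinalis",
    "d_rerio",
    "t_nigroviridis",
    "g_gallus",
    "m_domestica",
    "m_musculus",
    "r_norvegicus",
    "c_familiaris",
    "p_troglodytes",
    "h_sapiens",
)


@dataclass(frozen=True)
class ReferenceSpeciesSet:
    """An ordered, duplicate-free set of species tags defining the universe.

    All benchmarking is confined to these species: genes from any other
    species are removed before scoring, so that methods built on different
    species panels are compared on common ground.
    """

    species_ids: tuple[str, ...] = DEFAULT_REFERENCE_SPECIES

    def __post_init__(self) -> None:
        if not self.species_ids:
            raise ValueError("species set must be non-empty")
        if len(set(self.species_ids)) != len(self.species_ids):
            raise ValueError("duplicate species tags")

    def __contains__(self, species_id: str) -> bool:
        return species_id in set(self.species_ids)

    def __iter__(self) -> Iterator[str]:
        return iter(self.species_ids)

    def __len__(self) -> int:
        return len(self.species_ids)


GAP_CHARS = frozenset("-.")


@dataclass(frozen=True)
class Alignment:
    """A multiple sequence alignment as an ordered list of (gene_id, row).

    Rows are gapped amino-acid strings of equal length; gap characters are
    ``-`` and ``.``.  Columns are 0-based internally and 1-based in reports.
    """

    rows: tuple[tuple[str, str], ...]

    def __post_init__(self) -> None:
        if len(self.rows) < 2:
            raise ValueError("alignment needs at least 2 rows")
        lengths = {len(seq) for _, seq in self.rows}
        if len(lengths) != 1:
            raise ValueError(f"rows of unequal length: {sorted(lengths)}")

    @property
    def n_rows(self) -> int:
        return len(self.rows)

    @property
    def n_columns(self) -> int:
        return len(self.rows[0][1])

    def column(self, i: int) -> tuple[str, ...]:
        return tuple(seq[i] for _, seq in self.rows)


@dataclass(frozen=True)
class RefOG:
    """One curated reference orthologous group."""

    refog_id: str
    members: frozenset[GeneRecord]
    msa: Optional[Alignment] = None
    metadata: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.refog_id:
            raise ValueError("refog_id must be non-empty")
        if not self.members:
            raise ValueError(f"RefOG {self.refog_id!r} has no members")

    @property
    def size(self) -> int:
        return len(self.members)

    @property
    def member_ids(self) -> frozenset[str]:
        return frozenset(g.gene_id for g in self.members)


class RefOGSet:
    """A collection of disjoint RefOGs, ordered by refog_id.

    Membership is disjoint: a gene belongs to at most one RefOG.  Violations
    raise :class:`PartitionViolationError` at construction time.
    """

    def __init__(self, refogs: Iterable[RefOG]):
        ordered = sorted(refogs, key=lambda r: r.refog_id)
        seen: dict[str, str] = {}
        ids = set()
        for r in ordered:
            if r.refog_id in ids:
                raise ValueError(f"duplicate refog_id {r.refog_id!r}")
            ids.add(r.refog_id)
            for g in r.members:
                if g.gene_id in seen:
                    raise PartitionViolationError(
                        f"gene {g.gene_id!r} in RefOGs "
                        f"{seen[g.gene_id]!r} and {r.refog_id!r}"
                    )
                seen[g.gene_id] = r.refog_id
        self._refogs: dict[str, RefOG] = {r.refog_id: r for r in ordered}

    def __iter__(self) -> Iterator[RefOG]:
        return iter(self._refogs.values())

    def __len__(self) -> int:
        return len(self._refogs)

    def __getitem__(self, refog_id: str) -> RefOG:
        return self._refogs[refog_id]

    def __contains__(self, refog_id: str) -> bool:
        return refog_id in self._refogs

    @property
    def refog_ids(self) -> tuple[str, ...]:
        return tuple(self._refogs)

    @property
    def universe(self) -> frozenset[GeneRecord]:
        return frozenset(g for r in self for g in r.members)

    @property
    def n_genes(self) -> int:
        return sum(r.size for r in self)


class PredictedOGSet:
    """One method's partition of its gene universe into predicted OGs.

    Each gene appears in at most one OG; a duplicate assignment is a
    :class:`PartitionViolationError` (it indicates a corrupt input file,
    not a scoreable prediction).
    """

    def __init__(self, method_name: str, ogs: Mapping[str, Iterable[GeneRecord]]):
        if not method_name:
            raise ValueError("method_name must be non-empty")
        self.method_name = method_name
        built: dict[str, frozenset[GeneRecord]] = {}
        seen: dict[str, str] = {}
        for og_id in sorted(ogs):
            members = frozenset(ogs[og_id])
            for g in members:
                if g.gene_id in seen:
                    raise PartitionViolationError(
                        f"gene {g.gene_id!r} in OGs {seen[g.gene_id]!r} "
                        f"and {og_id!r}"
                    )
                seen[g.gene_id] = og_id
            built[og_id] = members
        self.ogs: dict[str, frozenset[GeneRecord]] = built
        self._og_of: dict[str, str] = seen

    def __len__(self) -> int:
        return len(self.ogs)

    def __iter__(self) -> Iterator[str]:
        return iter(self.ogs)

    @property
    def universe(self) -> frozenset[GeneRecord]:
        return frozenset(g for m in self.ogs.values() for g in m)

    def og_of(self, gene_id: str) -> Optional[str]:
        """The OG containing ``gene_id``, or None if the gene is absent."""
        return self._og_of.get(gene_id)

    def gene_to_og(self) -> dict[str, str]:
        return dict(self._og_of)


def restrict_genes(genes: Iterable[GeneRecord], species: ReferenceSpeciesSet) -> frozenset[GeneRecord]:
    allowed = set(species.species_ids)
    return frozenset(g for g in genes if g.species_id in allowed)
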