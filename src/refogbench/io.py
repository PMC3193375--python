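"""Readers and writers for the flat-file dialects used by orthology resources.

Supported prediction dialects:

``orthomcl_groups``
    One OG per line: ``OGID: sp|gene sp|gene ...`` (whitespace-separated).
``gene2group_tsv``
    Two tab-separated columns ``gene_id``, ``og_id``; optional third column
    ``species``.
``og_species_matrix``
    Header row of species tags, first column ``og_id``, cells holding
    comma-separated gene lists for that species.

RefOGs travel as a three-column TSV (``refog_id``, ``gene_id``, ``species``).
All TSVs are tab-delimited UTF-8; lines starting with ``#`` are comments.
Species are derived from a ``species|gene`` prefix when present, otherwise
from an explicit gene-to-species map; genes whose species cannot be derived
are rejected with a logged report of the offending lines — no input line is
ever dropped silently.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Iterable, Mapping, Optional

from Bio import AlignIO

from .model import (
    Alignment,
    GeneRecord,
    PartitionViolationError,
    PredictedOGSet,
    ReferenceSpeciesSet,
    RefOG,
    RefOGSet,
)

logger = logging.getLogger(__name__)

DIALECTS = ("orthomcl_groups", "gene2group_tsv", "og_species_matrix")

__all__ = [
    "DIALECTS",
    "ParseError",
    "parse_predicted_ogs",
    "write_predicted_ogs",
    "parse_refogs",
    "write_refogs",
    "read_alignment",
    "read_species_file",
    "read_domain_counts",
    "restrict_to_reference_species",
]


class ParseError(ValueError):
    """Malformed input; the message cites the offending line(s)."""


def _split_gene_token(token: str, species_map: Optional[Mapping[str, str]]) -> Optional[GeneRecord]:
    """Resolve a ``sp|gene`` token (or bare id + species_map) to a GeneRecord."""
    if "|" in token:
        sp, _, gid = token.partition("|")
        if sp and gid:
            return GeneRecord(gid, sp)
        return None
    if species_map is not None and token in species_map:
        return GeneRecord(token, species_map[token])
    return None


def _data_lines(path: Path) -> Iterable[tuple[int, str]]:
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            yield lineno, line


def parse_predicted_ogs(
    path: str | Path,
    dialect: str,
    method_name: Optional[str] = None,
    species_map: Optional[Mapping[str, str]] = None,
) -> PredictedOGSet:
    """Parse one method's predicted OGs from a flat file.

    Raises :class:`PartitionViolationError` if a gene appears in two OGs and
    :class:`ParseError` for an unknown dialect or structurally broken lines.
    Genes with underivable species are rejected; every rejected line is
    reported through the module logger.
    """
    path = Path(path)
    if dialect not in DIALECTS:
        raise ParseError(f"unknown dialect {dialect!r}; expected one of {DIALECTS}")
    name = method_name or path.stem
    ogs: dict[str, list[GeneRecord]] = {}
    rejected: list[tuple[int, str]] = []

    if dialect == "orthomcl_groups":
        for lineno, line in _data_lines(path):
            head, sep, rest = line.partition(":")
            if not sep or not head.strip():
                raise ParseError(f"{path}:{lineno}: expected 'OGID: gene ...', got {line!r}")
            og_id = head.strip()
            members = ogs.setdefault(og_id, [])
            for token in rest.split():
                gene = _split_gene_token(token, species_map)
                if gene is None:
                    rejected.append((lineno, token))
                else:
                    members.append(gene)
    elif dialect == "gene2group_tsv":
        for lineno, line in _data_lines(path):
            parts = line.split("\t")
            if len(parts) < 2:
                raise ParseError(f"{path}:{lineno}: expected >=2 tab-separated columns")
            gid_token, og_id = parts[0].strip(), parts[1].strip()
            if not og_id:
                raise ParseError(f"{path}:{lineno}: empty og_id")
            if len(parts) >= 3 and parts[2].strip():
                gene: Optional[GeneRecord] = GeneRecord(
                    gid_token.partition("|")[2] or gid_token, parts[2].strip()
                )
            else:
                gene = _split_gene_token(gid_token, species_map)
            if gene is None:
                rejected.append((lineno, gid_token))
            else:
                ogs.setdefault(og_id, []).append(gene)
    else:  # og_species_matrix
        lines = list(_data_lines(path))
        if not lines:
            return PredictedOGSet(name, {})
        header = lines[0][1].split("\t")
        species_cols = [s.strip() for s in header[1:]]
        for lineno, line in lines[1:]:
            cells = line.split("\t")
            og_id = cells[0].strip()
            if not og_id:
                raise ParseError(f"{path}:{lineno}: empty og_id")
            members = ogs.setdefault(og_id, [])
            for sp, cell in zip(species_cols, cells[1:]):
                for gid in filter(None, (g.strip() for g in cell.split(","))):
                    members.append(GeneRecord(gid.partition("|")[2] or gid, sp))

    if rejected:
        detail = "; ".join(f"line {ln}: {tok!r}" for ln, tok in rejected[:20])
        logger.warning(
            "%s: rejected %d gene token(s) with underivable species: %s",
            path, len(rejected), detail,
        )
    return PredictedOGSet(name, {og: members for og, members in ogs.items() if members})


def write_predicted_ogs(ogset: PredictedOGSet, path: str | Path, dialect: str) -> None:
    """Write a predicted OG set in any supported dialect (round-trip safe)."""
    path = Path(path)
    if dialect not in DIALECTS:
        raise ParseError(f"unknown dialect {dialect!r}; expected one of {DIALECTS}")
    with open(path, "w", encoding="utf-8") as fh:
        if dialect == "orthomcl_groups":
            for og_id in sorted(ogset.ogs):
                toks = sorted(f"{g.species_id}|{g.gene_id}" for g in ogset.ogs[og_id])
                fh.write(f"{og_id}: " + " ".join(toks) + "\n")
        elif dialect == "gene2group_tsv":
            fh.write("# gene_id\tog_id\tspecies\n")
            for og_id in sorted(ogset.ogs):
                for g in sorted(ogset.ogs[og_id], key=lambda g: g.gene_id):
                    fh.write(f"{g.gene_id}\t{og_id}\t{g.species_id}\n")
        else:
            species = sorted({g.species_id for m in ogset.ogs.values() for g in m})
            fh.write("og_id\t" + "\t".join(species) + "\n")
            for og_id in sorted(ogset.ogs):
                row = [og_id]
                for sp in species:
                    gids = sorted(g.gene_id for g in ogset.ogs[og_id] if g.species_id == sp)
                    row.append(",".join(gids))
                fh.write("\t".join(row) + "\n")


def parse_refogs(path: str | Path) -> RefOGSet:
    """Parse curated RefOGs from a three-column TSV (refog_id, gene_id, species).

    Exact duplicate rows are deduplicated with a warning; a gene assigned to
    two different RefOGs is a :class:`PartitionViolationError`.
    """
    path = Path(path)
    rows: dict[str, dict[str, GeneRecord]] = {}
    header_skipped = False
    for lineno, line in _data_lines(path):
        parts = [p.strip() for p in line.split("\t")]
        if len(parts) < 3:
            raise ParseError(f"{path}:{lineno}: expected 3 tab-separated columns")
        if not header_skipped and parts[0] == "refog_id":
            header_skipped = True
            continue
        refog_id, gene_id, species = parts[0], parts[1], parts[2]
        if not refog_id:
            raise ParseError(f"{path}:{lineno}: empty refog_id")
        if not gene_id or not species:
            raise ParseError(f"{path}:{lineno}: empty gene_id or species")
        members = rows.setdefault(refog_id, {})
        if gene_id in members:
            logger.warning("%s:%d: duplicate row for gene %r in %r, deduplicated",
                           path, lineno, gene_id, refog_id)
            continue
        members[gene_id] = GeneRecord(gene_id, species)
    return RefOGSet(
        RefOG(refog_id, frozenset(members.values())) for refog_id, members in rows.items()
    )


def write_refogs(refogs: RefOGSet, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("refog_id\tgene_id\tspecies\n")
        for r in refogs:
            for g in sorted(r.members, key=lambda g: g.gene_id):
                fh.write(f"{r.refog_id}\t{g.gene_id}\t{g.species_id}\n")


def read_alignment(path: str | Path) -> Alignment:
    """Read an aligned FASTA file into an :class:`Alignment`."""
    msa = AlignIO.read(str(path), "fasta")
    return Alignment(tuple((rec.id, str(rec.seq)) for rec in msa))


def read_species_file(path: str | Path) -> ReferenceSpeciesSet:
    """One species tag per line."""
    tags = [line for _, line in _data_lines(Path(path))]
    return ReferenceSpeciesSet(tuple(t.strip() for t in tags))


def read_domain_counts(path: str | Path) -> dict[str, int]:
    """TSV ``gene_id<TAB>domain_count`` -> mapping, skipping an optional header."""
    counts: dict[str, int] = {}
    for lineno, line in _data_lines(Path(path)):
        parts = line.split("\t")
        if len(parts) < 2:
            raise ParseError(f"{path}:{lineno}: expected 2 columns")
        gid, val = parts[0].strip(), parts[1].strip()
        if gid == "gene_id":
            continue
        try:
            counts[gid] = int(val)
        except ValueError as exc:
            raise ParseError(f"{path}:{lineno}: bad domain count {val!r}") from exc
    return counts


def restrict_to_reference_species(
    ogset: PredictedOGSet | RefOGSet, species: ReferenceSpeciesSet
):
    """Drop every gene whose species is outside ``species``.

    Groups emptied by the restriction are removed.  Idempotent; counts of
    removed genes are logged.
    """
    allowed = set(species.species_ids)
    if isinstance(ogset, PredictedOGSet):
        kept: dict[str, list[GeneRecord]] = {}
        removed = 0
        for og_id, members in ogset.ogs.items():
            ms = [g for g in members if g.species_id in allowed]
            removed += len(members) - len(ms)
            if ms:
                kept[og_id] = ms
        if removed:
            logger.info("%s: removed %d gene(s) outside the reference species",
                        ogset.method_name, removed)
        return PredictedOGSet(ogset.method_name, kept)
    if isinstance(ogset, RefOGSet):
        out = []
        removed = 0
        for r in ogset:
            ms = frozenset(g for g in r.members if g.species_id in allowed)
            removed += r.size - len(ms)
            if ms:
                out.append(RefOG(r.refog_id, ms, r.msa, r.metadata))
        if removed:
            logger.info("RefOGs: removed %d gene(s) outside the reference species", removed)
        return RefOGSet(out)
    raise TypeError(f"cannot restrict {type(ogset).__name__}")
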