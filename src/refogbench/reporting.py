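"""Byte-stable tabular reports: per-RefOG comparisons, method summaries, rankings.

Column orders are fixed; rows are sorted; no timestamps appear in data
files, so identical inputs yield identical bytes.
"""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import pandas as pd

from .metrics import MethodSummary, RefOGComparison, format_pct

__all__ = [
    "COMPARISON_COLUMNS",
    "SUMMARY_COLUMNS",
    "write_comparisons_tsv",
    "write_error_genes_tsv",
    "write_summary_tsv",
    "read_summary_tsv",
    "write_ranking_tsv",
    "digest_text",
]

COMPARISON_COLUMNS = (
    "refog_id", "matched_og", "n_missing", "n_erroneous",
    "fissions", "fusions", "gene_strict", "group_accurate",
)

SUMMARY_COLUMNS = (
    "method", "n_refogs", "gene_strict_accuracy_pct",
    "total_missing", "total_erroneous",
    "pct_refogs_with_missing", "pct_refogs_with_erroneous",
    "group_accuracy_pct", "total_fissions", "total_fusions",
    "pct_refogs_fissioned", "pct_refogs_fused", "total_errors",
)


def write_comparisons_tsv(comparisons: Sequence[RefOGComparison], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\t".join(COMPARISON_COLUMNS) + "\n")
        for c in sorted(comparisons, key=lambda c: c.refog_id):
            fh.write("\t".join(str(v) for v in (
                c.refog_id, c.matched_og_id or "-", len(c.missing), len(c.erroneous),
                c.fission_events, c.fusion_events,
                int(c.gene_strict), int(c.group_accurate),
            )) + "\n")


def write_error_genes_tsv(comparisons: Sequence[RefOGComparison], path: str | Path) -> None:
    """One row per mispredicted gene: refog_id, gene_id, species, error_type."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("refog_id\tgene_id\tspecies\terror_type\n")
        for c in sorted(comparisons, key=lambda c: c.refog_id):
            for kind, genes in (("missing", c.missing), ("erroneous", c.erroneous)):
                for g in sorted(genes, key=lambda g: g.gene_id):
                    fh.write(f"{c.refog_id}\t{g.gene_id}\t{g.species_id}\t{kind}\n")


def _summary_row(s: MethodSummary) -> list[str]:
    return [
        s.method_name, str(s.n_refogs), format_pct(s.gene_strict_accuracy_pct),
        str(s.total_missing), str(s.total_erroneous),
        format_pct(s.pct_refogs_with_missing), format_pct(s.pct_refogs_with_erroneous),
        format_pct(s.group_accuracy_pct), str(s.total_fissions), str(s.total_fusions),
        format_pct(s.pct_refogs_fissioned), format_pct(s.pct_refogs_fused),
        str(s.total_errors),
    ]


def write_summary_tsv(summaries: Sequence[MethodSummary], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\t".join(SUMMARY_COLUMNS) + "\n")
        for s in sorted(summaries, key=lambda s: s.method_name):
            fh.write("\t".join(_summary_row(s)) + "\n")


def read_summary_tsv(path: str | Path) -> list[MethodSummary]:
    df = pd.read_csv(path, sep="\t")
    out = []
    for r in df.itertuples(index=False):
        out.append(MethodSummary(
            method_name=str(r.method), n_refogs=int(r.n_refogs),
            gene_strict_accuracy_pct=float(r.gene_strict_accuracy_pct),
            total_missing=int(r.total_missing), total_erroneous=int(r.total_erroneous),
            pct_refogs_with_missing=float(r.pct_refogs_with_missing),
            pct_refogs_with_erroneous=float(r.pct_refogs_with_erroneous),
            group_accuracy_pct=float(r.group_accuracy_pct),
            total_fissions=int(r.total_fissions), total_fusions=int(r.total_fusions),
            pct_refogs_fissioned=float(r.pct_refogs_fissioned),
            pct_refogs_fused=float(r.pct_refogs_fused),
        ))
    return out


def write_ranking_tsv(ranked: Sequence[MethodSummary], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("rank\tmethod\ttotal_errors\tgene_strict_accuracy_pct\tgroup_accuracy_pct\n")
        for i, s in enumerate(ranked, start=1):
            fh.write(f"{i}\t{s.method_name}\t{s.total_errors}\t"
                     f"{format_pct(s.gene_strict_accuracy_pct)}\t"
                     f"{format_pct(s.group_accuracy_pct)}\n")


def digest_text(ranked: Sequence[MethodSummary]) -> str:
    """Plain-text digest of a benchmark run, best method first."""
    lines = [f"Benchmark over {ranked[0].n_refogs} reference orthologous groups",
             ""]
    for i, s in enumerate(ranked, start=1):
        lines.append(f"{i}. {s.method_name}: {s.total_errors} total errors")
        lines.append(f"   gene level : strict accuracy {format_pct(s.gene_strict_accuracy_pct)}%, "
                     f"{s.total_missing} missing / {s.total_erroneous} erroneous genes "
                     f"({format_pct(s.pct_refogs_with_missing)}% / "
                     f"{format_pct(s.pct_refogs_with_erroneous)}% of RefOGs affected)")
        lines.append(f"   group level: accuracy {format_pct(s.group_accuracy_pct)}%, "
                     f"{s.total_fissions} fissions / {s.total_fusions} fusions "
                     f"({format_pct(s.pct_refogs_fissioned)}% / "
                     f"{format_pct(s.pct_refogs_fused)}% of RefOGs affected)")
    return "\n".join(lines) + "\n"
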