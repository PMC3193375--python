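"""Independent exhaustive re-computation of the scoring definitions.

Deliberately naive and separate from the engine: works on plain gene-id
sets, enumerates every OG, and applies the written definitions directly.
Used as the oracle in equivalence tests.
"""

from __future__ import annotations


def brute_force_refog_score(
    refog_members: set[str],
    ogs: dict[str, set[str]],
    min_aliens_for_fusion: int = 4,
):
    """Score one RefOG against a gene-id -> OG partition by enumeration."""
    overlaps = {og: len(genes & refog_members) for og, genes in ogs.items()}
    bearing = sorted(og for og, o in overlaps.items() if o > 0)

    # scan in ascending og_id order and switch only on strict improvement:
    # larger overlap, then fewer aliens; the scan order itself realizes the
    # smallest-og_id tie-break
    matched = None
    for og in sorted(ogs):
        if overlaps[og] == 0:
            continue
        if matched is None:
            matched = og
            continue
        key_new = (overlaps[og], -(len(ogs[og]) - overlaps[og]))
        key_best = (overlaps[matched], -(len(ogs[matched]) - overlaps[matched]))
        if key_new > key_best:
            matched = og

    if matched is None:
        missing = set(refog_members)
        erroneous: set[str] = set()
        overlap = 0
    else:
        overlap = overlaps[matched]
        missing = refog_members - ogs[matched]
        erroneous = ogs[matched] - refog_members

    fissions = max(0, len(bearing) - 1)
    fusions = sum(
        1 for og in bearing
        if len(ogs[og]) - overlaps[og] >= min_aliens_for_fusion
    )
    return {
        "matched": matched,
        "overlap": overlap,
        "missing": missing,
        "erroneous": erroneous,
        "bearing": bearing,
        "fissions": fissions,
        "fusions": fusions,
        "gene_strict": not missing and not erroneous,
        "group_accurate": fissions == 0 and fusions == 0,
    }
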