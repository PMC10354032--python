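"""Cross-species ortholog mapping and directional-consistency scoring.

The mobile gene set is mapped to non-redundant orthologs in a
reference species, intersected with a published mobile-transcriptome
list, and each shared ortholog's flow-call directions are compared to
the reference direction.  The confidence level of a target is the
number of (combination, stage) flow calls matching the reference
direction; a target is directionally consistent when the level is >= 1
(a majority-vote mode is available behind a flag).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import pandas as pd


def map_to_nonredundant_orthologs(genes, ortho_map: pd.DataFrame) -> tuple[set, int]:
    """Distinct targets reachable from ``genes`` via the source->target map.

    Returns the target set and the count of unmapped source genes.
    ``ortho_map`` needs columns source_id, target_id; an empty map is
    an error.
    """
    if len(ortho_map) == 0:
        raise ValueError("empty ortholog map")
    genes = set(genes)
    sub = ortho_map[ortho_map["source_id"].isin(genes)]
    targets = set(sub["target_id"])
    n_unmapped = len(genes - set(sub["source_id"]))
    return targets, n_unmapped


def overlap_with_reference(ortholog_set, reference_list) -> tuple[int, float]:
    """Overlap count and percentage against a reference mobile-gene list.

    Percentage = 100 * |intersection| / |ortholog set|, truncated (not
    rounded) to one decimal to match one-decimal reporting conventions.
    """
    ortholog_set = set(ortholog_set)
    if not ortholog_set:
        raise ValueError("empty ortholog set: percentage undefined")
    count = len(ortholog_set & set(reference_list))
    pct = math.floor(1000.0 * count / len(ortholog_set) + 1e-9) / 10.0
    return count, pct


@dataclass(frozen=True)
class ConsistencySummary:
    n_assessed: int
    n_consistent: int
    fraction: float
    n_unassessable: int


def directional_consistency(
    flow_calls: pd.DataFrame,
    ortho_map: pd.DataFrame,
    reference_directions: pd.Series | dict,
    *,
    mode: str = "any",
) -> tuple[pd.DataFrame, ConsistencySummary]:
    """Compare mapped flow-call directions to reference directions.

    Per target gene, the confidence level counts the (combination,
    stage) calls of its source genes whose direction equals the
    reference.  ``mode='any'`` marks a target consistent when the level
    is >= 1; ``mode='majority'`` requires matches to outnumber
    mismatches.  Targets without a reference direction are
    unassessable.
    """
    if mode not in ("any", "majority"):
        raise ValueError("mode must be 'any' or 'majority'")
    ref = pd.Series(reference_directions)
    merged = flow_calls.merge(
        ortho_map[["source_id", "target_id"]].drop_duplicates(),
        left_on="gene_id", right_on="source_id", how="inner")
    rows = []
    n_unassessable = 0
    for target, grp in merged.groupby("target_id", sort=True):
        if target not in ref.index:
            n_unassessable += 1
            rows.append((target, 0, 0, False, "unassessable"))
            continue
        want = ref[target]
        matches = int((grp["direction"] == want).sum())
        mismatches = int((grp["direction"] != want).sum())
        consistent = matches >= 1 if mode == "any" else matches > mismatches
        rows.append((target, matches, mismatches, consistent, "ok"))
    table = pd.DataFrame(rows, columns=["target_id", "confidence_level",
                                        "n_mismatch", "consistent", "status"])
    assessed = table[table["status"] == "ok"]
    n_assessed = len(assessed)
    n_consistent = int(assessed["consistent"].sum())
    summary = ConsistencySummary(
        n_assessed=n_assessed,
        n_consistent=n_consistent,
        fraction=(n_consistent / n_assessed) if n_assessed else float("nan"),
        n_unassessable=n_unassessable,
    )
    return table, summary
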