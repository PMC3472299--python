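"""Venn partitioning of gene sets and multi-timepoint DE consistency."""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

__all__ = ["GeneSet", "venn_partition", "consistent_de_sets"]


@dataclass(frozen=True)
class GeneSet:
    label: str
    members: frozenset[str]

    def __len__(self) -> int:
        return len(self.members)


def venn_partition(
    sets: list[GeneSet],
) -> dict[tuple[bool, ...], tuple[int, frozenset[str]]]:
    """Partition the union of 2-3 gene sets into disjoint Venn regions.

    Region signatures are membership tuples in input order, e.g.
    ``(True, True, False)`` for genes in the first two sets only.  Only
    non-trivial signatures (at least one True) appear; region counts sum
    to the union size and every gene falls in exactly one region.
    """
    if not 2 <= len(sets) <= 3:
        raise ValueError(f"venn_partition supports 2 or 3 sets, got {len(sets)}")
    universe = frozenset().union(*(s.members for s in sets))
    regions: dict[tuple[bool, ...], set[str]] = {}
    for gene in universe:
        sig = tuple(gene in s.members for s in sets)
        regions.setdefault(sig, set()).add(gene)
    return {sig: (len(m), frozenset(m)) for sig, m in regions.items()}


def consistent_de_sets(
    results: dict[str, pd.DataFrame],
) -> tuple[GeneSet, GeneSet]:
    """Genes called up (resp. down) in *every* contrast.

    ``results`` maps contrast labels to classified DE tables (columns
    ``direction`` and ``degenerate``).  Genes flagged degenerate in any
    contrast are excluded — only measurable genes enter the sets.  The
    returned sets are disjoint by construction.
    """
    if not results:
        raise ValueError("no contrasts supplied")
    frames = list(results.values())
    universe = frames[0].index
    for df in frames[1:]:
        if not universe.equals(df.index):
            raise ValueError("contrasts have mismatched gene universes")
    measurable = ~pd.concat([df["degenerate"] for df in frames], axis=1).any(axis=1)
    up = measurable.copy()
    down = measurable.copy()
    for df in frames:
        up &= df["direction"] == 1
        down &= df["direction"] == -1
    return (
        GeneSet("up_all", frozenset(universe[up])),
        GeneSet("down_all", frozenset(universe[down])),
    )
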