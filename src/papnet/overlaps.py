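"""Shared vs set-specific partitioning of GO terms across subnetworks.

Given the per-subnetwork term sets of one namespace, every term in the union
is classified by its occurrence count: terms found in exactly one set are
specific to that set, terms found in two or more are shared. By construction
the specific groups and the shared group tile the union:

    sum_over_sets |specific| + |shared| = |union|.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations


@dataclass(frozen=True)
class TermPartition:
    specific: dict[str, frozenset[str]]  # set label -> its private terms
    shared: frozenset[str]  # terms occurring in >= 2 sets
    unique_total: int  # size of the union
    per_set_counts: dict[str, int]  # input set sizes
    total_with_multiplicity: int  # sum of input set sizes

    @property
    def specific_total(self) -> int:
        return sum(len(s) for s in self.specific.values())

    def __post_init__(self) -> None:
        if self.specific_total + len(self.shared) != self.unique_total:
            raise ValueError("partition does not tile the union")
        for (la, sa), (lb, sb) in combinations(self.specific.items(), 2):
            if sa & sb:
                raise ValueError(f"specific sets {la!r} and {lb!r} overlap")


def partition_terms(named_sets: dict[str, frozenset[str] | set[str]]) -> TermPartition:
    """Classify each term of the union as set-specific or shared."""
    if len(named_sets) < 2:
        raise ValueError("need at least two named sets")
    if any(not str(label) for label in named_sets):
        raise ValueError("empty set label")
    sets = {label: frozenset(s) for label, s in named_sets.items()}
    union = frozenset().union(*sets.values())
    occurrence = {
        t: sum(1 for s in sets.values() if t in s) for t in union
    }
    specific = {
        label: frozenset(t for t in s if occurrence[t] == 1)
        for label, s in sets.items()
    }
    shared = frozenset(t for t in union if occurrence[t] >= 2)
    return TermPartition(
        specific=specific,
        shared=shared,
        unique_total=len(union),
        per_set_counts={label: len(s) for label, s in sets.items()},
        total_with_multiplicity=sum(len(s) for s in sets.values()),
    )


def summarize_partition(partition: TermPartition) -> dict:
    """Count table for one namespace's partition."""
    return {
        "total_with_multiplicity": partition.total_with_multiplicity,
        "unique_total": partition.unique_total,
        "shared": len(partition.shared),
        "specific_total": partition.specific_total,
        "specific_per_set": {
            label: len(s) for label, s in sorted(partition.specific.items())
        },
    }


def intersection_cells(named_sets: dict[str, frozenset[str] | set[str]]) -> dict[str, int]:
    """Optional detailed breakdown: Venn cell -> term count.

    Cells are keyed by the sorted '+'-joined labels of the sets containing
    the terms (only non-empty cells are reported).
    """
    sets = {label: frozenset(s) for label, s in named_sets.items()}
    union = frozenset().union(*sets.values())
    cells: dict[str, int] = {}
    for t in union:
        key = "+".join(sorted(str(label) for label, s in sets.items() if t in s))
        cells[key] = cells.get(key, 0) + 1
    return dict(sorted(cells.items()))
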