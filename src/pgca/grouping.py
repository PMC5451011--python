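"""Local protein-group construction with optional refinement.

Within one run, a reported protein group is turned into a *local group*: the
ordered set of its accession numbers, top protein first.  Three modes control
how much of the group is retained for cross-run linking:

``all``
    the full accession list of the group (the featured approach; links the
    raw groups exactly as the processing software reported them);
``top_gene``
    the top entry plus every member sharing at least one gene symbol with it
    (and, when a rank column is available, the same rank as the top entry);
``top_identifier``
    only the top protein — every local group becomes a singleton, so linking
    degenerates to matching top accessions across runs.

Refined groups are always subsets of the ``all`` groups, and the number of
groups per run is identical in all modes.
"""

from __future__ import annotations

import enum
import warnings
from dataclasses import dataclass, field

from .io import ProteinEntry, ProteinSummary

__all__ = ["GroupingMode", "LocalGroup", "LocalGroupSet", "create_local_groups"]

#: Tolerance when comparing floating-point ranks with the top entry's rank.
RANK_TOLERANCE = 1e-9


class GroupingMode(str, enum.Enum):
    """How much of each reported group is retained for linking."""

    ALL = "all"
    TOP_GENE = "top_gene"
    TOP_IDENTIFIER = "top_identifier"

    @classmethod
    def coerce(cls, value: "GroupingMode | str") -> "GroupingMode":
        if isinstance(value, cls):
            return value
        return cls(str(value).replace("-", "_").lower())


@dataclass
class LocalGroup:
    """One protein group of one run, as a list of accessions (top first)."""

    accessions: list[str]
    top_accession: str
    run_id: str
    source_group_id: int

    def __post_init__(self) -> None:
        if not self.accessions:
            raise ValueError("a local group cannot be empty")
        if self.accessions[0] != self.top_accession:
            raise ValueError("top_accession must be the first element")

    def as_set(self) -> frozenset[str]:
        return frozenset(self.accessions)

    def __len__(self) -> int:
        return len(self.accessions)


@dataclass
class LocalGroupSet:
    """All local groups of one run under one grouping mode."""

    run_id: str
    mode: GroupingMode
    groups: list[LocalGroup] = field(default_factory=list)

    def as_sets(self) -> list[frozenset[str]]:
        return [g.as_set() for g in self.groups]

    def __len__(self) -> int:
        return len(self.groups)

    def __iter__(self):
        return iter(self.groups)


def _ranks_equal(a: float | None, b: float | None) -> bool:
    # absent ranks are treated as equal so gene matching alone decides
    if a is None or b is None:
        return True
    if float(a).is_integer() and float(b).is_integer():
        return a == b
    return abs(a - b) <= RANK_TOLERANCE


def _genes_overlap(a: list[str], b: list[str]) -> bool:
    return bool({g.lower() for g in a} & {g.lower() for g in b})


def _refine_block(block: list[ProteinEntry], mode: GroupingMode) -> list[ProteinEntry]:
    tops = [e for e in block if e.is_top]
    top = tops[0] if tops else block[0]
    if mode is GroupingMode.TOP_IDENTIFIER:
        return [top]
    if mode is GroupingMode.TOP_GENE:
        if not top.genes:
            # nothing to match against: degrade to the singleton top
            return [top]
        kept = [top]
        for entry in block:
            if entry is top:
                continue
            if _genes_overlap(entry.genes, top.genes) and _ranks_equal(entry.rank, top.rank):
                kept.append(entry)
        return kept
    members = [top] + [e for e in block if e is not top]
    return members


def create_local_groups(
    summary: ProteinSummary, mode: GroupingMode | str = GroupingMode.ALL
) -> LocalGroupSet:
    """Build the local groups of a run under the chosen mode.

    Every reported group produces exactly one local group in every mode; the
    modes differ only in which members are retained.  Duplicate accessions
    inside one reported group are dropped (first occurrence wins) since group
    membership is set-valued downstream.
    """
    mode = GroupingMode.coerce(mode)
    groups: list[LocalGroup] = []
    for block in summary.groups():
        members = _refine_block(block, mode)
        accessions: list[str] = []
        for entry in members:
            if entry.accession in accessions:
                warnings.warn(
                    f"duplicate accession {entry.accession!r} in group "
                    f"{block[0].group_id} of run {summary.run_id!r}; keeping the first",
                    stacklevel=2,
                )
                continue
            accessions.append(entry.accession)
        groups.append(
            LocalGroup(
                accessions=accessions,
                top_accession=accessions[0],
                run_id=summary.run_id,
                source_group_id=block[0].group_id,
            )
        )
    return LocalGroupSet(run_id=summary.run_id, mode=mode, groups=groups)
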