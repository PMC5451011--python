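"""Global protein groups and the incremental merge into a dictionary.

A *global group* is the union of all local groups that are transitively
connected by shared accessions across every processed run.  The dictionary
holds the current set of global groups — pairwise disjoint by construction —
and assigns each a stable positive integer *protein group code* (PGC).

Merging a run's local groups into the dictionary amounts to computing the
connected components of the overlap graph over (existing global groups ∪
incoming local groups), where two groups are linked iff they share at least
one accession.  The implementation uses a union-find over accessions; the
result is by contract identical to the repeat-until-fixpoint merge and is
cross-checked against an independent connected-components oracle in the test
suite.

Code stability across incremental updates:

* a group that is unchanged or merely extended keeps its PGC;
* when several existing groups merge, the smallest (oldest) PGC survives;
* brand-new groups take the next counter value; codes are never reused.

Group *composition* is invariant to the order in which runs are processed
and to splitting the processing into increments; code *values* are not.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import networkx as nx

from .grouping import GroupingMode, LocalGroupSet, create_local_groups
from .io import ProteinSummary

__all__ = [
    "GlobalGroup",
    "Dictionary",
    "MappingChange",
    "DictionaryFormatError",
    "update_dictionary",
    "build_dictionary",
    "is_connected",
    "serialize_dictionary",
    "load_dictionary",
]

logger = logging.getLogger(__name__)


class DictionaryFormatError(ValueError):
    """A serialized dictionary file violates the two-column contract."""


@dataclass(frozen=True)
class GlobalGroup:
    """A coded global protein group: a PGC and its accession set."""

    pgc: int
    accessions: frozenset[str]

    def __post_init__(self) -> None:
        if not self.accessions:
            raise ValueError("a global group cannot be empty")
        if self.pgc <= 0:
            raise ValueError("PGCs are positive integers")

    def __len__(self) -> int:
        return len(self.accessions)


@dataclass
class MappingChange:
    """What one update step did to the mapping.

    ``mergers`` counts consumed pre-existing groups: a merge of g existing
    groups into one contributes g − 1, so that, starting from empty,
    Σ new_groups − Σ mergers equals the final group count exactly.
    """

    run_id: str
    new_accessions: int = 0
    new_groups: int = 0
    mergers: int = 0


class Dictionary:
    """The mapping from accession numbers to protein group codes.

    Mutable; :meth:`update` merges one run's local groups in place and logs a
    :class:`MappingChange`.  Use the module-level :func:`update_dictionary`
    for the pure-function variant.
    """

    def __init__(
        self,
        groups: Iterable[GlobalGroup] = (),
        next_pgc: int | None = None,
    ) -> None:
        self._groups: dict[int, set[str]] = {}
        self._acc2pgc: dict[str, int] = {}
        self.history: list[MappingChange] = []
        for group in groups:
            if group.pgc in self._groups:
                raise ValueError(f"duplicate PGC {group.pgc}")
            for acc in group.accessions:
                if acc in self._acc2pgc:
                    raise ValueError(
                        f"accession {acc!r} appears in two global groups "
                        f"({self._acc2pgc[acc]} and {group.pgc})"
                    )
                self._acc2pgc[acc] = group.pgc
            self._groups[group.pgc] = set(group.accessions)
        floor = max(self._groups, default=0) + 1
        self.next_pgc = floor if next_pgc is None else max(next_pgc, floor)

    # -- views ------------------------------------------------------------

    @property
    def groups(self) -> list[GlobalGroup]:
        return [
            GlobalGroup(pgc, frozenset(accs))
            for pgc, accs in sorted(self._groups.items())
        ]

    def group_sets(self) -> set[frozenset[str]]:
        """Group compositions only (the order-invariant part of the mapping)."""
        return {frozenset(accs) for accs in self._groups.values()}

    def pgc_of(self, accession: str) -> int:
        """The code of the global group containing *accession* (KeyError if absent)."""
        return self._acc2pgc[accession]

    def __contains__(self, accession: str) -> bool:
        return accession in self._acc2pgc

    def __len__(self) -> int:
        return len(self._groups)

    @property
    def n_accessions(self) -> int:
        return len(self._acc2pgc)

    def copy(self) -> "Dictionary":
        clone = Dictionary(self.groups, next_pgc=self.next_pgc)
        clone.history = list(self.history)
        return clone

    # -- the merge --------------------------------------------------------

    def update(self, local_groups: LocalGroupSet | Iterable) -> MappingChange:
        """Merge one run's local groups into the dictionary.

        The resulting groups are exactly the connected components of
        (existing global groups ∪ incoming local groups) under transitive
        overlap.  Returns the change record, which is also appended to
        :attr:`history`.
        """
        run_id = getattr(local_groups, "run_id", "")
        incoming: list[frozenset[str]] = []
        for group in local_groups:
            accs = frozenset(getattr(group, "as_set", lambda g=group: frozenset(g))())
            if not accs:
                continue
            incoming.append(accs)

        parent: dict[str, str] = {}

        def find(x: str) -> str:
            root = x
            while parent[root] != root:
                root = parent[root]
            while parent[x] != root:  # path compression
                parent[x], x = root, parent[x]
            return root

        def union(a: str, b: str) -> None:
            ra, rb = find(a), find(b)
            if ra != rb:
                parent[rb] = ra

        def add_set(accs: Iterable[str]) -> None:
            first = None
            for acc in accs:
                if acc not in parent:
                    parent[acc] = acc
                if first is None:
                    first = acc
                else:
                    union(first, acc)

        for accs in self._groups.values():
            add_set(accs)
        new_accessions = 0
        for accs in incoming:
            new_accessions += sum(1 for a in accs if a not in self._acc2pgc and a not in parent)
            add_set(accs)

        components: dict[str, set[str]] = {}
        for acc in parent:
            components.setdefault(find(acc), set()).add(acc)

        change = MappingChange(run_id=run_id, new_accessions=new_accessions)
        new_groups: dict[int, set[str]] = {}
        for members in components.values():
            old_pgcs = sorted({self._acc2pgc[a] for a in members if a in self._acc2pgc})
            if old_pgcs:
                pgc = old_pgcs[0]
                if len(old_pgcs) > 1:
                    change.mergers += len(old_pgcs) - 1
                    logger.warning(
                        "run %r merges global groups %s into PGC %d",
                        run_id,
                        old_pgcs,
                        pgc,
                    )
            else:
                pgc = self.next_pgc
                self.next_pgc += 1
                change.new_groups += 1
            new_groups[pgc] = members

        self._groups = new_groups
        self._acc2pgc = {a: pgc for pgc, accs in new_groups.items() for a in accs}
        self.history.append(change)
        return change


def update_dictionary(
    dictionary: Dictionary, local_groups: LocalGroupSet
) -> Dictionary:
    """Pure variant of :meth:`Dictionary.update`: returns an updated copy."""
    updated = dictionary.copy()
    updated.update(local_groups)
    return updated


def build_dictionary(
    summaries: Sequence[ProteinSummary],
    mode: GroupingMode | str = GroupingMode.ALL,
) -> Dictionary:
    """Fold every run's local groups into a dictionary, starting from empty.

    Equivalent to repeatedly updating an empty dictionary with
    ``create_local_groups(summary, mode)`` in the given order; the group
    compositions of the result do not depend on that order.
    """
    if not summaries:
        raise ValueError("at least one protein summary is required")
    mode = GroupingMode.coerce(mode)
    dictionary = Dictionary()
    for summary in summaries:
        dictionary.update(create_local_groups(summary, mode))
    return dictionary


def is_connected(sets: Iterable[Iterable[str]]) -> bool:
    """Whether a collection of accession sets is transitively overlap-connected.

    True iff the overlap graph (one node per set, edge iff two sets share an
    accession) forms a single connected component, i.e. any two sets are
    joined either directly or through a chain of connector sets.  An empty
    collection is not connected by convention.  Serves as the connectivity
    oracle in property tests.
    """
    materialized = [frozenset(s) for s in sets]
    if not materialized:
        return False
    if any(not s for s in materialized):
        raise ValueError("all sets must be non-empty")
    graph = nx.Graph()
    graph.add_nodes_from(range(len(materialized)))
    for i in range(len(materialized)):
        for j in range(i + 1, len(materialized)):
            if materialized[i] & materialized[j]:
                graph.add_edge(i, j)
    return nx.is_connected(graph)


def serialize_dictionary(dictionary: Dictionary, path: str | Path) -> None:
    """Write the dictionary as diff-friendly two-column text.

    One row per accession, header ``PGC<TAB>Accession``, sorted by
    (PGC, accession).  A leading comment line records the code counter so a
    round trip is lossless even when the counter is ahead of max(PGC)+1.
    """
    with open(path, "w") as fh:
        fh.write(f"# next_pgc={dictionary.next_pgc}\n")
        fh.write("PGC\tAccession\n")
        for group in dictionary.groups:
            for acc in sorted(group.accessions):
                fh.write(f"{group.pgc}\t{acc}\n")


def load_dictionary(path: str | Path) -> Dictionary:
    """Read a dictionary written by :func:`serialize_dictionary`.

    Raises :class:`DictionaryFormatError` on malformed rows or when an
    accession is listed under two codes (a disjointness violation).
    """
    path = Path(path)
    next_pgc: int | None = None
    groups: dict[int, set[str]] = {}
    seen: dict[str, int] = {}
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh]
    body = []
    for line in lines:
        if line.startswith("#"):
            if "next_pgc=" in line:
                try:
                    next_pgc = int(line.split("next_pgc=", 1)[1])
                except ValueError:
                    raise DictionaryFormatError(f"{path}: bad counter line {line!r}")
            continue
        if line.strip():
            body.append(line)
    if not body:
        return Dictionary(next_pgc=next_pgc)
    if body[0].split("\t")[:2] != ["PGC", "Accession"]:
        raise DictionaryFormatError(f"{path}: expected header 'PGC\\tAccession'")
    for lineno, line in enumerate(body[1:], start=2):
        parts = line.split("\t")
        if len(parts) != 2 or not parts[1]:
            raise DictionaryFormatError(f"{path}:{lineno}: expected 'PGC<TAB>Accession'")
        try:
            pgc = int(parts[0])
        except ValueError:
            raise DictionaryFormatError(f"{path}:{lineno}: non-integer PGC {parts[0]!r}")
        acc = parts[1]
        if acc in seen and seen[acc] != pgc:
            raise DictionaryFormatError(
                f"{path}: accession {acc!r} listed under PGCs {seen[acc]} and {pgc}"
            )
        seen[acc] = pgc
        groups.setdefault(pgc, set()).add(acc)
    return Dictionary(
        (GlobalGroup(pgc, frozenset(accs)) for pgc, accs in groups.items()),
        next_pgc=next_pgc,
    )
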