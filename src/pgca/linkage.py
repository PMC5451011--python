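"""Cross-run analytics on coded summaries and dictionary histories.

These are the diagnostics a study runs after linking: which codes appear in
which runs (presence matrix), how many codes survive every run as runs
accumulate (common-code curve), how the mapping changed per processed file
(new identities / new groups / mergers), how group sizes distribute, and
Dice-coefficient comparisons of local against global groups and of top
proteins against the pool of tops representing a group.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import pandas as pd

from .coding import SENTINEL_PGC, code_protein_groups
from .dictionary import Dictionary, MappingChange, build_dictionary
from .grouping import GroupingMode
from .io import CodedSummary, ProteinSummary

__all__ = [
    "PresenceMatrix",
    "MappingChangeLog",
    "dice",
    "presence_matrix",
    "consistently_detected",
    "common_pgc_curve",
    "change_log",
    "group_size_histogram",
    "dice_vs_dictionary",
    "dice_top_proteins",
    "order_by_group_count",
    "SIZE_BINS",
]

#: Group-size bins conventionally reported: 1, 2, 3–5, >5.
SIZE_BINS = ("1", "2", "3-5", ">5")


def dice(a: Iterable[str], b: Iterable[str]) -> float:
    """Dice set-similarity coefficient, 2|A∩B| / (|A|+|B|).

    0 iff the sets are disjoint, 1 iff they are equal; symmetric; blind to
    element order.  Undefined (ValueError) when both sets are empty.
    """
    sa, sb = set(a), set(b)
    if not sa and not sb:
        raise ValueError("Dice coefficient is undefined for two empty sets")
    return 2.0 * len(sa & sb) / (len(sa) + len(sb))


@dataclass
class PresenceMatrix:
    """PGC × run indicator table: which codes were detected in which runs."""

    frame: pd.DataFrame  # bool, index = PGC, columns = run_id

    @property
    def pgcs(self) -> list[int]:
        return list(self.frame.index)

    @property
    def runs(self) -> list[str]:
        return list(self.frame.columns)

    def detection_fraction(self) -> pd.Series:
        """Fraction of runs in which each code was detected."""
        if self.frame.empty:
            return pd.Series(dtype=float)
        return self.frame.mean(axis=1)


@dataclass
class MappingChangeLog:
    """Per-file change records from an incremental dictionary build."""

    changes: list[MappingChange] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "run_id": [c.run_id for c in self.changes],
                "new_accessions": [c.new_accessions for c in self.changes],
                "new_groups": [c.new_groups for c in self.changes],
                "mergers": [c.mergers for c in self.changes],
            }
        )

    def __len__(self) -> int:
        return len(self.changes)

    def __iter__(self):
        return iter(self.changes)


def presence_matrix(coded: Sequence[CodedSummary]) -> PresenceMatrix:
    """Build the PGC × run presence table from coded runs.

    All runs must have been coded with the same dictionary (the codes carry
    no dictionary identity, so this is the caller's contract).  The sentinel
    code 0 is excluded; a code appears iff present in at least one run.
    """
    run_ids = [c.run_id for c in coded]
    per_run = {c.run_id: c.pgcs() for c in coded}
    all_pgcs = sorted(set().union(*per_run.values())) if per_run else []
    data = {rid: [p in per_run[rid] for p in all_pgcs] for rid in run_ids}
    frame = pd.DataFrame(data, index=all_pgcs, dtype=bool)
    return PresenceMatrix(frame=frame)


def consistently_detected(
    matrix: PresenceMatrix, threshold: float = 1.0
) -> list[int]:
    """Codes detected in a sufficient fraction of the runs.

    ``threshold=1.0`` (the default) keeps codes present in every run.  A
    smaller threshold keeps codes with detection fraction strictly above it,
    matching the "identified in more than 75% of runs" convention used when
    some dropout is tolerated.
    """
    frac = matrix.detection_fraction()
    if threshold >= 1.0:
        kept = frac[frac >= 1.0]
    else:
        kept = frac[frac > threshold]
    return sorted(kept.index)


def common_pgc_curve(coded: Sequence[CodedSummary]) -> list[int]:
    """Number of codes present in all of the first k runs, for each k.

    The runs are taken in the given order (conventionally decreasing group
    count, see :func:`order_by_group_count`); the curve is non-increasing.
    """
    curve: list[int] = []
    common: set[int] | None = None
    for summary in coded:
        pgcs = summary.pgcs()
        common = set(pgcs) if common is None else common & pgcs
        curve.append(len(common))
    return curve


def order_by_group_count(summaries: Sequence[ProteinSummary]) -> list[ProteinSummary]:
    """Order runs by decreasing number of protein groups (ties by run id)."""
    return sorted(summaries, key=lambda s: (-s.n_groups, s.run_id))


def change_log(
    summaries: Sequence[ProteinSummary],
    mode: GroupingMode | str = GroupingMode.ALL,
) -> MappingChangeLog:
    """Stepwise mapping-change diagnostics for processing runs in order.

    Per step: accessions never seen before, newly created global groups, and
    mergers of pre-existing groups (a merge of g groups counts g − 1).  The
    conservation identity Σ new_groups − Σ mergers = final group count holds
    exactly.
    """
    dictionary = build_dictionary(summaries, mode)
    return MappingChangeLog(changes=list(dictionary.history))


def _sizes(obj) -> list[int]:
    if isinstance(obj, Dictionary):
        return [len(g) for g in obj.groups]
    return [len(g) for g in obj]


def group_size_histogram(obj) -> dict[str, int]:
    """Group counts per size bin {1, 2, 3–5, >5}; bins sum to the group count."""
    counts = dict.fromkeys(SIZE_BINS, 0)
    for size in _sizes(obj):
        if size == 1:
            counts["1"] += 1
        elif size == 2:
            counts["2"] += 1
        elif size <= 5:
            counts["3-5"] += 1
        else:
            counts[">5"] += 1
    return counts


def _local_groups_by_pgc(
    coded: CodedSummary,
) -> dict[int, frozenset[str]]:
    """Map each PGC present in the run to the union of its local members there."""
    members: dict[int, set[str]] = {}
    for pgc, entry in coded.entries:
        if pgc == SENTINEL_PGC:
            continue
        members.setdefault(pgc, set()).add(entry.accession)
    return {pgc: frozenset(accs) for pgc, accs in members.items()}


def dice_vs_dictionary(
    coded: Sequence[CodedSummary], dictionary: Dictionary
) -> pd.DataFrame:
    """Run × global-group table of Dice(local group, global group).

    A cell is 1 when the run identified exactly the global group, 0 when the
    code is absent from the run, and in between when only part of the global
    group was seen.  Local groups and dictionary must come from the same
    all-mode build for the child/parent comparison to be meaningful.
    """
    pgcs = [g.pgc for g in dictionary.groups]
    globals_ = {g.pgc: set(g.accessions) for g in dictionary.groups}
    rows = {}
    for summary in coded:
        local = _local_groups_by_pgc(summary)
        rows[summary.run_id] = [
            dice(local[p], globals_[p]) if p in local else 0.0 for p in pgcs
        ]
    return pd.DataFrame.from_dict(rows, orient="index", columns=pgcs)


def _top_by_pgc(coded: CodedSummary) -> dict[int, str]:
    tops: dict[int, str] = {}
    for pgc, entry in coded.entries:
        if pgc == SENTINEL_PGC or not entry.is_top:
            continue
        tops.setdefault(pgc, entry.accession)
    return tops


def dice_top_proteins(
    coded: Sequence[CodedSummary], dictionary: Dictionary
) -> pd.DataFrame:
    """Run × global-group table of Dice(run's top, pool of tops for the group).

    For each global group the parent set is the union of the top proteins
    representing it across all runs.  A cell of 1 means a unique top
    represents the group everywhere; smaller values mean the representative
    changed between runs; 0 means the group was not identified in that run.
    """
    pgcs = [g.pgc for g in dictionary.groups]
    tops_per_run = {c.run_id: _top_by_pgc(c) for c in coded}
    pool: dict[int, set[str]] = {p: set() for p in pgcs}
    for tops in tops_per_run.values():
        for pgc, top in tops.items():
            if pgc in pool:
                pool[pgc].add(top)
    rows = {}
    for summary in coded:
        tops = tops_per_run[summary.run_id]
        rows[summary.run_id] = [
            dice({tops[p]}, pool[p]) if p in tops else 0.0 for p in pgcs
        ]
    return pd.DataFrame.from_dict(rows, orient="index", columns=pgcs)


def _refined_summary(summary: ProteinSummary, mode: GroupingMode) -> ProteinSummary:
    """Restrict a summary to the entries its refined local groups retain."""
    from .grouping import create_local_groups

    kept_per_group = {
        g.source_group_id: set(g.accessions)
        for g in create_local_groups(summary, mode)
    }
    entries = [
        e
        for e in summary.entries
        if e.accession in kept_per_group.get(e.group_id, ())
    ]
    return ProteinSummary(
        run_id=summary.run_id,
        entries=entries,
        dialect=summary.dialect,
        columns=summary.columns,
    )


def code_runs(
    summaries: Sequence[ProteinSummary],
    dictionary: Dictionary,
    mode: GroupingMode | str = GroupingMode.ALL,
    allow_missing: bool | None = None,
) -> list[CodedSummary]:
    """Code every run against one dictionary for cross-run analyses.

    Under the refined modes only the entries retained by the refinement are
    coded (a code counts as identified in a run iff the run's *refined*
    group maps to it, mirroring how the refined approaches keep only part of
    each group); pruned accessions may be absent from a refined dictionary,
    so missing accessions are tolerated by default in those modes.
    """
    mode = GroupingMode.coerce(mode)
    if allow_missing is None:
        allow_missing = mode is not GroupingMode.ALL
    coded = []
    for summary in summaries:
        if mode is not GroupingMode.ALL:
            summary = _refined_summary(summary, mode)
        coded.append(
            code_protein_groups(dictionary, summary, allow_missing=allow_missing)
        )
    return coded
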