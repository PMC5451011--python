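"""Translate protein summaries into coded summaries via a dictionary.

Coding is a pure per-accession lookup: each entry receives the PGC of the
global group its accession belongs to.  It keys on the accession, not the
local group id, so a local group whose members ended up in different global
groups (possible under the refined linking modes) is representable; a
consistency check reports such groups.
"""

from __future__ import annotations

import warnings

from .dictionary import Dictionary
from .io import CodedSummary, ProteinSummary

__all__ = ["MissingAccessionError", "code_protein_groups", "groups_with_multiple_pgcs"]

#: Code given to entries absent from the dictionary when they are tolerated.
SENTINEL_PGC = 0


class MissingAccessionError(KeyError):
    """An accession of the summary has no entry in the dictionary."""

    def __init__(self, accession: str, run_id: str):
        super().__init__(accession)
        self.accession = accession
        self.run_id = run_id

    def __str__(self) -> str:
        return (
            f"accession {self.accession!r} (run {self.run_id!r}) is not in the "
            "dictionary; rebuild the dictionary including this run or pass "
            "allow_missing=True to code it with the sentinel 0"
        )


def code_protein_groups(
    dictionary: Dictionary,
    summary: ProteinSummary,
    allow_missing: bool = False,
) -> CodedSummary:
    """Attach a PGC to every entry of *summary*.

    By default an accession absent from the dictionary is an error, matching
    the contract that the dictionary was built from a file set including (or
    superseding) this run.  With ``allow_missing`` such entries receive the
    sentinel code 0 and a single warning reports the per-file count — this is
    the normal situation under the top-gene / top-identifier modes, where
    pruned members never enter the dictionary.
    """
    coded: list[tuple[int, object]] = []
    n_missing = 0
    for entry in summary.entries:
        if entry.accession in dictionary:
            coded.append((dictionary.pgc_of(entry.accession), entry))
        elif allow_missing:
            coded.append((SENTINEL_PGC, entry))
            n_missing += 1
        else:
            raise MissingAccessionError(entry.accession, summary.run_id)
    if n_missing:
        warnings.warn(
            f"run {summary.run_id!r}: {n_missing} of {len(summary.entries)} "
            "entries are not in the dictionary and were coded 0",
            stacklevel=2,
        )
    return CodedSummary(
        run_id=summary.run_id,
        entries=coded,
        dialect=summary.dialect,
        columns=summary.columns,
    )


def groups_with_multiple_pgcs(coded: CodedSummary) -> dict[int, set[int]]:
    """Source groups whose members map to more than one PGC.

    Under an all-mode dictionary this is empty by construction (members of
    one local group are connected, hence share a global group); under refined
    modes it flags groups split across dictionary entries.  Sentinel-coded
    entries are ignored.
    """
    by_group: dict[int, set[int]] = {}
    for pgc, entry in coded.entries:
        if pgc == SENTINEL_PGC:
            continue
        by_group.setdefault(entry.group_id, set()).add(pgc)
    return {gid: pgcs for gid, pgcs in by_group.items() if len(pgcs) > 1}
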