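"""Reading and writing protein-summary files.

MS/MS processing software (ProteinPilot, Proteome Discoverer, ...) exports one
tab-delimited *protein summary* per experimental run.  Each row is one protein
identification; rows sharing a group identifier form a *protein group* — the
set of all plausible accessions matching a common set of identified peptides.
One member of each group is the *top* (master) protein, the identifier the
software selected to represent the group and carry its quantitative values.

Different tools name their columns differently, so parsing goes through a
:class:`Dialect` that maps logical fields (group id, accession, protein name,
gene symbols, master-protein flag, rank) onto concrete column names.  Two
presets are shipped (``proteinpilot`` and ``discoverer``); arbitrary mappings
can be supplied directly or loaded from a YAML config file.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Mapping

import pandas as pd
import yaml

__all__ = [
    "Dialect",
    "DIALECTS",
    "ProteinEntry",
    "ProteinSummary",
    "CodedSummary",
    "SummaryFormatError",
    "read_protein_summary",
    "read_coded_summary",
    "write_coded_summary",
    "load_dialect_config",
    "split_genes",
]

#: Characters that may separate multiple gene symbols in one cell.
GENE_SEPARATORS = (";", ",", "|")

#: Cell values recognised as a truthy master-protein flag.
TOP_FLAG_VALUES = frozenset({"master protein", "ismasterprotein", "true", "x", "1", "yes"})


class SummaryFormatError(ValueError):
    """A protein-summary file violates the expected tabular format."""


@dataclass(frozen=True)
class Dialect:
    """Column mapping from a software export onto the logical summary fields.

    ``top_col`` is optional: when absent the first row of each group (file
    order) is taken as the top protein, which is the ProteinPilot convention.
    ``rank_col`` is optional and only influences the top-gene refinement.
    """

    name: str
    group_col: str
    accession_col: str
    name_col: str | None = None
    gene_col: str | None = None
    top_col: str | None = None
    rank_col: str | None = None

    def required_columns(self) -> tuple[str, ...]:
        return (self.group_col, self.accession_col)


DIALECTS: dict[str, Dialect] = {
    "proteinpilot": Dialect(
        name="proteinpilot",
        group_col="N",
        accession_col="Accession",
        name_col="Name",
        gene_col="Gene",
    ),
    "discoverer": Dialect(
        name="discoverer",
        group_col="Group",
        accession_col="Accession",
        name_col="Description",
        gene_col="Gene Symbol",
        top_col="Master",
    ),
}


def split_genes(cell: str | None) -> list[str]:
    """Split a gene-symbol cell into a list of symbols.

    Splits on ";", "," and "|", strips whitespace, drops empties.  A missing
    or blank cell yields an empty list (never a sentinel string).
    """
    if cell is None:
        return []
    text = str(cell)
    for sep in GENE_SEPARATORS[1:]:
        text = text.replace(sep, GENE_SEPARATORS[0])
    return [tok.strip() for tok in text.split(GENE_SEPARATORS[0]) if tok.strip()]


@dataclass
class ProteinEntry:
    """One row of a protein summary.

    Parameters
    ----------
    group_id
        Within-run protein-group identifier (column ``N`` in ProteinPilot
        exports).  Only meaningful inside one run.
    accession
        Database identifier of the protein, possibly carrying a version
        suffix (``IPI00215894.1``).  Compared as an exact, case-sensitive
        string throughout; version suffixes are never stripped.
    protein_name
        Human-readable protein name.
    genes
        Gene symbols matching the protein; possibly empty, possibly several.
    is_top
        True iff this entry is the group's top (master) protein.
    rank
        Optional within-group rank/score used by the top-gene refinement.
    rest
        All remaining columns, preserved verbatim and never interpreted.
    """

    group_id: int
    accession: str
    protein_name: str = ""
    genes: list[str] = field(default_factory=list)
    is_top: bool = False
    rank: float | None = None
    rest: dict[str, str] = field(default_factory=dict)
    # original cell text of the mapped columns, kept so writing a coded
    # summary reproduces the input bytes exactly
    raw: dict[str, str] = field(default_factory=dict, compare=False, repr=False)

    def __post_init__(self) -> None:
        if not self.accession:
            raise ValueError("accession must be non-empty")


@dataclass
class ProteinSummary:
    """A parsed per-run protein summary: an ordered list of entries.

    Entry order preserves file order, which matters because the first entry
    of a group is its top protein under the ProteinPilot convention and
    because ranks are positional.
    """

    run_id: str
    entries: list[ProteinEntry]
    dialect: str = "proteinpilot"
    columns: list[str] = field(default_factory=list)

    def groups(self) -> Iterator[list[ProteinEntry]]:
        """Yield the maximal consecutive blocks of rows sharing a group id."""
        block: list[ProteinEntry] = []
        for entry in self.entries:
            if block and entry.group_id != block[-1].group_id:
                yield block
                block = []
            block.append(entry)
        if block:
            yield block

    @property
    def n_groups(self) -> int:
        return sum(1 for _ in self.groups())

    def accessions(self) -> set[str]:
        return {e.accession for e in self.entries}


@dataclass
class CodedSummary:
    """A protein summary with a protein group code (PGC) attached per entry.

    ``entries`` pairs each original entry with the integer code of the global
    group its accession belongs to; code 0 is the sentinel for "not in the
    dictionary" when missing accessions are tolerated.
    """

    run_id: str
    entries: list[tuple[int, ProteinEntry]]
    dialect: str = "proteinpilot"
    columns: list[str] = field(default_factory=list)

    def pgcs(self) -> set[int]:
        """Distinct codes present in this run (sentinel 0 excluded)."""
        return {pgc for pgc, _ in self.entries if pgc != 0}


def _resolve_dialect(dialect: str | Dialect | Mapping[str, str]) -> Dialect:
    if isinstance(dialect, Dialect):
        return dialect
    if isinstance(dialect, str):
        try:
            return DIALECTS[dialect]
        except KeyError:
            raise SummaryFormatError(
                f"unknown dialect {dialect!r}; known: {sorted(DIALECTS)}"
            ) from None
    mapping = dict(dialect)
    if "group_col" not in mapping or "accession_col" not in mapping:
        raise SummaryFormatError(
            "a dialect mapping must define at least 'group_col' and 'accession_col'"
        )
    mapping.setdefault("name", "custom")
    return Dialect(**mapping)


def load_dialect_config(path: str | Path) -> Dialect:
    """Load a custom column mapping from a YAML key-value file."""
    with open(path) as fh:
        data = yaml.safe_load(fh)
    if not isinstance(data, Mapping):
        raise SummaryFormatError(f"dialect config {path} must be a key-value mapping")
    return _resolve_dialect(data)


def _parse_rank(cell: str | None) -> float | None:
    if cell is None or str(cell).strip() == "":
        return None
    try:
        return float(cell)
    except ValueError:
        return None


def read_protein_summary(
    path: str | Path,
    dialect: str | Dialect | Mapping[str, str] = "proteinpilot",
    run_id: str | None = None,
    normalize_accession=None,
) -> ProteinSummary:
    """Parse a tab-delimited protein summary into a :class:`ProteinSummary`.

    Groups are the maximal runs of consecutive rows sharing a group id.  The
    first row of each group is flagged as the top protein unless the dialect
    names an explicit master-protein column.  Duplicate ``(group_id,
    accession)`` rows within a group are dropped with a warning.

    Parameters
    ----------
    normalize_accession
        Optional hook mapping raw accession strings; off (identity) by
        default — accessions are exact, case-sensitive, version included.
    """
    path = Path(path)
    spec = _resolve_dialect(dialect)
    try:
        frame = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    except pd.errors.EmptyDataError:
        raise SummaryFormatError(f"{path}: file is empty") from None
    return _summary_from_frame(
        frame,
        spec,
        run_id=run_id if run_id is not None else path.stem,
        label=str(path),
        normalize_accession=normalize_accession,
    )


def _summary_from_frame(
    frame: pd.DataFrame,
    spec: Dialect,
    run_id: str,
    label: str,
    normalize_accession=None,
) -> ProteinSummary:
    path = label
    if frame.empty and frame.columns.empty:
        raise SummaryFormatError(f"{path}: file is empty")
    for col in spec.required_columns():
        if col not in frame.columns:
            raise SummaryFormatError(f"{path}: missing required column {col!r}")

    entries: list[ProteinEntry] = []
    seen_in_group: set[tuple[int, str]] = set()
    prev_gid: int | None = None
    for _, row in frame.iterrows():
        try:
            gid = int(str(row[spec.group_col]).strip())
        except ValueError:
            raise SummaryFormatError(
                f"{path}: non-integer group id {row[spec.group_col]!r}"
            ) from None
        acc = str(row[spec.accession_col]).strip()
        if not acc:
            raise SummaryFormatError(f"{path}: empty accession in group {gid}")
        if normalize_accession is not None:
            acc = normalize_accession(acc)
        if gid != prev_gid:
            seen_in_group = set()
            prev_gid = gid
        if (gid, acc) in seen_in_group:
            warnings.warn(
                f"{path}: duplicate entry ({gid}, {acc}) dropped", stacklevel=2
            )
            continue
        seen_in_group.add((gid, acc))

        mapped = {spec.group_col, spec.accession_col}
        raw = {spec.group_col: str(row[spec.group_col]), spec.accession_col: str(row[spec.accession_col])}
        name = ""
        if spec.name_col and spec.name_col in frame.columns:
            name = str(row[spec.name_col])
            mapped.add(spec.name_col)
            raw[spec.name_col] = name
        genes: list[str] = []
        if spec.gene_col and spec.gene_col in frame.columns:
            genes = split_genes(row[spec.gene_col])
            mapped.add(spec.gene_col)
            raw[spec.gene_col] = str(row[spec.gene_col])
        rank = None
        if spec.rank_col and spec.rank_col in frame.columns:
            rank = _parse_rank(row[spec.rank_col])
            mapped.add(spec.rank_col)
            raw[spec.rank_col] = str(row[spec.rank_col])
        is_top = False
        if spec.top_col and spec.top_col in frame.columns:
            is_top = str(row[spec.top_col]).strip().lower() in TOP_FLAG_VALUES
            mapped.add(spec.top_col)
            raw[spec.top_col] = str(row[spec.top_col])
        rest = {c: str(row[c]) for c in frame.columns if c not in mapped}
        entries.append(
            ProteinEntry(
                group_id=gid,
                accession=acc,
                protein_name=name,
                genes=genes,
                is_top=is_top,
                rank=rank,
                rest=rest,
                raw=raw,
            )
        )

    summary = ProteinSummary(
        run_id=run_id,
        entries=entries,
        dialect=spec.name,
        columns=list(frame.columns),
    )
    if not (spec.top_col and spec.top_col in frame.columns):
        _flag_first_as_top(summary)
    else:
        _ensure_one_top(summary)
    return summary


def _flag_first_as_top(summary: ProteinSummary) -> None:
    for block in summary.groups():
        for i, entry in enumerate(block):
            entry.is_top = i == 0


def _ensure_one_top(summary: ProteinSummary) -> None:
    """Enforce the one-top-per-group invariant on explicitly flagged files."""
    for block in summary.groups():
        tops = [e for e in block if e.is_top]
        if not tops:
            block[0].is_top = True
        elif len(tops) > 1:
            warnings.warn(
                f"group {block[0].group_id} in run {summary.run_id!r} flags "
                f"{len(tops)} master proteins; keeping the first",
                stacklevel=3,
            )
            for extra in tops[1:]:
                extra.is_top = False


def _format_entry_cell(entry: ProteinEntry, col: str, spec: Dialect) -> str:
    if col in entry.raw:
        return entry.raw[col]
    if col == spec.group_col:
        return str(entry.group_id)
    if col == spec.accession_col:
        return entry.accession
    if spec.name_col and col == spec.name_col:
        return entry.protein_name
    if spec.gene_col and col == spec.gene_col:
        return "; ".join(entry.genes)
    if spec.rank_col and col == spec.rank_col:
        return "" if entry.rank is None else repr(entry.rank)
    if spec.top_col and col == spec.top_col:
        return "Master Protein" if entry.is_top else ""
    return entry.rest.get(col, "")


def write_coded_summary(coded: CodedSummary, path: str | Path) -> None:
    """Write a coded summary as tab-delimited text.

    The PGC is the first column; all original columns follow in their
    original order with their original cell contents.  ``read_coded_summary``
    on the result returns an equal :class:`CodedSummary`.
    """
    spec = _resolve_dialect(coded.dialect)
    columns = coded.columns or _default_columns(spec)
    for pgc, entry in coded.entries:
        if pgc is None:
            raise ValueError(f"entry {entry.accession} has no PGC assigned")
    with open(path, "w") as fh:
        fh.write("\t".join(["PGC", *columns]) + "\n")
        for pgc, entry in coded.entries:
            cells = [str(pgc)] + [_format_entry_cell(entry, c, spec) for c in columns]
            fh.write("\t".join(cells) + "\n")


def _default_columns(spec: Dialect) -> list[str]:
    cols = [spec.group_col, spec.accession_col]
    for col in (spec.name_col, spec.gene_col, spec.rank_col, spec.top_col):
        if col:
            cols.append(col)
    return cols


def read_coded_summary(
    path: str | Path,
    dialect: str | Dialect | Mapping[str, str] = "proteinpilot",
    run_id: str | None = None,
) -> CodedSummary:
    """Read back a file written by :func:`write_coded_summary`."""
    path = Path(path)
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
    if not header or header[0] != "PGC":
        raise SummaryFormatError(f"{path}: first column must be 'PGC'")
    frame = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    pgcs = [int(v) for v in frame["PGC"]]
    spec = _resolve_dialect(dialect)
    summary = _summary_from_frame(
        frame.drop(columns=["PGC"]),
        spec,
        run_id=run_id if run_id is not None else path.stem,
        label=str(path),
    )
    return CodedSummary(
        run_id=summary.run_id,
        entries=list(zip(pgcs, summary.entries)),
        dialect=summary.dialect,
        columns=summary.columns,
    )


def write_protein_summary(summary: ProteinSummary, path: str | Path) -> None:
    """Write a :class:`ProteinSummary` back to tab-delimited text."""
    spec = _resolve_dialect(summary.dialect)
    columns = summary.columns or _default_columns(spec)
    with open(path, "w") as fh:
        fh.write("\t".join(columns) + "\n")
        for entry in summary.entries:
            fh.write("\t".join(_format_entry_cell(entry, c, spec) for c in columns) + "\n")
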