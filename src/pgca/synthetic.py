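"""Synthetic multi-run protein summaries with known ground truth.

The protein inference problem in a multi-run study has three faces: group
identifiers are local to a run, group composition drifts between runs, and
the top (master) protein chosen to represent a group changes.  The generator
here emulates exactly those three effects on top of a fixed universe of
"true" protein groups, so every linking routine in the package can be tested
against a known answer without any external data.

Each true group has a fixed accession set and gene annotation.  Per run, a
group may drop out entirely, non-top members may drop out individually, and
the top may rotate to another surviving member; surviving groups receive
fresh sequential local identifiers.  The ground truth is returned as a
:class:`~pgca.dictionary.Dictionary` over the full true groups.

Two small deterministic fixtures reproduce textbook linking situations: a
kininogen-1 isoform group whose membership grows over three runs, and a
pyruvate-kinase group whose gene annotation and top protein differ across
three runs so the three linking modes give three different answers.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .dictionary import Dictionary, GlobalGroup
from .io import ProteinEntry, ProteinSummary, write_protein_summary

__all__ = [
    "SimulationConfig",
    "generate_runs",
    "write_runs",
    "kininogen_example",
    "pyruvate_kinase_example",
]

#: Default group-size weights, shaped like typical per-run summaries:
#: roughly 60% singletons and a rapidly decaying tail.
DEFAULT_SIZE_WEIGHTS: dict[int, float] = {
    1: 0.60,
    2: 0.16,
    3: 0.10,
    4: 0.06,
    5: 0.04,
    6: 0.02,
    7: 0.01,
    8: 0.01,
}


@dataclass
class SimulationConfig:
    """Parameters of the multi-run summary generator.

    Defaults describe a plasma-proteomics study of moderate size: 12 runs
    over 220 underlying groups, mostly singletons, with moderate run-level
    dropout, occasional loss of non-top members, one in five groups changing
    its representative per run, and 90% of groups annotated to a single
    shared gene (multi-gene groups are the minority in real summaries).
    """

    n_runs: int = 12
    n_true_groups: int = 220
    size_distribution: dict[int, float] = field(
        default_factory=lambda: dict(DEFAULT_SIZE_WEIGHTS)
    )
    dropout_prob: float = 0.15
    member_dropout_prob: float = 0.10
    top_swap_prob: float = 0.20
    shared_gene_prob: float = 0.90
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("dropout_prob", "member_dropout_prob", "top_swap_prob", "shared_gene_prob"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {p}")
        if self.n_runs < 1 or self.n_true_groups < 1:
            raise ValueError("n_runs and n_true_groups must be positive")
        if not self.size_distribution or any(s < 1 for s in self.size_distribution):
            raise ValueError("size_distribution needs sizes >= 1")


@dataclass
class _TrueGroup:
    accessions: list[str]  # canonical top first
    genes: dict[str, list[str]]  # accession -> gene symbols
    peptides: dict[str, int]  # accession -> nominal peptide count


def _sample_sizes(config: SimulationConfig, rng: np.random.Generator) -> np.ndarray:
    sizes = np.array(sorted(config.size_distribution), dtype=int)
    weights = np.array([config.size_distribution[s] for s in sizes], dtype=float)
    weights = weights / weights.sum()
    return rng.choice(sizes, size=config.n_true_groups, p=weights)


def _make_true_groups(
    config: SimulationConfig, rng: np.random.Generator
) -> list[_TrueGroup]:
    groups: list[_TrueGroup] = []
    acc_counter = 0
    for gidx, size in enumerate(_sample_sizes(config, rng)):
        accessions = []
        for _ in range(int(size)):
            acc_counter += 1
            version = int(rng.integers(1, 10))
            accessions.append(f"PROT{acc_counter:05d}.{version}")
        top_gene = f"GENE{gidx:04d}"
        shared = rng.random() < config.shared_gene_prob
        genes: dict[str, list[str]] = {}
        for i, acc in enumerate(accessions):
            if i == 0 or shared:
                genes[acc] = [top_gene]
            else:
                genes[acc] = [f"GENE{gidx:04d}X{i}"]
        peptides = {acc: int(rng.integers(1, 40)) for acc in accessions}
        groups.append(_TrueGroup(accessions=accessions, genes=genes, peptides=peptides))
    return groups


def generate_runs(
    config: SimulationConfig,
) -> tuple[list[ProteinSummary], Dictionary]:
    """Simulate per-run protein summaries and return them with ground truth.

    Every surviving true group appears in a run as one local group with a
    fresh sequential group id; the top protein is the group's canonical top
    unless a swap rotated it onto another surviving member.  The returned
    dictionary codes the *full* true groups (code = index + 1); analyses on
    observed data may need its restriction to observed accessions, and — when
    member dropout disconnects a group's realizations — the connected-
    component refinement of that restriction.

    Deterministic in ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    true_groups = _make_true_groups(config, rng)
    summaries: list[ProteinSummary] = []
    for run_idx in range(config.n_runs):
        run_id = f"RUN{run_idx + 1:02d}"
        entries: list[ProteinEntry] = []
        local_n = 0
        for group in true_groups:
            if rng.random() < config.dropout_prob:
                continue
            members = [group.accessions[0]] + [
                acc
                for acc in group.accessions[1:]
                if rng.random() >= config.member_dropout_prob
            ]
            top = members[0]
            if len(members) > 1 and rng.random() < config.top_swap_prob:
                top = members[int(rng.integers(1, len(members)))]
            ordered = [top] + [m for m in members if m != top]
            local_n += 1
            for i, acc in enumerate(ordered):
                entries.append(
                    ProteinEntry(
                        group_id=local_n,
                        accession=acc,
                        protein_name=f"Synthetic protein {acc.split('.')[0][4:]}",
                        genes=list(group.genes[acc]),
                        is_top=i == 0,
                        rest={"Peptides": str(group.peptides[acc])},
                    )
                )
        summaries.append(
            ProteinSummary(
                run_id=run_id,
                entries=entries,
                dialect="proteinpilot",
                columns=["N", "Accession", "Name", "Gene", "Peptides"],
            )
        )
    truth = Dictionary(
        GlobalGroup(idx + 1, frozenset(g.accessions))
        for idx, g in enumerate(true_groups)
    )
    return summaries, truth


def write_runs(
    config: SimulationConfig, out_dir: str | Path
) -> tuple[list[Path], Path]:
    """Write simulated runs as ProteinPilot-dialect files plus a truth TSV."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    summaries, truth = generate_runs(config)
    paths = []
    for summary in summaries:
        path = out_dir / f"{summary.run_id}.txt"
        write_protein_summary(summary, path)
        paths.append(path)
    truth_path = out_dir / "truth.tsv"
    from .dictionary import serialize_dictionary

    serialize_dictionary(truth, truth_path)
    return paths, truth_path


# ---------------------------------------------------------------------------
# Deterministic worked examples
# ---------------------------------------------------------------------------

_KNG_A = "IPI00215894.1"  # kininogen-1 isoform LMW
_KNG_B = "IPI00797833.3"  # near-identical to the LMW isoform
_KNG_C = "IPI00032328.2"  # kininogen-1 isoform HMW
_KNG_D = "IPI00465028.5"  # additional member appearing in the last run


def _entry(n, acc, name, genes, top, rest=None):
    return ProteinEntry(
        group_id=n,
        accession=acc,
        protein_name=name,
        genes=list(genes),
        is_top=top,
        rest=dict(rest or {}),
    )


def _summary(run_id, entries):
    return ProteinSummary(
        run_id=run_id,
        entries=entries,
        dialect="proteinpilot",
        columns=["N", "Accession", "Name", "Gene"],
    )


def kininogen_example() -> list[ProteinSummary]:
    """Three runs of a growing kininogen-1 isoform group.

    Run 1 reports the three isoform accessions as two separate groups
    ({A, B} and {C}); run 2 reports all three as one group, which merges the
    two global groups; run 3 adds a fourth accession to the group.  Building
    a dictionary over the three runs therefore yields 2 → 1 → 1 global
    groups, the final one holding four accessions.
    """
    kng = ["KNG1"]
    run1 = _summary(
        "EXP01",
        [
            _entry(1, _KNG_A, "Isoform LMW of Kininogen-1", kng, True),
            _entry(1, _KNG_B, "Kininogen-1 variant", kng, False),
            _entry(2, _KNG_C, "Isoform HMW of Kininogen-1", kng, True),
        ],
    )
    run2 = _summary(
        "EXP02",
        [
            _entry(1, _KNG_B, "Kininogen-1 variant", kng, True),
            _entry(1, _KNG_A, "Isoform LMW of Kininogen-1", kng, False),
            _entry(1, _KNG_C, "Isoform HMW of Kininogen-1", kng, False),
        ],
    )
    run3 = _summary(
        "EXP03",
        [
            _entry(1, _KNG_B, "Kininogen-1 variant", kng, True),
            _entry(1, _KNG_A, "Isoform LMW of Kininogen-1", kng, False),
            _entry(1, _KNG_C, "Isoform HMW of Kininogen-1", kng, False),
            _entry(1, _KNG_D, "Kininogen-1 fragment", kng, False),
        ],
    )
    return [run1, run2, run3]


_PKM_P1 = "Q504U3"  # top of run 1, annotated to gene PKM2
_PKM_P2 = "P14618"  # pyruvate kinase PKM
_PKM_P3 = "P14618-2"  # PKM isoform
_PKM_P4 = "B4DNK4"  # PKM fragment


def pyruvate_kinase_example() -> list[ProteinSummary]:
    """Three runs of one pyruvate-kinase group where the linking modes split.

    Run 1 groups {Q504U3 (top, gene PKM2), P14618, P14618-2 (gene PKM)};
    runs 2 and 3 report groups over {P14618, P14618-2, B4DNK4}, all on gene
    PKM, each with a different top protein, so the three runs carry three
    distinct tops.  Linking all members gives one global group of four
    proteins; linking by the top's gene gives two groups (no other run-1
    member shares the top's gene); linking by top identifier gives three.
    """
    run1 = _summary(
        "EXP01",
        [
            _entry(1, _PKM_P1, "Pyruvate kinase (putative)", ["PKM2"], True),
            _entry(1, _PKM_P2, "Pyruvate kinase PKM", ["PKM"], False),
            _entry(1, _PKM_P3, "Isoform M1 of Pyruvate kinase PKM", ["PKM"], False),
        ],
    )
    run2 = _summary(
        "EXP02",
        [
            _entry(1, _PKM_P2, "Pyruvate kinase PKM", ["PKM"], True),
            _entry(1, _PKM_P3, "Isoform M1 of Pyruvate kinase PKM", ["PKM"], False),
            _entry(1, _PKM_P4, "Pyruvate kinase (fragment)", ["PKM"], False),
        ],
    )
    run3 = _summary(
        "EXP03",
        [
            _entry(1, _PKM_P4, "Pyruvate kinase (fragment)", ["PKM"], True),
            _entry(1, _PKM_P3, "Isoform M1 of Pyruvate kinase PKM", ["PKM"], False),
        ],
    )
    return [run1, run2, run3]
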