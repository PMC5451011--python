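"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import numpy as np
import pytest

import pgca


def merge_to_fixpoint(sets):
    """Independent oracle: transitive-closure merge by literal fixpoint.

    Repeatedly unions any two overlapping sets until no pair overlaps.  This
    is deliberately the naive quadratic procedure, kept separate from the
    union-find implementation it checks.
    """
    pool = [set(s) for s in sets if s]
    changed = True
    while changed:
        changed = False
        for i in range(len(pool)):
            for j in range(i + 1, len(pool)):
                if pool[i] & pool[j]:
                    pool[i] |= pool[j]
                    del pool[j]
                    changed = True
                    break
            if changed:
                break
    return {frozenset(s) for s in pool}


def random_set_instance(rng: np.random.Generator, max_accessions=200, max_sets=60):
    """A random collection of accession sets over a bounded universe."""
    n_acc = int(rng.integers(2, max_accessions + 1))
    n_sets = int(rng.integers(1, max_sets + 1))
    universe = [f"ACC{i:04d}" for i in range(n_acc)]
    sets = []
    for _ in range(n_sets):
        size = int(rng.integers(1, min(8, n_acc) + 1))
        members = rng.choice(n_acc, size=size, replace=False)
        sets.append(frozenset(universe[m] for m in members))
    return sets


def summaries_from_sets(set_lists):
    """Wrap per-run collections of accession sets as ProteinSummary objects."""
    summaries = []
    for ridx, groups in enumerate(set_lists):
        entries = []
        for gidx, accs in enumerate(groups, start=1):
            for i, acc in enumerate(sorted(accs)):
                entries.append(
                    pgca.ProteinEntry(
                        group_id=gidx, accession=acc, is_top=i == 0
                    )
                )
        summaries.append(
            pgca.ProteinSummary(run_id=f"R{ridx:02d}", entries=entries)
        )
    return summaries


@pytest.fixture
def kininogen_runs():
    return pgca.kininogen_example()


@pytest.fixture
def pkm_runs():
    return pgca.pyruvate_kinase_example()


@pytest.fixture
def rng():
    return np.random.default_rng(20170531)
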