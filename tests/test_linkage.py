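"""Cross-run diagnostics: Dice, presence, curves, change log, histograms."""

from __future__ import annotations

import numpy as np
import pytest

import pgca
from pgca.linkage import (
    change_log,
    code_runs,
    common_pgc_curve,
    consistently_detected,
    dice,
    dice_top_proteins,
    dice_vs_dictionary,
    group_size_histogram,
    order_by_group_count,
    presence_matrix,
)


class TestDice:
    def test_equal_sets_give_one(self):
        assert dice({"a", "b"}, {"b", "a"}) == 1.0

    def test_disjoint_sets_give_zero(self):
        assert dice({"a"}, {"b"}) == 0.0

    def test_printed_formula_example(self):
        assert dice({"a", "b", "c"}, {"a", "b"}) == pytest.approx(0.8)

    def test_both_empty_is_undefined(self):
        with pytest.raises(ValueError):
            dice(set(), set())

    def test_matches_closed_form_on_random_sets(self, rng):
        universe = [f"A{i}" for i in range(30)]
        for _ in range(200):
            a = {universe[i] for i in rng.choice(30, rng.integers(1, 15), replace=False)}
            b = {universe[i] for i in rng.choice(30, rng.integers(1, 15), replace=False)}
            expected = 2 * len(a & b) / (len(a) + len(b))
            value = dice(a, b)
            assert value == pytest.approx(expected)
            assert value == pytest.approx(dice(b, a))
            assert 0.0 <= value <= 1.0


def identical_coded_runs(n=3):
    runs = [pgca.kininogen_example()[2]] * n
    runs = [
        pgca.ProteinSummary(run_id=f"R{i}", entries=list(runs[i].entries))
        for i in range(n)
    ]
    d = pgca.build_dictionary(runs)
    return code_runs(runs, d), d


class TestPresenceMatrix:
    def test_shared_and_private_codes(self):
        d = pgca.Dictionary()
        d.update([{"a"}, {"b"}, {"p1"}, {"p2"}, {"p3"}])

        def run(rid, accs):
            return pgca.ProteinSummary(
                run_id=rid,
                entries=[
                    pgca.ProteinEntry(group_id=i + 1, accession=a, is_top=True)
                    for i, a in enumerate(accs)
                ],
            )

        runs = [
            run("R1", ["a", "b", "p1"]),
            run("R2", ["a", "b", "p2"]),
            run("R3", ["a", "b", "p3"]),
        ]
        matrix = presence_matrix(code_runs(runs, d))
        frame = matrix.frame
        assert frame.shape == (5, 3)
        assert (frame.sum(axis=1) == 3).sum() == 2  # the two shared codes
        assert (frame.sum(axis=1) == 1).sum() == 3  # three private codes
        assert consistently_detected(matrix) == sorted(
            [d.pgc_of("a"), d.pgc_of("b")]
        )
        assert len(consistently_detected(matrix, 0.5)) == 2

    def test_single_run_is_one_true_column(self):
        coded, _ = identical_coded_runs(1)
        frame = presence_matrix(coded).frame
        assert frame.shape[1] == 1
        assert frame.all().all()

    def test_empty_input_gives_empty_matrix(self):
        matrix = presence_matrix([])
        assert matrix.frame.empty

    def test_sentinel_codes_excluded(self):
        coded = [
            pgca.CodedSummary(
                run_id="R",
                entries=[(0, pgca.ProteinEntry(group_id=1, accession="x", is_top=True))],
            )
        ]
        assert presence_matrix(coded).frame.empty


class TestCommonPgcCurve:
    def test_identical_runs_give_constant_curve(self):
        coded, _ = identical_coded_runs(4)
        curve = common_pgc_curve(coded)
        assert curve == [curve[0]] * 4

    def test_disjoint_runs_drop_to_zero(self):
        d = pgca.Dictionary()
        d.update([{"a"}, {"b"}])
        runs = [
            pgca.ProteinSummary(
                run_id=r, entries=[pgca.ProteinEntry(group_id=1, accession=a, is_top=True)]
            )
            for r, a in [("R1", "a"), ("R2", "b")]
        ]
        assert common_pgc_curve(code_runs(runs, d)) == [1, 0]

    def test_non_increasing_and_mode_ordering_on_synthetic_runs(self):
        runs, _ = pgca.generate_runs(
            pgca.SimulationConfig(n_runs=8, n_true_groups=60, seed=5)
        )
        ordered = order_by_group_count(runs)
        curves = {}
        for mode in ("all", "top_gene", "top_identifier"):
            d = pgca.build_dictionary(ordered, mode)
            coded = code_runs(ordered, d, mode)
            curve = common_pgc_curve(coded)
            assert all(a >= b for a, b in zip(curve, curve[1:]))
            curves[mode] = curve
        for k in range(len(ordered)):
            assert curves["all"][k] >= curves["top_gene"][k] >= curves["top_identifier"][k]


class TestChangeLog:
    def test_disjoint_file_has_no_mergers(self):
        d = pgca.Dictionary()
        d.update([{"a", "b"}])
        change = d.update([{"x", "y"}, {"z"}])
        assert change.mergers == 0
        assert change.new_groups == 2
        assert change.new_accessions == 3

    def test_connector_step_counts_one_merger_no_new_accessions(self):
        d = pgca.Dictionary()
        d.update([{"a", "b"}, {"c"}])
        change = d.update([{"a", "b", "c"}])
        assert change.mergers == 1
        assert change.new_accessions == 0
        assert change.new_groups == 0

    def test_repeat_of_processed_file_is_all_zero(self, kininogen_runs):
        log = change_log(kininogen_runs + [kininogen_runs[-1]])
        last = log.changes[-1]
        assert (last.new_accessions, last.new_groups, last.mergers) == (0, 0, 0)

    def test_conservation_identity_on_synthetic_runs(self):
        runs, _ = pgca.generate_runs(
            pgca.SimulationConfig(n_runs=10, n_true_groups=80, seed=23)
        )
        log = change_log(runs)
        frame = log.to_frame()
        d = pgca.build_dictionary(runs)
        assert frame["new_groups"].sum() - frame["mergers"].sum() == len(d)
        assert frame["new_accessions"].sum() == d.n_accessions
        assert (frame[["new_accessions", "new_groups", "mergers"]] >= 0).all().all()

    def test_merge_of_three_counts_two(self):
        d = pgca.Dictionary()
        d.update([{"a"}, {"b"}, {"c"}])
        change = d.update([{"a", "b", "c"}])
        assert change.mergers == 2


class TestGroupSizeHistogram:
    def test_documented_binning(self):
        groups = [["x"] * s for s in (1, 1, 2, 4, 7)]
        sets = [{f"{i}-{j}" for j in range(len(g))} for i, g in enumerate(groups)]
        assert group_size_histogram(sets) == {"1": 2, "2": 1, "3-5": 1, ">5": 1}

    def test_empty_and_all_singletons(self):
        assert group_size_histogram([]) == {"1": 0, "2": 0, "3-5": 0, ">5": 0}
        hist = group_size_histogram([{"a"}, {"b"}])
        assert hist == {"1": 2, "2": 0, "3-5": 0, ">5": 0}

    def test_bins_sum_to_group_count_for_dictionary(self):
        runs, _ = pgca.generate_runs(
            pgca.SimulationConfig(n_runs=4, n_true_groups=50, seed=31)
        )
        d = pgca.build_dictionary(runs)
        assert sum(group_size_histogram(d).values()) == len(d)


class TestDiceTables:
    def make_study(self):
        runs = pgca.kininogen_example()
        d = pgca.build_dictionary(runs)
        return code_runs(runs, d), d

    def test_local_equal_to_global_scores_one(self):
        coded, d = self.make_study()
        table = dice_vs_dictionary(coded, d)
        pgc = d.groups[0].pgc
        # the third run reports the full 4-member global group
        assert table.loc["EXP03", pgc] == 1.0

    def test_subset_follows_formula_and_absence_is_zero(self):
        d = pgca.Dictionary()
        d.update([{"A", "B", "C", "D"}])
        pgc = d.pgc_of("A")
        run1 = pgca.ProteinSummary(
            run_id="R1",
            entries=[
                pgca.ProteinEntry(group_id=1, accession="A", is_top=True),
                pgca.ProteinEntry(group_id=1, accession="B"),
            ],
        )
        run2 = pgca.ProteinSummary(run_id="R2", entries=[])
        table = dice_vs_dictionary(code_runs([run1, run2], d), d)
        assert table.loc["R1", pgc] == pytest.approx(2 * 2 / (2 + 4))
        assert table.loc["R2", pgc] == 0.0

    def test_values_bounded_and_one_iff_equal_on_synthetic(self):
        runs, _ = pgca.generate_runs(
            pgca.SimulationConfig(n_runs=5, n_true_groups=40, seed=41)
        )
        d = pgca.build_dictionary(runs)
        coded = code_runs(runs, d)
        table = dice_vs_dictionary(coded, d)
        assert ((table.values >= 0) & (table.values <= 1)).all()
        globals_ = {g.pgc: set(g.accessions) for g in d.groups}
        for summary in coded:
            by_pgc = {}
            for pgc, entry in summary.entries:
                by_pgc.setdefault(pgc, set()).add(entry.accession)
            for pgc, members in by_pgc.items():
                expected = 1.0 if members == globals_[pgc] else table.loc[summary.run_id, pgc]
                assert table.loc[summary.run_id, pgc] == pytest.approx(expected)
                if members == globals_[pgc]:
                    assert table.loc[summary.run_id, pgc] == 1.0

    def test_two_distinct_tops_score_two_thirds(self):
        coded, d = self.make_study()
        # EXP02 and EXP03 share the top; EXP01 uses a different one
        table = dice_top_proteins(coded, d)
        pgc = d.groups[0].pgc
        pool_size = 2  # two distinct tops across the three runs
        assert table.loc["EXP02", pgc] == pytest.approx(2 * 1 / (1 + pool_size))
        assert table.loc["EXP01", pgc] == pytest.approx(2 * 1 / (1 + pool_size))

    def test_unique_top_gives_ones_and_absence_zero(self):
        d = pgca.Dictionary()
        d.update([{"A", "B"}])
        pgc = d.pgc_of("A")

        def run(rid, accs, top):
            return pgca.ProteinSummary(
                run_id=rid,
                entries=[
                    pgca.ProteinEntry(group_id=1, accession=a, is_top=a == top)
                    for a in accs
                ],
            )

        runs = [run("R1", ["A", "B"], "A"), run("R2", ["A"], "A")]
        runs.append(pgca.ProteinSummary(run_id="R3", entries=[]))
        table = dice_top_proteins(code_runs(runs, d), d)
        assert table.loc["R1", pgc] == 1.0
        assert table.loc["R2", pgc] == 1.0
        assert table.loc["R3", pgc] == 0.0


def test_order_by_group_count_desc_with_name_ties():
    def run(rid, n_groups):
        entries = [
            pgca.ProteinEntry(group_id=i + 1, accession=f"{rid}-{i}", is_top=True)
            for i in range(n_groups)
        ]
        return pgca.ProteinSummary(run_id=rid, entries=entries)

    runs = [run("B", 2), run("A", 2), run("C", 5)]
    assert [s.run_id for s in order_by_group_count(runs)] == ["C", "A", "B"]
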