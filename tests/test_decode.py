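"""Decoder: >= 3-of-4 rule, ambiguity handling, oracle equivalence."""

import numpy as np
import pandas as pd
import pytest

from overgomap import SimConfig, build_design, simulate
from overgomap.datasets import make_probe_table, toy_screen
from overgomap.decode import (
    ValidationError,
    assignment_counts,
    candidate_probes,
    decode_screen,
    read_calls_tsv,
    write_calls_tsv,
)
from overgomap.design import Dimension, ProbeAddress


def brute_force_candidates(positive_labels, design):
    """Independent oracle: enumerate every occupied address from first
    principles (modular anti-diagonal arithmetic, no design internals)."""
    positives = set(positive_labels)
    out = []
    nd = max(design.n_rows, design.n_cols)
    for i, pid in enumerate(design.probe_order):
        plate, rem = divmod(i, design.n_rows * design.n_cols)
        row, col = divmod(rem, design.n_cols)
        pools = {f"PLATE{plate}", f"ROW{row}", f"COL{col}", f"DIAG{(row + col) % nd}"}
        support = len(pools & positives)
        if support >= 3:
            missing = None
            if support == 3:
                (missing_label,) = pools - positives
                missing = Dimension("".join(c for c in missing_label if not c.isdigit()))
            out.append((pid, support, missing))
    out.sort(key=lambda t: (-t[1], t[0]))
    return out


def sparse_config(**kw):
    """Desk clone count on the full-size genome: probe spacing (~6.2 Mb)
    dwarfs the insert length, so clones hit at most one probe."""
    base = dict(seed=0, genome_size_kb=simulate.FULL_GENOME_KB, filters_used=11)
    base.update(kw)
    return SimConfig.desk(**base)


class TestCandidateProbes:
    def test_full_support_at_intersection(self, design216):
        pid = design216.probe_at(ProbeAddress(1, 2, 3))
        cands = candidate_probes(["PLATE1", "ROW2", "COL3", "DIAG5"], design216)
        top = [c for c in cands if c[1] == 4]
        assert top == [(pid, 4, None)]

    def test_three_of_four_names_missing_dimension(self, design216):
        pid = design216.probe_at(ProbeAddress(1, 2, 3))
        cands = candidate_probes(["PLATE1", "ROW2", "COL3"], design216)
        assert (pid, 3, Dimension.DIAG) in cands
        assert all(c[1] < 4 for c in cands)

    def test_two_planted_probes_match_enumeration(self, design216):
        a = design216.probe_at(ProbeAddress(0, 0, 0))
        b = design216.probe_at(ProbeAddress(1, 1, 1))
        lit = {p.label for p in design216.pools_for_probe(a) | design216.pools_for_probe(b)}
        cands = candidate_probes(lit, design216)
        assert cands == brute_force_candidates(lit, design216)
        four = {c[0] for c in cands if c[1] == 4}
        assert {a, b} <= four

    def test_empty_positive_set(self, design216):
        assert candidate_probes([], design216) == []

    def test_unknown_pool_rejected(self, design216):
        with pytest.raises(ValidationError):
            candidate_probes(["PLATE9"], design216)

    def test_oracle_equivalence_random_call_sets(self, design216):
        rng = np.random.default_rng(7)
        labels = np.array([p.label for p in design216.pools])
        for _ in range(300):
            k = rng.integers(0, 13)
            lit = list(rng.choice(labels, size=k, replace=False))
            assert candidate_probes(lit, design216) == brute_force_candidates(lit, design216)


class TestDecodeScreen:
    def test_toy_screen_hand_decoded(self):
        design, calls, expected = toy_screen()
        report = decode_screen(calls, design)
        pd.testing.assert_frame_equal(report.accepted, expected)
        assert list(report.rejected["clone_id"]) == ["bac3"]

    def test_zero_noise_recovery_is_exact(self, probes, design216):
        for seed in range(8):
            sim = simulate.simulate_screen(sparse_config(seed=seed), probes, design216)
            report = decode_screen(sim.calls, design216)
            got = report.accepted[["clone_id", "probe_id"]].reset_index(drop=True)
            pd.testing.assert_frame_equal(got, sim.truth)
            assert (report.accepted["support"] == 4).all()
            assert len(report.ambiguity_groups) == 0

    def test_single_deletion_recovered_at_support_three(self, probes, design216):
        sim = simulate.simulate_screen(sparse_config(seed=1), probes, design216)
        truth = set(map(tuple, sim.truth.to_numpy()))
        for dim in Dimension:
            calls = sim.calls.copy()
            for clone, pid in truth:
                pool = next(
                    p for p in design216.pools_for_probe(pid) if p.dimension == dim
                )
                calls.loc[clone, pool.label] = False
            report = decode_screen(calls, design216, accept_ambiguous=True)
            acc = report.accepted
            for clone, pid in truth:
                row = acc[(acc["clone_id"] == clone) & (acc["probe_id"] == pid)]
                assert len(row) == 1
                assert row.iloc[0]["support"] == 3
                assert row.iloc[0]["missing_dimension"] == dim.value
            # plate deletion is the one ambiguous case: row+col+diag fix the
            # cell within a plate but not which plate
            assert report.ambiguity_groups["clone_id"].nunique() == (
                len(truth) if dim is Dimension.PLATE else 0
            )

    def test_double_deletion_always_rejected(self, probes, design216):
        import itertools

        sim = simulate.simulate_screen(sparse_config(seed=2), probes, design216)
        truth = set(map(tuple, sim.truth.to_numpy()))
        for d1, d2 in itertools.combinations(Dimension, 2):
            calls = sim.calls.copy()
            for clone, pid in truth:
                for pool in design216.pools_for_probe(pid):
                    if pool.dimension in (d1, d2):
                        calls.loc[clone, pool.label] = False
            report = decode_screen(calls, design216, accept_ambiguous=True)
            acc = set(map(tuple, report.accepted[["clone_id", "probe_id"]].to_numpy()))
            assert acc & truth == set()

    def test_false_positives_never_remove_assignments(self, probes, design216):
        sim = simulate.simulate_screen(sparse_config(seed=3), probes, design216)
        before = decode_screen(sim.calls, design216, accept_ambiguous=True)
        prior = set(map(tuple, before.accepted[["clone_id", "probe_id"]].to_numpy()))
        rng = np.random.default_rng(0)
        noisy = sim.calls.to_numpy() | (rng.random(sim.calls.shape) < 0.05)
        after = decode_screen(
            pd.DataFrame(noisy, index=sim.calls.index, columns=sim.calls.columns),
            design216,
            accept_ambiguous=True,
        )
        now = set(map(tuple, after.accepted[["clone_id", "probe_id"]].to_numpy()))
        assert prior <= now

    def test_missing_pool_column_is_an_error(self, design216):
        calls = pd.DataFrame(
            False, index=["c1"], columns=[p.label for p in design216.pools[:-1]]
        )
        with pytest.raises(ValidationError, match="missing"):
            decode_screen(calls, design216)


class TestAssignmentCounts:
    def test_empty_report_is_all_zero(self, probes, design216):
        calls = pd.DataFrame(
            False, index=["c1"], columns=[p.label for p in design216.pools]
        )
        report = decode_screen(calls, design216)
        counts = assignment_counts(report, probes)
        assert counts["n_successful_probes"] == 0
        assert counts["total_assignments"] == 0
        assert (counts["per_probe"] == 0).all()

    def test_counts_match_planted_truth(self, probes, design216):
        sim = simulate.simulate_screen(sparse_config(seed=4), probes, design216)
        report = decode_screen(sim.calls, design216)
        counts = assignment_counts(report, probes)
        planted = sim.truth.groupby("probe_id").size()
        assert counts["per_probe"][planted.index].equals(planted)
        assert counts["n_successful_probes"] == planted.index.nunique()
        assert counts["max_count"] == planted.max()


def test_calls_tsv_round_trip(tmp_path, probes, design216):
    sim = simulate.simulate_screen(sparse_config(seed=5), probes, design216)
    path = tmp_path / "calls.tsv"
    write_calls_tsv(sim.calls, path)
    back = read_calls_tsv(path, design216)
    # long form drops clone order but not content
    pd.testing.assert_frame_equal(
        back.sort_index(), sim.calls.sort_index(), check_names=False
    )
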