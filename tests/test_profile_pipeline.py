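"""Filtering, pooling, category aggregation, fold changes, flank summaries."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from repairscape.profile_pipeline import (
    aggregate_categories,
    filter_and_pool,
    insertion_flank_summary,
    lfc,
    summarize_lfc,
)
from repairscape.synthetic_data import GenerativeParams, make_library, sample_dataset

from conftest import make_site


def toy_counts(rows):
    return pd.DataFrame(
        rows, columns=["target", "line", "replicate", "timepoint", "outcome", "count"]
    )


class TestFilterAndPool:
    def test_low_coverage_target_dropped_everywhere(self):
        rows = []
        for tid, depth in [("A", 200), ("B", 99), ("C", 150)]:
            for rep in (1, 2):
                rows.append((tid, "control", rep, 1, "D:29-30", depth))
                rows.append((tid, "ko", rep, 1, "D:29-30", 200))
        counts = toy_counts(rows)
        prof = filter_and_pool(counts, min_reads=100)
        assert set(prof["target"]) == {"A", "C"}

    def test_target_missing_from_one_sample_dropped(self):
        rows = [
            ("A", "control", 1, 1, "D:29-30", 200),
            ("A", "control", 2, 1, "D:29-30", 200),
            ("A", "ko", 1, 1, "D:29-30", 200),
            # target A absent from (ko, rep 2) which exists for target B
            ("B", "control", 1, 1, "D:29-30", 200),
            ("B", "control", 2, 1, "D:29-30", 200),
            ("B", "ko", 1, 1, "D:29-30", 200),
            ("B", "ko", 2, 1, "D:29-30", 200),
        ]
        prof = filter_and_pool(toy_counts(rows), min_reads=100)
        assert set(prof["target"]) == {"B"}

    def test_single_read_outcome_dropped(self):
        rows = [
            ("A", "control", 1, 1, "D:29-30", 150),
            ("A", "control", 1, 1, "I:30:T", 1),  # single read across all samples
            ("A", "control", 2, 1, "D:29-30", 150),
        ]
        prof = filter_and_pool(toy_counts(rows), min_reads=100)
        assert set(prof["outcome"]) == {"D:29-30"}

    def test_replicates_pooled(self):
        rows = [
            ("A", "control", 1, 1, "D:29-30", 3),
            ("A", "control", 2, 1, "D:29-30", 4),
        ]
        prof = filter_and_pool(toy_counts(rows), min_reads=1)
        assert prof.loc[0, "count"] == 7
        assert prof.loc[0, "freq"] == 1.0

    def test_no_survivors_raises(self):
        with pytest.raises(ValueError, match="survive"):
            filter_and_pool(toy_counts([("A", "c", 1, 1, "D:29-30", 5)]), min_reads=10**9)

    def test_matches_reference_implementation(self):
        """Filter-then-pool agrees with a naive dict-based reference on random tables."""
        rng = np.random.default_rng(0)
        targets = [f"T{i}" for i in range(6)]
        outcomes = [f"D:{28 + i}-{30 + i}" for i in range(5)]
        rows = []
        for tid in targets:
            for line in ("control", "ko"):
                for rep in (1, 2):
                    for o in outcomes:
                        if rng.random() < 0.8:
                            rows.append((tid, line, rep, 1, o, int(rng.integers(0, 60))))
        counts = toy_counts(rows)
        counts = counts[counts["count"] > 0]
        min_reads = 40

        # reference: explicit loops over the observed sample grid
        grid = sorted({(l, r, tp) for l, r, tp in
                       zip(counts["line"], counts["replicate"], counts["timepoint"])})
        per_sample: dict = {}
        for row in counts.itertuples(index=False):
            per_sample.setdefault((row.target, row.line, row.replicate, row.timepoint), 0)
            per_sample[(row.target, row.line, row.replicate, row.timepoint)] += row.count
        keep = {
            t for t in set(counts["target"])
            if all(per_sample.get((t, l, r, tp), 0) >= min_reads for l, r, tp in grid)
        }
        outcome_tot: dict = {}
        for row in counts.itertuples(index=False):
            outcome_tot[(row.target, row.outcome)] = (
                outcome_tot.get((row.target, row.outcome), 0) + row.count
            )
        expected: dict = {}
        for row in counts.itertuples(index=False):
            if row.target in keep and outcome_tot[(row.target, row.outcome)] != 1:
                key = (row.target, row.line, row.outcome)
                expected[key] = expected.get(key, 0) + row.count

        prof = filter_and_pool(counts, min_reads=min_reads)
        got = {(r.target, r.line, r.outcome): r.count for r in prof.itertuples(index=False)}
        assert got == expected

    def test_frequencies_invariant_under_uniform_scaling(self):
        rows = [("A", "c", 1, 1, "D:29-30", 30), ("A", "c", 1, 1, "I:30:T", 70)]
        p1 = filter_and_pool(toy_counts(rows), min_reads=1)
        scaled = toy_counts([(t, l, r, tp, o, c * 10) for t, l, r, tp, o, c in rows])
        p2 = filter_and_pool(scaled, min_reads=1)
        assert np.allclose(p1["freq"], p2["freq"])


class TestAggregateCategories:
    def test_single_outcome_profile(self):
        t = make_site("A", seed=1)
        rows = [("A", "c", 1, 1, f"D:{t.cut - 2}-{t.cut + 1}", 50)]
        prof = filter_and_pool(toy_counts(rows), min_reads=1)
        vec = aggregate_categories(prof, [t])
        assert vec.to_numpy().sum() == pytest.approx(1.0)
        assert vec.to_numpy().max() == pytest.approx(1.0)

    def test_conservation_on_synthetic(self, library16):
        lib = library16[:6]
        counts, _ = sample_dataset(
            lib, [GenerativeParams(line="control", read_depth=500)], seed=2
        )
        prof = filter_and_pool(counts, min_reads=100)
        vec = aggregate_categories(prof, lib)
        assert np.allclose(vec.sum(axis=1), 1.0, atol=1e-9)

    def test_matches_ground_truth_at_depth(self, library16):
        lib = library16[:4]
        params = GenerativeParams(line="control", read_depth=50_000, fixed_depth=True)
        counts, truth = sample_dataset(lib, [params], seed=4)
        prof = filter_and_pool(counts, min_reads=100)
        vec = aggregate_categories(prof, lib)
        for t in lib:
            true_vec = truth.category_masses("control", t)
            got = vec.loc[(t.id, "control")]
            assert (got - true_vec).abs().max() < 0.01


class TestLFC:
    def _two_line_profiles(self, f_ko: float, f_ctrl: float):
        n = 10_000
        rows = [
            ("A", "control", 1, 1, "D:29-30", int(f_ctrl * n)),
            ("A", "control", 1, 1, "D:28-30", n - int(f_ctrl * n)),
            ("A", "ko", 1, 1, "D:29-30", int(f_ko * n)),
            ("A", "ko", 1, 1, "D:28-30", n - int(f_ko * n)),
        ]
        return filter_and_pool(toy_counts(rows), min_reads=1)

    def test_closed_form(self):
        prof = self._two_line_profiles(0.20, 0.10)
        table = lfc(prof, "control", pc=0.001, unit="outcome")
        got = table.set_index("unit").loc["D:29-30", "lfc"]
        assert got == pytest.approx(np.log2(0.201 / 0.101), abs=1e-9)

    def test_equal_frequencies_zero(self):
        prof = self._two_line_profiles(0.3, 0.3)
        table = lfc(prof, "control", unit="outcome")
        assert np.allclose(table["lfc"], 0.0)

    def test_antisymmetry(self, library16):
        lib = library16[:4]
        counts, _ = sample_dataset(
            lib,
            [
                GenerativeParams(line="control", read_depth=400),
                GenerativeParams(line="ko", read_depth=400,
                                 category_multipliers={"DEL_1": 1.5}),
            ],
            seed=6,
        )
        prof = filter_and_pool(counts, min_reads=100)
        fwd = lfc(prof, "control", unit="category", targets=lib)
        rev = lfc(prof, "ko", unit="category", targets=lib)
        key = ["unit", "target"]
        merged = fwd.set_index(key)[["lfc"]].join(
            rev.set_index(key)[["lfc"]], lsuffix="_f", rsuffix="_r"
        )
        assert np.allclose(merged["lfc_f"], -merged["lfc_r"], atol=1e-9)

    def test_absent_in_both_flagged(self):
        prof = self._two_line_profiles(0.2, 0.2)
        t = make_site("A", seed=1)
        table = lfc(prof, "control", unit="category", targets=[t])
        flagged = table[table["absent_in_both"]]
        assert (flagged["lfc"] == 0).all()
        assert len(flagged) > 0  # several categories unused by this toy profile

    def test_planted_multiplier_recovered(self, library16):
        lib = library16
        counts, _ = sample_dataset(
            lib,
            [
                GenerativeParams(line="control", read_depth=20_000, fixed_depth=True),
                GenerativeParams(line="ko", read_depth=20_000, fixed_depth=True,
                                 category_multipliers={"DEL_LONG_NOMH": 2.0}),
            ],
            seed=8,
        )
        prof = filter_and_pool(counts, min_reads=100)
        table = summarize_lfc(lfc(prof, "control", unit="category", targets=lib))
        got = table.set_index("unit").loc["DEL_LONG_NOMH", "mean_lfc"]
        assert got == pytest.approx(1.0, abs=0.1)


class TestInsertionFlankSummary:
    def test_identical_flank_targets_excluded_from_share(self):
        lib = make_library(6, seed=1, flank_pair=("T", "T"))
        counts, _ = sample_dataset(
            lib, [GenerativeParams(line="control", read_depth=500)], seed=1
        )
        prof = filter_and_pool(counts, min_reads=100)
        summ = insertion_flank_summary(prof, lib, n_boot=50, seed=0)
        assert len(summ["share"]) == 0
        assert len(summ["absolute"]) == 1

    def test_single_target_degenerate_ci(self):
        lib = make_library(1, seed=2, flank_pair=("T", "C"))
        counts, _ = sample_dataset(
            lib, [GenerativeParams(line="control", read_depth=2000)], seed=3
        )
        prof = filter_and_pool(counts, min_reads=100)
        summ = insertion_flank_summary(prof, lib, n_boot=50, seed=0)
        row = summ["share"].iloc[0]
        assert row["ci_lo"] == row["ci_hi"] == row["mean"]

    def test_deterministic_per_seed(self, library16):
        counts, _ = sample_dataset(
            library16, [GenerativeParams(line="control", read_depth=800)], seed=5
        )
        prof = filter_and_pool(counts, min_reads=100)
        s1 = insertion_flank_summary(prof, library16, n_boot=200, seed=7)
        s2 = insertion_flank_summary(prof, library16, n_boot=200, seed=7)
        pd.testing.assert_frame_equal(s1["share"], s2["share"])

    def test_rejects_multiple_lines(self, library16):
        counts, _ = sample_dataset(
            library16[:2],
            [
                GenerativeParams(line="control", read_depth=300),
                GenerativeParams(line="ko", read_depth=300,
                                 category_multipliers={"DEL_1": 2.0}),
            ],
            seed=5,
        )
        prof = filter_and_pool(counts, min_reads=1)
        with pytest.raises(ValueError):
            insertion_flank_summary(prof, library16[:2])
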