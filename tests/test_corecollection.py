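"""Allele coverage, core-subset optimization, and evaluation metrics."""

import itertools
import math

import numpy as np
import pytest

from gourdcore import (
    CoreConfig,
    PanelSimConfig,
    ValidationError,
    allele_coverage,
    entry_to_nearest_entry,
    evaluate_core,
    pairwise_distance,
    select_core,
    simulate_structured_panel,
)

from conftest import matrix_from_codes


class TestAlleleCoverage:
    def test_core_equals_whole(self, small_random_matrix):
        m = small_random_matrix
        assert allele_coverage(m, m.accession_ids) == 100.0

    def test_full_coverage_by_carriers(self):
        # a2 and a3 jointly carry every allele
        m = matrix_from_codes([[0, 0], [1, 1], [2, 2]])
        assert allele_coverage(m, ["a2"]) == 100.0  # het carries both
        assert allele_coverage(m, ["a1", "a3"]) == 100.0

    def test_single_homozygote_covers_half(self):
        m = matrix_from_codes([[0, 0], [2, 2]])
        assert allele_coverage(m, ["a1"]) == 50.0

    def test_empty_core_rejected(self, small_random_matrix):
        with pytest.raises(ValidationError):
            allele_coverage(small_random_matrix, [])


class TestSelectCore:
    def test_target_equal_to_whole(self, small_random_matrix):
        m = small_random_matrix
        res = select_core(m, CoreConfig(target_fraction=1.0, seed=0))
        assert sorted(res.core_ids) == sorted(m.accession_ids)
        assert res.metrics["CV"] == 100.0

    def test_private_allele_carriers_always_selected(self):
        """Accessions that are the sole carriers of private alleles are
        forced in by the coverage constraint."""
        rng = np.random.default_rng(3)
        calls = rng.choice(
            np.array([0, 2], dtype=np.int8), size=(10, 6)
        )
        calls[:, 4] = 0
        calls[0, 4] = 2  # a1 sole carrier of alt at M5
        calls[:, 5] = 2
        calls[1, 5] = 0  # a2 sole carrier of ref at M6
        m = matrix_from_codes(calls)
        for seed in range(3):
            res = select_core(m, CoreConfig(target_count=4, seed=seed))
            assert {"a1", "a2"} <= set(res.core_ids)
            assert res.metrics["CV"] == 100.0

    def test_forced_ids_kept(self, study_panels):
        m = study_panels[1]
        forced = tuple(m.accession_ids[:3])
        res = select_core(
            m, CoreConfig(target_count=40, forced_ids=forced, seed=1)
        )
        assert set(forced) <= set(res.core_ids)
        assert len(res.core_ids) == 40

    def test_infeasible_coverage_reports_minimum(self):
        # 4 accessions each sole carrier of a private allele; coverage
        # needs all 4, so target 2 is infeasible
        calls = np.zeros((4, 4), dtype=np.int8)
        np.fill_diagonal(calls, 2)
        m = matrix_from_codes(calls)
        with pytest.raises(ValidationError, match="needs 4"):
            select_core(m, CoreConfig(target_count=2, seed=0))

    def test_swap_search_never_decreases_objective(self, study_panels):
        m = study_panels[2]
        d = pairwise_distance(m, "modified_rogers").d
        no_swaps = select_core(
            m, CoreConfig(target_count=60, max_swap_iters=0, seed=0)
        )
        with_swaps = select_core(
            m, CoreConfig(target_count=60, max_swap_iters=150, seed=0)
        )
        assert with_swaps.objective >= no_swaps.objective - 1e-12

    def test_beats_random_cores(self, study_panels):
        """The optimized core's mean entry-to-nearest-entry distance
        exceeds that of 100 random same-size cores in >=99 cases."""
        m = study_panels[1]
        res = select_core(m, CoreConfig(target_count=102, seed=1))
        d = pairwise_distance(m, "modified_rogers").d
        rng = np.random.default_rng(0)
        wins = sum(
            res.objective
            > entry_to_nearest_entry(
                d, rng.choice(m.n_accessions, 102, replace=False)
            )
            for _ in range(100)
        )
        assert wins >= 99

    def test_cv_monotone_in_target_without_swaps(self, study_panels):
        """With the nested greedy+farthest initialization (swaps off),
        coverage never decreases as the target grows."""
        m = study_panels[3].subset(
            accession_ids=study_panels[3].accession_ids[:60]
        )
        cvs = []
        for target in (5, 10, 20, 40):
            res = select_core(
                m,
                CoreConfig(
                    target_count=target,
                    require_full_coverage=False,
                    max_swap_iters=0,
                    seed=0,
                ),
            )
            cvs.append(res.metrics["CV"])
        assert cvs == sorted(cvs)

    def test_determinism(self, study_panels):
        m = study_panels[5]
        cfg = CoreConfig(target_count=50, seed=9)
        assert select_core(m, cfg).core_ids == select_core(m, cfg).core_ids

    def test_config_validation(self):
        with pytest.raises(ValidationError):
            CoreConfig(target_fraction=0.5, target_count=10)
        with pytest.raises(ValidationError):
            CoreConfig(target_fraction=0.0)
        with pytest.raises(ValidationError):
            CoreConfig(metric="euclidean")


class TestEvaluateCore:
    def test_identical_accessions_zero_distance(self):
        m = matrix_from_codes([[0, 1], [0, 1], [0, 1], [2, 0]])
        metrics = evaluate_core(m, ["a1", "a2", "a3"])
        assert metrics["MR"] == pytest.approx(0.0)

    def test_core_equals_whole_matches_panel_statistics(
        self, small_random_matrix
    ):
        from gourdcore import panel_summary, shannon_index_pooled

        m = small_random_matrix
        metrics = evaluate_core(m, m.accession_ids)
        summary = panel_summary(m)
        assert metrics["HE"] == pytest.approx(summary.mean("he"))
        assert metrics["NE"] == pytest.approx(summary.mean("ne"))
        assert metrics["PIC"] == pytest.approx(summary.mean("pic_botstein"))
        assert metrics["SH"] == pytest.approx(shannon_index_pooled(m))
        assert metrics["CV"] == 100.0

    def test_against_brute_force_recomputation(self):
        """Evaluation equals a naive per-pair / per-locus recomputation
        on an 8-accession toy, to 1e-12."""
        rng = np.random.default_rng(17)
        calls = rng.choice(
            np.array([0, 1, 2], dtype=np.int8), size=(8, 6)
        )
        m = matrix_from_codes(calls)
        core = ["a1", "a3", "a4", "a7"]
        metrics = evaluate_core(m, core)

        rows = [m.accession_index(a) for a in core]
        sub = calls[rows]
        mr_vals = []
        for (i, j) in itertools.combinations(range(len(rows)), 2):
            s = 0.0
            for l in range(sub.shape[1]):
                xa = {0: (1, 0), 1: (0.5, 0.5), 2: (0, 1)}[sub[i, l]]
                ya = {0: (1, 0), 1: (0.5, 0.5), 2: (0, 1)}[sub[j, l]]
                s += sum((x - y) ** 2 for x, y in zip(xa, ya))
            mr_vals.append(math.sqrt(s / (2 * sub.shape[1])))
        assert metrics["MR"] == pytest.approx(
            np.mean(mr_vals), abs=1e-12
        )

        hes, nes = [], []
        for l in range(sub.shape[1]):
            p = (2 * (sub[:, l] == 0).sum() + (sub[:, l] == 1).sum()) / (
                2 * len(rows)
            )
            hes.append(2 * p * (1 - p))
            nes.append(1 / (p**2 + (1 - p) ** 2))
        assert metrics["HE"] == pytest.approx(np.mean(hes), abs=1e-12)
        assert metrics["NE"] == pytest.approx(np.mean(nes), abs=1e-12)

    def test_table_row_order(self, small_random_matrix):
        m = small_random_matrix
        res = select_core(m, CoreConfig(target_fraction=0.6, seed=2))
        table = res.to_table()
        assert list(table.columns) == [
            "n_whole", "n_core", "MR", "CE", "SH", "HE", "NE", "PIC", "CV"
        ]
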