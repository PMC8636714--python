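"""Marker filtering, thinning, and greedy discriminating-panel selection."""

import itertools

import numpy as np
import pytest

from gourdcore import (
    FilterCriteria,
    Marker,
    PanelSimConfig,
    ValidationError,
    filter_markers,
    panel_capacity,
    panel_summary,
    plant_known_duplicates,
    saturation_curve,
    select_core_panel,
    simulate_structured_panel,
    thin_per_chromosome,
)

from conftest import matrix_from_codes


def _matrix_with_mafs(mafs, n=100, missing=None):
    """One column per target maf; homozygous calls only."""
    cols = []
    for k, maf in enumerate(mafs):
        n_alt = int(round(maf * n))
        col = np.array([2] * n_alt + [0] * (n - n_alt), dtype=np.int8)
        if missing is not None and missing[k] > 0:
            col[: int(round(missing[k] * n))] = -1
        cols.append(col)
    return matrix_from_codes(np.stack(cols, axis=1))


class TestFilter:
    def test_strict_maf_threshold(self):
        m = _matrix_with_mafs([0.0, 0.04, 0.05, 0.06, 0.30])
        kept, report = filter_markers(m, FilterCriteria())
        assert kept.marker_ids == ["M4", "M5"]  # strictly > 0.05 only
        assert set(report.index) == {"M1", "M2", "M3"}
        assert (report["reason"] == "maf").all()

    def test_strict_missing_threshold(self):
        m = _matrix_with_mafs([0.3, 0.3], missing=[0.05, 0.0])
        kept, report = filter_markers(m, FilterCriteria())
        assert kept.marker_ids == ["M2"]  # rate 0.05 rejected (strict <)
        assert report.loc["M1", "reason"] == "missing"

    def test_monomorphic_rejected_with_reason(self):
        m = _matrix_with_mafs([0.0, 0.25])
        _, report = filter_markers(m)
        assert report.loc["M1", "reason"] == "maf"

    def test_empty_result_allowed(self):
        m = _matrix_with_mafs([0.0, 0.01])
        kept, report = filter_markers(m)
        assert kept.n_markers == 0
        assert len(report) == 2


class TestThinning:
    def test_endpoint_anchors(self):
        mks = [Marker(f"M{p}", "1", p, "A", "T") for p in range(1, 11)]
        picked = thin_per_chromosome(mks, 2)
        assert [mk.position_bp for mk in picked] == [1, 10]

    def test_k_exceeding_candidates_returns_all(self):
        mks = [Marker(f"M{p}", "1", p, "A", "T") for p in (3, 9)]
        assert len(thin_per_chromosome(mks, 5)) == 2

    def test_evenness_under_uniform_positions(self):
        """Selected spacing stays near the ideal even grid: no adjacent
        gap exceeds twice the even spacing plus the widest hole in the
        candidate set (a marker desert no selector can fill)."""
        rng = np.random.default_rng(0)
        pos = np.sort(rng.choice(np.arange(1, 3_000_000), 300, replace=False))
        mks = [Marker(f"M{i}", "1", int(p), "A", "T")
               for i, p in enumerate(pos)]
        picked = thin_per_chromosome(mks, 100)
        assert len(picked) == 100
        ps = np.array([mk.position_bp for mk in picked])
        even_gap = (pos[-1] - pos[0]) / 99
        assert np.diff(ps).max() <= 2 * even_gap + np.diff(pos).max()

    def test_evenness_strict_on_dense_candidates(self):
        """With candidates on a jittered grid (no deserts), the strict
        2x-even-spacing bound holds."""
        rng = np.random.default_rng(1)
        grid = np.arange(300) * 10_000 + 1
        pos = grid + rng.integers(0, 2_000, size=300)
        mks = [Marker(f"M{i}", "1", int(p), "A", "T")
               for i, p in enumerate(pos)]
        picked = thin_per_chromosome(mks, 100)
        ps = np.array([mk.position_bp for mk in picked])
        even_gap = (pos[-1] - pos[0]) / 99
        assert np.diff(ps).max() <= 2 * even_gap

    def test_tie_prefers_higher_score(self):
        # single anchor at the midpoint (6) is equidistant from both
        mks = [Marker("lo", "1", 4, "A", "T"), Marker("hi", "1", 8, "A", "T")]
        picked = thin_per_chromosome(mks, 1, ranks={"hi": 1.0, "lo": 0.5})
        assert [mk.marker_id for mk in picked] == ["hi"]


def brute_force_min_panel(m):
    """Smallest marker subset resolving all pairs (exhaustive search)."""
    n, L = m.calls.shape
    pairs = list(itertools.combinations(range(n), 2))

    def resolves_all(cols):
        for i, j in pairs:
            a, b = m.calls[i, list(cols)], m.calls[j, list(cols)]
            if not (((a != b) & (a != -1) & (b != -1)).any()):
                return False
        return True

    for size in range(1, L + 1):
        for cols in itertools.combinations(range(L), size):
            if resolves_all(cols):
                return size
    return None


class TestSelectCorePanel:
    def test_two_complementary_splitters(self):
        # M1 splits {a,b}|{c,d}; M2 splits {a,c}|{b,d}; no single marker
        # resolves all 6 pairs, the pair resolves everything
        m = matrix_from_codes(
            [[0, 0], [0, 2], [2, 0], [2, 2]],
            accession_ids=list("abcd"),
        )
        assert brute_force_min_panel(m) == 2
        res = select_core_panel(m, max_per_chrom=4)
        assert sorted(res.selected) == ["M1", "M2"]
        assert res.fully_resolving
        assert res.saturation[-1] == (2, 4, 6)

    def test_planted_duplicate_reported_unresolved(self):
        m = simulate_structured_panel(
            PanelSimConfig(n_accessions=12, n_markers=10, seed=2)
        )
        ids = m.accession_ids
        planted = plant_known_duplicates(m, [(ids[0], ids[1])])
        res = select_core_panel(planted, max_per_chrom=10)
        assert not res.fully_resolving
        assert tuple(sorted((ids[0], ids[1]))) in {
            tuple(sorted(p)) for p in res.unresolved_pairs
        }

    def test_capacity_of_22_marker_panel(self):
        assert panel_capacity(22) == 31_381_059_609
        assert panel_capacity(22) == 3**22

    def test_chromosome_quota_respected(self, study_panels):
        res = select_core_panel(study_panels[1], max_per_chrom=2,
                                target_size=22)
        assert max(res.per_chromosome_counts.values()) <= 2
        assert len(res.selected) <= 22
        assert res.capacity == 3 ** len(res.selected)

    def test_greedy_matches_exhaustive_optimum_on_small_instances(self):
        """Selection never beats the exhaustive optimum and matches it in
        at least 90% of small instances drawn from the package's own
        panel generator."""
        hits = trials = 0
        for seed in range(30):
            m = simulate_structured_panel(
                PanelSimConfig(n_accessions=10, n_markers=12, seed=seed)
            )
            opt = brute_force_min_panel(m)
            res = select_core_panel(m, max_per_chrom=12)
            if opt is None:
                assert not res.fully_resolving
                continue
            trials += 1
            assert len(res.selected) >= opt  # greedy can't undercut
            assert res.fully_resolving
            hits += len(res.selected) == opt
        assert trials >= 20
        assert hits / trials >= 0.9

    def test_resolution_monotone_and_saturation_nondecreasing(
        self, study_panels
    ):
        res = select_core_panel(study_panels[2], max_per_chrom=2,
                                target_size=22)
        sizes = [s for s, _, _ in res.saturation]
        distinct = [d for _, d, _ in res.saturation]
        resolved = [r for _, _, r in res.saturation]
        assert sizes == list(range(1, len(sizes) + 1))
        assert distinct == sorted(distinct)
        assert resolved == sorted(resolved)

    def test_target_size_completes_after_resolution(self, study_panels):
        free = select_core_panel(study_panels[1], max_per_chrom=2)
        forced = select_core_panel(study_panels[1], max_per_chrom=2,
                                   target_size=22)
        assert len(free.selected) <= 22
        assert len(forced.selected) == 22
        assert set(free.selected) <= set(forced.selected)
        assert free.fully_resolving and forced.fully_resolving

    def test_empty_matrix_rejected(self):
        m = matrix_from_codes([[0], [2]])
        with pytest.raises(ValidationError):
            select_core_panel(m.subset(marker_ids=[]))


class TestSaturationCurve:
    def test_prefix_zero_is_one_class(self, small_random_matrix):
        curve = saturation_curve(small_random_matrix, [])
        assert curve == [(0, 1)]

    def test_full_panel_reaches_all_accessions(self, study_panels):
        m = study_panels[1]
        res = select_core_panel(m, max_per_chrom=2, target_size=22)
        curve = saturation_curve(m, res.selected)
        assert curve[0] == (0, 1)
        assert curve[-1] == (22, m.n_accessions)
        counts = [c for _, c in curve]
        assert counts == sorted(counts)
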