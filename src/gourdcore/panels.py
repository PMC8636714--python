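"""Candidate marker filtering, thinning, and core-panel selection.

The core procedure: from a filtered candidate set, grow a minimal,
chromosome-balanced panel of markers that jointly discriminates every pair
of accessions. A marker *resolves* a pair only when both calls are present
and differ — a missing call never fakes a difference. Selection is greedy
set cover with a per-chromosome quota: at each step the eligible marker
resolving the most currently-unresolved pairs is added, with ties broken
by higher gene diversity, then by the chromosome with fewest selected
markers, then lexicographically by marker id.

The saturation curve — distinct multilocus genotype classes as a function
of cumulative panel size — is recorded at every step. For class counting,
a missing call is its own symbol, so two accessions that differ only by
missingness form distinct classes; such fragile distinctions are surfaced
separately as ``missingness_only_pairs``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .diversity import panel_summary
from .genotypes import GenotypeMatrix, Marker, ValidationError

__all__ = [
    "FilterCriteria",
    "PanelResult",
    "filter_markers",
    "thin_per_chromosome",
    "select_core_panel",
    "saturation_curve",
    "panel_capacity",
]


def panel_capacity(n_markers: int) -> int:
    """Theoretical number of distinguishable genotypes: 3 per marker."""
    return 3**n_markers


@dataclass(frozen=True)
class FilterCriteria:
    """Candidate retention rule: MAF strictly above ``maf_min`` and
    missing rate strictly below ``missing_max``."""

    maf_min: float = 0.05
    missing_max: float = 0.05

    def __post_init__(self) -> None:
        if not (0 <= self.maf_min <= 0.5):
            raise ValidationError("maf_min must be in [0, 0.5]")
        if not (0 <= self.missing_max <= 1):
            raise ValidationError("missing_max must be in [0, 1]")


def filter_markers(
    m: GenotypeMatrix, criteria: FilterCriteria = FilterCriteria()
) -> tuple[GenotypeMatrix, pd.DataFrame]:
    """Apply the retention rule; return (filtered matrix, rejection report).

    The report has one row per rejected marker with its maf, missing rate
    and the failed criterion ("maf", "missing" or "maf+missing"). An empty
    result is allowed, not an error.
    """
    stats = panel_summary(m).per_locus
    # strict thresholds, with an epsilon so a rate exactly at the boundary
    # is rejected even when float rounding nudges it (e.g. 1 - 0.95)
    eps = 1e-9
    low_maf = stats["maf"] <= criteria.maf_min + eps
    high_missing = stats["missing_rate"] >= criteria.missing_max - eps
    rejected = low_maf | high_missing
    reasons = np.select(
        [low_maf & high_missing, low_maf, high_missing],
        ["maf+missing", "maf", "missing"],
        default="",
    )
    report = pd.DataFrame(
        {
            "maf": stats["maf"][rejected],
            "missing_rate": stats["missing_rate"][rejected],
            "reason": reasons[rejected.to_numpy()],
        },
        index=stats.index[rejected],
    )
    kept = [mid for mid, rej in zip(m.marker_ids, rejected) if not rej]
    return m.subset(marker_ids=kept), report


def thin_per_chromosome(
    markers: list[Marker],
    k_per_chrom: int,
    ranks: dict[str, float] | None = None,
) -> list[Marker]:
    """Select up to ``k_per_chrom`` markers per chromosome, as evenly
    spaced as the candidates allow.

    Per chromosome, ``k`` anchor positions are placed evenly between the
    minimum and maximum candidate positions; each anchor takes the nearest
    not-yet-chosen marker, ties broken by higher rank score then lower
    position. With at most ``k`` candidates on a chromosome, all are kept.
    """
    if k_per_chrom < 1:
        raise ValidationError("k_per_chrom must be >= 1")
    ranks = ranks or {}
    by_chrom: dict[str, list[Marker]] = {}
    for mk in markers:
        by_chrom.setdefault(mk.chromosome, []).append(mk)
    chosen: list[Marker] = []
    for chrom in by_chrom:
        cands = sorted(by_chrom[chrom], key=lambda mk: mk.position_bp)
        if len(cands) <= k_per_chrom:
            chosen.extend(cands)
            continue
        lo = cands[0].position_bp
        hi = cands[-1].position_bp
        if k_per_chrom == 1:
            anchors = [(lo + hi) / 2.0]
        else:
            anchors = list(np.linspace(lo, hi, k_per_chrom))
        taken: list[Marker] = []
        pool = list(cands)
        for anchor in anchors:
            pool.sort(
                key=lambda mk: (
                    abs(mk.position_bp - anchor),
                    -ranks.get(mk.marker_id, 0.0),
                    mk.position_bp,
                )
            )
            taken.append(pool.pop(0))
        chosen.extend(sorted(taken, key=lambda mk: mk.position_bp))
    chosen.sort(key=lambda mk: (mk.chromosome, mk.position_bp))
    return chosen


@dataclass
class PanelResult:
    """Outcome of greedy core-panel selection."""

    selected: list[str]
    #: per selection step: (panel size, distinct classes, resolved pairs)
    saturation: list[tuple[int, int, int]]
    fully_resolving: bool
    capacity: int
    per_chromosome_counts: dict[str, int]
    #: pairs no selected marker resolves (both-called difference)
    unresolved_pairs: list[tuple[str, str]]
    #: unresolved pairs whose class labels nonetheless differ via missingness
    missingness_only_pairs: list[tuple[str, str]]

    def to_dict(self) -> dict:
        return {
            "selected": self.selected,
            "saturation": [list(t) for t in self.saturation],
            "fully_resolving": self.fully_resolving,
            "capacity": self.capacity,
            "per_chromosome_counts": self.per_chromosome_counts,
            "unresolved_pairs": [list(p) for p in self.unresolved_pairs],
            "missingness_only_pairs": [
                list(p) for p in self.missingness_only_pairs
            ],
        }


def _pair_resolution_matrix(
    calls: np.ndarray,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Boolean (L, n_pairs): marker resolves pair (both called, different)."""
    n = calls.shape[0]
    i1, i2 = np.triu_indices(n, k=1)
    a = calls[i1]  # (n_pairs, L)
    b = calls[i2]
    resolves = ((a != b) & (a != -1) & (b != -1)).T  # (L, n_pairs)
    return resolves, i1, i2


def _distinct_classes(calls: np.ndarray, cols: list[int]) -> int:
    if not cols:
        return 1
    return int(np.unique(calls[:, cols], axis=0).shape[0])


def select_core_panel(
    m: GenotypeMatrix,
    max_per_chrom: int = 2,
    target_size: int | None = None,
) -> PanelResult:
    """Greedy chromosome-balanced minimal discriminating panel.

    Stops once every accession pair is resolved (or no eligible marker
    gains); in that minimal-panel mode a reverse-delete pass then drops
    markers made redundant by later picks. With ``target_size`` set,
    selection instead continues by the same rule to that size, mirroring
    a balanced fixed-size panel design.
    """
    if m.n_markers == 0 or m.n_accessions < 2:
        raise ValidationError("need a nonempty matrix with >= 2 accessions")
    if max_per_chrom < 1:
        raise ValidationError("max_per_chrom must be >= 1")
    resolves, i1, i2 = _pair_resolution_matrix(m.calls)
    he = panel_summary(m).per_locus["he"].to_numpy()
    chroms = [mk.chromosome for mk in m.markers]
    chrom_counts: dict[str, int] = {c: 0 for c in dict.fromkeys(chroms)}

    n_pairs = resolves.shape[1]
    unresolved = np.ones(n_pairs, dtype=bool)
    selected_idx: list[int] = []
    saturation: list[tuple[int, int, int]] = []
    available = np.ones(m.n_markers, dtype=bool)

    while True:
        if target_size is not None and len(selected_idx) >= target_size:
            break
        if target_size is None and not unresolved.any():
            break
        eligible = available & np.array(
            [chrom_counts[c] < max_per_chrom for c in chroms]
        )
        if not eligible.any():
            break
        gains = resolves[:, unresolved].sum(axis=1)
        gains[~eligible] = -1
        best_gain = gains.max()
        if target_size is None and best_gain <= 0:
            break
        ties = np.flatnonzero(gains == best_gain)
        j = min(
            ties,
            key=lambda j: (
                -he[j],
                chrom_counts[chroms[j]],
                m.marker_ids[j],
            ),
        )
        selected_idx.append(int(j))
        available[j] = False
        chrom_counts[chroms[j]] += 1
        unresolved &= ~resolves[j]
        saturation.append(
            (
                len(selected_idx),
                _distinct_classes(m.calls, selected_idx),
                int(n_pairs - unresolved.sum()),
            )
        )

    # minimal-panel mode: greedy picks can become redundant once later
    # markers cover their pairs; a reverse-delete pass removes any marker
    # whose pairs the rest of the panel still resolves (classic set-cover
    # clean-up, measurably closing most of greedy's optimality gap)
    if target_size is None and not unresolved.any() and len(selected_idx) > 1:
        kept = list(selected_idx)
        for j in list(selected_idx):
            trial = [c for c in kept if c != j]
            if trial and resolves[trial].any(axis=0).all():
                kept = trial
        if len(kept) < len(selected_idx):
            selected_idx = kept
            covered = np.zeros(n_pairs, dtype=bool)
            saturation = []
            for step, j in enumerate(selected_idx, start=1):
                covered |= resolves[j]
                saturation.append(
                    (
                        step,
                        _distinct_classes(m.calls, selected_idx[:step]),
                        int(covered.sum()),
                    )
                )
            chrom_counts = {c: 0 for c in dict.fromkeys(chroms)}
            for j in selected_idx:
                chrom_counts[chroms[j]] += 1

    unresolved_pairs = [
        (m.accession_ids[i1[p]], m.accession_ids[i2[p]])
        for p in np.flatnonzero(unresolved)
    ]
    # among unresolved pairs, some still land in different classes because
    # of missingness; flag those as fragile rather than silently distinct
    missingness_only = []
    if selected_idx:
        sub = m.calls[:, selected_idx]
        for p in np.flatnonzero(unresolved):
            if not np.array_equal(sub[i1[p]], sub[i2[p]]):
                missingness_only.append(
                    (m.accession_ids[i1[p]], m.accession_ids[i2[p]])
                )
    return PanelResult(
        selected=[m.marker_ids[j] for j in selected_idx],
        saturation=saturation,
        fully_resolving=not unresolved.any(),
        capacity=panel_capacity(len(selected_idx)),
        per_chromosome_counts={
            c: k for c, k in chrom_counts.items() if k > 0
        },
        unresolved_pairs=unresolved_pairs,
        missingness_only_pairs=missingness_only,
    )


def saturation_curve(
    m: GenotypeMatrix, ordered_panel: list[str]
) -> list[tuple[int, int]]:
    """Distinct multilocus classes for every prefix of an ordered panel.

    Includes the empty prefix (one class). Missing calls count as their
    own symbol, matching :func:`select_core_panel`'s class counting.
    """
    cols = [m.marker_index(mid) for mid in ordered_panel]
    curve = [(0, 1)]
    for k in range(1, len(cols) + 1):
        curve.append((k, _distinct_classes(m.calls, cols[:k])))
    return curve
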