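"""Coverage-constrained core-collection selection and its evaluation.

A core collection is a subset of accessions that preserves the genetic
diversity of the whole collection at reduced size — here under a hard
constraint of 100% allele coverage (every locus/allele combination seen in
the whole collection is carried by at least one core member) and with the
average entry-to-nearest-entry genetic distance as the quality objective,
a standard measure for spreading core entries apart.

Selection runs in three phases, deterministic under the config seed:

1. forced inclusions plus greedy allele-coverage completion (each step
   adds the accession carrying the most still-uncovered alleles);
2. farthest-point completion to the target size under the chosen metric;
3. first-improvement swap search over a shuffled in/out neighborhood,
   rejecting swaps that would break full coverage or evict forced ids.

Evaluation reports the standard diversity panel for a core: mean modified
Rogers and Cavalli-Sforza–Edwards pairwise distances, pooled Shannon
index, mean gene diversity, mean effective allele number, mean Botstein
PIC, and allele coverage (CV, %).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .diversity import (
    DistanceMatrix,
    METRICS,
    pairwise_distance,
    panel_summary,
    shannon_index_pooled,
)
from .genotypes import GenotypeMatrix, ValidationError

__all__ = [
    "CoreConfig",
    "CoreResult",
    "allele_coverage",
    "select_core",
    "evaluate_core",
    "entry_to_nearest_entry",
]


@dataclass(frozen=True)
class CoreConfig:
    """Conditions for core selection. At most one of ``target_fraction``
    and ``target_count`` sets the core size (fraction of accessions, or an
    absolute count); with neither set, half the collection is kept."""

    target_fraction: float | None = None
    target_count: int | None = None
    metric: str = "modified_rogers"
    require_full_coverage: bool = True
    forced_ids: tuple[str, ...] = ()
    n_restarts: int = 1
    max_swap_iters: int = 200
    seed: int = 0

    def __post_init__(self) -> None:
        if self.target_fraction is not None and self.target_count is not None:
            raise ValidationError(
                "set at most one of target_fraction / target_count"
            )
        if self.target_fraction is not None and not (
            0 < self.target_fraction <= 1
        ):
            raise ValidationError("target_fraction must be in (0, 1]")
        if self.target_count is not None and self.target_count < 1:
            raise ValidationError("target_count must be >= 1")
        if self.metric not in METRICS:
            raise ValidationError(f"metric must be one of {METRICS}")
        if self.n_restarts < 1 or self.max_swap_iters < 0:
            raise ValidationError("bad n_restarts / max_swap_iters")

    def resolve_target(self, n: int) -> int:
        if self.target_count is not None:
            if self.target_count > n:
                raise ValidationError(
                    f"target_count {self.target_count} exceeds collection "
                    f"size {n}"
                )
            return self.target_count
        fraction = 0.5 if self.target_fraction is None else self.target_fraction
        return max(1, round(fraction * n))


def _carrier_matrix(m: GenotypeMatrix) -> np.ndarray:
    """(n, 2L) booleans: accession carries (locus, ref) / (locus, alt)."""
    c = m.calls
    ref = (c == 0) | (c == 1)
    alt = (c == 2) | (c == 1)
    return np.concatenate([ref, alt], axis=1)


def allele_coverage(whole: GenotypeMatrix, core_ids: list[str]) -> float:
    """Percent of the whole collection's observed (locus, allele) pairs
    carried by at least one core member. Heterozygotes carry both."""
    if not core_ids:
        raise ValidationError("empty core")
    carriers = _carrier_matrix(whole)
    observed = carriers.any(axis=0)
    rows = [whole.accession_index(a) for a in core_ids]
    in_core = carriers[rows].any(axis=0)
    return float(100.0 * (in_core & observed).sum() / observed.sum())


def entry_to_nearest_entry(d: np.ndarray, members: np.ndarray) -> float:
    """Mean, over core members, of the distance to the nearest other
    member — the objective the swap search maximizes."""
    sub = d[np.ix_(members, members)].copy()
    np.fill_diagonal(sub, np.inf)
    return float(sub.min(axis=1).mean())


@dataclass
class CoreResult:
    """A selected core with its diversity evaluation (one-row table in
    the order n_whole, n_core, MR, CE, SH, HE, NE, PIC, CV)."""

    core_ids: list[str]
    metrics: dict[str, float]
    objective: float | None = None

    def to_table(self) -> pd.DataFrame:
        cols = ["n_whole", "n_core", "MR", "CE", "SH", "HE", "NE", "PIC", "CV"]
        return pd.DataFrame([{c: self.metrics[c] for c in cols}])


def evaluate_core(
    whole: GenotypeMatrix, core_ids: list[str]
) -> dict[str, float]:
    """Diversity metrics of a core subset (distances computed within the
    core; coverage computed against the whole collection)."""
    core = whole.subset(accession_ids=core_ids)
    summary = panel_summary(core)
    mr = pairwise_distance(core, "modified_rogers").mean_offdiagonal()
    ce = pairwise_distance(core, "cavalli_sforza_edwards").mean_offdiagonal()
    return {
        "n_whole": float(whole.n_accessions),
        "n_core": float(len(core_ids)),
        "MR": mr,
        "CE": ce,
        "SH": shannon_index_pooled(core),
        "HE": summary.mean("he"),
        "NE": summary.mean("ne"),
        "PIC": summary.mean("pic_botstein"),
        "CV": allele_coverage(whole, core_ids),
    }


def _greedy_cover(
    carriers: np.ndarray,
    observed: np.ndarray,
    start: list[int],
    d: np.ndarray,
    ids: list[str],
    limit: int | None,
) -> tuple[list[int], bool]:
    """Greedy completion of ``start`` to full allele coverage.

    Returns (members, covered_fully). Stops at ``limit`` members if given.
    Ties on coverage gain break toward larger mean distance to the current
    members, then lexically by id.
    """
    members = list(start)
    in_core = np.zeros(carriers.shape[0], dtype=bool)
    in_core[members] = True
    covered = (
        carriers[members].any(axis=0)
        if members
        else np.zeros(carriers.shape[1], dtype=bool)
    )
    while True:
        uncovered = observed & ~covered
        if not uncovered.any():
            return members, True
        if limit is not None and len(members) >= limit:
            return members, False
        gains = carriers[:, uncovered].sum(axis=1)
        gains[in_core] = -1
        best = gains.max()
        if best <= 0:
            return members, False
        ties = np.flatnonzero(gains == best)
        if members:
            mean_d = d[np.ix_(ties, members)].mean(axis=1)
            pick = ties[
                min(
                    range(len(ties)),
                    key=lambda t: (-mean_d[t], ids[ties[t]]),
                )
            ]
        else:
            pick = min(ties, key=lambda t: ids[t])
        pick = int(pick)
        members.append(pick)
        in_core[pick] = True
        covered |= carriers[pick]


def _swap_search(
    d: np.ndarray,
    carriers: np.ndarray,
    observed: np.ndarray,
    members: list[int],
    forced: set[int],
    require_cov: bool,
    rng: np.random.Generator,
    max_iters: int,
) -> tuple[list[int], float]:
    """Randomized improving in/out swaps; the objective never decreases.

    Each iteration scores the whole swap neighborhood at once (incremental
    nearest-entry bookkeeping makes that an O(k * n) pass), then accepts
    one improving swap drawn at random — the seeded equivalent of a
    first-improvement sweep in shuffled order. Swaps that would break full
    coverage (the outgoing member solely carries an allele the incoming
    one lacks) or evict a forced id are never candidates.
    """
    members = list(members)
    n = d.shape[0]
    k = len(members)
    obj = entry_to_nearest_entry(d, np.array(members))
    accepted = 0
    while accepted < max_iters:
        mem = np.array(members)
        outs_pos = [p for p, i in enumerate(members) if i not in forced]
        ins = np.array(sorted(set(range(n)) - set(members)))
        if not outs_pos or ins.size == 0:
            break
        S = d[np.ix_(mem, mem)].copy()
        np.fill_diagonal(S, np.inf)
        near2 = np.argsort(S, axis=1, kind="stable")[:, :2]
        nn1pos = near2[:, 0]
        nn1val = S[np.arange(k), near2[:, 0]]
        nn2val = S[np.arange(k), near2[:, 1]]
        T = d[np.ix_(ins, mem)]  # incoming-to-member distances
        tnear2 = np.argsort(T, axis=1, kind="stable")[:, :2]
        t1pos = tnear2[:, 0]
        t1val = T[np.arange(ins.size), tnear2[:, 0]]
        t2val = T[np.arange(ins.size), tnear2[:, 1]]
        counts = carriers[mem].sum(axis=0) if require_cov else None

        cand_obj = np.full((len(outs_pos), ins.size), -np.inf)
        for a, o in enumerate(outs_pos):
            keep = np.ones(k, dtype=bool)
            keep[o] = False
            # members' nearest entries after removing o and adding each in
            base = np.where(nn1pos == o, nn2val, nn1val)[keep]
            new_nn = np.minimum(base[None, :], T[:, keep])
            in_nn = np.where(t1pos == o, t2val, t1val)
            cand_obj[a] = (new_nn.sum(axis=1) + in_nn) / k
            if require_cov:
                sole = carriers[members[o]] & observed & (counts == 1)
                if sole.any():
                    feasible = carriers[ins][:, sole].all(axis=1)
                    cand_obj[a, ~feasible] = -np.inf
        improving = np.argwhere(cand_obj > obj + 1e-12)
        if improving.size == 0:
            break
        a, b = improving[rng.integers(improving.shape[0])]
        members[outs_pos[int(a)]] = int(ins[int(b)])
        obj = float(cand_obj[int(a), int(b)])
        accepted += 1
    return members, obj


def select_core(whole: GenotypeMatrix, cfg: CoreConfig) -> CoreResult:
    """Select a core subset of the configured size.

    Raises when full coverage is required but infeasible at the target
    size, reporting the (greedy) minimum feasible size.
    """
    n = whole.n_accessions
    target = cfg.resolve_target(n)
    ids = list(whole.accession_ids)
    unknown = [a for a in cfg.forced_ids if a not in set(ids)]
    if unknown:
        raise ValidationError(f"forced ids not in collection: {unknown}")
    forced_idx = [whole.accession_index(a) for a in cfg.forced_ids]
    if len(forced_idx) > target:
        raise ValidationError("more forced ids than the target size")

    dm = pairwise_distance(whole, cfg.metric)
    d = dm.d
    carriers = _carrier_matrix(whole)
    observed = carriers.any(axis=0)

    members, covered = _greedy_cover(
        carriers, observed, forced_idx, d, ids, limit=target
    )
    if cfg.require_full_coverage and not covered:
        full, ok = _greedy_cover(
            carriers, observed, forced_idx, d, ids, limit=None
        )
        need = len(full) if ok else None
        raise ValidationError(
            f"full allele coverage infeasible at target {target}; "
            f"greedy cover needs {need} accessions"
        )

    # farthest-point completion to the target size
    members = list(members)
    in_core = np.zeros(n, dtype=bool)
    in_core[members] = True
    while len(members) < target:
        if members:
            mind = d[:, members].min(axis=1)
        else:
            mind = np.zeros(n)
        mind[in_core] = -1
        best = mind.max()
        ties = np.flatnonzero(mind == best)
        pick = int(min(ties, key=lambda t: ids[t]))
        members.append(pick)
        in_core[pick] = True

    best_members, best_obj = members, entry_to_nearest_entry(
        d, np.array(members)
    )
    if cfg.max_swap_iters > 0 and target > 1 and target < n:
        seeds = np.random.SeedSequence(cfg.seed).spawn(cfg.n_restarts)
        for ss in seeds:
            rng = np.random.default_rng(ss)
            cand, obj = _swap_search(
                d,
                carriers,
                observed,
                members,
                set(forced_idx),
                cfg.require_full_coverage,
                rng,
                cfg.max_swap_iters,
            )
            if obj > best_obj + 1e-12:
                best_members, best_obj = cand, obj

    core_ids = [ids[i] for i in sorted(best_members)]
    if cfg.require_full_coverage:
        cv = allele_coverage(whole, core_ids)
        assert cv == 100.0, "optimizer returned a coverage-breaking core"
    metrics = evaluate_core(whole, core_ids)
    return CoreResult(core_ids=core_ids, metrics=metrics, objective=best_obj)
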