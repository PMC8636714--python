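"""Per-locus diversity statistics and pairwise genetic distances.

Per-locus quantities are computed over called samples only: reference
allele frequency p = (2 nAA + nAB) / (2 n_called), MAF = min(p, 1-p),
observed heterozygosity Ho = nAB / n_called, gene diversity (expected
heterozygosity) He = 2p(1-p), Botstein's polymorphism information content
PIC = 1 - (p^2 + q^2) - 2 p^2 q^2, and the effective allele number
Ne = 1 / (p^2 + q^2).

He and PIC are reported side by side deliberately. For a biallelic locus
Botstein's PIC is capped at 0.375, yet published KASP marker tables often
label 2pq (cap 0.5) as "PIC"; carrying both avoids silently redefining
either. :func:`panel_summary` therefore exposes ``he`` and ``pic_botstein``
as separate columns.

Individual-level distances treat each accession as a within-locus allele
frequency vector — (1,0) for a reference homozygote, (0.5,0.5) for a
heterozygote, (0,1) for an alternate homozygote — with pairwise deletion
of loci missing in either member:

* modified Rogers:  MR = sqrt( sum_l sum_a (x_la - y_la)^2 / (2 L') )
* Cavalli-Sforza–Edwards chord:
  CE = sqrt( sum_l sum_a (sqrt(x_la) - sqrt(y_la))^2 / (2 L') )
* Nei standard:  D = -ln( sum xy / sqrt(sum x^2 * sum y^2) )

where L' is the number of loci called in both individuals.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np
import pandas as pd

from .genotypes import GenotypeMatrix, ValidationError

__all__ = [
    "LocusStats",
    "DistanceMatrix",
    "locus_stats",
    "panel_summary",
    "PanelSummary",
    "shannon_index_pooled",
    "pairwise_distance",
    "METRICS",
]

METRICS = ("modified_rogers", "cavalli_sforza_edwards", "nei_standard")

MetricName = Literal[
    "modified_rogers", "cavalli_sforza_edwards", "nei_standard"
]


@dataclass(frozen=True)
class LocusStats:
    marker_id: str
    p_ref: float
    maf: float
    ho: float
    he: float
    pic_botstein: float
    ne: float
    missing_rate: float
    n_called: int


def _column_stats(calls: np.ndarray) -> pd.DataFrame:
    """Vectorised per-column statistics for an (n, L) call grid."""
    n = calls.shape[0]
    n_aa = (calls == 0).sum(axis=0)
    n_ab = (calls == 1).sum(axis=0)
    n_bb = (calls == 2).sum(axis=0)
    n_called = n_aa + n_ab + n_bb
    with np.errstate(divide="ignore", invalid="ignore"):
        p = (2 * n_aa + n_ab) / (2 * n_called)
        ho = n_ab / n_called
    q = 1.0 - p
    he = 2 * p * q
    pic = 1.0 - (p**2 + q**2) - 2 * p**2 * q**2
    ne = 1.0 / (p**2 + q**2)
    return pd.DataFrame(
        {
            "p_ref": p,
            "maf": np.minimum(p, q),
            "ho": ho,
            "he": he,
            "pic_botstein": pic,
            "ne": ne,
            "missing_rate": (n - n_called) / n,
            "n_called": n_called,
        }
    )


def locus_stats(m: GenotypeMatrix, marker_id: str) -> LocusStats:
    """Diversity statistics for one marker, over called samples only."""
    j = m.marker_index(marker_id)
    row = _column_stats(m.calls[:, [j]]).iloc[0]
    if row["n_called"] == 0:
        raise ValidationError(f"marker {marker_id!r}: all calls missing")
    return LocusStats(
        marker_id=marker_id,
        p_ref=float(row["p_ref"]),
        maf=float(row["maf"]),
        ho=float(row["ho"]),
        he=float(row["he"]),
        pic_botstein=float(row["pic_botstein"]),
        ne=float(row["ne"]),
        missing_rate=float(row["missing_rate"]),
        n_called=int(row["n_called"]),
    )


@dataclass(frozen=True)
class PanelSummary:
    """Per-locus table plus mean/min/max aggregates over markers."""

    per_locus: pd.DataFrame
    aggregate: pd.DataFrame

    def mean(self, stat: str) -> float:
        return float(self.aggregate.loc["mean", stat])


def panel_summary(m: GenotypeMatrix) -> PanelSummary:
    """One :class:`LocusStats` row per marker, plus means/minima/maxima."""
    if m.n_markers == 0 or m.n_accessions == 0:
        raise ValidationError("empty genotype matrix")
    per_locus = _column_stats(m.calls)
    per_locus.index = pd.Index(m.marker_ids, name="marker_id")
    dead = per_locus.index[per_locus["n_called"] == 0].tolist()
    if dead:
        raise ValidationError(f"all calls missing at markers: {dead}")
    stat_cols = [
        "p_ref", "maf", "ho", "he", "pic_botstein", "ne", "missing_rate"
    ]
    aggregate = per_locus[stat_cols].agg(["mean", "min", "max"])
    return PanelSummary(per_locus=per_locus, aggregate=aggregate)


def shannon_index_pooled(m: GenotypeMatrix) -> float:
    """Shannon diversity over alleles pooled across loci.

    Each locus contributes its two allele frequencies with weight 1/L, so
    the pooled vector sums to one over (up to) 2L alleles and the index is
    bounded by ln(2L). Zero-frequency alleles contribute nothing.
    """
    summary = panel_summary(m)
    p = summary.per_locus["p_ref"].to_numpy()
    L = len(p)
    weights = np.concatenate([p, 1.0 - p]) / L
    weights = weights[weights > 0]
    return float(-(weights * np.log(weights)).sum())


@dataclass
class DistanceMatrix:
    """Symmetric pairwise distances with labels."""

    ids: list[str]
    d: np.ndarray
    metric_name: str

    def __post_init__(self) -> None:
        self.ids = list(self.ids)
        self.d = np.asarray(self.d, dtype=float)
        n = len(self.ids)
        if self.d.shape != (n, n):
            raise ValidationError(f"distance matrix is {self.d.shape}, ids {n}")
        if not np.allclose(self.d, self.d.T, atol=1e-10):
            raise ValidationError("distance matrix is not symmetric")
        if not np.allclose(np.diag(self.d), 0.0, atol=1e-10):
            raise ValidationError("distance matrix diagonal is not zero")
        if not np.isfinite(self.d).all() or (self.d < -1e-10).any():
            raise ValidationError("distances must be finite and nonnegative")
        self.d = np.clip((self.d + self.d.T) / 2.0, 0.0, None)
        np.fill_diagonal(self.d, 0.0)

    def value(self, a: str, b: str) -> float:
        i, j = self.ids.index(a), self.ids.index(b)
        return float(self.d[i, j])

    def mean_offdiagonal(self) -> float:
        n = len(self.ids)
        iu = np.triu_indices(n, k=1)
        return float(self.d[iu].mean())

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.d, index=self.ids, columns=self.ids)

    def subset(self, ids: list[str]) -> "DistanceMatrix":
        idx = [self.ids.index(a) for a in ids]
        return DistanceMatrix(ids, self.d[np.ix_(idx, idx)], self.metric_name)


def pairwise_distance(
    m: GenotypeMatrix, metric: MetricName = "modified_rogers"
) -> DistanceMatrix:
    """All-pairs individual genetic distances under the named metric.

    Loci missing in either member of a pair are dropped for that pair
    (pairwise deletion); a pair sharing no called locus is an error, as is
    an undefined Nei distance (zero genetic identity).
    """
    if metric not in METRICS:
        raise ValidationError(f"unknown metric {metric!r}; choose from {METRICS}")
    if m.n_accessions < 2:
        raise ValidationError("need at least 2 accessions for distances")

    P = m.ref_fraction()  # (n, L) in {1, .5, 0}, NaN missing
    mask = (~np.isnan(P)).astype(float)
    A = np.nan_to_num(P)  # ref-allele component, zero-filled
    B = np.nan_to_num(1.0 - P)  # alt-allele component

    shared = mask @ mask.T  # L' per pair
    np.fill_diagonal(shared, np.inf)  # avoid 0/0 on the diagonal
    empty = np.argwhere(shared == 0)
    if empty.size:
        pairs = [
            (m.accession_ids[i], m.accession_ids[j])
            for i, j in empty
            if i < j
        ]
        raise ValidationError(f"pairs share no called loci: {pairs}")

    if metric == "modified_rogers":
        # sum_a (x-y)^2 = (px-py)^2 + (qx-qy)^2, accumulated via products
        sq = (A**2 + B**2) @ mask.T
        cross = A @ A.T + B @ B.T
        num = sq + sq.T - 2 * cross
        d = np.sqrt(np.clip(num, 0.0, None) / (2.0 * shared))
    elif metric == "cavalli_sforza_edwards":
        Ar, Br = np.sqrt(A), np.sqrt(B)
        sq = (A + B) @ mask.T  # sum over shared loci of (sqrt x)^2 terms
        cross = Ar @ Ar.T + Br @ Br.T
        num = sq + sq.T - 2 * cross
        d = np.sqrt(np.clip(num, 0.0, None) / (2.0 * shared))
    else:  # nei_standard
        jxy = A @ A.T + B @ B.T
        sq = A**2 + B**2
        jxx = sq @ mask.T  # per pair: sum over shared loci of x.x
        identity_num = jxy
        with np.errstate(divide="ignore", invalid="ignore"):
            identity = identity_num / np.sqrt(jxx * jxx.T)
        np.fill_diagonal(identity, 1.0)
        bad = np.argwhere(identity <= 0)
        if bad.size:
            pairs = [
                (m.accession_ids[i], m.accession_ids[j])
                for i, j in bad
                if i < j
            ]
            raise ValidationError(
                f"Nei distance undefined (zero identity) for pairs: {pairs}"
            )
        d = -np.log(identity)

    np.fill_diagonal(d, 0.0)
    return DistanceMatrix(list(m.accession_ids), d, metric)
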