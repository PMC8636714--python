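"""Synthetic genotype panels with the structure the analyses assume.

Two generators are provided, standing in for unreleased germplasm data:

* :func:`simulate_structured_panel` — a collection of inbred accessions
  drawn from a small number of differentiated subpopulations. Ancestral
  allele frequencies are uniform above a MAF floor and subpopulation
  frequencies follow the Balding–Nichols Beta compound with differentiation
  parameter ``fst``. Accessions are fully inbred (homozygous), with a small
  per-call residual-heterozygosity flip and a per-call missingness mask —
  the noise levels a KASP assay on inbred lines shows in practice.

* :func:`simulate_magic_panel` — a multiparent RIL population: fully
  homozygous founders, each line a per-chromosome mosaic of founder
  haplotypes with geometric block lengths measured in markers, then the
  same het/missing noise.

All randomness flows from the explicit ``seed`` via one named generator;
the same config always yields the same matrix. Subpopulation (or founder)
truth is encoded in accession ids (``S1_A0001``, ``L0001``) so tests can
recover it without a side channel.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .genotypes import GenotypeMatrix, Marker, ValidationError

__all__ = [
    "PanelSimConfig",
    "MagicSimConfig",
    "simulate_structured_panel",
    "simulate_magic_founders",
    "simulate_magic_panel",
    "plant_known_duplicates",
    "subpopulation_of",
]

#: approximate chromosome length (bp) used for marker placement
_CHROM_LEN = 30_000_000


@dataclass(frozen=True)
class PanelSimConfig:
    """Conditions for a structured inbred-collection panel.

    Defaults emulate a 206-accession germplasm collection in two
    sub-gene-pools genotyped at 93 markers over 11 chromosomes: moderate
    differentiation (fst 0.1), residual heterozygosity ~2% of calls and
    ~3% missing calls.
    """

    n_accessions: int = 206
    n_markers: int = 93
    n_chromosomes: int = 11
    n_subpops: int = 2
    fst: float = 0.1
    maf_floor: float = 0.05
    het_rate: float = 0.02
    missing_rate: float = 0.03
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_accessions < 2:
            raise ValidationError("need at least 2 accessions")
        if not (0 <= self.fst < 1):
            raise ValidationError("fst must be in [0, 1)")
        if not (0 < self.maf_floor < 0.5):
            raise ValidationError("maf_floor must be in (0, 0.5)")
        if not (0 <= self.het_rate <= 0.1):
            raise ValidationError("het_rate must be in [0, 0.1]")
        if not (0 <= self.missing_rate <= 0.1):
            raise ValidationError("missing_rate must be in [0, 0.1]")
        if min(self.n_markers, self.n_chromosomes, self.n_subpops) < 1:
            raise ValidationError("counts must be positive")


@dataclass(frozen=True)
class MagicSimConfig:
    """Conditions for a multiparent (MAGIC-like) RIL panel.

    Defaults emulate 377 recombinant inbred lines from 8 founders at the
    22-marker validation scale, with noise levels matching the published
    per-marker summaries (mean heterozygosity ~0.04, missing <=0.06).
    """

    n_founders: int = 8
    n_lines: int = 377
    n_markers: int = 22
    n_chromosomes: int = 11
    block_len_markers: float = 3.0
    het_rate: float = 0.04
    missing_rate: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_founders < 2:
            raise ValidationError("need at least 2 founders")
        if self.block_len_markers < 1:
            raise ValidationError("block_len_markers must be >= 1")
        if self.n_lines < 1 or self.n_markers < 1 or self.n_chromosomes < 1:
            raise ValidationError("counts must be positive")
        if not (0 <= self.het_rate <= 0.1):
            raise ValidationError("het_rate must be in [0, 0.1]")
        if not (0 <= self.missing_rate <= 0.1):
            raise ValidationError("missing_rate must be in [0, 0.1]")


def _make_markers(
    rng: np.random.Generator, n_markers: int, n_chromosomes: int
) -> list[Marker]:
    """Round-robin chromosome assignment, sorted random positions within."""
    chroms = [str(c + 1) for c in range(n_chromosomes)]
    assign = [chroms[j % n_chromosomes] for j in range(n_markers)]
    positions = np.empty(n_markers, dtype=np.int64)
    for chrom in chroms:
        idx = [j for j, a in enumerate(assign) if a == chrom]
        pos = np.sort(
            rng.choice(np.arange(1, _CHROM_LEN), size=len(idx), replace=False)
        )
        positions[idx] = pos
    bases = np.array(list("ACGT"))
    markers = []
    for j in range(n_markers):
        ref, alt = rng.choice(4, size=2, replace=False)
        markers.append(
            Marker(
                f"M{j + 1:04d}",
                assign[j],
                int(positions[j]),
                str(bases[ref]),
                str(bases[alt]),
            )
        )
    return markers


def _apply_noise(
    rng: np.random.Generator,
    calls: np.ndarray,
    het_rate: float,
    missing_rate: float,
) -> np.ndarray:
    calls = calls.copy()
    if het_rate > 0:
        flip = rng.random(calls.shape) < het_rate
        calls[flip] = 1
    if missing_rate > 0:
        mask = rng.random(calls.shape) < missing_rate
        calls[mask] = -1
    return calls


def nominal_frequencies(cfg: PanelSimConfig) -> np.ndarray:
    """The ancestral ref-allele frequencies a structured-panel run draws.

    Exposed so parameter-recovery checks can compare realized frequencies
    against the generator's own nominal values without replaying RNG
    internals.
    """
    rng = np.random.default_rng(cfg.seed)
    _make_markers(rng, cfg.n_markers, cfg.n_chromosomes)
    return rng.uniform(cfg.maf_floor, 1 - cfg.maf_floor, size=cfg.n_markers)


def subpopulation_of(accession_id: str) -> str:
    """Truth label encoded in a structured-panel accession id."""
    return accession_id.split("_", 1)[0]


def simulate_structured_panel(cfg: PanelSimConfig) -> GenotypeMatrix:
    """Draw a structured panel of inbred accessions.

    Per marker: ancestral frequency p0 ~ U(maf_floor, 1 - maf_floor);
    subpopulation frequencies ~ Beta(p0 (1-F)/F, (1-p0)(1-F)/F) around p0
    (degenerate at p0 when fst = 0); each accession is homozygous for the
    reference allele with its subpopulation's frequency, then het-flipped
    and missing-masked.
    """
    rng = np.random.default_rng(cfg.seed)
    markers = _make_markers(rng, cfg.n_markers, cfg.n_chromosomes)

    p0 = rng.uniform(cfg.maf_floor, 1 - cfg.maf_floor, size=cfg.n_markers)
    if cfg.fst > 0:
        scale = (1 - cfg.fst) / cfg.fst
        p_sub = rng.beta(
            p0 * scale, (1 - p0) * scale, size=(cfg.n_subpops, cfg.n_markers)
        )
    else:
        p_sub = np.tile(p0, (cfg.n_subpops, 1))

    subpop = np.arange(cfg.n_accessions) % cfg.n_subpops
    width = len(str(cfg.n_accessions))
    accession_ids = [
        f"S{subpop[i] + 1}_A{i + 1:0{width}d}" for i in range(cfg.n_accessions)
    ]
    p_ind = p_sub[subpop]  # (n, L) per-accession ref-allele frequency
    hom_ref = rng.random((cfg.n_accessions, cfg.n_markers)) < p_ind
    calls = np.where(hom_ref, 0, 2).astype(np.int8)
    calls = _apply_noise(rng, calls, cfg.het_rate, cfg.missing_rate)
    return GenotypeMatrix(accession_ids, markers, calls)


def _founder_alleles(
    rng: np.random.Generator, cfg: MagicSimConfig
) -> np.ndarray:
    """(n_founders, n_markers) alt-allele indicators, drawn per marker."""
    p0 = rng.uniform(0.1, 0.9, size=cfg.n_markers)
    return (rng.random((cfg.n_founders, cfg.n_markers)) < p0).astype(np.int8)


def simulate_magic_founders(cfg: MagicSimConfig) -> GenotypeMatrix:
    """The fully homozygous founder panel of a MAGIC simulation (no noise)."""
    rng = np.random.default_rng(cfg.seed)
    markers = _make_markers(rng, cfg.n_markers, cfg.n_chromosomes)
    alleles = _founder_alleles(rng, cfg)
    calls = (2 * alleles).astype(np.int8)
    ids = [f"F{i + 1}" for i in range(cfg.n_founders)]
    return GenotypeMatrix(ids, markers, calls)


def simulate_magic_panel(cfg: MagicSimConfig) -> GenotypeMatrix:
    """Draw a MAGIC-like RIL panel as founder-haplotype mosaics.

    Each line, on each chromosome, is a run-length mosaic of founder
    haplotypes: block lengths (in markers) are geometric with mean
    ``block_len_markers``, founders drawn uniformly per block. Lines are
    fully inbred before the het/missing noise is applied.
    """
    rng = np.random.default_rng(cfg.seed)
    markers = _make_markers(rng, cfg.n_markers, cfg.n_chromosomes)
    alleles = _founder_alleles(rng, cfg)

    by_chrom: dict[str, list[int]] = {}
    for j, mk in enumerate(markers):
        by_chrom.setdefault(mk.chromosome, []).append(j)
    # per-chromosome columns ordered by position
    for chrom in by_chrom:
        by_chrom[chrom].sort(key=lambda j: markers[j].position_bp)

    p_switch = 1.0 / cfg.block_len_markers
    founder_of = np.empty((cfg.n_lines, cfg.n_markers), dtype=np.int64)
    for i in range(cfg.n_lines):
        for cols in by_chrom.values():
            f = int(rng.integers(cfg.n_founders))
            for j in cols:
                founder_of[i, j] = f
                if rng.random() < p_switch:
                    f = int(rng.integers(cfg.n_founders))
    calls = (2 * alleles[founder_of, np.arange(cfg.n_markers)]).astype(np.int8)
    calls = _apply_noise(rng, calls, cfg.het_rate, cfg.missing_rate)
    width = len(str(cfg.n_lines))
    ids = [f"L{i + 1:0{width}d}" for i in range(cfg.n_lines)]
    return GenotypeMatrix(ids, markers, calls)


def plant_known_duplicates(
    m: GenotypeMatrix, pairs: Sequence[tuple[str, str]]
) -> GenotypeMatrix:
    """Copy the first member's genotypes over the second, per pair.

    Test fixture for discrimination analyses: the returned matrix contains
    exact duplicates that no marker subset can resolve.
    """
    calls = m.calls.copy()
    for keep, clone in pairs:
        calls[m.accession_index(clone)] = calls[m.accession_index(keep)]
    return GenotypeMatrix(list(m.accession_ids), list(m.markers), calls)
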