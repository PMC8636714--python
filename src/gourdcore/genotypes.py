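"""Genotype data model and file IO.

The single substrate of every analysis stage is a :class:`GenotypeMatrix`:
an accessions x markers grid of codominant biallelic calls (``AA``, ``AB``,
``BB`` or no-call), as produced by KASP-style fluorescence assays or
extracted from a VCF. Calls are stored as a compact ``int8`` grid; the four
call states are the members of :class:`GenotypeCall`.

Coordinates are 1-based everywhere (VCF convention); heterozygote phase is
never tracked (``AB`` == ``BA``).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "GenotypeCall",
    "Marker",
    "GenotypeMatrix",
    "ValidationError",
    "FormatError",
    "read_genotype_table",
    "write_genotype_table",
    "read_vcf",
    "write_vcf",
    "read_marker_table",
    "write_marker_table",
    "allele_count_check",
]


class ValidationError(ValueError):
    """A matrix or marker set violates a structural invariant."""


class FormatError(ValueError):
    """An input file cannot be parsed under the declared dialect."""


class GenotypeCall(enum.IntEnum):
    """One codominant biallelic call. MISSING contributes no alleles."""

    HOM_REF = 0
    HET = 1
    HOM_ALT = 2
    MISSING = -1


#: call code -> text token emitted in genotype tables
CALL_TO_TOKEN = {0: "AA", 1: "AB", 2: "BB", -1: "NA"}
#: accepted input tokens (case-insensitive); "-" and "" also mean no-call
TOKEN_TO_CALL = {
    "AA": 0,
    "AB": 1,
    "BA": 1,
    "BB": 2,
    "NA": -1,
    "-": -1,
    "": -1,
}

#: call code -> fingerprint symbol
CALL_TO_SYMBOL = {0: "A", 1: "H", 2: "B", -1: "N"}


@dataclass(frozen=True)
class Marker:
    """A biallelic SNP marker with its genomic location.

    ``primers`` optionally carries the KASP assay trio (two allele-specific
    forward primers and the common reverse primer).
    """

    marker_id: str
    chromosome: str
    position_bp: int
    allele_ref: str
    allele_alt: str
    primers: tuple[str, str, str] | None = None

    def __post_init__(self) -> None:
        if self.position_bp < 1:
            raise ValidationError(
                f"marker {self.marker_id}: position must be >= 1 (1-based), "
                f"got {self.position_bp}"
            )
        if self.allele_ref == self.allele_alt:
            raise ValidationError(
                f"marker {self.marker_id}: ref and alt alleles are identical "
                f"({self.allele_ref!r})"
            )

    @property
    def variation_type(self) -> str:
        return f"{self.allele_ref}/{self.allele_alt}"


def _placeholder_markers(marker_ids: Sequence[str]) -> list[Marker]:
    """Markers for a bare genotype table with no metadata sidecar.

    Chromosome is the unknown label "un"; positions are the 1-based column
    ranks, alleles the generic A/B pair.
    """
    return [
        Marker(mid, "un", i + 1, "A", "B") for i, mid in enumerate(marker_ids)
    ]


@dataclass
class GenotypeMatrix:
    """Accessions x markers grid of :class:`GenotypeCall` codes.

    ``calls`` is an ``(n_accessions, n_markers)`` int8 array over
    {0, 1, 2, -1}. Rows follow ``accession_ids``, columns follow
    ``markers``.
    """

    accession_ids: list[str]
    markers: list[Marker]
    calls: np.ndarray

    def __post_init__(self) -> None:
        self.accession_ids = list(self.accession_ids)
        self.markers = list(self.markers)
        self.calls = np.asarray(self.calls, dtype=np.int8)
        n, L = len(self.accession_ids), len(self.markers)
        if self.calls.shape != (n, L):
            raise ValidationError(
                f"calls grid is {self.calls.shape}, expected ({n}, {L})"
            )
        if len(set(self.accession_ids)) != n:
            dupes = _duplicates(self.accession_ids)
            raise ValidationError(f"duplicate accession ids: {dupes}")
        mids = [m.marker_id for m in self.markers]
        if len(set(mids)) != L:
            raise ValidationError(f"duplicate marker ids: {_duplicates(mids)}")
        bad = ~np.isin(self.calls, (0, 1, 2, -1))
        if bad.any():
            raise ValidationError(
                f"invalid call codes at {int(bad.sum())} cells"
            )
        self._acc_index = {a: i for i, a in enumerate(self.accession_ids)}
        self._marker_index = {m: j for j, m in enumerate(mids)}

    # -- basic introspection -------------------------------------------------

    @property
    def n_accessions(self) -> int:
        return len(self.accession_ids)

    @property
    def n_markers(self) -> int:
        return len(self.markers)

    @property
    def marker_ids(self) -> list[str]:
        return [m.marker_id for m in self.markers]

    def accession_index(self, accession_id: str) -> int:
        try:
            return self._acc_index[accession_id]
        except KeyError:
            raise KeyError(f"unknown accession id: {accession_id!r}") from None

    def marker_index(self, marker_id: str) -> int:
        try:
            return self._marker_index[marker_id]
        except KeyError:
            raise KeyError(f"unknown marker id: {marker_id!r}") from None

    def column(self, marker_id: str) -> np.ndarray:
        return self.calls[:, self.marker_index(marker_id)]

    def row(self, accession_id: str) -> np.ndarray:
        return self.calls[self.accession_index(accession_id)]

    # -- derived views -------------------------------------------------------

    def subset(
        self,
        accession_ids: Sequence[str] | None = None,
        marker_ids: Sequence[str] | None = None,
    ) -> "GenotypeMatrix":
        """Row/column subset preserving the given orders."""
        rows = (
            [self.accession_index(a) for a in accession_ids]
            if accession_ids is not None
            else slice(None)
        )
        cols = (
            [self.marker_index(m) for m in marker_ids]
            if marker_ids is not None
            else slice(None)
        )
        acc = (
            list(accession_ids)
            if accession_ids is not None
            else list(self.accession_ids)
        )
        mk = (
            [self.markers[self.marker_index(m)] for m in marker_ids]
            if marker_ids is not None
            else list(self.markers)
        )
        return GenotypeMatrix(acc, mk, self.calls[rows][:, cols].copy())

    def dosage(self) -> np.ndarray:
        """Alt-allele dosage in {0, 1, 2} as float, NaN where missing."""
        d = self.calls.astype(float)
        d[self.calls == GenotypeCall.MISSING] = np.nan
        return d

    def ref_fraction(self) -> np.ndarray:
        """Per-cell reference-allele fraction {1, 0.5, 0}, NaN missing."""
        return 1.0 - self.dosage() / 2.0

    def to_dataframe(self) -> pd.DataFrame:
        tokens = np.vectorize(CALL_TO_TOKEN.get)(self.calls)
        return pd.DataFrame(
            tokens, index=self.accession_ids, columns=self.marker_ids
        )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GenotypeMatrix):
            return NotImplemented
        return (
            self.accession_ids == other.accession_ids
            and self.markers == other.markers
            and np.array_equal(self.calls, other.calls)
        )


def _duplicates(items: Iterable[str]) -> list[str]:
    seen: set[str] = set()
    out: list[str] = []
    for x in items:
        if x in seen and x not in out:
            out.append(x)
        seen.add(x)
    return sorted(out)


def allele_count_check(m: GenotypeMatrix) -> bool:
    """Bookkeeping identity: per column, 2*nAA + nAB + 2*nBB + nAB == 2*called.

    Counting ref alleles (2 per AA, 1 per AB) plus alt alleles (1 per AB,
    2 per BB) must recover two alleles per called sample; missing calls
    contribute nothing.
    """
    c = m.calls
    n_aa = (c == 0).sum(axis=0)
    n_ab = (c == 1).sum(axis=0)
    n_bb = (c == 2).sum(axis=0)
    called = (c != -1).sum(axis=0)
    return bool(np.all(2 * n_aa + n_ab + (n_ab + 2 * n_bb) == 2 * called))


# ---------------------------------------------------------------------------
# wide CSV genotype tables
# ---------------------------------------------------------------------------


def read_genotype_table(
    path: str | Path,
    markers: Sequence[Marker] | str | Path | None = None,
) -> GenotypeMatrix:
    """Read a wide CSV genotype table (rows = accessions, cols = markers).

    Cells must be one of AA/AB/BA/BB/NA/-/"" (case-insensitive); anything
    else raises :class:`FormatError` rather than being coerced to missing.
    ``markers`` optionally supplies marker metadata (a list or a marker TSV
    path); header ids must then match. Without it, placeholder metadata is
    attached (unknown chromosome, rank positions, A/B alleles).
    """
    path = Path(path)
    try:
        df = pd.read_csv(
            path, index_col=0, dtype=str, keep_default_na=False, header=0
        )
    except pd.errors.ParserError as exc:  # ragged rows etc.
        raise FormatError(f"{path}: {exc}") from exc
    marker_ids = [str(c) for c in df.columns]
    accession_ids = [str(i) for i in df.index]
    if len(set(accession_ids)) != len(accession_ids):
        raise ValidationError(
            f"{path}: duplicate accession ids: {_duplicates(accession_ids)}"
        )
    if len(set(marker_ids)) != len(marker_ids):
        raise ValidationError(
            f"{path}: duplicate marker ids: {_duplicates(marker_ids)}"
        )

    raw = df.to_numpy(dtype=object)
    calls = np.empty(raw.shape, dtype=np.int8)
    for (i, j), cell in np.ndenumerate(raw):
        token = str(cell).strip().upper()
        try:
            calls[i, j] = TOKEN_TO_CALL[token]
        except KeyError:
            raise FormatError(
                f"{path}: unparseable genotype {cell!r} for accession "
                f"{accession_ids[i]!r}, marker {marker_ids[j]!r}"
            ) from None

    if markers is None:
        marker_list = _placeholder_markers(marker_ids)
    else:
        if isinstance(markers, (str, Path)):
            markers = read_marker_table(markers)
        by_id = {mk.marker_id: mk for mk in markers}
        missing = [mid for mid in marker_ids if mid not in by_id]
        if missing:
            raise ValidationError(
                f"{path}: markers absent from metadata: {missing}"
            )
        marker_list = [by_id[mid] for mid in marker_ids]
    return GenotypeMatrix(accession_ids, marker_list, calls)


def write_genotype_table(m: GenotypeMatrix, path: str | Path) -> None:
    """Write the wide CSV dialect read by :func:`read_genotype_table`."""
    m.to_dataframe().to_csv(Path(path), index_label="accession")


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------


def read_vcf(
    path: str | Path, skip_log: list[tuple[str, str]] | None = None
) -> GenotypeMatrix:
    """Read biallelic SNP records with GT fields from a VCF.

    GT mapping: 0/0 -> HOM_REF, 0/1 or 1/0 -> HET, 1/1 -> HOM_ALT,
    ./. -> MISSING. Multiallelic records are rejected, not split; each
    rejection is appended to ``skip_log`` as ``(record, reason)``.
    """
    from cyvcf2 import VCF

    path = Path(path)
    vcf = VCF(str(path))
    samples = list(vcf.samples)
    if not samples:
        raise FormatError(f"{path}: VCF has no sample columns")
    markers: list[Marker] = []
    columns: list[np.ndarray] = []
    for v in vcf:
        label = v.ID if v.ID not in (None, ".") else f"{v.CHROM}_{v.POS}"
        if len(v.ALT) != 1:
            if skip_log is not None:
                skip_log.append((label, f"multiallelic ALT={','.join(v.ALT)}"))
            continue
        if len(v.REF) != 1 or len(v.ALT[0]) != 1:
            if skip_log is not None:
                skip_log.append((label, "not a SNP"))
            continue
        if v.FORMAT is None or "GT" not in v.FORMAT:
            raise FormatError(f"{path}: record {label} has no GT format field")
        # cyvcf2 gt_types: 0=hom-ref, 1=het, 2=unknown, 3=hom-alt
        gt = np.asarray(v.gt_types)
        col = np.full(len(samples), -1, dtype=np.int8)
        col[gt == 0] = 0
        col[gt == 1] = 1
        col[gt == 3] = 2
        markers.append(Marker(label, str(v.CHROM), int(v.POS), v.REF, v.ALT[0]))
        columns.append(col)
    vcf.close()
    if not columns:
        calls = np.empty((len(samples), 0), dtype=np.int8)
    else:
        calls = np.stack(columns, axis=1)
    return GenotypeMatrix(samples, markers, calls)


_GT_STRINGS = {0: "0/0", 1: "0/1", 2: "1/1", -1: "./."}


def write_vcf(m: GenotypeMatrix, path: str | Path) -> None:
    """Write a minimal GT-only VCF (one biallelic SNP record per marker)."""
    path = Path(path)
    order = sorted(
        range(m.n_markers),
        key=lambda j: (m.markers[j].chromosome, m.markers[j].position_bp),
    )
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for chrom in dict.fromkeys(m.markers[j].chromosome for j in order):
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(m.accession_ids)
            + "\n"
        )
        for j in order:
            mk = m.markers[j]
            gts = "\t".join(_GT_STRINGS[int(c)] for c in m.calls[:, j])
            fh.write(
                f"{mk.chromosome}\t{mk.position_bp}\t{mk.marker_id}\t"
                f"{mk.allele_ref}\t{mk.allele_alt}\t.\t.\t.\tGT\t{gts}\n"
            )


# ---------------------------------------------------------------------------
# marker metadata tables
# ---------------------------------------------------------------------------

_MARKER_COLUMNS = ["Name", "Chromosome", "Position", "Variation type", "F1", "F2", "R"]


def write_marker_table(markers: Sequence[Marker], path: str | Path) -> None:
    """Write marker metadata as TSV (KASP assay-table schema).

    Columns: Name, Chromosome, Position, Variation type (ref/alt), and the
    primer trio F1/F2/R (empty when no primers are attached).
    """
    if not markers:
        raise ValidationError("refusing to write an empty marker table")
    rows = []
    for mk in markers:
        f1, f2, r = mk.primers if mk.primers is not None else ("", "", "")
        rows.append(
            {
                "Name": mk.marker_id,
                "Chromosome": mk.chromosome,
                "Position": mk.position_bp,
                "Variation type": mk.variation_type,
                "F1": f1,
                "F2": f2,
                "R": r,
            }
        )
    pd.DataFrame(rows, columns=_MARKER_COLUMNS).to_csv(
        Path(path), sep="\t", index=False
    )


def read_marker_table(path: str | Path) -> list[Marker]:
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing_cols = [c for c in _MARKER_COLUMNS[:4] if c not in df.columns]
    if missing_cols:
        raise FormatError(f"{path}: missing columns {missing_cols}")
    markers = []
    for _, row in df.iterrows():
        vt = str(row["Variation type"])
        if "/" not in vt:
            raise FormatError(f"{path}: bad variation type {vt!r}")
        ref, alt = vt.split("/", 1)
        primers = None
        if {"F1", "F2", "R"} <= set(df.columns):
            trio = (str(row["F1"]), str(row["F2"]), str(row["R"]))
            if any(trio):
                primers = trio
        markers.append(
            Marker(
                str(row["Name"]),
                str(row["Chromosome"]),
                int(row["Position"]),
                ref,
                alt,
                primers,
            )
        )
    return markers
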