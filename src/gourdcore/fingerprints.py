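"""Multilocus fingerprints, duplicate detection, and seed authentication.

A fingerprint is the ordered string of per-marker genotype symbols over a
panel — ``A`` (reference homozygote), ``H`` (heterozygote), ``B``
(alternate homozygote), ``N`` (no call). The string doubles as a
Code128-compatible barcode payload for labelling seed lots; over n markers
there are exactly 3**n possible complete (N-free) codes.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .genotypes import CALL_TO_SYMBOL, GenotypeMatrix, ValidationError

__all__ = [
    "Fingerprint",
    "AuthReport",
    "PurityReport",
    "fingerprint",
    "fingerprint_all",
    "fingerprint_table",
    "find_duplicates",
    "authenticate",
    "hybrid_purity",
]

_SYMBOL_TO_CALL = {v: k for k, v in CALL_TO_SYMBOL.items()}


@dataclass(frozen=True)
class Fingerprint:
    accession_id: str
    panel_marker_ids: tuple[str, ...]
    code: str

    def __post_init__(self) -> None:
        if len(self.code) != len(self.panel_marker_ids):
            raise ValidationError(
                f"{self.accession_id}: code length {len(self.code)} != "
                f"panel size {len(self.panel_marker_ids)}"
            )
        bad = set(self.code) - set("AHBN")
        if bad:
            raise ValidationError(
                f"{self.accession_id}: invalid symbols {sorted(bad)}"
            )

    @property
    def payload(self) -> str:
        """Barcode text payload: the code string itself."""
        return self.code


def fingerprint(
    m: GenotypeMatrix, panel: Sequence[str], accession_id: str
) -> Fingerprint:
    """Build one accession's code over the panel, in panel order."""
    row = m.row(accession_id)
    cols = [m.marker_index(mid) for mid in panel]
    code = "".join(CALL_TO_SYMBOL[int(row[j])] for j in cols)
    return Fingerprint(accession_id, tuple(panel), code)


def fingerprint_all(
    m: GenotypeMatrix, panel: Sequence[str]
) -> list[Fingerprint]:
    return [fingerprint(m, panel, acc) for acc in m.accession_ids]


def fingerprint_table(fps: Iterable[Fingerprint]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {"accession_id": fp.accession_id, "code": fp.code,
             "payload": fp.payload}
            for fp in fps
        ]
    )


def _check_same_panel(fps: Sequence[Fingerprint]) -> tuple[str, ...]:
    panels = {fp.panel_marker_ids for fp in fps}
    if len(panels) > 1:
        raise ValidationError("fingerprints are not all on the same panel")
    return next(iter(panels))


def find_duplicates(
    fps: Sequence[Fingerprint],
    max_mismatch: int = 0,
    ignore_missing: bool = True,
) -> list[list[str]]:
    """Group near-identical fingerprints by single linkage.

    Two fingerprints are linked when their codes differ at no more than
    ``max_mismatch`` compared positions; with ``ignore_missing`` (default)
    a position is compared only when neither symbol is ``N``. Returns
    groups of two or more accession ids, each group sorted, groups sorted
    by first member.
    """
    _check_same_panel(fps)
    n = len(fps)
    parent = list(range(n))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    codes = [np.frombuffer(fp.code.encode(), dtype="S1") for fp in fps]
    for i in range(n):
        for j in range(i + 1, n):
            a, b = codes[i], codes[j]
            if ignore_missing:
                cmp = (a != b"N") & (b != b"N")
                mism = int(((a != b) & cmp).sum())
            else:
                mism = int((a != b).sum())
            if mism <= max_mismatch:
                parent[find(i)] = find(j)
    groups: dict[int, list[str]] = {}
    for i, fp in enumerate(fps):
        groups.setdefault(find(i), []).append(fp.accession_id)
    out = [sorted(g) for g in groups.values() if len(g) > 1]
    return sorted(out, key=lambda g: g[0])


@dataclass(frozen=True)
class AuthReport:
    """Outcome of a sample-vs-reference identity check."""

    n_compared: int
    n_match: int
    n_mismatch: int
    match_rate: float
    verdict: str  # match | mismatch | inconclusive


def authenticate(
    sample: Fingerprint,
    reference: Fingerprint,
    completeness_floor: float = 0.8,
) -> AuthReport:
    """Compare a sample's code with a reference variety's code.

    Only loci called in both are compared. Verdict is ``match`` when there
    is no mismatch and at least ``floor(completeness_floor * panel size)``
    loci were comparable; ``inconclusive`` below that floor; ``mismatch``
    otherwise.
    """
    panel = _check_same_panel([sample, reference])
    a = np.frombuffer(sample.code.encode(), dtype="S1")
    b = np.frombuffer(reference.code.encode(), dtype="S1")
    cmp = (a != b"N") & (b != b"N")
    n_compared = int(cmp.sum())
    n_mismatch = int(((a != b) & cmp).sum())
    n_match = n_compared - n_mismatch
    floor = int(np.floor(completeness_floor * len(panel)))
    if n_compared < floor:
        verdict = "inconclusive"
    elif n_mismatch == 0:
        verdict = "match"
    else:
        verdict = "mismatch"
    rate = n_match / n_compared if n_compared else float("nan")
    return AuthReport(n_compared, n_match, n_mismatch, rate, verdict)


@dataclass(frozen=True)
class PurityReport:
    """Hybrid seed-lot purity from parent-diagnostic loci."""

    diagnostic_markers: tuple[str, ...]
    n_seeds: int
    n_evaluated: int  # seeds with at least one called diagnostic locus
    n_true_hybrid: int
    n_selfed_parent1: int
    n_selfed_parent2: int
    n_offtype: int
    purity: float


def hybrid_purity(
    lot: GenotypeMatrix,
    parent1: Fingerprint,
    parent2: Fingerprint,
    panel: Sequence[str] | None = None,
    het_fraction: float = 1.0,
) -> PurityReport:
    """Score an F1 seed lot against its two parents.

    Diagnostic loci are those where the parents are opposite homozygotes;
    a true F1 is heterozygous there. A seed counts as a true hybrid when
    it is ``H`` at at least ``het_fraction`` of its called diagnostic loci
    (default: all of them); a seed homozygous like one parent across all
    its called diagnostic loci is classed as selfed toward that parent,
    anything else as off-type. Purity is true hybrids over seeds with at
    least one called diagnostic locus.
    """
    if panel is None:
        panel = list(parent1.panel_marker_ids)
    if tuple(panel) != _check_same_panel([parent1, parent2]):
        raise ValidationError("parents are not fingerprinted on this panel")
    p1 = np.frombuffer(parent1.code.encode(), dtype="S1")
    p2 = np.frombuffer(parent2.code.encode(), dtype="S1")
    hom = np.isin(p1, (b"A", b"B")) & np.isin(p2, (b"A", b"B"))
    diag = hom & (p1 != p2)
    diag_markers = tuple(mid for mid, d in zip(panel, diag) if d)
    if not diag_markers:
        raise ValidationError(
            "parents share genotypes at every panel locus; no diagnostic "
            "loci — extend the panel to distinguish these parents"
        )
    cols = [lot.marker_index(mid) for mid in diag_markers]
    p1_calls = np.array(
        [_SYMBOL_TO_CALL[p1[j].decode()] for j in np.flatnonzero(diag)],
        dtype=np.int8,
    )
    n_hybrid = n_self1 = n_self2 = n_off = n_eval = 0
    for i in range(lot.n_accessions):
        calls = lot.calls[i, cols]
        called = calls != -1
        k = int(called.sum())
        if k == 0:
            continue
        n_eval += 1
        n_het = int((calls[called] == 1).sum())
        if n_het >= het_fraction * k:
            n_hybrid += 1
        elif np.array_equal(calls[called], p1_calls[called]):
            n_self1 += 1
        elif np.array_equal(calls[called], 2 - p1_calls[called]):
            n_self2 += 1
        else:
            n_off += 1
    return PurityReport(
        diagnostic_markers=diag_markers,
        n_seeds=lot.n_accessions,
        n_evaluated=n_eval,
        n_true_hybrid=n_hybrid,
        n_selfed_parent1=n_self1,
        n_selfed_parent2=n_self2,
        n_offtype=n_off,
        purity=n_hybrid / n_eval if n_eval else float("nan"),
    )
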