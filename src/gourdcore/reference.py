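"""Published reference data for the 22-marker bottle gourd core SNP set.

:data:`CORE_MARKERS` carries the released KASP assay table for the core
set — marker names C1..C22, two per chromosome across the 11 bottle gourd
chromosomes, with 1-based positions, the allele pair, and the primer trio
(two allele-specific forward primers and the common reverse).

:data:`magic_diversity_reference` returns the published per-marker
diversity indices of the core set scored on the 377-line MAGIC validation
population: the reported "PIC" (which matches gene diversity 2pq, not
Botstein's statistic — see :mod:`gourdcore.diversity`), MAF, observed
heterozygosity, and missing-call rate.
"""

from __future__ import annotations

import pandas as pd

from .genotypes import Marker

__all__ = ["CORE_MARKERS", "magic_diversity_reference"]

_M = Marker

CORE_MARKERS: list[Marker] = [
    _M("C1", "1", 8431159, "A", "T", (
        "GAAGGTGACCAAGTTCATGCTGCTAAAGAGTTTAACTGGTTAATCTTAGATA",
        "GAAGGTCGGAGTCAACGGATTGCTAAAGAGTTTAACTGGTTAATCTTAGATT",
        "CTAATGGACCTACAAATCATGAACTCCAA")),
    _M("C2", "1", 14051095, "T", "A", (
        "GAAGGTGACCAAGTTCATGCTTCAATGTCCTGATCTTGTTGTCATCTT",
        "GAAGGTCGGAGTCAACGGATTTCAATGTCCTGATCTTGTTGTCATCTA",
        "TTTCATATAACATGGACCTTGGATGGTTATA")),
    _M("C3", "2", 589455, "T", "C", (
        "GAAGGTGACCAAGTTCATGCTTATATTAGGTTTAAATGCTACTTTGGTCCT",
        "GAAGGTCGGAGTCAACGGATTTATTAGGTTTAAATGCTACTTTGGTCCC",
        "GGACCAAAGTGAACCAAAACCAAAAGTATA")),
    _M("C4", "2", 15914116, "G", "A", (
        "GAAGGTGACCAAGTTCATGCTAAATTTTGTTAAACTCGTTTCCGTTCATAG",
        "GAAGGTCGGAGTCAACGGATTGAAATTTTGTTAAACTCGTTTCCGTTCATAA",
        "TAACCTCAAAGTTCTAAACTCAAAATTATTCTTTA")),
    _M("C5", "3", 3421007, "A", "T", (
        "GAAGGTGACCAAGTTCATGCTGTGGCCTCACCCACTATTTTTCAAA",
        "GAAGGTCGGAGTCAACGGATTGTGGCCTCACCCACTATTTTTCAAT",
        "GTATTGTGTATTTTGTGTTATCTGATTGTTATATTT")),
    _M("C6", "3", 28241399, "T", "C", (
        "GAAGGTGACCAAGTTCATGCTTAGTAGTCTTAGTGATCTCGAAGGAAT",
        "GAAGGTCGGAGTCAACGGATTGTAGTCTTAGTGATCTCGAAGGAAC",
        "TTCGAGATCACTATGACTGCCATGATAT")),
    _M("C7", "4", 5104280, "T", "C", (
        "GAAGGTGACCAAGTTCATGCTGAGACATGTGGCATTTTTTTAGTTT",
        "GAAGGTCGGAGTCAACGGATTGAGACATGTGGCATTTTTTTAGTTC",
        "CCATGTCATTACAACGAAAGTCC")),
    _M("C8", "4", 20784251, "C", "A", (
        "GAAGGTGACCAAGTTCATGCTCCGGACCTGTTCACTTCATCAC",
        "GAAGGTCGGAGTCAACGGATTGCCGGACCTGTTCACTTCATCAA",
        "GATTCAGCTACGCCGCCGTCAA")),
    _M("C9", "5", 1706273, "C", "T", (
        "GAAGGTGACCAAGTTCATGCTGAGAAGATCAATAGAAACCCC",
        "GAAGGTCGGAGTCAACGGATTGAGAAGATCAATAGAAACCCT",
        "CCTGTGCCTGATGCTCATGTCC")),
    _M("C10", "5", 27139793, "T", "C", (
        "GAAGGTGACCAAGTTCATGCTGTTCCCACTACCACTAGGCCAAT",
        "GAAGGTCGGAGTCAACGGATTTTCCCACTACCACTAGGCCAAC",
        "AGTGTATTAAATTAAAGAAGCATTTAAACCATCAT")),
    _M("C11", "6", 1594854, "A", "G", (
        "GAAGGTGACCAAGTTCATGCTGAGCTTAACTTGCTATGCACCTAGA",
        "GAAGGTCGGAGTCAACGGATTAGCTTAACTTGCTATGCACCTAGG",
        "CCATTAAGAGGGAGTCTCACATCTAAAA")),
    _M("C12", "6", 5974943, "G", "A", (
        "GAAGGTGACCAAGTTCATGCTGTACTATTGTCAATTATACATGCTGAGG",
        "GAAGGTCGGAGTCAACGGATTGTACTATTGTCAATTATACATGCTGAGA",
        "GACCGACTCTCTCAACCATATCCAT")),
    _M("C13", "7", 11605465, "T", "C", (
        "GAAGGTGACCAAGTTCATGCTTCGATGGTGTTCGTGATGAGACT",
        "GAAGGTCGGAGTCAACGGATTCGATGGTGTTCGTGATGAGACC",
        "CATATTGCCCATGAGGTGAGGCTT")),
    _M("C14", "7", 23829758, "T", "C", (
        "GAAGGTGACCAAGTTCATGCTGGATAGATGGGGATCAGCT",
        "GAAGGTCGGAGTCAACGGATTGGATAGATGGGGATCAGCC",
        "AAAAACTTGCATTGCGAACTCC")),
    _M("C15", "8", 20000834, "A", "G", (
        "GAAGGTGACCAAGTTCATGCTCCACTCTACCCACCCGAGGA",
        "GAAGGTCGGAGTCAACGGATTCACTCTACCCACCCGAGGG",
        "GTAATGTTGTTGCTCATTCTTCGGCTTAAA")),
    _M("C16", "8", 22529614, "T", "C", (
        "GAAGGTGACCAAGTTCATGCTGTGGACTGTTAATGTACCCATGTGAT",
        "GAAGGTCGGAGTCAACGGATTTGGACTGTTAATGTACCCATGTGAC",
        "TAGAGCATCATATCAATCACAGGCCTAA")),
    _M("C17", "9", 10095406, "T", "C", (
        "GAAGGTGACCAAGTTCATGCTTTGCAAATTCCTCCCAAATTGAGTAGT",
        "GAAGGTCGGAGTCAACGGATTGCAAATTCCTCCCAAATTGAGTAGC",
        "CTAGGGTACTACTCATGATTCTATCTCTT")),
    _M("C18", "9", 18607803, "A", "G", (
        "GAAGGTGACCAAGTTCATGCTTTGCATACTATCGATTGTAAGAAGGAAAAA",
        "GAAGGTCGGAGTCAACGGATTGCATACTATCGATTGTAAGAAGGAAAAG",
        "CAACGCTCTTGCCAGTAATTCTTTGATT")),
    _M("C19", "10", 2343761, "C", "A", (
        "GAAGGTGACCAAGTTCATGCTTCGTTGATGGGTGACGGTAAATTTC",
        "GAAGGTCGGAGTCAACGGATTTATCGTTGATGGGTGACGGTAAATTTA",
        "GACCAAACACACATATTGTTAGATGATATAATAA")),
    _M("C20", "10", 4261004, "T", "C", (
        "GAAGGTGACCAAGTTCATGCTCAGCTTATGTTTCCTGTTCTAGT",
        "GAAGGTCGGAGTCAACGGATTCAGCTTATGTTTCCTGTTCTAGC",
        "AGAGAACTCAAGATCACCTCCCAAGT")),
    _M("C21", "11", 14865743, "G", "T", (
        "GAAGGTGACCAAGTTCATGCTATAGTTTGATCTAGAATTGTTTGTAATAATTTG",
        "GAAGGTCGGAGTCAACGGATTGATAGTTTGATCTAGAAATTGTTTGTAATATTT",
        "ACAAACATTAGAAACTTTTACAACTTACACACTT")),
    _M("C22", "11", 15431610, "G", "A", (
        "GAAGGTGACCAAGTTCATGCTATTCTAATACTTTGAGAATACAAACTCTTTTTG",
        "GAAGGTCGGAGTCAACGGATTATTCTAATACTTTGAGAATACAAACTCTTTTTA",
        "GCCAATGAAATAGAAATAATATATCACATGTAAAAT")),
]

# per-marker (reported PIC, MAF, observed het, missing rate) on the
# 377-line MAGIC validation population
_MAGIC_ROWS = [
    ("C1", 0.50, 0.45, 0.05, 0.02),
    ("C2", 0.24, 0.14, 0.03, 0.06),
    ("C3", 0.50, 0.45, 0.06, 0.01),
    ("C4", 0.46, 0.35, 0.06, 0.02),
    ("C5", 0.49, 0.44, 0.05, 0.01),
    ("C6", 0.22, 0.12, 0.02, 0.01),
    ("C7", 0.46, 0.35, 0.10, 0.01),
    ("C8", 0.45, 0.34, 0.06, 0.00),
    ("C9", 0.32, 0.20, 0.01, 0.06),
    ("C10", 0.29, 0.18, 0.06, 0.01),
    ("C11", 0.49, 0.42, 0.06, 0.02),
    ("C12", 0.33, 0.21, 0.01, 0.01),
    ("C13", 0.39, 0.27, 0.04, 0.02),
    ("C14", 0.48, 0.39, 0.08, 0.03),
    ("C15", 0.37, 0.24, 0.06, 0.01),
    ("C16", 0.47, 0.38, 0.05, 0.02),
    ("C17", 0.50, 0.47, 0.01, 0.01),
    ("C18", 0.50, 0.46, 0.00, 0.00),
    ("C19", 0.28, 0.17, 0.07, 0.02),
    ("C20", 0.49, 0.42, 0.09, 0.02),
    ("C21", 0.12, 0.07, 0.01, 0.06),
    ("C22", 0.14, 0.07, 0.00, 0.00),
]


def magic_diversity_reference() -> pd.DataFrame:
    """Published per-marker diversity indices of the core set on the
    MAGIC population, indexed by marker id."""
    df = pd.DataFrame(
        _MAGIC_ROWS,
        columns=["marker_id", "pic_reported", "maf", "ho", "missing_rate"],
    )
    return df.set_index("marker_id")
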