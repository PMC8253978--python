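"""The published three-subtype REO biomarker ensemble.

The typeset table lists, per subtype, the gene expected higher and the gene
expected lower in each pair: a single pair (MT-ND5, RPS27) defines the
subtype-1 biomarker, 21 pairs define subtype 2, and 19 define subtype 3.
The flat symbol sequence below is transcribed from the publication's table
region in reading order; pairs are reconstructed from the six-column
row-major layout (row 1 carries one pair for each subtype; rows 2-19 carry
subtype-2 and subtype-3 pairs; rows 20-21 subtype-2 only).

Provenance caveat: the subtype-1 pair and the per-subtype pair counts
(1, 21, 19) are stated unambiguously in the running text; the exact
pairing of subtype-2 and subtype-3 columns is inferred from the layout
(``PAIR_PROVENANCE`` records which is which).
"""

from __future__ import annotations

from .classifier import Biomarker, ClassifierEnsemble
from .pairs import DirectedGenePair

__all__ = ["load_fixture_table1", "PAIR_PROVENANCE"]

# Reading-order gene symbols of the published table (82 = 2 * (1 + 21 + 19)).
_SYMBOLS = [
    "MT-ND5", "RPS27", "LRP2", "BOLA3", "BCL2L12", "OPA3",
    "EHHADH", "NDUFA4", "RCC1", "ACOX1",
    "RANBP2", "TPST2", "TARBP2", "CLCN5",
    "LRP2", "CCDC58", "RCC1", "MARK2",
    "MAP7", "MMAB", "ZNF581", "SLC22A11",
    "FRYL", "OSBPL3", "NOB1", "PCCA",
    "ITGA6", "NDUFA4", "ZNF581", "CRY2",
    "GAREM1", "MGME1", "SEMA4B", "RAPGEF2",
    "KIAA1671", "GGCT", "NLE1", "CLCN5",
    "LRP2", "TSR3", "HSCB", "GAREM1",
    "MAP7", "C12orf45", "IFT20", "HIBCH",
    "LRP2", "ATXN2L", "S100A3", "CDADC1",
    "ILK", "MRPS24", "FBXW9", "C1orf210",
    "TOPORS", "C12orf73", "C19orf48", "ANKIB1",
    "TLN2", "MECR", "STEAP3", "SLC17A1",
    "EHHADH", "BUD31", "RPL39L", "CLCN5",
    "DDAH1", "TIMM13", "PYM1", "HIBCH",
    "LRP2", "IFT22", "USE1", "PCCA",
    "EPHA4", "NEURL2", "SAT2", "SLC22A11",
    "BPNT1", "GGCT", "EPHA4", "PRELID3A",
]

PAIR_PROVENANCE = {
    "1": "stated in running text",
    "2": "inferred from table layout",
    "3": "inferred from table layout",
}


def _decode() -> tuple[list, list, list]:
    s = _SYMBOLS
    sub1 = [(s[0], s[1])]
    sub2, sub3 = [(s[2], s[3])], [(s[4], s[5])]
    p = 6
    for _ in range(18):  # rows 2-19: one subtype-2 and one subtype-3 pair each
        sub2.append((s[p], s[p + 1]))
        sub3.append((s[p + 2], s[p + 3]))
        p += 4
    for _ in range(2):   # rows 20-21: subtype-2 only
        sub2.append((s[p], s[p + 1]))
        p += 2
    assert p == len(s)
    return sub1, sub2, sub3


def load_fixture_table1() -> ClassifierEnsemble:
    """The published ensemble: 1, 21, and 19 pairs for subtypes 1, 2, 3."""
    sub1, sub2, sub3 = _decode()
    biomarkers = {
        name: Biomarker(subtype=name,
                        pairs=[DirectedGenePair(hi, lo) for hi, lo in pairs])
        for name, pairs in (("1", sub1), ("2", sub2), ("3", sub3))
    }
    return ClassifierEnsemble(biomarkers=biomarkers, application_order=["1", "2", "3"])
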