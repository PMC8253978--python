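"""Overlap and directional concordance of two differential-expression lists.

Two DEG lists drawn from a background of L commonly measured genes, with
L1 and L2 entries, share k genes of which s agree in dysregulation
direction. The concordance score is s/k, and the chance of observing at
least s consistent genes is scored by the cumulative hypergeometric tail

    P = 1 - sum_{i=0}^{s-1} C(L2, i) C(L - L2, L1 - i) / C(L, L1).

Note the tail variable: the published formula indexes the overlap
distribution (parameterized by L, L1, L2) by the consistency count s. It is
implemented exactly as printed; ``binomial_alternative`` offers a
sign-test-style sensitivity check (s successes in k trials at p0 = 1/2)
that is never used by default.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd
from scipy import stats

__all__ = [
    "DEGList",
    "ConcordanceResult",
    "hypergeom_tail",
    "concordance",
    "read_deg_tsv",
    "write_deg_tsv",
]


@dataclass
class DEGList:
    """Directed DEG calls against a background universe of size L."""

    entries: dict[str, int]  # gene_id -> +1 (up) or -1 (down)
    universe_size: int
    fdr: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        bad = {g: d for g, d in self.entries.items() if d not in (+1, -1)}
        if bad:
            raise ValueError(f"directions must be +/-1; offenders: {dict(list(bad.items())[:3])}")
        if self.universe_size < len(self.entries):
            raise ValueError(
                f"universe_size {self.universe_size} < number of DEGs {len(self.entries)}"
            )

    def __len__(self) -> int:
        return len(self.entries)


@dataclass
class ConcordanceResult:
    k: int        # overlapping genes
    s: int        # direction-consistent overlap
    score: float  # s / k
    p_value: float


def hypergeom_tail(L: int, L1: int, L2: int, s: int) -> float:
    """P(X >= s) for X ~ Hypergeom(L, L2, L1), as the printed formula.

    s = 0 gives 1; s beyond min(L1, L2) gives 0. Computed through scipy's
    log-space survival function.
    """
    for name, v in (("L", L), ("L1", L1), ("L2", L2), ("s", s)):
        if v < 0:
            raise ValueError(f"{name} must be non-negative, got {v}")
    if L1 > L or L2 > L:
        raise ValueError("list sizes cannot exceed the background size")
    if s == 0:
        return 1.0
    if s > min(L1, L2):
        return 0.0
    return float(stats.hypergeom.sf(s - 1, L, L2, L1))


def concordance(list1: DEGList, list2: DEGList,
                binomial_alternative: bool = False) -> ConcordanceResult:
    """Overlap k, consistent count s, score s/k, and tail probability.

    Both lists must declare the same background universe. A zero overlap
    leaves the score undefined and raises.
    """
    if list1.universe_size != list2.universe_size:
        raise ValueError(
            f"mismatched universes: {list1.universe_size} vs {list2.universe_size}"
        )
    L = list1.universe_size
    overlap = set(list1.entries) & set(list2.entries)
    k = len(overlap)
    if k == 0:
        raise ValueError("no overlapping genes; concordance score undefined")
    s = sum(1 for g in overlap if list1.entries[g] == list2.entries[g])
    if binomial_alternative:
        p = float(stats.binom.sf(s - 1, k, 0.5)) if s > 0 else 1.0
    else:
        p = hypergeom_tail(L, len(list1), len(list2), s)
    return ConcordanceResult(k=k, s=s, score=s / k, p_value=p)


def read_deg_tsv(path, universe_size: int) -> DEGList:
    """Read a (gene_id, direction, fdr) TSV; direction is +1/-1 or up/down."""
    df = pd.read_csv(path, sep="\t")
    cols = {c.lower(): c for c in df.columns}
    gene_c = cols.get("gene_id", df.columns[0])
    dir_c = cols.get("direction", df.columns[1])
    words = {"up": 1, "down": -1, "+1": 1, "-1": -1, "1": 1}
    dirs = {}
    for g, d in zip(df[gene_c].astype(str), df[dir_c]):
        dirs[g] = words.get(str(d).strip().lower(), None) or int(d)
    fdr = {}
    if "fdr" in cols:
        fdr = dict(zip(df[gene_c].astype(str), df[cols["fdr"]].astype(float)))
    return DEGList(entries=dirs, universe_size=universe_size, fdr=fdr)


def write_deg_tsv(degs: DEGList, path) -> None:
    rows = {
        "gene_id": list(degs.entries),
        "direction": [degs.entries[g] for g in degs.entries],
    }
    if degs.fdr:
        rows["fdr"] = [degs.fdr.get(g, float("nan")) for g in degs.entries]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
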