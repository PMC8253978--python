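"""Multi-cohort synthetic expression data with planted subtype structure.

The generator emulates the statistical shape of a two-cohort bulk RNA-seq
subtype study: heavy-tailed non-negative TPM-like abundances, three latent
subtypes with subtype-specific up/down gene programs, gene-wise per-cohort
batch shifts, and per-sample library-size scaling. Working on log2 scale,

    log2 x_gs = b_g + m_gs + c_g(cohort) + l_s + e_gs

with gene baselines b_g ~ N(baseline_log_mean, baseline_log_sd), marker
program shifts m_gs in {+effect_size, -effect_size, 0}, cohort batch shifts
c_g ~ N(0, batch_shift_sd) per cohort, library factors l_s ~ N(0,
libsize_sd), and within-group noise e_gs ~ N(0, noise_sd). Exponentiating
gives strictly positive, right-skewed values.

Each subtype's marker program splits into an *up* half and a *down* half:
up-markers sit ``effect_size`` above baseline in their own subtype and the
same amount below it elsewhere; down-markers mirror them. Pairing up-marker
i with down-marker i (their baselines are drawn once and shared) plants a
reversed gene pair — higher in the own subtype, lower everywhere else —
which is exactly the structure the stable-pair search is designed to
recover; :meth:`SyntheticSpec.planted_pairs` exposes the ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .concordance import DEGList
from .matrix import ExpressionMatrix
from .pairs import DirectedGenePair

__all__ = [
    "SyntheticSpec",
    "LabeledCohort",
    "generate_cohorts",
    "generate_deg_lists",
    "monotone_distort",
]


def _default_cohort_sizes() -> dict[str, dict[str, int]]:
    # Two cohorts of unequal depth, echoing a large and a small study arm
    # (per-subtype sizes scaled to desk size, larger arm ~2.5x the smaller).
    return {
        "cohortA": {"1": 52, "2": 78, "3": 46},
        "cohortB": {"1": 21, "2": 42, "3": 37},
    }


@dataclass
class SyntheticSpec:
    """Full parameterization of the simulated multi-cohort study.

    effect_size is the log2 half-separation of marker genes between their
    own subtype and the rest; noise/batch/library parameters are log2 SDs.
    """

    n_genes: int = 2000
    samples_per_subtype: dict[str, dict[str, int]] = field(
        default_factory=_default_cohort_sizes)
    n_subtypes: int = 3
    n_marker_genes_per_subtype: int = 50
    effect_size: float = 2.0
    batch_shift_sd: float = 0.5
    libsize_sd: float = 0.3
    noise_sd: float = 1.0
    baseline_log_mean: float = 3.0
    baseline_log_sd: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes <= 0 or self.n_marker_genes_per_subtype <= 0:
            raise ValueError("n_genes and n_marker_genes_per_subtype must be positive")
        if self.n_subtypes <= 0:
            raise ValueError("n_subtypes must be positive")
        if self.n_marker_genes_per_subtype % 2:
            raise ValueError("n_marker_genes_per_subtype must be even "
                             "(markers split into up and down halves)")
        if self.n_marker_genes_per_subtype * self.n_subtypes > self.n_genes:
            raise ValueError("marker genes exceed the gene universe")
        if self.effect_size < 0 or self.noise_sd <= 0:
            raise ValueError("effect_size must be >= 0 and noise_sd > 0")
        if self.batch_shift_sd < 0 or self.libsize_sd < 0:
            raise ValueError("batch_shift_sd and libsize_sd must be >= 0")
        for cohort, per_sub in self.samples_per_subtype.items():
            if sorted(per_sub) != [str(i + 1) for i in range(self.n_subtypes)]:
                raise ValueError(
                    f"cohort {cohort!r} must give sizes for subtypes "
                    f"1..{self.n_subtypes}")
            if any(n <= 0 for n in per_sub.values()):
                raise ValueError(f"cohort {cohort!r} has a non-positive group size")

    @property
    def subtypes(self) -> list[str]:
        return [str(i + 1) for i in range(self.n_subtypes)]

    def marker_genes(self, subtype: str) -> tuple[list[str], list[str]]:
        """(up-marker ids, down-marker ids) of one subtype; sets are disjoint
        across subtypes by construction."""
        m = self.n_marker_genes_per_subtype
        half = m // 2
        start = (int(subtype) - 1) * m
        ids = [f"g{start + i:05d}" for i in range(m)]
        return ids[:half], ids[half:]

    def planted_pairs(self, subtype: str) -> list[DirectedGenePair]:
        """Ground-truth reversed pairs for a subtype: up-marker i over
        down-marker i inside the subtype, reversed outside."""
        up, down = self.marker_genes(subtype)
        return [DirectedGenePair(u, d) for u, d in zip(up, down)]

    def gene_ids(self) -> list[str]:
        return [f"g{i:05d}" for i in range(self.n_genes)]


@dataclass
class LabeledCohort:
    matrix: ExpressionMatrix
    true_labels: dict[str, str]

    def __post_init__(self) -> None:
        if sorted(self.true_labels) != sorted(self.matrix.sample_ids):
            raise ValueError("labels must cover exactly the matrix's samples")


def generate_cohorts(spec: SyntheticSpec) -> list[LabeledCohort]:
    """Draw every cohort of the specified study. Deterministic under the seed."""
    rng = np.random.default_rng(spec.seed)
    genes = spec.gene_ids()
    baselines = rng.normal(spec.baseline_log_mean, spec.baseline_log_sd, spec.n_genes)
    gene_index = {g: i for i, g in enumerate(genes)}

    # planted pairs share one baseline so their mean orderings are exact
    for st in spec.subtypes:
        up, down = spec.marker_genes(st)
        for u, d in zip(up, down):
            baselines[gene_index[d]] = baselines[gene_index[u]]

    # program matrix: genes x subtypes, log2 shift of each gene in each subtype
    program = np.zeros((spec.n_genes, spec.n_subtypes))
    for j, st in enumerate(spec.subtypes):
        up, down = spec.marker_genes(st)
        for g in up:
            program[gene_index[g], :] = -spec.effect_size
            program[gene_index[g], j] = +spec.effect_size
        for g in down:
            program[gene_index[g], :] = +spec.effect_size
            program[gene_index[g], j] = -spec.effect_size

    cohorts = []
    for cohort in sorted(spec.samples_per_subtype):
        sizes = spec.samples_per_subtype[cohort]
        batch_shift = rng.normal(0.0, spec.batch_shift_sd, spec.n_genes)
        cols, labels = [], {}
        blocks = []
        for j, st in enumerate(spec.subtypes):
            n = sizes[st]
            lib = rng.normal(0.0, spec.libsize_sd, n)
            noise = rng.normal(0.0, spec.noise_sd, (spec.n_genes, n))
            logx = (baselines[:, None] + program[:, [j]] + batch_shift[:, None]
                    + lib[None, :] + noise)
            blocks.append(logx)
            for i in range(n):
                sid = f"{cohort}_s{st}_{i:03d}"
                cols.append(sid)
                labels[sid] = st
        values = np.exp2(np.concatenate(blocks, axis=1))
        df = pd.DataFrame(values, index=genes, columns=cols)
        matrix = ExpressionMatrix(df, unit="TPM-like",
                                  batch={s: cohort for s in cols})
        cohorts.append(LabeledCohort(matrix=matrix, true_labels=labels))
    return cohorts


def generate_deg_lists(n_background: int, n1: int, n2: int, n_overlap: int,
                       n_consistent: int, seed: int = 0) -> tuple[DEGList, DEGList, int]:
    """Two directed DEG lists with exactly the requested overlap structure.

    Returns (list1, list2, background size) with |overlap| = n_overlap of
    which exactly n_consistent agree in direction.
    """
    if not (0 <= n_consistent <= n_overlap <= min(n1, n2) <= n_background):
        raise ValueError(
            "need 0 <= n_consistent <= n_overlap <= min(n1, n2) <= n_background")
    if n1 + n2 - n_overlap > n_background:
        raise ValueError("background too small for the requested list sizes")
    rng = np.random.default_rng(seed)
    universe = [f"bg{i:06d}" for i in range(n_background)]
    chosen = rng.choice(n_background, size=n1 + n2 - n_overlap, replace=False)
    shared = [universe[i] for i in chosen[:n_overlap]]
    only1 = [universe[i] for i in chosen[n_overlap:n1]]
    only2 = [universe[i] for i in chosen[n1:]]
    dirs_shared = rng.choice([1, -1], size=n_overlap)
    l1 = {g: int(d) for g, d in zip(shared, dirs_shared)}
    l2 = {g: int(d) for g, d in zip(shared, dirs_shared)}
    for g in shared[n_consistent:]:
        l2[g] = -l2[g]
    for g in only1:
        l1[g] = int(rng.choice([1, -1]))
    for g in only2:
        l2[g] = int(rng.choice([1, -1]))
    return (DEGList(l1, n_background), DEGList(l2, n_background), n_background)


def monotone_distort(matrix: ExpressionMatrix, kind: str, seed: int = 0) -> ExpressionMatrix:
    """Apply a rank-preserving distortion; REO-based results must not move.

    kind="power"  : per-sample x -> x**gamma, gamma ~ Uniform(0.5, 1.5)
    kind="scale"  : per-sample x -> c x, c ~ LogUniform(0.2, 5)
    kind="log1p"  : global x -> log1p(x)

    All three are strictly increasing within each sample, so the rank order
    of genes inside every sample is preserved exactly.
    """
    rng = np.random.default_rng(seed)
    vals = matrix.values.to_numpy(float).copy()
    n = vals.shape[1]
    if kind == "power":
        gamma = rng.uniform(0.5, 1.5, n)
        vals = vals ** gamma[None, :]
    elif kind == "scale":
        c = np.exp(rng.uniform(np.log(0.2), np.log(5.0), n))
        vals = vals * c[None, :]
    elif kind == "log1p":
        vals = np.log1p(vals)
    else:
        raise ValueError(f"unknown distortion kind {kind!r}; "
                         "expected 'power', 'scale' or 'log1p'")
    df = pd.DataFrame(vals, index=matrix.values.index, columns=matrix.values.columns)
    return ExpressionMatrix(df, unit=matrix.unit, batch=dict(matrix.batch))
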