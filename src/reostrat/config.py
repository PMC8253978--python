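"""Pipeline-wide configuration with the study's default thresholds."""

from __future__ import annotations

from dataclasses import dataclass, asdict


@dataclass
class PipelineConfig:
    """Defaults of the published analysis protocol.

    mad_top_n
        Number of most-variable genes kept per cohort before clustering.
    expression_mean_threshold
        Genes with mean abundance strictly above this are retained.
    nmf_runs
        Stochastic NMF restarts pooled into each consensus matrix.
    rank_min, rank_max
        Inclusive grid of candidate cluster counts.
    stable_pair_fdr
        BH FDR cutoff for calling a gene-pair ordering stable in a group.
    deg_fdr
        FDR cutoff assumed for input DEG lists.
    train_fraction
        Fraction of samples assigned to the training split.
    seed
        Master seed; every stochastic step derives its stream from it.
    """

    mad_top_n: int = 1500
    expression_mean_threshold: float = 1.0
    nmf_runs: int = 200
    rank_min: int = 2
    rank_max: int = 8
    stable_pair_fdr: float = 1e-7
    deg_fdr: float = 0.01
    train_fraction: float = 0.7
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mad_top_n <= 0:
            raise ValueError("mad_top_n must be positive")
        if self.expression_mean_threshold <= 0:
            raise ValueError("expression_mean_threshold must be positive")
        if self.nmf_runs <= 0:
            raise ValueError("nmf_runs must be positive")
        if not (2 <= self.rank_min <= self.rank_max):
            raise ValueError("need 2 <= rank_min <= rank_max")
        if not 0 < self.stable_pair_fdr:
            raise ValueError("stable_pair_fdr must be positive")
        if not 0 < self.deg_fdr:
            raise ValueError("deg_fdr must be positive")
        if not 0.0 < self.train_fraction < 1.0:
            raise ValueError("train_fraction must lie in the open interval (0, 1)")

    def to_dict(self) -> dict:
        return asdict(self)
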