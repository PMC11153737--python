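"""Pipeline configuration.

A single frozen-ish dataclass carries every tunable knob so that a run is
fully determined by (inputs, config). All stochastic steps (random forests,
fold splits) draw their seeds from ``seed``.
"""

from __future__ import annotations

from dataclasses import dataclass, field


@dataclass
class PipelineConfig:
    """Knobs for the SSN -> GSN -> screening -> selection pipeline.

    Parameters
    ----------
    alpha
        Two-sided significance level for the per-sample ΔPCC edge test.
    cpm_threshold, cpm_fraction
        A gene is kept when its CPM exceeds ``cpm_threshold`` in at least
        ``cpm_fraction`` of the samples (strict ``>`` on CPM, ``>=`` on the
        sample count).
    top_edges
        Edges kept per group-specific network in the weight-ranking round.
    top_features
        Features kept after random-forest importance pre-screening.
    cbr_threshold
        Stopping level for the cost-benefit ratio; the optimal feature count
        is the one evaluated just before CBR first drops strictly below it.
    max_threshold
        Feature-count thresholds 1..max_threshold are evaluated by RFECV.
    outer_folds, inner_folds
        Stratified folds of the outer evaluation protocol and of the
        cross-validation used to score each candidate feature set.
    rf_trees
        Trees per random forest (importance screening, RFECV and the final
        classifier all use the same ensemble family).
    seed
        Master seed; every random component derives from it.
    signed_rank
        Rank GSN edges by signed weight instead of |weight| (the literal
        reading of "descending order based on the edge weights"); default
        False keeps strong lost-correlation edges.
    include_reference
        Include reference-group samples as a classifier class. Default False:
        the classifier discriminates among the non-reference groups.
    f1_average
        F1 averaging mode: "macro" (default), "weighted" or "micro".
    score_min
        Minimum PPI confidence score for an edge to count as validated.
    """

    alpha: float = 0.05
    cpm_threshold: float = 2.0
    cpm_fraction: float = 0.5
    top_edges: int = 50
    top_features: int = 50
    cbr_threshold: float = 0.5
    max_threshold: int = 10
    outer_folds: int = 10
    inner_folds: int = 5
    rf_trees: int = 500
    seed: int = 0
    signed_rank: bool = False
    include_reference: bool = False
    f1_average: str = "macro"
    score_min: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha < 1.0:
            raise ValueError(f"alpha must lie in (0, 1), got {self.alpha}")
        for name in ("top_edges", "top_features", "max_threshold"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.outer_folds < 2:
            raise ValueError("outer_folds must be >= 2")
        if self.inner_folds < 2:
            raise ValueError("inner_folds must be >= 2")
        if self.rf_trees < 1:
            raise ValueError("rf_trees must be >= 1")
        if not 0.0 <= self.cpm_fraction <= 1.0:
            raise ValueError("cpm_fraction must lie in [0, 1]")
        if self.f1_average not in {"macro", "weighted", "micro"}:
            raise ValueError(f"unknown f1_average {self.f1_average!r}")
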