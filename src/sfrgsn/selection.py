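"""Second selection round: recursive feature elimination and the CBR rule.

Starting from the pre-screened feature set, the least important feature
(by the same Gini-gain importance as the screening round) is removed one at
a time; whenever the current size equals an evaluated threshold the feature
set and its stratified cross-validated F1 are recorded. The cost-benefit
ratio between consecutive evaluated counts k_prev < k is

    CBR(k) = 100 * PR / (INF * UFC),   PR = (F1_k - F1_{k_prev}) / 100,
    INF = k - k_prev,  UFC = 1,

i.e. the F1 gain in percentage points per added feature; it is undefined at
the smallest evaluated count. Scanning k upward, the optimal count is the
one evaluated just before CBR first falls strictly below the threshold
(default 0.5); if it never does, the largest evaluated count wins.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from sklearn.model_selection import StratifiedKFold, cross_val_score

from .config import PipelineConfig
from .io import Pair
from .screening import EdgeFeatureMatrix, _forest, tree_gini_importances


@dataclass
class ThresholdRecord:
    k: int
    features: list[Pair]
    f1: float            # cross-validated F1, percent
    cbr: float | None = None  # undefined at the smallest evaluated k

    def __post_init__(self) -> None:
        if len(self.features) != self.k:
            raise ValueError("feature list length must equal k")
        if not 0.0 <= self.f1 <= 100.0:
            raise ValueError("F1 percent out of range")


@dataclass
class SelectionResult:
    records: dict[int, ThresholdRecord]
    optimal_k: int
    optimal_features: list[Pair] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.optimal_k not in self.records:
            raise ValueError("optimal_k must be one of the evaluated thresholds")
        if not self.optimal_features:
            self.optimal_features = list(self.records[self.optimal_k].features)


def _cv_f1(fm: EdgeFeatureMatrix, config: PipelineConfig) -> float:
    y = np.asarray(fm.groups)
    _, counts = np.unique(y, return_counts=True)
    if counts.min() < config.inner_folds:
        raise ValueError(
            f"smallest class has {counts.min()} sample(s) < {config.inner_folds} "
            "inner folds; reduce inner_folds"
        )
    cv = StratifiedKFold(n_splits=config.inner_folds, shuffle=True,
                         random_state=config.seed % (2 ** 31))
    scoring = f"f1_{config.f1_average}" if config.f1_average != "micro" else "f1_micro"
    scores = cross_val_score(_forest(config), fm.values, y, cv=cv,
                             scoring=scoring, n_jobs=1)
    return float(scores.mean() * 100.0)


def rfecv(fm: EdgeFeatureMatrix, thresholds: Sequence[int],
          config: PipelineConfig) -> dict[int, ThresholdRecord]:
    """Recursive feature elimination, recording CV F1 at each threshold.

    One feature is removed per iteration (the one with the smallest
    Gini-gain importance on the full training set; ties drop the
    lexicographically smallest pair). Returns records keyed by k.
    """
    thr = sorted(set(int(t) for t in thresholds))
    if not thr:
        raise ValueError("no thresholds given")
    if thr[0] < 1:
        raise ValueError("thresholds must be >= 1")
    if thr[-1] > len(fm.edge_ids):
        raise ValueError(
            f"largest threshold {thr[-1]} exceeds feature count {len(fm.edge_ids)}"
        )
    records: dict[int, ThresholdRecord] = {}
    S = list(fm.edge_ids)
    y = np.asarray(fm.groups)
    while S:
        k = len(S)
        if k in thr:
            sub = fm.subset_edges(S)
            records[k] = ThresholdRecord(k=k, features=list(S), f1=_cv_f1(sub, config))
            if k == thr[0]:
                break
        if k == 1:
            break
        rf = _forest(config)
        sub = fm.subset_edges(S)
        rf.fit(sub.values, y)
        imp = tree_gini_importances(rf.estimators_, len(S))
        scores = dict(zip(S, imp))
        drop = min(S, key=lambda e: (scores[e], e))
        S.remove(drop)
    return records


def compute_cbr_series(f1_by_k: Mapping[int, float]) -> dict[int, float]:
    """CBR between consecutive evaluated feature counts.

    Input maps feature count -> F1 percent; output maps every count except
    the smallest to its CBR (F1 percentage-point gain per added feature;
    gaps INF > 1 are allowed).
    """
    if not f1_by_k:
        raise ValueError("empty F1 map")
    ks = sorted(f1_by_k)
    out: dict[int, float] = {}
    for prev, k in zip(ks, ks[1:]):
        pr = (f1_by_k[k] - f1_by_k[prev]) / 100.0
        inf = k - prev
        out[k] = 100.0 * pr / (inf * 1.0)  # UFC = 1
    return out


def select_optimal_count(cbr_by_k: Mapping[int, float], threshold: float = 0.5,
                         smallest_k: int | None = None) -> int:
    """First-below-threshold stopping rule.

    Scanning counts in ascending order, let k* be the first with
    CBR(k*) < threshold (strict; a tie at the threshold is "not below").
    Returns the evaluated count immediately before k*, or the largest
    evaluated count when CBR never falls below the threshold.
    ``smallest_k`` names the count preceding the first CBR entry (defaults
    to the first entry minus the first gap).
    """
    if not cbr_by_k:
        raise ValueError("empty CBR map")
    ks = sorted(cbr_by_k)
    if smallest_k is None:
        gap = (ks[1] - ks[0]) if len(ks) > 1 else 1
        smallest_k = ks[0] - gap
    prev = smallest_k
    for k in ks:
        if cbr_by_k[k] < threshold:
            return prev
        prev = k
    return ks[-1]


def select_features(records: dict[int, ThresholdRecord],
                    cbr_threshold: float = 0.5) -> SelectionResult:
    """Fill in the CBR column of RFECV records and pick the optimal count."""
    if not records:
        raise ValueError("no threshold records")
    f1_by_k = {k: r.f1 for k, r in records.items()}
    cbr = compute_cbr_series(f1_by_k)
    for k, v in cbr.items():
        records[k].cbr = v
    if cbr:
        k_opt = select_optimal_count(cbr, cbr_threshold, smallest_k=min(records))
    else:  # single threshold evaluated
        k_opt = min(records)
    return SelectionResult(records=records, optimal_k=k_opt)


def write_threshold_table(records: dict[int, ThresholdRecord], path) -> None:
    with open(path, "w") as fh:
        fh.write("k\tf1_percent\tcbr\n")
        for k in sorted(records):
            r = records[k]
            cbr = "-" if r.cbr is None else f"{r.cbr:.4f}"
            fh.write(f"{k}\t{r.f1:.4f}\t{cbr}\n")
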