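"""Outer cross-validation protocol and classification metrics.

Each outer fold uses only its training samples end to end: the reference
network comes from the training normals, training disease samples get their
ΔPCC networks against it, per-group networks are aggregated, edges are
screened and the feature count is selected — the held-out samples first
appear when their own ΔPCC features (computed against the same training
reference) are scored by the fold's classifier. The final reported biomarker
set is re-derived once from the fold-averaged group networks using all
samples.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from sklearn.metrics import f1_score
from sklearn.model_selection import StratifiedKFold

from .config import PipelineConfig
from .gsn import (GroupSpecificNetwork, aggregate_group, average_fold_gsns,
                  check_gsn_within_ppi, intersect_ppi)
from .io import (ExpressionMatrix, GroupLabels, Pair, PPINetwork, cpm_filter,
                 log_cpm)
from .screening import (EdgeFeatureMatrix, _forest, build_candidate_set,
                        build_edge_features, prescreen_features)
from .selection import SelectionResult, rfecv, select_features
from .ssn import build_reference_network, build_ssns

logger = logging.getLogger(__name__)


def macro_f1(true_labels, predicted_labels, average: str = "macro") -> float:
    """Averaged F1 in percent; per-class F1 uses 0 for empty denominators."""
    true_labels = list(true_labels)
    predicted_labels = list(predicted_labels)
    if len(true_labels) != len(predicted_labels):
        raise ValueError("label sequences differ in length")
    if not true_labels:
        raise ValueError("empty label sequences")
    labels = sorted(set(true_labels) | set(predicted_labels))
    return float(f1_score(true_labels, predicted_labels, labels=labels,
                          average=average, zero_division=0) * 100.0)


@dataclass
class FoldResult:
    fold: int
    selected: list[Pair]
    test_f1: float    # macro F1 on the held-out disease samples, percent
    inner_f1: float   # RFECV cross-validated F1 at the selected count, percent


@dataclass
class CrossValReport:
    per_fold: list[FoldResult]
    mean_f1: float
    mean_inner_f1: float
    final_biomarkers: list[Pair]
    final_selection: SelectionResult
    config: PipelineConfig = field(repr=False, default=None)


def _fold_feature_rows(candidates, ssns, labels) -> EdgeFeatureMatrix:
    return build_edge_features(candidates, ssns, labels)


def _select_on_training(ssns_by_group: dict[str, list], labels: GroupLabels,
                        config: PipelineConfig):
    """Shared screening + selection path: GSNs -> candidates -> prescreen -> RFECV."""
    gsns = {g: aggregate_group(ssns, g) for g, ssns in ssns_by_group.items() if ssns}
    all_ssns = [s for lst in ssns_by_group.values() for s in lst]
    candidates = build_candidate_set(list(gsns.values()), config.top_edges,
                                     signed=config.signed_rank)
    fm = build_edge_features(candidates, all_ssns, labels,
                             include_reference=config.include_reference)
    ranking = prescreen_features(fm, config.top_features, config)
    kept = ranking.top(config.top_features)
    fm_pre = fm.subset_edges(kept)
    thresholds = list(range(1, min(config.max_threshold, len(kept)) + 1))
    records = rfecv(fm_pre, thresholds, config)
    selection = select_features(records, config.cbr_threshold)
    return gsns, fm_pre, selection


def run_pipeline(expr: ExpressionMatrix, labels: GroupLabels, ppi: PPINetwork,
                 config: PipelineConfig | None = None) -> CrossValReport:
    """Full stratified outer-CV evaluation plus the final biomarker set.

    Returns one test-F1 per fold (held-out disease samples scored on that
    fold's selected edges) alongside the fold's inner RFECV estimate, and the
    biomarkers selected once from the fold-averaged group networks.
    """
    config = config or PipelineConfig()
    labels = labels.restrict_to(expr)
    if expr.unit == "counts":
        expr = log_cpm(cpm_filter(expr, config.cpm_threshold, config.cpm_fraction))
    ppi = ppi.restrict_to_genes(expr.gene_ids)
    if not ppi.edges:
        raise ValueError("no PPI edge joins two genes of the filtered matrix")
    pair_set = ppi.edges

    samples = [s for s in expr.sample_ids if s in labels.assignments]
    y_groups = np.asarray([labels.assignments[s] for s in samples])
    _, counts = np.unique(y_groups, return_counts=True)
    if counts.min() < config.outer_folds:
        raise ValueError(
            f"smallest group has {counts.min()} sample(s) < {config.outer_folds} "
            "outer folds; reduce outer_folds"
        )

    skf = StratifiedKFold(n_splits=config.outer_folds, shuffle=True,
                          random_state=config.seed % (2 ** 31))
    per_fold: list[FoldResult] = []
    fold_gsns: dict[str, list[GroupSpecificNetwork]] = {}

    for fold, (train_idx, test_idx) in enumerate(skf.split(samples, y_groups)):
        train = [samples[i] for i in train_idx]
        test = [samples[i] for i in test_idx]
        train_labels = labels.subset(train)

        ref = build_reference_network(expr, train_labels, pair_set)
        ssns_by_group = {
            g: [intersect_ppi(s, ppi) for s in
                build_ssns(ref, expr, labels, train_labels.samples_in(g), config.alpha)]
            for g in train_labels.groups
        }
        gsns, fm_pre, selection = _select_on_training(ssns_by_group, labels, config)
        for g in gsns.values():
            check_gsn_within_ppi(g, ppi)
        for g, gsn in gsns.items():
            fold_gsns.setdefault(g, []).append(gsn)

        selected = selection.optimal_features
        clf = _forest(config)
        fm_sel = fm_pre.subset_edges(selected)
        clf.fit(fm_sel.values, np.asarray(fm_sel.groups))

        test_disease = [s for s in test
                        if labels.assignments[s] != labels.reference_group]
        test_ssns = [intersect_ppi(s, ppi) for s in
                     build_ssns(ref, expr, labels, test_disease, config.alpha)]
        fm_test = build_edge_features(selected, test_ssns, labels,
                                      include_reference=config.include_reference)
        pred = clf.predict(fm_test.values)
        f1 = macro_f1(fm_test.groups, pred, average=config.f1_average)
        per_fold.append(FoldResult(
            fold=fold, selected=list(selected), test_f1=f1,
            inner_f1=selection.records[selection.optimal_k].f1,
        ))
        logger.info("fold %d: %d candidates, k*=%d, test F1 %.2f",
                    fold, len(fm_pre.edge_ids), selection.optimal_k, f1)

    # final biomarkers: fold-averaged GSNs, screening/selection on all samples
    averaged = {g: average_fold_gsns(lst) for g, lst in fold_gsns.items()}
    ref_full = build_reference_network(expr, labels, pair_set)
    full_ssns = {
        g: [intersect_ppi(s, ppi) for s in
            build_ssns(ref_full, expr, labels, labels.samples_in(g), config.alpha)]
        for g in labels.groups
    }
    all_ssns = [s for lst in full_ssns.values() for s in lst]
    candidates = build_candidate_set(list(averaged.values()), config.top_edges,
                                     signed=config.signed_rank)
    fm = build_edge_features(candidates, all_ssns, labels,
                             include_reference=config.include_reference)
    ranking = prescreen_features(fm, config.top_features, config)
    fm_pre = fm.subset_edges(ranking.top(config.top_features))
    thresholds = list(range(1, min(config.max_threshold, len(fm_pre.edge_ids)) + 1))
    final_selection = select_features(rfecv(fm_pre, thresholds, config),
                                      config.cbr_threshold)

    return CrossValReport(
        per_fold=per_fold,
        mean_f1=float(np.mean([f.test_f1 for f in per_fold])),
        mean_inner_f1=float(np.mean([f.inner_f1 for f in per_fold])),
        final_biomarkers=list(final_selection.optimal_features),
        final_selection=final_selection,
        config=config,
    )
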