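"""End-to-end rebalancing pipeline and benchmark harness.

The full algorithm on one imbalanced binary dataset:

1. split the data into majority and minority class;
2. decompose the majority class into k > 1 clusters with PSO-assisted
   k-means, choosing k adaptively (every sub-dataset's screening kappa must
   exceed 0.2);
3. pair each majority cluster with the whole minority class; if the
   minority already outnumbers that sub-majority the classifier is applied
   directly, otherwise the dynamic multi-objective swarm searches the
   (N, k) SMOTE parameters for that sub-dataset;
4. average all per-sub-dataset metrics component-wise into the final
   result (the sub-datasets' classifiers are never combined into a
   prediction-time ensemble — only their metrics are averaged).

The verification classifier is a pluggable contract; the default is a
single-hidden-layer feed-forward network (scikit-learn MLP, seeded).
Fitness evaluations inside the swarm loops use a seeded stratified 70/30
holdout of the rebalanced sub-dataset; final reported numbers come from
stratified ten-fold cross-validation, repeated and averaged.

Cross-validation modes: ``paper_faithful`` rebalances first and
cross-validates the augmented data — the protocol of the original benchmark,
which leaks interpolated copies of training minority points into test folds
and therefore flatters every oversampler; ``within_fold`` generates
synthetic samples only from each training fold's minority rows and is the
methodologically clean alternative (supported for the non-swarm methods).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from typing import Callable, Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.exceptions import ConvergenceWarning
from sklearn.model_selection import StratifiedKFold, train_test_split
from sklearn.neural_network import MLPClassifier
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler
import warnings

from .cluster import DecompositionResult, adaptive_decompose
from .metrics import ConfusionMatrix, MetricsReport, confusion_matrix, report_from_confusion
from .rebalance import (
    LabeledDataset,
    ParamBounds,
    SmoteParams,
    apply_smote,
    full_balance_smote,
    random_smote,
)
from .swarm_mo import SwarmConfig, dmsmote_optimize, sra_optimize

logger = logging.getLogger(__name__)

__all__ = [
    "ClassifierConfig",
    "PipelineResult",
    "SubResult",
    "CrossValResult",
    "train_eval",
    "holdout_report",
    "make_evaluator",
    "aggregate",
    "run_ascb",
    "cross_validate",
    "benchmark",
    "METHODS",
]

METHODS = ("none", "smote", "random_smote", "sra", "ascb_dmsmote")

_METRIC_FIELDS = (
    "kappa",
    "accuracy",
    "g_mean",
    "f_measure",
    "reliable_accuracy",
    "majority_count",
    "minority_count",
)


@dataclass(frozen=True)
class ClassifierConfig:
    """The verification classifier: a single-hidden-layer network by default.

    ``hidden_units=None`` auto-sizes to max(5, ceil((d + 2) / 2)) for d
    input features.  Inputs are standardised (zero mean, unit variance,
    fitted on the training portion only) before the network, and training
    runs ``max_epochs`` adam epochs at ``learning_rate`` — the standard
    recipe for small tabular MLPs.  Deterministic given ``seed``.
    """

    kind: str = "mlp"
    hidden_units: Optional[int] = None
    max_epochs: int = 200
    learning_rate: float = 1e-3
    seed: int = 0
    fmeasure_positive: str = "minority"

    def __post_init__(self) -> None:
        if self.hidden_units is not None and self.hidden_units < 1:
            raise ValueError("hidden_units must be >= 1")
        if self.max_epochs < 1:
            raise ValueError("max_epochs must be >= 1")

    def resolved_hidden(self, n_features: int) -> int:
        return self.hidden_units if self.hidden_units is not None else max(5, math.ceil((n_features + 2) / 2))


def _build_classifier(config: ClassifierConfig, n_features: int):
    if config.kind != "mlp":
        raise ValueError(f"unknown classifier kind {config.kind!r}")
    return make_pipeline(
        StandardScaler(),
        MLPClassifier(
            hidden_layer_sizes=(config.resolved_hidden(n_features),),
            solver="adam",
            max_iter=config.max_epochs,
            learning_rate_init=config.learning_rate,
            random_state=config.seed,
        ),
    )


def train_eval(train: LabeledDataset, test: LabeledDataset, config: ClassifierConfig) -> ConfusionMatrix:
    """Train the configured classifier on ``train``, score ``test``; the
    minority class is the positive axis of the returned matrix."""
    if len(np.unique(train.labels)) < 2:
        raise ValueError("training set contains a single class")
    if len(test.labels) == 0:
        raise ValueError("test set is empty")
    if train.n_features != test.n_features:
        raise ValueError("train/test feature dimensions differ")
    clf = _build_classifier(config, train.n_features)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        clf.fit(train.features, train.labels)
        predicted = clf.predict(test.features)
    return confusion_matrix(test.labels, predicted, positive_label=train.minority_label)


def holdout_report(
    dataset: LabeledDataset,
    config: ClassifierConfig,
    seed: int,
    test_size: float = 0.3,
) -> MetricsReport:
    """Stratified holdout evaluation: train on (1 - test_size), score the rest."""
    idx = np.arange(len(dataset.labels))
    train_idx, test_idx = train_test_split(
        idx, test_size=test_size, random_state=seed, stratify=dataset.labels
    )
    cm = train_eval(dataset.subset(train_idx), dataset.subset(test_idx), config)
    return report_from_confusion(cm, fmeasure_positive=config.fmeasure_positive)


def make_evaluator(
    subdataset: LabeledDataset,
    config: ClassifierConfig,
    base_seed: int,
) -> Callable[[SmoteParams], MetricsReport]:
    """Fitness contract for the swarm searches on one sub-dataset.

    Maps (N, k) to a metrics report by oversampling the sub-dataset at those
    parameters and scoring a seeded stratified 70/30 holdout of the
    augmented data.  Both the synthesis draw and the split are derived
    deterministically from ``base_seed`` and the parameters, so the mapping
    is a pure function — which also makes caching inside the optimizers
    exact.
    """
    base = abs(int(base_seed)) % (2**31)

    def evaluator(params: SmoteParams) -> MetricsReport:
        rng = np.random.default_rng([base, params.n_rate, params.k_neighbors])
        augmented = apply_smote(subdataset, params, rng)
        split_seed = (base * 1009 + params.n_rate * 131 + params.k_neighbors) % (2**31 - 1)
        return holdout_report(augmented, config, seed=split_seed)

    return evaluator


# --------------------------------------------------------------------------
# Aggregation (final result = mean over sub-datasets)
# --------------------------------------------------------------------------

def aggregate(per_sub: Sequence[MetricsReport]) -> MetricsReport:
    """Component-wise arithmetic mean of every metric across sub-datasets."""
    if not per_sub:
        raise ValueError("cannot aggregate an empty list of reports")
    n = len(per_sub)
    return MetricsReport(**{f: sum(getattr(r, f) for r in per_sub) / n for f in _METRIC_FIELDS})


def _report_std(reports: Sequence[MetricsReport]) -> MetricsReport:
    arr = {f: np.std([getattr(r, f) for r in reports]) for f in _METRIC_FIELDS}
    return MetricsReport(**{k: float(v) for k, v in arr.items()})


@dataclass
class SubResult:
    cluster_index: int
    report: MetricsReport
    params: Optional[SmoteParams]  # None -> direct classification (skip rule)

    @property
    def direct(self) -> bool:
        return self.params is None


@dataclass
class PipelineResult:
    per_sub: list[SubResult]
    final: MetricsReport
    chosen_k: int
    fallback: bool
    size_before: tuple[int, int]  # (majority, minority)
    size_after: tuple[int, int]  # (majority, minority incl. synthetic, summed over subs)
    decomposition: Optional[DecompositionResult] = None

    @property
    def ratio_after(self) -> float:
        return self.size_after[0] / max(self.size_after[1], 1)


# --------------------------------------------------------------------------
# The end-to-end algorithm
# --------------------------------------------------------------------------

def run_ascb(
    dataset: LabeledDataset,
    swarm_config: SwarmConfig,
    classifier_config: ClassifierConfig,
    rng: Optional[np.random.Generator] = None,
) -> PipelineResult:
    """Adaptive swarm cluster-based dynamic multi-objective SMOTE, end to end.

    Decomposes the majority class, runs the multi-objective swarm per
    sub-dataset (or classifies directly where the minority already
    outnumbers the sub-majority), and averages the per-sub metrics into the
    final report.  Seeded-deterministic via ``swarm_config.seed`` when
    ``rng`` is not supplied.
    """
    if dataset.minority_count < 2:
        raise ValueError("minority class must have at least two samples")
    rng = rng if rng is not None else np.random.default_rng(abs(swarm_config.seed) % (2**31))

    def screen(sub: LabeledDataset) -> float:
        return holdout_report(sub, classifier_config, seed=classifier_config.seed).kappa

    decomp = adaptive_decompose(dataset, screen, swarm_config, rng)
    per_sub: list[SubResult] = []
    minority_after_total = 0
    for sub in decomp.subdatasets:
        sub_ds = sub.to_dataset(
            majority_label=dataset.majority_label, minority_label=dataset.minority_label
        )
        if sub_ds.minority_count >= sub_ds.majority_count:
            # skip rule: already minority-heavy, classify directly
            report = holdout_report(sub_ds, classifier_config, seed=classifier_config.seed)
            per_sub.append(SubResult(sub.cluster_index, report, None))
            minority_after_total += sub_ds.minority_count
        else:
            evaluator = make_evaluator(
                sub_ds, classifier_config, base_seed=swarm_config.seed * 97 + sub.cluster_index
            )
            result = dmsmote_optimize(sub_ds, swarm_config, evaluator, rng)
            per_sub.append(SubResult(sub.cluster_index, result.report, result.params))
            minority_after_total += sub_ds.minority_count * (1 + result.params.n_rate)
    final = aggregate([s.report for s in per_sub])
    return PipelineResult(
        per_sub=per_sub,
        final=final,
        chosen_k=decomp.k,
        fallback=decomp.fallback,
        size_before=(dataset.majority_count, dataset.minority_count),
        size_after=(dataset.majority_count, minority_after_total),
        decomposition=decomp,
    )


# --------------------------------------------------------------------------
# Cross-validated evaluation and the benchmark harness
# --------------------------------------------------------------------------

@dataclass
class CrossValResult:
    method: str
    mean: MetricsReport
    std: MetricsReport
    n_runs: int
    ratio_after: float
    flags: dict = field(default_factory=dict)
    fold_records: list[dict] = field(default_factory=list)


def _cv_fold_reports(
    dataset: LabeledDataset,
    config: ClassifierConfig,
    folds: int,
    seed: int,
) -> list[MetricsReport]:
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    reports = []
    for train_idx, test_idx in skf.split(dataset.features, dataset.labels):
        cm = train_eval(dataset.subset(train_idx), dataset.subset(test_idx), config)
        reports.append(report_from_confusion(cm, fmeasure_positive=config.fmeasure_positive))
    return reports


def _check_foldable(dataset: LabeledDataset, folds: int) -> None:
    if folds < 2:
        raise ValueError("folds must be >= 2")
    if dataset.minority_count < folds:
        raise ValueError(
            f"minority_count={dataset.minority_count} < folds={folds}: "
            f"use at most {dataset.minority_count} folds"
        )


def cross_validate(
    dataset: LabeledDataset,
    method: str = "none",
    folds: int = 10,
    repeats: int = 10,
    seed: int = 0,
    swarm_config: Optional[SwarmConfig] = None,
    classifier_config: Optional[ClassifierConfig] = None,
    bounds: Optional[ParamBounds] = None,
    cv_mode: str = "paper_faithful",
) -> CrossValResult:
    """Repeated stratified k-fold evaluation of one rebalancing method.

    Returns mean and standard deviation over all evaluation units (fold
    scores for the flat methods; per-repeat aggregated scores for
    ``ascb_dmsmote``, whose unit of analysis is the cluster average).

    ``cv_mode='paper_faithful'`` rebalances the whole dataset per repeat and
    folds the augmented data; ``cv_mode='within_fold'`` rebalances only each
    training fold (supported for none/smote/random_smote — running a full
    swarm search inside every fold is out of proportion to this mode's
    diagnostic purpose).
    """
    if method not in METHODS:
        raise ValueError(f"unknown method {method!r}; choose from {METHODS}")
    if cv_mode not in ("paper_faithful", "within_fold"):
        raise ValueError(f"unknown cv_mode {cv_mode!r}")
    if cv_mode == "within_fold" and method in ("sra", "ascb_dmsmote"):
        raise NotImplementedError(
            "within_fold CV is provided for the non-swarm methods (none, smote, random_smote)"
        )
    clf = classifier_config if classifier_config is not None else ClassifierConfig()
    swarm = swarm_config if swarm_config is not None else SwarmConfig()
    _check_foldable(dataset, folds)
    seed = abs(int(seed)) % (2**31 - 10**6)

    unit_reports: list[MetricsReport] = []
    ratios: list[float] = []
    flags: dict = {}
    fold_records: list[dict] = []

    for r in range(repeats):
        rep_seed = seed + 7919 * r
        rng = np.random.default_rng(rep_seed)
        # each repeat is an independent experiment: fresh fold shuffle AND a
        # fresh network initialization (r = 0 keeps the configured seed)
        clf_r = replace(clf, seed=(clf.seed + 104729 * r) % (2**31 - 1))
        if cv_mode == "within_fold":
            reports = _within_fold_reports(dataset, method, folds, rep_seed, clf_r, bounds, fold_records)
            unit_reports.extend(reports)
            ratios.append(dataset.imbalance_ratio if method == "none" else 1.0 if method == "smote" else float("nan"))
            continue
        if method == "none":
            unit_reports.extend(_cv_fold_reports(dataset, clf_r, folds, rep_seed))
            ratios.append(dataset.imbalance_ratio)
        elif method == "smote":
            aug = full_balance_smote(dataset, k=5, rng=rng)
            unit_reports.extend(_cv_fold_reports(aug, clf_r, folds, rep_seed))
            ratios.append(aug.imbalance_ratio)
        elif method == "random_smote":
            b = bounds if bounds is not None else ParamBounds.default_for(dataset)
            aug, params = random_smote(dataset, b, rng)
            unit_reports.extend(_cv_fold_reports(aug, clf_r, folds, rep_seed))
            ratios.append(aug.majority_count / max(aug.minority_count, 1))
            flags.setdefault("drawn_params", []).append((params.n_rate, params.k_neighbors))
            flags["bounds"] = (b.n_min, b.n_max, b.k_min, b.k_max)
        elif method == "sra":
            cfg = replace(swarm, seed=rep_seed)
            evaluator = make_evaluator(dataset, clf_r, base_seed=rep_seed)
            res = sra_optimize(dataset, cfg, evaluator, rng)
            if not res.feasible:
                flags["sra_infeasible"] = True
            aug = apply_smote(dataset, res.params, rng)
            unit_reports.extend(_cv_fold_reports(aug, clf_r, folds, rep_seed))
            ratios.append(aug.majority_count / max(aug.minority_count, 1))
        else:  # ascb_dmsmote
            cfg = replace(swarm, seed=rep_seed)
            result = run_ascb(dataset, cfg, clf_r, rng)
            if result.fallback:
                flags["decomposition_fallback"] = True
            per_sub_cv: list[MetricsReport] = []
            subs_by_index = {s.cluster_index: s for s in result.decomposition.subdatasets}
            for sub in result.per_sub:
                # rebuild the sub-dataset and CV it at the winning parameters
                sub_ds = subs_by_index[sub.cluster_index].to_dataset(
                    majority_label=dataset.majority_label,
                    minority_label=dataset.minority_label,
                )
                if sub.params is not None:
                    sub_ds = apply_smote(
                        sub_ds, sub.params, np.random.default_rng([rep_seed, sub.cluster_index])
                    )
                cv_folds = min(folds, sub_ds.minority_count)
                per_sub_cv.append(aggregate(_cv_fold_reports(sub_ds, clf_r, cv_folds, rep_seed)))
            unit_reports.append(aggregate(per_sub_cv))
            ratios.append(result.ratio_after)
            flags.setdefault("chosen_k", []).append(result.chosen_k)
    mean = aggregate(unit_reports)
    std = _report_std(unit_reports)
    ratio = float(np.nanmean(ratios)) if ratios else float("nan")
    return CrossValResult(
        method=method,
        mean=mean,
        std=std,
        n_runs=len(unit_reports),
        ratio_after=ratio,
        flags=flags,
        fold_records=fold_records,
    )


def _within_fold_reports(
    dataset: LabeledDataset,
    method: str,
    folds: int,
    seed: int,
    clf: ClassifierConfig,
    bounds: Optional[ParamBounds],
    fold_records: list[dict],
) -> list[MetricsReport]:
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    rng = np.random.default_rng(seed)
    reports = []
    for train_idx, test_idx in skf.split(dataset.features, dataset.labels):
        train = dataset.subset(train_idx)
        test = dataset.subset(test_idx)
        if method == "smote" and train.majority_count > train.minority_count:
            train_bal = full_balance_smote(train, k=5, rng=rng)
        elif method == "random_smote":
            b = bounds if bounds is not None else ParamBounds.default_for(train)
            train_bal, _ = random_smote(train, b, rng)
        else:
            train_bal = train
        cm = train_eval(train_bal, test, clf)
        reports.append(report_from_confusion(cm, fmeasure_positive=clf.fmeasure_positive))
        synth = train_bal.synthetic
        tmin = train.minority_features
        synth_rows = train_bal.features[synth]
        in_box = bool(
            len(synth_rows) == 0
            or (
                (synth_rows >= tmin.min(axis=0) - 1e-9).all()
                and (synth_rows <= tmin.max(axis=0) + 1e-9).all()
            )
        )
        fold_records.append(
            {
                "train_synthetic": int(synth.sum()),
                "test_synthetic": int(test.synthetic.sum()),
                "synthetic_within_train_minority_box": in_box,
            }
        )
    return reports


def benchmark(
    dataset: LabeledDataset,
    methods: Sequence[str] = METHODS,
    folds: int = 10,
    repeats: int = 10,
    seed: int = 0,
    swarm_config: Optional[SwarmConfig] = None,
    classifier_config: Optional[ClassifierConfig] = None,
    bounds: Optional[ParamBounds] = None,
    cv_mode: str = "paper_faithful",
) -> pd.DataFrame:
    """Compare rebalancing methods on one dataset.

    One row per method with the mean and standard deviation of every metric
    plus the resulting majority:minority ratio.  A method that raises is
    reported as a flagged row rather than failing the whole table.
    """
    if not methods:
        raise ValueError("at least one method required")
    rows = []
    for method in methods:
        try:
            res = cross_validate(
                dataset,
                method=method,
                folds=folds,
                repeats=repeats,
                seed=seed,
                swarm_config=swarm_config,
                classifier_config=classifier_config,
                bounds=bounds,
                cv_mode=cv_mode,
            )
            row = {"method": method, "failed": False}
            for f in _METRIC_FIELDS:
                row[f] = getattr(res.mean, f)
                row[f + "_std"] = getattr(res.std, f)
            row["ratio_after"] = res.ratio_after
            rows.append(row)
        except Exception as exc:  # a failing method must not kill the table
            logger.exception("method %s failed", method)
            row = {"method": method, "failed": True, "error": str(exc)}
            rows.append(row)
    return pd.DataFrame(rows).set_index("method")
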