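"""Confusion-matrix construction and evaluation statistics.

All rebalancing decisions in this package are driven by two objectives read
off a binary confusion matrix: plain accuracy and Cohen's kappa, the
chance-corrected agreement

    kappa = (Po - Pc) / (1 - Pc)

where ``Po`` is the observed agreement (the accuracy) and ``Pc`` the
agreement expected by chance from the marginals.  Under heavy class
imbalance a classifier that ignores the minority class can post high
accuracy with kappa near zero ("pseudo-accuracy"); kappa is therefore used
as the credibility objective throughout.  G-mean (geometric mean of the two
per-class recalls) and the F-measure are carried as auxiliary indices, and
``reliable_accuracy`` — the product kappa x accuracy — is the scalar used to
pick a single solution from a Pareto archive.
"""

from __future__ import annotations

import io
import json
import math
from dataclasses import dataclass, fields
from typing import Iterable, Sequence

__all__ = [
    "ConfusionMatrix",
    "MetricsReport",
    "UndefinedMetricError",
    "confusion_matrix",
    "accuracy",
    "kappa",
    "g_mean",
    "f_measure",
    "reliable_accuracy",
    "interpret_kappa",
    "sweep_confusion",
    "report_from_confusion",
]

REPORT_COLUMNS = (
    "kappa",
    "accuracy",
    "g_mean",
    "f_measure",
    "reliable_accuracy",
    "majority_count",
    "minority_count",
)


class UndefinedMetricError(ValueError):
    """A metric was requested on a confusion matrix where it is undefined."""


@dataclass(frozen=True)
class ConfusionMatrix:
    """Binary confusion counts; the positive class is the minority/target class.

    ``positives`` (P) is the number of true positive-class samples tp + fn;
    ``negatives`` (N) is tn + fp.
    """

    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        for f in fields(self):
            v = getattr(self, f.name)
            if v < 0 or v != int(v):
                raise ValueError(f"confusion count {f.name}={v!r} must be a non-negative integer")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn

    @property
    def positives(self) -> int:
        return self.tp + self.fn

    @property
    def negatives(self) -> int:
        return self.tn + self.fp


@dataclass(frozen=True)
class MetricsReport:
    """All evaluation indices for one classification run.

    ``majority_count`` / ``minority_count`` record the class sizes of the
    evaluated (possibly rebalanced) data; they are floats so that reports can
    be averaged component-wise across sub-datasets.
    """

    kappa: float
    accuracy: float
    g_mean: float
    f_measure: float
    reliable_accuracy: float
    majority_count: float
    minority_count: float

    def to_dict(self) -> dict[str, float]:
        return {c: getattr(self, c) for c in REPORT_COLUMNS}

    def to_json(self) -> str:
        return json.dumps(self.to_dict())

    @staticmethod
    def csv_header() -> str:
        return ",".join(REPORT_COLUMNS)

    def to_csv_row(self) -> str:
        return ",".join(repr(getattr(self, c)) for c in REPORT_COLUMNS)


def confusion_matrix(truth: Sequence, predicted: Sequence, positive_label) -> ConfusionMatrix:
    """Tally a binary confusion matrix.

    ``positive_label`` designates the positive (minority/target) class; every
    other observed label is treated as negative.  The label alphabet of
    ``truth`` and ``predicted`` combined must contain at most two values and
    must contain ``positive_label``.
    """
    truth = list(truth)
    predicted = list(predicted)
    if len(truth) != len(predicted):
        raise ValueError(f"length mismatch: {len(truth)} truth vs {len(predicted)} predicted labels")
    if not truth:
        raise ValueError("label sequences must be non-empty")
    alphabet = set(truth) | set(predicted)
    if positive_label not in alphabet:
        raise ValueError(f"positive_label {positive_label!r} absent from label alphabet {sorted(map(repr, alphabet))}")
    if len(alphabet) > 2:
        raise ValueError(f"expected binary labels, found {len(alphabet)} distinct values")
    tp = tn = fp = fn = 0
    for t, p in zip(truth, predicted):
        if t == positive_label:
            if p == positive_label:
                tp += 1
            else:
                fn += 1
        else:
            if p == positive_label:
                fp += 1
            else:
                tn += 1
    return ConfusionMatrix(tp=tp, tn=tn, fp=fp, fn=fn)


def _require_nonempty(cm: ConfusionMatrix) -> int:
    if cm.total < 1:
        raise UndefinedMetricError("metric undefined on an empty confusion matrix")
    return cm.total


def accuracy(cm: ConfusionMatrix) -> float:
    """(TP + TN) / (P + N)."""
    total = _require_nonempty(cm)
    return (cm.tp + cm.tn) / total


def kappa(cm: ConfusionMatrix) -> float:
    """Cohen's kappa (Po - Pc) / (1 - Pc).

    Po is the observed agreement (accuracy); Pc the chance agreement computed
    from the row/column marginals.  When Pc == 1 (all mass in a single cell)
    agreement cannot exceed chance in any realizable way and kappa is defined
    as 0.
    """
    total = _require_nonempty(cm)
    po = (cm.tp + cm.tn) / total
    pc = ((cm.tp + cm.fp) * (cm.tp + cm.fn) + (cm.fn + cm.tn) * (cm.fp + cm.tn)) / total**2
    if pc >= 1.0:
        return 0.0
    return (po - pc) / (1.0 - pc)


def g_mean(cm: ConfusionMatrix) -> float:
    """Geometric mean of sensitivity TP/(TP+FN) and specificity TN/(TN+FP)."""
    _require_nonempty(cm)
    if cm.positives < 1 or cm.negatives < 1:
        raise UndefinedMetricError("g_mean requires both classes present in the truth labels")
    sens = cm.tp / cm.positives
    spec = cm.tn / cm.negatives
    return math.sqrt(sens * spec)


def f_measure(cm: ConfusionMatrix) -> float:
    """F1 = 2 TP / (2 TP + FP + FN) for the positive class of ``cm``."""
    _require_nonempty(cm)
    denom = 2 * cm.tp + cm.fp + cm.fn
    if denom == 0:
        raise UndefinedMetricError("f_measure undefined when tp = fp = fn = 0")
    return 2 * cm.tp / denom


def reliable_accuracy(kappa_value: float, accuracy_value: float) -> float:
    """The decision value kappa x accuracy used to rank archive members."""
    if not -1.0 <= kappa_value <= 1.0:
        raise ValueError(f"kappa {kappa_value} outside [-1, 1]")
    if not 0.0 <= accuracy_value <= 1.0:
        raise ValueError(f"accuracy {accuracy_value} outside [0, 1]")
    return kappa_value * accuracy_value


# Agreement bands.  Each entry is (upper_edge, label); a kappa value belongs
# to the first band whose upper edge it does not exceed (boundaries closed on
# the right, matching the "0.41 <= kappa <= 0.60" style inequalities).  The
# six-band scheme's printed bins start at 0.01, leaving [0, 0.01) unassigned;
# that sliver is folded into "slight agreement".
_SIX_BAND = (
    (0.0, "less than chance agreement"),
    (0.20, "slight agreement"),
    (0.40, "fair agreement"),
    (0.60, "moderate agreement"),
    (0.80, "substantial agreement"),
    (1.0, "almost perfect agreement"),
)
_FOUR_BAND = (
    (0.0, "meaningless"),
    (0.40, "low credibility"),
    (0.75, "general credibility"),
    (1.0, "strong credibility"),
)


def interpret_kappa(kappa_value: float, scale: str = "six_band") -> str:
    """Map a kappa value to its qualitative agreement band.

    ``scale`` is ``"six_band"`` (less-than-chance ... almost perfect) or
    ``"four_band"`` (meaningless / low / general / strong credibility, with
    cut points 0, 0.4 and 0.75).  Bands are contiguous, cover [-1, 1] and are
    closed on the right.  The six-band scheme's printed bins label strictly
    negative values "less than chance agreement" and start "slight agreement"
    at 0.01; the unassigned sliver [0, 0.01) is folded into "slight
    agreement".
    """
    if not -1.0 <= kappa_value <= 1.0:
        raise ValueError(f"kappa {kappa_value} outside [-1, 1]")
    if scale == "six_band":
        bands = _SIX_BAND
    elif scale == "four_band":
        bands = _FOUR_BAND
    else:
        raise ValueError(f"unknown band scheme {scale!r}")
    if scale == "six_band" and kappa_value < 0.0:
        return bands[0][1]
    if scale == "four_band" and kappa_value <= 0.0:
        return bands[0][1]
    for upper, label in bands[1:]:
        if kappa_value <= upper:
            return label
    return bands[-1][1]  # pragma: no cover - unreachable for kappa <= 1


def sweep_confusion(majority: int, minority: int) -> list[ConfusionMatrix]:
    """Enumerate the full lattice of confusion matrices for fixed class sizes.

    With ``majority`` negatives and ``minority`` positives, every state
    TP in 0..majority (outer index) x TN in 0..minority (inner index) is
    emitted with FP = majority - TP and FN = minority - TN.  The first
    element is the all-wrong matrix, the last the all-correct one, and the
    sequence has (majority + 1) x (minority + 1) elements — 606 for the
    canonical 100-majority / 5-minority illustration.

    Every state satisfies TP + FP = majority and TN + FN = minority: the
    sweep walks majority samples from the FP cell into TP and minority
    samples from FN into TN, tracing the trajectory from the all-wrong
    matrix (0, 0, majority, minority) to the all-correct one
    (majority, minority, 0, 0).
    """
    if majority < 1 or minority < 1:
        raise ValueError("majority and minority must both be >= 1")
    states = []
    for tp in range(majority + 1):
        for tn in range(minority + 1):
            states.append(ConfusionMatrix(tp=tp, tn=tn, fp=majority - tp, fn=minority - tn))
    return states


def report_from_confusion(cm: ConfusionMatrix, fmeasure_positive: str = "minority") -> MetricsReport:
    """Compute the full metrics report for a confusion matrix.

    The matrix is assumed to have the minority/target class on the positive
    axis (the convention of :func:`swarmbalance.pipeline.train_eval`), so
    ``majority_count`` = tn + fp and ``minority_count`` = tp + fn.

    ``fmeasure_positive`` selects which class the F-measure (and only the
    F-measure) scores: ``"minority"`` (the imbalanced-learning convention,
    default) or ``"majority"`` (swaps the matrix roles; some published
    benchmark tables are only consistent with this reading).
    """
    if fmeasure_positive == "minority":
        fcm = cm
    elif fmeasure_positive == "majority":
        fcm = ConfusionMatrix(tp=cm.tn, tn=cm.tp, fp=cm.fn, fn=cm.fp)
    else:
        raise ValueError(f"fmeasure_positive must be 'minority' or 'majority', got {fmeasure_positive!r}")
    k = kappa(cm)
    a = accuracy(cm)
    return MetricsReport(
        kappa=k,
        accuracy=a,
        g_mean=g_mean(cm),
        f_measure=f_measure(fcm),
        reliable_accuracy=reliable_accuracy(k, a),
        majority_count=float(cm.negatives),
        minority_count=float(cm.positives),
    )


def reports_to_csv(reports: Iterable[MetricsReport]) -> str:
    """Serialize reports to CSV with the fixed column order."""
    buf = io.StringIO()
    buf.write(MetricsReport.csv_header() + "\n")
    for r in reports:
        buf.write(r.to_csv_row() + "\n")
    return buf.getvalue()
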