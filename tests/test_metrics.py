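"""Metric formulas, agreement bands and the confusion-matrix sweep."""

from fractions import Fraction

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from swarmbalance.metrics import (
    ConfusionMatrix,
    MetricsReport,
    UndefinedMetricError,
    accuracy,
    confusion_matrix,
    f_measure,
    g_mean,
    interpret_kappa,
    kappa,
    reliable_accuracy,
    report_from_confusion,
    reports_to_csv,
    sweep_confusion,
)


def oracle_metrics(tp, tn, fp, fn):
    """Independent from-the-formula arithmetic in exact rationals."""
    total = tp + tn + fp + fn
    acc = Fraction(tp + tn, total)
    pc = Fraction((tp + fp) * (tp + fn) + (fn + tn) * (fp + tn), total**2)
    kap = Fraction(0) if pc == 1 else (acc - pc) / (1 - pc)
    return float(acc), float(kap)


class TestConfusionMatrix:
    def test_identity_case(self):
        cm = confusion_matrix(["+", "-"], ["+", "-"], positive_label="+")
        assert (cm.tp, cm.tn, cm.fp, cm.fn) == (1, 1, 0, 0)

    def test_constant_majority_predictor_on_105_samples(self):
        truth = [1] * 5 + [0] * 100
        predicted = [0] * 105
        cm = confusion_matrix(truth, predicted, positive_label=1)
        assert (cm.tp, cm.tn, cm.fp, cm.fn) == (0, 100, 0, 5)

    def test_matches_per_pair_tally(self):
        rng = np.random.default_rng(0)
        truth = rng.integers(0, 2, 20)
        pred = rng.integers(0, 2, 20)
        cm = confusion_matrix(truth, pred, positive_label=1)
        tally = {"tp": 0, "tn": 0, "fp": 0, "fn": 0}
        for t, p in zip(truth, pred):
            key = ("t" if t == p else "f") + ("p" if p == 1 else "n")
            tally[key] += 1
        assert cm.tp == tally["tp"] and cm.tn == tally["tn"]
        assert cm.fp == tally["fp"] and cm.fn == tally["fn"]
        assert cm.total == 20

    def test_input_errors(self):
        with pytest.raises(ValueError, match="length mismatch"):
            confusion_matrix([1, 0], [1], positive_label=1)
        with pytest.raises(ValueError, match="absent"):
            confusion_matrix([1, 0], [1, 0], positive_label=2)
        with pytest.raises(ValueError):
            ConfusionMatrix(tp=-1, tn=0, fp=0, fn=1)


class TestPointValues:
    @pytest.mark.parametrize(
        "cm, expected",
        [
            (ConfusionMatrix(100, 5, 0, 0), 1.0),
            (ConfusionMatrix(0, 0, 100, 5), 0.0),
            (ConfusionMatrix(50, 50, 3, 2), 100 / 105),
        ],
    )
    def test_accuracy(self, cm, expected):
        assert accuracy(cm) == pytest.approx(expected, abs=1e-15)

    @pytest.mark.parametrize(
        "cm, expected",
        [
            (ConfusionMatrix(100, 5, 0, 0), 1.0),
            (ConfusionMatrix(0, 100, 0, 5), 0.0),  # constant predictor: Po == Pc
            (ConfusionMatrix(0, 0, 100, 5), oracle_metrics(0, 0, 100, 5)[1]),
        ],
    )
    def test_kappa(self, cm, expected):
        assert kappa(cm) == pytest.approx(expected, abs=1e-15)

    def test_kappa_all_wrong_is_about_minus_one_tenth(self):
        assert kappa(ConfusionMatrix(0, 0, 100, 5)) == pytest.approx(-0.0998, abs=5e-5)

    @pytest.mark.parametrize(
        "cm, expected",
        [
            (ConfusionMatrix(100, 5, 0, 0), 1.0),
            (ConfusionMatrix(0, 100, 0, 5), 0.0),
            (ConfusionMatrix(4, 80, 20, 1), 0.8),
        ],
    )
    def test_g_mean(self, cm, expected):
        assert g_mean(cm) == pytest.approx(expected, abs=1e-12)

    @pytest.mark.parametrize(
        "cm, expected",
        [
            (ConfusionMatrix(100, 5, 0, 0), 1.0),
            (ConfusionMatrix(0, 10, 3, 2), 0.0),
            (ConfusionMatrix(tp=4, tn=0, fp=2, fn=1), 8 / 11),
        ],
    )
    def test_f_measure(self, cm, expected):
        assert f_measure(cm) == pytest.approx(expected, abs=1e-12)

    def test_reliable_accuracy_is_exact_product(self):
        assert reliable_accuracy(1.0, 1.0) == 1.0
        assert reliable_accuracy(0.0, 0.95) == 0.0
        assert reliable_accuracy(0.8, 0.9) == pytest.approx(0.72, abs=1e-15)

    def test_undefined_cases_raise(self):
        with pytest.raises(UndefinedMetricError):
            g_mean(ConfusionMatrix(3, 0, 0, 2))  # no negatives in truth
        with pytest.raises(UndefinedMetricError):
            f_measure(ConfusionMatrix(0, 9, 0, 0))


@settings(max_examples=300, deadline=None, derandomize=True)
@given(
    tp=st.integers(0, 200),
    tn=st.integers(0, 200),
    fp=st.integers(0, 200),
    fn=st.integers(0, 200),
)
def test_kappa_and_accuracy_match_rational_oracle(tp, tn, fp, fn):
    if tp + tn + fp + fn == 0:
        return
    cm = ConfusionMatrix(tp, tn, fp, fn)
    acc_o, kap_o = oracle_metrics(tp, tn, fp, fn)
    assert accuracy(cm) == pytest.approx(acc_o, abs=1e-12)
    assert kappa(cm) == pytest.approx(kap_o, abs=1e-12)
    # chance-corrected agreement can never exceed raw agreement
    pc = ((tp + fp) * (tp + fn) + (fn + tn) * (fp + tn)) / (tp + tn + fp + fn) ** 2
    if pc < 1:
        assert kappa(cm) <= accuracy(cm) + 1e-12


@settings(max_examples=100, deadline=None, derandomize=True)
@given(p=st.integers(1, 500), n=st.integers(1, 500))
def test_constant_predictor_has_zero_kappa(p, n):
    """Predicting the majority class for everything earns no credibility."""
    assert kappa(ConfusionMatrix(tp=0, tn=n, fp=0, fn=p)) == 0.0
    assert kappa(ConfusionMatrix(tp=p, tn=0, fp=n, fn=0)) == 0.0


class TestInterpretKappa:
    @pytest.mark.parametrize(
        "value, band",
        [
            (0.85, "almost perfect agreement"),
            (-0.5, "less than chance agreement"),
            (0.5, "moderate agreement"),
            (0.60, "moderate agreement"),  # right-closed boundary
            (0.0, "slight agreement"),  # [0, 0.01) folded upward
        ],
    )
    def test_six_band_examples(self, value, band):
        assert interpret_kappa(value, "six_band") == band

    @pytest.mark.parametrize(
        "value, band",
        [
            (-0.2, "meaningless"),
            (0.2, "low credibility"),
            (0.5, "general credibility"),
            (0.9, "strong credibility"),
        ],
    )
    def test_four_band_examples(self, value, band):
        assert interpret_kappa(value, "four_band") == band

    @pytest.mark.parametrize("scale", ["six_band", "four_band"])
    def test_bands_partition_the_range(self, scale):
        grid = np.linspace(-1.0, 1.0, 2001)  # step 0.001
        labels = [interpret_kappa(float(v), scale) for v in grid]
        # total coverage: every grid point got exactly one label (no raise),
        # and bands appear as contiguous runs in ascending kappa order
        changes = [labels[0]] + [b for a, b in zip(labels, labels[1:]) if a != b]
        assert len(changes) == len(set(changes))  # each band is one run

    def test_out_of_range_raises(self):
        with pytest.raises(ValueError):
            interpret_kappa(1.5)


class TestSweep:
    def test_canonical_606_states(self):
        states = sweep_confusion(100, 5)
        assert len(states) == 606
        assert states[0] == ConfusionMatrix(0, 0, 100, 5)
        assert states[-1] == ConfusionMatrix(100, 5, 0, 0)
        assert kappa(states[-1]) == 1.0
        assert accuracy(states[-1]) == 1.0

    def test_two_by_two(self):
        assert len(sweep_confusion(1, 1)) == 4

    def test_marginals_and_kappa_bound(self):
        for m, n in [(2, 1), (3, 4)]:
            states = sweep_confusion(m, n)
            assert len(states) == (m + 1) * (n + 1)
            for cm in states:
                assert cm.tp + cm.fp == m
                assert cm.tn + cm.fn == n
                assert kappa(cm) <= accuracy(cm) + 1e-12


def test_report_serialization_order():
    r = report_from_confusion(ConfusionMatrix(4, 80, 20, 1))
    csv = reports_to_csv([r])
    header = csv.splitlines()[0]
    assert header == "kappa,accuracy,g_mean,f_measure,reliable_accuracy,majority_count,minority_count"
    assert list(r.to_dict()) == header.split(",")
    assert r.reliable_accuracy == pytest.approx(r.kappa * r.accuracy, abs=1e-15)


def test_fmeasure_positive_class_flag():
    cm = ConfusionMatrix(tp=0, tn=100, fp=0, fn=5)  # constant majority predictor
    r_min = report_from_confusion(cm, fmeasure_positive="minority")
    r_maj = report_from_confusion(cm, fmeasure_positive="majority")
    assert r_min.f_measure == 0.0  # minority never predicted
    assert r_maj.f_measure == pytest.approx(200 / 205)  # majority F1 looks great
    assert r_min.kappa == r_maj.kappa == 0.0
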