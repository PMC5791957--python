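"""Binary cascade: splitting, MCC, stage training, assembly, inference."""

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import matthews_corrcoef

from gummix.cascade import (CascadeClassifier, CascadeStage, ConfusionCounts,
                            UNCLASSIFIED, assemble_cascade, classify,
                            evaluate_cascade, h_sweep_values, mcc,
                            split_dataset, train_stage)
from gummix.errors import CalibrationError, InputError


def _planted(rng, n_per_class=40, k=6, gap=5.0):
    """Well-separated Gaussian classes along a shared direction."""
    classes = [0, 5, 10, 15, 20]
    x, y = [], []
    for i, t in enumerate(classes):
        centre = np.zeros(k)
        centre[:3] = i * gap
        x.append(rng.normal(centre, 1.0, size=(n_per_class, k)))
        y.append(np.full(n_per_class, t))
    return np.vstack(x), np.concatenate(y)


def _fixed_stage(target_t, k=3, fire=True):
    """A stage whose output is constant regardless of input."""
    bias = 50.0 if fire else -50.0
    return CascadeStage(
        target_t=target_t, h=2, feature_codes=[f"f{i}" for i in range(k)],
        scaler_mean=np.zeros(k), scaler_scale=np.ones(k),
        w1=np.zeros((k, 2)), b1=np.zeros(2), w2=np.zeros((2, 1)),
        b2=np.array([bias]), mcc_sg=0.99, seed=0,
    )


class TestSplit:
    def test_400_samples_split_160_120_120(self):
        labels = np.repeat([0, 5, 10, 15, 20], 80)
        tags = split_dataset(labels, seed=3)
        assert (tags == "TG").sum() == 160
        assert (tags == "VG").sum() == 120
        assert (tags == "SG").sum() == 120

    def test_stratified_per_class(self):
        labels = np.repeat([0, 5, 10, 15, 20], 80)
        tags = split_dataset(labels, seed=3)
        for cls in (0, 5, 10, 15, 20):
            sel = labels == cls
            assert (tags[sel] == "TG").sum() == 32
            assert (tags[sel] == "VG").sum() == 24
            assert (tags[sel] == "SG").sum() == 24

    def test_deterministic_and_small_class_error(self):
        labels = np.repeat([0, 5], 50)
        assert np.array_equal(split_dataset(labels, 7), split_dataset(labels, 7))
        with pytest.raises(InputError):
            split_dataset(np.array([0] * 5 + [1] * 50), 0)


class TestMCC:
    def test_closed_forms(self):
        assert mcc(ConfusionCounts(tp=50, tn=50, fp=0, fn=0)) == 1.0
        assert mcc(ConfusionCounts(tp=0, tn=0, fp=50, fn=50)) == -1.0
        assert mcc(ConfusionCounts(tp=25, tn=25, fp=25, fn=25)) == 0.0

    def test_zero_denominator_convention_and_empty(self):
        assert mcc(ConfusionCounts(tp=10, tn=0, fp=0, fn=5)) == 0.0
        with pytest.raises(InputError):
            mcc(ConfusionCounts())

    def test_symmetry_under_class_swap(self, rng):
        for _ in range(50):
            tp, tn, fp, fn = rng.integers(0, 40, size=4)
            if tp + tn + fp + fn == 0:
                continue
            a = mcc(ConfusionCounts(tp=tp, tn=tn, fp=fp, fn=fn))
            b = mcc(ConfusionCounts(tp=tn, tn=tp, fp=fn, fn=fp))
            assert a == pytest.approx(b)

    def test_oracle_equivalence_on_random_confusions(self, rng):
        """MCC from counts matches sklearn on expanded label vectors."""
        for _ in range(1000):
            tp, tn, fp, fn = (int(v) for v in rng.integers(0, 12, size=4))
            if tp + tn + fp + fn == 0:
                continue
            y_true = [1] * tp + [0] * tn + [0] * fp + [1] * fn
            y_pred = [1] * tp + [0] * tn + [1] * fp + [0] * fn
            ours = mcc(ConfusionCounts(tp=tp, tn=tn, fp=fp, fn=fn))
            theirs = matthews_corrcoef(y_true, y_pred)
            assert ours == pytest.approx(theirs, abs=1e-12)


class TestHSweep:
    def test_full_sweep_bounds(self):
        values = h_sweep_values(35)
        assert values[0] == 12 and values[-1] == 35 and len(values) == 24

    def test_reduced_sweep(self):
        values = h_sweep_values(35, 10)
        assert len(values) == 10
        assert values[0] == 12 and values[-1] == 35


class TestTrainStage:
    def test_separable_data_suitable(self, rng):
        x, y = _planted(rng)
        stage = train_stage(x, y, target_t=10, seed=1,
                            h_values=[3, 4], restarts=2)
        assert stage.mcc_sg == 1.0
        assert stage.suitable

    def test_permuted_labels_not_suitable(self, rng):
        x, y = _planted(rng)
        y_perm = rng.permutation(y)
        stage = train_stage(x, y_perm, target_t=10, seed=1,
                            h_values=[3], restarts=2, max_epochs=60)
        assert stage.mcc_sg < 0.5
        assert not stage.suitable


class TestAssembleAndClassify:
    def test_ordering_contract(self):
        stages = [_fixed_stage(t, fire=False) for t in (20, 0, 10, 5, 15)]
        cascade = assemble_cascade(stages)
        assert [s.target_t for s in cascade.stages] == [0, 5, 10, 15, 20]

    def test_unsuitable_stage_fails_calibration(self):
        bad = _fixed_stage(5)
        bad.mcc_sg = 0.90
        with pytest.raises(CalibrationError, match="5"):
            assemble_cascade([_fixed_stage(0), bad])
        with pytest.raises(CalibrationError):
            assemble_cascade([])

    def test_first_firing_stage_wins(self):
        stages = [_fixed_stage(0, fire=False), _fixed_stage(5, fire=True),
                  _fixed_stage(10, fire=True)]
        cascade = assemble_cascade(stages)
        assert classify(np.zeros(3), cascade) == 5

    def test_no_stage_fires_is_unclassified(self):
        cascade = assemble_cascade([_fixed_stage(t, fire=False) for t in (0, 5)])
        assert classify(np.zeros(3), cascade) is UNCLASSIFIED

    def test_feature_mismatch_rejected(self):
        cascade = assemble_cascade([_fixed_stage(0)])
        with pytest.raises(InputError):
            classify(pd.Series({"wrong": 1.0}), cascade)
        with pytest.raises(InputError):
            classify(np.zeros(7), cascade)

    def test_deterministic(self, rng):
        x, y = _planted(rng)
        stage = train_stage(x, y, target_t=0, seed=2, h_values=[3],
                            restarts=1, max_epochs=100)
        cascade = CascadeClassifier(stages=[stage])
        row = x[0]
        assert classify(row, cascade) == classify(row, cascade)


class TestEvaluate:
    def test_perfect_cascade_metrics(self, rng):
        x, y = _planted(rng)
        stages = [train_stage(x, y, target_t=t, seed=3, h_values=[4, 6],
                              restarts=3)
                  for t in (0, 5, 10, 15, 20)]
        cascade = assemble_cascade(stages)
        res = evaluate_cascade(cascade, x, y)
        assert res["mcc"] == 1.0
        assert res["sensitivity"] == 1.0
        assert res["specificity"] == 1.0
        assert res["accuracy"] == 1.0
        assert res["unclassified"] == 0

    def test_constant_false_cascade_reports_undefined(self, rng):
        cascade = assemble_cascade(
            [_fixed_stage(t, fire=False) for t in (0, 5, 10)])
        x = rng.normal(size=(20, 3))
        y = np.repeat([0, 5, 10], [7, 7, 6])
        res = evaluate_cascade(cascade, x, y)
        assert res["unclassified"] == 20
        assert res["mcc"] is None and res["accuracy"] is None

    def test_empty_test_set_rejected(self):
        cascade = assemble_cascade([_fixed_stage(0)])
        with pytest.raises(InputError):
            evaluate_cascade(cascade, np.empty((0, 3)), np.empty(0))
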