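"""Single-feature z-score classifier (comparison baseline).

Classical mixing indices reduce a specimen to one scalar (for instance
the circular variance of hue).  This baseline classifies such a scalar
by its z-score against per-class Training-Group statistics,

    z_{i,T} = (mp_i - mean_T) / sd_T ,

pre-classifying a sample into class ``T`` when ``|z| <= 0.25`` (used
for per-class "core" MCC tables) and finally assigning the class with
the smallest ``|z|``.  It exists to show how much a multi-feature
neural cascade buys over a single feature.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cascade import ConfusionCounts, confusion_from_predictions, mcc
from .errors import InputError, SelectionError

PRECLASSIFY_BAND = 0.25


@dataclass
class ZScoreModel:
    """Per-class mean/sd of one feature, estimated from the Training Group."""

    mfc_code: str
    classes: list[int]
    means: dict[int, float]
    sds: dict[int, float]


def fit_zscore_model(feature_values, stroke_labels, mfc_code: str = "") -> ZScoreModel:
    """Per-class mean and sample (n-1) standard deviation of one feature."""
    x = np.asarray(feature_values, dtype=np.float64)
    y = np.asarray(stroke_labels)
    classes = sorted(int(c) for c in np.unique(y))
    means, sds = {}, {}
    for c in classes:
        vals = x[y == c]
        if vals.size < 2 and len(classes) > 1:
            raise InputError(f"class {c} needs >=2 samples")
        means[c] = float(vals.mean())
        sd = float(vals.std(ddof=1)) if vals.size > 1 else 0.0
        if sd == 0.0:
            raise SelectionError(f"zero within-class variance for class {c}")
        sds[c] = sd
    return ZScoreModel(mfc_code=mfc_code, classes=classes, means=means, sds=sds)


def zscore(mp_value: float, model: ZScoreModel, T: int) -> float:
    """Standard score of a measurement against class ``T``'s statistics."""
    if T not in model.means:
        raise InputError(f"unknown stroke class {T}")
    return (float(mp_value) - model.means[T]) / model.sds[T]


def zscore_preclassify(mp_value: float, model: ZScoreModel, T: int) -> bool:
    """True when the measurement sits within the |z| <= 0.25 core band."""
    return abs(zscore(mp_value, model, T)) <= PRECLASSIFY_BAND


def zscore_classify(mp_value: float, model: ZScoreModel) -> int:
    """Class with the smallest |z|; ties go to the smaller stroke count."""
    best_cls = None
    best_abs = np.inf
    for c in model.classes:  # ascending, so ties keep the smaller count
        az = abs(zscore(mp_value, model, c))
        if az < best_abs - 1e-15:
            best_abs = az
            best_cls = c
    return int(best_cls)


def core_mcc_table(feature_values, stroke_labels, model: ZScoreModel) -> pd.DataFrame:
    """Per-class core MCC of the |z| <= 0.25 pre-classification rule.

    One row per stroke class T: the binary task "does this sample
    belong to T?" answered by the core band, scored with MCC.
    """
    x = np.asarray(feature_values, dtype=np.float64)
    y = np.asarray(stroke_labels)
    rows = []
    for c in model.classes:
        pred = np.array([zscore_preclassify(v, model, c) for v in x])
        rows.append({"mfc_code": model.mfc_code, "T": c,
                     "core_mcc": mcc(confusion_from_predictions(y == c, pred))})
    return pd.DataFrame(rows)


def global_mcc(feature_values, stroke_labels, model: ZScoreModel) -> float:
    """Pooled one-vs-rest MCC of the argmin-|z| classifier."""
    x = np.asarray(feature_values, dtype=np.float64)
    y = np.asarray(stroke_labels)
    preds = np.array([zscore_classify(v, model) for v in x])
    pooled = ConfusionCounts()
    for c in model.classes:
        cc = confusion_from_predictions(y == c, preds == c)
        pooled.tp += cc.tp
        pooled.tn += cc.tn
        pooled.fp += cc.fp
        pooled.fn += cc.fn
    return mcc(pooled)
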