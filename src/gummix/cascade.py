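"""Binary-cascade pattern classification of MP vectors.

For every calibrated stroke class ``t_i`` a one-vs-rest binary
multilayer perceptron (k inputs, h hidden logistic units, one logistic
output) is trained to answer "was this specimen chewed t_i strokes?".
The hidden-layer width ``h`` is swept from ``ceil(k/3)`` to ``k`` with
several independently seeded trainings per width; every candidate is
scored on a held-out Testing Group with the Matthews Correlation
Coefficient (MCC) and the best one becomes the class's stage.  A stage
is *suitable* only if its MCC exceeds 0.95; calibration fails loudly
otherwise.  Suitable stages, ordered by ascending stroke count, form
the cascade: a new MP vector is offered to each stage in turn and the
first stage that fires assigns its stroke count; if none fires the
specimen is UNCLASSIFIED (surfaced, never coerced to a class).

Training uses scikit-learn's MLP optimiser driven epoch-by-epoch so
that early stopping can monitor the explicit Validation Group; the
learned weights are extracted into plain arrays, and all subsequent
prediction runs through the package's own forward pass — this is what
makes serialized classifiers behave bit-identically after a round trip
through a portable record.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.neural_network import MLPClassifier

from .errors import CalibrationError, InputError, TrainingError

#: Sentinel returned when no cascade stage fires for a specimen.
UNCLASSIFIED = "UNCLASSIFIED"

SUITABILITY_THRESHOLD = 0.95
SPLIT_FRACTIONS = (0.4, 0.3, 0.3)  # TG, VG, SG


@dataclass
class ConfusionCounts:
    """Binary confusion-matrix counts."""

    tp: int = 0
    tn: int = 0
    fp: int = 0
    fn: int = 0

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


def mcc(confusion: ConfusionCounts) -> float:
    """Matthews Correlation Coefficient in [-1, 1].

    ``(TP*TN - FP*FN) / sqrt((TP+FP)(TP+FN)(TN+FP)(TN+FN))``; if any
    denominator factor is zero the score is 0 by the standard
    convention.
    """
    tp, tn, fp, fn = confusion.tp, confusion.tn, confusion.fp, confusion.fn
    if tp + tn + fp + fn == 0:
        raise InputError("empty confusion matrix")
    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    if denom == 0:
        return 0.0
    return float((tp * tn - fp * fn) / math.sqrt(denom))


def confusion_from_predictions(y_true, y_pred) -> ConfusionCounts:
    """Binary confusion counts from boolean prediction/label arrays."""
    t = np.asarray(y_true, bool)
    p = np.asarray(y_pred, bool)
    return ConfusionCounts(
        tp=int(np.sum(t & p)), tn=int(np.sum(~t & ~p)),
        fp=int(np.sum(~t & p)), fn=int(np.sum(t & ~p)),
    )


def split_dataset(labels, seed: int) -> np.ndarray:
    """Stratified random 40/30/30 split into TG/VG/SG tags.

    Every stroke class is split separately so each class appears in all
    three groups; deterministic per seed.  Returns an array of
    ``{"TG","VG","SG"}`` tags aligned with ``labels``.
    """
    y = np.asarray(labels)
    rng = np.random.default_rng(seed)
    tags = np.empty(y.size, dtype="<U2")
    for cls in np.unique(y):
        idx = np.flatnonzero(y == cls)
        if idx.size < 10:
            raise InputError(
                f"class {cls!r} has {idx.size} samples; need >=10 for a 40/30/30 split"
            )
        rng.shuffle(idx)
        n_tg = int(round(SPLIT_FRACTIONS[0] * idx.size))
        n_vg = int(round(SPLIT_FRACTIONS[1] * idx.size))
        tags[idx[:n_tg]] = "TG"
        tags[idx[n_tg:n_tg + n_vg]] = "VG"
        tags[idx[n_tg + n_vg:]] = "SG"
    return tags


def _logistic(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


@dataclass
class CascadeStage:
    """One trained one-vs-rest binary MLP with its validation score."""

    target_t: int
    h: int
    feature_codes: list[str]
    scaler_mean: np.ndarray
    scaler_scale: np.ndarray
    w1: np.ndarray  # (k, h)
    b1: np.ndarray  # (h,)
    w2: np.ndarray  # (h, 1)
    b2: np.ndarray  # (1,)
    mcc_sg: float
    seed: int
    epochs: int = 0
    threshold: float = 0.5

    @property
    def suitable(self) -> bool:
        return self.mcc_sg > SUITABILITY_THRESHOLD

    def decision(self, x: np.ndarray) -> np.ndarray:
        """Output-unit activation in [0, 1] for standardized-input rows."""
        x = np.asarray(x, dtype=np.float64)
        xs = (x - self.scaler_mean) / self.scaler_scale
        hidden = _logistic(xs @ self.w1 + self.b1)
        return _logistic(hidden @ self.w2 + self.b2).ravel()

    def predict(self, x: np.ndarray) -> np.ndarray:
        return self.decision(x) > self.threshold


@dataclass
class CascadeClassifier:
    """Ordered suitable stages plus the kept-feature contract."""

    stages: list[CascadeStage]
    feature_codes: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.stages and not self.feature_codes:
            self.feature_codes = list(self.stages[0].feature_codes)


def _as_matrix(x, feature_codes: list[str]) -> np.ndarray:
    if isinstance(x, pd.DataFrame):
        missing = [c for c in feature_codes if c not in x.columns]
        if missing:
            raise InputError(f"missing MFC codes: {missing}")
        return x[feature_codes].to_numpy(dtype=np.float64)
    return np.asarray(x, dtype=np.float64)


def _train_once(x_tg, y_tg, x_vg, y_vg, h: int, seed: int,
                max_epochs: int, patience: int, lr: float,
                min_epochs: int = 100):
    """One early-stopped training run; returns (weights, vg_mcc, epochs)."""
    # balance the 1-vs-rest classes by repeating positives in the TG
    pos = np.flatnonzero(y_tg)
    neg = np.flatnonzero(~y_tg)
    if pos.size == 0 or neg.size == 0:
        raise TrainingError("training group lacks one of the binary classes")
    reps = max(1, int(round(neg.size / pos.size)))
    idx = np.concatenate([neg] + [pos] * reps)
    rng = np.random.default_rng(seed)
    rng.shuffle(idx)
    xb, yb = x_tg[idx], y_tg[idx]

    clf = MLPClassifier(
        hidden_layer_sizes=(h,), activation="logistic", solver="adam",
        learning_rate_init=lr, random_state=seed, batch_size=min(64, len(yb)),
    )
    # the VG binary-decision score is a step function of the weights and
    # can sit flat for many epochs, so the stall counter watches the
    # smooth VG log-loss while the snapshot keeps the best-MCC weights
    best = None
    best_key = (-np.inf, -np.inf)
    best_loss = np.inf
    stall = 0
    perfect_run = 0
    y_vg_int = y_vg.astype(int)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for epoch in range(1, max_epochs + 1):
            clf.partial_fit(xb, yb.astype(int), classes=[0, 1])
            prob = np.clip(clf.predict_proba(x_vg)[:, 1], 1e-12, 1 - 1e-12)
            loss = -np.mean(y_vg_int * np.log(prob)
                            + (1 - y_vg_int) * np.log(1 - prob))
            score = mcc(confusion_from_predictions(y_vg, prob > 0.5))
            key = (score, -loss)
            if key > best_key:
                best_key = key
                best = ([w.copy() for w in clf.coefs_],
                        [b.copy() for b in clf.intercepts_], epoch)
            # a stage that has kept the VG perfectly separated for a
            # while will not change its SG decision any more
            perfect_run = perfect_run + 1 if score == 1.0 else 0
            if perfect_run >= 15:
                break
            if loss < best_loss - 1e-6:
                best_loss = loss
                stall = 0
            else:
                stall += 1
                # adam needs a warm-up before the VG loss moves at all
                if stall >= patience and epoch >= min_epochs:
                    break
    if best is None or not np.all([np.all(np.isfinite(w)) for w in best[0]]):
        raise TrainingError("training diverged")
    return best, best_key[0]


def h_sweep_values(k: int, n_values: int | None = None) -> list[int]:
    """Hidden-layer widths to try: ceil(k/3)..k, optionally subsampled.

    With ``n_values`` set, the sweep is thinned to that many evenly
    spaced widths (reduced-sweep policy for quick calibrations).
    """
    lo = max(1, math.ceil(k / 3))
    full = list(range(lo, k + 1))
    if n_values is None or n_values >= len(full):
        return full
    picks = np.unique(np.linspace(0, len(full) - 1, n_values).round().astype(int))
    return [full[i] for i in picks]


def train_stage(x, labels, target_t: int, seed: int = 0,
                h_values: list[int] | None = None, restarts: int = 10,
                max_epochs: int = 400, patience: int = 25,
                learning_rate: float = 0.01,
                feature_codes: list[str] | None = None) -> CascadeStage:
    """Train the one-vs-rest stage for one stroke class.

    For each hidden width in the sweep, ``restarts`` independently
    seeded trainings run on a fresh stratified 40/30/30 split (the data
    are re-split per training execution); each is early-stopped against
    the Validation Group and scored by MCC on the Testing Group.  The
    single best (h, seed) candidate becomes the stage.
    """
    if isinstance(x, pd.DataFrame):
        feature_codes = feature_codes or [str(c) for c in x.columns]
        x = x.to_numpy(dtype=np.float64)
    else:
        x = np.asarray(x, dtype=np.float64)
        feature_codes = feature_codes or [f"f{i}" for i in range(x.shape[1])]
    y = np.asarray(labels)
    k = x.shape[1]
    if h_values is None:
        h_values = h_sweep_values(k)
    master = np.random.default_rng(seed)
    best_stage = None
    last_error: Exception | None = None
    for h in h_values:
        for _ in range(restarts):
            run_seed = int(master.integers(0, 2**31 - 1))
            tags = split_dataset(y, run_seed)
            tg, vg, sg = tags == "TG", tags == "VG", tags == "SG"
            mu = x[tg].mean(axis=0)
            sd = x[tg].std(axis=0)
            sd[sd == 0] = 1.0
            xs = (x - mu) / sd
            y_bin = y == target_t
            try:
                (coefs, intercepts, epochs), _ = _train_once(
                    xs[tg], y_bin[tg], xs[vg], y_bin[vg], h, run_seed,
                    max_epochs, patience, learning_rate,
                )
            except TrainingError as exc:
                last_error = exc
                continue
            stage = CascadeStage(
                target_t=int(target_t), h=h, feature_codes=list(feature_codes),
                scaler_mean=mu, scaler_scale=sd,
                w1=coefs[0], b1=intercepts[0], w2=coefs[1], b2=intercepts[1],
                mcc_sg=0.0, seed=run_seed, epochs=epochs,
            )
            score = mcc(confusion_from_predictions(y_bin[sg], stage.predict(x[sg])))
            stage.mcc_sg = score
            if best_stage is None or score > best_stage.mcc_sg:
                best_stage = stage
    if best_stage is None:
        raise TrainingError(
            f"no network converged for stroke class {target_t}"
        ) from last_error
    return best_stage


def assemble_cascade(stages: list[CascadeStage]) -> CascadeClassifier:
    """Order suitable stages by ascending stroke count into one cascade.

    Calibration fails if the stage list is empty or any stage falls at
    or below the MCC suitability gate.
    """
    if not stages:
        raise CalibrationError("no stages to assemble")
    unsuitable = [s for s in stages if not s.suitable]
    if unsuitable:
        classes = [s.target_t for s in unsuitable]
        scores = [round(s.mcc_sg, 4) for s in unsuitable]
        raise CalibrationError(
            f"calibration failed: stroke classes {classes} have MCC {scores} "
            f"<= {SUITABILITY_THRESHOLD}"
        )
    ordered = sorted(stages, key=lambda s: s.target_t)
    return CascadeClassifier(stages=ordered)


def classify(mp, cascade: CascadeClassifier):
    """Run one MP vector through the cascade.

    Stages are queried in ascending stroke order; the first stage whose
    binary output fires determines the predicted stroke count P.  If no
    stage fires the sentinel :data:`UNCLASSIFIED` is returned.
    """
    if isinstance(mp, pd.Series):
        missing = [c for c in cascade.feature_codes if c not in mp.index]
        if missing:
            raise InputError(f"MP vector lacks MFC codes: {missing}")
        row = mp[cascade.feature_codes].to_numpy(dtype=np.float64)
    else:
        row = np.asarray(mp, dtype=np.float64)
        if row.size != len(cascade.feature_codes):
            raise InputError(
                f"expected {len(cascade.feature_codes)} features, got {row.size}"
            )
    row = row.reshape(1, -1)
    for stage in cascade.stages:
        if bool(stage.predict(row)[0]):
            return stage.target_t
    return UNCLASSIFIED


def evaluate_cascade(cascade: CascadeClassifier, x, labels) -> dict:
    """Confusion counts per stage and pooled global metrics on test rows.

    Cascade predictions are compared one-vs-rest against each stage's
    stroke class; per-stage counts are pooled into global MCC,
    sensitivity, specificity and accuracy.  UNCLASSIFIED specimens are
    counted separately (they contribute negatives to every stage).
    When every specimen is unclassified the global metrics are
    undefined and reported as None.
    """
    mat = _as_matrix(x, cascade.feature_codes)
    y = np.asarray(labels)
    if mat.shape[0] == 0:
        raise InputError("empty test set")
    preds = np.array([classify(row, cascade) for row in mat], dtype=object)
    unclassified = int(np.sum(preds == UNCLASSIFIED))
    per_stage: dict[int, ConfusionCounts] = {}
    pooled = ConfusionCounts()
    for stage in cascade.stages:
        t = stage.target_t
        cc = confusion_from_predictions(y == t, preds == t)
        per_stage[t] = cc
        pooled.tp += cc.tp
        pooled.tn += cc.tn
        pooled.fp += cc.fp
        pooled.fn += cc.fn
    if unclassified == len(preds):
        return {"per_stage": per_stage, "unclassified": unclassified,
                "mcc": None, "sensitivity": None, "specificity": None,
                "accuracy": None}
    sens = pooled.tp / (pooled.tp + pooled.fn) if pooled.tp + pooled.fn else None
    spec = pooled.tn / (pooled.tn + pooled.fp) if pooled.tn + pooled.fp else None
    acc = (pooled.tp + pooled.tn) / pooled.total
    return {"per_stage": per_stage, "unclassified": unclassified,
            "mcc": mcc(pooled), "sensitivity": sens, "specificity": spec,
            "accuracy": acc}
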