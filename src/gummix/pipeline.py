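"""End-to-end calibration and diagnosis drivers.

The system has two stages: a *calibration* stage that turns a labelled
specimen collection into a portable MEPAT record (segmentation ->
121-feature extraction -> relevancy selection -> cascade training ->
MCC validation), and a *diagnosis* stage that applies a MEPAT to new
specimens one at a time.  The functions here orchestrate the module
pipeline; the command-line interface is a thin wrapper over them.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .cascade import (assemble_cascade, evaluate_cascade, h_sweep_values,
                      split_dataset, train_stage)
from .errors import CalibrationError
from .features import extract_mp, mp_table
from .mepat import (Characterizer, ExperimentalSettings, MEPATRecord, Operator,
                    Performance, TestFood, read_mepat, write_mepat)
from .diagnosis import DiagnosisResult, diagnose, patient_summary
from .segmentation import SegmentationParams, segment_pair
from .synthetic import SyntheticSpecimen

log = logging.getLogger("gummix")


@dataclass(frozen=True)
class TrainingPolicy:
    """Cascade-training effort knobs.

    ``h_sweep=None`` runs the full hidden-width sweep ceil(k/3)..k with
    ``restarts`` trainings per width; an integer thins the sweep to
    that many evenly spaced widths (the quick-calibration policy).
    """

    h_sweep: int | None = None
    restarts: int = 10
    max_epochs: int = 400
    patience: int = 25
    learning_rate: float = 0.01
    seed: int = 0


@dataclass
class CalibrationResult:
    record: MEPATRecord
    relevancy: pd.DataFrame
    metrics: dict
    mp: pd.DataFrame
    labels: np.ndarray
    kept: list[str] = field(default_factory=list)


def extract_dataset(specimens: list[SyntheticSpecimen],
                    seg_params: SegmentationParams | None = None,
                    use_truth_masks: bool = False) -> tuple[pd.DataFrame, np.ndarray]:
    """Segment and featurize a specimen collection.

    Returns the MP table (one row per specimen, columns = MFC codes)
    and the stroke-label vector.  ``use_truth_masks`` skips
    segmentation in favour of generator ground truth (for isolating
    downstream stages in experiments).
    """
    if seg_params is None:
        seg_params = SegmentationParams()
    vectors, labels = [], []
    for i, s in enumerate(specimens):
        masks = s.roi_truth if use_truth_masks else segment_pair(s.images, seg_params)
        vectors.append(extract_mp(s.images, masks))
        labels.append(s.t)
        if (i + 1) % 50 == 0:
            log.info("featurized %d/%d specimens", i + 1, len(specimens))
    return mp_table(vectors), np.asarray(labels)


def calibrate(specimens: list[SyntheticSpecimen],
              seg_params: SegmentationParams | None = None,
              policy: TrainingPolicy | None = None,
              test_food: TestFood | None = None,
              operator: Operator | None = None,
              mp: pd.DataFrame | None = None,
              labels: np.ndarray | None = None) -> CalibrationResult:
    """Full calibration run: specimens in, validated MEPAT record out.

    Raises :class:`~gummix.errors.CalibrationError` (via cascade
    assembly) when any stroke class fails the MCC > 0.95 suitability
    gate.  Precomputed ``mp``/``labels`` may be passed to skip the
    image stages.
    """
    from .selection import select_features

    seg_params = seg_params or SegmentationParams()
    policy = policy or TrainingPolicy()
    if mp is None or labels is None:
        mp, labels = extract_dataset(specimens, seg_params)
    cycles = tuple(int(c) for c in np.unique(labels))

    kept, relevancy = select_features(mp, labels)
    if not kept:
        raise CalibrationError("no feature reached the q >= 0.5 relevancy gate")
    log.info("kept %d of %d features", len(kept), mp.shape[1])

    x = mp[kept]
    k = len(kept)
    h_values = h_sweep_values(k, policy.h_sweep)
    rng = np.random.default_rng(policy.seed)
    stages = []
    for t in cycles:
        stage_seed = int(rng.integers(0, 2**31 - 1))
        stage = train_stage(
            x, labels, target_t=t, seed=stage_seed, h_values=h_values,
            restarts=policy.restarts, max_epochs=policy.max_epochs,
            patience=policy.patience, learning_rate=policy.learning_rate,
        )
        log.info("stage t=%d: h=%d, SG MCC=%.4f", t, stage.h, stage.mcc_sg)
        stages.append(stage)
    cascade = assemble_cascade(stages)

    # held-out evaluation of the assembled cascade on a fresh split's SG
    tags = split_dataset(labels, int(rng.integers(0, 2**31 - 1)))
    sg = tags == "SG"
    metrics = evaluate_cascade(cascade, x[sg], labels[sg])

    rel_by_code = relevancy.set_index("mfc_code")
    record = MEPATRecord(
        test_food=test_food or TestFood(),
        settings=ExperimentalSettings(cycles=cycles, segmentation=seg_params),
        characterizers=[
            Characterizer(mfc_code=c, q=float(rel_by_code.loc[c, "q"]),
                          rho=float(rel_by_code.loc[c, "rho"]),
                          gamma=int(rel_by_code.loc[c, "gamma"]))
            for c in kept
        ],
        classifier=cascade,
        operator=operator or Operator(),
        performance=Performance(
            global_mcc=metrics["mcc"], sensitivity=metrics["sensitivity"],
            specificity=metrics["specificity"], accuracy=metrics["accuracy"],
            per_stage_mcc={s.target_t: s.mcc_sg for s in cascade.stages},
            unclassified=metrics["unclassified"],
        ),
    )
    record.validate()
    return CalibrationResult(record=record, relevancy=relevancy, metrics=metrics,
                             mp=mp, labels=labels, kept=kept)


def run_calibration(specimens, outdir, seg_params=None, policy=None,
                    test_food=None, operator=None) -> CalibrationResult:
    """Calibrate and write the MEPAT file, CSV reports and a provenance log."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    result = calibrate(specimens, seg_params, policy, test_food, operator)
    write_mepat(result.record, outdir / "calibration.mepat.xml")
    result.relevancy.to_csv(outdir / "relevancy.csv", index=False)
    result.mp.assign(t=result.labels).to_csv(outdir / "mp_vectors.csv", index=False)
    metrics = {k: v for k, v in result.metrics.items() if k != "per_stage"}
    metrics["per_stage_mcc"] = {
        str(t): mcc_val for t, mcc_val in
        result.record.performance.per_stage_mcc.items()
    }
    (outdir / "metrics.json").write_text(json.dumps(metrics, indent=2))
    _write_provenance(outdir, result.record, policy or TrainingPolicy())
    return result


def run_diagnosis(mepat_path, image_pairs: list[tuple], outdir,
                  T: int = 20, specimen_ids: list[str] | None = None) -> list:
    """Diagnose a batch of image pairs with a stored MEPAT.

    Per-specimen failures are reported and skipped; the run continues.
    Writes JSON-lines results plus a per-patient summary.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    record = read_mepat(mepat_path)
    ids = specimen_ids or [f"specimen-{i:03d}" for i in range(len(image_pairs))]
    results: list[DiagnosisResult | dict] = []
    with open(outdir / "diagnosis.jsonl", "w") as fh:
        for sid, pair in zip(ids, image_pairs):
            try:
                res = diagnose(pair, record, T=T, specimen_id=sid)
                results.append(res)
                fh.write(json.dumps({
                    "specimen_id": sid, "status": res.status, "P": res.P,
                    "T": res.T, "ME": res.ME, "ME_percent": res.me_percent,
                    "tag": res.tag, "mepat_uid": res.mepat_uid,
                }) + "\n")
            except Exception as exc:  # keep the batch going
                log.error("specimen %s failed: %s", sid, exc)
                results.append({"specimen_id": sid, "error": str(exc)})
                fh.write(json.dumps({"specimen_id": sid, "status": "error",
                                     "error": str(exc)}) + "\n")
    ok = [r for r in results if isinstance(r, DiagnosisResult)]
    summary = patient_summary(ok) if ok else {}
    (outdir / "summary.json").write_text(json.dumps(summary, indent=2))
    return results


def _write_provenance(outdir: Path, record: MEPATRecord,
                      policy: TrainingPolicy) -> None:
    import scipy
    import sklearn
    import skimage

    payload = {
        "gummix_version": __version__,
        "mepat_uid": record.uid,
        "policy": asdict(policy),
        "segmentation": asdict(record.settings.segmentation),
        "stage_seeds": [s.seed for s in record.classifier.stages],
        "versions": {"numpy": np.__version__, "scipy": scipy.__version__,
                     "sklearn": sklearn.__version__, "skimage": skimage.__version__,
                     "pandas": pd.__version__},
    }
    payload["config_hash"] = hashlib.sha256(
        json.dumps(payload["policy"], sort_keys=True).encode()
    ).hexdigest()
    (outdir / "provenance.json").write_text(json.dumps(payload, indent=2))
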