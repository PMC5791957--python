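"""Single-diagnosis mixing tests and the Masticatory Efficiency scale.

A patient chews one specimen exactly ``T`` strokes (20 by default, the
mean human mastication duration).  The scan pair is segmented with the
calibrated settings, the selected characterizer features are extracted,
and the cascade predicts ``P`` — the stroke count a healthy reference
individual would need to reach a similar mixture.  The Masticatory
Efficiency is then

    ME = P / T

so ME = 0 means a total absence of mixture, ME = 1 a normal level, and
ME > 1 better-than-reference chewing.  ME maps onto linguistic tags at
the anchor levels 0/25/50/75/100% (nearest level, midpoints rounding
up; anything above 100% is "Better than the norm").
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.metrics import cohen_kappa_score

from .cascade import UNCLASSIFIED, classify
from .errors import DiagnosisError, InputError
from .features import extract_mp
from .mepat import MEPATRecord
from .segmentation import segment_pair

DEFAULT_T = 20

#: Anchor levels of the linguistic ME scale.
TAG_LEVELS: tuple[tuple[float, str], ...] = (
    (0.00, "Totally impaired"),
    (0.25, "Impeded"),
    (0.50, "Limited"),
    (0.75, "Adequate"),
    (1.00, "Normal"),
)
TAG_ABOVE = "Better than the norm"


@dataclass
class DiagnosisResult:
    """Outcome of one single-specimen mixing test."""

    P: int | None              # predicted strokes; None when unclassified
    T: int
    ME: float | None           # P/T ratio; None when unclassified
    tag: str | None
    mepat_uid: str
    specimen_id: str = ""
    status: str = "classified"  # "classified" | "unclassified"

    @property
    def me_percent(self) -> float | None:
        return None if self.ME is None else self.ME * 100.0


def me_tag(me: float) -> str:
    """Linguistic tag for an ME ratio (>= 0)."""
    if me < 0:
        raise DiagnosisError("ME must be non-negative")
    if me > 1.0:
        return TAG_ABOVE
    levels = np.array([lv for lv, _ in TAG_LEVELS])
    dist = np.abs(levels - me)
    # midpoints round up: stable argmin prefers lower index, so nudge ties
    best = int(np.argmin(np.where(np.isclose(dist, dist.min()), -levels, np.inf)))
    return TAG_LEVELS[best][1]


def diagnose(image_pair, mepat: MEPATRecord, T: int = DEFAULT_T,
             specimen_id: str = "") -> DiagnosisResult:
    """Run one calibrated mixing test on a specimen scan pair.

    ``T`` must be one of the calibrated cycle counts (behaviour for
    uncalibrated stroke numbers is undefined, so they are rejected).
    An unclassifiable specimen is surfaced with ``status
    "unclassified"`` and undefined ME, never coerced to ME = 0.
    """
    if T <= 0:
        raise DiagnosisError("T must be positive")
    if T not in mepat.settings.cycles:
        raise DiagnosisError(
            f"T={T} is not among the calibrated cycle counts {mepat.settings.cycles}"
        )
    masks = segment_pair(image_pair, mepat.settings.segmentation)
    mp = extract_mp(image_pair, masks)
    kept = [c.mfc_code for c in mepat.characterizers]
    missing = [c for c in kept if c not in mp.index]
    if missing:
        raise DiagnosisError(f"MP vector lacks characterizer codes {missing}")
    p = classify(mp[kept], mepat.classifier)
    if p is UNCLASSIFIED:
        return DiagnosisResult(P=None, T=T, ME=None, tag=None,
                               mepat_uid=mepat.uid, specimen_id=specimen_id,
                               status="unclassified")
    me = p / T
    return DiagnosisResult(P=int(p), T=T, ME=me, tag=me_tag(me),
                           mepat_uid=mepat.uid, specimen_id=specimen_id)


def repeat_agreement(results_a, results_b) -> float:
    """Cohen's kappa between two paired lists of diagnosis outcomes.

    Accepts :class:`DiagnosisResult` lists or raw label lists; results
    are compared by predicted stroke count (unclassified is its own
    category).  Diagnostic statistic for repeated-measurement
    consistency.
    """
    def to_labels(results):
        out = []
        for r in results:
            if isinstance(r, DiagnosisResult):
                out.append("U" if r.P is None else str(r.P))
            else:
                out.append(str(r))
        return out

    a, b = to_labels(results_a), to_labels(results_b)
    if len(a) != len(b):
        raise InputError("paired result lists must have equal length")
    if a == b:
        return 1.0
    return float(cohen_kappa_score(a, b))


def patient_summary(results: list[DiagnosisResult]) -> dict:
    """Summary over a patient's repeated tests: the highest ME wins."""
    mes = [r.ME for r in results if r.ME is not None]
    if not mes:
        return {"ME": None, "tag": None, "n_unclassified": len(results)}
    best = max(mes)
    return {"ME": best, "tag": me_tag(best),
            "n_unclassified": sum(1 for r in results if r.ME is None)}
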