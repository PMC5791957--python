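"""Portable calibration records (MEPAT files).

A Masticatory Efficiency and Performance Assessment Technique (MEPAT)
record bundles everything a clinician needs to run single-specimen
diagnoses with a calibrated system:

* **TF** — the test food (gum brand, colour pair, wafer dimensions),
* **ES** — experimental settings (cycle list, scanner dpi, flattening
  thickness, segmentation parameters),
* **CH** — the selected mixture characterizers (MFC codes with their
  relevancy scores and extraction parameters),
* **CLS** — the trained binary cascade (per-stage weights, scalers,
  thresholds, seeds),
* **OP** — operator/institution metadata,
* **PER** — the validation performance block (per-stage and global MCC,
  sensitivity, specificity, accuracy),

plus a UUID, creation and upload timestamps.  Records serialize to a
UTF-8 XML dialect (``.mepat.xml``) validated against the XSD shipped
with the package; the schema is this package's own — interoperability
with other software's files is not claimed.

Weights are stored as shortest round-trip decimal text, so a cascade
read back from disk reproduces bit-identical predictions, and writing
an unmodified record reproduces the file byte-for-byte.
"""

from __future__ import annotations

import datetime as _dt
import uuid
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
from lxml import etree

from .cascade import CascadeClassifier, CascadeStage
from .colorspaces import CHANNEL_CODES
from .errors import (MEPATParseError, MEPATSchemaError, MEPATValidationError)
from .features import MODEL_CODES, N_BINS
from .segmentation import SegmentationParams

_SCHEMA_CACHE: etree.XMLSchema | None = None


def _fmt(x: float) -> str:
    """Locale-independent shortest round-trip decimal for a float."""
    return repr(float(x))


def _fmt_array(a: np.ndarray) -> str:
    return " ".join(_fmt(v) for v in np.asarray(a, dtype=np.float64).ravel())


def _parse_floats(text: str | None, expected: int | None = None) -> np.ndarray:
    try:
        vals = np.array([float(v) for v in (text or "").split()], dtype=np.float64)
    except ValueError as exc:
        raise MEPATParseError(f"uninterpretable numeric content: {exc}") from exc
    if not np.all(np.isfinite(vals)):
        raise MEPATParseError("non-finite value in numeric content")
    if expected is not None and vals.size != expected:
        raise MEPATParseError(
            f"truncated numeric block: expected {expected} values, got {vals.size}"
        )
    return vals


@dataclass
class TestFood:
    brand: str = "generic two-colour gum"
    colour_pair: str = "red-white"
    dimensions_mm: str = "30x30x3"
    description: str = ""


@dataclass
class ExperimentalSettings:
    cycles: tuple[int, ...] = (0, 5, 10, 15, 20)
    scanner_dpi: int = 300
    flattening_thickness_mm: float = 1.0
    segmentation: SegmentationParams = field(default_factory=SegmentationParams)


@dataclass
class Characterizer:
    mfc_code: str
    q: float
    rho: float = 0.0
    gamma: int = 0


@dataclass
class Operator:
    name: str = "unknown"
    institution: str = "unknown"


@dataclass
class Performance:
    global_mcc: float | None = None
    sensitivity: float | None = None
    specificity: float | None = None
    accuracy: float | None = None
    per_stage_mcc: dict[int, float] = field(default_factory=dict)
    unclassified: int = 0


@dataclass
class MEPATRecord:
    """The full portable calibration artefact (TF, ES, CH, CLS, OP, PER)."""

    test_food: TestFood
    settings: ExperimentalSettings
    characterizers: list[Characterizer]
    classifier: CascadeClassifier
    operator: Operator
    performance: Performance
    uid: str = ""
    created: str = ""
    uploaded: str = ""

    def __post_init__(self) -> None:
        if not self.uid:
            self.uid = str(uuid.uuid4())
        if not self.created:
            self.created = _dt.datetime.now(_dt.timezone.utc).isoformat(timespec="seconds")
        if not self.uploaded:
            self.uploaded = self.created

    def validate(self) -> None:
        problems = []
        if not self.characterizers:
            problems.append("CH block is empty")
        if len(self.classifier.stages) != len(self.settings.cycles):
            problems.append(
                f"CLS stage count {len(self.classifier.stages)} != "
                f"|ES.cycles| {len(self.settings.cycles)}"
            )
        try:
            uuid.UUID(self.uid)
        except ValueError:
            problems.append(f"UID {self.uid!r} is not a valid UUID")
        known = {m + c for m in MODEL_CODES for c in CHANNEL_CODES} | {"CVOH"}
        bad = [c.mfc_code for c in self.characterizers if c.mfc_code not in known]
        if bad:
            problems.append(f"unknown MFC codes: {bad}")
        if problems:
            raise MEPATValidationError("; ".join(problems))


def _schema() -> etree.XMLSchema:
    global _SCHEMA_CACHE
    if _SCHEMA_CACHE is None:
        text = resources.files("gummix.data").joinpath("mepat.xsd").read_text()
        _SCHEMA_CACHE = etree.XMLSchema(etree.fromstring(text.encode()))
    return _SCHEMA_CACHE


def _build_tree(record: MEPATRecord) -> etree._Element:
    root = etree.Element("mepat", uid=record.uid, created=record.created,
                         uploaded=record.uploaded)

    tf = etree.SubElement(root, "test_food", brand=record.test_food.brand,
                          colour_pair=record.test_food.colour_pair,
                          dimensions_mm=record.test_food.dimensions_mm)
    tf.text = record.test_food.description or None

    seg = record.settings.segmentation
    es = etree.SubElement(root, "experimental_settings",
                          scanner_dpi=str(record.settings.scanner_dpi),
                          flattening_thickness_mm=_fmt(record.settings.flattening_thickness_mm))
    etree.SubElement(es, "cycles").text = " ".join(str(c) for c in record.settings.cycles)
    etree.SubElement(es, "segmentation",
                     spatial_bandwidth=_fmt(seg.spatial_bandwidth),
                     range_bandwidth=_fmt(seg.range_bandwidth),
                     ms_iterations=str(seg.ms_iterations),
                     n_init=str(seg.n_init),
                     distance_weight=_fmt(seg.distance_weight),
                     min_colour_separation=_fmt(seg.min_colour_separation),
                     closing_radius=str(seg.closing_radius),
                     convex_hull="true" if seg.convex_hull else "false",
                     seed=str(seg.seed), variant=seg.variant)

    ch = etree.SubElement(root, "characterizers", n_bins=str(N_BINS))
    for c in record.characterizers:
        etree.SubElement(ch, "feature", code=c.mfc_code, q=_fmt(c.q),
                         rho=_fmt(c.rho), gamma=str(c.gamma))

    cls = etree.SubElement(root, "classifier")
    for s in record.classifier.stages:
        st = etree.SubElement(cls, "stage", target_t=str(s.target_t), h=str(s.h),
                              mcc_sg=_fmt(s.mcc_sg), seed=str(s.seed),
                              epochs=str(s.epochs), threshold=_fmt(s.threshold))
        etree.SubElement(st, "features").text = " ".join(s.feature_codes)
        etree.SubElement(st, "scaler_mean").text = _fmt_array(s.scaler_mean)
        etree.SubElement(st, "scaler_scale").text = _fmt_array(s.scaler_scale)
        k, h = s.w1.shape
        w1 = etree.SubElement(st, "w1", rows=str(k), cols=str(h))
        w1.text = _fmt_array(s.w1)
        etree.SubElement(st, "b1").text = _fmt_array(s.b1)
        w2 = etree.SubElement(st, "w2", rows=str(h), cols="1")
        w2.text = _fmt_array(s.w2)
        etree.SubElement(st, "b2").text = _fmt_array(s.b2)

    etree.SubElement(root, "operator", name=record.operator.name,
                     institution=record.operator.institution)

    per = record.performance
    pe = etree.SubElement(root, "performance", unclassified=str(per.unclassified))
    gl = etree.SubElement(pe, "global")
    for attr, val in (("mcc", per.global_mcc), ("sensitivity", per.sensitivity),
                      ("specificity", per.specificity), ("accuracy", per.accuracy)):
        if val is not None:
            gl.set(attr, _fmt(val))
    for t in sorted(per.per_stage_mcc):
        el = etree.SubElement(pe, "stage_mcc", t=str(t))
        el.text = _fmt(per.per_stage_mcc[t])
    return root


def write_mepat(record: MEPATRecord, path) -> Path:
    """Serialize a validated record to a ``.mepat.xml`` file.

    The output is deterministic given the record, validates against the
    shipped XSD, and uses locale-independent decimal text throughout.
    """
    record.validate()
    root = _build_tree(record)
    _schema().assertValid(root)
    data = etree.tostring(root, pretty_print=True, xml_declaration=True,
                          encoding="UTF-8")
    path = Path(path)
    path.write_bytes(data)
    return path


def validate_file(path) -> None:
    """Check a file against the MEPAT schema; raises on violation."""
    try:
        tree = etree.parse(str(path))
    except etree.XMLSyntaxError as exc:
        raise MEPATSchemaError(f"not well-formed XML: {exc}") from exc
    schema = _schema()
    if not schema.validate(tree):
        raise MEPATSchemaError(str(schema.error_log))


def read_mepat(path) -> MEPATRecord:
    """Reconstruct a record from a ``.mepat.xml`` file.

    The returned classifier reproduces bit-identical predictions to the
    cascade that was serialized.
    """
    validate_file(path)
    root = etree.parse(str(path)).getroot()

    tf_el = root.find("test_food")
    test_food = TestFood(brand=tf_el.get("brand"),
                         colour_pair=tf_el.get("colour_pair"),
                         dimensions_mm=tf_el.get("dimensions_mm"),
                         description=tf_el.text or "")

    es_el = root.find("experimental_settings")
    seg_el = es_el.find("segmentation")
    seg = SegmentationParams(
        spatial_bandwidth=float(seg_el.get("spatial_bandwidth")),
        range_bandwidth=float(seg_el.get("range_bandwidth")),
        ms_iterations=int(seg_el.get("ms_iterations")),
        n_init=int(seg_el.get("n_init")),
        distance_weight=float(seg_el.get("distance_weight")),
        min_colour_separation=float(seg_el.get("min_colour_separation")),
        closing_radius=int(seg_el.get("closing_radius")),
        convex_hull=seg_el.get("convex_hull") == "true",
        seed=int(seg_el.get("seed")), variant=seg_el.get("variant"),
    )
    cycles = tuple(int(v) for v in es_el.findtext("cycles").split())
    settings = ExperimentalSettings(
        cycles=cycles, scanner_dpi=int(es_el.get("scanner_dpi")),
        flattening_thickness_mm=float(es_el.get("flattening_thickness_mm")),
        segmentation=seg,
    )

    known = {m + c for m in MODEL_CODES for c in CHANNEL_CODES} | {"CVOH"}
    characterizers = []
    for f_el in root.find("characterizers"):
        code = f_el.get("code")
        if code not in known:
            raise MEPATParseError(f"unknown MFC code {code!r}")
        characterizers.append(Characterizer(
            mfc_code=code, q=float(f_el.get("q")), rho=float(f_el.get("rho")),
            gamma=int(f_el.get("gamma")),
        ))

    stages = []
    for st in root.find("classifier"):
        codes = (st.findtext("features") or "").split()
        k = int(st.find("w1").get("rows"))
        h = int(st.find("w1").get("cols"))
        if len(codes) != k:
            raise MEPATParseError("feature list length disagrees with w1 rows")
        stages.append(CascadeStage(
            target_t=int(st.get("target_t")), h=h, feature_codes=codes,
            scaler_mean=_parse_floats(st.findtext("scaler_mean"), k),
            scaler_scale=_parse_floats(st.findtext("scaler_scale"), k),
            w1=_parse_floats(st.findtext("w1"), k * h).reshape(k, h),
            b1=_parse_floats(st.findtext("b1"), h),
            w2=_parse_floats(st.findtext("w2"), h).reshape(h, 1),
            b2=_parse_floats(st.findtext("b2"), 1),
            mcc_sg=float(st.get("mcc_sg")), seed=int(st.get("seed")),
            epochs=int(st.get("epochs")), threshold=float(st.get("threshold")),
        ))
    classifier = CascadeClassifier(stages=stages)

    op_el = root.find("operator")
    operator = Operator(name=op_el.get("name"), institution=op_el.get("institution"))

    pe = root.find("performance")
    gl = pe.find("global")
    opt = lambda a: (float(gl.get(a)) if gl.get(a) is not None else None)
    performance = Performance(
        global_mcc=opt("mcc"), sensitivity=opt("sensitivity"),
        specificity=opt("specificity"), accuracy=opt("accuracy"),
        per_stage_mcc={int(el.get("t")): float(el.text) for el in pe.findall("stage_mcc")},
        unclassified=int(pe.get("unclassified")),
    )

    record = MEPATRecord(
        test_food=test_food, settings=settings, characterizers=characterizers,
        classifier=classifier, operator=operator, performance=performance,
        uid=root.get("uid"), created=root.get("created"),
        uploaded=root.get("uploaded"),
    )
    record.validate()
    return record
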