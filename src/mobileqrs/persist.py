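"""Structured-text persistence for learned subject models.

Everything is stored as JSON: support vectors, dual coefficients and
standardization constants of the SVM, the three template views with their
boundary indices, the distortion normalization anchor and threshold, the
calibration bias, and the full pipeline configuration snapshot.
"""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path

import numpy as np

from .detect import SVMModel
from .templates import HeartbeatTemplate
from .calibrate import CalibrationModel
from .pipeline import PipelineConfig, SubjectModel


def _tolist(a):
    return np.asarray(a).tolist()


def save_subject_model(model: SubjectModel, path: str | Path) -> None:
    doc = {
        "format": "mobileqrs-subject-model",
        "version": 1,
        "svm": None,
        "template": {
            "views": _tolist(model.template.views),
            "qrs_temp_off": model.template.qrs_temp_off,
            "qrs_temp_on": model.template.qrs_temp_on,
        },
        "reference_max": model.reference_max,
        "tau": model.tau,
        "calibration": {"bias_ms": model.calibration.bias_ms},
        "config": asdict(model.config),
        "stage_counts": model.stage_counts,
    }
    if model.svm is not None:
        doc["svm"] = {
            "support_vectors": _tolist(model.svm.support_vectors),
            "dual_coef": _tolist(model.svm.dual_coef),
            "bias": model.svm.bias,
            "center": _tolist(model.svm.center),
            "scale": _tolist(model.svm.scale),
        }
    Path(path).write_text(json.dumps(doc, indent=1))


def load_subject_model(path: str | Path) -> SubjectModel:
    doc = json.loads(Path(path).read_text())
    if doc.get("format") != "mobileqrs-subject-model":
        raise ValueError(f"{path}: not a subject model file")
    svm = None
    if doc["svm"] is not None:
        s = doc["svm"]
        svm = SVMModel(
            support_vectors=np.asarray(s["support_vectors"], dtype=float),
            dual_coef=np.asarray(s["dual_coef"], dtype=float),
            bias=float(s["bias"]),
            center=np.asarray(s["center"], dtype=float),
            scale=np.asarray(s["scale"], dtype=float),
        )
    t = doc["template"]
    template = HeartbeatTemplate(
        views=np.asarray(t["views"], dtype=float),
        qrs_temp_off=t["qrs_temp_off"], qrs_temp_on=t["qrs_temp_on"])
    return SubjectModel(
        svm=svm, template=template,
        reference_max=float(doc["reference_max"]), tau=float(doc["tau"]),
        calibration=CalibrationModel(bias_ms=float(doc["calibration"]["bias_ms"])),
        config=PipelineConfig.from_dict(doc["config"]),
        stage_counts=doc.get("stage_counts", {}),
    )
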