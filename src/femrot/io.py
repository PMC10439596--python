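"""Serialization: femur-model JSON, landmark/angle CSV, manifests.

File formats
------------
* Model JSON: ``{"subject_id", "side", "valgus_deg", "anterior", "landmarks":
  {name: [x, y, z]}, "shaft_section": [[...]], "notch_section": [[...]],
  "truth": {...}}`` — coordinates in mm.
* Angles CSV: one row per subject x observer x session with the three signed
  deviation angles and outlier flags.
* Truth CSV: the generator's ground-truth table.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .models import FemurModel, LandmarkSet

ANGLES_COLUMNS = [
    "subject_id",
    "observer_id",
    "session",
    "ws_deg",
    "atea_deg",
    "pcl_deg",
    "ws_outlier",
    "atea_outlier",
    "pcl_outlier",
]


def model_to_dict(model: FemurModel) -> dict:
    d = {
        "subject_id": model.subject_id,
        "side": model.side,
        "valgus_deg": model.valgus_deg,
        "anterior": model.anterior.tolist(),
        "landmarks": {k: v.tolist() for k, v in sorted(model.landmarks.points.items())},
        "shaft_section": model.shaft_section.tolist(),
        "notch_section": model.notch_section.tolist(),
    }
    if model.truth is not None:
        d["truth"] = model.truth
    return d


def model_from_dict(d: dict) -> FemurModel:
    lms = LandmarkSet(subject_id=d["subject_id"], side=d["side"], points=d["landmarks"])
    return FemurModel(
        subject_id=d["subject_id"],
        side=d["side"],
        landmarks=lms,
        shaft_section=np.asarray(d["shaft_section"], dtype=float),
        notch_section=np.asarray(d["notch_section"], dtype=float),
        valgus_deg=float(d["valgus_deg"]),
        anterior=np.asarray(d["anterior"], dtype=float),
        truth=d.get("truth"),
    )


def save_model(model: FemurModel, path: str | Path) -> None:
    Path(path).write_text(json.dumps(model_to_dict(model), indent=1, sort_keys=True))


def load_model(path: str | Path) -> FemurModel:
    return model_from_dict(json.loads(Path(path).read_text()))


def save_angles(records: list[dict], path: str | Path) -> pd.DataFrame:
    df = pd.DataFrame(records, columns=ANGLES_COLUMNS)
    df.to_csv(path, index=False)
    return df


def load_angles(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_json(obj: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(obj, indent=1, sort_keys=True))
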