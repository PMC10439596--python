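"""Per-subject measurement inputs: landmark sets and femur models.

Seven named bony landmarks of the distal femur define the four rotational
reference axes; two cross-section point clouds (femoral-shaft medullary
canal, intercondylar-notch apex) define the anatomical axis; the per-subject
femoral valgus angle relates the anatomical axis to the mechanical axis.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np

from .geometry import Side

#: Canonical landmark names, keyed by the conventional single-letter label.
LANDMARK_NAMES: dict[str, str] = {
    "a": "trochlear_groove_deepest",
    "b": "medial_epicondyle_prominence",
    "c": "medial_epicondylar_sulcus",
    "d": "medial_posterior_condyle_lowest",
    "e": "posterior_notch_deepest",
    "f": "lateral_posterior_condyle_lowest",
    "g": "lateral_epicondyle_prominence",
}

#: Reverse lookup: full name -> letter label.
LANDMARK_LETTERS: dict[str, str] = {v: k for k, v in LANDMARK_NAMES.items()}


@dataclass(frozen=True)
class LandmarkSet:
    """The seven distal-femur landmarks (mm) for one subject.

    Landmarks are keyed by full name (see :data:`LANDMARK_NAMES`); single
    letter labels are accepted on construction and normalized.
    """

    subject_id: str
    side: Side
    points: Mapping[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        pts: dict[str, np.ndarray] = {}
        for key, value in self.points.items():
            name = LANDMARK_NAMES.get(key, key)
            if name not in LANDMARK_LETTERS:
                raise ValueError(f"unknown landmark {key!r}")
            arr = np.asarray(value, dtype=float)
            if arr.shape != (3,) or not np.all(np.isfinite(arr)):
                raise ValueError(f"landmark {name!r} must be a finite 3-vector")
            pts[name] = arr
        missing = set(LANDMARK_LETTERS) - set(pts)
        if missing:
            raise ValueError(f"missing landmarks: {sorted(missing)}")
        object.__setattr__(self, "points", pts)

    def __getitem__(self, key: str) -> np.ndarray:
        return self.points[LANDMARK_NAMES.get(key, key)]


@dataclass(frozen=True)
class FemurModel:
    """One subject's measurement input.

    Attributes
    ----------
    landmarks:
        The seven named points.
    shaft_section, notch_section:
        Cross-section point clouds (n, 3) for the medullary-canal circle and
        the intercondylar-notch-apex circle.
    valgus_deg:
        Femoral valgus angle alpha (coronal angle between mechanical and
        anatomical axes), measured per subject on long-leg radiographs.
    anterior:
        Anterior-posterior unit direction of the model's frame; the varus
        correction rotates within the coronal plane about this direction.
    truth:
        Optional generator ground truth (true deviation angles), carried for
        validation only; never read by the measurement pipeline.
    """

    subject_id: str
    side: Side
    landmarks: LandmarkSet
    shaft_section: np.ndarray
    notch_section: np.ndarray
    valgus_deg: float
    anterior: np.ndarray
    truth: dict | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "shaft_section", np.atleast_2d(np.asarray(self.shaft_section, dtype=float)))
        object.__setattr__(self, "notch_section", np.atleast_2d(np.asarray(self.notch_section, dtype=float)))
        object.__setattr__(self, "anterior", np.asarray(self.anterior, dtype=float))

    def with_landmarks(self, landmarks: LandmarkSet) -> "FemurModel":
        """Copy of the model with the landmark set replaced (observer repeats)."""
        return replace(self, landmarks=landmarks)
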