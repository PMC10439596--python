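"""Core measurement procedure: landmarks + valgus angle -> deviation angles.

Given one subject's landmark set, the two cross-sections and the valgus
angle, the pipeline (i) fits circles to the shaft-canal and notch-apex
sections, (ii) joins the centers into the anatomical axis, (iii) applies the
valgus correction to obtain the mechanical axis, (iv) erects the transverse
plane "o" perpendicular to it, (v) builds the four reference axes from the
landmarks, (vi) projects them into plane "o", (vii) derives the simulated
component alignments (perpendicular of the projected Whiteside line; the
projected posterior condylar line externally rotated by 3 degrees) and
(viii) reports the three signed deviation angles from the projected
surgical transepicondylar axis, with outlier flags at |angle| > 2 degrees.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import DegenerateAxisError, FemrotError
from .geometry import (
    CrossSection,
    Line3,
    Plane3,
    Side,
    anatomical_axis,
    angle_between_lines,
    fit_circle,
    mechanical_axis,
    project_direction,
    rotate_in_plane,
    signed_angle,
    transverse_plane,
)
from .models import FemurModel, LandmarkSet

#: External rotation (degrees) applied to the projected posterior condylar
#: line to simulate the component alignment referenced to it.
PCL_EXTERNAL_ROTATION_DEG = 3.0

#: Deviation magnitude (degrees) strictly above which a subject is an outlier.
DEFAULT_OUTLIER_THRESHOLD_DEG = 2.0


@dataclass(frozen=True)
class AxisBundle:
    """The four rotational reference axes as 3D lines."""

    whiteside: Line3
    atea: Line3
    stea: Line3
    pcl: Line3


@dataclass(frozen=True)
class ProjectedAlignments:
    """In-plane directions in the transverse plane "o".

    ``whiteside_p/atea_p/stea_p/pcl_p`` are the projections of the four
    reference axes; ``pcl_plus3`` is the posterior-condylar-based simulated
    alignment (projected PCL externally rotated 3 degrees) and
    ``whiteside_perp`` the Whiteside-based one (perpendicular of the
    projected Whiteside line).
    """

    plane: Plane3
    whiteside_p: np.ndarray
    atea_p: np.ndarray
    stea_p: np.ndarray
    pcl_p: np.ndarray
    pcl_plus3: np.ndarray
    whiteside_perp: np.ndarray


@dataclass(frozen=True)
class DeviationAngles:
    """Signed deviation (degrees) of each simulated alignment from the sTEA."""

    subject_id: str
    ws: float
    atea: float
    pcl: float
    ws_outlier: bool
    atea_outlier: bool
    pcl_outlier: bool

    def as_dict(self) -> dict:
        return {
            "subject_id": self.subject_id,
            "ws_deg": self.ws,
            "atea_deg": self.atea,
            "pcl_deg": self.pcl,
            "ws_outlier": self.ws_outlier,
            "atea_outlier": self.atea_outlier,
            "pcl_outlier": self.pcl_outlier,
        }


def build_axes(lm: LandmarkSet) -> AxisBundle:
    """Construct the four reference axes from the seven landmarks.

    sTEA: lateral epicondyle prominence <-> medial epicondylar sulcus;
    aTEA: lateral <-> medial epicondyle prominences;
    Whiteside: trochlear groove deepest <-> posterior notch deepest;
    PCL: medial <-> lateral posterior condyle lowest points.
    """
    pairs = {
        "whiteside": ("trochlear_groove_deepest", "posterior_notch_deepest"),
        "atea": ("lateral_epicondyle_prominence", "medial_epicondyle_prominence"),
        "stea": ("lateral_epicondyle_prominence", "medial_epicondylar_sulcus"),
        "pcl": ("medial_posterior_condyle_lowest", "lateral_posterior_condyle_lowest"),
    }
    axes = {}
    for name, (p, q) in pairs.items():
        d = lm[q] - lm[p]
        if np.linalg.norm(d) < 1e-9:
            raise DegenerateAxisError(f"axis {name!r}: defining landmarks coincide")
        axes[name] = Line3(point=lm[p], direction=d)
    return AxisBundle(**axes)


def measure_valgus_angle(line_a, line_b) -> float:
    """Unsigned acute angle (degrees) between two coronal 2D lines.

    Each line is a (point, direction) pair of 2-vectors; only the directions
    matter. Returns a value in [0, 90].
    """
    da = np.asarray(line_a[1], dtype=float)
    db = np.asarray(line_b[1], dtype=float)
    return angle_between_lines(np.append(da, 0.0), np.append(db, 0.0))


def classify_outlier(angle_deg: float, threshold_deg: float = DEFAULT_OUTLIER_THRESHOLD_DEG) -> bool:
    """True iff |angle| strictly exceeds the threshold (default 2 degrees)."""
    if not np.isfinite(angle_deg):
        raise ValueError("outlier classification needs a finite angle")
    return abs(angle_deg) > threshold_deg


def project_axes(axes: AxisBundle, plane: Plane3, side: Side) -> ProjectedAlignments:
    """Project the reference axes into plane "o" and derive simulated alignments."""
    l1p = project_direction(axes.whiteside.direction, plane)
    l2p = project_direction(axes.atea.direction, plane)
    l3p = project_direction(axes.stea.direction, plane)
    l4p = project_direction(axes.pcl.direction, plane)
    l5 = rotate_in_plane(l4p, PCL_EXTERNAL_ROTATION_DEG, plane, "external", side)
    l6 = rotate_in_plane(l1p, 90.0, plane, "external", side)
    return ProjectedAlignments(
        plane=plane,
        whiteside_p=l1p,
        atea_p=l2p,
        stea_p=l3p,
        pcl_p=l4p,
        pcl_plus3=l5,
        whiteside_perp=l6,
    )


def measure_subject(
    model: FemurModel,
    landmarks: LandmarkSet | None = None,
    outlier_threshold_deg: float = DEFAULT_OUTLIER_THRESHOLD_DEG,
) -> DeviationAngles:
    """Run the full measurement procedure on one subject.

    ``landmarks`` overrides the model's landmark set (observer repeats); the
    cross-sections and valgus angle always come from the model.
    """
    lm = landmarks if landmarks is not None else model.landmarks
    try:
        shaft_center, _ = fit_circle(CrossSection.from_points(model.shaft_section))
        notch_center, _ = fit_circle(CrossSection.from_points(model.notch_section))
        anat = anatomical_axis(shaft_center, notch_center)
        mech = mechanical_axis(anat, model.valgus_deg, model.side, model.anterior)
        plane = transverse_plane(mech, notch_center)
        axes = build_axes(lm)
        proj = project_axes(axes, plane, model.side)
        ws = signed_angle(proj.stea_p, proj.whiteside_perp, plane, model.side)
        atea = signed_angle(proj.stea_p, proj.atea_p, plane, model.side)
        pcl = signed_angle(proj.stea_p, proj.pcl_plus3, plane, model.side)
    except FemrotError as exc:
        raise type(exc)(f"subject {model.subject_id!r}: {exc}") from exc
    return DeviationAngles(
        subject_id=model.subject_id,
        ws=ws,
        atea=atea,
        pcl=pcl,
        ws_outlier=classify_outlier(ws, outlier_threshold_deg),
        atea_outlier=classify_outlier(atea, outlier_threshold_deg),
        pcl_outlier=classify_outlier(pcl, outlier_threshold_deg),
    )
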