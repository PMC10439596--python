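"""Parametric distal-femur generator with known ground-truth axis geometry.

Each synthetic femur is built in a canonical right-handed frame — origin at
the intercondylar-notch apex, +Z proximal along the true mechanical axis,
+Y anterior, +X medial for a right femur (mirrored for a left one) — by
*inverting* the measurement procedure: the in-plane directions of the four
reference axes are laid out so that the pipeline's deviation angles equal
the specified truths exactly, endpoints are lifted out of the transverse
plane by per-landmark axial offsets (the reference axes of a real femur do
not share one CT section), and the shaft/notch cross-sections are sampled
exactly on circles centered on the anatomical axis, which is tilted from
the mechanical axis by the subject's valgus angle within the coronal plane.

Cohorts draw per-subject true deviation angles from Gaussians; repeat
observations perturb the seven landmarks with isotropic Gaussian placement
noise per observer/session while leaving the cross-sections fixed (the
canal and notch circle fits are treated as stable across readers).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import EmptyCohortError, InvalidSpecError
from .geometry import Side, side_sign
from .models import LANDMARK_NAMES, FemurModel, LandmarkSet

#: Mediolateral span of the epicondylar axes (mm).
DEFAULT_CONDYLAR_WIDTH = 80.0
#: Anteroposterior span of the Whiteside line (mm).
WHITESIDE_LENGTH = 40.0
#: Posterior offset of the posterior condylar line midpoint (mm).
POSTERIOR_CONDYLE_OFFSET = 25.0
#: Height of the shaft cross-section above the notch apex (mm).
DEFAULT_SHAFT_SECTION_HEIGHT = 120.0
#: Radii (mm) of the medullary-canal and notch-apex circles.
CANAL_RADIUS = 8.0
NOTCH_RADIUS = 12.0
#: Points sampled per cross-section circle.
SECTION_POINTS = 24
#: Range (mm) of the default per-landmark axial offsets.
DEFAULT_AXIAL_OFFSET_RANGE = 8.0


@dataclass(frozen=True)
class FemurSpec:
    """Ground-truth parameters of one synthetic femur.

    ``true_ws`` / ``true_atea`` are the signed deviations (degrees, external
    positive) of the Whiteside-perpendicular and anatomical-TEA alignments
    from the surgical TEA. ``true_pca`` is the posterior condylar angle: the
    surgical TEA is externally rotated by ``true_pca`` relative to the
    posterior condylar line, so the PCL+3° alignment deviates from the
    surgical TEA by ``3 - true_pca`` degrees.
    """

    subject_id: str
    side: Side = "right"
    condylar_width: float = DEFAULT_CONDYLAR_WIDTH
    true_ws: float = 0.0
    true_atea: float = 0.0
    true_pca: float = 3.0
    valgus_alpha: float = 7.9
    axial_offsets: dict[str, float] = field(default_factory=dict)
    shaft_section_height: float = DEFAULT_SHAFT_SECTION_HEIGHT

    def __post_init__(self) -> None:
        if self.condylar_width <= 0:
            raise InvalidSpecError("condylar width must be positive")
        if not (abs(self.true_ws) < 45 and abs(self.true_atea) < 45 and abs(self.true_pca) < 45):
            raise InvalidSpecError("true deviation angles must satisfy |angle| < 45 degrees")
        if not 0 <= self.valgus_alpha < 15:
            raise InvalidSpecError("valgus angle must lie in [0, 15) degrees")
        if self.shaft_section_height <= 0:
            raise InvalidSpecError("shaft section height must be positive")
        for key in self.axial_offsets:
            if key not in LANDMARK_NAMES and key not in LANDMARK_NAMES.values():
                raise InvalidSpecError(f"axial offset for unknown landmark {key!r}")

    @property
    def true_pcl(self) -> float:
        """Truth for the PCL+3° deviation angle under the sign convention."""
        return 3.0 - self.true_pca


@dataclass(frozen=True)
class CohortParams:
    """Cohort-level distribution parameters.

    Defaults emulate the study cohort: n = 120 subjects, per-subject true
    deviations N(2.54, 2.30) for the Whiteside perpendicular, N(4.21, 1.01)
    for the anatomical TEA and N(0.50, 1.06) for PCL+3° (degrees), valgus
    angle N(7.9, 1.5) truncated to (3, 12) degrees.
    """

    n: int = 120
    ws_mean: float = 2.54
    ws_sd: float = 2.30
    atea_mean: float = 4.21
    atea_sd: float = 1.01
    pcl_mean: float = 0.50
    pcl_sd: float = 1.06
    valgus_mean: float = 7.9
    valgus_sd: float = 1.5
    valgus_bounds: tuple[float, float] = (3.0, 12.0)
    side_fraction_right: float = 0.5
    axial_offset_range: float = DEFAULT_AXIAL_OFFSET_RANGE
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n < 1:
            raise EmptyCohortError("cohort size must be at least 1")
        for sd in (self.ws_sd, self.atea_sd, self.pcl_sd, self.valgus_sd):
            if sd < 0:
                raise InvalidSpecError("standard deviations must be non-negative")
        if not 0 <= self.side_fraction_right <= 1:
            raise InvalidSpecError("side_fraction_right must be in [0, 1]")


@dataclass(frozen=True)
class ObserverModel:
    """Landmark-placement noise model for one observer.

    ``landmark_sigma`` is the isotropic Gaussian placement noise (mm) added
    independently to each landmark coordinate; ``systematic_bias`` optionally
    adds a fixed per-landmark offset vector (mm). The default sigma is
    calibrated, for the default geometry scale, so that simulated cohorts
    yield ICCs in the "high" (> 0.75) band, as trained observers on 3D
    models do.
    """

    observer_id: str
    landmark_sigma: float = 0.3
    systematic_bias: dict[str, np.ndarray] | None = None

    def __post_init__(self) -> None:
        if self.landmark_sigma < 0:
            raise InvalidSpecError("landmark sigma must be non-negative")


def _inplane(theta_deg: float) -> np.ndarray:
    """Unit xy-plane direction at counterclockwise angle theta from +X."""
    t = math.radians(theta_deg)
    return np.array([math.cos(t), math.sin(t), 0.0])


def _circle_points(center: np.ndarray, normal: np.ndarray, radius: float, rng: np.random.Generator) -> np.ndarray:
    n = normal / np.linalg.norm(normal)
    seed = np.array([1.0, 0.0, 0.0]) if abs(n[0]) < 0.9 else np.array([0.0, 1.0, 0.0])
    e1 = seed - np.dot(seed, n) * n
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(n, e1)
    phase = rng.uniform(0.0, 2.0 * math.pi)
    angles = phase + np.linspace(0.0, 2.0 * math.pi, SECTION_POINTS, endpoint=False)
    return center + radius * (np.outer(np.cos(angles), e1) + np.outer(np.sin(angles), e2))


def generate_femur(spec: FemurSpec, rng: np.random.Generator) -> FemurModel:
    """Build a femur model whose noise-free measurement recovers the spec truths.

    The construction is done in the canonical *right*-femur frame and
    mirrored across the sagittal plane (x -> -x) for a left femur.
    """
    w = spec.condylar_width
    # In-plane reference-axis directions; external-positive angles are
    # counterclockwise about +Z in the right-femur frame.
    u_stea = _inplane(0.0)
    u_atea = _inplane(spec.true_atea)
    u_pcl = _inplane(-spec.true_pca)
    u_ws = _inplane(spec.true_ws - 90.0)

    g = np.array([-w / 2.0, 0.0, 0.0])  # lateral epicondyle prominence
    c = g + w * u_stea                   # medial epicondylar sulcus
    b = g + w * u_atea                   # medial epicondyle prominence
    e = np.array([0.0, -10.0, 0.0])      # posterior notch deepest
    a = e - WHITESIDE_LENGTH * u_ws      # trochlear groove deepest (anterior)
    pcl_mid = np.array([0.0, -POSTERIOR_CONDYLE_OFFSET, -5.0])
    f = pcl_mid - (w / 2.0) * u_pcl      # lateral posterior condyle lowest
    d = f + w * u_pcl                    # medial posterior condyle lowest

    points = {"a": a, "b": b, "c": c, "d": d, "e": e, "f": f, "g": g}
    zhat = np.array([0.0, 0.0, 1.0])
    for letter, name in LANDMARK_NAMES.items():
        off = spec.axial_offsets.get(letter, spec.axial_offsets.get(name, 0.0))
        points[letter] = points[letter] + off * zhat

    # Anatomical axis: tilted medially-proximally from the mechanical axis
    # (+Z) by the valgus angle, within the coronal (xz) plane.
    alpha = math.radians(spec.valgus_alpha)
    anat_dir = np.array([math.sin(alpha), 0.0, math.cos(alpha)])
    notch_center = np.zeros(3)
    shaft_center = notch_center + spec.shaft_section_height * anat_dir
    notch_section = _circle_points(notch_center, anat_dir, NOTCH_RADIUS, rng)
    shaft_section = _circle_points(shaft_center, anat_dir, CANAL_RADIUS, rng)

    if spec.side == "left":
        mirror = np.array([-1.0, 1.0, 1.0])
        points = {k: v * mirror for k, v in points.items()}
        notch_section = notch_section * mirror
        shaft_section = shaft_section * mirror

    landmarks = LandmarkSet(subject_id=spec.subject_id, side=spec.side, points=points)
    return FemurModel(
        subject_id=spec.subject_id,
        side=spec.side,
        landmarks=landmarks,
        shaft_section=shaft_section,
        notch_section=notch_section,
        valgus_deg=spec.valgus_alpha,
        anterior=np.array([0.0, 1.0, 0.0]),
        truth={
            "true_ws": spec.true_ws,
            "true_atea": spec.true_atea,
            "true_pca": spec.true_pca,
            "true_pcl": spec.true_pcl,
            "valgus_alpha": spec.valgus_alpha,
        },
    )


def random_spec(subject_id: str, rng: np.random.Generator, params: CohortParams) -> FemurSpec:
    """Draw one subject's ground-truth parameters from the cohort distributions."""
    side: Side = "right" if rng.random() < params.side_fraction_right else "left"
    true_ws = params.ws_mean + params.ws_sd * rng.standard_normal()
    true_atea = params.atea_mean + params.atea_sd * rng.standard_normal()
    true_pcl = params.pcl_mean + params.pcl_sd * rng.standard_normal()
    lo, hi = params.valgus_bounds
    if params.valgus_sd > 0:
        a, b = (lo - params.valgus_mean) / params.valgus_sd, (hi - params.valgus_mean) / params.valgus_sd
        valgus = float(stats.truncnorm.rvs(a, b, loc=params.valgus_mean, scale=params.valgus_sd, random_state=rng))
    else:
        valgus = params.valgus_mean
    offsets = {
        letter: float(rng.uniform(-params.axial_offset_range, params.axial_offset_range))
        for letter in LANDMARK_NAMES
    }
    return FemurSpec(
        subject_id=subject_id,
        side=side,
        true_ws=true_ws,
        true_atea=true_atea,
        true_pca=3.0 - true_pcl,
        valgus_alpha=valgus,
        axial_offsets=offsets,
    )


def generate_cohort(params: CohortParams) -> tuple[list[FemurModel], pd.DataFrame]:
    """Generate a cohort of femur models and its ground-truth table.

    Fully reproducible from ``params.seed``: the same parameters yield
    bit-identical truth tables and models.
    """
    rng = np.random.default_rng(params.seed)
    models: list[FemurModel] = []
    rows = []
    for i in range(params.n):
        spec = random_spec(f"S{i + 1:04d}", rng, params)
        models.append(generate_femur(spec, rng))
        rows.append(
            {
                "subject_id": spec.subject_id,
                "side": spec.side,
                "true_ws": spec.true_ws,
                "true_atea": spec.true_atea,
                "true_pca": spec.true_pca,
                "true_pcl": spec.true_pcl,
                "valgus_alpha": spec.valgus_alpha,
                "seed": params.seed,
            }
        )
    return models, pd.DataFrame(rows)


def simulate_observation(model: FemurModel, obs: ObserverModel, rng: np.random.Generator) -> LandmarkSet:
    """One observer's landmark placements: truth + isotropic noise (+ bias).

    Cross-sections are not perturbed; the canal/notch circle fits are
    assumed stable across observers and sessions.
    """
    bias = obs.systematic_bias or {}
    perturbed = {}
    for name, p in model.landmarks.points.items():
        delta = rng.normal(0.0, obs.landmark_sigma, size=3) if obs.landmark_sigma > 0 else np.zeros(3)
        b = np.asarray(bias.get(name, np.zeros(3)), dtype=float)
        perturbed[name] = p + delta + b
    return LandmarkSet(subject_id=model.subject_id, side=model.side, points=perturbed)


def generate_coronal_axes(spec: FemurSpec):
    """Coronal 2D mechanical/anatomical axis pair separated by the valgus angle.

    Returns two (point, direction) 2D lines whose unsigned angle equals
    ``spec.valgus_alpha``; the analogue of the long-leg-radiograph drawing
    from which the valgus angle is read.
    """
    mech = (np.zeros(2), np.array([0.0, 1.0]))
    t = math.radians(spec.valgus_alpha)
    anat = (np.zeros(2), np.array([math.sin(t), math.cos(t)]))
    return mech, anat


def mirror_model(model: FemurModel) -> FemurModel:
    """Mirror a femur across the sagittal plane, flipping the side flag.

    Signed deviation angles are invariant under this operation.
    """
    mirror = np.array([-1.0, 1.0, 1.0])
    new_side: Side = "left" if model.side == "right" else "right"
    lms = LandmarkSet(
        subject_id=model.subject_id,
        side=new_side,
        points={k: v * mirror for k, v in model.landmarks.points.items()},
    )
    return FemurModel(
        subject_id=model.subject_id,
        side=new_side,
        landmarks=lms,
        shaft_section=model.shaft_section * mirror,
        notch_section=model.notch_section * mirror,
        valgus_deg=model.valgus_deg,
        anterior=model.anterior * mirror,
        truth=model.truth,
    )


def transform_model(model: FemurModel, rotation: np.ndarray, translation: np.ndarray) -> FemurModel:
    """Apply one global rigid motion to every point (and the anterior direction)."""
    R = np.asarray(rotation, dtype=float)
    t = np.asarray(translation, dtype=float)
    lms = LandmarkSet(
        subject_id=model.subject_id,
        side=model.side,
        points={k: R @ v + t for k, v in model.landmarks.points.items()},
    )
    return FemurModel(
        subject_id=model.subject_id,
        side=model.side,
        landmarks=lms,
        shaft_section=model.shaft_section @ R.T + t,
        notch_section=model.notch_section @ R.T + t,
        valgus_deg=model.valgus_deg,
        anterior=R @ model.anterior,
        truth=model.truth,
    )
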