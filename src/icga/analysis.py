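"""Pipeline variants, group statistics and the spider-chart orientation.

Four named pipeline variants toggle the two optional processing steps:

====== ==== =====
name   FFC  nAUC
====== ==== =====
NP      –    –
nAUC    –    X
FFC     X    –
FFC+nAUC X   X
====== ==== =====

Motion-artifact correction is applied per curve when the detected artifact
fraction exceeds a threshold (default 2%).

Group differences per feature are tested with the two-sided Mann–Whitney U
(exact null when group sizes allow and there are no ties, normal
approximation with tie correction otherwise), reported with significance
tiers at p < 0.05 and p < 0.01 and no multiplicity correction by default.

The six relative features of one tissue class, drawn as a radar hexagon, are
summarized by the tilt of the ellipse through the six vertices: the
orientation is the signed angle of the major axis from the vertical, in
(−90°, 90°], positive counterclockwise.  A near-circular hexagon (normal
tissue) is flagged degenerate with orientation 0°.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .correction import FlatFieldSet, flat_field_correct, subtract_baseline
from .exceptions import ConfigurationError, DegenerateCurveError, IcgaError
from .features import LandmarkConfig, compute_features
from .ingest import FrameStack, select_time_window, spatial_downsample, temporal_bin
from .kinetics import (
    ROI,
    KineticsCurve,
    NormalizationSpec,
    correct_motion,
    detect_motion_artifacts,
    extract_curve,
    normalize,
)

__all__ = [
    "PipelineVariant",
    "GroupComparison",
    "SpiderOrientation",
    "run_pipeline",
    "relative_features",
    "compare_groups",
    "spider_orientation",
    "DEFAULT_FEATURE_ORDER",
]

#: Hexagon vertex order: first feature at the top, then clockwise.  The peak
#: value sits at the top vertex; the remaining order was chosen once, on
#: synthetic severity classes, so that hyperperfused (superficial) hexagons
#: tilt positive and hypoperfused (deep) ones negative.  The order is crucial
#: and configurable.
DEFAULT_FEATURE_ORDER = ("imax", "fwhm_s", "s1", "rauc", "s2", "mtt_s")

RELATIVE_FEATURES = ("imax", "rauc", "mtt_s", "fwhm_s", "s1", "s2")


@dataclass(frozen=True)
class PipelineVariant:
    """One row of the pipeline-variant table."""

    name: str
    use_ffc: bool
    use_nauc: bool
    mac_threshold: float = 0.02  # artifact fraction above which MAC is applied
    mac_method: str = "moving_average"
    mac_window: int = 5

    _NAMES = {
        "NP": (False, False),
        "nAUC": (False, True),
        "FFC": (True, False),
        "FFC+nAUC": (True, True),
    }

    def __post_init__(self) -> None:
        expected = self._NAMES.get(self.name)
        if expected is None:
            raise ConfigurationError(f"unknown pipeline variant {self.name!r}")
        if expected != (self.use_ffc, self.use_nauc):
            raise ConfigurationError(f"flags inconsistent with variant name {self.name!r}")

    @classmethod
    def from_name(cls, name: str, **kwargs) -> "PipelineVariant":
        if name not in cls._NAMES:
            raise ConfigurationError(f"unknown pipeline variant {name!r}")
        ffc, nauc = cls._NAMES[name]
        return cls(name=name, use_ffc=ffc, use_nauc=nauc, **kwargs)


@dataclass
class GroupComparison:
    feature: str
    class_a: str
    class_b: str
    n_a: int
    n_b: int
    u_statistic: float
    p_value: float
    tier: str  # "ns", "p<0.05", "p<0.01"


@dataclass
class SpiderOrientation:
    feature_order: tuple
    radii: np.ndarray
    vertex_angles_deg: np.ndarray
    center: tuple[float, float]
    semi_major: float
    semi_minor: float
    orientation_deg: float  # from vertical, (−90, 90], positive CCW
    degenerate: bool


def run_pipeline(
    data,
    rois: list[ROI] | None,
    variant: PipelineVariant,
    *,
    flat_field: FlatFieldSet | None = None,
    n_baseline: int = 10,
    time_window: tuple[float, float] | None = None,
    temporal_factor: int = 1,
    spatial_factor: int = 1,
    landmark_config: LandmarkConfig | None = None,
) -> pd.DataFrame:
    """Run one pipeline variant end to end and return the features table.

    ``data`` is either a fluorescence :class:`FrameStack` (with ``rois``) or a
    list of pre-extracted :class:`KineticsCurve`.  Steps run in order: volume
    reduction, baseline subtraction, optional flat-field correction, curve
    extraction, motion-artifact correction when the detected artifact fraction
    exceeds the variant's threshold, optional nAUC normalization, landmark
    detection and feature extraction.
    """
    if isinstance(data, FrameStack):
        stack = data
        if time_window is not None:
            stack = select_time_window(stack, *time_window)
        if temporal_factor > 1:
            stack = temporal_bin(stack, temporal_factor)
        if spatial_factor > 1:
            stack = spatial_downsample(stack, spatial_factor)
        stack = subtract_baseline(stack, n_baseline)
        if variant.use_ffc:
            if flat_field is None:
                raise ConfigurationError(f"variant {variant.name} requires calibration images")
            # baseline subtraction already removed the dark/ambient offset, so
            # only the gain field is divided out here
            stack = flat_field_correct(stack, flat_field, numerator="none")
        if rois is None:
            raise ConfigurationError("ROIs are required when processing a stack")
        curves = [extract_curve(stack, roi) for roi in rois]
    else:
        curves = [subtract_baseline(c, n_baseline) for c in data]
        if variant.use_ffc:
            raise ConfigurationError("FFC variants need image data, not pre-extracted curves")

    rows = []
    for curve in curves:
        mask = detect_motion_artifacts(curve)
        if mask.mean() > variant.mac_threshold:
            curve = correct_motion(curve, variant.mac_method, window=variant.mac_window)
        if variant.use_nauc:
            curve = normalize(curve, NormalizationSpec(mode="nAUC"))
        fs = compute_features(curve, config=landmark_config)
        rows.append(fs.as_row())
    return pd.DataFrame(rows)


def relative_features(
    table: pd.DataFrame,
    mode: str = "normal_median",
    reference_class: str = "normal",
    feature_columns: tuple = RELATIVE_FEATURES,
) -> pd.DataFrame:
    """Divide features by a median to make them unitless and comparable.

    ``normal_median`` divides each feature by the median over the
    reference-class ROIs; ``overall_median`` divides by the median over all
    ROIs.  The mode is recorded in the table attrs.
    """
    if mode not in ("normal_median", "overall_median"):
        raise ConfigurationError(f"unknown relative-features mode {mode!r}")
    out = table.copy()
    if mode == "normal_median":
        ref = table[table["tissue_class"] == reference_class]
        if len(ref) < 1:
            raise ConfigurationError(f"no ROIs of reference class {reference_class!r}")
    else:
        ref = table
    for col in feature_columns:
        med = float(ref[col].median())
        if med == 0 or not np.isfinite(med):
            raise DegenerateCurveError(f"reference median of {col!r} is zero or non-finite")
        out[col] = table[col] / med
    out.attrs["relative_mode"] = mode
    return out


def compare_groups(
    table: pd.DataFrame,
    feature: str,
    class_a: str,
    class_b: str,
    class_column: str = "tissue_class",
) -> GroupComparison:
    """Two-sided Mann–Whitney U between two tissue classes for one feature.

    The exact null distribution is used when n1·n2 <= 400 and the pooled data
    have no ties; otherwise the normal approximation with tie correction.
    """
    a = table.loc[table[class_column] == class_a, feature].dropna().to_numpy(dtype=float)
    b = table.loc[table[class_column] == class_b, feature].dropna().to_numpy(dtype=float)
    if len(a) < 3 or len(b) < 3:
        raise ConfigurationError("each group needs at least 3 observations")
    pooled = np.concatenate([a, b])
    no_ties = len(np.unique(pooled)) == len(pooled)
    method = "exact" if (len(a) * len(b) <= 400 and no_ties) else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    p = float(res.pvalue)
    tier = "p<0.01" if p < 0.01 else ("p<0.05" if p < 0.05 else "ns")
    return GroupComparison(
        feature=feature,
        class_a=class_a,
        class_b=class_b,
        n_a=len(a),
        n_b=len(b),
        u_statistic=float(res.statistic),
        p_value=p,
        tier=tier,
    )


def _fit_ellipse_direct(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Direct least-squares conic fit constrained to ellipses.

    Returns conic coefficients (A, B, C, D, E, F) for
    A x² + B xy + C y² + D x + E y + F = 0 with 4AC − B² > 0.
    """
    d1 = np.column_stack([x**2, x * y, y**2])
    d2 = np.column_stack([x, y, np.ones_like(x)])
    s1 = d1.T @ d1
    s2 = d1.T @ d2
    s3 = d2.T @ d2
    t = -np.linalg.solve(s3, s2.T)
    m = s1 + s2 @ t
    c1inv = np.array([[0.0, 0.0, 0.5], [0.0, -1.0, 0.0], [0.5, 0.0, 0.0]])
    m = c1inv @ m
    eigval, eigvec = np.linalg.eig(m)
    cond = 4 * eigvec[0] * eigvec[2] - eigvec[1] ** 2
    ok = np.where((cond > 0) & np.isfinite(eigval))[0]
    if len(ok) == 0:
        raise DegenerateCurveError("direct conic fit produced no ellipse solution")
    a1 = np.real(eigvec[:, ok[0]])
    return np.concatenate([a1, t @ a1])


def _conic_to_geometry(conic: np.ndarray) -> tuple[tuple[float, float], float, float, float]:
    """Center, semi-axes (a >= b) and major-axis angle (deg from +x) of a conic."""
    A, B, C, D, E, F = conic
    m = np.array([[A, B / 2], [B / 2, C]])
    center = np.linalg.solve(2 * m, [-D, -E])
    x0, y0 = center
    f0 = A * x0**2 + B * x0 * y0 + C * y0**2 + D * x0 + E * y0 + F
    eigval, eigvec = np.linalg.eigh(m)
    with np.errstate(invalid="raise"):
        axes = np.sqrt(-f0 / eigval)
    if not np.all(np.isfinite(axes)):
        raise DegenerateCurveError("conic is not a real ellipse")
    order = np.argsort(axes)[::-1]  # major first
    a, b = float(axes[order[0]]), float(axes[order[1]])
    major = eigvec[:, order[0]]
    angle = float(np.degrees(np.arctan2(major[1], major[0])))
    return (float(x0), float(y0)), a, b, angle


def _second_moment_axis(x: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    """Fallback: principal axes of the point cloud's second central moments."""
    pts = np.column_stack([x, y])
    pts = pts - pts.mean(axis=0)
    cov = pts.T @ pts / len(pts)
    eigval, eigvec = np.linalg.eigh(cov)
    a = float(np.sqrt(max(eigval[1], 0.0)))
    b = float(np.sqrt(max(eigval[0], 0.0)))
    angle = float(np.degrees(np.arctan2(eigvec[1, 1], eigvec[0, 1])))
    return a, b, angle


def _wrap_from_vertical(angle_from_x_deg: float) -> float:
    """Signed tilt from the vertical axis, mapped to (−90, 90], positive CCW."""
    tilt = angle_from_x_deg - 90.0
    tilt = (tilt + 90.0) % 180.0 - 90.0
    if tilt == -90.0:
        tilt = 90.0
    return tilt


def spider_orientation(
    radii,
    feature_order: tuple = DEFAULT_FEATURE_ORDER,
    *,
    degenerate_eps: float = 0.02,
    flip_sign: bool = False,
) -> SpiderOrientation:
    """Ellipse-orientation summary of a six-feature radar hexagon.

    ``radii`` may be a sequence of 6 positive values ordered as
    ``feature_order``, or a mapping/Series keyed by feature name, in which
    case slope radii are taken in absolute value.  Vertices sit at
    90° − k·60° (first feature at the top, then clockwise); an ellipse is
    fitted through the 6 Cartesian vertices by the direct least-squares conic
    method, falling back to the second-central-moment axes when the conic
    degenerates.  Near-circular fits (a/b − 1 < ``degenerate_eps``) are
    flagged degenerate with orientation 0°, the normal-tissue convention.
    """
    if hasattr(radii, "__getitem__") and not isinstance(radii, (list, tuple, np.ndarray)):
        radii = [abs(float(radii[f])) for f in feature_order]
    r = np.asarray(radii, dtype=float)
    if r.shape != (6,):
        raise ConfigurationError(f"need exactly 6 radii, got shape {r.shape}")
    if not np.all(np.isfinite(r)) or np.any(r <= 0):
        raise DegenerateCurveError("radii must be finite and positive")

    angles_deg = 90.0 - 60.0 * np.arange(6)
    theta = np.radians(angles_deg)
    x = r * np.cos(theta)
    y = r * np.sin(theta)

    try:
        conic = _fit_ellipse_direct(x, y)
        center, a, b, angle = _conic_to_geometry(conic)
    except (DegenerateCurveError, np.linalg.LinAlgError, FloatingPointError):
        a, b, angle = _second_moment_axis(x, y)
        center = (float(np.mean(x)), float(np.mean(y)))
        if b <= 0:
            raise DegenerateCurveError("degenerate point configuration") from None

    if b <= 0 or not np.isfinite(a / b):
        raise DegenerateCurveError("ellipse fit produced a non-positive minor axis")

    degenerate = (a / b - 1.0) < degenerate_eps
    orientation = 0.0 if degenerate else _wrap_from_vertical(angle)
    if flip_sign and not degenerate:
        orientation = -orientation if orientation != 90.0 else 90.0
    return SpiderOrientation(
        feature_order=tuple(feature_order),
        radii=r,
        vertex_angles_deg=angles_deg,
        center=center,
        semi_major=a,
        semi_minor=b,
        orientation_deg=orientation,
        degenerate=bool(degenerate),
    )


def class_spider_orientations(
    relative_table: pd.DataFrame,
    feature_order: tuple = DEFAULT_FEATURE_ORDER,
    class_column: str = "tissue_class",
    **kwargs,
) -> dict[str, SpiderOrientation]:
    """Median-radius spider orientation per tissue class."""
    out = {}
    for cls, grp in relative_table.groupby(class_column):
        radii = {f: float(grp[f].abs().median()) for f in feature_order}
        out[str(cls)] = spider_orientation(radii, feature_order, **kwargs)
    return out
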