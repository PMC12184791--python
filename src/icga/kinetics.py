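"""ROI kinetics: curve extraction, motion artifacts and normalization.

A kinetics curve is the mean intensity over a circular ROI, frame by frame.
Motion (breathing, subject movement) contaminates curves with spikes much
faster than the few-second dye kinetics; they are detected against a rolling
median/MAD band and corrected by removal, smoothing or local replacement.

Four normalization families are supported:

* constant: divide by the maximum (``constant_max``) or mean
  (``constant_mean``) of a normal-tissue reference curve N(t) — a pure
  rescaling that changes no timing information;
* SBR, the signal-to-background ratio B(t)/N(t);
* CBR, the contrast-to-background ratio (B(t) − N(t)) / std[N(t)];
* nAUC, division of each curve by its own trapezoidal area under the curve,
  which makes curves unit-area and comparable across subjects, injections and
  illumination conditions.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from scipy.ndimage import uniform_filter1d

from .exceptions import ConfigurationError, DegenerateCurveError, FormatError
from .ingest import FrameStack

__all__ = [
    "ROI",
    "KineticsCurve",
    "NormalizationSpec",
    "load_rois",
    "extract_curve",
    "detect_motion_artifacts",
    "correct_motion",
    "normalize",
    "resample_to_reference",
    "trapezoid_auc",
]

NORMALIZATIONS = ("none", "constant_max", "constant_mean", "SBR", "CBR", "nAUC")
TISSUE_CLASSES = ("normal", "burn", "unknown")


@dataclass(frozen=True)
class ROI:
    """Circular region of interest in pixel coordinates."""

    label: str
    cx: float
    cy: float
    radius: float
    tissue_class: str = "unknown"
    reference: bool = False

    def __post_init__(self) -> None:
        if self.radius <= 0:
            raise ConfigurationError("ROI radius must be positive")
        if self.tissue_class not in TISSUE_CLASSES:
            raise ConfigurationError(f"unknown tissue_class {self.tissue_class!r}")

    def member_mask(self, frame_shape: tuple[int, int]) -> np.ndarray:
        """Boolean mask of pixels whose centers lie within the disk."""
        h, w = frame_shape
        yy, xx = np.mgrid[0:h, 0:w]
        return (xx - self.cx) ** 2 + (yy - self.cy) ** 2 <= self.radius**2

    def validate_inside(self, frame_shape: tuple[int, int]) -> None:
        h, w = frame_shape
        if (
            self.cx - self.radius < -0.5
            or self.cy - self.radius < -0.5
            or self.cx + self.radius > w - 0.5
            or self.cy + self.radius > h - 0.5
        ):
            raise ConfigurationError(f"ROI {self.label!r} does not lie inside the frame")


def load_rois(path) -> list[ROI]:
    """Read a JSON array of {label, cx_px, cy_px, r_px, tissue_class, reference}."""
    import json

    entries = json.loads(Path(path).read_text())
    return [
        ROI(
            label=str(e["label"]),
            cx=float(e["cx_px"]),
            cy=float(e["cy_px"]),
            radius=float(e["r_px"]),
            tissue_class=e.get("tissue_class", "unknown"),
            reference=bool(e.get("reference", False)),
        )
        for e in entries
    ]


def save_rois(rois: list[ROI], path) -> None:
    import json

    Path(path).write_text(
        json.dumps(
            [
                {
                    "label": r.label,
                    "cx_px": r.cx,
                    "cy_px": r.cy,
                    "r_px": r.radius,
                    "tissue_class": r.tissue_class,
                    "reference": r.reference,
                }
                for r in rois
            ],
            indent=1,
        )
    )


@dataclass
class KineticsCurve:
    """A (time, intensity) series for one ROI with processing provenance."""

    times: np.ndarray
    values: np.ndarray
    roi_label: str = "roi"
    tissue_class: str = "unknown"
    normalization: str = "none"
    provenance: list[str] = field(default_factory=list)
    artifact_mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.times.ndim != 1 or self.times.shape != self.values.shape:
            raise FormatError("times and values must be 1D arrays of equal length")
        if len(self.times) > 1 and not np.all(np.diff(self.times) > 0):
            raise FormatError("times must be strictly increasing")
        if self.normalization not in NORMALIZATIONS:
            raise ConfigurationError(f"unknown normalization {self.normalization!r}")
        if self.artifact_mask is not None:
            self.artifact_mask = np.asarray(self.artifact_mask, dtype=bool)
            if self.artifact_mask.shape != self.values.shape:
                raise FormatError("artifact_mask must match values in length")

    def __len__(self) -> int:
        return len(self.values)

    @property
    def sampling_rate(self) -> float:
        """Median sampling rate in Hz (robust to removed samples)."""
        return 1.0 / float(np.median(np.diff(self.times)))

    def with_step(self, step: str, **changes) -> "KineticsCurve":
        return replace(self, provenance=[*self.provenance, step], **changes)


@dataclass(frozen=True)
class NormalizationSpec:
    """Normalization mode plus, where applicable, the reference curve N(t)."""

    mode: str
    reference: KineticsCurve | None = None

    def __post_init__(self) -> None:
        if self.mode not in NORMALIZATIONS or self.mode == "none":
            raise ConfigurationError(f"invalid normalization mode {self.mode!r}")
        needs_ref = self.mode in ("constant_max", "constant_mean", "SBR", "CBR")
        if needs_ref and self.reference is None:
            raise ConfigurationError(f"{self.mode} requires a reference curve")
        if not needs_ref and self.reference is not None:
            raise ConfigurationError(f"{self.mode} forbids a reference curve")


def trapezoid_auc(times, values, t_start=None, t_end=None) -> float:
    """Trapezoidal area under (times, values) restricted to [t_start, t_end].

    Window edges falling between samples are handled by linear interpolation.
    """
    times = np.asarray(times, dtype=float)
    values = np.asarray(values, dtype=float)
    a = times[0] if t_start is None else max(float(t_start), times[0])
    b = times[-1] if t_end is None else min(float(t_end), times[-1])
    if b <= a:
        return 0.0
    inside = (times >= a) & (times <= b)
    ts = times[inside]
    vs = values[inside]
    if len(ts) == 0 or ts[0] > a:
        ts = np.concatenate([[a], ts])
        vs = np.concatenate([[np.interp(a, times, values)], vs])
    if ts[-1] < b:
        ts = np.concatenate([ts, [b]])
        vs = np.concatenate([vs, [np.interp(b, times, values)]])
    return float(np.trapezoid(vs, ts))


def extract_curve(stack: FrameStack, roi: ROI) -> KineticsCurve:
    """Mean intensity over the ROI disk, frame by frame.

    Pixel membership is by pixel-center inclusion; NaN (masked) pixels are
    excluded from the mean.  The whole disk being masked is an error.
    """
    roi.validate_inside(stack.frame_shape)
    member = roi.member_mask(stack.frame_shape)
    if not member.any():
        raise ConfigurationError(f"ROI {roi.label!r} covers no pixel centers")
    pix = stack.frames[:, member]  # (T, n_pixels)
    valid = ~np.isnan(pix)
    if not valid.any(axis=1).all():
        raise DegenerateCurveError(f"ROI {roi.label!r} fully masked in some frames")
    with np.errstate(invalid="ignore"):
        values = np.nanmean(pix, axis=1)
    return KineticsCurve(
        times=stack.times.copy(),
        values=values,
        roi_label=roi.label,
        tissue_class=roi.tissue_class,
        provenance=[*stack.provenance, f"roi:{roi.label}"],
    )


def detect_motion_artifacts(
    curve: KineticsCurve, window_samples: int = 11, mad_k: float = 5.0
) -> np.ndarray:
    """Flag samples deviating from a rolling median by more than k rolling MADs.

    The MAD is floored at machine-epsilon scale so that constant segments
    (MAD = 0) produce no spurious flags.  The mask is stored on the curve and
    also returned.
    """
    if len(curve) < 2 * window_samples:
        raise ConfigurationError("curve too short for the detection window")
    half = window_samples // 2
    padded = np.pad(curve.values, half, mode="edge")
    windows = np.lib.stride_tricks.sliding_window_view(padded, 2 * half + 1)
    med = np.median(windows, axis=1)
    mad = np.median(np.abs(windows - med[:, None]), axis=1)
    dev = np.abs(curve.values - med)
    floor = np.finfo(float).eps * max(1.0, float(np.max(np.abs(curve.values))))
    mask = dev > mad_k * np.maximum(mad, floor)
    curve.artifact_mask = mask
    return mask


def correct_motion(
    curve: KineticsCurve, method: str = "moving_average", window: int = 5
) -> KineticsCurve:
    """Correct motion artifacts.

    ``remove`` deletes flagged samples (times stay irregular);
    ``moving_average`` applies a centered mean of width ``window`` to all
    samples; ``smooth_flagged`` replaces flagged samples by the median of
    their nearest unflagged neighbors.
    """
    if method == "moving_average":
        if window < 1:
            raise ConfigurationError("window must be >= 1")
        values = uniform_filter1d(curve.values, size=int(window), mode="nearest")
        return curve.with_step(f"mac:moving_average:{window}", values=values)

    if curve.artifact_mask is None:
        raise ConfigurationError(f"method {method!r} requires a prior artifact mask")
    mask = curve.artifact_mask

    if method == "remove":
        keep = ~mask
        if keep.sum() < 10:
            raise DegenerateCurveError("artifact removal would leave < 10 samples")
        return curve.with_step(
            "mac:remove",
            times=curve.times[keep],
            values=curve.values[keep],
            artifact_mask=np.zeros(int(keep.sum()), dtype=bool),
        )

    if method == "smooth_flagged":
        values = curve.values.copy()
        good_idx = np.flatnonzero(~mask)
        if len(good_idx) < 2:
            raise DegenerateCurveError("not enough unflagged samples to interpolate")
        for i in np.flatnonzero(mask):
            # median of the 4 nearest unflagged neighbors
            order = np.argsort(np.abs(good_idx - i))[:4]
            values[i] = float(np.median(curve.values[good_idx[order]]))
        return curve.with_step("mac:smooth_flagged", values=values)

    raise ConfigurationError(f"unknown motion-correction method {method!r}")


def _check_common_grid(curve: KineticsCurve, reference: KineticsCurve) -> None:
    if len(curve) != len(reference) or not np.allclose(
        curve.times, reference.times, rtol=0, atol=1e-9
    ):
        raise ConfigurationError(
            "curve and reference are on different time grids; call "
            "resample_to_reference explicitly first"
        )


def resample_to_reference(curve: KineticsCurve, reference: KineticsCurve) -> KineticsCurve:
    """Linearly interpolate the curve onto the reference's time grid."""
    values = np.interp(reference.times, curve.times, curve.values)
    return curve.with_step("resampled", times=reference.times.copy(), values=values, artifact_mask=None)


def normalize(curve: KineticsCurve, spec: NormalizationSpec, std_ddof: int = 1) -> KineticsCurve:
    """Apply one normalization strategy; a curve is normalized exactly once."""
    if curve.normalization != "none":
        raise ConfigurationError(f"curve already normalized ({curve.normalization})")
    mode, ref = spec.mode, spec.reference

    if mode == "constant_max":
        c = float(np.max(ref.values))
        if c <= 0:
            raise DegenerateCurveError("reference maximum must be positive")
        values = curve.values / c
    elif mode == "constant_mean":
        c = float(np.mean(ref.values))
        if c == 0:
            raise DegenerateCurveError("reference mean is zero")
        values = curve.values / c
    elif mode == "SBR":
        _check_common_grid(curve, ref)
        with np.errstate(divide="ignore", invalid="ignore"):
            values = np.where(ref.values != 0, curve.values / ref.values, np.nan)
    elif mode == "CBR":
        _check_common_grid(curve, ref)
        sd = float(np.std(ref.values, ddof=std_ddof))
        if sd == 0:
            raise DegenerateCurveError("std of the reference curve is zero")
        values = (curve.values - ref.values) / sd
    elif mode == "nAUC":
        auc = trapezoid_auc(curve.times, curve.values)
        if auc <= 0:
            raise DegenerateCurveError(f"AUC must be positive for nAUC, got {auc}")
        values = curve.values / auc
    else:  # pragma: no cover - NormalizationSpec already rejects
        raise ConfigurationError(f"unknown mode {mode!r}")

    return curve.with_step(f"norm:{mode}", values=values, normalization=mode)
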