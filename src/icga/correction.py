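"""Image-level corrections: baseline, flat-field and working-distance.

Baseline subtraction removes the pre-injection background by subtracting the
mean of the first few frames (or samples, for curves).  Flat-field correction
removes spatial illumination non-uniformity using a flat calibration image
``IF`` (uniform fluorescent scene) and a dark/background image ``IB``:

    IC = (IR - IB) / (IF - IB) * MFB,      MFB = mean(IF - IB)

Working-distance correction refers intensities recorded at distance ``D`` to a
standard distance ``Ds`` using the inverse-square falloff of an isotropic
emitter over a flat surface, where a pixel at object-plane offset (x, y) cm
from the principal point sits at distance sqrt(D² + x² + y²) from the camera:

    I_Ds(x, y) = I_D(x, y) * (D² + x² + y²) / (Ds² + x² + y²)
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .exceptions import CalibrationError, ConfigurationError, FormatError
from .ingest import FrameStack

__all__ = [
    "FlatFieldSet",
    "DistanceGeometry",
    "subtract_baseline",
    "flat_field_correct",
    "distance_correct",
]

# Pixels where |IF - IB| falls at or below this fraction of MFB are masked.
DENOMINATOR_TOL = 1e-6


@dataclass
class FlatFieldSet:
    """Flat/background calibration pair and the derived mean difference MFB."""

    flat: np.ndarray
    background: np.ndarray

    def __post_init__(self) -> None:
        self.flat = np.asarray(self.flat, dtype=float)
        self.background = np.asarray(self.background, dtype=float)
        if self.flat.shape != self.background.shape or self.flat.ndim != 2:
            raise FormatError("flat and background must be 2D images of equal shape")
        if self.mfb <= 0:
            raise CalibrationError("mean(flat - background) must be positive")

    @property
    def mfb(self) -> float:
        return float(np.mean(self.flat - self.background))

    @property
    def invalid_mask(self) -> np.ndarray:
        """Pixels whose denominator IF - IB is numerically unusable."""
        return np.abs(self.flat - self.background) <= DENOMINATOR_TOL * self.mfb


@dataclass(frozen=True)
class DistanceGeometry:
    """Geometry needed to evaluate the flat-surface distance correction.

    ``pixel_pitch`` is the object-plane size of one pixel in cm; the principal
    point (x0, y0) is the pixel where the optical axis meets the frame, in
    (col, row) pixel coordinates.
    """

    working_distance: float  # D, cm
    standard_distance: float  # Ds, cm
    pixel_pitch: float  # cm per pixel at the object plane
    principal_point: tuple[float, float]  # (x0, y0) pixels

    def __post_init__(self) -> None:
        if self.working_distance <= 0 or self.standard_distance <= 0:
            raise ConfigurationError("distances must be positive")
        if self.pixel_pitch <= 0:
            raise ConfigurationError("pixel_pitch must be positive")

    def factor_map(self, frame_shape: tuple[int, int]) -> np.ndarray:
        h, w = frame_shape
        x0, y0 = self.principal_point
        x = (np.arange(w) - x0) * self.pixel_pitch
        y = (np.arange(h) - y0) * self.pixel_pitch
        r2 = x[None, :] ** 2 + y[:, None] ** 2
        d2, ds2 = self.working_distance**2, self.standard_distance**2
        return (d2 + r2) / (ds2 + r2)


def subtract_baseline(obj, n_baseline: int = 10):
    """Subtract the mean of the first ``n_baseline`` frames/samples.

    Works on a :class:`FrameStack` (pixelwise mean frame) or a
    :class:`~icga.kinetics.KineticsCurve` (scalar mean).  Negative values in
    the result are preserved; clipping policy lives with the consumers.
    """
    if n_baseline < 1 or int(n_baseline) != n_baseline:
        raise ConfigurationError("n_baseline must be a positive integer")
    n_baseline = int(n_baseline)
    if isinstance(obj, FrameStack):
        if n_baseline >= obj.n_frames:
            raise ConfigurationError(
                f"n_baseline {n_baseline} must be < number of frames {obj.n_frames}"
            )
        baseline = obj.frames[:n_baseline].mean(axis=0)
        return obj.with_step(f"baseline:{n_baseline}", frames=obj.frames - baseline)
    # curve path — import here to avoid a module cycle
    from .kinetics import KineticsCurve

    if isinstance(obj, KineticsCurve):
        if n_baseline >= len(obj.values):
            raise ConfigurationError(
                f"n_baseline {n_baseline} must be < number of samples {len(obj.values)}"
            )
        level = float(obj.values[:n_baseline].mean())
        return obj.with_step(f"baseline:{n_baseline}", values=obj.values - level)
    raise TypeError(f"cannot subtract baseline from {type(obj).__name__}")


def flat_field_correct(
    stack: FrameStack, ffs: FlatFieldSet, numerator: str = "background"
) -> FrameStack:
    """Apply flat-field correction to every frame.

    ``numerator`` selects the raw-image offset: ``"background"`` (default)
    computes (IR − IB)/(IF − IB)·MFB, the standard flat-field form in which the
    dark counts are subtracted from both the raw and the flat images;
    ``"flat"`` computes (IR − IF)/(IF − IB)·MFB instead; ``"none"`` computes
    IR/(IF − IB)·MFB, the gain-only form for stacks whose dark/ambient offset
    was already removed by temporal baseline subtraction (subtracting IB again
    would leave a spatially varying offset).  Pixels with an unusable
    denominator become NaN.
    """
    if any(p.startswith("ffc") for p in stack.provenance):
        raise ConfigurationError("stack is already flat-field corrected")
    if ffs.flat.shape != stack.frame_shape:
        raise FormatError(
            f"calibration shape {ffs.flat.shape} != frame shape {stack.frame_shape}"
        )
    if numerator not in ("background", "flat", "none"):
        raise ConfigurationError(f"unknown numerator choice {numerator!r}")
    invalid = ffs.invalid_mask
    if invalid.mean() > 0.5:
        raise CalibrationError(
            f"{invalid.mean():.0%} of calibration pixels have IF ~= IB"
        )
    denom = ffs.flat - ffs.background
    denom_safe = np.where(invalid, 1.0, denom)
    if numerator == "none":
        moved = stack.frames
    else:
        moved = stack.frames - (
            ffs.background if numerator == "background" else ffs.flat
        )
    corrected = moved / denom_safe * ffs.mfb
    corrected[:, invalid] = np.nan
    return stack.with_step(f"ffc:{numerator}", frames=corrected)


def distance_correct(stack: FrameStack, geom: DistanceGeometry) -> FrameStack:
    """Refer a stack recorded at distance D to the standard distance Ds."""
    if stack.working_distance is None:
        raise ConfigurationError("stack has no working_distance metadata")
    if not np.isclose(stack.working_distance, geom.working_distance):
        raise ConfigurationError(
            f"stack recorded at {stack.working_distance} cm but geometry says "
            f"{geom.working_distance} cm"
        )
    factor = geom.factor_map(stack.frame_shape)
    return stack.with_step(
        f"wd:{geom.working_distance}->{geom.standard_distance}",
        frames=stack.frames * factor,
        working_distance=geom.standard_distance,
    )
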