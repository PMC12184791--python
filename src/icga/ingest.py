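"""Loading and data-volume reduction for ICGA frame stacks.

An angiography recording arrives either as a multi-page TIFF, a directory of
equally sized 2D frames, or a pre-extracted curve table (CSV).  Devices that
export composite frames (white-light / fluorescence / overlay tiled into one
image) are handled by :func:`split_fields` with a user-supplied
:class:`FieldLayout`.  Volume reduction — time-window selection, temporal
binning and spatial downsampling — happens here, before any correction, so the
rest of the pipeline works on small arrays.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from .exceptions import ConfigurationError, FormatError

__all__ = [
    "FrameStack",
    "FieldLayout",
    "load_stack",
    "load_curves",
    "write_stack",
    "write_curves",
    "split_fields",
    "select_time_window",
    "temporal_bin",
    "spatial_downsample",
]

FIELD_KINDS = ("white_light", "fluorescence", "overlay", "composite")


@dataclass
class FrameStack:
    """A time-ordered stack of 2D intensity frames.

    Parameters
    ----------
    frames:
        Array of shape (T, H, W), arbitrary intensity units.  Values may be
        negative after baseline subtraction.
    times:
        Strictly increasing timestamps in seconds, length T.
    frame_rate:
        Acquisition rate in frames per second (after any binning).
    field_kind:
        One of ``white_light``, ``fluorescence``, ``overlay``, ``composite``.
    working_distance:
        Camera-to-tissue distance in cm, if known.
    provenance:
        Ordered list of applied-step identifiers; each operation appends
        exactly one entry and never removes any.
    """

    frames: np.ndarray
    times: np.ndarray
    frame_rate: float
    field_kind: str = "fluorescence"
    working_distance: float | None = None
    provenance: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        self.times = np.asarray(self.times, dtype=float)
        if self.frames.ndim != 3:
            raise FormatError(f"frames must be T×H×W, got shape {self.frames.shape}")
        if self.times.ndim != 1 or len(self.times) != self.frames.shape[0]:
            raise FormatError(
                f"times length {self.times.shape} does not match T={self.frames.shape[0]}"
            )
        if len(self.times) > 1 and not np.all(np.diff(self.times) > 0):
            raise FormatError("timestamps must be strictly increasing")
        if self.field_kind not in FIELD_KINDS:
            raise ConfigurationError(f"unknown field_kind {self.field_kind!r}")
        if self.frame_rate <= 0:
            raise ConfigurationError("frame_rate must be positive")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def frame_shape(self) -> tuple[int, int]:
        return self.frames.shape[1], self.frames.shape[2]

    def with_step(self, step: str, **changes) -> "FrameStack":
        """Return a copy with one provenance entry appended."""
        return replace(self, provenance=[*self.provenance, step], **changes)


@dataclass(frozen=True)
class FieldLayout:
    """Named rectangular regions mapping a composite frame to its subframes.

    Each region is ``(row_start, row_stop, col_start, col_stop)`` with
    half-open, 0-based pixel ranges.  Regions must be disjoint and lie inside
    the frame they are applied to.
    """

    regions: dict[str, tuple[int, int, int, int]]

    def validate(self, frame_shape: tuple[int, int]) -> None:
        h, w = frame_shape
        covered = np.zeros((h, w), dtype=bool)
        for name, (r0, r1, c0, c1) in self.regions.items():
            if not (0 <= r0 < r1 <= h and 0 <= c0 < c1 <= w):
                raise FormatError(
                    f"layout region {name!r} {(r0, r1, c0, c1)} outside {h}×{w} frame"
                )
            block = covered[r0:r1, c0:c1]
            if block.any():
                raise FormatError(f"layout region {name!r} overlaps another region")
            covered[r0:r1, c0:c1] = True

    @classmethod
    def from_dict(cls, d: dict) -> "FieldLayout":
        return cls(regions={k: tuple(int(x) for x in v) for k, v in d.items()})


def _read_metadata(metadata_path) -> dict:
    meta = json.loads(Path(metadata_path).read_text())
    if "frame_rate_fps" not in meta:
        raise ConfigurationError("metadata must supply frame_rate_fps")
    return meta


def load_stack(path, metadata_path) -> FrameStack:
    """Load a frame stack from a multi-page TIFF or a directory of frames.

    The JSON metadata sidecar must contain ``frame_rate_fps``; it may also
    carry ``working_distance_cm``, ``field_kind``, ``field_layout`` and
    explicit ``times_s``.  When timestamps are absent they are computed as
    ``i / frame_rate``; explicit timestamps win.
    """
    import tifffile

    path = Path(path)
    meta = _read_metadata(metadata_path)

    if path.is_dir():
        import imageio.v3 as iio

        files = sorted(p for p in path.iterdir() if p.suffix.lower() in (".tif", ".tiff", ".png"))
        if not files:
            raise FormatError(f"no frames found in directory {path}")
        frames_list = [np.asarray(iio.imread(f), dtype=float) for f in files]
        shapes = {f.shape for f in frames_list}
        if len(shapes) != 1:
            raise FormatError(f"frames differ in shape: {sorted(shapes)}")
        frames = np.stack(frames_list)
    else:
        frames = np.asarray(tifffile.imread(path), dtype=float)
        if frames.ndim == 2:
            frames = frames[None]
        if frames.ndim != 3:
            raise FormatError(f"expected a stack of 2D frames, got shape {frames.shape}")

    rate = float(meta["frame_rate_fps"])
    times = meta.get("times_s")
    times = (
        np.asarray(times, dtype=float) if times is not None else np.arange(len(frames)) / rate
    )
    return FrameStack(
        frames=frames,
        times=times,
        frame_rate=rate,
        field_kind=meta.get("field_kind", "fluorescence"),
        working_distance=meta.get("working_distance_cm"),
        provenance=["loaded"],
    )


def write_stack(stack: FrameStack, path, metadata_path=None) -> None:
    """Write a stack as a float32 multi-page TIFF plus a JSON sidecar."""
    import tifffile

    tifffile.imwrite(path, stack.frames.astype(np.float32))
    if metadata_path is not None:
        meta = {
            "frame_rate_fps": stack.frame_rate,
            "field_kind": stack.field_kind,
            "times_s": [float(t) for t in stack.times],
        }
        if stack.working_distance is not None:
            meta["working_distance_cm"] = stack.working_distance
        Path(metadata_path).write_text(json.dumps(meta))


def load_curves(path) -> list:
    """Load a curve table: column 1 = time_s, one intensity column per ROI."""
    import pandas as pd

    from .kinetics import KineticsCurve

    df = pd.read_csv(path)
    if df.shape[1] < 2:
        raise FormatError("curve table needs a time column plus at least one ROI column")
    times = df.iloc[:, 0].to_numpy(dtype=float)
    curves = []
    for col in df.columns[1:]:
        if col.endswith("_artifact"):
            continue
        mask_col = f"{col}_artifact"
        mask = df[mask_col].to_numpy(dtype=bool) if mask_col in df.columns else None
        curves.append(
            KineticsCurve(
                times=times.copy(),
                values=df[col].to_numpy(dtype=float),
                roi_label=str(col),
                provenance=["loaded"],
                artifact_mask=mask,
            )
        )
    return curves


def write_curves(curves, path, include_masks: bool = False) -> None:
    """Write curves sharing one time grid to the CSV dialect of load_curves."""
    import pandas as pd

    times = curves[0].times
    for c in curves[1:]:
        if len(c.times) != len(times) or not np.allclose(c.times, times):
            raise FormatError("write_curves requires a common time grid")
    data = {"time_s": times}
    for c in curves:
        data[c.roi_label] = c.values
        if include_masks and c.artifact_mask is not None:
            data[f"{c.roi_label}_artifact"] = c.artifact_mask.astype(int)
    pd.DataFrame(data).to_csv(path, index=False)


def split_fields(stack: FrameStack, layout: FieldLayout) -> dict[str, FrameStack]:
    """Split a composite stack into white-light and fluorescence stacks.

    The overlay region, if present in the layout, is discarded.  A stack that
    is already a single field passes through unchanged with a warning.
    """
    if stack.field_kind != "composite":
        warnings.warn(
            f"split_fields called on a {stack.field_kind!r} stack; passing through",
            stacklevel=2,
        )
        return {stack.field_kind: stack}
    layout.validate(stack.frame_shape)
    out = {}
    for name, (r0, r1, c0, c1) in layout.regions.items():
        if name == "overlay":
            continue
        if name not in ("white_light", "fluorescence"):
            raise ConfigurationError(f"unknown layout field {name!r}")
        out[name] = FrameStack(
            frames=stack.frames[:, r0:r1, c0:c1].copy(),
            times=stack.times.copy(),
            frame_rate=stack.frame_rate,
            field_kind=name,
            working_distance=stack.working_distance,
            provenance=[*stack.provenance, f"split:{name}"],
        )
    return out


def select_time_window(
    stack: FrameStack, t_start: float, t_end: float, rezero: bool = False
) -> FrameStack:
    """Keep frames with ``t_start <= t < t_end`` (half-open window).

    Times are not re-zeroed unless ``rezero`` is set.
    """
    if not t_start < t_end:
        raise ConfigurationError("need t_start < t_end")
    keep = (stack.times >= t_start) & (stack.times < t_end)
    if not keep.any():
        raise ConfigurationError(
            f"window [{t_start}, {t_end}) does not intersect "
            f"[{stack.times[0]}, {stack.times[-1]}]"
        )
    times = stack.times[keep]
    if rezero:
        times = times - times[0]
    return stack.with_step(
        f"window:[{t_start},{t_end})", frames=stack.frames[keep], times=times
    )


def temporal_bin(stack: FrameStack, factor: int, mode: str = "average") -> FrameStack:
    """Reduce the sampling rate by an integer factor.

    ``average`` (default) replaces non-overlapping groups of ``factor``
    consecutive frames by their pixelwise mean, raising the per-frame SNR;
    ``decimate`` keeps the first frame of each group.  The trailing incomplete
    group is dropped; the new timestamp is the group-mean time (or the kept
    frame's time for decimation) and the frame rate divides by ``factor``.
    """
    if factor < 1 or int(factor) != factor:
        raise ConfigurationError("factor must be a positive integer")
    factor = int(factor)
    if factor > stack.n_frames:
        raise ConfigurationError(f"factor {factor} exceeds stack length {stack.n_frames}")
    if factor == 1:
        return stack.with_step("tbin:1")
    n = (stack.n_frames // factor) * factor
    grouped = stack.frames[:n].reshape(-1, factor, *stack.frame_shape)
    gtimes = stack.times[:n].reshape(-1, factor)
    if mode == "average":
        frames = grouped.mean(axis=1)
        times = gtimes.mean(axis=1)
    elif mode == "decimate":
        frames = grouped[:, 0].copy()
        times = gtimes[:, 0].copy()
    else:
        raise ConfigurationError(f"unknown temporal_bin mode {mode!r}")
    return stack.with_step(
        f"tbin:{factor}:{mode}",
        frames=frames,
        times=times,
        frame_rate=stack.frame_rate / factor,
    )


def spatial_downsample(stack: FrameStack, factor: int) -> FrameStack:
    """Block-average each frame over factor×factor tiles (partial tiles dropped)."""
    if factor < 1 or int(factor) != factor:
        raise ConfigurationError("factor must be a positive integer")
    factor = int(factor)
    h, w = stack.frame_shape
    if factor > h or factor > w:
        raise ConfigurationError(f"factor {factor} exceeds frame shape {h}×{w}")
    if factor == 1:
        return stack.with_step("sbin:1")
    hh, ww = h // factor, w // factor
    cropped = stack.frames[:, : hh * factor, : ww * factor]
    frames = cropped.reshape(stack.n_frames, hh, factor, ww, factor).mean(axis=(2, 4))
    return stack.with_step(f"sbin:{factor}", frames=frames)
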