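"""Synthetic ground-truth generators: curves, phantom stacks, artifacts.

The parametric curve model reproduces the four phases of a dye bolus transit:
a flat baseline, a gamma-variate uptake, a fast exponential washout and a slow
residual washout.  With onset t0, peak delay tp = α·β and Δ = t − t0,

    F(t) = b                                              t ≤ t0
    F(t) = b + A · (Δ/tp)^α · exp(α·(1 − Δ/tp))           t0 < t ≤ t0 + tp
    F(t) = b + A · [(1−ρ)·e^(−λf·(Δ−tp)) + ρ·e^(−λs·(Δ−tp))]   t > t0 + tp

The decay branch is anchored at the gamma-variate's analytic peak so that the
peak time (t0 + α·β) and peak height (A above baseline) are closed-form and
recorded in the truth dictionary.

Severity presets encode the qualitative burn findings: relative to normal
tissue, a superficial (hyperperfused) burn has a higher and earlier peak,
steeper ingress/egress and a narrower FWHM; a deep burn the reverse.  The
preset parameters were calibrated once against the directionality self-test
(:func:`preset_directionality`) and are frozen here.

Phantom frame stacks compose a vignetting field, the inverse-square working
distance falloff D²/(D² + x² + y²), per-region bolus curves, a dark level and
optional noise, and emit the matching flat/background calibration pair and
truth ROIs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .correction import FlatFieldSet
from .exceptions import ConfigurationError
from .ingest import FrameStack
from .kinetics import ROI, KineticsCurve

__all__ = [
    "CurveModel",
    "SeverityPreset",
    "SceneConfig",
    "severity_presets",
    "simulate_curve",
    "simulate_stack",
    "inject_breathing",
    "preset_directionality",
]


@dataclass(frozen=True)
class CurveModel:
    """Parameters of the four-phase bolus curve (see module docstring)."""

    t0: float = 10.0  # uptake onset, s
    amplitude: float = 100.0  # A, peak height above baseline, a.u.
    alpha: float = 3.0  # gamma-variate shape
    beta: float = 3.0  # gamma-variate scale, s (peak delay = alpha*beta)
    lam_fast: float = 0.08  # fast washout rate, 1/s
    rho: float = 0.35  # residual plateau fraction
    lam_slow: float = 0.005  # slow washout rate, 1/s
    baseline: float = 5.0  # b, a.u.
    noise_sd_frac: float = 0.0  # Gaussian sd as a fraction of A
    poisson_like: bool = False  # scale noise sd by sqrt(value/A)

    def __post_init__(self) -> None:
        if self.alpha <= 0 or self.beta <= 0 or self.amplitude <= 0:
            raise ConfigurationError("alpha, beta and amplitude must be positive")
        if not (self.lam_fast > self.lam_slow >= 0):
            raise ConfigurationError("need lam_fast > lam_slow >= 0")
        if not (0 <= self.rho < 1):
            raise ConfigurationError("rho must lie in [0, 1)")
        if self.noise_sd_frac < 0:
            raise ConfigurationError("noise_sd_frac must be >= 0")

    @property
    def peak_time(self) -> float:
        return self.t0 + self.alpha * self.beta

    def evaluate(self, times: np.ndarray) -> np.ndarray:
        """Noiseless curve values at the given times."""
        t = np.asarray(times, dtype=float)
        delta = t - self.t0
        tp = self.alpha * self.beta
        out = np.full_like(t, self.baseline)
        rise = (delta > 0) & (delta <= tp)
        with np.errstate(divide="ignore", invalid="ignore"):
            out[rise] = self.baseline + self.amplitude * (
                (delta[rise] / tp) ** self.alpha * np.exp(self.alpha * (1 - delta[rise] / tp))
            )
        fall = delta > tp
        dd = delta[fall] - tp
        out[fall] = self.baseline + self.amplitude * (
            (1 - self.rho) * np.exp(-self.lam_fast * dd)
            + self.rho * np.exp(-self.lam_slow * dd)
        )
        return out

    def truth(self) -> dict:
        """Analytic landmark record for generator-vs-extractor round trips."""
        return {
            "t0": self.t0,
            "t_peak": self.peak_time,
            "imax": self.amplitude,  # above baseline
            "baseline": self.baseline,
            "lam_fast": self.lam_fast,
            "lam_slow": self.lam_slow,
            "rho": self.rho,
        }


@dataclass(frozen=True)
class SeverityPreset:
    """Named burn-severity class and its curve model."""

    name: str
    model: CurveModel


def severity_presets() -> dict[str, SeverityPreset]:
    """Frozen severity presets (normal / superficial / deep).

    Superficial: hyperperfusion — higher, earlier, narrower bolus with steeper
    slopes and a higher residual plateau.  Deep: vascular destruction — lower,
    later, broader bolus with shallow slopes.
    """
    return {
        "normal": SeverityPreset(
            "normal",
            CurveModel(
                t0=10.0, amplitude=100.0, alpha=3.0, beta=3.0,
                lam_fast=0.08, rho=0.35, lam_slow=0.005, baseline=5.0,
            ),
        ),
        "superficial": SeverityPreset(
            "superficial",
            CurveModel(
                t0=8.0, amplitude=170.0, alpha=3.0, beta=1.5,
                lam_fast=0.10, rho=0.25, lam_slow=0.004, baseline=5.0,
            ),
        ),
        "deep": SeverityPreset(
            "deep",
            CurveModel(
                t0=14.0, amplitude=45.0, alpha=3.0, beta=5.0,
                lam_fast=0.045, rho=0.28, lam_slow=0.006, baseline=5.0,
            ),
        ),
    }


def simulate_curve(
    model: CurveModel, times, seed: int = 0, roi_label: str = "sim", tissue_class: str = "unknown"
) -> tuple[KineticsCurve, dict]:
    """Sample the curve model on a time grid, optionally with seeded noise."""
    times = np.asarray(times, dtype=float)
    if len(times) > 1 and not np.all(np.diff(times) > 0):
        raise ConfigurationError("times must be strictly increasing")
    values = model.evaluate(times)
    if model.noise_sd_frac > 0:
        rng = np.random.default_rng(seed)
        sd = model.noise_sd_frac * model.amplitude
        if model.poisson_like:
            scale = np.sqrt(np.clip(values, 0, None) / model.amplitude)
            noise = rng.normal(0.0, 1.0, len(times)) * sd * scale
        else:
            noise = rng.normal(0.0, sd, len(times))
        values = values + noise
    curve = KineticsCurve(
        times=times.copy(),
        values=values,
        roi_label=roi_label,
        tissue_class=tissue_class,
        provenance=["simulated"],
    )
    return curve, model.truth()


def inject_breathing(
    curve: KineticsCurve, amplitude_fraction: float, period_s: float, seed: int = 0
) -> tuple[KineticsCurve, np.ndarray]:
    """Add periodic positive one-sample spikes emulating breathing motion.

    Spikes land every ``period_s`` seconds starting at the first sample,
    jittered by at most one sample; each adds ``amplitude_fraction`` times the
    local value.  Returns the contaminated curve and the spike sample indices.
    """
    if amplitude_fraction <= 0:
        raise ConfigurationError("amplitude_fraction must be positive")
    fs = curve.sampling_rate
    if period_s <= 2.0 / fs:
        raise ConfigurationError("period must exceed two sample intervals")
    duration = len(curve) / fs  # recording length, not last-timestamp offset
    n_spikes = int(duration // period_s)
    rng = np.random.default_rng(seed)
    values = curve.values.copy()
    indices = []
    for k in range(n_spikes):
        t_spike = curve.times[0] + k * period_s
        i = int(np.argmin(np.abs(curve.times - t_spike)))
        i = int(np.clip(i + rng.integers(-1, 2), 0, len(values) - 1))
        if i in indices:  # keep spikes one sample wide and distinct
            i = min(i + 1, len(values) - 1)
        indices.append(i)
        values[i] = values[i] * (1.0 + amplitude_fraction)
    out = curve.with_step(f"breathing:{amplitude_fraction}:{period_s}", values=values)
    return out, np.asarray(sorted(set(indices)), dtype=int)


@dataclass(frozen=True)
class SceneConfig:
    """Phantom scene: disk regions with severity presets under vignetting."""

    shape: tuple[int, int] = (64, 64)  # H, W
    fps: float = 5.0
    duration: float = 120.0  # s
    regions: tuple = ()  # ((ROI, preset_name), ...)
    vignette: str = "gaussian"  # or "cos4" or "none"
    vignette_strength: float = 0.6  # gaussian: sigma = strength * min(H,W)/2
    working_distance: float = 30.0  # D, cm
    pixel_pitch: float = 0.05  # cm per pixel at the object plane
    distance_falloff: bool = True
    dark_level: float = 2.0
    background_level: float = 0.0  # fluorescence outside regions
    noise_sd: float = 0.0  # additive Gaussian sd per pixel
    seed: int = 0

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ConfigurationError("a seed is mandatory")
        h, w = self.shape
        for roi, _ in self.regions:
            roi.validate_inside((h, w))
        for i, (a, _) in enumerate(self.regions):
            for b, _ in list(self.regions)[i + 1:]:
                d = np.hypot(a.cx - b.cx, a.cy - b.cy)
                if d < a.radius + b.radius:
                    raise ConfigurationError(f"regions {a.label!r} and {b.label!r} overlap")


def _vignette_field(scene: SceneConfig) -> np.ndarray:
    h, w = scene.shape
    yy, xx = np.mgrid[0:h, 0:w]
    cx, cy = (w - 1) / 2.0, (h - 1) / 2.0
    r2 = (xx - cx) ** 2 + (yy - cy) ** 2
    if scene.vignette == "none":
        return np.ones((h, w))
    if scene.vignette == "gaussian":
        sigma = scene.vignette_strength * min(h, w) / 2.0
        return np.exp(-r2 / (2 * sigma**2))
    if scene.vignette == "cos4":
        # cos^4 of the field angle; strength sets the FOV half-angle reach
        r = np.sqrt(r2) / (min(h, w) / 2.0)
        theta = np.arctan(scene.vignette_strength * r)
        return np.cos(theta) ** 4
    raise ConfigurationError(f"unknown vignette model {scene.vignette!r}")


def _distance_field(scene: SceneConfig) -> np.ndarray:
    h, w = scene.shape
    if not scene.distance_falloff:
        return np.ones((h, w))
    yy, xx = np.mgrid[0:h, 0:w]
    cx, cy = (w - 1) / 2.0, (h - 1) / 2.0
    x = (xx - cx) * scene.pixel_pitch
    y = (yy - cy) * scene.pixel_pitch
    d2 = scene.working_distance**2
    return d2 / (d2 + x**2 + y**2)


def simulate_stack(
    scene: SceneConfig,
) -> tuple[FrameStack, list[ROI], FlatFieldSet, dict[str, KineticsCurve]]:
    """Render a phantom stack plus calibration pair, truth ROIs and curves.

    Per pixel: intensity = vignette · distance_falloff · region_curve(t)
    (+ background level outside regions) + dark level + noise.  The flat
    image images a uniform fluorescent scene through the same vignette and
    falloff, so flat-field correction with the emitted pair removes both.
    """
    presets = severity_presets()
    h, w = scene.shape
    n = int(round(scene.duration * scene.fps))
    times = np.arange(n) / scene.fps
    gain = _vignette_field(scene) * _distance_field(scene)

    spatial = np.full((h, w), float(scene.background_level))
    truth_curves: dict[str, KineticsCurve] = {}
    region_masks = []
    rois = []
    for roi, preset_name in scene.regions:
        if preset_name not in presets:
            raise ConfigurationError(f"unknown severity preset {preset_name!r}")
        model = presets[preset_name].model
        member = roi.member_mask((h, w))
        region_masks.append((member, model))
        rois.append(replace_tissue(roi, preset_name))
        truth_curves[roi.label] = KineticsCurve(
            times=times.copy(),
            values=model.evaluate(times),
            roi_label=roi.label,
            tissue_class="normal" if preset_name == "normal" else "burn",
            provenance=["truth"],
        )

    frames = np.empty((n, h, w))
    base = spatial * gain + scene.dark_level
    frames[:] = base
    for member, model in region_masks:
        curve_vals = model.evaluate(times)
        frames[:, member] = curve_vals[:, None] * gain[member][None, :] + scene.dark_level

    if scene.noise_sd > 0:
        rng = np.random.default_rng(scene.seed)
        frames = frames + rng.normal(0.0, scene.noise_sd, frames.shape)

    stack = FrameStack(
        frames=frames,
        times=times,
        frame_rate=scene.fps,
        field_kind="fluorescence",
        working_distance=scene.working_distance,
        provenance=["simulated"],
    )
    flat_level = 100.0
    ffs = FlatFieldSet(
        flat=flat_level * gain + scene.dark_level,
        background=np.full((h, w), float(scene.dark_level)),
    )
    return stack, rois, ffs, truth_curves


def replace_tissue(roi: ROI, preset_name: str) -> ROI:
    """Copy an ROI with its tissue class derived from the severity preset."""
    tissue = "normal" if preset_name == "normal" else "burn"
    return ROI(
        label=roi.label,
        cx=roi.cx,
        cy=roi.cy,
        radius=roi.radius,
        tissue_class=tissue,
        reference=roi.reference,
    )


def preset_directionality(fps: float = 5.0, duration: float = 120.0) -> dict[str, dict[str, float]]:
    """Self-test table: noiseless nAUC relative features per severity class.

    Returns, for superficial and deep, each hexagon feature divided by the
    normal-tissue value (slopes compared in absolute value).  The frozen
    presets must give superficial > 1 on imax/rauc/s1/|s2| and < 1 on
    mtt/fwhm, with deep reversed.
    """
    from .features import compute_features, detect_landmarks
    from .kinetics import NormalizationSpec, normalize

    times = np.arange(int(round(duration * fps))) / fps
    rows = {}
    for name, preset in severity_presets().items():
        model = replace(preset.model, baseline=0.0)  # already baseline-subtracted
        curve, _ = simulate_curve(model, times, seed=0, roi_label=name)
        curve = normalize(curve, NormalizationSpec(mode="nAUC"))
        fs = compute_features(curve, detect_landmarks(curve))
        rows[name] = {
            "imax": fs.imax,
            "rauc": fs.rauc,
            "mtt_s": fs.mtt_s,
            "fwhm_s": fs.fwhm_s,
            "s1": abs(fs.s1),
            "s2": abs(fs.s2),
        }
    normal = rows["normal"]
    return {
        cls: {k: rows[cls][k] / normal[k] for k in normal}
        for cls in ("superficial", "deep")
    }
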