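"""Curve landmarks and feature extraction.

A baseline-subtracted bolus curve has three landmarks: the uptake start t0
(first sustained rise above the baseline noise band), the peak time tP, and
the inflection time tInf where the fast washout hands over to the slow
residual washout.  tInf is found as the breakpoint of the best continuous
two-segment linear fit to the decay.

Features split into three families:

* intensity — IMAX (peak value), AUCs: total, perfusion (t0→tInf),
  permeability (tInf→end) and residual rAUC (tP→end);
* timing — tP, FWHM, the mean transit time MTT = Σ Fi·ti / Σ Fi and its
  variance V = Σ Fi·ti² / Σ Fi − MTT², where Fi is the (nonnegative) signal
  in time bin ti;
* mixed — the three linear-segment slopes: ingress s1, fast egress s2,
  residual egress s3.

MTT and V use plain sums over the sample grid, with negative samples clipped
to zero so that Fi acts as a nonnegative weight; the clipping applies only
here, never to AUCs or slopes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .exceptions import DegenerateCurveError, NoUptakeError
from .kinetics import KineticsCurve, trapezoid_auc

__all__ = [
    "LandmarkConfig",
    "Landmarks",
    "FeatureSet",
    "detect_landmarks",
    "compute_mtt",
    "compute_variance",
    "compute_fwhm",
    "compute_slopes",
    "compute_features",
    "FEATURE_COLUMNS",
]

FEATURE_COLUMNS = [
    "roi_label",
    "tissue_class",
    "imax",
    "auc_total",
    "auc_perf",
    "auc_perm",
    "rauc",
    "tp_s",
    "fwhm_s",
    "fwhm_censored",
    "mtt_s",
    "var_s2",
    "s1",
    "s2",
    "s3",
    "normalization",
]


@dataclass(frozen=True)
class LandmarkConfig:
    """Tunables for landmark detection.

    ``baseline_k`` baseline SD multiples and ``consecutive_m`` consecutive
    above-threshold samples define the uptake start; ``baseline_n`` samples
    estimate the baseline statistics; ``peak_smooth`` is the moving-average
    width used only for locating the peak; ``rise_band`` restricts the s1 fit
    to that fraction range of IMAX.
    """

    baseline_k: float = 3.0
    consecutive_m: int = 3
    baseline_n: int = 10
    peak_smooth: int = 3
    rise_band: tuple[float, float] = (0.10, 0.90)


@dataclass
class Landmarks:
    t0: float
    tp: float
    tinf: float | None  # None when censored
    tinf_censored: bool = False

    def __post_init__(self) -> None:
        if self.tp < self.t0:
            raise DegenerateCurveError(f"tP {self.tp} earlier than t0 {self.t0}")
        if self.tinf is not None and self.tinf < self.tp:
            raise DegenerateCurveError(f"tInf {self.tinf} earlier than tP {self.tp}")


@dataclass
class FeatureSet:
    roi_label: str
    tissue_class: str
    imax: float
    auc_total: float
    auc_perf: float
    auc_perm: float
    rauc: float
    tp_s: float
    fwhm_s: float
    fwhm_censored: bool
    mtt_s: float
    var_s2: float
    s1: float | None
    s2: float | None
    s3: float | None
    normalization: str = "none"
    r2: dict | None = None

    def as_row(self) -> dict:
        return {k: getattr(self, k) for k in FEATURE_COLUMNS}


def _moving_average(values: np.ndarray, width: int) -> np.ndarray:
    if width <= 1:
        return values
    from scipy.ndimage import uniform_filter1d

    return uniform_filter1d(values, size=int(width), mode="nearest")


def _two_segment_fit(t: np.ndarray, v: np.ndarray, bp: int) -> float:
    """SSE of the continuous two-segment linear fit with breakpoint index bp."""
    tb = t[bp]
    design = np.column_stack(
        [np.ones_like(t), t - tb, np.maximum(t - tb, 0.0)]
    )
    _, res, _, _ = np.linalg.lstsq(design, v, rcond=None)
    if res.size:
        return float(res[0])
    pred = design @ np.linalg.lstsq(design, v, rcond=None)[0]
    return float(np.sum((v - pred) ** 2))


def detect_landmarks(curve: KineticsCurve, config: LandmarkConfig | None = None) -> Landmarks:
    """Locate t0, tP and tInf on a baseline-subtracted curve.

    t0 is the first time with ``consecutive_m`` consecutive samples above
    ``baseline_k`` baseline SDs; tP the time of the (smoothed) global maximum;
    tInf the breakpoint of the best continuous two-segment linear fit over
    [tP, end], censored when fewer than 4 samples follow the peak.
    """
    cfg = config or LandmarkConfig()
    t, v = curve.times, curve.values
    if len(v) < 20:
        raise DegenerateCurveError("need at least 20 samples for landmark detection")

    nb = min(cfg.baseline_n, len(v) - 1)
    mu = float(np.mean(v[:nb]))
    sd = float(np.std(v[:nb], ddof=1)) if nb > 1 else 0.0
    # noiseless baselines: fall back to a small fraction of the dynamic range
    thresh = mu + cfg.baseline_k * sd
    if sd == 0.0:
        thresh = mu + 1e-9 * max(1.0, float(np.max(np.abs(v))))

    above = v > thresh
    m = cfg.consecutive_m
    i0 = None
    run = 0
    for i, a in enumerate(above):
        run = run + 1 if a else 0
        if run >= m:
            i0 = i - m + 1
            break
    if i0 is None:
        raise NoUptakeError("no sustained rise above the baseline noise band")

    smoothed = _moving_average(v, cfg.peak_smooth)
    ip = i0 + int(np.argmax(smoothed[i0:]))
    tp = float(t[ip])

    post = np.arange(ip, len(v))
    if len(post) < 4:
        return Landmarks(t0=float(t[i0]), tp=tp, tinf=None, tinf_censored=True)
    tt, vv = t[post], v[post]
    # candidate breakpoints leave >= 2 samples in each segment
    candidates = range(1, len(post) - 1)
    sses = [_two_segment_fit(tt, vv, bp) for bp in candidates]
    best = list(candidates)[int(np.argmin(sses))]
    tinf = float(tt[best])
    return Landmarks(t0=float(t[i0]), tp=tp, tinf=tinf, tinf_censored=False)


def _clipped_weights(curve: KineticsCurve, t_start, t_end) -> tuple[np.ndarray, np.ndarray]:
    t, v = curve.times, curve.values
    sel = np.ones(len(t), dtype=bool)
    if t_start is not None:
        sel &= t >= t_start
    if t_end is not None:
        sel &= t <= t_end
    f = np.clip(v[sel], 0.0, None)
    if not np.any(f > 0):
        raise DegenerateCurveError("all samples <= 0 in the analysis window")
    return f, t[sel]


def compute_mtt(curve: KineticsCurve, t_start=None, t_end=None) -> float:
    """Mean transit time: intensity-weighted mean of the sample times."""
    f, t = _clipped_weights(curve, t_start, t_end)
    return float(np.sum(f * t) / np.sum(f))


def compute_variance(curve: KineticsCurve, t_start=None, t_end=None) -> float:
    """Intensity-weighted variance of the sample times (second central moment)."""
    f, t = _clipped_weights(curve, t_start, t_end)
    mtt = np.sum(f * t) / np.sum(f)
    return float(np.sum(f * t**2) / np.sum(f) - mtt**2)


def compute_fwhm(curve: KineticsCurve, landmarks: Landmarks) -> tuple[float, bool]:
    """Full width at half maximum by linear interpolation at the half level.

    The rising crossing is the last up-crossing before the peak, the falling
    crossing the first down-crossing after it.  A curve still above the half
    level at the end of the recording is censored: the width runs to the last
    sample and the flag is set.
    """
    t, v = curve.times, curve.values
    ip = int(np.argmin(np.abs(t - landmarks.tp)))
    imax = float(v[ip])
    if imax <= 0:
        raise DegenerateCurveError("peak value must be positive for FWHM")
    half = imax / 2.0

    t_rise = float(t[0])
    for j in range(ip - 1, -1, -1):
        if v[j] < half <= v[j + 1]:
            t_rise = float(np.interp(half, [v[j], v[j + 1]], [t[j], t[j + 1]]))
            break
    else:
        if v[0] >= half and ip == 0:
            raise DegenerateCurveError("curve never rises through the half level")

    for j in range(ip, len(v) - 1):
        if v[j] >= half > v[j + 1]:
            # interpolate on the falling edge (values decreasing)
            t_fall = float(
                np.interp(half, [v[j + 1], v[j]], [t[j + 1], t[j]])
            )
            return t_fall - t_rise, False
    return float(t[-1]) - t_rise, True


def _ols_slope(t: np.ndarray, v: np.ndarray) -> tuple[float, float]:
    slope, intercept = np.polyfit(t, v, 1)
    pred = slope * t + intercept
    ss_res = float(np.sum((v - pred) ** 2))
    ss_tot = float(np.sum((v - v.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    return float(slope), r2


def compute_slopes(
    curve: KineticsCurve, landmarks: Landmarks, config: LandmarkConfig | None = None
) -> tuple[dict, dict]:
    """Ordinary least-squares slopes of the three dynamic segments.

    s1 fits the samples on [t0, tP] whose values lie within the configured
    rise band (default 10–90% of IMAX); s2 fits [tP, tInf]; s3 fits
    [tInf, end].  A segment with fewer than 3 samples yields None for that
    slope rather than an error; s3 is skipped when tInf is censored.
    """
    cfg = config or LandmarkConfig()
    t, v = curve.times, curve.values
    ip = int(np.argmin(np.abs(t - landmarks.tp)))
    imax = float(v[ip])
    lo, hi = cfg.rise_band

    slopes: dict = {"s1": None, "s2": None, "s3": None}
    r2s: dict = {"s1": None, "s2": None, "s3": None}

    rise = (t >= landmarks.t0) & (t <= landmarks.tp) & (v >= lo * imax) & (v <= hi * imax)
    if rise.sum() >= 3:
        slopes["s1"], r2s["s1"] = _ols_slope(t[rise], v[rise])

    if landmarks.tinf is not None:
        fast = (t >= landmarks.tp) & (t <= landmarks.tinf)
        if fast.sum() >= 3:
            slopes["s2"], r2s["s2"] = _ols_slope(t[fast], v[fast])
        slow = t >= landmarks.tinf
        if slow.sum() >= 3:
            slopes["s3"], r2s["s3"] = _ols_slope(t[slow], v[slow])
    return slopes, r2s


def compute_features(
    curve: KineticsCurve,
    landmarks: Landmarks | None = None,
    config: LandmarkConfig | None = None,
) -> FeatureSet:
    """Aggregate the full feature set of one baseline-subtracted curve."""
    lm = landmarks or detect_landmarks(curve, config)
    t, v = curve.times, curve.values
    t_end = float(t[-1])
    ip = int(np.argmin(np.abs(t - lm.tp)))
    imax = float(v[ip])

    tinf = lm.tinf if lm.tinf is not None else t_end
    auc_total = trapezoid_auc(t, v, lm.t0, t_end)
    auc_perf = trapezoid_auc(t, v, lm.t0, tinf)
    auc_perm = trapezoid_auc(t, v, tinf, t_end)
    rauc = trapezoid_auc(t, v, lm.tp, t_end)
    fwhm, censored = compute_fwhm(curve, lm)
    mtt = compute_mtt(curve, t_start=lm.t0)
    var = compute_variance(curve, t_start=lm.t0)
    slopes, r2s = compute_slopes(curve, lm, config)

    return FeatureSet(
        roi_label=curve.roi_label,
        tissue_class=curve.tissue_class,
        imax=imax,
        auc_total=auc_total,
        auc_perf=auc_perf,
        auc_perm=auc_perm,
        rauc=rauc,
        tp_s=lm.tp,
        fwhm_s=fwhm,
        fwhm_censored=censored,
        mtt_s=mtt,
        var_s2=var,
        s1=slopes["s1"],
        s2=slopes["s2"],
        s3=slopes["s3"],
        normalization=curve.normalization,
        r2=r2s,
    )
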