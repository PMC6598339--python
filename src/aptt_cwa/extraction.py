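"""Clot waveform analysis on sampled APTT curves.

Derivative curves come from Savitzky-Golay local-polynomial smoothing;
the first derivative is the coagulation velocity, the second the
coagulation acceleration.  From these the ten waveform parameters are
measured: peak times of the acceleration peak (2ndDP1), velocity peak
(1stDP) and half fibrin formation (1/2FF); peak heights of 2ndDP1,
1stDP, the negative deceleration peak (2ndDP2, reported as magnitude
"NH") and 1/2FF; and FWHM widths of the 1stDP, 2ndDP1 and 2ndDP2, with
explicit right-censoring at the acquisition-window end.  A biphasic
waveform (a pre-clot absorbance ramp, the DIC-associated abnormality)
is detected from the slope of the pre-clot segment and from doubled
acceleration peaks.

Differentiating a sampled trace trades bias against noise: a short
smoothing window tracks sharp acceleration peaks but amplifies
photometric noise as 1/dt^2, a long window suppresses noise but clips
peaks.  Peak measurement is therefore noise-adaptive: the photometric
noise level is estimated robustly from second differences of the
trace, each peak is located on the most-smoothed member of a window
ladder, and its height/time are then read from the shortest window
whose predicted derivative noise (filter coefficient norm times the
noise estimate) is below a set fraction of the peak height, refined to
sub-sample precision by a three-point parabolic fit.  On a noiseless
trace this reduces to the shortest window and reproduces the
continuous-domain parameters to a few tenths of a percent.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy.signal import argrelmax, savgol_coeffs, savgol_filter

from .curves import ClottingCurve, WaveformParameters
from .errors import (
    MalformedCurveError,
    NoCoagulationError,
    ValidationError,
)

__all__ = [
    "ExtractionSettings",
    "DerivativeCurves",
    "BiphasicResult",
    "differentiate",
    "extract_parameters",
    "detect_biphasic",
    "extract_curve",
    "extract_batch",
    "scale_batch",
    "apply_display_scale",
    "write_parameters",
]


@dataclass(frozen=True)
class ExtractionSettings:
    """Tunable knobs of the waveform analysis.

    ``smooth_window`` (s) and ``poly_order`` set the base
    Savitzky-Golay derivative estimate; the defaults (0.9 s, order 4)
    keep the sharp acceleration peak of strongly asymmetric curves
    within 1% of its continuous-domain height at a 0.1-s read
    interval.  ``window_ladder`` (s) lists the longer windows the
    noise-adaptive peak measurement may fall back to;
    ``height_noise_fraction`` is the admissible ratio of predicted
    derivative noise to peak height before widening.  ``min_rise``
    (mabs) is the minimum total absorbance rise for a curve to count
    as coagulated.  ``biphasic_slope_threshold`` (mabs/s) flags a
    pre-clot ramp.
    """

    smooth_window: float = 0.9
    poly_order: int = 4
    window_ladder: tuple = (1.5, 2.3, 3.5, 5.1, 7.5)
    height_noise_fraction: float = 0.01
    min_rise: float = 20.0
    biphasic_slope_threshold: float = 0.2
    edge_margin: float = 3.0  # s kept clear of window edges when peak-hunting


@dataclass(frozen=True)
class DerivativeCurves:
    """Smoothed absorbance and its first/second derivatives on the
    curve's time grid, at the base smoothing window (derivative units
    mabs/s and mabs/s^2; display scaling is a property of the
    generator, not of extraction).  ``noise_sd`` is the robust
    estimate of the per-sample photometric noise."""

    time: np.ndarray
    absorbance: np.ndarray        # smoothed, mabs
    first: np.ndarray             # mabs/s
    second: np.ndarray            # mabs/s^2
    raw: np.ndarray               # unsmoothed absorbance, mabs
    noise_sd: float
    settings: ExtractionSettings

    def __post_init__(self):
        n = len(self.time)
        for arr in (self.absorbance, self.first, self.second, self.raw):
            if len(arr) != n:
                raise ValidationError("derivative arrays must align with the time grid")


@dataclass(frozen=True)
class BiphasicResult:
    """Tri-state biphasic verdict plus the measured pre-clot slope."""

    flag: bool | None          # None = undetermined (segment too short)
    pre_clot_slope: float      # mabs/s


def _estimate_noise_sd(y: np.ndarray) -> float:
    """Robust per-sample noise sd from second differences (for i.i.d.
    Gaussian noise, diff^2 has sd sigma*sqrt(6); the median absolute
    value is insensitive to the localized clotting transition)."""
    d2 = np.diff(y, n=2)
    if len(d2) == 0:
        return 0.0
    return 1.4826 * float(np.median(np.abs(d2))) / math.sqrt(6.0)


def _odd_window(seconds: float, dt: float, n: int) -> int:
    w = max(5, int(round(seconds / dt)))
    if w % 2 == 0:
        w += 1
    cap = n - 1 if (n - 1) % 2 else n - 2
    return min(w, cap)


def differentiate(
    curve: ClottingCurve,
    smooth_window: float = ExtractionSettings.smooth_window,
    poly_order: int = ExtractionSettings.poly_order,
    settings: ExtractionSettings | None = None,
) -> DerivativeCurves:
    """Savitzky-Golay smoothed absorbance and derivatives at the base
    window.  Requires at least 25 uniform samples and a smoothing
    window of at least 5 samples."""
    if settings is None:
        settings = ExtractionSettings(
            smooth_window=smooth_window, poly_order=poly_order
        )
    y = curve.absorbance
    n = len(y)
    if n < 25:
        raise ValidationError("need at least 25 samples to differentiate")
    dt = curve.sampling_interval
    win = _odd_window(settings.smooth_window, dt, n)
    if win < 5:
        raise ValidationError("smoothing window shorter than 5 samples")
    order = min(settings.poly_order, win - 1)
    return DerivativeCurves(
        time=curve.time,
        absorbance=savgol_filter(y, win, order),
        first=savgol_filter(y, win, order, deriv=1, delta=dt),
        second=savgol_filter(y, win, order, deriv=2, delta=dt),
        raw=y,
        noise_sd=_estimate_noise_sd(y),
        settings=settings,
    )


class _DerivativeLadder:
    """Savitzky-Golay derivative estimates of one trace at increasing
    smoothing windows, with the predicted noise sd of each estimate."""

    def __init__(self, raw, dt, settings, noise_sd, deriv):
        self.dt = dt
        windows = [settings.smooth_window] + [
            w for w in settings.window_ladder if w > settings.smooth_window
        ]
        self.levels = []
        n = len(raw)
        for w_s in windows:
            win = _odd_window(w_s, dt, n)
            order = min(settings.poly_order, win - 1)
            arr = savgol_filter(raw, win, order, deriv=deriv, delta=dt)
            coeffs = savgol_coeffs(win, order, deriv=deriv, delta=dt, use="dot")
            pred_noise = noise_sd * float(np.linalg.norm(coeffs))
            self.levels.append((win, arr, pred_noise))

    @property
    def smoothest(self) -> np.ndarray:
        return self.levels[-1][1]


def _refine_peak(t, arr, i) -> tuple[float, float]:
    """Three-point parabolic sub-sample refinement of a local maximum."""
    if i <= 0 or i >= len(arr) - 1:
        return float(t[i]), float(arr[i])
    a, b, c = arr[i - 1], arr[i], arr[i + 1]
    den = a - 2.0 * b + c
    if den == 0:
        return float(t[i]), float(b)
    off = float(np.clip(0.5 * (a - c) / den, -1.0, 1.0))
    dt = float(t[1] - t[0])
    return float(t[i] + off * dt), float(b - 0.25 * (a - c) * off)


def _measure_peak(
    t: np.ndarray,
    ladder: _DerivativeLadder,
    valid: np.ndarray,
    noise_fraction: float,
):
    """Locate a peak on the most-smoothed derivative, then measure it
    on the shortest window whose predicted noise is below
    ``noise_fraction`` of the measured height.

    Returns (time, height, array used, window samples used).
    """
    if not valid.any():
        raise MalformedCurveError("no samples in the admissible peak region")
    coarse = np.where(valid, ladder.smoothest, -np.inf)
    i0 = int(np.argmax(coarse))
    result = None
    for win, arr, pred_noise in ladder.levels:
        lo = max(i0 - win, 0)
        hi = min(i0 + win + 1, len(arr))
        local = np.where(valid[lo:hi], arr[lo:hi], -np.inf)
        i = lo + int(np.argmax(local))
        tt, hh = _refine_peak(t, arr, i)
        result = (tt, hh, arr, win)
        if pred_noise <= noise_fraction * abs(hh):
            break
    return result


def _sustained_crossing(t, arr, i_peak, half, direction, hold):
    """First half-height crossing away from the peak that stays below
    half for ``hold`` consecutive samples (hysteresis against noise)."""
    n = len(arr)
    j = i_peak
    while 0 < j < n - 1:
        j += direction
        if arr[j] < half:
            stop = j + direction * hold
            seg = arr[j:stop:direction] if 0 <= stop <= n else arr[j::direction]
            if len(seg) < hold or np.all(seg < half):
                a, b = j - direction, j
                lo, hi = (arr[b], arr[a]) if arr[b] < arr[a] else (arr[a], arr[b])
                tlo, thi = (t[b], t[a]) if arr[b] < arr[a] else (t[a], t[b])
                return float(np.interp(half, [lo, hi], [tlo, thi]))
            j = stop - direction
    return None


def _fwhm(t, arr, t_peak, h_peak, name, window, censored, hold):
    """FWHM by linear interpolation of half-height crossings; a right
    crossing missing inside the window is censored at the window cap."""
    i_peak = int(np.argmin(np.abs(t - t_peak)))
    half = h_peak / 2.0
    left = _sustained_crossing(t, arr, i_peak, half, -1, hold)
    if left is None:
        raise MalformedCurveError(f"no left half-height crossing for {name}")
    right = _sustained_crossing(t, arr, i_peak, half, +1, hold)
    if right is None:
        censored.add(name)
        return window[1] - window[0]
    return right - left


def extract_parameters(
    d: DerivativeCurves, window: tuple[float, float] | None = None
) -> WaveformParameters:
    """Measure the ten waveform parameters from derivative curves.

    Raises :class:`NoCoagulationError` when the total absorbance rise
    is below ``settings.min_rise`` and :class:`MalformedCurveError`
    when a required half-height crossing cannot be found.
    """
    st = d.settings
    t, ys = d.time, d.absorbance
    dt = float(t[1] - t[0])
    if window is None:
        window = (float(t[0]), float(t[-1]))

    tail = max(3, int(round(1.0 / dt)))
    baseline = float(np.median(ys[:tail]))
    plateau = float(np.median(ys[-tail:]))
    rise = plateau - baseline
    if rise < st.min_rise:
        raise NoCoagulationError(
            f"absorbance rise {rise:.1f} mabs below threshold {st.min_rise} mabs"
        )

    ladder1 = _DerivativeLadder(d.raw, dt, st, d.noise_sd, deriv=1)
    ladder2 = _DerivativeLadder(d.raw, dt, st, d.noise_sd, deriv=2)

    margin = (t >= t[0] + st.edge_margin) & (t <= t[-1] - st.edge_margin)
    eta = st.height_noise_fraction

    t_1st, h_1st, arr_1st, win_1st = _measure_peak(t, ladder1, margin, eta)
    t_2nd1, h_2nd1, arr_2nd1, win_2nd1 = _measure_peak(
        t, ladder2, margin & (t < t_1st), eta
    )
    neg = _DerivativeLadderView(ladder2)
    t_2nd2, nh_2nd2, arr_2nd2, win_2nd2 = _measure_peak(
        t, neg, margin & (t > t_1st), eta
    )

    half_level = baseline + rise / 2.0
    above = np.nonzero(ys >= half_level)[0]
    above = above[above > 0]
    if len(above) == 0:
        raise MalformedCurveError("absorbance never reaches half formation")
    j = int(above[0])
    t_halfff = float(np.interp(half_level, [ys[j - 1], ys[j]], [t[j - 1], t[j]]))
    h_halfff = rise / 2.0

    censored: set[str] = set()
    w_1st = _fwhm(t, arr_1st, t_1st, h_1st, "w_1st", window, censored, win_1st)
    w_2nd1 = _fwhm(t, arr_2nd1, t_2nd1, h_2nd1, "w_2nd1", window, censored, win_2nd1)
    w_2nd2 = _fwhm(t, arr_2nd2, t_2nd2, nh_2nd2, "w_2nd2", window, censored, win_2nd2)

    return WaveformParameters(
        t_2nd1=t_2nd1, h_2nd1=h_2nd1, w_2nd1=w_2nd1,
        t_1st=t_1st, h_1st=h_1st, w_1st=w_1st,
        nh_2nd2=nh_2nd2, w_2nd2=w_2nd2,
        t_halfff=t_halfff, h_halfff=h_halfff,
        t_2nd2=t_2nd2, biphasic=None, pre_clot_slope=float("nan"),
        censored_widths=frozenset(censored),
    )


class _DerivativeLadderView:
    """Sign-flipped view of a ladder (for the negative 2ndDP2 lobe)."""

    def __init__(self, ladder: _DerivativeLadder):
        self.levels = [(w, -arr, n) for w, arr, n in ladder.levels]

    @property
    def smoothest(self):
        return self.levels[-1][1]


def detect_biphasic(
    curve: ClottingCurve,
    d: DerivativeCurves,
    params: WaveformParameters,
) -> BiphasicResult:
    """Biphasic-waveform check.

    Positive when the least-squares slope of the raw absorbance over
    the pre-clot segment exceeds the threshold, or when the
    acceleration curve shows two local maxima before the velocity peak
    separated by a trough below half the smaller maximum.  The
    pre-clot segment runs from the window start to whichever comes
    first of t_2nd1 - 2*smooth_window and the onset of measurable
    fibrin formation (1% of the absorbance rise), so that the foot of
    the clotting transition itself is never mistaken for a ramp.
    Undetermined (``flag=None``) when that segment is shorter than the
    smoothing window.
    """
    st = d.settings
    t = d.time
    tail = max(3, int(round(1.0 / float(t[1] - t[0]))))
    baseline = float(np.median(d.absorbance[:tail]))
    plateau = float(np.median(d.absorbance[-tail:]))
    onset_level = baseline + 0.01 * (plateau - baseline)
    risen = np.nonzero(d.absorbance > onset_level)[0]
    t_onset = float(t[risen[0]]) if len(risen) else float(t[-1])
    seg_end = min(params.t_2nd1 - 2.0 * st.smooth_window, t_onset)
    seg = (t >= t[0]) & (t <= seg_end)
    if seg_end - t[0] < st.smooth_window or seg.sum() < 3:
        return BiphasicResult(None, float("nan"))
    slope = float(np.polyfit(t[seg], d.raw[seg], 1)[0])
    if slope > st.biphasic_slope_threshold:
        return BiphasicResult(True, slope)

    # doubled acceleration peak before the velocity peak
    pre = t < params.t_1st
    d2 = d.second[pre]
    if len(d2) >= 5:
        top = d2.max()
        order = max(2, int(round(st.smooth_window / curve.sampling_interval)))
        idx = [i for i in argrelmax(d2, order=order)[0] if d2[i] > 0.05 * top]
        for a, b in zip(idx[:-1], idx[1:]):
            trough = d2[a : b + 1].min()
            if trough < 0.5 * min(d2[a], d2[b]):
                return BiphasicResult(True, slope)
    return BiphasicResult(False, slope)


def extract_curve(
    curve: ClottingCurve, settings: ExtractionSettings | None = None
) -> WaveformParameters:
    """Full per-curve analysis: differentiate, extract, biphasic check."""
    settings = settings or ExtractionSettings()
    d = differentiate(curve, settings=settings)
    params = extract_parameters(d, window=curve.window)
    bip = detect_biphasic(curve, d, params)
    return replace(params, biphasic=bip.flag, pre_clot_slope=bip.pre_clot_slope)


def apply_display_scale(
    params: WaveformParameters, scale_1st: float, scale_2nd: float
) -> WaveformParameters:
    """Convert derivative heights (mabs/s, mabs/s^2) to instrument
    display units using a generator's scale factors.  Times, widths
    and the 1/2FF height are unaffected."""
    return replace(
        params,
        h_1st=params.h_1st * scale_1st,
        h_2nd1=params.h_2nd1 * scale_2nd,
        nh_2nd2=params.nh_2nd2 * scale_2nd,
    )


PARAM_COLUMNS = [
    "sample_id", "t_2nd1_s", "h_2nd1_mabs", "w_2nd1_s", "t_1st_s",
    "h_1st_mabs", "w_1st_s", "nh_2nd2_mabs", "w_2nd2_s", "t_halfff_s",
    "h_halfff_mabs", "biphasic", "censored_widths", "status",
]


def extract_batch(
    curves, settings: ExtractionSettings | None = None
) -> pd.DataFrame:
    """Analyse a batch of curves; per-curve failures become rows with a
    ``status`` reason instead of aborting the batch."""
    curves = list(curves)
    if not curves:
        raise ValidationError("empty batch")
    settings = settings or ExtractionSettings()
    rows = []
    for c in curves:
        try:
            p = extract_curve(c, settings)
            rows.append({"sample_id": c.sample_id, **p.as_dict(), "status": "ok"})
        except NoCoagulationError:
            rows.append({"sample_id": c.sample_id, "status": "no-coagulation"})
        except MalformedCurveError:
            rows.append({"sample_id": c.sample_id, "status": "malformed-curve"})
        except ValidationError:
            rows.append({"sample_id": c.sample_id, "status": "invalid-input"})
    return pd.DataFrame(rows, columns=PARAM_COLUMNS)


def scale_batch(table: pd.DataFrame, presets: dict) -> pd.DataFrame:
    """Convert a batch table's derivative heights to instrument display
    units using each sample's generator preset (keyed by sample_id)."""
    out = table.copy()
    for i, sid in enumerate(out["sample_id"]):
        p = presets.get(sid)
        if p is None or out["status"].iat[i] != "ok":
            continue
        out.loc[out.index[i], "h_1st_mabs"] *= p.scale_1st
        out.loc[out.index[i], "h_2nd1_mabs"] *= p.scale_2nd
        out.loc[out.index[i], "nh_2nd2_mabs"] *= p.scale_2nd
    return out


def write_parameters(table: pd.DataFrame, path) -> None:
    table.to_csv(path, index=False)
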