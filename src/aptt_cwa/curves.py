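"""Parametric APTT clotting-curve model, curve generation and calibration.

The photometric APTT signal is modelled as a generalized (Richards)
sigmoid riding on a baseline, with an optional pre-clot linear ramp that
emulates the biphasic waveform signature seen in DIC:

    y(t) = B + c * min(t, t_b) + A * (1 + nu * exp(-(t - m)/s))**(-1/nu)

``A`` is the total absorbance rise (mabs), ``m`` the time of maximum
coagulation velocity (the sigmoid inflection; for every ``nu`` the first
derivative peaks exactly at ``t = m``), ``s`` the time scale of the
transition and ``nu`` the asymmetry: ``nu = 1`` is the symmetric
logistic, ``nu -> 0`` the Gompertz limit, and ``nu`` in (-0.5, 0)
produces curves with a finite onset lag and a long saturation tail, as
required to place the half-fibrin-formation time well after the
velocity peak.  ``nu <= -0.5`` is excluded: there the acceleration peak
degenerates onto the onset point.

Derivative heights are reported in instrument display units: the
analyzer prints both derivative peaks in "mabs", so free scale factors
``scale_1st`` (mabs per mabs/s) and ``scale_2nd`` (mabs per mabs/s^2)
absorb the unknown internal normalization.

All peak locations and heights have closed forms in this family; peak
widths (FWHM) are obtained by root bracketing on the exact derivative
expressions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields, replace

import numpy as np
import yaml
from scipy.optimize import brentq, least_squares

from .errors import CalibrationError, SchemaError, ValidationError

__all__ = [
    "GeneratorPreset",
    "ClottingCurve",
    "WaveformTargets",
    "WaveformParameters",
    "model_absorbance",
    "generate_curve",
    "analytic_parameters",
    "calibrate_preset",
    "write_curve",
    "read_curve",
    "write_curves",
    "read_curves",
    "write_preset",
    "read_preset",
]

_LN2 = math.log(2.0)
_NU_TINY = 1e-8  # below this |nu| the Gompertz limit is used
_NU_MIN = -0.5


@dataclass(frozen=True)
class GeneratorPreset:
    """Parameters of the generative clotting-curve model for one group.

    Units: mabs for amplitudes, seconds for times, mabs/s for the
    biphasic ramp slope.
    """

    amplitude: float               # A, total absorbance rise (mabs)
    center: float                  # m, velocity-peak time (s)
    slope: float                   # s, transition time scale (s)
    asymmetry: float = 1.0         # nu, dimensionless; 1 = logistic
    baseline: float = 0.0          # B (mabs)
    biphasic_slope: float = 0.0    # c, pre-clot ramp (mabs/s); 0 = none
    biphasic_end: float = 0.0      # t_b (s), ramp stops here
    noise_sd: float = 0.0          # additive Gaussian sd (mabs)
    t_start: float = 0.0           # acquisition window (s)
    t_end: float = 200.0
    sampling_interval: float = 0.1  # dt (s)
    scale_1st: float = 1.0         # k1: display units per mabs/s
    scale_2nd: float = 1.0         # k2: display units per mabs/s^2

    def __post_init__(self):
        if not self.amplitude >= 0:
            raise ValidationError("amplitude must be >= 0")
        if not self.slope > 0:
            raise ValidationError("slope must be > 0")
        if not self.asymmetry > _NU_MIN:
            raise ValidationError(
                f"asymmetry must be > {_NU_MIN} (acceleration peak "
                "degenerates onto the curve onset below that)"
            )
        if not self.noise_sd >= 0:
            raise ValidationError("noise_sd must be >= 0")
        if not self.sampling_interval > 0:
            raise ValidationError("sampling_interval must be > 0")
        if not (self.t_start < self.center < self.t_end):
            raise ValidationError("need t_start < center < t_end")
        if not (self.scale_1st > 0 and self.scale_2nd > 0):
            raise ValidationError("scale factors must be > 0")
        if self.biphasic_slope < 0:
            raise ValidationError("biphasic_slope must be >= 0")

    @property
    def window(self) -> tuple[float, float]:
        return (self.t_start, self.t_end)


@dataclass(frozen=True)
class ClottingCurve:
    """One sampled APTT absorbance trace."""

    time: np.ndarray        # s, uniform, strictly increasing
    absorbance: np.ndarray  # mabs
    sample_id: str = "sample"
    window: tuple[float, float] = (0.0, 200.0)

    def __post_init__(self):
        t = np.asarray(self.time, dtype=float)
        y = np.asarray(self.absorbance, dtype=float)
        if t.ndim != 1 or t.shape != y.shape:
            raise ValidationError("time and absorbance must be 1-D and equal length")
        if len(t) >= 2:
            dt = np.diff(t)
            if dt.min() <= 0:
                raise ValidationError("time must be strictly increasing")
            if not np.allclose(dt, dt[0], rtol=1e-6, atol=1e-9):
                raise ValidationError("time grid must be uniform")
        lo, hi = self.window
        if len(t) and (t[0] < lo - 1e-9 or t[-1] > hi + 1e-9):
            raise ValidationError("samples outside acquisition window")
        object.__setattr__(self, "time", t)
        object.__setattr__(self, "absorbance", y)

    @property
    def sampling_interval(self) -> float:
        return float(self.time[1] - self.time[0])


_TARGET_KEYS = ("t_2nd1", "t_1st", "t_halfff", "h_2nd1", "h_1st", "h_halfff")


@dataclass(frozen=True)
class WaveformTargets:
    """Calibration targets: any subset of the three peak times (s) and
    three peak heights (mabs) from a waveform-parameter table row."""

    t_2nd1: float | None = None
    t_1st: float | None = None
    t_halfff: float | None = None
    h_2nd1: float | None = None
    h_1st: float | None = None
    h_halfff: float | None = None

    def __post_init__(self):
        for k in _TARGET_KEYS:
            v = getattr(self, k)
            if v is not None and not v > 0:
                raise ValidationError(f"target {k} must be positive")
        t2, t1, th = self.t_2nd1, self.t_1st, self.t_halfff
        if t2 is not None and t1 is not None and not t2 < t1:
            raise ValidationError("need t_2nd1 < t_1st")
        if t1 is not None and th is not None and not t1 < th:
            raise ValidationError("need t_1st < t_halfff")

    def provided(self) -> dict[str, float]:
        return {k: getattr(self, k) for k in _TARGET_KEYS if getattr(self, k) is not None}


@dataclass(frozen=True)
class WaveformParameters:
    """The ten waveform parameters plus the deceleration-peak time and
    the biphasic flag for one curve.

    Times in seconds, heights in display mabs.  ``nh_2nd2`` is the
    magnitude of the negative second-derivative peak ("NH").  Widths are
    FWHM; a width equal to the window length with its name listed in
    ``censored_widths`` is right-censored at the acquisition end.
    ``biphasic`` is ``None`` when the pre-clot segment was too short to
    judge.
    """

    t_2nd1: float
    h_2nd1: float
    w_2nd1: float
    t_1st: float
    h_1st: float
    w_1st: float
    nh_2nd2: float
    w_2nd2: float
    t_halfff: float
    h_halfff: float
    t_2nd2: float | None = None
    biphasic: bool | None = False
    pre_clot_slope: float = 0.0
    censored_widths: frozenset[str] = field(default_factory=frozenset)

    def as_dict(self) -> dict:
        return {
            "t_2nd1_s": self.t_2nd1,
            "h_2nd1_mabs": self.h_2nd1,
            "w_2nd1_s": self.w_2nd1,
            "t_1st_s": self.t_1st,
            "h_1st_mabs": self.h_1st,
            "w_1st_s": self.w_1st,
            "nh_2nd2_mabs": self.nh_2nd2,
            "w_2nd2_s": self.w_2nd2,
            "t_halfff_s": self.t_halfff,
            "h_halfff_mabs": self.h_halfff,
            "biphasic": self.biphasic,
            "censored_widths": ";".join(sorted(self.censored_widths)),
        }


# ---------------------------------------------------------------------------
# model evaluation

def _shape(x, nu):
    """(1 + nu*exp(-x))**(-1/nu), Gompertz exp(-exp(-x)) at nu -> 0.

    For nu < 0 the expression is real only where 1 + nu*exp(-x) > 0;
    outside that the sigmoid contributes exactly 0 (pre-onset lag).
    """
    x = np.asarray(x, dtype=float)
    w = np.exp(np.minimum(-x, 700.0))
    if abs(nu) < _NU_TINY:
        return np.exp(-w)
    arg = 1.0 + nu * w
    out = np.zeros_like(w)
    ok = arg > 0.0
    out[ok] = np.exp(-np.log(arg[ok]) / nu)
    if nu > 0:  # arg can only be <= 0 through overflow; treat as 0
        out[~ok] = 0.0
    return out


def model_absorbance(preset: GeneratorPreset, t):
    """Noiseless model absorbance (mabs) at time(s) ``t`` (s).

    Nondecreasing in ``t`` whenever ``biphasic_slope >= 0``.
    """
    t = np.asarray(t, dtype=float)
    x = (t - preset.center) / preset.slope
    y = preset.baseline + preset.amplitude * _shape(x, preset.asymmetry)
    if preset.biphasic_slope > 0:
        y = y + preset.biphasic_slope * np.minimum(t, preset.biphasic_end)
    return y if y.ndim else float(y)


def generate_curve(
    preset: GeneratorPreset, seed: int, sample_id: str | None = None
) -> ClottingCurve:
    """Sample the model over the acquisition window with seeded additive
    Gaussian noise of sd ``preset.noise_sd``.

    Deterministic given ``(preset, seed)``; ``noise_sd = 0`` reproduces
    the model exactly.
    """
    dt = preset.sampling_interval
    n = int(math.floor((preset.t_end - preset.t_start) / dt + 0.5)) + 1
    t = preset.t_start + dt * np.arange(n)
    y = model_absorbance(preset, t)
    if preset.noise_sd > 0:
        rng = np.random.default_rng(seed)
        y = y + rng.normal(0.0, preset.noise_sd, size=n)
    return ClottingCurve(
        time=t,
        absorbance=y,
        sample_id=sample_id if sample_id is not None else f"sample-{seed}",
        window=preset.window,
    )


# ---------------------------------------------------------------------------
# closed-form waveform parameters

def _phi1(nu: float) -> float:
    """Unscaled first-derivative peak value factor (1+nu)**(-(1+nu)/nu)."""
    if abs(nu) < _NU_TINY:
        return math.exp(-1.0)
    return math.exp(-(1.0 + nu) / nu * math.log1p(nu))


def _x_half(nu: float) -> float:
    """x at which the sigmoid reaches half its amplitude."""
    if abs(nu) < _NU_TINY:
        return -math.log(_LN2)
    return -math.log(math.expm1(nu * _LN2) / nu)


def _w_accel(nu: float) -> tuple[float, float]:
    """Roots w+- of w^2 - (3+nu) w + 1 = 0: locations (in w = e^{-x})
    of the positive (w+ > 1) and negative (w- < 1) acceleration peaks."""
    b = 3.0 + nu
    d = math.sqrt(b * b - 4.0)
    return (b + d) / 2.0, (b - d) / 2.0


def _d1_unscaled(w, nu):
    """First derivative of the unit sigmoid wrt x, as a function of w."""
    w = np.asarray(w, dtype=float)
    if abs(nu) < _NU_TINY:
        return w * np.exp(-w)
    return w * np.exp((-1.0 / nu - 1.0) * np.log1p(nu * w))


def _d2_unscaled(w, nu):
    """Second derivative of the unit sigmoid wrt x, as a function of w.

    Positive for w > 1 (acceleration), negative for w < 1.
    """
    w = np.asarray(w, dtype=float)
    if abs(nu) < _NU_TINY:
        return w * (w - 1.0) * np.exp(-w)
    return w * (w - 1.0) * np.exp((-1.0 / nu - 2.0) * np.log1p(nu * w))


def _w_domain_max(nu: float) -> float:
    """Supremum of valid w: 1/|nu| for nu < 0, else unbounded."""
    return (1.0 / -nu) * (1.0 - 1e-12) if nu < 0 else math.inf


def _fwhm_crossings(f, w_peak: float, nu: float) -> tuple[float, float]:
    """Half-maximum crossings of ``f`` (a function of w) around its peak
    at ``w_peak``.  Returns (w_left, w_right) with w_left < w_peak <
    w_right; w maps to time as t = m - s*ln(w), so w_right is the
    *early*-time crossing.
    """
    half = f(w_peak) / 2.0
    g = lambda w: f(w) - half

    lo = w_peak
    while f(lo / 2.0) > half:
        lo /= 2.0
        if lo < 1e-300:
            raise CalibrationError("no lower half crossing")  # pragma: no cover
    w_left = brentq(g, lo / 2.0, w_peak, xtol=1e-12, rtol=1e-14)

    wmax = _w_domain_max(nu)
    if math.isinf(wmax):
        hi = w_peak * 2.0
        while f(hi) > half:
            hi *= 2.0
    else:
        hi = wmax
    w_right = brentq(g, w_peak, hi, xtol=1e-12, rtol=1e-14)
    return w_left, w_right


def _peak_params(preset: GeneratorPreset) -> dict[str, float]:
    """Closed-form peak times/heights (no widths) for c = 0."""
    A, m, s, nu = preset.amplitude, preset.center, preset.slope, preset.asymmetry
    k1, k2 = preset.scale_1st, preset.scale_2nd
    wp, wm = _w_accel(nu)
    return {
        "t_1st": m,
        "h_1st": k1 * (A / s) * _phi1(nu),
        "t_2nd1": m - s * math.log(wp),
        "h_2nd1": k2 * (A / s**2) * float(_d2_unscaled(wp, nu)),
        "t_2nd2": m - s * math.log(wm),
        "nh_2nd2": k2 * (A / s**2) * float(-_d2_unscaled(wm, nu)),
        "t_halfff": m + s * _x_half(nu),
        "h_halfff": A / 2.0,
    }


def analytic_parameters(preset: GeneratorPreset) -> WaveformParameters:
    """Exact continuous-domain waveform parameters of a pure-sigmoid
    preset (``biphasic_slope`` must be 0; ``noise_sd`` is ignored).

    Serves as the oracle for sampled-curve extraction.  Widths are FWHM
    of the exact derivative curves, right-censored at the window end.
    """
    if preset.biphasic_slope != 0:
        raise ValidationError("analytic parameters are defined for biphasic_slope == 0")
    A, m, s, nu = preset.amplitude, preset.center, preset.slope, preset.asymmetry
    if A <= 0:
        raise ValidationError("analytic parameters undefined for zero amplitude")
    p = _peak_params(preset)
    censored = set()

    def width(f, w_peak, name):
        w_left, w_right = _fwhm_crossings(f, w_peak, nu)
        t_late = m - s * math.log(w_left)   # small w = late time
        t_early = m - s * math.log(w_right)
        if t_late > preset.t_end:
            censored.add(name)
            return preset.t_end - preset.t_start
        return t_late - t_early

    wp, wm = _w_accel(nu)
    w_1st = width(lambda w: _d1_unscaled(w, nu), 1.0, "w_1st")
    w_2nd1 = width(lambda w: _d2_unscaled(w, nu), wp, "w_2nd1")
    w_2nd2 = width(lambda w: -_d2_unscaled(w, nu), wm, "w_2nd2")

    return WaveformParameters(
        t_2nd1=p["t_2nd1"], h_2nd1=p["h_2nd1"], w_2nd1=w_2nd1,
        t_1st=p["t_1st"], h_1st=p["h_1st"], w_1st=w_1st,
        nh_2nd2=p["nh_2nd2"], w_2nd2=w_2nd2,
        t_halfff=p["t_halfff"], h_halfff=p["h_halfff"],
        t_2nd2=p["t_2nd2"], biphasic=False, pre_clot_slope=0.0,
        censored_widths=frozenset(censored),
    )


# ---------------------------------------------------------------------------
# calibration

_NU_OFFSET = 0.5  # nu = exp(theta) - 0.5 maps R -> (-0.5, inf)


def calibrate_preset(
    targets: WaveformTargets,
    fixed: GeneratorPreset | None = None,
    tol: float = 0.01,
) -> GeneratorPreset:
    """Fit a preset whose analytic peak parameters match ``targets``.

    The amplitude is tied to the half-fibrin-formation height
    (``A = 2*h_halfff``) when that target is given, otherwise taken from
    ``fixed``.  Free parameters are the velocity-peak time ``m``, the
    time scale ``s``, the asymmetry ``nu`` and the display scale factors
    ``k1``/``k2`` (each scale only when its height target is present; the
    asymmetry only when all three times are present, ``s`` only when at
    least two times are present).  Deterministic least squares on
    transformed parameters from the documented start
    ``m = t_1st, s = (t_1st - t_2nd1)/ln(2+sqrt(3)), nu = 1, k1 = k2 = 1``.

    Raises :class:`CalibrationError` with diagnostics when any relative
    residual exceeds ``tol`` (default 1%).
    """
    want = targets.provided()
    if not want:
        raise CalibrationError("no targets provided")
    base = fixed if fixed is not None else GeneratorPreset(
        amplitude=1.0, center=50.0, slope=5.0
    )

    if targets.h_halfff is not None:
        A = 2.0 * targets.h_halfff
    else:
        A = base.amplitude
    if A <= 0:
        raise CalibrationError("amplitude is zero and no h_halfff target given")

    times = [k for k in ("t_2nd1", "t_1st", "t_halfff") if want.get(k) is not None]
    m0 = want.get("t_1st", base.center if fixed is not None else np.mean(
        [want[k] for k in times]) if times else base.center)
    if "t_1st" in want and "t_2nd1" in want:
        s0 = (want["t_1st"] - want["t_2nd1"]) / math.log(2.0 + math.sqrt(3.0))
    else:
        s0 = base.slope
    nu0 = base.asymmetry if fixed is not None else 1.0

    fit_m = bool(times)
    fit_s = len(times) >= 2
    fit_nu = len(times) >= 3
    fit_k1 = "h_1st" in want
    fit_k2 = "h_2nd1" in want

    names, z0 = [], []
    if fit_m:
        names.append("m"); z0.append(m0)
    if fit_s:
        names.append("log_s"); z0.append(math.log(s0))
    if fit_nu:
        names.append("theta"); z0.append(math.log(nu0 + _NU_OFFSET))
    if fit_k1:
        names.append("log_k1"); z0.append(0.0)
    if fit_k2:
        names.append("log_k2"); z0.append(0.0)

    order = sorted(want)

    def build(z) -> GeneratorPreset:
        zz = dict(zip(names, z))
        return replace(
            base,
            amplitude=A,
            center=zz.get("m", m0),
            slope=math.exp(zz["log_s"]) if "log_s" in zz else s0,
            asymmetry=(math.exp(zz["theta"]) - _NU_OFFSET) if "theta" in zz else nu0,
            scale_1st=math.exp(zz.get("log_k1", 0.0)) if fit_k1 else base.scale_1st,
            scale_2nd=math.exp(zz.get("log_k2", 0.0)) if fit_k2 else base.scale_2nd,
            biphasic_slope=0.0,
            noise_sd=base.noise_sd,
        )

    def resid(z):
        try:
            p = _peak_params(build(z))
        except ValidationError:
            return np.full(len(order), 1e6)
        return np.array([(p[k] - want[k]) / want[k] for k in order])

    if names:
        sol = least_squares(resid, np.asarray(z0), method="lm", xtol=1e-15, ftol=1e-15)
        z = sol.x
    else:
        z = np.asarray(z0)
    preset = build(z)
    r = resid(z)
    if not np.all(np.abs(r) <= tol):
        achieved = _peak_params(preset)
        raise CalibrationError(
            "calibration did not reach tolerance",
            diagnostics={
                "targets": want,
                "achieved": {k: achieved[k] for k in order},
                "relative_residuals": dict(zip(order, r.tolist())),
                "tol": tol,
            },
        )
    return preset


# ---------------------------------------------------------------------------
# CSV / YAML I/O

def write_curve(curve: ClottingCurve, path) -> None:
    """Two-column CSV with header ``time_s,absorbance_mabs``."""
    import pandas as pd

    pd.DataFrame(
        {"time_s": curve.time, "absorbance_mabs": curve.absorbance}
    ).to_csv(path, index=False)


def read_curve(path, sample_id: str | None = None) -> ClottingCurve:
    import pandas as pd

    df = pd.read_csv(path)
    for col in ("time_s", "absorbance_mabs"):
        if col not in df.columns:
            raise SchemaError(f"curve file missing column {col!r}")
    t = df["time_s"].to_numpy(dtype=float)
    return ClottingCurve(
        time=t,
        absorbance=df["absorbance_mabs"].to_numpy(dtype=float),
        sample_id=sample_id or str(path),
        window=(float(t[0]), float(t[-1])),
    )


def write_curves(curves, path) -> None:
    """Long-format CSV: ``sample_id,time_s,absorbance_mabs``."""
    import pandas as pd

    frames = [
        pd.DataFrame(
            {
                "sample_id": c.sample_id,
                "time_s": c.time,
                "absorbance_mabs": c.absorbance,
            }
        )
        for c in curves
    ]
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def read_curves(path) -> list[ClottingCurve]:
    import pandas as pd

    df = pd.read_csv(path)
    for col in ("sample_id", "time_s", "absorbance_mabs"):
        if col not in df.columns:
            raise SchemaError(f"curve file missing column {col!r}")
    out = []
    for sid, g in df.groupby("sample_id", sort=False):
        t = g["time_s"].to_numpy(dtype=float)
        out.append(
            ClottingCurve(
                time=t,
                absorbance=g["absorbance_mabs"].to_numpy(dtype=float),
                sample_id=str(sid),
                window=(float(t[0]), float(t[-1])),
            )
        )
    return out


def write_preset(preset: GeneratorPreset, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump({f.name: getattr(preset, f.name) for f in fields(preset)}, fh)


def read_preset(path) -> GeneratorPreset:
    with open(path) as fh:
        data = yaml.safe_load(fh)
    known = {f.name for f in fields(GeneratorPreset)}
    unknown = set(data) - known
    if unknown:
        raise SchemaError(f"unknown preset keys: {sorted(unknown)}")
    return GeneratorPreset(**data)
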