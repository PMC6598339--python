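"""Built-in group presets calibrated to published waveform medians.

Each of the five subject groups (healthy volunteers, patients without
DIC, pre-DIC, DIC without and DIC with hypofibrinogenemia) gets a
generator preset whose analytic peak times and heights reproduce the
published group medians: the positive acceleration-peak time/height
(2ndDP1), the velocity-peak time/height (1stDP) and the
half-fibrin-formation time/height (1/2FF).  Peak widths are emergent,
not calibration targets: with the amplitude tied to the 1/2FF height
the model has exactly as many free parameters as the six targets.

Calibration runs on first use and is cached; presets are never stored
as fitted numbers.
"""

from __future__ import annotations

from dataclasses import replace
from functools import lru_cache

from .curves import GeneratorPreset, WaveformTargets, calibrate_preset

__all__ = ["PRESET_NAMES", "PUBLISHED_WAVEFORM_MEDIANS", "builtin_preset", "builtin_targets"]

#: Published group medians: (t_2nd1, h_2nd1, t_1st, h_1st, t_halfff, h_halfff)
#: times in seconds, heights in display mabs.
PUBLISHED_WAVEFORM_MEDIANS: dict[str, dict[str, float]] = {
    "hv": dict(t_2nd1=35.5, h_2nd1=457.0, t_1st=38.7, h_1st=183.0,
               t_halfff=40.9, h_halfff=242.0),
    "non_dic": dict(t_2nd1=43.9, h_2nd1=648.0, t_1st=50.2, h_1st=389.0,
                    t_halfff=52.5, h_halfff=462.0),
    "pre_dic": dict(t_2nd1=54.6, h_2nd1=460.0, t_1st=60.5, h_1st=251.0,
                    t_halfff=61.6, h_halfff=328.0),
    "dic_no_hf": dict(t_2nd1=58.8, h_2nd1=286.0, t_1st=64.9, h_1st=200.0,
                      t_halfff=69.1, h_halfff=319.0),
    "dic_hf": dict(t_2nd1=72.5, h_2nd1=107.0, t_1st=78.6, h_1st=61.2,
                   t_halfff=80.9, h_halfff=195.0),
}

PRESET_NAMES = tuple(PUBLISHED_WAVEFORM_MEDIANS)

#: Default photometric noise sd (mabs) for generated group curves: an
#: optical coagulometer's processed absorbance channel is clean relative
#: to its few-hundred-mabs clotting signal.
DEFAULT_NOISE_SD = 0.5


def builtin_targets(name: str) -> WaveformTargets:
    """Calibration targets for a built-in group preset."""
    try:
        return WaveformTargets(**PUBLISHED_WAVEFORM_MEDIANS[name])
    except KeyError:
        raise KeyError(
            f"unknown preset {name!r}; available: {', '.join(PRESET_NAMES)}"
        ) from None


@lru_cache(maxsize=None)
def _calibrated(name: str) -> GeneratorPreset:
    return calibrate_preset(builtin_targets(name))


def builtin_preset(name: str, noise_sd: float = DEFAULT_NOISE_SD) -> GeneratorPreset:
    """Group preset calibrated to the published medians.

    ``noise_sd`` sets the additive noise used when generating curves
    from the preset (0 for noiseless round-trip experiments).
    """
    return replace(_calibrated(name), noise_sd=noise_sd)
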