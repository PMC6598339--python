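"""JMHLW DIC score, enrollment screen and classification.

The Japanese Ministry of Health, Labor and Welfare diagnostic score
sums banded points for platelet count, FDP, fibrinogen and PT ratio
with one point each for an underlying disease, bleeding and organ
failure.  A total below 6 is non-DIC, exactly 6 is pre-DIC and 7 or
more is DIC.  Hypofibrinogenemia (bleeding-type DIC marker) is
fibrinogen below 2 g/L (200 mg/dl).

The band table ships as an editable config object because criterion
variants exist; the hematologic-disorder variant (platelet and
bleeding items excluded, lower classification cuts) is available
behind a switch but off by default.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass

import pandas as pd
import yaml

from .errors import IncompleteRecordError, ValidationError

__all__ = [
    "ScoreBands",
    "screen_eligibility",
    "jmhlw_score",
    "classify",
    "hypofibrinogenemia_split",
    "score_cohort",
    "write_bands",
    "read_bands",
]

DIC_CLASSES = ("non_dic", "pre_dic", "dic")


@dataclass(frozen=True)
class ScoreBands:
    """Band tables and cuts of the JMHLW criteria.

    Bands are (cut, points) pairs evaluated from the worst band down;
    platelet/fibrinogen use ``value <= cut``, FDP/PT ratio use
    ``value >= cut``.  Screening cuts use the strict inequalities of
    the enrollment definition.
    """

    platelet_bands: tuple = ((5.0, 3), (8.0, 2), (12.0, 1))     # 1e4/ul, <=
    fdp_bands: tuple = ((40.0, 3), (20.0, 2), (10.0, 1))        # ug/ml, >=
    fibrinogen_bands: tuple = ((100.0, 2), (150.0, 1))          # mg/dl, <=
    pt_ratio_bands: tuple = ((1.67, 2), (1.25, 1))              # >=
    disease_points: int = 1
    bleeding_points: int = 1
    organ_failure_points: int = 1
    pre_dic_cut: int = 6     # score == cut -> pre-DIC
    dic_cut: int = 7         # score >= cut -> DIC
    hypofibrinogenemia_cut: float = 200.0   # mg/dl, strict <
    screen_platelet_below: float = 12.0     # 1e4/ul
    screen_fdp_above: float = 10.0          # ug/ml
    screen_pt_ratio_above: float = 1.27
    screen_fibrinogen_below: float = 150.0  # mg/dl
    hematologic_variant: bool = False
    hematologic_pre_dic_cut: int = 3
    hematologic_dic_cut: int = 4

    def __post_init__(self):
        if not self.pre_dic_cut < self.dic_cut:
            raise ValidationError("classification cuts must be ordered")
        for bands in (self.platelet_bands, self.fdp_bands,
                      self.fibrinogen_bands, self.pt_ratio_bands):
            if any(p < 0 for _, p in bands):
                raise ValidationError("band points must be nonnegative")


def _require(name: str, value) -> float:
    if value is None or (isinstance(value, float) and value != value):
        raise IncompleteRecordError(f"missing lab value {name!r}")
    return float(value)


def screen_eligibility(
    platelet: float,
    fdp: float,
    pt_ratio: float,
    fibrinogen: float,
    bands: ScoreBands | None = None,
) -> bool:
    """Enrollment screen: eligible if ANY hemostatic abnormality is
    present (platelet < 12e4/ul, FDP > 10 ug/ml, PT ratio > 1.27 or
    fibrinogen < 150 mg/dl)."""
    b = bands or ScoreBands()
    platelet = _require("platelet", platelet)
    fdp = _require("fdp", fdp)
    pt_ratio = _require("pt_ratio", pt_ratio)
    fibrinogen = _require("fibrinogen", fibrinogen)
    return (
        platelet < b.screen_platelet_below
        or fdp > b.screen_fdp_above
        or pt_ratio > b.screen_pt_ratio_above
        or fibrinogen < b.screen_fibrinogen_below
    )


def _band_points(value, bands, lower_is_worse):
    for cut, pts in bands:
        if (value <= cut) if lower_is_worse else (value >= cut):
            return pts
    return 0


def jmhlw_score(
    platelet: float,
    fdp: float,
    fibrinogen: float,
    pt_ratio: float,
    underlying_disease: bool = False,
    bleeding: bool = False,
    organ_failure: bool = False,
    bands: ScoreBands | None = None,
) -> int:
    """Total JMHLW DIC score (points).

    Monotone: worsening any lab (lower platelets/fibrinogen, higher
    FDP/PT ratio) never decreases the score.
    """
    b = bands or ScoreBands()
    platelet = _require("platelet", platelet)
    fdp = _require("fdp", fdp)
    fibrinogen = _require("fibrinogen", fibrinogen)
    pt_ratio = _require("pt_ratio", pt_ratio)
    for name, v in (("platelet", platelet), ("fdp", fdp),
                    ("fibrinogen", fibrinogen), ("pt_ratio", pt_ratio)):
        if v <= 0:
            raise ValidationError(f"{name} must be positive, got {v}")
    score = (
        _band_points(fdp, b.fdp_bands, lower_is_worse=False)
        + _band_points(fibrinogen, b.fibrinogen_bands, lower_is_worse=True)
        + _band_points(pt_ratio, b.pt_ratio_bands, lower_is_worse=False)
        + (b.disease_points if underlying_disease else 0)
        + (b.organ_failure_points if organ_failure else 0)
    )
    if not b.hematologic_variant:
        score += _band_points(platelet, b.platelet_bands, lower_is_worse=True)
        score += b.bleeding_points if bleeding else 0
    return score


def classify(score: int, bands: ScoreBands | None = None) -> str:
    """Map a score to ``non_dic`` / ``pre_dic`` / ``dic``."""
    b = bands or ScoreBands()
    if score < 0 or int(score) != score:
        raise ValidationError("score must be a nonnegative integer")
    pre = b.hematologic_pre_dic_cut if b.hematologic_variant else b.pre_dic_cut
    dic = b.hematologic_dic_cut if b.hematologic_variant else b.dic_cut
    if score >= dic:
        return "dic"
    if score >= pre:
        return "pre_dic"
    return "non_dic"


def hypofibrinogenemia_split(fibrinogen: float, bands: ScoreBands | None = None) -> bool:
    """True iff fibrinogen < 200 mg/dl (2 g/L); the boundary itself is
    no-hypofibrinogenemia."""
    b = bands or ScoreBands()
    fibrinogen = _require("fibrinogen", fibrinogen)
    if fibrinogen <= 0:
        raise ValidationError("fibrinogen must be positive")
    return fibrinogen < b.hypofibrinogenemia_cut


_COHORT_LAB_COLS = {
    "platelet_1e4_ul", "fdp_ug_ml", "fibrinogen_mg_dl", "pt_ratio",
    "disease", "bleeding", "organ_failure",
}


def score_cohort(patients: pd.DataFrame, bands: ScoreBands | None = None) -> pd.DataFrame:
    """Append ``score``, ``dic_class`` and ``hypofibrinogenemia``
    columns to a cohort table (healthy volunteers carry no underlying
    disease and score through the same bands)."""
    missing = _COHORT_LAB_COLS - set(patients.columns)
    if missing:
        raise IncompleteRecordError(f"cohort table missing columns {sorted(missing)}")
    b = bands or ScoreBands()
    out = patients.copy()
    scores, classes, hypo = [], [], []
    for rec in patients.itertuples(index=False):
        s = jmhlw_score(
            platelet=rec.platelet_1e4_ul,
            fdp=rec.fdp_ug_ml,
            fibrinogen=rec.fibrinogen_mg_dl,
            pt_ratio=rec.pt_ratio,
            underlying_disease=rec.disease not in ("none", "", None),
            bleeding=bool(rec.bleeding),
            organ_failure=bool(rec.organ_failure),
            bands=b,
        )
        scores.append(s)
        classes.append(classify(s, b))
        hypo.append(hypofibrinogenemia_split(rec.fibrinogen_mg_dl, b))
    out["score"] = scores
    out["dic_class"] = classes
    out["hypofibrinogenemia"] = hypo
    return out


def write_bands(bands: ScoreBands, path) -> None:
    data = asdict(bands)
    for key in ("platelet_bands", "fdp_bands", "fibrinogen_bands", "pt_ratio_bands"):
        data[key] = [list(b) for b in data[key]]
    with open(path, "w") as fh:
        yaml.safe_dump(data, fh)


def read_bands(path) -> ScoreBands:
    with open(path) as fh:
        data = yaml.safe_load(fh)
    for key in ("platelet_bands", "fdp_bands", "fibrinogen_bands", "pt_ratio_bands"):
        if key in data:
            data[key] = tuple(tuple(b) for b in data[key])
    return ScoreBands(**data)
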