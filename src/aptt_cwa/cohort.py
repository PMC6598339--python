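"""Seeded synthetic patient cohorts with the published study structure.

The generator reproduces, exactly, the printed composition of the
suspected-DIC cohort: 121 non-DIC, 25 pre-DIC, 35 DIC without and 30
DIC with hypofibrinogenemia (211 patients) plus 30 healthy volunteers;
the underlying-disease count table with its infectious fractions in the
two DIC subgroups (28/35 and 13/30); a 55/156 non-survivor/survivor
split and a 56/155 hemoglobin <8 / >=8 g/dl split.  Lab values are
drawn from log-normal distributions fitted by method of quantiles to
the published group medians and 25th-75th percentiles.

Each patient receives a waveform preset: the group preset with seeded
multiplicative jitter on amplitude, center and time scale.  Outcome and
low hemoglobin are preferentially assigned to patients with low
velocity-peak heights through rank-based weighted sampling, so that
outcome- and Hb-stratified contrasts reproduce the published direction;
the joint structure is a modelling convention, not a published fact.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.stats import norm

from .curves import GeneratorPreset
from .errors import SchemaError, ValidationError
from .presets import builtin_preset

__all__ = [
    "LabDistribution",
    "CohortSpec",
    "Cohort",
    "sample_lab",
    "generate_cohort",
    "write_cohort",
    "read_cohort",
    "PATIENT_GROUPS",
    "ALL_GROUPS",
]

PATIENT_GROUPS = ("non_dic", "pre_dic", "dic_no_hf", "dic_hf")
ALL_GROUPS = PATIENT_GROUPS + ("hv",)

_Z75 = float(norm.ppf(0.75))  # 0.6745


@dataclass(frozen=True)
class LabDistribution:
    """Median and 25th/75th percentiles of a positive lab quantity."""

    median: float
    q25: float
    q75: float

    def __post_init__(self):
        if not (0 < self.q25 <= self.median <= self.q75):
            raise ValidationError(
                f"quartiles must be positive and ordered, got "
                f"{self.q25}/{self.median}/{self.q75}"
            )

    @property
    def log_sd(self) -> float:
        return math.log(self.q75 / self.q25) / (2.0 * _Z75)


def sample_lab(dist: LabDistribution, n: int, seed) -> np.ndarray:
    """Draw ``n`` values from the log-normal fitted by method of
    quantiles: log-median = ln(median), log-sd = ln(q75/q25)/(2*z_0.75).

    ``seed`` may be an int or a numpy Generator.  Zero spread
    (q25 = median = q75) returns the median exactly.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    sd = dist.log_sd
    if sd == 0.0:
        return np.full(n, dist.median, dtype=float)
    return np.exp(rng.normal(math.log(dist.median), sd, size=n))


# Published group lab tables (median, q25, q75).
_LABS = {
    "non_dic": dict(
        platelet=LabDistribution(15.8, 9.7, 26.7),
        pt_ratio=LabDistribution(1.1, 1.0, 1.2),
        fdp=LabDistribution(13.6, 7.5, 29.5),
        fibrinogen=LabDistribution(443, 320, 598),
        age=LabDistribution(61, 37, 75),
    ),
    "pre_dic": dict(
        platelet=LabDistribution(7.5, 5.0, 11.4),
        pt_ratio=LabDistribution(1.3, 1.1, 1.5),
        fdp=LabDistribution(28.4, 15.0, 40.7),
        fibrinogen=LabDistribution(365, 293, 449),
        age=LabDistribution(71, 67, 80),
    ),
    "dic_no_hf": dict(
        platelet=LabDistribution(4.8, 3.3, 6.7),
        pt_ratio=LabDistribution(1.3, 1.1, 1.5),
        fdp=LabDistribution(44.4, 23.2, 71.8),
        fibrinogen=LabDistribution(345, 219, 404),
        age=LabDistribution(71, 58, 76),
    ),
    "dic_hf": dict(
        platelet=LabDistribution(4.4, 2.7, 5.9),
        pt_ratio=LabDistribution(1.4, 1.3, 1.7),
        fdp=LabDistribution(29.9, 13.8, 57.8),
        fibrinogen=LabDistribution(143, 103, 169),
        age=LabDistribution(63, 54, 70),
    ),
    # Healthy volunteers: no lab table was published beyond age; normal
    # adult reference values, modest spread (modelling convention).
    "hv": dict(
        platelet=LabDistribution(25.0, 21.0, 29.0),
        pt_ratio=LabDistribution(1.0, 0.95, 1.05),
        fdp=LabDistribution(2.0, 1.5, 3.0),
        fibrinogen=LabDistribution(280, 240, 320),
        age=LabDistribution(21, 20, 24),
    ),
}

# Published female:male counts per group.
_SEX_COUNTS = {
    "non_dic": (60, 61),
    "pre_dic": (8, 17),
    "dic_no_hf": (13, 22),
    "dic_hf": (13, 17),
    "hv": (10, 20),
}

# Published underlying-disease counts over the 211 patients.
_DISEASES = {
    "sepsis": 58,
    "pneumonia": 43,
    "other_infection": 9,
    "trauma": 41,
    "aneurysm": 15,
    "hemangioma_liver_transplant": 13,
    "hematopoietic_malignancy": 10,
    "cardiopulmonary_arrest": 10,
    "gynecological": 5,
    "autoimmune": 4,
    "solid_cancer": 3,
}
_INFECTIOUS = ("sepsis", "pneumonia", "other_infection")

# Hemoglobin strata (g/dl): no per-stratum distribution was published;
# anemic and non-anemic reference shapes (modelling convention).
_HB_LOW = LabDistribution(6.9, 6.2, 7.5)
_HB_HIGH = LabDistribution(10.5, 9.2, 12.0)
_HB_HV = LabDistribution(13.5, 12.5, 14.5)


@dataclass(frozen=True)
class CohortSpec:
    """Structure of the synthetic cohort; defaults are the published
    study composition."""

    group_sizes: dict = field(default_factory=lambda: {
        "non_dic": 121, "pre_dic": 25, "dic_no_hf": 35, "dic_hf": 30, "hv": 30,
    })
    labs: dict = field(default_factory=lambda: _LABS)
    disease_counts: dict = field(default_factory=lambda: dict(_DISEASES))
    infectious_quota: dict = field(default_factory=lambda: {
        "dic_no_hf": 28, "dic_hf": 13,
    })
    n_non_survivors: int = 55
    n_hb_low: int = 56
    hb_cut: float = 8.0                # g/dl
    jitter_sd: float = 0.2             # fractional (log-scale) sd on A, m, s
    coupling_strength: float = 3.0     # rank-weight exponent for outcome/Hb
    bleeding_prob_dic_hf: float = 0.7
    organ_failure_prob_infectious_dic: float = 0.7
    seed: int = 0

    def __post_init__(self):
        if any(n < 0 for n in self.group_sizes.values()):
            raise ValidationError("group sizes must be nonnegative")
        n_pat = sum(self.group_sizes.get(g, 0) for g in PATIENT_GROUPS)
        if self.disease_counts and sum(self.disease_counts.values()) != n_pat:
            raise ValidationError(
                "disease counts must sum to the number of patients"
            )
        n_inf = sum(self.disease_counts.get(d, 0) for d in _INFECTIOUS)
        quota = sum(self.infectious_quota.values())
        if quota > n_inf:
            raise ValidationError("infectious quota exceeds infectious diseases")
        for g, q in self.infectious_quota.items():
            if q > self.group_sizes.get(g, 0):
                raise ValidationError(f"infectious quota for {g} exceeds group size")
        if self.n_non_survivors > n_pat or self.n_hb_low > n_pat:
            raise ValidationError("outcome/Hb stratum larger than cohort")

    @property
    def n_patients(self) -> int:
        return sum(self.group_sizes.get(g, 0) for g in PATIENT_GROUPS)


@dataclass(frozen=True)
class Cohort:
    patients: pd.DataFrame
    presets: dict  # preset_id -> GeneratorPreset


def _largest_remainder(total: int, weights: list[float]) -> list[int]:
    """Deterministic apportionment of ``total`` by ``weights``."""
    if total == 0 or not weights:
        return [0] * len(weights)
    wsum = sum(weights)
    raw = [total * w / wsum for w in weights]
    base = [int(math.floor(r)) for r in raw]
    short = total - sum(base)
    order = sorted(range(len(raw)), key=lambda i: (raw[i] - base[i], -i), reverse=True)
    for i in order[:short]:
        base[i] += 1
    return base


def _allocate_diseases(spec: CohortSpec, rng) -> dict[str, list[str]]:
    """Assign disease labels to groups: infectious quotas exactly, the
    rest by largest-remainder apportionment; label order within each
    group is seeded-shuffled."""
    sizes = spec.group_sizes
    inf_pool = {d: spec.disease_counts.get(d, 0) for d in _INFECTIOUS}
    noninf_pool = {
        d: n for d, n in spec.disease_counts.items() if d not in _INFECTIOUS
    }
    inf_need = {g: spec.infectious_quota.get(g, 0) for g in PATIENT_GROUPS}
    n_inf_left = sum(inf_pool.values()) - sum(inf_need.values())
    free_groups = [g for g in PATIENT_GROUPS if g not in spec.infectious_quota]
    extra = _largest_remainder(n_inf_left, [sizes.get(g, 0) for g in free_groups])
    for g, e in zip(free_groups, extra):
        inf_need[g] += e

    labels: dict[str, list[str]] = {g: [] for g in PATIENT_GROUPS}

    def draw(pool: dict, group: str, count: int):
        names = [d for d in pool if pool[d] > 0]
        take = _largest_remainder(count, [pool[d] for d in names])
        # largest-remainder can over-assign vs pool; cap and fill greedily
        for d, k in zip(names, take):
            k = min(k, pool[d])
            labels[group].extend([d] * k)
            pool[d] -= k
        while len(labels[group]) < sum_len:
            for d in names:
                if pool[d] > 0 and len(labels[group]) < sum_len:
                    labels[group].append(d)
                    pool[d] -= 1

    for g in PATIENT_GROUPS:
        sum_len = inf_need[g]
        draw(inf_pool, g, inf_need[g])
    for g in PATIENT_GROUPS:
        noninf = sizes.get(g, 0) - inf_need[g]
        sum_len = sizes.get(g, 0)
        draw(noninf_pool, g, noninf)
    for g in PATIENT_GROUPS:
        if len(labels[g]) != sizes.get(g, 0):
            raise ValidationError("disease allocation infeasible for the given counts")
        rng.shuffle(labels[g])
    return labels


def _weighted_sample_without_replacement(rng, weights: np.ndarray, k: int) -> np.ndarray:
    """Efraimidis-Spirakis reservoir keys: indices of the k largest
    u^(1/w)."""
    u = rng.random(len(weights))
    keys = np.log(u) / weights
    return np.argsort(keys)[::-1][:k]


def generate_cohort(spec: CohortSpec | None = None) -> Cohort:
    """Build the cohort table and per-patient waveform presets.

    Deterministic given the spec (which carries the seed).  The table
    has one row per subject including healthy volunteers (group
    ``hv``); the four patient groups sum to 211 under the default spec.
    """
    spec = spec or CohortSpec()
    rng = np.random.default_rng(spec.seed)
    diseases = _allocate_diseases(spec, rng)

    rows = []
    presets: dict[str, GeneratorPreset] = {}
    for g in ALL_GROUPS:
        n = spec.group_sizes.get(g, 0)
        labs = spec.labs[g]
        platelet = sample_lab(labs["platelet"], n, rng)
        pt_ratio = sample_lab(labs["pt_ratio"], n, rng)
        fdp = sample_lab(labs["fdp"], n, rng)
        fibrinogen = sample_lab(labs["fibrinogen"], n, rng)
        age = sample_lab(labs["age"], n, rng)
        n_f, n_m = _SEX_COUNTS.get(g, (0, 0))
        sex = np.array(["F"] * n_f + ["M"] * n_m + ["F", "M"] * n)[:n]
        rng.shuffle(sex)
        group_preset = builtin_preset(g)
        base_labels = diseases.get(g, ["none"] * n)
        for i in range(n):
            pid = f"{g}-{i:03d}"
            jit = np.exp(rng.normal(0.0, spec.jitter_sd, size=3))
            preset = replace(
                group_preset,
                amplitude=group_preset.amplitude * jit[0],
                center=group_preset.center * jit[1],
                slope=group_preset.slope * jit[2],
            )
            presets[pid] = preset
            rows.append({
                "id": pid,
                "group": g,
                "age_years": round(float(age[i]), 1),
                "sex": sex[i],
                "platelet_1e4_ul": float(platelet[i]),
                "pt_ratio": float(pt_ratio[i]),
                "fdp_ug_ml": float(fdp[i]),
                "fibrinogen_mg_dl": float(fibrinogen[i]),
                "disease": base_labels[i] if g != "hv" else "none",
                "preset_id": pid,
            })
    col_order = [
        "id", "group", "age_years", "sex", "platelet_1e4_ul", "pt_ratio",
        "fdp_ug_ml", "fibrinogen_mg_dl", "hb_g_dl", "disease", "bleeding",
        "organ_failure", "outcome", "preset_id",
    ]
    if not rows:
        return Cohort(patients=pd.DataFrame(columns=col_order), presets={})
    df = pd.DataFrame(rows)

    # analytic velocity-peak height drives outcome / Hb coupling
    from .curves import _peak_params  # closed forms, no width solving

    h1 = np.array([
        _peak_params(presets[pid])["h_1st"] for pid in df["id"]
    ])
    is_patient = (df["group"] != "hv").to_numpy()
    pat_idx = np.nonzero(is_patient)[0]
    ranks = np.empty(len(pat_idx))
    ranks[np.argsort(h1[pat_idx])] = np.arange(len(pat_idx))
    norm_rank = ranks / max(len(pat_idx) - 1, 1)
    weights = np.exp(-spec.coupling_strength * norm_rank)

    outcome = np.array(["survivor"] * len(df), dtype=object)
    chosen = _weighted_sample_without_replacement(rng, weights, spec.n_non_survivors)
    outcome[pat_idx[chosen]] = "non_survivor"

    hb = np.empty(len(df))
    hb_low_mask = np.zeros(len(df), dtype=bool)
    chosen_hb = _weighted_sample_without_replacement(rng, weights, spec.n_hb_low)
    hb_low_mask[pat_idx[chosen_hb]] = True
    for i in range(len(df)):
        if df["group"].iat[i] == "hv":
            hb[i] = sample_lab(_HB_HV, 1, rng)[0]
            hb[i] = max(hb[i], spec.hb_cut)
        elif hb_low_mask[i]:
            hb[i] = min(sample_lab(_HB_LOW, 1, rng)[0], spec.hb_cut - 0.05)
        else:
            hb[i] = max(sample_lab(_HB_HIGH, 1, rng)[0], spec.hb_cut)

    infectious = df["disease"].isin(_INFECTIOUS).to_numpy()
    is_dic = df["group"].isin(("dic_no_hf", "dic_hf")).to_numpy()
    bleeding = (df["group"] == "dic_hf").to_numpy() & (
        rng.random(len(df)) < spec.bleeding_prob_dic_hf
    )
    organ_failure = (infectious & is_dic) & (
        rng.random(len(df)) < spec.organ_failure_prob_infectious_dic
    )

    df["hb_g_dl"] = np.round(hb, 2)
    df["bleeding"] = bleeding
    df["organ_failure"] = organ_failure
    df["outcome"] = outcome
    return Cohort(patients=df[col_order], presets=presets)


_SCHEMA_VERSION = "1"
_REQUIRED_COLS = [
    "id", "group", "platelet_1e4_ul", "pt_ratio", "fdp_ug_ml",
    "fibrinogen_mg_dl", "hb_g_dl", "disease", "bleeding", "organ_failure",
    "outcome", "preset_id",
]
_NUMERIC_COLS = [
    "platelet_1e4_ul", "pt_ratio", "fdp_ug_ml", "fibrinogen_mg_dl", "hb_g_dl",
]


def write_cohort(patients: pd.DataFrame, path) -> None:
    """CSV with a schema-version header comment; lossless round trip."""
    with open(path, "w") as fh:
        fh.write(f"# aptt-cwa cohort schema v{_SCHEMA_VERSION}\n")
        patients.to_csv(fh, index=False)


def read_cohort(path) -> pd.DataFrame:
    df = pd.read_csv(path, comment="#")
    missing = [c for c in _REQUIRED_COLS if c not in df.columns]
    if missing:
        raise SchemaError(f"cohort file missing columns {missing}")
    for c in _NUMERIC_COLS:
        if not pd.api.types.is_numeric_dtype(df[c]):
            raise SchemaError(f"cohort column {c!r} must be numeric")
    return df
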