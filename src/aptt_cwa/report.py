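"""Cohort-level reporting: group lab summaries, waveform-parameter
summaries, score-parameter correlations, and outcome-/hemoglobin-
stratified contrasts, plus the end-to-end seeded pipeline.

The report mirrors the structure of the published analysis: a lab
table by group with significance stars against a reference group, a
waveform-parameter table by group including healthy volunteers, a
ten-row correlation table of each waveform parameter against the DIC
score, and stratified two-group comparisons of every parameter by
28-day outcome and by the 8 g/dl hemoglobin cut.
"""

from __future__ import annotations

import json
import platform
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .cohort import ALL_GROUPS, PATIENT_GROUPS, Cohort, CohortSpec, generate_cohort, write_cohort
from .curves import generate_curve
from .errors import ValidationError
from .extraction import ExtractionSettings, extract_batch, scale_batch, write_parameters
from .scoring import ScoreBands, score_cohort
from .stats import compare_groups, median_iqr, pearson_ols, stars

__all__ = ["Report", "build_report", "run_all", "WAVEFORM_PARAMS"]

LAB_COLS = ["platelet_1e4_ul", "pt_ratio", "fdp_ug_ml", "fibrinogen_mg_dl"]

#: the ten waveform parameters, in reporting order
WAVEFORM_PARAMS = [
    "t_2nd1_s", "w_2nd1_s", "h_2nd1_mabs", "w_2nd2_s", "nh_2nd2_mabs",
    "t_1st_s", "h_1st_mabs", "w_1st_s", "t_halfff_s", "h_halfff_mabs",
]


@dataclass(frozen=True)
class Report:
    labs_by_group: pd.DataFrame
    waveform_by_group: pd.DataFrame
    score_correlations: pd.DataFrame
    outcome_comparisons: pd.DataFrame
    hb_comparisons: pd.DataFrame

    def tables(self) -> dict[str, pd.DataFrame]:
        return {
            "labs_by_group": self.labs_by_group,
            "waveform_by_group": self.waveform_by_group,
            "score_correlations": self.score_correlations,
            "outcome_comparisons": self.outcome_comparisons,
            "hb_comparisons": self.hb_comparisons,
        }


def _summary_vs_reference(df, value_cols, group_col, groups, reference):
    rows = []
    ref_df = df[df[group_col] == reference]
    for col in value_cols:
        for g in groups:
            sub = df[df[group_col] == g][col].dropna()
            if sub.empty:
                continue
            med, q25, q75 = median_iqr(sub)
            row = {
                "variable": col, "group": g, "n": len(sub),
                "median": med, "q25": q25, "q75": q75,
            }
            if g != reference and not ref_df.empty:
                cmp = compare_groups(
                    sub.to_numpy(), ref_df[col].dropna().to_numpy(),
                    g, reference,
                )
                row.update(u=cmp.u_statistic, p=cmp.p_value, star=cmp.star)
            else:
                row.update(u=np.nan, p=np.nan, star="")
            rows.append(row)
    return pd.DataFrame(rows)


def _stratified(df, value_cols, mask, label_true, label_false):
    rows = []
    for col in value_cols:
        a = df.loc[mask, col].dropna().to_numpy()
        b = df.loc[~mask, col].dropna().to_numpy()
        if len(a) == 0 or len(b) == 0:
            continue
        cmp = compare_groups(a, b, label_true, label_false)
        rows.append({
            "parameter": col,
            "group_a": label_true, "n_a": cmp.n_x, "median_a": cmp.median_x,
            "q25_a": cmp.q25_x, "q75_a": cmp.q75_x,
            "group_b": label_false, "n_b": cmp.n_y, "median_b": cmp.median_y,
            "q25_b": cmp.q25_y, "q75_b": cmp.q75_y,
            "u": cmp.u_statistic, "p": cmp.p_value, "star": cmp.star,
        })
    return pd.DataFrame(rows)


def build_report(
    scored: pd.DataFrame,
    params: pd.DataFrame,
    reference_group: str = "non_dic",
    hb_cut: float = 8.0,
) -> Report:
    """Assemble the four report tables from a scored cohort and its
    extracted waveform parameters (joined on ``id``/``sample_id``).

    Correlations and stratified contrasts use patients only (healthy
    volunteers appear in the waveform summary).  Deterministic given
    its inputs.
    """
    required = {"id", "group", "score", "outcome", "hb_g_dl"}
    missing = required - set(scored.columns)
    if missing:
        raise ValidationError(f"scored cohort missing columns {sorted(missing)}")
    if reference_group not in set(scored["group"]):
        raise ValidationError(f"reference group {reference_group!r} absent")
    if scored["group"].nunique() < 2:
        raise ValidationError("need at least two groups to compare")

    ok = params[params["status"] == "ok"] if "status" in params.columns else params
    merged = scored.merge(
        ok, left_on="id", right_on="sample_id", how="inner", suffixes=("", "_wf")
    )
    patients = merged[merged["group"] != "hv"]

    groups_present = [g for g in ALL_GROUPS if g in set(scored["group"])]
    pat_groups = [g for g in PATIENT_GROUPS if g in set(scored["group"])]

    labs = _summary_vs_reference(
        scored[scored["group"] != "hv"], LAB_COLS, "group", pat_groups,
        reference_group,
    )
    waveform = _summary_vs_reference(
        merged, WAVEFORM_PARAMS, "group", groups_present, reference_group
    )

    corr_rows = []
    for col in WAVEFORM_PARAMS:
        sub = patients[["score", col]].dropna()
        res = pearson_ols(sub["score"], sub[col], name=col)
        corr_rows.append({
            "parameter": col, "r": res.r, "slope": res.slope,
            "intercept": res.intercept, "p": res.p_value,
            "star": stars(res.p_value), "n": res.n,
        })
    correlations = pd.DataFrame(corr_rows)

    outcome = _stratified(
        patients, WAVEFORM_PARAMS,
        (patients["outcome"] == "non_survivor").to_numpy(),
        "non_survivor", "survivor",
    )
    hb = _stratified(
        patients, WAVEFORM_PARAMS,
        (patients["hb_g_dl"] < hb_cut).to_numpy(),
        "hb_low", "hb_high",
    )
    return Report(
        labs_by_group=labs,
        waveform_by_group=waveform,
        score_correlations=correlations,
        outcome_comparisons=outcome,
        hb_comparisons=hb,
    )


def _summary_markdown(report: Report) -> str:
    lines = ["# APTT waveform cohort report", ""]
    for name, table in report.tables().items():
        lines.append(f"## {name}")
        lines.append("")
        lines.append("```\n" + table.round(4).to_string(index=False) + "\n```")
        lines.append("")
    return "\n".join(lines)


def run_all(
    seed: int,
    out_dir,
    spec: CohortSpec | None = None,
    bands: ScoreBands | None = None,
    settings: ExtractionSettings | None = None,
    write_curves_csv: bool = False,
) -> dict:
    """Seeded end-to-end pipeline: synthesize cohort and curves,
    extract waveform parameters, score, report; write every table and
    a run manifest under ``out_dir``.  Two runs with the same seed
    produce byte-identical tables."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    spec = spec if spec is not None else CohortSpec(seed=seed)

    cohort = generate_cohort(spec)
    curve_seed = np.random.SeedSequence(spec.seed).spawn(1)[0]
    seeds = curve_seed.generate_state(len(cohort.patients)) % (2**31)
    curves = [
        generate_curve(cohort.presets[pid], int(s), sample_id=pid)
        for pid, s in zip(cohort.patients["id"], seeds)
    ]
    params = scale_batch(extract_batch(curves, settings), cohort.presets)
    scored = score_cohort(cohort.patients, bands)
    report = build_report(scored, params)

    write_cohort(scored, out / "cohort.csv")
    write_parameters(params, out / "waveform_parameters.csv")
    if write_curves_csv:
        from .curves import write_curves

        write_curves(curves, out / "curves.csv")
    for name, table in report.tables().items():
        table.to_csv(out / f"{name}.csv", index=False)
    (out / "summary.md").write_text(_summary_markdown(report))

    import aptt_cwa

    manifest = {
        "seed": seed,
        "n_patients": int((cohort.patients["group"] != "hv").sum()),
        "n_subjects": int(len(cohort.patients)),
        "extraction": vars(settings) if settings else vars(ExtractionSettings()),
        "package_version": aptt_cwa.__version__,
        "python": platform.python_version(),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    return {"cohort": scored, "params": params, "report": report, "manifest": manifest}
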