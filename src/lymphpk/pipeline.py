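"""Study-level orchestration: dataset -> NCA -> transport -> statistics.

Ties the module stages together into tidy result tables; used by the
command-line interface, the analysis drivers and the validation
scripts alike.
"""

from __future__ import annotations

import warnings as _warnings
from dataclasses import asdict

import pandas as pd

from .nca import NCAResult, handle_blq, nca_extravascular, nca_intravenous
from .simulate import StudyDataset
from .stats import (
    comparisons_table,
    format_summary_table,
    paired_formulation_comparison,
    recovery_report,
    summarize_parameters,
)
from .transport import lymph_profile_as_timeseries, transport_analysis
from .io import truth_frame

TRANSPORT_PARAMETERS = (
    "cmax_lymph", "cmax_serum", "cmax_ratio",
    "tmax_lymph", "tmax_serum", "tmax_ratio",
    "auc_lymph", "auc_serum", "auc_ratio",
    "f", "f_ap", "f_al", "f_rl",
)

ANALYSIS_SETTINGS = {
    "auc_method": "linear trapezoid on actual sampling times",
    "lambda_z_rule": "max adjusted R^2 over suffixes of >=3 post-Tmax points",
    "auc_inf_tail": "observed C_last / lambda_z",
    "blq_policy": "zero before first quantifiable, drop embedded and post-Tmax",
    "truncation_convention": "oral AUC and F_AL cut at t*; IV reference keeps full AUC_inf",
    "iv_c0": "log-linear back-extrapolation from first two declining samples",
    "tests": "two-sided; paired across formulations, Student unpaired across groups",
}


def iv_reference_nca(dataset: StudyDataset, lloq: float = 1.0) -> NCAResult | None:
    """NCA of the dataset's IV reference record, or None when absent."""
    ivs = dataset.iv_records
    if not ivs:
        return None
    if len(ivs) > 1:
        _warnings.warn("multiple IV records: using the first", stacklevel=2)
    rec = ivs[0]
    bw = rec.params.bodyweight if rec.params is not None else None
    return nca_intravenous(handle_blq(rec.serum, lloq), bodyweight=bw)


def nca_table(dataset: StudyDataset, lloq: float = 1.0) -> pd.DataFrame:
    """Tidy NCA results: one row per animal x period x fluid."""
    rows = []
    for rec in dataset.records:
        results = []
        if rec.route == "iv":
            bw = rec.params.bodyweight if rec.params is not None else None
            results.append(nca_intravenous(handle_blq(rec.serum, lloq), bodyweight=bw))
        else:
            results.append(nca_extravascular(handle_blq(rec.serum, lloq)))
            if len(rec.lymph) >= 3:
                lymph_profile = lymph_profile_as_timeseries(rec.lymph, rec.dose_mg)
                results.append(nca_extravascular(handle_blq(lymph_profile, lloq)))
        for res in results:
            row = {
                "animal_id": rec.animal_id,
                "period": rec.period,
                "formulation": rec.formulation,
                "route": res.route,
                "fluid": res.fluid,
                "dose_mg": rec.dose_mg,
                "cmax": res.cmax,
                "tmax": res.tmax,
                "auc_last": res.auc_last,
                "auc_inf": res.auc_inf,
                "pct_extrapolated": res.pct_extrapolated,
                "lambda_z": res.terminal.lambda_z if res.terminal else None,
                "t_half": res.terminal.t_half if res.terminal else None,
                "cl": res.cl,
                "mrt": res.mrt,
                "vss": res.vss,
                "cl_per_kg": res.cl_per_kg,
                "vss_per_kg": res.vss_per_kg,
                "warnings": "; ".join(res.warnings),
            }
            rows.append(row)
    return pd.DataFrame(rows)


def transport_table(
    dataset: StudyDataset,
    iv_nca: NCAResult | None = None,
    truncation_time: float | None = None,
    lloq: float = 1.0,
) -> pd.DataFrame:
    """Transport results for every oral record (one row each)."""
    if iv_nca is None:
        iv_nca = iv_reference_nca(dataset, lloq)
    rows = []
    for rec in dataset.oral_records:
        res = transport_analysis(rec, iv_nca, truncation_time, lloq)
        row = asdict(res)
        row["warnings"] = "; ".join(res.warnings)
        rows.append(row)
    return pd.DataFrame(rows)


def run_study(
    dataset: StudyDataset,
    lloq: float = 1.0,
    truncation_time: float | None = 8.0,
) -> dict[str, pd.DataFrame]:
    """Full pipeline over a dataset.

    Returns tidy tables: per-profile NCA, per-period transport results
    (full collection and, when requested, the truncated variant),
    publication-shaped mean +/- SD summaries with paired-test markers,
    the comparison statistics, and a parameter-recovery report when
    truth sidecars are present.
    """
    iv_nca = iv_reference_nca(dataset, lloq)
    tables: dict[str, pd.DataFrame] = {"nca": nca_table(dataset, lloq)}

    variants: list[tuple[str, float | None]] = [("full", None)]
    if truncation_time is not None:
        variants.append((f"truncated_{truncation_time:g}h", truncation_time))
    for label, t_star in variants:
        tt = transport_table(dataset, iv_nca, t_star, lloq)
        tables[f"transport_{label}"] = tt
        comparisons = {}
        n_complete = (
            tt.pivot_table(index="animal_id", columns="formulation", values="f_al")
            .dropna()
            .shape[0]
        )
        if n_complete >= 2:
            for par in TRANSPORT_PARAMETERS:
                if tt[par].notna().all():
                    comparisons[par] = paired_formulation_comparison(tt, par)
        summary = summarize_parameters(
            tt, ["formulation"], list(TRANSPORT_PARAMETERS), comparisons
        )
        tables[f"summary_{label}"] = summary
        tables[f"summary_{label}_formatted"] = format_summary_table(
            summary, ["formulation"]
        ).reset_index()
        if comparisons:
            tables[f"comparisons_{label}"] = comparisons_table(comparisons)

    truth = truth_frame(dataset)
    if not truth.empty:
        est = tables["transport_full"][
            ["animal_id", "period", "f_al", "f_ap", "f", "f_rl"]
        ]
        if est[["f_ap", "f", "f_rl"]].notna().all().all():
            tables["recovery"] = recovery_report(
                truth.drop(columns=["formulation"]), est
            )
    return tables
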