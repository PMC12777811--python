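"""Cross-over and interspecies statistics, summary tables, and the
parameter-recovery report.

Conventions: two-sided tests throughout; the paired t-test carries no
period/sequence adjustment; the unpaired test defaults to the classical
equal-variance (Student) form with Welch available behind a flag; the
significance level is 0.05 and no multiplicity correction is applied
across parameters.  Summaries report mean +/- sample SD (n - 1).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

ALPHA = 0.05


@dataclass(frozen=True)
class ComparisonResult:
    parameter: str
    groups: tuple[str, str]
    n: tuple[int, int]
    means: tuple[float, float]
    sds: tuple[float, float]
    test: str  # "paired" | "unpaired"
    t_stat: float
    p_value: float
    significant: bool
    degenerate: bool = False
    note: str = ""

    def __post_init__(self) -> None:
        if not (np.isnan(self.p_value) or 0.0 <= self.p_value <= 1.0):
            raise ValueError("p value outside [0, 1]")


def paired_ttest(x: np.ndarray, y: np.ndarray) -> tuple[float, float, bool]:
    """Two-sided paired t-test; returns (t, p, degenerate).

    Identical samples give t = 0, p = 1.  A constant non-zero
    difference with zero variance has no finite t statistic; it is
    reported as degenerate (t = +/-inf, p = nan) rather than p = 0.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 2:
        raise ValueError("paired test needs >= 2 matched pairs")
    d = x - y
    if np.ptp(d) == 0.0:
        if d[0] == 0.0:
            return 0.0, 1.0, False
        return float(np.sign(d[0]) * np.inf), float("nan"), True
    t, p = sps.ttest_rel(x, y)
    return float(t), float(p), False


def unpaired_ttest(
    a: np.ndarray, b: np.ndarray, equal_var: bool = True
) -> tuple[float, float, bool]:
    """Two-sided two-sample t-test; returns (t, p, degenerate)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("unpaired test needs >= 2 values per group")
    if np.ptp(a) == 0.0 and np.ptp(b) == 0.0:
        if a[0] == b[0]:
            return 0.0, 1.0, False
        return float(np.sign(a[0] - b[0]) * np.inf), float("nan"), True
    t, p = sps.ttest_ind(a, b, equal_var=equal_var)
    return float(t), float(p), False


def _sd(v: np.ndarray) -> float:
    return float(np.std(v, ddof=1)) if v.size >= 2 else float("nan")


def paired_formulation_comparison(
    results: pd.DataFrame,
    parameter: str,
    *,
    subject: str = "animal_id",
    group: str = "formulation",
) -> ComparisonResult:
    """Paired t-test of one parameter between the two formulations.

    ``results`` is a tidy table with one row per animal x period and a
    column per parameter; only animals with both periods enter the test.
    """
    wide = results.pivot_table(index=subject, columns=group, values=parameter)
    if wide.shape[1] != 2:
        raise ValueError("paired comparison requires exactly two formulations")
    wide = wide.dropna()
    if len(wide) < 2:
        raise ValueError("fewer than 2 complete pairs")
    g1, g2 = (str(c) for c in wide.columns)
    x, y = wide.iloc[:, 0].to_numpy(), wide.iloc[:, 1].to_numpy()
    t, p, degen = paired_ttest(x, y)
    return ComparisonResult(
        parameter=parameter,
        groups=(g1, g2),
        n=(len(wide), len(wide)),
        means=(float(x.mean()), float(y.mean())),
        sds=(_sd(x), _sd(y)),
        test="paired",
        t_stat=t,
        p_value=p,
        significant=bool(p < ALPHA),
        degenerate=degen,
        note="zero-variance difference" if degen else "",
    )


def unpaired_species_comparison(
    group_a: Sequence[float],
    group_b: Sequence[float],
    parameter: str,
    *,
    labels: tuple[str, str] = ("group A", "group B"),
    equal_var: bool = True,
) -> ComparisonResult:
    """Unpaired t-test between two independent groups (e.g. species)."""
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    t, p, degen = unpaired_ttest(a, b, equal_var=equal_var)
    return ComparisonResult(
        parameter=parameter,
        groups=labels,
        n=(a.size, b.size),
        means=(float(a.mean()), float(b.mean())),
        sds=(_sd(a), _sd(b)),
        test="unpaired" if equal_var else "unpaired (Welch)",
        t_stat=t,
        p_value=p,
        significant=bool(p < ALPHA),
        degenerate=degen,
        note="zero-variance groups" if degen else "",
    )


def summarize_parameters(
    results: pd.DataFrame,
    group_keys: Sequence[str],
    parameters: Sequence[str] | None = None,
    comparisons: Mapping[str, ComparisonResult] | None = None,
) -> pd.DataFrame:
    """Mean +/- sample SD per group per parameter, with significance flags.

    A group of size 1 reports its SD as absent (NaN), not 0.  When a
    comparison result is supplied for a parameter, its significance at
    p < 0.05 is flagged on every group row of that parameter (the
    asterisk convention of publication tables).
    """
    if parameters is None:
        parameters = [
            c
            for c in results.columns
            if c not in group_keys and pd.api.types.is_numeric_dtype(results[c])
        ]
    rows = []
    for keys, sub in results.groupby(list(group_keys), sort=False):
        if not isinstance(keys, tuple):
            keys = (keys,)
        for par in parameters:
            v = sub[par].dropna().to_numpy(dtype=float)
            comp = (comparisons or {}).get(par)
            rows.append(
                dict(zip(group_keys, keys))
                | {
                    "parameter": par,
                    "n": v.size,
                    "mean": float(v.mean()) if v.size else float("nan"),
                    "sd": _sd(v),
                    "significant": bool(comp.significant) if comp else False,
                    "p_value": comp.p_value if comp else float("nan"),
                }
            )
    return pd.DataFrame(rows)


def format_summary_table(
    summary: pd.DataFrame, group_keys: Sequence[str]
) -> pd.DataFrame:
    """Render a summary as publication-shaped 'mean +/- SD*' strings,
    one row per parameter and one column per group."""

    def _fmt(row) -> str:
        if row["n"] == 0 or np.isnan(row["mean"]):
            return "-"
        star = "*" if row["significant"] else ""
        if np.isnan(row["sd"]):
            return f"{row['mean']:.3g}{star}"
        return f"{row['mean']:.3g} ± {row['sd']:.2g}{star}"

    work = summary.copy()
    work["cell"] = work.apply(_fmt, axis=1)
    if len(group_keys) == 1:
        cols = work[group_keys[0]]
    else:
        cols = work[list(group_keys)].agg(" / ".join, axis=1)
    work = work.assign(group=cols)
    return work.pivot_table(
        index="parameter", columns="group", values="cell", aggfunc="first", sort=False
    )


def comparisons_table(comparisons: Mapping[str, ComparisonResult]) -> pd.DataFrame:
    """Comparison results as a tidy table (one row per parameter)."""
    rows = []
    for par, c in comparisons.items():
        rows.append(
            {
                "parameter": par,
                "test": c.test,
                "group_1": c.groups[0],
                "group_2": c.groups[1],
                "n_1": c.n[0],
                "n_2": c.n[1],
                "mean_1": c.means[0],
                "mean_2": c.means[1],
                "t_stat": c.t_stat,
                "p_value": c.p_value,
                "significant": c.significant,
                "degenerate": c.degenerate,
            }
        )
    return pd.DataFrame(rows)


def recovery_report(
    truth: pd.DataFrame,
    estimates: pd.DataFrame,
    *,
    on: Sequence[str] = ("animal_id", "period"),
    parameters: Mapping[str, str] | None = None,
) -> pd.DataFrame:
    """Bias, relative bias and RMSE of estimates against simulator truth.

    ``parameters`` maps truth columns to estimate columns (default: the
    four transport truths against f_al/f_ap/f/f_rl).  Records are
    matched one-to-one on ``on``; unmatched records raise.
    """
    if parameters is None:
        parameters = {
            "f_al_true": "f_al",
            "f_ap_true": "f_ap",
            "f_true": "f",
            "f_rl_true": "f_rl",
        }
    merged = truth.merge(
        estimates, on=list(on), how="outer", validate="one_to_one", indicator=True
    )
    if (merged["_merge"] != "both").any():
        bad = merged.loc[merged["_merge"] != "both", list(on)]
        raise ValueError(f"unmatched truth/estimate records: {bad.to_dict('records')}")
    rows = []
    for t_col, e_col in parameters.items():
        err = (merged[e_col] - merged[t_col]).to_numpy(dtype=float)
        tv = merged[t_col].to_numpy(dtype=float)
        bias = float(np.mean(err))
        denom = float(np.mean(np.abs(tv)))
        rows.append(
            {
                "parameter": e_col,
                "n": err.size,
                "truth_mean": float(tv.mean()),
                "bias": bias,
                "rel_bias_pct": 100.0 * bias / denom if denom > 0 else float("nan"),
                "rmse": float(np.sqrt(np.mean(err**2))),
                "median_abs_error": float(np.median(np.abs(err))),
            }
        )
    return pd.DataFrame(rows)
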