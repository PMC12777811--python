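"""Delimited-text interchange for study datasets, plus the study config.

Three comma-separated tables carry a study:

* serum:  animal_id, period, formulation, route, dose_mg, time_h,
  conc_ng_ml, blq_flag
* lymph:  animal_id, period, formulation, t_start_h, t_end_h, volume_ml,
  conc_ng_ml, blq_flag
* truth (simulation sidecar): animal_id, period, formulation,
  f_al_true, f_ap_true, f_true, f_rl_true

Times are hours post-dose (the dosing event defines t = 0), dot-decimal
floats.  Readers validate every declared invariant and report the
offending file lines; writers round-trip losslessly.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields, replace
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from .nca import ConcentrationProfile
from .simulate import (
    DEFAULT_FLOW,
    DEFAULT_IV_DOSE_MG,
    DEFAULT_NOISE,
    DEFAULT_ORAL_DOSE_MG,
    PKParameters,
    SimulatedAnimalRecord,
    StudyDataset,
    TransportTruth,
    default_nanoemulsion_params,
    default_oil_solution_params,
)
from .transport import LymphCollectionRecord

SERUM_COLUMNS = (
    "animal_id", "period", "formulation", "route", "dose_mg",
    "time_h", "conc_ng_ml", "blq_flag",
)
LYMPH_COLUMNS = (
    "animal_id", "period", "formulation", "t_start_h", "t_end_h",
    "volume_ml", "conc_ng_ml", "blq_flag",
)
TRUTH_COLUMNS = (
    "animal_id", "period", "formulation",
    "f_al_true", "f_ap_true", "f_true", "f_rl_true",
)

SERUM_TABLE = "serum.csv"
LYMPH_TABLE = "lymph.csv"
TRUTH_TABLE = "truth.csv"


class TableSchemaError(ValueError):
    """Raised when a table fails schema or invariant validation."""


class ConfigError(ValueError):
    """Raised on invalid study configuration."""


# Expected unit suffix per column stem, for actionable error messages when
# a file declares a different unit (e.g. "time_min").
_UNIT_STEMS = {
    "time": "time_h (hours post-dose)",
    "t_start": "t_start_h (hours)",
    "t_end": "t_end_h (hours)",
    "conc": "conc_ng_ml (ng/ml)",
    "volume": "volume_ml (ml)",
    "dose": "dose_mg (mg)",
}


def _check_columns(df: pd.DataFrame, expected: tuple[str, ...], path) -> None:
    missing = [c for c in expected if c not in df.columns]
    if not missing:
        return
    hints = []
    for col in missing:
        stem = next((s for s in _UNIT_STEMS if col.startswith(s)), None)
        if stem:
            stray = [c for c in df.columns if c.startswith(stem) and c != col]
            if stray:
                hints.append(
                    f"found {stray[0]!r} but expected {_UNIT_STEMS[stem]}; "
                    "convert the values and rename the column"
                )
    hint = ("; " + "; ".join(hints)) if hints else ""
    raise TableSchemaError(f"{path}: missing columns {missing}{hint}")


def _lines(df_index) -> list[int]:
    # +2: one for the header line, one for 0-based indexing
    return [int(i) + 2 for i in df_index]


def read_serum_table(path) -> list[SimulatedAnimalRecord]:
    """Read a serum table into one record per animal x period.

    Lymph collections are left empty; merge them in with
    :func:`assemble_dataset` or :func:`read_study_dir`.
    """
    path = Path(path)
    df = pd.read_csv(path, float_precision="round_trip")
    _check_columns(df, SERUM_COLUMNS, path)
    bad_route = df[~df["route"].isin(["oral", "iv"])]
    if len(bad_route):
        raise TableSchemaError(
            f"{path}: unknown route at lines {_lines(bad_route.index)}"
        )
    records = []
    for (animal, period, formulation, route), sub in df.groupby(
        ["animal_id", "period", "formulation", "route"], sort=False
    ):
        t = sub["time_h"].to_numpy(dtype=float)
        if np.any(np.diff(t) <= 0):
            i = int(np.flatnonzero(np.diff(t) <= 0)[0])
            l1, l2 = _lines(sub.index[[i, i + 1]])
            raise TableSchemaError(
                f"{path}: non-monotone times for {animal} period {period} "
                f"at lines {l1} and {l2}"
            )
        doses = sub["dose_mg"].unique()
        if len(doses) != 1:
            raise TableSchemaError(
                f"{path}: conflicting doses for {animal} period {period}"
            )
        profile = ConcentrationProfile(
            times=t,
            concentrations=sub["conc_ng_ml"].to_numpy(dtype=float),
            blq=sub["blq_flag"].to_numpy(dtype=bool),
            fluid="serum",
            route=str(route),
            dose_mg=float(doses[0]),
        )
        records.append(
            SimulatedAnimalRecord(
                animal_id=str(animal),
                period=int(period),
                formulation=str(formulation),
                route=str(route),
                dose_mg=float(doses[0]),
                serum=profile,
            )
        )
    if not records:
        raise TableSchemaError(f"{path}: no serum records")
    return records


def read_lymph_table(path) -> dict[tuple[str, int], tuple[LymphCollectionRecord, ...]]:
    """Read a lymph table into collections keyed by (animal_id, period)."""
    path = Path(path)
    df = pd.read_csv(path, float_precision="round_trip")
    _check_columns(df, LYMPH_COLUMNS, path)
    out: dict[tuple[str, int], tuple[LymphCollectionRecord, ...]] = {}
    for (animal, period), sub in df.groupby(["animal_id", "period"], sort=False):
        sub = sub.sort_values("t_start_h")
        starts = sub["t_start_h"].to_numpy(dtype=float)
        ends = sub["t_end_h"].to_numpy(dtype=float)
        overlap = np.flatnonzero(starts[1:] < ends[:-1] - 1e-9)
        if overlap.size:
            i = int(overlap[0])
            l1, l2 = _lines(sub.index[[i, i + 1]])
            raise TableSchemaError(
                f"{path}: overlapping lymph intervals for {animal} period "
                f"{period} at lines {l1} and {l2}"
            )
        recs = tuple(
            LymphCollectionRecord(
                t_start=float(r.t_start_h),
                t_end=float(r.t_end_h),
                volume_ml=float(r.volume_ml),
                conc_ng_ml=float(r.conc_ng_ml),
                blq=bool(r.blq_flag),
            )
            for r in sub.itertuples()
        )
        out[(str(animal), int(period))] = recs
    return out


def read_truth_table(path) -> pd.DataFrame:
    path = Path(path)
    df = pd.read_csv(path, float_precision="round_trip")
    _check_columns(df, TRUTH_COLUMNS, path)
    return df


def assemble_dataset(
    serum_records: list[SimulatedAnimalRecord],
    lymph: Mapping[tuple[str, int], tuple[LymphCollectionRecord, ...]] | None = None,
    truth: pd.DataFrame | None = None,
) -> StudyDataset:
    """Merge serum records, lymph collections and an optional truth sidecar."""
    truth_map: dict[tuple[str, int], TransportTruth] = {}
    if truth is not None:
        for r in truth.itertuples():
            truth_map[(str(r.animal_id), int(r.period))] = TransportTruth(
                f_al_true=float(r.f_al_true),
                f_ap_true=float(r.f_ap_true),
                f_true=float(r.f_true),
                f_rl_true=float(r.f_rl_true),
            )
    merged = []
    for rec in serum_records:
        key = (rec.animal_id, rec.period)
        updates = {}
        if lymph and key in lymph and rec.route == "oral":
            updates["lymph"] = lymph[key]
        if key in truth_map:
            updates["truth"] = truth_map[key]
        merged.append(replace(rec, **updates) if updates else rec)
    return StudyDataset(records=tuple(merged))


def serum_frame(dataset: StudyDataset) -> pd.DataFrame:
    rows = []
    for rec in dataset.records:
        for t, c, b in zip(
            rec.serum.times, rec.serum.concentrations, rec.serum.blq
        ):
            rows.append(
                {
                    "animal_id": rec.animal_id,
                    "period": rec.period,
                    "formulation": rec.formulation,
                    "route": rec.route,
                    "dose_mg": rec.dose_mg,
                    "time_h": t,
                    "conc_ng_ml": c,
                    "blq_flag": bool(b),
                }
            )
    return pd.DataFrame(rows, columns=list(SERUM_COLUMNS))


def lymph_frame(dataset: StudyDataset) -> pd.DataFrame:
    rows = []
    for rec in dataset.records:
        for lr in rec.lymph:
            rows.append(
                {
                    "animal_id": rec.animal_id,
                    "period": rec.period,
                    "formulation": rec.formulation,
                    "t_start_h": lr.t_start,
                    "t_end_h": lr.t_end,
                    "volume_ml": lr.volume_ml,
                    "conc_ng_ml": lr.conc_ng_ml,
                    "blq_flag": bool(lr.blq),
                }
            )
    return pd.DataFrame(rows, columns=list(LYMPH_COLUMNS))


def truth_frame(dataset: StudyDataset) -> pd.DataFrame:
    rows = []
    for rec in dataset.records:
        if rec.truth is None:
            continue
        rows.append(
            {
                "animal_id": rec.animal_id,
                "period": rec.period,
                "formulation": rec.formulation,
                "f_al_true": rec.truth.f_al_true,
                "f_ap_true": rec.truth.f_ap_true,
                "f_true": rec.truth.f_true,
                "f_rl_true": rec.truth.f_rl_true,
            }
        )
    return pd.DataFrame(rows, columns=list(TRUTH_COLUMNS))


def write_study_dataset(dataset: StudyDataset, outdir) -> dict[str, Path]:
    """Write serum/lymph/truth tables; returns the written paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}
    for name, frame in (
        (SERUM_TABLE, serum_frame(dataset)),
        (LYMPH_TABLE, lymph_frame(dataset)),
        (TRUTH_TABLE, truth_frame(dataset)),
    ):
        if name == TRUTH_TABLE and frame.empty:
            continue
        p = outdir / name
        frame.to_csv(p, index=False)
        paths[name] = p
    return paths


def read_study_dir(datadir) -> StudyDataset:
    """Load a dataset directory written by :func:`write_study_dataset`."""
    datadir = Path(datadir)
    serum = read_serum_table(datadir / SERUM_TABLE)
    lymph_path = datadir / LYMPH_TABLE
    truth_path = datadir / TRUTH_TABLE
    lymph = read_lymph_table(lymph_path) if lymph_path.exists() else None
    truth = read_truth_table(truth_path) if truth_path.exists() else None
    return assemble_dataset(serum, lymph, truth)


def write_results(tables: Mapping[str, pd.DataFrame], outdir) -> dict[str, Path]:
    """Write each named table as ``<name>.csv`` under ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}
    for name, frame in tables.items():
        p = outdir / f"{name}.csv"
        frame.to_csv(p, index=False)
        paths[name] = p
    return paths


# ---------------------------------------------------------------------------
# Study configuration


@dataclass(frozen=True)
class StudyConfig:
    """Study design and analysis settings, loadable from YAML.

    Defaults encode the reference design: 3 animals, 200 mg oral /
    20 mg IV, LLOQ 1 ng/ml, 8 h truncation for the interspecies-style
    table.  ``parameters`` optionally overrides simulator parameter
    fields per formulation.
    """

    n_animals: int = 3
    formulations: tuple[str, str] = ("oil_solution", "nanoemulsion")
    oral_dose_mg: float = DEFAULT_ORAL_DOSE_MG
    iv_dose_mg: float = DEFAULT_IV_DOSE_MG
    lloq: float = DEFAULT_NOISE.lloq
    truncation_time: float = 8.0
    seed: int = 0
    residual_cv: float = DEFAULT_NOISE.residual_cv
    iiv_cv: float = DEFAULT_NOISE.iiv_cv
    mean_flow_ml_h: float = DEFAULT_FLOW.mean_flow
    cv_flow: float = DEFAULT_FLOW.cv_flow
    equal_variance: bool = True
    parameters: Mapping[str, Mapping[str, float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.formulations) != 2:
            raise ConfigError("exactly two formulations are required")
        if self.n_animals < 1:
            raise ConfigError("n_animals must be at least 1")
        for name in ("oral_dose_mg", "iv_dose_mg", "lloq"):
            if not getattr(self, name) > 0:
                raise ConfigError(f"{name} must be positive")

    def params_by_formulation(self) -> dict[str, PKParameters]:
        builtin = {
            "oil_solution": default_oil_solution_params,
            "nanoemulsion": default_nanoemulsion_params,
        }
        valid_fields = {f.name for f in fields(PKParameters)}
        out = {}
        for name in self.formulations:
            overrides = dict(self.parameters.get(name, {}))
            unknown = set(overrides) - valid_fields
            if unknown:
                raise ConfigError(
                    f"unknown simulator parameter(s) {sorted(unknown)} "
                    f"for formulation {name!r}"
                )
            if name in builtin:
                out[name] = replace(builtin[name](), **overrides)
            elif set(overrides) >= (valid_fields - {"k12", "k21", "bodyweight"}):
                out[name] = PKParameters(**overrides)
            else:
                raise ConfigError(
                    f"formulation {name!r} is not built in; supply its full "
                    "parameter set under 'parameters'"
                )
        return out

    def as_dict(self) -> dict:
        d = asdict(self)
        d["formulations"] = list(self.formulations)
        d["parameters"] = {k: dict(v) for k, v in self.parameters.items()}
        return d


def load_config(path) -> StudyConfig:
    """Load and schema-validate a YAML study config; unknown keys raise."""
    raw = yaml.safe_load(Path(path).read_text())
    if raw is None:
        raw = {}
    if not isinstance(raw, dict):
        raise ConfigError(f"{path}: config must be a mapping")
    valid = {f.name for f in fields(StudyConfig)}
    unknown = set(raw) - valid
    if unknown:
        raise ConfigError(f"{path}: unknown config key(s) {sorted(unknown)}")
    if "formulations" in raw:
        raw["formulations"] = tuple(raw["formulations"])
    return StudyConfig(**raw)
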