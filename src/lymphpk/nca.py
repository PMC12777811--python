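"""Non-compartmental analysis (NCA) of concentration-time profiles.

Model-free pharmacokinetic parameter estimation as used for both serum
and lymph profiles: below-limit-of-quantification (BLQ) handling, linear
trapezoidal AUC/AUMC, terminal log-linear slope (lambda_z) selection by
adjusted R^2, extrapolation to infinite time, and the intravenous-bolus
disposition parameters CL, MRT and Vss.

Conventions (all reported in result objects for auditability):

* AUC uses the linear trapezoidal rule on the actual sampling times,
  including the descending limb.
* lambda_z is fit by ordinary least squares on ln C vs t over candidate
  tails (every suffix of >= 3 quantifiable points strictly after Tmax);
  the tail with the highest adjusted R^2 wins, ties going to the tail
  with more points.  A negative slope is required.
* The extrapolated tail uses the observed (not predicted) last
  quantifiable concentration: AUC_inf = AUC_last + C_last/lambda_z.
* Extravascular profiles get an imputed C = 0 point at t = 0 when the
  first sample is post-dose; IV-bolus profiles get a log-linearly
  back-extrapolated C(0) from the first two declining samples.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .units import ML_PER_L, NG_PER_MG

_FLUIDS = frozenset({"serum", "lymph"})
_ROUTES = frozenset({"oral", "iv"})


class ProfileError(ValueError):
    """Raised when a concentration profile violates its invariants."""


@dataclass(frozen=True)
class ConcentrationProfile:
    """A route- and dose-tagged concentration-time series in one fluid.

    Parameters
    ----------
    times
        Sampling times in hours post-dose, strictly increasing.
    concentrations
        Measured concentrations in ng/ml.  Quantifiable values must be
        non-negative; values flagged BLQ may hold the raw reading.
    fluid
        ``"serum"`` or ``"lymph"``.
    route
        ``"oral"`` or ``"iv"`` (route of the administered dose).
    dose_mg
        Administered dose in mg, or ``None`` when not applicable
        (e.g. a lymph profile used only for Cmax/Tmax/AUC).
    blq
        Boolean flags marking below-LLOQ observations.
    edits
        Provenance log of BLQ edits applied by :func:`handle_blq`.
    """

    times: np.ndarray
    concentrations: np.ndarray
    fluid: str = "serum"
    route: str = "oral"
    dose_mg: float | None = None
    blq: np.ndarray | None = None
    edits: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        c = np.asarray(self.concentrations, dtype=float)
        if t.ndim != 1 or c.ndim != 1 or t.size != c.size:
            raise ProfileError("times and concentrations must be 1-d arrays of equal length")
        if t.size and np.any(np.diff(t) <= 0):
            raise ProfileError("sampling times must be strictly increasing")
        if not np.all(np.isfinite(t)):
            raise ProfileError("non-finite sampling time")
        b = self.blq
        b = np.zeros(t.size, dtype=bool) if b is None else np.asarray(b, dtype=bool)
        if b.size != t.size:
            raise ProfileError("blq flags must match the number of samples")
        if np.any(~np.isfinite(c) & ~b):
            raise ProfileError("non-finite quantifiable concentration")
        if np.any((c < 0) & ~b):
            raise ProfileError("negative quantifiable concentration")
        for arr in (t, c, b):
            arr.setflags(write=False)
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "concentrations", c)
        object.__setattr__(self, "blq", b)
        if self.fluid not in _FLUIDS:
            raise ProfileError(f"unknown fluid {self.fluid!r}")
        if self.route not in _ROUTES:
            raise ProfileError(f"unknown route {self.route!r}")
        if self.dose_mg is not None and not self.dose_mg > 0:
            raise ProfileError("dose_mg must be positive when given")

    @property
    def quantifiable(self) -> np.ndarray:
        return ~self.blq

    @property
    def n_quantifiable(self) -> int:
        return int(np.count_nonzero(self.quantifiable))

    def __len__(self) -> int:
        return self.times.size


@dataclass(frozen=True)
class TerminalFit:
    """Terminal log-linear fit: lambda_z and derived half-life.

    ``t_half = ln 2 / lambda_z``; ``n_points`` is the number of tail
    points used; ``r2_adj`` the adjusted R^2 of the ln C vs t
    regression; ``time_span`` the width of the fitted tail in hours.
    """

    lambda_z: float
    t_half: float
    n_points: int
    r2_adj: float
    time_span: float
    log_intercept: float

    def __post_init__(self) -> None:
        if not self.lambda_z > 0:
            raise ValueError("lambda_z must be positive")
        if self.n_points < 3:
            raise ValueError("terminal fit requires >= 3 points")


@dataclass(frozen=True)
class NCAResult:
    """Non-compartmental outputs for one profile.

    ``cl``, ``mrt`` and ``vss`` are populated for IV profiles only;
    per-kg values additionally require a bodyweight.  ``auc_inf`` is
    ``None`` whenever no terminal phase could be fit, and every
    deviation from the happy path is recorded in ``warnings``.
    """

    route: str
    fluid: str
    dose_mg: float | None
    cmax: float
    tmax: float
    auc_last: float
    auc_inf: float | None = None
    aumc_last: float | None = None
    aumc_inf: float | None = None
    pct_extrapolated: float | None = None
    terminal: TerminalFit | None = None
    cl: float | None = None
    mrt: float | None = None
    vss: float | None = None
    cl_per_kg: float | None = None
    vss_per_kg: float | None = None
    warnings: tuple[str, ...] = ()
    settings: tuple[str, ...] = field(default=(
        "auc: linear trapezoid on actual times",
        "lambda_z: max adjusted R^2 over suffixes of >=3 post-Tmax points",
        "auc_inf tail: observed C_last / lambda_z",
    ))

    def __post_init__(self) -> None:
        if self.auc_inf is not None and self.auc_inf < self.auc_last - 1e-9:
            raise ValueError("auc_inf must not be smaller than auc_last")


# ---------------------------------------------------------------------------
# BLQ handling


def handle_blq(profile: ConcentrationProfile, lloq: float) -> ConcentrationProfile:
    """Apply the BLQ editing policy and return a fully quantifiable profile.

    Policy: observations below ``lloq`` (or already flagged BLQ) before
    the first quantifiable point are set to 0 and kept (pre-dose
    convention); BLQ observations after the first quantifiable point are
    dropped, whether embedded between quantifiable points or trailing
    after Tmax.  Each edit is logged in the returned profile's
    ``edits``.

    Raises
    ------
    ProfileError
        If ``lloq`` is not positive or every observation is BLQ.
    """
    if not lloq > 0:
        raise ProfileError("lloq must be positive")
    blq = profile.blq | (profile.concentrations < lloq)
    if blq.all():
        raise ProfileError("all observations are below the limit of quantification")
    quant = ~blq
    first_q = int(np.argmax(quant))
    last_q = int(len(profile) - 1 - np.argmax(quant[::-1]))

    keep = np.ones(len(profile), dtype=bool)
    conc = profile.concentrations.copy()
    edits: list[str] = list(profile.edits)
    for i in np.flatnonzero(blq):
        t = profile.times[i]
        if i < first_q:
            conc[i] = 0.0
            edits.append(f"t={t:g} h: leading BLQ set to 0")
        elif i > last_q:
            keep[i] = False
            edits.append(f"t={t:g} h: trailing post-Tmax BLQ dropped")
        else:
            keep[i] = False
            edits.append(f"t={t:g} h: embedded BLQ dropped")
    return replace(
        profile,
        times=profile.times[keep],
        concentrations=conc[keep],
        blq=np.zeros(int(keep.sum()), dtype=bool),
        edits=tuple(edits),
    )


def with_predose_zero(profile: ConcentrationProfile) -> ConcentrationProfile:
    """Prepend an imputed C = 0 observation at t = 0 when missing.

    Extravascular profiles start at zero by definition of the dosing
    event; this makes AUC from time zero well-defined when the first
    sample is post-dose.  Profiles already containing t = 0 are returned
    unchanged.
    """
    if len(profile) and profile.times[0] == 0.0:
        return profile
    return replace(
        profile,
        times=np.concatenate(([0.0], profile.times)),
        concentrations=np.concatenate(([0.0], profile.concentrations)),
        blq=np.concatenate(([False], profile.blq)),
        edits=profile.edits + ("t=0 h: imputed pre-dose zero",),
    )


# ---------------------------------------------------------------------------
# AUC


def _require_quantifiable(profile: ConcentrationProfile) -> tuple[np.ndarray, np.ndarray]:
    t = profile.times[profile.quantifiable]
    c = profile.concentrations[profile.quantifiable]
    return t, c


def auc_trapezoid(
    profile: ConcentrationProfile,
    t_start: float | None = None,
    t_end: float | None = None,
) -> float:
    """Linear-trapezoid AUC of a profile over ``[t_start, t_end]`` (ng·h/ml).

    The span defaults to the full observed range.  Boundary times that
    fall between samples are handled by linear interpolation of the
    concentration first, so the result is additive over adjacent
    sub-intervals.  BLQ-flagged points are ignored (run
    :func:`handle_blq` first for the full editing policy).
    """
    t, c = _require_quantifiable(profile)
    if t.size < 2:
        raise ProfileError("AUC requires at least 2 quantifiable points")
    lo = t[0] if t_start is None else float(t_start)
    hi = t[-1] if t_end is None else float(t_end)
    if not lo < hi:
        raise ProfileError("t_start must be earlier than t_end")
    if lo < t[0] - 1e-12 or hi > t[-1] + 1e-12:
        raise ProfileError(
            f"span [{lo:g}, {hi:g}] h lies outside the observed range [{t[0]:g}, {t[-1]:g}] h"
        )
    inner = (t > lo) & (t < hi)
    grid = np.concatenate(([lo], t[inner], [hi]))
    vals = np.concatenate(([np.interp(lo, t, c)], c[inner], [np.interp(hi, t, c)]))
    return float(np.trapezoid(vals, grid))


def _aumc_trapezoid(t: np.ndarray, c: np.ndarray) -> float:
    return float(np.trapezoid(t * c, t))


# ---------------------------------------------------------------------------
# Terminal slope


def estimate_lambda_z(profile: ConcentrationProfile) -> TerminalFit | None:
    """Estimate the terminal elimination rate constant lambda_z.

    Ordinary least squares on ln C vs t over every candidate tail (all
    suffixes of >= 3 positive quantifiable points strictly after Tmax).
    The tail maximizing adjusted R^2 is selected, ties broken toward
    more points, and a negative slope is required.  Returns ``None``
    when no admissible tail exists (callers flag the absence and leave
    AUC_inf undefined).
    """
    t, c = _require_quantifiable(profile)
    pos = c > 0
    t, c = t[pos], c[pos]
    if t.size < 4:  # Tmax plus at least 3 tail points
        return None
    imax = int(np.argmax(c))
    tt_all, cc_all = t[imax + 1 :], c[imax + 1 :]
    if tt_all.size < 3:
        return None
    y_all = np.log(cc_all)
    best: TerminalFit | None = None
    for start in range(tt_all.size - 2):
        x, y = tt_all[start:], y_all[start:]
        n = x.size
        slope, intercept = np.polyfit(x, y, 1)
        if slope >= 0:
            continue
        resid = y - (slope * x + intercept)
        ss_tot = float(np.sum((y - y.mean()) ** 2))
        if ss_tot == 0.0:
            continue
        r2 = 1.0 - float(np.sum(resid**2)) / ss_tot
        r2_adj = 1.0 - (1.0 - r2) * (n - 1) / (n - 2)
        if best is None or r2_adj > best.r2_adj + 1e-12:
            best = TerminalFit(
                lambda_z=float(-slope),
                t_half=float(math.log(2) / -slope),
                n_points=n,
                r2_adj=float(r2_adj),
                time_span=float(x[-1] - x[0]),
                log_intercept=float(intercept),
            )
    return best


# ---------------------------------------------------------------------------
# Full NCA


def _nca_core(p: ConcentrationProfile) -> dict:
    t, c = _require_quantifiable(p)
    auc_last = auc_trapezoid(p)
    aumc_last = _aumc_trapezoid(t, c)
    fit = estimate_lambda_z(p)
    out = {
        "auc_last": auc_last,
        "aumc_last": aumc_last,
        "terminal": fit,
        "warnings": [],
    }
    if fit is None:
        out["warnings"].append("no terminal phase: AUC_inf unavailable")
        return out
    c_last, t_last = c[-1], t[-1]
    auc_inf = auc_last + c_last / fit.lambda_z
    aumc_inf = aumc_last + c_last * t_last / fit.lambda_z + c_last / fit.lambda_z**2
    pct = 100.0 * (auc_inf - auc_last) / auc_inf
    out.update(auc_inf=auc_inf, aumc_inf=aumc_inf, pct_extrapolated=pct)
    if pct > 20.0:
        out["warnings"].append(f"extrapolated area is {pct:.1f}% of AUC_inf (> 20%)")
    return out


def _cmax_tmax(profile: ConcentrationProfile) -> tuple[float, float]:
    t, c = _require_quantifiable(profile)
    i = int(np.argmax(c))  # argmax takes the earliest index on ties
    return float(c[i]), float(t[i])


def nca_extravascular(profile: ConcentrationProfile) -> NCAResult:
    """NCA of an extravascular (oral) serum or lymph profile.

    Cmax/Tmax come from the observed quantifiable points (earliest time
    wins a tied maximum); AUC_last runs from t = 0 (imputed pre-dose
    zero if needed) to the last quantifiable point; AUC_inf adds the
    observed-C_last tail when a terminal phase exists.  A warning is
    attached when more than 20% of AUC_inf is extrapolated.
    """
    if profile.route == "iv":
        raise ProfileError("use nca_intravenous for IV profiles")
    if profile.n_quantifiable < 3:
        raise ProfileError("NCA requires at least 3 quantifiable points")
    cmax, tmax = _cmax_tmax(profile)
    p = with_predose_zero(profile)
    core = _nca_core(p)
    return NCAResult(
        route=profile.route,
        fluid=profile.fluid,
        dose_mg=profile.dose_mg,
        cmax=cmax,
        tmax=tmax,
        auc_last=core["auc_last"],
        auc_inf=core.get("auc_inf"),
        aumc_last=core["aumc_last"],
        aumc_inf=core.get("aumc_inf"),
        pct_extrapolated=core.get("pct_extrapolated"),
        terminal=core["terminal"],
        warnings=tuple(core["warnings"]),
    )


def _back_extrapolate_c0(profile: ConcentrationProfile) -> ConcentrationProfile:
    """Prepend the log-linear back-extrapolated C(0) for an IV bolus."""
    t, c = _require_quantifiable(profile)
    if t[0] == 0.0:
        return profile
    if t.size >= 2 and c[0] > c[1] > 0:
        slope = (math.log(c[1]) - math.log(c[0])) / (t[1] - t[0])
        c0 = math.exp(math.log(c[0]) - slope * t[0])
    else:
        c0 = float(c[0])  # non-declining start: carry the first value back
    return replace(
        profile,
        times=np.concatenate(([0.0], profile.times)),
        concentrations=np.concatenate(([c0], profile.concentrations)),
        blq=np.concatenate(([False], profile.blq)),
        edits=profile.edits + (f"t=0 h: back-extrapolated C0={c0:.6g} ng/ml",),
    )


def clearance_l_per_h(dose_mg: float, auc_inf: float) -> float:
    """Systemic clearance CL = dose / AUC_inf, converted to l/h.

    ``dose_mg`` in mg, ``auc_inf`` in ng·h/ml.
    """
    if not (dose_mg > 0 and auc_inf > 0):
        raise ValueError("dose and AUC_inf must be positive")
    return dose_mg * NG_PER_MG / auc_inf / ML_PER_L


def nca_intravenous(
    profile: ConcentrationProfile, bodyweight: float | None = None
) -> NCAResult:
    """NCA of an IV-bolus serum profile: adds CL, MRT and Vss.

    CL = dose/AUC_inf; MRT = AUMC_inf/AUC_inf (bolus, no infusion
    correction); Vss = CL·MRT.  AUC from time zero uses a log-linearly
    back-extrapolated C(0) from the first two declining samples.  When
    no terminal phase can be fit, CL/MRT/Vss stay undefined and the
    result carries an explicit warning.
    """
    if profile.route != "iv":
        raise ProfileError("nca_intravenous requires an IV profile")
    if profile.dose_mg is None:
        raise ProfileError("IV NCA requires the administered dose")
    if profile.n_quantifiable < 3:
        raise ProfileError("NCA requires at least 3 quantifiable points")
    cmax, tmax = _cmax_tmax(profile)
    p = _back_extrapolate_c0(profile)
    core = _nca_core(p)
    cl = mrt = vss = cl_kg = vss_kg = None
    if core.get("auc_inf") is not None:
        cl = clearance_l_per_h(profile.dose_mg, core["auc_inf"])
        mrt = core["aumc_inf"] / core["auc_inf"]
        vss = cl * mrt
        if bodyweight is not None:
            if not bodyweight > 0:
                raise ProfileError("bodyweight must be positive")
            cl_kg, vss_kg = cl / bodyweight, vss / bodyweight
    return NCAResult(
        route=profile.route,
        fluid=profile.fluid,
        dose_mg=profile.dose_mg,
        cmax=cmax,
        tmax=tmax,
        auc_last=core["auc_last"],
        auc_inf=core.get("auc_inf"),
        aumc_last=core["aumc_last"],
        aumc_inf=core.get("aumc_inf"),
        pct_extrapolated=core.get("pct_extrapolated"),
        terminal=core["terminal"],
        cl=cl,
        mrt=mrt,
        vss=vss,
        cl_per_kg=cl_kg,
        vss_per_kg=vss_kg,
        warnings=tuple(core["warnings"]),
    )
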