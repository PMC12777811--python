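"""Lymphatic-transport bioavailability partitioning.

The defining computation of a lymph-duct-cannulated study: cumulative
lymphatic transport by direct mass balance over timed lymph collections,
and the bioavailability partition

* ``F_AL`` — absolute bioavailability via lymph, the percentage of the
  dose recovered in collected lymph (sum of concentration x volume);
* ``F_AP`` — absolute bioavailability via the portal vein, the
  dose-normalized oral/IV serum AUC ratio in lymph-diverted animals;
* ``F = F_AL + F_AP`` — total absolute bioavailability;
* ``F_RL = 100 * F_AL / F`` — the share of systemically available drug
  that traveled through lymph.

A truncated mode (both F_AL and the oral AUC cut at a common time,
conventionally 8 h) supports interspecies comparison; the IV reference
is always dose-normalized by its full AUC_inf.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .nca import (
    ConcentrationProfile,
    NCAResult,
    ProfileError,
    auc_trapezoid,
    handle_blq,
    nca_extravascular,
    with_predose_zero,
)
from .units import NG_PER_MG

_OVERLAP_TOL = 1e-9


class TransportError(ValueError):
    """Raised on inconsistent lymph-collection or bioavailability input."""


@dataclass(frozen=True)
class LymphCollectionRecord:
    """One timed lymph-collection interval.

    ``volume_ml`` is the total lymph collected over
    ``[t_start, t_end]`` hours and ``conc_ng_ml`` the drug concentration
    of its aliquot, taken as the flow-weighted mean over the interval so
    that drug mass = concentration x volume exactly.  ``blq`` marks an
    aliquot below the limit of quantification (contributes zero mass).
    """

    t_start: float
    t_end: float
    volume_ml: float
    conc_ng_ml: float
    blq: bool = False

    def __post_init__(self) -> None:
        if not self.t_start < self.t_end:
            raise TransportError("interval must have t_start < t_end")
        if self.volume_ml < 0:
            raise TransportError("negative lymph volume")
        if self.conc_ng_ml < 0 and not self.blq:
            raise TransportError("negative lymph concentration")

    @property
    def amount_mg(self) -> float:
        """Drug mass collected in the interval (mg); zero when BLQ."""
        if self.blq:
            return 0.0
        return self.conc_ng_ml * self.volume_ml / NG_PER_MG


def _sorted_records(
    records: Sequence[LymphCollectionRecord],
) -> list[LymphCollectionRecord]:
    if not records:
        raise TransportError("no lymph-collection records")
    recs = sorted(records, key=lambda r: r.t_start)
    for a, b in zip(recs, recs[1:]):
        if b.t_start < a.t_end - _OVERLAP_TOL:
            raise TransportError(
                f"overlapping lymph intervals [{a.t_start:g}, {a.t_end:g}] and "
                f"[{b.t_start:g}, {b.t_end:g}] h"
            )
    return recs


@dataclass(frozen=True)
class CumulativeTransportCurve:
    """Cumulative lymphatic transport evaluated at interval ends.

    ``cumulative_pct_dose`` is F_AL(t): the running percentage of the
    dose recovered in lymph.
    """

    times: np.ndarray
    cumulative_amount_mg: np.ndarray
    cumulative_pct_dose: np.ndarray

    def __post_init__(self) -> None:
        for name in ("times", "cumulative_amount_mg", "cumulative_pct_dose"):
            arr = np.asarray(getattr(self, name), dtype=float)
            arr.setflags(write=False)
            object.__setattr__(self, name, arr)
        if np.any(np.diff(self.cumulative_amount_mg) < -1e-12):
            raise TransportError("cumulative transport must be non-decreasing")

    @property
    def f_al(self) -> float:
        """F_AL (%) at the end of collection."""
        return float(self.cumulative_pct_dose[-1])


def cumulative_transport(
    records: Sequence[LymphCollectionRecord], dose_mg: float
) -> CumulativeTransportCurve:
    """Cumulative lymph mass balance: amount_i = C_i x V_i, summed in time.

    BLQ aliquots contribute zero mass (conservative for F_AL).
    """
    if not dose_mg > 0:
        raise TransportError("dose must be positive")
    recs = _sorted_records(records)
    amounts = np.array([r.amount_mg for r in recs])
    cum = np.cumsum(amounts)
    return CumulativeTransportCurve(
        times=np.array([r.t_end for r in recs]),
        cumulative_amount_mg=cum,
        cumulative_pct_dose=100.0 * cum / dose_mg,
    )


def absolute_bioavailability_portal(
    auc_ent: float, dose_ent: float, auc_iv: float, dose_iv: float
) -> float:
    """F_AP (%): dose-normalized oral/IV AUC ratio.

    ``100 * (AUC_ent/dose_ent) / (AUC_iv/dose_iv)``, where AUC_ent is
    the serum exposure after enteral dosing in a lymph-diverted animal
    and AUC_iv the IV reference exposure.
    """
    for name, v in (
        ("auc_ent", auc_ent),
        ("dose_ent", dose_ent),
        ("auc_iv", auc_iv),
        ("dose_iv", dose_iv),
    ):
        if not v > 0:
            raise TransportError(f"{name} must be positive (got {v!r})")
    return 100.0 * (auc_ent / dose_ent) / (auc_iv / dose_iv)


def total_bioavailability(f_al: float, f_ap: float) -> float:
    """Total absolute bioavailability F (%) = F_AL + F_AP."""
    if f_al < 0 or f_ap < 0:
        raise TransportError("bioavailability components must be non-negative")
    return f_al + f_ap


def relative_lymph_bioavailability(f_al: float, f: float) -> float:
    """F_RL (%) = 100 * F_AL / F, the lymph share of systemic availability.

    Defined as 0 when F_AL = 0; an F of 0 with F_AL > 0 is inconsistent
    (lymph-recovered drug with no systemic availability) and raises.
    """
    if f_al < 0 or f < f_al - 1e-9:
        raise TransportError("require 0 <= f_al <= f")
    if f_al == 0:
        return 0.0
    if f <= 0:
        raise TransportError("F = 0 with F_AL > 0 is inconsistent")
    return 100.0 * f_al / f


def lymph_profile_as_timeseries(
    records: Sequence[LymphCollectionRecord], dose_mg: float | None = None
) -> ConcentrationProfile:
    """Interval concentrations as a time series at interval-end times.

    Matches the hourly sampling convention (a 0-1 h aliquot is the
    "1 h" lymph sample), enabling lymph Cmax/Tmax/AUC via the NCA
    engine.  Single-interval inputs yield a single-point profile, which
    the NCA entry points reject as insufficient.
    """
    recs = _sorted_records(records)
    return ConcentrationProfile(
        times=np.array([r.t_end for r in recs]),
        concentrations=np.array([r.conc_ng_ml for r in recs]),
        blq=np.array([r.blq for r in recs]),
        fluid="lymph",
        route="oral",
        dose_mg=dose_mg,
    )


@dataclass(frozen=True)
class TransportResult:
    """The bioavailability partition plus lymph/serum exposure ratios.

    The identities F = F_AL + F_AP and F_RL = 100 F_AL / F hold exactly
    by construction and are re-asserted post-construction.  Fields are
    ``None`` when their inputs are unavailable (e.g. no IV reference:
    F_AP, F and F_RL are undefined while F_AL is still reported).
    """

    f_al: float
    f_ap: float | None
    f: float | None
    f_rl: float | None
    auc_lymph: float | None = None
    auc_serum: float | None = None
    cmax_lymph: float | None = None
    cmax_serum: float | None = None
    tmax_lymph: float | None = None
    tmax_serum: float | None = None
    cmax_ratio: float | None = None
    auc_ratio: float | None = None
    tmax_ratio: float | None = None
    truncation_time: float | None = None
    animal_id: str | None = None
    period: int | None = None
    formulation: str | None = None
    warnings: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.f_al < 0:
            raise TransportError("F_AL must be non-negative")
        if self.f_ap is not None:
            if self.f is None or abs(self.f - (self.f_al + self.f_ap)) > 1e-9:
                raise TransportError("F = F_AL + F_AP identity violated")
            expected = relative_lymph_bioavailability(self.f_al, self.f)
            if self.f_rl is None or abs(self.f_rl - expected) > 1e-9:
                raise TransportError("F_RL = 100 F_AL / F identity violated")


def transport_analysis(
    animal_record,
    iv_reference_nca: NCAResult | None = None,
    truncation_time: float | None = None,
    lloq: float = 1.0,
) -> TransportResult:
    """Full bioavailability partition for one oral animal-period.

    Parameters
    ----------
    animal_record
        Any object with ``serum`` (a :class:`ConcentrationProfile`),
        ``lymph`` (a sequence of :class:`LymphCollectionRecord`) and
        ``dose_mg``; simulated and file-loaded records both qualify.
    iv_reference_nca
        IV NCA result providing the dose-normalizing AUC_inf.  When
        absent, F_AP/F/F_RL are left undefined and F_AL is still
        reported.
    truncation_time
        Common cut time t* in hours: F_AL uses intervals ending at or
        before t* and AUC_ent becomes AUC[0, t*].  The IV reference is
        always normalized by its full AUC_inf.  ``None`` means full
        collection and AUC_inf.
    lloq
        Assay limit of quantification (ng/ml) for BLQ handling.
    """
    serum_raw: ConcentrationProfile = animal_record.serum
    records: Sequence[LymphCollectionRecord] = tuple(animal_record.lymph)
    dose_mg: float = animal_record.dose_mg
    if serum_raw.route != "oral":
        raise TransportError("transport analysis applies to oral records")
    warnings: list[str] = []

    serum = handle_blq(serum_raw, lloq)
    serum_nca = nca_extravascular(serum)
    warnings.extend(serum_nca.warnings)

    # --- F_AL by direct lymph mass balance -------------------------------
    if truncation_time is not None:
        used = [r for r in records if r.t_end <= truncation_time + _OVERLAP_TOL]
        if not used:
            raise TransportError("no lymph interval ends before the truncation time")
    else:
        used = list(records)
    f_al = cumulative_transport(used, dose_mg).f_al if used else 0.0
    if not records:
        warnings.append("no lymph collections: F_AL taken as 0")

    # --- F_AP from the dose-normalized AUC ratio -------------------------
    f_ap = f = f_rl = None
    if truncation_time is not None:
        auc_ent = auc_trapezoid(with_predose_zero(serum), 0.0, truncation_time)
    else:
        auc_ent = serum_nca.auc_inf
        if auc_ent is None:
            warnings.append("serum AUC_inf unavailable: F_AP undefined")
    if iv_reference_nca is None:
        warnings.append("no IV reference: F_AP, F and F_RL undefined")
    elif iv_reference_nca.auc_inf is None or iv_reference_nca.dose_mg is None:
        warnings.append("IV reference lacks AUC_inf or dose: F_AP undefined")
    elif auc_ent is not None:
        f_ap = absolute_bioavailability_portal(
            auc_ent, dose_mg, iv_reference_nca.auc_inf, iv_reference_nca.dose_mg
        )
        f = total_bioavailability(f_al, f_ap)
        f_rl = relative_lymph_bioavailability(f_al, f)

    # --- lymph/serum exposure ratios (always on the full profiles) -------
    lymph_nca = None
    if len(records) >= 3:
        try:
            lymph_nca = nca_extravascular(
                handle_blq(lymph_profile_as_timeseries(records, dose_mg), lloq)
            )
            warnings.extend(f"lymph NCA: {w}" for w in lymph_nca.warnings)
        except ProfileError as exc:
            warnings.append(f"lymph NCA unavailable: {exc}")
    elif records:
        warnings.append("fewer than 3 lymph intervals: lymph NCA unavailable")

    def _ratio(a, b):
        return a / b if a is not None and b is not None and b > 0 else None

    return TransportResult(
        f_al=f_al,
        f_ap=f_ap,
        f=f,
        f_rl=f_rl,
        auc_lymph=lymph_nca.auc_inf if lymph_nca else None,
        auc_serum=serum_nca.auc_inf,
        cmax_lymph=lymph_nca.cmax if lymph_nca else None,
        cmax_serum=serum_nca.cmax,
        tmax_lymph=lymph_nca.tmax if lymph_nca else None,
        tmax_serum=serum_nca.tmax,
        cmax_ratio=_ratio(lymph_nca.cmax if lymph_nca else None, serum_nca.cmax),
        auc_ratio=_ratio(lymph_nca.auc_inf if lymph_nca else None, serum_nca.auc_inf),
        tmax_ratio=_ratio(lymph_nca.tmax if lymph_nca else None, serum_nca.tmax),
        truncation_time=truncation_time,
        animal_id=getattr(animal_record, "animal_id", None),
        period=getattr(animal_record, "period", None),
        formulation=getattr(animal_record, "formulation", None),
        warnings=tuple(warnings),
    )
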