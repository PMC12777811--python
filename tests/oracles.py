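"""Independent closed-form oracles for the linear kinetic model.

These are hand-derived solutions of the one-compartment limit
(k12 = k21 = 0) and generic linear-model identities, kept deliberately
separate from the package implementation (which propagates the system
with a matrix exponential).  Amounts in ng, times in h.
"""

import numpy as np

NG_PER_MG = 1.0e6
ML_PER_L = 1000.0


def oral_serum_conc_1cpt(p, dose_mg, t):
    """C(t) after oral dosing, one-compartment: the classic Bateman
    two-exponential with systemic fraction fa(1-phi)(1-eh)."""
    t = np.asarray(t, dtype=float)
    ke = p.cl / p.vc
    fsys = p.fa * (1 - p.phi_lymph) * (1 - p.eh)
    a0 = fsys * dose_mg * NG_PER_MG
    amount = a0 * p.ka / (ke - p.ka) * (np.exp(-p.ka * t) - np.exp(-ke * t))
    return amount / (p.vc * ML_PER_L)


def iv_serum_conc_1cpt(p, dose_mg, t):
    """C(t) after an IV bolus, one-compartment mono-exponential."""
    t = np.asarray(t, dtype=float)
    ke = p.cl / p.vc
    return dose_mg * NG_PER_MG / (p.vc * ML_PER_L) * np.exp(-ke * t)


def collected_lymph_ng(p, dose_mg, t):
    """Cumulative drug mass drained into the cannula by time t.

    Gut empties at ka, fraction phi_lymph feeds a lymph compartment
    drained at klt; integrating the drained flux gives
    phi*fa*D*[1 - (klt e^{-ka t} - ka e^{-klt t})/(klt - ka)].
    Independent of the disposition parameters.
    """
    t = np.asarray(t, dtype=float)
    a0 = p.fa * p.phi_lymph * dose_mg * NG_PER_MG
    frac = 1 - (p.klt * np.exp(-p.ka * t) - p.ka * np.exp(-p.klt * t)) / (
        p.klt - p.ka
    )
    return a0 * frac


def oral_auc_inf(p, dose_mg):
    """Analytic serum AUC_inf (ng*h/ml) after oral dosing.

    Holds for ANY linear disposition: AUC = systemic amount / CL.
    """
    fsys = p.fa * (1 - p.phi_lymph) * (1 - p.eh)
    return fsys * dose_mg * NG_PER_MG / (p.cl * ML_PER_L)


def iv_auc_inf(p, dose_mg):
    """Analytic IV AUC_inf = dose/CL (any linear disposition)."""
    return dose_mg * NG_PER_MG / (p.cl * ML_PER_L)


def slow_hybrid_rate(p):
    """The slow eigenvalue (terminal rate) of the two-compartment
    disposition block, via the quadratic for the hybrid constants."""
    k10 = p.cl / p.vc
    s = k10 + p.k12 + p.k21
    prod = k10 * p.k21
    return (s - np.sqrt(s**2 - 4 * prod)) / 2
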