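"""ITC isotherm fitting and proton-linkage enthalpy decomposition.

Zn(II) binding to a CCHH zinc finger displaces protons from the cysteine
thiols, so the calorimetric enthalpy dH_ITC mixes the binding event with
buffer protonation.  The decomposition chain implemented here separates the
contributions:

    dH_ITC  ->  dH_std   (buffer-protonation correction, HEPES heat)
    dH_std  ->  dH_Zn-pep (subtract thiol-deprotonation enthalpy n_H * 8.5)
    dH_Zn-pep -> dH_folding (subtract Zn-S / Zn-N bond enthalpies, -5.0 each)

together with dG_std from the competition -logKd and the entropic term
-T*dS = dG - dH.  All enthalpies in kcal/mol at 298.15 K.

Note the buffer correction sign: the working convention here is
dH_std = dH_ITC + n_H * dH_buff (HEPES dH_buff = +5.02 kcal/mol), i.e. the
heat the buffer releases on picking up the displaced protons is removed from
the observed exotherm.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.optimize import least_squares

__all__ = [
    "ItcExperiment",
    "ItcFit",
    "ThermoConstants",
    "ThermoDecomposition",
    "ItcError",
    "ItcFitFailure",
    "DEFAULT_CONSTANTS",
    "simulate_isotherm",
    "fit_isotherm",
    "buffer_corrected_enthalpy",
    "cys_deprotonation_enthalpy",
    "zn_pep_enthalpy",
    "folding_enthalpy",
    "gibbs_from_neg_log_kd",
    "entropy_term",
    "decompose",
]

KCAL_TO_UCAL = 1e9


class ItcError(ValueError):
    pass


class ItcFitFailure(ItcError):
    def __init__(self, message, last_iterate=None):
        super().__init__(message)
        self.last_iterate = last_iterate


@dataclass
class ItcExperiment:
    """A titration: Zn(II) syringe into peptide cell, integrated heats.

    Heats are net (dilution control already subtracted) or carry a constant
    per-injection dilution offset that the fit absorbs.
    """

    cell_volume_ml: float
    cell_concentration: float  # molar peptide in the cell
    syringe_concentration: float  # molar Zn in the syringe
    injection_volumes_ul: np.ndarray
    heats_ucal: np.ndarray
    temperature: float = 298.15
    buffer_name: str = "HEPES"

    def __post_init__(self):
        self.injection_volumes_ul = np.asarray(self.injection_volumes_ul, float)
        self.heats_ucal = np.asarray(self.heats_ucal, float)
        if self.cell_volume_ml <= 0 or np.any(self.injection_volumes_ul <= 0):
            raise ItcError("volumes must be positive")
        if self.injection_volumes_ul.size < 10:
            raise ItcError("need at least 10 injections")
        if self.injection_volumes_ul.shape != self.heats_ucal.shape:
            raise ItcError("injection volumes and heats must match in length")


@dataclass
class ItcFit:
    stoichiometry_n: float
    kb: float  # 1/molar
    dh_itc: float  # kcal/mol of injectant bound
    dilution_offset: float  # ucal per injection
    stderr: dict = field(default_factory=dict)
    rss: float = float("nan")
    saturation_reached: bool = True


@dataclass(frozen=True)
class ThermoConstants:
    """Literature constants entering the decomposition (kcal/mol unless noted)."""

    dh_buff: float = 5.02  # HEPES protonation heat
    dh_cysh_per_proton: float = 8.5  # thiol deprotonation
    dh_zn_s: float = -5.0  # Zn-thiolate bond (vs Zn-OH2)
    dh_zn_n: float = -5.0  # Zn-imidazole bond
    gas_constant: float = 1.9872e-3  # kcal/(mol K)
    temperature: float = 298.15  # K


DEFAULT_CONSTANTS = ThermoConstants()


@dataclass
class ThermoDecomposition:
    """Per-peptide thermodynamic ledger of Zn(II) binding."""

    dg: float
    ddg_vs_reference: float
    minus_tds: float
    dh_itc: float
    dh_std: float
    dh_cysh: float
    dh_zn_pep: float
    dh_folding: float
    n_h: float
    n_his: int


# ---------------------------------------------------------------------------
# single-site isotherm model
# ---------------------------------------------------------------------------


def _bound_concentration(p_tot, x_tot, n, kb):
    """[complex] for titrant X binding n-fold sites on P with constant kb."""
    sites = n * p_tot
    b = sites + x_tot + 1.0 / kb
    disc = b * b - 4.0 * sites * x_tot
    return 0.5 * (b - math.sqrt(max(disc, 0.0)))


def simulate_isotherm(
    kb: float,
    dh: float,
    n: float,
    design: ItcExperiment,
    dilution_offset: float = 0.0,
) -> np.ndarray:
    """Per-injection heats (ucal) of a single-site titration.

    Exact volume-displacement bookkeeping: the cell volume is constant; each
    injection expels liquid of pre-injection composition, so both cell
    species are diluted by (1 - dV/V0) per injection while the syringe adds
    titrant.  The heat of injection i is dh times the net change in bound
    complex inside the cell (the expelled complex does not contribute).
    """
    if kb <= 0:
        raise ItcError("kb must be positive")
    v0 = design.cell_volume_ml * 1e-3  # L
    p = design.cell_concentration
    x = 0.0
    bound_prev = 0.0
    heats = np.empty(design.injection_volumes_ul.size)
    for i, dv_ul in enumerate(design.injection_volumes_ul):
        dv = dv_ul * 1e-6  # L
        f = 1.0 - dv / v0
        p *= f
        x = x * f + design.syringe_concentration * dv / v0
        bound = _bound_concentration(p, x, n, kb)
        dq_mol = bound * v0 - bound_prev * f * v0  # moles newly bound
        heats[i] = dh * KCAL_TO_UCAL * dq_mol + dilution_offset
        bound_prev = bound
    return heats


def fit_isotherm(exp: ItcExperiment) -> ItcFit:
    """Least-squares (n, Kb, dH, offset) from integrated injection heats."""
    heats = exp.heats_ucal
    if np.allclose(heats, heats[0]):
        raise ItcFitFailure("heats carry no binding signal (unidentifiable)")

    # initial guesses: breakpoint of |heat| decay ~ equivalence
    v0 = exp.cell_volume_ml * 1e-3
    inj_moles = exp.injection_volumes_ul * 1e-6 * exp.syringe_concentration
    cell_moles0 = exp.cell_concentration * v0
    dh0 = float(heats[0] / (KCAL_TO_UCAL * inj_moles[0]))
    ratio = np.cumsum(inj_moles) / cell_moles0
    half = 0.5 * (heats[0] + heats[-1])
    idx = int(np.argmin(np.abs(heats - half)))
    n0 = float(np.clip(ratio[idx], 0.1, 2.0))

    def resid(p):
        n, log10kb, dh, off = p
        model = simulate_isotherm(10.0 ** log10kb, dh, n, exp, off)
        return model - heats

    x0 = np.array([n0, 7.0, dh0, 0.0])
    res = least_squares(
        resid, x0, method="trf",
        bounds=([1e-3, 2.0, -np.inf, -np.inf], [2.0, 15.0, np.inf, np.inf]),
        xtol=1e-12, ftol=1e-12, gtol=1e-12, max_nfev=10000,
    )
    if not res.success:
        raise ItcFitFailure("isotherm fit did not converge", last_iterate=res.x)
    n, log10kb, dh, off = res.x

    m, k = res.jac.shape
    dof = max(m - k, 1)
    s2 = float(res.fun @ res.fun) / dof
    try:
        cov = s2 * np.linalg.inv(res.jac.T @ res.jac)
        se = np.sqrt(np.clip(np.diag(cov), 0.0, None))
    except np.linalg.LinAlgError:
        se = np.full(k, np.nan)
    kb = 10.0 ** log10kb
    stderr = {"stoichiometry_n": se[0], "log10_kb": se[1],
              "kb": kb * math.log(10.0) * se[1],
              "dh_itc": se[2], "dilution_offset": se[3]}
    final_ratio = float(ratio[-1])
    return ItcFit(n, kb, dh, off, stderr=stderr,
                  rss=float(res.fun @ res.fun),
                  saturation_reached=final_ratio >= 1.2 * n)


# ---------------------------------------------------------------------------
# enthalpy decomposition chain
# ---------------------------------------------------------------------------


def buffer_corrected_enthalpy(
    dh_itc: float, n_h: float, constants: ThermoConstants = DEFAULT_CONSTANTS
) -> float:
    """Standard binding enthalpy after removing the buffer-protonation heat.

    dH_std = dH_ITC + n_H * dH_buff.  The n_H protons released by the thiols
    protonate the buffer; that heat is part of the observed exotherm and is
    added back out here.
    """
    return dh_itc + n_h * constants.dh_buff


def cys_deprotonation_enthalpy(
    n_h: float, constants: ThermoConstants = DEFAULT_CONSTANTS
) -> float:
    """Endothermic cost of deprotonating n_H thiol protons (n_H * 8.5)."""
    if not (0.0 <= n_h <= 2.0):
        raise ItcError("n_h must lie in [0, 2] for a two-Cys site")
    return n_h * constants.dh_cysh_per_proton


def zn_pep_enthalpy(dh_std: float, dh_cysh: float) -> float:
    """Enthalpy of Zn(II) binding to the deprotonated peptide."""
    return dh_std - dh_cysh


def folding_enthalpy(
    dh_zn_pep: float, n_his: int, constants: ThermoConstants = DEFAULT_CONSTANTS
) -> float:
    """Residual folding enthalpy after subtracting the four Zn-ligand bonds.

    dH_Zn-pep = (4 - n_His) dH_Zn-S + n_His dH_Zn-N + dH_folding.
    """
    if n_his not in (0, 1, 2, 3, 4):
        raise ItcError("n_his must be an integer in 0..4")
    bonds = (4 - n_his) * constants.dh_zn_s + n_his * constants.dh_zn_n
    return dh_zn_pep - bonds


def gibbs_from_neg_log_kd(
    neg_log_kd: float, constants: ThermoConstants = DEFAULT_CONSTANTS
) -> float:
    """dG_std = -RT ln Kb = -(ln 10) R T (-log10 Kd)."""
    if neg_log_kd < 0:
        raise ItcError("neg_log_kd must be nonnegative")
    return -math.log(10.0) * constants.gas_constant * constants.temperature \
        * neg_log_kd


def entropy_term(dg: float, dh_std: float) -> float:
    """-T dS = dG - dH."""
    return dg - dh_std


def decompose(
    dh_itc: float,
    n_h: float,
    neg_log_kd: float,
    n_his: int,
    constants: ThermoConstants = DEFAULT_CONSTANTS,
    reference_dg: Optional[float] = None,
) -> ThermoDecomposition:
    """Full proton-linkage ledger for one peptide.

    Applies the chain dH_ITC -> dH_std -> dH_Zn-pep -> dH_folding plus dG
    from the competition -logKd and the entropic term; ddg_vs_reference is
    reported against reference_dg when given (0 otherwise).
    """
    dh_std = buffer_corrected_enthalpy(dh_itc, n_h, constants)
    dh_cysh = cys_deprotonation_enthalpy(n_h, constants)
    dh_zp = zn_pep_enthalpy(dh_std, dh_cysh)
    dh_fold = folding_enthalpy(dh_zp, n_his, constants)
    dg = gibbs_from_neg_log_kd(neg_log_kd, constants)
    return ThermoDecomposition(
        dg=dg,
        ddg_vs_reference=(dg - reference_dg) if reference_dg is not None else 0.0,
        minus_tds=entropy_term(dg, dh_std),
        dh_itc=dh_itc,
        dh_std=dh_std,
        dh_cysh=dh_cysh,
        dh_zn_pep=dh_zp,
        dh_folding=dh_fold,
        n_h=n_h,
        n_his=n_his,
    )
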