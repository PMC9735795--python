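"""Spectrophotometric pKa fitting and chelator-competition Hill/Kd analysis.

Classical CCHH zinc fingers bind Zn(II) through two cysteine thiolates whose
acid-dissociation behaviour is read out spectrophotometrically (thiolate
absorbance near 218 nm rises as the thiols deprotonate).  The two macroscopic
pKa values fitted here feed the proton-linkage correction of the ITC analysis
(the average thiol protonation n_H at the working pH).  Zn(II) affinity itself
is measured by competition against chelator metal buffers: mean residue
ellipticity versus free Zn(II) is fitted to a Hill saturation curve, and the
free Zn(II) at half-saturation is the apparent dissociation constant.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.optimize import least_squares

__all__ = [
    "PhTitrationCurve",
    "PkaFit",
    "CompetitionSeries",
    "HillFit",
    "KdResult",
    "TitrationError",
    "InsufficientDataError",
    "FitFailureError",
    "UnidentifiableFitError",
    "predict_titration_absorbance",
    "fit_pka",
    "average_protonation",
    "predict_hill",
    "fit_hill",
    "kd_from_hill",
]


class TitrationError(ValueError):
    """Base class for titration-analysis errors."""


class InsufficientDataError(TitrationError):
    """Too few points to constrain the model."""


class FitFailureError(TitrationError):
    """Nonlinear fit did not converge; carries the last iterate."""

    def __init__(self, message: str, last_iterate=None):
        super().__init__(message)
        self.last_iterate = last_iterate


class UnidentifiableFitError(TitrationError):
    """Data do not span the transition needed to identify the parameters."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass
class PhTitrationCurve:
    """pH-titration trace of a metal-free peptide at a single wavelength."""

    peptide_id: str
    ph: np.ndarray
    absorbance: np.ndarray
    wavelength: float = 218.0

    def __post_init__(self):
        self.ph = np.asarray(self.ph, dtype=float)
        self.absorbance = np.asarray(self.absorbance, dtype=float)
        if self.ph.shape != self.absorbance.shape:
            raise TitrationError("pH and absorbance arrays must match in length")
        if self.ph.size < 8:
            raise InsufficientDataError(
                f"need at least 8 titration points, got {self.ph.size}"
            )
        if not np.all(np.diff(self.ph) > 0):
            raise TitrationError("pH values must be strictly increasing")
        if not np.all(np.isfinite(self.absorbance)):
            raise TitrationError("absorbance values must be finite")


@dataclass
class PkaFit:
    """Macroscopic two-proton dissociation fit (three plateaus, two pKa)."""

    pk1: float
    pk2: float
    a0: float
    a1: float
    a2: float
    stderr: dict = field(default_factory=dict)
    rss: float = float("nan")
    in_range: bool = True  # pK within sampled pH range +/- 1, else flagged

    def as_array(self) -> np.ndarray:
        return np.array([self.pk1, self.pk2, self.a0, self.a1, self.a2])


@dataclass
class CompetitionSeries:
    """Ellipticity vs pZn competition series (replicates already averaged)."""

    peptide_id: str
    pzn: np.ndarray
    ellipticity: np.ndarray
    wavelength: float = 220.0
    replicate_count: int = 1

    def __post_init__(self):
        self.pzn = np.asarray(self.pzn, dtype=float)
        self.ellipticity = np.asarray(self.ellipticity, dtype=float)
        if self.pzn.shape != self.ellipticity.shape:
            raise TitrationError("pzn and ellipticity arrays must match")
        if len(set(self.pzn.tolist())) != self.pzn.size:
            raise TitrationError("pzn values must be distinct")

    @staticmethod
    def from_replicates(
        peptide_id: str,
        pzn: Sequence[float],
        ellipticity_replicates: Sequence[Sequence[float]],
        wavelength: float = 220.0,
    ) -> "CompetitionSeries":
        """Average replicate readings per point before fitting."""
        reps = np.asarray(ellipticity_replicates, dtype=float)
        return CompetitionSeries(
            peptide_id,
            np.asarray(pzn, dtype=float),
            reps.mean(axis=0) if reps.ndim == 2 else reps,
            wavelength,
            replicate_count=reps.shape[0] if reps.ndim == 2 else 1,
        )


@dataclass
class HillFit:
    """Hill saturation parameters; zn_half is free Zn(II) at half-saturation."""

    theta_min: float
    theta_max: float
    hill_n: float
    zn_half: float
    stderr: dict = field(default_factory=dict)
    rss: float = float("nan")


@dataclass
class KdResult:
    """Apparent dissociation constant of the Zn-peptide complex."""

    kd: float
    neg_log_kd: float
    ph: float = 7.4
    method: str = "competition"


# ---------------------------------------------------------------------------
# two-proton titration model
# ---------------------------------------------------------------------------


def predict_titration_absorbance(fit: PkaFit, ph) -> np.ndarray | float:
    """Absorbance of the two-proton dissociation model.

    A = (A0 + A1*10^(pH-pK1) + 2*A2*10^(2pH-pK1-pK2))
        / (1 + 10^(pH-pK1) + 2*10^(2pH-pK1-pK2))

    The statistical factor 2 on the doubly deprotonated term follows the
    macroscopic two-site formulation used for the fits.
    """
    params = fit.as_array()
    if not np.all(np.isfinite(params)):
        raise TitrationError("non-finite fit parameters")
    return _eval_titration(fit.pk1, fit.pk2, fit.a0, fit.a1, fit.a2, ph)


def _eval_titration(pk1, pk2, a0, a1, a2, ph):
    ph = np.asarray(ph, dtype=float)
    # exponents can overflow float64 at extreme pH; clip harmlessly
    t1 = np.power(10.0, np.clip(ph - pk1, -300, 300))
    t2 = 2.0 * np.power(10.0, np.clip(2.0 * ph - pk1 - pk2, -300, 300))
    out = (a0 + a1 * t1 + a2 * t2) / (1.0 + t1 + t2)
    return float(out) if out.ndim == 0 else out


def fit_pka(curve: PhTitrationCurve, init: Optional[PkaFit] = None) -> PkaFit:
    """Least-squares fit of the two-proton model to a titration curve.

    Default initialization takes the plateau guesses from the curve extremes
    and places the two pKa at the 1/3 and 2/3 quantiles of the pH range.
    Exit convention: pK1 <= pK2 (the model is symmetric under exchange).
    """
    if curve.ph.size < 5:
        raise InsufficientDataError("fewer than 5 points")
    span = float(curve.absorbance.max() - curve.absorbance.min())
    if span == 0.0 or span < 1e-12 * max(1.0, abs(float(curve.absorbance.max()))):
        raise UnidentifiableFitError("flat curve: pKa values unidentifiable")

    if init is None:
        lo, hi = float(curve.ph.min()), float(curve.ph.max())
        init = PkaFit(
            pk1=lo + (hi - lo) / 3.0,
            pk2=lo + 2.0 * (hi - lo) / 3.0,
            a0=float(curve.absorbance.min()),
            a1=float(curve.absorbance.min() + 0.5 * span),
            a2=float(curve.absorbance.max()),
        )

    def resid(p):
        return _eval_titration(*p, curve.ph) - curve.absorbance

    x0 = np.array([init.pk1, init.pk2, init.a0, init.a1, init.a2])
    res = least_squares(resid, x0, method="trf", xtol=1e-10, ftol=1e-10,
                        gtol=1e-10, max_nfev=10000)
    if not res.success:
        raise FitFailureError("pKa fit did not converge", last_iterate=res.x)

    pk1, pk2, a0, a1, a2 = res.x
    if pk1 > pk2:  # ordering convention: swap labels on exit
        pk1, pk2 = pk2, pk1
    stderr = _stderr_from_jac(res)
    rss = float(res.fun @ res.fun)
    lo, hi = float(curve.ph.min()), float(curve.ph.max())
    in_range = (lo - 1.0 <= pk1 <= hi + 1.0) and (lo - 1.0 <= pk2 <= hi + 1.0)
    names = ["pk1", "pk2", "a0", "a1", "a2"]
    return PkaFit(pk1, pk2, a0, a1, a2,
                  stderr=dict(zip(names, stderr)), rss=rss, in_range=in_range)


def _stderr_from_jac(res) -> np.ndarray:
    """Asymptotic standard errors from the final Jacobian."""
    m, n = res.jac.shape
    dof = max(m - n, 1)
    s2 = float(res.fun @ res.fun) / dof
    try:
        cov = s2 * np.linalg.inv(res.jac.T @ res.jac)
        return np.sqrt(np.clip(np.diag(cov), 0.0, None))
    except np.linalg.LinAlgError:
        return np.full(n, np.nan)


def average_protonation(pk1: float, pk2: float, ph: float) -> float:
    """Average number of protons on the two-thiol system at the given pH.

    Macroscopic two-proton partition-function average:

        n_H = (10^(pK2-pH) + 2*10^(pK1+pK2-2pH))
              / (1 + 10^(pK2-pH) + 10^(pK1+pK2-2pH))

    bounded in [0, 2] and monotone nonincreasing in pH.
    """
    for v in (pk1, pk2, ph):
        if not math.isfinite(v):
            raise TitrationError("non-finite input")
    x = 10.0 ** min(pk2 - ph, 300.0)
    y = 10.0 ** min(pk1 + pk2 - 2.0 * ph, 300.0)
    return (x + 2.0 * y) / (1.0 + x + y)


# ---------------------------------------------------------------------------
# Hill competition model
# ---------------------------------------------------------------------------


def predict_hill(fit: HillFit, free_zn) -> np.ndarray | float:
    """Hill saturation value at a free Zn(II) concentration x (molar).

    Theta = Theta_min * x^n / (x^n + zn_half^n)
          + Theta_max * zn_half^n / (x^n + zn_half^n)

    Theta_max is the zero-zinc (apo) limit and Theta_min the saturated limit;
    with increasing free Zn the signal moves from Theta_max to Theta_min.
    """
    x = np.asarray(free_zn, dtype=float)
    if np.any(x < 0):
        raise TitrationError("free_zn must be nonnegative")
    out = _eval_hill(fit.theta_min, fit.theta_max, fit.hill_n, fit.zn_half, x)
    return float(out) if out.ndim == 0 else out


def _eval_hill(theta_min, theta_max, n, zn_half, x):
    x = np.asarray(x, dtype=float)
    # work with the saturation fraction to stay stable over wide pZn ranges
    with np.errstate(divide="ignore"):
        ratio = np.where(x > 0, (x / zn_half) ** n, 0.0)
    frac = ratio / (1.0 + ratio)  # x^n / (x^n + zn_half^n)
    return theta_min * frac + theta_max * (1.0 - frac)


def fit_hill(series: CompetitionSeries, init: Optional[HillFit] = None) -> HillFit:
    """Least-squares Hill fit of a competition series (fits in pZn space)."""
    if series.pzn.size < 6:
        raise InsufficientDataError("need at least 6 competition points")
    if series.pzn.max() - series.pzn.min() < 2.0:
        raise InsufficientDataError("series must span at least 2 pZn units")
    theta = series.ellipticity
    span = float(theta.max() - theta.min())
    if span == 0:
        raise UnidentifiableFitError("constant ellipticity")
    order = np.argsort(series.pzn)
    t_sorted = theta[order]

    if init is None:
        # midpoint guess: pzn where signal crosses mid-range
        mid = 0.5 * (theta.max() + theta.min())
        idx = int(np.argmin(np.abs(t_sorted - mid)))
        pzn_half = float(series.pzn[order][idx])
        # identify which plateau is apo: high pZn = low free Zn = Theta_max
        hi_pzn_theta = float(t_sorted[-1])
        lo_pzn_theta = float(t_sorted[0])
        init = HillFit(theta_min=lo_pzn_theta, theta_max=hi_pzn_theta,
                       hill_n=1.0, zn_half=10.0 ** (-pzn_half))

    # parameterize zn_half as -log10 for conditioning
    def resid(p):
        tmin, tmax, n, plzh = p
        return _eval_hill(tmin, tmax, n, 10.0 ** (-plzh),
                          10.0 ** (-series.pzn)) - theta

    x0 = np.array([init.theta_min, init.theta_max, init.hill_n,
                   -math.log10(init.zn_half)])
    res = least_squares(resid, x0, method="trf",
                        bounds=([-np.inf, -np.inf, 1e-3, 0.0],
                                [np.inf, np.inf, 10.0, 25.0]),
                        xtol=1e-12, ftol=1e-12, gtol=1e-12, max_nfev=10000)
    if not res.success:
        raise FitFailureError("Hill fit did not converge", last_iterate=res.x)
    tmin, tmax, n, plzh = res.x
    # identifiability: the half-saturation point must lie inside the sampled
    # pZn window and the data must traverse >= 20% of the fitted amplitude
    amplitude = abs(tmax - tmin)
    observed = abs(t_sorted[0] - t_sorted[-1])
    if not (series.pzn.min() <= plzh <= series.pzn.max()) or (
            amplitude > 0 and observed < 0.2 * amplitude):
        raise UnidentifiableFitError(
            "series does not span the saturation transition"
        )
    stderr_raw = _stderr_from_jac(res)
    zn_half = 10.0 ** (-plzh)
    # delta-method error for zn_half from the -log10 parameterization
    se = dict(zip(["theta_min", "theta_max", "hill_n", "neg_log_zn_half"],
                  stderr_raw))
    se["zn_half"] = zn_half * math.log(10.0) * se["neg_log_zn_half"]
    return HillFit(tmin, tmax, n, zn_half, stderr=se,
                   rss=float(res.fun @ res.fun))


def kd_from_hill(fit: HillFit, ph: float = 7.4) -> KdResult:
    """Dissociation constant from the half-saturation free Zn(II).

    For 1:1 binding Zn + L <-> ZnL, Kd = [Zn][L]/[ZnL]; at half-saturation
    [L] = [ZnL], so Kd equals the free Zn(II) concentration there.
    """
    if not (fit.zn_half > 0):
        raise TitrationError("zn_half must be positive")
    return KdResult(kd=fit.zn_half, neg_log_kd=-math.log10(fit.zn_half), ph=ph)
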