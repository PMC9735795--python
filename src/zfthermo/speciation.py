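"""Free-Zn(II) speciation in chelator metal buffers at fixed pH.

Competition experiments clamp free Zn(II) at sub-nanomolar levels with a
chelator/Zn "metal buffer".  The free concentration is never measured; it is
computed from the chelator's stability constants.  This module does that
computation with the standard conditional-constant treatment: at fixed pH the
chelator's protonation equilibria are folded into a side-reaction coefficient
alpha_H(L), giving a single effective 1:1 complexation constant beta', and the
two mass balances

    Zn_tot = [Zn] + beta'[Zn][L'],    L_tot = [L'] + beta'[Zn][L']

are solved for [Zn] and [L'] (L' = ligand summed over protonation states).
An optional correction subtracts the Zn(II) taken up by the zinc-finger
peptide, iterated to a fixed point when the peptide Kd is known.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

__all__ = [
    "Chelator",
    "MetalBuffer",
    "SpeciationResult",
    "SpeciationError",
    "InfeasibleBufferError",
    "NumericalFailureError",
    "proton_side_coefficient",
    "conditional_beta",
    "solve_free_zn",
    "peptide_corrected_pzn",
    "competition_pzn_series",
]


class SpeciationError(ValueError):
    pass


class InfeasibleBufferError(SpeciationError):
    pass


class NumericalFailureError(SpeciationError):
    def __init__(self, message, residuals=None):
        super().__init__(message)
        self.residuals = residuals


@dataclass
class Chelator:
    """A 1:1 Zn(II) chelator with stepwise protonation constants.

    log_protonation_constants are log10 stepwise proton-association constants
    (logK1 = log [HL]/([H][L]), etc.), ordered nonincreasing.  log_beta_znl is
    the log10 formation constant of ZnL; log_beta_znhl optionally adds the
    protonated ternary complex ZnHL (beta referred to Zn + H + L).
    """

    name: str
    log_protonation_constants: Sequence[float]
    log_beta_znl: float
    log_beta_znhl: Optional[float] = None
    reference: str = ""

    def __post_init__(self):
        ks = list(self.log_protonation_constants)
        if any(b > a + 1e-9 for a, b in zip(ks, ks[1:])):
            raise SpeciationError(
                f"{self.name}: protonation constants must be nonincreasing"
            )
        if not math.isfinite(self.log_beta_znl):
            raise SpeciationError(f"{self.name}: log_beta_znl must be finite")


@dataclass
class MetalBuffer:
    chelator: Chelator
    total_chelator: float  # molar
    total_zn: float  # molar
    ph: float
    peptide_total: Optional[float] = None
    peptide_kd: Optional[float] = None

    def __post_init__(self):
        if self.total_chelator <= 0:
            raise SpeciationError("total_chelator must be positive")
        if self.total_zn < 0:
            raise SpeciationError("total_zn must be nonnegative")
        if not (2.0 <= self.ph <= 12.0):
            raise SpeciationError("pH must lie in [2, 12]")


@dataclass
class SpeciationResult:
    free_zn: float
    pzn: float
    species: dict = field(default_factory=dict)
    mass_balance_residuals: tuple = (0.0, 0.0)
    iterations: int = 0
    degenerate: bool = False


def proton_side_coefficient(chelator: Chelator, ph: float) -> float:
    """Side-reaction coefficient alpha_H(L) = 1 + sum_i 10^(sum_{j<=i} logK_j - i*pH).

    Equals 1 when protonation is negligible at the working pH.
    """
    alpha = 1.0
    cum = 0.0
    for i, logk in enumerate(chelator.log_protonation_constants, start=1):
        cum += logk
        alpha += 10.0 ** (cum - i * ph)
    return alpha


def conditional_beta(chelator: Chelator, ph: float) -> float:
    """Conditional 1:1 formation constant beta' = ([ZnL]+[ZnHL])/([Zn][L']).

    beta' = (10^log_beta_znl + 10^(log_beta_znhl - pH)) / alpha_H(L); the
    ZnHL term is included only when the chelator defines it.
    """
    alpha = proton_side_coefficient(chelator, ph)
    beta = 10.0 ** chelator.log_beta_znl
    if chelator.log_beta_znhl is not None:
        beta += 10.0 ** (chelator.log_beta_znhl - ph)
    return beta / alpha


def _solve_pair(beta: float, zn_tot: float, l_tot: float,
                max_iter: int = 200) -> tuple[float, float, int]:
    """Solve Zn_tot = z + beta*z*l, L_tot = l + beta*z*l for z, l > 0.

    Damped Newton iteration on (log z, log l), started from the
    excess-ligand closed form.  Halves the step whenever the residual
    norm increases, which keeps both variables positive throughout.
    """
    # excess-ligand start: l ~ L_tot - Zn_tot (or small fraction), z from balance
    l0 = max(l_tot - zn_tot, 1e-6 * l_tot)
    z0 = zn_tot / (1.0 + beta * l0)
    u = np.array([math.log(max(z0, 1e-300)), math.log(max(l0, 1e-300))])

    def residual(u):
        z, l = np.exp(u)
        c = beta * z * l
        return np.array([(z + c - zn_tot) / zn_tot,
                         (l + c - l_tot) / l_tot]), z, l, c

    r, z, l, c = residual(u)
    it = 0
    for it in range(1, max_iter + 1):
        if np.max(np.abs(r)) < 1e-12:
            break
        # Jacobian wrt (log z, log l)
        J = np.array([[(z + c) / zn_tot, c / zn_tot],
                      [c / l_tot, (l + c) / l_tot]])
        try:
            step = np.linalg.solve(J, -r)
        except np.linalg.LinAlgError:
            raise NumericalFailureError("singular Jacobian", residuals=r)
        step = np.clip(step, -5.0, 5.0)
        norm0 = float(np.max(np.abs(r)))
        scale = 1.0
        for _ in range(60):
            r_new, z_n, l_n, c_n = residual(u + scale * step)
            if float(np.max(np.abs(r_new))) < norm0:
                break
            scale *= 0.5
        u = u + scale * step
        r, z, l, c = residual(u)
    else:
        if np.max(np.abs(r)) > 1e-8:
            raise NumericalFailureError(
                "speciation solver did not converge", residuals=r
            )
    return float(np.exp(u[0])), float(np.exp(u[1])), it


def solve_free_zn(buffer: MetalBuffer) -> SpeciationResult:
    """Free Zn(II) and species concentrations in a chelator metal buffer."""
    beta = conditional_beta(buffer.chelator, buffer.ph)
    if buffer.total_zn == 0.0:
        return SpeciationResult(
            free_zn=1e-300, pzn=300.0,
            species={"Zn": 0.0, "L'": buffer.total_chelator, "ZnL'": 0.0},
            degenerate=True,
        )
    z, l, it = _solve_pair(beta, buffer.total_zn, buffer.total_chelator)
    c = beta * z * l
    res = (
        abs(z + c - buffer.total_zn) / buffer.total_zn,
        abs(l + c - buffer.total_chelator) / buffer.total_chelator,
    )
    return SpeciationResult(
        free_zn=z, pzn=-math.log10(z),
        species={"Zn": z, "L'": l, "ZnL'": c},
        mass_balance_residuals=res, iterations=it,
    )


def peptide_corrected_pzn(
    buffer: MetalBuffer, saturation_fraction: Optional[float] = None
) -> SpeciationResult:
    """Re-solve the buffer after removing Zn(II) bound by the peptide.

    With a fixed saturation fraction this is a single corrected solve.  When
    the buffer carries a peptide Kd, the saturation is recomputed from the
    current free Zn (f = z/(z + Kd)) and the solve iterated to a fixed point
    (|delta pZn| < 1e-6).
    """
    if buffer.peptide_total is None:
        raise SpeciationError("peptide_total must be set for the correction")
    p_tot = buffer.peptide_total

    if saturation_fraction is None:
        if buffer.peptide_kd is None:
            raise SpeciationError(
                "either saturation_fraction or peptide_kd is required"
            )
        sat = 1.0  # start from full saturation (high-affinity peptide)
    else:
        if not (0.0 <= saturation_fraction <= 1.0):
            raise SpeciationError("saturation_fraction must lie in [0, 1]")
        sat = saturation_fraction

    prev_pzn = None
    result = None
    for it in range(100):
        zn_eff = buffer.total_zn - sat * p_tot
        if zn_eff <= 0:
            raise InfeasibleBufferError(
                "peptide uptake exceeds total Zn in the buffer"
            )
        corrected = MetalBuffer(buffer.chelator, buffer.total_chelator,
                                zn_eff, buffer.ph)
        result = solve_free_zn(corrected)
        result.species["Zn-peptide"] = sat * p_tot
        if saturation_fraction is not None or buffer.peptide_kd is None:
            return result
        if prev_pzn is not None and abs(result.pzn - prev_pzn) < 1e-6:
            result.iterations = it + 1
            return result
        prev_pzn = result.pzn
        sat = result.free_zn / (result.free_zn + buffer.peptide_kd)
    raise NumericalFailureError("peptide correction did not reach a fixed point")


def competition_pzn_series(
    chelator: Chelator, l_tot: float, zn_tots: Sequence[float], ph: float
) -> list[tuple[float, float]]:
    """pZn for a series of total-Zn loadings at fixed chelator and pH."""
    if len(zn_tots) == 0:
        raise SpeciationError("zn_tots must be nonempty")
    out = []
    for zn_tot in zn_tots:
        res = solve_free_zn(MetalBuffer(chelator, l_tot, zn_tot, ph))
        out.append((float(zn_tot), res.pzn))
    return out
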