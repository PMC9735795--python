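"""End-to-end orchestration: per-peptide Kd and thermodynamic ledgers.

Runs the full chain for a set of peptides — thiol pKa fit, average
protonation at the working pH, competition Hill fit, Kd, and the ITC
proton-linkage decomposition — then assembles affinity (Kd) and energetics
tables with difference columns against a reference peptide and
internal-consistency validation of every ledger.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from typing import Optional, Sequence

import pandas as pd

from .itc import (
    DEFAULT_CONSTANTS,
    ItcExperiment,
    ThermoConstants,
    ThermoDecomposition,
    decompose,
    fit_isotherm,
)
from .titration import (
    CompetitionSeries,
    PhTitrationCurve,
    average_protonation,
    fit_hill,
    fit_pka,
    kd_from_hill,
)

__all__ = ["PeptideRecord", "RunReport", "run_pipeline", "validate_ledger"]


@dataclass
class PeptideRecord:
    """Inputs for one peptide; stages may be supplied as data or as values.

    Each analysis stage accepts either its raw input (titration curve,
    competition series, ITC experiment) or an already-determined value
    (pk1/pk2, neg_log_kd, dh_itc), so partially measured peptides still
    produce a row.
    """

    peptide_id: str
    n_his: int = 2  # CCHH coordination
    titration: Optional[PhTitrationCurve] = None
    pk1: Optional[float] = None
    pk2: Optional[float] = None
    competition: Optional[CompetitionSeries] = None
    neg_log_kd: Optional[float] = None
    itc: Optional[ItcExperiment] = None
    dh_itc: Optional[float] = None
    ph: float = 7.4


@dataclass
class RunReport:
    reference_id: str
    kd_results: dict = field(default_factory=dict)
    decompositions: dict = field(default_factory=dict)
    flags: dict = field(default_factory=dict)
    metadata: dict = field(default_factory=dict)

    def table1(self) -> pd.DataFrame:
        """Affinity table: peptide, -logKd, Kd in fM, delta(-logKd) vs reference."""
        ref = self.kd_results.get(self.reference_id)
        rows = []
        for pid, kd in self.kd_results.items():
            rows.append({
                "peptide": pid,
                "neg_log_kd": kd.neg_log_kd,
                "kd_fM": kd.kd * 1e15,
                "delta_neg_log_kd": (ref.neg_log_kd - kd.neg_log_kd)
                if ref is not None else float("nan"),
            })
        return pd.DataFrame(rows)

    def table2(self) -> pd.DataFrame:
        """Energetics ledger: dG, ddG, -TdS, dH_ITC, dH, dH_CysH, dH_Zn-pep,
        dH_folding, n_H per peptide."""
        rows = []
        for pid, d in self.decompositions.items():
            rows.append({
                "peptide": pid, "dg": d.dg, "ddg": d.ddg_vs_reference,
                "minus_tds": d.minus_tds, "dh_itc": d.dh_itc,
                "dh_std": d.dh_std, "dh_cysh": d.dh_cysh,
                "dh_zn_pep": d.dh_zn_pep, "dh_folding": d.dh_folding,
                "n_h": d.n_h, "n_his": d.n_his,
            })
        return pd.DataFrame(rows)

    def to_json(self) -> str:
        return json.dumps({
            "reference_id": self.reference_id,
            "table1": self.table1().to_dict(orient="records"),
            "table2": self.table2().to_dict(orient="records"),
            "flags": self.flags,
            "metadata": self.metadata,
        }, indent=2)


def validate_ledger(
    decomp: ThermoDecomposition,
    tol: float = 0.05,
    constants: ThermoConstants = DEFAULT_CONSTANTS,
) -> list[str]:
    """Check the three internal identities of a thermodynamic ledger.

    Returns a list of human-readable violations (empty iff consistent
    within tol kcal/mol): dG = dH + (-TdS); dH = dH_Zn-pep + dH_CysH; and
    the bond-enthalpy identity for dH_Zn-pep.
    """
    v = []
    r1 = decomp.dg - (decomp.dh_std + decomp.minus_tds)
    if abs(r1) > tol:
        v.append(f"dG != dH + (-TdS): residual {r1:+.3f} kcal/mol")
    r2 = decomp.dh_std - (decomp.dh_zn_pep + decomp.dh_cysh)
    if abs(r2) > tol:
        v.append(f"dH != dH_Zn-pep + dH_CysH: residual {r2:+.3f} kcal/mol")
    bonds = (4 - decomp.n_his) * constants.dh_zn_s + decomp.n_his * constants.dh_zn_n
    r3 = decomp.dh_zn_pep - (bonds + decomp.dh_folding)
    if abs(r3) > tol:
        v.append(f"dH_Zn-pep bond identity: residual {r3:+.3f} kcal/mol")
    return v


def _stage_kd(rec: PeptideRecord, flags: list):
    if rec.neg_log_kd is not None:
        from .titration import KdResult

        return KdResult(kd=10.0 ** (-rec.neg_log_kd),
                        neg_log_kd=rec.neg_log_kd, ph=rec.ph)
    if rec.competition is not None:
        return kd_from_hill(fit_hill(rec.competition), ph=rec.ph)
    flags.append("no competition data: Kd unavailable")
    return None


def _stage_nh(rec: PeptideRecord, flags: list):
    pk1, pk2 = rec.pk1, rec.pk2
    if (pk1 is None or pk2 is None) and rec.titration is not None:
        fit = fit_pka(rec.titration)
        pk1, pk2 = fit.pk1, fit.pk2
    if pk1 is None or pk2 is None:
        flags.append("no pKa inputs: n_H unavailable")
        return None
    return average_protonation(pk1, pk2, rec.ph)


def _stage_dh_itc(rec: PeptideRecord, flags: list):
    if rec.dh_itc is not None:
        return rec.dh_itc
    if rec.itc is not None:
        return fit_isotherm(rec.itc).dh_itc
    flags.append("no ITC input: enthalpy ledger unavailable")
    return None


def run_pipeline(
    records: Sequence[PeptideRecord],
    reference_id: Optional[str] = None,
    constants: ThermoConstants = DEFAULT_CONSTANTS,
) -> RunReport:
    """Run every stage for every peptide; failures are recorded, not fatal.

    The reference for the difference columns defaults to the
    highest-affinity peptide (largest -logKd) when not named explicitly.
    """
    ids = [r.peptide_id for r in records]
    if len(set(ids)) != len(ids):
        raise ValueError("peptide_id values must be unique")
    if reference_id is not None and reference_id not in ids:
        raise ValueError(f"reference {reference_id!r} not among records")

    kd_results: dict = {}
    nh: dict = {}
    dh: dict = {}
    flags: dict = {pid: [] for pid in ids}
    for rec in records:
        try:
            res = _stage_kd(rec, flags[rec.peptide_id])
            if res is not None:
                kd_results[rec.peptide_id] = res
        except Exception as exc:  # a failed stage must not abort the run
            flags[rec.peptide_id].append(f"Kd stage failed: {exc}")
        try:
            v = _stage_nh(rec, flags[rec.peptide_id])
            if v is not None:
                nh[rec.peptide_id] = v
        except Exception as exc:
            flags[rec.peptide_id].append(f"pKa stage failed: {exc}")
        try:
            v = _stage_dh_itc(rec, flags[rec.peptide_id])
            if v is not None:
                dh[rec.peptide_id] = v
        except Exception as exc:
            flags[rec.peptide_id].append(f"ITC stage failed: {exc}")

    if reference_id is None:
        if not kd_results:
            raise ValueError("no Kd results to pick a reference from")
        reference_id = max(kd_results, key=lambda p: kd_results[p].neg_log_kd)

    ref_kd = kd_results.get(reference_id)
    ref_dg = None
    if ref_kd is not None:
        from .itc import gibbs_from_neg_log_kd

        ref_dg = gibbs_from_neg_log_kd(ref_kd.neg_log_kd, constants)

    decomps: dict = {}
    for rec in records:
        pid = rec.peptide_id
        if pid in kd_results and pid in nh and pid in dh:
            d = decompose(dh[pid], nh[pid], kd_results[pid].neg_log_kd,
                          rec.n_his, constants, reference_dg=ref_dg)
            decomps[pid] = d
            viol = validate_ledger(d, constants=constants)
            if viol:
                flags[pid].extend(viol)

    meta = {
        "reference_id": reference_id,
        "records_digest": hashlib.sha256(
            json.dumps(ids, sort_keys=True).encode()).hexdigest()[:16],
    }
    return RunReport(reference_id=reference_id, kd_results=kd_results,
                     decompositions=decomps,
                     flags={p: f for p, f in flags.items() if f},
                     metadata=meta)
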