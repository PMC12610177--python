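"""Factorial integration: maintenance + carcass growth + feather growth.

The daily requirement of each amino acid at age t (days) decomposes as

    AAR(t) = C * BW(t)**0.75 * AAm / AAD(t) / 1000
           + PRc(t) * AAc / APD(t)
           + PRf(t) * AAf / APD(t)

with C the phase-specific maintenance coefficient (mg protein/g^0.75/day,
hence the /1000 to grams), AAm/AAc/AAf the maintenance, carcass and
feather amino-acid patterns (fractions of crude protein), PRc/PRf the
analytic protein deposition rates (g/day), AAD and APD the apparent
amino-acid and protein digestibility fractions at age t. The maintenance
term is divided by the pooled amino-acid digestibility and both growth
terms by the protein digestibility.

Two maintenance phases apply: brooding (0-6 weeks) and early growing
(7-12 weeks), switching at a configurable age boundary (default 42 days,
inclusive to brooding).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import pandas as pd

from .allometry import AllometricParams, deposition_rate
from .composition import AMINO_ACIDS, AminoAcidProfile
from .digestibility import DigestibilityCurve, predict_digestibility
from .growth import GrowthParams, predict_bw
from .nitrogen_balance import METABOLIC_EXPONENT, MaintenancePhase

__all__ = [
    "ModelBundle",
    "RequirementRow",
    "phase_for_age",
    "maintenance_requirement",
    "growth_requirement",
    "requirement_table",
    "compare_to_reference",
    "phase_boundary_jump",
]


@dataclass(frozen=True)
class ModelBundle:
    """All fitted sub-models needed to evaluate the factorial model."""

    growth: GrowthParams
    carcass_allom: AllometricParams
    feather_allom: AllometricParams
    brooding: MaintenancePhase
    early_growing: MaintenancePhase
    aac: AminoAcidProfile
    aaf: AminoAcidProfile
    apd_curve: DigestibilityCurve
    aad_curve: DigestibilityCurve
    phase_boundary_days: float = 42.0

    def __post_init__(self) -> None:
        if not (0.0 < self.phase_boundary_days <= 84.0):
            raise ValueError("phase boundary must lie in (0, 84] days")


@dataclass(frozen=True)
class RequirementRow:
    """Requirements at one age: per-amino-acid components plus scalars."""

    age_days: float
    bw: float
    pr_m: float  # maintenance protein, g/day
    pr_c: float  # carcass protein deposition, g/day
    pr_f: float  # feather protein deposition, g/day
    maintenance_g_d: Mapping[str, float]
    carcass_g_d: Mapping[str, float]
    feather_g_d: Mapping[str, float]

    @property
    def total_g_d(self) -> dict[str, float]:
        return {
            aa: self.maintenance_g_d[aa] + self.carcass_g_d[aa] + self.feather_g_d[aa]
            for aa in AMINO_ACIDS
        }


def phase_for_age(bundle: ModelBundle, t: float) -> MaintenancePhase:
    """Maintenance phase applicable at age ``t`` (boundary goes to brooding)."""
    if t < 0:
        raise ValueError("age must be non-negative")
    return bundle.brooding if t <= bundle.phase_boundary_days else bundle.early_growing


def maintenance_requirement(
    bundle: ModelBundle, t: float
) -> tuple[dict[str, float], float]:
    """Per-amino-acid maintenance requirement (g/day) and pr_m at age t.

    pr_m = C * BW(t)**0.75 in mg/day, converted to g/day; each amino acid
    gets pr_m * AAm/100 divided by the amino-acid digestibility AAD(t).
    """
    phase = phase_for_age(bundle, t)
    bw = predict_bw(bundle.growth, t)
    pr_m = phase.C * bw**METABOLIC_EXPONENT / 1000.0  # g/day
    aad = predict_digestibility(bundle.aad_curve, t)
    per_aa = {aa: pr_m * phase.aam[aa] / 100.0 / aad for aa in AMINO_ACIDS}
    return per_aa, float(pr_m)


def growth_requirement(
    bundle: ModelBundle, t: float
) -> tuple[dict[str, float], dict[str, float], float, float]:
    """Carcass and feather growth requirements (g/day) plus PRc, PRf at age t."""
    rates = deposition_rate(bundle.growth, bundle.carcass_allom, bundle.feather_allom, t)
    apd = predict_digestibility(bundle.apd_curve, t)
    carcass = {aa: rates.pr_c * bundle.aac[aa] / 100.0 / apd for aa in AMINO_ACIDS}
    feather = {aa: rates.pr_f * bundle.aaf[aa] / 100.0 / apd for aa in AMINO_ACIDS}
    return carcass, feather, rates.pr_c, rates.pr_f


def requirement_row(bundle: ModelBundle, t: float) -> RequirementRow:
    maint, pr_m = maintenance_requirement(bundle, t)
    carcass, feather, pr_c, pr_f = growth_requirement(bundle, t)
    return RequirementRow(
        age_days=float(t),
        bw=float(predict_bw(bundle.growth, t)),
        pr_m=pr_m,
        pr_c=pr_c,
        pr_f=pr_f,
        maintenance_g_d=maint,
        carcass_g_d=carcass,
        feather_g_d=feather,
    )


def requirement_table(bundle: ModelBundle, ages: Iterable[float]) -> pd.DataFrame:
    """Tidy requirement table: one row per (age, amino acid).

    Columns: age_days, amino_acid, maintenance_g_d, carcass_g_d,
    feather_g_d, total_g_d, plus per-age scalars bw, pr_m, pr_c, pr_f.
    Totals are exact component sums.
    """
    records = []
    for t in ages:
        if t < 0:
            raise ValueError("ages must be non-negative")
        row = requirement_row(bundle, float(t))
        for aa in AMINO_ACIDS:
            records.append(
                {
                    "age_days": row.age_days,
                    "amino_acid": aa,
                    "maintenance_g_d": row.maintenance_g_d[aa],
                    "carcass_g_d": row.carcass_g_d[aa],
                    "feather_g_d": row.feather_g_d[aa],
                    "total_g_d": row.total_g_d[aa],
                    "bw": row.bw,
                    "pr_m": row.pr_m,
                    "pr_c": row.pr_c,
                    "pr_f": row.pr_f,
                }
            )
    return pd.DataFrame.from_records(records)


def compare_to_reference(
    table: pd.DataFrame, reference: pd.DataFrame
) -> pd.DataFrame:
    """Join a computed requirement table with a reference table.

    ``reference`` needs columns age_days, amino_acid, requirement_g_d.
    Adds reference_g_d, abs_diff and rel_diff columns; this is a diff
    report, not an assertion — the model and a published table may differ.
    """
    ref = reference.rename(columns={"requirement_g_d": "reference_g_d"})
    out = table.merge(ref[["age_days", "amino_acid", "reference_g_d"]],
                      on=["age_days", "amino_acid"], how="left")
    out["abs_diff"] = out["total_g_d"] - out["reference_g_d"]
    out["rel_diff"] = out["abs_diff"] / out["reference_g_d"]
    return out


def phase_boundary_jump(bundle: ModelBundle) -> pd.Series:
    """Per-amino-acid discontinuity (g/day) of the total requirement at the
    phase boundary: the early-growing-side value minus the brooding-side
    value evaluated at the same age."""
    t = bundle.phase_boundary_days
    eps = 1e-9
    left = requirement_row(bundle, t).total_g_d
    right_row = requirement_row(bundle, t + eps)
    right = right_row.total_g_d
    return pd.Series({aa: right[aa] - left[aa] for aa in AMINO_ACIDS}, name="jump_g_d")
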