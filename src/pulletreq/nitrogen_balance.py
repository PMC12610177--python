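"""Maintenance protein and amino-acid patterns from nitrogen-balance trials.

A paired nitrogen-free / low-nitrogen feeding design partitions the
obligatory nitrogen losses of a growing hen:

* endogenous nitrogen EN — total N excreted on the nitrogen-free diet
  (gut secretions, sloughed mucosa, urinary turnover);
* surface nitrogen NR — feather/dander N loss, measured as the apparent
  "retention" of the low-nitrogen group;
* creatinine N — an obligatory urinary loss with fixed stoichiometry.

The maintenance protein coefficient scales with metabolic body weight
BW**0.75 (BW in grams):

    C = (EN + NR) * 6.25 / meanBW**0.75   [mg protein / g^0.75 / day]

with meanBW the mean of initial and final body weight of the low-nitrogen
group. The per-amino-acid maintenance pattern AAm (% of maintenance crude
protein) is assembled from four loss routes: measured endogenous free
amino acids, a creatinine-equivalent route (Arg, Gly, Met), the residual
non-amino-acid nitrogen distributed with the carcass pattern AAc, and
feather/dander loss distributed with the feather pattern AAf.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Mapping

import pandas as pd

from .composition import AMINO_ACIDS, AminoAcidProfile, ProfileRole, canonical_amino_acid

__all__ = [
    "N_TO_PROTEIN",
    "METABOLIC_EXPONENT",
    "NITROGEN_ATOMIC_MASS",
    "CREATININE_MOLAR_MASS",
    "CREATININE_N_ATOMS",
    "AA_MOLAR_MASS",
    "AA_N_ATOMS",
    "Phase",
    "Diet",
    "BalanceGroup",
    "MaintenancePhase",
    "CreatininePartition",
    "maintenance_coefficient",
    "creatinine_partition",
    "endogenous_aa_nitrogen",
    "build_maintenance_table",
    "maintenance_phase",
]

#: Conventional nitrogen-to-crude-protein conversion factor.
N_TO_PROTEIN = 6.25
#: Exponent of metabolic body weight (BW in grams).
METABOLIC_EXPONENT = 0.75
NITROGEN_ATOMIC_MASS = 14.007
CREATININE_MOLAR_MASS = 113.118
CREATININE_N_ATOMS = 3

#: Free amino-acid molar masses (g/mol) and nitrogen atom counts.
AA_MOLAR_MASS: dict[str, float] = {
    "Asp": 133.10, "Glu": 147.13, "Ser": 105.09, "Arg": 174.20,
    "Gly": 75.07, "Thr": 119.12, "Pro": 115.13, "Ala": 89.09,
    "Val": 117.15, "Met": 149.21, "Cys": 121.16, "Ile": 131.17,
    "Leu": 131.17, "Phe": 165.19, "His": 155.15, "Lys": 146.19,
    "Tyr": 181.19, "Trp": 204.23,
}
AA_N_ATOMS: dict[str, int] = {
    "Asp": 1, "Glu": 1, "Ser": 1, "Arg": 4, "Gly": 1, "Thr": 1,
    "Pro": 1, "Ala": 1, "Val": 1, "Met": 1, "Cys": 1, "Ile": 1,
    "Leu": 1, "Phe": 1, "His": 3, "Lys": 2, "Tyr": 1, "Trp": 2,
}

#: Mole-per-mole amino-acid equivalents of creatinine degradation
#: (creatine synthesis consumes Arg, Gly and Met).
_CREATININE_EQUIVALENTS = ("Arg", "Gly", "Met")


class Phase(str, Enum):
    WEEK6_7 = "week6_7"
    WEEK11_12 = "week11_12"


class Diet(str, Enum):
    NITROGEN_FREE = "nitrogen_free"
    LOW_NITROGEN = "low_nitrogen"


@dataclass(frozen=True)
class BalanceGroup:
    """Mean outcomes of one diet group in one nitrogen-balance phase.

    Rates are per bird per day; nitrogen quantities in mg N/day.
    ``n_retention`` (surface/feather nitrogen loss) and
    ``creatinine_excretion`` are only measured for the low-nitrogen diet.
    Optional ``*_se`` fields carry the printed standard errors.
    """

    phase: Phase
    diet: Diet
    initial_bw: float
    final_bw: float
    feed_intake: float
    n_intake: float
    n_excretion: float
    n_retention: float | None = None
    creatinine_excretion: float | None = None
    initial_bw_se: float = 0.0
    final_bw_se: float = 0.0
    feed_intake_se: float = 0.0
    n_intake_se: float = 0.0
    n_excretion_se: float = 0.0
    n_retention_se: float | None = None
    creatinine_excretion_se: float | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "phase", Phase(self.phase))
        object.__setattr__(self, "diet", Diet(self.diet))
        for fld in ("initial_bw", "final_bw", "feed_intake", "n_intake", "n_excretion"):
            if getattr(self, fld) < 0:
                raise ValueError(f"{fld} must be non-negative")
        if self.diet is Diet.NITROGEN_FREE and self.n_retention is not None:
            raise ValueError("n_retention is only defined for the low-nitrogen diet")

    @property
    def mean_bw(self) -> float:
        return (self.initial_bw + self.final_bw) / 2.0


@dataclass(frozen=True)
class MaintenancePhase:
    """Phase label, maintenance coefficient C and maintenance pattern AAm.

    C is in mg maintenance crude protein per g^0.75 metabolic weight per
    day; ``aam`` is the maintenance amino-acid pattern in % of maintenance
    crude protein.
    """

    phase: Phase
    C: float
    aam: AminoAcidProfile

    def __post_init__(self) -> None:
        object.__setattr__(self, "phase", Phase(self.phase))
        if not self.C > 0:
            raise ValueError("maintenance coefficient must be positive")
        if self.aam.role is not ProfileRole.MAINTENANCE:
            raise ValueError("aam profile must have the maintenance role")


def maintenance_coefficient(nfree: BalanceGroup, lown: BalanceGroup) -> float:
    """Maintenance coefficient C (mg protein / g^0.75 / day) for one phase.

    Endogenous N comes from the nitrogen-free group's excretion; surface
    (feather/dander) N from the low-nitrogen group's apparent retention;
    the metabolic-weight base from the low-nitrogen group's mean BW.
    """
    if nfree.phase is not lown.phase:
        raise ValueError("groups must share a phase")
    if nfree.diet is not Diet.NITROGEN_FREE or lown.diet is not Diet.LOW_NITROGEN:
        raise ValueError("expected one nitrogen-free and one low-nitrogen group")
    if lown.n_retention is None:
        raise ValueError("low-nitrogen group lacks n_retention")
    total_n = nfree.n_excretion + lown.n_retention
    return total_n * N_TO_PROTEIN / lown.mean_bw**METABOLIC_EXPONENT


@dataclass(frozen=True)
class CreatininePartition:
    """Nitrogen and amino-acid equivalents of a daily creatinine loss."""

    creatinine_mg_day: float
    nitrogen_mg_day: float
    equivalents_mg_day: dict[str, float]  # Arg, Gly, Met


def creatinine_partition(creatinine_mg_day: float) -> CreatininePartition:
    """Partition a creatinine excretion into N and Arg/Gly/Met equivalents.

    Creatinine (113.118 g/mol, 3 N) derives from creatine, whose synthesis
    consumes one mole each of arginine, glycine and methionine per mole;
    the amino-acid equivalents are therefore mole-for-mole.
    """
    if creatinine_mg_day < 0:
        raise ValueError("creatinine excretion must be non-negative")
    moles = creatinine_mg_day / CREATININE_MOLAR_MASS
    nitrogen = moles * CREATININE_N_ATOMS * NITROGEN_ATOMIC_MASS
    equivalents = {aa: moles * AA_MOLAR_MASS[aa] for aa in _CREATININE_EQUIVALENTS}
    return CreatininePartition(
        creatinine_mg_day=float(creatinine_mg_day),
        nitrogen_mg_day=float(nitrogen),
        equivalents_mg_day=equivalents,
    )


def endogenous_aa_nitrogen(losses_mg_day: Mapping[str, float]) -> float:
    """Total nitrogen (mg N/day) in a set of free amino-acid losses.

    Each mass is converted with its free amino-acid molar mass and
    N-atom count: N = mass * n_atoms * 14.007 / molar_mass.
    """
    total = 0.0
    for name, mass in losses_mg_day.items():
        aa = canonical_amino_acid(name)
        if mass < 0:
            raise ValueError(f"negative loss for {aa}")
        total += mass * AA_N_ATOMS[aa] * NITROGEN_ATOMIC_MASS / AA_MOLAR_MASS[aa]
    return total


def build_maintenance_table(
    nfree: BalanceGroup,
    lown: BalanceGroup,
    aac: AminoAcidProfile,
    aaf: AminoAcidProfile,
    endogenous_losses_mg_day: Mapping[str, float],
    aa_n_total_mode: str = "measured_scalar",
    measured_aa_n_mg_day: float | None = None,
) -> pd.DataFrame:
    """Assemble the per-amino-acid maintenance loss table for one phase.

    Columns (all mg/day except the pattern):

    * ``endogenous`` — measured free amino-acid losses in excreta;
    * ``creatinine`` — Arg/Gly/Met equivalents of the creatinine loss;
    * ``non_aa`` — residual endogenous N (EN - AA-form N - creatinine N)
      expressed as crude protein and distributed with the carcass
      pattern AAc;
    * ``dander`` — surface N expressed as crude protein and distributed
      with the feather pattern AAf;
    * ``total`` — exact row sum of the four components;
    * ``pattern_pct`` — total / (total maintenance N x 6.25) x 100, the
      maintenance pattern AAm in % of maintenance crude protein.

    A ``Nitrogen`` row reports the scalar N bookkeeping. ``aa_n_total_mode``
    selects how the AA-form nitrogen scalar is obtained: ``"stoichiometric"``
    sums the per-amino-acid losses with free-amino-acid stoichiometry;
    ``"measured_scalar"`` uses ``measured_aa_n_mg_day`` as supplied (the
    two can differ when the amino-acid assay and the Kjeldahl nitrogen
    assay respond to different fractions of the excreta).
    """
    if lown.n_retention is None:
        raise ValueError("low-nitrogen group lacks n_retention")
    if lown.creatinine_excretion is None:
        raise ValueError("low-nitrogen group lacks creatinine excretion")
    losses = {canonical_amino_acid(k): float(v) for k, v in endogenous_losses_mg_day.items()}
    missing = set(AMINO_ACIDS) - set(losses)
    if missing:
        raise ValueError(f"endogenous losses missing amino acids: {sorted(missing)}")

    en = nfree.n_excretion
    surface_n = lown.n_retention
    creat = creatinine_partition(lown.creatinine_excretion)

    if aa_n_total_mode == "stoichiometric":
        aa_n = endogenous_aa_nitrogen(losses)
    elif aa_n_total_mode == "measured_scalar":
        if measured_aa_n_mg_day is None:
            raise ValueError("measured_scalar mode requires measured_aa_n_mg_day")
        aa_n = float(measured_aa_n_mg_day)
    else:
        raise ValueError(f"unknown aa_n_total_mode: {aa_n_total_mode!r}")

    non_aa_n = en - aa_n - creat.nitrogen_mg_day
    if non_aa_n < 0:
        raise ValueError(
            f"non-amino-acid nitrogen is negative ({non_aa_n:.3f} mg/day): "
            "inconsistent inputs"
        )
    total_n = en + surface_n
    total_protein = total_n * N_TO_PROTEIN

    rows = []
    for aa in AMINO_ACIDS:
        endo = losses[aa]
        cre = creat.equivalents_mg_day.get(aa, 0.0)
        non_aa = non_aa_n * N_TO_PROTEIN * aac[aa] / 100.0
        dander = surface_n * N_TO_PROTEIN * aaf[aa] / 100.0
        total = endo + non_aa + cre + dander
        rows.append(
            {
                "amino_acid": aa,
                "endogenous": endo,
                "non_aa": non_aa,
                "creatinine": cre,
                "dander": dander,
                "total": total,
                # degenerate all-zero trial: no maintenance protein, no pattern
                "pattern_pct": (total / total_protein * 100.0) if total_protein > 0 else 0.0,
            }
        )
    table = pd.DataFrame(rows).set_index("amino_acid")
    table.attrs["nitrogen"] = {
        "endogenous": en,
        "aa_form": aa_n,
        "non_aa": non_aa_n,
        "creatinine": creat.nitrogen_mg_day,
        "dander": surface_n,
        "total": total_n,
        "aa_n_total_mode": aa_n_total_mode,
    }
    return table


def maintenance_phase(
    nfree: BalanceGroup,
    lown: BalanceGroup,
    aac: AminoAcidProfile,
    aaf: AminoAcidProfile,
    endogenous_losses_mg_day: Mapping[str, float],
    aa_n_total_mode: str = "measured_scalar",
    measured_aa_n_mg_day: float | None = None,
) -> MaintenancePhase:
    """Maintenance coefficient plus AAm pattern for one trial phase."""
    table = build_maintenance_table(
        nfree,
        lown,
        aac,
        aaf,
        endogenous_losses_mg_day,
        aa_n_total_mode=aa_n_total_mode,
        measured_aa_n_mg_day=measured_aa_n_mg_day,
    )
    aam = AminoAcidProfile(table["pattern_pct"].to_dict(), ProfileRole.MAINTENANCE)
    return MaintenancePhase(
        phase=nfree.phase,
        C=maintenance_coefficient(nfree, lown),
        aam=aam,
    )
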