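"""Packaged study fixtures and reference-parameter model bundles.

The package ships the published summary tables of the underlying feeding
study as CSV fixtures: the per-age amino-acid panels of carcass and
feather protein, the derived AAc/AAf/AAm patterns, the nitrogen-balance
trial results, the per-amino-acid maintenance-loss tables, and the
published per-age requirement table used for diff reports. Loaders return
plain DataFrames or the package's domain objects.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd
import yaml

from .allometry import AllometricForm, AllometricParams, Compartment
from .composition import AminoAcidProfile, ProfilePanel, ProfileRole
from .digestibility import NutrientKind, logarithmic_curve
from .factorial import ModelBundle
from .growth import GrowthParams
from .nitrogen_balance import BalanceGroup, Diet, MaintenancePhase, Phase

__all__ = [
    "load_defaults",
    "load_panel",
    "load_profile",
    "load_maintenance_pattern",
    "load_balance_groups",
    "load_endogenous_losses",
    "load_maintenance_reference",
    "load_reference_requirements",
    "reference_bundle",
]


def _data_path(name: str):
    return resources.files("pulletreq.data").joinpath(name)


def _read_csv(name: str) -> pd.DataFrame:
    with resources.as_file(_data_path(name)) as path:
        return pd.read_csv(path)


def load_defaults() -> dict:
    """Default sub-model parameters (the published fitted values)."""
    with _data_path("defaults.yaml").open("r", encoding="utf-8") as fh:
        return yaml.safe_load(fh)


def load_panel(compartment: str) -> ProfilePanel:
    """Per-age amino-acid panel for ``carcass`` or ``feather`` protein."""
    role = ProfileRole(compartment)
    if role is ProfileRole.MAINTENANCE:
        raise ValueError("panels exist for carcass and feather only")
    df = _read_csv(f"{role.value}_panel.csv")
    return ProfilePanel(df.drop(columns=["compartment"]), role)


def load_profile(role: str) -> AminoAcidProfile:
    """Published representative pattern AAc (``carcass``) or AAf (``feather``)."""
    role = ProfileRole(role)
    name = {"carcass": "aac.csv", "feather": "aaf.csv"}[role.value]
    df = _read_csv(name)
    return AminoAcidProfile(dict(zip(df["amino_acid"], df["pct"])), role)


def load_maintenance_pattern(phase: str) -> AminoAcidProfile:
    """Published maintenance pattern AAm for one trial phase."""
    phase = Phase(phase)
    df = _read_csv("aam.csv")
    sub = df[df["phase"] == phase.value]
    return AminoAcidProfile(dict(zip(sub["amino_acid"], sub["pct"])), ProfileRole.MAINTENANCE)


def load_balance_groups() -> dict[tuple[Phase, Diet], BalanceGroup]:
    """Nitrogen-balance trial groups keyed by (phase, diet)."""
    df = _read_csv("balance.csv")
    out: dict[tuple[Phase, Diet], BalanceGroup] = {}
    for _, r in df.iterrows():
        phase, diet = Phase(r["phase"]), Diet(r["diet"])

        def opt(col):
            v = r[col]
            return None if pd.isna(v) else float(v)

        out[(phase, diet)] = BalanceGroup(
            phase=phase,
            diet=diet,
            initial_bw=float(r["initial_bw_g"]),
            final_bw=float(r["final_bw_g"]),
            feed_intake=float(r["feed_intake_g_d"]),
            n_intake=float(r["n_intake_mg_d"]),
            n_excretion=float(r["n_excretion_mg_d"]),
            n_retention=opt("n_retention_mg_d"),
            creatinine_excretion=opt("creatinine_mg_d"),
            initial_bw_se=float(r["initial_bw_se"]),
            final_bw_se=float(r["final_bw_se"]),
            feed_intake_se=float(r["feed_intake_se"]),
            n_intake_se=float(r["n_intake_se"]),
            n_excretion_se=float(r["n_excretion_se"]),
            n_retention_se=opt("n_retention_se"),
            creatinine_excretion_se=opt("creatinine_se"),
        )
    return out


def load_endogenous_losses(phase: str) -> dict[str, float]:
    """Per-amino-acid endogenous losses (mg/day) for one phase."""
    phase = Phase(phase)
    df = _read_csv("endogenous_aa.csv")
    sub = df[df["phase"] == phase.value]
    return dict(zip(sub["amino_acid"], sub["loss_mg_d"].astype(float)))


def load_maintenance_reference(phase: str) -> pd.DataFrame:
    """Published per-amino-acid maintenance-loss table for one phase.

    Includes the ``Nitrogen`` bookkeeping row; the published amino-acid
    form nitrogen scalar is that row's ``endogenous_mg_d`` entry.
    """
    phase = Phase(phase)
    df = _read_csv("maintenance_reference.csv")
    return df[df["phase"] == phase.value].set_index("item")


def load_reference_requirements() -> pd.DataFrame:
    """Published per-age requirement table (columns amino_acid, age_days,
    requirement_g_d) for diff reports."""
    return _read_csv("reference_requirements.csv")


def _maintenance_phase_from_defaults(cfg: dict, key: str) -> MaintenancePhase:
    entry = cfg["maintenance"][key]
    return MaintenancePhase(
        phase=Phase(entry["phase"]),
        C=float(entry["C"]),
        aam=load_maintenance_pattern(entry["phase"]),
    )


def reference_bundle() -> ModelBundle:
    """Model bundle assembled from the published fitted parameters.

    Uses the published growth curve, allometries, maintenance coefficients
    with the published AAm patterns, the published AAc/AAf patterns, and
    the published logarithmic digestibility curves.
    """
    cfg = load_defaults()
    g = cfg["growth"]
    growth = GrowthParams(g["family"], float(g["A"]), float(g["b"]), float(g["k"]))
    ca = cfg["allometry"]["carcass"]
    carcass = AllometricParams(
        AllometricForm(ca["form"]), float(ca["b0"]), float(ca["b1"]),
        target=Compartment.CARCASS,
    )
    fa = cfg["allometry"]["feather"]
    feather = AllometricParams(
        AllometricForm(fa["form"]), float(fa["b0"]), float(fa["b1"]), float(fa["b2"]),
        target=Compartment.FEATHER,
    )
    dp = cfg["digestibility"]["protein"]
    da = cfg["digestibility"]["amino_acid"]
    return ModelBundle(
        growth=growth,
        carcass_allom=carcass,
        feather_allom=feather,
        brooding=_maintenance_phase_from_defaults(cfg, "brooding"),
        early_growing=_maintenance_phase_from_defaults(cfg, "early_growing"),
        aac=load_profile("carcass"),
        aaf=load_profile("feather"),
        apd_curve=logarithmic_curve(dp["c0"], dp["c1"], NutrientKind.PROTEIN),
        aad_curve=logarithmic_curve(da["c0"], da["c1"], NutrientKind.AMINO_ACID),
        phase_boundary_days=float(cfg["maintenance"]["phase_boundary_days"]),
    )
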