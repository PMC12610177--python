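"""CSV readers and writers for the pipeline's tabular interchange formats.

All tabular interchange is CSV with a header row, UTF-8, '.' decimal
separator. Percent quantities are stored in percent units (e.g. 6.308);
digestibility predictions are the only fraction-scale columns and are
documented as such where written. Validation errors carry 1-based data
row numbers.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable

import pandas as pd

from .allometry import Compartment, ProteinObservation
from .composition import canonical_amino_acid
from .digestibility import DigestibilityObservation, NutrientKind
from .growth import WeightObservation
from .nitrogen_balance import BalanceGroup, Diet, Phase

__all__ = [
    "SchemaError",
    "read_table",
    "read_weights",
    "read_composition",
    "read_digestibility",
    "read_balance",
    "write_balance",
    "write_weights",
    "write_composition",
    "write_digestibility",
]


class SchemaError(ValueError):
    """A CSV file does not match its expected schema."""


def read_table(path: str | Path, schema: dict[str, type]) -> pd.DataFrame:
    """Read and validate a CSV against a column->type schema.

    ``schema`` maps required column names to ``float``, ``int`` or ``str``.
    Extra columns are preserved untouched. Non-convertible cells are
    reported with their 1-based data row number.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError as err:
        raise SchemaError(f"{path}: file is empty, expected header "
                          f"{sorted(schema)}") from err
    missing = set(schema) - set(df.columns)
    if missing:
        raise SchemaError(f"{path}: missing columns {sorted(missing)}")
    for col, typ in schema.items():
        if typ in (float, int):
            converted = pd.to_numeric(df[col], errors="coerce")
            bad = df.index[converted.isna() & df[col].notna()]
            if len(bad):
                raise SchemaError(
                    f"{path}: non-numeric value in column {col!r} at data "
                    f"row {bad[0] + 1}: {df.loc[bad[0], col]!r}"
                )
            df[col] = converted
    if "amino_acid" in df.columns:
        try:
            df["amino_acid"] = df["amino_acid"].map(canonical_amino_acid)
        except KeyError as err:
            raise SchemaError(f"{path}: {err.args[0]}") from err
    return df


def read_weights(path: str | Path) -> list[WeightObservation]:
    df = read_table(path, {"group_id": str, "age_days": float, "body_weight_g": float})
    return [
        WeightObservation(t=r.age_days, bw=r.body_weight_g, group_id=str(r.group_id))
        for r in df.itertuples()
    ]


def write_weights(observations: Iterable[WeightObservation], path: str | Path) -> None:
    pd.DataFrame(
        [{"group_id": o.group_id, "age_days": o.t, "body_weight_g": o.bw}
         for o in observations]
    ).to_csv(path, index=False)


def read_composition(path: str | Path) -> list[ProteinObservation]:
    """Read dissection records: age_days, live_bw_g, carcass_protein_g,
    feather_protein_g — one row expands to two observations."""
    df = read_table(
        path,
        {"age_days": float, "live_bw_g": float,
         "carcass_protein_g": float, "feather_protein_g": float},
    )
    out: list[ProteinObservation] = []
    for r in df.itertuples():
        out.append(ProteinObservation(bw=r.live_bw_g, protein_mass=r.carcass_protein_g,
                                      compartment=Compartment.CARCASS, age_days=r.age_days))
        out.append(ProteinObservation(bw=r.live_bw_g, protein_mass=r.feather_protein_g,
                                      compartment=Compartment.FEATHER, age_days=r.age_days))
    return out


def write_composition(observations: Iterable[ProteinObservation], path: str | Path) -> None:
    rows: dict[tuple[float, float], dict] = {}
    for o in observations:
        key = (o.age_days, o.bw)
        row = rows.setdefault(key, {"age_days": o.age_days, "live_bw_g": o.bw})
        col = ("carcass_protein_g" if o.compartment is Compartment.CARCASS
               else "feather_protein_g")
        row[col] = o.protein_mass
    pd.DataFrame(list(rows.values())).to_csv(path, index=False)


def read_digestibility(path: str | Path) -> list[DigestibilityObservation]:
    df = read_table(
        path,
        {"age_days": float, "nutrient_kind": str, "aia_feed_pct": float,
         "aia_feces_pct": float, "nutrient_feed_pct": float, "nutrient_feces_pct": float},
    )
    out = []
    for r in df.itertuples():
        out.append(
            DigestibilityObservation(
                age_days=r.age_days,
                aia_feed=r.aia_feed_pct,
                aia_feces=r.aia_feces_pct,
                nutrient_feed=r.nutrient_feed_pct,
                nutrient_feces=r.nutrient_feces_pct,
                nutrient_kind=NutrientKind(r.nutrient_kind),
            )
        )
    return out


def write_digestibility(
    observations: Iterable[DigestibilityObservation], path: str | Path
) -> None:
    pd.DataFrame(
        [
            {
                "age_days": o.age_days,
                "nutrient_kind": o.nutrient_kind.value,
                "aia_feed_pct": o.aia_feed,
                "aia_feces_pct": o.aia_feces,
                "nutrient_feed_pct": o.nutrient_feed,
                "nutrient_feces_pct": o.nutrient_feces,
            }
            for o in observations
        ]
    ).to_csv(path, index=False)


def write_balance(
    groups: dict[tuple[Phase, Diet], BalanceGroup], path: str | Path
) -> None:
    rows = []
    for (phase, diet), g in groups.items():
        rows.append(
            {
                "phase": phase.value,
                "diet": diet.value,
                "initial_bw_g": g.initial_bw,
                "final_bw_g": g.final_bw,
                "feed_intake_g_d": g.feed_intake,
                "n_intake_mg_d": g.n_intake,
                "n_excretion_mg_d": g.n_excretion,
                "n_retention_mg_d": g.n_retention,
                "creatinine_mg_d": g.creatinine_excretion,
            }
        )
    pd.DataFrame(rows).to_csv(path, index=False)


def read_balance(path: str | Path) -> dict[tuple[Phase, Diet], BalanceGroup]:
    df = read_table(
        path,
        {"phase": str, "diet": str, "initial_bw_g": float, "final_bw_g": float,
         "feed_intake_g_d": float, "n_intake_mg_d": float, "n_excretion_mg_d": float},
    )
    out: dict[tuple[Phase, Diet], BalanceGroup] = {}
    for _, r in df.iterrows():
        phase, diet = Phase(r["phase"]), Diet(r["diet"])

        def opt(col):
            if col not in df.columns or pd.isna(r[col]):
                return None
            return float(r[col])

        out[(phase, diet)] = BalanceGroup(
            phase=phase, diet=diet,
            initial_bw=float(r["initial_bw_g"]), final_bw=float(r["final_bw_g"]),
            feed_intake=float(r["feed_intake_g_d"]), n_intake=float(r["n_intake_mg_d"]),
            n_excretion=float(r["n_excretion_mg_d"]),
            n_retention=opt("n_retention_mg_d"),
            creatinine_excretion=opt("creatinine_mg_d"),
        )
    return out
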