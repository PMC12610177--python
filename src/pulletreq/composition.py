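"""Amino-acid composition patterns of carcass and feather protein.

Carcass and feather protein are characterised by the percentage of crude
protein contributed by each of 18 amino acids, measured at seven ages
(0-84 days, fortnightly). Because the patterns stabilise with age, a
representative pattern per compartment is taken as the unweighted mean of
the per-age means over a configured age window: 28/42/56 days for carcass
(AAc) and 56/70/84 days for feather (AAf). One-way ANOVA and Duncan's
multiple range test support the age-stability assessment.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "AMINO_ACIDS",
    "ProfileRole",
    "AminoAcidProfile",
    "ProfilePanel",
    "canonical_amino_acid",
    "representative_profile",
    "anova_oneway",
    "duncan_groups",
]

#: Canonical order of the 18 amino acids quantified in carcass and feather
#: protein hydrolysates (tryptophan reported separately from acid hydrolysis).
AMINO_ACIDS: tuple[str, ...] = (
    "Asp", "Glu", "Ser", "Arg", "Gly", "Thr", "Pro", "Ala", "Val",
    "Met", "Cys", "Ile", "Leu", "Phe", "His", "Lys", "Tyr", "Trp",
)

_ALIASES = {"try": "Trp", "trp": "Trp"}


def canonical_amino_acid(name: str) -> str:
    """Normalise an amino-acid label to the canonical three-letter key.

    Accepts any capitalisation and the legacy "Try" spelling of tryptophan.
    """
    key = name.strip()
    low = key.lower()
    if low in _ALIASES:
        return _ALIASES[low]
    for aa in AMINO_ACIDS:
        if low == aa.lower():
            return aa
    raise KeyError(f"unknown amino acid: {name!r}")


class ProfileRole(str, Enum):
    CARCASS = "carcass"
    FEATHER = "feather"
    MAINTENANCE = "maintenance"


@dataclass(frozen=True)
class AminoAcidProfile:
    """18 amino-acid percentages of crude protein for one role.

    Values are percent of crude protein, each in (0, 100); the 18 values
    sum to less than 100 (crude protein includes non-amino-acid nitrogen
    and water of hydrolysis).
    """

    values: Mapping[str, float]
    role: ProfileRole

    def __post_init__(self) -> None:
        object.__setattr__(self, "role", ProfileRole(self.role))
        vals = {canonical_amino_acid(k): float(v) for k, v in self.values.items()}
        missing = set(AMINO_ACIDS) - set(vals)
        if missing:
            raise ValueError(f"profile missing amino acids: {sorted(missing)}")
        extra = set(vals) - set(AMINO_ACIDS)
        if extra:
            raise ValueError(f"unknown amino acids in profile: {sorted(extra)}")
        for aa, v in vals.items():
            if not (0.0 < v < 100.0):
                raise ValueError(f"{aa} = {v} outside (0, 100) percent")
        if sum(vals.values()) >= 100.0:
            raise ValueError("amino-acid percentages must sum to < 100")
        object.__setattr__(self, "values", vals)

    def __getitem__(self, aa: str) -> float:
        return self.values[canonical_amino_acid(aa)]

    def as_series(self) -> pd.Series:
        return pd.Series({aa: self.values[aa] for aa in AMINO_ACIDS}, name=self.role.value)

    def scaled(self, factor: float) -> "AminoAcidProfile":
        return AminoAcidProfile(
            {aa: v * factor for aa, v in self.values.items()}, self.role
        )


@dataclass(frozen=True)
class ProfilePanel:
    """Per-age mean +/- SE of the 18 amino-acid percentages (long format).

    ``table`` holds columns age_days, amino_acid, mean_pct, se_pct, n.
    """

    table: pd.DataFrame
    compartment: ProfileRole

    def __post_init__(self) -> None:
        object.__setattr__(self, "compartment", ProfileRole(self.compartment))
        df = self.table.copy()
        required = {"age_days", "amino_acid", "mean_pct", "se_pct", "n"}
        missing = required - set(df.columns)
        if missing:
            raise ValueError(f"panel missing columns: {sorted(missing)}")
        df["amino_acid"] = df["amino_acid"].map(canonical_amino_acid)
        if (df["se_pct"] < 0).any():
            raise ValueError("standard errors must be non-negative")
        df = df.sort_values(["age_days", "amino_acid"]).reset_index(drop=True)
        object.__setattr__(self, "table", df)

    @property
    def ages(self) -> tuple[float, ...]:
        return tuple(sorted(self.table["age_days"].unique()))

    def means_at(self, age: float) -> dict[str, float]:
        sub = self.table[self.table["age_days"] == age]
        if sub.empty:
            raise KeyError(f"no panel data at age {age}")
        return dict(zip(sub["amino_acid"], sub["mean_pct"]))


def representative_profile(
    panel: ProfilePanel, ages: Iterable[float], role: ProfileRole | str | None = None
) -> AminoAcidProfile:
    """Unweighted per-amino-acid mean of the selected ages' means.

    No renormalisation is applied; the result is linear in the panel means
    and invariant to the order of ``ages``.
    """
    ages = sorted(set(float(a) for a in ages))
    if not ages:
        raise ValueError("at least one age required")
    missing = [a for a in ages if a not in panel.ages]
    if missing:
        raise KeyError(f"ages not in panel: {missing}")
    acc: dict[str, float] = {aa: 0.0 for aa in AMINO_ACIDS}
    for a in ages:
        for aa, v in panel.means_at(a).items():
            acc[aa] += v
    values = {aa: acc[aa] / len(ages) for aa in AMINO_ACIDS}
    return AminoAcidProfile(values, ProfileRole(role) if role else panel.compartment)


def anova_oneway(groups: Sequence[Sequence[float]]) -> tuple[float, float]:
    """One-way ANOVA F statistic and p-value across replicate groups.

    Degenerate inputs (zero within-group variance) are reported: with
    equal means F = 0 and p = 1; with unequal means and no within-group
    scatter the decomposition is singular and a ``ValueError`` is raised.
    """
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if len(arrays) < 2:
        raise ValueError("ANOVA needs at least two groups")
    if any(a.size < 2 for a in arrays):
        raise ValueError("each group needs at least two replicates")
    grand = np.concatenate(arrays)
    ssw = sum(float(np.sum((a - a.mean()) ** 2)) for a in arrays)
    means = [a.mean() for a in arrays]
    if ssw == 0.0:
        if np.ptp(means) == 0.0:
            return 0.0, 1.0
        raise ValueError(
            "zero within-group variance with unequal means: F is undefined"
        )
    ssb = sum(a.size * (a.mean() - grand.mean()) ** 2 for a in arrays)
    if ssb == 0.0:
        return 0.0, 1.0
    f, p = stats.f_oneway(*arrays)
    return float(f), float(p)


def duncan_groups(
    means: Sequence[float],
    mse: float,
    n_per_group: int,
    df_error: int,
    alpha: float = 0.05,
) -> list[str]:
    """Duncan's multiple range test letter assignment for balanced groups.

    The least significant range for a span of p ordered means uses the
    studentized range quantile at Duncan's protection level
    1 - (1 - alpha)**(p - 1). Groups sharing a letter do not differ
    significantly. Returns one letter string per input mean, in input order.
    """
    means = np.asarray(means, dtype=float)
    k = means.size
    if k < 2:
        raise ValueError("need at least two group means")
    if df_error <= 0:
        raise ValueError("df_error must be positive")
    if n_per_group < 1:
        raise ValueError("n_per_group must be at least 1")
    if mse < 0:
        raise ValueError("mse must be non-negative")

    se_mean = np.sqrt(mse / n_per_group)
    # least significant range for spans p = 2..k
    lsr = {}
    for p in range(2, k + 1):
        level = 1.0 - (1.0 - alpha) ** (p - 1)
        q = stats.studentized_range.ppf(1.0 - level, p, df_error)
        lsr[p] = q * se_mean

    order = np.argsort(means)  # ascending
    sorted_means = means[order]

    def homogeneous(i: int, j: int) -> bool:
        """True if the sorted means i..j (inclusive) form one Duncan group."""
        span = j - i + 1
        if span == 1:
            return True
        return (sorted_means[j] - sorted_means[i]) <= lsr[span]

    # maximal homogeneous runs over the sorted means -> letters
    runs: list[tuple[int, int]] = []
    i = 0
    while i < k:
        j = i
        while j + 1 < k and homogeneous(i, j + 1):
            j += 1
        if not runs or runs[-1][1] < j:
            runs.append((i, j))
        if j == k - 1:
            break
        i += 1
    letters_sorted = ["" for _ in range(k)]
    for r, (lo, hi) in enumerate(runs):
        letter = chr(ord("a") + r)
        for idx in range(lo, hi + 1):
            letters_sorted[idx] += letter
    out = ["" for _ in range(k)]
    for pos, original_idx in enumerate(order):
        out[original_idx] = letters_sorted[pos]
    return out
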