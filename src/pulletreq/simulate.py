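"""Seeded synthetic observation streams with known ground truth.

The feeding study behind the model reports only group summaries, so every
fitting stage is exercised on synthetic data generated from the published
fitted parameters as ground truth:

* body weights: the trial design of 6 replicate groups weighed
  fortnightly from hatch to 84 days, multiplicative Gaussian noise on the
  true growth curve (default sd 2% of the mean, the scale of the growth
  fit's residual spread);
* body composition: per-age dissections with carcass protein from the
  power allometry and feather protein from the quadratic, additive
  Gaussian noise in grams, feather mass floored at zero;
* nitrogen balance: the published group means perturbed by Gaussian noise
  scaled to each mean's published standard error;
* digestibility: the trial ages {5,...,85} with feed/feces concentration
  quadruples constructed so the implied apparent digestibility equals the
  true logarithmic curve plus additive noise (default sd 0.015 for
  protein and 0.003 for the pooled amino acid, the published residual
  scales of the two curves).

All randomness flows from the single ``seed``; the same configuration
reproduces the same observations bit for bit.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace

import numpy as np

from .allometry import AllometricForm, AllometricParams, Compartment, protein_mass
from .digestibility import (
    CurveFamily,
    DigestibilityCurve,
    DigestibilityObservation,
    NutrientKind,
    _raw_predict,
)
from .growth import GrowthFamily, GrowthParams, predict_bw
from .nitrogen_balance import BalanceGroup, Diet, Phase

__all__ = [
    "SimulationConfig",
    "simulate_weights",
    "simulate_composition",
    "simulate_balance",
    "simulate_digestibility",
]

from .growth import WeightObservation
from .allometry import ProteinObservation

_TRIAL_AGES = (0.0, 14.0, 28.0, 42.0, 56.0, 70.0, 84.0)
_DIGEST_AGES = (5.0, 10.0, 25.0, 35.0, 45.0, 55.0, 70.0, 85.0)


def _default_growth() -> GrowthParams:
    return GrowthParams(GrowthFamily.VON_BERTALANFFY, 1412.418, 0.748, 0.024)


def _default_carcass() -> AllometricParams:
    return AllometricParams(AllometricForm.POWER, 0.181, 1.007, target=Compartment.CARCASS)


def _default_feather() -> AllometricParams:
    return AllometricParams(
        AllometricForm.QUADRATIC, -3.393, 0.089, -1.46e-5, target=Compartment.FEATHER
    )


def _default_apd() -> DigestibilityCurve:
    return DigestibilityCurve(CurveFamily.LOGARITHMIC, (0.577, 0.037), NutrientKind.PROTEIN)


def _default_aad() -> DigestibilityCurve:
    return DigestibilityCurve(CurveFamily.LOGARITHMIC, (0.860, 0.004), NutrientKind.AMINO_ACID)


@dataclass(frozen=True)
class SimulationConfig:
    """Ground-truth parameters and noise levels for all synthetic streams.

    The defaults are the study conditions: published fitted parameters as
    truth, 6 replicate groups at 7 fortnightly ages, 2% multiplicative
    body-weight noise, 2 g additive protein noise, balance-group noise at
    1x the published SEs, and 0.015 absolute digestibility noise.
    """

    seed: int
    growth_truth: GrowthParams = field(default_factory=_default_growth)
    carcass_truth: AllometricParams = field(default_factory=_default_carcass)
    feather_truth: AllometricParams = field(default_factory=_default_feather)
    apd_truth: DigestibilityCurve = field(default_factory=_default_apd)
    aad_truth: DigestibilityCurve = field(default_factory=_default_aad)
    bw_noise_frac: float = 0.02
    protein_noise_g: float = 2.0
    balance_noise_se_scale: float = 1.0
    digestibility_noise: float = 0.015
    aa_digestibility_noise: float = 0.003
    n_groups: int = 6
    ages: tuple[float, ...] = _TRIAL_AGES
    # dissection ages start at 14 d: below ~40 g live weight the feather
    # quadratic's predicted mass is negative, so hatch-day records would
    # only ever contribute floored zeros and bias the fit
    composition_ages: tuple[float, ...] = _TRIAL_AGES[1:]
    digest_ages: tuple[float, ...] = _DIGEST_AGES

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("seed is mandatory")
        for fld in ("bw_noise_frac", "protein_noise_g", "balance_noise_se_scale",
                    "digestibility_noise", "aa_digestibility_noise"):
            if getattr(self, fld) < 0:
                raise ValueError(f"{fld} must be non-negative")

    def rng(self, stream: str) -> np.random.Generator:
        """Independent generator per stream, all derived from the one seed.

        The stream label enters through a stable CRC32 hash so that runs
        are reproducible across processes and Python versions.
        """
        return np.random.default_rng([self.seed, zlib.crc32(stream.encode())])

    def with_noise(self, **kwargs) -> "SimulationConfig":
        return replace(self, **kwargs)


def simulate_weights(config: SimulationConfig) -> list[WeightObservation]:
    """Group-mean body weights: truth curve times (1 + eps), eps ~ N(0, sd)."""
    rng = config.rng("weights")
    out = []
    for age in config.ages:
        truth = predict_bw(config.growth_truth, age)
        for g in range(config.n_groups):
            eps = rng.normal(0.0, config.bw_noise_frac) if config.bw_noise_frac else 0.0
            out.append(WeightObservation(t=age, bw=truth * (1.0 + eps), group_id=f"g{g + 1}"))
    return out


def simulate_composition(config: SimulationConfig) -> list[ProteinObservation]:
    """Dissection records: one bird per group and age, protein masses from
    the allometric truths plus additive Gaussian noise (feather floored at 0)."""
    rng = config.rng("composition")
    out = []
    for age in config.composition_ages:
        bw_true = predict_bw(config.growth_truth, age)
        for _ in range(config.n_groups):
            bw = bw_true * (1.0 + (rng.normal(0.0, config.bw_noise_frac)
                                   if config.bw_noise_frac else 0.0))
            cp = protein_mass(config.carcass_truth, bw)
            fp = protein_mass(config.feather_truth, bw)
            if config.protein_noise_g:
                cp += rng.normal(0.0, config.protein_noise_g)
                fp += rng.normal(0.0, config.protein_noise_g)
            out.append(ProteinObservation(bw=bw, protein_mass=max(cp, 0.0),
                                          compartment=Compartment.CARCASS, age_days=age))
            out.append(ProteinObservation(bw=bw, protein_mass=max(fp, 0.0),
                                          compartment=Compartment.FEATHER, age_days=age))
    return out


# Published nitrogen-balance group means (se) that the generator emulates.
_BALANCE_TRUTH = {
    (Phase.WEEK6_7, Diet.LOW_NITROGEN): dict(
        initial_bw=(519.509, 18.419), final_bw=(523.273, 17.022),
        feed_intake=(40.627, 2.200), n_intake=(520.136, 26.545),
        n_excretion=(359.478, 4.986), n_retention=(160.658, 8.717),
        creatinine_excretion=(1.535, 0.061),
    ),
    (Phase.WEEK6_7, Diet.NITROGEN_FREE): dict(
        initial_bw=(487.820, 8.759), final_bw=(421.379, 6.387),
        feed_intake=(20.961, 0.893), n_intake=(18.781, 0.799),
        n_excretion=(217.567, 8.486),
    ),
    (Phase.WEEK11_12, Diet.LOW_NITROGEN): dict(
        initial_bw=(867.936, 6.983), final_bw=(885.757, 12.839),
        feed_intake=(240.315, 5.779), n_intake=(724.789, 17.431),
        n_excretion=(346.966, 14.300), n_retention=(377.823, 18.502),
        creatinine_excretion=(2.124, 0.050),
    ),
    (Phase.WEEK11_12, Diet.NITROGEN_FREE): dict(
        initial_bw=(873.221, 8.283), final_bw=(840.339, 5.563),
        feed_intake=(161.983, 12.156), n_intake=(36.284, 2.722),
        n_excretion=(239.645, 19.991),
    ),
}


def simulate_balance(config: SimulationConfig) -> dict[tuple[Phase, Diet], BalanceGroup]:
    """Nitrogen-balance groups: published means perturbed by N(0, scale*SE).

    At ``balance_noise_se_scale = 0`` the published means are reproduced
    exactly. Perturbed quantities are floored at zero (they are rates)."""
    rng = config.rng("balance")
    scale = config.balance_noise_se_scale
    out: dict[tuple[Phase, Diet], BalanceGroup] = {}
    for (phase, diet), fields_ in _BALANCE_TRUTH.items():
        kwargs: dict[str, float] = {}
        for name, (mean, se) in fields_.items():
            val = mean + (rng.normal(0.0, scale * se) if scale else 0.0)
            kwargs[name] = max(val, 0.0)
            kwargs[name + "_se"] = se
        out[(phase, diet)] = BalanceGroup(phase=phase, diet=diet, **kwargs)
    return out


def simulate_digestibility(
    config: SimulationConfig, nutrient_kind: NutrientKind | str = NutrientKind.PROTEIN
) -> list[DigestibilityObservation]:
    """Feed/feces concentration quadruples with a known digestibility trend.

    AIA and nutrient feed concentrations are held fixed (1% and 20% of dry
    matter for protein, 1% for a pooled amino acid); the fecal nutrient
    concentration is solved so the implied apparent digestibility equals
    the truth curve plus additive noise.
    """
    kind = NutrientKind(nutrient_kind)
    if kind is NutrientKind.PROTEIN:
        truth, sd = config.apd_truth, config.digestibility_noise
    else:
        truth, sd = config.aad_truth, config.aa_digestibility_noise
    rng = config.rng(f"digestibility:{kind.value}")
    aia_feed, aia_feces = 1.0, 2.5
    nutrient_feed = 20.0 if kind is NutrientKind.PROTEIN else 1.0
    out = []
    for age in config.digest_ages:
        d = float(_raw_predict(truth, np.asarray([age]))[0])
        if sd:
            d += rng.normal(0.0, sd)
        d = min(d, 1.0 - 1e-6)
        nutrient_feces = (1.0 - d) * nutrient_feed * aia_feces / aia_feed
        out.append(
            DigestibilityObservation(
                age_days=age,
                aia_feed=aia_feed,
                aia_feces=aia_feces,
                nutrient_feed=nutrient_feed,
                nutrient_feces=nutrient_feces,
                nutrient_kind=kind,
            )
        )
    return out
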