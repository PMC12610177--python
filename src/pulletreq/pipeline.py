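"""End-to-end pipeline: fit every sub-model and assemble a ModelBundle.

This is the programmatic backbone of the ``report`` command: given the
four observation streams (body weights, body composition, nitrogen
balance, digestibility) plus the packaged amino-acid panels, it fits the
growth curve (with model selection), the carcass and feather allometries
(with form selection), the two digestibility curves, derives the
maintenance phases, and returns the assembled factorial model.
"""

from __future__ import annotations

from dataclasses import dataclass

from .allometry import (
    AllometricFit,
    AllometricForm,
    Compartment,
    ProteinObservation,
    fit_allometric,
    power_vb_leading_constant,
    quadratic_vb_term_constants,
    select_allometric,
)
from .composition import ProfileRole, representative_profile
from .datasets import (
    load_balance_groups,
    load_defaults,
    load_endogenous_losses,
    load_maintenance_reference,
    load_panel,
)
from .digestibility import (
    CurveFamily,
    DigestibilityCurve,
    DigestibilityObservation,
    NutrientKind,
    fit_digestibility_curve,
    select_digestibility_curve,
)
from .factorial import ModelBundle
from .growth import GrowthFamily, GrowthFit, WeightObservation, fit_growth, select_model
from .nitrogen_balance import BalanceGroup, Diet, Phase, maintenance_phase

__all__ = ["PipelineFits", "fit_bundle"]

_GROWTH_FAMILIES = (GrowthFamily.GOMPERTZ, GrowthFamily.LOGISTIC, GrowthFamily.VON_BERTALANFFY)
_ALLOM_FORMS = (
    AllometricForm.LINEAR,
    AllometricForm.QUADRATIC,
    AllometricForm.POWER,
    AllometricForm.EXPONENTIAL,
)
_CURVE_FAMILIES = (CurveFamily.LOGARITHMIC, CurveFamily.EXPONENTIAL, CurveFamily.QUADRATIC)


@dataclass(frozen=True)
class PipelineFits:
    """All candidate fits plus the selected bundle."""

    growth_ranking: list[GrowthFit]
    carcass_ranking: list[AllometricFit]
    feather_ranking: list[AllometricFit]
    apd_ranking: list[DigestibilityCurve]
    aad_ranking: list[DigestibilityCurve]
    bundle: ModelBundle

    @property
    def deposition_constants(self) -> dict[str, float]:
        """Closed-form deposition-rate constants of the selected models
        (available when carcass is power and feather quadratic over a
        Von Bertalanffy growth curve)."""
        out: dict[str, float] = {}
        g = self.bundle.growth
        if g.family is GrowthFamily.VON_BERTALANFFY:
            if self.bundle.carcass_allom.form is AllometricForm.POWER:
                out["carcass_leading"] = power_vb_leading_constant(
                    g, self.bundle.carcass_allom
                )
            if self.bundle.feather_allom.form is AllometricForm.QUADRATIC:
                lin, quad = quadratic_vb_term_constants(g, self.bundle.feather_allom)
                out["feather_linear_term"] = lin
                out["feather_quadratic_term"] = quad
        return out


def fit_bundle(
    weights: list[WeightObservation],
    composition: list[ProteinObservation],
    balance: dict[tuple[Phase, Diet], BalanceGroup] | None = None,
    apd_obs: list[DigestibilityObservation] | None = None,
    aad_obs: list[DigestibilityObservation] | None = None,
    aa_n_total_mode: str = "measured_scalar",
    phase_boundary_days: float | None = None,
) -> PipelineFits:
    """Fit all sub-models from observation streams and select the best.

    The nitrogen-balance stream defaults to the packaged trial results;
    the amino-acid panels always come from the packaged fixtures (the
    profile windows are configuration defaults). When digestibility
    observations are missing the packaged default curves are used. The
    published amino-acid-form nitrogen scalars back the maintenance
    patterns in ``measured_scalar`` mode; ``stoichiometric`` recomputes
    them from the endogenous losses.
    """
    cfg = load_defaults()
    if phase_boundary_days is None:
        phase_boundary_days = float(cfg["maintenance"]["phase_boundary_days"])

    growth_fits = [fit_growth(weights, fam) for fam in _GROWTH_FAMILIES]
    growth_ranking = select_model(growth_fits)
    growth = growth_ranking[0].params

    carcass_obs = [o for o in composition if o.compartment is Compartment.CARCASS]
    feather_obs = [o for o in composition if o.compartment is Compartment.FEATHER]

    def _fit_forms(obs):
        fits = []
        for form in _ALLOM_FORMS:
            try:
                fits.append(fit_allometric(obs, form))
            except (ValueError, RuntimeError):
                continue
        if len(fits) < 2:
            raise RuntimeError("fewer than two allometric forms could be fitted")
        return select_allometric(fits)

    carcass_ranking = _fit_forms(carcass_obs)
    feather_ranking = _fit_forms(feather_obs)

    # Amino-acid patterns from the packaged panels over the default windows.
    aac = representative_profile(
        load_panel("carcass"), cfg["composition"]["carcass_window"], ProfileRole.CARCASS
    )
    aaf = representative_profile(
        load_panel("feather"), cfg["composition"]["feather_window"], ProfileRole.FEATHER
    )

    if balance is None:
        balance = load_balance_groups()
    phases = {}
    for phase in (Phase.WEEK6_7, Phase.WEEK11_12):
        measured = None
        if aa_n_total_mode == "measured_scalar":
            ref = load_maintenance_reference(phase.value)
            measured = float(ref.loc["Nitrogen", "endogenous_mg_d"])
        phases[phase] = maintenance_phase(
            balance[(phase, Diet.NITROGEN_FREE)],
            balance[(phase, Diet.LOW_NITROGEN)],
            aac,
            aaf,
            load_endogenous_losses(phase.value),
            aa_n_total_mode=aa_n_total_mode,
            measured_aa_n_mg_day=measured,
        )

    def _fit_curves(obs, kind):
        if obs is None:
            d = cfg["digestibility"]["protein" if kind is NutrientKind.PROTEIN
                                     else "amino_acid"]
            return [DigestibilityCurve(CurveFamily(d["family"]),
                                       (float(d["c0"]), float(d["c1"])), kind)]
        fits = []
        for fam in _CURVE_FAMILIES:
            try:
                fits.append(fit_digestibility_curve(obs, fam))
            except (ValueError, RuntimeError):
                continue
        if len(fits) < 2:
            raise RuntimeError("fewer than two digestibility families could be fitted")
        return select_digestibility_curve(fits)

    apd_ranking = _fit_curves(apd_obs, NutrientKind.PROTEIN)
    aad_ranking = _fit_curves(aad_obs, NutrientKind.AMINO_ACID)

    bundle = ModelBundle(
        growth=growth,
        carcass_allom=carcass_ranking[0].params,
        feather_allom=feather_ranking[0].params,
        brooding=phases[Phase.WEEK6_7],
        early_growing=phases[Phase.WEEK11_12],
        aac=aac,
        aaf=aaf,
        apd_curve=apd_ranking[0],
        aad_curve=aad_ranking[0],
        phase_boundary_days=phase_boundary_days,
    )
    return PipelineFits(
        growth_ranking=growth_ranking,
        carcass_ranking=carcass_ranking,
        feather_ranking=feather_ranking,
        apd_ranking=apd_ranking,
        aad_ranking=aad_ranking,
        bundle=bundle,
    )
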