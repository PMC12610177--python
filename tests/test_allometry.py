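import numpy as np
import pytest

from pulletreq.allometry import (
    AllometricForm,
    AllometricParams,
    Compartment,
    ProteinObservation,
    deposition_rate,
    fit_allometric,
    power_vb_leading_constant,
    protein_mass,
    quadratic_vb_term_constants,
    select_allometric,
)
from pulletreq.growth import GrowthParams, predict_bw

BW_GRID = np.array([22.6, 120.0, 280.0, 460.0, 650.0, 840.0, 1031.0])
# the feather quadratic predicts negative mass below ~40 g live weight, so
# feather fitting data start at the 14-day weight
FEATHER_GRID = BW_GRID[1:]


def obs_from(params, compartment, bw=BW_GRID):
    return [
        ProteinObservation(bw=float(x), protein_mass=float(protein_mass(params, float(x))),
                           compartment=compartment)
        for x in bw
    ]


class TestProteinMass:
    def test_power_closed_form(self, carcass_power):
        assert protein_mass(carcass_power, 1000.0) == pytest.approx(
            0.181 * 1000.0**1.007, rel=1e-12
        )
        assert protein_mass(carcass_power, 1000.0) == pytest.approx(189.97, abs=0.1)

    def test_quadratic_arithmetic(self, feather_quadratic):
        assert protein_mass(feather_quadratic, 1000.0) == pytest.approx(71.007, rel=1e-9)

    def test_power_identity_exponent_is_linear(self):
        p = AllometricParams("power", 3.7, 1.0)
        assert protein_mass(p, 123.4) == pytest.approx(3.7 * 123.4, rel=1e-12)

    def test_nonpositive_bw_rejected(self, carcass_power):
        with pytest.raises(ValueError):
            protein_mass(carcass_power, 0.0)


class TestFit:
    def test_power_exact_recovery(self, carcass_power):
        fit = fit_allometric(obs_from(carcass_power, Compartment.CARCASS), "power")
        assert fit.params.b0 == pytest.approx(0.181, rel=1e-6)
        assert fit.params.b1 == pytest.approx(1.007, rel=1e-6)

    def test_quadratic_exact_recovery(self, feather_quadratic):
        fit = fit_allometric(
            obs_from(feather_quadratic, Compartment.FEATHER, bw=FEATHER_GRID), "quadratic"
        )
        assert fit.params.b0 == pytest.approx(-3.393, rel=1e-6)
        assert fit.params.b1 == pytest.approx(0.089, rel=1e-6)
        assert fit.params.b2 == pytest.approx(-1.46e-5, rel=1e-6)

    def test_too_few_observations_rejected(self, feather_quadratic):
        obs = obs_from(feather_quadratic, Compartment.FEATHER, bw=FEATHER_GRID[:3])
        with pytest.raises(ValueError):
            fit_allometric(obs, "quadratic")

    def test_selection_prefers_true_form_under_noise(self, carcass_power, feather_quadratic):
        """Across 100 noisy replicates (sd = 2 g) the feather quadratic wins
        the ranking in a majority of cases. The carcass exponent 1.007 makes
        power and linear nearly indistinguishable by construction (the same
        near-tie the published fit table shows at R2 = 0.998), so for the
        carcass the assertable property is weaker: power ranks in the top
        two forms in a majority of replicates and the exponential form never
        wins."""
        rng = np.random.default_rng(11)
        from collections import Counter

        wins = {"carcass": Counter(), "feather": Counter()}
        carcass_power_top2 = 0
        n_rep = 100
        for _ in range(n_rep):
            for key, truth, comp, grid in (
                ("carcass", carcass_power, Compartment.CARCASS, BW_GRID),
                ("feather", feather_quadratic, Compartment.FEATHER, FEATHER_GRID),
            ):
                obs = [
                    ProteinObservation(
                        bw=float(x),
                        protein_mass=float(
                            max(protein_mass(truth, float(x)) + rng.normal(0, 2.0), 0.0)
                        ),
                        compartment=comp,
                    )
                    for x in grid
                ]
                fits = []
                for f in AllometricForm:
                    try:
                        fits.append(fit_allometric(obs, f))
                    except (ValueError, RuntimeError):
                        pass
                ranked = select_allometric(fits)
                wins[key][ranked[0].params.form] += 1
                if key == "carcass" and AllometricForm.POWER in [
                    r.params.form for r in ranked[:2]
                ]:
                    carcass_power_top2 += 1
        assert wins["feather"][AllometricForm.QUADRATIC] > n_rep / 2
        assert carcass_power_top2 > n_rep / 2
        assert wins["carcass"][AllometricForm.EXPONENTIAL] == 0

    def test_exponent_recovery_under_noise(self, carcass_power):
        rng = np.random.default_rng(5)
        estimates = []
        for _ in range(100):
            obs = [
                ProteinObservation(
                    bw=float(x),
                    protein_mass=float(protein_mass(carcass_power, float(x)) + rng.normal(0, 2.0)),
                    compartment=Compartment.CARCASS,
                )
                for x in BW_GRID
            ]
            estimates.append(fit_allometric(obs, "power").params.b1)
        assert abs(float(np.mean(estimates)) - 1.007) < 0.02


class TestDeposition:
    def test_carcass_leading_constant(self, vb_params, carcass_power):
        k_const = power_vb_leading_constant(vb_params, carcass_power)
        assert k_const == pytest.approx(14.587, rel=5e-4)

    def test_feather_term_constants(self, vb_params, feather_quadratic):
        lin, quad = quadratic_vb_term_constants(vb_params, feather_quadratic)
        assert lin == pytest.approx(282.082, rel=5e-4)
        assert quad == pytest.approx(-130.717, rel=5e-4)

    def test_analytic_rate_matches_numeric_derivative(self, vb_params, carcass_power,
                                                      feather_quadratic):
        h = 1e-4
        for t in (0.5, 5.0, 20.0, 33.7, 60.0, 84.0):
            rates = deposition_rate(vb_params, carcass_power, feather_quadratic, t)

            def mass(params, tt):
                return protein_mass(params, predict_bw(vb_params, tt))

            num_c = (mass(carcass_power, t + h) - mass(carcass_power, t - h)) / (2 * h)
            num_f = (mass(feather_quadratic, t + h) - mass(feather_quadratic, t - h)) / (2 * h)
            assert rates.pr_c == pytest.approx(num_c, rel=1e-6)
            assert rates.pr_f == pytest.approx(num_f, rel=1e-6)

    def test_numeric_derivative_property_random_params(self, vb_params):
        """Chain-rule rates equal numeric derivatives for random valid
        parameter draws across forms and ages."""
        rng = np.random.default_rng(99)
        h = 1e-4
        for _ in range(25):
            growth = GrowthParams(
                "von_bertalanffy",
                A=float(rng.uniform(800, 2000)),
                b=float(rng.uniform(0.5, 0.95)),
                k=float(rng.uniform(0.01, 0.05)),
            )
            forms = [
                AllometricParams("linear", float(rng.uniform(-5, 5)), float(rng.uniform(0.01, 0.3))),
                AllometricParams("power", float(rng.uniform(0.05, 0.5)), float(rng.uniform(0.8, 1.2))),
                AllometricParams("quadratic", float(rng.uniform(-5, 5)),
                                 float(rng.uniform(0.01, 0.2)), float(rng.uniform(-3e-5, 3e-5))),
            ]
            t = float(rng.uniform(0.1, 120.0))
            for a1 in forms:
                for a2 in forms:
                    rates = deposition_rate(growth, a1, a2, t)
                    for params, got in ((a1, rates.pr_c), (a2, rates.pr_f)):
                        num = (
                            protein_mass(params, predict_bw(growth, t + h))
                            - protein_mass(params, predict_bw(growth, t - h))
                        ) / (2 * h)
                        assert got == pytest.approx(num, rel=1e-5, abs=1e-10)

    def test_carcass_rate_positive_with_interior_maximum(self, vb_params, carcass_power,
                                                         feather_quadratic):
        grid = np.linspace(0.0, 84.0, 841)
        pr_c = np.array([
            deposition_rate(vb_params, carcass_power, feather_quadratic, float(t)).pr_c
            for t in grid
        ])
        assert np.all(pr_c > 0)
        imax = int(np.argmax(pr_c))
        assert 0 < imax < len(grid) - 1  # unique interior maximum...
        # ...close to the growth inflection age
        assert grid[imax] == pytest.approx(33.68, abs=1.0)
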