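"""ITC forward model (perfusion bookkeeping) and global fitting."""

import numpy as np
import pytest

from pnpaging import (
    BindingSystem,
    ItcDesign,
    ItcExperiment,
    NoiseModel,
    fit_itc_global,
    generate_itc_experiments,
    simulate_itc,
)


def quadratic_free_ligand(l_tot, p_active, kd):
    b = kd + p_active - l_tot
    return (-b + np.sqrt(b * b + 4.0 * kd * l_tot)) / 2.0


@pytest.fixture(scope="module")
def design():
    return ItcExperiment("d", 200.0, 50.0, 3000.0, np.full(20, 2.0))


class TestForwardModel:
    def test_zero_enthalpy_returns_offset(self, design):
        system = BindingSystem((10.0, 100.0), (0.0, 0.0))
        ndh = simulate_itc(design, system, heat_offset=0.37)
        assert np.allclose(ndh, 0.37)

    def test_saturation_plateau_returns_to_offset(self):
        # tight site, strong ligand excess: cell is saturated after a few injections
        system = BindingSystem((0.5,), (-8.0,))
        exp = ItcExperiment("s", 200.0, 10.0, 1600.0, np.full(25, 2.0))
        ndh = simulate_itc(exp, system, heat_offset=-0.05)
        assert abs(ndh[0] - (-0.05)) > 1.0  # early injections release real heat
        assert ndh[-1] == pytest.approx(-0.05, abs=5e-3)

    def test_first_injection_matches_quadratic_closed_form(self):
        """Single-site first-injection heat rebuilt independently from the
        quadratic free-ligand solution and the displacement bookkeeping."""
        kd, dh, v0, p0, c_syr, v = 25.0, -6.0, 200.0, 40.0, 2400.0, 2.0
        system = BindingSystem((kd,), (dh,))
        exp = ItcExperiment("q", v0, p0, c_syr, np.array([v]))
        got = simulate_itc(exp, system)[0]

        d = v / v0
        p1 = p0 * (1 - d)
        l1 = c_syr * d
        free = quadratic_free_ligand(l1, p1, kd)
        q1 = v0 * p1 * dh * free / (kd + free)
        want = (q1 - 0.0 + d * (q1 + 0.0) / 2.0) / (v * c_syr)
        assert got == pytest.approx(want, rel=1e-6)

    def test_enthalpy_conservation_over_full_titration(self):
        """Sum of per-injection heats recovers active moles x sum(dH) within 2%
        once the titration saturates, at fine injection granularity."""
        system = BindingSystem((2.0, 10.0), (-5.0, -3.0))
        exp = ItcExperiment("c", 200.0, 20.0, 24000.0, np.full(80, 1.0))
        finc = 0.1
        ndh = simulate_itc(exp, system, incompetent_fraction=finc)
        moles_inj = exp.injection_volumes * exp.syringe_conc  # µL·µM units
        total_heat = float(np.sum(ndh * moles_inj))
        # initial active receptor content of the cell, same µL·µM units;
        # the displacement correction returns the heat carried out with the
        # expelled volume, so the sum approaches the initial active moles
        active0 = exp.cell_conc0 * (1 - finc) * exp.cell_volume
        expected = active0 * sum(system.dh)
        assert total_heat == pytest.approx(expected, rel=0.02)

    def test_heats_additive_in_dilute_receptor_limit(self):
        """With negligible receptor (no ligand depletion), a 3-site isotherm
        equals the sum of the three 1-site isotherms."""
        kd = (5.0, 50.0, 500.0)
        dh = (-4.0, -2.0, -6.0)
        vol = np.full(20, 2.0)
        three = simulate_itc(
            ItcExperiment("t", 200.0, 1e-4, 2000.0, vol), BindingSystem(kd, dh)
        )
        parts = [
            simulate_itc(
                ItcExperiment("p", 200.0, 1e-4, 2000.0, vol), BindingSystem((k,), (h,))
            )
            for k, h in zip(kd, dh)
        ]
        assert np.allclose(three, np.sum(parts, axis=0), rtol=1e-8)

    def test_requires_enthalpies(self, design):
        with pytest.raises(ValueError):
            simulate_itc(design, BindingSystem((10.0,)))


class TestGlobalFit:
    def test_one_site_roundtrip_zero_residuals(self):
        system = BindingSystem((30.0,), (-5.5,))
        designs = [ItcDesign(c, c * 40.0, experiment_id=f"e{c}") for c in (20.0, 80.0)]
        exps = generate_itc_experiments(designs, system, NoiseModel(scale=0.0))
        fit = fit_itc_global(exps, n_sites=1, seed=0, n_starts=4)
        assert fit.rss < 1e-10
        assert fit.params["kd1"] == pytest.approx(30.0, rel=1e-4)
        assert fit.params["dh1"] == pytest.approx(-5.5, rel=1e-4)

    def test_incompetent_fractions_recovered(self):
        """Local incompetent fractions come back to ±0.01 from noiseless data."""
        system = BindingSystem((8.85,), (-6.57,))
        fincs = (0.0784, 0.0664, 0.0050)
        designs = [
            ItcDesign(c, c * 40.0, experiment_id=f"e{i}")
            for i, c in enumerate((23.48, 69.28, 266.86))
        ]
        exps = generate_itc_experiments(
            designs, system, NoiseModel(scale=0.0), incompetent_fractions=fincs
        )
        fit = fit_itc_global(exps, n_sites=1, seed=0, n_starts=4)
        for ei, f in enumerate(fincs):
            assert fit.params[f"finc_{ei}"] == pytest.approx(f, abs=0.01)

    def test_exclude_first_injection_drops_points(self):
        system = BindingSystem((30.0,), (-5.5,))
        designs = [ItcDesign(50.0, 2000.0, experiment_id="e")]
        exps = generate_itc_experiments(designs, system, NoiseModel(scale=0.0))
        full = fit_itc_global(exps, n_sites=1, seed=0, n_starts=2)
        trimmed = fit_itc_global(exps, n_sites=1, seed=0, n_starts=2, exclude_first=True)
        assert trimmed.n == full.n - 1

    def test_noise_shrinks_toward_truth(self):
        """Fitted K_d converges to the generating value as noise shrinks."""
        system = BindingSystem((30.0,), (-5.5,))
        designs = [ItcDesign(c, c * 40.0, experiment_id=f"e{c}") for c in (20.0, 80.0)]
        errs = []
        for scale in (0.05, 0.005):
            exps = generate_itc_experiments(
                designs, system, NoiseModel(kind="gaussian_constant", scale=scale, seed=11)
            )
            fit = fit_itc_global(exps, n_sites=1, seed=0, n_starts=4)
            errs.append(abs(fit.params["kd1"] - 30.0) / 30.0)
        assert errs[1] < errs[0]
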