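"""Screened electrostatic binding model, Kd<->dG conversion, fits."""

import math

import numpy as np
import pytest

from cytodiff.binding import bound_fraction, effective_diffusion
from cytodiff.electrostatics import (
    GAS_CONSTANT,
    ChargeModelConstants,
    ChargeModelParams,
    IonicBindingParams,
    KdPoint,
    binding_free_energy,
    deff_of_charge,
    dg_from_kd,
    fit_charge_model,
    fit_ionic,
    kd_from_dg,
    screening_factor,
)

PRINTED_KD_TRIPLE = [(0.2, 6.7e-6), (0.8, 65e-6), (2.1, 155e-6)]


class TestBindingFreeEnergy:
    def test_zero_ionic_strength_no_screening(self):
        p = IonicBindingParams(-20400.0, -28900.0, 1.53)
        assert binding_free_energy(0.0, p) == -20400.0 - 28900.0

    def test_infinite_ionic_strength_leaves_non_ionic_part(self):
        p = IonicBindingParams(-20400.0, -28900.0, 1.53)
        assert binding_free_energy(1e6, p) == pytest.approx(-20400.0,
                                                            abs=1e-6)

    def test_matches_measured_affinity_at_physiological_salt(self):
        # dG(0.2 M) should be consistent with RT ln(6.7e-6) at 293 K
        p = IonicBindingParams(-20400.0, -28900.0, 1.53)
        dg = binding_free_energy(0.2, p)
        assert dg == pytest.approx(-29.0e3, abs=100.0)
        assert dg == pytest.approx(dg_from_kd(6.7e-6, 293.0), abs=150.0)

    def test_no_screening_parameter_means_flat_response(self):
        p = IonicBindingParams(-10000.0, -5000.0, c1=1e-9)
        assert binding_free_energy(3.0, p) == pytest.approx(-15000.0,
                                                            abs=1e-3)

    def test_rejects_negative_ionic_strength(self):
        p = IonicBindingParams(-20400.0, -28900.0, 1.53)
        with pytest.raises(ValueError):
            binding_free_energy(-0.1, p)


class TestKdDgConversion:
    def test_zero_energy_is_molar_standard_state(self):
        assert kd_from_dg(0.0, 293.0) == 1.0

    def test_round_trip(self):
        for dg in (-30000.0, -1.0, 0.0, 5000.0):
            assert dg_from_kd(kd_from_dg(dg, 293.0), 293.0) == pytest.approx(
                dg, abs=1e-9
            )

    def test_micromolar_affinity_energy(self):
        assert dg_from_kd(6.7e-6, 293.0) == pytest.approx(-2.90e4, rel=1e-2)

    def test_rejects_nonpositive_kd(self):
        with pytest.raises(ValueError):
            dg_from_kd(0.0, 293.0)


class TestFitIonic:
    def test_reproduces_printed_parameters(self):
        p = fit_ionic(PRINTED_KD_TRIPLE, temperature=293.0)
        assert p.dg_nio == pytest.approx(-20400.0, rel=0.02)
        assert p.dg_io0 == pytest.approx(-28900.0, rel=0.02)
        assert p.c1 == pytest.approx(1.53, rel=0.02)

    def test_three_points_interpolate_in_dg_space(self):
        p = fit_ionic(PRINTED_KD_TRIPLE, temperature=293.0)
        for ionic, kd in PRINTED_KD_TRIPLE:
            assert binding_free_energy(ionic, p) == pytest.approx(
                dg_from_kd(kd, 293.0), abs=1.0
            )

    def test_recovers_known_parameters_across_seeded_draws(self):
        rng = np.random.default_rng(42)
        for _ in range(50):
            dg_nio = rng.uniform(-30e3, -10e3)
            dg_io0 = rng.uniform(-40e3, -5e3)
            c1 = rng.uniform(0.5, 3.0)
            truth = IonicBindingParams(dg_nio, dg_io0, c1)
            ionic = np.array([0.05, 0.2, 0.8, 2.1])
            kds = [kd_from_dg(binding_free_energy(i, truth), 293.0)
                   for i in ionic]
            fit = fit_ionic(list(zip(ionic, kds)), temperature=293.0)
            assert fit.dg_nio == pytest.approx(dg_nio, rel=1e-6)
            assert fit.dg_io0 == pytest.approx(dg_io0, rel=1e-6)
            assert fit.c1 == pytest.approx(c1, rel=1e-6)

    def test_rejects_underdetermined_input(self):
        with pytest.raises(ValueError):
            fit_ionic(PRINTED_KD_TRIPLE[:2])
        with pytest.raises(ValueError):
            fit_ionic([(0.2, 1e-6), (0.2, 2e-6), (0.8, 3e-6)])

    def test_rejects_invalid_points(self):
        with pytest.raises(ValueError):
            KdPoint(ionic_strength=-0.1, kd=1e-6)
        with pytest.raises(ValueError):
            KdPoint(ionic_strength=0.1, kd=0.0)


class TestDeffOfCharge:
    def test_no_binding_limit_is_free_diffusion(self):
        p = ChargeModelParams(dg_nio=50000.0, dg_pc=-1000.0, c1=1.53)
        assert deff_of_charge(-30.0, p) == pytest.approx(10.0, rel=1e-6)

    def test_saturated_binding_limit_is_ribosome_diffusion(self):
        p = ChargeModelParams(dg_nio=-80000.0, dg_pc=-1000.0, c1=1.53)
        assert deff_of_charge(25.0, p) == pytest.approx(0.04, rel=1e-6)

    def test_monotone_non_increasing_in_charge(self):
        p = ChargeModelParams(dg_nio=-20400.0, dg_pc=-1156.0, c1=1.53)
        charges = np.linspace(-30, 25, 23)
        deff = deff_of_charge(charges, p)
        assert np.all(np.diff(deff) <= 1e-12)
        assert np.all((deff >= 0.04 - 1e-12) & (deff <= 10.0 + 1e-12))

    def test_composition_equals_elementary_relations(self):
        # the D_eff(charge) expression is exactly the composition of the
        # screened free energy, the 1 M-standard-state Kd, the saturation
        # law and the two-state mixing rule
        const = ChargeModelConstants()
        p = ChargeModelParams(-20400.0, -1156.0, 1.53, const)
        for q in (-30.0, 0.0, 11.0, 25.0):
            dg = -20400.0 + (-1156.0) * q * screening_factor(
                const.ionic_strength, 1.53
            )
            kd_uM = kd_from_dg(dg, const.temperature) * 1e6
            f_bound = bound_fraction(kd_uM, const.site_conc * 1e6)
            expected = effective_diffusion(1.0 - f_bound, const.d_free,
                                           const.d_bound)
            assert deff_of_charge(q, p) == pytest.approx(expected, rel=1e-12)


class TestFitChargeModel:
    TRUE = ChargeModelParams(-20400.0, -1156.0, 1.53)
    CHARGES = [-30.0, -7.0, 0.0, 7.0, 11.0, 15.0, 25.0]

    def _points(self):
        return [(q, deff_of_charge(q, self.TRUE)) for q in self.CHARGES]

    def test_noiseless_recovery_of_identifiable_parameters(self):
        # at one fixed ionic strength dg_pc and c1 enter only via their
        # product, so the identifiable quantities are dg_nio, the charge
        # slope and the fitted curve itself
        fit = fit_charge_model(self._points())
        assert fit.params.dg_nio == pytest.approx(-20400.0, rel=1e-4)
        true_slope = -1156.0 * float(screening_factor(0.2, 1.53))
        assert fit.charge_slope == pytest.approx(true_slope, rel=1e-4)
        for q, d in self._points():
            assert deff_of_charge(q, fit.params) == pytest.approx(d,
                                                                  rel=1e-4)

    def test_fit_is_locally_optimal_on_measured_medians(self):
        # representative population values across the charge series
        points = [(-30.0, 10.0), (-7.0, 10.0), (0.0, 8.6), (11.0, 2.7),
                  (25.0, 0.14)]
        fit = fit_charge_model(points)
        q = np.array([p[0] for p in points])
        logd = np.log10([p[1] for p in points])

        def rss(params):
            return float(np.sum(
                (np.log10(deff_of_charge(q, params)) - logd) ** 2
            ))

        base = rss(fit.params)
        assert base == pytest.approx(fit.rss, rel=1e-9, abs=1e-12)
        for factor in (0.9, 1.1):
            for i in range(3):
                vals = [fit.params.dg_nio, fit.params.dg_pc, fit.params.c1]
                vals[i] *= factor
                assert rss(ChargeModelParams(*vals)) >= base - 1e-12

    def test_flat_data_at_free_diffusion_is_flagged(self):
        points = [(q, 10.0) for q in self.CHARGES]
        fit = fit_charge_model(points)
        assert fit.boundary

    def test_rejects_underdetermined_input(self):
        with pytest.raises(ValueError):
            fit_charge_model(self._points()[:3])
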