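"""Forward diffusion model and FRAP fitting."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cytodiff.frap import (
    GaussianSpreadOracle,
    LineProfileStack,
    evolve_profile,
    fit_frap,
    gaussian_profile,
    read_stack,
    write_stack,
)
from cytodiff.synth import FrapSynthesisConfig, generate_frap_stack


def centered_grid(length, dx):
    n = int(round(length / dx))
    return (np.arange(n) + 0.5) * dx - length / 2


class TestEvolveProfile:
    def test_uniform_profile_is_steady_state(self):
        out = evolve_profile(np.full(16, 3.7), D=5.0, dx=0.2,
                             times=np.array([0.0, 0.1, 1.0]))
        assert np.allclose(out, 3.7, rtol=0, atol=1e-12)

    def test_zero_diffusion_freezes_profile(self):
        profile = np.array([1.0, 0.2, 0.8, 1.0, 0.5])
        out = evolve_profile(profile, D=0.0, dx=0.1,
                             times=np.array([0.0, 0.5, 2.0]))
        assert np.array_equal(out[1], profile)
        assert np.array_equal(out[2], profile)

    def test_matches_free_space_gaussian(self):
        # domain large enough (40 um) that the reflecting walls are
        # irrelevant for a sigma0=0.2 um pulse spread to sigma~1.4 um
        x = centered_grid(40.0, 0.05)
        oracle = GaussianSpreadOracle(sigma0=0.2, D=1.0)
        init = gaussian_profile(oracle, x, 0.0)
        out = evolve_profile(init, 1.0, 0.05, np.array([0.0, 1.0]))
        ref = gaussian_profile(oracle, x, 1.0)
        rel_l2 = np.linalg.norm(out[1] - ref) / np.linalg.norm(ref)
        assert rel_l2 < 1e-3

    def test_converges_to_spatial_mean(self):
        profile = np.array([1.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 1.0])
        out = evolve_profile(profile, D=1.0, dx=0.1,
                             times=np.array([0.0, 100.0]))
        assert np.allclose(out[1], profile.mean(), atol=1e-8)

    @pytest.mark.parametrize("bad", [
        dict(D=-1.0, dx=0.1),
        dict(D=1.0, dx=0.0),
        dict(D=1.0, dx=-0.5),
    ])
    def test_rejects_bad_arguments(self, bad):
        with pytest.raises(ValueError):
            evolve_profile(np.ones(4), times=np.array([0.0, 1.0]), **bad)

    def test_rejects_times_not_starting_at_zero(self):
        with pytest.raises(ValueError):
            evolve_profile(np.ones(4), 1.0, 0.1, np.array([0.1, 0.2]))

    @given(st.lists(st.floats(0.0, 10.0), min_size=4, max_size=32),
           st.floats(0.01, 20.0))
    @settings(max_examples=40, deadline=None)
    def test_mass_conservation_and_maximum_principle(self, values, d):
        profile = np.asarray(values)
        out = evolve_profile(profile, d, dx=0.25,
                             times=np.array([0.0, 0.05, 0.5]))
        total = profile.sum()
        for row in out:
            assert abs(row.sum() - total) <= 1e-10 * max(total, 1.0)
            assert row.min() >= profile.min() - 1e-12
            assert row.max() <= profile.max() + 1e-12


class TestGaussianProfile:
    def test_initial_width_is_sigma0(self):
        x = centered_grid(20.0, 0.02)
        oracle = GaussianSpreadOracle(sigma0=0.5, D=2.0, amplitude=3.0)
        v = gaussian_profile(oracle, x, 0.0)
        sd = np.sqrt(np.sum(v * x**2) / np.sum(v))
        assert sd == pytest.approx(0.5, abs=1e-3)
        assert np.sum(v) * 0.02 == pytest.approx(3.0, rel=1e-12)

    def test_variance_additivity(self):
        # sigma^2(t) = sigma0^2 + 2 D t: 0.25 + 2*2*0.25 = 1.25
        x = centered_grid(40.0, 0.02)
        oracle = GaussianSpreadOracle(sigma0=0.5, D=2.0)
        v = gaussian_profile(oracle, x, 0.25)
        sd = np.sqrt(np.sum(v * x**2) / np.sum(v))
        assert sd == pytest.approx(np.sqrt(1.25), abs=1e-3)

    def test_zero_diffusion_keeps_width(self):
        x = centered_grid(20.0, 0.02)
        frozen = GaussianSpreadOracle(sigma0=0.5, D=0.0)
        assert np.allclose(gaussian_profile(frozen, x, 5.0),
                           gaussian_profile(frozen, x, 0.0))

    def test_rejects_negative_time_and_sigma(self):
        with pytest.raises(ValueError):
            gaussian_profile(GaussianSpreadOracle(0.5, 1.0),
                             centered_grid(10, 0.1), -1.0)
        with pytest.raises(ValueError):
            GaussianSpreadOracle(sigma0=0.0, D=1.0)


class TestFitFrap:
    def test_noiseless_round_trip_within_1_percent(self):
        stack = generate_frap_stack(
            FrapSynthesisConfig(d_true=10.0, noise_sd=0.0, seed=1)
        )
        res = fit_frap(stack)
        assert res.converged and res.identifiable
        assert res.D == pytest.approx(10.0, rel=0.01)

    def test_slow_regime_with_noise_within_5_percent(self):
        # slowest regime observed for the most positive probe
        stack = generate_frap_stack(FrapSynthesisConfig(
            d_true=0.14, noise_sd=0.02, n_pixels=16, n_frames=150,
            frame_interval=0.1, seed=7,
        ))
        res = fit_frap(stack)
        assert res.D == pytest.approx(0.14, rel=0.05)

    def test_uniform_stack_flagged_non_identifiable(self):
        n = 12
        rng = np.random.default_rng(0)
        intens = 1.0 + rng.normal(0, 0.02, (20, n))
        stack = LineProfileStack(
            positions=np.arange(n) * 0.25,
            times=np.arange(20) * 0.01,
            intensities=np.clip(intens, 0, None),
        )
        res = fit_frap(stack)
        assert not res.identifiable
        assert not res.converged
        assert np.isnan(res.D)

    def test_grid_refinement_changes_d_by_less_than_half_percent(self):
        base = FrapSynthesisConfig(d_true=5.0, noise_sd=0.0, n_pixels=16,
                                   seed=3)
        fine = FrapSynthesisConfig(d_true=5.0, noise_sd=0.0, n_pixels=32,
                                   n_frames=99, frame_interval=0.002, seed=3)
        d_base = fit_frap(generate_frap_stack(base)).D
        d_fine = fit_frap(generate_frap_stack(fine)).D
        assert abs(d_fine / d_base - 1) < 0.005

    def test_deterministic_for_fixed_input(self):
        stack = generate_frap_stack(
            FrapSynthesisConfig(d_true=2.0, noise_sd=0.02, seed=11)
        )
        assert fit_frap(stack).D == fit_frap(stack).D

    def test_rejects_too_few_frames(self):
        stack = generate_frap_stack(
            FrapSynthesisConfig(d_true=1.0, n_frames=2, noise_sd=0.0)
        )
        with pytest.raises(ValueError):
            fit_frap(stack)

    def test_scale_and_offset_are_recovered(self):
        stack = generate_frap_stack(
            FrapSynthesisConfig(d_true=3.0, noise_sd=0.0, seed=2)
        )
        scaled = LineProfileStack(
            positions=stack.positions,
            times=stack.times,
            intensities=1.7 * stack.intensities + 0.3,
        )
        res = fit_frap(scaled, normalize=False)
        assert res.D == pytest.approx(3.0, rel=0.01)
        # the affine transform commutes with the diffusion operator, so the
        # fitted profiles still track the transformed data closely
        assert np.max(np.abs(res.profile_fit - scaled.intensities)) < 1e-3


class TestStackValidation:
    def test_rejects_non_uniform_grid(self):
        with pytest.raises(ValueError):
            LineProfileStack(
                positions=np.array([0.0, 0.1, 0.3]),
                times=np.array([0.0, 0.1]),
                intensities=np.ones((2, 3)),
            )

    def test_rejects_negative_intensity(self):
        with pytest.raises(ValueError):
            LineProfileStack(
                positions=np.arange(3) * 0.1,
                times=np.array([0.0, 0.1]),
                intensities=np.array([[1.0, -0.1, 1.0], [1, 1, 1.0]]),
            )

    def test_rejects_shape_mismatch(self):
        with pytest.raises(ValueError):
            LineProfileStack(
                positions=np.arange(4) * 0.1,
                times=np.array([0.0, 0.1]),
                intensities=np.ones((2, 3)),
            )


class TestStackIO:
    def test_csv_round_trip(self, tmp_path):
        stack = generate_frap_stack(
            FrapSynthesisConfig(d_true=4.0, noise_sd=0.02, seed=5)
        )
        path = tmp_path / "stack.csv"
        write_stack(stack, path)
        loaded = read_stack(path)
        assert np.allclose(loaded.positions, stack.positions)
        assert np.allclose(loaded.times, stack.times)
        assert np.allclose(loaded.intensities, stack.intensities)
        assert np.allclose(loaded.prebleach_profile, stack.prebleach_profile)
        assert fit_frap(loaded).D == pytest.approx(fit_frap(stack).D,
                                                   rel=1e-9)
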