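"""Exponential tilting, multiplier solving and the reference inversion."""

import math

import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy.linalg import null_space

from isomaxent.data_io import COLLAPSED_4, ExpressionProfile, IsotypeScheme
from isomaxent.maxent import (
    CalibrationConstants,
    EnergyVector,
    MaxEntProblem,
    MissingDataError,
    constraint_gap,
    derivative_energies,
    infer_reference_energies,
    mean_energy_from_logic50,
    posterior_weights,
    predict_expression,
    relative_entropy,
    solvable,
    solve_beta,
)
from isomaxent.synthetic import make_scenario

S2 = IsotypeScheme("two", ("A", "B"))


def _profile(fractions, scheme=None):
    fractions = np.asarray(fractions, float)
    scheme = scheme or IsotypeScheme(
        f"s{len(fractions)}", tuple(f"S{k}" for k in range(len(fractions)))
    )
    return ExpressionProfile("x", "colchicine", scheme, fractions)


def _problem(prior, energies, target):
    p = _profile(prior)
    return MaxEntProblem(p, EnergyVector(p.scheme, np.asarray(energies, float)), target)


class TestCalibration:
    def test_identity_calibration(self):
        calib = CalibrationConstants(slope=1.0, intercept=0.0)
        assert mean_energy_from_logic50(-6.46, calib) == -6.46

    def test_default_affinity_convention(self):
        assert mean_energy_from_logic50(-6.46, CalibrationConstants()) == pytest.approx(
            8.824, abs=1e-3
        )

    def test_zero_slope_rejected(self):
        with pytest.raises(ValueError):
            CalibrationConstants(slope=0.0)

    def test_missing_input_distinct_error(self):
        with pytest.raises(MissingDataError):
            mean_energy_from_logic50(float("nan"), CalibrationConstants())


class TestPosteriorWeights:
    def test_zero_multiplier_returns_prior(self):
        p = _profile([0.2, 0.3, 0.5])
        e = EnergyVector(p.scheme, [1.0, -2.0, 5.0])
        assert posterior_weights(p, e, 0.0).fractions == pytest.approx(p.fractions)

    def test_constant_energies_leave_prior(self):
        p = _profile([0.1, 0.9])
        e = EnergyVector(p.scheme, [3.0, 3.0])
        assert posterior_weights(p, e, 7.5).fractions == pytest.approx(p.fractions)

    def test_two_state_closed_form(self):
        p = _profile([0.5, 0.5])
        e = EnergyVector(p.scheme, [0.0, 1.0])
        post = posterior_weights(p, e, math.log(3)).fractions
        assert post == pytest.approx([0.75, 0.25], abs=1e-12)

    def test_stabilized_for_extreme_multiplier(self):
        p = _profile([0.5, 0.5])
        e = EnergyVector(p.scheme, [0.0, 1.0])
        post = posterior_weights(p, e, 700.0).fractions
        assert np.isfinite(post).all()
        assert post == pytest.approx([1.0, 0.0], abs=1e-12)


class TestConstraintGap:
    def test_zero_multiplier_gap_is_prior_mean_minus_target(self):
        prob = _problem([0.25, 0.75], [1.0, 3.0], 2.0)
        assert constraint_gap(prob, 0.0) == pytest.approx(0.25 * 1 + 0.75 * 3 - 2.0)

    def test_root_matches_closed_form(self):
        prob = _problem([0.5, 0.5], [0.0, 1.0], 0.25)
        assert constraint_gap(prob, math.log(3)) == pytest.approx(0.0, abs=1e-12)

    @given(
        st.integers(0, 2**31 - 1),
        st.floats(-3, 3),
        st.floats(0.01, 3),
    )
    def test_monotone_decreasing_in_beta(self, seed, beta, h):
        rng = np.random.default_rng(seed)
        prior = rng.dirichlet(np.ones(4))
        energies = rng.uniform(-10, 10, 4)
        prob = _problem(prior, energies, 0.0)
        assert constraint_gap(prob, beta + h) <= constraint_gap(prob, beta) + 1e-9


class TestSolvable:
    @pytest.mark.parametrize(
        "prior, energies, target, expected",
        [
            ([0.5, 0.5], [0.0, 1.0], 0.25, True),
            ([0.5, 0.5], [0.0, 1.0], 1.5, False),
            ([1.0, 0.0], [0.0, 1.0], 0.5, False),  # support excludes upper state
            ([0.5, 0.5], [2.0, 2.0], 2.0, True),  # degenerate equal energies
            ([0.5, 0.5], [0.0, 1.0], 1.0, False),  # boundary is not attainable
        ],
    )
    def test_hull_condition(self, prior, energies, target, expected):
        assert solvable(_problem(prior, energies, target)) is expected


class TestSolveBeta:
    def test_two_state_closed_form(self):
        sol = solve_beta(_problem([0.5, 0.5], [0.0, 1.0], 0.25))
        assert sol.solvable
        assert sol.beta == pytest.approx(math.log(3), abs=1e-10)
        assert sol.posterior == pytest.approx([0.75, 0.25], abs=1e-10)

    def test_target_at_prior_mean_gives_zero_beta(self):
        prior = np.array([0.2, 0.3, 0.5])
        energies = np.array([-1.0, 0.5, 2.0])
        sol = solve_beta(_problem(prior, energies, float(prior @ energies)))
        assert sol.beta == pytest.approx(0.0, abs=1e-10)
        assert sol.posterior == pytest.approx(prior, abs=1e-9)

    def test_outside_hull_returns_zero_posterior(self):
        sol = solve_beta(_problem([0.5, 0.5], [0.0, 1.0], 1.5))
        assert not sol.solvable
        assert (sol.posterior == 0).all()

    def test_initial_guess_does_not_change_root(self):
        prob = _problem([0.3, 0.3, 0.4], [-5.0, 1.0, 4.0], 2.0)
        betas = [solve_beta(prob, beta0=b0).beta for b0 in (-9.5, 0.0, 7.25)]
        assert max(betas) - min(betas) < 1e-9

    @pytest.mark.parametrize("seed", range(20))
    def test_agrees_with_grid_search_oracle(self, seed):
        """Coarse-to-fine exhaustive search over beta on 3-state problems."""
        rng = np.random.default_rng(seed)
        sc = make_scenario(
            3, beta_true=float(rng.uniform(-3, 3)), energy_range=(-10, 10), seed=seed
        )
        prior, energies, target = (
            sc.prior.fractions,
            sc.energies.values,
            sc.target_mean,
        )
        sol = solve_beta(MaxEntProblem(sc.prior, sc.energies, target))

        def grid_argmin(lo, hi, n):
            betas = np.linspace(lo, hi, n)
            logw = np.log(prior)[None, :] - betas[:, None] * energies[None, :]
            logw -= logw.max(axis=1, keepdims=True)
            w = np.exp(logw)
            means = (w * energies).sum(axis=1) / w.sum(axis=1)
            return betas[np.argmin(np.abs(means - target))]

        coarse = grid_argmin(-20.0, 20.0, 40001)  # step 1e-3
        fine = grid_argmin(coarse - 2e-3, coarse + 2e-3, 4001)  # step 1e-6
        assert abs(sol.beta - fine) < 1e-5

    @pytest.mark.parametrize("seed", range(10))
    def test_entropy_beats_constraint_satisfying_perturbations(self, seed):
        """Relative entropy of the solution majorizes projected alternatives."""
        rng = np.random.default_rng(1000 + seed)
        n = 5
        prior = rng.dirichlet(np.ones(n))
        energies = rng.uniform(-8, 8, n)
        prob = _problem(prior, energies, float(prior @ energies) * 0.9 + 0.1 * energies.max())
        if not solvable(prob):
            pytest.skip("random instance outside hull")
        sol = solve_beta(prob)
        s_star = relative_entropy(sol.posterior, prior)
        # perturbation directions keep both normalization and the mean fixed
        basis = null_space(np.vstack([np.ones(n), energies]))
        for _ in range(100):
            d = basis @ rng.normal(size=basis.shape[1])
            scale = 0.5 * rng.random()
            q = sol.posterior + scale * d
            if (q < 0).any():
                continue
            q = np.clip(q, 0, None)
            assert relative_entropy(q, prior) <= s_star + 1e-6


class TestReferenceInversion:
    def test_uniform_prior_gives_constant_energies(self):
        p = _profile([0.25] * 4, COLLAPSED_4)
        ref, beta_c = infer_reference_energies(p, 8.82)
        assert ref.values == pytest.approx([8.82] * 4, abs=1e-12)
        assert beta_c == pytest.approx(math.log(4) / 8.82)

    def test_entropy_of_a549_profile(self, expression):
        a549 = next(
            p for p in expression
            if p.cell_line == "A549" and p.treatment == "colchicine"
        )
        s = -(a549.fractions * np.log(a549.fractions)).sum()
        assert s == pytest.approx(1.094, abs=1e-3)

    def test_reconstruction_round_trip(self, expression):
        a549 = next(
            p for p in expression
            if p.cell_line == "A549" and p.treatment == "colchicine"
        )
        target = mean_energy_from_logic50(-6.46, CalibrationConstants())
        ref, beta_c = infer_reference_energies(a549, target)
        # the tilted uniform prior must reproduce the measured profile
        uniform = _profile([0.25] * 4, COLLAPSED_4)
        post = posterior_weights(uniform, ref, beta_c).fractions
        assert post == pytest.approx(a549.fractions, abs=1e-12)
        assert float(a549.fractions @ ref.values) == pytest.approx(target)

    def test_zero_fraction_rejected(self):
        p = _profile([0.5, 0.5, 0.0, 0.0], COLLAPSED_4)
        with pytest.raises(ValueError, match="floor"):
            infer_reference_energies(p, 5.0)

    def test_one_hot_prior_rejected(self):
        p = _profile([1.0, 0.0], S2)
        with pytest.raises(ValueError):
            infer_reference_energies(p, 5.0)


class TestDerivativeEnergies:
    def test_zero_shift_is_identity(self):
        ref = EnergyVector(COLLAPSED_4, [1.0, 2.0, 3.0, 4.0])
        out = derivative_energies(ref, np.zeros(4))
        assert out.values == pytest.approx(ref.values)

    def test_collapsed_d20_ordering(self, binding):
        from isomaxent.data_io import collapse_isotypes

        c4 = collapse_isotypes(binding, COLLAPSED_4)
        ddg, _ = c4.row("D20")
        ref = EnergyVector(COLLAPSED_4, np.full(4, 8.82))
        out = derivative_energies(ref, ddg)
        order = np.argsort(out.values)
        assert [COLLAPSED_4.labels[i] for i in order] == ["IV", "I", "II", "III"]

    def test_sd_variants_shift_by_sd(self, binding):
        m, s = binding.row("D20")
        ref = EnergyVector(binding.scheme, np.zeros(6))
        up = derivative_energies(ref, m, s, "mean+sd")
        down = derivative_energies(ref, m, s, "mean-sd")
        assert up.values == pytest.approx(m + s)
        assert down.values == pytest.approx(m - s)

    def test_scheme_mismatch_rejected(self):
        ref = EnergyVector(COLLAPSED_4, np.zeros(4))
        with pytest.raises(ValueError):
            derivative_energies(ref, np.zeros(6))


class TestPredictExpression:
    def test_recovers_known_multiplier(self):
        sc = make_scenario(4, beta_true=1.3, seed=5)
        calib = CalibrationConstants(slope=1.0, intercept=0.0)
        sol = predict_expression(
            sc.prior, sc.energies, sc.target_mean, calib, n_restarts=10, seed=0
        )
        assert sol.solvable
        assert sol.beta == pytest.approx(1.3, abs=1e-8)
        assert sol.posterior == pytest.approx(sc.posterior_true.fractions, abs=1e-8)
        assert sol.beta_sd == pytest.approx(0.0, abs=1e-9)

    def test_missing_logic50_is_distinct_from_unsolvable(self):
        sc = make_scenario(4, beta_true=0.5, seed=1)
        calib = CalibrationConstants(slope=1.0)
        with pytest.raises(MissingDataError):
            predict_expression(sc.prior, sc.energies, float("nan"), calib)
        # an out-of-hull target, in contrast, reports unsolvable
        sol = predict_expression(
            sc.prior, sc.energies, sc.energies.values.max() + 1.0, calib
        )
        assert not sol.solvable

    def test_colchicine_self_prediction_round_trip(self, expression):
        """Reference inversion + zero relative shift reproduces the prior."""
        calib = CalibrationConstants()
        for line, lic50 in [("A549", -6.46), ("HeLa", -6.86), ("M010B", -7.70)]:
            prior = next(
                p for p in expression
                if p.cell_line == line and p.treatment == "colchicine"
            ).floored(1e-4)
            ref, _ = infer_reference_energies(
                prior, mean_energy_from_logic50(lic50, calib)
            )
            sol = predict_expression(prior, ref, lic50, calib, n_restarts=5)
            assert sol.posterior == pytest.approx(prior.fractions, abs=1e-10)
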