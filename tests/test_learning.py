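"""Learning-layer tests: prior closed forms, objective symmetry, gradient
correctness by finite differences, optimizer contracts, and the window
heuristic's rule table and bookkeeping."""

import math
from dataclasses import replace

import numpy as np
import pytest
from scipy.special import gammaln

from dispos.learning import (
    Hyperparams,
    MspProblem,
    OptimizerConfig,
    apply_modification,
    count_detected_promoters,
    count_predicted_promoters,
    expand,
    insignificant_positions,
    log_prior,
    msp_objective,
    optimize,
    propose_modification,
    shift_left,
    shift_right,
    train_dispom,
    truncate,
)
from dispos.model import (
    BackgroundModel,
    ClassPriors,
    FlankingModel,
    ModelError,
    PWM,
    PositionPrior,
    ZoopsParams,
)
from dispos.seqdata import Sequence, build_dataset

from conftest import random_simplex, random_sequences, random_zoops


def uniform_zoops(w=3, L=12, p_occ=0.5):
    # all-uniform emissions: the ZOOPS likelihood collapses to 0.25^L for
    # any occurrence probability; gamma kept interior for a finite prior
    return ZoopsParams(
        p_occ=p_occ,
        pwm=PWM.uniform(w),
        flanking=FlankingModel.uniform(),
        position=PositionPrior(gamma=0.5, xi=(L - w) / 2, omega=L / 6),
    )


class TestLogPrior:
    def test_uniform_pwm_maximizes_dirichlet_part(self, rng):
        hyper = Hyperparams()
        bg = BackgroundModel.uniform(0)
        base = uniform_zoops()
        val_uniform = log_prior(base, bg, ClassPriors(0.5), hyper)
        for _ in range(10):
            other = replace(base, pwm=PWM(random_simplex(rng, 4, 3)))
            assert log_prior(other, bg, ClassPriors(0.5), hyper) <= val_uniform

    def test_gamma_term_closed_form(self):
        # difference of log priors at two scale values isolates the Gamma term
        hyper = Hyperparams(omega_prior_shape=2.0, omega_prior_rate=0.05)
        bg = BackgroundModel.uniform(0)
        base = uniform_zoops()
        a = replace(base, position=replace(base.position, omega=20.0))
        b = replace(base, position=replace(base.position, omega=35.0))

        def gamma_logpdf(om):
            k, r = 2.0, 0.05
            return (k - 1) * math.log(om) - r * om + k * math.log(r) - gammaln(k)

        got = log_prior(a, bg, ClassPriors(0.5), hyper) - log_prior(
            b, bg, ClassPriors(0.5), hyper
        )
        want = gamma_logpdf(20.0) - gamma_logpdf(35.0)
        assert got == pytest.approx(want, rel=1e-12)

    def test_doubling_ess_concentrates_prior(self):
        bg = BackgroundModel.uniform(0)
        weak, strong = Hyperparams(ess_motif=4), Hyperparams(ess_motif=8)
        base = uniform_zoops()
        tilted = replace(base, pwm=PWM(np.tile([0.4, 0.2, 0.2, 0.2], (3, 1))))
        drop_weak = log_prior(base, bg, ClassPriors(0.5), weak) - log_prior(
            tilted, bg, ClassPriors(0.5), weak
        )
        drop_strong = log_prior(base, bg, ClassPriors(0.5), strong) - log_prior(
            tilted, bg, ClassPriors(0.5), strong
        )
        assert drop_strong > drop_weak

    def test_boundary_parameters_give_minus_inf(self):
        bg = BackgroundModel.uniform(0)
        degenerate = replace(
            uniform_zoops(), pwm=PWM(np.tile([1.0, 0.0, 0.0, 0.0], (3, 1)))
        )
        assert log_prior(degenerate, bg, ClassPriors(0.5), Hyperparams()) == -np.inf


class TestMspObjective:
    def test_identical_likelihoods_give_n_log_half(self, tiny_dataset):
        fg = uniform_zoops(p_occ=0.5)
        bg = BackgroundModel.uniform(0)
        hyper = Hyperparams.default_for(12, 3)
        obj = msp_objective(fg, bg, ClassPriors(0.5), tiny_dataset, hyper)
        prior = log_prior(fg, bg, ClassPriors(0.5), hyper)
        assert obj - prior == pytest.approx(8 * math.log(0.5), rel=1e-12)

    def test_conditional_part_is_nonpositive(self, rng, tiny_dataset):
        hyper = Hyperparams.default_for(12, 3)
        for _ in range(5):
            fg = random_zoops(rng, 12, 3)
            bg = BackgroundModel(
                order=1,
                conditional=random_simplex(rng, 4, 4),
                initial=random_simplex(rng, 4, 1),
            )
            priors = ClassPriors(float(rng.uniform(0.1, 0.9)))
            obj = msp_objective(fg, bg, priors, tiny_dataset, hyper)
            assert obj - log_prior(fg, bg, priors, hyper) <= 1e-12

    def test_gradient_matches_finite_differences(self, rng, tiny_dataset):
        hyper = Hyperparams.default_for(12, 3)
        problem = MspProblem(tiny_dataset, hyper, w=3, bg_order=2)
        fg = random_zoops(rng, 12, 3)
        bg = BackgroundModel(
            order=2,
            conditional=random_simplex(rng, 4, 16),
            initial=random_simplex(rng, 4, 2),
        )
        vec = problem.pack(fg, bg, ClassPriors(0.45))
        _, grad = problem.value_and_grad(vec)
        h = 1e-6
        for i in range(len(vec)):
            vp, vm = vec.copy(), vec.copy()
            vp[i] += h
            vm[i] -= h
            fd = (problem.value(vp) - problem.value(vm)) / (2 * h)
            # relative 1e-5 with an absolute floor: near-zero gradients are
            # dominated by finite-difference truncation noise
            denom = max(1e-2, abs(fd) + abs(grad[i]))
            assert abs(grad[i] - fd) / denom < 1e-5, f"parameter {i}"

    def test_pack_unpack_round_trip(self, rng, tiny_dataset):
        hyper = Hyperparams.default_for(12, 3)
        problem = MspProblem(tiny_dataset, hyper, w=3, bg_order=1)
        fg = random_zoops(rng, 12, 3)
        fg = replace(fg, strand_weight=0.5)
        bg = BackgroundModel(
            order=1,
            conditional=random_simplex(rng, 4, 4),
            initial=random_simplex(rng, 4, 1),
        )
        fg2, bg2, priors2 = problem.unpack(problem.pack(fg, bg, ClassPriors(0.3)))
        np.testing.assert_allclose(fg2.pwm.probs, fg.pwm.probs, rtol=1e-12)
        np.testing.assert_allclose(bg2.conditional, bg.conditional, rtol=1e-12)
        assert fg2.p_occ == pytest.approx(fg.p_occ, rel=1e-12)
        assert priors2.pi_fg == pytest.approx(0.3, rel=1e-12)


class TestOptimize:
    def _setup(self, rng, n=10, L=20, w=3):
        data = build_dataset(
            random_sequences(rng, n, L, "f"), random_sequences(rng, n, L, "b"),
            tss_offset=-L,
        )
        fg = random_zoops(rng, L, w)
        fg = replace(fg, strand_weight=0.5)
        bg = BackgroundModel(
            order=1,
            conditional=random_simplex(rng, 4, 4),
            initial=random_simplex(rng, 4, 1),
        )
        hyper = Hyperparams.default_for(L, w)
        return data, fg, bg, hyper

    def test_objective_does_not_decrease(self, rng):
        data, fg, bg, hyper = self._setup(rng)
        config = OptimizerConfig(restarts=1, max_iterations=50, bg_order=1)
        start = msp_objective(fg, bg, ClassPriors(0.5), data, hyper)
        res = optimize(fg, bg, ClassPriors(0.5), data, hyper, config)
        assert res.objective >= start

    def test_deterministic_given_inputs(self, rng):
        data, fg, bg, hyper = self._setup(rng)
        config = OptimizerConfig(restarts=1, max_iterations=50, bg_order=1)
        r1 = optimize(fg, bg, ClassPriors(0.5), data, hyper, config)
        r2 = optimize(fg, bg, ClassPriors(0.5), data, hyper, config)
        assert r1.objective == r2.objective
        np.testing.assert_array_equal(r1.fg.pwm.probs, r2.fg.pwm.probs)


class TestPredictedPromoterCounts:
    def test_p_occ_zero_counts_nothing(self, rng):
        X = rng.integers(0, 4, size=(5, 12))
        assert count_predicted_promoters(uniform_zoops(p_occ=0.0), X) == 0

    def test_p_occ_one_counts_all(self, rng):
        X = rng.integers(0, 4, size=(5, 12))
        assert count_predicted_promoters(uniform_zoops(p_occ=1.0), X) == 5

    def test_matches_per_sequence_posterior(self, rng):
        from dispos.model import occurrence_posterior

        zp = random_zoops(rng, 12, 3)
        X = rng.integers(0, 4, size=(8, 12))
        want = sum(occurrence_posterior(x, zp) > 0.5 for x in X)
        assert count_predicted_promoters(zp, X) == want


class TestModificationRules:
    config = OptimizerConfig(min_motif_length=4, max_motif_length=20)

    def test_left_only_shifts_right(self):
        mod = propose_modification(2, 0, 10, set(), self.config)
        assert mod.kind == "shift_right" and mod.offset_delta == 2
        assert mod.width_delta == 0

    def test_right_only_shifts_left(self):
        mod = propose_modification(0, 3, 10, set(), self.config)
        assert mod.kind == "shift_left" and mod.offset_delta == -3

    def test_both_sides_truncate(self):
        mod = propose_modification(1, 1, 10, set(), self.config)
        assert mod.kind == "truncate" and mod.width_delta == -2

    def test_neither_side_expands(self):
        mod = propose_modification(0, 0, 10, set(), self.config)
        assert mod.kind == "expand" and mod.width_delta == 2

    def test_expand_blocked_at_max_length(self):
        assert propose_modification(0, 0, 20, set(), self.config) is None

    def test_truncate_blocked_below_min_length(self):
        assert propose_modification(2, 2, 7, set(), self.config) is None

    def test_visited_state_blocks_proposal(self):
        history = {(10, 2)}
        assert propose_modification(2, 0, 10, history, self.config, offset=0) is None


class TestApplyModification:
    def _params(self, rng, w):
        return replace(random_zoops(rng, 30, w), strand_weight=0.5)

    def test_expand_copies_middle_columns(self, rng):
        p = self._params(rng, 4)
        out = apply_modification(p, expand())
        assert out.width == 6
        np.testing.assert_array_equal(out.pwm.probs[1:5], p.pwm.probs)
        np.testing.assert_allclose(out.pwm.probs[0], 0.25)
        assert out.position.xi == pytest.approx(p.position.xi - 1)

    def test_shift_right_then_left_restores_overlap(self, rng):
        p = self._params(rng, 6)
        out = apply_modification(
            apply_modification(p, shift_right(2)), shift_left(2)
        )
        np.testing.assert_array_equal(out.pwm.probs[2:], p.pwm.probs[2:])
        np.testing.assert_allclose(out.pwm.probs[:2], 0.25)
        assert out.position.xi == pytest.approx(p.position.xi)

    def test_truncate_preserves_kept_columns_bit_exactly(self, rng):
        p = self._params(rng, 6)
        out = apply_modification(p, truncate(1, 1))
        assert out.width == 4
        np.testing.assert_array_equal(out.pwm.probs, p.pwm.probs[1:5])
        assert out.position.xi == pytest.approx(p.position.xi + 1)

    def test_shrinking_below_minimum_rejected(self, rng):
        p = self._params(rng, 5)
        with pytest.raises(ModelError):
            apply_modification(p, truncate(1, 1), min_motif_length=4)


class TestInsignificantPositions:
    def _make(self, rng, pad_left):
        """Sequences carrying a sharp 4-column site, modeled with an extra
        uninformative (flanking-equal) left column when pad_left is set."""
        from dispos.synthdata import sample_from_model

        core = np.full((4, 4), 0.04)
        core[np.arange(4), [0, 1, 2, 3]] = 0.88
        flank = np.array([0.25, 0.25, 0.25, 0.25])
        w = 5 if pad_left else 4
        cols = np.vstack([np.tile(flank, (1, 1)), core]) if pad_left else core
        true = ZoopsParams(
            p_occ=0.9,
            strand_weight=0.5,
            pwm=PWM(cols),
            flanking=FlankingModel(flank),
            position=PositionPrior(gamma=0.2, xi=20.0, omega=8.0, alpha_shape=0.0),
        )
        fg_seqs, _ = sample_from_model(true, 60, 60, seed=5, prefix="f")
        ctrl = ZoopsParams(
            p_occ=0.0, strand_weight=0.5, pwm=PWM.uniform(w),
            flanking=true.flanking, position=true.position,
        )
        bg_seqs, _ = sample_from_model(ctrl, 60, 60, seed=6, prefix="b")
        fg_X = np.stack([s.encode() for s in fg_seqs]).astype(np.int64)
        ctrl_X = np.stack([s.encode() for s in bg_seqs]).astype(np.int64)
        return true, fg_X, ctrl_X

    def test_padded_flanking_column_is_insignificant(self, rng):
        params, fg_X, ctrl_X = self._make(rng, pad_left=True)
        config = OptimizerConfig(min_motif_length=2, detection_pvalue=1e-3)
        left, right = insignificant_positions(params, fg_X, ctrl_X, config)
        assert left >= 1

    def test_informative_columns_are_significant(self, rng):
        params, fg_X, ctrl_X = self._make(rng, pad_left=False)
        config = OptimizerConfig(min_motif_length=2, detection_pvalue=1e-3)
        left, right = insignificant_positions(params, fg_X, ctrl_X, config)
        assert (left, right) == (0, 0)

    def test_budget_postcondition(self, rng):
        params, fg_X, ctrl_X = self._make(rng, pad_left=True)
        config = OptimizerConfig(min_motif_length=2, detection_pvalue=1e-3)
        left, right = insignificant_positions(params, fg_X, ctrl_X, config)
        assert left + right < params.width
        base = count_detected_promoters(params, fg_X, ctrl_X, 1e-3)
        trimmed = apply_modification(params, truncate(left, 0), 1)
        assert count_detected_promoters(trimmed, fg_X, ctrl_X, 1e-3) >= 0.8 * base


class TestTrainDispom:
    def test_heuristic_terminates_and_records_history(self, rng):
        data = build_dataset(
            random_sequences(rng, 8, 30, "f"), random_sequences(rng, 8, 30, "b"),
            tss_offset=-30,
        )
        config = OptimizerConfig(
            restarts=2, seed=7, init_motif_length=6, max_motif_length=10,
            min_motif_length=4, max_iterations=60, bg_order=0,
            init_candidates=3, polish=False,
        )
        model = train_dispom(data, None, config)
        assert len(model.restart_objectives) == 2
        assert model.objective == pytest.approx(max(model.restart_objectives))
        assert model.heuristic_history[0]["modification"] == "initial"
        # state bookkeeping bounds the number of steps
        assert len(model.heuristic_history) < 40

    def test_deterministic_given_seed(self, rng):
        data = build_dataset(
            random_sequences(rng, 6, 25, "f"), random_sequences(rng, 6, 25, "b"),
            tss_offset=-25,
        )
        config = OptimizerConfig(
            restarts=1, seed=3, init_motif_length=5, max_iterations=40,
            bg_order=0, init_candidates=3, adjust_length=False, polish=False,
        )
        m1 = train_dispom(data, None, config)
        m2 = train_dispom(data, None, config)
        np.testing.assert_array_equal(m1.fg.pwm.probs, m2.fg.pwm.probs)
        assert m1.objective == m2.objective

    def test_single_class_rejected(self, rng):
        seqs = random_sequences(rng, 4, 20)
        data = build_dataset(seqs, random_sequences(rng, 4, 20, "b"), tss_offset=-20)
        data.labels[:] = 1
        with pytest.raises(ModelError):
            train_dispom(data, None, OptimizerConfig(restarts=1))
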