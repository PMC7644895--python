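import numpy as np
import pytest

from handregard import protocol
from handregard.network import forward_step, init_weights, initial_state
from handregard.rtrl import (
    LearningConfig,
    SensitivityTensor,
    apply_updates,
    motor_command_error,
    update_sensitivities,
    weight_delta,
)
from handregard.world import Geometry, Rect, WorldState

from conftest import make_toy


def world_at(left, right=(0, 0)):
    return WorldState(left_hand=left, right_hand=right,
                      others=np.zeros((0, 2), dtype=np.int64))


class TestMotorError:
    """The teacher: signed displacement to the fov center on the 8 outputs."""

    def test_hand_at_reference_has_zero_errors(self, geom9):
        e = motor_command_error(world_at(left=(4, 4), right=(4, 4)), geom9, 0.1)
        np.testing.assert_array_equal(e, np.zeros(8))

    def test_documented_sign_convention(self, geom9):
        # left hand 3 cells right of the center, alpha = 0.1
        e = motor_command_error(world_at(left=(7, 4), right=(4, 4)), geom9, 0.1)
        assert e[0] == pytest.approx(-0.3)   # +x drive discouraged
        assert e[1] == pytest.approx(+0.3)   # -x drive encouraged
        assert e[2] == e[3] == 0.0
        np.testing.assert_array_equal(e[4:], np.zeros(4))

    def test_crossing_center_flips_signs(self, geom9):
        e_left_of = motor_command_error(world_at(left=(2, 4)), geom9, 0.1)[:4]
        e_right_of = motor_command_error(world_at(left=(6, 4)), geom9, 0.1)[:4]
        np.testing.assert_allclose(e_left_of[:2], -e_right_of[:2])
        assert e_left_of[0] > 0  # hand left of center: +x encouraged

    def test_each_hand_drives_its_own_outputs(self, geom9):
        e = motor_command_error(world_at(left=(4, 4), right=(4, 7)), geom9, 0.1)
        assert np.all(e[:4] == 0.0)
        assert e[6] == pytest.approx(-0.3) and e[7] == pytest.approx(0.3)


def run_forward(w, arch, xs):
    """Replay a fixed input sequence; return the final hidden/output outputs."""
    state = initial_state(arch)
    for x in xs:
        state = forward_step(w, state, x, arch)
    return state.y(arch)


class TestSensitivities:
    def test_base_case_from_zero_initialization(self):
        arch, mask = make_toy(n_input=3, n_own=1, n_agency=1, n_output=1)
        rng = np.random.default_rng(1)
        w = init_weights(mask, 0.5, rng)
        x = rng.uniform(size=arch.n_input)
        state = forward_step(w, initial_state(arch), x, arch)
        p = update_sensitivities(SensitivityTensor.zeros(mask), w, state)
        y = state.y(arch)
        fprime = y * (1 - y)
        # p_ij^k = f'(s_k) * delta_ik * z_j(0) at the first step
        for widx in range(mask.n_weights):
            i, j = mask.recv[widx], mask.send[widx]
            for k in range(arch.n_receivers):
                expected = fprime[k] * state.z_prev[j] if k == i else 0.0
                assert p.p[k, widx] == pytest.approx(expected, abs=1e-12)

    @pytest.mark.parametrize("sizes,steps", [
        ((3, 1, 1, 1), 5),   # 3-input / 2-hidden / 1-output
        ((5, 2, 2, 2), 8),
    ])
    def test_matches_finite_difference_oracle(self, sizes, steps):
        """RTRL sensitivities equal central finite differences of the outputs."""
        n_input, n_own, n_agency, n_output = sizes
        arch, mask = make_toy(n_input, n_own, n_agency, n_output)
        rng = np.random.default_rng(42)
        w = init_weights(mask, 0.7, rng)
        xs = rng.uniform(size=(steps, arch.n_input))

        state = initial_state(arch)
        p = SensitivityTensor.zeros(mask)
        for x in xs:
            state = forward_step(w, state, x, arch)
            p = update_sensitivities(p, w, state)

        h = 1e-6
        for widx in range(mask.n_weights):
            i, j = mask.recv[widx], mask.send[widx]
            wp, wm = w.copy(), w.copy()
            wp[i, j] += h
            wm[i, j] -= h
            fd = (run_forward(wp, arch, xs) - run_forward(wm, arch, xs)) / (2 * h)
            got = p.p[:, widx]
            denom = np.maximum(np.abs(fd), 1e-6)
            assert np.max(np.abs(got - fd) / denom) < 1e-4

    def test_masked_weights_have_no_sensitivity_columns(self):
        arch, mask = make_toy(n_input=4, n_own=2, n_agency=2, n_output=2)
        p = SensitivityTensor.zeros(mask)
        assert p.p.shape == (arch.n_receivers, mask.n_weights)
        assert mask.n_weights < arch.n_receivers * arch.n_units


class TestWeightDelta:
    def _setup(self):
        arch, mask = make_toy(n_input=4, n_own=2, n_agency=2, n_output=2)
        p = SensitivityTensor.zeros(mask)
        rng = np.random.default_rng(3)
        p.p[:] = rng.normal(size=p.p.shape)
        return arch, mask, p

    def test_zero_error_gives_zero_delta(self):
        arch, mask, p = self._setup()
        np.testing.assert_array_equal(weight_delta(np.zeros(arch.n_output), p, 0.1),
                                      np.zeros(mask.n_weights))

    def test_linear_in_eta(self):
        arch, mask, p = self._setup()
        e = np.array([0.3, -0.2])
        np.testing.assert_allclose(weight_delta(e, p, 0.2),
                                   2 * weight_delta(e, p, 0.1))

    def test_single_error_component_entrywise(self):
        arch, mask, p = self._setup()
        e = np.array([0.0, 0.7])
        got = weight_delta(e, p, 0.5)
        k_row = arch.output_rows.start + 1
        np.testing.assert_allclose(got, 0.5 * 0.7 * p.p[k_row])


class TestApplyUpdates:
    def test_zero_accumulator_is_identity(self):
        arch, mask = make_toy()
        w = init_weights(mask, 0.1, 0)
        np.testing.assert_array_equal(apply_updates(w, np.zeros(mask.n_weights), mask), w)

    def test_masked_entries_stay_zero(self):
        arch, mask = make_toy()
        w = init_weights(mask, 0.1, 0)
        out = apply_updates(w, np.ones(mask.n_weights), mask)
        assert np.all(out[~mask.allowed] == 0.0)

    def test_batched_equals_sum_of_deltas(self):
        arch, mask = make_toy(n_input=4, n_own=2, n_agency=2, n_output=2)
        rng = np.random.default_rng(9)
        w = init_weights(mask, 0.1, rng)
        deltas = rng.normal(scale=0.01, size=(10, mask.n_weights))
        w_once = apply_updates(w, deltas.sum(axis=0), mask)
        expected = w.copy()
        expected[mask.recv, mask.send] += deltas.sum(axis=0)
        np.testing.assert_allclose(w_once, expected, atol=1e-15)


class TestLearningLoop:
    def test_error_free_run_leaves_weights_invariant(self, small_setup):
        """alpha = 0 makes every motor error zero, so weights never change."""
        s = small_setup
        learn = LearningConfig(alpha=0.0)
        rec = protocol.train(s["geometry"], s["stim"], learn, seed=0,
                             n_steps=300, arch=s["arch"], mask=s["mask"])
        np.testing.assert_array_equal(rec.final_weights, rec.checkpoints[0])

    def test_mask_conserved_during_learning(self, small_setup):
        s = small_setup
        rec = protocol.train(s["geometry"], s["stim"], LearningConfig(), seed=1,
                             n_steps=500, arch=s["arch"], mask=s["mask"])
        assert np.abs(rec.final_weights[~s["mask"].allowed]).sum() == 0.0
        assert not np.array_equal(rec.final_weights, rec.checkpoints[0])

    def test_updates_drive_outputs_toward_center(self, geom9):
        """With the hand held left of center, learning increases the net
        rightward drive (+x output minus -x output) of that hand."""
        from handregard import network, world as world_mod
        from handregard.world import StimulusValues
        from handregard import rtrl as rtrl_mod

        arch, mask = make_toy(n_input=125, n_own=6, n_agency=6, n_output=8)
        rng = np.random.default_rng(2)
        w0 = init_weights(mask, 0.1, rng)
        stim = StimulusValues(n_others=0)
        wstate = world_at(left=(2, 4), right=(4, 4))  # left hand left of center

        def net_drive(w):
            state = initial_state(arch)
            p = SensitivityTensor.zeros(mask)
            acc = np.zeros(mask.n_weights)
            for _ in range(30):
                cd = world_mod.corollary_discharge(state.outputs(arch))
                x = world_mod.encode_inputs(wstate, stim, cd, geom9)
                state = forward_step(w, state, x, arch)
                p = update_sensitivities(p, w, state)
                e = motor_command_error(wstate, geom9, 0.1)
                acc += weight_delta(e, p, 0.1)
            out = state.outputs(arch)
            return out[0] - out[1], acc

        drive_before, acc = net_drive(w0)
        w1 = apply_updates(w0, acc, mask)
        drive_after, _ = net_drive(w1)
        assert drive_after > drive_before
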