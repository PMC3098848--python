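"""Scrambling, morphing, noise masking and motion energy."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from biomotion.kinematics import PointLightSequence
from biomotion.transforms import (
    NoiseMaskSpec,
    add_noise_mask,
    motion_energy,
    perturb,
    scramble_spatial,
)


class TestScramble:
    def test_preserves_per_dot_displacements(self, walk_seq):
        """Scrambling randomizes only the first frame: every dot keeps its
        own frame-to-frame motion trajectory."""
        scr = scramble_spatial(walk_seq, seed=3)
        assert np.abs(
            scr.scrambled.displacements() - walk_seq.displacements()
        ).max() <= 1e-9

    def test_first_frame_within_window(self, walk_seq):
        scr = scramble_spatial(walk_seq, window_deg=11.0, seed=3)
        assert np.abs(scr.scrambled.positions[0]).max() <= 5.5

    def test_deterministic_given_seed(self, walk_seq):
        a = scramble_spatial(walk_seq, seed=9)
        b = scramble_spatial(walk_seq, seed=9)
        assert np.array_equal(a.scrambled.positions, b.scrambled.positions)

    def test_static_input_stays_static(self):
        pos = np.tile(np.random.default_rng(0).uniform(-1, 1, (1, 12, 2)), (5, 1, 1))
        seq = PointLightSequence(pos, 0.05, tuple(f"d{i}" for i in range(12)))
        scr = scramble_spatial(seq, seed=1)
        assert np.allclose(scr.scrambled.positions, scr.scrambled.positions[0])

    def test_negative_window_rejected(self, walk_seq):
        with pytest.raises(ValueError):
            scramble_spatial(walk_seq, window_deg=-1.0)


class TestPerturb:
    def test_endpoints_are_original_and_scrambled(self, walk_seq):
        scr = scramble_spatial(walk_seq, seed=5)
        assert np.array_equal(perturb(walk_seq, scr, 0.0).positions,
                              walk_seq.positions)
        assert np.allclose(perturb(walk_seq, scr, 1.0).positions,
                           scr.scrambled.positions, atol=1e-12)

    def test_divides_offset_in_stated_ratio(self):
        """A dot at (0,0) whose scrambled twin is at (10,0) sits at (1.5,0)
        in the 15%-perturbed morph (the 15:85 split)."""
        pos = np.zeros((3, 12, 2))
        seq = PointLightSequence(pos, 0.05, tuple(f"d{i}" for i in range(12)))
        scr = scramble_spatial(seq, seed=0)
        # overwrite with a controlled offset for dot 0
        from biomotion.transforms import ScrambleResult

        offsets = np.zeros((12, 2))
        offsets[0] = (10.0, 0.0)
        scrambled = seq.with_positions(pos + offsets[None])
        scr = ScrambleResult(scrambled=scrambled, offsets=offsets, seed=0)
        p = perturb(seq, scr, 0.15)
        assert p.positions[0, 0] == pytest.approx((1.5, 0.0))

    @given(lam=st.floats(min_value=0.0, max_value=1.0))
    @settings(max_examples=25, deadline=None)
    def test_linear_in_lam_with_invariant_velocities(self, walk_seq, lam):
        scr = scramble_spatial(walk_seq, seed=5)
        p = perturb(walk_seq, scr, lam)
        expected = (1 - lam) * walk_seq.positions + lam * scr.scrambled.positions
        assert np.allclose(p.positions, expected, atol=1e-9)
        assert np.abs(p.displacements() - walk_seq.displacements()).max() <= 1e-9

    def test_motion_energy_invariant_across_morph_levels(self, jump_seq):
        """All morph levels of one action carry identical local motion."""
        scr = scramble_spatial(jump_seq, seed=2)
        ref = motion_energy(jump_seq)
        for lam in (0.15, 0.375, 0.6, 1.0):
            m = motion_energy(perturb(jump_seq, scr, lam))
            assert m.angular_deviation_total == pytest.approx(
                ref.angular_deviation_total, abs=1e-6
            )
            assert m.path_excursion_total == pytest.approx(
                ref.path_excursion_total, abs=1e-9
            )

    def test_out_of_range_lam_and_mismatched_scramble(self, walk_seq, jump_seq):
        scr = scramble_spatial(walk_seq, seed=5)
        with pytest.raises(ValueError):
            perturb(walk_seq, scr, 1.5)
        with pytest.raises(ValueError):
            perturb(jump_seq, scr, 0.5)


class TestNoiseMask:
    def test_no_noise_keeps_twelve_dots(self, walk_seq):
        res = add_noise_mask(walk_seq, NoiseMaskSpec(n_noise=0, seed=4))
        assert res.sequence.n_dots == 12

    def test_noise_dots_replay_figure_trajectories(self, walk_seq):
        """Each of 60 noise dots carries the displacement sequence of some
        figure dot, modulo the toroidal window wrap."""
        spec = NoiseMaskSpec(n_noise=60, seed=4)
        res = add_noise_mask(walk_seq, spec)
        seq = res.sequence
        assert seq.n_dots == 72
        fig_disp = walk_seq.displacements()  # (T-1, 12, 2)
        w = spec.window_deg
        noise_idx = [i for i in range(72) if i not in set(res.figure_indices)]
        for i in noise_idx:
            d = np.diff(seq.positions[:, i, :], axis=0)
            # un-wrap: displacements congruent to a figure dot's mod window
            diffs = d[:, None, :] - fig_disp  # (T-1, 12, 2)
            wrapped = (diffs + w / 2) % w - w / 2
            matches = np.all(np.abs(wrapped) < 1e-6, axis=(0, 2))
            assert matches.any()

    def test_zero_jitter_leaves_figure_in_place(self, walk_seq):
        spec = NoiseMaskSpec(n_noise=10, jitter_deg=0.0, seed=4)
        res = add_noise_mask(walk_seq, spec)
        fig = res.sequence.positions[:, res.figure_indices, :]
        assert np.allclose(fig, walk_seq.positions, atol=1e-12)

    def test_jitter_preserves_figure_geometry(self, walk_seq):
        """Jitter translates the figure rigidly: inter-dot distances survive."""
        res = add_noise_mask(walk_seq, NoiseMaskSpec(n_noise=20, seed=8))
        fig = res.sequence.positions[:, res.figure_indices, :]
        orig = walk_seq.positions
        for t in (0, 10, 19):
            d0 = np.linalg.norm(orig[t, :, None] - orig[t, None, :], axis=-1)
            d1 = np.linalg.norm(fig[t, :, None] - fig[t, None, :], axis=-1)
            assert np.allclose(d0, d1, atol=1e-9)

    def test_invalid_specs_rejected(self):
        with pytest.raises(ValueError):
            NoiseMaskSpec(n_noise=-1)
        with pytest.raises(ValueError):
            NoiseMaskSpec(window_deg=5.0, figure_window_deg=7.0)


class TestMotionEnergy:
    def _single_dot(self, xy):
        """12-dot sequence where dot 0 follows ``xy`` and the rest are static."""
        T = len(xy)
        pos = np.zeros((T, 12, 2))
        pos[:, 0, :] = xy
        return PointLightSequence(pos, 0.05, tuple(f"d{i}" for i in range(12)))

    def test_straight_line_has_zero_angular_energy(self):
        xy = np.column_stack([np.arange(11.0), np.zeros(11)])
        m = motion_energy(self._single_dot(xy), method="excursion")
        assert m.path_excursion_total == pytest.approx(10.0)
        assert m.angular_deviation_total == pytest.approx(0.0)

    def test_closed_square_path_turns_360_degrees(self):
        """Exterior angles of a closed convex path sum to 360 deg."""
        pts = [(0, 0), (1, 0), (2, 0), (2, 1), (2, 2), (1, 2), (0, 2),
               (0, 1), (0, 0), (1, 0)]  # returns to start direction
        m = motion_energy(self._single_dot(np.array(pts, float)))
        assert m.angular_deviation_total == pytest.approx(360.0)

    def test_static_sequence_has_zero_energy(self):
        m = motion_energy(self._single_dot(np.zeros((5, 2))))
        assert m.angular_deviation_total == 0.0
        assert m.path_excursion_total == 0.0

    def test_angular_needs_three_frames(self):
        seq = self._single_dot(np.zeros((2, 2)))
        with pytest.raises(ValueError):
            motion_energy(seq, method="angular")
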