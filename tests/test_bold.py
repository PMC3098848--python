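"""BOLD simulation, GLM, FDR-based ROI definition, event-related averaging."""

import numpy as np
import pytest

from biomotion.bold import (
    BlockDesign,
    EventDesign,
    LatticeSpec,
    define_roi,
    double_gamma_hrf,
    event_related_average,
    glm_contrast,
    load_lattice,
    peak_percent_change,
    roi_mean_series,
    run_bold_experiment,
    save_lattice,
    simulate_bold,
    _sampled_regressor,
)


def _tiny_spec(**kw):
    kw.setdefault("shape", (8, 8, 6))
    kw.setdefault("region_radii", (2.2, 2.2, 1.6))
    return LatticeSpec(**kw)


def _noiseless(**kw):
    return _tiny_spec(noise_sd=1e-12, ar1=0.0, **kw)


class TestSimulation:
    def test_hrf_unit_peak(self):
        t = np.arange(0, 32, 0.01)
        h = double_gamma_hrf(t)
        assert h.max() == pytest.approx(1.0, abs=1e-9)
        assert h[0] == pytest.approx(0.0, abs=1e-6)

    def test_single_event_peaks_at_amplitude(self):
        """Noiseless single event of amplitude 1 -> series peak exactly 1."""
        des = EventDesign(onsets_s=(10.0,), conditions=("hit",))
        lat = simulate_bold(des, _noiseless(), {"hit": 1.0}, seed=0)
        series = lat.data[lat.region_mask][0] - lat.spec.baseline
        assert series.max() == pytest.approx(1.0, abs=1e-6)

    def test_superposition_of_two_events(self):
        """Two events 12 s apart superpose linearly (noiseless oracle by
        direct convolution)."""
        des2 = EventDesign(onsets_s=(10.0, 22.0), conditions=("hit", "hit"))
        lat2 = simulate_bold(des2, _noiseless(), {"hit": 0.7}, seed=0)
        got = lat2.data[lat2.region_mask][0] - lat2.spec.baseline

        one = 0.7 * _sampled_regressor(
            EventDesign(onsets_s=(10.0,), conditions=("hit",),
                        run_length_s=des2.run_length_s),
            "hit",
        )
        two = 0.7 * _sampled_regressor(
            EventDesign(onsets_s=(22.0,), conditions=("hit",),
                        run_length_s=des2.run_length_s),
            "hit",
        )
        # data is stored float32 around a baseline of 100 -> ~1e-5 absolute
        assert np.allclose(got, one + two, atol=1e-4)

    def test_zero_amplitude_region_indistinguishable(self):
        spec = _tiny_spec()
        des = EventDesign.balanced(seed=1)
        lat = simulate_bold(des, spec, {}, seed=5)
        inside = lat.data[lat.region_mask].std()
        outside = lat.data[~lat.region_mask].std()
        assert inside == pytest.approx(outside, rel=0.1)

    def test_deterministic_given_seed(self):
        des = EventDesign.balanced(seed=2)
        a = simulate_bold(des, _tiny_spec(), {"hit": 0.5}, seed=9)
        b = simulate_bold(des, _tiny_spec(), {"hit": 0.5}, seed=9)
        assert np.array_equal(a.data, b.data)

    def test_close_events_warn(self):
        des = EventDesign(onsets_s=(10.0, 11.0), conditions=("hit", "hit"))
        with pytest.warns(UserWarning, match="TR"):
            simulate_bold(des, _tiny_spec(), {"hit": 1.0}, seed=0)


class TestGlm:
    def test_noiseless_responsive_voxel_is_certain(self):
        des = BlockDesign()
        lat = simulate_bold(des, _noiseless(),
                            {"biological": 1.0, "scrambled": 0.2}, seed=0)
        g = glm_contrast(lat, des, {"biological": 1.0, "scrambled": -1.0})
        assert g.t[lat.region_mask].min() > 1e3
        assert g.p[lat.region_mask].max() <= 1e-30

    def test_equal_amplitudes_null_contrast(self):
        des = BlockDesign()
        ts = []
        for s in range(10):
            lat = simulate_bold(des, _tiny_spec(),
                                {"biological": 0.5, "scrambled": 0.5}, seed=s)
            g = glm_contrast(lat, des, {"biological": 1.0, "scrambled": -1.0})
            ts.append(g.t[lat.region_mask].mean())
        assert abs(np.mean(ts)) < 0.3

    def test_null_pvalues_are_uniform(self):
        """Pure-noise voxels give uniform p-values (KS check, ~1900 voxels)."""
        from scipy.stats import kstest

        des = BlockDesign()
        # white noise: OLS p-values are exactly calibrated only without
        # temporal autocorrelation
        spec = LatticeSpec(shape=(16, 12, 10), region_radii=(0.1, 0.1, 0.1),
                           ar1=0.0)
        lat = simulate_bold(des, spec, {}, seed=77)
        g = glm_contrast(lat, des, {"biological": 1.0, "scrambled": -1.0})
        stat, _ = kstest(g.p.ravel(), "uniform")
        assert stat < 0.05

    def test_rank_deficiency_reported(self):
        # two conditions with identical onsets give identical regressors
        import warnings

        des = EventDesign(onsets_s=(10.0, 10.0), conditions=("a", "b"))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            lat = simulate_bold(des, _tiny_spec(), {}, seed=0)
        with pytest.raises(ValueError, match="collinear"):
            glm_contrast(lat, des, {"a": 1.0, "b": -1.0})

    def test_unknown_contrast_condition(self):
        des = EventDesign(onsets_s=(10.0,), conditions=("hit",))
        lat = simulate_bold(des, _tiny_spec(), {}, seed=0)
        with pytest.raises(ValueError, match="unknown condition"):
            glm_contrast(lat, des, {"nope": 1.0})


class TestRoi:
    def test_step_up_hand_example(self):
        """p = [.01,.02,.03,.04] with m=4 at q=.05: all rejected by step-up."""
        p = np.array([0.01, 0.02, 0.03, 0.04]).reshape(2, 2, 1)
        roi = define_roi(p, q=0.05)
        assert roi.mask.all()
        assert roi.threshold_used == "fdr_q05"

    def test_all_ones_is_unlocalizable(self):
        roi = define_roi(np.ones((3, 3, 3)))
        assert not roi.localized
        assert roi.n_voxels == 0
        assert roi.threshold_used == "none"

    def test_fallback_threshold_used_when_fdr_empty(self):
        p = np.full((4, 4, 2), 0.5)
        p[0, 0, 0] = 0.002  # survives p<.003 but not BH over 32 voxels
        roi = define_roi(p)
        assert roi.threshold_used == "p003_uncorrected"
        assert roi.n_voxels == 1

    def test_matches_brute_force_step_up(self):
        """Oracle: literal Benjamini-Hochberg step-up on random p-vectors."""
        rng = np.random.default_rng(0)
        for trial in range(60):
            n = int(rng.integers(5, 2000))
            p = rng.uniform(size=n) ** rng.uniform(0.3, 3.0)
            q = 0.05
            # brute force step-up
            order = np.argsort(p)
            ranked = p[order]
            thresh = q * (np.arange(1, n + 1)) / n
            below = np.flatnonzero(ranked <= thresh)
            k = below.max() + 1 if below.size else 0
            expect = np.zeros(n, dtype=bool)
            expect[order[:k]] = True

            from statsmodels.stats.multitest import multipletests

            got = multipletests(p, alpha=q, method="fdr_bh")[0]
            assert np.array_equal(got, expect)

    def test_largest_connected_component_kept(self):
        p = np.ones((6, 6, 1))
        p[0:2, 0, 0] = 1e-6  # 2-voxel component
        p[3:6, 3, 0] = 1e-6  # 3-voxel component
        roi = define_roi(p)
        assert roi.n_voxels == 3
        assert roi.mask[4, 3, 0]
        assert not roi.mask[0, 0, 0]

    def test_six_connectivity_not_diagonal(self):
        p = np.ones((4, 4, 1))
        p[0, 0, 0] = 1e-9
        p[1, 1, 0] = 1e-9  # diagonal neighbour: separate component
        roi = define_roi(p)
        assert roi.n_voxels == 1

    def test_recovers_embedded_truth_region(self):
        """Monte-Carlo recovery: the surviving component covers >=90% of the
        ground-truth region voxels."""
        covered = []
        for s in range(5):
            spec = LatticeSpec()
            des = BlockDesign()
            lat = simulate_bold(des, spec,
                                {"biological": 1.2, "scrambled": 0.2}, seed=s)
            g = glm_contrast(lat, des, {"biological": 1.0, "scrambled": -1.0})
            roi = define_roi(g.p, t=g.t)
            covered.append(
                (roi.mask & lat.region_mask).sum() / lat.region_mask.sum()
            )
        assert np.mean(covered) >= 0.9

    def test_invalid_pvalues_rejected(self):
        with pytest.raises(ValueError):
            define_roi(np.array([[[1.5]]]))


class TestEventAveraging:
    def test_identical_noiseless_epochs_average_to_one_epoch(self):
        des = EventDesign.balanced(seed=3)
        lat = simulate_bold(des, _noiseless(), {"hit": 0.6}, seed=0)
        series = roi_mean_series(lat, lat.region_mask)
        times, avg, n = event_related_average(series, des, "hit")
        assert n == 8
        assert times[0] == 0.0 and times[-1] == 10.0
        # every hit epoch is identical up to overlap from neighbours
        assert peak_percent_change(avg) == pytest.approx(0.6, abs=0.05)

    def test_missing_condition_raises(self):
        des = EventDesign(onsets_s=(10.0,), conditions=("hit",))
        lat = simulate_bold(des, _noiseless(), {"hit": 0.5}, seed=0)
        series = roi_mean_series(lat, lat.region_mask)
        with pytest.raises(ValueError, match="sparse"):
            event_related_average(series, des, "false_alarm")

    def test_amplitude_round_trip(self):
        """Injected amplitude is recovered as the epoch peak (noiseless)."""
        for a in (0.3, 0.6):
            des = EventDesign.balanced(seed=5)
            lat = simulate_bold(des, _noiseless(), {"correct_rejection": a},
                                seed=0)
            series = roi_mean_series(lat, lat.region_mask)
            _, avg, _ = event_related_average(series, des, "correct_rejection")
            assert peak_percent_change(avg) == pytest.approx(a, abs=0.05)

    def test_peak_percent_change_contract(self):
        assert peak_percent_change(np.array([0.1, 0.2, 0.5, 0.3])) == (
            pytest.approx(0.4)
        )
        assert peak_percent_change(np.zeros(6)) == 0.0
        with pytest.raises(ValueError):
            peak_percent_change(np.array([0.1, 0.2, 0.3]))


class TestPipeline:
    def test_nifti_round_trip(self, tmp_path):
        des = EventDesign.balanced(seed=1)
        lat = simulate_bold(des, _tiny_spec(), {"hit": 0.5}, seed=2)
        path = tmp_path / "run.nii.gz"
        save_lattice(lat, path)
        back = load_lattice(path)
        assert np.allclose(back.data, lat.data, atol=1e-5)
        assert back.TR_s == pytest.approx(2.0)

    def test_balanced_design_counts(self):
        des = EventDesign.balanced(seed=0)
        from collections import Counter

        c = Counter(des.conditions)
        assert c == {"hit": 8, "correct_rejection": 4, "false_alarm": 4,
                     "intermediate": 8}
        assert np.allclose(np.diff(des.onsets_s), 12.0)

    def test_design_from_trial_log(self):
        from biomotion.experiments import run_exp3_behavioral
        from biomotion.observers import categorization_preset

        obs = categorization_preset("patient", seed=3)
        res = run_exp3_behavioral(obs, seed=3)
        des = EventDesign.from_trial_log(res.trial_log, run=0)
        assert len(des.onsets_s) == 24
        assert set(des.conditions) <= {
            "hit", "miss", "correct_rejection", "false_alarm", "intermediate"
        }

    def test_group_experiments_show_expected_patterns(self):
        from biomotion.bold import classify_response_pattern

        co = run_bold_experiment("control", seed=5, n_event_runs=4)
        pa = run_bold_experiment("patient", seed=5, n_event_runs=4)
        assert co.roi.localized and pa.roi.localized
        assert classify_response_pattern(co.peaks) == "selective"
        assert classify_response_pattern(pa.peaks) == "undifferentiated"
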