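"""Analysis: binarization, activity metrics, sigmoid fits, species tests."""

import numpy as np
import pytest

from islethub.analysis import (activity_metrics, binarize_traces,
                               compare_species, fit_dose_response,
                               ic50_as_percent_of_hubs, logistic_decreasing)
from islethub.engine import SimulationResult


def make_result(ca, dt_s=0.1, epochs=None):
    """Wrap a (n_t, n_cells) Ca array as a SimulationResult."""
    n_t, n_cells = ca.shape
    t = np.arange(n_t) * dt_s
    if epochs is None:
        half = n_t // 2 * dt_s
        epochs = {"baseline": (0.0, half), "inhibition": (half, n_t * dt_s)}
    return SimulationResult(time_s=t, vm=np.full_like(ca, -60.0), ca=ca,
                            epochs=epochs, inhibited=np.array([], dtype=int),
                            clamp_mv=-100.0)


def square_wave(n_t, period, duty=0.5, lo=0.05, hi=0.45, phase=0):
    idx = (np.arange(n_t) + phase) % period
    return np.where(idx < duty * period, hi, lo)


class TestBinarization:
    def test_constant_low_trace_is_inactive(self):
        """0.1 µM against a baseline max of 0.5 µM is 20% < 40%."""
        ca = np.column_stack([np.full(100, 0.1)])
        ca[0, 0] = 0.5                      # baseline max
        raster = binarize_traces(ca, np.arange(100) * 0.1)
        assert not raster.active[1:, 0].any()

    def test_square_wave_active_exactly_on_high_phase(self):
        wave = square_wave(200, 40, lo=0.05, hi=0.45)
        ca = wave[:, None]
        raster = binarize_traces(ca, np.arange(200) * 0.1)
        assert np.array_equal(raster.active[:, 0], wave > 0.4 * 0.45)

    def test_matches_elementwise_oracle_on_random_traces(self):
        """Binarization equals a per-sample brute-force comparison."""
        rng = np.random.default_rng(5)
        ca = rng.uniform(0, 1.0, size=(300, 20))
        t = np.arange(300) * 0.1
        baseline = t < 15.0
        raster = binarize_traces(ca, t, baseline_mask=baseline)
        for c in range(20):
            ref = ca[baseline, c].max()
            for k in range(300):
                assert raster.active[k, c] == (ca[k, c] / ref > 0.4)

    def test_absolute_threshold_mode(self):
        ca = np.array([[0.1], [0.25], [0.19]])
        raster = binarize_traces(ca, np.arange(3) * 0.1, abs_threshold=0.2)
        assert raster.active[:, 0].tolist() == [False, True, False]

    def test_all_zero_trace_warns_and_is_inactive(self):
        ca = np.zeros((50, 2))
        ca[:, 1] = square_wave(50, 10)
        with pytest.warns(UserWarning, match="all-zero"):
            raster = binarize_traces(ca, np.arange(50) * 0.1)
        assert not raster.active[:, 0].any()

    def test_order_independent_across_cells(self):
        rng = np.random.default_rng(6)
        ca = rng.uniform(0, 1, size=(100, 10))
        t = np.arange(100) * 0.1
        perm = rng.permutation(10)
        a = binarize_traces(ca, t).active
        b = binarize_traces(ca[:, perm], t).active
        assert np.array_equal(a[:, perm], b)

    def test_negative_traces_rejected(self):
        with pytest.raises(ValueError):
            binarize_traces(np.array([[-0.1]]), np.array([0.0]))

    def test_interval_export_matches_raster(self):
        ca = square_wave(100, 20)[:, None]
        raster = binarize_traces(ca, np.arange(100) * 0.1)
        iv = raster.intervals()
        assert (iv.t_off_s > iv.t_on_s).all()
        assert len(iv) == raster.active[:, 0].astype(int).sum() / 10


class TestActivityMetrics:
    def test_identical_epochs_give_hundred_percent(self):
        ca = np.column_stack([square_wave(400, 40, phase=p)
                              for p in (0, 0, 0)])
        res = make_result(ca)
        raster = binarize_traces(ca, res.time_s,
                                 baseline_mask=res.epoch_mask("baseline"))
        m = activity_metrics(res, raster, "inhibition")
        assert m["summed"] == pytest.approx(100.0, abs=1e-6)
        assert m["amplitude"] == pytest.approx(100.0, abs=1e-6)

    def test_silent_epoch_gives_zero_summed_activity(self):
        wave = square_wave(200, 40)
        ca = np.concatenate([wave, np.full(200, 0.05)])[:, None]
        res = make_result(ca)
        raster = binarize_traces(ca, res.time_s,
                                 baseline_mask=res.epoch_mask("baseline"))
        assert activity_metrics(res, raster,
                                "inhibition")["summed"] == 0.0

    def test_half_silenced_cells_give_fifty_percent_summed(self):
        """10 synchronous cells; 5 go silent in the second epoch while the
        others are unchanged — summed activity is 50% of baseline."""
        n_t = 400
        cells = []
        for c in range(10):
            wave = square_wave(n_t, 40)
            if c < 5:
                wave[n_t // 2:] = 0.05
            cells.append(wave)
        ca = np.column_stack(cells)
        res = make_result(ca)
        raster = binarize_traces(ca, res.time_s,
                                 baseline_mask=res.epoch_mask("baseline"))
        m = activity_metrics(res, raster, "inhibition")
        assert m["summed"] == pytest.approx(50.0, abs=1e-6)

    def test_summed_metric_invariant_to_uniform_rescaling(self):
        rng = np.random.default_rng(7)
        ca = rng.uniform(0.05, 0.6, size=(300, 8))
        res_a = make_result(ca)
        res_b = make_result(3.7 * ca)
        for res in (res_a, res_b):
            pass
        ra = binarize_traces(res_a.ca, res_a.time_s,
                             baseline_mask=res_a.epoch_mask("baseline"))
        rb = binarize_traces(res_b.ca, res_b.time_s,
                             baseline_mask=res_b.epoch_mask("baseline"))
        ma = activity_metrics(res_a, ra, "inhibition")
        mb = activity_metrics(res_b, rb, "inhibition")
        assert ma["summed"] == pytest.approx(mb["summed"], rel=1e-9)
        assert ma["amplitude"] == pytest.approx(mb["amplitude"], rel=1e-9)

    def test_zero_baseline_activity_is_an_explicit_error(self):
        ca = np.full((200, 3), 0.01)
        res = make_result(ca)
        raster = binarize_traces(ca, res.time_s,
                                 baseline_mask=res.epoch_mask("baseline"))
        with pytest.raises(ZeroDivisionError):
            activity_metrics(res, raster, "inhibition")

    def test_unknown_epoch_rejected(self):
        ca = square_wave(100, 20)[:, None]
        res = make_result(ca)
        raster = binarize_traces(ca, res.time_s)
        with pytest.raises(KeyError):
            activity_metrics(res, raster, "washout")


class TestDoseResponseFit:
    def test_noise_free_parameters_recovered_within_one_percent(self):
        x = np.array([0.0, 1.0, 2.0, 3.0, 4.0, 6.0, 8.0])
        y = logistic_decreasing(x, 3.0, 0.5)
        fit = fit_dose_response(x, y)
        assert fit.x0 == pytest.approx(3.0, rel=0.01)
        assert fit.k == pytest.approx(0.5, rel=0.01)
        assert fit.r2 > 0.999 and not fit.flagged

    def test_median_recovery_under_five_percent_noise(self):
        """100 noisy replicates: median recovered IC50 within 10%."""
        rng = np.random.default_rng(0)
        x = np.array([0.0, 1.0, 2.0, 3.0, 4.0, 6.0, 8.0])
        clean = logistic_decreasing(x, 3.0, 0.5)
        x0s = []
        for _ in range(100):
            y = np.clip(clean + rng.normal(0, 5.0, size=x.size), 0, None)
            y[0] = 100.0
            x0s.append(fit_dose_response(x, y).x0)
        assert abs(np.median(x0s) - 3.0) / 3.0 < 0.10

    def test_flat_response_is_an_explicit_failure(self):
        x = np.array([0.0, 2.0, 4.0, 6.0])
        with pytest.raises(RuntimeError, match="flat"):
            fit_dose_response(x, np.full(4, 100.0))

    def test_too_few_dose_levels_rejected(self):
        with pytest.raises(ValueError):
            fit_dose_response([0, 2, 4], [100, 60, 20])

    def test_missing_zero_point_rejected(self):
        with pytest.raises(ValueError):
            fit_dose_response([1, 2, 4, 8], [90, 70, 40, 10])

    def test_poor_fit_is_flagged_not_hidden(self):
        x = np.array([0.0, 1.0, 2.0, 3.0, 4.0, 5.0])
        rng = np.random.default_rng(1)
        y = rng.uniform(20, 100, size=6)
        y[0] = 100.0
        fit = fit_dose_response(x, y)
        assert fit.flagged == (not (fit.r2 > 0.9))

    def test_free_top_variant(self):
        x = np.array([0.0, 1.0, 2.0, 3.0, 5.0, 8.0])
        y = logistic_decreasing(x, 3.0, 0.8, top=120.0)
        fit = fit_dose_response(x, y, free_top=True)
        assert fit.x0 == pytest.approx(3.0, rel=0.02)

    def test_parameter_recovery_with_seed_averaged_noise(self):
        """SEM-sized noise averaged over 6 seeds per dose point recovers
        the IC50 with < 5% median bias (100 studies)."""
        rng = np.random.default_rng(2)
        x = np.array([0.0, 1.0, 2.0, 3.0, 4.0, 6.0, 8.0])
        clean = logistic_decreasing(x, 3.0, 0.7)
        biases = []
        for _ in range(100):
            reps = clean + rng.normal(0, 8.0, size=(6, x.size))
            y = np.clip(reps.mean(axis=0), 0, None)
            y[0] = 100.0
            biases.append((fit_dose_response(x, y).x0 - 3.0) / 3.0)
        assert abs(np.median(biases)) < 0.05

    def test_hub_pool_conversion(self):
        assert ic50_as_percent_of_hubs(2.0, 0.10) == pytest.approx(20.0)


class TestCompareSpecies:
    def test_identical_groups_give_null_result(self):
        out = compare_species([2.0, 2.1, 1.9], [2.0, 2.1, 1.9], paired=True)
        assert out["t"] == pytest.approx(0.0)
        assert out["p"] == pytest.approx(1.0)
        assert out["degenerate"]

    def test_constant_offset_pairs_are_degenerate_flagged(self):
        out = compare_species([2, 2, 2], [1, 1, 1], paired=True)
        assert out["degenerate"]
        assert out["p"] == 0.0 and np.isinf(out["t"])

    def test_matches_closed_form_paired_t(self):
        """Cross-check against the textbook formula t = d̄·√n/s_d."""
        rng = np.random.default_rng(3)
        a = rng.normal(2.0, 0.3, size=12)
        b = rng.normal(1.5, 0.3, size=12)
        out = compare_species(a, b, paired=True)
        d = a - b
        t_ref = d.mean() * np.sqrt(d.size) / d.std(ddof=1)
        from scipy import stats

        p_ref = 2 * stats.t.sf(abs(t_ref), d.size - 1)
        assert out["t"] == pytest.approx(t_ref, abs=1e-6)
        assert out["p"] == pytest.approx(p_ref, abs=1e-6)

    def test_unpaired_variant_matches_closed_form(self):
        rng = np.random.default_rng(4)
        a = rng.normal(2.0, 0.4, size=10)
        b = rng.normal(1.4, 0.4, size=10)
        out = compare_species(a, b, paired=False)
        sp = np.sqrt(((a.var(ddof=1) + b.var(ddof=1)) / 2))
        t_ref = (a.mean() - b.mean()) / (sp * np.sqrt(2 / 10))
        assert out["t"] == pytest.approx(t_ref, abs=1e-6)

    def test_tiny_groups_rejected(self):
        with pytest.raises(ValueError):
            compare_species([1.0], [2.0])

    def test_paired_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            compare_species([1, 2, 3], [1, 2], paired=True)
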