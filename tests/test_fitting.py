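import numpy as np
import pytest

from conftest import rice_draw
from liveriron.fitting import (FitConfig, detect_and_reverse_swap,
                               dixon_magnitude_fit, fit_voxels,
                               noise_corrected_fit, truncation_fit)
from liveriron.signal import (EchoSeries, NoiseModel, TissueState,
                              expected_signal, fat_dephasing,
                              noiseless_magnitude, rician_expectation)


def series_from_state(state, spectrum, protocol, sigma=0.0):
    return expected_signal(state, spectrum, protocol, NoiseModel(sigma))


class TestTruncationFit:
    def test_exact_monoexponential(self, megre):
        te = megre.echo_times
        s = EchoSeries(te, 100.0 * np.exp(-100.0 * te))
        res = truncation_fit(s, NoiseModel(0.0))
        assert res.r2star_hat == pytest.approx(100.0, rel=1e-6)
        assert res.n_echoes_used == 12
        assert res.converged

    def test_constant_series(self, megre):
        s = EchoSeries(megre.echo_times, np.full(12, 55.0))
        res = truncation_fit(s, NoiseModel(1.0))
        assert res.r2star_hat == pytest.approx(0.0, abs=1e-9)

    def test_noise_floor_truncation_beats_full_fit(self, megre):
        # trailing echoes pinned at the Rayleigh floor corrupt the
        # untruncated fit; truncation recovers the true rate
        te = megre.echo_times
        sigma = 2.0
        truth = 400.0
        clean = 100.0 * np.exp(-truth * te)
        corrupted = np.maximum(clean, 1.2533 * sigma)
        res = truncation_fit(EchoSeries(te, corrupted), NoiseModel(sigma))
        full = truncation_fit(EchoSeries(te, corrupted), NoiseModel(0.0))
        assert full.n_echoes_used == 12
        assert res.n_echoes_used < 12
        assert res.r2star_hat == pytest.approx(truth, rel=0.02)
        assert abs(full.r2star_hat - truth) > abs(res.r2star_hat - truth)

    def test_all_zero_series_flagged(self, megre):
        s = EchoSeries(megre.echo_times, np.zeros(12))
        res = truncation_fit(s, NoiseModel(1.0))
        assert not res.converged
        assert np.isnan(res.r2star_hat)

    def test_needs_three_echoes(self):
        s = EchoSeries(np.array([1e-3, 2e-3]), np.array([1.0, 0.5]))
        with pytest.raises(ValueError):
            truncation_fit(s, NoiseModel(0.0))

    def test_deterministic(self, megre, rng):
        te = megre.echo_times
        s = EchoSeries(te, rice_draw(80 * np.exp(-200 * te), 2.0, rng))
        a = truncation_fit(s, NoiseModel(2.0))
        b = truncation_fit(s, NoiseModel(2.0))
        assert a == b


class TestDixonMagnitudeFit:
    def test_noiseless_recovery(self, spectrum, wip):
        state = TissueState(80.0, 20.0, 150.0)
        res = dixon_magnitude_fit(series_from_state(state, spectrum, wip),
                                  spectrum, wip)
        assert res.r2star_hat == pytest.approx(150.0, rel=1e-3)
        assert res.w_hat == pytest.approx(80.0, rel=1e-3)
        assert res.f_hat == pytest.approx(20.0, rel=1e-3)
        assert not res.swap_flag

    def test_pure_water_low_pdff(self, spectrum, wip):
        state = TissueState(100.0, 0.0, 150.0)
        res = dixon_magnitude_fit(series_from_state(state, spectrum, wip),
                                  spectrum, wip)
        assert res.pdff_hat < 0.01
        assert not res.swap_flag

    def test_fat_dominant_truth_produces_classic_swap(self, spectrum, wip):
        # water-preferring resolution returns the mirrored (wrong) basin
        # and flags the ambiguity; the global mode recovers the truth
        state = TissueState(20.0, 80.0, 150.0)
        series = series_from_state(state, spectrum, wip)
        preferred = dixon_magnitude_fit(series, spectrum, wip,
                                        FitConfig(mode="prefer_water"))
        assert preferred.pdff_hat <= 0.5
        assert preferred.swap_flag
        unres = dixon_magnitude_fit(series, spectrum, wip,
                                    FitConfig(mode="global"))
        assert unres.pdff_hat == pytest.approx(0.8, abs=1e-3)
        assert unres.r2star_hat == pytest.approx(150.0, rel=1e-3)

    def test_brute_force_grid_oracle(self, spectrum, wip, rng):
        # exhaustive 1 1/s-resolution scan written independently; the
        # fitter's optimum residual must not exceed the scan's
        te = wip.echo_times
        c = fat_dephasing(spectrum, te)
        for w, f, r2 in [(90, 10, 60), (70, 30, 250), (95, 5, 500),
                         (80, 20, 120)]:
            state = TissueState(float(w), float(f), float(r2))
            nu = noiseless_magnitude(state, c, te)
            s = rice_draw(nu, 1.0, rng)
            best = np.inf
            for r in np.arange(0.0, 1001.0, 1.0):
                decay = np.exp(-r * te)
                for phi in np.linspace(0.0, 1.0, 101):
                    m = np.abs((1 - phi) + phi * c) * decay
                    a = max(float(s @ m) / float(m @ m), 0.0)
                    best = min(best, float(np.sum((a * m - s) ** 2)))
            res = dixon_magnitude_fit(EchoSeries(te, s), spectrum, wip,
                                      FitConfig(mode="global"))
            assert res.residual <= best + 1e-9

    def test_cap_clamps_and_flags(self, spectrum, qdixon):
        state = TissueState(95.0, 5.0, 600.0)
        series = series_from_state(state, spectrum, qdixon)
        res = dixon_magnitude_fit(series, spectrum, qdixon,
                                  FitConfig(r2star_cap=400.0, mode="global"))
        assert res.r2star_hat == 400.0
        assert res.capped

    def test_needs_four_echoes(self, spectrum, wip):
        s = EchoSeries(np.array([1e-3, 2e-3, 3e-3]), np.array([3.0, 2.0, 1.0]))
        with pytest.raises(ValueError):
            dixon_magnitude_fit(s, spectrum, wip)

    def test_degenerate_grid_rejected(self):
        with pytest.raises(ValueError):
            FitConfig(r2star_min=100.0, r2star_max=100.0)

    def test_deterministic(self, spectrum, wip, rng):
        te = wip.echo_times
        state = TissueState(85.0, 15.0, 300.0)
        s = EchoSeries(te, rice_draw(
            noiseless_magnitude(state, fat_dephasing(spectrum, te), te),
            2.0, rng))
        assert dixon_magnitude_fit(s, spectrum, wip) == \
            dixon_magnitude_fit(s, spectrum, wip)


class TestNoiseCorrectedFit:
    def test_sigma_zero_equals_dixon(self, spectrum, wip):
        state = TissueState(80.0, 20.0, 150.0)
        series = series_from_state(state, spectrum, wip)
        naive = dixon_magnitude_fit(series, spectrum, wip)
        nc = noise_corrected_fit(series, spectrum, wip, NoiseModel(0.0))
        assert nc.r2star_hat == pytest.approx(naive.r2star_hat, rel=1e-6)
        assert nc.w_hat == pytest.approx(naive.w_hat, rel=1e-6)

    def test_inverse_crime_recovery(self, spectrum, wip):
        # series constructed as the exact Rician expectation of the model
        sigma = 5.0
        truth = TissueState(100.0, 0.0, 200.0)
        series = series_from_state(truth, spectrum, wip, sigma=sigma)
        res = noise_corrected_fit(series, spectrum, wip, NoiseModel(sigma))
        assert res.r2star_hat == pytest.approx(200.0, rel=5e-3)
        assert res.w_hat == pytest.approx(100.0, rel=5e-3)
        assert res.f_hat == pytest.approx(0.0, abs=0.5)

    def test_less_biased_than_naive_at_high_r2star(self, spectrum, wip, rng):
        # small paired Monte-Carlo (the full-size version is an acceptance
        # criterion); noise correction must shrink the mean bias
        truth = TissueState(90.0, 10.0, 500.0)
        c = fat_dephasing(spectrum, wip.echo_times)
        nu = noiseless_magnitude(truth, c, wip.echo_times)
        sigma = nu[0] / 40.0
        naive, corrected = [], []
        for _ in range(80):
            s = EchoSeries(wip.echo_times, rice_draw(nu, sigma, rng))
            naive.append(dixon_magnitude_fit(s, spectrum, wip).r2star_hat)
            corrected.append(noise_corrected_fit(
                s, spectrum, wip, NoiseModel(sigma)).r2star_hat)
        assert abs(np.mean(corrected) - 500.0) < abs(np.mean(naive) - 500.0)


class TestParameterRecovery:
    def test_median_relative_error_below_5pct(self, spectrum, megre, qdixon,
                                              wip, rng):
        # simulated mini-cohort at first-echo SNR >= 30; per-patient value
        # is the mean over a small ROI's worth of voxel fits, as measured
        sigma = 1.5
        n_roi_voxels = 9
        truths = [TissueState(100 * (1 - p), 100 * p, r2)
                  for p, r2 in [(0.05, 40), (0.1, 80), (0.2, 150),
                                (0.02, 250), (0.15, 330), (0.08, 60),
                                (0.12, 110), (0.03, 200)]]
        errors = {"truncation": [], "dixon": [], "nc": []}
        for truth in truths:
            # reference arm: fat-suppressed mono-exponential acquisition
            sat = TissueState(truth.w, truth.f * 0.05, truth.r2star)
            c_m = fat_dephasing(spectrum, megre.echo_times)
            nu_m = noiseless_magnitude(sat, c_m, megre.echo_times)
            c_q = fat_dephasing(spectrum, qdixon.echo_times)
            nu_q = noiseless_magnitude(truth, c_q, qdixon.echo_times)
            c_w = fat_dephasing(spectrum, wip.echo_times)
            nu_w = noiseless_magnitude(truth, c_w, wip.echo_times)
            per_voxel = {"truncation": [], "dixon": [], "nc": []}
            for _ in range(n_roi_voxels):
                s_m = EchoSeries(megre.echo_times,
                                 rice_draw(nu_m, sigma, rng))
                per_voxel["truncation"].append(
                    truncation_fit(s_m, NoiseModel(sigma)).r2star_hat)
                s_q = EchoSeries(qdixon.echo_times,
                                 rice_draw(nu_q, sigma, rng))
                per_voxel["dixon"].append(
                    dixon_magnitude_fit(s_q, spectrum, qdixon).r2star_hat)
                s_w = EchoSeries(wip.echo_times, rice_draw(nu_w, sigma, rng))
                per_voxel["nc"].append(noise_corrected_fit(
                    s_w, spectrum, wip, NoiseModel(sigma)).r2star_hat)
            for engine, vals in per_voxel.items():
                errors[engine].append(np.mean(vals))
        truths_r2 = np.array([t.r2star for t in truths])
        for engine, estimates in errors.items():
            rel = np.abs(np.array(estimates) - truths_r2) / truths_r2
            assert np.median(rel) < 0.05, engine


class TestSwapDetection:
    def _maps(self, pdff_value, shape=(6, 6)):
        return {"w": np.full(shape, 100.0 * (1 - pdff_value)),
                "f": np.full(shape, 100.0 * pdff_value),
                "pdff": np.full(shape, pdff_value),
                "r2star": np.full(shape, 90.0)}

    def test_high_pdff_reversed(self):
        maps = self._maps(0.85)
        mask = np.ones((6, 6), dtype=bool)
        corrected, report = detect_and_reverse_swap(maps, mask)
        assert report["swap"] and report["reversed"]
        assert np.median(corrected["pdff"]) == pytest.approx(0.15)
        np.testing.assert_array_equal(corrected["w"], maps["f"])

    def test_low_pdff_unchanged(self):
        maps = self._maps(0.08)
        corrected, report = detect_and_reverse_swap(
            maps, np.ones((6, 6), dtype=bool))
        assert not report["swap"]
        np.testing.assert_array_equal(corrected["pdff"], maps["pdff"])

    def test_detect_only_mode(self):
        maps = self._maps(0.9)
        corrected, report = detect_and_reverse_swap(
            maps, np.ones((6, 6), dtype=bool), reverse=False)
        assert report["swap"] and not report["reversed"]
        np.testing.assert_array_equal(corrected["pdff"], maps["pdff"])

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError):
            detect_and_reverse_swap(self._maps(0.5), np.zeros((6, 6), bool))


class TestFitVoxels:
    def test_matches_scalar_path(self, spectrum, wip, rng):
        te = wip.echo_times
        states = [TissueState(90.0, 10.0, 80.0), TissueState(70.0, 30.0, 250.0)]
        c = fat_dephasing(spectrum, te)
        stack = np.zeros((1, 2, te.size))
        for j, st in enumerate(states):
            stack[0, j] = rice_draw(noiseless_magnitude(st, c, te), 1.5, rng)
        mask = np.ones((1, 2), dtype=bool)
        out = fit_voxels(stack, mask, "dixon", wip, spectrum=spectrum,
                         noise=NoiseModel(1.5))
        for j in range(2):
            single = dixon_magnitude_fit(EchoSeries(te, stack[0, j]),
                                         spectrum, wip)
            assert out["r2star"][j] == pytest.approx(single.r2star_hat,
                                                     rel=1e-9)

    def test_shape_checks(self, spectrum, wip):
        with pytest.raises(ValueError):
            fit_voxels(np.zeros((3, 3, 6)), np.ones((4, 4), bool), "dixon",
                       wip, spectrum=spectrum, noise=NoiseModel(1.0))
        with pytest.raises(ValueError):
            fit_voxels(np.zeros((3, 3, 5)), np.ones((3, 3), bool), "dixon",
                       wip, spectrum=spectrum, noise=NoiseModel(1.0))
        with pytest.raises(ValueError):
            fit_voxels(np.zeros((3, 3, 6)), np.ones((3, 3), bool), "nope",
                       wip, spectrum=spectrum, noise=NoiseModel(1.0))
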