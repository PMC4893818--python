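"""PCC computation, decay curves, decay fitting and group comparison."""

import dataclasses

import numpy as np
import pytest
from scipy import stats

from lysoquant import (
    CellMask,
    ImageFrame,
    MotilitySpec,
    PCCDecayCurve,
    SyntheticCellSpec,
    ValidationError,
    compare_decay,
    fit_decay,
    generate_timeseries,
    pcc,
    pcc_decay_curve,
)
from lysoquant.motility import _decay_model
from lysoquant.synthetic import _cell_mask, _render_spots, _sample_puncta, _shape_harmonics


@pytest.fixture(scope="module")
def noise_frames():
    rng = np.random.default_rng(9)
    a = ImageFrame(rng.uniform(0, 1000, (500, 500)))
    b = ImageFrame(rng.uniform(0, 1000, (500, 500)))
    mask = CellMask(np.ones((500, 500), dtype=bool))
    return a, b, mask


class TestPCC:
    def test_self_correlation_is_one(self, noise_frames):
        a, _, mask = noise_frames
        assert pcc(a, a, mask) == pytest.approx(1.0, abs=1e-12)

    def test_negative_affine_gives_minus_one(self, noise_frames):
        a, _, mask = noise_frames
        neg = ImageFrame(1000.0 - a.pixels)
        assert pcc(a, neg, mask, threshold_mode="mask") == pytest.approx(-1.0, abs=1e-9)

    def test_affine_invariance_positive_slope(self, noise_frames):
        a, b, mask = noise_frames
        r1 = pcc(a, b, mask, threshold_mode="mask")
        r2 = pcc(a, ImageFrame(b.pixels * 0.05 + 7.0), mask, threshold_mode="mask")
        assert r1 == pytest.approx(r2, abs=1e-10)

    def test_independent_noise_frames_near_zero(self, noise_frames):
        # Unbiased pixel sets: the raw statistic sits near 0 for
        # independent frames.  The union rule instead has a deterministic
        # negative baseline (pixels selected for being bright in either
        # frame are anti-correlated by construction), checked separately.
        a, b, mask = noise_frames
        assert abs(pcc(a, b, mask, threshold_mode="mask")) < 0.1
        assert abs(pcc(a, b, mask, threshold_mode="intersection")) < 0.1
        assert pcc(a, b, mask, threshold_mode="union") < 0.0

    def test_constant_vector_rejected(self):
        mask = CellMask(np.ones((32, 32), dtype=bool))
        const = ImageFrame(np.full((32, 32), 10.0))
        with pytest.raises(ValidationError):
            pcc(const, const, mask, threshold_mode="mask")

    def test_matches_covariance_oracle(self, noise_frames):
        a, b, mask = noise_frames
        r = pcc(a, b, mask, threshold_mode="mask")
        oracle = stats.pearsonr(a.pixels.ravel(), b.pixels.ravel()).statistic
        assert r == pytest.approx(oracle, abs=1e-12)


class TestDecayCurve:
    def test_static_noiseless_movie_stays_at_one(self):
        spec = SyntheticCellSpec(
            image_size=128,
            cell_radius_px=45,
            n_puncta=40,
            noise_gaussian_sd=0.0,
            noise_poisson=False,
            seed=2,
        )
        mot = MotilitySpec(n_frames=6, run_speed_um_s=0.0, confinement_radius_px=0.0, seed=3)
        movie, truth = generate_timeseries(spec, mot)
        curve = pcc_decay_curve(movie, truth.cell_mask)
        assert np.allclose(curve.pcc, 1.0)

    def test_rerandomized_puncta_reach_independence_baseline(self):
        # Frames with freshly sampled puncta each time: the PCC against
        # frame 0 should match the PCC between two independent renders.
        spec = SyntheticCellSpec(image_size=128, cell_radius_px=45, n_puncta=60, seed=1)
        rng = np.random.default_rng(spec.seed)
        amps, phases = _shape_harmonics(rng)
        cell = _cell_mask(spec, amps, phases)
        mask = CellMask(cell)

        def render(seed):
            r = np.random.default_rng(seed)
            pos, _ = _sample_puncta(spec, r, amps, phases, cell)
            img = _render_spots(cell.shape, pos, 5000.0, 1.5)
            return ImageFrame(np.minimum(img + 100.0 * cell, 65535))

        frames = [render(s) for s in range(6)]
        vals = [pcc(frames[0], f, mask) for f in frames[1:]]
        baselines = [pcc(render(100 + 2 * i), render(101 + 2 * i), mask) for i in range(5)]
        assert abs(np.mean(vals) - np.mean(baselines)) < 0.15

    def test_mobile_movie_decays_below_immobile(self, small_spec):
        curves = {}
        for name, speed, frac in (("mobile", 1.0, 1.0), ("immobile", 0.0, 0.0)):
            mot = MotilitySpec(
                n_frames=10,
                run_speed_um_s=speed,
                fraction_mobile=frac,
                confinement_radius_px=1.0,
                seed=5,
            )
            movie, truth = generate_timeseries(small_spec, mot)
            curves[name] = pcc_decay_curve(movie, truth.cell_mask)
        assert np.all(curves["mobile"].pcc[1:] < curves["immobile"].pcc[1:])

    def test_missing_frame_interval_rejected(self, small_spec):
        mot = MotilitySpec(n_frames=4, seed=1)
        movie, truth = generate_timeseries(small_spec, mot)
        movie.frame_interval_s = None
        with pytest.raises(ValidationError):
            pcc_decay_curve(movie, truth.cell_mask)


class TestFitDecay:
    def test_noiseless_self_consistency(self):
        t = np.arange(0, 120.0)
        y = _decay_model(t, 0.4, 0.05)
        fit = fit_decay(PCCDecayCurve(times_s=t, pcc=y))
        assert fit.plateau == pytest.approx(0.4, abs=1e-4)
        assert fit.rate_per_s == pytest.approx(0.05, abs=1e-4)

    def test_constant_curve_has_zero_rate(self):
        t = np.arange(0, 10.0)
        fit = fit_decay(PCCDecayCurve(times_s=t, pcc=np.ones(10)))
        assert fit.rate_per_s == 0.0
        assert fit.plateau == 1.0

    def test_rate_recovery_on_noisy_curves(self):
        rng = np.random.default_rng(0)
        t = np.arange(0, 120.0)
        errors = []
        for _ in range(50):
            y = np.clip(_decay_model(t, 0.4, 0.05) + rng.normal(0, 0.02, t.size), -1, 1)
            fit = fit_decay(PCCDecayCurve(times_s=t, pcc=y))
            errors.append(abs(fit.rate_per_s / 0.05 - 1))
        assert max(errors) < 0.10

    def test_too_few_points_rejected(self):
        with pytest.raises(ValidationError):
            fit_decay(PCCDecayCurve(times_s=np.arange(3.0), pcc=np.zeros(3)))


class TestCompareDecay:
    def _noisy_curves(self, rng, n_curves, plateau=0.4, rate=0.05):
        t = np.arange(0, 60.0)
        return [
            PCCDecayCurve(
                times_s=t,
                pcc=np.clip(
                    _decay_model(t, plateau, rate) + rng.normal(0, 0.03, t.size),
                    -1,
                    1,
                ),
            )
            for _ in range(n_curves)
        ]

    def test_duplicate_group_gives_null_result(self):
        rng = np.random.default_rng(1)
        group = self._noisy_curves(rng, 5)
        res = compare_decay(group, list(group))
        assert res.f_stat == pytest.approx(0.0, abs=1e-6)
        assert res.p_value == pytest.approx(1.0, abs=1e-6)

    def test_null_rejection_rate_near_nominal(self):
        rng = np.random.default_rng(2)
        reps = 300
        rej = 0
        for _ in range(reps):
            res = compare_decay(self._noisy_curves(rng, 5), self._noisy_curves(rng, 5))
            rej += res.p_value < 0.05
        half = 1.96 * np.sqrt(0.05 * 0.95 / reps)
        assert 0.05 - half <= rej / reps <= 0.05 + half

    def test_power_fast_vs_immobile_movies(self, small_spec):
        groups = {}
        for name, speed, frac in (("fast", 1.0, 0.8), ("still", 0.0, 0.0)):
            curves = []
            for s in range(5):
                mot = MotilitySpec(
                    n_frames=12,
                    run_speed_um_s=speed,
                    fraction_mobile=frac,
                    confinement_radius_px=1.0,
                    seed=40 + s,
                )
                spec = dataclasses.replace(small_spec, seed=60 + s)
                movie, truth = generate_timeseries(spec, mot)
                curves.append(pcc_decay_curve(movie, truth.cell_mask))
            groups[name] = curves
        res = compare_decay(groups["fast"], groups["still"])
        assert res.p_value < 0.01

    def test_expected_pcc_non_increasing_in_speed(self):
        spec = SyntheticCellSpec(image_size=128, cell_radius_px=45, n_puncta=60)
        means = []
        for speed in (0.0, 0.2, 0.5, 1.0):
            vals = []
            for s in range(10):
                mot = MotilitySpec(
                    n_frames=3,
                    run_speed_um_s=speed,
                    fraction_mobile=0.5,
                    confinement_radius_px=1.0,
                    seed=100 + s,
                )
                movie, truth = generate_timeseries(
                    dataclasses.replace(spec, seed=200 + s), mot
                )
                vals.append(pcc_decay_curve(movie, truth.cell_mask).pcc[1])
            means.append(np.mean(vals))
        assert all(np.diff(means) <= 0)
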