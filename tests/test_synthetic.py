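"""Generator ground truth: determinism, clustering law, kinematics."""

import dataclasses

import numpy as np
import pytest

from lysoquant import (
    MotilitySpec,
    SyntheticCellSpec,
    ValidationError,
    generate_cell,
    generate_population,
    generate_timeseries,
    sample_profile_population,
)


def positions_inside(mask, positions):
    xi = np.rint(positions[..., 0]).astype(int)
    yi = np.rint(positions[..., 1]).astype(int)
    return bool(mask[yi, xi].all())


class TestGenerateCell:
    def test_seed_determinism_bit_identical(self, small_spec):
        a, _ = generate_cell(small_spec)
        b, _ = generate_cell(small_spec)
        assert np.array_equal(a.data, b.data)

    def test_no_puncta_no_noise_gives_flat_background(self):
        spec = SyntheticCellSpec(
            n_puncta=0,
            cytoplasm_level=0.0,
            noise_gaussian_sd=0.0,
            noise_poisson=False,
            golgi_fraction=0.0,
        )
        stack, _ = generate_cell(spec)
        organelle = stack.frame("LAMP1", 0).pixels
        assert np.all(organelle == spec.background_level)

    def test_puncta_lie_inside_cell_mask(self, rendered_cell):
        _, truth = rendered_cell
        assert positions_inside(truth.cell_mask.mask, truth.positions)

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"image_size": 64},
            {"shape_irregularity": 1.5},
            {"n_puncta": -1},
            {"clustering_beta": -0.1},
            {"golgi_fraction": 1.2},
            {"bit_depth": 12},
        ],
    )
    def test_invalid_spec_raises_naming_field(self, kwargs):
        with pytest.raises(ValidationError) as err:
            SyntheticCellSpec(**kwargs)
        assert next(iter(kwargs)) in str(err.value)

    def test_clustering_shifts_puncta_toward_centroid(self):
        # Uniform-disk closed form: E[d] = 2/3 for beta = 0; the clustered
        # expectation comes from sampling the stated Beta(2, beta+1) law.
        oracle = np.random.default_rng(123).beta(2.0, 9.0, size=200_000).mean()
        means = {}
        for beta in (0.0, 8.0):
            d = np.concatenate(
                [
                    generate_cell(
                        SyntheticCellSpec(
                            n_puncta=200, clustering_beta=beta, seed=s
                        )
                    )[1].norm_dist
                    for s in range(5)
                ]
            )
            means[beta] = d.mean()
        assert abs(means[0.0] - 2 / 3) < 0.05
        assert means[8.0] < 0.35
        assert abs(means[8.0] - oracle) < 0.03

    def test_mean_distance_non_increasing_in_beta(self):
        mean_by_beta = []
        for beta in (0.0, 2.0, 4.0, 8.0):
            d = np.concatenate(
                [
                    generate_cell(
                        SyntheticCellSpec(
                            image_size=128,
                            cell_radius_px=45,
                            n_puncta=200,
                            clustering_beta=beta,
                            seed=s,
                        )
                    )[1].norm_dist
                    for s in range(20)
                ]
            )
            mean_by_beta.append(d.mean())
        assert all(np.diff(mean_by_beta) < 0)

    def test_noise_off_total_intensity_matches_gaussian_integral(self):
        spec = SyntheticCellSpec(
            n_puncta=40,
            background_level=0.0,
            cytoplasm_level=0.0,
            golgi_fraction=0.0,
            noise_gaussian_sd=0.0,
            noise_poisson=False,
            seed=3,
        )
        stack, _ = generate_cell(spec)
        total = stack.frame("LAMP1", 0).pixels.astype(float).sum()
        expected = (
            spec.n_puncta * 2 * np.pi * spec.punctum_sigma_px**2 * spec.punctum_amplitude
        )
        assert abs(total - expected) / expected < 0.01


class TestGeneratePopulation:
    def test_population_reproducible_and_distinct(self, small_spec):
        pop1 = generate_population(30, small_spec, seed=11)
        pop2 = generate_population(30, small_spec, seed=11)
        assert len(pop1) == 30
        for (s1, t1), (s2, t2) in zip(pop1, pop2):
            assert np.array_equal(s1.data, s2.data)
        layouts = {tuple(np.round(t.positions[0, :, 0], 3)) for _, t in pop1}
        assert len(layouts) == 30

    def test_single_cell_and_seed_sensitivity(self, small_spec):
        assert len(generate_population(1, small_spec, seed=0)) == 1
        a = generate_population(2, small_spec, seed=1)
        b = generate_population(2, small_spec, seed=2)
        assert not np.array_equal(a[0][0].data, b[0][0].data)

    def test_invalid_count(self, small_spec):
        with pytest.raises(ValidationError):
            generate_population(0, small_spec, seed=0)


class TestGenerateTimeseries:
    def test_static_spec_gives_constant_trajectories(self, small_spec):
        mot = MotilitySpec(
            n_frames=5, run_speed_um_s=0.0, confinement_radius_px=0.0, seed=2
        )
        _, truth = generate_timeseries(small_spec, mot)
        assert np.all(truth.positions == truth.positions[0])

    def test_mean_step_matches_speed(self):
        spec = SyntheticCellSpec(
            image_size=256, cell_radius_px=90, n_puncta=60, seed=5
        )
        mot = MotilitySpec(
            n_frames=30,
            run_speed_um_s=0.5,
            fraction_mobile=1.0,
            pixel_size_um=0.16,
            seed=9,
        )
        _, truth = generate_timeseries(spec, mot)
        steps = np.linalg.norm(np.diff(truth.positions, axis=0), axis=2)
        expected = mot.run_speed_um_s * mot.frame_interval_s / mot.pixel_size_um
        assert steps.size >= 1000
        assert abs(steps.mean() / expected - 1) < 0.05

    def test_trajectories_stay_inside_mask(self, small_spec):
        mot = MotilitySpec(
            n_frames=15, run_speed_um_s=1.5, fraction_mobile=0.7, seed=4
        )
        _, truth = generate_timeseries(small_spec, mot)
        assert positions_inside(truth.cell_mask.mask, truth.positions)

    def test_seed_determinism(self, small_spec):
        mot = MotilitySpec(n_frames=6, seed=3)
        a, ta = generate_timeseries(small_spec, mot)
        b, tb = generate_timeseries(small_spec, mot)
        assert np.array_equal(a.data, b.data)
        assert np.array_equal(ta.positions, tb.positions)

    def test_invalid_pixel_size(self):
        with pytest.raises(ValidationError):
            MotilitySpec(pixel_size_um=0.0)


class TestProfileSampling:
    def test_profiles_valid_and_deterministic(self, small_spec):
        a = sample_profile_population(10, small_spec, seed=1)
        b = sample_profile_population(10, small_spec, seed=1)
        assert len(a) == 10
        for pa, pb in zip(a, b):
            assert np.array_equal(pa.y, pb.y)
            assert pa.y[0] == 0.0 and pa.y[-1] == 1.0
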