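"""Density profiles, reshuffle null, gamma fit and interval calls."""

import numpy as np
import pandas as pd
import pytest

from enspatial.errors import DegenerateSampleError, GridMismatchError, NoCentersError
from enspatial.geometry import Circle, clipped_area_analytic
from enspatial.spatial import (
    DEFAULT_RADII,
    DensityProfile,
    NullDistribution,
    analyze_pairs,
    build_null,
    classify,
    density_profile,
    fit_gamma,
    frame_center_densities,
    reshuffle_frame,
)


def naive_profile_per_center(frame, center_ph, target_ph, radii, exclude_self=True):
    """Independent pure-python per-center densities, ordered by cell index."""
    rows = []
    for i in range(frame.n_cells):
        if frame.phenotype[i] != center_ph:
            continue
        row = []
        for r in radii:
            n = 0
            for j in range(frame.n_cells):
                if frame.phenotype[j] != target_ph:
                    continue
                if exclude_self and j == i:
                    continue
                d2 = (frame.x[j] - frame.x[i]) ** 2 + (frame.y[j] - frame.y[i]) ** 2
                if d2 <= r * r:
                    n += 1
            area = clipped_area_analytic(Circle(frame.x[i], frame.y[i], r), frame.rect)
            row.append(n / area)
        rows.append(row)
    return np.array(rows).reshape(len(rows), len(radii))


def naive_profile(frames, center_ph, target_ph, radii, exclude_self=True):
    """Grand mean of the naive per-center densities over pooled frames."""
    per_center = [
        naive_profile_per_center(f, center_ph, target_ph, radii, exclude_self)
        for f in frames
    ]
    return np.vstack(per_center).mean(axis=0)


class TestDensityProfile:
    def test_single_interior_center(self, make_frame):
        cells = [(225, 225, "C")] + [(225 + dx, 225, "T") for dx in (-30, -10, 5, 10, 30)]
        profile = density_profile([make_frame(cells)], "C", "T", radii=(40.0,))
        assert profile.density[0] == pytest.approx(5 / (np.pi * 1600), rel=1e-12)
        assert profile.n_centers == 1

    def test_two_centers_average(self, make_frame):
        # one center sees 1 target, the other 0, at r = 40
        frame = make_frame([(100, 100, "C"), (300, 300, "C"), (120, 100, "T")])
        profile = density_profile([frame], "C", "T", radii=(40.0,))
        d1 = 1 / (np.pi * 1600)
        assert profile.density[0] == pytest.approx(d1 / 2, rel=1e-12)

    def test_matches_naive_double_loop(self, random_frame):
        radii = (20.0, 60.0, 150.0, 500.0)
        frames = [
            random_frame(25, ["C", "T", "X"], seed=100 + k, image_id=f"f{k}")
            for k in range(10)
        ]
        # per-center densities are bit-exact against the pure-python loop
        for frame in frames:
            naive = naive_profile_per_center(frame, "C", "T", radii)
            np.testing.assert_array_equal(
                frame_center_densities(frame, "C", "T", radii), naive
            )
        profile = density_profile(frames, "C", "T", radii=radii)
        np.testing.assert_allclose(
            profile.density, naive_profile(frames, "C", "T", radii), rtol=1e-13
        )

    def test_homotypic_matches_naive_with_self_exclusion(self, random_frame):
        radii = (30.0, 100.0, 450.0)
        frames = [random_frame(20, ["C", "X"], seed=7 + k) for k in range(5)]
        for frame in frames:
            np.testing.assert_array_equal(
                frame_center_densities(frame, "C", "C", radii),
                naive_profile_per_center(frame, "C", "C", radii),
            )
        profile = density_profile(frames, "C", "C", radii=radii)
        np.testing.assert_allclose(
            profile.density, naive_profile(frames, "C", "C", radii), rtol=1e-13
        )

    def test_no_centers_error_names_phenotype(self, make_frame):
        with pytest.raises(NoCentersError, match="'C'"):
            density_profile([make_frame([(10, 10, "T")])], "C", "T", radii=(40.0,))


class TestReshuffle:
    def test_conserves_phenotype_counts(self, random_frame):
        frame = random_frame(60, ["A", "B", "C"], seed=1)
        shuffled = reshuffle_frame(frame, seed=2)
        assert shuffled.phenotype_counts() == frame.phenotype_counts()
        assert not np.array_equal(shuffled.x, frame.x)

    def test_same_seed_identical(self, random_frame):
        frame = random_frame(30, ["A", "B"], seed=3)
        a, b = reshuffle_frame(frame, seed=9), reshuffle_frame(frame, seed=9)
        np.testing.assert_array_equal(a.x, b.x)
        np.testing.assert_array_equal(a.y, b.y)

    def test_positions_uniform_over_frame(self, make_frame):
        # 2000 reshuffles of one cell: empirical mean near (W/2, H/2)
        frame = make_frame([(10.0, 10.0, "A")])
        xs, ys = zip(
            *[(f.x[0], f.y[0]) for f in (reshuffle_frame(frame, s) for s in range(2000))]
        )
        se = 450 / np.sqrt(12) / np.sqrt(2000)
        assert abs(np.mean(xs) - 225) <= 3 * se
        assert abs(np.mean(ys) - 225) <= 3 * se


class TestFitGamma:
    def test_method_of_moments_hand_computation(self):
        # mean 2.5, unbiased variance 5/3
        k, theta = fit_gamma([1, 2, 3, 4], method="mom")
        assert k == pytest.approx(2.5**2 / (5 / 3), rel=1e-12)
        assert theta == pytest.approx((5 / 3) / 2.5, rel=1e-12)

    def test_mle_recovers_known_shape(self):
        rng = np.random.default_rng(12)
        draws = rng.gamma(shape=4.0, scale=2.0, size=10_000)
        k, theta = fit_gamma(draws)
        assert k == pytest.approx(4.0, rel=0.05)
        assert k * theta == pytest.approx(draws.mean(), rel=0.01)

    def test_mom_used_when_zeros_present(self):
        samples = np.array([0.0, 1.0, 2.0, 3.0])
        k, theta = fit_gamma(samples)
        assert k * theta == pytest.approx(samples.mean(), rel=1e-12)

    @pytest.mark.parametrize("samples", [[5.0, 5.0, 5.0], [0.0, 0.0]])
    def test_degenerate_samples_rejected(self, samples):
        with pytest.raises(DegenerateSampleError):
            fit_gamma(samples)


class TestBuildNull:
    def test_sample_count_is_frames_times_reshuffles(self, make_frame):
        # every frame holds center cells, so all 41 contribute 50 samples
        frames = [
            make_frame(
                [(10.0 + k, 20.0, "C"), (50.0, 60.0 + k, "C"), (200.0, 100.0, "T")],
                image_id=f"f{k}",
            )
            for k in range(41)
        ]
        null = build_null(frames, "C", "T", radii=(40.0,), reshuffles_per_frame=50, seed=0)
        assert null.n_samples == 41 * 50 == 2050

    def test_null_mean_matches_uniform_expectation(self, random_frame):
        # E[edge-corrected density] of uniform targets = n_target / (W·H)
        frames = [random_frame(30, ["C", "T"], seed=60 + k, image_id=f"f{k}") for k in range(10)]
        null = build_null(frames, "C", "T", radii=(40.0, 200.0), reshuffles_per_frame=100, seed=4)
        n_t = np.mean([f.indices_of("T").size for f in frames])
        expected = n_t / (450 * 450)
        for j in range(2):
            se = null.samples[:, j].std(ddof=1) / np.sqrt(null.n_samples)
            assert abs(null.samples[:, j].mean() - expected) <= 4 * se

    def test_fixed_seed_bit_identical(self, random_frame):
        frames = [random_frame(10, ["C", "T"], seed=70)]
        a = build_null(frames, "C", "T", radii=(40.0,), reshuffles_per_frame=20, seed=8)
        b = build_null(frames, "C", "T", radii=(40.0,), reshuffles_per_frame=20, seed=8)
        np.testing.assert_array_equal(a.samples, b.samples)
        np.testing.assert_array_equal(a.lo, b.lo)
        np.testing.assert_array_equal(a.hi, b.hi)

    def test_all_zero_samples_flagged_degenerate(self, make_frame):
        # centers but no targets anywhere: every null sample is 0
        frame = make_frame([(100, 100, "C"), (200, 200, "C")])
        null = build_null([frame], "C", "T", radii=(40.0,), reshuffles_per_frame=10, seed=1)
        assert null.degenerate[0]
        assert null.lo[0] == null.hi[0] == 0.0
        assert np.isnan(null.shape[0])

    def test_gamma_mean_tracks_sample_mean(self, random_frame):
        frames = [random_frame(40, ["C", "T"], seed=80 + k, image_id=f"f{k}") for k in range(5)]
        null = build_null(frames, "C", "T", radii=(100.0,), reshuffles_per_frame=50, seed=2)
        fitted_mean = null.shape[0] * null.scale[0]
        assert fitted_mean == pytest.approx(null.samples[:, 0].mean(), rel=0.01)


class TestClassify:
    @staticmethod
    def _null(lo, hi, degenerate=False):
        return NullDistribution(
            "C", "T", np.array([40.0]), np.zeros((2, 1)),
            np.array([1.0]), np.array([1.0]),
            np.array([lo]), np.array([hi]), 0.9,
            np.array([degenerate]), np.array(["mle"], dtype=object),
        )

    @staticmethod
    def _profile(value):
        return DensityProfile("C", "T", np.array([40.0]), np.array([value]), 1, 1)

    @pytest.mark.parametrize(
        ("observed", "lo", "hi", "expected"),
        [
            (2e-3, 1e-4, 5e-4, "above"),
            (5e-4, 1e-4, 5e-4, "inside"),  # boundary is inside
            (0.0, 1e-5, 9e-5, "below"),
            (3e-5, 1e-5, 9e-5, "inside"),
        ],
    )
    def test_calls(self, observed, lo, hi, expected):
        calls = classify(self._profile(observed), self._null(lo, hi))
        assert calls[0].call == expected

    def test_degenerate_called_inside_with_flag(self):
        calls = classify(self._profile(1e-3), self._null(0.0, 0.0, degenerate=True))
        assert calls[0].call == "inside"
        assert calls[0].degenerate

    def test_grid_mismatch_rejected(self):
        profile = DensityProfile("C", "T", np.array([30.0]), np.array([0.0]), 1, 1)
        with pytest.raises(GridMismatchError):
            classify(profile, self._null(0.0, 1.0))


class TestAnalyzePairs:
    def test_deterministic_for_fixed_seed(self, random_frame):
        frames = [random_frame(30, ["C", "T"], seed=90 + k, image_id=f"f{k}") for k in range(3)]
        kwargs = dict(radii=(20.0, 40.0), reshuffles_per_frame=10, seed=123)
        a = analyze_pairs(frames, [("C", "T"), ("C", "C")], **kwargs)
        b = analyze_pairs(frames, [("C", "T"), ("C", "C")], **kwargs)
        pd.testing.assert_frame_equal(a, b)

    def test_emits_one_row_per_pair_and_radius(self, random_frame):
        frames = [random_frame(20, ["C", "T"], seed=95)]
        df = analyze_pairs(frames, [("C", "T")], radii=DEFAULT_RADII,
                           reshuffles_per_frame=5, seed=0)
        assert len(df) == len(DEFAULT_RADII)
        assert set(df["call"]) <= {"above", "inside", "below"}
        assert (df["n_null_samples"] == 5).all()
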