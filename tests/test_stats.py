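import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import ndimage

from fibrespot import (
    ShearMeasurement,
    ValidationError,
    coefficient_of_variation,
    degree_of_organisation,
    generate_spot,
    group_summary_table,
    mean_normalise,
    organisation_table,
    pseudocolour_map,
    spearman_correlation,
    spec_for_orientation,
    summarise_group,
)
from oracles import spearman_midrank

# group means of the four-jerky validation study
ORGANISATION_MEANS = [2.68, 2.53, 2.31, 1.98]
ORIENTATION_MEANS = [1.56, 1.40, 1.25, 1.20]


class TestDegreeOfOrganisation:
    def test_equal_forces_give_one(self):
        assert degree_of_organisation(ShearMeasurement("s1", 12.0, 12.0)) == 1.0

    def test_beef_group_mean_forces(self):
        # ratio of the printed mean forces; the printed group value 2.68 is
        # instead the mean of per-sample ratios
        r = degree_of_organisation(ShearMeasurement("beef", 100.53, 37.81))
        assert r == pytest.approx(2.659, abs=5e-4)

    def test_zero_longitudinal_force_rejected(self):
        with pytest.raises(ValidationError):
            ShearMeasurement("s1", 10.0, 0.0)


class TestCoefficientOfVariation:
    def test_constant_samples_give_zero(self):
        assert coefficient_of_variation([3.0, 3.0, 3.0]) == 0.0

    def test_one_two_three_gives_fifty(self):
        assert coefficient_of_variation([1, 2, 3]) == pytest.approx(50.0)

    def test_mean_and_sd_example(self):
        # mean 1.40, sd 0.07 -> CV 5.0
        x = np.array([1.33, 1.40, 1.47])
        x = (x - x.mean()) / x.std(ddof=1) * 0.07 + 1.40
        assert coefficient_of_variation(x) == pytest.approx(5.0)

    @settings(deadline=None, derandomize=True, max_examples=40)
    @given(
        values=st.lists(st.floats(0.1, 100.0), min_size=2, max_size=12),
        scale=st.floats(0.01, 1000.0),
    )
    def test_scale_invariance(self, values, scale):
        x = np.asarray(values)
        assert coefficient_of_variation(scale * x) == pytest.approx(
            coefficient_of_variation(x), rel=1e-9
        )

    @pytest.mark.parametrize("bad", [[1.0], [-2.0, 0.0]])
    def test_invalid_inputs_rejected(self, bad):
        with pytest.raises(ValidationError):
            coefficient_of_variation(bad)


class TestMeanNormalise:
    def test_two_point_symmetry(self):
        np.testing.assert_allclose(mean_normalise([0.0, 1.0]), [-0.5, 0.5])

    def test_output_sums_to_zero(self, rng):
        out = mean_normalise(rng.random(50))
        assert abs(out.sum()) < 1e-12

    def test_orientation_group_means(self):
        # direct formula: mean 1.3525, range 0.36
        out = mean_normalise(ORIENTATION_MEANS)
        expected = (np.array(ORIENTATION_MEANS) - 1.3525) / 0.36
        np.testing.assert_allclose(out, expected, atol=1e-12)

    def test_constant_input_rejected(self):
        with pytest.raises(ValidationError):
            mean_normalise([2.0, 2.0])


class TestSpearmanCorrelation:
    def test_perfect_concordance_and_discordance(self):
        x = [1.0, 2.0, 5.0, 9.0]
        assert spearman_correlation(x, [2.0, 3.0, 4.0, 8.0]) == pytest.approx(1.0)
        assert spearman_correlation(x, [8.0, 4.0, 3.0, 2.0]) == pytest.approx(-1.0)

    def test_identical_group_rankings_give_one(self):
        assert spearman_correlation(
            ORGANISATION_MEANS, ORIENTATION_MEANS
        ) == pytest.approx(1.0)

    def test_matches_midrank_oracle_with_ties(self, rng):
        for _ in range(20):
            x = rng.integers(0, 5, size=12).astype(float)  # plenty of ties
            y = rng.integers(0, 5, size=12).astype(float)
            if np.ptp(x) == 0 or np.ptp(y) == 0:
                continue
            assert spearman_correlation(x, y) == pytest.approx(
                spearman_midrank(x, y), abs=1e-12
            )

    def test_invariant_under_monotone_transforms(self, rng):
        x = rng.random(15)
        y = rng.random(15)
        r = spearman_correlation(x, y)
        assert spearman_correlation(np.exp(3 * x), y) == pytest.approx(r)
        assert spearman_correlation(x, y**3 + 5) == pytest.approx(r)

    def test_normalisation_does_not_change_ranks(self, rng):
        x = rng.random(10)
        y = rng.random(10)
        assert spearman_correlation(
            mean_normalise(x), mean_normalise(y)
        ) == pytest.approx(spearman_correlation(x, y))

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValidationError):
            spearman_correlation([1, 2, 3], [1, 2])
        with pytest.raises(ValidationError):
            spearman_correlation([1, 1, 1], [1, 2, 3])
        with pytest.raises(ValidationError):
            spearman_correlation([1, 2], [3, 4])


class TestGroupSummaries:
    def test_constant_group(self):
        s = summarise_group("g", [1.0, 1.0, 1.0])
        assert (s.mean, s.sd, s.cv_percent) == (1.0, 0.0, 0.0)

    def test_two_sample_group_by_hand(self):
        s = summarise_group("g", [2.0, 4.0])
        assert s.mean == 3.0
        assert s.sd == pytest.approx(np.sqrt(2.0))
        assert (s.min, s.max, s.n) == (2.0, 4.0, 2)

    def test_empty_group_rejected(self):
        with pytest.raises(ValidationError):
            summarise_group("g", [])

    def test_organisation_table_and_summary(self):
        shear = pd.DataFrame(
            {
                "group": ["a", "a", "b", "b"],
                "sample_id": ["a1", "a2", "b1", "b2"],
                "transverse_force_N": [10.0, 12.0, 20.0, 22.0],
                "longitudinal_force_N": [5.0, 5.0, 10.0, 11.0],
            }
        )
        table = organisation_table(shear)
        np.testing.assert_allclose(
            table["degree_of_organisation"], [2.0, 2.4, 2.0, 2.0]
        )
        summary = group_summary_table(table, "degree_of_organisation")
        assert summary["group"].tolist() == ["a", "b"]
        assert summary.loc[0, "mean"] == pytest.approx(2.2)

    def test_missing_columns_rejected(self):
        with pytest.raises(ValidationError, match="missing"):
            organisation_table(pd.DataFrame({"group": []}))


class TestPseudocolourMap:
    def test_endpoints_map_to_colormap_extremes(self):
        import matplotlib

        grid = np.linspace(0, 1, 256).reshape(16, 16)
        img = pseudocolour_map(grid, "viridis")
        lut = (np.asarray(matplotlib.colormaps["viridis"](
            np.linspace(0, 1, 256)))[:, :3] * 255).round().astype(np.uint8)
        np.testing.assert_array_equal(img.reshape(-1, 3)[0], lut[0])
        np.testing.assert_array_equal(img.reshape(-1, 3)[-1], lut[-1])

    def test_monotone_rows_give_monotone_colour_index(self):
        grid = np.tile(np.linspace(0, 1, 64), (16, 1))
        img = pseudocolour_map(grid, "gray")  # gray map: index == intensity
        assert (np.diff(img[0, :, 0].astype(int)) >= 0).all()

    def test_constant_grid_single_colour_with_warning(self):
        with pytest.warns(UserWarning, match="single colour"):
            img = pseudocolour_map(np.full((16, 16), 0.5))
        assert len(np.unique(img.reshape(-1, 3), axis=0)) == 1

    def test_elliptical_spot_band_is_an_elliptical_ring(self):
        img, _ = generate_spot(
            spec_for_orientation(
                1.4, sigma_minor=60.0, height=512, width=512,
                speckle_contrast=0.0, background_noise_sd=0.0,
            )
        )
        grid = img[:, :, 0] / 255.0
        pc = pseudocolour_map(grid, "viridis")
        # pixels sharing the outermost strong colour band form a ring whose
        # complement splits into inside and outside
        idx = np.round((grid - grid.min()) / np.ptp(grid) * 255).astype(int)
        band = (idx >= 64) & (idx <= 72)
        labels, n = ndimage.label(~band)
        assert n >= 2
        centre_label = labels[256, 256]
        corner_label = labels[0, 0]
        assert centre_label != corner_label != 0 and centre_label != 0
        # and the rendered band is a single colour
        assert len(np.unique(pc[idx == 68].reshape(-1, 3), axis=0)) == 1
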