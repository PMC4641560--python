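"""Forward sectioning model: closed form, template operator, sampler."""

import numpy as np
import pytest
from scipy.stats import kstest

from ldcv.geometry import (
    ApparentHistogram,
    DiameterGrid,
    PopulationWeights,
    SectioningModel,
    apparent_cdf,
    build_template,
    default_grid,
    mean_apparent_diameter,
    sample_sections,
    section_spheres,
)


def delta_weights(grid, diameter):
    """All population mass in the bin whose representative is `diameter`."""
    w = np.zeros(grid.n_bins)
    w[list(grid.representatives).index(diameter)] = 1.0
    return PopulationWeights(grid, w)


class TestApparentCdf:
    @pytest.mark.parametrize(
        "d, D, expected",
        [
            (0.0, 500.0, 0.0),  # no section smaller than 0
            (500.0, 500.0, 1.0),  # apex-to-apex coverage
            # Monte-Carlo oracle: sin(phi)~U(-1,1), d=500*cos(phi), n=1e6
            # gave empirical CDF 0.13394 +- 0.0004; closed form 1-sqrt(3)/2.
            (250.0, 500.0, 0.13397),
        ],
    )
    def test_values(self, d, D, expected):
        assert apparent_cdf(d, D) == pytest.approx(expected, abs=1e-5)

    def test_monotone_and_vectorised(self):
        d = np.linspace(0, 300, 50)
        cdf = apparent_cdf(d, 300.0)
        assert np.all(np.diff(cdf) >= 0)
        assert cdf[-1] == pytest.approx(1.0)

    @pytest.mark.parametrize("d, D", [(-1.0, 500.0), (501.0, 500.0), (10.0, 0.0)])
    def test_domain_errors(self, d, D):
        with pytest.raises(ValueError):
            apparent_cdf(d, D)

    def test_closed_form_matches_monte_carlo(self):
        """The analytic CDF is the distribution the sampler actually draws."""
        rng = np.random.default_rng(7)
        for D in (100.0, 300.0, 500.0):
            d = section_spheres(np.full(200_000, D), rng)
            res = kstest(d, lambda x, D=D: apparent_cdf(np.clip(x, 0, D), D))
            assert res.statistic < 0.005


class TestMeanApparentDiameter:
    @pytest.mark.parametrize("D", [100.0, 500.0])
    def test_pi_over_four_law(self, D):
        # numeric integration of d * f(d) over [0, D] (independent oracle)
        d = np.linspace(0, D, 200_001)
        cdf = apparent_cdf(d, D)
        numeric = np.trapezoid(1.0 - cdf, d)  # E[X] = int (1 - F) for X >= 0
        assert mean_apparent_diameter(D) == pytest.approx(numeric, rel=1e-6)
        assert mean_apparent_diameter(D) == pytest.approx(np.pi / 4 * D, rel=1e-12)

    def test_degenerate_sphere_rejected(self):
        with pytest.raises(ValueError):
            mean_apparent_diameter(0.0)


class TestGrids:
    def test_default_grid_shape(self):
        grid = default_grid()
        assert grid.bin_edges[0] == 0.0
        assert grid.bin_edges[-1] == 700.0
        assert grid.bin_width == 25.0
        assert grid.n_bins == 28

    def test_representative_modes(self):
        grid = default_grid()
        assert grid.representatives[-1] == 700.0
        mid = default_grid("midpoint")
        assert mid.representatives[0] == 12.5

    @pytest.mark.parametrize(
        "edges", [[0.0], [0.0, 25.0, 20.0], [0.0, 25.0, 60.0]]
    )
    def test_invalid_edges(self, edges):
        with pytest.raises(ValueError):
            DiameterGrid(np.asarray(edges))


class TestTemplate:
    def test_columns_sum_to_one(self):
        grid = default_grid()
        tpl = build_template(grid, grid, SectioningModel())
        np.testing.assert_allclose(tpl.matrix.sum(axis=0), 1.0, atol=1e-9)

    def test_top_bin_mass_for_500(self):
        # P(section in [475, 500)) = 1 - CDF(475; 500) = sqrt(1 - 0.95^2)
        grid = default_grid()
        tpl = build_template(grid, grid, SectioningModel())
        j = list(grid.representatives).index(500.0)
        i = int(np.searchsorted(grid.bin_edges, 500.0)) - 1
        assert tpl.matrix[i, j] == pytest.approx(0.3122499, abs=1e-6)

    def test_no_mass_above_true_diameter(self):
        grid = default_grid()
        tpl = build_template(grid, grid, SectioningModel())
        j = list(grid.representatives).index(100.0)
        above = grid.lower_edges >= 100.0
        assert tpl.matrix[above, j].sum() == 0.0

    def test_modal_bin_contains_true_diameter(self):
        """Negative skew: each column's mode is the bin holding D itself."""
        grid = default_grid()
        tpl = build_template(grid, grid, SectioningModel())
        for j, D in enumerate(grid.representatives):
            mode_bin = int(np.argmax(tpl.matrix[:, j]))
            assert grid.lower_edges[mode_bin] < D <= grid.upper_edges[mode_bin]

    def test_enumerated_agrees_with_analytic(self):
        """1-nm enumerated cut levels converge on the closed form."""
        grid = default_grid()
        analytic = build_template(grid, grid, SectioningModel(section_step=1.0))
        enum = build_template(
            grid, grid, SectioningModel(section_step=1.0), method="enumerate"
        )
        # boundary quantisation error of midpoint enumeration is at most
        # ~2 cut levels per bin edge, i.e. 2/(D/step) per column
        n_steps = grid.representatives / 1.0
        col_err = np.abs(analytic.matrix - enum.matrix).max(axis=0)
        assert np.all(col_err <= 2.0 / n_steps + 1e-12)
        # and for the larger spheres the agreement is tight in absolute terms
        assert col_err[grid.representatives >= 300].max() < 0.007

    def test_detection_floor_truncates_and_renormalises(self):
        grid = default_grid()
        tpl = build_template(
            grid, grid, SectioningModel(min_detectable_diameter=70.0)
        )
        sums = tpl.matrix.sum(axis=0)
        live = grid.representatives > 70.0
        np.testing.assert_allclose(sums[live], 1.0, atol=1e-9)
        assert np.all(sums[~live] == 0.0)
        assert np.all(tpl.truncated_mass[~live] == 1.0)
        # truncated mass for D=500 is CDF(70; 500)
        j = list(grid.representatives).index(500.0)
        assert tpl.truncated_mass[j] == pytest.approx(
            apparent_cdf(70.0, 500.0), abs=1e-12
        )

    def test_apparent_grid_must_cover_true_range(self):
        grid = default_grid()
        with pytest.raises(ValueError):
            build_template(grid, np.arange(0.0, 500.0, 25.0), SectioningModel())

    def test_csv_round_trip(self, tmp_path):
        grid = default_grid()
        tpl = build_template(grid, grid, SectioningModel())
        path = tmp_path / "template.csv"
        tpl.to_csv(path)
        back = type(tpl).from_csv(path)
        np.testing.assert_allclose(back.matrix, tpl.matrix, atol=1e-10)
        assert back.true_grid == tpl.true_grid


class TestSampler:
    def test_mean_law(self):
        """Empirical mean of sections approaches (pi/4) * D."""
        grid = default_grid()
        sample = sample_sections(
            delta_weights(grid, 500.0), 100_000, SectioningModel(rng_seed=3)
        )
        se = sample.diameters.std() / np.sqrt(len(sample))
        assert abs(sample.diameters.mean() - np.pi / 4 * 500.0) < 3 * se

    def test_no_magnification(self):
        grid = default_grid()
        w = PopulationWeights(grid, np.ones(grid.n_bins))
        sample = sample_sections(w, 20_000, SectioningModel(rng_seed=5))
        assert sample.diameters.max() <= grid.bin_edges[-1]

    def test_seeded_determinism(self):
        grid = default_grid()
        w = delta_weights(grid, 300.0)
        a = sample_sections(w, 1000, SectioningModel(rng_seed=11))
        b = sample_sections(w, 1000, SectioningModel(rng_seed=11))
        np.testing.assert_array_equal(a.diameters, b.diameters)
        assert a.n_discarded == b.n_discarded

    def test_detection_floor_discards_are_counted(self):
        grid = default_grid()
        sample = sample_sections(
            delta_weights(grid, 300.0),
            50_000,
            SectioningModel(min_detectable_diameter=70.0, rng_seed=1),
        )
        assert sample.diameters.min() >= 70.0
        # discard fraction should approximate CDF(70; 300) = 1 - sqrt(1-(7/30)^2)
        frac = sample.n_discarded / (sample.n_discarded + len(sample))
        assert frac == pytest.approx(apparent_cdf(70.0, 300.0), abs=0.005)

    def test_errors(self):
        grid = default_grid()
        with pytest.raises(ValueError):
            sample_sections(delta_weights(grid, 300.0), 0)
        with pytest.raises(ValueError):
            sample_sections(PopulationWeights(grid, np.zeros(grid.n_bins)), 10)

    def test_histogram_norm_guard(self):
        grid = default_grid()
        with pytest.raises(ValueError):
            ApparentHistogram(grid, np.zeros(grid.n_bins)).frequencies
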