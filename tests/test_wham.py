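import numpy as np
import pytest

from prebound import wham
from prebound.synthetic_data import generate_umbrella_samples

KT = wham.KB_KJ_PER_MOL_K * 300.0


def double_well(xi, barrier=12.0, offset=2.0, width=0.05):
    xi = np.asarray(xi, dtype=float)
    return (
        -barrier * np.exp(-((xi - 0.30) ** 2) / (2 * width**2))
        - (barrier - offset) * np.exp(-((xi - 0.60) ** 2) / (2 * width**2))
    )


def quadratic(xi):
    return 50.0 * (np.asarray(xi, float) - 0.45) ** 2


def flat(xi):
    return np.zeros_like(np.asarray(xi, float))


#: population SD over m leave-one-out combinations -> jackknife standard error
JACKKNIFE_SCALE = (5 - 1) / np.sqrt(5)


@pytest.fixture(scope="module")
def double_well_windows():
    return generate_umbrella_samples(
        double_well, wham.DEFAULT_WINDOW_CENTERS, wham.DEFAULT_FORCE_CONSTANT,
        n_per_window=4000, seed=3,
    )


class TestWindowTypes:
    def test_window_needs_samples(self):
        with pytest.raises(ValueError):
            wham.UmbrellaWindow(0.3, samples=np.array([0.3]))

    def test_centers_must_increase(self):
        w = [wham.UmbrellaWindow(c, samples=np.array([c, c])) for c in (0.3, 0.3)]
        with pytest.raises(ValueError):
            wham.WindowSet(w)

    def test_non_overlapping_windows_error_lists_gap(self):
        w1 = wham.UmbrellaWindow(0.30, samples=np.array([0.29, 0.30, 0.31]))
        w2 = wham.UmbrellaWindow(0.60, samples=np.array([0.59, 0.60, 0.61]))
        with pytest.raises(wham.WhamError, match="0.3"):
            wham.binless_wham(wham.WindowSet([w1, w2]))


class TestBinlessWham:
    def test_quadratic_potential_recovered(self):
        """G matches the planted quadratic up to a constant within statistical error."""
        windows = generate_umbrella_samples(
            quadratic, wham.DEFAULT_WINDOW_CENTERS, wham.DEFAULT_FORCE_CONSTANT,
            n_per_window=4000, seed=6,
        )
        mean, _ = wham.bootstrap_pmf(windows)
        truth = quadratic(mean.xi)
        truth -= truth[np.isfinite(mean.g_kjmol)].min()
        mask = np.isfinite(mean.g_kjmol) & (mean.xi >= 0.25) & (mean.xi <= 0.70)
        max_err = np.max(np.abs(mean.g_kjmol[mask] - truth[mask]))
        se = JACKKNIFE_SCALE * np.nanmax(mean.sd_kjmol[mask])
        assert max_err < 3.0 * se

    def test_flat_landscape_stays_flat(self):
        windows = generate_umbrella_samples(
            flat, wham.DEFAULT_WINDOW_CENTERS, wham.DEFAULT_FORCE_CONSTANT,
            n_per_window=4000, seed=4,
        )
        mean, _ = wham.bootstrap_pmf(windows)
        finite = np.isfinite(mean.g_kjmol)
        assert np.nanmax(mean.g_kjmol[finite]) < 3.0 * np.nanmax(mean.sd_kjmol[finite])

    def test_double_well_barrier_recovered(self, double_well_windows):
        mean, profiles = wham.bootstrap_pmf(double_well_windows)
        report = wham.barrier_and_minima(mean)
        barriers = [
            wham.barrier_and_minima(p).barrier_height_kjmol for p in profiles
        ]
        sd = float(np.std(barriers))
        fine = np.linspace(0.2, 0.75, 5001)
        truth = wham.barrier_and_minima(
            wham.PMFProfile(fine, double_well(fine) - double_well(fine).min())
        ).barrier_height_kjmol
        assert report.barrier_height_kjmol == pytest.approx(truth, abs=3 * sd)

    def test_profile_minimum_is_zero(self, double_well_windows):
        profile = wham.binless_wham(double_well_windows)
        assert np.nanmin(profile.g_kjmol) == pytest.approx(0.0, abs=1e-12)

    def test_window_permutation_leaves_profile_unchanged(self, double_well_windows):
        profile = wham.binless_wham(double_well_windows)
        # permute then let WindowSet ordering constraints re-sort explicitly
        reversed_windows = list(reversed(double_well_windows.windows))
        reordered = wham.WindowSet(sorted(reversed_windows, key=lambda w: w.center),
                                   double_well_windows.temperature)
        profile2 = wham.binless_wham(reordered)
        np.testing.assert_array_equal(profile.g_kjmol, profile2.g_kjmol)

    def test_single_nearly_unbiased_window_reduces_to_log_histogram(self, rng):
        # weak bias: WHAM should reproduce -kT ln(histogram) up to a constant
        samples = rng.normal(0.45, 0.03, size=4000)
        window = wham.UmbrellaWindow(0.45, force_constant=1e-6, samples=samples)
        ws = wham.WindowSet([window])
        grid = np.linspace(0.35, 0.55, 41)
        profile = wham.binless_wham(ws, grid=grid, bandwidth=None)
        edges = np.concatenate([[grid[0] - 0.0025], grid[:-1] + 0.0025, [grid[-1] + 0.0025]])
        hist, _ = np.histogram(samples, bins=edges, density=True)
        with np.errstate(divide="ignore"):
            reference = -KT * np.log(hist)
        mask = np.isfinite(profile.g_kjmol) & np.isfinite(reference) & (hist * samples.size * 0.005 > 20)
        diff = profile.g_kjmol[mask] - reference[mask]
        assert np.ptp(diff) < 0.05  # constant offset only, within binning noise


class TestBootstrap:
    def test_two_segments_sd_is_half_absolute_difference(self, double_well_windows):
        mean, profiles = wham.bootstrap_pmf(
            double_well_windows, wham.BootstrapScheme(n_segments=2)
        )
        a, b = profiles[0].g_kjmol, profiles[1].g_kjmol
        mask = np.isfinite(a) & np.isfinite(b)
        np.testing.assert_allclose(
            mean.sd_kjmol[mask], np.abs(a - b)[mask] / 2.0, atol=1e-10
        )

    def test_identical_segments_give_zero_sd(self):
        block = np.linspace(0.40, 0.50, 60)
        samples = np.tile(block, 5)
        windows = [
            wham.UmbrellaWindow(0.45, samples=samples),
            wham.UmbrellaWindow(0.46, samples=samples + 0.01),
        ]
        mean, _ = wham.bootstrap_pmf(wham.WindowSet(windows))
        finite = np.isfinite(mean.sd_kjmol)
        assert np.nanmax(mean.sd_kjmol[finite]) == pytest.approx(0.0, abs=1e-9)

    def test_sd_shrinks_with_sampling(self):
        sds = []
        for n in (400, 3200):
            windows = generate_umbrella_samples(
                flat, (0.40, 0.45, 0.50), wham.DEFAULT_FORCE_CONSTANT, n_per_window=n, seed=8
            )
            mean, _ = wham.bootstrap_pmf(windows)
            center = np.abs(mean.xi - 0.45) < 0.03
            sds.append(np.nanmean(mean.sd_kjmol[center]))
        assert sds[1] < sds[0]

    def test_short_segments_error(self):
        windows = [
            wham.UmbrellaWindow(0.45, samples=np.linspace(0.4, 0.5, 20)),
            wham.UmbrellaWindow(0.46, samples=np.linspace(0.41, 0.51, 20)),
        ]
        with pytest.raises(wham.WhamError, match="segment"):
            wham.bootstrap_pmf(wham.WindowSet(windows), wham.BootstrapScheme(n_segments=5))


class TestBarrierAndMinima:
    def test_analytic_double_well_exact_on_fine_grid(self):
        fine = np.linspace(0.2, 0.75, 20001)
        g = double_well(fine)
        g -= g.min()
        report = wham.barrier_and_minima(wham.PMFProfile(fine, g))
        assert report.xi_min_bound == pytest.approx(0.30, abs=1e-3)
        assert report.xi_min_prebound == pytest.approx(0.60, abs=1e-3)
        interior = (fine > report.xi_min_bound) & (fine < report.xi_min_prebound)
        assert report.barrier_height_kjmol == pytest.approx(
            g[interior].max() - report.g_min_bound, abs=1e-9
        )

    def test_single_well_reports_no_barrier(self):
        fine = np.linspace(0.2, 0.75, 2001)
        g = quadratic(fine)
        g -= g.min()
        report = wham.barrier_and_minima(wham.PMFProfile(fine, g))
        assert not report.has_barrier
        assert report.barrier_height_kjmol is None

    def test_region_defaults_bracket_study_minima(self, double_well_windows):
        mean, _ = wham.bootstrap_pmf(double_well_windows)
        report = wham.barrier_and_minima(mean)
        assert 0.25 <= report.xi_min_bound <= 0.45
        assert 0.50 <= report.xi_min_prebound <= 0.70
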