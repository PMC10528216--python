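"""Mass-photometry histogramming, Gaussian peak fitting and windowed counting."""

import numpy as np
import pytest

from secmp.errors import DomainError, InsufficientDataError, ParseError
from secmp.mp_analysis import (
    GaussianPeakFit,
    MassWindow,
    MPRun,
    count_in_window,
    detect_and_fit_peaks,
    fraction_full,
    full_window,
    genome_mass_from_peaks,
    histogram,
    is_homogeneous,
    load_mp_events,
    replicate_summary,
)
from secmp.simulate import write_mp_events

TEN_MASSES = [3500.0, 4000.0, 5200.0, 5300.0, 5350.0, 6500.0, 2000.0, 5000.0, 4900.0, 5120.0]


def make_fit(mu, sigma, count=1000):
    return GaussianPeakFit(
        mu=mu, sigma=sigma, count=count, fit_window=MassWindow(mu - 500, mu + 500), redchi=1.0
    )


class TestLoad:
    def test_single_column_csv(self, tmp_path):
        p = tmp_path / "mp.csv"
        p.write_text("mass_kDa\n" + "\n".join(str(m) for m in TEN_MASSES) + "\n")
        run = load_mp_events(p)
        assert len(run) == 10

    def test_simulator_round_trip(self, tmp_path):
        run = MPRun(masses=np.array(TEN_MASSES))
        p = tmp_path / "mp.csv"
        write_mp_events(run, p)
        back = load_mp_events(p)
        np.testing.assert_allclose(back.masses, run.masses, rtol=1e-9)

    def test_mda_column_converted(self, tmp_path):
        p = tmp_path / "mp.csv"
        p.write_text("mass_MDa\n3.76\n4.60\n")
        run = load_mp_events(p)
        np.testing.assert_allclose(run.masses, [3760.0, 4600.0])

    def test_non_numeric_row_has_line_number(self, tmp_path):
        p = tmp_path / "mp.csv"
        p.write_text("mass_kDa\n3500\nnope\n4000\n")
        with pytest.raises(ParseError) as err:
            load_mp_events(p)
        assert err.value.line == 3

    def test_empty_file_rejected(self, tmp_path):
        p = tmp_path / "mp.csv"
        p.write_text("mass_kDa\n")
        with pytest.raises(ParseError, match="no events"):
            load_mp_events(p)


class TestHistogram:
    def test_no_overlap_gives_zero_bins(self):
        run = MPRun(masses=np.array([100.0, 200.0]))
        _, counts = histogram(run, 25.0, MassWindow(3000, 6000))
        assert counts.sum() == 0

    def test_count_conservation(self, rng):
        masses = rng.uniform(1000, 8000, size=500)
        run = MPRun(masses=masses)
        win = MassWindow(3000, 6000)
        _, counts = histogram(run, 37.0, win)
        brute = int(np.sum((masses >= 3000) & (masses <= 6000)))
        assert counts.sum() == brute

    def test_bin_edge_event_counted_once(self):
        run = MPRun(masses=np.array([3025.0]))  # exactly on an interior edge
        _, counts = histogram(run, 25.0, MassWindow(3000, 6000))
        assert counts.sum() == 1
        assert counts[1] == 1  # half-open: goes to the bin starting at the edge


class TestPeakFitting:
    def test_single_gaussian_recovered(self, rng):
        masses = rng.normal(3760, 135, size=10_000)
        fits = detect_and_fit_peaks(MPRun(masses=masses), MassWindow(3000, 6000))
        assert len(fits) == 1
        (fit,) = fits
        se = 135 / np.sqrt(10_000)
        assert abs(fit.mu - 3760) < 3 * se + 5  # binning granularity allowance
        assert fit.sigma == pytest.approx(135, rel=0.10)
        assert fit.count == pytest.approx(10_000, rel=0.05)

    def test_two_component_mixture_recovered(self, rng):
        masses = np.concatenate(
            [rng.normal(3760, 135, size=5000), rng.normal(4600, 110, size=5000)]
        )
        fits = detect_and_fit_peaks(MPRun(masses=masses), MassWindow(3000, 6000))
        assert len(fits) == 2
        se = 135 / np.sqrt(5000)
        assert abs(fits[0].mu - 3760) < 3 * se + 5
        assert abs(fits[1].mu - 4600) < 3 * se + 5
        assert fits[0].mu < fits[1].mu  # sorted by mass

    def test_flat_distribution_yields_no_peaks(self, rng):
        masses = rng.uniform(3000, 6000, size=10_000)
        fits = detect_and_fit_peaks(MPRun(masses=masses), MassWindow(3000, 6000))
        assert fits == []

    def test_too_few_events_rejected(self, rng):
        masses = rng.normal(4600, 110, size=20)
        with pytest.raises(InsufficientDataError, match="20 events"):
            detect_and_fit_peaks(MPRun(masses=masses), MassWindow(3000, 6000))

    def test_convergence_with_event_count(self, rng):
        errs = []
        for n in (1000, 10_000):
            masses = rng.normal(4600, 110, size=n)
            (fit,) = detect_and_fit_peaks(MPRun(masses=masses), MassWindow(3000, 6000))
            errs.append(abs(fit.sigma - 110))
        assert errs[1] < errs[0]


class TestHomogeneity:
    @pytest.mark.parametrize(
        "sigma,expected", [(135.0, True), (110.0, True), (150.0, True), (150.1, False)]
    )
    def test_sigma_threshold_inclusive(self, sigma, expected):
        assert is_homogeneous(make_fit(4600, sigma)) is expected


class TestCounting:
    @pytest.mark.parametrize(
        "window,expected", [(MassWindow(5100, 5400), 4), (MassWindow(3000, 6000), 8)]
    )
    def test_hand_enumeration(self, window, expected):
        assert count_in_window(MPRun(masses=np.array(TEN_MASSES)), window) == expected

    def test_matches_brute_force_on_random_runs(self, rng):
        for _ in range(100):
            masses = rng.uniform(0, 10_000, size=rng.integers(1, 300))
            lo = rng.uniform(0, 9000)
            hi = lo + rng.uniform(10, 1000)
            run = MPRun(masses=masses)
            brute = sum(1 for m in masses if lo <= m <= hi)
            assert count_in_window(run, MassWindow(lo, hi)) == brute

    def test_fraction_full_hand_case(self):
        run = MPRun(masses=np.array(TEN_MASSES))
        frac, counts = fraction_full(run, m_theory=5250.0)
        assert frac == 0.5
        assert (counts.n_full, counts.n_total) == (4, 8)

    def test_full_window_construction(self):
        win = full_window(5250.0, 150.0)
        assert (win.lo, win.hi) == (5100.0, 5400.0)

    def test_all_events_at_theory_mass(self):
        run = MPRun(masses=np.full(20, 5250.0))
        frac, _ = fraction_full(run, 5250.0)
        assert frac == 1.0

    def test_invariant_under_shuffle_and_out_of_window_events(self, rng):
        masses = rng.normal(5000, 400, size=500)
        run = MPRun(masses=masses)
        frac, _ = fraction_full(run, 5250.0)
        shuffled = masses.copy()
        rng.shuffle(shuffled)
        extra = np.concatenate([shuffled, [100.0, 9000.0, 15_000.0]])
        frac2, _ = fraction_full(MPRun(masses=extra), 5250.0)
        assert frac2 == frac

    def test_empty_total_window_rejected(self):
        run = MPRun(masses=np.array([100.0]))
        with pytest.raises(InsufficientDataError):
            fraction_full(run, 5250.0)

    def test_non_nested_window_rejected(self):
        run = MPRun(masses=np.array(TEN_MASSES))
        with pytest.raises(DomainError, match="nested"):
            fraction_full(run, 5950.0)


class TestReplicates:
    @pytest.mark.parametrize(
        "fractions,mean,sd",
        [
            ([0.5, 0.5, 0.5], 0.5, 0.0),
            ([0.1, 0.2], 0.15, 0.07071067811865477),
        ],
    )
    def test_mean_and_sample_sd(self, fractions, mean, sd):
        got_mean, got_sd = replicate_summary(fractions)
        assert got_mean == pytest.approx(mean)
        assert got_sd == pytest.approx(sd)

    def test_single_replicate_has_no_sd(self):
        assert replicate_summary([0.3]) == (0.3, None)

    def test_empty_rejected(self):
        with pytest.raises(DomainError):
            replicate_summary([])


class TestGenomeMassFromPeaks:
    def test_full_minus_empty(self):
        mass = genome_mass_from_peaks(make_fit(4600, 110), make_fit(3760, 135))
        assert mass == pytest.approx(840_000.0)

    def test_equal_means_rejected(self):
        with pytest.raises(DomainError):
            genome_mass_from_peaks(make_fit(4600, 110), make_fit(4600, 135))

    def test_simulated_mixture_recovery(self, rng):
        genome_kda = 840.0
        masses = np.concatenate(
            [rng.normal(3760, 120, size=5000), rng.normal(3760 + genome_kda, 120, size=5000)]
        )
        fits = detect_and_fit_peaks(MPRun(masses=masses), MassWindow(3000, 6000))
        assert len(fits) == 2
        got = genome_mass_from_peaks(fits[1], fits[0])
        se_da = 120.0 / np.sqrt(5000) * 1000 * np.sqrt(2)
        assert abs(got - 840_000.0) < 3 * se_da + 10_000  # binning allowance
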