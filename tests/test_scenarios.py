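"""Scenario classification, per-branch titer reports and mixture arithmetic."""

import numpy as np
import pytest

from secmp import simulate as sim
from secmp.errors import ConfigurationError, DomainError, InsufficientDataError
from secmp.mp_analysis import GaussianPeakFit, MassWindow, WindowCounts
from secmp.scenarios import (
    GenomeSpec,
    analyze_scenario1,
    analyze_scenario2,
    analyze_scenario3,
    classify_scenario,
    mixture_expectation,
)
from secmp.uv_quant import AVOGADRO, UVQuantResult, genome_size_from_mass, round_sig


def make_fit(mu, sigma):
    return GaussianPeakFit(
        mu=mu, sigma=sigma, count=1000, fit_window=MassWindow(mu - 500, mu + 500), redchi=1.0
    )


def make_uv(cp_per_ml, genome_mass_da):
    c_cap = cp_per_ml * 1000.0 / AVOGADRO
    w_dna = c_cap * genome_mass_da
    return UVQuantResult(
        c_cap=c_cap,
        w_dna=w_dna,
        cp_per_ml=cp_per_ml,
        genome_mass_da=genome_mass_da,
        genome_size_knt=genome_size_from_mass(genome_mass_da),
    )


class TestClassification:
    def test_single_narrow_peak_is_scenario1(self):
        call = classify_scenario([make_fit(4600, 110)])
        assert call.scenario == 1

    def test_two_narrow_peaks_is_scenario2(self):
        call = classify_scenario([make_fit(3760, 135), make_fit(4600, 110)])
        assert call.scenario == 2

    @pytest.mark.parametrize(
        "fits",
        [
            [make_fit(4200, 300)],  # single broad peak
            [make_fit(3760, 135), make_fit(4600, 180)],  # one broad of two
            [make_fit(3760, 120), make_fit(4300, 120), make_fit(4900, 120)],  # >2 modes
            [],  # events present but no accepted mode
        ],
    )
    def test_everything_else_is_scenario3(self, fits):
        assert classify_scenario(fits, n_events=5000).scenario == 3

    def test_no_events_rejected(self):
        with pytest.raises(InsufficientDataError):
            classify_scenario([], n_events=0)

    def test_classification_is_total(self, rng):
        # any list of valid fits maps to exactly one scenario
        for _ in range(50):
            n = rng.integers(0, 5)
            fits = [make_fit(rng.uniform(3000, 6000), rng.uniform(50, 400)) for _ in range(n)]
            assert classify_scenario(fits, n_events=1000).scenario in (1, 2, 3)


class TestScenario1:
    def test_empty_capsids_have_zero_effective_titer(self):
        rep = analyze_scenario1(make_uv(2.40e12, 0.0))
        assert rep.genome_size_knt == 0.0
        assert rep.effective_titer == 0.0
        assert any("empty" in n for n in rep.notes)

    def test_full_capsids_effective_titer_equals_total(self):
        rep = analyze_scenario1(make_uv(1.14e13, 839_202.1))
        assert rep.effective_titer == rep.cp_per_ml
        assert rep.genome_size_knt == pytest.approx(2.763, abs=1e-6)
        assert round_sig(rep.genome_size_knt, 2) == 2.8

    def test_genome_mismatch_flagged(self):
        rep = analyze_scenario1(
            make_uv(1e13, 839_202.1), expected=GenomeSpec(n_nt=4787), genome_tol_knt=0.1
        )
        assert any("differs" in w for w in rep.warnings)

    def test_zero_capsid_rejected(self):
        uv = UVQuantResult(
            c_cap=0.0, w_dna=0.0, cp_per_ml=0.0, genome_mass_da=0.0, genome_size_knt=0.0
        )
        with pytest.raises(DomainError, match="c_cap"):
            analyze_scenario1(uv)


class TestScenario2:
    GENOME = GenomeSpec(m_genome_da=839_202.1)

    @pytest.mark.parametrize("occupancy", [0.0, 0.83, 1.0])
    def test_dna_mass_balance(self, occupancy):
        uv = make_uv(6.9e12, occupancy * self.GENOME.m_genome_da)
        rep = analyze_scenario2(uv, self.GENOME)
        assert rep.percent_full == pytest.approx(occupancy, abs=1e-12)
        assert rep.effective_titer == pytest.approx(uv.cp_per_ml * occupancy)

    def test_above_unity_flagged_not_clamped(self):
        uv = make_uv(7.01e12, 1.36 * self.GENOME.m_genome_da)
        rep = analyze_scenario2(uv, self.GENOME)
        assert rep.percent_full == pytest.approx(1.36)
        assert any("exceeds 100%" in w for w in rep.warnings)

    def test_missing_genome_spec_rejected(self):
        with pytest.raises(ConfigurationError):
            analyze_scenario2(make_uv(1e13, 8e5), GenomeSpec())


class TestScenario3:
    def make_counts(self, n_full, n_total):
        return WindowCounts(
            n_full=n_full,
            n_total=n_total,
            full_window=MassWindow(5100, 5400),
            total_window=MassWindow(3000, 6000),
        )

    def test_heterogeneous_sample_titer(self):
        # counting fraction 8.70% on 4.08e12 Cp/mL total capsids
        uv = make_uv(4.08e12, 5e5)
        rep = analyze_scenario3(uv, 0.0870, self.make_counts(870, 10_000))
        assert round_sig(rep.effective_titer, 3) == 3.55e11

    def test_zero_fraction_gives_zero_titer(self):
        uv = make_uv(4.08e12, 5e5)
        rep = analyze_scenario3(uv, 0.0, self.make_counts(0, 10_000))
        assert rep.effective_titer == 0.0

    def test_occupancy_reported_with_caveat(self):
        uv = make_uv(4.08e12, 0.4 * 839_202.1)
        rep = analyze_scenario3(
            uv, 0.087, self.make_counts(870, 10_000), genome=GenomeSpec(m_genome_da=839_202.1)
        )
        assert rep.dna_occupancy == pytest.approx(0.4)
        assert any("occupancy" in n.lower() for n in rep.notes)

    def test_effective_titer_monotone_in_both_factors(self):
        base = analyze_scenario3(make_uv(4e12, 5e5), 0.10, self.make_counts(1000, 10_000))
        more_cp = analyze_scenario3(make_uv(5e12, 5e5), 0.10, self.make_counts(1000, 10_000))
        more_full = analyze_scenario3(make_uv(4e12, 5e5), 0.15, self.make_counts(1500, 10_000))
        assert more_cp.effective_titer > base.effective_titer
        assert more_full.effective_titer > base.effective_titer


class TestMixtureExpectation:
    def test_equal_volume_empty_full_mixture(self):
        cp, frac = mixture_expectation(
            [(2.40e12, 0.5, False), (1.14e13, 0.5, True)]
        )
        assert round_sig(cp, 2) == 6.9e12
        assert round(100 * frac) == 83

    def test_single_component_passthrough(self):
        cp, frac = mixture_expectation([(5e12, 1.0, True)])
        assert cp == 5e12 and frac == 1.0

    def test_fractions_must_sum_to_one(self):
        with pytest.raises(DomainError, match="sum"):
            mixture_expectation([(1e12, 0.6, True), (1e12, 0.3, False)])


class TestCrossMethodConsistency:
    def test_counting_and_mass_balance_agree_for_two_species(self):
        """For a clean empty+full mixture the counting %full (branch 3) and
        the DNA-mass %full (branch 2) agree within 3 percentage points."""
        genome = 839_202.1
        mix = sim.SpeciesMix(
            species=(
                sim.Species("empty", "capsid", 3760.0, 0.0, 1.2e12, 8.5, 0.15),
                sim.Species(
                    "full", "capsid", 3760.0 + genome / 1000, genome, 5.7e12, 8.5, 0.15, full=True
                ),
            )
        )
        truth = sim.ground_truth(mix)
        noise = sim.NoiseModel(seed=7)
        run = sim.simulate_mp_events(mix, 10_000, noise)
        from secmp.mp_analysis import fraction_full

        frac, _ = fraction_full(run, 3760.0 + genome / 1000, half_width=350.0)
        uv = make_uv(truth.total_cp_per_ml, truth.w_dna_mg_per_ml / truth.c_cap_mol_per_l)
        rep2 = analyze_scenario2(uv, GenomeSpec(m_genome_da=genome))
        assert abs(frac - rep2.percent_full) < 0.03
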