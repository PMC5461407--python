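"""Population simulator: schedules, averages, runouts, coverage, foci."""

import math

import numpy as np
import pytest
from scipy import integrate

from corycycle.cycle_core import (
    CellCycleParams,
    CycleModelError,
    mean_dna_content,
    mean_oris,
    mean_ters,
    predicted_ori_ter_ratio,
)
from corycycle.popsim import (
    CohesionModel,
    age_cdf,
    age_pdf,
    cell_state_at_age,
    locus_copy_number,
    marker_frequency_profile,
    mean_age,
    observed_focus_counts,
    relative_copy_number,
    runout_histogram,
    sample_ages,
    sample_population,
)


class TestAgeDistribution:
    def test_cdf_endpoints_and_midpoint(self):
        td = 63.0
        assert age_cdf(0.0, td) == 0.0
        assert age_cdf(td, td) == pytest.approx(1.0)
        assert age_cdf(td / 2, td) == pytest.approx(2.0 * (1.0 - 1.0 / math.sqrt(2)), abs=1e-12)
        assert age_cdf(td / 2, td) == pytest.approx(0.5858, abs=1e-4)

    def test_pdf_integrates_to_one(self):
        td = 97.0
        val, _ = integrate.quad(lambda a: age_pdf(a, td), 0, td)
        assert val == pytest.approx(1.0, rel=1e-8)

    def test_mean_age(self):
        td = 63.0
        val, _ = integrate.quad(lambda a: a * age_pdf(a, td), 0, td)
        assert val == pytest.approx(mean_age(td), rel=1e-8)
        assert mean_age(td) == pytest.approx(0.4427 * td, rel=1e-3)

    def test_domain(self):
        with pytest.raises(CycleModelError):
            age_pdf(-1.0, 63.0)
        with pytest.raises(CycleModelError):
            age_cdf(64.0, 63.0)

    def test_sampling_matches_mean(self):
        ages = sample_ages(100_000, 63.0, np.random.default_rng(7))
        assert ages.min() >= 0 and ages.max() < 63.0
        assert ages.mean() == pytest.approx(27.89, rel=5e-3)

    def test_sampling_reproducible(self):
        a = sample_ages(100, 63.0, np.random.default_rng(3))
        b = sample_ages(100, 63.0, np.random.default_rng(3))
        np.testing.assert_array_equal(a, b)


class TestCellState:
    def test_fast_growth_newborn(self, bhi_params):
        s = cell_state_at_age(0.0, bhi_params)
        assert (s.ori_count, s.ter_count) == (4, 2)
        assert len(s.fork_rounds) == 1
        assert s.fork_rounds[0].fraction == pytest.approx(35.0 / 78.0)
        assert s.dna_content == pytest.approx(2.90, abs=0.01)

    def test_slow_growth_newborn_has_b_period(self, mmi_params):
        s = cell_state_at_age(0.0, mmi_params)
        assert (s.ori_count, s.ter_count) == (2, 2)
        assert s.fork_rounds == ()
        assert s.dna_content == 2.0

    def test_fast_growth_after_both_events(self, bhi_params):
        s = cell_state_at_age(50.0, bhi_params)
        assert (s.ori_count, s.ter_count) == (8, 4)
        assert s.fork_rounds[0].fraction == pytest.approx(22.0 / 78.0)
        assert s.dna_content == pytest.approx(2 * 2 * (1 + 22.0 / 78.0))

    def test_overlap_window_has_two_rounds(self, bhi_params):
        s = cell_state_at_age(30.0, bhi_params)
        fr = sorted(r.fraction for r in s.fork_rounds)
        assert len(fr) == 2
        assert fr[0] == pytest.approx(2.0 / 78.0)      # just-initiated round
        assert fr[1] == pytest.approx(65.0 / 78.0)     # round from mother

    def test_dna_doubles_over_one_generation(self):
        # conservation at division for several parameter sets
        for td, c, d in [(63, 78, 20), (130, 97, 26), (83, 96, 18), (100, 70, 30)]:
            p = CellCycleParams(td, c, d)
            end = np.nextafter(float(td), 0.0)
            ratio = cell_state_at_age(end, p).dna_content / cell_state_at_age(0.0, p).dna_content
            assert ratio == pytest.approx(2.0, rel=1e-9)

    def test_copy_numbers_are_ploidy_powers_of_two(self, bhi_params):
        for a in np.linspace(0, 62.99, 40):
            s = cell_state_at_age(a, bhi_params)
            for count in (s.ori_count, s.ter_count):
                k = count / bhi_params.ploidy
                assert k == 2 ** int(math.log2(k))

    def test_age_domain(self, bhi_params):
        with pytest.raises(CycleModelError):
            cell_state_at_age(63.0, bhi_params)


class TestPopulationAverages:
    N = 40_000

    def test_monte_carlo_matches_closed_forms(self, bhi_params):
        snap = sample_population(self.N, bhi_params, seed=11)
        tol = 3.0 / math.sqrt(self.N)
        assert snap.ori_counts.mean() == pytest.approx(mean_oris(78, 20, 63), rel=tol)
        assert snap.ter_counts.mean() == pytest.approx(mean_ters(20, 63), rel=tol)
        assert snap.dna_contents.mean() == pytest.approx(mean_dna_content(bhi_params), rel=tol)

    def test_monoploid_matches_numerical_integration(self):
        # ploidy=1 degenerates to the classic monoploid model; integrate
        # the per-age state against the age density as independent oracle
        p = CellCycleParams(td=60.0, c=45.0, d=20.0, ploidy=1)
        for attr, closed in [
            ("ori_count", mean_oris(45, 20, 60, 1)),
            ("ter_count", mean_ters(20, 60, 1)),
            ("dna_content", mean_dna_content(p)),
        ]:
            val, _ = integrate.quad(
                lambda a: getattr(cell_state_at_age(a, p), attr) * age_pdf(a, p.td),
                0.0, p.td, limit=200, points=[15.0, 40.0],
            )
            assert val == pytest.approx(closed, rel=1e-6), attr

    def test_diploid_closed_forms_against_integration(self, mmi_params):
        val, _ = integrate.quad(
            lambda a: cell_state_at_age(a, mmi_params).dna_content
            * age_pdf(a, mmi_params.td),
            0.0, mmi_params.td, limit=200, points=[7.0, 104.0],
        )
        assert val == pytest.approx(mean_dna_content(mmi_params), rel=1e-6)


class TestRunout:
    def test_fast_growth_histogram(self, bhi_params):
        h = runout_histogram(bhi_params)
        assert set(h.counts) == {4, 8}
        assert h.counts[4] == pytest.approx(0.530, abs=5e-4)
        assert h.counts[8] == pytest.approx(0.470, abs=5e-4)
        assert h.mean == pytest.approx(5.88, abs=5e-3)

    def test_slow_growth_histogram(self, mmi_params):
        h = runout_histogram(mmi_params)
        assert h.counts[2] == pytest.approx(0.073, abs=5e-4)
        assert h.counts[4] == pytest.approx(0.927, abs=5e-4)
        assert h.mean == pytest.approx(3.85, abs=5e-3)

    def test_boundary_single_bar(self):
        h = runout_histogram(CellCycleParams(100, 70, 30))
        assert h.counts == {4: 1.0}

    def test_monte_carlo_agrees_with_analytic(self, bhi_params):
        n = 50_000
        mc = runout_histogram(bhi_params, mode="monte_carlo", n=n, seed=5)
        an = runout_histogram(bhi_params)
        assert set(mc.counts) == set(an.counts)
        for k, f in an.counts.items():
            se = math.sqrt(f * (1 - f) / n)
            assert abs(mc.counts[k] - f) < 4 * se


class TestCoverageProfile:
    def test_closed_form_values(self, bhi_params):
        assert relative_copy_number(1.0, bhi_params) == 1.0
        assert relative_copy_number(0.0, bhi_params) == pytest.approx(2.355, abs=5e-3)
        assert relative_copy_number(0.5, bhi_params) == pytest.approx(1.535, abs=5e-3)

    def test_endpoint_ratio_equals_predicted(self, bhi_params, mmi_params):
        for p in (bhi_params, mmi_params):
            r = relative_copy_number(0.0, p) / relative_copy_number(1.0, p)
            assert r == pytest.approx(predicted_ori_ter_ratio(p.c, p.td), rel=1e-12)

    def test_profile_symmetric_and_monotone(self):
        # window-aligned genome so mirror windows pair up exactly
        p = CellCycleParams(td=63, c=78, d=20, genome_length=3_200_000)
        prof = marker_frequency_profile(p, window_bp=50_000)
        v = prof.values
        np.testing.assert_allclose(v, v[::-1], rtol=1e-12)
        half = len(v) // 2
        assert np.all(np.diff(v[: half + 1]) <= 1e-12)  # ori -> ter non-increasing

    def test_percent_of_mean_normalization(self, bhi_params):
        prof = marker_frequency_profile(bhi_params, normalization="percent_of_mean")
        assert prof.values.mean() == pytest.approx(100.0)

    def test_monte_carlo_agrees_with_closed_form(self, bhi_params):
        snap = sample_population(4000, bhi_params, seed=2)
        mc = marker_frequency_profile(bhi_params, mode="monte_carlo", snapshot=snap)
        an = marker_frequency_profile(bhi_params)
        np.testing.assert_allclose(mc.values, an.values, rtol=0.05)

    def test_locus_copy_number_consistency(self, bhi_params):
        s = cell_state_at_age(30.0, bhi_params)
        assert locus_copy_number(0.0, s, 2) == s.ori_count
        assert locus_copy_number(1.0, s, 2) == s.ter_count

    def test_bedgraph_output(self, bhi_params, tmp_path):
        prof = marker_frequency_profile(bhi_params)
        path = tmp_path / "cov.bedGraph"
        prof.to_bedgraph(path)
        lines = path.read_text().strip().split("\n")
        assert len(lines) == len(prof.starts)
        chrom, start, end, value = lines[0].split("\t")
        assert (start, end) == ("0", "50000")
        assert float(value) > 2.0


class TestCohesionModel:
    def test_truncated_gamma_calibration(self):
        m = CohesionModel()
        t = m.sample(100_000, np.random.default_rng(1))
        assert t.min() >= 5.0 and t.max() <= 80.0
        assert t.mean() == pytest.approx(36.0, abs=0.3)

    def test_invalid_bounds(self):
        with pytest.raises(ValueError):
            CohesionModel(mean=100.0, minimum=5.0, maximum=80.0)


class TestObservedFoci:
    def test_zero_cohesion_shows_true_counts(self, bhi_params):
        snap = sample_population(500, bhi_params, seed=3)
        zero = CohesionModel(mean=0.0, minimum=0.0, maximum=0.0, family="fixed")
        obs = observed_focus_counts(snap, zero, channel="ori", seed=1)
        np.testing.assert_array_equal(obs, snap.ori_counts)

    def test_full_cohesion_shows_birth_counts(self, bhi_params):
        snap = sample_population(500, bhi_params, seed=3)
        full = CohesionModel(mean=100.0, minimum=100.0, maximum=100.0, family="fixed")
        obs = observed_focus_counts(snap, full, channel="ori", seed=1)
        # every pair from this generation's initiation is still merged
        birth = np.where(
            snap.ages >= 28.0, snap.ori_counts // 2, snap.ori_counts
        )
        np.testing.assert_array_equal(obs, birth)

    def test_default_model_between_bounds_with_odd_counts(self, bhi_params):
        snap = sample_population(10_000, bhi_params, seed=4)
        obs = observed_focus_counts(snap, CohesionModel(), channel="ori", seed=5)
        lower = np.where(snap.ages >= 28.0, snap.ori_counts // 2, snap.ori_counts)
        assert lower.mean() < obs.mean() < snap.ori_counts.mean()
        assert np.any(obs % 2 == 1)
        assert obs.min() >= bhi_params.ploidy

    def test_ter_channel_merging(self, bhi_params):
        snap = sample_population(2000, bhi_params, seed=6)
        never = CohesionModel(ter_merge_prob=0.0)
        always = CohesionModel(ter_merge_prob=1.0)
        obs_never = observed_focus_counts(snap, never, channel="ter", seed=7)
        obs_always = observed_focus_counts(snap, always, channel="ter", seed=7)
        np.testing.assert_array_equal(obs_never, snap.ter_counts)
        post = snap.ages >= 43.0
        np.testing.assert_array_equal(obs_always[post], snap.ter_counts[post] // 2)

    def test_unknown_channel(self, bhi_params):
        snap = sample_population(5, bhi_params, seed=1)
        with pytest.raises(ValueError):
            observed_focus_counts(snap, CohesionModel(), channel="replisome")
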