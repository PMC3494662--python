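"""Transmission statistics: frozen oracles, invariances, parameter recovery."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pms_pipeline.datatypes import AIRecord, TransmissionCounts
from pms_pipeline.simulate import (
    SimulationConfig,
    simulate_ai_records,
    simulate_birth_counts,
    simulate_sperm_counts,
)
from pms_pipeline.stats import (
    LethalityConfig,
    chi2_goodness_of_fit,
    chi2_independence_2x2,
    filter_ai_records,
    inheritance_report,
    lethality_from_birth_counts,
    lethality_window,
    mosaicism_from_sperm,
    stage_comparison,
    welch_t,
)

# the observed birth table: rows sex (F, M), columns status (horned/wt, polled/del)
BIRTH_TABLE = [[31, 14], [29, 2]]


class TestChi2Independence:
    def test_birth_table_statistic(self):
        # exact uncorrected Pearson value 6.7156 (printed as truncated 6.71)
        res = chi2_independence_2x2(BIRTH_TABLE)
        assert res.statistic == pytest.approx(6.7156, abs=5e-4)
        assert res.df == 1
        assert res.p < 0.01

    def test_perfect_independence_zero(self):
        assert chi2_independence_2x2([[10, 10], [10, 10]]).statistic == 0.0

    def test_diagonal_hand_value(self):
        # all expected cells 2.5; statistic = 4 * (2.5)^2/2.5 = 10
        assert chi2_independence_2x2([[5, 0], [0, 5]]).statistic == pytest.approx(10.0)

    def test_zero_marginal_error(self):
        with pytest.raises(ValueError, match="marginal"):
            chi2_independence_2x2([[0, 0], [5, 5]])

    @settings(derandomize=True, max_examples=50)
    @given(st.lists(st.integers(1, 100), min_size=4, max_size=4))
    def test_permutation_and_transpose_invariance(self, cells):
        a, b, c, d = cells
        base = chi2_independence_2x2([[a, b], [c, d]]).statistic
        for t in ([[b, a], [d, c]], [[c, d], [a, b]], [[a, c], [b, d]]):
            assert chi2_independence_2x2(t).statistic == pytest.approx(base)


class TestChi2GoodnessOfFit:
    def test_dominant_expectation_birth_counts(self):
        res = chi2_goodness_of_fit([31, 29, 14, 2], [0.25] * 4)
        assert res.statistic == pytest.approx(558 / 19)
        assert round(res.statistic, 2) == 29.37
        assert res.df == 3
        assert res.p < 0.0001

    def test_proportional_observed_zero(self):
        res = chi2_goodness_of_fit([40, 30, 20, 10], [0.4, 0.3, 0.2, 0.1])
        assert res.statistic == pytest.approx(0.0)

    def test_two_cell_hand_value(self):
        assert chi2_goodness_of_fit([8, 2], [0.5, 0.5]).statistic == pytest.approx(3.6)

    def test_zero_expected_cell_error(self):
        with pytest.raises(ValueError):
            chi2_goodness_of_fit([5, 5], [1.0, 0.0])

    @settings(derandomize=True, max_examples=50)
    @given(
        st.lists(st.integers(1, 50), min_size=2, max_size=6),
        st.integers(2, 10),
    )
    def test_zero_iff_proportional(self, obs, scale):
        props = np.asarray(obs) / sum(obs)
        assert chi2_goodness_of_fit(
            [o * scale for o in obs], props
        ).statistic == pytest.approx(0.0, abs=1e-9)


class TestStageComparison:
    def test_scaled_reference_zero(self):
        ref = TransmissionCounts.from_vector("sperm", [40, 20, 40, 20])
        obs = TransmissionCounts.from_vector("blastocyst", [80, 40, 80, 40])
        assert stage_comparison(obs, ref).statistic == pytest.approx(0.0)

    def test_hand_fixture(self):
        # expected (16, 12, 8, 4): 2.25 + 1/3 + 0.5 + 9 = 12.0833
        ref = TransmissionCounts.from_vector("sperm", [40, 30, 20, 10])
        obs = TransmissionCounts.from_vector("birth", [10, 10, 10, 10])
        res = stage_comparison(obs, ref)
        assert res.statistic == pytest.approx(12.0833, abs=1e-3)
        assert res.df == 3

    def test_zero_reference_cell_pools_by_carrier(self):
        ref = TransmissionCounts.from_vector("blastocyst", [50, 25, 50, 0])
        obs = TransmissionCounts.from_vector("birth", [40, 10, 40, 2])
        res = stage_comparison(obs, ref)
        assert res.df == 1  # pooled to wt vs del

    def test_simulated_qualitative_pattern(self):
        # power from the noncentral chi-square at the design sizes is ~0.80
        # at alpha = 0.05 for sperm-vs-birth; sperm-vs-blastocyst is null
        cfg = SimulationConfig()
        rng = np.random.default_rng(2024)
        ns_sb = sig_svb = 0
        n_rep = 200
        for _ in range(n_rep):
            sperm, _ = simulate_sperm_counts(cfg, rng)
            blasto = TransmissionCounts.from_vector(
                "blastocyst",
                rng.multinomial(cfg.n_blastocysts, sperm.as_vector() / sperm.total),
            )
            birth = simulate_birth_counts(
                cfg.n_progeny_birth, cfg.germline_mosaicism, cfg.male_lethality, rng
            )
            ns_sb += stage_comparison(blasto, sperm).p > 0.05
            sig_svb += stage_comparison(birth, sperm).p < 0.05
        assert ns_sb >= 0.85 * n_rep
        assert sig_svb >= 0.70 * n_rep


class TestWelchT:
    def test_identical_groups(self):
        res = welch_t(10.0, 2.0, 30, 10.0, 2.0, 30)
        assert res.statistic == 0.0
        assert res.p == pytest.approx(1.0)

    def test_epidermis_thickness_summaries(self):
        res = welch_t(15.8, 3.0, 100, 22.1, 3.7, 100)
        assert abs(res.statistic) == pytest.approx(13.226, abs=0.005)
        assert res.df == pytest.approx(189.87, abs=0.1)
        assert 1e-30 < res.p < 1e-26

    def test_equal_variance_equal_n_matches_pooled_t(self):
        # with n1 = n2 and sd1 = sd2 the Welch statistic equals Student's t
        m1, m2, sd, n = 5.0, 6.0, 1.5, 40
        res = welch_t(m1, sd, n, m2, sd, n)
        pooled_t = (m1 - m2) / (sd * np.sqrt(2 / n))
        assert res.statistic == pytest.approx(pooled_t)
        assert res.df == pytest.approx(2 * n - 2)

    def test_degenerate_inputs(self):
        with pytest.raises(ValueError):
            welch_t(1, 1.0, 1, 2, 1.0, 10)
        with pytest.raises(ValueError):
            welch_t(1, 0.0, 10, 2, 1.0, 10)


class TestMosaicism:
    @pytest.mark.parametrize("k,expected", [(33, 0.66), (35, 0.70)])
    def test_sperm_fish_point_estimates(self, k, expected):
        est = mosaicism_from_sperm(k, 100)
        assert est.mosaicism == pytest.approx(expected)

    def test_zero_carriers(self):
        est = mosaicism_from_sperm(0, 100)
        assert est.mosaicism == 0.0
        assert est.ci_low == 0.0

    def test_cap_at_one(self):
        assert mosaicism_from_sperm(90, 100).mosaicism == 1.0

    def test_ci_contains_point_estimate(self):
        for k in (1, 33, 50, 99):
            est = mosaicism_from_sperm(k, 100)
            assert est.ci_low <= est.mosaicism <= est.ci_high

    def test_doubled_clopper_pearson_coverage(self):
        # coverage of the doubled interval for the mosaicism parameter
        rng = np.random.default_rng(5)
        n_draws, n = 2000, 100
        covered = 0
        for _ in range(n_draws):
            m = rng.uniform(0.0, 1.0)
            k = rng.binomial(n, m / 2)
            est = mosaicism_from_sperm(k, n)
            covered += est.ci_low <= m <= est.ci_high
        assert covered / n_draws >= 0.95


class TestLethalityEstimate:
    def test_birth_table_point_estimate(self):
        birth = TransmissionCounts.from_vector("birth", [31, 14, 29, 2])
        assert lethality_from_birth_counts(birth) == pytest.approx(1 - 2 / 14)

    def test_recovery_at_scaled_cohort(self):
        # method-of-moments recovery within 0.1 at 760 births
        cfg = SimulationConfig()
        rng = np.random.default_rng(17)
        errs = []
        for _ in range(50):
            birth = simulate_birth_counts(
                760, cfg.germline_mosaicism, cfg.male_lethality, rng
            )
            errs.append(abs(lethality_from_birth_counts(birth) - cfg.male_lethality))
        assert np.median(errs) <= 0.1

    def test_mosaicism_recovery_from_sperm(self):
        cfg = SimulationConfig()
        rng = np.random.default_rng(23)
        m = cfg.germline_mosaicism
        errs = []
        for _ in range(200):
            _, exps = simulate_sperm_counts(cfg, rng)
            k, n = exps[0]
            errs.append(abs(mosaicism_from_sperm(k, n).mosaicism - m))
        se = 2 * np.sqrt((m / 2) * (1 - m / 2) / cfg.n_sperm_scored)
        assert np.median(errs) <= se


def record(cow="c1", day=0, outcome="failure", superov=False, nxt="ai",
           nxt_day=42, consec=1):
    return AIRecord(cow, day, outcome, superov, nxt, nxt_day, consec)


class TestAIFilter:
    def test_generator_accounting_retains_twenty(self, rng):
        recs = simulate_ai_records(SimulationConfig(), rng)
        retained, discarded = filter_ai_records(recs)
        assert len(retained) == 20
        reasons = {}
        for d in discarded:
            reasons[d.reason] = reasons.get(d.reason, 0) + 1
        assert reasons["superovulation"] == 1
        assert reasons["adjacent_ai"] == 6
        assert reasons["low_fertility"] == 8
        assert reasons["not_failure"] == 26

    def test_empty_input(self):
        retained, discarded = filter_ai_records([])
        assert retained == [] and discarded == []

    def test_first_matching_rule_wins(self):
        # superovulated AND adjacent AND low-fertility: one discard, first rule
        r = record(superov=True, nxt="ai", nxt_day=1, consec=5)
        retained, discarded = filter_ai_records([r])
        assert retained == []
        assert len(discarded) == 1
        assert discarded[0].reason == "superovulation"


class TestLethalityWindow:
    def test_next_ai_bound(self):
        res = lethality_window([record(nxt="ai", nxt_day=42)])
        assert res.bounds[0].bound_days == 21
        assert res.max_bound_days == 21

    def test_next_calving_bound(self):
        res = lethality_window([record(nxt="calving", nxt_day=400)])
        assert res.bounds[0].bound_days == 94

    def test_nonpositive_bounds_excluded(self):
        res = lethality_window([record(nxt="ai", nxt_day=10)])
        assert not res.bounds[0].valid
        assert res.max_bound_days is None

    def test_no_next_event_error(self):
        with pytest.raises(ValueError):
            lethality_window([record(nxt="none", nxt_day=None)])

    @settings(derandomize=True, max_examples=30)
    @given(st.integers(-10**6, 10**6))
    def test_global_day_offset_invariance(self, offset):
        base = [
            record(day=0, nxt="ai", nxt_day=50),
            record(cow="c2", day=10, nxt="calving", nxt_day=420),
        ]
        shifted = [
            AIRecord(r.cow_id, r.ai_day + offset, r.outcome, r.superovulation,
                     r.next_event, r.next_event_day + offset,
                     r.consecutive_failures_for_cow)
            for r in base
        ]
        assert (
            lethality_window(base).max_bound_days
            == lethality_window(shifted).max_bound_days
        )

    def test_generator_bounds_never_exceed_truth(self, rng):
        cfg = SimulationConfig()
        recs = simulate_ai_records(cfg, rng)
        retained, _ = filter_ai_records(recs)
        res = lethality_window(retained)
        assert res.max_bound_days is not None
        assert res.max_bound_days <= cfg.max_death_day


class TestInheritanceReport:
    def test_observed_birth_counts_report(self):
        birth = TransmissionCounts.from_vector("birth", [31, 14, 29, 2])
        rep = inheritance_report(birth)
        d = rep.to_dict()
        assert d["sex_by_phenotype_independence"]["statistic"] == pytest.approx(
            6.7156, abs=5e-4
        )
        assert d["dominant_gof"]["statistic"] == pytest.approx(29.37, abs=0.005)
        assert d["sex_ratio_carrier"] == pytest.approx(2 / 14)

    def test_all_equal_counts_report(self):
        birth = TransmissionCounts.from_vector("birth", [10, 10, 10, 10])
        d = inheritance_report(birth).to_dict()
        assert d["sex_by_phenotype_independence"]["statistic"] == 0.0
        assert d["dominant_gof"]["statistic"] == 0.0

    def test_simulated_cohort_report_schema(self, bundle7):
        rep = inheritance_report(
            birth=bundle7.counts["birth"],
            sperm=bundle7.counts["sperm"],
            blastocyst=bundle7.counts["blastocyst"],
            sperm_experiments=bundle7.sperm_experiments,
            ai_records=bundle7.ai_records,
        )
        d = rep.to_dict()
        assert set(d["stage_tests"]) == {
            "sperm_vs_blastocyst", "blastocyst_vs_birth", "sperm_vs_birth"
        }
        assert len(d["mosaicism"]) == 2
        assert d["n_retained_ai"] == 20
        assert d["max_bound_days"] <= bundle7.config.max_death_day
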