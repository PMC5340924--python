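"""Post-hoc CAT: EAP estimation, item selection, stopping rules, summaries."""

import numpy as np
import pytest

import gradedcat as gc
from gradedcat.bank import GrmItem, ItemBank
from gradedcat.cat import table_totals
from gradedcat.grm import category_probs, item_information


def fine_grid_eap(items, responses, points=2001):
    """Independent dense-quadrature oracle for the posterior mean and SD."""
    grid = np.linspace(-6, 6, points)
    logpost = -0.5 * grid**2
    for it, x in zip(items, responses):
        logpost += np.log(np.clip(category_probs(it, grid)[int(x)],
                                  1e-300, None))
    w = np.exp(logpost - logpost.max())
    w /= w.sum()
    mean = float(w @ grid)
    sd = float(np.sqrt(w @ (grid - mean) ** 2))
    return mean, sd


class TestEap:
    def test_zero_items_returns_prior(self):
        est = gc.eap([], [])
        assert (est.theta, est.se, est.n_items_used) == (0.0, 1.0, 0)

    def test_all_top_responses_give_positive_trait(self, depression_bank):
        est = gc.eap(list(depression_bank), [2] * 6)
        assert est.theta > 0

    def test_matches_fine_grid_oracle(self, depression_bank):
        rng = np.random.default_rng(41)
        items = list(depression_bank)
        for _ in range(100):
            resp = rng.integers(0, 3, size=6)
            est = gc.eap(items, resp)
            mean, sd = fine_grid_eap(items, resp)
            assert est.theta == pytest.approx(mean, abs=1e-3)
            assert est.se == pytest.approx(sd, abs=1e-3)

    def test_response_count_checked(self, depression_bank):
        with pytest.raises(ValueError):
            gc.eap(list(depression_bank), [1, 2])


class TestSelectNext:
    def test_singleton_pool(self, depression_bank):
        assert gc.select_next(depression_bank, ["dep35"], 0.0) == "dep35"

    def test_agrees_with_exhaustive_scan(self):
        rng = np.random.default_rng(42)
        for trial in range(200):
            bank = gc.generate_bank(10, seed=1000 + trial)
            theta = float(rng.uniform(-3, 3))
            pool = list(rng.choice(bank.item_ids, size=6, replace=False))
            brute = max(
                sorted(pool, key=bank.item_ids.index),
                key=lambda i: (item_information(bank[i], theta),
                               -bank.item_ids.index(i)),
            )
            assert gc.select_next(bank, pool, theta) == brute

    def test_tie_breaks_to_lower_index(self):
        twin = ItemBank([GrmItem("a", "s", 2.0, -0.5, 0.5),
                         GrmItem("b", "s", 2.0, -0.5, 0.5)])
        assert gc.select_next(twin, ["a", "b"], 0.3) == "a"
        assert gc.select_next(twin, ["b", "a"], 0.3) == "a"

    def test_empty_pool_rejected(self, depression_bank):
        with pytest.raises(ValueError):
            gc.select_next(depression_bank, [], 0.0)


@pytest.fixture()
def record(cohort):
    codes = cohort.responses.subset("depression").codes
    return codes.iloc[17].to_dict()


class TestRunCat:
    def test_infinite_tolerance_stops_after_one_item(self, depression_bank,
                                                     record):
        res = gc.run_cat(depression_bank, record, stop_se=np.inf)
        assert len(res.administered) == 1
        assert res.stop_reason == "se_met"  # SE rule is checked first

    def test_unreachable_precision_exhausts_pool(self, depression_bank,
                                                 record):
        res = gc.run_cat(depression_bank, record, stop_se=0.0)
        assert res.stop_reason == "pool_exhausted"
        assert sorted(res.administered) == sorted(depression_bank.item_ids)

    def test_half_length_cap_binds(self, depression_bank, record):
        res = gc.run_cat(depression_bank, record, stop_se=0.0, max_items=3)
        assert res.stop_reason == "max_items"
        assert len(res.administered) == 3

    def test_se_met_implies_threshold_satisfied(self, depression_bank,
                                                cohort):
        codes = cohort.responses.subset("depression").codes
        for i in range(40):
            res = gc.run_cat(depression_bank, codes.iloc[i].to_dict(),
                             stop_se=0.45)
            assert len(set(res.administered)) == len(res.administered)
            if res.stop_reason == "se_met":
                assert res.se_final <= 0.45

    def test_dominance_in_stop_se(self, depression_bank, cohort):
        codes = cohort.responses.subset("depression").codes
        for i in range(30):
            rec = codes.iloc[i].to_dict()
            tight = gc.run_cat(depression_bank, rec, stop_se=0.35)
            loose = gc.run_cat(depression_bank, rec, stop_se=0.55)
            assert len(tight.administered) >= len(loose.administered)

    def test_se_trace_mostly_decreasing(self, depression_bank, cohort):
        codes = cohort.responses.subset("depression").codes
        for i in range(30):
            res = gc.run_cat(depression_bank, codes.iloc[i].to_dict(),
                             stop_se=0.0)
            ses = [e.se for e in res.theta_trace]
            assert all(b <= a + 0.05 for a, b in zip(ses, ses[1:]))

    def test_incomplete_record_rejected(self, depression_bank, record):
        partial = dict(record)
        partial.pop("dep33")
        with pytest.raises(ValueError, match="incomplete"):
            gc.run_cat(depression_bank, partial, stop_se=0.4)

    def test_deterministic_replay(self, depression_bank, record):
        a = gc.run_cat(depression_bank, record, stop_se=0.4)
        b = gc.run_cat(depression_bank, record, stop_se=0.4)
        assert a.administered == b.administered
        assert a.theta_final == b.theta_final


class TestCohortSimulation:
    def test_zero_tolerance_reproduces_full_test(self, depression_bank,
                                                 cohort):
        s = gc.simulate_cohort(depression_bank, cohort.responses, 0.0)
        assert s.mean_items == len(depression_bank)
        assert s.correlation == 1.0
        finals = np.array([r.theta_final for r in s.results])
        fulls = np.array([r.theta_full for r in s.results])
        assert np.array_equal(finals, fulls)

    def test_high_precision_cat_tracks_full_scale(self, depression_bank,
                                                  fixture_bank):
        # ten seeds: adaptive scores at SE <= 0.4 stay close to full scores
        for seed in range(10):
            c = gc.make_cohort(fixture_bank, n_persons=379, seed=300 + seed)
            s = gc.simulate_cohort(depression_bank, c.responses, 0.4)
            assert s.correlation >= 0.95

    def test_sd_zero_when_cap_always_binds(self, depression_bank, cohort):
        s = gc.simulate_cohort(depression_bank, cohort.responses, 0.0,
                               max_items=3)
        assert s.mean_items == 3.0
        assert s.sd_items == 0.0


class TestSeGrid:
    def test_mean_items_non_increasing(self, depression_bank, cohort):
        tab = gc.se_grid(depression_bank, cohort.responses)
        assert list(tab["stop_se"]) == [0.2, 0.3, 0.4, 0.5, 0.6, 0.7, 0.8]
        assert np.all(np.diff(tab["mean_items"]) <= 0)

    def test_correlations_non_increasing_within_tolerance(self,
                                                          depression_bank,
                                                          cohort):
        tab = gc.se_grid(depression_bank, cohort.responses)
        assert np.all(np.diff(tab["correlation"]) <= 0.02)

    def test_unsorted_grid_rejected(self, depression_bank, cohort):
        with pytest.raises(ValueError):
            gc.se_grid(depression_bank, cohort.responses, grid=(0.4, 0.3))


class TestReferenceSe:
    def test_saturating_bank_hits_grid_floor(self, cohort):
        huge = ItemBank([GrmItem(f"h{j}", "depression", 50.0,
                                 -2.0 + 0.2 * j, -1.0 + 0.2 * j)
                         for j in range(16)])
        rm = gc.simulate_responses(
            huge, np.random.default_rng(6).standard_normal(100), seed=7)
        ref, raw = gc.full_scale_reference_se(huge, rm)
        assert ref == 0.2
        assert raw < 0.2

    def test_reference_is_grid_member_and_covers_mean(self, fixture_bank,
                                                      cohort):
        for scale in fixture_bank.scales:
            ref, raw = gc.full_scale_reference_se(fixture_bank.subset(scale),
                                                  cohort.responses)
            assert ref in (0.2, 0.3, 0.4, 0.5, 0.6, 0.7, 0.8)
            assert ref >= raw - 1e-12


class TestCombinedReport:
    def test_caps_only_reduce_to_half_length(self, fixture_bank):
        # unreachable SE, caps bind everywhere: 8 + 3 + 6 + 8 of 50 items
        c = gc.make_cohort(fixture_bank, n_persons=40, seed=55)
        banks = {s: fixture_bank.subset(s) for s in fixture_bank.scales}
        rms = {s: c.responses for s in fixture_bank.scales}
        from gradedcat.cat import combined_rule_report
        rep = combined_rule_report(
            banks, rms, {s: True for s in banks},
            grid=(1e-9,),  # effectively unreachable precision
        )
        assert rep.total_full == 50
        assert rep.total_cat == 8 + 3 + 6 + 8
        assert rep.reduction_percent == 50

    def test_table_totals_arithmetic(self):
        total, rounded, red = table_totals([16, 6, 12, 16], [16, 6, 12, 16])
        assert (total, rounded, red) == (50.0, 50, 0)
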