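import itertools
import math

import numpy as np
import pytest

from cohortsample.designs import (
    DesignSpec,
    DesignError,
    EmptyStratumError,
    risk_set,
    draw_srs,
    draw_ncc,
    draw_modncc,
    draw_cc,
    draw_modcc,
    draw_egs,
    draw_design,
    calibrate_egs_t1,
    km_type_weights,
    ipw_weights,
)
from cohortsample.synthetic_cohorts import dachs_like
from .conftest import make_cohort


def rng(seed=0):
    return np.random.default_rng(seed)


class TestDesignSpec:
    def test_irrelevant_parameter_rejected(self):
        with pytest.raises(DesignError, match="t1"):
            DesignSpec(name="srs", target_n=10, t1=1.0)

    def test_egs_boundary_order(self):
        with pytest.raises(DesignError):
            DesignSpec(name="egs", t1=5.0, t2=1.0)

    def test_probability_domain(self):
        with pytest.raises(DesignError):
            DesignSpec(name="modncc", case_probability=1.5)


class TestSRS:
    def test_full_sample_is_cohort(self, toy10):
        s = draw_srs(toy10, n=10, rng=rng())
        assert s.n_sample == 10
        assert (s.df.weight == 1).all()

    def test_size_errors(self, toy10):
        with pytest.raises(DesignError):
            draw_srs(toy10, 0, rng())
        with pytest.raises(DesignError):
            draw_srs(toy10, 11, rng())

    def test_hypergeometric_event_mean(self, toy10):
        # N=10 with 4 events, n=4 -> E[events sampled] = 4*4/10 = 1.6
        g = rng(1)
        counts = [draw_srs(toy10, 4, g).n_event for _ in range(10_000)]
        assert np.mean(counts) == pytest.approx(1.6, abs=3 * np.std(counts) / 100)


class TestRiskSet:
    def test_membership_is_time_geq_t(self, toy5):
        assert risk_set(toy5, 3) == {"p2", "p3", "p4"}

    def test_beyond_max_time_empty(self, toy5):
        assert risk_set(toy5, 6) == set()

    def test_tied_times_included(self):
        cohort = make_cohort([1, 2, 2, 3], [1, 0, 0, 0])
        assert risk_set(cohort, 2) == {"p1", "p2", "p3"}


class TestNCC:
    def test_toy_enumeration(self, toy5):
        # cases at t=1,3 always in; one control each; overlap gives n=3
        g = rng(2)
        for _ in range(200):
            s = draw_ncc(toy5, m=1, rng=g)
            assert s.n_event == 2
            assert s.n_sample in (3, 4)
            assert set(s.df.loc[s.df.role == "case", "id"]) == {"p0", "p2"}

    def test_saturation_with_large_m(self, toy5):
        s = draw_ncc(toy5, m=10, rng=rng())
        # every at-risk subject of every risk set enters
        assert s.n_sample == 5

    def test_no_events_yields_empty_sample(self, caplog):
        cohort = make_cohort([1, 2, 3], [0, 0, 0])
        with caplog.at_level("WARNING"):
            s = draw_ncc(cohort, rng=rng())
        assert s.n_sample == 0
        assert "no events" in caplog.text


class TestModNCC:
    def test_p_one_equals_ncc_in_distribution(self, toy5):
        # inclusion frequencies match between ncc and modncc(P=1)
        g1, g2 = rng(3), rng(3)
        freq_ncc = np.zeros(5)
        freq_mod = np.zeros(5)
        B = 2500
        for _ in range(B):
            for freq, draw in ((freq_ncc, draw_ncc(toy5, 1, g1)),
                               (freq_mod, draw_modncc(toy5, case_probability=1.0,
                                                      m=1, rng=g2))):
                idx = [int(i[1:]) for i in draw.df.id]
                freq[idx] += 1
        assert np.allclose(freq_ncc / B, freq_mod / B, atol=0.05)

    def test_fixed_count_draws_exactly(self):
        cohort = make_cohort(np.arange(1, 9), [1, 1, 1, 1, 0, 0, 0, 0])
        s = draw_modncc(cohort, case_count=1, m=1, rng=rng(4))
        assert (s.df.role == "case").sum() == 1
        assert s.n_sample == 2

    def test_fixed_count_too_large(self, toy5):
        with pytest.raises(DesignError):
            draw_modncc(toy5, case_count=3, rng=rng())

    def test_medium_resource_sample_fraction(self):
        # P=.4, 1:1 matching on the colorectal-like cohort samples ~27% of N
        cohort = dachs_like(seed=5)
        g = rng(5)
        fracs = [draw_modncc(cohort, case_probability=0.4, m=1, rng=g).n_sample
                 / cohort.n for _ in range(300)]
        assert np.mean(fracs) == pytest.approx(0.27, abs=0.012)


class TestKMTypeWeights:
    def test_hand_computed_control_weight(self, toy5):
        # subject at t=5, P=1, m=1: p0 = 1-(1-1/4)(1-1/2) = 0.625 -> w = 1.6
        w = km_type_weights(toy5, ["p4"], m=1, P=1.0)
        assert w[0] == pytest.approx(1.6)

    def test_case_weight_one_under_full_case_sampling(self, toy5):
        w = km_type_weights(toy5, ["p0", "p2"], m=1, P=1.0)
        assert np.allclose(w, 1.0)

    def test_inclusion_probabilities_match_simulation(self, toy5):
        P, B = 0.7, 10_000
        g = rng(6)
        freq = np.zeros(5)
        for _ in range(B):
            s = draw_modncc(toy5, case_probability=P, m=1, rng=g)
            freq[[int(i[1:]) for i in s.df.id]] += 1
        pi_emp = freq / B
        f1, f3 = 1 - P / 4, 1 - P / 2
        pi = np.array([P,                      # case at t=1, never a control
                       P / 4,                  # control only at t=1
                       P + (1 - P) * (P / 4),  # case at t=3 or control at t=1
                       1 - f1 * f3,            # at risk at both event times
                       1 - f1 * f3])
        tol = 3 * np.sqrt(pi * (1 - pi) / B)
        assert (np.abs(pi_emp - pi) < tol).all()

    def test_horvitz_thompson_totals(self, toy5):
        # E[sum of weights] = N and E[sum of weight*event] = cohort events
        g = rng(7)
        tot, tot_ev = [], []
        for _ in range(4000):
            s = draw_modncc(toy5, case_probability=0.6, m=1, rng=g)
            tot.append(s.df.weight.sum())
            tot_ev.append((s.df.weight * s.df.event).sum())
        assert np.mean(tot) == pytest.approx(5, abs=3 * np.std(tot) / math.sqrt(4000))
        assert np.mean(tot_ev) == pytest.approx(
            2, abs=3 * np.std(tot_ev) / math.sqrt(4000))

    def test_inverse_weight_sum_bounded_by_n(self, toy5):
        g = rng(8)
        for _ in range(50):
            s = draw_modncc(toy5, case_probability=0.5, m=1, rng=g)
            assert (1 / s.df.weight).sum() <= toy5.n + 1e-9


class TestCaseCohort:
    def test_full_subcohort_all_weights_one(self, toy10):
        s = draw_cc(toy10, subcohort_size=10, rng=rng())
        assert (s.df.weight == 1).all()

    def test_all_cases_retained(self, toy10):
        for seed in range(20):
            s = draw_cc(toy10, subcohort_size=4, rng=rng(seed))
            assert s.n_event == 4

    def test_sample_size_distribution_matches_enumeration(self):
        # N=6 with 2 events, subcohort size 3: enumerate all C(6,3) subcohorts
        cohort = make_cohort([1, 2, 3, 4, 5, 6], [1, 1, 0, 0, 0, 0])
        sizes = {}
        for sub in itertools.combinations(range(6), 3):
            n = len(set(sub) | {0, 1})
            sizes[n] = sizes.get(n, 0) + 1
        expect = {k: v / 20 for k, v in sizes.items()}
        g = rng(9)
        draws = [draw_cc(cohort, subcohort_size=3, rng=g).n_sample
                 for _ in range(4000)]
        vals, counts = np.unique(draws, return_counts=True)
        assert set(vals) <= set(expect)
        for v, c in zip(vals, counts):
            p = expect[v]
            assert c / 4000 == pytest.approx(p, abs=3 * math.sqrt(p * (1 - p) / 4000))

    def test_modcc_r1_equals_cc(self, toy10):
        s1 = draw_cc(toy10, subcohort_size=4, rng=rng(10))
        s2 = draw_modcc(toy10, subcohort_size=4, extra_case_fraction=1.0, rng=rng(10))
        assert list(s1.df.id) == list(s2.df.id)
        assert np.allclose(s1.df.weight, s2.df.weight)

    def test_modcc_r0_is_subcohort_only(self, toy10):
        s = draw_modcc(toy10, subcohort_size=4, extra_case_fraction=0.0, rng=rng(11))
        assert s.n_sample == 4
        assert (s.df.role == "subcohort").all()

    def test_modcc_expected_event_count(self, toy10):
        # E[n_event] = n_case * (q + (1-q) r)
        q, r = 0.5, 0.4
        g = rng(12)
        evs = [draw_modcc(toy10, subcohort_fraction=q, extra_case_fraction=r,
                          rng=g).n_event for _ in range(4000)]
        expect = 4 * (q + (1 - q) * r)
        assert np.mean(evs) == pytest.approx(
            expect, abs=3 * np.std(evs) / math.sqrt(4000))

    def test_ipw_weight_values(self, toy10):
        # cc special case: q=.5, r=1 -> non-case weight 2, case weight 1
        w = ipw_weights(toy10, ["p0", "p2"], q=0.5, r=1.0)  # p0 case, p2 censored
        assert w == pytest.approx([1.0, 2.0])
        # modcc: q=.2, r=.5 -> case weight 1/0.6
        w = ipw_weights(toy10, ["p0"], q=0.2, r=0.5)
        assert w[0] == pytest.approx(1 / 0.6)
        # q=1 -> everything 1
        assert np.allclose(ipw_weights(toy10, list(toy10.ids), q=1.0), 1.0)

    def test_ipw_inclusion_matches_simulation(self, toy10):
        q, r, B = 0.5, 0.5, 10_000
        g = rng(13)
        freq = np.zeros(10)
        for _ in range(B):
            s = draw_modcc(toy10, subcohort_fraction=q, extra_case_fraction=r, rng=g)
            freq[[int(i[1:]) for i in s.df.id]] += 1
        pi = np.where(toy10.event == 1, q + (1 - q) * r, q)
        tol = 3 * np.sqrt(pi * (1 - pi) / B)
        assert (np.abs(freq / B - pi) < tol).all()

    def test_invalid_q(self, toy10):
        with pytest.raises(DesignError):
            ipw_weights(toy10, ["p0"], q=0.0)


class TestEGS:
    def test_worked_partition(self, toy_egs):
        s = draw_egs(toy_egs, t1=1.0, t2=5.0, rng=rng(14))
        cases = set(s.df.loc[s.df.role == "egs_case", "id"])
        assert cases == {"p0"}  # only the event at 0.5 < t1
        controls = set(s.df.loc[s.df.role == "egs_control", "id"])
        assert controls <= {"p3", "p4"}  # times 6, 7 are event-free at t2=5
        # subjects at 1.5 and 3 are excluded
        assert {"p1", "p2"}.isdisjoint(set(s.df.id))

    def test_equal_boundaries(self, toy_egs):
        s = draw_egs(toy_egs, t1=1.0, t2=1.0, rng=rng(15))
        assert set(s.df.loc[s.df.role == "egs_case", "id"]) == {"p0"}
        # eligible controls: all with time >= 1 -> one is drawn (1:1)
        assert (s.df.role == "egs_control").sum() == 1
        assert s.meta["n_eligible_controls"] == 4

    def test_one_to_one_size(self, toy_egs):
        s = draw_egs(toy_egs, t1=2.0, t2=2.0, rng=rng(16))
        n_cases = (s.df.role == "egs_case").sum()
        assert s.n_sample == 2 * n_cases

    def test_partition_exhaustive_exclusive(self, toy_egs):
        t1, t2 = 1.0, 5.0
        time, event = toy_egs.time, toy_egs.event
        is_case = (event == 1) & (time < t1)
        eligible = time >= t2
        excluded = ~is_case & ~eligible
        assert (is_case.astype(int) + eligible + excluded == 1).all()

    def test_empty_stratum_errors(self, toy_egs):
        with pytest.raises(EmptyStratumError):
            draw_egs(toy_egs, t1=0.1, t2=0.5, rng=rng())
        with pytest.raises(EmptyStratumError):
            draw_egs(toy_egs, t1=1.0, t2=8.0, rng=rng())


class TestEGSCalibration:
    def test_single_case_suffices(self, toy_egs):
        cal = calibrate_egs_t1(toy_egs, target_n=2, t2=5.0)
        assert cal.t1 == pytest.approx(0.5, abs=1e-9)
        assert cal.t1 > 0.5  # strictly above the first event time
        assert cal.n_achieved == 2

    def test_achieved_n_monotone_in_target(self, toy_egs):
        achieved = [calibrate_egs_t1(toy_egs, target_n=k, t2="equal-to-t1").n_achieved
                    for k in (2, 3, 4)]
        assert achieved == sorted(achieved)

    def test_unachievable_reports_range(self, toy_egs):
        with pytest.raises(DesignError, match="achievable"):
            calibrate_egs_t1(toy_egs, target_n=100, t2=5.0)

    def test_dachs_like_boundary_near_one_year(self):
        # matching the medium-resource size needs t1 somewhere around a year
        t1s = [calibrate_egs_t1(dachs_like(seed=s), 419, t2="equal-to-t1").t1
               for s in range(5)]
        assert 0.8 <= np.mean(t1s) <= 1.3


class TestDispatcherInvariants:
    @pytest.mark.parametrize("design", [
        DesignSpec(name="srs", target_n=6),
        DesignSpec(name="ncc", m=1),
        DesignSpec(name="modncc", case_probability=0.6),
        DesignSpec(name="cc", subcohort_fraction=0.5),
        DesignSpec(name="modcc", subcohort_fraction=0.4, extra_case_fraction=0.5),
        DesignSpec(name="egs", t1=2.0, t2=2.0),
        DesignSpec(name="full"),
    ])
    def test_sample_invariants(self, toy10, design):
        for seed in range(5):
            s = draw_design(toy10, design, rng(seed))
            assert not s.df.id.duplicated().any()
            assert (s.df.weight >= 1 - 1e-9).all()
            assert s.n_event == int(s.df.event.sum())
            assert (1 / s.df.weight).sum() <= toy10.n + 1e-9

    def test_serialization_roundtrip(self, toy10, tmp_path):
        s = draw_design(toy10, DesignSpec(name="cc", subcohort_fraction=0.5), rng(1))
        out = tmp_path / "s.csv"
        s.write(out)
        assert out.exists() and (tmp_path / "s.csv.json").exists()
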