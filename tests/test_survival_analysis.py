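"""Endpoints, product-limit estimator, log-rank and Cox contracts."""

import itertools
from datetime import date
from types import SimpleNamespace

import numpy as np
import pandas as pd
import pytest

import metabrisk as mb
from metabrisk.survival_analysis import SurvivalRecord, records_to_frame

from conftest import km_product_limit_oracle


def _patient(relapse=None, death=None, bc=False, followup=9.6):
    group = "eBC_relapsed" if relapse is not None else "eBC_FFDR"
    return mb.PatientRecord(
        patient_id="P1", stage_group=group, subtype="luminal", t_stage="T1",
        n_stage="N0", grade="G2", acquisition_date=date(2012, 1, 1),
        latent_metastatic_likeness=0.4, followup_years=followup,
        relapse_time_years=relapse, death_time_years=death, death_bc_related=bc,
    )


def _recs(times, events):
    return [
        SurvivalRecord(f"P{i}", "RFI", float(t), int(e))
        for i, (t, e) in enumerate(zip(times, events))
    ]


class TestEndpoints:
    def test_relapse_is_an_event(self):
        r = mb.compute_endpoints(_patient(relapse=2.0, followup=5.0))
        assert (r.time_years, r.event) == (2.0, 1)

    def test_death_without_relapse_censors(self):
        r = mb.compute_endpoints(_patient(death=4.0, followup=9.0))
        assert (r.time_years, r.event) == (4.0, 0)

    def test_alive_relapse_free_censors_at_followup(self):
        r = mb.compute_endpoints(_patient(followup=9.6))
        assert (r.time_years, r.event) == (9.6, 0)

    def test_bc_specific_and_os_endpoints(self):
        p = _patient(relapse=2.0, death=3.0, bc=True, followup=9.0)
        assert mb.compute_endpoints(p, "OS").event == 1
        assert mb.compute_endpoints(p, "BC_specific").event == 1
        q = _patient(death=3.0, followup=9.0)
        assert mb.compute_endpoints(q, "BC_specific").event == 0

    def test_missing_followup_rejected(self):
        stub = SimpleNamespace(
            patient_id="X", followup_years=float("nan"),
            relapse_time_years=None, death_time_years=None,
            death_bc_related=False,
        )
        with pytest.raises(mb.InputError, match="follow-up"):
            mb.compute_endpoints(stub)


class TestKaplanMeier:
    def test_four_subject_hand_example(self):
        """Event at 1, censor at 2, event at 3, censor at 5:
        S = 3/4 on [1, 3), then 3/8 afterwards."""
        est = mb.km_estimate(_recs([1, 2, 3, 5], [1, 0, 1, 0]))
        np.testing.assert_allclose(est.survival([0.5, 1.5, 2.5, 4.0]),
                                   [1.0, 0.75, 0.75, 0.375])

    def test_no_events_flat_curve(self):
        est = mb.km_estimate(_recs([1, 2, 3], [0, 0, 0]))
        assert np.all(est.survival([0.5, 2.9, 10.0]) == 1.0)

    def test_no_extrapolation_beyond_last_time(self):
        est = mb.km_estimate(_recs([1, 2], [1, 1]))
        assert est.survival(100.0)[0] == est.survival(2.0)[0]

    def test_empty_input_rejected(self):
        with pytest.raises(mb.InputError):
            mb.km_estimate([])

    def test_exhaustive_patterns_match_product_limit_oracle(self):
        """All 2^10 event/censor patterns at distinct times, plus all 2^6
        patterns on a tied-time grid, agree with the hand estimator."""
        times10 = np.arange(1.0, 11.0)
        eval_at = np.concatenate([times10, times10 + 0.5])
        for pattern in itertools.product([0, 1], repeat=10):
            est = mb.km_estimate(_recs(times10, pattern))
            np.testing.assert_allclose(
                est.survival(eval_at),
                km_product_limit_oracle(times10, pattern, eval_at),
                atol=1e-12,
            )
        times6 = np.array([1.0, 1.0, 2.0, 2.0, 2.0, 4.0])
        for pattern in itertools.product([0, 1], repeat=6):
            est = mb.km_estimate(_recs(times6, pattern))
            np.testing.assert_allclose(
                est.survival([1.0, 2.0, 3.0, 4.0, 5.0]),
                km_product_limit_oracle(times6, pattern, [1, 2, 3, 4, 5]),
                atol=1e-12,
            )


class TestLogRank:
    def test_identical_groups_null(self):
        times, events = [1, 2, 3, 4], [1, 0, 1, 1]
        recs = _recs(times + times, events + events)
        groups = {r.patient_id: ("A" if i < 4 else "B")
                  for i, r in enumerate(recs)}
        chi2, p = mb.logrank_test(recs, groups)
        assert chi2 == pytest.approx(0.0, abs=1e-9)
        assert p == pytest.approx(1.0, abs=1e-9)

    def test_separated_groups_significant(self):
        recs = _recs([1, 1.5, 2, 8, 9, 10], [1, 1, 1, 1, 1, 1])
        groups = {f"P{i}": ("A" if i < 3 else "B") for i in range(6)}
        chi2, p = mb.logrank_test(recs, groups)
        assert p < 0.05

    def test_label_swap_and_time_rescaling_invariance(self):
        rng = np.random.default_rng(0)
        times = rng.exponential(5, 20)
        events = rng.integers(0, 2, 20)
        events[0] = 1
        recs = _recs(times, events)
        groups = {f"P{i}": ("A" if i % 2 else "B") for i in range(20)}
        chi2, _ = mb.logrank_test(recs, groups)
        swapped = {k: ("B" if v == "A" else "A") for k, v in groups.items()}
        chi2_swap, _ = mb.logrank_test(recs, swapped)
        assert chi2_swap == pytest.approx(chi2, rel=1e-9)
        rescaled = _recs(3.7 * times, events)
        chi2_scale, _ = mb.logrank_test(rescaled, groups)
        assert chi2_scale == pytest.approx(chi2, rel=1e-9)

    def test_single_group_rejected(self):
        recs = _recs([1, 2], [1, 1])
        with pytest.raises(mb.InputError):
            mb.logrank_test(recs, {"P0": "A", "P1": "A"})


class TestCox:
    def _two_group_data(self, n, rate_ratio, seed, censor_at=50.0):
        rng = np.random.default_rng(seed)
        group = np.repeat([0, 1], n // 2)
        t = rng.exponential(1.0 / (0.1 * rate_ratio**group))
        events = (t <= censor_at).astype(int)
        t = np.minimum(t, censor_at)
        recs = _recs(t, events)
        cov = pd.DataFrame(
            {"risk_class": np.where(group == 1, "high", "low")},
            index=[f"P{i}" for i in range(n)],
        )
        return recs, cov

    def test_null_covariate_hr_near_one(self):
        recs, cov = self._two_group_data(200, 1.0, seed=1)
        res = mb.cox_fit(recs, cov, ["risk_class"])[0]
        assert res.ci_low < 1.0 < res.ci_high

    def test_rate_ratio_three_recovered(self):
        recs, cov = self._two_group_data(500, 3.0, seed=2)
        res = mb.cox_fit(recs, cov, ["risk_class"])[0]
        assert 2.4 < res.hr < 3.75

    def test_wald_interval_algebra(self):
        """HR and CI come from the same coefficient: the geometric mean of
        the Wald CI bounds is the HR itself."""
        recs, cov = self._two_group_data(120, 2.0, seed=3)
        res = mb.cox_fit(recs, cov, ["risk_class"])[0]
        assert np.sqrt(res.ci_low * res.ci_high) == pytest.approx(res.hr, rel=1e-6)
        assert res.ci_low <= res.hr <= res.ci_high

    def test_zero_event_level_flagged(self):
        recs = _recs([1, 2, 3, 4, 5, 6], [1, 1, 0, 0, 0, 0])
        cov = pd.DataFrame(
            {"risk_class": ["low", "low", "high", "high", "high", "low"]},
            index=[f"P{i}" for i in range(6)],
        )
        res = mb.cox_fit(recs, cov, ["risk_class"])[0]
        assert not res.converged


class TestSubgroups:
    def test_single_class_stratum_inestimable(self):
        recs = _recs([1, 2, 3, 4], [1, 1, 1, 0])
        ids = [r.patient_id for r in recs]
        risk = pd.Series(["low"] * 4, index=ids)
        strata = pd.Series(["N0"] * 4, index=ids)
        out = mb.subgroup_rfi(recs, risk, strata)
        assert out["N0"]["inestimable"] and out["N0"]["cox"] is None

    def test_stratum_specific_effect_recovered(self):
        """Hazard doubling confined to the node-positive stratum shows up
        there and not in the node-negative stratum."""
        rng = np.random.default_rng(5)
        n = 400
        strata = np.repeat(["N+", "N0"], n // 2)
        risk = np.tile(np.repeat(["high", "low"], n // 4), 2)
        rate = 0.1 * np.where((strata == "N+") & (risk == "high"), 3.0, 1.0)
        t = rng.exponential(1.0 / rate)
        recs = _recs(t, np.ones(n, dtype=int))
        ids = [r.patient_id for r in recs]
        out = mb.subgroup_rfi(
            recs, pd.Series(risk, index=ids), pd.Series(strata, index=ids)
        )
        assert out["N+"]["cox"].hr > 2.0
        assert out["N0"]["cox"].ci_low < 1.0 < out["N0"]["cox"].ci_high

    def test_pooled_hr_between_balanced_stratum_hrs(self):
        rng = np.random.default_rng(6)
        n = 400
        strata = np.repeat(["A", "B"], n // 2)
        risk = np.tile(np.repeat(["high", "low"], n // 4), 2)
        rr = np.where(strata == "A", 4.0, 1.5)
        rate = 0.1 * np.where(risk == "high", rr, 1.0)
        t = rng.exponential(1.0 / rate)
        recs = _recs(t, np.ones(n, dtype=int))
        ids = [r.patient_id for r in recs]
        out = mb.subgroup_rfi(
            recs, pd.Series(risk, index=ids), pd.Series(strata, index=ids)
        )
        pooled = mb.cox_fit(
            recs, pd.DataFrame({"risk_class": risk}, index=ids), ["risk_class"]
        )[0]
        lo, hi = sorted([out["A"]["cox"].hr, out["B"]["cox"].hr])
        assert lo < pooled.hr < hi
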