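"""Interval derivation, summaries and comparison statistics.

Statistical routines are checked against hand-written textbook formulas
(independent of the scipy/statsmodels implementations behind them).
"""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from clinicflow import analysis, synthetic_emr as emr
from clinicflow.analysis import (
    EmptySummaryError,
    IntervalRecord,
    SimParams,
    bonferroni,
    compare_means,
    compare_proportions_chi2,
    derive_intervals,
    derive_sim_params,
    percent_change,
    share,
    summarize,
    top_box_rate,
    two_proportion_z,
    visit_end_time,
)


def _rec(timestamps, **kwargs):
    defaults = dict(encounter_id="e", era="covid", modality="in_person", age=75.0)
    defaults.update(kwargs)
    return emr.EncounterRecord(timestamps=timestamps, **defaults)


# ---------------------------------------------------------------------------
# visit end / interval derivation
# ---------------------------------------------------------------------------

class TestVisitEndTime:
    def test_earlier_of_the_two_completion_stamps(self):
        rec = _rec({"visit_complete": 600.0, "visit_complete_note_pending": 590.0})
        assert visit_end_time(rec) == 590.0

    def test_single_stamp_is_used(self):
        assert visit_end_time(_rec({"visit_complete": 600.0})) == 600.0

    def test_missing_when_neither_present(self):
        assert visit_end_time(_rec({"check_in": 480.0})) is None


class TestDeriveIntervals:
    def test_worked_example(self):
        """Hand arithmetic on the derivation rules (values near era means)."""
        rec = _rec({
            "check_in": 540.0,
            "in_with_technician": 543.0,
            "done_rooming": 562.0,
            "in_with_provider": 573.0,
            "visit_complete": 587.0,
        })
        iv = derive_intervals(rec)
        assert iv.visit_length == 47.0
        assert iv.checkin_to_tech == 3.0
        assert iv.time_with_tech == 19.0
        assert iv.checkin_to_provider == 33.0
        assert iv.provider_phase == 14.0
        assert not iv.erroneous

    def test_only_check_in_gives_all_missing(self):
        iv = derive_intervals(_rec({"check_in": 480.0}))
        for name in analysis.INTERVAL_NAMES:
            assert getattr(iv, name) is None

    def test_completion_before_check_in_is_erroneous(self):
        iv = derive_intervals(_rec({"check_in": 540.0, "visit_complete": 500.0}))
        assert iv.visit_length is None
        assert iv.erroneous

    def test_tech_time_zero_when_only_tech_stamp_present(self):
        """No post-rooming marker: the interval collapses to 0 and is kept."""
        iv = derive_intervals(_rec({
            "check_in": 540.0, "in_with_technician": 545.0, "visit_complete": 600.0,
        }))
        assert iv.time_with_tech == 0.0

    def test_dilating_stamp_can_end_tech_time(self):
        iv = derive_intervals(_rec({
            "check_in": 540.0,
            "in_with_technician": 543.0,
            "dilating_in_waiting_room": 560.0,
            "done_rooming": 565.0,
        }))
        assert iv.time_with_tech == 17.0  # earliest post-rooming marker wins

    def test_interval_ordering_invariant(self, covid_cohort):
        """check-in-to-tech <= check-in-to-provider <= visit length."""
        frame = analysis.intervals_frame(covid_cohort)
        complete = frame.dropna(
            subset=["checkin_to_tech", "checkin_to_provider", "visit_length"]
        )
        assert not complete.empty
        assert (complete.checkin_to_tech <= complete.checkin_to_provider + 1e-9).all()
        assert (complete.checkin_to_provider <= complete.visit_length + 1e-9).all()


# ---------------------------------------------------------------------------
# summaries and volume arithmetic
# ---------------------------------------------------------------------------

class TestSummarize:
    def test_basic_statistics(self):
        s = summarize([10, 20, 30])
        assert (s.mean, s.sd, s.median, s.min, s.max, s.n) == (20, 10, 20, 10, 30, 3)

    def test_single_value_flags_undefined_sd(self):
        s = summarize([5])
        assert (s.mean, s.median, s.sd) == (5, 5, 0.0)
        assert not s.sd_defined

    def test_empty_after_dropping_missing_raises(self):
        with pytest.raises(EmptySummaryError):
            summarize([float("nan")])

    def test_missingness_accounting(self):
        """Volume counts include records no interval summary can use."""
        cohort = emr.generate_cohort(emr.era_preset("covid", 200, seed=13))
        frame = analysis.intervals_frame(cohort)
        report = analysis.cohort_volume_report(cohort)
        n_volume = report[["pre_covid", "covid"]].to_numpy().sum()
        assert n_volume == 200
        for name in analysis.INTERVAL_NAMES:
            assert frame[name].notna().sum() <= n_volume


class TestVolumeArithmetic:
    @pytest.mark.parametrize(
        "before, after, expected",
        [(2647, 1015, 62), (14486, 1774, 88), (1245, 425, 66), (100, 100, 0)],
    )
    def test_percent_decline_rounds_to_printed_integers(self, before, after, expected):
        assert round(percent_change(before, after)) == expected

    def test_zero_baseline_is_undefined(self):
        assert percent_change(0, 5) is None

    def test_share(self):
        assert round(share(2647, 14486)) == 18
        assert share(1, 0) is None

    def test_cohort_volume_report_changes(self):
        records = [
            _rec({}, era="pre_covid", encounter_id=f"a{i}") for i in range(100)
        ] + [_rec({}, era="covid", encounter_id=f"b{i}") for i in range(38)]
        report = analysis.cohort_volume_report(records)
        row = report[report.modality == "in_person"].iloc[0]
        assert (row.pre_covid, row.covid, row.pct_change_display) == (100, 38, 62)


# ---------------------------------------------------------------------------
# comparison statistics vs. textbook oracles
# ---------------------------------------------------------------------------

def _welch_oracle(a, b):
    a, b = np.asarray(a, float), np.asarray(b, float)
    va, vb = a.var(ddof=1) / a.size, b.var(ddof=1) / b.size
    t = (a.mean() - b.mean()) / math.sqrt(va + vb)
    df = (va + vb) ** 2 / (va**2 / (a.size - 1) + vb**2 / (b.size - 1))
    from scipy.stats import t as tdist

    return t, 2 * tdist.sf(abs(t), df)


def _pearson_chi2_oracle(table):
    table = np.asarray(table, float)
    total = table.sum()
    expected = np.outer(table.sum(1), table.sum(0)) / total
    return ((table - expected) ** 2 / expected).sum()


def _pooled_z_oracle(p1, n1, p2, n2):
    pooled = (p1 * n1 + p2 * n2) / (n1 + n2)
    return (p1 - p2) / math.sqrt(pooled * (1 - pooled) * (1 / n1 + 1 / n2))


class TestCompareMeans:
    def test_identical_groups(self):
        t, p = compare_means([1, 2, 3], [1, 2, 3])
        assert (t, p) == (0.0, 1.0)

    def test_separated_groups(self):
        _, p = compare_means([1, 2, 3], [101, 102, 103])
        assert p < 1e-3

    def test_era_scale_contrast_is_significant(self):
        """N(87,35) vs N(47,33) at n=200 — the era visit-length contrast."""
        rng = np.random.default_rng(0)
        _, p = compare_means(rng.normal(87, 35, 200), rng.normal(47, 33, 200))
        assert p < 1e-3

    def test_insufficient_n_rejected(self):
        with pytest.raises(ValueError):
            compare_means([1], [2, 3])

    @settings(max_examples=40, derandomize=True)
    @given(seed=st.integers(0, 2**20), na=st.integers(3, 40), nb=st.integers(3, 40))
    def test_agrees_with_textbook_welch(self, seed, na, nb):
        rng = np.random.default_rng(seed)
        a, b = rng.normal(10, 3, na), rng.normal(12, 5, nb)
        t, p = compare_means(a, b)
        t0, p0 = _welch_oracle(a, b)
        assert t == pytest.approx(t0, abs=1e-9)
        assert p == pytest.approx(p0, abs=1e-9)


class TestChiSquare:
    def test_no_association(self):
        chi2, p = compare_proportions_chi2([[50, 50], [50, 50]])
        assert (chi2, p) == (0.0, 1.0)

    def test_matches_hand_pearson_on_era_counts(self):
        table = [[2647, 11839], [1015, 759]]
        chi2, _ = compare_proportions_chi2(table)
        assert chi2 == pytest.approx(_pearson_chi2_oracle(table), abs=1e-9)

    def test_perfect_association(self):
        _, p = compare_proportions_chi2([[10, 0], [0, 10]])
        assert p < 1e-3

    def test_zero_expected_cell_rejected(self):
        with pytest.raises(ValueError):
            compare_proportions_chi2([[0, 0], [5, 5]])

    def test_bonferroni_caps_at_one(self):
        assert bonferroni(0.02, 4) == pytest.approx(0.08)
        assert bonferroni(0.4, 4) == 1.0


class TestTopBoxAndZ:
    def test_top_box_examples(self):
        assert top_box_rate([5, 5, 4, 3]) == 0.5
        assert top_box_rate([5, 5, 5]) == 1.0
        assert top_box_rate([1, 2, 3, 4]) == 0.0

    def test_top_box_rejects_bad_scores(self):
        with pytest.raises(ValueError):
            top_box_rate([5, 6])
        with pytest.raises(ValueError):
            top_box_rate([])

    def test_equal_proportions(self):
        z, p = two_proportion_z(0.5, 30, 0.5, 60)
        assert (z, p) == (0.0, 1.0)
        assert two_proportion_z(0.9, 10, 0.9, 10)[0] == 0.0

    def test_hand_evaluated_pooled_z(self):
        z, _ = two_proportion_z(0.8, 40, 0.6, 40)
        assert z == pytest.approx(1.952, abs=5e-3)

    def test_degenerate_pooled_proportion_rejected(self):
        with pytest.raises(ValueError):
            two_proportion_z(0.0, 10, 0.0, 10)

    @settings(max_examples=40, derandomize=True)
    @given(
        x1=st.integers(1, 39), n1=st.integers(40, 80),
        x2=st.integers(1, 39), n2=st.integers(40, 80),
    )
    def test_agrees_with_textbook_pooled_z(self, x1, n1, x2, n2):
        p1, p2 = x1 / n1, x2 / n2
        z, _ = two_proportion_z(p1, n1, p2, n2)
        assert z == pytest.approx(_pooled_z_oracle(p1, n1, p2, n2), abs=1e-9)


# ---------------------------------------------------------------------------
# simulation-parameter derivation
# ---------------------------------------------------------------------------

class TestDeriveSimParams:
    def test_provider_phase_is_halved_per_encounter(self):
        records = [
            _rec(
                {"check_in": 0.0, "in_with_technician": 2.0, "done_rooming": 10.0,
                 "in_with_provider": 20.0, "visit_complete": 36.0},
                encounter_id=f"e{i}",
            )
            for i in range(3)
        ]
        params = derive_sim_params(records)
        assert params.exam_time == (8.0, 0.0)  # provider phase 16 halved

    def test_all_missing_interval_names_the_culprit(self):
        records = [_rec({"check_in": 0.0, "visit_complete": 30.0})]
        with pytest.raises(EmptySummaryError, match="checkin_to_tech"):
            derive_sim_params(records)

    def test_parameter_recovery_round_trip(self):
        """Generator -> interval analysis recovers configured values (3 SE, n=5000)."""
        n = 5000
        cfg = emr.era_preset("covid", n, seed=17, missingness_rate=0.0)
        records = emr.generate_cohort(cfg)
        params = derive_sim_params(records)
        spec = cfg.phase_duration_specs
        checks = [
            (params.waiting_room_time, spec["checkin_to_tech"]),
            (params.tech_time, spec["time_with_tech"]),
            (params.exam_time, tuple(v / 2 for v in spec["provider_phase"][:2])),
        ]
        for (got_mean, _), (want_mean, want_sd, *_) in checks:
            assert got_mean == pytest.approx(want_mean, abs=3 * want_sd / np.sqrt(n))
        rates = cfg.procedure_rates
        p_dil = rates["dilation_one_eye"] + rates["dilation_both_eyes"]
        assert params.p_dilation == pytest.approx(p_dil, abs=3 * np.sqrt(p_dil * (1 - p_dil) / n))

    def test_sim_params_json_round_trip(self, tmp_path):
        params = SimParams.covid_defaults()
        path = tmp_path / "params.json"
        params.to_json(path)
        assert SimParams.from_json(path) == params


class TestModelResults:
    def test_fit_produces_summary_and_params(self, covid_cohort):
        res = analysis.ClinicFlowModel(covid_cohort).fit()
        assert res.sim_params is not None
        text = res.summary()
        assert "waiting room" in text and "p(dilation)" in text
        assert set(res.summary_frame()["interval"]) <= set(analysis.INTERVAL_NAMES)

    def test_model_from_event_log(self, covid_cohort, tmp_path):
        path = tmp_path / "events.csv"
        emr.write_event_log(covid_cohort, path)
        res = analysis.ClinicFlowModel.from_event_log(path).fit()
        assert res.n_encounters == len(covid_cohort)

    def test_era_comparison(self, covid_cohort):
        pre = emr.generate_cohort(emr.era_preset("pre_covid", 300, seed=8,
                                                 missingness_rate=0.0))
        res_pre = analysis.ClinicFlowModel(pre).fit()
        res_covid = analysis.ClinicFlowModel(covid_cohort).fit()
        t, p = res_pre.compare(res_covid, "visit_length")
        assert t > 0 and p < 1e-3  # pandemic-era visits are much shorter
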