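"""Drug-era chaining, exposure flags, medication counts, descriptive table."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from polyfrac import (
    build_design,
    build_drug_intervals,
    comorbidity_flags,
    concomitant_flags,
    default_maps,
    medication_count,
    standardized_difference,
    standardized_difference_binary,
    standardized_difference_continuous,
    descriptive_table,
)
from polyfrac.errors import MappingError, SchemaError
from conftest import toy_dataset

MAPS = default_maps()
RX1 = "ATC01001"  # resolves to category rx01
RX2 = "ATC02001"


def _rx(rows):
    return pd.DataFrame(rows, columns=["patient_id", "drug_code", "start_date", "days_supplied"])


def _episodes(rows):
    """rows: (drug_code, start, end); category resolved via the default maps."""
    recs = []
    for code, s, e in rows:
        recs.append(
            {
                "patient_id": "A",
                "drug_code": code,
                "med_category": MAPS.med_variables[MAPS.med_index(code)],
                "episode_start": pd.Timestamp(s),
                "episode_end": pd.Timestamp(e),
            }
        )
    return pd.DataFrame(recs)


class TestDrugIntervals:
    def test_single_prescription_covers_inclusive_interval(self):
        eps = build_drug_intervals(_rx([("A", RX1, "2017-01-01", 30)]))
        assert len(eps) == 1
        assert eps.loc[0, "episode_start"] == pd.Timestamp("2017-01-01")
        assert eps.loc[0, "episode_end"] == pd.Timestamp("2017-01-30")

    def test_refill_within_grace_merges(self):
        # coverage ends 2017-01-30; refill on 02-05 leaves a 5-day gap <= 7
        eps = build_drug_intervals(
            _rx([("A", RX1, "2017-01-01", 30), ("A", RX1, "2017-02-05", 30)])
        )
        assert len(eps) == 1
        assert eps.loc[0, "episode_end"] == pd.Timestamp("2017-03-06")

    def test_refill_beyond_grace_splits(self):
        eps = build_drug_intervals(
            _rx([("A", RX1, "2017-01-01", 30), ("A", RX1, "2017-02-10", 30)])
        )
        assert len(eps) == 2

    def test_unmapped_drug_code_raises(self):
        with pytest.raises(MappingError, match="XYZ"):
            build_drug_intervals(_rx([("A", "XYZ99001", "2017-01-01", 30)]))

    def test_nonpositive_days_supplied_rejected(self):
        with pytest.raises(SchemaError):
            build_drug_intervals(_rx([("A", RX1, "2017-01-01", 0)]))

    @given(
        length=st.integers(2, 90),
        cuts=st.lists(st.integers(1, 89), max_size=4, unique=True),
    )
    def test_splitting_into_contiguous_refills_changes_nothing(self, length, cuts):
        whole = build_drug_intervals(_rx([("A", RX1, "2017-03-01", length)]))
        bounds = sorted({0, length, *[c for c in cuts if c < length]})
        pieces = [
            (
                "A",
                RX1,
                (pd.Timestamp("2017-03-01") + pd.Timedelta(days=a)).date().isoformat(),
                b - a,
            )
            for a, b in zip(bounds[:-1], bounds[1:])
        ]
        split = build_drug_intervals(_rx(pieces))
        pd.testing.assert_frame_equal(whole, split)


class TestConcomitantFlags:
    def test_episode_spanning_index_sets_flag(self):
        idx = pd.Timestamp("2018-06-15")
        eps = _episodes([(RX1, idx - pd.Timedelta(days=30), idx + pd.Timedelta(days=10))])
        assert concomitant_flags(eps, idx)[0] == 1

    def test_discontinued_within_seven_days_still_counts(self):
        idx = pd.Timestamp("2018-06-15")
        eps = _episodes([(RX1, "2018-04-01", idx - pd.Timedelta(days=5))])
        assert concomitant_flags(eps, idx)[0] == 1

    def test_long_discontinued_episode_ignored(self):
        idx = pd.Timestamp("2018-06-15")
        eps = _episodes([(RX1, "2018-04-01", idx - pd.Timedelta(days=20))])
        assert concomitant_flags(eps, idx)[0] == 0

    def test_episode_starting_on_index_date_does_not_count(self):
        idx = pd.Timestamp("2018-06-15")
        eps = _episodes([(RX1, idx, idx + pd.Timedelta(days=30))])
        assert concomitant_flags(eps, idx).sum() == 0

    def test_only_the_recency_window_matters(self):
        idx = pd.Timestamp("2018-06-15")
        near = _episodes([(RX1, "2018-05-01", "2018-06-20")])
        far = _episodes(
            [
                (RX1, "2018-05-01", "2018-06-20"),
                (RX2, "2016-01-01", "2016-03-01"),  # ends long before index-7
            ]
        )
        a, b = concomitant_flags(near, idx), concomitant_flags(far, idx)
        assert a[0] == b[0] == 1 and b[1] == 0


class TestMedicationCount:
    def test_no_episodes_counts_zero(self):
        assert medication_count(_episodes([]), "2018-06-15") == 0

    def test_overlapping_drugs_counted_on_best_day(self):
        # drug A covers days 1-30, drug B days 25-40; at index day 35 the
        # max over the pre-index week (days 28-35) is 2, reached on 28-30
        base = pd.Timestamp("2018-01-01")
        eps = _episodes(
            [
                (RX1, base, base + pd.Timedelta(days=29)),
                (RX2, base + pd.Timedelta(days=24), base + pd.Timedelta(days=39)),
            ]
        )
        assert medication_count(eps, base + pd.Timedelta(days=34)) == 2

    def test_many_simultaneous_drugs(self):
        idx = pd.Timestamp("2018-06-15")
        rows = [
            (f"ATC{k + 1:02d}001", "2018-05-01", "2018-07-01") for k in range(17)
        ]
        assert medication_count(_episodes(rows), idx) >= 15

    def test_count_monotone_under_added_prescriptions(self):
        rng = np.random.default_rng(8)
        idx = pd.Timestamp("2018-06-15")
        rows = []
        prev = 0
        for k in range(12):
            start = idx - pd.Timedelta(days=int(rng.integers(1, 60)))
            rows.append(("A", f"ATC{int(rng.integers(1, 61)):02d}001",
                         start.date().isoformat(), int(rng.integers(5, 40))))
            eps = build_drug_intervals(_rx(rows))
            cur = medication_count(eps, idx)
            assert cur >= prev
            prev = cur

    def test_centered_window_can_see_post_index_starts(self):
        idx = pd.Timestamp("2018-06-15")
        eps = _episodes([(RX1, idx + pd.Timedelta(days=2), idx + pd.Timedelta(days=20))])
        assert medication_count(eps, idx, count_window="pre") == 0
        assert medication_count(eps, idx, count_window="centered") == 1


class TestComorbidityFlags:
    IDX = pd.Timestamp("2018-06-15")

    def _dx(self, rows):
        return pd.DataFrame(
            rows, columns=["patient_id", "icd10_code", "confirmed", "start_date", "end_date"]
        )

    def test_open_ended_confirmed_diagnosis_sets_chapter_flag(self):
        dx = self._dx([("A", "I50", True, "2018-03-01", None)])
        flags = comorbidity_flags(dx, self.IDX)
        assert flags[MAPS.chapter_keys.index("circulatory")] == 1

    def test_diagnosis_closed_before_index_is_ignored(self):
        dx = self._dx([("A", "I50", True, "2018-03-01", "2018-06-05")])
        assert comorbidity_flags(dx, self.IDX).sum() == 0

    def test_unconfirmed_diagnosis_is_ignored(self):
        dx = self._dx([("A", "I50", False, "2018-03-01", None)])
        assert comorbidity_flags(dx, self.IDX).sum() == 0

    def test_unmapped_code_raises(self):
        dx = self._dx([("A", "U07", True, "2018-03-01", None)])
        with pytest.raises(MappingError):
            comorbidity_flags(dx, self.IDX)


class TestStandardizedDifference:
    def test_binary_matches_printed_values_from_counts(self):
        assert round(standardized_difference_binary(25615, 34717, 22895, 34717), 3) == 0.171
        assert round(standardized_difference_binary(5724, 34717, 8040, 34717), 3) == -0.168

    def test_identical_groups_give_zero(self):
        assert standardized_difference((100, 400), (100, 400), "binary") == 0.0
        assert standardized_difference((5.0, 1.2), (5.0, 1.2), "continuous") == 0.0

    def test_continuous_formula(self):
        got = standardized_difference_continuous(5.8, 4.2, 5.3, 4.0)
        assert got == pytest.approx((5.8 - 5.3) / np.sqrt((4.2**2 + 4.0**2) / 2))

    def test_zero_pooled_variance_with_unequal_stats_is_infinite(self):
        assert np.isinf(standardized_difference_binary(0, 10, 10, 10))
        assert np.isinf(standardized_difference_continuous(1.0, 0.0, 2.0, 0.0))


class TestDescriptiveTable:
    def test_copied_controls_balance_everything(self):
        ds = toy_dataset(n_pairs=60, seed=1)
        data = ds.data.copy()
        ctrl = data[data["role"] == "case"].copy()
        ctrl["role"] = "control"
        mirrored = type(ds)(
            pd.concat([data[data["role"] == "case"], ctrl], ignore_index=True),
            ds.variables,
            ds.labels,
        )
        tab = descriptive_table(mirrored)
        unmatched = tab[~tab["matched"]]
        assert (unmatched["std_diff"].fillna(0) == 0).all()

    def test_matched_variables_reported_as_balanced(self):
        tab = descriptive_table(toy_dataset(n_pairs=80, seed=2))
        matched = tab[tab["matched"]]
        assert set(matched["variable"]) == {
            "Age category: early elderly",
            "Age category: late elderly",
            "Sex: male",
            "Sex: female",
        }
        assert matched["std_diff"].isna().all()

    def test_std_diffs_match_independent_recomputation(self):
        ds = toy_dataset(n_pairs=120, beta_rx=0.8, seed=3)
        tab = descriptive_table(ds).set_index("variable")
        d = ds.data
        cases = d[d["role"] == "case"]
        ctrls = d[d["role"] == "control"]
        for var in ["cm_c0", "rx01", "rx04"]:
            c1, c2 = int(cases[var].sum()), int(ctrls[var].sum())
            p1, p2 = c1 / len(cases), c2 / len(ctrls)
            expect = (p1 - p2) / np.sqrt((p1 * (1 - p1) + p2 * (1 - p2)) / 2)
            assert tab.loc[ds.labels[var], "std_diff"] == pytest.approx(
                round(expect, 3), abs=1e-9
            )
        # continuous row recomputed with the averaged-variance formula
        m1, s1 = cases["med_count"].mean(), cases["med_count"].std(ddof=1)
        m2, s2 = ctrls["med_count"].mean(), ctrls["med_count"].std(ddof=1)
        expect = (m1 - m2) / np.sqrt((s1**2 + s2**2) / 2)
        assert tab.loc["Number of medications, mean (SD)", "std_diff"] == pytest.approx(
            round(expect, 3), abs=1e-9
        )


class TestBuildDesign:
    def test_early_stratum_from_case_age(self, study_dataset):
        strata = study_dataset.strata
        cases = study_dataset.data[study_dataset.data["role"] == "case"]
        early_ids = set(cases.loc[cases["age_at_index"] < 75, "pair_id"])
        assert set(strata[strata == "early"].index) == early_ids

    def test_strata_partition_pairs(self, study_dataset):
        n_early = study_dataset.filter("early").n_pairs
        n_late = study_dataset.filter("late").n_pairs
        assert n_early + n_late == study_dataset.n_pairs

    def test_missing_covariates_listed(self):
        cohort = pd.DataFrame(
            {
                "pair_id": [1, 1],
                "role": ["case", "control"],
                "patient_id": ["A", "B"],
                "index_date": pd.Timestamp("2017-01-01"),
                "age_at_index": [70, 71],
                "sex": "female",
                "age_band": 1,
            }
        )
        cov = pd.DataFrame({"patient_id": ["A"], "med_count": [2]})
        for v in MAPS.chapter_variables + MAPS.med_variables:
            cov[v] = 0
        with pytest.raises(SchemaError, match="B"):
            build_design(cohort, cov, MAPS)
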