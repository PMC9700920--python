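"""Window arithmetic, the derived feature battery, and the encoder contract."""

import datetime as dt

import numpy as np
import pandas as pd
import pytest

from readmit.bundle import RecordBundle
from readmit.cohort import build_cohort
from readmit.features import FeatureEncoder, build_manual_features, count_in_window


class TestCountInWindow:
    REF = dt.date(2016, 6, 1)

    def test_no_events(self):
        assert count_in_window([], self.REF, 180) == 0

    def test_boundaries(self):
        events = [self.REF - dt.timedelta(days=1), self.REF - dt.timedelta(days=181)]
        assert count_in_window(events, self.REF, 180) == 1

    def test_closed_left_edge_counted(self):
        assert count_in_window([self.REF - dt.timedelta(days=180)], self.REF, 180) == 1

    def test_reference_day_excluded_unless_flagged(self):
        assert count_in_window([self.REF], self.REF, 180) == 0
        assert count_in_window([self.REF], self.REF, 180, include_reference=True) == 1

    def test_bad_window_rejected(self):
        with pytest.raises(ValueError):
            count_in_window([], self.REF, 0)


def _tiny_bundle():
    """One patient whose only history is the index episode itself."""
    demo = pd.DataFrame(
        {"patient_id": ["p1"], "sex": ["F"],
         "birth_date": [pd.Timestamp("1955-06-01")], "postal_prefix": ["T5K"]}
    )
    hosp = pd.DataFrame(
        {
            "record_id": [0],
            "patient_id": ["p1"],
            "institution": ["INST01"],
            "admit_date": [pd.Timestamp("2015-03-01")],
            "discharge_date": [pd.Timestamp("2015-03-05")],
            "discharge_disposition": ["05"],
            "diagnosis_codes": ["K65 I21 K65"],
            "procedure_codes": ["1.SQ.52 1.SQ.52"],
            "admitted_via_ed": [True],
        }
    )
    empty = dict(patient_id=pd.Series(dtype=str))
    amb = pd.DataFrame({**empty, "visit_date": pd.Series(dtype="datetime64[ns]"),
                        "visit_mode": pd.Series(dtype=str),
                        "diagnosis_codes": pd.Series(dtype=str),
                        "procedure_codes": pd.Series(dtype=str)})
    claims = pd.DataFrame({**empty, "visit_date": pd.Series(dtype="datetime64[ns]"),
                           "specialty": pd.Series(dtype=str),
                           "paid_amount": pd.Series(dtype=float),
                           "diagnosis_codes": pd.Series(dtype=str)})
    rx = pd.DataFrame({**empty, "atc_code": pd.Series(dtype=str),
                       "dispense_date": pd.Series(dtype="datetime64[ns]"),
                       "quantity": pd.Series(dtype=int),
                       "days_supply": pd.Series(dtype=int)})
    labs = pd.DataFrame({**empty, "test_code": pd.Series(dtype=str),
                         "date": pd.Series(dtype="datetime64[ns]"),
                         "result_value": pd.Series(dtype=float),
                         "reference_low": pd.Series(dtype=float),
                         "reference_high": pd.Series(dtype=float)})
    return RecordBundle(demographics=demo, hospitalizations=hosp, ambulatory=amb,
                        claims=claims, prescriptions=rx, labs=labs)


class TestManualFeatures:
    def _build(self):
        bundle = _tiny_bundle()
        cohort, episodes, _ = build_cohort(bundle, seed=0)
        feats, meta = build_manual_features(cohort, bundle, episodes,
                                            lab_tests=["LAB01"])
        return feats.iloc[0], meta

    def test_empty_history_gives_zero_counts(self):
        row, _ = self._build()
        for col in ["n_discharges_182d", "n_discharges_730d", "hosp_days_730d",
                    "ed_visits_182d", "outpatient_visits_730d",
                    "visits_family_365d", "rx_records_730d"]:
            assert row[col] == 0, col
        assert not row["claim_any_1460d"]
        for cond in ["hypertension", "diabetes", "heart_failure", "asthma"]:
            assert not row[f"chronic_{cond}"]
        assert row["lab_LAB01"] == "missing"

    def test_index_length_of_stay_by_date_arithmetic(self):
        row, _ = self._build()
        assert row["index_los_days"] == 4  # 2015-03-01 .. 2015-03-05

    def test_index_code_counts_distinguish_unique(self):
        row, _ = self._build()
        assert row["index_unique_diag"] == 2       # K65, I21 (K65 repeated)
        assert row["index_procedures"] == 2
        assert row["index_unique_procedures"] == 1

    def test_charlson_includes_index_admission(self):
        row, _ = self._build()
        assert row["charlson_730d"] == 1  # I21 during the index episode

    def test_lace_column_consistent(self):
        from readmit.scores import lace

        row, meta = self._build()
        assert meta["lace_score"]["group"] == "lace"
        assert row["lace_score"] == lace(4, True, 1, 0)

    def test_duplicate_atc_counts_records_not_drugs(self):
        bundle = _tiny_bundle()
        bundle.prescriptions = pd.DataFrame(
            {
                "patient_id": ["p1", "p1"],
                "atc_code": ["J01DH", "J01DH"],
                "dispense_date": [pd.Timestamp("2014-06-01"),
                                  pd.Timestamp("2014-07-01")],
                "quantity": [30, 30],
                "days_supply": [30, 30],
            }
        )
        cohort, episodes, _ = build_cohort(bundle, seed=0)
        feats, _ = build_manual_features(cohort, bundle, episodes, lab_tests=[])
        assert feats.iloc[0]["rx_records_730d"] == 2
        assert feats.iloc[0]["rx_unique_730d"] == 1


@pytest.fixture(scope="module")
def built(small_bundle, small_cohort):
    cohort, episodes, _ = small_cohort
    feats, meta = build_manual_features(cohort, small_bundle, episodes)
    return cohort, feats, meta


class TestOnGeneratedData:
    def test_window_nesting(self, built):
        _, feats, _ = built
        assert (feats["ed_visits_182d"] <= feats["ed_visits_365d"]).all()
        assert (feats["ed_visits_365d"] <= feats["ed_visits_730d"]).all()
        assert (feats["n_discharges_182d"] <= feats["n_discharges_365d"]).all()
        assert (feats["n_discharges_365d"] <= feats["n_discharges_730d"]).all()
        assert (feats["claim_amount_730d"] <= feats["claim_amount_1460d"]).all()

    def test_counts_nonnegative_and_unique_bounded(self, built):
        _, feats, _ = built
        num = feats.select_dtypes(include=[np.number])
        assert (num.drop(columns=["age_years"]) >= 0).all().all()
        assert (feats["rx_unique_730d"] <= feats["rx_records_730d"]).all()
        assert (feats["rx_days_730d"] >= 0).all()

    def test_reproducible(self, small_bundle, small_cohort, built):
        cohort, episodes, _ = small_cohort
        _, feats, _ = built
        again, _ = build_manual_features(cohort, small_bundle, episodes)
        pd.testing.assert_frame_equal(feats, again)

    def test_row_order_matches_cohort(self, built):
        cohort, feats, _ = built
        assert list(feats.index) == list(cohort["patient_id"])

    def test_unknown_cohort_patient_rejected(self, small_bundle, small_cohort):
        cohort, episodes, _ = small_cohort
        bad = cohort.copy()
        bad.loc[0, "patient_id"] = "NOBODY"
        with pytest.raises(ValueError, match="NOBODY"):
            build_manual_features(bad, small_bundle, episodes)


class TestEncoder:
    def _frame(self):
        feats = pd.DataFrame(
            {
                "x": [1.0, 2.0, 3.0],
                "flag": [True, False, True],
                "dispo": ["01", "02", "03"],
            }
        )
        meta = {c: {"group": "manual"} for c in feats.columns}
        return feats, meta

    def test_categorical_levels_become_indicators(self):
        feats, meta = self._frame()
        feats8 = pd.concat([feats] * 3, ignore_index=True)
        feats8["dispo"] = [f"{i:02d}" for i in range(1, 9)] + ["01"]
        enc = FeatureEncoder().fit(feats8, meta)
        dispo_cols = [c for c in enc.encoded_columns_ if c.startswith("dispo=")]
        assert len(dispo_cols) == 8 + 1  # 8 observed levels + explicit other

    def test_numeric_identity_and_bool(self):
        feats, meta = self._frame()
        enc = FeatureEncoder().fit(feats, meta)
        x = enc.transform(feats)
        assert x.shape[0] == 3
        np.testing.assert_array_equal(x[:, 0], [1.0, 2.0, 3.0])
        np.testing.assert_array_equal(x[:, 1], [1.0, 0.0, 1.0])

    def test_unseen_category_maps_to_other(self):
        feats, meta = self._frame()
        enc = FeatureEncoder().fit(feats, meta)
        new = feats.copy()
        new.loc[0, "dispo"] = "99"
        x = enc.transform(new)
        other = enc.encoded_columns_.index("dispo=__other__")
        assert x[0, other] == 1.0
        assert x[1, other] == 0.0
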