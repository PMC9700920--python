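"""Episode linking, exclusion rules, index selection, labeling, splitting."""

import numpy as np
import pandas as pd
import pytest

from conftest import make_hosp_frame
from readmit.cohort import (
    CohortError,
    apply_exclusions,
    build_cohort,
    label_outcome,
    link_episodes,
    part_sizes,
    select_index,
    split_cohort,
)

WINDOW = (pd.Timestamp("2015-01-01").date(), pd.Timestamp("2016-12-31").date())


def _demo(pids=("p1",), prefix="T5K"):
    return pd.DataFrame(
        {
            "patient_id": list(pids),
            "sex": "F",
            "birth_date": pd.Timestamp("1960-01-01"),
            "postal_prefix": prefix,
        }
    )


class TestLinking:
    def test_single_record_single_episode(self):
        eps = link_episodes(make_hosp_frame([("2015-01-01", "2015-01-05", "05")]))
        assert len(eps) == 1
        assert eps[0].admit_date == pd.Timestamp("2015-01-01").date()
        assert eps[0].discharge_date == pd.Timestamp("2015-01-05").date()

    def test_transfer_disposition_merges(self):
        # B admits on A's discharge day, A was an acute transfer -> one episode
        eps = link_episodes(
            make_hosp_frame(
                [("2015-01-01", "2015-01-05", "01"), ("2015-01-05", "2015-01-09", "05")]
            )
        )
        assert len(eps) == 1
        assert eps[0].admit_date == pd.Timestamp("2015-01-01").date()
        assert eps[0].discharge_date == pd.Timestamp("2015-01-09").date()
        assert eps[0].discharge_disposition == "05"
        assert eps[0].record_ids == [0, 1]

    def test_ten_day_gap_stays_separate(self):
        eps = link_episodes(
            make_hosp_frame(
                [("2015-01-01", "2015-01-05", "05"), ("2015-01-15", "2015-01-20", "05")]
            )
        )
        assert len(eps) == 2

    def test_next_day_readmission_merges_as_continuation(self):
        eps = link_episodes(
            make_hosp_frame(
                [("2015-01-01", "2015-01-05", "05"), ("2015-01-06", "2015-01-08", "05")]
            )
        )
        assert len(eps) == 1

    def test_primary_diagnosis_is_first_records_first_code(self):
        eps = link_episodes(
            make_hosp_frame(
                [
                    ("2015-01-01", "2015-01-05", "01", "K65 I21"),
                    ("2015-01-05", "2015-01-09", "05", "C78"),
                ]
            )
        )
        assert eps[0].primary_diagnosis == "K65"


class TestExclusions:
    def _episodes(self, **over):
        from readmit.cohort import build_episodes

        rows = [
            ("2015-02-01", "2015-02-03", "05", "K65"),
            ("2015-03-01", "2015-03-04", "07", "K65"),   # died in hospital
            ("2015-04-01", "2015-04-02", "05", "F32"),   # psychiatric primary
            ("2015-05-01", "2015-05-02", "05", "F10"),   # substance: exempt
            ("2015-06-01", "2015-06-02", "02", "K65"),   # transfer (unlinked tail)
        ]
        return build_episodes(make_hosp_frame(rows))

    def test_rules_and_log(self):
        eps = self._episodes()
        cand, log = apply_exclusions(eps, _demo(), WINDOW)
        kept = set(cand["primary_diagnosis"])
        assert kept == {"K65", "F10"}
        assert log.died_or_invalid_id_or_out_of_province == 1
        assert log.transfer_disposition == 1
        assert log.psychiatric_primary == 1
        # counts reconcile: window candidates - retained == sum of rules
        assert log.candidates_in_window - len(cand) == log.total_excluded_episodes

    def test_out_of_province_patient_fully_excluded(self):
        eps = self._episodes()
        cand, log = apply_exclusions(eps, _demo(prefix="V6B"), WINDOW)
        assert len(cand) == 0
        assert log.died_or_invalid_id_or_out_of_province == len(eps)

    def test_unknown_disposition_strict_raises(self):
        from readmit.cohort import build_episodes

        eps = build_episodes(make_hosp_frame([("2015-02-01", "2015-02-03", "99")]))
        with pytest.raises(CohortError, match="99"):
            apply_exclusions(eps, _demo(), WINDOW, strict_dispositions=True)
        _, log = apply_exclusions(eps, _demo(), WINDOW, strict_dispositions=False)
        assert log.unknown_disposition_warnings == 1


class TestIndexSelection:
    def _candidates(self, n):
        from readmit.cohort import build_episodes

        rows = [(f"2015-0{i + 1}-01", f"2015-0{i + 1}-03", "05") for i in range(n)]
        return build_episodes(make_hosp_frame(rows))

    def test_single_candidate_always_chosen(self):
        cand = self._candidates(1)
        for seed in (0, 1, 99):
            assert select_index(cand, seed)["episode_id"].iloc[0] == 0

    def test_deterministic_under_seed(self):
        cand = self._candidates(3)
        a = select_index(cand, 42)["episode_id"].iloc[0]
        b = select_index(cand, 42)["episode_id"].iloc[0]
        assert a == b

    def test_selection_uniform_over_reseeded_draws(self):
        cand = self._candidates(2)
        picks = [select_index(cand, seed)["episode_id"].iloc[0] for seed in range(10_000)]
        frac = np.mean(np.asarray(picks) == 0)
        assert abs(frac - 0.5) <= 0.02

    def test_order_invariant(self):
        cand = self._candidates(3)
        shuffled = cand.sample(frac=1.0, random_state=0)
        assert (
            select_index(cand, 7)["episode_id"].iloc[0]
            == select_index(shuffled, 7)["episode_id"].iloc[0]
        )


class TestLabeling:
    def _label(self, gap_days):
        idx = pd.DataFrame(
            {
                "patient_id": ["p1"],
                "episode_id": [0],
                "discharge_date": [pd.Timestamp("2015-06-30")],
            }
        )
        eps = pd.DataFrame(
            {
                "patient_id": ["p1", "p1"],
                "admit_date": [
                    pd.Timestamp("2015-06-01"),
                    pd.Timestamp("2015-06-30") + pd.Timedelta(days=gap_days),
                ],
            }
        )
        return bool(label_outcome(idx, eps)[0])

    def test_boundary_30_days_counts(self):
        assert self._label(30) is True

    def test_boundary_31_days_does_not(self):
        assert self._label(31) is False

    def test_no_subsequent_episode_false(self):
        idx = pd.DataFrame(
            {"patient_id": ["p1"], "episode_id": [0],
             "discharge_date": [pd.Timestamp("2015-06-30")]}
        )
        eps = pd.DataFrame(
            {"patient_id": ["p1"], "admit_date": [pd.Timestamp("2015-06-01")]}
        )
        assert not label_outcome(idx, eps)[0]

    def test_label_invariant_to_episode_row_order(self, small_bundle):
        cohort, episodes, _ = build_cohort(small_bundle, seed=11)
        shuffled = episodes.sample(frac=1.0, random_state=3)
        a = label_outcome(cohort, episodes).to_numpy()
        b = label_outcome(cohort, shuffled).to_numpy()
        assert (a == b).all()

    def test_readmission_never_a_member_of_the_index_episode(self, small_cohort):
        cohort, episodes, _ = small_cohort
        readmitted = cohort[cohort["label"]]
        ep = episodes.set_index("episode_id")
        for row in readmitted.itertuples():
            later = ep[
                (ep["patient_id"] == row.patient_id)
                & (ep["admit_date"] > row.discharge_date)
                & (ep["admit_date"] <= row.discharge_date + pd.Timedelta(days=30))
            ]
            assert len(later) >= 1
            # the readmitting episode shares no records with the index episode
            for rec_ids in later["record_ids"]:
                assert not set(rec_ids) & set(row.record_ids)


class TestSplit:
    def test_part_size_arithmetic_large_cohort(self):
        sizes = part_sizes(428_669, 11)
        assert sum(sizes) == 428_669
        assert max(sizes) - min(sizes) <= 1
        assert sorted(set(sizes)) == [38_969, 38_970]

    def test_eleven_singletons(self):
        cohort = pd.DataFrame({"patient_id": [f"p{i}" for i in range(11)]})
        parts = split_cohort(cohort, seed=0)
        assert sorted(parts) == list(range(11))

    def test_partition_properties(self, small_cohort):
        cohort, _, _ = small_cohort
        parts = split_cohort(cohort, seed=5)
        assert len(parts) == len(cohort)
        counts = np.bincount(parts, minlength=11)
        assert counts.sum() == len(cohort)
        assert counts.max() - counts.min() <= 1

    def test_too_small_cohort_raises(self):
        with pytest.raises(CohortError):
            split_cohort(pd.DataFrame({"patient_id": ["a", "b"]}), seed=0)
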