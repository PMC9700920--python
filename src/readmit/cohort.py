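"""Cohort construction: care episodes, exclusions, index selection, outcome.

The unit of prediction is one *index episode* per patient: hospital discharge
records are first linked into episodes of continuous care, exclusion rules
remove episodes that cannot serve as an index admission, one candidate is
drawn uniformly at random per patient from the index window, and the outcome
is all-cause readmission within 30 days of the index discharge.

Linking rule (continuation of care): a later record is merged into the
episode of the earlier one when it admits at most one day after the earlier
record's discharge, or when the earlier record's discharge disposition is a
transfer code (01, 02, 03).  Because linking runs before labeling, a
continuation stay is never counted as a readmission.

30-day convention: an episode counts as a readmission of the index iff its
admit date ``d`` satisfies ``0 < d - index_discharge <= 30`` calendar days
(half-open on the left, so a same-day re-entry is a continuation, and an
admission exactly 30 days later still counts).
"""

from __future__ import annotations

import dataclasses
import datetime as dt

import numpy as np
import pandas as pd

from .bundle import RecordBundle

__all__ = [
    "Episode",
    "ExclusionLog",
    "TRANSFER_DISPOSITIONS",
    "KNOWN_DISPOSITIONS",
    "link_episodes",
    "build_episodes",
    "apply_exclusions",
    "select_index",
    "label_outcome",
    "build_cohort",
    "split_cohort",
    "part_sizes",
]

TRANSFER_DISPOSITIONS = {"01", "02", "03"}
DIED_DISPOSITION = "07"
KNOWN_DISPOSITIONS = {"01", "02", "03", "04", "05", "06", "07", "12"}
READMIT_WINDOW_DAYS = 30
#: maximum gap (days) between discharge and the next admission that still
#: counts as the same episode of care
LINK_GAP_DAYS = 1


@dataclasses.dataclass
class Episode:
    """One linked episode of continuous hospital care."""

    patient_id: str
    admit_date: dt.date
    discharge_date: dt.date
    record_ids: list[int]
    primary_diagnosis: str
    discharge_disposition: str
    admitted_via_ed: bool


class CohortError(ValueError):
    pass


def build_episodes(hospitalizations: pd.DataFrame) -> pd.DataFrame:
    """Vectorized episode linking over all patients.

    Returns one row per episode with columns ``patient_id, episode_id,
    admit_date, discharge_date, primary_diagnosis, discharge_disposition,
    admitted_via_ed, record_ids, n_records, n_overlapping``.
    """
    cols = ["patient_id", "episode_id", "admit_date", "discharge_date",
            "primary_diagnosis", "discharge_disposition", "admitted_via_ed",
            "record_ids", "n_records"]
    if len(hospitalizations) == 0:
        return pd.DataFrame(columns=cols)
    h = hospitalizations.sort_values(
        ["patient_id", "admit_date", "discharge_date"], kind="mergesort"
    ).reset_index(drop=True)
    same_patient = h["patient_id"].eq(h["patient_id"].shift())
    prev_discharge = h["discharge_date"].shift()
    prev_dispo = h["discharge_disposition"].shift()
    gap = (h["admit_date"] - prev_discharge).dt.days
    linked = same_patient & (
        (gap <= LINK_GAP_DAYS) | prev_dispo.isin(TRANSFER_DISPOSITIONS)
    )
    # overlapping stays are flagged (they are merged by the gap rule, never silently)
    overlap = (same_patient & (gap < 0)).astype(int)
    eid = (~linked).cumsum() - 1
    h = h.assign(_eid=eid, _overlap=overlap)
    h["_primary"] = h["diagnosis_codes"].str.split(" ").str[0].fillna("")
    g = h.groupby("_eid", sort=True)
    episodes = pd.DataFrame(
        {
            "patient_id": g["patient_id"].first(),
            "admit_date": g["admit_date"].first(),
            "discharge_date": g["discharge_date"].max(),
            "primary_diagnosis": g["_primary"].first(),
            "discharge_disposition": g["discharge_disposition"].last(),
            "admitted_via_ed": g["admitted_via_ed"].first(),
            "record_ids": g["record_id"].agg(list),
            "n_records": g.size(),
            "n_overlapping": g["_overlap"].sum(),
        }
    ).reset_index(drop=True)
    episodes.insert(1, "episode_id", np.arange(len(episodes)))
    return episodes


def link_episodes(records: pd.DataFrame) -> list[Episode]:
    """Link one patient's hospitalization records into :class:`Episode` objects."""
    if records["patient_id"].nunique() > 1:
        raise CohortError("link_episodes expects records of a single patient")
    r = records.copy()
    if "record_id" not in r.columns:
        r["record_id"] = np.arange(len(r))
    df = build_episodes(r)
    return [
        Episode(
            patient_id=row.patient_id,
            admit_date=row.admit_date.date(),
            discharge_date=row.discharge_date.date(),
            record_ids=list(row.record_ids),
            primary_diagnosis=row.primary_diagnosis,
            discharge_disposition=row.discharge_disposition,
            admitted_via_ed=bool(row.admitted_via_ed),
        )
        for row in df.itertuples()
    ]


@dataclasses.dataclass
class ExclusionLog:
    """Counts of index-candidate episodes removed per rule, in rule order."""

    candidates_in_window: int = 0
    died_or_invalid_id_or_out_of_province: int = 0
    transfer_disposition: int = 0
    psychiatric_primary: int = 0
    unknown_disposition_warnings: int = 0
    patients_dropped_no_candidate: int = 0

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @property
    def total_excluded_episodes(self) -> int:
        return (
            self.died_or_invalid_id_or_out_of_province
            + self.transfer_disposition
            + self.psychiatric_primary
        )


def _is_psychiatric(primary: pd.Series) -> pd.Series:
    """Mental/behavioural primary diagnosis: F00-F99 except the F10-F19 block."""
    f = primary.str.upper().str.startswith("F")
    block = primary.str.upper().str.slice(0, 3).str.slice(1).str.isdigit()
    num = pd.to_numeric(primary.str.upper().str.slice(1, 3), errors="coerce")
    substance = f & block & (num >= 10) & (num <= 19)
    return f & ~substance


def apply_exclusions(
    episodes: pd.DataFrame,
    demographics: pd.DataFrame,
    index_window: tuple[dt.date, dt.date],
    province_prefix: str = "T",
    strict_dispositions: bool = False,
) -> tuple[pd.DataFrame, ExclusionLog]:
    """Filter index-window episodes down to index candidates.

    Rules apply in order to episodes discharged inside ``index_window``:

    1. in-hospital deaths (disposition 07), invalid/missing patient ids, and
       every episode of patients with any out-of-province postal prefix;
    2. transfer dispositions (01, 02, 03);
    3. psychiatric primary diagnosis (F00-F99 except F10-F19).

    Episodes outside the window are not candidates but remain available for
    outcome labeling.  Returns (candidates, log).
    """
    log = ExclusionLog()
    lo, hi = (pd.Timestamp(index_window[0]), pd.Timestamp(index_window[1]))
    cand = episodes[
        (episodes["discharge_date"] >= lo) & (episodes["discharge_date"] <= hi)
    ].copy()
    log.candidates_in_window = len(cand)

    unknown = ~cand["discharge_disposition"].isin(KNOWN_DISPOSITIONS)
    if unknown.any():
        if strict_dispositions:
            bad = cand.loc[unknown, "discharge_disposition"].iloc[0]
            raise CohortError(f"unknown discharge disposition code {bad!r}")
        log.unknown_disposition_warnings = int(unknown.sum())

    known_ids = set(demographics["patient_id"])
    out_of_prov = set(
        demographics.loc[
            ~demographics["postal_prefix"].str.upper().str.startswith(province_prefix),
            "patient_id",
        ]
    )
    bad_id = (
        cand["patient_id"].isna()
        | (cand["patient_id"] == "")
        | ~cand["patient_id"].isin(known_ids)
    )
    rule1 = (
        (cand["discharge_disposition"] == DIED_DISPOSITION)
        | bad_id
        | cand["patient_id"].isin(out_of_prov)
    )
    log.died_or_invalid_id_or_out_of_province = int(rule1.sum())
    cand = cand[~rule1]

    rule2 = cand["discharge_disposition"].isin(TRANSFER_DISPOSITIONS)
    log.transfer_disposition = int(rule2.sum())
    cand = cand[~rule2]

    rule3 = _is_psychiatric(cand["primary_diagnosis"])
    log.psychiatric_primary = int(rule3.sum())
    cand = cand[~rule3]

    return cand.reset_index(drop=True), log


def select_index(candidates: pd.DataFrame, seed: int) -> pd.DataFrame:
    """Uniformly select one candidate episode per patient, reproducibly.

    Patients are processed in sorted id order with a single seeded generator,
    so the selection does not depend on the row order of ``candidates``.
    """
    if len(candidates) == 0:
        return candidates.copy()
    c = candidates.sort_values(
        ["patient_id", "admit_date", "episode_id"], kind="mergesort"
    ).reset_index(drop=True)
    sizes = c.groupby("patient_id", sort=True).size()
    rng = np.random.default_rng(seed)
    picks = rng.integers(0, sizes.to_numpy())
    offsets = np.concatenate([[0], sizes.to_numpy().cumsum()[:-1]])
    return c.iloc[offsets + picks].reset_index(drop=True)


def label_outcome(
    index_episodes: pd.DataFrame, all_episodes: pd.DataFrame
) -> pd.Series:
    """30-day all-cause readmission label per index row.

    True iff some episode of the same patient admits within
    ``(discharge, discharge + 30 days]``.  Episode linking has already merged
    continuations, so those never count.
    """
    adm = all_episodes[["patient_id", "admit_date"]].rename(
        columns={"admit_date": "next_admit"}
    )
    merged = index_episodes[["patient_id", "episode_id", "discharge_date"]].merge(
        adm, on="patient_id", how="left"
    )
    gap = (merged["next_admit"] - merged["discharge_date"]).dt.days
    hit = (gap > 0) & (gap <= READMIT_WINDOW_DAYS)
    out = hit.groupby(merged["episode_id"]).any()
    return (
        index_episodes["episode_id"].map(out).fillna(False).astype(bool)
    )


def build_cohort(
    bundle: RecordBundle,
    seed: int,
    index_window: tuple[dt.date, dt.date] | None = None,
    strict_dispositions: bool = False,
) -> tuple[pd.DataFrame, pd.DataFrame, ExclusionLog]:
    """Full cohort pipeline: episodes -> exclusions -> index -> label.

    Returns ``(cohort, episodes, exclusion_log)``.  ``cohort`` has one row per
    retained patient: the index episode's fields plus the boolean ``label``.
    """
    episodes = build_episodes(bundle.hospitalizations)
    if index_window is None:
        last = bundle.hospitalizations["discharge_date"].max()
        if pd.isna(last):
            raise CohortError("no hospitalization records: cannot infer index window")
        index_window = (dt.date(last.year - 1, 1, 1), dt.date(last.year, 12, 31))
    candidates, log = apply_exclusions(
        episodes, bundle.demographics, index_window,
        strict_dispositions=strict_dispositions,
    )
    n_cand_patients = candidates["patient_id"].nunique()
    cohort = select_index(candidates, seed)
    cohort = cohort.copy()
    cohort["label"] = label_outcome(cohort, episodes).to_numpy()
    log.patients_dropped_no_candidate = int(
        pd.Series(list(set(bundle.demographics["patient_id"]))).nunique()
        - n_cand_patients
    )
    return cohort.reset_index(drop=True), episodes, log


def part_sizes(n: int, n_parts: int = 11) -> list[int]:
    """Near-equal part sizes (differ by at most 1) summing to ``n``."""
    base, rem = divmod(n, n_parts)
    return [base + (1 if i < rem else 0) for i in range(n_parts)]


def split_cohort(cohort: pd.DataFrame, seed: int, n_parts: int = 11) -> np.ndarray:
    """Random patient-level partition into ``n_parts`` near-equal parts.

    Returns an integer part index per cohort row; part 0 is the holdout test
    set, parts 1..10 are the cross-validation folds.
    """
    n = len(cohort)
    if n < n_parts:
        raise CohortError(f"cohort of {n} rows cannot be split into {n_parts} parts")
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    sizes = part_sizes(n, n_parts)
    parts = np.empty(n, dtype=int)
    start = 0
    for i, s in enumerate(sizes):
        parts[order[start : start + s]] = i
        start += s
    return parts
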