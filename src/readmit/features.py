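"""Raw and manually derived features for each cohort row.

Every feature is anchored to the patient's index episode.  Pre-admission
windows are closed-open ``[admit - w, admit)`` — they end the day before the
index admission — except the features defined over the index episode itself
(which use the episode's member records) and the Charlson score, whose
two-year lookback includes the index admission and therefore ends at the
index discharge.  Window lengths: 6 months = 182 days, 1 year = 365,
2/3/4 years = 730/1095/1460.

The feature table is a plain DataFrame (one row per cohort patient, in cohort
order) plus a metadata dict mapping each column to its group (``raw``,
``manual``, ``lace``), anchor, and window.  Missingness is explicit: count
features default to 0, lab categories to the string ``"missing"``.
"""

from __future__ import annotations

import datetime as dt

import numpy as np
import pandas as pd

from . import scores
from .bundle import RecordBundle

__all__ = ["count_in_window", "build_manual_features", "FeatureEncoder"]

WIN_6M, WIN_1Y, WIN_2Y, WIN_3Y, WIN_4Y = 182, 365, 730, 1095, 1460


def count_in_window(
    event_dates, reference: dt.date, window_days: int, include_reference: bool = False
) -> int:
    """Count events with date in ``[reference - window_days, reference)``.

    With ``include_reference`` the interval is closed at the reference day.
    """
    if window_days <= 0:
        raise ValueError("window_days must be positive")
    lo = reference - dt.timedelta(days=window_days)
    n = 0
    for d in event_dates:
        d = d.date() if hasattr(d, "date") else d
        if lo <= d < reference or (include_reference and d == reference):
            n += 1
    return int(n)


def _anchor_frame(cohort: pd.DataFrame) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "patient_id": cohort["patient_id"].to_numpy(),
            "anchor_admit": cohort["admit_date"].to_numpy(),
            "anchor_discharge": cohort["discharge_date"].to_numpy(),
        }
    )


def _window_counts(cohort, events, date_col, windows, mask=None, value_col=None):
    """Per-patient windowed aggregates of an event table, anchored at index admit.

    ``windows``: {suffix: days}.  Counts events (or sums ``value_col``) with
    date in [admit - days, admit).  Returns {suffix: Series indexed by patient}.
    """
    ev = events if mask is None else events[mask]
    merged = ev.merge(_anchor_frame(cohort), on="patient_id", how="inner")
    delta = (merged["anchor_admit"] - merged[date_col]).dt.days
    out = {}
    for suffix, days in windows.items():
        sel = (delta >= 1) & (delta <= days)
        sub = merged[sel]
        if value_col is None:
            out[suffix] = sub.groupby("patient_id").size()
        else:
            out[suffix] = sub.groupby("patient_id")[value_col].sum()
    return out


def _explode_codes(df, code_col, date_col):
    sub = df.loc[df[code_col] != "", ["patient_id", date_col, code_col]]
    sub = sub.assign(code=sub[code_col].str.split(" ")).explode("code")
    sub["code"] = sub["code"].str.upper().str.replace(".", "", regex=False)
    return sub[["patient_id", date_col, "code"]]


def build_manual_features(
    cohort: pd.DataFrame,
    bundle: RecordBundle,
    episodes: pd.DataFrame,
    chronic_rules=scores.DEFAULT_CHRONIC_RULES,
    lab_tests: list[str] | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Compute the raw + manual + lace feature groups for every cohort row."""
    missing = ~cohort["patient_id"].isin(set(bundle.demographics["patient_id"]))
    if missing.any():
        raise ValueError(
            f"cohort patient {cohort.loc[missing, 'patient_id'].iloc[0]!r} "
            "absent from demographics"
        )
    pid = cohort["patient_id"].to_numpy()
    idx = pd.Index(pid, name="patient_id")
    feat = pd.DataFrame(index=idx)
    meta: dict[str, dict] = {}

    def add(name, series_or_array, group, anchor, window, fill=0):
        if isinstance(series_or_array, pd.Series):
            vals = series_or_array.reindex(idx)
            if isinstance(fill, bool):
                vals = vals.astype("boolean").fillna(fill).astype(bool)
            elif vals.isna().any():
                vals = vals.fillna(fill)
        else:
            vals = series_or_array
        feat[name] = vals
        meta[name] = {"group": group, "anchor": anchor, "window_days": window}

    # ---- raw --------------------------------------------------------------
    demo = bundle.demographics.set_index("patient_id")
    birth = demo["birth_date"].reindex(idx)
    disch = pd.Series(cohort["discharge_date"].to_numpy(), index=idx)
    admit = pd.Series(cohort["admit_date"].to_numpy(), index=idx)
    add("age_years", ((disch - birth).dt.days / 365.25).astype(float),
        "raw", "index_discharge", None)
    add("sex", demo["sex"].reindex(idx), "raw", None, None, fill="")
    add("discharge_disposition",
        pd.Series(cohort["discharge_disposition"].to_numpy(), index=idx),
        "raw", "index_episode", None, fill="")
    add("index_los_days", (disch - admit).dt.days.astype(int),
        "raw", "index_episode", None)

    # ---- hospital utilization before the index admission --------------------
    ep = episodes.rename(columns={"admit_date": "ep_admit", "discharge_date": "ep_disch"})
    counts = _window_counts(
        cohort, ep, "ep_disch",
        {"182d": WIN_6M, "365d": WIN_1Y, "730d": WIN_2Y},
    )
    for sfx, days in [("182d", WIN_6M), ("365d", WIN_1Y), ("730d", WIN_2Y)]:
        add(f"n_discharges_{sfx}", counts[sfx], "manual", "index_admit", days)
    # in-hospital days: overlap of each stay with the window
    merged = ep.merge(_anchor_frame(cohort), on="patient_id", how="inner")
    for sfx, days in [("182d", WIN_6M), ("365d", WIN_1Y), ("730d", WIN_2Y)]:
        lo = merged["anchor_admit"] - pd.to_timedelta(days, unit="D")
        overlap = (
            (np.minimum(merged["ep_disch"], merged["anchor_admit"])
             - np.maximum(merged["ep_admit"], lo)).dt.days.clip(lower=0)
        )
        add(f"hosp_days_{sfx}", overlap.groupby(merged["patient_id"]).sum(),
            "manual", "index_admit", days)

    # ---- Charlson over 2 years including the index admission ----------------
    dad_dx = _explode_codes(bundle.hospitalizations, "diagnosis_codes", "admit_date")
    dd = dad_dx.merge(_anchor_frame(cohort), on="patient_id", how="inner")
    in_win = (
        (dd["admit_date"] >= dd["anchor_admit"] - pd.to_timedelta(WIN_2Y, unit="D"))
        & (dd["admit_date"] <= dd["anchor_discharge"])
    )
    charlson = scores.charlson_bulk(dd.loc[in_win, ["patient_id", "code"]])
    add("charlson_730d", charlson, "manual", "index_discharge", WIN_2Y)

    # ---- index-episode code counts -------------------------------------------
    member_map = cohort[["patient_id", "record_ids"]].explode("record_ids")
    member_ids = set(member_map["record_ids"].dropna().astype(int))
    idx_recs = bundle.hospitalizations[
        bundle.hospitalizations["record_id"].isin(member_ids)
    ]
    idx_dx = _explode_codes(idx_recs, "diagnosis_codes", "admit_date")
    add("index_unique_diag", idx_dx.groupby("patient_id")["code"].nunique(),
        "manual", "index_episode", None)
    idx_pr = _explode_codes(idx_recs, "procedure_codes", "admit_date")
    add("index_procedures", idx_pr.groupby("patient_id").size(),
        "manual", "index_episode", None)
    add("index_unique_procedures", idx_pr.groupby("patient_id")["code"].nunique(),
        "manual", "index_episode", None)

    # ---- ambulatory visits ----------------------------------------------------
    amb = bundle.ambulatory
    is_ed = amb["visit_mode"] == "emergency"
    wins = {"182d": WIN_6M, "365d": WIN_1Y, "730d": WIN_2Y}
    for label_, mask in [("ed_visits", is_ed), ("outpatient_visits", ~is_ed)]:
        counts = _window_counts(cohort, amb, "visit_date", wins, mask=mask)
        for sfx, days in wins.items():
            add(f"{label_}_{sfx}", counts[sfx], "manual", "index_admit", days)
    add("admitted_via_ed",
        pd.Series(cohort["admitted_via_ed"].to_numpy(), index=idx).astype(bool),
        "manual", "index_episode", None, fill=False)

    # ---- physician claims ------------------------------------------------------
    cl = bundle.claims
    for spec_name in ["family", "internal_medicine", "general_surgery"]:
        counts = _window_counts(
            cohort, cl, "visit_date", {"182d": WIN_6M, "365d": WIN_1Y},
            mask=cl["specialty"] == spec_name,
        )
        for sfx, days in [("182d", WIN_6M), ("365d", WIN_1Y)]:
            add(f"visits_{spec_name}_{sfx}", counts[sfx], "manual", "index_admit", days)
    long_wins = {"730d": WIN_2Y, "1095d": WIN_3Y, "1460d": WIN_4Y}
    counts = _window_counts(cohort, cl, "visit_date", long_wins)
    amounts = _window_counts(cohort, cl, "visit_date", long_wins, value_col="paid_amount")
    for sfx, days in long_wins.items():
        add(f"claim_any_{sfx}", (counts[sfx] > 0), "manual", "index_admit", days,
            fill=False)
        add(f"claim_amount_{sfx}", amounts[sfx].astype(float), "manual",
            "index_admit", days, fill=0.0)

    # ---- prescriptions -----------------------------------------------------------
    rx = bundle.prescriptions
    counts = _window_counts(cohort, rx, "dispense_date", {"730d": WIN_2Y})
    days_sum = _window_counts(cohort, rx, "dispense_date", {"730d": WIN_2Y},
                              value_col="days_supply")
    add("rx_records_730d", counts["730d"], "manual", "index_admit", WIN_2Y)
    add("rx_days_730d", days_sum["730d"], "manual", "index_admit", WIN_2Y)
    rxm = rx.merge(_anchor_frame(cohort), on="patient_id", how="inner")
    delta = (rxm["anchor_admit"] - rxm["dispense_date"]).dt.days
    pre = rxm[(delta >= 1) & (delta <= WIN_2Y)]
    add("rx_unique_730d", pre.groupby("patient_id")["atc_code"].nunique(),
        "manual", "index_admit", WIN_2Y)
    during = rxm[
        (rxm["dispense_date"] >= rxm["anchor_admit"])
        & (rxm["dispense_date"] <= rxm["anchor_discharge"])
    ]
    add("rx_records_index", during.groupby("patient_id").size(),
        "manual", "index_episode", None)
    add("rx_days_index", during.groupby("patient_id")["days_supply"].sum(),
        "manual", "index_episode", None)
    add("rx_unique_index", during.groupby("patient_id")["atc_code"].nunique(),
        "manual", "index_episode", None)

    # ---- chronic-condition flags --------------------------------------------------
    claim_dx = _explode_codes(cl, "diagnosis_codes", "visit_date")
    claim_m = claim_dx.merge(_anchor_frame(cohort), on="patient_id", how="inner")
    dad_m = dd  # hospital diagnosis codes merged with anchors, computed above
    for rule in chronic_rules:
        flags = []
        for frame, date_col, prefixes, needed in [
            (dad_m, "admit_date", rule.hospital_prefixes, rule.n_hospital),
            (claim_m, "visit_date", rule.claim_prefixes, rule.n_claims),
        ]:
            lo = frame["anchor_discharge"] - pd.to_timedelta(rule.lookback_days, "D")
            sel = (
                (frame[date_col] >= lo)
                & (frame[date_col] <= frame["anchor_discharge"])
                & frame["code"].str.startswith(tuple(prefixes))
            )
            cnt = sel.groupby(frame["patient_id"]).sum()
            flags.append(cnt.reindex(idx).fillna(0) >= needed)
        add(f"chronic_{rule.name}", flags[0] | flags[1], "manual",
            "index_discharge", rule.lookback_days, fill=False)

    # ---- simplified lab features -----------------------------------------------------
    if lab_tests is None:
        lab_tests = sorted(bundle.labs["test_code"].unique())
    lb = bundle.labs.merge(_anchor_frame(cohort), on="patient_id", how="inner")
    lb = lb[
        (lb["date"] <= lb["anchor_discharge"])
        & (lb["date"] >= lb["anchor_discharge"] - pd.to_timedelta(WIN_2Y, "D"))
    ]
    lb = lb.sort_values("date", kind="mergesort").groupby(
        ["patient_id", "test_code"], sort=False
    ).last()
    cat = np.select(
        [lb["result_value"] < lb["reference_low"],
         lb["result_value"] > lb["reference_high"]],
        ["low", "high"],
        default="normal",
    )
    lb = lb.assign(category=cat).reset_index()
    pivot = lb.pivot(index="patient_id", columns="test_code", values="category")
    for test in lab_tests:
        col = (
            pivot[test].reindex(idx) if test in pivot.columns
            else pd.Series(np.nan, index=idx)
        )
        add(f"lab_{test}", col.fillna("missing"), "manual",
            "index_discharge", WIN_2Y, fill="missing")

    # ---- LACE ---------------------------------------------------------------------
    lace_vals = scores.lace_bulk(
        feat["index_los_days"].to_numpy(),
        feat["admitted_via_ed"].to_numpy(),
        feat["charlson_730d"].to_numpy().astype(int),
        feat["ed_visits_182d"].to_numpy().astype(int),
    )
    add("lace_score", lace_vals, "lace", "index_episode", None)

    # tidy dtypes: counts to int
    for col, m in meta.items():
        if feat[col].dtype == float and col.startswith(
            ("n_", "hosp_days", "ed_visits", "outpatient_visits", "visits_",
             "rx_", "index_", "charlson")
        ):
            feat[col] = feat[col].astype(int)
    return feat, meta


class FeatureEncoder:
    """Deterministic design-matrix encoder with a fit/transform contract.

    Categorical columns are one-hot encoded against the category vocabulary
    observed at fit time; a category unseen at transform time maps to the
    column's explicit ``=__other__`` indicator.  Booleans become 0/1 and
    numeric columns pass through.  Column order follows the input frame.
    """

    def __init__(self):
        self.columns_: list[str] | None = None
        self.categories_: dict[str, list[str]] = {}
        self.encoded_columns_: list[str] = []
        self.column_meta_: list[dict] = []

    def fit(self, feat: pd.DataFrame, meta: dict) -> "FeatureEncoder":
        self.columns_ = list(feat.columns)
        self.categories_ = {}
        self.encoded_columns_ = []
        self.column_meta_ = []
        for col in self.columns_:
            group = meta[col]["group"]
            if feat[col].dtype == object or str(feat[col].dtype) == "category":
                cats = sorted(feat[col].astype(str).unique())
                self.categories_[col] = cats
                for c in cats + ["__other__"]:
                    self.encoded_columns_.append(f"{col}={c}")
                    self.column_meta_.append(
                        {"column": f"{col}={c}", "source": col, "group": group}
                    )
            else:
                self.encoded_columns_.append(col)
                self.column_meta_.append({"column": col, "source": col, "group": group})
        return self

    def transform(self, feat: pd.DataFrame) -> np.ndarray:
        if self.columns_ is None:
            raise RuntimeError("encoder not fitted")
        blocks = []
        for col in self.columns_:
            if col in self.categories_:
                cats = self.categories_[col]
                vals = feat[col].astype(str).to_numpy()
                known = np.isin(vals, cats)
                block = np.zeros((len(feat), len(cats) + 1))
                pos = {c: i for i, c in enumerate(cats)}
                for i, (v, k) in enumerate(zip(vals, known)):
                    block[i, pos[v] if k else len(cats)] = 1.0
                blocks.append(block)
            else:
                blocks.append(
                    feat[col].astype(float).to_numpy().reshape(-1, 1)
                )
        return np.hstack(blocks)

    def fit_transform(self, feat: pd.DataFrame, meta: dict) -> np.ndarray:
        return self.fit(feat, meta).transform(feat)

    def group_mask(self, groups: set[str]) -> np.ndarray:
        """Boolean mask over encoded columns whose source group is in ``groups``."""
        return np.array([m["group"] in groups for m in self.column_meta_])
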