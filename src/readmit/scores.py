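"""Deterministic clinical scores: Charlson comorbidity, LACE, chronic flags.

The Charlson Comorbidity Index is computed from ICD-10-style diagnosis codes
with the standard prefix-based coding algorithm (shipped as an editable data
file ``data/charlson_map.csv``: one row per code prefix with its condition
and original integer weight).  Hierarchy rules are applied as supersession
pairs — a metastatic tumour supersedes a primary malignancy, complicated
diabetes supersedes uncomplicated, severe liver disease supersedes mild — so
adding codes can never lower the score.

The LACE index sums points for Length of stay, Acuity (emergent admission),
Charlson score, and Emergency-department visits in the prior six months; the
point bins live in ``data/lace_points.csv`` and total at most 19.

Chronic-condition flags (asthma, hypertension, heart failure, diabetes)
follow administrative case definitions of the usual "1 hospitalization code
or 2 physician claims within a lookback window" shape; prefixes, counts and
windows are configurable per condition.
"""

from __future__ import annotations

import dataclasses
import datetime as dt
from functools import lru_cache
from importlib import resources

import numpy as np
import pandas as pd

__all__ = [
    "load_charlson_map",
    "load_lace_points",
    "normalize_dx",
    "charlson",
    "charlson_conditions",
    "charlson_bulk",
    "lace",
    "lace_bulk",
    "ChronicRule",
    "DEFAULT_CHRONIC_RULES",
    "chronic_flags",
    "SUPERSEDES",
]

#: condition -> condition it supersedes when both are present
SUPERSEDES = {
    "metastatic_cancer": "malignancy",
    "severe_liver_disease": "mild_liver_disease",
    "diabetes_complicated": "diabetes_uncomplicated",
}


def _data_path(name: str):
    return resources.files("readmit.data").joinpath(name)


@lru_cache(maxsize=None)
def load_charlson_map() -> pd.DataFrame:
    """Prefix table: columns ``condition, prefix, weight``."""
    with resources.as_file(_data_path("charlson_map.csv")) as p:
        df = pd.read_csv(p, dtype={"prefix": str})
    if (df["weight"] < 1).any():
        raise ValueError("charlson_map.csv: weights must be >= 1")
    if (df["prefix"] != df["prefix"].str.upper()).any():
        raise ValueError("charlson_map.csv: prefixes must be uppercase")
    return df


@lru_cache(maxsize=None)
def load_lace_points() -> pd.DataFrame:
    """Bin table: columns ``component, min, max, points`` (max empty = open)."""
    with resources.as_file(_data_path("lace_points.csv")) as p:
        df = pd.read_csv(p)
    df["max"] = df["max"].fillna(np.inf)
    return df


def normalize_dx(code: str) -> str:
    """Uppercase and strip periods/whitespace from a diagnosis code."""
    return str(code).upper().replace(".", "").strip()


@lru_cache(maxsize=None)
def _prefix_lookup() -> tuple[dict, dict, dict]:
    cmap = load_charlson_map()
    weights = dict(zip(cmap["condition"], cmap["weight"]))
    by3 = {p: c for p, c in zip(cmap["prefix"], cmap["condition"]) if len(p) == 3}
    by4 = {p: c for p, c in zip(cmap["prefix"], cmap["condition"]) if len(p) == 4}
    return by3, by4, weights


def charlson_conditions(codes) -> set[str]:
    """Set of Charlson conditions matched by any code, after supersession."""
    by3, by4, _ = _prefix_lookup()
    conds = set()
    for raw in codes:
        code = normalize_dx(raw)
        if code[:3] in by3:
            conds.add(by3[code[:3]])
        if code[:4] in by4:
            conds.add(by4[code[:4]])
    for winner, loser in SUPERSEDES.items():
        if winner in conds:
            conds.discard(loser)
    return conds


def charlson(codes) -> int:
    """Charlson Comorbidity Index of a code collection (0 if nothing matches)."""
    _, _, weights = _prefix_lookup()
    return int(sum(weights[c] for c in charlson_conditions(codes)))


def charlson_bulk(codes: pd.DataFrame) -> pd.Series:
    """Per-patient Charlson from a long frame with columns ``patient_id, code``.

    Codes must already be normalized (uppercase, no punctuation).
    """
    if len(codes) == 0:
        return pd.Series(dtype=int)
    by3, by4, weights = _prefix_lookup()
    c = codes["code"]
    cond = c.str.slice(0, 4).map(by4)
    cond = cond.fillna(c.str.slice(0, 3).map(by3))
    hits = codes.assign(condition=cond).dropna(subset=["condition"])
    # note: a single code can in principle hit both a 3- and a 4-char prefix of
    # different conditions; the 4-char (more specific) match wins here, which
    # matches the shipped table where 4-char prefixes refine 3-char families.
    per = hits.drop_duplicates(["patient_id", "condition"])
    pivot = per.groupby("patient_id")["condition"].agg(set)

    def score(conds: set) -> int:
        conds = set(conds)
        for winner, loser in SUPERSEDES.items():
            if winner in conds:
                conds.discard(loser)
        return sum(weights[c] for c in conds)

    return pivot.map(score).astype(int)


def _step_points(table: pd.DataFrame, component: str, value) -> np.ndarray:
    rows = table[table["component"] == component]
    v = np.atleast_1d(np.asarray(value, dtype=float))
    pts = np.zeros(len(v), dtype=int)
    matched = np.zeros(len(v), dtype=bool)
    for _, r in rows.iterrows():
        m = (v >= r["min"]) & (v <= r["max"])
        pts[m] = int(r["points"])
        matched |= m
    if not matched.all():
        raise ValueError(f"LACE component {component!r}: value out of table range")
    return pts


def lace(
    los_days: int, admitted_via_ed: bool, charlson_score: int, ed_visits_6m: int
) -> int:
    """LACE score in [0, 19] from its four components."""
    if min(los_days, charlson_score, ed_visits_6m) < 0:
        raise ValueError("LACE inputs must be non-negative")
    return int(
        lace_bulk(
            np.array([los_days]),
            np.array([bool(admitted_via_ed)]),
            np.array([charlson_score]),
            np.array([ed_visits_6m]),
        )[0]
    )


def lace_bulk(los_days, admitted_via_ed, charlson_score, ed_visits_6m) -> np.ndarray:
    """Vectorized LACE over aligned component arrays."""
    table = load_lace_points()
    if min(np.min(los_days, initial=0), np.min(charlson_score, initial=0),
           np.min(ed_visits_6m, initial=0)) < 0:
        raise ValueError("LACE inputs must be non-negative")
    return (
        _step_points(table, "los", los_days)
        + _step_points(table, "acuity", np.asarray(admitted_via_ed).astype(int))
        + _step_points(table, "charlson", charlson_score)
        + _step_points(table, "ed_visits", ed_visits_6m)
    )


@dataclasses.dataclass(frozen=True)
class ChronicRule:
    """Case definition for one chronic condition."""

    name: str
    hospital_prefixes: tuple[str, ...]
    claim_prefixes: tuple[str, ...]
    n_hospital: int = 1
    n_claims: int = 2
    lookback_days: int = 730

    def __post_init__(self):
        if self.n_hospital < 1 or self.n_claims < 1:
            raise ValueError("occurrence counts must be >= 1")


DEFAULT_CHRONIC_RULES = (
    ChronicRule("asthma", ("J45", "J46"), ("493",)),
    ChronicRule("hypertension", ("I10", "I11", "I12", "I13", "I15"),
                ("401", "402", "403", "404", "405")),
    ChronicRule("heart_failure", ("I50",), ("428",)),
    ChronicRule("diabetes", ("E10", "E11", "E12", "E13", "E14"), ("250",)),
)


def _count_matches(dated_codes, prefixes, lo, hi) -> int:
    n = 0
    for d, raw in dated_codes:
        if lo <= d <= hi:
            code = normalize_dx(raw)
            if any(code.startswith(p) for p in prefixes):
                n += 1
    return n


def chronic_flags(
    hospital_codes: list[tuple[dt.date, str]],
    claim_codes: list[tuple[dt.date, str]],
    as_of: dt.date,
    rules=DEFAULT_CHRONIC_RULES,
) -> dict[str, bool]:
    """Per-condition flags from dated (date, code) events ending at ``as_of``."""
    out = {}
    for rule in rules:
        lo = as_of - dt.timedelta(days=rule.lookback_days)
        n_h = _count_matches(hospital_codes, rule.hospital_prefixes, lo, as_of)
        n_c = _count_matches(claim_codes, rule.claim_prefixes, lo, as_of)
        out[rule.name] = n_h >= rule.n_hospital or n_c >= rule.n_claims
    return out
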