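"""Patient "sentences": chronologically ordered normalized medical codes.

Every medical data entry a patient accrues — hospital diagnosis and procedure
codes, ambulatory codes, claim diagnoses, dispensed ATC codes, and optional
event markers such as an emergent admission — becomes one word.  Codes are
normalized (uppercased, periods and whitespace stripped: ``"1.SQ.52"`` becomes
``"1SQ52"``) and sorted by date; ties on the same day are broken by a fixed
source order and then lexicographically, so sentences are reproducible.

Sentences are always built up to a per-patient cutoff date (the index-episode
discharge by default), so nothing dated after the prediction time can leak
into embedding training or patient vectors.
"""

from __future__ import annotations

import dataclasses
import datetime as dt

import pandas as pd

from .bundle import RecordBundle

__all__ = ["PatientSentence", "normalize_code", "build_sentence", "build_sentences",
           "EMERGENT_ADMISSION_TOKEN"]

EMERGENT_ADMISSION_TOKEN = "EMERGADMIT"

#: fixed source order for same-day ties
_SOURCE_RANKS = {
    "event": 0,
    "dad_diagnosis": 1,
    "dad_procedure": 2,
    "nacrs_diagnosis": 3,
    "nacrs_procedure": 4,
    "claim_diagnosis": 5,
    "atc": 6,
}


@dataclasses.dataclass
class PatientSentence:
    patient_id: str
    tokens: list[str]
    dates: list[dt.date]

    def __post_init__(self):
        assert len(self.tokens) == len(self.dates)

    def __len__(self):
        return len(self.tokens)

    def text(self) -> str:
        return " ".join(self.tokens)


def normalize_code(raw: str) -> str | None:
    """Uppercase and strip periods/whitespace; ``None`` if nothing remains."""
    token = "".join(str(raw).upper().split()).replace(".", "")
    return token or None


def build_sentence(events, cutoff: dt.date, patient_id: str = "") -> PatientSentence:
    """Build one sentence from ``(date, source, raw_code)`` triples.

    ``source`` is one of the keys of the fixed source-order table (unknown
    sources sort last).  Events dated after ``cutoff`` are dropped; codes that
    normalize to nothing are rejected.
    """
    rows = []
    for date, source, raw in events:
        d = date.date() if hasattr(date, "date") else date
        if d > cutoff:
            continue
        token = normalize_code(raw)
        if token is None:
            continue
        rows.append((d, _SOURCE_RANKS.get(source, len(_SOURCE_RANKS)), token))
    rows.sort()
    return PatientSentence(
        patient_id=patient_id,
        tokens=[t for _, _, t in rows],
        dates=[d for d, _, _ in rows],
    )


def _code_events(df, code_col, date_col, source):
    sub = df.loc[df[code_col] != "", ["patient_id", date_col, code_col]]
    sub = sub.assign(token=sub[code_col].str.split(" ")).explode("token")
    return pd.DataFrame(
        {
            "patient_id": sub["patient_id"],
            "date": sub[date_col],
            "rank": _SOURCE_RANKS[source],
            "token": sub["token"],
        }
    )


def build_sentences(
    bundle: RecordBundle,
    cutoffs: pd.Series,
    include_event_tokens: bool = True,
) -> dict[str, PatientSentence]:
    """Sentences for every patient in ``cutoffs`` (patient_id -> cutoff date).

    Vectorized over the whole bundle; returns a dict keyed by patient id.
    Patients with no events before their cutoff get an empty sentence.
    """
    parts = [
        _code_events(bundle.hospitalizations, "diagnosis_codes", "admit_date",
                     "dad_diagnosis"),
        _code_events(bundle.hospitalizations, "procedure_codes", "admit_date",
                     "dad_procedure"),
        _code_events(bundle.ambulatory, "diagnosis_codes", "visit_date",
                     "nacrs_diagnosis"),
        _code_events(bundle.ambulatory, "procedure_codes", "visit_date",
                     "nacrs_procedure"),
        _code_events(bundle.claims, "diagnosis_codes", "visit_date",
                     "claim_diagnosis"),
        pd.DataFrame(
            {
                "patient_id": bundle.prescriptions["patient_id"],
                "date": bundle.prescriptions["dispense_date"],
                "rank": _SOURCE_RANKS["atc"],
                "token": bundle.prescriptions["atc_code"],
            }
        ),
    ]
    if include_event_tokens:
        ed = bundle.hospitalizations[bundle.hospitalizations["admitted_via_ed"]]
        parts.append(
            pd.DataFrame(
                {
                    "patient_id": ed["patient_id"],
                    "date": ed["admit_date"],
                    "rank": _SOURCE_RANKS["event"],
                    "token": EMERGENT_ADMISSION_TOKEN,
                }
            )
        )
    ev = pd.concat(parts, ignore_index=True)
    ev["token"] = (
        ev["token"].str.upper()
        .str.replace(".", "", regex=False)
        .str.replace(r"\s", "", regex=True)
    )
    ev = ev[ev["token"] != ""]
    cut = cutoffs.rename("cutoff")
    cut.index.name = "patient_id"
    ev = ev.merge(cut, left_on="patient_id", right_index=True, how="inner")
    ev = ev[ev["date"] <= pd.to_datetime(ev["cutoff"])]
    ev = ev.sort_values(["patient_id", "date", "rank", "token"], kind="mergesort")
    grouped_tokens = ev.groupby("patient_id", sort=False)["token"].agg(list)
    grouped_dates = ev.groupby("patient_id", sort=False)["date"].agg(list)
    out = {}
    for pid in cutoffs.index:
        toks = grouped_tokens.get(pid, [])
        dates = grouped_dates.get(pid, [])
        out[pid] = PatientSentence(
            patient_id=pid,
            tokens=list(toks),
            dates=[d.date() for d in dates],
        )
    return out
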