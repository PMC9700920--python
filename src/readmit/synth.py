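"""Synthetic linked administrative health data with a planted risk structure.

The generator emulates the kind of population-level linked data a Canadian
province collects: per patient, a demographics row plus event streams in five
tables (hospital discharge abstracts, ambulatory visits, physician claims,
prescription dispenses, lab results) over a multi-year observation window.

The generative model is deliberately simple but gives every downstream stage
real signal to find:

* Each patient carries a latent standard-normal risk score ``z``.
* Utilization: per-table event rates are Poisson with rate scaled by
  ``exp(0.3 z)``, so high-risk patients use more care.
* Code content: synthetic-but-format-faithful vocabularies (``K65``-like
  diagnoses, ``1.SQ.52``-like procedures, ``J01DH``-like ATC codes) are
  partitioned into clusters; each patient is assigned a home cluster whose
  identity tilts with ``z``, and ~70% of their codes are drawn from it.  This
  plants both co-occurrence structure (for embeddings) and risk-correlated
  content.
* Outcome: after each hospital episode's final discharge, a 30-day
  readmission is planted with probability
  ``logistic(logit(base_readmit_rate) + risk_effect * z)``.  Background
  admissions are spaced more than 30 days after any prior discharge, so a
  realized 30-day readmission occurs if and only if it was planted — at
  ``risk_effect = 0`` the outcome is exactly independent of everything else.
* Chronic conditions (hypertension, diabetes, heart failure, asthma) are
  assigned with realistic prevalences tilted by ``z`` and leave both hospital
  diagnosis codes and physician-claim codes behind, so the validated
  case-definition algorithms have something to detect.

Everything is driven by a single seeded generator: identical configs produce
byte-identical bundles.
"""

from __future__ import annotations

import dataclasses
import datetime as dt

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from .bundle import RecordBundle

__all__ = ["SynthConfig", "CodeVocabulary", "generate", "CHRONIC_CONDITIONS"]

#: condition -> (hospital ICD-10-like code, claim ICD-9-like code, prevalence)
CHRONIC_CONDITIONS = {
    "hypertension": ("I10", "401", 0.29),
    "diabetes": ("E11", "250", 0.14),
    "heart_failure": ("I50", "428", 0.06),
    "asthma": ("J45", "493", 0.02),
}

_PSYCH_CODES = ["F20", "F32", "F41", "F60", "F99"]
_SUBSTANCE_CODES = ["F10", "F11", "F17", "F19"]  # exempt from the psychiatric exclusion

_FINAL_DISPOSITIONS = ["04", "05", "06", "07", "12"]
_FINAL_DISPOSITION_P = [0.080, 0.896, 0.011, 0.004, 0.009]
_TRANSFER_DISPOSITIONS = ["01", "02", "03"]

#: share of the overall per-patient event rate allocated to each table
_TABLE_SHARES = {"dad": 0.10, "nacrs": 0.28, "claims": 0.36, "pin": 0.16, "labs": 0.10}

_N_LAB_TESTS = 20


@dataclasses.dataclass(frozen=True)
class SynthConfig:
    """Study conditions for one synthetic population."""

    n_patients: int = 1000
    start_date: dt.date = dt.date(2011, 1, 1)
    end_date: dt.date = dt.date(2017, 12, 31)
    #: final N calendar years form the index-selection window
    index_years: int = 2
    base_readmit_rate: float = 0.06
    #: log-odds coefficient of the latent risk on 30-day readmission
    risk_effect: float = 1.0
    n_code_clusters: int = 10
    codes_per_cluster: int = 30
    mean_events_per_patient_year: float = 6.0
    seed: int = 0
    # population composition (defaults mirror a general admitted population)
    female_frac: float = 0.62
    ed_admit_frac: float = 0.88
    out_of_province_frac: float = 0.005
    psych_primary_frac: float = 0.04
    #: probability a hospital episode starts with a transfer-linked record pair
    chain_frac: float = 0.05
    #: utilization rate multiplier is exp(utilization_coef * z)
    utilization_coef: float = 0.3
    #: strength of the latent-risk tilt on cluster assignment
    cluster_risk_coef: float = 1.5

    def __post_init__(self):
        if self.n_patients < 1:
            raise ValueError("n_patients must be >= 1")
        if not 0.0 <= self.base_readmit_rate <= 1.0:
            raise ValueError("base_readmit_rate must be in [0, 1]")
        if self.start_date >= self.end_date:
            raise ValueError("start_date must precede end_date")
        if (self.end_date - self.start_date).days < 730:
            raise ValueError(
                "observation window shorter than 2 years cannot host lookback features"
            )
        if min(self.n_code_clusters, self.codes_per_cluster, self.index_years) < 1:
            raise ValueError("all counts must be >= 1")

    @property
    def window_days(self) -> int:
        return (self.end_date - self.start_date).days + 1

    @property
    def index_window(self) -> tuple[dt.date, dt.date]:
        """The index-selection years: the ``index_years`` calendar years before
        the final year, which is reserved for outcome follow-up."""
        return (
            dt.date(self.end_date.year - self.index_years, 1, 1),
            dt.date(self.end_date.year - 1, 12, 31),
        )


@dataclasses.dataclass
class CodeVocabulary:
    """Clustered synthetic code vocabularies (diagnoses, procedures, ATC)."""

    diag: np.ndarray  # (n_clusters, m_diag) ICD-10-like, e.g. "K65"
    proc: np.ndarray  # (n_clusters, m_proc) dotted raw form, e.g. "1.SQ.52"
    atc: np.ndarray  # (n_clusters, m_atc) e.g. "J01DH"
    claim_dx: np.ndarray  # global ICD-9-like 3-digit codes

    @property
    def n_clusters(self) -> int:
        return self.diag.shape[0]

    def cluster_tokens(self, c: int) -> set[str]:
        """Normalized tokens belonging to cluster ``c`` (for structure checks)."""
        toks = list(self.diag[c]) + [p.replace(".", "") for p in self.proc[c]]
        return set(toks) | set(self.atc[c])


def _make_vocabulary(rng: np.random.Generator, config: SynthConfig) -> CodeVocabulary:
    nc, per = config.n_code_clusters, config.codes_per_cluster
    m_diag = max(1, per // 2)
    m_proc = max(1, per // 4)
    m_atc = max(1, per - m_diag - m_proc)
    letters = np.array(list("ABCDEGHIJKLMNR"))  # no F (psychiatric), no O/P (obstetric)
    reserved = {code for code, _, _ in
                [(v[0], v[1], v[2]) for v in CHRONIC_CONDITIONS.values()]}
    seen: set[str] = set(reserved) | set(_PSYCH_CODES) | set(_SUBSTANCE_CODES)

    def draw_unique(make, count):
        out = []
        while len(out) < count:
            code = make()
            if code not in seen:
                seen.add(code)
                out.append(code)
        return out

    def mk_diag():
        return f"{rng.choice(letters)}{rng.integers(0, 100):02d}"

    def mk_proc():
        a = rng.integers(1, 10)
        b = "".join(rng.choice(letters, size=2))
        c = rng.integers(0, 100)
        return f"{a}.{b}.{c:02d}"

    def mk_atc():
        a = rng.choice(letters)
        b = rng.integers(0, 100)
        c = "".join(rng.choice(letters, size=2))
        return f"{a}{b:02d}{c}"

    diag = np.array([draw_unique(mk_diag, m_diag) for _ in range(nc)])
    proc = np.array([draw_unique(mk_proc, m_proc) for _ in range(nc)])
    atc = np.array([draw_unique(mk_atc, m_atc) for _ in range(nc)])
    claim_pool = [f"{v}" for v in rng.choice(np.arange(100, 1000), 80, replace=False)]
    claim_dx = np.array([c for c in claim_pool
                         if c not in {v[1] for v in CHRONIC_CONDITIONS.values()}])
    return CodeVocabulary(diag=diag, proc=proc, atc=atc, claim_dx=claim_dx)


def _assign_clusters(rng, z, config: SynthConfig) -> np.ndarray:
    """Home cluster per patient; higher-risk patients lean to 'severe' clusters."""
    nc = config.n_code_clusters
    severity = np.linspace(-1.0, 1.0, nc) if nc > 1 else np.zeros(1)
    logits = config.cluster_risk_coef * np.outer(z, severity)
    p = np.exp(logits - logits.max(axis=1, keepdims=True))
    p /= p.sum(axis=1, keepdims=True)
    u = rng.random(len(z))
    return (p.cumsum(axis=1) < u[:, None]).sum(axis=1)


def _draw_clustered(rng, event_cluster, cluster_mat, p_cluster=0.7):
    """Vectorized draw: from the event's cluster w.p. ``p_cluster``, else global."""
    m = len(event_cluster)
    if m == 0:
        return np.array([], dtype=cluster_mat.dtype)
    within = rng.random(m) < p_cluster
    col = rng.integers(0, cluster_mat.shape[1], m)
    flat = cluster_mat.ravel()
    g = rng.integers(0, flat.size, m)
    return np.where(within, cluster_mat[event_cluster, col], flat[g])


def _generate_hospitalizations(rng, config, z, cluster, chronic, vocab):
    """Sequential per-patient episode streams with planted 30-day readmissions.

    Returns a list of record dicts (day offsets, not dates).  Spacing rule:
    a new background episode never admits within 31 days of any earlier
    discharge, so the only admissions inside a 30-day post-discharge window
    are the planted readmissions.
    """
    w = config.window_days
    years = w / 365.25
    lam = _TABLE_SHARES["dad"] * config.mean_events_per_patient_year
    iw_lo, iw_hi = config.index_window
    idx_start = max(0, (iw_lo - config.start_date).days)
    idx_end = min(w - 2, (iw_hi - config.start_date).days)
    p_readmit = (
        expit(logit(config.base_readmit_rate) + config.risk_effect * z)
        if config.base_readmit_rate > 0
        else np.zeros(len(z))
    )
    util = np.exp(config.utilization_coef * z)
    chronic_codes = {c: CHRONIC_CONDITIONS[c][0] for c in CHRONIC_CONDITIONS}
    rows: list[dict] = []

    def make_codes(i, force_psych=False):
        # primary + secondary diagnoses and procedures for one record
        if force_psych:
            primary = _PSYCH_CODES[rng.integers(0, len(_PSYCH_CODES))]
        elif rng.random() < config.psych_primary_frac:
            pool = _SUBSTANCE_CODES if rng.random() < 0.5 else _PSYCH_CODES
            primary = pool[rng.integers(0, len(pool))]
        else:
            primary = _draw_clustered(rng, np.array([cluster[i]]), vocab.diag)[0]
        n_sec = rng.poisson(1.8)
        sec = list(_draw_clustered(rng, np.full(n_sec, cluster[i]), vocab.diag))
        for cond, code in chronic_codes.items():
            if chronic[cond][i] and rng.random() < 0.3:
                sec.append(code)
        n_proc = rng.poisson(1.2)
        procs = list(_draw_clustered(rng, np.full(n_proc, cluster[i]), vocab.proc))
        return " ".join([primary] + sec), " ".join(procs)

    def add_record(i, admit, disch, dispo, via_ed=None, force_psych=False):
        dx, procs = make_codes(i, force_psych)
        if via_ed is None:
            via_ed = bool(rng.random() < config.ed_admit_frac)
        rows.append(
            dict(
                patient=i,
                institution=f"INST{rng.integers(1, 31):02d}",
                admit_day=admit,
                discharge_day=disch,
                discharge_disposition=dispo,
                diagnosis_codes=dx,
                procedure_codes=procs,
                admitted_via_ed=via_ed,
            )
        )

    for i in range(config.n_patients):
        k = rng.poisson(lam * years * util[i])
        times = rng.integers(0, max(1, w - 60), size=k)
        forced = rng.integers(idx_start, max(idx_start + 1, idx_end - 10))
        times = np.sort(np.append(times, forced))
        last_discharge = -(10**9)
        alive = True
        for t in times:
            if not alive or t < last_discharge + 31:
                continue
            admit = int(t)
            disch = min(admit + min(int(rng.poisson(2.0)), 45), w - 1)
            chained = rng.random() < config.chain_frac and disch + 2 < w - 1
            if chained:
                # transfer-linked continuation: first record gets a transfer code
                t_dispo = _TRANSFER_DISPOSITIONS[rng.integers(0, 3)]
                add_record(i, admit, disch, t_dispo)
                admit2 = min(disch + int(rng.integers(0, 2)), w - 1)
                disch2 = min(admit2 + min(int(rng.poisson(2.0)), 45), w - 1)
                final_admit, disch = admit2, max(disch2, admit2)
            else:
                final_admit = admit
            dispo = _FINAL_DISPOSITIONS[
                rng.choice(len(_FINAL_DISPOSITIONS), p=_FINAL_DISPOSITION_P)
            ]
            add_record(i, final_admit, disch, dispo, via_ed=False if chained else None)
            last_discharge = disch
            if dispo == "07":
                alive = False
                continue
            # Outcome planting.  The readmission record carries a psychiatric
            # primary diagnosis: under the cohort rules it therefore counts as
            # an (all-cause) readmission outcome but can never itself become an
            # index candidate.  Every candidate episode's outcome is then an
            # independent logistic(base + risk_effect * z) coin, so at
            # risk_effect = 0 labels are exactly independent of everything.
            if p_readmit[i] > 0 and rng.random() < p_readmit[i]:
                r_admit = last_discharge + int(rng.integers(2, 31))
                if r_admit <= w - 1:
                    r_disch = min(r_admit + min(int(rng.poisson(2.0)), 45), w - 1)
                    r_dispo = _FINAL_DISPOSITIONS[
                        rng.choice(len(_FINAL_DISPOSITIONS), p=_FINAL_DISPOSITION_P)
                    ]
                    add_record(i, r_admit, r_disch, r_dispo, force_psych=True)
                    last_discharge = r_disch
                    if r_dispo == "07":
                        alive = False
    return rows


def generate(config: SynthConfig) -> RecordBundle:
    """Generate a linked-record bundle under ``config``; deterministic in seed."""
    rng = np.random.default_rng(config.seed)
    n, w = config.n_patients, config.window_days
    years = w / 365.25
    start = pd.Timestamp(config.start_date)

    vocab = _make_vocabulary(rng, config)
    z = rng.standard_normal(n)
    cluster = _assign_clusters(rng, z, config)
    util = np.exp(config.utilization_coef * z)
    chronic = {
        cond: rng.random(n) < expit(logit(prev) + 0.5 * z)
        for cond, (_, _, prev) in CHRONIC_CONDITIONS.items()
    }

    # --- demographics -----------------------------------------------------
    pid = np.array([f"P{i:07d}" for i in range(n)])
    sex = np.where(rng.random(n) < config.female_frac, "F", "M")
    age_days = rng.integers(0, 90 * 365, n)
    birth = start - pd.to_timedelta(age_days, unit="D")
    out_prov = rng.random(n) < config.out_of_province_frac
    prov = np.where(out_prov, rng.choice(list("VSKR"), n), "T")
    postal = np.array(
        [f"{p}{d}{l}" for p, d, l in
         zip(prov, rng.integers(0, 10, n), rng.choice(list("ABCEGHJKLM"), n))]
    )
    demographics = pd.DataFrame(
        {"patient_id": pid, "sex": sex, "birth_date": birth, "postal_prefix": postal}
    )

    # --- hospitalizations (sequential; carries the planted outcome) -------
    hosp_rows = _generate_hospitalizations(rng, config, z, cluster, chronic, vocab)
    if hosp_rows:
        hosp = pd.DataFrame(hosp_rows)
        hosp["patient_id"] = pid[hosp.pop("patient").to_numpy()]
        hosp["admit_date"] = start + pd.to_timedelta(hosp.pop("admit_day"), unit="D")
        hosp["discharge_date"] = start + pd.to_timedelta(
            hosp.pop("discharge_day"), unit="D"
        )
    else:  # degenerate tiny configs
        hosp = pd.DataFrame(
            columns=["institution", "discharge_disposition", "diagnosis_codes",
                     "procedure_codes", "admitted_via_ed", "patient_id",
                     "admit_date", "discharge_date"]
        )
    hosp = hosp.sort_values(
        ["patient_id", "admit_date", "discharge_date"], kind="mergesort"
    ).reset_index(drop=True)
    hosp.insert(0, "record_id", np.arange(len(hosp)))
    hosp = hosp[
        ["record_id", "patient_id", "institution", "admit_date", "discharge_date",
         "discharge_disposition", "diagnosis_codes", "procedure_codes",
         "admitted_via_ed"]
    ]

    # --- ambulatory visits -------------------------------------------------
    lam = _TABLE_SHARES["nacrs"] * config.mean_events_per_patient_year
    counts = rng.poisson(lam * years * util)
    ev_pat = np.repeat(np.arange(n), counts)
    m = len(ev_pat)
    day = rng.integers(0, w, m)
    mode = np.where(rng.random(m) < 0.35, "emergency", "non-emergency")
    dx1 = _draw_clustered(rng, cluster[ev_pat], vocab.diag)
    dx2 = _draw_clustered(rng, cluster[ev_pat], vocab.diag)
    has2 = rng.random(m) < 0.4
    dx = np.where(has2, [f"{a} {b}" for a, b in zip(dx1, dx2)], dx1) if m else dx1
    pr = _draw_clustered(rng, cluster[ev_pat], vocab.proc)
    pr = np.where(rng.random(m) < 0.3, pr, "")
    ambulatory = pd.DataFrame(
        {
            "patient_id": pid[ev_pat] if m else pd.Series([], dtype=str),
            "visit_date": start + pd.to_timedelta(day, unit="D"),
            "visit_mode": mode,
            "diagnosis_codes": dx,
            "procedure_codes": pr,
        }
    )

    # --- physician claims ---------------------------------------------------
    lam = _TABLE_SHARES["claims"] * config.mean_events_per_patient_year
    counts = rng.poisson(lam * years * util)
    ev_pat = np.repeat(np.arange(n), counts)
    m = len(ev_pat)
    day = rng.integers(0, w, m)
    spec = np.array(["family", "internal_medicine", "general_surgery"])[
        rng.choice(3, m, p=[0.75, 0.15, 0.10])
    ]
    paid = np.round(rng.lognormal(4.0, 0.6, m), 2)
    cdx = vocab.claim_dx[rng.integers(0, len(vocab.claim_dx), m)]
    frames = [
        pd.DataFrame(
            {"patient_id": pid[ev_pat] if m else pd.Series([], dtype=str),
             "visit_date": start + pd.to_timedelta(day, unit="D"),
             "specialty": spec, "paid_amount": paid, "diagnosis_codes": cdx}
        )
    ]
    # chronic-condition claims in the final 3 years (feeds the 2-claim rules)
    for cond, (_, claim_code, _) in CHRONIC_CONDITIONS.items():
        who = np.flatnonzero(chronic[cond])
        extra = 2 + rng.poisson(1.0, len(who))
        ev = np.repeat(who, extra)
        me = len(ev)
        if me == 0:
            continue
        day_e = rng.integers(max(0, w - 1095), w, me)
        frames.append(
            pd.DataFrame(
                {"patient_id": pid[ev],
                 "visit_date": start + pd.to_timedelta(day_e, unit="D"),
                 "specialty": "family",
                 "paid_amount": np.round(rng.lognormal(4.0, 0.6, me), 2),
                 "diagnosis_codes": claim_code}
            )
        )
    claims = pd.concat(frames, ignore_index=True)

    # --- prescriptions -------------------------------------------------------
    lam = _TABLE_SHARES["pin"] * config.mean_events_per_patient_year
    counts = rng.poisson(lam * years * util)
    ev_pat = np.repeat(np.arange(n), counts)
    m = len(ev_pat)
    prescriptions = pd.DataFrame(
        {
            "patient_id": pid[ev_pat] if m else pd.Series([], dtype=str),
            "atc_code": _draw_clustered(rng, cluster[ev_pat], vocab.atc),
            "dispense_date": start + pd.to_timedelta(rng.integers(0, w, m), unit="D"),
            "quantity": rng.integers(10, 121, m),
            "days_supply": np.array([0, 7, 14, 30, 90])[
                rng.choice(5, m, p=[0.02, 0.18, 0.15, 0.45, 0.20])
            ],
        }
    )

    # --- labs ----------------------------------------------------------------
    lab_lo = np.round(rng.uniform(1, 5, _N_LAB_TESTS), 1)
    lab_hi = np.round(lab_lo + rng.uniform(2, 10, _N_LAB_TESTS), 1)
    lam = _TABLE_SHARES["labs"] * config.mean_events_per_patient_year
    counts = rng.poisson(lam * years * util)
    ev_pat = np.repeat(np.arange(n), counts)
    m = len(ev_pat)
    t_idx = rng.integers(0, _N_LAB_TESTS, m)
    frac = rng.normal(0.5, 0.35, m) + 0.12 * z[ev_pat]
    labs = pd.DataFrame(
        {
            "patient_id": pid[ev_pat] if m else pd.Series([], dtype=str),
            "test_code": np.array([f"LAB{i + 1:02d}" for i in range(_N_LAB_TESTS)])[t_idx],
            "date": start + pd.to_timedelta(rng.integers(0, w, m), unit="D"),
            "result_value": np.round(lab_lo[t_idx] + frac * (lab_hi[t_idx] - lab_lo[t_idx]), 2),
            "reference_low": lab_lo[t_idx],
            "reference_high": lab_hi[t_idx],
        }
    )

    for df, col in [(ambulatory, "visit_date"), (claims, "visit_date"),
                    (prescriptions, "dispense_date"), (labs, "date")]:
        df.sort_values(["patient_id", col], kind="mergesort", inplace=True)
        df.reset_index(drop=True, inplace=True)

    truth = pd.DataFrame({"patient_id": pid, "latent_risk": z, "cluster": cluster})
    bundle = RecordBundle(
        demographics=demographics,
        hospitalizations=hosp,
        ambulatory=ambulatory,
        claims=claims,
        prescriptions=prescriptions,
        labs=labs,
        truth=truth,
    )
    bundle.vocabulary = vocab  # ground-truth clusters, for structure checks
    return bundle
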