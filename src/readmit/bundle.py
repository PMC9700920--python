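"""Linked administrative tables: in-memory container, validation, and CSV round-trip.

A :class:`RecordBundle` holds the six linked tables the pipeline consumes —
demographics, hospitalizations (DAD-like discharge abstracts), ambulatory
visits (NACRS-like), physician claims, prescriptions (PIN-like), and lab
results — all keyed by ``patient_id``.  Cells that hold several medical codes
(e.g. the ordered diagnosis list of a hospitalization) are stored as a single
space-joined string; the first diagnosis code is the primary one.

Everything is serialized as plain comma-separated text with ISO-8601 dates,
one file per table, so a bundle directory is portable and diffable.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import pandas as pd

__all__ = [
    "RecordBundle",
    "BundleValidationError",
    "TABLE_FILES",
    "write_bundle",
    "read_bundle",
    "validate_bundle",
    "bundles_equal",
]

#: table attribute -> file name inside a bundle directory
TABLE_FILES = {
    "demographics": "demographics.csv",
    "hospitalizations": "dad.csv",
    "ambulatory": "nacrs.csv",
    "claims": "claims.csv",
    "prescriptions": "pin.csv",
    "labs": "labs.csv",
}

_DATE_COLUMNS = {
    "demographics": ["birth_date"],
    "hospitalizations": ["admit_date", "discharge_date"],
    "ambulatory": ["visit_date"],
    "claims": ["visit_date"],
    "prescriptions": ["dispense_date"],
    "labs": ["date"],
}

_STR_COLUMNS = {
    "demographics": ["patient_id", "sex", "postal_prefix"],
    "hospitalizations": [
        "patient_id",
        "institution",
        "discharge_disposition",
        "diagnosis_codes",
        "procedure_codes",
    ],
    "ambulatory": ["patient_id", "visit_mode", "diagnosis_codes", "procedure_codes"],
    "claims": ["patient_id", "specialty", "diagnosis_codes"],
    "prescriptions": ["patient_id", "atc_code"],
    "labs": ["patient_id", "test_code"],
}


class BundleValidationError(ValueError):
    """Raised when a bundle violates its invariants; names table and row."""


@dataclasses.dataclass
class RecordBundle:
    """The six linked administrative tables, plus optional simulation truth.

    ``truth`` (``patient_id``, ``latent_risk``, ``cluster``) is only present
    on synthetic bundles; it is ground truth for oracle evaluation and is
    never consumed by cohort construction, features, or models.
    """

    demographics: pd.DataFrame
    hospitalizations: pd.DataFrame
    ambulatory: pd.DataFrame
    claims: pd.DataFrame
    prescriptions: pd.DataFrame
    labs: pd.DataFrame
    truth: pd.DataFrame | None = None

    def tables(self) -> dict[str, pd.DataFrame]:
        return {name: getattr(self, name) for name in TABLE_FILES}

    @property
    def n_patients(self) -> int:
        return len(self.demographics)


def _prepare_for_write(name: str, df: pd.DataFrame) -> pd.DataFrame:
    out = df.copy()
    for col in _DATE_COLUMNS.get(name, []):
        out[col] = pd.to_datetime(out[col]).dt.strftime("%Y-%m-%d")
    for col in out.columns:
        if out[col].dtype == bool:
            out[col] = out[col].astype(int)
    return out


def write_bundle(bundle: RecordBundle, directory: str | Path) -> list[Path]:
    """Write one CSV per table (plus truth.csv for synthetic bundles)."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    written = []
    for name, fname in TABLE_FILES.items():
        path = directory / fname
        _prepare_for_write(name, getattr(bundle, name)).to_csv(path, index=False)
        written.append(path)
    if bundle.truth is not None:
        path = directory / "truth.csv"
        bundle.truth.to_csv(path, index=False)
        written.append(path)
    return written


def _read_table(name: str, path: Path) -> pd.DataFrame:
    if not path.exists():
        raise BundleValidationError(f"missing table file for '{name}': {path}")
    dtype = {col: str for col in _STR_COLUMNS[name]}
    try:
        df = pd.read_csv(path, dtype=dtype, keep_default_na=False, na_values=[])
    except Exception as exc:  # malformed header / unreadable file
        raise BundleValidationError(f"malformed table '{name}' at {path}: {exc}") from exc
    expected = set(_STR_COLUMNS[name]) | set(_DATE_COLUMNS[name])
    missing = expected - set(df.columns)
    if missing:
        raise BundleValidationError(
            f"table '{name}' is missing columns {sorted(missing)}"
        )
    for col in _DATE_COLUMNS[name]:
        parsed = pd.to_datetime(df[col], format="%Y-%m-%d", errors="coerce")
        bad = parsed.isna() & df[col].notna() & (df[col].astype(str) != "")
        if bad.any():
            row = int(bad.idxmax())
            raise BundleValidationError(
                f"table '{name}' row {row}: cannot parse date "
                f"{df.loc[row, col]!r} in column '{col}'"
            )
        df[col] = parsed
    return df


def read_bundle(directory: str | Path, validate: bool = True) -> RecordBundle:
    """Read a bundle directory written by :func:`write_bundle`.

    Errors name the offending table (and row, for invariant violations).
    """
    directory = Path(directory)
    frames = {
        name: _read_table(name, directory / fname)
        for name, fname in TABLE_FILES.items()
    }
    if "admitted_via_ed" in frames["hospitalizations"].columns:
        frames["hospitalizations"]["admitted_via_ed"] = (
            frames["hospitalizations"]["admitted_via_ed"].astype(int).astype(bool)
        )
    truth_path = directory / "truth.csv"
    truth = pd.read_csv(truth_path) if truth_path.exists() else None
    bundle = RecordBundle(truth=truth, **frames)
    if validate:
        validate_bundle(bundle)
    return bundle


def validate_bundle(bundle: RecordBundle) -> None:
    """Check bundle invariants; raise :class:`BundleValidationError` on the first hit."""
    hosp = bundle.hospitalizations
    bad = hosp["discharge_date"] < hosp["admit_date"]
    if bad.any():
        row = int(bad.idxmax())
        raise BundleValidationError(
            f"table 'hospitalizations' row {row}: discharge_date "
            f"{hosp.loc[row, 'discharge_date'].date()} before admit_date "
            f"{hosp.loc[row, 'admit_date'].date()}"
        )
    known = set(bundle.demographics["patient_id"])
    for name, date_col in [
        ("hospitalizations", "admit_date"),
        ("ambulatory", "visit_date"),
        ("claims", "visit_date"),
        ("prescriptions", "dispense_date"),
        ("labs", "date"),
    ]:
        df = getattr(bundle, name)
        ids = df["patient_id"]
        unknown = ~ids.isin(known) & (ids != "") & ids.notna()
        if unknown.any():
            row = int(unknown.idxmax())
            raise BundleValidationError(
                f"table '{name}' row {row}: patient_id "
                f"{ids.iloc[row]!r} not in demographics"
            )
    if (bundle.claims["paid_amount"] < 0).any():
        row = int((bundle.claims["paid_amount"] < 0).idxmax())
        raise BundleValidationError(f"table 'claims' row {row}: negative paid_amount")
    if (bundle.prescriptions["days_supply"] < 0).any():
        row = int((bundle.prescriptions["days_supply"] < 0).idxmax())
        raise BundleValidationError(
            f"table 'prescriptions' row {row}: negative days_supply"
        )


def bundles_equal(a: RecordBundle, b: RecordBundle) -> bool:
    """Field-for-field equality of the six tables (used for round-trip checks)."""
    for name in TABLE_FILES:
        x, y = getattr(a, name), getattr(b, name)
        try:
            pd.testing.assert_frame_equal(
                x.reset_index(drop=True), y.reset_index(drop=True), check_dtype=False
            )
        except AssertionError:
            return False
    return True
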