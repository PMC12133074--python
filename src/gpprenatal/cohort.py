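"""Pregnancy cohort identification and the exclusion cascade.

Pregnancy status is established per contact through three routes: (1) at least
one pregnancy-defining ICPC code on the contact (miscarriage codes count;
W90 "normal delivery liveborn" never does, because of false carry-over
registrations); (2) a case-insensitive free-text pattern match in the
physician's note, which only makes the contact a *candidate* until a manual
assessment confirms it; (3) the manual assessment itself, supplied as a
machine-readable verdict table. Contacts for which none of the routes is
irrefutable are excluded as indeterminate.

The exclusion cascade then removes patients (death in period, deregistration,
deregistration reason without date, unknown birth date, registration shorter
than a configurable minimum, missing pseudonymization data) and contacts
(age outside 20-45 at contact date, weekends, holidays, outside office hours),
auditing each entity once at the first rule that removes it.
"""

from __future__ import annotations

import datetime as dt
import json
import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .config import (
    ConfigurationError,
    DEFAULT_PREGNANCY_CODES,
    DEFAULT_TEXT_PATTERN,
    EXCLUDED_DELIVERY_CODE,
    STUDY_END,
    STUDY_START,
    ValidationError,
)

__all__ = [
    "parse_icpc_field",
    "flag_by_icpc",
    "flag_by_text",
    "merge_evidence",
    "label_contacts",
    "apply_exclusions",
    "select_cohort",
    "compute_denominators",
    "ExclusionAudit",
]

_ICPC_RE = re.compile(r"^[A-Z]\d{2}(\.\d{2})?$")

CONFIRMED_ICPC = "confirmed_icpc"
CONFIRMED_TEXT_MANUAL = "confirmed_text_manual"
EXCLUDED_INDETERMINATE = "excluded_indeterminate"

#: patient-level exclusion rules, applied in this order
PATIENT_RULES = (
    "died_in_period",
    "deregistered_in_period",
    "deregistration_reason_without_date",
    "unknown_birth_date",
    "registered_lt_min_days",
    "missing_zip",
    "no_included_contacts",
)
CONTACT_RULES = (
    "age_outside_range",
    "patient_excluded",
    "not_confirmed_pregnant",
    "weekend",
    "holiday",
    "outside_office_hours",
)


def parse_icpc_field(field_value: str, row_id: str | None = None) -> list[str]:
    """Split a ';'-separated ICPC field, validating each code (letter + two
    digits, optional two-digit subcode)."""
    codes = [c.strip() for c in str(field_value).split(";") if c.strip()]
    for c in codes:
        if not _ICPC_RE.match(c):
            where = f" in row {row_id}" if row_id else ""
            raise ValidationError(f"malformed ICPC code {c!r}{where}")
    return codes


def flag_by_icpc(
    icpc_codes: Iterable[str] | str,
    pregnancy_codes: frozenset[str] | set[str] = DEFAULT_PREGNANCY_CODES,
) -> tuple[bool, list[str]]:
    """True iff the contact carries at least one pregnancy-defining code.

    Subcoded registrations match through their base code (W84.02 matches a set
    containing W84). The delivery code W90 must not be in the defining set.
    """
    if not pregnancy_codes:
        raise ConfigurationError("pregnancy code set is empty")
    if EXCLUDED_DELIVERY_CODE in pregnancy_codes:
        raise ConfigurationError(
            f"{EXCLUDED_DELIVERY_CODE} must not define pregnancy status")
    if isinstance(icpc_codes, str):
        icpc_codes = parse_icpc_field(icpc_codes)
    matched = [
        c for c in icpc_codes
        if (c in pregnancy_codes or c.split(".")[0] in pregnancy_codes)
        and c.split(".")[0] != EXCLUDED_DELIVERY_CODE
    ]
    return bool(matched), matched


def flag_by_text(
    note_text: str, pattern: str | re.Pattern = DEFAULT_TEXT_PATTERN
) -> tuple[bool, list[tuple[int, int]]]:
    """All non-overlapping case-insensitive match spans of the pregnancy
    pattern in the note. A match makes the contact a candidate only; manual
    confirmation decides (see :func:`merge_evidence`)."""
    if isinstance(pattern, str):
        try:
            pattern = re.compile(pattern, re.IGNORECASE)
        except re.error as exc:
            raise ConfigurationError(f"invalid text pattern: {exc}") from exc
    spans = [m.span() for m in pattern.finditer(note_text or "")]
    return bool(spans), spans


def merge_evidence(icpc_flag: bool, text_flag: bool, manual_label: str = "absent") -> str:
    """Combine the three evidence routes into one contact label.

    An ICPC match confirms directly (a manual ``reject`` overrides it); a text
    match confirms only together with a manual ``confirm``; anything else is
    indeterminate and excluded.
    """
    if manual_label not in ("confirm", "reject", "absent"):
        raise ValidationError(f"unknown manual label {manual_label!r}")
    if icpc_flag:
        return EXCLUDED_INDETERMINATE if manual_label == "reject" else CONFIRMED_ICPC
    if text_flag and manual_label == "confirm":
        return CONFIRMED_TEXT_MANUAL
    return EXCLUDED_INDETERMINATE


def label_contacts(
    contacts: pd.DataFrame,
    pregnancy_codes=DEFAULT_PREGNANCY_CODES,
    text_pattern: str = DEFAULT_TEXT_PATTERN,
    manual_labels: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Per-contact pregnancy labels with their evidence.

    Returns a DataFrame (contact_id, patient_id, icpc_flag, matched_codes,
    text_flag, matched_spans, manual, status). Duplicate conflicting manual
    verdicts for one contact raise :class:`ValidationError`.
    """
    manual: dict[str, str] = {}
    if manual_labels is not None and len(manual_labels):
        for row in manual_labels.itertuples(index=False):
            cid, verdict = str(row.contact_id), str(row.verdict)
            if cid in manual and manual[cid] != verdict:
                raise ValidationError(f"conflicting manual labels for contact {cid}")
            manual[cid] = verdict
    pattern = re.compile(text_pattern, re.IGNORECASE)
    rows = []
    for row in contacts.itertuples(index=False):
        codes = parse_icpc_field(row.icpc_codes, row_id=row.contact_id)
        if not codes:
            raise ValidationError(
                f"contact {row.contact_id} carries no ICPC code")
        iflag, matched = flag_by_icpc(codes, pregnancy_codes)
        tflag, spans = flag_by_text(row.note_text, pattern)
        m = manual.get(str(row.contact_id), "absent")
        status = merge_evidence(iflag, tflag, m)
        rows.append((row.contact_id, row.patient_id, iflag, ";".join(matched),
                     tflag, json.dumps(spans), m, status))
    return pd.DataFrame(rows, columns=[
        "contact_id", "patient_id", "icpc_flag", "matched_codes",
        "text_flag", "matched_spans", "manual", "status"])


@dataclass
class ExclusionAudit:
    """Flowchart-style record of the exclusion cascade.

    Each patient/contact is counted once, at the first rule that removes it;
    input totals equal included totals plus the per-rule removals.
    """

    patients_in: int = 0
    contacts_in: int = 0
    patient_removals: dict[str, int] = field(default_factory=dict)
    contact_removals: dict[str, int] = field(default_factory=dict)
    patients_included: int = 0
    contacts_included: int = 0

    def conserves(self) -> bool:
        return (
            self.patients_in == self.patients_included + sum(self.patient_removals.values())
            and self.contacts_in == self.contacts_included + sum(self.contact_removals.values())
        )

    def to_json(self, path=None) -> str:
        payload = json.dumps(self.__dict__, indent=2, sort_keys=True)
        if path is not None:
            with open(path, "w", encoding="utf-8") as fh:
                fh.write(payload)
        return payload


def _age_at(birth: dt.date, on: dt.date) -> int:
    return on.year - birth.year - ((on.month, on.day) < (birth.month, birth.day))


def apply_exclusions(
    patients: pd.DataFrame,
    contacts: pd.DataFrame,
    labels: pd.DataFrame,
    holidays: Sequence[dt.date] = (),
    min_registration_days: int = 90,
    age_range: tuple[int, int] = (20, 45),
    study_start: dt.date = STUDY_START,
    study_end: dt.date = STUDY_END,
) -> tuple[pd.DataFrame, pd.DataFrame, ExclusionAudit]:
    """Apply the exclusion cascade; returns included patients, included
    contacts and the audit.

    Contact-level age filtering (20-45 at contact date) runs first, then the
    patient rules in their documented order, then the confirmed-pregnancy
    filter and the calendar rules (weekday, holiday, office hours). Patients
    left without any included contact are removed last. Contacts referencing
    unknown patients raise :class:`ValidationError`.
    """
    known = set(patients["patient_id"])
    orphans = [c for c in contacts["patient_id"] if c not in known]
    if orphans:
        raise ValidationError(
            f"{len(orphans)} contacts reference unknown patients, e.g. {orphans[0]!r}")

    audit = ExclusionAudit(patients_in=len(patients), contacts_in=len(contacts))
    hol = set(holidays)
    status = dict(zip(labels["contact_id"], labels["status"]))
    birth = dict(zip(patients["patient_id"], patients["birth_date"]))

    removed_contacts: dict[str, str] = {}  # contact_id -> rule
    lo, hi = age_range
    for row in contacts.itertuples(index=False):
        b = birth.get(row.patient_id)
        if isinstance(b, dt.date) and not lo <= _age_at(b, row.date) <= hi:
            removed_contacts[row.contact_id] = "age_outside_range"

    # patient rules, first match wins
    removed_patients: dict[str, str] = {}
    for row in patients.itertuples(index=False):
        reg_end = row.registration_end if isinstance(row.registration_end, dt.date) else None
        reason = str(row.deregistration_reason or "")
        rule = None
        if bool(row.death_in_period):
            rule = "died_in_period"
        elif reg_end is not None and study_start <= reg_end <= study_end:
            rule = "deregistered_in_period"
        elif reason and reg_end is None:
            rule = "deregistration_reason_without_date"
        elif not isinstance(row.birth_date, dt.date):
            rule = "unknown_birth_date"
        else:
            w_start = max(row.registration_start, study_start)
            w_end = min(reg_end or study_end, study_end)
            if (w_end - w_start).days < min_registration_days:
                rule = "registered_lt_min_days"
            elif not bool(row.zip_available):
                rule = "missing_zip"
        if rule:
            removed_patients[row.patient_id] = rule

    for row in contacts.itertuples(index=False):
        cid = row.contact_id
        if cid in removed_contacts:
            continue
        if row.patient_id in removed_patients:
            removed_contacts[cid] = "patient_excluded"
        elif not str(status.get(cid, EXCLUDED_INDETERMINATE)).startswith("confirmed"):
            removed_contacts[cid] = "not_confirmed_pregnant"
        elif row.date.weekday() >= 5:
            removed_contacts[cid] = "weekend"
        elif row.date in hol:
            removed_contacts[cid] = "holiday"
        elif not bool(row.in_office_hours):
            removed_contacts[cid] = "outside_office_hours"

    included_contacts = contacts[~contacts["contact_id"].isin(removed_contacts)].copy()
    with_contact = set(included_contacts["patient_id"])
    for pid in patients["patient_id"]:
        if pid not in removed_patients and pid not in with_contact:
            removed_patients[pid] = "no_included_contacts"
    included_patients = patients[~patients["patient_id"].isin(removed_patients)].copy()

    for rule in PATIENT_RULES:
        n = sum(1 for r in removed_patients.values() if r == rule)
        if n:
            audit.patient_removals[rule] = n
    for rule in CONTACT_RULES:
        n = sum(1 for r in removed_contacts.values() if r == rule)
        if n:
            audit.contact_removals[rule] = n
    audit.patients_included = len(included_patients)
    audit.contacts_included = len(included_contacts)
    return included_patients, included_contacts, audit


def select_cohort(
    patients: pd.DataFrame,
    contacts: pd.DataFrame,
    manual_labels: pd.DataFrame | None = None,
    pregnancy_codes=DEFAULT_PREGNANCY_CODES,
    text_pattern: str = DEFAULT_TEXT_PATTERN,
    holidays: Sequence[dt.date] = (),
    min_registration_days: int = 90,
    age_range: tuple[int, int] = (20, 45),
    study_start: dt.date = STUDY_START,
    study_end: dt.date = STUDY_END,
):
    """Label contacts then apply exclusions.

    Returns (labels, included_patients, included_contacts, audit).
    """
    labels = label_contacts(contacts, pregnancy_codes, text_pattern, manual_labels)
    inc_p, inc_c, audit = apply_exclusions(
        patients, contacts, labels, holidays, min_registration_days,
        age_range, study_start, study_end)
    return labels, inc_p, inc_c, audit


def compute_denominators(
    patients: pd.DataFrame,
    included_contacts: pd.DataFrame,
    labels: pd.DataFrame,
    calendar: pd.DataFrame,
    mode: str = "year_label",
) -> dict[dt.date, int]:
    """Registered pregnant patients per weekday — the rate denominator.

    ``year_label`` (default): a patient counts on day ``d`` when her practice
    registration covers ``d`` and she has at least one confirmed contact in
    the calendar year containing ``d``. ``registered``: every registered
    patient with any confirmed contact in the study counts while registered.
    """
    if mode not in ("year_label", "registered"):
        raise ConfigurationError(f"unknown denominator mode {mode!r}")
    confirmed = labels[labels["status"].str.startswith("confirmed")]
    conf_contacts = included_contacts[
        included_contacts["contact_id"].isin(set(confirmed["contact_id"]))]
    years_by_patient: dict[str, set[int]] = {}
    for row in conf_contacts.itertuples(index=False):
        years_by_patient.setdefault(row.patient_id, set()).add(row.date.year)
    reg = {
        row.patient_id: (row.registration_start,
                         row.registration_end if isinstance(row.registration_end, dt.date) else None)
        for row in patients.itertuples(index=False)
    }
    out: dict[dt.date, int] = {}
    for d in calendar["date"]:
        n = 0
        for pid, years in years_by_patient.items():
            if mode == "year_label" and d.year not in years:
                continue
            rs, re_ = reg.get(pid, (None, None))
            if rs is not None and rs <= d and (re_ is None or d <= re_):
                n += 1
        out[d] = n
    return out
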