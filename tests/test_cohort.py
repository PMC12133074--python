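import datetime as dt

import pandas as pd
import pytest

from gpprenatal import (
    ConfigurationError,
    ValidationError,
    apply_exclusions,
    flag_by_icpc,
    flag_by_text,
    label_contacts,
    merge_evidence,
    select_cohort,
)
from gpprenatal.cohort import (
    CONFIRMED_ICPC,
    CONFIRMED_TEXT_MANUAL,
    EXCLUDED_INDETERMINATE,
    parse_icpc_field,
)


class TestIcpcFlag:
    @pytest.mark.parametrize(
        "codes, expect_flag, expect_match",
        [
            ("W78", True, ["W78"]),          # pregnancy confirmed
            ("U71", False, []),              # cystitis: not pregnancy-defining
            ("W90", False, []),              # delivery code never triggers inclusion
            ("U71;W05", True, ["W05"]),      # nausea of pregnancy among others
            ("W84.02", True, ["W84.02"]),    # subcode matches through base W84
            ("W82", True, ["W82"]),          # miscarriage counts as pregnancy
        ],
    )
    def test_flagging(self, codes, expect_flag, expect_match):
        flag, matched = flag_by_icpc(codes)
        assert flag is expect_flag
        assert matched == expect_match

    def test_malformed_code_names_row(self):
        with pytest.raises(ValidationError, match="row C1"):
            parse_icpc_field("W7", row_id="C1")

    def test_w90_in_defining_set_rejected(self):
        with pytest.raises(ConfigurationError):
            flag_by_icpc("W78", frozenset({"W78", "W90"}))

    def test_empty_defining_set_rejected(self):
        with pytest.raises(ConfigurationError):
            flag_by_icpc("W78", frozenset())


class TestTextFlag:
    def test_empty_note_no_match(self):
        assert flag_by_text("") == (False, [])

    def test_lexicon_matches_zwanger(self):
        # hand evaluation: 'zwanger' occupies positions 21..28
        note = "patiente is 12 weken zwanger"
        flag, spans = flag_by_text(note)
        assert flag and spans == [(21, 28)]
        assert note[spans[0][0]:spans[0][1]] == "zwanger"

    def test_decoy_still_matches_at_pattern_level(self):
        # the pattern alone cannot see negation; candidate status only
        flag, spans = flag_by_text("zwangerschapstest negatief")
        assert flag and spans == [(0, 7)]

    def test_case_insensitive(self):
        assert flag_by_text("ZWANGER")[0]

    def test_invalid_pattern_rejected(self):
        with pytest.raises(ConfigurationError):
            flag_by_text("x", "(unclosed")


class TestMergeEvidence:
    @pytest.mark.parametrize(
        "icpc, text, manual, expected",
        [
            (True, False, "absent", CONFIRMED_ICPC),
            (True, True, "absent", CONFIRMED_ICPC),
            (False, True, "absent", EXCLUDED_INDETERMINATE),  # needs manual confirm
            (False, True, "confirm", CONFIRMED_TEXT_MANUAL),
            (False, True, "reject", EXCLUDED_INDETERMINATE),
            (True, False, "reject", EXCLUDED_INDETERMINATE),  # manual overrides
            (False, False, "absent", EXCLUDED_INDETERMINATE),
            (False, False, "confirm", EXCLUDED_INDETERMINATE),  # nothing to confirm
        ],
    )
    def test_rule_table(self, icpc, text, manual, expected):
        assert merge_evidence(icpc, text, manual) == expected

    def test_unknown_manual_label_rejected(self):
        with pytest.raises(ValidationError):
            merge_evidence(True, False, "maybe")

    def test_conflicting_manual_labels_rejected(self):
        contacts = pd.DataFrame({
            "contact_id": ["C1"], "patient_id": ["P1"],
            "date": [dt.date(2019, 3, 4)], "icpc_codes": ["A97"],
            "note_text": ["zwanger"], "contact_type": ["clinic"],
            "in_office_hours": [True]})
        manual = pd.DataFrame({"contact_id": ["C1", "C1"],
                               "verdict": ["confirm", "reject"]})
        with pytest.raises(ValidationError, match="conflicting"):
            label_contacts(contacts, manual_labels=manual)


def _patient(pid="P1", birth=dt.date(1990, 5, 1), reg_start=dt.date(2015, 1, 1),
             reg_end=None, reason="", died=False, zip_ok=True):
    return {
        "patient_id": pid, "birth_date": birth, "sex": "female",
        "practice_id": "PR01", "registration_start": reg_start,
        "registration_end": reg_end, "deregistration_reason": reason,
        "death_in_period": died, "zip_available": zip_ok,
    }


def _contact(cid="C1", pid="P1", date=dt.date(2019, 3, 4), codes="W78",
             note="", ctype="clinic", office=True):
    return {
        "contact_id": cid, "patient_id": pid, "date": date, "icpc_codes": codes,
        "note_text": note, "contact_type": ctype, "in_office_hours": office,
    }


def _run(patients_rows, contacts_rows, **kwargs):
    patients = pd.DataFrame(patients_rows)
    contacts = pd.DataFrame(contacts_rows)
    labels = label_contacts(contacts)
    return apply_exclusions(patients, contacts, labels, **kwargs)


class TestExclusions:
    def test_missing_birth_date_audited(self):
        _, inc, audit = _run([_patient(birth=None)], [_contact()])
        assert inc.empty
        assert audit.patient_removals == {"unknown_birth_date": 1}

    def test_two_month_registration_excluded(self):
        p = _patient(reg_start=dt.date(2019, 2, 1), reg_end=dt.date(2019, 4, 1),
                     reason="moved")
        # deregistration-in-period fires first; shrink the window instead
        _, _, audit = _run(
            [p], [_contact()],
            study_start=dt.date(2019, 1, 1), study_end=dt.date(2019, 4, 2))
        assert "deregistered_in_period" in audit.patient_removals

    def test_short_registration_window_excluded(self):
        p = _patient(reg_start=dt.date(2019, 11, 1))
        _, inc, audit = _run(
            [p], [_contact(date=dt.date(2019, 11, 15))],
            study_start=dt.date(2019, 1, 1), study_end=dt.date(2019, 12, 31))
        assert inc.empty
        assert audit.patient_removals == {"registered_lt_min_days": 1}

    def test_saturday_contact_dropped_patient_retained(self):
        contacts = [
            _contact("C1", date=dt.date(2019, 3, 2)),   # Saturday
            _contact("C2", date=dt.date(2019, 3, 4)),   # Monday
        ]
        inc_p, inc_c, audit = _run([_patient()], contacts)
        assert list(inc_c["contact_id"]) == ["C2"]
        assert audit.contact_removals["weekend"] == 1
        assert len(inc_p) == 1

    def test_holiday_and_office_hours_dropped(self):
        contacts = [
            _contact("C1", date=dt.date(2019, 4, 22)),  # Easter Monday
            _contact("C2", office=False),
            _contact("C3"),
        ]
        _, inc_c, audit = _run([_patient()], contacts,
                               holidays=[dt.date(2019, 4, 22)])
        assert list(inc_c["contact_id"]) == ["C3"]
        assert audit.contact_removals["holiday"] == 1
        assert audit.contact_removals["outside_office_hours"] == 1

    def test_age_filter_at_contact_date(self):
        # born 2001-06-01: aged 17 at the 2019 contact, 20 at the 2021 one
        p = _patient(birth=dt.date(2001, 6, 1))
        contacts = [_contact("C1", date=dt.date(2019, 3, 4)),
                    _contact("C2", date=dt.date(2021, 7, 5))]
        _, inc_c, audit = _run([p], contacts)
        assert list(inc_c["contact_id"]) == ["C2"]
        assert audit.contact_removals["age_outside_range"] == 1

    def test_unknown_patient_reference_rejected(self):
        with pytest.raises(ValidationError, match="unknown patient"):
            _run([_patient()], [_contact(pid="GHOST")])

    def test_unconfirmed_contacts_removed(self):
        contacts = [_contact("C1", codes="U71", note="geen bijzonderheden")]
        _, inc_c, audit = _run([_patient()], contacts)
        assert inc_c.empty
        assert audit.contact_removals["not_confirmed_pregnant"] == 1
        assert audit.patient_removals["no_included_contacts"] == 1


class TestSelectionProperties:
    def test_audit_conservation(self, medium_dataset, medium_manual_labels):
        _, patients, contacts, _ = medium_dataset
        _, _, _, audit = select_cohort(patients, contacts, medium_manual_labels)
        assert audit.conserves()

    def test_icpc_channel_sensitivity_is_one(self, medium_dataset):
        """Every truth-pregnant contact whose channel is icpc is labelled
        confirmed_icpc even without any manual labels."""
        _, _, contacts, truth = medium_dataset
        labels = label_contacts(contacts)
        merged = labels.merge(truth.contacts[["contact_id", "channel"]], on="contact_id")
        icpc = merged[merged["channel"] == "icpc"]
        assert (icpc["status"] == CONFIRMED_ICPC).all()

    def test_idempotence(self, medium_dataset, medium_manual_labels):
        """Selecting from the selection's own output changes nothing."""
        _, patients, contacts, _ = medium_dataset
        _, inc_p, inc_c, _ = select_cohort(patients, contacts, medium_manual_labels)
        _, p2, c2, audit2 = select_cohort(inc_p, inc_c, medium_manual_labels)
        assert set(c2["contact_id"]) == set(inc_c["contact_id"])
        assert set(p2["patient_id"]) == set(inc_p["patient_id"])
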