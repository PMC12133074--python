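"""Pregnancy-relevant ICPC code surveillance across pandemic subphases.

Ranks the most frequently registered pregnancy-relevant codes, normalizes
registrations per 1000 contacts, and tests each code's subphase frequency
against the prepandemic baseline with a two-sided Fisher exact test on the
2x2 table [[a, b], [c, d]] (a = contacts in the subphase carrying the code,
b = without it; c, d the same for the baseline). Two views of the unit of
analysis are available: ``contacts`` (a contact registering a code twice
counts once) and ``registrations`` (every registration counts). No multiple
testing correction is applied by default; Benjamini-Hochberg is available as
an option and the output flags its absence.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from typing import Mapping

import pandas as pd
from scipy import stats

from .config import BASELINE_SUBPHASE, ConfigurationError, DEFAULT_RELEVANT_CODES
from .cohort import parse_icpc_field

__all__ = [
    "rank_pregnancy_codes",
    "CodePhaseTest",
    "fisher_code_phase",
    "code_phase_table",
]


def _registrations(contacts: pd.DataFrame) -> pd.DataFrame:
    """Long table (contact_id, subphase?, code) with one row per registration."""
    rows = []
    has_sub = "subphase" in contacts.columns
    for row in contacts.itertuples(index=False):
        for code in parse_icpc_field(row.icpc_codes, row_id=row.contact_id):
            rows.append((row.contact_id, row.subphase if has_sub else None, code))
    return pd.DataFrame(rows, columns=["contact_id", "subphase", "code"])


def rank_pregnancy_codes(
    included_contacts: pd.DataFrame,
    relevant_codes: Mapping[str, str] | None = None,
    k: int = 10,
) -> list[tuple[str, int]]:
    """Top-k pregnancy-relevant codes by registration count.

    Only codes in the relevant set are counted; a contact carrying m relevant
    codes contributes m registrations. Sorted by count descending, ties broken
    lexicographically.
    """
    relevant = relevant_codes if relevant_codes is not None else DEFAULT_RELEVANT_CODES
    if not relevant:
        raise ConfigurationError("relevant code set is empty")
    if k <= 0 or included_contacts.empty:
        return []
    reg = _registrations(included_contacts)
    reg = reg[reg["code"].isin(set(relevant))]
    counts = reg.groupby("code").size()
    ranked = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    return [(code, int(n)) for code, n in ranked[:k]]


@dataclass
class CodePhaseTest:
    """One code x subphase Fisher exact comparison against baseline."""

    icpc_code: str
    subphase: str
    a: int  # contacts (or registrations) in subphase with the code
    b: int  # ... without it
    c: int  # baseline with the code
    d: int  # baseline without it
    rate_phase: float      # per 1000 contacts
    rate_baseline: float
    p_value: float
    degenerate: bool = False


def _fisher_two_sided(a: int, b: int, c: int, d: int) -> tuple[float, bool]:
    if (a + c == 0) or (b + d == 0) or (a + b == 0) or (c + d == 0):
        return 1.0, True
    _, p = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
    return float(min(p, 1.0)), False


def fisher_code_phase(
    code: str,
    subphase_contacts: pd.DataFrame,
    baseline_contacts: pd.DataFrame,
    subphase: str = "?",
    unit: str = "contacts",
) -> CodePhaseTest:
    """Fisher exact test of one code's frequency in a subphase vs baseline.

    ``unit='contacts'`` counts contact-level presence/absence;
    ``unit='registrations'`` counts every registration against the total
    number of registrations. Degenerate margins (all-zero row or column)
    report P=1 with a flag.
    """
    if unit not in ("contacts", "registrations"):
        raise ConfigurationError(f"unknown unit {unit!r}")

    def split(contacts: pd.DataFrame) -> tuple[int, int]:
        if contacts.empty:
            return 0, 0
        if unit == "contacts":
            with_code = 0
            for field in contacts["icpc_codes"]:
                if code in parse_icpc_field(field):
                    with_code += 1
            return with_code, len(contacts) - with_code
        reg = _registrations(contacts)
        with_code = int((reg["code"] == code).sum())
        return with_code, len(reg) - with_code

    a, b = split(subphase_contacts)
    c, d = split(baseline_contacts)
    if a + b == 0 or c + d == 0:
        raise ConfigurationError(
            f"empty contact set for code {code} (subphase {subphase})")
    p, degenerate = _fisher_two_sided(a, b, c, d)
    return CodePhaseTest(
        icpc_code=code, subphase=subphase, a=a, b=b, c=c, d=d,
        rate_phase=1000.0 * a / (a + b), rate_baseline=1000.0 * c / (c + d),
        p_value=p, degenerate=degenerate)


def code_phase_table(
    included_contacts: pd.DataFrame,
    calendar: pd.DataFrame,
    relevant_codes: Mapping[str, str] | None = None,
    k: int = 10,
    baseline: str = BASELINE_SUBPHASE,
    unit: str = "contacts",
    bh_correction: bool = False,
) -> pd.DataFrame:
    """Top-k codes x pandemic subphases grid of rates and Fisher P values.

    Contacts are assigned subphases through the calendar. With
    ``bh_correction`` a ``p_adjusted`` (Benjamini-Hochberg) column is added;
    otherwise the table carries ``multiple_testing='none'`` as an explicit
    warning that many tests are run at the nominal level.
    """
    relevant = relevant_codes if relevant_codes is not None else DEFAULT_RELEVANT_CODES
    sub_of = dict(zip(calendar["date"], calendar["subphase"]))
    contacts = included_contacts.copy()
    contacts["subphase"] = contacts["date"].map(sub_of)
    top = rank_pregnancy_codes(contacts, relevant, k)
    base = contacts[contacts["subphase"] == baseline]
    rows = []
    order = [s for s in calendar["subphase"].drop_duplicates() if s != baseline]
    for code, total in top:
        for sub in order:
            seg = contacts[contacts["subphase"] == sub]
            if seg.empty or base.empty:
                continue
            t = fisher_code_phase(code, seg, base, subphase=sub, unit=unit)
            row = asdict(t)
            row["total_registrations"] = total
            row["category"] = relevant.get(code, "")
            rows.append(row)
    out = pd.DataFrame(rows)
    if out.empty:
        return out
    if bh_correction:
        from statsmodels.stats.multitest import multipletests

        out["p_adjusted"] = multipletests(out["p_value"], method="fdr_bh")[1]
        out["multiple_testing"] = "benjamini_hochberg"
    else:
        out["multiple_testing"] = "none"
    return out
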