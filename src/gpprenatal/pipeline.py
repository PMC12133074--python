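"""End-to-end orchestration: simulate -> select -> ITS -> codes -> mix -> report.

The pipeline stitches the stages together around CSV interfaces so each stage
can also be run (and cached) on its own: synthetic or user-supplied patient
and contact tables go through cohort selection, the selected contacts through
the interrupted time-series fit, the code-frequency tests and the contact-mix
descriptives, and everything is written as a bundle of CSV/JSON outputs plus a
human-readable report that doubles as an inclusion/exclusion flowchart.
"""

from __future__ import annotations

import datetime as dt
import json
import logging
from pathlib import Path

import pandas as pd

from .config import PipelineConfig, SimulationConfig, ValidationError
from .phases import build_phase_calendar
from . import cohort as _cohort
from . import codes as _codes
from . import its as _its
from . import mix as _mix
from . import synthetic as _syn

__all__ = ["validate_dataset", "run_pipeline", "simulate_to_dir"]

log = logging.getLogger("gpprenatal")

_PATIENT_COLS = [
    "patient_id", "birth_date", "sex", "practice_id", "registration_start",
    "registration_end", "deregistration_reason", "death_in_period", "zip_available"]
_CONTACT_COLS = [
    "contact_id", "patient_id", "date", "icpc_codes", "note_text",
    "contact_type", "in_office_hours"]


def validate_dataset(patients: pd.DataFrame, contacts: pd.DataFrame) -> dict:
    """Schema, format and referential-integrity report for the input tables.

    Returns a dict with per-check problem counts and row-level examples;
    ``valid`` is True when no problems were found. Headers-only tables are
    valid with zero rows.
    """
    problems: dict[str, list[str]] = {}

    def add(check: str, msg: str) -> None:
        problems.setdefault(check, []).append(msg)

    for name, df, cols in (("patients", patients, _PATIENT_COLS),
                           ("contacts", contacts, _CONTACT_COLS)):
        missing = [c for c in cols if c not in df.columns]
        if missing:
            add("schema", f"{name}: missing columns {missing}")
    if "schema" not in problems:
        known = set(patients["patient_id"])
        for row in contacts.itertuples(index=False):
            if row.patient_id not in known:
                add("referential_integrity",
                    f"contact {row.contact_id} references unknown patient "
                    f"{row.patient_id}")
            if not isinstance(row.date, dt.date):
                add("date_format", f"contact {row.contact_id}: bad date {row.date!r}")
            try:
                codes = _cohort.parse_icpc_field(row.icpc_codes, row_id=row.contact_id)
                if not codes:
                    # every contact must carry at least one problem code
                    add("icpc_missing",
                        f"contact {row.contact_id} has an empty ICPC field")
            except ValidationError as exc:
                add("icpc_format", str(exc))
        for row in patients.itertuples(index=False):
            rs, re_ = row.registration_start, row.registration_end
            if isinstance(rs, dt.date) and isinstance(re_, dt.date) and re_ < rs:
                add("registration_interval",
                    f"patient {row.patient_id}: registration_end precedes start")
    return {
        "valid": not problems,
        "n_patients": len(patients),
        "n_contacts": len(contacts),
        "problems": {k: {"count": len(v), "examples": v[:5]}
                     for k, v in problems.items()},
    }


def simulate_to_dir(sim_config: SimulationConfig, out_dir) -> dict[str, Path]:
    """Generate a synthetic dataset, write it (plus the auto manual-label
    file) to ``out_dir`` and return the file paths."""
    patients, contacts, truth = _syn.generate_dataset(sim_config)
    paths = _syn.write_dataset(patients, contacts, truth, out_dir)
    manual = _syn.make_manual_labels(contacts, truth)
    paths["manual_labels"] = Path(out_dir) / "manual_labels.csv"
    manual.to_csv(paths["manual_labels"], index=False)
    return paths


def run_pipeline(
    config: PipelineConfig,
    data_dir,
    out_dir,
    make_plots: bool = False,
) -> dict[str, Path]:
    """Run every analysis stage on the dataset in ``data_dir``.

    ``data_dir`` must hold patients.csv and contacts.csv (optionally
    manual_labels.csv, truth.csv, denominators.csv). Writes labels.csv,
    included_contacts.csv, audit.json, fits.csv, comparisons.csv,
    code_tests.csv, mix.csv, summary.csv, denominators.csv and report.txt to
    ``out_dir`` and returns the paths. Deterministic given the inputs.
    """
    config.validate()
    data_dir, out_dir = Path(data_dir), Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    patients = _syn.read_patients(data_dir / "patients.csv")
    contacts = _syn.read_contacts(data_dir / "contacts.csv")
    report = validate_dataset(patients, contacts)
    if not report["valid"]:
        raise ValidationError(f"input validation failed: {report['problems']}")

    manual = None
    manual_path = data_dir / "manual_labels.csv"
    if manual_path.exists():
        manual = pd.read_csv(manual_path, dtype=str, keep_default_na=False)

    calendar = build_phase_calendar(config.phase_spec)
    study_start = calendar["date"].min()
    study_end = calendar["date"].max()

    log.info("labelling %d contacts", len(contacts))
    labels, inc_patients, inc_contacts, audit = _cohort.select_cohort(
        patients, contacts, manual,
        pregnancy_codes=config.pregnancy_codes,
        text_pattern=config.text_pattern,
        holidays=config.holidays,
        min_registration_days=config.min_registration_days,
        age_range=config.age_range,
        study_start=study_start, study_end=study_end)
    log.info("included %d/%d contacts", len(inc_contacts), len(contacts))

    paths["labels"] = out_dir / "labels.csv"
    labels.to_csv(paths["labels"], index=False)
    paths["included_contacts"] = out_dir / "included_contacts.csv"
    inc_out = inc_contacts.copy()
    inc_out["date"] = inc_out["date"].map(lambda d: d.isoformat())
    inc_out.to_csv(paths["included_contacts"], index=False)
    paths["audit"] = out_dir / "audit.json"
    audit.to_json(paths["audit"])

    # denominators: explicit file > truth ledger > label-based
    den_path = data_dir / "denominators.csv"
    truth_path = data_dir / "truth.csv"
    if den_path.exists():
        den_df = pd.read_csv(den_path, dtype=str, keep_default_na=False)
        denominators = {
            dt.date.fromisoformat(r.date): int(r.count)
            for r in den_df.itertuples(index=False)}
    elif config.denominator_mode == "truth_episode" and truth_path.exists():
        _, _, truth = _syn.read_dataset(data_dir)
        denominators = _syn.truth_denominators(patients, truth, calendar)
    else:
        denominators = _cohort.compute_denominators(
            patients, inc_contacts, labels, calendar,
            mode="registered" if config.denominator_mode == "registered" else "year_label")
    paths["denominators"] = out_dir / "denominators.csv"
    pd.DataFrame(
        [(d.isoformat(), n) for d, n in sorted(denominators.items())],
        columns=["date", "count"],
    ).to_csv(paths["denominators"], index=False)

    fits, comparisons = _its.run_its(
        inc_contacts, denominators, calendar,
        holidays=config.holidays, window=config.ma_window,
        smoothing_scope=config.smoothing_scope, robust_se=config.robust_se)
    paths["fits"] = out_dir / "fits.csv"
    fits.to_csv(paths["fits"], index=False)
    paths["comparisons"] = out_dir / "comparisons.csv"
    comparisons.to_csv(paths["comparisons"], index=False)

    code_tests = _codes.code_phase_table(
        inc_contacts, calendar, config.relevant_codes, k=config.top_k_codes,
        unit=config.code_test_unit, bh_correction=config.bh_correction)
    paths["code_tests"] = out_dir / "code_tests.csv"
    code_tests.to_csv(paths["code_tests"], index=False)

    mix_series = _mix.contact_type_proportions(inc_contacts, calendar, config.ma_window)
    paths["mix"] = out_dir / "mix.csv"
    mix_out = mix_series.copy()
    mix_out["date"] = mix_out["date"].map(lambda d: d.isoformat())
    mix_out.to_csv(paths["mix"], index=False)

    summary = _mix.descriptive_summary(patients, inc_contacts, labels)
    paths["summary"] = out_dir / "summary.csv"
    summary.to_csv(paths["summary"], index=False)

    paths["report"] = out_dir / "report.txt"
    paths["report"].write_text(_render_report(report, audit, fits, comparisons,
                                              code_tests, summary, config))
    if make_plots:
        paths.update(_write_plots(out_dir, inc_contacts, denominators, calendar,
                                  mix_series, config))
    return paths


def _render_report(validation, audit, fits, comparisons, code_tests, summary,
                   config: PipelineConfig) -> str:
    lines = ["GP prenatal-care utilisation pipeline report", "=" * 44, ""]
    lines.append(f"input: {validation['n_patients']} patients, "
                 f"{validation['n_contacts']} contacts (validation passed)")
    lines.append("")
    lines.append("Inclusion/exclusion flowchart")
    lines.append(f"  patients in: {audit.patients_in}")
    for rule, n in audit.patient_removals.items():
        lines.append(f"    - {rule}: {n}")
    lines.append(f"  patients included: {audit.patients_included}")
    lines.append(f"  contacts in: {audit.contacts_in}")
    for rule, n in audit.contact_removals.items():
        lines.append(f"    - {rule}: {n}")
    lines.append(f"  contacts included: {audit.contacts_included}")
    lines.append("")
    lines.append("Segmented fits (rate per 1000 registered pregnant patients/day)")
    for row in fits.itertuples(index=False):
        lines.append(
            f"  phase {row.subphase:>2}: b0={row.beta0:6.2f} (SE {row.se_beta0:.2f})  "
            f"b1={row.beta1:+.3f} (SE {row.se_beta1:.3f})  "
            f"R2={row.r_squared:.2f} adjR2={row.adj_r_squared:.2f} n={row.n_obs}")
    sig = comparisons[comparisons["p_value"] < 0.05]
    lines.append(f"  baseline comparisons: {len(comparisons)} z-tests, "
                 f"{len(sig)} significant at 0.05")
    lines.append("")
    if len(code_tests):
        lines.append("Code-frequency surveillance (Fisher exact vs baseline)")
        if not config.bh_correction:
            lines.append("  warning: no multiple-testing correction "
                         f"({len(code_tests)} tests at nominal alpha=0.05)")
        csig = code_tests[code_tests["p_value"] < 0.05]
        lines.append(f"  {len(csig)}/{len(code_tests)} code x subphase tests "
                     "significant at 0.05")
        lines.append("")
    lines.append("Yearly summary")
    for row in summary.itertuples(index=False):
        lines.append(f"  {row.year}: {row.pregnant_women} women, "
                     f"{row.total_contacts} contacts, "
                     f"{row.mean_contacts_per_patient:.1f} "
                     f"(SD {row.sd_contacts_per_patient:.1f}) contacts/patient")
    return "\n".join(lines) + "\n"


def _write_plots(out_dir: Path, inc_contacts, denominators, calendar,
                 mix_series, config: PipelineConfig) -> dict[str, Path]:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    paths = {}
    series = _its.compute_daily_rates(inc_contacts, denominators, calendar,
                                      config.holidays)
    series = _its.add_smoothed(series, config.ma_window, config.smoothing_scope)
    fig, ax = plt.subplots(figsize=(12, 4))
    ax.plot(series["date"], series["rate"], ".", ms=2, alpha=0.4, label="daily rate")
    ax.plot(series["date"], series["smoothed"], "-", lw=1.5, label="3-week MA")
    for d in series.loc[series["subphase"].ne(series["subphase"].shift()), "date"][1:]:
        ax.axvline(d, color="grey", lw=0.5, ls="--")
    ax.set_ylabel("contacts / 1000 pregnant patients / day")
    ax.legend()
    paths["rates_plot"] = out_dir / "rates.png"
    fig.savefig(paths["rates_plot"], dpi=120, bbox_inches="tight")
    plt.close(fig)

    fig, ax = plt.subplots(figsize=(12, 4))
    from .config import CONTACT_TYPES

    for ct in CONTACT_TYPES:
        smoothed = _mix.loess_smooth(
            mix_series[f"smooth_{ct}"].to_numpy(), span=config.loess_span)
        ax.plot(mix_series["date"], 100 * smoothed, label=ct)
    ax.set_ylabel("% of contacts")
    ax.legend()
    paths["mix_plot"] = out_dir / "mix.png"
    fig.savefig(paths["mix_plot"], dpi=120, bbox_inches="tight")
    plt.close(fig)
    return paths
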