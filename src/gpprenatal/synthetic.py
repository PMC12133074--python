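"""Synthetic primary-care EHR generator with a ground-truth ledger.

The source EHR of the emulated study (three Dutch GP research networks,
~410,000 patients) is not publicly available, so every downstream stage is
exercised on synthetic patient and contact tables whose statistical structure
matches what the analysis assumes:

* women aged 20-45, a configurable fraction of whom carry one pregnancy
  episode (default prevalence 13.9%);
* population-level daily contact counts drawn Poisson around a piecewise
  linear per-1000-patients intensity per pandemic subphase, with seasonal
  intercept shifts, then attributed to patients whose episode covers the day;
* ICPC codes (pregnancy-defining and general), free-text Dutch notes with
  pregnancy phrases, decoy phrases and neutral filler;
* four contact types with a subphase-specific mix;
* per-rule fractions of patients carrying each exclusion trait.

Weekends and national holidays generate no contacts, matching the analysis
window. A single seed feeds named per-stage substreams so partial reruns are
reproducible. The ground truth (pregnancy episodes, per-contact pregnancy
status and intended detection channel, the generating rate parameters) is kept
in a :class:`SyntheticTruth` ledger for recovery testing.
"""

from __future__ import annotations

import datetime as dt
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .config import (
    CONTACT_TYPES,
    ConfigurationError,
    DEFAULT_PREGNANCY_CODES,
    RateParams,
    SimulationConfig,
)
from .phases import build_phase_calendar, subphase_spans

__all__ = [
    "SyntheticTruth",
    "generate_population",
    "generate_contacts",
    "simulate_rate_series",
    "truth_denominators",
    "make_manual_labels",
    "generate_dataset",
    "write_dataset",
    "read_dataset",
]

_STAGES = ("population", "episodes", "contacts", "background")


def _substreams(seed: int) -> dict[str, np.random.Generator]:
    children = np.random.SeedSequence(seed).spawn(len(_STAGES))
    return {name: np.random.default_rng(ss) for name, ss in zip(_STAGES, children)}


@dataclass
class SyntheticTruth:
    """Generating ground truth for one synthetic dataset.

    ``patients`` has one row per patient (pregnancy flag and episode interval);
    ``contacts`` one row per contact (pregnancy-at-contact flag and intended
    detection channel: ``icpc``, ``text_only`` or ``none``); ``rate_params``
    echoes the generating intensities verbatim.
    """

    patients: pd.DataFrame
    contacts: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(
            columns=["contact_id", "patient_id", "truth_pregnant", "channel"]))
    rate_params: Mapping[str, RateParams] = field(default_factory=dict)

    def episode_covering(self, patient_id: str, date: dt.date) -> bool:
        row = self.patients[self.patients["patient_id"] == patient_id]
        if row.empty or not bool(row["pregnant"].iloc[0]):
            return False
        start, end = row["episode_start"].iloc[0], row["episode_end"].iloc[0]
        return start is not None and start <= date <= end


# --------------------------------------------------------------------------
# Population
# --------------------------------------------------------------------------

def generate_population(config: SimulationConfig) -> tuple[pd.DataFrame, SyntheticTruth]:
    """Generate the patient registry and per-patient pregnancy ground truth.

    All patients are women aged 20-45 at some point in the date range. Each
    exclusion trait (death in period, deregistration variants, unknown birth
    date, short registration, missing zip) is assigned independently to its
    configured fraction of patients. ~``pregnancy_prevalence`` of patients get
    one pregnancy episode of ``episode_days`` days inside the range.
    """
    config.validate()
    rngs = _substreams(config.seed)
    n = config.n_patients
    start, end = config.date_start, config.date_end
    span_days = (end - start).days

    if n == 0:
        patients = pd.DataFrame(columns=[
            "patient_id", "birth_date", "sex", "practice_id",
            "registration_start", "registration_end", "deregistration_reason",
            "death_in_period", "zip_available"])
        truth_pat = pd.DataFrame(columns=[
            "patient_id", "pregnant", "episode_start", "episode_end"])
        return patients, SyntheticTruth(truth_pat, rate_params=dict(config.phase_rate_params))

    rng = rngs["population"]
    ids = [f"P{i:06d}" for i in range(n)]
    mid = start + dt.timedelta(days=span_days // 2)
    # age 21-44 at mid-study keeps everyone inside 20-45 somewhere in range
    age_days = rng.integers(int(21 * 365.25), int(44 * 365.25), size=n)
    birth = [mid - dt.timedelta(days=int(a)) for a in age_days]
    practice = rng.integers(0, 5, size=n)
    reg_start_off = rng.integers(1, 3650, size=n)
    reg_start = [start - dt.timedelta(days=int(o)) for o in reg_start_off]

    patients = pd.DataFrame({
        "patient_id": ids,
        "birth_date": birth,
        "sex": "female",
        "practice_id": [f"PR{p:02d}" for p in practice],
        "registration_start": reg_start,
        "registration_end": [None] * n,
        "deregistration_reason": [""] * n,
        "death_in_period": False,
        "zip_available": True,
    })

    frac = dict(config.exclusion_fractions)

    def trait(name: str) -> np.ndarray:
        return rng.random(n) < frac.get(name, 0.0)

    patients.loc[trait("died_in_period"), "death_in_period"] = True
    m = trait("deregistered_in_period")
    if m.any():
        offs = rng.integers(0, max(span_days, 1), size=int(m.sum()))
        patients.loc[m, "registration_end"] = [
            start + dt.timedelta(days=int(o)) for o in offs]
        patients.loc[m, "deregistration_reason"] = "moved"
    m = trait("deregistration_reason_without_date")
    patients.loc[m & patients["registration_end"].isna(), "deregistration_reason"] = "moved"
    patients.loc[trait("unknown_birth_date"), "birth_date"] = None
    m = trait("registered_lt_min_days")
    if m.any():
        k = int(m.sum())
        s_off = rng.integers(0, max(span_days - 90, 1), size=k)
        durs = rng.integers(10, 80, size=k)
        starts = [start + dt.timedelta(days=int(o)) for o in s_off]
        patients.loc[m, "registration_start"] = starts
        patients.loc[m, "registration_end"] = [
            s + dt.timedelta(days=int(d)) for s, d in zip(starts, durs)]
    patients.loc[trait("missing_zip"), "zip_available"] = False

    # pregnancy episodes
    erng = rngs["episodes"]
    pregnant = erng.random(n) < config.pregnancy_prevalence
    ep_start_off = erng.integers(0, max(span_days - 59, 1), size=n)
    ep_start, ep_end = [], []
    for flag, off in zip(pregnant, ep_start_off):
        if not flag:
            ep_start.append(None)
            ep_end.append(None)
            continue
        s = start + dt.timedelta(days=int(off))
        e = min(s + dt.timedelta(days=config.episode_days), end)
        ep_start.append(s)
        ep_end.append(e)
    truth_pat = pd.DataFrame({
        "patient_id": ids,
        "pregnant": pregnant,
        "episode_start": ep_start,
        "episode_end": ep_end,
    })
    return patients, SyntheticTruth(truth_pat, rate_params=dict(config.phase_rate_params))


# --------------------------------------------------------------------------
# Rate machinery (shared by the generator and the recovery studies)
# --------------------------------------------------------------------------

def simulate_rate_series(
    rate_params: Mapping[str, RateParams],
    calendar: pd.DataFrame,
    denominator,
    rng: np.random.Generator | None = None,
    holidays=(),
    noise: bool = True,
) -> pd.DataFrame:
    """Daily contact counts from the piecewise-linear intensity model.

    ``denominator`` is either a scalar or a mapping date -> count of
    registered pregnant patients. Counts are Poisson with mean
    ``intensity(d) * denominator(d) / 1000``; with ``noise=False`` the exact
    (fractional) mean is returned instead, for noise-free recovery checks.
    Holiday dates are dropped. Raises on negative implied intensity.
    """
    hol = set(holidays)
    days = calendar[~calendar["date"].isin(hol)].reset_index(drop=True)
    get_den = denominator.get if hasattr(denominator, "get") else (lambda d: denominator)
    intensities = np.empty(len(days))
    dens = np.empty(len(days))
    for i, row in enumerate(days.itertuples(index=False)):
        rp = rate_params.get(row.subphase)
        if rp is None:
            raise ConfigurationError(f"no rate parameters for subphase {row.subphase}")
        lam = rp.intensity(row.t_days, row.season)
        if lam < 0:
            raise ConfigurationError(
                f"negative implied intensity {lam:.3f} on {row.date} "
                f"(subphase {row.subphase})")
        intensities[i] = lam
        dens[i] = get_den(row.date) or 0
    mean = intensities * dens / 1000.0
    if noise:
        if rng is None:
            rng = np.random.default_rng()
        counts = rng.poisson(mean).astype(float)
    else:
        counts = mean
    out = days.copy()
    out["intensity"] = intensities
    out["denominator"] = dens
    out["n_contacts"] = counts
    return out


def truth_denominators(
    patients: pd.DataFrame, truth: SyntheticTruth, calendar: pd.DataFrame
) -> dict[dt.date, int]:
    """Registered pregnant patients per weekday, from the ground truth.

    A patient counts on day ``d`` when her practice registration covers ``d``
    and her true pregnancy episode overlaps the calendar year containing ``d``
    (the per-year labelling frame the rate normalization uses).
    """
    t = truth.patients
    preg = t[t["pregnant"].astype(bool)].merge(
        patients[["patient_id", "registration_start", "registration_end"]],
        on="patient_id", how="left")
    if preg.empty:
        return {d: 0 for d in calendar["date"]}
    ep_s = np.array([d.toordinal() for d in preg["episode_start"]])
    ep_e = np.array([d.toordinal() for d in preg["episode_end"]])
    reg_s = np.array([d.toordinal() for d in preg["registration_start"]])
    reg_e = np.array([
        (d.toordinal() if isinstance(d, dt.date) else 10**9)
        for d in preg["registration_end"]])
    out: dict[dt.date, int] = {}
    for d in calendar["date"]:
        o = d.toordinal()
        y0 = dt.date(d.year, 1, 1).toordinal()
        y1 = dt.date(d.year, 12, 31).toordinal()
        mask = (reg_s <= o) & (reg_e >= o) & (ep_s <= y1) & (ep_e >= y0)
        out[d] = int(mask.sum())
    return out


# --------------------------------------------------------------------------
# Contacts
# --------------------------------------------------------------------------

def _renormalize(dist: Mapping[str, float], bumps: Mapping[str, float] | None = None,
                 keep=None) -> tuple[list[str], np.ndarray]:
    items = {c: p for c, p in dist.items() if keep is None or keep(c)}
    if bumps:
        items = {c: p * bumps.get(c, 1.0) for c, p in items.items()}
    codes = sorted(items)
    probs = np.array([items[c] for c in codes], dtype=float)
    total = probs.sum()
    if total <= 0:
        raise ConfigurationError("code emission distribution sums to zero")
    return codes, probs / total


def _is_pregnancy_code(code: str, pregnancy_codes=DEFAULT_PREGNANCY_CODES) -> bool:
    base = code.split(".")[0]
    return code in pregnancy_codes or base in pregnancy_codes


def generate_contacts(
    patients: pd.DataFrame, truth: SyntheticTruth, config: SimulationConfig
) -> pd.DataFrame:
    """Generate the contact table and fill the per-contact truth ledger.

    Pregnant-population counts follow :func:`simulate_rate_series` with the
    truth-based denominator and are attributed uniformly to patients whose
    episode covers the day. Each truth-pregnant contact either carries at
    least one pregnancy-defining ICPC code (channel ``icpc``) or, with
    probability ``text_signal_rate``, only a pregnancy note phrase (channel
    ``text_only``). Non-pregnant background contacts are added at the constant
    ``background_rate`` with decoy phrases in a ``decoy_rate`` fraction of
    notes. Weekends and holidays generate nothing.
    """
    cal = build_phase_calendar(config.phase_spec, config.date_start, config.date_end)
    config.validate(subphase_spans(cal))
    rngs = _substreams(config.seed)
    rng = rngs["contacts"]
    brng = rngs["background"]

    empty = pd.DataFrame(columns=[
        "contact_id", "patient_id", "date", "icpc_codes", "note_text",
        "contact_type", "in_office_hours"])
    if patients.empty:
        truth.contacts = pd.DataFrame(
            columns=["contact_id", "patient_id", "truth_pregnant", "channel"])
        return empty

    den = truth_denominators(patients, truth, cal)
    series = simulate_rate_series(
        config.phase_rate_params, cal, den, rng, holidays=config.holidays)

    t = truth.patients
    preg = t[t["pregnant"].astype(bool)].merge(
        patients[["patient_id", "registration_start", "registration_end"]],
        on="patient_id", how="left")
    preg_ids = preg["patient_id"].to_numpy()
    ep_s = np.array([d.toordinal() for d in preg["episode_start"]]) if len(preg) else np.array([], int)
    ep_e = np.array([d.toordinal() for d in preg["episode_end"]]) if len(preg) else np.array([], int)
    p_reg_s = np.array([d.toordinal() for d in preg["registration_start"]]) if len(preg) else np.array([], int)
    p_reg_e = np.array([
        (d.toordinal() if isinstance(d, dt.date) else 10**9)
        for d in preg["registration_end"]]) if len(preg) else np.array([], int)

    nonpreg = t[~t["pregnant"].astype(bool)]["patient_id"].to_numpy()

    mix_types = list(CONTACT_TYPES)
    preg_codes_only, preg_codes_p = {}, {}
    general_only, general_p = {}, {}
    for sub in {r for r in cal["subphase"].unique()}:
        bumps = config.code_emission_bumps.get(sub)
        preg_codes_only[sub], preg_codes_p[sub] = _renormalize(
            config.pregnant_code_dist, bumps)
        general_only[sub], general_p[sub] = _renormalize(
            config.pregnant_code_dist, bumps, keep=lambda c: not _is_pregnancy_code(c))
    preg_def_codes, preg_def_p = _renormalize(
        config.pregnant_code_dist, keep=_is_pregnancy_code)
    bg_codes, bg_p = _renormalize(config.general_code_dist)
    extra_pool, extra_p = _renormalize(config.general_code_dist)

    rows: list[tuple] = []
    truth_rows: list[tuple] = []
    counter = 0

    def emit(pid, date, codes, note, ctype, rgen, is_preg, channel):
        nonlocal counter
        ooh = bool(rgen.random() < config.out_of_hours_rate)
        cid = f"C{counter:07d}"
        counter += 1
        rows.append((cid, pid, date, ";".join(codes), note, ctype, not ooh))
        truth_rows.append((cid, pid, is_preg, channel))

    for day in series.itertuples(index=False):
        n_c = int(day.n_contacts)
        d_ord = day.date.toordinal()
        if n_c > 0:
            if len(preg) == 0:
                n_c = 0
            else:
                active = (ep_s <= d_ord) & (ep_e >= d_ord) & \
                         (p_reg_s <= d_ord) & (p_reg_e >= d_ord)
                pool = preg_ids[active]
                if len(pool) == 0:
                    n_c = 0
        mix = config.contact_type_mix[day.subphase]
        mix_p = np.array([mix[ct] for ct in mix_types])
        for _ in range(n_c):
            pid = str(pool[rng.integers(0, len(pool))])
            ctype = mix_types[rng.choice(len(mix_types), p=mix_p)]
            text_only = rng.random() < config.text_signal_rate
            if text_only:
                cs, ps = general_only[day.subphase], general_p[day.subphase]
                codes = [cs[rng.choice(len(cs), p=ps)]]
                note = config.pregnancy_phrases[rng.integers(0, len(config.pregnancy_phrases))]
                channel = "text_only"
            else:
                cs, ps = preg_codes_only[day.subphase], preg_codes_p[day.subphase]
                codes = [cs[rng.choice(len(cs), p=ps)]]
                if not any(_is_pregnancy_code(c) for c in codes):
                    codes.append(preg_def_codes[rng.choice(len(preg_def_codes), p=preg_def_p)])
                note = config.neutral_phrases[rng.integers(0, len(config.neutral_phrases))]
                channel = "icpc"
            n_extra = int(rng.poisson(config.extra_codes_mean))
            for _ in range(n_extra):
                extra = extra_pool[rng.choice(len(extra_pool), p=extra_p)]
                if extra not in codes:
                    codes.append(extra)
            emit(pid, day.date, codes, note, ctype, rng, True, channel)

        # background stream: non-pregnant women, constant intensity
        if config.background_rate > 0 and len(nonpreg):
            lam = config.background_rate * len(nonpreg) / 1000.0
            n_b = int(brng.poisson(lam))
            for _ in range(n_b):
                pid = str(nonpreg[brng.integers(0, len(nonpreg))])
                ctype = mix_types[brng.choice(len(mix_types), p=mix_p)]
                codes = [bg_codes[brng.choice(len(bg_codes), p=bg_p)]]
                if brng.random() < config.decoy_rate:
                    note = config.decoy_phrases[brng.integers(0, len(config.decoy_phrases))]
                else:
                    note = config.neutral_phrases[brng.integers(0, len(config.neutral_phrases))]
                emit(pid, day.date, codes, note, ctype, brng, False, "none")

    contacts = pd.DataFrame(rows, columns=[
        "contact_id", "patient_id", "date", "icpc_codes", "note_text",
        "contact_type", "in_office_hours"])
    truth.contacts = pd.DataFrame(truth_rows, columns=[
        "contact_id", "patient_id", "truth_pregnant", "channel"])
    return contacts


def generate_dataset(config: SimulationConfig):
    """Population + contacts in one call. Returns (patients, contacts, truth)."""
    patients, truth = generate_population(config)
    contacts = generate_contacts(patients, truth, config)
    return patients, contacts, truth


def make_manual_labels(contacts: pd.DataFrame, truth: SyntheticTruth) -> pd.DataFrame:
    """Complete manual-assessment stand-in derived from ground truth.

    Emits a verdict for every contact that only a human could adjudicate:
    ``confirm`` for truth-pregnant text-only contacts, ``reject`` for
    non-pregnant contacts whose note happens to mention pregnancy (decoys).
    """
    merged = contacts.merge(truth.contacts[["contact_id", "truth_pregnant", "channel"]],
                            on="contact_id", how="left")
    rows = []
    for row in merged.itertuples(index=False):
        if row.channel == "text_only":
            rows.append((row.contact_id, "confirm"))
        elif not row.truth_pregnant and "zwanger" in str(row.note_text).lower():
            rows.append((row.contact_id, "reject"))
    return pd.DataFrame(rows, columns=["contact_id", "verdict"])


# --------------------------------------------------------------------------
# I/O (UTF-8 CSV, ISO-8601 dates, header mandatory, '' for missing)
# --------------------------------------------------------------------------

def _date_str(v) -> str:
    return v.isoformat() if isinstance(v, dt.date) else ""


def write_dataset(patients: pd.DataFrame, contacts: pd.DataFrame,
                  truth: SyntheticTruth, directory) -> dict[str, Path]:
    """Write patients.csv, contacts.csv and the combined truth.csv ledger.

    The truth ledger holds one ``patient`` row per patient and one ``contact``
    row per contact; the generating rate parameters are echoed to
    truth_params.json. Read-back via :func:`read_dataset` round-trips
    losslessly.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {}

    p = patients.copy()
    for col in ("birth_date", "registration_start", "registration_end"):
        p[col] = p[col].map(_date_str) if len(p) else p[col]
    for col in ("death_in_period", "zip_available"):
        p[col] = p[col].map(lambda b: "true" if b else "false") if len(p) else p[col]
    paths["patients"] = directory / "patients.csv"
    p.to_csv(paths["patients"], index=False)

    c = contacts.copy()
    if len(c):
        c["date"] = c["date"].map(_date_str)
        c["in_office_hours"] = c["in_office_hours"].map(lambda b: "true" if b else "false")
    paths["contacts"] = directory / "contacts.csv"
    c.to_csv(paths["contacts"], index=False)

    ledger = []
    for row in truth.patients.itertuples(index=False):
        ledger.append(("patient", row.patient_id, "",
                       "true" if row.pregnant else "false",
                       _date_str(row.episode_start), _date_str(row.episode_end), ""))
    for row in truth.contacts.itertuples(index=False):
        ledger.append(("contact", row.patient_id, row.contact_id,
                       "true" if row.truth_pregnant else "false", "", "", row.channel))
    t = pd.DataFrame(ledger, columns=[
        "record_type", "patient_id", "contact_id", "pregnant",
        "episode_start", "episode_end", "channel"])
    paths["truth"] = directory / "truth.csv"
    t.to_csv(paths["truth"], index=False)

    paths["params"] = directory / "truth_params.json"
    params = {
        sub: {"intercept": rp.intercept, "slope": rp.slope,
              "seasonal": dict(rp.seasonal)}
        for sub, rp in truth.rate_params.items()
    }
    paths["params"].write_text(json.dumps(params, indent=2, sort_keys=True))
    return paths


def _opt_date(s: str):
    return dt.date.fromisoformat(s) if s else None


def read_patients(path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    for col in ("birth_date", "registration_start", "registration_end"):
        df[col] = df[col].map(_opt_date)
    for col in ("death_in_period", "zip_available"):
        df[col] = df[col].map(lambda s: s == "true")
    return df


def read_contacts(path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    df["date"] = df["date"].map(_opt_date)
    df["in_office_hours"] = df["in_office_hours"].map(lambda s: s == "true")
    return df


def read_dataset(directory) -> tuple[pd.DataFrame, pd.DataFrame, SyntheticTruth]:
    """Inverse of :func:`write_dataset`."""
    directory = Path(directory)
    patients = read_patients(directory / "patients.csv")
    contacts = read_contacts(directory / "contacts.csv")
    t = pd.read_csv(directory / "truth.csv", dtype=str, keep_default_na=False)
    pat = t[t["record_type"] == "patient"]
    truth_pat = pd.DataFrame({
        "patient_id": pat["patient_id"].to_numpy(),
        "pregnant": (pat["pregnant"] == "true").to_numpy(),
        "episode_start": pat["episode_start"].map(_opt_date).to_numpy(),
        "episode_end": pat["episode_end"].map(_opt_date).to_numpy(),
    })
    con = t[t["record_type"] == "contact"]
    truth_con = pd.DataFrame({
        "contact_id": con["contact_id"].to_numpy(),
        "patient_id": con["patient_id"].to_numpy(),
        "truth_pregnant": (con["pregnant"] == "true").to_numpy(),
        "channel": con["channel"].to_numpy(),
    })
    params_path = directory / "truth_params.json"
    rate_params: dict[str, RateParams] = {}
    if params_path.exists():
        raw = json.loads(params_path.read_text())
        rate_params = {
            sub: RateParams(v["intercept"], v["slope"], v["seasonal"])
            for sub, v in raw.items()
        }
    return patients, contacts, SyntheticTruth(truth_pat, truth_con, rate_params)
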