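"""Configuration objects, defaults and shared errors.

All substantive defaults live here as plain data: the pandemic phase calendar
spec, the pregnancy-defining ICPC code set, the pregnancy-relevant code list
used for symptom/diagnosis surveillance, the Dutch free-text pregnancy lexicon,
national holidays, and the synthetic-data generating parameters. Users swap any
of them through :class:`PipelineConfig` / :class:`SimulationConfig` or a YAML
file; nothing downstream hard-codes them.
"""

from __future__ import annotations

import datetime as dt
import re
from dataclasses import dataclass, field, asdict
from typing import Mapping, Sequence

import yaml


class ConfigurationError(ValueError):
    """Invalid configuration (bad phase spec, probabilities, patterns ...)."""


class ValidationError(ValueError):
    """Invalid input data (malformed rows, broken references ...)."""


# --------------------------------------------------------------------------
# Study window and pandemic phase calendar (ISO-8601 weeks)
# --------------------------------------------------------------------------

STUDY_START = dt.date(2019, 1, 1)
STUDY_END = dt.date(2021, 12, 31)

SUBPHASES: tuple[str, ...] = (
    "0", "1a", "1b", "2a", "2b", "3a", "3b", "3c", "4", "5a", "5b", "6a", "6b",
)
BASELINE_SUBPHASE = "0"

#: subphase -> list of (iso_year, first_week, last_week), inclusive.
DEFAULT_PHASE_SPEC: dict[str, list[tuple[int, int, int]]] = {
    "0": [(2019, 1, 52), (2020, 1, 8)],
    "1a": [(2020, 9, 13)],
    "1b": [(2020, 14, 22)],
    "2a": [(2020, 23, 28)],
    "2b": [(2020, 29, 40)],
    "3a": [(2020, 41, 44)],
    "3b": [(2020, 45, 53)],
    "3c": [(2021, 1, 3)],
    "4": [(2021, 4, 17)],
    "5a": [(2021, 18, 26)],
    "5b": [(2021, 27, 43)],
    "6a": [(2021, 44, 48)],
    "6b": [(2021, 49, 52)],
}

SEASONS = ("winter", "spring", "summer", "autumn")
#: dummy-coded seasonal intercepts; spring is the reference level.
SEASON_REFERENCE = "spring"

CONTACT_TYPES = ("clinic", "home_visit", "telephone", "digital")


# --------------------------------------------------------------------------
# ICPC code sets (configurable data, not code)
# --------------------------------------------------------------------------

#: Pregnancy/childbearing chapter-W codes that define pregnancy status.
#: W90 ("normal delivery liveborn") is deliberately absent: it is excluded from
#: cohort definition because of false carry-over registrations from previous
#: pregnancies, and validation refuses a set containing it.
DEFAULT_PREGNANCY_CODES: frozenset[str] = frozenset({
    "W01", "W02", "W03", "W05", "W17", "W18", "W19", "W21",
    "W27", "W28", "W29", "W70", "W71", "W75", "W76", "W78",
    "W79", "W80", "W81", "W82", "W83", "W84", "W85", "W96",
})

EXCLUDED_DELIVERY_CODE = "W90"

#: Pregnancy-relevant codes tracked for symptom/diagnosis surveillance,
#: tagged pregnancy-related vs general health.
DEFAULT_RELEVANT_CODES: dict[str, str] = {
    "W78": "pregnancy",   # pregnancy confirmed
    "W05": "pregnancy",   # vomiting/nausea of pregnancy
    "W82": "pregnancy",   # spontaneous abortion
    "W79": "pregnancy",   # unwanted pregnancy confirmed
    "W84.02": "pregnancy",  # gestational diabetes mellitus
    "U71": "general",     # cystitis / urine infection
    "U02": "general",     # frequent/urgent urination
    "X72": "general",     # urogenital candidiasis
    "D06": "general",     # localized abdominal pain
    "D12": "general",     # constipation
}

#: Case-insensitive Dutch pregnancy lexicon for free-text screening.
DEFAULT_TEXT_PATTERN = r"zwanger|gravid[ae]?|graviditeit|weken\s+amenorroe"

#: Phrases the synthetic generator writes into truth-pregnant notes that carry
#: no pregnancy ICPC code (the text-only detection channel).
DEFAULT_PREGNANCY_PHRASES = (
    "patiente is 12 weken zwanger",
    "zwangerschap bevestigd, graviditeit verloopt goed",
    "controle ivm 20 weken amenorroe",
    "zwanger, klachten besproken",
)

#: Decoy phrases: they match the lexicon but do not indicate pregnancy, so a
#: manual assessment must reject them.
DEFAULT_DECOY_PHRASES = (
    "niet zwanger",
    "zwangerschapstest negatief",
    "wil graag zwanger worden, advies gegeven",
)

DEFAULT_NEUTRAL_PHRASES = (
    "controle, geen bijzonderheden",
    "telefonisch overleg klachten",
    "medicatie herhaald",
    "verwezen naar specialist",
    "uitslag besproken",
)


# --------------------------------------------------------------------------
# Dutch national holidays 2019-2021
# --------------------------------------------------------------------------

DEFAULT_HOLIDAYS: tuple[dt.date, ...] = tuple(
    dt.date(y, m, d)
    for y, m, d in [
        (2019, 1, 1), (2019, 4, 19), (2019, 4, 21), (2019, 4, 22),
        (2019, 4, 27), (2019, 5, 5), (2019, 5, 30), (2019, 6, 9),
        (2019, 6, 10), (2019, 12, 25), (2019, 12, 26),
        (2020, 1, 1), (2020, 4, 10), (2020, 4, 12), (2020, 4, 13),
        (2020, 4, 27), (2020, 5, 5), (2020, 5, 21), (2020, 5, 31),
        (2020, 6, 1), (2020, 12, 25), (2020, 12, 26),
        (2021, 1, 1), (2021, 4, 2), (2021, 4, 4), (2021, 4, 5),
        (2021, 4, 27), (2021, 5, 5), (2021, 5, 13), (2021, 5, 23),
        (2021, 5, 24), (2021, 12, 25), (2021, 12, 26),
    ]
)


# --------------------------------------------------------------------------
# Synthetic-data generating parameters
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class RateParams:
    """Piecewise-linear daily contact intensity for one subphase.

    ``intercept`` and ``slope`` are in contacts per 1000 registered pregnant
    patients per day (slope per day into the subphase); ``seasonal`` holds
    additive intercept offsets for winter/summer/autumn (spring = 0).
    """

    intercept: float
    slope: float
    seasonal: Mapping[str, float] = field(
        default_factory=lambda: {"winter": 0.0, "summer": 0.0, "autumn": 0.0}
    )

    def intensity(self, t_days: float, season: str) -> float:
        offset = 0.0 if season == SEASON_REFERENCE else self.seasonal.get(season, 0.0)
        return self.intercept + self.slope * t_days + offset


_DEFAULT_SEASONAL = {"winter": -0.4, "summer": 0.5, "autumn": -0.2}

#: Generating intercepts/slopes per subphase; magnitudes follow the reported
#: real-cohort segment fits (intercepts ~8-11 per 1000 per day, |slope|<=0.08).
DEFAULT_PHASE_RATE_PARAMS: dict[str, RateParams] = {
    "0": RateParams(10.22, -0.001, _DEFAULT_SEASONAL),
    "1a": RateParams(10.54, -0.03, _DEFAULT_SEASONAL),
    "1b": RateParams(9.97, -0.004, _DEFAULT_SEASONAL),
    "2a": RateParams(9.62, -0.03, _DEFAULT_SEASONAL),
    "2b": RateParams(8.16, 0.04, _DEFAULT_SEASONAL),
    "3a": RateParams(9.88, -0.01, _DEFAULT_SEASONAL),
    "3b": RateParams(9.92, 0.01, _DEFAULT_SEASONAL),
    "3c": RateParams(9.92, 0.02, _DEFAULT_SEASONAL),
    "4": RateParams(11.34, -0.01, _DEFAULT_SEASONAL),
    "5a": RateParams(11.23, -0.04, _DEFAULT_SEASONAL),
    "5b": RateParams(9.62, 0.004, _DEFAULT_SEASONAL),
    "6a": RateParams(10.06, -0.01, _DEFAULT_SEASONAL),
    "6b": RateParams(9.41, -0.08, _DEFAULT_SEASONAL),
}

_BASELINE_MIX = {"clinic": 0.649, "home_visit": 0.020, "telephone": 0.317, "digital": 0.014}
_PANDEMIC_MIX = {
    "1a": {"clinic": 0.40, "home_visit": 0.015, "telephone": 0.545, "digital": 0.040},
    "1b": {"clinic": 0.45, "home_visit": 0.015, "telephone": 0.495, "digital": 0.040},
    "2a": {"clinic": 0.52, "home_visit": 0.015, "telephone": 0.430, "digital": 0.035},
    "2b": {"clinic": 0.55, "home_visit": 0.015, "telephone": 0.400, "digital": 0.035},
    "3a": {"clinic": 0.53, "home_visit": 0.015, "telephone": 0.420, "digital": 0.035},
    "3b": {"clinic": 0.52, "home_visit": 0.015, "telephone": 0.430, "digital": 0.035},
    "3c": {"clinic": 0.52, "home_visit": 0.015, "telephone": 0.430, "digital": 0.035},
    "4": {"clinic": 0.54, "home_visit": 0.015, "telephone": 0.410, "digital": 0.035},
    "5a": {"clinic": 0.56, "home_visit": 0.015, "telephone": 0.390, "digital": 0.035},
    "5b": {"clinic": 0.58, "home_visit": 0.015, "telephone": 0.370, "digital": 0.035},
    "6a": {"clinic": 0.57, "home_visit": 0.015, "telephone": 0.380, "digital": 0.035},
    "6b": {"clinic": 0.55, "home_visit": 0.015, "telephone": 0.400, "digital": 0.035},
}

DEFAULT_CONTACT_TYPE_MIX: dict[str, dict[str, float]] = {
    "0": dict(_BASELINE_MIX),
    **{k: dict(v) for k, v in _PANDEMIC_MIX.items()},
}

#: Primary-code emission probabilities for truth-pregnant contacts.
DEFAULT_PREGNANT_CODE_DIST: dict[str, float] = {
    "W78": 0.30, "W05": 0.12, "W82": 0.05, "W79": 0.04, "W84.02": 0.04,
    "U71": 0.10, "U02": 0.05, "X72": 0.05, "D06": 0.07, "D12": 0.04,
    "A97": 0.14,
}

#: Primary-code emission probabilities for background (non-pregnant) contacts.
DEFAULT_GENERAL_CODE_DIST: dict[str, float] = {
    "U71": 0.08, "U02": 0.04, "X72": 0.03, "D06": 0.10, "D12": 0.05,
    "A97": 0.25, "R74": 0.20, "L03": 0.15, "P76": 0.10,
}

#: Per-subphase multiplicative bumps on pregnant code emission (e.g. the
#: gestational-diabetes signal in mid/late pandemic subphases).
DEFAULT_CODE_EMISSION_BUMPS: dict[str, dict[str, float]] = {
    "2a": {"W84.02": 1.8, "W05": 1.5},
    "2b": {"W05": 1.5},
    "4": {"W84.02": 1.8, "W05": 1.3},
    "5a": {"W84.02": 1.8},
    "5b": {"W84.02": 1.8},
    "6b": {"W05": 1.5},
}

DEFAULT_EXCLUSION_FRACTIONS: dict[str, float] = {
    "died_in_period": 0.005,
    "deregistered_in_period": 0.010,
    "deregistration_reason_without_date": 0.005,
    "unknown_birth_date": 0.005,
    "registered_lt_min_days": 0.010,
    "missing_zip": 0.005,
}


@dataclass
class SimulationConfig:
    """Generating conditions for the synthetic primary-care EHR.

    Defaults emulate the studied population: women of reproductive age
    (20-45 y) of whom ~13.9% are pregnant during 2019-2021, daily contact
    intensities that are piecewise linear per pandemic subphase with seasonal
    intercept shifts, four contact types whose mix shifts away from clinic
    visits toward telephone during the pandemic, and Dutch free-text notes
    carrying pregnancy phrases and decoys.
    """

    n_patients: int = 5000
    date_start: dt.date = STUDY_START
    date_end: dt.date = STUDY_END
    pregnancy_prevalence: float = 0.139
    episode_days: int = 280
    phase_rate_params: Mapping[str, RateParams] = field(
        default_factory=lambda: dict(DEFAULT_PHASE_RATE_PARAMS))
    contact_type_mix: Mapping[str, Mapping[str, float]] = field(
        default_factory=lambda: {k: dict(v) for k, v in DEFAULT_CONTACT_TYPE_MIX.items()})
    pregnant_code_dist: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_PREGNANT_CODE_DIST))
    general_code_dist: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_GENERAL_CODE_DIST))
    code_emission_bumps: Mapping[str, Mapping[str, float]] = field(
        default_factory=lambda: {k: dict(v) for k, v in DEFAULT_CODE_EMISSION_BUMPS.items()})
    extra_codes_mean: float = 0.13   # Poisson mean of additional codes per contact
    text_signal_rate: float = 0.05   # truth-pregnant contacts detectable via note only
    decoy_rate: float = 0.05         # non-pregnant notes carrying a decoy phrase
    background_rate: float = 3.0     # per-1000-per-day intensity, non-pregnant women
    out_of_hours_rate: float = 0.02
    exclusion_fractions: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_EXCLUSION_FRACTIONS))
    pregnancy_phrases: Sequence[str] = DEFAULT_PREGNANCY_PHRASES
    decoy_phrases: Sequence[str] = DEFAULT_DECOY_PHRASES
    neutral_phrases: Sequence[str] = DEFAULT_NEUTRAL_PHRASES
    phase_spec: Mapping[str, list[tuple[int, int, int]]] = field(
        default_factory=lambda: dict(DEFAULT_PHASE_SPEC))
    holidays: Sequence[dt.date] = DEFAULT_HOLIDAYS
    seed: int = 0

    def validate(self, subphase_spans: Mapping[str, int] | None = None) -> None:
        """Raise :class:`ConfigurationError` on inconsistent parameters.

        ``subphase_spans`` maps subphase -> span in days, used to verify the
        piecewise-linear intensities stay nonnegative over their whole span.
        """
        if self.n_patients < 0:
            raise ConfigurationError("n_patients must be >= 0")
        if self.date_end < self.date_start:
            raise ConfigurationError("empty date_range: date_end precedes date_start")
        for name, p in [("pregnancy_prevalence", self.pregnancy_prevalence),
                        ("text_signal_rate", self.text_signal_rate),
                        ("decoy_rate", self.decoy_rate),
                        ("out_of_hours_rate", self.out_of_hours_rate)]:
            if not 0.0 <= p <= 1.0:
                raise ConfigurationError(f"{name}={p} outside [0, 1]")
        for sub, mix in self.contact_type_mix.items():
            total = sum(mix.values())
            if abs(total - 1.0) > 1e-9:
                raise ConfigurationError(
                    f"contact_type_mix for subphase {sub} sums to {total}, not 1")
            if any(v < 0 for v in mix.values()):
                raise ConfigurationError(f"negative mix probability in subphase {sub}")
        if subphase_spans:
            for sub, span in subphase_spans.items():
                rp = self.phase_rate_params.get(sub)
                if rp is None:
                    raise ConfigurationError(f"no rate parameters for subphase {sub}")
                for season in SEASONS:
                    for t in (0, span):
                        if rp.intensity(t, season) < 0:
                            raise ConfigurationError(
                                f"negative implied intensity in subphase {sub} "
                                f"(t={t}, season={season})")


# --------------------------------------------------------------------------
# Pipeline configuration
# --------------------------------------------------------------------------

@dataclass
class PipelineConfig:
    """End-to-end analysis options; every study-ambiguous choice is named here."""

    pregnancy_codes: frozenset[str] = DEFAULT_PREGNANCY_CODES
    relevant_codes: Mapping[str, str] = field(
        default_factory=lambda: dict(DEFAULT_RELEVANT_CODES))
    text_pattern: str = DEFAULT_TEXT_PATTERN
    holidays: Sequence[dt.date] = DEFAULT_HOLIDAYS
    phase_spec: Mapping[str, list[tuple[int, int, int]]] = field(
        default_factory=lambda: dict(DEFAULT_PHASE_SPEC))
    min_registration_days: int = 90
    age_range: tuple[int, int] = (20, 45)
    ma_window: int = 15              # 3 weeks x 5 weekdays, centered
    smoothing_scope: str = "global"  # or "within_subphase"
    loess_span: float = 0.3
    top_k_codes: int = 10
    denominator_mode: str = "year_label"  # or "truth_episode", "registered"
    code_test_unit: str = "contacts"      # or "registrations"
    robust_se: bool = False          # HAC (Newey-West) standard errors
    bh_correction: bool = False      # Benjamini-Hochberg on Fisher P values
    seed: int = 0

    def validate(self) -> None:
        if EXCLUDED_DELIVERY_CODE in self.pregnancy_codes:
            raise ConfigurationError(
                f"{EXCLUDED_DELIVERY_CODE} must not be in the pregnancy-defining set")
        try:
            re.compile(self.text_pattern, re.IGNORECASE)
        except re.error as exc:
            raise ConfigurationError(f"invalid text pattern: {exc}") from exc
        if self.ma_window < 1 or self.ma_window % 2 == 0:
            raise ConfigurationError("ma_window must be an odd positive count")
        if not 0.0 < self.loess_span <= 1.0:
            raise ConfigurationError("loess_span must be in (0, 1]")
        if self.smoothing_scope not in ("global", "within_subphase"):
            raise ConfigurationError(f"unknown smoothing_scope {self.smoothing_scope!r}")
        if self.denominator_mode not in ("year_label", "truth_episode", "registered"):
            raise ConfigurationError(f"unknown denominator_mode {self.denominator_mode!r}")
        if self.code_test_unit not in ("contacts", "registrations"):
            raise ConfigurationError(f"unknown code_test_unit {self.code_test_unit!r}")
        if self.min_registration_days < 0:
            raise ConfigurationError("min_registration_days must be >= 0")

    # -- YAML round trip ----------------------------------------------------

    def to_yaml(self, path) -> None:
        data = asdict(self)
        data["pregnancy_codes"] = sorted(self.pregnancy_codes)
        data["holidays"] = [d.isoformat() for d in self.holidays]
        data["age_range"] = list(self.age_range)
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(data, fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path, encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        if "pregnancy_codes" in data:
            data["pregnancy_codes"] = frozenset(data["pregnancy_codes"])
        if "holidays" in data:
            data["holidays"] = [dt.date.fromisoformat(d) for d in data["holidays"]]
        if "age_range" in data:
            data["age_range"] = tuple(data["age_range"])
        if "phase_spec" in data:
            data["phase_spec"] = {
                str(k): [tuple(span) for span in v] for k, v in data["phase_spec"].items()
            }
        cfg = cls(**data)
        cfg.validate()
        return cfg
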