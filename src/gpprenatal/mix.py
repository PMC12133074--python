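"""Contact-type mix over time, smoothing, and year-level descriptives.

Per weekday, the share of each contact type (clinic, home visit, telephone,
digital) among all included contacts is computed, smoothed with the centered
3-week moving average and renormalized, and optionally run through a locally
weighted (tricube) polynomial smoother for display. Year-level summaries give
the counts and means the study population table reports, with likelihood-ratio
(G) goodness-of-fit tests for across-year count comparisons.
"""

from __future__ import annotations

import math
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .config import CONTACT_TYPES, ConfigurationError, ValidationError
from .cohort import parse_icpc_field
from .its import smooth_centered

__all__ = [
    "contact_type_proportions",
    "loess_smooth",
    "g_test",
    "descriptive_summary",
]


def contact_type_proportions(
    included_contacts: pd.DataFrame,
    calendar: pd.DataFrame,
    window: int = 15,
) -> pd.DataFrame:
    """Per-date contact-type proportions, raw and moving-average smoothed.

    Returns one row per date with contacts: ``raw_<type>`` columns summing to
    one, ``smooth_<type>`` columns (each type smoothed separately, then
    renormalized so the smoothed shares also sum to one), and the subphase.
    Unknown contact-type values raise :class:`ValidationError`.
    """
    bad = set(included_contacts["contact_type"]) - set(CONTACT_TYPES)
    if bad:
        raise ValidationError(f"unknown contact type values: {sorted(bad)}")
    sub_of = dict(zip(calendar["date"], calendar["subphase"]))
    counts = (
        included_contacts.groupby(["date", "contact_type"]).size().unstack(fill_value=0)
    )
    for ct in CONTACT_TYPES:
        if ct not in counts.columns:
            counts[ct] = 0
    counts = counts[list(CONTACT_TYPES)].sort_index()
    totals = counts.sum(axis=1)
    counts = counts[totals > 0]
    totals = totals[totals > 0]
    raw = counts.div(totals, axis=0)

    out = pd.DataFrame({"date": raw.index})
    out["subphase"] = out["date"].map(sub_of)
    out["n_contacts"] = totals.to_numpy()
    for ct in CONTACT_TYPES:
        out[f"raw_{ct}"] = raw[ct].to_numpy()
    sm_cols = np.column_stack([
        smooth_centered(raw[ct].to_numpy(), window) for ct in CONTACT_TYPES])
    row_sums = sm_cols.sum(axis=1, keepdims=True)
    sm_cols = np.divide(sm_cols, row_sums, out=np.zeros_like(sm_cols),
                        where=row_sums > 0)
    for j, ct in enumerate(CONTACT_TYPES):
        out[f"smooth_{ct}"] = sm_cols[:, j]
    return out


def loess_smooth(y, x=None, span: float = 0.3, degree: int = 1) -> np.ndarray:
    """Locally weighted polynomial regression (tricube weights).

    At each point, a degree-``degree`` polynomial is fit by weighted least
    squares over the ``ceil(span*n)`` nearest neighbours, weighted by the
    tricube kernel of distance scaled to the farthest in-window neighbour.
    When the window covers the entire series the weights are uniform, so
    span=1, degree=1 reduces to the global least-squares line. Exactly linear
    input is reproduced for any span (a local line fits a global line
    everywhere).
    """
    y = np.asarray(y, dtype=float)
    n = len(y)
    if n < 3:
        raise ConfigurationError("loess needs at least 3 points")
    if not 0.0 < span <= 1.0:
        raise ConfigurationError(f"span {span} outside (0, 1]")
    x = np.arange(n, dtype=float) if x is None else np.asarray(x, dtype=float)
    q = max(int(math.ceil(span * n)), degree + 2)
    if q > n:
        raise ConfigurationError(
            f"window of {q} points exceeds series length {n}")
    out = np.empty(n)
    for i in range(n):
        d = np.abs(x - x[i])
        idx = np.argsort(d, kind="stable")[:q]
        dmax = d[idx].max()
        if q >= n or dmax == 0:
            w = np.ones(len(idx))
        else:
            w = (1.0 - (d[idx] / dmax) ** 3) ** 3
            w = np.clip(w, 0.0, None)
        X = np.vander(x[idx] - x[i], degree + 1, increasing=True)
        sw = np.sqrt(w)
        beta, *_ = np.linalg.lstsq(X * sw[:, None], y[idx] * sw, rcond=None)
        out[i] = beta[0]
    return out


def g_test(observed, expected=None) -> tuple[float, int, float]:
    """Likelihood-ratio goodness-of-fit test.

    G = 2 * sum(O * ln(O/E)) over cells with O > 0, df = cells - 1, P from the
    chi-square upper tail. ``expected=None`` means equal expected counts.
    An expected cell of 0 with observed > 0 is an error.
    """
    obs = np.asarray(observed, dtype=float)
    if (obs < 0).any():
        raise ValidationError("negative observed count")
    total = obs.sum()
    if expected is None:
        exp = np.full_like(obs, total / len(obs))
    else:
        exp = np.asarray(expected, dtype=float)
        if len(exp) != len(obs):
            raise ValidationError("observed and expected lengths differ")
        if not math.isclose(exp.sum(), total, rel_tol=1e-9, abs_tol=1e-9):
            raise ValidationError("expected counts must sum to the observed total")
    if ((exp == 0) & (obs > 0)).any():
        raise ValidationError("expected cell is 0 where observed > 0")
    mask = obs > 0
    g = 2.0 * float((obs[mask] * np.log(obs[mask] / exp[mask])).sum())
    df = len(obs) - 1
    p = float(stats.chi2.sf(g, df)) if df > 0 else 1.0
    return g, df, p


def _mean_sd(values: Sequence[float]) -> tuple[float, float]:
    arr = np.asarray(list(values), dtype=float)
    if len(arr) == 0:
        return float("nan"), float("nan")
    sd = float(arr.std(ddof=1)) if len(arr) > 1 else 0.0
    return float(arr.mean()), sd


def descriptive_summary(
    patients: pd.DataFrame,
    included_contacts: pd.DataFrame,
    labels: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Study-population characteristics per year plus the overall total.

    Per calendar year: pregnant women with at least one included contact that
    year, total contacts, mean (sample SD) contacts per patient, mean (SD)
    ICPC registrations per contact, mean (SD) age at first contact of the
    year. Yearly populations may overlap; the ``total`` row is computed over
    the union of patients and all contacts. Across-year G-tests (equal-counts
    null) are attached for the women and contact counts.
    """
    contacts = included_contacts.copy()
    if labels is not None and len(labels):
        confirmed = set(labels.loc[
            labels["status"].str.startswith("confirmed"), "contact_id"])
        contacts = contacts[contacts["contact_id"].isin(confirmed)]
    birth = dict(zip(patients["patient_id"], patients["birth_date"]))

    def summarize(subset: pd.DataFrame, label) -> dict:
        by_patient = subset.groupby("patient_id")
        n_contacts_pp = by_patient.size()
        mean_c, sd_c = _mean_sd(n_contacts_pp)
        regs = [len(parse_icpc_field(f)) for f in subset["icpc_codes"]]
        mean_r, sd_r = _mean_sd(regs)
        ages = []
        for pid, grp in by_patient:
            b = birth.get(pid)
            if b is not None and not (isinstance(b, float) and math.isnan(b)):
                first = grp["date"].min()
                ages.append(first.year - b.year
                            - ((first.month, first.day) < (b.month, b.day)))
        mean_a, sd_a = _mean_sd(ages)
        return {
            "year": label,
            "pregnant_women": int(subset["patient_id"].nunique()),
            "total_contacts": int(len(subset)),
            "mean_contacts_per_patient": mean_c,
            "sd_contacts_per_patient": sd_c,
            "mean_registrations_per_contact": mean_r,
            "sd_registrations_per_contact": sd_r,
            "mean_age": mean_a,
            "sd_age": sd_a,
        }

    years = sorted({d.year for d in contacts["date"]}) if len(contacts) else []
    rows = [summarize(contacts[[d.year == y for d in contacts["date"]]], y)
            for y in years]
    rows.append(summarize(contacts, "total"))
    out = pd.DataFrame(rows)

    if len(years) > 1:
        g_w, df_w, p_w = g_test([r["pregnant_women"] for r in rows[:-1]])
        g_c, df_c, p_c = g_test([r["total_contacts"] for r in rows[:-1]])
        out.attrs["g_test_women"] = {"G": g_w, "df": df_w, "p": p_w}
        out.attrs["g_test_contacts"] = {"G": g_c, "df": df_c, "p": p_c}
    return out
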