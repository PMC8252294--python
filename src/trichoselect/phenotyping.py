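"""Bioassay phenotyping: resistant/susceptible labels from raw assay records.

Whitefly no-choice cage assays are analysed with a fixed-effects binomial GLM
(logit link) on per-plant alive/dead counts, with a designated susceptible
standard accession as the intercept; an accession is labelled resistant when
its coefficient is negative (lower survival odds than the standard) and
Wald-significant at ``alpha`` (default 0.05).  Accessions with 0% survival
cannot enter the logit fit and are excluded and labelled resistant directly.

Thrips leaf-disc assays (one larva per well, observed daily, right-censored
at the follow-up horizon) are summarised per accession by the Kaplan-Meier
median survival time and modelled jointly with a Cox proportional-hazards
regression on accession (Efron tie handling by default — the daily grid
produces heavy ties); an accession is labelled resistant when its hazard
ratio versus the standard exceeds 1 at ``alpha`` (default 0.01): larvae die
faster on resistant plants.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from lifelines import CoxPHFitter, KaplanMeierFitter

__all__ = [
    "mean_survival",
    "fit_whitefly_glm",
    "classify_whitefly",
    "kaplan_meier",
    "fit_cox",
    "classify_thrips",
    "phenotype_whitefly",
    "phenotype_thrips",
]

# Wald SEs beyond this (logit / log-hazard scale) indicate separation or a
# monotone likelihood: the coefficient is reported but flagged non-estimable.
_SE_NON_ESTIMABLE = 50.0


class MissingDataError(ValueError):
    pass


def _check_whitefly(records: pd.DataFrame) -> pd.DataFrame:
    need = {"accession", "plant_id", "n_alive", "n_dead"}
    missing = need - set(records.columns)
    if missing:
        raise MissingDataError(f"whitefly records missing columns {sorted(missing)}")
    if records.empty:
        raise MissingDataError("no whitefly records")
    if (records["n_alive"] < 0).any() or (records["n_dead"] < 0).any():
        raise ValueError("negative counts")
    if ((records["n_alive"] + records["n_dead"]) <= 0).any():
        raise ValueError("cage with no insects")
    return records


def mean_survival(records: pd.DataFrame) -> pd.DataFrame:
    """Per-accession mean survival fraction and SE.

    Averaging order follows the assay design: cage fraction -> mean over the
    cages of a plant -> mean over plants; the SE is across plant means
    (ddof=1; NaN for a single plant).
    """
    rec = _check_whitefly(records).copy()
    rec["fraction"] = rec["n_alive"] / (rec["n_alive"] + rec["n_dead"])
    plant = rec.groupby(["accession", "plant_id"])["fraction"].mean()
    grouped = plant.groupby("accession")
    out = pd.DataFrame(
        {
            "mean_survival": grouped.mean(),
            "se": grouped.sem(ddof=1),
            "n_plants": grouped.size(),
        }
    )
    return out


def fit_whitefly_glm(
    records: pd.DataFrame, baseline_accession: str
) -> pd.DataFrame:
    """Binomial GLM (logit) of per-plant alive/dead counts on accession.

    The baseline accession is the reference level (intercept); every other
    accession gets a logit-scale coefficient, Wald SE and p-value.
    Accessions whose overall survival is exactly 0% are excluded from the fit
    (their logit is -inf) and returned flagged; other separations (e.g. 100%
    survival) are reported as non-estimable rather than raising.
    """
    rec = _check_whitefly(records)
    accs = sorted(rec["accession"].unique())
    if baseline_accession not in accs:
        raise MissingDataError(f"baseline accession {baseline_accession!r} absent")
    if len(accs) < 2:
        raise MissingDataError("need at least two accessions")

    totals = rec.groupby("accession")[["n_alive", "n_dead"]].sum()
    zero_surv = totals.index[totals["n_alive"] == 0].tolist()
    if baseline_accession in zero_surv:
        raise MissingDataError("baseline accession has zero survival")

    plant = rec.groupby(["accession", "plant_id"])[["n_alive", "n_dead"]].sum().reset_index()
    fit_data = plant[~plant["accession"].isin(zero_surv)]
    levels = [baseline_accession] + [
        a for a in sorted(fit_data["accession"].unique()) if a != baseline_accession
    ]
    cat = pd.Categorical(fit_data["accession"], categories=levels)
    X = pd.get_dummies(pd.Series(cat, name="accession"), drop_first=True, dtype=float)
    X = sm.add_constant(X)
    endog = fit_data[["n_alive", "n_dead"]].to_numpy(dtype=float)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # separation warnings handled via SE flag
        res = sm.GLM(endog, X, family=sm.families.Binomial()).fit()

    rows = []
    for acc in accs:
        if acc == baseline_accession:
            rows.append((acc, 0.0, 0.0, np.nan, "baseline"))
        elif acc in zero_surv:
            rows.append((acc, -np.inf, np.nan, np.nan, "excluded from GLM: zero survival"))
        else:
            coef = res.params[acc]
            se = res.bse[acc]
            p = res.pvalues[acc]
            note = "" if se < _SE_NON_ESTIMABLE else "non-estimable: separation"
            rows.append((acc, coef, se, p, note))
    return pd.DataFrame(
        rows, columns=["accession", "coefficient", "se", "p_value", "note"]
    ).set_index("accession")


def classify_whitefly(glm_results: pd.DataFrame, alpha: float = 0.05) -> pd.DataFrame:
    """Resistant iff coefficient < 0 (lower survival than standard) and p < alpha.

    Zero-survival exclusions are resistant by construction; the baseline and
    non-estimable accessions are susceptible.
    """
    rows = []
    for acc, r in glm_results.iterrows():
        note = r["note"]
        if note == "baseline":
            cls = "susceptible"
        elif note.startswith("excluded"):
            cls = "resistant"
        elif note.startswith("non-estimable"):
            cls = "susceptible"
        else:
            cls = (
                "resistant"
                if (r["coefficient"] < 0 and r["p_value"] < alpha)
                else "susceptible"
            )
        rows.append(
            (acc, "whitefly", cls, r["coefficient"], np.exp(r["coefficient"]),
             r["p_value"], note)
        )
    return pd.DataFrame(
        rows,
        columns=["accession", "insect", "class", "coefficient",
                 "exp_coefficient", "p_value", "note"],
    )


def _check_thrips(events: pd.DataFrame) -> pd.DataFrame:
    need = {"accession", "day", "status"}
    missing = need - set(events.columns)
    if missing:
        raise MissingDataError(f"thrips records missing columns {sorted(missing)}")
    if events.empty:
        raise MissingDataError("no thrips records")
    if (events["day"] < 1).any():
        raise ValueError("event days must be >= 1")
    if not events["status"].isin([0, 1]).all():
        raise ValueError("status must be 0 (censored) or 1 (died)")
    return events


def kaplan_meier(events: pd.DataFrame, interpolate: bool = False) -> pd.DataFrame:
    """Product-limit survival estimate and median survival time per accession.

    The median is the smallest observed time with S(t) <= 0.5; if the curve
    never reaches 0.5 the median is reported as ``inf`` (beyond the horizon).
    ``interpolate=True`` instead linearly interpolates the step curve between
    grid days to the 0.5 crossing, mimicking tools that report half-days.
    Returns a per-accession frame plus the full curves in ``attrs['curves']``.
    """
    ev = _check_thrips(events)
    rows = []
    curves = []
    for acc, g in ev.groupby("accession"):
        kmf = KaplanMeierFitter()
        kmf.fit(g["day"], g["status"], label=str(acc))
        median = float(kmf.median_survival_time_)
        if interpolate and np.isfinite(median):
            sf = kmf.survival_function_.iloc[:, 0]
            below = sf[sf <= 0.5]
            t1 = below.index[0]
            prev = sf[sf.index < t1]
            if len(prev) and below.iloc[0] < 0.5:
                t0, s0 = prev.index[-1], prev.iloc[-1]
                s1 = below.iloc[0]
                median = float(t0 + (s0 - 0.5) * (t1 - t0) / (s0 - s1))
        rows.append((acc, median, int(g["status"].sum()), len(g)))
        cf = kmf.survival_function_.reset_index()
        cf.columns = ["day", "survival"]
        cf.insert(0, "accession", acc)
        curves.append(cf)
    out = pd.DataFrame(rows, columns=["accession", "median_survival", "n_deaths", "n"])
    out = out.set_index("accession")
    out.attrs["curves"] = pd.concat(curves, ignore_index=True)
    return out


def fit_cox(
    events: pd.DataFrame,
    baseline_accession: str,
    ties: str = "efron",
) -> pd.DataFrame:
    """Cox proportional-hazards fit with accession as the explanatory variable.

    Returns per-accession log-hazard coefficient versus the baseline, its
    exponential (the hazard ratio), SE and p-value.  Accessions with zero
    deaths make the partial likelihood monotone; they are excluded from the
    fit and flagged non-estimable.  ``ties`` is "efron" (default, via
    lifelines — appropriate for the heavy ties of a daily grid) or "breslow"
    (via statsmodels PHReg).
    """
    if ties not in ("efron", "breslow"):
        raise ValueError("ties must be 'efron' or 'breslow'")
    ev = _check_thrips(events)
    accs = sorted(ev["accession"].unique())
    if baseline_accession not in accs:
        raise MissingDataError(f"baseline accession {baseline_accession!r} absent")
    if len(accs) < 2:
        raise MissingDataError("need at least two accessions")
    if ev["status"].sum() == 0:
        raise MissingDataError("no deaths observed; Cox model undefined")

    deaths = ev.groupby("accession")["status"].sum()
    no_death = deaths.index[deaths == 0].tolist()
    fit_ev = ev[~ev["accession"].isin(no_death)].copy()

    levels = [baseline_accession] + [
        a for a in sorted(fit_ev["accession"].unique()) if a != baseline_accession
    ]
    dummies = pd.get_dummies(
        pd.Categorical(fit_ev["accession"], categories=levels), drop_first=True,
        dtype=float,
    )
    dummies.columns = [str(c) for c in dummies.columns]
    df = pd.concat(
        [fit_ev[["day", "status"]].reset_index(drop=True),
         dummies.reset_index(drop=True)],
        axis=1,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        if ties == "efron":
            cph = CoxPHFitter()
            cph.fit(df, duration_col="day", event_col="status")
            params = cph.params_
            ses = cph.standard_errors_
            pvals = cph.summary["p"]
        else:
            exog = df.drop(columns=["day", "status"])
            res = sm.PHReg(
                df["day"], exog, status=df["status"], ties="breslow"
            ).fit()
            params = pd.Series(res.params, index=exog.columns)
            ses = pd.Series(res.bse, index=exog.columns)
            pvals = pd.Series(res.pvalues, index=exog.columns)

    rows = []
    for acc in accs:
        if acc == baseline_accession:
            rows.append((acc, 0.0, 1.0, 0.0, np.nan, "baseline"))
        elif acc in no_death:
            rows.append((acc, np.nan, np.nan, np.nan, np.nan,
                         "non-estimable: zero deaths"))
        else:
            coef = float(params[acc])
            se = float(ses[acc])
            p = float(pvals[acc])
            note = "" if se < _SE_NON_ESTIMABLE else "non-estimable: monotone likelihood"
            rows.append((acc, coef, float(np.exp(coef)), se, p, note))
    return pd.DataFrame(
        rows,
        columns=["accession", "coefficient", "exp_coefficient", "se", "p_value", "note"],
    ).set_index("accession")


def classify_thrips(cox_results: pd.DataFrame, alpha: float = 0.01) -> pd.DataFrame:
    """Resistant iff hazard ratio > 1 and p < alpha; baseline susceptible.

    Zero-death accessions (nothing died: a hospitable host) are susceptible.
    """
    rows = []
    for acc, r in cox_results.iterrows():
        note = r["note"]
        if note == "baseline" or note.startswith("non-estimable"):
            cls = "susceptible"
        else:
            cls = (
                "resistant"
                if (r["exp_coefficient"] > 1 and r["p_value"] < alpha)
                else "susceptible"
            )
        rows.append(
            (acc, "thrips", cls, r["coefficient"], r["exp_coefficient"],
             r["p_value"], note)
        )
    return pd.DataFrame(
        rows,
        columns=["accession", "insect", "class", "coefficient",
                 "exp_coefficient", "p_value", "note"],
    )


def phenotype_whitefly(
    records: pd.DataFrame, baseline_accession: str, alpha: float = 0.05
) -> pd.DataFrame:
    """GLM fit + classification in one call."""
    return classify_whitefly(fit_whitefly_glm(records, baseline_accession), alpha)


def phenotype_thrips(
    records: pd.DataFrame,
    baseline_accession: str,
    alpha: float = 0.01,
    ties: str = "efron",
) -> pd.DataFrame:
    """Cox fit + classification in one call."""
    return classify_thrips(fit_cox(records, baseline_accession, ties=ties), alpha)
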