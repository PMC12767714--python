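"""Raw-record harmonization, chained-equation imputation, and weighted
descriptive summaries.

Harmonization turns raw service fields (visit and dose counts, care flags)
into the 12 binary indicators.  The antenatal-care threshold follows the
WHO guideline change: at least 4 visits for surveys before 2017, at least 8
from 2017 on.  Tetanus protection requires >= 2 toxoid doses; DPT and polio
require the full 3-dose series.  Age-appropriate breastfeeding arrives as a
pre-coded binary flag and is passed through unchanged.  Missing inputs
propagate to missing indicators.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .measurement import IndicatorMatrix
from .synthetic import INDICATOR_NAMES

# raw column -> (indicator, rule); counts are thresholded, flags pass through
RAW_COLUMNS = {
    "anc_visits": "count",
    "tetanus_doses": "count",
    "facility_delivery": "flag",
    "skilled_attendant": "flag",
    "pnc_mother_2d": "flag",
    "pnc_newborn_2d": "flag",
    "modern_fp": "flag",
    "bcg": "flag",
    "dpt_doses": "count",
    "polio_doses": "count",
    "measles": "flag",
    "age_appropriate_bf": "flag",
}

_FLAG_TO_INDICATOR = {
    "facility_delivery": "facility_delivery",
    "skilled_attendant": "skilled_attendant",
    "pnc_mother_2d": "pnc_mother",
    "pnc_newborn_2d": "pnc_newborn",
    "modern_fp": "modern_fp",
    "bcg": "bcg",
    "measles": "measles",
    "age_appropriate_bf": "breastfeeding",
}

ANC_GUIDELINE_CHANGE_YEAR = 2017
TETANUS_MIN_DOSES = 2
DPT_MIN_DOSES = 3
POLIO_MIN_DOSES = 3


@dataclass
class PreparedDataset:
    """Harmonized indicators plus covariates and weights."""

    indicators: IndicatorMatrix
    individual_covariates: pd.DataFrame | None = None
    country_covariates: pd.DataFrame | None = None
    standardization: pd.DataFrame | None = None   # mean/sd used on country covs
    error_report: pd.DataFrame | None = None

    @property
    def weights(self) -> np.ndarray:
        return self.indicators.weights


def _threshold(series: pd.Series, minimum: int) -> np.ndarray:
    vals = pd.to_numeric(series, errors="coerce")
    out = (vals >= minimum).astype(float)
    out[vals.isna()] = np.nan
    return out.to_numpy()


def harmonize_indicators(raw: pd.DataFrame) -> tuple[IndicatorMatrix, pd.DataFrame]:
    """Harmonize a raw record table into the N x 12 indicator matrix.

    Requires ``country_id`` and ``survey_year``; ``weight`` defaults to 1.
    ANC = 1 iff visits >= 4 for survey_year < 2017, else visits >= 8;
    records with an unparseable year are retained with ANC missing and
    reported in the returned error table.
    """
    if "country_id" not in raw.columns:
        raise ValueError("raw table needs a country_id column")
    n = len(raw)
    if n == 0:
        raise ValueError("empty raw table")
    year = pd.to_numeric(raw.get("survey_year"), errors="coerce")
    bad_year = year.isna() | (year < 1000) | (year > 9999)
    errors = pd.DataFrame({
        "row": np.flatnonzero(bad_year.to_numpy()),
        "problem": "unknown survey_year; ANC indicator set missing",
    })

    cols = {}
    visits = pd.to_numeric(raw.get("anc_visits"), errors="coerce")
    need = np.where(year < ANC_GUIDELINE_CHANGE_YEAR, 4, 8)
    anc = (visits >= need).astype(float)
    anc[visits.isna() | bad_year] = np.nan
    cols["anc4"] = anc.to_numpy()
    cols["tetanus2"] = _threshold(raw.get("tetanus_doses", pd.Series(np.nan, index=raw.index)),
                                  TETANUS_MIN_DOSES)
    cols["dpt3"] = _threshold(raw.get("dpt_doses", pd.Series(np.nan, index=raw.index)),
                              DPT_MIN_DOSES)
    cols["polio3"] = _threshold(raw.get("polio_doses", pd.Series(np.nan, index=raw.index)),
                                POLIO_MIN_DOSES)
    for rawname, indname in _FLAG_TO_INDICATOR.items():
        s = pd.to_numeric(raw.get(rawname, pd.Series(np.nan, index=raw.index)),
                          errors="coerce")
        ok = s.isin([0, 1]) | s.isna()
        if not ok.all():
            raise ValueError(f"column {rawname} must be 0/1/missing")
        cols[indname] = s.to_numpy(dtype=float)

    values = np.column_stack([cols[name] for name in INDICATOR_NAMES])
    weights = pd.to_numeric(raw.get("weight", pd.Series(1.0, index=raw.index)),
                            errors="coerce").fillna(1.0).to_numpy()
    mat = IndicatorMatrix(values=values, group_ids=raw["country_id"].to_numpy(),
                          weights=weights, indicator_names=list(INDICATOR_NAMES))
    return mat, errors


def standardize_country_covariates(df: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """z-score continuous country-level covariates; returns the transformed
    frame and a (column, mean, sd) table for back-transforming reports."""
    out = df.copy()
    rows = []
    for c in df.columns:
        if pd.api.types.is_numeric_dtype(df[c]):
            mu, sd = float(df[c].mean()), float(df[c].std(ddof=0))
            sd = sd if sd > 0 else 1.0
            out[c] = (df[c] - mu) / sd
            rows.append({"column": c, "mean": mu, "sd": sd})
    return out, pd.DataFrame(rows)


def chained_impute(data: PreparedDataset, cycles: int = 10, m: int = 5,
                   seed: int = 0) -> list[PreparedDataset]:
    """Multiple imputation by chained equations on the indicator matrix.

    Each incomplete binary indicator is regressed (logistic) on all other
    indicators and any individual covariates; imputations are Bernoulli
    draws from the fitted predictive probability.  Variables are visited in
    order of increasing missingness, for ``cycles`` full passes, producing
    ``m`` completed datasets.  Observed cells are never altered.
    """
    from sklearn.linear_model import LogisticRegression

    Y = data.indicators.values
    miss = np.isnan(Y)
    if (miss.all(axis=0)).any():
        j = int(np.flatnonzero(miss.all(axis=0))[0])
        name = (data.indicators.indicator_names or [f"y{i+1}" for i in range(Y.shape[1])])[j]
        raise ValueError(f"column {name!r} has no observed values and cannot be imputed")
    if not miss.any():
        return [data] * m

    extra = None
    if data.individual_covariates is not None and len(data.individual_covariates.columns):
        extra = pd.get_dummies(data.individual_covariates, drop_first=True).to_numpy(float)

    order = np.argsort(miss.sum(axis=0))
    order = [j for j in order if miss[:, j].any()]
    ss = np.random.SeedSequence(seed)
    out = []
    for child in ss.spawn(m):
        rng = np.random.default_rng(child)
        # initial fill: draws from the observed marginal
        Yc = Y.copy()
        for j in range(Y.shape[1]):
            mj = miss[:, j]
            if mj.any():
                p = np.nanmean(Y[:, j])
                Yc[mj, j] = rng.binomial(1, p, size=mj.sum())
        for _ in range(cycles):
            for j in order:
                mj = miss[:, j]
                others = np.delete(Yc, j, axis=1)
                X = others if extra is None else np.column_stack([others, extra])
                yobs = Yc[~mj, j]
                if len(np.unique(yobs)) < 2:
                    p = np.full(mj.sum(), yobs.mean() if len(yobs) else 0.5)
                else:
                    clf = LogisticRegression(max_iter=200, C=1e4)
                    clf.fit(X[~mj], yobs)
                    p = clf.predict_proba(X[mj])[:, 1]
                Yc[mj, j] = rng.binomial(1, p)
        mat = IndicatorMatrix(values=Yc, group_ids=data.indicators.group_ids,
                              weights=data.indicators.weights.copy(),
                              indicator_names=data.indicators.indicator_names)
        out.append(PreparedDataset(indicators=mat,
                                   individual_covariates=data.individual_covariates,
                                   country_covariates=data.country_covariates,
                                   standardization=data.standardization))
    return out


def weighted_summaries(data: PreparedDataset):
    """Weighted descriptive tables.

    Returns (indicator_table, country_table): per-indicator weighted count
    and percent of the total weighted sample (one decimal), and per-country
    weighted count and percent share.
    """
    mat = data.indicators
    if mat.n_records == 0:
        raise ValueError("empty dataset")
    w = mat.weights
    total = w.sum()
    names = mat.indicator_names or [f"y{h+1}" for h in range(mat.H)]
    rows = []
    for h, name in enumerate(names):
        obs = ~np.isnan(mat.values[:, h])
        wn = float((w[obs] * mat.values[obs, h]).sum())
        rows.append({"name": name, "weighted_n": wn,
                     "percent": round(100.0 * wn / total, 1)})
    ind = pd.DataFrame(rows)
    cdf = pd.DataFrame({"country": np.asarray(mat.group_labels)[mat.group_index],
                        "weight": w})
    by = cdf.groupby("country")["weight"].sum()
    country = pd.DataFrame({"name": by.index, "weighted_n": by.to_numpy(),
                            "percent": np.round(100.0 * by.to_numpy() / total, 1)})
    return ind, country.reset_index(drop=True)
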