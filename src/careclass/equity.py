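"""Health-inequality measures on a stratified outcome.

The outcome is the posterior probability of belonging to the optimal
utilization class (a MAP indicator is available via a flag upstream); the
stratifiers are equity dimensions such as wealth quintile, maternal
education, residence, and occupation.  Four measure families:

- simple: absolute difference and relative ratio between an advantaged and a
  disadvantaged subgroup;
- disproportionality (ordered stratifiers): absolute and relative
  concentration indices from grouped data with midpoint cumulative ranks;
- regression-based (ordered stratifiers): slope and relative index of
  inequality from a share-weighted regression of subgroup means on midpoint
  rank (logit link by default; identity available);
- impact: population attributable risk and fraction against the
  best-performing (or named) reference subgroup.

Confidence intervals resample countries with replacement (percentile
bootstrap), reflecting clustering of outcomes at the national level.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import expit


@dataclass
class StratifiedOutcome:
    """Subgroup-aggregated outcome with per-record backing data.

    ``order`` lists subgroup labels from most disadvantaged to most
    advantaged when the stratifier is ordered; for unordered (binary)
    dimensions pass ``ordered=False`` and any label order.
    """

    records: pd.DataFrame          # columns: outcome, subgroup, country, weight
    order: list
    ordered: bool = True
    dimension: str = ""

    def __post_init__(self) -> None:
        req = {"outcome", "subgroup", "country", "weight"}
        if not req.issubset(self.records.columns):
            raise ValueError(f"records must have columns {sorted(req)}")
        present = set(self.records["subgroup"].unique())
        if not present.issubset(set(self.order)):
            raise ValueError("order must cover every subgroup present")
        out = self.records["outcome"].to_numpy(dtype=float)
        if ((out < 0) | (out > 1)).any():
            raise ValueError("outcome must lie in [0, 1]")

    @classmethod
    def from_arrays(cls, outcome, subgroup, country, weight=None, order=None,
                    ordered=True, dimension=""):
        outcome = np.asarray(outcome, dtype=float)
        df = pd.DataFrame({
            "outcome": outcome,
            "subgroup": np.asarray(subgroup),
            "country": np.asarray(country),
            "weight": np.ones(len(outcome)) if weight is None else np.asarray(weight, float),
        })
        if order is None:
            order = sorted(df["subgroup"].unique().tolist())
        return cls(records=df, order=list(order), ordered=ordered, dimension=dimension)

    def aggregate(self, records: pd.DataFrame | None = None):
        """(labels, p_g shares, y_g means, mu) in ``order``; absent subgroups
        are dropped."""
        df = self.records if records is None else records
        g = df.groupby("subgroup", sort=False)
        wsum = g["weight"].sum()
        wy = g.apply(lambda s: np.average(s["outcome"], weights=s["weight"]),
                     include_groups=False)
        labels = [l for l in self.order if l in wsum.index]
        p = np.array([wsum[l] for l in labels], dtype=float)
        p = p / p.sum()
        y = np.array([wy[l] for l in labels], dtype=float)
        mu = float(p @ y)
        return labels, p, y, mu


@dataclass
class EquityEstimate:
    dimension: str
    measure: str
    estimate: float
    ci_low: float | None = None
    ci_high: float | None = None
    kind: str = ""                # "absolute" or "relative"


def simple_measures(s: StratifiedOutcome, advantaged, disadvantaged):
    """(difference, ratio) = (y_adv - y_dis, y_adv / y_dis)."""
    labels, p, y, mu = s.aggregate()
    means = dict(zip(labels, y))
    if advantaged not in means or disadvantaged not in means:
        raise ValueError("both subgroup labels must be present")
    ya, yd = means[advantaged], means[disadvantaged]
    if yd == 0:
        raise ZeroDivisionError("disadvantaged subgroup mean is zero; ratio undefined")
    return ya - yd, ya / yd


def _midpoint_ranks(p: np.ndarray) -> np.ndarray:
    """Cumulative population share at the subgroup midpoint, in the stated
    disadvantaged -> advantaged order."""
    c = np.concatenate([[0.0], np.cumsum(p)])
    return c[:-1] + p / 2


def concentration_indices(s: StratifiedOutcome, records: pd.DataFrame | None = None):
    """(ACI, RCI) from grouped data.

    RCI = (2/mu) * sum_g p_g y_g x_g - 1 with x_g the midpoint cumulative
    rank; ACI = mu * RCI.  Positive values mean the outcome is concentrated
    among the advantaged.
    """
    if not s.ordered:
        raise ValueError("concentration indices need an ordered stratifier")
    _, p, y, mu = s.aggregate(records)
    x = _midpoint_ranks(p)
    rci = (2.0 / mu) * float(np.sum(p * y * x)) - 1.0
    return mu * rci, rci


def sii_rii(s: StratifiedOutcome, link: str = "logit",
            records: pd.DataFrame | None = None):
    """(SII, RII) from a share-weighted regression of y_g on midpoint rank.

    Predictions at rank 1 (most advantaged, nu1) and rank 0 (nu0) give
    SII = nu1 - nu0 and RII = nu1 / nu0.  The default logit link keeps
    predictions inside (0, 1) for this bounded outcome; ``link="identity"``
    uses weighted least squares.
    """
    if not s.ordered:
        raise ValueError("SII/RII need an ordered stratifier")
    _, p, y, _ = s.aggregate(records)
    if len(p) < 2:
        raise ValueError("need at least 2 subgroups")
    x = _midpoint_ranks(p)
    if link == "identity":
        Xd = np.column_stack([np.ones_like(x), x])
        W = np.diag(p)
        coef = np.linalg.solve(Xd.T @ W @ Xd, Xd.T @ W @ y)
        nu0, nu1 = coef[0], coef[0] + coef[1]
        if nu0 == 0:
            raise ZeroDivisionError("prediction at rank 0 is zero; RII undefined")
    elif link == "logit":
        import statsmodels.api as sm
        Xd = sm.add_constant(x)
        eps = 1e-9
        yy = np.clip(y, eps, 1 - eps)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = sm.GLM(yy, Xd, family=sm.families.Binomial(),
                         var_weights=p * len(p)).fit()
        a, b = fit.params
        nu0, nu1 = expit(a), expit(a + b)
    else:
        raise ValueError("link must be 'logit' or 'identity'")
    return float(nu1 - nu0), float(nu1 / nu0)


def par_paf(s: StratifiedOutcome, reference="best",
            records: pd.DataFrame | None = None):
    """(PAR, PAF): absolute and percentage gain in overall coverage if every
    subgroup matched the reference.

    PAR = max(y_ref - mu, 0); PAF = 100 * PAR / mu.  ``reference="best"``
    takes the best-performing subgroup of this favourable outcome.
    """
    labels, p, y, mu = s.aggregate(records)
    if mu <= 0:
        raise ValueError("overall mean must be positive")
    if reference == "best":
        y_ref = float(np.max(y))
    else:
        means = dict(zip(labels, y))
        if reference not in means:
            raise ValueError(f"reference subgroup {reference!r} not present")
        y_ref = means[reference]
    par = max(y_ref - mu, 0.0)
    return par, 100.0 * par / mu


_MEASURES = {
    "ACI": lambda s, rec: concentration_indices(s, rec)[0],
    "RCI": lambda s, rec: concentration_indices(s, rec)[1],
    "SII": lambda s, rec: sii_rii(s, records=rec)[0],
    "RII": lambda s, rec: sii_rii(s, records=rec)[1],
    "PAR": lambda s, rec: par_paf(s, records=rec)[0],
    "PAF": lambda s, rec: par_paf(s, records=rec)[1],
}

_KIND = {"difference": "absolute", "ratio": "relative", "ACI": "absolute",
         "RCI": "relative", "SII": "absolute", "RII": "relative",
         "PAR": "absolute", "PAF": "relative"}


def cluster_bootstrap_ci(s: StratifiedOutcome, measure: str, B: int = 1000,
                         level: float = 0.95, seed: int = 0,
                         advantaged=None, disadvantaged=None) -> EquityEstimate:
    """Percentile bootstrap CI resampling countries with replacement.

    ``measure`` is one of difference, ratio, ACI, RCI, SII, RII, PAR, PAF.
    For the simple measures pass the advantaged/disadvantaged labels.
    """
    countries = s.records["country"].unique()
    if len(countries) < 2:
        raise ValueError("cluster bootstrap needs at least 2 countries")
    if B < 2:
        warnings.warn("B < 2 gives a degenerate interval")

    if measure in ("difference", "ratio"):
        idx = 0 if measure == "difference" else 1

        def compute(rec):
            sub = StratifiedOutcome(records=rec, order=s.order,
                                    ordered=s.ordered, dimension=s.dimension)
            return simple_measures(sub, advantaged, disadvantaged)[idx]
        point = compute(s.records)
    elif measure in _MEASURES:
        def compute(rec):
            return _MEASURES[measure](s, rec)
        point = compute(s.records)
    else:
        raise ValueError(f"unknown measure {measure!r}")

    rng = np.random.default_rng(seed)
    by_country = {c: g for c, g in s.records.groupby("country")}
    reps = []
    for _ in range(B):
        draw = rng.choice(countries, size=len(countries), replace=True)
        rec = pd.concat([by_country[c] for c in draw], ignore_index=True)
        try:
            reps.append(compute(rec))
        except (ZeroDivisionError, ValueError):
            continue
    reps = np.asarray(reps, dtype=float)
    alpha = 1 - level
    lo, hi = np.quantile(reps, [alpha / 2, 1 - alpha / 2])
    return EquityEstimate(dimension=s.dimension, measure=measure,
                          estimate=float(point), ci_low=float(lo),
                          ci_high=float(hi), kind=_KIND[measure])


def equity_table(outcomes: dict[str, StratifiedOutcome], B: int = 1000,
                 seed: int = 0, level: float = 0.95,
                 simple_pairs: dict[str, tuple] | None = None) -> pd.DataFrame:
    """Full inequality table across dimensions.

    Ordered dimensions get ACI/RCI, SII/RII, PAR/PAF; unordered (binary)
    dimensions get difference/ratio using the pair in ``simple_pairs``
    (advantaged, disadvantaged) or the two labels in reverse order.
    """
    rows = []
    for dim, s in outcomes.items():
        if s.ordered:
            measures = ["ACI", "RCI", "SII", "RII", "PAR", "PAF"]
            kwargs = {}
        else:
            measures = ["difference", "ratio"]
            if simple_pairs and dim in simple_pairs:
                adv, dis = simple_pairs[dim]
            else:
                adv, dis = s.order[-1], s.order[0]
            kwargs = {"advantaged": adv, "disadvantaged": dis}
        for m in measures:
            est = cluster_bootstrap_ci(s, m, B=B, seed=seed, level=level, **kwargs)
            rows.append({"dimension": dim, "measure": m, "estimate": est.estimate,
                         "CI_low": est.ci_low, "CI_high": est.ci_high,
                         "kind": est.kind})
    return pd.DataFrame(rows)
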