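"""Class enumeration: entropy, information criteria, sequential (K, M)
selection, and subgroup sensitivity refits.

Entropy is the normalized classification certainty E = 1 - EN/(n log K),
where EN is the summed Shannon entropy of the posterior rows; E = 1 means
one-hot posteriors (perfect separation), E = 0 means uniform posteriors.
For the higher level the sum runs over groups with denominator J log M by
default (``per_individual=True`` replicates the per-individual form, summing
each group's posterior entropy over its records).  Natural logarithms are
used throughout; the normalization cancels the base.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd

from .measurement import IndicatorMatrix, FitResult, PosteriorSet, fit_measurement


def _entropy(p: np.ndarray) -> float:
    """Sum of -p log p over all entries, with 0 log 0 := 0."""
    q = np.clip(p, 1e-300, None)
    return float(-(np.where(p > 0, p * np.log(q), 0.0)).sum())


def entropy_scores(posteriors: PosteriorSet,
                   group_index: np.ndarray | None = None,
                   per_individual: bool = False) -> tuple[float, float]:
    """(E_low, E_high) normalized entropies; K=1 or M=1 returns 1 by
    convention (classification is trivially certain)."""
    K, M = posteriors.K, posteriors.M
    n = posteriors.indiv_post.shape[0]
    J = posteriors.group_post.shape[0]
    if K == 1:
        e_low = 1.0
    else:
        e_low = 1.0 - _entropy(posteriors.indiv_post) / (n * np.log(K))
    if M == 1:
        e_high = 1.0
    elif per_individual:
        if group_index is None:
            raise ValueError("per-individual high-level entropy needs group_index")
        per_rec = posteriors.group_post[np.asarray(group_index)]
        e_high = 1.0 - _entropy(per_rec) / (n * np.log(M))
    else:
        e_high = 1.0 - _entropy(posteriors.group_post) / (J * np.log(M))
    return float(e_low), float(e_high)


@dataclass
class SelectionRecord:
    K: int
    M: int
    loglik: float
    n_params: int
    AIC: float
    BIC_low: float
    BIC_high: float
    ICL_BIC_high: float
    E_low: float
    E_high: float


@dataclass
class SelectionTable:
    records: list[SelectionRecord]
    chosen: tuple[int, int]
    criterion: str

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([asdict(r) for r in self.records])


def information_criteria(fit: FitResult, n_low: int, n_high: int) -> SelectionRecord:
    """AIC/BIC at both levels plus the entropy-penalized ICL-BIC.

    p = (M-1) + M(K-1) + K*H free measurement parameters;
    AIC = -2l + 2p; BIC_low = -2l + p log n_low; BIC_high = -2l + p log n_high;
    ICL_BIC_high = BIC_high + 2*EN_high with EN_high the summed entropy of the
    group posteriors (zero for one-hot classification, in which case the two
    criteria coincide).
    """
    p = fit.params.n_params
    ll = fit.loglik
    aic = -2 * ll + 2 * p
    bic_low = -2 * ll + p * np.log(n_low)
    bic_high = -2 * ll + p * np.log(n_high)
    en_high = _entropy(fit.posteriors.group_post)
    e_low, e_high = entropy_scores(fit.posteriors)
    return SelectionRecord(
        K=fit.params.K, M=fit.params.M, loglik=ll, n_params=p,
        AIC=aic, BIC_low=bic_low, BIC_high=bic_high,
        ICL_BIC_high=bic_high + 2 * en_high, E_low=e_low, E_high=e_high,
    )


_CRITERIA = {"aic": "AIC", "bic": "BIC_low", "bic_low": "BIC_low",
             "bic_high": "BIC_high", "icl_bic_high": "ICL_BIC_high"}


def _fit_record(data, K, M, seed, **fit_kw) -> tuple[FitResult, SelectionRecord]:
    fit = fit_measurement(data, K=K, M=M, seed=seed, **fit_kw)
    return fit, information_criteria(fit, n_low=data.n_records, n_high=data.n_groups)


def select_structure(data: IndicatorMatrix, K_range, M_range,
                     criterion: str = "bic", seed: int = 0,
                     n_starts: int = 8, **fit_kw) -> SelectionTable:
    """Sequential class-number selection.

    Step 1 sweeps K with M = 1 and picks K* by the low-level criterion
    (BIC_low by default); step 2 sweeps M at K* picking M* by the high-level
    analog (BIC_high when the default criterion is BIC); step 3 re-sweeps K
    at M* and keeps the winner.  The full sweep table is returned.
    """
    K_range, M_range = list(K_range), list(M_range)
    if not K_range or not M_range:
        raise ValueError("K_range and M_range must be non-empty")
    low_col = _CRITERIA[criterion.lower()]
    high_col = "BIC_high" if low_col == "BIC_low" else low_col
    records: list[SelectionRecord] = []
    cache: dict[tuple[int, int], SelectionRecord] = {}

    def record(K, M):
        if (K, M) not in cache:
            _, rec = _fit_record(data, K, M, seed=seed + 1000 * K + M,
                                 n_starts=n_starts, **fit_kw)
            cache[(K, M)] = rec
            records.append(rec)
        return cache[(K, M)]

    step1 = [record(K, min(M_range)) for K in K_range]
    K_star = step1[int(np.argmin([getattr(r, low_col) for r in step1]))].K
    step2 = [record(K_star, M) for M in M_range]
    M_star = step2[int(np.argmin([getattr(r, high_col) for r in step2]))].M
    step3 = [record(K, M_star) for K in K_range]
    K_star = step3[int(np.argmin([getattr(r, low_col) for r in step3]))].K
    return SelectionTable(records=records, chosen=(K_star, M_star), criterion=criterion)


def sensitivity_subsets(data: IndicatorMatrix, groups: dict[str, list[int]],
                        K: int = 2, M: int = 2, seed: int = 0,
                        n_starts: int = 8, **fit_kw) -> pd.DataFrame:
    """Refit the (K, M) model on disjoint indicator subsets.

    ``groups`` maps a subset name to indicator column indices; subsets must be
    disjoint.  Returns a table with fit indices (AIC, BIC_low, BIC_high) for
    the full model and each subset model, plus the adjusted Rand index
    between each subset model's individual MAP assignment and the full
    model's, on all records.
    """
    from sklearn.metrics import adjusted_rand_score
    import warnings

    cols: list[int] = []
    for name, idx in groups.items():
        if set(idx) & set(cols):
            raise ValueError("indicator subsets must be disjoint")
        cols.extend(idx)
        if len(idx) < 2:
            warnings.warn(f"subset {name!r} has fewer than 2 indicators")

    full_fit, full_rec = _fit_record(data, K, M, seed=seed, n_starts=n_starts, **fit_kw)
    rows = [{"model": "full", "n_indicators": data.H, "K": K, "M": M,
             "AIC": full_rec.AIC, "BIC_low": full_rec.BIC_low,
             "BIC_high": full_rec.BIC_high, "ARI_vs_full": 1.0}]
    for name, idx in groups.items():
        sub = IndicatorMatrix(values=data.values[:, idx], group_ids=data.group_ids,
                              weights=data.weights,
                              indicator_names=([data.indicator_names[i] for i in idx]
                                               if data.indicator_names else None))
        fit, rec = _fit_record(sub, K, M, seed=seed, n_starts=n_starts, **fit_kw)
        ari = adjusted_rand_score(full_fit.posteriors.map_indiv, fit.posteriors.map_indiv)
        rows.append({"model": name, "n_indicators": len(idx), "K": K, "M": M,
                     "AIC": rec.AIC, "BIC_low": rec.BIC_low,
                     "BIC_high": rec.BIC_high, "ARI_vs_full": ari})
    return pd.DataFrame(rows)


# canonical split of the 12 indicators used for the robustness comparison
MATERNAL_CARE = [0, 1, 2, 3, 4, 5, 6]   # ANC, tetanus, facility, skilled, PNC x2, FP
CHILD_CARE = [7, 8, 9, 10, 11]          # BCG, DPT, polio, measles, breastfeeding
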