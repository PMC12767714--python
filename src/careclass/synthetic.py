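"""Synthetic two-level latent class populations.

Emulates the hierarchical structure of a multi-country maternal/child health
survey: countries carry a latent coverage class W_j, women within each
country carry a latent utilization class C_i, and the twelve binary service
indicators are conditionally independent Bernoulli draws given C_i.  The
default configuration encodes the published two-class indicator profile
(optimal vs suboptimal utilizers) and class-proportion tables, so that
fitting the measurement model to generated data is a genuine parameter
recovery experiment with known truth.

One integer seed governs all draws: a ``numpy.random.SeedSequence`` is
spawned into independent child streams for, in order, group sizes, country
classes, individual classes, indicators, covariates, and weights.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .measurement import IndicatorMatrix

INDICATOR_NAMES = [
    "anc4",            # >=4 antenatal visits (>=8 for surveys after 2017)
    "tetanus2",        # >=2 tetanus toxoid doses
    "facility_delivery",
    "skilled_attendant",
    "pnc_mother",      # maternal check within 2 days of delivery
    "pnc_newborn",     # newborn check within 2 days
    "modern_fp",       # modern family planning method
    "bcg",
    "dpt3",
    "polio3",
    "measles",
    "breastfeeding",   # age-appropriate breastfeeding
]

# Published class-conditional probabilities (optimal, suboptimal) for 11 of
# the 12 indicators.  The tetanus pair is NOT published; (0.55, 0.30) is a
# documented free default chosen to sit between the ANC and facility-care
# contrasts, and must not be treated as ground truth.
PUBLISHED_RHO_PAIRS = {
    "anc4": (0.25, 0.12),
    "tetanus2": (0.55, 0.30),
    "facility_delivery": (0.97, 0.20),
    "skilled_attendant": (0.98, 0.25),
    "pnc_mother": (0.73, 0.10),
    "pnc_newborn": (0.76, 0.09),
    "modern_fp": (0.41, 0.15),
    "bcg": (0.97, 0.60),
    "dpt3": (0.87, 0.39),
    "polio3": (0.77, 0.38),
    "measles": (0.86, 0.44),
    "breastfeeding": (0.66, 0.63),
}

PUBLISHED_PI = (0.656, 0.344)                       # high-, low-coverage countries
PUBLISHED_TAU = ((0.827, 0.173), (0.465, 0.535))    # optimal/suboptimal within each


@dataclass
class CovariateSet:
    """Individual-level (Z2, one row per record) and country-level (Z1, one
    row per group) covariate frames."""

    individual: pd.DataFrame
    country: pd.DataFrame


@dataclass
class TruthRecord:
    """Ground-truth latent classes exported alongside simulated data."""

    W: np.ndarray                # length J, country classes in 0..M-1
    C: np.ndarray                # length N, individual classes in 0..K-1
    config_echo: "GeneratorConfig"


@dataclass
class GeneratorConfig:
    """Parameters of the two-level generative model.

    ``group_size_spec`` is either an int (all groups equal), a sequence of J
    ints, or the string ``"lognormal"`` which draws unequal sizes with the
    requested mean (sigma 0.5 on the log scale, minimum size 1).
    ``alpha`` (M-1 x P1) and ``gamma`` (M x (K-1) x P2) are logistic
    coefficients, reference class last, applied to the country / individual
    covariates when nonzero; with all-zero coefficients membership reduces to
    pi and tau exactly.
    """

    J: int
    group_size_spec: int | list[int] | str = 500
    mean_group_size: int = 500
    M: int = 2
    K: int = 2
    pi: np.ndarray = field(default_factory=lambda: np.array(PUBLISHED_PI))
    tau: np.ndarray = field(default_factory=lambda: np.array(PUBLISHED_TAU))
    rho: np.ndarray = field(default_factory=lambda: np.array(
        [PUBLISHED_RHO_PAIRS[n] for n in INDICATOR_NAMES]).T)
    alpha: np.ndarray | None = None
    gamma: np.ndarray | None = None
    covariate_spec: dict | None = None
    weight_spec: str = "ones"        # "ones" or "gamma" (DHS-style, mean 1)
    seed: int = 0
    indicator_names: list[str] = field(default_factory=lambda: list(INDICATOR_NAMES))

    def __post_init__(self) -> None:
        self.pi = np.asarray(self.pi, dtype=float)
        self.tau = np.asarray(self.tau, dtype=float)
        self.rho = np.asarray(self.rho, dtype=float)
        if self.J < 1:
            raise ValueError("J must be >= 1")
        if abs(self.pi.sum() - 1.0) > 1e-12:
            raise ValueError("pi must sum to 1")
        if not np.allclose(self.tau.sum(axis=1), 1.0, atol=1e-12):
            raise ValueError("every tau row must sum to 1")
        if ((self.rho < 0) | (self.rho > 1)).any():
            raise ValueError("rho entries must lie in [0, 1]")
        if self.tau.shape != (self.M, self.K) or self.rho.shape[0] != self.K:
            raise ValueError("pi/tau/rho dimensions inconsistent with M, K")
        if len(self.indicator_names) != self.rho.shape[1]:
            self.indicator_names = [f"y{h + 1}" for h in range(self.rho.shape[1])]
        if isinstance(self.group_size_spec, (list, tuple, np.ndarray)):
            sizes = np.asarray(self.group_size_spec)
            if len(sizes) != self.J or (sizes < 1).any():
                raise ValueError("per-group sizes must list J values >= 1")

    @property
    def H(self) -> int:
        return self.rho.shape[1]


def published_profile_config(J: int = 29, n_per_group: int = 500, seed: int = 0,
                         unequal_sizes: bool = False) -> GeneratorConfig:
    """Configuration encoding the published class profile.

    pi = (0.656, 0.344) high/low-coverage countries; tau rows (0.827, 0.173)
    and (0.465, 0.535); rho columns set to the published optimal/suboptimal
    probability pairs (tetanus uses a documented non-published default).
    Covariate effects default to zero.
    """
    if J < 2:
        raise ValueError("need at least 2 country groups")
    if n_per_group < 1:
        raise ValueError("group size must be >= 1")
    return GeneratorConfig(
        J=J,
        group_size_spec="lognormal" if unequal_sizes else n_per_group,
        mean_group_size=n_per_group,
        seed=seed,
    )


def _softmax_rows(eta: np.ndarray) -> np.ndarray:
    z = eta - eta.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def _draw_sizes(config: GeneratorConfig, rng: np.random.Generator) -> np.ndarray:
    spec = config.group_size_spec
    if isinstance(spec, str):
        if spec != "lognormal":
            raise ValueError(f"unknown group_size_spec {spec!r}")
        raw = rng.lognormal(mean=0.0, sigma=0.5, size=config.J)
        sizes = np.maximum(1, np.round(raw / raw.mean() * config.mean_group_size))
        return sizes.astype(int)
    if isinstance(spec, (list, tuple, np.ndarray)):
        return np.asarray(spec, dtype=int)
    return np.full(config.J, int(spec))


def _draw_covariates(config: GeneratorConfig, sizes: np.ndarray,
                     rng: np.random.Generator) -> CovariateSet:
    n = int(sizes.sum())
    spec = config.covariate_spec or {}
    indiv = {}
    for name, cs in spec.get("individual", {}).items():
        kind = cs.get("dist", "bernoulli")
        if kind == "bernoulli":
            indiv[name] = rng.binomial(1, cs.get("p", 0.5), size=n)
        elif kind == "normal":
            indiv[name] = rng.normal(cs.get("mean", 0.0), cs.get("sd", 1.0), size=n)
        elif kind == "categorical":
            probs = np.asarray(cs["probs"], dtype=float)
            indiv[name] = rng.choice(len(probs), size=n, p=probs / probs.sum())
        else:
            raise ValueError(f"unknown covariate distribution {kind!r}")
    country = {}
    for name, cs in spec.get("country", {}).items():
        country[name] = rng.normal(cs.get("mean", 0.0), cs.get("sd", 1.0), size=config.J)
    return CovariateSet(individual=pd.DataFrame(indiv, index=range(n)),
                        country=pd.DataFrame(country, index=range(config.J)))


def simulate(config: GeneratorConfig):
    """Draw one population from the generative model.

    Returns ``(IndicatorMatrix, CovariateSet, TruthRecord)``.  With nonzero
    ``alpha`` (and country covariates) country classes follow the multinomial
    logistic model with reference class M-1; likewise ``gamma`` for
    individual classes within each country class.  Identical seeds give
    bit-identical output.
    """
    ss = np.random.SeedSequence(config.seed)
    r_sizes, r_w, r_c, r_y, r_cov, r_wt = (np.random.default_rng(s) for s in ss.spawn(6))
    sizes = _draw_sizes(config, r_sizes)
    n = int(sizes.sum())
    covs = _draw_covariates(config, sizes, r_cov)

    # country classes
    if config.alpha is not None and np.any(config.alpha) and len(covs.country.columns):
        Z1 = np.column_stack([np.ones(config.J), covs.country.to_numpy()])
        eta = np.column_stack([Z1 @ np.atleast_2d(config.alpha).T,
                               np.zeros(config.J)])
        W = np.array([r_w.choice(config.M, p=p) for p in _softmax_rows(eta)])
    else:
        W = r_w.choice(config.M, size=config.J, p=config.pi)

    group_ids = np.repeat(np.arange(config.J), sizes)
    Wi = W[group_ids]

    # individual classes
    if config.gamma is not None and np.any(config.gamma) and len(covs.individual.columns):
        Z2 = np.column_stack([np.ones(n), covs.individual.to_numpy()])
        C = np.empty(n, dtype=int)
        for m in range(config.M):
            mask = Wi == m
            if not mask.any():
                continue
            eta = np.column_stack([Z2[mask] @ np.atleast_2d(config.gamma[m]).T,
                                   np.zeros(mask.sum())])
            p = _softmax_rows(eta)
            u = r_c.random(mask.sum())
            C[mask] = (u[:, None] > p.cumsum(axis=1)).sum(axis=1)
        C = np.clip(C, 0, config.K - 1)
    else:
        u = r_c.random(n)
        cum = config.tau.cumsum(axis=1)[Wi]
        C = (u[:, None] > cum).sum(axis=1)
        C = np.clip(C, 0, config.K - 1)

    y = (r_y.random((n, config.H)) < config.rho[C]).astype(float)

    if config.weight_spec == "gamma":
        weights = r_wt.gamma(shape=4.0, scale=0.25, size=n)  # mean 1, DHS-like spread
    elif config.weight_spec == "ones":
        weights = np.ones(n)
    else:
        raise ValueError(f"unknown weight_spec {config.weight_spec!r}")

    data = IndicatorMatrix(values=y, group_ids=group_ids, weights=weights,
                           indicator_names=list(config.indicator_names))
    truth = TruthRecord(W=W, C=C, config_echo=config)
    return data, covs, truth


def inject_missing(data: IndicatorMatrix, rate: float,
                   mechanism: str = "MCAR", seed: int = 0,
                   covariate: np.ndarray | None = None) -> IndicatorMatrix:
    """Mask indicator cells at the requested rate.

    MCAR masks cells as iid coin flips.  MAR makes the per-record masking
    probability depend on ``covariate`` x through a logistic rule centered on
    the overall rate: p_i = expit(logit(rate) + x_i_standardized), applied
    uniformly across that record's cells.
    """
    if not 0 <= rate < 1:
        raise ValueError("rate must lie in [0, 1)")
    if rate == 0:
        return IndicatorMatrix(values=data.values.copy(), group_ids=data.group_ids,
                               weights=data.weights.copy(),
                               indicator_names=data.indicator_names)
    rng = np.random.default_rng(seed)
    n, H = data.values.shape
    if mechanism.upper() == "MCAR":
        mask = rng.random((n, H)) < rate
    elif mechanism.upper() == "MAR":
        if covariate is None:
            raise ValueError("MAR mechanism needs a covariate")
        x = np.asarray(covariate, dtype=float)
        x = (x - x.mean()) / (x.std() + 1e-12)
        from scipy.special import expit, logit
        p = expit(logit(rate) + x)
        mask = rng.random((n, H)) < p[:, None]
    else:
        raise ValueError(f"unknown mechanism {mechanism!r}")
    values = data.values.copy()
    values[mask] = np.nan
    return IndicatorMatrix(values=values, group_ids=data.group_ids,
                           weights=data.weights.copy(),
                           indicator_names=data.indicator_names)


def marginal_indicator_means(config: GeneratorConfig) -> np.ndarray:
    """Closed-form marginal mean of each indicator:
    sum_m pi_m sum_k tau_{k|m} rho_{kh}."""
    return (config.pi @ config.tau) @ config.rho


def to_unit_records(data: IndicatorMatrix, covs: CovariateSet | None = None) -> pd.DataFrame:
    """Unit-record frame in the interchange schema:
    country_id, weight, y1..yH, then covariate columns."""
    df = pd.DataFrame({"country_id": np.asarray(data.group_labels)[data.group_index],
                       "weight": data.weights})
    for h in range(data.H):
        df[f"y{h + 1}"] = data.values[:, h]
    if covs is not None and len(covs.individual.columns):
        for c in covs.individual.columns:
            df[c] = covs.individual[c].to_numpy()
    return df


def truth_frames(truth: TruthRecord):
    """Sidecar ground-truth tables: (group id, W) and (record id, C)."""
    g = pd.DataFrame({"group_id": np.arange(len(truth.W)), "W": truth.W})
    r = pd.DataFrame({"record_id": np.arange(len(truth.C)), "C": truth.C})
    return g, r
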