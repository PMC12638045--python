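"""Probability model for partially pooled analysis of multiregion cell counts.

The observed data are labelled cell counts ``y_i``, one per (region, group,
animal[, hemisphere]) combination, together with the area of the tissue
section each count was recorded from.  The model is a hierarchical count
regression on the log scale:

    y_i        ~ Poisson(lambda_i)            (or ZIPoisson(pi, lambda_i))
    log lambda_i = theta_{r[i],g[i]} + gamma_i + E_i
    gamma_i    ~ Normal(0, tau_{r[i],g[i]})          (normal prior)
               ~ Normal(0, tau_{r[i],g[i]} * kappa_i), kappa_i ~ HalfNormal(1)
                                                      (horseshoe prior)
    tau_{r,g}  ~ HalfNormal(log s)

``theta_{r,g}`` is the fixed effect (group-level mean log count for a region
under a condition), ``gamma_i`` the per-observation random effect capturing
animal/sample variability, and ``E_i = log(area_i)`` an exposure offset so
rates scale with the recorded area.  The hyperprior scale ``s`` (default
1.05) places 95% of the prior mass for ``tau`` below ``log 1.1`` — roughly
10% within-group variation at the upper end.

The zero-inflated likelihood mixes a point mass at zero (probability
``pi``) with the Poisson, modelling anomalous zeros such as registration
failures; the Bernoulli indicator is marginalised out so every sampled
parameter is continuous.

This module exposes every density as a plain function plus an exact
(unnormalised) joint log posterior usable by any generic sampler or
optimiser; out-of-support parameter points return ``-inf`` rather than
raising.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.special import betaln, gammaln
from scipy.stats import halfnorm

logger = logging.getLogger("bayescount")

LOG_ZERO = -np.inf

LIKELIHOODS = ("poisson", "zip")
RANDOM_EFFECT_PRIORS = ("normal", "horseshoe")

#: columns of the CSV count-table dialect (``hemisphere`` is optional; a
#: missing ``area`` column is tolerated with a warning and exposure 0).
REQUIRED_COLUMNS = ("count", "region", "group", "animal")

_HALF_LOG_2_OVER_PI = 0.5 * np.log(2.0 / np.pi)
_HALF_LOG_2PI = 0.5 * np.log(2.0 * np.pi)


class ValidationError(ValueError):
    """Raised when an input table, config, or parameter state is malformed."""


# ---------------------------------------------------------------------------
# data model
# ---------------------------------------------------------------------------

def _first_appearance_codes(labels: Sequence) -> tuple[np.ndarray, list]:
    """Dense integer codes in order of first appearance (kept stable so the
    theta/tau columns of any output are interpretable)."""
    seen: dict = {}
    codes = np.empty(len(labels), dtype=np.int64)
    for i, lab in enumerate(labels):
        codes[i] = seen.setdefault(lab, len(seen))
    return codes, list(seen)


@dataclass
class CellCountTable:
    """Observed cell counts with region/group/animal labels and exposures.

    Attributes
    ----------
    counts : (N,) int array, cells per observation, all >= 0.
    region_codes, group_codes, animal_codes : dense 0-based integer codes.
    region_labels, group_labels, animal_labels : code -> label, in first
        appearance order of the input.
    areas : (N,) positive recording areas (arbitrary units); the exposure is
        ``E_i = log(area_i)``.
    hemispheres : optional (N,) labels.
    """

    counts: np.ndarray
    region_codes: np.ndarray
    group_codes: np.ndarray
    animal_codes: np.ndarray
    region_labels: list
    group_labels: list
    animal_labels: list
    areas: np.ndarray
    hemispheres: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 1 or self.counts.size == 0:
            raise ValidationError("counts must be a non-empty 1-D array")
        if not np.all(np.isfinite(self.counts)):
            raise ValidationError("counts contain non-finite values")
        if np.any(self.counts != np.floor(self.counts)) or np.any(self.counts < 0):
            bad = np.flatnonzero(
                (self.counts != np.floor(self.counts)) | (self.counts < 0)
            )
            raise ValidationError(
                f"counts must be non-negative integers (rows {bad[:5].tolist()})"
            )
        self.counts = self.counts.astype(np.int64)
        n = self.counts.size
        self.areas = np.asarray(self.areas, dtype=float)
        if self.areas.shape != (n,):
            raise ValidationError("areas must align with counts")
        if np.any(~np.isfinite(self.areas)) or np.any(self.areas <= 0):
            bad = np.flatnonzero(~np.isfinite(self.areas) | (self.areas <= 0))
            raise ValidationError(
                f"areas must be strictly positive (rows {bad[:5].tolist()})"
            )
        for name in ("region_codes", "group_codes", "animal_codes"):
            arr = np.asarray(getattr(self, name), dtype=np.int64)
            setattr(self, name, arr)
            if arr.shape != (n,):
                raise ValidationError(f"{name} must align with counts")
        for codes, labels, what in (
            (self.region_codes, self.region_labels, "region"),
            (self.group_codes, self.group_labels, "group"),
            (self.animal_codes, self.animal_labels, "animal"),
        ):
            k = len(labels)
            if codes.min() < 0 or codes.max() >= k or len(np.unique(codes)) != k:
                raise ValidationError(f"{what} codes are not dense 0..{k - 1}")

    # -- shapes -------------------------------------------------------------
    @property
    def n_obs(self) -> int:
        return int(self.counts.size)

    @property
    def n_regions(self) -> int:
        return len(self.region_labels)

    @property
    def n_groups(self) -> int:
        return len(self.group_labels)

    @property
    def n_animals(self) -> int:
        return len(self.animal_labels)

    @property
    def exposures(self) -> np.ndarray:
        """E_i = log(area_i)."""
        return np.log(self.areas)

    @property
    def cell_codes(self) -> np.ndarray:
        """Flat (region, group) cell index r*G + g, 0..R*G-1."""
        return self.region_codes * self.n_groups + self.group_codes

    # -- construction / I/O -------------------------------------------------
    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "CellCountTable":
        missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
        if missing:
            raise ValidationError(f"count table is missing columns: {missing}")
        for col in ("region", "group"):
            if df[col].isna().any():
                rows = df.index[df[col].isna()].tolist()
                raise ValidationError(f"missing {col} label on rows {rows[:5]}")
        if "area" in df.columns:
            areas = df["area"].to_numpy(dtype=float)
        else:
            logger.warning(
                "count table has no 'area' column; exposure offsets set to 0"
            )
            areas = np.ones(len(df))
        r, rl = _first_appearance_codes(df["region"].tolist())
        g, gl = _first_appearance_codes(df["group"].tolist())
        a, al = _first_appearance_codes(df["animal"].tolist())
        hemi = None
        if "hemisphere" in df.columns:
            hemi = df["hemisphere"].to_numpy(dtype=object)
        return cls(
            counts=df["count"].to_numpy(),
            region_codes=r,
            group_codes=g,
            animal_codes=a,
            region_labels=rl,
            group_labels=gl,
            animal_labels=al,
            areas=areas,
            hemispheres=hemi,
        )

    @classmethod
    def from_csv(cls, path) -> "CellCountTable":
        try:
            df = pd.read_csv(path)
        except pd.errors.ParserError as exc:  # pragma: no cover - pandas msg
            raise ValidationError(f"ill-formed CSV {path}: {exc}") from exc
        return cls.from_frame(df)

    def to_frame(self) -> pd.DataFrame:
        data = {
            "count": self.counts,
            "region": [self.region_labels[c] for c in self.region_codes],
            "group": [self.group_labels[c] for c in self.group_codes],
            "animal": [self.animal_labels[c] for c in self.animal_codes],
            "area": self.areas,
        }
        if self.hemispheres is not None:
            data["hemisphere"] = self.hemispheres
        return pd.DataFrame(data)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


@dataclass
class ModelConfig:
    """Likelihood family, random-effect prior family and hyperprior settings.

    ``theta_prior_location=None`` means "resolve from the data": the log of
    the dataset-wide mean count, exposure-adjusted (see
    :func:`resolve_theta_location`).
    """

    likelihood: str = "poisson"
    random_effect_prior: str = "normal"
    s: float = 1.05
    theta_prior_location: Optional[float] = None
    theta_prior_scale: float = 5.0
    pi_prior: tuple = (1.0, 1.0)
    use_exposure: bool = True

    def __post_init__(self) -> None:
        if self.likelihood not in LIKELIHOODS:
            raise ValidationError(f"likelihood must be one of {LIKELIHOODS}")
        if self.random_effect_prior not in RANDOM_EFFECT_PRIORS:
            raise ValidationError(
                f"random_effect_prior must be one of {RANDOM_EFFECT_PRIORS}"
            )
        if not self.s > 1:
            raise ValidationError("s must be > 1 so that log(s) > 0")
        if not self.theta_prior_scale > 0:
            raise ValidationError("theta_prior_scale must be positive")
        a, b = self.pi_prior
        if not (a > 0 and b > 0):
            raise ValidationError("pi_prior shape parameters must be positive")
        self.pi_prior = (float(a), float(b))

    @property
    def tau_scale(self) -> float:
        """Scale of the half-normal hyperprior on tau: log(s)."""
        return float(np.log(self.s))

    def to_dict(self) -> dict:
        return {
            "likelihood": self.likelihood,
            "random_effect_prior": self.random_effect_prior,
            "s": self.s,
            "theta_prior_location": self.theta_prior_location,
            "theta_prior_scale": self.theta_prior_scale,
            "pi_prior": list(self.pi_prior),
            "use_exposure": self.use_exposure,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ModelConfig":
        d = dict(d)
        if "pi_prior" in d and d["pi_prior"] is not None:
            d["pi_prior"] = tuple(d["pi_prior"])
        return cls(**d)


@dataclass
class ParameterState:
    """One point in parameter space for density evaluation.

    ``kappa`` is present iff the horseshoe prior is used; ``pi`` iff the
    likelihood is zero-inflated.
    """

    theta: np.ndarray  # (R, G)
    gamma: np.ndarray  # (N,)
    tau: np.ndarray  # (R, G)
    kappa: Optional[np.ndarray] = None  # (N,)
    pi: Optional[float] = None

    def __post_init__(self) -> None:
        self.theta = np.asarray(self.theta, dtype=float)
        self.gamma = np.asarray(self.gamma, dtype=float)
        self.tau = np.asarray(self.tau, dtype=float)
        if self.kappa is not None:
            self.kappa = np.asarray(self.kappa, dtype=float)

    def validate(self, data: CellCountTable, config: ModelConfig) -> None:
        shape = (data.n_regions, data.n_groups)
        if self.theta.shape != shape:
            raise ValidationError(f"theta must have shape {shape}")
        if self.tau.shape != shape:
            raise ValidationError(f"tau must have shape {shape}")
        if self.gamma.shape != (data.n_obs,):
            raise ValidationError(f"gamma must have shape ({data.n_obs},)")
        if config.random_effect_prior == "horseshoe":
            if self.kappa is None:
                raise ValidationError("horseshoe prior requires kappa")
            if self.kappa.shape != (data.n_obs,):
                raise ValidationError(f"kappa must have shape ({data.n_obs},)")
        if config.likelihood == "zip" and self.pi is None:
            raise ValidationError("zip likelihood requires pi")


# ---------------------------------------------------------------------------
# densities
# ---------------------------------------------------------------------------

def _normal_logpdf(x, scale):
    return -_HALF_LOG_2PI - np.log(scale) - 0.5 * (x / scale) ** 2


def _halfnormal_logpdf(x, scale):
    # support x >= 0; callers handle negative arguments
    return _HALF_LOG_2_OVER_PI - np.log(scale) - 0.5 * (x / scale) ** 2


def log_rate(params: ParameterState, data: CellCountTable, i: int,
             config: Optional[ModelConfig] = None) -> float:
    """log lambda_i = theta_{r[i],g[i]} + gamma_i + E_i for one observation."""
    if not 0 <= i < data.n_obs:
        raise IndexError(f"observation index {i} out of range 0..{data.n_obs - 1}")
    if params.theta.shape != (data.n_regions, data.n_groups):
        raise ValidationError("theta dimensions do not match the data")
    if params.gamma.shape != (data.n_obs,):
        raise ValidationError("gamma dimensions do not match the data")
    use_exp = config.use_exposure if config is not None else True
    e = data.exposures[i] if use_exp else 0.0
    return float(
        params.theta[data.region_codes[i], data.group_codes[i]]
        + params.gamma[i]
        + e
    )


def log_rates(params: ParameterState, data: CellCountTable,
              config: Optional[ModelConfig] = None) -> np.ndarray:
    """Vectorised log lambda for every observation."""
    use_exp = config.use_exposure if config is not None else True
    e = data.exposures if use_exp else 0.0
    return params.theta[data.region_codes, data.group_codes] + params.gamma + e


def poisson_log_pmf(y, lam):
    """log Poisson pmf, computed stably via log-gamma; vectorises."""
    y_arr = np.asarray(y)
    lam_arr = np.asarray(lam, dtype=float)
    if np.any(y_arr != np.floor(y_arr)) or np.any(y_arr < 0):
        raise ValidationError("y must be a non-negative integer")
    if np.any(lam_arr <= 0):
        raise ValidationError("lam must be strictly positive")
    out = y_arr * np.log(lam_arr) - lam_arr - gammaln(y_arr + 1.0)
    return out if out.ndim else float(out)


def zip_log_pmf(y, pi, lam):
    """log zero-inflated-Poisson pmf.

    For y = 0 the two routes to zero are mixed on the log scale with
    log-sum-exp: log(pi + (1-pi) e^{-lam}); for y > 0 the inflation only
    rescales the Poisson term by (1 - pi).
    """
    y_arr = np.asarray(y)
    pi_arr = np.asarray(pi, dtype=float)
    lam_arr = np.asarray(lam, dtype=float)
    if np.any((pi_arr < 0) | (pi_arr > 1)):
        raise ValidationError("pi must lie in [0, 1]")
    if np.any(y_arr != np.floor(y_arr)) or np.any(y_arr < 0):
        raise ValidationError("y must be a non-negative integer")
    if np.any(lam_arr <= 0):
        raise ValidationError("lam must be strictly positive")
    with np.errstate(divide="ignore"):
        log_pi = np.log(pi_arr)
        log_1mpi = np.log1p(-pi_arr)
    zero_branch = np.logaddexp(log_pi, log_1mpi - lam_arr)
    pos_branch = log_1mpi + np.asarray(
        y_arr * np.log(lam_arr) - lam_arr - gammaln(y_arr + 1.0)
    )
    out = np.where(y_arr == 0, zero_branch, pos_branch)
    return out if out.ndim else float(out)


def log_prior_gamma(params: ParameterState, data: CellCountTable,
                    config: ModelConfig) -> float:
    """Log prior of the random effects (and, in horseshoe mode, their local
    scales).

    A zero population scale with a nonzero random effect has density zero
    (returns -inf).  The degenerate point tau*kappa = 0 with gamma = 0 is
    treated as a point mass and contributes 0 to the log density.
    """
    sigma = params.tau[data.region_codes, data.group_codes]
    total = 0.0
    if config.random_effect_prior == "horseshoe":
        if params.kappa is None:
            raise ValidationError("horseshoe prior requires kappa")
        if np.any(params.kappa <= 0):
            return LOG_ZERO
        sigma = sigma * params.kappa
        total += float(np.sum(_halfnormal_logpdf(params.kappa, 1.0)))
    if np.any(sigma < 0):
        return LOG_ZERO
    zero = sigma == 0
    if np.any(zero & (params.gamma != 0)):
        return LOG_ZERO
    ok = ~zero
    total += float(np.sum(_normal_logpdf(params.gamma[ok], sigma[ok])))
    return total


def log_prior_tau(tau: np.ndarray, s: float) -> float:
    """Sum of HalfNormal(log s) log densities over all tau_{r,g}."""
    if not s > 1:
        raise ValidationError("s must be > 1")
    tau = np.asarray(tau, dtype=float)
    if np.any(tau < 0):
        return LOG_ZERO
    return float(np.sum(_halfnormal_logpdf(tau, np.log(s))))


def halfnormal_mass(scale: float, upper: float) -> float:
    """Prior mass of a half-normal(scale) on [0, upper].

    With scale = log(1.05) and upper = log(1.1) this is ~0.95: the
    calibration behind the default hyperprior.
    """
    if not (scale > 0 and upper > 0):
        raise ValidationError("scale and upper must be positive")
    return float(halfnorm.cdf(upper, scale=scale))


def resolve_theta_location(data: CellCountTable, config: ModelConfig) -> float:
    """Default theta prior location: log of the dataset-wide mean count,
    exposure-adjusted (mean of count/area when exposures are in use)."""
    if config.theta_prior_location is not None:
        return float(config.theta_prior_location)
    if config.use_exposure:
        mean_rate = float(np.mean(data.counts / data.areas))
    else:
        mean_rate = float(np.mean(data.counts))
    return float(np.log(max(mean_rate, 1e-3)))


def log_prior_theta(theta: np.ndarray, config: ModelConfig,
                    data: Optional[CellCountTable] = None) -> float:
    """Weakly informative Normal prior on each fixed effect theta_{r,g}."""
    loc = config.theta_prior_location
    if loc is None:
        if data is None:
            raise ValidationError(
                "theta_prior_location is unresolved; pass the data table"
            )
        loc = resolve_theta_location(data, config)
    return float(
        np.sum(_normal_logpdf(np.asarray(theta, dtype=float) - loc,
                              config.theta_prior_scale))
    )


def log_prior_pi(pi: float, config: ModelConfig) -> float:
    """Beta(a, b) log prior for the zero-inflation probability."""
    a, b = config.pi_prior
    if not 0.0 <= pi <= 1.0:
        return LOG_ZERO
    with np.errstate(divide="ignore", invalid="ignore"):
        val = (a - 1.0) * np.log(pi) + (b - 1.0) * np.log1p(-pi) - betaln(a, b)
    if np.isnan(val):  # 0*log(0) corner at the boundary
        return LOG_ZERO
    return float(val)


def joint_log_posterior(params: ParameterState, data: CellCountTable,
                        config: ModelConfig) -> float:
    """Unnormalised joint log posterior of (theta, gamma, tau[, kappa][, pi]).

    Out-of-support points return -inf so generic samplers and optimisers can
    probe freely.
    """
    params.validate(data, config)
    if np.any(params.tau < 0):
        return LOG_ZERO
    if config.random_effect_prior == "horseshoe" and np.any(params.kappa <= 0):
        return LOG_ZERO
    if config.likelihood == "zip" and not 0.0 <= params.pi <= 1.0:
        return LOG_ZERO

    loglam = log_rates(params, data, config)
    with np.errstate(over="ignore"):
        lam = np.exp(loglam)
    y = data.counts
    if config.likelihood == "poisson":
        ll = y * loglam - lam - gammaln(y + 1.0)
    else:
        with np.errstate(divide="ignore"):
            log_pi = np.log(params.pi)
            log_1mpi = np.log1p(-params.pi)
        zero = y == 0
        ll = np.where(
            zero,
            np.logaddexp(log_pi, log_1mpi - lam),
            log_1mpi + (y * loglam - lam - gammaln(y + 1.0)),
        )
    total = float(np.sum(ll))
    total += log_prior_gamma(params, data, config)
    total += log_prior_tau(params.tau, config.s)
    total += log_prior_theta(params.theta, config, data)
    if config.likelihood == "zip":
        total += log_prior_pi(params.pi, config)
    if np.isnan(total):
        return LOG_ZERO
    return total
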