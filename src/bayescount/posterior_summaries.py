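"""Posterior summaries: fold changes, HDIs, the Welch comparator, and the
partial-pooling profile.

Group differences are reported as log2-fold changes of the fixed effects,
``(theta_{r,g1} - theta_{r,g2}) / ln 2`` per posterior draw — one unit is
one doubling of the estimated count.  Exposures and random effects cancel
by construction since theta is the group-level log mean.  Each region's
posterior is summarised by its mean and a 95% highest density interval
(the smallest-width interval holding the requested probability mass), and
set beside an uncorrected Welch's t-test on per-sample log2 counts — the
field-standard frequentist comparator.  No multiplicity correction is
applied anywhere, deliberately mirroring that comparator.

``pooling_profile`` computes the partial-pooling continuum: the
conditional posterior mean E[exp(gamma_i) | theta, tau, y_i] as a function
of the population scale tau, by deterministic quadrature, for all four
likelihood x prior combinations.  At tau = 0 every observation is fully
pooled (the expectation is 1); as tau grows the expectation approaches the
per-observation estimate y_i / exp(theta).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import integrate, stats
from scipy.special import gammaln

from .model_core import CellCountTable, ValidationError

logger = logging.getLogger("bayescount")

__all__ = [
    "RegionContrast",
    "hdi",
    "log2_fold_change",
    "welch_test",
    "contrast_table",
    "contrasts_to_frame",
    "pooling_profile",
    "plot_contrasts",
]

LN2 = np.log(2.0)


# ---------------------------------------------------------------------------
# highest density interval
# ---------------------------------------------------------------------------

def hdi(samples, prob: float = 0.95) -> tuple[float, float]:
    """Smallest-width contiguous interval containing ``prob`` of the samples.

    Among all windows of ``ceil(prob * n)`` consecutive sorted samples the
    minimal-width one is returned; ties break toward the lowest lower bound.
    """
    x = np.sort(np.asarray(samples, dtype=float).ravel())
    if x.size < 2:
        raise ValidationError("hdi requires at least 2 samples")
    if not 0.0 < prob < 1.0:
        raise ValidationError("prob must lie in (0, 1)")
    n = x.size
    k = int(np.ceil(prob * n))
    k = min(max(k, 1), n)
    widths = x[k - 1:] - x[: n - k + 1]
    j = int(np.argmin(widths))  # first minimum = lowest lower bound
    return float(x[j]), float(x[j + k - 1])


# ---------------------------------------------------------------------------
# fold changes and the Welch comparator
# ---------------------------------------------------------------------------

def log2_fold_change(draws, region: str, groups: tuple) -> np.ndarray:
    """Per-draw log2 fold change of the fixed effect between two groups."""
    g1, g2 = groups
    meta = draws.meta
    if meta:
        if region not in meta.get("region_labels", [region]):
            raise ValidationError(f"unknown region {region!r}")
        for g in (g1, g2):
            if g not in meta.get("group_labels", [g]):
                raise ValidationError(f"unknown group {g!r}")
    try:
        a = draws.column(f"theta[{region},{g1}]")
        b = draws.column(f"theta[{region},{g2}]")
    except KeyError as exc:
        raise ValidationError(str(exc)) from exc
    return (a - b) / LN2


@dataclass
class WelchResult:
    mean_diff: float
    ci_low: float
    ci_high: float
    p: float
    t: float
    df: float


def welch_test(x, y, conf: float = 0.95) -> WelchResult:
    """Welch's unequal-variance t-test with a two-sided p and CI at ``conf``.

    Uses the Welch-Satterthwaite degrees of freedom.  Groups of fewer than
    two values, or a degenerate (zero) standard error, are errors.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValidationError("welch_test requires at least 2 values per group")
    if not 0.0 < conf < 1.0:
        raise ValidationError("conf must lie in (0, 1)")
    if x.var(ddof=1) == 0.0 and y.var(ddof=1) == 0.0:
        raise ValidationError("degenerate variance: Welch CI undefined")
    res = stats.ttest_ind(x, y, equal_var=False)
    ci = res.confidence_interval(conf)
    return WelchResult(
        mean_diff=float(x.mean() - y.mean()),
        ci_low=float(ci.low),
        ci_high=float(ci.high),
        p=float(res.pvalue),
        t=float(res.statistic),
        df=float(res.df),
    )


@dataclass
class RegionContrast:
    """Per-region contrast: Bayesian log2-fold-change summary plus the
    Welch comparator."""

    region: str
    group_pair: tuple
    posterior_mean_log2fc: float
    hdi_low: float
    hdi_high: float
    hdi_prob: float
    welch_mean_diff: float
    welch_ci_low: float
    welch_ci_high: float
    welch_p: float

    def __post_init__(self) -> None:
        if self.hdi_low > self.hdi_high:
            raise ValidationError("hdi_low must not exceed hdi_high")
        if self.welch_ci_low > self.welch_ci_high:
            raise ValidationError("welch_ci_low must not exceed welch_ci_high")
        if not (
            self.hdi_low <= self.posterior_mean_log2fc <= self.hdi_high
        ):
            # legal only under pathological multimodality; flag, don't forbid
            logger.warning(
                "posterior mean for %s falls outside its HDI", self.region
            )


def _welch_transform(counts, areas, pseudo_count: float) -> np.ndarray:
    """Per-sample comparator transform: log2 of the area-normalised count
    with a pseudo-count so zeros stay defined.  Applied only to the Welch
    comparator, never to the Bayesian model."""
    return np.log2(counts / areas + pseudo_count)


def contrast_table(draws, data: CellCountTable, groups: tuple,
                   hdi_prob: float = 0.95, conf: float = 0.95,
                   pseudo_count: float = 0.5) -> list:
    """One RegionContrast per region, sorted by decreasing Welch p-value.

    The Bayesian columns summarise the posterior log2 fold change; the
    Welch columns come from an uncorrected t-test on log2(count/area +
    pseudo_count).  No multiple-testing correction is applied.
    """
    g1, g2 = groups
    for g in (g1, g2):
        if g not in data.group_labels:
            raise ValidationError(f"unknown group {g!r}")
    logger.info(
        "Welch comparator uses per-sample log2(count/area + %.3g); the "
        "pseudo-count is comparator-only",
        pseudo_count,
    )
    j1 = data.group_labels.index(g1)
    j2 = data.group_labels.index(g2)
    out = []
    for r, region in enumerate(data.region_labels):
        fc = log2_fold_change(draws, region, (g1, g2))
        lo, hi = hdi(fc, hdi_prob)
        m1 = (data.region_codes == r) & (data.group_codes == j1)
        m2 = (data.region_codes == r) & (data.group_codes == j2)
        w = welch_test(
            _welch_transform(data.counts[m1], data.areas[m1], pseudo_count),
            _welch_transform(data.counts[m2], data.areas[m2], pseudo_count),
            conf,
        )
        out.append(
            RegionContrast(
                region=region,
                group_pair=(g1, g2),
                posterior_mean_log2fc=float(np.mean(fc)),
                hdi_low=lo,
                hdi_high=hi,
                hdi_prob=hdi_prob,
                welch_mean_diff=w.mean_diff,
                welch_ci_low=w.ci_low,
                welch_ci_high=w.ci_high,
                welch_p=w.p,
            )
        )
    out.sort(key=lambda c: -c.welch_p)
    return out


def contrasts_to_frame(contrasts: Sequence[RegionContrast]) -> pd.DataFrame:
    rows = []
    for c in contrasts:
        rows.append(
            {
                "region": c.region,
                "group1": c.group_pair[0],
                "group2": c.group_pair[1],
                "posterior_mean_log2fc": c.posterior_mean_log2fc,
                f"hdi_{c.hdi_prob:g}_low": c.hdi_low,
                f"hdi_{c.hdi_prob:g}_high": c.hdi_high,
                "welch_mean_diff": c.welch_mean_diff,
                "welch_ci_low": c.welch_ci_low,
                "welch_ci_high": c.welch_ci_high,
                "welch_p": c.welch_p,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# pooling profile (partial-pooling continuum by quadrature)
# ---------------------------------------------------------------------------

def _loglik_scalar(y: float, theta_plus_gamma, likelihood: str, pi: float):
    with np.errstate(over="ignore"):
        lam = np.exp(theta_plus_gamma)
        base = y * theta_plus_gamma - lam - gammaln(y + 1.0)
    if likelihood == "poisson":
        return base
    if y == 0:
        with np.errstate(divide="ignore"):
            return np.logaddexp(np.log(pi), np.log1p(-pi) - lam)
    return np.log1p(-pi) + base


def _log_integral_tilted(y, theta, sigma, tilt, likelihood, pi):
    """log of the integral over gamma of
    exp(tilt * gamma) * likelihood(y | e^{theta+gamma}) * Normal(gamma; 0, sigma).
    """
    def h(g):
        g = np.asarray(g, dtype=float)
        return (
            tilt * g
            + _loglik_scalar(y, theta + g, likelihood, pi)
            - 0.5 * (g / sigma) ** 2
            - np.log(sigma)
            - 0.5 * np.log(2.0 * np.pi)
        )

    gamma_mle = np.log(max(y, 0.5)) - theta
    lo = min(0.0, gamma_mle) - 10.0 * sigma - 2.0
    hi = max(0.0, gamma_mle) + 10.0 * sigma + 2.0 + abs(tilt) * sigma**2

    # locate the mode by successive grid refinement (the integrand can be a
    # very narrow spike when either the prior scale or the likelihood width
    # is much smaller than the integration range)
    grid = np.linspace(lo, hi, 801)
    for _ in range(5):
        hv = h(grid)
        j = int(np.argmax(hv))
        step = grid[1] - grid[0]
        grid = np.linspace(
            max(lo, grid[j] - step), min(hi, grid[j] + step), 81
        )
    hv = h(grid)
    j = int(np.argmax(hv))
    g0 = float(grid[j])
    m = float(hv[j])
    # peak width: expand a symmetric step until the log density drops by ~1/2
    d = 1e-9 * (1.0 + abs(g0))
    drop = 0.0
    while drop < 0.5 and d < (hi - lo):
        d *= 2.0
        drop = m - 0.5 * float(h(g0 + d) + h(g0 - d))
    width = d / np.sqrt(max(2.0 * drop, 1.0)) if drop > 0 else sigma
    width = min(max(width, 1e-12), hi - lo)

    # integrate the peak and the two tails separately so adaptive quadrature
    # never has to discover a narrow spike inside a wide interval
    cuts = [lo, max(lo, g0 - 10.0 * width), min(hi, g0 + 10.0 * width), hi]
    cuts = sorted(set(cuts))
    val = 0.0
    err = 0.0
    for a, b in zip(cuts[:-1], cuts[1:]):
        if b <= a:
            continue
        v, e = integrate.quad(
            lambda g: np.exp(h(g) - m), a, b, limit=200, epsabs=1e-14,
            epsrel=1e-11,
        )
        val += v
        err += e
    if val <= 0 or not np.isfinite(val):
        raise ValidationError("quadrature failed to converge")
    if err > 1e-6 * val:
        logger.warning("pooling-profile quadrature error %.2e relative", err / val)
    return m + np.log(val)


def _conditional_mean_exp_gamma(y, theta, tau, likelihood, prior, pi):
    if tau < 1e-12:
        return 1.0  # complete pooling: the prior collapses to a point at 0
    if prior == "normal":
        num = _log_integral_tilted(y, theta, tau, 1.0, likelihood, pi)
        den = _log_integral_tilted(y, theta, tau, 0.0, likelihood, pi)
        return float(np.exp(num - den))

    # horseshoe: integrate the local scale kappa ~ HalfNormal(1) as well
    def log_inner(kappa, tilt):
        sigma = tau * kappa
        if sigma < 1e-8:
            return tilt * 0.0 + float(
                _loglik_scalar(y, np.asarray(theta), likelihood, pi)
            )
        return _log_integral_tilted(y, theta, sigma, tilt, likelihood, pi)

    def log_outer(tilt):
        ks = np.linspace(1e-4, 8.0, 60)
        hv = np.array(
            [log_inner(k, tilt) - 0.5 * k**2 for k in ks]
        )  # halfnorm(1) up to a constant
        j = int(np.argmax(hv))
        m = float(hv[j])
        k0 = float(ks[j])
        val, _ = integrate.quad(
            lambda k: np.exp(log_inner(k, tilt) - 0.5 * k**2 - m),
            1e-6,
            10.0,
            points=[k0],
            limit=100,
        )
        if val <= 0 or not np.isfinite(val):
            raise ValidationError("quadrature failed to converge")
        return m + np.log(val)

    return float(np.exp(log_outer(1.0) - log_outer(0.0)))


def pooling_profile(y, theta: float, tau_grid, likelihood: str = "poisson",
                    prior: str = "normal", pi: float = 0.1) -> np.ndarray:
    """E[exp(gamma_i) | theta, tau, y_i] on a grid of population scales.

    Returns an array of shape (len(tau_grid), len(y)).  ``pi`` is the
    zero-inflation probability used when ``likelihood='zip'``.  The
    expectation is computed by deterministic numerical integration of the
    unnormalised conditional density over gamma (and over the local scale
    kappa in horseshoe mode) — small demonstration scale only.
    """
    y = np.atleast_1d(np.asarray(y, dtype=float))
    tau_grid = np.atleast_1d(np.asarray(tau_grid, dtype=float))
    if np.any(tau_grid < 0):
        raise ValidationError("tau grid must be non-negative")
    if likelihood not in ("poisson", "zip"):
        raise ValidationError("likelihood must be 'poisson' or 'zip'")
    if prior not in ("normal", "horseshoe"):
        raise ValidationError("prior must be 'normal' or 'horseshoe'")
    out = np.empty((tau_grid.size, y.size))
    for t, tau in enumerate(tau_grid):
        for i, yi in enumerate(y):
            out[t, i] = _conditional_mean_exp_gamma(
                yi, theta, tau, likelihood, prior, pi
            )
    return out


# ---------------------------------------------------------------------------
# plotting
# ---------------------------------------------------------------------------

def plot_contrasts(contrasts: Sequence[RegionContrast], path=None, ax=None):
    """Interval-ladder plot: Bayesian HDIs (green) beside Welch CIs (orange),
    regions ordered as given (decreasing p-value from contrast_table)."""
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    if ax is None:
        fig, ax = plt.subplots(
            figsize=(max(6.0, 0.35 * len(contrasts)), 4.0)
        )
    else:
        fig = ax.figure
    xs = np.arange(len(contrasts))
    for x, c in zip(xs, contrasts):
        ax.plot([x - 0.15] * 2, [c.hdi_low, c.hdi_high], color="seagreen", lw=3)
        ax.plot(
            [x - 0.27, x - 0.03],
            [c.posterior_mean_log2fc] * 2,
            color="seagreen",
            lw=1.5,
        )
        ax.plot(
            [x + 0.15] * 2, [c.welch_ci_low, c.welch_ci_high],
            color="darkorange", lw=3,
        )
        ax.plot(
            [x + 0.03, x + 0.27], [c.welch_mean_diff] * 2,
            color="darkorange", lw=1.5,
        )
    ax.axhline(0.0, color="grey", lw=0.8, ls="--")
    ax.set_xticks(xs)
    ax.set_xticklabels([c.region for c in contrasts], rotation=90, fontsize=7)
    ax.set_ylabel("log2 fold change")
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return ax
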