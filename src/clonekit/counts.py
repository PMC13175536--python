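"""Neutral null models for ramets-per-genet counts.

Because a genet with zero sampled ramets is unobservable, the natural
neutral model for ramets per multilocus lineage is a zero-truncated Poisson
(ZTP): vegetative expansion as sampling with replacement, conditioned on at
least one observation.  The module fits ZTP models with a single rate or a
rate per patch by maximum likelihood (log link; the by-patch model is
separable, so each patch rate is a one-dimensional score-equation solve),
compares them with a likelihood-ratio test, evaluates Pearson goodness of
fit over the observed ramet-count categories, and attempts a zero-truncated
negative binomial (ZTNB) alternative whose numerical instabilities are
detected and reported as structured diagnostics rather than silent answers.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq, minimize
from scipy.special import gammaln
from scipy.stats import chi2

_LAM_FLOOR = 1e-8  # boundary representation for lambda -> 0+


def ztp_pmf(y, lam: float):
    """Zero-truncated Poisson pmf, computed in log space.

    ``P(Y = y) = lam^y e^{-lam} / (y! (1 - e^{-lam}))`` for y >= 1.
    """
    y_arr = np.asarray(y)
    if np.any(y_arr < 1):
        raise ValueError("zero-truncated support starts at y = 1")
    if lam <= 0:
        raise ValueError("rate must be positive")
    log_norm = np.log(-np.expm1(-lam))
    logp = y_arr * np.log(lam) - lam - gammaln(y_arr + 1) - log_norm
    out = np.exp(logp)
    return float(out) if np.isscalar(y) else out


def ztp_mean(lam: float) -> float:
    """Mean of the zero-truncated Poisson: lam / (1 - e^{-lam})."""
    return lam / -np.expm1(-lam)


def _ztp_loglik(counts: np.ndarray, lam: float) -> float:
    n = len(counts)
    return float(
        counts.sum() * np.log(lam)
        - n * lam
        - gammaln(counts + 1).sum()
        - n * np.log(-np.expm1(-lam))
    )


def _ztp_mle(counts: np.ndarray) -> tuple[float, bool]:
    """Solve the score equation mean(y) = lam/(1-e^{-lam}); returns (lam, boundary)."""
    ybar = counts.mean()
    if ybar <= 1.0 + 1e-12:
        return _LAM_FLOOR, True
    lo, hi = 1e-10, ybar  # ZTP mean > lam, so the root lies below ybar
    f = lambda lam: ztp_mean(lam) - ybar
    if f(hi) < 0:
        hi = ybar * 2
        while f(hi) < 0:
            hi *= 2
    lam = brentq(f, lo, hi, xtol=1e-12, rtol=1e-12)
    return float(lam), False


def _ztp_info_logscale(counts: np.ndarray, lam: float) -> float:
    """Observed information for theta = log(lam), by analytic second derivative.

    ll'(theta) = sum(y) - n*lam - n*lam*g(lam) with g = e^{-lam}/(1-e^{-lam});
    differentiating again in theta gives
    -n*lam - n*lam*d/dlam[lam*g(lam)]*... computed via d(lam*g)/dlam.
    """
    n = len(counts)
    g = 1.0 / np.expm1(lam)  # e^{-lam}/(1-e^{-lam})
    dg = -np.exp(lam) / np.expm1(lam) ** 2
    # ll'(theta) = S - n*lam - n*lam*g(lam); chain rule through lam = e^theta
    ll2 = lam * (-n - n * (g + lam * dg))
    return float(-ll2)


@dataclass
class CountModelFit:
    """A fitted zero-truncated count model."""

    model: str  # ztp_pooled | ztp_by_patch | ztnb_pooled | ztnb_by_patch
    coefficients: dict[str, float]  # log-scale rate per patch (or "pooled")
    std_errors: dict[str, float]
    log_likelihood: float
    df: int
    n_obs: int
    n_mll_per_patch: dict[str, int]
    rates: dict[str, float]  # natural-scale lambda per patch
    converged: bool = True
    flags: dict[str, list[str]] = field(default_factory=dict)
    extra: dict[str, float] = field(default_factory=dict)
    _data_token: tuple = field(default=(), repr=False)


def fit_ztp(
    counts, patches=None, by_patch: bool = False
) -> CountModelFit:
    """Maximum-likelihood zero-truncated Poisson fit to ramets-per-MLL counts.

    With ``by_patch=True`` one log-rate coefficient is fitted per patch
    (equivalent to a log-link regression on the patch factor; the likelihood
    separates, so each rate solves its own score equation).  Coefficients and
    standard errors (from observed information) are on the log scale.
    Boundary fits (all counts equal to 1, rate -> 0+) are flagged rather than
    raised.
    """
    counts = np.asarray(counts, dtype=int)
    if np.any(counts < 1):
        raise ValueError("ramet counts must be >= 1")
    if patches is None:
        patches = np.asarray(["all"] * len(counts), dtype=object)
    else:
        patches = np.asarray(patches, dtype=object)
    groups = (
        {p: counts[patches == p] for p in dict.fromkeys(patches)}
        if by_patch
        else {"pooled": counts}
    )
    coeffs, ses, rates, nm, flags = {}, {}, {}, {}, {}
    ll = 0.0
    converged = True
    for name, c in groups.items():
        lam, boundary = _ztp_mle(c)
        rates[name] = lam
        nm[name] = len(c)
        coeffs[name] = float(np.log(lam))
        if boundary:
            flags.setdefault(name, []).append("boundary_rate_zero")
            converged = False
            ses[name] = float("inf")
            ll += float(-gammaln(c + 1).sum())  # limit: all mass at y=1
        else:
            info = _ztp_info_logscale(c, lam)
            ses[name] = float(1.0 / np.sqrt(info)) if info > 0 else float("inf")
            ll += _ztp_loglik(c, lam)
    if by_patch:
        nm = {p: len(groups[p]) for p in groups}
    return CountModelFit(
        model="ztp_by_patch" if by_patch else "ztp_pooled",
        coefficients=coeffs,
        std_errors=ses,
        log_likelihood=float(ll),
        df=len(groups),
        n_obs=len(counts),
        n_mll_per_patch=nm,
        rates=rates,
        converged=converged,
        flags=flags,
        _data_token=(len(counts), int(counts.sum()), tuple(np.bincount(counts).tolist())),
    )


@dataclass
class LRTResult:
    statistic: float
    df: int
    p_value: float


def lrt(full: CountModelFit, reduced: CountModelFit) -> LRTResult:
    """Likelihood-ratio test of nested count models fitted to the same data."""
    if full._data_token != reduced._data_token:
        raise ValueError("models were fitted to different data")
    if full.df < reduced.df:
        raise ValueError("'full' model must have at least as many parameters as 'reduced'")
    stat = 2.0 * (full.log_likelihood - reduced.log_likelihood)
    stat = max(stat, 0.0)
    df = full.df - reduced.df
    p = float(chi2.sf(stat, df)) if df > 0 else 1.0
    return LRTResult(statistic=float(stat), df=df, p_value=p)


@dataclass
class GofResult:
    chi2: dict[str, float]
    df: dict[str, int]
    p_value: dict[str, float]
    overdispersed: dict[str, bool]
    ratio: dict[str, float]


def pearson_gof(
    fit: CountModelFit,
    counts,
    patches=None,
    overdispersion_ratio: float = 2.0,
    bin_tail: float | None = None,
) -> GofResult:
    """Pearson chi-squared goodness of fit per patch.

    By default the categories are the observed distinct ramets-per-MLL
    values of the patch (no tail binning); ``E_i = ztp_pmf(i) * n_mll``;
    df = #categories minus the number of parameters estimated for that patch
    (one rate).  An expected count of zero under an observed category is
    floored at 1e-12 with a warning, which drives the statistic very large —
    the signature of extreme outlying counts.

    ``bin_tail`` switches to the classical grouped statistic: categories are
    consecutive values 1, 2, ... with the upper tail merged into one ">=K"
    class so that every expected count is at least ``bin_tail`` (e.g. 5).
    """
    counts = np.asarray(counts, dtype=int)
    if patches is None:
        patches = np.asarray(["all"] * len(counts), dtype=object)
    else:
        patches = np.asarray(patches, dtype=object)
    out_chi, out_df, out_p, out_over, out_ratio = {}, {}, {}, {}, {}
    for patch in dict.fromkeys(patches):
        c = counts[patches == patch]
        key = patch if patch in fit.rates else "pooled"
        lam = fit.rates[key]
        if bin_tail is not None and lam > _LAM_FLOOR:
            stat, df = _binned_chi2(c, lam, bin_tail)
        else:
            cats, obs = np.unique(c, return_counts=True)
            if lam <= _LAM_FLOOR:
                expected = np.where(cats == 1, float(len(c)), 0.0)
            else:
                expected = ztp_pmf(cats, lam) * len(c)
            floored = expected <= 0
            if floored.any():
                warnings.warn(
                    f"patch {patch}: {int(floored.sum())} categories with zero "
                    "expected count floored at 1e-12"
                )
                expected = np.maximum(expected, 1e-12)
            stat = float(((obs - expected) ** 2 / expected).sum())
            df = max(len(cats) - 1, 0)
        out_chi[patch] = stat
        out_df[patch] = df
        out_p[patch] = float(chi2.sf(stat, df)) if df > 0 else float("nan")
        ratio = stat / df if df > 0 else float("inf")
        out_ratio[patch] = ratio
        out_over[patch] = bool(ratio > overdispersion_ratio)
    return GofResult(out_chi, out_df, out_p, out_over, out_ratio)


def _binned_chi2(c: np.ndarray, lam: float, min_expected: float) -> tuple[float, int]:
    """Grouped Pearson statistic: consecutive classes 1..K-1 plus a >=K tail,
    K chosen so every expected count reaches ``min_expected``."""
    n = len(c)
    ymax = int(c.max())
    ys = np.arange(1, ymax + 1)
    probs = ztp_pmf(ys, lam)
    tail = max(1.0 - probs.sum(), 0.0)
    # walk down from the top merging classes until the tail class is big enough
    k = ymax
    while k > 1 and (probs[k - 1 :].sum() + tail) * n < min_expected:
        k -= 1
    exp = np.append(probs[: k - 1] * n, (probs[k - 1 :].sum() + tail) * n)
    obs = np.append(
        [int((c == y).sum()) for y in range(1, k)], int((c >= k).sum())
    ).astype(float)
    keep = exp > 0
    stat = float(((obs[keep] - exp[keep]) ** 2 / exp[keep]).sum())
    df = max(int(keep.sum()) - 1, 0)
    return stat, df


def fitted_mll_counts(fit: CountModelFit, patch: str, max_y: int | None = None) -> dict:
    """Expected number of MLLs at each ramets-per-MLL value for one patch.

    Returns ``{y: expected count}`` for y = 1..max_y plus a ``"tail"`` entry
    holding the remaining mass, so the values sum to the patch's MLL count.
    """
    key = patch if patch in fit.rates else "pooled"
    lam = fit.rates[key]
    n_mll = fit.n_mll_per_patch.get(patch, fit.n_mll_per_patch.get(key, fit.n_obs))
    if lam <= _LAM_FLOOR:
        return {1: float(n_mll), "tail": 0.0}
    if max_y is None:
        max_y = int(max(10, np.ceil(lam + 10 * np.sqrt(lam))))
    ys = np.arange(1, max_y + 1)
    probs = ztp_pmf(ys, lam)
    out = {int(y): float(p * n_mll) for y, p in zip(ys, probs)}
    out["tail"] = float(max(n_mll - sum(out.values()), 0.0))
    return out


# ---------------------------------------------------------------------------
# zero-truncated negative binomial


def _ztnb_loglik(counts: np.ndarray, log_mu: float, log_size: float) -> float:
    mu = np.exp(log_mu)
    size = np.exp(log_size)
    p0 = (size / (size + mu)) ** size
    if p0 >= 1.0:
        return -np.inf
    y = counts
    ll = (
        gammaln(y + size)
        - gammaln(size)
        - gammaln(y + 1)
        + size * (np.log(size) - np.log(size + mu))
        + y * (np.log(mu) - np.log(size + mu))
    ).sum()
    return float(ll - len(y) * np.log1p(-p0))


def fit_ztnb(counts, patches=None, by_patch: bool = False) -> CountModelFit:
    """Maximum-likelihood zero-truncated negative binomial fit.

    Parameters are (log mean, log size) per group.  Instability — failure to
    converge, size diverging (the Poisson limit), or coefficients beyond
    |10| on the log scale — is detected and recorded in ``flags``; such fits
    are returned with ``converged=False``, never silently as valid.
    Count data clustered at 1 with isolated large values (the pattern that
    makes this model unidentifiable) typically trips these flags.
    """
    counts = np.asarray(counts, dtype=int)
    if np.any(counts < 1):
        raise ValueError("ramet counts must be >= 1")
    if patches is None:
        patches = np.asarray(["all"] * len(counts), dtype=object)
    else:
        patches = np.asarray(patches, dtype=object)
    groups = (
        {p: counts[patches == p] for p in dict.fromkeys(patches)}
        if by_patch
        else {"pooled": counts}
    )
    coeffs, ses, rates, nm, flags = {}, {}, {}, {}, {}
    ll_total = 0.0
    converged = True
    for name, c in groups.items():
        nm[name] = len(c)
        start = np.array([np.log(max(c.mean() - 1e-6, 1e-3)), 0.0])
        res = minimize(
            lambda th: -_ztnb_loglik(c, th[0], th[1]),
            start,
            method="L-BFGS-B",
            bounds=[(-20, 20), (-20, 20)],
        )
        log_mu, log_size = res.x
        group_flags: list[str] = []
        if not res.success:
            group_flags.append("optimizer_failed")
        if abs(log_mu) > 10:
            group_flags.append("mean_coefficient_extreme")
        if log_size > 10:
            group_flags.append("size_diverged_poisson_limit")
        if log_size < -10:
            group_flags.append("size_boundary_small")
        # flat ridge toward size -> infinity: no improvement over the Poisson
        # limit means the dispersion parameter is unidentified
        lam_ztp, boundary = _ztp_mle(c)
        ll_ztp = (
            float(-gammaln(c + 1).sum()) if boundary else _ztp_loglik(c, lam_ztp)
        )
        if "size_diverged_poisson_limit" not in group_flags and (
            _ztnb_loglik(c, log_mu, log_size) <= ll_ztp + 1e-6
        ):
            group_flags.append("size_diverged_poisson_limit")
        # crude curvature check for SEs
        se_mu = se_size = float("nan")
        try:
            h = 1e-5
            f0 = _ztnb_loglik(c, log_mu, log_size)
            d2mu = (
                _ztnb_loglik(c, log_mu + h, log_size)
                - 2 * f0
                + _ztnb_loglik(c, log_mu - h, log_size)
            ) / h**2
            if d2mu < 0:
                se_mu = float(1.0 / np.sqrt(-d2mu))
            else:
                group_flags.append("non_concave_at_optimum")
        except (FloatingPointError, ValueError):
            group_flags.append("curvature_evaluation_failed")
        if group_flags:
            converged = False
            flags[name] = group_flags
        coeffs[name] = float(log_mu)
        ses[name] = se_mu
        rates[name] = float(np.exp(log_mu))
        # keep size on record
        ll_total += _ztnb_loglik(c, log_mu, log_size)
        coeffs[f"{name}_log_size"] = float(log_size)
    return CountModelFit(
        model="ztnb_by_patch" if by_patch else "ztnb_pooled",
        coefficients=coeffs,
        std_errors=ses,
        log_likelihood=float(ll_total),
        df=2 * len(groups),
        n_obs=len(counts),
        n_mll_per_patch=nm,
        rates=rates,
        converged=converged,
        flags=flags,
        _data_token=(len(counts), int(counts.sum()), tuple(np.bincount(counts).tolist())),
    )


def exclude_above(counts, patches, cutoff: int):
    """Drop MLLs with more than ``cutoff`` ramets (sensitivity refit helper)."""
    counts = np.asarray(counts, dtype=int)
    patches = np.asarray(patches, dtype=object)
    keep = counts <= cutoff
    return counts[keep], patches[keep]
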