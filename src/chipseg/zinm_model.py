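"""Zero-inflated negative binomial and negative multinomial distributions.

ChIP-seq read counts per genomic window are overdispersed relative to the
Poisson distribution (windows differ in copy number, PCR propensity and
mappability) and carry an excess of zeros caused by unmappable windows.
The univariate model used here is therefore the zero-inflated negative
binomial (ZINB): a mixture of a point mass at zero, with weight ``pi``,
and a negative binomial distribution with shape ``alpha`` and success
probability ``p``.

The multivariate extension for ``r`` replicate profiles is the
zero-inflated negative multinomial (ZINM).  It arises from a shared
Gamma-Poisson construction -- each mappable window draws a single
Gamma(alpha) intensity that multiplies every replicate's rate -- and its
mass function for a count vector ``y = (y_1, ..., y_r)`` is

    P(y) = pi + (1 - pi) * p0**alpha                       if y == 0,
    P(y) = (1 - pi) * Gamma(alpha + sum(y)) / (Gamma(alpha) * prod(y_j!))
           * p0**alpha * prod(p_j**y_j)                    otherwise,

with probabilities p0 + p1 + ... + pr = 1.  The implied mean count of
replicate ``j`` on a mappable window is ``alpha * p_j / p0``.

Maximum likelihood fitting of the ZINB is done with an EM scheme over the
structural-zero indicator whose inner M-step solves the profile score
equation for ``alpha`` with a damped Newton iteration (bisection
fallback).  The negative multinomial probability update used inside the
HMM M-step reduces, after profiling out ``p_1..p_r``, to a
one-dimensional score equation for ``p0`` solved the same way.

All probability computations are carried out in log space via
``scipy.special.gammaln``; no factorial is ever formed directly.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.special import digamma, gammaln, polygamma

__all__ = [
    "ZINBParams",
    "ZINMParams",
    "PoissonParams",
    "FitResult",
    "zinb_log_pmf",
    "zinm_log_pmf",
    "fit_zinb",
    "fit_nb",
    "fit_poisson",
    "poisson_nb_reference_fits",
    "fit_nm_probs_given_pi_alpha",
    "zinm_params_from_means",
]

_ALPHA_MIN = 1e-8
_ALPHA_MAX = 1e12


@dataclass(frozen=True)
class ZINBParams:
    """Parameters of the zero-inflated negative binomial.

    ``pi`` is the zero-inflation (unmappable) probability, ``alpha`` the
    shape of the negative binomial component and ``p`` its success
    probability; ``p0 = 1 - p`` is the complementary mass parameter.
    ``alpha = inf`` denotes the Poisson limit of the family, in which
    case the mean must be supplied explicitly (``p`` degenerates to 0).
    """

    pi: float
    alpha: float
    p: float
    mean: float = field(default=float("nan"))

    def __post_init__(self) -> None:
        if not 0.0 <= self.pi <= 1.0:
            raise ValueError(f"pi must be in [0, 1], got {self.pi}")
        if not self.alpha > 0.0:
            raise ValueError(f"alpha must be > 0, got {self.alpha}")
        if math.isinf(self.alpha):
            if not math.isfinite(self.mean) or self.mean < 0:
                raise ValueError("Poisson limit (alpha=inf) requires a finite mean")
            if self.p != 0.0:
                raise ValueError("p must be 0 in the Poisson limit")
        else:
            if not 0.0 < self.p < 1.0:
                raise ValueError(f"p must be in (0, 1), got {self.p}")
            object.__setattr__(
                self, "mean", self.alpha * self.p / (1.0 - self.p)
            )

    @property
    def p0(self) -> float:
        return 1.0 - self.p

    @classmethod
    def from_mean(cls, pi: float, alpha: float, mean: float) -> "ZINBParams":
        """Build from the mean of the NB component instead of ``p``."""
        if math.isinf(alpha):
            return cls(pi=pi, alpha=alpha, p=0.0, mean=mean)
        return cls(pi=pi, alpha=alpha, p=mean / (alpha + mean))


@dataclass(frozen=True)
class ZINMParams:
    """Parameters of the zero-inflated negative multinomial.

    ``p`` holds the full probability vector ``(p0, p1, ..., pr)``; the
    entries are positive and sum to one.
    """

    pi: float
    alpha: float
    p: np.ndarray

    def __post_init__(self) -> None:
        p = np.asarray(self.p, dtype=float)
        object.__setattr__(self, "p", p)
        if not 0.0 <= self.pi <= 1.0:
            raise ValueError(f"pi must be in [0, 1], got {self.pi}")
        if not (self.alpha > 0.0 and math.isfinite(self.alpha)):
            raise ValueError(f"alpha must be positive and finite, got {self.alpha}")
        if p.ndim != 1 or p.size < 2:
            raise ValueError("p must be a vector (p0, p1, ..., pr) with r >= 1")
        if np.any(p <= 0.0):
            raise ValueError("all probabilities must be > 0")
        if abs(p.sum() - 1.0) > 1e-8:
            raise ValueError(f"probabilities must sum to 1, got {p.sum()}")

    @property
    def r(self) -> int:
        """Number of replicate dimensions."""
        return self.p.size - 1

    @property
    def p0(self) -> float:
        return float(self.p[0])

    def means(self) -> np.ndarray:
        """Mean count per replicate on a mappable window: alpha*p_j/p0."""
        return self.alpha * self.p[1:] / self.p[0]


@dataclass(frozen=True)
class PoissonParams:
    rate: float


@dataclass
class FitResult:
    """Outcome of a maximum-likelihood fit."""

    params: object
    loglik: float
    n_iter: int
    converged: bool


# ---------------------------------------------------------------------------
# Probability mass functions
# ---------------------------------------------------------------------------

def _nb_log_pmf(k: np.ndarray, alpha: float, mean: float) -> np.ndarray:
    """NB log-pmf in the (shape, mean) parameterization; alpha=inf -> Poisson."""
    k = np.asarray(k, dtype=float)
    if math.isinf(alpha):
        if mean == 0.0:
            return np.where(k == 0, 0.0, -np.inf)
        return k * math.log(mean) - mean - gammaln(k + 1.0)
    if alpha > 1e4:
        # gammaln(alpha+k) - gammaln(alpha) cancels catastrophically for
        # huge alpha; rewrite the pmf as a Poisson correction,
        #   log P(k) = k log(m) - gammaln(k+1) - alpha log1p(m/alpha)
        #              + sum_{i<k} log1p((i - m) / (alpha + m)),
        # whose terms all stay O(1).
        kmax = int(k.max()) if k.size else 0
        i = np.arange(max(kmax, 1), dtype=float)
        D = np.concatenate(([0.0], np.cumsum(np.log1p((i - mean) / (alpha + mean)))))
        with np.errstate(divide="ignore", invalid="ignore"):
            out = (
                np.where(k > 0, k * math.log(mean), 0.0)
                - gammaln(k + 1.0)
                - alpha * math.log1p(mean / alpha)
                + D[k.astype(int)]
            )
        return out
    # alpha * log(p0) computed as -alpha*log1p(mean/alpha) for accuracy at
    # very large alpha.
    log_p0_a = -alpha * math.log1p(mean / alpha)
    log_p = math.log(mean) - math.log(alpha + mean) if mean > 0 else -np.inf
    out = gammaln(alpha + k) - gammaln(alpha) - gammaln(k + 1.0) + log_p0_a
    with np.errstate(invalid="ignore"):
        out = out + np.where(k > 0, k * log_p, 0.0)
    return out


def _nb_log_zeroprob(alpha: float, mean: float) -> float:
    if math.isinf(alpha):
        return -mean
    return -alpha * math.log1p(mean / alpha)


def zinb_log_pmf(k, params: ZINBParams) -> np.ndarray:
    """Log-probability of counts ``k`` under the ZINB distribution.

    Vectorized over ``k``.  The value at 0 is
    ``log(pi + (1 - pi) * p0**alpha)``.
    """
    k = np.asarray(k)
    if np.any(k < 0):
        raise ValueError("counts must be non-negative")
    pi = params.pi
    log_zp = _nb_log_zeroprob(params.alpha, params.mean)
    if pi >= 1.0:
        return np.where(k == 0, 0.0, -np.inf)
    log1mpi = math.log1p(-pi)
    nb = log1mpi + _nb_log_pmf(k, params.alpha, params.mean)
    zero_val = np.logaddexp(math.log(pi), log1mpi + log_zp) if pi > 0 else log1mpi + log_zp
    return np.where(k == 0, zero_val, nb)


def zinm_log_pmf(y, params: ZINMParams) -> np.ndarray:
    """Log-probability of count vectors under the ZINM distribution.

    ``y`` may be a single length-``r`` vector or an ``(n, r)`` array; a
    value per row is returned in the latter case.  For ``r = 1`` this
    agrees with :func:`zinb_log_pmf` with ``p = p1``.
    """
    y = np.asarray(y)
    single = y.ndim == 1
    Y = np.atleast_2d(y).astype(float)
    if Y.shape[1] != params.r:
        raise ValueError(f"expected vectors of length r={params.r}, got {Y.shape[1]}")
    if np.any(Y < 0):
        raise ValueError("counts must be non-negative")
    pi, alpha = params.pi, params.alpha
    logp = np.log(params.p)
    tot = Y.sum(axis=1)
    body = (
        gammaln(alpha + tot)
        - gammaln(alpha)
        - gammaln(Y + 1.0).sum(axis=1)
        + alpha * logp[0]
        + Y @ logp[1:]
    )
    if pi >= 1.0:
        out = np.where(tot == 0, 0.0, -np.inf)
    else:
        log1mpi = math.log1p(-pi)
        if pi > 0:
            zero_val = np.logaddexp(math.log(pi), log1mpi + alpha * logp[0])
        else:
            zero_val = log1mpi + alpha * logp[0]
        out = np.where(tot == 0, zero_val, log1mpi + body)
    return float(out[0]) if single else out


def zinm_params_from_means(pi: float, alpha: float, means) -> ZINMParams:
    """ZINM parameters whose per-replicate mappable-window means are ``means``.

    Inverts ``mean_j = alpha * p_j / p0`` on the probability simplex.
    """
    means = np.asarray(means, dtype=float)
    if np.any(means <= 0):
        raise ValueError("means must be positive")
    c = means / alpha
    denom = 1.0 + c.sum()
    p = np.concatenate(([1.0], c)) / denom
    return ZINMParams(pi=pi, alpha=alpha, p=p)


# ---------------------------------------------------------------------------
# Root finding: damped Newton with bracketed bisection fallback
# ---------------------------------------------------------------------------

def _newton_bisect(score, dscore, lo, hi, x0, tol=1e-12, max_iter=200):
    """Find the root of a decreasing ``score`` on [lo, hi].

    Requires score(lo) >= 0 >= score(hi).  Takes Newton steps from ``x0``
    and falls back to bisection whenever a step leaves the bracket or
    fails to shrink it.
    """
    x = min(max(x0, lo), hi)
    for _ in range(max_iter):
        s = score(x)
        if s > 0:
            lo = x
        else:
            hi = x
        if hi - lo < tol * max(1.0, abs(x)) or abs(s) < 1e-14:
            return x
        d = dscore(x)
        step_ok = False
        if d < 0 and np.isfinite(d):
            xn = x - s / d
            if lo < xn < hi:
                x = xn
                step_ok = True
        if not step_ok:
            x = 0.5 * (lo + hi)
    return x


# ---------------------------------------------------------------------------
# Negative binomial machinery (weighted, on unique-count summaries)
# ---------------------------------------------------------------------------

def _weighted_nb_fit(vals: np.ndarray, wts: np.ndarray):
    """Weighted NB maximum likelihood -> (alpha, mean).

    ``vals`` are unique count values with non-negative weights ``wts``.
    The success probability is profiled out (p = m/(alpha+m) with m the
    weighted mean), leaving the one-dimensional score

        u(alpha) = sum_i w_i [psi(alpha + k_i) - psi(alpha)]
                   + W * log(alpha / (alpha + m)),

    solved by damped Newton.  When the score is positive for all alpha
    (underdispersed data) the MLE sits at the Poisson boundary and
    ``alpha = inf`` is returned.
    """
    W = wts.sum()
    m = float((wts * vals).sum() / W)
    if m <= 0:
        raise ValueError("degenerate data: weighted mean is zero")

    kmax = int(vals.max())
    kints = vals.astype(int)

    def score(a):
        if a > 1e4:
            # digamma differences cancel at large alpha; use the exact
            # harmonic sums psi(a+k) - psi(a) = sum_{i<k} 1/(a+i).
            H = np.concatenate(([0.0], np.cumsum(1.0 / (a + np.arange(kmax)))))
            return float((wts * H[kints]).sum() - W * math.log1p(m / a))
        return float(
            (wts * (digamma(a + vals) - digamma(a))).sum()
            - W * math.log1p(m / a)
        )

    def dscore(a):
        if a > 1e4:
            H2 = np.concatenate(
                ([0.0], np.cumsum(1.0 / (a + np.arange(kmax)) ** 2))
            )
            return float(
                -(wts * H2[kints]).sum() + W * (1.0 / a - 1.0 / (a + m))
            )
        return float(
            (wts * (polygamma(1, a + vals) - polygamma(1, a))).sum()
            + W * (1.0 / a - 1.0 / (a + m))
        )

    var = float((wts * (vals - m) ** 2).sum() / W)
    a0 = m * m / (var - m) if var > m * 1.0001 else 100.0

    hi = max(a0 * 2, 1.0)
    while score(hi) > 0:
        hi *= 4.0
        if hi > _ALPHA_MAX:
            return math.inf, m  # Poisson boundary
    lo = _ALPHA_MIN
    if score(lo) < 0:
        return lo, m
    alpha = _newton_bisect(score, dscore, lo, hi, a0)
    return alpha, m


def _zinb_loglik(vals, wts, pi, alpha, mean) -> float:
    """Weighted ZINB log-likelihood on a unique-count summary."""
    log_zp = _nb_log_zeroprob(alpha, mean)
    if pi >= 1.0:
        lz = 0.0
    elif pi > 0:
        lz = np.logaddexp(math.log(pi), math.log1p(-pi) + log_zp)
    else:
        lz = log_zp
    pos = vals > 0
    ll = float(wts[~pos].sum()) * lz
    if pos.any():
        if pi >= 1.0:
            return -math.inf
        ll += float(
            (wts[pos] * (math.log1p(-pi) + _nb_log_pmf(vals[pos], alpha, mean))).sum()
        )
    return ll


def fit_poisson(counts) -> FitResult:
    """Closed-form Poisson maximum likelihood (rate = sample mean)."""
    k = np.asarray(counts, dtype=float)
    rate = float(k.mean())
    ll = float((k * (math.log(rate) if rate > 0 else -math.inf) - rate - gammaln(k + 1)).sum()) \
        if rate > 0 else float(-gammaln(k + 1).sum()) if np.all(k == 0) else -math.inf
    return FitResult(params=PoissonParams(rate=rate), loglik=ll, n_iter=0, converged=True)


def fit_nb(counts) -> FitResult:
    """Negative binomial maximum likelihood (no zero inflation).

    Returns the Poisson boundary (``alpha = inf``) when the data are not
    overdispersed, so the NB log-likelihood never falls below the
    Poisson one.
    """
    k = _validate_counts(counts)
    vals, wts = np.unique(k, return_counts=True)
    vals = vals.astype(float)
    wts = wts.astype(float)
    alpha, m = _weighted_nb_fit(vals, wts)
    ll = float((wts * _nb_log_pmf(vals, alpha, m)).sum())
    return FitResult(
        params=ZINBParams.from_mean(0.0, alpha, m),
        loglik=ll,
        n_iter=1,
        converged=True,
    )


def poisson_nb_reference_fits(counts):
    """Maximum-likelihood Poisson and NB fits for model comparison."""
    return fit_poisson(counts), fit_nb(counts)


def _validate_counts(counts) -> np.ndarray:
    k = np.asarray(counts)
    if k.ndim != 1 or k.size < 10:
        raise ValueError("need a 1-d vector of at least 10 counts")
    if np.any(k < 0):
        raise ValueError("counts must be non-negative")
    if np.all(k == k[0]):
        raise ValueError("degenerate data: all counts equal")
    return k.astype(float)


def fit_zinb(counts, tol: float = 1e-11, max_iter: int = 500) -> FitResult:
    """Maximum-likelihood fit of the ZINB distribution.

    EM over the structural-zero indicator: the E-step computes the
    posterior probability that each zero window is structural, the
    M-step updates ``pi`` in closed form and solves the weighted NB
    score equation for ``alpha`` by damped Newton with bisection
    fallback.  Convergence is declared when the relative log-likelihood
    change drops below ``tol``.  A boundary fit ``pi = 0`` is a valid
    output.
    """
    k = _validate_counts(counts)
    n = k.size
    vals, wts = np.unique(k, return_counts=True)
    vals = vals.astype(float)
    wts = wts.astype(float)
    has_zero = vals[0] == 0.0
    f0 = float(wts[0] / n) if has_zero else 0.0

    # Initialization: NB moment fit, pi = excess zeros over its prediction.
    alpha, mean = _weighted_nb_fit(vals, wts)
    zp = math.exp(_nb_log_zeroprob(alpha, mean))
    pi = min(max((f0 - zp) / (1.0 - zp), 0.0), 0.95) if zp < 1.0 else 0.0

    ll = _zinb_loglik(vals, wts, pi, alpha, mean)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        # E-step: responsibility of the structural-zero component.
        if has_zero and pi > 0:
            zp = math.exp(_nb_log_zeroprob(alpha, mean))
            z = pi / (pi + (1.0 - pi) * zp)
        else:
            z = 0.0
        # M-step.
        pi = f0 * z
        w = wts.copy()
        if has_zero:
            w[0] *= 1.0 - z
        alpha, mean = _weighted_nb_fit(vals, w)
        ll_new = _zinb_loglik(vals, wts, pi, alpha, mean)
        if abs(ll_new - ll) <= tol * max(1.0, abs(ll)):
            ll = ll_new
            converged = True
            break
        ll = ll_new
    if not converged:
        warnings.warn("fit_zinb did not converge; returning best iterate")
    return FitResult(
        params=ZINBParams.from_mean(pi, alpha, mean),
        loglik=ll,
        n_iter=it,
        converged=converged,
    )


# ---------------------------------------------------------------------------
# Negative multinomial probability update (HMM M-step workhorse)
# ---------------------------------------------------------------------------

def fit_nm_probs_given_pi_alpha(counts, weights, pi: float, alpha: float) -> np.ndarray:
    """Weighted ML update of the ZINM probability vector, (pi, alpha) fixed.

    Maximizes ``sum_i w_i log g(y_i | pi, alpha, p)`` over the simplex
    ``p0 + ... + pr = 1``.  Profiling: at the optimum ``p_j`` is
    proportional to the weighted column total ``T_j``, leaving a
    one-dimensional score in ``p0``,

        f'(p0) = W0 (1-pi) alpha p0^(alpha-1) / (pi + (1-pi) p0^alpha)
                 + W+ alpha / p0 - T / (1 - p0),

    where ``W0``/``W+`` are the total weights of all-zero / non-zero
    windows and ``T = sum_j T_j``.  The root is found by damped Newton
    with bisection fallback.
    """
    Y = np.atleast_2d(np.asarray(counts, dtype=float))
    w = np.asarray(weights, dtype=float)
    if w.shape != (Y.shape[0],):
        raise ValueError("weights must have one entry per observation")
    if np.any(w < 0):
        raise ValueError("weights must be non-negative")
    if w.sum() <= 0:
        raise ValueError("all weights are zero: empty state")
    r = Y.shape[1]
    zero = Y.sum(axis=1) == 0
    W0 = float(w[zero].sum())
    Wp = float(w[~zero].sum())
    T_j = w @ Y
    T = float(T_j.sum())

    if T <= 0:  # every weighted observation is zero: push p0 to the boundary
        eps = 1e-9
        p = np.full(r + 1, eps)
        p[0] = 1.0 - r * eps
        return p

    one_m_pi = 1.0 - pi

    def score(p0):
        s = Wp * alpha / p0 - T / (1.0 - p0)
        if W0 > 0:
            num = one_m_pi * alpha * p0 ** (alpha - 1.0)
            s += W0 * num / (pi + one_m_pi * p0 ** alpha)
        return s

    def dscore(p0):
        d = -Wp * alpha / p0 ** 2 - T / (1.0 - p0) ** 2
        if W0 > 0:
            g = pi + one_m_pi * p0 ** alpha
            gp = one_m_pi * alpha * p0 ** (alpha - 1.0)
            gpp = one_m_pi * alpha * (alpha - 1.0) * p0 ** (alpha - 2.0)
            d += W0 * (gpp * g - gp * gp) / (g * g)
        return d

    lo, hi = 1e-12, 1.0 - 1e-12
    x0 = Wp * alpha / (Wp * alpha + T) if Wp > 0 else 0.5
    if Wp == 0:
        # no non-zero mass term pushing p0 up besides the zero branch
        x0 = 0.5
    p0 = _newton_bisect(score, dscore, lo, hi, x0)
    p = np.empty(r + 1)
    p[0] = p0
    p[1:] = (1.0 - p0) * T_j / T
    # guard against exactly-zero replicate totals (keep params valid)
    tiny = 1e-12
    if np.any(p[1:] <= tiny):
        p[1:] = np.maximum(p[1:], tiny)
        p /= p.sum()
    return p
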