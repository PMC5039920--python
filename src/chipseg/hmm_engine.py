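"""Three-state hidden Markov model with ZINM emissions.

The discretizer models the per-window ChIP count vectors as emissions of
a 3-state HMM whose states correspond to low, medium and high abundance
of the chromatin feature.  Two states absorb the piece-wise baseline
variation so that the third ("high") state tracks the actual targets.

The zero-inflation probability ``pi`` and the shape ``alpha`` are
state-independent -- they describe the baseline read distribution -- and
are fitted once from the pooled negative-control profiles before the EM
cycles; estimating them inside Baum-Welch slows convergence and can
produce aberrant solutions.  Baum-Welch then alternates a scaled
forward-backward E-step with closed-form updates of the initial
distribution ``nu`` and the transition matrix ``Q`` and a Newton-solved
update of each state's emission probabilities.  The final segmentation
is the Viterbi path; the posterior probability of the called state is
reported as the per-window confidence.

Chromosomes are treated as independent chains sharing all parameters:
each chromosome block restarts from ``nu`` and block log-likelihoods are
summed.

Free parameters: 2 in ``nu``, 6 in ``Q``, the shape ``alpha`` and ``r``
emission probabilities per state (the probability vector of length
``r + 1`` loses one degree of freedom to the simplex constraint), for a
total of 3r + 9.  The zero-inflation ``pi`` is not counted: it is pinned
to the structural-zero excess of the control profiles rather than
estimated freely alongside the HMM parameters.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .io_binning import CountMatrix
from .zinm_model import (
    FitResult,
    ZINMParams,
    fit_nm_probs_given_pi_alpha,
    fit_zinb,
)

logger = logging.getLogger(__name__)

__all__ = [
    "N_STATES",
    "HMMParams",
    "HMMFit",
    "DiscretizedProfile",
    "forward_backward",
    "viterbi",
    "fit_baseline_from_controls",
    "baum_welch",
    "identify_state_roles",
    "discretize",
    "n_free_parameters",
]

N_STATES = 3
LOW, MEDIUM, HIGH = 0, 1, 2
_ROLE_NAMES = ("low", "medium", "high")


@dataclass
class HMMParams:
    """Initial distribution, transition matrix and per-state emissions."""

    nu: np.ndarray
    Q: np.ndarray
    emissions: Sequence[ZINMParams]

    def __post_init__(self):
        self.nu = np.asarray(self.nu, dtype=float)
        self.Q = np.asarray(self.Q, dtype=float)
        if self.nu.shape != (N_STATES,) or self.Q.shape != (N_STATES, N_STATES):
            raise ValueError(f"expected {N_STATES} states")
        if np.any(self.nu < 0) or np.any(self.Q < 0):
            raise ValueError("probabilities must be non-negative")
        if abs(self.nu.sum() - 1.0) > 1e-8:
            raise ValueError("nu must sum to 1")
        if np.any(np.abs(self.Q.sum(axis=1) - 1.0) > 1e-8):
            raise ValueError("rows of Q must sum to 1")
        if len(self.emissions) != N_STATES:
            raise ValueError("one emission distribution per state required")
        e0 = self.emissions[0]
        for e in self.emissions[1:]:
            if abs(e.pi - e0.pi) > 1e-12 or abs(e.alpha - e0.alpha) > 1e-12:
                raise ValueError("pi and alpha must be state-independent")
            if e.r != e0.r:
                raise ValueError("emission dimensions must agree across states")

    @property
    def r(self) -> int:
        return self.emissions[0].r

    @property
    def pi(self) -> float:
        return self.emissions[0].pi

    @property
    def alpha(self) -> float:
        return self.emissions[0].alpha


def n_free_parameters(params_or_r) -> int:
    """Number of independently estimated scalars: 3r + 9.

    Counts 2 free entries in ``nu``, 6 in ``Q``, the shape ``alpha`` and
    ``r`` free emission probabilities per state; the pinned
    zero-inflation ``pi`` is excluded (see module docstring).
    """
    r = params_or_r.r if isinstance(params_or_r, HMMParams) else int(params_or_r)
    return (N_STATES - 1) + N_STATES * (N_STATES - 1) + 1 + N_STATES * r


@dataclass
class HMMFit:
    """Result of fitting the ZINM-HMM to a count matrix."""

    params: HMMParams
    posteriors: np.ndarray          # (n, 3) state probabilities
    viterbi_path: np.ndarray        # (n,) raw state indices
    loglik_trace: list
    state_order: np.ndarray         # role_of_state[raw] in {0=low,1=medium,2=high}
    n_iter: int
    converged: bool

    @property
    def loglik(self) -> float:
        return self.loglik_trace[-1]

    @property
    def role_path(self) -> np.ndarray:
        """Viterbi path expressed as roles (0=low, 1=medium, 2=high)."""
        return self.state_order[self.viterbi_path]


@dataclass
class DiscretizedProfile:
    """Per-window state calls with confidence and optional QC verdict."""

    counts: CountMatrix
    fit: HMMFit
    states: np.ndarray       # roles per window
    confidence: np.ndarray   # posterior probability of the called state
    targets: np.ndarray      # boolean: 'high' windows with at least one read
    verdict: object = None

    def to_frame(self) -> pd.DataFrame:
        frame = self.counts.grid.to_frame()
        frame["state"] = self.states
        frame["confidence"] = self.confidence
        return frame

    def target_frame(self) -> pd.DataFrame:
        """Maximal runs of target windows as BED intervals."""
        frame = self.counts.grid.to_frame()
        rows = []
        for block in self.counts.blocks:
            tgt = self.targets[block]
            if not tgt.any():
                continue
            sub = frame.iloc[block]
            edges = np.flatnonzero(np.diff(np.r_[0, tgt.astype(int), 0]))
            for lo, hi in zip(edges[::2], edges[1::2]):
                rows.append(
                    (
                        sub["chrom"].iloc[0],
                        int(sub["start"].iloc[lo]),
                        int(sub["end"].iloc[hi - 1]),
                    )
                )
        return pd.DataFrame(rows, columns=["chrom", "start", "end"])


# ---------------------------------------------------------------------------
# Emission probabilities
# ---------------------------------------------------------------------------

def _emission_log_probs(Y: np.ndarray, params: HMMParams) -> np.ndarray:
    """Per-window, per-state ZINM log-probabilities, vectorized.

    The gamma-function terms that do not depend on the state are
    computed once and shared.
    """
    Y = np.asarray(Y, dtype=float)
    n, r = Y.shape
    pi, alpha = params.pi, params.alpha
    tot = Y.sum(axis=1)
    const = gammaln(alpha + tot) - gammaln(alpha) - gammaln(Y + 1.0).sum(axis=1)
    zero = tot == 0
    log1mpi = math.log1p(-pi) if pi < 1 else -np.inf
    out = np.empty((n, N_STATES))
    for s, em in enumerate(params.emissions):
        logp = np.log(em.p)
        body = log1mpi + const + alpha * logp[0] + Y @ logp[1:]
        if pi > 0:
            zval = np.logaddexp(math.log(pi), log1mpi + alpha * logp[0])
        else:
            zval = log1mpi + alpha * logp[0]
        out[:, s] = np.where(zero, zval, body)
    return out


# ---------------------------------------------------------------------------
# Forward-backward and Viterbi
# ---------------------------------------------------------------------------

def _forward_backward_logE(logE, params: HMMParams, blocks):
    """Scaled forward-backward on precomputed emission log-probs."""
    n = logE.shape[0]
    gamma = np.empty((n, N_STATES))
    xi_sum = np.zeros((N_STATES, N_STATES))
    start_post = np.zeros(N_STATES)
    loglik = 0.0
    Q, nu = params.Q, params.nu
    for sl in blocks:
        lb = logE[sl]
        T = lb.shape[0]
        mx = lb.max(axis=1)
        e = np.exp(lb - mx[:, None])
        F = np.empty((T, N_STATES))
        c = np.empty(T)
        f = nu * e[0]
        c[0] = f.sum()
        if c[0] <= 0:
            raise FloatingPointError("forward recursion underflow")
        F[0] = f / c[0]
        for t in range(1, T):
            f = (F[t - 1] @ Q) * e[t]
            c[t] = f.sum()
            if c[t] <= 0:
                raise FloatingPointError("forward recursion underflow")
            F[t] = f / c[t]
        B = np.empty((T, N_STATES))
        B[-1] = 1.0
        for t in range(T - 2, -1, -1):
            B[t] = (Q @ (e[t + 1] * B[t + 1])) / c[t + 1]
        g = F * B
        g /= g.sum(axis=1, keepdims=True)
        gamma[sl] = g
        start_post += g[0]
        if T > 1:
            M = np.einsum("ti,ij,tj->tij", F[:-1], Q, e[1:] * B[1:])
            M /= M.sum(axis=(1, 2), keepdims=True)
            xi_sum += M.sum(axis=0)
        loglik += float(np.log(c).sum() + mx.sum())
    return gamma, xi_sum, start_post, loglik


def forward_backward(chip_counts, params: HMMParams, blocks=None):
    """Posterior state probabilities, transition expectations and log-likelihood.

    ``chip_counts`` is the ``(n, r)`` ChIP count matrix; ``blocks`` is a
    list of per-chromosome index slices (one single chain by default).
    Each block is an independent sequence restarted from ``nu``.
    """
    Y = np.atleast_2d(np.asarray(chip_counts))
    if blocks is None:
        blocks = [slice(0, Y.shape[0])]
    logE = _emission_log_probs(Y, params)
    gamma, xi_sum, _, loglik = _forward_backward_logE(logE, params, blocks)
    return gamma, xi_sum, loglik


def viterbi(chip_counts, params: HMMParams, blocks=None) -> np.ndarray:
    """Most probable state path; chromosome blocks decoded independently.

    Ties are broken toward the lower state index at every backtracking
    step (including the final state).
    """
    Y = np.atleast_2d(np.asarray(chip_counts))
    if blocks is None:
        blocks = [slice(0, Y.shape[0])]
    logE = _emission_log_probs(Y, params)
    with np.errstate(divide="ignore"):
        logQ = np.log(params.Q)
        lognu = np.log(params.nu)
    path = np.empty(Y.shape[0], dtype=np.int64)
    for sl in blocks:
        lb = logE[sl]
        T = lb.shape[0]
        delta = lognu + lb[0]
        psi = np.empty((T, N_STATES), dtype=np.int64)
        for t in range(1, T):
            cand = delta[:, None] + logQ
            psi[t] = cand.argmax(axis=0)  # first occurrence = lowest index
            delta = cand[psi[t], np.arange(N_STATES)] + lb[t]
        states = np.empty(T, dtype=np.int64)
        states[-1] = int(delta.argmax())
        for t in range(T - 2, -1, -1):
            states[t] = psi[t + 1][states[t + 1]]
        path[sl] = states
    return path


# ---------------------------------------------------------------------------
# Fitting
# ---------------------------------------------------------------------------

def fit_baseline_from_controls(control_counts, alpha_max: float = 1e5):
    """(pi, alpha) from the ZINB fit of the pooled negative controls.

    Control columns are summed per window and a ZINB is fitted; the
    resulting zero-inflation and shape are held fixed through all EM
    iterations.  A boundary (Poisson-like) shape is capped at
    ``alpha_max`` so the downstream ZINM stays well defined.
    """
    C = np.atleast_2d(np.asarray(control_counts))
    if C.ndim != 2 or C.shape[1] < 1:
        raise ValueError("need at least one control column")
    pooled = C.sum(axis=1)
    if np.all(pooled == 0):
        raise ValueError("degenerate controls: all windows are zero")
    res = fit_zinb(pooled)
    pi, alpha = res.params.pi, res.params.alpha
    if not math.isfinite(alpha) or alpha > alpha_max:
        warnings.warn(
            "control shape estimate at the Poisson boundary; capping alpha"
        )
        alpha = alpha_max
    return pi, alpha


# Candidate rank splits used to seed the low/medium/high emissions.  EM
# from a single split can stall in a local optimum where two states share
# the baseline; running the deterministic splits below and keeping the
# best-likelihood fit escapes it without any randomness.
SEED_SPLITS = ((0.50, 0.90), (0.75, 0.95), (0.90, 0.99))


def _quantile_seed(Y: np.ndarray, pi: float, alpha: float, split=(0.5, 0.9)) -> HMMParams:
    """Deterministic initialization from total-count rank quantiles.

    Windows are rank-split by total ChIP count at the given quantile
    pair to seed the low/medium/high emissions; nu is uniform and Q
    sticky (0.95 on the diagonal).
    """
    n = Y.shape[0]
    order = np.argsort(Y.sum(axis=1), kind="stable")
    cuts = [0, int(split[0] * n), int(split[1] * n), n]
    emissions = []
    for s in range(N_STATES):
        w = np.zeros(n)
        w[order[cuts[s]:cuts[s + 1]]] = 1.0
        p = fit_nm_probs_given_pi_alpha(Y, w, pi, alpha)
        emissions.append(ZINMParams(pi=pi, alpha=alpha, p=p))
    nu = np.full(N_STATES, 1.0 / N_STATES)
    Q = np.full((N_STATES, N_STATES), 0.05 / (N_STATES - 1))
    np.fill_diagonal(Q, 0.95)
    return HMMParams(nu=nu, Q=Q, emissions=emissions)


def baum_welch(
    counts: CountMatrix,
    pi: float,
    alpha: float,
    init: HMMParams = None,
    max_iter: int = 100,
    tol: float = 1e-6,
) -> HMMFit:
    """EM fit of the 3-state ZINM-HMM with (pi, alpha) held fixed.

    The E-step runs the scaled forward-backward recursions per
    chromosome; the M-step re-estimates ``nu`` and ``Q`` from the
    expected counts and each state's probability vector from the
    posterior-weighted ZINM likelihood equations.  The log-likelihood
    trace is non-decreasing up to numerical slack; iteration stops when
    its relative change falls below ``tol``.

    Without an explicit ``init`` the EM is restarted from each of the
    deterministic rank-quantile seeds in :data:`SEED_SPLITS` and the fit
    with the highest final log-likelihood is returned.
    """
    Y = counts.chip_counts
    if Y.shape[1] < 1:
        raise ValueError("at least one chip column is required")
    if init is None:
        best = None
        for split in SEED_SPLITS:
            seed_params = _quantile_seed(Y, pi, alpha, split)
            fit = baum_welch(
                counts, pi=pi, alpha=alpha, init=seed_params,
                max_iter=max_iter, tol=tol,
            )
            if best is None or fit.loglik > best.loglik:
                best = fit
        return best
    blocks = counts.blocks
    params = init
    if abs(params.pi - pi) > 1e-9 or abs(params.alpha - alpha) > 1e-9:
        raise ValueError("init emissions must carry the pinned (pi, alpha)")

    trace = []
    converged = False
    n_m_steps = 0
    gamma = None
    for _ in range(max_iter + 1):
        logE = _emission_log_probs(Y, params)
        gamma, xi_sum, start_post, ll = _forward_backward_logE(logE, params, blocks)
        if trace and abs(ll - trace[-1]) <= tol * max(1.0, abs(trace[-1])):
            trace.append(ll)
            converged = True
            break
        trace.append(ll)
        if n_m_steps >= max_iter:
            break
        # M-step
        nu = start_post / start_post.sum()
        rows = xi_sum.sum(axis=1, keepdims=True)
        Q = params.Q.copy()
        ok = rows[:, 0] > 0
        Q[ok] = xi_sum[ok] / rows[ok]
        emissions = list(params.emissions)
        for s in range(N_STATES):
            resp = gamma[:, s]
            if resp.sum() < 1e-8:
                warnings.warn(f"state {s} collapsed; emission update skipped")
                continue
            p = fit_nm_probs_given_pi_alpha(Y, resp, pi, alpha)
            emissions[s] = ZINMParams(pi=pi, alpha=alpha, p=p)
        params = HMMParams(nu=nu, Q=Q, emissions=emissions)
        n_m_steps += 1

    path = viterbi(Y, params, blocks)
    state_order = identify_state_roles(params)
    return HMMFit(
        params=params,
        posteriors=gamma,
        viterbi_path=path,
        loglik_trace=trace,
        state_order=state_order,
        n_iter=n_m_steps,
        converged=converged,
    )


def identify_state_roles(params: HMMParams) -> np.ndarray:
    """Map raw states to roles by expected total ChIP signal per window.

    States are ranked by the sum over replicates of the mean implied by
    their emission parameters (``alpha * p_j / p0``), ascending; the
    result maps raw state index to 0=low, 1=medium, 2=high.  Ties fall
    back to raw-index order with a warning.
    """
    totals = np.array([em.means().sum() for em in params.emissions])
    if len(np.unique(totals)) < N_STATES:
        warnings.warn("tied state mean totals; role order falls back to raw index")
    ranks = np.argsort(totals, kind="stable")
    role_of_state = np.empty(N_STATES, dtype=np.int64)
    role_of_state[ranks] = np.arange(N_STATES)
    return role_of_state


def discretize(
    counts: CountMatrix,
    max_iter: int = 100,
    tol: float = 1e-6,
    init: HMMParams = None,
) -> DiscretizedProfile:
    """Full discretization: baseline fit, Baum-Welch, Viterbi, role calls.

    Returns per-window roles (0=low, 1=medium, 2=high) with the posterior
    probability of the called state as confidence.  Windows with zero
    counts in every profile stay in the chain (the zero-inflation
    component absorbs them) but are never reported as targets.
    """
    if len(counts.control_columns) < 1 or len(counts.chip_columns) < 1:
        raise ValueError(
            "discretization requires at least one control and one chip column"
        )
    pi, alpha = fit_baseline_from_controls(counts.control_counts)
    fit = baum_welch(counts, pi=pi, alpha=alpha, init=init, max_iter=max_iter, tol=tol)
    states = fit.role_path
    confidence = fit.posteriors[np.arange(counts.n), fit.viterbi_path]
    all_zero = counts.counts.sum(axis=1) == 0
    targets = (states == HIGH) & ~all_zero
    logger.info(
        "discretization: %d EM iterations, loglik %.2f, %d target windows",
        fit.n_iter, fit.loglik, int(targets.sum()),
    )
    return DiscretizedProfile(
        counts=counts,
        fit=fit,
        states=states,
        confidence=confidence,
        targets=targets,
    )
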