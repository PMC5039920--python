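"""Independent brute-force oracles used by the HMM tests.

Everything here works by exhaustive enumeration over all state paths and
is deliberately independent of the recursions it checks.
"""

import itertools

import numpy as np

from chipseg.hmm_engine import N_STATES, _emission_log_probs


def enumerate_paths(logE, nu, Q):
    """Joint log-probability of every state path (dict path -> logp)."""
    T = logE.shape[0]
    with np.errstate(divide="ignore"):
        logQ = np.log(Q)
        lognu = np.log(nu)
    out = {}
    for path in itertools.product(range(N_STATES), repeat=T):
        lp = lognu[path[0]] + logE[0, path[0]]
        for t in range(1, T):
            lp += logQ[path[t - 1], path[t]] + logE[t, path[t]]
        out[path] = lp
    return out

def brute_force_posteriors(Y, params):
    """Posterior state probabilities by summing over all paths."""
    logE = _emission_log_probs(np.atleast_2d(Y), params)
    paths = enumerate_paths(logE, params.nu, params.Q)
    T = logE.shape[0]
    logps = np.array(list(paths.values()))
    mx = logps.max()
    total = mx + np.log(np.exp(logps - mx).sum())
    post = np.zeros((T, N_STATES))
    for path, lp in paths.items():
        w = np.exp(lp - total)
        for t, s in enumerate(path):
            post[t, s] += w
    return post, total

def brute_force_viterbi(Y, params):
    """All maximum-probability paths (ties included) and the optimum."""
    logE = _emission_log_probs(np.atleast_2d(Y), params)
    paths = enumerate_paths(logE, params.nu, params.Q)
    best = max(paths.values())
    winners = [np.array(p) for p, lp in paths.items() if lp >= best - 1e-12]
    return winners, best
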