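"""Numba kernel for the Dirichlet-process Binomial-mixture Gibbs sampler.

One sweep resamples each preference parameter theta_i in turn from its full
conditional: copy an existing atom theta_j (j != i) with probability
proportional to Binomial(k_i; n_i, theta_j), or draw a fresh value from the
single-cue posterior Beta(1 + k_i, 1 + n_i - k_i) with probability
proportional to alpha times the Beta-Binomial marginal of (k_i, n_i).
The shared Binomial coefficient C(n_i, k_i) cancels and is dropped.
"""

import math

import numpy as np
from numba import njit

__all__ = ["gibbs_chain"]

_TINY = 1e-300


@njit(cache=True)
def gibbs_chain(k, n, alpha, n_keep, burn_in, thin, seed):
    """Run the collapsed-state Gibbs chain and return (n_keep, m) theta samples.

    ``k``/``n`` are float64 per-cue purple counts / trial counts; the chain is
    initialized from the independent single-cue posteriors.  Deterministic
    given ``seed``.
    """
    m = k.shape[0]
    np.random.seed(seed)
    thetas = np.empty(m)
    log_marg = np.empty(m)
    for i in range(m):
        thetas[i] = np.random.beta(1.0 + k[i], 1.0 + n[i] - k[i])
        # log Beta(k+1, n-k+1) = marginal likelihood without C(n, k)
        log_marg[i] = (
            math.lgamma(k[i] + 1.0)
            + math.lgamma(n[i] - k[i] + 1.0)
            - math.lgamma(n[i] + 2.0)
        )
    out = np.empty((n_keep, m))
    w = np.empty(m + 1)  # slots 0..m-1: existing atoms; slot m: fresh draw
    la = math.log(alpha)
    total = burn_in + n_keep * thin
    kept = 0
    for sweep in range(total):
        for i in range(m):
            best = la + log_marg[i]
            w[m] = best
            for j in range(m):
                if j == i:
                    w[j] = -1e308
                else:
                    tj = thetas[j]
                    if tj < _TINY:
                        tj = _TINY
                    omt = 1.0 - tj
                    if omt < _TINY:
                        omt = _TINY
                    lw = 0.0
                    if k[i] > 0.0:
                        lw += k[i] * math.log(tj)
                    if n[i] - k[i] > 0.0:
                        lw += (n[i] - k[i]) * math.log(omt)
                    w[j] = lw
                    if lw > best:
                        best = lw
            tot = 0.0
            for j in range(m + 1):
                w[j] = math.exp(w[j] - best)
                tot += w[j]
            u = np.random.random() * tot
            acc = 0.0
            pick = m
            for j in range(m + 1):
                acc += w[j]
                if u <= acc:
                    pick = j
                    break
            if pick == m:
                thetas[i] = np.random.beta(1.0 + k[i], 1.0 + n[i] - k[i])
            else:
                thetas[i] = thetas[pick]
        if sweep >= burn_in and (sweep - burn_in) % thin == 0 and kept < n_keep:
            for j in range(m):
                out[kept, j] = thetas[j]
            kept += 1
    return out
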