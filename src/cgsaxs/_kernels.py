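"""Numba-compiled Metropolis-Hastings chain for one q-bin.

The posterior of a form-factor vector f in the box [0, f_max]^L given N
training structures is a product of Gaussians
N(I_i | f^T G_i f, sigma_i); the geometry kernels G_i are precomputed once
per structure.  Proposals re-sample a single randomly chosen component
uniformly from [max(0, f-m), min(f_max, f+m)]; the asymmetric window widths
at the box edges enter the acceptance ratio so detailed balance holds.
"""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=False)
def run_chain(G, I_ref, sigma, f_max, m, n_iter, burn_in, thin, seed,
              anneal_ratio=1.0):
    """Sample a per-bin form-factor posterior.

    Parameters: G (N, L, L) symmetric kernels, I_ref (N,) reference
    intensities, sigma (N,) standard deviations, box bound f_max, proposal
    half-width m, chain length, burn-in, thinning stride, RNG seed.
    Returns (samples (T, L), n_accepted).

    With ``anneal_ratio > 1`` the likelihood standard deviations start at
    ``anneal_ratio * sigma`` and tighten geometrically to ``sigma`` over the
    burn-in (an initialization aid for very tight posteriors, where a cold
    single-component chain freezes in curved valleys); the post-burn-in
    phase is always plain Metropolis-Hastings at the final sigma.
    """
    np.random.seed(seed)
    N, L, _ = G.shape
    f = np.empty(L)
    for t in range(L):
        f[t] = np.random.uniform(0.0, f_max)
    # current per-structure intensities u_i = f^T G_i f and gradients h_i = G_i f
    u = np.zeros(N)
    h = np.zeros((N, L))
    for i in range(N):
        for t in range(L):
            acc = 0.0
            for s in range(L):
                acc += G[i, t, s] * f[s]
            h[i, t] = acc
            u[i] += f[t] * acc
    # sum of squared residuals scaled by the final sigma; the log-likelihood
    # at annealing multiplier c is -ssq / (2 c^2)
    ssq = 0.0
    for i in range(N):
        r = (I_ref[i] - u[i]) / sigma[i]
        ssq += r * r
    log_anneal = np.log(anneal_ratio)
    n_keep = (n_iter - burn_in + thin - 1) // thin
    samples = np.empty((n_keep, L))
    kept = 0
    accepted = 0
    for it in range(n_iter):
        if log_anneal > 0.0 and it < burn_in:
            mult = np.exp(log_anneal * (1.0 - it / burn_in))
        else:
            mult = 1.0
        c = np.random.randint(0, L)
        fc = f[c]
        lo = fc - m
        if lo < 0.0:
            lo = 0.0
        hi = fc + m
        if hi > f_max:
            hi = f_max
        w_fwd = hi - lo
        fp = lo + np.random.random() * w_fwd
        lo2 = fp - m
        if lo2 < 0.0:
            lo2 = 0.0
        hi2 = fp + m
        if hi2 > f_max:
            hi2 = f_max
        w_rev = hi2 - lo2
        df = fp - fc
        dsq = fp * fp - fc * fc
        new_ssq = 0.0
        for i in range(N):
            u_new = u[i] + dsq * G[i, c, c] + 2.0 * df * (h[i, c] - G[i, c, c] * fc)
            r = (I_ref[i] - u_new) / sigma[i]
            new_ssq += r * r
        # acceptance: min{1, P' Q(rev) / (P Q(fwd))}, Q = 1/window width
        log_ratio = (-0.5 * (new_ssq - ssq) / (mult * mult)
                     + np.log(w_fwd) - np.log(w_rev))
        if log_ratio >= 0.0 or np.random.random() < np.exp(log_ratio):
            accepted += 1
            ssq = new_ssq
            for i in range(N):
                u[i] += dsq * G[i, c, c] + 2.0 * df * (h[i, c] - G[i, c, c] * fc)
                for t in range(L):
                    h[i, t] += G[i, t, c] * df
            f[c] = fp
        if it >= burn_in and (it - burn_in) % thin == 0:
            for t in range(L):
                samples[kept, t] = f[t]
            kept += 1
    return samples[:kept], accepted
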