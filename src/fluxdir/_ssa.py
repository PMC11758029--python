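"""Compiled Gillespie kernel over the elementary rate-term table.

The kernel mirrors :meth:`fluxdir.models.NetworkModel.birth_rates`; the
pure-Python reference implementation lives in :mod:`fluxdir.simulate`
and the two are cross-checked distributionally in the test suite.
"""

import numpy as np
from numba import njit


@njit(cache=False)
def ssa_sample(V, n_latent, tt, ts, tk, ta, tK, tn, birth_scale, conc_scale,
               tau, latent_rate, N, burn_in, spacing, seed):
    """Single-trajectory SSA from the zero state; returns an (N, V) int64
    matrix of states recorded at times burn_in + m * spacing."""
    np.random.seed(seed)
    ns = V + n_latent
    x = np.zeros(ns)
    for l in range(n_latent):
        x[V + l] = np.random.random()
    out = np.zeros((N, V), dtype=np.int64)
    birth = np.zeros(V)
    n_terms = tt.shape[0]
    t = 0.0
    t_next = burn_in
    rec = 0
    while rec < N:
        for i in range(V):
            birth[i] = 0.0
        for m in range(n_terms):
            s = ts[m]
            u = 0.0
            if s >= 0:
                u = x[s] / conc_scale[s]
            kind = tk[m]
            if kind == 0:
                v = ta[m]
            elif kind == 1:
                v = ta[m] * u
            elif kind == 2:
                v = ta[m] * u / (tK[m] + u)
            elif kind == 3:
                v = ta[m] / (tK[m] + u)
            else:
                v = ta[m] / ((u / tK[m]) ** tn[m] + 1.0)
            birth[tt[m]] += v
        total = 0.0
        for i in range(V):
            birth[i] *= birth_scale[i]
            total += birth[i] + x[i] / tau[i]
        total += n_latent * latent_rate
        if total <= 0.0:
            # frozen state: every remaining snapshot sees it unchanged
            while rec < N:
                for i in range(V):
                    out[rec, i] = np.int64(x[i])
                rec += 1
            break
        dt = -np.log(1.0 - np.random.random()) / total
        while rec < N and t_next <= t + dt:
            for i in range(V):
                out[rec, i] = np.int64(x[i])
            rec += 1
            t_next += spacing
        if rec >= N:
            break
        t += dt
        r = np.random.random() * total
        acc = 0.0
        fired = False
        for i in range(V):
            acc += birth[i]
            if r < acc:
                x[i] += 1.0
                fired = True
                break
        if not fired:
            for i in range(V):
                acc += x[i] / tau[i]
                if r < acc:
                    x[i] -= 1.0
                    fired = True
                    break
        if not fired:
            for l in range(n_latent):
                acc += latent_rate
                if r < acc:
                    x[V + l] = np.random.random()
                    fired = True
                    break
        # if rounding left the draw unassigned (r ~ total), skip the event
    return out
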