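"""Independent reference implementations used only to check the package.

These deliberately share no code with nbprs: the pruning oracle re-derives
the documented greedy from scratch with naive loops, and the Cox oracle
maximizes a hand-written Breslow log partial likelihood by scalar
optimization.
"""

import numpy as np
from scipy.optimize import minimize_scalar


def greedy_prune_bruteforce(variants, dosages, r2_max):
    """Naive re-derivation of ascending-p greedy LD pruning.

    ``variants``: list of (id, chrom, pos, p); ``dosages``: dict id -> vector.
    Returns kept ids in genomic order.
    """
    def r2(a, b):
        return np.corrcoef(dosages[a], dosages[b])[0, 1] ** 2

    remaining = sorted(variants, key=lambda v: (v[3], v[2], v[0]))
    kept = []
    while remaining:
        best = remaining.pop(0)
        kept.append(best)
        remaining = [v for v in remaining
                     if v[1] != best[1] or r2(v[0], best[0]) <= r2_max]
    return [v[0] for v in sorted(kept, key=lambda v: (v[1], v[2], v[0]))]


def breslow_loglik(beta, time, event, x):
    """Breslow log partial likelihood for a single covariate."""
    ll = 0.0
    eta = beta * np.asarray(x, dtype=float)
    for t in np.sort(np.asarray(time)[np.asarray(event) == 1]):
        at_risk = np.asarray(time) >= t
        dead = (np.asarray(time) == t) & (np.asarray(event) == 1)
        ll += eta[dead].sum() - dead.sum() * np.log(np.exp(eta[at_risk]).sum())
    return ll


def cox_mle_gridsearch(time, event, x, bound=4.0):
    """Maximize the Breslow partial likelihood over beta in [-bound, bound]."""
    res = minimize_scalar(lambda b: -breslow_loglik(b, time, event, x),
                          bounds=(-bound, bound), method="bounded",
                          options={"xatol": 1e-10})
    return float(res.x)
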