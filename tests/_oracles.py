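"""Independent reference computations used by the test suite only."""

import numpy as np
from scipy import optimize

from olihl import log_likelihood


def mle_grid_oracle(x, lam_lo=1e-3, lam_hi=100.0):
    """Independent MLE from log-likelihood evaluations only.

    Dense log-grid scan, golden-section refinement, then a root find of the
    Richardson-extrapolated central-difference score inside the golden
    bracket (plain golden section stalls at the ~1e-7 flatness floor of the
    double-precision likelihood).
    """
    grid = np.exp(np.linspace(np.log(lam_lo), np.log(lam_hi), 2000))
    vals = np.array([-log_likelihood(x, l) for l in grid])
    k = int(np.argmin(vals))
    res = optimize.minimize_scalar(
        lambda l: -log_likelihood(x, l),
        bracket=(grid[max(k - 1, 0)], grid[k], grid[min(k + 1, len(grid) - 1)]),
        method="golden", options={"xtol": 1e-12},
    )
    lam0 = float(res.x)

    def score(lam):
        h = 1e-4 * (1.0 + lam)
        d1 = (log_likelihood(x, lam + h) - log_likelihood(x, lam - h)) / (2 * h)
        d2 = (log_likelihood(x, lam + h / 2) - log_likelihood(x, lam - h / 2)) / h
        return (4.0 * d2 - d1) / 3.0

    a, b = lam0 * 0.98, lam0 * 1.02
    sa, sb = score(a), score(b)
    if sa * sb > 0:  # already at the floor; golden answer stands
        return lam0
    return float(optimize.brentq(score, a, b, xtol=1e-12))
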