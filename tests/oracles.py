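"""Independent brute-force oracles used by the test suite.

The restricted log-likelihood here is written directly from its definition
(determinants and GLS residuals via generic numpy calls) and shares no code
with the package's REML solvers; the grid search maximizes it by staged
exhaustive refinement down to a 1e-3 step.
"""

import itertools

import numpy as np


def restricted_ll(y, X, V):
    Vi = np.linalg.inv(V)
    XtViX = X.T @ Vi @ X
    beta = np.linalg.solve(XtViX, X.T @ Vi @ y)
    r = y - X @ beta
    return float(-0.5 * (np.linalg.slogdet(V)[1]
                         + np.linalg.slogdet(XtViX)[1]
                         + r @ Vi @ r))


def grid_search_reml(y, X, kernels, upper, final_step=1e-3):
    """Exhaustive staged grid search of the restricted likelihood.

    Starts on a coarse grid over [final_step, upper]^k and refines around
    the incumbent until the grid step reaches ``final_step``.  Returns the
    arg-max variance components.
    """
    k = len(kernels)
    lo = np.full(k, final_step)
    hi = np.full(k, upper)
    step = (upper - final_step) / 12.0
    best = None
    while True:
        axes = [np.arange(lo[i], hi[i] + step / 2, step) for i in range(k)]
        best_ll = -np.inf
        for point in itertools.product(*axes):
            V = sum(s * C for s, C in zip(point, kernels))
            ll = restricted_ll(y, X, V)
            if ll > best_ll:
                best_ll, best = ll, np.array(point)
        if step <= final_step:
            return best, best_ll
        lo = np.maximum(best - 1.2 * step, final_step)
        hi = best + 1.2 * step
        step = max(step / 6.0, final_step)
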