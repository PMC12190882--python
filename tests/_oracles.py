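"""Independent numerical oracles shared by the test suite."""

import numpy as np


def brute_force_rho(X, Y, n_restarts=24, seed=0):
    """Maximize corr(w_x'X, w_y'Y) over weight pairs by multi-start BFGS.

    Direct optimization on the correlation objective, independent of the
    eigen-decomposition route used by the implementation.
    """
    from scipy.optimize import minimize

    Xc = X - X.mean(axis=1, keepdims=True)
    Yc = Y - Y.mean(axis=1, keepdims=True)
    mx = X.shape[0]

    def neg_corr(w):
        u, v = w[:mx] @ Xc, w[mx:] @ Yc
        nu, nv = np.linalg.norm(u), np.linalg.norm(v)
        if nu == 0 or nv == 0:
            return 0.0
        return -abs(u @ v) / (nu * nv)

    rng = np.random.default_rng(seed)
    best = 0.0
    for _ in range(n_restarts):
        res = minimize(neg_corr, rng.standard_normal(mx + Y.shape[0]),
                       method="BFGS", options={"maxiter": 500, "gtol": 1e-10})
        best = max(best, -res.fun)
    return best
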