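"""Independent test oracles (never used by the implementation)."""

import numpy as np
from scipy import stats

from txswitch.lna import grid_moments


def joint_gaussian_loglik(y, params):
    """Brute-force likelihood of the classical (non-restarting) LNA
    state-space model: stack all transitions into one joint multivariate
    normal over the observations and evaluate it directly."""
    T = len(y) - 1
    phi, F, Q = grid_moments(params, y.times, scaled=True)
    n = T + 1
    mean_x = phi.copy()
    cov_x = np.zeros((n, 2, n, 2))
    for i in range(1, n):
        cov_x[i, :, i, :] = (F[i - 1] @ cov_x[i - 1, :, i - 1, :]
                             @ F[i - 1].T + Q[i - 1])
        for j in range(i):
            cov_x[i, :, j, :] = F[i - 1] @ cov_x[i - 1, :, j, :]
            cov_x[j, :, i, :] = cov_x[i, :, j, :].T
    H = np.array([0.0, 1.0])
    mean_y = mean_x @ H
    cov_y = np.einsum("a,iajb,b->ij", H, cov_x, H) \
        + params.sigma_eps ** 2 * np.eye(n)
    return stats.multivariate_normal.logpdf(y.values, mean_y, cov_y)
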