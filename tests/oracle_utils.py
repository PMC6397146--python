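"""Brute-force oracles, independent of the package's recursive algorithms.

The joint-Gaussian oracle builds the full prior covariance of the state
sequence from the transition law, conditions on all observations at once,
and evaluates the likelihood as one multivariate-normal density — no
Kalman recursion anywhere.
"""
import numpy as np
from scipy.stats import multivariate_normal


def _sys_mats(dt, spec, nvrs, sigma2):
    """Transition and process covariance over one gap, built longhand."""
    d = spec.state_dim
    F = np.eye(d)
    Q = np.zeros((d, d))
    q_tr = nvrs[0] * sigma2
    if spec.trend.kind == "integrated_random_walk":
        F[0, 1] = dt
        Q[0, 0] = q_tr * dt ** 3 / 3.0
        Q[0, 1] = Q[1, 0] = q_tr * dt ** 2 / 2.0
        Q[1, 1] = q_tr * dt
    else:
        Q[0, 0] = q_tr * dt
    s0 = spec.trend_dim
    for i in range(spec.n_harmonics):
        Q[s0 + 2 * i, s0 + 2 * i] = nvrs[1 + i] * sigma2 * dt
        Q[s0 + 2 * i + 1, s0 + 2 * i + 1] = nvrs[1 + i] * sigma2 * dt
    return F, Q


def _obs_row(t, spec):
    d = spec.state_dim
    h = np.zeros(d)
    h[0] = 1.0
    for i, w in enumerate(spec.frequencies):
        h[spec.trend_dim + 2 * i] = np.cos(w * t)
        h[spec.trend_dim + 2 * i + 1] = np.sin(w * t)
    return h


def joint_gaussian_reference(times, y, spec, nvrs, sigma2, init_mean, init_var):
    """Posterior state means/variances and log-likelihood by direct conditioning.

    Returns dict with 'means' (n, d), 'variances' (n, d) and 'loglik'.
    """
    times = np.asarray(times, float)
    y = np.asarray(y, float)
    n, d = times.size, spec.state_dim

    prior_means = [np.asarray(init_mean, float)]
    prior_covs = [init_var * np.eye(d)]
    Fs = []
    for k in range(1, n):
        F, Q = _sys_mats(times[k] - times[k - 1], spec, nvrs, sigma2)
        Fs.append(F)
        prior_means.append(F @ prior_means[-1])
        prior_covs.append(F @ prior_covs[-1] @ F.T + Q)

    # Phi[i][j]: transition from time i to time j (j >= i)
    Phi = [[None] * n for _ in range(n)]
    for i in range(n):
        Phi[i][i] = np.eye(d)
        for j in range(i + 1, n):
            Phi[i][j] = Fs[j - 1] @ Phi[i][j - 1]
    Sx = [[None] * n for _ in range(n)]
    for i in range(n):
        for j in range(i, n):
            Sx[i][j] = prior_covs[i] @ Phi[i][j].T
            Sx[j][i] = Sx[i][j].T

    H = np.array([_obs_row(t, spec) for t in times])
    Sy = np.array([[H[i] @ Sx[i][j] @ H[j] for j in range(n)] for i in range(n)])
    Sy += sigma2 * np.eye(n)
    mu_y = np.array([H[i] @ prior_means[i] for i in range(n)])
    loglik = multivariate_normal(mean=mu_y, cov=Sy).logpdf(y)

    sol = np.linalg.solve(Sy, y - mu_y)
    means = np.empty((n, d))
    variances = np.empty((n, d))
    for i in range(n):
        Cxy = np.column_stack([Sx[i][j] @ H[j] for j in range(n)])   # d x n
        means[i] = prior_means[i] + Cxy @ sol
        Ppost = prior_covs[i] - Cxy @ np.linalg.solve(Sy, Cxy.T)
        variances[i] = np.diag(Ppost)
    return {"means": means, "variances": variances, "loglik": float(loglik)}
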