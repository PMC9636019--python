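"""Independent oracles used by the test suite.

These implementations deliberately avoid the package's own code paths:
the Kalman filter/smoother below is the textbook closed-form recursion
for linear-Gaussian models, written directly from the standard equations.
"""

import numpy as np


def kalman_filter_rts(y, mask, A, H, Q, R, mu0, P0):
    """Closed-form Kalman filter + RTS smoother with missing coordinates.

    y: (T, m); mask: (T, m) observed flags; A: (n, n); H: (m, n);
    Q, R: process/measurement covariances; returns dict of moments and
    the exact log-likelihood over observed coordinates.
    """
    T, m = y.shape
    n = len(mu0)
    fm = np.zeros((T, n)); fP = np.zeros((T, n, n))
    pm = np.zeros((T, n)); pP = np.zeros((T, n, n))
    ll = 0.0
    mean, cov = mu0.copy(), P0.copy()
    for t in range(T):
        if t > 0:
            mean = A @ mean
            cov = A @ cov @ A.T + Q
        pm[t], pP[t] = mean, cov
        o = np.nonzero(mask[t])[0]
        if len(o):
            Ho = H[o]
            S = Ho @ cov @ Ho.T + R[np.ix_(o, o)]
            K = cov @ Ho.T @ np.linalg.inv(S)
            innov = y[t, o] - Ho @ mean
            sign, logdet = np.linalg.slogdet(S)
            ll += -0.5 * (innov @ np.linalg.solve(S, innov) + logdet
                          + len(o) * np.log(2 * np.pi))
            mean = mean + K @ innov
            cov = cov - K @ S @ K.T
        fm[t], fP[t] = mean, cov
    sm = fm.copy(); sP = fP.copy()
    for t in range(T - 2, -1, -1):
        G = fP[t] @ A.T @ np.linalg.inv(pP[t + 1])
        sm[t] = fm[t] + G @ (sm[t + 1] - pm[t + 1])
        sP[t] = fP[t] + G @ (sP[t + 1] - pP[t + 1]) @ G.T
    return {
        "filtered_means": fm, "filtered_covs": fP,
        "smoothed_means": sm, "smoothed_covs": sP, "loglik": ll,
    }


def spearman_bruteforce(x, y):
    """Rank correlation from first principles (average ranks for ties)."""
    def ranks(v):
        order = np.argsort(v, kind="stable")
        r = np.empty(len(v), dtype=float)
        r[order] = np.arange(1, len(v) + 1)
        # average tied ranks
        for val in np.unique(v):
            sel = v == val
            r[sel] = r[sel].mean()
        return r
    rx, ry = ranks(np.asarray(x, float)), ranks(np.asarray(y, float))
    rx -= rx.mean(); ry -= ry.mean()
    return float((rx @ ry) / np.sqrt((rx @ rx) * (ry @ ry)))


def rotation_matrix_axis_angle(axis, angle):
    """Rodrigues formula written out directly, for composition oracles."""
    axis = np.asarray(axis, float)
    axis = axis / np.linalg.norm(axis)
    K = np.array([
        [0, -axis[2], axis[1]],
        [axis[2], 0, -axis[0]],
        [-axis[1], axis[0], 0],
    ])
    return np.eye(3) + np.sin(angle) * K + (1 - np.cos(angle)) * (K @ K)
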