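"""Shared brute-force oracles for sampler tests."""

import numpy as np

from hpwhmm.model import confined_moments


def dense_center_posterior(traj, z, params, v0):
    """Exact joint-Gaussian conditional of the center path C.

    Assembles the full precision matrix per coordinate: prior N(X_0, v0) on
    C_1, random-walk transitions with z-dependent variance, and rescaled
    displacement observations during confined increments.  Returns
    (mean (M, 2), cov (M, M)); the covariance is shared by both coordinates.
    """
    dts = traj.dts
    dX = traj.displacements
    X = traj.positions[:-1]
    m = dts.size
    beta, var_conf = confined_moments(params.kappa, params.D, dts)
    y = X + dX / beta[:, None]
    r = var_conf / beta**2
    q = 2.0 * dts[:-1] * np.where(z[:-1] == 1, params.DC, params.Dest)

    prec = np.zeros((m, m))
    prec[0, 0] += 1.0 / v0
    rhs = np.zeros((m, 2))
    rhs[0] += traj.positions[0] / v0
    for i in range(m - 1):
        prec[i, i] += 1.0 / q[i]
        prec[i + 1, i + 1] += 1.0 / q[i]
        prec[i, i + 1] -= 1.0 / q[i]
        prec[i + 1, i] -= 1.0 / q[i]
    for i in range(m):
        if z[i] == 1:
            prec[i, i] += 1.0 / r[i]
            rhs[i] += y[i] / r[i]
    cov = np.linalg.inv(prec)
    return cov @ rhs, cov
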