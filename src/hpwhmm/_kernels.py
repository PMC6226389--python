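"""Sequential numerical kernels (numba-compiled).

The forward-filter/backward-sample recursions for the discrete state chain
and for the scalar linear-Gaussian center chain are inherently sequential,
so they are JIT-compiled; everything around them is vectorized numpy.
"""

from __future__ import annotations

import numpy as np
from numba import njit

VAR_FLOOR = 1e-12  # um^2; guards Kalman recursions when DC is sampled tiny


@njit(cache=True)
def build_arrays(dts, dX, X, D, DC, Dest, kappa):
    """One-pass construction of the per-increment emission quantities.

    Returns (y, r, log_jac, lp_free, q_conf, q_free, beta, g_conf):
    the rescaled pseudo-observation of the center and its variance, the
    dX->y log-Jacobian, the free-state displacement log-density, the two
    center step variances, the OU shrinkage factor and the confined
    variance divided by D.
    """
    m = dts.shape[0]
    y = np.empty((m, 2))
    r = np.empty(m)
    log_jac = np.empty(m)
    lp_free = np.empty(m)
    q_conf = np.empty(m)
    q_free = np.empty(m)
    beta = np.empty(m)
    g_conf = np.empty(m)
    log2pi = np.log(2.0 * np.pi)
    # time steps are uniform in practice: recompute the transcendentals
    # only when dt changes
    dt_prev = -1.0
    b = 0.0
    g = 0.0
    ri = 0.0
    lj = 0.0
    vf = 0.0
    log_vf = 0.0
    for i in range(m):
        dt = dts[i]
        if dt != dt_prev:
            b = -np.expm1(-kappa * dt)
            g = -np.expm1(-2.0 * kappa * dt) / kappa
            ri = D * g / (b * b)
            lj = -2.0 * np.log(b)
            vf = 2.0 * D * dt
            log_vf = np.log(vf)
            dt_prev = dt
        beta[i] = b
        g_conf[i] = g
        y[i, 0] = X[i, 0] + dX[i, 0] / b
        y[i, 1] = X[i, 1] + dX[i, 1] / b
        r[i] = ri
        log_jac[i] = lj
        lp_free[i] = (
            -log2pi - log_vf
            - 0.5 * (dX[i, 0] ** 2 + dX[i, 1] ** 2) / vf
        )
        q_conf[i] = 2.0 * dt * DC
        q_free[i] = 2.0 * dt * Dest
    return y, r, log_jac, lp_free, q_conf, q_free, beta, g_conf


@njit(cache=True)
def state_emissions(y, r, log_jac, lp_free, q_conf, q_free, C):
    """Per-increment log emissions for the 2-state chain given centers C."""
    m = r.shape[0]
    log_b = np.empty((m, 2))
    log2pi = np.log(2.0 * np.pi)
    r_prev = -1.0
    log_r = 0.0
    qf_prev = -1.0
    log_qf = 0.0
    qc_prev = -1.0
    log_qc = 0.0
    for i in range(m):
        if r[i] != r_prev:
            log_r = np.log(r[i])
            r_prev = r[i]
        log_b[i, 0] = lp_free[i]
        log_b[i, 1] = (
            log_jac[i] - log2pi - log_r
            - 0.5
            * ((y[i, 0] - C[i, 0]) ** 2 + (y[i, 1] - C[i, 1]) ** 2)
            / r[i]
        )
        if i < m - 1:
            if q_free[i] != qf_prev:
                log_qf = np.log(q_free[i])
                qf_prev = q_free[i]
            if q_conf[i] != qc_prev:
                log_qc = np.log(q_conf[i])
                qc_prev = q_conf[i]
            dcx = C[i + 1, 0] - C[i, 0]
            dcy = C[i + 1, 1] - C[i, 1]
            sq = dcx * dcx + dcy * dcy
            log_b[i, 0] += -log2pi - log_qf - 0.5 * sq / q_free[i]
            log_b[i, 1] += -log2pi - log_qc - 0.5 * sq / q_conf[i]
    return log_b


@njit(cache=True)
def diffusivity_sums(z, C, X, dX, dts, beta, g_conf):
    """Sufficient statistics for the D and DC conditionals.

    Returns (rate_d, n_inc, rate_dc_times_dc... ) —
    specifically (sum resid^2/g over both coordinates / 2, number of
    confined center increments, sum dC^2/(4 dt) over confined increments).
    """
    m = z.shape[0]
    rate_d = 0.0
    for i in range(m):
        if z[i] == 1:
            rx = dX[i, 0] - (C[i, 0] - X[i, 0]) * beta[i]
            ry = dX[i, 1] - (C[i, 1] - X[i, 1]) * beta[i]
            rate_d += 0.5 * (rx * rx + ry * ry) / g_conf[i]
        else:
            g = 2.0 * dts[i]
            rate_d += 0.5 * (dX[i, 0] ** 2 + dX[i, 1] ** 2) / g
    n_conf = 0
    rate_dc = 0.0
    for i in range(m - 1):
        if z[i] == 1:
            n_conf += 1
            dcx = C[i + 1, 0] - C[i, 0]
            dcy = C[i + 1, 1] - C[i, 1]
            rate_dc += (dcx * dcx + dcy * dcy) / (4.0 * dts[i])
    return rate_d, n_conf, rate_dc


@njit(cache=True)
def kappa_loglik_confined(z, X, dX, C, dts, D, kappa):
    """Log-likelihood of the confined increments as a function of kappa."""
    m = z.shape[0]
    out = 0.0
    log2pi = np.log(2.0 * np.pi)
    dt_prev = -1.0
    b = 0.0
    v = 1.0
    log_v = 0.0
    for i in range(m):
        if z[i] == 1:
            if dts[i] != dt_prev:
                b = -np.expm1(-kappa * dts[i])
                v = (D / kappa) * -np.expm1(-2.0 * kappa * dts[i])
                log_v = np.log(v)
                dt_prev = dts[i]
            rx = dX[i, 0] - (C[i, 0] - X[i, 0]) * b
            ry = dX[i, 1] - (C[i, 1] - X[i, 1]) * b
            out += -log2pi - log_v - 0.5 * (rx * rx + ry * ry) / v
    return out


@njit(cache=True)
def ffbs_binary(log_b, trans, init_p1, u):
    """Exact draw of a binary state path from its HMM full conditional.

    Parameters
    ----------
    log_b : (M, 2) log emission density per increment and state
    trans : (2, 2) transition matrix, trans[i, j] = P(z_next=j | z_now=i)
    init_p1 : prior probability that the first state is 1
    u : (M,) uniform variates driving the backward draw

    Returns the sampled path and the filtered P(z_i = 1 | data up to i).
    """
    m = log_b.shape[0]
    f1 = np.empty(m)
    # forward filter, normalized linear domain with per-step log rescaling
    b_max = max(log_b[0, 0], log_b[0, 1])
    a0 = (1.0 - init_p1) * np.exp(log_b[0, 0] - b_max)
    a1 = init_p1 * np.exp(log_b[0, 1] - b_max)
    s = a0 + a1
    a0 /= s
    a1 /= s
    f1[0] = a1
    filt0 = np.empty(m)
    filt0[0] = a0
    for i in range(1, m):
        p0 = a0 * trans[0, 0] + a1 * trans[1, 0]
        p1 = a0 * trans[0, 1] + a1 * trans[1, 1]
        b_max = max(log_b[i, 0], log_b[i, 1])
        a0 = p0 * np.exp(log_b[i, 0] - b_max)
        a1 = p1 * np.exp(log_b[i, 1] - b_max)
        s = a0 + a1
        a0 /= s
        a1 /= s
        f1[i] = a1
        filt0[i] = a0
    # backward sample
    z = np.empty(m, dtype=np.int8)
    z[m - 1] = 1 if u[m - 1] < f1[m - 1] else 0
    for i in range(m - 2, -1, -1):
        w1 = f1[i] * trans[1, z[i + 1]]
        w0 = filt0[i] * trans[0, z[i + 1]]
        p1 = w1 / (w0 + w1)
        z[i] = 1 if u[i] < p1 else 0
    return z, f1


@njit(cache=True)
def pair_gibbs_pass(
    z,
    C,
    y,
    r,
    log_jac,
    lp_free,
    q_conf,
    q_free,
    trans,
    prior_m,
    prior_v,
    u,
    normals,
    forward,
):
    """Sequential exact Gibbs updates of each (z_j, C_j) pair in place.

    For each index j the latent center C_j is integrated out analytically
    under both states, z_j is drawn from the resulting two-point marginal,
    and C_j is then drawn from its conditional Gaussian.  This local move
    complements the blocked FFBS updates: it lets a misplaced confinement
    boundary creep (and cascade) even though the blocked moves are
    effectively vetoed by the center-increment variance mismatch between
    the free and confined states.

    Parameters
    ----------
    z, C : current state and center paths, modified in place
    y, r : per-index pseudo-observation of C_j under the confined state
        (y = X + dX/beta, per coordinate variance r) and ``log_jac`` the
        log-Jacobian constant per index relating the dX density to the
        y density (2 coordinates)
    lp_free : per-index log-density of dX under the free state
    q_conf, q_free : per-index center-step variances 2*dt*DC and 2*dt*Dest
        (q[j] is the variance of C_{j+1} - C_j)
    trans : 2x2 state transition matrix
    prior_m, prior_v : Gaussian prior on C_0 (per-coordinate variance)
    u : (M,) uniforms for the state draws
    normals : (M, 2) normals for the center draws
    forward : sweep direction flag (alternate between passes)
    """
    m_tot = z.shape[0]
    lw = np.empty(2)
    mm = np.empty((2, 2))
    vv = np.empty(2)
    log_trans = np.log(trans)
    for step in range(m_tot):
        j = step if forward else m_tot - 1 - step
        for s in range(2):
            # state-chain terms
            w = 0.0
            if j > 0:
                w += log_trans[z[j - 1], s]
            if j < m_tot - 1:
                w += log_trans[s, z[j + 1]]
            # center prior from the left (depends on z_{j-1}, fixed)
            if j > 0:
                m0x = C[j - 1, 0]
                m0y = C[j - 1, 1]
                v0 = q_conf[j - 1] if z[j - 1] == 1 else q_free[j - 1]
            else:
                m0x = prior_m[0]
                m0y = prior_m[1]
                v0 = prior_v
            mx = m0x
            my = m0y
            v = v0
            if s == 1:
                # particle displacement as a noisy observation of C_j
                vy = v + r[j]
                w += (
                    log_jac[j]
                    - np.log(2.0 * np.pi * vy)
                    - 0.5 * ((y[j, 0] - mx) ** 2 + (y[j, 1] - my) ** 2) / vy
                )
                k = v / vy
                mx = mx + k * (y[j, 0] - mx)
                my = my + k * (y[j, 1] - my)
                v = (1.0 - k) * v
            else:
                w += lp_free[j]
            if j < m_tot - 1:
                vo = q_conf[j] if s == 1 else q_free[j]
                vp = v + vo
                w += (
                    -np.log(2.0 * np.pi * vp)
                    - 0.5
                    * ((C[j + 1, 0] - mx) ** 2 + (C[j + 1, 1] - my) ** 2)
                    / vp
                )
                k = v / vp
                mx = mx + k * (C[j + 1, 0] - mx)
                my = my + k * (C[j + 1, 1] - my)
                v = (1.0 - k) * v
            lw[s] = w
            mm[s, 0] = mx
            mm[s, 1] = my
            vv[s] = v if v > VAR_FLOOR else VAR_FLOOR
        wmax = lw[0] if lw[0] > lw[1] else lw[1]
        p1 = np.exp(lw[1] - wmax)
        p1 = p1 / (np.exp(lw[0] - wmax) + p1)
        s = 1 if u[j] < p1 else 0
        z[j] = s
        sd = np.sqrt(vv[s])
        C[j, 0] = mm[s, 0] + sd * normals[j, 0]
        C[j, 1] = mm[s, 1] + sd * normals[j, 1]


@njit(cache=True)
def window_flip_pass(
    z,
    C,
    y,
    r,
    log_jac,
    lp_free,
    q_conf,
    q_free,
    trans,
    prior_m,
    prior_v,
    window,
    offset,
    u,
    normals,
    mf,
    vf,
):
    """Metropolis nucleation/annihilation of whole confinement windows.

    For each window of ``window`` consecutive indices (starting at
    ``offset``) whose states are currently uniform, propose flipping all of
    them to the opposite state.  The center path is integrated out
    analytically over the window *and the adjoining free runs*, anchoring
    at the nearest confined centers outside (or the prior on C_0): free
    centers carry no observations, so far-away anchors simply contribute
    accumulated random-walk variance instead of vetoing the proposal.  The
    acceptance ratio is the exact marginal ratio; on acceptance the whole
    region's centers are redrawn from their conditional.  This is the
    sampler's nucleation move — it can seed a confinement event in the
    middle of a free stretch or dissolve a spurious one wholesale, which
    the blocked FFBS and single-site moves cannot do at a useful rate.

    ``u``: one uniform per window; ``normals``: one pair per index;
    ``mf``/``vf``: scratch buffers of shape (M, 2) and (M,).  Modifies z
    and C in place.  Returns (n_proposed, n_accepted).
    """
    m_tot = z.shape[0]
    n_prop = 0
    n_acc = 0
    w_idx = 0
    j0 = offset
    while j0 < m_tot:
        j1 = j0 + window
        if j1 > m_tot:
            j1 = m_tot
        length = j1 - j0
        # uniform-state windows only: the flip proposal is its own inverse
        s_cur = z[j0]
        uniform = True
        for i in range(j0, j1):
            if z[i] != s_cur:
                uniform = False
                break
        if not uniform:
            j0 += window
            w_idx += 1
            continue
        n_prop += 1
        s_new = 1 - s_cur
        # region of C to marginalize: from the nearest confined index on
        # the left (exclusive) to the nearest on the right (exclusive)
        a = j0 - 1
        while a >= 0 and z[a] == 0:
            a -= 1
        b = j1
        while b < m_tot and z[b] == 0:
            b += 1
        lw0 = 0.0
        lw1 = 0.0
        for variant in range(2):
            s = s_cur if variant == 0 else s_new
            w = 0.0
            if j0 > 0:
                w += np.log(trans[z[j0 - 1], s])
            w += (length - 1) * np.log(trans[s, s])
            if j1 < m_tot:
                w += np.log(trans[s, z[j1]])
            # forward filter from the left anchor across the region
            if a >= 0:
                mx = C[a, 0]
                my = C[a, 1]
                v = q_conf[a] if z[a] == 1 else q_free[a]
                start = a + 1
            else:
                mx = prior_m[0]
                my = prior_m[1]
                v = prior_v
                start = 0
            for i in range(start, b):
                inside = j0 <= i < j1
                zi = s if inside else 0
                if zi == 1:
                    vy = v + r[i]
                    w += (
                        log_jac[i]
                        - np.log(2.0 * np.pi * vy)
                        - 0.5
                        * ((y[i, 0] - mx) ** 2 + (y[i, 1] - my) ** 2)
                        / vy
                    )
                    k = v / vy
                    mx = mx + k * (y[i, 0] - mx)
                    my = my + k * (y[i, 1] - my)
                    v = (1.0 - k) * v
                else:
                    w += lp_free[i]
                if variant == 1:
                    mf[i, 0] = mx
                    mf[i, 1] = my
                    vf[i] = v if v > VAR_FLOOR else VAR_FLOOR
                if i < m_tot - 1:
                    v = v + (q_conf[i] if zi == 1 else q_free[i])
            # right anchor observed through the accumulated variance
            if b < m_tot:
                w += (
                    -np.log(2.0 * np.pi * v)
                    - 0.5
                    * ((C[b, 0] - mx) ** 2 + (C[b, 1] - my) ** 2)
                    / v
                )
            if variant == 0:
                lw0 = w
            else:
                lw1 = w
        if np.log(u[w_idx]) < lw1 - lw0:
            n_acc += 1
            for i in range(j0, j1):
                z[i] = s_new
            start = a + 1 if a >= 0 else 0
            for i in range(b - 1, start - 1, -1):
                mx = mf[i, 0]
                my = mf[i, 1]
                v = vf[i]
                if i < m_tot - 1:
                    inside = j0 <= i < j1
                    zi = s_new if inside else 0
                    qi = q_conf[i] if zi == 1 else q_free[i]
                    if qi < VAR_FLOOR:
                        qi = VAR_FLOOR
                    if i < b - 1 or b < m_tot:
                        # condition on C[i+1] (fresh draw or right anchor)
                        g = v / (v + qi)
                        mx = mx + g * (C[i + 1, 0] - mx)
                        my = my + g * (C[i + 1, 1] - my)
                        v = (1.0 - g) * v
                        if v < VAR_FLOOR:
                            v = VAR_FLOOR
                sd = np.sqrt(v)
                C[i, 0] = mx + sd * normals[i, 0]
                C[i, 1] = my + sd * normals[i, 1]
        j0 += window
        w_idx += 1
    return n_prop, n_acc


@njit(cache=True)
def kalman_ffbs(y, r, obs, q, m0, v0, normals):
    """Joint draw of a scalar random-walk state path given noisy observations.

    State: x_{i+1} = x_i + w_i, w_i ~ N(0, q[i]), i = 0..M-2.
    Observation at index i (where obs[i]): y[i] = x_i + e, e ~ N(0, r[i]).
    Prior: x_0 ~ N(m0, v0).

    Returns one exact sample of (x_0, ..., x_{M-1}).
    """
    m = q.shape[0] + 1
    mf = np.empty(m)
    vf = np.empty(m)
    mean = m0
    var = v0
    for i in range(m):
        if i > 0:
            var = var + q[i - 1]
        if obs[i]:
            ri = r[i] if r[i] > VAR_FLOOR else VAR_FLOOR
            k = var / (var + ri)
            mean = mean + k * (y[i] - mean)
            var = (1.0 - k) * var
        if var < VAR_FLOOR:
            var = VAR_FLOOR
        mf[i] = mean
        vf[i] = var
    x = np.empty(m)
    x[m - 1] = mf[m - 1] + np.sqrt(vf[m - 1]) * normals[m - 1]
    for i in range(m - 2, -1, -1):
        qi = q[i] if q[i] > VAR_FLOOR else VAR_FLOOR
        g = vf[i] / (vf[i] + qi)
        cmean = mf[i] + g * (x[i + 1] - mf[i])
        cvar = (1.0 - g) * vf[i]
        if cvar < VAR_FLOOR:
            cvar = VAR_FLOOR
        x[i] = cmean + np.sqrt(cvar) * normals[i]
    return x
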