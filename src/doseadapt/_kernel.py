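"""Numba kernel: blocked Gibbs sampler for the second-order NDLM.

Model (arm index l = 0..J-1, placebo at l = 0):

    y_i     = theta_{l(i)} + beta * yblc_i + nu_i,   nu_i ~ N(0, sig2)
    theta_l = theta_{l-1} + delta_{l-1} + omega_l,   omega_l ~ N(0, W*sig2)
    delta_l = delta_{l-1} + eps_l,                   eps_l   ~ N(0, W*sig2)

with a diffuse N(0, v0) prior on the pre-placebo state (theta_init,
delta_init) and on beta, U(w_lo, w_hi) on W, and a half-normal prior on
either the observational SD or variance.

The state block (theta_l, delta_l) is drawn jointly by forward filtering /
backward sampling; beta has a conjugate Gaussian conditional; sigma and W
are drawn by univariate slice sampling on the log scale (W within its
bounds).  All 2x2 matrix algebra is written out in scalars.

Per-iteration cost is O(J) after a one-off O(n) reduction to per-arm
sufficient statistics, so chain length — not sample size — drives runtime.
"""

import math

import numpy as np
from numba import njit

@njit(cache=True)
def _logp_log_s(ls, n_terms, ss_total, hn_scale, prior_on_sd):
    # density of log(sigma); ss_total = SS_obs + SS_w / W
    s = math.exp(ls)
    s2 = s * s
    lp = -n_terms * ls - ss_total / (2.0 * s2)
    if prior_on_sd:
        lp += -s2 / (2.0 * hn_scale * hn_scale)
    else:
        lp += -(s2 * s2) / (2.0 * hn_scale * hn_scale) + math.log(2.0 * s)
    return lp + ls  # Jacobian


@njit(cache=True)
def _logp_log_w(lw, J, ss_w_over_2s2):
    # density of log(W): likelihood (W*s2)^{-J} exp(-SS_w/(2 W s2)), flat prior
    return -(J - 1.0) * lw - ss_w_over_2s2 * math.exp(-lw)


@njit(cache=True)
def _slice_log_s(ls0, n_terms, ss_total, hn_scale, prior_on_sd):
    w = 0.5
    lp0 = _logp_log_s(ls0, n_terms, ss_total, hn_scale, prior_on_sd)
    logy = lp0 - np.random.exponential(1.0)
    u = np.random.random()
    left = ls0 - w * u
    right = left + w
    for _ in range(60):
        if _logp_log_s(left, n_terms, ss_total, hn_scale, prior_on_sd) <= logy:
            break
        left -= w
    for _ in range(60):
        if _logp_log_s(right, n_terms, ss_total, hn_scale, prior_on_sd) <= logy:
            break
        right += w
    for _ in range(200):
        x = left + np.random.random() * (right - left)
        if _logp_log_s(x, n_terms, ss_total, hn_scale, prior_on_sd) > logy:
            return x
        if x < ls0:
            left = x
        else:
            right = x
    return ls0


@njit(cache=True)
def _slice_log_w(lw0, J, ss_w_over_2s2, lw_lo, lw_hi):
    w = 1.0
    lp0 = _logp_log_w(lw0, J, ss_w_over_2s2)
    logy = lp0 - np.random.exponential(1.0)
    u = np.random.random()
    left = lw0 - w * u
    right = left + w
    for _ in range(60):
        if left <= lw_lo or _logp_log_w(left, J, ss_w_over_2s2) <= logy:
            break
        left -= w
    for _ in range(60):
        if right >= lw_hi or _logp_log_w(right, J, ss_w_over_2s2) <= logy:
            break
        right += w
    left = max(left, lw_lo)
    right = min(right, lw_hi)
    for _ in range(200):
        x = left + np.random.random() * (right - left)
        if _logp_log_w(x, J, ss_w_over_2s2) > logy:
            return x
        if x < lw0:
            left = x
        else:
            right = x
    return lw0


@njit(cache=True)
def gibbs_ndlm(
    n_arm,        # (J,) observations per arm
    sum_y,        # (J,) per-arm sums of y
    sum_x,        # (J,) per-arm sums of centred baseline
    sum_y2,       # (J,)
    sum_x2,       # (J,)
    sum_xy,       # (J,)
    n_keep,
    n_burn,
    v0,           # prior variance for theta_init, delta_init, beta (10000)
    w_lo,
    w_hi,
    hn_scale,
    prior_on_sd,
    fix_sigma,    # <= 0 means "sample"; otherwise sigma fixed at this SD
    fix_w,        # <= 0 means "sample"
    fix_beta_flag,
    beta_fixed,
    seed,
):
    """Run the Gibbs sampler; returns (theta, delta, beta, sig2, W) draws."""
    np.random.seed(seed)
    J = n_arm.shape[0]
    n_tot = 0.0
    sxx = 0.0
    for l in range(J):
        n_tot += n_arm[l]
        sxx += sum_x2[l]

    theta_out = np.empty((n_keep, J))
    delta_out = np.empty((n_keep, J))
    beta_out = np.empty(n_keep)
    sig2_out = np.empty(n_keep)
    w_out = np.empty(n_keep)

    # initial values
    beta = beta_fixed if fix_beta_flag else 0.0
    ybar_all = 0.0
    for l in range(J):
        ybar_all += sum_y[l]
    ybar_all /= max(n_tot, 1.0)
    var_y = 0.0
    for l in range(J):
        var_y += sum_y2[l]
    var_y = var_y / max(n_tot, 1.0) - ybar_all * ybar_all
    s = math.sqrt(var_y) if var_y > 1e-12 else 1.0
    if fix_sigma > 0.0:
        s = fix_sigma
    W = 1.0
    if fix_w > 0.0:
        W = fix_w
    if W < w_lo:
        W = w_lo
    if W > w_hi:
        W = w_hi

    theta = np.zeros(J)
    delta = np.zeros(J)
    # filtered moments for states k = 0..J (k=0 is the pre-placebo prior state)
    fm1 = np.empty(J + 1)
    fm2 = np.empty(J + 1)
    fc11 = np.empty(J + 1)
    fc12 = np.empty(J + 1)
    fc22 = np.empty(J + 1)
    pa1 = np.empty(J + 1)   # predicted mean / cov at k (valid for k >= 1)
    pa2 = np.empty(J + 1)
    pr11 = np.empty(J + 1)
    pr12 = np.empty(J + 1)
    pr22 = np.empty(J + 1)
    x1 = np.empty(J + 1)
    x2 = np.empty(J + 1)

    lw_lo = math.log(w_lo)
    lw_hi = math.log(w_hi)

    for it in range(n_burn + n_keep):
        s2 = s * s
        q = W * s2

        # ---- forward filter ----
        fm1[0] = 0.0
        fm2[0] = 0.0
        fc11[0] = v0
        fc12[0] = 0.0
        fc22[0] = v0
        for k in range(1, J + 1):
            l = k - 1
            a1 = fm1[k - 1] + fm2[k - 1]
            a2 = fm2[k - 1]
            r11 = fc11[k - 1] + 2.0 * fc12[k - 1] + fc22[k - 1] + q
            r12 = fc12[k - 1] + fc22[k - 1]
            r22 = fc22[k - 1] + q
            pa1[k] = a1
            pa2[k] = a2
            pr11[k] = r11
            pr12[k] = r12
            pr22[k] = r22
            if n_arm[l] > 0:
                vobs = s2 / n_arm[l]
                zbar = (sum_y[l] - beta * sum_x[l]) / n_arm[l]
                qq = r11 + vobs
                k1 = r11 / qq
                k2 = r12 / qq
                e = zbar - a1
                fm1[k] = a1 + k1 * e
                fm2[k] = a2 + k2 * e
                fc11[k] = r11 - k1 * r11
                fc12[k] = r12 - k1 * r12
                fc22[k] = r22 - k2 * r12
            else:
                fm1[k] = a1
                fm2[k] = a2
                fc11[k] = r11
                fc12[k] = r12
                fc22[k] = r22

        # ---- backward sample ----
        c11 = fc11[J]
        c12 = fc12[J]
        c22 = fc22[J]
        l11 = math.sqrt(max(c11, 1e-300))
        l21 = c12 / l11
        l22 = math.sqrt(max(c22 - l21 * l21, 0.0))
        z1 = np.random.normal()
        z2 = np.random.normal()
        x1[J] = fm1[J] + l11 * z1
        x2[J] = fm2[J] + l21 * z1 + l22 * z2
        for k in range(J - 1, -1, -1):
            c11 = fc11[k]
            c12 = fc12[k]
            c22 = fc22[k]
            r11 = pr11[k + 1]
            r12 = pr12[k + 1]
            r22 = pr22[k + 1]
            det = r11 * r22 - r12 * r12
            if det < 1e-300:
                det = 1e-300
            i11 = r22 / det
            i12 = -r12 / det
            i22 = r11 / det
            # C G' with G' = [[1,0],[1,1]]
            cg11 = c11 + c12
            cg12 = c12
            cg21 = c12 + c22
            cg22 = c22
            b11 = cg11 * i11 + cg12 * i12
            b12 = cg11 * i12 + cg12 * i22
            b21 = cg21 * i11 + cg22 * i12
            b22 = cg21 * i12 + cg22 * i22
            e1 = x1[k + 1] - pa1[k + 1]
            e2 = x2[k + 1] - pa2[k + 1]
            h1 = fm1[k] + b11 * e1 + b12 * e2
            h2 = fm2[k] + b21 * e1 + b22 * e2
            # H = C - B R B'
            br11 = b11 * r11 + b12 * r12
            br12 = b11 * r12 + b12 * r22
            br21 = b21 * r11 + b22 * r12
            br22 = b21 * r12 + b22 * r22
            h11 = c11 - (br11 * b11 + br12 * b12)
            h12 = c12 - (br11 * b21 + br12 * b22)
            h22 = c22 - (br21 * b21 + br22 * b22)
            l11 = math.sqrt(max(h11, 0.0))
            l21 = h12 / l11 if l11 > 0.0 else 0.0
            l22 = math.sqrt(max(h22 - l21 * l21, 0.0))
            z1 = np.random.normal()
            z2 = np.random.normal()
            x1[k] = h1 + l11 * z1
            x2[k] = h2 + l21 * z1 + l22 * z2

        for l in range(J):
            theta[l] = x1[l + 1]
            delta[l] = x2[l + 1]

        # ---- beta (conjugate) ----
        if not fix_beta_flag:
            sxy = 0.0
            for l in range(J):
                sxy += sum_xy[l] - theta[l] * sum_x[l]
            prec = sxx / s2 + 1.0 / v0
            mu = (sxy / s2) / prec
            beta = mu + np.random.normal() / math.sqrt(prec)

        # ---- sufficient sums for variance updates ----
        ss_obs = 0.0
        for l in range(J):
            if n_arm[l] > 0:
                # sum over i in arm l of (y - theta_l - beta*x)^2
                ss_obs += (
                    sum_y2[l]
                    - 2.0 * beta * sum_xy[l]
                    + beta * beta * sum_x2[l]
                    - 2.0 * theta[l] * (sum_y[l] - beta * sum_x[l])
                    + n_arm[l] * theta[l] * theta[l]
                )
        ss_w = 0.0
        for k in range(1, J + 1):
            om = x1[k] - x1[k - 1] - x2[k - 1]
            ep = x2[k] - x2[k - 1]
            ss_w += om * om + ep * ep

        if fix_sigma <= 0.0:
            n_terms = n_tot + 2.0 * J
            ls = _slice_log_s(
                math.log(s), n_terms, ss_obs + ss_w / W, hn_scale, prior_on_sd
            )
            s = math.exp(ls)
        if fix_w <= 0.0:
            lw = _slice_log_w(
                math.log(W), float(J), ss_w / (2.0 * s * s), lw_lo, lw_hi
            )
            W = math.exp(lw)

        if it >= n_burn:
            idx = it - n_burn
            for l in range(J):
                theta_out[idx, l] = theta[l]
                delta_out[idx, l] = delta[l]
            beta_out[idx] = beta
            sig2_out[idx] = s * s
            w_out[idx] = W

    return theta_out, delta_out, beta_out, sig2_out, w_out
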