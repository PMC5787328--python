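"""Compiled single-site Gibbs sweep for the directional-dominance model.

All conditional-moment formulas live here as tiny njit functions so the
fast chain loop and the Python-level ``update_*`` operations in
:mod:`dirdom.gibbs_sampler` share one implementation.  The chain kernel
maintains the residual vector incrementally and re-derives it from
scratch at checkpoints; the worst checkpoint discrepancy is returned so
callers can assert residual consistency.

Scalar trace column order (must match ``gibbs_sampler.SCALAR_COLS``):
mu, b, lam, sig_r2, sig_c2, sig_a2, sig_d2, sig_e2, t2, t3, t4,
V_A, V_D, I_D.
"""

import numpy as np
from numba import njit

N_SCALARS = 14

STATUS_OK = 0
STATUS_NONFINITE = 1


@njit(cache=True)
def loc_moments(wtw, wty, sigma_e2, prior_prec):
    """Conditional (mean, var) of a Gaussian location effect.

    var = sigma_e2 / (w'w + sigma_e2 * prior_prec);
    mean = w'(e + w*old) / (w'w + sigma_e2 * prior_prec), with
    prior_prec = 0 for flat-prior effects.
    """
    denom = wtw + sigma_e2 * prior_prec
    return wty / denom, sigma_e2 / denom


@njit(cache=True)
def dominance_moments(ktk, kty, sigma_e2, sigma_d2, lam_u):
    """Conditional (mean, var) of a dominance effect with prior N(lam*u, sigma_d2)."""
    v = 1.0 / (ktk / sigma_e2 + 1.0 / sigma_d2)
    return v * (kty / sigma_e2 + lam_u / sigma_d2), v


@njit(cache=True)
def auxiliary_moments(d_j, lam, sigma_d2):
    """Conditional (mean, var) of the half-normal auxiliary before truncation."""
    v = 1.0 / (1.0 + lam * lam / sigma_d2)
    return v * lam * d_j / sigma_d2, v


@njit(cache=True)
def lambda_moments(sum_ud, sum_uu, sigma_d2):
    """Conditional (mean, var) of the asymmetry parameter under a flat prior."""
    return sum_ud / sum_uu, sigma_d2 / sum_uu


@njit(cache=True)
def sample_trunc_nonneg(mean, var):
    """Draw from N(mean, var) truncated to [0, inf).

    Naive accept-reject near/below the mode; Robert (1995)
    exponential-rejection once the truncation point is deep in the
    upper tail, which stays efficient and finite for mean/sd << 0.
    """
    sd = np.sqrt(var)
    alpha = -mean / sd
    if alpha < 0.7:
        while True:
            z = np.random.normal()
            if z >= alpha:
                return mean + sd * z
    a_star = 0.5 * (alpha + np.sqrt(alpha * alpha + 4.0))
    while True:
        z = alpha - np.log(np.random.random()) / a_star
        diff = z - a_star
        if np.random.random() <= np.exp(-0.5 * diff * diff):
            return mean + sd * z


@njit(cache=True)
def sample_scaled_inv_chi2(sum_sq, n_terms, nu, s2):
    """(sum_sq + nu*S2) / chi2_{n_terms + nu} draw."""
    df = n_terms + nu
    chi2 = 2.0 * np.random.gamma(0.5 * df, 1.0)
    return (sum_sq + nu * s2) / chi2


@njit(cache=True)
def _recompute_residual(y, mu, b, h, tvec, par, r, grp, c, sow, Z, K, a, d, out):
    n = y.size
    for i in range(n):
        out[i] = y[i] - mu - b * h[i] - tvec[par[i]] - r[grp[i]] - c[sow[i]]
    m = Z.shape[0]
    for j in range(m):
        aj = a[j]
        dj = d[j]
        for i in range(n):
            out[i] -= Z[j, i] * aj + K[j, i] * dj


@njit(cache=True)
def _update_group_effects(e, idx, coef, cnt, sigma_e2, prior_prec):
    """One pass of conditional draws for a whole indexed random-effect family."""
    n_lev = coef.size
    sums = np.zeros(n_lev)
    for i in range(e.size):
        sums[idx[i]] += e[i]
    delta = np.zeros(n_lev)
    for g in range(n_lev):
        if cnt[g] == 0:
            # level unobserved: draw from the prior (proper because prior_prec > 0)
            new = np.random.normal() / np.sqrt(prior_prec)
            delta[g] = coef[g] - new
            coef[g] = new
            continue
        wty = sums[g] + cnt[g] * coef[g]
        mean, var = loc_moments(cnt[g], wty, sigma_e2, prior_prec)
        new = mean + np.sqrt(var) * np.random.normal()
        delta[g] = coef[g] - new
        coef[g] = new
    for i in range(e.size):
        e[i] += delta[idx[i]]


@njit(cache=True)
def run_chain(
    seed,
    n_iter,
    burn_in,
    thin,
    y,
    sow,
    grp,
    par,
    h,
    Z,
    K,
    zsq,
    ksq,
    v_dir,
    two_pq,
    one_minus_2p,
    n_ind,
    n_grp,
    include_b,
    include_lam,
    clamp_lam,
    fixed_var,
    nu,
    s2_r,
    s2_c,
    s2_a,
    s2_d,
    s2_e,
    init_var,
    effects_stride,
    check_every,
    scal,
    fitted,
    sum_alpha,
    sum_d,
    a_store,
    d_store,
):
    np.random.seed(seed)
    n = y.size
    m = Z.shape[0]

    mu = y.mean()
    b = 0.0
    lam = 0.0
    tvec = np.zeros(4)
    r = np.zeros(n_grp)
    c = np.zeros(n_ind)
    a = np.zeros(m)
    d = np.zeros(m)
    if include_lam:
        u = np.full(m, np.sqrt(2.0 / np.pi))
    else:
        u = np.zeros(m)
    sig_r2, sig_c2, sig_a2, sig_d2, sig_e2 = (
        init_var[0],
        init_var[1],
        init_var[2],
        init_var[3],
        init_var[4],
    )

    e = y - mu
    cnt_grp = np.zeros(n_grp, dtype=np.int64)
    cnt_sow = np.zeros(n_ind, dtype=np.int64)
    cnt_par = np.zeros(4, dtype=np.int64)
    hth = 0.0
    mean_two_pq = two_pq.mean()
    for i in range(n):
        cnt_grp[grp[i]] += 1
        cnt_sow[sow[i]] += 1
        cnt_par[par[i]] += 1
        hth += h[i] * h[i]

    vtv = 0.0
    for i in range(n):
        vtv += v_dir[i] * v_dir[i]
    mu_comp = 1.0 - mean_two_pq

    scratch = np.empty(n)
    max_resid_err = 0.0
    n_kept = 0
    n_stored = 0

    for it in range(n_iter):
        # --- general mean (flat prior) ---
        s = 0.0
        for i in range(n):
            s += e[i]
        mean, var = loc_moments(float(n), s + n * mu, sig_e2, 0.0)
        new = mean + np.sqrt(var) * np.random.normal()
        dmu = mu - new
        mu = new
        for i in range(n):
            e[i] += dmu

        # --- homozygosity regression b (flat prior) ---
        if include_b and hth > 0.0:
            s = 0.0
            for i in range(n):
                s += h[i] * e[i]
            mean, var = loc_moments(hth, s + hth * b, sig_e2, 0.0)
            new = mean + np.sqrt(var) * np.random.normal()
            db = b - new
            b = new
            for i in range(n):
                e[i] += db * h[i]

        # --- parity effects, level 1 constrained to 0 (flat prior) ---
        sums = np.zeros(4)
        for i in range(n):
            sums[par[i]] += e[i]
        dpar = np.zeros(4)
        for l in range(1, 4):
            if cnt_par[l] == 0:
                continue
            wty = sums[l] + cnt_par[l] * tvec[l]
            mean, var = loc_moments(float(cnt_par[l]), wty, sig_e2, 0.0)
            new = mean + np.sqrt(var) * np.random.normal()
            dpar[l] = tvec[l] - new
            tvec[l] = new
        for i in range(n):
            e[i] += dpar[par[i]]

        # --- contemporary-group and permanent-environment effects ---
        _update_group_effects(e, grp, r, cnt_grp, sig_e2, 1.0 / sig_r2)
        _update_group_effects(e, sow, c, cnt_sow, sig_e2, 1.0 / sig_c2)

        # --- SNP additive effects ---
        prec_a = 1.0 / sig_a2
        for j in range(m):
            old = a[j]
            s = 0.0
            for i in range(n):
                s += Z[j, i] * e[i]
            mean, var = loc_moments(zsq[j], s + zsq[j] * old, sig_e2, prec_a)
            new = mean + np.sqrt(var) * np.random.normal()
            da = old - new
            a[j] = new
            if da != 0.0:
                for i in range(n):
                    e[i] += Z[j, i] * da

        # --- SNP dominance effects ---
        for j in range(m):
            old = d[j]
            s = 0.0
            for i in range(n):
                s += K[j, i] * e[i]
            mean, var = dominance_moments(
                ksq[j], s + ksq[j] * old, sig_e2, sig_d2, lam * u[j]
            )
            new = mean + np.sqrt(var) * np.random.normal()
            dd = old - new
            d[j] = new
            if dd != 0.0:
                for i in range(n):
                    e[i] += K[j, i] * dd

        # --- recentering move along the b / mean-dominance ridge ---
        # Average homozygosity is one minus the average heterozygote fraction,
        # so b and the mean of d are nearly collinear; single-site updates mix
        # across that ridge extremely slowly.  Sample the exact Gaussian
        # conditional of the shift delta that moves b by delta and every d_j
        # by delta/m (mu compensates), a linear reparameterization whose
        # likelihood term involves only the small residual direction v.
        if include_b and m > 0:
            s_e = 0.0
            for i in range(n):
                s_e += v_dir[i] * e[i]
            s_dev = 0.0
            for j in range(m):
                s_dev += d[j] - lam * u[j]
            prec = vtv / sig_e2 + 1.0 / (m * sig_d2)
            mean = (s_e / sig_e2 - s_dev / (m * sig_d2)) / prec
            delta = mean + np.random.normal() / np.sqrt(prec)
            b += delta
            mu -= delta * mu_comp
            inv_m = delta / m
            for j in range(m):
                d[j] += inv_m
            for i in range(n):
                e[i] -= delta * v_dir[i]

        # --- auxiliary half-normal variables and asymmetry parameter ---
        if include_lam:
            for j in range(m):
                mean, var = auxiliary_moments(d[j], lam, sig_d2)
                u[j] = sample_trunc_nonneg(mean, var)
            sum_ud = 0.0
            sum_uu = 0.0
            for j in range(m):
                sum_ud += u[j] * d[j]
                sum_uu += u[j] * u[j]
            mean, var = lambda_moments(sum_ud, sum_uu, sig_d2)
            lam = mean + np.sqrt(var) * np.random.normal()
            if clamp_lam:
                # nesting check: keep the auxiliary machinery active but pin
                # the asymmetry at zero; must reproduce the symmetric model
                lam = 0.0

        # --- variance components (scaled inverse chi-square conditionals) ---
        if not fixed_var:
            ss = 0.0
            for g in range(n_grp):
                ss += r[g] * r[g]
            sig_r2 = sample_scaled_inv_chi2(ss, n_grp, nu, s2_r)
            ss = 0.0
            for k in range(n_ind):
                ss += c[k] * c[k]
            sig_c2 = sample_scaled_inv_chi2(ss, n_ind, nu, s2_c)
            ss = 0.0
            for j in range(m):
                ss += a[j] * a[j]
            sig_a2 = sample_scaled_inv_chi2(ss, m, nu, s2_a)
            ss = 0.0
            for j in range(m):
                dev = d[j] - lam * u[j]
                ss += dev * dev
            sig_d2 = sample_scaled_inv_chi2(ss, m, nu, s2_d)
            ss = 0.0
            for i in range(n):
                ss += e[i] * e[i]
            sig_e2 = sample_scaled_inv_chi2(ss, n, nu, s2_e)

        # --- second recentering pass (variances have changed since the first) ---
        if include_b and m > 0 and not fixed_var:
            s_e = 0.0
            for i in range(n):
                s_e += v_dir[i] * e[i]
            s_dev = 0.0
            for j in range(m):
                s_dev += d[j] - lam * u[j]
            prec = vtv / sig_e2 + 1.0 / (m * sig_d2)
            mean = (s_e / sig_e2 - s_dev / (m * sig_d2)) / prec
            delta = mean + np.random.normal() / np.sqrt(prec)
            b += delta
            mu -= delta * mu_comp
            inv_m = delta / m
            for j in range(m):
                d[j] += inv_m
            for i in range(n):
                e[i] -= delta * v_dir[i]

        # --- residual-consistency checkpoint ---
        if check_every > 0 and (it + 1) % check_every == 0:
            _recompute_residual(y, mu, b, h, tvec, par, r, grp, c, sow, Z, K, a, d, scratch)
            err = 0.0
            for i in range(n):
                diff = abs(scratch[i] - e[i])
                if diff > err:
                    err = diff
            if err > max_resid_err:
                max_resid_err = err
            for i in range(n):
                e[i] = scratch[i]

        if not (np.isfinite(mu) and np.isfinite(sig_e2) and np.isfinite(lam)):
            return STATUS_NONFINITE, it, max_resid_err, n_kept, n_stored

        # --- retain draw ---
        if it >= burn_in and (it - burn_in) % thin == 0:
            v_a = 0.0
            v_d = 0.0
            s_pqd = 0.0
            for j in range(m):
                alpha_j = a[j] + one_minus_2p[j] * d[j]
                v_a += two_pq[j] * alpha_j * alpha_j
                tmp = two_pq[j] * d[j]
                v_d += tmp * tmp
                s_pqd += tmp
                sum_alpha[j] += alpha_j
                sum_d[j] += d[j]
            i_d = 0.01 * (b * mean_two_pq - s_pqd)

            scal[n_kept, 0] = mu
            scal[n_kept, 1] = b
            scal[n_kept, 2] = lam
            scal[n_kept, 3] = sig_r2
            scal[n_kept, 4] = sig_c2
            scal[n_kept, 5] = sig_a2
            scal[n_kept, 6] = sig_d2
            scal[n_kept, 7] = sig_e2
            scal[n_kept, 8] = tvec[1]
            scal[n_kept, 9] = tvec[2]
            scal[n_kept, 10] = tvec[3]
            scal[n_kept, 11] = v_a
            scal[n_kept, 12] = v_d
            scal[n_kept, 13] = i_d
            for i in range(n):
                fitted[n_kept, i] = y[i] - e[i]
            if effects_stride > 0 and n_kept % effects_stride == 0:
                for j in range(m):
                    a_store[n_stored, j] = a[j]
                    d_store[n_stored, j] = d[j]
                n_stored += 1
            n_kept += 1

    return STATUS_OK, n_iter, max_resid_err, n_kept, n_stored
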