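"""Compiled kernel for the group-level marginal posterior.

Scalar re-implementation of the adaptive-quadrature participant integrals
in :class:`vantage.circular.GroupMarginalPosterior`, JIT-compiled with
numba.  The numpy implementation remains the reference; a unit test pins
the two paths together.  Special functions are implemented to double
precision: log I0 via its power series (k < 18) and asymptotic expansion
(k >= 18), log Phi via math.erfc with an asymptotic branch for far
negative arguments.
"""

from __future__ import annotations

import math

import numba
import numpy as np

_LOG2PI = math.log(2.0 * math.pi)
_SQRT2 = math.sqrt(2.0)


@numba.njit(cache=True, fastmath=False)
def _log_i0(k):
    if k < 18.0:
        term = 1.0
        total = 1.0
        q = 0.25 * k * k
        for m in range(1, 60):
            term *= q / (m * m)
            total += term
            if term < 1e-18 * total:
                break
        return math.log(total)
    # asymptotic: I0(k) ~ e^k / sqrt(2 pi k) * (1 + 1/8k + 9/128k^2 + ...)
    x = 1.0 / (8.0 * k)
    s = 1.0 + x * (1.0 + x * (4.5 + x * (37.5 + x * (459.375
        + x * (7441.875 + x * (150077.8125 + x * 3623307.1875))))))
    return k - 0.5 * math.log(2.0 * math.pi * k) + math.log(s)


@numba.njit(cache=True, fastmath=False)
def _log_ndtr(x):
    if x > -30.0:
        return math.log(0.5 * math.erfc(-x / _SQRT2))
    # asymptotic tail: Phi(x) ~ phi(x)/|x| * (1 - 1/x^2 + 3/x^4)
    x2 = x * x
    return (-0.5 * x2 - 0.5 * _LOG2PI - math.log(-x)
            + math.log(1.0 - 1.0 / x2 + 3.0 / (x2 * x2)))


@numba.njit(cache=True, fastmath=False)
def _mu_laplace(kA, mub, am, sm):
    """Newton mode and curvature of kA cos(mu-mub) + log N(mu; am, sm)."""
    ism2 = 1.0 / (sm * sm)
    mu = (kA * mub + am * ism2) / (kA + ism2)
    for _ in range(3):
        g1 = -kA * math.sin(mu - mub) - (mu - am) * ism2
        p = max(kA * math.cos(mu - mub), 0.1 * kA) + ism2
        step = g1 / p
        if step > 1.0:
            step = 1.0
        elif step < -1.0:
            step = -1.0
        mu += step
    p = max(kA * math.cos(mu - mub) + ism2, 0.5 * ism2)
    return mu, p


@numba.njit(cache=True, fastmath=False)
def _logg_laplace(u, A, n, mub, am, ak, sm, sk):
    k = math.exp(u)
    kA = k * A
    mu0, p = _mu_laplace(kA, mub, am, sm)
    zc = (mu0 - am) / sm
    logJ = (kA * math.cos(mu0 - mub) - 0.5 * zc * zc - math.log(sm)
            - 0.5 * _LOG2PI + 0.5 * math.log(2.0 * math.pi / p))
    zk = (k - ak) / sk
    ltr = (-0.5 * zk * zk - math.log(sk) - 0.5 * _LOG2PI
           - _log_ndtr(ak / sk))
    return logJ - n * (_LOG2PI + _log_i0(k)) + ltr + u


@numba.njit(cache=True, fastmath=False)
def _logg_exact(u, A, n, mub, am, ak, sm, sk, t_mu, lw_mu, infl):
    k = math.exp(u)
    kA = k * A
    mu0, p = _mu_laplace(kA, mub, am, sm)
    w = infl / math.sqrt(p)
    lw = math.log(_SQRT2 * w)
    mmax = -1e300
    nq = t_mu.shape[0]
    vals = np.empty(nq)
    for q in range(nq):
        mu = mu0 + _SQRT2 * w * t_mu[q]
        zc = (mu - am) / sm
        v = (kA * math.cos(mu - mub) - 0.5 * zc * zc - math.log(sm)
             - 0.5 * _LOG2PI + lw_mu[q] + lw)
        vals[q] = v
        if v > mmax:
            mmax = v
    s = 0.0
    for q in range(nq):
        s += math.exp(vals[q] - mmax)
    logJ = mmax + math.log(s)
    zk = (k - ak) / sk
    ltr = (-0.5 * zk * zk - math.log(sk) - 0.5 * _LOG2PI
           - _log_ndtr(ak / sk))
    return logJ - n * (_LOG2PI + _log_i0(k)) + ltr + u


@numba.njit(cache=True, fastmath=False)
def marginal_chunk(A, mub, nvec, am2, ak2, sm1, sk1, ugrid,
                   t_mu, lw_mu, t_k, lw_k, infl):
    """Sum over participants of log m_i for each group point in the chunk."""
    B, P = am2.shape
    NU = ugrid.shape[0]
    NK = t_k.shape[0]
    du = ugrid[1] - ugrid[0]
    out = np.zeros(B)
    psi = np.empty(NU)
    vals = np.empty(NK)
    for b in range(B):
        sm = sm1[b]
        sk = sk1[b]
        acc = 0.0
        for i in range(P):
            Ai = A[i]
            mb = mub[i]
            ni = nvec[i]
            am = am2[b, i]
            ak = ak2[b, i]
            # stage 1: coarse mode search (Laplace inner)
            bj = 1
            best = -1e300
            for j in range(NU):
                psi[j] = _logg_laplace(ugrid[j], Ai, ni, mb, am, ak, sm, sk)
                if psi[j] > best:
                    best = psi[j]
                    bj = j
            if bj < 1:
                bj = 1
            elif bj > NU - 2:
                bj = NU - 2
            fm, f0, fp = psi[bj - 1], psi[bj], psi[bj + 1]
            denom = min(fm + fp - 2.0 * f0, -1e-12)
            ustar = ugrid[bj] + 0.5 * (fm - fp) / denom * du
            sd = math.sqrt(-du * du / denom)
            # stage 2: local parabola refinement
            delta = min(max(sd, 0.02), du)
            fm = _logg_laplace(ustar - delta, Ai, ni, mb, am, ak, sm, sk)
            f0 = _logg_laplace(ustar, Ai, ni, mb, am, ak, sm, sk)
            fp = _logg_laplace(ustar + delta, Ai, ni, mb, am, ak, sm, sk)
            denom = min(fm + fp - 2.0 * f0, -1e-12)
            ustar += 0.5 * (fm - fp) / denom * delta
            sd = min(max(math.sqrt(-delta * delta / denom), 1e-3), 4.0)
            # stage 3: adaptive GH with the exact integrand
            w = infl * sd
            lw = math.log(_SQRT2 * w)
            mmax = -1e300
            for q in range(NK):
                u = ustar + _SQRT2 * w * t_k[q]
                v = _logg_exact(u, Ai, ni, mb, am, ak, sm, sk,
                                t_mu, lw_mu, infl) + lw_k[q] + lw
                vals[q] = v
                if v > mmax:
                    mmax = v
            s = 0.0
            for q in range(NK):
                s += math.exp(vals[q] - mmax)
            acc += mmax + math.log(s)
        out[b] = acc
    return out


# ---------------------------------------------------------------------------
# MCMC sampler kernel


@numba.njit(cache=True, fastmath=False)
def _loglik_i(mu, lk, Ci, Si, ni):
    kappa = math.exp(lk)
    R = Ci * math.cos(mu) + Si * math.sin(mu)
    return kappa * R - ni * (_LOG2PI + _log_i0(kappa))


@numba.njit(cache=True, fastmath=False)
def _hier_i(mu, lk, am, ak, sm, sk):
    kappa = math.exp(lk)
    zm = (mu - am) / sm
    zk = (kappa - ak) / sk
    return (-0.5 * zm * zm - math.log(sm)
            - 0.5 * zk * zk - math.log(sk) - _LOG2PI
            - _log_ndtr(ak / sk) + lk)


@numba.njit(cache=True, fastmath=False)
def _delta_lp(x, scale, df):
    if df <= 0.0:
        z = x / scale
        return -0.5 * z * z - math.log(scale) - 0.5 * _LOG2PI
    c = (math.lgamma(0.5 * (df + 1.0)) - math.lgamma(0.5 * df)
         - 0.5 * math.log(df * math.pi) - math.log(scale))
    z = x / scale
    return c - 0.5 * (df + 1.0) * math.log1p(z * z / df)


@numba.njit(cache=True, fastmath=False)
def _group_prior_nb(grow, G, amu_s, ak_s, d_s, d_df, sm_s, sk_s):
    if G == 8:
        amu = grow[0]; lak = grow[3]; lsm = grow[6]; lsk = grow[7]
    else:
        amu = grow[0]; lak = grow[1]; lsm = grow[2]; lsk = grow[3]
    ak = math.exp(lak); sm = math.exp(lsm); sk = math.exp(lsk)
    log2 = 0.6931471805599453
    tot = -0.5 * (amu / amu_s) ** 2 - math.log(amu_s) - 0.5 * _LOG2PI
    tot += (-0.5 * (ak / ak_s) ** 2 - math.log(ak_s) - 0.5 * _LOG2PI
            + log2 + lak)
    tot += (-0.5 * (sm / sm_s) ** 2 - math.log(sm_s) - 0.5 * _LOG2PI
            + log2 + lsm)
    tot += (-0.5 * (sk / sk_s) ** 2 - math.log(sk_s) - 0.5 * _LOG2PI
            + log2 + lsk)
    if G == 8:
        tot += _delta_lp(grow[1], d_s, d_df) + _delta_lp(grow[2], d_s, d_df)
        tot += _delta_lp(grow[4], d_s, d_df) + _delta_lp(grow[5], d_s, d_df)
    return tot


@numba.njit(cache=True, fastmath=False)
def _a_of(grow, G, c):
    """Condition-specific group means (am, ak) from the unconstrained row."""
    if G == 8:
        am = grow[0]
        ak = math.exp(grow[3])
        if c == 1:
            am += grow[1]; ak += grow[4]
        elif c == 2:
            am += grow[2]; ak += grow[5]
        return am, ak
    return grow[0], math.exp(grow[1])


@numba.njit(cache=True, fastmath=False)
def run_mcmc(seed, C, G, warmup, iters, cond, Cc, Ss, nvec,
             amu_s, ak_s, d_s, d_df, sm_s, sk_s, z0):
    """Adaptive Metropolis-within-Gibbs over the unconstrained hierarchy.

    Moves per iteration and chain: a joint (mu_i, log kappa_i) proposal for
    every participant, scalar proposals for each group parameter, and
    hierarchical translation/scale moves that shift or rescale a group
    location together with its participants' parameters.  Proposal scales
    adapt toward standard targets during warmup only.
    """
    np.random.seed(seed)
    P = Cc.shape[0]
    dim = G + 2 * P
    g = z0[:, :G].copy()
    mu = z0[:, G:G + P].copy()
    lk = z0[:, G + P:].copy()
    s_part = np.full((C, P), 0.5)
    s_grp = np.full((C, G), 0.2)
    M = 8 if G == 8 else 4
    s_mov = np.full((C, M), 0.2)
    draws = np.empty((C, iters, dim))
    mu_t = np.empty(P)
    lk_t = np.empty(P)

    for it in range(warmup + iters):
        adapting = it < warmup
        eta = min(0.25, 2.0 / math.sqrt(it + 10.0)) if adapting else 0.0
        for ch in range(C):
            grow = g[ch]
            sm = math.exp(grow[G - 2])
            sk = math.exp(grow[G - 1])

            # 1. participant block
            for i in range(P):
                am, ak = _a_of(grow, G, cond[i])
                cur = (_loglik_i(mu[ch, i], lk[ch, i], Cc[i], Ss[i], nvec[i])
                       + _hier_i(mu[ch, i], lk[ch, i], am, ak, sm, sk))
                mup = mu[ch, i] + s_part[ch, i] * np.random.normal()
                lkp = lk[ch, i] + s_part[ch, i] * np.random.normal()
                prop = (_loglik_i(mup, lkp, Cc[i], Ss[i], nvec[i])
                        + _hier_i(mup, lkp, am, ak, sm, sk))
                acc = 0.0
                if math.log(np.random.random()) < prop - cur:
                    mu[ch, i] = mup
                    lk[ch, i] = lkp
                    acc = 1.0
                if adapting:
                    s_part[ch, i] *= math.exp(eta * (acc - 0.35))

            # 2. group scalar updates
            hsum = 0.0
            for i in range(P):
                am, ak = _a_of(grow, G, cond[i])
                hsum += _hier_i(mu[ch, i], lk[ch, i], am, ak, sm, sk)
            gp = _group_prior_nb(grow, G, amu_s, ak_s, d_s, d_df, sm_s, sk_s)
            for j in range(G):
                old = grow[j]
                grow[j] = old + s_grp[ch, j] * np.random.normal()
                if grow[j] < -40.0 or grow[j] > 40.0:   # numerical guard
                    grow[j] = old
                    if adapting:
                        s_grp[ch, j] *= math.exp(-eta * 0.44)
                    continue
                sm_n = math.exp(grow[G - 2])
                sk_n = math.exp(grow[G - 1])
                hsum_n = 0.0
                for i in range(P):
                    am, ak = _a_of(grow, G, cond[i])
                    hsum_n += _hier_i(mu[ch, i], lk[ch, i], am, ak, sm_n, sk_n)
                gp_n = _group_prior_nb(grow, G, amu_s, ak_s, d_s, d_df,
                                       sm_s, sk_s)
                acc = 0.0
                if math.log(np.random.random()) < (gp_n + hsum_n) - (gp + hsum):
                    gp = gp_n
                    hsum = hsum_n
                    acc = 1.0
                else:
                    grow[j] = old
                if adapting:
                    s_grp[ch, j] *= math.exp(eta * (acc - 0.44))
            sm = math.exp(grow[G - 2])
            sk = math.exp(grow[G - 1])

            # 3. hierarchical translation / scale moves
            liksum = 0.0
            for i in range(P):
                liksum += _loglik_i(mu[ch, i], lk[ch, i], Cc[i], Ss[i], nvec[i])
            for m in range(M):
                if G == 8:
                    # 0-2 mu translations, 3-5 kappa translations, 6-7 scales
                    kind = 0 if m < 3 else (1 if m < 6 else 2 + (m - 6))
                    cm = -1 if m in (0, 3, 6, 7) else (1 if m in (1, 4) else 2)
                    j = m
                else:
                    kind = (0, 1, 2, 3)[m]
                    cm = -1
                    j = (0, 1, 2, 3)[m]
                e = s_mov[ch, m] * np.random.normal()
                old = grow[j]
                adj = 0.0   # term added to the log acceptance ratio
                ok = True
                if kind == 0:            # mu translation
                    grow[j] = old + e
                    for i in range(P):
                        if cm < 0 or cond[i] == cm:
                            mu_t[i] = mu[ch, i] + e
                        else:
                            mu_t[i] = mu[ch, i]
                    for i in range(P):
                        lk_t[i] = lk[ch, i]
                elif kind == 1:          # kappa translation (constrained scale)
                    # symmetric translation in kappa coordinates: subtract
                    # the z-space log-Jacobian change from the ratio
                    if (G == 8 and j == 3) or (G == 4 and j == 1):
                        akn = math.exp(old) + e
                        if akn <= 0.0:
                            ok = False
                        else:
                            grow[j] = math.log(akn)
                            adj -= grow[j] - old
                    else:
                        grow[j] = old + e
                    if ok:
                        for i in range(P):
                            mu_t[i] = mu[ch, i]
                            if cm < 0 or cond[i] == cm:
                                kn = math.exp(lk[ch, i]) + e
                                if kn <= 0.0:
                                    ok = False
                                    break
                                lk_t[i] = math.log(kn)
                                adj -= lk_t[i] - lk[ch, i]
                            else:
                                lk_t[i] = lk[ch, i]
                elif kind == 2:          # mu scale: sigma_mu with residuals
                    # deterministic scaling map: log-determinant P*e is
                    # added to the ratio
                    grow[j] = old + e
                    f = math.exp(e)
                    for i in range(P):
                        am, ak = _a_of(grow, G, cond[i])
                        mu_t[i] = am + f * (mu[ch, i] - am)
                        lk_t[i] = lk[ch, i]
                    adj = P * e
                else:                    # kappa scale: sigma_kappa w/ residuals
                    grow[j] = old + e
                    f = math.exp(e)
                    for i in range(P):
                        mu_t[i] = mu[ch, i]
                        am, ak = _a_of(grow, G, cond[i])
                        kn = ak + f * (math.exp(lk[ch, i]) - ak)
                        if kn <= 0.0:
                            ok = False
                            break
                        lk_t[i] = math.log(kn)
                    if ok:
                        adj = P * e
                        for i in range(P):
                            adj += lk[ch, i] - lk_t[i]
                if grow[j] < -40.0 or grow[j] > 40.0:   # numerical guard
                    ok = False
                acc = 0.0
                if ok:
                    sm_n = math.exp(grow[G - 2])
                    sk_n = math.exp(grow[G - 1])
                    hsum_n = 0.0
                    lik_n = 0.0
                    for i in range(P):
                        am, ak = _a_of(grow, G, cond[i])
                        hsum_n += _hier_i(mu_t[i], lk_t[i], am, ak, sm_n, sk_n)
                        lik_n += _loglik_i(mu_t[i], lk_t[i], Cc[i], Ss[i],
                                           nvec[i])
                    gp_n = _group_prior_nb(grow, G, amu_s, ak_s, d_s, d_df,
                                           sm_s, sk_s)
                    lp_new = gp_n + hsum_n + lik_n
                    lp_now = gp + hsum + liksum
                    if math.log(np.random.random()) < lp_new + adj - lp_now:
                        acc = 1.0
                        gp = gp_n
                        hsum = hsum_n
                        liksum = lik_n
                        for i in range(P):
                            mu[ch, i] = mu_t[i]
                            lk[ch, i] = lk_t[i]
                        sm = sm_n
                        sk = sk_n
                if acc == 0.0:
                    grow[j] = old
                if adapting:
                    s_mov[ch, m] *= math.exp(eta * (acc - 0.44))

            if it >= warmup:
                k = it - warmup
                for j in range(G):
                    draws[ch, k, j] = grow[j]
                for i in range(P):
                    draws[ch, k, G + i] = mu[ch, i]
                    draws[ch, k, G + P + i] = lk[ch, i]
    return draws
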