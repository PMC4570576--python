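"""Numba kernels for the gene-expression switch model.

Everything here works on the reparameterized latent scale (M, P~) where
P~ = kappa * P and the translation rate enters as at = kappa * alpha.
Setting kap=1 and at=alpha recovers the molecule-count scale.

The LNA/moment propagation uses the fact that for this network the first
and second conditional moments obey a closed linear ODE system.  With the
ordering v = (phi_M, phi_P, S_MM, S_MP, S_PP) the system matrix is lower
triangular and the piecewise-constant transcription rate beta enters as an
affine forcing term, so each constant-beta segment is solved exactly by one
small matrix exponential.
"""

import math

import numpy as np
from numba import njit

_LOG2PI = math.log(2.0 * math.pi)


# ---------------------------------------------------------------------------
# small dense matrix exponential (scaling & squaring + Taylor)
# ---------------------------------------------------------------------------

@njit(cache=True)
def expm_small(A):
    n = A.shape[0]
    # row-sum norm
    nrm = 0.0
    for i in range(n):
        r = 0.0
        for j in range(n):
            r += abs(A[i, j])
        if r > nrm:
            nrm = r
    s = 0
    if nrm > 0.5:
        s = int(math.ceil(math.log(nrm / 0.5) / math.log(2.0)))
    As = A * (2.0 ** (-s))
    E = np.eye(n)
    term = np.eye(n)
    tmp = np.empty((n, n))
    for k in range(1, 26):
        mx = 0.0
        for i in range(n):
            for j in range(n):
                acc = 0.0
                for l in range(n):
                    acc += term[i, l] * As[l, j]
                acc /= k
                tmp[i, j] = acc
                if abs(acc) > mx:
                    mx = abs(acc)
        for i in range(n):
            for j in range(n):
                term[i, j] = tmp[i, j]
                E[i, j] += tmp[i, j]
        if mx < 1e-18:
            break
    for _ in range(s):
        for i in range(n):
            for j in range(n):
                acc = 0.0
                for l in range(n):
                    acc += E[i, l] * E[l, j]
                tmp[i, j] = acc
        for i in range(n):
            for j in range(n):
                E[i, j] = tmp[i, j]
    return E


@njit(cache=True)
def _moment_propagator(dm, dp, at, kap, dt):
    """Exact propagator of the conditional-moment ODEs over a constant-beta
    piece of length dt.  Returns (E, G) with v(dt) = E @ v(0) + beta * G."""
    A = np.zeros((6, 6))
    # phi_M' = -dm phi_M + beta
    A[0, 0] = -dm
    A[0, 5] = 1.0
    # phi_P' = at phi_M - dp phi_P
    A[1, 0] = at
    A[1, 1] = -dp
    # S_MM' = dm phi_M - 2 dm S_MM + beta
    A[2, 0] = dm
    A[2, 2] = -2.0 * dm
    A[2, 5] = 1.0
    # S_MP' = at S_MM - (dm+dp) S_MP
    A[3, 2] = at
    A[3, 3] = -(dm + dp)
    # S_PP' = kap*at phi_M + kap*dp phi_P + 2 at S_MP - 2 dp S_PP
    A[4, 0] = kap * at
    A[4, 1] = kap * dp
    A[4, 3] = 2.0 * at
    A[4, 4] = -2.0 * dp
    F = expm_small(A * dt)
    E = F[:5, :5].copy()
    G = F[:5, 5].copy()
    return E, G


@njit(cache=True)
def _prop_moments(v, w, beta, dm, dp, at, kap, dt):
    """Closed-form solution of the conditional-moment ODEs over a
    constant-beta piece: w = E(dt) v + beta G(dt), written into w.

    v = (phi_M, phi_P, S_MM, S_MP, S_PP).  Valid when the exponential
    rates are distinct; returns False near the degenerate combinations
    (dm ~ dp or dm ~ 2 dp), where the caller falls back to the matrix
    exponential.
    """
    scale = dm + dp
    if abs(dp - dm) < 1e-7 * scale or abs(2.0 * dp - dm) < 1e-7 * scale:
        return False
    Em = math.exp(-dm * dt)
    Ep = math.exp(-dp * dt)
    E2m = Em * Em
    E2p = Ep * Ep
    Emp = Em * Ep
    B = v[0] - beta / dm
    C = beta / dm
    # phi_M
    w[0] = C + B * Em
    # phi_P
    qm = at * B / (dp - dm)
    qc = at * C / dp
    qp = v[1] - qm - qc
    w[1] = qm * Em + qp * Ep + qc
    # S_MM
    A = v[2] - B - C
    w[2] = A * E2m + B * Em + C
    # S_MP: coefficients on (e^{-2dm}, e^{-dm}, e^{-(dm+dp)}, 1)
    p2m = at * A / (dp - dm)
    pm = at * B / dp
    pc = at * C / scale
    pmp = v[3] - p2m - pm - pc
    w[3] = p2m * E2m + pm * Em + pmp * Emp + pc
    # S_PP forcing g(s) = 2 at S_MP + kap (at phi_M + dp phi_P)
    g2m = 2.0 * at * p2m
    gm = 2.0 * at * pm + kap * at * B + kap * dp * qm
    gmp = 2.0 * at * pmp
    gp = kap * dp * qp
    gc = 2.0 * at * pc + kap * at * C + kap * dp * qc
    acc = v[4] * E2p
    acc += g2m * (E2m - E2p) / (2.0 * dp - 2.0 * dm)
    acc += gm * (Em - E2p) / (2.0 * dp - dm)
    acc += gmp * (Emp - E2p) / (dp - dm)
    acc += gp * (Ep - E2p) / dp
    acc += gc * (1.0 - E2p) / (2.0 * dp)
    w[4] = acc
    return True


@njit(cache=True)
def _prop_step(v, w, beta, dm, dp, at, kap, dt):
    """Moment propagation with automatic fallback to the matrix
    exponential near degenerate rate combinations."""
    if _prop_moments(v, w, beta, dm, dp, at, kap, dt):
        return
    E, G = _moment_propagator(dm, dp, at, kap, dt)
    for j in range(5):
        acc = beta * G[j]
        for l in range(5):
            acc += E[j, l] * v[l]
        w[j] = acc


@njit(cache=True)
def _expJ(dm, dp, at, tau):
    """Closed-form exp(J*tau) for J = [[-dm, 0], [at, -dp]]."""
    em = math.exp(-dm * tau)
    ep = math.exp(-dp * tau)
    F = np.empty((2, 2))
    F[0, 0] = em
    F[0, 1] = 0.0
    if abs(dm - dp) > 1e-9:
        F[1, 0] = at * (ep - em) / (dm - dp)
    else:
        F[1, 0] = at * tau * em
    F[1, 1] = ep
    return F


@njit(cache=True)
def _beta_at(t, s_times, betas):
    """Piecewise-constant rate, intervals [s_{i-1}, s_i)."""
    k = s_times.shape[0]
    i = 0
    while i < k and t >= s_times[i]:
        i += 1
    return betas[i]


@njit(cache=True)
def lna_grid_moments(tobs, s_times, betas, dm, dp, at, kap, M0, Pt0):
    """Macroscopic mean path and per-interval LNA transition moments.

    Returns (phi (T+1,2), F (T,2,2), Q (T,2,2)).  phi solves the macroscopic
    ODE from (M0, Pt0); Q[i] is the transition covariance over
    (tobs[i], tobs[i+1]) started from zero fluctuation covariance, with the
    diffusion evaluated along phi and split exactly at interior switch times.
    """
    T = tobs.shape[0] - 1
    k = s_times.shape[0]
    phi = np.empty((T + 1, 2))
    F = np.empty((T, 2, 2))
    Q = np.empty((T, 2, 2))
    v = np.zeros(5)
    v[0] = M0
    v[1] = Pt0
    phi[0, 0] = M0
    phi[0, 1] = Pt0

    # cache propagator for the (usually unique) grid spacing
    cached_dt = -1.0
    Ec = np.empty((5, 5))
    Gc = np.empty(5)

    si = 0  # next switch index
    for i in range(T):
        t0 = tobs[i]
        t1 = tobs[i + 1]
        F[i] = _expJ(dm, dp, at, t1 - t0)
        # reset fluctuation covariance at interval start
        v[2] = 0.0
        v[3] = 0.0
        v[4] = 0.0
        t = t0
        while si < k and s_times[si] <= t0:
            si += 1
        sj = si
        while t < t1 - 1e-13:
            if sj < k and s_times[sj] < t1 - 1e-13:
                tn = s_times[sj]
                if tn <= t + 1e-13:
                    sj += 1
                    continue
            else:
                tn = t1
            dt = tn - t
            beta = _beta_at(0.5 * (t + tn), s_times, betas)
            if abs(dt - cached_dt) < 1e-14:
                E = Ec
                G = Gc
            else:
                E, G = _moment_propagator(dm, dp, at, kap, dt)
                cached_dt = dt
                Ec = E
                Gc = G
            v = E @ v + beta * G
            t = tn
            if sj < k and abs(tn - s_times[sj]) < 1e-13:
                sj += 1
        phi[i + 1, 0] = v[0]
        phi[i + 1, 1] = v[1]
        Q[i, 0, 0] = v[2]
        Q[i, 0, 1] = v[3]
        Q[i, 1, 0] = v[3]
        Q[i, 1, 1] = v[4]
    return phi, F, Q


@njit(cache=True)
def _kalman_restart(y, tobs, s_times, betas, dm, dp, at, kap, sig, M0,
                    Pt0):
    T = tobs.shape[0] - 1
    k = s_times.shape[0]
    s2 = sig * sig
    pred_mean = np.empty(T + 1)
    pred_var = np.empty(T + 1)
    filt_mean = np.empty((T + 1, 2))
    v = np.zeros(5)
    w = np.zeros(5)
    m0_ = M0
    m1_ = Pt0
    c00 = 0.0
    c01 = 0.0
    c11 = 0.0
    loglik = 0.0
    si = 0
    for i in range(T + 1):
        if i > 0:
            t0 = tobs[i - 1]
            t1 = tobs[i]
            tau = t1 - t0
            while si < k and s_times[si] <= t0 + 1e-13:
                si += 1
            v[0] = m0_
            v[1] = m1_
            v[2] = 0.0
            v[3] = 0.0
            v[4] = 0.0
            t = t0
            sj = si
            while t < t1 - 1e-13:
                if sj < k and s_times[sj] < t1 - 1e-13 \
                        and s_times[sj] > t + 1e-13:
                    tn = s_times[sj]
                else:
                    tn = t1
                _prop_step(v, w, betas[sj], dm, dp, at, kap, tn - t)
                for j in range(5):
                    v[j] = w[j]
                t = tn
                if sj < k and abs(tn - s_times[sj]) < 1e-13:
                    sj += 1
            F = _expJ(dm, dp, at, tau)
            m0_ = v[0]
            m1_ = v[1]
            a00 = F[0, 0] * c00
            a10 = F[1, 0] * c00 + F[1, 1] * c01
            a11 = F[1, 0] * c01 + F[1, 1] * c11
            c00 = a00 * F[0, 0] + v[2]
            c01 = a10 * F[0, 0] + v[3]
            c11 = a10 * F[1, 0] + a11 * F[1, 1] + v[4]
        S = c11 + s2
        if S < 1e-12:
            S = 1e-12
        r = y[i] - m1_
        loglik += -0.5 * (_LOG2PI + math.log(S) + r * r / S)
        pred_mean[i] = m1_
        pred_var[i] = S
        k0 = c01 / S
        k1 = c11 / S
        m0_ += k0 * r
        m1_ += k1 * r
        b00 = c00 - k0 * c01
        b01 = c01 - k0 * c11
        b11 = c11 - k1 * c11
        c00 = b00 - b01 * k0 + s2 * k0 * k0
        c01 = b01 - b11 * k0 + s2 * k0 * k1
        c11 = b11 * (1.0 - k1) + s2 * k1 * k1
        if c00 < 0.0:
            c00 = 0.0
        if c11 < 0.0:
            c11 = 0.0
        filt_mean[i, 0] = m0_
        filt_mean[i, 1] = m1_
    return loglik, pred_mean, pred_var, filt_mean


@njit(cache=True)
def kalman_core(y, tobs, s_times, betas, dm, dp, at, kap, sig, M0, Pt0,
                restart=True):
    """Kalman filter for the LNA state-space model on the (M, P~) scale.

    Observation: y_t = P~_t + eps, eps ~ N(0, sig^2); x_0 = (M0, Pt0) is a
    point mass.  Returns (loglik, pred_mean, pred_var, filt_mean (T+1,2)).

    With `restart` (default) the macroscopic path is re-centered at the
    filtered mean before every prediction, which for this affine-hazard
    network makes the one-step predictive moments the exact conditional
    moments of the jump process.  restart=False keeps the classical LNA
    with a single global macroscopic path (a generative linear-Gaussian
    model, used by the brute-force likelihood cross-checks).
    """
    if restart:
        return _kalman_restart(y, tobs, s_times, betas, dm, dp, at, kap,
                               sig, M0, Pt0)
    phi, F, Q = lna_grid_moments(tobs, s_times, betas, dm, dp, at, kap, M0, Pt0)
    T = tobs.shape[0] - 1
    s2 = sig * sig
    pred_mean = np.empty(T + 1)
    pred_var = np.empty(T + 1)
    filt_mean = np.empty((T + 1, 2))

    m0_ = M0
    m1_ = Pt0
    c00 = 0.0
    c01 = 0.0
    c11 = 0.0
    loglik = 0.0
    for i in range(T + 1):
        if i > 0:
            f00 = F[i - 1, 0, 0]
            f10 = F[i - 1, 1, 0]
            f11 = F[i - 1, 1, 1]
            dm0 = m0_ - phi[i - 1, 0]
            dm1 = m1_ - phi[i - 1, 1]
            m0_ = phi[i, 0] + f00 * dm0
            m1_ = phi[i, 1] + f10 * dm0 + f11 * dm1
            # C = F C F' + Q  (F lower triangular, F[0,1]=0)
            a00 = f00 * c00
            a01 = f00 * c01
            a10 = f10 * c00 + f11 * c01
            a11 = f10 * c01 + f11 * c11
            c00 = a00 * f00 + Q[i - 1, 0, 0]
            c01 = a10 * f00 + Q[i - 1, 0, 1]
            c11 = a10 * f10 + a11 * f11 + Q[i - 1, 1, 1]
        # observation update on component 1
        S = c11 + s2
        if S < 1e-12:
            S = 1e-12
        r = y[i] - m1_
        loglik += -0.5 * (_LOG2PI + math.log(S) + r * r / S)
        pred_mean[i] = m1_
        pred_var[i] = S
        k0 = c01 / S
        k1 = c11 / S
        m0_ += k0 * r
        m1_ += k1 * r
        # Joseph form: C = (I-KH) C (I-KH)' + s2 K K'
        b00 = c00 - k0 * c01
        b01 = c01 - k0 * c11
        b10 = c01 - k1 * c01
        b11 = c11 - k1 * c11
        n00 = b00 - b01 * k0 + s2 * k0 * k0
        n01 = b01 - b11 * k0 + s2 * k0 * k1
        n11 = b11 * (1.0 - k1) + s2 * k1 * k1
        c00 = n00
        c01 = n01
        c11 = n11
        if c00 < 0.0:
            c00 = 0.0
        if c11 < 0.0:
            c11 = 0.0
        filt_mean[i, 0] = m0_
        filt_mean[i, 1] = m1_
    return loglik, pred_mean, pred_var, filt_mean


@njit(cache=True)
def kalman_loglik_core(y, tobs, s_times, betas, dm, dp, at, kap, sig, M0,
                       Pt0):
    """Fused, allocation-light Kalman log-likelihood (the MCMC hot path).

    Identical model to kalman_core with restart=True (the filter
    re-centers the macroscopic path at the filtered mean each step);
    moment propagation is done with scalar arithmetic and a cached
    propagator for the dominant grid spacing.
    """
    T = tobs.shape[0] - 1
    k = s_times.shape[0]
    s2 = sig * sig
    v = np.zeros(5)
    w = np.zeros(5)
    # cache the affine propagator for the dominant grid spacing
    base_dt = tobs[1] - tobs[0]
    Eb = np.empty((5, 5))
    Gb = np.empty(5)
    for j in range(5):
        for l in range(5):
            v[l] = 1.0 if l == j else 0.0
        _prop_step(v, w, 0.0, dm, dp, at, kap, base_dt)
        for l in range(5):
            Eb[l, j] = w[l]
    for l in range(5):
        v[l] = 0.0
    _prop_step(v, w, 1.0, dm, dp, at, kap, base_dt)
    for l in range(5):
        Gb[l] = w[l]
    emb = math.exp(-dm * base_dt)
    epb = math.exp(-dp * base_dt)
    if abs(dm - dp) > 1e-9:
        f10b = at * (epb - emb) / (dm - dp)
    else:
        f10b = at * base_dt * emb
    v[0] = M0
    v[1] = Pt0
    m0_ = M0
    m1_ = Pt0
    c00 = 0.0
    c01 = 0.0
    c11 = 0.0
    S = s2
    r = y[0] - m1_
    ll = -0.5 * (_LOG2PI + math.log(S) + r * r / S)
    si = 0
    for i in range(T):
        t0 = tobs[i]
        t1 = tobs[i + 1]
        tau = t1 - t0
        while si < k and s_times[si] <= t0 + 1e-13:
            si += 1
        v[0] = m0_
        v[1] = m1_
        v[2] = 0.0
        v[3] = 0.0
        v[4] = 0.0
        if si < k and s_times[si] < t1 - 1e-13:
            # switch(es) inside the interval: exact piecewise propagation
            t = t0
            sj = si
            while t < t1 - 1e-13:
                if sj < k and s_times[sj] < t1 - 1e-13 and s_times[sj] > t + 1e-13:
                    tn = s_times[sj]
                else:
                    tn = t1
                _prop_step(v, w, betas[sj], dm, dp, at, kap, tn - t)
                for j in range(5):
                    v[j] = w[j]
                t = tn
                if sj < k and abs(tn - s_times[sj]) < 1e-13:
                    sj += 1
        elif abs(tau - base_dt) < 1e-14:
            beta = betas[si]
            for j in range(5):
                acc = beta * Gb[j]
                for l in range(5):
                    acc += Eb[j, l] * v[l]
                w[j] = acc
            for j in range(5):
                v[j] = w[j]
        else:
            _prop_step(v, w, betas[si], dm, dp, at, kap, tau)
            for j in range(5):
                v[j] = w[j]
        if abs(tau - base_dt) < 1e-14:
            f00 = emb
            f11 = epb
            f10 = f10b
        else:
            em = math.exp(-dm * tau)
            ep = math.exp(-dp * tau)
            f00 = em
            f11 = ep
            if abs(dm - dp) > 1e-9:
                f10 = at * (ep - em) / (dm - dp)
            else:
                f10 = at * tau * em
        m0_ = v[0]
        m1_ = v[1]
        a00 = f00 * c00
        a10 = f10 * c00 + f11 * c01
        a11 = f10 * c01 + f11 * c11
        nc00 = a00 * f00 + v[2]
        nc01 = a10 * f00 + v[3]
        nc11 = a10 * f10 + a11 * f11 + v[4]
        c00 = nc00
        c01 = nc01
        c11 = nc11
        S = c11 + s2
        if S < 1e-12:
            S = 1e-12
        r = y[i + 1] - m1_
        ll += -0.5 * (_LOG2PI + math.log(S) + r * r / S)
        k0 = c01 / S
        k1 = c11 / S
        m0_ += k0 * r
        m1_ += k1 * r
        b00 = c00 - k0 * c01
        b01 = c01 - k0 * c11
        b11 = c11 - k1 * c11
        n00 = b00 - b01 * k0 + s2 * k0 * k0
        n01 = b01 - b11 * k0 + s2 * k0 * k1
        n11 = b11 * (1.0 - k1) + s2 * k1 * k1
        c00 = n00
        c01 = n01
        c11 = n11
        if c00 < 0.0:
            c00 = 0.0
        if c11 < 0.0:
            c11 = 0.0
    return ll


# ---------------------------------------------------------------------------
# exact SSA
# ---------------------------------------------------------------------------

@njit(cache=True)
def ssa_grid(grid, s_times, betas, dm, dp, alpha, M0, P0, seed):
    """Exact simulation, returning states sampled on `grid` only.

    The time-inhomogeneous hazard (piecewise-constant beta) is handled by
    restarting the exponential clock at each switch time, which is exact by
    the memoryless property.
    """
    np.random.seed(seed)
    n = grid.shape[0]
    Mg = np.empty(n, np.int64)
    Pg = np.empty(n, np.int64)
    k = s_times.shape[0]
    horizon = grid[n - 1]
    t = 0.0
    M = M0
    P = P0
    gi = 0
    si = 0
    while True:
        # record grid points passed
        seg_end = horizon
        if si < k and s_times[si] < horizon:
            seg_end = s_times[si]
        beta = betas[si]
        while t < seg_end:
            h1 = beta
            h2 = dm * M
            h3 = alpha * M
            h4 = dp * P
            h0 = h1 + h2 + h3 + h4
            if h0 <= 0.0:
                t = seg_end
                break
            tau = np.random.exponential(1.0 / h0)
            if t + tau >= seg_end:
                t = seg_end
                break
            t = t + tau
            while gi < n and grid[gi] < t:
                Mg[gi] = M
                Pg[gi] = P
                gi += 1
            u = np.random.random() * h0
            if u < h1:
                M += 1
            elif u < h1 + h2:
                M -= 1
            elif u < h1 + h2 + h3:
                P += 1
            else:
                P -= 1
        while gi < n and grid[gi] <= t + 1e-12:
            Mg[gi] = M
            Pg[gi] = P
            gi += 1
        if si < k and seg_end == s_times[si]:
            si += 1
        else:
            break
    while gi < n:
        Mg[gi] = M
        Pg[gi] = P
        gi += 1
    return Mg, Pg


@njit(cache=True)
def ssa_events(horizon, s_times, betas, dm, dp, alpha, M0, P0, seed):
    """Exact simulation recording every reaction.

    Returns (times, types, Ms, Ps) where types are 1..4 in the order
    (transcription, mRNA decay, translation, protein decay) and (Ms, Ps) are
    the states immediately after each reaction.
    """
    np.random.seed(seed)
    cap = 1024
    ts = np.empty(cap)
    tys = np.empty(cap, np.int64)
    Ms = np.empty(cap, np.int64)
    Ps = np.empty(cap, np.int64)
    nev = 0
    k = s_times.shape[0]
    t = 0.0
    M = M0
    P = P0
    si = 0
    while True:
        seg_end = horizon
        if si < k and s_times[si] < horizon:
            seg_end = s_times[si]
        beta = betas[si]
        while t < seg_end:
            h1 = beta
            h2 = dm * M
            h3 = alpha * M
            h4 = dp * P
            h0 = h1 + h2 + h3 + h4
            if h0 <= 0.0:
                t = seg_end
                break
            tau = np.random.exponential(1.0 / h0)
            if t + tau >= seg_end:
                t = seg_end
                break
            t = t + tau
            u = np.random.random() * h0
            if u < h1:
                M += 1
                ty = 1
            elif u < h1 + h2:
                M -= 1
                ty = 2
            elif u < h1 + h2 + h3:
                P += 1
                ty = 3
            else:
                P -= 1
                ty = 4
            if nev == cap:
                cap *= 2
                ts2 = np.empty(cap)
                tys2 = np.empty(cap, np.int64)
                Ms2 = np.empty(cap, np.int64)
                Ps2 = np.empty(cap, np.int64)
                ts2[:nev] = ts
                tys2[:nev] = tys
                Ms2[:nev] = Ms
                Ps2[:nev] = Ps
                ts = ts2
                tys = tys2
                Ms = Ms2
                Ps = Ps2
            ts[nev] = t
            tys[nev] = ty
            Ms[nev] = M
            Ps[nev] = P
            nev += 1
        if si < k and seg_end == s_times[si]:
            si += 1
        else:
            break
    return ts[:nev].copy(), tys[:nev].copy(), Ms[:nev].copy(), Ps[:nev].copy()


# ---------------------------------------------------------------------------
# birth-death decomposition helpers
# ---------------------------------------------------------------------------

@njit(cache=True)
def lam_mrna(t0, t1, s_times, betas, dm):
    """Poisson immigration mean of the mRNA transition over (t0, t1):
    integral of beta(s) * exp(-dm (t1 - s)) ds, exact per segment."""
    k = s_times.shape[0]
    lam = 0.0
    a = t0
    si = 0
    while si < k and s_times[si] <= t0:
        si += 1
    while a < t1 - 1e-13:
        if si < k and s_times[si] < t1:
            b = s_times[si]
        else:
            b = t1
        beta = betas[si]
        if dm > 0.0:
            lam += beta / dm * (math.exp(-dm * (t1 - b)) - math.exp(-dm * (t1 - a)))
        else:
            lam += beta * (b - a)
        a = b
        si += 1
    return lam


@njit(cache=True)
def norm_logcdf(z):
    # log Phi(z), stable for moderate negative z
    if z > -8.0:
        return math.log(0.5 * math.erfc(-z / math.sqrt(2.0)))
    # asymptotic expansion
    return -0.5 * z * z - 0.5 * _LOG2PI - math.log(-z)


@njit(cache=True)
def tn_logpdf(x, mu, var):
    """log density of N(mu, var) truncated to (0, inf)."""
    if x <= 0.0:
        return -np.inf
    if var < 1e-300:
        return -np.inf
    sd = math.sqrt(var)
    z = (x - mu) / sd
    return -0.5 * (_LOG2PI + math.log(var)) - 0.5 * z * z - norm_logcdf(mu / sd)


@njit(cache=True)
def tn_sample(mu, sd):
    """Sample N(mu, sd^2) truncated to (0, inf)."""
    alpha = -mu / sd
    if alpha < 0.7:
        # plain rejection: acceptance >= P(Z > alpha) ~ 0.24
        while True:
            x = mu + sd * np.random.standard_normal()
            if x > 0.0:
                return x
    # Robert (1995) translated-exponential rejection on the standard scale
    lam = 0.5 * (alpha + math.sqrt(alpha * alpha + 4.0))
    while True:
        z = alpha + np.random.exponential(1.0 / lam)
        rho = math.exp(-0.5 * (z - lam) ** 2)
        if np.random.random() <= rho:
            return mu + sd * z


@njit(cache=True)
def bda_interval_consts(tobs, s_times, betas, dm, dp):
    """Per-interval constants of the BDA transition kernels:
    (pM, lam, pP, fP) with fP = (1 - exp(-dp tau))/dp."""
    T = tobs.shape[0] - 1
    pM = np.empty(T)
    lam = np.empty(T)
    pP = np.empty(T)
    fP = np.empty(T)
    for i in range(T):
        tau = tobs[i + 1] - tobs[i]
        pM[i] = math.exp(-dm * tau)
        lam[i] = lam_mrna(tobs[i], tobs[i + 1], s_times, betas, dm)
        pP[i] = math.exp(-dp * tau)
        fP[i] = (1.0 - pP[i]) / dp if dp > 0.0 else tau
    return pM, lam, pP, fP


@njit(cache=True)
def bda_path_loglik(Mp, Pp, y, tobs, s_times, betas, dm, dp, at, kap, sig,
                    M0, Pt0):
    """Complete-data log density of a latent path plus observations under
    the BDA (truncated-normal transitions on the (M, P~) scale)."""
    T = tobs.shape[0] - 1
    pM, lam, pP, fP = bda_interval_consts(tobs, s_times, betas, dm, dp)
    s2 = sig * sig
    ll = -0.5 * (_LOG2PI + math.log(s2)) - 0.5 * (y[0] - Pt0) ** 2 / s2
    mprev = M0
    pprev = Pt0
    for i in range(T):
        muM = mprev * pM[i] + lam[i]
        vM = mprev * pM[i] * (1.0 - pM[i]) + lam[i]
        muP = pprev * pP[i] + at * mprev * fP[i]
        vP = kap * (pprev * pP[i] * (1.0 - pP[i]) + at * mprev * fP[i])
        if vM < 1e-12:
            vM = 1e-12
        if vP < 1e-12:
            vP = 1e-12
        ll += tn_logpdf(Mp[i], muM, vM)
        ll += tn_logpdf(Pp[i], muP, vP)
        r = y[i + 1] - Pp[i]
        ll += -0.5 * (_LOG2PI + math.log(s2)) - 0.5 * r * r / s2
        mprev = Mp[i]
        pprev = Pp[i]
    return ll


@njit(cache=True)
def _systematic_resample(w, u):
    """Systematic resampling; w normalized, u ~ U(0,1). Returns indices."""
    n = w.shape[0]
    idx = np.empty(n, np.int64)
    c = w[0]
    j = 0
    for i in range(n):
        target = (i + u) / n
        while c < target and j < n - 1:
            j += 1
            c += w[j]
        idx[i] = j
    return idx


@njit(cache=True)
def csmc_core(y, tobs, s_times, betas, dm, dp, at, kap, sig, M0, Pt0,
              Mref, Pref, n_particles, seed, conditional):
    """(Conditional) SMC for the BDA state-space model.

    Proposals: mRNA bootstrap from its truncated-normal transition; protein
    from the Gaussian-conjugate combination of its transition with the
    observation density, truncated at zero.  The incremental weight is then
    N(y; muP, vP + sig^2) * Phi(mu*/sd*) / Phi(muP/sdP), independent of the
    sampled value.

    Returns (M path, P~ path (length T, times 1..T), loglik estimate,
    min_ess).  When `conditional`, particle 0 is pinned to the reference
    path and one path is drawn by ancestral tracing.
    """
    np.random.seed(seed)
    T = tobs.shape[0] - 1
    Np = n_particles
    pM, lam, pP, fP = bda_interval_consts(tobs, s_times, betas, dm, dp)
    s2 = sig * sig

    Mh = np.empty((T, Np))
    Ph = np.empty((T, Np))
    anc = np.empty((T, Np), np.int64)
    Mcur = np.full(Np, M0)
    Pcur = np.full(Np, Pt0)
    logw = np.zeros(Np)
    w = np.full(Np, 1.0 / Np)

    loglik = -0.5 * (_LOG2PI + math.log(s2)) - 0.5 * (y[0] - Pt0) ** 2 / s2
    min_ess = float(Np)

    for i in range(T):
        # resample ancestors (weights from previous step; uniform at i=0)
        if i == 0:
            a = np.arange(Np)
        else:
            u = np.random.random()
            a = _systematic_resample(w, u)
            if conditional:
                a[0] = 0
        anc[i] = a
        yt = y[i + 1]
        for p in range(Np):
            mprev = Mcur[a[p]]
            pprev = Pcur[a[p]]
            muM = mprev * pM[i] + lam[i]
            vM = mprev * pM[i] * (1.0 - pM[i]) + lam[i]
            if vM < 1e-12:
                vM = 1e-12
            muP = pprev * pP[i] + at * mprev * fP[i]
            vP = kap * (pprev * pP[i] * (1.0 - pP[i]) + at * mprev * fP[i])
            if vP < 1e-12:
                vP = 1e-12
            vstar = 1.0 / (1.0 / vP + 1.0 / s2)
            mustar = vstar * (muP / vP + yt / s2)
            if conditional and p == 0:
                m = Mref[i]
                pp_ = Pref[i]
            else:
                m = tn_sample(muM, math.sqrt(vM))
                pp_ = tn_sample(mustar, math.sqrt(vstar))
            Mh[i, p] = m
            Ph[i, p] = pp_
            # weight: marginal of y under the untruncated product, times
            # the ratio of truncation normalizers
            vm = vP + s2
            lw = -0.5 * (_LOG2PI + math.log(vm)) - 0.5 * (yt - muP) ** 2 / vm
            lw += norm_logcdf(mustar / math.sqrt(vstar))
            lw -= norm_logcdf(muP / math.sqrt(vP))
            logw[p] = lw
        mx = logw[0]
        for p in range(1, Np):
            if logw[p] > mx:
                mx = logw[p]
        if not np.isfinite(mx):
            return Mref, Pref, -np.inf, 0.0
        sw = 0.0
        for p in range(Np):
            w[p] = math.exp(logw[p] - mx)
            sw += w[p]
        loglik += mx + math.log(sw / Np)
        s2w = 0.0
        for p in range(Np):
            w[p] /= sw
            s2w += w[p] * w[p]
        ess = 1.0 / s2w
        if ess < min_ess:
            min_ess = ess
        Mcur = Mh[i]
        Pcur = Ph[i]

    # draw one path by ancestral tracing
    u = np.random.random()
    c = 0.0
    j = Np - 1
    for p in range(Np):
        c += w[p]
        if u <= c:
            j = p
            break
    Mout = np.empty(T)
    Pout = np.empty(T)
    for i in range(T - 1, -1, -1):
        Mout[i] = Mh[i, j]
        Pout[i] = Ph[i, j]
        j = anc[i, j]
    return Mout, Pout, loglik, min_ess


# ---------------------------------------------------------------------------
# fused per-cell Gibbs sweep (RJ + two MH blocks) for the chain driver
# ---------------------------------------------------------------------------

@njit(cache=True)
def seed_rng(seed):
    np.random.seed(seed)


@njit(cache=True)
def _nlp(x, mu, sd):
    z = (x - mu) / sd
    return -0.5 * z * z - math.log(sd) - 0.5 * _LOG2PI


@njit(cache=True)
def _mix_lp(x, w, mu, v):
    acc = 0.0
    for m in range(w.shape[0]):
        z = x - mu[m]
        acc += w[m] * math.exp(-0.5 * z * z / v[m]) \
            / math.sqrt(2.0 * math.pi * v[m])
    if acc <= 0.0:
        return -1e308
    return math.log(acc)


@njit(cache=True)
def _mix_draw(w, mu, v):
    u = np.random.random()
    c = 0.0
    m = w.shape[0] - 1
    for j in range(w.shape[0]):
        c += w[j]
        if u <= c:
            m = j
            break
    return mu[m] + math.sqrt(v[m]) * np.random.standard_normal()


@njit(cache=True)
def _lps(k, horizon, min_sep):
    if k == 0:
        return 0.0
    span = horizon - (k + 1) * min_sep
    if span <= 0.0:
        return -1e308
    return math.lgamma(k + 1.0) - k * math.log(span)


@njit(cache=True)
def _ll_nb(mode, y, tobs, s_arr, k, lb_arr, scal, Mp, Pp):
    if mode == 2:
        return 0.0
    s = s_arr[:k]
    b = np.exp(lb_arr[:k + 1])
    dm = math.exp(scal[0])
    dp = math.exp(scal[1])
    at = math.exp(scal[2])
    kap = math.exp(scal[3])
    sig = math.exp(scal[4])
    M0 = math.exp(scal[5])
    P0 = math.exp(scal[6])
    if mode == 0:
        return kalman_loglik_core(y, tobs, s, b, dm, dp, at, kap, sig,
                                  M0, P0)
    return bda_path_loglik(Mp, Pp, y, tobs, s, b, dm, dp, at, kap, sig,
                           M0, P0)


@njit(cache=True)
def gibbs_cell_sweep(mode, y, tobs, s_arr, lb_arr, kdim, scal, ll_arr,
                     Mp, Pp, w_mix, mu_mix, v_mix, pk_tab, pv, hyp,
                     kmax, kap_free, it, adapt_start,
                     diag_n, diag_mean, diag_M2,
                     blk_cnt, blk_mean, blk_M2, chol_mat):
    """One per-cell Gibbs iteration: RJ move, then the two adaptive MH
    blocks.  Mirrors mcmc.rj_update / mcmc.mh_update_block; mode 0 = LNA
    marginal likelihood, 1 = BDA complete-data likelihood, 2 = flat
    (prior sampling).  All state arrays are mutated in place.

    pv layout: (mu_dm, sd_dm, mu_dp, sd_dp, mu_lM0, sd_lM0, mu_lP0,
    sd_lP0, horizon, min_sep, log_bound, move_sd, fixed_sd);
    hyp layout: (mu_alpha, var_alpha, mu_kappa, var_kappa, mu_sigma,
    var_sigma).
    """
    acc_rj = 0
    acc_b1 = 0
    acc_b2 = 0
    horizon = pv[8]
    min_sep = pv[9]
    log_bound = pv[10]
    move_sd = pv[11]
    fixed_sd = pv[12]
    k = int(kdim[0])

    # ---------------- RJ ----------------
    u = np.random.random()
    if u < 1.0 / 3.0:
        if k < kmax:
            s_new = np.random.random() * horizon
            j = 0
            while j < k and s_arr[j] < s_new:
                j += 1
            left = s_arr[j - 1] if j > 0 else 0.0
            right = s_arr[j] if j < k else horizon
            if s_new - left >= min_sep and right - s_new >= min_sep:
                lb_new = _mix_draw(w_mix, mu_mix, v_mix)
                if abs(lb_new) <= log_bound:
                    keep_left = np.random.random() < 0.5
                    s_p = np.empty(k + 1)
                    lb_p = np.empty(k + 2)
                    for i2 in range(j):
                        s_p[i2] = s_arr[i2]
                    s_p[j] = s_new
                    for i2 in range(j, k):
                        s_p[i2 + 1] = s_arr[i2]
                    ins = j + 1 if keep_left else j
                    for i2 in range(ins):
                        lb_p[i2] = lb_arr[i2]
                    lb_p[ins] = lb_new
                    for i2 in range(ins, k + 1):
                        lb_p[i2 + 1] = lb_arr[i2]
                    ll_p = _ll_nb(mode, y, tobs, s_p, k + 1, lb_p, scal,
                                  Mp, Pp)
                    if np.isfinite(ll_p):
                        log_a = (ll_p - ll_arr[0]
                                 + pk_tab[k + 1] - pk_tab[k]
                                 + _lps(k + 1, horizon, min_sep)
                                 - _lps(k, horizon, min_sep)
                                 + math.log(horizon) - math.log(k + 1.0))
                        if math.log(np.random.random() + 1e-300) < log_a:
                            for i2 in range(k + 1):
                                s_arr[i2] = s_p[i2]
                            for i2 in range(k + 2):
                                lb_arr[i2] = lb_p[i2]
                            k += 1
                            kdim[0] = k
                            ll_arr[0] = ll_p
                            acc_rj = 1
    elif u < 2.0 / 3.0:
        if k > 0:
            j = np.random.randint(k)
            keep_left = np.random.random() < 0.5
            rem = j + 1 if keep_left else j
            s_p = np.empty(max(k - 1, 1))
            lb_p = np.empty(k)
            for i2 in range(j):
                s_p[i2] = s_arr[i2]
            for i2 in range(j + 1, k):
                s_p[i2 - 1] = s_arr[i2]
            for i2 in range(rem):
                lb_p[i2] = lb_arr[i2]
            for i2 in range(rem + 1, k + 1):
                lb_p[i2 - 1] = lb_arr[i2]
            ll_p = _ll_nb(mode, y, tobs, s_p, k - 1, lb_p, scal, Mp, Pp)
            if np.isfinite(ll_p):
                log_a = (ll_p - ll_arr[0]
                         + pk_tab[k - 1] - pk_tab[k]
                         + _lps(k - 1, horizon, min_sep)
                         - _lps(k, horizon, min_sep)
                         + math.log(1.0 * k) - math.log(horizon))
                if math.log(np.random.random() + 1e-300) < log_a:
                    for i2 in range(k - 1):
                        s_arr[i2] = s_p[i2]
                    for i2 in range(k):
                        lb_arr[i2] = lb_p[i2]
                    k -= 1
                    kdim[0] = k
                    ll_arr[0] = ll_p
                    acc_rj = 1
    else:
        if k > 0:
            j = np.random.randint(k)
            s_new = s_arr[j] + move_sd * np.random.standard_normal()
            left = s_arr[j - 1] if j > 0 else 0.0
            right = s_arr[j + 1] if j < k - 1 else horizon
            if s_new - left >= min_sep and right - s_new >= min_sep:
                old = s_arr[j]
                s_arr[j] = s_new
                ll_p = _ll_nb(mode, y, tobs, s_arr, k, lb_arr, scal,
                              Mp, Pp)
                if (np.isfinite(ll_p)
                        and math.log(np.random.random() + 1e-300)
                        < ll_p - ll_arr[0]):
                    ll_arr[0] = ll_p
                    acc_rj = 1
                else:
                    s_arr[j] = old

    # ---------------- block 1: rates, degradations, M0 ----------------
    nr = k + 1
    d = nr + 3
    adapting = it >= adapt_start and np.random.random() > 0.05
    scale = 2.38 * 2.38 / d
    sd_r = fixed_sd
    sd_dm_ = min(fixed_sd, 0.04)
    sd_dp_ = min(fixed_sd, 0.04)
    sd_m0 = fixed_sd
    if adapting:
        if diag_n[0] >= 10:
            sd_r = math.sqrt(scale * diag_M2[0] / (diag_n[0] - 1) + 1e-6)
        if diag_n[1] >= 10:
            sd_dm_ = math.sqrt(scale * diag_M2[1] / (diag_n[1] - 1) + 1e-6)
        if diag_n[2] >= 10:
            sd_dp_ = math.sqrt(scale * diag_M2[2] / (diag_n[2] - 1) + 1e-6)
        if diag_n[3] >= 10:
            sd_m0 = math.sqrt(scale * diag_M2[3] / (diag_n[3] - 1) + 1e-6)
    lb_p = np.empty(nr)
    ok = True
    for i2 in range(nr):
        lb_p[i2] = lb_arr[i2] + sd_r * np.random.standard_normal()
        if abs(lb_p[i2]) > log_bound:
            ok = False
    ldm_p = scal[0] + sd_dm_ * np.random.standard_normal()
    ldp_p = scal[1] + sd_dp_ * np.random.standard_normal()
    lm0_p = scal[5] + sd_m0 * np.random.standard_normal()
    if (abs(ldm_p) > log_bound or abs(ldp_p) > log_bound
            or abs(lm0_p) > log_bound):
        ok = False
    if ok:
        scal_p = scal.copy()
        scal_p[0] = ldm_p
        scal_p[1] = ldp_p
        scal_p[5] = lm0_p
        ll_p = _ll_nb(mode, y, tobs, s_arr, k, lb_p, scal_p, Mp, Pp)
        if np.isfinite(ll_p):
            dpr = 0.0
            for i2 in range(nr):
                dpr += (_mix_lp(lb_p[i2], w_mix, mu_mix, v_mix)
                        - _mix_lp(lb_arr[i2], w_mix, mu_mix, v_mix))
            dpr += _nlp(ldm_p, pv[0], pv[1]) - _nlp(scal[0], pv[0], pv[1])
            dpr += _nlp(ldp_p, pv[2], pv[3]) - _nlp(scal[1], pv[2], pv[3])
            dpr += _nlp(lm0_p, pv[4], pv[5]) - _nlp(scal[5], pv[4], pv[5])
            if math.log(np.random.random() + 1e-300) < \
                    ll_p - ll_arr[0] + dpr:
                for i2 in range(nr):
                    lb_arr[i2] = lb_p[i2]
                scal[0] = ldm_p
                scal[1] = ldp_p
                scal[5] = lm0_p
                ll_arr[0] = ll_p
                acc_b1 = 1
    # adaptation with realized values
    for i2 in range(nr):
        diag_n[0] += 1
        dd = lb_arr[i2] - diag_mean[0]
        diag_mean[0] += dd / diag_n[0]
        diag_M2[0] += dd * (lb_arr[i2] - diag_mean[0])
    for (jj, val) in ((1, scal[0]), (2, scal[1]), (3, scal[5])):
        diag_n[jj] += 1
        dd = val - diag_mean[jj]
        diag_mean[jj] += dd / diag_n[jj]
        diag_M2[jj] += dd * (val - diag_mean[jj])

    # ---------------- block 2: alpha~, (kappa), sigma, P~0 ----------------
    d2 = 4 if kap_free == 1 else 3
    x = np.empty(d2)
    x[0] = scal[2]
    if kap_free == 1:
        x[1] = scal[3]
        x[2] = scal[4]
        x[3] = scal[6]
    else:
        x[1] = scal[4]
        x[2] = scal[6]
    use_chol = (it >= adapt_start and blk_cnt[0] >= 10
                and np.random.random() > 0.05)
    if use_chol:
        if blk_cnt[1] >= 25 or blk_cnt[2] == 0:
            cov = blk_M2 / (blk_cnt[0] - 1)
            cov = (2.38 * 2.38 / d2) * cov + 1e-6 * np.eye(d2)
            chol_mat[:, :] = np.linalg.cholesky(cov)
            blk_cnt[1] = 0
            blk_cnt[2] = 1
        z = np.random.standard_normal(d2)
        xp = x + chol_mat @ z
    else:
        xp = x.copy()
        for i2 in range(d2):
            xp[i2] += fixed_sd * np.random.standard_normal()
    ok = True
    for i2 in range(d2):
        if abs(xp[i2]) > log_bound:
            ok = False
    if ok:
        scal_p = scal.copy()
        if kap_free == 1:
            scal_p[2] = xp[0]
            scal_p[3] = xp[1]
            scal_p[4] = xp[2]
            scal_p[6] = xp[3]
        else:
            scal_p[2] = xp[0]
            scal_p[4] = xp[1]
            scal_p[6] = xp[2]
        ll_p = _ll_nb(mode, y, tobs, s_arr, k, lb_arr, scal_p, Mp, Pp)
        if np.isfinite(ll_p):
            dpr = (_nlp(scal_p[2] - scal_p[3], hyp[0], math.sqrt(hyp[1]))
                   - _nlp(scal[2] - scal[3], hyp[0], math.sqrt(hyp[1])))
            dpr += (_nlp(scal_p[3], hyp[2], math.sqrt(hyp[3]))
                    - _nlp(scal[3], hyp[2], math.sqrt(hyp[3])))
            dpr += (_nlp(scal_p[4], hyp[4], math.sqrt(hyp[5]))
                    - _nlp(scal[4], hyp[4], math.sqrt(hyp[5])))
            dpr += (_nlp(scal_p[6], pv[6], pv[7])
                    - _nlp(scal[6], pv[6], pv[7]))
            if math.log(np.random.random() + 1e-300) < \
                    ll_p - ll_arr[0] + dpr:
                scal[2] = scal_p[2]
                scal[3] = scal_p[3]
                scal[4] = scal_p[4]
                scal[6] = scal_p[6]
                ll_arr[0] = ll_p
                acc_b2 = 1
    # Welford update with realized values
    blk_cnt[0] += 1
    blk_cnt[1] += 1
    x[0] = scal[2]
    if kap_free == 1:
        x[1] = scal[3]
        x[2] = scal[4]
        x[3] = scal[6]
    else:
        x[1] = scal[4]
        x[2] = scal[6]
    n_ = blk_cnt[0]
    dold = np.empty(d2)
    for i2 in range(d2):
        dold[i2] = x[i2] - blk_mean[i2]
        blk_mean[i2] += dold[i2] / n_
    for i2 in range(d2):
        dnew_i = x[i2] - blk_mean[i2]
        for j2 in range(d2):
            blk_M2[i2, j2] += dold[j2] * dnew_i
    return acc_rj, acc_b1, acc_b2


@njit(cache=True)
def smc_lna_loglik(y, phi, F, Q, sig, M0, Pt0, n_particles, seed):
    """Bootstrap particle filter evidence estimate for the LNA-Gaussian
    state-space model (test surrogate; unbiased for the likelihood)."""
    np.random.seed(seed)
    T = phi.shape[0] - 1
    Np = n_particles
    s2 = sig * sig
    X = np.empty((Np, 2))
    for p in range(Np):
        X[p, 0] = M0
        X[p, 1] = Pt0
    loglik = -0.5 * (_LOG2PI + math.log(s2)) - 0.5 * (y[0] - Pt0) ** 2 / s2
    w = np.full(Np, 1.0 / Np)
    logw = np.empty(Np)
    for i in range(T):
        u = np.random.random()
        a = _systematic_resample(w, u)
        Xn = np.empty((Np, 2))
        # cholesky of 2x2 Q
        q00 = Q[i, 0, 0]
        q01 = Q[i, 0, 1]
        q11 = Q[i, 1, 1]
        l00 = math.sqrt(max(q00, 0.0))
        l10 = q01 / l00 if l00 > 0.0 else 0.0
        d = q11 - l10 * l10
        l11 = math.sqrt(max(d, 0.0))
        for p in range(Np):
            x0 = X[a[p], 0] - phi[i, 0]
            x1 = X[a[p], 1] - phi[i, 1]
            m0 = phi[i + 1, 0] + F[i, 0, 0] * x0
            m1 = phi[i + 1, 1] + F[i, 1, 0] * x0 + F[i, 1, 1] * x1
            z0 = np.random.standard_normal()
            z1 = np.random.standard_normal()
            Xn[p, 0] = m0 + l00 * z0
            Xn[p, 1] = m1 + l10 * z0 + l11 * z1
            r = y[i + 1] - Xn[p, 1]
            logw[p] = -0.5 * (_LOG2PI + math.log(s2)) - 0.5 * r * r / s2
        mx = logw[0]
        for p in range(1, Np):
            if logw[p] > mx:
                mx = logw[p]
        sw = 0.0
        for p in range(Np):
            w[p] = math.exp(logw[p] - mx)
            sw += w[p]
        loglik += mx + math.log(sw / Np)
        for p in range(Np):
            w[p] /= sw
        X = Xn
    return loglik
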