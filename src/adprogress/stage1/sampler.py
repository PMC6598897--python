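"""Blocked Gibbs / Metropolis-within-Gibbs sampler for the longitudinal models.

The three families share one likelihood skeleton on the percentile scale:

    y_ijk = x'_ij beta_k + [gamma_k (t_ij + delta_i)]   (LTJMM only)
            + alpha_0ik + alpha_1ik t_ij + eps_ijk,   eps_ijk ~ N(0, sigma_k^2)

with the per-subject random-effect vector u_i = (alpha_0i., alpha_1i.)
distributed MVN(0, D), D = V Omega V, Omega = L L' (L a lower-triangular
Cholesky factor with unit-norm rows).  Priors: beta ~ N(0, 10^2),
half-Cauchy(0, 2.5) on every scale (diagonal of V, sigma_k, gamma_k,
sigma_delta; gamma_k > 0), LKJ(eta = 1) on L.

Update scheme per iteration:

* beta_k and u_i: exact Gaussian conditionals (conjugate).
* delta_i: exact Gaussian conditional (the shift enters linearly).
* sigma_k, diagonal of V, gamma_k, sigma_delta: componentwise random-walk
  Metropolis on the log scale, step sizes adapted during warmup toward a
  0.44 acceptance rate.
* L: componentwise Metropolis on unconstrained canonical partial
  correlations (tanh transform), with the LKJ density and transform
  Jacobian in the target.

Conditioning the scale/correlation updates on the sampled random effects
makes every Metropolis evaluation an O(r^3) matrix computation with
r = 2p, so iterations stay cheap even for ten-marker panels.
"""

from __future__ import annotations

import numpy as np
from scipy.linalg import solve_triangular

HALF_CAUCHY_SCALE = 2.5
BETA_PRIOR_SD = 10.0
LKJ_ETA = 1.0
_TINY = 1e-12


def half_cauchy_logpdf(x: np.ndarray, scale: float = HALF_CAUCHY_SCALE) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    return np.log(2.0 / (np.pi * scale)) - np.log1p((x / scale) ** 2)


def chol_corr_from_unconstrained(ell: np.ndarray, r: int) -> tuple[np.ndarray, float]:
    """Map unconstrained reals to a correlation Cholesky factor.

    Uses canonical partial correlations z = tanh(ell) row by row; returns
    (L, log|Jacobian|) where the Jacobian is of the map ell -> strict
    lower triangle of L.  Rows of L have unit norm by construction.
    """
    z = np.tanh(ell)
    L = np.zeros((r, r))
    L[0, 0] = 1.0
    logjac = float(np.sum(np.log1p(-z**2 + _TINY)))
    m = 0
    for i in range(1, r):
        rem = 1.0
        for j in range(i):
            L[i, j] = z[m] * np.sqrt(rem)
            logjac += 0.5 * np.log(rem + _TINY)
            rem = max(rem - L[i, j] ** 2, _TINY)
            m += 1
        L[i, i] = np.sqrt(rem)
    return L, logjac


def lkj_chol_logpdf(L: np.ndarray, eta: float = LKJ_ETA) -> float:
    r = L.shape[0]
    i = np.arange(2, r + 1)
    return float(np.sum((r - i + 2.0 * eta - 2.0) * np.log(np.diag(L)[1:] + _TINY)))


class _AdaptiveStep:
    """Robbins-Monro adaptation of a vector of log proposal scales."""

    def __init__(self, n: int, init: float = 0.25, target: float = 0.44):
        self.log_s = np.full(n, np.log(init))
        self.target = target

    def scale(self, j: int) -> float:
        return float(np.exp(self.log_s[j]))

    def update(self, j: int, accepted: bool, iteration: int) -> None:
        gamma = min(0.5, 3.0 / (iteration + 10) ** 0.6)
        self.log_s[j] += gamma * ((1.0 if accepted else 0.0) - self.target)
        self.log_s[j] = np.clip(self.log_s[j], -8.0, 3.0)


def _d_logpost(v: np.ndarray, L: np.ndarray, logjac: float, S: np.ndarray, n_sub: int) -> float:
    """Log conditional of the random-effect covariance parameters given u.

    v holds log standard deviations (diagonal of V); S = sum_i u_i u_i'.
    """
    sd = np.exp(v)
    W = sd[:, None] * L  # Cholesky factor of D
    logdet = 2.0 * (np.sum(v) + np.sum(np.log(np.diag(L) + _TINY)))
    M = solve_triangular(W, np.eye(len(v)), lower=True)
    trace = float(np.sum((M.T @ M) * S))
    logp = -0.5 * n_sub * logdet - 0.5 * trace
    logp += float(np.sum(half_cauchy_logpdf(sd))) + float(np.sum(v))  # prior + log-jacobian
    logp += lkj_chol_logpdf(L) + logjac
    return logp


def run_chain(
    design,
    family: str,
    config,
    chain_seed: int,
    d_update_sweeps: int = 2,
    with_slope: bool = True,
) -> dict[str, np.ndarray]:
    """Run one MCMC chain; returns stacked retained draws.

    ``design`` is a :class:`~adprogress.stage1.design.Design` restricted to
    the markers of the model being fitted.  With ``with_slope=False`` only
    random intercepts are fitted (r = p instead of 2p).
    """
    rng = np.random.default_rng(chain_seed)
    y, t, X = design.y, design.t, design.X
    subj, mk = design.subj_idx, design.marker_idx
    n, p, d = design.n_subjects, design.n_markers, X.shape[1]
    N = len(y)
    r = 2 * p if with_slope else p
    ltjmm = family == "LTJMM"

    # For the latent-time family the per-marker random-effect blocks are
    # independent across markers (cross-marker correlation is carried by the
    # shared shift delta_i); otherwise a free D would absorb the rank-1
    # sigma_delta^2 * gamma gamma' intercept covariance and leave sigma_delta
    # unidentified.  Freeing only the (slope_k, intercept_k) canonical
    # partial correlations constrains L (hence Omega) to that block shape.
    if ltjmm and with_slope:
        free_pairs = {(p + k, k) for k in range(p)}
        free_ell = np.array(
            [(i, j) in free_pairs for i in range(1, r) for j in range(i)]
        )
    elif ltjmm:
        free_ell = np.zeros(r * (r - 1) // 2, dtype=bool)
    else:
        free_ell = np.ones(r * (r - 1) // 2, dtype=bool)

    # --- fixed index structures -------------------------------------
    sm = subj * p + mk  # (subject, marker) flat index
    n_sm = np.bincount(sm, minlength=n * p).reshape(n, p)
    st_sm = np.bincount(sm, weights=t, minlength=n * p).reshape(n, p)
    stt_sm = np.bincount(sm, weights=t * t, minlength=n * p).reshape(n, p)
    rows_k = [np.flatnonzero(mk == k) for k in range(p)]
    XtX_k = [X[rows].T @ X[rows] for rows in rows_k]
    n_k = np.array([len(rows) for rows in rows_k])

    # --- initialization ----------------------------------------------
    beta = np.zeros((p, d))
    sigma = np.zeros(p)
    for k, rows in enumerate(rows_k):
        bk = np.linalg.solve(XtX_k[k] + 1e-6 * np.eye(d), X[rows].T @ y[rows])
        beta[k] = bk
        resid = y[rows] - X[rows] @ bk
        sigma[k] = max(float(np.std(resid)), 0.02)
    u = np.zeros((n, r))
    if with_slope:
        v = np.concatenate([np.full(p, np.log(0.15)), np.full(p, np.log(0.05))])
    else:
        v = np.full(p, np.log(0.15))
    v = v + 0.05 * rng.standard_normal(r)
    n_ell = r * (r - 1) // 2
    ell = 0.02 * rng.standard_normal(n_ell)
    L, logjac = chol_corr_from_unconstrained(ell, r)
    gamma = 0.05 * (1.0 + 0.5 * np.abs(rng.standard_normal(p))) if ltjmm else None
    delta = np.zeros(n) if ltjmm else None
    log_sigma_delta = np.log(0.2) if ltjmm else None

    steps_sigma = _AdaptiveStep(p)
    steps_v = _AdaptiveStep(r)
    steps_ell = _AdaptiveStep(n_ell, init=0.15)
    steps_gamma = _AdaptiveStep(p) if ltjmm else None
    steps_sd = _AdaptiveStep(1) if ltjmm else None

    def xb_vec() -> np.ndarray:
        out = np.empty(N)
        for k, rows in enumerate(rows_k):
            out[rows] = X[rows] @ beta[k]
        return out

    def re_vec() -> np.ndarray:
        out = u[subj, mk]
        if with_slope:
            out = out + u[subj, p + mk] * t
        return out

    def lt_vec() -> np.ndarray:
        if not ltjmm:
            return np.zeros(N)
        return gamma[mk] * (t + delta[subj])

    xb = xb_vec()

    keep: dict[str, list] = {k: [] for k in ("beta", "sigma", "v", "L", "z", "gamma", "delta", "sigma_delta", "iteration")}

    for it in range(config.iterations):
        adapt = it < config.warmup
        inv_s2 = 1.0 / sigma**2

        # ----- random effects u_i (exact Gaussian conditional) -------
        sd_v = np.exp(v)
        W = sd_v[:, None] * L
        Minv = solve_triangular(W, np.eye(r), lower=True)
        Dinv = Minv.T @ Minv
        resid = y - xb - lt_vec()
        r0 = np.bincount(sm, weights=resid, minlength=n * p).reshape(n, p)
        P = np.broadcast_to(Dinv, (n, r, r)).copy()
        kk = np.arange(p)
        P[:, kk, kk] += n_sm * inv_s2
        if with_slope:
            r1 = np.bincount(sm, weights=resid * t, minlength=n * p).reshape(n, p)
            P[:, kk, p + kk] += st_sm * inv_s2
            P[:, p + kk, kk] += st_sm * inv_s2
            P[:, p + kk, p + kk] += stt_sm * inv_s2
            rhs = np.concatenate([r0 * inv_s2, r1 * inv_s2], axis=1)
        else:
            rhs = r0 * inv_s2
        cholP = np.linalg.cholesky(P)
        mean = np.linalg.solve(P, rhs[..., None])[..., 0]
        noise = rng.standard_normal((n, r))
        u = mean + np.linalg.solve(np.transpose(cholP, (0, 2, 1)), noise[..., None])[..., 0]

        # ----- fixed effects beta_k (exact Gaussian conditional) -----
        re = re_vec()
        lt = lt_vec()
        for k, rows in enumerate(rows_k):
            rk = y[rows] - re[rows] - lt[rows]
            A = XtX_k[k] * inv_s2[k] + np.eye(d) / BETA_PRIOR_SD**2
            b = X[rows].T @ rk * inv_s2[k]
            cA = np.linalg.cholesky(A)
            mean_b = np.linalg.solve(A, b)
            beta[k] = mean_b + solve_triangular(cA.T, rng.standard_normal(d), lower=False)
        xb = xb_vec()

        if ltjmm:
            # ----- latent shifts delta_i (exact Gaussian) ------------
            sigma_delta = float(np.exp(log_sigma_delta))
            resid = y - xb - re - gamma[mk] * t
            g_is2 = gamma[mk] ** 2 * inv_s2[mk]
            prec = np.bincount(subj, weights=g_is2, minlength=n) + 1.0 / sigma_delta**2
            num = np.bincount(subj, weights=resid * gamma[mk] * inv_s2[mk], minlength=n)
            delta = num / prec + rng.standard_normal(n) / np.sqrt(prec)

            # ----- gamma_k (log-scale Metropolis) --------------------
            s_shift = t + delta[subj]
            resid = y - xb - re
            for k, rows in enumerate(rows_k):
                a = float(np.sum(s_shift[rows] ** 2)) * inv_s2[k]
                b = float(np.sum(resid[rows] * s_shift[rows])) * inv_s2[k]

                def logp_g(g: float) -> float:
                    return -0.5 * a * g * g + b * g + float(half_cauchy_logpdf(g)) + np.log(g)

                w0 = np.log(gamma[k])
                w1 = w0 + steps_gamma.scale(k) * rng.standard_normal()
                acc = np.log(rng.uniform()) < logp_g(np.exp(w1)) - logp_g(np.exp(w0))
                if acc:
                    gamma[k] = float(np.exp(w1))
                if adapt:
                    steps_gamma.update(k, acc, it)

            # ----- sigma_delta (log-scale Metropolis) ----------------
            ssd = float(np.sum(delta**2))

            def logp_sd(w: float) -> float:
                s = np.exp(w)
                return -n * w - ssd / (2 * s * s) + float(half_cauchy_logpdf(s)) + w

            w1 = log_sigma_delta + steps_sd.scale(0) * rng.standard_normal()
            acc = np.log(rng.uniform()) < logp_sd(w1) - logp_sd(log_sigma_delta)
            if acc:
                log_sigma_delta = float(w1)
            if adapt:
                steps_sd.update(0, acc, it)

        # ----- residual scales sigma_k (log-scale Metropolis) --------
        e = y - xb - re_vec() - lt_vec()
        sse = np.bincount(mk, weights=e * e, minlength=p)
        for k in range(p):
            def logp_s(w: float) -> float:
                s = np.exp(w)
                return -n_k[k] * w - sse[k] / (2 * s * s) + float(half_cauchy_logpdf(s)) + w

            w0 = np.log(sigma[k])
            w1 = w0 + steps_sigma.scale(k) * rng.standard_normal()
            acc = np.log(rng.uniform()) < logp_s(w1) - logp_s(w0)
            if acc:
                sigma[k] = float(np.exp(w1))
            if adapt:
                steps_sigma.update(k, acc, it)

        # ----- random-effect covariance (componentwise Metropolis) ---
        S = u.T @ u
        logp_cur = _d_logpost(v, L, logjac, S, n)
        for _ in range(d_update_sweeps):
            for j in range(r):
                v1 = v.copy()
                v1[j] += steps_v.scale(j) * rng.standard_normal()
                logp_new = _d_logpost(v1, L, logjac, S, n)
                acc = np.log(rng.uniform()) < logp_new - logp_cur
                if acc:
                    v, logp_cur = v1, logp_new
                if adapt:
                    steps_v.update(j, acc, it)
            for m in range(n_ell):
                if not free_ell[m]:
                    continue
                ell1 = ell.copy()
                ell1[m] += steps_ell.scale(m) * rng.standard_normal()
                L1, logjac1 = chol_corr_from_unconstrained(ell1, r)
                logp_new = _d_logpost(v, L1, logjac1, S, n)
                acc = np.log(rng.uniform()) < logp_new - logp_cur
                if acc:
                    ell, L, logjac, logp_cur = ell1, L1, logjac1, logp_new
                if adapt:
                    steps_ell.update(m, acc, it)

        # ----- retain ------------------------------------------------
        if it >= config.warmup and (it - config.warmup) % config.thin == 0:
            sd_v = np.exp(v)
            W = sd_v[:, None] * L
            z = solve_triangular(W, u.T, lower=True).T
            keep["beta"].append(beta.copy())
            keep["sigma"].append(sigma.copy())
            keep["v"].append(sd_v.copy())
            keep["L"].append(L.copy())
            keep["z"].append(z.copy())
            keep["iteration"].append(it)
            if ltjmm:
                keep["gamma"].append(gamma.copy())
                keep["delta"].append(delta.copy())
                keep["sigma_delta"].append(float(np.exp(log_sigma_delta)))

    out = {k: np.asarray(vv) for k, vv in keep.items() if len(vv)}
    return out
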