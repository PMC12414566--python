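"""Maximum-likelihood estimation of latent growth models.

The mixture likelihood is maximized by an expectation-maximization (EM)
algorithm in which both the class label and the within-class random
effects are treated as missing data, so every M-step is closed form:

* E-step: posterior class probabilities ``w_ik`` and, per class, the
  conditional mean/covariance of the random effects given the observed
  visits;
* M-step: mixing proportions from mean posteriors, per-class weighted
  least squares for the growth coefficients, moment updates for the
  random-effect covariance(s) and the residual variances (pooled
  according to the residual structure).

EM is monotone in the marginal log-likelihood.  Local maxima are
handled with a two-stage random multistart protocol (short EM runs for
all starts, full convergence for the best quarter) followed by an
optional quasi-Newton polish of the full likelihood, and a replication
rule that doubles the number of starts until the best log-likelihood is
reproduced by two independent runs.

Time is rescaled internally to the unit interval for optimizer
conditioning; reported coefficients are always back-transformed to the
original (month) units.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize

from .models import (
    FittedModel,
    GrowthParameters,
    LongitudinalDataset,
    ModelSpec,
    ResidualStructure,
    count_parameters,
    design_matrix,
    marginal_loglik,
    random_effect_design,
    scale_time,
)

__all__ = [
    "StartProtocol",
    "EstimationError",
    "fit",
    "multistart_replicated",
    "adapt_parameters",
]

# EM control defaults: relative log-likelihood tolerance and iteration caps.
EM_TOL = 1e-8
EM_MAX_ITER = 2000
STAGE1_ITERS = 10
VARIANCE_FLOOR_FRAC = 1e-6


class EstimationError(RuntimeError):
    """No start of the multistart protocol produced a usable solution."""


@dataclass(frozen=True)
class StartProtocol:
    """Random multistart protocol (Mplus-style two-stage scheme).

    ``n_starts`` random starts each run a few EM iterations; the best
    ``n_final_stage`` (default ``n_starts / 4``) are iterated to
    convergence.  ``multistart_replicated`` doubles ``n_starts`` up to
    ``max_doublings`` times until two independent runs agree within
    ``replication_tolerance`` log-likelihood units.
    """

    n_starts: int = 500
    n_final_stage: int | None = None
    max_doublings: int = 3
    replication_tolerance: float = 1e-4
    stage1_iters: int = STAGE1_ITERS
    em_tol: float = EM_TOL
    em_max_iter: int = EM_MAX_ITER
    polish: bool = True
    polish_maxiter: int = 30

    def __post_init__(self) -> None:
        if self.n_starts < 1:
            raise ValueError("n_starts must be >= 1")
        if self.replication_tolerance <= 0:
            raise ValueError("replication_tolerance must be > 0")
        if self.n_final_stage is not None and self.n_final_stage > self.n_starts:
            raise ValueError("n_final_stage cannot exceed n_starts")

    @property
    def final_stage(self) -> int:
        return self.n_final_stage or max(1, self.n_starts // 4)

    def doubled(self) -> "StartProtocol":
        return dataclasses.replace(
            self,
            n_starts=self.n_starts * 2,
            n_final_stage=None if self.n_final_stage is None else self.n_final_stage * 2,
        )


def _rng(seed) -> np.random.Generator:
    return np.random.default_rng(seed)


# ---------------------------------------------------------------------------
# EM engine
# ---------------------------------------------------------------------------


class _Engine:
    """Per-(spec, data) EM workspace with cached designs and patterns."""

    def __init__(self, spec: ModelSpec, data: LongitudinalDataset):
        self.spec = spec
        self.data = data
        self.times = np.asarray(spec.visit_times)
        self.K = spec.n_classes
        self.N = data.n_subjects
        self.T = spec.n_visits
        self.X = [design_matrix(self.times, p) for p in spec.poly_order_per_class]
        self.Z = random_effect_design(self.times, spec.random_effect_terms)
        self.r = spec.n_random_effects
        self.mask = data.mask
        self.y0 = np.nan_to_num(data.y)
        obs_vals = data.y[self.mask]
        self.var_floor = VARIANCE_FLOOR_FRAC * max(float(np.var(obs_vals)), 1e-12)
        self.floor_active = False

    # -- E-step quantities -------------------------------------------------

    def estep(self, params):
        """Posteriors, log-likelihood and (for RE models) reusable pattern cache."""
        if self.r == 0:
            cl = self._component_logliks_diag(params)
            cache = None
        else:
            cl, cache = self._component_logliks_re(params)
        with np.errstate(divide="ignore"):
            logpi = np.log(params.class_proportions)
        joint = cl + logpi
        # inline log-sum-exp (hot path)
        m = joint.max(axis=1)
        w = np.exp(joint - m[:, None])
        tot = w.sum(axis=1)
        w /= tot[:, None]
        lse = m + np.log(tot)
        return w, float(lse.sum()), cache

    def posteriors_and_ll(self, params):
        w, ll, _ = self.estep(params)
        return w, ll

    def _component_logliks_diag(self, params):
        """No-RE per-class log-densities via pure matrix products (hot path).

        With a diagonal covariance the density factorizes over observed
        visits, so the quadratic form expands into three matmuls.
        """
        theta = params.residual_table(self.spec)  # (K, T)
        mus = np.stack(
            [self.X[k] @ b for k, b in enumerate(params.growth_coefficients)]
        )  # (K, T)
        inv = 1.0 / theta
        log_term = np.log(2.0 * np.pi) + np.log(theta)  # (K, T)
        m, my, my2 = self._diag_moments()
        quad = my2 @ inv.T - 2.0 * (my @ (mus * inv).T) + m @ (mus**2 * inv).T
        return -0.5 * (m @ log_term.T + quad)

    def _diag_moments(self):
        if "diag_moments" not in self.data._cache:
            m = self.mask.astype(float)
            self.data._cache["diag_moments"] = (m, m * self.y0, m * self.y0**2)
        return self.data._cache["diag_moments"]

    def _component_logliks_re(self, params):
        """Per-class marginal log-densities plus a reusable Woodbury cache.

        The per-subject marginal covariance is ``Theta_obs + Z Psi Z'``
        with diagonal ``Theta``, so the Woodbury/push-through identities
        reduce everything to batched r x r (r <= 2) linear algebra over
        subjects — no per-missingness-pattern loops:

        ``Sigma^-1 = Theta^-1 - Theta^-1 Z (I + Psi S)^-1 Psi Z' Theta^-1``
        with ``S = Z' Theta_obs^-1 Z`` and
        ``log|Sigma| = sum_obs log(theta) + log det(I + Psi S)``.
        """
        spec = self.spec
        theta = params.residual_table(spec)  # (K, T)
        covs = params.re_covariances(spec)
        Z = self.Z
        r = self.r
        mask = self.mask
        out = np.empty((self.N, self.K))
        cache = []
        log2pi = float(np.log(2.0 * np.pi))
        n_obs = mask.sum(axis=1)
        eye = np.eye(r)
        for k in range(self.K):
            psi = covs[k]
            mu = self.X[k] @ params.growth_coefficients[k]
            invt = mask / theta[k]  # (N, T): m_it / theta_t
            resid = (self.y0 - mu) * mask  # (N, T)
            a = (resid**2 * (1.0 / theta[k])).sum(axis=1)
            u = np.einsum("nt,ta->na", resid / theta[k], Z)  # Z' Theta^-1 r
            S = np.einsum("nt,ta,tb->nab", invt, Z, Z)
            G = eye[None] + np.einsum("ab,nbc->nac", psi, S)
            detG = np.linalg.det(G)
            if np.any(detG <= 0) or not np.all(np.isfinite(detG)):
                from .models import SingularCovarianceError

                bad = int(np.flatnonzero((detG <= 0) | ~np.isfinite(detG))[0])
                raise SingularCovarianceError(
                    f"singular marginal covariance for subject "
                    f"{self.data.subject_ids[bad]!r} in class {k}"
                )
            v = u @ psi.T  # Psi u  (psi symmetric)
            w_ = np.linalg.solve(G, v[:, :, None])[:, :, 0]  # (I+PsiS)^-1 Psi u
            maha = a - np.einsum("na,na->n", u, w_)
            logdet = (mask * np.log(theta[k])).sum(axis=1) + np.log(detG)
            out[:, k] = -0.5 * (n_obs * log2pi + logdet + maha)
            cache.append(
                {"resid": resid, "u": u, "S": S, "G": G, "w": w_, "psi": psi}
            )
        return out, cache

    # -- M-step --------------------------------------------------------------

    def m_step(self, w, params, cache=None) -> GrowthParameters:
        """Closed-form M-step given responsibilities ``w`` (ECM sequence)."""
        spec = self.spec
        K, T = self.K, self.T
        pi_new = w.mean(axis=0)
        theta_old = params.residual_table(spec)  # (K, T)

        if self.r == 0:
            betas, num, den = self._mstep_no_re(w, theta_old)
            re_new = None
        else:
            betas, num, den, re_new = self._mstep_re(w, params, theta_old, cache)

        theta_new = self._pool_theta(num, den)
        return GrowthParameters(
            class_proportions=pi_new,
            growth_coefficients=tuple(betas),
            re_covariance=re_new,
            residual_variances=theta_new,
        )

    def _mstep_no_re(self, w, theta_old):
        # fully batched over classes: weighted per-visit moments are matmuls
        m, my, my2 = self._diag_moments()
        col = w.T @ m  # (K, T)  sum_i w_ik m_it
        wy = w.T @ my  # (K, T)  sum_i w_ik m_it y_it
        wy2 = w.T @ my2
        inv_th = 1.0 / theta_old  # (K, T)
        betas = []
        mus = np.empty((self.K, self.T))
        same_order = len({p for p in self.spec.poly_order_per_class}) == 1
        if same_order:
            X = self.X[0]
            A = np.einsum("kt,tc,td->kcd", col * inv_th, X, X)
            b = np.einsum("kt,tc->kc", wy * inv_th, X)
            beta_all = np.linalg.solve(A, b[:, :, None])[:, :, 0]
            betas = list(beta_all)
            mus = beta_all @ X.T
        else:
            for k in range(self.K):
                X = self.X[k]
                A = (X * (col[k] * inv_th[k])[:, None]).T @ X
                b = X.T @ (wy[k] * inv_th[k])
                beta = np.linalg.solve(A, b)
                betas.append(beta)
                mus[k] = X @ beta
        num = wy2 - 2.0 * mus * wy + mus**2 * col
        return betas, num, col

    def _mstep_re(self, w, params, theta_old, cache=None):
        spec = self.spec
        K, T, r = self.K, self.T, self.r
        Z = self.Z
        covs = params.re_covariances(spec)
        num = np.zeros((K, T))
        den = np.zeros((K, T))
        betas = []
        S_acc = np.zeros((K, r, r))  # sum_i w_ik (E b E b' + Cov b)
        wsum = w.sum(axis=0)
        if cache is None:
            _, cache = self._component_logliks_re(params)

        for k in range(K):
            psi = covs[k]
            ck = cache[k]
            u, S, G, w_ = ck["u"], ck["S"], ck["G"], ck["w"]
            # conditional random-effect moments via the Woodbury cache
            Eb = (u - np.einsum("nab,nb->na", S, w_)) @ psi.T  # (n, r)
            psiS = np.einsum("ab,nbc->nac", psi, S)
            GinvPsiS = np.linalg.solve(G, psiS)
            inner = S - np.einsum("nab,nbc->nac", S, GinvPsiS)
            Cb = psi[None] - np.einsum(
                "ab,nbc,cd->nad", psi, inner, psi
            )  # (n, r, r)
            zCz = np.einsum("ta,nab,tb->nt", Z, Cb, Z)  # (n, T)

            wk = w[:, k]
            S_acc[k] = np.einsum("n,na,nb->ab", wk, Eb, Eb) + np.einsum(
                "n,nab->ab", wk, Cb
            )
            # WLS for beta on y - Z E[b]
            U = self.y0 - Eb @ Z.T  # (N, T); masked below
            X = self.X[k]
            wt = wk[:, None] * self.mask
            col = wt.sum(axis=0)
            inv_th = 1.0 / theta_old[k]
            A = (X * (col * inv_th)[:, None]).T @ X
            b = X.T @ ((wt * U).sum(axis=0) * inv_th)
            beta = np.linalg.solve(A, b)
            betas.append(beta)
            resid2 = (U - X @ beta) ** 2 + zCz
            num[k] = (wt * resid2).sum(axis=0)
            den[k] = col

        if spec.class_variant_re:
            re_new = tuple(S_acc[k] / max(wsum[k], 1e-300) for k in range(K))
        else:
            re_new = S_acc.sum(axis=0) / self.N
        return betas, num, den, re_new

    def _pool_theta(self, num, den):
        rs = self.spec.residual_structure
        floor = self.var_floor
        if rs is ResidualStructure.FIXED:
            theta = num.sum() / den.sum()
        elif rs is ResidualStructure.FREE_OVER_TIME:
            theta = num.sum(axis=0) / np.maximum(den.sum(axis=0), 1e-300)
        elif rs is ResidualStructure.FREE_OVER_CLASSES:
            theta = num.sum(axis=1) / np.maximum(den.sum(axis=1), 1e-300)
        else:
            theta = num / np.maximum(den, 1e-300)
        theta = np.where(np.isfinite(theta) & (theta > floor), theta, floor)
        if np.any(theta <= floor * (1 + 1e-9)):
            self.floor_active = True
        if rs is ResidualStructure.FIXED:
            return float(np.asarray(theta).reshape(()))
        return theta

    # -- EM loop -------------------------------------------------------------

    def run_em(self, params, max_iter, tol):
        """Iterate EM from ``params``; returns (params, loglik, status).

        Plain EM steps are interleaved with SQUAREM-style extrapolation:
        the squared secant step is accepted only when it does not lower
        the likelihood, so the per-cycle log-likelihood sequence stays
        monotone while convergence is typically an order of magnitude
        faster than unaccelerated EM.
        """
        spec = self.spec
        ll_prev = -np.inf
        status = "maxiter"
        it = 0
        while it < max_iter:
            w, ll, cache = self.estep(params)
            if not np.isfinite(ll):
                return params, ll, "failed"
            if ll - ll_prev < tol * (abs(ll_prev) + 1.0) and np.isfinite(ll_prev):
                return params, float(ll), "converged"
            ll_prev = ll
            p1 = self.m_step(w, params, cache)
            it += 1
            if it >= max_iter:
                params = p1
                break
            w1, ll1, cache1 = self.estep(p1)
            if not np.isfinite(ll1):
                return p1, ll1, "failed"
            p2 = self.m_step(w1, p1, cache1)
            it += 1
            accelerated = False
            try:
                x0 = _pack(spec, params)
                x1 = _pack(spec, p1)
                x2 = _pack(spec, p2)
                r = x1 - x0
                v = (x2 - x1) - r
                nv = float(np.linalg.norm(v))
                if nv > 0:
                    alpha = -max(float(np.linalg.norm(r)) / nv, 1.0)
                    xa = x0 - 2.0 * alpha * r + alpha * alpha * v
                    pa = _unpack(spec, xa)
                    with np.errstate(over="ignore", invalid="ignore"):
                        wa, lla, cache_a = self.estep(pa)
                    if np.isfinite(lla) and lla >= ll1:
                        params = self.m_step(wa, pa, cache_a)  # stabilizing EM step
                        it += 1
                        accelerated = True
            except (np.linalg.LinAlgError, FloatingPointError, ValueError):
                accelerated = False
            if not accelerated:
                params = p2
        _, ll = self.posteriors_and_ll(params)
        return params, float(ll), status

    # -- start values ---------------------------------------------------------

    def subject_ols_coefs(self, order: int) -> np.ndarray:
        """Per-subject least-squares polynomial coefficients (min-norm if few visits)."""
        out = np.zeros((self.N, order + 1))
        X = design_matrix(self.times, order)
        for grp in self.data.pattern_groups():
            obs, subj, pat_of, yobs = grp["obs"], grp["subj"], grp["pat_of"], grp["y"]
            pinv = np.linalg.pinv(X[obs])  # (P, order+1, t)
            out[subj] = np.einsum("nct,nt->nc", pinv[pat_of], yobs)
        return out

    def initial_params(self, rng: np.random.Generator) -> GrowthParameters:
        """Random start: perturbed nearest-center partition of subject OLS coefficients."""
        spec = self.spec
        K = self.K
        max_order = max(spec.poly_order_per_class)
        coefs = self.subject_ols_coefs(max_order)
        # partition on level/slope only: higher-order subject OLS terms are
        # too noisy at a handful of visits to separate classes
        feats = self.subject_ols_coefs(1)
        if K == 1:
            assign = np.zeros(self.N, dtype=int)
        else:
            centers = feats[rng.choice(self.N, size=K, replace=False)]
            scale = feats.std(axis=0) + 1e-12
            d = (((feats[:, None, :] - centers[None]) / scale) ** 2).sum(axis=2)
            assign = np.argmin(d, axis=1)
            flip = rng.random(self.N) < 0.1  # jitter the partition
            assign[flip] = rng.integers(0, K, size=flip.sum())
            # guarantee every class non-empty
            for k in range(K):
                if not np.any(assign == k):
                    assign[rng.integers(0, self.N)] = k
        w = np.zeros((self.N, K))
        w[np.arange(self.N), assign] = 1.0
        params0 = self._moment_start(w, coefs)
        return params0

    def _moment_start(self, w, coefs):
        spec = self.spec
        K = self.K
        pi0 = np.maximum(w.mean(axis=0), 1.0 / self.N)
        pi0 = pi0 / pi0.sum()
        # pooled per-class OLS on the raw observations: stable where the
        # mean of noisy per-subject polynomial fits is not
        betas = []
        for k in range(K):
            p = spec.poly_order_per_class[k]
            X = self.X[k]
            wt = w[:, k : k + 1] * self.mask
            col = wt.sum(axis=0)
            A = (X * col[:, None]).T @ X + 1e-10 * np.eye(p + 1)
            b = X.T @ (wt * self.y0).sum(axis=0)
            betas.append(np.linalg.solve(A, b))
        obs_var = float(np.var(self.data.y[self.mask]))
        # within-partition residual variance around the class curves
        assign0 = np.argmax(w, axis=1)
        fit_resid2 = np.zeros_like(self.y0)
        for k in range(K):
            sel = assign0 == k
            fit_resid2[sel] = (self.y0[sel] - self.X[k] @ betas[k]) ** 2
        resid_var = float((fit_resid2 * self.mask).sum() / self.mask.sum())
        resid_var = max(resid_var, 0.05 * obs_var)
        if self.r:
            # per-subject random-effect projection of the residual from the
            # assigned class's mean curve; its pooled covariance (halved, to
            # leave room for residual noise) scales the Psi start correctly
            assign = np.argmax(w, axis=1)
            resid = np.zeros_like(self.y0)
            for k in range(K):
                sel = assign == k
                mu = self.X[k] @ betas[k]
                resid[sel] = self.y0[sel] - mu
            bhats = []
            noises = []
            for grp in self.data.pattern_groups():
                obs, subj, pat_of = grp["obs"], grp["subj"], grp["pat_of"]
                if obs.shape[1] < self.r + 1:
                    continue  # too few visits for a stable projection
                Zo = self.Z[obs]
                pinv = np.linalg.pinv(Zo)  # (P, r, t)
                r_obs = resid[subj[:, None], obs[pat_of]]
                bhats.append(np.einsum("nrt,nt->nr", pinv[pat_of], r_obs))
                # OLS sampling covariance of bhat under residual noise
                zz_inv = np.linalg.inv(np.einsum("pta,ptb->pab", Zo, Zo))
                noises.append(resid_var * zz_inv[pat_of])
            if bhats:
                bhat = np.concatenate(bhats)
                emp = np.atleast_2d(np.cov(bhat.T))
                noise = np.concatenate(noises).mean(axis=0)
                raw = emp - noise  # method-of-moments Psi estimate
                ev, V = np.linalg.eigh(raw)
                ev = np.maximum(ev, 1e-3 * obs_var)
                psi0 = (V * ev) @ V.T
            else:
                psi0 = 1e-2 * obs_var * np.eye(self.r)
            re0 = tuple(psi0.copy() for _ in range(K)) if spec.class_variant_re else psi0
            resid_scale = resid_var
        else:
            re0 = None
            resid_scale = resid_var
        rs = spec.residual_structure
        T = self.T
        if rs is ResidualStructure.FIXED:
            th0 = resid_scale
        elif rs is ResidualStructure.FREE_OVER_TIME:
            th0 = np.full(T, resid_scale)
        elif rs is ResidualStructure.FREE_OVER_CLASSES:
            th0 = np.full(K, resid_scale)
        else:
            th0 = np.full((K, T), resid_scale)
        return GrowthParameters(pi0, tuple(betas), re0, th0)

    # -- expected-information SEs for growth coefficients ---------------------

    def beta_covariances(self, params, w):
        """Per-class GLS covariance of beta: inv(sum_i w_ik X' V_k^-1 X)."""
        spec = self.spec
        theta = params.residual_table(spec)
        out = []
        if self.r == 0:
            for k in range(self.K):
                X = self.X[k]
                wt = w[:, k : k + 1] * self.mask
                col = wt.sum(axis=0) / theta[k]
                A = (X * col[:, None]).T @ X
                out.append(np.linalg.inv(A))
            return tuple(out)
        covs = params.re_covariances(spec)
        for k in range(self.K):
            X = self.X[k]
            psi = covs[k]
            sigma_full = self.Z @ psi @ self.Z.T + np.diag(theta[k])
            A = np.zeros((X.shape[1], X.shape[1]))
            for grp in self.data.pattern_groups():
                obs, subj, pat_of = grp["obs"], grp["subj"], grp["pat_of"]
                sig = sigma_full[obs[:, :, None], obs[:, None, :]]
                inv = np.linalg.inv(sig)
                Xo = X[obs]  # (P, t, c)
                XVX = np.einsum("pta,ptu,pub->pab", Xo, inv, Xo)  # (P, c, c)
                wk = np.bincount(pat_of, weights=w[subj, k], minlength=obs.shape[0])
                A += np.einsum("p,pab->ab", wk, XVX)
            out.append(np.linalg.inv(A))
        return tuple(out)


# ---------------------------------------------------------------------------
# quasi-Newton polish
# ---------------------------------------------------------------------------


def _pack(spec: ModelSpec, params: GrowthParameters) -> np.ndarray:
    parts = [np.log(np.maximum(params.class_proportions[:-1], 1e-12))
             - np.log(max(params.class_proportions[-1], 1e-12))]
    parts += [b for b in params.growth_coefficients]
    r = spec.n_random_effects
    if r:
        tril = np.tril_indices(r)
        for m in params.re_covariances(spec)[: spec.n_classes if spec.class_variant_re else 1]:
            L = np.linalg.cholesky(m + 1e-10 * np.eye(r))
            parts.append(L[tril])
    th = np.atleast_1d(np.asarray(params.residual_variances, dtype=float)).ravel()
    parts.append(np.log(th))
    return np.concatenate([np.atleast_1d(p) for p in parts])


def _unpack(spec: ModelSpec, x: np.ndarray) -> GrowthParameters:
    K, T = spec.n_classes, spec.n_visits
    i = 0
    alpha = np.concatenate([x[: K - 1], [0.0]])
    i += K - 1
    ea = np.exp(alpha - alpha.max())
    pi = ea / ea.sum()
    betas = []
    for p in spec.poly_order_per_class:
        betas.append(x[i : i + p + 1])
        i += p + 1
    r = spec.n_random_effects
    re_cov = None
    if r:
        tril = np.tril_indices(r)
        n_l = r * (r + 1) // 2
        mats = []
        n_mats = K if spec.class_variant_re else 1
        for _ in range(n_mats):
            L = np.zeros((r, r))
            L[tril] = x[i : i + n_l]
            i += n_l
            mats.append(L @ L.T)
        re_cov = tuple(mats) if spec.class_variant_re else mats[0]
    rs = spec.residual_structure
    n_th = {
        ResidualStructure.FIXED: 1,
        ResidualStructure.FREE_OVER_TIME: T,
        ResidualStructure.FREE_OVER_CLASSES: K,
        ResidualStructure.FREE_BOTH: K * T,
    }[rs]
    th = np.exp(x[i : i + n_th])
    if rs is ResidualStructure.FIXED:
        theta = float(th[0])
    elif rs is ResidualStructure.FREE_BOTH:
        theta = th.reshape(K, T)
    else:
        theta = th
    return GrowthParameters(pi, tuple(betas), re_cov, theta)


def _polish(spec, data, params, maxiter):
    x0 = _pack(spec, params)

    def neg_ll(x):
        try:
            val = -marginal_loglik(spec, _unpack(spec, x), data)
        except (np.linalg.LinAlgError, RuntimeError):
            return 1e12
        return val if np.isfinite(val) else 1e12

    res = minimize(neg_ll, x0, method="L-BFGS-B", options={"maxiter": maxiter})
    if np.isfinite(res.fun) and -res.fun > marginal_loglik(spec, params, data):
        return _unpack(spec, res.x), float(-res.fun)
    return params, marginal_loglik(spec, params, data)


# ---------------------------------------------------------------------------
# public API
# ---------------------------------------------------------------------------


def fit(
    spec: ModelSpec,
    data: LongitudinalDataset,
    protocol: StartProtocol | None = None,
    seed: int | np.random.SeedSequence = 0,
    extra_inits: tuple = (),
) -> FittedModel:
    """Fit ``spec`` to ``data`` with the replicated random multistart EM.

    Deterministic given ``seed``.  Returns the best solution over all
    starts with posteriors, fit indices and a convergence report.
    ``extra_inits`` adds deterministic starting parameter sets (month
    units, matching ``spec``) to the random-start pool — used by the
    selection pipeline to warm-start each stage from the previous
    stage's solution.

    Raises
    ------
    EstimationError
        If no start yields a finite likelihood.
    """
    if data.n_subjects == 0:
        raise ValueError("dataset is empty")
    protocol = protocol or StartProtocol()
    factor = max(abs(t) for t in spec.visit_times) or 1.0
    spec_s = dataclasses.replace(
        spec, visit_times=tuple(t / factor for t in spec.visit_times)
    )
    data_s = data.with_time_factor(factor)
    eng = _Engine(spec_s, data_s)
    rng = _rng(seed)

    n_starts = 1 if spec.n_classes == 1 else protocol.n_starts
    n_final = 1 if spec.n_classes == 1 else min(
        protocol.final_stage + len(extra_inits), n_starts + len(extra_inits)
    )

    starts: list = [
        scale_time(spec, p, 1.0 / factor) for p in extra_inits
    ]  # warm starts, re-expressed on the scaled clock
    stage1 = []
    statuses = []
    for s in range(n_starts):
        starts.append(None)
    for p0 in starts:
        try:
            if p0 is None:
                p0 = eng.initial_params(rng)
            p1, ll1, st = eng.run_em(p0, protocol.stage1_iters, protocol.em_tol)
        except (np.linalg.LinAlgError, RuntimeError):
            statuses.append("failed")
            continue
        statuses.append(st if st != "maxiter" else "stage1")
        if np.isfinite(ll1):
            stage1.append((ll1, p1))
    if not stage1:
        raise EstimationError(
            f"no start converged ({n_starts} starts, statuses {statuses})"
        )
    stage1.sort(key=lambda t: -t[0])

    final = []
    for ll1, p1 in stage1[:n_final]:
        try:
            p2, ll2, st = eng.run_em(p1, protocol.em_max_iter, protocol.em_tol)
        except (np.linalg.LinAlgError, RuntimeError):
            continue
        if np.isfinite(ll2):
            final.append((ll2, p2, st))
    if not final:
        raise EstimationError("no final-stage start converged")
    final.sort(key=lambda t: -t[0])
    best_ll, best_params, best_status = final[0]

    if protocol.polish:
        best_params, best_ll = _polish(
            spec_s, data_s, best_params, protocol.polish_maxiter
        )

    n_rep = sum(
        1 for ll, _, _ in final if abs(ll - best_ll) <= protocol.replication_tolerance
    )
    w, ll_final = eng.posteriors_and_ll(best_params)
    modal = np.argmax(w, axis=1)
    degenerate = np.flatnonzero(
        best_params.class_proportions < 1.0 / data.n_subjects
    ).tolist()

    se_cov = eng.beta_covariances(best_params, w)
    # back-transform to month units
    params_out = scale_time(spec_s, best_params, factor)
    se_out = []
    for k, cov in enumerate(se_cov):
        j = np.arange(cov.shape[0])
        scale = factor ** (-j)
        se_out.append(np.sqrt(np.diag(cov)) * scale)

    from .selection import appa, bic, scaled_entropy  # deferred: avoids cycle

    counts = np.bincount(modal, minlength=spec.n_classes)
    fi = {
        "bic": bic(ll_final, count_parameters(spec), data.n_subjects),
        "n_params": count_parameters(spec),
        "scaled_entropy": scaled_entropy(w) if spec.n_classes > 1 else None,
        "appa": appa(w, modal),
        "class_counts": counts,
        "class_proportions_modal": counts / data.n_subjects,
    }
    report = {
        "n_starts": n_starts,
        "n_final_stage": n_final,
        "best_loglik": ll_final,
        "best_loglik_replications": n_rep,
        "n_replications_within_run": n_rep,
        "replicated_between_runs": None,
        "n_doublings_used": 0,
        "converged": best_status == "converged" or protocol.polish,
        "degenerate_classes": degenerate,
        "variance_floor_active": eng.floor_active,
        "start_statuses": statuses,
    }
    return FittedModel(
        spec=spec,
        params=params_out,
        loglik=ll_final,
        posteriors=w,
        modal_assignment=modal,
        fit_indices=fi,
        convergence_report=report,
        se_growth_coefficients=tuple(se_out),
    )


def multistart_replicated(
    spec: ModelSpec,
    data: LongitudinalDataset,
    protocol: StartProtocol | None = None,
    seed: int = 0,
    extra_inits: tuple = (),
) -> FittedModel:
    """Fit twice with independent seeds, doubling starts until replication.

    Two independent runs of :func:`fit` must agree in best log-likelihood
    within ``protocol.replication_tolerance``; otherwise the number of
    random starts is doubled, up to ``protocol.max_doublings`` times.  If
    replication is never achieved the best solution found is returned
    with ``replicated_between_runs = False`` in its convergence report.
    """
    protocol = protocol or StartProtocol()
    current = protocol
    best = None
    for level in range(protocol.max_doublings + 1):
        ss_a, ss_b = np.random.SeedSequence([seed, level, 0]), np.random.SeedSequence(
            [seed, level, 1]
        )
        run_a = fit(spec, data, current, ss_a, extra_inits=extra_inits)
        run_b = fit(spec, data, current, ss_b, extra_inits=extra_inits)
        cand = run_a if run_a.loglik >= run_b.loglik else run_b
        if best is None or cand.loglik > best.loglik:
            best = cand
        gap = abs(run_a.loglik - run_b.loglik)
        if gap <= current.replication_tolerance:
            best.convergence_report["replicated_between_runs"] = True
            best.convergence_report["n_doublings_used"] = level
            best.convergence_report["between_run_gap"] = gap
            return best
        current = current.doubled()
    best.convergence_report["replicated_between_runs"] = False
    best.convergence_report["n_doublings_used"] = protocol.max_doublings
    best.convergence_report["warning"] = (
        "best log-likelihood not replicated between runs within tolerance"
    )
    return best


def adapt_parameters(
    old_spec: ModelSpec,
    params: GrowthParameters,
    new_spec: ModelSpec,
    drop_class: int | None = None,
) -> GrowthParameters:
    """Map a fitted parameter set onto a related spec as a warm start.

    Used by the selection ladder: growth coefficients are truncated or
    zero-padded to the new polynomial orders, residual variances are
    pooled or broadcast to the new residual structure, random-effect
    covariances are carried over where the terms match and otherwise
    initialized small relative to the residual scale.  ``drop_class``
    removes one class (for K -> K-1 comparisons), renormalizing the
    mixing proportions.
    """
    K_new = new_spec.n_classes
    idx = [k for k in range(old_spec.n_classes) if k != drop_class]
    idx = idx[:K_new]
    while len(idx) < K_new:
        idx.append(idx[-1])
    pi = np.maximum(params.class_proportions[idx], 1e-6)
    pi = pi / pi.sum()
    betas = []
    for j, k in zip(range(K_new), idx):
        b = params.growth_coefficients[k]
        want = new_spec.poly_order_per_class[j] + 1
        bb = np.zeros(want)
        m = min(want, b.size)
        bb[:m] = b[:m]
        betas.append(bb)
    table = params.residual_table(old_spec)[idx]  # (K_new, T)
    rs = new_spec.residual_structure
    if rs is ResidualStructure.FIXED:
        theta = float(table.mean())
    elif rs is ResidualStructure.FREE_OVER_TIME:
        theta = table.mean(axis=0)
    elif rs is ResidualStructure.FREE_OVER_CLASSES:
        theta = table.mean(axis=1)
    else:
        theta = table.copy()
    r_new = new_spec.n_random_effects
    if r_new == 0:
        re_cov = None
    else:
        t_max = max(abs(t) for t in new_spec.visit_times) or 1.0
        scale = float(table.mean())
        default = np.diag(
            [
                0.1 * scale if term == "intercept" else 0.02 * scale / t_max**2
                for term in new_spec.random_effect_terms
            ]
        )
        old_terms = old_spec.random_effect_terms
        mats = []
        old_covs = params.re_covariances(old_spec) if old_terms else None
        for k in idx:
            m = default.copy()
            if old_terms:
                src = old_covs[k]
                for a, ta in enumerate(new_spec.random_effect_terms):
                    for b2, tb in enumerate(new_spec.random_effect_terms):
                        if ta in old_terms and tb in old_terms:
                            m[a, b2] = src[old_terms.index(ta), old_terms.index(tb)]
            mats.append(m)
        if new_spec.class_variant_re:
            re_cov = tuple(mats)
        else:
            re_cov = sum(mats) / len(mats)
    return GrowthParameters(pi, tuple(betas), re_cov, theta)
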