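"""ReML engine for the structured polygenic model, GLS and Wald contrasts.

The polygenic ("null") model for line *l* of genetic background *k* is

    Y_kl = mu + alpha_k + G_kl + E_kl,
    Cov(G_kl, G_k'l') = K[kl, k'l'] * sigma_Gkk',      E_kl ~ N(0, sigma2_E),

i.e. the genetic covariance is the multi-group kinship scaled blockwise
by a per-background-pair (co)variance Sigma_G (3 x 3 when D, A and F
are all present).  Sigma_G is parameterized by its Cholesky factor, so
positive semidefiniteness is enforced by construction, and the
restricted log-likelihood is maximized by quasi-Newton iterations with
analytic gradients and (by default) three starting points.

GWAS testing is two-step: the null-model variance parameters are
plugged into a genetic covariance G = Sigma_G[blocks] o K and an error
covariance R = sigma2_E I; each SNP is then tested by GLS with
V = G + R, optionally re-estimating a single global scale of V per SNP
(the default), and linear combinations of the SNP fixed effects are
tested with Wald statistics against chi-square(1).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import scipy.linalg as sla
from scipy import optimize, stats

from .kinship import KinshipSet

log = logging.getLogger(__name__)

_LOG2PI = np.log(2.0 * np.pi)


class ModelError(RuntimeError):
    pass


# ---------------------------------------------------------------------------
# restricted log-likelihood machinery
# ---------------------------------------------------------------------------


def _reml_pieces(V: np.ndarray, X: np.ndarray, y: np.ndarray):
    """Cholesky-based REML quantities for one V.

    Returns (nll, P, u) where ``nll`` is the negative restricted
    log-likelihood (up to the usual constant), ``P`` the REML projection
    matrix and ``u = P y``.
    """
    n, p = X.shape
    try:
        c, low = sla.cho_factor(V, lower=True, check_finite=False)
    except sla.LinAlgError:
        return None
    logdet_v = 2.0 * np.sum(np.log(np.diag(c)))
    Vi_X = sla.cho_solve((c, low), X, check_finite=False)
    Vi_y = sla.cho_solve((c, low), y, check_finite=False)
    A = X.T @ Vi_X
    try:
        ca, lowa = sla.cho_factor(A, lower=True, check_finite=False)
    except sla.LinAlgError:
        return None
    logdet_a = 2.0 * np.sum(np.log(np.diag(ca)))
    Xt_Vi_y = X.T @ Vi_y
    beta = sla.cho_solve((ca, lowa), Xt_Vi_y, check_finite=False)
    u = Vi_y - Vi_X @ beta
    ypy = float(y @ u)
    nll = 0.5 * (logdet_v + logdet_a + ypy + (n - p) * _LOG2PI)
    Vi = sla.cho_solve((c, low), np.eye(n), check_finite=False)
    W = sla.cho_solve((ca, lowa), Vi_X.T, check_finite=False)
    P = Vi - Vi_X @ W
    return nll, P, u, beta, sla.cho_solve((ca, lowa), np.eye(p), check_finite=False)


class _StructuredObjective:
    """Negative restricted log-likelihood of the blockwise-scaled model.

    Parameters are the lower-triangular entries of the Cholesky factor
    of Sigma_G (group order fixed) followed by log(sigma2_E).
    """

    def __init__(self, y, X, K, group_index, n_groups):
        self.y = np.asarray(y, float)
        self.X = np.asarray(X, float)
        self.K = np.asarray(K, float)
        self.g = group_index  # per line, 0..n_groups-1
        self.ng = n_groups
        self.tril = np.tril_indices(n_groups)
        self.n_par = len(self.tril[0]) + 1
        # per-line-pair group ids for fancy indexing
        self._gi = self.g[:, None]
        self._gj = self.g[None, :]

    def sigma_from(self, theta):
        L = np.zeros((self.ng, self.ng))
        L[self.tril] = theta[:-1]
        return L @ L.T, L

    def build_v(self, theta):
        sigma, _ = self.sigma_from(theta)
        V = sigma[self._gi, self._gj] * self.K
        V[np.diag_indices_from(V)] += np.exp(theta[-1])
        return V

    def __call__(self, theta):
        V = self.build_v(theta)
        pieces = _reml_pieces(V, self.X, self.y)
        if pieces is None:
            return 1e10, np.zeros(self.n_par)
        nll, P, u, _beta, _covb = pieces
        # blockwise sums of P o K and (u u') o K give the gradient
        PK = P * self.K
        UK = np.outer(u, u) * self.K
        T = np.zeros((self.ng, self.ng))
        Q = np.zeros((self.ng, self.ng))
        for a in range(self.ng):
            ia = self.g == a
            for b in range(a, self.ng):
                ib = self.g == b
                t = PK[np.ix_(ia, ib)].sum()
                q = UK[np.ix_(ia, ib)].sum()
                T[a, b] = T[b, a] = t
                Q[a, b] = Q[b, a] = q
        _sigma, L = self.sigma_from(theta)
        grad = np.empty(self.n_par)
        for idx, (i, j) in enumerate(zip(*self.tril)):
            # dSigma for unit change of L[i,j]: e_i l_j' + l_j e_i'
            lj = L[:, j]
            # tr(P dV) = sum_ab dSigma[a,b] * T[a,b]; dSigma[a,b] = d_ai lj_b + d_bi lj_a
            tr_term = 2.0 * float(lj @ T[i])
            q_term = 2.0 * float(lj @ Q[i])
            grad[idx] = 0.5 * (tr_term - q_term)
        s2e = np.exp(theta[-1])
        grad[-1] = 0.5 * s2e * (np.trace(P) - float(u @ u))
        return nll, grad


@dataclass
class PolygenicFit:
    """ReML estimates of the structured polygenic model."""

    groups: list                 # background labels in Sigma_G order
    Sigma_G: np.ndarray          # genetic (co)variance across backgrounds
    sigma2_E: float
    beta: np.ndarray             # GLS fixed effects at the optimum
    beta_cov: np.ndarray
    loglik: float                # restricted log-likelihood
    converged: bool
    n_iter: int
    boundary: bool               # variance ~0 or |correlation| ~1
    theta: np.ndarray = field(repr=False, default=None)

    def genetic_correlations(self) -> np.ndarray:
        d = np.sqrt(np.clip(np.diag(self.Sigma_G), 1e-300, None))
        return self.Sigma_G / np.outer(d, d)


def _design_groups(kset: KinshipSet):
    labels = [k for k in ("D", "A", "F") if (kset.backgrounds == k).any()]
    gidx = np.array([labels.index(b) for b in kset.backgrounds])
    return labels, gidx


def reml_fit(y: np.ndarray, X: np.ndarray, kset: KinshipSet,
             n_starts: int = 3, warm_start: np.ndarray | None = None,
             max_iter: int = 200, tol: float = 1e-8) -> PolygenicFit:
    """Maximize the restricted likelihood over (Sigma_G, sigma2_E).

    ``X`` is the fixed-effect design (a cell-means background design for
    the null model).  With ``warm_start`` (a previous fit's ``theta``)
    a single optimization from that point is run first and the grid of
    default starts is skipped when it converges.
    """
    y = np.asarray(y, float)
    X = np.atleast_2d(np.asarray(X, float))
    if X.shape[0] != y.shape[0]:
        X = X.T
    labels, gidx = _design_groups(kset)
    ng = len(labels)
    n = len(y)
    if n <= X.shape[1] + ng * (ng + 1) // 2 + 1:
        raise ModelError("too few lines for the number of parameters")

    s = float(np.std(y)) or 1.0
    ys = y / s
    obj = _StructuredObjective(ys, X, kset.K, gidx, ng)

    def starts():
        if warm_start is not None:
            th = np.array(warm_start, float)
            th[:-1] = th[:-1] / s            # back to unit scale
            th[-1] = th[-1] - 2 * np.log(s)
            yield th
        for h2 in (0.5, 0.2, 0.8)[: max(n_starts, 1)]:
            sigma0 = h2 * (0.6 * np.eye(ng) + 0.4 * np.ones((ng, ng)))
            L0 = np.linalg.cholesky(sigma0 + 1e-9 * np.eye(ng))
            yield np.concatenate([L0[obj.tril], [np.log(1 - h2)]])

    best = None
    n_tried = 0
    bounds = [(-20.0, 20.0)] * (obj.n_par - 1) + [(-30.0, 10.0)]
    for th0 in starts():
        res = optimize.minimize(
            obj, np.clip(th0, [b[0] for b in bounds], [b[1] for b in bounds]),
            jac=True, method="L-BFGS-B", bounds=bounds,
            options={"maxiter": max_iter, "ftol": tol * 1e-2, "gtol": 1e-7})
        n_tried += 1
        if best is None or res.fun < best.fun - 1e-9:
            best = res
        if warm_start is not None and n_tried == 1 and res.success:
            break

    theta = best.x
    sigma, _ = obj.sigma_from(theta)
    s2e = float(np.exp(theta[-1]))
    V = obj.build_v(theta)
    pieces = _reml_pieces(V, X, ys)
    if pieces is None:
        raise ModelError("singular covariance at the optimum")
    nll, _P, _u, beta, covb = pieces

    dvar = np.diag(sigma)
    corr = sigma / np.sqrt(np.outer(np.clip(dvar, 1e-300, None),
                                    np.clip(dvar, 1e-300, None)))
    boundary = bool((dvar < 1e-6).any()
                    or (np.abs(corr[np.triu_indices(ng, 1)]) > 0.999).any())
    if not best.success:
        log.warning("ReML did not converge: %s", best.message)

    theta_orig = theta.copy()
    theta_orig[:-1] *= s
    theta_orig[-1] += 2 * np.log(s)
    return PolygenicFit(
        groups=labels,
        Sigma_G=sigma * s ** 2,
        sigma2_E=s2e * s ** 2,
        beta=beta * s,
        beta_cov=covb * s ** 2,
        loglik=-nll - 0.5 * (len(y) - X.shape[1]) * 2 * np.log(s),
        converged=bool(best.success),
        n_iter=int(best.nit),
        boundary=boundary,
        theta=theta_orig,
    )


def restricted_loglik_at(y, X, kset: KinshipSet, Sigma_G, sigma2_E) -> float:
    """Restricted log-likelihood at user-supplied parameter values."""
    labels, gidx = _design_groups(kset)
    Sigma_G = np.atleast_2d(np.asarray(Sigma_G, float))
    V = Sigma_G[gidx[:, None], gidx[None, :]] * kset.K
    V[np.diag_indices_from(V)] += sigma2_E
    pieces = _reml_pieces(V, np.atleast_2d(np.asarray(X, float)), np.asarray(y, float))
    if pieces is None:
        raise ModelError("supplied parameters give a singular covariance")
    return -pieces[0]


# ---------------------------------------------------------------------------
# generic variance components (V = sum_c sigma2_c B_c)
# ---------------------------------------------------------------------------


class _ComponentsObjective:
    """Negative REML log-likelihood for V = sum_c exp(t_c) * B_c."""

    def __init__(self, y, X, comps):
        self.y = np.asarray(y, float)
        self.X = np.atleast_2d(np.asarray(X, float))
        if self.X.shape[0] != len(self.y):
            self.X = self.X.T
        self.comps = [np.asarray(B, float) for B in comps]
        self.n_par = len(comps)

    def build_v(self, t):
        V = np.zeros_like(self.comps[0])
        for tc, B in zip(t, self.comps):
            V += np.exp(tc) * B
        return V

    def __call__(self, t):
        V = self.build_v(t)
        pieces = _reml_pieces(V, self.X, self.y)
        if pieces is None:
            return 1e10, np.zeros(self.n_par)
        nll, P, u, _b, _c = pieces
        grad = np.array([
            0.5 * np.exp(tc) * (np.sum(P * B) - float(u @ (B @ u)))
            for tc, B in zip(t, self.comps)
        ])
        return nll, grad


@dataclass
class ComponentsFit:
    """ReML fit of a plain variance-components model."""

    names: list
    variances: dict
    loglik: float
    converged: bool
    boundary: bool


def reml_components(y, X, comps, names, max_iter: int = 200,
                    tol: float = 1e-8) -> ComponentsFit:
    """ReML for a sum-of-components covariance (log-variance parameters).

    Components driven to the lower parameter bound (variance ~ 0) are
    flagged as boundary estimates, as expected under a null of absent
    variance.
    """
    y = np.asarray(y, float)
    s = float(np.std(y)) or 1.0
    obj = _ComponentsObjective(y / s, X, comps)
    ncomp = len(comps)
    lo, hi = -30.0, 10.0
    best = None
    for frac in (1.0 / ncomp, 0.6):
        t0 = np.full(ncomp, np.log(frac))
        res = optimize.minimize(
            obj, t0, jac=True, method="L-BFGS-B",
            bounds=[(lo, hi)] * ncomp,
            options={"maxiter": max_iter, "ftol": tol * 1e-2, "gtol": 1e-7})
        if best is None or res.fun < best.fun - 1e-9:
            best = res
    variances = {nm: float(np.exp(t)) * s ** 2 for nm, t in zip(names, best.x)}
    n, p = len(y), obj.X.shape[1]
    loglik = -best.fun - (n - p) * np.log(s)
    boundary = bool((best.x <= lo + 1e-6).any())
    return ComponentsFit(list(names), variances, loglik,
                         bool(best.success), boundary)


# ---------------------------------------------------------------------------
# plugged covariances and GLS
# ---------------------------------------------------------------------------


@dataclass
class PluggedCovariance:
    """G and R assembled from a converged null fit; V = G + R."""

    G: np.ndarray
    R: np.ndarray

    @property
    def V(self) -> np.ndarray:
        return self.G + self.R


def plug_covariances(fit: PolygenicFit, kset: KinshipSet) -> PluggedCovariance:
    labels, gidx = _design_groups(kset)
    if labels != fit.groups:
        raise ModelError("kinship backgrounds do not match the fit")
    G = fit.Sigma_G[gidx[:, None], gidx[None, :]] * kset.K
    # Cholesky parameterization keeps Sigma_G PSD, so G is PSD already;
    # guard anyway against numerically indefinite assemblies.
    w = np.linalg.eigvalsh((G + G.T) / 2)
    if w.min() < -1e-8 * max(w.max(), 1.0):
        log.warning("assembled G indefinite (min eig %.3g); projecting to PSD",
                    w.min())
        vals, vecs = np.linalg.eigh((G + G.T) / 2)
        G = (vecs * np.clip(vals, 0, None)) @ vecs.T
    R = fit.sigma2_E * np.eye(kset.K.shape[0])
    return PluggedCovariance(G, R)


@dataclass
class GLSFit:
    beta: np.ndarray
    cov_unscaled: np.ndarray      # pinv(X' V^-1 X)
    scale: float                  # global variance scale (1 when frozen)
    rank: int
    resid_df: int
    _rowspace: np.ndarray = field(repr=False, default=None)  # A+ A projector

    @property
    def cov(self) -> np.ndarray:
        return self.scale * self.cov_unscaled

    def estimable(self, c: np.ndarray, tol: float = 1e-8) -> bool:
        c = np.asarray(c, float)
        nc = np.linalg.norm(c)
        if nc == 0:
            return True
        return bool(np.linalg.norm(self._rowspace @ c - c) <= tol * nc)


def gls_fit(y: np.ndarray, X: np.ndarray, V: np.ndarray | None = None,
            Vi: np.ndarray | None = None, reestimate_scale: bool = False,
            rcond: float = 1e-10) -> GLSFit:
    """Generalized least squares with a fixed Moore-Penrose convention.

    ``X`` may be rank-deficient (e.g. intercept plus a full set of state
    indicators); estimable functions of beta are invariant to the
    generalized inverse used.  With ``reestimate_scale`` the covariance
    of beta is multiplied by the residual quadratic form over its
    degrees of freedom (the per-SNP global variance rescale of the
    two-step strategy).
    """
    y = np.asarray(y, float)
    X = np.atleast_2d(np.asarray(X, float))
    if Vi is None:
        Vi = np.eye(len(y)) if V is None else np.linalg.inv(V)
    ViX = Vi @ X
    A = X.T @ ViX
    Apinv = np.linalg.pinv(A, rcond=rcond, hermitian=True)
    beta = Apinv @ (ViX.T @ y)
    # estimability is a property of the design alone: project onto row(X)
    _u, sv, vt = np.linalg.svd(X, full_matrices=False)
    rank = int(np.sum(sv > max(X.shape) * np.finfo(float).eps * sv[0]))
    rowspace = vt[:rank].T @ vt[:rank]
    resid_df = len(y) - rank
    scale = 1.0
    if reestimate_scale:
        r = y - X @ beta
        scale = float(r @ (Vi @ r)) / max(resid_df, 1)
    return GLSFit(beta, Apinv, scale, rank, resid_df, _rowspace=rowspace)


@dataclass
class ContrastResult:
    estimate: float
    se: float
    wald: float
    p: float


def wald_contrast(fit: GLSFit, c: np.ndarray) -> ContrastResult:
    """Wald test of H0: c' beta = 0 against chi-square(1)."""
    c = np.asarray(c, float)
    if not fit.estimable(c):
        raise ModelError("contrast is not estimable under this design")
    est = float(c @ fit.beta)
    var = float(c @ fit.cov @ c)
    if var <= 0:
        if abs(est) > 1e-12:
            raise ModelError("zero-variance contrast with nonzero estimate")
        return ContrastResult(0.0, 0.0, 0.0, 1.0)
    w = est * est / var
    return ContrastResult(est, float(np.sqrt(var)), w,
                          float(stats.chi2.sf(w, df=1)))
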