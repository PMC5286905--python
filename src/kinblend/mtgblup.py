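"""Multi-trait GBLUP: REML estimation and breeding-value prediction.

The model for T traits on n individuals is, in stacked (individual-major)
form::

    y = (1_n (x) I_T) mu + g + e,
    g ~ N(0, K (x) Q),    e ~ N(0, I_n (x) R),

where K is the (pedigree, genomic, or blended) kinship kernel, Q and R are
the T x T genetic and residual covariance matrices among traits, and mu
holds per-trait intercepts (all other fixed effects are removed upstream by
pre-correction).

The restricted likelihood is evaluated through the eigendecomposition
``K = U D U'``: rotating the n x T phenotype matrix by ``U'`` decouples the
nT-dimensional Gaussian into n independent T-dimensional blocks with
covariance ``d_i Q + R``, which makes each likelihood evaluation O(n T^3)
instead of O((nT)^3).  REML maximization runs a quasi-Newton search over
Cholesky factors of Q and R (positive semidefiniteness by construction)
from several starting points; standard errors come from the inverse
numerical Hessian with delta-method mapping to heritabilities and
correlations.

Phenotypes are standardized per trait internally and estimates mapped back,
so results are equivariant under rescaling of any trait.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize
from statsmodels.tools import numdiff

from .kinship import KinshipMatrix

logger = logging.getLogger("kinblend")

__all__ = [
    "MTModelSpec",
    "TraitCovariances",
    "MTModelFit",
    "DGVPrediction",
    "restricted_loglik",
    "reml_fit",
    "derive_parameters",
    "predict_dgv",
]

_LOG2PI = np.log(2.0 * np.pi)


@dataclass
class MTModelSpec:
    """Phenotypes plus an aligned kinship kernel.

    ``phenotypes`` is indexed by individual id with one numeric column per
    trait and no missing cells (every trait observed on every individual).
    The kinship matrix must cover all phenotype ids; it is subset and
    reordered to match them.
    """

    phenotypes: pd.DataFrame
    kinship: KinshipMatrix
    _eig: tuple | None = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        if self.phenotypes.isna().any().any():
            raise ValueError("phenotypes contain missing cells; the model "
                             "requires every trait on every individual")
        ids = [str(i) for i in self.phenotypes.index]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate individual ids in phenotypes")
        self.kinship = self.kinship.align(ids)

    @property
    def ids(self) -> list[str]:
        return [str(i) for i in self.phenotypes.index]

    @property
    def trait_names(self) -> list[str]:
        return [str(c) for c in self.phenotypes.columns]

    @property
    def Y(self) -> np.ndarray:
        return self.phenotypes.to_numpy(dtype=float)

    @property
    def n(self) -> int:
        return len(self.phenotypes)

    @property
    def n_traits(self) -> int:
        return self.phenotypes.shape[1]

    def eig(self) -> tuple[np.ndarray, np.ndarray]:
        """Cached eigendecomposition of K (ascending eigenvalues)."""
        if self._eig is None:
            d, U = np.linalg.eigh(self.kinship.values)
            self._eig = (np.maximum(d, 0.0), U)
        return self._eig


@dataclass
class TraitCovariances:
    """Among-trait genetic (Q) and residual (R) covariances plus intercepts."""

    Q: np.ndarray
    R: np.ndarray
    mu: np.ndarray

    def __post_init__(self) -> None:
        self.Q = np.asarray(self.Q, dtype=float)
        self.R = np.asarray(self.R, dtype=float)
        self.mu = np.asarray(self.mu, dtype=float)
        T = self.Q.shape[0]
        if self.Q.shape != (T, T) or self.R.shape != (T, T) or self.mu.shape != (T,):
            raise ValueError("inconsistent Q/R/mu dimensions")
        if not (np.allclose(self.Q, self.Q.T, atol=1e-8)
                and np.allclose(self.R, self.R.T, atol=1e-8)):
            raise ValueError("Q and R must be symmetric")


@dataclass
class MTModelFit:
    """A converged (or boundary-flagged) REML fit."""

    spec: MTModelSpec
    params: TraitCovariances
    restricted_loglik: float
    heritabilities: pd.Series
    genetic_corr: pd.DataFrame
    residual_corr: pd.DataFrame
    phenotypic_corr: pd.DataFrame
    se: pd.Series
    converged: bool
    n_iter: int
    boundary: bool

    def summary(self) -> pd.DataFrame:
        """Long-format (parameter, estimate, SE) table."""
        traits = self.spec.trait_names
        rows = []
        for t, name in enumerate(traits):
            rows.append((f"h2:{name}", self.heritabilities.iloc[t],
                         self.se.get(f"h2:{name}", np.nan)))
        for i in range(len(traits)):
            for j in range(i + 1, len(traits)):
                pair = f"{traits[i]}:{traits[j]}"
                rows.append((f"r_G:{pair}", self.genetic_corr.iloc[i, j],
                             self.se.get(f"r_G:{pair}", np.nan)))
                rows.append((f"r_e:{pair}", self.residual_corr.iloc[i, j],
                             self.se.get(f"r_e:{pair}", np.nan)))
                rows.append((f"r_P:{pair}", self.phenotypic_corr.iloc[i, j],
                             self.se.get(f"r_P:{pair}", np.nan)))
        for i in range(len(traits)):
            for j in range(i, len(traits)):
                rows.append((f"Q:{traits[i]}:{traits[j]}", self.params.Q[i, j],
                             self.se.get(f"Q:{traits[i]}:{traits[j]}", np.nan)))
                rows.append((f"R:{traits[i]}:{traits[j]}", self.params.R[i, j],
                             self.se.get(f"R:{traits[i]}:{traits[j]}", np.nan)))
        return pd.DataFrame(rows, columns=["parameter", "estimate", "se"])


@dataclass
class DGVPrediction:
    """Predicted breeding values (direct genomic values) for target ids."""

    values: pd.DataFrame
    source_fit: MTModelFit

    @property
    def ids(self) -> list[str]:
        return [str(i) for i in self.values.index]


# ---------------------------------------------------------------------------
# likelihood machinery

def _core_loglik(
    d: np.ndarray, Yt: np.ndarray, u: np.ndarray, Q: np.ndarray, R: np.ndarray
) -> tuple[float, np.ndarray]:
    """Restricted log-likelihood and GLS intercepts in rotated coordinates.

    ``d`` are the eigenvalues of K, ``Yt = U' Y`` the rotated phenotypes,
    and ``u = U' 1`` the rotated intercept design; each individual block i
    has covariance ``Sigma_i = d_i Q + R``.
    """
    n, T = Yt.shape
    Sigma = d[:, None, None] * Q + R
    try:
        L = np.linalg.cholesky(Sigma)
    except np.linalg.LinAlgError:
        return -np.inf, np.full(T, np.nan)
    logdetV = 2.0 * np.sum(np.log(np.einsum("ijj->ij", L)))
    Sinv = np.linalg.inv(Sigma)
    XtViX = np.einsum("i,ijk->jk", u * u, Sinv)
    XtViy = np.einsum("i,ijk,ik->j", u, Sinv, Yt)
    sign, logdetX = np.linalg.slogdet(XtViX)
    if sign <= 0:
        return -np.inf, np.full(T, np.nan)
    beta = np.linalg.solve(XtViX, XtViy)
    E = Yt - u[:, None] * beta
    quad = np.einsum("ij,ijk,ik->", E, Sinv, E)
    ll = -0.5 * ((n - 1) * T * _LOG2PI + logdetV + logdetX + quad)
    return float(ll), beta


def _core_loglik_grad(
    d: np.ndarray, Yt: np.ndarray, u: np.ndarray, Q: np.ndarray, R: np.ndarray
) -> tuple[float, np.ndarray, np.ndarray]:
    """Restricted log-likelihood with its analytic gradient wrt Q and R.

    Uses the standard REML identity ``dl/dV_theta = -0.5 [tr(P dV) -
    y'P dV P y]`` with ``P y = V^-1 (y - X beta_gls)``, evaluated blockwise
    in the rotated coordinates; ``dV/dQ_ab = K (x) E_ab`` and
    ``dV/dR_ab = I (x) E_ab`` make both trace terms sums of T x T blocks.
    """
    n, T = Yt.shape
    Sigma = d[:, None, None] * Q + R
    try:
        L = np.linalg.cholesky(Sigma)
    except np.linalg.LinAlgError:
        return -np.inf, np.full((T, T), np.nan), np.full((T, T), np.nan)
    logdetV = 2.0 * np.sum(np.log(np.einsum("ijj->ij", L)))
    Sinv = np.linalg.inv(Sigma)
    XtViX = np.einsum("i,ijk->jk", u * u, Sinv)
    XtViy = np.einsum("i,ijk,ik->j", u, Sinv, Yt)
    sign, logdetX = np.linalg.slogdet(XtViX)
    if sign <= 0:
        return -np.inf, np.full((T, T), np.nan), np.full((T, T), np.nan)
    Minv = np.linalg.inv(XtViX)
    beta = Minv @ XtViy
    E = Yt - u[:, None] * beta
    Pv = np.einsum("ijk,ik->ij", Sinv, E)  # rows of P y
    quad = np.einsum("ij,ij->", E, Pv)
    ll = -0.5 * ((n - 1) * T * _LOG2PI + logdetV + logdetX + quad)
    # trace(P dV) and quadratic terms, weights d_i (for Q) and 1 (for R)
    SMS = np.einsum("ijk,kl,ilm->ijm", Sinv, Minv, Sinv)
    grads = []
    for w in (d, np.ones(n)):
        tr_term = (
            np.einsum("i,ijk->jk", w, Sinv)
            - np.einsum("i,ijk->jk", w * u * u, SMS)
        )
        quad_term = np.einsum("i,ij,ik->jk", w, Pv, Pv)
        grads.append(-0.5 * (tr_term - quad_term))
    return float(ll), grads[0], grads[1]


def restricted_loglik(spec: MTModelSpec, params: TraitCovariances) -> float:
    """REML log-likelihood of ``y ~ N((1 (x) I) mu, K (x) Q + I (x) R)``.

    The value includes the Gaussian constant and the fixed-effect
    log-determinant correction, so it is directly comparable with the dense
    formula ``-0.5 [ (nT - T) log 2pi + log|V| + log|X'V^-1 X| + y'Py ]``.
    A singular individual block yields ``-inf`` rather than an exception.
    """
    d, U = spec.eig()
    Yt = U.T @ spec.Y
    u = U.T @ np.ones(spec.n)
    ll, _ = _core_loglik(d, Yt, u, params.Q, params.R)
    return ll


def _tril_pack(L: np.ndarray) -> np.ndarray:
    return L[np.tril_indices(L.shape[0])]


def _tril_unpack(v: np.ndarray, T: int) -> np.ndarray:
    L = np.zeros((T, T))
    L[np.tril_indices(T)] = v
    return L


def _theta_to_QR(theta: np.ndarray, T: int) -> tuple[np.ndarray, np.ndarray]:
    k = T * (T + 1) // 2
    Lq = _tril_unpack(theta[:k], T)
    Lr = _tril_unpack(theta[k:], T)
    return Lq @ Lq.T, Lr @ Lr.T


def _safe_chol(M: np.ndarray) -> np.ndarray:
    w = np.linalg.eigvalsh(M)[0]
    if w <= 1e-10:
        M = M + (1e-8 + max(0.0, -w)) * np.eye(M.shape[0])
    return np.linalg.cholesky(M)


def derive_parameters(params: TraitCovariances, trait_names=None) -> dict:
    """Heritabilities and genetic / residual / phenotypic correlations.

    ``h2_t = Q_tt / (Q_tt + R_tt)``; correlations from Q, R and Q + R.
    Zero variances give NaN entries (logged).
    """
    Q, R = params.Q, params.R
    T = Q.shape[0]
    names = list(trait_names) if trait_names is not None else [f"trait{i+1}" for i in range(T)]

    def _corr(M: np.ndarray) -> np.ndarray:
        dgn = np.diag(M).copy()
        bad = dgn <= 0
        if bad.any():
            logger.warning("zero variance for trait(s) %s: correlations undefined",
                           [names[i] for i in np.nonzero(bad)[0]])
        dgn[bad] = np.nan
        s = np.sqrt(dgn)
        return M / np.outer(s, s)

    pvar = np.diag(Q) + np.diag(R)
    with np.errstate(invalid="ignore", divide="ignore"):
        h2 = np.where(pvar > 0, np.diag(Q) / pvar, np.nan)
        out = {
            "h2": pd.Series(h2, index=names, name="h2"),
            "r_G": pd.DataFrame(_corr(Q), index=names, columns=names),
            "r_e": pd.DataFrame(_corr(R), index=names, columns=names),
            "r_P": pd.DataFrame(_corr(Q + R), index=names, columns=names),
        }
    return out


def _derived_vector(Q: np.ndarray, R: np.ndarray) -> tuple[np.ndarray, list[str]]:
    """Flat vector of reportable statistics for delta-method SEs (on the
    standardized scale; entries of Q/R are rescaled by the caller)."""
    T = Q.shape[0]
    vals, labels = [], []
    pvar = np.diag(Q) + np.diag(R)
    for t in range(T):
        vals.append(np.diag(Q)[t] / pvar[t] if pvar[t] > 0 else np.nan)
        labels.append(("h2", t, t))
    with np.errstate(invalid="ignore", divide="ignore"):
        for kind, M in (("r_G", Q), ("r_e", R), ("r_P", Q + R)):
            s = np.sqrt(np.diag(M))
            for i in range(T):
                for j in range(i + 1, T):
                    vals.append(M[i, j] / (s[i] * s[j]))
                    labels.append((kind, i, j))
    for kind, M in (("Q", Q), ("R", R)):
        for i in range(T):
            for j in range(i, T):
                vals.append(M[i, j])
                labels.append((kind, i, j))
    return np.array(vals, dtype=float), labels


def reml_fit(
    spec: MTModelSpec,
    n_starts: int = 3,
    compute_se: bool = True,
    max_iter: int = 500,
) -> MTModelFit:
    """Maximize the restricted likelihood over Cholesky-parametrized Q, R.

    Multi-start L-BFGS-B (genetic share of the phenotypic covariance at
    50/10/90% for the three default starts); the best converged optimum
    wins.  Estimates on or near the Q boundary (smallest eigenvalue below
    1e-6 of trace) are flagged, not fatal.
    """
    n, T = spec.n, spec.n_traits
    if n <= T:
        raise ValueError(f"need more individuals ({n}) than traits ({T})")
    d, U = spec.eig()
    if np.ptp(d) < 1e-10 * max(1.0, d.max()):
        raise ValueError("kinship matrix is proportional to I: genetic and "
                         "residual covariances are not separable")
    Y = spec.Y
    scale = Y.std(axis=0, ddof=1)
    if np.any(scale <= 0):
        bad = [spec.trait_names[i] for i in np.nonzero(scale <= 0)[0]]
        raise ValueError(f"constant phenotype for trait(s) {bad}")
    Ys = Y / scale
    Yt = U.T @ Ys
    u = U.T @ np.ones(n)

    S = np.cov(Ys, rowvar=False).reshape(T, T)

    k = T * (T + 1) // 2
    tril = np.tril_indices(T)

    def negll(theta: np.ndarray) -> float:
        Q, R = _theta_to_QR(theta, T)
        ll, _ = _core_loglik(d, Yt, u, Q, R)
        return np.inf if not np.isfinite(ll) else -ll

    def negll_grad(theta: np.ndarray):
        Lq = _tril_unpack(theta[:k], T)
        Lr = _tril_unpack(theta[k:], T)
        ll, dQ, dR = _core_loglik_grad(d, Yt, u, Lq @ Lq.T, Lr @ Lr.T)
        if not np.isfinite(ll):
            return np.inf, np.zeros_like(theta)
        # chain rule through Q = Lq Lq': dl/dLq = 2 (dl/dQ) Lq
        g = np.concatenate(
            [-(2.0 * dQ @ Lq)[tril], -(2.0 * dR @ Lr)[tril]]
        )
        return -ll, g

    fracs = (0.5, 0.1, 0.9)[:n_starts] or (0.5,)
    best = None
    start_lls = []
    n_iter_total = 0
    for f in fracs:
        theta0 = np.concatenate(
            [_tril_pack(_safe_chol(f * S)), _tril_pack(_safe_chol((1 - f) * S))]
        )
        start_lls.append(-negll(theta0))
        res = optimize.minimize(
            negll_grad, theta0, jac=True, method="L-BFGS-B",
            options={"maxiter": max_iter, "ftol": 1e-13, "gtol": 1e-8},
        )
        n_iter_total += res.nit
        if best is None or res.fun < best.fun:
            best = res
    assert best is not None
    if not np.isfinite(best.fun):
        raise RuntimeError("REML failed to converge from every start "
                           f"(best objective {best.fun})")
    # gradient tolerance relative to the objective scale (|logL| grows ~n)
    grad_norm = float(np.linalg.norm(best.jac))
    grad_tol = 1e-5 * max(1.0, abs(best.fun))
    converged = bool(best.success) and grad_norm < max(grad_tol, 1e-2)
    if not converged:
        logger.warning("REML convergence flag not met (success=%s, |grad|=%.2e)",
                       best.success, grad_norm)

    theta_hat = best.x
    Qs, Rs = _theta_to_QR(theta_hat, T)
    ll_hat, beta_s = _core_loglik(d, Yt, u, Qs, Rs)
    # map back from the standardized scale; the restricted likelihood picks
    # up a Jacobian term of (n-1) log s_t per trait (n-1 error contrasts)
    ll_hat = ll_hat - (n - 1) * float(np.sum(np.log(scale)))
    D = np.outer(scale, scale)
    Q_hat, R_hat = Qs * D, Rs * D
    mu_hat = beta_s * scale
    params = TraitCovariances(Q=Q_hat, R=R_hat, mu=mu_hat)
    derived = derive_parameters(params, spec.trait_names)
    boundary = bool(np.linalg.eigvalsh(Qs)[0] < 1e-6 * max(np.trace(Qs), 1e-300))
    if boundary:
        logger.info("genetic covariance estimate is at or near the PSD boundary")

    se = pd.Series(dtype=float)
    if compute_se:
        se = _delta_se(theta_hat, negll, T, scale, spec.trait_names)

    return MTModelFit(
        spec=spec,
        params=params,
        restricted_loglik=float(ll_hat),
        heritabilities=derived["h2"],
        genetic_corr=derived["r_G"],
        residual_corr=derived["r_e"],
        phenotypic_corr=derived["r_P"],
        se=se,
        converged=converged,
        n_iter=int(n_iter_total),
        boundary=boundary,
    )


def _delta_se(theta_hat, negll, T, scale, trait_names) -> pd.Series:
    """Asymptotic SEs: inverse numerical Hessian on the unconstrained
    parametrization, delta-method mapped to the reported statistics."""
    try:
        H = numdiff.approx_hess1(theta_hat, negll)
        cov_theta = np.linalg.pinv(0.5 * (H + H.T))
    except Exception:  # singular / non-finite Hessian near boundaries
        logger.warning("Hessian evaluation failed; SEs unavailable")
        return pd.Series(dtype=float)

    def stat_vec(theta: np.ndarray) -> np.ndarray:
        Q, R = _theta_to_QR(theta, T)
        v, _ = _derived_vector(Q, R)
        return v

    vals, labels = _derived_vector(*_theta_to_QR(theta_hat, T))
    J = numdiff.approx_fprime(theta_hat, stat_vec)
    var = np.einsum("ij,jk,ik->i", J, cov_theta, J)
    se = np.sqrt(np.maximum(var, 0.0))
    names = list(trait_names)
    out = {}
    for (kind, i, j), s, v in zip(labels, se, vals):
        if kind == "h2":
            key, fac = f"h2:{names[i]}", 1.0
        elif kind in ("Q", "R"):
            key, fac = f"{kind}:{names[i]}:{names[j]}", scale[i] * scale[j]
        else:
            key, fac = f"{kind}:{names[i]}:{names[j]}", 1.0
        out[key] = s * fac if np.isfinite(v) else np.nan
    return pd.Series(out)


def predict_dgv(
    fit: MTModelFit,
    K_full: KinshipMatrix,
    train_ids: list[str],
    target_ids: list[str],
) -> DGVPrediction:
    """Multi-trait BLUP of breeding values for ``target_ids``.

    ``ghat_target = (K_target,train (x) Q) V_train^-1 (y_train - X mu)``,
    the conditional mean of the target genetic values given training
    phenotypes, computed through the eigendecomposition of the training
    block of K.  Target phenotypes never enter the computation, so held-out
    evaluation is leakage-free by construction.
    """
    train_ids = [str(i) for i in train_ids]
    target_ids = [str(i) for i in target_ids]
    if set(train_ids) != set(fit.spec.ids):
        raise ValueError("train_ids must be exactly the individuals the model "
                         "was fitted on")
    Q, R, mu = fit.params.Q, fit.params.R, fit.params.mu
    Y_train = fit.spec.phenotypes.loc[train_ids].to_numpy(dtype=float)

    index = {x: i for i, x in enumerate(K_full.ids)}
    missing = [x for x in train_ids + target_ids if x not in index]
    if missing:
        raise KeyError(f"ids absent from the full kinship matrix: {missing[:5]}")
    it = np.array([index[x] for x in train_ids])
    ig = np.array([index[x] for x in target_ids])
    K_tt = K_full.values[np.ix_(it, it)]
    K_ct = K_full.values[np.ix_(ig, it)]

    dd, U = np.linalg.eigh(K_tt)
    dd = np.maximum(dd, 0.0)
    E = Y_train - mu
    Et = U.T @ E
    Sigma = dd[:, None, None] * Q + R
    alpha = np.linalg.solve(Sigma, Et[:, :, None])[:, :, 0]
    M = U @ alpha  # rows of V_train^-1 (y - X mu), individual-major
    ghat = K_ct @ M @ Q
    values = pd.DataFrame(ghat, index=target_ids, columns=fit.spec.trait_names)
    values.index.name = "id"
    return DGVPrediction(values=values, source_fit=fit)
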