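"""Laplace-approximation logistic GLMM with crossed random intercepts.

Implements the standard penalized-IRLS inner loop (jointly solving for fixed
effects and random-effect modes given the variance parameters) with a
Nelder-Mead outer optimization of the Laplace-approximated deviance over the
log variance components.  This is the nAGQ=1 strategy of mainstream
mixed-model software, specialized to crossed intercept-only random effects,
which is all the dyadic hosting model needs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.linalg as sla
import scipy.optimize as sopt
import scipy.sparse as sp

_EPS_W = 1e-10
_LOGVAR_LO, _LOGVAR_HI = -8.0, 4.0


@dataclass
class LaplaceFit:
    beta: np.ndarray
    u: np.ndarray
    var_components: dict[str, float]
    deviance: float  # -2 * Laplace log-likelihood
    aic: float
    converged: bool
    message: str = ""
    n_obs: int = 0
    group_sizes: dict[str, int] = field(default_factory=dict)


def _make_z(groups: dict[str, np.ndarray], n: int):
    """Sparse indicator matrix for the concatenated random effects."""
    blocks, sizes = [], {}
    for name, codes in groups.items():
        q = int(codes.max()) + 1
        sizes[name] = q
        blocks.append(
            sp.csr_matrix(
                (np.ones(n), (np.arange(n), codes)), shape=(n, q)
            )
        )
    Z = sp.hstack(blocks, format="csr") if blocks else None
    return Z, sizes


def _pirls(y, X, Z, dinv_diag, beta, u, max_iter=50, tol=1e-6):
    """Penalized IRLS for (beta, u) at fixed variance parameters."""
    n, p = X.shape
    q = Z.shape[1] if Z is not None else 0
    for it in range(max_iter):
        eta = X @ beta + (Z @ u if q else 0.0)
        mu = 1.0 / (1.0 + np.exp(-eta))
        w = np.maximum(mu * (1.0 - mu), _EPS_W)
        z = eta + (y - mu) / w

        Xw = X * w[:, None]
        A11 = X.T @ Xw
        b1 = Xw.T @ z
        if q:
            Zw = Z.multiply(w[:, None]).tocsr()
            A22 = (Z.T @ Zw).toarray()
            A22[np.diag_indices(q)] += dinv_diag
            A12 = np.asarray((Zw.T @ X).T)  # (p, q) without densifying Zw
            b2 = Zw.T @ z
            A = np.block([[A11, A12], [A12.T, A22]])
            b = np.concatenate([b1, b2])
        else:
            A = A11
            b = b1
        A[np.diag_indices_from(A)] += 1e-9
        try:
            cf = sla.cho_factor(A, lower=True, check_finite=False)
            sol = sla.cho_solve(cf, b, check_finite=False)
        except sla.LinAlgError:
            return beta, u, False
        new_beta, new_u = sol[:p], sol[p:]
        step = max(
            np.max(np.abs(new_beta - beta)) if p else 0.0,
            np.max(np.abs(new_u - u)) if q else 0.0,
        )
        beta, u = new_beta, new_u
        if step < tol * (1.0 + np.max(np.abs(beta)) if p else 1.0):
            return beta, u, True
    return beta, u, True  # accepted at max_iter; objective monitored outside


def _laplace_deviance(y, X, Z, dinv_diag, logdet_d, beta, u):
    eta = X @ beta + (Z @ u if Z is not None else 0.0)
    mu = 1.0 / (1.0 + np.exp(-eta))
    mu = np.clip(mu, 1e-12, 1 - 1e-12)
    ll = float(y @ np.log(mu) + (1 - y) @ np.log1p(-mu))
    if Z is None:
        return -2.0 * ll
    pen = float(u @ (dinv_diag * u))
    w = np.maximum(mu * (1.0 - mu), _EPS_W)
    Zw = Z.multiply(w[:, None]).tocsr()
    H = (Z.T @ Zw).toarray()
    q = H.shape[0]
    H[np.diag_indices(q)] += dinv_diag
    try:
        L = sla.cholesky(H, lower=True, check_finite=False)
    except sla.LinAlgError:
        return np.inf
    logdet_h = 2.0 * float(np.sum(np.log(np.diag(L))))
    # log det(D Z'WZ + I) = log det(Z'WZ + D^-1) + log det(D)
    return -2.0 * ll + pen + logdet_h + logdet_d


def fit_laplace(y: np.ndarray, X: np.ndarray,
                groups: dict[str, np.ndarray] | None = None,
                start_logvar: dict[str, float] | None = None,
                xtol: float = 0.02) -> LaplaceFit:
    """Fit a logistic model with optional crossed random intercepts.

    groups maps a component name to an integer code array (one code per row).
    With no groups this reduces to plain IRLS logistic regression.
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    groups = groups or {}

    if y.min() == y.max():
        return LaplaceFit(
            beta=np.full(p, np.nan), u=np.zeros(0), var_components={},
            deviance=np.nan, aic=np.nan, converged=False,
            message="degenerate outcome: all responses identical", n_obs=n,
        )

    Z, sizes = _make_z(groups, n)
    names = list(groups)
    k = len(names)

    if k == 0:
        beta, u, ok = _pirls(y, X, None, None, np.zeros(p), np.zeros(0))
        dev = _laplace_deviance(y, X, None, None, 0.0, beta, u)
        return LaplaceFit(beta=beta, u=u, var_components={}, deviance=dev,
                          aic=dev + 2 * p, converged=ok, n_obs=n)

    q_bounds = np.array([sizes[nm] for nm in names])

    state = {"beta": np.zeros(p), "u": np.zeros(int(q_bounds.sum()))}

    def dinv_of(logvar: np.ndarray):
        var = np.exp(logvar)
        dinv = np.concatenate(
            [np.full(sizes[nm], 1.0 / var[i]) for i, nm in enumerate(names)]
        )
        logdet_d = float(np.sum([sizes[nm] * logvar[i] for i, nm in enumerate(names)]))
        return dinv, logdet_d

    def objective(logvar: np.ndarray) -> float:
        logvar = np.clip(logvar, _LOGVAR_LO, _LOGVAR_HI)
        dinv, logdet_d = dinv_of(logvar)
        beta, u, ok = _pirls(y, X, Z, dinv, state["beta"], state["u"])
        if not ok:
            return np.inf
        state["beta"], state["u"] = beta, u
        return _laplace_deviance(y, X, Z, dinv, logdet_d, beta, u)

    x0 = np.array(
        [start_logvar.get(nm, 0.0) if start_logvar else 0.0 for nm in names]
    )
    if k == 1:
        res = sopt.minimize_scalar(
            lambda v: objective(np.array([v])),
            bounds=(_LOGVAR_LO, _LOGVAR_HI), method="bounded",
            options={"xatol": xtol},
        )
        xopt = np.array([res.x])
        ok = res.success
    else:
        # log-variance precision of ~0.03 is far below the sampling noise of
        # the components; tighter outer tolerances only burn refits.  The
        # initial simplex must span the plausible variance range — the
        # default (tiny steps around 0) stalls immediately.
        simplex = np.vstack([x0] + [x0 + 1.5 * e for e in np.eye(k)])
        res = sopt.minimize(
            objective, x0, method="Nelder-Mead",
            options={"xatol": max(xtol, 0.05), "fatol": 0.05, "maxfev": 150,
                     "initial_simplex": simplex},
        )
        xopt = np.clip(res.x, _LOGVAR_LO, _LOGVAR_HI)
        ok = res.success or res.fun < np.inf

    dev = objective(xopt)
    var = {nm: float(np.exp(v)) for nm, v in zip(names, xopt)}
    return LaplaceFit(
        beta=state["beta"], u=state["u"], var_components=var,
        deviance=float(dev), aic=float(dev + 2 * (p + k)),
        converged=bool(ok and np.isfinite(dev)),
        message="" if ok else "outer optimizer did not report convergence",
        n_obs=n, group_sizes=sizes,
    )
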