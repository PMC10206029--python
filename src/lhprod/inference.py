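"""Generic mixed-model machinery: Laplace-approximated marginal likelihood.

The models in this package share one estimation pattern, standard in
ecological state-space work (TMB-style): a joint negative log-density over
fixed effects :math:`\\theta` and random effects :math:`u` is integrated over
:math:`u` with a Laplace approximation,

.. math::

    -\\log L(\\theta) \\approx f(\\theta, \\hat u)
        + \\tfrac12 \\log\\det H(\\theta, \\hat u)
        - \\tfrac{n_u}{2} \\log 2\\pi,

where :math:`\\hat u` minimizes the joint NLL :math:`f` over :math:`u` and
:math:`H` is its Hessian in :math:`u`.  The marginal NLL is minimized over
:math:`\\theta`, and the fixed-effect covariance comes from the inverse of the
(finite-difference) Hessian of the marginal NLL, or from the cheaper
joint-precision Schur complement for large models.

No automatic-differentiation package is available in this environment, so the
inner problem relies on analytic gradients and sparse Hessians supplied by
each model module; small models may omit them and fall back to finite
differences.  All variance parameters are handled on the log scale and
correlations on the atanh scale via per-parameter transforms.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
from scipy.optimize import minimize
from scipy.sparse.linalg import splu
from scipy.special import expit, logit

from lhprod.errors import ConvergenceError

__all__ = [
    "MixedModelSpec",
    "FitResult",
    "laplace_marginal_nll",
    "fit",
    "mvn_bootstrap_draws",
]

_LOG2PI = np.log(2.0 * np.pi)

#: natural -> transformed, transformed -> natural
_TRANSFORMS = {
    "identity": (lambda x: x, lambda z: z),
    "log": (np.log, np.exp),
    "atanh": (np.arctanh, np.tanh),
    "logit": (logit, expit),
}

#: default box bounds on the transformed scale, per transform kind
_DEFAULT_BOUNDS = {
    "identity": (None, None),
    "log": (-9.0, 6.0),
    "atanh": (-4.0, 4.0),
    "logit": (-9.0, 9.0),
}


class MixedModelSpec:
    """Joint negative log-density of (fixed effects, random effects, data).

    Parameters
    ----------
    joint_nll
        Callable ``joint_nll(fixed, random) -> float`` where ``fixed`` is on
        the *transformed* scale (see ``transforms``).
    n_fixed, n_random
        Dimensions of the two blocks.  ``n_random`` may be zero, in which
        case the marginal NLL is the joint NLL itself.
    grad_random, hess_random
        Analytic first/second derivatives of ``joint_nll`` with respect to
        the random effects; ``hess_random`` must return a square scipy sparse
        matrix.  When omitted, finite differences are used (small models
        only).
    transforms
        Per-fixed-effect transform names: ``identity``, ``log``, ``atanh`` or
        ``logit``.  Defaults to identity for all.
    fixed_names, random_names
        Optional labels used in fit results and diagnostics.
    bounds
        Optional ``(lo, hi)`` pairs on the transformed scale; defaults depend
        on the transform.
    """

    def __init__(
        self,
        joint_nll,
        n_fixed,
        n_random,
        grad_random=None,
        hess_random=None,
        transforms=None,
        fixed_names=None,
        random_names=None,
        bounds=None,
    ):
        self.joint_nll = joint_nll
        self.n_fixed = int(n_fixed)
        self.n_random = int(n_random)
        self._grad_random = grad_random
        self._hess_random = hess_random
        if transforms is None:
            transforms = ["identity"] * self.n_fixed
        if len(transforms) != self.n_fixed:
            raise ValueError("transforms length must equal n_fixed")
        unknown = set(transforms) - set(_TRANSFORMS)
        if unknown:
            raise ValueError(f"unknown transform(s): {sorted(unknown)}")
        self.transforms = list(transforms)
        self.fixed_names = (
            list(fixed_names)
            if fixed_names is not None
            else [f"theta[{i}]" for i in range(self.n_fixed)]
        )
        self.random_names = random_names
        if bounds is None:
            bounds = [_DEFAULT_BOUNDS[t] for t in self.transforms]
        self.bounds = list(bounds)

    # -- transforms ----------------------------------------------------

    def transform(self, natural):
        """Map fixed effects from the natural to the transformed scale."""
        natural = np.asarray(natural, dtype=float)
        return np.array(
            [_TRANSFORMS[t][0](x) for t, x in zip(self.transforms, natural)]
        )

    def untransform(self, transformed):
        """Map fixed effects from the transformed to the natural scale."""
        transformed = np.asarray(transformed, dtype=float)
        return np.array(
            [_TRANSFORMS[t][1](z) for t, z in zip(self.transforms, transformed)]
        )

    # -- derivatives over the random effects ---------------------------

    def grad_random(self, fixed, random):
        if self._grad_random is not None:
            return np.asarray(self._grad_random(fixed, random), dtype=float)
        return _fd_grad(lambda u: self.joint_nll(fixed, u), random)

    def hess_random(self, fixed, random):
        if self._hess_random is not None:
            H = self._hess_random(fixed, random)
            return sp.csc_matrix(H)
        return sp.csc_matrix(
            _fd_jac(lambda u: self.grad_random(fixed, u), random)
        )


def _fd_grad(f, x, h=1e-6):
    x = np.asarray(x, dtype=float)
    g = np.empty_like(x)
    for i in range(x.size):
        hi = h * max(1.0, abs(x[i]))
        xp = x.copy()
        xm = x.copy()
        xp[i] += hi
        xm[i] -= hi
        g[i] = (f(xp) - f(xm)) / (2 * hi)
    return g


def _fd_jac(g, x, h=1e-5):
    x = np.asarray(x, dtype=float)
    n = x.size
    J = np.empty((n, n))
    for i in range(n):
        hi = h * max(1.0, abs(x[i]))
        xp = x.copy()
        xm = x.copy()
        xp[i] += hi
        xm[i] -= hi
        J[:, i] = (np.asarray(g(xp)) - np.asarray(g(xm))) / (2 * hi)
    return 0.5 * (J + J.T)


@dataclass
class _InnerResult:
    u: np.ndarray
    nll: float
    grad_norm: float
    n_iter: int
    logdet: float
    converged: bool
    lu: object = None
    ridge: float = 0.0


def _factor_spd(H, ridge=0.0, max_tries=12):
    """LU-factorize a (nominally SPD) sparse matrix, escalating a ridge until
    all pivots are positive.  Returns (lu, logdet, ridge_used)."""
    n = H.shape[0]
    eye = sp.identity(n, format="csc")
    H = sp.csc_matrix(H)
    base = max(1e-12, 1e-8 * abs(H.diagonal()).max())
    for _ in range(max_tries):
        try:
            # symmetric mode + diagonal pivoting: for an SPD matrix this is
            # Cholesky-like, so positive U pivots certify definiteness
            lu = splu(H + ridge * eye if ridge else H,
                      permc_spec="MMD_AT_PLUS_A", diag_pivot_thresh=0.0,
                      options={"SymmetricMode": True})
            d = lu.U.diagonal()
            if np.all(d > 0) and np.all(np.isfinite(d)):
                return lu, float(np.sum(np.log(d))), ridge
        except RuntimeError:
            pass
        ridge = base if ridge == 0.0 else ridge * 1000.0
    raise ConvergenceError("could not factorize inner Hessian as SPD")


def _inner_mode(spec, fixed, u0, tol=1e-8, max_iter=60):
    """Newton minimization of the joint NLL over the random effects."""
    u = np.array(u0, dtype=float)
    f = spec.joint_nll(fixed, u)
    if not np.isfinite(f):
        # a cold start can land in a non-finite region; retreat to zero
        u = np.zeros_like(u)
        f = spec.joint_nll(fixed, u)
        if not np.isfinite(f):
            raise ConvergenceError(
                "joint NLL non-finite at inner start", last_iterate=u
            )
    gn = np.inf
    lu = logdet = None
    ridge = 0.0
    it = 0
    for it in range(1, max_iter + 1):
        g = spec.grad_random(fixed, u)
        gn = float(np.max(np.abs(g))) if g.size else 0.0
        H = spec.hess_random(fixed, u)
        lu, logdet, ridge = _factor_spd(H, 0.0)
        if gn < tol:
            return _InnerResult(u, f, gn, it, logdet, True, lu, ridge)
        step = -lu.solve(g)
        slope = float(g @ step)
        if not np.isfinite(slope) or slope >= 0:
            step = -g
            slope = -float(g @ g)
        # Newton decrement below float resolution of f: converged in practice
        if -0.5 * slope < 1e-12 * (1.0 + abs(f)):
            return _InnerResult(u, f, gn, it, logdet, True, lu, ridge)
        # Armijo backtracking
        alpha = 1.0
        for _ in range(50):
            f_new = spec.joint_nll(fixed, u + alpha * step)
            if np.isfinite(f_new) and f_new <= f + 1e-4 * alpha * slope:
                break
            alpha *= 0.5
        else:
            # no acceptable step: treat current point as (non)converged mode
            return _InnerResult(u, f, gn, it, logdet, gn < 1e-4, lu, ridge)
        u = u + alpha * step
        f = f_new
    g = spec.grad_random(fixed, u)
    gn = float(np.max(np.abs(g))) if g.size else 0.0
    H = spec.hess_random(fixed, u)
    lu, logdet, ridge = _factor_spd(H, 0.0)
    return _InnerResult(u, f, gn, it, logdet, gn < 1e-4, lu, ridge)


def laplace_marginal_nll(
    spec, fixed, random_start=None, inner_tol=1e-8, inner_max_iter=60
):
    """Negative log of the Laplace-approximated marginal likelihood.

    Exact whenever the joint density is Gaussian in the random effects.  With
    ``n_random == 0`` this is simply the joint NLL at the fixed effects.
    """
    fixed = np.asarray(fixed, dtype=float)
    if spec.n_random == 0:
        return float(spec.joint_nll(fixed, np.empty(0)))
    if random_start is None:
        random_start = np.zeros(spec.n_random)
    res = _inner_mode(spec, fixed, random_start, inner_tol, inner_max_iter)
    if not res.converged and res.grad_norm > 1e-3:
        raise ConvergenceError(
            f"inner optimization did not converge (grad norm {res.grad_norm:.3g})",
            last_iterate=res.u,
            grad_norm=res.grad_norm,
        )
    return float(res.nll + 0.5 * res.logdet - 0.5 * spec.n_random * _LOG2PI)


@dataclass
class FitResult:
    """Maximum-marginal-likelihood fit of a :class:`MixedModelSpec`.

    ``fixed`` is on the transformed (optimization) scale, ``fixed_natural``
    on the natural scale; ``cov`` is the covariance of the transformed fixed
    effects.  ``random_mode`` holds the empirical-Bayes modes of the random
    effects at the solution.
    """

    spec: MixedModelSpec
    fixed: np.ndarray
    fixed_natural: np.ndarray
    fixed_names: list
    random_mode: np.ndarray
    nll: float
    cov: np.ndarray | None
    grad_norm: float
    converged: bool
    n_iter: int
    message: str
    boundary: list = field(default_factory=list)
    cov_method: str = "none"
    cov_flagged: bool = False

    def se(self):
        """Standard errors of the transformed fixed effects."""
        if self.cov is None:
            raise ValueError("fit was run without covariance computation")
        return np.sqrt(np.clip(np.diag(self.cov), 0.0, None))

    def summary(self):
        import pandas as pd

        out = {
            "name": self.fixed_names,
            "transformed": self.fixed,
            "estimate": self.fixed_natural,
        }
        if self.cov is not None:
            out["se_transformed"] = self.se()
        return pd.DataFrame(out)


class _LaplaceObjective:
    """Marginal NLL as a warm-started callable for the outer optimizer."""

    def __init__(self, spec, u0, inner_tol=1e-8, inner_max_iter=60,
                 fd_step=1e-4):
        self.spec = spec
        self.u = np.array(u0, dtype=float)
        self.inner_tol = inner_tol
        self.inner_max_iter = inner_max_iter
        self.fd_step = fd_step
        self.n_eval = 0

    def value(self, theta, update_warm=True, max_iter=None):
        self.n_eval += 1
        if self.spec.n_random == 0:
            v = self.spec.joint_nll(np.asarray(theta, float), np.empty(0))
            return float(v) if np.isfinite(v) else np.inf
        try:
            res = _inner_mode(
                self.spec, np.asarray(theta, float), self.u,
                self.inner_tol, max_iter or self.inner_max_iter,
            )
        except ConvergenceError:
            return np.inf
        if not np.isfinite(res.nll) or not np.isfinite(res.logdet):
            return np.inf
        if update_warm:
            self.u = res.u
        v = res.nll + 0.5 * res.logdet - 0.5 * self.spec.n_random * _LOG2PI
        return float(v)

    def value_and_grad(self, theta):
        theta = np.asarray(theta, dtype=float)
        f0 = self.value(theta)
        if not np.isfinite(f0):
            return np.inf, np.zeros_like(theta)
        u_base = self.u.copy()
        g = np.zeros_like(theta)
        for i in range(theta.size):
            h = self.fd_step * max(1.0, abs(theta[i]))
            tp = theta.copy()
            tp[i] += h
            self.u = u_base.copy()
            # the envelope property makes the marginal insensitive to small
            # inner-mode error, so two Newton steps suffice for FD points
            fp = self.value(tp, update_warm=False, max_iter=2)
            if not np.isfinite(fp):
                tp[i] = theta[i] - h
                fm = self.value(tp, update_warm=False, max_iter=2)
                g[i] = (f0 - fm) / h if np.isfinite(fm) else 0.0
            else:
                g[i] = (fp - f0) / h
        self.u = u_base
        return f0, g


def fit(
    spec,
    start,
    tol=1e-6,
    max_iter=300,
    inner_tol=1e-8,
    covariance="fd-marginal",
    fd_step=1e-4,
    random_start=None,
    boundary_tol=1e-4,
):
    """Maximize the Laplace-approximated marginal likelihood.

    Parameters
    ----------
    start
        Initial fixed effects on the transformed scale.
    tol
        Projected-gradient tolerance for the outer quasi-Newton (L-BFGS-B)
        optimization.
    covariance
        ``"fd-marginal"`` (finite-difference Hessian of the marginal NLL,
        inverted), ``"joint-schur"`` (Schur complement of the joint Hessian,
        the cheaper joint-precision approximation), or ``"none"``.
    """
    start = np.asarray(start, dtype=float)
    if start.size != spec.n_fixed:
        raise ValueError("start has wrong length")
    if not np.all(np.isfinite(start)):
        raise ValueError("start must be finite")
    u0 = (
        np.zeros(spec.n_random)
        if random_start is None
        else np.asarray(random_start, dtype=float)
    )
    obj = _LaplaceObjective(spec, u0, inner_tol=inner_tol, fd_step=fd_step)
    f_start = obj.value(start)
    if not np.isfinite(f_start):
        raise ConvergenceError("marginal NLL non-finite at start")

    res = minimize(
        obj.value_and_grad,
        start,
        jac=True,
        method="L-BFGS-B",
        bounds=spec.bounds,
        options={"maxiter": max_iter, "gtol": tol, "ftol": 1e-9},
    )
    theta = np.asarray(res.x, dtype=float)
    f_final = obj.value(theta)
    # guard the monotonicity contract even on abnormal line-search exits
    if f_final > f_start + 1e-9:
        theta = start
        f_final = f_start
    _, g_final = obj.value_and_grad(theta)
    grad_norm = float(np.max(np.abs(g_final))) if theta.size else 0.0

    boundary = []
    for i, (lo, hi) in enumerate(spec.bounds):
        if lo is not None and theta[i] - lo < boundary_tol:
            boundary.append(spec.fixed_names[i])
        if hi is not None and hi - theta[i] < boundary_tol:
            boundary.append(spec.fixed_names[i])

    cov = None
    cov_flagged = False
    if covariance in ("fd-marginal", "joint-schur") and spec.n_fixed > 0:
        if covariance == "fd-marginal":
            H = _fd_hessian(lambda t: obj.value(t, update_warm=True), theta)
        else:
            H = joint_schur_hessian(spec, theta, obj.u)
        # parameters pinned at a bound are treated as fixed: their rows and
        # columns are excluded from the inversion and reported with zero
        # variance (the standard sdreport convention for active bounds)
        free = np.array([spec.fixed_names[i] not in boundary
                         for i in range(spec.n_fixed)])
        cov = np.zeros_like(H)
        if free.any():
            sub, cov_flagged = _invert_hessian(H[np.ix_(free, free)])
            cov[np.ix_(free, free)] = sub

    return FitResult(
        spec=spec,
        fixed=theta,
        fixed_natural=spec.untransform(theta),
        fixed_names=list(spec.fixed_names),
        random_mode=obj.u.copy(),
        nll=float(f_final),
        cov=cov,
        grad_norm=grad_norm,
        converged=bool(res.success) or grad_norm < 10 * tol or bool(boundary),
        n_iter=int(res.nit),
        message=str(res.message),
        boundary=boundary,
        cov_method=covariance,
        cov_flagged=cov_flagged,
    )


def _fd_hessian(f, x, h=1e-2):
    """Central finite-difference Hessian from function values."""
    x = np.asarray(x, dtype=float)
    n = x.size
    hs = h * np.maximum(1.0, np.abs(x))
    f0 = f(x)
    H = np.empty((n, n))
    fp = np.empty(n)
    fm = np.empty(n)
    for i in range(n):
        xp = x.copy()
        xm = x.copy()
        xp[i] += hs[i]
        xm[i] -= hs[i]
        fp[i] = f(xp)
        fm[i] = f(xm)
        H[i, i] = (fp[i] - 2 * f0 + fm[i]) / hs[i] ** 2
    for i in range(n):
        for j in range(i + 1, n):
            xpp = x.copy()
            xpp[i] += hs[i]
            xpp[j] += hs[j]
            fpp = f(xpp)
            # one-sided cross difference reuses the axis evaluations
            H[i, j] = H[j, i] = (fpp - fp[i] - fp[j] + f0) / (hs[i] * hs[j])
    return 0.5 * (H + H.T)


def _invert_hessian(H):
    """Invert a Hessian into a covariance; pseudo-inverse + warning if the
    Hessian is not positive definite."""
    try:
        ev = np.linalg.eigvalsh(H)
        if np.all(ev > 0):
            cov = np.linalg.inv(H)
            return 0.5 * (cov + cov.T), False
    except np.linalg.LinAlgError:
        pass
    warnings.warn(
        "Hessian not positive definite; clipping small eigenvalues "
        "(flat/indeterminate directions get large variances)",
        RuntimeWarning,
    )
    ev, V = np.linalg.eigh(0.5 * (H + H.T))
    floor = 1e-8 * max(abs(ev).max(), 1.0)
    cov = (V / np.maximum(ev, floor)) @ V.T
    return 0.5 * (cov + cov.T), True


def joint_schur_hessian(spec, theta, u, fd_step=1e-4):
    """Approximate marginal-NLL Hessian via the joint-Hessian Schur complement.

    Equivalent to inverting the joint precision of (fixed, random) and reading
    off the fixed block; ignores the dependence of the Laplace log-determinant
    on the fixed effects, which is accurate for location-like parameters and a
    standard large-model shortcut.
    """
    theta = np.asarray(theta, dtype=float)
    n_t = theta.size
    if spec.n_random == 0:
        return _fd_hessian(lambda t: spec.joint_nll(t, np.empty(0)), theta)
    H_uu = sp.csc_matrix(spec.hess_random(theta, u))
    # mixed block by central FD of the analytic u-gradient over theta
    H_ut = np.empty((spec.n_random, n_t))
    for i in range(n_t):
        h = fd_step * max(1.0, abs(theta[i]))
        tp = theta.copy()
        tm = theta.copy()
        tp[i] += h
        tm[i] -= h
        H_ut[:, i] = (
            spec.grad_random(tp, u) - spec.grad_random(tm, u)
        ) / (2 * h)
    H_tt = _fd_hessian(lambda t: spec.joint_nll(t, u), theta, h=1e-4)
    lu, _, _ = _factor_spd(H_uu, 0.0)
    X = lu.solve(H_ut)
    S = H_tt - H_ut.T @ X
    return 0.5 * (S + S.T)


def conditional_random_sd(spec, theta, u, cov_theta, indices, fd_step=1e-4):
    """Standard errors of selected random effects.

    Combines the conditional curvature ``H_uu^{-1}`` with propagation of
    fixed-effect uncertainty through the mode shift ``du/dtheta = -H_uu^{-1}
    H_utheta`` (the joint-precision delta method used for penalized
    hyperparameters that are formally random effects).
    """
    indices = np.asarray(indices, dtype=int)
    H_uu = sp.csc_matrix(spec.hess_random(theta, u))
    lu, _, _ = _factor_spd(H_uu, 0.0)
    n_t = theta.size
    H_ut = np.empty((spec.n_random, n_t))
    for i in range(n_t):
        h = fd_step * max(1.0, abs(theta[i]))
        tp = theta.copy()
        tm = theta.copy()
        tp[i] += h
        tm[i] -= h
        H_ut[:, i] = (
            spec.grad_random(tp, u) - spec.grad_random(tm, u)
        ) / (2 * h)
    B = -lu.solve(H_ut)  # du/dtheta
    var = np.empty(indices.size)
    for j, k in enumerate(indices):
        e = np.zeros(spec.n_random)
        e[k] = 1.0
        cond = lu.solve(e)[k]
        prop = B[k] @ cov_theta @ B[k]
        var[j] = cond + prop
    return np.sqrt(np.clip(var, 0.0, None))


def mvn_bootstrap_draws(fit_or_mean, n_draws, seed, cov=None):
    """Seeded multivariate-normal parameter draws.

    Accepts a :class:`FitResult` (drawing on the transformed scale from its
    estimate/covariance) or an explicit ``(mean, cov)`` pair.  The empirical
    mean and covariance of the draws converge to the inputs as ``n_draws``
    grows; a zero covariance returns the point estimate in every row.
    """
    if n_draws < 2:
        raise ValueError("n_draws must be >= 2")
    if isinstance(fit_or_mean, FitResult):
        mean = fit_or_mean.fixed
        if cov is None:
            cov = fit_or_mean.cov
        if cov is None:
            raise ValueError("fit has no covariance; rerun fit with covariance")
    else:
        mean = np.asarray(fit_or_mean, dtype=float)
        if cov is None:
            raise ValueError("cov required when mean is an array")
    cov = np.asarray(cov, dtype=float)
    rng = np.random.default_rng(seed)
    if not np.any(cov):
        return np.tile(mean, (int(n_draws), 1))
    return rng.multivariate_normal(mean, cov, size=int(n_draws), method="svd")
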