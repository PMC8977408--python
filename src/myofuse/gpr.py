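"""Gaussian process regression with the rational quadratic kernel.

The covariance between feature vectors x, x' is

    k(x, x') = sigma^2 * (1 + r^2 / (2 * alpha * l^2))^(-alpha),
    r^2 = (x - x')^T (x - x'),

a scale mixture of squared-exponential kernels: alpha -> inf recovers the
squared exponential with length-scale l.  Hyperparameters (sigma, alpha, l,
observation noise SD) are fitted by maximizing the log marginal likelihood
with a multi-restart quasi-Newton search using analytic gradients in
log-parameter space.  Features and target are standardized from the training
rows; the mean function is the training-target mean (zero after
standardization).  Above a configurable block size the model trains on a
seeded subset of observations; the likelihood itself may additionally be
evaluated on a smaller subset to keep hyperparameter search cheap.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
from scipy import optimize
from scipy.linalg import cho_factor, cho_solve

__all__ = [
    "KernelParams",
    "OptConfig",
    "GPRModel",
    "DegenerateTargetError",
    "rq_kernel",
    "fit_gpr",
    "predict_mean",
    "save_model",
    "load_model",
]

_JITTER = 1e-10


class DegenerateTargetError(ValueError):
    """Training target has zero variance."""


@dataclass(frozen=True)
class KernelParams:
    """Rational quadratic kernel hyperparameters.

    sigma : signal SD (amplitude), output units.
    alpha : positive scale-mixture parameter (dimensionless).
    length_scale : l > 0, feature-space units.
    noise_sd : observation noise SD, output units (>= 0).
    """

    sigma: float
    alpha: float
    length_scale: float
    noise_sd: float

    def __post_init__(self):
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")
        if self.alpha <= 0:
            raise ValueError("alpha must be positive")
        if self.length_scale <= 0:
            raise ValueError("length_scale must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")


@dataclass(frozen=True)
class OptConfig:
    """Marginal-likelihood optimizer settings.

    grad_tol / step_tol : convergence tolerances (projected gradient and
        relative objective change).
    max_iter : iteration cap per restart.
    n_restarts : seeded random restarts of the search.
    block_size : above this many rows, train on a seeded subset this large.
    opt_subset : rows used for the marginal-likelihood search itself.
    """

    grad_tol: float = 1e-3
    step_tol: float = 1e-3
    max_iter: int = 1000
    n_restarts: int = 3
    block_size: int = 1000
    opt_subset: int = 400
    seed: int = 0


@dataclass
class GPRModel:
    """Fitted model: hyperparameters plus the cached training solve.

    ``params`` lives on the standardized feature/target scale; predictions
    are de-standardized back to output units.  The mean function is the
    (stored) training-target mean.
    """

    params: KernelParams
    X_train: np.ndarray  # standardized training inputs (prediction set)
    alpha_vec: np.ndarray  # (K + noise^2 I)^-1 y_std
    x_mean: np.ndarray
    x_sd: np.ndarray
    y_mean: float
    y_sd: float
    converged: bool = True
    log_marginal_likelihood: float = np.nan
    n_train_total: int = 0

    @property
    def n_train(self) -> int:
        return self.X_train.shape[0]


def rq_kernel(x: np.ndarray, x_prime: np.ndarray, params: KernelParams) -> float:
    """Rational quadratic covariance between two feature vectors."""
    x = np.asarray(x, dtype=float)
    x_prime = np.asarray(x_prime, dtype=float)
    if x.shape != x_prime.shape:
        raise ValueError("vectors must have equal length")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(x_prime))):
        raise ValueError("non-finite inputs")
    r2 = float(np.sum((x - x_prime) ** 2))
    base = 1.0 + r2 / (2.0 * params.alpha * params.length_scale**2)
    return float(params.sigma**2 * base ** (-params.alpha))


def _sq_dists(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    aa = np.sum(A * A, axis=1)[:, None]
    bb = np.sum(B * B, axis=1)[None, :]
    d2 = aa + bb - 2.0 * (A @ B.T)
    return np.maximum(d2, 0.0)


def _rq_gram(D2: np.ndarray, sigma: float, alpha: float, ell: float) -> np.ndarray:
    base = 1.0 + D2 / (2.0 * alpha * ell**2)
    return sigma**2 * base ** (-alpha)


def _nll_and_grad(theta: np.ndarray, D2: np.ndarray, y: np.ndarray):
    """Negative log marginal likelihood and gradient in log-parameters."""
    from scipy.linalg.lapack import dpotri

    log_s, log_a, log_l, log_n = theta
    sigma, alpha, ell, noise = np.exp((log_s, log_a, log_l, log_n))
    n = len(y)
    scaled = D2 / (2.0 * alpha * ell**2)
    logB = np.log1p(scaled)
    K = sigma**2 * np.exp(-alpha * logB)
    Ky = K.copy()
    Ky[np.diag_indices(n)] += noise**2 + _JITTER
    try:
        L, lower = cho_factor(Ky, lower=True, check_finite=False)
    except np.linalg.LinAlgError:
        return 1e25, np.zeros(4)
    a_vec = cho_solve((L, lower), y, check_finite=False)
    nll = (
        0.5 * float(y @ a_vec)
        + float(np.sum(np.log(np.diag(L))))
        + 0.5 * n * np.log(2.0 * np.pi)
    )
    # W = Ky^-1 - a a^T; dNLL/dtheta_j = 0.5 * sum(W * dK/dtheta_j)
    Kinv, info = dpotri(L, lower=lower)
    if info != 0:
        return 1e25, np.zeros(4)
    # dpotri fills only one triangle; mirror it into a full matrix
    tri = np.tril(Kinv) if lower else np.triu(Kinv)
    Kinv = tri + tri.T
    Kinv[np.diag_indices(n)] *= 0.5
    W = Kinv - np.outer(a_vec, a_vec)
    frac = scaled / (1.0 + scaled)  # (B - 1) / B
    dK_ds = 2.0 * K
    dK_dl = K * (2.0 * alpha * frac)
    dK_da = K * (alpha * (frac - logB))
    grad = np.array(
        [
            0.5 * np.sum(W * dK_ds),
            0.5 * np.sum(W * dK_da),
            0.5 * np.sum(W * dK_dl),
            0.5 * np.trace(W) * 2.0 * noise**2,
        ]
    )
    return nll, grad


_BOUNDS = [(-5.0, 5.0), (-5.0, 7.0), (-5.0, 8.0), (np.log(1e-3), 3.0)]


def _standardize(X: np.ndarray, y: np.ndarray):
    x_mean = X.mean(axis=0)
    x_sd = X.std(axis=0)
    x_sd = np.where(x_sd == 0.0, 1.0, x_sd)
    y_mean = float(y.mean())
    y_sd = float(y.std())
    return (X - x_mean) / x_sd, (y - y_mean) / y_sd, x_mean, x_sd, y_mean, y_sd


def fit_gpr(
    X: np.ndarray,
    y: np.ndarray,
    opt_cfg: OptConfig = OptConfig(),
    params: KernelParams = None,
) -> GPRModel:
    """Fit a rational quadratic GP to (X, y).

    If ``params`` is given (interpreted on the standardized scale), the
    hyperparameter search is skipped and only the prediction cache is built;
    otherwise the log marginal likelihood is maximized over
    (sigma, alpha, length_scale, noise_sd) with seeded multi-restarts.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    if X.ndim != 2 or X.shape[0] != len(y):
        raise ValueError("X must be (n, d) with n matching len(y)")
    if len(y) < 10:
        raise ValueError("need at least 10 training rows")
    if not (np.all(np.isfinite(X)) and np.all(np.isfinite(y))):
        raise ValueError("non-finite training data")
    if np.ptp(y) == 0.0:
        raise DegenerateTargetError("training target has zero variance")

    Xs, ys, x_mean, x_sd, y_mean, y_sd = _standardize(X, y)
    n = len(ys)
    rng = np.random.default_rng(int(opt_cfg.seed) & 0x7FFFFFFF)

    # prediction training set: everything, or a seeded block above the cap
    if n > opt_cfg.block_size:
        pred_idx = np.sort(rng.choice(n, opt_cfg.block_size, replace=False))
    else:
        pred_idx = np.arange(n)
    Xp, yp = Xs[pred_idx], ys[pred_idx]

    converged = True
    best_nll = np.inf
    if params is None:
        # hyperparameter search on a (possibly smaller) seeded subset
        if len(pred_idx) > opt_cfg.opt_subset:
            oi = np.sort(
                rng.choice(len(pred_idx), opt_cfg.opt_subset, replace=False)
            )
            Xo, yo = Xp[oi], yp[oi]
        else:
            Xo, yo = Xp, yp
        D2o = _sq_dists(Xo, Xo)
        pos = D2o[D2o > 0]
        med = float(np.median(pos)) if pos.size else 1.0
        theta0 = np.array([0.0, 0.0, 0.5 * np.log(med), np.log(0.1)])
        best_theta = None
        converged = False
        for k in range(max(1, opt_cfg.n_restarts)):
            start = theta0 if k == 0 else theta0 + rng.normal(
                0.0, (0.3, 0.8, 0.8, 0.8)
            )
            start = np.clip(
                start, [b[0] for b in _BOUNDS], [b[1] for b in _BOUNDS]
            )
            res = optimize.minimize(
                _nll_and_grad,
                start,
                args=(D2o, yo),
                jac=True,
                method="L-BFGS-B",
                bounds=_BOUNDS,
                options={
                    "gtol": opt_cfg.grad_tol,
                    "ftol": opt_cfg.step_tol * 1e-6,
                    "maxiter": opt_cfg.max_iter,
                },
            )
            if res.fun < best_nll:
                best_nll = float(res.fun)
                best_theta = res.x
                converged = bool(res.success) or converged
        sigma, alpha, ell, noise = np.exp(best_theta)
        params = KernelParams(sigma, alpha, ell, noise)

    # prediction cache on the full (or block-capped) training set
    D2p = _sq_dists(Xp, Xp)
    Kp = _rq_gram(D2p, params.sigma, params.alpha, params.length_scale)
    Kp[np.diag_indices_from(Kp)] += params.noise_sd**2 + _JITTER
    L, lower = cho_factor(Kp, lower=True, check_finite=False)
    alpha_vec = cho_solve((L, lower), yp, check_finite=False)

    return GPRModel(
        params=params,
        X_train=Xp,
        alpha_vec=alpha_vec,
        x_mean=x_mean,
        x_sd=x_sd,
        y_mean=y_mean,
        y_sd=y_sd,
        converged=converged,
        log_marginal_likelihood=-best_nll if np.isfinite(best_nll) else np.nan,
        n_train_total=n,
    )


def predict_mean(model: GPRModel, X_new: np.ndarray) -> np.ndarray:
    """Posterior mean at new inputs, de-standardized to output units."""
    X_new = np.asarray(X_new, dtype=float)
    if X_new.ndim == 1:
        X_new = X_new[None, :]
    if X_new.shape[1] != model.X_train.shape[1]:
        raise ValueError(
            f"feature count {X_new.shape[1]} does not match training "
            f"({model.X_train.shape[1]})"
        )
    Xn = (X_new - model.x_mean) / model.x_sd
    D2 = _sq_dists(Xn, model.X_train)
    Kx = _rq_gram(
        D2, model.params.sigma, model.params.alpha, model.params.length_scale
    )
    mean_std = Kx @ model.alpha_vec
    return model.y_mean + model.y_sd * mean_std


def save_model(model: GPRModel, path) -> None:
    """Serialize a fitted model to an .npz archive with a version header."""
    header = {
        "format": "myofuse-gpr",
        "version": 1,
        "params": {
            "sigma": model.params.sigma,
            "alpha": model.params.alpha,
            "length_scale": model.params.length_scale,
            "noise_sd": model.params.noise_sd,
        },
        "y_mean": model.y_mean,
        "y_sd": model.y_sd,
        "converged": model.converged,
        "log_marginal_likelihood": float(model.log_marginal_likelihood),
        "n_train_total": model.n_train_total,
    }
    np.savez_compressed(
        path,
        header=json.dumps(header),
        X_train=model.X_train,
        alpha_vec=model.alpha_vec,
        x_mean=model.x_mean,
        x_sd=model.x_sd,
    )


def load_model(path) -> GPRModel:
    with np.load(path, allow_pickle=False) as z:
        header = json.loads(str(z["header"]))
        if header.get("format") != "myofuse-gpr":
            raise ValueError("not a myofuse GPR model archive")
        p = header["params"]
        return GPRModel(
            params=KernelParams(
                p["sigma"], p["alpha"], p["length_scale"], p["noise_sd"]
            ),
            X_train=z["X_train"],
            alpha_vec=z["alpha_vec"],
            x_mean=z["x_mean"],
            x_sd=z["x_sd"],
            y_mean=header["y_mean"],
            y_sd=header["y_sd"],
            converged=header["converged"],
            log_marginal_likelihood=header["log_marginal_likelihood"],
            n_train_total=header["n_train_total"],
        )
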