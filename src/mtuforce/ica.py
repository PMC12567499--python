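"""Maximum-likelihood ICA for high-density sEMG separation.

The observed channels are modelled as an instantaneous linear mixture
x(t) = A s(t) + n(t) of statistically independent, super-Gaussian sources.
Separation proceeds in three steps:

1. centering — subtract the per-channel mean mu;
2. whitening — project onto the top ``n_components`` principal axes and
   rescale by the inverse square roots of the covariance eigenvalues, so
   cov(Z) = I (this also performs the dimension reduction);
3. maximum-likelihood estimation of the square separation matrix W acting
   on the whitened data, by natural-gradient ascent on the log-likelihood

       L(W) = sum_t sum_i log p(y_i(t)) + T log|det W|,   y = W Z,

   under a hyperbolic-secant source prior p(u) = 1/(pi cosh u), whose score
   g(u) = -tanh(u) suits super-Gaussian sEMG amplitude statistics.  The
   natural-gradient update is dW = eta (I + g(y) y^T / T) W.

The overall unmixing is W W_Z; the mixing matrix is estimated as its
pseudo-inverse, and its column magnitudes carry the spatial information
used downstream for localization.  ICA leaves permutation, sign and scale
undetermined; ``canonicalize`` fixes a convention.
"""
from __future__ import annotations

from dataclasses import dataclass
import warnings

import numpy as np

from .preprocessing import SemgRecording

_LOG_PI = float(np.log(np.pi))


@dataclass
class IcaConfig:
    """ICA hyperparameters.

    Defaults: 5 components, at most 1000 iterations, convergence when the
    Frobenius norm of the multiplicative update drops below 1e-4, and
    natural-gradient learning rate 0.020.
    """

    n_components: int = 5
    max_iter: int = 1000
    tol: float = 1e-4
    learning_rate: float = 0.020
    seed: int = 0


@dataclass
class WhiteningResult:
    mean: np.ndarray               # per-channel mean mu
    whitening_matrix: np.ndarray   # W_Z, (n_components, n_channels)
    eig_values: np.ndarray         # covariance spectrum, descending


@dataclass
class IcaResult:
    separation: np.ndarray         # W, (k, k), acts on whitened data
    whitening: WhiteningResult
    mixing_estimate: np.ndarray    # A-hat = pinv(W W_Z), (n_channels, k)
    sources: np.ndarray            # (k, T)
    loglik_trace: np.ndarray
    n_iter: int
    converged: bool

    @property
    def unmixing_total(self) -> np.ndarray:
        """Overall unmixing W W_Z mapping raw (centered) channels to sources."""
        return self.separation @ self.whitening.whitening_matrix


def center(X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Remove the per-channel mean: X* = X - mu."""
    X = np.asarray(X, float)
    if not np.all(np.isfinite(X)):
        raise ValueError("input contains non-finite values")
    if X.ndim != 2 or X.shape[1] < 2:
        raise ValueError("need a (n_channels, T) matrix with T >= 2")
    mu = X.mean(axis=1, keepdims=True)
    return X - mu, mu.ravel()


def whiten(Xc: np.ndarray, n_components: int) -> tuple[np.ndarray, WhiteningResult]:
    """PCA whitening with eigenvalue truncation to ``n_components``.

    Eigendecompose B = cov(Xc); W_Z = D^{-1/2} E^T restricted to the top
    ``n_components`` eigenpairs; Z = W_Z Xc has identity covariance.
    """
    Xc = np.asarray(Xc, float)
    n_ch, T = Xc.shape
    if n_components > n_ch:
        raise ValueError(f"{n_components} components exceed {n_ch} channels")
    B = (Xc @ Xc.T) / (T - 1)
    evals, evecs = np.linalg.eigh(B)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    rank = int(np.sum(evals > max(evals[0], 0) * 1e-12))
    if rank < n_components:
        raise ValueError(
            f"covariance rank {rank} below requested {n_components} components"
        )
    top = evals[:n_components]
    Wz = (evecs[:, :n_components] / np.sqrt(top)[None, :]).T
    Z = Wz @ Xc
    return Z, WhiteningResult(
        mean=np.zeros(n_ch), whitening_matrix=Wz, eig_values=np.clip(evals, 0, None)
    )


def _log_prior(u: np.ndarray) -> np.ndarray:
    # log p(u) for p(u) = 1/(pi cosh u); stable log cosh
    au = np.abs(u)
    return -(_LOG_PI + au + np.log1p(np.exp(-2.0 * au)) - np.log(2.0))


def log_likelihood(W: np.ndarray, Z: np.ndarray) -> float:
    """Log-likelihood L(W) = sum log p(y) + T log|det W| of whitened data."""
    W = np.asarray(W, float)
    Z = np.asarray(Z, float)
    T = Z.shape[1]
    sign, logdet = np.linalg.slogdet(W)
    if sign == 0 or not np.isfinite(logdet):
        warnings.warn("singular separation matrix; log-likelihood is -inf")
        return -np.inf
    Y = W @ Z
    return float(np.sum(_log_prior(Y)) + T * logdet)


def fit_separation(Z: np.ndarray, config: IcaConfig | None = None) -> IcaResult:
    """Estimate the separation matrix by natural-gradient likelihood ascent.

    Requires whitened input (covariance within 1e-3 of identity).  Iterates
    dW = eta (I + g(y) y^T / T) W with g = -tanh until the update's
    Frobenius norm falls below ``tol`` or ``max_iter`` is reached.  The
    per-iteration log-likelihood is recorded in ``loglik_trace``.
    """
    cfg = config or IcaConfig()
    Z = np.asarray(Z, float)
    k, T = Z.shape
    cov = (Z @ Z.T) / (T - 1)
    if np.max(np.abs(cov - np.eye(k))) > 1e-3:
        raise ValueError("input is not whitened: covariance deviates from identity")
    rng = np.random.default_rng(cfg.seed)
    W = np.eye(k) + 0.01 * rng.standard_normal((k, k))
    eye = np.eye(k)
    trace: list[float] = []
    converged = False
    n_iter = 0
    for n_iter in range(1, cfg.max_iter + 1):
        Y = W @ Z
        G = -np.tanh(Y)
        delta = cfg.learning_rate * ((eye + (G @ Y.T) / T) @ W)
        if not np.all(np.isfinite(delta)):
            raise FloatingPointError(
                "ICA update diverged; retry with a smaller learning_rate"
            )
        W = W + delta
        trace.append(log_likelihood(W, Z))
        if np.linalg.norm(delta, "fro") < cfg.tol:
            converged = True
            break
    sources = W @ Z
    whitening = WhiteningResult(
        mean=np.zeros(Z.shape[0]), whitening_matrix=np.eye(k), eig_values=np.ones(k)
    )
    return IcaResult(
        separation=W,
        whitening=whitening,
        mixing_estimate=np.linalg.pinv(W),
        sources=sources,
        loglik_trace=np.asarray(trace),
        n_iter=n_iter,
        converged=converged,
    )


def recover_sources(W_total: np.ndarray, X: np.ndarray, mu: np.ndarray) -> np.ndarray:
    """Apply the overall unmixing to raw data: s(t) = W_total (x(t) - mu)."""
    W_total = np.asarray(W_total, float)
    X = np.asarray(X, float)
    mu = np.asarray(mu, float).reshape(-1, 1)
    if W_total.shape[1] != X.shape[0] or mu.shape[0] != X.shape[0]:
        raise ValueError(
            f"unmixing {W_total.shape}, data {X.shape} and mean {mu.shape} disagree"
        )
    return W_total @ (X - mu)


def canonicalize(result: IcaResult) -> IcaResult:
    """Fix ICA's permutation/sign indeterminacy by a deterministic convention.

    Components are ordered by descending variance of their reconstructed
    channel contribution ||a_i||^2 var(s_i); each source is sign-flipped so
    its largest-magnitude sample is positive.  The mixing estimate and
    separation rows are adjusted so A-hat s (and all reconstructions) are
    unchanged.
    """
    A = result.mixing_estimate
    S = result.sources
    contrib = np.sum(A**2, axis=0) * S.var(axis=1)
    order = np.argsort(contrib)[::-1]
    signs = np.empty(len(order))
    for i, j in enumerate(order):
        peak = np.argmax(np.abs(S[j]))
        signs[i] = 1.0 if S[j][peak] >= 0 else -1.0
    S_new = signs[:, None] * S[order]
    A_new = A[:, order] / signs[None, :]
    W_new = signs[:, None] * result.separation[order]
    return IcaResult(
        separation=W_new,
        whitening=result.whitening,
        mixing_estimate=A_new,
        sources=S_new,
        loglik_trace=result.loglik_trace,
        n_iter=result.n_iter,
        converged=result.converged,
    )


def separate(
    data: SemgRecording | np.ndarray, config: IcaConfig | None = None
) -> IcaResult:
    """Full separation chain: center -> whiten -> ML estimation -> canonicalize.

    ``data`` may be a recording or a raw (n_channels, T) matrix.  The
    returned result's mixing estimate is expressed in channel space
    (pseudo-inverse of the overall unmixing), so its column magnitudes map
    directly onto the electrode grid.
    """
    cfg = config or IcaConfig()
    X = data.samples if isinstance(data, SemgRecording) else np.asarray(data, float)
    Xc, mu = center(X)
    Z, white = whiten(Xc, cfg.n_components)
    fitted = fit_separation(Z, cfg)
    W_total = fitted.separation @ white.whitening_matrix
    result = IcaResult(
        separation=fitted.separation,
        whitening=WhiteningResult(
            mean=mu,
            whitening_matrix=white.whitening_matrix,
            eig_values=white.eig_values,
        ),
        mixing_estimate=np.linalg.pinv(W_total),
        sources=recover_sources(W_total, X, mu),
        loglik_trace=fitted.loglik_trace,
        n_iter=fitted.n_iter,
        converged=fitted.converged,
    )
    return canonicalize(result)
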