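"""Non-smooth NMF deconvolution of 96-class mutation catalogs.

Non-smooth NMF factorises a nonnegative catalog matrix X (96 x samples)
as X ~ W S(theta) H, where W holds mutational signatures (columns sum
to 1), H holds per-sample exposures, and the smoothing operator
S(theta) = (1 - theta) I + (theta / k) J absorbs noise, driving both W
and H towards sparser, less correlated solutions than plain NMF.
Fitting alternates multiplicative Kullback-Leibler updates: H is
updated against the effective basis W S, and W against the effective
coefficients S H, so each half-step inherits the monotonicity of
classical KL-NMF.  theta = 0 recovers classical KL-NMF exactly.

Also provided: exposure refitting of a new catalog against a fixed
signature set, and Hoyer-sparseness diagnostics.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import linear_sum_assignment

_EPS = 1e-12


def smoothing_matrix(k: int, theta: float) -> np.ndarray:
    """The nonsmooth-NMF smoothing operator S = (1-theta) I + (theta/k) J.

    Every row (and column) sums to 1; theta=0 gives the identity and
    theta=1 the uniform averaging matrix.
    """
    if k < 1:
        raise ValueError(f"k must be >= 1, got {k}")
    if not 0.0 <= theta <= 1.0:
        raise ValueError(f"theta must lie in [0, 1], got {theta}")
    return (1.0 - theta) * np.eye(k) + (theta / k) * np.ones((k, k))


def _kl_divergence(X: np.ndarray, Xhat: np.ndarray) -> float:
    """Generalised KL divergence D(X || Xhat), the NMF objective."""
    Xhat = np.maximum(Xhat, _EPS)
    with np.errstate(divide="ignore", invalid="ignore"):
        term = np.where(X > 0, X * np.log(X / Xhat), 0.0)
    return float(np.sum(term - X + Xhat))


@dataclass
class SignatureModel:
    """Fitted nsNMF model: basis W (96 x k, columns sum to 1), exposures H."""

    W: np.ndarray
    H: np.ndarray
    theta: float
    k: int
    divergence: float
    n_restarts: int
    seed: int
    history: list[float] = field(default_factory=list)
    monotone: bool = True

    @property
    def S(self) -> np.ndarray:
        return smoothing_matrix(self.k, self.theta)

    def reconstruction(self) -> np.ndarray:
        return self.W @ self.S @ self.H


def _update_h(X: np.ndarray, A: np.ndarray, H: np.ndarray) -> np.ndarray:
    """Multiplicative KL update of H for X ~ A H (A fixed)."""
    AH = np.maximum(A @ H, _EPS)
    numer = A.T @ (X / AH)
    denom = np.maximum(A.sum(axis=0)[:, None], _EPS)
    return H * numer / denom


def _update_w(X: np.ndarray, W: np.ndarray, B: np.ndarray) -> np.ndarray:
    """Multiplicative KL update of W for X ~ W B (B fixed)."""
    WB = np.maximum(W @ B, _EPS)
    numer = (X / WB) @ B.T
    denom = np.maximum(B.sum(axis=1)[None, :], _EPS)
    return W * numer / denom


def nsnmf_factorize(
    X: np.ndarray,
    k: int,
    theta: float = 0.5,
    n_restarts: int = 10,
    max_iter: int = 2000,
    tol: float = 1e-6,
    seed: int = 0,
    polish_iter: int = 200,
) -> SignatureModel:
    """Factorise a nonnegative catalog matrix X ~ W S(theta) H.

    Runs ``n_restarts`` random initialisations and keeps the best by KL
    divergence.  Within each restart, updates are alternated without
    rescaling, so the recorded divergence history is non-increasing (a
    tolerated increase beyond 1e-8 sets ``monotone=False`` and stops the
    restart).  After the main loop W is column-normalised with the
    compensating rescale of H, followed by H-only polish updates against
    the normalised basis so the reconstruction re-converges.

    Parameters
    ----------
    X : (m, n) array
        Nonnegative counts; requires ``k < min(m, n)``.
    theta : float
        Smoothing parameter in [0, 1]; 0 is classical KL-NMF.
    tol : float
        Convergence when the relative divergence change drops below
        this value.
    """
    X = np.asarray(X, dtype=float)
    if not np.all(np.isfinite(X)) or np.any(X < 0):
        raise ValueError("X must be finite and nonnegative")
    m, n = X.shape
    if not k < min(m, n):
        raise ValueError(f"k={k} must be smaller than min{X.shape}")
    S = smoothing_matrix(k, theta)
    rng = np.random.default_rng(seed)
    scale = max(X.mean(), _EPS)

    best: SignatureModel | None = None
    for _ in range(n_restarts):
        W = rng.uniform(0.5, 1.5, size=(m, k)) * scale
        H = rng.uniform(0.5, 1.5, size=(k, n))
        history: list[float] = [_kl_divergence(X, W @ S @ H)]
        monotone = True
        for _it in range(max_iter):
            H = _update_h(X, W @ S, H)
            W = _update_w(X, W, S @ H)
            d = _kl_divergence(X, W @ S @ H)
            prev = history[-1]
            history.append(d)
            if d > prev + 1e-8 * max(1.0, abs(prev)):
                monotone = False
                break
            if abs(prev - d) <= tol * max(1.0, abs(prev)):
                break
        # Final normalisation: unit-sum signature columns, exposures
        # rescaled; H-only polish re-converges the reconstruction
        # against the fixed normalised basis.
        colsum = np.maximum(W.sum(axis=0), _EPS)
        W = W / colsum
        H = colsum[:, None] * H
        WS = W @ S
        for _it in range(polish_iter):
            H_new = _update_h(X, WS, H)
            if np.max(np.abs(H_new - H)) <= tol * max(1.0, H.max()):
                H = H_new
                break
            H = H_new
        d_final = _kl_divergence(X, W @ S @ H)
        model = SignatureModel(
            W=W,
            H=H,
            theta=theta,
            k=k,
            divergence=d_final,
            n_restarts=n_restarts,
            seed=seed,
            history=history,
            monotone=monotone,
        )
        if best is None or model.divergence < best.divergence:
            best = model
    assert best is not None
    return best


def fit_exposures(
    W: np.ndarray,
    catalog: np.ndarray,
    method: str = "kl",
    max_iter: int = 5000,
    tol: float = 1e-10,
) -> np.ndarray:
    """Exposure proportions of one catalog against a fixed signature set.

    Finds nonnegative weights h minimising the KL divergence (or squared
    error with ``method="ls"``) between the catalog and W h, and returns
    them normalised to proportions summing to 1.  A zero-count catalog
    yields an all-NaN sentinel.
    """
    W = np.asarray(W, dtype=float)
    x = np.asarray(catalog, dtype=float).ravel()
    k = W.shape[1]
    if x.sum() <= 0:
        return np.full(k, np.nan)
    if method == "ls":
        from scipy.optimize import nnls

        h, _ = nnls(W, x)
    elif method == "kl":
        h = np.full(k, x.sum() / k)
        X = x[:, None]
        Hm = h[:, None]
        for _ in range(max_iter):
            H_new = _update_h(X, W, Hm)
            if np.max(np.abs(H_new - Hm)) <= tol * max(1.0, Hm.max()):
                Hm = H_new
                break
            Hm = H_new
        h = Hm.ravel()
    else:
        raise ValueError(f"unknown method {method!r}")
    total = h.sum()
    if total <= 0:
        return np.full(k, np.nan)
    return h / total


def hoyer_sparseness(x: np.ndarray) -> float:
    """Hoyer sparseness in [0, 1]: 1 for one-hot, 0 for constant vectors.

    Undefined (NaN) for the zero vector.
    """
    x = np.asarray(x, dtype=float).ravel()
    n = x.size
    l2 = np.linalg.norm(x)
    if l2 == 0:
        return float("nan")
    if n == 1:
        return 1.0
    return float((np.sqrt(n) - np.abs(x).sum() / l2) / (np.sqrt(n) - 1.0))


def sparseness_report(model: SignatureModel) -> dict:
    """Per-signature and per-exposure Hoyer sparseness, plus basis correlation.

    Returns a dict with per-column sparseness of W, per-row sparseness
    of H, their means, and the mean pairwise Pearson correlation
    between signatures (lower means more orthogonal).
    """
    w_sp = np.array([hoyer_sparseness(model.W[:, j]) for j in range(model.k)])
    h_sp = np.array([hoyer_sparseness(model.H[i, :]) for i in range(model.k)])
    if model.k > 1:
        corr = np.corrcoef(model.W.T)
        iu = np.triu_indices(model.k, 1)
        mean_corr = float(np.nanmean(corr[iu]))
    else:
        mean_corr = float("nan")
    return {
        "W_sparseness": w_sp,
        "H_sparseness": h_sp,
        "mean_W_sparseness": float(np.nanmean(w_sp)),
        "mean_H_sparseness": float(np.nanmean(h_sp)),
        "mean_signature_correlation": mean_corr,
    }


def match_signatures(W_est: np.ndarray, W_true: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Optimal column matching between two signature bases.

    Maximum-weight bipartite matching (Hungarian algorithm) on cosine
    similarity.  Returns (permutation, cosines) such that column
    ``permutation[j]`` of ``W_est`` matches column ``j`` of ``W_true``.
    """
    def _unit(M: np.ndarray) -> np.ndarray:
        norms = np.maximum(np.linalg.norm(M, axis=0), _EPS)
        return M / norms

    C = _unit(W_est).T @ _unit(W_true)  # est x true cosine
    rows, cols = linear_sum_assignment(-C)
    perm = np.empty(W_true.shape[1], dtype=int)
    cosines = np.empty(W_true.shape[1])
    for r, c in zip(rows, cols):
        perm[c] = r
        cosines[c] = C[r, c]
    return perm, cosines
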