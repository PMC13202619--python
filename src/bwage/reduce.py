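"""Flattening, energy-threshold truncated SVD, and batch harmonization.

A symmetric R x R connectome is fully described by its upper triangle
including the diagonal, a vector of length D = R(R+1)/2 (70876 for the
376-region parcellation the pipeline targets).  Stacking participants gives
a flat table ``A`` (participants x D) which is compressed with a truncated
SVD: the smallest number ``k`` of leading right singular vectors whose
squared singular values sum to at least a proportion ``pi`` of the total
energy is retained, and features are ``A @ W.T`` with ``W`` the k x D basis.

Compressed features from different acquisition sites are then harmonized
with a ComBat-style location/scale model: per feature, a linear model with
biological covariates (age, sex) and batch terms is fit, batch location and
scale parameters are shrunk across features by parametric empirical Bayes,
and the batch effects are removed while the covariate-explained signal is
restored.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "flatten_upper",
    "unflatten_upper",
    "flatten_connectomes",
    "CompressionBasis",
    "fit_svd_basis",
    "compress",
    "reconstruct",
    "HarmonizationModel",
    "harmonize",
]


def flatten_upper(C: np.ndarray, tol: float = 1e-8) -> np.ndarray:
    """Upper triangle (including diagonal) of a symmetric matrix, row-major.

    Length is ``R(R+1)/2``; the inverse is :func:`unflatten_upper`.
    """
    C = np.asarray(C, dtype=float)
    if C.ndim != 2 or C.shape[0] != C.shape[1]:
        raise ValueError("expected a square matrix")
    if not np.allclose(C, C.T, atol=tol):
        raise ValueError(f"matrix is asymmetric beyond {tol}")
    iu = np.triu_indices(C.shape[0])
    return C[iu]


def unflatten_upper(v: np.ndarray, n_regions: int | None = None) -> np.ndarray:
    """Rebuild the symmetric matrix whose upper triangle is ``v``."""
    v = np.asarray(v, dtype=float)
    if n_regions is None:
        n_regions = int(round((np.sqrt(8 * v.size + 1) - 1) / 2))
    if n_regions * (n_regions + 1) // 2 != v.size:
        raise ValueError(f"length {v.size} is not a triangular number for R={n_regions}")
    M = np.zeros((n_regions, n_regions))
    iu = np.triu_indices(n_regions)
    M[iu] = v
    M = M + M.T - np.diag(np.diag(M))
    return M


def flatten_connectomes(connectomes) -> tuple[np.ndarray, list[str], str]:
    """Stack a list of same-kind connectomes into a flat table.

    Returns ``(A, ids, kind)`` with ``A`` of shape (n, R(R+1)/2).
    """
    kinds = {c.kind for c in connectomes}
    if len(kinds) != 1:
        raise ValueError(f"mixed connectome representations: {sorted(kinds)}")
    A = np.vstack([flatten_upper(c.matrix) for c in connectomes])
    ids = [c.participant_id for c in connectomes]
    return A, ids, kinds.pop()


@dataclass
class CompressionBasis:
    """Retained right-singular-vector rows and the energy they capture."""

    W: np.ndarray
    target_energy: float
    achieved_energy: float
    singular_values: np.ndarray = field(default=None, repr=False)

    @property
    def k(self) -> int:
        return self.W.shape[0]


def fit_svd_basis(A: np.ndarray, pi: float = 0.999) -> CompressionBasis:
    """Truncated SVD basis capturing at least a proportion ``pi`` of energy.

    ``k`` is the smallest number of leading singular values whose squared
    sum reaches ``pi`` times the squared Frobenius norm of ``A``; ties in
    the singular values at the cut (relative 1e-12) extend ``k`` past the
    tie so the basis is deterministic.  Each retained vector is scaled so
    its largest-magnitude entry is positive (SVD sign convention).
    """
    A = np.asarray(A, dtype=float)
    if A.size == 0:
        raise ValueError("empty data matrix")
    if not 0.0 < pi <= 1.0:
        raise ValueError("pi must lie in (0, 1]")
    U, s, Vt = np.linalg.svd(A, full_matrices=False)
    energy = s**2
    total = energy.sum()
    if total == 0:
        raise ValueError("data matrix is identically zero")
    cum = np.cumsum(energy) / total
    k = int(np.searchsorted(cum, pi - 1e-12) + 1)
    k = min(k, len(s))
    # extend past ties at the cut
    while k < len(s) and s[k] > 0 and abs(s[k] - s[k - 1]) <= 1e-12 * s[k - 1]:
        k += 1
    W = Vt[:k].copy()
    for row in W:
        j = int(np.argmax(np.abs(row)))
        if row[j] < 0:
            row *= -1.0
    return CompressionBasis(
        W=W, target_energy=pi, achieved_energy=float(cum[k - 1]), singular_values=s
    )


def compress(A: np.ndarray, basis: CompressionBasis | np.ndarray) -> np.ndarray:
    """Project flat rows onto the retained basis: ``A @ W.T``."""
    W = basis.W if isinstance(basis, CompressionBasis) else np.asarray(basis)
    A = np.asarray(A, dtype=float)
    if A.shape[-1] != W.shape[1]:
        raise ValueError(f"feature dimension mismatch: {A.shape[-1]} vs {W.shape[1]}")
    return A @ W.T


def reconstruct(Abar: np.ndarray, basis: CompressionBasis | np.ndarray) -> np.ndarray:
    """Map compressed rows back to flat connectome space: ``Abar @ W``."""
    W = basis.W if isinstance(basis, CompressionBasis) else np.asarray(basis)
    return np.asarray(Abar, dtype=float) @ W


# ---------------------------------------------------------------------------
# ComBat-style harmonization
# ---------------------------------------------------------------------------


@dataclass
class HarmonizationModel:
    """Fitted location/scale batch-adjustment parameters.

    ``gamma_star``/``delta_star`` are the (empirical-Bayes shrunk) per-batch
    per-feature location and scale adjustments in standardized units;
    ``apply`` harmonizes new rows with known batch and covariates.
    """

    batches: list
    gamma_star: dict  # batch -> (G,) location
    delta_star: dict  # batch -> (G,) scale
    alpha: np.ndarray  # (G,) grand mean
    beta_cov: np.ndarray  # (q, G) covariate effects
    sigma: np.ndarray  # (G,) pooled residual SD
    kept: np.ndarray  # boolean mask of non-constant features
    identity: bool = False

    def apply(self, A: np.ndarray, batch, covariates: np.ndarray) -> np.ndarray:
        if self.identity:
            return np.asarray(A, dtype=float).copy()
        A = np.asarray(A, dtype=float)
        X = np.atleast_2d(np.asarray(covariates, dtype=float))
        out = A.copy()
        batch = np.asarray(batch)
        for b in np.unique(batch):
            if b not in self.gamma_star:
                raise ValueError(f"batch {b!r} was not seen during fitting")
            rows = batch == b
            stand_mean = self.alpha + X[rows] @ self.beta_cov
            z = (A[rows][:, self.kept] - stand_mean[:, self.kept]) / self.sigma[self.kept]
            z = (z - self.gamma_star[b]) / self.delta_star[b]
            out[np.ix_(rows, self.kept)] = (
                z * self.sigma[self.kept] + stand_mean[:, self.kept]
            )
        return out


def _eb_iterate(
    Z: np.ndarray, gamma_bar: float, tau2: float, lam: float, theta: float,
    max_iter: int = 100, tol: float = 1e-6,
) -> tuple[np.ndarray, np.ndarray]:
    """Iterative parametric empirical-Bayes solve for one batch.

    ``Z`` is the standardized data of the batch (rows x features); returns
    the shrunk location ``gamma*`` and squared scale ``delta*^2`` per
    feature (normal prior on locations, inverse-gamma prior on variances,
    moment-matched hyperparameters).
    """
    n = Z.shape[0]
    g_hat = Z.mean(axis=0)
    d_hat2 = Z.var(axis=0, ddof=1)
    g_star, d_star2 = g_hat.copy(), d_hat2.copy()
    for _ in range(max_iter):
        g_new = (n * tau2 * g_hat + d_star2 * gamma_bar) / (n * tau2 + d_star2)
        sse = ((Z - g_new) ** 2).sum(axis=0)
        d_new2 = (theta + 0.5 * sse) / (n / 2.0 + lam - 1.0)
        change = max(
            np.max(np.abs(g_new - g_star) / (np.abs(g_star) + 1e-12)),
            np.max(np.abs(d_new2 - d_star2) / (d_star2 + 1e-12)),
        )
        g_star, d_star2 = g_new, d_new2
        if change < tol:
            break
    return g_star, d_star2


def harmonize(
    A: np.ndarray,
    batch,
    covariates: np.ndarray,
    empirical_bayes: bool = True,
) -> tuple[np.ndarray, HarmonizationModel]:
    """Remove batch location/scale effects while preserving covariate signal.

    Per feature, a linear model with batch indicators and covariates is fit;
    features are standardized by the pooled residual SD; per-batch location
    and scale parameters are estimated and (optionally) shrunk across
    features by parametric empirical Bayes before being removed.  With a
    single batch the input is returned unchanged with an identity model;
    constant features are skipped with a warning.

    Parameters
    ----------
    A : (n, G) array of compressed features.
    batch : (n,) array of site labels.
    covariates : (n, q) array of biological covariates (age, sex) whose
        effects must be preserved.
    empirical_bayes : bool
        Disable to use the raw per-batch moments (non-EB fallback, useful
        for very small feature counts where the prior is uninformative).
    """
    A = np.asarray(A, dtype=float)
    batch = np.asarray(batch)
    X_cov = np.atleast_2d(np.asarray(covariates, dtype=float))
    if X_cov.shape[0] != A.shape[0] or batch.shape[0] != A.shape[0]:
        raise ValueError("A, batch and covariates must agree on the sample axis")
    if np.isnan(X_cov).any():
        raise ValueError("covariates must be complete (no NaN)")
    levels = list(dict.fromkeys(batch.tolist()))
    if len(levels) < 2:
        model = HarmonizationModel(
            batches=levels, gamma_star={}, delta_star={}, alpha=np.zeros(A.shape[1]),
            beta_cov=np.zeros((X_cov.shape[1], A.shape[1])),
            sigma=np.ones(A.shape[1]), kept=np.ones(A.shape[1], dtype=bool),
            identity=True,
        )
        return A.copy(), model
    counts = {b: int(np.sum(batch == b)) for b in levels}
    for b, c in counts.items():
        if c < 2:
            raise ValueError(f"batch {b!r} has fewer than 2 rows")

    kept = A.std(axis=0) > 1e-12 * (np.abs(A).mean(axis=0) + 1.0)
    if not kept.all():
        warnings.warn(
            f"skipping {int((~kept).sum())} constant feature(s) during harmonization",
            stacklevel=2,
        )
    Y = A[:, kept]
    n, G = Y.shape
    nb = len(levels)
    B = np.zeros((n, nb))
    for j, b in enumerate(levels):
        B[batch == b, j] = 1.0
    X = np.hstack([B, X_cov])
    beta, *_ = np.linalg.lstsq(X, Y, rcond=None)
    batch_coefs = beta[:nb]  # (nb, G)
    beta_cov = beta[nb:]  # (q, G)
    w = np.array([counts[b] / n for b in levels])
    alpha = w @ batch_coefs  # (G,) grand mean
    resid = Y - X @ beta
    sigma = np.sqrt((resid**2).mean(axis=0))
    # features (near-)perfectly explained by the design carry no residual to
    # standardize; flooring sigma at a tiny fraction of the feature scale
    # makes their adjustment collapse to the model prediction instead of
    # amplifying rounding noise
    scale = Y.std(axis=0)
    sigma = np.maximum(sigma, 1e-8 * np.maximum(scale, 1.0))
    stand_mean = alpha + X_cov @ beta_cov  # (n, G)
    Z = (Y - stand_mean) / sigma

    gamma_star, delta_star = {}, {}
    for b in levels:
        Zb = Z[batch == b]
        g_hat = Zb.mean(axis=0)
        d_hat2 = Zb.var(axis=0, ddof=1)
        d_hat2 = np.maximum(d_hat2, 1e-12)
        if empirical_bayes and G >= 2:
            gamma_bar = float(g_hat.mean())
            tau2 = float(g_hat.var(ddof=1)) if G >= 2 else 1.0
            tau2 = max(tau2, 1e-12)
            m, v = float(d_hat2.mean()), float(d_hat2.var(ddof=1)) if G >= 2 else 0.0
            if v > 0:
                lam = (2 * v + m**2) / v  # inverse-gamma moment matching
                theta = (m * v + m**3) / v
            else:
                lam, theta = 2.0, m
            g_s, d_s2 = _eb_iterate(Zb, gamma_bar, tau2, lam, theta)
        else:
            g_s, d_s2 = g_hat, d_hat2
        gamma_star[b] = g_s
        delta_star[b] = np.sqrt(np.maximum(d_s2, 1e-12))

    full_kept = np.zeros(A.shape[1], dtype=bool)
    full_kept[np.flatnonzero(kept)] = True
    alpha_full = np.zeros(A.shape[1])
    alpha_full[full_kept] = alpha
    beta_full = np.zeros((X_cov.shape[1], A.shape[1]))
    beta_full[:, full_kept] = beta_cov
    sigma_full = np.ones(A.shape[1])
    sigma_full[full_kept] = sigma
    model = HarmonizationModel(
        batches=levels,
        gamma_star=gamma_star,
        delta_star=delta_star,
        alpha=alpha_full,
        beta_cov=beta_full,
        sigma=sigma_full,
        kept=full_kept,
    )
    return model.apply(A, batch, X_cov), model
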