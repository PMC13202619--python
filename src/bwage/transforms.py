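"""Connectome representations: Fisher z and the Bures-Wasserstein log matrix.

Correlation connectomes live on the cone of symmetric positive-(semi)definite
(SPD) matrices.  Two transforms are provided to move them to an unconstrained
vector space before statistical modelling:

* a clipped elementwise Fisher z-transform, ``D = atanh(clip * C)``, where the
  clip constant keeps the map finite at correlations of exactly +/-1;
* the Bures-Wasserstein (BW) log matrix, the optimal-transport tangent-space
  parametrization of an SPD matrix around a reference connectome ``B``,

      E = (B C)^{1/2} + (C B)^{1/2} - 2 B,

  computed with matrix (not elementwise) square roots.  With the identity
  reference the conventional form ``E = 2 C^{1/2} - I`` is used; it differs
  from the general expression evaluated at ``B = I`` by the constant shift
  ``+I``, which is irrelevant for downstream regression but makes the inverse
  map the simple square ``C = ((E + I) / 2)^2``.

All operations act on plain ``numpy`` arrays and preserve symmetry exactly
(outputs are explicitly symmetrized).
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "DEFAULT_CLIP",
    "EIG_FLOOR",
    "fisher_z",
    "spd_sqrt",
    "bw_log",
    "bw_log_identity",
    "bw_inverse",
    "is_spd",
]

#: Clip constant applied inside the Fisher z-transform so that correlations of
#: exactly +/-1 map to a finite value, atanh(0.999) ~ 3.8.
DEFAULT_CLIP = 0.999

#: Eigenvalues below this (after symmetrization) are floored when taking
#: matrix square roots; inputs with eigenvalues below -EIG_FLOOR are rejected.
EIG_FLOOR = 1e-12


def _check_symmetric(M: np.ndarray, tol: float = 1e-8, name: str = "matrix") -> np.ndarray:
    M = np.asarray(M, dtype=float)
    if M.ndim != 2 or M.shape[0] != M.shape[1]:
        raise ValueError(f"{name} must be square, got shape {M.shape}")
    if not np.allclose(M, M.T, atol=tol):
        raise ValueError(f"{name} is not symmetric within {tol}")
    return 0.5 * (M + M.T)


def is_spd(M: np.ndarray, floor: float = 0.0) -> bool:
    """True when ``M`` is symmetric with smallest eigenvalue > ``floor``."""
    M = np.asarray(M, dtype=float)
    if M.ndim != 2 or M.shape[0] != M.shape[1] or not np.allclose(M, M.T, atol=1e-8):
        return False
    return float(np.linalg.eigvalsh(0.5 * (M + M.T))[0]) > floor


def fisher_z(C: np.ndarray, clip: float = DEFAULT_CLIP) -> np.ndarray:
    """Clipped elementwise Fisher z-transform of a correlation matrix.

    ``D_ij = 0.5 * log((1 + clip * C_ij) / (1 - clip * C_ij))``, an odd,
    strictly increasing map bounded by ``+/- atanh(clip)``.

    Parameters
    ----------
    C : array
        Matrix of correlation values in ``[-1, 1]``.
    clip : float
        Multiplicative clip constant in ``(0, 1)``.
    """
    if not 0.0 < clip < 1.0:
        raise ValueError(f"clip must lie in (0, 1), got {clip}")
    C = np.asarray(C, dtype=float)
    if np.any(np.abs(C) > 1.0 + 1e-12):
        raise ValueError("correlation entries must lie in [-1, 1]")
    return np.arctanh(clip * np.clip(C, -1.0, 1.0))


def spd_sqrt(M: np.ndarray, floor: float = EIG_FLOOR) -> np.ndarray:
    """Symmetric PSD square root via eigendecomposition.

    Eigenvalues in ``[-floor, floor]`` are floored at ``floor`` to keep the
    root well defined on numerically rank-deficient inputs; an eigenvalue
    below ``-floor`` raises, as the matrix is then genuinely not PSD.
    """
    M = _check_symmetric(M)
    vals, vecs = np.linalg.eigh(M)
    if vals[0] < -floor:
        raise ValueError(
            f"matrix is not positive semidefinite: smallest eigenvalue {vals[0]:.3e}"
        )
    vals = np.maximum(vals, floor)
    S = (vecs * np.sqrt(vals)) @ vecs.T
    return 0.5 * (S + S.T)


def _spd_inv_sqrt(M: np.ndarray, floor: float = EIG_FLOOR) -> np.ndarray:
    M = _check_symmetric(M)
    vals, vecs = np.linalg.eigh(M)
    if vals[0] < -floor:
        raise ValueError("matrix is not positive semidefinite")
    vals = np.maximum(vals, floor)
    S = (vecs / np.sqrt(vals)) @ vecs.T
    return 0.5 * (S + S.T)


def bw_log(C: np.ndarray, B: np.ndarray, floor: float = EIG_FLOOR) -> np.ndarray:
    """Bures-Wasserstein log matrix of ``C`` around an SPD reference ``B``.

    ``E = (BC)^{1/2} + (CB)^{1/2} - 2B``.  The non-symmetric root is obtained
    through the similarity identity ``(BC)^{1/2} = B^{1/2} (B^{1/2} C
    B^{1/2})^{1/2} B^{-1/2}`` so that every square root is taken on a
    symmetric matrix; the sum is symmetrized afterwards.  ``E = 0`` iff
    ``C = B``.
    """
    C = _check_symmetric(C, name="C")
    B = _check_symmetric(B, name="B")
    if not is_spd(B, floor=0.0):
        raise ValueError("reference matrix B must be SPD")
    Bh = spd_sqrt(B, floor)
    Bih = _spd_inv_sqrt(B, floor)
    inner = spd_sqrt(Bh @ C @ Bh, floor)
    M = Bh @ inner @ Bih  # (BC)^{1/2}; (CB)^{1/2} is its transpose
    E = M + M.T - 2.0 * B
    return 0.5 * (E + E.T)


def bw_log_identity(C: np.ndarray, floor: float = EIG_FLOOR) -> np.ndarray:
    """Identity-reference BW log matrix, ``E = 2 C^{1/2} - I``.

    This is the convention used throughout the pipeline; its exact inverse is
    :func:`bw_inverse`.  It equals ``bw_log(C, I) + I``.
    """
    C = _check_symmetric(C, name="C")
    return 2.0 * spd_sqrt(C, floor) - np.eye(C.shape[0])


def bw_inverse(E: np.ndarray, floor: float = EIG_FLOOR) -> np.ndarray:
    """Invert the identity-reference BW log map: ``C = ((E + I) / 2)^2``.

    Requires ``(E + I) / 2`` to be PSD (it is ``C^{1/2}`` for any valid log
    matrix).
    """
    E = _check_symmetric(E, name="E")
    R = 0.5 * (E + np.eye(E.shape[0]))
    vals = np.linalg.eigvalsh(R)
    if vals[0] < -floor:
        raise ValueError(
            f"(E + I)/2 has eigenvalue {vals[0]:.3e} < 0; not a valid BW log matrix"
        )
    C = R @ R
    return 0.5 * (C + C.T)
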