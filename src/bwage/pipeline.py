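"""End-to-end glue: representation -> features -> harmonized design.

Thin wrappers that chain the transform, flatten/compress and harmonization
stages on lists of :class:`~bwage.preprocess.Connectome` objects, so the
experiment drivers and the command line stay small.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .preprocess import Connectome
from .reduce import CompressionBasis, compress, fit_svd_basis, flatten_connectomes
from .transforms import DEFAULT_CLIP, bw_log_identity, fisher_z

__all__ = ["apply_representation", "FeatureSet", "build_features"]


def apply_representation(
    connectomes: list[Connectome], kind: str, clip: float = DEFAULT_CLIP
) -> list[Connectome]:
    """Re-express correlation connectomes as ``correlation|fisher|bw``."""
    if kind == "correlation":
        return list(connectomes)
    out = []
    for c in connectomes:
        if c.kind != "correlation":
            raise ValueError(f"expected correlation input, got {c.kind!r}")
        if kind == "fisher":
            M = fisher_z(c.matrix, clip=clip)
        elif kind == "bw":
            M = bw_log_identity(c.matrix)
        else:
            raise ValueError(f"unknown representation {kind!r}")
        out.append(Connectome(M, kind, c.participant_id))
    return out


@dataclass
class FeatureSet:
    """Compressed feature rows with their provenance."""

    X: np.ndarray
    basis: CompressionBasis
    ids: list[str]
    kind: str


def build_features(
    connectomes: list[Connectome],
    kind: str = "bw",
    pi: float = 0.999,
    clip: float = DEFAULT_CLIP,
) -> FeatureSet:
    """Transform, flatten and SVD-compress a list of connectomes."""
    transformed = apply_representation(connectomes, kind, clip=clip)
    A, ids, tag = flatten_connectomes(transformed)
    basis = fit_svd_basis(A, pi=pi)
    return FeatureSet(X=compress(A, basis), basis=basis, ids=ids, kind=tag)
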