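"""Mapping linear model weights back to connectome space.

A linear age model fitted on SVD-compressed Bures-Wasserstein features has a
weight vector over k components; projecting it through the compression basis
W and unflattening yields a symmetric aging direction matrix ``B`` in
connectome space.  Around the cohort-average BW connectome ``A``, the
first-order change of the *covariance* ``C(A) = ((A + I)/2)^2`` along ``B``
is the effect operator

    D(B) = c_b * B + (A B + B A) / 4,

whose exact first-order coefficient is ``c_b = 1/2`` (directional derivative
of the inverse BW map; verified against a finite-difference oracle in the
tests).  A variant with ``c_b = 1`` is kept selectable for comparison with
reports that use that convention.

The elementwise product of ``D`` with the average connectome separates
connections reinforced by aging (positive product: positive correlations
increasing or anti-correlations deepening) from weakening ones.  For
readability, parcel-level matrices are aggregated per hemisphere into large
atlas regions by block averaging (22 regions for the HCP atlas), and
direction matrices are normalized to unit standard deviation of entries.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .preprocess import Connectome
from .reduce import CompressionBasis, unflatten_upper

__all__ = [
    "RegionGrouping",
    "project_weights",
    "mean_connectome",
    "aging_effect",
    "strengthening_map",
    "aggregate_regions",
]


def project_weights(beta: np.ndarray, basis: CompressionBasis | np.ndarray) -> np.ndarray:
    """Project compressed-space weights to a symmetric connectome-space matrix.

    ``beta`` must exclude the intercept (which has no connectome-space
    image): length k for a k x D basis.  The flat vector ``beta @ W`` is
    unflattened to the upper triangle and mirrored.
    """
    W = basis.W if isinstance(basis, CompressionBasis) else np.asarray(basis)
    beta = np.asarray(beta, dtype=float).ravel()
    if beta.shape[0] != W.shape[0]:
        raise ValueError(
            f"weight length {beta.shape[0]} does not match basis rank {W.shape[0]}"
        )
    return unflatten_upper(beta @ W)


def mean_connectome(connectomes: list[Connectome]) -> Connectome:
    """Entrywise mean of same-representation connectomes."""
    if not connectomes:
        raise ValueError("no connectomes to average")
    kinds = {c.kind for c in connectomes}
    if len(kinds) != 1:
        raise ValueError(f"mixed connectome representations: {sorted(kinds)}")
    M = np.mean([c.matrix for c in connectomes], axis=0)
    return Connectome(0.5 * (M + M.T), kinds.pop(), "mean")


def aging_effect(A: np.ndarray, B: np.ndarray, coeff_b: float = 0.5) -> np.ndarray:
    """Effect operator ``D = coeff_b * B + (A B + B A) / 4``.

    With ``coeff_b = 1/2`` (default) this is the exact first-order term of
    ``C(A + delta B)`` in delta, where ``C`` is the inverse BW transform;
    ``coeff_b = 1`` selects the alternative convention.
    """
    A = np.asarray(A, dtype=float)
    B = np.asarray(B, dtype=float)
    if A.shape != B.shape:
        raise ValueError("mean connectome and direction must have equal shape")
    for M, name in ((A, "A"), (B, "B")):
        if not np.allclose(M, M.T, atol=1e-8):
            raise ValueError(f"{name} must be symmetric")
    D = coeff_b * B + 0.25 * (A @ B + B @ A)
    return 0.5 * (D + D.T)


def strengthening_map(A: np.ndarray, D: np.ndarray) -> np.ndarray:
    """Elementwise product of average connectome and effect operator.

    Positive entries mark connections reinforced by aging, negative entries
    weakening ones.
    """
    A = np.asarray(A, dtype=float)
    D = np.asarray(D, dtype=float)
    if A.shape != D.shape:
        raise ValueError("shape mismatch")
    return A * D


@dataclass
class RegionGrouping:
    """Map from fine parcels to (hemisphere, large region) pairs.

    Built from a table with columns ``parcel`` (index into the connectome),
    ``hemisphere`` and ``group``.  Group order follows first appearance in
    the table.
    """

    parcel_hemisphere: dict[int, str]
    parcel_group: dict[int, str]
    group_order: list[str]

    @classmethod
    def from_table(cls, table: pd.DataFrame) -> "RegionGrouping":
        for col in ("parcel", "hemisphere", "group"):
            if col not in table.columns:
                raise ValueError(f"grouping table needs a {col!r} column")
        if table["parcel"].duplicated().any():
            dup = table.loc[table["parcel"].duplicated(), "parcel"].tolist()
            raise ValueError(f"parcels mapped more than once: {dup}")
        return cls(
            parcel_hemisphere=dict(zip(table["parcel"].astype(int), table["hemisphere"])),
            parcel_group=dict(zip(table["parcel"].astype(int), table["group"])),
            group_order=list(dict.fromkeys(table["group"])),
        )

    @classmethod
    def from_csv(cls, path) -> "RegionGrouping":
        return cls.from_table(pd.read_csv(path))

    def parcels(self, hemisphere: str) -> list[int]:
        return [p for p, h in self.parcel_hemisphere.items() if h == hemisphere]


def aggregate_regions(
    M: np.ndarray,
    grouping: RegionGrouping,
    hemisphere: str,
    normalize_sd: bool = False,
) -> pd.DataFrame:
    """Block-average a parcel-level matrix into large atlas regions.

    Every parcel of the selected hemisphere must be covered by the
    grouping.  ``normalize_sd`` rescales the aggregated matrix to unit
    standard deviation of its entries (the convention for direction
    matrices; average connectomes are reported unscaled).

    Returns a groups x groups DataFrame labeled in group order.
    """
    M = np.asarray(M, dtype=float)
    parcels = grouping.parcels(hemisphere)
    if not parcels:
        raise ValueError(f"grouping covers no parcels for hemisphere {hemisphere!r}")
    bad = [p for p in parcels if p >= M.shape[0]]
    if bad:
        raise ValueError(f"parcels outside the matrix: {bad}")
    groups = [g for g in grouping.group_order
              if any(grouping.parcel_group[p] == g for p in parcels)]
    members = {g: [p for p in parcels if grouping.parcel_group[p] == g] for g in groups}
    G = len(groups)
    out = np.zeros((G, G))
    for i, gi in enumerate(groups):
        for j, gj in enumerate(groups):
            out[i, j] = M[np.ix_(members[gi], members[gj])].mean()
    if normalize_sd:
        sd = out.std()
        if sd == 0:
            raise ValueError("cannot normalize a constant matrix to unit SD")
        out = out / sd
    return pd.DataFrame(out, index=groups, columns=groups)
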