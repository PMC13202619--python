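"""Regional-signal conditioning and connectome estimation.

Turns regional resting-state fMRI time series (time x regions, with a known
sampling interval ``tr`` in seconds) into shrinkage-stabilized Pearson
correlation connectomes.  The chain applied per scan is

    detrend -> band-pass (0.01-0.1 Hz Butterworth, order 2, zero-phase)
    -> [optional outlier-frame scrubbing + nuisance regression]
    -> global signal regression -> zero-mean / unit-L2 normalization,

after which the scans of a participant are concatenated, re-normalized, and
correlated; the Oracle Approximating Shrinkage (OAS) pulls the resulting
correlation matrix toward the scaled identity with a data-driven intensity,
which stabilizes connectomes estimated from finite scans.

The module starts at regional series: voxel-level registration, motion
correction and denoising are upstream concerns.  Motion and tissue-component
nuisance regressors must therefore be supplied by the caller; only the
polynomial trend columns are built here (Legendre construction).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import signal

__all__ = [
    "RegionalTimeSeries",
    "Connectome",
    "detrend",
    "bandpass",
    "flag_outlier_frames",
    "legendre_trend_columns",
    "regress_nuisance",
    "global_signal_regress",
    "normalize",
    "concatenate",
    "average_series",
    "pearson_connectome",
    "oas_shrinkage_intensity",
    "oas_shrink",
    "connectome_from_scans",
]


@dataclass
class RegionalTimeSeries:
    """A time x regions signal matrix with its sampling interval.

    Attributes
    ----------
    data : (T, R) array
    tr : float
        Seconds per frame; must be positive.
    labels : list of str
        Region labels, one per column.
    """

    data: np.ndarray
    tr: float
    labels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("time series data must be 2-D (time x regions)")
        if self.tr <= 0:
            raise ValueError(f"tr must be positive, got {self.tr}")
        if not self.labels:
            self.labels = [f"r{i}" for i in range(self.data.shape[1])]
        if len(self.labels) != self.data.shape[1]:
            raise ValueError("one label per region required")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("time series contains non-finite values")

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]

    @property
    def n_regions(self) -> int:
        return self.data.shape[1]


@dataclass
class Connectome:
    """Symmetric region x region matrix tagged with its representation.

    ``kind`` is one of ``correlation`` (unit diagonal, PSD), ``fisher``
    (elementwise Fisher z) or ``bw`` (Bures-Wasserstein log matrix).
    """

    matrix: np.ndarray
    kind: str = "correlation"
    participant_id: str = ""

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.kind not in ("correlation", "fisher", "bw"):
            raise ValueError(f"unknown representation kind {self.kind!r}")
        M = self.matrix
        if M.ndim != 2 or M.shape[0] != M.shape[1]:
            raise ValueError("connectome must be a square matrix")
        if not np.allclose(M, M.T, atol=1e-10):
            raise ValueError("connectome must be symmetric within 1e-10")

    @property
    def n_regions(self) -> int:
        return self.matrix.shape[0]


def _with_data(ts: RegionalTimeSeries, data: np.ndarray) -> RegionalTimeSeries:
    return replace(ts, data=data)


def detrend(ts: RegionalTimeSeries) -> RegionalTimeSeries:
    """Remove the best-fit linear trend (including intercept) per region."""
    if ts.n_frames < 3:
        raise ValueError("detrending requires at least 3 frames")
    return _with_data(ts, signal.detrend(ts.data, axis=0, type="linear"))


def bandpass(
    ts: RegionalTimeSeries,
    low: float = 0.01,
    high: float = 0.1,
    order: int = 2,
) -> RegionalTimeSeries:
    """Zero-phase Butterworth band-pass filter.

    The filter is applied forward and backward (``filtfilt``), so the
    effective attenuation is the squared magnitude response of the designed
    filter and no phase lag is introduced into the correlations.
    """
    fs = 1.0 / ts.tr
    if not 0.0 < low < high:
        raise ValueError("need 0 < low < high")
    if high >= fs / 2:
        raise ValueError(
            f"band edge {high} Hz infeasible at sampling frequency {fs:.4f} Hz"
        )
    sos = signal.butter(order, [low, high], btype="band", fs=fs, output="sos")
    return _with_data(ts, signal.sosfiltfilt(sos, ts.data, axis=0))


def flag_outlier_frames(
    position: np.ndarray,
    intensity: np.ndarray,
    displacement_mm: float = 3.0,
    intensity_sd: float = 3.0,
) -> np.ndarray:
    """Boolean mask of corrupted frames.

    A frame is flagged when its mean signal intensity deviates more than
    ``intensity_sd`` standard deviations from the scan mean (mean and SD
    computed once, not iteratively), or when the head position changes by
    more than ``displacement_mm`` millimetres relative to the previous frame
    (the later frame of the offending pair is flagged).

    Parameters
    ----------
    position : (T,) array
        Scalar head-position summary per frame, in mm.
    intensity : (T,) array
        Mean signal intensity per frame.
    """
    position = np.asarray(position, dtype=float)
    intensity = np.asarray(intensity, dtype=float)
    if position.shape != intensity.shape or position.ndim != 1:
        raise ValueError("position and intensity must be 1-D of equal length")
    mask = np.zeros(position.shape[0], dtype=bool)
    sd = intensity.std()
    if sd > 0:
        mask |= np.abs(intensity - intensity.mean()) > intensity_sd * sd
    jumps = np.abs(np.diff(position)) > displacement_mm
    mask[1:] |= jumps
    return mask


def legendre_trend_columns(n_frames: int, degree: int = 2) -> np.ndarray:
    """Orthogonal polynomial trend regressors (Legendre on [-1, 1]).

    Returns an ``(n_frames, degree + 1)`` matrix whose columns are the
    Legendre polynomials P0..P_degree evaluated on an even grid: intercept,
    linear and quadratic trends for the default degree.
    """
    x = np.linspace(-1.0, 1.0, n_frames)
    return np.polynomial.legendre.legvander(x, degree)


def regress_nuisance(
    ts: RegionalTimeSeries,
    nuisance: np.ndarray,
    mask: np.ndarray | None = None,
) -> RegionalTimeSeries:
    """Remove nuisance series and interpolate corrupted frames.

    The nuisance design (frames x regressors; motion terms, tissue
    components, trend columns) is fit by least squares on the retained
    frames only.  Retained frames keep their residual; frames flagged in
    ``mask`` are replaced by the model interpolation, i.e. their residual is
    zero.  Residuals are exactly orthogonal to the design columns.
    """
    N = np.atleast_2d(np.asarray(nuisance, dtype=float))
    if N.shape[0] != ts.n_frames:
        raise ValueError("nuisance design must have one row per frame")
    if mask is None:
        mask = np.zeros(ts.n_frames, dtype=bool)
    mask = np.asarray(mask, dtype=bool)
    good = ~mask
    Ng = N[good]
    rank = np.linalg.matrix_rank(Ng)
    if rank < N.shape[1]:
        # identify collinear columns incrementally for the error message
        bad_cols, r = [], 0
        for j in range(N.shape[1]):
            rj = np.linalg.matrix_rank(Ng[:, : j + 1])
            if rj == r:
                bad_cols.append(j)
            r = rj
        raise ValueError(
            f"nuisance design is rank deficient on retained frames; "
            f"collinear columns: {bad_cols}"
        )
    coef, *_ = np.linalg.lstsq(Ng, ts.data[good], rcond=None)
    resid = np.zeros_like(ts.data)
    resid[good] = ts.data[good] - Ng @ coef
    return _with_data(ts, resid)


def global_signal_regress(ts: RegionalTimeSeries) -> RegionalTimeSeries:
    """Regress the across-region mean series out of every region."""
    if ts.n_regions < 2:
        raise ValueError("global signal regression needs at least 2 regions")
    g = ts.data.mean(axis=1, keepdims=True)
    gg = float(g.ravel() @ g.ravel())
    if gg == 0.0:
        return ts
    beta = (g.T @ ts.data) / gg
    return _with_data(ts, ts.data - g @ beta)


def normalize(ts: RegionalTimeSeries) -> RegionalTimeSeries:
    """Center each region to zero mean and scale to unit L2 norm."""
    X = ts.data - ts.data.mean(axis=0, keepdims=True)
    norms = np.linalg.norm(X, axis=0)
    zero = np.flatnonzero(norms == 0)
    if zero.size:
        names = [ts.labels[i] for i in zero]
        raise ValueError(f"zero-variance regions cannot be normalized: {names}")
    return _with_data(ts, X / norms)


def concatenate(scans: list[RegionalTimeSeries]) -> RegionalTimeSeries:
    """Stack per-scan normalized series in time, then re-normalize.

    Every scan is normalized (zero mean, unit L2) individually, the rows are
    stacked, and each concatenated column is rescaled to unit L2 norm (it is
    already zero-mean).  Region labels must agree across scans.
    """
    if not scans:
        raise ValueError("no scans to concatenate")
    labels = scans[0].labels
    for s in scans[1:]:
        if s.labels != labels:
            raise ValueError("scans have mismatched region labels")
    parts = [normalize(s).data for s in scans]
    X = np.vstack(parts)
    X = X / np.linalg.norm(X, axis=0)
    return RegionalTimeSeries(X, scans[0].tr, list(labels))


def average_series(a: RegionalTimeSeries, b: RegionalTimeSeries) -> RegionalTimeSeries:
    """Frame-wise average of two aligned series over the same regions."""
    if a.data.shape != b.data.shape or a.labels != b.labels:
        raise ValueError("series must be aligned (same shape and regions)")
    return replace(a, data=0.5 * (a.data + b.data))


def pearson_connectome(ts: RegionalTimeSeries, participant_id: str = "") -> Connectome:
    """Pearson correlations between regional series.

    For zero-mean, unit-norm columns this is the Gram matrix of the columns;
    the diagonal is set to exactly 1 and the output symmetrized.
    """
    X = ts.data - ts.data.mean(axis=0, keepdims=True)
    norms = np.linalg.norm(X, axis=0)
    if np.any(norms == 0):
        raise ValueError("zero-variance region; normalize input first")
    X = X / norms
    C = X.T @ X
    C = 0.5 * (C + C.T)
    np.fill_diagonal(C, 1.0)
    np.clip(C, -1.0, 1.0, out=C)
    return Connectome(C, "correlation", participant_id)


def oas_shrinkage_intensity(C: np.ndarray, n: int) -> float:
    """Closed-form OAS shrinkage intensity toward ``(tr(C)/p) I``.

    For a p x p sample covariance (here: correlation) matrix estimated from
    ``n`` observations,

        rho = [(1 - 2/p) tr(C^2) + tr(C)^2]
              / [(n + 1 - 2/p) (tr(C^2) - tr(C)^2 / p)],

    clipped to [0, 1]; a non-positive denominator (e.g. C already a scaled
    identity) yields rho = 1.
    """
    C = np.asarray(C, dtype=float)
    p = C.shape[0]
    if n < 2:
        raise ValueError("OAS requires n >= 2 observations")
    tr = float(np.trace(C))
    tr2 = float(np.sum(C * C))  # trace(C @ C) for symmetric C
    num = (1.0 - 2.0 / p) * tr2 + tr**2
    den = (n + 1.0 - 2.0 / p) * (tr2 - tr**2 / p)
    if den <= 0.0:
        return 1.0
    return float(min(1.0, num / den))


def oas_shrink(C: Connectome, n: int, rho: float | None = None) -> Connectome:
    """Apply Oracle Approximating Shrinkage to a correlation connectome.

    Output is ``(1 - rho) C + rho (tr(C)/p) I`` with the OAS closed-form
    intensity (or a forced ``rho``), after which the diagonal is reset to
    exactly 1: the target's diagonal is already ``tr(C)/p = 1`` for a
    correlation matrix, so this only removes rounding.  ``n`` is the number
    of retained frames behind the correlation estimate.
    """
    if C.kind != "correlation":
        raise ValueError("OAS shrinkage applies to correlation connectomes")
    M = C.matrix
    p = M.shape[0]
    if rho is None:
        rho = oas_shrinkage_intensity(M, n)
    if not 0.0 <= rho <= 1.0:
        raise ValueError("shrinkage intensity must lie in [0, 1]")
    target = (np.trace(M) / p) * np.eye(p)
    out = (1.0 - rho) * M + rho * target
    np.fill_diagonal(out, 1.0)
    return Connectome(out, "correlation", C.participant_id)


def connectome_from_scans(
    scans: list[RegionalTimeSeries],
    participant_id: str = "",
    low: float = 0.01,
    high: float = 0.1,
    gsr: bool = True,
    oas: bool = True,
    nuisance: list[np.ndarray] | None = None,
    masks: list[np.ndarray] | None = None,
) -> Connectome:
    """Full per-participant chain from raw regional scans to a connectome.

    Each scan is detrended, band-pass filtered, optionally nuisance-cleaned
    (with frame scrubbing), global-signal regressed and normalized; scans are
    concatenated and correlated; OAS shrinkage uses the total retained frame
    count as its effective n.
    """
    cleaned = []
    n_eff = 0
    for i, scan in enumerate(scans):
        ts = bandpass(detrend(scan), low=low, high=high)
        mask = None if masks is None else masks[i]
        if nuisance is not None:
            ts = regress_nuisance(ts, nuisance[i], mask)
        if gsr:
            ts = global_signal_regress(ts)
        cleaned.append(normalize(ts))
        n_eff += scan.n_frames - (0 if mask is None else int(np.sum(mask)))
    ts = concatenate(cleaned)
    C = pearson_connectome(ts, participant_id)
    if oas:
        C = oas_shrink(C, n=n_eff)
    return C
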