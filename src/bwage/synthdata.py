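"""Synthetic multi-study cohorts with planted age/sex/site structure.

Real multi-cohort resting-state fMRI data cannot be redistributed, so this
module generates a stand-in cohort with known ground truth at every level:

* **participants** — per-study, per-sex sample sizes and age distributions
  whose defaults mirror the demographics of the four cohort studies the
  pipeline targets (a young-adult study, two elderly cohorts and one very
  large mid-to-late-life biobank, ~47% men / 53% women overall);
* **connectomes** — SPD correlation matrices whose Bures-Wasserstein log
  matrix varies *linearly* with age along a planted symmetric direction,
  plus sex and site offsets, with Wishart-type sampling noise (the sample
  covariance of a finite number of normal draws from the target matrix,
  which is how real connectomes arise from finite scans and guarantees SPD
  outputs);
* **regional time series** drawn from a target covariance, to exercise the
  preprocessing chain; and
* **health-biomarker columns** with planted correlations to a known true
  brain-age gap.

Everything is deterministic given its seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .preprocess import Connectome, RegionalTimeSeries
from .transforms import bw_inverse, bw_log_identity, is_spd

__all__ = [
    "StudyArm",
    "CohortSpec",
    "PlantedModel",
    "SEX_MAN",
    "SEX_WOMAN",
    "default_cohort_spec",
    "table1_demographics",
    "generate_cohort",
    "default_planted_model",
    "bw_mean_matrix",
    "generate_connectomes",
    "generate_timeseries",
    "generate_biomarkers",
]

SEX_MAN = 0
SEX_WOMAN = 1

# Printed per-study, per-sex demographics (n, mean age, age SD in years) of
# the four-cohort sample the pipeline was designed for.  These cells are both
# the default cohort spec and the input to the descriptive-statistics
# worked examples.
_DEMOGRAPHICS: dict[str, dict[int, tuple[int, float, float]]] = {
    "FHS": {SEX_MAN: (211, 58.54, 10.35), SEX_WOMAN: (202, 58.20, 10.16)},
    "HCP": {SEX_MAN: (471, 28.07, 3.61), SEX_WOMAN: (544, 29.46, 3.43)},
    "MESA": {SEX_MAN: (496, 74.18, 8.07), SEX_WOMAN: (561, 74.19, 8.23)},
    "UKBB": {SEX_MAN: (17787, 64.38, 7.65), SEX_WOMAN: (20142, 63.08, 7.39)},
}


@dataclass
class StudyArm:
    """Sample size and age distribution of one study x sex cell."""

    n: int
    age_mean: float
    age_sd: float

    def validate(self) -> None:
        if self.n < 0:
            raise ValueError("sample size must be >= 0")
        if self.age_sd <= 0:
            raise ValueError("age SD must be > 0")
        if self.age_mean <= 0:
            raise ValueError("mean age must be > 0")


@dataclass
class CohortSpec:
    """Per-study, per-sex sample sizes and age moments, plus site effects.

    ``arms[study][sex]`` holds a :class:`StudyArm`; ``site_effect`` gives the
    magnitude (Frobenius norm, BW-space units) of each study's location
    offset when connectomes are generated.
    """

    arms: dict[str, dict[int, StudyArm]]
    site_effect: dict[str, float] = field(default_factory=dict)
    seed: int = 0

    def validate(self) -> None:
        if not self.arms:
            raise ValueError("cohort spec declares no studies")
        for study, by_sex in self.arms.items():
            for sex, arm in by_sex.items():
                if sex not in (SEX_MAN, SEX_WOMAN):
                    raise ValueError(f"sex code must be 0 or 1, got {sex}")
                arm.validate()

    @property
    def studies(self) -> list[str]:
        return list(self.arms)

    @property
    def n_total(self) -> int:
        return sum(arm.n for by_sex in self.arms.values() for arm in by_sex.values())

    def sex_proportions(self) -> dict[int, float]:
        counts = {SEX_MAN: 0, SEX_WOMAN: 0}
        for by_sex in self.arms.values():
            for sex, arm in by_sex.items():
                counts[sex] += arm.n
        total = sum(counts.values())
        return {sex: c / total for sex, c in counts.items()}


def default_cohort_spec(scale: float = 1.0, seed: int = 0) -> CohortSpec:
    """The four-study cohort spec; ``scale`` shrinks every cell (floor, min 2).

    ``scale=1`` reproduces the full 40414-participant sample; scaled-down
    presets (e.g. ``scale=0.05``) keep the age structure for fast tests.
    """
    if scale <= 0:
        raise ValueError("scale must be positive")
    arms = {
        study: {
            sex: StudyArm(
                n=(n if scale == 1.0 else max(2, int(np.floor(n * scale)))),
                age_mean=m,
                age_sd=s,
            )
            for sex, (n, m, s) in by_sex.items()
        }
        for study, by_sex in _DEMOGRAPHICS.items()
    }
    return CohortSpec(arms=arms, site_effect={s: 0.05 for s in arms}, seed=seed)


def table1_demographics() -> pd.DataFrame:
    """Long-format table of the printed per-study, per-sex cells."""
    rows = [
        {"study": study, "sex": sex, "n": n, "age_mean": m, "age_sd": s}
        for study, by_sex in _DEMOGRAPHICS.items()
        for sex, (n, m, s) in by_sex.items()
    ]
    return pd.DataFrame(rows)


def generate_cohort(spec: CohortSpec, seed: int | None = None) -> pd.DataFrame:
    """Draw a participant table from a cohort spec.

    Ages are sampled per study x sex cell from a normal distribution
    truncated at zero (redraw semantics, i.e. the exact truncated-normal
    law, so cell means stay unbiased for the adult parameter ranges used).

    Returns a DataFrame with columns ``id, age, sex, study``.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    frames = []
    for study, by_sex in spec.arms.items():
        for sex, arm in by_sex.items():
            if arm.n == 0:
                continue
            a = (0.0 - arm.age_mean) / arm.age_sd
            ages = stats.truncnorm.rvs(
                a, np.inf, loc=arm.age_mean, scale=arm.age_sd,
                size=arm.n, random_state=rng,
            )
            frames.append(
                pd.DataFrame(
                    {
                        "id": [f"{study}_{sex}_{i:05d}" for i in range(arm.n)],
                        "age": ages,
                        "sex": sex,
                        "study": study,
                    }
                )
            )
    return pd.concat(frames, ignore_index=True)


@dataclass
class PlantedModel:
    """Generative model for connectomes: linear in BW space.

    The noise-free Bures-Wasserstein log matrix of participant ``s`` is

        E_s = E_base + slope * (age_s - age_center) * direction
              + sex_s * sex_offset + site_offset[study_s],

    mapped back to a covariance via the inverse BW transform, perturbed by
    Wishart-type noise (sample covariance of ``noise_df`` normal draws) and
    renormalized to unit diagonal.

    ``direction`` is symmetric with unit Frobenius norm; its diagonal is
    zero by default so the correlation renormalization perturbs the planted
    signal only at second order.
    """

    base: np.ndarray
    direction: np.ndarray
    slope: float
    age_center: float
    sex_offset: np.ndarray
    site_offsets: dict[str, np.ndarray] = field(default_factory=dict)
    noise_df: int | None = 200
    seed: int = 0

    def __post_init__(self) -> None:
        self.base = np.asarray(self.base, dtype=float)
        self.direction = np.asarray(self.direction, dtype=float)
        self.sex_offset = np.asarray(self.sex_offset, dtype=float)
        if not is_spd(self.base):
            raise ValueError("base matrix must be SPD")
        if not np.allclose(self.direction, self.direction.T, atol=1e-10):
            raise ValueError("planted direction must be symmetric")
        nrm = np.linalg.norm(self.direction)
        if nrm > 0 and abs(nrm - 1.0) > 1e-8:
            self.direction = self.direction / nrm
        if self.noise_df is not None and self.noise_df <= self.base.shape[0]:
            raise ValueError("noise_df must exceed the number of regions")

    @property
    def n_regions(self) -> int:
        return self.base.shape[0]


def _random_correlation(R: int, rng: np.random.Generator, n_factors: int = 3) -> np.ndarray:
    """Structured random correlation matrix from a low-rank factor model."""
    L = rng.standard_normal((R, n_factors)) / np.sqrt(n_factors)
    C = L @ L.T + 0.5 * np.eye(R)
    d = np.sqrt(np.diag(C))
    return C / np.outer(d, d)


def _random_symmetric_direction(
    R: int, rng: np.random.Generator, zero_diagonal: bool = True
) -> np.ndarray:
    M = rng.standard_normal((R, R))
    M = 0.5 * (M + M.T)
    if zero_diagonal:
        np.fill_diagonal(M, 0.0)
    return M / np.linalg.norm(M)


def default_planted_model(
    n_regions: int = 20,
    slope: float = 0.01,
    age_center: float = 63.0,
    sex_magnitude: float = 0.05,
    site_effect: dict[str, float] | None = None,
    noise_df: int | None = 200,
    seed: int = 0,
) -> PlantedModel:
    """Planted model with realistic scales.

    Defaults: a 0.01/year BW-space slope (so ages spanning ~50 years move
    the log matrix by ~0.5 Frobenius along the direction, comparable to the
    sex and site offsets of 0.05), and Wishart noise with 200 degrees of
    freedom, mimicking the effective frame count of a few minutes of
    scrubbed fMRI.
    """
    rng = np.random.default_rng(seed)
    base = _random_correlation(n_regions, rng)
    direction = _random_symmetric_direction(n_regions, rng)
    sex_off = sex_magnitude * _random_symmetric_direction(n_regions, rng)
    site_offsets = {}
    if site_effect:
        for study, mag in site_effect.items():
            site_offsets[study] = mag * _random_symmetric_direction(n_regions, rng)
    return PlantedModel(
        base=base,
        direction=direction,
        slope=slope,
        age_center=age_center,
        sex_offset=sex_off,
        site_offsets=site_offsets,
        noise_df=noise_df,
        seed=seed,
    )


def bw_mean_matrix(model: PlantedModel, age: float, sex: int, study: str) -> np.ndarray:
    """Noise-free BW log matrix for one participant under the planted model."""
    E = bw_log_identity(model.base).copy()
    E += model.slope * (age - model.age_center) * model.direction
    if sex == SEX_WOMAN:
        E += model.sex_offset
    if study in model.site_offsets:
        E += model.site_offsets[study]
    return E


def _to_correlation(S: np.ndarray) -> np.ndarray:
    d = np.sqrt(np.diag(S))
    C = S / np.outer(d, d)
    C = 0.5 * (C + C.T)
    np.fill_diagonal(C, 1.0)
    return C


def generate_connectomes(
    records: pd.DataFrame,
    model: PlantedModel,
    seed: int | None = None,
) -> list[Connectome]:
    """Sample one SPD correlation connectome per participant.

    Wishart-type noise: the sample covariance of ``noise_df`` independent
    normal draws from the participant's noise-free covariance (``None``
    disables noise).  All outputs are renormalized to unit diagonal and
    checked SPD.
    """
    rng = np.random.default_rng(model.seed if seed is None else seed)
    R = model.n_regions
    out = []
    for rec in records.itertuples(index=False):
        E = bw_mean_matrix(model, rec.age, rec.sex, rec.study)
        try:
            cov = bw_inverse(E)
        except ValueError as err:
            raise ValueError(
                f"participant {rec.id}: planted BW matrix maps to a "
                f"non-SPD covariance ({err})"
            ) from err
        if model.noise_df is not None:
            L = np.linalg.cholesky(cov + 1e-12 * np.eye(R))
            X = rng.standard_normal((model.noise_df, R)) @ L.T
            cov = (X.T @ X) / model.noise_df
        C = _to_correlation(cov)
        if not is_spd(C, floor=0.0):
            raise ValueError(f"participant {rec.id}: generated connectome not SPD")
        out.append(Connectome(C, "correlation", rec.id))
    return out


def generate_timeseries(
    cov: Connectome | np.ndarray,
    n_frames: int,
    tr: float = 0.7275,
    seed: int = 0,
) -> RegionalTimeSeries:
    """Draw a multivariate-normal regional time series with covariance ``cov``."""
    M = cov.matrix if isinstance(cov, Connectome) else np.asarray(cov, dtype=float)
    if not is_spd(M, floor=0.0):
        raise ValueError("covariance must be SPD")
    rng = np.random.default_rng(seed)
    L = np.linalg.cholesky(M)
    data = rng.standard_normal((n_frames, M.shape[0])) @ L.T
    return RegionalTimeSeries(data, tr=tr)


def generate_biomarkers(
    records: pd.DataFrame,
    true_gap: np.ndarray,
    target_correlations: dict[str, float],
    missing_rates: dict[str, float] | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Append biomarker columns with planted correlations to a true age gap.

    Each column is ``rho * z(gap) + sqrt(1 - rho^2) * noise`` (standardized
    units), so its population Pearson correlation with the gap is exactly
    the target; optional missingness is planted completely at random.
    """
    true_gap = np.asarray(true_gap, dtype=float)
    if len(true_gap) != len(records):
        raise ValueError("true_gap must have one value per participant")
    for name, rho in target_correlations.items():
        if not -1.0 < rho < 1.0:
            raise ValueError(f"target correlation for {name!r} must be in (-1, 1)")
    rng = np.random.default_rng(seed)
    z = (true_gap - true_gap.mean()) / true_gap.std()
    out = records.copy()
    missing_rates = missing_rates or {}
    for name, rho in target_correlations.items():
        noise = rng.standard_normal(len(records))
        col = rho * z + np.sqrt(1.0 - rho**2) * noise
        rate = missing_rates.get(name, 0.0)
        if rate > 0:
            col = np.where(rng.random(len(records)) < rate, np.nan, col)
        out[f"biomarker_{name}"] = col
    return out
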