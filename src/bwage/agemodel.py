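"""Age regressors, the two-stage cross-validation protocol, and cohort stats.

Three regressor families predict chronological age from compressed
connectome features: ridge regression (with the intercept column penalized,
``beta = (X'X + lambda I)^{-1} X'Y`` on the ones-augmented design), linear
epsilon-insensitive support vector regression, and RBF-kernel SVR.  SVR
hyperparameters are stored as the *inverse* of C, matching the grids below.

Model selection and validation follow a two-stage protocol:

1. **parameter setting** — a stratified 10% subset (floor of 10% per
   study x sex cell after a seeded shuffle) on which a 25-repeat
   Monte-Carlo cross-validation (shuffled half/half splits, stratified by
   study) scans the hyperparameter grids;
2. **method validation** — the remaining 90%, on which a study-stratified
   ten-fold cross-validation compares the frozen models; the RBF SVR trains
   on a random tenth of each fold's training rows for tractability.

The same folds are used for every model, so per-fold MAEs are genuinely
paired and comparable with Wilcoxon signed-rank tests.  The module also
provides the descriptive statistics used to characterize a multi-study
cohort (two-sample t-tests from summary cells, pooled-SD Cohen's d, Fisher
exact tests of sex composition).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.svm import SVR, LinearSVR

__all__ = [
    "DEFAULT_GRIDS",
    "AgeModel",
    "CVPlan",
    "stratified_split",
    "ridge_fit",
    "ridge_predict",
    "svr_fit",
    "svr_predict",
    "make_model",
    "mae",
    "monte_carlo_cv",
    "kfold_cv",
    "select_hyperparameters",
    "wilcoxon_compare",
    "two_sample_stats",
    "pooled_mean",
    "cohort_stats",
]

#: Hyperparameter grids scanned during parameter setting: ridge penalties
#: lambda, and inverse-C values for the two SVR kinds.
DEFAULT_GRIDS: dict[str, tuple[float, ...]] = {
    "ridge": (0, 10, 25, 50, 75, 100, 250, 500, 750, 1000, 2500, 5000),
    "linear-svr": (10, 25, 50, 75, 100, 250, 500, 750, 1000),
    "rbf-svr": (0.001, 0.0025, 0.005, 0.0075, 0.01, 0.025, 0.05, 0.075, 0.1),
}

#: Epsilon of the epsilon-insensitive SVR loss, in years.
SVR_EPSILON = 0.1


@dataclass
class AgeModel:
    """A fitted age regressor.

    ``hyper`` is the ridge penalty lambda for ``kind='ridge'`` and the
    inverse of C for the SVR kinds.  For linear kinds, ``beta`` holds the
    weight vector over features (ridge: intercept first).
    """

    kind: str
    hyper: float
    beta: np.ndarray | None = None
    estimator: object = None

    def predict(self, X: np.ndarray) -> np.ndarray:
        if self.kind == "ridge":
            return ridge_predict(self, X)
        return svr_predict(self, X)


def _augment(X: np.ndarray) -> np.ndarray:
    X = np.atleast_2d(np.asarray(X, dtype=float))
    return np.hstack([np.ones((X.shape[0], 1)), X])


def ridge_fit(X: np.ndarray, y: np.ndarray, lam: float) -> AgeModel:
    """Ridge regression on the ones-augmented design, intercept penalized.

    Solves ``(X_'X_ + lambda I) beta = X_'y`` with a linear solve.  At
    ``lambda = 0`` a singular system falls back to the least-squares
    pseudo-solution with a warning.
    """
    if lam < 0:
        raise ValueError("ridge penalty must be >= 0")
    Xa = _augment(X)
    y = np.asarray(y, dtype=float)
    G = Xa.T @ Xa + lam * np.eye(Xa.shape[1])
    rhs = Xa.T @ y
    try:
        if lam == 0 and np.linalg.matrix_rank(Xa) < Xa.shape[1]:
            raise np.linalg.LinAlgError("singular design at lambda=0")
        beta = np.linalg.solve(G, rhs)
    except np.linalg.LinAlgError:
        warnings.warn(
            "singular normal equations at lambda=0; using least-squares "
            "pseudo-solution (consider lambda > 0)",
            stacklevel=2,
        )
        beta, *_ = np.linalg.lstsq(Xa, y, rcond=None)
    return AgeModel(kind="ridge", hyper=lam, beta=beta)


def ridge_predict(model: AgeModel, X: np.ndarray) -> np.ndarray:
    return _augment(X) @ model.beta


def svr_fit(X: np.ndarray, y: np.ndarray, kind: str, inverse_c: float) -> AgeModel:
    """Epsilon-insensitive SVR with a linear or RBF kernel.

    ``inverse_c`` is 1/C; the linear kind uses the primal LIBLINEAR-style
    solver, the RBF kind the kernelized LIBSVM-style solver.
    """
    if inverse_c <= 0:
        raise ValueError("inverse-C must be > 0")
    C = 1.0 / inverse_c
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float)
    if kind == "linear-svr":
        est = LinearSVR(
            C=C, epsilon=SVR_EPSILON, loss="epsilon_insensitive",
            random_state=0, max_iter=20000, dual=True,
        )
    elif kind == "rbf-svr":
        est = SVR(kernel="rbf", C=C, epsilon=SVR_EPSILON)
    else:
        raise ValueError(f"unknown SVR kind {kind!r}")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        est.fit(X, y)
    beta = None
    if kind == "linear-svr":
        beta = np.concatenate([[est.intercept_.item()], est.coef_.ravel()])
    return AgeModel(kind=kind, hyper=inverse_c, beta=beta, estimator=est)


def svr_predict(model: AgeModel, X: np.ndarray) -> np.ndarray:
    yp = model.estimator.predict(np.atleast_2d(np.asarray(X, dtype=float)))
    if not np.all(np.isfinite(yp)):
        raise RuntimeError("SVR produced non-finite predictions")
    return yp


class _ModelFactory:
    """Unfitted model handle with a uniform fit(X, y) -> AgeModel surface."""

    def __init__(self, kind: str, hyper: float):
        self.kind, self.hyper = kind, hyper

    def fit(self, X, y) -> AgeModel:
        if self.kind == "ridge":
            return ridge_fit(X, y, self.hyper)
        return svr_fit(X, y, self.kind, self.hyper)


def make_model(kind: str, hyper: float) -> _ModelFactory:
    if kind not in ("ridge", "linear-svr", "rbf-svr"):
        raise ValueError(f"unknown model kind {kind!r}")
    return _ModelFactory(kind, hyper)


def mae(y_pred: np.ndarray, y_true: np.ndarray) -> float:
    """Mean absolute error in years."""
    y_pred = np.asarray(y_pred, dtype=float)
    y_true = np.asarray(y_true, dtype=float)
    if y_pred.shape != y_true.shape:
        raise ValueError("prediction and truth lengths differ")
    return float(np.mean(np.abs(y_pred - y_true)))


# ---------------------------------------------------------------------------
# Splits and cross-validation
# ---------------------------------------------------------------------------


@dataclass
class CVPlan:
    """Settings of one cross-validation stage."""

    stage: str  # "parameter-setting" | "method-validation"
    n_repeats: int = 25
    n_folds: int = 10
    grids: dict = field(default_factory=lambda: dict(DEFAULT_GRIDS))
    subsample: dict = field(default_factory=lambda: {"rbf-svr": 0.1})
    seed: int = 0

    def __post_init__(self) -> None:
        if self.stage not in ("parameter-setting", "method-validation"):
            raise ValueError(f"unknown CV stage {self.stage!r}")
        if self.n_repeats < 1 or self.n_folds < 1:
            raise ValueError("repeats and folds must be >= 1")


def stratified_split(
    records: pd.DataFrame, fraction: float = 0.10, seed: int = 0
) -> tuple[pd.Index, pd.Index]:
    """Split participant rows into parameter-setting and method-validation sets.

    Within each study x sex cell, rows are shuffled with the run seed and
    the first ``floor(fraction * n)`` go to the parameter-setting set; the
    remainder form the method-validation set.  Returns two disjoint row
    indexes covering all rows.
    """
    if not 0.0 < fraction < 1.0:
        raise ValueError("fraction must lie in (0, 1)")
    for col in ("study", "sex"):
        if col not in records.columns:
            raise ValueError(f"records must have a {col!r} column")
    rng = np.random.default_rng(seed)
    ps_parts, mv_parts = [], []
    for _, cell in records.groupby(["study", "sex"], sort=True):
        idx = cell.index.to_numpy()
        rng.shuffle(idx)
        n_ps = int(np.floor(fraction * len(idx)))
        ps_parts.append(idx[:n_ps])
        mv_parts.append(idx[n_ps:])
    return (
        pd.Index(np.concatenate(ps_parts) if ps_parts else []),
        pd.Index(np.concatenate(mv_parts) if mv_parts else []),
    )


def _stratified_half(strata: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Boolean mask selecting a stratified random half of the rows."""
    mask = np.zeros(len(strata), dtype=bool)
    for s in np.unique(strata):
        idx = np.flatnonzero(strata == s)
        rng.shuffle(idx)
        mask[idx[: len(idx) // 2]] = True
    return mask


def _stratified_folds(
    strata: np.ndarray, n_folds: int, rng: np.random.Generator
) -> np.ndarray:
    """Fold labels balanced within each stratum (sizes differ by <= 1)."""
    folds = np.zeros(len(strata), dtype=int)
    for s in np.unique(strata):
        idx = np.flatnonzero(strata == s)
        rng.shuffle(idx)
        folds[idx] = np.arange(len(idx)) % n_folds
    return folds


def monte_carlo_cv(
    X: np.ndarray,
    y: np.ndarray,
    strata: np.ndarray,
    plan: CVPlan,
    models: dict[str, tuple[float, ...]] | None = None,
) -> pd.DataFrame:
    """Repeated stratified half/half cross-validation over hyperparameter grids.

    For each of ``plan.n_repeats`` repeats, the rows are shuffled and split
    into two stratified halves; every (model kind, hyperparameter) pair is
    trained on the first half and scored (MAE) on the second.  The same
    halves are reused across all models, so MAE columns are pairable.

    Returns a tidy DataFrame with columns ``model, hyper, repeat, mae``.
    """
    if plan.stage != "parameter-setting":
        raise ValueError("monte_carlo_cv requires a parameter-setting plan")
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float)
    strata = np.asarray(strata)
    grids = models if models is not None else plan.grids
    rng = np.random.default_rng(plan.seed)
    rows = []
    for rep in range(plan.n_repeats):
        train = _stratified_half(strata, rng)
        test = ~train
        for kind, grid in grids.items():
            for hyper in grid:
                try:
                    m = make_model(kind, hyper).fit(X[train], y[train])
                    err = mae(m.predict(X[test]), y[test])
                except Exception as exc:  # noqa: BLE001 - recorded, fold skipped
                    warnings.warn(
                        f"{kind}(hyper={hyper}) failed on repeat {rep}: {exc}",
                        stacklevel=2,
                    )
                    continue
                rows.append({"model": kind, "hyper": hyper, "repeat": rep, "mae": err})
    return pd.DataFrame(rows)


def select_hyperparameters(results: pd.DataFrame) -> dict[str, float]:
    """Best hyperparameter per model kind by mean MAE over repeats."""
    means = results.groupby(["model", "hyper"])["mae"].mean()
    return {kind: float(sub.idxmin()[1]) for kind, sub in means.groupby(level=0)}


def kfold_cv(
    X: np.ndarray,
    y: np.ndarray,
    strata: np.ndarray,
    plan: CVPlan,
    models: dict[str, float],
) -> pd.DataFrame:
    """Study-stratified k-fold comparison of frozen models.

    ``models`` maps model kind to its (already selected) hyperparameter.
    Folds are identical for every model.  Kinds listed in
    ``plan.subsample`` train on the given random fraction of each fold's
    training rows (the RBF SVR trains on a random tenth by default); all
    models are evaluated on the complete test fold.

    Returns a tidy DataFrame with columns ``model, fold, mae``.
    """
    if plan.stage != "method-validation":
        raise ValueError("kfold_cv requires a method-validation plan")
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float)
    strata = np.asarray(strata)
    rng = np.random.default_rng(plan.seed)
    folds = _stratified_folds(strata, plan.n_folds, rng)
    sub_rng = np.random.default_rng(plan.seed + 1)
    rows = []
    for fold in range(plan.n_folds):
        test = folds == fold
        train_idx = np.flatnonzero(~test)
        for kind, hyper in models.items():
            idx = train_idx
            frac = plan.subsample.get(kind)
            if frac is not None and frac < 1.0:
                n_sub = max(1, int(round(frac * len(train_idx))))
                idx = sub_rng.choice(train_idx, size=n_sub, replace=False)
            try:
                m = make_model(kind, hyper).fit(X[idx], y[idx])
                err = mae(m.predict(X[test]), y[test])
            except Exception as exc:  # noqa: BLE001
                warnings.warn(f"{kind} failed on fold {fold}: {exc}", stacklevel=2)
                continue
            rows.append({"model": kind, "fold": fold, "mae": err})
    return pd.DataFrame(rows)


def wilcoxon_compare(mae_a: np.ndarray, mae_b: np.ndarray) -> float:
    """Two-sided Wilcoxon signed-rank p-value for paired MAE vectors.

    Exact null distribution for n <= 25 (when free of ties after zero
    removal), normal approximation beyond.  All-zero differences give p=1.
    """
    a = np.asarray(mae_a, dtype=float)
    b = np.asarray(mae_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired MAE vectors must have equal length")
    if len(a) < 5:
        raise ValueError("need at least 5 paired folds")
    d = a - b
    if np.all(d == 0):
        return 1.0
    method = "exact" if len(a) <= 25 else "approx"
    try:
        res = stats.wilcoxon(a, b, alternative="two-sided", method=method)
    except ValueError:
        res = stats.wilcoxon(a, b, alternative="two-sided", method="approx")
    return float(res.pvalue)


# ---------------------------------------------------------------------------
# Cohort descriptive statistics
# ---------------------------------------------------------------------------


def two_sample_stats(
    n1: int, m1: float, s1: float, n2: int, m2: float, s2: float
) -> dict[str, float]:
    """Two-sample t-test and Cohen's d from summary statistics.

    Student's t with the pooled variance, and Cohen's d with the pooled SD
    weighted by (n-1):

        d = |m1 - m2| / sqrt(((n1-1) s1^2 + (n2-1) s2^2) / (n1 + n2 - 2)).
    """
    if min(n1, n2) < 2:
        raise ValueError("each group needs at least 2 observations")
    res = stats.ttest_ind_from_stats(m1, s1, n1, m2, s2, n2, equal_var=True)
    pooled_sd = np.sqrt(((n1 - 1) * s1**2 + (n2 - 1) * s2**2) / (n1 + n2 - 2))
    return {
        "mean_diff": m1 - m2,
        "t": float(res.statistic),
        "p": float(res.pvalue),
        "cohen_d": float(abs(m1 - m2) / pooled_sd),
    }


def pooled_mean(ns, means) -> float:
    """Sample-size weighted mean of group means."""
    ns = np.asarray(ns, dtype=float)
    means = np.asarray(means, dtype=float)
    return float((ns * means).sum() / ns.sum())


def cohort_stats(records: pd.DataFrame) -> pd.DataFrame:
    """Descriptive comparisons of a multi-study participant table.

    For every study: the men-vs-women age comparison within the study, the
    study-vs-entire-sample age comparison, and a Fisher exact test of the
    study's sex composition against the rest of the sample.  Returns a tidy
    DataFrame with one row per comparison.
    """
    for col in ("age", "sex", "study"):
        if col not in records.columns:
            raise ValueError(f"records must have a {col!r} column")
    rows = []
    all_age = records["age"]
    n_all, m_all, s_all = len(all_age), all_age.mean(), all_age.std(ddof=1)
    for study, grp in records.groupby("study", sort=True):
        men = grp.loc[grp["sex"] == 0, "age"]
        women = grp.loc[grp["sex"] == 1, "age"]
        if len(men) >= 2 and len(women) >= 2:
            st = two_sample_stats(
                len(men), men.mean(), men.std(ddof=1),
                len(women), women.mean(), women.std(ddof=1),
            )
            rows.append({"study": study, "comparison": "men_vs_women", **st})
        st = two_sample_stats(
            len(grp), grp["age"].mean(), grp["age"].std(ddof=1), n_all, m_all, s_all
        )
        rows.append({"study": study, "comparison": "study_vs_all", **st})
        rest = records.loc[records["study"] != study]
        table = [
            [int((grp["sex"] == 0).sum()), int((grp["sex"] == 1).sum())],
            [int((rest["sex"] == 0).sum()), int((rest["sex"] == 1).sum())],
        ]
        _, p_fisher = stats.fisher_exact(table)
        rows.append(
            {
                "study": study,
                "comparison": "sex_composition_fisher",
                "mean_diff": np.nan,
                "t": np.nan,
                "p": float(p_fisher),
                "cohen_d": np.nan,
            }
        )
    return pd.DataFrame(rows)
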