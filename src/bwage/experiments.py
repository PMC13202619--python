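"""Seeded end-to-end experiments on synthetic cohorts.

These drivers exercise the whole pipeline under known ground truth and are
used both by the test suite and the results-reproduction script:

* :func:`recovery_experiment` — plants a linear age signal in
  Bures-Wasserstein (BW) space, runs the two-stage protocol per sex, and
  measures (a) how close BW + ridge gets to the oracle regression that
  knows the true direction, (b) whether BW features beat raw correlations
  on paired folds, and (c) how well the fitted weights recover the planted
  direction;
* :func:`crossover_experiment` — a fixed nonlinear-signal design on which
  the RBF SVR overtakes ridge as the training sample grows;
* :func:`harmonization_experiment` — planted site shifts on top of a
  shared age slope; measures residual shift and slope preservation;
* :func:`null_association_calibration` — distribution of association
  p-values when the biomarker is independent of mu.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .agemodel import (
    CVPlan,
    kfold_cv,
    make_model,
    mae,
    monte_carlo_cv,
    ridge_fit,
    stratified_split,
    wilcoxon_compare,
)
from .biomarker import associate
from .interpret import project_weights
from .pipeline import build_features
from .reduce import harmonize
from .synthdata import (
    default_cohort_spec,
    default_planted_model,
    generate_cohort,
    generate_connectomes,
)

__all__ = [
    "recovery_experiment",
    "crossover_experiment",
    "harmonization_experiment",
    "null_association_calibration",
]


def _cosine(A: np.ndarray, B: np.ndarray) -> float:
    a, b = A.ravel(), B.ravel()
    return float(a @ b / (np.linalg.norm(a) * np.linalg.norm(b)))


def recovery_experiment(
    seed: int = 0,
    scale: float = 0.1,
    n_regions: int = 20,
    slope: float = 0.01,
    noise_df: int = 200,
    pi: float = 0.999,
    ridge_grid: tuple[float, ...] = (0, 10, 25, 50, 75, 100, 250, 500, 750, 1000, 2500, 5000),
    n_repeats: int = 25,
) -> dict:
    """Parameter-recovery run of the full pipeline on a planted cohort.

    A multi-study cohort (default ``scale=0.1``, ~4000 participants) is
    generated with a linear BW-space age slope plus sex and site offsets
    and Wishart noise.  Separately per sex: features are built for the BW
    and raw-correlation representations (SVD compression + harmonization
    across studies with age as covariate, both fit on the sex's full
    table), the ridge penalty is selected on the stratified 10%
    parameter-setting subset by Monte-Carlo cross-validation, and the
    frozen models are compared by study-stratified ten-fold CV on the
    method-validation rows — on identical folds, together with the oracle
    1-D regression on the true planted direction.

    Returns a dict with per-sex fold tables and the pooled summary:
    ``mae_bw``, ``mae_corr``, ``mae_oracle`` (mean over 20 paired folds),
    ``wilcoxon_p_bw_vs_corr``, ``cosine`` (min over sexes),
    ``mae_ratio_vs_oracle``.
    """
    spec = default_cohort_spec(scale=scale, seed=seed)
    model = default_planted_model(
        n_regions=n_regions, slope=slope, site_effect=spec.site_effect,
        noise_df=noise_df, seed=seed + 1,
    )
    records = generate_cohort(spec, seed=seed + 2)
    conns = generate_connectomes(records, model, seed=seed + 3)

    fold_frames, cosines = [], []
    for sex in sorted(records["sex"].unique()):
        sel = (records["sex"] == sex).to_numpy()
        recs = records.loc[sel].reset_index(drop=True)
        sub = [c for c, m in zip(conns, sel) if m]
        age = recs["age"].to_numpy()
        study = recs["study"].to_numpy()
        covs = age[:, None]  # sex constant within the group

        feats, bases = {}, {}
        for kind in ("bw", "correlation"):
            fs = build_features(sub, kind=kind, pi=pi)
            Xh, _ = harmonize(fs.X, study, covs)
            feats[kind] = Xh
            bases[kind] = fs.basis
        # oracle: score along the true planted direction (Frobenius inner
        # product with each participant's BW log matrix)
        from .pipeline import apply_representation

        bw_mats = [c.matrix for c in apply_representation(sub, "bw")]
        oracle_score = np.array([_frob_inner(E, model.direction) for E in bw_mats])
        feats["oracle"] = oracle_score[:, None]

        ps_idx, mv_idx = stratified_split(recs, fraction=0.10, seed=seed + 10)
        ps = recs.index.isin(ps_idx)
        mv = ~ps

        lambdas = {}
        for kind in ("bw", "correlation"):
            plan = CVPlan(stage="parameter-setting", n_repeats=n_repeats, seed=seed + 20)
            res = monte_carlo_cv(
                feats[kind][ps], age[ps], study[ps], plan, models={"ridge": ridge_grid}
            )
            lambdas[kind] = float(res.groupby("hyper")["mae"].mean().idxmin())
        lambdas["oracle"] = 0.0

        plan_mv = CVPlan(stage="method-validation", n_folds=10, seed=seed + 30, subsample={})
        per_kind = {}
        for kind in ("bw", "correlation", "oracle"):
            tbl = kfold_cv(
                feats[kind][mv], age[mv], study[mv], plan_mv, {"ridge": lambdas[kind]}
            )
            tbl = tbl.assign(representation=kind, sex=sex)
            per_kind[kind] = tbl
            fold_frames.append(tbl)

        fitted = ridge_fit(feats["bw"][mv], age[mv], lambdas["bw"])
        B = project_weights(fitted.beta[1:], bases["bw"])
        cosines.append(abs(_cosine(B, model.direction)))

    folds = pd.concat(fold_frames, ignore_index=True)
    pivot = folds.pivot_table(
        index=["sex", "fold"], columns="representation", values="mae"
    )
    p = wilcoxon_compare(pivot["bw"].to_numpy(), pivot["correlation"].to_numpy())
    mae_bw = float(pivot["bw"].mean())
    mae_oracle = float(pivot["oracle"].mean())
    return {
        "folds": folds,
        "mae_bw": mae_bw,
        "mae_corr": float(pivot["correlation"].mean()),
        "mae_oracle": mae_oracle,
        "mae_ratio_vs_oracle": mae_bw / mae_oracle,
        "wilcoxon_p_bw_vs_corr": p,
        "cosine": float(min(cosines)),
        "n_participants": int(len(records)),
    }


def _frob_inner(A: np.ndarray, B: np.ndarray) -> float:
    return float(np.sum(A * B))


def _crossover_features(
    n: int, rng: np.random.Generator, n_noise: int = 16
) -> tuple[np.ndarray, np.ndarray]:
    """Fixed nonlinear design: age is recoverable from a noisy squared
    latent plus a noisy linear channel, embedded in pure-noise features.

    The linear channel alone gives a linear model a solid error floor; the
    squared channel can only be exploited nonlinearly, and the distractor
    dimensions slow kernel methods down at small sample sizes.
    """
    age = rng.uniform(40.0, 80.0, size=n)
    z = (age - 60.0) / 12.0
    x1 = z**2 + 0.5 * rng.standard_normal(n)
    x2 = z + 0.6 * rng.standard_normal(n)
    noise = rng.standard_normal((n, n_noise))
    X = np.column_stack([x1, x2, noise])
    return X, age


def crossover_experiment(
    seed: int = 0,
    n_small: int = 500,
    n_large: int = 3000,
    n_test: int = 2000,
    select_repeats: int = 5,
    grids: dict | None = None,
) -> dict:
    """Sample-size crossover between ridge and the RBF SVR.

    At each training size, each model's hyperparameter is selected by
    Monte-Carlo cross-validation (stratified halves) inside the training
    set over the standard grids, the model is refit on the full training
    set, and the MAE is measured on a common held-out test set.

    Returns per-size MAEs: ridge should be at least as good as the RBF SVR
    at the small size and strictly worse at the large one.
    """
    if grids is None:
        from .agemodel import DEFAULT_GRIDS

        grids = {"ridge": DEFAULT_GRIDS["ridge"], "rbf-svr": DEFAULT_GRIDS["rbf-svr"]}
    rng = np.random.default_rng(seed)
    X_test, y_test = _crossover_features(n_test, rng)
    out: dict = {"seed": seed}
    for label, n in (("small", n_small), ("large", n_large)):
        X, y = _crossover_features(n, rng)
        strata = np.zeros(n, dtype=int)
        plan = CVPlan(stage="parameter-setting", n_repeats=select_repeats, seed=seed + 7)
        res = monte_carlo_cv(X, y, strata, plan, models=grids)
        means = res.groupby(["model", "hyper"])["mae"].mean()
        for kind in grids:
            hyper = float(means.loc[kind].idxmin())
            m = make_model(kind, hyper).fit(X, y)
            out[f"mae_{kind.replace('-', '_')}_{label}"] = mae(m.predict(X_test), y_test)
            out[f"hyper_{kind.replace('-', '_')}_{label}"] = hyper
    return out


def harmonization_experiment(
    n_per_site: int = 300,
    n_sites: int = 3,
    n_features: int = 20,
    shift_sd: float = 1.0,
    noise_sd: float = 1.0,
    slope_sd: float = 0.05,
    seed: int = 0,
) -> dict:
    """Planted site shifts on top of a shared age slope.

    Each feature carries the same age slope at every site, plus a per-site
    per-feature mean shift and unit-SD noise.  After harmonization (age and
    sex as covariates) the maximum absolute between-site mean difference of
    each feature is compared to the within-site SD.  Slope preservation is
    measured by refitting the age slope feature-wise before (with site
    dummies, so the planted shifts do not confound it) and after
    harmonization: the comparison isolates what harmonization changes,
    independently of OLS sampling noise shared by both fits.

    Returns ``residual_shift_ratio`` (max over features of between-site
    mean spread / within-site SD) and ``max_slope_error`` (max relative
    slope change, after vs before).
    """
    rng = np.random.default_rng(seed)
    sites = np.repeat(np.arange(n_sites), n_per_site)
    n = len(sites)
    age = rng.uniform(40.0, 80.0, size=n)
    sex = rng.integers(0, 2, size=n)
    slopes = slope_sd * rng.standard_normal(n_features)
    slopes[np.abs(slopes) < 0.02] = 0.02  # keep relative errors well defined
    shifts = shift_sd * rng.standard_normal((n_sites, n_features))
    Y = (
        np.outer(age - 60.0, slopes)
        + shifts[sites]
        + noise_sd * rng.standard_normal((n, n_features))
    )
    covs = np.column_stack([age, sex])
    Yh, _ = harmonize(Y, sites, covs)

    site_dummies = np.eye(n_sites)[sites]
    design_raw = np.column_stack([site_dummies, age, sex])
    coef_raw, *_ = np.linalg.lstsq(design_raw, Y, rcond=None)
    slope_raw = coef_raw[n_sites]
    design = np.column_stack([np.ones(n), age, sex])
    coef, *_ = np.linalg.lstsq(design, Yh, rcond=None)
    slope_h = coef[1]
    resid = Yh - design @ coef
    shift_ratios = []
    for g in range(n_features):
        means = np.array([resid[sites == s, g].mean() for s in range(n_sites)])
        within = np.mean([resid[sites == s, g].std(ddof=1) for s in range(n_sites)])
        shift_ratios.append((means.max() - means.min()) / within)
    slope_errs = np.abs(slope_h - slope_raw) / np.abs(slope_raw)
    return {
        "residual_shift_ratio": float(np.max(shift_ratios)),
        "max_slope_error": float(np.max(slope_errs)),
        "planted_shift_sd": shift_sd,
    }


def null_association_calibration(
    n: int = 200, replicates: int = 500, seed: int = 0
) -> dict:
    """Association p-values when mu and the biomarker are independent.

    Under the null the coefficient p-value is Uniform(0, 1); returns the
    replicate p-values and a Kolmogorov-Smirnov test against uniformity.
    """
    rng = np.random.default_rng(seed)
    pvals = np.empty(replicates)
    for r in range(replicates):
        mu = rng.standard_normal(n)
        x = rng.standard_normal(n)
        pvals[r] = associate(mu, x, name="null").p
    ks = stats.kstest(pvals, "uniform")
    return {"pvalues": pvals, "ks_p": float(ks.pvalue), "replicates": replicates}
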