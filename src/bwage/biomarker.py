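"""The residualized brain-age-gap biomarker and its audits.

The raw brain-age gap ``delta = predicted - actual age`` correlates with age
itself (regression-to-the-mean of any imperfect age predictor), so the
biomarker is defined as the *negated residual* of a linear age/sex trend:

    mu = -(delta - delta*),   delta* = b1 + b2*age + b3*sex + b4*age*sex,

fitted by OLS.  The sign flip makes mu positive when the brain appears
younger than expected, so that higher mu is expected to accompany better
health.  By construction mu is exactly uncorrelated with age, sex and their
interaction on the fitting sample.

Associations with health/cognitive variables are simple OLS fits
``mu ~ const + biomarker`` reporting the raw coefficient alpha, adjusted
R^2, the standardized coefficient ``beta = alpha * sd(biomarker) / sd(mu)``
(equal to the Pearson correlation), its 95% CI and the coefficient p-value.
Categorical fields are ordinally encoded and physiologically impossible
records excluded first (see :class:`EncodingRules`).

Bias audits check mu across demographic groups with Kruskal-Wallis H tests
(run separately per sex; small groups dropped) and against neighborhood
composition proportions with Pearson correlations.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

__all__ = [
    "TrendFit",
    "AssociationResult",
    "EncodingRules",
    "default_encoding_rules",
    "compute_delta",
    "fit_age_trend",
    "compute_mu",
    "mu_from_predictions",
    "encode_biomarkers",
    "associate",
    "associate_all",
    "bias_audit_groups",
    "bias_audit_proportions",
    "majority_group",
]


def compute_delta(y_pred: np.ndarray, y_true: np.ndarray) -> np.ndarray:
    """Brain-age gap: predicted minus actual age, in years."""
    y_pred = np.asarray(y_pred, dtype=float)
    y_true = np.asarray(y_true, dtype=float)
    if y_pred.shape != y_true.shape:
        raise ValueError("prediction and age vectors must be paired")
    return y_pred - y_true


@dataclass
class TrendFit:
    """OLS age/sex trend of delta: coefficients and fitted values."""

    beta: np.ndarray  # (b1, b2, b3, b4) = intercept, age, sex, age*sex
    delta_star: np.ndarray
    dropped_sex_terms: bool = False


def fit_age_trend(delta: np.ndarray, age: np.ndarray, sex: np.ndarray) -> TrendFit:
    """Fit ``delta* = b1 + b2*age + b3*sex + b4*age*sex`` by OLS.

    With a single-sex sample the sex and interaction columns are collinear
    with the rest of the design; they are dropped with a warning and their
    coefficients reported as 0.
    """
    delta = np.asarray(delta, dtype=float)
    age = np.asarray(age, dtype=float)
    sex = np.asarray(sex, dtype=float)
    if not (len(delta) == len(age) == len(sex)):
        raise ValueError("delta, age and sex must be aligned")
    if len(delta) <= 4:
        raise ValueError("need more than 4 observations to fit the trend")
    dropped = np.unique(sex).size < 2
    if dropped:
        warnings.warn(
            "single-sex sample: dropping sex and age*sex terms from the "
            "delta trend",
            stacklevel=2,
        )
        X = np.column_stack([np.ones_like(age), age])
    else:
        X = np.column_stack([np.ones_like(age), age, sex, age * sex])
    fit = sm.OLS(delta, X).fit()
    beta = np.zeros(4)
    if dropped:
        beta[:2] = fit.params
    else:
        beta[:] = fit.params
    return TrendFit(beta=beta, delta_star=np.asarray(fit.fittedvalues), dropped_sex_terms=dropped)


def compute_mu(delta: np.ndarray, delta_star: np.ndarray) -> np.ndarray:
    """The biomarker ``mu = -(delta - delta*)``; positive = younger-looking."""
    delta = np.asarray(delta, dtype=float)
    delta_star = np.asarray(delta_star, dtype=float)
    if delta.shape != delta_star.shape:
        raise ValueError("delta and delta* must be paired")
    return -(delta - delta_star)


def mu_from_predictions(
    y_pred: np.ndarray, y_true: np.ndarray, sex: np.ndarray
) -> tuple[np.ndarray, TrendFit]:
    """Convenience chain: delta, trend fit, mu, in one call."""
    delta = compute_delta(y_pred, y_true)
    trend = fit_age_trend(delta, y_true, sex)
    return compute_mu(delta, trend.delta_star), trend


# ---------------------------------------------------------------------------
# Encoding and exclusion rules for health/cognitive variables
# ---------------------------------------------------------------------------

OVERALL_HEALTH_ENCODING = {"poor": 0, "fair": 1, "good": 2, "excellent": 3}
ALCOHOL_ENCODING = {
    "never": 0,
    "special occasions only": 1,
    "one to three times a month": 2,
    "once or twice a week": 3,
    "three or four times a week": 4,
    "daily or almost daily": 5,
}
PROCESSED_MEAT_ENCODING = {
    "never": 0,
    "less than once a week": 1,
    "once a week": 2,
    "2-4 times a week": 3,
    "5-6 times a week": 4,
    "once or more daily": 5,
}


@dataclass
class EncodingRules:
    """How raw biomarker columns become numeric analysis columns.

    * ``ordinal``: per-column string -> integer codes (case-insensitive);
    * ``exclusions``: per-column ``(op, threshold)`` pairs, ``op`` one of
      ``"<"``/``">"``; matching values are discarded (set NaN) and logged;
    * ``derived``: arterial stiffness index = height / pulse propagation
      time, computed when both source columns are present.

    Encoding and exclusion commute: codes are assigned independently of
    exclusions, so encode-then-exclude equals exclude-then-encode.
    """

    ordinal: dict[str, dict[str, int]] = field(default_factory=dict)
    exclusions: dict[str, tuple[str, float]] = field(default_factory=dict)
    stiffness_from: tuple[str, str] | None = None  # (height, pulse_time)
    stiffness_name: str = "stiffness"


def default_encoding_rules() -> EncodingRules:
    """Default encodings and abnormal-record filters.

    Overall health 0-3, alcohol frequency 0-5, processed-meat intake 0-5;
    education completed before age 15 and arterial stiffness index above 3
    are treated as abnormal records and discarded.
    """
    return EncodingRules(
        ordinal={
            "health": OVERALL_HEALTH_ENCODING,
            "alcohol": ALCOHOL_ENCODING,
            "meat": PROCESSED_MEAT_ENCODING,
        },
        exclusions={"education": ("<", 15.0), "stiffness": (">", 3.0)},
        stiffness_from=("height", "pulse_time"),
    )


def encode_biomarkers(
    df: pd.DataFrame, rules: EncodingRules
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Apply derivations, ordinal encodings and exclusion rules.

    Returns the encoded copy and a log of excluded cells (columns: ``row``,
    ``column``, ``value``, ``reason``).
    """
    out = df.copy()
    log_rows = []
    if rules.stiffness_from is not None:
        h, t = rules.stiffness_from
        if h in out.columns and t in out.columns:
            with np.errstate(divide="ignore", invalid="ignore"):
                out[rules.stiffness_name] = out[h] / out[t]
    for col, mapping in rules.ordinal.items():
        if col not in out.columns:
            continue
        if out[col].dtype == object:
            lowered = {k.lower(): v for k, v in mapping.items()}
            enc = out[col].map(lambda s: lowered.get(s.lower()) if isinstance(s, str) else s)
            bad = out[col].notna() & enc.isna()
            for i in out.index[bad]:
                log_rows.append(
                    {"row": i, "column": col, "value": out.at[i, col], "reason": "unmapped level"}
                )
            out[col] = enc.astype(float)
        values = out[col].dropna()
        lo, hi = min(mapping.values()), max(mapping.values())
        if len(values) and (values.min() < lo or values.max() > hi):
            raise ValueError(f"encoded values for {col!r} fall outside [{lo}, {hi}]")
    for col, (op, thresh) in rules.exclusions.items():
        if col not in out.columns:
            continue
        vals = out[col]
        bad = (vals < thresh) if op == "<" else (vals > thresh)
        bad &= vals.notna()
        for i in out.index[bad]:
            log_rows.append(
                {"row": i, "column": col, "value": vals[i], "reason": f"{col} {op} {thresh}"}
            )
        out.loc[bad, col] = np.nan
    return out, pd.DataFrame(log_rows, columns=["row", "column", "value", "reason"])


# ---------------------------------------------------------------------------
# Associations
# ---------------------------------------------------------------------------


@dataclass
class AssociationResult:
    """One row of the association report."""

    name: str
    n: int
    alpha: float
    adj_r2: float
    beta: float  # standardized coefficient = Pearson r
    ci_low: float
    ci_high: float
    p: float


def associate(mu: np.ndarray, biomarker: np.ndarray, name: str = "") -> AssociationResult:
    """OLS of mu on one encoded biomarker; standardized effect and CI.

    Rows with missing values are dropped; at least 10 complete pairs are
    required.  The standardized coefficient ``beta = alpha * sd(biomarker)
    / sd(mu)`` equals the Pearson correlation between the two variables;
    its 95% CI is the alpha CI scaled by the same ratio.
    """
    mu = np.asarray(mu, dtype=float)
    x = np.asarray(biomarker, dtype=float)
    if mu.shape != x.shape:
        raise ValueError("mu and biomarker must be aligned")
    keep = np.isfinite(mu) & np.isfinite(x)
    mu, x = mu[keep], x[keep]
    n = len(mu)
    if n < 10:
        raise ValueError(f"need at least 10 complete pairs, got {n}")
    if np.std(x) == 0:
        raise ValueError(f"biomarker {name!r} has zero variance")
    X = sm.add_constant(x)
    fit = sm.OLS(mu, X).fit()
    alpha = float(fit.params[1])
    scale = float(np.std(x, ddof=1) / np.std(mu, ddof=1))
    ci = fit.conf_int(alpha=0.05)[1]
    return AssociationResult(
        name=name,
        n=n,
        alpha=alpha,
        adj_r2=float(fit.rsquared_adj),
        beta=alpha * scale,
        ci_low=float(ci[0]) * scale,
        ci_high=float(ci[1]) * scale,
        p=float(fit.pvalues[1]),
    )


def associate_all(
    mu: np.ndarray,
    biomarkers: pd.DataFrame,
    rules: EncodingRules | None = None,
) -> pd.DataFrame:
    """Association report for every biomarker column, in one pass.

    Applies the encoding/exclusion rules first when given.  Returns a tidy
    DataFrame with columns ``biomarker, n, adj_r2, beta, ci_low, ci_high,
    p`` (one row per analyzable column; columns failing preconditions are
    reported with NaN statistics).
    """
    if rules is not None:
        biomarkers, _ = encode_biomarkers(biomarkers, rules)
    rows = []
    for col in biomarkers.columns:
        try:
            r = associate(mu, biomarkers[col].to_numpy(dtype=float), name=col)
            rows.append(
                {
                    "biomarker": col, "n": r.n, "adj_r2": r.adj_r2, "beta": r.beta,
                    "ci_low": r.ci_low, "ci_high": r.ci_high, "p": r.p,
                }
            )
        except (ValueError, TypeError) as exc:
            warnings.warn(f"skipping {col!r}: {exc}", stacklevel=2)
            rows.append(
                {
                    "biomarker": col, "n": 0, "adj_r2": np.nan, "beta": np.nan,
                    "ci_low": np.nan, "ci_high": np.nan, "p": np.nan,
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Bias audits
# ---------------------------------------------------------------------------


def bias_audit_groups(
    mu: np.ndarray,
    memberships: pd.DataFrame,
    sex: np.ndarray,
    min_group_size: int = 7,
) -> pd.DataFrame:
    """Kruskal-Wallis H test of mu across (possibly overlapping) groups.

    ``memberships`` holds one binary column per group; a participant in
    several groups contributes their mu once per group, so group samples
    are not statistically independent (flagged in the output).  Groups with
    fewer than ``min_group_size`` members are dropped with a warning.  The
    test runs separately per sex.

    Returns a DataFrame with columns ``sex, H, p, n_groups, overlapping``.
    """
    mu = np.asarray(mu, dtype=float)
    sex = np.asarray(sex)
    M = memberships.astype(bool)
    rows = []
    for s in np.unique(sex):
        sel = sex == s
        samples, used = [], []
        for col in M.columns:
            grp = mu[sel & M[col].to_numpy()]
            if len(grp) < min_group_size:
                warnings.warn(
                    f"group {col!r} (sex={s}) has {len(grp)} members; dropped",
                    stacklevel=2,
                )
                continue
            samples.append(grp)
            used.append(col)
        if len(samples) < 2:
            raise ValueError(f"fewer than 2 usable groups for sex={s}")
        H, p = stats.kruskal(*samples)
        overlap = bool((M[used].to_numpy()[sel].sum(axis=1) > 1).any())
        rows.append(
            {"sex": s, "H": float(H), "p": float(p), "n_groups": len(used),
             "overlapping": overlap}
        )
    return pd.DataFrame(rows)


def majority_group(proportions: pd.DataFrame) -> pd.Series:
    """Assign each row to its largest proportion (ties: first declared column)."""
    P = proportions.to_numpy(dtype=float)
    if np.any(P < 0) or np.any(P > 1):
        raise ValueError("proportions must lie in [0, 1]")
    cols = list(proportions.columns)
    return pd.Series(
        [cols[j] for j in np.argmax(P, axis=1)], index=proportions.index, name="majority"
    )


def bias_audit_proportions(
    mu: np.ndarray,
    proportions: pd.DataFrame,
    sex: np.ndarray,
    min_group_size: int = 7,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pearson correlation of mu with each neighborhood proportion, per sex.

    Also assigns every participant to the most frequent group in their
    neighborhood and repeats the Kruskal-Wallis audit on that grouping.
    Returns ``(correlations, kruskal)`` DataFrames.
    """
    mu = np.asarray(mu, dtype=float)
    sex = np.asarray(sex)
    rows = []
    for s in np.unique(sex):
        sel = sex == s
        for col in proportions.columns:
            x = proportions[col].to_numpy(dtype=float)[sel]
            if np.std(x) == 0:
                warnings.warn(f"proportion {col!r} constant for sex={s}; skipped", stacklevel=2)
                rows.append({"sex": s, "proportion": col, "r": np.nan, "p": np.nan})
                continue
            r, p = stats.pearsonr(x, mu[sel])
            rows.append({"sex": s, "proportion": col, "r": float(r), "p": float(p)})
    assigned = majority_group(proportions)
    membership = pd.get_dummies(assigned)
    kw = bias_audit_groups(mu, membership, sex, min_group_size=min_group_size)
    return pd.DataFrame(rows), kw
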