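"""Downstream clinical statistics for the stratified cohort.

Operations mirror a randomized sham-controlled stimulation trial analyzed after
model-based stratification: a chi-squared control for treatment/subtype
allocation, per-item change scores referenced to the sham group's median
improvement, balanced resampling of treatment-by-subtype cells, logistic models
of baseline items on subtype with 1000-replicate bootstrap odds-ratio CIs,
linear models of symptom change with a treatment-by-subtype interaction, and a
nested ANOVA of subtype within treatment.  Higher scores mean more severe
symptoms on every scale, so improvement = -(follow-up - baseline).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

__all__ = [
    "SCALES",
    "BootstrapResult",
    "item_columns",
    "validate_cohort",
    "chi2_2x2",
    "allocation_table",
    "change_scores",
    "balanced_bootstrap",
    "fit_logistic_bootstrap",
    "fit_linear_bootstrap",
    "nested_anova",
]

logger = logging.getLogger(__name__)

#: symptom scales: name -> (number of items, per-item maximum; minimum is 0)
SCALES = {"madrs": (9, 6), "bprs": (5, 7), "cains": (13, 4)}
#: executive-function tasks analyzed on the log-seconds scale
TMT_TASKS = ("tmt_a", "tmt_b")

REQUIRED_META = ["subject_id", "treatment", "subtype", "age", "sex"]


def item_columns() -> list[str]:
    """All per-item score column stems (without the _base/_fu suffix)."""
    cols = [f"{scale}{i}" for scale, (n, _mx) in SCALES.items() for i in range(1, n + 1)]
    return cols + list(TMT_TASKS)


def validate_cohort(df: pd.DataFrame) -> None:
    missing = [c for c in REQUIRED_META if c not in df.columns]
    if missing:
        raise ValueError(f"cohort table missing columns: {missing}")
    if df["subject_id"].duplicated().any():
        raise ValueError("duplicate subject ids")
    if not set(df["treatment"]).issubset({"active", "sham"}):
        raise ValueError("treatment must be 'active' or 'sham'")
    if not set(df["subtype"]).issubset({"DEP1", "DEP2"}):
        raise ValueError("subtype must be 'DEP1' or 'DEP2'")
    for scale, (n, mx) in SCALES.items():
        for i in range(1, n + 1):
            for sess in ("base", "fu"):
                col = f"{scale}{i}_{sess}"
                if col in df.columns:
                    vals = df[col].dropna()
                    if ((vals < 0) | (vals > mx)).any():
                        raise ValueError(f"{col}: scores outside [0, {mx}]")


def chi2_2x2(table: np.ndarray) -> tuple[float, int, float]:
    """Pearson chi-squared for a 2x2 table, no continuity correction.

    Returns (statistic, df=1, p).  Expected counts come from the product of
    marginals over the grand total.
    """
    obs = np.asarray(table, dtype=float)
    if obs.shape != (2, 2):
        raise ValueError("need a 2x2 table")
    if np.any(obs < 0):
        raise ValueError("counts must be nonnegative")
    row = obs.sum(axis=1, keepdims=True)
    col = obs.sum(axis=0, keepdims=True)
    total = obs.sum()
    if np.any(row == 0) or np.any(col == 0):
        raise ValueError("zero marginal in contingency table")
    expected = row @ col / total
    statistic = float(((obs - expected) ** 2 / expected).sum())
    return statistic, 1, float(stats.chi2.sf(statistic, 1))


def allocation_table(df: pd.DataFrame) -> np.ndarray:
    """2x2 treatment (sham, active) x subtype (DEP1, DEP2) counts."""
    return np.array(
        [
            [
                int(((df["treatment"] == t) & (df["subtype"] == s)).sum())
                for s in ("DEP1", "DEP2")
            ]
            for t in ("sham", "active")
        ]
    )


def change_scores(df: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-item change (follow-up - baseline) and improvement vs sham median.

    Improvement is -change (all scales score severity); the second table is
    each subject's improvement minus the sham group's median improvement for
    that item.  Subjects with a missing baseline or follow-up are dropped for
    that item (counts logged).
    """
    validate_cohort(df)
    meta = df[REQUIRED_META].copy()
    change = meta.copy()
    vs_sham = meta.copy()
    sham_mask = (df["treatment"] == "sham").to_numpy()
    for stem in item_columns():
        b, f = f"{stem}_base", f"{stem}_fu"
        if b not in df.columns or f not in df.columns:
            continue
        delta = df[f] - df[b]
        n_missing = int(delta.isna().sum())
        if n_missing:
            logger.info("item %s: dropping %d subject(s) with missing cells", stem, n_missing)
        improvement = -delta
        sham_median = improvement[sham_mask].median()
        change[stem] = delta
        vs_sham[stem] = improvement - sham_median
    return change, vs_sham


def balanced_bootstrap(df: pd.DataFrame, seed: int = 0) -> pd.DataFrame:
    """Equalize subtype cell sizes within each treatment arm by resampling.

    Within each arm the smaller subtype cell is resampled with replacement up
    to the larger cell's size; already-equal cells pass through unchanged.
    Deterministic given seed.
    """
    validate_cohort(df)
    rng = np.random.default_rng(seed)
    pieces = []
    for arm in ("sham", "active"):
        cells = {
            s: df[(df["treatment"] == arm) & (df["subtype"] == s)]
            for s in ("DEP1", "DEP2")
        }
        sizes = {s: len(c) for s, c in cells.items()}
        if min(sizes.values()) == 0:
            raise ValueError(f"empty treatment-by-subtype cell in arm {arm!r}")
        target = max(sizes.values())
        for s in ("DEP1", "DEP2"):
            cell = cells[s]
            if len(cell) == target:
                pieces.append(cell)
            else:
                idx = rng.integers(0, len(cell), size=target)
                pieces.append(cell.iloc[idx])
    return pd.concat(pieces, ignore_index=True)


@dataclass
class BootstrapResult:
    term: str
    estimate: float
    ci_low: float
    ci_high: float
    n_boot: int
    seed: int
    n_dropped: int = 0


def _logit_fit(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    """IRLS maximum-likelihood logistic fit; raises on separation/divergence."""
    model = sm.GLM(y, X, family=sm.families.Binomial())
    res = model.fit(maxiter=100, tol=1e-8)
    coef = np.asarray(res.params)
    if not np.all(np.isfinite(coef)) or np.abs(coef).max() > 15:
        # |coef| > 15 on ordinal predictors means fitted odds beyond e15:
        # (quasi-)complete separation rather than a real effect
        raise np.linalg.LinAlgError("separation")
    return coef


def fit_logistic_bootstrap(
    items: pd.DataFrame,
    subtype: np.ndarray,
    n_boot: int = 1000,
    seed: int = 0,
) -> list[BootstrapResult]:
    """Logistic model of binary subtype on item scores with bootstrap ORs.

    Fits by IRLS on the full sample, then resamples subjects with replacement
    ``n_boot`` times, refitting and recording exp(coefficients).  Replicates
    that fail to converge or separate are dropped and counted; more than 50%
    dropped raises an 'unstable model' error.  Returns one percentile-CI
    result per item on the odds-ratio scale (intercept omitted).
    """
    y = np.asarray(subtype, dtype=float)
    classes, counts = np.unique(y, return_counts=True)
    if classes.size != 2 or counts.min() < 2:
        raise ValueError("need at least 2 subjects in each class")
    X = np.column_stack([np.ones(len(items)), items.to_numpy(dtype=float)])
    names = list(items.columns)
    try:
        full = _logit_fit(X, y)
    except Exception as exc:  # noqa: BLE001 - separation on the full sample
        raise ValueError(f"logistic fit failed on the full sample: {exc}") from exc

    rng = np.random.default_rng(seed)
    n = len(y)
    boots = []
    dropped = 0
    for _ in range(n_boot):
        idx = rng.integers(0, n, size=n)
        if np.unique(y[idx]).size < 2:
            dropped += 1
            continue
        try:
            boots.append(_logit_fit(X[idx], y[idx]))
        except Exception:  # noqa: BLE001
            dropped += 1
    if dropped > n_boot / 2:
        raise ValueError(
            f"unstable model: {dropped}/{n_boot} bootstrap replicates dropped"
        )
    if dropped:
        logger.info("logistic bootstrap: dropped %d/%d replicates", dropped, n_boot)
    arr = np.exp(np.vstack(boots))  # odds-ratio scale
    lo, hi = np.percentile(arr, [2.5, 97.5], axis=0)
    return [
        BootstrapResult(name, float(np.exp(full[k + 1])), float(lo[k + 1]),
                        float(hi[k + 1]), n_boot, seed, dropped)
        for k, name in enumerate(names)
    ]


def _linear_design(
    treatment: np.ndarray,
    subtype: np.ndarray,
    baseline: np.ndarray,
    age: np.ndarray,
    sex: np.ndarray,
) -> tuple[np.ndarray, list[str]]:
    t = (np.asarray(treatment) == "active").astype(float)
    s = (np.asarray(subtype) == "DEP2").astype(float)
    x = (np.asarray(sex) == "F").astype(float) if np.asarray(sex).dtype.kind in "OU" else np.asarray(sex, float)
    X = np.column_stack([
        np.ones(t.size), t, s, t * s,
        np.asarray(baseline, float), np.asarray(age, float), x,
    ])
    return X, ["intercept", "treatment", "subtype", "treatment:subtype", "baseline", "age", "sex"]


def fit_linear_bootstrap(
    change: np.ndarray,
    treatment: np.ndarray,
    subtype: np.ndarray,
    baseline_score: np.ndarray,
    age: np.ndarray,
    sex: np.ndarray,
    n_boot: int = 1000,
    seed: int = 0,
) -> BootstrapResult:
    """OLS of change ~ treatment + subtype + treatment:subtype + baseline +
    age + sex, with a subject-resampling percentile bootstrap CI for the
    treatment-by-subtype interaction.  Rank-deficient replicates are dropped
    and counted."""
    y = np.asarray(change, dtype=float)
    X, names = _linear_design(treatment, subtype, baseline_score, age, sex)
    p = X.shape[1]
    coef, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    if rank < p:
        raise ValueError("rank-deficient design matrix on the original sample")
    k = names.index("treatment:subtype")

    rng = np.random.default_rng(seed)
    n = y.size
    boots = np.empty(n_boot)
    dropped = 0
    kept = 0
    for _ in range(n_boot):
        idx = rng.integers(0, n, size=n)
        b, _, r, _ = np.linalg.lstsq(X[idx], y[idx], rcond=None)
        if r < p:
            dropped += 1
            continue
        boots[kept] = b[k]
        kept += 1
    if dropped:
        logger.info("linear bootstrap: dropped %d/%d rank-deficient replicates", dropped, n_boot)
    lo, hi = np.percentile(boots[:kept], [2.5, 97.5])
    return BootstrapResult("treatment:subtype", float(coef[k]), float(lo), float(hi),
                           n_boot, seed, dropped)


def nested_anova(
    change: np.ndarray,
    treatment: np.ndarray,
    subtype: np.ndarray,
    age: np.ndarray,
    sex: np.ndarray,
) -> tuple[float, int, int, float]:
    """F-test of subtype nested within treatment, controlling age and sex.

    The full model has a treatment main effect plus one subtype contrast per
    treatment arm (df1 = 2); the reduced model drops both nested columns.
    Returns (F, df1, df2, p) with df2 the residual df of the full model.
    """
    y = np.asarray(change, dtype=float)
    t = (np.asarray(treatment) == "active").astype(float)
    s = (np.asarray(subtype) == "DEP2").astype(float)
    for arm in (0.0, 1.0):
        if np.unique(s[t == arm]).size < 2:
            raise ValueError("each treatment arm must contain both subtypes")
    x = (np.asarray(sex) == "F").astype(float) if np.asarray(sex).dtype.kind in "OU" else np.asarray(sex, float)
    covs = np.column_stack([np.ones(y.size), t, np.asarray(age, float), x])
    nested = np.column_stack([s * (1 - t), s * t])
    X_full = np.column_stack([covs, nested])

    def rss(X: np.ndarray) -> float:
        beta, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
        if rank < X.shape[1]:
            raise ValueError("rank-deficient design in nested ANOVA")
        resid = y - X @ beta
        return float(resid @ resid)

    rss_full = rss(X_full)
    rss_red = rss(covs)
    df1 = 2
    df2 = y.size - X_full.shape[1]
    if df2 <= 0:
        raise ValueError("not enough residual degrees of freedom")
    if rss_full <= 0:
        return float("inf"), df1, df2, 0.0
    F = ((rss_red - rss_full) / df1) / (rss_full / df2)
    return float(F), df1, df2, float(stats.f.sf(F, df1, df2))
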