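"""Statistical routines supporting the PPD assessment pipeline.

Covers: Pearson correlation with a t-based two-sided test, the
method-equality drop-term F-test on score dispersions (a drop1-style table
for the model ``sdPPD ~ mt * cv + tp``), one-way ANOVA with LSD/HSD post hoc
comparisons, PCA with supplementary variables (correlation-circle style),
dry-matter-content arithmetic, and thin delegations for Shapiro-Wilk
normality screening and the two-sample t-test.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .exceptions import ModelSpecificationError, UndefinedCorrelationError

__all__ = [
    "CorrelationResult",
    "pearson_test",
    "drop_term_f_test",
    "AnovaResult",
    "one_way_anova",
    "posthoc_pairwise",
    "PCAResult",
    "pca_supplementary",
    "dmc_percent",
    "shapiro_wilk",
    "two_sample_t",
]


# ---------------------------------------------------------------------------
# Pearson correlation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CorrelationResult:
    r: float
    p: float
    n: int
    df: int


def pearson_test(x: Sequence[float], y: Sequence[float]) -> CorrelationResult:
    """Pearson product-moment correlation with a two-sided t test.

    The test statistic is t = r * sqrt((n - 2) / (1 - r^2)) on n - 2
    degrees of freedom.  Both inputs must have nonzero variance.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D vectors of equal length")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("inputs must be finite")
    n = x.size
    if n < 3:
        raise UndefinedCorrelationError(f"need n >= 3, got {n}")
    xd = x - x.mean()
    yd = y - y.mean()
    denom = np.sqrt((xd**2).sum() * (yd**2).sum())
    if denom == 0.0:
        raise UndefinedCorrelationError("zero variance in x or y")
    r = float(np.clip((xd * yd).sum() / denom, -1.0, 1.0))
    df = n - 2
    p = correlation_p_value(r, n)
    return CorrelationResult(r=r, p=p, n=n, df=df)


def correlation_p_value(r: float, n: int) -> float:
    """Two-sided p-value of a Pearson r at sample size n (df = n - 2)."""
    if n < 3:
        raise UndefinedCorrelationError(f"need n >= 3, got {n}")
    if abs(r) >= 1.0:
        return 0.0
    t = r * np.sqrt((n - 2) / (1.0 - r * r))
    return float(2.0 * sps.t.sf(abs(t), n - 2))


# ---------------------------------------------------------------------------
# drop-term F-test (method-equality test on score dispersions)
# ---------------------------------------------------------------------------

def _treatment_design(
    records: pd.DataFrame, *, include_tp: bool, include_interaction: bool
) -> np.ndarray:
    """Treatment-coded (first level = reference) design matrix for
    ``sdPPD ~ mt + cv (+ mt:cv) (+ tp)``."""
    def dummies(col: str) -> np.ndarray:
        levels = sorted(records[col].astype(str).unique())
        return np.column_stack(
            [(records[col].astype(str) == lv).to_numpy(float) for lv in levels[1:]]
        ) if len(levels) > 1 else np.empty((len(records), 0))

    blocks = [np.ones((len(records), 1)), dummies("mt"), dummies("cv")]
    if include_tp:
        blocks.append(dummies("tp"))
    if include_interaction:
        mt_d, cv_d = dummies("mt"), dummies("cv")
        inter = np.einsum("ni,nj->nij", mt_d, cv_d).reshape(len(records), -1)
        blocks.append(inter)
    return np.hstack(blocks)


def _ols_rss(X: np.ndarray, y: np.ndarray) -> tuple[float, int]:
    """Residual sum of squares and rank of a least-squares fit."""
    beta, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    return float(resid @ resid), int(rank)


def drop_term_f_test(records: pd.DataFrame) -> pd.DataFrame:
    """Drop1-style table for the dispersion model ``sdPPD ~ mt * cv + tp``.

    ``records`` holds one row per method x cultivar x timepoint cell with
    columns ``sdPPD`` (the per-cell standard deviation of PPD scores),
    ``mt`` (assessment method), ``cv`` (cultivar) and ``tp`` (timepoint,
    e.g. 4 vs 7 dph).  For each droppable marginal term (``tp`` and the
    ``mt:cv`` interaction) the model is refit without it and the table
    reports

    - ``Df``: drop in model degrees of freedom,
    - ``Sum_of_Sq``: RSS(reduced) - RSS(full),
    - ``RSS``, ``AIC`` = n*ln(RSS/n) + 2*edf  (extractAIC convention),
    - ``F_value`` = (Sum_of_Sq/Df) / (RSS_full/df_residual_full),
    - ``Pr_F``: upper-tail F probability.

    The main effects ``mt`` and ``cv`` are not droppable while their
    interaction is retained (marginality).
    """
    required = {"sdPPD", "mt", "cv", "tp"}
    if not required.issubset(records.columns):
        raise ValueError(f"records must have columns {sorted(required)}")
    records = records.reset_index(drop=True)
    y = records["sdPPD"].to_numpy(float)
    if np.isnan(y).any():
        raise ValueError("sdPPD contains missing values")
    n = len(records)

    X_full = _treatment_design(records, include_tp=True, include_interaction=True)
    if np.linalg.matrix_rank(X_full) < X_full.shape[1]:
        raise ModelSpecificationError(
            "rank-deficient design: some mt:cv/tp combinations are aliased "
            "(the design must be a complete mt x cv x tp factorial)"
        )
    rss_full, rank_full = _ols_rss(X_full, y)
    df_resid_full = n - rank_full
    if df_resid_full <= 0:
        raise ModelSpecificationError("saturated model: no residual df")

    def aic(rss: float, edf: int) -> float:
        return n * np.log(rss / n) + 2 * edf

    rows = {
        "<none>": {
            "Df": np.nan,
            "Sum_of_Sq": np.nan,
            "RSS": rss_full,
            "AIC": aic(rss_full, rank_full),
            "F_value": np.nan,
            "Pr_F": np.nan,
        }
    }
    reduced_specs = {
        "tp": dict(include_tp=False, include_interaction=True),
        "mt:cv": dict(include_tp=True, include_interaction=False),
    }
    for term, spec in reduced_specs.items():
        X_red = _treatment_design(records, **spec)
        rss_red, rank_red = _ols_rss(X_red, y)
        df_term = rank_full - rank_red
        ss = rss_red - rss_full
        f = (ss / df_term) / (rss_full / df_resid_full)
        rows[term] = {
            "Df": df_term,
            "Sum_of_Sq": ss,
            "RSS": rss_red,
            "AIC": aic(rss_red, rank_red),
            "F_value": f,
            "Pr_F": float(sps.f.sf(f, df_term, df_resid_full)),
        }
    table = pd.DataFrame.from_dict(rows, orient="index")
    table.index.name = "term"
    return table


# ---------------------------------------------------------------------------
# one-way ANOVA and post hoc comparisons
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AnovaResult:
    F: float
    p: float
    df_between: int
    df_within: int
    ms_error: float


def one_way_anova(groups: Sequence[Sequence[float]]) -> AnovaResult:
    """Classical one-way ANOVA between/within decomposition."""
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if len(arrays) < 2:
        raise ValueError("need at least two groups")
    if any(a.size < 2 for a in arrays):
        raise ValueError("every group needs n >= 2")
    all_values = np.concatenate(arrays)
    grand = all_values.mean()
    n_total = all_values.size
    k = len(arrays)
    ss_between = sum(a.size * (a.mean() - grand) ** 2 for a in arrays)
    ss_within = sum(((a - a.mean()) ** 2).sum() for a in arrays)
    df_b, df_w = k - 1, n_total - k
    ms_error = ss_within / df_w
    if ms_error == 0.0:
        # All residuals zero: F is 0 for identical group means (up to fp
        # noise in the mean computations) and +inf otherwise.
        eps = n_total * (4 * np.finfo(float).eps * max(1.0, abs(grand))) ** 2
        f = 0.0 if ss_between <= eps else np.inf
    else:
        f = (ss_between / df_b) / ms_error
    p = float(sps.f.sf(f, df_b, df_w)) if np.isfinite(f) else 0.0
    return AnovaResult(F=float(f), p=p, df_between=df_b, df_within=df_w,
                       ms_error=float(ms_error))


def posthoc_pairwise(
    groups: Sequence[Sequence[float]],
    *,
    labels: Sequence[str] | None = None,
    method: str = "lsd",
    alpha: float = 0.05,
) -> pd.DataFrame:
    """All-pairs mean comparisons after a one-way ANOVA.

    method "lsd": Fisher's least significant difference,
        crit = t(1 - alpha/2, N - k) * sqrt(MSE * (1/ni + 1/nj)).
    method "hsd": Tukey's honest significant difference with the
        Tukey-Kramer correction for unequal sizes,
        crit = q(1 - alpha, k, N - k) * sqrt(MSE/2 * (1/ni + 1/nj)).

    Returns a table with one row per pair: absolute mean difference, the
    critical difference, and a significance flag.
    """
    if method not in ("lsd", "hsd"):
        raise ValueError("method must be 'lsd' or 'hsd'")
    arrays = [np.asarray(g, dtype=float) for g in groups]
    k = len(arrays)
    labels = list(labels) if labels is not None else [str(i) for i in range(k)]
    if len(labels) != k:
        raise ValueError("labels must match the number of groups")
    anova = one_way_anova(arrays)
    rows = []
    for i in range(k):
        for j in range(i + 1, k):
            ni, nj = arrays[i].size, arrays[j].size
            diff = abs(arrays[i].mean() - arrays[j].mean())
            if method == "lsd":
                crit = sps.t.ppf(1 - alpha / 2, anova.df_within) * np.sqrt(
                    anova.ms_error * (1 / ni + 1 / nj)
                )
            else:
                q = sps.studentized_range.ppf(1 - alpha, k, anova.df_within)
                crit = q * np.sqrt(anova.ms_error / 2 * (1 / ni + 1 / nj))
            rows.append(
                {
                    "group_i": labels[i],
                    "group_j": labels[j],
                    "difference": diff,
                    "critical_value": float(crit),
                    "significant": bool(diff > crit),
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# PCA with supplementary variables
# ---------------------------------------------------------------------------

@dataclass
class PCAResult:
    """Correlation-matrix PCA with supplementary (non-fitted) variables.

    eigenvalues sum to the number of active variables; ``coordinates`` are
    the individual scores (variance on dimension d equals eigenvalue d,
    n-1 denominator); ``loadings`` and ``supplementary`` hold the Pearson
    correlations of active / supplementary variables with each dimension.
    """

    eigenvalues: np.ndarray
    coordinates: pd.DataFrame
    loadings: pd.DataFrame
    supplementary: pd.DataFrame | None = None


def pca_supplementary(
    active: pd.DataFrame,
    supplementary: pd.DataFrame | None = None,
) -> PCAResult:
    """PCA of standardized active variables, projecting extra variables in.

    Active variables are centered and scaled to unit variance (sample SD);
    the correlation matrix is eigendecomposed; individual coordinates are
    the standardized data times the eigenvectors.  Supplementary variables
    take no part in the fit and are represented by their correlation with
    the individual coordinates on each dimension — the dotted arrows of a
    correlation-circle plot.
    """
    X = active.to_numpy(dtype=float)
    n, p = X.shape
    if np.isnan(X).any():
        raise ValueError("active variables contain missing values")
    if n < p:
        raise ValueError(f"need at least as many rows ({n}) as active variables ({p})")
    sd = X.std(axis=0, ddof=1)
    constant = [c for c, s in zip(active.columns, sd) if s == 0.0]
    if constant:
        raise ValueError(f"constant active variable(s): {constant}")
    Z = (X - X.mean(axis=0)) / sd
    corr = Z.T @ Z / (n - 1)
    eigval, eigvec = np.linalg.eigh(corr)
    order = np.argsort(eigval)[::-1]
    eigval = np.clip(eigval[order], 0.0, None)
    eigvec = eigvec[:, order]
    # Deterministic sign: largest-magnitude loading of each axis positive.
    for d in range(p):
        peak = np.abs(eigvec[:, d]).argmax()
        if eigvec[peak, d] < 0:
            eigvec[:, d] = -eigvec[:, d]

    coords = Z @ eigvec
    dims = [f"dim{d + 1}" for d in range(p)]
    coordinates = pd.DataFrame(coords, index=active.index, columns=dims)
    with np.errstate(invalid="ignore", divide="ignore"):
        loadings = pd.DataFrame(
            eigvec * np.sqrt(eigval), index=active.columns, columns=dims
        )

    supp = None
    if supplementary is not None:
        S = supplementary.to_numpy(dtype=float)
        rows = {}
        for name, col in zip(supplementary.columns, S.T):
            rows[name] = [
                _safe_corr(col, coords[:, d]) for d in range(p)
            ]
        supp = pd.DataFrame.from_dict(rows, orient="index", columns=dims)
    return PCAResult(
        eigenvalues=eigval, coordinates=coordinates, loadings=loadings,
        supplementary=supp,
    )


def _safe_corr(a: np.ndarray, b: np.ndarray) -> float:
    sa, sb = a.std(), b.std()
    if sa == 0.0 or sb == 0.0:
        return float("nan")
    return float(np.corrcoef(a, b)[0, 1])


# ---------------------------------------------------------------------------
# small utilities
# ---------------------------------------------------------------------------

def dmc_percent(fresh_mass: float, dry_mass: float) -> float:
    """Dry matter content: percentage of dry weight relative to fresh."""
    if fresh_mass <= 0:
        raise ValueError("fresh mass must be positive")
    if dry_mass < 0 or dry_mass > fresh_mass:
        raise ValueError("dry mass must lie in [0, fresh mass] (weighing fault?)")
    return 100.0 * dry_mass / fresh_mass


def shapiro_wilk(x: Sequence[float]) -> tuple[float, float]:
    """Shapiro-Wilk W and p (normality screening), delegated to scipy."""
    res = sps.shapiro(np.asarray(x, dtype=float))
    return float(res.statistic), float(res.pvalue)


def two_sample_t(
    x: Sequence[float], y: Sequence[float], *, equal_var: bool = True
) -> tuple[float, float]:
    """Two-sided two-sample t-test (pooled by default), delegated to scipy."""
    res = sps.ttest_ind(np.asarray(x, float), np.asarray(y, float),
                        equal_var=equal_var)
    return float(res.statistic), float(res.pvalue)
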