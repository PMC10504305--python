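"""Distance-matrix statistics: sequential PERMANOVA, Mantel, distance decay.

PERMANOVA partitions the variance of a distance matrix among covariates with
sequential (Type-I) sums of squares, exactly as adonis2 does with terms in
model order: the Gower-centered inner-product matrix G of -d²/2 is projected
onto nested design matrices, each term's SS is the trace increment, and
significance comes from free permutation of sample labels with the whole
sequential decomposition recomputed per permutation. On Euclidean distances
of univariate data the decomposition (and pseudo-F) reduces exactly to
classical ANOVA, which the test suite exploits as an oracle.

Continuous covariates enter as single-df regression terms; categorical
covariates as (levels - 1)-df dummy blocks.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .formats import DistanceMatrix, ValidationError

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# design-matrix helpers
# ---------------------------------------------------------------------------

def _term_columns(series: pd.Series) -> np.ndarray:
    """Encode one covariate as design columns (numeric: 1; factor: L-1)."""
    if pd.api.types.is_numeric_dtype(series):
        return series.to_numpy(dtype=float)[:, None]
    dummies = pd.get_dummies(series.astype(str), drop_first=True)
    if dummies.shape[1] == 0:
        raise ValidationError(f"covariate {series.name!r} has a single level")
    return dummies.to_numpy(dtype=float)


def _gower_center(d: np.ndarray) -> np.ndarray:
    n = len(d)
    a = -0.5 * d.astype(float) ** 2
    J = np.eye(n) - np.ones((n, n)) / n
    return J @ a @ J


def _hat(X: np.ndarray) -> np.ndarray:
    return X @ np.linalg.pinv(X)


@dataclass
class PermanovaTable:
    terms: list[str]
    df: dict[str, int]
    sum_of_squares: dict[str, float]     # includes 'Residual' and 'Total'
    r_squared: dict[str, float]
    pseudo_f: dict[str, float]
    p_value: dict[str, float]
    n_perm: int
    seed: int | None

    def summary(self) -> pd.DataFrame:
        rows = []
        for t in self.terms:
            rows.append({"term": t, "df": self.df[t],
                         "SumOfSqs": self.sum_of_squares[t],
                         "R2": self.r_squared[t], "F": self.pseudo_f[t],
                         "p": self.p_value[t]})
        rows.append({"term": "Residual", "df": self.df["Residual"],
                     "SumOfSqs": self.sum_of_squares["Residual"],
                     "R2": self.r_squared["Residual"],
                     "F": np.nan, "p": np.nan})
        rows.append({"term": "Total", "df": self.df["Total"],
                     "SumOfSqs": self.sum_of_squares["Total"], "R2": 1.0,
                     "F": np.nan, "p": np.nan})
        return pd.DataFrame(rows).set_index("term")


def _sequential_ss(G: np.ndarray, increments: list[np.ndarray],
                   H_full: np.ndarray) -> tuple[np.ndarray, float]:
    """Trace of each projection increment against G, plus residual SS."""
    ss = np.array([float(np.sum(dH * G)) for dH in increments])
    n = len(G)
    ss_res = float(np.trace(G) - np.sum((H_full * G)))
    return ss, ss_res


def permanova_sequential(d: DistanceMatrix, covariates: pd.DataFrame,
                         n_perm: int = 999,
                         seed: int | None = None) -> PermanovaTable:
    """Sequential (Type-I) PERMANOVA of a distance matrix on ordered terms.

    ``covariates`` columns are the terms, in model order, aligned to d.ids.
    """
    if n_perm < 1:
        raise ValidationError("n_perm must be >= 1")
    if not np.isfinite(d.d).all():
        raise ValidationError("PERMANOVA requires finite distances")
    cov = covariates.loc[list(d.ids)] if not covariates.index.equals(
        pd.Index(d.ids)) else covariates
    if cov.isna().any().any():
        raise ValidationError("covariates contain missing values")
    n = len(d.ids)
    terms = list(cov.columns)
    G = _gower_center(d.d)
    ss_total = float(np.trace(G))

    # nested designs; detect rank-deficient (collinear) additions
    X = np.ones((n, 1))
    rank_prev = 1
    H_prev = np.full((n, n), 1.0 / n)
    increments: list[np.ndarray] = []
    dfs: list[int] = []
    for t in terms:
        cols = _term_columns(cov[t])
        X = np.hstack([X, cols])
        rank = np.linalg.matrix_rank(X)
        df_t = rank - rank_prev
        if df_t < cols.shape[1]:
            other = _collinear_partner(cov, t)
            raise ValidationError(
                f"covariate {t!r} is collinear with {other!r}"
            )
        H = _hat(X)
        increments.append(H - H_prev)
        dfs.append(df_t)
        H_prev, rank_prev = H, rank
    H_full = H_prev
    df_res = n - rank_prev
    if df_res < 1:
        raise ValidationError("no residual degrees of freedom")

    ss_obs, ss_res = _sequential_ss(G, increments, H_full)
    ms_res = ss_res / df_res
    f_obs = (ss_obs / np.array(dfs)) / ms_res

    rng = np.random.default_rng(seed)
    exceed = np.zeros(len(terms))
    for _ in range(n_perm):
        perm = rng.permutation(n)
        Gp = G[np.ix_(perm, perm)]
        ss_p, ss_res_p = _sequential_ss(Gp, increments, H_full)
        f_p = (ss_p / np.array(dfs)) / (ss_res_p / df_res)
        exceed += f_p >= f_obs - 1e-12
    p = (1 + exceed) / (n_perm + 1)

    ss = {t: float(s) for t, s in zip(terms, ss_obs)}
    ss["Residual"] = ss_res
    ss["Total"] = ss_total
    return PermanovaTable(
        terms=terms,
        df={**{t: int(k) for t, k in zip(terms, dfs)},
            "Residual": int(df_res), "Total": n - 1},
        sum_of_squares=ss,
        r_squared={**{t: float(s / ss_total) for t, s in zip(terms, ss_obs)},
                   "Residual": float(ss_res / ss_total)},
        pseudo_f={t: float(f) for t, f in zip(terms, f_obs)},
        p_value={t: float(v) for t, v in zip(terms, p)},
        n_perm=n_perm, seed=seed,
    )


def _collinear_partner(cov: pd.DataFrame, term: str) -> str:
    """Best-effort identification of the earlier term collinear with `term`."""
    cols = _term_columns(cov[term])
    for other in cov.columns:
        if other == term:
            break
        oc = _term_columns(cov[other])
        X = np.hstack([np.ones((len(cov), 1)), oc, cols])
        if np.linalg.matrix_rank(X) < X.shape[1]:
            return other
    return "preceding terms"


def order_terms_by_marginal_r2(d: DistanceMatrix, fixed_first: str,
                               candidates: list[str], covariates: pd.DataFrame,
                               n_perm: int = 1,
                               seed: int | None = None) -> list[str]:
    """Order candidate terms by their sequential R² after a fixed first term.

    Fits d ~ fixed_first + candidate for each candidate and sorts candidates
    by the second term's R², descending; ties break by name.
    """
    scored = []
    for cand in candidates:
        tab = permanova_sequential(d, covariates[[fixed_first, cand]],
                                   n_perm=n_perm, seed=seed)
        scored.append((-(tab.r_squared[cand]), cand))
    scored.sort()
    return [fixed_first] + [c for _, c in scored]


# ---------------------------------------------------------------------------
# Mantel
# ---------------------------------------------------------------------------

@dataclass
class MantelResult:
    r: float
    r_squared: float
    p_value: float
    n_perm: int


def mantel(d1: DistanceMatrix, d2: DistanceMatrix, n_perm: int = 999,
           seed: int | None = None) -> MantelResult:
    """Mantel test: Pearson r between matrices' upper triangles.

    p is two-sided, from joint row/column permutations of d2:
    (1 + #{|r_perm| >= |r_obs|}) / (n_perm + 1).
    """
    if list(d1.ids) != list(d2.ids):
        raise ValidationError("Mantel requires matching ids in the same order")
    if not (np.isfinite(d1.d).all() and np.isfinite(d2.d).all()):
        raise ValidationError("Mantel requires finite distances")
    n = len(d1.ids)
    iu = np.triu_indices(n, k=1)
    x = d1.d[iu]
    if np.ptp(x) == 0 or np.ptp(d2.d[iu]) == 0:
        raise ValidationError("constant upper triangle")
    xc = x - x.mean()
    xnorm = np.sqrt(float(xc @ xc))

    def corr(mat: np.ndarray) -> float:
        y = mat[iu]
        yc = y - y.mean()
        return float(xc @ yc) / (xnorm * np.sqrt(float(yc @ yc)))

    r_obs = corr(d2.d)
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        if abs(corr(d2.d[np.ix_(perm, perm)])) >= abs(r_obs) - 1e-12:
            count += 1
    p = (1 + count) / (n_perm + 1)
    return MantelResult(r=r_obs, r_squared=r_obs ** 2, p_value=p, n_perm=n_perm)


# ---------------------------------------------------------------------------
# distance decay
# ---------------------------------------------------------------------------

@dataclass
class DecayResult:
    slope_overall: float
    slope_within: float
    slope_between: float
    intercept_overall: float
    intercept_within: float
    intercept_between: float
    n_pairs_overall: int
    n_pairs_within: int
    n_pairs_between: int


def _ols_slope(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    if len(x) < 3 or np.ptp(x) == 0:
        return np.nan, np.nan
    slope, intercept = np.polyfit(x, y, deg=1)
    return float(slope), float(intercept)


def distance_decay(d: DistanceMatrix, geo: DistanceMatrix,
                   transects: pd.Series) -> DecayResult:
    """OLS of pairwise dissimilarity on geographic distance, stratified.

    Fits the overall regression plus separate fits over same-transect and
    cross-transect pairs. A stratum with fewer than 3 pairs yields NaN.
    """
    if list(d.ids) != list(geo.ids):
        raise ValidationError("distance matrices have mismatched ids")
    if not np.isfinite(geo.d).all():
        raise ValidationError("geographic distances must be finite")
    n = len(d.ids)
    iu = np.triu_indices(n, k=1)
    y = d.d[iu]
    x = geo.d[iu]
    t = transects.loc[list(d.ids)].to_numpy()
    same = (t[iu[0]] == t[iu[1]])
    slope_o, int_o = _ols_slope(x, y)
    slope_w, int_w = _ols_slope(x[same], y[same])
    slope_b, int_b = _ols_slope(x[~same], y[~same])
    return DecayResult(
        slope_overall=slope_o, slope_within=slope_w, slope_between=slope_b,
        intercept_overall=int_o, intercept_within=int_w, intercept_between=int_b,
        n_pairs_overall=len(x), n_pairs_within=int(same.sum()),
        n_pairs_between=int((~same).sum()),
    )


# ---------------------------------------------------------------------------
# two-group comparison and correlation
# ---------------------------------------------------------------------------

def group_compare(values: pd.Series, labels: pd.Series
                  ) -> tuple[float, float, float]:
    """Welch two-sample t-test between exactly two groups: (t, df, p)."""
    labels = labels.loc[values.index]
    groups = labels.unique()
    if len(groups) != 2:
        raise ValidationError(f"expected exactly 2 groups, got {len(groups)}")
    a = values[labels == groups[0]].to_numpy(dtype=float)
    b = values[labels == groups[1]].to_numpy(dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValidationError("each group needs >=2 values")
    res = sps.ttest_ind(a, b, equal_var=False)
    return float(res.statistic), float(res.df), float(res.pvalue)


def correlate(x, y, method: str = "pearson") -> tuple[float, float]:
    """Pearson or Spearman correlation with a two-sided p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if np.isnan(x).any() or np.isnan(y).any():
        raise ValidationError("correlate does not accept missing values")
    if method == "pearson":
        r, p = sps.pearsonr(x, y)
    elif method == "spearman":
        r, p = sps.spearmanr(x, y)
    else:
        raise ValidationError(f"unknown correlation method {method!r}")
    return float(r), float(p)
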