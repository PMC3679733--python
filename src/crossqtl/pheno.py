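"""Phenotype cleaning, derived growth traits and null-model selection.

Outliers are flagged by the boxplot rule (beyond 1.5 IQR from the quartiles,
quartiles by linear interpolation of order statistics) and then resolved
against two retention rules for longitudinal trait families: a flag is kept
(not excluded) when the same bird is flagged at consecutive ages, or when
several birds are flagged on the same side at the same age — isolated
flags become missing values.

Growth rate (GR) is the body-weight gain over an age window; feed conversion
ratio (FCR) is window feed intake divided by the gain.  The null model for
each trait (trait ~ mean + fixed effects + covariates) is chosen by backward
elimination with partial F-tests; its residuals and residual mean square
feed every genome scan.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .core import DataError

__all__ = [
    "flag_outliers",
    "resolve_outliers",
    "clean_trait_family",
    "derive_traits",
    "trait_correlations",
    "NullModelSpec",
    "select_null_model",
]


def flag_outliers(values, whisker: float = 1.5) -> np.ndarray:
    """Boxplot outlier flags: -1 below the lower fence, +1 above the upper.

    Fences are Q1 - whisker*IQR and Q3 + whisker*IQR with quartiles by
    linear interpolation.  Missing values are never flagged.  Requires at
    least 4 non-missing values.
    """
    v = np.asarray(values, dtype=float)
    ok = ~np.isnan(v)
    if ok.sum() == 0:
        raise DataError("all values missing")
    if ok.sum() < 4:
        raise DataError("need at least 4 non-missing values for quartiles")
    q1, q3 = np.percentile(v[ok], [25, 75])
    iqr = q3 - q1
    lo, hi = q1 - whisker * iqr, q3 + whisker * iqr
    flags = np.zeros(v.shape, dtype=np.int8)
    flags[ok & (v < lo)] = -1
    flags[ok & (v > hi)] = 1
    return flags


def resolve_outliers(flags: pd.DataFrame, min_cluster: int = 5) -> pd.DataFrame:
    """Exclusion mask for a longitudinal family of flagged traits.

    `flags` is individuals x age-ordered trait columns with values in
    {-1, 0, 1}.  A flagged value is *retained* if (a) the same individual is
    flagged at >=2 consecutive ages, or (b) at least `min_cluster`
    individuals are flagged on the same side at the same age.  Everything
    else that is flagged is excluded (True in the returned mask).
    """
    f = flags.to_numpy()
    flagged = f != 0
    keep = np.zeros_like(flagged)
    # (a) consistency across consecutive ages
    for j in range(f.shape[1] - 1):
        both = flagged[:, j] & flagged[:, j + 1]
        keep[both, j] = True
        keep[both, j + 1] = True
    # (b) same-side cluster at one age
    for j in range(f.shape[1]):
        for side in (-1, 1):
            hits = f[:, j] == side
            if hits.sum() >= min_cluster:
                keep[hits, j] = True
    return pd.DataFrame(flagged & ~keep, index=flags.index, columns=flags.columns)


def clean_trait_family(
    table: pd.DataFrame, columns: list, whisker: float = 1.5, min_cluster: int = 5
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Flag + resolve outliers for age-ordered `columns`; excluded values
    become NaN.  Returns (cleaned copy, exclusion mask)."""
    flags = pd.DataFrame(
        {c: flag_outliers(table[c], whisker=whisker) for c in columns}, index=table.index
    )
    drop = resolve_outliers(flags, min_cluster=min_cluster)
    out = table.copy()
    for c in columns:
        out.loc[drop[c], c] = np.nan
    return out, drop


GR_WINDOWS = [("GR0_4", "BW0", "BW4"), ("GR4_8", "BW4", "BW8"), ("GR8_12", "BW8", "BW12")]
FCR_WINDOWS = [
    ("FCR6_8", "FI6_8", "BW6", "BW8"),
    ("FCR8_10", "FI8_10", "BW8", "BW10"),
    ("FCR10_12", "FI10_12", "BW10", "BW12"),
]


def derive_traits(table: pd.DataFrame) -> pd.DataFrame:
    """Add GR and FCR columns from body weights and window feed intakes.

    GR_w = BW_end - BW_start (0-4, 4-8, 8-12 wk); FCR_w = intake / gain
    (6-8, 8-10, 10-12 wk).  A missing endpoint propagates; zero or negative
    gain leaves FCR missing (the ratio is undefined/unstable) with a warning.
    Re-deriving is idempotent: columns are recomputed from their sources.
    """
    out = table.copy()
    for name, start, end in GR_WINDOWS:
        if start in out.columns and end in out.columns:
            out[name] = out[end] - out[start]
    n_bad = 0
    for name, intake, start, end in FCR_WINDOWS:
        if intake in out.columns and start in out.columns and end in out.columns:
            gain = out[end] - out[start]
            bad = gain <= 0
            n_bad += int(bad.sum())
            with np.errstate(divide="ignore", invalid="ignore"):
                fcr = out[intake] / gain
            fcr[bad] = np.nan
            out[name] = fcr
    if n_bad:
        warnings.warn(f"{n_bad} non-positive gains; FCR set missing", stacklevel=2)
    return out


def trait_correlations(table: pd.DataFrame, traits: list | None = None):
    """Pairwise-complete Pearson correlations with two-sided p-values.

    p-values come from the t transform t = r * sqrt((n-2)/(1-r^2)).
    Pairs with < 3 complete observations or a zero-variance column are NaN.
    """
    if traits is None:
        traits = [c for c in table.columns if pd.api.types.is_numeric_dtype(table[c])]
    k = len(traits)
    r = np.full((k, k), np.nan)
    p = np.full((k, k), np.nan)
    data = table[traits].to_numpy(float)
    for i in range(k):
        for j in range(i, k):
            ok = ~np.isnan(data[:, i]) & ~np.isnan(data[:, j])
            n = int(ok.sum())
            if n < 3:
                continue
            x, y = data[ok, i], data[ok, j]
            if x.std() == 0 or y.std() == 0:
                continue
            rij = float(np.corrcoef(x, y)[0, 1])
            r[i, j] = r[j, i] = rij
            if abs(rij) >= 1.0:
                p[i, j] = p[j, i] = 0.0
            else:
                t = rij * np.sqrt((n - 2) / (1 - rij**2))
                p[i, j] = p[j, i] = 2 * stats.t.sf(abs(t), n - 2)
    R = pd.DataFrame(r, index=traits, columns=traits)
    P = pd.DataFrame(p, index=traits, columns=traits)
    return R, P


# ----------------------------------------------------------------------
# null (non-genetic) model


@dataclass
class NullModelSpec:
    """Fitted non-genetic model for one trait: y = mu + beta*F + gamma*C + e.

    Holds everything a genome scan needs: the ids of the usable (non-missing)
    individuals, the design matrix Z (intercept + retained factor dummies +
    retained covariates), the trait vector, residuals, and the residual mean
    square / degrees of freedom of the fit.
    """

    trait: str
    ids: list
    factors: list
    covariates: list
    Z: np.ndarray = field(repr=False)
    y: np.ndarray = field(repr=False)
    coef: np.ndarray = field(repr=False)
    residuals: np.ndarray = field(repr=False)
    rss: float = 0.0
    df_resid: int = 0

    @property
    def ms_resid(self) -> float:
        return self.rss / self.df_resid if self.df_resid > 0 else np.nan

    @property
    def n(self) -> int:
        return len(self.ids)


def _design_columns(table: pd.DataFrame, factors, covariates):
    """Intercept + treatment-coded dummies per factor + covariate columns.
    Returns (matrix, list of (term, column-count))."""
    n = len(table)
    blocks = [np.ones((n, 1))]
    terms = [("intercept", 1)]
    for f in factors:
        d = pd.get_dummies(table[f].astype(str), drop_first=True).to_numpy(float)
        if d.shape[1] > 0:
            blocks.append(d)
            terms.append((f, d.shape[1]))
    for c in covariates:
        blocks.append(table[c].to_numpy(float)[:, None])
        terms.append((c, 1))
    return np.hstack(blocks), terms


def _ols_rss(X, y):
    coef, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ coef
    return coef, resid, float(resid @ resid), rank


def select_null_model(
    table: pd.DataFrame,
    trait: str,
    factors: tuple = ("sex", "batch", "family"),
    covariates: tuple = (),
    alpha: float = 0.05,
) -> NullModelSpec:
    """Backward elimination of non-genetic terms by partial F-test.

    Starting from all candidate factors and covariates present in `table`,
    repeatedly drop the least significant term whose partial F p-value
    exceeds `alpha`; what remains defines the null model whose residuals the
    QTL scans analyse.  Aliased (rank-deficient) terms contribute no extra
    rank and are eliminated naturally.  With no candidates the model is
    intercept-only (residuals = centred trait).
    """
    factors = [f for f in factors if f in table.columns]
    covariates = [c for c in covariates if c in table.columns]
    need = [trait] + factors + covariates
    sub = table[need].dropna(subset=[trait])
    sub = sub.dropna(subset=covariates) if covariates else sub
    y = sub[trait].to_numpy(float)
    n = len(y)
    if n < 4:
        raise DataError(f"too few observations for trait {trait!r}")

    current_f, current_c = list(factors), list(covariates)
    while True:
        X, terms = _design_columns(sub, current_f, current_c)
        coef, resid, rss_full, rank_full = _ols_rss(X, y)
        df_full = n - rank_full
        worst, worst_p = None, alpha
        for term, _w in terms[1:]:
            keep_f = [f for f in current_f if f != term]
            keep_c = [c for c in current_c if c != term]
            Xr, _ = _design_columns(sub, keep_f, keep_c)
            _, _, rss_red, rank_red = _ols_rss(Xr, y)
            df_num = rank_full - rank_red
            if df_num <= 0:  # aliased term: carries no rank, drop outright
                warnings.warn(f"term {term!r} aliased; dropped", stacklevel=2)
                worst, worst_p = term, np.inf
                break
            f_stat = ((rss_red - rss_full) / df_num) / (rss_full / df_full)
            pval = stats.f.sf(f_stat, df_num, df_full)
            if pval > worst_p:
                worst, worst_p = term, pval
        if worst is None:
            break
        current_f = [f for f in current_f if f != worst]
        current_c = [c for c in current_c if c != worst]

    X, _ = _design_columns(sub, current_f, current_c)
    coef, resid, rss, rank = _ols_rss(X, y)
    return NullModelSpec(
        trait=trait,
        ids=list(sub.index),
        factors=current_f,
        covariates=current_c,
        Z=X,
        y=y,
        coef=coef,
        residuals=resid,
        rss=rss,
        df_resid=n - rank,
    )
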