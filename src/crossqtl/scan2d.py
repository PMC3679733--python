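"""Exhaustive two-locus epistasis scan.

For every admissible pair of grid positions (default 5 cM spacing; same-
chromosome pairs must be at least two grid steps apart) two nested models
are compared:

    null (marginal): y = mu + beta*F + gamma*C + a1*A1 + d1*D1 + a2*A2 + d2*D2 + e
    full (epistatic): ... + i1*A1A2 + i2*A1D2 + i3*D1A2 + i4*D1D2 + e

where the interaction indicators are elementwise products of the marginal
Haley-Knott indicators.  F has 4 numerator degrees of freedom.  Significant
pairs clear a permutation threshold on the pair-grid maximum; suggestive
pairs clear a fixed F cutoff (default 8) and are reported separately.
Adjacent significant grid points are merged into pair regions, since an
interacting pair is a property of two QTL-peak regions rather than of two
single positions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .origin import LineOriginGrid, indicators
from .pheno import NullModelSpec
from .scan1d import _base_q, _project_out, _rows_for, variance_explained

__all__ = [
    "InteractionIndicators",
    "EpistasisFit",
    "EpistasisScanResult",
    "TwoLocusMap",
    "interaction_indicators",
    "admissible_pairs",
    "scan_pairs",
    "max_f_pairs_many",
    "decompose_epistasis",
    "genotype_phenotype_map",
]

TERMS = ("i_aa", "i_ad", "i_da", "i_dd")


@dataclass
class InteractionIndicators:
    """Products of marginal indicators for one locus pair."""

    i_aa: np.ndarray
    i_ad: np.ndarray
    i_da: np.ndarray
    i_dd: np.ndarray

    def stack(self) -> np.ndarray:
        return np.column_stack([self.i_aa, self.i_ad, self.i_da, self.i_dd])


def interaction_indicators(A1, D1, A2, D2) -> InteractionIndicators:
    """I_A1A2 = A1*A2, I_A1D2 = A1*D2, I_D1A2 = D1*A2, I_D1D2 = D1*D2."""
    A1, D1, A2, D2 = (np.asarray(v, dtype=float) for v in (A1, D1, A2, D2))
    return InteractionIndicators(A1 * A2, A1 * D2, D1 * A2, D1 * D2)


@dataclass
class EpistasisFit:
    group1: object
    cm1: float
    group2: object
    cm2: float
    f: float
    rss_marginal: float
    rss_full: float
    df_full: int
    var_pct: float | None = None


@dataclass
class EpistasisScanResult:
    trait: str
    pairs: pd.DataFrame  # every admissible pair with its F
    significant: list = field(default_factory=list)  # EpistasisFit above threshold
    suggestive: list = field(default_factory=list)  # EpistasisFit with F > suggestive cutoff
    regions: pd.DataFrame | None = None  # merged significant pair regions
    threshold: float | None = None
    suggestive_f: float = 8.0


def admissible_pairs(grid: LineOriginGrid, min_sep_steps: int = 2) -> np.ndarray:
    """Index pairs (j, k) of grid columns eligible for the 2D scan.

    Distinct positions only; same-group pairs must be >= `min_sep_steps`
    grid steps apart (collinearity guard).
    """
    groups = grid.positions["group"].to_numpy()
    cms = grid.positions["cm"].to_numpy(float)
    P = len(groups)
    jj, kk = np.triu_indices(P, k=1)
    same = groups[jj] == groups[kk]
    far = np.abs(cms[jj] - cms[kk]) >= min_sep_steps * grid.step - 1e-9
    keep = ~same | far
    return np.column_stack([jj[keep], kk[keep]])


def _prep(spec, grid):
    rows = _rows_for(spec, grid)
    ind = indicators(grid)
    A = ind.A[rows]
    D = ind.D[rows]
    Q = _base_q(spec, None)
    return A, D, Q


def _gram_rss(W, y_r, rss0):
    G = W.T @ W
    b = W.T @ y_r
    try:
        c = np.linalg.solve(G, b)
    except np.linalg.LinAlgError:
        c = np.linalg.lstsq(G, b, rcond=None)[0]
    return float(rss0 - b @ c)


def scan_pairs(
    spec: NullModelSpec,
    grid: LineOriginGrid,
    threshold: float | None = None,
    suggestive_f: float = 8.0,
    min_sep_steps: int = 2,
    merge_cm: float = 20.0,
) -> EpistasisScanResult:
    """F statistics for every admissible pair of grid positions.

    F = ((RSS_marginal - RSS_full)/4) / (RSS_full / df_full).  Pairs above
    `threshold` are significant; pairs above `suggestive_f` are reported as
    suggestive.  Significant pairs are merged into peak regions when both
    axes lie within `merge_cm` of an already-merged pair.
    """
    A, D, Q = _prep(spec, grid)
    n, k = Q.shape
    y_r = _project_out(Q, spec.y)
    rss0 = float(y_r @ y_r)
    A_r = _project_out(Q, A)
    D_r = _project_out(Q, D)
    pairs = admissible_pairs(grid, min_sep_steps=min_sep_steps)
    groups = grid.positions["group"].to_numpy()
    cms = grid.positions["cm"].to_numpy(float)
    df_full = n - k - 8
    df_marg = n - k - 4

    fvals = np.empty(len(pairs))
    rss3s = np.empty(len(pairs))
    rss4s = np.empty(len(pairs))
    for idx, (j, kk_) in enumerate(pairs):
        W3 = np.column_stack([A_r[:, j], D_r[:, j], A_r[:, kk_], D_r[:, kk_]])
        inter = interaction_indicators(A[:, j], D[:, j], A[:, kk_], D[:, kk_]).stack()
        inter_r = _project_out(Q, inter)
        W4 = np.hstack([W3, inter_r])
        rss3 = _gram_rss(W3, y_r, rss0)
        rss4 = _gram_rss(W4, y_r, rss0)
        rss4 = min(rss4, rss3)  # nesting can only help; guard rounding
        fvals[idx] = ((rss3 - rss4) / 4) / (rss4 / df_full) if rss4 > 0 else np.inf
        rss3s[idx], rss4s[idx] = rss3, rss4

    table = pd.DataFrame(
        {
            "group1": groups[pairs[:, 0]],
            "cm1": cms[pairs[:, 0]],
            "group2": groups[pairs[:, 1]],
            "cm2": cms[pairs[:, 1]],
            "f": fvals,
        }
    )

    def _fits(mask):
        out = []
        for i in np.flatnonzero(mask):
            fit = EpistasisFit(
                group1=groups[pairs[i, 0]], cm1=float(cms[pairs[i, 0]]),
                group2=groups[pairs[i, 1]], cm2=float(cms[pairs[i, 1]]),
                f=float(fvals[i]), rss_marginal=float(rss3s[i]),
                rss_full=float(rss4s[i]), df_full=df_full,
            )
            fit.var_pct = variance_explained(
                rss3s[i] / df_marg, rss4s[i] / df_full, spec.ms_resid
            )
            out.append(fit)
        return sorted(out, key=lambda x: -x.f)

    significant = _fits(fvals > threshold) if threshold is not None else []
    suggestive = _fits(
        (fvals > suggestive_f) & ((fvals <= threshold) if threshold is not None else True)
    )
    regions = _merge_regions(significant, merge_cm) if significant else None
    return EpistasisScanResult(
        trait=spec.trait, pairs=table, significant=significant,
        suggestive=suggestive, regions=regions, threshold=threshold,
        suggestive_f=suggestive_f,
    )


def _merge_regions(fits: list, merge_cm: float) -> pd.DataFrame:
    """Cluster significant pairs whose loci are within `merge_cm` on both
    axes (same chromosome pair); report the peak pair of each cluster."""
    clusters: list[list] = []
    for fit in fits:  # fits sorted by decreasing F
        placed = False
        for cl in clusters:
            head = cl[0]
            if (
                head.group1 == fit.group1 and head.group2 == fit.group2
                and abs(head.cm1 - fit.cm1) <= merge_cm
                and abs(head.cm2 - fit.cm2) <= merge_cm
            ):
                cl.append(fit)
                placed = True
                break
        if not placed:
            clusters.append([fit])
    rows = []
    for cl in clusters:
        head = cl[0]
        rows.append(
            {
                "group1": head.group1, "cm1": head.cm1,
                "group2": head.group2, "cm2": head.cm2,
                "f": head.f, "var_pct": head.var_pct,
                "n_grid_pairs": len(cl),
                "cm1_lo": min(x.cm1 for x in cl), "cm1_hi": max(x.cm1 for x in cl),
                "cm2_lo": min(x.cm2 for x in cl), "cm2_hi": max(x.cm2 for x in cl),
            }
        )
    return pd.DataFrame(rows)


def max_f_pairs_many(
    spec: NullModelSpec,
    grid: LineOriginGrid,
    Y: np.ndarray,
    min_sep_steps: int = 2,
) -> np.ndarray:
    """Pair-grid maximum F for each column of a response matrix (the 2D
    permutation workhorse)."""
    A, D, Q = _prep(spec, grid)
    n, k = Q.shape
    Y_r = _project_out(Q, Y)
    rss0 = np.einsum("ij,ij->j", Y_r, Y_r)  # (m,)
    A_r = _project_out(Q, A)
    D_r = _project_out(Q, D)
    AtY = A_r.T @ Y_r  # (P, m)
    DtY = D_r.T @ Y_r
    pairs = admissible_pairs(grid, min_sep_steps=min_sep_steps)
    df_full = n - k - 8
    m = Y.shape[1]
    best = np.zeros(m)
    for j, kk_ in pairs:
        W3 = np.column_stack([A_r[:, j], D_r[:, j], A_r[:, kk_], D_r[:, kk_]])
        inter = interaction_indicators(A[:, j], D[:, j], A[:, kk_], D[:, kk_]).stack()
        inter_r = _project_out(Q, inter)
        W4 = np.hstack([W3, inter_r])
        B3 = np.vstack([AtY[j], DtY[j], AtY[kk_], DtY[kk_]])  # (4, m)
        B4 = np.vstack([B3, inter_r.T @ Y_r])  # (8, m)
        G3 = W3.T @ W3
        G4 = W4.T @ W4
        rss3 = rss0 - np.einsum("im,im->m", B3, _solve(G3, B3))
        rss4 = rss0 - np.einsum("im,im->m", B4, _solve(G4, B4))
        rss4 = np.minimum(rss4, rss3)
        with np.errstate(divide="ignore", invalid="ignore"):
            f = ((rss3 - rss4) / 4) / (rss4 / df_full)
        np.maximum(best, f, out=best)
    return best


def _solve(G, B):
    try:
        return np.linalg.solve(G, B)
    except np.linalg.LinAlgError:
        return np.linalg.lstsq(G, B, rcond=None)[0]


def decompose_epistasis(
    spec: NullModelSpec, grid: LineOriginGrid, pos1: tuple, pos2: tuple
) -> pd.DataFrame:
    """Per-term t statistics of i1..i4 from the full two-locus fit.

    Returns a frame with estimate, SE and t per interaction term, sorted in
    TERMS order; the dominant term is the row with the largest |t|.
    """
    rows = _rows_for(spec, grid)
    ind = indicators(grid)
    j1 = grid.column(*pos1)
    j2 = grid.column(*pos2)
    inter = interaction_indicators(
        ind.A[rows, j1], ind.D[rows, j1], ind.A[rows, j2], ind.D[rows, j2]
    )
    X = np.hstack(
        [
            spec.Z,
            np.column_stack(
                [ind.A[rows, j1], ind.D[rows, j1], ind.A[rows, j2], ind.D[rows, j2]]
            ),
            inter.stack(),
        ]
    )
    y = spec.y
    coef, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ coef
    df = len(y) - rank
    sigma2 = float(resid @ resid) / df
    cov = sigma2 * np.linalg.pinv(X.T @ X)
    est = coef[-4:]
    se = np.sqrt(np.diag(cov)[-4:])
    with np.errstate(divide="ignore", invalid="ignore"):
        t = est / se
    return pd.DataFrame({"term": TERMS, "estimate": est, "se": se, "t": t})


@dataclass
class TwoLocusMap:
    """Discretised two-locus genotype classes with residual-phenotype means.

    `counts` and `means` are 3x3 (AA/AB/BB x AA/AB/BB, heterozygote
    orientations pooled) unless built with pooled=False, in which case they
    are 4x4 over the full origin states.
    """

    classes1: tuple
    classes2: tuple
    counts: np.ndarray
    means: np.ndarray
    n_used: int


def genotype_phenotype_map(
    spec: NullModelSpec,
    grid: LineOriginGrid,
    pos1: tuple,
    pos2: tuple,
    min_prob: float = 0.8,
    pooled: bool = True,
) -> TwoLocusMap:
    """Mean null-model residual per discretised two-locus genotype class.

    An individual enters a class at a locus only when that class's posterior
    probability strictly exceeds `min_prob` (AB and BA are pooled by summing
    before thresholding when `pooled`); individuals without a confident call
    at either locus are dropped.
    """
    rows = _rows_for(spec, grid)
    j1 = grid.column(*pos1)
    j2 = grid.column(*pos2)
    resid = spec.residuals

    def _classify(j):
        p = grid.probs[rows, j, :]
        if pooled:
            cls = np.column_stack([p[:, 0], p[:, 1] + p[:, 2], p[:, 3]])
            labels = ("AA", "AB", "BB")
        else:
            cls = p
            labels = ("AA", "AB", "BA", "BB")
        best = np.argmax(cls, axis=1)
        conf = cls[np.arange(len(best)), best] > min_prob
        return best, conf, labels

    g1, ok1, lab1 = _classify(j1)
    g2, ok2, lab2 = _classify(j2)
    use = ok1 & ok2
    k1, k2 = len(lab1), len(lab2)
    counts = np.zeros((k1, k2), dtype=int)
    sums = np.zeros((k1, k2))
    np.add.at(counts, (g1[use], g2[use]), 1)
    np.add.at(sums, (g1[use], g2[use]), resid[use])
    with np.errstate(invalid="ignore"):
        means = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    if not use.any():
        import warnings

        warnings.warn("no individuals pass the confidence rule; empty map", stacklevel=2)
    return TwoLocusMap(
        classes1=lab1, classes2=lab2, counts=counts, means=means, n_used=int(use.sum())
    )
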