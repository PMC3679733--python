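"""One-dimensional Haley-Knott genome scan with cofactor selection.

At every grid position the trait is regressed on the line-origin indicators
A and D on top of the null (non-genetic) model, optionally with previously
detected QTL frozen as cofactors:

    full:    y = mu + beta*F + gamma*C + [cofactors] + a*A + d*D + e
    reduced: y = mu + beta*F + gamma*C + [cofactors] + e

and F = ((RSS_red - RSS_full)/2) / (RSS_full / df_full) with 2 numerator
degrees of freedom.  The sign convention follows the cross: a > 0 means the
line-A (commercial, fast-growing) allele increases the trait.

The scan is vectorised across positions by projecting y, A and D onto the
orthogonal complement of the base design (Frisch-Waugh), which is exact.
Forward selection freezes the most significant genome-wide-significant peak
as a cofactor and rescans until nothing exceeds the threshold; linked pairs
on one chromosome can be re-tested jointly.  The share of residual variance
a QTL explains is Var% = (MS'_R - MS_F) / MS_R x 100, where MS'_R is the
residual mean square of the reduced model (other QTL included as
cofactors), MS_F that of the full model, and MS_R that of the plain null
model with no QTL at all.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .origin import LineOriginGrid, indicators
from .pheno import NullModelSpec

__all__ = [
    "PositionFit",
    "ScanResult",
    "QtlCall",
    "CollinearityError",
    "fit_position",
    "scan_genome",
    "max_f_many",
    "forward_scan",
    "test_linked_pair",
    "variance_explained",
]

_DEGENERATE_TOL = 1e-10


class CollinearityError(ValueError):
    """Two tested positions are too close to separate."""


@dataclass
class PositionFit:
    group: object
    cm: float
    f: float
    a: float
    se_a: float
    d: float
    se_d: float
    rss_full: float
    rss_reduced: float
    df_full: int
    degenerate: bool = False


@dataclass
class ScanResult:
    trait: str
    profile: pd.DataFrame  # group, cm, f, a, se_a, d, se_d
    peak: PositionFit
    peak_marker: str | None = None
    cofactors: list = field(default_factory=list)
    thresholds: dict = field(default_factory=dict)


@dataclass
class QtlCall:
    name: str
    trait: str
    group: object
    cm: float
    peak_marker: str | None
    f: float
    a: float
    se_a: float
    d: float
    se_d: float
    var_pct: float | None
    level: str  # "5%" or "1%" genome-wide


# ----------------------------------------------------------------------
# alignment helpers


def _rows_for(spec: NullModelSpec, grid: LineOriginGrid) -> np.ndarray:
    lookup = {i: k for k, i in enumerate(grid.ids)}
    try:
        return np.array([lookup[i] for i in spec.ids], dtype=int)
    except KeyError as e:  # pragma: no cover - contract violation
        raise KeyError(f"phenotyped individual {e} missing from the origin grid") from e


def _cofactor_columns(grid: LineOriginGrid, rows, cofactors) -> np.ndarray | None:
    if not cofactors:
        return None
    ind = indicators(grid)
    cols = []
    for g, cm in cofactors:
        j = grid.column(g, cm)
        cols += [ind.A[rows, j], ind.D[rows, j]]
    return np.column_stack(cols)


def _base_q(spec: NullModelSpec, extra: np.ndarray | None) -> np.ndarray:
    Z = spec.Z if extra is None else np.hstack([spec.Z, extra])
    q, r = np.linalg.qr(Z)
    keep = np.abs(np.diag(r)) > 1e-9 * max(1.0, np.abs(np.diag(r)).max())
    return q[:, keep]


# ----------------------------------------------------------------------
# single-position fit (reference implementation used by the scan's tests)


def fit_position(
    spec: NullModelSpec,
    A: np.ndarray,
    D: np.ndarray,
    cofactors: np.ndarray | None = None,
    group=None,
    cm: float = np.nan,
) -> PositionFit:
    """Least-squares fit of the two-indicator QTL model at one position.

    `A` and `D` must align with ``spec.ids``.  A perfect fit (RSS_full = 0)
    is reported as a degenerate-fit signal with infinite F, not a number
    pretending to be finite.
    """
    y = spec.y
    n = len(y)
    Zr = spec.Z if cofactors is None else np.hstack([spec.Z, cofactors])
    X = np.hstack([Zr, A[:, None], D[:, None]])
    coef_r, _, rank_r, _ = np.linalg.lstsq(Zr, y, rcond=None)
    rss_red = float(np.sum((y - Zr @ coef_r) ** 2))
    coef_f, _, rank_f, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ coef_f
    rss_full = float(resid @ resid)
    df_full = n - rank_f
    a, d = float(coef_f[-2]), float(coef_f[-1])
    degenerate = rss_full <= _DEGENERATE_TOL * max(rss_red, 1.0)
    if degenerate or df_full <= 0:
        return PositionFit(group, cm, np.inf, a, 0.0, d, 0.0, rss_full, rss_red, df_full, True)
    sigma2 = rss_full / df_full
    xtx_inv = np.linalg.pinv(X.T @ X)
    se_a = float(np.sqrt(sigma2 * xtx_inv[-2, -2]))
    se_d = float(np.sqrt(sigma2 * xtx_inv[-1, -1]))
    f = ((rss_red - rss_full) / 2) / sigma2
    return PositionFit(group, cm, max(f, 0.0), a, se_a, d, se_d, rss_full, rss_red, df_full)


# ----------------------------------------------------------------------
# vectorised genome scan


def _scan_arrays(spec, grid, cofactors):
    rows = _rows_for(spec, grid)
    ind = indicators(grid)
    A = ind.A[rows]
    D = ind.D[rows]
    Q = _base_q(spec, _cofactor_columns(grid, rows, cofactors))
    return A, D, Q


def _project_out(Q, M):
    return M - Q @ (Q.T @ M)


def scan_genome(
    spec: NullModelSpec,
    grid: LineOriginGrid,
    cofactors: list | None = None,
    gmap=None,
    thresholds: dict | None = None,
) -> ScanResult:
    """Fit the QTL model at every grid position; deterministic given inputs.

    Ties in the maximum F are broken by grid order (first group in the map,
    then smallest cM).
    """
    cofactors = list(cofactors or [])
    A, D, Q = _scan_arrays(spec, grid, cofactors)
    n, k = Q.shape
    y_r = _project_out(Q, spec.y)
    rss_red = float(y_r @ y_r)
    A_r = _project_out(Q, A)
    D_r = _project_out(Q, D)

    saa = np.einsum("ij,ij->j", A_r, A_r)
    sdd = np.einsum("ij,ij->j", D_r, D_r)
    sad = np.einsum("ij,ij->j", A_r, D_r)
    say = A_r.T @ y_r
    sdy = D_r.T @ y_r
    det = saa * sdd - sad**2
    ok = det > 1e-12 * np.maximum(saa * sdd, 1e-300)
    safe_det = np.where(ok, det, 1.0)
    beta_a = np.where(ok, (sdd * say - sad * sdy) / safe_det, 0.0)
    beta_d = np.where(ok, (saa * sdy - sad * say) / safe_det, 0.0)
    explained = np.clip(beta_a * say + beta_d * sdy, 0.0, rss_red)
    rss_full = rss_red - explained
    df_full = n - k - 2
    degenerate = rss_full <= _DEGENERATE_TOL * max(rss_red, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        sigma2 = rss_full / df_full
        f = np.where(degenerate, np.inf, (explained / 2) / sigma2)
        se_a = np.sqrt(np.where(ok, sigma2 * sdd / safe_det, np.nan))
        se_d = np.sqrt(np.where(ok, sigma2 * saa / safe_det, np.nan))

    prof = grid.positions.copy()
    prof["f"] = f
    prof["a"] = beta_a
    prof["se_a"] = se_a
    prof["d"] = beta_d
    prof["se_d"] = se_d
    ipk = int(np.argmax(f))
    peak = PositionFit(
        group=prof["group"].iloc[ipk],
        cm=float(prof["cm"].iloc[ipk]),
        f=float(f[ipk]),
        a=float(beta_a[ipk]),
        se_a=float(se_a[ipk]),
        d=float(beta_d[ipk]),
        se_d=float(se_d[ipk]),
        rss_full=float(rss_full[ipk]),
        rss_reduced=rss_red,
        df_full=df_full,
        degenerate=bool(degenerate[ipk]),
    )
    marker = gmap.nearest_marker(peak.group, peak.cm) if gmap is not None else None
    return ScanResult(
        trait=spec.trait,
        profile=prof,
        peak=peak,
        peak_marker=marker,
        cofactors=cofactors,
        thresholds=dict(thresholds or {}),
    )


def max_f_many(
    spec: NullModelSpec,
    grid: LineOriginGrid,
    Y: np.ndarray,
    cofactors: list | None = None,
) -> np.ndarray:
    """Genome-wide maximum F for each column of a response matrix.

    The workhorse of permutation thresholds: Y is (n, m) with one permuted
    response per column; the same base design is projected out of all of
    them at once.
    """
    A, D, Q = _scan_arrays(spec, grid, list(cofactors or []))
    n, k = Q.shape
    Y_r = _project_out(Q, Y)
    rss_red = np.einsum("ij,ij->j", Y_r, Y_r)  # (m,)
    A_r = _project_out(Q, A)
    D_r = _project_out(Q, D)
    saa = np.einsum("ij,ij->j", A_r, A_r)[:, None]
    sdd = np.einsum("ij,ij->j", D_r, D_r)[:, None]
    sad = np.einsum("ij,ij->j", A_r, D_r)[:, None]
    say = A_r.T @ Y_r  # (P, m)
    sdy = D_r.T @ Y_r
    det = saa * sdd - sad**2
    ok = det > 1e-12 * np.maximum(saa * sdd, 1e-300)
    safe_det = np.where(ok, det, 1.0)
    beta_a = np.where(ok, (sdd * say - sad * sdy) / safe_det, 0.0)
    beta_d = np.where(ok, (saa * sdy - sad * say) / safe_det, 0.0)
    explained = np.clip(beta_a * say + beta_d * sdy, 0.0, rss_red[None, :])
    df_full = n - k - 2
    with np.errstate(divide="ignore", invalid="ignore"):
        f = (explained / 2) / ((rss_red[None, :] - explained) / df_full)
    return np.nanmax(f, axis=0)


# ----------------------------------------------------------------------
# forward selection and linked-QTL handling


def forward_scan(
    spec: NullModelSpec,
    grid: LineOriginGrid,
    threshold5: float,
    threshold1: float | None = None,
    gmap=None,
    cross_tag: str = "CAU_AB",
    max_rounds: int = 20,
) -> tuple[list[QtlCall], list[ScanResult]]:
    """Iterative cofactor scan: freeze the top significant peak, rescan,
    stop when no peak clears the 5% genome-wide threshold.

    Thresholds are computed once per trait (first-round permutations) and
    reused across rounds.  Calls are named `<tag> <group><letter>` with
    letters increasing along the chromosome.
    """
    cofactors: list = []
    picked: list[PositionFit] = []
    markers: list = []
    rounds: list[ScanResult] = []
    for _ in range(max_rounds):
        res = scan_genome(spec, grid, cofactors=cofactors, gmap=gmap,
                          thresholds={"5%": threshold5, "1%": threshold1})
        rounds.append(res)
        if not (res.peak.f > threshold5):
            break
        picked.append(res.peak)
        markers.append(res.peak_marker)
        cofactors.append((res.peak.group, res.peak.cm))

    # letter suffixes in cM order per chromosome
    order = sorted(range(len(picked)), key=lambda i: (str(picked[i].group), picked[i].cm))
    names = [""] * len(picked)
    per_group: dict = {}
    for i in order:
        g = picked[i].group
        per_group[g] = per_group.get(g, 0) + 1
    seen: dict = {}
    for i in order:
        g = picked[i].group
        seen[g] = seen.get(g, 0) + 1
        suffix = chr(ord("a") + seen[g] - 1) if per_group[g] > 1 else ""
        names[i] = f"{cross_tag} {g}{suffix}"

    var = variance_for_calls(spec, grid, [(p.group, p.cm) for p in picked])
    calls = []
    for i, p in enumerate(picked):
        level = "1%" if threshold1 is not None and p.f > threshold1 else "5%"
        calls.append(
            QtlCall(
                name=names[i], trait=spec.trait, group=p.group, cm=p.cm,
                peak_marker=markers[i], f=p.f, a=p.a, se_a=p.se_a, d=p.d,
                se_d=p.se_d, var_pct=var[i], level=level,
            )
        )
    return calls, rounds


def variance_for_calls(spec: NullModelSpec, grid: LineOriginGrid, positions: list) -> list:
    """Var% for each called QTL with the other calls as cofactors."""
    out = []
    rows = _rows_for(spec, grid)
    ind = indicators(grid)
    for i, (g, cm) in enumerate(positions):
        others = [p for j, p in enumerate(positions) if j != i]
        cof = _cofactor_columns(grid, rows, others)
        j = grid.column(g, cm)
        fit = fit_position(spec, ind.A[rows, j], ind.D[rows, j], cofactors=cof, group=g, cm=cm)
        dfr = fit.df_full + 2
        ms_rp = fit.rss_reduced / dfr
        ms_f = fit.rss_full / fit.df_full if fit.df_full > 0 else np.nan
        out.append(variance_explained(ms_rp, ms_f, spec.ms_resid))
    return out


def test_linked_pair(
    spec: NullModelSpec,
    grid: LineOriginGrid,
    pos1: tuple,
    pos2: tuple,
    threshold: float,
) -> dict:
    """Joint two-QTL fit for two peaks on one chromosome.

    Each QTL's partial F drops its own (a, d) pair from the joint model;
    the pair is called independent iff both partial Fs clear the threshold.
    Positions closer than one grid step are rejected as collinear.
    """
    (g1, cm1), (g2, cm2) = pos1, pos2
    if g1 == g2 and abs(cm1 - cm2) < grid.step:
        raise CollinearityError(
            f"positions {cm1} and {cm2} cM on group {g1} are closer than one grid step"
        )
    rows = _rows_for(spec, grid)
    ind = indicators(grid)
    j1, j2 = grid.column(g1, cm1), grid.column(g2, cm2)
    W1 = np.column_stack([ind.A[rows, j1], ind.D[rows, j1]])
    W2 = np.column_stack([ind.A[rows, j2], ind.D[rows, j2]])
    y, Z = spec.y, spec.Z
    n = len(y)
    X = np.hstack([Z, W1, W2])
    _, _, rank_f, _ = np.linalg.lstsq(X, y, rcond=None)
    rss_full = _rss(X, y)
    df_full = n - rank_f
    partial = []
    for Wdrop, Wkeep in ((W1, W2), (W2, W1)):
        rss_red = _rss(np.hstack([Z, Wkeep]), y)
        fval = ((rss_red - rss_full) / 2) / (rss_full / df_full)
        partial.append(max(float(fval), 0.0))
    return {
        "f_partial_1": partial[0],
        "f_partial_2": partial[1],
        "threshold": threshold,
        "independent": bool(partial[0] > threshold and partial[1] > threshold),
    }


def _rss(X, y) -> float:
    coef, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    r = y - X @ coef
    return float(r @ r)


def variance_explained(ms_reduced_prime: float, ms_full: float, ms_reduced: float) -> float:
    """Percent of residual phenotypic variance attributed to a QTL (or pair):
    (MS'_R - MS_F) / MS_R x 100."""
    for v in (ms_reduced_prime, ms_full, ms_reduced):
        if v < 0:
            raise ValueError("mean squares must be non-negative")
    if ms_reduced == 0:
        raise ZeroDivisionError("null-model residual mean square is zero")
    return (ms_reduced_prime - ms_full) / ms_reduced * 100.0
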