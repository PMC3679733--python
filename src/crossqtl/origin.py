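"""Multipoint line-origin probabilities for F2 individuals.

For each F2 and each grid position we want the posterior probability of the
four line-origin states AA, AB, BA, BB (maternal gamete origin first), i.e.
whether each of the two alleles descends from founder line A or line B.
The model is the standard line-cross multipoint model: per gamete, origin
along a chromosome is a first-order Markov chain whose switching probability
between adjacent loci is the Haldane recombination fraction of the cM gap;
the two gametes are independent, so the joint 4-state chain factorises.
Emissions are the probability of the observed biallelic call given the
state and the line allele frequencies (outbred founder lines make markers
only partially informative); missing calls emit 1.  Posteriors on the
evaluation grid come from inserting pseudo-loci with unit emission and
running a forward-backward pass.  The chromosome-start prior is the F2
expectation (1/4, 1/4, 1/4, 1/4).

The regression indicators of Haley-Knott line-cross mapping follow directly:
A = P(AA) - P(BB) and D = P(AB) + P(BA).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import MISSING, CrossGenotypes, DataError
from .genmap import MapError, haldane_r

__all__ = [
    "LineAlleleFrequencies",
    "LineOriginGrid",
    "OriginIndicators",
    "estimate_line_frequencies",
    "compute_line_origin",
    "indicators",
]

STATES = ("AA", "AB", "BA", "BB")  # (maternal origin, paternal origin)


@dataclass
class LineAlleleFrequencies:
    """Per-marker frequency of allele 2 in each founder line."""

    freq_a: np.ndarray
    freq_b: np.ndarray
    n_uninformative: int = 0  # markers unscored in at least one line


def estimate_line_frequencies(
    genos: CrossGenotypes, pseudocount: float = 0.5
) -> LineAlleleFrequencies:
    """Observed allele proportions among the genotyped F0 of each line.

    A pseudocount (default 0.5 per allele) avoids 0/1 degeneracy at
    miscalled markers; a marker with no founder calls in a line gets the
    uninformative frequency 0.5 (with a warning).
    """
    ped = genos.individuals
    freqs = {}
    n_unscored = 0
    for line in ("A", "B"):
        cols = np.flatnonzero(
            ((ped["generation"] == "F0") & (ped["line"] == line)).to_numpy()
        )
        if cols.size == 0:
            raise DataError(f"no genotyped F0 founders for line {line}")
        sub = genos.calls[:, cols]
        called = sub != MISSING
        n_alleles = 2 * called.sum(axis=1)
        count2 = np.where(called, sub, 0).sum(axis=1)
        freqs[line] = (count2 + pseudocount) / (n_alleles + 2 * pseudocount)
        n_unscored += int((n_alleles == 0).sum())
    if n_unscored:
        warnings.warn(
            f"{n_unscored} marker/line combinations had no founder calls; "
            "frequency set to 0.5",
            stacklevel=2,
        )
    return LineAlleleFrequencies(
        freq_a=freqs["A"], freq_b=freqs["B"], n_uninformative=n_unscored
    )


@dataclass
class OriginIndicators:
    """Haley-Knott regression indicators per individual x grid position."""

    positions: pd.DataFrame  # columns: group, cm
    ids: list
    A: np.ndarray  # in [-1, 1]
    D: np.ndarray  # in [0, 1]


@dataclass
class LineOriginGrid:
    """Posterior line-origin state probabilities on an evaluation grid.

    ``probs`` has shape (n_individuals, n_grid_positions, 4) in STATES
    order; ``positions`` lists (group, cm) per grid column.
    """

    positions: pd.DataFrame
    ids: list
    probs: np.ndarray
    step: float = 1.0

    def __post_init__(self) -> None:
        s = self.probs.sum(axis=2)
        if not np.allclose(s, 1.0, atol=1e-9):
            raise ValueError("state probabilities must sum to 1")

    def group_slice(self, group) -> slice:
        idx = np.flatnonzero((self.positions["group"] == group).to_numpy())
        return slice(int(idx[0]), int(idx[-1]) + 1)

    def column(self, group, cm: float) -> int:
        sub = self.positions
        hits = np.flatnonzero(
            ((sub["group"] == group) & (np.abs(sub["cm"] - cm) < 1e-6)).to_numpy()
        )
        if hits.size == 0:
            raise KeyError(f"no grid position at {group}:{cm} cM")
        return int(hits[0])

    def to_frame(self) -> pd.DataFrame:
        n_ind, n_pos, _ = self.probs.shape
        return pd.DataFrame(
            {
                "id": np.repeat(self.ids, n_pos),
                "group": np.tile(self.positions["group"].to_numpy(), n_ind),
                "cm": np.tile(self.positions["cm"].to_numpy(), n_ind),
                "p_aa": self.probs[:, :, 0].ravel(),
                "p_ab": self.probs[:, :, 1].ravel(),
                "p_ba": self.probs[:, :, 2].ravel(),
                "p_bb": self.probs[:, :, 3].ravel(),
            }
        )

    def write_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False, float_format="%.6g")

    @classmethod
    def read_tsv(cls, path, step: float = 1.0) -> "LineOriginGrid":
        t = pd.read_csv(path, sep="\t")
        ids = list(dict.fromkeys(t["id"]))
        n_ind = len(ids)
        n_pos = len(t) // n_ind
        pos = t.iloc[:n_pos][["group", "cm"]].reset_index(drop=True)
        probs = t[["p_aa", "p_ab", "p_ba", "p_bb"]].to_numpy().reshape(n_ind, n_pos, 4)
        return cls(positions=pos, ids=ids, probs=probs, step=step)


def indicators(grid: LineOriginGrid) -> OriginIndicators:
    """A = P(AA) - P(BB); D = P(AB) + P(BA), elementwise."""
    return OriginIndicators(
        positions=grid.positions,
        ids=grid.ids,
        A=grid.probs[:, :, 0] - grid.probs[:, :, 3],
        D=grid.probs[:, :, 1] + grid.probs[:, :, 2],
    )


# ----------------------------------------------------------------------
# forward-backward machinery


def _emissions(calls, fa, fb, error_rate):
    """P(observed call | state) for one chromosome.

    calls: (n_ind, n_markers) dosages of allele 2 (-1 missing).
    fa/fb: allele-2 frequency per marker in each line.
    Returns (n_ind, n_markers, 4).
    """
    n_ind, n_mark = calls.shape
    f_by_origin = np.stack([fa, fb])  # origin 0 = line A
    # genotype distribution per state: P(dosage g | maternal origin, paternal origin)
    pg = np.empty((4, n_mark, 3))
    for s, (om, op) in enumerate([(0, 0), (0, 1), (1, 0), (1, 1)]):
        fm, fp = f_by_origin[om], f_by_origin[op]
        pg[s, :, 0] = (1 - fm) * (1 - fp)
        pg[s, :, 1] = fm * (1 - fp) + (1 - fm) * fp
        pg[s, :, 2] = fm * fp
    if error_rate > 0:
        # symmetric miscall: correct with prob 1-e, each wrong class e/2
        e = error_rate
        pg = (1 - 1.5 * e) * pg + (e / 2) * pg.sum(axis=2, keepdims=True)
    em = np.ones((n_ind, n_mark, 4))
    obs = calls != MISSING
    idx_i, idx_m = np.nonzero(obs)
    g = calls[idx_i, idx_m]
    for s in range(4):
        em[idx_i, idx_m, s] = pg[s, idx_m, g]
    return em


def _transition(r: float) -> np.ndarray:
    """4-state transition matrix: independent per-gamete switching."""
    t = np.array([[1 - r, r], [r, 1 - r]])
    return np.kron(t, t)


def compute_line_origin(
    genos: CrossGenotypes,
    line_freqs: LineAlleleFrequencies,
    grid_step: float = 1.0,
    error_rate: float = 0.0,
    individuals: list | None = None,
) -> LineOriginGrid:
    """Posterior line-origin probabilities at every grid position.

    Runs a scaled forward-backward pass per chromosome over the union of
    marker and grid positions, vectorised over individuals.  `individuals`
    defaults to all F2s in the pedigree.
    """
    gmap = genos.gmap
    if individuals is None:
        individuals = genos.generation_ids("F2")
    cols = genos.col_index(individuals)
    n_ind = len(cols)

    all_pos, all_probs = [], []
    for g in gmap.groups:
        rows = np.flatnonzero((gmap.table["group"] == g).to_numpy())
        mpos = np.round(gmap.positions(g), 9)
        gpos = np.round(gmap.grid(g, step=grid_step), 9)
        union = np.union1d(mpos, gpos)
        gaps = np.diff(union)
        if (gaps < 0).any():
            raise MapError(f"negative cM gap on group {g}")
        r = haldane_r(gaps)
        midx = np.searchsorted(union, mpos)
        gidx = np.searchsorted(union, gpos)
        nu = len(union)

        em_m = _emissions(
            genos.calls[np.ix_(rows, cols)].T,
            line_freqs.freq_a[rows],
            line_freqs.freq_b[rows],
            error_rate,
        )
        em = np.ones((n_ind, nu, 4))
        if len(np.unique(midx)) == len(midx):
            em[:, midx, :] = em_m
        else:  # co-located markers: emissions multiply
            for i, u in enumerate(midx):
                em[:, u, :] *= em_m[:, i, :]

        trans = [_transition(rk) for rk in r]
        # forward, scaled
        alpha = np.empty((n_ind, nu, 4))
        a = 0.25 * em[:, 0, :]
        scale = a.sum(axis=1, keepdims=True)
        alpha[:, 0, :] = a / scale
        for k in range(1, nu):
            a = (alpha[:, k - 1, :] @ trans[k - 1]) * em[:, k, :]
            s = a.sum(axis=1, keepdims=True)
            alpha[:, k, :] = a / s
        # backward, scaled
        post = np.empty_like(alpha)
        b = np.ones((n_ind, 4))
        post[:, nu - 1, :] = alpha[:, nu - 1, :]
        for k in range(nu - 2, -1, -1):
            b = (b * em[:, k + 1, :]) @ trans[k].T
            b /= b.sum(axis=1, keepdims=True)
            p = alpha[:, k, :] * b
            post[:, k, :] = p / p.sum(axis=1, keepdims=True)

        all_probs.append(post[:, gidx, :])
        all_pos.append(pd.DataFrame({"group": g, "cm": union[gidx]}))

    return LineOriginGrid(
        positions=pd.concat(all_pos, ignore_index=True),
        ids=list(individuals),
        probs=np.concatenate(all_probs, axis=1),
        step=grid_step,
    )
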