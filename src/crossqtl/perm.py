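"""Permutation machinery: genome-wide thresholds and region-overlap tests.

Genome-wide significance follows the Churchill-Doerge recipe: the residuals
of the null (non-genetic) model are shuffled among individuals while the
genotype indicators stay fixed, the genome-wide (or pair-grid) maximum F is
recorded per shuffle, and the threshold is the empirical (1 - alpha)
quantile of those maxima.  Shuffling residuals rather than raw phenotypes
preserves the fixed-effect structure under the null.

The region-overlap permutation asks how surprising it is that an observed
set of genomic regions hits members of a gene set: each replicate re-places
regions of the observed sizes (drawn without replacement) on chromosomes
drawn uniformly with replacement, rejecting infeasible or overlapping
placements, and scores how many placed regions contain at least one gene.
Intervals are 1-based inclusive; any shared base counts as containment.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .pheno import NullModelSpec
from .origin import LineOriginGrid
from . import scan1d, scan2d

__all__ = [
    "ThresholdSet",
    "OverlapNull",
    "permutation_threshold",
    "count_region_overlaps",
    "region_overlap_permutation",
    "bed_to_regions",
    "regions_to_bed",
]


@dataclass
class ThresholdSet:
    trait: str
    scan: str  # "1d" or "2d"
    n_perm: int
    seed: int
    thresholds: dict  # alpha -> F threshold
    maxima: np.ndarray = field(repr=False, default=None)

    def threshold(self, alpha: float) -> float:
        return self.thresholds[alpha]


def permutation_threshold(
    spec: NullModelSpec,
    grid: LineOriginGrid,
    scan: str = "1d",
    n_perm: int = 1000,
    alphas: tuple = (0.05, 0.01),
    seed: int = 0,
    cofactors: list | None = None,
    min_sep_steps: int = 2,
) -> ThresholdSet:
    """Genome-wide F thresholds from shuffled null-model residuals.

    Deterministic given `seed`.  `n_perm` must be at least 100 for the tail
    quantiles to mean anything.
    """
    for a in alphas:
        if not 0 < a < 1:
            raise ValueError(f"alpha {a} outside (0, 1)")
    if n_perm < 100:
        raise ValueError("need at least 100 permutations")
    rng = np.random.default_rng(seed)
    resid = spec.residuals
    Y = np.column_stack([rng.permutation(resid) for _ in range(n_perm)])
    if scan == "1d":
        maxima = scan1d.max_f_many(spec, grid, Y, cofactors=cofactors)
    elif scan == "2d":
        maxima = scan2d.max_f_pairs_many(spec, grid, Y, min_sep_steps=min_sep_steps)
    else:
        raise ValueError(f"unknown scan type {scan!r}")
    thresholds = {a: float(np.quantile(maxima, 1 - a)) for a in alphas}
    return ThresholdSet(
        trait=spec.trait, scan=scan, n_perm=n_perm, seed=seed,
        thresholds=thresholds, maxima=maxima,
    )


# ----------------------------------------------------------------------
# region-overlap permutation test


@dataclass
class OverlapNull:
    """Null distribution of the number of regions containing gene-set genes."""

    n_regions: int
    observed: int
    n_replicates: int
    seed: int
    histogram: np.ndarray  # counts of replicates with overlap 0..n_regions
    p_ge: float  # P(count >= observed)
    p_eq: float  # P(count == observed)

    def __post_init__(self) -> None:
        assert int(self.histogram.sum()) == self.n_replicates


def _check_intervals(df: pd.DataFrame, what: str) -> pd.DataFrame:
    if (df["start"] > df["end"]).any():
        raise ValueError(f"{what}: start > end")
    return df


def count_region_overlaps(regions: pd.DataFrame, genes: pd.DataFrame) -> int:
    """Number of regions intersecting at least one gene (closed 1-based
    intervals; any shared base counts)."""
    _check_intervals(regions, "regions")
    _check_intervals(genes, "genes")
    n = 0
    for _, r in regions.iterrows():
        g = genes[genes["chrom"] == r["chrom"]]
        if ((g["start"] <= r["end"]) & (g["end"] >= r["start"])).any():
            n += 1
    return n


def region_overlap_permutation(
    regions: pd.DataFrame,
    genes: pd.DataFrame,
    chrom_sizes: dict,
    n_replicates: int = 10_000,
    seed: int = 0,
    max_tries: int = 1000,
) -> OverlapNull:
    """Permutation null for the count of gene-containing regions.

    `regions` and `genes` need columns chrom, start, end (1-based
    inclusive); `chrom_sizes` maps chromosome id -> length in bp (regions
    may be placed on any of these chromosomes, sampled uniformly with
    replacement).  Per replicate the observed region sizes are drawn without
    replacement; a chromosome assignment is rejected and redrawn when the
    sizes already placed there plus the new one exceed the chromosome, and
    start positions are redrawn on overlap or boundary overrun.
    """
    _check_intervals(regions, "regions")
    sizes = (regions["end"] - regions["start"] + 1).to_numpy(np.int64)
    chroms = list(chrom_sizes)
    lens = np.array([chrom_sizes[c] for c in chroms], dtype=np.int64)
    if (sizes > lens.max()).any():
        raise ValueError("a region is larger than every chromosome")
    n_reg = len(sizes)
    rng = np.random.default_rng(seed)

    gene_by_chrom = {
        c: (g["start"].to_numpy(np.int64), g["end"].to_numpy(np.int64))
        for c, g in genes.groupby("chrom")
    }
    observed = count_region_overlaps(regions, genes)

    hist = np.zeros(n_reg + 1, dtype=np.int64)
    for _ in range(n_replicates):
        order = rng.permutation(n_reg)  # sizes without replacement
        placed: dict = {c: [] for c in chroms}
        used: dict = {c: 0 for c in chroms}
        score = 0
        for w in sizes[order]:
            # chromosome assignment, re-drawn until the summed sizes fit;
            # if no non-overlapping start is found (the size check does not
            # guarantee one exists), the chromosome itself is re-drawn
            start = end = c = None
            for _try in range(max_tries):
                ci = int(rng.integers(0, len(chroms)))
                c = chroms[ci]
                if used[c] + w > lens[ci]:
                    continue
                L = int(lens[ci])
                for _s in range(20):
                    s0 = int(rng.integers(1, L - w + 2))
                    e0 = s0 + int(w) - 1
                    if all(not (s0 <= e and e0 >= s) for s, e in placed[c]):
                        start, end = s0, e0
                        break
                if start is not None:
                    break
            else:  # pragma: no cover - pathological geometry
                raise RuntimeError("could not place region; chromosomes too full")
            placed[c].append((start, end))
            used[c] += int(w)
            gs = gene_by_chrom.get(c)
            if gs is not None and ((gs[0] <= end) & (gs[1] >= start)).any():
                score += 1
        hist[score] += 1

    p_ge = float(hist[observed:].sum() / n_replicates)
    p_eq = float(hist[observed] / n_replicates)
    return OverlapNull(
        n_regions=n_reg, observed=observed, n_replicates=n_replicates,
        seed=seed, histogram=hist, p_ge=p_ge, p_eq=p_eq,
    )


# ----------------------------------------------------------------------
# interval convention converters (1-based inclusive <-> BED half-open)


def bed_to_regions(bed: pd.DataFrame) -> pd.DataFrame:
    """0-based half-open BED rows -> 1-based inclusive regions."""
    out = bed.rename(columns={bed.columns[0]: "chrom"}).copy()
    out["start"] = bed.iloc[:, 1] + 1
    out["end"] = bed.iloc[:, 2]
    return out[["chrom", "start", "end"]]


def regions_to_bed(regions: pd.DataFrame) -> pd.DataFrame:
    """1-based inclusive regions -> 0-based half-open BED."""
    return pd.DataFrame(
        {
            "chrom": regions["chrom"],
            "start": regions["start"] - 1,
            "end": regions["end"],
        }
    )
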