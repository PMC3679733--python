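"""Shared containers for a three-generation line cross.

``CrossGenotypes`` holds the pedigree, the genetic map and the biallelic SNP
call matrix; when produced by the simulator it additionally retains the true
line origin of every F2 gamete on the evaluation grid, which downstream tests
use as ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genmap import GeneticMap

MISSING = -1  # sentinel in the int8 call matrix

__all__ = ["CrossGenotypes", "TrueOrigin", "MISSING", "DataError"]


class DataError(ValueError):
    """Raised for irrecoverable data inconsistencies."""


@dataclass
class TrueOrigin:
    """True gamete line origins for simulated F2s on a position grid.

    ``positions[group]`` are cM coordinates; ``maternal[group]`` and
    ``paternal[group]`` are (n_f2, n_positions) int8 arrays with 0 = line A,
    1 = line B.  Rows align with ``f2_ids``.
    """

    f2_ids: list
    positions: dict
    maternal: dict
    paternal: dict

    def genotype_class(self, group) -> np.ndarray:
        """0 = AA, 1 = heterozygous, 2 = BB at every grid position."""
        return self.maternal[group] + self.paternal[group]

    def additive(self, group) -> np.ndarray:
        """True additive indicator: +1 for AA, 0 for het, -1 for BB."""
        return 1.0 - self.genotype_class(group).astype(float)

    def dominance(self, group) -> np.ndarray:
        """True dominance indicator: 1 for heterozygotes, 0 otherwise."""
        return (self.genotype_class(group) == 1).astype(float)


@dataclass
class CrossGenotypes:
    """Pedigree + SNP calls for an F2 line cross.

    Attributes
    ----------
    individuals:
        DataFrame indexed by individual id with columns ``generation``
        ("F0"/"F1"/"F2"), ``line`` ("A"/"B" for F0, else ""), ``sire``,
        ``dam`` (ids or ""), ``sex`` ("M"/"F") and ``cross_type``
        ("AxB"/"BxA" for F1, else "").
    gmap:
        The genetic map; rows of ``calls`` follow ``gmap.table`` order.
    calls:
        int8 array (n_markers, n_individuals); value = copies of allele 2,
        ``MISSING`` (-1) when not called.
    alleles:
        (n_markers, 2) array of single-character allele codes for file IO.
    true_origin:
        Simulator-only ground truth (None for real data).
    """

    individuals: pd.DataFrame
    gmap: GeneticMap
    calls: np.ndarray
    alleles: np.ndarray | None = None
    true_origin: TrueOrigin | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if self.calls.shape != (self.gmap.n_markers, len(self.individuals)):
            raise DataError(
                f"call matrix {self.calls.shape} does not match "
                f"{self.gmap.n_markers} markers x {len(self.individuals)} individuals"
            )
        ped = self.individuals
        f2 = ped[ped["generation"] == "F2"]
        f1_ids = set(ped.index[ped["generation"] == "F1"])
        # non-blank parent links of F2s must resolve to F1s in the pedigree
        # (QC may sever a link by removing the parent; the link is then blanked)
        for col in ("sire", "dam"):
            nonblank = f2[f2[col] != ""]
            bad = nonblank[~nonblank[col].isin(f1_ids)]
            if len(bad):
                raise DataError(
                    f"F2 individuals with unresolvable F1 {col}s: {list(bad.index[:5])}"
                )
        if self.alleles is None:
            self.alleles = np.tile(np.array(["A", "B"]), (self.gmap.n_markers, 1))

    # -- convenience views --------------------------------------------

    @property
    def ids(self) -> list:
        return list(self.individuals.index)

    def generation_ids(self, gen: str) -> list:
        return list(self.individuals.index[self.individuals["generation"] == gen])

    def col_index(self, ids) -> np.ndarray:
        lookup = {i: k for k, i in enumerate(self.individuals.index)}
        return np.array([lookup[i] for i in ids], dtype=int)

    def call_rate_individuals(self) -> np.ndarray:
        return (self.calls != MISSING).mean(axis=0)

    def call_rate_markers(self) -> np.ndarray:
        return (self.calls != MISSING).mean(axis=1)

    def subset(self, keep_ids=None, keep_markers=None) -> "CrossGenotypes":
        """Return a copy restricted to the given individuals and/or markers."""
        ids = self.ids if keep_ids is None else list(keep_ids)
        cols = self.col_index(ids)
        if keep_markers is None:
            mrows = np.arange(self.gmap.n_markers)
            gmap = self.gmap
        else:
            keep = set(keep_markers)
            mask = self.gmap.table["marker"].isin(keep).to_numpy()
            mrows = np.flatnonzero(mask)
            gmap = GeneticMap(self.gmap.table.loc[mask].reset_index(drop=True))
        ped = self.individuals.loc[ids].copy()
        # parent links pointing at removed individuals are blanked
        present = set(ids)
        for col in ("sire", "dam"):
            ped[col] = [p if p in present else "" for p in ped[col]]
        return CrossGenotypes(
            individuals=ped,
            gmap=gmap,
            calls=self.calls[np.ix_(mrows, cols)].copy(),
            alleles=self.alleles[mrows].copy(),
            true_origin=self.true_origin,
        )
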