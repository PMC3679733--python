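"""Genetic maps: ordered markers on linkage groups with cM (and optional bp) positions.

The map is an *input* to every other stage (map construction itself is out of
scope): a table of (group, marker, cM[, bp]) rows, non-decreasing in cM within
each group.  Distances are converted to recombination fractions with the
Haldane map function, which assumes crossovers arrive as a Poisson process
with no interference.
"""

from __future__ import annotations

import decimal
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "GeneticMap",
    "MapSummary",
    "haldane_r",
    "haldane_cm",
    "summarize_map",
]


def haldane_r(cm: np.ndarray | float) -> np.ndarray | float:
    """Recombination fraction for a map distance in centiMorgans.

    r = (1 - exp(-2d)) / 2 with d in Morgans; r -> 0.5 as d -> inf.
    """
    d = np.asarray(cm, dtype=float) / 100.0
    r = 0.5 * (1.0 - np.exp(-2.0 * d))
    return float(r) if np.isscalar(cm) else r


def haldane_cm(r: np.ndarray | float) -> np.ndarray | float:
    """Inverse Haldane map function: cM distance for a recombination fraction."""
    r = np.asarray(r, dtype=float)
    cm = -50.0 * np.log(1.0 - 2.0 * r)
    return float(cm) if cm.ndim == 0 else cm


class MapError(ValueError):
    """Raised for inconsistent or empty genetic maps."""


@dataclass
class GeneticMap:
    """Ordered markers per linkage group.

    Parameters
    ----------
    table:
        DataFrame with columns ``group``, ``marker``, ``cm`` and optionally
        ``bp`` (1-based).  Markers must be unique; cM non-decreasing within
        each group.  Group-local origin is the first marker's position.
    """

    table: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        required = {"group", "marker", "cm"}
        missing = required - set(self.table.columns)
        if missing:
            raise MapError(f"map table lacks columns: {sorted(missing)}")
        if len(self.table) == 0:
            raise MapError("empty genetic map")
        if self.table["marker"].duplicated().any():
            dups = self.table.loc[self.table["marker"].duplicated(), "marker"]
            raise MapError(f"duplicate markers: {sorted(set(dups))[:5]}")
        t = self.table.reset_index(drop=True)
        for g, sub in t.groupby("group", sort=False):
            d = np.diff(sub["cm"].to_numpy(float))
            if (d < 0).any():
                raise MapError(f"cM positions decrease within group {g!r}")
        self.table = t

    # -- basic queries -------------------------------------------------

    @property
    def groups(self) -> list:
        return list(dict.fromkeys(self.table["group"]))

    @property
    def n_markers(self) -> int:
        return len(self.table)

    def markers(self, group) -> pd.DataFrame:
        return self.table[self.table["group"] == group]

    def positions(self, group) -> np.ndarray:
        return self.markers(group)["cm"].to_numpy(float)

    def length(self, group) -> float:
        p = self.positions(group)
        return float(p[-1] - p[0])

    def grid(self, group, step: float = 1.0) -> np.ndarray:
        """Evaluation grid: first marker to last marker inclusive, `step` cM.

        The last marker is always included even when the group length is not
        a multiple of the step.
        """
        p = self.positions(group)
        lo, hi = p[0], p[-1]
        g = lo + step * np.arange(int(np.floor((hi - lo) / step)) + 1)
        if hi - g[-1] > 1e-9:
            g = np.append(g, hi)
        return g

    def nearest_marker(self, group, cm: float) -> str:
        sub = self.markers(group)
        i = int(np.argmin(np.abs(sub["cm"].to_numpy(float) - cm)))
        return str(sub["marker"].iloc[i])

    # -- io ------------------------------------------------------------

    @classmethod
    def read_tsv(cls, path) -> "GeneticMap":
        t = pd.read_csv(path, sep="\t")
        t.columns = [c.lower() for c in t.columns]
        return cls(t)

    def write_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)


def _round_half_up(x: float, ndigits: int = 1) -> float:
    q = decimal.Decimal(10) ** -ndigits
    return float(decimal.Decimal(repr(x)).quantize(q, rounding=decimal.ROUND_HALF_UP))


@dataclass
class MapSummary:
    """Per-group physical size, marker count, cM length and cM/Mb rate.

    ``per_group`` has one row per linkage group; ``totals`` is the summary
    row (sums, with the overall rate computed from the summed columns).
    Rates are rounded half-up to one decimal and left undefined (NaN) for
    groups physically smaller than ``min_mb``.
    """

    per_group: pd.DataFrame
    totals: pd.Series


def summarize_map(
    groups: pd.DataFrame,
    *,
    min_mb: float = 3.0,
) -> MapSummary:
    """Summarise a linkage map from per-group physical and genetic sizes.

    Parameters
    ----------
    groups:
        DataFrame with columns ``group``, ``mb`` (physical size, Mb),
        ``n_markers`` and ``cm`` (sex-average length).
    min_mb:
        Recombination rate is reported as undefined below this physical size;
        tiny groups give unstable cM/Mb ratios.
    """
    required = {"group", "mb", "n_markers", "cm"}
    if not required <= set(groups.columns):
        raise ValueError(f"need columns {sorted(required)}")
    if (groups["mb"].to_numpy(float) < 0).any():
        raise ValueError("negative physical size")
    per = groups.loc[:, ["group", "mb", "n_markers", "cm"]].copy()
    rate = []
    for mb, cm in zip(per["mb"], per["cm"]):
        if mb < min_mb:
            rate.append(np.nan)
        elif mb == 0:
            rate.append(0.0)
        else:
            rate.append(_round_half_up(cm / mb))
    per["rate_cm_per_mb"] = rate
    tot_mb = _round_half_up(float(per["mb"].sum()))
    tot_cm = _round_half_up(float(per["cm"].sum()))
    totals = pd.Series(
        {
            "group": "total",
            "mb": tot_mb,
            "n_markers": int(per["n_markers"].sum()),
            "cm": tot_cm,
            "rate_cm_per_mb": _round_half_up(tot_cm / tot_mb) if tot_mb > 0 else 0.0,
        }
    )
    return MapSummary(per_group=per, totals=totals)
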