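"""Bundled reference data for the chicken HB x HQLA intercross.

Small published summaries of the cross this package was built around: the
per-chromosome linkage-map summary (29 autosomal linkage groups from the
60K SNP chip map), the significant epistatic QTL pairs, the growth-pathway
candidate genes found in the epistatic regions, and the descriptive trait
statistics of the ~493 phenotyped F2 birds.  These serve as inputs for the
examples and for arithmetic checks; the full genotype/phenotype records are
not redistributable here.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = [
    "linkage_map_summary",
    "chrom_sizes_bp",
    "epistatic_pairs",
    "candidate_genes",
    "trait_statistics",
    "study_trait_model",
]

# chromosome, physical size (Mb), SNPs on the map, sex-average length (cM)
_MAP_ROWS = [
    ("GGA1", 201, 6800, 491.2), ("GGA2", 155, 5073, 318.8),
    ("GGA3", 114, 3924, 269.3), ("GGA4", 94, 3143, 183.0),
    ("GGA5", 62, 2112, 170.1), ("GGA6", 37, 1595, 98.8),
    ("GGA7", 38, 1627, 103.9), ("GGA8", 31, 1330, 107.4),
    ("GGA9", 26, 1115, 90.2), ("GGA10", 22.6, 1247, 77.0),
    ("GGA11", 21.9, 1172, 77.2), ("GGA12", 20.5, 1252, 94.1),
    ("GGA13", 18.9, 1090, 76.8), ("GGA14", 15.8, 968, 67.1),
    ("GGA15", 13, 993, 65.9), ("GGA16", 0.43, 13, 0.8),
    ("GGA17", 11.2, 830, 66.8), ("GGA18", 10.9, 826, 65.0),
    ("GGA19", 9.9, 779, 62.8), ("GGA20", 14, 1346, 75.2),
    ("GGA21", 7, 730, 54.2), ("GGA22", 3.9, 285, 47.4),
    ("GGA23", 6, 562, 60.2), ("GGA24", 6.4, 659, 60.6),
    ("GGA25", 2.03, 164, 61.8), ("GGA26", 5.1, 601, 57.5),
    ("GGA27", 4.8, 436, 57.8), ("GGA28", 4.5, 503, 55.5),
    ("LGE22", 0.9, 103, 52.0),
]


def linkage_map_summary() -> pd.DataFrame:
    """Per-linkage-group physical size, marker count and genetic length."""
    return pd.DataFrame(_MAP_ROWS, columns=["group", "mb", "n_markers", "cm"])


def chrom_sizes_bp(autosomes_only: bool = True) -> dict:
    """Chromosome sizes in bp (physical Mb x 1e6), GGA1-GGA28 by default."""
    out = {}
    for g, mb, _n, _cm in _MAP_ROWS:
        if autosomes_only and not g.startswith("GGA"):
            continue
        out[int(g[3:]) if g.startswith("GGA") else g] = int(round(mb * 1e6))
    return out


def epistatic_pairs() -> pd.DataFrame:
    """Significant epistatic QTL pairs from the two-dimensional scan of the
    cross (chromosome + cM per locus, pair F, residual variance %)."""
    rows = [
        ("BW6", 4, 55, 7, 100, 9.8, 6.8),
        ("GR4_8", 6, 40, 25, 60, 9.5, 6.5),
        ("GR4_8", 1, 300, 5, 120, 8.8, 6.1),  # suggestive (F > 8)
        ("FCR6_8", 3, 215, 26, 40, 11.1, 8.1),
        ("FCR8_10", 20, 10, 22, 40, 9.4, 6.4),
    ]
    return pd.DataFrame(
        rows, columns=["trait", "chrom1", "cm1", "chrom2", "cm2", "f", "var_pct"]
    )


def candidate_genes() -> pd.DataFrame:
    """Growth-pathway candidate genes inside the epistatic QTL regions
    (bp coordinates, 1-based inclusive; UMP = ubiquitin-mediated
    proteolysis, ER = ErbB signalling)."""
    rows = [
        ("UBE2A", 4, 16506437, 16512992, "UMP"),
        ("MARCH7", 7, 36187561, 36207776, "UMP"),
        ("HERC4", 6, 10024961, 10054292, "UMP"),
        ("ZBTB1", 5, 52791938, 52805593, "UMP"),
        ("MID1", 1, 124042084, 124134384, "UMP"),
        ("RNF144A", 3, 94598486, 94657682, "UMP"),
        ("ITCH", 20, 1769346, 1829955, "UMP"),
        ("NRAS", 26, 3847830, 3854232, "ER"),
        ("TGFA", 22, 3012283, 3020403, "ER"),
    ]
    return pd.DataFrame(rows, columns=["gene", "chrom", "start", "end", "pathway"])


def trait_statistics() -> pd.DataFrame:
    """Descriptive statistics of the phenotyped F2 birds (records, mean, SD,
    min, max); weights in g, SC in cm, SL in mm, FCR dimensionless."""
    rows = [
        ("BW2", 493, 167.2, 21.6, 115.0, 251.0),
        ("BW4", 491, 443.5, 74.2, 273.0, 708.5),
        ("BW6", 492, 803.1, 131.6, 439.0, 1290.5),
        ("BW8", 492, 1240.1, 208.5, 475.5, 2005.5),
        ("BW10", 493, 1662.0, 287.2, 727.5, 2719.5),
        ("BW12", 492, 2032.2, 352.4, 1042.0, 3250.0),
        ("GR0_4", 490, 415.9, 73.5, 246.4, 676.8),
        ("GR4_8", 490, 798.3, 154.5, 110.5, 1297.0),
        ("GR8_12", 491, 792.5, 177.7, 20.5, 1277.5),
        ("SC4", 493, 2.9, 0.25, 2.2, 3.5),
        ("SC6", 493, 3.4, 0.27, 2.7, 4.1),
        ("SC8", 493, 3.8, 0.31, 2.9, 4.5),
        ("SC10", 493, 4.0, 0.32, 3.3, 4.7),
        ("SC12", 493, 4.2, 0.36, 3.1, 5.0),
        ("SL4", 493, 54.9, 3.9, 43.0, 63.5),
        ("SL6", 493, 68.2, 4.7, 55.5, 80.7),
        ("SL8", 493, 80.4, 6.2, 61.6, 97.2),
        ("SL10", 493, 89.3, 8.2, 68.1, 106.4),
        ("SL12", 493, 92.8, 10.2, 73.5, 114.3),
        ("SW", 493, 19.1, 3.9, 10.2, 36.3),
        ("AFW", 490, 83.3, 33.7, 2.3, 169.1),
        ("FCR6_8", 490, 2.9, 0.39, 1.9, 7.1),
        ("FCR8_10", 492, 3.5, 0.46, 2.1, 5.6),
        ("FCR10_12", 486, 4.4, 0.76, 2.9, 11.1),
    ]
    return pd.DataFrame(rows, columns=["trait", "n", "mean", "sd", "min", "max"])


def study_trait_model(trait: str = "BW10", qtl: list | None = None, epistasis: list | None = None):
    """A TraitModel whose mean and residual SD match the study trait, with a
    moderate sex effect; QTL/epistasis supplied by the caller."""
    from .simulate import TraitModel

    stats = trait_statistics().set_index("trait")
    if trait not in stats.index:
        raise KeyError(f"unknown trait {trait!r}")
    mean, sd = float(stats.loc[trait, "mean"]), float(stats.loc[trait, "sd"])
    return TraitModel(
        name=trait,
        mean=mean,
        residual_sd=sd,
        sex_effect=0.5 * sd,  # cockerels grow faster; order of half an SD
        batch_effects=tuple(np.linspace(-0.2, 0.2, 6) * sd),
        qtl=list(qtl or []),
        epistasis=list(epistasis or []),
    )
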