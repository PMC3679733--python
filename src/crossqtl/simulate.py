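"""Synthetic F2 line-cross generator.

Emulates the design of the slow x fast-growing chicken intercross that this
package analyses: reciprocal matings of 4 cocks x 12 hens per founder line,
a selected set of F1 parents (8 cocks, 48 hens by default) crossed into ~48
full-sib F2 families, and growth-type quantitative traits controlled by a
known set of additive/dominance QTL, epistatic pairs, fixed effects and
covariates.  Because the true line origin of every F2 gamete is retained on
the evaluation grid, every downstream estimator has a parameter-recovery
test surface.

Recombination follows the Haldane model: crossovers are a Poisson process
along the chromosome with no interference, so gamete origin along a
chromosome is a two-state Markov chain with switching probability equal to
the Haldane recombination fraction of each interval.  Founders are simulated
as unrelated within line and markers are only partially informative (the
founder lines are outbred): each line has its own per-marker allele
frequency, with a configurable fraction of fully diagnostic markers.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import MISSING, CrossGenotypes, TrueOrigin
from .genmap import GeneticMap, MapError, haldane_r

__all__ = [
    "CrossDesign",
    "FounderModel",
    "QTLEffect",
    "EpistasisEffect",
    "TraitModel",
    "DesignError",
    "PositionError",
    "simulate_cross",
    "simulate_phenotypes",
    "simulate_intake",
]


class DesignError(ValueError):
    """Infeasible cross design."""


class PositionError(ValueError):
    """A simulated QTL position does not lie on the map."""


@dataclass
class CrossDesign:
    """Counts and structure of the three-generation cross.

    Defaults mirror the study population: 4 cocks and 12 hens per founder
    line, 56 selected F1 parents (8 cocks + 48 hens), 800 F2 birds hatched
    in 6 batches across 48 full-sib families.
    """

    n_f0_males_per_line: int = 4
    n_f0_females_per_line: int = 12
    n_f1_selected: int = 56
    n_f2: int = 800
    reciprocal: bool = True
    n_batches: int = 6
    missing_rate: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_f0_males_per_line", "n_f0_females_per_line", "n_f1_selected", "n_f2"):
            if getattr(self, name) <= 0:
                raise DesignError(f"{name} must be positive")
        if not 0 <= self.missing_rate < 1:
            raise DesignError("missing_rate must be in [0, 1)")
        n_types = 2 if self.reciprocal else 1
        self.n_f1_sires = n_types * self.n_f0_males_per_line
        self.n_f1_dams = self.n_f1_selected - self.n_f1_sires
        if self.n_f1_dams < self.n_f1_sires:
            raise DesignError("n_f1_selected too small for the number of F1 sires")
        if self.reciprocal and (self.n_f1_sires % 2 or self.n_f1_dams % 2):
            raise DesignError("reciprocal design needs even F1 sire and dam counts")
        self.dams_per_sire = self.n_f1_dams // self.n_f1_sires
        self.n_families = self.n_f1_sires * self.dams_per_sire


@dataclass
class FounderModel:
    """Per-marker allele frequencies (of allele 2) in each founder line.

    Diagnostic markers have frequency 1 in one line and 0 in the other.
    """

    freq_a: np.ndarray
    freq_b: np.ndarray

    def __post_init__(self) -> None:
        self.freq_a = np.asarray(self.freq_a, dtype=float)
        self.freq_b = np.asarray(self.freq_b, dtype=float)
        for f in (self.freq_a, self.freq_b):
            if ((f < 0) | (f > 1)).any():
                raise ValueError("allele frequencies must lie in [0, 1]")
        if self.freq_a.shape != self.freq_b.shape:
            raise ValueError("frequency vectors differ in length")

    @property
    def is_diagnostic(self) -> np.ndarray:
        return np.abs(self.freq_a - self.freq_b) == 1.0

    @classmethod
    def random(
        cls,
        n_markers: int,
        diagnostic_fraction: float = 0.3,
        rng: np.random.Generator | int | None = None,
    ) -> "FounderModel":
        """Divergent outbred lines: a `diagnostic_fraction` of markers are
        fixed for opposite alleles; the rest get line frequencies drawn from
        U(0.55, 1) in line A and U(0, 0.45) in line B (partially informative)."""
        rng = np.random.default_rng(rng)
        fa = rng.uniform(0.55, 1.0, n_markers)
        fb = rng.uniform(0.0, 0.45, n_markers)
        diag = rng.random(n_markers) < diagnostic_fraction
        fa[diag], fb[diag] = 1.0, 0.0
        return cls(freq_a=fa, freq_b=fb)


@dataclass
class QTLEffect:
    group: object
    cm: float
    a: float = 0.0
    d: float = 0.0


@dataclass
class EpistasisEffect:
    locus1: tuple  # (group, cm)
    locus2: tuple
    i_aa: float = 0.0  # additive x additive
    i_ad: float = 0.0  # additive x dominance
    i_da: float = 0.0  # dominance x additive
    i_dd: float = 0.0  # dominance x dominance


@dataclass
class TraitModel:
    """Generative model for one trait: mean + fixed effects + covariates
    + sum of QTL additive/dominance terms + epistatic terms + N(0, sd) noise."""

    name: str = "trait"
    mean: float = 0.0
    residual_sd: float = 1.0
    sex_effect: float = 0.0  # added for males
    batch_effects: tuple = ()  # one offset per batch level, first = reference
    covariate_slopes: dict = field(default_factory=dict)  # covariate name -> slope
    qtl: list = field(default_factory=list)
    epistasis: list = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.residual_sd < 0:
            raise ValueError("residual_sd must be non-negative")


# ----------------------------------------------------------------------
# gamete machinery


def _union_positions(gmap: GeneticMap, group, grid_step: float):
    """Marker positions merged with the evaluation grid; returns
    (union positions, index of each marker within the union)."""
    m = gmap.positions(group)
    g = gmap.grid(group, step=grid_step)
    union = np.union1d(np.round(m, 9), np.round(g, 9))
    marker_idx = np.searchsorted(union, np.round(m, 9))
    return union, marker_idx


def _meiosis(hap0, hap1, orig0, orig1, r, marker_idx, rng):
    """Vectorised meioses for a batch of gametes on one chromosome.

    hap0/hap1: (G, n_markers) parental haplotype alleles per gamete.
    orig0/orig1: (G, n_union) parental haplotype line origins.
    r: (n_union - 1,) Haldane recombination fractions between union positions.
    Returns (gamete alleles (G, n_markers), gamete origins (G, n_union)).
    """
    G, n_union = orig0.shape
    state = np.empty((G, n_union), dtype=np.int8)
    state[:, 0] = rng.integers(0, 2, G)
    if n_union > 1:
        switches = (rng.random((G, n_union - 1)) < r).astype(np.int8)
        state[:, 1:] = (state[:, :1] + np.cumsum(switches, axis=1)) % 2
    origins = np.where(state == 0, orig0, orig1)
    s_m = state[:, marker_idx]
    alleles = np.where(s_m == 0, hap0, hap1)
    return alleles.astype(np.int8), origins.astype(np.int8)


def simulate_cross(
    gmap: GeneticMap,
    design: CrossDesign,
    founders: FounderModel,
    grid_step: float = 1.0,
) -> CrossGenotypes:
    """Simulate F0 -> F1 -> F2 genotypes with true line origins retained.

    Every F2 carries two gametes, each a mosaic of line-A / line-B segments
    produced by the Markov (Haldane) recombination process along each
    chromosome; SNP alleles are inherited through the actual founder
    haplotypes, which are drawn from the line allele frequencies.  True
    origins are recorded at the union of marker and grid positions
    (`grid_step` cM).
    """
    if gmap.n_markers == 0:
        raise MapError("empty genetic map")
    if len(founders.freq_a) != gmap.n_markers:
        raise ValueError("founder model length does not match map")
    rng = np.random.default_rng(design.seed)

    groups = gmap.groups
    chrom = {}  # group -> dict of per-chromosome layout
    for g in groups:
        union, midx = _union_positions(gmap, g, grid_step)
        chrom[g] = {
            "union": union,
            "marker_idx": midx,
            "r": haldane_r(np.diff(union)),
            "rows": np.flatnonzero((gmap.table["group"] == g).to_numpy()),
        }

    # ---- pedigree bookkeeping
    def _ids(prefix, n):
        return [f"{prefix}{k:04d}" for k in range(n)]

    nA_m, nA_f = design.n_f0_males_per_line, design.n_f0_females_per_line
    f0 = []
    for line in ("A", "B"):
        f0 += [(f"F0_{line}M{k}", "M", line) for k in range(nA_m)]
        f0 += [(f"F0_{line}F{k}", "F", line) for k in range(nA_f)]
    f0_ids = [x[0] for x in f0]

    # founder haplotypes: both haplotypes of an F0 are pure-line draws
    n_mark = gmap.n_markers
    f0_haps = {}
    for iid, _sex, line in f0:
        f = founders.freq_a if line == "A" else founders.freq_b
        f0_haps[iid] = (rng.random((2, n_mark)) < f).astype(np.int8)

    # ---- F1: produce the selected parents directly, balanced over F0 matings
    cross_types = ["AxB", "BxA"] if design.reciprocal else ["AxB"]
    per_type_sires = design.n_f1_sires // len(cross_types)
    per_type_dams = design.n_f1_dams // len(cross_types)
    f1_rows = []  # (id, sex, cross_type, f0 sire, f0 dam)
    for ct in cross_types:
        sire_line, dam_line = ct[0], ct[2]
        cocks = [i for i, s, l in f0 if l == sire_line and s == "M"]
        hens = [i for i, s, l in f0 if l == dam_line and s == "F"]
        need = [("M", per_type_sires), ("F", per_type_dams)]
        k = 0
        for sex, n in need:
            for _ in range(n):
                f1_rows.append(
                    (f"F1_{ct}_{sex}{k:03d}", sex, ct, cocks[k % len(cocks)], hens[k % len(hens)])
                )
                k += 1

    f1_ids = [r[0] for r in f1_rows]
    # F1 haplotypes: hap0 from the sire (pure sire-line), hap1 from the dam
    f1_haps = {}
    f1_hap_origin = {}  # per F1: (origin of hap0, origin of hap1) as 0=A,1=B
    for iid, _sex, ct, sire, dam in f1_rows:
        haps = np.empty((2, n_mark), dtype=np.int8)
        for g in groups:
            c = chrom[g]
            for j, parent in enumerate((sire, dam)):
                ph = f0_haps[parent][:, c["rows"]]
                orig = np.zeros((1, len(c["union"])), dtype=np.int8)
                al, _ = _meiosis(ph[:1], ph[1:2], orig, orig, c["r"], c["marker_idx"], rng)
                haps[j, c["rows"]] = al[0]
        f1_haps[iid] = haps
        o0 = 0 if ct[0] == "A" else 1
        f1_hap_origin[iid] = (o0, 1 - o0)

    # ---- F1 matings -> F2 families
    sires = [r for r in f1_rows if r[1] == "M"]
    dams = [r for r in f1_rows if r[1] == "F"]
    matings = []
    if design.reciprocal:
        for ct, oct_ in (("AxB", "BxA"), ("BxA", "AxB")):
            ss = [r for r in sires if r[2] == ct]
            dd = [r for r in dams if r[2] == oct_]
            for si, s in enumerate(ss):
                for d in dd[si * design.dams_per_sire : (si + 1) * design.dams_per_sire]:
                    matings.append((s[0], d[0]))
    else:
        for si, s in enumerate(sires):
            for d in dams[si * design.dams_per_sire : (si + 1) * design.dams_per_sire]:
                matings.append((s[0], d[0]))
    if not matings:
        raise DesignError("no feasible F1 matings under this design")

    # F2 individuals round-robin across families; batches round-robin by hatch
    n_f2 = design.n_f2
    fam_of = [k % len(matings) for k in range(n_f2)]
    f2_ids = _ids("F2_", n_f2)
    f2_sex = np.where(rng.random(n_f2) < 0.5, "M", "F")
    f2_batch = np.array([k % design.n_batches for k in range(n_f2)])

    # ---- F2 meioses, batched per chromosome over all individuals
    calls = np.empty((n_mark, len(f0_ids) + len(f1_ids) + n_f2), dtype=np.int8)
    positions, mat_orig, pat_orig = {}, {}, {}
    sire_arr = np.array([matings[f][0] for f in fam_of])
    dam_arr = np.array([matings[f][1] for f in fam_of])
    f2_haps = np.empty((n_f2, 2, n_mark), dtype=np.int8)
    for g in groups:
        c = chrom[g]
        nu = len(c["union"])
        positions[g] = c["union"]
        for j, parents in enumerate((sire_arr, dam_arr)):
            hap0 = np.stack([f1_haps[p][0, c["rows"]] for p in parents])
            hap1 = np.stack([f1_haps[p][1, c["rows"]] for p in parents])
            o0 = np.array([f1_hap_origin[p][0] for p in parents], dtype=np.int8)
            o1 = np.array([f1_hap_origin[p][1] for p in parents], dtype=np.int8)
            orig0 = np.repeat(o0[:, None], nu, axis=1)
            orig1 = np.repeat(o1[:, None], nu, axis=1)
            al, orig = _meiosis(hap0, hap1, orig0, orig1, c["r"], c["marker_idx"], rng)
            f2_haps[:, j, c["rows"]] = al
            if j == 0:
                pat_orig[g] = orig  # gamete from the sire
            else:
                mat_orig[g] = orig

    # ---- assemble call matrix (allele-2 dosage), inject missingness
    col = 0
    for iid in f0_ids:
        calls[:, col] = f0_haps[iid].sum(axis=0)
        col += 1
    for iid in f1_ids:
        calls[:, col] = f1_haps[iid].sum(axis=0)
        col += 1
    calls[:, col:] = f2_haps.sum(axis=1).T
    if design.missing_rate > 0:
        calls[rng.random(calls.shape) < design.missing_rate] = MISSING

    ped = pd.DataFrame(
        index=pd.Index(f0_ids + f1_ids + f2_ids, name="id"),
        data={
            "generation": ["F0"] * len(f0_ids) + ["F1"] * len(f1_ids) + ["F2"] * n_f2,
            "line": [x[2] for x in f0] + [""] * (len(f1_ids) + n_f2),
            "sire": [""] * len(f0_ids) + [r[3] for r in f1_rows] + list(sire_arr),
            "dam": [""] * len(f0_ids) + [r[4] for r in f1_rows] + list(dam_arr),
            "sex": [x[1] for x in f0] + [r[1] for r in f1_rows] + list(f2_sex),
            "cross_type": [""] * len(f0_ids) + [r[2] for r in f1_rows] + [""] * n_f2,
            "family": [""] * (len(f0_ids) + len(f1_ids)) + [f"fam{f:03d}" for f in fam_of],
            "batch": [-1] * (len(f0_ids) + len(f1_ids)) + list(f2_batch),
        },
    )
    origin = TrueOrigin(f2_ids=f2_ids, positions=positions, maternal=mat_orig, paternal=pat_orig)
    return CrossGenotypes(individuals=ped, gmap=gmap, calls=calls, true_origin=origin)


# ----------------------------------------------------------------------
# phenotypes


def _origin_index(origin: TrueOrigin, group, cm: float) -> int:
    if group not in origin.positions:
        raise PositionError(f"linkage group {group!r} not on the map")
    pos = origin.positions[group]
    i = int(np.argmin(np.abs(pos - cm)))
    if abs(pos[i] - cm) > 1e-6:
        raise PositionError(f"position {cm} cM not on the origin grid of group {group!r}")
    return i


def true_indicators(origin: TrueOrigin, group, cm: float):
    """(A, D) indicator vectors implied by the true origin at one position."""
    i = _origin_index(origin, group, cm)
    cls = origin.genotype_class(group)[:, i].astype(float)
    return 1.0 - cls, (cls == 1.0).astype(float)


def simulate_phenotypes(
    genos: CrossGenotypes,
    traits: list[TraitModel] | TraitModel,
    seed: int | None = None,
    covariates: pd.DataFrame | None = None,
    dropout: float = 0.0,
) -> pd.DataFrame:
    """Simulate trait values for all F2s from their *true* line origins.

    Returns a phenotype table with one row per F2 (id, sex, batch, family,
    covariates, one column per trait).  Covariates not supplied are drawn
    standard-normal.  `dropout` sets each trait value missing independently
    with that probability (phenotype attrition is modelled as random
    dropout).
    """
    if genos.true_origin is None:
        raise ValueError("genotypes carry no true origin (not simulator output)")
    if isinstance(traits, TraitModel):
        traits = [traits]
    rng = np.random.default_rng(seed)
    origin = genos.true_origin
    f2 = genos.individuals[genos.individuals["generation"] == "F2"].loc[origin.f2_ids]
    n = len(f2)

    cov_names = sorted({c for t in traits for c in t.covariate_slopes})
    if covariates is None:
        covariates = pd.DataFrame(
            {c: rng.standard_normal(n) for c in cov_names}, index=f2.index
        )
    table = pd.DataFrame(
        {
            "sex": f2["sex"].to_numpy(),
            "batch": f2["batch"].to_numpy(),
            "family": f2["family"].to_numpy(),
        },
        index=f2.index,
    )
    for c in cov_names:
        table[c] = covariates[c].to_numpy()

    male = (f2["sex"] == "M").to_numpy(float)
    batch = f2["batch"].to_numpy(int)
    for t in traits:
        y = np.full(n, t.mean, dtype=float)
        y += t.sex_effect * male
        if len(t.batch_effects):
            eff = np.asarray(t.batch_effects, dtype=float)
            y += eff[batch % len(eff)]
        for c, slope in t.covariate_slopes.items():
            y += slope * table[c].to_numpy(float)
        for q in t.qtl:
            A, D = true_indicators(origin, q.group, q.cm)
            y += q.a * A + q.d * D
        for e in t.epistasis:
            A1, D1 = true_indicators(origin, *e.locus1)
            A2, D2 = true_indicators(origin, *e.locus2)
            y += e.i_aa * A1 * A2 + e.i_ad * A1 * D2 + e.i_da * D1 * A2 + e.i_dd * D1 * D2
        y += t.residual_sd * rng.standard_normal(n)
        if dropout > 0:
            y[rng.random(n) < dropout] = np.nan
        table[t.name] = y
    return table


def simulate_intake(gain: np.ndarray, fcr_true: float, noise_sd: float, rng) -> np.ndarray:
    """Feed intake for a growth window: gain x (true FCR + noise).

    Intake recording granularity is unknown for the real birds, so intake is
    generated directly from the gain it must explain.
    """
    gain = np.asarray(gain, dtype=float)
    rng = np.random.default_rng(rng)
    return gain * (fcr_true + noise_sd * rng.standard_normal(gain.shape))
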