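"""File formats and genotype quality control.

Formats
-------
* genotype matrix: tab-delimited, rows = markers, columns = individuals,
  first column the marker name, header row the individual ids; cells are
  two-character allele calls (e.g. ``AB``) with a configurable missing code
  (default ``--``).
* map: TSV with columns group, marker, cm[, bp]; bp are 1-based.
* pedigree: TSV with columns id, sire, dam, generation, line, sex
  (plus optional cross_type, family, batch).
* phenotypes: plain CSV, one row per individual.

QC applies the standard line-cross chip filters: individual call rate,
marker call frequency, minor allele frequency, and parent-offspring
inheritance-error rate, with individuals filtered before markers.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import MISSING, CrossGenotypes
from .genmap import GeneticMap

__all__ = [
    "FormatError",
    "ReconciliationError",
    "QCReport",
    "read_genotypes",
    "write_genotypes",
    "read_pedigree",
    "write_pedigree",
    "apply_qc",
    "inheritance_errors",
]


class FormatError(ValueError):
    """Malformed input file."""


class ReconciliationError(ValueError):
    """Markers in the genotype file that the map does not know."""


# ----------------------------------------------------------------------
# genotype matrix dialect


def write_genotypes(genos: CrossGenotypes, path, missing_code: str = "--") -> None:
    ids = genos.ids
    with open(path, "w") as fh:
        fh.write("marker\t" + "\t".join(map(str, ids)) + "\n")
        for r, marker in enumerate(genos.gmap.table["marker"]):
            a1, a2 = genos.alleles[r]
            code = {0: a1 + a1, 1: a1 + a2, 2: a2 + a2, MISSING: missing_code}
            row = genos.calls[r]
            fh.write(str(marker) + "\t" + "\t".join(code[int(c)] for c in row) + "\n")


def read_genotypes(
    path,
    gmap: GeneticMap,
    pedigree: pd.DataFrame,
    missing_code: str = "--",
) -> CrossGenotypes:
    """Parse a genotype matrix against a map and pedigree.

    Calls are coded per marker as the dosage of the lexicographically larger
    allele; unknown tokens become missing (the count is recorded on the
    returned object as ``n_unknown_tokens``).
    """
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if len(header) < 2:
            raise FormatError("genotype file has no individual columns")
        ids = header[1:]
        width = len(header)
        rows, names = [], []
        for lineno, line in enumerate(fh, start=2):
            parts = line.rstrip("\n").split("\t")
            if len(parts) != width:
                raise FormatError(f"ragged row at line {lineno}: {len(parts)} != {width} fields")
            names.append(parts[0])
            rows.append(parts[1:])

    known = set(gmap.table["marker"].astype(str))
    unknown = [m for m in names if m not in known]
    if unknown:
        raise ReconciliationError(f"markers absent from the map: {unknown[:10]}")

    order = {str(m): i for i, m in enumerate(gmap.table["marker"])}
    calls = np.full((gmap.n_markers, len(ids)), MISSING, dtype=np.int8)
    alleles = np.full((gmap.n_markers, 2), "?", dtype="<U1")
    n_unknown = 0
    for name, row in zip(names, rows):
        r = order[name]
        chars = sorted({c for tok in row if tok != missing_code for c in tok if len(tok) == 2})
        if len(chars) > 2:
            raise FormatError(f"marker {name}: more than two alleles {chars}")
        a1 = chars[0] if chars else "?"
        a2 = chars[1] if len(chars) > 1 else "?"
        alleles[r] = (a1, a2)
        code = {missing_code: MISSING, a1 + a1: 0, a1 + a2: 1, a2 + a1: 1, a2 + a2: 2}
        for j, tok in enumerate(row):
            v = code.get(tok)
            if v is None:
                n_unknown += 1
                v = MISSING
            calls[r, j] = v

    ped = pedigree.loc[ids]
    out = CrossGenotypes(individuals=ped, gmap=gmap, calls=calls, alleles=alleles)
    out.n_unknown_tokens = n_unknown
    return out


# ----------------------------------------------------------------------
# pedigree / phenotypes


def write_pedigree(individuals: pd.DataFrame, path) -> None:
    individuals.to_csv(path, sep="\t", index=True, index_label="id")


def read_pedigree(path) -> pd.DataFrame:
    ped = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False).set_index("id")
    if "batch" in ped.columns:
        ped["batch"] = pd.to_numeric(ped["batch"], errors="coerce").fillna(-1).astype(int)
    return ped


# ----------------------------------------------------------------------
# inheritance errors

# child dosage possible given (sire, dam) dosages; -1 rows/cols = parent missing
_ALLELES_FROM = {0: (0,), 1: (0, 1), 2: (1,)}


def _trio_table() -> np.ndarray:
    # index [gs+1, gd+1, gc+1]; missing (-1 -> 0) parent acts as a wildcard
    ok = np.zeros((4, 4, 4), dtype=bool)
    ok[:, :, 0] = True  # missing child: never an error (not compared either)
    for gs, gd in itertools.product((-1, 0, 1, 2), repeat=2):
        s_opts = (0, 1) if gs == -1 else _ALLELES_FROM[gs]
        d_opts = (0, 1) if gd == -1 else _ALLELES_FROM[gd]
        for a in s_opts:
            for b in d_opts:
                ok[gs + 1, gd + 1, a + b + 1] = True
    return ok


_TRIO_OK = _trio_table()


def inheritance_errors(genos: CrossGenotypes):
    """Parent-offspring genotype incompatibilities at biallelic loci.

    A comparison is made at every marker where the child is called and at
    least one parent is called; a Mendelian impossibility (e.g. both parents
    homozygous-ref, child carrying the alt allele) counts as one error,
    attributed to both the child and the marker.  Returns
    (errors per individual, comparisons per individual,
     errors per marker, comparisons per marker) as aligned arrays.
    """
    ped = genos.individuals
    ids = list(ped.index)
    col = {i: k for k, i in enumerate(ids)}
    n_ind, n_mark = len(ids), genos.gmap.n_markers
    err_i = np.zeros(n_ind)
    cmp_i = np.zeros(n_ind)
    err_m = np.zeros(n_mark)
    cmp_m = np.zeros(n_mark)

    child_rows = ped[(ped["sire"] != "") | (ped["dam"] != "")]
    if len(child_rows) == 0:
        return err_i, cmp_i, err_m, cmp_m
    cc = np.array([col[i] for i in child_rows.index])
    miss_col = np.full(n_mark, MISSING, dtype=np.int8)
    gs = np.stack(
        [genos.calls[:, col[s]] if s in col else miss_col for s in child_rows["sire"]], axis=1
    )
    gd = np.stack(
        [genos.calls[:, col[d]] if d in col else miss_col for d in child_rows["dam"]], axis=1
    )
    gc = genos.calls[:, cc]
    compared = (gc != MISSING) & ((gs != MISSING) | (gd != MISSING))
    bad = ~_TRIO_OK[gs + 1, gd + 1, gc + 1] & compared
    err_i[cc] = bad.sum(axis=0)
    cmp_i[cc] = compared.sum(axis=0)
    err_m = bad.sum(axis=1).astype(float)
    cmp_m = compared.sum(axis=1).astype(float)
    return err_i, cmp_i, err_m, cmp_m


# ----------------------------------------------------------------------
# quality control


@dataclass
class QCReport:
    """Audit trail of a QC pass.

    ``excluded_individuals`` / ``excluded_markers`` carry one primary reason
    each (the first failing criterion in the documented order);
    ``criterion_counts`` gives how many records failed each criterion,
    counted independently (a record can fail several).
    """

    excluded_individuals: pd.DataFrame
    excluded_markers: pd.DataFrame
    criterion_counts: dict = field(default_factory=dict)
    thresholds: dict = field(default_factory=dict)

    @property
    def n_excluded_individuals(self) -> int:
        return len(self.excluded_individuals)

    @property
    def n_excluded_markers(self) -> int:
        return len(self.excluded_markers)

    def to_log(self) -> str:
        lines = [
            "QC report",
            f"  thresholds: {self.thresholds}",
            f"  excluded individuals: {self.n_excluded_individuals}",
            f"  excluded markers: {self.n_excluded_markers}",
            "  per-criterion failure counts (overlapping):",
        ]
        for k, v in self.criterion_counts.items():
            lines.append(f"    {k}: {v}")
        return "\n".join(lines)

    def write(self, ind_path, marker_path) -> None:
        self.excluded_individuals.to_csv(ind_path, index=False)
        self.excluded_markers.to_csv(marker_path, index=False)


def apply_qc(
    genos: CrossGenotypes,
    min_ind_call_rate: float = 0.9,
    min_marker_call_freq: float = 0.9,
    min_maf: float = 0.05,
    max_inherit_err: float = 0.05,
    maf_generation: str = "F2",
) -> tuple[CrossGenotypes, QCReport]:
    """Filter individuals then markers by the chip QC criteria.

    Keep rules are strict, matching the stated criteria: individual call
    rate > `min_ind_call_rate`, marker call frequency > `min_marker_call_freq`,
    MAF > `min_maf` (computed among retained individuals of
    `maf_generation`; founder lines are divergent by design so pooled MAF
    would mislead), and inheritance-error rate < `max_inherit_err` for both
    individuals and markers.  Error-rate denominators are non-missing
    parent-offspring comparisons.
    """
    for name, v in {
        "min_ind_call_rate": min_ind_call_rate,
        "min_marker_call_freq": min_marker_call_freq,
        "min_maf": min_maf,
        "max_inherit_err": max_inherit_err,
    }.items():
        if not 0 <= v <= 1:
            raise ValueError(f"{name} must lie in [0, 1]")

    ids = np.array(genos.ids)
    # -- stage 1: individuals
    call_rate = genos.call_rate_individuals()
    err_i, cmp_i, _, _ = inheritance_errors(genos)
    with np.errstate(invalid="ignore"):
        rate_i = np.where(cmp_i > 0, err_i / np.maximum(cmp_i, 1), 0.0)
    fail_cr = ~(call_rate > min_ind_call_rate)
    fail_ie_i = ~(rate_i < max_inherit_err)
    drop_ind = fail_cr | fail_ie_i
    reasons_i = np.where(fail_cr, "call_rate", "inherit_error")
    excl_ind = pd.DataFrame(
        {"id": ids[drop_ind], "reason": reasons_i[drop_ind],
         "call_rate": call_rate[drop_ind], "inherit_error_rate": rate_i[drop_ind]}
    )
    kept = genos.subset(keep_ids=list(ids[~drop_ind]))

    # -- stage 2: markers, statistics over retained individuals only
    call_freq = kept.call_rate_markers()
    gen = kept.individuals["generation"].to_numpy()
    maf_cols = np.flatnonzero(gen == maf_generation)
    if maf_cols.size == 0:
        maf_cols = np.arange(len(kept.ids))
    sub = kept.calls[:, maf_cols]
    called = sub != MISSING
    n_alleles = 2 * called.sum(axis=1)
    count2 = np.where(called, sub, 0).sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        f2 = np.where(n_alleles > 0, count2 / np.maximum(n_alleles, 1), 0.0)
    maf = np.minimum(f2, 1 - f2)
    _, _, err_m, cmp_m = inheritance_errors(kept)
    rate_m = np.where(cmp_m > 0, err_m / np.maximum(cmp_m, 1), 0.0)
    fail_cf = ~(call_freq > min_marker_call_freq)
    fail_maf = ~(maf > min_maf)
    fail_ie_m = ~(rate_m < max_inherit_err)
    drop_m = fail_cf | fail_maf | fail_ie_m
    reasons_m = np.select(
        [fail_cf, fail_maf], ["call_freq", "maf"], default="inherit_error"
    )
    markers = kept.gmap.table["marker"].to_numpy()
    excl_mark = pd.DataFrame(
        {"marker": markers[drop_m], "reason": reasons_m[drop_m],
         "call_freq": call_freq[drop_m], "maf": maf[drop_m],
         "inherit_error_rate": rate_m[drop_m]}
    )
    out = kept.subset(keep_markers=list(markers[~drop_m]))

    report = QCReport(
        excluded_individuals=excl_ind,
        excluded_markers=excl_mark,
        criterion_counts={
            "individual_call_rate": int(fail_cr.sum()),
            "individual_inherit_error": int(fail_ie_i.sum()),
            "marker_call_freq": int(fail_cf.sum()),
            "marker_maf": int(fail_maf.sum()),
            "marker_inherit_error": int(fail_ie_m.sum()),
        },
        thresholds={
            "min_ind_call_rate": min_ind_call_rate,
            "min_marker_call_freq": min_marker_call_freq,
            "min_maf": min_maf,
            "max_inherit_err": max_inherit_err,
        },
    )
    return out, report
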