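"""Reproducible simulation studies at reduced desk scale.

The real cross's phenotype records were never deposited, so the pipeline's
statistical behaviour is validated on synthetic crosses with known truth.
The functions here define the study conditions used by the test suite and
by ``scripts/acceptance.py``: a 5-chromosome x 100 cM map with markers
every 2 cM, n = 500 phenotyped F2s, a single QTL explaining ~15% of the
phenotypic variance for recovery studies, an additive-by-additive pair
contributing ~6% for epistasis studies, and reduced permutation counts
(200 for 1D calibration, 100 for the 2D threshold).  Problem sizes are
chosen so each study finishes in minutes on one core while keeping the
Monte-Carlo error of the reported rates small relative to the properties
being checked.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .genmap import GeneticMap, haldane_r
from .origin import compute_line_origin, estimate_line_frequencies
from .pheno import select_null_model
from .perm import permutation_threshold
from .scan1d import max_f_many, scan_genome, variance_for_calls
from .scan2d import decompose_epistasis, scan_pairs
from .simulate import (
    CrossDesign,
    EpistasisEffect,
    FounderModel,
    QTLEffect,
    TraitModel,
    simulate_cross,
    simulate_phenotypes,
)

__all__ = [
    "reduced_map",
    "simulate_study_cross",
    "haldane_calibration",
    "single_qtl_recovery",
    "threshold_calibration",
    "epistasis_recovery",
]


def reduced_map(n_groups: int = 5, length_cm: float = 100.0, marker_step: float = 2.0) -> GeneticMap:
    """Evenly spaced marker map for simulation studies."""
    rows = []
    for g in range(1, n_groups + 1):
        for k, cm in enumerate(np.arange(0.0, length_cm + 1e-9, marker_step)):
            rows.append((g, f"snp{g}_{k:03d}", float(cm)))
    return GeneticMap(pd.DataFrame(rows, columns=["group", "marker", "cm"]))


def simulate_study_cross(
    gmap: GeneticMap,
    n_f2: int = 500,
    seed: int = 0,
    grid_step: float = 1.0,
    diagnostic_fraction: float = 0.3,
    missing_rate: float = 0.02,
):
    """One cross under the study design, with its line-origin grid.

    Returns (genotypes, origin grid).  The F1 structure follows the real
    design (8 F1 cocks x 6 hens each); only the F2 count is scaled.
    """
    design = CrossDesign(n_f2=n_f2, missing_rate=missing_rate, seed=seed)
    founders = FounderModel.random(gmap.n_markers, diagnostic_fraction, rng=seed + 1)
    genos = simulate_cross(gmap, design, founders, grid_step=grid_step)
    freqs = estimate_line_frequencies(genos)
    grid = compute_line_origin(genos, freqs, grid_step=grid_step)
    return genos, grid


def haldane_calibration(distance_cm: float = 10.0, n_meioses: int = 10_000, seed: int = 0) -> dict:
    """Observed recombinant fraction between two markers vs the Haldane
    closed form, and mean crossovers per Morgan of map."""
    gmap = GeneticMap(
        pd.DataFrame(
            {"group": [1, 1], "marker": ["mL", "mR"], "cm": [0.0, distance_cm]}
        )
    )
    n_f2 = (n_meioses + 1) // 2
    design = CrossDesign(n_f2=n_f2, missing_rate=0.0, seed=seed)
    founders = FounderModel(freq_a=np.ones(2), freq_b=np.zeros(2))
    genos = simulate_cross(gmap, design, founders, grid_step=distance_cm)
    to = genos.true_origin
    rec = 0
    tot = 0
    for arr in (to.maternal[1], to.paternal[1]):
        rec += int((arr[:, 0] != arr[:, -1]).sum())
        tot += arr.shape[0]
    return {
        "observed_fraction": rec / tot,
        "expected_fraction": float(haldane_r(distance_cm)),
        "n_meioses": tot,
    }


def _qtl_effect_for_share(share: float, residual_sd: float = 1.0) -> float:
    # additive indicator has variance 1/2 in an F2, so share = a^2/2 / (a^2/2 + sd^2)
    return float(np.sqrt(2 * share / (1 - share)) * residual_sd)


def single_qtl_recovery(
    n_reps: int = 100,
    n_f2: int = 500,
    share: float = 0.15,
    qtl_group: int = 3,
    qtl_cm: float = 50.0,
    seed: int = 0,
) -> dict:
    """Localisation and effect recovery for a lone additive QTL.

    Each replicate simulates a fresh cross and trait, scans the genome and
    records whether the peak lies within 10 cM of the truth, whether the
    estimated additive effect covers the truth within 2 SE, and the
    estimated Var%.
    """
    gmap = reduced_map()
    a_true = _qtl_effect_for_share(share)
    ss = np.random.SeedSequence(seed)
    hits, covered, var_pct, dist = [], [], [], []
    for child in ss.spawn(n_reps):
        s = int(child.generate_state(1)[0] % (2**31))
        genos, grid = simulate_study_cross(gmap, n_f2=n_f2, seed=s)
        tm = TraitModel(name="y", residual_sd=1.0, qtl=[QTLEffect(qtl_group, qtl_cm, a=a_true)])
        ph = simulate_phenotypes(genos, tm, seed=s + 1)
        spec = select_null_model(ph, "y", factors=(), covariates=())
        res = scan_genome(spec, grid)
        pk = res.peak
        d = abs(pk.cm - qtl_cm) if pk.group == qtl_group else np.inf
        dist.append(d)
        hits.append(d <= 10.0)
        covered.append(abs(pk.a - a_true) <= 2 * pk.se_a)
        var_pct.append(variance_for_calls(spec, grid, [(pk.group, pk.cm)])[0])
    return {
        "n_reps": n_reps,
        "a_true": a_true,
        "share_true_pct": share * 100,
        "localisation_rate": float(np.mean(hits)),
        "coverage_2se": float(np.mean(covered)),
        "mean_var_pct": float(np.mean(var_pct)),
        "median_peak_distance_cm": float(np.median([d for d in dist if np.isfinite(d)])),
    }


def threshold_calibration(
    n_traits: int = 200,
    n_perm: int = 200,
    n_f2: int = 500,
    alpha: float = 0.05,
    seed: int = 0,
) -> dict:
    """Genome-wide type-I error of the permutation threshold.

    One simulated cross; each replicate draws an independent null trait,
    derives its own permutation threshold (shuffling the centred trait) and
    records whether the genome-wide maximum F exceeds it.
    """
    gmap = reduced_map()
    genos, grid = simulate_study_cross(gmap, n_f2=n_f2, seed=seed)
    rng = np.random.default_rng(seed + 1)
    f2_ids = genos.true_origin.f2_ids
    rejections = 0
    for _ in range(n_traits):
        y = rng.standard_normal(len(f2_ids))
        table = pd.DataFrame({"y": y}, index=pd.Index(f2_ids, name="id"))
        spec = select_null_model(table, "y", factors=(), covariates=())
        Y = np.column_stack(
            [spec.y] + [rng.permutation(spec.residuals) for _ in range(n_perm)]
        )
        maxf = max_f_many(spec, grid, Y)
        thr = float(np.quantile(maxf[1:], 1 - alpha))
        rejections += int(maxf[0] > thr)
    return {
        "n_traits": n_traits,
        "n_perm": n_perm,
        "alpha": alpha,
        "rejection_rate": rejections / n_traits,
    }


def epistasis_recovery(
    n_reps: int = 50,
    n_f2: int = 500,
    share: float = 0.06,
    loci: tuple = ((1, 30.0), (4, 60.0)),
    n_perm: int = 100,
    window_cm: float = 30.0,
    seed: int = 0,
) -> dict:
    """Detection of a pure additive-by-additive pair on the reduced map.

    The pair contributes `share` of the phenotypic variance (the indicator
    product A1*A2 has variance 1/4 for unlinked loci).  Genotypes are fixed
    across replicates; phenotypes are redrawn.  The 2D permutation
    threshold is computed once (thresholds are a per-trait property of the
    genotype grid under the null).  A replicate counts as detected when a
    significant pair has both loci within `window_cm` of the truth and the
    additive-by-additive term is the dominant one by |t|.
    """
    gmap = reduced_map()
    genos, grid = simulate_study_cross(gmap, n_f2=n_f2, seed=seed, grid_step=5.0)
    i_aa = float(np.sqrt(4 * share / (1 - share)))
    tm = TraitModel(
        name="y", residual_sd=1.0,
        epistasis=[EpistasisEffect(loci[0], loci[1], i_aa=i_aa)],
    )
    (g1, cm1), (g2, cm2) = loci

    # threshold from the first replicate's null-model residuals
    ph0 = simulate_phenotypes(genos, tm, seed=seed + 1)
    spec0 = select_null_model(ph0, "y", factors=(), covariates=())
    th = permutation_threshold(spec0, grid, scan="2d", n_perm=n_perm, seed=seed + 2)
    thr = th.thresholds[0.05]

    detected, dominant = [], []
    ss = np.random.SeedSequence(seed + 3)
    for child in ss.spawn(n_reps):
        s = int(child.generate_state(1)[0] % (2**31))
        ph = simulate_phenotypes(genos, tm, seed=s)
        spec = select_null_model(ph, "y", factors=(), covariates=())
        res = scan_pairs(spec, grid, threshold=thr)
        hit = None
        for fit in res.significant:
            pairs_match = (
                fit.group1 == g1 and fit.group2 == g2
                and abs(fit.cm1 - cm1) <= window_cm and abs(fit.cm2 - cm2) <= window_cm
            ) or (
                fit.group1 == g2 and fit.group2 == g1
                and abs(fit.cm1 - cm2) <= window_cm and abs(fit.cm2 - cm1) <= window_cm
            )
            if pairs_match:
                hit = fit
                break
        detected.append(hit is not None)
        if hit is not None:
            dec = decompose_epistasis(spec, grid, (hit.group1, hit.cm1), (hit.group2, hit.cm2))
            dominant.append(dec.loc[dec["t"].abs().idxmax(), "term"] == "i_aa")
        else:
            dominant.append(False)
    return {
        "n_reps": n_reps,
        "i_aa_true": i_aa,
        "threshold_5pct": thr,
        "detection_rate": float(np.mean(detected)),
        "detected_with_aa_dominant_rate": float(np.mean(dominant)),
    }
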