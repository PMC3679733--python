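import numpy as np
import pandas as pd
import pytest

import crossqtl as cq


@pytest.fixture(scope="session")
def toy_map() -> cq.GeneticMap:
    """3 linkage groups of 60 cM with markers every 3 cM."""
    rows = []
    for g in range(1, 4):
        for k, cm in enumerate(np.arange(0.0, 61.0, 3.0)):
            rows.append((g, f"m{g}_{k}", float(cm)))
    return cq.GeneticMap(pd.DataFrame(rows, columns=["group", "marker", "cm"]))


@pytest.fixture(scope="session")
def sim_cross(toy_map):
    """One simulated cross (400 F2) shared across tests: genotypes, line
    frequencies and the 1 cM line-origin grid."""
    design = cq.CrossDesign(n_f2=400, seed=11)
    founders = cq.FounderModel.random(toy_map.n_markers, 0.3, rng=12)
    genos = cq.simulate_cross(toy_map, design, founders, grid_step=1.0)
    freqs = cq.estimate_line_frequencies(genos)
    grid = cq.compute_line_origin(genos, freqs, grid_step=1.0)
    return genos, freqs, grid


def make_spec(y: np.ndarray, ids) -> cq.NullModelSpec:
    """Intercept-only null model for a raw response vector."""
    table = pd.DataFrame({"y": y}, index=pd.Index(ids, name="id"))
    return cq.select_null_model(table, "y", factors=(), covariates=())


@pytest.fixture(scope="session")
def qtl_trait(sim_cross):
    """Trait with one additive+dominant QTL at group 2, 30 cM (a=0.6, d=0.2)."""
    genos, _, _ = sim_cross
    tm = cq.TraitModel(
        name="y", mean=5.0, residual_sd=1.0,
        qtl=[cq.QTLEffect(2, 30.0, a=0.6, d=0.2)],
    )
    return cq.simulate_phenotypes(genos, tm, seed=13), tm
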