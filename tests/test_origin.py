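import numpy as np
import pandas as pd
import pytest

import crossqtl as cq
from crossqtl.core import MISSING, DataError
from crossqtl.origin import LineAlleleFrequencies, LineOriginGrid

from oracles import brute_force_posterior


class TestLineFrequencies:
    def test_pseudocount_formula(self, toy_map):
        """10 line-A founders all homozygous-ref: ref frequency
        (20 + 0.5) / 21."""
        n = toy_map.n_markers
        ped = pd.DataFrame(
            index=pd.Index([f"a{i}" for i in range(10)] + [f"b{i}" for i in range(10)]
                           + ["f1s", "f1d", "kid"], name="id"),
            data={
                "generation": ["F0"] * 20 + ["F1", "F1", "F2"],
                "line": ["A"] * 10 + ["B"] * 10 + ["", "", ""],
                "sire": [""] * 20 + ["a0", "a0", "f1s"],
                "dam": [""] * 20 + ["b0", "b0", "f1d"],
                "sex": ["M"] * 10 + ["F"] * 10 + ["M", "F", "M"],
            },
        )
        calls = np.zeros((n, 23), dtype=np.int8)
        calls[:, 10:20] = 2  # line B founders homozygous-alt
        genos = cq.CrossGenotypes(individuals=ped, gmap=toy_map, calls=calls)
        freqs = cq.estimate_line_frequencies(genos)
        assert np.allclose(1 - freqs.freq_a, 20.5 / 21)
        assert np.allclose(freqs.freq_b, 20.5 / 21)

    def test_unscored_marker_gets_half_with_warning(self, toy_map):
        n = toy_map.n_markers
        ped = pd.DataFrame(
            index=pd.Index(["a0", "b0"], name="id"),
            data={"generation": ["F0", "F0"], "line": ["A", "B"],
                  "sire": ["", ""], "dam": ["", ""], "sex": ["M", "F"]},
        )
        calls = np.zeros((n, 2), dtype=np.int8)
        calls[0, 0] = MISSING  # marker 0 unscored in line A
        genos = cq.CrossGenotypes(individuals=ped, gmap=toy_map, calls=calls)
        with pytest.warns(UserWarning, match="no founder calls"):
            freqs = cq.estimate_line_frequencies(genos)
        assert freqs.freq_a[0] == 0.5

    def test_no_founders_for_line_is_an_error(self, toy_map):
        ped = pd.DataFrame(
            index=pd.Index(["a0"], name="id"),
            data={"generation": ["F0"], "line": ["A"], "sire": [""], "dam": [""],
                  "sex": ["M"]},
        )
        genos = cq.CrossGenotypes(
            individuals=ped, gmap=toy_map,
            calls=np.zeros((toy_map.n_markers, 1), dtype=np.int8),
        )
        with pytest.raises(DataError, match="line B"):
            cq.estimate_line_frequencies(genos)

    def test_diagnostic_marker_divergence_recovered(self, sim_cross):
        genos, freqs, _ = sim_cross
        # simulator founders: diagnostic markers have |freqA - freqB| = 1
        # estimated divergence should be near 1 there (pseudocount-shrunk)
        est_gap = np.abs(freqs.freq_a - freqs.freq_b)
        assert est_gap.max() > 0.9


def _one_chrom_cross(calls_by_marker, cms, fa, fb):
    """Minimal cross with one F2 whose calls at the markers are given."""
    gmap = cq.GeneticMap(
        pd.DataFrame({"group": [1] * len(cms), "marker": [f"m{i}" for i in range(len(cms))],
                      "cm": cms})
    )
    ped = pd.DataFrame(
        index=pd.Index(["a0", "b0", "f1s", "f1d", "kid"], name="id"),
        data={
            "generation": ["F0", "F0", "F1", "F1", "F2"],
            "line": ["A", "B", "", "", ""],
            "sire": ["", "", "a0", "a0", "f1s"],
            "dam": ["", "", "b0", "b0", "f1d"],
            "sex": ["M", "F", "M", "F", "M"],
        },
    )
    calls = np.full((len(cms), 5), MISSING, dtype=np.int8)
    calls[:, 4] = calls_by_marker
    genos = cq.CrossGenotypes(individuals=ped, gmap=gmap, calls=calls)
    freqs = LineAlleleFrequencies(freq_a=np.asarray(fa, float), freq_b=np.asarray(fb, float))
    return genos, freqs


class TestForwardBackward:
    def test_diagnostic_homozygote_is_certain(self):
        genos, freqs = _one_chrom_cross([2], [0.0], fa=[1.0], fb=[0.0])
        grid = cq.compute_line_origin(genos, freqs, grid_step=1.0)
        assert np.allclose(grid.probs[0, 0], [1, 0, 0, 0])

    def test_uninformative_chromosome_returns_prior(self):
        genos, freqs = _one_chrom_cross(
            [MISSING, MISSING], [0.0, 10.0], fa=[0.5, 0.5], fb=[0.5, 0.5]
        )
        grid = cq.compute_line_origin(genos, freqs, grid_step=1.0)
        assert np.allclose(grid.probs, 0.25)

    @pytest.mark.parametrize(
        "calls,cms,fa,fb",
        [
            ([1, 2, 0], [0.0, 7.0, 13.0], [0.9, 1.0, 0.7], [0.2, 0.0, 0.4]),
            ([2, MISSING, 1], [0.0, 4.0, 30.0], [0.8, 0.6, 0.95], [0.1, 0.3, 0.05]),
            ([0, 1, 1, 2], [0.0, 5.0, 5.0, 22.0], [0.9, 0.7, 0.8, 1.0], [0.1, 0.2, 0.3, 0.0]),
        ],
    )
    def test_posteriors_equal_exhaustive_enumeration(self, calls, cms, fa, fb):
        """Forward-backward equals brute-force enumeration over all
        gamete-origin configurations, to 1e-10, at markers and pseudo-loci."""
        genos, freqs = _one_chrom_cross(calls, cms, fa, fb)
        grid = cq.compute_line_origin(genos, freqs, grid_step=1.0)
        for j in range(grid.probs.shape[1]):
            q = float(grid.positions["cm"].iloc[j])
            expect = brute_force_posterior(calls, cms, fa, fb, q)
            assert np.allclose(grid.probs[0, j], expect, atol=1e-10)

    def test_probabilities_sum_to_one(self, sim_cross):
        _, _, grid = sim_cross
        assert np.allclose(grid.probs.sum(axis=2), 1.0, atol=1e-9)

    def test_posterior_calibration_by_decile(self, sim_cross):
        """Binned P(AA) matches the empirical fraction of true AA states."""
        genos, _, grid = sim_cross
        to = genos.true_origin
        p_all, t_all = [], []
        for g in (1, 2, 3):
            sl = grid.group_slice(g)
            pos = grid.positions["cm"].iloc[sl].to_numpy()
            tidx = np.searchsorted(np.round(to.positions[g], 9), np.round(pos, 9))
            truth = to.genotype_class(g)[:, tidx] == 0
            p_all.append(grid.probs[:, sl, 0].ravel())
            t_all.append(truth.ravel())
        p = np.concatenate(p_all)
        t = np.concatenate(t_all)
        for lo, hi in [(0.0, 0.1), (0.2, 0.4), (0.6, 0.8), (0.9, 1.01)]:
            mask = (p >= lo) & (p < hi)
            if mask.sum() < 200:
                continue
            expect = p[mask].mean()
            se = np.sqrt(max(expect * (1 - expect), 1e-4) / mask.sum())
            # correlated observations (same gamete over nearby cM): wide band
            assert abs(t[mask].mean() - expect) < max(10 * se, 0.05)

    def test_mean_indicators_match_mendelian_expectation(self, sim_cross):
        _, _, grid = sim_cross
        ind = cq.indicators(grid)
        assert abs(ind.A.mean()) < 0.05
        assert abs(ind.D.mean() - 0.5) < 0.05


class TestIndicators:
    @pytest.mark.parametrize(
        "quad,a,d",
        [((1, 0, 0, 0), 1.0, 0.0), ((0.25, 0.25, 0.25, 0.25), 0.0, 0.5),
         ((0.1, 0.2, 0.3, 0.4), -0.3, 0.5)],
    )
    def test_formulas(self, quad, a, d):
        grid = LineOriginGrid(
            positions=pd.DataFrame({"group": [1], "cm": [0.0]}),
            ids=["x"],
            probs=np.array(quad, float).reshape(1, 1, 4),
        )
        ind = cq.indicators(grid)
        assert ind.A[0, 0] == pytest.approx(a)
        assert ind.D[0, 0] == pytest.approx(d)

    def test_bounds_on_simulated_grid(self, sim_cross):
        _, _, grid = sim_cross
        ind = cq.indicators(grid)
        assert (ind.A >= -1).all() and (ind.A <= 1).all()
        assert (ind.D >= 0).all() and (ind.D <= 1).all()


def test_grid_round_trip(sim_cross, tmp_path):
    _, _, grid = sim_cross
    p = tmp_path / "probs.tsv"
    sub = LineOriginGrid(
        positions=grid.positions, ids=grid.ids[:5], probs=grid.probs[:5], step=grid.step
    )
    sub.write_tsv(p)
    back = LineOriginGrid.read_tsv(p)
    assert back.ids == sub.ids
    assert np.allclose(back.probs, sub.probs, atol=1e-5)
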