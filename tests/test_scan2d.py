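import numpy as np
import pandas as pd
import pytest

import crossqtl as cq
from crossqtl.origin import LineOriginGrid, indicators
from crossqtl.scan2d import admissible_pairs, max_f_pairs_many

from conftest import make_spec


@pytest.fixture(scope="module")
def grid5(sim_cross):
    genos, freqs, _ = sim_cross
    return cq.compute_line_origin(genos, freqs, grid_step=5.0)


@pytest.fixture(scope="module")
def epi_trait(sim_cross):
    genos, _, _ = sim_cross
    i_aa = np.sqrt(4 * 0.08 / 0.92)
    tm = cq.TraitModel(
        name="y", residual_sd=1.0,
        epistasis=[cq.EpistasisEffect((1, 30.0), (3, 45.0), i_aa=i_aa)],
    )
    ph = cq.simulate_phenotypes(genos, tm, seed=41)
    return ph, i_aa


class TestInteractionIndicators:
    @pytest.mark.parametrize(
        "a1,d1,a2,d2,expect",
        [
            (1.0, 0.0, -1.0, 0.0, (-1.0, 0.0, 0.0, 0.0)),
            (0.0, 0.5, 0.0, 0.5, (0.0, 0.0, 0.0, 0.25)),
            (0.6, 0.4, -0.5, 0.9, (-0.30, 0.54, -0.20, 0.36)),
        ],
    )
    def test_products(self, a1, d1, a2, d2, expect):
        out = cq.interaction_indicators([a1], [d1], [a2], [d2])
        got = (out.i_aa[0], out.i_ad[0], out.i_da[0], out.i_dd[0])
        assert got == pytest.approx(expect)


class TestScanPairs:
    def test_same_position_excluded_and_min_separation(self, grid5):
        pairs = admissible_pairs(grid5, min_sep_steps=2)
        groups = grid5.positions["group"].to_numpy()
        cms = grid5.positions["cm"].to_numpy()
        same = groups[pairs[:, 0]] == groups[pairs[:, 1]]
        gaps = np.abs(cms[pairs[:, 0]] - cms[pairs[:, 1]])
        assert (gaps[same] >= 2 * grid5.step - 1e-9).all()
        assert (gaps > 0).all() | ~same.all()

    def test_nesting_rss4_le_rss3(self, grid5, epi_trait):
        ph, _ = epi_trait
        spec = make_spec(ph["y"].to_numpy(), list(ph.index))
        res = cq.scan_pairs(spec, grid5, threshold=6.0)
        for fit in res.significant + res.suggestive:
            assert fit.rss_full <= fit.rss_marginal + 1e-9

    def test_f_invariant_under_locus_swap(self, grid5, epi_trait):
        ph, _ = epi_trait
        spec = make_spec(ph["y"].to_numpy(), list(ph.index))
        rows = np.arange(len(spec.ids))
        ind = indicators(grid5)
        j1, j2 = grid5.column(1, 30.0), grid5.column(3, 45.0)

        def pair_f(ja, jb):
            sub_pos = grid5.positions.iloc[[ja, jb]].reset_index(drop=True)
            sub = LineOriginGrid(
                positions=sub_pos, ids=grid5.ids,
                probs=grid5.probs[:, [ja, jb], :], step=grid5.step,
            )
            return cq.scan_pairs(spec, sub).pairs["f"].iloc[0]

        assert pair_f(j1, j2) == pytest.approx(pair_f(j2, j1), abs=1e-8)

    def test_pure_aa_pair_detected_with_aa_dominant(self, grid5, epi_trait):
        ph, _ = epi_trait
        spec = make_spec(ph["y"].to_numpy(), list(ph.index))
        res = cq.scan_pairs(spec, grid5, threshold=None, suggestive_f=8.0)
        top = res.pairs.sort_values("f", ascending=False).iloc[0]
        assert {top["group1"], top["group2"]} == {1, 3}
        dec = cq.decompose_epistasis(
            spec, grid5, (top["group1"], top["cm1"]), (top["group2"], top["cm2"])
        )
        assert dec.loc[dec["t"].abs().idxmax(), "term"] == "i_aa"

    def test_marginal_only_trait_has_interactions_near_zero(self, sim_cross, grid5):
        """With purely additive genetics, interaction estimates centre on 0."""
        genos, _, _ = sim_cross
        tm = cq.TraitModel(name="y", residual_sd=1.0, qtl=[cq.QTLEffect(2, 30.0, a=0.6)])
        ph = cq.simulate_phenotypes(genos, tm, seed=43)
        spec = make_spec(ph["y"].to_numpy(), list(ph.index))
        ests = []
        for (g1, c1, g2, c2) in [(1, 20.0, 2, 30.0), (2, 30.0, 3, 50.0), (1, 5.0, 3, 10.0)]:
            dec = cq.decompose_epistasis(spec, grid5, (g1, c1), (g2, c2))
            ests.extend(dec["estimate"].tolist())
        assert abs(np.mean(ests)) < 0.15

    def test_permutation_maxima_match_direct_scan(self, grid5, epi_trait):
        ph, _ = epi_trait
        spec = make_spec(ph["y"].to_numpy(), list(ph.index))
        Y = spec.y[:, None]
        maxf = max_f_pairs_many(spec, grid5, Y)
        res = cq.scan_pairs(spec, grid5)
        assert maxf[0] == pytest.approx(res.pairs["f"].max(), abs=1e-8)


class TestDecompose:
    def test_dd_only_pair_recovered(self, sim_cross, grid5):
        genos, _, _ = sim_cross
        tm = cq.TraitModel(
            name="y", residual_sd=1.0,
            epistasis=[cq.EpistasisEffect((1, 30.0), (3, 45.0), i_dd=1.4)],
        )
        ph = cq.simulate_phenotypes(genos, tm, seed=47)
        spec = make_spec(ph["y"].to_numpy(), list(ph.index))
        dec = cq.decompose_epistasis(spec, grid5, (1, 30.0), (3, 45.0))
        assert dec.loc[dec["t"].abs().idxmax(), "term"] == "i_dd"

    def test_null_interactions_rarely_significant(self, sim_cross, grid5):
        genos, _, _ = sim_cross
        rng = np.random.default_rng(48)
        n_sig, n_tot = 0, 0
        for rep in range(10):
            y = rng.standard_normal(len(grid5.ids))
            spec = make_spec(y, grid5.ids)
            dec = cq.decompose_epistasis(spec, grid5, (1, 25.0), (2, 40.0))
            n_sig += int((dec["t"].abs() > 2).sum())
            n_tot += 4
        assert n_sig / n_tot < 0.25


class TestGenotypePhenotypeMap:
    def test_confidence_rule_is_strict(self, grid5):
        probs = np.zeros((5, 1, 4))
        probs[0, 0] = [0.79, 0.10, 0.11, 0.0]  # max pooled prob 0.79 -> dropped
        probs[1, 0] = [0.85, 0.05, 0.05, 0.05]
        probs[2, 0] = [0.0, 0.45, 0.45, 0.10]  # pooled het 0.9 -> kept
        probs[3, 0] = [0.05, 0.05, 0.05, 0.85]
        probs[4, 0] = [0.80, 0.10, 0.10, 0.0]  # exactly 0.8 is not > 0.8
        ids = ["u", "v", "w", "x", "z"]
        g = LineOriginGrid(
            positions=pd.DataFrame({"group": [1], "cm": [0.0]}),
            ids=ids, probs=probs,
        )
        table = pd.DataFrame({"y": [1.0, 2.0, 3.0, 4.0, 5.0]}, index=ids)
        spec = cq.select_null_model(table, "y", factors=(), covariates=())
        m = cq.genotype_phenotype_map(spec, g, (1, 0.0), (1, 0.0), min_prob=0.8)
        assert m.n_used == 3

    def test_noise_free_two_locus_means(self, sim_cross):
        """Fully informative markers + no noise: every bird is assigned and
        cell means equal the true two-locus class means."""
        genos, _, _ = sim_cross
        tm = cq.TraitModel(
            name="y", residual_sd=0.0,
            epistasis=[cq.EpistasisEffect((1, 30.0), (3, 45.0), i_aa=1.0)],
        )
        ph = cq.simulate_phenotypes(genos, tm, seed=51)
        spec = make_spec(ph["y"].to_numpy(), list(ph.index))
        # degenerate grid from the true origins themselves
        to = genos.true_origin
        probs = np.zeros((len(to.f2_ids), 2, 4))
        for k, (g, cm) in enumerate([(1, 30.0), (3, 45.0)]):
            i = int(np.argmin(np.abs(to.positions[g] - cm)))
            m = to.maternal[g][:, i]
            p = to.paternal[g][:, i]
            probs[np.arange(len(m)), k, m * 2 + p] = 1.0
        grid = LineOriginGrid(
            positions=pd.DataFrame({"group": [1, 3], "cm": [30.0, 45.0]}),
            ids=to.f2_ids, probs=probs,
        )
        m = cq.genotype_phenotype_map(spec, grid, (1, 30.0), (3, 45.0))
        assert m.n_used == len(to.f2_ids)
        ybar = spec.y.mean()
        # class means of the centred trait: i_aa * A1 * A2 - overall mean
        for i, a1 in enumerate([1, 0, -1]):
            for j, a2 in enumerate([1, 0, -1]):
                if m.counts[i, j] > 0:
                    assert m.means[i, j] == pytest.approx(a1 * a2 - ybar, abs=1e-9)

    def test_cell_means_match_groupby_oracle(self, grid5, epi_trait):
        ph, _ = epi_trait
        spec = make_spec(ph["y"].to_numpy(), list(ph.index))
        m = cq.genotype_phenotype_map(spec, grid5, (1, 30.0), (3, 45.0), min_prob=0.8)
        # naive recomputation with pandas
        j1, j2 = grid5.column(1, 30.0), grid5.column(3, 45.0)
        rows = []
        for k, iid in enumerate(spec.ids):
            r = list(grid5.ids).index(iid)
            rec = {}
            for lab, j in (("g1", j1), ("g2", j2)):
                p = grid5.probs[r, j]
                pooled = {"AA": p[0], "AB": p[1] + p[2], "BB": p[3]}
                best = max(pooled, key=pooled.get)
                rec[lab] = best if pooled[best] > 0.8 else None
            rec["resid"] = spec.residuals[k]
            rows.append(rec)
        df = pd.DataFrame(rows).dropna()
        expect = df.groupby(["g1", "g2"])["resid"].mean()
        for (l1, l2), v in expect.items():
            i, j = m.classes1.index(l1), m.classes2.index(l2)
            assert m.means[i, j] == pytest.approx(v, abs=1e-12)
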