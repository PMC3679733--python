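import numpy as np
import pandas as pd
import pytest

import crossqtl as cq
from crossqtl.origin import indicators
from crossqtl.scan1d import CollinearityError, max_f_many, variance_for_calls

from conftest import make_spec
from oracles import normal_equations_ols


@pytest.fixture(scope="module")
def spec_and_grid(sim_cross, qtl_trait):
    _, _, grid = sim_cross
    ph, _ = qtl_trait
    spec = make_spec(ph["y"].to_numpy(), list(ph.index))
    return spec, grid


class TestFitPosition:
    def test_perfect_fit_is_degenerate_signal(self, sim_cross):
        genos, _, grid = sim_cross
        ind = indicators(grid)
        j = grid.column(1, 20.0)
        A, D = ind.A[:, j], ind.D[:, j]
        spec = make_spec(2.0 * A, grid.ids)
        fit = cq.fit_position(spec, A, D)
        assert fit.degenerate
        assert np.isinf(fit.f)
        assert fit.a == pytest.approx(2.0, abs=1e-8)
        assert fit.d == pytest.approx(0.0, abs=1e-8)

    def test_matches_normal_equations_oracle(self, spec_and_grid):
        """Both the single fit and the vectorised scan agree with an
        explicit normal-equations solve to 1e-10."""
        spec, grid = spec_and_grid
        ind = indicators(grid)
        res = cq.scan_genome(spec, grid)
        for g, cm in [(1, 5.0), (2, 30.0), (3, 47.0)]:
            j = grid.column(g, cm)
            A, D = ind.A[:, j], ind.D[:, j]
            X = np.column_stack([np.ones(len(A)), A, D])
            beta, rss_full, se, df = normal_equations_ols(X, spec.y)
            rss_red = float(np.sum((spec.y - spec.y.mean()) ** 2))
            f_expect = ((rss_red - rss_full) / 2) / (rss_full / df)

            fit = cq.fit_position(spec, A, D, group=g, cm=cm)
            assert fit.a == pytest.approx(beta[1], abs=1e-10)
            assert fit.d == pytest.approx(beta[2], abs=1e-10)
            assert fit.se_a == pytest.approx(se[1], abs=1e-10)
            assert fit.f == pytest.approx(f_expect, abs=1e-10)

            row = res.profile[(res.profile["group"] == g) & (res.profile["cm"] == cm)].iloc[0]
            assert row["a"] == pytest.approx(beta[1], abs=1e-10)
            assert row["f"] == pytest.approx(f_expect, abs=1e-8)
            assert row["se_a"] == pytest.approx(se[1], abs=1e-10)

    def test_null_f_has_mean_near_df_ratio(self, sim_cross):
        """Under a pure-noise trait, F averages df/(df-2) across positions
        and replicates."""
        _, _, grid = sim_cross
        rng = np.random.default_rng(8)
        n = len(grid.ids)
        fs = []
        for _ in range(20):
            spec = make_spec(rng.standard_normal(n), grid.ids)
            res = cq.scan_genome(spec, grid)
            fs.append(res.profile["f"].to_numpy())
        df = n - 1 - 2
        assert np.mean(fs) == pytest.approx(df / (df - 2), abs=0.15)


class TestScanGenome:
    def test_deterministic(self, spec_and_grid):
        spec, grid = spec_and_grid
        a = cq.scan_genome(spec, grid)
        b = cq.scan_genome(spec, grid)
        pd.testing.assert_frame_equal(a.profile, b.profile)

    def test_affine_invariance_of_f_profile(self, spec_and_grid):
        spec, grid = spec_and_grid
        a = cq.scan_genome(spec, grid)
        spec2 = make_spec(3.0 * spec.y + 7.0, spec.ids)
        b = cq.scan_genome(spec2, grid)
        assert np.allclose(a.profile["f"], b.profile["f"], atol=1e-8)
        assert np.allclose(3.0 * a.profile["a"], b.profile["a"], atol=1e-8)

    def test_peak_marker_is_nearest(self, spec_and_grid, toy_map):
        spec, grid = spec_and_grid
        res = cq.scan_genome(spec, grid, gmap=toy_map)
        cm = res.peak.cm
        marker_cms = toy_map.positions(res.peak.group)
        nearest = toy_map.markers(res.peak.group)["marker"].iloc[
            int(np.argmin(np.abs(marker_cms - cm)))
        ]
        assert res.peak_marker == nearest

    def test_cofactor_freezes_own_position(self, spec_and_grid):
        """Rescanning with the peak as cofactor kills the signal there."""
        spec, grid = spec_and_grid
        res = cq.scan_genome(spec, grid)
        pk = res.peak
        res2 = cq.scan_genome(spec, grid, cofactors=[(pk.group, pk.cm)])
        row = res2.profile[
            (res2.profile["group"] == pk.group) & (res2.profile["cm"] == pk.cm)
        ].iloc[0]
        # down from a peak F of ~30+; residual is numerical projection noise
        assert res.peak.f > 10
        assert row["f"] < 0.1

    def test_max_f_many_matches_scan(self, spec_and_grid):
        spec, grid = spec_and_grid
        rng = np.random.default_rng(9)
        Y = np.column_stack([spec.y, rng.standard_normal(len(spec.y))])
        maxf = max_f_many(spec, grid, Y)
        res = cq.scan_genome(spec, grid)
        assert maxf[0] == pytest.approx(res.peak.f, abs=1e-8)


class TestForwardScan:
    def test_two_unlinked_qtl_recovered(self, sim_cross):
        genos, _, grid = sim_cross
        tm = cq.TraitModel(
            name="y", residual_sd=1.0,
            qtl=[cq.QTLEffect(1, 15.0, a=0.55), cq.QTLEffect(3, 45.0, a=0.55)],
        )
        ph = cq.simulate_phenotypes(genos, tm, seed=17)
        spec = make_spec(ph["y"].to_numpy(), list(ph.index))
        th = cq.permutation_threshold(spec, grid, n_perm=200, seed=18)
        calls, _ = cq.forward_scan(spec, grid, th.thresholds[0.05], th.thresholds[0.01])
        assert len(calls) == 2
        assert any(g == 1 and abs(cm - 15) <= 10 for g, cm in ((c.group, c.cm) for c in calls))
        assert any(g == 3 and abs(cm - 45) <= 10 for g, cm in ((c.group, c.cm) for c in calls))

    def test_single_qtl_no_ghost_call(self, spec_and_grid):
        spec, grid = spec_and_grid
        th = cq.permutation_threshold(spec, grid, n_perm=200, seed=19)
        calls, _ = cq.forward_scan(spec, grid, th.thresholds[0.05], th.thresholds[0.01])
        assert len(calls) == 1
        assert calls[0].group == 2 and abs(calls[0].cm - 30.0) <= 10

    def test_letter_suffixes_follow_cm_order(self, sim_cross):
        genos, _, grid = sim_cross
        tm = cq.TraitModel(
            name="y", residual_sd=1.0,
            qtl=[cq.QTLEffect(1, 5.0, a=0.6), cq.QTLEffect(1, 55.0, a=0.6)],
        )
        ph = cq.simulate_phenotypes(genos, tm, seed=23)
        spec = make_spec(ph["y"].to_numpy(), list(ph.index))
        th = cq.permutation_threshold(spec, grid, n_perm=200, seed=24)
        calls, _ = cq.forward_scan(spec, grid, th.thresholds[0.05])
        ones = sorted((c.cm, c.name) for c in calls if c.group == 1)
        if len(ones) == 2:
            assert ones[0][1].endswith("a") and ones[1][1].endswith("b")


class TestLinkedPair:
    def test_identical_positions_rejected(self, spec_and_grid):
        spec, grid = spec_and_grid
        with pytest.raises(CollinearityError):
            cq.test_linked_pair(spec, grid, (1, 10.0), (1, 10.0), threshold=5.0)

    def test_two_distant_qtl_on_one_chromosome_independent(self, sim_cross):
        genos, _, grid = sim_cross
        tm = cq.TraitModel(
            name="y", residual_sd=1.0,
            qtl=[cq.QTLEffect(1, 5.0, a=0.7), cq.QTLEffect(1, 55.0, a=0.7)],
        )
        ph = cq.simulate_phenotypes(genos, tm, seed=25)
        spec = make_spec(ph["y"].to_numpy(), list(ph.index))
        out = cq.test_linked_pair(spec, grid, (1, 5.0), (1, 55.0), threshold=8.0)
        assert out["independent"]

    def test_shoulder_of_single_qtl_fails(self, spec_and_grid):
        spec, grid = spec_and_grid
        res = cq.scan_genome(spec, grid)
        pk = res.peak
        out = cq.test_linked_pair(
            spec, grid, (pk.group, pk.cm), (pk.group, pk.cm + 10.0), threshold=8.0
        )
        assert not out["independent"]


class TestVarianceExplained:
    def test_zero_when_full_equals_reduced(self):
        assert cq.variance_explained(1.0, 1.0, 2.0) == 0.0

    def test_stated_arithmetic(self):
        assert cq.variance_explained(110.0, 90.0, 120.0) == pytest.approx(100 / 6)

    def test_zero_reduced_ms_is_an_error(self):
        with pytest.raises(ZeroDivisionError):
            cq.variance_explained(1.0, 0.5, 0.0)

    def test_recovers_simulated_share(self, sim_cross):
        """A QTL built to explain ~15% of variance yields Var% near 15."""
        genos, _, grid = sim_cross
        a = np.sqrt(2 * 0.15 / 0.85)
        tm = cq.TraitModel(name="y", residual_sd=1.0, qtl=[cq.QTLEffect(2, 30.0, a=a)])
        vals = []
        for seed in range(5):
            ph = cq.simulate_phenotypes(genos, tm, seed=100 + seed)
            spec = make_spec(ph["y"].to_numpy(), list(ph.index))
            res = cq.scan_genome(spec, grid)
            vals.append(variance_for_calls(spec, grid, [(res.peak.group, res.peak.cm)])[0])
        assert abs(np.mean(vals) - 15.0) < 4.0
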