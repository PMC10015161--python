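"""Topology tests: delta/SE, RELL resampling, KH, SH, AU, ranked table."""

import numpy as np
import pytest

from dupsplit.toptest import (RellConfig, SiteLogLik, au_test, build_table,
                              delta_and_se, kh_test, rell_resample, sh_test)


def make_sl(matrix, counts=None, trees=None):
    matrix = np.asarray(matrix, dtype=float)
    if counts is None:
        counts = np.ones(matrix.shape[1], dtype=int)
    if trees is None:
        trees = [f"t{i};" for i in range(matrix.shape[0])]
    return SiteLogLik(trees=trees, matrix=matrix, counts=np.asarray(counts))


@pytest.fixture
def random_sl():
    rng = np.random.default_rng(1234)
    base = rng.normal(-3.0, 0.4, size=300)
    rows = [base,
            base + rng.normal(-0.02, 0.15, size=300),
            base + rng.normal(-0.05, 0.2, size=300),
            base + rng.normal(-0.3, 0.3, size=300)]
    return make_sl(np.vstack(rows))


class TestRellConfig:
    def test_requires_scale_one(self):
        with pytest.raises(ValueError):
            RellConfig(scales=(0.5, 0.7, 1.2))

    def test_requires_min_replicates(self):
        with pytest.raises(ValueError):
            RellConfig(n_replicates=10)

    def test_default_scales(self):
        cfg = RellConfig()
        assert len(cfg.scales) == 10
        assert cfg.scales[0] == pytest.approx(0.5)
        assert cfg.scales[-1] == pytest.approx(1.4)


class TestDeltaAndSe:
    def test_duplicated_ml_row(self):
        sl = make_sl([[-1.0, -2.0], [-1.0, -2.0]])
        delta, se = delta_and_se(sl)
        assert delta[1] == pytest.approx(0.0)
        assert se[1] == pytest.approx(0.0)

    def test_constant_per_site_difference_has_zero_se(self):
        # second tree worse by exactly c per site -> SE 0, delta = n*c
        n, c = 8, 0.25
        row = np.full(n, -2.0)
        sl = make_sl([row, row - c])
        delta, se = delta_and_se(sl)
        assert delta[1] == pytest.approx(n * c)
        assert se[1] == pytest.approx(0.0, abs=1e-12)

    def test_matches_direct_recomputation(self):
        rng = np.random.default_rng(7)
        mat = rng.normal(-2, 0.5, size=(3, 8))
        counts = np.array([1, 2, 1, 3, 1, 1, 2, 1])
        sl = make_sl(mat, counts)
        delta, se = delta_and_se(sl)
        # spreadsheet-style oracle: expand patterns to sites, plain loops
        sites = np.repeat(np.arange(8), counts)
        totals = [sum(mat[t, s] for s in sites) for t in range(3)]
        ml = int(np.argmax(totals))
        n = len(sites)
        for t in range(3):
            d = [mat[ml, s] - mat[t, s] for s in sites]
            dbar = sum(d) / n
            ssq = sum((x - dbar) ** 2 for x in d)
            exp_se = np.sqrt(n / (n - 1) * ssq) if t != ml else 0.0
            assert delta[t] == pytest.approx(totals[ml] - totals[t], abs=1e-10)
            assert se[t] == pytest.approx(exp_se, abs=1e-10)

    def test_single_tree_rejected(self):
        with pytest.raises(ValueError):
            delta_and_se(make_sl([[-1.0, -2.0]]))

    def test_ml_tie_breaks_on_tree_string(self):
        sl = make_sl([[-1.0, -2.0], [-1.0, -2.0]], trees=["zz;", "aa;"])
        assert sl.ml_index() == 1  # lexicographically smallest string wins


class TestRellResample:
    def test_seed_determinism(self, random_sl):
        cfg = RellConfig(n_replicates=500, seed=3)
        r1 = rell_resample(random_sl, cfg, 1.0)
        r2 = rell_resample(random_sl, cfg, 1.0)
        assert np.array_equal(r1, r2)

    def test_identical_rows_give_identical_totals(self):
        row = np.random.default_rng(0).normal(-2, 0.3, 50)
        sl = make_sl([row, row.copy(), row.copy()])
        rep = rell_resample(sl, RellConfig(n_replicates=200, seed=1), 1.0)
        assert np.allclose(rep[:, 0], rep[:, 1])
        assert np.allclose(rep[:, 0], rep[:, 2])

    def test_replicate_mean_matches_scaled_total(self, random_sl):
        cfg = RellConfig(n_replicates=4000, seed=5)
        rep = rell_resample(random_sl, cfg, 1.0)
        totals = random_sl.totals
        n = random_sl.n_sites
        per_site_sd = random_sl.matrix.std(axis=1)
        se = per_site_sd * np.sqrt(n) / np.sqrt(cfg.n_replicates)
        assert np.all(np.abs(rep.mean(axis=0) - totals) < 4 * se + 1e-9)

    def test_scale_changes_replicate_size(self, random_sl):
        cfg = RellConfig(n_replicates=300, seed=2)
        r_half = rell_resample(random_sl, cfg, 0.5)
        r_full = rell_resample(random_sl, cfg, 1.0)
        # totals at scale 0.5 are ~half the scale-1 totals
        assert abs(r_half.mean() / r_full.mean() - 0.5) < 0.05

    def test_unknown_scale_rejected(self, random_sl):
        with pytest.raises(ValueError):
            rell_resample(random_sl, RellConfig(n_replicates=200), 0.77)


class TestKhSh:
    def test_kh_of_duplicated_ml_row_is_one(self):
        row = np.random.default_rng(3).normal(-2, 0.4, 100)
        sl = make_sl([row, row.copy()])
        p = kh_test(sl, RellConfig(n_replicates=500, seed=0))
        assert p[0] == pytest.approx(1.0)
        assert p[1] == pytest.approx(1.0)

    def test_kh_near_half_for_symmetric_null(self):
        # per-site differences are iid symmetric noise, observed delta ~ 0
        rng = np.random.default_rng(11)
        base = rng.normal(-2, 0.3, 2000)
        noise = rng.normal(0, 0.2, 2000)
        noise -= noise.mean()          # observed delta exactly 0
        sl = make_sl([base, base + noise])
        p = kh_test(sl, RellConfig(n_replicates=4000, seed=1))
        assert abs(p[1] - 0.5) < 0.05

    def test_sh_of_ml_topology_is_one(self, random_sl):
        cfg = RellConfig(n_replicates=1000, seed=9)
        p_sh = sh_test(random_sl, cfg)
        assert p_sh[random_sl.ml_index()] == pytest.approx(1.0)

    def test_sh_dominates_kh_pointwise(self, random_sl):
        cfg = RellConfig(n_replicates=1000, seed=9)
        rep = rell_resample(random_sl, cfg, 1.0)
        p_kh = kh_test(random_sl, cfg, rep)
        p_sh = sh_test(random_sl, cfg, rep)
        assert np.all(p_sh >= p_kh - 1e-12)

    def test_huge_delta_drives_p_to_zero(self):
        rng = np.random.default_rng(8)
        base = rng.normal(-2, 0.3, 400)
        sl = make_sl([base, base - 1.0])   # catastrophic per-site deficit
        cfg = RellConfig(n_replicates=1000, seed=2)
        assert sh_test(sl, cfg)[1] < 0.01
        assert kh_test(sl, cfg)[1] < 0.01


class TestAu:
    def test_dominant_tree_flagged_with_p_one(self):
        rng = np.random.default_rng(5)
        base = rng.normal(-2, 0.3, 500)
        sl = make_sl([base, base - 0.5])
        p, info = au_test(sl, RellConfig(n_replicates=500, seed=0),
                          return_details=True)
        assert info["flags"][0] and info["flags"][1]
        assert p[0] == 1.0 and p[1] == 0.0

    def test_needs_three_scales(self):
        sl = make_sl(np.random.default_rng(0).normal(-2, 0.3, (2, 50)))
        with pytest.raises(ValueError):
            au_test(sl, RellConfig(n_replicates=200, scales=(0.5, 1.0)))

    def test_probabilities_in_unit_interval(self, random_sl):
        p = au_test(random_sl, RellConfig(n_replicates=500, seed=4))
        assert np.all((p >= 0) & (p <= 1))

    def test_near_uniform_on_smooth_boundary(self):
        # two hypotheses with per-site logL rows +x/-x and E[x]=0: the truth
        # lies on the smooth boundary between the regions, where AU p-values
        # should be approximately uniform -> rejection near the nominal level
        rng = np.random.default_rng(99)
        n, n_datasets = 600, 120
        pvals = np.empty(n_datasets)
        for d in range(n_datasets):
            x = rng.standard_normal(n)
            sl = make_sl([x, -x])
            pvals[d] = au_test(sl, RellConfig(n_replicates=500, seed=d))[0]
        rej = (pvals <= 0.05).mean()
        # 95% binomial envelope around 0.05 for 120 draws, plus MC slack
        assert 0.0 <= rej <= 0.11
        assert 0.35 < pvals.mean() < 0.65


class TestBuildTable:
    def test_structure_and_ordering(self, random_sl):
        cfg = RellConfig(n_replicates=800, seed=6)
        table = build_table(random_sl, cfg)
        assert list(table["rank"]) == list(range(1, random_sl.n_trees + 1))
        ratios = table["ratio"].to_numpy()
        assert np.all(np.diff(ratios) >= -1e-12)
        assert table.loc[0, "delta_logl"] == pytest.approx(0.0)
        assert table.loc[0, "ratio"] == pytest.approx(0.0)
        assert table.loc[0, "p_sh"] == pytest.approx(1.0)
        assert bool(table.loc[0, "within_1se"])
        assert np.all(table["p_sh"].to_numpy() >= table["p_kh"].to_numpy() - 1e-12)

    def test_scenario_labels_carried_through(self, random_sl):
        cfg = RellConfig(n_replicates=500, seed=6)
        labels = ["a", "b", "c", "d"]
        table = build_table(random_sl, cfg, scenario_labels=labels)
        assert set(table["scenario"]) == set(labels)

    def test_within_1se_flag_matches_ratio(self, random_sl):
        table = build_table(random_sl, RellConfig(n_replicates=500, seed=2))
        assert ((table["ratio"] <= 1.0) == table["within_1se"]).all()


class TestSiteLogLikIO:
    def test_tsv_roundtrip(self, tmp_path, random_sl):
        path = tmp_path / "sl.tsv"
        random_sl.to_tsv(path)
        back = SiteLogLik.from_tsv(path)
        assert back.trees == [str(t) for t in random_sl.trees]
        assert np.allclose(back.matrix, random_sl.matrix)
        assert np.array_equal(back.counts, random_sl.counts)
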