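"""Mixed-model SNP association, GEM regression and table plumbing."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from culmat.association_engine import (
    adjust_pvalues,
    fit_null_mlm,
    gem_as_trait,
    gem_association,
    genomic_inflation,
    manhattan_table,
    snp_association,
)
from culmat.marker_scoring import ExpressionMatrix, GenotypeMatrix, compute_rpkm
from culmat.population_structure import kinship_ibs
from culmat.synthetic_panel import (
    SimulationConfig,
    simulate_expression,
    simulate_genotypes,
    simulate_phenotypes,
)


def _identity_kinship(accessions):
    return pd.DataFrame(np.eye(len(accessions)), index=accessions, columns=accessions)


def _sim_gm(seed=41, n=50, m=200, **kw):
    cfg = SimulationConfig(seed=seed, n_accessions=n, n_snps=m, n_unigenes=10, **kw)
    return simulate_genotypes(cfg)


class TestNullModel:
    def test_heritability_recovery(self):
        # median recovered h2 over 20 seeds within +-0.15 of the truth
        cfg = SimulationConfig(
            seed=42, n_accessions=200, n_snps=800, fst=0.4, dirichlet_alpha=0.05
        )
        gm, _ = simulate_genotypes(cfg)
        K = kinship_ibs(gm).to_numpy()
        lam, U = np.linalg.eigh(K)
        lam = np.clip(lam, 0, None)
        h2_true = 0.5  # sigma_g2 = sigma_e2 = 1 in the model parameterisation
        estimates = []
        for s in range(20):
            rng = np.random.default_rng(1000 + s)
            u = U @ (np.sqrt(lam) * rng.standard_normal(len(K)))
            y = u + rng.standard_normal(len(K))
            fit = fit_null_mlm(y, None, K)
            estimates.append(fit.heritability)
        assert abs(np.median(estimates) - h2_true) < 0.15

    def test_identity_kinship_reduces_to_ols(self):
        gm, _ = _sim_gm()
        rng = np.random.default_rng(0)
        y = pd.Series(rng.normal(size=50), index=gm.accessions)
        K = _identity_kinship(gm.accessions)
        tab = snp_association(y, gm, None, K)
        for mkr in gm.markers[:50]:
            g = gm.calls[mkr].to_numpy()
            if np.std(g) == 0:
                continue
            sl = stats.linregress(g, y.to_numpy())
            assert tab.set_index("id").loc[mkr, "p"] == pytest.approx(
                sl.pvalue, abs=1e-8
            )

    def test_degenerate_fit_flagged(self):
        gm, _ = _sim_gm(n=20, m=30)
        # y exactly linear in the covariate -> zero residual variance
        cov = pd.DataFrame(
            {"c": np.arange(20, dtype=float)}, index=gm.accessions
        )
        y = 2.0 + 3.0 * cov["c"]
        fit = fit_null_mlm(
            y.to_numpy(), cov.to_numpy(), _identity_kinship(gm.accessions).to_numpy()
        )
        assert fit.boundary or fit.sigma_g2 < 1e-10 or fit.sigma_e2 < 1e-10

    def test_non_psd_kinship_rejected(self):
        bad = np.array([[1.0, 2.0], [2.0, 1.0]])
        with pytest.raises(ValueError):
            fit_null_mlm(np.array([0.0, 1.0, 2.0, 3.0]), None, np.kron(bad, np.eye(2)))


class TestSnpAssociation:
    @pytest.fixture(scope="class")
    def structured(self):
        cfg = SimulationConfig(
            seed=43, n_accessions=60, n_snps=150, fst=0.3, dirichlet_alpha=0.05
        )
        gm, truth = simulate_genotypes(cfg)
        kin = kinship_ibs(gm)
        cfg_ph = SimulationConfig(
            seed=43, n_accessions=60, n_snps=150, h2_polygenic=0.5, sigma_e=1.0,
            year_effects={1: 0.0}, reps_per_year={1: 1},
        )
        _, latent = simulate_phenotypes(gm, None, kin, cfg_ph, seed=9)
        q = pd.DataFrame(truth.admixture_q[:, :-1], index=gm.accessions)
        return gm, kin, latent, q

    def test_matches_brute_force_gls(self, structured):
        # explicit-covariance GLS oracle on a 20-accession toy
        gm_full, kin_full, latent, q = structured
        acc = gm_full.accessions[:20]
        calls = gm_full.calls.loc[acc].iloc[:, :40]
        gm = GenotypeMatrix(calls, gm_full.info.iloc[:40])
        kin = kin_full.loc[acc, acc]
        y = latent[acc]
        tab = snp_association(y, gm, None, kin).set_index("id")

        null = fit_null_mlm(y.to_numpy(), None, kin.to_numpy())
        V = null.sigma_g2 * kin.to_numpy() + null.sigma_e2 * np.eye(20)
        Vinv = np.linalg.inv(V)
        for mkr in gm.markers:
            g = calls[mkr].to_numpy()
            if np.std(g) == 0:
                continue
            X = np.column_stack([np.ones(20), g])
            XtVi = X.T @ Vinv
            beta = np.linalg.solve(XtVi @ X, XtVi @ y.to_numpy())
            resid = y.to_numpy() - X @ beta
            rss1 = resid @ Vinv @ resid
            X0 = np.ones((20, 1))
            b0 = np.linalg.solve(X0.T @ Vinv @ X0, X0.T @ Vinv @ y.to_numpy())
            r0 = y.to_numpy() - X0 @ b0
            rss0 = r0 @ Vinv @ r0
            F = (rss0 - rss1) / (rss1 / (20 - 2))
            p = stats.f.sf(F, 1, 18)
            assert tab.loc[mkr, "p"] == pytest.approx(p, abs=1e-8)

    def test_orthogonal_marker_null_p(self):
        gm, _ = _sim_gm(n=30, m=5)
        rng = np.random.default_rng(2)
        y = rng.normal(size=30)
        g = gm.calls.iloc[:, 0].to_numpy().copy()
        # force exact orthogonality of the residualised marker and trait
        yc = y - y.mean()
        gc = g - g.mean()
        y_orth = yc - gc * (yc @ gc) / (gc @ gc)
        tab = snp_association(
            pd.Series(y_orth, index=gm.accessions),
            GenotypeMatrix(gm.calls.iloc[:, [0]], gm.info.iloc[[0]]),
            None,
            _identity_kinship(gm.accessions),
        )
        assert tab["stat"].iloc[0] == pytest.approx(0.0, abs=1e-10)
        assert tab["p"].iloc[0] == pytest.approx(1.0, abs=1e-8)

    def test_missing_genotypes_casewise_deleted(self, structured):
        gm_full, kin, latent, q = structured
        calls = gm_full.calls.copy()
        calls.iloc[:5, 0] = np.nan
        gm = GenotypeMatrix(calls, gm_full.info)
        tab = snp_association(latent, gm, None, kin).set_index("id")
        first = gm.markers[0]
        assert tab.loc[first, "n"] == len(gm.accessions) - 5

    def test_monomorphic_marker_nan_row(self, structured):
        gm_full, kin, latent, q = structured
        calls = gm_full.calls.copy()
        calls.iloc[:, 0] = 0.0
        gm = GenotypeMatrix(calls, gm_full.info)
        with pytest.warns(UserWarning):
            tab = snp_association(latent, gm, None, kin).set_index("id")
        assert np.isnan(tab.loc[gm.markers[0], "p"])
        assert len(tab) == len(gm.markers)  # rows conserved

    def test_p3d_and_exact_agree(self, structured):
        gm, kin, latent, q = structured
        t1 = snp_association(latent, gm, q, kin, mode="P3D")
        t2 = snp_association(latent, gm, q, kin, mode="exact")
        d = np.abs(t1["neglog10p"] - t2["neglog10p"])
        assert np.nanmax(d.to_numpy()) < 0.2

    def test_p_values_in_unit_interval(self, structured):
        gm, kin, latent, q = structured
        tab = snp_association(latent, gm, q, kin)
        p = tab["p"].dropna()
        assert ((p > 0) & (p <= 1)).all()


class TestGemAssociation:
    def _expr_from(self, values, accessions):
        rpkm = pd.DataFrame(values, index=accessions)
        return ExpressionMatrix(
            rpkm,
            pd.Series(1000.0, index=rpkm.columns),
            pd.Series(1e6, index=accessions),
        )

    def test_worked_p_for_r09(self):
        x = np.array([-1.0, -0.5, 0.0, 0.5, 1.0])
        rng = np.random.default_rng(3)
        z = rng.normal(size=5)
        z -= z.mean()
        z -= x * (z @ x) / (x @ x)
        y = 0.9 * x / np.std(x) + np.sqrt(0.19) * z / np.std(z)
        acc = [f"a{i}" for i in range(5)]
        expr = self._expr_from({"u1": y - y.min() + 0.1}, acc)
        tab = gem_association(pd.Series(x, index=acc), expr)
        assert tab["r"].iloc[0] == pytest.approx(0.9, abs=1e-9)
        assert tab["p"].iloc[0] == pytest.approx(0.0374, abs=5e-4)

    def test_role_swap_leaves_p_unchanged(self):
        rng = np.random.default_rng(4)
        acc = [f"a{i}" for i in range(30)]
        e = rng.uniform(1, 5, size=30)
        t = 0.5 * e + rng.normal(size=30)
        expr_a = self._expr_from({"u1": e}, acc)
        expr_b = self._expr_from({"u1": t - t.min() + 0.1}, acc)
        p1 = gem_association(pd.Series(t, index=acc), expr_a)["p"].iloc[0]
        p2 = gem_association(pd.Series(e, index=acc), expr_b)["p"].iloc[0]
        assert p1 == pytest.approx(p2, rel=1e-9)

    def test_planted_gem_top_ranked_with_sign(self):
        cfg = SimulationConfig(
            seed=45, n_accessions=100, n_snps=50, n_unigenes=60,
            causal_gems=[(7, 2.5)], h2_polygenic=0.3, sigma_e=1.0,
            expr_baseline_mean=6.0, expr_baseline_sd=0.5,
            year_effects={1: 0.0}, reps_per_year={1: 1},
        )
        gm, _ = simulate_genotypes(cfg)
        counts, lengths, totals = simulate_expression(gm, cfg, seed=46)
        expr = compute_rpkm(counts, lengths, totals)
        kin = kinship_ibs(gm)
        _, latent = simulate_phenotypes(
            gm, np.log2(expr.rpkm + 1e-9), kin, cfg, seed=47
        )
        tab = gem_association(latent, expr)
        top = tab.sort_values("p").iloc[0]
        assert top["id"] == "UG00007"
        assert top["effect"] > 0

    def test_constant_unigene_nan_with_warning(self):
        acc = [f"a{i}" for i in range(10)]
        expr = self._expr_from(
            {"u1": np.ones(10), "u2": np.arange(10.0)}, acc
        )
        y = pd.Series(np.arange(10.0), index=acc)
        with pytest.warns(UserWarning):
            tab = gem_association(y, expr).set_index("id")
        assert np.isnan(tab.loc["u1", "p"])
        assert np.isfinite(tab.loc["u2", "p"])


class TestGemAsTrait:
    def test_cis_marker_is_top_hit(self):
        cfg = SimulationConfig(
            seed=48, n_accessions=100, n_snps=200, n_unigenes=30,
            cis_links=[(5, 17, 2.0)], expr_baseline_mean=6.0,
            expr_baseline_sd=0.0, expr_sigma=0.0,
        )
        gm, _ = simulate_genotypes(cfg)
        counts, lengths, totals = simulate_expression(gm, cfg, seed=49)
        expr = compute_rpkm(counts, lengths, totals)
        kin = kinship_ibs(gm)
        tab = gem_as_trait("UG00005", expr, gm, None, kin)
        top = tab.sort_values("p").iloc[0]
        assert top["id"] == gm.markers[17]
        assert top["p"] < 1e-6

    def test_equals_direct_snp_association(self, small_panel):
        gm = small_panel["genotypes"]
        expr = small_panel["expression"]
        kin = small_panel["kinship"]
        u = expr.unigenes[0]
        t1 = gem_as_trait(u, expr, gm, None, kin)
        t2 = snp_association(expr.rpkm[u], gm, None, kin)
        pd.testing.assert_frame_equal(t1, t2)

    def test_unknown_or_constant_unigene_rejected(self, small_panel):
        with pytest.raises(KeyError):
            gem_as_trait(
                "nope", small_panel["expression"], small_panel["genotypes"],
                None, small_panel["kinship"],
            )


class TestTablePlumbing:
    def _assoc(self, ids, ps, unigenes=None):
        return pd.DataFrame(
            {
                "id": ids,
                "unigene": unigenes if unigenes is not None else ids,
                "p": ps,
                "neglog10p": -np.log10(ps),
            }
        )

    def test_single_chromosome_ordinal_positions(self):
        mmap = pd.DataFrame(
            {"chromosome": ["1A"] * 3, "position": [1, 2, 3]},
            index=["u1", "u2", "u3"],
        )
        tab = manhattan_table(self._assoc(["u2", "u3", "u1"], [0.1, 0.2, 0.3]), mmap)
        assert list(tab["x"]) == [1.0, 2.0, 3.0]
        assert list(tab["id"]) == ["u1", "u2", "u3"]

    def test_unplaced_markers_appended(self):
        mmap = pd.DataFrame(
            {"chromosome": ["1A"], "position": [1]}, index=["u1"]
        )
        with pytest.warns(UserWarning):
            tab = manhattan_table(self._assoc(["u1", "zz"], [0.1, 0.2]), mmap)
        assert len(tab) == 2
        assert tab.iloc[-1]["chromosome"] == "unplaced"

    def test_natural_chromosome_order(self):
        mmap = pd.DataFrame(
            {"chromosome": ["2A", "1B", "1A", "10A"], "position": [1, 1, 1, 1]},
            index=["w", "x", "y", "z"],
        )
        tab = manhattan_table(
            self._assoc(["w", "x", "y", "z"], [0.1] * 4), mmap
        )
        assert list(tab["chromosome"]) == ["1A", "1B", "2A", "10A"]

    def test_bonferroni_direct(self):
        tab = adjust_pvalues(self._assoc(list("abc"), [0.01, 0.02, 0.03]))
        assert list(tab["p_bonferroni"]) == pytest.approx([0.03, 0.06, 0.09])

    def test_all_ones_stay_ones(self):
        tab = adjust_pvalues(self._assoc(list("ab"), [1.0, 1.0]))
        assert (tab["p_bonferroni"] == 1.0).all()
        assert (tab["p_bh"] == 1.0).all()

    def test_bh_monotone(self):
        rng = np.random.default_rng(5)
        p = rng.uniform(size=40)
        tab = adjust_pvalues(self._assoc([f"m{i}" for i in range(40)], p))
        order = np.argsort(p)
        assert np.all(np.diff(tab["p_bh"].to_numpy()[order]) >= -1e-12)

    def test_manhattan_plot_written(self, tmp_path):
        from culmat.association_engine import manhattan_plot

        mmap = pd.DataFrame(
            {"chromosome": ["1A", "1A", "2B"], "position": [1, 2, 1]},
            index=["u1", "u2", "u3"],
        )
        tab = manhattan_table(
            self._assoc(["u1", "u2", "u3"], [0.1, 0.01, 0.5]), mmap
        )
        out = manhattan_plot(tab, tmp_path / "scan.png")
        assert out.exists() and out.stat().st_size > 0

    def test_genomic_inflation_uniform_p_near_one(self):
        rng = np.random.default_rng(6)
        lam = genomic_inflation(rng.uniform(size=20000))
        assert lam == pytest.approx(1.0, abs=0.05)
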