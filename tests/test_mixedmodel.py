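import numpy as np
import pandas as pd
import pytest

from gslab.mixedmodel import (
    ModelSpec,
    PedigreeBLUP,
    ablup_cross_validate,
    build_mme,
    em_reml,
    solve_blup,
)
from gslab.pedigree import (
    PedigreeTable,
    RelationshipMatrix,
    build_numerator_relationship,
)
from gslab.varcomp import VarianceComponents, heritability
from oracles import anova_oneway_family, gls_mixed_model


def _simple_phen(y, ids=None, site="S1", block="B1", family=None):
    n = len(y)
    ids = ids or [f"i{k}" for k in range(n)]
    return pd.DataFrame(
        {
            "id": ids,
            "family": family if family is not None else ["F1"] * n,
            "site": [site] * n if isinstance(site, str) else site,
            "block": [block] * n if isinstance(block, str) else block,
            "y": np.asarray(y, float),
        }
    )


def _identity_A(ids):
    return RelationshipMatrix(np.eye(len(ids)), list(ids))


class TestBLUPClosedForms:
    def test_scalar_shrinkage_with_identity_A(self):
        rng = np.random.default_rng(1)
        y = rng.normal(10.0, 2.0, size=30)
        phen = _simple_phen(y)
        A = _identity_A(phen["id"])
        vc = VarianceComponents(sigma2_a=3.0, sigma2_e=1.0)
        spec = ModelSpec.custom(["additive"])
        res = solve_blup(build_mme(phen, spec, A, vc))
        h2 = 3.0 / 4.0
        np.testing.assert_allclose(
            res.ebv.to_numpy(), h2 * (y - y.mean()), atol=1e-10
        )

    def test_infinite_shrinkage_limit(self):
        rng = np.random.default_rng(2)
        phen = _simple_phen(rng.normal(size=25))
        A = _identity_A(phen["id"])
        vc = VarianceComponents(sigma2_a=1e-10, sigma2_e=1.0)
        res = solve_blup(build_mme(phen, ModelSpec.custom(["additive"]), A, vc))
        assert np.abs(res.ebv.to_numpy()).max() < 1e-8

    def test_mean_ebv_near_zero_with_overall_mean(self, fs_trial):
        phen = fs_trial.phenotypes
        A = build_numerator_relationship(fs_trial.population.pedigree_table())
        vc = VarianceComponents(2.0, 1.0, 0.5, 0.5, 0.5, 5.5)
        res = solve_blup(build_mme(phen, ModelSpec.fullsib(), A, vc))
        ebv = res.ebv.to_numpy()
        assert abs(ebv.mean()) < 0.05 * ebv.std()


class TestGLSOracle:
    def _toy(self, seed=4, n_per=4):
        # 3-site toy with 12 records on a real (related) pedigree
        records = [("s1", "0", "0"), ("s2", "0", "0"), ("d1", "0", "0"), ("d2", "0", "0")]
        kids = []
        for k in range(12):
            sire = "s1" if k % 2 == 0 else "s2"
            dam = "d1" if k < 6 else "d2"
            records.append((f"o{k}", sire, dam))
            kids.append(f"o{k}")
        A = build_numerator_relationship(PedigreeTable.from_records(records))
        rng = np.random.default_rng(seed)
        phen = pd.DataFrame(
            {
                "id": kids,
                "family": [f"{r[1]}x{r[2]}" for r in records[4:]],
                "site": [f"S{1 + k % 3}" for k in range(12)],
                "block": [f"B{1 + (k // 3) % 2}" for k in range(12)],
                "y": rng.normal(5.0, 2.0, size=12),
            }
        )
        return phen, A

    @pytest.mark.parametrize("kind", ["fullsib", "halfsib"])
    def test_blup_equals_direct_gls(self, kind):
        phen, A = self._toy()
        spec = ModelSpec.fullsib() if kind == "fullsib" else ModelSpec.halfsib()
        vc = VarianceComponents(1.5, 0.8, 0.4, 0.6, 0.7, 2.5)
        res = solve_blup(build_mme(phen, spec, A, vc))

        # oracle design matrices built independently with pandas dummies
        X = np.column_stack(
            [np.ones(12)]
            + [
                (phen["site"] == s).to_numpy(float)
                for s in sorted(phen["site"].unique())[1:]
            ]
        )
        obs = A.indices(phen["id"])
        Z_a = np.zeros((12, len(A.ids)))
        Z_a[np.arange(12), obs] = 1.0
        site = phen["site"].to_numpy()
        G_sa = A.values[np.ix_(obs, obs)] * (site[:, None] == site[None, :])
        Zb = pd.get_dummies(phen["site"] + ":" + phen["block"]).to_numpy(float)
        Zsf = pd.get_dummies(phen["site"] + ":" + phen["family"]).to_numpy(float)
        Zf = pd.get_dummies(phen["family"]).to_numpy(float)
        Zs = [Z_a, np.eye(12), Zb]
        Gs = [A.values, G_sa, None]
        s2 = [vc.sigma2_a, vc.sigma2_sa, vc.sigma2_srep]
        if kind == "fullsib":
            Zs += [Zsf, Zf]
            Gs += [None, None]
            s2 += [vc.sigma2_sf, vc.sigma2_f]
        beta, us = gls_mixed_model(phen["y"], X, Zs, Gs, s2, vc.sigma2_e)

        np.testing.assert_allclose(res.fixed_effects.to_numpy(), beta, atol=1e-8)
        np.testing.assert_allclose(res.ebv.to_numpy(), us[0], atol=1e-8)
        np.testing.assert_allclose(
            res.random_solutions["block"].to_numpy(),
            us[2][np.argsort(sorted(range(Zb.shape[1])))],
            atol=1e-8,
        )

    def test_included_term_with_zero_variance_rejected(self):
        phen, A = self._toy()
        vc = VarianceComponents(sigma2_a=1.0, sigma2_e=1.0)  # sa, srep, ... zero
        with pytest.raises(ValueError, match="positive"):
            build_mme(phen, ModelSpec.fullsib(), A, vc)


class TestEMREML:
    def test_null_heritability_hits_boundary(self):
        rng = np.random.default_rng(8)
        n = 120
        fams = [f"F{k % 8}" for k in range(n)]
        records = [(f"p{j}", "0", "0") for j in range(16)]
        records += [
            (f"i{k}", f"p{2 * (k % 8)}", f"p{2 * (k % 8) + 1}") for k in range(n)
        ]
        A = build_numerator_relationship(PedigreeTable.from_records(records))
        phen = _simple_phen(rng.normal(size=n), ids=[f"i{k}" for k in range(n)],
                            family=fams)
        res = em_reml(phen, ModelSpec.custom(["additive"]), A, tol=1e-8, max_iter=400)
        assert res.vc.sigma2_a < 0.05 * res.vc.sigma2_e

    def test_balanced_halfsib_matches_anova_moments(self):
        # balanced single-site half-sib toy: animal-model REML maps exactly
        # onto the one-way ANOVA components (s2_B = s2_a/4)
        rng = np.random.default_rng(9)
        k_fam, m = 20, 10
        n = k_fam * m
        records = [(f"s{j}", "0", "0") for j in range(k_fam)]
        records += [(f"d{i}", "0", "0") for i in range(n)]
        ids, fams = [], []
        for j in range(k_fam):
            for r in range(m):
                i = j * m + r
                records.append((f"i{i}", f"s{j}", f"d{i}"))
                ids.append(f"i{i}")
                fams.append(f"F{j}")
        A = build_numerator_relationship(PedigreeTable.from_records(records))
        sigma_a, sigma_e = 1.2, 1.0
        fam_eff = rng.normal(0, np.sqrt(sigma_a / 4), k_fam)
        y = np.repeat(fam_eff, m) + rng.normal(0, np.sqrt(0.75 * sigma_a + sigma_e), n)
        phen = _simple_phen(y, ids=ids, family=fams)
        res = em_reml(phen, ModelSpec.custom(["additive"]), A, tol=1e-12, max_iter=3000)
        s2_b, _ = anova_oneway_family(y, fams)
        assert res.vc.sigma2_a == pytest.approx(4.0 * s2_b, rel=1e-6)

    def test_loglik_monotone_every_iteration(self, fs_trial):
        A = build_numerator_relationship(fs_trial.population.pedigree_table())
        res = em_reml(fs_trial.phenotypes, ModelSpec.fullsib(), A, tol=1e-5,
                      max_iter=120)
        ll = res.loglik_path
        assert np.all(np.diff(ll) >= -1e-7 * np.maximum(1.0, np.abs(ll[:-1])))

    def test_nonconvergence_flagged(self, fs_trial):
        A = build_numerator_relationship(fs_trial.population.pedigree_table())
        res = em_reml(fs_trial.phenotypes, ModelSpec.fullsib(), A, tol=1e-14, max_iter=5)
        assert not res.converged
        assert res.n_iter == 5

    def test_bad_init_rejected(self, fs_trial):
        A = build_numerator_relationship(fs_trial.population.pedigree_table())
        with pytest.raises(ValueError, match="positive"):
            em_reml(fs_trial.phenotypes, ModelSpec.fullsib(), A,
                    init=VarianceComponents(sigma2_a=0.0, sigma2_e=1.0))


class TestHeritability:
    def test_fullsib_formula(self):
        vc = VarianceComponents(2.0, 1.0, 99.0, 0.5, 0.5, 6.0)  # block excluded
        assert heritability(vc, "fullsib") == pytest.approx(0.2)

    def test_halfsib_formula(self):
        vc = VarianceComponents(1.0, 0.0, 99.0, 0.0, 0.0, 1.0)
        assert heritability(vc, "halfsib") == pytest.approx(0.5)

    def test_zero_additive_gives_zero(self):
        assert heritability(VarianceComponents(0.0, 1.0, 0, 0, 0, 1.0), "fullsib") == 0.0

    def test_scale_invariance(self):
        vc = VarianceComponents(2.0, 1.0, 0.5, 0.5, 0.5, 5.5)
        for c in (0.1, 3.0, 1e4):
            assert heritability(vc.scaled(c), "fullsib") == pytest.approx(
                heritability(vc, "fullsib")
            )

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            heritability(VarianceComponents(0.0), "halfsib")


class TestABLUPCrossValidation:
    def test_no_signal_predictions_uncorrelated_with_true_breeding_values(self):
        # near-zero-heritability trait: pedigree predictions carry no real
        # signal, so they are uncorrelated with the true additive values.
        # (The r(EBV_pred, EBV_full) statistic itself stays well above zero
        # on null data because both sides share family-mean noise — the
        # known optimism of validating against non-deregressed EBVs.)
        from gslab.simdata import simulate_trial

        trial = simulate_trial(
            "full-sib", seed=31, n_families=60, offspring_per_family=8,
            n_markers=400, n_qtl=80, n_parents=120, blocks_per_site=2,
            vc=VarianceComponents(sigma2_a=0.001, sigma2_e=8.0),
        )
        phen = trial.phenotypes
        A = build_numerator_relationship(trial.population.pedigree_table())
        vc = VarianceComponents(sigma2_a=0.001, sigma2_e=8.0)
        spec = ModelSpec.custom(["additive"])
        _, preds = ablup_cross_validate(phen, spec, A, vc, k=5, reps=2, seed=3,
                                        return_predictions=True)
        merged = preds.merge(phen[["id", "true_a"]], on="id")
        r = np.corrcoef(merged["predicted"], merged["true_a"])[0, 1]
        assert abs(r) < 0.25

    def test_nfold_equals_explicit_leave_one_out(self):
        # 20-individual toy: k = n folds reproduce a brute-force LOO loop
        records = [("s1", "0", "0"), ("s2", "0", "0"), ("d1", "0", "0"), ("d2", "0", "0")]
        ids = []
        for k in range(20):
            records.append((f"o{k}", "s1" if k % 2 else "s2", "d1" if k < 10 else "d2"))
            ids.append(f"o{k}")
        A = build_numerator_relationship(PedigreeTable.from_records(records))
        rng = np.random.default_rng(5)
        phen = _simple_phen(rng.normal(size=20), ids=ids,
                            family=[f"{r[1]}x{r[2]}" for r in records[4:]])
        vc = VarianceComponents(sigma2_a=1.0, sigma2_e=1.0)
        spec = ModelSpec.custom(["additive"])
        _, preds = ablup_cross_validate(phen, spec, A, vc, k=20, reps=1, seed=0,
                                        return_predictions=True)
        preds = preds.set_index("id")["predicted"]
        for iid in ids:
            train = phen[phen["id"] != iid]
            res = solve_blup(build_mme(train, spec, A, vc))
            assert preds.loc[iid] == pytest.approx(res.ebv.loc[iid], abs=1e-10)

    def test_masking_nothing_reproduces_full_ebvs(self, fs_trial):
        phen = fs_trial.phenotypes
        A = build_numerator_relationship(fs_trial.population.pedigree_table())
        vc = VarianceComponents(2.0, 1.0, 0.5, 0.5, 0.5, 5.5)
        spec = ModelSpec.fullsib()
        a = solve_blup(build_mme(phen, spec, A, vc)).ebv
        b = solve_blup(build_mme(phen, spec, A, vc)).ebv
        pd.testing.assert_series_equal(a, b)

    def test_accuracies_bounded(self, fs_trial):
        phen = fs_trial.phenotypes
        A = build_numerator_relationship(fs_trial.population.pedigree_table())
        vc = VarianceComponents(2.0, 1.0, 0.5, 0.5, 0.5, 5.5)
        detail = ablup_cross_validate(phen, ModelSpec.fullsib(), A, vc, k=5, reps=2, seed=1)
        ok = detail[~detail["missing"]]["accuracy"]
        assert ((ok >= -1) & (ok <= 1)).all()
        assert ok.mean() > 0.3  # heritable trait: pedigree carries real signal


class TestPedigreeBLUPClass:
    def test_fit_with_supplied_components_and_summary(self, fs_trial):
        vc = VarianceComponents(2.0, 1.0, 0.5, 0.5, 0.5, 5.5)
        model = PedigreeBLUP(fs_trial.phenotypes,
                             fs_trial.population.pedigree_table(), kind="fullsib")
        res = model.fit(varcomp=vc)
        assert res.converged
        assert res.heritability == pytest.approx(heritability(vc, "fullsib"))
        # EBVs exist for non-phenotyped parents too
        assert set(res.ebv.index) == set(fs_trial.population.ids)
        text = res.summary()
        assert "sigma2_a" in text and "heritability" in text

    def test_reml_fit_close_to_generative_components(self, fs_trial):
        model = PedigreeBLUP(fs_trial.phenotypes,
                             fs_trial.population.pedigree_table(), kind="fullsib")
        res = model.fit(tol=1e-4, maxiter=150)
        # small trial: only sanity bounds, not tight recovery
        assert 0.0 <= res.heritability <= 1.0
        assert res.varcomp.sigma2_e > 0.5

    def test_missing_columns_rejected(self, fs_trial):
        with pytest.raises(ValueError, match="column"):
            PedigreeBLUP(fs_trial.phenotypes.drop(columns=["block"]),
                         fs_trial.population.pedigree_table(), kind="fullsib")
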