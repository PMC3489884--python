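import numpy as np
import pandas as pd
import pytest
from sklearn.base import clone

from chondrotime import (
    ComponentSet,
    FactorScoreTable,
    PlantedBlock,
    SimulationConfig,
    TimeCourseDesign,
    TimeCourseProfileSelector,
    annotate_selection,
    classify_subgroups,
    expected_null_fraction,
    factor_scores,
    fit_pca,
    generate_dataset,
    orient_components,
    select_probes,
    timepoint_means,
)
from conftest import recovery_rate


def toy_components(oriented=True):
    """Hand-built orthonormal level/ramp/bump profiles over 6 time points."""
    c1 = np.ones(6) / np.sqrt(6.0)
    ramp = np.linspace(-0.5, 0.5, 6)
    c2 = ramp / np.linalg.norm(ramp)
    bump = np.array([-0.5, 0.0, 0.5, 0.5, 0.0, -0.5])
    c3 = bump / np.linalg.norm(bump)
    components = pd.DataFrame(
        np.column_stack([c1, c2, c3]),
        index=pd.RangeIndex(6, name="timepoint"),
        columns=["PC1", "PC2", "PC3"],
    )
    eig = np.array([3.0, 2.0, 1.0])
    return ComponentSet(components, eig, eig / eig.sum(), oriented=oriented)


def scores_table(f2, f3, pvalue=0.001):
    """Craft a FactorScoreTable directly from component-2/3 scores."""
    n = len(f2)
    idx = pd.Index([f"P{i:03d}" for i in range(n)], name="probe_id")
    scores = pd.DataFrame(
        {"PC1": np.zeros(n), "PC2": f2, "PC3": f3}, index=idx, dtype=float
    )
    pvals = pd.DataFrame(np.full((n, 3), pvalue), index=idx, columns=scores.columns)
    return FactorScoreTable(scores.copy(), scores, pvals, df_resid=8)


class TestFitPca:
    def test_level_only_variation_is_one_component(self):
        # probes share one profile and differ by an additive constant:
        # all between-probe variance lies on the constant direction
        profile = np.array([3.0, 1.0, 4.0, 1.0, 5.0, 9.0])
        offsets = np.arange(10.0)
        em = pd.DataFrame(profile[None, :] + offsets[:, None])
        cs = fit_pca(em)
        assert cs.variance_fraction[0] == pytest.approx(1.0, abs=1e-12)
        np.testing.assert_allclose(
            np.abs(cs.components["PC1"]), 1.0 / np.sqrt(6.0), atol=1e-12
        )

    def test_eigenvalues_match_characteristic_polynomial_roots(self):
        rng = np.random.default_rng(3)
        mpm = pd.DataFrame(rng.normal(size=(8, 3)))
        cs = fit_pca(mpm)
        cov = np.cov(mpm.to_numpy(), rowvar=False, ddof=1)
        # Faddeev-LeVerrier charpoly coefficients, roots via companion matrix
        n = cov.shape[0]
        coeffs = [1.0]
        M = np.zeros_like(cov)
        for k in range(1, n + 1):
            M = cov @ M + coeffs[-1] * np.eye(n)
            coeffs.append(-np.trace(cov @ M) / k)
        roots = np.sort(np.roots(coeffs).real)[::-1]
        np.testing.assert_allclose(cs.eigenvalues, roots, atol=1e-8)

    def test_component_set_invariants(self, fitted_selector):
        cs = fitted_selector.component_set_
        V = cs.components.to_numpy()
        np.testing.assert_allclose(V.T @ V, np.eye(V.shape[1]), atol=1e-8)
        assert (np.diff(cs.eigenvalues) <= 1e-12).all()
        assert cs.variance_fraction.sum() == pytest.approx(1.0, abs=1e-9)

    def test_eigenvalue_sum_equals_trace(self, planted_dataset):
        em, design, _, _ = planted_dataset
        mpm = timepoint_means(em, design)
        cs = fit_pca(mpm)
        trace = float(np.trace(np.cov(mpm.to_numpy(), rowvar=False, ddof=1)))
        assert cs.eigenvalues.sum() == pytest.approx(trace, rel=1e-9)

    def test_three_components_explain_nearly_all_variance(self, fitted_selector):
        # level + trend + transient structure: >= 99% in three components
        assert fitted_selector.explained_variance_ratio_[:3].sum() >= 0.99

    def test_constant_matrix_rejected(self):
        em = pd.DataFrame(np.full((5, 6), 2.0))
        with pytest.raises(ValueError, match="variance"):
            fit_pca(em)


class TestOrientation:
    def test_descending_ramp_is_flipped(self):
        cs = toy_components(oriented=False)
        flipped = ComponentSet(
            -cs.components, cs.eigenvalues, cs.variance_fraction, oriented=False
        )
        oriented = orient_components(flipped)
        # ascending again, positive mean level, interior-elevated bump
        assert (np.diff(oriented.components["PC2"]) > 0).all()
        assert oriented.components["PC1"].mean() > 0
        c3 = oriented.components["PC3"]
        assert c3.iloc[1:-1].mean() > (c3.iloc[0] + c3.iloc[-1]) / 2

    def test_idempotent(self):
        once = orient_components(toy_components(oriented=False))
        twice = orient_components(once)
        pd.testing.assert_frame_equal(once.components, twice.components)
        assert twice.oriented

    @pytest.mark.parametrize("seed", range(25))
    def test_random_orthonormal_sets_satisfy_criteria(self, seed):
        rng = np.random.default_rng(seed)
        Q, _ = np.linalg.qr(rng.normal(size=(6, 6)))
        cs = ComponentSet(
            pd.DataFrame(Q, columns=[f"PC{i+1}" for i in range(6)]),
            np.arange(6.0, 0.0, -1.0),
            np.full(6, 1 / 6),
        )
        out = orient_components(cs).components
        t = np.arange(6.0)
        assert out["PC1"].mean() >= 0
        slope = out["PC2"] @ t - out["PC2"].mean() * t.sum()
        assert slope >= 0
        assert out["PC3"].iloc[1:-1].mean() >= (
            out["PC3"].iloc[0] + out["PC3"].iloc[-1]
        ) / 2


class TestFactorScores:
    def test_noise_free_probe_recovers_component_amplitude(self):
        cs = toy_components()
        design = TimeCourseDesign.from_layout(6, 2)
        tp = design.timepoint_of().to_numpy()
        c2 = cs.components["PC2"].to_numpy()
        rng = np.random.default_rng(0)
        rows = [5.0 + c2[tp]]  # exact component-2 profile, amplitude 1
        rows += [rng.normal(8, 1, 12) for _ in range(9)]
        em = pd.DataFrame(rows, index=[f"P{i}" for i in range(10)],
                          columns=design.sample_ids)
        fst = factor_scores(em, design, cs, k=3)
        assert fst.coefficients.loc["P0", "PC2"] == pytest.approx(1.0, abs=1e-10)
        assert fst.coefficients.loc["P0", "PC3"] == pytest.approx(0.0, abs=1e-10)
        assert fst.pvalues.loc["P0", "PC2"] == pytest.approx(0.0, abs=1e-12)

    def test_scores_standardized_mean_zero_sd_one(self, fitted_selector):
        scores = fitted_selector.factor_scores_
        np.testing.assert_allclose(scores.mean(axis=0), 0.0, atol=1e-6)
        np.testing.assert_allclose(scores.std(axis=0, ddof=1), 1.0, atol=1e-6)

    def test_matches_hand_ols_oracle(self):
        from scipy import stats

        cs = toy_components()
        design = TimeCourseDesign.from_layout(6, 2)
        rng = np.random.default_rng(5)
        em = pd.DataFrame(
            rng.normal(8, 1, size=(20, 12)),
            index=[f"P{i:02d}" for i in range(20)],
            columns=design.sample_ids,
        )
        fst = factor_scores(em, design, cs, k=3)
        tp = design.timepoint_of().to_numpy()
        X = cs.components.to_numpy()[tp, :3]
        df = 12 - 3
        for probe in em.index:
            y = em.loc[probe].to_numpy()
            beta = np.linalg.solve(X.T @ X, X.T @ y)
            resid = y - X @ beta
            s2 = resid @ resid / df
            se = np.sqrt(s2 * np.diag(np.linalg.inv(X.T @ X)))
            tstat = beta / se
            pvals = 2 * stats.t.sf(np.abs(tstat), df)
            np.testing.assert_allclose(
                fst.coefficients.loc[probe].to_numpy(), beta, atol=1e-8
            )
            np.testing.assert_allclose(
                fst.pvalues.loc[probe].to_numpy(), pvals, atol=1e-8
            )

    def test_requires_residual_degrees_of_freedom(self):
        cs = toy_components()
        design = TimeCourseDesign(
            pd.DataFrame(
                {"timepoint": [0, 1, 2], "replicate": [1, 1, 1]},
                index=["a", "b", "c"],
            )
        )
        em = pd.DataFrame(
            np.random.default_rng(0).normal(size=(5, 3)),
            columns=["a", "b", "c"],
        )
        cs3 = ComponentSet(
            cs.components.iloc[:3], cs.eigenvalues, cs.variance_fraction, True
        )
        with pytest.raises(ValueError, match="degrees of freedom"):
            factor_scores(em, design, cs3, k=3)

    def test_unoriented_components_rejected(self, planted_dataset):
        em, design, _, _ = planted_dataset
        cs = fit_pca(timepoint_means(em, design))
        with pytest.raises(ValueError, match="orient"):
            factor_scores(em, design, cs)


class TestExpectedNullFraction:
    def test_two_sided_cutoff_selects_one_per_mille(self):
        assert expected_null_fraction(3.29, "two") == pytest.approx(0.001, abs=5e-5)

    def test_one_sided_half_rate(self):
        assert expected_null_fraction(3.29, "one") == pytest.approx(0.0005, abs=2.5e-5)

    def test_zero_cutoff_selects_everything(self):
        assert expected_null_fraction(0.0, "two") == pytest.approx(1.0)

    def test_negative_cutoff_rejected(self):
        with pytest.raises(ValueError):
            expected_null_fraction(-1.0)


class TestSelection:
    def test_all_below_cutoff_selects_nothing(self):
        fst = scores_table(f2=[1.0, -2.0, 3.0], f3=[0.5, -3.2, 0.0])
        sel = select_probes(fst)
        assert not sel.table["selected"].any()

    def test_boundary_score_is_selected(self):
        fst = scores_table(f2=[3.29, 3.2889], f3=[0.0, 0.0])
        sel = select_probes(fst, require_significance=False)
        assert sel.table["selected"].tolist() == [True, False]

    def test_significance_filter_removes_nonsignificant(self):
        fst = scores_table(f2=[4.0, 4.0], f3=[0.0, 0.0])
        fst.pvalues.iloc[1, 1] = 0.5  # PC2 p-value of the second probe
        sel = select_probes(fst, require_significance=True)
        assert sel.table["selected"].tolist() == [True, False]
        unfiltered = select_probes(fst, require_significance=False)
        assert unfiltered.table["selected"].tolist() == [True, True]

    def test_component_one_never_triggers(self):
        fst = scores_table(f2=[0.0], f3=[0.0])
        fst.scores["PC1"] = 10.0
        sel = select_probes(fst)
        assert not sel.table["selected"].any()

    def test_invalid_parameters_rejected(self):
        fst = scores_table(f2=[0.0], f3=[0.0])
        with pytest.raises(ValueError):
            select_probes(fst, cutoff=-1)
        with pytest.raises(ValueError):
            select_probes(fst, alpha=1.5)


class TestClassification:
    def test_four_subgroups(self):
        fst = scores_table(
            f2=[-4.0, 4.0, 0.0, 0.0, 1.0],
            f3=[0.0, 0.0, 4.0, -4.0, 1.0],
        )
        sel = classify_subgroups(fst, select_probes(fst))
        assert sel.table["subgroup"].tolist()[:4] == [1, 2, 3, 4]
        assert pd.isna(sel.table["subgroup"].iloc[4])
        assert sel.subgroup_sizes() == {1: 1, 2: 1, 3: 1, 4: 1}

    def test_component_two_precedence(self):
        fst = scores_table(f2=[5.0], f3=[5.0])
        sel = classify_subgroups(fst, select_probes(fst))
        assert sel.table["subgroup"].iloc[0] == 2
        assert sel.table["component"].iloc[0] == 2

    def test_no_selection_means_no_subgroups(self):
        fst = scores_table(f2=[0.0, 1.0], f3=[0.0, -1.0])
        sel = classify_subgroups(fst, select_probes(fst))
        assert sel.subgroup_sizes() == {1: 0, 2: 0, 3: 0, 4: 0}

    def test_subgroups_disjoint_and_cover_selection(self, fitted_selector):
        table = fitted_selector.selection_.table
        selected = table[table["selected"]]
        assert selected["subgroup"].notna().all()
        assert (~table["selected"] == table["subgroup"].isna()).all()


class TestAnnotateSelection:
    def test_unannotated_probes_discarded_and_counted(self):
        fst = scores_table(f2=[4.0] * 10, f3=[0.0] * 10)
        sel = classify_subgroups(fst, select_probes(fst))
        symbols = [f"G{i}" for i in range(7)] + [None] * 3
        ann = pd.Series(symbols, index=fst.scores.index, dtype="string")
        genes, n_unannotated = annotate_selection(sel, ann)
        assert len(genes) == 7
        assert n_unannotated == 3
        assert (genes["subgroup"] == 2).all()

    def test_fully_annotated(self):
        fst = scores_table(f2=[4.0, -4.0], f3=[0.0, 0.0])
        sel = classify_subgroups(fst, select_probes(fst))
        ann = pd.Series(["A", "B"], index=fst.scores.index, dtype="string")
        genes, n_unannotated = annotate_selection(sel, ann)
        assert n_unannotated == 0
        assert sorted(genes["gene_symbol"]) == ["A", "B"]

    def test_probe_absent_from_annotation_is_error(self):
        fst = scores_table(f2=[4.0], f3=[0.0])
        sel = select_probes(fst)
        ann = pd.Series(["A"], index=["other_probe"], dtype="string")
        with pytest.raises(ValueError, match="absent from annotation"):
            annotate_selection(sel, ann)


class TestProfileSelectorEstimator:
    def test_sklearn_contract(self):
        est = TimeCourseProfileSelector(cutoff=3.0)
        params = clone(est).get_params()
        assert params["cutoff"] == 3.0
        assert params["require_significance"] is True

    def test_fitted_attributes_and_transform(self, fitted_selector, planted_dataset):
        em, _, _, _ = planted_dataset
        assert fitted_selector.components_.shape == (6, 6)
        assert fitted_selector.factor_scores_.shape[0] == em.shape[0]
        picked = fitted_selector.transform(em)
        assert picked.index.equals(fitted_selector.get_support())

    def test_planted_profiles_recovered(self, fitted_selector, planted_dataset):
        # 2.5 log2-unit effects against 0.25 log2-unit noise: the four
        # planted classes land in their subgroups nearly perfectly
        _, _, _, truth = planted_dataset
        table = fitted_selector.selection_.table
        for cls, grp in [
            ("sustained_decrease", 1),
            ("sustained_increase", 2),
            ("transient_peak", 3),
            ("transient_dip", 4),
        ]:
            assert recovery_rate(table, truth, cls, grp) >= 0.95
        flat = table.join(truth).query("profile_class == 'flat'")
        assert flat["selected"].mean() <= 0.01

    def test_strong_sustained_block_recovered(self):
        # 200 strongly increasing probes (4 log2 units) among 20,000 flat
        cfg = SimulationConfig(
            n_probes=20_200,
            planted=(PlantedBlock("sustained_increase", 200, 4.0),),
            seed=1,
        )
        em, design, _, truth = generate_dataset(cfg)
        sel = TimeCourseProfileSelector().fit(em, design)
        rate = recovery_rate(sel.selection_.table, truth, "sustained_increase", 2)
        assert rate >= 0.95

    def test_stronger_effects_never_weaken_scores(self):
        # expectation of |f2| grows with planted effect size
        mean_abs_f2 = {}
        for effect in (1.5, 2.5):
            rates = []
            for seed in (11, 12, 13):
                cfg = SimulationConfig(
                    n_probes=3000,
                    planted=(PlantedBlock("sustained_increase", 60, effect),),
                    seed=seed,
                )
                em, design, _, truth = generate_dataset(cfg)
                sel = TimeCourseProfileSelector().fit(em, design)
                f2 = sel.factor_scores_["PC2"]
                rates.append(f2[truth["profile_class"] != "flat"].abs().mean())
            mean_abs_f2[effect] = np.mean(rates)
        assert mean_abs_f2[2.5] >= mean_abs_f2[1.5]

    def test_significance_filter_only_shrinks_selection(self, planted_dataset):
        em, design, _, _ = planted_dataset
        with_filter = TimeCourseProfileSelector().fit(em, design)
        without = TimeCourseProfileSelector(require_significance=False).fit(
            em, design
        )
        assert set(with_filter.get_support()) <= set(without.get_support())
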