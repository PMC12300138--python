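import numpy as np
import pytest

from soilmetal.core_io import METALS, load_reference_summary
from soilmetal.source_apportionment import (assign_factor_labels, bartlett,
                                            build_uncertainty, compare_layers,
                                            contribution_percent,
                                            floor_at_mdl, kmo,
                                            pca_varimax, pearson_matrix,
                                            pmf_fit)
from soilmetal.synthetic_data import SyntheticConfig, generate, \
    truth_contributions


class TestCorrelation:
    def test_duplicated_column_gives_unit_r(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=(30, 8))
        x[:, 1] = x[:, 0]
        res = pearson_matrix(x)
        assert res.r.iloc[0, 1] == pytest.approx(1.0)

    def test_independent_columns_near_zero(self):
        x = np.random.default_rng(1).normal(size=(4000, 8))
        res = pearson_matrix(x)
        off = res.r.to_numpy()[~np.eye(8, dtype=bool)]
        assert np.abs(off).max() < 0.06

    def test_toy_vectors_match_hand_formula(self):
        a = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        b = np.array([2.0, 1.0, 4.0, 3.0, 6.0])
        x = np.column_stack([a, b] + [a + i for i in range(6)])
        # direct covariance / sigma sigma evaluation
        expected = (((a - a.mean()) * (b - b.mean())).mean()
                    / (a.std() * b.std()))
        res = pearson_matrix(x)
        assert res.r.iloc[0, 1] == pytest.approx(expected, rel=1e-12)
        assert np.allclose(res.r, res.r.T)
        assert np.allclose(np.diag(res.r), 1.0)

    def test_constant_column_flagged(self):
        x = np.random.default_rng(2).normal(size=(20, 8))
        x[:, 3] = 7.0
        res = pearson_matrix(x)
        assert any("Pb" in f for f in res.flags)


class TestAdequacy:
    def test_identity_correlation_bartlett_zero(self):
        stat, p = bartlett(np.eye(8), n=72)
        assert stat == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_kmo_equicorrelated_matches_formula_oracle(self):
        # R = 0.5*I + 0.5*J (3x3): inverse is 2I - 0.5J, so partials are 1/3
        # KMO = 6*0.25 / (6*0.25 + 6*(1/9))
        r = np.full((3, 3), 0.5)
        np.fill_diagonal(r, 1.0)
        expected = 0.25 / (0.25 + 1.0 / 9.0)
        assert kmo(r) == pytest.approx(expected, rel=1e-12)

    def test_singular_matrix_raises_with_diagnostic(self):
        r = np.ones((4, 4))
        with pytest.raises(ValueError, match="cond"):
            kmo(r)

    def test_synthetic_survey_passes_adequacy_gate(self, samples):
        for layer in ("surface", "deep"):
            res = pearson_matrix(samples.matrix(layer))
            assert kmo(res.r.to_numpy()) > 0.5
            _, p = bartlett(res.r.to_numpy(), len(samples.layer(layer)))
            assert p < 0.001


class TestPca:
    def test_two_source_data_retains_exactly_two_components(self, samples):
        for layer in ("surface", "deep"):
            res = pca_varimax(samples.matrix(layer))
            assert res.n_retained == 2
            assert res.eigenvalues[1] > 1.0 > res.eigenvalues[2]

    def test_eigenvalue_trace_identity(self, samples):
        res = pca_varimax(samples.matrix("surface"))
        assert res.eigenvalues.sum() == pytest.approx(8.0)
        assert np.all(np.diff(res.eigenvalues) <= 1e-12)

    def test_rotation_is_orthogonal_and_preserves_communalities(self, samples):
        res = pca_varimax(samples.matrix("surface"))
        a = res.unrotated_loadings.to_numpy()
        b = res.loadings.to_numpy()
        t, *_ = np.linalg.lstsq(a, b, rcond=None)
        np.testing.assert_allclose(t.T @ t, np.eye(2), atol=1e-8)
        np.testing.assert_allclose((a**2).sum(axis=1), (b**2).sum(axis=1),
                                   rtol=1e-8)


class TestUncertainty:
    def test_below_detection_branch(self, mdl):
        c = np.full((1, 8), 10.0)
        c[0, list(METALS).index("Cd")] = 0.0005   # < MDL 0.001
        u = build_uncertainty(c, mdl, 0.1)
        assert u[0, list(METALS).index("Cd")] == pytest.approx(5 / 6 * 0.001)

    def test_above_detection_branch(self, mdl):
        c = np.zeros((1, 8)) + 100.0
        j = list(METALS).index("Cd")
        c[0, j] = 0.46
        u = build_uncertainty(c, mdl, 0.1)
        expected = np.hypot(0.046, 0.001 / 3.0)
        assert u[0, j] == pytest.approx(expected, rel=1e-12)

    def test_limit_small_mdl_is_delta_c(self, mdl):
        from soilmetal.core_io import DetectionLimits
        tiny = DetectionLimits(mdl={m: 1e-12 for m in METALS})
        c = np.full((2, 8), 3.0)
        u = build_uncertainty(c, tiny, 0.2)
        np.testing.assert_allclose(u, 0.2 * c, rtol=1e-9)

    def test_positive_everywhere(self, samples, mdl):
        u = build_uncertainty(samples.matrix("surface"), mdl)
        assert (u > 0).all()


class TestPmf:
    def test_noise_free_exact_recovery(self, mdl):
        cfg = SyntheticConfig(seed=2, noise_cv=0.0)
        table, truth = generate(cfg)
        x = table.matrix("surface")
        model = pmf_fit(x, np.ones_like(x), k=2, n_restarts=10, seed=2)
        assert model.Q < 1e-6 * np.linalg.norm(x) ** 2
        lab = assign_factor_labels(model)
        tru = truth_contributions(truth, "surface")["anthropogenic"] * 100
        assert (lab.anthropogenic - tru).abs().max() < 0.1

    def test_small_matrix_matches_independent_nmf_oracle(self):
        # independent oracle: scikit-learn's coordinate-descent NMF
        from sklearn.decomposition import NMF

        rng = np.random.default_rng(0)
        x = rng.uniform(0.5, 2.0, (6, 2)) @ rng.uniform(0.5, 2.0, (2, 4))
        x += rng.uniform(0.0, 0.05, x.shape)
        model = pmf_fit(x, np.ones_like(x), k=2, n_restarts=10, seed=1)
        best = np.inf
        for rs in range(5):
            nmf = NMF(n_components=2, init="random", random_state=rs,
                      tol=1e-12, max_iter=20000)
            w = nmf.fit_transform(x)
            best = min(best, ((x - w @ nmf.components_) ** 2).sum())
        assert model.Q <= best * 1.01 + 1e-12

    def test_noisy_recovery_within_ten_points_both_layers(self, default_dataset,
                                                          mdl):
        table, truth = default_dataset
        for layer in ("surface", "deep"):
            x = floor_at_mdl(table.matrix(layer), mdl)
            u = build_uncertainty(x, mdl, 0.1)
            model = pmf_fit(x, u, k=2, n_restarts=20, seed=1)
            lab = assign_factor_labels(model)
            tru = truth_contributions(truth, layer)["anthropogenic"] * 100
            assert (lab.anthropogenic - tru).abs().max() < 10.0

    def test_q_monotone_nonincreasing_within_run(self, samples, mdl):
        x = floor_at_mdl(samples.matrix("surface"), mdl)
        u = build_uncertainty(x, mdl, 0.1)
        model = pmf_fit(x, u, k=2, n_restarts=3, seed=0)
        q = model.q_history
        assert np.all(np.diff(q) <= 1e-9 * q[:-1] + 1e-12)
        assert model.Q >= 0

    def test_scores_normalized_to_unit_mean(self, samples, mdl):
        x = floor_at_mdl(samples.matrix("surface"), mdl)
        u = build_uncertainty(x, mdl, 0.1)
        model = pmf_fit(x, u, k=2, n_restarts=5, seed=0)
        np.testing.assert_allclose(model.G.mean(axis=0), 1.0, rtol=1e-9)
        assert (model.G >= 0).all() and (model.F >= 0).all()

    def test_contract_violations_rejected(self, samples, mdl):
        x = samples.matrix("surface")
        u = build_uncertainty(x, mdl)
        with pytest.raises(ValueError):
            pmf_fit(-x, u)
        with pytest.raises(ValueError):
            pmf_fit(x, 0.0 * u)
        with pytest.raises(ValueError):
            pmf_fit(x, u, k=8)


class TestContributionsAndLabels:
    def test_rows_sum_to_hundred(self):
        f = np.random.default_rng(0).uniform(0.1, 5.0, (2, 8))
        pct = contribution_percent(f)
        np.testing.assert_allclose(pct.sum(axis=1), 100.0, rtol=1e-12)

    def test_equal_profiles_split_fifty_fifty(self):
        f = np.vstack([np.ones(8), np.ones(8)])
        pct = contribution_percent(f)
        np.testing.assert_allclose(pct, 50.0)

    def test_published_profile_percentages(self):
        ref = load_reference_summary()["pmf_profiles"]
        surf = np.array([ref["surface"]["factor1"], ref["surface"]["factor2"]])
        pct = contribution_percent(surf, columns=ref["metals"])
        assert pct.loc["Cu", "factor1"] == pytest.approx(65.4, abs=0.06)
        deep = np.array([ref["deep"]["factor1"], ref["deep"]["factor2"]])
        pct_d = contribution_percent(deep, columns=ref["metals"])
        assert pct_d.loc["As", "factor1"] == pytest.approx(38.9, abs=0.06)

    def test_labelling_survives_factor_permutation(self, samples, mdl):
        x = floor_at_mdl(samples.matrix("surface"), mdl)
        u = build_uncertainty(x, mdl, 0.1)
        model = pmf_fit(x, u, k=2, n_restarts=5, seed=3)
        lab = assign_factor_labels(model)
        swapped = type(model)(G=model.G[:, ::-1], F=model.F[::-1],
                              E=model.E, Q=model.Q, k=2,
                              uncertainty=model.uncertainty,
                              q_history=model.q_history,
                              restarts=model.restarts,
                              converged=model.converged)
        lab2 = assign_factor_labels(swapped)
        assert lab.percent.equals(lab2.percent)

    def test_natural_factor_found_on_synthetic_truth(self, default_dataset,
                                                     mdl, background):
        table, truth = default_dataset
        x = floor_at_mdl(table.matrix("surface"), mdl)
        u = build_uncertainty(x, mdl, 0.1)
        model = pmf_fit(x, u, k=2, n_restarts=10, seed=0)
        lab = assign_factor_labels(model, background)
        # Pb and As are natural tracers in the generator
        assert lab.percent.loc["Pb", "natural"] > 90
        assert lab.percent.loc["As", "natural"] > 90

    def test_label_requires_two_factors(self, samples, mdl):
        x = floor_at_mdl(samples.matrix("surface"), mdl)
        u = build_uncertainty(x, mdl, 0.1)
        model = pmf_fit(x, u, k=3, n_restarts=3, seed=0)
        with pytest.raises(ValueError):
            assign_factor_labels(model)


class TestCompareLayers:
    def test_identical_inputs_zero_delta(self, default_dataset, mdl):
        table, _ = default_dataset
        x = floor_at_mdl(table.matrix("surface"), mdl)
        u = build_uncertainty(x, mdl, 0.1)
        lab = assign_factor_labels(pmf_fit(x, u, seed=1, n_restarts=5))
        delta = compare_layers(lab, lab)
        np.testing.assert_allclose(delta, 0.0)

    def test_published_as_contrast(self):
        # printed profiles: As anthropogenic share rises from ~19.7% at the
        # surface to ~38.9% at depth
        ref = load_reference_summary()["pmf_profiles"]
        out = {}
        for layer in ("surface", "deep"):
            f = np.array([ref[layer]["factor1"], ref[layer]["factor2"]])
            pct = contribution_percent(f, columns=ref["metals"],
                                       factor_names=["anthropogenic",
                                                     "natural"])
            from soilmetal.source_apportionment import SourceContributions
            out[layer] = SourceContributions(percent=pct)
        delta = compare_layers(out["surface"], out["deep"])
        assert delta["As"] == pytest.approx(19.2, abs=0.1)

    def test_antisymmetric(self, default_dataset, mdl):
        table, _ = default_dataset
        labs = []
        for layer in ("surface", "deep"):
            x = floor_at_mdl(table.matrix(layer), mdl)
            u = build_uncertainty(x, mdl, 0.1)
            labs.append(assign_factor_labels(pmf_fit(x, u, seed=2,
                                                     n_restarts=5)))
        d1 = compare_layers(labs[0], labs[1])
        d2 = compare_layers(labs[1], labs[0])
        np.testing.assert_allclose(d1, -d2)
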