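import warnings

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from sklearn.metrics import silhouette_score

from seednet import (collapse_probes, fit_region_expression, pca_qc,
                     per_brain_region_means)
from seednet.lmm import fit_random_intercept


class TestCollapseProbes:
    def test_single_probe_identity_and_mean(self, small_expression):
        mapping = {"g0": "A", "g1": "B", "g2": "B"}
        out = collapse_probes(small_expression, mapping)
        np.testing.assert_array_equal(out.loc["A"], small_expression.loc["g0"])
        np.testing.assert_allclose(
            out.loc["B"],
            (small_expression.loc["g1"] + small_expression.loc["g2"]) / 2)
        assert list(out.columns) == list(small_expression.columns)

    def test_matches_per_gene_mean_oracle(self):
        rng = np.random.default_rng(1)
        probes = pd.DataFrame(rng.normal(size=(50, 7)),
                              index=[f"p{i}" for i in range(50)],
                              columns=[f"s{i}" for i in range(7)])
        mapping = {f"p{i}": f"gene{i % 10}" for i in range(50)}
        out = collapse_probes(probes, mapping)
        for gene in out.index:
            members = [p for p, g in mapping.items() if g == gene]
            np.testing.assert_allclose(out.loc[gene],
                                       probes.loc[members].mean(axis=0))

    def test_no_mapped_probe_errors(self, small_expression):
        with pytest.raises(ValueError, match="no probe maps"):
            collapse_probes(small_expression, {"zzz": "A"})


class TestRegionExpression:
    def test_balanced_design_equals_region_means(
            self, small_expression, small_annotations):
        out = fit_region_expression(small_expression, small_annotations)
        means = small_expression.T.groupby(
            small_annotations["region_low"]).mean().T
        # balanced design: GLS region estimates equal plain region means
        np.testing.assert_allclose(out.values.to_numpy(),
                                   means[out.values.columns].to_numpy(),
                                   atol=1e-8)

    def test_exact_identifiability_noise_free(self):
        # one gene, two regions, two donors, additive, zero noise
        ann = pd.DataFrame(
            {"brain_id": ["B1", "B1", "B2", "B2"],
             "structure_high": ["cerebrum"] * 4,
             "structure_mid": ["m"] * 4,
             "region_low": ["r1", "r2", "r1", "r2"]},
            index=["a", "b", "c", "d"])
        region = {"r1": 1.0, "r2": 3.5}
        donor = {"B1": -0.4, "B2": 0.4}
        y = [region[r] + donor[b]
             for r, b in zip(ann["region_low"], ann["brain_id"])]
        expr = pd.DataFrame([y], index=["g"], columns=ann.index)
        out = fit_region_expression(expr, ann)
        contrast = out.values.loc["g", "r2"] - out.values.loc["g", "r1"]
        assert contrast == pytest.approx(2.5, abs=1e-6)

    def test_recovers_planted_region_effects(self, tiny_study,
                                             tiny_region_expr):
        truth = tiny_study.truth.region_effects
        est = tiny_region_expr.values[truth.columns]
        r = np.array([np.corrcoef(est.loc[g], truth.loc[g])[0, 1]
                      for g in truth.index])
        assert np.median(r) > 0.9

    def test_low_noise_recovery_is_near_exact(self):
        from seednet import SimConfig, generate
        cfg = SimConfig(n_genes=40, n_seed=5, n_brains=6,
                        regions_per_structure={"cerebrum_late": 15},
                        samples_per_region_per_brain=1,
                        sigma_noise=0.1, rng_seed=11)
        study = generate(cfg)
        out = fit_region_expression(study.expression, study.annotations)
        truth = study.truth.region_effects
        est = out.values[truth.columns]
        r = np.array([np.corrcoef(est.loc[g], truth.loc[g])[0, 1]
                      for g in truth.index])
        assert r.min() > 0.99

    def test_single_donor_rejected(self, small_expression, small_annotations):
        ann = small_annotations.copy()
        ann["brain_id"] = "B1"
        with pytest.raises(ValueError, match="2 donors"):
            fit_region_expression(small_expression, ann)


class TestRemlSolver:
    def test_agrees_with_statsmodels_mixedlm(self):
        """Independent oracle: gene-by-gene MixedLM on an unbalanced design."""
        rng = np.random.default_rng(3)
        n, p, q = 60, 5, 4
        reg = rng.integers(0, p, n); reg[:p] = np.arange(p)
        don = rng.integers(0, q, n); don[p:p + q] = np.arange(q)
        beta = rng.normal(0, 1, (3, p))
        u = rng.normal(0, 0.7, (3, q))
        y = beta[:, reg] + u[:, don] + rng.normal(0, 0.5, (3, n))
        fit = fit_random_intercept(y, reg, don, p, q)
        X = pd.get_dummies(pd.Categorical(reg), dtype=float).to_numpy()
        for g in range(3):
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                ref = sm.MixedLM(y[g], X, groups=don).fit(reml=True)
            np.testing.assert_allclose(fit.region_effects[g], ref.fe_params,
                                       atol=1e-4)
            assert fit.sigma_e2[g] == pytest.approx(ref.scale, rel=1e-3)
            assert fit.sigma_u2[g] == pytest.approx(
                float(np.asarray(ref.cov_re).ravel()[0]), rel=5e-3, abs=1e-4)

    def test_flat_gene_handled(self):
        reg = np.array([0, 0, 1, 1]); don = np.array([0, 1, 0, 1])
        fit = fit_random_intercept(np.full((1, 4), 2.0), reg, don, 2, 2)
        np.testing.assert_allclose(fit.region_effects[0], [2.0, 2.0])
        assert fit.sigma_u2[0] == 0.0


class TestPerBrainMeans:
    def test_matches_groupby_oracle(self, tiny_study):
        brain = tiny_study.annotations["brain_id"].iloc[0]
        out = per_brain_region_means(tiny_study.expression,
                                     tiny_study.annotations, brain)
        ann = tiny_study.annotations
        cols = ann.index[ann["brain_id"] == brain]
        oracle = (tiny_study.expression[cols].T
                  .groupby(ann.loc[cols, "region_low"]).mean().T)
        np.testing.assert_allclose(out.values.to_numpy(),
                                   oracle[out.values.columns].to_numpy())
        assert out.provenance == "per_brain_mean"
        assert out.brain_id == brain

    def test_two_samples_average(self, small_expression, small_annotations):
        out = per_brain_region_means(small_expression, small_annotations, "B1")
        expected = (small_expression["B1_r1_1"] + small_expression["B1_r1_2"]) / 2
        np.testing.assert_allclose(out.values["r1"], expected)

    def test_unknown_donor_errors(self, small_expression, small_annotations):
        with pytest.raises(ValueError, match="no annotated samples"):
            per_brain_region_means(small_expression, small_annotations, "B9")


class TestPcaQc:
    def test_separates_two_clouds(self):
        rng = np.random.default_rng(5)
        a = rng.normal(0, 0.3, (30, 20))   # 30 samples x 20 genes, cloud 1
        b = rng.normal(4, 0.3, (30, 20))   # cloud 2
        expr = pd.DataFrame(np.vstack([a, b]).T,
                            index=[f"g{i}" for i in range(20)],
                            columns=[f"s{i}" for i in range(60)])
        coords = pca_qc(expr)
        labels = [0] * 30 + [1] * 30
        assert silhouette_score(coords[["PC1"]], labels) > 0.5

    def test_duplicated_profile_identical_coordinates(self, small_expression):
        expr = small_expression.copy()
        expr["dup"] = expr.iloc[:, 0]
        coords = pca_qc(expr)
        np.testing.assert_allclose(coords.loc["dup", ["PC1", "PC2"]],
                                   coords.iloc[0][["PC1", "PC2"]], atol=1e-9)

    def test_rotation_invariance_of_scores(self, small_expression):
        rng = np.random.default_rng(2)
        q, _ = np.linalg.qr(rng.normal(size=(6, 6)))
        rotated = pd.DataFrame(q @ small_expression.to_numpy(),
                               index=small_expression.index,
                               columns=small_expression.columns)
        c0 = pca_qc(small_expression).to_numpy()
        c1 = pca_qc(rotated).to_numpy()
        for j in range(c0.shape[1]):
            assert (np.allclose(c0[:, j], c1[:, j], atol=1e-8)
                    or np.allclose(c0[:, j], -c1[:, j], atol=1e-8))

    def test_too_few_samples(self, small_expression):
        with pytest.raises(ValueError, match="at least 3"):
            pca_qc(small_expression.iloc[:, :2])
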