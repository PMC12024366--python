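"""PCA, variable selection, species domains, classification."""

import numpy as np
import pandas as pd
import pytest

from coprofir import (
    Spectrum,
    build_domains,
    classify,
    domain_overlaps,
    fit_reference,
    pairwise_correlation,
    run_pca,
    select_variables,
)
from coprofir.bands import MINERAL_VARIABLES, ORGANIC_VARIABLES
from coprofir.chemometrics import iterative_discard
from coprofir.simulate import (
    ORGANIC_PLANTED_CORR,
    plant_correlated_features,
)


def brute_force_pca(X):
    """Independent oracle: eigendecomposition of the correlation matrix,
    with the same sign convention (largest-|loading| entry positive)."""
    R = np.corrcoef(X, rowvar=False)
    evals, evecs = np.linalg.eigh(R)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    for j in range(evecs.shape[1]):
        if evecs[np.argmax(np.abs(evecs[:, j])), j] < 0:
            evecs[:, j] *= -1.0
    return evals / evals.sum(), evecs


class TestPairwiseCorrelation:
    def _spectra(self, arrays):
        w = np.arange(4000.0, 399.0, -4.0)
        return [Spectrum(w, np.resize(np.asarray(a, float), w.size), sample_id=f"s{i}")
                for i, a in enumerate(arrays)]

    def test_self_correlation_is_one(self):
        rng = np.random.default_rng(0)
        a = rng.normal(size=901)
        R = pairwise_correlation(self._spectra([a, a]))
        assert R.iloc[0, 1] == pytest.approx(1.0)

    def test_negation_gives_minus_one(self):
        rng = np.random.default_rng(1)
        a = rng.normal(size=901)
        R = pairwise_correlation(self._spectra([a, -a]))
        assert R.iloc[0, 1] == pytest.approx(-1.0)

    def test_matches_covariance_formula_oracle(self):
        rng = np.random.default_rng(2)
        a, b = rng.normal(size=(2, 901))
        R = pairwise_correlation(self._spectra([a, b]))
        oracle = float(np.mean((a - a.mean()) * (b - b.mean())) / (a.std() * b.std()))
        assert R.iloc[0, 1] == pytest.approx(oracle, abs=1e-12)

    def test_constant_spectrum_flagged_undefined(self):
        rng = np.random.default_rng(3)
        R = pairwise_correlation(self._spectra([rng.normal(size=901), np.zeros(901)]))
        assert np.isnan(R.iloc[0, 1])
        assert R.iloc[1, 1] == 1.0


class TestRunPCA:
    def test_perfectly_correlated_pair_loads_on_pc1(self):
        rng = np.random.default_rng(4)
        x = rng.normal(size=30)
        df = pd.DataFrame({"a": x, "b": 3.0 * x + 1.0})
        res = run_pca(df, ["a", "b"])
        assert res.explained_fraction[0] == pytest.approx(1.0)

    def test_independent_variables_share_variance(self):
        rng = np.random.default_rng(5)
        df = pd.DataFrame(rng.standard_normal((10_000, 6)),
                          columns=list("abcdef"))
        res = run_pca(df, list("abcdef"))
        np.testing.assert_allclose(res.explained_fraction, 1 / 6, atol=0.05)

    def test_matches_eigendecomposition_oracle(self):
        """100 random instances agree with the correlation-matrix
        eigendecomposition to 1e-8 (fractions, loadings, scores)."""
        rng = np.random.default_rng(6)
        for _ in range(100):
            n = int(rng.integers(5, 51))
            p = int(rng.integers(2, min(n - 1, 11) + 1))
            base = rng.standard_normal((n, p))
            mix = rng.standard_normal((p, p)) * 0.5 + np.eye(p)
            X = base @ mix
            df = pd.DataFrame(X, columns=[f"v{j}" for j in range(p)])
            res = run_pca(df, list(df.columns))
            frac, vecs = brute_force_pca(X)
            np.testing.assert_allclose(res.explained_fraction, frac[:len(res.explained_fraction)],
                                       atol=1e-8)
            L = res.loadings.to_numpy()
            V = vecs[:, :L.shape[1]]
            # sign conventions can differ at exact magnitude ties; align
            # each component by the sign of its dot product
            V = V * np.sign(np.sum(V * L, axis=0))
            np.testing.assert_allclose(L, V, atol=1e-8)

    def test_loadings_orthonormal_fractions_monotone(self):
        feats = plant_correlated_features(60, seed=9)
        res = run_pca(feats)
        L = res.loadings.to_numpy()
        np.testing.assert_allclose(L.T @ L, np.eye(L.shape[1]), atol=1e-8)
        assert np.all(np.diff(res.explained_fraction) <= 1e-12)
        assert res.explained_fraction.sum() <= 1.0 + 1e-9
        assert np.all(res.explained_fraction > 0)

    def test_sample_order_invariance(self):
        feats = plant_correlated_features(80, seed=10)
        shuffled = feats.sample(frac=1.0, random_state=1)
        a = run_pca(feats)
        b = run_pca(shuffled)
        np.testing.assert_allclose(a.explained_fraction, b.explained_fraction, atol=1e-10)
        ra = select_variables(feats)
        rb = select_variables(shuffled)
        assert ra.selected_mineral == rb.selected_mineral
        assert ra.selected_organic == rb.selected_organic

    def test_zero_variance_variable_named(self):
        df = pd.DataFrame({"a": np.arange(5.0), "b": np.ones(5)})
        with pytest.raises(ValueError, match="b"):
            run_pca(df, ["a", "b"])

    def test_undefined_rows_dropped(self):
        feats = plant_correlated_features(30, seed=11)
        feats.iloc[0, feats.columns.get_loc("CO3PO4b")] = np.nan
        res = run_pca(feats)
        assert res.n_dropped == 1
        assert len(res.scores) == 29


class TestSelection:
    def test_exact_copy_discarded_first(self):
        """A variable that is an exact linear copy of an earlier-listed one
        is perfectly redundant and discarded first."""
        rng = np.random.default_rng(12)
        df = pd.DataFrame(rng.standard_normal((50, 6)), columns=MINERAL_VARIABLES)
        df["CI"] = 2.0 * df["CO3"] + 1.0
        order, kept = iterative_discard(df.corr(), MINERAL_VARIABLES)
        assert order[0] == "CI"
        assert len(kept) == 3

    def test_planted_structure_recovers_study_selection(self):
        feats = plant_correlated_features(200, seed=0)
        rep = select_variables(feats)
        assert set(rep.selected_mineral) == {"CO3", "PO4", "CO3PO4b"}
        assert set(rep.selected_organic) == {"chitin", "cholesterol", "amideI"}
        assert len(rep.mineral_discard_order) == 3
        assert len(rep.organic_discard_order) == 2

    def test_collinear_amides_keep_exactly_one(self):
        """With amide I/II planted at r=0.99, exactly one of the pair
        survives the organic screen."""
        feats = plant_correlated_features(200, seed=1)
        rep = select_variables(feats)
        survivors = {"amideI", "amideII"} & set(rep.selected_organic)
        assert len(survivors) == 1

    def test_report_is_machine_readable(self):
        rep = select_variables(plant_correlated_features(50, seed=2))
        text = rep.to_text()
        assert "selected_mineral" in text and "selected_organic" in text

    def test_too_few_candidates_rejected(self):
        feats = plant_correlated_features(50, seed=3)
        with pytest.raises(ValueError, match="3 candidates"):
            select_variables(feats, mineral_candidates=["PO4", "CO3"])

    def test_too_few_samples_rejected(self):
        feats = plant_correlated_features(5, seed=4)
        with pytest.raises(ValueError, match="6 samples"):
            select_variables(feats)


class TestDomains:
    def _pca_from_scores(self, coords, ids):
        feats = pd.DataFrame(coords, columns=["x", "y"], index=ids)
        feats["x"] += np.arange(len(ids)) * 1e-9  # avoid exact degeneracy
        return run_pca(feats, ["x", "y"], standardize=False)

    def test_triangle_hull_contains_members(self):
        pts = np.array([[0.0, 0.0], [1.0, 0.0], [0.0, 1.0], [2.0, 2.0]])
        pca = self._pca_from_scores(pts, ["a", "b", "c", "d"])
        domains = build_domains(pca, {k: "one" for k in "abcd"})
        assert len(domains) == 1
        for _, row in pca.scores.iterrows():
            assert domains[0].contains_point(row["PC1"], row["PC2"])

    def test_separated_clusters_do_not_overlap(self):
        rng = np.random.default_rng(13)
        a = rng.normal(0.0, 1.0, size=(10, 2))
        b = rng.normal(20.0, 1.0, size=(10, 2))  # 20 SD apart
        ids = [f"s{i}" for i in range(20)]
        pca = self._pca_from_scores(np.vstack([a, b]), ids)
        labels = {f"s{i}": ("A" if i < 10 else "B") for i in range(20)}
        ov = domain_overlaps(build_domains(pca, labels))
        assert ov["overlap_area"].iloc[0] == 0.0
        assert bool(ov["disjoint"].iloc[0])

    def test_degenerate_species_have_zero_area(self):
        pts = np.array([[0, 0], [1, 1], [2, 0], [5, 5], [6, 6]], float)
        ids = list("abcde")
        pca = self._pca_from_scores(pts, ids)
        labels = {"a": "tri", "b": "tri", "c": "tri", "d": "pair", "e": "pair"}
        domains = {d.species: d for d in build_domains(pca, labels)}
        assert domains["tri"].area > 0
        assert domains["pair"].area == 0.0
        assert domains["pair"].n_samples == 2

    def test_unlabelled_sample_rejected(self):
        pts = np.array([[0, 0], [1, 1], [2, 0]], float)
        pca = self._pca_from_scores(pts, list("abc"))
        with pytest.raises(ValueError, match="no species label"):
            build_domains(pca, {"a": "x", "b": "x"})


class TestClassification:
    @pytest.fixture()
    def reference(self):
        rng = np.random.default_rng(14)
        rows, labels = [], {}
        for sp, mu in (("A", 0.0), ("B", 4.0), ("C", 9.0)):
            for i in range(12):
                sid = f"{sp}{i}"
                rows.append(pd.Series(mu + rng.normal(0, 1, 4),
                                      index=list("wxyz"), name=sid))
                labels[sid] = sp
        return fit_reference(pd.DataFrame(rows), labels, list("wxyz")), labels

    def test_centroid_classifies_to_own_species(self, reference):
        model, _ = reference
        for sp, c in model.centroids.iterrows():
            raw = c.to_numpy() * model.stds + model.means
            out = classify(dict(zip(model.variables, raw)), model, sample_id=sp)
            assert out.species == sp
            assert out.distances[sp] == pytest.approx(0.0, abs=1e-9)
            assert 0.0 < out.confidence <= 1.0

    def test_hull_membership_reported(self, reference):
        model, _ = reference
        c = model.centroids.iloc[0]
        raw = c.to_numpy() * model.stds + model.means
        out = classify(dict(zip(model.variables, raw)), model)
        assert set(out.in_hull) == set(model.centroids.index)

    def test_undefined_variable_rejected(self, reference):
        model, _ = reference
        fv = dict(zip(model.variables, [1.0, 2.0, np.nan, 0.5]))
        with pytest.raises(ValueError, match="undefined"):
            classify(fv, model)

    def test_zero_variance_reference_rejected(self):
        rows = {f"s{i}": pd.Series([1.0, float(i)], index=["u", "v"])
                for i in range(8)}
        labels = {k: ("A" if int(k[1]) < 4 else "B") for k in rows}
        with pytest.raises(ValueError, match="zero-variance"):
            fit_reference(pd.DataFrame(rows).T, labels, ["u", "v"])
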