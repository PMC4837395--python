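"""Signature selection and the three classifiers, with grid-search / hand oracles."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from chemosig import signature
from chemosig.io import CohortTable
from chemosig.simulate import simulate_cohort


@pytest.fixture(scope="module")
def table17():
    return signature.load_signature_table()


@pytest.fixture(scope="module")
def cohort27(table17):
    sig = signature.filter_signature_table(table17)
    return simulate_cohort(sig.directions, seed=11)


def _toy_cohort(expr: np.ndarray, labels, genes=None):
    genes = genes or [f"g{i}" for i in range(expr.shape[1])]
    table = pd.DataFrame(expr, columns=genes,
                         index=pd.Index([f"p{i}" for i in range(expr.shape[0])]))
    table.insert(0, "label", labels)
    table.insert(1, "time", 1.0)
    table.insert(2, "event", 0)
    return CohortTable(table)


class TestSignatureTable:
    def test_seventeen_genes_pass_the_selection_filter(self, table17):
        model = signature.filter_signature_table(table17, p_max=0.10)
        assert len(model) == 17
        assert max(model.p_values.values()) <= 0.094

    def test_direction_column_preserved(self, table17):
        model = signature.filter_signature_table(table17)
        assert model.directions["ABCC3"] == "down"
        assert model.directions["TUSC3"] == "up"
        assert sum(d == "down" for d in model.directions.values()) == 4


class TestSelectSignature:
    def test_planted_informative_genes_match_per_gene_oracle(self):
        """50 genes, 5 with a large location shift: batch selection equals the
        same U-test run independently gene by gene."""
        rng = np.random.default_rng(3)
        n_s, n_r = 10, 12
        genes = [f"g{i}" for i in range(50)]
        expr = rng.normal(0, 1, size=(n_s + n_r, 50))
        informative = genes[:5]
        expr[n_s:, :5] += 2.5  # up in resistant
        cohort = _toy_cohort(expr, ["sensitive"] * n_s + ["resistant"] * n_r, genes)
        model = signature.select_signature(genes, cohort, p_max=0.10)
        oracle = set()
        for i, g in enumerate(genes):
            p = stats.mannwhitneyu(expr[n_s:, i], expr[:n_s, i], alternative="two-sided").pvalue
            if p < 0.10:
                oracle.add(g)
        assert set(model.genes) == oracle
        assert set(informative) <= set(model.genes)
        for g in informative:
            assert model.directions[g] == "up"

    def test_missing_candidate_warns_and_skips(self, cohort27):
        model = signature.select_signature(["NOT_A_GENE"] + cohort27.genes[:3], cohort27)
        assert any("NOT_A_GENE" in w for w in model.warnings)
        assert "NOT_A_GENE" not in model.genes

    def test_empty_candidates_give_empty_signature(self, cohort27):
        model = signature.select_signature([], cohort27)
        assert model.genes == []


class TestBBR:
    def test_map_coefficients_match_grid_search_oracle(self):
        """1-D toy: Newton MAP equals a fine 2-D grid search over the penalized
        probit log-likelihood (intercept + slope) to 1e-4."""
        scores = np.array([-2.0, -1.0, 1.0, 2.0])
        y = np.array([0.0, 0.0, 1.0, 1.0])
        X = np.column_stack([np.ones(4), scores])
        beta, _ = signature._probit_map(X, y, prior_precision=1.0)

        def neg_obj(b0, b1):
            eta = b0 + b1 * scores
            ll = np.sum(
                y * stats.norm.logcdf(eta) + (1 - y) * stats.norm.logcdf(-eta)
            )
            return ll - 0.5 * (b0**2 + b1**2)

        lo0, hi0, lo1, hi1 = -3.0, 3.0, -3.0, 3.0
        best = None
        for _ in range(6):  # successive grid refinement
            b0s = np.linspace(lo0, hi0, 41)
            b1s = np.linspace(lo1, hi1, 41)
            vals = np.array([[neg_obj(a, b) for b in b1s] for a in b0s])
            i, j = np.unravel_index(np.argmax(vals), vals.shape)
            best = (b0s[i], b1s[j])
            span0, span1 = (hi0 - lo0) / 8, (hi1 - lo1) / 8
            lo0, hi0 = best[0] - span0, best[0] + span0
            lo1, hi1 = best[1] - span1, best[1] + span1
        assert beta[0] == pytest.approx(best[0], abs=1e-4)
        assert beta[1] == pytest.approx(best[1], abs=1e-4)

    def test_separable_metagene_gives_perfect_in_sample_accuracy(self):
        rng = np.random.default_rng(5)
        n = 20
        base = np.concatenate([rng.normal(-2, 0.3, n // 2), rng.normal(2, 0.3, n // 2)])
        expr = np.outer(base, np.ones(6)) + rng.normal(0, 0.1, size=(n, 6))
        cohort = _toy_cohort(expr, ["sensitive"] * (n // 2) + ["resistant"] * (n // 2))
        assert signature.bbr_accuracy(cohort) == 1.0

    def test_training_cohort_at_study_scale_is_perfect(self, cohort27):
        assert signature.bbr_accuracy(cohort27) == 1.0

    def test_label_swap_flips_probabilities(self, cohort27):
        params = signature.fit_bbr(cohort27)
        probs = {
            r.patient_id: r.probability_resistant
            for r in signature.predict_bbr(params, cohort27.table[params.genes])
        }
        swapped_table = cohort27.table.copy()
        swapped_table["label"] = swapped_table["label"].map(
            {"sensitive": "resistant", "resistant": "sensitive"}
        )
        swapped = CohortTable(swapped_table)
        params2 = signature.fit_bbr(swapped)
        for r in signature.predict_bbr(params2, swapped.table[params2.genes]):
            assert r.probability_resistant == pytest.approx(1 - probs[r.patient_id], abs=1e-6)

    def test_scale_invariance(self, cohort27):
        params = signature.fit_bbr(cohort27)
        preds = [r.predicted for r in signature.predict_bbr(params, cohort27.table[params.genes])]
        scaled_table = cohort27.table.copy()
        scaled_table[cohort27.genes] = scaled_table[cohort27.genes] * 37.5
        scaled = CohortTable(scaled_table)
        params2 = signature.fit_bbr(scaled)
        preds2 = [r.predicted for r in signature.predict_bbr(params2, scaled.table[params2.genes])]
        assert preds == preds2

    def test_nonconvergence_raises_with_iteration_count(self):
        X = np.column_stack([np.ones(4), [-2.0, -1.0, 1.0, 2.0]])
        y = np.array([0.0, 0.0, 1.0, 1.0])
        with pytest.raises(RuntimeError, match="2 iterations"):
            signature._probit_map(X, y, prior_precision=1.0, max_iter=2)

    def test_invalid_metagene_count_rejected(self, cohort27):
        with pytest.raises(ValueError):
            signature.fit_bbr(cohort27, n_metagenes=0)


class TestHclust:
    def test_two_tight_groups_perfectly_recovered(self):
        rng = np.random.default_rng(7)
        pattern = np.array([1.0, -1.0, 1.0, -1.0, 1.0])
        expr = np.vstack(
            [pattern * 3 + rng.normal(0, 0.2, 5) for _ in range(6)]
            + [-pattern * 3 + rng.normal(0, 0.2, 5) for _ in range(6)]
        )
        cohort = _toy_cohort(expr, ["sensitive"] * 6 + ["resistant"] * 6)
        _, acc, _ = signature.hclust_classify(cohort)
        assert acc == 1.0

    def test_linkage_matches_naive_average_linkage_trace(self):
        """4-patient fixture: merge heights equal an independently hand-rolled
        average-linkage on the same correlation distances."""
        rng = np.random.default_rng(9)
        expr = rng.normal(0, 1, size=(4, 6))
        cohort = _toy_cohort(expr, ["sensitive", "sensitive", "resistant", "resistant"])
        _, _, Z = signature.hclust_classify(cohort)

        # naive oracle
        d = 1 - np.corrcoef(expr)
        clusters = {i: [i] for i in range(4)}
        heights = []
        next_id = 4
        while len(clusters) > 1:
            keys = sorted(clusters)
            best = None
            for i in range(len(keys)):
                for j in range(i + 1, len(keys)):
                    a, b = keys[i], keys[j]
                    dist = np.mean([d[x, y] for x in clusters[a] for y in clusters[b]])
                    if best is None or dist < best[0]:
                        best = (dist, a, b)
            dist, a, b = best
            heights.append(dist)
            clusters[next_id] = clusters.pop(a) + clusters.pop(b)
            next_id += 1
        assert np.allclose(sorted(Z[:, 2]), sorted(heights), atol=1e-10)

    def test_study_scale_cohort_is_perfect(self, cohort27, table17):
        sig = signature.filter_signature_table(table17)
        _, acc, _ = signature.hclust_classify(cohort27, directions=sig.directions)
        assert acc == 1.0

    def test_constant_patient_vector_names_patient(self):
        expr = np.array([[1.0, 1.0, 1.0], [0.0, 1.0, 2.0], [2.0, 1.0, 0.0], [0.0, 2.0, 1.0]])
        cohort = _toy_cohort(expr, ["sensitive", "sensitive", "resistant", "resistant"])
        with pytest.raises(ValueError, match="p0"):
            signature.hclust_classify(cohort)

    def test_scale_invariance(self, cohort27):
        _, acc, _ = signature.hclust_classify(cohort27)
        scaled_table = cohort27.table.copy()
        scaled_table[cohort27.genes] = scaled_table[cohort27.genes] * 0.01
        _, acc2, _ = signature.hclust_classify(CohortTable(scaled_table))
        assert acc == acc2


class TestCentroid:
    def _reference(self):
        expr = np.array(
            [[0.0, 0.0], [0.2, -0.2], [-0.2, 0.2], [4.0, 4.0], [3.8, 4.2], [4.2, 3.8]]
        )
        return _toy_cohort(expr, ["sensitive"] * 3 + ["resistant"] * 3, ["gA", "gB"])

    def test_query_equal_to_resistant_centroid(self):
        ref = self._reference()
        centroid = ref.table[ref.table["label"] == "resistant"][["gA", "gB"]].mean()
        query = pd.DataFrame([centroid], index=["q"])
        (res,) = signature.centroid_classify(ref, query)
        assert res.predicted == "resistant"

    def test_two_gene_toy_distances(self):
        """Centroids at (0,0) and (4,4) in raw space; query (1,1) is nearer the
        sensitive one (1.41 vs 4.24 before z-scoring, same ordering after)."""
        ref = self._reference()
        (res,) = signature.centroid_classify(ref, pd.DataFrame([[1.0, 1.0]], columns=["gA", "gB"], index=["q"]))
        assert res.predicted == "sensitive"

    def test_exact_midpoint_tie_goes_to_sensitive(self):
        ref = self._reference()
        (res,) = signature.centroid_classify(ref, pd.DataFrame([[2.0, 2.0]], columns=["gA", "gB"], index=["q"]))
        assert res.predicted == "sensitive"

    def test_matches_brute_force_on_random_fixture(self, cohort27):
        got = signature.centroid_classify(cohort27, cohort27.expression)
        genes = cohort27.genes
        expr = cohort27.expression.to_numpy(dtype=float)
        mean, sd = expr.mean(axis=0), expr.std(axis=0, ddof=1)
        z = (expr - mean) / sd
        lab = cohort27.labels.to_numpy()
        cen_s = z[lab == "sensitive"].mean(axis=0)
        cen_r = z[lab == "resistant"].mean(axis=0)
        for i, r in enumerate(got):
            ds = np.sqrt(((z[i] - cen_s) ** 2).sum())
            dr = np.sqrt(((z[i] - cen_r) ** 2).sum())
            expected = "resistant" if dr < ds else "sensitive"
            assert r.predicted == expected

    def test_missing_gene_columns_listed(self, cohort27):
        with pytest.raises(ValueError, match=cohort27.genes[0]):
            signature.centroid_classify(cohort27, pd.DataFrame({"other": [1.0]}))

    def test_scale_invariance(self, cohort27):
        preds = [r.predicted for r in signature.centroid_classify(cohort27, cohort27.expression)]
        scaled_table = cohort27.table.copy()
        scaled_table[cohort27.genes] = scaled_table[cohort27.genes] * 5.0
        scaled = CohortTable(scaled_table)
        preds2 = [r.predicted for r in signature.centroid_classify(scaled, scaled.table[cohort27.genes])]
        assert preds == preds2

    def test_knn_agrees_on_well_separated_cohort(self, cohort27):
        knn = signature.knn_classify(cohort27, cohort27.expression, k=3)
        labels = cohort27.labels
        acc = np.mean([r.predicted == labels[r.patient_id] for r in knn])
        assert acc == 1.0
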