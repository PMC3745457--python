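from itertools import combinations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from stromasig import (
    ExpressionMatrix,
    GeneSignature,
    OrthologMap,
    SampleAnnotation,
    gen_stroma_dataset,
    map_orthologs,
    pca_project,
    row_standardize,
    separation_test,
    signature_score,
    variance_filter,
    wilcoxon_rank_sum,
)


class TestMapOrthologs:
    def test_identity_map_is_noop(self):
        sig = GeneSignature("s", [("a", "up"), ("b", "down")])
        omap = OrthologMap([("a", "a"), ("b", "b")])
        assert map_orthologs(sig, omap).entries == sig.entries

    def test_fixture_matches_set_arithmetic(self):
        # 10 genes, 3 unmapped, 2 mapped but off-platform -> 5 survive
        genes = [f"m{i}" for i in range(10)]
        sig = GeneSignature("s", [(g, "up" if i % 2 else "down") for i, g in enumerate(genes)])
        mapped_sources = genes[:7]  # m7,m8,m9 unmapped
        omap = OrthologMap([(g, g.upper()) for g in mapped_sources])
        platform = {g.upper() for g in mapped_sources[:5]}  # M5,M6 off platform
        out = map_orthologs(sig, omap, platform)
        expected = sorted(
            {g.upper() for g in mapped_sources} & platform
        )
        assert sorted(out.genes) == expected
        # directions carried over
        for src in mapped_sources[:5]:
            assert out.directions[src.upper()] == sig.directions[src]

    def test_many_to_many_keeps_first_target(self):
        sig = GeneSignature("s", [("a", "up")])
        omap = OrthologMap([("a", "X"), ("a", "Y")])
        assert map_orthologs(sig, omap).genes == ["X"]

    def test_nothing_maps_returns_none(self):
        sig = GeneSignature("s", [("a", "up")])
        assert map_orthologs(sig, OrthologMap([("z", "Z")])) is None


class TestVarianceFilter:
    def test_strict_cutoff(self):
        # rows engineered to exact variances 0.4, 0.5, 0.6:
        # with two samples, ddof=1 variance = (x1-x2)^2 / 2
        vals = np.array([
            [0.0, np.sqrt(2 * 0.4)],
            [0.0, np.sqrt(2 * 0.5)],
            [0.0, np.sqrt(2 * 0.6)],
            [5.0, 5.0],  # constant row
        ])
        m = ExpressionMatrix(["a", "b", "c", "const"], ["s1", "s2"], vals)
        sig = GeneSignature("s", [(g, "up") for g in ["a", "b", "c", "const", "absent"]])
        out = variance_filter(m, sig, 0.5)
        assert out.genes == ["c"]

    def test_constant_row_always_removed(self, small_matrix):
        vals = small_matrix.values.copy()
        vals[0] = 3.0
        m = ExpressionMatrix(small_matrix.gene_ids, small_matrix.sample_ids, vals)
        sig = GeneSignature("s", [("g0", "up"), ("g1", "up")])
        out = variance_filter(m, sig, 0.0)
        assert "g0" not in out.genes

    def test_single_sample_rejected(self):
        m = ExpressionMatrix(["g"], ["s"], [[1.0]])
        with pytest.raises(ValueError):
            variance_filter(m, GeneSignature("s", [("g", "up")]), 0.5)


class TestRowStandardize:
    def test_rows_have_zero_mean_unit_variance(self, small_matrix):
        z = row_standardize(small_matrix)
        means = z.values.mean(axis=1)
        variances = z.values.var(axis=1, ddof=1)
        assert np.abs(means).max() < 1e-9
        assert np.abs(variances - 1).max() < 1e-6
        # independent per-row check
        for i, g in enumerate(z.gene_ids):
            row = small_matrix.values[small_matrix.gene_index()[g]]
            np.testing.assert_allclose(
                z.values[i], (row - row.mean()) / row.std(ddof=1), atol=1e-12
            )

    def test_idempotent(self, small_matrix):
        z1 = row_standardize(small_matrix)
        z2 = row_standardize(z1)
        np.testing.assert_allclose(z1.values, z2.values, atol=1e-6)

    def test_constant_rows_dropped_all_constant_error(self):
        m = ExpressionMatrix(["a", "b"], ["s1", "s2", "s3"], [[1, 1, 1], [1, 2, 3]])
        z = row_standardize(m)
        assert z.gene_ids == ["b"]
        allc = ExpressionMatrix(["a"], ["s1", "s2"], [[1, 1]])
        with pytest.raises(ValueError):
            row_standardize(allc)


class TestSignatureScore:
    def test_single_up_gene_identity(self, small_matrix):
        z = row_standardize(small_matrix)
        sig = GeneSignature("s", [("g3", "up")])
        scores = signature_score(z, sig)
        np.testing.assert_allclose(scores.values, z.values[z.gene_index()["g3"]])

    def test_direction_flip_negates(self, small_matrix):
        z = row_standardize(small_matrix)
        sig = GeneSignature("s", [("g0", "up"), ("g1", "down"), ("g2", "up")])
        flipped = GeneSignature(
            "s", [(g, "down" if d == "up" else "up") for g, d in sig.entries]
        )
        np.testing.assert_allclose(
            signature_score(z, sig).values, -signature_score(z, flipped).values
        )

    def test_matches_bruteforce_weighted_mean(self, small_matrix):
        z = row_standardize(small_matrix)
        entries = [("g0", "up"), ("g4", "down"), ("g7", "up"), ("g9", "down"), ("g12", "up")]
        scores = signature_score(z, GeneSignature("s", entries))
        gidx = z.gene_index()
        for j, s in enumerate(z.sample_ids):
            manual = np.mean(
                [(1 if d == "up" else -1) * z.values[gidx[g], j] for g, d in entries]
            )
            assert scores[s] == pytest.approx(manual, abs=1e-9)

    def test_no_gene_present_error(self, small_matrix):
        z = row_standardize(small_matrix)
        with pytest.raises(ValueError):
            signature_score(z, GeneSignature("s", [("missing", "up")]))


def _enumeration_p(x, y, alternative="greater"):
    """Exact one-sided rank-sum p by enumerating all label assignments."""
    pooled = np.concatenate([x, y])
    n1 = len(x)
    ranks = stats.rankdata(pooled)
    u_obs = ranks[:n1].sum() - n1 * (n1 + 1) / 2
    count = total = 0
    for comb in combinations(range(len(pooled)), n1):
        u = ranks[list(comb)].sum() - n1 * (n1 + 1) / 2
        total += 1
        if alternative == "greater":
            count += u >= u_obs
        else:
            count += u <= u_obs
    return u_obs, count / total


class TestWilcoxonRankSum:
    def test_textbook_exact_example(self):
        u, p = wilcoxon_rank_sum([4, 5, 6], [1, 2, 3], "greater")
        assert u == 9.0
        assert p == pytest.approx(1 / 20, abs=1e-12)

    def test_identical_samples_symmetric(self):
        x = [1.0, 2.0, 3.0]
        for alt in ("greater", "less"):
            _, p = wilcoxon_rank_sum(x, x, alt)
            assert p >= 0.5

    @pytest.mark.parametrize("n1,n2", [(2, 2), (3, 3), (4, 4), (3, 5), (2, 6)])
    def test_exact_matches_enumeration(self, n1, n2):
        rng = np.random.default_rng(n1 * 10 + n2)
        x = rng.normal(size=n1)
        y = rng.normal(size=n2)
        for alt in ("greater", "less"):
            u, p = wilcoxon_rank_sum(x, y, alt)
            u_ref, p_ref = _enumeration_p(x, y, alt)
            assert u == pytest.approx(u_ref, abs=1e-12)
            assert p == pytest.approx(p_ref, abs=1e-12)

    def test_approximation_close_to_exact(self):
        rng = np.random.default_rng(5)
        x, y = rng.normal(size=4), rng.normal(size=4)
        _, p_exact = wilcoxon_rank_sum(x, y, "greater")
        res = stats.mannwhitneyu(x, y, alternative="greater", method="asymptotic")
        assert abs(p_exact - res.pvalue) < 0.02

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            wilcoxon_rank_sum([], [1.0], "greater")

    @given(
        x=st.lists(st.integers(-5, 5), min_size=1, max_size=8),
        y=st.lists(st.integers(-5, 5), min_size=1, max_size=8),
    )
    @settings(max_examples=150, derandomize=True, deadline=None)
    def test_rank_sum_identities(self, x, y):
        # U_x + U_y = n1*n2 with mid-ranks, and p is a valid probability
        # for either alternative, including heavily tied integer data
        ux, p_g = wilcoxon_rank_sum(x, y, "greater")
        uy, p_l = wilcoxon_rank_sum(y, x, "less")
        assert 0 < p_g <= 1 and 0 < p_l <= 1
        uy_direct, _ = wilcoxon_rank_sum(y, x, "greater")
        assert ux + uy_direct == pytest.approx(len(x) * len(y), abs=1e-9)


class TestSeparationTest:
    def test_add_one_lower_bound_and_determinism(self):
        m, annot, sig, _ = gen_stroma_dataset(
            n_genes=200, n_per_group=10, n_signature=8, effect_size=2.0, seed=3
        )
        r1 = separation_test(m, annot, sig, n_perm=99, seed=5, tumor_group="tumor")
        r2 = separation_test(m, annot, sig, n_perm=99, seed=5, tumor_group="tumor")
        assert r1.p >= 1 / 100
        assert r1.to_dict() == r2.to_dict()
        r3 = separation_test(m, annot, sig, n_perm=99, seed=6, tumor_group="tumor")
        assert r3.seed != r1.seed

    def test_planted_signal_detected(self):
        m, annot, sig, _ = gen_stroma_dataset(
            n_genes=300, n_per_group=30, n_signature=10, effect_size=1.0, seed=0
        )
        r = separation_test(m, annot, sig, n_perm=1000, seed=1, tumor_group="tumor")
        assert r.p < 0.01

    def test_flip_reverses_orientation(self):
        m, annot, sig, _ = gen_stroma_dataset(
            n_genes=300, n_per_group=20, n_signature=10, effect_size=1.5, seed=2
        )
        r = separation_test(m, annot, sig, n_perm=200, seed=1, tumor_group="normal", flip=True)
        assert r.p < 0.05  # flipping the normal orientation recovers the signal

    def test_gene_row_order_invariance(self):
        m, annot, sig, _ = gen_stroma_dataset(
            n_genes=100, n_per_group=10, n_signature=5, effect_size=1.0, seed=4
        )
        perm = np.random.default_rng(0).permutation(m.n_genes)
        shuffled = ExpressionMatrix(
            [m.gene_ids[i] for i in perm], list(m.sample_ids), m.values[perm]
        )
        r1 = separation_test(m, annot, sig, n_perm=50, seed=9, tumor_group="tumor")
        r2 = separation_test(shuffled, annot, sig, n_perm=50, seed=9, tumor_group="tumor")
        assert r1.observed_u == r2.observed_u

    def test_oversized_signature_rejected(self):
        m, annot, _, _ = gen_stroma_dataset(
            n_genes=20, n_per_group=5, n_signature=5, effect_size=0.0, seed=0
        )
        big = GeneSignature("big", [(f"g{i:02d}", "up") for i in range(20)] + [("extra", "up")])
        # 'extra' is dropped (not in matrix) so this still runs; a signature
        # demanding more genes than the universe cannot be drawn
        r = separation_test(m, annot, big, n_perm=10, seed=0, tumor_group="tumor")
        assert r.n_genes_used == 20


class TestPCAProject:
    def test_duplicated_samples_identical_coords(self):
        rng = np.random.default_rng(8)
        vals = rng.normal(size=(10, 4))
        vals = np.hstack([vals, vals[:, :1]])  # s4 duplicates s0
        m = ExpressionMatrix([f"g{i}" for i in range(10)], [f"s{j}" for j in range(5)], vals)
        sig = GeneSignature("s", [(f"g{i}", "up") for i in range(10)])
        coords = pca_project(m, sig)
        np.testing.assert_allclose(coords.loc["s0"], coords.loc["s4"], atol=1e-9)

    def test_variance_ordering(self, small_matrix):
        sig = GeneSignature("s", [(g, "up") for g in small_matrix.gene_ids[:10]])
        coords = pca_project(small_matrix, sig)
        ev = coords.attrs["explained_variance_ratio"]
        assert ev[0] >= ev[1] >= 0

    def test_matches_eigendecomposition(self):
        rng = np.random.default_rng(12)
        vals = rng.normal(size=(20, 10))
        m = ExpressionMatrix([f"g{i:02d}" for i in range(20)], [f"s{j}" for j in range(10)], vals)
        sig = GeneSignature("s", [(g, "up") for g in m.gene_ids])
        coords = pca_project(m, sig)
        # brute-force: eigendecompose the gene-space covariance of the
        # standardized matrix and project
        z = row_standardize(m)
        cov = z.values @ z.values.T
        w, v = np.linalg.eigh(cov)
        order = np.argsort(w)[::-1]
        for k in range(2):
            vec = v[:, order[k]]
            if vec[0] < 0:  # g00 is alphabetically first
                vec = -vec
            proj = vec @ z.values
            np.testing.assert_allclose(coords.iloc[:, k].to_numpy(), proj, atol=1e-6)

    def test_too_few_samples_rejected(self):
        m = ExpressionMatrix(["a", "b"], ["s1", "s2"], [[1, 2], [3, 4]])
        with pytest.raises(ValueError):
            pca_project(m, GeneSignature("s", [("a", "up"), ("b", "up")]))
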