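import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from grace.coexpression import (
    autocorrelation_profile,
    correlation_matrix,
    neighbor_count_distribution,
    pool_topk_rho,
    random_neighbor_baseline,
    spearman_rho,
    top_coexpressed,
    topk_partner_indices,
)
from grace.errors import DataError

from conftest import make_annotation, make_matrix


def spearman_oracle_no_ties(u, v):
    """1 - 6 sum(d^2) / (n (n^2-1)), valid without ties."""
    ru = np.argsort(np.argsort(u))
    rv = np.argsort(np.argsort(v))
    d = ru - rv
    n = len(u)
    return 1 - 6 * np.sum(d * d) / (n * (n * n - 1))


class TestSpearman:
    def test_monotone_transform_gives_one(self):
        u = np.array([0.1, 1.0, 2.0, 5.0, 9.0])
        assert spearman_rho(u, np.exp(u)) == pytest.approx(1.0)

    def test_reversed_order_gives_minus_one(self):
        u = np.array([3.0, 1.0, 7.0, 2.0])
        assert spearman_rho(u, -u) == pytest.approx(-1.0)

    def test_hand_enumerated_value(self):
        assert spearman_rho([1, 2, 3, 4, 5], [2, 1, 4, 3, 5]) == pytest.approx(0.8)

    def test_matches_rank_formula_oracle(self, rng):
        for _ in range(20):
            u = rng.permutation(12).astype(float)
            v = rng.permutation(12).astype(float)
            assert spearman_rho(u, v) == pytest.approx(spearman_oracle_no_ties(u, v), abs=1e-12)

    def test_constant_vector_gives_nan(self):
        assert np.isnan(spearman_rho([1, 1, 1], [1, 2, 3]))

    def test_length_mismatch_error(self):
        with pytest.raises(DataError):
            spearman_rho([1, 2, 3], [1, 2])

    @settings(max_examples=30, derandomize=True, deadline=None)
    @given(st.integers(0, 2**31 - 1))
    def test_invariant_under_strictly_monotone_transforms(self, seed):
        r = np.random.default_rng(seed)
        u = r.normal(size=15)
        v = r.normal(size=15)
        base = spearman_rho(u, v)
        assert spearman_rho(np.exp(u), v) == pytest.approx(base, abs=1e-12)
        assert spearman_rho(u, v**3) == pytest.approx(base, abs=1e-12)


class TestTopCoexpressed:
    def test_k_zero_gives_empty_table(self, rng):
        m = make_matrix(rng.normal(size=(4, 10)))
        assert len(top_coexpressed(m, "G0", 0).table) == 0

    def test_duplicated_row_ranks_first_with_rho_one(self, rng):
        vals = rng.normal(size=(5, 12))
        vals[3] = vals[0]
        m = make_matrix(vals)
        table = top_coexpressed(m, "G0", 2).table
        assert table.iloc[0]["partner"] == "G3"
        assert table.iloc[0]["rho"] == pytest.approx(1.0)

    def test_order_matches_brute_force_all_pairs(self, rng):
        vals = rng.normal(size=(6, 20))
        vals[1] += 0.8 * vals[0]
        vals[4] -= 0.5 * vals[0]
        m = make_matrix(vals)
        table = top_coexpressed(m, "G0", 5).table
        brute = sorted(
            ((spearman_rho(vals[0], vals[i]), f"G{i}") for i in range(1, 6)),
            key=lambda t: (-round(t[0], 12), t[1]),
        )
        assert list(table["partner"]) == [g for _, g in brute]
        assert np.allclose(table["rho"], [r for r, _ in brute], atol=1e-12)

    def test_query_absent_error(self, rng):
        m = make_matrix(rng.normal(size=(3, 8)))
        with pytest.raises(DataError, match="nope"):
            top_coexpressed(m, "nope", 2)

    def test_k_truncated_with_warning(self, rng, caplog):
        m = make_matrix(rng.normal(size=(4, 8)))
        with caplog.at_level("WARNING"):
            table = top_coexpressed(m, "G0", 99).table
        assert len(table) == 3 and "truncat" in caplog.text

    def test_method_tag_follows_matrix_kind(self, rng):
        vals = rng.normal(size=(3, 9))
        assert top_coexpressed(make_matrix(vals), "G0", 1).method == "standard"
        assert top_coexpressed(make_matrix(vals, kind="residual"), "G0", 1).method == "grace"

    def test_tie_break_is_lexicographic(self):
        base = np.array([1.0, 2.0, 3.0, 4.0])
        vals = np.vstack([base, base, base, -base])
        m = make_matrix(vals, gene_ids=["Gq", "Gz", "Ga", "Gneg"])
        table = top_coexpressed(m, "Gq", 3).table
        assert list(table["partner"]) == ["Ga", "Gz", "Gneg"]


class TestBlockwise:
    def test_correlation_matrix_independent_of_block_size(self, rng):
        m = make_matrix(rng.normal(size=(15, 25)))
        full = correlation_matrix(m)
        for bs in (1, 4, 7, 100):
            assert np.allclose(correlation_matrix(m, block_size=bs), full, atol=1e-12)

    def test_topk_independent_of_block_size(self, rng):
        m = make_matrix(rng.normal(size=(20, 30)))
        idx_full, _ = topk_partner_indices(m, 5)
        for bs in (3, 8):
            idx, _ = topk_partner_indices(m, 5, block_size=bs)
            assert np.array_equal(idx, idx_full)


class TestNeighborCounts:
    def test_single_chromosome_point_mass_at_k(self, rng):
        m = make_matrix(rng.normal(size=(8, 15)))
        ann = make_annotation(["chr1"] * 8)
        dist = neighbor_count_distribution(m, ann, k=3)
        assert dist.frequencies[3] == pytest.approx(1.0)

    def test_all_isolated_point_mass_at_zero(self, rng):
        m = make_matrix(rng.normal(size=(6, 15)))
        ann = make_annotation([f"chr{i}" for i in range(6)])
        dist = neighbor_count_distribution(m, ann, k=3)
        assert dist.frequencies[0] == pytest.approx(1.0)

    def test_matches_brute_force_counting(self, rng):
        n = 40
        m = make_matrix(rng.normal(size=(n, 25)))
        chroms = [f"chr{i % 5}" for i in range(n)]
        ann = make_annotation(chroms)
        dist = neighbor_count_distribution(m, ann, k=10)
        counts = np.zeros(11)
        for qi in range(n):
            rhos = sorted(
                ((spearman_rho(m.values[qi], m.values[j]), f"G{j}", j) for j in range(n) if j != qi),
                key=lambda t: (-round(t[0], 12), t[1]),
            )[:10]
            same = sum(1 for _, _, j in rhos if chroms[j] == chroms[qi])
            counts[same] += 1
        assert np.allclose(dist.frequencies, counts / n, atol=1e-12)

    def test_unannotated_gene_error(self, rng):
        m = make_matrix(rng.normal(size=(4, 10)))
        ann = make_annotation(["chr1", "chr1"], gene_ids=["G0", "G1"])
        with pytest.raises(DataError, match="G2"):
            neighbor_count_distribution(m, ann, k=2)

    def test_frequencies_sum_to_one(self, rng):
        m = make_matrix(rng.normal(size=(30, 12)))
        ann = make_annotation([f"chr{i % 4}" for i in range(30)])
        dist = neighbor_count_distribution(m, ann, k=7)
        assert dist.frequencies.sum() == pytest.approx(1.0, abs=1e-12)


class TestRandomBaseline:
    def test_single_chromosome_point_mass_at_k(self):
        ann = make_annotation(["chr1"] * 12)
        dist = random_neighbor_baseline(ann, k=4, seed=0)
        assert dist.frequencies[4] == pytest.approx(1.0)

    def test_mean_matches_hypergeometric_expectation(self):
        # one chromosome with m of G genes: E[same] = k (m-1)/(G-1)
        G, m_chr, k = 60, 20, 10
        ann = make_annotation(["chrA"] * m_chr + ["chrB"] * (G - m_chr))
        dist = random_neighbor_baseline(ann, k=k, n_draws=4000, seed=7)
        mean = float(np.arange(k + 1) @ dist.frequencies)
        # queries split between chromosomes; expectation averages over both
        expected = (m_chr * (m_chr - 1) + (G - m_chr) * (G - m_chr - 1)) / G * k / (G - 1)
        assert mean == pytest.approx(expected, abs=0.15)

    def test_seed_reproducibility(self):
        ann = make_annotation([f"chr{i % 3}" for i in range(30)])
        d1 = random_neighbor_baseline(ann, k=5, seed=11)
        d2 = random_neighbor_baseline(ann, k=5, seed=11)
        assert np.array_equal(d1.frequencies, d2.frequencies)


class TestAutocorrelation:
    def test_iid_noise_is_near_zero_everywhere(self, rng):
        m = make_matrix(rng.normal(size=(200, 40)))
        ann = make_annotation(["chr1"] * 100 + ["chr2"] * 100)
        prof = autocorrelation_profile(m, ann, max_gap=10)
        assert np.nanmax(np.abs(prof.mean_r)) < 0.15

    def test_segment_structure_decays_with_gap(self, rng):
        # constant within segments of 20 genes per sample -> high at gap 0
        n_genes, n_samples = 200, 30
        seg = rng.normal(size=(n_genes // 20, n_samples))
        vals = np.repeat(seg, 20, axis=0) + 0.1 * rng.normal(size=(n_genes, n_samples))
        m = make_matrix(vals)
        ann = make_annotation(["chr1"] * n_genes)
        prof = autocorrelation_profile(m, ann, max_gap=30)
        assert prof.mean_r[0] > prof.mean_r[30] + 0.3

    def test_gap_zero_means_adjacent_genes(self, rng):
        # even rows random, odd rows copy the previous row: adjacent pairs
        # (2i, 2i+1) correlate perfectly, pairs at gap 1 do not
        base = rng.normal(size=(10, 50))
        vals = np.repeat(base, 2, axis=0)
        m = make_matrix(vals)
        ann = make_annotation(["chr1"] * 20)
        prof = autocorrelation_profile(m, ann, max_gap=1)
        assert prof.mean_r[0] > 0.4 > abs(prof.mean_r[1])

    def test_pairs_do_not_cross_chromosomes(self, rng):
        # two chromosomes carrying anti-correlated signals: the boundary-
        # crossing pair drags pooled gap-0 correlation down if included
        a = rng.normal(size=(1, 40))
        vals = np.vstack([a, a, a, -a, -a, -a])
        m = make_matrix(vals)
        prof_one = autocorrelation_profile(m, make_annotation(["chr1"] * 6), max_gap=0)
        prof_two = autocorrelation_profile(
            m, make_annotation(["chr1"] * 3 + ["chr2"] * 3), max_gap=0
        )
        assert prof_two.mean_r[0] == pytest.approx(1.0, abs=1e-9)
        assert prof_two.mean_r[0] > prof_one.mean_r[0]


class TestPooledRho:
    def test_single_chromosome_inter_empty(self, rng):
        m = make_matrix(rng.normal(size=(8, 12)))
        ann = make_annotation(["chr1"] * 8)
        intra, inter = pool_topk_rho(m, ann, k=3)
        assert inter.size == 0 and intra.size == 8 * 3

    def test_conservation_of_entries(self, rng):
        m = make_matrix(rng.normal(size=(25, 15)))
        ann = make_annotation([f"chr{i % 6}" for i in range(25)])
        intra, inter = pool_topk_rho(m, ann, k=10)
        assert intra.size + inter.size == 25 * 10
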