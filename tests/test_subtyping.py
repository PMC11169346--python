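"""Consensus subtyping: eta2, k-means, consensus, dip/PAC selection, AP."""

import numpy as np
import pytest
from sklearn.metrics import adjusted_rand_score

from morphsev.dip import dip_pvalue, dip_statistic
from morphsev.subtyping import (
    ConsensusConfig,
    consensus_matrix,
    eta2,
    extract_clusters_ap,
    kmeans_eta2,
    pac,
    run_consensus,
    select_solution,
)


def archetype_maps(rng, n_per=10, n_arch=3, d=120, noise=0.05):
    """Well-separated planted archetypes with small iid noise."""
    arch = rng.normal(size=(n_arch, d)) * 2.0
    maps, labels = [], []
    for a in range(n_arch):
        for _ in range(n_per):
            maps.append(arch[a] + rng.normal(0, noise, d))
            labels.append(a)
    return np.asarray(maps), np.asarray(labels)


class TestEta2:
    def test_self_similarity_is_one(self, rng):
        for _ in range(5):
            v = rng.normal(size=30)
            assert eta2(v, v) == pytest.approx(1.0)

    def test_hand_computed_example(self):
        assert eta2([0, 1], [1, 0]) == pytest.approx(0.0)

    def test_numerator_is_half_squared_distance(self, rng):
        for _ in range(10):
            a, b = rng.normal(size=50), rng.normal(size=50)
            m = 0.5 * (a + b)
            num = np.sum((a - m) ** 2 + (b - m) ** 2)
            assert num == pytest.approx(0.5 * np.sum((a - b) ** 2))

    def test_symmetry_and_scale_sensitivity(self, rng):
        a, b = rng.normal(size=40), rng.normal(size=40)
        assert eta2(a, b) == pytest.approx(eta2(b, a))
        # unlike correlation, eta2 penalizes scaling
        assert eta2(a, 3 * a) < 1.0

    def test_constant_identical_pair_defined_as_one(self):
        assert eta2(np.ones(5), np.ones(5)) == 1.0

    def test_bounded_below_by_zero(self, rng):
        """num - den = -0.5 * sum(a + b - 2M)^2 <= 0, so eta2 >= 0 always."""
        worst = min(
            eta2(rng.normal(size=20), rng.normal(size=20)) for _ in range(50)
        )
        assert worst >= -1e-12
        assert eta2([1.0, 2.0, 3.0], [3.0, 2.0, 1.0]) == pytest.approx(0.0)


class TestKmeansEta2:
    def test_k_equals_n_gives_singletons(self, rng):
        x = rng.normal(size=(5, 20))
        labels = kmeans_eta2(x, 5, replicates=5, rng=0)
        assert len(set(labels.tolist())) == 5

    def test_planted_archetypes_recovered(self, rng):
        maps, truth = archetype_maps(rng)
        labels = kmeans_eta2(maps, 3, replicates=10, rng=0)
        assert adjusted_rand_score(truth, labels) == 1.0

    def test_duplicates_always_co_clustered(self, rng):
        base = rng.normal(size=(4, 30))
        x = np.vstack([base, base])  # every map duplicated
        labels = kmeans_eta2(x, 4, replicates=10, rng=1)
        assert np.array_equal(labels[:4], labels[4:])

    def test_more_clusters_than_maps_rejected(self, rng):
        with pytest.raises(ValueError):
            kmeans_eta2(rng.normal(size=(3, 10)), 4)


class TestConsensus:
    def test_separated_archetypes_give_binary_consensus(self, rng):
        maps, truth = archetype_maps(rng, n_per=6)
        m = consensus_matrix(maps, 3, n_subsamples=30, km_replicates=5, rng=0)
        same = truth[:, None] == truth[None, :]
        assert np.allclose(m[same], 1.0)
        assert np.allclose(m[~same], 0.0)

    def test_single_subsample_is_binary(self, rng):
        maps, _ = archetype_maps(rng, n_per=4)
        m = consensus_matrix(maps, 3, n_subsamples=1, km_replicates=3, rng=0)
        assert np.isin(m, [0.0, 1.0]).all()

    def test_symmetric_unit_diagonal(self, rng):
        maps = rng.normal(size=(10, 50))
        m = consensus_matrix(maps, 3, n_subsamples=10, km_replicates=3, rng=0)
        assert np.allclose(m, m.T)
        assert np.allclose(np.diag(m), 1.0)
        assert (m >= 0).all() and (m <= 1).all()


class TestDip:
    def test_nonnegative_and_floor_on_even_spacing(self):
        x = np.linspace(0, 1, 50)
        assert dip_statistic(x) == pytest.approx(1 / 100, abs=1e-12)
        assert dip_statistic(np.random.default_rng(0).random(100)) >= 0

    def test_two_point_mixture_rejected(self, rng):
        vals = np.r_[rng.normal(0.05, 0.01, 150), rng.normal(0.95, 0.01, 150)]
        _, p = dip_pvalue(vals, n_boot=100, seed=0)
        assert p < 0.05

    def test_uniform_null_p_behaves_uniformly(self):
        ps = []
        for seed in range(12):
            rng = np.random.default_rng(seed)
            ps.append(dip_pvalue(rng.random(200), n_boot=60, seed=seed)[1])
        assert np.median(ps) > 0.2
        assert min(ps) > 0.01

    def test_two_mass_sample_approaches_half_smaller_mass(self):
        """Heavily tied binary samples (perfect consensus matrices) are the
        extreme bimodal case: dip -> min(mass)/2."""
        x = np.array([0.0] * 667 + [1.0] * 333)
        assert dip_statistic(x) == pytest.approx(1 / 3 / 2, abs=1e-3)
        assert dip_statistic(np.array([0.0] * 50 + [1.0] * 50)) == pytest.approx(0.25)

    def test_too_few_values_rejected(self):
        with pytest.raises(ValueError):
            dip_statistic([1.0, 2.0, 3.0])


class TestPAC:
    def test_binary_consensus_has_zero_pac(self):
        m = np.array([[1, 0, 1], [0, 1, 0], [1, 0, 1]], dtype=float)
        assert pac(m) == 0.0

    def test_fully_ambiguous_is_one(self):
        m = np.full((4, 4), 0.5)
        np.fill_diagonal(m, 1.0)
        assert pac(m, 0.1, 0.9) == 1.0

    def test_direct_count(self):
        m = np.eye(3)
        m[0, 1] = m[1, 0] = 0.05
        m[0, 2] = m[2, 0] = 0.5
        m[1, 2] = m[2, 1] = 0.95
        assert pac(m, 0.1, 0.9) == pytest.approx(1 / 3)

    def test_invalid_bounds_rejected(self):
        with pytest.raises(ValueError):
            pac(np.eye(3), 0.9, 0.1)


class TestSelection:
    def test_only_one_qualifies(self):
        stats = {3: {"dip_p": 0.01, "pac": 0.02}, 5: {"dip_p": 0.5, "pac": 0.02}}
        k, ok = select_solution(stats)
        assert k == 3 and ok

    def test_most_complex_qualifying_solution_wins(self):
        stats = {
            k: {"dip_p": 0.01, "pac": 0.01} if k in (3, 5, 7) else {"dip_p": 0.9, "pac": 0.9}
            for k in range(3, 9)
        }
        k, ok = select_solution(stats)
        assert k == 7 and ok

    def test_fallback_to_min_pac_with_warning(self):
        stats = {3: {"dip_p": 0.5, "pac": 0.3}, 4: {"dip_p": 0.6, "pac": 0.2}}
        with pytest.warns(UserWarning):
            k, ok = select_solution(stats)
        assert k == 4 and not ok


class TestAffinityPropagation:
    def test_block_diagonal_consensus_recovered(self):
        m = np.zeros((10, 10))
        m[:5, :5] = 1.0
        m[5:, 5:] = 1.0
        labels, exemplars = extract_clusters_ap(m, 2)
        assert len(exemplars) == 2
        assert len(set(labels[:5].tolist())) == 1
        assert len(set(labels[5:].tolist())) == 1
        assert labels[0] != labels[5]

    def test_exemplars_belong_to_their_clusters(self, rng):
        maps, truth = archetype_maps(rng, n_per=5)
        m = consensus_matrix(maps, 3, n_subsamples=20, km_replicates=5, rng=0)
        labels, exemplars = extract_clusters_ap(m, 3)
        for ci, ex in enumerate(exemplars):
            assert labels[ex] == ci


class TestEndToEnd:
    def test_planted_three_archetypes_selected_and_recovered(self, rng):
        """The consensus pipeline picks k=3 with tight PAC and perfect ARI."""
        maps, truth = archetype_maps(rng, n_per=8, d=100)
        cfg = ConsensusConfig(
            k_range=(3, 6), n_subsamples=25, km_replicates=5, dip_boot=60, seed=0
        )
        run = run_consensus(maps, cfg)
        assert run.selected_k == 3
        assert run.pac[3] <= 0.05
        assert adjusted_rand_score(truth, run.labels) == 1.0
        # within-cluster eta2 exceeds between-cluster eta2
        sims = np.array([[eta2(a, b) for b in maps] for a in maps])
        same = run.labels[:, None] == run.labels[None, :]
        np.fill_diagonal(same, False)
        off = ~np.eye(len(maps), dtype=bool)
        assert sims[same].mean() > sims[off & ~same].mean()

    def test_noise_amplitude_does_not_reduce_pac_ranking(self, rng):
        """More noise never makes the true-k solution look more reliable."""
        pacs = []
        for noise in (0.05, 0.6, 1.5):
            vals = []
            for seed in range(3):
                r = np.random.default_rng(seed)
                maps, _ = archetype_maps(r, n_per=6, d=60, noise=noise)
                m = consensus_matrix(maps, 3, n_subsamples=15, km_replicates=3, rng=seed)
                vals.append(pac(m))
            pacs.append(np.mean(vals))
        assert pacs[0] <= pacs[1] + 1e-9 <= pacs[2] + 2e-2
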