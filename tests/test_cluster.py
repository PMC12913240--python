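"""Paired t maps, TFCE, sign-flip permutation machinery, cluster reporting."""

import itertools

import numpy as np
import pytest

from pairlg.cluster import (GroupData, Lattice, T_CAP, paired_t_map,
                            permutation_test, report_representative, tfce)

ADJ2 = np.array([[False, True], [True, False]])


def brute_force_tfce(m, adj, E=0.5, H=2.0, dh=1.0):
    """Literal threshold-by-threshold summation with BFS components."""
    n_ch, n_t = m.shape
    out = np.zeros_like(m, dtype=float)
    vmax = np.abs(m).max()
    for sign in (1, -1):
        for j in range(1, int(np.floor(vmax / dh + 1e-12)) + 1):
            h = dh * j
            act = (sign * m > 0) & (np.abs(m) >= h)
            seen = np.zeros_like(act)
            for i0, t0 in zip(*np.nonzero(act)):
                if seen[i0, t0]:
                    continue
                comp, queue = [], [(i0, t0)]
                seen[i0, t0] = True
                while queue:
                    a, b = queue.pop()
                    comp.append((a, b))
                    steps = [(a, b - 1), (a, b + 1)] + \
                            [(x, b) for x in range(n_ch) if adj[a, x]]
                    for c, d in steps:
                        if 0 <= d < n_t and act[c, d] and not seen[c, d]:
                            seen[c, d] = True
                            queue.append((c, d))
                for a, b in comp:
                    out[a, b] += sign * len(comp) ** E * h**H * dh
    return out


class TestPairedTMap:
    def _group(self, diffs_cell, n, shape=(2, 2), cell=(0, 0), seed=0):
        rng = np.random.default_rng(seed)
        a = rng.normal(size=(n, *shape))
        b = rng.normal(size=(n, *shape))
        a[:, cell[0], cell[1]] = b[:, cell[0], cell[1]] + np.asarray(diffs_cell)
        return GroupData(cond_a=a, cond_b=b, times=np.arange(shape[1]) * 4.0,
                         channels=tuple("ab"[: shape[0]]), adjacency=ADJ2)

    def test_hand_computed_t_value(self):
        # differences {1, 2, 0, 1}: mean 1, sd sqrt(2/3), t = 1/(sd/2) = sqrt(6)
        g = self._group([1.0, 2.0, 0.0, 1.0], n=4)
        t = paired_t_map(g)
        assert t[0, 0] == pytest.approx(np.sqrt(6.0))

    def test_identical_conditions_give_zero_map(self):
        a = np.random.default_rng(0).normal(size=(3, 2, 4))
        g = GroupData(cond_a=a, cond_b=a.copy(), times=np.arange(4.0),
                      channels=("a", "b"), adjacency=ADJ2)
        with pytest.warns(RuntimeWarning):
            t = paired_t_map(g)
        assert np.array_equal(t, np.zeros((2, 4)))

    def test_zero_variance_nonzero_mean_capped(self):
        g = self._group([1.0, 1.0, 1.0], n=3)
        with pytest.warns(RuntimeWarning):
            t = paired_t_map(g)
        assert t[0, 0] == T_CAP

    def test_single_participant_rejected(self):
        g = GroupData(cond_a=np.zeros((1, 2, 3)), cond_b=np.zeros((1, 2, 3)),
                      times=np.arange(3.0), channels=("a", "b"), adjacency=ADJ2)
        with pytest.raises(ValueError):
            paired_t_map(g)


class TestTfce:
    def test_spec_example_map(self):
        m = np.array([[2.0, 2.0, 0.0], [2.0, 0.0, 0.0]])
        out = tfce(m, ADJ2, e=0.5, h=2.0, dh=1.0)
        np.testing.assert_allclose(out, brute_force_tfce(m, ADJ2))
        # h=1 and h=2 both see the 3-point component: 2 * sqrt(3) * h^2
        assert out[0, 0] == pytest.approx(np.sqrt(3) * (1 + 4))

    def test_all_zero_map(self):
        assert not tfce(np.zeros((2, 4)), ADJ2).any()

    def test_matches_brute_force_on_random_integer_maps(self):
        rng = np.random.default_rng(1)
        for _ in range(50):
            m = rng.integers(-3, 4, size=(2, 4)).astype(float)
            np.testing.assert_allclose(tfce(m, ADJ2, dh=1.0),
                                       brute_force_tfce(m, ADJ2))

    def test_scaling_up_never_decreases_enhancement(self):
        rng = np.random.default_rng(2)
        m = rng.normal(size=(2, 4))
        lo, hi = tfce(m, ADJ2), tfce(2.5 * m, ADJ2)
        assert (np.abs(hi) >= np.abs(lo) - 1e-12).all()
        assert (np.sign(hi) == np.sign(lo)).all()

    def test_empty_map_rejected(self):
        with pytest.raises(ValueError):
            tfce(np.empty((0, 0)), ADJ2)

    def test_lattice_rejects_asymmetric_adjacency(self):
        bad = np.array([[False, True], [False, False]])
        with pytest.raises(ValueError):
            Lattice(bad, 3)


def _random_effect_group(n, n_ch=4, n_t=12, effect=1.0, seed=0):
    rng = np.random.default_rng(seed)
    adj = np.zeros((n_ch, n_ch), dtype=bool)
    for i in range(n_ch - 1):
        adj[i, i + 1] = adj[i + 1, i] = True
    a = rng.normal(size=(n, n_ch, n_t))
    b = rng.normal(size=(n, n_ch, n_t))
    a[:, 1:3, 4:11] += effect   # 2 adjacent channels x 28 ms
    return GroupData(cond_a=a, cond_b=b, times=np.arange(n_t) * 4.0,
                     channels=tuple(f"c{i}" for i in range(n_ch)), adjacency=adj)


class TestPermutationTest:
    def test_small_cohorts_enumerate_exhaustively(self):
        g = _random_effect_group(n=4, effect=3.0)
        res = permutation_test(g, n_perm=1000, seed=0)
        assert res.n_permutations == 16      # all 2^4 sign patterns

    def test_monte_carlo_close_to_enumeration(self):
        g = _random_effect_group(n=4, effect=1.5, seed=3)
        exact = permutation_test(g, n_perm=16, seed=0)
        mc = permutation_test(g, n_perm=2000, seed=1, exhaustive=False)
        assert abs(exact.p_map.min() - mc.p_map.min()) <= 0.02

    def test_sign_symmetry(self):
        g = _random_effect_group(n=6, effect=2.0, seed=4)
        flipped = GroupData(cond_a=g.cond_b, cond_b=g.cond_a, times=g.times,
                            channels=g.channels, adjacency=g.adjacency)
        r1 = permutation_test(g, n_perm=200, seed=7)
        r2 = permutation_test(flipped, n_perm=200, seed=7)
        np.testing.assert_allclose(r1.tfce_map, -r2.tfce_map)
        np.testing.assert_allclose(r1.p_map, r2.p_map)
        assert [c.polarity for c in r1.clusters] == \
               [-c.polarity for c in r2.clusters]
        assert [c.p_value for c in r1.clusters] == [c.p_value for c in r2.clusters]

    def test_reported_clusters_respect_duration_and_adjacency(self):
        for seed in range(5):
            g = _random_effect_group(n=8, effect=1.2, seed=seed)
            res = permutation_test(g, n_perm=200, seed=seed)
            for c in res.clusters:
                assert c.duration_ms >= 20.0
                assert 0 <= c.p_value <= 1
                idx = [g.channels.index(ch) for ch in c.channels]
                assert len(idx) >= 2
                assert g.adjacency[np.ix_(idx, idx)].any()

    def test_deterministic_under_seed(self):
        g = _random_effect_group(n=7, effect=1.0, seed=5)
        r1 = permutation_test(g, n_perm=150, seed=3)
        r2 = permutation_test(g, n_perm=150, seed=3)
        np.testing.assert_array_equal(r1.null_max, r2.null_max)

    def test_tiny_permutation_budget_warns(self):
        g = _random_effect_group(n=6, effect=1.0)
        with pytest.warns(RuntimeWarning):
            permutation_test(g, n_perm=50, seed=0)


class TestRepresentativeReport:
    def test_restriction_stays_within_cluster_bounds(self):
        g = _random_effect_group(n=8, effect=3.0, seed=1)
        res = permutation_test(g, n_perm=200, seed=0)
        assert res.clusters, "expected a cluster for a strong effect"
        cl = res.clusters[0]
        for ch in cl.channels:
            rep = report_representative(res, ch)
            entry = rep[res.clusters.index(cl)]
            if entry.present:
                assert entry.onset_ms >= cl.onset_ms
                assert entry.offset_ms <= cl.offset_ms
                assert cl.onset_ms <= entry.peak_latency_ms <= cl.offset_ms

    def test_channel_outside_cluster_flagged_absent(self):
        g = _random_effect_group(n=8, effect=3.0, seed=1)
        res = permutation_test(g, n_perm=200, seed=0)
        cl = res.clusters[0]
        outside = [ch for ch in g.channels if ch not in cl.channels]
        if outside:
            rep = report_representative(res, outside[0])
            assert not rep[res.clusters.index(cl)].present

    def test_unknown_channel_rejected(self):
        g = _random_effect_group(n=4, effect=2.0)
        res = permutation_test(g, n_perm=16, seed=0)
        with pytest.raises(KeyError):
            report_representative(res, "Oz")
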