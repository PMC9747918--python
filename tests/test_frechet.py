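"""Discrete Fréchet distance: DP vs exhaustive couplings, metric properties."""

import numpy as np
import pytest

from oracles import embed_points, frechet_bruteforce
from trajclust import (Trajectory, TrajectorySet, assign_by_reference,
                       discrete_frechet, pairwise_frechet)
from trajclust.cluster import reference_profiles
import pandas as pd


def _traj(values, times=None, gene="g"):
    values = np.asarray(values, dtype=float)
    if times is None:
        times = np.arange(1.0, len(values) + 1)
    return Trajectory(gene, times, values)


def _random_traj(rng, gene="g"):
    n = rng.integers(1, 6)
    times = np.sort(rng.uniform(0, 48, size=n))
    while len(np.unique(times)) < n:
        times = np.sort(rng.uniform(0, 48, size=n))
    return Trajectory(gene, times, rng.normal(0, 2, size=n))


class TestDiscreteFrechet:

    def test_identity_is_zero(self):
        rng = np.random.default_rng(0)
        for _ in range(10):
            a = _random_traj(rng)
            assert discrete_frechet(a, a) == 0.0

    def test_vertical_offset_between_flat_curves(self):
        a = _traj([0, 0, 0], times=[4, 12, 24])
        b = _traj([3, 3, 3], times=[4, 12, 24])
        assert discrete_frechet(a, b) == pytest.approx(3.0)

    def test_spike_versus_flat_matches_enumeration(self):
        a = _traj([0, 2, 0], times=[0.0, 0.5, 1.0])
        b = _traj([0, 0, 0], times=[0.0, 0.5, 1.0])
        expected = frechet_bruteforce(embed_points(a.times, a.values),
                                      embed_points(b.times, b.values))
        assert discrete_frechet(a, b) == pytest.approx(expected)

    def test_dp_equals_exhaustive_coupling_enumeration(self):
        rng = np.random.default_rng(42)
        for _ in range(250):
            a, b = _random_traj(rng), _random_traj(rng)
            scale = float(rng.choice([0.0, 0.5, 1.0]))
            expected = frechet_bruteforce(
                embed_points(a.times, a.values, scale),
                embed_points(b.times, b.values, scale))
            got = discrete_frechet(a, b, time_scale=scale)
            assert got == pytest.approx(expected, abs=1e-12)

    def test_pseudometric_on_random_triples(self):
        rng = np.random.default_rng(7)
        for _ in range(100):
            a, b, c = (_random_traj(rng) for _ in range(3))
            dab = discrete_frechet(a, b)
            dba = discrete_frechet(b, a)
            dac = discrete_frechet(a, c)
            dcb = discrete_frechet(c, b)
            assert dab >= 0
            assert dab == pytest.approx(dba, abs=1e-12)
            assert dab <= dac + dcb + 1e-9

    def test_endpoint_lower_bound(self):
        rng = np.random.default_rng(5)
        for _ in range(50):
            a, b = _random_traj(rng), _random_traj(rng)
            PA = embed_points(a.times, a.values)
            PB = embed_points(b.times, b.values)
            lb = max(np.linalg.norm(PA[0] - PB[0]),
                     np.linalg.norm(PA[-1] - PB[-1]))
            assert discrete_frechet(a, b) >= lb - 1e-12

    def test_shifting_a_flat_curve_shifts_distance_exactly(self):
        times = [4.0, 12, 24, 48]
        base = discrete_frechet(_traj([0] * 4, times), _traj([1.0] * 4, times))
        for c in (0.5, 2.0, 10.0):
            d = discrete_frechet(_traj([0] * 4, times),
                                 _traj([1.0 + c] * 4, times))
            assert d == pytest.approx(base + c)

    def test_mean_variant_basic_properties(self):
        a = _traj([0, 1, 0], times=[4, 12, 24])
        b = _traj([2, 3, 2], times=[4, 12, 24])
        assert discrete_frechet(a, a, variant="mean") == 0.0
        d1 = discrete_frechet(a, b, variant="mean")
        d2 = discrete_frechet(b, a, variant="mean")
        assert d1 == pytest.approx(d2)
        assert d1 > 0


class TestPairwise:

    def _set(self, rng, n=12, T=4):
        times = np.array([4.0, 12, 24, 48])[:T]
        vals = pd.DataFrame(rng.normal(0, 1.5, size=(n, T)),
                            index=[f"g{i}" for i in range(n)])
        return TrajectorySet(times, vals, "logfc")

    def test_matrix_matches_single_pair_calls(self):
        rng = np.random.default_rng(3)
        ts = self._set(rng)
        dm = pairwise_frechet(ts)
        for i in (0, 3, 7):
            for j in (1, 5, 11):
                single = discrete_frechet(ts.trajectory(f"g{i}"),
                                          ts.trajectory(f"g{j}"))
                assert dm.values[i, j] == pytest.approx(single, abs=1e-12)
        np.testing.assert_allclose(dm.values, dm.values.T)
        np.testing.assert_allclose(np.diag(dm.values), 0.0)

    def test_singleton_set(self):
        rng = np.random.default_rng(1)
        ts = self._set(rng, n=1)
        dm = pairwise_frechet(ts)
        assert dm.values.shape == (1, 1)
        assert dm.values[0, 0] == 0.0

    def test_blocked_computation_is_seamless(self):
        rng = np.random.default_rng(2)
        ts = self._set(rng, n=30)
        a = pairwise_frechet(ts, block=7)
        b = pairwise_frechet(ts, block=1000)
        np.testing.assert_allclose(a.values, b.values)


class TestAssignByReference:

    def _refs(self, ts, labels):
        return reference_profiles(ts, pd.Series(labels, index=ts.gene_ids))

    def test_gene_identical_to_reference_gets_it_with_zero_distance(self):
        times = np.array([4.0, 12, 24, 48])
        vals = pd.DataFrame([[0, 1, 2, 3], [5, 5, 5, 5], [0, 1, 2, 3]],
                            index=["a", "b", "probe"], dtype=float)
        ts = TrajectorySet(times, vals, "logfc")
        refs = self._refs(ts.subset(["a", "b"]), {"a": 0, "b": 1})
        out = assign_by_reference(ts, refs)
        assert out.labels["probe"] == 0
        assert out.table.loc["probe", "dist_0"] == 0.0

    def test_equidistant_tie_breaks_to_lowest_reference(self):
        times = np.array([4.0, 12.0])
        vals = pd.DataFrame([[0.0, 0.0], [2.0, 2.0], [1.0, 1.0]],
                            index=["lo", "hi", "mid"])
        ts = TrajectorySet(times, vals, "logfc")
        refs = self._refs(ts.subset(["lo", "hi"]), {"lo": 1, "hi": 3})
        out = assign_by_reference(ts, refs)
        assert out.labels["mid"] == 1

    def test_labels_equal_brute_force_argmin(self):
        rng = np.random.default_rng(9)
        times = np.array([4.0, 12, 24, 48])
        vals = pd.DataFrame(rng.normal(0, 2, size=(40, 4)),
                            index=[f"g{i}" for i in range(40)])
        ts = TrajectorySet(times, vals, "logfc")
        train = ts.subset([f"g{i}" for i in range(9)])
        labels = {f"g{i}": i % 3 for i in range(9)}
        refs = self._refs(train, labels)
        out = assign_by_reference(ts, refs)
        for g in ts.gene_ids:
            dists = [discrete_frechet(ts.trajectory(g),
                                      Trajectory("r", times,
                                                 refs.profiles.loc[c].to_numpy()))
                     for c in refs.profiles.index]
            assert out.labels[g] == refs.profiles.index[int(np.argmin(dists))]

    def test_empty_reference_set_rejected(self, template_set):
        ts, _ = template_set
        from trajclust.cluster import ReferenceProfiles
        refs = ReferenceProfiles(ts.times,
                                 pd.DataFrame(np.empty((0, 4)),
                                              columns=ts.values.columns),
                                 pd.Series(dtype=int))
        with pytest.raises(ValueError, match="empty"):
            assign_by_reference(ts, refs)
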