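import numpy as np
import pandas as pd
import pytest

import admixpipe as ap
from admixpipe.io import MISSING
from admixpipe.popdiff import DistanceMatrix, MDSConfiguration
from conftest import make_genotypes


class TestASD:
    def test_identical_and_opposite(self):
        d = np.array([[0, 1, 2], [0, 1, 2], [2, 1, 0]], dtype=np.int8)
        m = ap.asd_matrix(make_genotypes(d)).matrix
        assert m[0, 1] == 0.0
        # rows 0 and 2: |0-2|,|1-1|,|2-0| -> shares 0,1,0 -> ASD = 2/3
        assert m[0, 2] == pytest.approx(2 / 3)

    def test_opposite_homozygotes(self):
        d = np.array([[0] * 5, [2] * 5], dtype=np.int8)
        assert ap.asd_matrix(make_genotypes(d)).matrix[0, 1] == 1.0

    def test_hand_count_with_mixed_genotypes(self):
        d = np.array([[0, 1, 2], [1, 1, 0]], dtype=np.int8)
        assert ap.asd_matrix(make_genotypes(d)).matrix[0, 1] == pytest.approx(0.5)

    def test_pairwise_complete_restriction(self):
        d = np.array([[0, 1, MISSING], [MISSING, 1, 2], [0, 1, 0]], dtype=np.int8)
        m = ap.asd_matrix(make_genotypes(d)).matrix
        assert m[0, 1] == 0.0  # only the middle SNP overlaps, identical there

    def test_no_overlap_raises(self):
        d = np.array([[0, MISSING], [MISSING, 2]], dtype=np.int8)
        with pytest.raises(ValueError, match="share no genotyped"):
            ap.asd_matrix(make_genotypes(d))

    def test_metric_on_complete_data(self):
        rng = np.random.default_rng(0)
        d = rng.integers(0, 3, size=(12, 60)).astype(np.int8)
        m = ap.asd_matrix(make_genotypes(d)).matrix
        assert np.allclose(m, m.T)
        assert np.allclose(np.diag(m), 0)
        for i in range(12):
            for j in range(12):
                for k in range(12):
                    assert m[i, k] <= m[i, j] + m[j, k] + 1e-12


class TestBuildGroups:
    def _pops(self, dists, specials=None):
        n = len(dists)
        return pd.DataFrame({
            "population": [f"p{i}" for i in range(n)],
            "distance_km": dists,
            "special_group": specials or ["none"] * n,
            "exclude_from_grouping": [False] * n,
        })

    def test_gap_rule(self):
        scheme = ap.build_groups(self._pops([100.0, 150.0, 900.0]), d=350.0)
        a = scheme.assignment
        assert a["p0"] == a["p1"] != a["p2"]

    def test_single_group_when_threshold_large(self):
        scheme = ap.build_groups(self._pops([0.0, 100.0, 300.0, 450.0]), d=1e6)
        assert len(set(scheme.assignment.values())) == 1

    def test_every_population_alone_when_threshold_small(self):
        scheme = ap.build_groups(self._pops([0.0, 100.0, 300.0, 450.0]), d=1.0)
        assert len(set(scheme.assignment.values())) == 4

    def test_specials_formed_first(self):
        pops = self._pops([10.0, 20.0, 30.0], specials=["indigenous_NW", "none", "none"])
        scheme = ap.build_groups(pops, d=350.0)
        assert scheme.assignment["p0"] != scheme.assignment["p1"]
        assert scheme.assignment["p1"] == scheme.assignment["p2"]
        assert scheme.special_groups == ["indigenous_NW"]

    def test_transitive_chaining_spans_more_than_threshold(self):
        scheme = ap.build_groups(self._pops([0.0, 300.0, 600.0, 900.0]), d=350.0)
        assert len(set(scheme.assignment.values())) == 1  # 900 km end to end

    def test_invalid_threshold(self):
        with pytest.raises(ValueError):
            ap.build_groups(self._pops([1.0, 2.0]), d=0.0)


def _random_asd(rng, n, prefix="i"):
    pts = rng.normal(size=(n, 3))
    D = np.sqrt(((pts[:, None] - pts[None]) ** 2).sum(-1))
    return DistanceMatrix([f"{prefix}{k}" for k in range(n)], D, "ASD")


class TestResampledMDS:
    def test_degenerate_when_groups_small(self):
        rng = np.random.default_rng(0)
        asd = _random_asd(rng, 10)
        pops = pd.DataFrame({"population": ["x", "y"], "distance_km": [0.0, 5000.0],
                             "special_group": ["none"] * 2,
                             "exclude_from_grouping": [False] * 2})
        scheme = ap.build_groups(pops, d=350.0)
        ipops = {f"i{k}": ("x" if k < 5 else "y") for k in range(10)}
        conf, sampled, log = ap.resampled_mds(asd, scheme, ipops, n_per_group=82,
                                              replicates=5, seed=1)
        assert sorted(sampled) == sorted(asd.labels)  # everyone sampled
        assert log["rho"].nunique() == 1  # identical replicates

    def test_returned_rho_is_max_and_sizes_respected(self):
        rng = np.random.default_rng(1)
        asd = _random_asd(rng, 30)
        pops = pd.DataFrame({"population": ["x", "y"], "distance_km": [0.0, 5000.0],
                             "special_group": ["none"] * 2,
                             "exclude_from_grouping": [False] * 2})
        scheme = ap.build_groups(pops, d=350.0)
        ipops = {f"i{k}": ("x" if k < 20 else "y") for k in range(30)}
        conf, sampled, log = ap.resampled_mds(asd, scheme, ipops, n_per_group=8,
                                              replicates=20, seed=2)
        assert conf.rho == pytest.approx(log["rho"].max())
        by_pop = {"x": 0, "y": 0}
        for s in sampled:
            by_pop[ipops[s]] += 1
        assert by_pop == {"x": 8, "y": 8}

    def test_single_replicate_equals_direct_mds(self):
        rng = np.random.default_rng(2)
        asd = _random_asd(rng, 8)
        pops = pd.DataFrame({"population": ["x"], "distance_km": [0.0],
                             "special_group": ["none"],
                             "exclude_from_grouping": [False]})
        scheme = ap.build_groups(pops, d=350.0)
        ipops = {f"i{k}": "x" for k in range(8)}
        conf, sampled, _ = ap.resampled_mds(asd, scheme, ipops, n_per_group=82,
                                            replicates=1, seed=3)
        direct = ap.classical_mds(asd, dims=2)
        rows = [asd.labels.index(s) for s in sampled]
        assert np.allclose(np.abs(conf.coordinates), np.abs(direct.coordinates[rows]), atol=1e-9)


class TestProcrustes:
    def _conf(self, coords, prefix="i"):
        return MDSConfiguration([f"{prefix}{k}" for k in range(len(coords))],
                                np.asarray(coords, float), np.zeros(2), 1.0)

    def test_similarity_transform_recovered(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(25, 2))
        ang = 1.1
        R = np.array([[np.cos(ang), -np.sin(ang)], [np.sin(ang), np.cos(ang)]])
        Y = X @ R.T * 3.7 + np.array([5.0, -2.0])
        res = ap.procrustes_align(self._conf(X), self._conf(Y))
        assert res.t0 == pytest.approx(1.0, abs=1e-9)

    def test_reflection_allowed(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(15, 2))
        Y = X @ np.diag([1.0, -1.0])
        res = ap.procrustes_align(self._conf(X), self._conf(Y))
        assert res.t0 == pytest.approx(1.0, abs=1e-9)

    def test_matches_rotation_grid_brute_force(self):
        """t0 for random configs matches a brute-force search over rotation
        angle (and reflection) with optimal scaling at each angle."""
        rng = np.random.default_rng(2)
        X = rng.normal(size=(100, 2))
        Y = rng.normal(size=(100, 2))

        def norm(Z):
            Z = Z - Z.mean(0)
            return Z / np.sqrt((Z**2).sum())

        Xn, Yn = norm(X), norm(Y)
        best = np.inf
        for refl in (1.0, -1.0):
            Yr = Yn @ np.diag([1.0, refl])
            for ang in np.linspace(0, 2 * np.pi, 100_000, endpoint=False):
                R = np.array([[np.cos(ang), -np.sin(ang)], [np.sin(ang), np.cos(ang)]])
                Z = Yr @ R.T
                s = (Xn * Z).sum()  # optimal dilation for unit-norm configs
                D = 1 - s**2 if s > 0 else ((Xn - 0 * Z) ** 2).sum()
                best = min(best, D)
        res = ap.procrustes_align(self._conf(X), self._conf(Y))
        assert np.sqrt(1 - best) == pytest.approx(res.t0, abs=1e-3)

    def test_label_intersection_and_order_invariance(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(10, 2))
        ref = self._conf(X)
        # moving has extra labels and shuffled order
        order = rng.permutation(10)
        mov = MDSConfiguration([f"i{k}" for k in order] + ["extra"],
                               np.vstack([(X @ np.diag([1, -1]))[order], [[9.0, 9.0]]]),
                               np.zeros(2), 1.0)
        res = ap.procrustes_align(ref, mov)
        assert res.t0 == pytest.approx(1.0, abs=1e-9)
        assert len(res.labels) == 10

    def test_degenerate_rejected(self):
        X = np.zeros((5, 2))
        with pytest.raises(ValueError, match="degenerate"):
            ap.procrustes_align(self._conf(X), self._conf(np.random.normal(size=(5, 2))))
        with pytest.raises(ValueError, match="shared labels"):
            ap.procrustes_align(self._conf(np.random.normal(size=(4, 2))),
                                self._conf(np.random.normal(size=(4, 2)), prefix="z"))


class TestL0Test:
    def _conf(self, coords):
        return MDSConfiguration([f"i{k}" for k in range(len(coords))],
                                np.asarray(coords, float), np.zeros(2), 1.0)

    def test_label_swap_symmetry(self):
        rng = np.random.default_rng(0)
        conf = self._conf(rng.normal(size=(20, 2)))
        a = [f"i{k}" for k in range(8)]
        b = [f"i{k}" for k in range(8, 20)]
        r1 = ap.l0_test(conf, a, b, n_perm=50, seed=1)
        r2 = ap.l0_test(conf, b, a, n_perm=50, seed=1)
        assert r1.observed_l0 == pytest.approx(r2.observed_l0)

    def test_extreme_separation(self):
        rng = np.random.default_rng(1)
        pts = np.vstack([rng.normal(0, 1, (15, 2)), rng.normal(500, 1, (15, 2))])
        conf = self._conf(pts)
        a = [f"i{k}" for k in range(15)]
        b = [f"i{k}" for k in range(15, 30)]
        res = ap.l0_test(conf, a, b, n_perm=1000, seed=2)
        assert res.p_value < 0.001
        assert res.p_display.startswith("<")

    def test_interior_vs_coastal_on_study_fixture(self, study_fixture):
        g, pops, _, _ = study_fixture
        asd = ap.asd_matrix(g)
        conf = ap.classical_mds(asd, dims=2)
        ipops = {i.individual_id: i.population for i in g.individuals}
        a = [x for x in conf.labels if ipops[x].startswith("coastal")]
        b = [x for x in conf.labels if ipops[x].startswith("interior")]
        res = ap.l0_test(conf, a, b, n_perm=200, seed=3)
        assert res.p_value < 0.05

    def test_empty_group_rejected(self):
        conf = self._conf(np.random.normal(size=(4, 2)))
        with pytest.raises(ValueError):
            ap.l0_test(conf, [], ["i0"], n_perm=10)
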