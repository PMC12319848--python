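"""Sphere geometry, neural RDMs, RDM regression and the searchlight itself."""

import itertools

import numpy as np
import pytest

from readrsa.glm import ItemPatternSet
from readrsa.rdm import MEASURES, ModelRDM, rdm_vectorize
from readrsa.searchlight import (
    SearchlightRSA,
    SearchlightSpec,
    neural_rdm,
    rdm_regression,
    run_searchlight,
    sphere_offsets,
)


def brute_force_offsets(radius):
    r = int(np.ceil(radius))
    return [
        (x, y, z)
        for x in range(-r, r + 1)
        for y in range(-r, r + 1)
        for z in range(-r, r + 1)
        if x * x + y * y + z * z <= radius * radius
    ]


class TestSphereOffsets:
    @pytest.mark.parametrize("radius,count", [(0, 1), (1, 7), (2, 33), (3, 123)])
    def test_counts_match_lattice_enumeration(self, radius, count):
        offs = sphere_offsets(radius)
        assert len(offs) == count
        assert len(offs) == len(brute_force_offsets(radius))

    def test_lexicographic_and_contains_origin(self):
        offs = sphere_offsets(2)
        assert [tuple(o) for o in offs] == sorted(tuple(o) for o in offs)
        assert (0, 0, 0) in {tuple(o) for o in offs}

    def test_negative_radius(self):
        with pytest.raises(ValueError):
            sphere_offsets(-1)


class TestNeuralRDM:
    def test_duplicate_item_distance_zero(self):
        rng = np.random.default_rng(0)
        p = rng.standard_normal((4, 30))
        p[1] = p[0]
        d = neural_rdm(p)
        assert d[0, 1] == pytest.approx(0.0, abs=1e-12)

    def test_anticorrelated_distance_two(self):
        p0 = np.array([1.0, 2.0, 4.0, -1.0])
        p = np.stack([p0, -(p0 - p0.mean()) + 5.0, np.array([0.0, 1.0, 0.0, 2.0])])
        d = neural_rdm(p)
        assert d[0, 1] == pytest.approx(2.0)

    def test_matches_hand_computed_pearson(self):
        p = np.array(
            [[1.0, 2.0, 3.0, 4.0], [2.0, 1.0, 4.0, 3.0], [0.0, 5.0, 1.0, 2.0]]
        )
        d = neural_rdm(p)
        for i, j in itertools.combinations(range(3), 2):
            r = np.corrcoef(p[i], p[j])[0, 1]
            assert d[i, j] == pytest.approx(1 - r, abs=1e-12)

    def test_constant_pattern_rejected(self):
        p = np.ones((3, 5))
        with pytest.raises(ValueError):
            neural_rdm(p)


class TestRDMRegression:
    def _orthogonalish_models(self, rng, n_pairs=105, k=5):
        return rng.standard_normal((n_pairs, k))

    def test_recovers_pure_model(self):
        rng = np.random.default_rng(1)
        M = self._orthogonalish_models(rng)
        # make columns exactly orthogonal after z-scoring
        from scipy.linalg import qr

        Mz = (M - M.mean(0)) / M.std(0, ddof=1)
        Q, _ = qr(Mz, mode="economic")
        Mo = Q * np.sqrt(len(M) - 1)  # unit sample-sd orthogonal columns
        beta = rdm_regression(Mo[:, 0], Mo)
        assert np.allclose(beta, [1, 0, 0, 0, 0], atol=1e-8)

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_normal_equations_oracle(self, seed):
        rng = np.random.default_rng(seed)
        M = self._orthogonalish_models(rng)
        y = rng.standard_normal(105)
        beta = rdm_regression(y, M)
        yz = (y - y.mean()) / y.std(ddof=1)
        Mz = (M - M.mean(0)) / M.std(0, ddof=1)
        X = np.column_stack([Mz, np.ones(105)])
        oracle = np.linalg.solve(X.T @ X, X.T @ yz)[:5]
        assert np.allclose(beta, oracle, rtol=1e-6, atol=1e-10)

    def test_noise_coefficients_small(self):
        rng = np.random.default_rng(123)
        M = self._orthogonalish_models(rng)
        y = rng.standard_normal(105)
        assert np.all(np.abs(rdm_regression(y, M)) < 0.5)

    def test_collinear_models_rejected(self):
        rng = np.random.default_rng(2)
        M = self._orthogonalish_models(rng)
        M[:, 1] = 2.0 * M[:, 0] + 3.0
        with pytest.raises(np.linalg.LinAlgError):
            rdm_regression(rng.standard_normal(105), M)

    def test_zero_variance_rejected(self):
        rng = np.random.default_rng(3)
        with pytest.raises(ValueError):
            rdm_regression(np.ones(105), self._orthogonalish_models(rng))


def make_models(rng, items):
    models = {}
    for name in MEASURES:
        a = rng.standard_normal((len(items), len(items)))
        d = np.abs(a - a.T)
        np.fill_diagonal(d, 0)
        models[name] = ModelRDM(items, d, name)
    return models


def make_item_set(rng, mask, n_items=15):
    pats = rng.standard_normal((n_items, int(mask.sum())))
    pats -= pats.mean(axis=0, keepdims=True)
    items = tuple(f"w{i:02d}" for i in range(n_items))
    return ItemPatternSet(pats, items, "aloud", mask, np.eye(4), centered=True)


class TestRunSearchlight:
    def test_matches_brute_force_oracle_on_8x8x8(self):
        """Whole-volume maps equal an independent per-voxel recomputation."""
        rng = np.random.default_rng(42)
        mask = np.ones((8, 8, 8), bool)
        mask[0, 0, 0] = False  # non-trivial mask
        items = make_item_set(rng, mask)
        models = make_models(rng, items.items)
        spec = SearchlightSpec(radius=3.0, min_voxels=10)
        maps = run_searchlight(items, models, spec)

        # brute force: recompute everything from scratch per voxel
        index_vol = np.full(mask.shape, -1)
        coords = np.argwhere(mask)
        index_vol[mask] = np.arange(len(coords))
        names = list(maps)
        Mz = np.column_stack(
            [
                (lambda v: (v - v.mean()) / v.std(ddof=1))(
                    rdm_vectorize(models[m].matrix)
                )
                for m in names
            ]
        )
        X = np.column_stack([Mz, np.ones(len(Mz))])
        checked = 0
        for cx, cy, cz in coords:
            member = []
            for ox, oy, oz in brute_force_offsets(3.0):
                p = (cx + ox, cy + oy, cz + oz)
                if all(0 <= p[k] < 8 for k in range(3)) and mask[p]:
                    member.append(index_vol[p])
            local = items.patterns[:, member]
            d = 1.0 - np.corrcoef(local)
            vec = d[np.tril_indices(15, k=-1)]
            vecz = (vec - vec.mean()) / vec.std(ddof=1)
            expected = np.linalg.lstsq(X, vecz, rcond=None)[0][:5]
            for k, name in enumerate(names):
                assert maps[name][cx, cy, cz] == pytest.approx(
                    expected[k], abs=1e-8
                )
            checked += 1
        assert checked == int(mask.sum())

    def test_outside_mask_is_missing(self):
        rng = np.random.default_rng(0)
        mask = np.zeros((6, 6, 6), bool)
        mask[1:5, 1:5, 1:5] = True
        items = make_item_set(rng, mask)
        maps = run_searchlight(items, make_models(rng, items.items))
        for vol in maps.values():
            assert np.all(np.isnan(vol[~mask]))

    def test_label_permutation_equivariance(self):
        rng = np.random.default_rng(5)
        mask = np.ones((6, 6, 4), bool)
        items = make_item_set(rng, mask)
        models = make_models(rng, items.items)
        maps = run_searchlight(items, models)
        perm = rng.permutation(15)
        p_items = ItemPatternSet(
            items.patterns[perm],
            tuple(items.items[i] for i in perm),
            "aloud",
            mask,
            np.eye(4),
            centered=True,
        )
        p_models = {m: models[m].reorder(list(p_items.items)) for m in models}
        p_maps = run_searchlight(p_items, p_models)
        for m in maps:
            assert np.allclose(maps[m], p_maps[m], equal_nan=True)

    def test_scale_invariance_of_patterns(self):
        rng = np.random.default_rng(6)
        mask = np.ones((6, 6, 4), bool)
        items = make_item_set(rng, mask)
        models = make_models(rng, items.items)
        maps = run_searchlight(items, models)
        scaled = ItemPatternSet(
            items.patterns * 7.3, items.items, "aloud", mask, np.eye(4), True
        )
        maps2 = run_searchlight(scaled, models)
        for m in maps:
            assert np.allclose(maps[m], maps2[m], equal_nan=True, atol=1e-10)

    def test_min_voxel_floor_rejects_small_spheres(self):
        rng = np.random.default_rng(7)
        mask = np.zeros((9, 3, 3), bool)
        mask[:, 1, 1] = True  # a thin line: spheres have at most 7 voxels
        items = make_item_set(rng, mask)
        maps = run_searchlight(
            items, make_models(rng, items.items), SearchlightSpec(3.0, 10)
        )
        assert all(np.all(np.isnan(v)) for v in maps.values())

    def test_model_results_interface(self):
        rng = np.random.default_rng(8)
        mask = np.ones((6, 6, 4), bool)
        items = make_item_set(rng, mask)
        res = SearchlightRSA(items, make_models(rng, items.items)).fit()
        assert set(res.beta_maps) == set(MEASURES)
        assert res.condition == "aloud"
        assert "radius" in res.summary()

    def test_item_label_mismatch_rejected(self):
        rng = np.random.default_rng(9)
        mask = np.ones((5, 5, 3), bool)
        items = make_item_set(rng, mask)
        other = tuple(f"x{i}" for i in range(15))
        with pytest.raises(ValueError):
            SearchlightRSA(items, make_models(rng, other))
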