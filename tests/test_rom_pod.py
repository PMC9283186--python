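import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from scaffoldrom.rom_pod import (
    RomError,
    SnapshotSet,
    build_snapshots,
    build_variant_basis,
    corner_sampling,
    grid_sampling,
    local_center,
    pod_basis,
    quadratic_column_count,
    quadratic_expand,
    reduced_solve,
    relative_error,
    sample_grid,
    select_neighbors,
    truncation_rank,
)
from scaffoldrom.transport_fe import (
    TABLE_RANGES,
    ParameterPoint,
    picard_solve,
)


class TestSampling:
    def test_corner_count(self):
        assert len(corner_sampling()) == 64

    def test_grid_count(self):
        assert len(grid_sampling(levels=3)) == 729

    def test_levels_two_equals_corner(self):
        assert grid_sampling(levels=2) == corner_sampling()

    def test_single_range_two_points(self):
        assert sample_grid([(0.0, 1.0)], 2).shape == (2, 1)

    def test_midpoints_present(self):
        points = grid_sampling(levels=3)
        mids = [0.5 * (lo + hi) for lo, hi in TABLE_RANGES.values()]
        assert any(
            np.allclose(p.as_array(), mids) for p in points
        )

    def test_deterministic_order_and_dedup(self):
        a = [p.as_array() for p in corner_sampling()]
        b = [p.as_array() for p in corner_sampling()]
        assert np.array_equal(a, b)
        assert len({tuple(x) for x in a}) == 64

    def test_degenerate_ranges_collapse(self):
        ranges = dict(TABLE_RANGES)
        for k in ("beta", "alpha", "eta", "r"):
            lo, _ = ranges[k]
            ranges[k] = (lo, lo)
        assert len(corner_sampling(ranges)) == 4


class TestPodBasis:
    def test_rank_one(self):
        X = np.outer(np.arange(1.0, 9.0), [1.0, 2.0, 3.0])
        basis = pod_basis(X, eps=0.5)
        assert basis.k == 1

    def test_eps_zero_keeps_rank(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(8, 4)) @ np.diag([1.0, 1.0, 1.0, 0.0])
        basis = pod_basis(X, eps=0.0)
        assert basis.k == np.linalg.matrix_rank(X)

    def test_gram_matrix_oracle(self):
        # singular values against brute-force eigendecomposition of XᵀX
        rng = np.random.default_rng(42)
        X = rng.normal(size=(8, 4))
        basis = pod_basis(X, eps=0.0)
        gram_eigs = np.sort(np.linalg.eigvalsh(X.T @ X))[::-1]
        assert np.allclose(
            basis.singular_values, np.sqrt(np.clip(gram_eigs, 0, None)),
            atol=1e-10,
        )

    def test_orthonormal(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(30, 7))
        basis = pod_basis(X, eps=1e-3)
        eye = basis.U.T @ basis.U
        assert np.allclose(eye, np.eye(basis.k), atol=1e-10)

    def test_zero_matrix_error(self):
        with pytest.raises(RomError):
            pod_basis(np.zeros((5, 3)), eps=0.1)

    @settings(max_examples=50, deadline=None)
    @given(st.integers(0, 2**31 - 1), st.floats(1e-6, 0.5))
    def test_truncation_minimality(self, seed, eps):
        rng = np.random.default_rng(seed)
        s = np.sort(rng.uniform(0.1, 10.0, size=rng.integers(2, 12)))[::-1]
        k = truncation_rank(s, eps)
        total = s.sum()
        assert s[:k].sum() >= (1 - eps) * total
        if k > 1:
            assert s[: k - 1].sum() < (1 - eps) * total


class TestNeighbors:
    def _points(self):
        return np.array(
            [
                [1.0, 10.0, 10.0, 0.0, 5e-4, 0.5],
                [60.0, 10.0, 10.0, 0.0, 5e-4, 0.5],
                [30.0, 80.0, 10.0, 0.0, 5e-4, 0.5],
            ]
        )

    def test_all_neighbors(self):
        mu = ParameterPoint(30.0, 45.0, 45.0, 0.5, 1e-3, 1.25)
        sel = select_neighbors(mu, self._points(), 3)
        assert set(sel.indices) == {0, 1, 2}

    def test_training_point_distance_zero(self):
        mu = ParameterPoint.from_array(self._points()[1])
        sel = select_neighbors(mu, self._points(), 1)
        assert sel.indices[0] == 1
        assert sel.distances[0] == 0.0

    def test_normalized_ordering_differs_from_raw(self):
        # hand-computed distances with unequal range lengths: raw
        # Euclidean favours point 1 (Δr = 0.75 < Δv = 1), but after
        # normalizing by range lengths point 0 is closer
        points = np.array(
            [
                [31.0, 45.0, 45.0, 0.5, 1e-3, 1.25],  # Δv = 1 (range 59)
                [30.0, 45.0, 45.0, 0.5, 1e-3, 2.0],  # Δr = 0.75 (range 1.5)
            ]
        )
        mu = ParameterPoint(30.0, 45.0, 45.0, 0.5, 1e-3, 1.25)
        raw = np.linalg.norm(points - mu.as_array(), axis=1)
        assert raw[1] < raw[0]
        sel = select_neighbors(mu, points, 1)
        # normalized: 1/59 ≈ 0.017 vs 0.75/1.5 = 0.5
        assert sel.indices[0] == 0
        assert sel.distances[0] == pytest.approx(1.0 / 59.0)
        both = select_neighbors(mu, points, 2)
        assert both.distances[1] == pytest.approx(0.5)

    def test_too_many_neighbors(self):
        mu = ParameterPoint(30.0, 45.0, 45.0, 0.5, 1e-3, 1.25)
        with pytest.raises(RomError):
            select_neighbors(mu, self._points(), 4)


class TestLocalCenter:
    def _snapshots(self):
        rng = np.random.default_rng(5)
        raw = rng.normal(size=(10, 4))
        mean = raw.mean(axis=1)
        return SnapshotSet(
            X=raw - mean[:, None],
            mean=mean,
            mu=rng.normal(size=(4, 6)),
            mesh_fingerprint="",
        )

    def test_all_indices_reduces_to_global(self):
        snaps = self._snapshots()
        Xl, lmean = local_center(snaps, np.arange(4))
        assert np.allclose(Xl, snaps.X, atol=1e-12)
        assert np.allclose(lmean, snaps.mean, atol=1e-12)

    def test_single_neighbor_zero_column(self):
        snaps = self._snapshots()
        Xl, _ = local_center(snaps, np.array([2]))
        assert np.allclose(Xl, 0.0, atol=1e-14)

    def test_two_neighbors_antisymmetric(self):
        snaps = self._snapshots()
        Xl, _ = local_center(snaps, np.array([0, 3]))
        c0, c3 = snaps.raw(0), snaps.raw(3)
        assert np.allclose(Xl[:, 0], (c0 - c3) / 2.0, atol=1e-12)
        assert np.allclose(Xl[:, 1], (c3 - c0) / 2.0, atol=1e-12)


class TestQuadraticExpand:
    def test_single_snapshot_two_columns(self):
        X = np.array([[1.0], [2.0]])
        assert quadratic_expand(X).shape == (2, 2)

    def test_predicted_count_729(self):
        assert quadratic_column_count(729) == 266814

    def test_hand_three_columns(self):
        X = np.array([[1.0, 2.0, 3.0], [4.0, 5.0, 6.0]])
        Xq = quadratic_expand(X)
        expected = np.array(
            [
                [1, 2, 3, 1, 2, 3, 4, 6, 9],
                [4, 5, 6, 16, 20, 24, 25, 30, 36],
            ],
            dtype=float,
        )
        assert Xq.shape == (2, 9)
        assert np.array_equal(Xq, expected)

    def test_memory_cap(self):
        X = np.ones((100, 50))
        with pytest.raises(RomError, match="local variant"):
            quadratic_expand(X, memory_cap_bytes=1000)

    @given(st.integers(1, 200))
    def test_column_count_formula(self, n):
        assert quadratic_column_count(n) == 2 * n + n * (n - 1) // 2


class TestRelativeError:
    def test_identical(self):
        c = np.arange(1.0, 5.0)
        assert relative_error(c, c) == 0.0

    def test_one_percent(self):
        c = np.arange(1.0, 5.0)
        assert relative_error(1.01 * c, c) == pytest.approx(0.01, rel=1e-9)

    def test_matches_independent_norms(self):
        rng = np.random.default_rng(11)
        a, b = rng.normal(size=20), rng.normal(size=20)
        expected = np.sqrt(((a - b) ** 2).sum()) / np.sqrt((b**2).sum())
        assert relative_error(a, b) == pytest.approx(expected, rel=1e-12)

    def test_zero_reference(self):
        with pytest.raises(RomError):
            relative_error(np.ones(3), np.zeros(3))


@pytest.fixture(scope="module")
def toy_points():
    """2 varying parameters (v, r), others fixed mid-range: 4 corners."""
    ranges = dict(TABLE_RANGES)
    for k in ("gamma", "beta", "alpha", "eta"):
        lo, hi = ranges[k]
        mid = 0.5 * (lo + hi)
        ranges[k] = (mid, mid)
    return corner_sampling(ranges)


class TestBuildSnapshots:
    def test_toy_corner_snapshots(self, structured_fixture, toy_points):
        _, mesh, ops, flow = structured_fixture
        snaps = build_snapshots(mesh, toy_points, flow, ops=ops)
        assert snaps.n_snapshots == 4
        assert np.all(np.isfinite(snaps.X))
        norms = np.linalg.norm(snaps.X, axis=0)
        assert (norms > 0).all()
        # centering invariant: rows of X sum to zero over columns
        assert np.abs(snaps.X.sum(axis=1)).max() <= 1e-10 * np.linalg.norm(
            snaps.X
        )

    def test_single_snapshot_zero_column(self, structured_fixture, toy_points):
        _, mesh, ops, flow = structured_fixture
        snaps = build_snapshots(mesh, toy_points[:1], flow, ops=ops)
        assert np.allclose(snaps.X, 0.0, atol=1e-14)

    def test_identical_points_identical_columns(
        self, structured_fixture, toy_points
    ):
        _, mesh, ops, flow = structured_fixture
        snaps = build_snapshots(
            mesh, [toy_points[0], toy_points[0]], flow, ops=ops
        )
        assert np.array_equal(snaps.X[:, 0], snaps.X[:, 1])

    def test_cache_resume(self, structured_fixture, toy_points, tmp_path, monkeypatch):
        _, mesh, ops, flow = structured_fixture
        cache = tmp_path / "cache.h5"
        first = build_snapshots(
            mesh, toy_points[:2], flow, ops=ops, cache=str(cache)
        )

        def boom(*args, **kwargs):
            raise AssertionError("solver should not be called on cache hit")

        import scaffoldrom.rom_pod as rp

        monkeypatch.setattr(rp, "picard_solve", boom)
        again = rp.build_snapshots(
            mesh, toy_points[:2], flow, ops=ops, cache=str(cache)
        )
        assert np.array_equal(first.X, again.X)


class TestVariants:
    def test_local_all_equals_global(self, structured_fixture, snaps64):
        basis_g = build_variant_basis(snaps64, "global", 1e-2)
        mu = ParameterPoint(30.0, 45.0, 45.0, 0.5, 1e-3, 1.25)
        basis_l = build_variant_basis(
            snaps64, "local", 1e-2, mu=mu, n_neighbors=snaps64.n_snapshots
        )
        assert basis_l.k == basis_g.k
        # identical up to the fixed sign convention
        assert np.allclose(basis_l.U, basis_g.U, atol=1e-9)

    def test_unknown_variant(self, snaps64):
        with pytest.raises(RomError):
            build_variant_basis(snaps64, "cubic", 1e-2)

    def test_local_needs_query(self, snaps64):
        with pytest.raises(RomError, match="query"):
            build_variant_basis(snaps64, "local", 1e-2)


class TestReducedSolve:
    def test_training_point_reproduction(self, structured_fixture, snaps64):
        # α = 0 training point, untruncated basis: exact reproduction
        _, mesh, ops, flow = structured_fixture
        basis = build_variant_basis(snaps64, "global", 0.0)
        idx = next(
            i
            for i in range(snaps64.n_snapshots)
            if snaps64.mu[i][3] == 0.0
        )
        mu = snaps64.parameter_point(idx)
        rom = reduced_solve(mesh, mu, basis, flow, ops=ops)
        assert relative_error(rom.values, snaps64.raw(idx)) <= 1e-8

    def test_single_snapshot_basis_reproduction(self, structured_fixture):
        # degenerate k=1 case: one snapshot pair, queried at α=0 point
        _, mesh, ops, flow = structured_fixture
        mu = ParameterPoint(30.0, 45.0, 45.0, 0.0, 1e-3, 1.25)
        other = ParameterPoint(60.0, 45.0, 45.0, 0.0, 1e-3, 2.0)
        snaps = build_snapshots(mesh, [mu, other], flow, ops=ops)
        basis = build_variant_basis(snaps, "global", 0.0)
        assert basis.k == 1
        rom = reduced_solve(mesh, mu, basis, flow, ops=ops)
        assert relative_error(rom.values, snaps.raw(0)) <= 1e-8

    def test_midrange_accuracy(self, structured_fixture, snaps64, quiet_angles):
        _, mesh, ops, flow = structured_fixture
        basis = build_variant_basis(snaps64, "global", 1e-2)
        mu = ParameterPoint(30.0, 45.0, 45.0, 0.5, 1e-3, 1.25)
        full = picard_solve(mesh, mu, flow, ops=ops)
        rom = reduced_solve(mesh, mu, basis, flow, ops=ops)
        assert relative_error(rom.values, full.values) <= 5e-2

    def test_mesh_mismatch(self, structured_fixture, foamed_fixture, snaps64):
        _, foam_mesh, foam_ops, foam_flow = foamed_fixture
        basis = build_variant_basis(snaps64, "global", 1e-2)
        mu = ParameterPoint(30.0, 45.0, 45.0, 0.5, 1e-3, 1.25)
        with pytest.raises(RomError, match="mesh"):
            reduced_solve(foam_mesh, mu, basis, foam_flow, ops=foam_ops)
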