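import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from facetshift.diversity import (
    CommunityStack, alpha, beta_temporal, facet_maps, stack_maps,
)
from facetshift.grids import RasterGrid
from facetshift.trees import FacetTree
from facetshift.synthetic import simulate_pure_birth


def pd_brute(tree: FacetTree, present_idx):
    """Brute-force Faith-style PD: walk every branch, include it when any
    present tip descends through it."""
    total = 0.0
    sets = tree.tip_sets()
    for e in range(tree.n_nodes):
        if any(sets[e, i] for i in present_idx):
            total += tree.lengths[e]
    return total


def beta_brute(tree: FacetTree, p_idx, f_idx):
    sets = tree.tip_sets()
    a = b = c = 0.0
    for e in range(tree.n_nodes):
        on_p = any(sets[e, i] for i in p_idx)
        on_f = any(sets[e, i] for i in f_idx)
        if on_p and on_f:
            a += tree.lengths[e]
        elif on_p:
            b += tree.lengths[e]
        elif on_f:
            c += tree.lengths[e]
    tot = a + b + c
    if tot == 0:
        return 0.0, 0.0, 0.0
    return (b + c) / tot, 2 * min(b, c) / tot, abs(b - c) / tot


def stack_of(matrix, species, shape=(1, None)):
    matrix = np.atleast_2d(matrix)
    grid = RasterGrid(np.zeros((1, matrix.shape[0])), origin=(0, 50), cell_size=0.1)
    return CommunityStack(matrix, species, grid)


class TestAlpha:
    def test_matches_brute_force_on_random_subsets(self, tree20, rng):
        labels = tree20.tip_labels
        grid = RasterGrid(np.zeros((1, 200)), origin=(0, 50), cell_size=0.1)
        mat = rng.random((200, 20)) < 0.3
        stack = CommunityStack(mat, labels, grid)
        vals = alpha(stack, tree20).values.ravel()
        for cell in range(200):
            idx = np.flatnonzero(mat[cell])
            assert vals[cell] == pytest.approx(pd_brute(tree20, idx), abs=1e-12)

    def test_full_community_equals_total_tree_length(self, tree20):
        stack = stack_of(np.ones((1, 20), dtype=bool), tree20.tip_labels)
        assert alpha(stack, tree20).values[0, 0] == pytest.approx(tree20.total_length())

    def test_singleton_equals_root_to_tip_distance(self, tree20):
        mat = np.zeros((1, 20), dtype=bool)
        mat[0, 4] = True
        stack = stack_of(mat, tree20.tip_labels)
        assert alpha(stack, tree20).values[0, 0] == pytest.approx(tree20.tip_depths()[4])

    def test_without_tree_counts_species(self, tree20, rng):
        mat = rng.random((1, 20)) < 0.5
        stack = stack_of(mat, tree20.tip_labels)
        assert alpha(stack, None).values[0, 0] == mat.sum()

    def test_tree_alpha_bounded_below_by_deepest_present_tip(self, tree20, rng):
        mat = rng.random((1, 20)) < 0.4
        if not mat.any():
            mat[0, 0] = True
        stack = stack_of(mat, tree20.tip_labels)
        a = alpha(stack, tree20).values[0, 0]
        assert a >= tree20.tip_depths()[mat.ravel()].max() - 1e-12


class TestBetaTemporal:
    def test_identical_communities_score_zero(self, tree20, rng):
        v = rng.random(20) < 0.5
        assert beta_temporal(v, v, tree20) == (0.0, 0.0, 0.0)

    def test_disjoint_equal_communities_on_star_tree(self):
        star = FacetTree.star(list("abcd"))
        p = np.array([True, True, False, False])
        f = ~p
        bt, br, bh = beta_temporal(p, f, star)
        assert (bt, br, bh) == (1.0, 1.0, 0.0)

    def test_nested_future_gives_pure_richness_loss(self, tree20, rng):
        p = rng.random(20) < 0.7
        f = p & (rng.random(20) < 0.5)
        if f.sum() == p.sum():
            f[np.flatnonzero(p)[0]] = False
        bt, br, bh = beta_temporal(p, f, tree20)
        assert br == 0.0
        assert bt == pytest.approx(bh, abs=1e-15)

    def test_decomposition_identity_and_brute_force(self, tree20, rng):
        for _ in range(100):
            p = np.flatnonzero(rng.random(20) < 0.4)
            f = np.flatnonzero(rng.random(20) < 0.4)
            pv = np.isin(np.arange(20), p)
            fv = np.isin(np.arange(20), f)
            bt, br, bh = beta_temporal(pv, fv, tree20)
            ref = beta_brute(tree20, p, f)
            assert (bt, br, bh) == pytest.approx(ref, abs=1e-12)
            assert bt == pytest.approx(br + bh, abs=1e-12)

    def test_symmetric_under_time_swap(self, tree20, rng):
        p = rng.random(20) < 0.4
        f = rng.random(20) < 0.4
        assert beta_temporal(p, f, tree20) == pytest.approx(beta_temporal(f, p, tree20))

    def test_species_absent_from_both_changes_nothing(self, tree20, rng):
        p = rng.random(20) < 0.4
        f = rng.random(20) < 0.4
        p[7] = f[7] = False
        full = beta_temporal(p, f, tree20)
        keep = [lbl for i, lbl in enumerate(tree20.tip_labels) if i != 7]
        # the absent species' pendant branch contributes to no component
        sub = beta_temporal(np.delete(p, 7), np.delete(f, 7), tree20, species=keep)
        assert full == pytest.approx(sub, abs=1e-12)

    def test_both_empty_is_zero(self, tree20):
        z = np.zeros(20, dtype=bool)
        assert beta_temporal(z, z, tree20) == (0.0, 0.0, 0.0)

    @settings(max_examples=200, derandomize=True, deadline=None)
    @given(st.integers(0, 2**20 - 1), st.integers(0, 2**20 - 1), st.integers(0, 2**31 - 1))
    def test_decomposition_properties_hold_for_all_communities(self, p_bits, f_bits, tree_seed):
        """Identity, symmetry and range of the decomposition for arbitrary
        20-species communities on arbitrary pure-birth trees."""
        tree = simulate_pure_birth(20, 1.0, seed=tree_seed % 1000)
        p = np.array([(p_bits >> i) & 1 for i in range(20)], dtype=bool)
        f = np.array([(f_bits >> i) & 1 for i in range(20)], dtype=bool)
        bt, br, bh = beta_temporal(p, f, tree)
        assert bt == pytest.approx(br + bh, abs=1e-12)
        assert 0.0 <= bt <= 1.0 and br >= 0.0 and bh >= 0.0
        assert beta_temporal(f, p, tree) == pytest.approx((bt, br, bh), abs=1e-15)


class TestStackAndFacetMaps:
    def grid(self, rows=4, cols=5):
        return RasterGrid(np.zeros((rows, cols)), origin=(0, 50), cell_size=0.1)

    def binary_map(self, rng, grid, name):
        return grid.like((rng.random(grid.shape) < 0.4).astype(float), name=name)

    def test_stack_round_trips_to_maps(self, rng):
        grid = self.grid()
        maps = {f"sp{i}": self.binary_map(rng, grid, f"sp{i}") for i in range(3)}
        stack = stack_maps(maps)
        for sp, m in maps.items():
            assert np.array_equal(stack.map_for(sp).values, m.values)
        for sp in maps:
            j = stack.species.index(sp)
            assert stack.matrix[:, j].sum() == maps[sp].values.sum()

    def test_disjoint_ranges_give_row_sums_at_most_one(self):
        grid = self.grid(1, 6)
        m1 = grid.like(np.array([[1, 1, 0, 0, 0, 0.0]]))
        m2 = grid.like(np.array([[0, 0, 1, 1, 0, 0.0]]))
        m3 = grid.like(np.array([[0, 0, 0, 0, 1, 0.0]]))
        stack = stack_maps({"a": m1, "b": m2, "c": m3})
        assert set(stack.matrix.sum(axis=1)) <= {0, 1}

    def test_grid_mismatch_rejected(self, rng):
        g1, g2 = self.grid(), RasterGrid(np.zeros((4, 5)), origin=(1, 50), cell_size=0.1)
        with pytest.raises(ValueError, match="aligned"):
            stack_maps({"a": self.binary_map(rng, g1, "a"), "b": self.binary_map(rng, g2, "b")})

    def test_identical_periods_give_zero_deltas_and_betas(self, tree20, rng):
        grid = self.grid(3, 3)
        maps = {lbl: self.binary_map(rng, grid, lbl) for lbl in tree20.tip_labels[:6]}
        present = stack_maps(maps)
        future = stack_maps(maps)
        out = facet_maps(present, future, phylogenetic_tree=tree20)
        for facet in ("TD", "PD"):
            assert np.allclose(out[facet].delta_alpha.values, 0.0)
            assert np.allclose(out[facet].beta_total.values, 0.0)

    def test_one_species_added_everywhere_raises_td_by_one(self, rng):
        grid = self.grid(3, 3)
        base = {f"sp{i}": self.binary_map(rng, grid, f"sp{i}") for i in range(4)}
        newcomer_absent = grid.like(np.zeros(grid.shape))
        newcomer_present = grid.like(np.ones(grid.shape))
        present = stack_maps({**base, "new": newcomer_absent})
        future = stack_maps({**base, "new": newcomer_present})
        out = facet_maps(present, future)
        assert np.allclose(out["TD"].delta_alpha.values, 1.0)

    def test_beta_maps_match_per_cell_calls(self, tree20, rng):
        grid = self.grid(4, 4)
        labels = tree20.tip_labels[:8]
        maps_p = {lbl: self.binary_map(rng, grid, lbl) for lbl in labels}
        maps_f = {lbl: self.binary_map(rng, grid, lbl) for lbl in labels}
        present, future = stack_maps(maps_p), stack_maps(maps_f)
        out = facet_maps(present, future, phylogenetic_tree=tree20)["PD"]
        for cell in range(16):
            ref = beta_temporal(present.matrix[cell], future.matrix[cell],
                                tree20, species=labels)
            got = (out.beta_total.values.ravel()[cell],
                   out.beta_repl.values.ravel()[cell],
                   out.beta_rich.values.ravel()[cell])
            assert got == pytest.approx(ref, abs=1e-12)
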