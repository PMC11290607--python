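"""Stacked-range diversity: per-cell alpha and temporal beta across the
taxonomic (TD), functional (FD) and phylogenetic (PD) facets.

Alpha for the tree facets is Faith-style: the summed length of every branch
whose descendant tips include at least one present species (the root path is
included, so a single-species cell scores its root-to-tip distance).  The
taxonomic facet is the same computation on a unit-branch star tree, i.e. a
species count.

Temporal beta compares a cell's present and future communities on the shared
tree.  With ``a`` the branch length shared by both communities, ``b`` unique
to the present and ``c`` unique to the future:

    beta_total = (b + c) / (a + b + c)
    beta_repl  = 2 min(b, c) / (a + b + c)      (balanced replacement)
    beta_rich  = |b - c| / (a + b + c)          (net richness difference)

so ``beta_total = beta_repl + beta_rich`` by construction.  Cells empty in
both periods score 0 on all three components (and are flagged in a mask).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .grids import RasterGrid
from .trees import FacetTree

__all__ = [
    "CommunityStack", "stack_maps", "alpha", "beta_temporal",
    "alpha_maps", "beta_maps", "facet_maps", "FacetMaps",
]


@dataclass
class CommunityStack:
    """Cell x species boolean occupancy matrix on a reference grid."""

    matrix: np.ndarray  # (n_cells, n_species) bool, cells in row-major grid order
    species: list[str]
    grid: RasterGrid
    scenario: str = "current"
    period: str = "current"

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=bool)
        n_cells = self.grid.n_rows * self.grid.n_cols
        if self.matrix.shape != (n_cells, len(self.species)):
            raise ValueError("community matrix shape does not match grid/species")

    def richness_map(self) -> RasterGrid:
        return self.grid.like(self.matrix.sum(axis=1).reshape(self.grid.shape),
                              name="richness")

    def map_for(self, species: str) -> RasterGrid:
        j = self.species.index(species)
        return self.grid.like(self.matrix[:, j].reshape(self.grid.shape).astype(float),
                              name=species)


def stack_maps(binary_maps: dict[str, RasterGrid], scenario: str = "current",
               period: str = "current") -> CommunityStack:
    """Stack per-species binary range maps into a community matrix.

    All maps must share the grid; species order follows the dict order.
    """
    if not binary_maps:
        raise ValueError("no maps to stack")
    species = list(binary_maps)
    ref = binary_maps[species[0]]
    cols = []
    for sp in species:
        g = binary_maps[sp]
        if not g.same_grid(ref):
            raise ValueError(f"map for {sp!r} is not aligned with the reference grid")
        cols.append(g.values.ravel() > 0.5)
    return CommunityStack(np.column_stack(cols), species, ref,
                          scenario=scenario, period=period)


def _branch_structure(tree: FacetTree, species: list[str]):
    """Branch lengths and branch x species incidence aligned to ``species``.

    Precondition: every species is a tip of the tree (extra tips are allowed
    and simply never light up shared branches on their own).
    """
    missing = [s for s in species if s not in tree.tip_labels]
    if missing:
        raise ValueError(f"species not in tree: {missing}")
    order = [tree.tip_labels.index(s) for s in species]
    incidence = tree.tip_sets()[:, order]  # (M, n_species)
    return tree.lengths, incidence


def alpha(stack: CommunityStack, tree: FacetTree | None = None) -> RasterGrid:
    """Per-cell alpha diversity map.

    Without a tree: species count (taxonomic).  With a tree: total branch
    length of the minimal root-inclusive subtree spanning the present
    species.  Empty cells score 0.
    """
    if tree is None:
        return stack.richness_map()
    lengths, inc = _branch_structure(tree, stack.species)
    touched = stack.matrix @ inc.T.astype(np.uint8) > 0  # (cells, M)
    vals = touched @ lengths
    return stack.grid.like(vals.reshape(stack.grid.shape), name=f"alpha_{tree.kind}")


def beta_temporal(present, future, tree: FacetTree, species: list[str] | None = None):
    """Replacement/richness decomposition of temporal beta for one community.

    Parameters
    ----------
    present, future : boolean vectors over ``species`` (or over
        ``tree.tip_labels`` when ``species`` is None).
    tree : FacetTree; use a unit star tree for the taxonomic facet.

    Returns
    -------
    (beta_total, beta_repl, beta_rich)
    """
    species = list(species) if species is not None else list(tree.tip_labels)
    p = np.asarray(present, dtype=bool)
    f = np.asarray(future, dtype=bool)
    lengths, inc = _branch_structure(tree, species)
    on_p = inc[:, p].any(axis=1) if p.any() else np.zeros(len(lengths), dtype=bool)
    on_f = inc[:, f].any(axis=1) if f.any() else np.zeros(len(lengths), dtype=bool)
    a = float(lengths[on_p & on_f].sum())
    b = float(lengths[on_p & ~on_f].sum())
    c = float(lengths[on_f & ~on_p].sum())
    tot = a + b + c
    if tot == 0:
        return 0.0, 0.0, 0.0
    return (b + c) / tot, 2.0 * min(b, c) / tot, abs(b - c) / tot


@dataclass
class FacetMaps:
    """Alpha/Delta-alpha/beta maps for one facet."""

    facet: str
    alpha_present: RasterGrid
    alpha_future: RasterGrid
    delta_alpha: RasterGrid
    beta_total: RasterGrid
    beta_repl: RasterGrid
    beta_rich: RasterGrid
    both_empty: RasterGrid = None  # 1 where neither period has any species


def alpha_maps(present: CommunityStack, future: CommunityStack,
               tree: FacetTree | None, facet: str) -> tuple[RasterGrid, RasterGrid, RasterGrid]:
    a_now = alpha(present, tree)
    a_fut = alpha(future, tree)
    delta = present.grid.like(a_fut.values - a_now.values, name=f"delta_alpha_{facet}")
    a_now.name = f"alpha_{facet}_present"
    a_fut.name = f"alpha_{facet}_future"
    return a_now, a_fut, delta


def beta_maps(present: CommunityStack, future: CommunityStack,
              tree: FacetTree, facet: str) -> tuple[RasterGrid, RasterGrid, RasterGrid, RasterGrid]:
    """Vectorised per-cell beta decomposition over the whole grid."""
    if present.species != future.species:
        raise ValueError("present and future stacks must share species order")
    if not present.grid.same_grid(future.grid):
        raise ValueError("present and future stacks must share the grid")
    lengths, inc = _branch_structure(tree, present.species)
    inc_u8 = inc.T.astype(np.uint8)  # (n_species, M)
    on_p = present.matrix @ inc_u8 > 0  # (cells, M)
    on_f = future.matrix @ inc_u8 > 0
    a = (on_p & on_f) @ lengths
    b = (on_p & ~on_f) @ lengths
    c = (on_f & ~on_p) @ lengths
    tot = a + b + c
    empty = tot == 0
    safe = np.where(empty, 1.0, tot)
    b_total = np.where(empty, 0.0, (b + c) / safe)
    b_repl = np.where(empty, 0.0, 2.0 * np.minimum(b, c) / safe)
    b_rich = np.where(empty, 0.0, np.abs(b - c) / safe)
    shape = present.grid.shape
    g = present.grid
    return (
        g.like(b_total.reshape(shape), name=f"beta_total_{facet}"),
        g.like(b_repl.reshape(shape), name=f"beta_repl_{facet}"),
        g.like(b_rich.reshape(shape), name=f"beta_rich_{facet}"),
        g.like(empty.reshape(shape).astype(float), name=f"both_empty_{facet}"),
    )


def facet_maps(present: CommunityStack, future: CommunityStack,
               functional_tree: FacetTree | None = None,
               phylogenetic_tree: FacetTree | None = None) -> dict[str, FacetMaps]:
    """Alpha and beta maps for every available facet.

    TD always; FD/PD when the corresponding tree is given.  Species in the
    stacks but absent from a tree are excluded from that facet (reported in
    the returned object names would be overkill — the caller reconciles
    species via :func:`facetshift.trees.load_tree`).
    """
    out: dict[str, FacetMaps] = {}
    star = FacetTree.star(present.species)
    facets: list[tuple[str, FacetTree]] = [("TD", star)]
    if functional_tree is not None:
        facets.append(("FD", functional_tree))
    if phylogenetic_tree is not None:
        facets.append(("PD", phylogenetic_tree))
    for facet, tree in facets:
        pres, fut = present, future
        covered = [s for s in present.species if s in tree.tip_labels]
        if len(covered) != len(present.species):
            sel = np.array([s in tree.tip_labels for s in present.species])
            pres = CommunityStack(present.matrix[:, sel], covered, present.grid,
                                  present.scenario, present.period)
            fut = CommunityStack(future.matrix[:, sel], covered, future.grid,
                                 future.scenario, future.period)
        a_now, a_fut, delta = alpha_maps(pres, fut, None if facet == "TD" else tree, facet)
        bt, br, bh, empty = beta_maps(pres, fut, tree if facet != "TD" else FacetTree.star(covered), facet)
        out[facet] = FacetMaps(facet, a_now, a_fut, delta, bt, br, bh, empty)
    return out
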