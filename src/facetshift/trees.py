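"""Rooted trees with branch lengths: phylogenies and functional dendrograms.

A :class:`FacetTree` backs both tree-based diversity (Faith-style branch-length
sums) and the phylogenetic comparative methods (via the Brownian-motion
covariance matrix).  Nodes are stored in flat arrays — tips first — which makes
the branch x tip incidence structure needed by the diversity metrics cheap to
build and easy to test against brute force.

Newick parsing/writing goes through dendropy.
"""

from __future__ import annotations

import io

import numpy as np

__all__ = ["FacetTree", "load_tree", "build_dendrogram"]


class FacetTree:
    """Rooted tree with non-negative branch lengths.

    Attributes
    ----------
    parent : (M,) int array; parent node index, -1 for the root.
    lengths : (M,) float array; length of the edge above each node (0 at the
        root unless the source Newick carried a root edge).
    tip_labels : list of str, the first ``n_tips`` node indices in order.
    kind : "phylogenetic", "functional" or "star".
    """

    def __init__(self, parent, lengths, tip_labels, kind: str = "phylogenetic"):
        self.parent = np.asarray(parent, dtype=int)
        self.lengths = np.asarray(lengths, dtype=float)
        self.tip_labels = list(tip_labels)
        self.kind = kind
        self._validate()
        self._tip_sets: np.ndarray | None = None

    # ------------------------------------------------------------- validation
    def _validate(self) -> None:
        m = self.parent.size
        if self.lengths.size != m:
            raise ValueError("parent and lengths must have equal size")
        if len(set(self.tip_labels)) != len(self.tip_labels):
            dupes = sorted({t for t in self.tip_labels if self.tip_labels.count(t) > 1})
            raise ValueError(f"duplicate tip labels: {dupes}")
        if np.any(self.lengths < 0) or not np.all(np.isfinite(self.lengths)):
            raise ValueError("branch lengths must be finite and non-negative")
        if (self.parent == -1).sum() != 1:
            raise ValueError("tree must have exactly one root")
        # children of earlier indices must have larger indices than... no such
        # constraint; but parents must be valid indices
        nonroot = self.parent[self.parent != -1]
        if nonroot.size and (nonroot.min() < 0 or nonroot.max() >= m):
            raise ValueError("invalid parent indices")

    # -------------------------------------------------------------- structure
    @property
    def n_tips(self) -> int:
        return len(self.tip_labels)

    @property
    def n_nodes(self) -> int:
        return self.parent.size

    @property
    def root(self) -> int:
        return int(np.flatnonzero(self.parent == -1)[0])

    def total_length(self) -> float:
        return float(self.lengths.sum())

    def node_depths(self) -> np.ndarray:
        """Distance from the root to each node (root depth 0 plus any root
        edge length)."""
        depths = np.zeros(self.n_nodes)
        order = self._topo_order()
        for u in order:
            p = self.parent[u]
            depths[u] = self.lengths[u] + (depths[p] if p != -1 else 0.0)
        return depths

    def _topo_order(self) -> list[int]:
        """Nodes ordered root -> leaves."""
        children: list[list[int]] = [[] for _ in range(self.n_nodes)]
        for u, p in enumerate(self.parent):
            if p != -1:
                children[p].append(u)
        order, stack = [], [self.root]
        while stack:
            u = stack.pop()
            order.append(u)
            stack.extend(children[u])
        return order

    def tip_depths(self) -> np.ndarray:
        return self.node_depths()[: self.n_tips]

    def is_ultrametric(self, tol: float = 1e-6) -> bool:
        d = self.tip_depths()
        return bool(np.ptp(d) <= tol)

    def tip_sets(self) -> np.ndarray:
        """(M, n_tips) boolean incidence: entry (e, j) is True iff tip j
        descends through the edge above node e (edges are identified with the
        node below them).  Row e of this matrix is exactly the set of tips
        whose root path uses branch e."""
        if self._tip_sets is None:
            m, n = self.n_nodes, self.n_tips
            sets = np.zeros((m, n), dtype=bool)
            sets[np.arange(n), np.arange(n)] = True
            for u in reversed(self._topo_order()):  # leaves -> root
                p = self.parent[u]
                if p != -1:
                    sets[p] |= sets[u]
            self._tip_sets = sets
        return self._tip_sets

    def ancestor_edges(self) -> np.ndarray:
        """(M, M) boolean: entry (u, e) True iff edge e lies on the root path
        of node u (including u's own edge)."""
        m = self.n_nodes
        anc = np.zeros((m, m), dtype=bool)
        for u in self._topo_order():
            p = self.parent[u]
            if p != -1:
                anc[u] = anc[p]
            anc[u, u] = True
        return anc

    def cov_matrix(self) -> np.ndarray:
        """Brownian-motion covariance among tips: shared root-path length.

        ``C[i, j]`` is the summed length of branches on the root paths of both
        tip i and tip j (= depth of their most recent common ancestor); the
        diagonal holds root-to-tip distances.
        """
        b = self.tip_sets().astype(float)
        return b.T @ (self.lengths[:, None] * b)

    # ----------------------------------------------------------- construction
    @classmethod
    def star(cls, tip_labels, branch_length: float = 1.0, kind: str = "star") -> "FacetTree":
        """Star tree: every tip hangs directly off the root with equal branch
        lengths.  With unit branches, tree-based diversity metrics reduce to
        species counts."""
        n = len(tip_labels)
        parent = np.concatenate([np.full(n, n), [-1]])
        lengths = np.concatenate([np.full(n, float(branch_length)), [0.0]])
        return cls(parent, lengths, tip_labels, kind=kind)

    @classmethod
    def from_linkage(cls, z: np.ndarray, labels, kind: str = "functional") -> "FacetTree":
        """Tree from a scipy linkage matrix.

        Merge at distance d places the new node at height d/2 (so the
        cophenetic distance between tips joined there is d); each branch length
        is parent height minus child height.  For UPGMA on ultrametric input
        this reproduces the input distances exactly.  Non-monotone linkages
        (possible with e.g. centroid linkage) would give negative branch
        lengths and are rejected.
        """
        z = np.asarray(z, dtype=float)
        n = len(labels)
        if z.shape != (n - 1, 4) and z.shape != (n - 1, 3):
            raise ValueError("linkage matrix does not match label count")
        m = 2 * n - 1
        parent = np.full(m, -1, dtype=int)
        heights = np.zeros(m)
        for i in range(n - 1):
            a, b_, d = int(z[i, 0]), int(z[i, 1]), z[i, 2]
            node = n + i
            parent[a] = node
            parent[b_] = node
            heights[node] = d / 2.0
        lengths = np.zeros(m)
        for u in range(m):
            if parent[u] != -1:
                lengths[u] = heights[parent[u]] - heights[u]
        if np.any(lengths < -1e-12):
            raise ValueError("non-monotone linkage: negative branch lengths")
        lengths = np.clip(lengths, 0.0, None)
        return cls(parent, lengths, list(labels), kind=kind)

    @classmethod
    def from_newick(cls, text: str, kind: str = "phylogenetic") -> "FacetTree":
        import dendropy

        try:
            dtree = dendropy.Tree.get(data=text, schema="newick")
        except Exception as exc:  # dendropy raises several parse error types
            raise ValueError(f"malformed Newick: {exc}") from exc
        return cls.from_dendropy(dtree, kind=kind)

    @classmethod
    def from_dendropy(cls, dtree, kind: str = "phylogenetic") -> "FacetTree":
        nodes = list(dtree.preorder_node_iter())
        tips = [nd for nd in nodes if nd.is_leaf()]
        internals = [nd for nd in nodes if not nd.is_leaf()]
        labels = [nd.taxon.label if nd.taxon else "" for nd in tips]
        if any(lbl == "" for lbl in labels):
            raise ValueError("tree has unlabelled tips")
        index = {id(nd): i for i, nd in enumerate(tips)}
        index.update({id(nd): len(tips) + j for j, nd in enumerate(internals)})
        m = len(nodes)
        parent = np.full(m, -1, dtype=int)
        lengths = np.zeros(m)
        for nd in nodes:
            i = index[id(nd)]
            if nd.parent_node is not None:
                parent[i] = index[id(nd.parent_node)]
            el = nd.edge.length
            lengths[i] = float(el) if el is not None else 0.0
        return cls(parent, lengths, labels, kind=kind)

    # ---------------------------------------------------------------- editing
    def prune(self, keep_labels) -> "FacetTree":
        """Subtree induced on the given tips (root kept; unary internal nodes
        collapsed, their branch lengths merged)."""
        keep = [lbl for lbl in self.tip_labels if lbl in set(keep_labels)]
        if len(keep) < 1:
            raise ValueError("prune would remove every tip")
        keep_idx = {self.tip_labels.index(lbl) for lbl in keep}
        sets = self.tip_sets()
        alive = np.array([bool(sets[u, list(keep_idx)].any()) for u in range(self.n_nodes)])

        # map each alive node to its nearest alive "real" ancestor, collapsing
        # unary chains by merging lengths.
        children: list[list[int]] = [[] for _ in range(self.n_nodes)]
        for u, p in enumerate(self.parent):
            if p != -1 and alive[u]:
                children[p].append(u)

        new_parent: list[int] = []
        new_lengths: list[float] = []
        new_labels: list[str] = []
        node_map: dict[int, int] = {}

        def build(u: int, extra_len: float, parent_new: int) -> None:
            kids = children[u] if alive[u] else []
            is_tip = u < self.n_tips
            if not is_tip and len(kids) == 1:
                # unary internal node: collapse into the child edge
                build(kids[0], extra_len + self.lengths[kids[0]], parent_new)
                return
            idx = len(new_parent)
            node_map[u] = idx
            new_parent.append(parent_new)
            new_lengths.append(extra_len)
            if is_tip:
                new_labels.append(self.tip_labels[u])
            for k in kids:
                build(k, self.lengths[k], idx)

        root = self.root
        # descend past unary chains at the root as well, zeroing the stem
        u = root
        while not (u < self.n_tips) and sum(1 for k in children[u] if alive[k]) == 1 and alive[u]:
            u = next(k for k in children[u] if alive[k])
        build(u, 0.0, -1)

        # reorder: tips first, preserving original tip order
        tip_positions = [node_map[self.tip_labels.index(lbl)] for lbl in keep]
        others = [i for i in range(len(new_parent)) if i not in set(tip_positions)]
        perm = tip_positions + others
        inv = {old: new for new, old in enumerate(perm)}
        parent_arr = np.array([inv[new_parent[old]] if new_parent[old] != -1 else -1
                               for old in perm])
        lengths_arr = np.array([new_lengths[old] for old in perm])
        return FacetTree(parent_arr, lengths_arr, keep, kind=self.kind)

    # ------------------------------------------------------------------- I/O
    def to_newick(self) -> str:
        children: list[list[int]] = [[] for _ in range(self.n_nodes)]
        for u, p in enumerate(self.parent):
            if p != -1:
                children[p].append(u)

        out = io.StringIO()

        def write(u: int) -> None:
            if u < self.n_tips:
                out.write(self.tip_labels[u].replace(" ", "_"))
            else:
                out.write("(")
                for i, k in enumerate(children[u]):
                    if i:
                        out.write(",")
                    write(k)
                out.write(")")
            if self.parent[u] != -1:
                out.write(f":{self.lengths[u]:.10g}")

        write(self.root)
        out.write(";")
        return out.getvalue()


def load_tree(newick_text: str, community=None, kind: str = "phylogenetic"):
    """Parse and validate a Newick tree; optionally reconcile it with a
    community species list.

    Returns ``(tree, report)`` where ``report`` is a dict with keys
    ``missing_from_tree`` (community species with no tip — excluded from
    tree-based facets, as happens when sequence data are lacking) and
    ``pruned_tips`` (tips not in the community, removed).  With
    ``community=None`` the report is empty and the full tree is returned.
    """
    tree = FacetTree.from_newick(newick_text, kind=kind)
    report = {"missing_from_tree": [], "pruned_tips": []}
    if community is not None:
        community = list(community)
        tips = set(tree.tip_labels)
        report["missing_from_tree"] = sorted(set(community) - tips)
        report["pruned_tips"] = sorted(tips - set(community))
        usable = [s for s in community if s in tips]
        if not usable:
            raise ValueError("no community species present in the tree")
        if report["pruned_tips"]:
            tree = tree.prune(usable)
    return tree, report


def build_dendrogram(dissimilarity: np.ndarray, labels, linkage_method: str = "average"):
    """Functional dendrogram from a dissimilarity matrix.

    Agglomerative clustering (default UPGMA/average linkage); merge heights
    become node heights (see :meth:`FacetTree.from_linkage`).
    """
    from scipy.cluster.hierarchy import linkage
    from scipy.spatial.distance import squareform

    d = np.asarray(dissimilarity, dtype=float)
    if d.ndim != 2 or d.shape[0] != d.shape[1]:
        raise ValueError("dissimilarity must be square")
    if d.shape[0] < 2:
        raise ValueError("need at least two species to build a dendrogram")
    if not np.allclose(d, d.T):
        raise ValueError("dissimilarity must be symmetric")
    z = linkage(squareform(d, checks=False), method=linkage_method)
    return FacetTree.from_linkage(z, labels, kind="functional")
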