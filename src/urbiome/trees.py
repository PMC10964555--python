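"""Rooted phylogenies with branch lengths, plus the traversal products the
diversity and null-model code needs.

A :class:`PhyloTree` wraps a dendropy tree and caches two derived objects:

* an *edge table* — for every edge, its length and the set of tips that
  descend from it.  Faith PD and both UniFrac variants are sums over this
  table.
* the *patristic matrix* — all pairwise tip-to-tip path lengths, computed
  from the edge table as ``d(i,j) = depth_i + depth_j - 2 * shared(i,j)``
  where ``shared`` is the branch length common to both root paths.

Tip order is fixed at construction and shared by every derived array, so a
sample's composition can be handled as a plain numpy vector.
"""

from __future__ import annotations

import io

import dendropy
import numpy as np

__all__ = ["PhyloTree"]


class PhyloTree:
    """A rooted tree with branch lengths and uniquely labelled tips."""

    def __init__(self, tree: dendropy.Tree):
        self._tree = tree
        labels = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
        if len(set(labels)) != len(labels):
            raise ValueError("tip labels are not unique")
        self.tip_labels: list[str] = labels
        self._tip_index = {lab: i for i, lab in enumerate(labels)}
        self._edge_lengths: np.ndarray | None = None
        self._edge_tips: np.ndarray | None = None
        self._patristic: np.ndarray | None = None

    # ---------------------------------------------------------------- io
    @classmethod
    def from_newick(cls, newick: str) -> "PhyloTree":
        tree = dendropy.Tree.get(data=newick, schema="newick")
        return cls(tree)

    @classmethod
    def read(cls, path) -> "PhyloTree":
        with open(path) as fh:
            return cls.from_newick(fh.read())

    def to_newick(self) -> str:
        s = io.StringIO()
        self._tree.write(file=s, schema="newick", suppress_rooting=True)
        return s.getvalue().strip()

    def write(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(self.to_newick() + "\n")

    # ------------------------------------------------------------ basics
    @property
    def n_tips(self) -> int:
        return len(self.tip_labels)

    def tip_indices(self, labels) -> np.ndarray:
        try:
            return np.array([self._tip_index[l] for l in labels], dtype=int)
        except KeyError as exc:
            raise KeyError(f"tip label not in tree: {exc.args[0]!r}") from None

    # -------------------------------------------------------- edge table
    def _build_edges(self) -> None:
        lengths = []
        masks = []
        n = self.n_tips
        # postorder: accumulate descendant-tip masks bottom-up
        node_mask: dict[int, np.ndarray] = {}
        for node in self._tree.postorder_node_iter():
            if node.is_leaf():
                m = np.zeros(n, dtype=bool)
                m[self._tip_index[node.taxon.label]] = True
            else:
                m = np.zeros(n, dtype=bool)
                for ch in node.child_nodes():
                    m |= node_mask[id(ch)]
            node_mask[id(node)] = m
            if node.parent_node is not None:
                lengths.append(node.edge.length or 0.0)
                masks.append(m)
        self._edge_lengths = np.asarray(lengths, dtype=float)
        self._edge_tips = np.array(masks, dtype=bool)

    def edge_table(self) -> tuple[np.ndarray, np.ndarray]:
        """Return ``(lengths, tip_incidence)``.

        ``lengths`` has one entry per edge (root edge excluded);
        ``tip_incidence`` is a boolean (n_edges, n_tips) matrix marking the
        tips descending from each edge.
        """
        if self._edge_lengths is None:
            self._build_edges()
        return self._edge_lengths, self._edge_tips

    # --------------------------------------------------------- patristic
    def patristic_matrix(self) -> np.ndarray:
        """All pairwise tip-to-tip path lengths, in ``tip_labels`` order."""
        if self._patristic is None:
            lengths, inc = self.edge_table()
            weighted = inc * lengths[:, None]          # (E, n)
            shared = inc.T.astype(float) @ weighted    # shared[i,j]
            depth = np.diag(shared).copy()
            self._patristic = depth[:, None] + depth[None, :] - 2.0 * shared
            np.fill_diagonal(self._patristic, 0.0)
        return self._patristic

    def total_branch_length(self) -> float:
        lengths, _ = self.edge_table()
        return float(lengths.sum())
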