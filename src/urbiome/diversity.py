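"""Alpha and beta diversity at taxonomic, phylogenetic and functional level.

Alpha: richness, Shannon entropy (nats), Faith phylogenetic diversity,
mean nearest-taxon distance (MNTD) and its standardized effect size, the
Nearest Taxon Index (NTI).  Beta: Bray-Curtis, presence Jaccard, and
unweighted / normalized weighted UniFrac.

NTI sign convention: ``NTI = -(MNTD_obs - mean(MNTD_null)) / sd(MNTD_null)``
so phylogenetic *clustering* (co-occurring taxa closer than chance) gives
NTI > 2 and overdispersion gives NTI < -2.  The null shuffles tip labels on
the patristic distance matrix ("taxa labels" randomization).
"""

from __future__ import annotations

import itertools
import math

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

from .trees import PhyloTree

__all__ = [
    "richness",
    "shannon",
    "faith_pd",
    "mntd",
    "nti",
    "functional_richness",
    "alpha_table",
    "beta_matrix",
]

BETA_METRICS = (
    "bray_curtis",
    "jaccard",
    "unweighted_unifrac",
    "weighted_unifrac_normalized",
)


def _as_array(row) -> np.ndarray:
    return np.asarray(row, dtype=float).ravel()


def richness(sample_row) -> int:
    """Number of features with abundance > 0."""
    return int(np.count_nonzero(_as_array(sample_row) > 0))


def shannon(sample_row) -> float:
    """Shannon entropy in nats, over renormalized positive entries."""
    x = _as_array(sample_row)
    x = x[x > 0]
    if x.size == 0:
        raise ValueError("all-zero sample")
    p = x / x.sum()
    return float(-(p * np.log(p)).sum())


functional_richness = richness  # same count, applied to a function table row


def _present_indices(sample_row, tree: PhyloTree) -> np.ndarray:
    if isinstance(sample_row, pd.Series):
        present = sample_row[sample_row > 0].index
        missing = [p for p in present if p not in set(tree.tip_labels)]
        if missing:
            raise KeyError(f"features not in tree: {missing[:5]}")
        return tree.tip_indices(present)
    x = _as_array(sample_row)
    if x.size != tree.n_tips:
        raise ValueError("row length does not match number of tips")
    return np.flatnonzero(x > 0)


def faith_pd(sample_row, tree: PhyloTree, include_root: bool = True) -> float:
    """Faith phylogenetic diversity of the tips present in the sample.

    Sum of branch lengths of the union of root-to-tip paths over present
    tips (the default keeps the path to the root; ``include_root=False``
    restricts to branches below the MRCA of the present set).
    """
    idx = _present_indices(sample_row, tree)
    if idx.size == 0:
        return 0.0
    lengths, inc = tree.edge_table()
    covered = inc[:, idx].any(axis=1)
    if not include_root:
        # drop edges on the path above the MRCA: those covering *all*
        # present tips while being ancestral (cover set equals present set
        # superset and the edge covers every present tip)
        covers_all = inc[:, idx].all(axis=1)
        covered = covered & ~covers_all if idx.size > 1 else covered
    return float(lengths[covered].sum())


def mntd(sample_row, tree: PhyloTree, abundance_weighted: bool = False) -> float:
    """Mean distance from each present tip to its nearest present neighbor."""
    idx = _present_indices(sample_row, tree)
    if idx.size < 2:
        raise ValueError("MNTD needs at least 2 present tips")
    D = tree.patristic_matrix()[np.ix_(idx, idx)].copy()
    np.fill_diagonal(D, np.inf)
    nearest = D.min(axis=1)
    if abundance_weighted:
        w = _as_array(
            sample_row[sample_row > 0] if isinstance(sample_row, pd.Series)
            else np.asarray(sample_row)[idx]
        )
        w = w / w.sum()
        return float((nearest * w).sum())
    return float(nearest.mean())


def _mntd_from_matrix(D: np.ndarray, idx: np.ndarray, w: np.ndarray | None) -> float:
    sub = D[np.ix_(idx, idx)].copy()
    np.fill_diagonal(sub, np.inf)
    nearest = sub.min(axis=1)
    if w is None:
        return float(nearest.mean())
    return float((nearest * w).sum())


def nti(
    sample_row,
    tree: PhyloTree,
    n_null: int = 999,
    seed: int | None = None,
    abundance_weighted: bool = False,
    exhaustive: bool = False,
) -> float:
    """Nearest Taxon Index: -SES(MNTD) under tip-label randomization.

    ``exhaustive=True`` enumerates every tip-label permutation instead of
    Monte-Carlo sampling (only feasible on very small trees).
    """
    idx = _present_indices(sample_row, tree)
    if idx.size < 2:
        raise ValueError("NTI needs at least 2 present tips")
    if not exhaustive and n_null < 100:
        raise ValueError("n_null must be >= 100")
    D = tree.patristic_matrix()
    if abundance_weighted:
        w = _as_array(
            sample_row[sample_row > 0] if isinstance(sample_row, pd.Series)
            else np.asarray(sample_row)[idx]
        )
        w = w / w.sum()
    else:
        w = None
    obs = _mntd_from_matrix(D, idx, w)
    n = tree.n_tips
    if exhaustive:
        if math.factorial(n) > 500_000:
            raise ValueError("exhaustive null infeasible for this tree size")
        nulls = np.array(
            [
                _mntd_from_matrix(D[np.ix_(perm, perm)], idx, w)
                for perm in itertools.permutations(range(n))
            ]
        )
    else:
        rng = np.random.default_rng(seed)
        nulls = np.empty(n_null)
        for b in range(n_null):
            perm = rng.permutation(n)
            nulls[b] = _mntd_from_matrix(D[np.ix_(perm, perm)], idx, w)
    sd = nulls.std(ddof=1)
    if sd == 0 or not np.isfinite(sd):
        raise FloatingPointError("null distribution has zero spread")
    return float(-(obs - nulls.mean()) / sd)


def alpha_table(
    table: pd.DataFrame,
    tree: PhyloTree | None = None,
    functions: pd.DataFrame | None = None,
    n_null: int = 999,
    seed: int | None = None,
) -> pd.DataFrame:
    """Per-sample alpha diversity records.

    Columns: richness, shannon and, when a tree (resp. function table) is
    supplied, faith_pd and nti (resp. functional_richness).
    """
    rng = np.random.default_rng(seed)
    rows = {}
    for sample, row in table.iterrows():
        rec = {"richness": richness(row), "shannon": shannon(row)}
        if tree is not None:
            rec["faith_pd"] = faith_pd(row, tree)
            rec["nti"] = nti(row, tree, n_null=n_null, seed=int(rng.integers(2**31)))
        if functions is not None:
            rec["functional_richness"] = richness(functions.loc[sample])
        rows[sample] = rec
    return pd.DataFrame.from_dict(rows, orient="index")


# ------------------------------------------------------------------- beta
def _unifrac_matrices(table: pd.DataFrame, tree: PhyloTree):
    idx = tree.tip_indices(table.columns)
    lengths, inc = tree.edge_table()
    inc = inc[:, idx]  # align edge incidence to table column order
    props = table.div(table.sum(axis=1), axis=0).to_numpy()
    edge_prop = inc.astype(float) @ props.T          # (E, n_samples)
    edge_pres = (inc.astype(float) @ (table.to_numpy().T > 0)) > 0
    return lengths, edge_prop, edge_pres


def beta_matrix(
    table: pd.DataFrame, metric: str, tree: PhyloTree | None = None
) -> pd.DataFrame:
    """Pairwise sample dissimilarity matrix.

    ``metric`` is one of ``bray_curtis``, ``jaccard`` (on presence),
    ``unweighted_unifrac`` or ``weighted_unifrac_normalized`` (the
    [0,1]-bounded weighted variant); the UniFrac metrics require ``tree``.
    """
    if metric not in BETA_METRICS:
        raise ValueError(f"unknown metric {metric!r}")
    samples = table.index
    if metric == "bray_curtis":
        D = squareform(pdist(table.to_numpy(dtype=float), metric="braycurtis"))
    elif metric == "jaccard":
        D = squareform(
            pdist((table.to_numpy() > 0).astype(float), metric="jaccard")
        )
    else:
        if tree is None:
            raise ValueError("UniFrac metrics require a tree")
        lengths, edge_prop, edge_pres = _unifrac_matrices(table, tree)
        n = table.shape[0]
        D = np.zeros((n, n))
        for i in range(n):
            for j in range(i + 1, n):
                if metric == "unweighted_unifrac":
                    a, b = edge_pres[:, i], edge_pres[:, j]
                    union = lengths[a | b].sum()
                    uniq = lengths[a ^ b].sum()
                    D[i, j] = D[j, i] = uniq / union if union > 0 else 0.0
                else:
                    pa, pb = edge_prop[:, i], edge_prop[:, j]
                    den = (lengths * (pa + pb)).sum()
                    num = (lengths * np.abs(pa - pb)).sum()
                    D[i, j] = D[j, i] = num / den if den > 0 else 0.0
    D = np.maximum(D, 0.0)
    np.fill_diagonal(D, 0.0)
    return pd.DataFrame(D, index=samples, columns=samples)
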