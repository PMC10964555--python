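"""Distance-based inferential statistics: PERMANOVA, multivariate
dispersion (PERMDISP), distance-based RDA with forward selection, pairwise
post-hoc tests and (partial) Mantel correlations.

All permutation p-values use the add-one estimator
``p = (1 + #{perm >= obs}) / (1 + n_perm)`` and are reproducible given a
seed.  Sums of squares are computed from squared distances through the
Gower-centered inner-product matrix ``G = -1/2 J D^2 J``; for a projection
``H`` onto (centered) explanatory variables the explained sum of squares is
``tr(HG)`` and the pseudo-F follows with the usual degrees of freedom.

Negative eigenvalues of non-Euclidean distance matrices are handled in two
deliberately different, documented ways: the dispersion test keeps the
imaginary axes and subtracts their squared contribution (vegan's
betadisper convention) while db-RDA applies a Lingoes additive constant so
all axes are real.
"""

from __future__ import annotations

import dataclasses
import itertools
import warnings

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

__all__ = [
    "PermutationTestResult",
    "permanova",
    "betadisper",
    "pcoa",
    "dbrda",
    "forward_select",
    "pairwise_permanova",
    "mantel",
    "partial_mantel",
]


@dataclasses.dataclass
class PermutationTestResult:
    name: str
    statistic: float
    r2: float | None
    n_permutations: int
    p: float
    df: tuple[int, int] | None = None


def _as_square(D) -> np.ndarray:
    A = np.asarray(D, dtype=float)
    if A.ndim != 2 or A.shape[0] != A.shape[1]:
        raise ValueError("distance matrix must be square")
    if not np.allclose(A, A.T, atol=1e-10):
        raise ValueError("distance matrix must be symmetric")
    if not np.allclose(np.diag(A), 0.0, atol=1e-10):
        raise ValueError("distance matrix must have zero diagonal")
    return A


def _gower(D: np.ndarray) -> np.ndarray:
    A = -0.5 * D**2
    n = A.shape[0]
    J = np.eye(n) - np.ones((n, n)) / n
    return J @ A @ J


def _design_matrix(x) -> np.ndarray:
    """Column-centered numeric design from a vector/DataFrame; factors are
    dummy-coded (full rank, first level dropped)."""
    if isinstance(x, pd.DataFrame):
        cols = []
        for c in x.columns:
            col = x[c]
            if col.dtype.kind in "OUSb" or isinstance(col.dtype, pd.CategoricalDtype):
                d = pd.get_dummies(col, drop_first=True).to_numpy(dtype=float)
                cols.append(d)
            else:
                cols.append(col.to_numpy(dtype=float)[:, None])
        X = np.hstack(cols)
    elif isinstance(x, pd.Series) and (
        x.dtype.kind in "OUSb" or isinstance(x.dtype, pd.CategoricalDtype)
    ):
        X = pd.get_dummies(x, drop_first=True).to_numpy(dtype=float)
    else:
        X = np.asarray(x, dtype=float)
        if X.ndim == 1:
            if X.dtype.kind in "OUS":
                X = pd.get_dummies(pd.Series(X), drop_first=True).to_numpy(float)
            else:
                X = X[:, None]
    return X - X.mean(axis=0)


def _hat(X: np.ndarray) -> tuple[np.ndarray, int]:
    """Projection matrix onto the column space of centered X and its rank."""
    U, s, _ = np.linalg.svd(X, full_matrices=False)
    rank = int((s > s.max() * 1e-10).sum()) if s.size and s.max() > 0 else 0
    U = U[:, :rank]
    return U @ U.T, rank


def permanova(
    D,
    groups=None,
    design=None,
    n_perm: int = 999,
    seed: int | None = None,
    name: str = "PERMANOVA",
) -> PermutationTestResult:
    """Permutational multivariate ANOVA on a distance matrix.

    Provide either ``groups`` (a label vector) or ``design`` (numeric /
    factor table).  Pseudo-F uses ``tr(HG)`` with sequential (single-block)
    projection; p by free permutation of sample labels.
    """
    A = _as_square(D)
    n = A.shape[0]
    if groups is not None:
        g = pd.Series(list(groups))
        counts = g.value_counts()
        if len(counts) < 2 or (counts < 2).any():
            raise ValueError("need >= 2 groups with >= 2 members")
        X = _design_matrix(g.astype(str))
    elif design is not None:
        X = _design_matrix(design)
    else:
        raise ValueError("either groups or design is required")
    if n_perm < 99:
        warnings.warn("fewer than 99 permutations; p-value is coarse")
    H, q = _hat(X)
    if q == 0:
        raise ValueError("degenerate grouping/design (no contrasts)")
    G = _gower(A)
    ss_total = float(np.trace(G))
    df_b, df_w = q, n - q - 1

    def f_stat(Gm: np.ndarray) -> float:
        ss_b = float(np.sum(H * Gm))  # tr(H G), H symmetric
        ss_w = ss_total - ss_b
        return (ss_b / df_b) / (ss_w / df_w)

    f_obs = f_stat(G)
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        if f_stat(G[np.ix_(perm, perm)]) >= f_obs:
            hits += 1
    p = (1 + hits) / (1 + n_perm)
    r2 = float(np.sum(H * G)) / ss_total
    return PermutationTestResult(name, float(f_obs), float(r2), n_perm, float(p),
                                 df=(df_b, df_w))


# ------------------------------------------------------------------ PCoA
def pcoa(D, correction: str | None = None) -> tuple[np.ndarray, np.ndarray]:
    """Principal coordinates of a distance matrix.

    Returns ``(coordinates, eigenvalues)``; eigenvalues may be negative for
    non-Euclidean input.  ``correction='lingoes'`` adds the smallest
    constant to all squared off-diagonal distances that makes every
    eigenvalue non-negative.
    """
    A = _as_square(D)
    if correction == "lingoes":
        eig = np.linalg.eigvalsh(_gower(A))
        c = -eig.min()
        if c > 1e-12:
            A = np.sqrt(A**2 + 2.0 * c)
            np.fill_diagonal(A, 0.0)
    G = _gower(A)
    eigval, eigvec = np.linalg.eigh(G)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = eigval[order], eigvec[:, order]
    coords = eigvec * np.sqrt(np.abs(eigval))[None, :]
    return coords, eigval


def betadisper(
    D, groups, n_perm: int = 999, seed: int | None = None
) -> dict:
    """Homogeneity of multivariate dispersions (PERMDISP).

    Embeds the distance matrix by principal coordinates keeping negative
    eigenvalues; a sample's squared distance to its group centroid is the
    real-axis squared distance minus the imaginary-axis squared distance,
    clipped at zero.  The F statistic of a one-way ANOVA on these distances
    is tested by permuting group labels.  Size-1 groups get distance 0 and
    are excluded from the F test with a warning.
    """
    A = _as_square(D)
    g = pd.Series(list(groups))
    coords, eigval = pcoa(A)
    pos = eigval > 1e-12
    neg = eigval < -1e-12
    Xr, Xi = coords[:, pos], coords[:, neg]
    dist = np.zeros(A.shape[0])
    for lev in g.unique():
        m = (g == lev).to_numpy()
        cr = Xr[m].mean(axis=0)
        ci = Xi[m].mean(axis=0) if Xi.size else np.zeros(0)
        d2 = ((Xr[m] - cr) ** 2).sum(axis=1)
        if Xi.size:
            d2 = d2 - ((Xi[m] - ci) ** 2).sum(axis=1)
        dist[m] = np.sqrt(np.clip(d2, 0.0, None))

    sizes = g.value_counts()
    singletons = sizes[sizes < 2].index
    if len(singletons):
        warnings.warn(f"size-1 group(s) excluded from F test: {list(singletons)}")
    keep = ~g.isin(singletons).to_numpy()
    z, gk = dist[keep], g[keep].reset_index(drop=True)
    k = gk.nunique()
    if k < 2:
        raise ValueError("need >= 2 groups of size >= 2")

    def anova_f(vals: np.ndarray, labels: pd.Series) -> float:
        grand = vals.mean()
        ss_b = sum(
            (vals[(labels == lev).to_numpy()].mean() - grand) ** 2
            * (labels == lev).sum()
            for lev in labels.unique()
        )
        ss_w = sum(
            ((vals[(labels == lev).to_numpy()]
              - vals[(labels == lev).to_numpy()].mean()) ** 2).sum()
            for lev in labels.unique()
        )
        return (ss_b / (k - 1)) / (ss_w / (len(vals) - k))

    f_obs = anova_f(z, gk)
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_perm):
        if anova_f(z, gk.sample(frac=1, random_state=rng.integers(2**31))
                   .reset_index(drop=True)) >= f_obs:
            hits += 1
    p = (1 + hits) / (1 + n_perm)
    index = D.index if isinstance(D, pd.DataFrame) else pd.RangeIndex(len(dist))
    return {
        "distances": pd.Series(dist, index=index, name="dist_to_centroid"),
        "test": PermutationTestResult(
            "PERMDISP", float(f_obs), None, n_perm, float(p),
            df=(k - 1, int(keep.sum()) - k),
        ),
    }


# ----------------------------------------------------------------- db-RDA
@dataclasses.dataclass
class DBRDAResult:
    eigenvalues: np.ndarray
    sample_scores: pd.DataFrame
    inertia_total: float
    inertia_constrained: float
    r2: float
    adj_r2: float
    test: PermutationTestResult


def dbrda(
    D, constraints, n_perm: int = 999, seed: int | None = None
) -> DBRDAResult:
    """Distance-based redundancy analysis.

    PCoA with Lingoes correction for negative eigenvalues, regression of
    the coordinates on the (dummy-coded, centered) constraints, and an
    overall pseudo-F permutation test.  Collinear constraint columns are
    dropped via the rank of the design.
    """
    A = _as_square(D)
    n = A.shape[0]
    Y, eigval = pcoa(A, correction="lingoes")
    Y = Y[:, eigval > 1e-9 * max(eigval.max(), 1.0)]
    X = _design_matrix(constraints)
    H, q = _hat(X)
    if q == 0:
        raise ValueError("constraints are degenerate")
    if n < q + 2:
        raise ValueError("more constraints than samples allow")
    total = float((Y**2).sum())

    def f_stat(Ym: np.ndarray) -> float:
        fitted = float(np.sum((H @ Ym) ** 2))
        return (fitted / q) / ((total - fitted) / (n - q - 1))

    fitted_Y = H @ Y
    constrained = float((fitted_Y**2).sum())
    # eigen-decomposition of the fitted variation -> constrained axes
    u, s, _ = np.linalg.svd(fitted_Y, full_matrices=False)
    eig_constrained = (s**2)[s**2 > 1e-12 * max(total, 1.0)]
    scores = u[:, : len(eig_constrained)] * s[: len(eig_constrained)]

    f_obs = f_stat(Y)
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        if f_stat(Y[perm]) >= f_obs:
            hits += 1
    p = (1 + hits) / (1 + n_perm)
    r2 = constrained / total
    adj = 1.0 - (1.0 - r2) * (n - 1) / (n - q - 1)
    index = D.index if isinstance(D, pd.DataFrame) else pd.RangeIndex(n)
    return DBRDAResult(
        eigenvalues=eig_constrained,
        sample_scores=pd.DataFrame(
            scores, index=index,
            columns=[f"CAP{i + 1}" for i in range(scores.shape[1])],
        ),
        inertia_total=total,
        inertia_constrained=constrained,
        r2=float(r2),
        adj_r2=float(adj),
        test=PermutationTestResult(
            "db-RDA", float(f_obs), float(r2), n_perm, float(p),
            df=(q, n - q - 1),
        ),
    )


def forward_select(
    D,
    candidates: pd.DataFrame,
    n_perm: int = 999,
    seed: int | None = None,
    alpha: float = 0.05,
) -> dict:
    """Greedy forward selection of db-RDA constraint terms.

    At each step the candidate maximizing adjusted R^2 is admitted only if
    its conditional permutation p-value is <= alpha and the resulting
    adjusted R^2 does not exceed that of the full model.  Because adjusted
    R^2 is unbiased under pure noise, a sub-model can exceed the full
    model's value by sampling fluctuation alone (dropping a noise term is
    a coin flip); the ceiling therefore carries a small df-aware tolerance
    ``2 (q_full - q_cand) (1 - adjR2) / n`` instead of being exact.
    """
    if candidates.shape[1] < 1:
        raise ValueError("at least one candidate term required")
    rng = np.random.default_rng(seed)
    n = np.asarray(D).shape[0]
    full = dbrda(D, candidates, n_perm=n_perm, seed=int(rng.integers(2**31)))
    q_full = full.test.df[0]
    selected: list[str] = []
    path: list[float] = []
    current_adj = 0.0
    remaining = list(candidates.columns)
    while remaining:
        best_term, best_adj, best_q = None, current_adj, 0
        for term in remaining:
            cand = dbrda(
                D, candidates[selected + [term]], n_perm=99,
                seed=int(rng.integers(2**31)),
            )
            if cand.adj_r2 > best_adj:
                best_term, best_adj = term, cand.adj_r2
                best_q = cand.test.df[0]
        ceiling_tol = 2.0 * max(q_full - best_q, 0) * (1 - best_adj) / n
        if best_term is None or best_adj > full.adj_r2 + ceiling_tol:
            break
        test = dbrda(
            D, candidates[selected + [best_term]], n_perm=n_perm,
            seed=int(rng.integers(2**31)),
        )
        if test.test.p > alpha:
            break
        selected.append(best_term)
        remaining.remove(best_term)
        current_adj = best_adj
        path.append(current_adj)
    return {"selected": selected, "adj_r2_path": path, "full_adj_r2": full.adj_r2}


def pairwise_permanova(
    D,
    groups,
    n_perm: int = 999,
    seed: int | None = None,
    correction: str = "fdr_bh",
) -> pd.DataFrame:
    """PERMANOVA on each pair of groups with BH-adjusted p-values."""
    A = _as_square(D)
    g = pd.Series(list(groups))
    rng = np.random.default_rng(seed)
    rows = []
    for a, b in itertools.combinations(sorted(g.unique()), 2):
        m = g.isin([a, b]).to_numpy()
        sub = A[np.ix_(m, m)]
        res = permanova(
            sub, groups=g[m], n_perm=n_perm, seed=int(rng.integers(2**31))
        )
        rows.append({"group_a": a, "group_b": b, "F": res.statistic,
                     "r2": res.r2, "p": res.p})
    out = pd.DataFrame(rows)
    out["p_adj"] = multipletests(out["p"], method=correction)[1]
    return out


# ----------------------------------------------------------------- Mantel
def _offdiag(D: np.ndarray) -> np.ndarray:
    iu = np.triu_indices_from(D, k=1)
    return D[iu]


def mantel(
    D1, D2, n_perm: int = 999, seed: int | None = None
) -> PermutationTestResult:
    """Mantel correlation between two distance matrices."""
    A, B = _as_square(D1), _as_square(D2)
    a, b = _offdiag(A), _offdiag(B)
    if a.std() == 0 or b.std() == 0:
        raise FloatingPointError("constant distance matrix")
    r_obs = float(np.corrcoef(a, b)[0, 1])
    rng = np.random.default_rng(seed)
    n = A.shape[0]
    hits = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        if np.corrcoef(_offdiag(A[np.ix_(perm, perm)]), b)[0, 1] >= r_obs:
            hits += 1
    return PermutationTestResult(
        "Mantel", r_obs, None, n_perm, (1 + hits) / (1 + n_perm)
    )


def _partial_r(a: np.ndarray, b: np.ndarray, c: np.ndarray) -> float:
    r_ab = np.corrcoef(a, b)[0, 1]
    r_ac = np.corrcoef(a, c)[0, 1]
    r_bc = np.corrcoef(b, c)[0, 1]
    den = np.sqrt((1 - r_ac**2) * (1 - r_bc**2))
    if den == 0:
        raise FloatingPointError("degenerate partial correlation")
    return (r_ab - r_ac * r_bc) / den


def partial_mantel(
    D1, D2, D3, n_perm: int = 999, seed: int | None = None
) -> PermutationTestResult:
    """Partial Mantel: correlation of D1 and D2 controlling for D3.

    p-value by jointly permuting rows/columns of D1.
    """
    A, B, C = _as_square(D1), _as_square(D2), _as_square(D3)
    a, b, c = _offdiag(A), _offdiag(B), _offdiag(C)
    for v in (a, b, c):
        if v.std() == 0:
            raise FloatingPointError("constant distance matrix")
    r_obs = float(_partial_r(a, b, c))
    rng = np.random.default_rng(seed)
    n = A.shape[0]
    hits = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        if _partial_r(_offdiag(A[np.ix_(perm, perm)]), b, c) >= r_obs:
            hits += 1
    return PermutationTestResult(
        "partial Mantel", r_obs, None, n_perm, (1 + hits) / (1 + n_perm)
    )
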