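"""Phylogenetic turnover null models: betaMNTD, betaNTI and the
selection-vs-stochasticity classification of community assembly.

For a pair of samples, betaMNTD is the (symmetrized, optionally
abundance-weighted) mean distance from each taxon present in one sample to
its nearest taxon present in the other.  A null distribution is built by
reshuffling the tips of the phylogeny — one shuffle per iteration, applied
consistently to every pair, so per-iteration betaMNTD matrices are
internally coherent.  betaNTI is the standardized effect size

    betaNTI = (betaMNTD_obs - mean(betaMNTD_null)) / sd(betaMNTD_null)

and a pair is labelled ``homogeneous_selection`` (betaNTI < -2, less
turnover than chance), ``variable_selection`` (betaNTI > 2, more turnover
than chance) or ``stochastic`` otherwise.
"""

from __future__ import annotations

import dataclasses
import itertools
import math
import warnings

import numpy as np
import pandas as pd
from scipy import stats

from .trees import PhyloTree

__all__ = [
    "ProcessClassification",
    "BetaNTIResult",
    "bmntd",
    "bmntd_matrix",
    "bnti_matrix",
    "process_proportions",
    "process_chi_square",
    "classify_bnti",
]

SELECTION_LABELS = ("homogeneous_selection", "variable_selection")


@dataclasses.dataclass
class ProcessClassification:
    pair: tuple[str, str]
    bnti: float
    label: str


def classify_bnti(value: float) -> str:
    if not np.isfinite(value):
        return "undefined"
    if value < -2:
        return "homogeneous_selection"
    if value > 2:
        return "variable_selection"
    return "stochastic"


def _weights(table: pd.DataFrame, abundance_weighted: bool) -> np.ndarray:
    x = table.to_numpy(dtype=float)
    if not abundance_weighted:
        x = (x > 0).astype(float)
    sums = x.sum(axis=1, keepdims=True)
    if (sums == 0).any():
        empty = table.index[(x.sum(axis=1) == 0)].tolist()
        raise ValueError(f"empty sample(s): {empty}")
    return x / sums


def _bmntd_all_pairs(W: np.ndarray, pres: np.ndarray, D: np.ndarray) -> np.ndarray:
    """betaMNTD matrix for all sample pairs given one distance matrix.

    ``W`` is (samples, tips) row-normalized weights, ``pres`` the boolean
    presence matrix.  For each sample t, ``M[:, t]`` holds every tip's
    distance to its nearest tip present in t; the weighted average over the
    tips of sample s then gives the directed term, symmetrized by the mean
    of the two directions.
    """
    n_samples, n_tips = W.shape
    M = np.empty((n_tips, n_samples))
    for t in range(n_samples):
        M[:, t] = D[:, pres[t]].min(axis=1)
    directed = W @ M  # directed[s, t] = mean_{i in s} min_{j in t} d_ij
    return 0.5 * (directed + directed.T)


def bmntd(
    row_a: pd.Series,
    row_b: pd.Series,
    tree: PhyloTree,
    abundance_weighted: bool = True,
) -> float:
    """betaMNTD for a single pair of samples."""
    table = pd.DataFrame([row_a, row_b]).reindex(columns=tree.tip_labels).fillna(0)
    return float(
        bmntd_matrix(table, tree, abundance_weighted=abundance_weighted).iloc[0, 1]
    )


def bmntd_matrix(
    table: pd.DataFrame, tree: PhyloTree, abundance_weighted: bool = True
) -> pd.DataFrame:
    """betaMNTD for every pair of samples in the table."""
    idx = tree.tip_indices(table.columns)
    D = tree.patristic_matrix()[np.ix_(idx, idx)]
    W = _weights(table, abundance_weighted)
    pres = table.to_numpy() > 0
    out = _bmntd_all_pairs(W, pres, D)
    np.fill_diagonal(out, 0.0)
    return pd.DataFrame(out, index=table.index, columns=table.index)


@dataclasses.dataclass
class BetaNTIResult:
    bmntd_obs: pd.DataFrame
    null_mean: pd.DataFrame
    null_sd: pd.DataFrame
    bnti: pd.DataFrame

    def classifications(self) -> list[ProcessClassification]:
        out = []
        samples = list(self.bnti.index)
        vals = self.bnti.to_numpy()
        for i, j in itertools.combinations(range(len(samples)), 2):
            v = float(vals[i, j])
            out.append(
                ProcessClassification((samples[i], samples[j]), v, classify_bnti(v))
            )
        return out

    def to_frame(self) -> pd.DataFrame:
        recs = self.classifications()
        return pd.DataFrame(
            {
                "sample_a": [r.pair[0] for r in recs],
                "sample_b": [r.pair[1] for r in recs],
                "bnti": [r.bnti for r in recs],
                "label": [r.label for r in recs],
            }
        )


def bnti_matrix(
    table: pd.DataFrame,
    tree: PhyloTree,
    n_null: int = 1000,
    seed: int | None = None,
    abundance_weighted: bool = True,
    exhaustive: bool = False,
) -> BetaNTIResult:
    """betaNTI for every sample pair via tip-label reshuffling.

    One tip permutation per null iteration, shared across all pairs.
    ``exhaustive=True`` enumerates all permutations (tiny trees only).
    """
    if not exhaustive and n_null < 100:
        raise ValueError("n_null must be >= 100")
    idx = tree.tip_indices(table.columns)
    D = tree.patristic_matrix()[np.ix_(idx, idx)]
    W = _weights(table, abundance_weighted)
    pres = table.to_numpy() > 0
    obs = _bmntd_all_pairs(W, pres, D)

    n_tips = D.shape[0]
    if exhaustive:
        if math.factorial(n_tips) > 500_000:
            raise ValueError("exhaustive null infeasible for this tree size")
        perms = itertools.permutations(range(n_tips))
        nulls = np.array(
            [_bmntd_all_pairs(W, pres, D[np.ix_(p, p)]) for p in perms]
        )
    else:
        rng = np.random.default_rng(seed)
        nulls = np.empty((n_null, *obs.shape))
        for b in range(n_null):
            p = rng.permutation(n_tips)
            nulls[b] = _bmntd_all_pairs(W, pres, D[np.ix_(p, p)])
    mean = nulls.mean(axis=0)
    sd = nulls.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = (obs - mean) / sd
    z[~np.isfinite(z)] = np.nan
    np.fill_diagonal(z, 0.0)
    ix = table.index
    return BetaNTIResult(
        bmntd_obs=pd.DataFrame(obs, index=ix, columns=ix),
        null_mean=pd.DataFrame(mean, index=ix, columns=ix),
        null_sd=pd.DataFrame(sd, index=ix, columns=ix),
        bnti=pd.DataFrame(z, index=ix, columns=ix),
    )


def process_proportions(
    classifications: pd.DataFrame | list[ProcessClassification],
    groups: pd.Series,
) -> pd.DataFrame:
    """Per-group percentages of selection vs stochastic within-group pairs.

    ``groups`` maps sample id -> group key.  Between-group pairs are
    excluded; groups with fewer than 2 samples are skipped with a warning.
    Both selection labels are pooled into ``pct_selection``; percentages
    sum to 100 per group (undefined pairs are dropped).
    """
    if not isinstance(classifications, pd.DataFrame):
        classifications = pd.DataFrame(
            {
                "sample_a": [c.pair[0] for c in classifications],
                "sample_b": [c.pair[1] for c in classifications],
                "bnti": [c.bnti for c in classifications],
                "label": [c.label for c in classifications],
            }
        )
    small = groups.value_counts()
    for g in small[small < 2].index:
        warnings.warn(f"group {g!r} has < 2 samples; excluded")
    ga = groups.reindex(classifications["sample_a"]).to_numpy()
    gb = groups.reindex(classifications["sample_b"]).to_numpy()
    within = classifications[(ga == gb) & (classifications["label"] != "undefined")]
    within = within.assign(group=ga[(ga == gb) & (classifications["label"] != "undefined")])
    rows = []
    for g, sub in within.groupby("group"):
        n = len(sub)
        n_sel = int(sub["label"].isin(SELECTION_LABELS).sum())
        rows.append(
            {
                "group": g,
                "n_pairs": n,
                "n_selection": n_sel,
                "n_stochastic": n - n_sel,
                "pct_selection": 100.0 * n_sel / n,
                "pct_stochastic": 100.0 * (n - n_sel) / n,
            }
        )
    return pd.DataFrame(rows).set_index("group")


def process_chi_square(group_counts: pd.DataFrame) -> tuple[float, int, float]:
    """Pearson chi-square of the groups x {selection, stochastic} table.

    Expected counts come from the pooled marginal proportions; groups whose
    expected count in any cell falls below 1 are dropped (re-pooling the
    remainder) before computing the statistic.
    """
    obs = group_counts[["n_selection", "n_stochastic"]].to_numpy(dtype=float)
    if obs.shape[0] < 2:
        raise ValueError("chi-square needs at least two groups")
    while True:
        row = obs.sum(axis=1, keepdims=True)
        col = obs.sum(axis=0, keepdims=True)
        expected = row @ col / obs.sum()
        bad = (expected < 1).any(axis=1)
        if not bad.any() or (~bad).sum() < 2:
            break
        obs = obs[~bad]
    chi2 = float(((obs - expected) ** 2 / expected).sum())
    df = (obs.shape[0] - 1) * (obs.shape[1] - 1)
    p = float(stats.chi2.sf(chi2, df))
    return chi2, df, p
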