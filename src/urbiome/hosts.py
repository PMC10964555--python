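"""Small-mammal host community analysis: trapping-success index,
urbanization axis, community dissimilarity and the urban
avoider / adapter / dweller classification.

The trapping-success index corrects captures for effort:
``-100 * ln(1 - captures / (traps * nights))``; it approaches the plain
capture percentage at low capture rates and inflates it as traps saturate.
The urbanization axis is the first principal component of the standardized
site environmental table, oriented so urban-indicator features load
positively.
"""

from __future__ import annotations

import math
import warnings

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

__all__ = [
    "trapping_success",
    "capture_rate",
    "screen_covariates",
    "urbanization_axis",
    "community_dissimilarity",
    "classify_urban_response",
    "trapping_success_matrix",
]

URBAN_INDICATORS = ("Continuous urban fabric", "Industrial")


def trapping_success(captures: int, traps: int, nights: int) -> float:
    """Effort-corrected abundance index ``-100 ln(1 - c/(traps*nights))``."""
    effort = traps * nights
    if effort <= 0:
        raise ValueError("traps and nights must be positive")
    if not 0 <= captures <= effort:
        raise ValueError("captures must be in [0, traps*nights]")
    if captures == effort:
        raise ValueError("all traps full every night: index is infinite")
    return -100.0 * math.log(1.0 - captures / effort)


def capture_rate(total_captures: int, total_trap_nights: int) -> float:
    """Global trapping success as a percentage, to one decimal."""
    if total_trap_nights <= 0:
        raise ValueError("trap-nights must be positive")
    return round(100.0 * total_captures / total_trap_nights, 1)


def trapping_success_matrix(records: pd.DataFrame) -> pd.DataFrame:
    """Site x species trapping-success matrix from long trapping records."""
    out = records.assign(
        ts=[
            trapping_success(c, t, n)
            for c, t, n in zip(records["captures"], records["traps"],
                               records["nights"])
        ]
    )
    return out.pivot_table(index="site", columns="species", values="ts",
                           fill_value=0.0)


def screen_covariates(env_table: pd.DataFrame, r_threshold: float = 0.9) -> list[str]:
    """Drop one of each feature pair with |Pearson r| above the threshold.

    Iterates in column order keeping the earlier feature of a correlated
    pair; returns the retained feature names.
    """
    numeric = env_table.select_dtypes(include=[np.number])
    if numeric.shape[1] < 2:
        return list(numeric.columns)
    retained: list[str] = []
    for col in numeric.columns:
        drop = False
        for kept in retained:
            a, b = numeric[col], numeric[kept]
            if a.std() == 0 or b.std() == 0:
                continue
            if abs(np.corrcoef(a, b)[0, 1]) > r_threshold:
                drop = True
                break
        if not drop:
            retained.append(col)
    return retained


def urbanization_axis(
    env_table: pd.DataFrame,
    urban_indicators: tuple[str, ...] = URBAN_INDICATORS,
) -> dict:
    """PCA (correlation matrix) of the site environmental table.

    Returns per-site axis-1 scores (oriented so the summed loading of the
    urban-indicator features is positive), the loadings and per-axis
    variance fractions.
    """
    if env_table.shape[0] < 3:
        raise ValueError("need at least 3 sites for a PCA")
    X = env_table.select_dtypes(include=[np.number]).copy()
    sd = X.std(ddof=1)
    X = X.loc[:, sd > 0]
    Z = (X - X.mean()) / X.std(ddof=1)
    U, s, Vt = np.linalg.svd(Z.to_numpy(), full_matrices=False)
    var = s**2
    var_frac = var / var.sum()
    scores = U * s
    loadings = Vt
    present = [c for c in urban_indicators if c in X.columns]
    orient = np.sign(loadings[0, [X.columns.get_loc(c) for c in present]].sum()) \
        if present else 1.0
    if orient == 0:
        orient = 1.0
    return {
        "scores": pd.Series(orient * scores[:, 0], index=env_table.index,
                            name="urbanization"),
        "loadings": pd.DataFrame(
            (loadings * np.array([orient] + [1.0] * (loadings.shape[0] - 1))[:, None]).T,
            index=X.columns,
            columns=[f"PC{i + 1}" for i in range(loadings.shape[0])],
        ),
        "variance_fraction": pd.Series(
            var_frac, index=[f"PC{i + 1}" for i in range(len(var_frac))]
        ),
    }


def community_dissimilarity(ts_matrix: pd.DataFrame) -> pd.DataFrame:
    """Bray-Curtis dissimilarity between sites from trapping success."""
    if (ts_matrix.sum(axis=1) == 0).any():
        empty = ts_matrix.index[ts_matrix.sum(axis=1) == 0].tolist()
        raise ValueError(f"site(s) with empty community: {empty}")
    D = squareform(pdist(ts_matrix.to_numpy(dtype=float), metric="braycurtis"))
    return pd.DataFrame(D, index=ts_matrix.index, columns=ts_matrix.index)


def classify_urban_response(
    presence: pd.DataFrame, site_labels: dict[str, str] | pd.Series
) -> pd.DataFrame:
    """Classify species as avoider / adapter / dweller.

    ``presence`` is a site x species matrix (>0 means present);
    ``site_labels`` maps each site to 'urban' or 'rural'.  Species present
    only in rural sites are avoiders, only in urban sites dwellers, in both
    adapters; species absent everywhere are excluded with a warning.
    """
    labels = pd.Series(site_labels)
    bad = set(presence.index) - set(labels.index)
    if bad:
        raise ValueError(f"unlabelled site(s): {sorted(bad)}")
    if not set(labels.loc[list(presence.index)]) <= {"urban", "rural"}:
        raise ValueError("site labels must be 'urban' or 'rural'")
    rows = []
    for species in presence.columns:
        pres = presence[species] > 0
        if not pres.any():
            warnings.warn(f"species {species!r} absent everywhere; excluded")
            continue
        in_urban = pres[labels.loc[presence.index] == "urban"].any()
        in_rural = pres[labels.loc[presence.index] == "rural"].any()
        label = "adapter" if in_urban and in_rural else (
            "dweller" if in_urban else "avoider"
        )
        rows.append({"species": species, "label": label})
    return pd.DataFrame(rows).set_index("species")
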