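"""False-positive filtering and normalization of raw amplicon (ASV) tables.

The pipeline mirrors standard practice for 16S runs sequenced with
duplicated libraries and negative controls:

1. per-ASV thresholds — T_CC (cross-contamination: the maximum count of
   the ASV over all negative controls) and T_FA (false assignment / index
   hopping: run-total reads x misassignment rate, optionally re-estimated
   from an internal DNA control); counts at or below the larger threshold
   are zeroed,
2. replicate confirmation — an occurrence is kept only when both technical
   replicates are positive after thresholding, in which case their reads
   are summed,
3. taxonomy-based removal (non-Bacteria, chloroplast/unassigned phyla,
   Mitochondria family),
4. a rarefaction plateau check dropping under-sequenced samples,
5. a minimum group-size filter on species-site combinations,
6. proportional normalization per sample.

The composed filter never increases a count and is idempotent on its own
output (re-applying thresholds/taxonomy to an already-filtered table is a
no-op).
"""

from __future__ import annotations

import dataclasses
import math
import warnings

import numpy as np
import pandas as pd
from scipy.special import gammaln

__all__ = [
    "RawRun",
    "FilterThresholds",
    "compute_tcc",
    "compute_tfa",
    "apply_thresholds",
    "confirm_replicates",
    "taxonomic_filter",
    "rarefaction_check",
    "rarefaction_curve",
    "group_size_filter",
    "normalize_proportions",
    "run_filter_pipeline",
]


@dataclasses.dataclass
class RawRun:
    """A raw sequencing run: two technical replicates plus controls."""

    replicate1: pd.DataFrame
    replicate2: pd.DataFrame
    negative_control_ids: list[str]
    internal_control: tuple[str, str] | None = None  # (sample, feature)
    taxonomy: pd.DataFrame | None = None

    def __post_init__(self):
        if not self.replicate1.index.equals(self.replicate2.index) or not (
            self.replicate1.columns.equals(self.replicate2.columns)
        ):
            raise ValueError("replicate tables must share identical indexes")
        for rep in (self.replicate1, self.replicate2):
            if (rep.to_numpy() < 0).any():
                raise ValueError("counts must be non-negative")


@dataclasses.dataclass
class FilterThresholds:
    t_cc: pd.Series
    t_fa: pd.Series
    misassignment_rate: float = 1e-4

    @property
    def combined(self) -> pd.Series:
        return pd.concat([self.t_cc, self.t_fa], axis=1).max(axis=1)


def compute_tcc(run: RawRun) -> pd.Series:
    """Per-feature cross-contamination threshold.

    The maximum count observed for the feature across every negative
    control in both replicates.
    """
    if not run.negative_control_ids:
        raise ValueError("no negative controls in run")
    neg = pd.concat(
        [
            run.replicate1.loc[run.negative_control_ids],
            run.replicate2.loc[run.negative_control_ids],
        ]
    )
    return neg.max(axis=0).astype(int).rename("t_cc")


def compute_tfa(run: RawRun, misassignment_rate: float = 1e-4) -> pd.Series:
    """Per-feature false-assignment threshold.

    ``ceil(run-total reads of the feature x rate)`` where the rate is the
    maximum of the supplied default and, when an internal DNA control is
    present, the rate estimated from its leakage (reads of the control
    feature observed outside its designated sample / its run total).
    """
    if not 0 <= misassignment_rate < 1:
        raise ValueError("misassignment_rate must be in [0, 1)")
    totals = (run.replicate1.sum(axis=0) + run.replicate2.sum(axis=0)).astype(float)
    rate = misassignment_rate
    if run.internal_control is not None:
        ic_sample, ic_feature = run.internal_control
        if ic_feature in totals.index and totals[ic_feature] > 0:
            leaked = (
                run.replicate1[ic_feature].drop(ic_sample, errors="ignore").sum()
                + run.replicate2[ic_feature].drop(ic_sample, errors="ignore").sum()
            )
            rate = max(rate, leaked / totals[ic_feature])
    return pd.Series(
        np.ceil(totals * rate).astype(int), index=totals.index, name="t_fa"
    )


def apply_thresholds(
    table: pd.DataFrame, thresholds: FilterThresholds, strict: bool = False
) -> pd.DataFrame:
    """Zero out counts at or below ``max(t_cc, t_fa)`` for their feature.

    The threshold equals the worst observed artifact, so counts equal to it
    are untrustworthy and discarded by default; ``strict=True`` switches to
    discarding only counts strictly below the threshold.
    """
    combined = thresholds.combined.reindex(table.columns)
    if combined.isna().any():
        missing = combined[combined.isna()].index.tolist()[:5]
        raise KeyError(f"thresholds missing for features: {missing}")
    vals = table.to_numpy()
    thr = combined.to_numpy()
    keep = vals < thr if strict else vals <= thr
    return pd.DataFrame(
        np.where(keep, 0, vals), index=table.index, columns=table.columns
    )


def confirm_replicates(rep1: pd.DataFrame, rep2: pd.DataFrame) -> pd.DataFrame:
    """Keep occurrences confirmed by both replicates; sum their reads."""
    if not rep1.index.equals(rep2.index) or not rep1.columns.equals(rep2.columns):
        raise ValueError("replicate tables must share identical indexes")
    both = (rep1 > 0) & (rep2 > 0)
    return (rep1 + rep2).where(both, 0)


_UNASSIGNED = {"", "unknown", "unassigned", "unclassified", "na", "nan", "none"}


def taxonomic_filter(table: pd.DataFrame, taxonomy: pd.DataFrame) -> pd.DataFrame:
    """Retain Bacteria; drop chloroplast/unassigned phyla and Mitochondria.

    ``taxonomy`` is indexed by feature with (at least) Kingdom, Phylum and
    Family columns; features absent from it count as unaffiliated and are
    dropped.
    """
    cols = {c.lower(): c for c in taxonomy.columns}
    kingdom = taxonomy[cols.get("kingdom")] if "kingdom" in cols else None
    phylum = taxonomy[cols.get("phylum")] if "phylum" in cols else None
    family = taxonomy[cols.get("family")] if "family" in cols else None

    def ok(feature: str) -> bool:
        if feature not in taxonomy.index:
            return False
        if kingdom is not None and str(kingdom.get(feature)).lower() != "bacteria":
            return False
        if phylum is not None:
            p = str(phylum.get(feature)).strip().lower()
            if p in _UNASSIGNED or p == "chloroplast":
                return False
        if family is not None and str(family.get(feature)).lower() == "mitochondria":
            return False
        return True

    keep = [f for f in table.columns if ok(f)]
    return table[keep]


def _expected_richness_hypergeom(counts: np.ndarray, m: int) -> float:
    """Exact expected richness of a subsample of size m (without replacement)."""
    n = counts.sum()
    if m > n:
        raise ValueError("subsample larger than sample")
    lognum = gammaln(n - counts + 1) + gammaln(n - m + 1)
    logden = gammaln(n - counts - m + 1) + gammaln(n + 1)
    with np.errstate(invalid="ignore"):
        p_absent = np.where(n - counts >= m, np.exp(lognum - logden), 0.0)
    return float(np.sum(1.0 - p_absent))


def rarefaction_curve(sample_row: pd.Series, depths=None) -> pd.Series:
    """Analytic (hypergeometric) expected-richness rarefaction curve."""
    counts = sample_row.to_numpy(dtype=float)
    counts = counts[counts > 0]
    n = int(counts.sum())
    if n == 0:
        return pd.Series(dtype=float)
    if depths is None:
        depths = np.unique(np.linspace(1, n, 25).astype(int))
    return pd.Series(
        [_expected_richness_hypergeom(counts, int(m)) for m in depths],
        index=pd.Index(depths, name="depth"),
        name=sample_row.name,
    )


def rarefaction_check(
    table: pd.DataFrame, tolerance: float = 1.0, window: int = 1000
) -> pd.DataFrame:
    """Flag samples whose rarefaction curve has not plateaued.

    A sample is dropped when the expected number of *new* features in
    ``window`` additional reads beyond its observed depth exceeds
    ``tolerance``.  The extrapolated increment uses the multinomial
    approximation ``sum_f (1-p_f)^N (1-(1-p_f)^window)``.
    """
    rows = []
    for sample, row in table.iterrows():
        counts = row.to_numpy(dtype=float)
        counts = counts[counts > 0]
        n = counts.sum()
        if n == 0:
            warnings.warn(f"sample {sample!r} has zero depth; dropped")
            rows.append({"sample": sample, "depth": 0, "slope": math.inf,
                         "keep": False})
            continue
        p = counts / n
        log1mp = np.log1p(-np.minimum(p, 1 - 1e-15))
        absent_now = np.exp(n * log1mp)
        slope = float(np.sum(absent_now * (1.0 - np.exp(window * log1mp))))
        rows.append({"sample": sample, "depth": int(n), "slope": slope,
                     "keep": slope <= tolerance})
    return pd.DataFrame(rows).set_index("sample")


def group_size_filter(
    metadata: pd.DataFrame,
    min_n: int = 5,
    species_col: str = "species",
    site_col: str = "site",
    dead_col: str = "dead",
    exclude_species: tuple[str, ...] = (),
) -> list[str]:
    """Samples whose species-site combination keeps >= min_n individuals.

    Dead-on-trap individuals (boolean ``dead`` column) and user-listed
    outlier species are removed before counting.
    """
    if min_n < 1:
        raise ValueError("min_n must be >= 1")
    md = metadata.copy()
    if dead_col in md.columns:
        md = md[~md[dead_col].astype(bool)]
    if exclude_species:
        md = md[~md[species_col].isin(exclude_species)]
    sizes = md.groupby([species_col, site_col])[species_col].transform("size")
    return list(md.index[sizes >= min_n])


def normalize_proportions(table: pd.DataFrame) -> pd.DataFrame:
    """Normalize each sample row to proportional abundance (rows sum to 1)."""
    if (table.to_numpy() < 0).any():
        raise ValueError("negative counts")
    sums = table.sum(axis=1)
    zero = sums[sums == 0]
    if len(zero):
        raise ValueError(f"all-zero sample(s): {list(zero.index)}")
    return table.div(sums, axis=0)


def run_filter_pipeline(
    run: RawRun,
    metadata: pd.DataFrame | None = None,
    misassignment_rate: float = 1e-4,
    min_group: int = 5,
    tolerance: float = 1.0,
    strict: bool = False,
    exclude_species: tuple[str, ...] = (),
) -> dict:
    """Run the full filter: thresholds -> confirmation -> taxonomy ->
    rarefaction -> group size -> proportions.

    Returns a dict with ``counts`` (filtered summed counts),
    ``proportions`` and a per-stage ``report``.
    """
    report: dict = {}
    t_cc = compute_tcc(run)
    t_fa = compute_tfa(run, misassignment_rate)
    thr = FilterThresholds(t_cc=t_cc, t_fa=t_fa, misassignment_rate=misassignment_rate)
    report["thresholds"] = {
        "n_features": int(len(t_cc)),
        "max_t_cc": int(t_cc.max()),
        "max_t_fa": int(t_fa.max()),
    }
    rep1 = apply_thresholds(run.replicate1, thr, strict=strict)
    rep2 = apply_thresholds(run.replicate2, thr, strict=strict)
    confirmed = confirm_replicates(rep1, rep2)

    # controls have served their purpose
    drop_rows = set(run.negative_control_ids)
    drop_cols: set[str] = set()
    if run.internal_control is not None:
        drop_rows.add(run.internal_control[0])
        drop_cols.add(run.internal_control[1])
    confirmed = confirmed.drop(index=list(drop_rows & set(confirmed.index)))
    confirmed = confirmed.drop(columns=list(drop_cols & set(confirmed.columns)))

    if run.taxonomy is not None:
        before = confirmed.shape[1]
        confirmed = taxonomic_filter(confirmed, run.taxonomy)
        report["taxonomy"] = {"features_removed": int(before - confirmed.shape[1])}

    rare = rarefaction_check(confirmed, tolerance=tolerance)
    keep_samples = rare.index[rare["keep"]]
    report["rarefaction"] = {
        "samples_removed": sorted(set(confirmed.index) - set(keep_samples))
    }
    confirmed = confirmed.loc[keep_samples]

    if metadata is not None:
        kept = group_size_filter(
            metadata.loc[metadata.index.intersection(confirmed.index)],
            min_n=min_group,
            exclude_species=exclude_species,
        )
        report["group_size"] = {
            "samples_removed": sorted(set(confirmed.index) - set(kept))
        }
        confirmed = confirmed.loc[confirmed.index.intersection(kept)]

    confirmed = confirmed.loc[:, confirmed.sum(axis=0) > 0]
    confirmed = confirmed[confirmed.sum(axis=1) > 0]
    report["final"] = {
        "n_samples": int(confirmed.shape[0]),
        "n_features": int(confirmed.shape[1]),
    }
    return {
        "counts": confirmed,
        "proportions": normalize_proportions(confirmed),
        "thresholds": thr,
        "report": report,
    }
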