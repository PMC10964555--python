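"""Univariate models for alpha diversity and differential abundance.

* ``fit_glm`` — iteratively reweighted least squares for Gaussian
  (identity link) and negative-binomial (log link, NB2) responses, with
  the NB dispersion estimated by profiling the likelihood.  AICc uses
  ``-2 l + 2k + 2k(k+1)/(n-k-1)`` with k counting every estimated
  parameter (coefficients plus the scale/dispersion).
* ``all_subsets_select`` — exhaustive AICc model selection respecting
  marginality (interactions only with their main effects).
* ``variance_partition`` — per-term explained-deviance fractions,
  sequential and averaged over all term orderings.
* ``pairwise_contrasts`` — Wald tests on a user contrast matrix with
  Benjamini-Hochberg adjustment.
* ``redundancy_ancova`` — per-group slopes of functional on taxonomic
  richness, a slope-heterogeneity F test and pairwise slope contrasts;
  slope < 1 flags functional redundancy.
* ``nb_wald_da`` — a simplified negative-binomial Wald differential
  abundance test: +1 pseudocount, median-of-ratios size factors,
  per-feature NB GLM, Wald tests and BH correction.  No fold-change
  shrinkage and no empirical-Bayes dispersion sharing; equivalence with
  heavier reference tools is deliberately not claimed.
"""

from __future__ import annotations

import dataclasses
import itertools

import numpy as np
import pandas as pd
from scipy import optimize, special, stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "ModelFit",
    "SlopeRecord",
    "build_design",
    "fit_glm",
    "all_subsets_select",
    "variance_partition",
    "pairwise_contrasts",
    "redundancy_ancova",
    "size_factors",
    "nb_wald_da",
]

FAMILIES = ("gaussian", "negative_binomial")


# ------------------------------------------------------------ design build
def _encode(col: pd.Series, name: str) -> tuple[np.ndarray, list[str]]:
    if col.dtype.kind in "OUSb" or isinstance(col.dtype, pd.CategoricalDtype):
        dummies = pd.get_dummies(col.astype(str), drop_first=True)
        return dummies.to_numpy(dtype=float), [
            f"{name}[{lev}]" for lev in dummies.columns
        ]
    return col.to_numpy(dtype=float)[:, None], [name]


def build_design(data: pd.DataFrame, terms: list[str]) -> tuple[np.ndarray, list[str], dict]:
    """Design matrix with intercept from metadata columns.

    Terms are column names; ``a:b`` denotes the interaction (all products
    of the two encodings).  Returns ``(X, names, blocks)`` where blocks
    maps each term to its column slice in X.
    """
    n = len(data)
    cols = [np.ones((n, 1))]
    names = ["Intercept"]
    blocks: dict[str, slice] = {}
    pos = 1
    for term in terms:
        if ":" in term:
            a, b = term.split(":", 1)
            Xa, na = _encode(data[a], a)
            Xb, nb = _encode(data[b], b)
            X = np.hstack(
                [Xa[:, [i]] * Xb[:, [j]] for i in range(Xa.shape[1])
                 for j in range(Xb.shape[1])]
            )
            nm = [f"{x}:{y}" for x in na for y in nb]
        else:
            X, nm = _encode(data[term], term)
        cols.append(X)
        blocks[term] = slice(pos, pos + X.shape[1])
        pos += X.shape[1]
        names.extend(nm)
    return np.hstack(cols), names, blocks


# ------------------------------------------------------------------- GLMs
@dataclasses.dataclass
class ModelFit:
    response: str
    family: str
    terms: tuple[str, ...]
    coef: pd.Series
    cov: pd.DataFrame
    llf: float
    aic: float
    aicc: float
    n: int
    k: int
    fitted: np.ndarray
    alpha: float | None = None  # NB dispersion
    scale: float | None = None  # gaussian sigma^2 (MLE)
    deviance: float | None = None
    design: tuple | None = None  # (X, names, blocks), kept for contrasts
    y: np.ndarray | None = None

    @property
    def df_resid(self) -> int:
        return self.n - len(self.coef)


def _nb_llf(y: np.ndarray, mu: np.ndarray, alpha: float) -> float:
    inv = 1.0 / alpha
    return float(
        np.sum(
            special.gammaln(y + inv)
            - special.gammaln(inv)
            - special.gammaln(y + 1)
            + y * np.log(alpha * mu / (1 + alpha * mu))
            - inv * np.log1p(alpha * mu)
        )
    )


def _nb_irls(
    y: np.ndarray, X: np.ndarray, alpha: float, offset: np.ndarray,
    max_iter: int = 60, tol: float = 1e-9,
) -> tuple[np.ndarray, np.ndarray, float]:
    """IRLS for NB2 with log link; returns (beta, mu, llf)."""
    beta, *_ = np.linalg.lstsq(X, np.log(y + 0.5) - offset, rcond=None)
    llf_old = -np.inf
    for _ in range(max_iter):
        eta = np.clip(X @ beta + offset, -30, 30)
        mu = np.exp(eta)
        W = mu / (1.0 + alpha * mu)
        z = (eta - offset) + (y - mu) / mu
        XtW = X.T * W
        try:
            beta = np.linalg.solve(XtW @ X, XtW @ z)
        except np.linalg.LinAlgError:
            beta = np.linalg.lstsq(XtW @ X, XtW @ z, rcond=None)[0]
        llf = _nb_llf(y, np.exp(np.clip(X @ beta + offset, -30, 30)), alpha)
        if abs(llf - llf_old) < tol * (abs(llf_old) + 1.0):
            break
        llf_old = llf
    else:
        raise RuntimeError("IRLS did not converge")
    eta = np.clip(X @ beta + offset, -30, 30)
    mu = np.exp(eta)
    return beta, mu, _nb_llf(y, mu, alpha)


def fit_glm(
    y,
    data: pd.DataFrame | None = None,
    terms: list[str] | None = None,
    X: np.ndarray | None = None,
    names: list[str] | None = None,
    family: str = "gaussian",
    alpha: float | None = None,
    offset: np.ndarray | None = None,
    response_name: str = "y",
) -> ModelFit:
    """Fit a Gaussian or negative-binomial GLM.

    Either pass ``data``+``terms`` (design built with intercept) or an
    explicit design matrix ``X``/``names``.  For the NB family the
    dispersion ``alpha`` is profiled by maximum likelihood unless given.
    """
    if family not in FAMILIES:
        raise ValueError(f"unknown family {family!r}")
    yv = np.asarray(y, dtype=float).ravel()
    blocks: dict = {}
    if X is None:
        if data is None or terms is None:
            raise ValueError("provide data+terms or X")
        X, names, blocks = build_design(data, terms)
    elif names is None:
        names = [f"x{i}" for i in range(X.shape[1])]
    n, p = X.shape
    if n <= p + 1:
        raise ValueError("need n > k + 1 observations")
    off = np.zeros(n) if offset is None else np.asarray(offset, float)

    if family == "gaussian":
        beta, *_ = np.linalg.lstsq(X, yv - off, rcond=None)
        fitted = X @ beta + off
        resid = yv - fitted
        rss = float(resid @ resid)
        sigma2 = rss / n
        llf = -0.5 * n * (np.log(2 * np.pi * max(sigma2, 1e-300)) + 1)
        s2_unbiased = rss / max(n - p, 1)
        cov = s2_unbiased * np.linalg.pinv(X.T @ X)
        k = p + 1  # + sigma
        fit = ModelFit(
            response=response_name, family=family, terms=tuple(terms or ()),
            coef=pd.Series(beta, index=names), cov=pd.DataFrame(cov, index=names, columns=names),
            llf=float(llf), aic=np.nan, aicc=np.nan, n=n, k=k, fitted=fitted,
            scale=sigma2, deviance=rss, design=(X, names, blocks), y=yv,
        )
    else:
        yv = np.asarray(y, dtype=float).ravel()
        if (yv < 0).any():
            raise ValueError("negative counts for NB family")

        if alpha is None:
            # moment start from a Poisson-like fit, then profile the
            # Cox-Reid adjusted likelihood (the -1/2 log|X'WX| term
            # corrects the downward bias of plain ML dispersion, which
            # otherwise shrinks Wald standard errors)
            beta0, mu0, _ = _nb_irls(yv, X, 1e-8, off)
            pearson = float(np.sum(((yv - mu0) ** 2 - mu0) / mu0**2))
            a0 = max(pearson / max(n - p, 1), 1e-6)

            def neg_profile(log_a: float) -> float:
                a = float(np.exp(log_a))
                _, mu_a, llf_a = _nb_irls(yv, X, a, off)
                W = mu_a / (1.0 + a * mu_a)
                sign, logdet = np.linalg.slogdet((X.T * W) @ X)
                return -(llf_a - 0.5 * logdet)

            res = optimize.minimize_scalar(
                neg_profile,
                bounds=(np.log(1e-8), np.log(1e4)),
                method="bounded",
                options={"xatol": 1e-6},
            )
            alpha_hat = float(np.exp(res.x))
            if neg_profile(np.log(a0)) < res.fun:  # keep the better of the two
                alpha_hat = a0
        else:
            alpha_hat = float(alpha)
        beta, mu, llf = _nb_irls(yv, X, alpha_hat, off)
        W = mu / (1.0 + alpha_hat * mu)
        cov = np.linalg.pinv((X.T * W) @ X)
        k = p + (1 if alpha is None else 0)
        sat = _nb_llf(yv, np.maximum(yv, 1e-8), alpha_hat)
        fit = ModelFit(
            response=response_name, family=family, terms=tuple(terms or ()),
            coef=pd.Series(beta, index=names),
            cov=pd.DataFrame(cov, index=names, columns=names),
            llf=float(llf), aic=np.nan, aicc=np.nan, n=n, k=k, fitted=mu,
            alpha=alpha_hat, deviance=float(2 * (sat - llf)),
            design=(X, names, blocks), y=yv,
        )
    fit.aic = -2 * fit.llf + 2 * fit.k
    denom = n - fit.k - 1
    fit.aicc = fit.aic + (2 * fit.k * (fit.k + 1) / denom if denom > 0 else np.inf)
    return fit


def lr_test(full: ModelFit, reduced: ModelFit) -> tuple[float, int, float]:
    """Likelihood-ratio chi-square test of nested fits."""
    lr = 2 * (full.llf - reduced.llf)
    df = len(full.coef) - len(reduced.coef)
    return float(lr), df, float(stats.chi2.sf(max(lr, 0.0), max(df, 1)))


# ----------------------------------------------------------- model search
def _subsets(candidates: list[str]):
    for r in range(len(candidates) + 1):
        for combo in itertools.combinations(candidates, r):
            parents_ok = all(
                set(t.split(":")) <= {c for c in combo if ":" not in c}
                for t in combo if ":" in t
            )
            if parents_ok:
                yield list(combo)


def all_subsets_select(
    y,
    data: pd.DataFrame,
    candidates: list[str],
    family: str = "gaussian",
    response_name: str = "y",
) -> tuple[ModelFit, pd.DataFrame]:
    """Fit every admissible submodel; rank by AICc.

    Ties are broken by fewer parameters, then lexicographic term order.
    Interactions are admitted only together with their main effects.
    """
    rows = []
    fits = {}
    for terms in _subsets(candidates):
        fit = fit_glm(y, data=data, terms=terms, family=family,
                      response_name=response_name)
        key = " + ".join(terms) if terms else "1"
        fits[key] = fit
        rows.append({"model": key, "k": fit.k, "aicc": fit.aicc,
                     "loglik": fit.llf})
    table = pd.DataFrame(rows).sort_values(
        ["aicc", "k", "model"], kind="mergesort"
    ).reset_index(drop=True)
    table["delta_aicc"] = table["aicc"] - table["aicc"].iloc[0]
    return fits[table["model"].iloc[0]], table


def variance_partition(
    y,
    data: pd.DataFrame,
    terms: list[str],
    family: str = "gaussian",
) -> pd.Series:
    """Per-term fraction of deviance explained, sequential SS averaged
    over all term orderings (plus a residual fraction); sums to 1."""
    null_fit = fit_glm(y, data=data, terms=[], family=family)
    full_fit = fit_glm(y, data=data, terms=terms, family=family)
    d_null, d_full = null_fit.deviance, full_fit.deviance
    total = d_null
    contrib = {t: 0.0 for t in terms}
    orderings = list(itertools.permutations(terms))
    cache: dict[tuple, float] = {(): d_null}

    def dev(sub: tuple) -> float:
        if sub not in cache:
            cache[sub] = fit_glm(y, data=data, terms=list(sub), family=family).deviance
        return cache[sub]

    for order in orderings:
        prev: tuple = ()
        for t in order:
            cur = tuple(sorted(prev + (t,)))
            contrib[t] += dev(prev) - dev(cur)
            prev = cur
    out = pd.Series({t: contrib[t] / len(orderings) / total for t in terms})
    out["residual"] = d_full / total
    return out


def pairwise_contrasts(
    fit: ModelFit,
    contrasts: pd.DataFrame | np.ndarray,
    correction: str = "fdr_bh",
) -> pd.DataFrame:
    """Wald tests of contrast rows L with BH adjustment.

    Rows of ``contrasts`` are coefficient-space vectors (columns must match
    the fit's coefficient names when a DataFrame).  Inestimable contrasts
    (zero variance but nonzero estimate space) are flagged and excluded
    from adjustment.
    """
    if isinstance(contrasts, pd.DataFrame):
        L = contrasts.reindex(columns=fit.coef.index).fillna(0.0).to_numpy()
        labels = list(contrasts.index)
    else:
        L = np.asarray(contrasts, dtype=float)
        labels = [f"c{i}" for i in range(L.shape[0])]
    est = L @ fit.coef.to_numpy()
    var = np.einsum("ij,jk,ik->i", L, fit.cov.to_numpy(), L)
    se = np.sqrt(np.clip(var, 0.0, None))
    rows = []
    for lab, e, s in zip(labels, est, se):
        if s == 0:
            stat = 0.0 if e == 0 else np.nan
            p = 1.0 if e == 0 else np.nan
        else:
            stat = e / s
            if fit.family == "gaussian":
                p = 2 * stats.t.sf(abs(stat), fit.df_resid)
            else:
                p = 2 * stats.norm.sf(abs(stat))
        rows.append({"contrast": lab, "estimate": e, "se": s,
                     "statistic": stat, "p": p})
    out = pd.DataFrame(rows).set_index("contrast")
    ok = out["p"].notna()
    out["p_adj"] = np.nan
    if ok.any():
        out.loc[ok, "p_adj"] = multipletests(out.loc[ok, "p"], method=correction)[1]
    return out


# ----------------------------------------------------- functional redundancy
@dataclasses.dataclass
class SlopeRecord:
    group: str
    slope: float
    intercept: float
    n: int

    @property
    def redundant(self) -> bool:
        return self.slope < 1.0


def redundancy_ancova(
    functional_richness,
    taxonomic_richness,
    groups,
    correction: str = "fdr_bh",
) -> dict:
    """Functional-vs-taxonomic richness slopes per group, with ANCOVA.

    Returns per-group :class:`SlopeRecord` (slope < 1 means functional
    redundancy), the F test for slope heterogeneity (interaction of the
    covariate with group) and BH-adjusted pairwise slope contrasts.
    Groups with < 3 samples or zero covariate variance are flagged and
    skipped.
    """
    df = pd.DataFrame(
        {
            "f": np.asarray(functional_richness, float),
            "t": np.asarray(taxonomic_richness, float),
            "g": list(groups),
        }
    )
    records, flagged = [], []
    for g, sub in df.groupby("g"):
        if len(sub) < 3:
            flagged.append({"group": g, "reason": "n < 3"})
            continue
        if sub["t"].var() == 0:
            flagged.append({"group": g, "reason": "zero covariate variance"})
            continue
        slope, intercept = np.polyfit(sub["t"], sub["f"], 1)
        records.append(SlopeRecord(str(g), float(slope), float(intercept), len(sub)))

    usable = df[df["g"].isin([r.group for r in records])].reset_index(drop=True)
    het = None
    pairwise = pd.DataFrame()
    if usable["g"].nunique() >= 2:
        full = fit_glm(usable["f"], data=usable, terms=["t", "g", "t:g"],
                       family="gaussian")
        reduced = fit_glm(usable["f"], data=usable, terms=["t", "g"],
                          family="gaussian")
        df1 = len(full.coef) - len(reduced.coef)
        df2 = full.df_resid
        f_stat = ((reduced.deviance - full.deviance) / df1) / (
            full.deviance / df2
        )
        het = {"F": float(f_stat), "df": (df1, df2),
               "p": float(stats.f.sf(f_stat, df1, df2))}
        # pairwise slope differences from the interaction parametrization:
        # slope(level) = beta_t + beta_{t:g[level]} (reference level has 0)
        levels = sorted(usable["g"].astype(str).unique())
        names = list(full.coef.index)
        rows = {}
        for a, b in itertools.combinations(levels, 2):
            L = pd.Series(0.0, index=names)
            ca, cb = f"t:g[{a}]", f"t:g[{b}]"
            if ca in names:
                L[ca] += 1.0
            if cb in names:
                L[cb] -= 1.0
            rows[f"{a} - {b}"] = L
        if rows:
            pairwise = pairwise_contrasts(
                full, pd.DataFrame(rows).T, correction=correction
            )
    return {"slopes": records, "heterogeneity": het, "pairwise": pairwise,
            "flagged": flagged}


# ------------------------------------------------- differential abundance
def size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factors (rows are samples)."""
    log_counts = np.log(counts.to_numpy(dtype=float))
    with np.errstate(divide="ignore"):
        log_geo = log_counts.mean(axis=0)
    usable = np.isfinite(log_geo)
    if not usable.any():
        raise ValueError("no feature with all-positive counts")
    ratios = log_counts[:, usable] - log_geo[usable]
    return pd.Series(np.exp(np.median(ratios, axis=1)), index=counts.index,
                     name="size_factor")


def nb_wald_da(
    count_table: pd.DataFrame,
    groups,
    pseudocount: int = 1,
    correction: str = "fdr_bh",
) -> pd.DataFrame:
    """Simplified negative-binomial Wald differential abundance test.

    ``pseudocount`` is added to every cell; size factors are estimated by
    median-of-ratios; each feature gets an NB GLM on the group factor with
    a log size-factor offset; Wald tests per non-intercept coefficient are
    BH-adjusted across all feature-coefficient pairs.  Log2 fold changes
    are unshrunken.  Single-sample groups are excluded.
    """
    g = pd.Series(list(groups), index=count_table.index, name="g")
    sizes = g.value_counts()
    keep = g.isin(sizes[sizes >= 2].index)
    g = g[keep].astype(str)
    counts = count_table.loc[keep.index[keep]] + pseudocount
    sf = size_factors(counts)
    offset = np.log(sf.to_numpy())
    data = pd.DataFrame({"g": g.to_numpy()}, index=counts.index)
    rows = []
    for feature in counts.columns:
        y = counts[feature].to_numpy(dtype=float)
        try:
            fit = fit_glm(y, data=data, terms=["g"], family="negative_binomial",
                          offset=offset)
        except (RuntimeError, np.linalg.LinAlgError):
            continue
        for name in fit.coef.index:
            if name == "Intercept":
                continue
            se = float(np.sqrt(max(fit.cov.loc[name, name], 0.0)))
            if se == 0:
                continue
            beta = float(fit.coef[name])
            z = beta / se
            # t reference with residual df: small-sample correction for
            # the extra uncertainty of the estimated dispersion
            rows.append(
                {
                    "feature": feature,
                    "coef": name,
                    "log2_fold_change": beta / np.log(2),
                    "wald": z,
                    "p": 2 * stats.t.sf(abs(z), fit.df_resid),
                }
            )
    out = pd.DataFrame(rows)
    if len(out):
        out["p_adj"] = multipletests(out["p"], method=correction)[1]
    return out
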