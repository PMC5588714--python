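"""Association analyses on presence/absence insertion markers.

A general linear model per marker (trait ~ intercept + structure PCs +
marker) with Bonferroni thresholds, PCA structure covariates from a marker
subsample, Welch tests of expression against carrier status, and the
arithmetic of assay-vs-prediction concordance tables.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class PCAResult:
    scores: pd.DataFrame       # lines x k
    explained_variance: np.ndarray  # fraction per component
    n_markers_used: int


def pca_covariates(markers: pd.DataFrame, k: int = 3,
                   n_subsample: int | None = None, seed: int = 0) -> PCAResult:
    """Top-k principal components of the line x marker matrix.

    Columns are mean-centered (no variance scaling); an optional seeded
    random subsample of columns mirrors structure estimation from a
    separate marker set. Component sign is fixed by making each component's
    largest-magnitude loading positive.
    """
    if k >= len(markers):
        raise ValueError("k must be smaller than the number of lines")
    X = markers.to_numpy(float)
    if n_subsample is not None and n_subsample < X.shape[1]:
        rng = np.random.default_rng(seed)
        X = X[:, rng.choice(X.shape[1], size=n_subsample, replace=False)]
    X = X - X.mean(axis=0)
    if not X.any():
        raise ValueError("zero-variance marker matrix")
    u, s, vt = np.linalg.svd(X, full_matrices=False)
    scores = u[:, :k] * s[:k]
    for j in range(k):
        i = int(np.argmax(np.abs(vt[j])))
        if vt[j, i] < 0:
            scores[:, j] = -scores[:, j]
    ev = s ** 2 / (s ** 2).sum()
    return PCAResult(
        scores=pd.DataFrame(scores, index=markers.index,
                            columns=[f"PC{i + 1}" for i in range(k)]),
        explained_variance=ev[:k], n_markers_used=X.shape[1])


@dataclass
class AssocResult:
    marker_id: str
    trait: str
    effect: float
    se: float
    p_value: float
    n_used: int
    significant: bool
    defined: bool = True


def glm_assoc(trait: pd.Series, marker: pd.Series,
              covariates: pd.DataFrame | None = None,
              threshold: float = 0.05, marker_id: str = "",
              trait_name: str = "") -> AssocResult:
    """Least squares of trait on [intercept, covariates, marker]; the
    marker p-value is from its t statistic. Collinear or constant markers
    yield a flagged undefined result."""
    data = pd.DataFrame({"trait": trait, "marker": marker})
    if covariates is not None and len(covariates.columns):
        data = data.join(covariates)
    data = data.dropna()
    n = len(data)
    covs = data.drop(columns=["trait", "marker"]).to_numpy(float)
    if n < covs.shape[1] + 3:
        raise ValueError("too few complete cases")
    X = np.column_stack([np.ones(n), covs, data["marker"].to_numpy(float)])
    y = data["trait"].to_numpy(float)
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        return AssocResult(marker_id, trait_name, float("nan"), float("nan"),
                           float("nan"), n, False, defined=False)
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    dof = n - X.shape[1]
    sigma2 = resid @ resid / dof
    xtx_inv = np.linalg.inv(X.T @ X)
    se = float(np.sqrt(sigma2 * xtx_inv[-1, -1]))
    t = beta[-1] / se if se > 0 else np.inf
    p = float(2 * stats.t.sf(abs(t), dof)) if np.isfinite(t) else 0.0
    p = max(p, np.finfo(float).tiny)
    return AssocResult(marker_id, trait_name, float(beta[-1]), se, p, n,
                       significant=p <= threshold)


def bonferroni_threshold(m: int, alpha: float = 1.0) -> float:
    """Per-test p threshold alpha/m."""
    if m < 1 or not (0 < alpha <= 1):
        raise ValueError("need m >= 1 and alpha in (0, 1]")
    return alpha / m


def maf_filter(genotypes: pd.DataFrame, maf_min: float = 0.15) -> pd.DataFrame:
    """Markers whose minor-allele (carrier) frequency over genotyped lines
    is >= maf_min; the boundary is inclusive."""
    g = genotypes.where(genotypes >= 0)
    f = g.mean(axis=0)
    maf = np.minimum(f, 1 - f)
    return genotypes.loc[:, maf >= maf_min]


def gwas_scan(trait: pd.Series, genotypes: pd.DataFrame,
              covariates: pd.DataFrame | None = None, alpha: float = 1.0,
              maf_min: float = 0.15, trait_name: str = "trait",
              positions: pd.DataFrame | None = None) -> pd.DataFrame:
    """GLM association of one trait against every retained marker.

    Markers are MAF-filtered first; the significance threshold is
    Bonferroni alpha / (number of tested markers). Returns a table with
    effect, p, and significance per marker (plus coordinates when a
    locus table is supplied).
    """
    kept = maf_filter(genotypes, maf_min=maf_min)
    thr = bonferroni_threshold(kept.shape[1], alpha)
    rows = []
    for mid in kept.columns:
        res = glm_assoc(trait, kept[mid], covariates, threshold=thr,
                        marker_id=mid, trait_name=trait_name)
        rows.append((mid, trait_name, res.effect, res.se, res.p_value,
                     res.n_used, res.significant, res.defined))
    out = pd.DataFrame(rows, columns=["marker", "trait", "beta", "se", "p",
                                      "n", "significant", "defined"])
    if positions is not None:
        coords = positions.set_index("locus_id")[["chrom", "position"]]
        out = out.join(coords, on="marker")
        out["neglog10p"] = -np.log10(out["p"])
    out.attrs["threshold"] = thr
    return out


def expression_assoc(expression: pd.DataFrame, marker: pd.Series,
                     alpha: float = 1.0) -> pd.DataFrame:
    """Welch two-sample t-test of each gene's expression between carriers
    and non-carriers of one insertion marker.

    ``expression`` is genes x lines; the genome-wide threshold is
    Bonferroni alpha / n_genes. A gene is undefined when either carrier
    class has < 2 lines.
    """
    lines = [l for l in expression.columns if l in marker.index]
    m = marker[lines]
    carriers = [l for l in lines if m[l] == 1]
    others = [l for l in lines if m[l] == 0]
    thr = bonferroni_threshold(len(expression), alpha)
    rows = []
    for gid, row in expression.iterrows():
        a = row[carriers].to_numpy(float)
        b = row[others].to_numpy(float)
        if len(a) < 2 or len(b) < 2:
            rows.append((gid, np.nan, np.nan, np.nan, False, False))
            continue
        if np.var(a) == 0 and np.var(b) == 0 and a.mean() == b.mean():
            p = 1.0
        else:
            p = float(stats.ttest_ind(a, b, equal_var=False).pvalue)
        rows.append((gid, float(a.mean()), float(b.mean()), p, p <= thr, True))
    out = pd.DataFrame(rows, columns=["gene_id", "mean_carrier",
                                      "mean_noncarrier", "p", "significant",
                                      "defined"])
    out.attrs["threshold"] = thr
    return out


@dataclass
class ConcordanceTable:
    n_total: int
    n_agree: int
    n_assay_only: int   # insertion by assay, absent in silico
    n_silico_only: int  # insertion in silico, absent by assay
    pct_agree: float
    pct_assay_only: float
    pct_silico_only: float


def concordance(assay_calls: pd.Series, silico_calls: pd.Series) -> ConcordanceTable:
    """Agreement between assay presence/absence calls and computational
    predictions over the same lines; percentages to one decimal."""
    if set(assay_calls.index) != set(silico_calls.index):
        raise ValueError("assay and in-silico call line sets differ")
    a = assay_calls.astype(int)
    s = silico_calls[a.index].astype(int)
    agree = int((a == s).sum())
    assay_only = int(((a == 1) & (s == 0)).sum())
    silico_only = int(((a == 0) & (s == 1)).sum())
    n = len(a)
    return ConcordanceTable(
        n_total=n, n_agree=agree, n_assay_only=assay_only,
        n_silico_only=silico_only,
        pct_agree=round(100 * agree / n, 1),
        pct_assay_only=round(100 * assay_only / n, 1),
        pct_silico_only=round(100 * silico_only / n, 1),
    )
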