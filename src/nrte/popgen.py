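"""Population genetics on presence/absence insertion markers.

Frequency spectra, Hudson-style Fst with a resampling confidence interval,
Qst from nested variance components, the Qst-Fst selection-regime call,
and linkage disequilibrium statistics with Gabriel-style block detection.

Lines are fully inbred and treated as haploid: carrier fractions play the
role of allele frequencies, and all estimators use haploid sample-size
corrections.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd


# ---------------------------------------------------------------- spectra

@dataclass
class FreqSpectrum:
    population: str
    n_low: int            # frequency < 0.1
    n_intermediate: int   # 0.1 <= frequency <= 0.5
    n_high: int           # frequency > 0.5
    mean_frequency: float
    density_per_mb: float  # loci present (freq > 0) per Mb of genome


def spectrum(frequencies: pd.Series, genome_size: int,
             population: str = "") -> FreqSpectrum:
    """Bin per-locus carrier frequencies into low/intermediate/high classes.

    Loci with undefined (NaN) frequency are ignored; zero-frequency loci
    count in the low bin but not toward density.
    """
    f = frequencies.dropna().to_numpy(float)
    return FreqSpectrum(
        population=population,
        n_low=int((f < 0.1).sum()),
        n_intermediate=int(((f >= 0.1) & (f <= 0.5)).sum()),
        n_high=int((f > 0.5).sum()),
        mean_frequency=float(f.mean()) if len(f) else float("nan"),
        density_per_mb=float((f > 0).sum() / (genome_size / 1e6)),
    )


# ------------------------------------------------------------------- Fst

def fst_components(p1, n1, p2, n2):
    """Hudson numerator/denominator for haploid samples.

    Hw = mean within-population heterozygosity with n/(n-1) small-sample
    correction, Hb = between-population heterozygosity; Fst = 1 - Hw/Hb.
    Returns (Hb - Hw, Hb) so callers can form ratio-of-sums means.
    """
    p1 = np.asarray(p1, float)
    p2 = np.asarray(p2, float)
    if np.any(np.asarray(n1) < 2) or np.any(np.asarray(n2) < 2):
        raise ValueError("need >= 2 sampled lines per population")
    hw = 0.5 * (p1 * (1 - p1) * n1 / (n1 - 1) + p2 * (1 - p2) * n2 / (n2 - 1))
    hb = 0.5 * (p1 * (1 - p2) + p2 * (1 - p1))
    return hb - hw, hb


def fst_locus(p1: float, n1: int, p2: float, n2: int,
              estimator: str = "hudson") -> float:
    """Per-locus Fst from carrier fractions of haploid lines.

    NaN when the locus is monomorphic in both populations (Hb = 0).
    """
    if estimator == "hudson":
        num, den = fst_components(p1, n1, p2, n2)
        return float(num / den) if den > 0 else float("nan")
    if estimator == "wc":
        return _fst_wc(p1, n1, p2, n2)
    raise ValueError(f"unknown estimator {estimator!r}")


def _fst_wc(p1, n1, p2, n2):
    """Weir & Cockerham theta for two haploid samples."""
    n = np.array([n1, n2], float)
    p = np.array([p1, p2], float)
    nbar = n.mean()
    k = 2
    nc = (n.sum() - (n ** 2).sum() / n.sum()) / (k - 1)
    pbar = (n * p).sum() / n.sum()
    s2 = (n * (p - pbar) ** 2).sum() / ((k - 1) * nbar)
    a = (nbar / nc) * (s2 - (pbar * (1 - pbar) - (k - 1) / k * s2) / (nbar - 1))
    b = (nbar / (nbar - 1)) * (pbar * (1 - pbar) - (k - 1) / k * s2)
    return float(a / (a + b)) if (a + b) != 0 else float("nan")


@dataclass
class FstResult:
    per_locus: np.ndarray      # clamped to [0, 1] for reporting
    mean: float                # ratio-of-sums over informative loci
    resample_means: np.ndarray
    ci99: tuple
    n_informative: int


def resample_fst(p1, n1, p2, n2, B: int = 1000, L: int = 1000,
                 seed: int = 0) -> FstResult:
    """Resampled distribution of mean Fst.

    Each of B replicates draws L informative loci without replacement and
    forms the ratio-of-sums mean; the 99% CI is the empirical 0.5/99.5
    percentile pair. L is reduced with a warning when fewer informative
    loci exist.
    """
    num, den = fst_components(np.asarray(p1, float), n1, np.asarray(p2, float), n2)
    keep = den > 0
    num, den = num[keep], den[keep]
    m = len(num)
    if m == 0:
        raise ValueError("no informative loci")
    if L > m:
        warnings.warn(f"only {m} informative loci; reducing L from {L}")
        L = m
    per_locus = np.clip(num / den, 0.0, 1.0)
    mean = float(num.sum() / den.sum())
    rng = np.random.default_rng(seed)
    means = np.empty(B)
    for b in range(B):
        idx = rng.choice(m, size=L, replace=False)
        means[b] = num[idx].sum() / den[idx].sum()
    lo, hi = np.percentile(means, [0.5, 99.5])
    return FstResult(per_locus=per_locus, mean=mean, resample_means=means,
                     ci99=(float(lo), float(hi)), n_informative=m)


# ------------------------------------------------------------------- Qst

@dataclass
class QstResult:
    msb: float          # mean square among populations (on line means)
    msw_lines: float    # mean square among lines within populations
    ms_error: float     # pooled replicate mean square
    n0: float           # effective per-population line count
    sigma2_gb: float
    sigma2_gw: float
    qst: float          # NaN when total genetic variance is zero
    defined: bool = True


def qst(trait_table: pd.DataFrame, panel: pd.Series) -> QstResult:
    """Qst = sigma2_GB / (sigma2_GB + 2 * sigma2_GW) by nested random-effects
    ANOVA (population / line-within-population / replicate).

    Works on line means when replicated, subtracting the replicate-noise
    contribution so both components are genetic; negative component
    estimates are clamped to zero. ``trait_table`` has columns line /
    replicate / trait.
    """
    df = trait_table.dropna(subset=["trait"]).copy()
    df["population"] = df["line"].map(panel)
    pops = df["population"].unique()
    if len(pops) < 2:
        raise ValueError("need >= 2 populations")
    line_means = df.groupby(["population", "line"])["trait"].mean()
    reps = df.groupby("line")["trait"].count()
    r_mean = float(reps.mean())

    # replicate (error) mean square, pooled over lines with >= 2 replicates
    if (reps > 1).any():
        within = df.groupby("line")["trait"].var(ddof=1).dropna()
        ms_error = float(within.mean())
    else:
        ms_error = 0.0

    k = len(pops)
    ni = line_means.groupby("population").size().to_numpy(float)
    if np.any(ni < 2):
        raise ValueError("need >= 2 lines per population")
    N = ni.sum()
    n0 = (N - (ni ** 2).sum() / N) / (k - 1)

    grand = line_means.mean()
    pop_means = line_means.groupby("population").mean()
    msb = float((ni * (pop_means.to_numpy() - grand) ** 2).sum() / (k - 1))
    ssw = sum(((line_means[pop] - pop_means[pop]) ** 2).sum() for pop in pops)
    msw = float(ssw / (N - k))

    sigma2_gw = max(msw - ms_error / r_mean, 0.0)
    sigma2_gb = max((msb - msw) / n0, 0.0)
    total = sigma2_gb + sigma2_gw
    if total == 0:
        return QstResult(msb, msw, ms_error, n0, 0.0, 0.0, float("nan"),
                         defined=False)
    q = sigma2_gb / (sigma2_gb + 2 * sigma2_gw)
    return QstResult(msb, msw, ms_error, float(n0), sigma2_gb, sigma2_gw,
                     float(q))


@dataclass
class SelectionCall:
    regime: str  # directional | drift | stabilizing
    qst: float
    fst_ci99: tuple


def qst_fst_call(qst_value: float, fst_result: FstResult) -> SelectionCall:
    """Directional when Qst exceeds the upper 99% Fst bound, stabilizing
    when below the lower bound, drift otherwise."""
    lo, hi = fst_result.ci99
    if qst_value > hi:
        regime = "directional"
    elif qst_value < lo:
        regime = "stabilizing"
    else:
        regime = "drift"
    return SelectionCall(regime=regime, qst=float(qst_value), fst_ci99=(lo, hi))


# -------------------------------------------------------------------- LD

def _pair_ld(x: np.ndarray, y: np.ndarray):
    """(r2, |D'|, D) from two haploid 0/1 vectors over complete cases."""
    ok = (x >= 0) & (y >= 0)
    x, y = x[ok], y[ok]
    pa, pb = x.mean(), y.mean()
    if pa in (0.0, 1.0) or pb in (0.0, 1.0):
        return np.nan, np.nan, np.nan
    pab = (x & y).mean()
    d = pab - pa * pb
    denom = pa * (1 - pa) * pb * (1 - pb)
    r2 = d * d / denom
    dmax = min(pa * (1 - pb), pb * (1 - pa)) if d > 0 else min(pa * pb, (1 - pa) * (1 - pb))
    dprime = abs(d) / dmax if dmax > 0 else np.nan
    return float(r2), float(dprime), float(d)


def ld_stats(genotypes: pd.DataFrame, positions: pd.Series,
             max_distance: int = 500_000, min_geno: float = 0.5,
             hw_cutoff: float | None = None) -> pd.DataFrame:
    """Pairwise r2 and |D'| for marker pairs within ``max_distance``.

    Markers genotyped in fewer than ``min_geno`` of lines, and monomorphic
    markers, are removed first. ``hw_cutoff`` (a Hardy-Weinberg filter in
    the diploid original) is inapplicable to haploid inbred lines and is
    accepted but ignored with a warning. Missing genotypes are coded < 0.
    """
    if hw_cutoff is not None:
        warnings.warn("Hardy-Weinberg cutoff ignored for haploid inbred data")
    g = genotypes.to_numpy()
    called = (g >= 0).mean(axis=0)
    poly = np.array([
        0 < g[g[:, j] >= 0, j].mean() < 1 if (g[:, j] >= 0).any() else False
        for j in range(g.shape[1])])
    keep = (called >= min_geno) & poly
    cols = genotypes.columns[keep]
    pos = positions[cols].to_numpy()
    order = np.argsort(pos, kind="stable")
    cols = cols[order]
    pos = pos[order]
    rows = []
    for i in range(len(cols)):
        for j in range(i + 1, len(cols)):
            dist = int(pos[j] - pos[i])
            if dist > max_distance:
                break
            r2, dp, d = _pair_ld(genotypes[cols[i]].to_numpy(),
                                 genotypes[cols[j]].to_numpy())
            rows.append((cols[i], cols[j], int(pos[i]), int(pos[j]),
                         dist, r2, dp, d))
    return pd.DataFrame(rows, columns=["marker_i", "marker_j", "pos_i",
                                       "pos_j", "distance", "r2", "dprime", "d"])


@dataclass
class LDBlockSet:
    blocks: pd.DataFrame  # chrom, start, end, n_markers, span_bp
    pairwise: pd.DataFrame
    size_classes: dict = field(default_factory=dict)


def ld_blocks(genotypes: pd.DataFrame, positions: pd.Series, chrom: str = "",
              max_distance: int = 500_000, min_geno: float = 0.5,
              ci_reps: int = 100, seed: int = 0,
              strong_low: float = 0.70, strong_high: float = 0.98,
              recomb_high: float = 0.90, strong_fraction: float = 0.95) -> LDBlockSet:
    """Gabriel-style LD blocks from D' bootstrap confidence intervals.

    A pair is "strong LD" when its bootstrap D' CI has lower bound >=
    ``strong_low`` and upper bound >= ``strong_high``, and shows "evidence
    of recombination" when the upper bound is < ``recomb_high``. Maximal
    runs of consecutive markers in which at least ``strong_fraction`` of
    informative pairs are strong become blocks. The D' CI is a percentile
    bootstrap over lines (the likelihood CI of the original Haploview
    implementation is replaced by a seeded nonparametric one).
    """
    pw = ld_stats(genotypes, positions, max_distance=max_distance,
                  min_geno=min_geno)
    if len(pw) == 0:
        empty = pd.DataFrame(columns=["chrom", "start", "end", "n_markers",
                                      "span_bp"])
        return LDBlockSet(blocks=empty, pairwise=pw,
                          size_classes={"lt1kb": 0, "1to5kb": 0, "ge5kb": 0})
    markers = sorted(set(pw["marker_i"]) | set(pw["marker_j"]),
                     key=lambda m: positions[m])
    index = {m: i for i, m in enumerate(markers)}
    rng = np.random.default_rng(seed)
    n_lines = len(genotypes)
    status = {}
    for _, row in pw.iterrows():
        x = genotypes[row["marker_i"]].to_numpy()
        y = genotypes[row["marker_j"]].to_numpy()
        boots = np.empty(ci_reps)
        for b in range(ci_reps):
            idx = rng.integers(0, n_lines, n_lines)
            boots[b] = _pair_ld(x[idx], y[idx])[1]
        boots = boots[~np.isnan(boots)]
        if len(boots) == 0:
            continue
        lo, hi = np.percentile(boots, [2.5, 97.5])
        i, j = index[row["marker_i"]], index[row["marker_j"]]
        if lo >= strong_low and hi >= strong_high:
            status[(i, j)] = "strong"
        elif hi < recomb_high:
            status[(i, j)] = "recomb"

    def run_is_block(i, j):
        pairs = [status.get((a, b)) for a in range(i, j + 1)
                 for b in range(a + 1, j + 1) if (a, b) in status]
        if not pairs:
            return False
        return pairs.count("strong") / len(pairs) >= strong_fraction

    blocks, used = [], np.zeros(len(markers), bool)
    # longest-first maximal runs; blocks never overlap
    for span in range(len(markers) - 1, 0, -1):
        for i in range(0, len(markers) - span):
            j = i + span
            if used[i:j + 1].any():
                continue
            if run_is_block(i, j):
                start = int(positions[markers[i]])
                end = int(positions[markers[j]])
                blocks.append((chrom, start, end, span + 1, end - start))
                used[i:j + 1] = True
    bdf = pd.DataFrame(sorted(blocks, key=lambda r: r[1]),
                       columns=["chrom", "start", "end", "n_markers", "span_bp"])
    sizes = {
        "lt1kb": int((bdf["span_bp"] < 1000).sum()) if len(bdf) else 0,
        "1to5kb": int(((bdf["span_bp"] >= 1000) & (bdf["span_bp"] < 5000)).sum()) if len(bdf) else 0,
        "ge5kb": int((bdf["span_bp"] >= 5000).sum()) if len(bdf) else 0,
    }
    return LDBlockSet(blocks=bdf, pairwise=pw, size_classes=sizes)
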