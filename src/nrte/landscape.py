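"""Window-based genomic landscape: densities, recombination rate, gene
context of insertions, and correlations between window tracks.

Chromosomes are tiled with contiguous 1-Mb windows (the last window may be
short); every per-window value is normalized per Mb of actual window
width. Recombination rate comes from a Marey map — genetic position (cM)
against physical position (bp) — interpolated piecewise-linearly so window
rates integrate exactly back to the chromosome's total cM span.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

WINDOW_SIZE = 1_000_000

CONTEXTS = ("exon", "five_prime_UTR", "three_prime_UTR", "intron",
            "upstream_1kb", "downstream_1kb", "intergenic")


def make_windows(chrom_lengths: dict, size: int = WINDOW_SIZE) -> pd.DataFrame:
    rows = []
    for chrom, L in chrom_lengths.items():
        starts = np.arange(0, L, size)
        for s in starts:
            rows.append((chrom, int(s), int(min(s + size, L))))
    return pd.DataFrame(rows, columns=["chrom", "start", "end"])


@dataclass
class WindowTrack:
    name: str
    windows: pd.DataFrame  # chrom, start, end
    values: np.ndarray
    region: np.ndarray | None = None  # "arm" | "pericentromere" per window

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if len(self.values) != len(self.windows):
            raise ValueError("values/windows length mismatch")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("window values must be finite")

    def to_bedgraph(self, path) -> None:
        df = self.windows.copy()
        df["value"] = self.values
        df.to_csv(path, sep="\t", header=False, index=False)


def label_regions(windows: pd.DataFrame, pericentromeres: pd.DataFrame) -> np.ndarray:
    """Label each window arm/pericentromere from an interval table
    (chrom, start, end); a window overlapping a pericentromere by any
    amount is pericentromeric."""
    labels = np.array(["arm"] * len(windows), dtype=object)
    for _, p in pericentromeres.iterrows():
        m = ((windows["chrom"] == p["chrom"]) & (windows["start"] < p["end"])
             & (windows["end"] > p["start"]))
        labels[m.to_numpy()] = "pericentromere"
    return labels


def window_density(positions: pd.DataFrame, windows: pd.DataFrame,
                   chrom_lengths: dict, name: str = "density",
                   region: np.ndarray | None = None) -> WindowTrack:
    """Count per window, normalized per Mb of actual window width.

    ``positions`` needs chrom + position columns (point features); interval
    features should be reduced to a representative point (e.g. midpoint)
    by the caller.
    """
    for _, r in positions.iterrows():
        if r["position"] < 0 or r["position"] >= chrom_lengths[r["chrom"]]:
            raise ValueError(f"feature outside chromosome: {tuple(r)}")
    values = np.zeros(len(windows))
    for chrom, grp in positions.groupby("chrom"):
        wmask = windows["chrom"] == chrom
        w = windows[wmask]
        edges = np.append(w["start"].to_numpy(), w["end"].to_numpy()[-1])
        counts, _ = np.histogram(grp["position"], bins=edges)
        values[wmask.to_numpy()] = counts
    width_mb = (windows["end"] - windows["start"]).to_numpy() / 1e6
    return WindowTrack(name=name, windows=windows, values=values / width_mb,
                       region=region)


class GeneticMap:
    """Cleaned Marey map with piecewise-linear interpolation.

    Within each chromosome cM must be non-decreasing in bp after removing
    exact duplicates; beyond the terminal markers the nearest segment's
    slope is extrapolated.
    """

    def __init__(self, table: pd.DataFrame):
        self.curves = {}
        for chrom, grp in table.groupby("chrom"):
            grp = grp.sort_values("position").drop_duplicates("position")
            pos = grp["position"].to_numpy(float)
            cm = grp["cm"].to_numpy(float)
            if len(pos) < 2:
                raise ValueError(f"{chrom}: need >= 2 map markers")
            bad = np.flatnonzero(np.diff(cm) < 0)
            if len(bad):
                raise ValueError(
                    f"{chrom}: non-monotone cM at markers "
                    f"{[(int(pos[i]), float(cm[i])) for i in bad]}")
            self.curves[chrom] = (pos, cm)

    def cm_at(self, chrom: str, x: np.ndarray) -> np.ndarray:
        pos, cm = self.curves[chrom]
        x = np.asarray(x, dtype=float)
        out = np.interp(x, pos, cm)
        lo_slope = (cm[1] - cm[0]) / (pos[1] - pos[0])
        hi_slope = (cm[-1] - cm[-2]) / (pos[-1] - pos[-2])
        left = x < pos[0]
        right = x > pos[-1]
        out[left] = cm[0] + (x[left] - pos[0]) * lo_slope
        out[right] = cm[-1] + (x[right] - pos[-1]) * hi_slope
        return out


def gr_rate(genetic_map: GeneticMap | pd.DataFrame, windows: pd.DataFrame,
            region: np.ndarray | None = None) -> WindowTrack:
    """cM/Mb per window from the Marey curve."""
    gmap = genetic_map if isinstance(genetic_map, GeneticMap) else GeneticMap(genetic_map)
    rates = np.empty(len(windows))
    for chrom, grp in windows.groupby("chrom"):
        a = gmap.cm_at(chrom, grp["start"].to_numpy())
        b = gmap.cm_at(chrom, grp["end"].to_numpy())
        width_mb = (grp["end"] - grp["start"]).to_numpy() / 1e6
        rates[grp.index.to_numpy()] = (b - a) / width_mb
    return WindowTrack(name="cM/Mb", windows=windows, values=rates, region=region)


def classify_context(loci: pd.DataFrame, genes: pd.DataFrame,
                     gene_features: pd.DataFrame, flank_bp: int = 1000) -> pd.Series:
    """Gene context of each insertion point, one category per locus.

    Precedence: exon > UTR > intron > 1-kb flank > intergenic. Up/downstream
    is strand-aware; a locus in the flank of two genes goes to the nearer
    one, ties to upstream. Genes without exon-level features are rejected.
    """
    by_gene = dict(tuple(gene_features.groupby("gene_id")))
    for gid in genes["gene_id"]:
        feats = by_gene.get(gid)
        if feats is None or not (feats["feature"] == "exon").any():
            raise ValueError(f"gene {gid} has no exon features")

    out = []
    for _, loc in loci.iterrows():
        chrom, pos = loc["chrom"], loc["position"]
        g = genes[genes["chrom"] == chrom]
        inside = g[(g["start"] <= pos) & (pos < g["end"])]
        category = None
        if len(inside):
            gid = inside.iloc[0]["gene_id"]
            feats = by_gene[gid]
            hit = feats[(feats["start"] <= pos) & (pos < feats["end"])]
            priority = {"exon": 0, "five_prime_UTR": 1, "three_prime_UTR": 1}
            if len(hit):
                category = hit.sort_values(
                    "feature", key=lambda s: s.map(lambda f: priority.get(f, 2))
                ).iloc[0]["feature"]
            else:
                category = "intron"
        else:
            best = None  # (distance, category)
            for _, gene in g.iterrows():
                if pos < gene["start"] and gene["start"] - pos <= flank_bp:
                    d = gene["start"] - pos
                    cat = "upstream_1kb" if gene["strand"] == "+" else "downstream_1kb"
                elif pos >= gene["end"] and pos - gene["end"] + 1 <= flank_bp:
                    d = pos - gene["end"] + 1
                    cat = "downstream_1kb" if gene["strand"] == "+" else "upstream_1kb"
                else:
                    continue
                rank = (d, 0 if cat == "upstream_1kb" else 1)
                if best is None or rank < best[0]:
                    best = (rank, cat)
            category = best[1] if best else "intergenic"
        out.append(category)
    return pd.Series(out, index=loci.index, name="context")


@dataclass
class Correlation:
    r: float
    p_value: float
    n: int
    defined: bool = True


def correlate_tracks(a: WindowTrack, b: WindowTrack,
                     region: str = "all") -> Correlation:
    """Pearson correlation between two tracks over shared windows.

    ``region='arms'`` drops pericentromeric windows (both tracks must carry
    region labels). Zero-variance input yields an undefined (flagged)
    result rather than an arbitrary number.
    """
    if not a.windows.reset_index(drop=True).equals(b.windows.reset_index(drop=True)):
        raise ValueError("tracks are on different windows")
    x, y = a.values, b.values
    if region == "arms":
        if a.region is None:
            raise ValueError("region labels required for arm-only correlation")
        keep = np.asarray(a.region) == "arm"
        x, y = x[keep], y[keep]
    if len(x) < 3 or np.std(x) == 0 or np.std(y) == 0:
        return Correlation(r=float("nan"), p_value=float("nan"), n=len(x),
                           defined=False)
    r, p = stats.pearsonr(x, y)
    return Correlation(r=float(r), p_value=float(p), n=len(x))
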