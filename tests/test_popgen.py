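"""Frequency spectra, Hudson Fst + resampling CI, Qst variance components,
the selection-regime call, and LD statistics/blocks."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats as sps

from nrte.popgen import (FstResult, fst_components, fst_locus, ld_blocks,
                         ld_stats, qst, qst_fst_call, resample_fst, spectrum)


# ------------------------------------------------------------- spectrum

def test_spectrum_bins_and_boundaries():
    s = spectrum(pd.Series([0.05, 0.3, 0.9]), genome_size=1_000_000)
    assert (s.n_low, s.n_intermediate, s.n_high) == (1, 1, 1)
    # boundary convention: [0, 0.1) / [0.1, 0.5] / (0.5, 1]
    s2 = spectrum(pd.Series([0.1, 0.5, 0.0999]), genome_size=1_000_000)
    assert (s2.n_low, s2.n_intermediate, s2.n_high) == (1, 2, 0)


def test_spectrum_density_counts_present_loci_only():
    s = spectrum(pd.Series([0.0, 0.0, 0.2]), genome_size=2_000_000)
    assert s.density_per_mb == pytest.approx(0.5)
    s0 = spectrum(pd.Series([0.0, 0.0]), genome_size=2_000_000)
    assert s0.density_per_mb == 0.0


def test_spectrum_beta_bins_match_cdf():
    """Beta(0.5, 5) frequencies: realized bin proportions within 2 SE of
    the Beta CDF expectation."""
    rng = np.random.default_rng(12)
    n = 4000
    f = pd.Series(rng.beta(0.5, 5, n))
    s = spectrum(f, genome_size=1_000_000)
    p_low = sps.beta.cdf(0.1, 0.5, 5)
    se = np.sqrt(p_low * (1 - p_low) / n)
    assert abs(s.n_low / n - p_low) < 2 * se


# ------------------------------------------------------------------ Fst

def test_fst_no_differentiation_and_fixed_difference():
    assert fst_locus(0.5, 10_000, 0.5, 10_000) == pytest.approx(0.0, abs=1e-3)
    assert fst_locus(1.0, 31, 0.0, 52) == pytest.approx(1.0)


def test_fst_matches_hand_computed_hudson():
    # Hw = ((.8*.2*31/30) + (.1*.9*52/51))/2, Hb = (.8*.9 + .1*.2)/2
    p1, n1, p2, n2 = 0.8, 31, 0.1, 52
    hw = 0.5 * (p1 * (1 - p1) * n1 / (n1 - 1) + p2 * (1 - p2) * n2 / (n2 - 1))
    hb = 0.5 * (p1 * (1 - p2) + p2 * (1 - p1))
    assert fst_locus(p1, n1, p2, n2) == pytest.approx(1 - hw / hb)


def test_fst_monomorphic_both_undefined():
    assert np.isnan(fst_locus(0.0, 10, 0.0, 10))
    assert np.isnan(fst_locus(1.0, 10, 1.0, 10))


@settings(max_examples=100, deadline=None)
@given(c1=st.integers(0, 200), c2=st.integers(0, 200),
       n1=st.integers(2, 200), n2=st.integers(2, 200))
def test_fst_symmetry_and_allele_relabeling(c1, c2, n1, n2):
    # frequencies are realizable carrier fractions of haploid lines
    p1, p2 = min(c1, n1) / n1, min(c2, n2) / n2
    a = fst_locus(p1, n1, p2, n2)
    b = fst_locus(p2, n2, p1, n1)
    c = fst_locus(1 - p1, n1, 1 - p2, n2)
    if np.isnan(a):
        assert np.isnan(b) and np.isnan(c)
    else:
        assert a == pytest.approx(b, rel=1e-9, abs=1e-9)
        assert a == pytest.approx(c, rel=1e-9, abs=1e-9)


def test_weir_cockerham_switch_agrees_on_large_samples():
    h = fst_locus(0.7, 500, 0.2, 500, estimator="hudson")
    w = fst_locus(0.7, 500, 0.2, 500, estimator="wc")
    assert h == pytest.approx(w, abs=0.02)


def test_resample_fst_degenerate_and_single_replicate():
    p1 = np.full(50, 0.9)
    p2 = np.full(50, 0.1)
    res = resample_fst(p1, 20, p2, 20, B=10, L=50, seed=0)
    assert res.ci99[0] == pytest.approx(res.ci99[1])  # all loci identical
    one = resample_fst(p1, 20, p2, 20, B=1, L=50, seed=0)
    assert one.ci99[0] == pytest.approx(one.resample_means[0])


def test_resample_fst_seeded_and_covers_full_mean():
    rng = np.random.default_rng(7)
    p1 = rng.beta(0.8, 0.8, 300)
    p2 = rng.beta(0.8, 0.8, 300)
    a = resample_fst(p1, 31, p2, 52, B=200, L=100, seed=5)
    b = resample_fst(p1, 31, p2, 52, B=200, L=100, seed=5)
    assert a.ci99 == b.ci99
    assert np.array_equal(a.resample_means, b.resample_means)
    # resampled means bracket the exhaustive full-data ratio-of-sums mean
    assert a.ci99[0] <= a.mean <= a.ci99[1]
    assert a.resample_means.min() <= a.mean <= a.resample_means.max()


def test_resample_fst_reduces_l_with_warning():
    with pytest.warns(UserWarning, match="reducing L"):
        resample_fst(np.array([0.9, 0.2]), 10, np.array([0.1, 0.8]), 10,
                     B=5, L=1000, seed=0)


# ------------------------------------------------------------------ Qst

def _nested_data(rng, n_lines=20, reps=2, d=0.0, gw_sd=1.0, e_sd=1.0):
    rows = []
    for pi, pop in enumerate(("temperate", "tropical")):
        mu = (-d / 2, d / 2)[pi]
        g = mu + rng.normal(0, gw_sd, n_lines)
        for l in range(n_lines):
            for r in range(reps):
                rows.append((f"{pop[:3]}{l}", r + 1, g[l] + rng.normal(0, e_sd)))
    df = pd.DataFrame(rows, columns=["line", "replicate", "trait"])
    panel = pd.Series({f"{p[:3]}{l}": p for p in ("temperate", "tropical")
                       for l in range(n_lines)})
    return df, panel


def test_qst_formula_identity_balanced_plugin():
    """Construct balanced noise-free data with exactly known components:
    equal between- and within-population components give Qst = 1/3.

    4 lines per population, deviations (-3,-1,1,3) around pop means +/- a:
    MSW = 20/3; MSB = 8 a^2; n0 = 4, so choosing a^2 = 25/6 makes the
    between component (MSB - MSW)/n0 equal the within component exactly.
    """
    a = np.sqrt(25 / 6)
    rows = []
    for pop, mu in (("A", -a), ("B", a)):
        for i, dev in enumerate((-3.0, -1.0, 1.0, 3.0)):
            rows.append((f"{pop}{i}", 1, mu + dev))
    df = pd.DataFrame(rows, columns=["line", "replicate", "trait"])
    panel = pd.Series({r[0]: {"A": "temperate", "B": "tropical"}[r[0][0]]
                       for r in rows})
    res = qst(df, panel)
    assert res.sigma2_gb == pytest.approx(res.sigma2_gw)
    assert res.qst == pytest.approx(1 / 3)


def test_qst_zero_between_component_gives_zero():
    rng = np.random.default_rng(0)
    df, panel = _nested_data(rng, n_lines=200, d=0.0, gw_sd=1.0, e_sd=0.0)
    res = qst(df, panel)
    assert res.qst < 0.05  # clamped near zero without true divergence


def test_qst_monotone_in_between_component():
    rng = np.random.default_rng(1)
    vals = []
    for d in (0.0, 1.0, 2.0, 4.0):
        df, panel = _nested_data(np.random.default_rng(9), n_lines=100, d=d,
                                 e_sd=0.2)
        vals.append(qst(df, panel).qst)
    assert vals == sorted(vals)
    del rng


def test_qst_undefined_without_genetic_variance():
    df, panel = _nested_data(np.random.default_rng(2), n_lines=5, d=0.0,
                             gw_sd=0.0, e_sd=0.0)
    res = qst(df, panel)
    assert not res.defined and np.isnan(res.qst)


def test_qst_recovers_generating_ratio():
    """200 nested datasets with realized sigma2_GB/sigma2_GW = 2: the mean
    Qst estimate lands within 0.05 of 2/(2+2) = 0.5."""
    ests = []
    rng = np.random.default_rng(42)
    for _ in range(200):
        df, panel = _nested_data(rng, n_lines=30, reps=2, d=2.0, gw_sd=1.0)
        ests.append(qst(df, panel).qst)
    assert np.mean(ests) == pytest.approx(0.5, abs=0.05)


@pytest.mark.parametrize("q,expected", [
    (0.9, "directional"), (0.15, "drift"), (0.05, "stabilizing")])
def test_selection_call_regimes(q, expected):
    fst = FstResult(per_locus=np.array([0.15]), mean=0.15,
                    resample_means=np.array([0.15]), ci99=(0.1, 0.2),
                    n_informative=1)
    assert qst_fst_call(q, fst).regime == expected


# -------------------------------------------------------------------- LD

def test_ld_identical_markers_perfect():
    rng = np.random.default_rng(0)
    x = rng.integers(0, 2, 40)
    g = pd.DataFrame({"a": x, "b": x})
    pw = ld_stats(g, pd.Series({"a": 100, "b": 500}))
    assert pw.iloc[0]["r2"] == pytest.approx(1.0)
    assert pw.iloc[0]["dprime"] == pytest.approx(1.0)


def test_ld_respects_max_distance_and_monomorphic_exclusion():
    rng = np.random.default_rng(1)
    g = pd.DataFrame({"a": rng.integers(0, 2, 30),
                      "b": rng.integers(0, 2, 30),
                      "mono": np.ones(30, dtype=int)})
    pos = pd.Series({"a": 0, "b": 600_000, "mono": 100})
    pw = ld_stats(g, pos, max_distance=500_000)
    assert len(pw) == 0  # monomorphic dropped; remaining pair too far


def test_ld_r2_d_identity_and_null_level():
    """r2 * pA(1-pA)pB(1-pB) == D^2 by construction, and independent
    markers show mean r2 near 1/n."""
    rng = np.random.default_rng(2)
    n, m = 200, 30
    g = pd.DataFrame(rng.integers(0, 2, (n, m)),
                     columns=[f"s{i}" for i in range(m)])
    pos = pd.Series(np.arange(m) * 10, index=g.columns)
    pw = ld_stats(g, pos)
    for _, row in pw.head(50).iterrows():
        pa = g[row["marker_i"]].mean()
        pb = g[row["marker_j"]].mean()
        assert row["r2"] * pa * (1 - pa) * pb * (1 - pb) == pytest.approx(
            row["d"] ** 2)
    mean_r2 = pw["r2"].mean()
    se = pw["r2"].std() / np.sqrt(len(pw))
    assert abs(mean_r2 - 1 / n) < 2 * se + 1e-3


def test_ld_min_geno_filter():
    g = pd.DataFrame({"a": [1, 0, 1, 0], "b": [-1, -1, -1, 0]})
    pw = ld_stats(g, pd.Series({"a": 0, "b": 10}), min_geno=0.5)
    assert len(pw) == 0  # marker b only 25% genotyped


def test_ld_hw_cutoff_ignored_with_warning():
    g = pd.DataFrame({"a": [1, 0, 1, 0], "b": [1, 0, 0, 1]})
    with pytest.warns(UserWarning, match="Hardy-Weinberg"):
        ld_stats(g, pd.Series({"a": 0, "b": 10}), hw_cutoff=0.001)


def test_ld_blocks_perfect_run_single_block():
    rng = np.random.default_rng(3)
    hap = rng.integers(0, 2, 60)
    g = pd.DataFrame({f"m{i}": hap for i in range(5)})
    pos = pd.Series({f"m{i}": 1000 * i for i in range(5)})
    res = ld_blocks(g, pos, chrom="c", ci_reps=50, seed=0)
    assert len(res.blocks) == 1
    blk = res.blocks.iloc[0]
    assert blk["n_markers"] == 5 and blk["start"] == 0 and blk["end"] == 4000
    assert res.size_classes["1to5kb"] == 1


def test_ld_blocks_independent_markers_none():
    rng = np.random.default_rng(4)
    g = pd.DataFrame(rng.integers(0, 2, (80, 8)),
                     columns=[f"m{i}" for i in range(8)])
    pos = pd.Series(np.arange(8) * 500, index=g.columns)
    res = ld_blocks(g, pos, ci_reps=50, seed=1)
    assert len(res.blocks) == 0


def test_ld_blocks_recombinant_marker_splits_runs():
    rng = np.random.default_rng(5)
    h1 = rng.integers(0, 2, 80)
    h2 = rng.integers(0, 2, 80)
    cols = {f"a{i}": h1 for i in range(3)}
    cols["x"] = rng.integers(0, 2, 80)  # independent, breaks the run
    cols.update({f"b{i}": h2 for i in range(3)})
    g = pd.DataFrame(cols)
    pos = pd.Series({c: 1000 * i for i, c in enumerate(g.columns)})
    res = ld_blocks(g, pos, chrom="c", ci_reps=50, seed=2)
    spans = set(zip(res.blocks["start"], res.blocks["end"]))
    assert (0, 2000) in spans and (4000, 6000) in spans
    assert len(res.blocks) == 2
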