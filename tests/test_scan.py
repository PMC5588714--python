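"""Junction detection: constructed read fixtures, the reference-resident
filter, unique flank placement, clustering, and truth-set oracles."""

import numpy as np
import pandas as pd
import pytest

from conftest import match_truth
from nrte._seq import revcomp
from nrte.edges import build_edge_db
from nrte.scan import (JunctionScanner, TE_LEFT, TE_RIGHT, cluster_hits,
                       hits_to_frame, iter_fastq, population_frequencies,
                       qc_read, sharing_spectrum)
from nrte.simulate import TEMPERATE


# ------------------------------------------------------------------ qc

def test_qc_truncates_clean_read():
    seq, qual = b"A" * 100, bytes([63]) * 100  # Q30
    assert qc_read(seq, qual) == b"A" * 75


def test_qc_drops_short_read():
    assert qc_read(b"A" * 70, bytes([63]) * 70) is None


def test_qc_trims_trailing_low_quality_then_truncates():
    # 80 good bases + 30 trailing Q2: the stated rule trims the tail first
    # (leaving 80 >= 75), then hard-truncates to 75
    seq = b"C" * 110
    qual = bytes([63]) * 80 + bytes([35]) * 30  # Q30 then Q2
    assert qc_read(seq, qual, quality_threshold=20) == b"C" * 75
    # trailing bad tail leaving only 60 bases -> dropped
    qual2 = bytes([63]) * 60 + bytes([35]) * 50
    assert qc_read(seq, qual2, quality_threshold=20) is None


def test_qc_rejects_length_mismatch_and_bad_fastq(tmp_path):
    with pytest.raises(ValueError):
        qc_read(b"ACGT", b"!!!")
    bad = tmp_path / "bad.fastq"
    bad.write_text("@r1\nACGT\nnot-plus\n!!!!\n")
    with pytest.raises(ValueError, match="record #0"):
        list(iter_fastq(bad))


# ----------------------------------------------- constructed junction reads

@pytest.fixture(scope="module")
def toy():
    """One TE on a random 10-kb reference; scanner over both."""
    rng = np.random.default_rng(99)
    ref = bytes(rng.choice(np.frombuffer(b"ACGT", np.uint8), 10_000).tobytes())
    te = bytes(rng.choice(np.frombuffer(b"ACGT", np.uint8), 400).tobytes())
    db = build_edge_db({"DTM_toy": te})
    sc = JunctionScanner(db, {"chr1": ref})
    return ref, te, db, sc


def test_match_te_edge_suffix_of_3prime_edge(toy):
    ref, te, db, sc = toy
    read = te[-30:] + ref[5000:5045]  # 30 bp TE 3' end + 45 bp flank
    stubs = sc.match_te_edge(read)
    assert len(stubs) == 1
    idx, k, side, strand, flank = stubs[0]
    assert k == 30 and side == TE_LEFT and strand == "+" and flank == ref[5000:5045]


def test_match_te_edge_prefix_reverse_strand(toy):
    ref, te, db, sc = toy
    fragment = ref[7000:7040] + te[:35]  # flank + TE 5' start
    read = revcomp(fragment)
    stubs = sc.match_te_edge(read)
    assert len(stubs) == 1
    idx, k, side, strand, flank = stubs[0]
    assert k == 35 and side == TE_LEFT and strand == "-"
    assert flank == revcomp(ref[7000:7040])


def test_match_te_edge_below_floor_and_inside_te(toy):
    ref, te, db, sc = toy
    assert sc.match_te_edge(te[-19:] + ref[100:156]) == []  # 19 bp < floor
    assert sc.match_te_edge(te[100:175]) == []  # wholly internal to the TE
    assert sc.match_te_edge(te[:56] + ref[0:19]) == []  # flank below 20 bp


def test_hit_invariant_te_plus_flank_is_75(toy):
    ref, te, db, sc = toy
    for k in (20, 37, 55):
        read = te[-k:] + ref[3000:3000 + 75 - k]
        (idx, kk, side, strand, flank), = sc.match_te_edge(read)
        assert kk + len(flank) == 75


# ------------------------------------------------- reference filter

def test_reference_filter_discards_verbatim_read(toy):
    ref, te, db, sc = toy
    assert sc.reference_te_filter(ref[2000:2075]) is False  # 75/75 match


def test_reference_filter_keeps_true_junction(toy):
    ref, te, db, sc = toy
    read = te[-30:] + ref[5000:5045]  # flank 45 < 65 matchable bases
    assert sc.reference_te_filter(read) is True


def test_reference_filter_discards_two_error_read(toy):
    # identity 73/75 = 97.3% over a 75-bp span >= 65 -> excluded
    ref, te, db, sc = toy
    read = bytearray(ref[2000:2075])
    for pos in (10, 50):
        read[pos] = ord("A") if read[pos] != ord("A") else ord("C")
    assert sc.reference_te_filter(bytes(read)) is False


def test_reference_filter_keeps_five_error_read(toy):
    # 70/75 = 93.3% overall; best 65-span identity still < 95%
    ref, te, db, sc = toy
    read = bytearray(ref[2000:2075])
    for pos in (5, 20, 35, 50, 65):
        read[pos] = ord("A") if read[pos] != ord("A") else ord("C")
    assert sc.reference_te_filter(bytes(read)) is True


# ------------------------------------------------- flank placement

def test_map_flank_unique_exact(toy):
    ref, te, db, sc = toy
    read = te[-30:] + ref[5000:5045]
    stub, = sc.match_te_edge(read)
    hit = sc.map_flank(stub, "L1")
    assert hit is not None
    assert hit.chrom == "chr1" and hit.breakpoint == 5000
    assert hit.te_match_len == 30


def test_map_flank_reverse_strand_same_breakpoint(toy):
    ref, te, db, sc = toy
    read = revcomp(ref[4960:5000] + te[:35])  # left junction at 5000, minus
    stub, = sc.match_te_edge(read)
    hit = sc.map_flank(stub, "L1")
    assert hit is not None and hit.breakpoint == 5000


def test_map_flank_rejects_nonunique_and_imperfect():
    rng = np.random.default_rng(5)
    core = bytes(rng.choice(np.frombuffer(b"ACGT", np.uint8), 600).tobytes())
    dup = core[100:150]
    ref = core + dup + core[200:300]  # the 50-mer occurs twice
    te = bytes(rng.choice(np.frombuffer(b"ACGT", np.uint8), 300).tobytes())
    sc = JunctionScanner(build_edge_db({"DTM_z": te}), {"c": ref})
    read = te[-25:] + ref[100:150]
    stub, = sc.match_te_edge(read)
    assert sc.map_flank(stub, "L") is None  # two locations
    mut = bytearray(ref[300:350])
    mut[10] ^= 6  # one mismatch in the flank
    stub2 = (stub[0], 25, TE_LEFT, "+", bytes(mut))
    assert sc.map_flank(stub2, "L") is None  # 100% rule


# ------------------------------------------------- clustering & genotypes

def _hits_frame(rows):
    return pd.DataFrame(rows, columns=["line_id", "chrom", "breakpoint",
                                       "te_class", "family", "edge_id",
                                       "te_match_len", "strand", "te_side"])


def test_cluster_nearby_hits_merge_distant_split():
    rows = [("A", "chr1", 1000, "DNA", "DTM", "e", 30, "+", TE_LEFT),
            ("B", "chr1", 1003, "DNA", "DTM", "e", 30, "+", TE_LEFT),
            ("A", "chr1", 1500, "DNA", "DTM", "e", 30, "+", TE_LEFT)]
    loci, geno = cluster_hits(_hits_frame(rows), lines=["A", "B"], tolerance_bp=10)
    assert len(loci) == 2
    assert loci["position"].tolist() == [1001, 1500]
    first = loci.iloc[0]["locus_id"]
    assert geno.loc["A", first] == 1 and geno.loc["B", first] == 1


def test_cluster_separates_superfamily_classes():
    rows = [("A", "chr1", 1000, "DNA", "DTM", "e", 30, "+", TE_LEFT),
            ("A", "chr1", 1002, "LTR/Gypsy", "RLG", "f", 30, "+", TE_LEFT)]
    loci, _ = cluster_hits(_hits_frame(rows), lines=["A"])
    assert len(loci) == 2


def test_min_support_filters_single_read_calls():
    rows = [("A", "chr1", 1000, "DNA", "DTM", "e", 30, "+", TE_LEFT),
            ("B", "chr1", 1001, "DNA", "DTM", "e", 30, "+", TE_LEFT),
            ("B", "chr1", 1002, "DNA", "DTM", "e", 30, "+", TE_LEFT)]
    loci, geno = cluster_hits(_hits_frame(rows), lines=["A", "B"], min_support=2)
    assert len(loci) == 1
    lid = loci.iloc[0]["locus_id"]
    assert geno.loc["A", lid] == 0 and geno.loc["B", lid] == 1


def test_sharing_spectrum_counts():
    g = pd.DataFrame({"l1": [1, 0, 0], "l2": [1, 1, 0], "l3": [1, 1, 1]},
                     index=["A", "B", "C"])
    assert sharing_spectrum(g) == (1, 1, 1)
    allg = pd.DataFrame(np.ones((4, 3), int), index=list("ABCD"))
    assert sharing_spectrum(allg) == (0, 0, 3)


def test_population_frequencies_missing_excluded():
    g = pd.DataFrame({"l1": [1, 0, -1, 1], "l2": [0, 0, 0, 0]},
                     index=["a", "b", "c", "d"])
    panel = pd.Series(["temperate"] * 2 + ["tropical"] * 2,
                      index=["a", "b", "c", "d"])
    f = population_frequencies(g, panel)
    assert f.loc["l1", "temperate"] == 0.5
    assert f.loc["l1", "tropical"] == 1.0  # one missing excluded from denom
    assert f.loc["l2", "tropical"] == 0.0
    # a population with zero genotyped lines -> undefined, not 0
    g2 = pd.DataFrame({"l1": [1, 1, -1, -1]}, index=["a", "b", "c", "d"])
    assert np.isnan(population_frequencies(g2, panel).loc["l1", "tropical"])


# ------------------------------------------------- end-to-end oracles

def test_detection_matches_truth_on_small_panel(small_cfg, panel_truth, called):
    """Error-free simulation: locus set, genotypes and frequencies all
    equal the planted truth."""
    truth, _ = panel_truth
    hits, loci, geno = called
    assert len(loci) == len(truth.loci)
    matches = match_truth(loci, truth.loci)
    assert all(len(v) == 1 for v in matches.values())
    for tl, (ci,) in matches.items():
        cl = loci.loc[ci, "locus_id"]
        assert (geno[cl].loc[truth.genotypes.index]
                == truth.genotypes[tl]).all()
    # frequencies equal truth frequencies
    freqs = population_frequencies(geno, truth.panel)
    for tl, (ci,) in matches.items():
        cl = loci.loc[ci, "locus_id"]
        assert freqs.loc[cl, TEMPERATE] == truth.frequencies.loc[tl, TEMPERATE]
    # sharing spectrum equals the truth-derived spectrum
    assert sharing_spectrum(geno) == sharing_spectrum(truth.genotypes)


def test_every_hit_obeys_match_length_bounds(called):
    hits, _, _ = called
    for h in hits:
        assert 20 <= h.te_match_len <= 55


def test_genotypes_invariant_under_read_and_line_order(small_cfg, panel_truth,
                                                       scanner, called):
    truth, blocks = panel_truth
    _, loci, geno = called
    # rescan one line with reads reversed: same hits, hence same calls
    blk = blocks[0]
    reads = list(blk)[::-1]
    hits_rev = scanner.scan_reads(blk.line_id, reads)
    hits_fwd = scanner.scan_reads(blk.line_id, list(blk))
    key = lambda h: (h.chrom, h.breakpoint, h.edge_id, h.te_match_len)
    assert sorted(map(key, hits_rev)) == sorted(map(key, hits_fwd))
    # frequencies invariant under line reordering
    panel = truth.panel
    shuffled = geno.sample(frac=1, random_state=0)
    f1 = population_frequencies(geno, panel)
    f2 = population_frequencies(shuffled, panel)
    pd.testing.assert_frame_equal(f1, f2)
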