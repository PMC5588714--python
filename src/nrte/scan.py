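"""Split-read detection of non-reference TE insertions.

The five-step pipeline: (1) quality-trim reads and truncate to 75 bp;
(2) find reads whose terminal 20-55 bp perfectly match the extremity of a
TE edge, leaving a 20-55 bp putative genomic flank; (3) discard reads that
align to the reference over >= 65 bp at >= 95% identity (TE copies already
resident in the assembly, not new junctions); (4) place the flank in the
reference, requiring a perfect match at exactly one location on either
strand; (5) cluster breakpoints into loci, genotype the panel by
presence/absence and compute per-population carrier frequencies.

All matching is exact (the junction rule is a 100%-identity rule); the
reference filter uses k-mer-seeded gapless alignment with substitutions
only.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._seq import KmerIndex, revcomp
from .edges import EdgeDB, FIVE_PRIME, THREE_PRIME

logger = logging.getLogger(__name__)

READ_LEN = 75
MATCH_MIN = 20
MATCH_MAX = 55
ANCHOR = 20
TE_LEFT = "left_of_flank"
TE_RIGHT = "right_of_flank"


def qc_read(seq: bytes, qual: bytes, quality_threshold: int = 20,
            min_length: int = READ_LEN) -> bytes | None:
    """Trim trailing low-quality bases, drop short reads, truncate to 75 bp.

    Qualities are Phred+33. Returns the surviving 75-bp sequence or None.
    """
    if len(seq) != len(qual):
        raise ValueError("sequence/quality length mismatch")
    thr = quality_threshold + 33
    j = len(qual)
    while j > 0 and qual[j - 1] < thr:
        j -= 1
    if j < min_length or j < READ_LEN:
        return None
    return seq[:READ_LEN]


def iter_fastq(path):
    """(seq, qual) byte pairs from an uncompressed FASTQ file; malformed
    records abort with the record index."""
    with open(path, "rb") as fh:
        i = 0
        while True:
            header = fh.readline()
            if not header:
                return
            seq = fh.readline().rstrip()
            plus = fh.readline()
            qual = fh.readline().rstrip()
            if not header.startswith(b"@") or not plus.startswith(b"+") \
                    or len(seq) != len(qual) or not qual:
                raise ValueError(f"malformed FASTQ record #{i} in {path}")
            yield seq, qual
            i += 1


@dataclass
class JunctionHit:
    line_id: str
    edge_id: str
    te_match_len: int
    te_side: str  # TE_LEFT | TE_RIGHT (relative to the flank in the read)
    chrom: str
    breakpoint: int  # 0-based reference insertion point
    strand: str
    te_class: str
    family: str


class JunctionScanner:
    """Exact-match junction detector over a TE edge DB and a reference.

    The edge index anchors on the 20 bases of the TE segment nearest the
    read boundary: one dictionary lookup of the read's first and last
    20-mer retrieves every (edge, match-length, strand) candidate, which is
    then verified by full string comparison. Both strands are covered by
    also indexing reverse-complemented edge extremities.
    """

    def __init__(self, edge_db: EdgeDB, reference_chromosomes: dict,
                 identity_min_span: int = 65, identity_threshold: float = 0.95):
        self.edge_db = edge_db
        self.identity_min_span = identity_min_span
        self.identity_threshold = identity_threshold
        self.ref_index = KmerIndex(reference_chromosomes, k=ANCHOR)
        # key: terminal 20-mer of the TE segment at the read boundary
        self._left: dict[bytes, list] = {}   # keyed by read[:20]
        self._right: dict[bytes, list] = {}  # keyed by read[-20:]
        for idx, e in enumerate(edge_db.edges):
            seq = e.sequence
            n = len(seq)
            for k in range(MATCH_MIN, min(MATCH_MAX, n) + 1):
                if e.end == FIVE_PRIME:
                    # junction spans the TE start: read suffix == edge prefix
                    fwd = seq[:k]
                    self._right.setdefault(fwd[-ANCHOR:], []).append((idx, k, "+"))
                    rc = revcomp(fwd)
                    self._left.setdefault(rc[:ANCHOR], []).append((idx, k, "-"))
                else:
                    # junction spans the TE end: read prefix == edge suffix
                    fwd = seq[n - k:]
                    self._left.setdefault(fwd[:ANCHOR], []).append((idx, k, "+"))
                    rc = revcomp(fwd)
                    self._right.setdefault(rc[-ANCHOR:], []).append((idx, k, "-"))

    # -- step 2: TE edge matching -------------------------------------
    def match_te_edge(self, read: bytes) -> list:
        """Candidate stubs (edge_idx, k, te_side, strand, flank) for a 75-bp
        read; the maximal match length per (edge, side) is kept."""
        if len(read) != READ_LEN:
            return []
        stubs: dict[tuple, tuple] = {}
        cands = self._right.get(read[-ANCHOR:])
        if cands:
            for idx, k, strand in cands:
                e = self.edge_db.edges[idx]
                te = e.sequence[:k] if strand == "+" else revcomp(e.sequence[len(e.sequence) - k:])
                if read[READ_LEN - k:] == te:
                    key = (idx, TE_RIGHT)
                    if key not in stubs or stubs[key][1] < k:
                        stubs[key] = (idx, k, TE_RIGHT, strand, read[: READ_LEN - k])
        cands = self._left.get(read[:ANCHOR])
        if cands:
            for idx, k, strand in cands:
                e = self.edge_db.edges[idx]
                te = e.sequence[len(e.sequence) - k:] if strand == "+" else revcomp(e.sequence[:k])
                if read[:k] == te:
                    key = (idx, TE_LEFT)
                    if key not in stubs or stubs[key][1] < k:
                        stubs[key] = (idx, k, TE_LEFT, strand, read[k:])
        return list(stubs.values())

    # -- step 3: reference-resident TE filter -------------------------
    def reference_te_filter(self, read: bytes) -> bool:
        """True = keep. Discards reads aligning to the reference over
        >= 65 bp at >= 95% identity on either strand (substitutions only):
        such reads come from TE copies the assembly already carries."""
        ident = self.ref_index.best_identity_span(read, self.identity_min_span)
        return ident < self.identity_threshold

    # -- step 4: unique perfect flank placement ------------------------
    def map_flank(self, stub, line_id: str) -> JunctionHit | None:
        idx, k, te_side, strand, flank = stub
        hits = self.ref_index.find_exact(flank, max_hits=2)
        if len(hits) != 1:
            return None
        chrom, start, map_strand = hits[0]
        te_left = te_side == TE_LEFT
        if te_left != (map_strand == "+"):
            breakpoint = start + len(flank)
        else:
            breakpoint = start
        e = self.edge_db.edges[idx]
        fams = set(e.families)
        family = e.families[0] if len(fams) == 1 else e.te_class
        return JunctionHit(line_id=line_id, edge_id=e.edge_id, te_match_len=k,
                           te_side=te_side, chrom=chrom, breakpoint=breakpoint,
                           strand=map_strand, te_class=e.te_class, family=family)

    # -- full per-line scan --------------------------------------------
    def scan_reads(self, line_id: str, reads, quality_threshold: int = 20,
                   min_length: int = READ_LEN) -> list:
        """Run steps 1-4 over (seq, qual) pairs; returns JunctionHits."""
        left_index = self._left
        right_index = self._right
        hits = []
        thr = quality_threshold + 33
        for seq, qual in reads:
            j = len(qual)
            while j > 0 and qual[j - 1] < thr:
                j -= 1
            if j < READ_LEN or j < min_length:
                continue
            read = seq[:READ_LEN]
            if read[-ANCHOR:] not in right_index and read[:ANCHOR] not in left_index:
                continue
            stubs = self.match_te_edge(read)
            if not stubs:
                continue
            if not self.reference_te_filter(read):
                continue
            for stub in stubs:
                hit = self.map_flank(stub, line_id)
                if hit is not None:
                    hits.append(hit)
        return hits

    def scan_block(self, block) -> list:
        return self.scan_reads(block.line_id, iter(block))

    def scan_fastq(self, line_id: str, path, **kw) -> list:
        return self.scan_reads(line_id, iter_fastq(path), **kw)


def hits_to_frame(hits: list) -> pd.DataFrame:
    return pd.DataFrame(
        [(h.line_id, h.chrom, h.breakpoint, h.te_class, h.family,
          h.edge_id, h.te_match_len, h.strand, h.te_side) for h in hits],
        columns=["line_id", "chrom", "breakpoint", "te_class", "family",
                 "edge_id", "te_match_len", "strand", "te_side"])


def cluster_hits(hits: pd.DataFrame, lines: list, tolerance_bp: int = 10,
                 min_support: int = 1) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Single-linkage clustering of junction hits into insertion loci.

    Hits on the same chromosome with the same superfamily class are chained
    while consecutive breakpoints are within ``tolerance_bp``; a chain
    spanning more than 10x the tolerance is split at its largest gap. Locus
    position is the median member breakpoint; a line is called present when
    it contributes >= ``min_support`` hits.

    Returns (loci, genotypes): loci indexed by locus_id with chrom /
    position / te_class / family / n_hits; genotypes lines x loci in {0,1}.
    """
    loci_rows = []
    geno = {}
    if len(hits) == 0:
        loci = pd.DataFrame(columns=["locus_id", "chrom", "position",
                                     "te_class", "family", "n_hits"])
        return loci, pd.DataFrame(index=list(lines))
    for (chrom, te_class), grp in hits.groupby(["chrom", "te_class"], sort=True):
        grp = grp.sort_values("breakpoint")
        bp = grp["breakpoint"].to_numpy()
        splits = np.flatnonzero(np.diff(bp) > tolerance_bp) + 1
        for chunk in np.split(np.arange(len(bp)), splits):
            for member_idx in _maybe_split_wide(bp[chunk], tolerance_bp):
                members = grp.iloc[chunk[member_idx]]
                support = members["line_id"].value_counts()
                carriers = support[support >= min_support].index
                if len(carriers) == 0:
                    continue
                pos = int(np.median(members["breakpoint"]))
                fams = members["family"].unique()
                family = fams[0] if len(fams) == 1 else te_class
                locus_id = f"{family}-{chrom}-{pos}"
                loci_rows.append((locus_id, chrom, pos, te_class, family,
                                  len(members)))
                col = pd.Series(0, index=list(lines), dtype=np.int8)
                col[carriers] = 1
                geno[locus_id] = col
    loci = pd.DataFrame(loci_rows, columns=[
        "locus_id", "chrom", "position", "te_class", "family", "n_hits"]
    ).sort_values(["chrom", "position"]).reset_index(drop=True)
    genotypes = pd.DataFrame(geno, index=list(lines))[loci["locus_id"]]
    return loci, genotypes


def _maybe_split_wide(bp: np.ndarray, tolerance_bp: int):
    """Split a chained cluster wider than 10x tolerance at its largest gap."""
    if len(bp) < 2 or bp[-1] - bp[0] <= 10 * tolerance_bp:
        return [np.arange(len(bp))]
    gaps = np.diff(bp)
    cut = int(np.argmax(gaps)) + 1
    logger.info("splitting over-wide cluster (span %d) at gap %d",
                bp[-1] - bp[0], gaps[cut - 1])
    left = _maybe_split_wide(bp[:cut], tolerance_bp)
    right = _maybe_split_wide(bp[cut:], tolerance_bp)
    return left + [p + cut for p in right]


def sharing_spectrum(genotypes: pd.DataFrame) -> tuple[int, int, int]:
    """Loci present in exactly 1, exactly 2, and >= 3 lines."""
    counts = (genotypes == 1).sum(axis=0)
    return (int((counts == 1).sum()), int((counts == 2).sum()),
            int((counts >= 3).sum()))


def population_frequencies(genotypes: pd.DataFrame, panel: pd.Series) -> pd.DataFrame:
    """Per-locus carrier fraction per population.

    Missing genotypes (coded negative or NaN) are excluded from the
    denominator; a population with zero genotyped lines at a locus gets NaN
    (undefined), never 0.
    """
    out = {}
    for pop in panel.unique():
        sub = genotypes.loc[panel.index[panel == pop]]
        valid = sub.notna() & (sub >= 0)
        n = valid.sum(axis=0)
        carriers = ((sub == 1) & valid).sum(axis=0)
        out[pop] = carriers / n.where(n > 0)
    return pd.DataFrame(out, index=genotypes.columns)
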