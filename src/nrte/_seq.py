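"""Byte-level DNA utilities and an exact-match k-mer reference index.

Sequences are handled as ``bytes`` of upper-case ACGT throughout the
detection pipeline; numpy 2-bit encodings back the k-mer machinery.
"""

from __future__ import annotations

import numpy as np

BASES = b"ACGT"

_COMP = bytes.maketrans(b"ACGTacgt", b"TGCAtgca")

# base byte -> 2-bit code; non-ACGT maps to 0 (simulated data is pure ACGT)
_CODE = np.zeros(256, dtype=np.uint8)
for _i, _b in enumerate(BASES):
    _CODE[_b] = _i
    _CODE[_b + 32] = _i

_DECODE = np.frombuffer(BASES, dtype=np.uint8)


def revcomp(seq: bytes) -> bytes:
    return seq.translate(_COMP)[::-1]


def encode(seq: bytes) -> np.ndarray:
    """2-bit codes (uint8 array in 0..3) for a byte sequence."""
    return _CODE[np.frombuffer(seq, dtype=np.uint8)]


def decode(codes: np.ndarray) -> bytes:
    return _DECODE[codes].tobytes()


def rolling_kmers(codes: np.ndarray, k: int) -> np.ndarray:
    """uint64 packed k-mers at every position (len(codes) - k + 1 values).

    k must be <= 32 so the packed k-mer fits in 64 bits.
    """
    if k > 32:
        raise ValueError("k must be <= 32")
    n = len(codes) - k + 1
    if n <= 0:
        return np.empty(0, dtype=np.uint64)
    c = codes.astype(np.uint64)
    out = np.zeros(n, dtype=np.uint64)
    for j in range(k):
        out <<= np.uint64(2)
        out |= c[j : j + n]
    return out


def pack_kmer(seq: bytes) -> int:
    v = 0
    for code in encode(seq):
        v = (v << 2) | int(code)
    return v


class KmerIndex:
    """Sorted-array index of every k-mer position in a genome.

    Supports exact-occurrence lookup of patterns of length >= k on the
    forward strand; callers query the reverse complement explicitly for
    minus-strand matches.
    """

    def __init__(self, chromosomes: dict[str, bytes], k: int = 20):
        self.k = k
        self.chrom_names = list(chromosomes)
        self.chrom_seqs = [bytes(chromosomes[c]) for c in self.chrom_names]
        self.chrom_lengths = np.array([len(s) for s in self.chrom_seqs])
        self.offsets = np.concatenate([[0], np.cumsum(self.chrom_lengths)])
        kmers = []
        positions = []
        for ci, seq in enumerate(self.chrom_seqs):
            km = rolling_kmers(encode(seq), k)
            kmers.append(km)
            positions.append(np.arange(len(km), dtype=np.int64) + self.offsets[ci])
        allk = np.concatenate(kmers) if kmers else np.empty(0, dtype=np.uint64)
        allp = np.concatenate(positions) if positions else np.empty(0, dtype=np.int64)
        order = np.argsort(allk, kind="stable")
        self._kmers = allk[order]
        self._positions = allp[order]

    def _global_to_local(self, gpos: int) -> tuple[int, int]:
        ci = int(np.searchsorted(self.offsets, gpos, side="right")) - 1
        return ci, int(gpos - self.offsets[ci])

    def seed_positions(self, seed: bytes) -> np.ndarray:
        """Global start positions of exact occurrences of a length-k seed."""
        if len(seed) != self.k:
            raise ValueError(f"seed must have length {self.k}")
        key = np.uint64(pack_kmer(seed))
        lo = int(np.searchsorted(self._kmers, key, side="left"))
        hi = int(np.searchsorted(self._kmers, key, side="right"))
        return self._positions[lo:hi]

    def find_exact(self, pattern: bytes, max_hits: int = 2) -> list[tuple[str, int, str]]:
        """All exact occurrences of ``pattern`` (length >= k), both strands.

        Returns up to ``max_hits`` of (chrom, 0-based start on forward
        strand, strand); stops early once max_hits are found, which is all
        the uniqueness test needs.
        """
        if len(pattern) < self.k:
            raise ValueError("pattern shorter than index k")
        hits: list[tuple[str, int, str]] = []
        for strand, pat in ((b"+", pattern), (b"-", revcomp(pattern))):
            for gpos in self.seed_positions(pat[: self.k]):
                ci, pos = self._global_to_local(int(gpos))
                seq = self.chrom_seqs[ci]
                if seq[pos : pos + len(pat)] == pat:
                    hits.append((self.chrom_names[ci], pos, strand.decode()))
                    if len(hits) >= max_hits:
                        return hits
        return hits

    def best_identity_span(self, read: bytes, min_span: int = 65,
                           seed_offsets: tuple[int, ...] | None = None,
                           max_diagonals: int = 64) -> float:
        """Best percent identity over any >= min_span substitution-only
        alignment of ``read`` to the genome, seeded by exact k-mers.

        Considers the diagonals implied by exact k-mer seeds taken at a few
        read offsets (both strands). Returns 0.0 when no seed anchors.
        """
        n = len(read)
        if seed_offsets is None:
            step = max(1, (n - self.k) // 5)
            seed_offsets = tuple(range(0, n - self.k + 1, step))
        best = 0.0
        for pat, flip in ((read, False), (revcomp(read), True)):
            seen: set[tuple[int, int]] = set()
            for off in seed_offsets:
                seed = pat[off : off + self.k]
                for gpos in self.seed_positions(seed):
                    ci, pos = self._global_to_local(int(gpos))
                    start = pos - off  # read origin on this diagonal
                    key = (ci, start)
                    if key in seen:
                        continue
                    seen.add(key)
                    if len(seen) > max_diagonals:
                        break
                    ident = _diagonal_identity(pat, self.chrom_seqs[ci], start, min_span)
                    if ident > best:
                        best = ident
            del flip
        return best


def _diagonal_identity(read: bytes, ref: bytes, start: int, min_span: int) -> float:
    """Best identity over any window of length >= min_span of the gapless
    alignment of ``read`` against ``ref`` beginning at ref offset ``start``.
    """
    n = len(read)
    lo = max(0, -start)
    hi = min(n, len(ref) - start)
    if hi - lo < min_span:
        return 0.0
    r = np.frombuffer(read, dtype=np.uint8)[lo:hi]
    g = np.frombuffer(ref, dtype=np.uint8)[start + lo : start + hi]
    match = (r == g).astype(np.int32)
    csum = np.concatenate([[0], np.cumsum(match)])
    m = len(match)
    best = 0.0
    for span in range(min_span, m + 1):
        window_matches = csum[span:] - csum[: m - span + 1]
        ident = window_matches.max() / span
        if ident > best:
            best = float(ident)
    return best
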