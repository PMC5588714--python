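"""Synthetic maize-like panel with a known insertion truth set.

Generates a miniature two-population panel of fully inbred (haploid)
lines: a random reference genome with gene models, a TE library whose
full-length copies are embedded in the reference (false-positive bait for
the detection pipeline), planted non-reference insertions with controlled
per-population frequency spectra, short reads with substitution errors, a
polygenic trait with population divergence, and an expression matrix
perturbed by selected insertions.

Design choices: lines are haploid donors (inbred panel), reads are
single-end, insertions are clean splice-ins without target-site
duplications, and base composition is uniform i.i.d. so that exact k-mer
uniqueness arguments hold on simulated data. Genotype frequencies are
realized first and the *empirical* carrier fractions recorded, so truth
frequencies match the genotype matrix exactly.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._seq import decode

TEMPERATE = "temperate"
TROPICAL = "tropical"
LOCUS_CLASSES = ("private_temperate", "private_tropical", "shared")

# TE superfamily mix used for the simulated library; mirrors the observed
# predominance of LTR retrotransposons over DNA transposons in maize.
_TE_PREFIXES = ("DTM", "RLG", "RLC", "RST")
_TE_FAMILY_PROBS = (0.31, 0.40, 0.26, 0.03)


@dataclass
class SimConfig:
    """All knobs of the synthetic panel.

    Defaults give a desk-scale panel: a 2-Mb genome over two chromosomes,
    two populations of 10 inbred lines each, 100 planted insertion loci and
    15x single-end coverage with error-free reads.
    """

    seed: int = 0
    n_chromosomes: int = 2
    chrom_length: int = 1_000_000
    n_genes: int = 40
    te_library_size: int = 20
    te_length_range: tuple[int, int] = (200, 3000)
    reference_te_copies: int = 6
    n_lines_per_pop: tuple[int, int] = (10, 10)
    n_insertion_loci: int = 100
    # per locus class: per-population Beta(a, b) for the carrier frequency;
    # None means the locus is absent from that population.
    freq_model: dict = field(default_factory=lambda: {
        "private_temperate": {TEMPERATE: (0.6, 2.0), TROPICAL: None},
        "private_tropical": {TEMPERATE: None, TROPICAL: (0.6, 2.0)},
        "shared": {TEMPERATE: (0.8, 0.8), TROPICAL: (0.8, 0.8)},
    })
    class_proportions: dict = field(default_factory=lambda: {
        "private_temperate": 0.3, "private_tropical": 0.3, "shared": 0.4,
    })
    read_length: int = 100
    coverage: float = 15.0
    error_rate: float = 0.0
    low_quality_errors: bool = False  # emit Q10 at error-simulated bases
    n_causal_loci: int = 5
    effect_sizes: float = 1.0
    pop_mean_shift: float = 2.0
    polygenic_sd: float = 0.5
    residual_sd: float = 1.0
    n_replicates: int = 2
    n_expression_effects: int = 3
    expression_multiplier: float = 0.67
    expression_noise_logsd: float = 0.25
    # genetic map: marker spacing and cM/Mb on arms vs the pericentromeric
    # middle third of each chromosome (suppressed recombination)
    map_marker_spacing: int = 50_000
    arm_cm_per_mb: float = 1.5
    peri_cm_per_mb: float = 0.1

    def __post_init__(self):
        for name in ("n_chromosomes", "chrom_length", "te_library_size",
                     "read_length", "n_replicates"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if not (0 <= self.error_rate < 0.1):
            raise ValueError("error_rate must be in [0, 0.1)")
        if self.read_length < 75:
            raise ValueError("read_length must be >= 75")
        if self.chrom_length < 10 * self.read_length:
            raise ValueError("chrom_length must be >= 10 * read_length")
        if min(self.n_lines_per_pop) < 1:
            raise ValueError("each population needs >= 1 line")

    @property
    def line_ids(self) -> list[str]:
        nt, nr = self.n_lines_per_pop
        return [f"tem{i:03d}" for i in range(nt)] + [f"tro{i:03d}" for i in range(nr)]

    @property
    def panel(self) -> pd.Series:
        nt, nr = self.n_lines_per_pop
        return pd.Series([TEMPERATE] * nt + [TROPICAL] * nr,
                         index=self.line_ids, name="population")


@dataclass
class Reference:
    """Simulated reference assembly plus its annotation bundle."""
    chromosomes: dict  # chrom -> bytes
    genes: pd.DataFrame  # gene_id, chrom, start, end, strand (0-based half-open)
    gene_features: pd.DataFrame  # gene_id, chrom, start, end, strand, feature
    te_library: dict  # te_id -> bytes
    te_meta: pd.DataFrame  # te_id, family, te_class
    ref_te_copies: pd.DataFrame  # te_id, chrom, start, end
    genetic_map: pd.DataFrame  # chrom, position (bp), cm

    @property
    def genome_size(self) -> int:
        return sum(len(s) for s in self.chromosomes.values())


@dataclass
class TruthSet:
    """Planted insertions, genotypes and effects — the detection oracle."""
    loci: pd.DataFrame  # locus_id, chrom, position, te_id, family, te_class, locus_class
    genotypes: pd.DataFrame  # lines x loci, 0/1
    frequencies: pd.DataFrame  # loci x populations, realized carrier fractions
    panel: pd.Series  # line -> population
    causal_effects: dict  # locus_id -> trait effect
    expression_effects: dict  # (gene_id, locus_id) -> multiplier
    genetic_values: pd.Series | None = None  # filled by simulate_phenotypes

    def validate(self):
        for pop in (TEMPERATE, TROPICAL):
            lines = self.panel.index[self.panel == pop]
            emp = self.genotypes.loc[lines].mean(axis=0)
            if not np.allclose(emp.values, self.frequencies[pop].values):
                raise AssertionError("truth frequencies are not the realized ones")


def _rng_stream(seed: int, label: str) -> np.random.Generator:
    """Independent, deterministic stream per simulation stage."""
    tag = zlib.crc32(label.encode()) & 0x7FFFFFFF
    return np.random.default_rng(np.random.SeedSequence((seed, tag)))


def _random_seq(rng: np.random.Generator, length: int) -> bytes:
    return decode(rng.integers(0, 4, size=length).astype(np.uint8))


def _place_intervals(rng, lengths, chrom_length, occupied, margin=50, max_tries=2000):
    """Place intervals of the given lengths uniformly without overlap.

    ``occupied`` is a list of (start, end) already reserved; returns list of
    (start, end). Raises if placement fails — genome too crowded.
    """
    placed = []
    taken = list(occupied)
    for L in lengths:
        ok = False
        for _ in range(max_tries):
            s = int(rng.integers(margin, chrom_length - L - margin))
            e = s + L
            if all(e + margin <= a or s >= b + margin for a, b in taken):
                taken.append((s, e))
                placed.append((s, e))
                ok = True
                break
        if not ok:
            raise ValueError("cannot place features without overlap; genome too small")
    return placed


def _gene_structure(rng, start, end, strand):
    """Split a gene interval into 5'UTR / exons / introns / 3'UTR.

    Intron positions are implicit (gaps between exon-level features).
    """
    span = end - start
    utr5 = int(rng.integers(100, 200))
    utr3 = int(rng.integers(100, 250))
    n_exons = int(rng.integers(2, 5))
    body = span - utr5 - utr3
    # alternate exon/intron inside the body
    cuts = np.sort(rng.integers(1, body, size=2 * n_exons - 2))
    bounds = np.concatenate([[0], cuts, [body]])
    feats = []
    if strand == "+":
        feats.append(("five_prime_UTR", start, start + utr5))
        pos = start + utr5
        for i in range(len(bounds) - 1):
            a, b = pos + int(bounds[i]), pos + int(bounds[i + 1])
            if i % 2 == 0 and b > a:
                feats.append(("exon", a, b))
        feats.append(("three_prime_UTR", end - utr3, end))
    else:
        feats.append(("three_prime_UTR", start, start + utr3))
        pos = start + utr3
        for i in range(len(bounds) - 1):
            a, b = pos + int(bounds[i]), pos + int(bounds[i + 1])
            if i % 2 == 0 and b > a:
                feats.append(("exon", a, b))
        feats.append(("five_prime_UTR", end - utr5, end))
    return feats


def simulate_reference(config: SimConfig) -> Reference:
    """Reference genome, gene annotation, TE library, embedded reference TE
    copies and a genetic map with a low-recombination pericentromeric third.
    """
    rng = _rng_stream(config.seed, "reference")

    # TE library
    lo, hi = config.te_length_range
    te_library, te_rows = {}, []
    for i in range(config.te_library_size):
        fam_idx = int(rng.choice(4, p=_TE_FAMILY_PROBS))
        prefix = _TE_PREFIXES[fam_idx]
        te_id = f"{prefix}_sim{i:03d}"
        te_library[te_id] = _random_seq(rng, int(rng.integers(lo, hi + 1)))
        te_class = {"DTM": "DNA", "RLG": "LTR/Gypsy", "RLC": "LTR/Copia",
                    "RST": "other"}[prefix]
        te_rows.append((te_id, prefix, te_class))
    te_meta = pd.DataFrame(te_rows, columns=["te_id", "family", "te_class"])

    chroms = {f"chr{i + 1}": bytearray(_random_seq(rng, config.chrom_length))
              for i in range(config.n_chromosomes)}
    names = list(chroms)

    # embed full-length reference TE copies (overwrite, keeping length)
    copy_rows = []
    per_chrom_occupied = {c: [] for c in names}
    for j in range(config.reference_te_copies):
        te_id = str(rng.choice(te_meta["te_id"]))
        seq = te_library[te_id]
        chrom = names[j % len(names)]
        (s, e), = _place_intervals(rng, [len(seq)], config.chrom_length,
                                   per_chrom_occupied[chrom],
                                   margin=2 * config.read_length)
        chroms[chrom][s:e] = seq
        per_chrom_occupied[chrom].append((s, e))
        copy_rows.append((te_id, chrom, s, e))
    ref_te_copies = pd.DataFrame(copy_rows, columns=["te_id", "chrom", "start", "end"])

    # gene models, non-overlapping with each other and with TE copies
    gene_rows, feat_rows = [], []
    genes_per_chrom = np.full(len(names), config.n_genes // len(names))
    genes_per_chrom[: config.n_genes % len(names)] += 1
    g = 0
    for chrom, n in zip(names, genes_per_chrom):
        lengths = rng.integers(1500, 4000, size=int(n))
        spans = _place_intervals(rng, lengths, config.chrom_length,
                                 per_chrom_occupied[chrom])
        for s, e in spans:
            strand = "+" if rng.random() < 0.5 else "-"
            gid = f"GENE{g:04d}"
            g += 1
            gene_rows.append((gid, chrom, s, e, strand))
            for feat, a, b in _gene_structure(rng, s, e, strand):
                feat_rows.append((gid, chrom, a, b, strand, feat))
            per_chrom_occupied[chrom].append((s, e))
    genes = pd.DataFrame(gene_rows, columns=["gene_id", "chrom", "start", "end", "strand"])
    gene_features = pd.DataFrame(
        feat_rows, columns=["gene_id", "chrom", "start", "end", "strand", "feature"])

    # Marey-style genetic map: linear arms, suppressed middle third
    map_rows = []
    L = config.chrom_length
    third = L / 3.0
    for chrom in names:
        positions = np.arange(0, L + 1, config.map_marker_spacing)
        if positions[-1] != L:
            positions = np.append(positions, L)
        cm = np.empty(len(positions))
        for i, p in enumerate(positions):
            a = min(p, third)
            b = min(max(p - third, 0.0), third)
            c = max(p - 2 * third, 0.0)
            cm[i] = (a * config.arm_cm_per_mb + b * config.peri_cm_per_mb
                     + c * config.arm_cm_per_mb) / 1e6
        for p, m in zip(positions, cm):
            map_rows.append((chrom, int(p), float(m)))
    genetic_map = pd.DataFrame(map_rows, columns=["chrom", "position", "cm"])

    return Reference(
        chromosomes={c: bytes(b) for c, b in chroms.items()},
        genes=genes, gene_features=gene_features,
        te_library=te_library, te_meta=te_meta,
        ref_te_copies=ref_te_copies, genetic_map=genetic_map,
    )


def _draw_genotype_column(rng, n, freq_params):
    """Realize one population's genotype column; at least the model is honest:
    an all-zero draw is kept (the locus is simply absent there)."""
    if freq_params is None:
        return np.zeros(n, dtype=np.int8)
    a, b = freq_params
    f = rng.beta(a, b)
    return (rng.random(n) < f).astype(np.int8)


def plant_insertions(config: SimConfig, reference: Reference) -> TruthSet:
    """Choose insertion sites and realize the panel's genotype matrix.

    Sites keep a +/- read_length buffer away from reference TE copies and
    chromosome ends, and are pairwise farther apart than read_length so
    clusters are unambiguous. Loci with zero carriers overall are redrawn
    (a never-planted locus is not an insertion).
    """
    rng = _rng_stream(config.seed, "insertions")
    names = list(reference.chromosomes)
    buf = config.read_length
    forbidden = {c: [] for c in names}
    for _, row in reference.ref_te_copies.iterrows():
        forbidden[row.chrom].append((row.start - buf, row.end + buf))

    loci_rows = []
    geno_cols = {}
    panel = config.panel
    tem_lines = panel.index[panel == TEMPERATE]
    tro_lines = panel.index[panel == TROPICAL]
    classes = list(config.class_proportions)
    probs = np.array([config.class_proportions[c] for c in classes], dtype=float)
    probs /= probs.sum()

    chosen: dict[str, list[int]] = {c: [] for c in names}
    for j in range(config.n_insertion_loci):
        for _ in range(5000):
            chrom = names[int(rng.integers(len(names)))]
            pos = int(rng.integers(buf, config.chrom_length - buf))
            if any(a <= pos <= b for a, b in forbidden[chrom]):
                continue
            if any(abs(pos - q) <= buf for q in chosen[chrom]):
                continue
            break
        else:
            raise ValueError("cannot place insertion loci without collisions")
        chosen[chrom].append(pos)
        locus_class = classes[int(rng.choice(len(classes), p=probs))]
        te_id = str(rng.choice(reference.te_meta["te_id"]))
        meta = reference.te_meta.set_index("te_id").loc[te_id]
        model = config.freq_model[locus_class]
        for _ in range(200):
            g_tem = _draw_genotype_column(rng, len(tem_lines), model[TEMPERATE])
            g_tro = _draw_genotype_column(rng, len(tro_lines), model[TROPICAL])
            if g_tem.sum() + g_tro.sum() > 0:
                break
        family = meta["family"]
        locus_id = f"{family}-{chrom}-{pos}"
        loci_rows.append((locus_id, chrom, pos, te_id, family,
                          meta["te_class"], locus_class))
        geno_cols[locus_id] = np.concatenate([g_tem, g_tro])

    loci = pd.DataFrame(loci_rows, columns=[
        "locus_id", "chrom", "position", "te_id", "family", "te_class",
        "locus_class"]).sort_values(["chrom", "position"]).reset_index(drop=True)
    genotypes = pd.DataFrame(geno_cols, index=panel.index)[loci["locus_id"]]
    freqs = pd.DataFrame({
        TEMPERATE: genotypes.loc[tem_lines].mean(axis=0),
        TROPICAL: genotypes.loc[tro_lines].mean(axis=0),
    })

    # causal trait loci: prefer population-differentiated ones so the trait
    # genuinely diverges between groups
    dfreq = (freqs[TEMPERATE] - freqs[TROPICAL]).abs().sort_values(ascending=False)
    causal = list(dfreq.index[: config.n_causal_loci])
    causal_effects = {lid: float(config.effect_sizes) for lid in causal}

    expression_effects = {}
    if len(reference.genes) and config.n_expression_effects > 0:
        gene_ids = list(reference.genes["gene_id"])
        pick_loci = [str(x) for x in rng.choice(loci["locus_id"],
                     size=min(config.n_expression_effects, len(loci)), replace=False)]
        pick_genes = [str(x) for x in rng.choice(gene_ids, size=len(pick_loci),
                                                 replace=False)]
        for gid, lid in zip(pick_genes, pick_loci):
            expression_effects[(gid, lid)] = float(config.expression_multiplier)

    truth = TruthSet(loci=loci, genotypes=genotypes, frequencies=freqs,
                     panel=panel, causal_effects=causal_effects,
                     expression_effects=expression_effects)
    truth.validate()
    return truth


def donor_genome(reference: Reference, truth: TruthSet, line_id: str) -> dict:
    """The line's haploid genome: reference with its carried TEs spliced in."""
    carried = truth.genotypes.loc[line_id]
    out = {}
    for chrom, refseq in reference.chromosomes.items():
        rows = truth.loci[(truth.loci["chrom"] == chrom)
                          & truth.loci["locus_id"].map(lambda l: carried[l] == 1)]
        parts, prev = [], 0
        for _, r in rows.sort_values("position").iterrows():
            parts.append(refseq[prev:r.position])
            parts.append(reference.te_library[r.te_id])
            prev = r.position
        parts.append(refseq[prev:])
        out[chrom] = b"".join(parts)
    return out


@dataclass
class ReadBlock:
    """Fixed-length single-end reads for one line, packed in one buffer."""
    line_id: str
    read_length: int
    data: bytes          # n_reads * read_length concatenated bases
    qualities: bytes     # same layout, Phred+33
    n_reads: int

    def __iter__(self):
        L = self.read_length
        for i in range(self.n_reads):
            yield self.data[i * L:(i + 1) * L], self.qualities[i * L:(i + 1) * L]


def simulate_reads(config: SimConfig, reference: Reference, truth: TruthSet,
                   line_id: str) -> ReadBlock:
    """Uniform single-end reads from the line's donor genome at the
    configured coverage, with i.i.d. substitution errors."""
    rng = _rng_stream(config.seed, f"reads:{line_id}")
    donor = donor_genome(reference, truth, line_id)
    L = config.read_length
    chunks, quals = [], []
    n_total = 0
    q30 = ord("?")  # Phred 30
    q10 = ord("+")  # Phred 10
    for chrom in donor:
        seq = donor[chrom]
        n_reads = int(round(config.coverage * len(seq) / L))
        if n_reads == 0 or len(seq) < L:
            continue
        starts = rng.integers(0, len(seq) - L + 1, size=n_reads)
        arr = np.frombuffer(seq, dtype=np.uint8)
        reads = arr[starts[:, None] + np.arange(L)]
        qual = np.full(reads.shape, q30, dtype=np.uint8)
        if config.error_rate > 0:
            mask = rng.random(reads.shape) < config.error_rate
            if mask.any():
                from ._seq import _CODE, _DECODE
                codes = _CODE[reads[mask]]
                shifted = (codes + rng.integers(1, 4, size=codes.shape)) % 4
                reads[mask] = _DECODE[shifted]
                if config.low_quality_errors:
                    qual[mask] = q10
        chunks.append(reads.tobytes())
        quals.append(qual.tobytes())
        n_total += n_reads
    return ReadBlock(line_id=line_id, read_length=L,
                     data=b"".join(chunks), qualities=b"".join(quals),
                     n_reads=n_total)


def simulate_panel(config: SimConfig, reference: Reference):
    """TruthSet plus a lazy per-line read generator.

    Returns (truth, reads_iter) where reads_iter yields one ReadBlock per
    line; reads are generated on demand to keep memory flat.
    """
    truth = plant_insertions(config, reference)

    def reads_iter():
        for line_id in config.line_ids:
            yield simulate_reads(config, reference, truth, line_id)

    return truth, reads_iter


def simulate_phenotypes(truth: TruthSet, config: SimConfig) -> pd.DataFrame:
    """Replicated trait values: population shift + causal insertion effects
    + line-level polygenic deviate + replicate noise.

    Stores each line's genetic value on the truth set so variance-component
    recovery can be checked against the realized components.
    """
    rng = _rng_stream(config.seed, "phenotypes")
    panel = truth.panel
    g = pd.Series(0.0, index=panel.index)
    g[panel == TROPICAL] += config.pop_mean_shift
    for lid, eff in truth.causal_effects.items():
        g += eff * truth.genotypes[lid]
    g += rng.normal(0.0, config.polygenic_sd, size=len(g))
    truth.genetic_values = g
    rows = []
    for line in panel.index:
        for rep in range(config.n_replicates):
            rows.append((line, rep + 1,
                         g[line] + rng.normal(0.0, config.residual_sd)))
    return pd.DataFrame(rows, columns=["line", "replicate", "trait"])


def simulate_expression(truth: TruthSet, config: SimConfig,
                        gene_ids: list[str]) -> pd.DataFrame:
    """FPKM-like gene x line table: log-normal baselines, carriers of an
    effect locus have the gene's mean multiplied by the recorded factor."""
    rng = _rng_stream(config.seed, "expression")
    lines = list(truth.panel.index)
    base = np.exp(rng.normal(2.0, 1.0, size=len(gene_ids)))
    mult = pd.DataFrame(1.0, index=gene_ids, columns=lines)
    for (gid, lid), m in truth.expression_effects.items():
        if gid in mult.index:
            carriers = truth.genotypes.index[truth.genotypes[lid] == 1]
            mult.loc[gid, carriers] = m
    noise = np.exp(rng.normal(0.0, config.expression_noise_logsd,
                              size=(len(gene_ids), len(lines))))
    values = base[:, None] * mult.values * noise
    return pd.DataFrame(values, index=gene_ids, columns=lines)
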