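"""Readers/writers for the pipeline's on-disk formats.

Conventions: internal coordinates are 0-based half-open; emitted GFF3 and
the locus report TSV are 1-based inclusive; BED stays 0-based half-open.
FASTQ is Phred+33. All writers are deterministic for a fixed input.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd
from Bio import SeqIO

from .simulate import Reference, ReadBlock


def write_fasta(sequences: dict, path, width: int = 80) -> None:
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            s = seq.decode() if isinstance(seq, (bytes, bytearray)) else str(seq)
            fh.write(f">{name}\n")
            for i in range(0, len(s), width):
                fh.write(s[i:i + width] + "\n")


def read_fasta(path) -> dict:
    return {rec.id: str(rec.seq).upper().encode()
            for rec in SeqIO.parse(str(path), "fasta")}


def write_gff3(genes: pd.DataFrame, gene_features: pd.DataFrame, path) -> None:
    """Gene models with five_prime_UTR/exon/three_prime_UTR children."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        feats = gene_features.groupby("gene_id")
        for _, g in genes.iterrows():
            fh.write(f"{g.chrom}\tnrte_sim\tgene\t{g.start + 1}\t{g.end}\t.\t"
                     f"{g.strand}\t.\tID={g.gene_id}\n")
            for _, f in feats.get_group(g.gene_id).sort_values("start").iterrows():
                fh.write(f"{f.chrom}\tnrte_sim\t{f.feature}\t{f.start + 1}\t"
                         f"{f.end}\t.\t{f.strand}\t.\tParent={g.gene_id}\n")


def read_gff3(path) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Back to the internal 0-based gene / feature frames."""
    genes, feats = [], []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#"):
                continue
            chrom, _, ftype, start, end, _, strand, _, attrs = line.rstrip("\n").split("\t")
            tags = dict(kv.split("=", 1) for kv in attrs.split(";") if "=" in kv)
            if ftype == "gene":
                genes.append((tags["ID"], chrom, int(start) - 1, int(end), strand))
            else:
                feats.append((tags["Parent"], chrom, int(start) - 1, int(end),
                              strand, ftype))
    return (pd.DataFrame(genes, columns=["gene_id", "chrom", "start", "end", "strand"]),
            pd.DataFrame(feats, columns=["gene_id", "chrom", "start", "end",
                                         "strand", "feature"]))


def write_bed6(intervals: pd.DataFrame, path, name_col: str = "te_id") -> None:
    with open(path, "w") as fh:
        for _, r in intervals.iterrows():
            fh.write(f"{r.chrom}\t{r.start}\t{r.end}\t{r[name_col]}\t0\t+\n")


def write_fastq(block: ReadBlock, path) -> None:
    with open(path, "w") as fh:
        for i, (seq, qual) in enumerate(block):
            fh.write(f"@{block.line_id}:{i}\n{seq.decode()}\n+\n{qual.decode()}\n")


def write_reference(reference: Reference, outdir) -> None:
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    write_fasta(reference.chromosomes, out / "reference.fa")
    write_fasta(reference.te_library, out / "te_library.fa")
    write_gff3(reference.genes, reference.gene_features, out / "genes.gff3")
    write_bed6(reference.ref_te_copies, out / "reference_te_copies.bed")
    reference.genetic_map.to_csv(out / "genetic_map.tsv", sep="\t", index=False)
    reference.te_meta.to_csv(out / "te_meta.tsv", sep="\t", index=False)


def write_truth(truth, outdir) -> None:
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    truth.loci.to_csv(out / "truth_loci.tsv", sep="\t", index=False)
    truth.genotypes.to_csv(out / "truth_genotypes.tsv", sep="\t")
    truth.frequencies.to_csv(out / "truth_frequencies.tsv", sep="\t")
    truth.panel.to_frame().to_csv(out / "panel.tsv", sep="\t")
    pd.Series(truth.causal_effects, name="effect").rename_axis("locus_id") \
        .to_csv(out / "truth_causal_effects.tsv", sep="\t")


def write_locus_report(loci: pd.DataFrame, genotypes: pd.DataFrame, path) -> None:
    """VCF-like TSV: CHROM, POS (1-based), ID, TE_FAMILY, CLASS, then one
    0/1/. column per line."""
    out = loci[["chrom", "position", "locus_id", "family", "te_class"]].copy()
    out.columns = ["CHROM", "POS", "ID", "TE_FAMILY", "CLASS"]
    out["POS"] = out["POS"] + 1
    calls = genotypes.T.reindex(loci["locus_id"])
    calls = calls.map(lambda v: "." if pd.isna(v) or v < 0 else str(int(v)))
    out = pd.concat([out.reset_index(drop=True), calls.reset_index(drop=True)], axis=1)
    out.to_csv(path, sep="\t", index=False)


def read_panel(path) -> pd.Series:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return df.iloc[:, 0]
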