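"""Window landscape of the called insertions: densities, recombination
rate, gene context, and the correlation table.

Tiles the genome into 1-Mb windows, computes insertion / gene densities
and cM/Mb from the Marey map, labels the pericentromeric middle third of
each chromosome, and correlates the tracks genome-wide and on arms only.
"""

import pandas as pd

from common import RESULTS, study_config
from nrte.landscape import (classify_context, correlate_tracks, gr_rate,
                            label_regions, make_windows, window_density)
from nrte.simulate import simulate_reference


def main():
    RESULTS.mkdir(exist_ok=True)
    cfg = study_config()
    ref = simulate_reference(cfg)
    called = pd.read_csv(RESULTS / "called_loci.tsv", sep="\t")
    loci = pd.DataFrame({"chrom": called["CHROM"],
                         "position": called["POS"] - 1})

    chrom_lengths = {c: len(s) for c, s in ref.chromosomes.items()}
    # windows are 250 kb here so each chromosome contributes several
    # windows at this genome size; the window machinery is size-agnostic
    windows = make_windows(chrom_lengths, size=250_000)
    third = cfg.chrom_length / 3
    peri = pd.DataFrame([(c, int(third), int(2 * third)) for c in chrom_lengths],
                        columns=["chrom", "start", "end"])
    region = label_regions(windows, peri)

    nrte = window_density(loci, windows, chrom_lengths, "nrte", region)
    gene_mid = ref.genes.assign(position=(ref.genes["start"] + ref.genes["end"]) // 2)
    genes = window_density(gene_mid, windows, chrom_lengths, "genes", region)
    rate = gr_rate(ref.genetic_map, windows, region=region)

    rows = []
    for track, label in ((genes, "gene_density"), (rate, "cM_per_Mb")):
        for reg in ("all", "arms"):
            c = correlate_tracks(nrte, track, region=reg)
            rows.append((label, reg, round(c.r, 3), c.p_value, c.n))
    corr = pd.DataFrame(rows, columns=["feature", "region", "pearson_r", "p", "n_windows"])
    corr.to_csv(RESULTS / "landscape_correlations.tsv", sep="\t", index=False)

    ctx = classify_context(loci, ref.genes, ref.gene_features)
    ctx.value_counts().rename_axis("context").to_frame("n_loci") \
        .to_csv(RESULTS / "context_counts.tsv", sep="\t")

    print("NRTE density vs genomic features (Pearson r):")
    print(corr.to_string(index=False))
    print("\ninsertion context counts:")
    print(ctx.value_counts().to_string())


if __name__ == "__main__":
    main()
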