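"""Generate the study panel and record its ground truth.

Writes the planted locus table, per-line genotypes, realized population
frequencies, phenotypes and the panel labels under results/. The reference
genome itself is regenerated deterministically by later scripts rather
than stored.
"""

from common import RESULTS, study_panel
from nrte.simulate import TEMPERATE, TROPICAL, simulate_expression, simulate_phenotypes


def main():
    RESULTS.mkdir(exist_ok=True)
    cfg, ref, truth, _ = study_panel()
    truth.loci.to_csv(RESULTS / "truth_loci.tsv", sep="\t", index=False)
    truth.genotypes.to_csv(RESULTS / "truth_genotypes.tsv", sep="\t")
    truth.frequencies.to_csv(RESULTS / "truth_frequencies.tsv", sep="\t")
    truth.panel.to_frame().to_csv(RESULTS / "panel.tsv", sep="\t")
    pheno = simulate_phenotypes(truth, cfg)
    pheno.to_csv(RESULTS / "phenotypes.tsv", sep="\t", index=False)
    expr = simulate_expression(truth, cfg, list(ref.genes["gene_id"]))
    expr.to_csv(RESULTS / "expression.tsv", sep="\t")

    by_class = truth.loci["te_class"].value_counts()
    print(f"panel: {len(truth.panel)} lines "
          f"({(truth.panel == TEMPERATE).sum()} temperate, "
          f"{(truth.panel == TROPICAL).sum()} tropical)")
    print(f"planted {len(truth.loci)} insertion loci over "
          f"{cfg.n_chromosomes} x {cfg.chrom_length / 1e6:.0f} Mb:")
    for cls, n in by_class.items():
        print(f"  {cls}: {n}")
    print(f"causal trait loci: {len(truth.causal_effects)}; "
          f"expression effects: {len(truth.expression_effects)}")


if __name__ == "__main__":
    main()
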