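"""Marker-trait association on the called insertions.

PCA structure covariates from the genotype matrix, a GLM scan of the
simulated trait over MAF-filtered markers at the Bonferroni threshold,
an expression association for one planted expression-effect locus, and
an assay-vs-prediction concordance table built by corrupting a truth
column (synthetic stand-in for a wet-lab assay).
"""

import numpy as np
import pandas as pd

from common import RESULTS, study_panel
from nrte.assoc import concordance, expression_assoc, gwas_scan, pca_covariates


def main():
    RESULTS.mkdir(exist_ok=True)
    cfg, ref, truth, _ = study_panel()
    geno = pd.read_csv(RESULTS / "called_genotypes.tsv", sep="\t", index_col=0)
    pheno = pd.read_csv(RESULTS / "phenotypes.tsv", sep="\t")
    expr = pd.read_csv(RESULTS / "expression.tsv", sep="\t", index_col=0)

    trait = pheno.groupby("line")["trait"].mean()
    pca = pca_covariates(geno, k=3, seed=cfg.seed)
    print("PC explained variance:",
          np.round(pca.explained_variance, 3).tolist())
    called = pd.read_csv(RESULTS / "called_loci.tsv", sep="\t")
    positions = called.rename(columns={"ID": "locus_id", "CHROM": "chrom",
                                       "POS": "position"})
    scan = gwas_scan(trait, geno, pca.scores, alpha=1.0, maf_min=0.15,
                     positions=positions)
    scan.to_csv(RESULTS / "gwas.tsv", sep="\t", index=False)
    sig = scan[scan["significant"]]
    print(f"GWAS: {len(scan)} markers (MAF >= 0.15), threshold "
          f"{scan.attrs['threshold']:.3g}, {len(sig)} significant")
    causal = set(truth.causal_effects)
    print("significant markers that are planted causal loci:",
          int(sig["marker"].isin(causal).sum()), "/", len(sig))

    if truth.expression_effects:
        (gid, lid), mult = next(iter(truth.expression_effects.items()))
        marker = truth.genotypes[lid]
        res = expression_assoc(expr, marker)
        row = res.set_index("gene_id").loc[gid]
        print(f"expression effect at {lid} on {gid} (x{mult}): "
              f"carrier mean {row['mean_carrier']:.2f} vs "
              f"{row['mean_noncarrier']:.2f}, p = {row['p']:.2e}")

    # synthetic assay: truth genotypes for one locus with 3 flipped lines
    lid = truth.loci["locus_id"].iloc[0]
    assay = truth.genotypes[lid].copy()
    flip = assay.index[:3]
    assay[flip] = 1 - assay[flip]
    t = concordance(assay, truth.genotypes[lid])
    print(f"concordance demo at {lid}: agree {t.pct_agree}%, "
          f"assay-only {t.pct_assay_only}%, in-silico-only {t.pct_silico_only}%")


if __name__ == "__main__":
    main()
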