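import numpy as np
import pandas as pd
import pytest

from nrte.edges import build_edge_db
from nrte.scan import JunctionScanner, cluster_hits, hits_to_frame
from nrte.simulate import SimConfig, simulate_panel, simulate_reference


@pytest.fixture(scope="session")
def small_cfg():
    """A miniature panel that still exercises every pipeline stage."""
    return SimConfig(seed=11, n_chromosomes=1, chrom_length=200_000,
                     n_genes=8, te_library_size=6, reference_te_copies=2,
                     n_lines_per_pop=(5, 5), n_insertion_loci=15,
                     coverage=12.0)


@pytest.fixture(scope="session")
def reference(small_cfg):
    return simulate_reference(small_cfg)


@pytest.fixture(scope="session")
def panel_truth(small_cfg, reference):
    truth, reads_iter = simulate_panel(small_cfg, reference)
    blocks = list(reads_iter())
    return truth, blocks


@pytest.fixture(scope="session")
def edge_db(reference):
    classes = dict(zip(reference.te_meta["te_id"], reference.te_meta["te_class"]))
    return build_edge_db(reference.te_library, classes)


@pytest.fixture(scope="session")
def scanner(edge_db, reference):
    return JunctionScanner(edge_db, reference.chromosomes)


@pytest.fixture(scope="session")
def called(small_cfg, panel_truth, scanner):
    _, blocks = panel_truth
    hits = []
    for blk in blocks:
        hits.extend(scanner.scan_block(blk))
    loci, genotypes = cluster_hits(hits_to_frame(hits),
                                   lines=list(small_cfg.line_ids))
    return hits, loci, genotypes


def match_truth(called_loci: pd.DataFrame, truth_loci: pd.DataFrame,
                tol: int = 10) -> dict:
    """truth locus_id -> list of called row indices within tolerance."""
    out = {}
    for _, t in truth_loci.iterrows():
        m = called_loci[(called_loci["chrom"] == t["chrom"])
                        & (np.abs(called_loci["position"] - t["position"]) <= tol)]
        out[t["locus_id"]] = list(m.index)
    return out
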