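"""Shared study configuration for the numbered analysis scripts.

One deterministic desk-scale panel is used throughout: a 2-Mb genome over
two chromosomes, 10 temperate + 10 tropical inbred lines, 100 planted
insertion loci, 15x error-free single-end coverage. Scripts communicate
through small TSV/JSON tables under results/; anything bulky is
regenerated deterministically from this config instead of being stored.
"""

from pathlib import Path

from nrte.simulate import SimConfig, simulate_panel, simulate_reference

RESULTS = Path(__file__).resolve().parent.parent / "results"
STUDY_SEED = 2024


def study_config(**overrides) -> SimConfig:
    kw = dict(seed=STUDY_SEED)
    kw.update(overrides)
    return SimConfig(**kw)


def study_panel():
    """(config, reference, truth, reads_iter) for the shared panel."""
    cfg = study_config()
    ref = simulate_reference(cfg)
    truth, reads_iter = simulate_panel(cfg, ref)
    return cfg, ref, truth, reads_iter
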