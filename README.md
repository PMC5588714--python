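# nrte

Detection of **non-reference transposable-element (NRTE) insertions** —
TE copies present in a resequenced inbred line but absent from the
reference assembly — from short-read panels, together with the
population-genomic analyses that such a catalogue supports: window-based
landscape correlations, per-population frequency spectra, Fst with a
resampling confidence interval, a Qst–Fst divergent-selection test, LD
blocks, and presence/absence-marker GWAS.

The package is aimed at maize-style panels of fully inbred (effectively
haploid) lines split into two populations (here *temperate* vs
*tropical*), and ships a first-class synthetic-data module that generates
a miniature panel with a known insertion truth set, so every stage is
testable end to end without any external download.

## The method

**Split-read junction detection.** From a TE library, the terminal 100 bp
of each element end is collected into a database of *edge sequences*.
Reads are quality-trimmed and hard-truncated to 75 bp; a read is a
junction candidate when 20–55 bp at one of its ends matches a TE edge
extremity perfectly (100%), leaving a 20–55 bp putative genomic flank
(the two segments always sum to 75 bp). The chance that two random
flanks share an identical >20 bp stretch at a fixed junction is
(1/4)²¹ ≤ 4⁻²⁰, which is what makes the exact-match rule specific.
Candidates that align to the reference over ≥65 bp at ≥95% identity are
discarded — they arise from TE copies the assembly already carries, not
from new insertions. Surviving flanks are placed in the reference only if
they match perfectly at exactly one location (either strand); breakpoints
are clustered into loci (single-linkage, 10 bp tolerance, same
superfamily), each line is genotyped present/absent, and per-population
carrier frequencies follow.

**Population genetics.** Per-locus Fst uses Hudson's estimator for
haploid samples, `Fst = 1 − Hw/Hb`; the panel mean is a ratio of sums,
and its null distribution is built by repeatedly resampling loci without
replacement (B = 1000 draws of L = 1000 loci) with a 99% empirical CI.
Qst comes from a nested random-effects ANOVA
(population / line-within-population / replicate):
`Qst = σ²GB / (σ²GB + 2 σ²GW)`. A trait is called under **directional**
selection when Qst exceeds the upper 99% bound of the resampled Fst,
**stabilizing** when below the lower bound, **drift** otherwise.
LD blocks follow the Gabriel D′-confidence-interval rule with bootstrap
CIs over lines.

**Association.** A general linear model per marker
(trait ~ intercept + structure PCs + marker) over MAF ≥ 0.15 markers with
Bonferroni thresholds (e.g. α/m = 1/48,296 ≈ 2.07 × 10⁻⁵), Welch tests of
expression against carrier status, and assay-vs-prediction concordance
arithmetic.

## Worked example

The numbered scripts under `analysis/` run the whole study on the
bundled synthetic panel (2 × 1 Mb genome, 10 + 10 inbred lines, 100
planted insertions, 15× coverage). `python analysis/02_detect_insertions.py`
prints:

```
scanned 6,111,742 reads -> 6,145 junction hits
called 100 loci; recall vs truth 100.0% (100/100)
by superfamily: {'LTR/Gypsy': 60, 'LTR/Copia': 22, 'DNA': 14, 'other': 4}
sharing spectrum: 17 singleton, 13 in two lines, 70 in >= 3 lines
mean carrier frequency: {'temperate': 0.282, 'tropical': 0.276}
```

Every planted insertion is recovered at its exact breakpoint with the
correct per-line genotypes, and none of the TE copies embedded in the
reference produces a false call. `analysis/04_population_genetics.py`
then reports the frequency spectra, the resampled mean Fst with its 99%
CI, and the Qst of the simulated flowering-like trait — here
`Qst = 0.955` against `Fst ≈ 0.41`, a directional-selection call, as
expected for a trait generated with a large between-population shift.

The same stages are available as a CLI (`nrte simulate`, `nrte
build-edges`, `nrte scan`, `nrte run`, ...) for file-based use.

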