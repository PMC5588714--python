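# Methods

## Scope and model

The package detects non-reference TE insertions (NRTEs) from short reads
of fully inbred lines and runs the downstream population-genomic and
association analyses on the resulting presence/absence matrix. Lines are
treated as haploid throughout: an inbred line carries one allele per
locus, carrier fractions play the role of allele frequencies, and no
heterozygous state exists. Reads are single-end; paired-end information
is not used anywhere in detection.

## Junction detection

1. **Edge database.** The terminal 100 bp of each end of every library TE
   is an *edge*; a TE shorter than 200 bp yields overlapping edges, and
   one shorter than 100 bp contributes its whole sequence at both ends.
   Identical (end, sequence) pairs across family members are collapsed
   with all source TEs retained, so a junction hit is never counted once
   per duplicate family member. Superfamily classes are parsed from the
   maize three-letter code (D·· → DNA, RLG → Gypsy, RLC → Copia,
   otherwise "other"); an unrecognized token falls back to "other" with a
   warning rather than aborting.
2. **Read QC.** Trailing bases below Q20 are trimmed, reads shorter than
   75 bp are dropped, survivors are hard-truncated to exactly 75 bp. The
   75-bp length is load-bearing: the junction rule below partitions each
   read into a TE segment of k ∈ [20, 55] bp and a flank of 75 − k bp,
   both within [20, 55].
3. **Edge matching.** A read is a candidate when its first or last k
   bases equal the *extremity* of an edge exactly — the prefix of a
   5′ edge or the suffix of a 3′ edge — on either strand (reverse
   complements of the extremities are indexed too). Matching is anchored
   on the 20 bases of the TE segment adjacent to the read boundary: one
   dictionary lookup of the read's first and last 20-mer returns every
   candidate (edge, k, strand), verified by full comparison; the maximal
   k per edge/side is kept. Exactness is deliberate — the probability of
   a chance ≥21-bp identity at a fixed junction is (1/4)²¹ — and makes
   the scan O(1) per read.
4. **Reference-resident filter.** Candidates aligning to the reference
   over any ≥65-bp window at ≥95% identity (substitutions only) are
   discarded as reads from TE copies the assembly already contains.
   Alignment is gapless on diagonals seeded by exact 20-mers at six read
   offsets, both strands. With ≤3 mismatches allowed in 65 bp, a read
   whose mismatches happen to break every seed could in principle slip
   through; that failure mode requires ≥3 errors placed pathologically
   and only weakens the filter (a kept read must still pass unique
   perfect flank placement), so the approximation is conservative for
   specificity of the *call set*, and exact for error-free data.
5. **Flank placement.** The 20–55-bp flank must match the reference
   perfectly at exactly one position counting both strands; non-unique
   or imperfect flanks are dropped. The breakpoint is recorded as the
   0-based reference insertion point (the coordinate at which the TE
   abuts the flank), which is identical for left- and right-side
   junction reads of the same insertion, so the two read families
   cluster at the same position.
6. **Clustering and genotyping.** Hits on one chromosome with the same
   superfamily are chained while consecutive breakpoints are ≤10 bp
   apart (config-exposed); chains wider than 10× the tolerance are split
   at the largest gap. Locus position is the median member breakpoint. A
   line is called present with ≥1 supporting hit by default
   (`min_support` exposed); absence is coded 0, matching the
   presence/absence treatment of the original screen — a "missing"
   state is reserved for externally supplied matrices.

## Synthetic panel

The generator produces the study conditions used by the tests and the
analysis scripts: two chromosomes of 1 Mb with uniform i.i.d. base
composition; 40 gene models with 5′UTR/exon/intron/3′UTR structure; a
20-element TE library (class mix ~31% DNA, 40% Gypsy, 26% Copia, 3%
other, mirroring the maize superfamily proportions); six full-length TE
copies embedded in the reference as false-positive bait; 100 insertion
loci over 10 temperate + 10 tropical lines; 15× coverage of 100-bp
single-end reads (truncated to 75 bp by QC) with i.i.d. substitution
errors (default 0, 0.5% in the error-robustness checks). Insertion sites
keep a read-length buffer from reference TE copies, chromosome ends and
each other, so clustering is unambiguous by construction.

Locus classes (private-temperate / private-tropical / shared, 0.3 / 0.3 /
0.4) draw carrier frequencies from per-class Beta distributions —
Beta(0.6, 2) for private classes (low-frequency-skewed), Beta(0.8, 0.8)
for shared — then genotypes are realized as Bernoulli draws and the
*empirical* carrier fraction is recorded as the truth frequency, so truth
and genotype matrix agree exactly. Uniform base composition keeps the
4⁻ᵏ uniqueness argument exact on synthetic data; real genomes have
repeat structure the simulator deliberately omits (see Limitations).

Phenotypes follow
`y(line, rep) = shift·[tropical] + Σ effect·g + N(0, σ²_line) + N(0, σ²_rep)`
with defaults shift 2.0, five causal loci of effect 1.0 (chosen among the
most population-differentiated loci so the trait genuinely diverges),
line SD 0.5, replicate SD 1.0, two replicates — a strongly diverged
trait, so the worked example lands in the directional-selection regime.
Expression is log-normal per gene with carrier multipliers (default
0.67×) on a few planted (gene, locus) pairs.

Determinism: each stage derives an independent generator from
(seed, crc32(stage label)), so identical configurations give
byte-identical outputs and stages can be regenerated independently.

## Landscape

Chromosomes are tiled with contiguous windows (1 Mb canonically; the
analysis scripts use 250 kb so a 1-Mb chromosome contributes several
windows — the machinery is size-agnostic); the last window may be short
and every count is normalized per Mb of actual width. Gene density is
gene count per Mb (midpoint assignment). Recombination rate is the slope
of the Marey curve (cM against bp), interpolated piecewise-linearly —
chosen over loess/spline smoothing for determinism and because window
rates then integrate exactly back to the chromosome's cM span — with
terminal-segment slopes extrapolated beyond the outermost markers.
Pericentromere boundaries are an input interval table, not inferred.
Gene context uses the precedence exon > UTR > intron > 1-kb flank >
intergenic, strand-aware for up/downstream; a locus in the flank of two
genes goes to the nearer one, ties to upstream. Track correlations are
plain Pearson r with the two-sided t p-value; zero-variance tracks yield
a flagged undefined result.

## Population genetics

- **Fst.** Hudson's two-population estimator with haploid small-sample
  correction: `Hw = ½[p₁(1−p₁)n₁/(n₁−1) + p₂(1−p₂)n₂/(n₂−1)]`,
  `Hb = ½[p₁(1−p₂) + p₂(1−p₁)]`, `Fst = 1 − Hw/Hb`; monomorphic-in-both
  loci are undefined and excluded. Chosen because it is well behaved for
  two populations and presence/absence data; Weir–Cockerham is available
  behind a switch. The panel mean is the ratio of sums, not the mean of
  ratios. The resampled distribution draws L = 1000 loci without
  replacement per replicate, B = 1000 times, seeded; the 99% CI is the
  empirical 0.5/99.5 percentile pair. When fewer informative loci exist,
  L is reduced with a warning; the desk-scale analysis scripts draw half
  the loci per replicate so the resampled means actually vary.
- **Qst.** Nested ANOVA on line means: `MSB` among populations, `MSW`
  among lines within populations, with unbalanced
  `n₀ = (N − Σnᵢ²/N)/(k−1)`. The replicate mean square (pooled
  within-line variance) divided by the mean replicate count is
  subtracted from `MSW` so σ²GW is purely genetic; both components are
  clamped at zero before forming `Qst = σ²GB/(σ²GB + 2σ²GW)`; zero total
  genetic variance yields a flagged undefined result.
- **Selection call.** Directional iff Qst exceeds the upper 99% Fst
  bound, stabilizing iff below the lower, drift otherwise.
- **LD.** Haploid r² and |D′| from the 2×2 haplotype table over complete
  cases, pairs within 500 kb, markers required ≥50% genotyped and
  polymorphic. A Hardy–Weinberg cutoff parameter is accepted for
  interface compatibility but ignored with a warning — it has no meaning
  for haploid inbreds. Blocks follow the Gabriel thresholds
  (strong LD: D′ CI lower ≥0.70 and upper ≥0.98; recombination: upper
  <0.90; a run is a block when ≥95% of its informative pairs are strong),
  with the D′ CI from a seeded percentile bootstrap over lines (100
  reps) in place of the original likelihood CI; blocks are taken
  longest-first and never overlap.

## Association

Structure covariates are the top k = 3 principal components (exposed) of
the mean-centered marker matrix, optionally from a seeded column
subsample (mirroring structure estimation from a separate SNP set);
component signs are fixed by making the largest-magnitude loading
positive. The per-marker GLM is ordinary least squares of the trait on
[intercept, PCs, marker]; the marker p-value is the two-sided t test of
its coefficient, equivalent to the nested-model F. Markers are filtered
at MAF ≥ 0.15 (boundary inclusive) and thresholded at Bonferroni α/m.
In power statements, a "1-SD effect" means a standardized regression
effect — the trait shifts by one residual SD per SD of marker dosage
(β = σ/sd(g)) — the package's convention for expressing effect sizes on
a MAF-independent scale. Expression uses Welch's unequal-variance t
between carriers and non-carriers. Concordance tables report exact
percentages n/total × 100 at one decimal.

## Numerical and design notes

- Coordinates are 0-based half-open internally; GFF3 and the locus
  report TSV are 1-based inclusive; BED stays 0-based.
- Insertions are clean splice-ins without target-site duplications; a
  TSD would shift left/right junction breakpoints by a few bp, which the
  10-bp cluster tolerance absorbs.
- All matching in detection is exact by design; the only
  approximation is the seeded gapless alignment in the reference filter
  (see above).
- Problem sizes in the tests and acceptance script (2-Mb genome, 20
  lines, 100 loci, 15×; 200-replicate estimator recoveries; 500-window
  correlation checks) are the package's desk-scale study conditions,
  chosen so each oracle has enough resolution for its stated tolerance.

## Limitations

Passing tests on the synthetic panel show the pipeline implements its
rules correctly, not that those rules suffice on real data: the
simulator has no nested or truncated TEs, no repeat-rich background (so
flank uniqueness is easier than in a real genome), no indel sequencing
errors, no heterozygosity, and no TE excision. Absence genotyping via
spanning reads, breakpoint refinement under TSDs, and detection of
deletions of reference TEs are out of scope. Background recombination
estimation with a coalescent PAC model is not re-implemented. With >2
populations the Fst machinery does not apply.
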