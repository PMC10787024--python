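# Methods note

This note records the statistical models, numerical conventions, and
simulator designs used by `palmscan`, along with the reasoning behind the
non-obvious choices and the known limitations.

## 1. Data model

Genotypes are biallelic SNPs over diploid samples, stored as an
`n_sites × n_samples` matrix of alt-allele dosages (0/1/2, −1 for missing).
VCF input is restricted to biallelic A/C/G/T SNPs; everything else is dropped
and logged.  Coordinates are 0-based half-open internally; VCF and GFF3
readers/writers convert at the boundary.  Windows are fixed-width sliding
windows (default 100 kb size, 50 kb step); truncated terminal windows are
excluded unless requested.

## 2. Estimators

**Site π.**  For a site with `c` alt alleles among `n` called alleles,
`π = c(n−c) / C(n,2)`; undefined for `n < 2`.  Windowed π is the sum of site
π over the window divided by window length (per-bp units).

**Watterson's θW** is `S / (a1 · L)` with `a1 = Σ_{i<n} 1/i` and `n` the
median called-allele count over the window's sites; per-bp units.

**Tajima's D** uses the full Tajima (1989) constant set
(`a1, a2, b1, b2, c1, c2, e1, e2`) with the same window-level `n`.
D is undefined (NaN) exactly when `S = 0`; undefined windows are excluded
from outlier quantiles and can never be outliers.

**Weir–Cockerham FST (1984), two populations.**  Per-site variance
components `a` (between populations), `b` (between individuals within
populations), and `c` (within individuals) are computed with the
finite-sample corrections of the original paper from `(n_i, p_i, h_i)` —
sample sizes, allele frequencies, and observed heterozygote frequencies.
Sites where the pooled frequency is 0 or 1 are skipped.  Multi-site FST is
the ratio of sums `Σa / Σ(a+b+c)`; negative per-site components are retained
(they cancel in expectation).  The implementation is verified exhaustively
against an independent ANOVA mean-squares formulation (MSP/MSI/MSG).

**LD.**  r² is the squared Pearson correlation of dosage vectors over
samples called at both sites (composite / Rogers–Huff LD, valid for unphased
data).  Decay curves bin pairs by distance; the half-decay distance is the
first bin (after a centred moving-average smooth) at which mean r² falls to
`(peak + floor)/2`, with the floor estimated from the last 10% of bins.

**Nei–Gojobori (1986) Ka/Ks.**  Synonymous site counts are fractional
(each codon position contributes `s/3` where `s` is the number of synonymous
single-base changes; changes to stop codons count as nonsynonymous).
Between-codon differences are averaged over all minimal substitution
pathways, excluding pathways that pass through a stop codon (if all pathways
are blocked, stop-passing pathways are counted as a fallback).  Proportions
are Jukes–Cantor corrected; `ps ≥ 0.75` marks the pair saturated (Ks = NaN).
Alignments with internal stop codons raise; the batch interface skips and
logs them.  Codon columns containing gaps or ambiguity codes are removed at
construction.

**Alignment.**  Global alignment with free end gaps
(match 1, mismatch −1, gap −2 by default) via Biopython's PairwiseAligner.
Identity is matched columns divided by aligned columns between the first and
last aligned pair — terminal overhangs are excluded, internal gaps count
against identity.

**Peak detection.**  Gaussian KDE with Silverman bandwidth on the pooled
values; local maxima of the density on a 1024-point grid; modes below 10% of
the density maximum are discarded; remaining modes are greedily thinned
(highest first) to a minimum separation.  A degenerate constant sample
returns a single mode.  At least 50 finite values are required.

**LTR insertion age.**  `T = K / (2μ)` with `K = 1 − identity` of the twin
LTRs and `μ = 1.3×10⁻⁸` substitutions/site/year.  JC correction is optional
and off by default — intact elements have small `K`, where the correction is
negligible.

## 3. Selection scan

The scan intersects, at the window level, the upper 5% tails of FST and of
the π-ratio (π_ancestral / π_introduced), merges overlapping or book-ended
outlier windows into regions, overlays Tajima's D support
(≥ 1 window of the region in the lower 5% tail of D in the introduced
population — an annotation, not a third intersection term), and reports
genes overlapping regions by ≥ 1 bp.

**Quantile convention.**  Empirical tails use the nearest-rank rule with
inclusive ties: the upper-tail threshold is the ascending-rank
`ceil((1−q)·m)` order statistic and outliers are values `≥` threshold; the
lower tail mirrors it.  For 100 distinct values at `q = 0.05` this flags 6
windows (ranks 95–100).  Ties at the threshold all qualify, so the flagged
fraction can exceed `q`; this inclusive convention is deterministic and
never silently discards a window equal to the threshold.

## 4. Simulators

All simulators are deterministic under a fixed seed and write plain text.

**Two-population genotypes.**  The number of segregating sites is
`S ~ Poisson(θ · a1 · L)`; each site draws a derived-allele count `i` with
`P(i) ∝ i^(−1)` (the neutral frequency spectrum).  At `F = 0` the `i`
derived alleles are assigned to the `2(n₁+n₂)` allele slots *exactly*
(hypergeometric sampling without replacement), which makes `E[π] = E[θW] = θ`
and `E[D] ≈ 0` by construction.  (Drawing each allele independently
Binomial(`i/2n`) instead inflates Tajima's D by ≈ +0.34 at these sample
sizes because it adds extra between-site variance in realized frequencies;
the exact-count construction is the one that actually delivers a calibrated
neutral null.)  At `F > 0`, population-specific frequencies are drawn from
the Balding–Nichols Beta distribution around the ancestral frequency and
genotypes are Binomial(2, p_pop), giving `E[FST] ≈ F` under the
Weir–Cockerham estimator.  Sweep regions thin the introduced population's
variants with probability `1 − ρ_sweep` and redraw surviving frequencies
with `P(i) ∝ i^(−rare_skew)`; `ρ = 1` with `rare_skew = 1` is an exact
no-op.  Optional `ld_block_bp` copies genotype rows within blocks (r² = 1
inside a block) to create tunable LD decay.

**Coding pairs.**  Genes are built from 4-fold-degenerate codons whose first
two positions never create synonymy or stop-adjacency (Ala/Val/Thr/Pro), so
every codon has exactly one synonymous site and no nonsynonymous changes are
introduced.  For a target Ks drawn from the configured mixture, third
positions of one copy mutate with `p = (3/4)(1 − e^{−4Ks/3})` — the exact
inverse of the Jukes–Cantor correction, so NG86 recovers the target in
expectation.

**TE subfamilies.**  Each subfamily gets a random consensus; each copy
mutates per-site with `q = (3/4)(1 − √(1 − (4/3)(1 − I)))`, the exact
solution of `(1−q)² + q²/3 = I`, so the *pairwise* identity of two copies is
`I` in expectation.  The burst epoch (target identity) is assigned per
subfamily by default: copies of one subfamily share one amplification burst,
which keeps the pooled identity distribution bimodal.  Per-copy epoch
assignment is available but produces cross-epoch pairs at intermediate
identity that fill the valley between modes.

**LTR elements.**  Twin LTRs start identical and each mutates per-site with
probability `μT`; the expected divergence is `K = 2μT` (per-branch
mutations), so dating with `T = K/(2μ)` is unbiased for small `K`.

**Annotation.**  Per-window gene counts, repeat-coverage fractions, and GC
content are realized exactly (one repeat interval per window with the exact
requested coverage; per-base GC sampling with the requested rate); tandem
arrays and family singletons are planted at configured positions with
spacing validated against the chaining threshold, so array truth is exact.

**Linkage map.**  Markers are spread along contigs with intra-block gaps
kept below any planted chimera boundary gap (blocks shrink and anchor
against their boundary when needed); chimeric contigs carry consecutive
blocks from different linkage groups separated by a configured gap, with the
truth boundary at the gap centre.  Optional noise flips each marker's
linkage group with the configured rate.

## 5. Genome features

**Tandem arrays.**  Family-labelled genes on a chromosome are chained while
`next.start − prev.end < 100 kb` (overlap counts as distance 0); chains of
≥ 2 are arrays.  Pooled across families by default (family composition
reported per array), optionally per family.

**Landscape tracks.**  Per-window gene density (midpoint counts), repeat
coverage (interval-union bp), GC fraction, and optional user tracks, with a
pairwise-complete Pearson correlation matrix.

**Chimeric contigs.**  A contig is chimeric when ≥ 2 linkage groups each
contribute ≥ 5 markers ("more than four"); stray markers from non-qualifying
groups are ignored.  Each split is placed at the midpoint of the gap between
adjacent qualifying-group markers of different groups.  Splitting produces
`contig.k` pieces plus a lift table; pieces concatenate back to the source.

## 6. Default problem sizes

The defaults mirror the intended use case: θ = 0.001/bp, 20+20 diploids,
F = 0.05 between populations, 100-kb/50-kb windows, q = 0.05 tails,
ρ_sweep = 0.2 partial sweeps, Ks mixture around 0.22/0.32, TE identity
epochs 0.92/0.82 (30 subfamilies × 100 copies), μ = 1.3×10⁻⁸ for LTR
dating, 100-kb tandem-gap threshold, 5-marker chimera minority rule.  The
verification suite and `scripts/acceptance.py` run these defaults at desk
scale (1–10 Mb chromosomes, hundreds to thousands of pairs) chosen so the
full suite completes in minutes on one CPU while keeping Monte-Carlo
standard errors well inside the asserted tolerances.

## 7. Limitations

- The genotype simulator draws sites independently (no coalescent
  genealogies); LD is injected mechanically via block copying, so LD decay
  curves are stylized, not population-genetic.
- Sweeps are modelled as variant thinning plus spectrum skew, not as
  trajectories of a beneficial allele; linked-selection shoulders are absent.
- NG86 is the equal-rates estimator; no transition/transversion or codon
  frequency weighting (maximum-likelihood Ka/Ks is out of scope).
- KDE mode counts depend on bandwidth for strongly overlapping mixtures;
  the defaults are tuned for mode separations ≳ 2σ.
- The chimera rule places one split per adjacent qualifying-group
  transition; a noise-flipped marker adjacent to a true boundary can
  displace the split by up to about one marker spacing.
- Window-level statistics assume a per-window median sample size; windows
  with extreme missingness heterogeneity are better filtered upstream
  (`filter_variants`).
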