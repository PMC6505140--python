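# Methods

## Colony quantification ("Eclipse")

A pinned psh colony is modelled as three hard color classes: a bright ring
(the rim of the dense inner colony), a gray filamentous halo, and the agar
background. Measurement proceeds in four steps:

1. **Pixel classification.** A pixel is *achromatic* when its RGB channel
   spread (max − min) is ≤ `max_chroma` (default 30). Achromatic pixels
   with mean intensity ≥ `white_min` (default 200) are ring; those in
   [`gray_min`, `gray_max`) (defaults 110, 200) are filament; everything
   else is background. The defaults separate the renderer's default colors
   — ring (245,245,245), filament (150,150,150), background (80,90,110) —
   with wide margins; real scans should use `calibrate_thresholds` or
   explicit values.
2. **Threshold calibration.** Three-class Otsu thresholding of the
   tray-wide luminance histogram, refined by a short Lloyd iteration so
   the two cut points sit midway between the three class means (plain
   multi-Otsu can return a cut inside a histogram spike on synthetic,
   noise-free images). A blank or two-mode tray raises a calibration
   error or flags an empty filament band. One set of thresholds is used
   for a whole tray, never tuned per colony.
3. **Ring-extrema ellipse and eclipse.** The minimal/maximal row and
   column of any ring pixel define an axis-aligned ellipse (center at the
   midpoints, semi-axes half the spans). A pixel (r, c) is eclipsed iff
   ((r−cᵣ)/sᵣ)² + ((c−c_c)/s_c)² ≤ 1 at integer pixel centers; the
   boundary counts as inside. This inclusion rule is fixed so results are
   bit-reproducible.
4. **Index.** `index = 100 · n_outside / n_eclipsed` where `n_outside`
   counts ring *and* filament pixels outside the ellipse (off-axis ring
   overflow is genuine signal of an irregular colony boundary and is
   deliberately included; the stricter filament-only count is reported
   alongside as `n_filament_outside`), and `n_eclipsed` counts every
   pixel inside the ellipse regardless of class. A
   `denominator="nonbackground"` variant restricts the denominator to
   colony-class pixels.

Per-tray processing crops the 8×12 grid, applies declarative exclusion
rectangles (manual crop of smudges/cracks; affected wells are marked
CROPPED, excluded pixels leave both numerator and denominator), and turns
ring failures into DROPPED rows rather than exceptions. A crop whose
border is >60% ring pixels is flagged as likely neighbor bleed-through.

**Coordinate conventions.** Image coordinates are 0-based (row, col) with
row 0 at the top; crops and exclusion rectangles are half-open.

## Synthetic colony renderer

The renderer paints hard, non-anti-aliased classes so the painted class
map is unambiguous ground truth. The ring is an elliptical annulus whose
outer boundary can be perturbed by smooth periodic per-angle noise
(`ring_irregularity`, a fraction of the radius, implemented as 2–5-cycle
random harmonics); the halo is the annulus extending `halo_extent` px
beyond the ring, each halo pixel painted filament-gray independently with
probability `halo_coverage`. Ground truth is computed by direct pixel
counting inside the renderer — including its own point-in-ellipse test —
and never by calling the measurement code, so renderer and quantifier are
independent implementations of the same definitions. Plates composite 96
cell-local renders (per-position RNG streams spawned from one seed) and
paint near-white artifact rectangles last, flagging overlapped positions.

What the renderer does *not* emulate: anti-aliased edges, lighting
gradients, agar texture, out-of-grid colonies, chromatic casts. Passing
the ground-truth-recovery tests therefore demonstrates correctness of the
geometry and counting logic, not robustness to scanner noise; on real
scans the index is a rough relative measure and threshold calibration
quality dominates.

## Phenotype aggregation

Group summaries report the arithmetic mean, sample (n−1) standard
deviation and s.e.m.; single-replicate groups are flagged rather than
given a fake zero. Within-plate z-scores, z = (x − plate mean)/plate sd,
absorb tray-to-tray level differences; plates with fewer than two
QC-passing colonies or zero spread are flagged and left missing. Pool
selection ranks segregants by mean z; means within ε = 0.05 z-units of
the k-th rank are treated as near-ties and resolved toward lower replicate
variance (the declared convention for combining "most extreme" with "most
consistent"; default pool size k = 22). ANOVA-style model fitting is out
of scope — `export_tidy` writes a per-colony table with the usual model
term columns for external statistics software.

## Smoothed-G bulk segregant scan

Per SNP the 2×2 table of (ref, alt) read counts in the high and low bulks
gives G = 2 Σ nᵢⱼ ln(nᵢⱼ/n̂ᵢⱼ), with expected counts from the margins and
0·ln 0 ≡ 0. G is invariant under swapping bulks or alleles. Within each
chromosome, G′ at a focal SNP is the tricube-weighted mean of G over SNPs
within `window/2` bp (window = full width, default 60 kb; weights
(1−(d/(w/2))³)³ normalized to sum 1; windows truncate at chromosome
ends). The companion diagnostic Δ = alt-frequency(high) −
alt-frequency(low) is reported per SNP.

**Null model.** ln G′ is fitted as Normal(m, MAD²) with m the median and
MAD the 1.4826-scaled median absolute deviation; values above
m + 5.2·MAD (Hampel's rule) are treated as putative QTL and removed, the
fit is repeated, and upper-tail p-values are taken from the refitted
normal. p-values are BH-adjusted; SNPs with q ≤ `fdr_q` (default 0.01)
form runs, and runs separated by less than window/2 bp merge into one
peak. The log-normal family is exact when G′ values are independent
draws; on real (or simulated) scans neighbouring G′ share pool-sampling
noise, and the mid-tail of ln G′ is heavier than normal, so raw p-values
are mildly anticonservative at the 0.05 level while remaining
well-behaved where it matters, in the far tail used at FDR 0.01 (no-QTL
simulations yield essentially no q ≤ 0.01 calls). Filtering defaults:
site quality ≥ 20, per-bulk depth in [10, 220] (≈4× the expected 55×
coverage).

## F5 pool simulator

Each segregant's genotype along a chromosome is a two-state Markov chain
over the SNP grid: an interval of d bp corresponds to
d / `map_density` cM (default 2 kb/cM, budding-yeast scale) multiplied by
`map_expansion` (default 2.0, the approximate map expansion of an F5
relative to an F2), converted to a recombination fraction by the Haldane
map function r = ½(1 − e^(−2d)). Phenotype = Σ QTL-effect·genotype +
Normal(0, noise_sd²) (noise_sd default 1.0, so a planted effect of 3 is a
3-sd locus — a major-effect QTL). The top and bottom `k_per_pool`
(default 22) of `n_segregants` (default 360) form the bulks; per SNP and
bulk, depth ~ Poisson(`mean_depth`, default 55) and alt reads ~
Binomial(depth, realized pool allele frequency). The default genome is 16
chromosomes at real yeast chromosome lengths (~12 Mb; ~24,000 SNPs at the
default 500 bp spacing). A full simulate-plus-scan cycle takes about one
second, so no reduced problem size is used anywhere.

The simulator emulates selection, linkage, map expansion and read
sampling; it does not model segregation distortion, genotyping error,
variable SNP density, mapping bias toward the reference allele, or
non-additive QTL. Planted-QTL recovery results therefore speak to the
scan's statistical behaviour under the declared design, not to artefacts
of real short-read data.

**Stochasticity of peak counts.** Peak calling on simulated data is a
Monte-Carlo quantity: with two planted 3-sd QTL, the scan calls exactly
two peaks in ~9 of 10 seeds (occasionally a chance pool-divergence block
adds a third, or a QTL run splits). Likewise the direction "more peaks at
smaller windows" holds in ~9 of 10 seeds; the exceptions occur when a
marginal sub-peak drops below the FDR cut-off at a smaller window. Tests
pin seeds; the acceptance script reports whatever the supplied seed
produces.

## Numerical and degenerate-input choices

- Ellipse boundary pixels count as eclipsed; ties in pool selection break
  deterministically (variance, then id).
- G for an all-zero table, smoothing of unsorted positions, p-values from
  fewer than 50 SNPs, and out-of-range p inputs are errors, not silent
  results.
- A G′ of exactly 0 (possible only when every G in the window is 0)
  receives p ≈ 1.
- BH adjustment is order-preserving and capped at 1; q ≥ p always.
- All RNG streams derive from explicit integer seeds; plate positions use
  `SeedSequence.spawn` so per-colony noise is independent of neighbours
  but fully reproducible.

## Known limitations

- The index conflates halo density and halo extent; two colonies with the
  same index can have different halo morphologies.
- Ring-extrema fitting uses all ring-class pixels in the crop; a bright
  artifact inside the crop corrupts the ellipse unless excluded (that is
  what exclusion rectangles and the QC flags are for).
- Auto-calibration needs all three luminance modes present on the tray;
  trays of uniformly non-filamentous colonies need explicit thresholds.
- The scan assumes biallelic SNPs from exactly two pooled samples;
  multiallelic sites and indels are skipped on input.
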