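# Methods

This note documents the statistical model, the conventions and numerical
choices of `hotqtl`, and what the synthetic-data generators do and do not
emulate.

## Map geometry and conventions

Positions are genetic distances in cM, 0-based per chromosome. All distance ↔
recombination conversions use the Haldane map function, r(d) = (1 −
e^(−2d/100))/2; the linkage parameter λ = 1 − 2r = e^(−2d/100) is
multiplicative over adjacent segments, so composite spans sum distances.
Haldane (no interference) is the assumption under which the closed-form
correlation values quoted in the tests hold.

Hotspot bins are half-open `[x, x + Δ)` tiling each chromosome from 0; a
partial terminal bin is kept (not merged) so every full bin has exactly size
Δ. A chromosome's right end belongs to its last bin. The global bin index
concatenates chromosomes in map order; the same concatenation, closed into a
circle, is the coordinate system of the permutation schemes. Default Δ = 2 cM.

## Interval mapping

`hk_scan` is single-QTL Haley–Knott regression for a backcross: at each scan
position the phenotype is regressed on E[x | flanking genotypes] under
Haldane, and LOD = −(n/2)·log10(1 − R²). R² is capped at 1 − 1e−12 so a
perfect fit yields a large finite LOD rather than overflow; constant
phenotypes or degenerate design columns give LOD 0. Missing genotypes are
handled per individual by conditioning on the nearest informative flanking
markers (single flank at chromosome ends, prior 1/2 with no information).

The default scan grid is the regular `step` grid (step = Δ = 2 cM), *without*
adding marker positions as extra scan points. LOD is thus recorded once per
bin and estimated peaks snap to bin-aligned positions, which is the
convention under which per-bin QTL counts aggregate cleanly; a denser scan
(`include_markers=True`) is available but scatters peak estimates across bin
boundaries.

`detect_qtl` reports at most one QTL per trait per chromosome: the
chromosome-wide LOD argmax (leftmost on ties, for determinism) when it
reaches the threshold. The support interval is the drop rule (default 1.5
LOD, read as a 95% interval): the outermost crossing points of `peak − drop`,
linearly interpolated between grid points and clipped at chromosome ends. The
peak SD is `si = (b − a)/(2·z)` with z the normal quantile of the coverage
(1.96 for 95%), i.e. the interval is read as peak ± z·si. The multi-peak
alternative (several separated peaks per chromosome) is deliberately not
implemented; one-per-chromosome is what makes "number of QTL per trait"
well-defined across LOD thresholds.

`permutation_lod_threshold` shuffles phenotype rows (genotypes fixed),
records the genome-wide maximum LOD per permutation, and returns the
empirical order statistic ceil((1 − α)B). On the default design (n = 100,
5 × 100 cM) with one standard-normal trait and B = 1000 this lands near LOD
2.45–2.60 for a 5% genome-wide error rate.

## EQF model

A detected QTL contributes a probability distribution for its location:
Normal(peak, si²) truncated to the support interval and re-normalized
(individual-level data), or Uniform(a, b) (database intervals). Truncation
keeps the per-QTL mass exactly 1 — "the fractions within the bins sum to
one" — where an untruncated normal would leak ~5% outside a 95% interval.
Intervals are clipped to chromosome bounds first, then re-normalized.
Zero-width intervals (QTL localized at a marker) put mass 1 in the containing
bin. `point_mass=True` in `multi_threshold_eqf` instead assigns each QTL to
its peak bin with mass 1 — the count representation used when comparing
count-based hotspot methods on a common footing, and the representation used
by the reference simulation analysis.

## Trait grouping and permutation

Empirical trait grouping joins traits whose detected QTL peaks share a bin;
groups are the connected components of the trait–bin incidence graph (a trait
with QTL in two pile-up bins merges the groups, because its QTL must move
coherently). A bin's shared QTL form a *trunk* only if it holds ≥ 2 QTL from
≥ 2 traits; single-trait pile-ups dissolve into free QTL. The grouping grid
may differ from the EQF grid (`grouping_bins`), default: same grid.

Two permutation schemes estimate the null of randomly placed QTL:

* **EQF-bin** (default): every unit — each trunk, each free QTL — gets one
  uniform random whole-bin offset on the W-bin circle; per-QTL bin-mass
  vectors shift jointly within a unit. Per-trait row sums are conserved
  exactly.
* **QTL-interval**: units get continuous uniform offsets in [0, G) cM on the
  concatenated circle; intervals keep width and internal density shape, may
  wrap across chromosome joins, and their bin masses are recomputed at the
  new location. Continuous offsets keep this scheme genuinely distinct from
  the bin-shift scheme (whole-bin shifts would make the two algebraically
  identical); the two agree within Monte-Carlo error on the ladder values.

For each permutation the architecture's descending order statistics F*(1) ≥
F*(2) ≥ … are stored in one pass; γₙ,α is the order statistic
ceil((1 − α)B) of the F*(n) sample. β re-runs the same machinery with every
QTL free and takes the quantile of the genome-wide maximum (the Q-method);
k is the largest n with γₙ,α ≥ β. Hotspot calls use strict `F_w > γ`
("higher than"); a `ge` flag admits borderline equality. One RNG stream,
seeded per run, drives grouped and baseline passes in a fixed order, so
thresholds are bit-reproducible.

Conservatism on null data: empirical grouping freezes whatever chance
co-localizations the observed data contain into trunks, which every
permutation then preserves while adding fresh collisions on top; γ₁ therefore
dominates the observed maximum and the realized error rate on pure-null data
is far below α. This is the price of robustness to trait correlation. The
calibration property of the machinery itself is checked in the no-grouping
configuration (which on no-pleiotropy null data coincides with perfect
grouping), where the realized rate is ≈ α.

## Top-γ profiles

For a bin, n(L) = min{n : γₙ,α(L) ≤ F_w(L)} (equality significant, per the
threshold's definition as an attained order statistic), or "ns" if even γₖ is
missed. The trend over the LOD ladder is classified by Kendall's τ between L
and n: τ ≥ +0.5 with a non-degenerate range → increasing (type i), τ ≤ −0.5
→ decreasing (type ii), else flat (type iii); all-ns → none. "ns" entries
enter the trend as k + 1 so a hotspot fading out of significance reads as
increasing. The τ cutoff and a minimum-range gate are configurable; the
default accepts a monotone one-step change (e.g. 3→2) as a trend, since
single-step declines are exactly how strong-LOD hotspots present on short
ladders.

## Synthetic data

`simulate_backcross` draws each chromosome as a Markov chain over the marker
positions (first locus Bernoulli(1/2), switches with probability r(d));
chromosomes and individuals independent. True gene positions are simulated
jointly with the markers.

`simulate_reference_design` is the package's reference study: n = 100 progeny,
5 × 100 cM, 50 equally spaced markers per chromosome, 600 traits in three
pleiotropic hotspots (A: chr1@50, 100 traits, h² ~ U(0.30, 0.45), 60
monogenic and 40 di-/trigenic with secondary genes uniform on chromosomes 2
and/or 4; B: chr3@50, 300 traits, half h² ~ U(0.10, 0.45) and half
U(0.30, 0.45); C: chr5@50, 200 traits, h² ~ U(0.10, 0.20)). Conventions the
design leaves open were fixed once:

* "Equally spaced" means spacing = length/n_markers (markers at 0, 2, …, 98
  cM), i.e. one marker per 2-cM bin, consistent with recording LOD at bins;
  the hotspot genes at 50 cM then coincide with markers. The span-ends
  alternative (`span_ends=True`) puts the genes mid-interval on a bin
  boundary and splits every hotspot across two bins.
* Primary-gene effects are +1 for all traits, so pleiotropic traits correlate
  positively on average (pairwise trait correlations ≈ −0.4…0.7, mean ≈ 0.1);
  secondary effects have magnitude U(0.5, 1) × primary and random sign.
* Heritability is enforced against the model-implied genetic variance
  (backcross genotype variance 1/4 per locus plus λ/4 linkage covariances):
  the residual SD is solved so the generating model's h² equals the drawn
  target exactly.

`simulate_null` provides pure-noise and monogenic-uniform null crosses;
`simulate_null_qtlset` draws summarized null QTL sets directly (uniform
peaks, U(1, 3) cM peak SDs) for fast error-rate calibration.
`simulate_summarized` emits database-style interval tables whose width
classes default to the empirical mix of a large rice QTL database (3.76%
point intervals, 46.14% ≤ 0.5 cM, …); the width table's unprinted remainder
(22.55%) is assigned to a 20–80 cM class, which also reproduces the reported
mean/SD of interval sizes (≈ 9.8/16.8 cM).

What the generators do *not* emulate: non-normal expression noise, shared
environmental/batch correlation between traits (all residuals are
independent), epistasis, missing genotypes, and segregation distortion.
Passing tests therefore demonstrate correct behaviour of the machinery under
the stated generative model, not robustness to those real-data features —
though the permutation thresholds themselves are distribution-free given the
QTL matrix.

## Numerical choices and limitations

* Quantiles are attained order statistics (ceil((1 − α)B)), never
  interpolated, so thresholds are values the statistic actually takes.
* Ties at LOD argmax break leftmost; trunk iteration order is by bin index;
  unit RNG order is trunks (by bin) then free QTL (by QTL index).
* B = 1000 and α = 0.05 are the defaults for thresholds; B < 100 warns.
* The realization of the reference design varies with the seed: hotspot
  bin counts, γ values and top-n values move by tens of percent between
  seeds, while the qualitative structure (three true hotspots at γ₄,
  grouped ≪ Q-method calls, profile types ii/iii/i) is stable.
* The Q-method baseline β is the no-grouping genome-wide maximum quantile;
  with it, the profile of the dominant hotspot is bounded below by n = 2
  whenever its own trunk equals its bin count (the permuted maximum then
  always matches the observed bin, plus occasional collisions), so n = 1
  profiles require mass in the bin beyond its own trunk.
* Multiple-QTL mapping, EM interval mapping, intercross designs, FDR-based
  alternatives and sliding windows are out of scope.
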