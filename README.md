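# hotqtl

Genome-wide QTL hotspot detection with trait-grouped permutation thresholds.

## The problem

When many quantitative traits are mapped in one cross (a genetical-genomics
experiment with thousands of molecular traits) or collected from a public QTL
database, the detected QTL pile up in some genomic regions — QTL *hotspots* —
that may harbor regulators of many traits. Deciding which pile-ups are real is
a multiple-testing problem with a twist: correlated traits (controlled by
pleiotropic or tightly linked QTL) co-localize by construction, so permutation
nulls that shuffle every QTL independently badly underestimate the thresholds
and flood the result with spurious hotspots. Methods that instead permute the
individual-level data preserve trait correlation but need a full QTL-mapping
re-scan per permutation, which is computationally prohibitive.

`hotqtl` implements a framework that operates on the QTL mapping *results*
(one scan only) and still accounts for trait correlation:

1. **EQF architectures.** Each detected QTL (LOD peak `p`, support interval
   `[a, b]`, peak SD `s = (b − a)/(2·1.96)` from the 1.5-LOD 95% interval) is
   spread over Δ-cM genome bins as the mass of a Normal(p, s²) truncated to
   `[a, b]` (uniform over `[a, b]` for database intervals, where only the
   flanking markers are known). A trait's bin masses form a row of the
   expected-QTL-frequency matrix `F = [f_tw]` (T × W); the column sums
   `F_w = Σ_t f_tw` are the genome's EQF architecture. One architecture is
   built per LOD threshold `L_1 < … < L_m`.
2. **Empirical trait grouping.** Traits whose QTL peaks share a bin are
   grouped; each shared-bin QTL cluster (*trunk*) is a single permutation
   unit. Position-based grouping is used because the genetic correlation of
   linked/pleiotropic trait pairs can be *anything* in [−1, 1] — the package
   includes the closed forms showing this (see below).
3. **γ(n, α) thresholds.** The genome is treated as one circle; trunks and
   free QTL are shifted by uniform random offsets, B times. The empirical
   (1 − α) quantile of the n-th largest permuted bin sum `F*(n)` is the
   threshold γₙ,α for the statistic `qFreq(n)` (the n-th largest observed bin
   sum), controlling the genome-wide error rate of declaring at least n
   spurious hotspots. The no-grouping Q-method baseline β closes the ladder at
   k where β = γₖ,α.
4. **Top-γ profiles.** For each bin, the smallest significant n at every LOD
   threshold; a rising n pattern (type i) marks a hotspot of mostly
   moderate-LOD QTL, a falling pattern (type ii) one rich in strong-LOD QTL,
   and a flat pattern (type iii) balanced LOD scores.

The genetic-correlation calculus for two digenic traits on loci
Qi–Qj–Qk–Ql (effects a₁,a₂ and b₁,b₂; λ = 1 − 2r = e^(−2d/100) under Haldane):

    ρ_G = (λ_ij a₁b₁ + λ_jk a₂b₁ + λ_il a₁b₂ + λ_kl a₂b₂)
          / sqrt((a₁² + a₂² + 2λ_ik a₁a₂)(b₁² + b₂² + 2λ_jl b₁b₂))

with the fully pleiotropic, unlinked-pair limit
ρ_G = (a₁b₁ + a₂b₂) / sqrt((a₁b₁ + a₂b₂)² + (a₁b₂ − a₂b₁)²), and the
phenotypic decomposition ρ_P = ρ_G √(h₁²h₂²) + ρ_E √((1−h₁²)(1−h₂²)).

## Worked example

The package ships a seeded generator of its reference study: 100 backcross
progeny, 5 chromosomes × 100 cM with 50 equally spaced markers, and 600
traits in three pleiotropic hotspots at 50 cM of chromosomes 1 (100 traits,
h² 0.30–0.45, 40 of them di-/trigenic), 3 (300 traits, h² 0.10–0.45) and 5
(200 traits, h² 0.10–0.20).

```python
import hotqtl as h

cross, truth = h.simulate_reference_design(seed=1)
lod   = h.hk_scan(cross, step=2.0)
bins  = h.build_bins(cross.genetic_map, 2.0)
qset, emat, arch = h.multi_threshold_eqf(lod, [2.47], bins, point_mass=True)[0]
groups = h.group_traits(qset, bins)
thr    = h.gamma_thresholds(emat, groups, B=1000, alpha=0.05, seed=3)
print(h.call_hotspots(arch, thr, n=4, eqf=emat).table)
```

Running `python examples/03_hotspot_thresholds_profiles.py` prints:

```
620 QTL -> 35 trait groups (36 trunks, 55 free QTL)
gamma(1)=208  gamma(2)=79  gamma(4)=40  Q-method beta=10  k=13
hotspots with EQF > gamma(4) = 40:
chromosome  bin_start  bin_end  bin    Fw  n_traits
         3       50.0     52.0  125 203.0       203
         5       50.0     52.0  225  72.0        72
         1       50.0     52.0   25  66.0        66
(the Q-method threshold beta=10 would call 12 bins)

top-gamma profiles (n per LOD threshold 2..6):
  hotspot A (chr 1 @ 50 cM): n = [4, 3, 3, 3, 3] -> decreasing, type ii
  hotspot B (chr 3 @ 50 cM): n = [2, 2, 2, 2, 2] -> flat, type iii
  hotspot C (chr 5 @ 50 cM): n = [3, 4, 4, 4, 6] -> increasing, type i
```

Reading: at the single-trait 5% GWER detection threshold (LOD 2.47, itself
obtainable with `permutation_lod_threshold`, B = 1000) the three simulated
hotspots hold 66/203/72 QTL. The grouped permutation ladder is far stricter
than the Q-method baseline (γ₁ = 208 vs β = 10): at γ₄ = 40 exactly the three
true bins are called, where β would call 12. The profiles separate the
hotspot types: the high-heritability hotspot A keeps its strong-LOD QTL as
the threshold rises (falling n, type ii), the big balanced hotspot B stays at
a constant n (type iii), and the low-heritability hotspot C fades (rising n,
type i).

The other examples cover the correlation calculus (`01`), mapping and QTL
detection (`02`), and database-style summarized QTL tables with the uniform
interval model and the empirical five-times-mean-EQF rule (`04`). A thin CLI
(`hotqtl simulate|scan|eqf|detect|profile|correlations|run`) wraps the same
functions for shell use; `hotqtl run --config run.yaml` executes the whole
pipeline and writes a reproducibility manifest.

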