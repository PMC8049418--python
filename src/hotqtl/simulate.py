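"""Seeded generators: backcross meiosis, the three-hotspot pleiotropy design,
null data for error-rate calibration, and database-style summarized QTL tables.

All generators take an integer seed (or a Generator) and are fully
deterministic: a single numpy ``default_rng`` stream is consumed in a fixed
order (trait structure first, then genotypes chromosome by chromosome and locus
by locus, then phenotype noise trait by trait).

The default cross design emulates a small genetical-genomics experiment: 100
backcross progeny, 5 chromosomes of 100 cM with 50 equally spaced markers each
(markers at 0, 100/49, ..., 100 cM, so a gene at 50 cM sits between markers),
and 600 molecular traits organized in three pleiotropic hotspots:

* hotspot A - chromosome 1 at 50 cM, 100 traits, h2 ~ U(0.3, 0.45); 60 traits
  monogenic, 40 digenic or trigenic with secondary genes at uniform positions
  on chromosomes 2 and/or 4;
* hotspot B - chromosome 3 at 50 cM, 300 monogenic traits, 150 with
  h2 ~ U(0.1, 0.45) and 150 with h2 ~ U(0.3, 0.45);
* hotspot C - chromosome 5 at 50 cM, 200 monogenic traits, h2 ~ U(0.1, 0.2).

Each trait is sum(effect * genotype) + normal noise.  The primary-gene effect
is +1 for every trait (shared direction, so pleiotropic traits correlate
positively on average), secondary effects 0.5-1 times that with random signs;
the
residual SD is solved so the generating model's heritability (genetic variance
over total, with backcross genotype variance 1/4 per locus and linkage
covariances lambda/4) equals the drawn target exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genome import BinGrid, GeneticMap, haldane_r, linkage_lambda
from .mapping import CrossData, QTLInterval, QTLSet

__all__ = [
    "HotspotDesign",
    "SummarizedQTLSpec",
    "simulate_backcross",
    "simulate_reference_design",
    "simulate_null",
    "simulate_null_qtlset",
    "simulate_summarized",
    "genetic_variance",
    "default_design",
]


def _as_rng(seed):
    return seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)


def simulate_backcross(genetic_map: GeneticMap, n: int, seed,
                       extra_loci: dict[str, np.ndarray] | None = None):
    """Backcross genotypes at the mapped markers (0/1 coding).

    Per chromosome the genotype sequence is a Markov chain: the first locus is
    Bernoulli(1/2) and successive loci switch with probability r(d) under
    Haldane; chromosomes and individuals are independent.  ``extra_loci`` maps a
    chromosome name to additional positions (e.g. true gene locations) simulated
    jointly with the markers; their genotypes are returned separately as a dict
    keyed by (chromosome, position).

    Returns ``(genotypes, extras)`` with genotypes n x M int8.
    """
    if n < 1:
        raise ValueError("need at least one individual")
    rng = _as_rng(seed)
    extra_loci = extra_loci or {}
    marker_cols, extras = [], {}
    for chrom in genetic_map.chromosomes:
        extra = np.asarray(extra_loci.get(chrom.name, ()), dtype=float)
        pos = np.unique(np.concatenate([chrom.positions, extra]))
        G = np.empty((n, pos.size), dtype=np.int8)
        G[:, 0] = rng.integers(0, 2, size=n)
        for j in range(1, pos.size):
            r = haldane_r(pos[j] - pos[j - 1])
            switch = rng.random(n) < r
            G[:, j] = G[:, j - 1] ^ switch
        is_marker = np.isin(pos, chrom.positions)
        # map each marker to its simulated column (duplicates share a column)
        col_of = np.searchsorted(pos, chrom.positions)
        marker_cols.append(G[:, col_of])
        for p in extra:
            extras[(chrom.name, float(p))] = G[:, int(np.searchsorted(pos, p))].copy()
        del is_marker
    return np.concatenate(marker_cols, axis=1), extras


def genetic_variance(loci: list[tuple[str, float]], effects: np.ndarray) -> float:
    """Model genetic variance of sum(a_j x_j): var x = 1/4, cov = lambda/4 within
    a chromosome, 0 across chromosomes."""
    effects = np.asarray(effects, dtype=float)
    k = len(loci)
    V = np.zeros((k, k))
    for i in range(k):
        for j in range(k):
            if loci[i][0] == loci[j][0]:
                V[i, j] = linkage_lambda(abs(loci[i][1] - loci[j][1])) / 4.0
    return float(effects @ V @ effects)


@dataclass(frozen=True)
class HotspotDesign:
    """One simulated pleiotropic hotspot: a gene shared by many traits."""

    name: str
    chromosome: str
    position: float
    n_traits: int
    h2_range: tuple[float, float]
    n_multigenic: int = 0
    secondary_chromosomes: tuple[str, ...] = ()

    def __post_init__(self):
        lo, hi = self.h2_range
        if not 0.0 < lo <= hi < 1.0:
            raise ValueError("heritability range must lie inside (0, 1)")
        if self.n_multigenic > self.n_traits:
            raise ValueError("more multigenic traits than traits")


def default_design() -> list[HotspotDesign]:
    """The three-hotspot study design (hotspot B split by its two h2 ranges)."""
    return [
        HotspotDesign("A", "1", 50.0, 100, (0.30, 0.45),
                      n_multigenic=40, secondary_chromosomes=("2", "4")),
        HotspotDesign("B", "3", 50.0, 150, (0.10, 0.45)),
        HotspotDesign("B", "3", 50.0, 150, (0.30, 0.45)),
        HotspotDesign("C", "5", 50.0, 200, (0.10, 0.20)),
    ]


def simulate_reference_design(seed, n: int = 100,
                          design: list[HotspotDesign] | None = None,
                          genetic_map: GeneticMap | None = None,
                          secondary_effect_range: tuple[float, float] = (0.5, 1.0)):
    """The three-hotspot genetical-genomics data set.

    Returns ``(cross, truth)`` where ``truth`` is a frame with one row per
    generated gene effect (trait, hotspot, chromosome, position, effect, h2).
    """
    rng = _as_rng(seed)
    if design is None:
        design = default_design()
    if genetic_map is None:
        genetic_map = GeneticMap.equally_spaced(5, 100.0, 50)
    # 1) trait structure (loci, effects, target h2), consuming the stream first
    traits = []   # (name, hotspot, loci [(chrom,pos)], effects, h2)
    counters: dict[str, int] = {}
    for spec in design:
        for _ in range(spec.n_traits):
            counters[spec.name] = counters.get(spec.name, 0) + 1
            tname = f"{spec.name}{counters[spec.name]:03d}"
            loci = [(spec.chromosome, spec.position)]
            # primary effects share a direction, giving the positive-mean
            # pairwise trait correlations of hotspot-driven molecular traits;
            # secondary-gene signs stay random
            effects = [1.0]
            h2 = float(rng.uniform(*spec.h2_range))
            traits.append([tname, spec.name, loci, effects, h2])
    # multigenic traits: the first n_multigenic of each spec get secondary genes
    idx = 0
    for spec in design:
        for j in range(spec.n_traits):
            if j < spec.n_multigenic:
                chroms = (list(spec.secondary_chromosomes)
                          if rng.random() < 0.5 and len(spec.secondary_chromosomes) > 1
                          else [spec.secondary_chromosomes[
                              int(rng.integers(len(spec.secondary_chromosomes)))]])
                for ch in chroms:  # digenic (one extra) or trigenic (one per chrom)
                    pos = float(rng.uniform(0.0, genetic_map.chromosome(ch).length))
                    mag = float(rng.uniform(*secondary_effect_range))
                    sign = 1.0 if rng.random() < 0.5 else -1.0
                    traits[idx + j][2].append((ch, pos))
                    traits[idx + j][3].append(mag * sign)
        idx += spec.n_traits
    # 2) genotypes at markers plus every true gene position
    extra: dict[str, list[float]] = {}
    for _, _, loci, _, _ in traits:
        for ch, p in loci:
            extra.setdefault(ch, []).append(p)
    extra_arr = {ch: np.unique(np.array(v)) for ch, v in extra.items()}
    G, gene_geno = simulate_backcross(genetic_map, n, rng, extra_loci=extra_arr)
    # 3) phenotypes: scaled genetic values plus noise at the target heritability
    Y = np.empty((n, len(traits)))
    rows = []
    for t, (tname, hname, loci, effects, h2) in enumerate(traits):
        a = np.asarray(effects)
        g = sum(ai * gene_geno[(ch, float(p))] for ai, (ch, p) in zip(a, loci))
        var_g = genetic_variance(loci, a)
        sd_e = np.sqrt(var_g * (1.0 - h2) / h2) if h2 > 0 else 1.0
        Y[:, t] = (g if h2 > 0 else 0.0) + rng.normal(0.0, sd_e, size=n)
        for ai, (ch, p) in zip(a, loci):
            rows.append((tname, hname, ch, p, float(ai), h2))
    truth = pd.DataFrame(rows, columns=["trait", "hotspot", "chromosome",
                                        "position_cM", "effect", "h2"])
    cross = CrossData(genotypes=G, phenotypes=Y, genetic_map=genetic_map,
                      trait_names=[t[0] for t in traits])
    return cross, truth


def simulate_null(genetic_map: GeneticMap, n: int, T: int, seed,
                  mode: str = "noise", h2_range: tuple[float, float] = (0.1, 0.45)):
    """Null cross data: pure-noise traits or monogenic traits at uniform positions.

    ``mode="noise"`` gives standard-normal traits (h2 = 0); ``mode="monogenic"``
    gives each trait one gene at a uniformly random genome position (chromosome
    chosen proportionally to length, no pleiotropy) with h2 ~ U(h2_range).
    Returns ``(cross, truth)``; truth is empty in noise mode.
    """
    rng = _as_rng(seed)
    if mode == "noise":
        G, _ = simulate_backcross(genetic_map, n, rng)
        Y = rng.normal(size=(n, T))
        return (CrossData(genotypes=G, phenotypes=Y, genetic_map=genetic_map),
                pd.DataFrame(columns=["trait", "chromosome", "position_cM", "h2"]))
    if mode != "monogenic":
        raise ValueError("mode must be 'noise' or 'monogenic'")
    lengths = np.array([c.length for c in genetic_map.chromosomes])
    chrom_idx = rng.choice(len(lengths), size=T, p=lengths / lengths.sum())
    pos = rng.uniform(0.0, lengths[chrom_idx])
    h2 = rng.uniform(*h2_range, size=T)
    signs = np.where(rng.random(T) < 0.5, 1.0, -1.0)
    extra: dict[str, list[float]] = {}
    for ci, p in zip(chrom_idx, pos):
        extra.setdefault(genetic_map.names[ci], []).append(float(p))
    G, gene_geno = simulate_backcross(
        genetic_map, n, rng, {ch: np.unique(v) for ch, v in extra.items()})
    Y = np.empty((n, T))
    rows = []
    for t in range(T):
        ch = genetic_map.names[chrom_idx[t]]
        g = signs[t] * gene_geno[(ch, float(pos[t]))]
        sd_e = np.sqrt((1.0 / 4.0) * (1.0 - h2[t]) / h2[t])
        Y[:, t] = g + rng.normal(0.0, sd_e, size=n)
        rows.append((f"t{t + 1}", ch, float(pos[t]), float(h2[t])))
    truth = pd.DataFrame(rows, columns=["trait", "chromosome", "position_cM", "h2"])
    return CrossData(genotypes=G, phenotypes=Y, genetic_map=genetic_map), truth


def simulate_null_qtlset(bins: BinGrid, T: int, seed,
                         sd_range: tuple[float, float] = (1.0, 3.0),
                         coverage_z: float = 1.96) -> QTLSet:
    """A summarized null QTL set: one QTL per trait at a uniform genome position.

    Peaks are uniform over the concatenated genome, peak SDs ~ U(sd_range), and
    intervals are peak +/- z * sd clipped to the chromosome, mimicking detected
    support intervals without pleiotropy.  Used for error-rate calibration of
    the permutation thresholds.
    """
    rng = _as_rng(seed)
    gmap = bins.genetic_map
    lengths = np.array([c.length for c in gmap.chromosomes])
    chrom_idx = rng.choice(len(lengths), size=T, p=lengths / lengths.sum())
    pos = rng.uniform(0.0, lengths[chrom_idx])
    sds = rng.uniform(*sd_range, size=T)
    qtls = []
    for t in range(T):
        ch = gmap.names[chrom_idx[t]]
        length = lengths[chrom_idx[t]]
        a = max(float(pos[t] - coverage_z * sds[t]), 0.0)
        b = min(float(pos[t] + coverage_z * sds[t]), float(length))
        qtls.append(QTLInterval(trait=f"t{t + 1}", chromosome=ch, peak=float(pos[t]),
                                start=a, end=b, sd=float(sds[t]), lod=3.0))
    return QTLSet(qtls=qtls, genetic_map=gmap)


# Rice-database-like interval-width classes: (low, high, probability); a (0, 0) class
# is a point mass (QTL localized exactly at a marker).  The printed width table
# covers 77.45% of QTL; the remainder is assigned to a wide 20-80 cM class.
_DEFAULT_WIDTH_CLASSES = (
    (0.0, 0.0, 0.0376),
    (0.0, 0.5, 0.4614),
    (0.5, 1.0, 0.0090),
    (1.0, 2.0, 0.0243),
    (2.0, 5.0, 0.0620),
    (5.0, 10.0, 0.0557),
    (10.0, 20.0, 0.1245),
    (20.0, 80.0, 0.2255),
)


@dataclass(frozen=True)
class SummarizedQTLSpec:
    """Generator spec for a database-style summarized QTL table."""

    genetic_map: GeneticMap
    n_traits: int = 236
    n_qtl: int = 1000
    width_classes: tuple[tuple[float, float, float], ...] = _DEFAULT_WIDTH_CLASSES
    hotspot_positions: tuple[tuple[str, float], ...] = ()
    clustering: float = 0.0        # probability a QTL is drawn at a hotspot
    cluster_sd: float = 0.25       # cM jitter of clustered QTL centres

    def __post_init__(self):
        probs = np.array([p for _, _, p in self.width_classes])
        if abs(probs.sum() - 1.0) > 1e-9:
            raise ValueError("width-class probabilities must sum to 1")
        if self.n_qtl < self.n_traits:
            raise ValueError("need at least one QTL per trait")
        if self.clustering > 0 and not self.hotspot_positions:
            raise ValueError("clustering requires hotspot positions")


def simulate_summarized(spec: SummarizedQTLSpec, seed) -> pd.DataFrame:
    """Summarized QTL table (trait, chromosome, start_cM, end_cM).

    Interval widths follow the class distribution (uniform within a class);
    centres are uniform over the genome, or placed at a random hotspot with
    probability ``clustering``.  The first ``n_traits`` QTL go to distinct
    traits so every trait has at least one QTL.
    """
    rng = _as_rng(seed)
    gmap = spec.genetic_map
    lengths = np.array([c.length for c in gmap.chromosomes])
    probs = np.array([p for _, _, p in spec.width_classes])
    classes = rng.choice(len(probs), size=spec.n_qtl, p=probs)
    widths = np.array([
        0.0 if spec.width_classes[c][1] == 0.0
        else rng.uniform(spec.width_classes[c][0], spec.width_classes[c][1])
        for c in classes])
    trait_ids = np.concatenate([
        np.arange(spec.n_traits),
        rng.integers(0, spec.n_traits, size=spec.n_qtl - spec.n_traits)])
    rows = []
    for i in range(spec.n_qtl):
        if spec.clustering > 0 and rng.random() < spec.clustering:
            ch, p = spec.hotspot_positions[int(rng.integers(len(spec.hotspot_positions)))]
            centre = p + rng.normal(0.0, spec.cluster_sd)
            ci = gmap.names.index(ch)
        else:
            ci = int(rng.choice(len(lengths), p=lengths / lengths.sum()))
            ch = gmap.names[ci]
            centre = float(rng.uniform(0.0, lengths[ci]))
        centre = min(max(centre, 0.0), float(lengths[ci]))
        a = max(centre - widths[i] / 2.0, 0.0)
        b = min(centre + widths[i] / 2.0, float(lengths[ci]))
        rows.append((f"trait{trait_ids[i] + 1}", ch, a, b))
    return pd.DataFrame(rows, columns=["trait", "chromosome", "start_cM", "end_cM"])
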