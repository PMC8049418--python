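"""Trait grouping, grouped circular permutations, gamma(n, alpha) thresholds and
top-gamma hotspot profiles.

Randomly placed QTL define the null for hotspot detection.  The test statistic
qFreq(n) is the n-th largest observed bin EQF sum; its null distribution is
estimated by permuting QTL positions over the genome, treated as a single circle
over the concatenated chromosomes.  Because tightly linked or pleiotropic QTL of
correlated traits co-localize, permuting every QTL independently (the Q-method)
underestimates the thresholds.  Empirical trait grouping therefore joins traits
whose detected QTL peaks share a bin; each shared-bin QTL cluster (a "trunk")
moves as one unit during permutation, while the remaining QTL move alone.  The
(1 - alpha) quantile of the permuted n-th order statistic is the threshold
gamma(n, alpha); the Q-method baseline beta (all QTL free, n = 1) closes the
ladder at k where beta = gamma(k, alpha).

For a ladder of LOD thresholds L1 < ... < Lm, each with its own architecture and
gamma ladder, a bin's top-gamma profile records at every Li the smallest n whose
threshold it clears.  Its trend classifies the hotspot: an increasing n pattern
(type i) marks a hotspot dominated by moderate-LOD QTL, a decreasing pattern
(type ii) one with relatively many strong-LOD QTL, and a flat pattern (type iii)
a balanced hotspot.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import ndtr
from scipy.stats import kendalltau

from .eqf import EQFArchitecture, EQFMatrix, build_eqf
from .genome import BinGrid
from .mapping import QTLSet

__all__ = [
    "TraitGroups",
    "GammaThresholds",
    "HotspotReport",
    "TopGammaProfile",
    "group_traits",
    "permute_eqf_bins",
    "permute_qtl_intervals",
    "gamma_thresholds",
    "call_hotspots",
    "top_gamma_profile",
]


@dataclass
class TraitGroups:
    """Connected components of the trait-bin co-localization graph.

    ``trunks`` maps a (grouping-grid) bin index to the QTL indices whose peaks
    share it (at least two QTL from at least two traits); ``free`` lists the
    remaining QTL.  ``group_of_trait`` labels every trait with its component.
    """

    n_qtl: int
    trunks: dict[int, np.ndarray]
    free: np.ndarray
    group_of_trait: dict[str, int]
    grouping_bin_size: float

    @property
    def R(self) -> int:
        """Number of trait groups."""
        return len(set(self.group_of_trait.values()))

    def group_sizes(self) -> np.ndarray:
        sizes: dict[int, int] = {}
        for g in self.group_of_trait.values():
            sizes[g] = sizes.get(g, 0) + 1
        return np.array(sorted(sizes.values(), reverse=True))

    def units(self) -> list[np.ndarray]:
        """Permutation units: one per trunk, one per free QTL (deterministic order)."""
        out = [np.asarray(idx, dtype=int) for _, idx in sorted(self.trunks.items())]
        out.extend(np.array([i]) for i in self.free)
        return out

    @classmethod
    def all_free(cls, n_qtl: int, traits) -> "TraitGroups":
        """The no-grouping (Q-method) structure: every QTL is its own unit."""
        return cls(n_qtl=n_qtl, trunks={}, free=np.arange(n_qtl),
                   group_of_trait={t: i for i, t in enumerate(dict.fromkeys(traits))},
                   grouping_bin_size=float("nan"))


class _UnionFind:
    def __init__(self, items):
        self.parent = {x: x for x in items}

    def find(self, x):
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def union(self, a, b):
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.parent[ra] = rb


def group_traits(qtls: QTLSet, bins: BinGrid,
                 grouping_bins: BinGrid | None = None) -> TraitGroups:
    """Empirical trait grouping from shared QTL peak bins.

    QTL whose peaks fall in the same bin are taken as tightly linked and/or
    pleiotropic; their traits join the same group (transitively), and the
    shared-bin QTL form a trunk that permutes as one unit.  A bin holding QTL of
    a single trait only is dissolved: those QTL stay free.  ``grouping_bins``
    lets the grouping grid differ from the EQF grid (default: same grid).
    """
    grid = grouping_bins if grouping_bins is not None else bins
    traits = [q.trait for q in qtls.qtls]
    peak_bin = np.array([grid.position_to_bin(q.chromosome, q.peak) for q in qtls.qtls],
                        dtype=int) if len(qtls.qtls) else np.empty(0, dtype=int)
    by_bin: dict[int, list[int]] = {}
    for i, w in enumerate(peak_bin):
        by_bin.setdefault(int(w), []).append(i)
    uf = _UnionFind(dict.fromkeys(traits))
    trunks: dict[int, np.ndarray] = {}
    in_trunk = np.zeros(len(traits), dtype=bool)
    for w, members in by_bin.items():
        member_traits = {traits[i] for i in members}
        if len(members) >= 2 and len(member_traits) >= 2:
            trunks[w] = np.array(members, dtype=int)
            in_trunk[members] = True
            first = traits[members[0]]
            for i in members[1:]:
                uf.union(first, traits[i])
    roots = {t: uf.find(t) for t in uf.parent}
    labels = {r: g for g, r in enumerate(dict.fromkeys(roots.values()))}
    return TraitGroups(
        n_qtl=len(traits), trunks=trunks, free=np.flatnonzero(~in_trunk),
        group_of_trait={t: labels[r] for t, r in roots.items()},
        grouping_bin_size=grid.bin_size)


# ---------------------------------------------------------------------------
# Permutation schemes
# ---------------------------------------------------------------------------

def permute_eqf_bins(F: EQFMatrix, groups: TraitGroups, rng) -> EQFMatrix:
    """EQF-bin permutation: circular whole-bin shifts of each unit's masses.

    Every unit (trunk or free QTL) receives one uniform random offset over the W
    bins of the concatenated circular genome; the per-QTL bin-mass vectors shift
    jointly within a unit, so relative positions, interval widths and per-trait
    row sums are conserved exactly.
    """
    W = F.bins.W
    new_bins = [b.copy() for b in F.qtl_bins]
    for unit in groups.units():
        off = int(rng.integers(W))
        for i in unit:
            new_bins[i] = (F.qtl_bins[i] + off) % W
    return EQFMatrix(bins=F.bins, traits=F.traits, qtl_set=F.qtl_set, model=F.model,
                     qtl_trait_index=F.qtl_trait_index, qtl_bins=new_bins,
                     qtl_masses=[m.copy() for m in F.qtl_masses],
                     threshold=F.threshold)


def _global_bin_edges(bins: BinGrid) -> np.ndarray:
    """Start coordinate of every bin on the concatenated genome, plus its end."""
    edges = []
    for ci, chrom in enumerate(bins.genetic_map.chromosomes):
        n = bins.n_bins_per_chrom[ci]
        edges.append(bins.cm_offsets[ci] + np.arange(n) * bins.bin_size)
    edges.append([bins.genome_length])
    return np.concatenate(edges)


def _shifted_interval_masses(start: float, width: float, cdf, edges: np.ndarray,
                             W: int, G: float):
    """Bin masses of a QTL whose interval now occupies [start, start+width) on the
    circle; ``cdf(t)`` is the within-interval position CDF at offset t from the
    interval start."""
    pieces = [(start % G, min(start % G + width, G), 0.0)]
    over = (start % G) + width - G
    if over > 1e-12:
        pieces.append((0.0, over, G - (start % G)))
    idx_all, mass_all = [], []
    for lo, hi, local0 in pieces:
        w0 = int(np.searchsorted(edges, lo, side="right") - 1)
        w1 = int(np.searchsorted(edges, hi - 1e-12, side="right") - 1)
        w1 = min(w1, W - 1)
        for w in range(w0, w1 + 1):
            x1, x2 = max(edges[w], lo), min(edges[w + 1], hi)
            if x2 <= x1:
                continue
            m = cdf(local0 + (x2 - lo)) - cdf(local0 + (x1 - lo))
            if m > 0:
                idx_all.append(w)
                mass_all.append(m)
    return np.array(idx_all, dtype=int), np.array(mass_all)


def permute_qtl_intervals(qtls: QTLSet, groups: TraitGroups, bins: BinGrid,
                          rng, model: str = "normal") -> EQFMatrix:
    """QTL-interval permutation: continuous circular shifts of the intervals.

    Each unit receives one uniform offset in [0, G) cM on the concatenated
    circular genome; intervals keep their widths and internal density shape
    (truncated normal or uniform), wrap across chromosome joins and the genome
    end, and their bin masses are recomputed at the new location.  Returns the
    permuted EQF matrix.
    """
    G = bins.genome_length
    base = build_eqf(qtls, bins, model=model)  # validates inputs, fixes trait order
    edges = _global_bin_edges(bins)
    starts, widths, cdfs = [], [], []
    for q in qtls.qtls:
        ci = bins.chrom_index(q.chromosome)
        length = bins.genetic_map.chromosomes[ci].length
        if q.end - q.start > G:
            raise ValueError("QTL interval longer than the genome")
        a, b = max(q.start, 0.0), min(q.end, length)
        width = b - a
        starts.append(bins.to_concat_cm(q.chromosome, a))
        widths.append(width)
        if width <= 1e-12:
            cdfs.append(lambda t: 1.0 if t > 0 else 0.0)
        elif model == "uniform":
            cdfs.append(lambda t, w=width: min(max(t / w, 0.0), 1.0))
        else:
            z0 = ndtr((a - q.peak) / q.sd)
            z1 = ndtr((b - q.peak) / q.sd)
            cdfs.append(lambda t, a=a, p=q.peak, s=q.sd, z0=z0, z=(z1 - z0):
                        float(np.clip((ndtr((a + t - p) / s) - z0) / z, 0.0, 1.0)))
    new_bins, new_masses = list(base.qtl_bins), list(base.qtl_masses)
    for unit in groups.units():
        off = float(rng.uniform(0.0, G))
        for i in unit:
            if widths[i] <= 1e-12:  # point QTL: lands wholly in one bin
                x = (starts[i] + off) % G
                w = int(np.searchsorted(edges, x, side="right") - 1)
                new_bins[i] = np.array([min(w, bins.W - 1)])
                new_masses[i] = np.array([1.0])
            else:
                idx, m = _shifted_interval_masses(starts[i] + off, widths[i],
                                                  cdfs[i], edges, bins.W, G)
                total = m.sum()
                new_bins[i], new_masses[i] = idx, m / total
    return EQFMatrix(bins=bins, traits=base.traits, qtl_set=qtls, model=model,
                     qtl_trait_index=base.qtl_trait_index, qtl_bins=new_bins,
                     qtl_masses=new_masses, threshold=qtls.threshold)


# ---------------------------------------------------------------------------
# Thresholds
# ---------------------------------------------------------------------------

def _upper_quantile(samples: np.ndarray, alpha: float) -> np.ndarray:
    """Empirical upper (1 - alpha) quantile: order statistic ceil((1 - alpha) B)."""
    B = samples.shape[0]
    k = min(max(int(np.ceil((1.0 - alpha) * B)), 1), B)
    return np.sort(samples, axis=0)[k - 1]


@dataclass
class GammaThresholds:
    """The gamma(n, alpha) ladder for one EQF architecture, with Q-method beta.

    ``gammas[n-1]`` is the threshold for the statistic qFreq(n); the ladder is
    non-increasing in n because all thresholds come from the same permutation
    samples.  ``beta`` is the no-grouping genome-wide maximum threshold and
    ``k`` the largest n with gamma(n) >= beta (the useful ladder depth).
    """

    alpha: float
    B: int
    scheme: str
    gammas: np.ndarray
    beta: float
    k: int
    lod_threshold: float | None = None
    seed: int | None = None
    samples: np.ndarray | None = field(default=None, repr=False)

    def gamma(self, n: int) -> float:
        if not 1 <= n <= len(self.gammas):
            raise ValueError(f"n must lie in [1, {len(self.gammas)}]")
        return float(self.gammas[n - 1])

    def to_dict(self) -> dict:
        n_keep = max(self.k, 1)
        return {
            "alpha": self.alpha, "B": self.B, "scheme": self.scheme,
            "lod_threshold": self.lod_threshold, "seed": self.seed,
            "beta": self.beta, "k": self.k,
            "gamma": [[n + 1, float(g)] for n, g in enumerate(self.gammas[:n_keep])],
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)


def _permuted_order_stats(F: EQFMatrix, units: list[np.ndarray], B: int, rng,
                          scheme: str, qtls: QTLSet | None, groups, n_store: int):
    """B x n_store matrix of descending order statistics of permuted architectures."""
    W = F.bins.W
    unit_of_entry = np.empty(0, dtype=int)
    ent_bins_parts, ent_mass_parts, unit_parts = [], [], []
    for u, unit in enumerate(units):
        for i in unit:
            ent_bins_parts.append(F.qtl_bins[i])
            ent_mass_parts.append(F.qtl_masses[i])
            unit_parts.append(np.full(len(F.qtl_bins[i]), u))
    ent_bins = np.concatenate(ent_bins_parts) if ent_bins_parts else np.empty(0, dtype=int)
    ent_mass = np.concatenate(ent_mass_parts) if ent_mass_parts else np.empty(0)
    unit_of_entry = np.concatenate(unit_parts).astype(int) if unit_parts else unit_of_entry
    out = np.zeros((B, n_store))
    for b in range(B):
        if scheme == "eqf-bin":
            offsets = rng.integers(0, W, size=len(units))
            shifted = (ent_bins + offsets[unit_of_entry]) % W
            Fw = np.bincount(shifted, weights=ent_mass, minlength=W)
        elif scheme == "qtl-interval":
            Fperm = permute_qtl_intervals(qtls, groups, F.bins, rng, model=F.model)
            Fw = Fperm.architecture().Fw
        else:
            raise ValueError(f"unknown permutation scheme {scheme!r}")
        out[b] = np.sort(Fw)[::-1][:n_store]
    return out


def gamma_thresholds(F: EQFMatrix, groups: TraitGroups, B: int = 1000,
                     alpha: float = 0.05, seed=None, scheme: str = "eqf-bin",
                     n_store: int | None = None,
                     keep_samples: bool = True) -> GammaThresholds:
    """Compute the gamma(n, alpha) ladder by grouped circular permutation.

    For b = 1..B the units (trunks and free QTL) are shifted around the circular
    genome, the permuted architecture's descending order statistics F*(1) >=
    F*(2) >= ... are recorded in one pass, and gamma(n, alpha) is the empirical
    upper (1 - alpha) quantile of the F*(n) samples.  beta re-runs the same
    machinery with every QTL free (the Q-method) and takes the quantile of the
    genome-wide maximum; k is the largest n with gamma(n) >= beta.
    """
    if B < 100:
        warnings.warn(f"B={B} permutations give unstable threshold quantiles")
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must lie in (0, 1)")
    rng = np.random.default_rng(seed)
    W = F.bins.W
    n_store = W if n_store is None else min(n_store, W)
    samples = _permuted_order_stats(F, groups.units(), B, rng, scheme,
                                    F.qtl_set, groups, n_store)
    gammas = _upper_quantile(samples, alpha)
    free = TraitGroups.all_free(F.n_qtl, F.traits)
    beta_samples = _permuted_order_stats(F, free.units(), B, rng, scheme,
                                         F.qtl_set, free, 1)
    beta = float(_upper_quantile(beta_samples, alpha)[0])
    above = np.flatnonzero(gammas >= beta)
    k = int(above[-1] + 1) if above.size else 0
    return GammaThresholds(alpha=alpha, B=B, scheme=scheme, gammas=gammas,
                           beta=beta, k=k, lod_threshold=F.threshold,
                           seed=seed if isinstance(seed, (int, np.integer)) else None,
                           samples=samples if keep_samples else None)


# ---------------------------------------------------------------------------
# Hotspot calls and profiles
# ---------------------------------------------------------------------------

@dataclass
class HotspotReport:
    """Bins exceeding gamma(n, alpha), sorted by EQF descending."""

    n: int
    gamma: float
    table: pd.DataFrame   # chromosome, bin_start, bin_end, bin, Fw[, n_traits]

    @property
    def n_called(self) -> int:
        return len(self.table)

    @property
    def bins(self) -> np.ndarray:
        return self.table["bin"].to_numpy()

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False, float_format="%.6g")


def call_hotspots(arch: EQFArchitecture, thresholds: GammaThresholds, n: int = 1,
                  eqf: EQFMatrix | None = None, ge: bool = False) -> HotspotReport:
    """Bins whose EQF sum exceeds gamma(n, alpha) (strictly, unless ``ge``).

    ``n`` must not exceed the ladder depth k: beyond k the threshold is more
    liberal than the Q-method baseline beta and the ladder is not meaningful.
    """
    if n > thresholds.k:
        raise ValueError(
            f"n={n} exceeds the ladder depth k={thresholds.k}; beyond k the "
            f"Q-method baseline beta={thresholds.beta:.4g} applies")
    g = thresholds.gamma(n)
    hit = arch.Fw >= g if ge else arch.Fw > g
    idx = np.flatnonzero(hit)
    idx = idx[np.argsort(arch.Fw[idx])[::-1]]
    rows = []
    for w in idx:
        chrom, lo, hi = arch.bins.bin_to_interval(int(w))
        row = {"chromosome": chrom, "bin_start": lo, "bin_end": hi,
               "bin": int(w), "Fw": float(arch.Fw[w])}
        if eqf is not None:
            row["n_traits"] = eqf.contributing_traits(int(w))
        rows.append(row)
    cols = ["chromosome", "bin_start", "bin_end", "bin", "Fw"] + (
        ["n_traits"] if eqf is not None else [])
    return HotspotReport(n=n, gamma=g, table=pd.DataFrame(rows, columns=cols))


@dataclass
class TopGammaProfile:
    """The top-gamma indices of one bin across the LOD-threshold ladder.

    ``entries`` holds (Li, Fw(Li), n(Li) or None) where n(Li) is the smallest n
    with gamma(n, alpha)(Li) <= Fw(Li) within the ladder depth k, and None marks
    "not significant".  ``trend`` is increasing/decreasing/flat and
    ``hotspot_type`` the corresponding label i/ii/iii (or "none" if the bin is
    nowhere significant).
    """

    bin: int
    chromosome: str
    bin_start: float
    bin_end: float
    entries: list[tuple[float, float, int | None]]
    trend: str
    hotspot_type: str

    @property
    def n_values(self) -> list[int | None]:
        return [e[2] for e in self.entries]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(self.bin, self.chromosome, L, F, "ns" if n is None else n,
              self.trend, self.hotspot_type) for L, F, n in self.entries],
            columns=["bin", "chromosome", "lod_threshold", "Fw", "top_n",
                     "trend", "type"])


def _classify_trend(lods, ns, tau_cut: float = 0.5, min_range: int = 1) -> str:
    """Kendall-tau trend of the top-n sequence over the LOD ladder."""
    ns = np.asarray(ns, dtype=float)
    if len(ns) < 2 or np.all(ns == ns[0]):
        return "flat"
    tau = kendalltau(lods, ns).statistic
    spread = ns.max() - ns.min()
    if np.isnan(tau) or spread < min_range:
        return "flat"
    if tau >= tau_cut:
        return "increasing"
    if tau <= -tau_cut:
        return "decreasing"
    return "flat"


_TYPE_OF_TREND = {"increasing": "i", "decreasing": "ii", "flat": "iii"}


def top_gamma_profile(w: int, ladder: list[tuple[float, EQFArchitecture, GammaThresholds]],
                      tau_cut: float = 0.5, min_range: int = 1) -> TopGammaProfile:
    """Profile bin ``w`` across LOD thresholds: n(Li) = min{n : gamma(n) <= Fw}.

    A "ns" (not significant) entry is treated as n = k + 1 of its own ladder
    when computing the trend, so a hotspot fading out of significance at strict
    LOD thresholds still reads as an increasing-n (type i) pattern.
    """
    entries, trend_ns, lods = [], [], []
    chrom, lo, hi = ladder[0][1].bins.bin_to_interval(int(w))
    for L, arch, thr in ladder:
        Fw = float(arch.Fw[w])
        kk = max(thr.k, 1)
        ok = np.flatnonzero(thr.gammas[:kk] <= Fw)
        n = int(ok[0] + 1) if ok.size else None
        entries.append((L, Fw, n))
        trend_ns.append(kk + 1 if n is None else n)
        lods.append(L)
    if all(n is None for _, _, n in entries):
        trend, htype = "flat", "none"
    else:
        trend = _classify_trend(lods, trend_ns, tau_cut=tau_cut, min_range=min_range)
        htype = _TYPE_OF_TREND[trend]
    return TopGammaProfile(bin=int(w), chromosome=chrom, bin_start=lo, bin_end=hi,
                           entries=entries, trend=trend, hotspot_type=htype)
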