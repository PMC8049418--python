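"""Expected QTL frequency (EQF) matrices and genome architectures.

Each detected QTL is represented by a probability distribution for its position
over its own support interval [a, b]: a normal density centred at the LOD peak
with the peak SD, truncated to [a, b] and re-normalized (individual-level data),
or a uniform density on [a, b] (database intervals, where only flanking markers
are known).  The mass falling in each genome bin is the QTL's EQF contribution;
the fractions over the bins of one QTL sum to one.  Summing over a trait's QTL
gives its row of the EQF matrix F = [f_tw] (T x W), and the column sums
F_w = sum_t f_tw form the EQF architecture of the genome, whose peaks are the
candidate hotspots.

A point interval (b == a, a QTL localized exactly at a marker) places mass 1 in
the containing bin under either model.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import norm

from .genome import BinGrid
from .mapping import LODMatrix, QTLInterval, QTLSet, detect_qtl

__all__ = [
    "eqf_from_interval",
    "build_eqf",
    "multi_threshold_eqf",
    "EQFMatrix",
    "EQFArchitecture",
    "mean_eqf_threshold",
]


def _bin_edges(bins: BinGrid, chrom_index: int) -> np.ndarray:
    n = bins.n_bins_per_chrom[chrom_index]
    length = bins.genetic_map.chromosomes[chrom_index].length
    edges = np.arange(n + 1, dtype=float) * bins.bin_size
    edges[-1] = min(edges[-1], length)
    return edges


def _interval_masses(a: float, b: float, peak: float | None, sd: float | None,
                     edges: np.ndarray, model: str) -> np.ndarray:
    """Mass of the QTL position distribution in each cell of ``edges`` over [a, b]."""
    lo = np.maximum(edges[:-1], a)
    hi = np.minimum(edges[1:], b)
    if model == "uniform":
        masses = np.clip(hi - lo, 0.0, None) / (b - a)
    elif model == "normal":
        if sd is None or sd <= 0:
            raise ValueError("normal model requires a positive peak SD")
        if peak is None:
            raise ValueError("normal model requires a peak position")
        total = norm.cdf(b, peak, sd) - norm.cdf(a, peak, sd)
        if total <= 0:  # peak numerically outside [a, b]: degenerate, use uniform
            masses = np.clip(hi - lo, 0.0, None) / (b - a)
        else:
            masses = np.clip(
                norm.cdf(hi, peak, sd) - norm.cdf(np.minimum(lo, hi), peak, sd),
                0.0, None) / total
    else:
        raise ValueError(f"unknown interval model {model!r}")
    return masses


def eqf_from_interval(q: QTLInterval, bins: BinGrid, model: str = "normal"):
    """Per-bin EQF masses of one QTL: ``(global_bin_indices, masses)``.

    The interval is clipped to the chromosome and the masses re-normalized so the
    QTL contributes exactly 1 across its bins.
    """
    ci = bins.chrom_index(q.chromosome)
    length = bins.genetic_map.chromosomes[ci].length
    a = max(q.start, 0.0)
    b = min(q.end, length)
    if b < a:
        raise ValueError(f"QTL of trait {q.trait}: interval end below start")
    if b - a <= 1e-12:  # localized at a point (e.g. at a marker)
        return np.array([bins.position_to_bin(q.chromosome, a)]), np.array([1.0])
    edges = _bin_edges(bins, ci)
    masses = _interval_masses(a, b, q.peak, q.sd, edges, model)
    total = masses.sum()
    if total <= 0:
        raise ValueError(f"QTL of trait {q.trait}: no mass assigned")
    masses = masses / total
    keep = masses > 0
    idx = np.flatnonzero(keep) + bins.offsets[ci]
    return idx, masses[keep]


@dataclass
class EQFArchitecture:
    """Column sums F_w of an EQF matrix, with their descending order statistics."""

    bins: BinGrid
    Fw: np.ndarray

    @property
    def ordered(self) -> np.ndarray:
        return np.sort(self.Fw)[::-1]

    def qfreq(self, n: int) -> float:
        """The n-th largest observed bin EQF sum (the hotspot test statistic)."""
        if not 1 <= n <= self.bins.W:
            raise ValueError(f"n must lie in [1, {self.bins.W}]")
        return float(self.ordered[n - 1])

    @property
    def total(self) -> float:
        return float(self.Fw.sum())

    def to_frame(self) -> pd.DataFrame:
        df = self.bins.bin_table()
        df["Fw"] = self.Fw
        return df

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False, float_format="%.6g")


@dataclass
class EQFMatrix:
    """The T x W EQF matrix with per-QTL bin-mass bookkeeping.

    ``qtl_bins[i]`` / ``qtl_masses[i]`` hold the sparse bin masses of QTL ``i``
    (in ``qtl_set`` order); the permutation schemes shift these per-QTL vectors,
    so the bookkeeping must be retained alongside the dense matrix.
    """

    bins: BinGrid
    traits: list[str]
    qtl_set: QTLSet
    model: str
    qtl_trait_index: np.ndarray = field(repr=False)   # QTL -> row of F
    qtl_bins: list[np.ndarray] = field(repr=False)
    qtl_masses: list[np.ndarray] = field(repr=False)
    threshold: float | None = None

    @property
    def n_qtl(self) -> int:
        return len(self.qtl_bins)

    @property
    def F(self) -> np.ndarray:
        F = np.zeros((len(self.traits), self.bins.W))
        for t, idx, m in zip(self.qtl_trait_index, self.qtl_bins, self.qtl_masses):
            F[t, idx] += m
        return F

    def architecture(self) -> EQFArchitecture:
        Fw = np.zeros(self.bins.W)
        for idx, m in zip(self.qtl_bins, self.qtl_masses):
            Fw[idx] += m
        return EQFArchitecture(bins=self.bins, Fw=Fw)

    def peak_bins(self) -> np.ndarray:
        """Global bin index of each QTL's peak (its point location for grouping)."""
        return np.array([self.bins.position_to_bin(q.chromosome, q.peak)
                         for q in self.qtl_set.qtls], dtype=int)

    def contributing_traits(self, w: int) -> int:
        """Number of distinct traits with positive EQF mass in bin ``w``."""
        seen = set()
        for t, idx in zip(self.qtl_trait_index, self.qtl_bins):
            if w in idx:
                seen.add(t)
        return len(seen)

    def to_triplet_frame(self) -> pd.DataFrame:
        rows = []
        for t, idx, m in zip(self.qtl_trait_index, self.qtl_bins, self.qtl_masses):
            for w, v in zip(idx, m):
                rows.append((self.traits[t], int(w), v))
        df = pd.DataFrame(rows, columns=["trait", "bin", "eqf"])
        return df.groupby(["trait", "bin"], as_index=False)["eqf"].sum()


def build_eqf(qtls: QTLSet, bins: BinGrid, model: str = "normal",
              trait_names: list[str] | None = None) -> EQFMatrix:
    """Assemble the EQF matrix (and bookkeeping) from a set of detected QTL.

    ``model`` is "normal" (truncated normal over each support interval) or
    "uniform" (database intervals).  Traits appear in ``trait_names`` order when
    given, else in order of first appearance.
    """
    if bins.W < 1:
        raise ValueError("empty bin grid")
    if trait_names is None:
        trait_names = list(dict.fromkeys(q.trait for q in qtls.qtls))
    t_index = {t: i for i, t in enumerate(trait_names)}
    qtl_trait_index, qtl_bins, qtl_masses = [], [], []
    for q in qtls.qtls:
        if q.chromosome not in bins.genetic_map.names:
            raise ValueError(f"QTL of trait {q.trait} on unknown chromosome {q.chromosome!r}")
        if q.trait not in t_index:
            t_index[q.trait] = len(trait_names)
            trait_names.append(q.trait)
        idx, m = eqf_from_interval(q, bins, model)
        qtl_trait_index.append(t_index[q.trait])
        qtl_bins.append(idx)
        qtl_masses.append(m)
    return EQFMatrix(bins=bins, traits=list(trait_names), qtl_set=qtls, model=model,
                     qtl_trait_index=np.array(qtl_trait_index, dtype=int),
                     qtl_bins=qtl_bins, qtl_masses=qtl_masses,
                     threshold=qtls.threshold)


def multi_threshold_eqf(lod: LODMatrix, thresholds, bins: BinGrid,
                        drop: float = 1.5, model: str = "normal",
                        point_mass: bool = False):
    """One (QTLSet, EQFMatrix, EQFArchitecture) triple per LOD threshold.

    Thresholds must be strictly increasing; QTL counts are then non-increasing
    along the ladder.  With ``point_mass`` each detected QTL contributes mass 1
    to the bin containing its peak (the representation used when comparing
    count-based methods on a common footing).
    """
    thresholds = list(thresholds)
    if any(b <= a for a, b in zip(thresholds, thresholds[1:])):
        raise ValueError("LOD thresholds must be strictly increasing")
    out = []
    for L in thresholds:
        qset = detect_qtl(lod, L, drop=drop)
        if point_mass:
            qset = QTLSet(qtls=[QTLInterval(trait=q.trait, chromosome=q.chromosome,
                                            peak=q.peak, start=q.peak, end=q.peak,
                                            sd=q.sd, lod=q.lod) for q in qset.qtls],
                          threshold=qset.threshold)
        emat = build_eqf(qset, bins, model=model, trait_names=list(lod.traits))
        out.append((qset, emat, emat.architecture()))
    return out


def mean_eqf_threshold(qtl_density_per_cm: float, bin_size: float,
                       factor: float = 5.0) -> float:
    """The empirical 'five times the average EQF per bin' hotspot threshold.

    With N QTL over a genome of G cM the density is N/G per cM, the mean EQF per
    bin of size delta is density * delta, and the rule flags bins above
    ``factor`` times that mean.
    """
    return factor * qtl_density_per_cm * bin_size
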