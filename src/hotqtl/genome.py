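"""Genetic-map geometry: chromosomes, marker grids, bins, and map-function conversions.

All positions are genetic distances in centimorgans (cM), 0-based from the start of
each chromosome.  Distances are converted to recombination fractions with the Haldane
map function (no crossover interference),

    r(d) = (1 - exp(-2 d / 100)) / 2,

whose linkage parameter lambda = 1 - 2 r = exp(-2 d / 100) is multiplicative over
adjacent segments, so the lambda of a composite span is obtained from the summed
distance.  For hotspot counting the genome is tiled by half-open bins [x, x + delta);
a final partial bin is retained when a chromosome length is not a multiple of delta.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "haldane_r",
    "haldane_d",
    "linkage_lambda",
    "Chromosome",
    "GeneticMap",
    "BinGrid",
    "build_bins",
]


def haldane_r(d):
    """Recombination fraction for a genetic distance ``d`` in cM (Haldane).

    Monotone increasing on [0, inf), bounded by 0.5.  Accepts scalars or arrays.
    """
    d = np.asarray(d, dtype=float)
    if np.any(d < 0):
        raise ValueError("genetic distance must be non-negative")
    r = 0.5 * (1.0 - np.exp(-2.0 * d / 100.0))
    return float(r) if r.ndim == 0 else r


def haldane_d(r):
    """Inverse of :func:`haldane_r`: distance in cM for recombination fraction ``r``."""
    r = np.asarray(r, dtype=float)
    if np.any((r < 0) | (r >= 0.5)):
        raise ValueError("recombination fraction must lie in [0, 0.5)")
    d = -50.0 * np.log(1.0 - 2.0 * r)
    return float(d) if d.ndim == 0 else d


def linkage_lambda(d):
    """Linkage parameter lambda = 1 - 2 r(d) = exp(-2 d / 100) for ``d`` in cM."""
    d = np.asarray(d, dtype=float)
    if np.any(d < 0):
        raise ValueError("genetic distance must be non-negative")
    lam = np.exp(-2.0 * d / 100.0)
    return float(lam) if lam.ndim == 0 else lam


@dataclass(frozen=True)
class Chromosome:
    """One linkage group: a name, a length in cM and ascending marker positions."""

    name: str
    length: float
    positions: np.ndarray

    def __post_init__(self):
        pos = np.asarray(self.positions, dtype=float)
        object.__setattr__(self, "positions", pos)
        if self.length <= 0:
            raise ValueError(f"chromosome {self.name}: length must be positive")
        if pos.size < 2:
            raise ValueError(f"chromosome {self.name}: needs at least 2 markers")
        if np.any(np.diff(pos) <= 0):
            raise ValueError(f"chromosome {self.name}: marker positions must be strictly increasing")
        if pos[0] < 0 or pos[-1] > self.length:
            raise ValueError(f"chromosome {self.name}: marker positions must lie in [0, length]")

    @property
    def n_markers(self) -> int:
        return int(self.positions.size)


@dataclass(frozen=True)
class GeneticMap:
    """An ordered collection of chromosomes with mapped marker positions."""

    chromosomes: tuple[Chromosome, ...]

    def __post_init__(self):
        chroms = tuple(self.chromosomes)
        object.__setattr__(self, "chromosomes", chroms)
        names = [c.name for c in chroms]
        if len(set(names)) != len(names):
            raise ValueError("duplicate chromosome names")
        if not chroms:
            raise ValueError("a genetic map needs at least one chromosome")

    @classmethod
    def equally_spaced(cls, n_chromosomes: int = 5, length: float = 100.0,
                       n_markers: int = 50, span_ends: bool = False) -> "GeneticMap":
        """A uniform map of ``n_markers`` equally spaced markers per chromosome.

        By default the spacing is length / n_markers with markers at 0,
        length/n, ..., so a 100-cM chromosome carries 50 markers 2 cM apart,
        one per 2-cM bin (and a gene at 50 cM coincides with a marker).  With
        ``span_ends`` the markers run 0 ... length inclusive instead
        (spacing length / (n - 1)).
        """
        if span_ends:
            pos = np.linspace(0.0, length, n_markers)
        else:
            pos = np.arange(n_markers) * (length / n_markers)
        return cls(tuple(
            Chromosome(name=str(i + 1), length=length, positions=pos.copy())
            for i in range(n_chromosomes)
        ))

    @property
    def names(self) -> list[str]:
        return [c.name for c in self.chromosomes]

    @property
    def n_markers(self) -> int:
        return sum(c.n_markers for c in self.chromosomes)

    @property
    def total_length(self) -> float:
        return float(sum(c.length for c in self.chromosomes))

    def chromosome(self, name: str) -> Chromosome:
        for c in self.chromosomes:
            if c.name == name:
                return c
        raise KeyError(f"unknown chromosome {name!r}")

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for c in self.chromosomes:
            for j, p in enumerate(c.positions):
                rows.append((c.name, f"{c.name}_m{j + 1}", p))
        return pd.DataFrame(rows, columns=["chromosome", "marker", "position_cM"])

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False, float_format="%.6g")

    @classmethod
    def from_tsv(cls, path) -> "GeneticMap":
        df = pd.read_csv(path, sep="\t", dtype={"chromosome": str})
        chroms = []
        for name, grp in df.groupby("chromosome", sort=False):
            pos = grp["position_cM"].to_numpy(dtype=float)
            chroms.append(Chromosome(name=str(name), length=float(pos[-1]), positions=pos))
        return cls(tuple(chroms))


@dataclass
class BinGrid:
    """A tiling of the genome by half-open bins [x, x + delta) of common size.

    Bins are indexed globally, concatenating chromosomes in map order; the grid
    also exposes the concatenated ("circular") cM coordinate used by the
    permutation schemes.
    """

    genetic_map: GeneticMap
    bin_size: float
    n_bins_per_chrom: np.ndarray = field(init=False)
    offsets: np.ndarray = field(init=False)       # first global bin index per chromosome
    cm_offsets: np.ndarray = field(init=False)    # concatenated-cM start per chromosome
    W: int = field(init=False)

    def __post_init__(self):
        if self.bin_size <= 0:
            raise ValueError("bin size must be positive")
        lengths = np.array([c.length for c in self.genetic_map.chromosomes])
        if self.bin_size > lengths.min():
            raise ValueError("bin size exceeds the shortest chromosome length")
        self.n_bins_per_chrom = np.ceil(lengths / self.bin_size - 1e-12).astype(int)
        self.offsets = np.concatenate([[0], np.cumsum(self.n_bins_per_chrom)])
        self.cm_offsets = np.concatenate([[0.0], np.cumsum(lengths)])
        self.W = int(self.n_bins_per_chrom.sum())

    @property
    def genome_length(self) -> float:
        return float(self.cm_offsets[-1])

    def chrom_index(self, name: str) -> int:
        return self.genetic_map.names.index(name)

    def position_to_bin(self, chromosome: str, position: float) -> int:
        """Global bin index of a (chromosome, cM) position."""
        ci = self.chrom_index(chromosome)
        length = self.genetic_map.chromosomes[ci].length
        if not 0 <= position <= length:
            raise ValueError(f"position {position} outside chromosome {chromosome}")
        k = int(position // self.bin_size)
        k = min(k, self.n_bins_per_chrom[ci] - 1)  # right end belongs to the last bin
        return int(self.offsets[ci] + k)

    def bin_to_interval(self, w: int) -> tuple[str, float, float]:
        """(chromosome, start_cM, end_cM) of global bin ``w``; end is clipped to length."""
        if not 0 <= w < self.W:
            raise IndexError(f"bin index {w} out of range [0, {self.W})")
        ci = int(np.searchsorted(self.offsets, w, side="right") - 1)
        chrom = self.genetic_map.chromosomes[ci]
        k = w - self.offsets[ci]
        start = k * self.bin_size
        end = min(start + self.bin_size, chrom.length)
        return chrom.name, float(start), float(end)

    def bin_table(self) -> pd.DataFrame:
        rows = [self.bin_to_interval(w) for w in range(self.W)]
        return pd.DataFrame(rows, columns=["chromosome", "bin_start", "bin_end"])

    # --- concatenated ("circular") coordinates used by interval permutation ---

    def to_concat_cm(self, chromosome: str, position: float) -> float:
        return float(self.cm_offsets[self.chrom_index(chromosome)] + position)

    def from_concat_cm(self, x: float) -> tuple[str, float]:
        x = float(x) % self.genome_length
        ci = int(np.searchsorted(self.cm_offsets, x, side="right") - 1)
        ci = min(ci, len(self.genetic_map.chromosomes) - 1)
        return self.genetic_map.chromosomes[ci].name, x - float(self.cm_offsets[ci])


def build_bins(genetic_map: GeneticMap, bin_size: float) -> BinGrid:
    """Tile ``genetic_map`` with half-open bins of ``bin_size`` cM."""
    return BinGrid(genetic_map=genetic_map, bin_size=bin_size)
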