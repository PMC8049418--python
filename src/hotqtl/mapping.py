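"""Single-QTL regression interval mapping for backcross populations.

The scan follows Haley-Knott regression: at each grid position the phenotype is
regressed on the conditional expectation of the QTL genotype given the flanking
marker genotypes (Haldane probabilities), and

    LOD = (n / 2) * log10(RSS0 / RSS1) = -(n / 2) * log10(1 - R^2)

where RSS0 is the residual sum of squares of the mean-only model.  Detected QTL
are summarized by the LOD peak, a drop-based support interval (default 1.5 LOD,
read as a 95% interval) and the peak SD implied by that interval,
sd = (b - a) / (2 * 1.96).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import norm

from .genome import GeneticMap, haldane_r

__all__ = [
    "CrossData",
    "LODMatrix",
    "QTLInterval",
    "QTLSet",
    "hk_scan",
    "permutation_lod_threshold",
    "detect_qtl",
]

_MAX_R2 = 1.0 - 1e-12  # caps LOD at (n/2)*12 for perfect fits


@dataclass
class CrossData:
    """Backcross genotypes (0/1, -1 = missing), phenotypes and their genetic map."""

    genotypes: np.ndarray      # n x M, int8
    phenotypes: np.ndarray     # n x T, float
    genetic_map: GeneticMap
    trait_names: list[str] = field(default_factory=list)

    def __post_init__(self):
        self.genotypes = np.asarray(self.genotypes, dtype=np.int8)
        self.phenotypes = np.atleast_2d(np.asarray(self.phenotypes, dtype=float))
        n, m = self.genotypes.shape
        if n < 10:
            raise ValueError(f"need at least 10 individuals, got {n}")
        if m != self.genetic_map.n_markers:
            raise ValueError(
                f"{m} genotype columns but the map has {self.genetic_map.n_markers} markers")
        if self.phenotypes.shape[0] != n:
            raise ValueError("genotype and phenotype row counts differ")
        bad = ~np.isin(self.genotypes, (-1, 0, 1))
        if bad.any():
            raise ValueError("genotypes must be coded 0/1 (-1 for missing)")
        if not self.trait_names:
            self.trait_names = [f"t{j + 1}" for j in range(self.n_traits)]
        if len(self.trait_names) != self.n_traits:
            raise ValueError("trait_names length does not match phenotype columns")

    @property
    def n_individuals(self) -> int:
        return self.genotypes.shape[0]

    @property
    def n_traits(self) -> int:
        return self.phenotypes.shape[1]

    def marker_slices(self) -> list[slice]:
        """Column slice of the genotype matrix for each chromosome, in map order."""
        out, start = [], 0
        for c in self.genetic_map.chromosomes:
            out.append(slice(start, start + c.n_markers))
            start += c.n_markers
        return out


def _scan_positions(chrom, step: float, include_markers: bool = False) -> np.ndarray:
    """Scan grid of one chromosome: a regular step grid (optionally plus markers).

    The default grid matches the hotspot bin resolution, so estimated peaks snap
    to bin-aligned positions; ``include_markers`` adds every marker position as
    an extra scan point for a denser scan.
    """
    grid = np.append(np.arange(0.0, chrom.length + 1e-9, step), chrom.length)
    pos = np.union1d(grid, chrom.positions) if include_markers else np.unique(grid)
    keep = np.concatenate([[True], np.diff(pos) > 1e-9])
    return pos[keep]


def _cond_expectation(gL, gR, r_left, r_right, r_span):
    """P(QTL genotype = 1 | flanking genotypes) for a backcross under Haldane."""
    pa1 = np.where(gL == 1, 1.0 - r_left, r_left)
    p1b = np.where(gR == 1, 1.0 - r_right, r_right)
    pab = np.where(gL == gR, 1.0 - r_span, r_span)
    return pa1 * p1b / pab


def expected_genotype_design(cross: CrossData, step: float = 2.0,
                             include_markers: bool = False):
    """Expected QTL genotype at every scan position.

    Returns ``(X, positions)`` where ``X`` is n x P and ``positions`` is a frame
    with columns ``chromosome`` and ``position_cM``.  Missing marker genotypes are
    handled per individual by conditioning on the nearest informative flanking
    markers (or a single flank / the prior 1/2 at chromosome ends).
    """
    n = cross.n_individuals
    cols, chrom_names, cm = [], [], []
    for chrom, sl in zip(cross.genetic_map.chromosomes, cross.marker_slices()):
        G = cross.genotypes[:, sl].astype(float)
        G[G < 0] = np.nan
        has_missing = np.isnan(G).any()
        pos = chrom.positions
        for s in _scan_positions(chrom, step, include_markers):
            iR = int(np.searchsorted(pos, s - 1e-9))
            if iR < len(pos) and abs(pos[iR] - s) <= 1e-9 and not has_missing:
                x = G[:, iR].copy()
            elif not has_missing:
                iL = iR - 1
                if iL < 0:          # left of the first marker
                    r = haldane_r(pos[0] - s)
                    x = np.where(G[:, 0] == 1, 1.0 - r, r)
                elif iR >= len(pos):  # right of the last marker
                    r = haldane_r(s - pos[-1])
                    x = np.where(G[:, -1] == 1, 1.0 - r, r)
                else:
                    x = _cond_expectation(
                        G[:, iL], G[:, iR],
                        haldane_r(s - pos[iL]), haldane_r(pos[iR] - s),
                        haldane_r(pos[iR] - pos[iL]))
            else:
                x = np.empty(n)
                for i in range(n):
                    obs = np.flatnonzero(~np.isnan(G[i]))
                    left = obs[pos[obs] <= s + 1e-9]
                    right = obs[pos[obs] >= s - 1e-9]
                    if left.size and right.size:
                        jL, jR = left[-1], right[0]
                        if jL == jR:
                            x[i] = G[i, jL]
                        else:
                            x[i] = _cond_expectation(
                                G[i, jL], G[i, jR],
                                haldane_r(s - pos[jL]), haldane_r(pos[jR] - s),
                                haldane_r(pos[jR] - pos[jL]))
                    elif left.size:
                        r = haldane_r(s - pos[left[-1]])
                        x[i] = 1.0 - r if G[i, left[-1]] == 1 else r
                    elif right.size:
                        r = haldane_r(pos[right[0]] - s)
                        x[i] = 1.0 - r if G[i, right[0]] == 1 else r
                    else:
                        x[i] = 0.5
            cols.append(x)
            chrom_names.append(chrom.name)
            cm.append(s)
    X = np.column_stack(cols)
    positions = pd.DataFrame({"chromosome": chrom_names, "position_cM": cm})
    return X, positions


@dataclass
class LODMatrix:
    """LOD scores for every trait (rows) at every scan position (columns)."""

    traits: list[str]
    positions: pd.DataFrame      # columns: chromosome, position_cM
    lod: np.ndarray              # T x P, non-negative
    step: float

    def chromosome_mask(self, name: str) -> np.ndarray:
        return (self.positions["chromosome"] == name).to_numpy()

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("chromosome\t" + "\t".join(self.positions["chromosome"]) + "\n")
            fh.write("position_cM\t" + "\t".join(
                f"{p:.6g}" for p in self.positions["position_cM"]) + "\n")
            fh.write(f"step\t{self.step:.6g}" + "\t" * (len(self.positions) - 1) + "\n")
            for name, row in zip(self.traits, self.lod):
                fh.write(name + "\t" + "\t".join(f"{v:.5f}" for v in row) + "\n")

    @classmethod
    def from_tsv(cls, path) -> "LODMatrix":
        with open(path) as fh:
            chroms = fh.readline().rstrip("\n").split("\t")[1:]
            pos = [float(v) for v in fh.readline().rstrip("\n").split("\t")[1:]]
            step = float(fh.readline().rstrip("\n").split("\t")[1])
            traits, rows = [], []
            for line in fh:
                parts = line.rstrip("\n").split("\t")
                traits.append(parts[0])
                rows.append([float(v) for v in parts[1:]])
        return cls(traits=traits,
                   positions=pd.DataFrame({"chromosome": chroms, "position_cM": pos}),
                   lod=np.array(rows), step=step)


def _standardize(A: np.ndarray):
    """Column z-scores; zero-variance columns become all-zero (flagged by sd == 0)."""
    mu = A.mean(axis=0)
    sd = A.std(axis=0)
    Z = (A - mu) / np.where(sd > 0, sd, 1.0)
    Z[:, sd == 0] = 0.0
    return Z, sd


def _lod_from_corr(R: np.ndarray, n: int) -> np.ndarray:
    r2 = np.clip(R * R, 0.0, _MAX_R2)
    return -(n / 2.0) * np.log10(1.0 - r2)


def hk_scan(cross: CrossData, step: float = 2.0,
            include_markers: bool = False) -> LODMatrix:
    """LOD score matrix from a Haley-Knott regression scan of every trait.

    Constant phenotypes or degenerate (constant) design positions yield LOD 0.
    """
    n = cross.n_individuals
    if n < 3:
        raise ValueError("need at least 3 informative individuals")
    X, positions = expected_genotype_design(cross, step, include_markers)
    Zx, sdx = _standardize(X)
    if np.any(sdx == 0):
        warnings.warn("singular design at some scan positions; their LOD is set to 0")
    Zy, _ = _standardize(cross.phenotypes)
    R = (Zy.T @ Zx) / n
    return LODMatrix(traits=list(cross.trait_names), positions=positions,
                     lod=_lod_from_corr(R, n), step=step)


def permutation_lod_threshold(cross: CrossData, traits=None, B: int = 1000,
                              alpha: float = 0.05, step: float = 2.0,
                              seed=None, return_maxima: bool = False):
    """Single-trait permutation LOD threshold controlling genome-wide error rate.

    Individuals' phenotype rows are shuffled (genotypes fixed) and the genome-wide
    maximum LOD of each permuted scan is recorded; the threshold is the empirical
    (1 - alpha) quantile (order statistic ceil((1 - alpha) B)) of the B maxima.
    ``traits`` selects phenotype columns (default: all); the maximum is taken over
    the selected traits jointly, so a single trait gives the usual GWER threshold.
    """
    if B < 100:
        warnings.warn(f"B={B} permutations give an unstable quantile estimate")
    rng = np.random.default_rng(seed)
    n = cross.n_individuals
    Y = cross.phenotypes if traits is None else cross.phenotypes[:, np.atleast_1d(traits)]
    X, _ = expected_genotype_design(cross, step)
    Zx, _ = _standardize(X)
    Zy, _ = _standardize(Y)
    maxima = np.empty(B)
    for b in range(B):
        perm = rng.permutation(n)
        R = (Zy[perm].T @ Zx) / n
        maxima[b] = _lod_from_corr(np.abs(R).max(), n)
    order = np.sort(maxima)
    k = max(int(np.ceil((1.0 - alpha) * B)), 1)
    threshold = float(order[k - 1])
    return (threshold, maxima) if return_maxima else threshold


@dataclass(frozen=True)
class QTLInterval:
    """A detected QTL: peak, support interval [start, end], peak SD, peak LOD."""

    trait: str
    chromosome: str
    peak: float
    start: float
    end: float
    sd: float
    lod: float

    def __post_init__(self):
        if not self.start <= self.peak <= self.end:
            raise ValueError("QTL peak must lie inside its support interval")
        if self.sd <= 0:
            raise ValueError("peak SD must be positive")


@dataclass
class QTLSet:
    """Detected QTL of all traits at one LOD threshold."""

    qtls: list[QTLInterval]
    threshold: float | None = None
    genetic_map: GeneticMap | None = None

    def __len__(self) -> int:
        return len(self.qtls)

    @property
    def n_qtl(self) -> int:
        return len(self.qtls)

    def counts_per_trait(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for q in self.qtls:
            out[q.trait] = out.get(q.trait, 0) + 1
        return out

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(q.trait, q.chromosome, q.start, q.end, q.peak, q.lod, q.sd) for q in self.qtls],
            columns=["trait", "chromosome", "start_cM", "end_cM", "peak_cM", "LOD", "sd_cM"])

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False, float_format="%.6g")


def _interp_crossing(pos, lod, i_out, i_in, level):
    """Linear interpolation of the position where LOD crosses ``level``."""
    x0, x1 = pos[i_out], pos[i_in]
    y0, y1 = lod[i_out], lod[i_in]
    if y1 == y0:
        return x1
    return x0 + (level - y0) * (x1 - x0) / (y1 - y0)


def support_interval(pos: np.ndarray, lod: np.ndarray, peak_idx: int,
                     drop: float = 1.5) -> tuple[float, float]:
    """Drop-based support interval around a LOD peak, linearly interpolated.

    The interval runs to the outermost flanking positions where the LOD curve
    crosses peak - drop, clipped at the chromosome ends.
    """
    level = lod[peak_idx] - drop
    i = peak_idx
    while i > 0 and lod[i - 1] >= level:
        i -= 1
    a = pos[0] if i == 0 else _interp_crossing(pos, lod, i - 1, i, level)
    j = peak_idx
    while j < len(pos) - 1 and lod[j + 1] >= level:
        j += 1
    b = pos[-1] if j == len(pos) - 1 else _interp_crossing(pos, lod, j + 1, j, level)
    return float(a), float(b)


def detect_qtl(lod: LODMatrix, threshold: float, drop: float = 1.5,
               coverage: float = 0.95) -> QTLSet:
    """Call QTL: per trait and chromosome, the LOD argmax if it reaches ``threshold``.

    Ties at the argmax break to the leftmost position.  The peak SD is the
    support-interval width divided by twice the normal quantile of ``coverage``
    (1.96 for 95%), so the interval reads as peak +/- z * sd.
    """
    if threshold <= 0:
        raise ValueError("LOD threshold must be positive")
    z = norm.ppf(0.5 + coverage / 2.0)
    chroms = lod.positions["chromosome"].to_numpy()
    pos_all = lod.positions["position_cM"].to_numpy()
    qtls = []
    for name in dict.fromkeys(chroms):  # map order
        m = chroms == name
        pos = pos_all[m]
        L = lod.lod[:, m]
        peaks = L.argmax(axis=1)
        for t, pk in enumerate(peaks):
            if L[t, pk] < threshold:
                continue
            a, b = support_interval(pos, L[t], pk, drop)
            sd = max((b - a) / (2.0 * z), 1e-8)
            qtls.append(QTLInterval(trait=lod.traits[t], chromosome=name,
                                    peak=float(pos[pk]), start=a, end=b,
                                    sd=sd, lod=float(L[t, pk])))
    qtls.sort(key=lambda q: (q.trait, q.chromosome, q.peak))
    return QTLSet(qtls=qtls, threshold=threshold)
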