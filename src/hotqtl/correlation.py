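"""Genetic-correlation calculus for linked and pleiotropic trait pairs.

These closed forms explain why position-based trait grouping is used instead of
correlation-based grouping: two traits controlled by tightly linked or even
fully pleiotropic QTL can show any genetic correlation in [-1, 1] (including 0)
depending on effect signs, magnitudes and linkage parameters, so genetic or
phenotypic correlation cannot reliably recover co-localized QTL.

Model: backcross genotypes x in {0, 1}; a trait's genotypic value is
G = mu + sum_j a_j x_j.  Between two loci at distance d cM, cov(x_i, x_j) =
lambda_ij / 4 with lambda = 1 - 2 r(d) = exp(-2 d / 100) under Haldane; the
lambda of a composite span multiplies over segments (equivalently, distances
add).  The phenotypic correlation decomposes as

    rho_P = rho_G * sqrt(h1^2 h2^2) + rho_E * sqrt((1 - h1^2)(1 - h2^2)).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .genome import haldane_r, linkage_lambda
from .mapping import CrossData, QTLSet, expected_genotype_design

__all__ = [
    "TraitCorrelation",
    "DigenicModel",
    "phenotypic_correlation",
    "genetic_correlation_digenic",
    "genetic_correlation_pleiotropic",
    "monogenic_linked_correlation",
    "shared_single_qtl_correlation",
    "empirical_correlations",
    "pairwise_correlation_table",
]


@dataclass(frozen=True)
class TraitCorrelation:
    """Phenotypic, genetic and residual correlations of a trait pair."""

    rho_p: float
    rho_g: float        # nan when either trait has no detected QTL
    rho_e: float
    h2_1: float
    h2_2: float


def phenotypic_correlation(rho_g: float, rho_e: float, h2_1: float, h2_2: float) -> float:
    """Phenotypic correlation from its genetic and residual components.

    The value is returned raw; for arbitrary (rho_g, rho_e) pairs it is not
    guaranteed to stay inside [-1, 1], and a warning-worthy |value| > 1 signals
    inconsistent inputs rather than being clamped.
    """
    for h2 in (h2_1, h2_2):
        if not 0.0 <= h2 <= 1.0:
            raise ValueError("heritability must lie in [0, 1]")
    return (rho_g * math.sqrt(h2_1 * h2_2)
            + rho_e * math.sqrt((1.0 - h2_1) * (1.0 - h2_2)))


@dataclass(frozen=True)
class DigenicModel:
    """Two digenic traits on four ordered loci Qi - Qj - Qk - Ql.

    Trait 1 is controlled by Qi and Qk with effects (a1, a2); trait 2 by Qj and
    Ql with effects (b1, b2).  ``d_ij``, ``d_jk``, ``d_kl`` are the inter-locus
    distances in cM; composite spans sum the distances (no interference).
    """

    a1: float
    a2: float
    b1: float
    b2: float
    d_ij: float
    d_jk: float
    d_kl: float

    def __post_init__(self):
        if min(self.d_ij, self.d_jk, self.d_kl) < 0:
            raise ValueError("inter-QTL distances must be non-negative")
        if self.a1 == self.a2 == 0 or self.b1 == self.b2 == 0:
            raise ValueError("each trait needs at least one nonzero effect")

    def lambdas(self) -> dict[str, float]:
        d = {"ij": self.d_ij, "jk": self.d_jk, "kl": self.d_kl,
             "ik": self.d_ij + self.d_jk, "jl": self.d_jk + self.d_kl,
             "il": self.d_ij + self.d_jk + self.d_kl}
        return {key: linkage_lambda(v) for key, v in d.items()}


def genetic_correlation_digenic(model: DigenicModel) -> float:
    """Genetic correlation of two digenic traits under linkage.

    rho_G = (l_ij a1 b1 + l_jk a2 b1 + l_il a1 b2 + l_kl a2 b2)
            / sqrt((a1^2 + a2^2 + 2 l_ik a1 a2)(b1^2 + b2^2 + 2 l_jl b1 b2)).
    """
    lam = model.lambdas()
    a1, a2, b1, b2 = model.a1, model.a2, model.b1, model.b2
    num = (lam["ij"] * a1 * b1 + lam["jk"] * a2 * b1
           + lam["il"] * a1 * b2 + lam["kl"] * a2 * b2)
    var1 = a1 * a1 + a2 * a2 + 2.0 * lam["ik"] * a1 * a2
    var2 = b1 * b1 + b2 * b2 + 2.0 * lam["jl"] * b1 * b2
    denom = math.sqrt(var1 * var2) if var1 > 0 and var2 > 0 else 0.0
    if denom <= 0:
        raise ZeroDivisionError("genetic variance of a trait vanishes (effects cancel)")
    return num / denom


def genetic_correlation_pleiotropic(a1: float, a2: float, b1: float, b2: float) -> float:
    """Genetic correlation of two digenic traits sharing both (unlinked) QTL.

    rho_G = (a1 b1 + a2 b2) / sqrt((a1 b1 + a2 b2)^2 + (a1 b2 - a2 b1)^2);
    the limit of the digenic-linkage formula for d_ij = d_kl = 0, d_jk -> inf.
    """
    num = a1 * b1 + a2 * b2
    cross = a1 * b2 - a2 * b1
    denom = math.hypot(num, cross)
    if denom == 0:
        raise ZeroDivisionError("all effect products vanish; correlation undefined")
    return num / denom


def monogenic_linked_correlation(d: float, same_direction: bool = True) -> float:
    """Genetic correlation of two monogenic traits with QTL ``d`` cM apart.

    rho_G = +/- (1 - 2 r(d)); +/-1 at d = 0 (pleiotropy), -> 0 when unlinked.
    """
    lam = 1.0 - 2.0 * haldane_r(d)
    return lam if same_direction else -lam


def shared_single_qtl_correlation(a1: float, a2: float, b1: float, b2: float) -> float:
    """Genetic correlation when two digenic traits share only their first QTL.

    rho_G = a1 b1 / sqrt((a1^2 + a2^2)(b1^2 + b2^2)): the pleiotropic component
    a1 b1 is diluted by the unshared, unlinked QTL effects a2 and b2.
    """
    v1, v2 = a1 * a1 + a2 * a2, b1 * b1 + b2 * b2
    if v1 == 0 or v2 == 0:
        raise ZeroDivisionError("each trait needs a nonzero effect")
    return a1 * b1 / math.sqrt(v1 * v2)


def _corr(x: np.ndarray, y: np.ndarray) -> float:
    if np.ptp(x) == 0 or np.ptp(y) == 0:  # constant vector: undefined
        return float("nan")
    return float(np.corrcoef(x, y)[0, 1])


def _fit_genetic_values(cross: CrossData, qtls: QTLSet, trait: str,
                        design_cache: dict) -> tuple[np.ndarray, float]:
    """Fitted genotypic values and model R^2 of one trait's detected-QTL model."""
    t = cross.trait_names.index(trait)
    y = cross.phenotypes[:, t]
    peaks = [(q.chromosome, q.peak) for q in qtls.qtls if q.trait == trait]
    if not peaks:
        return np.full_like(y, y.mean()), 0.0
    cols = []
    for chrom, peak in peaks:
        key = (chrom, round(peak, 6))
        if key not in design_cache:
            X, positions = design_cache["__design__"]
            mask = ((positions["chromosome"] == chrom)
                    & (np.abs(positions["position_cM"] - peak) < 1e-6)).to_numpy()
            if mask.any():
                design_cache[key] = X[:, np.flatnonzero(mask)[0]]
            else:  # peak off the cached grid: nearest scan position on the chromosome
                on_chrom = np.flatnonzero((positions["chromosome"] == chrom).to_numpy())
                j = on_chrom[np.abs(
                    positions["position_cM"].to_numpy()[on_chrom] - peak).argmin()]
                design_cache[key] = X[:, j]
        cols.append(design_cache[key])
    A = np.column_stack([np.ones(len(y))] + cols)
    coef, *_ = np.linalg.lstsq(A, y, rcond=None)
    ghat = A @ coef
    ss_tot = ((y - y.mean()) ** 2).sum()
    r2 = 0.0 if ss_tot == 0 else float(1.0 - ((y - ghat) ** 2).sum() / ss_tot)
    return ghat, max(r2, 0.0)


def empirical_correlations(cross: CrossData, qtls: QTLSet, trait1: str, trait2: str,
                           step: float = 2.0, _cache: dict | None = None) -> TraitCorrelation:
    """Phenotypic/genetic/residual correlations of a trait pair from mapped QTL.

    Each trait's genotypic values are the fitted values of a linear model on the
    expected genotypes at its detected QTL peaks; heritability is the model R^2.
    rho_G is the correlation of the fitted values (nan when a trait has no QTL,
    in which case its genotypic value is flat), rho_E of the residuals.
    """
    cache = _cache if _cache is not None else {}
    if "__design__" not in cache:
        cache["__design__"] = expected_genotype_design(cross, step)
    y1 = cross.phenotypes[:, cross.trait_names.index(trait1)]
    y2 = cross.phenotypes[:, cross.trait_names.index(trait2)]
    g1, h2_1 = _fit_genetic_values(cross, qtls, trait1, cache)
    g2, h2_2 = _fit_genetic_values(cross, qtls, trait2, cache)
    return TraitCorrelation(
        rho_p=_corr(y1, y2),
        rho_g=_corr(g1, g2),
        rho_e=_corr(y1 - g1, y2 - g2),
        h2_1=h2_1, h2_2=h2_2)


def pairwise_correlation_table(cross: CrossData, qtls: QTLSet, pairs,
                               groups=None, step: float = 2.0):
    """Correlation table for many trait pairs (shared design cache).

    ``pairs`` is an iterable of (trait1, trait2); ``groups`` (a TraitGroups)
    adds a ``same_group`` column.  Returns a pandas DataFrame.
    """
    import pandas as pd

    cache: dict = {}
    rows = []
    for t1, t2 in pairs:
        c = empirical_correlations(cross, qtls, t1, t2, step=step, _cache=cache)
        row = {"trait1": t1, "trait2": t2, "rhoP": c.rho_p, "rhoG": c.rho_g,
               "rhoE": c.rho_e, "h2_1": c.h2_1, "h2_2": c.h2_2}
        if groups is not None:
            row["same_group"] = (groups.group_of_trait.get(t1)
                                 == groups.group_of_trait.get(t2))
        rows.append(row)
    return pd.DataFrame(rows)
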