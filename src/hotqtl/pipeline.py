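"""End-to-end orchestration: configuration, staged outputs and run manifests.

A run reads either individual-level cross data (scan -> detect -> EQF per LOD
threshold) or a summarized QTL table (EQF directly, uniform model), computes
grouped-permutation gamma ladders, calls hotspots and writes top-gamma profiles
for the called bins.  Every artifact lands in the output directory together
with a JSON manifest recording the seed, parameters, software version and
wall-clock time, from which the run can be reproduced exactly.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from . import __version__
from .eqf import build_eqf, multi_threshold_eqf
from .genome import build_bins
from .hotspots import call_hotspots, gamma_thresholds, group_traits, top_gamma_profile
from .io import read_cross, read_summarized_qtl
from .mapping import hk_scan

log = logging.getLogger("hotqtl")

__all__ = ["RunConfig", "run_pipeline"]


@dataclass
class RunConfig:
    """Parameters of one hotspot-detection run."""

    input_path: str
    input_format: str = "cross"            # "cross" | "summarized"
    out_dir: str = "hotqtl_out"
    bin_size: float = 2.0
    step: float = 2.0
    drop: float = 1.5
    lod_thresholds: list[float] = field(default_factory=lambda: [3, 4, 5, 6, 7, 8])
    alpha: float = 0.05
    B: int = 1000
    scheme: str = "eqf-bin"                # "eqf-bin" | "qtl-interval"
    grouping: str = "empirical"            # "empirical" | "none"
    model: str = "normal"                  # "normal" | "uniform" | "point"
    n: int = 1                             # which gamma(n, alpha) to call with
    seed: int = 0

    def __post_init__(self):
        if self.input_format not in ("cross", "summarized"):
            raise ValueError("input_format must be 'cross' or 'summarized'")
        if any(b <= a for a, b in zip(self.lod_thresholds, self.lod_thresholds[1:])):
            raise ValueError("lod_thresholds must be strictly increasing")
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must lie in (0, 1)")
        if self.grouping not in ("empirical", "none"):
            raise ValueError("grouping must be 'empirical' or 'none'")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls(**yaml.safe_load(fh))

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)


def _ladder_from_cross(config: RunConfig, out: Path):
    cross = read_cross(config.input_path)
    log.info("cross: %d individuals, %d traits, %d markers",
             cross.n_individuals, cross.n_traits, cross.genetic_map.n_markers)
    lod = hk_scan(cross, step=config.step)
    lod.to_tsv(out / "lod_matrix.tsv")
    bins = build_bins(cross.genetic_map, config.bin_size)
    triples = multi_threshold_eqf(lod, config.lod_thresholds, bins,
                                  drop=config.drop,
                                  model="normal" if config.model == "point" else config.model,
                                  point_mass=config.model == "point")
    return bins, list(zip(config.lod_thresholds, triples))


def _ladder_from_summarized(config: RunConfig, out: Path):
    qtls, inferred_model = read_summarized_qtl(config.input_path)
    model = inferred_model if config.model == "normal" else config.model
    log.info("summarized QTL: %d QTL, %d traits (%s model)",
             qtls.n_qtl, len(qtls.counts_per_trait()), model)
    bins = build_bins(qtls.genetic_map, config.bin_size)
    emat = build_eqf(qtls, bins, model="normal" if model == "point" else model)
    return bins, [(qtls.threshold or 0.0, (qtls, emat, emat.architecture()))]


def run_pipeline(config: RunConfig) -> dict:
    """Execute a full run; returns the manifest dict (also written to disk)."""
    t0 = time.time()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    try:
        if config.input_format == "cross":
            bins, ladder_in = _ladder_from_cross(config, out)
        else:
            bins, ladder_in = _ladder_from_summarized(config, out)
        ladder, reports = [], []
        for i, (L, (qset, emat, arch)) in enumerate(ladder_in):
            tag = f"L{L:g}" if config.input_format == "cross" else "summary"
            log.info("%s: %d QTL in %d bins (W=%d)", tag, qset.n_qtl,
                     int((arch.Fw > 0).sum()), bins.W)
            qset.to_tsv(out / f"qtl_{tag}.tsv")
            arch.to_tsv(out / f"eqf_architecture_{tag}.tsv")
            if config.grouping == "empirical":
                groups = group_traits(qset, bins)
            else:
                from .hotspots import TraitGroups
                groups = TraitGroups.all_free(emat.n_qtl, emat.traits)
            log.info("%s: %d trait groups, %d trunks, %d free QTL", tag,
                     groups.R, len(groups.trunks), len(groups.free))
            thr = gamma_thresholds(emat, groups, B=config.B, alpha=config.alpha,
                                   seed=config.seed + i, scheme=config.scheme,
                                   keep_samples=False)
            thr.to_json(out / f"thresholds_{tag}.json")
            n = min(config.n, thr.k) if thr.k >= 1 else 0
            if n >= 1:
                rep = call_hotspots(arch, thr, n=n, eqf=emat)
                rep.to_tsv(out / f"hotspots_{tag}.tsv")
                reports.append((L, rep))
                log.info("%s: %d hotspots at gamma(%d)=%.4g (beta=%.4g, k=%d)",
                         tag, rep.n_called, n, rep.gamma, thr.beta, thr.k)
            ladder.append((L, arch, thr))
        profile_path = None
        if len(ladder) > 1 and reports:
            called = sorted({int(w) for _, rep in reports for w in rep.bins})
            frames = [top_gamma_profile(w, ladder).to_frame() for w in called]
            if frames:
                import pandas as pd
                profile_path = out / "profiles.tsv"
                pd.concat(frames).to_csv(profile_path, sep="\t", index=False,
                                         float_format="%.6g")
        manifest = {
            "config": asdict(config),
            "version": __version__,
            "W": bins.W,
            "wall_clock_s": round(time.time() - t0, 3),
            "outputs": sorted(p.name for p in out.iterdir() if p.name != "manifest.json"),
        }
        with open(out / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=1)
        return manifest
    except Exception:
        marker = out / "RUN_FAILED"
        marker.write_text("this run did not complete; outputs may be partial\n")
        raise
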