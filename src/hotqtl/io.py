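"""Readers and writers for the cross-CSV and summarized-QTL table formats.

Cross CSV (the dialect used by common QTL-mapping software): column-oriented,
phenotype columns first, then marker columns; row 1 holds trait/marker names,
row 2 chromosome ids (blank under traits), row 3 marker positions in cM (blank
under traits), and each following row one individual.  Backcross genotypes are
coded by two configurable strings (default "A"/"H"; "-" = missing).

Summarized QTL TSV: one row per QTL with columns trait, chromosome, start_cM,
end_cM and optional peak_cM / LOD.  When peak_cM is absent only the flanking
interval is known and the uniform interval model applies.
"""

from __future__ import annotations

import csv

import numpy as np
import pandas as pd

from .genome import Chromosome, GeneticMap
from .mapping import CrossData, QTLInterval, QTLSet

__all__ = ["read_cross", "write_cross", "read_summarized_qtl", "write_summarized_qtl"]


def read_cross(path, genotype_codes: tuple[str, str] = ("A", "H"),
               missing_code: str = "-") -> CrossData:
    """Read a cross-CSV file into :class:`CrossData`.

    Raises descriptive errors (with row/column numbers) on ragged rows, unknown
    genotype codes, or non-numeric phenotype values.
    """
    with open(path, newline="") as fh:
        rows = list(csv.reader(fh))
    if len(rows) < 4:
        raise ValueError(f"{path}: need 3 header rows plus at least one individual")
    names, chrom_row, pos_row = rows[0], rows[1], rows[2]
    ncol = len(names)
    for i, row in enumerate(rows[1:], start=2):
        if len(row) != ncol:
            raise ValueError(f"{path}: line {i} has {len(row)} fields, expected {ncol}")
    is_marker = [c.strip() != "" for c in chrom_row]
    trait_cols = [j for j, m in enumerate(is_marker) if not m]
    marker_cols = [j for j, m in enumerate(is_marker) if m]
    if not marker_cols:
        raise ValueError(f"{path}: no marker columns (row 2 chromosome ids all blank)")
    chroms: list[Chromosome] = []
    cur_name, cur_pos = None, []
    for j in marker_cols:
        ch, p = chrom_row[j].strip(), float(pos_row[j])
        if ch != cur_name:
            if cur_name is not None:
                chroms.append(Chromosome(cur_name, cur_pos[-1], np.array(cur_pos)))
            cur_name, cur_pos = ch, []
        cur_pos.append(p)
    chroms.append(Chromosome(cur_name, cur_pos[-1], np.array(cur_pos)))
    gmap = GeneticMap(tuple(chroms))
    code = {genotype_codes[0]: 0, genotype_codes[1]: 1, missing_code: -1, "": -1}
    n = len(rows) - 3
    G = np.empty((n, len(marker_cols)), dtype=np.int8)
    Y = np.empty((n, len(trait_cols)))
    for i, row in enumerate(rows[3:], start=4):
        for k, j in enumerate(marker_cols):
            v = row[j].strip()
            if v not in code:
                raise ValueError(
                    f"{path}: line {i}, column {j + 1} ({names[j]}): "
                    f"unknown genotype code {v!r}")
            G[i - 4, k] = code[v]
        for k, j in enumerate(trait_cols):
            try:
                Y[i - 4, k] = float(row[j])
            except ValueError:
                raise ValueError(
                    f"{path}: line {i}, column {j + 1} ({names[j]}): "
                    f"non-numeric phenotype {row[j]!r}") from None
    return CrossData(genotypes=G, phenotypes=Y, genetic_map=gmap,
                     trait_names=[names[j] for j in trait_cols])


def write_cross(cross: CrossData, path,
                genotype_codes: tuple[str, str] = ("A", "H"),
                missing_code: str = "-") -> None:
    """Write :class:`CrossData` in the cross-CSV dialect (traits first)."""
    marker_names, chrom_ids, positions = [], [], []
    for c in cross.genetic_map.chromosomes:
        for j, p in enumerate(c.positions):
            marker_names.append(f"{c.name}_m{j + 1}")
            chrom_ids.append(c.name)
            positions.append(f"{p:.6g}")
    code = {0: genotype_codes[0], 1: genotype_codes[1], -1: missing_code}
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(cross.trait_names + marker_names)
        w.writerow([""] * cross.n_traits + chrom_ids)
        w.writerow([""] * cross.n_traits + positions)
        for i in range(cross.n_individuals):
            w.writerow([f"{v:.10g}" for v in cross.phenotypes[i]]
                       + [code[int(g)] for g in cross.genotypes[i]])


def read_summarized_qtl(path, genetic_map: GeneticMap | None = None,
                        coverage_z: float = 1.96):
    """Read a summarized QTL TSV into ``(QTLSet, model)``.

    ``model`` is "normal" when a peak_cM column is present, else "uniform".
    Without a genetic map, chromosome lengths are inferred as the largest end
    position seen per chromosome.  Records sorted or unsorted load identically
    (the set is ordered by trait, chromosome, then peak).
    """
    df = pd.read_csv(path, sep="\t", dtype={"chromosome": str, "trait": str})
    required = {"trait", "chromosome", "start_cM", "end_cM"}
    if not required.issubset(df.columns):
        raise ValueError(f"{path}: missing columns {sorted(required - set(df.columns))}")
    if (df["end_cM"] < df["start_cM"]).any():
        bad = df.index[df["end_cM"] < df["start_cM"]][0]
        raise ValueError(f"{path}: record {bad + 1}: end_cM below start_cM")
    has_peak = "peak_cM" in df.columns and df["peak_cM"].notna().all()
    if genetic_map is None:
        lengths = df.groupby("chromosome", sort=False)["end_cM"].max()
        genetic_map = GeneticMap(tuple(
            Chromosome(str(ch), max(float(ln), 1e-6),
                       np.array([0.0, max(float(ln), 1e-6)]))
            for ch, ln in lengths.items()))
    known = set(genetic_map.names)
    qtls = []
    for idx, row in df.iterrows():
        ch = str(row["chromosome"])
        if ch not in known:
            raise ValueError(f"{path}: record {idx + 1}: unknown chromosome {ch!r}")
        a, b = float(row["start_cM"]), float(row["end_cM"])
        peak = float(row["peak_cM"]) if has_peak else (a + b) / 2.0
        width = b - a
        sd = max(width, 1e-6) / (2.0 * coverage_z)
        lod = float(row["LOD"]) if "LOD" in df.columns and pd.notna(row.get("LOD")) else 0.0
        qtls.append(QTLInterval(trait=str(row["trait"]), chromosome=ch, peak=peak,
                                start=a, end=b, sd=sd, lod=lod))
    qtls.sort(key=lambda q: (q.trait, q.chromosome, q.peak))
    return (QTLSet(qtls=qtls, genetic_map=genetic_map),
            "normal" if has_peak else "uniform")


def write_summarized_qtl(qtls: QTLSet, path, include_peak: bool = True) -> None:
    df = qtls.to_frame()
    if not include_peak:
        df = df[["trait", "chromosome", "start_cM", "end_cM"]]
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")
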