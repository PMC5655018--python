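"""Published summary tables for the durum x wild-emmer RIL reference map.

These are the printed per-linkage-group characteristics (lengths, skeleton
and bound marker counts, reference-collinear counts) and population
diversity means of the high-density durum ('Langdon') x wild emmer
(PI 428082) reference map that the synthetic generator emulates. They serve as arithmetic inputs:
genome-wise mean linkage-group lengths, marker spacing and fractions, and
the polyploid diversity decomposition are recomputed from them at run time.

The four arms of the 3B-6B reciprocal translocation were kept as separate
linkage groups in the source map; chromosome totals below sum them.
"""

from __future__ import annotations

import pandas as pd

from .popgen import decompose_diversity

__all__ = [
    "linkage_group_table", "diversity_means_table", "marker_accounting",
    "chromosome_lengths", "mean_chromosome_length", "skeleton_marker_spacing",
    "ordered_marker_fraction", "repeat_marker_fraction",
    "polyploid_new_diversity",
]

_LG_ROWS = [
    # lg, length_cm, segregating, cosegregating, total, collinear
    ("1A", 112.76, 188, 490, 678, 604),
    ("1B", 116.27, 217, 694, 911, 763),
    ("2A", 124.80, 168, 551, 719, 625),
    ("2B", 122.86, 236, 1110, 1346, 1173),
    ("3A", 133.83, 220, 533, 753, 619),
    ("3BS", 47.55, 84, 270, 354, 256),
    ("3BL", 68.69, 125, 354, 479, 399),
    ("4A", 128.19, 163, 390, 553, 456),
    ("4B", 108.03, 141, 365, 506, 364),
    ("5A", 176.48, 177, 445, 622, 482),
    ("5B", 138.66, 229, 755, 984, 871),
    ("6A", 101.55, 155, 394, 549, 499),
    ("6BS", 46.82, 71, 247, 318, 253),
    ("6BL", 48.94, 82, 404, 486, 391),
    ("7A", 135.10, 221, 576, 797, 635),
    ("7B", 117.38, 173, 686, 859, 653),
]

# per-genome diversity means (x 1e-3 for the thetas), by population
_DIVERSITY_ROWS = [
    # region, population, theta_w_e3, theta_pi_e3, tajimas_d
    ("A genome", "bread_wheat", 0.62, 0.60, -0.07),
    ("A genome", "wild_emmer", 0.68, 0.73, 0.18),
    ("4A", "bread_wheat", 0.45, 0.42, -0.11),
    ("4A", "wild_emmer", 0.59, 0.50, -0.39),
    ("4AS distal", "bread_wheat", 0.38, 0.27, -0.62),
    ("4AS distal", "wild_emmer", 0.57, 0.51, -0.28),
    ("sweep area", "bread_wheat", 0.47, 0.65, 0.95),
    ("sweep area", "wild_emmer", 0.03, 0.01, -1.11),
    ("4AL distal", "bread_wheat", 0.68, 0.44, -0.71),
    ("4AL distal", "wild_emmer", 1.10, 0.96, -0.33),
]

#: diversity of the hexaploid D genome (x 1e-3), essentially all contributed
#: by recent gene flow from the diploid progenitor — used as the estimate of
#: the introgressed component theta_pi_i in the polyploid decomposition
D_GENOME_THETA_PI_E3 = 0.18


def linkage_group_table() -> pd.DataFrame:
    return pd.DataFrame(_LG_ROWS, columns=[
        "lg", "length_cm", "segregating", "cosegregating", "total", "collinear"])


def diversity_means_table() -> pd.DataFrame:
    return pd.DataFrame(_DIVERSITY_ROWS, columns=[
        "region", "population", "theta_w_e3", "theta_pi_e3", "tajimas_d"])


def marker_accounting() -> dict:
    """Map-wide marker counts: total mapped, reference-ordered, repeat-derived."""
    return {"total": 10_914, "ordered": 9_131, "repeat_derived": 42}


def chromosome_lengths(table: pd.DataFrame | None = None) -> pd.Series:
    """Per-chromosome genetic lengths, summing split translocation arms."""
    table = linkage_group_table() if table is None else table
    chrom = table["lg"].str.replace(r"[SL]$", "", regex=True)
    return table.groupby(chrom)["length_cm"].sum()


def mean_chromosome_length(genome: str, exclude=()) -> float:
    """Mean genetic chromosome length for one genome (A or B), in cM."""
    lengths = chromosome_lengths()
    keep = [c for c in lengths.index if c.endswith(genome) and c not in exclude]
    if not keep:
        raise ValueError(f"no chromosomes for genome {genome!r}")
    return float(lengths.loc[keep].mean())


def skeleton_marker_spacing() -> float:
    """Average cM per segregating (skeleton) marker across the whole map."""
    t = linkage_group_table()
    return float(t["length_cm"].sum() / t["segregating"].sum())


def ordered_marker_fraction() -> float:
    acc = marker_accounting()
    return acc["ordered"] / acc["total"]


def repeat_marker_fraction() -> float:
    acc = marker_accounting()
    return acc["repeat_derived"] / acc["total"]


def polyploid_new_diversity(population: str) -> float:
    """theta_pi_p (x 1e-3) for the non-4A A genome of one population.

    Total A-genome theta_pi minus the D-genome diversity (the introgressed
    component theta_pi_i), via the decomposition theta_pi = theta_pi_i +
    theta_pi_p.
    """
    t = diversity_means_table()
    row = t[(t["region"] == "A genome") & (t["population"] == population)]
    if row.empty:
        raise ValueError(f"unknown population {population!r}")
    return decompose_diversity(float(row["theta_pi_e3"].iloc[0]), D_GENOME_THETA_PI_E3)
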