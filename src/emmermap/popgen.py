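"""Per-locus diversity statistics, regional summaries and sweep detection.

Implements Watterson's theta_w = S / (a1 * L), nucleotide diversity
theta_pi = Pi / L (Pi the mean pairwise difference count), Tajima's D with
its standard normalising constants, genetic-map position imputation by
linear interpolation between anchored markers, label-permutation tests for
regional means, run-based selective-sweep detection, and the polyploid
diversity decomposition theta_pi = theta_pi_i + theta_pi_p (introgressed
from the diploid progenitors vs accumulated since polyploid origin).
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "watterson_theta", "nucleotide_diversity", "tajimas_d",
    "impute_genetic_position", "annotate_diversity",
    "RegionSummary", "region_diversity_summary",
    "SweepRegion", "detect_sweep", "decompose_diversity",
]


def _a1(n: int) -> float:
    return sum(1.0 / i for i in range(1, n))


def watterson_theta(S: int, n: int, L: float) -> float:
    """Watterson per-site estimator theta_w = S / (a1 * L), a1 = sum 1/i."""
    if n < 2:
        raise ValueError("need n >= 2 samples")
    if L <= 0:
        raise ValueError("locus length must be positive")
    if S < 0:
        raise ValueError("segregating sites cannot be negative")
    return S / (_a1(n) * L)


def nucleotide_diversity(data, n: int | None = None, L: float | None = None):
    """Mean pairwise diversity: returns ``(theta_pi_per_site, Pi)``.

    ``data`` is either a flat sequence of all C(n,2) pairwise difference
    counts (then ``n`` and ``L`` are required), or an ``(n, sites)`` integer
    matrix of sequences where negative values mark missing data. With
    sequences, each pair is compared under pairwise deletion: sites missing
    in either sequence are ignored and that pair's length is reduced
    accordingly; the per-site value is the mean over pairs of the per-pair
    per-site diversity.
    """
    arr = np.asarray(data)
    if arr.ndim == 2:
        nseq = arr.shape[0]
        if nseq < 2:
            raise ValueError("need n >= 2 sequences")
        diffs, rates = [], []
        for i, j in itertools.combinations(range(nseq), 2):
            ok = (arr[i] >= 0) & (arr[j] >= 0)
            L_pair = int(ok.sum())
            d = int(np.sum(arr[i, ok] != arr[j, ok]))
            diffs.append(d)
            rates.append(d / L_pair if L_pair else 0.0)
        return float(np.mean(rates)), float(np.mean(diffs))
    if n is None or L is None:
        raise ValueError("pairwise difference counts need explicit n and L")
    if n < 2:
        raise ValueError("need n >= 2 samples")
    expected = n * (n - 1) // 2
    if len(arr) != expected:
        raise ValueError(f"expected {expected} pairwise values, got {len(arr)}")
    Pi = float(np.mean(arr))
    return Pi / L, Pi


def tajimas_d(S: int, Pi: float, n: int) -> float:
    """Tajima's D = (Pi - S/a1) / sqrt(e1*S + e2*S*(S-1)).

    Returns NaN (undefined, not zero) when S = 0.
    """
    if n < 2:
        raise ValueError("need n >= 2 samples")
    if S == 0:
        return float("nan")
    a1 = _a1(n)
    a2 = sum(1.0 / i ** 2 for i in range(1, n))
    b1 = (n + 1) / (3.0 * (n - 1))
    b2 = 2.0 * (n ** 2 + n + 3) / (9.0 * n * (n - 1))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1 ** 2
    e1 = c1 / a1
    e2 = c2 / (a1 ** 2 + a2)
    var = e1 * S + e2 * S * (S - 1)
    if var <= 0:
        # the normalising constants vanish for n <= 3; D is undefined there
        return float("nan")
    return (Pi - S / a1) / math.sqrt(var)


def annotate_diversity(table: pd.DataFrame) -> pd.DataFrame:
    """Add theta_w, theta_pi and tajimas_d columns to a per-locus table.

    Expects columns n, S, pi_count, length_bp (as emitted by the synthetic
    diversity panel or loaded from a per-locus table).
    """
    out = table.copy()
    out["theta_w"] = [watterson_theta(r.S, r.n, r.length_bp) for r in table.itertuples()]
    out["theta_pi"] = table["pi_count"] / table["length_bp"]
    out["tajimas_d"] = [tajimas_d(r.S, r.pi_count, r.n) for r in table.itertuples()]
    return out


def impute_genetic_position(physical_bp, anchor_bp, anchor_cm):
    """Impute cM by linear interpolation between flanking anchored markers.

    Positions outside the anchored range are clamped to the terminal
    marker's cM and flagged extrapolated. Returns ``(cm, extrapolated)``
    arrays (scalars for scalar input).
    """
    anchor_bp = np.asarray(anchor_bp, dtype=float)
    anchor_cm = np.asarray(anchor_cm, dtype=float)
    if anchor_bp.size < 2:
        raise ValueError("need at least two anchored markers")
    order = np.argsort(anchor_bp, kind="stable")
    anchor_bp, anchor_cm = anchor_bp[order], anchor_cm[order]
    q = np.asarray(physical_bp, dtype=float)
    cm = np.interp(q, anchor_bp, anchor_cm)
    extrapolated = (q < anchor_bp[0]) | (q > anchor_bp[-1])
    if cm.ndim == 0:
        return float(cm), bool(extrapolated)
    return cm, extrapolated


# ---------------------------------------------------------------------------
# regional summaries with permutation significance

@dataclass
class RegionSummary:
    label: str
    n_loci: int
    mean_theta_w: float
    mean_theta_pi: float
    mean_tajimas_d: float
    p_theta_w: float
    p_theta_pi: float
    p_tajimas_d: float


def _perm_pvalue(values: np.ndarray, in_region: np.ndarray, n_perm: int,
                 rng: np.random.Generator) -> float:
    """Two-sided label-permutation p for |mean(region) - mean(complement)|.

    Uses exhaustive enumeration of label assignments when there are no more
    than ``n_perm`` of them, otherwise Monte Carlo with the add-one
    estimator.
    """
    k = int(in_region.sum())
    n = len(values)
    if k == 0 or k == n:
        return float("nan")

    def diff(mask):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            return abs(np.nanmean(values[mask]) - np.nanmean(values[~mask]))

    obs = diff(in_region)
    if np.isnan(obs):
        return float("nan")
    if math.comb(n, k) <= n_perm:
        hits = total = 0
        for combo in itertools.combinations(range(n), k):
            mask = np.zeros(n, dtype=bool)
            mask[list(combo)] = True
            d = diff(mask)
            if np.isnan(d):
                continue
            total += 1
            hits += d >= obs - 1e-12
        return hits / total if total else float("nan")
    hits = 0
    for _ in range(n_perm):
        mask = np.zeros(n, dtype=bool)
        mask[rng.choice(n, size=k, replace=False)] = True
        d = diff(mask)
        hits += (not np.isnan(d)) and d >= obs - 1e-12
    return (hits + 1) / (n_perm + 1)


def region_diversity_summary(table: pd.DataFrame, regions: dict,
                             position_col: str = "cm", n_perm: int = 10_000,
                             seed: int = 0) -> list:
    """Unweighted regional means of theta_w / theta_pi / Tajima's D.

    ``regions`` maps a label to a ``(low, high)`` interval on
    ``position_col`` (inclusive). Significance of each region mean against
    its complement is assessed by a two-sided permutation of locus-to-region
    labels (undefined Tajima's D values are excluded from means). Empty
    regions raise an error naming the region.
    """
    rng = np.random.default_rng(seed)
    out = []
    pos = table[position_col].to_numpy()
    for label, (lo, hi) in regions.items():
        mask = (pos >= lo) & (pos <= hi)
        if not mask.any():
            raise ValueError(f"region {label!r} contains no loci")
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            means = {c: float(np.nanmean(table[c].to_numpy()[mask]))
                     for c in ("theta_w", "theta_pi", "tajimas_d")}
        ps = {c: _perm_pvalue(table[c].to_numpy(), mask, n_perm, rng)
              for c in ("theta_w", "theta_pi", "tajimas_d")}
        out.append(RegionSummary(label, int(mask.sum()),
                                 means["theta_w"], means["theta_pi"],
                                 means["tajimas_d"], ps["theta_w"],
                                 ps["theta_pi"], ps["tajimas_d"]))
    return out


# ---------------------------------------------------------------------------
# sweep detection

@dataclass
class SweepRegion:
    chrom: str
    start: float
    end: float
    n_loci: int
    loci: tuple


def detect_sweep(table: pd.DataFrame, k: int = 10, fraction: float = 0.1,
                 value_col: str = "theta_pi", position_col: str = "cm") -> list:
    """Maximal runs of >= k consecutive low-diversity loci per chromosome.

    A locus is "low" when its ``value_col`` is below ``fraction`` times the
    chromosome-wide mean. Loci are taken in ``position_col`` order within
    each chromosome. Defaults (k=10, fraction=0.1) are tuned to flag a
    centromeric 30-locus near-zero stretch while leaving a uniform profile
    unflagged.
    """
    regions = []
    for chrom, sub in table.groupby("chrom", sort=True):
        sub = sub.sort_values(position_col, kind="stable")
        mean = float(sub[value_col].mean())
        if mean <= 0:
            continue
        low = (sub[value_col] < fraction * mean).to_numpy()
        i = 0
        while i < len(low):
            if not low[i]:
                i += 1
                continue
            j = i
            while j < len(low) and low[j]:
                j += 1
            if j - i >= k:
                chunk = sub.iloc[i:j]
                regions.append(SweepRegion(
                    chrom=str(chrom),
                    start=float(chunk[position_col].iloc[0]),
                    end=float(chunk[position_col].iloc[-1]),
                    n_loci=j - i, loci=tuple(chunk["locus"])))
            i = j
    return regions


def decompose_diversity(theta_pi_total: float, theta_pi_i: float) -> float:
    """Polyploid decomposition: theta_pi_p = theta_pi_total - theta_pi_i.

    theta_pi_i is the component introgressed from the diploid progenitors;
    the remainder accumulated since the polyploid's origin. Floored at zero
    with a warning when the introgressed component exceeds the total.
    """
    if theta_pi_total < 0 or theta_pi_i < 0:
        raise ValueError("diversity components cannot be negative")
    if theta_pi_i > theta_pi_total:
        warnings.warn("theta_pi_i exceeds theta_pi_total; flooring theta_pi_p at 0")
        return 0.0
    return theta_pi_total - theta_pi_i
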