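"""Linkage-map construction from RIL genotype matrices.

The chain mirrors classic two-point RIL mapping practice:

1. pairwise recombination-fraction (RF) estimation on homozygous calls;
2. co-segregation binning (skeleton marker per bin, bound markers attached);
3. single-linkage clustering into linkage groups at an RF threshold;
4. within-group ordering by minimum adjacent per-meiosis distance with a
   monotony control step that drops order-breaking markers;
5. the Haldane–Waddington per-meiosis correction for selfed RILs,
   r = R / (2(1 - R)), undoing the accumulation of recombination over
   repeated selfing generations;
6. Kosambi map distances d = 25 ln((1+2r)/(1-2r)) cM;
7. graphical-genotype QC blanking heterozygous blocks;
8. chimeric-group detection as reciprocal-translocation evidence.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

from .genotypes import GenotypeMatrix, HET, MISSING, PARENT1, PARENT2

__all__ = [
    "RFMatrix", "MarkerBin", "LinkageGroup", "ChimeraReport",
    "estimate_rf", "bin_markers", "cluster_linkage_groups",
    "order_linkage_group", "rf_to_per_meiosis", "per_meiosis_to_rf",
    "rf_to_per_meiosis_exact", "expected_rf_at_generation",
    "kosambi_cm", "kosambi_r", "build_linkage_group",
    "qc_graphical_genotypes", "detect_chimeric_groups",
]


# ---------------------------------------------------------------------------
# mapping-function arithmetic

def rf_to_per_meiosis(R):
    """Haldane–Waddington inversion for selfed RILs at the inbreeding limit.

    The observed RF in a RIL population, R = 2r/(1+2r), accumulates
    recombination over generations; this returns the per-meiosis r.
    Values R >= 0.5 are capped at r = 0.4999 (effectively unlinked).
    """
    R = np.asarray(R, dtype=float)
    if np.any(R < 0) or np.any(R >= 1):
        raise ValueError("observed RF must lie in [0, 1)")
    r = np.where(R >= 0.5, 0.4999, R / (2.0 * (1.0 - np.minimum(R, 0.499999))))
    r = np.minimum(r, 0.4999)
    return float(r) if r.ndim == 0 else r


def _gamete_dist(h1: int, h2: int, r: float) -> dict:
    # haplotypes code two loci: 0=AB, 1=Ab, 2=aB, 3=ab
    if h1 == h2:
        return {h1: 1.0}
    rec1 = (h1 & 2) | (h2 & 1)
    rec2 = (h2 & 2) | (h1 & 1)
    out: dict = {}
    for h, p in ((h1, (1 - r) / 2), (h2, (1 - r) / 2),
                 (rec1, r / 2), (rec2, r / 2)):
        out[h] = out.get(h, 0.0) + p
    return out


def expected_rf_at_generation(r: float, generations: int) -> float:
    """Expected observed RF among doubly homozygous selfed RILs at F_t.

    Exact two-locus Markov chain over diplotype states from the fully
    heterozygous F1, conditioning on fixation at both loci — the quantity
    the pairwise estimator measures. Converges to the Haldane-Waddington
    limit 2r/(1+2r) as t grows.
    """
    if generations < 2:
        raise ValueError("generations must be >= 2 (F2 or later)")
    dist = {(0, 3): 1.0}                       # F1: AB/ab
    for _ in range(generations - 1):
        new: dict = {}
        for (h1, h2), p in dist.items():
            g = _gamete_dist(h1, h2, r)
            for a, pa in g.items():
                for b, pb in g.items():
                    key = (a, b) if a <= b else (b, a)
                    new[key] = new.get(key, 0.0) + p * pa * pb
        dist = new
    parental = dist.get((0, 0), 0.0) + dist.get((3, 3), 0.0)
    recombinant = dist.get((1, 1), 0.0) + dist.get((2, 2), 0.0)
    total = parental + recombinant
    return recombinant / total if total > 0 else 0.0


def rf_to_per_meiosis_exact(R, generations: int):
    """Invert the generation-exact RIL transform numerically.

    At F6-F8 the F-infinity inversion R/(2(1-R)) under-corrects the
    observed RF by several percent because recombination has not finished
    accumulating; this inversion uses the exact finite-generation
    expectation instead. Falls back to the cap for R at or beyond the
    attainable maximum.
    """
    from scipy.optimize import brentq
    scalar = np.isscalar(R)
    out = []
    for Rv in np.atleast_1d(np.asarray(R, dtype=float)):
        if Rv < 0 or Rv >= 1:
            raise ValueError("observed RF must lie in [0, 1)")
        upper = expected_rf_at_generation(0.4999, generations)
        if Rv <= 0:
            out.append(0.0)
        elif Rv >= upper:
            out.append(0.4999)
        else:
            out.append(brentq(lambda rv: expected_rf_at_generation(rv, generations) - Rv,
                              0.0, 0.4999, xtol=1e-12))
    res = np.array(out)
    return float(res[0]) if scalar else res


def per_meiosis_to_rf(r):
    """Forward Haldane–Waddington map: R = 2r/(1+2r) for selfed RILs."""
    r = np.asarray(r, dtype=float)
    if np.any(r < 0) or np.any(r > 0.5):
        raise ValueError("per-meiosis RF must lie in [0, 0.5]")
    R = 2.0 * r / (1.0 + 2.0 * r)
    return float(R) if R.ndim == 0 else R


def kosambi_cm(r):
    """Kosambi map distance d = 25 ln((1+2r)/(1-2r)) in centimorgans."""
    r = np.asarray(r, dtype=float)
    if np.any(r < 0) or np.any(r >= 0.5):
        raise ValueError("per-meiosis RF must lie in [0, 0.5)")
    d = 25.0 * np.log((1.0 + 2.0 * r) / (1.0 - 2.0 * r))
    return float(d) if d.ndim == 0 else d


def kosambi_r(d):
    """Inverse Kosambi: r = tanh(d/50)/2 for d in centimorgans."""
    d = np.asarray(d, dtype=float)
    if np.any(d < 0):
        raise ValueError("map distance must be non-negative")
    r = 0.5 * np.tanh(d / 50.0)
    return float(r) if r.ndim == 0 else r


# ---------------------------------------------------------------------------
# recombination fractions

@dataclass
class RFMatrix:
    """Symmetric observed-RF matrix with informative-line counts.

    ``rf[i, j]`` is NaN when fewer than ``min_informative`` lines were
    homozygous and non-missing at both markers (flagged undefined, never an
    error).
    """

    rf: np.ndarray
    n_informative: np.ndarray
    marker_ids: list

    def index(self, marker_id: str) -> int:
        return self.marker_ids.index(marker_id)

    def submatrix(self, marker_ids) -> "RFMatrix":
        idx = np.array([self.index(m) for m in marker_ids])
        return RFMatrix(self.rf[np.ix_(idx, idx)], self.n_informative[np.ix_(idx, idx)],
                        list(marker_ids))


def estimate_rf(matrix: GenotypeMatrix, min_informative: int = 50) -> RFMatrix:
    """Observed pairwise RF on homozygous calls.

    R = (# lines with discordant homozygous parent codes) /
        (# lines homozygous and non-missing at both markers).

    Heterozygous and missing calls are excluded from numerator and
    denominator (het-as-missing convention).
    """
    g = matrix.calls
    a = (g == PARENT1).astype(np.float64)
    b = (g == PARENT2).astype(np.float64)
    hom = a + b
    discordant = a.T @ b
    discordant = discordant + discordant.T
    informative = hom.T @ hom
    with np.errstate(divide="ignore", invalid="ignore"):
        rf = discordant / informative
    rf[informative < max(min_informative, 1)] = np.nan
    np.fill_diagonal(rf, 0.0)
    return RFMatrix(rf, informative.astype(np.int64), list(matrix.marker_ids))


# ---------------------------------------------------------------------------
# co-segregation binning

@dataclass
class MarkerBin:
    skeleton: str
    members: list  # all markers of the bin, skeleton included


def bin_markers(matrix: GenotypeMatrix, min_overlap: int = 30) -> list:
    """Group co-segregating markers into bins.

    Two markers are equivalent when their non-missing homozygous calls never
    conflict and they overlap on >= ``min_overlap`` informative lines; bins
    are connected components of that relation. The skeleton representative
    is the member with the fewest missing calls (tie: lexicographically
    smallest ID). Returns bins sorted by skeleton ID.
    """
    g = matrix.calls
    a = (g == PARENT1).astype(np.float64)
    b = (g == PARENT2).astype(np.float64)
    conflicts = a.T @ b
    conflicts = conflicts + conflicts.T
    overlap = (a + b).T @ (a + b)
    adj = (conflicts == 0) & (overlap >= min_overlap)
    np.fill_diagonal(adj, False)
    n_comp, labels = connected_components(csr_matrix(adj), directed=False)
    missing_counts = (g == MISSING).sum(axis=0)
    bins = []
    for c in range(n_comp):
        idx = np.flatnonzero(labels == c)
        members = sorted(matrix.marker_ids[i] for i in idx)
        best = min(idx, key=lambda i: (missing_counts[i], matrix.marker_ids[i]))
        bins.append(MarkerBin(skeleton=matrix.marker_ids[best], members=members))
    bins.sort(key=lambda bn: bn.skeleton)
    return bins


# ---------------------------------------------------------------------------
# linkage-group clustering

def cluster_linkage_groups(rf: RFMatrix, threshold: float = 0.1) -> list:
    """Single-linkage components of the graph with edges R < threshold.

    Undefined (NaN) pairs are non-edges. Returns a list of marker-ID lists,
    largest group first (ties: by first marker ID).
    """
    with np.errstate(invalid="ignore"):
        adj = rf.rf < threshold
    adj &= ~np.isnan(rf.rf)
    np.fill_diagonal(adj, False)
    n_comp, labels = connected_components(csr_matrix(adj), directed=False)
    groups = []
    for c in range(n_comp):
        ids = [rf.marker_ids[i] for i in np.flatnonzero(labels == c)]
        groups.append(sorted(ids))
    groups.sort(key=lambda ids: (-len(ids), ids[0]))
    return groups


# ---------------------------------------------------------------------------
# ordering

def _path_cost(order: np.ndarray, dist: np.ndarray) -> float:
    return float(dist[order[:-1], order[1:]].sum())


def _two_opt(order: np.ndarray, dist: np.ndarray) -> np.ndarray:
    """Best-improvement 2-opt plus single-marker Or-opt moves on a path."""
    order = order.copy()
    n = len(order)
    improved = True
    while improved:
        improved = False
        cost = _path_cost(order, dist)
        best_delta, best_order = 0.0, None
        # 2-opt: reverse order[i:j]
        for i in range(n - 1):
            for j in range(i + 2, n + 1):
                if i == 0 and j == n:
                    continue
                cand = np.concatenate([order[:i], order[i:j][::-1], order[j:]])
                delta = _path_cost(cand, dist) - cost
                if delta < best_delta - 1e-12:
                    best_delta, best_order = delta, cand
        # Or-opt: relocate a single marker
        for i in range(n):
            rest = np.delete(order, i)
            for j in range(n):
                if j == i:
                    continue
                cand = np.insert(rest, j, order[i])
                delta = _path_cost(cand, dist) - cost
                if delta < best_delta - 1e-12:
                    best_delta, best_order = delta, cand
        if best_order is not None:
            order = best_order
            improved = True
    return order


def _monotony_violations(R: np.ndarray, N: np.ndarray) -> int:
    """Count triples i<j<k with observed R(i,k) < max(R(i,j), R(j,k)) - tol.

    tol is twice the binomial standard error of the larger flanking RF
    estimate — a principled allowance for sampling noise.
    """
    n = R.shape[0]
    total = 0
    for j in range(1, n - 1):
        Rij = R[:j, j][:, None]          # i < j
        Rjk = R[j, j + 1:][None, :]      # k > j
        Nij = N[:j, j][:, None].astype(float)
        Njk = N[j, j + 1:][None, :].astype(float)
        Rik = R[:j, j + 1:]
        flank = np.fmax(Rij, Rjk)
        n_fl = np.where(Rij >= Rjk, Nij, Njk)
        with np.errstate(invalid="ignore", divide="ignore"):
            tol = 2.0 * np.sqrt(flank * (1.0 - flank) / np.maximum(n_fl, 1.0))
        viol = Rik < (flank - tol)
        total += int(np.nansum(viol & ~np.isnan(Rik) & ~np.isnan(flank)))
    return total


def order_linkage_group(group, rf: RFMatrix, max_removals: int | None = None):
    """Order a linkage group by minimum adjacent per-meiosis distance.

    Greedy farthest-pair seeding + best-position insertion, refined by
    2-opt/Or-opt, then monotony control: markers whose removal reduces the
    number of non-monotone RF triples are iteratively dropped.

    Returns ``(ordered_ids, removed_ids)``. The orientation of the order is
    arbitrary up to reflection; a canonical reflection (first ID before
    last ID) is applied for determinism.
    """
    group = list(group)
    if len(group) < 2:
        return group, []
    sub = rf.submatrix(group)
    r = rf_to_per_meiosis(np.nan_to_num(sub.rf, nan=0.5))
    np.fill_diagonal(r, 0.0)
    n = len(group)
    # farthest-pair seeding
    i0, j0 = np.unravel_index(np.argmax(r), r.shape)
    order = [int(i0), int(j0)]
    remaining = [k for k in range(n) if k not in order]
    for k in remaining:
        costs = []
        for pos in range(len(order) + 1):
            cand = order[:pos] + [k] + order[pos:]
            costs.append(_path_cost(np.array(cand), r))
        best = int(np.argmin(costs))
        order = order[:best] + [k] + order[best:]
    order = _two_opt(np.array(order), r)

    # monotony control on observed RF along the chosen order
    keep = list(order)
    if max_removals is None:
        max_removals = max(1, n // 5)
    removed_idx = []
    for _ in range(max_removals):
        Ro = sub.rf[np.ix_(keep, keep)]
        No = sub.n_informative[np.ix_(keep, keep)]
        base = _monotony_violations(Ro, No)
        if base == 0:
            break
        best_gain, best_pos = 0, None
        for p in range(len(keep)):
            trial = keep[:p] + keep[p + 1:]
            Rt = sub.rf[np.ix_(trial, trial)]
            Nt = sub.n_informative[np.ix_(trial, trial)]
            gain = base - _monotony_violations(Rt, Nt)
            if gain > best_gain:
                best_gain, best_pos = gain, p
        if best_pos is None:
            break
        removed_idx.append(keep.pop(best_pos))
    if keep and group[keep[0]] > group[keep[-1]]:
        keep = keep[::-1]
    return [group[i] for i in keep], [group[i] for i in removed_idx]


# ---------------------------------------------------------------------------
# map assembly

@dataclass
class LinkageGroup:
    """Ordered skeleton markers with per-meiosis Kosambi cM positions."""

    name: str
    markers: list
    positions_cm: np.ndarray
    bins: dict = field(default_factory=dict)     # skeleton -> bound members
    chromosome: str | None = None

    @property
    def length_cm(self) -> float:
        return float(self.positions_cm[-1]) if len(self.positions_cm) else 0.0

    @property
    def n_bound(self) -> int:
        return sum(len(v) for v in self.bins.values())


def build_linkage_group(name, ordered_markers, rf: RFMatrix, bins=None,
                        chromosome=None, generations: int | None = None) -> LinkageGroup:
    """Cumulative Kosambi cM positions from adjacent observed RFs.

    Each adjacent observed RF is first converted to per-meiosis scale
    (Haldane–Waddington; generation-exact when ``generations`` is given),
    then to cM (Kosambi). Undefined adjacent RFs are treated as R = 0.4999
    (should not occur inside a connected group).
    """
    pos = [0.0]
    for m1, m2 in zip(ordered_markers[:-1], ordered_markers[1:]):
        R = rf.rf[rf.index(m1), rf.index(m2)]
        if np.isnan(R):
            R = 0.4999
        R = min(R, 0.9999)
        r = (rf_to_per_meiosis_exact(R, generations) if generations
             else rf_to_per_meiosis(R))
        pos.append(pos[-1] + kosambi_cm(r))
    binmap = {}
    if bins:
        by_skeleton = {b.skeleton: [m for m in b.members if m != b.skeleton]
                       for b in bins}
        for m in ordered_markers:
            binmap[m] = by_skeleton.get(m, [])
    return LinkageGroup(name, list(ordered_markers), np.asarray(pos), binmap, chromosome)


# ---------------------------------------------------------------------------
# graphical-genotype QC

def qc_graphical_genotypes(matrix: GenotypeMatrix, ordered_lgs, min_block: int = 2):
    """Blank heterozygous blocks along the ordered map, per line.

    Within a line and linkage group, runs of het calls separated by fewer
    than ``min_block`` non-het calls form one heterozygous block; the
    interrupting calls are treated as inconsistent and the whole block is
    set to missing. Returns ``(cleaned_matrix, report)`` where report maps
    line ID -> number of calls blanked.
    """
    cleaned = matrix.calls.copy()
    report: dict = {}
    col_of = {m: j for j, m in enumerate(matrix.marker_ids)}
    for lg in ordered_lgs:
        order = lg.markers if isinstance(lg, LinkageGroup) else list(lg)
        cols = [col_of[m] for m in order if m in col_of]
        for i in range(matrix.n_lines):
            row = cleaned[i, cols]
            het_pos = np.flatnonzero(row == HET)
            if het_pos.size == 0:
                continue
            blocks = []
            start = end = het_pos[0]
            for p in het_pos[1:]:
                # count interrupting non-missing, non-het calls between
                gap = np.sum((row[end + 1:p] != HET) & (row[end + 1:p] != MISSING))
                if gap < min_block:
                    end = p
                else:
                    blocks.append((start, end))
                    start = end = p
            blocks.append((start, end))
            for s, e in blocks:
                seg = slice(s, e + 1)
                n_blanked = int(np.sum(row[seg] != MISSING))
                if n_blanked:
                    report[matrix.line_ids[i]] = report.get(matrix.line_ids[i], 0) + n_blanked
                row[seg] = MISSING
            cleaned[i, cols] = row
    return GenotypeMatrix(cleaned, list(matrix.line_ids), list(matrix.marker_ids)), report


# ---------------------------------------------------------------------------
# chimeric linkage groups / reciprocal translocations

@dataclass
class ChimericGroup:
    lg_name: str
    chromosomes: tuple
    junction_index: int            # order index where majority switches
    junction_markers: tuple        # marker IDs flanking the junction


@dataclass
class ChimeraReport:
    chimeric: list
    reciprocal_pairs: list         # (chrom_pair, [ChimericGroup, ...])
    warning: str | None = None


def detect_chimeric_groups(lgs, assignments: dict, min_markers: int = 3) -> ChimeraReport:
    """Flag linkage groups that join two chromosomes.

    ``assignments`` maps marker ID -> consensus chromosome. An LG with >=
    ``min_markers`` assigned markers from each of >=2 chromosomes is
    chimeric; the junction is the ordered position where the majority
    assignment switches. Two chimeric LGs sharing the same chromosome pair
    are reported as a reciprocal-translocation pair.
    """
    if not assignments:
        return ChimeraReport([], [], warning="no marker-chromosome assignments available")
    chimeric = []
    for lg in lgs:
        order = lg.markers if isinstance(lg, LinkageGroup) else list(lg)
        name = lg.name if isinstance(lg, LinkageGroup) else ",".join(order[:1])
        chroms = [assignments.get(m) for m in order]
        counts: dict = {}
        for c in chroms:
            if c is not None:
                counts[c] = counts.get(c, 0) + 1
        major = sorted((c for c, k in counts.items() if k >= min_markers),
                       key=lambda c: -counts[c])
        if len(major) < 2:
            continue
        c1, c2 = major[0], major[1]
        # junction: cut maximizing (c_left in prefix + c_right in suffix)
        best = (-1, 1, (c1, c2))
        arr = np.array([{c1: 1, c2: 2}.get(c, 0) for c in chroms])
        for left, right in ((1, 2), (2, 1)):
            pre = np.cumsum(arr == left)
            suf = np.cumsum((arr == right)[::-1])[::-1]
            for cut in range(1, len(arr)):
                score = pre[cut - 1] + suf[cut]
                if score > best[0]:
                    best = (score, cut, (c1, c2) if left == 1 else (c2, c1))
        cut = best[1]
        chimeric.append(ChimericGroup(
            lg_name=name, chromosomes=tuple(sorted((c1, c2))),
            junction_index=cut, junction_markers=(order[cut - 1], order[cut])))
    pairs: dict = {}
    for cg in chimeric:
        pairs.setdefault(cg.chromosomes, []).append(cg)
    reciprocal = [(pair, members) for pair, members in sorted(pairs.items())
                  if len(members) >= 2]
    return ChimeraReport(chimeric, reciprocal)
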