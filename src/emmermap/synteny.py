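"""Reference-anchored synteny analysis of a genetic map.

Markers are anchored to reference pseudomolecules through 12-column BLAST
tabular hits, bound markers are ordered within their co-segregation bins by
reference position, maximal collinear runs (strictly monotone stretches of
reference positions along the map) are extracted, and breaks between runs
are classified into chromosome rearrangements: paracentric / pericentric
inversions, intra- and interchromosomal translocations, and reciprocal
translocations (the latter via chimeric-linkage-group evidence).

A run must contain at least three distinct loci to count as collinear;
markers in shorter runs are labelled non-collinear. Multiple assay probes
hitting within ``locus_collapse_bp`` of each other count as a single locus.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

logger = logging.getLogger(__name__)

BLAST_COLUMNS = ("qseqid", "sseqid", "pident", "length", "mismatch", "gapopen",
                 "qstart", "qend", "sstart", "send", "evalue", "bitscore")

__all__ = [
    "AnchorHit", "AnchorSet", "CollinearRun", "RearrangementEvent",
    "RunScan", "ExpandedMap", "Polarity", "PhylogenyResult",
    "load_anchor_hits", "order_bound_markers", "find_collinear_runs",
    "classify_rearrangements", "assign_ancestral_state", "inversion_phylogeny",
]


# ---------------------------------------------------------------------------
# anchoring

@dataclass(frozen=True)
class AnchorHit:
    chrom: str
    start: int          # min(sstart, send): strand never flips positions
    evalue: float
    bitscore: float


@dataclass
class AnchorSet:
    """Best reference hit per marker plus repeat/unanchored flags."""

    best: dict
    hit_count: dict
    unanchored: set
    repeat_derived: set

    def position(self, marker):
        """(chrom, start) of the best hit, or None if unusable."""
        if marker in self.repeat_derived or marker not in self.best:
            return None
        h = self.best[marker]
        return h.chrom, h.start

    def is_usable(self, marker) -> bool:
        return marker in self.best and marker not in self.repeat_derived


def load_anchor_hits(source, evalue_max: float = 1e-5, repeat_threshold: int = 10,
                     marker_ids=None) -> AnchorSet:
    """Parse 12-column BLAST tabular output into an AnchorSet.

    Hits with e-value < ``evalue_max`` are retained; the best hit per marker
    has the lowest e-value, ties broken by highest bit score, then lowest
    (chromosome, start). Markers with more than ``repeat_threshold`` passing
    hits are flagged repeat-derived; markers from ``marker_ids`` with no
    passing hit are flagged unanchored. Malformed rows are skipped with a
    logged warning.
    """
    if isinstance(source, (str, bytes)) or hasattr(source, "__fspath__"):
        with open(source) as fh:
            lines = fh.readlines()
    else:
        lines = list(source)
    hits: dict = {}
    for lineno, line in enumerate(lines, 1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t") if "\t" in line else line.split()
        if len(parts) < 12:
            logger.warning("skipping malformed BLAST row %d: %r", lineno, line[:80])
            continue
        try:
            q, s = parts[0], parts[1]
            sstart, send = int(parts[8]), int(parts[9])
            evalue, bitscore = float(parts[10]), float(parts[11])
        except ValueError:
            logger.warning("skipping malformed BLAST row %d: %r", lineno, line[:80])
            continue
        if not evalue < evalue_max:
            continue
        hits.setdefault(q, []).append(AnchorHit(s, min(sstart, send), evalue, bitscore))
    best, counts = {}, {}
    for q, hs in hits.items():
        counts[q] = len(hs)
        best[q] = min(hs, key=lambda h: (h.evalue, -h.bitscore, h.chrom, h.start))
    repeat = {q for q, c in counts.items() if c > repeat_threshold}
    unanchored = set()
    if marker_ids is not None:
        unanchored = {m for m in marker_ids if m not in best}
    return AnchorSet(best, counts, unanchored, repeat)


# ---------------------------------------------------------------------------
# bound-marker ordering

@dataclass
class ExpandedMap:
    """Per-LG expanded marker order with bin/anchoring metadata.

    ``entries[lg_name]`` is a list of dicts with keys ``marker``, ``skeleton``
    (the bin representative), ``cm``, ``ref_chrom``, ``ref_bp``, ``status``
    (ordered / unordered / unanchored / repeat).
    """

    entries: dict
    unordered_bins: list = field(default_factory=list)

    @property
    def fraction_ordered(self) -> float:
        total = placed = 0
        for rows in self.entries.values():
            for row in rows:
                total += 1
                placed += row["status"] == "ordered"
        return placed / total if total else 0.0

    def lg_markers(self, lg) -> list:
        return [row["marker"] for row in self.entries[lg]]


def _nearest_anchor(positions, k, step):
    j = k + step
    while 0 <= j < len(positions):
        if positions[j] is not None:
            return positions[j]
        j += step
    return None


def _orientation_score(seq):
    """(direction changes, -break gap): lower is a more plausible order.

    A good orientation leaves the local window monotone; when both leave
    one break, the one whose break falls at the larger physical gap wins
    (breakpoints live at big jumps), mirroring the run-segmentation rule.
    """
    diffs = [b - a for a, b in zip(seq[:-1], seq[1:]) if b != a]
    signs = [1 if d > 0 else -1 for d in diffs]
    changes = [i for i in range(1, len(signs)) if signs[i] != signs[i - 1]]
    gap = max((max(abs(diffs[i - 1]), abs(diffs[i])) for i in changes), default=0)
    return (len(changes), -gap)


def order_bound_markers(lgs, anchors: AnchorSet) -> ExpandedMap:
    """Order bound markers within bins by reference position.

    Within each co-segregation bin the anchored markers are sorted by
    reference start, ascending or descending depending on the reference
    positions of the flanking skeleton markers; unanchored and
    repeat-derived markers keep a stable position at the bin end. Bins whose
    flanking skeleton anchors are both missing stay in input order and are
    flagged.
    """
    entries: dict = {}
    unordered_bins = []
    for lg in lgs:
        skeletons = lg.markers
        skel_pos = []
        for m in skeletons:
            p = anchors.position(m)
            skel_pos.append(p[1] if p else None)
        rows = []
        for k, skel in enumerate(skeletons):
            members = [skel] + list(lg.bins.get(skel, []))
            prev_p = _nearest_anchor(skel_pos, k, -1) if k > 0 else None
            next_p = _nearest_anchor(skel_pos, k, +1)
            here = skel_pos[k]
            lo = prev_p if prev_p is not None else here
            hi = next_p if next_p is not None else here
            anchored = [m for m in members if anchors.is_usable(m)]
            rest = [m for m in members if not anchors.is_usable(m)]
            if (lo is None and hi is None) or lo == hi or not anchored:
                if len(members) > 1:
                    unordered_bins.append((lg.name, skel))
                ordered, orientable = members, False
            else:
                starts = sorted(anchors.best[m].start for m in anchored)
                flank_l = [lo] if lo is not None else []
                flank_r = [hi] if hi is not None else []
                asc_score = _orientation_score(flank_l + starts + flank_r)
                desc_score = _orientation_score(flank_l + starts[::-1] + flank_r)
                if asc_score == desc_score:
                    ascending = (hi if hi is not None else 0) > (lo if lo is not None else 0)
                else:
                    ascending = asc_score < desc_score
                ordered = sorted(anchored, key=lambda m: anchors.best[m].start,
                                 reverse=not ascending) + rest
                orientable = True
            cm = float(lg.positions_cm[k])
            for m in ordered:
                p = anchors.position(m)
                if m in anchors.repeat_derived:
                    status = "repeat"
                elif p is None:
                    status = "unanchored"
                elif orientable or len(members) == 1:
                    status = "ordered"
                else:
                    status = "unordered"
                rows.append({"marker": m, "skeleton": skel, "cm": cm,
                             "ref_chrom": p[0] if p else None,
                             "ref_bp": p[1] if p else None,
                             "status": status})
        entries[lg.name] = rows
    return ExpandedMap(entries, unordered_bins)


# ---------------------------------------------------------------------------
# collinear runs

@dataclass
class CollinearRun:
    lg: str
    chrom: str
    direction: str              # "asc" | "desc"
    loci: list                  # [(position, [marker, ...]), ...] in map order
    span: tuple                 # (min bp, max bp)

    @property
    def n_loci(self) -> int:
        return len(self.loci)

    @property
    def markers(self) -> list:
        return [m for _, ms in self.loci for m in ms]

    @property
    def positions(self) -> list:
        return [p for p, _ in self.loci]


@dataclass
class RunScan:
    runs: list                  # CollinearRun with >= min_loci loci, map order
    non_collinear: list         # markers in sub-threshold runs
    outlier_candidates: list    # single loci breaking an otherwise monotone stretch


def _collapse_loci(seq, collapse_bp):
    """Merge consecutive markers within ``collapse_bp`` into single loci."""
    loci = []
    for marker, chrom, pos in seq:
        if loci and loci[-1][0] == chrom and abs(pos - loci[-1][1]) <= collapse_bp:
            loci[-1][2].append(marker)
        else:
            loci.append([chrom, pos, [marker]])
    return loci


def _direction(a, b):
    return "asc" if b > a else ("desc" if b < a else "tie")


def _segment_monotone(loci):
    """Split a same-chromosome locus sequence into maximal monotone runs.

    At a direction change the pivot locus is attached to the side with the
    smaller reference-bp gap (tie: it stays with the preceding run), so a
    breakpoint is placed at the larger physical jump.
    """
    segments = []
    cur = [loci[0]]
    direction = None
    for x in loci[1:]:
        if direction is None:
            d = _direction(cur[-1][1], x[1])
            if d == "tie":
                segments.append(cur)
                cur, direction = [x], None
                continue
            cur.append(x)
            direction = d
            continue
        d = _direction(cur[-1][1], x[1])
        if d == direction:
            cur.append(x)
            continue
        # violation: decide where the pivot (last of cur) belongs
        if len(cur) >= 2 and d != "tie":
            gap_prev = abs(cur[-1][1] - cur[-2][1])
            gap_next = abs(x[1] - cur[-1][1])
            if gap_next < gap_prev:
                pivot = cur.pop()
                segments.append(cur)
                cur, direction = [pivot, x], d
                continue
        segments.append(cur)
        cur, direction = [x], None
    segments.append(cur)
    return segments


def _segment_all(loci):
    """Chromosome-aware monotone segmentation of a locus sequence."""
    blocks = []
    cur = [loci[0]]
    for loc in loci[1:]:
        if loc[0] == cur[-1][0]:
            cur.append(loc)
        else:
            blocks.append(cur)
            cur = [loc]
    blocks.append(cur)
    segments = []
    for block in blocks:
        segments.extend(_segment_monotone(block))
    return [s for s in segments if s]


def _seg_dir(seg):
    if len(seg) < 2:
        return "single"
    return "asc" if seg[-1][1] > seg[0][1] else "desc"


def _mergeable_across(a, b):
    """Would runs a and b form one monotone run if joined directly?"""
    if a[-1][0] != b[0][0]:
        return False
    da, db = _seg_dir(a), _seg_dir(b)
    d = da if da != "single" else db
    if db != "single" and da != "single" and da != db:
        return False
    if d == "single":
        d = _direction(a[-1][1], b[0][1])
    step = _direction(a[-1][1], b[0][1])
    return step == d


def find_collinear_runs(expanded: ExpandedMap, anchors: AnchorSet, min_loci: int = 3,
                        locus_collapse_bp: int = 2000) -> dict:
    """Extract maximal strictly monotone runs per linkage group.

    Repeat-derived and unanchored markers are excluded before the scan.
    Sub-threshold runs (< ``min_loci`` distinct loci) are labelled
    non-collinear and removed iteratively — an interrupting short run whose
    flanking runs merge monotonically without it is removed first, then the
    remaining loci are re-segmented — so that, e.g., a two-locus insertion
    inside an otherwise monotone stretch leaves one long collinear run.
    Returns ``{lg_name: RunScan}``.
    """
    results = {}
    for lg_name, rows in expanded.entries.items():
        seq = [(r["marker"], r["ref_chrom"], r["ref_bp"]) for r in rows
               if r["ref_chrom"] is not None and anchors.is_usable(r["marker"])]
        runs, non_col, outliers = [], [], []
        if seq:
            loci = _collapse_loci(seq, locus_collapse_bp)
            while loci:
                segments = _segment_all(loci)
                short = [i for i, s in enumerate(segments) if len(s) < min_loci]
                if not short:
                    runs = segments
                    break
                # prefer an interrupting short run: removal lets flanks merge
                pick = None
                for i in short:
                    if 0 < i < len(segments) - 1 and \
                            _mergeable_across(segments[i - 1], segments[i + 1]):
                        pick = i
                        break
                if pick is None:
                    pick = min(short, key=lambda i: len(segments[i]))
                removed = segments[pick]
                markers = [m for s in removed for m in s[2]]
                non_col.extend(markers)
                if len(removed) == 1 and 0 < pick < len(segments) - 1:
                    outliers.extend(markers)
                drop = {id(s) for s in removed}
                loci = [s for s in loci if id(s) not in drop]
            collinear_runs = []
            for seg in runs:
                positions = [s[1] for s in seg]
                collinear_runs.append(CollinearRun(
                    lg=lg_name, chrom=seg[0][0],
                    direction="asc" if positions[-1] > positions[0] else "desc",
                    loci=[(s[1], list(s[2])) for s in seg],
                    span=(min(positions), max(positions))))
            runs = collinear_runs
        results[lg_name] = RunScan(runs, non_col, sorted(set(outliers)))
    return results


# ---------------------------------------------------------------------------
# rearrangement classification

@dataclass
class RearrangementEvent:
    """A classified structural change, one record per event (Table-2 shape)."""

    type: str
    chromosome: str
    lg: str | None = None
    arm: str | None = None
    markers: tuple = ()
    span: tuple | None = None
    segment_length_bp: int | None = None
    traversed_bp: int | None = None
    polarity: str = "unresolved"
    notes: str = ""

    def __post_init__(self):
        if self.span is not None and self.segment_length_bp is None:
            self.segment_length_bp = int(self.span[1] - self.span[0])


def _arm_label(chrom, span, centromeres):
    cen = centromeres.get(chrom) if centromeres else None
    if cen is None:
        return None
    if span[1] < cen[0]:
        return f"{chrom}S"
    if span[0] > cen[1]:
        return f"{chrom}L"
    return f"{chrom}C"


def _overlaps(span, interval):
    return span[0] <= interval[1] and interval[0] <= span[1]


def _make_event(etype, run, centromeres, **kw):
    return RearrangementEvent(
        type=etype, chromosome=run.chrom, lg=run.lg,
        arm=_arm_label(run.chrom, kw.get("span", run.span), centromeres),
        markers=tuple(kw.pop("markers", run.markers)),
        span=kw.pop("span", run.span), **kw)


def _traversed(block_span, flank_positions):
    """Reference-bp gap between a moved block and its insertion junction."""
    flanks = [p for p in flank_positions if p is not None]
    if not flanks:
        return None
    if block_span[0] > max(flanks):
        return int(block_span[0] - max(flanks))
    if block_span[1] < min(flanks):
        return int(min(flanks) - block_span[1])
    gaps = [g for g in (min(flanks) - block_span[1], block_span[0] - max(flanks)) if g > 0]
    return int(min(gaps)) if gaps else 0


def _extract_moved_block(a: CollinearRun, b: CollinearRun):
    """Moved block from two out-of-sequence same-direction adjacent runs.

    Candidates: the part of the later run invading the earlier run's span,
    and the part of the earlier run beyond the later run's start. The block
    with the smaller bp span is deemed moved (tie: leftmost in reference).
    """
    if a.direction == "asc":
        block_b = [(p, ms) for p, ms in b.loci if p <= a.span[1]]
        block_a = [(p, ms) for p, ms in a.loci if p >= b.span[0]]
    else:
        block_b = [(p, ms) for p, ms in b.loci if p >= a.span[0]]
        block_a = [(p, ms) for p, ms in a.loci if p <= b.span[1]]
    cands = []
    for owner, block in (("a", block_a), ("b", block_b)):
        if block:
            pos = [p for p, _ in block]
            cands.append((max(pos) - min(pos), min(pos), owner, block))
    if not cands:
        return None
    cands.sort(key=lambda c: (c[0], c[1]))
    _, _, owner, block = cands[0]
    pos = [p for p, _ in block]
    span = (min(pos), max(pos))
    # map-adjacent flanking loci around the moved block
    if owner == "b":
        before = a.loci[-1][0] if a.loci[-1] not in block else None
        after_loci = [pl for pl in b.loci if pl not in block]
        after = after_loci[0][0] if after_loci else None
        flanks = (before, after)
    else:
        before_loci = [pl for pl in a.loci if pl not in block]
        before = before_loci[-1][0] if before_loci else None
        after = b.loci[0][0] if b.loci else None
        flanks = (before, after)
    markers = [m for _, ms in block for m in ms]
    return span, markers, flanks


def classify_rearrangements(scans: dict, centromeres: dict | None = None,
                            lg_assignments: dict | None = None,
                            chimera_report=None, min_loci: int = 3) -> list:
    """Classify breaks between collinear runs into rearrangement events.

    * a run opposing the direction of its flanking same-chromosome runs,
      with an in-sequence span, is an inversion — pericentric when the span
      overlaps the centromere interval, paracentric otherwise (unknown when
      no centromere table is supplied);
    * a run (or part of a run) whose span is out of sequence with its
      flanks on the same chromosome is an intrachromosomal translocation;
      the shorter candidate block is deemed moved (tie: leftmost) and the
      traversed distance is the reference-bp gap between the block and its
      insertion junction;
    * runs on a different chromosome than the linkage-group assignment are
      interchromosomal translocations — reciprocal when complementary
      chimeric-LG evidence exists, in which case a single reciprocal record
      per chromosome pair is emitted.
    """
    centromeres = centromeres or {}
    lg_assignments = lg_assignments or {}
    events = []
    reciprocal_pairs = set()
    if chimera_report is not None:
        reciprocal_pairs = {pair for pair, _ in chimera_report.reciprocal_pairs}
    emitted_reciprocal = set()

    for lg_name, scan in scans.items():
        runs = scan.runs
        if not runs:
            continue
        lg_chrom = lg_assignments.get(lg_name)
        if lg_chrom is None:
            weights: dict = {}
            for r in runs:
                weights[r.chrom] = weights.get(r.chrom, 0) + r.n_loci
            lg_chrom = max(sorted(weights), key=lambda c: weights[c])

        # foreign-chromosome runs
        for run in runs:
            if run.chrom == lg_chrom:
                continue
            pair = tuple(sorted((run.chrom, lg_chrom)))
            if pair in reciprocal_pairs:
                if pair not in emitted_reciprocal:
                    emitted_reciprocal.add(pair)
                    members = [cg for p, cgs in chimera_report.reciprocal_pairs
                               if p == pair for cg in cgs]
                    events.append(RearrangementEvent(
                        type="reciprocal_translocation",
                        chromosome="-".join(pair), lg=lg_name,
                        arm=f"{pair[0]} centromere/{pair[1]} centromere",
                        markers=tuple(m for cg in members for m in cg.junction_markers),
                        notes="chimeric linkage groups: "
                              + ",".join(cg.lg_name for cg in members)))
            else:
                events.append(_make_event(
                    "interchromosomal_translocation", run, centromeres,
                    notes=f"inserted in LG assigned to {lg_chrom}"))

        same = [r for r in runs if r.chrom == lg_chrom]
        handled = set()

        # displaced blocks between adjacent same-direction runs
        for i in range(len(same) - 1):
            a, b = same[i], same[i + 1]
            if a.direction != b.direction:
                continue
            out_of_order = (b.span[0] <= a.span[1]) if a.direction == "asc" \
                else (b.span[1] >= a.span[0])
            if not out_of_order:
                continue
            extracted = _extract_moved_block(a, b)
            if extracted is None:
                continue
            span, markers, flanks = extracted
            if len({p for p, _ in a.loci + b.loci
                    if span[0] <= p <= span[1]}) < min_loci:
                # the moved block falls below the three-locus rule
                handled.update((i, i + 1))
                continue
            events.append(RearrangementEvent(
                type="intrachromosomal_translocation", chromosome=a.chrom,
                lg=lg_name, arm=_arm_label(a.chrom, span, centromeres),
                markers=tuple(markers), span=span,
                traversed_bp=_traversed(span, flanks)))
            handled.update((i, i + 1))

        # inversions and whole-run displacements
        for i, run in enumerate(same):
            prev_r = same[i - 1] if i > 0 else None
            next_r = same[i + 1] if i + 1 < len(same) else None
            if prev_r is None and next_r is None:
                continue
            flank_dirs = {r.direction for r in (prev_r, next_r) if r is not None}
            opposes = flank_dirs and run.direction not in flank_dirs and len(flank_dirs) == 1
            # in-sequence check against flanks
            lo = prev_r.span if prev_r else None
            hi = next_r.span if next_r else None
            context_dir = next(iter(flank_dirs)) if len(flank_dirs) == 1 else None
            in_sequence = True
            if context_dir == "asc":
                if lo and run.span[0] < lo[1]:
                    in_sequence = False
                if hi and run.span[1] > hi[0]:
                    in_sequence = False
            elif context_dir == "desc":
                if lo and run.span[1] > lo[0]:
                    in_sequence = False
                if hi and run.span[0] < hi[1]:
                    in_sequence = False
            if opposes and in_sequence:
                if run.chrom in centromeres:
                    etype = ("pericentric_inversion"
                             if _overlaps(run.span, centromeres[run.chrom])
                             else "paracentric_inversion")
                else:
                    etype = "inversion"
                events.append(_make_event(etype, run, centromeres))
            elif not in_sequence and i not in handled and not opposes:
                flanks = (lo[1] if lo and context_dir == "asc" else (lo[0] if lo else None),
                          hi[0] if hi and context_dir == "asc" else (hi[1] if hi else None))
                events.append(_make_event(
                    "intrachromosomal_translocation", run, centromeres,
                    traversed_bp=_traversed(run.span, flanks)))
    return events


# ---------------------------------------------------------------------------
# ancestral states and inversion phylogeny

@dataclass
class Polarity:
    status: str                   # "resolved" | "unresolved"
    ancestral_order: str | None   # "same" | "inverted"
    derived_genomes: tuple = ()
    warning: str | None = None


def assign_ancestral_state(orders: dict, outgroups) -> Polarity:
    """Polarize an inversion from marker orders across genomes.

    ``orders`` maps genome name to "same" or "inverted" (relative to an
    arbitrary reference order); missing genomes may map to None. The order
    shared by the strict majority of outgroups is ancestral; ingroup genomes
    with the alternative order are derived. Outgroup tie or absence gives
    an unresolved polarity.
    """
    out_states = [orders.get(o) for o in outgroups if orders.get(o) in ("same", "inverted")]
    if not out_states:
        return Polarity("unresolved", None, warning="no outgroup data")
    n_same = sum(s == "same" for s in out_states)
    n_inv = len(out_states) - n_same
    if n_same == n_inv:
        return Polarity("unresolved", None, warning="outgroup tie")
    ancestral = "same" if n_same > n_inv else "inverted"
    derived = tuple(sorted(g for g, s in orders.items()
                           if g not in outgroups and s is not None and s != ancestral))
    return Polarity("resolved", ancestral, derived)


@dataclass
class CladeNode:
    genomes: tuple
    children: list = field(default_factory=list)
    characters: list = field(default_factory=list)

    def to_newick(self, top=True) -> str:
        if len(self.genomes) == 1 and not self.children:
            s = self.genomes[0]
        else:
            s = "(" + ",".join(c.to_newick(top=False) for c in self.children) + ")"
        return s + ";" if top else s


@dataclass
class PhylogenyResult:
    tree: CladeNode | None
    edge_characters: dict         # character name -> tuple of genomes (its clade)
    conflicts: list               # [(char1, char2), ...]

    @property
    def newick(self) -> str | None:
        return self.tree.to_newick() if self.tree else None


def inversion_phylogeny(characters: dict, genomes) -> PhylogenyResult:
    """Perfect phylogeny from binary derived-state characters.

    ``characters`` maps a character name (e.g. an inversion) to the set of
    genomes carrying the derived state. Characters are treated as
    irreversible (Dollo); a tree exists iff the derived sets are pairwise
    nested or disjoint, in which case each character is assigned to the
    edge subtending its derived clade. Incompatible pairs are reported and
    no tree is forced. Output is invariant to character input order.
    """
    genomes = tuple(sorted(genomes))
    sets = {name: frozenset(s) & frozenset(genomes) for name, s in characters.items()}
    names = sorted(sets)
    conflicts = []
    for i, n1 in enumerate(names):
        for n2 in names[i + 1:]:
            s1, s2 = sets[n1], sets[n2]
            if s1 & s2 and not (s1 <= s2 or s2 <= s1):
                conflicts.append((n1, n2))
    edge_chars = {name: tuple(sorted(s)) for name, s in sets.items()}
    if conflicts:
        return PhylogenyResult(None, edge_chars, conflicts)
    # laminar family -> containment tree
    clades = sorted({s for s in sets.values() if s}, key=lambda s: (-len(s), sorted(s)))
    root = CladeNode(genomes)
    node_of = {frozenset(genomes): root}
    for s in clades:
        if s in node_of:
            continue
        # smallest strict superset among existing nodes
        supersets = [t for t in node_of if s < t]
        parent = node_of[min(supersets, key=len)]
        node = CladeNode(tuple(sorted(s)))
        parent.children.append(node)
        node_of[s] = node
    # attach leaves to the smallest containing clade
    for g in genomes:
        containing = [t for t in node_of if g in t]
        parent = node_of[min(containing, key=len)]
        if len(parent.genomes) > 1:
            parent.children.append(CladeNode((g,)))
    # collapse: a clade of one genome is the leaf itself
    def _tidy(node):
        new_children = []
        for c in node.children:
            _tidy(c)
            if len(c.genomes) == 1 and len(c.children) == 1:
                new_children.append(c.children[0])
            else:
                new_children.append(c)
        node.children = sorted(new_children, key=lambda c: min(c.genomes))
    _tidy(root)
    for name, s in sets.items():
        if s in node_of:
            node_of[s].characters.append(name)
    return PhylogenyResult(root, edge_chars, [])
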