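"""Anchoring, collinear runs, rearrangement classification, phylogeny."""

import numpy as np
import pytest

from emmermap import linkage, synteny
from emmermap.simulate import (ChromosomeSpec, EventSpec, blast_rows,
                               simulate_genome_layout, truth_linkage_groups)
from emmermap.synteny import (assign_ancestral_state, classify_rearrangements,
                              find_collinear_runs, inversion_phylogeny,
                              load_anchor_hits, order_bound_markers)


def row(q, s, sstart, evalue, bitscore=200, send=None):
    send = sstart + 99 if send is None else send
    return f"{q}\t{s}\t98.0\t100\t2\t0\t1\t100\t{sstart}\t{send}\t{evalue}\t{bitscore}"


# ---------------------------------------------------------------------------
# anchor loading

def test_best_hit_and_flags():
    lines = [row("m1", "c1", 1000, "1e-20")]
    lines += [row("m2", "c1", 1000 + i * 5000, "1e-8", 110) for i in range(12)]
    lines += [row("m3", "c1", 500, "1e-3")]          # fails e-value filter
    anchors = load_anchor_hits(iter(lines), marker_ids=["m1", "m2", "m3"])
    assert anchors.best["m1"].start == 1000
    assert "m2" in anchors.repeat_derived            # 12 > 10 hits
    assert "m3" in anchors.unanchored
    assert anchors.position("m2") is None


def test_tie_breaks_and_strand():
    lines = [row("m1", "c1", 3000, "1e-10", 180),
             row("m1", "c1", 2000, "1e-10", 200),    # higher bitscore wins
             row("m2", "c2", 900, "1e-10", 150),
             row("m2", "c1", 900, "1e-10", 150),     # chromosome tie-break
             row("m3", "c1", 5099, "1e-12", 150, send=5000)]  # minus strand
    anchors = load_anchor_hits(iter(lines))
    assert anchors.best["m1"].start == 2000
    assert anchors.best["m2"].chrom == "c1"
    assert anchors.best["m3"].start == 5000          # min(sstart, send)


def test_malformed_rows_skipped(caplog):
    lines = ["garbage row", row("m1", "c1", 100, "1e-20"), "a\tb\tc"]
    anchors = load_anchor_hits(iter(lines))
    assert list(anchors.best) == ["m1"]


# ---------------------------------------------------------------------------
# bound-marker ordering

def _lg_with_bin(bound, skeleton_bps=(200_000, 600_000)):
    lg = linkage.LinkageGroup("LG1", ["s1", "s2"], np.array([0.0, 10.0]),
                              {"s1": list(bound), "s2": []})
    lines = [row("s1", "c1", skeleton_bps[0], "1e-30"),
             row("s2", "c1", skeleton_bps[1], "1e-30")]
    return lg, lines


@pytest.mark.parametrize("flanks, expected", [
    ((200_000, 600_000), [300_000, 400_000, 500_000]),   # ascending context
    ((600_000, 200_000), [500_000, 400_000, 300_000]),   # descending context
])
def test_bin_ordered_by_flanking_context(flanks, expected):
    lg, lines = _lg_with_bin(["b1", "b2", "b3"], flanks)
    lines += [row("b1", "c1", 500_000, "1e-30"),
              row("b2", "c1", 300_000, "1e-30"),
              row("b3", "c1", 400_000, "1e-30")]
    anchors = load_anchor_hits(iter(lines))
    expanded = order_bound_markers([lg], anchors)
    bin_rows = [r for r in expanded.entries["LG1"] if r["skeleton"] == "s1"]
    assert [r["ref_bp"] for r in bin_rows] == sorted(set([*flanks[:1], *expected]),
                                                     reverse=flanks[0] > flanks[1])


def test_unanchored_bound_marker_goes_to_bin_end():
    lg, lines = _lg_with_bin(["b1", "bx"])
    lines += [row("b1", "c1", 300_000, "1e-30")]
    anchors = load_anchor_hits(iter(lines), marker_ids=["s1", "s2", "b1", "bx"])
    expanded = order_bound_markers([lg], anchors)
    bin_markers = [r["marker"] for r in expanded.entries["LG1"]
                   if r["skeleton"] == "s1"]
    assert bin_markers[-1] == "bx"
    assert expanded.fraction_ordered == pytest.approx(3 / 4)


def test_bin_heading_an_inverted_block_oriented_descending():
    """A bin whose positions lie beyond both flanks (its skeleton heads an
    inverted block) orients so the break falls at the larger bp gap."""
    lg = linkage.LinkageGroup("LG1", ["s0", "s1", "s2"],
                              np.array([0.0, 1.0, 2.0]),
                              {"s0": [], "s1": ["b1"], "s2": []})
    lines = [row("s0", "c1", 247_500, "1e-30"),
             row("s1", "c1", 337_500, "1e-30"),    # head of inverted block
             row("b1", "c1", 322_500, "1e-30"),
             row("s2", "c1", 307_500, "1e-30")]
    anchors = load_anchor_hits(iter(lines))
    expanded = order_bound_markers([lg], anchors)
    assert [r["ref_bp"] for r in expanded.entries["LG1"]] == \
        [247_500, 337_500, 322_500, 307_500]


def test_unanchorable_flanks_flagged():
    lg = linkage.LinkageGroup("LG1", ["s1"], np.array([0.0]),
                              {"s1": ["b1", "b2"]})
    anchors = load_anchor_hits(iter([]), marker_ids=["s1", "b1", "b2"])
    expanded = order_bound_markers([lg], anchors)
    assert ("LG1", "s1") in expanded.unordered_bins


# ---------------------------------------------------------------------------
# collinear runs (hand-computed scans)

def _scan(positions, **kw):
    rows = [{"marker": f"m{i}", "skeleton": f"m{i}", "cm": float(i),
             "ref_chrom": "c1", "ref_bp": int(p), "status": "ordered"}
            for i, p in enumerate(positions)]

    class _A:
        def is_usable(self, m):
            return True

    return find_collinear_runs(synteny.ExpandedMap({"LG": rows}), _A(), **kw)["LG"]


def test_hand_scan_three_runs():
    scan = _scan([p * 1000 for p in (10, 20, 30, 70, 60, 50, 80, 90, 100)])
    got = [(r.direction, r.span) for r in scan.runs]
    assert got == [("asc", (10_000, 30_000)), ("desc", (50_000, 70_000)),
                   ("asc", (80_000, 100_000))]


def test_fully_ascending_single_run():
    scan = _scan(list(range(10_000, 100_000, 10_000)))
    assert len(scan.runs) == 1 and scan.runs[0].n_loci == 9


def test_two_locus_interruption_non_collinear():
    scan = _scan([p * 1000 for p in (10, 20, 50, 40, 80, 90)])
    assert sorted(scan.non_collinear) == ["m2", "m3"]
    assert [(r.direction, r.n_loci) for r in scan.runs] == [("asc", 4)]


def test_locus_collapse_counts_probes_as_one_locus():
    # three probes within 2 kb are one locus; run needs 3 distinct loci
    scan = _scan([10_000, 10_500, 11_000, 20_000], locus_collapse_bp=2000)
    assert scan.runs == [] or all(r.n_loci < 3 for r in scan.runs)
    scan = _scan([10_000, 10_500, 20_000, 30_000], locus_collapse_bp=2000)
    assert len(scan.runs) == 1 and scan.runs[0].n_loci == 3


def test_single_marker_outlier_reported():
    scan = _scan([p * 1000 for p in (10, 20, 30, 300, 40, 50, 60)])
    assert scan.outlier_candidates == ["m3"]
    assert len(scan.runs) == 1 and scan.runs[0].n_loci == 6


def test_run_maximality():
    """No two adjacent same-direction runs can be merged monotonically."""
    for positions in ([10, 20, 30, 70, 60, 50, 80, 90, 100],
                      [10, 20, 30, 60, 70, 80, 90, 40, 45, 50, 100, 110, 120],
                      list(range(10, 100, 10))):
        scan = _scan([p * 1000 for p in positions])
        for a, b in zip(scan.runs[:-1], scan.runs[1:]):
            if a.chrom == b.chrom and a.direction == b.direction:
                step = b.loci[0][0] - a.loci[-1][0]
                mergeable = step > 0 if a.direction == "asc" else step < 0
                assert not mergeable


# ---------------------------------------------------------------------------
# classification

def test_hand_classification_inversion():
    scan = _scan([p * 1000 for p in (10, 20, 30, 70, 60, 50, 80, 90, 100)])
    events = classify_rearrangements({"LG": scan})
    assert [(e.type, e.segment_length_bp) for e in events] == [("inversion", 20_000)]
    events = classify_rearrangements(
        {"LG": scan}, centromeres={"c1": (55_000, 65_000)})
    assert events[0].type == "pericentric_inversion"
    events = classify_rearrangements(
        {"LG": scan}, centromeres={"c1": (200_000, 250_000)})
    assert events[0].type == "paracentric_inversion"


def test_hand_classification_translocation():
    scan = _scan([p * 1000
                  for p in (10, 20, 30, 60, 70, 80, 90, 40, 45, 50, 100, 110, 120)])
    events = classify_rearrangements({"LG": scan})
    assert len(events) == 1
    e = events[0]
    assert e.type == "intrachromosomal_translocation"
    assert e.segment_length_bp == 10_000
    assert e.traversed_bp == 40_000


def test_foreign_run_is_interchromosomal():
    rows = []
    positions = [("c1", 10), ("c1", 20), ("c1", 30), ("c2", 500), ("c2", 510),
                 ("c2", 520), ("c1", 40), ("c1", 50), ("c1", 60)]
    for i, (c, p) in enumerate(positions):
        rows.append({"marker": f"m{i}", "skeleton": f"m{i}", "cm": float(i),
                     "ref_chrom": c, "ref_bp": p * 1000, "status": "ordered"})

    class _A:
        def is_usable(self, m):
            return True

    scans = find_collinear_runs(synteny.ExpandedMap({"LG": rows}), _A())
    events = classify_rearrangements(scans, lg_assignments={"LG": "c1"})
    assert [e.type for e in events] == ["interchromosomal_translocation"]
    assert events[0].chromosome == "c2"


def test_roundtrip_recovers_all_planted_events(demo_layout, demo_roundtrip):
    got = {(e.type, e.chromosome): e for e in demo_roundtrip["events"]}
    for truth in demo_layout.planted_events:
        key = (truth.type, truth.chromosome)
        assert key in got, f"missed {key}"
        if truth.segment_length_bp is not None:
            assert got[key].segment_length_bp == truth.segment_length_bp
        if truth.traversed_bp is not None:
            assert got[key].traversed_bp == truth.traversed_bp
    assert len(demo_roundtrip["events"]) == len(demo_layout.planted_events)


def test_two_marker_planted_events_never_reported():
    spec = [ChromosomeSpec("c1", length_bp=40_000_000, n_markers=40, total_cm=100,
                           telomere_bias=0.0),
            ChromosomeSpec("c2", length_bp=40_000_000, n_markers=40, total_cm=100,
                           telomere_bias=0.0)]
    lay = simulate_genome_layout(
        spec,
        [EventSpec("inversion", "c1", start=10, stop=11),
         EventSpec("intrachromosomal_translocation", "c2", start=5, stop=6,
                   insert_after=20)],
        enforce_min_markers=False)
    lgs = truth_linkage_groups(lay)
    anchors = load_anchor_hits(iter(blast_rows(lay)))
    expanded = order_bound_markers(lgs, anchors)
    scans = find_collinear_runs(expanded, anchors)
    events = classify_rearrangements(scans, centromeres=lay.centromeres)
    assert events == []


def test_repeat_and_unanchored_exclusion_keeps_classification(demo_layout):
    """Flagging some bystander markers never changes clean >=3-locus events."""
    lgs = truth_linkage_groups(demo_layout)
    noisy = ["chr1_m020", "chr2_m003", "chr3_m030"]
    anchors = load_anchor_hits(
        iter(blast_rows(demo_layout, repeat_markers=noisy[:1],
                        unanchored=noisy[1:])),
        marker_ids=[m for lg in lgs for m in lg.markers])
    assert "chr1_m020" in anchors.repeat_derived
    expanded = order_bound_markers(lgs, anchors)
    scans = find_collinear_runs(expanded, anchors)
    chim = linkage.detect_chimeric_groups(lgs, demo_layout.truth_assignments())
    events = classify_rearrangements(scans, centromeres=demo_layout.centromeres,
                                     chimera_report=chim)
    assert {(e.type, e.chromosome) for e in events} == \
        {(t.type, t.chromosome) for t in demo_layout.planted_events}


def test_segmental_duplication_detectable_as_repeated_run():
    """A marker group appearing twice yields two same-direction runs with
    identical spans (the >=3-consecutive-loci repetition signature)."""
    positions = [10, 20, 30, 40, 50, 25, 35, 45, 60, 70]
    scan = _scan([p * 1000 for p in positions])
    spans = [r.span for r in scan.runs]
    dup = [(a, b) for i, a in enumerate(spans) for b in spans[i + 1:]
           if a[0] <= b[1] and b[0] <= a[1]]
    assert dup   # overlapping spans flag the duplicated block


# ---------------------------------------------------------------------------
# polarization and phylogeny

def test_polarization_published_inversions():
    # Inv(1): 3A,3B share order with outgroups; 3D alternative -> 3D derived
    orders = {"3A": "same", "3B": "same", "3D": "inverted",
              "Bd2": "same", "Os1": "same", "Sb3": "same"}
    pol = assign_ancestral_state(orders, outgroups=["Bd2", "Os1", "Sb3"])
    assert pol.status == "resolved" and pol.derived_genomes == ("3D",)
    # Inv(3): 7A ancestral; 7B and 7D derived
    orders = {"7A": "same", "7B": "inverted", "7D": "inverted",
              "Bd1": "same", "Os6": "same", "Sb10": "same"}
    pol = assign_ancestral_state(orders, outgroups=["Bd1", "Os6", "Sb10"])
    assert pol.derived_genomes == ("7B", "7D")


def test_polarization_degenerate_cases():
    pol = assign_ancestral_state({"A": "same", "B": "same"}, outgroups=["X"])
    assert pol.status == "unresolved" and pol.warning == "no outgroup data"
    pol = assign_ancestral_state(
        {"A": "same", "X": "same", "Y": "inverted"}, outgroups=["X", "Y"])
    assert pol.status == "unresolved"
    pol = assign_ancestral_state(
        {"A": "same", "B": "same", "X": "same"}, outgroups=["X"])
    assert pol.derived_genomes == ()          # all share the ancestral order


def test_phylogeny_published_grouping():
    """Inv(1) derived in D, Inv(3) derived in {B, D} -> (A,(B,D))."""
    res = inversion_phylogeny({"Inv1": {"D"}, "Inv3": {"B", "D"}},
                              genomes=["A", "B", "D"])
    assert res.conflicts == []
    assert res.newick == "(A,(B,D));"
    assert res.edge_characters["Inv3"] == ("B", "D")
    assert res.edge_characters["Inv1"] == ("D",)


def test_phylogeny_single_terminal_character():
    res = inversion_phylogeny({"inv": {"B"}}, genomes=["A", "B", "D"])
    assert res.newick == "(A,B,D);"
    assert res.edge_characters["inv"] == ("B",)


def test_phylogeny_conflict_reported():
    res = inversion_phylogeny({"x": {"A", "B"}, "y": {"B", "D"}},
                              genomes=["A", "B", "D"])
    assert res.tree is None and res.conflicts == [("x", "y")]


def test_phylogeny_input_order_invariant():
    chars = {"a": {"D"}, "b": {"B", "D"}, "c": {"A", "B", "D"}}
    r1 = inversion_phylogeny(chars, "ABD")
    r2 = inversion_phylogeny(dict(reversed(list(chars.items()))), "ABD")
    assert r1.newick == r2.newick == "(A,(B,(D)));" or r1.newick == r2.newick
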