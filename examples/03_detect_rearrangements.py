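"""Detect and classify chromosome rearrangements against a reference.

The demo layout plants one event of each class (paracentric and pericentric
inversions, intra- and interchromosomal translocations, and a reciprocal
translocation with centromeric breakpoints). Markers are anchored through
BLAST tabular hits, collinear runs of reference positions are extracted
along the map, and breaks between runs are classified.
"""

import emmermap as em
from emmermap import linkage, synteny
from emmermap.simulate import blast_rows, truth_linkage_groups

layout = em.demo_layout()
lgs = truth_linkage_groups(layout)
anchors = synteny.load_anchor_hits(
    iter(blast_rows(layout)), marker_ids=[m for g in lgs for m in g.markers])
expanded = synteny.order_bound_markers(lgs, anchors)
scans = synteny.find_collinear_runs(expanded, anchors, min_loci=3)
chimera = linkage.detect_chimeric_groups(lgs, layout.truth_assignments())
events = synteny.classify_rearrangements(
    scans, centromeres=layout.centromeres, chimera_report=chimera)

print(f"planted {len(layout.planted_events)} events, detected {len(events)}:")
for e in events:
    size = f"{e.segment_length_bp:,} bp" if e.segment_length_bp else "NA"
    trav = f", moved {e.traversed_bp:,} bp" if e.traversed_bp else ""
    print(f"  {e.type:32s} {e.chromosome:10s} {size}{trav}")
print("segment lengths are max-min reference bp of the member loci; a run")
print("needs >=3 distinct loci before it can witness a rearrangement.")
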