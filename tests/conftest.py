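import numpy as np
import pytest

import emmermap as em
from emmermap import linkage, synteny
from emmermap.simulate import (ChromosomeSpec, SimConfig, blast_rows,
                               simulate_genome_layout, simulate_ril_population,
                               truth_linkage_groups)


@pytest.fixture(scope="session")
def demo_layout():
    return em.demo_layout()


@pytest.fixture(scope="session")
def demo_roundtrip(demo_layout):
    """Truth-order map of the demo layout pushed through the synteny chain."""
    lgs = truth_linkage_groups(demo_layout)
    anchors = synteny.load_anchor_hits(
        iter(blast_rows(demo_layout)),
        marker_ids=[m for lg in lgs for m in lg.markers])
    expanded = synteny.order_bound_markers(lgs, anchors)
    scans = synteny.find_collinear_runs(expanded, anchors)
    chimera = linkage.detect_chimeric_groups(lgs, demo_layout.truth_assignments())
    events = synteny.classify_rearrangements(
        scans, centromeres=demo_layout.centromeres, chimera_report=chimera)
    return {"lgs": lgs, "anchors": anchors, "expanded": expanded,
            "scans": scans, "chimera": chimera, "events": events}


@pytest.fixture(scope="session")
def clean_two_chrom_population():
    """Two rearrangement-free chromosomes, 500 error-free lines."""
    layout = simulate_genome_layout([
        ChromosomeSpec("cA", length_bp=400_000_000, n_markers=40,
                       total_cm=100.0, telomere_bias=0.5),
        ChromosomeSpec("cB", length_bp=400_000_000, n_markers=40,
                       total_cm=100.0, telomere_bias=0.5),
    ])
    cfg = SimConfig(n_lines=500, final_generation=7, genotyping_error=0.0,
                    missing_rate=0.0, seed=11)
    observed, truth = simulate_ril_population(layout, cfg)
    return layout, observed, truth


def rf_from_true_cm(cm_positions, n_informative=500):
    """Noise-free observed-RF matrix implied by true cM positions.

    Adjacent/total distances map to per-meiosis r via the inverse Kosambi
    function and then to RIL-observed R via the Haldane-Waddington forward
    map — the exact expectation the estimator targets.
    """
    cm = np.asarray(cm_positions, dtype=float)
    d = np.abs(cm[:, None] - cm[None, :])
    r = linkage.kosambi_r(d)
    R = linkage.per_meiosis_to_rf(r)
    ids = [f"t{i}" for i in range(len(cm))]
    return linkage.RFMatrix(R, np.full_like(R, n_informative, dtype=np.int64), ids)
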