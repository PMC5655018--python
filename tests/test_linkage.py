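"""Map construction: RF estimation, binning, clustering, ordering, QC."""

import itertools

import numpy as np
import pytest
from scipy.stats import kendalltau

from emmermap import linkage
from emmermap.genotypes import GenotypeMatrix
from emmermap.linkage import (bin_markers, build_linkage_group,
                              cluster_linkage_groups, detect_chimeric_groups,
                              estimate_rf, order_linkage_group,
                              qc_graphical_genotypes)
from emmermap.simulate import ChromosomeSpec, SimConfig, \
    simulate_genome_layout, simulate_ril_population

from conftest import rf_from_true_cm


def gm(rows, marker_ids=None):
    return GenotypeMatrix(np.array(rows, dtype=np.int8), marker_ids=marker_ids)


# ---------------------------------------------------------------------------
# RF estimation

def test_rf_direct_count():
    # 6 lines: 4 concordant, 2 discordant homozygous pairs -> R = 2/6
    m = gm([[0, 0], [0, 0], [2, 2], [2, 2], [0, 2], [2, 0]])
    rf = estimate_rf(m, min_informative=1)
    assert rf.rf[0, 1] == pytest.approx(2 / 6)
    assert rf.n_informative[0, 1] == 6


def test_rf_identical_columns_zero():
    m = gm([[0, 0], [2, 2], [0, 0], [2, 2]])
    assert estimate_rf(m, min_informative=1).rf[0, 1] == 0.0


def test_rf_het_and_missing_excluded():
    # het / missing rows contribute to neither numerator nor denominator
    m = gm([[0, 0], [1, 0], [0, -1], [2, 0], [2, 2]])
    rf = estimate_rf(m, min_informative=1)
    assert rf.n_informative[0, 1] == 3
    assert rf.rf[0, 1] == pytest.approx(1 / 3)


def test_rf_all_het_column_undefined():
    m = gm([[1, 0], [1, 2], [1, 0], [1, 2]])
    rf = estimate_rf(m, min_informative=1)
    assert np.isnan(rf.rf[0, 1])


def test_rf_min_informative_flags():
    m = gm([[0, 0], [2, 2], [0, 0], [2, 2]])
    assert np.isnan(estimate_rf(m, min_informative=5).rf[0, 1])


# ---------------------------------------------------------------------------
# binning

def test_identical_columns_one_bin():
    m = gm([[0, 0, 2], [2, 2, 0], [0, 0, 0], [2, 2, 2]], ["a", "b", "c"])
    bins = bin_markers(m, min_overlap=3)
    assert sorted(tuple(b.members) for b in bins) == [("a", "b"), ("c",)]


def test_missing_cell_still_cobinned_and_skeleton_choice():
    m = gm([[0, 0], [2, 2], [0, -1], [2, 2]], ["a", "b"])
    bins = bin_markers(m, min_overlap=3)
    assert len(bins) == 1
    assert bins[0].skeleton == "a"          # fewest missing calls


def test_single_conflict_separates():
    m = gm([[0, 0], [2, 2], [0, 2], [2, 2]], ["a", "b"])
    assert len(bin_markers(m, min_overlap=2)) == 2


def test_binning_partition_and_order_invariance():
    rng = np.random.default_rng(3)
    base = rng.integers(0, 2, size=(40, 6)) * 2
    calls = np.repeat(base, 2, axis=1)       # 12 markers, duplicated pairs
    calls[rng.random(calls.shape) < 0.1] = -1
    ids = [f"m{i}" for i in range(12)]
    m = GenotypeMatrix(calls.astype(np.int8), marker_ids=ids)
    bins = bin_markers(m, min_overlap=10)
    seen = sorted(x for b in bins for x in b.members)
    assert seen == sorted(ids)               # a partition
    perm = list(rng.permutation(12))
    m2 = GenotypeMatrix(calls[:, perm].astype(np.int8),
                        marker_ids=[ids[i] for i in perm])
    bins2 = bin_markers(m2, min_overlap=10)
    assert sorted(tuple(b.members) for b in bins) == \
        sorted(tuple(b.members) for b in bins2)


# ---------------------------------------------------------------------------
# clustering

def test_two_blocks_two_groups():
    R = np.full((6, 6), 0.45)
    R[:3, :3] = 0.05
    R[3:, 3:] = 0.05
    np.fill_diagonal(R, 0.0)
    rf = linkage.RFMatrix(R, np.full((6, 6), 100), [f"m{i}" for i in range(6)])
    groups = cluster_linkage_groups(rf, threshold=0.1)
    assert sorted(map(len, groups)) == [3, 3]


def test_threshold_zero_all_singletons():
    R = np.full((4, 4), 0.05)
    np.fill_diagonal(R, 0.0)
    rf = linkage.RFMatrix(R, np.full((4, 4), 100), list("abcd"))
    assert all(len(g) == 1 for g in cluster_linkage_groups(rf, threshold=0.0))


def test_simulated_two_chromosomes_cluster_to_truth(clean_two_chrom_population):
    layout, observed, _ = clean_two_chrom_population
    rf = estimate_rf(observed, min_informative=50)
    groups = cluster_linkage_groups(rf, threshold=0.1)
    big = [g for g in groups if len(g) > 1]
    assert len(big) == 2
    truth = layout.truth_assignments()
    for g in big:
        assert len({truth[m] for m in g}) == 1


# ---------------------------------------------------------------------------
# ordering

def test_noise_free_equidistant_order_recovered():
    rf = rf_from_true_cm([0, 5, 10, 15, 20])
    shuffled = ["t3", "t0", "t4", "t2", "t1"]
    order, removed = order_linkage_group(shuffled, rf)
    assert removed == []
    idx = [int(m[1:]) for m in order]
    assert idx == sorted(idx) or idx == sorted(idx)[::-1]


def test_two_marker_group_reflection_symmetric():
    rf = rf_from_true_cm([0, 10])
    order, removed = order_linkage_group(["t0", "t1"], rf)
    assert sorted(order) == ["t0", "t1"] and removed == []


def test_ordering_matches_exhaustive_optimum():
    """Heuristic adjacent-distance sum equals brute-force permutation minimum."""
    rng = np.random.default_rng(7)
    for trial in range(6):
        n = rng.integers(5, 9)
        cm = np.sort(rng.uniform(0, 60, size=n))
        rf = rf_from_true_cm(cm)
        noise = rng.normal(0, 0.01, size=(n, n))
        R = np.clip(rf.rf + noise + noise.T, 0, 0.95)
        np.fill_diagonal(R, 0)
        rf = linkage.RFMatrix(R, rf.n_informative, rf.marker_ids)
        r = linkage.rf_to_per_meiosis(R)

        def cost(perm):
            return sum(r[perm[i], perm[i + 1]] for i in range(len(perm) - 1))

        best = min(cost(p) for p in itertools.permutations(range(n)))
        order, _ = order_linkage_group(list(rf.marker_ids), rf)
        got = cost([rf.marker_ids.index(m) for m in order])
        assert got == pytest.approx(best, abs=1e-9), f"trial {trial}"


def test_simulated_lg_order_perfect_kendall(clean_two_chrom_population):
    layout, observed, _ = clean_two_chrom_population
    markers = [f"cA_m{i:03d}" for i in range(30)]
    rf = estimate_rf(observed, min_informative=50).submatrix(
        sorted(markers, key=lambda m: hash(m)))
    order, removed = order_linkage_group(rf.marker_ids, rf)
    truth_rank = [int(m.split("_m")[1]) for m in order]
    tau = kendalltau(truth_rank, range(len(order))).statistic
    assert abs(tau) == pytest.approx(1.0)
    assert removed == []


def test_map_length_recovered_within_ten_percent(clean_two_chrom_population):
    layout, observed, _ = clean_two_chrom_population
    rf = estimate_rf(observed, min_informative=50)
    groups = [g for g in cluster_linkage_groups(rf, 0.1) if len(g) > 1]
    assert len(groups) == 2
    total = 0.0
    for g in groups:
        order, _ = order_linkage_group(g, rf)
        lg = build_linkage_group("lg", order, rf, generations=7)
        total += lg.length_cm
    assert total == pytest.approx(layout.total_cm, rel=0.10)


def test_generation_exact_transform_converges_to_limit():
    """The finite-generation expectation approaches 2r/(1+2r), from below."""
    for r in (0.05, 0.2, 0.4):
        limit = linkage.per_meiosis_to_rf(r)
        R7 = linkage.expected_rf_at_generation(r, 7)
        R40 = linkage.expected_rf_at_generation(r, 40)
        assert R7 < limit
        assert R40 == pytest.approx(limit, rel=1e-6)
        # roundtrip of the exact inversion
        assert linkage.rf_to_per_meiosis_exact(R7, 7) == pytest.approx(r, abs=1e-9)


# ---------------------------------------------------------------------------
# graphical-genotype QC

def test_isolated_call_inside_het_block_blanked():
    m = gm([[1, 1, 0, 1, 1], [0, 0, 0, 0, 0]],
           [f"m{i}" for i in range(5)])
    cleaned, report = qc_graphical_genotypes(
        m, [[f"m{i}" for i in range(5)]], min_block=2)
    assert (cleaned.calls[0] == -1).all()      # whole block missing
    assert (cleaned.calls[1] == 0).all()       # het-free line unchanged
    assert report == {"RIL1": 5}


def test_het_block_at_lg_end_blanked():
    m = gm([[0, 0, 0, 1, 1], [0, 2, 0, 2, 0]], [f"m{i}" for i in range(5)])
    cleaned, _ = qc_graphical_genotypes(m, [[f"m{i}" for i in range(5)]], min_block=2)
    assert list(cleaned.calls[0]) == [0, 0, 0, -1, -1]


def test_separated_het_runs_stay_separate():
    # two het calls separated by >= min_block homozygous calls: two blocks,
    # the homozygous stretch between them survives
    m = gm([[1, 0, 0, 1, 2], [0, 0, 0, 0, 0]], [f"m{i}" for i in range(5)])
    cleaned, _ = qc_graphical_genotypes(m, [[f"m{i}" for i in range(5)]], min_block=2)
    assert list(cleaned.calls[0]) == [-1, 0, 0, -1, 2]


# ---------------------------------------------------------------------------
# chimeric linkage groups

def _lg(name, markers):
    return linkage.LinkageGroup(name, markers, np.arange(len(markers), dtype=float))


def test_clean_lg_not_flagged():
    lg = _lg("LG1", [f"a{i}" for i in range(6)])
    rep = detect_chimeric_groups([lg], {m: "c1" for m in lg.markers})
    assert rep.chimeric == [] and rep.reciprocal_pairs == []


def test_single_stray_marker_below_rule():
    markers = [f"a{i}" for i in range(6)]
    assign = {m: "c1" for m in markers}
    assign["a3"] = "c2"
    rep = detect_chimeric_groups([_lg("LG1", markers)], assign)
    assert rep.chimeric == []


def test_no_assignments_warns():
    rep = detect_chimeric_groups([_lg("LG1", ["a", "b", "c"])], {})
    assert rep.warning is not None and rep.chimeric == []


def test_reciprocal_translocation_population_gives_two_chimeric_lgs():
    """A carrier-parent 2-chromosome cross yields complementary chimeric LGs
    with junctions at the centromeric breakpoints."""
    from emmermap.simulate import EventSpec
    layout = simulate_genome_layout(
        [ChromosomeSpec("c1", n_markers=30, total_cm=100, telomere_bias=0.5),
         ChromosomeSpec("c2", n_markers=30, total_cm=100, telomere_bias=0.5)],
        [EventSpec("reciprocal_translocation", "c1", target_chromosome="c2",
                   break_index=15, partner_break_index=15)])
    observed, _ = simulate_ril_population(
        layout, SimConfig(n_lines=400, genotyping_error=0.0, missing_rate=0.0,
                          seed=5))
    rf = estimate_rf(observed, min_informative=50)
    groups = [g for g in cluster_linkage_groups(rf, 0.1) if len(g) > 1]
    lgs = []
    for i, g in enumerate(groups):
        order, _ = order_linkage_group(g, rf)
        lgs.append(build_linkage_group(f"LG{i}", order, rf))
    rep = detect_chimeric_groups(lgs, layout.truth_assignments())
    assert len(rep.chimeric) == 2
    assert len(rep.reciprocal_pairs) == 1
    pair, members = rep.reciprocal_pairs[0]
    assert pair == ("c1", "c2")
    # junction markers flank the planted break (marker index 15 on each)
    for cg in members:
        idx = sorted(int(m.split("_m")[1]) for m in cg.junction_markers)
        assert 13 <= idx[0] <= 16 and 14 <= idx[1] <= 17
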