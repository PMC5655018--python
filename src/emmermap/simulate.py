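"""Synthetic study system: reference layouts, RIL populations, diversity panels.

This module generates everything downstream stages consume, with known
truth, emulating a Langdon x wild-emmer style single-seed-descent (SSD)
mapping population: a reference genome layout with markers and planted
chromosome rearrangements of every class, an F6-F8 RIL genotype matrix
with genotyping error and missing data, BLAST-tabular anchor hits against
the reference, and a per-locus sequence-diversity panel with an optional
low-diversity sweep region.

Meiosis uses Poisson crossovers with uniform placement on the cM scale (no
interference; Haldane model). Rearrangements other than a reciprocal
translocation are treated as homozygous in the cross (shared by both
parents), so meiosis operates on the rearranged marker order; a reciprocal
translocation is carried by one parent only and is modelled by running
meiosis on the carrier's translocated chromosome structure, which produces
the pseudo-linkage across the two centromeres that makes linkage groups
chimeric.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genotypes import GenotypeMatrix
from .synteny import RearrangementEvent

__all__ = [
    "ChromosomeSpec", "EventSpec", "SimConfig", "ReferenceLayout",
    "simulate_genome_layout", "simulate_ril_population",
    "simulate_diversity_panel", "make_locus_table", "truth_linkage_groups",
    "blast_rows", "write_blast_tabular", "demo_layout",
]


# ---------------------------------------------------------------------------
# specifications

@dataclass
class ChromosomeSpec:
    """One reference chromosome: physical size, marker count, genetic length.

    ``telomere_bias`` in [0, 1) shapes the bp->cM profile: the local
    recombination rate is proportional to 1 + bias*cos(2*pi*x/L), high at
    the telomeres and low around the centromere, the canonical Triticeae
    pattern.
    """

    name: str
    length_bp: int = 600_000_000
    n_markers: int = 40
    total_cm: float = 120.0
    centromere: tuple | None = None      # bp interval; default middle 10%
    telomere_bias: float = 0.8

    def __post_init__(self):
        if self.n_markers < 2:
            raise ValueError(f"{self.name}: need >=2 markers per chromosome")
        if self.centromere is None:
            self.centromere = (int(0.45 * self.length_bp), int(0.55 * self.length_bp))


@dataclass
class EventSpec:
    """A planted rearrangement, indices into the current marker arrangement.

    ``start``/``stop`` are 0-based inclusive marker indices on
    ``chromosome``; translocations give ``insert_after`` (index after whose
    marker the block lands, -1 for the front), interchromosomal ones add
    ``target_chromosome``; a reciprocal translocation instead gives
    ``break_index`` on ``chromosome`` and ``partner_break_index`` on
    ``target_chromosome`` (first index of the exchanged tail).
    """

    type: str
    chromosome: str
    start: int = 0
    stop: int = 0
    insert_after: int | None = None
    target_chromosome: str | None = None
    break_index: int | None = None
    partner_break_index: int | None = None


@dataclass
class SimConfig:
    """Population-simulation parameters for an SSD RIL panel.

    Defaults emulate the study conditions: 445 independent RILs advanced to
    roughly F7 by single seed descent; small genotyping-error and missing
    rates typical of array genotyping (the original population's rates are
    not published).
    """

    n_lines: int = 445
    final_generation: int = 7
    genotyping_error: float = 0.002
    missing_rate: float = 0.01
    crossover_model: str = "haldane"
    seed: int = 0
    allow_zero_length: bool = False

    def __post_init__(self):
        if self.n_lines < 1:
            raise ValueError("n_lines must be >= 1")
        if self.final_generation < 2:
            raise ValueError("final_generation must be >= 2")
        for p in (self.genotyping_error, self.missing_rate):
            if not 0.0 <= p <= 1.0:
                raise ValueError("rates must lie in [0, 1]")
        if self.crossover_model != "haldane":
            raise ValueError("only the Poisson/Haldane crossover model is implemented")


# ---------------------------------------------------------------------------
# layout

@dataclass
class ReferenceLayout:
    """Reference genome layout plus the map-order truth.

    ``markers`` has one row per marker: marker, chrom, pos_bp (1-based
    reference position), cm (true genetic position before rearrangement).
    ``arrangements`` encodes the map order actually segregating in the
    cross: LG name -> DataFrame (marker, ref_chrom, ref_bp, cm), with
    rearranged blocks moved/reversed and reciprocal-translocation products
    as chimeric LGs. ``planted_events`` are the truth records.
    """

    chromosomes: dict
    markers: pd.DataFrame
    arrangements: dict
    planted_events: list = field(default_factory=list)
    sweep_region: tuple | None = None     # (chrom, start_bp, end_bp, factor)

    @property
    def centromeres(self) -> dict:
        return {name: spec.centromere for name, spec in self.chromosomes.items()}

    @property
    def total_cm(self) -> float:
        return float(sum(df["cm"].iloc[-1] for df in self.arrangements.values()))

    def truth_assignments(self) -> dict:
        """marker -> reference chromosome (consensus-map surrogate)."""
        return dict(zip(self.markers["marker"], self.markers["chrom"]))


def _cm_profile(u: np.ndarray, bias: float) -> np.ndarray:
    # integral of 1 + bias*cos(2 pi u), normalised to [0, 1]
    return u + bias * np.sin(2.0 * np.pi * u) / (2.0 * np.pi)


def simulate_genome_layout(chromosomes, events=(), sweep_region=None,
                           enforce_min_markers: bool = True) -> ReferenceLayout:
    """Build a reference layout and apply planted rearrangements.

    Markers are evenly spaced along each chromosome; the pre-rearrangement
    genetic position is the telomere-biased profile of the physical
    position. Events are applied in order to the running arrangement.
    With ``enforce_min_markers`` (default), an inversion or translocation
    spanning fewer than 3 markers is rejected, because such an event can
    never satisfy the three-locus collinearity rule downstream and would be
    undetectable by construction.
    """
    chrom_specs = {c.name: c for c in chromosomes}
    rows = []
    for spec in chrom_specs.values():
        pos = np.round((np.arange(spec.n_markers) + 0.5)
                       * spec.length_bp / spec.n_markers).astype(np.int64)
        u = pos / spec.length_bp
        cm = spec.total_cm * _cm_profile(u, spec.telomere_bias)
        for i in range(spec.n_markers):
            rows.append({"marker": f"{spec.name}_m{i:03d}", "chrom": spec.name,
                         "pos_bp": int(pos[i]), "cm": float(cm[i])})
    markers = pd.DataFrame(rows)

    arr = {spec.name: [(r["marker"], r["chrom"], r["pos_bp"])
                       for r in rows if r["chrom"] == spec.name]
           for spec in chrom_specs.values()}
    truth = []

    for ev in events:
        if ev.type == "reciprocal_translocation":
            a, b = ev.chromosome, ev.target_chromosome
            ia, ib = ev.break_index, ev.partner_break_index
            A, B = arr.pop(a), arr.pop(b)
            lg1, lg2 = f"{a}-{b}_1", f"{a}-{b}_2"
            arr[lg1] = A[:ia] + B[ib:]
            arr[lg2] = B[:ib] + A[ia:]
            truth.append(RearrangementEvent(
                type="reciprocal_translocation", chromosome=f"{a}-{b}",
                lg=f"{lg1}+{lg2}",
                markers=(A[ia - 1][0], A[ia][0], B[ib - 1][0], B[ib][0]),
                notes="breakpoints at centromeric junctions"))
            continue
        seq = arr[ev.chromosome]
        n_block = ev.stop - ev.start + 1
        if n_block < 3 and enforce_min_markers:
            raise ValueError(
                f"planted {ev.type} on {ev.chromosome} spans {n_block} marker(s); "
                "events need >=3 markers to be detectable under the "
                "three-locus collinearity rule")
        block = seq[ev.start:ev.stop + 1]
        bps = [p for _, _, p in block]
        span = (min(bps), max(bps))
        if ev.type in ("inversion", "paracentric_inversion", "pericentric_inversion"):
            arr[ev.chromosome] = seq[:ev.start] + block[::-1] + seq[ev.stop + 1:]
            cen = chrom_specs[ev.chromosome].centromere
            actual = ("pericentric_inversion"
                      if span[0] <= cen[1] and cen[0] <= span[1]
                      else "paracentric_inversion")
            if ev.type != "inversion" and ev.type != actual:
                raise ValueError(
                    f"event declared {ev.type} but span {span} vs centromere {cen} "
                    f"makes it a {actual}")
            truth.append(RearrangementEvent(
                type=actual, chromosome=ev.chromosome,
                markers=tuple(m for m, _, _ in block), span=span))
        elif ev.type == "intrachromosomal_translocation":
            rest = seq[:ev.start] + seq[ev.stop + 1:]
            j = ev.insert_after
            if ev.start <= j <= ev.stop:
                raise ValueError("insertion point lies inside the moved block")
            jj = j if j < ev.start else j - n_block
            arr[ev.chromosome] = rest[:jj + 1] + block + rest[jj + 1:]
            if j < ev.start:             # block moved left; junction flank on right
                flank_bp = seq[j + 1][2]
                traversed = span[0] - flank_bp
            else:                        # block moved right; junction flank on left
                flank_bp = seq[j][2]
                traversed = flank_bp - span[1]
            truth.append(RearrangementEvent(
                type="intrachromosomal_translocation", chromosome=ev.chromosome,
                markers=tuple(m for m, _, _ in block), span=span,
                traversed_bp=int(traversed)))
        elif ev.type == "interchromosomal_translocation":
            arr[ev.chromosome] = seq[:ev.start] + seq[ev.stop + 1:]
            tgt = arr[ev.target_chromosome]
            j = ev.insert_after
            arr[ev.target_chromosome] = tgt[:j + 1] + block + tgt[j + 1:]
            truth.append(RearrangementEvent(
                type="interchromosomal_translocation", chromosome=ev.chromosome,
                lg=ev.target_chromosome,
                markers=tuple(m for m, _, _ in block), span=span))
        else:
            raise ValueError(f"unknown event type {ev.type!r}")

    arrangements = {}
    for lg_name, seq in arr.items():
        n = len(seq)
        total_cm = sum(chrom_specs[c].total_cm / chrom_specs[c].n_markers
                       for _, c, _ in seq)
        bias = np.mean([chrom_specs[c].telomere_bias for _, c, _ in seq])
        u = np.arange(n) / max(n - 1, 1)
        cm = total_cm * _cm_profile(u, float(bias))
        arrangements[lg_name] = pd.DataFrame(
            {"marker": [m for m, _, _ in seq],
             "ref_chrom": [c for _, c, _ in seq],
             "ref_bp": [p for _, _, p in seq],
             "cm": cm})
    return ReferenceLayout(chrom_specs, markers, arrangements, truth, sweep_region)


def demo_layout(sweep_factor: float = 0.02) -> ReferenceLayout:
    """Seven-chromosome demo layout with one planted event of each class.

    Chromosomes are 600 Mb / 120 cM with 40 evenly spaced markers each;
    planted: a paracentric and a pericentric inversion, an intra- and an
    interchromosomal translocation, a reciprocal translocation with
    centromeric breakpoints, and a centromeric sweep region on chr1 sized
    so that 30 of 110 evenly spaced diversity loci fall inside it.
    """
    chroms = [ChromosomeSpec(f"chr{i}") for i in range(1, 8)]
    events = [
        EventSpec("paracentric_inversion", "chr1", start=5, stop=9),
        EventSpec("pericentric_inversion", "chr2", start=17, stop=22),
        EventSpec("intrachromosomal_translocation", "chr3", start=8, stop=10,
                  insert_after=25),
        EventSpec("interchromosomal_translocation", "chr4", start=30, stop=33,
                  target_chromosome="chr5", insert_after=20),
        EventSpec("reciprocal_translocation", "chr6", target_chromosome="chr7",
                  break_index=20, partner_break_index=20),
    ]
    sweep = ("chr1", int(40 * 600e6 / 110), int(70 * 600e6 / 110), sweep_factor)
    return simulate_genome_layout(chroms, events, sweep_region=sweep)


# ---------------------------------------------------------------------------
# RIL population

def _meiosis(h1, h2, cm, rng):
    """One gamete from a heterozygous individual: Poisson crossovers, uniform
    on the cM scale, no interference."""
    L = cm[-1] - cm[0]
    k = rng.poisson(L / 100.0) if L > 0 else 0
    if k:
        breaks = np.sort(rng.uniform(cm[0], cm[-1], size=k))
        seg = np.searchsorted(breaks, cm, side="right")
    else:
        seg = np.zeros(len(cm), dtype=np.int64)
    choice = (seg + rng.integers(2)) % 2
    return np.where(choice == 0, h1, h2)


def simulate_ril_population(layout: ReferenceLayout, config: SimConfig):
    """Simulate an SSD RIL genotype matrix plus its error-free truth.

    The F1 is fully heterozygous; each subsequent generation draws two
    gametes from the same individual (selfing). Genotyping error flips a
    call to a uniformly chosen different code; missing entries are injected
    independently. Returns ``(observed, truth)`` GenotypeMatrix objects with
    markers in a seed-determined shuffled column order.
    """
    ss = np.random.SeedSequence(config.seed).spawn(4)
    rng_meiosis = np.random.default_rng(ss[0])
    rng_err = np.random.default_rng(ss[1])
    rng_miss = np.random.default_rng(ss[2])
    rng_shuffle = np.random.default_rng(ss[3])

    lg_cms, lg_markers = [], []
    for name, df in sorted(layout.arrangements.items()):
        cm = df["cm"].to_numpy()
        if len(cm) > 1 and cm[-1] - cm[0] <= 0 and not config.allow_zero_length:
            raise ValueError(
                f"LG {name} has a zero-length map with {len(cm)} markers; "
                "they would be perfectly linked (set allow_zero_length to permit)")
        lg_cms.append(cm)
        lg_markers.append(list(df["marker"]))

    n_rounds = config.final_generation - 1
    genotypes = []
    for _ in range(config.n_lines):
        line = []
        for cm in lg_cms:
            m = len(cm)
            h1, h2 = np.zeros(m, dtype=np.int8), np.ones(m, dtype=np.int8)
            for _ in range(n_rounds):
                g1 = _meiosis(h1, h2, cm, rng_meiosis)
                g2 = _meiosis(h1, h2, cm, rng_meiosis)
                h1, h2 = g1, g2
            line.append((h1 + h2).astype(np.int8))     # 0 / 1 / 2
        genotypes.append(np.concatenate(line))
    truth_calls = np.array(genotypes, dtype=np.int8)
    marker_ids = [m for ms in lg_markers for m in ms]

    calls = truth_calls.copy()
    if config.genotyping_error > 0:
        flip = rng_err.random(calls.shape) < config.genotyping_error
        # uniformly chosen different code among {0,1,2}
        shift = rng_err.integers(1, 3, size=calls.shape)
        calls = np.where(flip, (calls + shift) % 3, calls).astype(np.int8)
    if config.missing_rate > 0:
        calls = np.where(rng_miss.random(calls.shape) < config.missing_rate,
                         np.int8(-1), calls)

    order = rng_shuffle.permutation(len(marker_ids))
    marker_ids = [marker_ids[i] for i in order]
    observed = GenotypeMatrix(calls[:, order], marker_ids=marker_ids)
    truth = GenotypeMatrix(truth_calls[:, order],
                           line_ids=list(observed.line_ids), marker_ids=list(marker_ids))
    return observed, truth


def truth_linkage_groups(layout: ReferenceLayout) -> list:
    """The layout's arrangements as perfectly ordered linkage groups.

    Each marker is its own bin; useful for exercising downstream stages on
    error-free map truth.
    """
    from .linkage import LinkageGroup
    return [LinkageGroup(name, list(df["marker"]), df["cm"].to_numpy(),
                         {m: [] for m in df["marker"]})
            for name, df in sorted(layout.arrangements.items())]


# ---------------------------------------------------------------------------
# anchor hits (12-column BLAST tabular)

def blast_rows(layout: ReferenceLayout, repeat_markers=(), unanchored=(),
               n_repeat_hits: int = 12) -> list:
    """Emit one best hit per marker (plus decoy hits for repeat markers).

    qseqid sseqid pident length mismatch gapopen qstart qend sstart send
    evalue bitscore. Markers in ``unanchored`` are omitted entirely.
    """
    rows = []
    repeat_markers, unanchored = set(repeat_markers), set(unanchored)
    for rec in layout.markers.itertuples():
        if rec.marker in unanchored:
            continue
        rows.append(f"{rec.marker}\t{rec.chrom}\t98.00\t100\t2\t0\t1\t100\t"
                    f"{rec.pos_bp}\t{rec.pos_bp + 99}\t1e-40\t190")
        if rec.marker in repeat_markers:
            for k in range(n_repeat_hits - 1):
                pos = rec.pos_bp + (k + 1) * 1_000_000
                rows.append(f"{rec.marker}\t{rec.chrom}\t90.00\t100\t10\t0\t1\t100\t"
                            f"{pos}\t{pos + 99}\t1e-08\t110")
    return rows


def write_blast_tabular(layout: ReferenceLayout, path, **kw) -> None:
    with open(path, "w") as fh:
        fh.write("\n".join(blast_rows(layout, **kw)) + "\n")


# ---------------------------------------------------------------------------
# diversity panel (coalescent)

def _neutral_branches(n, rng):
    """Kingman coalescent: [(leafset, branch length)] in 2N-generation units."""
    active = [frozenset({i}) for i in range(n)]
    acc = {ls: 0.0 for ls in active}
    branches = []
    while len(active) > 1:
        k = len(active)
        dt = rng.exponential(2.0 / (k * (k - 1)))
        for ls in active:
            acc[ls] += dt
        i, j = sorted(rng.choice(k, size=2, replace=False))
        b, a = active.pop(j), active.pop(i)
        branches.append((a, acc.pop(a)))
        branches.append((b, acc.pop(b)))
        new = a | b
        active.append(new)
        acc[new] = 0.0
    return branches


def _simulate_locus(n, mut_rate, rng, star_depth=None):
    """Infinite-sites mutations on a genealogy; returns an (n, S) 0/1 matrix.

    ``mut_rate`` is mutations per unit branch length (= theta*L/2).
    ``star_depth`` switches to a star genealogy of that depth (post-sweep
    model): every branch external, all mutations singletons.
    """
    if star_depth is not None:
        branches = [(frozenset({i}), float(star_depth)) for i in range(n)]
    else:
        branches = _neutral_branches(n, rng)
    total = sum(b for _, b in branches)
    n_mut = rng.poisson(mut_rate * total) if total > 0 else 0
    if n_mut == 0:
        return np.zeros((n, 0), dtype=np.int8)
    probs = np.array([b for _, b in branches]) / total
    picks = rng.choice(len(branches), size=n_mut, p=probs)
    mat = np.zeros((n, n_mut), dtype=np.int8)
    for col, b_idx in enumerate(picks):
        for leaf in branches[b_idx][0]:
            mat[leaf, col] = 1
    return mat


def make_locus_table(layout: ReferenceLayout, n_per_chrom: int = 110,
                     length_bp: int = 2000, chrom: str | None = None) -> pd.DataFrame:
    """Evenly spaced diversity loci (one chromosome or all)."""
    names = [chrom] if chrom else list(layout.chromosomes)
    rows = []
    for name in names:
        L = layout.chromosomes[name].length_bp
        for i in range(n_per_chrom):
            pos = int((i + 0.5) * L / n_per_chrom)
            rows.append({"locus": f"{name}_L{i:03d}", "chrom": name,
                         "pos_bp": pos, "length_bp": length_bp})
    return pd.DataFrame(rows)


def simulate_diversity_panel(layout: ReferenceLayout, n_samples: int = 10,
                             theta_per_site: float = 0.73e-3, loci=None,
                             seed: int = 0, return_sequences: bool = False):
    """Simulate per-locus diversity inputs under the neutral coalescent.

    Each locus gets an independent Kingman genealogy for ``n_samples``
    haplotypes with Poisson infinite-sites mutations at rate theta*L/2 per
    unit branch length. Loci inside the layout's sweep region instead use a
    star genealogy of depth equal to the sweep factor (in 2N units): the
    expected diversity is factor * theta (so factor 0 gives S = 0) and all
    variants are singletons, the footprint of a recent sweep followed by
    expansion.

    Returns a DataFrame (locus, chrom, pos_bp, length_bp, in_sweep, n, S,
    pi_count), plus ``{locus: 0/1 matrix}`` when ``return_sequences``.
    """
    if n_samples < 2:
        raise ValueError("n_samples must be >= 2")
    if theta_per_site <= 0:
        raise ValueError("theta_per_site must be positive")
    if loci is None:
        loci = make_locus_table(layout)
    loci = pd.DataFrame(loci).reset_index(drop=True)
    if (loci["length_bp"] <= 0).any():
        raise ValueError("locus length must be positive")
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    sweep = layout.sweep_region
    out, seqs = [], {}
    npairs = n_samples * (n_samples - 1) / 2.0
    for rec in loci.itertuples():
        in_sweep = bool(sweep and rec.chrom == sweep[0]
                        and sweep[1] <= rec.pos_bp <= sweep[2])
        star = sweep[3] if in_sweep else None
        mat = _simulate_locus(n_samples, theta_per_site * rec.length_bp / 2.0,
                              rng, star_depth=star)
        counts = mat.sum(axis=0)
        S = int(mat.shape[1])
        pi_count = float(np.sum(counts * (n_samples - counts)) / npairs)
        out.append({"locus": rec.locus, "chrom": rec.chrom, "pos_bp": rec.pos_bp,
                    "length_bp": rec.length_bp, "in_sweep": in_sweep,
                    "n": n_samples, "S": S, "pi_count": pi_count})
        if return_sequences:
            seqs[rec.locus] = mat
    table = pd.DataFrame(out)
    return (table, seqs) if return_sequences else table
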