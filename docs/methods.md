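# Methods

This note documents the models, parameter defaults, numerical choices and
known limitations behind `emmermap`. It is written for a user deciding
whether the package's assumptions fit their data.

## RIL genetics and the map builder

**Population model.** Lines descend from a fully heterozygous F1 by
single seed descent (SSD): each generation an individual produces two
independent gametes that form its sole offspring. At F_t the expected
residual heterozygosity per locus is (1/2)^(t−1); the default generation
is F7, the midpoint of an F6–F8 population.

**Recombination-fraction estimation.** For a marker pair, R is the share
of discordant homozygous parent-code pairs among lines homozygous and
non-missing at both markers. Heterozygous calls are excluded on both
sides of the ratio ("het as missing"), consistent with blanking het
blocks during QC; pairs with fewer than `min_informative` (default 50)
informative lines are flagged undefined rather than estimated.

**Per-meiosis correction.** Observed RIL RFs accumulate recombination
over selfing generations. The classical selfing-limit inversion
r = R/(2(1−R)) is exposed as `rf_to_per_meiosis` and is exact only at
F∞. Simulation shows that at F7 it still under-corrects enough to bias
total map length by ~5–8% — substantially more than the residual
heterozygosity fraction (≈1.6%) suggests, because late-fixing lines carry
most of the outstanding recombination opportunity. The map builder
therefore also provides `rf_to_per_meiosis_exact(R, generations)`: the
expected observed RF at F_t is computed from the exact two-locus selfing
Markov chain over diplotype states (conditioning on fixation at both
loci, which is what the estimator measures) and inverted numerically with
Brent's method. `build_linkage_group` uses the exact inversion whenever
the generation is supplied; with it, simulated 500-line maps recover the
truth length to within ~2–8% (residual error is dominated by the Kosambi
assumption, below, and by occasional linkage-group splits at marginal
adjacent RFs).

**Kosambi distances.** d = 25 ln((1+2r)/(1−2r)) cM, inverse
r = tanh(d/50)/2; round-trips hold to 1e-10. The simulator places
crossovers without interference (Haldane), so Kosambi distances
systematically under-estimate simulated distances by ~2–3% at typical
marker spacings. This mismatch is deliberate — it is documented and
bounded by the map-length tests rather than hidden by making the
estimator and simulator share assumptions.

**Binning and clustering.** Co-segregation bins are connected components
of the relation "no conflicting homozygous calls and ≥ `min_overlap`
(default 30) shared informative lines"; the skeleton representative is
the member with the fewest missing calls (ties broken lexicographically).
Linkage groups are single-linkage components of the graph with edges
R < 0.1; undefined RFs are non-edges.

**Ordering and monotony control.** Within a group, ordering minimizes the
sum of adjacent per-meiosis distances: farthest-pair seeding, cheapest
insertion, then best-improvement 2-opt plus single-marker relocation
until no move helps. For groups of ≤ 8 markers this reaches the
exhaustive-permutation optimum in the test suite. Monotony control then
counts triples i<j<k whose direct RF is smaller than the larger flanking
RF beyond twice its binomial standard error, and greedily removes markers
while removal reduces the count (at most n/5 removals). The 2-SE
tolerance is a principled noise allowance; the orientation of a finished
group is arbitrary up to reflection and is fixed against reference
anchors (rank correlation of cM with bp) when available.

**Graphical-genotype QC.** Per line and linkage group, het calls
separated by fewer than `min_block` (default 2) non-het calls form one
heterozygous block; interrupting calls are treated as inconsistent and
the entire block is set to missing.

**Chimeric groups.** A linkage group with ≥ 3 consensus-assigned markers
from each of two chromosomes is flagged chimeric; the junction is the cut
maximizing prefix/suffix assignment agreement. Two chimeric groups over
the same chromosome pair constitute reciprocal-translocation evidence
with both breakpoint neighbourhoods.

## Synteny and rearrangement classification

**Anchoring.** 12-column BLAST tabular rows; hits with e-value < 1e-5
are retained, the best hit per marker is chosen by (e-value, −bitscore,
chromosome, start), and "start" is min(sstart, send) so strand never
flips a position (run direction uses subject locations only). Markers
with more than 10 passing hits are flagged repeat-derived and excluded,
as are markers with no passing hit.

**Bound-marker ordering.** Within a co-segregation bin, anchored markers
are sorted by reference start in the orientation consistent with the
flanking skeleton anchors. Consistency is scored on the local window
(flank, bin members, flank): fewer monotonicity breaks wins, and when
both orientations leave one break — which happens when the bin's skeleton
heads an inverted block, so the bin lies beyond both flanks — the
orientation placing the break at the larger physical gap is chosen.
Unanchored and repeat-derived members keep a stable position at the bin
end; bins with no usable flanks stay in input order and are flagged.

**Loci and runs.** Markers whose best hits lie within `locus_collapse_bp`
(default 2,000 bp — several assay probes from one gene must count once)
collapse into single loci. The locus sequence of each linkage group is
segmented into maximal strictly monotone runs. Two non-obvious choices:

* at a direction change the pivot locus attaches to the side with the
  smaller reference-bp gap (tie: it stays with the preceding run), so
  breakpoints land at the larger physical jump;
* runs with fewer than 3 distinct loci are non-collinear; they are
  removed iteratively — interrupting short runs whose removal lets the
  flanking runs merge go first — and the remaining loci are re-segmented.
  A two-locus insertion inside a monotone stretch therefore leaves one
  long collinear run, and planted two-marker events are structurally
  invisible, matching the three-locus rule.

**Classification.** Within a group, a run opposing the direction of its
same-chromosome flanks with an in-sequence span is an inversion
(pericentric when its span overlaps the centromere interval, paracentric
otherwise, undetermined without a centromere table). Out-of-sequence
spans are intrachromosomal translocations; when two adjacent
same-direction runs overlap, the invading block with the smaller bp span
is deemed moved (tie: leftmost). The traversed distance is defined as the
reference-bp gap between the moved block and its insertion junction —
the quantity is reported in the source literature without a definition,
so this explicit choice is stated prominently. Runs on a different
chromosome than the group's assignment are interchromosomal
translocations; with complementary chimeric-group evidence a single
reciprocal-translocation record per chromosome pair is emitted instead.
No traversed distance is defined across chromosomes. Nested events are
reported independently, without hierarchy. Segmental duplications
(a ≥3-locus block appearing twice) surface as same-direction runs with
overlapping spans.

**Polarization and phylogeny.** For an inversion interval, the marker
order shared by the strict majority of outgroup genomes is ancestral;
ingroup genomes with the alternative order are derived (ties or missing
outgroups give "unresolved"). Derived-state sets are treated as
irreversible binary characters; a perfect phylogeny exists iff the sets
are pairwise nested or disjoint, and each character maps to the edge
subtending its clade. Incompatible pairs are reported as conflicts and no
tree is forced.

## Recombination-rate profiles

At each grid point (1 Mb default spacing here, 5 Mb in the pipeline) a
degree-3 polynomial of cM on (Mb − x0) is fitted with Gaussian weights
exp(−((x−x0)/h)²/2), h = 20 Mb by default; the first-order coefficient is
the rate. Grid points whose kernel-weight sum falls below degree+1, or
with a rank-deficient local design, are masked rather than extrapolated;
estimates within one bandwidth of the data edge are kept but flagged
boundary. Local polynomial fits reproduce polynomials up to the fit
degree exactly — the defining oracle — and are equivariant under
physical-axis scaling and genetic-axis shifts. Physical ties collapse to
their mean cM before fitting.

## Diversity statistics

θw = S/(a1·L) with a1 = Σ 1/i; θπ = Π/L with Π the mean pairwise
difference count (pairwise deletion when computed from sequences: sites
missing in either member of a pair are ignored and that pair's length
reduced); Tajima's D uses the standard constants and is undefined (NaN,
never zero) at S = 0 and for n ≤ 3, where its normalising constants
vanish. Note that the exact neutral mean of D is slightly negative
(≈ −0.06 for n = 10 at θL = 2, confirmed against an independent
coalescent implementation); tests compare against that null rather than
against zero. Genetic positions of loci are imputed by linear
interpolation between flanking anchored markers, clamping and flagging
positions outside the anchored range.

**Regional significance.** The source study marks regional contrasts with
asterisks without naming a test; a two-sided label-permutation test of
the region mean against its complement is used here (exhaustive
enumeration when the number of label assignments is at most `n_perm`,
otherwise Monte Carlo with the add-one estimator; seeded).

**Sweep detection.** Maximal runs of at least k = 10 consecutive loci
each below fraction f = 0.1 of the chromosome-wide mean θπ. The defaults
flag a 30-locus centromeric near-zero stretch while leaving a uniform
profile unflagged; because the criterion is per-locus, a stochastic
post-sweep locus that drew a mutation can split a detected run, so
simulated sweeps are typically recovered as one-or-two runs inside the
planted interval rather than always as a single 30-locus run.

**Polyploid decomposition.** θπ_p = θπ − θπ_i, floored at zero with a
warning; θπ_i is the component introgressed from the diploid progenitors,
for which the young D genome's diversity (0.18 × 10⁻³) serves as the
estimate in the bundled tables.

## Synthetic data

**Layout.** Markers are evenly spaced; the bp→cM profile integrates a
local rate ∝ 1 + bias·cos(2πx/L) (default bias 0.8), high at telomeres
and low at the centromere as in Triticeae. Centromeres default to the
middle 10%. Planted events permute the marker arrangement (inverted
blocks reversed, translocated blocks moved) and truth records store type,
members, span and traversed distance by construction. Events spanning
fewer than 3 markers are rejected by default because they are
undetectable under the three-locus rule; tests disable the check to
verify exactly that invisibility.

**Meiosis.** Crossovers per linkage structure are Poisson(map length in
Morgans) with positions uniform on the cM scale — no interference; the
known, bounded mismatch with Kosambi estimation is discussed above.
Rearrangements other than a reciprocal translocation are modelled as
homozygous in the cross (shared by both parents), so meiosis operates on
the rearranged order. A reciprocal translocation is carried by one parent
only: gametes are generated on the carrier's translocated chromosome
structure, which produces the pseudo-linkage across the two centromeres
that makes linkage groups chimeric; unbalanced gametes are implicitly
discarded and semisterility is not modelled. Genotyping error flips a
call to a uniformly chosen different code; missing entries are injected
independently; one integer seed drives all stages through independent
substreams, giving bit-identical reruns.

**Diversity panels.** Each locus draws an independent Kingman genealogy
(pairwise coalescence rate 1 in 2N-generation units) with
infinite-sites mutations at rate θ·L/2 per unit branch length, so
E[S] = θ·L·a1 and E[θπ] = θ. Loci inside the sweep region instead use a
star genealogy of depth equal to the sweep factor (in 2N units): expected
diversity is factor × θ — preserving the "θ scaled by the factor"
semantics, including S = 0 at factor 0 — while every variant is a
singleton, reproducing the negative Tajima's D footprint of a recent
sweep followed by expansion. A factor of 0.02 emulates the observed
~50-fold diversity depression in the motivating data. The generator omits
selection during line development, segregation distortion and
sequence-level reads; passing tests therefore demonstrate correctness of
the analysis chain under these idealisations, not robustness to
real-data artefacts such as allele-calling bias or cryptic paralogy.

## Problem sizes

The bundled demo uses seven 600-Mb/120-cM chromosomes with 40 markers
each, 445 lines at F7 (the emulated study's scale for lines, scaled down
~40-fold in marker count), 110 diversity loci with a 30-locus sweep, and
200-replicate sweep panels; property tests use 400–2,000-line populations
where the binomial tolerances require them. These sizes were chosen so
the whole suite and the acceptance script each run in well under a few
minutes while keeping every statistical check at 3-SE resolution.

## Known limitations

* Two-point ordering only; no multipoint likelihood. Proprietary-tool
  intermediates of the emulated workflow (e.g. its initial 55 linkage
  groups) are not reproduction targets.
* Linkage groups can split at adjacent RFs near the 0.1 threshold in
  noisy data, shortening total map length by the lost junction distances.
* Traversed distance for interchromosomal translocations is undefined.
* The permutation test treats loci as exchangeable, ignoring linkage
  between neighbouring loci; p-values for strongly autocorrelated
  diversity profiles are optimistic.
* The coalescent panel has no intralocus recombination and free
  recombination between loci.
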