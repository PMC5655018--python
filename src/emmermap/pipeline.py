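"""End-to-end orchestration: simulate -> map -> synteny -> rate -> diversity.

Every stage writes delimited-text artifacts into the output directory
before the next stage starts, together with the fully resolved
configuration (for provenance: re-running with the same config and seed
reproduces all outputs byte-identically).
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import linkage, popgen, recomb, synteny
from .genotypes import GenotypeMatrix
from .simulate import SimConfig, demo_layout, simulate_diversity_panel, \
    simulate_ril_population, make_locus_table, write_blast_tabular

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline"]


@dataclass
class PipelineConfig:
    """All stage parameters and toggles; unknown keys are rejected."""

    seed: int = 0
    out_dir: str = "emmermap_run"
    # simulation
    n_lines: int = 445
    final_generation: int = 7
    genotyping_error: float = 0.002
    missing_rate: float = 0.01
    sweep_factor: float = 0.02
    # optional external inputs (simulated when absent)
    genotype_path: str | None = None
    blast_path: str | None = None
    # map construction
    min_informative: int = 50
    min_overlap: int = 30
    min_block: int = 2
    rf_threshold: float = 0.1
    # synteny
    evalue_max: float = 1e-5
    repeat_threshold: int = 10
    min_loci: int = 3
    locus_collapse_bp: int = 2000
    # recombination rate
    bandwidth_mb: float = 20.0
    grid_step_mb: float = 5.0
    # diversity
    n_samples: int = 10
    theta_per_site: float = 0.73e-3
    n_diversity_loci: int = 110
    sweep_k: int = 10
    sweep_fraction: float = 0.1
    n_perm: int = 2000
    # stage toggles
    stages: tuple = ("simulate", "map", "synteny", "rate", "diversity")

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown configuration keys: {sorted(unknown)}")
        cfg = cls(**d)
        if isinstance(cfg.stages, list):
            cfg.stages = tuple(cfg.stages)
        return cfg

    def to_json(self) -> str:
        d = dataclasses.asdict(self)
        d["stages"] = list(d["stages"])
        return json.dumps(d, indent=2, sort_keys=True)


@dataclass
class PipelineResult:
    config: PipelineConfig
    layout: object = None
    matrix: GenotypeMatrix | None = None
    linkage_groups: list = field(default_factory=list)
    expanded_map: object = None
    events: list = field(default_factory=list)
    rate_profiles: dict = field(default_factory=dict)
    diversity: pd.DataFrame | None = None
    sweeps: list = field(default_factory=list)
    region_summaries: list = field(default_factory=list)
    summary: dict = field(default_factory=dict)


class StageError(RuntimeError):
    def __init__(self, stage: str, detail: str):
        super().__init__(f"stage {stage!r} failed: {detail}")
        self.stage = stage


def _orient_lg(lg: linkage.LinkageGroup, anchors: synteny.AnchorSet) -> None:
    """Flip an LG so cM increases with reference bp (majority vote)."""
    pos = [(lg.positions_cm[i], anchors.position(m))
           for i, m in enumerate(lg.markers)]
    pairs = [(cm, p[1]) for cm, p in pos if p is not None]
    if len(pairs) < 3:
        return
    cms, bps = zip(*pairs)
    rho = np.corrcoef(np.argsort(np.argsort(cms)), np.argsort(np.argsort(bps)))[0, 1]
    if rho < 0:
        lg.markers = lg.markers[::-1]
        lg.positions_cm = lg.positions_cm[-1] - lg.positions_cm[::-1]


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "config.json").write_text(config.to_json() + "\n")
    res = PipelineResult(config=config)
    summary: dict = {}

    # --- simulate -----------------------------------------------------
    layout = demo_layout(sweep_factor=config.sweep_factor)
    res.layout = layout
    if "simulate" in config.stages:
        sim = SimConfig(n_lines=config.n_lines,
                        final_generation=config.final_generation,
                        genotyping_error=config.genotyping_error,
                        missing_rate=config.missing_rate, seed=config.seed)
        matrix, truth = simulate_ril_population(layout, sim)
        matrix.write(out / "genotypes.tsv")
        truth.write(out / "genotypes_truth.tsv")
        write_blast_tabular(layout, out / "anchors.blast.tsv")
        layout.markers.to_csv(out / "reference_markers.tsv", sep="\t", index=False)
    else:
        if not config.genotype_path:
            raise StageError("map", "no genotype matrix: simulation disabled and "
                                    "genotype_path not given")
        if not Path(config.genotype_path).exists():
            raise StageError("map", f"genotype matrix not found: {config.genotype_path}")
        matrix = GenotypeMatrix.read(config.genotype_path)
    res.matrix = matrix

    blast_path = config.blast_path or out / "anchors.blast.tsv"
    if not Path(blast_path).exists():
        raise StageError("synteny", f"anchor hits not found: {blast_path}")

    anchors = synteny.load_anchor_hits(blast_path, evalue_max=config.evalue_max,
                                       repeat_threshold=config.repeat_threshold,
                                       marker_ids=matrix.marker_ids)

    # --- map ----------------------------------------------------------
    lgs: list = []
    if "map" in config.stages:
        try:
            rf = linkage.estimate_rf(matrix, min_informative=config.min_informative)
            bins = linkage.bin_markers(matrix, min_overlap=config.min_overlap)
            skeletons = [b.skeleton for b in bins]
            skel_rf = rf.submatrix(skeletons)
            groups = linkage.cluster_linkage_groups(skel_rf, threshold=config.rf_threshold)
            for gi, group in enumerate(groups):
                if len(group) < 2:
                    continue
                order, removed = linkage.order_linkage_group(group, skel_rf)
                lg = linkage.build_linkage_group(f"LG{gi + 1}", order, skel_rf, bins,
                                                 generations=config.final_generation)
                _orient_lg(lg, anchors)
                lgs.append(lg)
            cleaned, qc_report = linkage.qc_graphical_genotypes(
                matrix, lgs, min_block=config.min_block)
            cleaned.write(out / "genotypes_qc.tsv")
            rows = []
            for lg in lgs:
                for m, cm in zip(lg.markers, lg.positions_cm):
                    rows.append({"lg": lg.name, "marker": m, "cm": round(float(cm), 4),
                                 "bound": ";".join(lg.bins.get(m, []))})
            pd.DataFrame(rows).to_csv(out / "linkage_map.tsv", sep="\t", index=False)
            summary["n_linkage_groups"] = len(lgs)
            summary["total_map_cm"] = round(sum(lg.length_cm for lg in lgs), 2)
            summary["n_skeleton_markers"] = sum(len(lg.markers) for lg in lgs)
            summary["n_bound_markers"] = sum(lg.n_bound for lg in lgs)
            summary["qc_calls_blanked"] = int(sum(qc_report.values()))
        except (ValueError, KeyError) as exc:
            raise StageError("map", str(exc)) from exc
    res.linkage_groups = lgs

    # --- synteny ------------------------------------------------------
    if "synteny" in config.stages and lgs:
        try:
            assignments = layout.truth_assignments()
            chimera = linkage.detect_chimeric_groups(lgs, assignments)
            expanded = synteny.order_bound_markers(lgs, anchors)
            scans = synteny.find_collinear_runs(
                expanded, anchors, min_loci=config.min_loci,
                locus_collapse_bp=config.locus_collapse_bp)
            events = synteny.classify_rearrangements(
                scans, centromeres=layout.centromeres, chimera_report=chimera)
            res.expanded_map = expanded
            res.events = events
            ev_rows = [{"type": e.type, "chromosome": e.chromosome, "lg": e.lg,
                        "arm": e.arm, "n_markers": len(e.markers),
                        "length_bp": e.segment_length_bp,
                        "traversed_bp": e.traversed_bp,
                        "markers": ";".join(e.markers)} for e in events]
            pd.DataFrame(ev_rows).to_csv(out / "rearrangements.tsv", sep="\t", index=False)
            col_rows = []
            for lg_name, rows in expanded.entries.items():
                for r in rows:
                    col_rows.append({"lg": lg_name, **r})
            pd.DataFrame(col_rows).to_csv(out / "expanded_map.tsv", sep="\t", index=False)
            summary["n_rearrangements"] = len(events)
            summary["event_types"] = sorted({e.type for e in events})
            summary["fraction_ordered"] = round(expanded.fraction_ordered, 4)
        except (ValueError, KeyError) as exc:
            raise StageError("synteny", str(exc)) from exc

    # --- recombination rate -------------------------------------------
    if "rate" in config.stages and lgs:
        profiles = {}
        rate_rows = []
        for lg in lgs:
            pts = [(anchors.position(m), cm)
                   for m, cm in zip(lg.markers, lg.positions_cm)
                   if anchors.position(m) is not None]
            by_chrom: dict = {}
            for (chrom, bp), cm in pts:
                by_chrom.setdefault(chrom, []).append((bp / 1e6, cm))
            chrom = max(by_chrom, key=lambda c: len(by_chrom[c])) if by_chrom else None
            if chrom is None or len(by_chrom[chrom]) < 6:
                continue
            mb, cm = zip(*sorted(by_chrom[chrom]))
            prof = recomb.rate_profile(cm, mb, bandwidth_mb=config.bandwidth_mb,
                                       grid_step_mb=config.grid_step_mb)
            profiles[lg.name] = prof
            for x0, r, ok, bd in zip(prof.grid_mb, prof.rate, prof.valid, prof.boundary):
                rate_rows.append({"lg": lg.name, "chrom": chrom, "mb": round(x0, 3),
                                  "cm_per_mb": round(float(r), 6) if ok else "",
                                  "boundary": int(bd)})
        pd.DataFrame(rate_rows).to_csv(out / "recombination_rate.tsv", sep="\t",
                                       index=False)
        res.rate_profiles = profiles
        summary["n_rate_profiles"] = len(profiles)

    # --- diversity ----------------------------------------------------
    if "diversity" in config.stages:
        try:
            sweep_chrom = layout.sweep_region[0]
            loci = make_locus_table(layout, n_per_chrom=config.n_diversity_loci,
                                    chrom=sweep_chrom)
            panel = simulate_diversity_panel(
                layout, n_samples=config.n_samples,
                theta_per_site=config.theta_per_site, loci=loci,
                seed=config.seed + 1)
            panel = popgen.annotate_diversity(panel)
            anchor_df = layout.arrangements.get(sweep_chrom)
            if anchor_df is not None:
                same = anchor_df[anchor_df["ref_chrom"] == sweep_chrom]
                cm, extrap = popgen.impute_genetic_position(
                    panel["pos_bp"], same["ref_bp"], same["cm"])
                panel["cm"] = np.round(cm, 4)
                panel["extrapolated"] = extrap
            else:
                panel["cm"] = np.nan
            panel.to_csv(out / "diversity_loci.tsv", sep="\t", index=False)
            sweeps = popgen.detect_sweep(panel, k=config.sweep_k,
                                         fraction=config.sweep_fraction,
                                         position_col="pos_bp")
            regions = {"sweep area": (layout.sweep_region[1], layout.sweep_region[2]),
                       "S distal": (0, layout.sweep_region[1] - 1),
                       "L distal": (layout.sweep_region[2] + 1,
                                    layout.chromosomes[sweep_chrom].length_bp)}
            summaries = popgen.region_diversity_summary(
                panel, regions, position_col="pos_bp", n_perm=config.n_perm,
                seed=config.seed + 2)
            reg_rows = [{"region": s.label, "n_loci": s.n_loci,
                         "theta_w_e3": round(s.mean_theta_w * 1e3, 3),
                         "theta_pi_e3": round(s.mean_theta_pi * 1e3, 3),
                         "tajimas_d": round(s.mean_tajimas_d, 3),
                         "p_theta_pi": round(s.p_theta_pi, 5)} for s in summaries]
            pd.DataFrame(reg_rows).to_csv(out / "region_summary.tsv", sep="\t",
                                          index=False)
            sw_rows = [{"chrom": s.chrom, "start_bp": s.start, "end_bp": s.end,
                        "n_loci": s.n_loci} for s in sweeps]
            pd.DataFrame(sw_rows).to_csv(out / "sweep_regions.tsv", sep="\t",
                                         index=False)
            res.diversity = panel
            res.sweeps = sweeps
            res.region_summaries = summaries
            summary["n_sweep_regions"] = len(sweeps)
            summary["sweep_loci"] = int(sum(s.n_loci for s in sweeps))
        except (ValueError, KeyError) as exc:
            raise StageError("diversity", str(exc)) from exc

    res.summary = summary
    (out / "summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True) + "\n")
    return res
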