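"""End-to-end pipeline: simulate -> fingerprint -> overlap -> assemble ->
MTP -> anchor -> stats, with a reproducibility manifest.

All stage outputs are plain text (FASTA/BED/TSV/JSON plus the bands
dialect) and are byte-reproducible from the configuration and seed.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import __version__, anchor as anchor_mod, io as pio
from .assembly import (build_contigs, conservation_counts, exclude_q,
                       merge_scaffolds, select_mtp, validate_scaffolds)
from .fingerprint import fingerprint_windows, quality_filter
from .overlap import overlap_network
from .params import AssemblyParams, HicfParams, MatchParams, params_to_dict
from .simlib import (SimConfig, clone_fingerprints, corrupt_fingerprints,
                     generate_chromosome, generate_decoy, mutate_reference,
                     simulate_bac_library)
from .stats import assembly_stats, depth_report, size_class_report

log = logging.getLogger("physmap")


@dataclass
class RunConfig:
    """Full pipeline configuration; round-trips losslessly through YAML."""

    sim: SimConfig = field(default_factory=SimConfig)
    hicf: HicfParams = field(default_factory=HicfParams)
    match: MatchParams = field(default_factory=MatchParams)
    assembly: AssemblyParams = field(default_factory=AssemblyParams)
    with_reference: bool = True
    mtp_mode: str = "ltc"
    calibrate_gel_space: bool = True
    seed: int = 0

    def to_dict(self) -> dict:
        return {"sim": params_to_dict(self.sim), "hicf": params_to_dict(self.hicf),
                "match": params_to_dict(self.match),
                "assembly": params_to_dict(self.assembly),
                "with_reference": self.with_reference,
                "mtp_mode": self.mtp_mode,
                "calibrate_gel_space": self.calibrate_gel_space,
                "seed": self.seed}

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        sim = dict(d.get("sim", {}))
        if "repeat_blocks" in sim:
            sim["repeat_blocks"] = [tuple(b) for b in sim["repeat_blocks"]]
        match = dict(d.get("match", {}))
        for key in ("mtp_cutoff_range", "mtp_shared_fraction"):
            if key in match:
                match[key] = tuple(match[key])
        return cls(sim=SimConfig(**sim), hicf=HicfParams(**d.get("hicf", {})),
                   match=MatchParams(**match),
                   assembly=AssemblyParams(**d.get("assembly", {})),
                   with_reference=d.get("with_reference", True),
                   mtp_mode=d.get("mtp_mode", "ltc"),
                   calibrate_gel_space=d.get("calibrate_gel_space", True),
                   seed=d.get("seed", 0))

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        return cls.from_dict(pio.read_yaml(path))

    def to_yaml(self, path) -> None:
        pio.write_yaml(self.to_dict(), path)


def run_pipeline(config: RunConfig, outdir: str | Path) -> dict:
    """Execute every stage and write all artifacts into ``outdir``.

    Returns a result dictionary with the in-memory objects of each stage;
    the manifest records inputs, parameters, seed, versions and per-stage
    record counts.  Idempotent for a fixed seed.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed)
    counts: dict[str, int] = {}

    log.info("[simulate] generating chromosome (%d bp)", config.sim.chromosome_length)
    chrom = generate_chromosome(config.sim, rng)
    decoy = generate_decoy(config.sim, rng)
    clone_set = simulate_bac_library(chrom, decoy, config.sim, rng)
    pio.write_fasta({"chrom": chrom.sequence}, outdir / "chrom.fasta")
    pio.write_fasta({"decoy": decoy.sequence}, outdir / "decoy.fasta")
    pio.write_bed(chrom.repeat_annotations and
                  [(a, b, cls_) for a, b, cls_ in chrom.repeat_annotations] or [],
                  "chrom", outdir / "repeats.bed")
    pio.write_tsv(pio.marker_table(chrom), outdir / "markers.tsv")
    pio.write_tsv(pio.clone_table(clone_set), outdir / "clones.tsv")
    counts["clones"] = len(clone_set)

    log.info("[fingerprint] fingerprinting %d clones", len(clone_set))
    fps = clone_fingerprints(clone_set, chrom, decoy, config.hicf)
    fps = corrupt_fingerprints(fps, clone_set.corrupted, config.hicf, rng)
    retained, rejected = quality_filter(fps, config.hicf)
    pio.write_bands(fps, outdir / "bands.txt")
    counts["fingerprints"] = len(fps)
    counts["quality_retained"] = len(retained)

    log.info("[overlap] building Sulston network on %d fingerprints", len(retained))
    match_params = config.match
    if config.calibrate_gel_space and retained:
        from .overlap import calibrate_match_params
        match_params = calibrate_match_params(config.match, retained)
        counts["gel_space"] = match_params.gel_space
    graph = overlap_network(retained, match_params)
    pio.write_tsv(pio.edge_table(graph), outdir / "edges.tsv")
    counts["edges"] = graph.number_of_edges()

    log.info("[assemble] Q exclusion and linear-topology contigs")
    fp_map = {fp.owner: fp for fp in retained}
    cleaned, q_report = exclude_q(graph, match_params)
    contigs, singletons, build_report = build_contigs(
        cleaned, fp_map, match_params, config.assembly)
    report = q_report + build_report
    pio.write_tsv(pio.contig_table(contigs), outdir / "contigs.tsv")
    counts["contigs"] = len(contigs)
    counts["singletons"] = len(singletons)
    counts["excluded"] = sum(1 for r in report if r.get("kind") == "clone")

    log.info("[mtp] selecting minimal tiling paths (%s mode)", config.mtp_mode)
    mtp: dict[str, list] = {}
    mtp_warnings: list[str] = []
    for c in contigs:
        sel, warn = select_mtp(c, fp_map, match_params, config.assembly,
                               mode=config.mtp_mode)
        mtp[c.id] = sel
        mtp_warnings.extend(warn)
    import pandas as pd
    pio.write_tsv(pd.DataFrame([{"contig_id": cid, "clone_id": cl}
                                for cid, sel in mtp.items() for cl in sel]),
                  outdir / "mtp.tsv")
    counts["mtp_clones"] = sum(len(v) for v in mtp.values())

    log.info("[anchor] staged anchoring")
    clone_to_contig = {cl: c.id for c in contigs for cl in c.clones}
    stage_pairs: list[tuple[str, int]] = []
    anchor_records: list = []
    # stage 1: SSR markers screened against library pools
    ssr = [(mid, pos) for mid, mtype, pos in chrom.marker_loci if mtype == "SSR"]
    screen = anchor_mod.screen_pools(ssr, clone_set,
                                     restrict_to=set(clone_to_contig))
    for marker, res in screen.items():
        pos = dict(ssr)[marker]
        for hit in res["hits"]:
            ctg = clone_to_contig.get(hit)
            if ctg:
                stage_pairs.append((ctg, 1))
                anchor_records.append(anchor_mod.AnchorRecord(
                    ctg, "marker", pos, 1))
    # stage 2: remaining marker types carry bin/external positions
    other = [(mid, pos) for mid, mtype, pos in chrom.marker_loci if mtype != "SSR"]
    screen2 = anchor_mod.screen_pools(other, clone_set,
                                      restrict_to=set(clone_to_contig))
    pos_of = dict(other)
    for marker, res in screen2.items():
        frac = pos_of[marker] / chrom.length
        bins = anchor_mod.assign_bins(frac)
        for hit in res["hits"]:
            ctg = clone_to_contig.get(hit)
            if ctg:
                stage_pairs.append((ctg, 2))
                anchor_records.append(anchor_mod.AnchorRecord(
                    ctg, "bin", bins[0] if bins else "", 2))
    # stage 3: reference-window fingerprint comparison of MTP clones
    ref_anchor_info: dict[str, dict] = {}
    if config.with_reference:
        reference = mutate_reference(chrom, config.sim.divergence_rate, rng)
        pio.write_fasta({"reference": reference.sequence}, outdir / "reference.fasta")
        window_fps = fingerprint_windows(reference.sequence, config.hicf)
        pio.write_bands(window_fps, outdir / "refbands.txt")
        mtp_fps = [fp_map[cl] for sel in mtp.values() for cl in sel]
        anchor_params = match_params
        if config.calibrate_gel_space:
            from .overlap import calibrate_match_params
            anchor_params = calibrate_match_params(config.match,
                                                   mtp_fps + window_fps)
        recs = anchor_mod.anchor_by_reference(mtp_fps, window_fps, anchor_params)
        anchor_records.extend(recs)
        ref_anchor_info = anchor_mod.contig_reference_anchors(
            recs, contigs, clone_to_contig)
        stage_pairs.extend((cid, 3) for cid in ref_anchor_info)
    stage_of = anchor_mod.earliest_stage(stage_pairs)
    contig_kb = {c.id: c.estimated_length_kb for c in contigs}
    chrom_kb = chrom.length / 1000.0
    coverage = anchor_mod.staged_coverage(stage_of, contig_kb, chrom_kb)
    pio.write_tsv(pio.anchor_table(anchor_records), outdir / "anchors.tsv")
    counts["anchored_contigs"] = len(stage_of)

    # marker hits over all markers, for scaffolding/validation
    all_markers = [(mid, pos) for mid, _, pos in chrom.marker_loci]
    screen_all = anchor_mod.screen_pools(all_markers, clone_set,
                                         restrict_to=set(clone_to_contig))
    marker_hits = {m: r["hits"] for m, r in screen_all.items() if r["hits"]}
    scaffolds, merge_report = merge_scaffolds(contigs, graph, marker_hits,
                                              match_params)
    genetic_map = {}  # no genetic positions in the default simulation
    val_flags = validate_scaffolds(scaffolds, contigs, marker_hits, genetic_map,
                                   config.assembly)
    pio.write_json({"scaffolds": [{"id": s.id, "contigs": s.contig_ids,
                                   "junctions": s.junctions, "flags": s.flags}
                                  for s in scaffolds],
                    "validation_flags": val_flags,
                    "merge_report": merge_report},
                   outdir / "scaffolds.json")
    counts["scaffolds"] = len(scaffolds)

    log.info("[stats] summarising")
    stats = assembly_stats(contigs, singletons, len(clone_set), len(retained),
                           chrom_kb, counts["mtp_clones"])
    anchor_mid = {cid: info["position"] / 1000.0
                  for cid, info in ref_anchor_info.items()}
    size_report = size_class_report(contigs, anchor_mid, chrom_kb)
    conservation = conservation_counts(len(retained), contigs, singletons, report)
    pio.write_json({"assembly": dataclasses.asdict(stats),
                    "depth": depth_report(contigs, config.assembly),
                    "staged_coverage": coverage,
                    "size_classes": {"counts": size_report.counts,
                                     "unplaced": size_report.unplaced,
                                     "interval_edges_kb": size_report.interval_edges_kb},
                    "conservation": conservation},
                   outdir / "stats.json")

    manifest = {"config": config.to_dict(), "seed": config.seed,
                "versions": {"physmap": __version__, "numpy": np.__version__},
                "counts": counts,
                "outputs": sorted(p.name for p in outdir.iterdir())}
    pio.write_json(manifest, outdir / "manifest.json")

    return {"chrom": chrom, "decoy": decoy, "clone_set": clone_set,
            "fingerprints": fps, "retained": retained, "rejected": rejected,
            "graph": graph, "cleaned": cleaned, "contigs": contigs,
            "singletons": singletons, "report": report, "mtp": mtp,
            "mtp_warnings": mtp_warnings, "anchor_records": anchor_records,
            "ref_anchor_info": ref_anchor_info, "stage_of": stage_of,
            "staged_coverage": coverage, "scaffolds": scaffolds,
            "validation_flags": val_flags, "stats": stats,
            "size_report": size_report, "conservation": conservation,
            "manifest": manifest, "outdir": outdir}
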