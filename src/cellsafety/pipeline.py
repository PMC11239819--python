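"""End-to-end orchestration of the genomic safety assessment.

One configuration drives the full chain: per-caller consensus for each
cell type -> known-site filtering -> region annotation -> three-cell-type
merge -> specificity analysis (k-scan clustering + cutoff filtering +
concordance) -> off-target homology/coverage forensics -> a machine-
readable summary.  Every stage writes its table under the output
directory, so stages are individually re-runnable from intermediates, and
the whole run is deterministic for a fixed seed.
"""

from __future__ import annotations

import json
import logging
import os
from dataclasses import dataclass, field

import pandas as pd

from . import offtarget, specificity, variants

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Paths and thresholds for one safety-assessment run.

    ``caller_vcfs`` maps cell type ("fibro" | "ipsc" | "isc") to the list
    of per-caller VCF paths whose full overlap forms the consensus.
    """

    caller_vcfs: dict[str, list[str]]
    out_dir: str
    known_sites_vcf: str | None = None
    features_bed: str | None = None
    depth_tracks: dict[str, str] = field(default_factory=dict)
    guide: offtarget.GuideSpec | None = None
    site_window_fastas: dict[str, str] = field(default_factory=dict)
    variant_type: str = "SNV"
    af_threshold: float = specificity.DEFAULT_AF_THRESHOLD
    or_threshold: float = specificity.DEFAULT_OR_THRESHOLD
    epsilon: float = specificity.DEFAULT_EPSILON
    k_scan: tuple[int, int] = (3, 9)
    seed: int = 0

    @classmethod
    def from_file(cls, path: str) -> "RunConfig":
        """Parse a plain-text key/value config (``key = value`` lines;
        cell-type-scoped keys like ``vcf.fibro`` take comma-separated
        lists).  Schema version 1."""
        kv: dict[str, str] = {}
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                key, _, value = line.partition("=")
                kv[key.strip()] = value.strip()
        if kv.get("schema", "1") != "1":
            raise ValueError(f"unsupported config schema {kv.get('schema')!r}")
        caller_vcfs = {ct: [p.strip() for p in kv[f"vcf.{ct}"].split(",")]
                       for ct in ("fibro", "ipsc", "isc") if f"vcf.{ct}" in kv}
        depth_tracks = {ct: kv[f"depth.{ct}"]
                        for ct in ("fibro", "ipsc", "isc") if f"depth.{ct}" in kv}
        guide = None
        if "guide.protospacer" in kv:
            guide = offtarget.GuideSpec(
                protospacer=kv["guide.protospacer"],
                pam_pattern=kv.get("guide.pam", "NRG"),
                window_bases=int(kv.get("guide.window", "25")))
        lo, _, hi = kv.get("k_scan", "3:9").partition(":")
        return cls(
            caller_vcfs=caller_vcfs,
            out_dir=kv.get("out_dir", "cellsafety_out"),
            known_sites_vcf=kv.get("known_sites") or None,
            features_bed=kv.get("features") or None,
            depth_tracks=depth_tracks,
            guide=guide,
            variant_type=kv.get("variant_type", "SNV"),
            af_threshold=float(kv.get("af_threshold", specificity.DEFAULT_AF_THRESHOLD)),
            or_threshold=float(kv.get("or_threshold", specificity.DEFAULT_OR_THRESHOLD)),
            epsilon=float(kv.get("epsilon", specificity.DEFAULT_EPSILON)),
            k_scan=(int(lo), int(hi or lo)),
            seed=int(kv.get("seed", "0")),
        )


def _consensus_for_cell_type(config: RunConfig, cell_type: str):
    paths = config.caller_vcfs[cell_type]
    callsets = [variants.read_caller_vcf(p, caller_name=f"caller{i}",
                                         variant_type=config.variant_type)
                for i, p in enumerate(paths)]
    return variants.intersect_callers(callsets)


def run_safety_pipeline(config: RunConfig) -> dict:
    """Run every stage and return the summary dict (also written to disk)."""
    os.makedirs(config.out_dir, exist_ok=True)
    summary: dict = {"seed": config.seed}

    def stage(name):
        logger.info("stage %s starting", name)

    try:
        stage("consensus")
        consensus = {ct: _consensus_for_cell_type(config, ct)
                     for ct in ("fibro", "ipsc", "isc")}
    except Exception as exc:
        raise RuntimeError(f"stage consensus failed: {exc}") from exc

    known: set[variants.VariantKey] = set()
    if config.known_sites_vcf:
        known = variants.read_known_sites(config.known_sites_vcf)
        consensus = {ct: variants.filter_known_sites(c, known)
                     for ct, c in consensus.items()}

    regions = None
    if config.features_bed:
        features = variants.read_features_bed(config.features_bed)
        all_keys = set().union(*[set(c) for c in consensus.values()])
        regions = variants.annotate_regions(all_keys, features)

    depth_lookup = {ct: variants.read_depth_track(path)
                    for ct, path in config.depth_tracks.items()} or None

    try:
        stage("merge")
        table = variants.merge_cell_types(consensus["fibro"], consensus["ipsc"],
                                          consensus["isc"], depth_lookup=depth_lookup,
                                          regions=regions)
    except Exception as exc:
        raise RuntimeError(f"stage merge failed: {exc}") from exc
    variants.write_merged_table(table, os.path.join(config.out_dir, "merged.tsv"))
    summary["n_variants"] = int(len(table))
    summary["region_histogram"] = (table["region"].value_counts().to_dict()
                                   if len(table) else {})

    stage("specificity")
    if len(table):
        calls = specificity.classify_table(table, config.af_threshold,
                                           config.or_threshold, config.epsilon)
        calls.to_csv(os.path.join(config.out_dir, "specificity_calls.tsv"),
                     sep="\t", index=False)
        label_counts = calls["label"].value_counts().to_dict()
        matrix = specificity.build_af_matrix(table)
        result = specificity.scan_k(matrix, seed=config.seed, k_range=config.k_scan,
                                    af_threshold=config.af_threshold)
        if result is not None:
            specificity.cluster_summary(result).to_csv(
                os.path.join(config.out_dir, "cluster_summary.tsv"), sep="\t", index=False)
            kmeans_keys = specificity.keys_in_flagged_clusters(table, result)
            filter_keys = specificity.keys_with_label(calls)
            summary["kmeans_k"] = result.k
            summary["kmeans_flagged_variants"] = len(kmeans_keys)
            summary["concordance"] = (specificity.concordance(kmeans_keys, filter_keys)
                                      if kmeans_keys else None)
        else:
            summary["kmeans_k"] = None
            summary["kmeans_flagged_variants"] = 0
            summary["concordance"] = None
        summary["label_counts"] = {lbl: int(label_counts.get(lbl, 0)) for lbl in
                                   (specificity.SHARED_IPSC_ISC, specificity.IPSC_ONLY,
                                    specificity.ISC_ONLY, specificity.NONE)}
    else:
        summary["label_counts"] = {lbl: 0 for lbl in
                                   (specificity.SHARED_IPSC_ISC, specificity.IPSC_ONLY,
                                    specificity.ISC_ONLY, specificity.NONE)}
        summary["kmeans_k"] = None
        summary["kmeans_flagged_variants"] = 0
        summary["concordance"] = None

    if config.guide is not None and config.site_window_fastas:
        stage("offtarget")
        from Bio import SeqIO
        mins = {}
        for label, fasta in config.site_window_fastas.items():
            best = None
            for rec in SeqIO.parse(fasta, "fasta"):
                _, mm = offtarget.scan_guide_homology(str(rec.seq), config.guide)
                if mm is not None and (best is None or mm < best):
                    best = mm
            mins[label] = best
        summary["homology_min_mismatches"] = mins
        pd.DataFrame([{"site": k, "min_mismatches": v} for k, v in mins.items()]).to_csv(
            os.path.join(config.out_dir, "homology_report.tsv"), sep="\t", index=False)

    summary_path = os.path.join(config.out_dir, "summary.json")
    with open(summary_path, "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
    rows = [{"metric": k, "value": json.dumps(v) if isinstance(v, dict) else v}
            for k, v in summary.items()]
    pd.DataFrame(rows).to_csv(os.path.join(config.out_dir, "summary.tsv"),
                              sep="\t", index=False)
    logger.info("pipeline complete: %s", summary_path)
    return summary
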