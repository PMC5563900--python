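"""End-to-end orchestration: counts -> densities -> 5'LR -> differential
-> stratified statistics, with a machine-readable output manifest.

All tables are written as TSV with sorted, deterministic row order and a
fixed float format, so two runs with the same inputs and seed produce
byte-identical artifacts.
"""

from __future__ import annotations

import json
import logging
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import annotation as ann
from . import asite, counting, differential, stratified
from .simulate import SimulationConfig, condition_of_sample

logger = logging.getLogger(__name__)

FLOAT_FORMAT = "%.8g"


@dataclass
class RunConfig:
    """Paths, thresholds and comparisons for one pipeline run."""

    annotation_path: str
    reads_path: str
    elements_path: str
    outdir: str
    dialect: str = "gtf"
    control: str = "0h"
    comparisons: list[tuple[str, str]] = field(default_factory=list)
    condition_of_sample: dict[str, str] = field(default_factory=dict)
    thresholds: differential.Thresholds = field(default_factory=differential.Thresholds)
    lr_config: asite.LoadingRatioConfig = field(default_factory=asite.LoadingRatioConfig)
    cluster_k: int = 5
    seed: int = 0

    def validate(self) -> None:
        for p in (self.annotation_path, self.reads_path, self.elements_path):
            if not os.path.exists(p):
                raise FileNotFoundError(p)


def _infer_conditions(samples, control: str) -> dict[str, str]:
    """Default sample -> condition map for ids shaped {condition}_rep{n}."""
    out = {}
    for s in samples:
        out[s] = s.rsplit("_rep", 1)[0] if "_rep" in s else s
    return out


def _write(df: pd.DataFrame, path: str, manifest: dict, index=True) -> None:
    df.to_csv(path, sep="\t", float_format=FLOAT_FORMAT, index=index)
    manifest[os.path.basename(path)] = int(len(df))


def run_pipeline(config: RunConfig) -> dict:
    """Run the full analysis and return the output manifest.

    The manifest maps artifact file name -> row count and is also written
    as ``manifest.json`` in the output directory.
    """
    config.validate()
    os.makedirs(config.outdir, exist_ok=True)
    manifest: dict = {}

    models = ann.load_annotation(config.annotation_path, config.dialect)
    canonical = ann.canonical_transcripts(models)
    elements = ann.load_element_table(
        config.elements_path, annotation_genes={m.gene_id for m in models}
    )
    reads = counting.read_alignment_tsv(config.reads_path)

    samples = sorted(reads["sample"].unique())
    cond_map = config.condition_of_sample or _infer_conditions(samples, config.control)
    conditions = sorted(set(cond_map.values()))
    comparisons = config.comparisons or [
        (c, config.control) for c in conditions if c != config.control
    ]

    canon_models = {m.transcript_id: m for m in canonical.values()}

    # counts, densities, QC ------------------------------------------------
    cm = counting.count_reads(reads, canon_models)
    _write(cm.counts, os.path.join(config.outdir, "counts.tsv"), manifest)
    lib = cm.library_size.rename("library_size").to_frame()
    _write(lib, os.path.join(config.outdir, "library_sizes.tsv"), manifest)
    dens = counting.region_density_table(cm, canon_models)
    _write(dens, os.path.join(config.outdir, "region_densities.tsv"), manifest)

    hist = (
        reads[reads["assay"] == "RPF"]
        .pipe(counting.read_length_histogram)
        .rename("count")
        .to_frame()
    )
    _write(hist, os.path.join(config.outdir, "rpf_length_histogram.tsv"), manifest)

    rpkm = counting.rpkm_table(cm, canon_models)
    rpkm_flat = rpkm.copy()
    rpkm_flat.columns = [f"{a}:{s}" for a, s in rpkm.columns]
    _write(rpkm_flat, os.path.join(config.outdir, "rpkm.tsv"), manifest)

    qc_rows = []
    for assay in ("RPF", "mRNA"):
        if assay not in rpkm.columns.get_level_values(0):
            continue
        sub = rpkm[assay]
        by_cond: dict[str, list[str]] = {}
        for s in sub.columns:
            by_cond.setdefault(cond_map.get(s, s), []).append(s)
        for c, ss in sorted(by_cond.items()):
            if len(ss) >= 2:
                r = counting.replicate_correlation(sub[ss[0]], sub[ss[1]])
                qc_rows.append({"assay": assay, "condition": c, "pearson_r": r})
    _write(
        pd.DataFrame(qc_rows),
        os.path.join(config.outdir, "replicate_correlation.tsv"),
        manifest,
        index=False,
    )

    # A-site profiles and loading ratios ------------------------------------
    profiles = asite.build_profiles(reads, canonical, cond_map)
    lr = asite.loading_ratio_table(profiles, comparisons, config.lr_config)
    _write(lr, os.path.join(config.outdir, "loading_ratios.tsv"), manifest)

    # differential ----------------------------------------------------------
    mrna_rpkm = differential.condition_means(rpkm["mRNA"], cond_map)
    rpf_rpkm = differential.condition_means(rpkm["RPF"], cond_map)
    metrics = differential.gene_metrics(
        mrna_rpkm, rpf_rpkm, comparisons, config.thresholds
    )
    _write(metrics, os.path.join(config.outdir, "gene_metrics.tsv"), manifest)

    if len(comparisons) == 3:
        for flag, fname in (("deg", "venn_deg.tsv"), ("dtg", "venn_dtg.tsv"),
                            ("dte", "venn_dte.tsv")):
            sets = {
                f"{s}_vs_{c}": set(
                    metrics.index[metrics[f"{flag}_{s}_vs_{c}"]]
                )
                for s, c in comparisons
            }
            venn = pd.DataFrame(
                sorted(differential.overlap_sets(sets).items()),
                columns=["pattern", "count"],
            )
            _write(venn, os.path.join(config.outdir, fname), manifest, index=False)

    # stratified statistics ---------------------------------------------------
    comps = []
    for stress, control in comparisons:
        tag = f"{stress}_vs_{control}"
        for element in stratified.ELEMENTS:
            for metric, col in (
                ("r5lr", f"r5lr_{tag}"),
                ("log2fc_te", f"log2fc_te_{tag}"),
            ):
                values = lr[col] if col in lr.columns else metrics.get(col)
                if values is None or values.dropna().empty:
                    continue
                try:
                    comps.append(
                        stratified.compare_by_element(
                            values, elements, element, metric, stress
                        )
                    )
                except ValueError as exc:
                    logger.warning("skipping %s/%s %s: %s", element, metric, tag, exc)
    _write(
        stratified.comparisons_to_frame(comps),
        os.path.join(config.outdir, "element_comparisons.tsv"),
        manifest,
        index=False,
    )

    for stress, control in comparisons:
        col = f"r5lr_{stress}_vs_{control}"
        if col in lr.columns and lr[col].notna().sum() > 0:
            table, med = stratified.ecdf_and_median(lr[col].dropna())
            table.insert(0, "comparison", f"{stress}_vs_{control}")
            _write(
                table,
                os.path.join(config.outdir, f"r5lr_ecdf_{stress}_vs_{control}.tsv"),
                manifest,
                index=False,
            )

    # cluster dynamic TE fold-change profiles over time points
    fc_cols = [f"log2fc_te_{s}_vs_{c}" for s, c in comparisons]
    fc = metrics[fc_cols].dropna()
    if len(comparisons) >= 2 and len(fc) >= config.cluster_k:
        result = stratified.cluster_profiles(fc, config.cluster_k, config.seed)
        _write(
            result.labels.to_frame(),
            os.path.join(config.outdir, "clusters.tsv"),
            manifest,
        )
        _write(
            result.centroids,
            os.path.join(config.outdir, "cluster_centroids.tsv"),
            manifest,
        )

    with open(os.path.join(config.outdir, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
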