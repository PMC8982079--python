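"""End-to-end pipeline driver: simulate -> demux -> count -> bin -> QC ->
spatial statistics -> deconvolution -> regulon activity.

Every stage writes its artifact under the run directory and registers it
in ``manifest.json`` together with the parameters and seeds that produced
it, so a rerun with the same config is byte-identical and any stage can be
skipped when its inputs already exist.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from sklearn.metrics import adjusted_rand_score

from . import binning, demux, io, qc, quantify, spatial, synthetic
from .deconv import CellTypeReference, deconvolve_section
from .matrix import ValidationError
from .regulons import score_section

logger = logging.getLogger(__name__)


class UpstreamMissingError(RuntimeError):
    """An enabled stage is missing the artifact a previous stage produces."""


@dataclass
class PipelineConfig:
    """All knobs of one run; every stochastic stage has an explicit seed."""

    outdir: str = "stereopipe_run"
    # simulation
    simulate: bool = True
    width: int = 200
    height: int = 200
    depth: float = 2.0
    noisy: bool = True
    reads_per_molecule: int = 2
    seed: int = 0
    # inputs when not simulating
    fq1: str | None = None
    fq2: str | None = None
    whitelist: str | None = None
    reference_fasta: str | None = None
    # stage parameters
    max_mismatch: int = 1
    mapq_threshold: int = 10
    bin_size: int = 50
    analysis_bin_size: int = 10
    knn_k: int = 15
    n_perm: int = 500
    svg_q_threshold: float = 0.05
    module_threshold: float = 0.3
    # 10 is the full-scale working default; the built-in synthetic section
    # plants four regions, so its config clusters at k = 4
    kmeans_k: int = 4
    kmeans_n_init: int = 10
    max_types: int = 4
    top_fraction: float = 0.05

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute all stages in order and return the manifest dict.

    The analysis stages (spatial statistics, deconvolution, regulons) run
    at ``analysis_bin_size`` — the desk-scale chip is only a few bin50
    squares wide, so the default working resolution for the synthetic
    section is bin 10 while the bin50 matrix is still produced and
    written, as in the full-scale workflow.
    """
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"parameters": asdict(config), "stages": {}, "metrics": {}}

    # --- simulate ---------------------------------------------------------
    truth = None
    if config.simulate:
        section = synthetic.simulate_section(
            seed=config.seed,
            width=config.width,
            height=config.height,
            depth=config.depth,
            error_model=(
                synthetic.ErrorModel.noisy() if config.noisy else synthetic.ErrorModel.clean()
            ),
            reads_per_molecule=config.reads_per_molecule,
        )
        truth = section.truth
        layout, panel, reads = section.layout, section.gene_panel, section.reads
        io.write_whitelist(layout, out / "whitelist.tsv")
        io.write_reference_fasta(panel, out / "reference.fa")
        io.write_fastq(reads.read1, out / "reads_1.fq.gz")
        io.write_fastq(reads.read2, out / "reads_2.fq.gz")
        io.write_table(reads.provenance, out / "provenance.tsv")
        manifest["stages"]["simulate"] = {
            "seed": config.seed,
            "outputs": ["whitelist.tsv", "reference.fa", "reads_1.fq.gz", "reads_2.fq.gz"],
        }
        read1, read2 = reads.read1, reads.read2
    else:
        for name, p in (("fq1", config.fq1), ("fq2", config.fq2),
                        ("whitelist", config.whitelist),
                        ("reference_fasta", config.reference_fasta)):
            if p is None or not Path(p).exists():
                raise UpstreamMissingError(f"demux stage: missing input {name}")
        layout = io.read_whitelist(config.whitelist)
        panel = io.read_reference_fasta(config.reference_fasta)
        read1 = list(io.read_fastq(config.fq1))
        read2 = list(io.read_fastq(config.fq2))

    # --- demux ------------------------------------------------------------
    result = demux.demux_stream(read1, read2, layout, max_mismatch=config.max_mismatch)
    io.write_table(result.records.drop(columns=["cdna_qual"]), out / "demux_records.tsv")
    q30 = qc.qc_from_reads(read1, read2)
    manifest["stages"]["demux"] = {"counters": result.counters}

    # --- count ------------------------------------------------------------
    bin1, ratios = quantify.count_pipeline(
        result.records, panel, layout.width, layout.height,
        mapq_threshold=config.mapq_threshold, pitch_nm=layout.pitch_nm,
    )
    io.write_gem(bin1, out / "bin1.gem")
    manifest["stages"]["count"] = {"ratios": ratios, "outputs": ["bin1.gem"]}

    # --- bin --------------------------------------------------------------
    final = binning.aggregate(bin1, config.bin_size)
    io.write_gem(final, out / f"bin{config.bin_size}.gem")
    working = binning.aggregate(bin1, config.analysis_bin_size)
    io.write_gem(working, out / f"bin{config.analysis_bin_size}.gem")
    io.write_mtx(working, out / f"bin{config.analysis_bin_size}")
    manifest["stages"]["bin"] = {
        "bin_size": config.bin_size,
        "analysis_bin_size": config.analysis_bin_size,
        "physical": binning.physical_bin_size(config.bin_size, layout.pitch_nm),
    }

    # --- qc ---------------------------------------------------------------
    report = qc.QCReport(
        total_read_pairs=result.counters["total_read_pairs"],
        q30_cid=q30["q30_cid"],
        q30_umi=q30["q30_umi"],
        q30_cdna=q30["q30_cdna"],
        barcode_mapping_ratio=result.barcode_mapping_ratio,
        reads_mapping_ratio=ratios["reads_mapping_ratio"],
        counters=result.counters,
    )
    maps = qc.per_bin_maps(working, panel)
    io.write_table(maps, out / "per_bin_qc.tsv")
    report.to_json(out / "qc_report.json")
    manifest["stages"]["qc"] = {"outputs": ["qc_report.json", "per_bin_qc.tsv"]}
    manifest["metrics"]["barcode_mapping_ratio"] = result.barcode_mapping_ratio
    manifest["metrics"]["reads_mapping_ratio"] = ratios["reads_mapping_ratio"]

    # --- spatial statistics ----------------------------------------------
    bins, genes, X = working.to_dense()
    graph = spatial.build_knn_graph(bins[["x", "y"]].to_numpy(), k=config.knn_k)
    svg = spatial.svg_test(X, graph, n_perm=config.n_perm, seed=config.seed + 10, genes=genes)
    io.write_table(svg, out / "svg.tsv", meta={"seed": config.seed + 10, "n_perm": config.n_perm})
    sig = svg[(svg["testable"]) & (svg["q"] < config.svg_q_threshold)]["gene"].tolist()
    if len(sig) < 2:
        raise ValidationError("fewer than two spatially variable genes detected")
    modules = spatial.detect_modules(
        sig, X, graph, threshold=config.module_threshold, genes=genes
    )
    mod_df = pd.DataFrame(
        [(m, g) for m, gs in modules.modules.items() for g in gs]
        + [("unassigned", g) for g in modules.unassigned],
        columns=["module", "gene"],
    )
    io.write_table(mod_df, out / "modules.tsv")
    scores = spatial.module_scores(X, modules, genes=genes)
    io.write_table(pd.concat([bins, scores], axis=1), out / "module_scores.tsv")
    k_eff = min(config.kmeans_k, len(bins))
    regions = spatial.kmeans_regions(
        scores, k=k_eff, seed=config.seed + 11, n_init=config.kmeans_n_init,
        expression=spatial.normalize_counts(X),
    )
    lab_df = bins.copy()
    lab_df["label"] = regions.labels
    io.write_table(lab_df, out / "region_labels.tsv", meta={"seed": config.seed + 11, "k": k_eff})
    manifest["stages"]["spatial"] = {
        "n_svg": len(sig),
        "n_modules": len(modules.modules),
        "k": k_eff,
        "cluster_percentages": {int(k): float(v) for k, v in regions.percentages.items()},
    }
    top2 = regions.percentages.sort_values(ascending=False).index[:2]
    if (regions.labels == top2[0]).sum() >= 3 and (regions.labels == top2[1]).sum() >= 3:
        deg = spatial.deg_between(X, regions.labels, int(top2[0]), int(top2[1]), genes=genes)
        io.write_table(deg, out / "deg.tsv")
        manifest["stages"]["deg"] = {
            "cluster_a": int(top2[0]), "cluster_b": int(top2[1]),
            "n_significant": int((deg["q"] < 0.05).sum()),
        }

    if truth is not None:
        truth_labels = truth.region_labels(config.analysis_bin_size)
        merged = lab_df.merge(truth_labels, on=["x", "y"])
        ari = adjusted_rand_score(merged["region"], merged["label"])
        manifest["metrics"]["region_ari"] = float(ari)

    # --- deconvolution ----------------------------------------------------
    profiles = synthetic.cell_type_profiles(panel)
    expressed = profiles.index[profiles.sum(axis=1) > 0]
    reference = CellTypeReference(
        profiles=profiles.loc[expressed],
        cell_counts={t: 200 for t in profiles.columns},
    )
    io.write_celltype_reference(
        reference.profiles, reference.cell_counts,
        out / "celltype_profiles.tsv", out / "celltype_meta.tsv",
    )
    deconv_res = deconvolve_section(working, reference, max_types=config.max_types)
    wdf = pd.concat([deconv_res.bins, deconv_res.weights], axis=1)
    io.write_table(wdf, out / "deconv_weights.tsv")
    io.write_table(deconv_res.correlations, out / "deconv_correlations.tsv", index=True)
    (out / "deconv_summary.json").write_text(
        json.dumps(
            {
                "relative_cell_number_pct": deconv_res.relative_cell_number.to_dict(),
                "max_types": config.max_types,
            },
            indent=2, sort_keys=True,
        )
        + "\n"
    )
    manifest["stages"]["deconvolve"] = {
        "relative_cell_number_pct": deconv_res.relative_cell_number.to_dict()
    }
    if truth is not None:
        tw = truth.cell_type_weights(config.analysis_bin_size)
        tw = tw.reindex(pd.MultiIndex.from_frame(deconv_res.bins[["x", "y"]]))
        common = [t for t in deconv_res.weights.columns if t in tw.columns]
        rmse = float(
            np.sqrt(
                np.mean(
                    (deconv_res.weights[common].to_numpy() - tw[common].to_numpy()) ** 2
                )
            )
        )
        manifest["metrics"]["deconv_weight_rmse"] = rmse

    # --- regulon activity -------------------------------------------------
    regulon_set = synthetic.make_default_regulons()
    io.write_regulons(regulon_set, out / "regulons.tsv")
    activity = score_section(
        working, regulon_set, top_fraction=config.top_fraction, seed=config.seed + 12
    )
    io.write_table(
        pd.concat([activity.bins, activity.scores], axis=1),
        out / "regulon_activity.tsv",
        meta={"seed": config.seed + 12, "top_fraction": config.top_fraction},
    )
    io.write_table(activity.correlations, out / "regulon_correlations.tsv", index=True)
    manifest["stages"]["regulons"] = {"n_regulons": len(regulon_set)}

    manifest_path = out / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return manifest
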