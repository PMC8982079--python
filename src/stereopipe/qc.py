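"""Quality-control metrics: Q30, mapping ratios, per-bin maps, section R2.

The metric definitions mirror standard sequencing QC: Q30 is the fraction
of bases at Phred >= 30 (Phred+33 encoding); the barcode mapping ratio is
the fraction of read pairs with a valid, unambiguous CID; the reads
mapping ratio is the fraction of demux-accepted reads that align.  Between
sections, reproducibility is summarized as the squared Pearson correlation
of log1p per-gene pseudobulk totals.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
import pandas as pd
from scipy import stats

from .matrix import CountMatrix, ValidationError
from .quantify import GeneReference, MITO_PREFIX


def q30_fraction(quality_strings: Iterable[str]) -> float:
    """Fraction of bases with Phred score >= 30 across all given strings."""
    total = 0
    good = 0
    for q in quality_strings:
        total += len(q)
        good += sum(1 for c in q if ord(c) - 33 >= 30)
    if total == 0:
        raise ValidationError("no bases supplied to q30_fraction")
    return good / total


def per_bin_maps(matrix: CountMatrix, reference: GeneReference | None = None) -> pd.DataFrame:
    """Per-bin UMI totals and mitochondrial fraction.

    Mito genes are identified by the ``mt-`` prefix (from the reference if
    given, else from gene names in the matrix).  Bins with zero total get
    ``mito_fraction = 0`` and ``mito_defined = False``.
    """
    if len(matrix.counts) == 0:
        raise ValidationError("empty matrix")
    if reference is not None:
        mito = set(reference.mito_genes())
    else:
        mito = {g for g in matrix.counts["gene"].unique() if g.startswith(MITO_PREFIX)}
    df = matrix.counts
    totals = df.groupby(["x", "y"])["count"].sum()
    mito_totals = (
        df[df["gene"].isin(mito)].groupby(["x", "y"])["count"].sum()
        if mito
        else pd.Series(dtype=np.int64)
    )
    out = totals.to_frame("total")
    out["mito"] = mito_totals
    out["mito"] = out["mito"].fillna(0).astype(np.int64)
    out["mito_defined"] = out["total"] > 0
    out["mito_fraction"] = np.where(out["total"] > 0, out["mito"] / out["total"], 0.0)
    return out.reset_index()


def section_r2(matrix_a: CountMatrix, matrix_b: CountMatrix) -> float:
    """Between-section reproducibility R^2.

    Per-gene pseudobulk sums over the union gene universe (absent genes
    count 0), log1p transformed, squared Pearson correlation across genes.
    Symmetric and invariant to any common gene reordering.
    """
    sa = matrix_a.counts.groupby("gene")["count"].sum()
    sb = matrix_b.counts.groupby("gene")["count"].sum()
    genes = sorted(set(sa.index) | set(sb.index))
    va = np.log1p(sa.reindex(genes).fillna(0).to_numpy(dtype=float))
    vb = np.log1p(sb.reindex(genes).fillna(0).to_numpy(dtype=float))
    if len(genes) < 2 or len(np.unique(va)) < 2 or len(np.unique(vb)) < 2:
        raise ValidationError("need >= 2 genes with nonzero variance for R^2")
    r, _ = stats.pearsonr(va, vb)
    return float(r**2)


@dataclass
class QCReport:
    """Merged QC block written alongside every pipeline run."""

    total_read_pairs: int = 0
    q30_cid: float = float("nan")
    q30_umi: float = float("nan")
    q30_cdna: float = float("nan")
    barcode_mapping_ratio: float = float("nan")
    reads_mapping_ratio: float = float("nan")
    counters: dict = field(default_factory=dict)
    section_r2: dict = field(default_factory=dict)
    notes: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name in (
            "q30_cid",
            "q30_umi",
            "q30_cdna",
            "barcode_mapping_ratio",
            "reads_mapping_ratio",
        ):
            v = getattr(self, name)
            if not (np.isnan(v) or 0 <= v <= 1):
                raise ValidationError(f"{name} outside [0, 1]")

    def to_dict(self) -> dict:
        return {
            "total_read_pairs": self.total_read_pairs,
            "q30_cid": self.q30_cid,
            "q30_umi": self.q30_umi,
            "q30_cdna": self.q30_cdna,
            "barcode_mapping_ratio": self.barcode_mapping_ratio,
            "barcode_mapping_ratio_definition": "reads with valid unambiguous CID / total read pairs",
            "reads_mapping_ratio": self.reads_mapping_ratio,
            "reads_mapping_ratio_definition": "mapped reads / reads entering alignment",
            "counters": self.counters,
            "section_r2": self.section_r2,
            "notes": self.notes,
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2, sort_keys=True)
            fh.write("\n")


def qc_from_reads(
    read1: Iterable[tuple[str, str, str]],
    read2: Iterable[tuple[str, str, str]],
) -> dict:
    """Per-segment Q30 from raw paired reads (CID / UMI / cDNA split)."""
    cid_q, umi_q, cdna_q = [], [], []
    for (_, _, q1), (_, _, q2) in zip(read1, read2):
        if len(q1) >= 35:
            cid_q.append(q1[:25])
            umi_q.append(q1[25:35])
        cdna_q.append(q2)
    return {
        "q30_cid": q30_fraction(cid_q),
        "q30_umi": q30_fraction(umi_q),
        "q30_cdna": q30_fraction(cdna_q),
    }
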