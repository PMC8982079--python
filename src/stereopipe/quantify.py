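"""Toy alignment, MAPQ filtering, UMI deduplication and the bin1 matrix.

A real Stereo-seq run aligns cDNA to a genome with a splice-aware aligner;
here the reference is a small set of unspliced gene sequences and alignment
is exact substring search on both strands.  The disposal rule for poor
alignments is kept as-is: anything with MAPQ below 10 is dropped.  External
alignment tables (read_id, gene, mapq) can be fed straight into
:func:`dedup_and_count` for real data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .matrix import CountMatrix, ValidationError

MITO_PREFIX = "mt-"
#: conventional scores: unique placement / multi-gene placement
MAPQ_UNIQUE = 255
MAPQ_MULTI = 3

_RC = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    return seq.translate(_RC)[::-1]


@dataclass
class GeneReference:
    """Gene id -> sequence map; ids with the ``mt-`` prefix are mitochondrial."""

    genes: dict[str, str]

    def __post_init__(self) -> None:
        if not self.genes:
            raise ValidationError("empty gene reference")
        for gid, seq in self.genes.items():
            if not seq:
                raise ValidationError(f"gene {gid!r} has an empty sequence")
        self.genes = dict(self.genes)

    def __len__(self) -> int:
        return len(self.genes)

    def ids(self) -> list[str]:
        return sorted(self.genes)

    def mito_genes(self) -> list[str]:
        return sorted(g for g in self.genes if g.startswith(MITO_PREFIX))


@dataclass(frozen=True)
class Alignment:
    read_id: str
    gene: str | None
    mapq: int


def align_read(cdna_seq: str, reference: GeneReference) -> tuple[str | None, int]:
    """Place a read by exact substring search over both strands.

    Returns ``(gene, mapq)``: a unique hit scores MAPQ 255, a hit in two or
    more genes scores MAPQ 3 (disposed of downstream by the MAPQ < 10
    rule), no hit returns ``(None, 0)``.  The search stops as soon as two
    distinct genes have hit — the MAPQ outcome is already decided then.
    """
    if not cdna_seq:
        raise ValueError("empty read")
    rc = revcomp(cdna_seq)
    hits: list[str] = []
    for gid, seq in reference.genes.items():
        if cdna_seq in seq or rc in seq:
            hits.append(gid)
            if len(hits) == 2:
                break
    if not hits:
        return None, 0
    if len(hits) == 1:
        return hits[0], MAPQ_UNIQUE
    return hits[0], MAPQ_MULTI


class ReadAligner:
    """Memoizing bulk wrapper around :func:`align_read`.

    PCR duplicates share their cDNA string, so a small cache removes most
    repeated scans without changing any result.
    """

    def __init__(self, reference: GeneReference):
        self.reference = reference
        self._cache: dict[str, tuple[str | None, int]] = {}

    def align(self, cdna_seq: str) -> tuple[str | None, int]:
        hit = self._cache.get(cdna_seq)
        if hit is None:
            hit = align_read(cdna_seq, self.reference)
            self._cache[cdna_seq] = hit
        return hit

    def align_records(self, records: pd.DataFrame) -> pd.DataFrame:
        """Align a demux record table -> (read_id, gene, mapq) table."""
        out = [self.align(s) for s in records["cdna_seq"]]
        genes = [g for g, _ in out]
        mapqs = [q for _, q in out]
        return pd.DataFrame(
            {"read_id": records["read_id"].to_numpy(), "gene": genes, "mapq": mapqs}
        )


def filter_mapq(alignments: pd.DataFrame, threshold: int = 10) -> pd.DataFrame:
    """Keep mapped alignments with MAPQ >= threshold (strict '< 10' removal)."""
    mapped = alignments["gene"].notna()
    return alignments[mapped & (alignments["mapq"] >= threshold)].reset_index(drop=True)


def mapping_ratios(alignments: pd.DataFrame, threshold: int = 10) -> dict:
    """Reads-mapping ratio and post-MAPQ retention for the QC report.

    ``reads_mapping_ratio`` = mapped reads / reads entering alignment,
    measured before the MAPQ filter; ``mapq_retention`` is the fraction of
    entering reads surviving the filter as well.
    """
    n = len(alignments)
    if n == 0:
        return {"reads_mapping_ratio": float("nan"), "mapq_retention": float("nan")}
    mapped = int(alignments["gene"].notna().sum())
    kept = len(filter_mapq(alignments, threshold))
    return {"reads_mapping_ratio": mapped / n, "mapq_retention": kept / n}


def dedup_and_count(
    records: pd.DataFrame, width: int, height: int, pitch_nm: int = 500
) -> CountMatrix:
    """Collapse UMI duplicates and build the bin1 matrix.

    ``records`` must carry columns x, y, gene, umi (accepted demux records
    joined to MAPQ-kept alignments).  The count at (gene, x, y) is the
    number of distinct UMI strings at that key; no edit-distance merging.
    """
    needed = {"x", "y", "gene", "umi"}
    if not needed <= set(records.columns):
        raise ValidationError(f"records need columns {sorted(needed)}")
    if len(records) == 0:
        return CountMatrix(
            pd.DataFrame(columns=["gene", "x", "y", "count"]), width, height, 1, pitch_nm
        )
    uniq = records.drop_duplicates(subset=["gene", "x", "y", "umi"])
    counts = (
        uniq.groupby(["gene", "x", "y"], as_index=False)
        .size()
        .rename(columns={"size": "count"})
    )
    return CountMatrix(counts, width, height, 1, pitch_nm)


def count_pipeline(
    demux_records: pd.DataFrame,
    reference: GeneReference,
    width: int,
    height: int,
    mapq_threshold: int = 10,
    pitch_nm: int = 500,
) -> tuple[CountMatrix, dict]:
    """Demux records -> aligned, filtered, deduplicated bin1 matrix + ratios."""
    aligner = ReadAligner(reference)
    aln = aligner.align_records(demux_records)
    ratios = mapping_ratios(aln, mapq_threshold)
    kept = filter_mapq(aln, mapq_threshold)
    joined = demux_records.merge(kept[["read_id", "gene"]], on="read_id", how="inner")
    mat = dedup_and_count(joined, width, height, pitch_nm)
    ratios["reads_entering_alignment"] = len(aln)
    ratios["reads_after_mapq"] = len(kept)
    return mat, ratios
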