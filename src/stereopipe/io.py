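"""Readers and writers for every on-disk format the pipeline touches.

Dialects:

* GEM: tab-separated ``geneID  x  y  MIDCount`` with ``#key=value``
  comment lines carrying provenance (stage, bin_size, pitch, seed).
* MTX: MatrixMarket triplets (genes x bins) plus ``.features.tsv`` and
  ``.barcodes.tsv`` companions; barcodes encode coordinates as ``x_y``.
* FASTQ: 4-line records, optionally gzip (parsed with Biopython's fast
  iterator); gzip members are written with a zeroed mtime so repeated
  runs are byte-identical.
* whitelist TSV ``cid  x  y`` (no header); cell-type reference TSV pair;
  regulon TSV ``tf  target`` long format.
"""

from __future__ import annotations

import gzip
import io as _io
from pathlib import Path
from typing import Iterable, Iterator

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.SeqIO.QualityIO import FastqGeneralIterator
from scipy import io as scipy_io
from scipy import sparse

from .matrix import CountMatrix, ValidationError
from .quantify import GeneReference
from .regulons import Regulon
from .synthetic import ChipLayout

GEM_HEADER = ["geneID", "x", "y", "MIDCount"]


# ---------------------------------------------------------------------------
# GEM
# ---------------------------------------------------------------------------


def write_gem(matrix: CountMatrix, path) -> None:
    meta = {
        "format": "gem v1",
        "width": matrix.width,
        "height": matrix.height,
        "bin_size": matrix.bin_size,
        "pitch_nm": matrix.pitch_nm,
        **matrix.meta,
    }
    df = matrix.counts.rename(
        columns={"gene": "geneID", "count": "MIDCount"}
    ).sort_values(["geneID", "x", "y"])
    with open(path, "w") as fh:
        for k, v in meta.items():
            fh.write(f"#{k}={v}\n")
        df.to_csv(fh, sep="\t", index=False, columns=GEM_HEADER)


def read_gem(path) -> CountMatrix:
    meta: dict = {}
    n_comment = 0
    with open(path) as fh:
        pos = fh.tell()
        for line in fh:
            if not line.startswith("#"):
                break
            n_comment += 1
            body = line[1:].strip()
            if "=" in body:
                k, v = body.split("=", 1)
                meta[k] = v
        fh.seek(pos)
        for _ in range(n_comment):
            fh.readline()
        try:
            df = pd.read_csv(fh, sep="\t", dtype={"geneID": str})
        except Exception as exc:
            raise ValidationError(f"{path}: malformed GEM table: {exc}") from exc
    if list(df.columns) != GEM_HEADER:
        raise ValidationError(
            f"{path}: unknown header {list(df.columns)}; expected {GEM_HEADER}"
        )
    for col in ("x", "y", "MIDCount"):
        bad = df.index[~np.isfinite(pd.to_numeric(df[col], errors="coerce"))]
        if len(bad):
            raise ValidationError(
                f"{path}: non-numeric {col} at line {bad[0] + n_comment + 2}"
            )
    neg = df.index[(df["MIDCount"] <= 0) | (df["x"] < 0) | (df["y"] < 0)]
    if len(neg):
        raise ValidationError(
            f"{path}: invalid count/coordinate at line {neg[0] + n_comment + 2}"
        )
    width = int(meta.pop("width", df["x"].max() + 1))
    height = int(meta.pop("height", df["y"].max() + 1))
    bin_size = int(meta.pop("bin_size", 1))
    pitch_nm = int(meta.pop("pitch_nm", 500))
    meta.pop("format", None)
    counts = df.rename(columns={"geneID": "gene", "MIDCount": "count"})
    # GEM width/height are in bin1 units even for binned matrices
    return CountMatrix(counts, width, height, bin_size, pitch_nm, meta)


# ---------------------------------------------------------------------------
# MTX triplet + features + barcodes
# ---------------------------------------------------------------------------


def write_mtx(matrix: CountMatrix, prefix) -> None:
    """Write ``<prefix>.mtx`` plus features/barcodes companions."""
    prefix = Path(prefix)
    genes = matrix.genes()
    df = matrix.counts
    barcodes = sorted(set(zip(df["x"], df["y"])))
    g_idx = {g: i for i, g in enumerate(genes)}
    b_idx = {b: i for i, b in enumerate(barcodes)}
    rows = df["gene"].map(g_idx).to_numpy()
    cols = [b_idx[(x, y)] for x, y in zip(df["x"], df["y"])]
    M = sparse.coo_matrix(
        (df["count"].to_numpy(), (rows, cols)), shape=(len(genes), len(barcodes))
    )
    comment = (
        f"stereopipe mtx; width={matrix.width} height={matrix.height} "
        f"bin_size={matrix.bin_size} pitch_nm={matrix.pitch_nm}"
    )
    scipy_io.mmwrite(str(prefix) + ".mtx", M, comment=comment, field="integer")
    Path(str(prefix) + ".features.tsv").write_text("".join(g + "\n" for g in genes))
    Path(str(prefix) + ".barcodes.tsv").write_text(
        "".join(f"{x}_{y}\n" for x, y in barcodes)
    )


def read_mtx(prefix) -> CountMatrix:
    prefix = str(prefix)
    with open(prefix + ".mtx") as fh:
        header = [fh.readline() for _ in range(2)]
    meta: dict = {}
    for line in header:
        if line.startswith("%") and "stereopipe mtx" in line:
            for tok in line.split(";", 1)[1].split():
                k, v = tok.split("=")
                meta[k] = int(v)
    M = scipy_io.mmread(prefix + ".mtx").tocoo()
    genes = Path(prefix + ".features.tsv").read_text().splitlines()
    barcodes = Path(prefix + ".barcodes.tsv").read_text().splitlines()
    coords = [tuple(int(v) for v in b.split("_")) for b in barcodes]
    counts = pd.DataFrame(
        {
            "gene": [genes[i] for i in M.row],
            "x": [coords[j][0] for j in M.col],
            "y": [coords[j][1] for j in M.col],
            "count": M.data.astype(np.int64),
        }
    )
    width = meta.get("width", int(counts["x"].max()) + 1 if len(counts) else 1)
    height = meta.get("height", int(counts["y"].max()) + 1 if len(counts) else 1)
    return CountMatrix(
        counts,
        width,
        height,
        meta.get("bin_size", 1),
        meta.get("pitch_nm", 500),
    )


# ---------------------------------------------------------------------------
# FASTQ
# ---------------------------------------------------------------------------


def _open_text(path, mode: str):
    path = str(path)
    if path.endswith(".gz"):
        if "w" in mode:
            # fixed mtime/filename so identical content -> identical bytes
            raw = open(path, "wb")
            gz = gzip.GzipFile(filename="", mode="wb", fileobj=raw, mtime=0)
            return _io.TextIOWrapper(gz, encoding="ascii", newline="\n")
        return gzip.open(path, "rt")
    return open(path, mode)


def write_fastq(reads: Iterable[tuple[str, str, str]], path) -> None:
    """Write ``(id, seq, qual)`` records as plain or gzip FASTQ."""
    with _open_text(path, "w") as fh:
        for rid, seq, qual in reads:
            fh.write(f"@{rid}\n{seq}\n+\n{qual}\n")


def read_fastq(path) -> Iterator[tuple[str, str, str]]:
    """Yield ``(id, seq, qual)`` from plain or gzip FASTQ."""
    with _open_text(path, "r") as fh:
        for rid, seq, qual in FastqGeneralIterator(fh):
            yield rid, seq, qual


# ---------------------------------------------------------------------------
# whitelist
# ---------------------------------------------------------------------------


def write_whitelist(layout: ChipLayout, path) -> None:
    with open(path, "w") as fh:
        for cid, (x, y) in sorted(layout.entries.items(), key=lambda kv: (kv[1][1], kv[1][0])):
            fh.write(f"{cid}\t{x}\t{y}\n")


def read_whitelist(path, width: int | None = None, height: int | None = None,
                   pitch_nm: int = 500) -> ChipLayout:
    entries: dict[str, tuple[int, int]] = {}
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            parts = line.rstrip("\n").split("\t")
            if len(parts) != 3:
                raise ValidationError(f"{path}: malformed whitelist row at line {ln}")
            cid, xs, ys = parts
            try:
                x, y = int(xs), int(ys)
            except ValueError as exc:
                raise ValidationError(
                    f"{path}: non-integer coordinate at line {ln}"
                ) from exc
            if cid in entries:
                raise ValidationError(f"{path}: duplicate CID at line {ln}")
            entries[cid] = (x, y)
    if not entries:
        raise ValidationError(f"{path}: empty whitelist")
    xs = [x for x, _ in entries.values()]
    ys = [y for _, y in entries.values()]
    return ChipLayout(
        width=width if width is not None else max(xs) + 1,
        height=height if height is not None else max(ys) + 1,
        entries=entries,
        pitch_nm=pitch_nm,
    )


# ---------------------------------------------------------------------------
# gene reference, cell-type reference, regulons, generic tables
# ---------------------------------------------------------------------------


def write_reference_fasta(reference: GeneReference, path) -> None:
    with open(path, "w") as fh:
        for gid in reference.ids():
            fh.write(f">{gid}\n{reference.genes[gid]}\n")


def read_reference_fasta(path) -> GeneReference:
    genes = {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}
    if not genes:
        raise ValidationError(f"{path}: no FASTA records")
    return GeneReference(genes)


def write_celltype_reference(profiles: pd.DataFrame, cell_counts: dict[str, int],
                             profile_path, meta_path) -> None:
    profiles.rename_axis("gene").to_csv(profile_path, sep="\t")
    pd.DataFrame(
        {"cell_type": list(cell_counts), "n_cells": list(cell_counts.values())}
    ).to_csv(meta_path, sep="\t", index=False)


def read_celltype_reference(profile_path, meta_path):
    from .deconv import CellTypeReference

    profiles = pd.read_csv(profile_path, sep="\t", index_col="gene")
    meta = pd.read_csv(meta_path, sep="\t")
    if not {"cell_type", "n_cells"} <= set(meta.columns):
        raise ValidationError(f"{meta_path}: expected cell_type and n_cells columns")
    counts = dict(zip(meta["cell_type"], meta["n_cells"].astype(int)))
    return CellTypeReference(profiles=profiles, cell_counts=counts)


def write_regulons(regulons: list[Regulon], path) -> None:
    with open(path, "w") as fh:
        fh.write("tf\ttarget\n")
        for r in regulons:
            for t in r.targets:
                fh.write(f"{r.tf}\t{t}\n")


def read_regulons(path) -> list[Regulon]:
    df = pd.read_csv(path, sep="\t")
    if list(df.columns) != ["tf", "target"]:
        raise ValidationError(f"{path}: expected header 'tf\\ttarget'")
    out = []
    for tf, grp in df.groupby("tf", sort=True):
        out.append(Regulon(tf, tuple(grp["target"])))
    return out


def write_table(df: pd.DataFrame, path, meta: dict | None = None, index: bool = False) -> None:
    """Generic TSV writer with a ``#key=value`` provenance header block."""
    with open(path, "w") as fh:
        for k, v in (meta or {}).items():
            fh.write(f"#{k}={v}\n")
        df.to_csv(fh, sep="\t", index=index)


def read_table(path, **kwargs) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", **kwargs)
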