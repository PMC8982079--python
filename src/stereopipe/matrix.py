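"""Sparse spatial count containers shared by all pipeline stages.

A Stereo-seq expression matrix is a set of ``(gene, x, y) -> UMI count``
triplets over a rectangular lattice of capture spots.  At native resolution
(``bin_size == 1``) a coordinate is one 500 nm-pitch spot; after aggregation
a coordinate indexes a square block of ``bin_size`` x ``bin_size`` spots.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

COUNT_COLUMNS = ("gene", "x", "y", "count")


class ValidationError(ValueError):
    """Raised when an input object or file violates its format contract."""


@dataclass
class CountMatrix:
    """Triplet-form spatial count matrix.

    Parameters
    ----------
    counts
        DataFrame with columns ``gene, x, y, count``; one row per occupied
        (gene, coordinate) key, counts strictly positive integers.
    width, height
        Chip extent in bin1 spots (always in native units, independent of
        ``bin_size``).
    bin_size
        Aggregation factor; 1 for the raw matrix.
    pitch_nm
        Physical center-to-center spot distance.
    """

    counts: pd.DataFrame
    width: int
    height: int
    bin_size: int = 1
    pitch_nm: int = 500
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.width < 1 or self.height < 1:
            raise ValidationError("chip dimensions must be positive")
        if self.bin_size < 1:
            raise ValidationError("bin_size must be >= 1")
        df = self.counts
        missing = set(COUNT_COLUMNS) - set(df.columns)
        if missing:
            raise ValidationError(f"count table missing columns: {sorted(missing)}")
        df = df.loc[:, list(COUNT_COLUMNS)].reset_index(drop=True)
        if len(df):
            if (df["count"] <= 0).any():
                raise ValidationError("counts must be strictly positive")
            if df.duplicated(subset=["gene", "x", "y"]).any():
                raise ValidationError("(gene, x, y) keys must be unique")
            if (df["x"] < 0).any() or (df["y"] < 0).any():
                raise ValidationError("coordinates must be non-negative")
            if (df["x"] >= self.nx).any() or (df["y"] >= self.ny).any():
                raise ValidationError("coordinates outside the chip")
        self.counts = df.astype(
            {"gene": str, "x": np.int64, "y": np.int64, "count": np.int64}
        )

    # -- geometry ---------------------------------------------------------

    @property
    def nx(self) -> int:
        """Number of bins along x at the current bin_size."""
        return math.ceil(self.width / self.bin_size)

    @property
    def ny(self) -> int:
        return math.ceil(self.height / self.bin_size)

    def bin_center(self, bx: int, by: int) -> tuple[float, float]:
        """Center of a bin in bin1 units (the 'assigned coordinate')."""
        s = self.bin_size
        return (bx * s + (s - 1) / 2.0, by * s + (s - 1) / 2.0)

    # -- summaries --------------------------------------------------------

    def total(self) -> int:
        return int(self.counts["count"].sum())

    def genes(self) -> list[str]:
        return sorted(self.counts["gene"].unique())

    def per_bin_totals(self) -> pd.DataFrame:
        """Total UMI count per occupied bin (columns x, y, total)."""
        out = (
            self.counts.groupby(["x", "y"], as_index=False)["count"]
            .sum()
            .rename(columns={"count": "total"})
        )
        return out

    def to_dense(
        self, genes: list[str] | None = None, drop_empty: bool = True
    ) -> tuple[pd.DataFrame, list[str], np.ndarray]:
        """Densify to (bins table, gene list, bins x genes array).

        Bins are ordered row-major (y slow, x fast).  With ``drop_empty``
        only bins holding at least one count are returned, which is what
        the spatial statistics operate on.
        """
        if genes is None:
            genes = self.genes()
        gene_idx = {g: i for i, g in enumerate(genes)}
        df = self.counts[self.counts["gene"].isin(gene_idx)]
        nx, ny = self.nx, self.ny
        X = np.zeros((nx * ny, len(genes)), dtype=np.float64)
        flat = df["y"].to_numpy() * nx + df["x"].to_numpy()
        cols = df["gene"].map(gene_idx).to_numpy()
        np.add.at(X, (flat, cols), df["count"].to_numpy())
        bx, by = np.meshgrid(np.arange(nx), np.arange(ny))
        bins = pd.DataFrame({"x": bx.ravel(), "y": by.ravel()})
        if drop_empty:
            keep = X.sum(axis=1) > 0
            bins = bins.loc[keep].reset_index(drop=True)
            X = X[keep]
        return bins, list(genes), X

    def copy(self) -> "CountMatrix":
        return CountMatrix(
            self.counts.copy(),
            self.width,
            self.height,
            self.bin_size,
            self.pitch_nm,
            dict(self.meta),
        )


def matrices_equal(a: CountMatrix, b: CountMatrix) -> bool:
    """Exact triplet-set equality (ignores row order and metadata)."""
    key = ["gene", "x", "y"]
    da = a.counts.sort_values(key).reset_index(drop=True)
    db = b.counts.sort_values(key).reset_index(drop=True)
    return da.equals(db)
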