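"""Bin aggregation: collapse the raw bin1 matrix into binN squares.

Default working resolution follows the study design: 50 x 50 spots per
bin, i.e. 25 um at the 500 nm pitch.  Bins are half-open floor-division
squares with 0-based coordinates; partial bins at the chip edge are kept
and flagged with their true spot capacity.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .matrix import CountMatrix, ValidationError


def assign_bin(x: int, y: int, bin_size: int) -> tuple[int, int]:
    """Map a bin1 coordinate to its binN coordinate (floor division)."""
    if bin_size < 1:
        raise ValidationError("bin_size must be >= 1")
    if x < 0 or y < 0:
        raise ValidationError("coordinates must be non-negative")
    return x // bin_size, y // bin_size


def aggregate(matrix: CountMatrix, bin_size: int) -> CountMatrix:
    """Sum counts over bin_size x bin_size squares; totals are conserved.

    The recorded bin center is ``(bx*s + (s-1)/2, by*s + (s-1)/2)`` in
    bin1 units, available through :meth:`CountMatrix.bin_center`.
    """
    if bin_size < 1:
        raise ValidationError("bin_size must be >= 1")
    if matrix.bin_size != 1:
        raise ValidationError("aggregate expects a bin1 matrix; use rebin() to nest")
    df = matrix.counts.copy()
    df["x"] = df["x"] // bin_size
    df["y"] = df["y"] // bin_size
    out = df.groupby(["gene", "x", "y"], as_index=False)["count"].sum()
    meta = dict(matrix.meta)
    meta["bin_size"] = bin_size
    return CountMatrix(out, matrix.width, matrix.height, bin_size, matrix.pitch_nm, meta)


def rebin(matrix: CountMatrix, factor: int) -> CountMatrix:
    """Aggregate an already-binned matrix by a further integer factor."""
    if factor < 1:
        raise ValidationError("factor must be >= 1")
    df = matrix.counts.copy()
    df["x"] = df["x"] // factor
    df["y"] = df["y"] // factor
    out = df.groupby(["gene", "x", "y"], as_index=False)["count"].sum()
    return CountMatrix(
        out,
        matrix.width,
        matrix.height,
        matrix.bin_size * factor,
        matrix.pitch_nm,
        dict(matrix.meta),
    )


def bin_capacity(width: int, height: int, bin_size: int) -> pd.DataFrame:
    """Spots actually covered by each bin; flags partial edge bins.

    Per-area normalizations should exclude (or rescale) bins with
    ``partial == True``.
    """
    nx = -(-width // bin_size)
    ny = -(-height // bin_size)
    bx, by = np.meshgrid(np.arange(nx), np.arange(ny))
    wx = np.minimum((bx + 1) * bin_size, width) - bx * bin_size
    wy = np.minimum((by + 1) * bin_size, height) - by * bin_size
    cap = (wx * wy).ravel()
    return pd.DataFrame(
        {
            "x": bx.ravel(),
            "y": by.ravel(),
            "n_spots": cap,
            "partial": cap < bin_size * bin_size,
        }
    )


def physical_bin_size(bin_size: int, pitch_nm: int = 500) -> dict:
    """Edge length of a bin in physical units (nm and um)."""
    if bin_size < 1 or pitch_nm <= 0:
        raise ValidationError("bin_size and pitch must be positive")
    nm = bin_size * pitch_nm
    return {"nm": nm, "um": nm / 1000.0}
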