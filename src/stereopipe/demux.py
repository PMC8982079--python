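"""Read parsing, CID whitelist matching and UMI quality filtering.

Stereo-seq read1 carries the coordinate identity (CID) in bases 1-25 and the
UMI in bases 26-35 (1-based, inclusive); read2 is the cDNA payload.  A read
pair is kept when its CID matches the chip whitelist with at most one base
mismatch (unambiguously) and its UMI passes the quality rule: no 'N' base
and fewer than two bases below Phred 10.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Iterator

import numpy as np
import pandas as pd

CID_LEN = 25
UMI_LEN = 10
READ1_MIN_LEN = CID_LEN + UMI_LEN

_BASES = "ACGT"

#: rejection reasons, in the order the per-read decision cascade applies them
REJECTION_REASONS = ("too_short", "invalid_cid", "ambiguous_cid", "low_quality_umi")


@dataclass(frozen=True)
class ParsedRead:
    read_id: str
    cid: str
    cid_qual: str
    umi: str
    umi_qual: str
    cdna_seq: str = ""
    cdna_qual: str = ""


def parse_read1(seq: str, qual: str, read_id: str = "") -> ParsedRead | None:
    """Split read1 into CID and UMI segments; ``None`` if too short.

    Bases beyond position 35 (e.g. sequencing adapters) are ignored.
    """
    if len(seq) != len(qual):
        raise ValueError("sequence and quality strings differ in length")
    if len(seq) < READ1_MIN_LEN:
        return None
    return ParsedRead(
        read_id=read_id,
        cid=seq[:CID_LEN],
        cid_qual=qual[:CID_LEN],
        umi=seq[CID_LEN:READ1_MIN_LEN],
        umi_qual=qual[CID_LEN:READ1_MIN_LEN],
    )


def umi_passes_filter(umi: str, umi_qual: str) -> bool:
    """False iff the UMI holds any 'N' or >= 2 bases with Phred < 10.

    Phred scores are ASCII - 33; "lower than 10" is strict, so Q10 ('+')
    bases do not count against the read.
    """
    if "N" in umi:
        return False
    low = sum(1 for c in umi_qual if ord(c) - 33 < 10)
    return low < 2


class CIDIndex:
    """Exact-lookup whitelist index with 1-neighborhood probing.

    An exact hash hit short-circuits; otherwise all 75 single-base variants
    of the query are probed against the same hash, which finds exactly the
    whitelist entries at Hamming distance 1.  'N' in the query is never in
    the whitelist alphabet, so it behaves as a mismatch at that position.
    """

    def __init__(self, entries: dict[str, tuple[int, int]]):
        for cid in entries:
            if len(cid) != CID_LEN:
                raise ValueError(f"whitelist CID of length {len(cid)} != {CID_LEN}")
        self._exact = dict(entries)

    def __len__(self) -> int:
        return len(self._exact)

    def match(self, cid: str, max_mismatch: int = 1):
        """Return ``(status, coord)``; status in {'unique','invalid','ambiguous'}."""
        if len(cid) != CID_LEN:
            raise ValueError("query CID must be 25 bases")
        if max_mismatch not in (0, 1):
            raise NotImplementedError("only 0 or 1 mismatch tolerance supported")
        hit = self._exact.get(cid)
        if hit is not None:
            return "unique", hit
        if max_mismatch == 0:
            return "invalid", None
        found: list[tuple[int, int]] = []
        for pos in range(CID_LEN):
            orig = cid[pos]
            prefix, suffix = cid[:pos], cid[pos + 1 :]
            for base in _BASES:
                if base == orig:
                    continue
                coord = self._exact.get(prefix + base + suffix)
                if coord is not None:
                    found.append(coord)
                    if len(found) > 1:
                        return "ambiguous", None
        if len(found) == 1:
            return "unique", found[0]
        return "invalid", None


def match_cid(cid: str, layout, max_mismatch: int = 1):
    """Convenience wrapper building a throwaway index from a ChipLayout."""
    entries = layout.entries if hasattr(layout, "entries") else layout
    return CIDIndex(entries).match(cid, max_mismatch=max_mismatch)


@dataclass
class DemuxResult:
    """Accepted records plus the per-reason rejection bookkeeping."""

    records: pd.DataFrame  # read_id, x, y, umi, cdna_seq, cdna_qual
    rejections: pd.DataFrame  # read_id, reason
    counters: dict

    @property
    def barcode_mapping_ratio(self) -> float:
        """Reads with a valid, unambiguous CID over all read pairs."""
        total = self.counters["total_read_pairs"]
        if total == 0:
            return float("nan")
        valid = total - sum(
            self.counters[r] for r in ("too_short", "invalid_cid", "ambiguous_cid")
        )
        return valid / total


def demux_stream(
    read1: Iterable[tuple[str, str, str]],
    read2: Iterable[tuple[str, str, str]],
    layout,
    max_mismatch: int = 1,
) -> DemuxResult:
    """Demultiplex paired ``(read_id, seq, qual)`` streams.

    The decision cascade per read pair is parse -> CID match -> UMI filter;
    a read failing several rules is attributed to the first one, so the
    counters partition the input exactly.
    """
    entries = layout.entries if hasattr(layout, "entries") else layout
    index = CIDIndex(entries)
    counters = {r: 0 for r in REJECTION_REASONS}
    accepted: list[tuple] = []
    rejected: list[tuple[str, str]] = []
    total = 0
    it1: Iterator = iter(read1)
    it2: Iterator = iter(read2)
    try:
        pairs = zip(it1, it2, strict=True)
        for (rid1, seq1, qual1), (rid2, seq2, qual2) in pairs:
            total += 1
            parsed = parse_read1(seq1, qual1, read_id=rid1)
            if parsed is None:
                counters["too_short"] += 1
                rejected.append((rid1, "too_short"))
                continue
            status, coord = index.match(parsed.cid, max_mismatch=max_mismatch)
            if status == "invalid":
                counters["invalid_cid"] += 1
                rejected.append((rid1, "invalid_cid"))
                continue
            if status == "ambiguous":
                counters["ambiguous_cid"] += 1
                rejected.append((rid1, "ambiguous_cid"))
                continue
            if not umi_passes_filter(parsed.umi, parsed.umi_qual):
                counters["low_quality_umi"] += 1
                rejected.append((rid1, "low_quality_umi"))
                continue
            accepted.append((rid1, coord[0], coord[1], parsed.umi, seq2, qual2))
    except ValueError as exc:  # zip(strict=True) length mismatch
        raise ValueError("read1/read2 files are not paired (unequal length)") from exc

    counters["total_read_pairs"] = total
    counters["accepted"] = len(accepted)
    records = pd.DataFrame(
        accepted, columns=["read_id", "x", "y", "umi", "cdna_seq", "cdna_qual"]
    )
    rejections = pd.DataFrame(rejected, columns=["read_id", "reason"])
    result = DemuxResult(records=records, rejections=rejections, counters=counters)
    if total == 0:
        warnings.warn("empty FASTQ pair: barcode mapping ratio undefined")
    return result


def hamming_scan(cid: str, entries: dict[str, tuple[int, int]]):
    """All-pairs Hamming reference matcher (oracle for :class:`CIDIndex`).

    Deliberately brute force: scans every whitelist entry and applies the
    same exact/1-mismatch/ambiguous policy.  Quadratic; testing use only.
    """
    exact = entries.get(cid)
    if exact is not None:
        return "unique", exact
    hits = []
    for entry, coord in entries.items():
        d = sum(1 for a, b in zip(cid, entry) if a != b)
        if d == 1:
            hits.append(coord)
    if len(hits) == 1:
        return "unique", hits[0]
    if len(hits) >= 2:
        return "ambiguous", None
    return "invalid", None
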