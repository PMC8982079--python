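"""Miniature Stereo-seq experiment generator with full ground truth.

The simulator emulates, at desk scale, the structures the downstream
analysis assumes: a chip of unique 25-base coordinate-identity barcodes
(CIDs) on a 500 nm-pitch lattice, a mouse-lung-like section with planted
regions (a bronchiole ring, an alveolar background, a vessel stripe and
scattered immune foci), marker-gene profiles per region, a set of genes
whose rate rises monotonically along the proximal-to-distal (y) axis,
and UMI-tagged paired reads with configurable barcode / quality / mapping
errors.  Every emitted molecule and read is recorded in a provenance
table, so each pipeline stage can be checked against exact truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import binning
from .demux import CIDIndex
from .matrix import CountMatrix, ValidationError
from .quantify import GeneReference
from .regulons import Regulon

CID_LEN = 25
UMI_LEN = 10
_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_BASE_STR = "ACGT"
#: chip codes are kept at pairwise Hamming distance >= 3 so that 1-mismatch
#: decoding is unambiguous by construction
MIN_CODE_DISTANCE = 3


# ---------------------------------------------------------------------------
# chip
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ClosePair:
    """A deliberately planted distance-2 code pair and its ambiguous probe.

    ``probe`` sits at Hamming distance 1 from both ``cid_a`` and ``cid_b``
    and at distance >= 2 from every other whitelist entry, so feeding it to
    the demultiplexer must yield an 'ambiguous' rejection.
    """

    cid_a: str
    cid_b: str
    probe: str


@dataclass
class ChipLayout:
    """The whitelist: unique 25-base CIDs bound to lattice coordinates."""

    width: int
    height: int
    entries: dict[str, tuple[int, int]]
    pitch_nm: int = 500
    spot_diameter_nm: int = 220
    close_pairs: list[ClosePair] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.width < 1 or self.height < 1:
            raise ValidationError("chip dimensions must be positive")
        if self.pitch_nm <= 0:
            raise ValidationError("pitch must be positive")
        coords = set()
        for cid, (x, y) in self.entries.items():
            if len(cid) != CID_LEN:
                raise ValidationError("all CIDs must be 25 bases")
            if not (0 <= x < self.width and 0 <= y < self.height):
                raise ValidationError(f"coordinate {(x, y)} outside chip")
            coords.add((x, y))
        if len(coords) != len(self.entries):
            raise ValidationError("duplicate coordinates in whitelist")

    def coord_to_cid(self) -> dict[tuple[int, int], str]:
        return {xy: cid for cid, xy in self.entries.items()}


def _codes_to_strings(codes: np.ndarray) -> list[str]:
    return [bytes(_BASES[row]).decode() for row in codes]


def _pairwise_min_distance_violations(codes: np.ndarray) -> set[int]:
    """Indices of codes closer than MIN_CODE_DISTANCE to an earlier code.

    Pigeonhole over three segments (9/8/8 bases): two codes at distance
    <= 2 must agree on at least one full segment, so only codes sharing a
    segment key need an explicit Hamming check.
    """
    n = codes.shape[0]
    bad: set[int] = set()
    for lo, hi in ((0, 9), (9, 17), (17, 25)):
        powers = 4 ** np.arange(hi - lo, dtype=np.int64)
        keys = codes[:, lo:hi].astype(np.int64) @ powers
        order = np.argsort(keys, kind="stable")
        sorted_keys = keys[order]
        group_starts = np.flatnonzero(
            np.r_[True, sorted_keys[1:] != sorted_keys[:-1]]
        )
        bounds = np.r_[group_starts, n]
        for s, e in zip(bounds[:-1], bounds[1:]):
            if e - s < 2:
                continue
            idx = np.sort(order[s:e])
            sub = codes[idx]
            dist = (sub[:, None, :] != sub[None, :, :]).sum(axis=2)
            ii, jj = np.where(dist < MIN_CODE_DISTANCE)
            for a, b in zip(ii, jj):
                if a < b:
                    bad.add(int(idx[b]))
    return bad


def generate_chip(
    width: int,
    height: int,
    seed: int,
    pitch_nm: int = 500,
    allow_close_codes: bool = False,
    close_pair_fraction: float = 0.0,
) -> ChipLayout:
    """Generate a whitelist of unique CIDs on a width x height lattice.

    Codes are rejection-sampled to pairwise Hamming distance >= 3.  With
    ``allow_close_codes`` a ``close_pair_fraction`` of entries is rewritten
    into planted distance-2 pairs (recorded with their ambiguous probe) to
    exercise ambiguity handling downstream.
    """
    if width < 1 or height < 1:
        raise ValidationError("chip dimensions must be positive")
    if close_pair_fraction and not allow_close_codes:
        raise ValidationError("close pairs require allow_close_codes=True")
    n = width * height
    rng = np.random.default_rng(seed)
    codes = rng.integers(0, 4, size=(n, CID_LEN), dtype=np.uint8)
    while True:
        bad = _pairwise_min_distance_violations(codes)
        if not bad:
            break
        idx = np.fromiter(bad, dtype=np.int64)
        codes[idx] = rng.integers(0, 4, size=(len(idx), CID_LEN), dtype=np.uint8)

    close_pairs: list[ClosePair] = []
    if allow_close_codes and close_pair_fraction > 0:
        n_pairs = max(1, int(round(n * close_pair_fraction / 2)))
        chosen = rng.choice(n, size=2 * n_pairs, replace=False)
        for a, b in chosen.reshape(-1, 2):
            pos = rng.choice(CID_LEN, size=2, replace=False)
            codes[b] = codes[a]
            probe = codes[a].copy()
            for j, p in enumerate(pos):
                shift = rng.integers(1, 4)
                codes[b, p] = (codes[a, p] + shift) % 4
            # probe: take one of the two substitutions only
            probe[pos[0]] = codes[b, pos[0]]
            close_pairs.append(
                ClosePair(
                    cid_a=bytes(_BASES[codes[a]]).decode(),
                    cid_b=bytes(_BASES[codes[b]]).decode(),
                    probe=bytes(_BASES[probe]).decode(),
                )
            )

    strings = _codes_to_strings(codes)
    if len(set(strings)) != n:  # vanishing probability; planted pairs keep d=2
        return generate_chip(
            width, height, seed + 1, pitch_nm, allow_close_codes, close_pair_fraction
        )
    entries = {strings[i]: (i % width, i // width) for i in range(n)}
    return ChipLayout(
        width=width,
        height=height,
        entries=entries,
        pitch_nm=pitch_nm,
        close_pairs=close_pairs,
    )


# ---------------------------------------------------------------------------
# gene panel and cell-type profiles
# ---------------------------------------------------------------------------

#: canonical mouse-lung markers planted per cell type (relative weights)
TYPE_MARKERS: dict[str, dict[str, float]] = {
    "Clara": {"Scgb1a1": 8, "Scgb3a2": 6, "Cyp2f2": 4, "Hp": 3},
    "AT2": {"Sftpc": 8, "Ager": 4, "Car4": 3},
    "SmoothMuscle": {"Acta2": 8, "Myh6": 5, "Myl7": 4},
    "Neutrophil": {"S100a8": 8, "S100a9": 7},
    "AlveolarFibroblast": {"Dcn": 6, "Cdk8": 2},
}
MITO_GENES = ("mt-Nd1", "mt-Nd2", "mt-Nd4", "mt-Co1", "mt-Cytb")
GRADIENT_GENES = ("Malat1", "Jarid2", "Lars2", "Il31ra")
DECOY_GENES = ("DecoyA", "DecoyB")
N_FILLER = 35  # brings the default panel to 60 genes


def default_gene_names() -> list[str]:
    markers = sorted({g for m in TYPE_MARKERS.values() for g in m})
    fillers = [f"Filler{i:02d}" for i in range(1, N_FILLER + 1)]
    return markers + list(MITO_GENES) + list(GRADIENT_GENES) + list(DECOY_GENES) + fillers


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return bytes(_BASES[rng.integers(0, 4, size=length)]).decode()


def make_gene_panel(
    seed: int, seq_len: int = 400, shared_block_len: int = 80
) -> GeneReference:
    """Random gene sequences with every read-length window unique per gene.

    The two decoy genes share an internal ``shared_block_len`` block so the
    simulator can emit genuinely multi-mapping reads; decoys are never
    expressed by any region.  Window uniqueness (both strands, 50-mers) is
    verified so that ordinary reads always place uniquely.
    """
    from .quantify import revcomp

    rng = np.random.default_rng(seed)
    names = default_gene_names()
    window = 50
    for _attempt in range(20):
        genes: dict[str, str] = {}
        shared = _random_seq(rng, shared_block_len)
        for name in names:
            if name == "DecoyA":
                genes[name] = _random_seq(rng, 160) + shared + _random_seq(rng, 160)
            elif name == "DecoyB":
                genes[name] = _random_seq(rng, 140) + shared + _random_seq(rng, 180)
            else:
                genes[name] = _random_seq(rng, seq_len)
        owner: dict[str, str] = {}
        clash = False
        for name, seq in genes.items():
            if name in DECOY_GENES:
                continue  # decoys intentionally share windows with each other
            for strand in (seq, revcomp(seq)):
                for i in range(len(strand) - window + 1):
                    w = strand[i : i + window]
                    if owner.setdefault(w, name) != name:
                        clash = True
                        break
                if clash:
                    break
            if clash:
                break
        if not clash:
            # decoy windows must not collide with expressed genes either
            decoy_ok = True
            for name in DECOY_GENES:
                seq = genes[name]
                for strand in (seq, revcomp(seq)):
                    for i in range(len(strand) - window + 1):
                        if owner.get(strand[i : i + window]) is not None:
                            decoy_ok = False
                            break
                    if not decoy_ok:
                        break
                if not decoy_ok:
                    break
            if decoy_ok:
                return GeneReference(genes)
    raise RuntimeError("could not build a collision-free gene panel")


def cell_type_profiles(panel: GeneReference) -> pd.DataFrame:
    """Genes x types expression-probability matrix (columns sum to 1).

    Each type expresses its markers strongly, the mitochondrial genes at a
    low shared level (for the mito-fraction QC map) and the filler genes at
    a faint background; gradient and decoy genes stay at zero so the
    deconvolution gene set excludes them.
    """
    genes = panel.ids()
    types = sorted(TYPE_MARKERS)
    prof = pd.DataFrame(0.0, index=genes, columns=types)
    for t in types:
        for g, w in TYPE_MARKERS[t].items():
            prof.loc[g, t] = w
        for g in MITO_GENES:
            prof.loc[g, t] = 0.3
        for g in genes:
            if g.startswith("Filler"):
                prof.loc[g, t] = 0.1
    return prof / prof.sum(axis=0)


# ---------------------------------------------------------------------------
# regions
# ---------------------------------------------------------------------------


@dataclass
class Region:
    name: str
    mask: np.ndarray  # (height, width) boolean
    cell_type_weights: dict[str, float]

    def __post_init__(self) -> None:
        total = sum(self.cell_type_weights.values())
        if total <= 0 or any(v < 0 for v in self.cell_type_weights.values()):
            raise ValidationError(f"region {self.name}: invalid cell-type weights")
        self.cell_type_weights = {
            k: v / total for k, v in self.cell_type_weights.items()
        }


@dataclass
class GradientSpec:
    """Monotone linear rate ramp along one lattice axis (per bin1 spot)."""

    axis: str  # 'x' or 'y'
    low: float
    high: float

    def __post_init__(self) -> None:
        if self.axis not in ("x", "y"):
            raise ValidationError("gradient axis must be 'x' or 'y'")
        if self.low < 0 or self.high < 0:
            raise ValidationError("gradient rates must be non-negative")


@dataclass
class RegionSpec:
    """Planted tissue architecture: prioritized region masks + gene rates.

    ``regions`` are in decreasing priority order; the last region's mask
    must cover the whole lattice (it is the background).  Per-spot gene
    rates are ``depth * profiles @ region_type_weights`` with gradient
    genes added on top, so bin counts are exactly a Poisson mixture of the
    cell-type signatures — the generative model the deconvolution assumes.
    """

    regions: list[Region]
    profiles: pd.DataFrame  # genes x types, columns sum to 1
    depth: float = 2.0  # expected non-gradient transcripts per bin1 spot
    gradients: dict[str, GradientSpec] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.regions:
            raise ValidationError("need at least one region")
        shape = self.regions[0].mask.shape
        covered = np.zeros(shape, dtype=bool)
        for r in self.regions:
            if r.mask.shape != shape:
                raise ValidationError("region masks disagree in shape")
            covered |= r.mask
        if not covered.all():
            raise ValidationError("region masks must cover the lattice")
        if self.depth < 0:
            raise ValidationError("depth must be non-negative")
        types = set(self.profiles.columns)
        for r in self.regions:
            if not set(r.cell_type_weights) <= types:
                raise ValidationError(f"region {r.name} references unknown cell type")

    @property
    def shape(self) -> tuple[int, int]:
        return self.regions[0].mask.shape

    def label_map(self) -> np.ndarray:
        """(height, width) array of region indices, first match wins."""
        h, w = self.shape
        lab = np.full((h, w), -1, dtype=np.int64)
        for i in reversed(range(len(self.regions))):
            lab[self.regions[i].mask] = i
        # reversed order means earlier (higher-priority) regions overwrite
        return lab

    def region_names(self) -> list[str]:
        return [r.name for r in self.regions]

    def rate_maps(self, genes: list[str]) -> dict[str, np.ndarray]:
        """Per-gene (height, width) Poisson rate per bin1 spot."""
        unknown = set(self.profiles.index) - set(genes)
        if unknown:
            raise ValidationError(f"region profile references unknown genes: {sorted(unknown)}")
        unknown_grad = set(self.gradients) - set(genes)
        if unknown_grad:
            raise ValidationError(f"gradient references unknown genes: {sorted(unknown_grad)}")
        h, w = self.shape
        lab = self.label_map()
        types = list(self.profiles.columns)
        # per-region per-gene rate vectors
        region_rates = np.zeros((len(self.regions), len(self.profiles.index)))
        for i, r in enumerate(self.regions):
            wvec = np.array([r.cell_type_weights.get(t, 0.0) for t in types])
            region_rates[i] = self.depth * (self.profiles.to_numpy() @ wvec)
        maps: dict[str, np.ndarray] = {}
        for gi, g in enumerate(self.profiles.index):
            col = region_rates[:, gi]
            if col.any():
                maps[g] = col[lab]
        yy, xx = np.mgrid[0:h, 0:w]
        for g, spec in self.gradients.items():
            coord = yy if spec.axis == "y" else xx
            extent = max(h - 1, 1) if spec.axis == "y" else max(w - 1, 1)
            ramp = spec.low + (spec.high - spec.low) * coord / extent
            maps[g] = maps.get(g, np.zeros((h, w))) + ramp
        return maps

    def cell_type_weight_map(self) -> tuple[list[str], np.ndarray]:
        """(types, (height, width, n_types)) true weights per spot."""
        types = list(self.profiles.columns)
        lab = self.label_map()
        table = np.zeros((len(self.regions), len(types)))
        for i, r in enumerate(self.regions):
            table[i] = [r.cell_type_weights.get(t, 0.0) for t in types]
        return types, table[lab]


def default_region_spec(
    panel: GeneReference, width: int = 200, height: int = 200, depth: float = 2.0
) -> RegionSpec:
    """The default synthetic lung section.

    A bronchiole ring (Clara-cell dominated), a vessel stripe (smooth
    muscle), three immune foci (neutrophils) and an alveolar background
    (AT2 + fibroblast); four distal-gradient genes rise along +y.
    """
    yy, xx = np.mgrid[0:height, 0:width]
    scale = min(width, height)
    cy, cx = 0.30 * height, 0.30 * width
    rr = np.hypot(yy - cy, xx - cx)
    bronchiole = (rr >= 0.08 * scale) & (rr < 0.15 * scale)
    vessel = (xx >= 0.72 * width) & (xx < 0.86 * width)
    immune = np.zeros((height, width), dtype=bool)
    for fy, fx in ((0.80, 0.15), (0.15, 0.55), (0.72, 0.52)):
        immune |= np.hypot(yy - fy * height, xx - fx * width) < 0.045 * scale
    background = np.ones((height, width), dtype=bool)
    profiles = cell_type_profiles(panel)
    regions = [
        Region("immune", immune, {"Neutrophil": 0.8, "AT2": 0.2}),
        Region("vessel", vessel, {"SmoothMuscle": 0.85, "AlveolarFibroblast": 0.15}),
        Region("bronchiole", bronchiole, {"Clara": 0.8, "AT2": 0.2}),
        Region("alveoli", background, {"AT2": 0.6, "AlveolarFibroblast": 0.4}),
    ]
    gradients = {g: GradientSpec("y", 0.02, 0.30) for g in GRADIENT_GENES}
    return RegionSpec(regions=regions, profiles=profiles, depth=depth, gradients=gradients)


# ---------------------------------------------------------------------------
# ground truth
# ---------------------------------------------------------------------------


@dataclass
class GroundTruth:
    """Sampled molecules plus the planted structure they came from."""

    molecules: pd.DataFrame  # molecule_id, gene, x, y, umi, cid
    bin1_counts: CountMatrix
    region_spec: RegionSpec
    layout: ChipLayout
    gene_panel: GeneReference

    def region_labels(self, bin_size: int) -> pd.DataFrame:
        """Majority planted region per bin (columns x, y, region)."""
        lab = self.region_spec.label_map()
        names = self.region_spec.region_names()
        h, w = lab.shape
        yy, xx = np.mgrid[0:h, 0:w]
        df = pd.DataFrame(
            {
                "x": (xx.ravel() // bin_size),
                "y": (yy.ravel() // bin_size),
                "region": lab.ravel(),
            }
        )
        maj = (
            df.groupby(["x", "y"])["region"]
            .agg(lambda s: s.value_counts().idxmax())
            .reset_index()
        )
        maj["region"] = [names[i] for i in maj["region"]]
        return maj

    def cell_type_weights(self, bin_size: int) -> pd.DataFrame:
        """Area-averaged true cell-type weights per bin (index x, y)."""
        types, wmap = self.region_spec.cell_type_weight_map()
        h, w, _ = wmap.shape
        yy, xx = np.mgrid[0:h, 0:w]
        df = pd.DataFrame(wmap.reshape(-1, len(types)), columns=types)
        df["x"] = xx.ravel() // bin_size
        df["y"] = yy.ravel() // bin_size
        return df.groupby(["x", "y"]).mean()

    def binned_counts(self, bin_size: int) -> CountMatrix:
        return binning.aggregate(self.bin1_counts, bin_size)


def _umi_int_to_str(vals: np.ndarray) -> list[str]:
    out = []
    for v in vals:
        chars = []
        for _ in range(UMI_LEN):
            chars.append(_BASE_STR[v & 3])
            v >>= 2
        out.append("".join(chars))
    return out


def generate_truth(
    layout: ChipLayout, region_spec: RegionSpec, gene_panel: GeneReference, seed: int
) -> GroundTruth:
    """Draw per-spot molecule counts Poisson from the planted rates.

    UMIs are uniform over 4^10 but kept distinct within each (gene, x, y)
    key, so deduplicated counts reproduce molecule counts exactly (real
    UMI collisions are a <1e-5 effect at these depths and are not
    simulated).
    """
    if region_spec.shape != (layout.height, layout.width):
        raise ValidationError("region spec shape disagrees with chip")
    rng = np.random.default_rng(seed)
    genes = gene_panel.ids()
    maps = region_spec.rate_maps(genes)
    rows = []
    for g in sorted(maps):
        counts = rng.poisson(maps[g])
        ys, xs = np.nonzero(counts)
        if len(ys):
            rows.append(
                pd.DataFrame(
                    {"gene": g, "x": xs, "y": ys, "count": counts[ys, xs]}
                )
            )
    if rows:
        triplets = pd.concat(rows, ignore_index=True)
    else:
        triplets = pd.DataFrame(columns=["gene", "x", "y", "count"])
    bin1 = CountMatrix(triplets, layout.width, layout.height, 1, layout.pitch_nm)

    # expand to molecules with per-key-distinct UMIs
    if len(triplets):
        reps = triplets.loc[triplets.index.repeat(triplets["count"])]
        mols = reps[["gene", "x", "y"]].reset_index(drop=True)
        n = len(mols)
        umi = rng.integers(0, 4**UMI_LEN, size=n)
        key = (
            mols["gene"].astype(str)
            + ":"
            + mols["x"].astype(str)
            + ":"
            + mols["y"].astype(str)
        )
        for _ in range(64):
            dup = pd.DataFrame({"k": key, "u": umi}).duplicated().to_numpy()
            ndup = int(dup.sum())
            if ndup == 0:
                break
            umi[dup] = rng.integers(0, 4**UMI_LEN, size=ndup)
        mols["umi"] = _umi_int_to_str(umi)
        mols.insert(0, "molecule_id", [f"m{i:08d}" for i in range(n)])
        c2c = layout.coord_to_cid()
        mols["cid"] = [c2c[(x, y)] for x, y in zip(mols["x"], mols["y"])]
    else:
        mols = pd.DataFrame(columns=["molecule_id", "gene", "x", "y", "umi", "cid"])
    return GroundTruth(
        molecules=mols,
        bin1_counts=bin1,
        region_spec=region_spec,
        layout=layout,
        gene_panel=gene_panel,
    )


# ---------------------------------------------------------------------------
# reads
# ---------------------------------------------------------------------------


@dataclass
class ErrorModel:
    """Per-read injection rates for every failure mode the pipeline filters.

    At most one error is injected per read (a single categorical draw), so
    demultiplexer rejection counters are comparable flag-for-flag with the
    provenance table.  Base qualities are drawn i.i.d. from
    ``quality_levels`` with ``quality_probs`` (Phred+33 on output).
    """

    cid_substitution_rate: float = 0.0  # benign at 1 sub on a distance-3 chip
    cid_n_substitutions: int = 1
    cid_invalid_rate: float = 0.0  # CID replaced by a verified off-whitelist code
    cid_ambiguous_rate: float = 0.0  # CID replaced by a planted close-pair probe
    umi_low_quality_rate: float = 0.0  # two UMI bases forced to Q2 ('#')
    umi_N_rate: float = 0.0  # one UMI base set to 'N' at Q0
    unmappable_read_rate: float = 0.0  # cDNA replaced by an alien sequence
    multimap_read_rate: float = 0.0  # cDNA drawn from the decoys' shared block
    quality_levels: tuple[int, ...] = (40, 37, 33, 28, 20)
    quality_probs: tuple[float, ...] = (0.60, 0.20, 0.10, 0.07, 0.03)

    _CATEGORIES = (
        "cid_substitution",
        "invalid_cid",
        "ambiguous_cid",
        "low_quality_umi",
        "umi_N",
        "unmappable",
        "multimap",
    )

    def __post_init__(self) -> None:
        rates = self.rates()
        if any(not 0 <= r <= 1 for r in rates):
            raise ValidationError("error rates must lie in [0, 1]")
        if sum(rates) > 1:
            raise ValidationError("error rates sum above 1")
        if abs(sum(self.quality_probs) - 1) > 1e-9:
            raise ValidationError("quality probabilities must sum to 1")

    def rates(self) -> tuple[float, ...]:
        return (
            self.cid_substitution_rate,
            self.cid_invalid_rate,
            self.cid_ambiguous_rate,
            self.umi_low_quality_rate,
            self.umi_N_rate,
            self.unmappable_read_rate,
            self.multimap_read_rate,
        )

    @classmethod
    def clean(cls) -> "ErrorModel":
        return cls()

    @classmethod
    def noisy(cls) -> "ErrorModel":
        """The default noisy channel: 1% invalid CID, 1% ambiguous CID,
        2% low-quality UMI, plus modest N / unmappable / multimap rates."""
        return cls(
            cid_invalid_rate=0.01,
            cid_ambiguous_rate=0.01,
            umi_low_quality_rate=0.02,
            umi_N_rate=0.005,
            unmappable_read_rate=0.02,
            multimap_read_rate=0.01,
        )


@dataclass
class SimulatedReads:
    """In-memory paired reads plus per-read provenance."""

    read1: list[tuple[str, str, str]]  # (id, seq, qual)
    read2: list[tuple[str, str, str]]
    provenance: pd.DataFrame

    def __len__(self) -> int:
        return len(self.read1)


def _qual_block(rng, model: ErrorModel, n: int, length: int) -> np.ndarray:
    """(n, length) uint8 array of Phred+33 ASCII codes."""
    levels = np.array(model.quality_levels, dtype=np.uint8) + 33
    picks = rng.choice(len(levels), size=(n, length), p=np.array(model.quality_probs))
    return levels[picks]


def _make_invalid_pool(rng, layout: ChipLayout, size: int = 32) -> list[str]:
    index = CIDIndex(layout.entries)
    pool = []
    while len(pool) < size:
        cand = _random_seq(rng, CID_LEN)
        if index.match(cand)[0] == "invalid":
            pool.append(cand)
    return pool


def simulate_reads(
    truth: GroundTruth,
    layout: ChipLayout,
    error_model: ErrorModel,
    seed: int,
    reads_per_molecule: int = 2,
    cdna_length: int = 50,
) -> SimulatedReads:
    """Emit UMI-tagged paired reads for every truth molecule.

    read1 = CID(25) + UMI(10); read2 = a ``cdna_length`` substring of the
    molecule's gene sequence (uniform offset).  Errors are injected per
    the model and flagged in the provenance column ``error``.
    """
    if reads_per_molecule < 1:
        raise ValidationError("reads_per_molecule must be >= 1")
    rng = np.random.default_rng(seed)
    mols = truth.molecules
    n_reads = len(mols) * reads_per_molecule
    genes = truth.gene_panel.genes

    if error_model.cid_ambiguous_rate > 0 and not layout.close_pairs:
        raise ValidationError(
            "ambiguous-CID injection needs a chip with planted close pairs "
            "(generate_chip(..., allow_close_codes=True, close_pair_fraction>0))"
        )

    rates = np.array(error_model.rates())
    cum = np.cumsum(rates)
    u = rng.random(n_reads)
    cat = np.searchsorted(cum, u, side="left")  # == len(rates) -> no error
    cat_names = list(ErrorModel._CATEGORIES) + ["none"]

    invalid_pool = (
        _make_invalid_pool(rng, layout) if error_model.cid_invalid_rate > 0 else []
    )
    probes = [p.probe for p in layout.close_pairs]
    decoy_shared = None
    if error_model.multimap_read_rate > 0:
        a, b = genes["DecoyA"], genes["DecoyB"]
        # longest run of 'a' windows present in b: use the known shared block
        for i in range(len(a) - cdna_length + 1):
            if a[i : i + cdna_length] in b:
                decoy_shared = (a, i)
                break
        if decoy_shared is None:
            raise ValidationError("decoy genes share no read-length block")

    q1 = _qual_block(rng, error_model, n_reads, CID_LEN + UMI_LEN)
    q2 = _qual_block(rng, error_model, n_reads, cdna_length)

    mol_gene = np.repeat(mols["gene"].to_numpy(), reads_per_molecule)
    mol_x = np.repeat(mols["x"].to_numpy(), reads_per_molecule)
    mol_y = np.repeat(mols["y"].to_numpy(), reads_per_molecule)
    mol_umi = np.repeat(mols["umi"].to_numpy(), reads_per_molecule)
    mol_cid = np.repeat(mols["cid"].to_numpy(), reads_per_molecule)
    mol_id = np.repeat(mols["molecule_id"].to_numpy(), reads_per_molecule)
    gene_len = {g: len(s) for g, s in genes.items()}
    offsets = np.array(
        [rng.integers(0, gene_len[g] - cdna_length + 1) for g in mol_gene]
    )

    read1, read2, prov_err = [], [], []
    for i in range(n_reads):
        rid = f"r{i:08d}"
        cid = mol_cid[i]
        umi = mol_umi[i]
        qual1 = q1[i]
        qual2 = q2[i]
        cdna = genes[mol_gene[i]][offsets[i] : offsets[i] + cdna_length]
        c = cat[i]
        name = cat_names[c] if c < len(rates) else "none"
        if name == "cid_substitution":
            pos = rng.choice(CID_LEN, size=error_model.cid_n_substitutions, replace=False)
            arr = list(cid)
            for p in pos:
                arr[p] = _BASE_STR[(_BASE_STR.index(arr[p]) + rng.integers(1, 4)) % 4]
            cid = "".join(arr)
        elif name == "invalid_cid":
            cid = invalid_pool[rng.integers(0, len(invalid_pool))]
        elif name == "ambiguous_cid":
            cid = probes[rng.integers(0, len(probes))]
        elif name == "low_quality_umi":
            pos = rng.choice(UMI_LEN, size=2, replace=False)
            qual1 = qual1.copy()
            qual1[CID_LEN + pos] = 33 + 2  # Q2 '#'
        elif name == "umi_N":
            p = int(rng.integers(0, UMI_LEN))
            umi = umi[:p] + "N" + umi[p + 1 :]
            qual1 = qual1.copy()
            qual1[CID_LEN + p] = 33  # Q0 '!'
        elif name == "unmappable":
            while True:
                cand = _random_seq(rng, cdna_length)
                if not any(cand in s for s in genes.values()):
                    cdna = cand
                    break
        elif name == "multimap":
            src, base = decoy_shared
            cdna = src[base : base + cdna_length]
        read1.append((rid, cid + umi, bytes(qual1).decode()))
        read2.append((rid, cdna, bytes(qual2).decode()))
        prov_err.append(name)

    provenance = pd.DataFrame(
        {
            "read_id": [r[0] for r in read1],
            "molecule_id": mol_id,
            "cid": mol_cid,
            "x": mol_x,
            "y": mol_y,
            "gene": mol_gene,
            "umi": mol_umi,
            "error": prov_err,
        }
    )
    return SimulatedReads(read1=read1, read2=read2, provenance=provenance)


# ---------------------------------------------------------------------------
# convenience bundles
# ---------------------------------------------------------------------------


@dataclass
class SyntheticSection:
    layout: ChipLayout
    gene_panel: GeneReference
    region_spec: RegionSpec
    truth: GroundTruth
    reads: SimulatedReads | None = None


def simulate_section(
    seed: int,
    width: int = 200,
    height: int = 200,
    depth: float = 2.0,
    error_model: ErrorModel | None = None,
    with_reads: bool = True,
    reads_per_molecule: int = 2,
) -> SyntheticSection:
    """One-call default experiment: chip + truth (+ reads).

    Seeds for the chip, truth and read channel are derived from ``seed``
    so the three stages stay independently reproducible.
    """
    error_model = error_model if error_model is not None else ErrorModel.clean()
    need_close = error_model.cid_ambiguous_rate > 0
    layout = generate_chip(
        width,
        height,
        seed=seed,
        allow_close_codes=need_close,
        close_pair_fraction=0.02 if need_close else 0.0,
    )
    panel = make_gene_panel(seed + 1)
    spec = default_region_spec(panel, width, height, depth)
    truth = generate_truth(layout, spec, panel, seed + 2)
    reads = None
    if with_reads:
        reads = simulate_reads(
            truth, layout, error_model, seed + 3, reads_per_molecule=reads_per_molecule
        )
    return SyntheticSection(layout, panel, spec, truth, reads)


def simulate_mixture_bins(
    signatures: pd.DataFrame,
    weights: np.ndarray,
    depth: float,
    seed: int,
) -> np.ndarray:
    """Draw bins x genes Poisson counts from a signature mixture.

    ``signatures`` is genes x types with columns summing to 1; ``weights``
    is bins x types on the simplex; expected depth per bin is ``depth``.
    Used by the deconvolution parameter-recovery checks.
    """
    rng = np.random.default_rng(seed)
    lam = depth * weights @ signatures.to_numpy().T
    return rng.poisson(lam).astype(np.float64)


def make_default_regulons() -> list[Regulon]:
    """Synthetic regulons wired to the planted architecture.

    Each 'TF' targets one region's marker set (so its activity map should
    light up that region); one extra regulon targets filler genes as a
    spatially flat control.  These are synthetic stand-ins for regulon
    sets inferred from real data; discovery itself is out of scope.
    """
    return [
        Regulon("BronchioTF(+)", tuple(sorted(TYPE_MARKERS["Clara"]))),
        Regulon("AlveolarTF(+)", tuple(sorted(TYPE_MARKERS["AT2"]))),
        Regulon("VesselTF(+)", tuple(sorted(TYPE_MARKERS["SmoothMuscle"]))),
        Regulon("ImmuneTF(+)", tuple(sorted(TYPE_MARKERS["Neutrophil"]))),
        Regulon("FlatTF(+)", ("Filler01", "Filler02", "Filler03", "Filler04")),
    ]
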