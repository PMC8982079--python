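"""Per-bin regulon activity via rank-based recovery-curve AUC.

A regulon is a transcription factor plus its target gene set (discovery of
the sets is out of scope; they are inputs, conventionally labeled
``Tf(+)``).  For each bin, all measured genes are ranked by expression
(descending, ties broken by a seeded random order so alphabetical bias
cannot masquerade as signal); activity is the area under the step curve of
regulon hits within the top ``top_fraction`` of the ranking, normalized by
the maximal area achievable if every regulon gene were packed at the top.
Scores therefore live in [0, 1].
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .matrix import CountMatrix, ValidationError


@dataclass(frozen=True)
class Regulon:
    tf: str
    targets: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.targets:
            raise ValidationError(f"regulon {self.tf}: empty target set")
        if len(set(self.targets)) != len(self.targets):
            raise ValidationError(f"regulon {self.tf}: duplicate targets")


def _recovery_auc(rank_of_gene: np.ndarray, hit_mask: np.ndarray, window: int) -> float:
    """Area under the recovery curve over the top ``window`` ranks.

    ``rank_of_gene[j]`` is gene j's 0-based rank; the step curve value at
    rank r (1-based) is the number of hits among the top r genes, and the
    area is its sum over r = 1..window.
    """
    hit_ranks = np.sort(rank_of_gene[hit_mask])
    m = len(hit_ranks)
    # hits at 0-based rank t contribute to positions t+1..window
    in_window = hit_ranks[hit_ranks < window]
    area = int(np.sum(window - in_window))
    max_area = int(sum(min(r, m) for r in range(1, window + 1)))
    return area / max_area if max_area else 0.0


def aucell_score(
    expression: np.ndarray,
    gene_names: list[str],
    regulon: Regulon,
    top_fraction: float = 0.05,
    tie_break: np.ndarray | None = None,
    seed: int = 0,
) -> float:
    """Recovery-curve activity of one regulon in one bin.

    ``tie_break`` (uniform per-gene jitter) fixes the order of equal
    expression values; when absent it is drawn from ``seed``.  Returns a
    score in [0, 1]; raises if no regulon gene is measured.
    """
    if not 0 < top_fraction <= 0.5:
        raise ValidationError("top_fraction must lie in (0, 0.5]")
    expr = np.asarray(expression, dtype=float)
    G = len(expr)
    if G != len(gene_names):
        raise ValidationError("expression and gene name lengths disagree")
    targets = set(regulon.targets)
    hit_mask = np.array([g in targets for g in gene_names])
    if not hit_mask.any():
        raise ValidationError(f"regulon {regulon.tf}: no target measured")
    if tie_break is None:
        tie_break = np.random.default_rng(seed).random(G)
    order = np.lexsort((tie_break, -expr))  # descending expression
    rank_of_gene = np.empty(G, dtype=np.int64)
    rank_of_gene[order] = np.arange(G)
    window = int(np.ceil(top_fraction * G))
    return float(np.clip(_recovery_auc(rank_of_gene, hit_mask, window), 0.0, 1.0))


@dataclass
class ActivityMatrix:
    """Bins x regulons activity scores plus their spatial correlations."""

    bins: pd.DataFrame
    scores: pd.DataFrame  # columns = regulon labels
    correlations: pd.DataFrame
    top_fraction: float
    seed: int

    def __post_init__(self) -> None:
        vals = self.scores.to_numpy(dtype=float)
        finite = np.isfinite(vals)
        if ((vals[finite] < 0) | (vals[finite] > 1)).any():
            raise ValidationError("activity scores outside [0, 1]")


def score_section(
    matrix_or_X,
    regulon_set: list[Regulon],
    top_fraction: float = 0.05,
    seed: int = 0,
    genes: list[str] | None = None,
    bins: pd.DataFrame | None = None,
) -> ActivityMatrix:
    """Score every (bin, regulon) pair and correlate the activity maps.

    One random tie-break order is drawn per bin from ``seed``, shared by
    all regulons in that bin, and the seed is recorded in the output.
    Regulons with no measured target are reported as NaN columns.
    """
    if not regulon_set:
        raise ValidationError("empty regulon set")
    if isinstance(matrix_or_X, CountMatrix):
        bins, genes, X = matrix_or_X.to_dense()
    else:
        X = np.asarray(matrix_or_X, dtype=float)
        if genes is None:
            raise ValidationError("gene names required with a raw array")
        if bins is None:
            bins = pd.DataFrame({"x": np.arange(len(X)), "y": 0})
    n, G = X.shape
    rng = np.random.default_rng(seed)
    tie = rng.random((n, G))
    measured = [
        any(g in set(r.targets) for g in genes) for r in regulon_set
    ]
    scores = np.full((n, len(regulon_set)), np.nan)
    for i in range(n):
        for j, r in enumerate(regulon_set):
            if not measured[j]:
                continue
            scores[i, j] = aucell_score(
                X[i], list(genes), r, top_fraction=top_fraction, tie_break=tie[i]
            )
    labels = [r.tf for r in regulon_set]
    sdf = pd.DataFrame(scores, columns=labels)
    ok = [l for l, m in zip(labels, measured) if m]
    if len(ok) >= 2:
        corr = sdf[ok].corr(method="pearson")
    else:
        corr = pd.DataFrame(index=ok, columns=ok, dtype=float)
    return ActivityMatrix(
        bins=bins.reset_index(drop=True),
        scores=sdf,
        correlations=corr,
        top_fraction=top_fraction,
        seed=seed,
    )
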