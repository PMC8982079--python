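"""Reference-based cell-type deconvolution of spatial bins.

Model: the counts ``c`` of one bin are a Poisson/multinomial draw from a
convex mixture of per-type expression probability columns,
``c_g ~ Poisson(N * sum_t w_t theta_gt)``, and the simplex weights ``w``
are the per-bin cell-type composition.  The log-likelihood is concave in
``w``, so the multiplicative EM update

    w_t <- w_t * sum_g [ c_g theta_gt / sum_u w_u theta_gu ] / sum_g c_g

converges to the global maximum.  Bins may hold several types; a greedy
backward elimination caps the per-bin type count.  Reference cell types
supported by fewer than 20 cells are removed up front.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .matrix import CountMatrix, ValidationError
from .quantify import MITO_PREFIX

logger = logging.getLogger(__name__)

MIN_CELLS_DEFAULT = 20


@dataclass
class CellTypeReference:
    """Per-type mean expression profiles plus supporting cell counts."""

    profiles: pd.DataFrame  # genes x types, mean expression (>= 0)
    cell_counts: dict[str, int]

    def __post_init__(self) -> None:
        if self.profiles.empty:
            raise ValidationError("empty cell-type reference")
        if (self.profiles.to_numpy() < 0).any():
            raise ValidationError("profiles must be non-negative")
        missing = set(self.profiles.columns) - set(self.cell_counts)
        if missing:
            raise ValidationError(f"types without cell counts: {sorted(missing)}")
        if any(v < 0 for v in self.cell_counts.values()):
            raise ValidationError("cell counts must be >= 0")

    def types(self) -> list[str]:
        return list(self.profiles.columns)


def filter_reference(
    reference: CellTypeReference, min_cells: int = MIN_CELLS_DEFAULT
) -> CellTypeReference:
    """Drop cell types supported by fewer than ``min_cells`` cells (strict)."""
    keep = [t for t in reference.types() if reference.cell_counts[t] >= min_cells]
    dropped = sorted(set(reference.types()) - set(keep))
    if dropped:
        logger.info("pre-removed cell types with < %d cells: %s", min_cells, dropped)
    if not keep:
        raise ValidationError("all cell types removed by the minimum-cell filter")
    return CellTypeReference(
        profiles=reference.profiles[keep].copy(),
        cell_counts={t: reference.cell_counts[t] for t in keep},
    )


def build_signatures(reference: CellTypeReference) -> pd.DataFrame:
    """Column-normalize mean profiles into expression probabilities.

    Emits a collinearity warning when two types have (numerically)
    proportional profiles — such pairs are not identifiable.
    """
    prof = reference.profiles
    sums = prof.sum(axis=0)
    if (sums <= 0).any():
        bad = list(sums.index[sums <= 0])
        raise ValidationError(f"all-zero expression profile for types: {bad}")
    theta = prof / sums
    T = theta.to_numpy()
    for i in range(T.shape[1]):
        for j in range(i + 1, T.shape[1]):
            if np.allclose(T[:, i], T[:, j], atol=1e-12):
                warnings.warn(
                    f"collinear signatures: {theta.columns[i]} and {theta.columns[j]}"
                )
    return theta


def estimate_weights(
    bin_counts: np.ndarray,
    theta: np.ndarray,
    max_iter: int = 500,
    tol: float = 1e-8,
    return_trace: bool = False,
):
    """Maximum-likelihood simplex weights for one bin via EM.

    Returns ``(w, loglik, converged)`` (plus the per-iteration log-
    likelihood trace when requested).  Non-convergence at ``max_iter``
    sets ``converged = False`` rather than raising.
    """
    c = np.asarray(bin_counts, dtype=float)
    T = np.asarray(theta, dtype=float)
    if c.sum() <= 0:
        raise ValidationError("bin has zero counts")
    n_types = T.shape[1]
    used = c > 0
    cu, Tu = c[used], T[used]
    w = np.full(n_types, 1.0 / n_types)
    total = cu.sum()
    trace = []
    ll_prev = -np.inf
    converged = False
    for _ in range(max_iter):
        mix = Tu @ w
        mix = np.maximum(mix, 1e-300)
        ll = float(cu @ np.log(mix))
        trace.append(ll)
        if ll - ll_prev < tol and np.isfinite(ll_prev):
            converged = True
            break
        ll_prev = ll
        w = w * (Tu.T @ (cu / mix)) / total
        w = w / w.sum()  # guard drift
    else:
        mix = np.maximum(Tu @ w, 1e-300)
        ll = float(cu @ np.log(mix))
        trace.append(ll)
    if return_trace:
        return w, ll, converged, np.array(trace)
    return w, ll, converged


@dataclass
class DeconvolutionResult:
    """Per-bin simplex weights plus the section-level summaries."""

    bins: pd.DataFrame  # x, y per fitted bin
    weights: pd.DataFrame  # bins x types (simplex rows)
    loglik: np.ndarray
    converged: np.ndarray
    selected: list[tuple[str, ...]]  # per bin, types surviving the cap
    correlations: pd.DataFrame  # type x type Pearson of weight maps
    relative_cell_number: pd.Series  # per type, % of summed weight
    skipped_bins: pd.DataFrame = field(default_factory=pd.DataFrame)

    def composition_percentages(self) -> pd.DataFrame:
        """Per-bin composition in percent (rows sum to 100)."""
        return self.weights * 100.0


def deconvolve_section(
    matrix_or_X,
    reference: CellTypeReference,
    max_types: int = 4,
    min_cells: int = MIN_CELLS_DEFAULT,
    elimination_frac: float = 0.01,
    exclude_mito: bool = True,
    max_iter: int = 500,
    tol: float = 1e-8,
    genes: list[str] | None = None,
    bins: pd.DataFrame | None = None,
) -> DeconvolutionResult:
    """Decompose every bin of a section into reference cell types.

    Genes used are the intersection of reference and section genes (minus
    ``mt-`` genes by default).  Each bin gets a full-simplex EM fit, then
    greedy backward elimination: repeatedly refit without the cheapest
    type and drop it while more than ``max_types`` remain or while the
    log-likelihood loss is below ``elimination_frac * |loglik|``; the
    final fit runs on the surviving set.  Summaries: type x type Pearson
    correlation of weight maps over bins, per-bin composition, and the
    relative cell number per type (summed weights, normalized to %).
    """
    if isinstance(matrix_or_X, CountMatrix):
        bins, genes, X = matrix_or_X.to_dense()
    else:
        X = np.asarray(matrix_or_X, dtype=float)
        if genes is None:
            raise ValidationError("gene names required with a raw array")
        if bins is None:
            bins = pd.DataFrame({"x": np.arange(len(X)), "y": 0})
    reference = filter_reference(reference, min_cells)
    theta_full = build_signatures(reference)
    shared = [g for g in genes if g in theta_full.index]
    if exclude_mito:
        shared = [g for g in shared if not g.startswith(MITO_PREFIX)]
    dropped = sorted(set(theta_full.index) - set(shared))
    if dropped:
        logger.info("reference genes absent from the section: %s", dropped[:10])
    if len(shared) < 2:
        raise ValidationError("shared gene universe is trivial")
    theta = theta_full.loc[shared]
    theta = theta / theta.sum(axis=0)  # renormalize over the used gene set
    T = theta.to_numpy()
    types = list(theta.columns)
    col_idx = [list(genes).index(g) for g in shared]
    Xs = X[:, col_idx]

    n_bins = len(Xs)
    W = np.zeros((n_bins, len(types)))
    ll_out = np.full(n_bins, np.nan)
    conv = np.zeros(n_bins, dtype=bool)
    selected: list[tuple[str, ...]] = []
    skipped = []
    for i in range(n_bins):
        c = Xs[i]
        if c.sum() <= 0:
            skipped.append(i)
            selected.append(())
            continue
        w, ll, ok = estimate_weights(c, T, max_iter=max_iter, tol=tol)
        active = list(range(len(types)))
        threshold = elimination_frac * abs(ll)
        # the cap drives elimination; the threshold only grades how cheap
        # each forced elimination was (a costly one flags a strained fit)
        worst_loss = 0.0
        while len(active) > max_types:
            best_loss, best_t = np.inf, None
            for t in active:
                trial = [u for u in active if u != t]
                _, ll_trial, _ = estimate_weights(c, T[:, trial], max_iter=max_iter, tol=tol)
                loss = ll - ll_trial
                if loss < best_loss:
                    best_loss, best_t = loss, t
            active = [u for u in active if u != best_t]
            worst_loss = max(worst_loss, best_loss)
            _, ll, _ = estimate_weights(c, T[:, active], max_iter=max_iter, tol=tol)
        if worst_loss >= threshold:
            logger.info("bin %d: capped elimination cost %.3g nats", i, worst_loss)
        w_final = np.zeros(len(types))
        w_sub, ll_final, ok = estimate_weights(c, T[:, active], max_iter=max_iter, tol=tol)
        w_final[active] = w_sub
        W[i] = w_final
        ll_out[i] = ll_final
        conv[i] = ok
        selected.append(tuple(types[t] for t in active))
        if not ok:
            warnings.warn(f"bin {i}: EM did not converge in {max_iter} iterations")

    fitted = np.setdiff1d(np.arange(n_bins), skipped)
    weights = pd.DataFrame(W, columns=types)
    wf = weights.iloc[fitted]
    if len(types) >= 2 and len(fitted) >= 2:
        corr = pd.DataFrame(np.corrcoef(wf.to_numpy().T), index=types, columns=types)
    else:
        corr = pd.DataFrame(index=types, columns=types, dtype=float)
    sums = wf.sum(axis=0)
    rel = sums / sums.sum() * 100.0 if sums.sum() > 0 else sums
    return DeconvolutionResult(
        bins=bins.reset_index(drop=True),
        weights=weights,
        loglik=ll_out,
        converged=conv,
        selected=selected,
        correlations=corr,
        relative_cell_number=rel,
        skipped_bins=bins.iloc[skipped].reset_index(drop=True),
    )
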