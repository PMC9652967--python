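"""Single-sample gene-set variation scoring (GSVA-style), from scratch.

The score for a gene set in one sample is built in three steps:

1. **Kernel-CDF transform** — each gene's expression vector across samples is
   replaced by a cumulative-distribution estimate, either a Gaussian kernel
   CDF with bandwidth ``h_i = s_i / 4`` (``s_i`` the gene's sample SD) or the
   plain empirical CDF.  This makes genes comparable regardless of their
   dynamic range.
2. **Symmetric rank statistic** — within each sample, genes are ordered by
   the transformed value (descending); the gene at 1-based position ``r`` out
   of ``p`` gets weight ``|p/2 - r|``, so both extremes of the ranking carry
   weight and the middle carries none.
3. **Weighted Kolmogorov–Smirnov walk** — walking down the ranking, set genes
   push the statistic up in proportion to ``weight**tau``, non-set genes push
   it down by ``1/(p - m)``.  The enrichment score is either the maximum
   deviation of the walk, or (default) the sum of its largest positive and
   largest negative excursions (``mx_diff``).

All tie-breaks are deterministic (ascending gene index), so scores are
bit-reproducible across platforms.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import ndtr

from .io_formats import ExpressionMatrix, GeneSet, GeneSetCollection

logger = logging.getLogger(__name__)

__all__ = [
    "GsvaParams",
    "kernel_cdf_transform",
    "rank_weights",
    "enrichment_walk",
    "gsva_scores",
]


@dataclass(frozen=True)
class GsvaParams:
    """Tunables of the scoring kernel.

    kcdf
        ``"gaussian"`` for continuous log-scale expression (the default),
        ``"ecdf"`` for a purely rank-based transform.
    tau
        Exponent on the rank weights in the walk; ``tau=1`` weights linearly,
        ``tau=0`` reduces to the classical unweighted KS statistic.
    es_mode
        ``"mx_diff"`` (default) sums the walk's largest positive and largest
        negative excursions, yielding roughly symmetric, unimodal scores;
        ``"max_deviation"`` takes the single signed extreme.
    min_set_genes_present
        A set retaining fewer matched genes than this is an error rather than
        a silently unstable score.
    """

    kcdf: str = "gaussian"
    tau: float = 1.0
    es_mode: str = "mx_diff"
    min_set_genes_present: int = 5

    def __post_init__(self) -> None:
        if self.kcdf not in ("gaussian", "ecdf"):
            raise ValueError(f"kcdf must be 'gaussian' or 'ecdf', got {self.kcdf!r}")
        if self.es_mode not in ("mx_diff", "max_deviation"):
            raise ValueError(f"unknown es_mode {self.es_mode!r}")
        if self.tau < 0:
            raise ValueError("tau must be >= 0")
        if self.min_set_genes_present < 1:
            raise ValueError("min_set_genes_present must be >= 1")


def kernel_cdf_transform(matrix: ExpressionMatrix, kcdf: str = "gaussian") -> pd.DataFrame:
    """Per-gene CDF estimate of each expression value across samples.

    Gaussian: ``z_ij = (1/n) * sum_k Phi((x_ij - x_ik) / h_i)`` with
    bandwidth ``h_i = s_i / 4``; genes with zero variance have no usable
    bandwidth and are dropped with a warning.  ECDF:
    ``z_ij = #{k : x_ik <= x_ij} / n``.  Either way ``z`` lies in (0, 1].
    """
    x = matrix.values.to_numpy(dtype=float)
    n = x.shape[1]
    if n < 2:
        raise ValueError("kernel CDF transform needs at least 2 samples")
    if kcdf == "ecdf":
        z = np.empty_like(x)
        for i in range(x.shape[0]):
            z[i] = (x[i][:, None] >= x[i][None, :]).mean(axis=1)
        return pd.DataFrame(z, index=matrix.values.index, columns=matrix.values.columns)
    if kcdf != "gaussian":
        raise ValueError(f"unknown kcdf {kcdf!r}")
    s = x.std(axis=1, ddof=1)
    keep = s > 0
    if not keep.any():
        raise ValueError("all genes have zero variance; gaussian kernel CDF undefined")
    if not keep.all():
        logger.warning(
            "dropping %d zero-variance gene(s) before gaussian kernel CDF",
            int((~keep).sum()),
        )
    x = x[keep]
    h = s[keep] / 4.0
    # chunk over genes: the pairwise (n x n) kernel matrix is built per chunk
    # to keep memory bounded on cohort-sized inputs
    z = np.empty_like(x)
    chunk = max(1, int(2e7 // max(n * n, 1)))
    for lo in range(0, x.shape[0], chunk):
        hi = min(lo + chunk, x.shape[0])
        diff = (x[lo:hi, :, None] - x[lo:hi, None, :]) / h[lo:hi, None, None]
        z[lo:hi] = ndtr(diff).mean(axis=2)
    return pd.DataFrame(
        z, index=matrix.values.index[keep], columns=matrix.values.columns
    )


def rank_weights(z_column: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Order genes by transformed value and attach symmetric rank weights.

    Returns ``(ordering, weights)`` where ``ordering[r-1]`` is the gene index
    at 1-based rank ``r`` (z descending, ties broken by ascending gene
    index), and ``weights[r-1] = |p/2 - r|``.  The weights depend only on
    ``p``, hence are identical for every sample.
    """
    z = np.asarray(z_column, dtype=float)
    p = z.shape[0]
    # stable sort on -z preserves ascending gene index among ties
    ordering = np.argsort(-z, kind="stable")
    ranks = np.arange(1, p + 1, dtype=float)
    weights = np.abs(p / 2.0 - ranks)
    return ordering, weights


def enrichment_walk(
    ordering: np.ndarray,
    weights: np.ndarray,
    set_membership: np.ndarray,
    tau: float = 1.0,
    es_mode: str = "mx_diff",
) -> float:
    """Weighted KS random walk down a ranked gene list.

    ``set_membership`` is a boolean vector over gene indices.  At position
    ``l`` the walk value is::

        nu(l) = (sum of w_r**tau over set genes at ranks <= l)
                / (sum of w_r**tau over all set genes)
              - #{non-set genes at ranks <= l} / (p - m)

    ``mx_diff`` returns ``max(nu, 0).max() + min(nu, 0).min()``;
    ``max_deviation`` returns ``nu`` at the position of maximum ``|nu|``
    (first such position on ties).  Both lie in [-1, 1].
    """
    member_in_order = np.asarray(set_membership, dtype=bool)[ordering]
    m = int(member_in_order.sum())
    p = member_in_order.shape[0]
    if m == 0 or m == p:
        raise ValueError("gene set must cover some but not all ranked genes")
    wt = np.asarray(weights, dtype=float) ** tau
    inc = np.where(member_in_order, wt, 0.0)
    denom = inc.sum()
    if denom == 0:
        raise ValueError("all set genes carry zero weight; walk undefined")
    hits = np.cumsum(inc) / denom
    misses = np.cumsum(~member_in_order) / (p - m)
    nu = hits - misses
    if es_mode == "mx_diff":
        return float(max(nu.max(), 0.0) + min(nu.min(), 0.0))
    if es_mode == "max_deviation":
        return float(nu[int(np.argmax(np.abs(nu)))])
    raise ValueError(f"unknown es_mode {es_mode!r}")


def _match_set(matrix_like: pd.DataFrame, gene_set: GeneSet) -> np.ndarray:
    from .io_formats import normalize_symbol

    lookup = {normalize_symbol(g): i for i, g in enumerate(matrix_like.index)}
    idx = [lookup[normalize_symbol(g)] for g in gene_set.genes
           if normalize_symbol(g) in lookup]
    mask = np.zeros(len(matrix_like.index), dtype=bool)
    mask[idx] = True
    return mask


def gsva_scores(
    matrix: ExpressionMatrix,
    sets: GeneSetCollection | GeneSet,
    params: GsvaParams | None = None,
) -> pd.DataFrame:
    """Score every (gene set, sample) pair; returns samples x set-names frame.

    Set genes absent from the matrix are dropped (count logged); a set left
    with fewer than ``min_set_genes_present`` matched genes is an error.  The
    gaussian kernel expects log-scale input, so a TPM-scale matrix is
    rejected under ``kcdf='gaussian'``.
    """
    params = params or GsvaParams()
    if isinstance(sets, GeneSet):
        sets = GeneSetCollection((sets,))
    if params.kcdf == "gaussian" and matrix.scale != "log2":
        raise ValueError(
            "gaussian kernel CDF expects log2-scale expression; "
            "convert with tpm_to_log2 first"
        )
    z = kernel_cdf_transform(matrix, params.kcdf)
    p = z.shape[0]

    memberships = {}
    for s in sets:
        mask = _match_set(z, s)
        n_matched = int(mask.sum())
        if n_matched < len(s.genes):
            logger.info(
                "set %s: %d of %d genes absent from matrix",
                s.name, len(s.genes) - n_matched, len(s.genes),
            )
        if n_matched < params.min_set_genes_present:
            raise ValueError(
                f"gene set {s.name!r} retains {n_matched} gene(s) after matching; "
                f"need at least {params.min_set_genes_present}"
            )
        if n_matched == p:
            raise ValueError(f"gene set {s.name!r} covers every gene in the matrix")
        memberships[s.name] = mask

    zv = z.to_numpy()
    out = np.empty((z.shape[1], len(memberships)))
    for j in range(z.shape[1]):
        ordering, weights = rank_weights(zv[:, j])
        for k, mask in enumerate(memberships.values()):
            out[j, k] = enrichment_walk(
                ordering, weights, mask, tau=params.tau, es_mode=params.es_mode
            )
    return pd.DataFrame(out, index=z.columns, columns=list(memberships))
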