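"""Signature discovery: per-gene ROC-AUC against mutation status, intersected
across cohorts.

For every gene the screen computes the area under the ROC curve that ranks
mutant versus wildtype samples by the gene's expression (midrank tie
handling, mutants as positives).  Because AUC is rank-based, each cohort is
screened on its native scale — no cross-cohort normalization — and only the
resulting gene lists are intersected: the signature is the set of genes whose
AUC strictly exceeds the threshold in *every* cohort.

By default only the over-expressed-in-mutant tail (AUC > threshold) is kept;
``require_both_directions`` additionally admits genes consistently
under-expressed in mutants (AUC < 1 - threshold in every cohort) as
sign-flipped members.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .io_formats import ExpressionMatrix, GeneSet

__all__ = ["ScreenParams", "ScreenResult", "binary_auc", "per_gene_screen", "intersect_cohorts"]


@dataclass(frozen=True)
class ScreenParams:
    auc_threshold: float = 0.650
    positive_class: int = 1
    require_both_directions: bool = False

    def __post_init__(self) -> None:
        if not (0.5 <= self.auc_threshold < 1.0):
            raise ValueError("auc_threshold must lie in [0.5, 1)")


@dataclass(frozen=True)
class ScreenResult:
    """Per-cohort AUC tables plus the intersected signature."""

    per_cohort: tuple[pd.Series, ...]  # one gene -> AUC series per cohort
    signature: GeneSet | None
    params: ScreenParams
    flipped_genes: tuple[str, ...] = field(default_factory=tuple)

    @property
    def n_cohorts(self) -> int:
        return len(self.per_cohort)


def binary_auc(values, labels) -> float:
    """ROC-AUC of ``values`` for separating ``labels`` (1 = positive class).

    Uses the rank-sum identity ``AUC = (R1 - n1(n1+1)/2) / (n1 * n0)`` with
    midranks, which equals (#concordant pairs + 0.5 * #tied pairs) / (n1*n0).
    """
    v = np.asarray(values, dtype=float)
    y = np.asarray(labels)
    if v.shape != y.shape:
        raise ValueError("values and labels must have equal length")
    if not np.isfinite(v).all():
        raise ValueError("values must be finite")
    pos = y == 1
    n1, n0 = int(pos.sum()), int((~pos).sum())
    if n1 == 0 or n0 == 0:
        raise ValueError("both classes must be present to compute an AUC")
    ranks = rankdata(v, method="average")
    u = ranks[pos].sum() - n1 * (n1 + 1) / 2.0
    return float(u / (n1 * n0))


def per_gene_screen(matrix: ExpressionMatrix, mutation) -> pd.Series:
    """AUC of every gene versus binary mutation labels (1 = mutant).

    Vectorized midrank computation over all genes at once; a zero-variance
    gene has every pair tied, so its AUC is exactly 0.5.
    """
    y = np.asarray(mutation)
    if len(y) != matrix.shape[1]:
        raise ValueError("one mutation label per sample is required")
    pos = y == 1
    n1, n0 = int(pos.sum()), int((~pos).sum())
    if n1 < 2 or n0 < 2:
        raise ValueError("need at least 2 mutant and 2 wildtype samples")
    x = matrix.values.to_numpy(dtype=float)
    ranks = rankdata(x, method="average", axis=1)
    u = ranks[:, pos].sum(axis=1) - n1 * (n1 + 1) / 2.0
    auc = u / (n1 * n0)
    auc[x.std(axis=1) == 0] = 0.5
    return pd.Series(auc, index=matrix.values.index, name="auc")


def intersect_cohorts(
    tables: list[pd.Series], params: ScreenParams | None = None
) -> ScreenResult:
    """Signature = genes with AUC strictly above threshold in every cohort.

    Genes are ordered by mean AUC descending, ties broken by symbol.  With
    ``require_both_directions``, genes below ``1 - threshold`` in every
    cohort join as sign-flipped members (recorded in ``flipped_genes``).
    """
    params = params or ScreenParams()
    if len(tables) < 2:
        raise ValueError("cohort intersection needs at least 2 AUC tables")
    common = tables[0].index
    for t in tables[1:]:
        common = common.intersection(t.index)
    if len(common) == 0:
        raise ValueError("cohort gene universes do not intersect")

    aucs = pd.DataFrame({i: t.loc[common] for i, t in enumerate(tables)})
    up = (aucs > params.auc_threshold).all(axis=1)
    chosen = aucs[up]
    flipped: tuple[str, ...] = ()
    if params.require_both_directions:
        down = (aucs < 1.0 - params.auc_threshold).all(axis=1)
        flipped = tuple(sorted(aucs.index[down]))
        chosen = pd.concat([chosen, aucs[down]])

    mean_auc = chosen.mean(axis=1)
    # mean AUC descending, symbol ascending on ties
    genes = sorted(chosen.index, key=lambda g: (-mean_auc.loc[g], g))
    signature = None
    if genes:
        signature = GeneSet(
            name="SIGNATURE",
            description=f"AUC > {params.auc_threshold} in {len(tables)} cohorts",
            genes=tuple(genes),
        )
    return ScreenResult(
        per_cohort=tuple(tables), signature=signature, params=params, flipped_genes=flipped
    )
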