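"""Composite per-sample scores: BRCAness, DNA repair, cytolytic activity
(CYT) and an immune checkpoint index (ICI).

BRCAness and DNA-repair scores are single-sample gene-set variation scores
(see :mod:`brcaness.gsva`) of, respectively, a 34-gene BRCA1-mutation-
associated signature and the 150-gene Hallmark DNA repair set.  Two GMT
fixtures ship with the package for offline use:

* ``hallmark_dna_repair.gmt`` — the 150-gene Hallmark DNA repair panel.
* ``brcaness_34_synthetic.gmt`` — a *synthetic stand-in* 34-gene BRCAness
  panel assembled from well-known BRCA1-mutation-associated DNA-repair and
  proliferation genes; it has the size and character of a discovered
  signature but is not a published gene list.  Real analyses should pass a
  signature discovered from their own cohorts.

CYT is the geometric mean of PRF1 (perforin) and GZMA (granzyme A) TPM, a
standard proxy for immune cytolytic activity.  ICI summarizes checkpoint-
molecule expression as the mean of per-gene z-scored log2 expression over a
configurable checkpoint panel; its gene list and aggregation are a documented
convention of this package, not a published formula.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd

from .gsva import GsvaParams, gsva_scores
from .io_formats import ExpressionMatrix, GeneSet, read_gmt

logger = logging.getLogger(__name__)

__all__ = [
    "CytConfig",
    "IciConfig",
    "load_brcaness_signature",
    "load_dna_repair_set",
    "brcaness_score",
    "dna_repair_score",
    "cyt_score",
    "ici_score",
]

DEFAULT_CHECKPOINT_GENES = (
    "PDCD1", "CD274", "CTLA4", "LAG3", "HAVCR2", "IDO1", "PDCD1LG2", "TIGIT",
)


@dataclass(frozen=True)
class CytConfig:
    """Cytolytic activity: geometric mean of two effector genes in TPM, with a
    small pseudo-expression offset so all-zero samples stay defined."""

    gene_a: str = "PRF1"
    gene_b: str = "GZMA"
    offset: float = 0.01

    def __post_init__(self) -> None:
        if self.offset <= 0:
            raise ValueError("offset must be > 0")


@dataclass(frozen=True)
class IciConfig:
    """Immune checkpoint index: mean of per-gene z-scored log2 expression over
    a checkpoint panel (>= 2 genes must match the matrix)."""

    checkpoint_genes: tuple[str, ...] = DEFAULT_CHECKPOINT_GENES
    min_genes_present: int = 2


def _bundled(name: str) -> GeneSet:
    ref = resources.files("brcaness.data").joinpath(name)
    with resources.as_file(ref) as path:
        return read_gmt(path).sets[0]


def load_brcaness_signature() -> GeneSet:
    """The packaged 34-gene BRCAness panel (synthetic stand-in; see module docs)."""
    return _bundled("brcaness_34_synthetic.gmt")


def load_dna_repair_set() -> GeneSet:
    """The packaged 150-gene Hallmark DNA repair set."""
    return _bundled("hallmark_dna_repair.gmt")


def brcaness_score(
    matrix: ExpressionMatrix,
    signature: GeneSet | None = None,
    params: GsvaParams | None = None,
) -> pd.Series:
    """Single-sample BRCAness score: GSVA of ``signature`` (default: the
    packaged 34-gene panel) against the full matrix.  Returns one value in
    [-1, 1] per sample."""
    signature = signature or load_brcaness_signature()
    table = gsva_scores(matrix, signature, params)
    return table.iloc[:, 0].rename("brcaness")


def dna_repair_score(
    matrix: ExpressionMatrix, params: GsvaParams | None = None
) -> pd.Series:
    """DNA-repair activity score: GSVA of the 150-gene Hallmark DNA repair set."""
    table = gsva_scores(matrix, load_dna_repair_set(), params)
    return table.iloc[:, 0].rename("dna_repair")


def cyt_score(matrix: ExpressionMatrix, config: CytConfig | None = None) -> pd.Series:
    """CYT per sample: sqrt((PRF1 + offset) * (GZMA + offset)) on TPM scale."""
    config = config or CytConfig()
    if matrix.scale != "tpm":
        raise ValueError("CYT is defined on TPM-scale expression")
    rows = {}
    for g in (config.gene_a, config.gene_b):
        hit = matrix.match_genes([g])
        if not hit:
            raise ValueError(f"gene {g!r} required for CYT is absent from the matrix")
        rows[g] = matrix.values.loc[hit[0]].to_numpy(dtype=float)
    cyt = np.sqrt(
        (rows[config.gene_a] + config.offset) * (rows[config.gene_b] + config.offset)
    )
    return pd.Series(cyt, index=matrix.values.columns, name="cyt")


def ici_score(matrix: ExpressionMatrix, config: IciConfig | None = None) -> pd.Series:
    """ICI per sample: mean over matched checkpoint genes of z-scored log2
    expression.  Zero-variance genes are dropped; fewer than two usable genes
    is an error.  The column mean is ~0 by construction."""
    config = config or IciConfig()
    if matrix.shape[1] < 2:
        raise ValueError("ICI needs at least 2 samples")
    from .io_formats import tpm_to_log2

    if matrix.scale == "tpm":
        matrix = tpm_to_log2(matrix)
    matched = matrix.match_genes(config.checkpoint_genes)
    if len(matched) < config.min_genes_present:
        raise ValueError(
            f"only {len(matched)} checkpoint gene(s) matched; "
            f"need at least {config.min_genes_present}"
        )
    sub = matrix.values.loc[matched]
    sd = sub.std(axis=1, ddof=1)
    usable = sub[sd > 0]
    if len(usable) < config.min_genes_present:
        raise ValueError(
            "fewer than 2 checkpoint genes with non-zero variance; ICI undefined"
        )
    if len(usable) < len(sub):
        logger.warning("ICI: dropped %d zero-variance checkpoint gene(s)",
                       len(sub) - len(usable))
    z = usable.sub(usable.mean(axis=1), axis=0).div(usable.std(axis=1, ddof=1), axis=0)
    return z.mean(axis=0).rename("ici")
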