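"""Readers, writers and validated containers for the pipeline's file formats.

Three kinds of input move through the pipeline: gene-by-sample expression
matrices (tab-delimited or GCT 1.2), MSigDB-style GMT gene-set files, and
per-sample clinical annotation tables (TSV, with an optional YAML mapping of
column names to semantic roles).  Each reader validates into a typed
container; scoring code downstream assumes these invariants and never
re-checks them.

Gene symbols are matched case-insensitively after whitespace stripping, with
no alias resolution.  Missing expression values are rejected rather than
imputed, because the rank-based scoring assumes complete rows.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger(__name__)

__all__ = [
    "ExpressionMatrix",
    "GeneSet",
    "GeneSetCollection",
    "ClinicalTable",
    "FormatError",
    "read_gmt",
    "write_gmt",
    "read_expression",
    "write_expression",
    "read_clinical",
    "tpm_to_log2",
    "normalize_symbol",
]

#: Semantic roles a clinical column may carry.
CLINICAL_ROLES = (
    "mutation_status",
    "subtype",
    "grade",
    "response",
    "survival_time",
    "survival_event",
)

_BINARY_ROLES = frozenset({"mutation_status", "response", "survival_event"})


class FormatError(ValueError):
    """Raised when an input file violates its declared format."""


def normalize_symbol(symbol: str) -> str:
    """Canonical form used for gene-symbol matching: strip whitespace, uppercase."""
    return symbol.strip().upper()


@dataclass(frozen=True)
class GeneSet:
    """A named, ordered list of unique gene symbols."""

    name: str
    description: str
    genes: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.name:
            raise ValueError("gene set name must be non-empty")
        if not self.genes:
            raise ValueError(f"gene set {self.name!r} is empty")
        object.__setattr__(self, "genes", tuple(self.genes))
        norm = [normalize_symbol(g) for g in self.genes]
        if len(set(norm)) != len(norm):
            raise ValueError(f"gene set {self.name!r} contains duplicate genes")

    def __len__(self) -> int:
        return len(self.genes)

    def __iter__(self) -> Iterator[str]:
        return iter(self.genes)


@dataclass(frozen=True)
class GeneSetCollection:
    """An ordered collection of gene sets with unique names."""

    sets: tuple[GeneSet, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "sets", tuple(self.sets))
        names = [s.name for s in self.sets]
        if len(set(names)) != len(names):
            dupes = sorted({n for n in names if names.count(n) > 1})
            raise ValueError(f"duplicate gene set names: {dupes}")

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self) -> Iterator[GeneSet]:
        return iter(self.sets)

    def __getitem__(self, name: str) -> GeneSet:
        for s in self.sets:
            if s.name == name:
                return s
        raise KeyError(name)

    @property
    def names(self) -> list[str]:
        return [s.name for s in self.sets]


@dataclass
class ExpressionMatrix:
    """Genes x samples numeric expression matrix with a declared scale.

    ``scale`` is ``"tpm"`` (linear, non-negative) or ``"log2"``
    (log2(TPM + 1) or comparable log-intensity).  ``cohort`` is a free-text
    label; scores are always computed within a single cohort because the
    kernel-CDF transform is cohort-relative.
    """

    values: pd.DataFrame  # index = gene symbols, columns = sample ids
    scale: str
    cohort: str = ""

    def __post_init__(self) -> None:
        if self.scale not in ("tpm", "log2"):
            raise ValueError(f"scale must be 'tpm' or 'log2', got {self.scale!r}")
        df = self.values
        if df.index.has_duplicates:
            raise ValueError("duplicate gene_ids in expression matrix")
        if df.columns.has_duplicates:
            raise ValueError("duplicate sample_ids in expression matrix")
        arr = df.to_numpy()
        if not np.issubdtype(arr.dtype, np.number):
            raise ValueError("expression values must be numeric")
        if not np.isfinite(arr).all():
            raise ValueError("expression values must all be finite")
        if self.scale == "tpm" and (arr < 0).any():
            raise ValueError("negative values are not allowed under scale='tpm'")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def match_genes(self, genes: Sequence[str]) -> list[str]:
        """Return matrix gene ids matching ``genes`` (case-insensitive),
        in the order given, silently dropping unmatched symbols."""
        lookup = {normalize_symbol(g): g for g in self.values.index}
        out = []
        for g in genes:
            hit = lookup.get(normalize_symbol(g))
            if hit is not None:
                out.append(hit)
        return out


@dataclass
class ClinicalTable:
    """Per-sample clinical annotations with role-tagged columns.

    ``roles`` maps a semantic role (e.g. ``"mutation_status"``) to a column
    name in ``data``.  Binary roles must contain only {0, 1, missing};
    survival times must be non-negative where present.  Any further numeric
    columns (precomputed HRD, intratumor heterogeneity, immune fractions...)
    ride along untyped.
    """

    data: pd.DataFrame  # index = sample ids
    roles: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.data.index.has_duplicates:
            raise ValueError("duplicate sample_ids in clinical table")
        for role, col in self.roles.items():
            if col not in self.data.columns:
                raise ValueError(f"role {role!r} maps to missing column {col!r}")
            if role in _BINARY_ROLES:
                vals = self.data[col].dropna().unique()
                if not set(np.asarray(vals, dtype=float)) <= {0.0, 1.0}:
                    raise ValueError(
                        f"binary column {col!r} (role {role}) contains values "
                        f"outside {{0,1,missing}}: {sorted(vals)[:5]}"
                    )
            if role == "survival_time":
                t = self.data[col].dropna()
                if (t < 0).any():
                    raise ValueError(f"survival_time column {col!r} has negative values")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    def column(self, role: str) -> pd.Series:
        """The series carrying ``role``; KeyError if the role is unmapped."""
        return self.data[self.roles[role]]


# ---------------------------------------------------------------------------
# GMT gene sets


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Parse an MSigDB-dialect GMT file: one set per line,
    ``name<TAB>description<TAB>gene1<TAB>gene2...``.

    Duplicate genes within a line are dropped keeping the first occurrence.
    A line with fewer than three fields, or a repeated set name, is a
    :class:`FormatError`.
    """
    sets: list[GeneSet] = []
    seen: set[str] = set()
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n").rstrip("\r")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(
                    f"{path}: line {lineno} has {len(fields)} field(s); "
                    "expected name, description and at least one gene"
                )
            name, description = fields[0].strip(), fields[1].strip()
            if name in seen:
                raise FormatError(f"{path}: duplicate gene set name {name!r} at line {lineno}")
            seen.add(name)
            genes: list[str] = []
            present: set[str] = set()
            for g in fields[2:]:
                g = g.strip()
                if not g:
                    continue
                key = normalize_symbol(g)
                if key not in present:
                    present.add(key)
                    genes.append(g)
            sets.append(GeneSet(name=name, description=description, genes=tuple(genes)))
    return GeneSetCollection(tuple(sets))


def write_gmt(collection: GeneSetCollection | Sequence[GeneSet], path: str | Path) -> None:
    """Write gene sets in the same GMT dialect :func:`read_gmt` consumes."""
    with open(path, "w") as fh:
        for s in collection:
            fh.write("\t".join([s.name, s.description or "na", *s.genes]) + "\n")


# ---------------------------------------------------------------------------
# Expression matrices


def _collapse_duplicate_genes(df: pd.DataFrame, path: str | Path) -> pd.DataFrame:
    """Keep, per duplicated symbol, the row with the highest mean expression
    (the usual microarray convention for many-probes-per-gene)."""
    if not df.index.has_duplicates:
        return df
    n_before = len(df)
    means = df.mean(axis=1).to_numpy()
    order = np.argsort(-means, kind="stable")
    deduped = df.iloc[order][~df.index[order].duplicated(keep="first")]
    # restore original first-occurrence gene order
    deduped = deduped.loc[df.index.drop_duplicates()]
    logger.warning(
        "%s: collapsed %d duplicate gene rows by max row mean", path, n_before - len(deduped)
    )
    return deduped


def read_expression(
    path: str | Path, scale: str, cohort: str = ""
) -> ExpressionMatrix:
    """Read a gene-by-sample expression matrix (TSV, or GCT 1.2 by extension).

    TSV layout: header row of sample ids, first column gene symbols, numeric
    body.  GCT 1.2: two header lines (version tag, then dimensions) followed
    by Name/Description columns and the sample block.  Non-numeric or missing
    cells are errors; duplicate gene rows collapse by highest row mean.
    """
    path = Path(path)
    if path.suffix.lower() == ".gct":
        with open(path) as fh:
            version = fh.readline().strip()
            if not version.startswith("#1.2"):
                raise FormatError(f"{path}: expected GCT 1.2 header, got {version!r}")
            fh.readline()  # dimension line; trusted but unused
            df = pd.read_csv(fh, sep="\t", index_col=0, dtype={0: str})
        df = df.drop(columns=df.columns[0])  # Description column
    else:
        df = pd.read_csv(path, sep="\t", index_col=0, dtype={0: str})
    df.index = df.index.astype(str).str.strip()

    body = df.apply(pd.to_numeric, errors="coerce")
    bad = body.isna() & df.notna()
    if bad.to_numpy().any():
        r, c = np.argwhere(bad.to_numpy())[0]
        raise FormatError(
            f"{path}: non-numeric cell at gene {df.index[r]!r}, sample {df.columns[c]!r}"
        )
    if body.isna().to_numpy().any():
        r, c = np.argwhere(body.isna().to_numpy())[0]
        raise FormatError(
            f"{path}: missing expression at gene {df.index[r]!r}, sample "
            f"{df.columns[c]!r} (missing values are not supported)"
        )
    body = _collapse_duplicate_genes(body, path)
    if scale == "tpm" and (body.to_numpy() < 0).any():
        raise FormatError(f"{path}: negative value in a matrix declared scale='tpm'")
    return ExpressionMatrix(values=body.astype(float), scale=scale, cohort=cohort)


def write_expression(matrix: ExpressionMatrix, path: str | Path) -> None:
    """Write the matrix as TSV with gene symbols in the first column."""
    matrix.values.to_csv(path, sep="\t", index_label="gene")


def tpm_to_log2(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Return a new matrix with values log2(TPM + 1); refuses a double transform."""
    if matrix.scale != "tpm":
        raise ValueError("matrix is already on log2 scale; refusing to transform twice")
    return ExpressionMatrix(
        values=np.log2(matrix.values + 1.0), scale="log2", cohort=matrix.cohort
    )


# ---------------------------------------------------------------------------
# Clinical tables


def read_clinical(
    path: str | Path,
    roles: Mapping[str, str] | str | Path | None = None,
    sample_col: str | None = None,
) -> ClinicalTable:
    """Read a clinical TSV; ``roles`` maps semantic roles to column names and
    may be given inline or as a path to a YAML file with a ``roles:`` mapping.

    The sample-id column is ``sample_col``, or the first column if omitted.
    """
    df = pd.read_csv(path, sep="\t", dtype={0: str})
    if sample_col is None:
        sample_col = df.columns[0]
    df = df.set_index(sample_col)
    df.index = df.index.astype(str)

    role_map: dict[str, str] = {}
    if isinstance(roles, (str, Path)):
        with open(roles) as fh:
            spec = yaml.safe_load(fh) or {}
        role_map = dict(spec.get("roles", spec))
    elif roles is not None:
        role_map = dict(roles)
    unknown = set(role_map) - set(CLINICAL_ROLES)
    if unknown:
        raise FormatError(f"unknown clinical roles: {sorted(unknown)}")
    return ClinicalTable(data=df, roles=role_map)
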