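"""Synthetic two-cohort expression studies with planted BRCAness structure.

The generator emulates the shape of a dual-cohort case/control expression
study: a few percent of samples carry the driver mutation, a planted subset
of signature genes is mean-shifted upward in mutants, every gene carries its
own lognormal noise (normal in log2 space), cohorts differ by a global scale
factor, and a binary treatment-response label is logistically linked to each
sample's true signal.  Ground truth (planted genes, mutation labels, true
per-sample signal, response labels) is returned alongside the data so
recovery of the signature, the score's separation of mutants, and the
response AUC can all be tested without any external download.

Per gene g and sample j the log2 expression is

    x_gj ~ Normal(mu_g + delta * sigma_g * [mutant_j] * [planted_g], sigma_g)

with mu_g drawn once per gene from Normal(base_log2_mean, base_log2_mean_sd)
and sigma_g from Uniform(noise_sd_range).  Matrices are exported on TPM scale
via 2**x - 1 (clipped at 0), exercising the tpm -> log2 path downstream.

What this does *not* emulate: platform artifacts, batch structure within a
cohort, gene-gene correlation beyond the shared mutation effect, copy-number
signal, or realistic zero inflation.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .io_formats import ClinicalTable, ExpressionMatrix

__all__ = ["SimParams", "SyntheticTruth", "generate_cohort", "generate_two_cohort_study"]


@dataclass(frozen=True)
class SimParams:
    """Study-design knobs of one synthetic cohort.

    Defaults describe the reference condition used throughout the test
    suite: 500 samples, 2000 genes of which 40 are planted signature genes,
    5% mutation prevalence, and a mutant mean shift of 2 within-gene SDs
    (per-gene AUC ~ Phi(2/sqrt(2)) ~ 0.92).  The response link gives
    wildtype samples a baseline response probability of ~25%
    (intercept = -1.1) rising with the true signal (slope = 1.0).
    """

    n_samples: int = 500
    n_genes: int = 2000
    n_signature_genes: int = 40
    mutation_prevalence: float = 0.05
    effect_size: float = 2.0  # mean shift in within-gene SD units
    base_log2_mean: float = 5.0
    base_log2_mean_sd: float = 2.0
    noise_sd_range: tuple[float, float] = (0.5, 1.5)
    cohort_scale_factor: float = 1.0  # multiplicative, on TPM scale
    response_intercept: float = -1.1
    response_slope: float = 1.0
    embed_real_symbols: bool = False
    seed: int = 0
    cohort: str = "synthetic"

    def __post_init__(self) -> None:
        if not (0.0 < self.mutation_prevalence < 0.5):
            raise ValueError("mutation_prevalence must lie in (0, 0.5)")
        if self.n_signature_genes >= self.n_genes:
            raise ValueError("n_signature_genes must be < n_genes")
        if self.effect_size < 0:
            raise ValueError("effect_size must be >= 0")
        if self.cohort_scale_factor <= 0:
            raise ValueError("cohort_scale_factor must be > 0")
        if self.n_samples < 4 or self.n_genes < 2:
            raise ValueError("cohort too small to be useful")


@dataclass(frozen=True)
class SyntheticTruth:
    """Ground truth of one generated cohort, bit-reproducible from the seed."""

    planted_genes: tuple[str, ...]
    mutation: np.ndarray  # 0/1 per sample
    true_signal: np.ndarray  # mean planted-gene z per sample
    response: np.ndarray  # 0/1 per sample
    seed: int


def _gene_ids(n: int) -> list[str]:
    width = max(4, len(str(n)))
    return [f"G{i:0{width}d}" for i in range(1, n + 1)]


def _real_symbol_pool() -> list[str]:
    """Real gene symbols to embed as background genes so downstream scores
    that key on named genes (DNA repair, CYT, ICI) run on synthetic data."""
    from .scores import DEFAULT_CHECKPOINT_GENES, load_dna_repair_set

    pool = list(load_dna_repair_set().genes)
    for g in (*DEFAULT_CHECKPOINT_GENES, "PRF1", "GZMA"):
        if g not in pool:
            pool.append(g)
    return pool


def _sample_ids(n: int, cohort: str) -> list[str]:
    width = max(4, len(str(n)))
    return [f"{cohort}_S{j:0{width}d}" for j in range(1, n + 1)]


def generate_cohort(
    params: SimParams, planted_genes: tuple[str, ...] | None = None
) -> tuple[ExpressionMatrix, ClinicalTable, SyntheticTruth]:
    """Generate one cohort; optionally reuse a fixed planted gene set.

    Returns the TPM-scale expression matrix, a clinical table carrying
    mutation and response columns, and the ground truth.
    """
    rng = np.random.default_rng(params.seed)
    genes = _gene_ids(params.n_genes)
    reserved = 0
    if params.embed_real_symbols:
        pool = _real_symbol_pool()
        reserved = len(pool)
        if params.n_genes < reserved + params.n_signature_genes + 10:
            raise ValueError(
                f"n_genes too small to embed {reserved} real symbols plus planted genes"
            )
        genes[:reserved] = pool
    samples = _sample_ids(params.n_samples, params.cohort)

    # planted genes come from the synthetic-id block, never the real-symbol block
    draw = rng.choice(
        params.n_genes - reserved, size=params.n_signature_genes, replace=False
    )
    if planted_genes is None:
        planted = tuple(sorted(genes[reserved + i] for i in draw))
    else:
        missing = set(planted_genes) - set(genes)
        if missing:
            raise ValueError(f"planted genes outside gene universe: {sorted(missing)[:5]}")
        planted = tuple(sorted(planted_genes))
    planted_mask = np.isin(np.array(genes), np.array(planted))

    mutation = (rng.random(params.n_samples) < params.mutation_prevalence).astype(int)
    mu = rng.normal(params.base_log2_mean, params.base_log2_mean_sd, size=params.n_genes)
    sigma = rng.uniform(*params.noise_sd_range, size=params.n_genes)

    noise = rng.standard_normal((params.n_genes, params.n_samples))
    shift = (
        params.effect_size
        * planted_mask[:, None].astype(float)
        * mutation[None, :].astype(float)
    )
    x_log2 = mu[:, None] + sigma[:, None] * (noise + shift)

    # true signal: mean planted-gene z-deviation from the gene baseline
    z = (x_log2[planted_mask] - mu[planted_mask, None]) / sigma[planted_mask, None]
    true_signal = z.mean(axis=0)

    logits = params.response_intercept + params.response_slope * true_signal
    response = (rng.random(params.n_samples) < 1.0 / (1.0 + np.exp(-logits))).astype(int)

    tpm = np.clip(2.0 ** x_log2 - 1.0, 0.0, None) * params.cohort_scale_factor
    matrix = ExpressionMatrix(
        values=pd.DataFrame(tpm, index=genes, columns=samples),
        scale="tpm",
        cohort=params.cohort,
    )
    clinical = ClinicalTable(
        data=pd.DataFrame(
            {"BRCA1_mutation": mutation, "pCR": response, "true_signal": true_signal},
            index=pd.Index(samples, name="sample_id"),
        ),
        roles={"mutation_status": "BRCA1_mutation", "response": "pCR"},
    )
    truth = SyntheticTruth(
        planted_genes=planted,
        mutation=mutation,
        true_signal=true_signal,
        response=response,
        seed=params.seed,
    )
    return matrix, clinical, truth


def generate_two_cohort_study(
    params_a: SimParams,
    params_b: SimParams,
    shared_planted: bool = True,
):
    """Generate two cohorts over the same gene universe.

    With ``shared_planted`` the same planted signature is injected into both
    cohorts (the dual-cohort discovery setting); otherwise each cohort plants
    its own independent set and their intersection is chance-level.
    """
    if (params_a.n_genes != params_b.n_genes
            or params_a.embed_real_symbols != params_b.embed_real_symbols):
        raise ValueError("cohorts must share the same gene universe")
    if params_a.cohort == params_b.cohort:
        params_b = replace(params_b, cohort=params_b.cohort + "_b")
    a = generate_cohort(params_a)
    if shared_planted:
        b = generate_cohort(params_b, planted_genes=a[2].planted_genes)
    else:
        b = generate_cohort(params_b)
    return a, b
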