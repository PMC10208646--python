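"""Expression level and spatial diversity (pleiotropy) per gene.

Expression is consumed as a genes x tissues TPM matrix (already
aggregated across individuals or cells upstream). Two summaries are
computed per gene: the maximum TPM across tissues, taken as the
representative expression level, and Shannon's diversity index

    H' = -sum_k p_k ln p_k,   p_k = TPM_k / sum_k TPM_k,

a proxy for how broadly the gene is expressed: H' = ln R for perfectly
uniform expression over R tissues, 0 for single-tissue expression. Genes
with H' below a threshold (default 1.0) are classed as spatially
restricted, the rest as ubiquitous; unexpressed genes (all-zero rows)
are assigned H' = 0 and therefore fall in the restricted class.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = [
    "DEFAULT_H_THRESHOLD",
    "read_expression_tsv",
    "shannon_diversity",
    "max_expression",
    "pleiotropy_class",
    "expression_features",
]

DEFAULT_H_THRESHOLD = 1.0
RESTRICTED = "restricted"
UBIQUITOUS = "ubiquitous"


def read_expression_tsv(path) -> pd.DataFrame:
    """Read a genes x tissues TPM matrix (gene ids in the first column)."""
    mat = pd.read_csv(path, sep="\t", index_col=0)
    validate_matrix(mat)
    return mat


def validate_matrix(mat: pd.DataFrame) -> None:
    if mat.columns.duplicated().any():
        raise ValueError("duplicate tissue names in expression matrix")
    if (mat.to_numpy() < 0).any():
        raise ValueError("negative TPM in expression matrix")


def shannon_diversity(tpm) -> float:
    """H' (nats) of one TPM row; 0 for an all-zero row, with 0*ln 0 = 0."""
    x = np.asarray(tpm, dtype=float)
    if x.ndim != 1 or x.size == 0:
        raise ValueError("expected a nonempty 1-D TPM row")
    if (x < 0).any():
        raise ValueError("negative TPM value")
    total = x.sum()
    if total == 0:
        return 0.0
    p = x / total
    nz = p[p > 0]
    return float(-(nz * np.log(nz)).sum())


def max_expression(tpm) -> float:
    """Maximum TPM across tissues (representative expression level)."""
    x = np.asarray(tpm, dtype=float)
    if x.size == 0:
        raise ValueError("empty TPM row")
    return float(x.max())


def pleiotropy_class(h_prime: float, threshold: float = DEFAULT_H_THRESHOLD) -> str:
    """'restricted' iff H' < threshold; the boundary H' == threshold is ubiquitous."""
    if threshold <= 0:
        raise ValueError("threshold must be > 0")
    return RESTRICTED if h_prime < threshold else UBIQUITOUS


def expression_features(mat: pd.DataFrame, threshold: float = DEFAULT_H_THRESHOLD) -> pd.DataFrame:
    """Per-gene H', max TPM and pleiotropy class for a whole matrix."""
    validate_matrix(mat)
    x = mat.to_numpy(dtype=float)
    totals = x.sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        p = np.where(totals[:, None] > 0, x / np.where(totals == 0, 1, totals)[:, None], 0.0)
        plogp = np.where(p > 0, p * np.log(p), 0.0)
    h = -plogp.sum(axis=1)
    out = pd.DataFrame(
        {
            "h_prime": h,
            "max_tpm": x.max(axis=1) if x.shape[1] else 0.0,
        },
        index=mat.index,
    )
    out["restricted_expression"] = out["h_prime"] < threshold
    return out
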