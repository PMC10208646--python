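"""Nonparametric group comparisons with FDR control.

Authored implementations of the three procedures the analysis rests on,
kept oracle-checkable:

* two-sided Mann-Whitney U with midrank ties -- exact by enumeration of
  all C(n+m, n) rank assignments when n+m <= 20 (tied data included),
  otherwise the normal approximation with tie and continuity correction;
* two-sided Fisher's exact test by the probability-at-most-observed rule
  (the R convention), with hypergeometric ties included via a relative
  tolerance of 1e-7;
* Benjamini-Hochberg step-up q-values.

``compare_fate_groups`` runs a declared set of contrasts over a per-gene
feature table: numeric features via Mann-Whitney, boolean features via
Fisher on the 2x2 of group x flag, BH applied within each declared
family, significance flagged at q < 0.05.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from math import comb
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.stats import hypergeom, norm, rankdata

__all__ = [
    "SIGNIFICANCE_LEVEL",
    "Contrast",
    "mann_whitney_u",
    "fisher_exact",
    "bh_adjust",
    "compare_fate_groups",
]

SIGNIFICANCE_LEVEL = 0.05
EXACT_MWU_MAX_N = 20
FISHER_REL_TOL = 1e-7


def mann_whitney_u(x, y) -> tuple[float, float]:
    """Two-sided Mann-Whitney U test; returns (U for x, p).

    Small samples (n_x + n_y <= 20) are tested exactly by enumerating
    every assignment of the pooled midranks to the x-sample and summing
    the probability of rank sums at least as far from the null mean as
    observed. Larger (or practitioner's choice) samples use the normal
    approximation with tie correction and continuity correction.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be nonempty")
    n1, n2 = x.size, y.size
    pooled = np.concatenate([x, y])
    ranks = rankdata(pooled)
    r1 = ranks[:n1].sum()
    u1 = r1 - n1 * (n1 + 1) / 2.0
    mu = n1 * n2 / 2.0

    if n1 + n2 <= EXACT_MWU_MAX_N:
        # Enumerate rank assignments; midranks make this valid under ties.
        obs_dev = abs(u1 - mu)
        hits = 0
        total = comb(n1 + n2, n1)
        min_offset = n1 * (n1 + 1) / 2.0
        for subset in combinations(range(n1 + n2), n1):
            u = ranks[list(subset)].sum() - min_offset
            if abs(u - mu) >= obs_dev - 1e-12:
                hits += 1
        return u1, hits / total

    # Normal approximation with tie correction and continuity correction.
    n = n1 + n2
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = (counts**3 - counts).sum() / (n * (n - 1))
    sigma2 = n1 * n2 / 12.0 * ((n + 1) - tie_term)
    if sigma2 <= 0:  # all observations identical
        return u1, 1.0
    z = max(0.0, abs(u1 - mu) - 0.5) / np.sqrt(sigma2)
    return u1, min(1.0, 2.0 * norm.sf(z))


def fisher_exact(table) -> float:
    """Two-sided Fisher's exact test on a 2x2 table of counts.

    Sums the hypergeometric probabilities of every table with the observed
    margins whose probability does not exceed that of the observed table
    (within relative tolerance 1e-7).
    """
    t = np.asarray(table)
    if t.shape != (2, 2):
        raise ValueError("expected a 2x2 table")
    if (t < 0).any() or not np.issubdtype(t.dtype, np.integer):
        raise ValueError("table entries must be nonnegative integers")
    a, b = int(t[0, 0]), int(t[0, 1])
    c, d = int(t[1, 0]), int(t[1, 1])
    n = a + b + c + d
    row1 = a + b
    col1 = a + c
    if 0 in (row1, a + c, c + d, b + d):
        raise ValueError("Fisher's exact test requires positive margins")
    dist = hypergeom(n, row1, col1)
    support = np.arange(max(0, col1 - (c + d)), min(row1, col1) + 1)
    probs = dist.pmf(support)
    probs = probs / probs.sum()  # guard float drift so the full sum is exactly 1
    p_obs = probs[support == a][0]
    return float(min(1.0, probs[probs <= p_obs * (1 + FISHER_REL_TOL)].sum()))


def bh_adjust(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, in the input order."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if (p <= 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in (0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    q_sorted = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(q_sorted[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


@dataclass
class Contrast:
    """One declared group comparison over a feature table.

    ``side_a`` / ``side_b`` are (label, boolean mask) pairs selecting the
    two gene sets; features are tested one by one and corrected within the
    family named per feature (default: one family per contrast).
    """

    name: str
    side_a: tuple[str, pd.Series]
    side_b: tuple[str, pd.Series]
    numeric_features: Sequence[str] = ()
    boolean_features: Sequence[str] = ()
    families: dict[str, str] = field(default_factory=dict)  # feature -> family name


def compare_fate_groups(
    table: pd.DataFrame,
    contrasts: Sequence[Contrast],
    alpha: float = SIGNIFICANCE_LEVEL,
    mwu=mann_whitney_u,
    fisher=fisher_exact,
) -> pd.DataFrame:
    """Run all declared contrasts; one row per (contrast, feature).

    Rows with missing feature values are dropped per feature, never
    imputed. Direction is the sign of the median (numeric) or proportion
    (boolean) difference, side A minus side B. q-values are BH-adjusted
    within each (contrast, family) and flagged significant at q < alpha.
    """
    rows = []
    for contrast in contrasts:
        label_a, mask_a = contrast.side_a
        label_b, mask_b = contrast.side_b
        if not mask_a.any() or not mask_b.any():
            raise ValueError(f"contrast {contrast.name!r} has an empty side")
        for feature in list(contrast.numeric_features) + list(contrast.boolean_features):
            is_numeric = feature in contrast.numeric_features
            col = table[feature]
            a = col[mask_a & col.notna()]
            b = col[mask_b & col.notna()]
            if a.empty or b.empty:
                continue
            if is_numeric:
                stat, p = mwu(a.to_numpy(float), b.to_numpy(float))
                direction = int(np.sign(a.median() - b.median()))
                test = "mann_whitney"
            else:
                fa, fb = a.astype(bool), b.astype(bool)
                t = np.array(
                    [[int(fa.sum()), int((~fa).sum())], [int(fb.sum()), int((~fb).sum())]]
                )
                if 0 in t.sum(axis=0) or 0 in t.sum(axis=1):
                    stat, p = np.nan, 1.0
                else:
                    stat, p = np.nan, fisher(t)
                direction = int(np.sign(fa.mean() - fb.mean()))
                test = "fisher"
            rows.append(
                {
                    "contrast": contrast.name,
                    "feature": feature,
                    "family": contrast.families.get(feature, contrast.name),
                    "test": test,
                    "statistic": stat,
                    "p": p,
                    "direction": direction,
                    "n_a": int(len(a)),
                    "n_b": int(len(b)),
                    "group_a": label_a,
                    "group_b": label_b,
                }
            )
    result = pd.DataFrame(
        rows,
        columns=[
            "contrast", "feature", "family", "test", "statistic", "p",
            "direction", "n_a", "n_b", "group_a", "group_b",
        ],
    )
    if result.empty:
        result["q"] = pd.Series(dtype=float)
        result["significant"] = pd.Series(dtype=bool)
        return result
    result["q"] = np.nan
    for (_, _), idx in result.groupby(["contrast", "family"]).groups.items():
        result.loc[idx, "q"] = bh_adjust(result.loc[idx, "p"].to_numpy())
    result["significant"] = result["q"] < alpha
    return result
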