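"""Two-group differential expression on log2 expression matrices.

Implements the classic microarray-style analysis: per-gene fold change as a
difference of group means on the log2 scale, a two-tailed Student t-test with
pooled variance, Benjamini-Hochberg FDR correction across all genes of a
contrast, and DEG calling at configurable fold-change / FDR thresholds.

The fold-change threshold is interpreted as a bound on the *linear* fold
change in either direction: a gene is called differentially expressed when
|log2FC| >= log2(fc_threshold) and q <= fdr_threshold (both inclusive by
default; ``strict`` switches to ``>`` / ``<``).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import ContractError, ValidationError

__all__ = [
    "Contrast",
    "pooled_t_test",
    "bh_fdr",
    "run_contrast",
    "DegenerateVarianceWarning",
]

RESULT_COLUMNS = ["gene_id", "log2fc", "t", "df", "p", "q", "is_deg", "direction"]


class DegenerateVarianceWarning(UserWarning):
    """Pooled variance is zero but the group means differ."""


@dataclass(frozen=True)
class Contrast:
    """A named two-group comparison, group_a vs group_b (log2FC = mean_a - mean_b)."""

    name: str
    group_a: Sequence[str]
    group_b: Sequence[str]

    def __post_init__(self) -> None:
        a, b = set(self.group_a), set(self.group_b)
        if len(a) != len(self.group_a) or len(b) != len(self.group_b):
            raise ValidationError(f"contrast {self.name!r}: duplicate sample ids within a group")
        if a & b:
            raise ValidationError(
                f"contrast {self.name!r}: groups overlap on samples {sorted(a & b)}"
            )
        if len(a) < 2 or len(b) < 2:
            raise ValidationError(f"contrast {self.name!r}: each group needs >= 2 samples")


def pooled_t_test(values_a: Sequence[float], values_b: Sequence[float]):
    """Two-tailed t-test with pooled variance.

    Returns ``(t, df, p)`` with ``t = (mean_a - mean_b) / (s_p * sqrt(1/n_a + 1/n_b))``,
    ``s_p**2`` the pooled sample variance and ``df = n_a + n_b - 2``.

    Degenerate variance is resolved deterministically: identical group means give
    ``t = 0, p = 1``; differing means with zero pooled variance give ``p = 0``
    and a :class:`DegenerateVarianceWarning`.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValidationError("pooled_t_test requires >= 2 observations per group")
    t, df, p = _vectorized_pooled_t(a[None, :], b[None, :])
    return float(t[0]), int(df), float(p[0])


def _vectorized_pooled_t(a: np.ndarray, b: np.ndarray):
    """Row-wise pooled t over 2-D arrays (genes x samples). Returns (t, df, p)."""
    na, nb = a.shape[1], b.shape[1]
    df = na + nb - 2
    diff = a.mean(axis=1) - b.mean(axis=1)
    ss = a.var(axis=1, ddof=1) * (na - 1) + b.var(axis=1, ddof=1) * (nb - 1)
    sp2 = ss / df
    se = np.sqrt(sp2 * (1.0 / na + 1.0 / nb))

    t = np.zeros_like(diff)
    p = np.ones_like(diff)
    ok = se > 0
    t[ok] = diff[ok] / se[ok]
    p[ok] = 2.0 * stats.t.sf(np.abs(t[ok]), df)
    degenerate = (~ok) & (diff != 0)
    if degenerate.any():
        warnings.warn(
            f"{int(degenerate.sum())} gene(s) with zero pooled variance but unequal "
            "means; reporting p = 0 for them",
            DegenerateVarianceWarning,
            stacklevel=3,
        )
        t[degenerate] = np.inf * np.sign(diff[degenerate])
        p[degenerate] = 0.0
    return t, df, p


def bh_fdr(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, in input order, capped at 1."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any(~np.isfinite(p)) or p.min() < 0 or p.max() > 1:
        raise ValidationError("p-values must lie in [0, 1]")
    # statsmodels implements the standard step-up adjustment
    return multipletests(p, method="fdr_bh")[1]


def run_contrast(
    matrix: pd.DataFrame,
    contrast: Contrast,
    fc_threshold: float = 2.0,
    fdr_threshold: float = 0.05,
    strict: bool = False,
) -> pd.DataFrame:
    """Differential expression for one contrast over all genes of a log2 matrix.

    Parameters
    ----------
    matrix
        Genes x samples log2 expression, indexed by unique gene id.
    contrast
        Sample groups to compare; all samples must be matrix columns.
    fc_threshold
        Linear fold-change bound; the DEG gate is |log2FC| >= log2(fc_threshold).
    fdr_threshold
        BH q-value bound for the DEG gate.
    strict
        Use strict inequalities (|log2FC| > threshold, q < threshold) instead
        of the default inclusive ones.

    Returns
    -------
    DataFrame with columns gene_id, log2fc, t, df, p, q, is_deg, direction
    (one row per gene, in matrix order).
    """
    if fc_threshold <= 0 or fdr_threshold <= 0:
        raise ValidationError("thresholds must be positive")
    if matrix.index.has_duplicates:
        dups = matrix.index[matrix.index.duplicated()].unique().tolist()
        raise ValidationError(f"duplicate gene ids in matrix: {dups[:5]}")
    missing = [s for s in list(contrast.group_a) + list(contrast.group_b) if s not in matrix.columns]
    if missing:
        raise ContractError(f"contrast {contrast.name!r}: samples absent from matrix: {missing}")

    a = matrix.loc[:, list(contrast.group_a)].to_numpy(dtype=float)
    b = matrix.loc[:, list(contrast.group_b)].to_numpy(dtype=float)
    log2fc = a.mean(axis=1) - b.mean(axis=1)
    t, df, p = _vectorized_pooled_t(a, b)
    q = bh_fdr(p)

    lfc_gate = np.log2(fc_threshold)
    if strict:
        is_deg = (np.abs(log2fc) > lfc_gate) & (q < fdr_threshold)
    else:
        is_deg = (np.abs(log2fc) >= lfc_gate) & (q <= fdr_threshold)
    direction = np.where(~is_deg, "none", np.where(log2fc > 0, "up", "down"))

    return pd.DataFrame(
        {
            "gene_id": matrix.index.to_numpy(),
            "log2fc": log2fc,
            "t": t,
            "df": df,
            "p": p,
            "q": q,
            "is_deg": is_deg,
            "direction": direction,
        }
    )
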