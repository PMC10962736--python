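"""Modifier-dependence classification for stress-responsive genes.

The experimental design has three arms per model: unstressed controls,
stressed animals carrying the signaling modifier (e.g. Dele1+), and stressed
animals with the modifier knocked out.  Two contrasts summarize it:

* stress contrast  — stress/modifier+ vs control (``lfc_stress``)
* KO contrast      — stress/modifierKO vs stress/modifier+ (``lfc_ko``)

A stress DEG is *modifier-dependent* when the KO contrast passes the same
fold-change and FDR gates and its fold change points in the opposite
direction, i.e. knockout reverts the stress response toward control.

Percent dependence quantifies how much of the stress effect reverts.  Two
definitions are provided:

log2 (default)
    ``100 * (-lfc_ko) / lfc_stress`` — the fraction of the log2 stress effect
    undone in the knockout.  Full reversion to the control mean gives exactly
    100%; overshoot gives > 100%, co-directional change gives < 0%.

linear
    percent change of the KO arm vs the stress arm divided by the percent
    change of the stress arm vs control, computed on linear fold changes and
    sign-arranged so that full reversion of either an up- or down-regulated
    gene evaluates to 100%:
    ``100 * 2**lfc_stress * (1 - 2**lfc_ko) / (2**lfc_stress - 1)``.

The log2 form is the default because it is the one for which "fully
reverted" means exactly 100% regardless of effect size; the linear form is
retained for comparability with percent-change bookkeeping on the linear
scale.  Neither is clamped.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .errors import ContractError, ValidationError

__all__ = [
    "percent_dependence",
    "classify_dependent",
    "threshold_dependent_set",
    "PCT_DEFINITIONS",
]

PCT_DEFINITIONS = ("log2", "linear")


def percent_dependence(lfc_stress, lfc_ko, definition: str = "log2"):
    """Percent of the stress-induced change reverted in the knockout arm.

    Accepts scalars or arrays.  ``lfc_stress == 0`` yields NaN (dependence is
    undefined when there is no stress effect to revert).
    """
    if definition not in PCT_DEFINITIONS:
        raise ValidationError(f"unknown percent-dependence definition {definition!r}")
    s = np.asarray(lfc_stress, dtype=float)
    k = np.asarray(lfc_ko, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        if definition == "log2":
            pct = 100.0 * (-k) / s
        else:
            pct = 100.0 * np.exp2(s) * (1.0 - np.exp2(k)) / (np.exp2(s) - 1.0)
        pct = np.where(s == 0, np.nan, pct)
    if np.ndim(lfc_stress) == 0 and np.ndim(lfc_ko) == 0:
        return float(pct)
    return pct


def classify_dependent(
    stress_results: pd.DataFrame,
    ko_results: pd.DataFrame,
    fc_threshold: float = 2.0,
    fdr_threshold: float = 0.05,
    model: str = "",
    pct_definition: str = "log2",
    include_non_degs: bool = False,
) -> pd.DataFrame:
    """Classify stress DEGs as modifier-dependent and attach percent dependence.

    Parameters
    ----------
    stress_results, ko_results
        ``run_contrast`` outputs for the stress and KO comparisons over the
        same gene universe.
    fc_threshold, fdr_threshold
        Gates re-applied to the KO contrast (the stress table's ``is_deg``
        flags are taken as-is for stress-DEG status).
    model
        Label copied into the output's ``model`` column.
    include_non_degs
        When true, emit a record for every gene rather than only stress DEGs
        (dependence is defined only for stress DEGs; extra rows carry
        ``is_stress_deg = False`` and are never called dependent).

    Returns
    -------
    DataFrame with columns model, gene_id, lfc_stress, lfc_ko, q_stress,
    q_ko, is_stress_deg, is_dependent, pct_dependence, pct_definition.
    """
    s_ids = set(stress_results["gene_id"])
    k_ids = set(ko_results["gene_id"])
    if s_ids != k_ids:
        diff = sorted(s_ids.symmetric_difference(k_ids))
        raise ContractError(f"gene universes differ between contrasts: {diff[:10]}")

    ko = ko_results.set_index("gene_id")
    st = stress_results.set_index("gene_id")
    merged = st.join(ko, lsuffix="_stress", rsuffix="_ko")

    lfc_gate = np.log2(fc_threshold)
    ko_passes = (np.abs(merged["log2fc_ko"]) >= lfc_gate) & (merged["q_ko"] <= fdr_threshold)
    opposite = np.sign(merged["log2fc_ko"]) == -np.sign(merged["log2fc_stress"])
    is_dep = merged["is_deg_stress"] & ko_passes & opposite

    pct = percent_dependence(
        merged["log2fc_stress"].to_numpy(),
        merged["log2fc_ko"].to_numpy(),
        definition=pct_definition,
    )
    out = pd.DataFrame(
        {
            "model": model,
            "gene_id": merged.index.to_numpy(),
            "lfc_stress": merged["log2fc_stress"].to_numpy(),
            "lfc_ko": merged["log2fc_ko"].to_numpy(),
            "q_stress": merged["q_stress"].to_numpy(),
            "q_ko": merged["q_ko"].to_numpy(),
            "is_stress_deg": merged["is_deg_stress"].to_numpy(),
            "is_dependent": is_dep.to_numpy(),
            "pct_dependence": pct,
            "pct_definition": pct_definition,
        }
    )
    if not include_non_degs:
        out = out[out["is_stress_deg"]].reset_index(drop=True)
    return out


def threshold_dependent_set(
    shared_degs,
    records_by_model: dict[str, pd.DataFrame],
    cutoff: float = 50.0,
) -> set[str]:
    """Shared stress DEGs with percent dependence >= ``cutoff`` in every model.

    The bound is inclusive ("at least").  Every shared DEG must have a
    dependence record in every model.
    """
    shared = set(shared_degs)
    result = shared
    for model, rec in records_by_model.items():
        pct = rec.set_index("gene_id")["pct_dependence"]
        missing = shared - set(pct.index)
        if missing:
            raise ContractError(
                f"model {model!r}: no dependence record for shared DEGs {sorted(missing)[:10]}"
            )
        passing = set(pct.index[(pct >= cutoff).to_numpy() & pct.notna().to_numpy()])
        result = result & passing
    return result
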