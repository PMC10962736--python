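"""Cross-model, cross-tissue, and cross-species gene-signature set operations.

Builds shared stress-DEG sets across disease models, the core dependent-gene
signature (dependent in every model), "additional" k-of-n dependent sets, and
overlap statistics against another tissue's dependent set or human patient
cohorts via an ortholog map.

All set outputs are returned as plain Python sets; writers emit them in
lexicographic gene order so repeated runs are byte-identical.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ContractError, ValidationError

__all__ = [
    "shared_degs",
    "k_of_n_dependent",
    "dependent_fractions",
    "tissue_overlap",
    "cross_species_overlap",
    "signature_report",
    "TissueOverlap",
    "CrossSpeciesResult",
]


def shared_degs(
    per_model_results: dict[str, pd.DataFrame],
    require_direction_consistency: bool = True,
) -> set[str]:
    """Genes called stress DEGs in every model (>= 2 models required).

    With ``require_direction_consistency`` (default) a gene must additionally
    change in the same direction in every model.
    """
    if len(per_model_results) < 2:
        raise ContractError("shared_degs needs results from at least two models")
    shared: set[str] | None = None
    directions: dict[str, set[str]] = {}
    for model, res in per_model_results.items():
        degs = res[res["is_deg"]]
        ids = set(degs["gene_id"])
        shared = ids if shared is None else shared & ids
        for gid, d in zip(degs["gene_id"], degs["direction"]):
            directions.setdefault(gid, set()).add(d)
    assert shared is not None
    if require_direction_consistency:
        shared = {g for g in shared if len(directions[g]) == 1}
    return shared


def _dependent_sets(per_model_dependence: dict[str, pd.DataFrame]) -> dict[str, set[str]]:
    return {
        m: set(rec.loc[rec["is_dependent"], "gene_id"])
        for m, rec in per_model_dependence.items()
    }


def k_of_n_dependent(per_model_dependence: dict[str, pd.DataFrame], k: int) -> set[str]:
    """Genes dependent in exactly ``k`` of the n models.

    ``k = n`` is the core signature; smaller ``k`` gives the "additional" sets
    which by construction exclude the core.
    """
    n = len(per_model_dependence)
    if not 1 <= k <= n:
        raise ValidationError(f"k must be in [1, {n}], got {k}")
    counts: dict[str, int] = {}
    for dep in _dependent_sets(per_model_dependence).values():
        for g in dep:
            counts[g] = counts.get(g, 0) + 1
    return {g for g, c in counts.items() if c == k}


def dependent_fractions(per_model_dependence: dict[str, pd.DataFrame]) -> pd.DataFrame:
    """Per model: number of stress DEGs, number dependent, and the dependent fraction."""
    rows = []
    for model, rec in per_model_dependence.items():
        n_deg = int(rec["is_stress_deg"].sum())
        n_dep = int(rec["is_dependent"].sum())
        rows.append(
            {
                "model": model,
                "n_stress_degs": n_deg,
                "n_dependent": n_dep,
                "dependent_fraction": n_dep / n_deg if n_deg else np.nan,
            }
        )
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class TissueOverlap:
    overlap: frozenset
    n_signature: int
    n_overlap: int

    @property
    def fraction(self) -> float:
        return self.n_overlap / self.n_signature

    @property
    def percent(self) -> float:
        return 100.0 * self.fraction


def tissue_overlap(signature: set, other_tissue_dependent: set) -> TissueOverlap:
    """Overlap of a signature with another tissue's dependent-gene set."""
    sig = set(signature)
    if not sig:
        raise ContractError("tissue_overlap: signature set is empty")
    ov = sig & set(other_tissue_dependent)
    return TissueOverlap(overlap=frozenset(ov), n_signature=len(sig), n_overlap=len(ov))


@dataclass(frozen=True)
class CrossSpeciesResult:
    genes: frozenset            # signature (mouse) gene ids passing the mean-FC bound
    orthologs: dict             # passing mouse id -> human symbol
    unmapped: frozenset         # signature genes absent from the ortholog map
    partial_coverage: frozenset # passing genes averaged over < all studies
    mean_fc: dict               # mouse id -> mean linear FC (all mapped genes)


def cross_species_overlap(
    signature: set,
    ortholog_map: pd.DataFrame,
    study_fc: pd.DataFrame,
    min_mean_fc: float = 2.0,
    mean: str = "arithmetic",
) -> CrossSpeciesResult:
    """Signature genes whose human ortholog is induced >= ``min_mean_fc`` on average.

    Parameters
    ----------
    ortholog_map
        Two columns, ``mouse_gene`` and ``human_gene``; must be one-to-one on
        the signature genes it covers.
    study_fc
        One row per human gene (index or ``human_gene`` column), one column of
        *linear* fold changes per study.  Genes absent from a study (NaN) are
        averaged over the studies where they appear and flagged in
        ``partial_coverage``.
    mean
        ``arithmetic`` (default) or ``geometric`` averaging of linear FCs.
    """
    if mean not in ("arithmetic", "geometric"):
        raise ValidationError(f"unknown mean {mean!r}")
    m2h = dict(zip(ortholog_map["mouse_gene"], ortholog_map["human_gene"]))
    sig_mapped = {g for g in signature if g in m2h}
    human_of = {g: m2h[g] for g in sig_mapped}
    if len(set(human_of.values())) != len(human_of):
        raise ValidationError("ortholog map is not one-to-one on the signature genes")
    unmapped = frozenset(set(signature) - sig_mapped)

    fc = study_fc.set_index("human_gene") if "human_gene" in study_fc.columns else study_fc
    study_cols = list(fc.columns)

    passing, partial, means = set(), set(), {}
    for g, h in human_of.items():
        if h not in fc.index:
            unmapped = frozenset(unmapped | {g})
            continue
        vals = fc.loc[h, study_cols].astype(float)
        avail = vals.dropna()
        if avail.empty:
            unmapped = frozenset(unmapped | {g})
            continue
        mu = float(avail.mean()) if mean == "arithmetic" else float(np.exp(np.log(avail).mean()))
        means[g] = mu
        if mu >= min_mean_fc:
            passing.add(g)
            if len(avail) < len(study_cols):
                partial.add(g)
    return CrossSpeciesResult(
        genes=frozenset(passing),
        orthologs={g: human_of[g] for g in passing},
        unmapped=unmapped,
        partial_coverage=frozenset(partial),
        mean_fc=means,
    )


def signature_report(
    per_model_results: dict[str, pd.DataFrame],
    per_model_dependence: dict[str, pd.DataFrame],
    partial_k: int | None = None,
) -> pd.DataFrame:
    """Per-gene membership table across models.

    Columns: per-model ``<model>_stress_deg`` / ``<model>_dependent`` flags,
    the model counts, and ``in_core`` / ``in_partial_k`` membership.
    """
    models = list(per_model_results)
    n = len(models)
    if partial_k is None:
        partial_k = n - 1
    deg_sets = {
        m: set(res.loc[res["is_deg"], "gene_id"]) for m, res in per_model_results.items()
    }
    dep_sets = _dependent_sets(per_model_dependence)
    universe = sorted(set().union(*deg_sets.values(), *dep_sets.values()))
    rows = []
    for g in universe:
        row: dict = {"gene_id": g}
        for m in models:
            row[f"{m}_stress_deg"] = g in deg_sets[m]
            row[f"{m}_dependent"] = g in dep_sets[m]
        row["n_models_deg"] = sum(g in deg_sets[m] for m in models)
        row["n_models_dependent"] = sum(g in dep_sets[m] for m in models)
        row["in_core"] = row["n_models_dependent"] == n
        row["in_partial_k"] = row["n_models_dependent"] == partial_k
        rows.append(row)
    return pd.DataFrame(rows)
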