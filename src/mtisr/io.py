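"""Readers, writers, run configuration, and the full-pipeline driver.

Canonical tabular dialect: tab-separated UTF-8 with a header row; lines
starting with ``#`` are comments.  Every file written by a configured run
carries the run-config hash in a ``#`` header comment so outputs can be
matched to the configuration that produced them.  Masks and intensity images
are 16-bit single-channel TIFF.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from . import __version__
from .dependence import classify_dependent, threshold_dependent_set
from .diffexpr import Contrast, run_contrast
from .errors import ContractError, ValidationError
from .morphometry import (
    LabelMask,
    fiber_quantify,
    group_percent_difference,
    region_features,
    summarize_population,
)
from .signature import (
    dependent_fractions,
    k_of_n_dependent,
    shared_degs,
    signature_report,
)
from .simulate import ARMS

log = logging.getLogger(__name__)

__all__ = [
    "RunConfig",
    "read_expression",
    "write_matrix",
    "write_table",
    "read_table",
    "read_mask",
    "write_mask",
    "arm_contrasts",
    "run_pipeline",
]


@dataclass
class RunConfig:
    """All knobs of a reproducible run; round-trips losslessly through YAML."""

    fc_threshold: float = 2.0
    fdr_threshold: float = 0.05
    dependence_cutoff: float = 50.0
    pct_definition: str = "log2"
    direction_consistency: bool = True
    seed: int = 1
    pixel_size_nm: float | None = None
    paths: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.fc_threshold <= 0 or self.fdr_threshold <= 0 or self.dependence_cutoff <= 0:
            raise ValidationError("thresholds must be positive")

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=True))

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        return cls(**yaml.safe_load(Path(path).read_text()))

    @property
    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


def _header(config: RunConfig | None) -> str:
    lines = [f"# mtisr {__version__}"]
    if config is not None:
        lines.append(f"# config_hash: {config.config_hash}")
    return "\n".join(lines) + "\n"


def write_table(df: pd.DataFrame, path, config: RunConfig | None = None, index: bool = False) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with path.open("w") as fh:
        fh.write(_header(config))
        df.to_csv(fh, sep="\t", index=index)


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")


def write_matrix(matrix: pd.DataFrame, path, config: RunConfig | None = None) -> None:
    write_table(matrix, path, config=config, index=True)


def read_expression(matrix_path, samples_path):
    """Read and cross-validate a log2 matrix (genes x samples) and sample sheet.

    The matrix TSV's first column holds gene ids; the sheet must have a
    ``sample_id`` column whose every entry is a matrix column.
    """
    matrix = pd.read_csv(matrix_path, sep="\t", comment="#", index_col=0)
    matrix.index = matrix.index.astype(str)
    if matrix.index.has_duplicates:
        dups = matrix.index[matrix.index.duplicated()].unique().tolist()
        raise ValidationError(f"duplicate gene ids in {matrix_path}: {dups[:5]}")
    if not all(np.issubdtype(dt, np.number) for dt in matrix.dtypes):
        raise ValidationError(f"{matrix_path}: non-numeric expression values")
    samples = read_table(samples_path)
    if "sample_id" not in samples.columns:
        raise ValidationError(f"{samples_path}: missing sample_id column")
    missing = [s for s in samples["sample_id"] if s not in matrix.columns]
    if missing:
        raise ContractError(f"samples absent from matrix columns: {missing}")
    return matrix, samples


def read_mask(path, pixel_size_nm: float) -> LabelMask:
    arr = tifffile.imread(path)
    return LabelMask(labels=np.asarray(arr), pixel_size_nm=pixel_size_nm)


def write_mask(labels: np.ndarray, path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    arr = np.asarray(labels)
    if arr.max(initial=0) >= 2**16:
        raise ValidationError("more than 65535 labels; cannot write 16-bit TIFF")
    tifffile.imwrite(path, arr.astype(np.uint16))


def arm_contrasts(samples: pd.DataFrame, model: str) -> tuple[Contrast, Contrast]:
    """Build the stress and KO contrasts for one model from a sample sheet.

    Stress: ``stress_plus`` vs ``control``; KO: ``stress_ko`` vs
    ``stress_plus``.  Heterozygous-modifier samples belong in the
    ``stress_plus`` arm — the pooling is encoded in the sheet's ``arm``
    column, not here.
    """
    sub = samples[samples["model"] == model]
    arms = {a: list(sub.loc[sub["arm"] == a, "sample_id"]) for a in ARMS}
    empty = [a for a in ARMS if not arms[a]]
    if empty:
        raise ContractError(f"model {model!r}: no samples in arm(s) {empty}")
    stress = Contrast(f"{model}:stress_vs_control", arms["stress_plus"], arms["control"])
    ko = Contrast(f"{model}:ko_vs_stress", arms["stress_ko"], arms["stress_plus"])
    return stress, ko


def run_pipeline(config: RunConfig, out_dir) -> dict:
    """Execute the expression pipeline (DE -> dependence -> signature).

    Reads ``config.paths['matrix']`` and ``config.paths['samples']``, runs
    both contrasts for every model in the sheet, classifies dependence,
    derives shared/core/k-of-n sets, and writes per-stage TSVs plus a JSON
    summary and a run manifest into ``out_dir``.  Identical config + inputs
    produce byte-identical outputs.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    matrix, samples = read_expression(config.paths["matrix"], config.paths["samples"])
    models = list(dict.fromkeys(samples["model"]))

    stress_results: dict[str, pd.DataFrame] = {}
    dependence: dict[str, pd.DataFrame] = {}
    for model in models:
        stress_c, ko_c = arm_contrasts(samples, model)
        sres = run_contrast(matrix, stress_c, config.fc_threshold, config.fdr_threshold)
        kres = run_contrast(matrix, ko_c, config.fc_threshold, config.fdr_threshold)
        dep = classify_dependent(
            sres, kres, config.fc_threshold, config.fdr_threshold,
            model=model, pct_definition=config.pct_definition,
        )
        stress_results[model] = sres
        dependence[model] = dep
        write_table(sres, out / f"de_{model}_stress.tsv", config)
        write_table(kres, out / f"de_{model}_ko.tsv", config)
        write_table(dep.sort_values("gene_id"), out / f"dependence_{model}.tsv", config)

    summary: dict = {"models": models, "config_hash": config.config_hash}
    if len(models) >= 2:
        shared = shared_degs(stress_results, config.direction_consistency)
        core = k_of_n_dependent(dependence, k=len(models))
        additional = k_of_n_dependent(dependence, k=len(models) - 1)
        thresholded = threshold_dependent_set(shared, dependence, config.dependence_cutoff)
        report = signature_report(stress_results, dependence)
        write_table(report, out / "signature_report.tsv", config)
        summary.update(
            n_shared_degs=len(shared),
            n_core=len(core),
            n_additional=len(additional),
            n_threshold_dependent=len(thresholded),
            core=sorted(core),
            shared_degs=sorted(shared),
            additional=sorted(additional),
            threshold_dependent=sorted(thresholded),
        )
    fractions = dependent_fractions(dependence)
    write_table(fractions, out / "dependent_fractions.tsv", config)
    summary["dependent_fractions"] = {
        r["model"]: r["dependent_fraction"] for _, r in fractions.iterrows()
    }
    (out / "summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True) + "\n")
    manifest = {
        "config": asdict(config),
        "config_hash": config.config_hash,
        "version": __version__,
        "outputs": sorted(p.name for p in out.iterdir() if p.name != "manifest.json"),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True, default=str) + "\n")
    return summary
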