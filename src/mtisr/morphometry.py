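"""Rule-based morphometry on instance-segmentation label masks.

Consumes 2-D integer label images (0 = background) with a known physical
pixel size and tabulates per-instance geometry: area, major/minor axis of
the equivalent ellipse, and aspect ratio.  Axis lengths follow the standard
region-properties convention — the full axis is ``4 * sqrt(lambda)`` where
``lambda`` is an eigenvalue of the region's second-central-moment matrix, so
for an ideal filled ellipse the recovered axes equal the true ones.  Area is
the member-pixel count times the pixel area; no sub-pixel boundary
correction is applied.

Two quantification tasks build on this:

* mitochondrial thin-section profiles, with the nano-mitochondria rule
  (minor axis < 250 nm and aspect ratio < 1.5, both strict) and population
  summaries that fold in user-supplied manual ultrastructure annotations;
* myofiber cross-sections, with per-fiber cross-sectional area (CSA, um^2)
  and mean intensity over a paired grayscale image, grouped by an optional
  aggregate-status annotation.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from skimage.measure import label as cc_label
from skimage.measure import regionprops_table

from .errors import ContractError, ValidationError

__all__ = [
    "LabelMask",
    "region_features",
    "classify_nano",
    "summarize_population",
    "fiber_quantify",
    "group_percent_difference",
    "NANO_MINOR_NM",
    "NANO_MAX_AR",
]

log = logging.getLogger(__name__)

NANO_MINOR_NM = 250.0
NANO_MAX_AR = 1.5

DEGENERATE_PIXELS = 4  # below this, moment axes are unreliable


@dataclass(frozen=True)
class LabelMask:
    """An instance-segmentation label image with physical pixel size.

    ``labels`` is a 2-D non-negative integer array; 0 is background and each
    positive id is one instance.  Ids need not be contiguous.  An id whose
    pixels form more than one 8-connected component is accepted but logged.
    """

    labels: np.ndarray
    pixel_size_nm: float

    def __post_init__(self) -> None:
        arr = np.asarray(self.labels)
        if arr.ndim != 2:
            raise ValidationError(f"label mask must be 2-D, got shape {arr.shape}")
        if not np.issubdtype(arr.dtype, np.integer):
            raise ValidationError(f"label mask must be integer-typed, got {arr.dtype}")
        if arr.min() < 0:
            raise ValidationError("label mask contains negative ids")
        if self.pixel_size_nm <= 0:
            raise ValidationError("pixel_size_nm must be positive")
        object.__setattr__(self, "labels", arr)

    @property
    def ids(self) -> np.ndarray:
        ids = np.unique(self.labels)
        return ids[ids > 0]

    def check_connectivity(self) -> list[int]:
        """Ids split into multiple 8-connected components (logged, not fatal)."""
        bad = []
        for i in self.ids:
            _, n = cc_label(self.labels == i, connectivity=2, return_num=True)
            if n > 1:
                bad.append(int(i))
        if bad:
            log.warning("labels with multiple connected components: %s", bad)
        return bad


def region_features(mask: LabelMask) -> pd.DataFrame:
    """Per-label geometry: area (um^2), equivalent-ellipse axes (nm), aspect ratio.

    Labels of fewer than 4 pixels get ``degenerate = True``; their axes are
    still reported but should not be trusted.  The ``is_nano`` column applies
    :func:`classify_nano` to every record.
    """
    props = regionprops_table(
        mask.labels,
        properties=("label", "area", "axis_major_length", "axis_minor_length"),
    )
    px = mask.pixel_size_nm
    area_um2 = props["area"] * (px / 1000.0) ** 2
    major_nm = props["axis_major_length"] * px
    minor_nm = props["axis_minor_length"] * px
    with np.errstate(divide="ignore", invalid="ignore"):
        ar = np.where(minor_nm > 0, major_nm / minor_nm, np.inf)
    out = pd.DataFrame(
        {
            "label": props["label"].astype(int),
            "area_um2": area_um2,
            "major_axis_nm": major_nm,
            "minor_axis_nm": minor_nm,
            "aspect_ratio": ar,
            "degenerate": props["area"] < DEGENERATE_PIXELS,
        }
    )
    out["is_nano"] = classify_nano(out["minor_axis_nm"].to_numpy(), out["aspect_ratio"].to_numpy())
    return out


def classify_nano(minor_axis_nm, aspect_ratio):
    """Nano-mitochondrion rule: minor axis < 250 nm AND aspect ratio < 1.5.

    Both inequalities strict; accepts scalars or arrays.
    """
    minor = np.asarray(minor_axis_nm, dtype=float)
    ar = np.asarray(aspect_ratio, dtype=float)
    result = (minor < NANO_MINOR_NM) & (ar < NANO_MAX_AR)
    if np.ndim(minor_axis_nm) == 0 and np.ndim(aspect_ratio) == 0:
        return bool(result)
    return result


def summarize_population(
    records: pd.DataFrame,
    annotations: pd.DataFrame | None = None,
) -> dict:
    """Population summary: n, median/IQR of area and aspect ratio, class frequencies.

    ``annotations`` is an optional (label, class) table of manual
    ultrastructure calls; its labels must be a subset of the record labels.
    Class percentages are over all records (rule-based nano) or all annotated
    records (manual classes).
    """
    n = len(records)
    area = records["area_um2"]
    ar = records["aspect_ratio"]
    summary = {
        "n": n,
        "median_area_um2": float(area.median()),
        "iqr_area_um2": [float(area.quantile(0.25)), float(area.quantile(0.75))],
        "median_aspect_ratio": float(ar.median()),
        "iqr_aspect_ratio": [float(ar.quantile(0.25)), float(ar.quantile(0.75))],
        "pct_nano": 100.0 * float(records["is_nano"].mean()) if n else math.nan,
        "manual_class_pct": {},
    }
    if annotations is not None and len(annotations):
        unknown = set(annotations["label"]) - set(records["label"])
        if unknown:
            raise ContractError(f"annotation labels absent from mask: {sorted(unknown)[:10]}")
        counts = annotations["class"].value_counts()
        summary["manual_class_pct"] = {
            str(c): 100.0 * int(k) / n for c, k in counts.items()
        }
    return summary


def fiber_quantify(
    mask: LabelMask,
    intensity: np.ndarray,
    ub_annotations: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Per-fiber CSA (um^2) and mean intensity, with optional aggregate status.

    ``ub_annotations`` maps fiber label -> status (``pos``/``neg``, typically
    ubiquitin-aggregate positivity); unannotated fibers keep status NA and
    are excluded from group comparisons.
    """
    intensity = np.asarray(intensity, dtype=float)
    if intensity.shape != mask.labels.shape:
        raise ContractError(
            f"intensity shape {intensity.shape} != mask shape {mask.labels.shape}"
        )
    props = regionprops_table(
        mask.labels, intensity_image=intensity, properties=("label", "area", "intensity_mean")
    )
    out = pd.DataFrame(
        {
            "label": props["label"].astype(int),
            "csa_um2": props["area"] * (mask.pixel_size_nm / 1000.0) ** 2,
            "mean_intensity": props["intensity_mean"],
            "ub_status": pd.Series(pd.NA, index=range(len(props["label"])), dtype="string"),
        }
    )
    if ub_annotations is not None and len(ub_annotations):
        status = dict(zip(ub_annotations["label"], ub_annotations["ub_status"]))
        bad = {s for s in status.values() if s not in ("pos", "neg")}
        if bad:
            raise ValidationError(f"ub_status values must be pos/neg, got {sorted(bad)}")
        out["ub_status"] = out["label"].map(status).astype("string")
    return out


def group_percent_difference(records: pd.DataFrame, field: str = "mean_intensity") -> float:
    """Percent difference of the pos-group mean over the neg-group mean.

    ``100 * (mean_pos - mean_neg) / mean_neg``; NaN when a group is empty or
    the neg-group mean is zero (degenerate grouping).
    """
    if field not in ("mean_intensity", "csa_um2"):
        raise ValidationError(f"field must be mean_intensity or csa_um2, got {field!r}")
    pos = records.loc[records["ub_status"] == "pos", field]
    neg = records.loc[records["ub_status"] == "neg", field]
    if pos.empty or neg.empty:
        log.warning("group_percent_difference: a group is empty; result undefined")
        return math.nan
    mu_pos, mu_neg = float(pos.mean()), float(neg.mean())
    if mu_neg == 0:
        log.warning("group_percent_difference: zero denominator; result undefined")
        return math.nan
    return 100.0 * (mu_pos - mu_neg) / mu_neg
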