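"""Synthetic fixtures with planted ground truth.

Every downstream stage of the package is testable without external data:
this module generates (a) log2 expression matrices with a planted three-arm
factorial structure per disease model (control; stress with the signaling
modifier intact; stress with the modifier knocked out), (b) instance label
masks rasterized from planted ellipse populations, and (c) tessellated
myofiber masks with planted per-group cross-sectional areas and intensities.
Each generator emits a truth table computed from the planted parameters, not
from the noisy realization, so recovery can be scored exactly.

The expression model for a gene with baseline ``mu``, stress effect ``beta``
(log2 fold change, modifier+ stress arm vs control) and dependence ``d`` (the
percent of ``beta`` reverted in the knockout arm) plants arm means::

    control:      mu
    stress_plus:  mu + beta
    stress_ko:    mu + beta * (1 - d/100)

with i.i.d. Gaussian noise of per-gene standard deviation on the log2 scale
(zero in noiseless mode) — the noise model under which the pooled-variance
t-test downstream is exact.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from skimage.draw import ellipse as draw_ellipse

from .errors import PlacementError, ValidationError

__all__ = [
    "GenePlan",
    "FixtureSpec",
    "ExpressionFixture",
    "generate_expression_fixture",
    "EllipseShape",
    "MaskPlan",
    "MaskFixture",
    "place_shapes",
    "generate_mask_fixture",
    "FiberFixture",
    "generate_fiber_fixture",
    "ARMS",
]

ARMS = ("control", "stress_plus", "stress_ko")


@dataclass(frozen=True)
class GenePlan:
    """Planted parameters for one gene in one model.

    ``beta`` is the stress log2 fold change (stress/modifier+ vs control);
    ``dependence_pct`` the percent of ``beta`` reverted in the knockout arm
    (may exceed 100 for overshoot); ``noise_sd`` the per-replicate Gaussian
    noise on the log2 scale.
    """

    gene_id: str
    baseline: float = 8.0
    beta: float = 0.0
    dependence_pct: float = 0.0
    noise_sd: float = 0.1

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValidationError(f"{self.gene_id}: noise_sd must be >= 0")
        if not -50.0 <= self.dependence_pct <= 150.0:
            raise ValidationError(f"{self.gene_id}: dependence_pct outside [-50, 150]")

    def arm_means(self) -> dict[str, float]:
        return {
            "control": self.baseline,
            "stress_plus": self.baseline + self.beta,
            "stress_ko": self.baseline + self.beta * (1.0 - self.dependence_pct / 100.0),
        }


@dataclass(frozen=True)
class FixtureSpec:
    """A multi-model expression fixture: per-model gene plans over one universe."""

    models: tuple[str, ...]
    genes: dict[str, list[GenePlan]]
    n_per_arm: int = 6
    seed: int = 1
    noiseless: bool = False
    tissue: str = "heart"

    def __post_init__(self) -> None:
        if self.n_per_arm < 2:
            raise ValidationError("n_per_arm must be >= 2 (sample variance undefined otherwise)")
        if set(self.models) != set(self.genes):
            raise ValidationError("genes must provide a plan list for every model")
        universe = None
        for model, plans in self.genes.items():
            ids = [p.gene_id for p in plans]
            if len(set(ids)) != len(ids):
                dups = sorted({g for g in ids if ids.count(g) > 1})
                raise ValidationError(f"model {model!r}: duplicate gene ids {dups[:5]}")
            if universe is None:
                universe = ids
            elif ids != universe:
                raise ValidationError("all models must share one gene universe in one order")


@dataclass(frozen=True)
class ExpressionFixture:
    matrix: pd.DataFrame       # genes x samples, log2
    samples: pd.DataFrame      # sample sheet
    truth: pd.DataFrame        # planted per-model, per-gene truth


def generate_expression_fixture(
    spec: FixtureSpec,
    fc_threshold: float = 2.0,
    fdr_threshold: float = 0.05,
) -> ExpressionFixture:
    """Realize a :class:`FixtureSpec` into matrix, sample sheet, and truth table.

    The truth table's ``expected_deg`` / ``expected_dependent`` flags are
    evaluated on the planted arm means against the configured thresholds
    (``expected_dependent`` additionally requires reversion, i.e. a positive
    planted dependence), independent of the noise realization.
    """
    rng = np.random.default_rng(spec.seed)
    lfc_gate = math.log2(fc_threshold)

    columns: list[str] = []
    sheet_rows: list[dict] = []
    blocks: list[np.ndarray] = []
    truth_rows: list[dict] = []
    gene_ids = [p.gene_id for p in spec.genes[spec.models[0]]]

    for model in spec.models:
        plans = spec.genes[model]
        means = np.empty((len(plans), 3 * spec.n_per_arm))
        sds = np.empty((len(plans), 1))
        for gi, plan in enumerate(plans):
            am = plan.arm_means()
            means[gi] = np.repeat([am[a] for a in ARMS], spec.n_per_arm)
            sds[gi] = plan.noise_sd
            lfc_ko = -plan.beta * plan.dependence_pct / 100.0
            exp_deg = abs(plan.beta) >= lfc_gate and plan.beta != 0
            exp_dep = (
                exp_deg
                and abs(lfc_ko) >= lfc_gate
                and plan.dependence_pct > 0
            )
            truth_rows.append(
                {
                    "model": model,
                    "gene_id": plan.gene_id,
                    "beta": plan.beta,
                    "dependence_pct": plan.dependence_pct,
                    "expected_deg": exp_deg,
                    "expected_dependent": exp_dep,
                }
            )
        noise = np.zeros_like(means) if spec.noiseless else rng.normal(0.0, 1.0, means.shape) * sds
        blocks.append(means + noise)
        for arm in ARMS:
            for rep in range(1, spec.n_per_arm + 1):
                sid = f"{model}_{arm}_r{rep}"
                columns.append(sid)
                sheet_rows.append(
                    {
                        "sample_id": sid,
                        "model": model,
                        "tissue": spec.tissue,
                        "stress": arm != "control",
                        "genotype": "ko" if arm == "stress_ko" else "plus",
                        "arm": arm,
                        "replicate": rep,
                    }
                )

    matrix = pd.DataFrame(np.hstack(blocks), index=pd.Index(gene_ids, name="gene_id"), columns=columns)
    samples = pd.DataFrame(sheet_rows)
    truth = pd.DataFrame(truth_rows)
    return ExpressionFixture(matrix=matrix, samples=samples, truth=truth)


# ---------------------------------------------------------------------------
# label-mask fixtures


@dataclass(frozen=True)
class EllipseShape:
    """A placed ellipse in pixel units (semi-axes; rotation in radians)."""

    semi_major_px: float
    semi_minor_px: float
    rotation: float
    center: tuple[float, float]  # (row, col)

    def __post_init__(self) -> None:
        if not self.semi_major_px >= self.semi_minor_px > 0:
            raise ValidationError("need semi_major >= semi_minor > 0")


@dataclass(frozen=True)
class MaskPlan:
    shapes: tuple[EllipseShape, ...]
    pixel_size_nm: float
    image_shape: tuple[int, int]
    seed: int = 0

    def __post_init__(self) -> None:
        if self.pixel_size_nm <= 0:
            raise ValidationError("pixel_size_nm must be positive")
        rows, cols = self.image_shape
        for s in self.shapes:
            r, c = s.center
            m = s.semi_major_px + 1
            if not (m <= r <= rows - 1 - m and m <= c <= cols - 1 - m):
                raise ValidationError(f"shape at {s.center} not fully inside {self.image_shape}")


@dataclass(frozen=True)
class MaskFixture:
    labels: np.ndarray
    pixel_size_nm: float
    truth: pd.DataFrame  # per-label planted geometry and nano status


def place_shapes(
    axes: Sequence[tuple[float, float]],
    image_shape: tuple[int, int],
    pixel_size_nm: float,
    seed: int,
    max_retries: int = 1000,
) -> MaskPlan:
    """Place ellipses with random centers and rotations, without overlap.

    Rejection sampling on bounding circles (separation > r_i + r_j + 1 px)
    guarantees the rasterized labels cannot touch.  Shapes are placed largest
    first in a deterministic order under the seed; exhausting the retry
    budget raises :class:`PlacementError`.
    """
    rng = np.random.default_rng(seed)
    order = sorted(range(len(axes)), key=lambda i: (-axes[i][0], i))
    rows, cols = image_shape
    placed: list[tuple[int, float, float, float, float]] = []  # (orig idx, r, c, rot, radius)
    for i in order:
        a, b = axes[i]
        if not a >= b > 0:
            raise ValidationError(f"shape {i}: need semi_major >= semi_minor > 0")
        margin = a + 2
        if rows - 2 * margin <= 0 or cols - 2 * margin <= 0:
            raise PlacementError(f"shape {i} does not fit inside image {image_shape}")
        for _ in range(max_retries):
            r = rng.uniform(margin, rows - 1 - margin)
            c = rng.uniform(margin, cols - 1 - margin)
            rot = rng.uniform(0.0, math.pi)
            if all(math.hypot(r - pr, c - pc) > a + prad + 1 for _, pr, pc, _, prad in placed):
                placed.append((i, r, c, rot, a))
                break
        else:
            raise PlacementError(
                f"could not place shape {i} (semi-axes {a}, {b}) after {max_retries} retries"
            )
    placed.sort(key=lambda t: t[0])  # restore caller order for labeling
    shapes = tuple(
        EllipseShape(axes[i][0], axes[i][1], rot, (r, c)) for i, r, c, rot, _ in placed
    )
    return MaskPlan(shapes=shapes, pixel_size_nm=pixel_size_nm, image_shape=image_shape, seed=seed)


def generate_mask_fixture(plan: MaskPlan) -> MaskFixture:
    """Rasterize a mask plan into a 16-bit label image plus planted truth.

    Truth records each label's planted axes (nm), planted area (um^2, from
    the continuous ellipse), and nano status under the population rule
    evaluated on the planted geometry.
    """
    from .morphometry import classify_nano  # avoid import cycle at module load

    labels = np.zeros(plan.image_shape, dtype=np.uint16)
    rows = []
    px = plan.pixel_size_nm
    for k, s in enumerate(plan.shapes, start=1):
        rr, cc = draw_ellipse(
            s.center[0], s.center[1], s.semi_major_px, s.semi_minor_px,
            shape=plan.image_shape, rotation=s.rotation,
        )
        if np.any(labels[rr, cc] != 0):
            raise PlacementError(f"rasterized shape {k} collides with an earlier shape")
        labels[rr, cc] = k
        minor_nm = 2.0 * s.semi_minor_px * px
        major_nm = 2.0 * s.semi_major_px * px
        ar = s.semi_major_px / s.semi_minor_px
        rows.append(
            {
                "label": k,
                "major_axis_nm": major_nm,
                "minor_axis_nm": minor_nm,
                "aspect_ratio": ar,
                "area_um2": math.pi * s.semi_major_px * s.semi_minor_px * (px / 1000.0) ** 2,
                "is_nano": classify_nano(minor_nm, ar),
            }
        )
    return MaskFixture(labels=labels, pixel_size_nm=px, truth=pd.DataFrame(rows))


# ---------------------------------------------------------------------------
# myofiber fixtures


@dataclass(frozen=True)
class FiberFixture:
    labels: np.ndarray
    intensity: np.ndarray
    pixel_size_nm: float
    truth: pd.DataFrame  # per-label group, CSA, planted intensity


def generate_fiber_fixture(
    n_fibers: dict[str, int],
    csa_means_by_group: dict[str, float],
    intensity_means_by_group: dict[str, float],
    seed: int = 1,
    pixel_size_nm: float = 500.0,
    noiseless: bool = True,
    csa_spread: float = 0.15,
) -> FiberFixture:
    """Tessellated fiber labels with planted per-group mean CSA and intensity.

    Fibers are contiguous pixel runs tiling the image; per-fiber pixel counts
    are spread around the group target but constrained to sum to
    ``round(n * mean_csa / pixel_area)``, so in noiseless mode each group's
    mean CSA equals its planted value exactly whenever that value is
    representable as (integer pixels) x (pixel area) / n.  Intensity is
    uniform within a fiber; noiseless mode plants the group mean exactly,
    otherwise per-fiber means are jittered by 10%.
    """
    groups = list(n_fibers)
    if set(groups) - {"ub_pos", "ub_neg"}:
        raise ValidationError("groups must be among 'ub_pos', 'ub_neg'")
    for g in groups:
        if csa_means_by_group[g] <= 0 or intensity_means_by_group[g] <= 0:
            raise ValidationError(f"group {g!r}: planted means must be positive")
        if n_fibers[g] < 1:
            raise ValidationError(f"group {g!r}: need at least one fiber")

    rng = np.random.default_rng(seed)
    pa = (pixel_size_nm / 1000.0) ** 2  # um^2 per pixel
    fibers: list[tuple[str, int]] = []  # (group, pixel count)
    for g in groups:
        n = n_fibers[g]
        total = round(n * csa_means_by_group[g] / pa)
        # symmetric linear spread, then fix the rounding residual on the middle fiber
        offsets = np.linspace(-csa_spread, csa_spread, n) if n > 1 else np.zeros(1)
        counts = np.round(total / n * (1 + offsets)).astype(int)
        counts[n // 2] += total - counts.sum()
        if np.any(counts < 1):
            raise ValidationError(f"group {g!r}: planted CSA too small for the pixel size")
        fibers.extend((g, int(c)) for c in counts)
    order = rng.permutation(len(fibers))
    fibers = [fibers[i] for i in order]

    total_px = sum(c for _, c in fibers)
    cols = math.ceil(math.sqrt(total_px))
    nrows = math.ceil(total_px / cols)
    flat_labels = np.zeros(nrows * cols, dtype=np.uint16)
    flat_intensity = np.zeros(nrows * cols, dtype=float)

    truth_rows = []
    pos = 0
    for k, (g, c) in enumerate(fibers, start=1):
        inten = intensity_means_by_group[g]
        if not noiseless:
            inten *= float(rng.normal(1.0, 0.10))
        flat_labels[pos : pos + c] = k
        flat_intensity[pos : pos + c] = inten
        truth_rows.append({"label": k, "group": g, "csa_um2": c * pa, "intensity": inten})
        pos += c

    return FiberFixture(
        labels=flat_labels.reshape(nrows, cols),
        intensity=flat_intensity.reshape(nrows, cols),
        pixel_size_nm=pixel_size_nm,
        truth=pd.DataFrame(truth_rows),
    )
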