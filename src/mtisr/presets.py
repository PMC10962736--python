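"""Documented fixture presets.

Each preset fixes a planted structure (which genes respond to stress, how
modifier-dependent each response is, which shapes satisfy the nano rule, and
so on); the seed controls only the noise realization and random placement.
The planted parameters are chosen so that every decision quantity sits at
least ~3.5 estimated-standard-errors away from the nearest classification
threshold, making recovery robust to the seed.

Expression presets
------------------
``heart_threemodel``
    Three cardiomyopathy/myopathy models over a shared 500-gene universe:

    * genes g0001-g0051: stress DEGs in all three models, strongly
      modifier-dependent everywhere (the planted core signature, 51 genes);
    * g0052-g0057: stress DEGs in all models with ~60% dependence but a
      knockout-arm fold change below the 2x gate — members of the "at least
      50% dependent" set (57 genes with the core) without meeting the strict
      significance-plus-reversion criterion;
    * g0058-g0111: stress DEGs in all models, dependence 0 (together with
      the above, 111 direction-consistent shared stress DEGs);
    * g0112-g0150: dependent DEGs in exactly two of the three models
      (13 genes per model pair, 39 total);
    * g0151-g0500: unresponsive.

``bat_coldstress``
    Brown adipose tissue under cold stress, one model, seven animals per
    arm: 11 dependent DEGs named after canonical ISR targets with planted
    dependence spanning 70-97%, 20 stress DEGs with no dependence, and 299
    unresponsive genes.

``gastroc_overlay``
    Skeletal muscle (gastrocnemius) of the G58R model over the same gene
    universe as ``heart_threemodel``: 42 planted dependent DEGs of which 32
    lie inside the heart core signature (g0001-g0032).

Mask and fiber presets
----------------------
``s59l_population``
    200 ellipses at 10 nm/px: 44 (22%) inside the nano rule (minor axis
    160-200 nm, aspect ratio <= 1.3), 100 large round profiles, and 56
    elongated tubules whose aspect ratio >= 1.7 excludes them despite a
    sometimes-small minor axis.  All planted shapes sit > 5% away from both
    rule boundaries.

``fiber_sunset``
    Ten myofibers at 500 nm/px, five aggregate-positive with planted mean
    CSA 330.0 um^2 and intensity 2712, five aggregate-negative with mean CSA
    446.9 um^2 and intensity 1000 (intensity ratio 2.712, i.e. a +171.2%
    group difference).
"""

from __future__ import annotations

import importlib.resources

import numpy as np
import pandas as pd

from .simulate import (
    FiberFixture,
    FixtureSpec,
    GenePlan,
    MaskPlan,
    generate_fiber_fixture,
    place_shapes,
)

__all__ = [
    "heart_threemodel",
    "HEART_MODELS",
    "HEART_CORE_IDS",
    "bat_coldstress",
    "BAT_ISR_GENES",
    "gastroc_overlay",
    "s59l_population",
    "fiber_sunset",
    "load_cross_species_fixture",
    "EXPRESSION_PRESETS",
]

HEART_MODELS = ("G58R", "S59L", "TfamKO")
HEART_NOISE_SD = 0.05
HEART_N_PER_ARM = 6

_N_CORE = 51
_N_NEARMISS = 6
_N_SHAREDONLY = 54
_N_PAIRWISE = 39
_N_UNIVERSE = 500

HEART_CORE_IDS = tuple(f"g{i:04d}" for i in range(1, _N_CORE + 1))


def _gid(i: int) -> str:
    return f"g{i:04d}"


def _sign(i: int) -> float:
    # ~25% of responsive genes are planted down-regulated
    return -1.0 if i % 4 == 3 else 1.0


def _heart_plan(model_idx: int) -> list[GenePlan]:
    plans = []
    for i in range(1, _N_UNIVERSE + 1):
        gid = _gid(i)
        baseline = 6.0 + (i * 29) % 50 / 10.0  # 6.0 .. 10.9 log2 units
        beta, dep = 0.0, 0.0
        if i <= _N_CORE:
            beta = _sign(i) * (1.8 + ((i * 37) % 9) / 10.0)          # |beta| 1.8-2.6
            dep = 80.0 + (i * 13 + model_idx * 5) % 18               # 80-97%
        elif i <= _N_CORE + _N_NEARMISS:
            beta = 1.30 + 0.02 * (i % 6)                             # 1.30-1.40
            dep = 60.0 + (i % 5)                                     # 60-64%
        elif i <= _N_CORE + _N_NEARMISS + _N_SHAREDONLY:
            beta = _sign(i) * (1.8 + ((i * 31) % 7) / 10.0)          # |beta| 1.8-2.4
            dep = 0.0
        elif i <= _N_CORE + _N_NEARMISS + _N_SHAREDONLY + _N_PAIRWISE:
            j = i - (_N_CORE + _N_NEARMISS + _N_SHAREDONLY) - 1      # 0..38
            skipped_model = j // 13                                  # 13 genes per pair
            if model_idx != skipped_model:
                beta = _sign(i) * (2.0 + (j % 5) / 10.0)
                dep = 85.0 + (j * 7) % 11                            # 85-95%
        plans.append(
            GenePlan(gene_id=gid, baseline=baseline, beta=beta,
                     dependence_pct=dep, noise_sd=HEART_NOISE_SD)
        )
    return plans


def heart_threemodel(seed: int = 1, noiseless: bool = False) -> FixtureSpec:
    """Three-model heart fixture (see module docstring for the planted sets)."""
    return FixtureSpec(
        models=HEART_MODELS,
        genes={m: _heart_plan(k) for k, m in enumerate(HEART_MODELS)},
        n_per_arm=HEART_N_PER_ARM,
        seed=seed,
        noiseless=noiseless,
        tissue="heart",
    )


# canonical ISR target genes used to name the planted BAT responders
BAT_ISR_GENES = (
    "Mthfd2", "Cth", "Fgf21", "Chac1", "Atf5", "Asns",
    "Trib3", "Psat1", "Phgdh", "Pck2", "Slc7a11",
)
_BAT_DEPENDENCE = (70.0, 73.0, 76.0, 79.0, 82.0, 85.0, 88.0, 91.0, 94.0, 96.0, 97.0)
BAT_N_PER_ARM = 7
BAT_NOISE_SD = 0.1


def bat_coldstress(seed: int = 1, noiseless: bool = False) -> FixtureSpec:
    """BAT cold-stress fixture: 11 dependent DEGs with dependence 70-97%."""
    plans = []
    for k, (gene, dep) in enumerate(zip(BAT_ISR_GENES, _BAT_DEPENDENCE)):
        plans.append(
            GenePlan(gene_id=gene, baseline=7.0 + 0.3 * k, beta=2.0 + 0.12 * k,
                     dependence_pct=dep, noise_sd=BAT_NOISE_SD)
        )
    for i in range(1, 21):  # stress DEGs with no modifier dependence
        plans.append(
            GenePlan(gene_id=f"b{i:04d}", baseline=6.0 + (i % 7) * 0.5,
                     beta=_sign(i) * (1.8 + (i % 8) / 10.0),
                     dependence_pct=0.0, noise_sd=BAT_NOISE_SD)
        )
    for i in range(21, 320):  # unresponsive
        plans.append(
            GenePlan(gene_id=f"b{i:04d}", baseline=6.0 + (i % 9) * 0.4,
                     beta=0.0, dependence_pct=0.0, noise_sd=BAT_NOISE_SD)
        )
    return FixtureSpec(models=("BATcold",), genes={"BATcold": plans},
                       n_per_arm=BAT_N_PER_ARM, seed=seed, noiseless=noiseless, tissue="BAT")


def gastroc_overlay(seed: int = 1, noiseless: bool = False) -> FixtureSpec:
    """Gastrocnemius fixture sharing the heart universe; 32 of the planted
    dependent DEGs lie inside the heart core signature."""
    plans = []
    for i in range(1, _N_UNIVERSE + 1):
        gid = _gid(i)
        baseline = 6.0 + (i * 23) % 50 / 10.0
        beta, dep = 0.0, 0.0
        if i <= 32:  # core-signature genes also dependent in this tissue
            beta = _sign(i) * (1.9 + ((i * 41) % 8) / 10.0)
            dep = 82.0 + (i * 11) % 15
        elif 112 <= i <= 121:  # dependent here but outside the heart core
            beta = 2.1 + (i % 4) / 10.0
            dep = 85.0 + (i % 9)
        elif 58 <= i <= 77:  # stress DEGs without dependence
            beta = _sign(i) * (1.8 + (i % 6) / 10.0)
            dep = 0.0
        plans.append(
            GenePlan(gene_id=gid, baseline=baseline, beta=beta,
                     dependence_pct=dep, noise_sd=HEART_NOISE_SD)
        )
    return FixtureSpec(models=("G58Rgastroc",), genes={"G58Rgastroc": plans},
                       n_per_arm=HEART_N_PER_ARM, seed=seed, noiseless=noiseless,
                       tissue="gastrocnemius")


EXPRESSION_PRESETS = {
    "heart_threemodel": heart_threemodel,
    "bat_coldstress": bat_coldstress,
    "gastroc_overlay": gastroc_overlay,
}


def s59l_population(seed: int = 1) -> MaskPlan:
    """Mask plan with 22% of 200 planted ellipses inside the nano rule."""
    rng = np.random.default_rng(seed)
    axes: list[tuple[float, float]] = []
    for _ in range(44):   # nano: minor 160-200 nm at 10 nm/px, AR 1.05-1.3
        b = rng.uniform(8.0, 10.0)
        axes.append((b * rng.uniform(1.05, 1.3), b))
    for _ in range(100):  # large round profiles: minor >= 300 nm
        b = rng.uniform(15.0, 24.0)
        axes.append((b * rng.uniform(1.05, 1.35), b))
    for _ in range(56):   # elongated tubules: AR >= 1.7 fails the nano rule
        b = rng.uniform(9.0, 14.0)
        axes.append((b * rng.uniform(1.7, 2.8), b))
    return place_shapes(axes, image_shape=(1600, 1600), pixel_size_nm=10.0, seed=seed)


def fiber_sunset(seed: int = 1, noiseless: bool = True) -> FiberFixture:
    """Myofiber fixture with planted group CSAs 330.0 / 446.9 um^2 and a
    planted 2.712x intensity ratio (a +171.2% group difference)."""
    return generate_fiber_fixture(
        n_fibers={"ub_pos": 5, "ub_neg": 5},
        csa_means_by_group={"ub_pos": 330.0, "ub_neg": 446.9},
        intensity_means_by_group={"ub_pos": 2712.0, "ub_neg": 1000.0},
        seed=seed,
        pixel_size_nm=500.0,
        noiseless=noiseless,
    )


def load_cross_species_fixture() -> tuple[pd.DataFrame, pd.DataFrame]:
    """Load the shipped synthetic ortholog map and three-study fold-change table.

    Both tables are synthetic stand-ins keyed to the heart core-signature
    gene ids: 49 of the 51 core genes carry a human ortholog (two are left
    unmapped on purpose), and exactly 11 orthologs have an arithmetic mean
    linear fold change >= 2 across the three study columns — including one
    averaged over two studies only and one sitting exactly at 2.0.
    """
    data = importlib.resources.files("mtisr.data")
    with (data / "ortholog_map_synthetic.tsv").open() as fh:
        orth = pd.read_csv(fh, sep="\t", comment="#")
    with (data / "human_study_fc_synthetic.tsv").open() as fh:
        fc = pd.read_csv(fh, sep="\t", comment="#")
    return orth, fc
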