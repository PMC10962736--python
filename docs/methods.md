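# Methods

## Statistical model

Expression is analyzed on the log2 scale, gene by gene. A two-group
comparison uses the two-tailed Student t-test with pooled variance:

    t = (x̄_a − x̄_b) / (s_p · sqrt(1/n_a + 1/n_b)),   df = n_a + n_b − 2,

with `s_p²` the pooled sample variance. Multiple testing is corrected per
contrast over all genes with the Benjamini–Hochberg step-up adjustment
(`statsmodels` implementation; no independent filtering). A gene is a DEG
when |log2FC| ≥ log2(fc_threshold) and q ≤ fdr_threshold; defaults are a
2-fold change and a 5% FDR, both bounds inclusive (a `strict` flag switches
to strict inequalities). The fold-change gate is deliberately two-sided on
the magnitude — "at least 2-fold up or down".

Degenerate variance is resolved deterministically rather than propagating
NaNs: equal means with zero pooled variance give t = 0, p = 1; unequal means
with zero pooled variance give p = 0 with a `DegenerateVarianceWarning`.
The latter arises routinely when noiseless synthetic fixtures are pushed
through the test, which is intended usage.

## Dependence classification

Each model contributes two contrasts: stress (stress/modifier+ vs control)
and KO (stress/modifierKO vs stress/modifier+). A stress DEG is
modifier-dependent iff the KO contrast passes the *same* fold-change and FDR
gates and its fold change has the opposite sign — i.e. knockout reverts the
stress response toward control. A significant co-directional KO change
(amplification) is explicitly not dependence.

Percent dependence is reported for every stress DEG regardless of the
dependence call:

* **log2 definition (default):** `100 · (−lfc_ko) / lfc_stress`. Full
  reversion to the control mean gives exactly 100% for any effect size;
  values are not clamped, so overshoot (> 100%) and co-directional change
  (< 0%) are visible in the output.
* **linear definition:** the percent change of the KO arm vs the stress arm
  divided by the percent change of stress vs control, on linear fold
  changes, sign-arranged as
  `100 · 2^lfc_stress · (1 − 2^lfc_ko) / (2^lfc_stress − 1)` so that full
  reversion of an up- or down-regulated gene also evaluates to 100%.

The log2 form is the default because a ratio of raw percent changes has
different denominators in its two halves and does not in general equal 100%
at full reversion; the log2 ratio is the quantity with the intended fixed
points (0% = no reversion, 100% = full reversion). The definition is a flag
(`pct_definition`) everywhere it matters, and dependence *classification*
never depends on it. Genes with a zero stress fold change have undefined
dependence and carry NaN.

The alternative ≥ 50%-dependence set applies an inclusive cutoff to the
measured percent dependence of the shared stress DEGs in every model; by
construction it is a superset of the strict core signature whenever core
genes are strongly dependent.

## Signatures and overlaps

Shared stress DEGs across n ≥ 2 models require DEG status in every model
and, by default, a consistent direction (disable with a flag). The core
signature is the set dependent in all n models; "additional" k-of-n sets
count genes dependent in *exactly* k models and therefore exclude the core.
Cross-tissue overlap is a plain intersection with the other tissue's
dependent set, reported with counts and percent. Cross-species overlap maps
signature genes through a user-supplied one-to-one ortholog table and keeps
genes whose mean *linear* fold change across study columns is ≥ 2
(arithmetic mean by default — "averaged" — geometric by flag; inclusive
bound). Genes absent from some studies are averaged over the available ones
and flagged rather than dropped, preserving auditability across platforms;
unmapped genes are excluded and counted. Set outputs are serialized in
lexicographic order.

## Morphometry conventions

Masks are 2-D integer label images (0 = background) with a required
physical pixel size in nm. Area is the member-pixel count times the pixel
area, with no sub-pixel boundary correction; the per-image sum of label
areas therefore equals the nonzero-pixel count times the pixel area exactly.
Axis lengths use the equivalent-ellipse convention: full axis =
4·sqrt(eigenvalue) of the 2×2 second-central-moment matrix of member pixel
coordinates (the standard region-properties convention, computed via
scikit-image). The planted-truth generators use the same convention, and on
rasterized ellipses with minor semi-axis ≥ 8 px the recovered axes agree
with the planted ones to well under 2%.

The nano-mitochondrion rule is `minor axis < 250 nm AND aspect ratio <
1.5`, both strict. Labels under 4 pixels are flagged degenerate (axes
reported but unreliable). Label ids split into several 8-connected
components are logged, not rejected. Manual ultrastructure classes
(cristal inclusions, electrolucent matrix, etc.) are consumed as annotation
tables and tabulated as frequencies; no image-based detection is attempted.

Myofiber quantification reports per-fiber cross-sectional area in µm² and
the mean of a paired intensity image over member pixels. The group percent
difference is `100·(mean_pos − mean_neg)/mean_neg`, NaN-flagged when a
group is empty or the denominator is zero.

## Synthetic-data generators

The expression generator plants, per gene and model, a baseline `mu`, a
stress effect `beta` (log2), and a dependence fraction `d`; arm means are
`mu`, `mu + beta`, and `mu + beta·(1 − d/100)`, with i.i.d. Gaussian noise
of per-gene sd on the log2 scale (zero in noiseless mode) — exactly the
model under which the pooled t-test is the correct analysis. Truth tables
are computed from planted means and the configured thresholds, never from
the noisy realization. Identical spec + seed reproduce outputs bitwise.

Preset design: planted effects sit ≥ ~3.5 estimated standard errors from
every decision boundary (DEG gate, KO gate, 50% cutoff), so recovery is
robust to the seed. Replicate counts per arm are 7 for the brown-adipose
preset and 6 for the heart/muscle presets; 6 is a package default documented
here as such, chosen as a typical microarray group size. Per-gene noise is
0.05–0.1 log2 units, small relative to the planted effects by design —
these fixtures verify decision logic, not power. The planted set sizes of
`heart_threemodel` (111 shared DEGs; 51-gene core; 39 genes in exactly two
models; 57 genes at ≥ 50% dependence, including 6 that pass the 50% rule
while their KO fold change stays below the 2× gate), `bat_coldstress`
(11 dependent DEGs, dependence 70–97%), and `gastroc_overlay` (32 of the
core inside the muscle dependent set) mirror the reported biology of the
mt-ISR models these fixtures emulate, so end-to-end recovery doubles as a
worked reproduction at desk scale.

The mask generator rasterizes planted ellipses (scikit-image pixel-center
rasterization) after rejection-sampling centers against bounding-circle
overlap with a one-pixel margin, largest-first in a deterministic order
under the seed; retry exhaustion raises a placement error. The
`s59l_population` preset plants 200 profiles of which exactly 22% satisfy
the nano rule, all > 5% clear of both rule boundaries. The fiber generator
tessellates the image into contiguous pixel runs with per-fiber counts
constrained to sum to `round(n · mean_CSA / pixel_area)`, so group mean
CSAs are exact in noiseless mode whenever representable on the pixel grid
(the shipped preset — 330.0 and 446.9 µm² at 0.25 µm²/px, five fibers per
group — is exact); run-length tiling was chosen over an organic-looking
partition because exact planted-area control is the point and geometric
realism is a non-goal. Planted intensities are uniform within a fiber; the
shipped 2.712× group ratio yields a +171.2% group difference.

What the fixtures do **not** emulate: probe-level microarray artifacts and
normalization, heavy-tailed or correlated replicate noise, batch structure,
image noise/texture, or realistic organelle shape diversity. Passing tests
therefore demonstrate correctness of the decision rules and statistics under
the stated noise model, not robustness to real-data pathologies.

The shipped ortholog map and three-study fold-change table
(`src/mtisr/data/*_synthetic.tsv`) are synthetic stand-ins keyed to the
fixture gene universe: 49 of the 51 core genes are mapped (two deliberately
unmapped), and exactly 11 orthologs — including one covered by only two
studies and one sitting exactly at the inclusive 2.0 bound — pass the
mean-fold-change filter.

## Numerical choices and edge cases

* BH q-values come from `statsmodels.stats.multitest.multipletests`; the
  test suite checks them against a hand-written step-up oracle and the
  classic rejection-set equivalence on 1000 random p-vectors.
* Contrasts are vectorized across genes; t p-values use the exact t
  distribution survival function.
* Threshold comparisons are inclusive everywhere a quantity is defined as
  "at least"; the nano rule is strict on both boundaries.
* Heterozygous modifier animals are pooled with wildtype into the "+" arm
  via the sample sheet's `arm` column; nothing is hard-coded.
* Pipeline runs are deterministic: a single seed feeds every random draw,
  outputs embed a config hash, and reruns are byte-identical.

## Known limitations

* No moderated (empirical-Bayes) variance estimation, batch correction, or
  normalization — inputs are assumed normalized log2 matrices.
* Dependence is a two-contrast intersection, not an interaction-term linear
  model or causal mediation analysis.
* Morphometry is 2-D single-section; no serial-section reconstruction.
* Segmentation itself is upstream and out of scope; the package consumes
  label masks.
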